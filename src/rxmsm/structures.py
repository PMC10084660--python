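"""Multi-state structures over medication cycles and their transition data.

Seven nested structures of increasing complexity are supported:

* ``A`` — single-event survival: start -> cycle1.
* ``B`` — competing risks: start -> {cycle1, death}.
* ``C`` — three-state illness–death: B plus cycle1 -> death.
* ``D`` — four-state unidirectional: C plus cycle1 -> disc1 -> death.
* ``E`` — four-state bidirectional: a single cycle state and a single
  discontinuation state with a back-transition disc -> cycle.
* ``F`` — recurrent chain: cycle_1 .. cycle_K and disc_1 .. disc_{K-1},
  every non-absorbing state -> death; subjects entering cycle_K are
  treated as chronic users (only exit: death).
* ``G`` — same graph as F plus shared-parameter constraint tags: all
  cycle_k -> death transitions share one parameter vector, likewise all
  disc_k -> death; cycle_k -> disc_k (k = 1..K-1) share a common baseline
  shape and covariate effects with transition-specific proportionality
  intercepts, likewise disc_k -> cycle_{k+1}.

``episodes_to_transition_data`` expands derived episode timelines into
long-format rows (one row per visited state and allowed exit) under a
clock-reset, clock-forward or mixed timescale, with times in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cycles import DAYS_PER_YEAR, EpisodeTimeline, state_kind, episode_order

START, DEATH = "start", "death"

STRUCTURE_IDS = ("A", "B", "C", "D", "E", "F", "G")


def _cyc(k: int) -> str:
    return f"cycle{k}"


def _dsc(k: int) -> str:
    return f"disc{k}"


@dataclass(frozen=True)
class StructureSpec:
    structure_id: str
    states: tuple[str, ...]
    transitions: tuple[tuple[str, str, str], ...]  # (from, to, transition_id)
    absorbing: frozenset[str]
    k_cap: int | None = None
    # constraint group -> {"kind": "shared"|"proportional", "transitions": [...]}
    constraint_groups: dict[str, dict] = field(default_factory=dict)

    def out_transitions(self, state: str) -> list[tuple[str, str, str]]:
        return [t for t in self.transitions if t[0] == state]

    @property
    def transition_ids(self) -> tuple[str, ...]:
        return tuple(t[2] for t in self.transitions)

    def to_adjacency(self) -> dict:
        adj: dict[str, list] = {s: [] for s in self.states}
        for frm, to, tid in self.transitions:
            adj[frm].append({"to": to, "transition_id": tid})
        return adj


def make_structure(structure_id: str, k_cap: int = 6) -> StructureSpec:
    """Build the state graph (and, for G, constraint tags) of one structure."""
    sid = structure_id.upper()
    t = lambda a, b: (a, b, f"{a}-{b}")

    if sid == "A":
        return StructureSpec("A", (START, _cyc(1)), (t(START, _cyc(1)),),
                             frozenset({_cyc(1)}))
    if sid == "B":
        return StructureSpec(
            "B", (START, _cyc(1), DEATH),
            (t(START, _cyc(1)), t(START, DEATH)),
            frozenset({_cyc(1), DEATH}),
        )
    if sid == "C":
        return StructureSpec(
            "C", (START, _cyc(1), DEATH),
            (t(START, _cyc(1)), t(START, DEATH), t(_cyc(1), DEATH)),
            frozenset({DEATH}),
        )
    if sid == "D":
        return StructureSpec(
            "D", (START, _cyc(1), _dsc(1), DEATH),
            (t(START, _cyc(1)), t(START, DEATH), t(_cyc(1), _dsc(1)),
             t(_cyc(1), DEATH), t(_dsc(1), DEATH)),
            frozenset({DEATH}),
        )
    if sid == "E":
        return StructureSpec(
            "E", (START, "cycle", "disc", DEATH),
            (t(START, "cycle"), t(START, DEATH), t("cycle", "disc"),
             t("cycle", DEATH), t("disc", "cycle"), t("disc", DEATH)),
            frozenset({DEATH}),
        )
    if sid in ("F", "G"):
        states = [START] + [_cyc(k) for k in range(1, k_cap + 1)] \
            + [_dsc(k) for k in range(1, k_cap)] + [DEATH]
        trans = [t(START, _cyc(1)), t(START, DEATH)]
        for k in range(1, k_cap):
            trans += [t(_cyc(k), _dsc(k)), t(_cyc(k), DEATH)]
            trans += [t(_dsc(k), _cyc(k + 1)), t(_dsc(k), DEATH)]
        trans.append(t(_cyc(k_cap), DEATH))
        groups = {}
        if sid == "G":
            groups = {
                "cycle-death": {
                    "kind": "shared",
                    "transitions": [f"{_cyc(k)}-{DEATH}" for k in range(1, k_cap + 1)],
                },
                "disc-death": {
                    "kind": "shared",
                    "transitions": [f"{_dsc(k)}-{DEATH}" for k in range(1, k_cap)],
                },
                "cycle-disc": {
                    "kind": "proportional",
                    "transitions": [f"{_cyc(k)}-{_dsc(k)}" for k in range(1, k_cap)],
                },
                "disc-cycle": {
                    "kind": "proportional",
                    "transitions": [f"{_dsc(k)}-{_cyc(k + 1)}" for k in range(1, k_cap)],
                },
            }
        return StructureSpec(sid, tuple(states), tuple(trans), frozenset({DEATH}),
                             k_cap=k_cap, constraint_groups=groups)
    raise ValueError(f"unknown structure id: {structure_id!r}")


# ---------------------------------------------------------------------------
# Clock specification


@dataclass(frozen=True)
class ClockSpec:
    """Timescale convention: 'reset', 'forward', or 'mix'.

    Under 'mix', transitions into the death state run on the forward
    clock (time since start of follow-up, with state-entry time as left
    truncation) and all others on the reset clock (time since state
    entry).
    """

    mode: str = "reset"

    def __post_init__(self):
        if self.mode not in ("reset", "forward", "mix"):
            raise ValueError(f"unknown clock mode: {self.mode!r}")

    def is_forward(self, to_state: str) -> bool:
        if self.mode == "forward":
            return True
        if self.mode == "mix":
            return to_state == DEATH
        return False


# ---------------------------------------------------------------------------
# Visit extraction: structure-specific interpretation of a timeline


def _timeline_visits(tl: EpisodeTimeline, subject, structure: StructureSpec,
                     censor_disc1_at_reentry: bool = False):
    """List of (state, start_day, end_day, next_state-or-None) per subject.

    ``next_state`` is the structure state actually entered at ``end_day``
    (``'death'`` included); ``None`` means censored there.  Interprets the
    raw episode sequence according to the structure's semantics: which
    visits are tracked, where tracking stops, and the chronic-user merge
    for F/G.
    """
    sid = structure.structure_id
    t_exit = float(subject.t_exit_days)
    died = subject.exit_reason == "death"
    eps = tl.episodes
    death_or_none = DEATH if died else None

    # entry day of the first cycle, if any
    first_cycle_start = None
    for e in eps:
        if state_kind(e.state_label) == "cycle":
            first_cycle_start = e.start_day
            break

    visits = []
    if sid == "A":
        # death is not modelled: treated as censoring
        end = first_cycle_start if first_cycle_start is not None else t_exit
        nxt = _cyc(1) if first_cycle_start is not None else None
        visits.append((START, 0.0, end, nxt))
        return visits

    if sid in ("B", "C"):
        if first_cycle_start is not None:
            visits.append((START, 0.0, first_cycle_start, _cyc(1)))
            if sid == "C":
                visits.append((_cyc(1), first_cycle_start, t_exit, death_or_none))
        else:
            visits.append((START, 0.0, t_exit, death_or_none))
        return visits

    if sid == "D":
        if first_cycle_start is None:
            visits.append((START, 0.0, t_exit, death_or_none))
            return visits
        visits.append((START, 0.0, first_cycle_start, _cyc(1)))
        cyc1 = next(e for e in eps if state_kind(e.state_label) == "cycle")
        if cyc1.end_day >= t_exit:
            visits.append((_cyc(1), cyc1.start_day, t_exit, death_or_none))
            return visits
        visits.append((_cyc(1), cyc1.start_day, cyc1.end_day, _dsc(1)))
        if censor_disc1_at_reentry:
            reentry = next(
                (e.start_day for e in eps
                 if state_kind(e.state_label) == "cycle" and episode_order(e.state_label) == 2),
                None,
            )
            end = reentry if reentry is not None else t_exit
            visits.append((_dsc(1), cyc1.end_day, end, death_or_none if end == t_exit else None))
        else:
            # default: disc1 = "ever exited the 1st cycle and still alive";
            # later cycles do not interrupt the visit
            visits.append((_dsc(1), cyc1.end_day, t_exit, death_or_none))
        return visits

    # E, F, G: walk the full alternating episode sequence
    k_cap = structure.k_cap if sid in ("F", "G") else None
    for i, e in enumerate(eps):
        kind = state_kind(e.state_label)
        k = episode_order(e.state_label)
        if kind == "pre":
            state = START
        elif kind == "cycle":
            state = "cycle" if sid == "E" else _cyc(min(k, k_cap))
        else:
            state = "disc" if sid == "E" else _dsc(k)

        if sid in ("F", "G") and kind == "cycle" and k >= k_cap:
            # chronic-user cap: merge everything from entry into cycle_K
            visits.append((state, e.start_day, t_exit, death_or_none))
            break
        last = i == len(eps) - 1
        if last:
            visits.append((state, e.start_day, e.end_day, death_or_none))
        else:
            nxt_e = eps[i + 1]
            nk = state_kind(nxt_e.state_label)
            nkk = episode_order(nxt_e.state_label)
            if nk == "cycle":
                nxt = "cycle" if sid == "E" else _cyc(min(nkk, k_cap))
            else:
                nxt = "disc" if sid == "E" else _dsc(nkk)
            visits.append((state, e.start_day, e.end_day, nxt))
    return visits


def episodes_to_transition_data(
    timelines: list[EpisodeTimeline],
    subjects: pd.DataFrame,
    structure: StructureSpec,
    clock: ClockSpec = ClockSpec("reset"),
    censor_disc1_at_reentry: bool = False,
) -> pd.DataFrame:
    """Expand timelines into long-format transition rows.

    One row per (subject, visited non-absorbing state, allowed exit
    transition); ``event`` is 1 for the transition actually taken and 0
    for competing exits and censoring.  Times are in years on the
    transition's timescale: reset rows have ``t_entry = 0`` and
    ``t_exit`` equal to the sojourn; forward rows carry the state-entry
    time as left truncation.  Zero-length visits are dropped (counted in
    the log).
    """
    subj_by_id = {row.subject_id: row for row in subjects.itertuples(index=False)}
    rows = []
    n_dropped = 0
    for tl in timelines:
        subject = subj_by_id[tl.subject_id]
        visits = _timeline_visits(tl, subject, structure, censor_disc1_at_reentry)
        for visit_id, (state, a, b, nxt) in enumerate(visits):
            if state in structure.absorbing:
                continue
            if b <= a:
                n_dropped += 1
                continue
            for frm, to, tid in structure.out_transitions(state):
                if clock.is_forward(to):
                    t0, t1 = a / DAYS_PER_YEAR, b / DAYS_PER_YEAR
                else:
                    t0, t1 = 0.0, (b - a) / DAYS_PER_YEAR
                rows.append((
                    tl.subject_id, visit_id, frm, to, tid, t0, t1,
                    int(nxt == to), subject.case_status, subject.age_group,
                ))
    if n_dropped:
        import logging
        logging.getLogger(__name__).info("dropped %d zero-length visits", n_dropped)
    return pd.DataFrame(
        rows,
        columns=["subject_id", "visit_id", "from_state", "to_state", "transition_id",
                 "t_entry", "t_exit", "event", "case_status", "age_group"],
    )


def validate_transition_data(rows: pd.DataFrame, structure: StructureSpec) -> dict:
    """Structural checks on a long-format transition dataset.

    Verifies, per visited state: row count equals the state's out-degree
    and at most one event per visit; and that every row has
    ``t_exit > t_entry >= 0``.  Returns a machine-readable report with a
    (possibly empty) failure list.
    """
    failures = []
    out_degree = {s: len(structure.out_transitions(s)) for s in structure.states}
    bad_time = rows[(rows["t_exit"] <= rows["t_entry"]) | (rows["t_entry"] < 0)]
    for idx in bad_time.index:
        failures.append({"check": "time_order", "row": int(idx)})
    grouped = rows.groupby(["subject_id", "visit_id", "from_state"], sort=False)
    counts = grouped.size()
    events = grouped["event"].sum()
    for (sid, vid, frm), n in counts.items():
        if n != out_degree[frm]:
            failures.append({
                "check": "row_count", "subject_id": int(sid), "visit_id": int(vid),
                "from_state": frm, "n_rows": int(n), "out_degree": out_degree[frm],
            })
    for (sid, vid, frm), ev in events.items():
        if ev > 1:
            failures.append({
                "check": "event_sum", "subject_id": int(sid), "visit_id": int(vid),
                "from_state": frm, "n_events": int(ev),
            })
    return {
        "n_rows": int(len(rows)),
        "n_visits": int(len(counts)),
        "events_by_transition": {
            tid: int(v) for tid, v in rows.groupby("transition_id")["event"].sum().items()
        },
        "failures": failures,
        "ok": not failures,
    }
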