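"""Config-driven end-to-end analysis runs.

One run executes: generate (or load) registry -> washout -> episode
derivation per gap threshold -> structure expansion -> transition-model
fitting -> microsimulation prediction, writing machine-readable outputs
(CSV/JSON) and a manifest.  Sensitivity analyses sweep the gap threshold
(90/120/150 days, i.e. 3/4/5-month cycle definitions) and the timescale
convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cycles import apply_washout, derive_timelines, summarize_episodes, timelines_to_frame
from .fpsm import FPSMFit, ModelSpec, fit_constrained, fit_transition
from .predict import PredictionRequest, simulate_msm
from .structures import (
    ClockSpec,
    StructureSpec,
    episodes_to_transition_data,
    make_structure,
    validate_transition_data,
)
from .synthetic import CASE, COMPARATOR, GeneratorConfig, generate_registry, read_registry, write_registry

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    structures: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G")
    clock: str = "reset"
    gap_days: tuple[int, ...] = (90, 120, 150)
    washout_days: int = 365
    baseline_df: int = 4
    td_df: int = 3
    include_age: bool = True
    include_interactions: bool = True
    age_group: str = "60-69"
    time_grid: tuple[float, ...] = tuple(np.round(np.linspace(0.05, 6.0, 60), 4))
    n_sim: int = 100_000
    k_cap: int = 6
    seed: int = 0
    generator: GeneratorConfig | None = None
    registry_dir: str | None = None

    def __post_init__(self):
        if not self.structures:
            raise ValueError("at least one structure required")
        if not self.gap_days:
            raise ValueError("gap_days must be non-empty")
        if self.generator is None and self.registry_dir is None:
            self.generator = GeneratorConfig(n_cases=500, seed=self.seed)

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_from_yaml(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gen = raw.pop("generator", None)
    cfg = PipelineConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()},
                         generator=GeneratorConfig(**gen) if gen else None)
    return cfg


# ---------------------------------------------------------------------------
# Transition-model fitting policy


def _wants_td(transition_id: str, to_state: str) -> bool:
    """Time-dependent case effects: transitions into a discontinuation
    state, plus start -> death (the emulated-bidirectional structure is
    handled separately in its joint fit)."""
    return to_state.startswith("disc") or transition_id == "start-death"


def fit_structure(rows: pd.DataFrame, structure: StructureSpec,
                  base_spec: ModelSpec) -> dict[str, FPSMFit]:
    """Fit every transition of a structure (jointly for G, else per
    transition), degrading the spline df when events are too few and
    substituting a near-zero exponential hazard for event-free
    transitions."""
    if structure.constraint_groups:
        last_err = None
        for df in range(base_spec.baseline_df, 0, -1):
            try:
                joint = fit_constrained(rows, structure, replace(base_spec, baseline_df=df))
                return joint.fits
            except ValueError as err:
                last_err = err
                logger.info("constrained fit df=%d failed (%s); degrading", df, err)
        raise ValueError(f"constrained fit failed at every df: {last_err}")

    fits: dict[str, FPSMFit] = {}
    for frm, to, tid in structure.transitions:
        sub = rows[rows["transition_id"] == tid]
        n_events = int(sub["event"].sum()) if len(sub) else 0
        if n_events == 0:
            logger.warning("%s: no events; substituting near-zero hazard", tid)
            fits[tid] = FPSMFit.from_constant(tid, rate=1e-10)
            continue
        td = base_spec.td_df if _wants_td(tid, to) else 0
        spec = replace(base_spec, td_df=td)
        fits[tid] = _fit_with_fallback(sub, spec, tid)
    return fits


def _fit_with_fallback(sub: pd.DataFrame, spec: ModelSpec, tid: str) -> FPSMFit:
    n_events = int(sub["event"].sum())
    if n_events < 10:
        return _exponential_fit(sub, tid)
    for df in range(spec.baseline_df, 0, -1):
        for td in sorted({min(spec.td_df, df), 0}, reverse=True):
            if n_events < 5 * (df + td):
                continue  # too few events for this flexibility
            try:
                return fit_transition(sub, replace(spec, baseline_df=df, td_df=td),
                                      transition_id=tid)
            except ValueError as err:
                logger.info("%s: df=%d td=%d failed (%s); degrading", tid, df, td, err)
    return _exponential_fit(sub, tid)


def _exponential_fit(sub: pd.DataFrame, tid: str) -> FPSMFit:
    """Closed-form constant-hazard MLE (rate = events / exposure) for
    transitions too sparse for any spline fit."""
    d = float(sub["event"].sum())
    exposure = float((sub["t_exit"] - sub["t_entry"]).sum())
    rate = max(d, 0.5) / max(exposure, 1e-12)
    logger.warning("%s: %d event(s); falling back to exponential rate %.3g/yr",
                   tid, int(d), rate)
    fit = FPSMFit.from_constant(tid, rate)
    fit.n, fit.n_events = len(sub), int(d)
    # delta-method variance of log rate; shape pinned at 1
    fit.vcov = np.array([[1.0 / max(d, 0.5), 0.0], [0.0, 0.0]])
    return fit


# ---------------------------------------------------------------------------
# End-to-end run


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the full analysis chain; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "versions": _versions(),
        "stages": {},
        "files": [],
        "counts": {},
    }
    t_start = time.perf_counter()

    def stage(name):
        manifest["stages"][name] = round(time.perf_counter() - t_start, 3)

    # 1. registry
    if config.registry_dir is not None:
        subjects, prescriptions = read_registry(config.registry_dir)
    else:
        subjects, prescriptions, _ = generate_registry(config.generator)
    paths = write_registry(subjects, prescriptions, outdir)
    manifest["files"] += [p.name for p in paths.values()]
    manifest["counts"]["subjects"] = int(len(subjects))
    manifest["counts"]["prescriptions"] = int(len(prescriptions))
    stage("registry")

    # 2. washout
    eligible, prescriptions = apply_washout(subjects, prescriptions, config.washout_days)
    subjects = subjects[subjects["subject_id"].map(eligible)].reset_index(drop=True)
    prescriptions = prescriptions[prescriptions["subject_id"].isin(subjects["subject_id"])]
    manifest["counts"]["eligible_subjects"] = int(len(subjects))
    stage("washout")

    clock = ClockSpec(config.clock)
    base_spec = ModelSpec(
        baseline_df=config.baseline_df, td_df=config.td_df,
        include_age=config.include_age, include_interactions=config.include_interactions,
    )
    grid = np.asarray(config.time_grid)

    for gap in config.gap_days:
        timelines = derive_timelines(subjects, prescriptions, gap_days=gap)
        ep_name = f"episodes_gap{gap}.csv"
        timelines_to_frame(timelines).to_csv(outdir / ep_name, index=False)
        summary = summarize_episodes(timelines)
        (outdir / f"episode_summary_gap{gap}.json").write_text(
            json.dumps(summary.to_dict(), indent=1))
        manifest["files"] += [ep_name, f"episode_summary_gap{gap}.json"]
        manifest["counts"][f"episodes_gap{gap}"] = int(
            sum(len(tl.episodes) for tl in timelines))
        stage(f"derive_gap{gap}")

        for sid in config.structures:
            structure = make_structure(sid, k_cap=config.k_cap)
            rows = episodes_to_transition_data(timelines, subjects, structure, clock)
            report = validate_transition_data(rows, structure)
            if not report["ok"]:
                raise RuntimeError(
                    f"structure {sid}, gap {gap}: transition data invalid: "
                    f"{report['failures'][:3]}")
            tr_name = f"transitions_{sid}_gap{gap}_{config.clock}.csv"
            rows.to_csv(outdir / tr_name, index=False)
            manifest["files"].append(tr_name)
            manifest["counts"][f"rows_{sid}_gap{gap}"] = int(len(rows))
            manifest["counts"][f"events_{sid}_gap{gap}"] = report["events_by_transition"]

            fits = fit_structure(rows, structure, base_spec)
            fits_name = f"fits_{sid}_gap{gap}_{config.clock}.json"
            (outdir / fits_name).write_text(
                json.dumps({tid: f.to_dict() for tid, f in fits.items()}, indent=1))
            manifest["files"].append(fits_name)
            stage(f"fit_{sid}_gap{gap}")

            frames = []
            for case_status in (COMPARATOR, CASE):
                request = PredictionRequest(
                    time_grid=grid, case_status=case_status, age_group=config.age_group,
                    n_sim=config.n_sim, seed=_derive_seed(config.seed, sid, gap, case_status),
                )
                result = simulate_msm(fits, structure, clock, request)
                _check_prediction(result)
                frame = result.to_frame()
                frame.insert(0, "case_status", case_status)
                agg = pd.DataFrame({
                    "case_status": case_status, "time": result.time_grid,
                    "state": "any_cycle", "probability": result.in_cycle,
                    "se": result.in_cycle_se, "length_of_stay": result.in_cycle_los,
                    "ever_visit": np.nan, "lci": np.nan, "uci": np.nan,
                })
                frames.append(pd.concat([frame, agg], ignore_index=True))
            pred_name = f"predictions_{sid}_gap{gap}_{config.clock}.csv"
            pd.concat(frames, ignore_index=True).to_csv(outdir / pred_name, index=False)
            manifest["files"].append(pred_name)
            stage(f"predict_{sid}_gap{gap}")

    manifest["total_seconds"] = round(time.perf_counter() - t_start, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def _derive_seed(seed: int, sid: str, gap: int, case_status: str) -> int:
    digest = hashlib.sha256(f"{seed}|{sid}|{gap}|{case_status}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _check_prediction(result) -> None:
    """In-run invariant checks on every prediction."""
    total = result.occupancy.sum(axis=0)
    if not np.allclose(total, 1.0, atol=1e-12):
        raise RuntimeError("occupation probabilities do not sum to 1")
    if "death" in result.states:
        dead = result.occupancy[result.states.index("death")]
        if np.any(np.diff(dead) < 0):
            raise RuntimeError("death occupancy decreased")


def _versions() -> dict:
    import scipy
    return {
        "rxmsm": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


# ---------------------------------------------------------------------------
# Run comparison (sensitivity analyses)


def compare_runs(outdirs: list, structure_id: str, gap: int | None = None,
                 clock: str | None = None, case_status: str = CASE) -> pd.DataFrame:
    """Align P(in any medication cycle) curves across completed runs.

    Reads each run's prediction CSV for ``structure_id`` (any gap/clock
    when unspecified, provided it is unique in the run) and returns a
    wide table of curves plus the maximum pairwise discrepancy.
    """
    curves = {}
    for d in outdirs:
        d = Path(d)
        pattern = f"predictions_{structure_id}_gap{gap or '*'}_{clock or '*'}.csv"
        matches = sorted(d.glob(pattern))
        if len(matches) != 1:
            raise ValueError(f"{d}: expected one match for {pattern}, got {len(matches)}")
        df = pd.read_csv(matches[0])
        sel = df[(df["state"] == "any_cycle") & (df["case_status"] == case_status)]
        curves[str(d)] = sel.set_index("time")["probability"]
    table = pd.DataFrame(curves)
    if table.isna().any().any():
        raise ValueError("runs have mismatched time grids")
    cols = list(table.columns)
    max_disc = 0.0
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            max_disc = max(max_disc, float((table[cols[i]] - table[cols[j]]).abs().max()))
    table.attrs["max_discrepancy"] = max_disc
    return table
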