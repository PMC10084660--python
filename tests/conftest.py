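import numpy as np
import pytest

import rxmsm
from rxmsm import GeneratorConfig


@pytest.fixture(scope="session")
def default_registry():
    """A moderately sized synthetic registry shared across tests."""
    cfg = GeneratorConfig(n_cases=300, seed=42)
    subjects, prescriptions, timelines = rxmsm.generate_registry(cfg)
    return cfg, subjects, prescriptions, timelines


@pytest.fixture(scope="session")
def derived_timelines(default_registry):
    _, subjects, prescriptions, _ = default_registry
    eligible, rx = rxmsm.apply_washout(subjects, prescriptions)
    keep = subjects[subjects["subject_id"].map(eligible)].reset_index(drop=True)
    return keep, rxmsm.derive_timelines(keep, rx)


def random_registry(rng, max_rx=20, horizon=2000):
    """One random toy subject: (t_exit, rx_days, supplies)."""
    t_exit = int(rng.integers(30, horizon))
    n_rx = int(rng.integers(0, max_rx + 1))
    days = np.sort(rng.integers(0, t_exit, size=n_rx))
    supplies = rng.integers(1, 400, size=n_rx)
    return t_exit, days, supplies
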