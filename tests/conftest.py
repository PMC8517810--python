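import numpy as np
import pytest

from stepop.pipeline import run_all, small_config
from stepop.synthetic import SimConfig, simulate_record


@pytest.fixture(scope="session")
def clean_record():
    """One noise-free-ish record with a single scheduled dip."""
    cfg = SimConfig(
        n_patients=1,
        duration_s=1200.0,
        event_schedule=((700.0, 120.0, 55.0),),
        noise_sd=1.0,
        artifact_rate=0.0,
        seed=3,
    )
    record, truth = simulate_record(cfg, 0)
    return cfg, record, truth


@pytest.fixture(scope="session")
def learnable_run(tmp_path_factory):
    """One full pipeline run on the default desk-scale learnable cohort.

    Shared across the end-to-end tests so the expensive training happens
    exactly once per session.
    """
    run_dir = tmp_path_factory.mktemp("learnable") / "run"
    result = run_all(small_config(seed=1), run_dir)
    return result


def random_pulse_segment(rng: np.random.Generator, n: int = 2000, fs: int = 100) -> np.ndarray:
    """A clean synthetic pulse train within QC limits (helper, not a fixture)."""
    hr = rng.uniform(50, 140)
    t = np.arange(n) / fs
    base = rng.uniform(70, 110)
    pp = rng.uniform(30, 60)
    return base + pp / 2 * np.sin(2 * np.pi * hr / 60 * t) + rng.normal(0, 0.5, n)
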