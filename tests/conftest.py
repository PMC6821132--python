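import numpy as np
import pytest

from astroclear.synthetic_data import (
    DeathSimConfig,
    generate_quant_scene,
    simulate_death_process,
)


@pytest.fixture(scope="session")
def rgc_like_series():
    """A simulated series whose rates mirror the rat RGC decline
    (per-day loss ~5.2%, clearance 2.47 h over 10 days)."""
    cfg = DeathSimConfig(
        S0=100_000, per_day_loss=0.0522, clearance_hours=2.47, n_days=10, seed=7
    )
    return simulate_death_process(cfg)


@pytest.fixture(scope="session")
def arbor_scene():
    """A noiseless arbor-coverage scene with exact ground truths."""
    return generate_quant_scene(seed=11, marker_kind="arbor", coverage_target_percent=20.0)


@pytest.fixture(scope="session")
def puncta_scene():
    """A lysosome-puncta scene with exact ground truths."""
    return generate_quant_scene(seed=13, marker_kind="puncta")
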