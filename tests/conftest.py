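import numpy as np
import pytest
from hypothesis import settings

import beepsych as bp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def pooled_params() -> bp.PsychometricParams:
    """Pooled-data parameter estimate for the bumblebee colonies."""
    return bp.BEE_POOLED_PARAMS


@pytest.fixture
def small_dataset() -> list[bp.ResponseRecord]:
    """Three-intensity dataset small enough for the grid oracle."""
    return [
        bp.ResponseRecord(0.2, 30, 50),
        bp.ResponseRecord(0.4, 44, 50),
        bp.ResponseRecord(0.6, 47, 50),
    ]


@pytest.fixture(scope="session")
def two_day_schedule() -> list[bp.DayCondition]:
    """One reversal pair at relative intensity 0.67."""
    return [
        bp.DayCondition(1, 1, 30.0, 15.0),
        bp.DayCondition(1, 2, 15.0, 30.0),
    ]


@pytest.fixture(scope="session")
def fast_mcmc() -> bp.McmcConfig:
    return bp.McmcConfig(n_draws=1500, seed=11)


def make_events(colors, rewarded=None, bee_id="B001", day=1, conc=(30.0, 15.0)):
    """Hand-build a minimal event frame from a color sequence."""
    import pandas as pd

    n = len(colors)
    if rewarded is None:
        rewarded = [True] * n
    conc_map = {"blue": conc[0], "yellow": conc[1]}
    return pd.DataFrame(
        {
            "day": day,
            "time_s": np.arange(n, dtype=float),
            "bee_id": bee_id,
            "feeder_id": [1 if c == "blue" else 11 for c in colors],
            "color": list(colors),
            "concentration": [conc_map[c] for c in colors],
            "rewarded": list(rewarded),
        }
    )
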