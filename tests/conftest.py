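import numpy as np
import pytest

from ecoclim import oil_palm_preset, run_grid
from ecoclim.phenoclim import WeeklyClimate, WEEK_DAYS
from ecoclim.synthetic import SyntheticSpec, make_climatology, make_gradient_testbed


@pytest.fixture(scope="session")
def preset():
    return oil_palm_preset()


@pytest.fixture(scope="session")
def gradient():
    """Gradient testbed climatology, expectations, and its model run."""
    clim, expected = make_gradient_testbed()
    res = run_grid(clim, oil_palm_preset())
    return clim, expected, res


@pytest.fixture(scope="session")
def tropical_pair():
    """Baseline tropical grid and its +4 °C perturbation, both run."""
    from ecoclim import apply_scenario_delta

    p = oil_palm_preset()
    base = make_climatology(SyntheticSpec(seed=7))
    warm = apply_scenario_delta(base, dT=4.0)
    return run_grid(base, p), run_grid(warm, p)


def random_weekly(rng: np.random.Generator, n: int) -> WeeklyClimate:
    """n random but valid weekly climate series spanning extreme conditions.

    Each series is a random annual structure (base level, seasonal cycle,
    weekly noise) so the ensemble covers everything from polar to
    hyper-arid to ideal tropical cells.
    """
    base = rng.uniform(-15.0, 32.0, n)
    amp = rng.uniform(0.0, 15.0, n)
    phase = rng.uniform(0.0, 2.0 * np.pi, n)
    angle = 2.0 * np.pi * np.arange(52)[:, None] / 52.0
    t_min = base + amp * np.cos(angle + phase) + rng.normal(0.0, 2.0, (52, n))
    t_max = t_min + rng.uniform(2.0, 18.0, (52, n))
    weights = rng.uniform(0.01, 1.0, (52, n))
    precip = rng.uniform(0.0, 6000.0, n) * weights / weights.sum(axis=0)
    rh = np.clip(rng.uniform(10.0, 95.0, n) + rng.normal(0.0, 5.0, (52, n)), 0.0, 100.0)
    return WeeklyClimate(
        t_min=t_min,
        t_max=t_max,
        t_avg=0.5 * (t_min + t_max),
        precip=precip,
        rh_mean=rh,
    )
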