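import numpy as np
import pytest

from kosem.constants import ME_INDEX, MICROENVS, N_MICROENVS, N_SLOTS
from kosem.diaries import Diary
from kosem.me_grid import FittedDistribution, SlotGrid, build_grid, fit_grid
from kosem.synthetic import (
    CampaignSpec,
    PopulationSpec,
    generate_campaign,
    generate_population,
)

SMALL_MINUTES = {"residential_indoor": 30, "transportation": 12, "other": 25}


def make_grid(means, available=None, fits=None, min_obs=1):
    """Construct a SlotGrid directly from a (144, 3) mean array."""
    means = np.asarray(means, dtype=float)
    if available is None:
        available = ~np.isnan(means)
    n_obs = np.where(available, min_obs, 0)
    return SlotGrid(
        n_obs=n_obs.astype(int),
        means=means,
        sds=np.zeros_like(means),
        available=np.asarray(available, dtype=bool),
        min_obs_per_cell=min_obs,
        fits=dict(fits or {}),
    )


def constant_grid(value=20.0):
    return make_grid(np.full((N_SLOTS, N_MICROENVS), float(value)))


def diary_all(code, subject_id="s1", day_type="weekday"):
    return Diary(subject_id, day_type,
                 np.full(N_SLOTS, ME_INDEX[code], dtype=np.int8))


def point_mass_fits(grid):
    """Degenerate fitted distributions equal to each available cell mean."""
    fits = {}
    for t in range(1, N_SLOTS + 1):
        for j, m in enumerate(MICROENVS):
            if grid.available[t - 1, j]:
                fits[(t, m)] = FittedDistribution(
                    "point_mass", {"value": float(grid.means[t - 1, j])})
    return fits


@pytest.fixture(scope="session")
def small_campaign():
    return generate_campaign(CampaignSpec(seed=11, minutes_per_cell=SMALL_MINUTES))


@pytest.fixture(scope="session")
def fitted_grid(small_campaign):
    grid = build_grid(small_campaign, min_obs_per_cell=5)
    return fit_grid(grid)


@pytest.fixture(scope="session")
def population_small():
    diaries, truth = generate_population(PopulationSpec(n_subjects=400, seed=7))
    return diaries, truth
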