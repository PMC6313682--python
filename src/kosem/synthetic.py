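"""Synthetic measurement campaigns and diary populations.

The generator emulates the statistical structure the model assumes so that
every stage is testable without external data: lognormal diurnal
concentration series per microenvironment (right-skewed, SD of the same
order as or larger than the mean, with a midday bump at home and an
evening/night elevation in "other" venues), day-type-dependent
block-structured activity schedules (sleep - morning commute - daytime
block - evening commute - evening at home), and a demographic covariate
table with controllable effect sizes that tilt schedules toward
high-concentration microenvironments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from kosem.constants import DAY_TYPES, ME_INDEX, MICROENVS, N_SLOTS
from kosem.diaries import Diary


def _hourly_means(base: float, shape: np.ndarray) -> np.ndarray:
    """Scale a relative 24-h shape so the flat average equals ``base``."""
    shape = np.asarray(shape, dtype=float)
    return base * shape / shape.mean()


def _default_profiles() -> dict:
    res_shape = np.ones(24)
    res_shape[12] = 1.5                   # lunch-time cooking bump at home
    oth_shape = np.ones(24)
    oth_shape[18:23] = 2.0                # restaurants/bars in the evening
    return {
        "residential_indoor": _hourly_means(23.7, res_shape),
        "transportation": _hourly_means(24.2, np.ones(24)),
        "other": _hourly_means(34.7, oth_shape),
    }


#: Geometric standard deviations chosen so the lognormal CV matches the
#: arithmetic mean/SD ratios of the three microenvironments
#: (23.7/24.1, 24.2/22.8, 34.7/62.3): GSD = exp(sqrt(ln(1 + cv^2))).
def _gsd_from_cv(cv: float) -> float:
    return math.exp(math.sqrt(math.log1p(cv * cv)))


DEFAULT_GSDS = {
    "residential_indoor": _gsd_from_cv(24.1 / 23.7),
    "transportation": _gsd_from_cv(22.8 / 24.2),
    "other": _gsd_from_cv(62.3 / 34.7),
}

#: Observation counts per cell mirroring the campaign's per-microenvironment
#: totals (~33k residential, ~5.3k transportation, ~21.7k other minutes
#: spread over 144 slots).
DEFAULT_MINUTES_PER_CELL = {
    "residential_indoor": 229,
    "transportation": 37,
    "other": 150,
}

#: 23 night / early-morning transportation cells left unmeasured
#: (02:10-05:59), covering the 04:00-05:59 window whose missing transit
#: concentrations force a reduced exposure denominator.
DEFAULT_BLANKED_CELLS = tuple((s, "transportation") for s in range(14, 37))


@dataclass
class CampaignSpec:
    """Parameters of a synthetic 1-min measurement campaign."""

    hourly_means: dict = field(default_factory=_default_profiles)
    gsds: dict = field(default_factory=lambda: dict(DEFAULT_GSDS))
    minutes_per_cell: dict = field(
        default_factory=lambda: dict(DEFAULT_MINUTES_PER_CELL))
    blanked_cells: Sequence = DEFAULT_BLANKED_CELLS
    correction_factor: float = 1.0     # emitted raw = true / factor
    run_id: str = "run1"
    seed: int = 0

    def __post_init__(self):
        for m in MICROENVS:
            if (np.asarray(self.hourly_means[m]) <= 0).any():
                raise ValueError(f"non-positive mean profile for {m}")
            if self.gsds[m] < 1:
                raise ValueError(f"GSD < 1 for {m}")
        for s, m in self.blanked_cells:
            if not (1 <= s <= N_SLOTS) or m not in MICROENVS:
                raise ValueError(f"blanked cell ({s}, {m}) outside the grid")


def generate_campaign(spec: CampaignSpec) -> pd.DataFrame:
    """Draw a measurement table (date, minute_of_day, pm25_ugm3, microenv,
    run_id): per non-blanked cell, lognormal 1-min values whose arithmetic
    mean matches the cell's diurnal profile. Reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    blanked = set((int(s), m) for s, m in spec.blanked_cells)
    frames = []
    for t in range(1, N_SLOTS + 1):
        hour = (t - 1) // 6
        for m in MICROENVS:
            if (t, m) in blanked:
                continue
            n = int(spec.minutes_per_cell[m])
            mean = float(spec.hourly_means[m][hour])
            gsd = float(spec.gsds[m])
            if gsd == 1.0:
                true = np.full(n, mean)
            else:
                sigma = math.log(gsd)
                mu = math.log(mean) - sigma * sigma / 2.0
                true = rng.lognormal(mu, sigma, n)
            k = np.arange(n)
            frames.append(pd.DataFrame({
                "date": (k // 10 + 1),
                "minute_of_day": (t - 1) * 10 + k % 10,
                "pm25_ugm3": true / spec.correction_factor,
                "microenv": m,
                "run_id": spec.run_id,
            }))
    df = pd.concat(frames, ignore_index=True)
    df["date"] = "d" + df["date"].astype(str)
    return df


def campaign_correction_factors(spec: CampaignSpec) -> dict:
    return {spec.run_id: spec.correction_factor}


# ---------------------------------------------------------------------------
# Diary population
# ---------------------------------------------------------------------------

#: Survey-scale day-type mix (weekday : Saturday : Sunday person-days).
DEFAULT_DAY_TYPE_COUNTS = {"weekday": 4849, "saturday": 1608, "sunday": 1618}

#: Time-budget targets (mean, SD) in hours for residential indoor and
#: transportation; "other" takes the remainder of the 24-h day
#: (weekday 13.95/2.03/8.01, Saturday 15.02/2.02/6.96, Sunday 17.01/1.76/5.23).
DEFAULT_BUDGETS = {
    "weekday": {"residential": (13.95, 4.77), "transportation": (2.03, 1.68)},
    "saturday": {"residential": (15.02, 5.09), "transportation": (2.02, 1.72)},
    "sunday": {"residential": (17.01, 5.40), "transportation": (1.76, 1.86)},
}

#: Marginal covariate distributions patterned on the survey population
#: (low-exposure-group column percentages).
DEFAULT_COVARIATE_MARGINALS = {
    "p_male": 0.465,
    "age_mean": 38.0, "age_sd": 18.0, "age_min": 10, "age_max": 93,
    "p_married": 0.555,
    "p_education": {"middle_school_or_below": 0.281,
                    "college_or_below": 0.362,
                    "university_or_above": 0.357},
    "p_employed": 0.537,
    "p_industry": {"primary_secondary": 0.18, "tertiary": 0.541,
                   "other": 0.279},
    "p_office": 0.469,
    "hours_mean": 45.0, "hours_sd": 15.0, "hours_max": 120.0,
    "p_income_ge_2000": 0.148,
    "house_size_median": 66.1, "house_size_log_sd": 0.5,
    "house_size_min": 9.9, "house_size_max": 337.2,
    "p_owns_house": 0.525,
    "p_owns_car": 0.639,
}


@dataclass
class PopulationSpec:
    """Parameters of a synthetic diary population.

    ``effects`` maps covariates to log-odds-scale tilts: keys are
    ``"var=level"`` for a categorical indicator or ``"var"`` for a centered
    continuous variable. A positive tilt moves hours from residential
    indoor to the (higher-concentration) "other" microenvironment, placing
    them late in the day, so tilted subjects drift toward the top of the
    exposure distribution."""

    n_subjects: int = 8072
    day_type_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DAY_TYPE_COUNTS))
    budgets: Mapping = field(default_factory=lambda: DEFAULT_BUDGETS)
    covariate_marginals: Mapping = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINALS))
    effects: Mapping[str, float] = field(default_factory=dict)
    effect_scale_hours: float = 3.0    # max hours shifted at saturating tilt
    early_transit_fraction: float = 511 / 8072
    seed: int = 0

    def __post_init__(self):
        w = np.array([self.day_type_weights[d] for d in DAY_TYPES], float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("day_type_weights must be non-negative, not all 0")
        for dt in DAY_TYPES:
            b = self.budgets[dt]
            if b["residential"][0] + b["transportation"][0] > 24:
                raise ValueError(f"infeasible budget targets for {dt}")


def _sample_covariates(n: int, marg: Mapping, rng: np.random.Generator
                       ) -> pd.DataFrame:
    m = marg
    sex = np.where(rng.random(n) < m["p_male"], "male", "female")
    age = np.clip(np.round(rng.normal(m["age_mean"], m["age_sd"], n)),
                  m["age_min"], m["age_max"]).astype(int)
    marital = np.where(rng.random(n) < m["p_married"], "married", "unmarried")
    edu_levels = list(m["p_education"])
    edu = rng.choice(edu_levels, size=n, p=list(m["p_education"].values()))
    employed = rng.random(n) < m["p_employed"]
    ind_levels = list(m["p_industry"])
    industry = np.where(
        employed,
        rng.choice(ind_levels, size=n, p=list(m["p_industry"].values())),
        "not_applicable")
    job = np.where(
        employed,
        np.where(rng.random(n) < m["p_office"], "office", "non_office"),
        "not_applicable")
    hours = np.where(
        employed,
        np.clip(rng.normal(m["hours_mean"], m["hours_sd"], n), 1.0,
                m["hours_max"]),
        0.0)
    income = np.where(rng.random(n) < m["p_income_ge_2000"],
                      "ge_2000", "lt_2000")
    house = np.clip(
        np.exp(rng.normal(math.log(m["house_size_median"]),
                          m["house_size_log_sd"], n)),
        m["house_size_min"], m["house_size_max"]).round(1)
    return pd.DataFrame({
        "sex": sex, "age": age, "marital": marital, "education": edu,
        "industry": industry, "job": job,
        "working_hours": hours.round(1),
        "income_band": income, "house_size": house,
        "owns_house": rng.random(n) < m["p_owns_house"],
        "owns_car": rng.random(n) < m["p_owns_car"],
    })


def _latent_tilt(cov: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    z = np.zeros(len(cov))
    for key, beta in effects.items():
        if "=" in key:
            var, level = key.split("=", 1)
            z += beta * (cov[var].astype(str) == level).to_numpy(float)
        else:
            x = cov[key].to_numpy(float)
            z += beta * (x - x.mean())
    return z


def _build_schedule(res_s: int, tra_s: int, night_home: int) -> np.ndarray:
    oth_s = N_SLOTS - res_s - tra_s
    night = min(res_s, night_home)
    c1 = tra_s // 2
    c2 = tra_s - c1
    codes = ([0] * night + [1] * c1 + [2] * oth_s + [1] * c2
             + [0] * (res_s - night))
    return np.array(codes, dtype=np.int8)


def generate_population(
    spec: PopulationSpec,
) -> tuple[list, dict]:
    """Generate diaries with covariates; returns (diaries, truth).

    ``truth`` records everything used to generate the data: the covariate
    table (indexed by subject_id, including day_type), the latent tilt per
    subject, which subjects were forced into early-morning transit, and the
    spec itself — the raw material for recovery tests."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    w = np.array([spec.day_type_weights[d] for d in DAY_TYPES], float)
    w /= w.sum()
    day_types = rng.choice(DAY_TYPES, size=n, p=w)
    cov = _sample_covariates(n, spec.covariate_marginals, rng)
    subject_ids = [f"s{i + 1:06d}" for i in range(n)]
    cov.index = pd.Index(subject_ids, name="subject_id")
    cov.insert(0, "day_type", day_types)

    z = _latent_tilt(cov, spec.effects)
    # hours moved from residential to late-day "other"; zero tilt moves none
    shift_h = spec.effect_scale_hours * (1.0 / (1.0 + np.exp(-z)) - 0.5) * 2.0
    early_transit = rng.random(n) < spec.early_transit_fraction
    wake = rng.integers(36, 49, size=n)    # sleep until ~06:00-08:00

    diaries = []
    for i in range(n):
        dt = day_types[i]
        bm = spec.budgets[dt]
        res_h = float(np.clip(rng.normal(*bm["residential"]), 4.0, 24.0))
        tra_h = float(np.clip(rng.normal(*bm["transportation"]), 0.0, 6.0))
        res_h = float(np.clip(res_h - shift_h[i], 4.0, 24.0))
        if res_h + tra_h > 24.0:
            tra_h = 24.0 - res_h
        res_s = int(round(res_h * 6))
        tra_s = int(round(tra_h * 6))
        if res_s + tra_s > N_SLOTS:
            tra_s = N_SLOTS - res_s
        slots = _build_schedule(res_s, tra_s, int(wake[i]))
        if early_transit[i]:
            # transit in the 04:00-04:19 window (unmeasured transportation
            # cells) at the expense of two night residential slots
            slots[24:26] = 1
        diaries.append(Diary(subject_id=subject_ids[i], day_type=dt,
                             slots=slots,
                             covariates=cov.iloc[i].to_dict()))
    truth = {
        "covariates": cov,
        "latent_tilt": pd.Series(z, index=cov.index, name="latent_tilt"),
        "early_transit": pd.Series(early_transit, index=cov.index,
                                   name="early_transit"),
        "effects": dict(spec.effects),
        "spec": spec,
    }
    return diaries, truth


def covariates_frame(diaries: Sequence[Diary]) -> pd.DataFrame:
    """Covariate table (incl. day_type) recovered from a diary list."""
    rows = []
    for d in diaries:
        row = {"subject_id": d.subject_id, "day_type": d.day_type}
        row.update({k: v for k, v in d.covariates.items() if k != "day_type"})
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
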