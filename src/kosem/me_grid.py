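"""Slot-grid construction and per-cell distribution fitting.

The grid holds, for each of the 144 ten-minute slots and each of the three
microenvironments (432 cells), the corrected 1-min PM2.5 observations that
fell into that cell, their summary statistics, and optionally a fitted
concentration distribution. Cells with fewer than ``min_obs_per_cell``
observations are flagged unavailable; the exposure engine excludes them from
the daily time-weighted average and shrinks the denominator accordingly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from kosem.constants import (
    ME_INDEX,
    MICROENVS,
    N_MICROENVS,
    N_SLOTS,
    slot_of_minute,
)

DEFAULT_MIN_OBS_PER_CELL = 5
DEFAULT_FAMILIES = ("lognormal", "gamma", "weibull", "normal_truncated_at_zero")

MEASUREMENT_COLUMNS = ("date", "minute_of_day", "pm25_ugm3", "microenv", "run_id")


class MinuteRecord(NamedTuple):
    """One corrected or raw 1-min PM2.5 observation."""

    minute_of_day: int
    pm25: float
    microenv: str
    run_id: str = "run1"
    date: str = "d1"


class GridError(ValueError):
    pass


def records_to_frame(records: Iterable[MinuteRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalize measurement input to a DataFrame with the standard columns."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        missing = {"minute_of_day", "pm25_ugm3", "microenv"} - set(df.columns)
        if missing:
            raise GridError(f"measurement table lacks columns: {sorted(missing)}")
        if "run_id" not in df.columns:
            df["run_id"] = "run1"
        if "date" not in df.columns:
            df["date"] = "d1"
        return df
    rows = list(records)
    return pd.DataFrame(
        {
            "date": [r.date for r in rows],
            "minute_of_day": [r.minute_of_day for r in rows],
            "pm25_ugm3": [r.pm25 for r in rows],
            "microenv": [r.microenv for r in rows],
            "run_id": [r.run_id for r in rows],
        }
    )


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Reject negative concentrations, unknown microenvironment codes and
    out-of-range minutes. Instrument output is non-negative, so a negative
    value signals a parse error rather than a measurement to be clipped."""
    df = records_to_frame(df)
    bad_me = ~df["microenv"].isin(MICROENVS)
    if bad_me.any():
        i = int(np.flatnonzero(bad_me.to_numpy())[0])
        raise GridError(
            f"row {i}: unknown microenv code {df['microenv'].iloc[i]!r} "
            f"(expected one of {MICROENVS})"
        )
    minutes = df["minute_of_day"].to_numpy()
    if ((minutes < 0) | (minutes > 1439)).any():
        i = int(np.flatnonzero((minutes < 0) | (minutes > 1439))[0])
        raise GridError(f"row {i}: minute_of_day {minutes[i]} outside [0, 1439]")
    pm = df["pm25_ugm3"].to_numpy(dtype=float)
    if np.isnan(pm).any():
        i = int(np.flatnonzero(np.isnan(pm))[0])
        raise GridError(f"row {i}: non-numeric pm25_ugm3")
    if (pm < 0).any():
        i = int(np.flatnonzero(pm < 0)[0])
        raise GridError(f"row {i}: negative pm25_ugm3 {pm[i]}")
    return df


def apply_correction(
    records: Iterable[MinuteRecord] | pd.DataFrame,
    factors: Mapping[str, float],
) -> pd.DataFrame:
    """Apply per-run gravimetric correction factors (pm25 * factor).

    Every run_id present in the data must have a positive factor; a single
    global multiplier is expressed as a one-entry map covering all runs or a
    map with the same factor for each run.
    """
    df = records_to_frame(records)
    runs = df["run_id"].unique()
    missing = [r for r in runs if r not in factors]
    if missing:
        raise GridError(f"no correction factor for run(s): {missing}")
    bad = [r for r in runs if not factors[r] > 0]
    if bad:
        raise GridError(f"non-positive correction factor for run(s): {bad}")
    out = df.copy()
    out["pm25_ugm3"] = out["pm25_ugm3"].astype(float) * out["run_id"].map(factors).astype(float)
    return out


# ---------------------------------------------------------------------------
# Fitted distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedDistribution:
    """A non-negative concentration distribution fitted to one grid cell.

    ``family`` is one of lognormal, gamma, weibull,
    normal_truncated_at_zero, or point_mass (degenerate fallback).
    ``fit_score`` is the model-selection criterion value (AIC or the KS
    statistic) under which the family was chosen.
    """

    family: str
    params: dict
    fit_score: float = math.nan
    criterion: str = "aic"

    def _frozen(self):
        p = self.params
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        if self.family == "gamma":
            return stats.gamma(a=p["shape"], scale=p["scale"])
        if self.family == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        if self.family == "normal_truncated_at_zero":
            mu, sigma = p["mu"], p["sigma"]
            return stats.truncnorm(a=-mu / sigma, b=np.inf, loc=mu, scale=sigma)
        raise ValueError(f"unknown family {self.family!r}")

    def mean(self) -> float:
        if self.family == "point_mass":
            return float(self.params["value"])
        return float(self._frozen().mean())

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw i.i.d. values; guaranteed >= 0 for every family."""
        if self.family == "point_mass":
            return np.full(size, float(self.params["value"]))
        return np.asarray(self._frozen().rvs(size=size, random_state=rng), dtype=float)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        if self.family == "point_mass":
            raise ValueError("point mass has no density")
        return self._frozen().logpdf(x)


def _fit_lognormal(x: np.ndarray) -> dict:
    logs = np.log(x)
    return {"mu": float(logs.mean()), "sigma": float(logs.std(ddof=0))}


def _fit_truncnorm(x: np.ndarray) -> dict:
    # ML over (mu, log sigma) of a normal truncated to [0, inf):
    # nll = n[log sigma + log Phi(mu/sigma) + log sqrt(2 pi)]
    #       + sum (x - mu)^2 / (2 sigma^2)
    from scipy.special import ndtr

    n = x.size
    half_log_2pi = 0.5 * math.log(2 * math.pi)

    def nll(theta):
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        z = (x - mu) / sigma
        norm_c = ndtr(mu / sigma)
        if norm_c <= 0:
            return np.inf
        return n * (log_sigma + math.log(norm_c) + half_log_2pi) \
            + 0.5 * float(z @ z)

    x0 = np.array([x.mean(), math.log(max(x.std(ddof=0), 1e-8))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 500})
    mu, log_sigma = res.x
    return {"mu": float(mu), "sigma": float(math.exp(log_sigma))}


def _fit_family(x: np.ndarray, family: str) -> FittedDistribution | None:
    try:
        if family == "lognormal":
            if (x <= 0).any():
                return None
            params = _fit_lognormal(x)
        elif family == "gamma":
            if (x <= 0).any():
                return None
            a, _, scale = stats.gamma.fit(x, floc=0)
            params = {"shape": float(a), "scale": float(scale)}
        elif family == "weibull":
            if (x <= 0).any():
                return None
            c, _, scale = stats.weibull_min.fit(x, floc=0)
            params = {"shape": float(c), "scale": float(scale)}
        elif family == "normal_truncated_at_zero":
            params = _fit_truncnorm(x)
        else:
            raise ValueError(f"unknown family {family!r}")
    except Exception:
        return None
    fd = FittedDistribution(family=family, params=params)
    if not all(v > 0 or k == "mu" for k, v in params.items()):
        return None
    return fd


def fit_cell_distribution(
    values: np.ndarray | Sequence[float],
    families: Sequence[str] = DEFAULT_FAMILIES,
    criterion: str = "aic",
) -> FittedDistribution:
    """Fit each candidate family by maximum likelihood and return the one
    minimizing the criterion (AIC by default; 'ks' selects by the
    Kolmogorov-Smirnov statistic).

    A zero-variance cell collapses to a point mass at the common value with
    a warning; every returned distribution samples only non-negative values.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise GridError("cannot fit a distribution to an empty cell")
    if criterion not in ("aic", "ks"):
        raise GridError(f"unknown criterion {criterion!r} (use 'aic' or 'ks')")
    if np.ptp(x) == 0:
        warnings.warn(
            f"degenerate cell (all {x.size} observations equal {x[0]}); "
            "using a point mass", stacklevel=2)
        return FittedDistribution("point_mass", {"value": float(x[0])},
                                  fit_score=math.nan, criterion=criterion)

    best = None
    for fam in families:
        fd = _fit_family(x, fam)
        if fd is None:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            if criterion == "aic":
                ll = float(np.sum(fd.logpdf(x)))
                score = 2 * len(fd.params) - 2 * ll
            else:
                score = float(stats.kstest(x, fd._frozen().cdf).statistic)
        if not math.isfinite(score):
            continue
        if best is None or score < best.fit_score:
            best = replace(fd, fit_score=score, criterion=criterion)
    if best is None:
        raise GridError("no candidate family could be fitted to the cell")
    return best


# ---------------------------------------------------------------------------
# The grid
# ---------------------------------------------------------------------------

@dataclass
class SlotCell:
    slot_index: int            # 1-based, slot t covers minutes [10(t-1), 10t)
    microenv: str
    n_obs: int
    mean: float
    sd: float
    available: bool
    fitted: FittedDistribution | None = None


@dataclass
class SlotGrid:
    """144 x 3 grid of per-cell concentration summaries and fitted
    distributions. ``means``/``sds`` are (144, 3) arrays (NaN where empty);
    ``available`` is the boolean mask of cells with enough observations."""

    n_obs: np.ndarray          # (144, 3) int
    means: np.ndarray          # (144, 3) float, NaN where n_obs == 0
    sds: np.ndarray            # (144, 3) float
    available: np.ndarray      # (144, 3) bool
    min_obs_per_cell: int
    fits: dict = field(default_factory=dict)   # (slot, microenv) -> FittedDistribution
    data: dict = field(default_factory=dict)   # (slot, microenv) -> np.ndarray of obs

    @property
    def n_available(self) -> int:
        return int(self.available.sum())

    def cell(self, slot: int, microenv: str) -> SlotCell:
        j = ME_INDEX[microenv]
        return SlotCell(
            slot_index=slot,
            microenv=microenv,
            n_obs=int(self.n_obs[slot - 1, j]),
            mean=float(self.means[slot - 1, j]),
            sd=float(self.sds[slot - 1, j]),
            available=bool(self.available[slot - 1, j]),
            fitted=self.fits.get((slot, microenv)),
        )

    def cells(self):
        """All 432 cells in canonical order (slot-major, microenv-minor)."""
        for t in range(1, N_SLOTS + 1):
            for m in MICROENVS:
                yield self.cell(t, m)

    def fitted_means(self) -> np.ndarray:
        """(144, 3) array of fitted-distribution means, NaN where unfitted."""
        out = np.full((N_SLOTS, N_MICROENVS), np.nan)
        for (t, m), fd in self.fits.items():
            out[t - 1, ME_INDEX[m]] = fd.mean()
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells():
            fd = c.fitted
            rows.append({
                "slot": c.slot_index,
                "microenv": c.microenv,
                "n_obs": c.n_obs,
                "mean": c.mean,
                "sd": c.sd,
                "family": fd.family if fd else "",
                "params_json": json.dumps(fd.params) if fd else "",
                "fit_score": fd.fit_score if fd else math.nan,
                "available": c.available,
            })
        return pd.DataFrame(rows)


def build_grid(
    records: Iterable[MinuteRecord] | pd.DataFrame,
    min_obs_per_cell: int = DEFAULT_MIN_OBS_PER_CELL,
    keep_data: bool = True,
) -> SlotGrid:
    """Arrange corrected 1-min observations into the 432-cell grid.

    Multi-day campaigns are pooled into a single diurnal grid: each record
    lands in slot floor(minute/10)+1 of its microenvironment regardless of
    date. Cells with fewer than ``min_obs_per_cell`` observations are
    flagged unavailable (empty cells are valid, just unavailable).
    """
    df = validate_measurements(records)
    if df.empty:
        raise GridError("no measurement records")
    if min_obs_per_cell < 1:
        raise GridError("min_obs_per_cell must be >= 1")

    slots = df["minute_of_day"].to_numpy() // 10          # 0-based
    mes = df["microenv"].map(ME_INDEX).to_numpy()
    pm = df["pm25_ugm3"].to_numpy(dtype=float)

    n_obs = np.zeros((N_SLOTS, N_MICROENVS), dtype=int)
    sums = np.zeros((N_SLOTS, N_MICROENVS))
    np.add.at(n_obs, (slots, mes), 1)
    np.add.at(sums, (slots, mes), pm)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n_obs > 0, sums / np.maximum(n_obs, 1), np.nan)
    sq = np.zeros((N_SLOTS, N_MICROENVS))
    np.add.at(sq, (slots, mes), (pm - means[slots, mes]) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sds = np.where(n_obs > 1, np.sqrt(sq / np.maximum(n_obs - 1, 1)), np.nan)
    sds[n_obs == 1] = 0.0

    data = {}
    if keep_data:
        order = np.lexsort((pm, mes, slots))
        s_sorted, m_sorted, p_sorted = slots[order], mes[order], pm[order]
        # split contiguous runs of identical (slot, me)
        keys = s_sorted * N_MICROENVS + m_sorted
        bounds = np.flatnonzero(np.diff(keys)) + 1
        for chunk, k in zip(
            np.split(p_sorted, bounds),
            np.concatenate(([keys[0]], keys[bounds])) if keys.size else [],
        ):
            t, j = divmod(int(k), N_MICROENVS)
            data[(t + 1, MICROENVS[j])] = chunk

    return SlotGrid(
        n_obs=n_obs,
        means=means,
        sds=sds,
        available=n_obs >= min_obs_per_cell,
        min_obs_per_cell=min_obs_per_cell,
        data=data,
    )


def fit_grid(
    grid: SlotGrid,
    families: Sequence[str] = DEFAULT_FAMILIES,
    criterion: str = "aic",
) -> SlotGrid:
    """Fit a concentration distribution to every available cell in place."""
    if not grid.data:
        raise GridError("grid was built without raw data; cannot fit")
    for (t, m), vals in grid.data.items():
        if grid.available[t - 1, ME_INDEX[m]]:
            grid.fits[(t, m)] = fit_cell_distribution(vals, families, criterion)
    return grid
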