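"""Time-activity diaries: 144-slot person-days, time budgets, and
day-type comparisons (one-way ANOVA with Scheffé post-hoc contrasts)."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from kosem.constants import (
    DAY_TYPES,
    ME_INDEX,
    MICROENVS,
    N_SLOTS,
    SEVEN_CATEGORY_MAP,
)

BUDGET_COMPONENTS = ("residential", "transportation", "other")

#: Covariates carried with each diary; categorical unless listed continuous.
CONTINUOUS_COVARIATES = ("age", "working_hours", "house_size")
CATEGORICAL_COVARIATES = (
    "day_type", "sex", "marital", "education", "industry", "job",
    "income_band", "owns_house", "owns_car",
)


class DiaryError(ValueError):
    pass


@dataclass
class Diary:
    """One person-day: 144 microenvironment codes plus covariates.

    ``slots`` is an int8 array of microenvironment indices (0 residential
    indoor, 1 transportation, 2 other) in chronological order, slot t
    covering minutes [10(t-1), 10t)."""

    subject_id: str
    day_type: str
    slots: np.ndarray
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        self.slots = np.asarray(self.slots, dtype=np.int8)
        if self.slots.shape != (N_SLOTS,):
            raise DiaryError(
                f"diary {self.subject_id}: expected {N_SLOTS} slots, "
                f"got {self.slots.shape}")
        if ((self.slots < 0) | (self.slots > 2)).any():
            raise DiaryError(f"diary {self.subject_id}: slot code outside 0..2")
        if self.day_type not in DAY_TYPES:
            raise DiaryError(
                f"diary {self.subject_id}: unknown day_type {self.day_type!r}")

    def slot_codes(self) -> list[str]:
        return [MICROENVS[i] for i in self.slots]


def day_type_of_date(date: _dt.date) -> str:
    wd = date.weekday()
    return "weekday" if wd < 5 else ("saturday" if wd == 5 else "sunday")


def diary_from_codes(
    subject_id: str,
    day_type: str,
    codes: Sequence[str],
    covariates: Mapping | None = None,
    date: _dt.date | None = None,
    accept_seven_category: bool = False,
) -> Diary:
    """Build a Diary from textual microenvironment codes.

    Codes outside the three-category scheme are rejected, unless
    ``accept_seven_category`` maps the finer seven-category survey scheme
    (own home / walk / private & public transport / workplace-school /
    restaurant / other) onto the three model categories. A calendar date,
    if given, must be consistent with the declared day type."""
    if date is not None and day_type_of_date(date) != day_type:
        raise DiaryError(
            f"diary {subject_id}: date {date} is a "
            f"{day_type_of_date(date)}, not a {day_type}")
    idx = []
    for k, c in enumerate(codes):
        if accept_seven_category and c in SEVEN_CATEGORY_MAP:
            c = SEVEN_CATEGORY_MAP[c]
        if c not in ME_INDEX:
            raise DiaryError(
                f"diary {subject_id}, slot {k + 1}: unknown code {c!r}")
        idx.append(ME_INDEX[c])
    return Diary(subject_id=str(subject_id), day_type=day_type,
                 slots=np.array(idx, dtype=np.int8),
                 covariates=dict(covariates or {}))


@dataclass(frozen=True)
class TimeBudget:
    """Hours per day in each microenvironment; components sum to 24."""

    hours_residential: float
    hours_transport: float
    hours_other: float

    def as_tuple(self):
        return (self.hours_residential, self.hours_transport, self.hours_other)


def time_budget(diary: Diary) -> TimeBudget:
    """Hours spent per microenvironment: slot counts / 6."""
    counts = np.bincount(diary.slots, minlength=3)
    return TimeBudget(*(counts / 6.0))


def budgets_frame(diaries: Iterable[Diary]) -> pd.DataFrame:
    """One row per diary: subject_id, day_type, hours per component."""
    rows = []
    for d in diaries:
        b = time_budget(d)
        rows.append({
            "subject_id": d.subject_id,
            "day_type": d.day_type,
            "residential": b.hours_residential,
            "transportation": b.hours_transport,
            "other": b.hours_other,
        })
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict
    group_sizes: dict
    scheffe: pd.DataFrame   # group_1, group_2, mean_diff, f_stat, p_adj


def scheffe_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Scheffé simultaneous pairwise comparisons after a one-way ANOVA.

    For groups i, j: F_ij = (x̄_i − x̄_j)² / [(k−1)·MSW·(1/n_i + 1/n_j)],
    referred to an F(k−1, N−k) distribution — conservative by construction.
    """
    names = list(groups)
    k = len(names)
    ns = {g: len(groups[g]) for g in names}
    N = sum(ns.values())
    means = {g: float(np.mean(groups[g])) for g in names}
    ssw = sum(float(np.sum((np.asarray(groups[g]) - means[g]) ** 2)) for g in names)
    msw = ssw / (N - k)
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            g1, g2 = names[a], names[b]
            diff = means[g1] - means[g2]
            if msw == 0:
                f = np.inf if diff != 0 else 0.0
            else:
                f = diff ** 2 / ((k - 1) * msw * (1 / ns[g1] + 1 / ns[g2]))
            p = float(stats.f.sf(f, k - 1, N - k))
            rows.append({"group_1": g1, "group_2": g2, "mean_diff": diff,
                         "f_stat": f, "p_adj": p})
    return pd.DataFrame(rows)


def compare_budgets_by_daytype(
    diaries: Sequence[Diary],
    component: str = "residential",
) -> AnovaResult:
    """One-way ANOVA of a time-budget component across weekday / Saturday /
    Sunday, with Scheffé post-hoc pairwise contrasts."""
    if component not in BUDGET_COMPONENTS:
        raise DiaryError(f"component must be one of {BUDGET_COMPONENTS}")
    df = budgets_frame(diaries)
    groups = {}
    for dt in DAY_TYPES:
        vals = df.loc[df["day_type"] == dt, component].to_numpy()
        if len(vals) < 2:
            raise DiaryError(
                f"day type {dt!r} has {len(vals)} diaries; "
                "need at least 2 per group for ANOVA")
        groups[dt] = vals
    f_stat, p = stats.f_oneway(*groups.values())
    if not np.isfinite(f_stat):   # zero within-group variance
        f_stat, p = (0.0, 1.0) if all(
            np.ptp(v) == 0 for v in groups.values()
        ) and len({v[0] for v in groups.values()}) == 1 else (np.inf, 0.0)
    N = sum(len(v) for v in groups.values())
    return AnovaResult(
        f_stat=float(f_stat),
        p_value=float(p),
        df_between=len(groups) - 1,
        df_within=N - len(groups),
        group_means={g: float(np.mean(v)) for g, v in groups.items()},
        group_sizes={g: len(v) for g, v in groups.items()},
        scheffe=scheffe_posthoc(groups),
    )
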