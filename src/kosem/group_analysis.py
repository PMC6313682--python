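"""High-exposure-group classification and characterization.

The top fraction (default 5%) of the daily-exposure distribution forms the
high-exposure group. Categorical covariates are screened with Fisher's
exact test of independence (full enumeration over tables with fixed margins
where feasible, seeded Monte-Carlo otherwise), continuous covariates with
Welch's t-test. Variables passing the screen (p < 0.1) enter a multivariate
logistic regression after variance-inflation-factor pruning; per-variable
significance is a drop-one likelihood-ratio test and effect sizes are odds
ratios with 95% Wald intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from kosem.utils import round_half_up

DEFAULT_FRACTION = 0.05
DEFAULT_ALPHA_IN = 0.1
DEFAULT_VIF_THRESHOLD = 10.0
Z_95 = 1.959963984540054          # two-sided 95% normal quantile

#: Reference levels for dummy coding (first level of each bracketed group).
DEFAULT_REFERENCES = {
    "day_type": "weekday",
    "sex": "male",
    "marital": "married",
    "education": "middle_school_or_below",
    "industry": "primary_secondary",
    "job": "office",
    "income_band": "lt_2000",
    "owns_house": "yes",
    "owns_car": "yes",
}

#: Level meaning "does not apply" (non-working respondents for industry/job);
#: excluded per variable from contingency tables and from the model fit.
NOT_APPLICABLE = "not_applicable"


class GroupAnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

@dataclass
class GroupLabeling:
    threshold: float               # minimum exposure in the high group
    labels: pd.Series              # subject_id -> "high" | "low"
    n_high: int
    n_low: int


def label_top_fraction(
    exposures: Mapping[str, float] | pd.Series,
    fraction: float = DEFAULT_FRACTION,
) -> GroupLabeling:
    """Label the ceil(fraction * N) highest-exposure subjects "high".

    Ties at the threshold are broken deterministically by subject_id order
    (stable sort on descending exposure, then ascending subject_id)."""
    if not 0 < fraction < 1:
        raise GroupAnalysisError(f"fraction must be in (0, 1), got {fraction}")
    s = pd.Series(exposures, dtype=float)
    if s.empty:
        raise GroupAnalysisError("no exposures to label")
    n = len(s)
    n_high = math.ceil(fraction * n)
    order = s.rename_axis("subject_id").reset_index(name="exposure")
    order = order.sort_values(
        ["exposure", "subject_id"], ascending=[False, True], kind="mergesort")
    high_ids = order["subject_id"].iloc[:n_high]
    labels = pd.Series("low", index=s.index, name="group")
    labels.loc[high_ids] = "high"
    return GroupLabeling(
        threshold=float(order["exposure"].iloc[n_high - 1]),
        labels=labels,
        n_high=n_high,
        n_low=n - n_high,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test (r x c)
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    p_value: float
    method: str                    # "exact" | "monte_carlo"
    n_tables: int = 0              # tables enumerated (exact)
    mc_se: float | None = None     # standard error of the MC estimate

#: log(1 + 1e-7): relative tolerance when comparing table probabilities.
_LOG_REL_TOL = math.log1p(1e-7)


def _log_table_prob_const(row_m: np.ndarray, col_m: np.ndarray) -> float:
    n = row_m.sum()
    return float(gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum()
                 - gammaln(n + 1))


class _BudgetExceeded(Exception):
    pass


def _enumerate_exact(row_m, col_m, log_p_obs, budget):
    """Two-sided exact p: sum probabilities of all fixed-margin tables no
    more probable than the observed one. Recursion fills row by row."""
    r = len(row_m)
    state = {"p": 0.0, "count": 0}

    def rec_row(i, rem_cols, acc):
        if state["count"] > budget:
            raise _BudgetExceeded
        if i == r - 1:
            # last row forced by the remaining column margins
            state["count"] += 1
            lp = acc - gammaln(rem_cols + 1).sum()
            if lp <= log_p_obs + _LOG_REL_TOL:
                state["p"] += math.exp(lp)
            return
        # enumerate compositions of row_m[i] bounded by rem_cols
        def rec_cell(j, left, rem, acc2):
            if j == len(rem) - 1:
                if left <= rem[j]:
                    rem2 = rem.copy()
                    rem2[j] -= left
                    rec_row(i + 1, rem2, acc2 - gammaln(left + 1))
                return
            hi = min(left, rem[j])
            lo = max(0, left - rem[j + 1:].sum())
            for x in range(lo, hi + 1):
                rem2 = rem.copy()
                rem2[j] -= x
                rec_cell(j + 1, left - x, rem2, acc2 - gammaln(x + 1))

        rec_cell(0, int(row_m[i]), rem_cols, acc)

    rec_row(0, col_m.astype(int).copy(), _log_table_prob_const(row_m, col_m))
    return min(state["p"], 1.0), state["count"]


def fisher_exact(
    table,
    budget: int = 500_000,
    n_mc: int = 200_000,
    seed: int = 0,
) -> FisherResult:
    """Two-sided Fisher exact test of independence for an r x c table.

    Probability-ordering convention: the p-value sums the null (fixed-margin
    multivariate hypergeometric) probabilities of every table whose
    probability does not exceed the observed table's. When the number of
    fixed-margin tables exceeds ``budget``, a seeded Monte-Carlo estimate
    (Patefield sampler) is returned with its standard error."""
    T = np.asarray(table, dtype=int)
    if T.ndim != 2 or (T < 0).any():
        raise GroupAnalysisError("table must be a 2-D array of counts >= 0")
    row_m, col_m = T.sum(axis=1), T.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        raise GroupAnalysisError("degenerate table: all-zero row or column")
    const = _log_table_prob_const(row_m, col_m)
    log_p_obs = const - float(gammaln(T + 1).sum())
    try:
        p, n_tab = _enumerate_exact(row_m, col_m, log_p_obs, budget)
        return FisherResult(p_value=p, method="exact", n_tables=n_tab)
    except _BudgetExceeded:
        pass
    rng = np.random.default_rng(seed)
    dist = stats.random_table(row_m, col_m)
    samples = dist.rvs(size=n_mc, random_state=rng)
    lps = const - gammaln(samples + 1).sum(axis=(1, 2))
    hits = int((lps <= log_p_obs + _LOG_REL_TOL).sum())
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return FisherResult(p_value=min(p, 1.0), method="monte_carlo",
                        n_tables=n_mc, mc_se=se)


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

def _normalize_categorical(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col.map({True: "yes", False: "no"})
    return col.astype(str).where(col.notna(), other=pd.NA)


def _is_continuous(col: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(col) and col.dtype != bool


def univariate_screen(
    labeling: GroupLabeling,
    covariates: pd.DataFrame,
    alpha_in: float = DEFAULT_ALPHA_IN,
    variables: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """Per-variable tests of the high/low contrast.

    Categorical variables get Fisher's exact test on the level x group
    contingency table ("not_applicable" rows excluded per variable);
    continuous variables get Welch's unequal-variance t-test. Returns the
    test table and the list of variables with p strictly below ``alpha_in``.
    """
    labels = labeling.labels
    cov = covariates.loc[labels.index]
    rows = []
    for var in (variables or cov.columns):
        col = cov[var]
        if _is_continuous(col):
            ok = col.notna()
            a = col[ok & (labels == "high")].to_numpy(dtype=float)
            b = col[ok & (labels == "low")].to_numpy(dtype=float)
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"variable": var, "test": "welch_t",
                         "statistic": float(t), "p_value": float(p)})
        else:
            c = _normalize_categorical(col)
            ok = c.notna() & (c != NOT_APPLICABLE)
            tab = pd.crosstab(c[ok], labels[ok])
            res = fisher_exact(tab.to_numpy(), seed=seed)
            rows.append({"variable": var, "test": "fisher_exact",
                         "statistic": math.nan, "p_value": res.p_value})
    frame = pd.DataFrame(rows)
    selected = frame.loc[frame["p_value"] < alpha_in, "variable"].tolist()
    return frame, selected


# ---------------------------------------------------------------------------
# Design matrix, VIF, logistic model
# ---------------------------------------------------------------------------

def build_design(
    covariates: pd.DataFrame,
    terms: Sequence[str],
    references: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Dummy-coded design matrix for the given variables.

    Categorical variables are coded against their reference level
    (column names ``var[level]``); continuous variables enter linearly.
    Rows with missing values or a "not_applicable" level in any term are
    dropped (complete-case). Returns (X, variable -> column names)."""
    refs = dict(DEFAULT_REFERENCES)
    refs.update(references or {})
    pieces, var_cols = [], {}
    keep = pd.Series(True, index=covariates.index)
    for var in terms:
        col = covariates[var]
        if _is_continuous(col):
            keep &= col.notna()
        else:
            c = _normalize_categorical(col)
            keep &= c.notna() & (c != NOT_APPLICABLE)
    for var in terms:
        col = covariates.loc[keep, var]
        if _is_continuous(col):
            pieces.append(col.astype(float).rename(var))
            var_cols[var] = [var]
        else:
            c = _normalize_categorical(col)
            levels = sorted(c.unique())
            ref = refs.get(var)
            if ref in levels:
                levels.remove(ref)
            else:
                warnings.warn(
                    f"reference level {ref!r} absent for {var}; "
                    f"using {levels[0]!r}", stacklevel=2)
                levels = levels[1:]
            names = []
            for lev in levels:
                name = f"{var}[{lev}]"
                pieces.append((c == lev).astype(float).rename(name))
                names.append(name)
            var_cols[var] = names
    X = pd.concat(pieces, axis=1)
    return X, var_cols


@dataclass
class VifReport:
    vifs: dict                    # final per-column VIF
    dropped: list                 # column names removed, in drop order
    retained_columns: list
    retained_variables: list


def check_collinearity(
    covariates: pd.DataFrame,
    selected: Sequence[str],
    vif_threshold: float = DEFAULT_VIF_THRESHOLD,
    references: Mapping[str, str] | None = None,
) -> VifReport:
    """Variance inflation factors on the dummy-coded design; columns above
    the threshold are dropped iteratively (highest first; exact-collinearity
    ties drop the later-ordered column) until all are below it."""
    if not selected:
        raise GroupAnalysisError("no selected variables to check")
    X, var_cols = build_design(covariates, selected, references)
    cols = list(X.columns)
    dropped = []
    while len(cols) > 1:
        A = sm.add_constant(X[cols].to_numpy(dtype=float), has_constant="add")
        with np.errstate(divide="ignore", invalid="ignore"):
            vifs = np.array([
                _vif(A, k + 1) for k in range(len(cols))
            ])
        if np.nanmax(vifs) <= vif_threshold:
            break
        if np.isinf(vifs).any():
            k = int(np.flatnonzero(np.isinf(vifs))[-1])   # later-ordered copy
            warnings.warn(
                f"perfect collinearity: dropping {cols[k]!r}", stacklevel=2)
        else:
            k = int(np.nanargmax(vifs))
        dropped.append(cols.pop(k))
    A = sm.add_constant(X[cols].to_numpy(dtype=float), has_constant="add")
    with np.errstate(divide="ignore", invalid="ignore"):
        final = {c: _vif(A, k + 1) for k, c in enumerate(cols)}
    retained_vars = [v for v, names in var_cols.items()
                     if any(nm in cols for nm in names)]
    return VifReport(vifs=final, dropped=dropped,
                     retained_columns=cols, retained_variables=retained_vars)


def _vif(exog: np.ndarray, idx: int) -> float:
    """1 / (1 - R^2) of column idx regressed on the remaining columns."""
    y = exog[:, idx]
    others = np.delete(exog, idx, axis=1)
    res = sm.OLS(y, others).fit()
    r2 = res.rsquared
    return math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)


@dataclass
class LogisticModel:
    """Multivariate logistic fit of high vs low exposure group.

    ``terms`` rows: variable, level ('' for continuous), coefficient, se,
    odds_ratio = exp(coefficient), ci_low/ci_high = exp(coef -/+ 1.96 se).
    ``variable_lrt_p`` holds drop-one likelihood-ratio p-values."""

    terms: pd.DataFrame
    variable_lrt_p: dict
    reference_levels: dict
    n_obs: int
    n_events: int
    llf: float
    intercept: float
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out["lrt_p"] = out["variable"].map(self.variable_lrt_p)
        return out


def fit_logistic(
    labeling: GroupLabeling,
    covariates: pd.DataFrame,
    terms: Sequence[str],
    references: Mapping[str, str] | None = None,
) -> LogisticModel:
    """Maximum-likelihood logistic regression of group membership.

    Per-variable p-values come from drop-one likelihood-ratio tests
    (chi-square with one df per dummy column removed). Fewer than ~10
    events per parameter triggers a warning; non-convergence and complete
    separation raise."""
    refs = dict(DEFAULT_REFERENCES)
    refs.update(references or {})
    cov = covariates.loc[labeling.labels.index]
    X, var_cols = build_design(cov, list(terms), refs)
    y = (labeling.labels.loc[X.index] == "high").astype(float)
    n_events = int(y.sum())
    n_params = X.shape[1] + 1
    if n_events < 10 * n_params:
        warnings.warn(
            f"{n_events} events for {n_params} parameters "
            "(< 10 events per parameter)", stacklevel=2)

    def _fit(Xd):
        Xc = sm.add_constant(Xd.to_numpy(dtype=float), has_constant="add")
        model = sm.Logit(y.to_numpy(), Xc)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception as exc:   # PerfectSeparationError and friends
            raise GroupAnalysisError(
                f"logistic fit failed ({type(exc).__name__}): {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise GroupAnalysisError(
                f"logistic fit did not converge: {res.mle_retvals}")
        return res

    full = _fit(X)
    coefs = full.params[1:]
    ses = full.bse[1:]
    rows = []
    for k, col in enumerate(X.columns):
        var = next(v for v, names in var_cols.items() if col in names)
        level = col[len(var) + 1:-1] if col != var else ""
        b, se = float(coefs[k]), float(ses[k])
        rows.append({
            "variable": var, "level": level, "coefficient": b,
            "se": se, "odds_ratio": math.exp(b),
            "ci_low": math.exp(b - Z_95 * se),
            "ci_high": math.exp(b + Z_95 * se),
        })
    terms_df = pd.DataFrame(rows)
    # internal consistency: OR = exp(beta), CI brackets OR
    assert np.allclose(terms_df["odds_ratio"],
                       np.exp(terms_df["coefficient"]))
    assert (terms_df["ci_low"] <= terms_df["odds_ratio"] + 1e-12).all()
    assert (terms_df["odds_ratio"] <= terms_df["ci_high"] + 1e-12).all()

    lrt = {}
    for var in terms:
        cols_v = var_cols[var]
        reduced_cols = [c for c in X.columns if c not in cols_v]
        if reduced_cols:
            red = _fit(X[reduced_cols])
        else:   # intercept-only reduced model
            red = sm.Logit(y.to_numpy(), np.ones((len(y), 1))).fit(disp=0)
        stat = 2 * (full.llf - red.llf)
        lrt[var] = float(stats.chi2.sf(max(stat, 0.0), df=len(cols_v)))

    return LogisticModel(
        terms=terms_df,
        variable_lrt_p=lrt,
        reference_levels={v: refs.get(v, "") for v in terms
                          if var_cols[v] and "[" in var_cols[v][0]},
        n_obs=int(len(y)),
        n_events=n_events,
        llf=float(full.llf),
        intercept=float(full.params[0]),
    )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def table1_frame(
    labeling: GroupLabeling,
    covariates: pd.DataFrame,
    screen: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Characteristics table: per categorical level, counts and column
    percentages (half-up, 1 decimal) in the low and high groups; per
    continuous variable, medians and ranges."""
    labels = labeling.labels
    cov = covariates.loc[labels.index]
    pmap = {} if screen is None else dict(
        zip(screen["variable"], screen["p_value"]))
    rows = []
    for var in cov.columns:
        col = cov[var]
        if _is_continuous(col):
            vals_low = col[labels == "low"].dropna()
            vals_high = col[labels == "high"].dropna()
            rows.append({
                "variable": var, "level": "median (range)",
                "n_low": float(vals_low.median()),
                "pct_low": math.nan,
                "n_high": float(vals_high.median()),
                "pct_high": math.nan,
                "test": "welch_t", "p_value": pmap.get(var, math.nan),
            })
        else:
            c = _normalize_categorical(col)
            ok = c.notna() & (c != NOT_APPLICABLE)
            tab = pd.crosstab(c[ok], labels[ok])
            for grp in ("low", "high"):
                if grp not in tab.columns:
                    tab[grp] = 0
            tot = tab.sum(axis=0)
            for lev in tab.index:
                rows.append({
                    "variable": var, "level": lev,
                    "n_low": int(tab.loc[lev, "low"]),
                    "pct_low": round_half_up(
                        100 * tab.loc[lev, "low"] / tot["low"], 1),
                    "n_high": int(tab.loc[lev, "high"]),
                    "pct_high": round_half_up(
                        100 * tab.loc[lev, "high"] / tot["high"], 1),
                    "test": "fisher_exact",
                    "p_value": pmap.get(var, math.nan),
                })
    return pd.DataFrame(rows)


def table2_frame(model: LogisticModel) -> pd.DataFrame:
    """Model table: coefficient, SE, drop-one LRT p, OR and 95% CI,
    rounded half-up to 3 decimals."""
    out = model.to_frame()
    for c in ("coefficient", "se", "lrt_p", "odds_ratio", "ci_low", "ci_high"):
        out[c] = out[c].map(lambda v: round_half_up(v, 3))
    return out[["variable", "level", "coefficient", "se", "lrt_p",
                "odds_ratio", "ci_low", "ci_high"]]
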