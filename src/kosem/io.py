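"""CSV / JSON readers and writers for the pipeline's artifact files.

All CSVs are UTF-8 with mandatory headers; numeric columns are written at
full precision (report tables are rounded only by the report formatters).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from kosem.constants import ME_INDEX, MICROENVS, N_MICROENVS, N_SLOTS
from kosem.diaries import Diary, diary_from_codes
from kosem.me_grid import (
    MEASUREMENT_COLUMNS,
    FittedDistribution,
    GridError,
    SlotGrid,
    validate_measurements,
)

SLOT_COLUMNS = [f"s{k:03d}" for k in range(1, N_SLOTS + 1)]


class SchemaError(ValueError):
    pass


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_measurements(path) -> pd.DataFrame:
    """Typed 1-min measurement records; rows with negative pm25, unknown
    microenvironment codes or out-of-range minutes are rejected with a
    line-numbered error (line 1 is the header)."""
    df = _read_csv(path, MEASUREMENT_COLUMNS)
    try:
        return validate_measurements(df)
    except GridError as exc:
        msg = str(exc)
        if msg.startswith("row "):
            row = int(msg.split(":")[0].split()[1])
            raise SchemaError(f"{path}, line {row + 2}: "
                              + msg.split(": ", 1)[1]) from None
        raise SchemaError(f"{path}: {msg}") from None


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(MEASUREMENT_COLUMNS))


def read_correction_factors(path) -> dict:
    df = _read_csv(path, ("run_id", "factor"))
    return dict(zip(df["run_id"], df["factor"].astype(float)))


def write_correction_factors(factors: dict, path) -> None:
    pd.DataFrame({"run_id": list(factors),
                  "factor": list(factors.values())}).to_csv(path, index=False)


def read_diaries(path, covariates_path=None) -> list:
    """Wide diary CSV (subject_id, day_type, s001..s144) plus an optional
    covariate table keyed by subject_id."""
    df = _read_csv(path, ["subject_id", "day_type"] + SLOT_COLUMNS)
    cov = None
    if covariates_path is not None:
        cov = read_covariates(covariates_path)
    diaries = []
    for i, row in enumerate(df.itertuples(index=False)):
        codes = [getattr(row, c) for c in SLOT_COLUMNS]
        covs = {}
        if cov is not None:
            if row.subject_id not in cov.index:
                raise SchemaError(
                    f"{covariates_path}: no covariates for subject "
                    f"{row.subject_id!r}")
            covs = cov.loc[row.subject_id].to_dict()
        try:
            diaries.append(diary_from_codes(
                row.subject_id, row.day_type, codes, covariates=covs))
        except ValueError as exc:
            raise SchemaError(f"{path}, line {i + 2}: {exc}") from None
    return diaries


def write_diaries(diaries: Sequence[Diary], path) -> None:
    rows = []
    for d in diaries:
        row = {"subject_id": d.subject_id, "day_type": d.day_type}
        row.update(dict(zip(SLOT_COLUMNS, d.slot_codes())))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    df = _read_csv(path, ("subject_id",))
    return df.set_index("subject_id")


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, index=True)


def write_grid(grid: SlotGrid, path) -> None:
    grid.to_frame().to_csv(path, index=False)


def read_grid(path, min_obs_per_cell: int | None = None) -> SlotGrid:
    """Rebuild a SlotGrid (summaries + fitted distributions, not raw data)
    from the grid summary CSV written by ``write_grid``."""
    df = _read_csv(path, ("slot", "microenv", "n_obs", "mean", "sd",
                          "family", "params_json", "available"))
    n_obs = np.zeros((N_SLOTS, N_MICROENVS), dtype=int)
    means = np.full((N_SLOTS, N_MICROENVS), np.nan)
    sds = np.full((N_SLOTS, N_MICROENVS), np.nan)
    avail = np.zeros((N_SLOTS, N_MICROENVS), dtype=bool)
    fits = {}
    for row in df.itertuples(index=False):
        t, j = int(row.slot), ME_INDEX[row.microenv]
        n_obs[t - 1, j] = int(row.n_obs)
        means[t - 1, j] = float(row.mean)
        sds[t - 1, j] = float(row.sd)
        avail[t - 1, j] = bool(row.available)
        if isinstance(row.family, str) and row.family:
            fits[(t, row.microenv)] = FittedDistribution(
                family=row.family,
                params=json.loads(row.params_json),
                fit_score=float(row.fit_score)
                if "fit_score" in df.columns and not pd.isna(row.fit_score)
                else math.nan,
            )
    if min_obs_per_cell is None:
        min_obs_per_cell = int(n_obs[avail].min()) if avail.any() else 1
    return SlotGrid(n_obs=n_obs, means=means, sds=sds, available=avail,
                    min_obs_per_cell=min_obs_per_cell, fits=fits)


def write_exposures(exposures: pd.DataFrame, path) -> None:
    exposures.to_csv(path, index=False)


def read_exposures(path) -> pd.DataFrame:
    return _read_csv(path, ("subject_id", "exposure_ugm3", "minutes_used",
                            "n_excluded_slots"))


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyJSONEncoder)
        + "\n")
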