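"""Cross-sectional time binning and residual age acceleration.

Serial samples over the 14 days post-injury are collapsed into five
cross-sectional time bins (days 0-2, 3-5, 6-8, 9-11, 12-14).  Age
acceleration is the residual of DNAm age regressed on chronological age
within each (clock, tissue, time-bin) stratum — positive residuals mean the
methylome looks older than expected for the chronological age.  The adjusted
flavor additionally includes K-1 putative cell-type proportions as covariates
(the least-variable cell type is excluded to break the simplex constraint).
Extreme DNAm ages are flagged with Tukey fences at 3 x IQR but retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "assign_time_bin",
    "filter_blood_to_time1",
    "residual_acceleration",
    "flag_outliers",
    "build_acceleration_table",
    "RankDeficientError",
]

#: Inclusive day ranges for the five cross-sectional time bins.
TIME_BINS = {1: (0, 2), 2: (3, 5), 3: (6, 8), 4: (9, 11), 5: (12, 14)}


class RankDeficientError(np.linalg.LinAlgError):
    """OLS design matrix is rank deficient; names the collinear columns."""


def assign_time_bin(day: int) -> int | None:
    """Map a day post-injury to its time bin (1-5), or None outside 0-14."""
    day = int(day)
    for idx, (lo, hi) in TIME_BINS.items():
        if lo <= day <= hi:
            return idx
    return None


def filter_blood_to_time1(sheet: pd.DataFrame) -> pd.DataFrame:
    """Drop blood rows outside time bin 1 (days 0-2); CSF rows untouched.

    Blood is collected essentially only in the first window, so the handful of
    blood samples outside it are excluded from cross-tissue analyses.
    """
    bins = sheet["day"].map(assign_time_bin)
    keep = (sheet["tissue"] != "blood") | (bins == 1)
    return sheet.loc[keep].copy()


def residual_acceleration(
    ages: np.ndarray | pd.Series,
    dnam_ages: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> np.ndarray:
    """OLS residuals of DNAm age on chronological age (+ optional covariates).

    Fits ``dnam_age ~ 1 + age [+ covariates]`` by ordinary least squares and
    returns the residual vector — the age-acceleration values for one
    stratum.  Residuals have mean zero and zero sample covariance with every
    regressor, by the normal equations.

    Raises
    ------
    RankDeficientError
        If the design matrix is rank deficient (e.g. a constant or collinear
        covariate), naming the offending columns.
    ValueError
        If there are fewer than p + 2 observations for p regressors, or any
        missing values.
    """
    y = np.asarray(dnam_ages, dtype=float)
    a = np.asarray(ages, dtype=float)
    if y.shape != a.shape or y.ndim != 1:
        raise ValueError("ages and dnam_ages must be 1-D and equally long")
    cols = ["intercept", "age"]
    X = [np.ones_like(a), a]
    if covariates is not None:
        C = pd.DataFrame(covariates)
        cols += [str(c) for c in C.columns]
        X += [C[c].to_numpy(dtype=float) for c in C.columns]
    X = np.column_stack(X)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in stratum")
    p = X.shape[1] - 1
    if len(y) < p + 2:
        raise ValueError(f"stratum too small: {len(y)} observations for {p} regressors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(cols[j])
            r = rj
        raise RankDeficientError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def flag_outliers(dnam_ages: np.ndarray | pd.Series, multiplier: float = 3.0, two_sided: bool = True) -> np.ndarray:
    """Tukey-fence outlier flags on DNAm age within a stratum.

    Flags values outside [Q1 - multiplier*IQR, Q3 + multiplier*IQR] (or only
    above the upper fence when ``two_sided=False``).  Quartiles use the
    linear-interpolation convention (numpy default, R type 7).  Flagged
    observations are reported, not removed.
    """
    x = np.asarray(dnam_ages, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations to compute fences")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    hi = x > q3 + multiplier * iqr
    if not two_sided:
        return hi
    lo = x < q1 - multiplier * iqr
    return lo | hi


def build_acceleration_table(
    sheet: pd.DataFrame,
    dnam_ages: pd.DataFrame,
    cell_props: pd.DataFrame | None = None,
    min_stratum: int | None = None,
) -> pd.DataFrame:
    """Per-sample residual age acceleration across clocks, strata and flavors.

    Joins the DNAm-age table (rows indexed by sample_id, columns ``clock``,
    ``dnam_age``) with the sample sheet, computes residual acceleration
    separately within every (clock, tissue, time_bin) stratum, and — when
    ``cell_props`` is given (samples x proportions with the dropped cell
    already excluded) — a second, cell-type-adjusted flavor.  Samples with
    missing covariates are excluded from the adjusted flavor only.  Strata
    with too few observations are skipped with a warning.

    Returns a long table: sample_id, participant_id, clock, tissue, time_bin,
    flavor, residual, outlier_flag.
    """
    meta = sheet.set_index("sample_id")
    if "time_bin" not in meta.columns:
        meta = meta.assign(time_bin=meta["day"].map(assign_time_bin))
    rows: list[pd.DataFrame] = []
    for clock_name, tbl in dnam_ages.groupby("clock"):
        joined = tbl.join(meta[["participant_id", "tissue", "day", "age", "time_bin"]], how="inner")
        for (tissue, time_bin), stratum in joined.groupby(["tissue", "time_bin"], dropna=True):
            flavors: dict[str, pd.DataFrame] = {"unadjusted": stratum}
            if cell_props is not None:
                adj = stratum.join(cell_props, how="inner").dropna(subset=list(cell_props.columns))
                flavors["cth_adjusted"] = adj
            for flavor, data in flavors.items():
                covs = data[list(cell_props.columns)] if flavor == "cth_adjusted" else None
                if covs is not None:
                    # constant-within-stratum proportions carry no information and
                    # would make the design rank deficient; drop them here so the
                    # adjusted flavor degrades gracefully to the unadjusted fit
                    spread = covs.std(ddof=0)
                    covs = covs.loc[:, spread > 1e-12 * (covs.abs().mean() + 1.0)]
                    if covs.shape[1] == 0:
                        covs = None
                p = 1 + (0 if covs is None else covs.shape[1])
                needed = max(p + 2, min_stratum or 0, 4)
                if len(data) < needed:
                    warnings.warn(
                        f"stratum skipped ({clock_name}/{tissue}/bin {time_bin}/{flavor}): "
                        f"{len(data)} < {needed} observations",
                        stacklevel=2,
                    )
                    continue
                resid = residual_acceleration(data["age"], data["dnam_age"], covs)
                flags = flag_outliers(data["dnam_age"])
                rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": data.index,
                            "participant_id": data["participant_id"].to_numpy(),
                            "clock": clock_name,
                            "tissue": tissue,
                            "time_bin": int(time_bin),
                            "flavor": flavor,
                            "residual": resid,
                            "outlier_flag": flags,
                        }
                    )
                )
    if not rows:
        return pd.DataFrame(
            columns=["sample_id", "participant_id", "clock", "tissue", "time_bin", "flavor", "residual", "outlier_flag"]
        )
    return pd.concat(rows, ignore_index=True)
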