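"""ROI-level brain-behavior regression with Benjamini-Hochberg FDR.

Each region's measure (subcortical volume in mm^3 or ROI-mean cortical
thickness in mm) is regressed on the behavioral sensitivity index with age
as a covariate — plus intracranial volume for volumes, since larger heads
have larger structures — and the per-ROI sensitivity p-values are corrected
across regions with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

MODES = ("volume", "thickness")


def _ols_t(y: np.ndarray, X: np.ndarray, col: int) -> tuple[float, float, float, int]:
    """OLS fit; returns (beta, t, p, df) for design column ``col``."""
    n, p_full = X.shape
    df = n - p_full
    if df < 1:
        raise ValidationError("not enough subjects for the requested predictors")
    if np.linalg.matrix_rank(X) < p_full:
        raise ValidationError("rank-deficient ROI design matrix")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * xtx_inv[col, col])
    t = beta[col] / se if se > 0 else np.sign(beta[col]) * np.inf
    p = 2 * stats.t.sf(abs(t), df)
    return float(beta[col]), float(t), float(p), df


def roi_regression(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    mode: str = "volume",
    *,
    include_sex: bool = False,
    target: str = "sensitivity",
) -> pd.DataFrame:
    """Per-ROI regression of the measure on the sensitivity index.

    ``mode='volume'`` adds intracranial volume (``icv``) to the predictors;
    ``mode='thickness'`` uses sensitivity and age only.  Returns one row per
    (roi_name, hemisphere) with the sensitivity slope, t and two-sided p.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    predictors = [target, "age"] + (["icv"] if mode == "volume" else [])
    if include_sex:
        predictors.append("sex")
    missing = [p for p in predictors if p not in covariates.columns]
    if missing:
        raise ValidationError(f"missing covariates: {missing}")
    cov = covariates.set_index("subject_id")
    rows = []
    for (name, hemi), cell in table.groupby(["roi_name", "hemisphere"], sort=True):
        cell = cell.set_index("subject_id")
        joined = cell.join(cov, how="inner")
        if len(joined) < len(cell):
            raise ValidationError(
                f"covariates missing for some subjects of ROI {(name, hemi)!r}"
            )
        X = np.column_stack(
            [np.ones(len(joined))] + [joined[p].to_numpy(dtype=float) for p in predictors]
        )
        beta, t, p, df = _ols_t(joined["value"].to_numpy(dtype=float), X, 1)
        rows.append(
            {
                "roi_name": name,
                "hemisphere": hemi,
                "beta": beta,
                "t": t,
                "p": p,
                "df": df,
                "n": len(joined),
            }
        )
    return pd.DataFrame(rows)


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over ``m`` p-values at level ``q``.

    Returns (reject flags, adjusted p-values); adjusted p-values are monotone
    in the raw-p ranks and invariant to input order.  Empty input yields
    empty output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def roi_analysis(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    mode: str = "volume",
    q: float = 0.05,
    *,
    include_sex: bool = False,
) -> pd.DataFrame:
    """ROI regressions plus BH-FDR correction across all ROIs."""
    res = roi_regression(table, covariates, mode, include_sex=include_sex)
    reject, p_adj = bh_fdr(res["p"].to_numpy(), q)
    res = res.copy()
    res["p_fdr"] = p_adj
    res["significant"] = reject
    return res
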