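"""Ordinal (proportional-odds) inference for regularity-rating data.

The behavioral outcome is an ordinal rating (1-7) of how structured an
auditory sequence sounded.  The group-level analysis is a cumulative-logit
(proportional-odds) regression of ratings on statistical-structure level,
with repeated measures handled by a cluster-robust (subject-level sandwich)
covariance; the per-subject analysis fits the same model within each subject
and summarizes sensitivity to structure as the 2-df omnibus Wald chi-square
of the condition effect.

The cumulative-logit model for a J-category outcome is

    P(Y <= j | x) = logistic(theta_j - x' beta),   j = 1..J-1,

with strictly increasing thresholds theta and a single slope vector beta
shared across category boundaries (the proportional-odds assumption, checked
by ``parallel_lines_test``).  With this sign convention exp(beta_k) is the
odds ratio of being in a *higher* rating category per unit of predictor k.

Fitting is by Newton scoring on the analytic gradient/Hessian with
step-halving; no external regression library is involved, which keeps the
per-subject index and its degenerate-fit diagnostics fully under the
package's control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NumericalError, SeparationError, ValidationError

CONDITION_ORDER: tuple[str, ...] = ("low", "mid", "high")

# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class OrdinalFit:
    """A fitted proportional-odds model.

    Parameters are ordered thresholds first (one per boundary between the
    ``J`` observed categories) then one slope per predictor column.
    ``cov`` is the model-based (inverse observed information) covariance of
    the full parameter vector; ``cov_robust`` is the cluster-sandwich
    covariance when cluster ids were supplied, else None.
    """

    thresholds: np.ndarray
    slopes: np.ndarray
    cov: np.ndarray
    cov_robust: np.ndarray | None
    loglik: float
    J: int
    n_obs: int
    n_iter: int
    converged: bool
    term_names: tuple[str, ...]
    y_levels: np.ndarray

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.thresholds, self.slopes])

    @property
    def slope_cov(self) -> np.ndarray:
        """Covariance of the slope block (robust if available)."""
        cov = self.cov_robust if self.cov_robust is not None else self.cov
        k = self.thresholds.size
        return cov[k:, k:]


@dataclass
class SensitivityIndex:
    """Per-subject sensitivity to statistical structure.

    ``wald_chi2`` is the omnibus Wald statistic (df = number of condition
    dummies) from that subject's own ordinal regression; invalid flags mark
    degenerate fits (single rating category, separation, non-convergence).
    """

    subject_id: object
    wald_chi2: float
    df: int
    valid: bool
    message: str = ""


# ---------------------------------------------------------------------------
# Cumulative-logit likelihood machinery
# ---------------------------------------------------------------------------

_SEPARATION_BOUND = 15.0  # |slope| on the log-odds scale implying separation


def _as_design(predictors) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(predictors, pd.DataFrame):
        return predictors.to_numpy(dtype=float), tuple(map(str, predictors.columns))
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, tuple(f"x{i}" for i in range(X.shape[1]))


def _encode_outcome(outcome) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(outcome)
    levels, y01 = np.unique(y, return_inverse=True)
    return y01, levels


def _sigma(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def cumulative_logit_loglik(
    theta: np.ndarray, beta: np.ndarray, y01: np.ndarray, X: np.ndarray
) -> float:
    """Log-likelihood of the shared-slope cumulative-logit model."""
    eta = X @ beta
    upper = np.where(y01 < theta.size, _sigma(theta[np.minimum(y01, theta.size - 1)] - eta), 1.0)
    lower = np.where(y01 > 0, _sigma(theta[np.maximum(y01 - 1, 0)] - eta), 0.0)
    p = np.clip(upper - lower, 1e-300, None)
    return float(np.log(p).sum())


def _grad_hess(
    theta: np.ndarray, beta: np.ndarray, y01: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradient, observed Hessian, and per-observation score matrix."""
    n, p_dim = X.shape
    q = theta.size
    eta = X @ beta
    has_u = y01 < q
    has_l = y01 > 0
    ju = np.minimum(y01, q - 1)
    jl = np.maximum(y01 - 1, 0)
    sig_u = np.where(has_u, _sigma(theta[ju] - eta), 1.0)
    sig_l = np.where(has_l, _sigma(theta[jl] - eta), 0.0)
    phi_u = np.where(has_u, sig_u * (1 - sig_u), 0.0)
    phi_l = np.where(has_l, sig_l * (1 - sig_l), 0.0)
    prob = np.clip(sig_u - sig_l, 1e-300, None)
    su = phi_u / prob
    sl = phi_l / prob
    # per-observation scores
    scores = np.zeros((n, q + p_dim))
    rows = np.arange(n)
    np.add.at(scores, (rows[has_u], ju[has_u]), su[has_u])
    np.add.at(scores, (rows[has_l], jl[has_l]), -sl[has_l])
    scores[:, q:] = -X * (su - sl)[:, None]
    grad = scores.sum(axis=0)
    # observed Hessian
    dphi_u = phi_u * (1 - 2 * sig_u)
    dphi_l = phi_l * (1 - 2 * sig_l)
    a_uu = np.where(has_u, dphi_u / prob, 0.0) - su**2
    a_ll = np.where(has_l, -dphi_l / prob, 0.0) - sl**2
    a_ul = su * sl
    H = np.zeros((q + p_dim, q + p_dim))
    np.add.at(H, (ju[has_u], ju[has_u]), a_uu[has_u])
    np.add.at(H, (jl[has_l], jl[has_l]), a_ll[has_l])
    both = has_u & has_l
    np.add.at(H, (ju[both], jl[both]), a_ul[both])
    np.add.at(H, (jl[both], ju[both]), a_ul[both])
    # theta-beta block: row j_u gets -x(a_uu + a_ul), row j_l gets -x(a_ll + a_ul)
    tb = np.zeros((q, p_dim))
    wu = np.where(has_u, a_uu, 0.0) + np.where(both, a_ul, 0.0)
    wl = np.where(has_l, a_ll, 0.0) + np.where(both, a_ul, 0.0)
    np.add.at(tb, ju[has_u], -X[has_u] * wu[has_u, None])
    np.add.at(tb, jl[has_l], -X[has_l] * wl[has_l, None])
    H[:q, q:] = tb
    H[q:, :q] = tb.T
    w_bb = np.where(has_u, a_uu, 0.0) + np.where(has_l, a_ll, 0.0) + 2 * np.where(both, a_ul, 0.0)
    H[q:, q:] = (X * w_bb[:, None]).T @ X
    return grad, H, scores


def fit_proportional_odds(
    outcome,
    predictors,
    cluster_ids=None,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> OrdinalFit:
    """Fit the shared-slope cumulative-logit model by Newton scoring.

    ``outcome`` is an ordinal response (any orderable values; thresholds are
    defined over the observed categories only).  ``predictors`` is a design
    matrix or DataFrame *without* an intercept (the thresholds absorb it).
    When ``cluster_ids`` is given a cluster-sandwich robust covariance is
    attached (independence working model), which is how repeated measures
    within subjects are handled.
    """
    X, term_names = _as_design(predictors)
    y01, levels = _encode_outcome(outcome)
    n, p_dim = X.shape
    if y01.size != n:
        raise ValidationError("outcome and predictors have different lengths")
    J = levels.size
    if J < 2:
        raise ValidationError("outcome has a single observed category; model undefined")
    if p_dim and np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p_dim + 1:
        raise ValidationError("predictor matrix is rank deficient")

    # start: empirical cumulative logits, zero slopes
    cum = np.cumsum(np.bincount(y01, minlength=J))[:-1] / n
    cum = np.clip(cum, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    theta = np.log(cum / (1 - cum))
    beta = np.zeros(p_dim)
    ll = cumulative_logit_loglik(theta, beta, y01, X)
    trace = [ll]
    converged = False
    for it in range(1, max_iter + 1):
        grad, H, _ = _grad_hess(theta, beta, y01, X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular information matrix at iteration {it}") from exc
        step = -step  # ascend: H is the (negative-definite) Hessian
        scale = 1.0
        for _ in range(40):
            theta_new = theta + scale * step[: theta.size]
            beta_new = beta + scale * step[theta.size :]
            if np.all(np.diff(theta_new) > 0):
                ll_new = cumulative_logit_loglik(theta_new, beta_new, y01, X)
                if ll_new >= ll - 1e-12:
                    break
            scale *= 0.5
        else:
            raise NumericalError(
                f"step-halving failed to improve the likelihood at iteration {it}; "
                f"trace={np.round(trace, 6).tolist()}"
            )
        theta, beta = theta_new, beta_new
        improved = ll_new - ll
        ll = ll_new
        trace.append(ll)
        if p_dim and np.max(np.abs(beta)) > _SEPARATION_BOUND:
            worst = term_names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"separation suspected: |coefficient| of {worst!r} exceeds "
                f"{_SEPARATION_BOUND} on the log-odds scale"
            )
        if abs(improved) < tol * (abs(ll) + 1.0):
            converged = True
            break
    if not converged:
        raise NumericalError(
            f"no convergence in {max_iter} iterations; log-likelihood trace tail="
            f"{np.round(trace[-5:], 6).tolist()}"
        )

    grad, H, scores = _grad_hess(theta, beta, y01, X)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("observed information is singular at the optimum") from exc
    cov_robust = None
    if cluster_ids is not None:
        cl = np.asarray(cluster_ids)
        if cl.size != n:
            raise ValidationError("cluster_ids length must match the data")
        _, inv = np.unique(cl, return_inverse=True)
        g = np.zeros((inv.max() + 1, scores.shape[1]))
        np.add.at(g, inv, scores)
        bread = cov
        meat = g.T @ g
        cov_robust = bread @ meat @ bread
    return OrdinalFit(
        thresholds=theta,
        slopes=beta,
        cov=cov,
        cov_robust=cov_robust,
        loglik=ll,
        J=J,
        n_obs=n,
        n_iter=it,
        converged=converged,
        term_names=term_names,
        y_levels=levels,
    )


# ---------------------------------------------------------------------------
# Wald inference
# ---------------------------------------------------------------------------


def _slope_indices(fit: OrdinalFit, which) -> np.ndarray:
    if which is None:
        return np.arange(len(fit.term_names))
    idx = []
    for w in which if isinstance(which, (list, tuple)) else [which]:
        if isinstance(w, str):
            if w not in fit.term_names:
                raise ValidationError(f"unknown predictor {w!r}; terms: {fit.term_names}")
            idx.append(fit.term_names.index(w))
        else:
            idx.append(int(w))
    return np.asarray(idx, dtype=int)


def wald_omnibus(fit: OrdinalFit, which=None) -> tuple[float, int, float]:
    """Wald chi-square of a block of slope coefficients (robust cov if present).

    Returns ``(chi2, df, p)`` where df is the block size.
    """
    idx = _slope_indices(fit, which)
    b = fit.slopes[idx]
    V = fit.slope_cov[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular covariance in Wald test") from exc
    chi2 = max(chi2, 0.0)
    df = idx.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def odds_ratio_ci(
    fit: OrdinalFit, contrast, level: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio exp(c'beta) with a Wald confidence interval.

    ``contrast`` is a weight vector over the slope terms (or a name->weight
    mapping).  Reversing the contrast gives the reciprocal OR with swapped
    reciprocal bounds.
    """
    if isinstance(contrast, Mapping):
        c = np.zeros(len(fit.term_names))
        for name, w in contrast.items():
            c[fit.term_names.index(name)] = w
    else:
        c = np.asarray(contrast, dtype=float)
    if c.size != fit.slopes.size:
        raise ValidationError("contrast length must match the number of slopes")
    est = float(c @ fit.slopes)
    se = float(np.sqrt(c @ fit.slope_cov @ c))
    z = stats.norm.ppf(0.5 + level / 2)
    return (np.exp(est), np.exp(est - z * se), np.exp(est + z * se))


def contrast_wald(fit: OrdinalFit, contrast) -> tuple[float, int, float]:
    """1-df Wald chi-square for a single slope contrast."""
    if isinstance(contrast, Mapping):
        c = np.zeros(len(fit.term_names))
        for name, w in contrast.items():
            c[fit.term_names.index(name)] = w
    else:
        c = np.asarray(contrast, dtype=float)
    est = float(c @ fit.slopes)
    var = float(c @ fit.slope_cov @ c)
    if var <= 0:
        raise NumericalError("non-positive contrast variance")
    chi2 = est**2 / var
    return chi2, 1, float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Assumption checks
# ---------------------------------------------------------------------------


def parallel_lines_test(outcome, predictors) -> tuple[float, int, float]:
    """Likelihood-ratio test of the proportional-odds assumption.

    Compares the shared-slope cumulative-logit fit to the varying-location
    model in which each category boundary has its own slopes.  For a
    full-rank categorical design (number of distinct predictor rows equal to
    p+1, e.g. the three-condition design) the varying-location optimum
    coincides with the saturated-by-pattern multinomial, which is how it is
    computed here; other designs are rejected.  df = p * (J - 2).
    """
    X, _ = _as_design(predictors)
    y01, levels = _encode_outcome(outcome)
    J = levels.size
    if J < 3:
        raise ValidationError("parallel-lines test undefined for J < 3 categories")
    p_dim = X.shape[1]
    patterns, pat_idx = np.unique(X, axis=0, return_inverse=True)
    if patterns.shape[0] != p_dim + 1:
        raise ValidationError(
            "parallel-lines test implemented for full-rank categorical designs "
            f"(expected {p_dim + 1} distinct predictor rows, got {patterns.shape[0]})"
        )
    fit = fit_proportional_odds(y01, X)
    # saturated multinomial over (pattern, category) cells
    counts = np.zeros((patterns.shape[0], J))
    np.add.at(counts, (pat_idx, y01), 1.0)
    n_g = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_sat = float(np.where(counts > 0, counts * np.log(counts / n_g), 0.0).sum())
    chi2 = 2.0 * (ll_sat - fit.loglik)
    chi2 = max(chi2, 0.0)
    df = p_dim * (J - 2)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def collinearity_diagnostics(predictors) -> pd.DataFrame:
    """Tolerance and VIF per predictor (each regressed on the others)."""
    X, names = _as_design(predictors)
    n, p_dim = X.shape
    rows = []
    for k in range(p_dim):
        xk = X[:, k]
        others = np.column_stack([np.ones(n), np.delete(X, k, axis=1)])
        sst = float(((xk - xk.mean()) ** 2).sum())
        if sst == 0:
            rows.append({"term": names[k], "r_squared": np.nan, "tolerance": np.nan, "vif": np.inf})
            continue
        coef, *_ = np.linalg.lstsq(others, xk, rcond=None)
        ssr = float(((xk - others @ coef) ** 2).sum())
        r2 = 1.0 - ssr / sst
        tol = max(1.0 - r2, 0.0)
        vif = np.inf if tol == 0 else 1.0 / tol
        rows.append({"term": names[k], "r_squared": r2, "tolerance": tol, "vif": vif})
    return pd.DataFrame(rows)


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic, p)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValidationError("normality check needs at least 3 values")
    if np.ptp(v) == 0:
        raise ValidationError("normality check undefined for constant input")
    w, p = stats.shapiro(v)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Rating-table analyses
# ---------------------------------------------------------------------------


def condition_dummies(conditions, order: Sequence[str] = CONDITION_ORDER) -> pd.DataFrame:
    """Categorical coding of structure level: dummies vs the lowest level."""
    cond = pd.Categorical(conditions, categories=list(order), ordered=True)
    if cond.isna().any():
        raise ValidationError(f"conditions outside {tuple(order)} encountered")
    index = conditions.index if isinstance(conditions, (pd.Series, pd.DataFrame)) else None
    return pd.DataFrame(
        {f"cond_{lvl}": (cond == lvl).astype(float) for lvl in order[1:]},
        index=index,
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def aggregate_group_table(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-subject per-condition mean rating, rounded half-away-from-zero."""
    grouped = (
        ratings.groupby(["subject_id", "category", "condition"], as_index=False)["rating"]
        .mean()
        .rename(columns={"rating": "mean_rating"})
    )
    grouped["rating"] = _round_half_away(grouped["mean_rating"].to_numpy()).astype(int)
    return grouped


def fit_group_rmolr(
    ratings: pd.DataFrame,
    category: str | None = None,
    *,
    aggregated: bool = True,
    order: Sequence[str] = CONDITION_ORDER,
) -> tuple[OrdinalFit, pd.DataFrame]:
    """Group-level repeated-measures ordinal regression of rating on condition.

    With ``aggregated=True`` (the default analysis) each subject contributes
    one rounded mean rating per condition; with False the trial-level table
    is used.  Either way inference is cluster-robust by subject.  Returns the
    fit and a contrast summary (high vs low, mid vs low, high vs mid) with
    odds ratios, 95% CIs, Wald chi-squares and p-values.
    """
    df = ratings if category is None else ratings[ratings["category"] == category]
    if df.empty:
        raise ValidationError(f"no rows for category {category!r}")
    if aggregated:
        df = aggregate_group_table(df)
    X = condition_dummies(df["condition"], order)
    fit = fit_proportional_odds(df["rating"].to_numpy(), X, cluster_ids=df["subject_id"])
    hi, mid = f"cond_{order[2]}", f"cond_{order[1]}"
    contrasts = {
        "high_vs_low": {hi: 1.0},
        "mid_vs_low": {mid: 1.0},
        "high_vs_mid": {hi: 1.0, mid: -1.0},
    }
    rows = []
    for name, c in contrasts.items():
        or_, lo_, hi_ = odds_ratio_ci(fit, c)
        chi2, dfree, p = contrast_wald(fit, c)
        rows.append(
            {
                "contrast": name,
                "odds_ratio": or_,
                "ci_low": lo_,
                "ci_high": hi_,
                "wald_chi2": chi2,
                "df": dfree,
                "p": p,
            }
        )
    omni_chi2, omni_df, omni_p = wald_omnibus(fit)
    rows.append(
        {
            "contrast": "omnibus",
            "odds_ratio": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "wald_chi2": omni_chi2,
            "df": omni_df,
            "p": omni_p,
        }
    )
    return fit, pd.DataFrame(rows)


def subject_sensitivity(
    subject_ratings: pd.DataFrame,
    subject_id=None,
    order: Sequence[str] = CONDITION_ORDER,
) -> SensitivityIndex:
    """Sensitivity index of one subject: 2-df omnibus Wald chi-square.

    Fits an ordinal regression of that subject's ratings on condition
    (categorical, lowest level as reference).  Degenerate fits — a single
    observed rating category, separation, or non-convergence — are flagged
    ``valid=False`` with a diagnostic message rather than raising.
    """
    if subject_id is None:
        subject_id = subject_ratings["subject_id"].iloc[0]
    y = subject_ratings["rating"].to_numpy()
    df_dummies = len(order) - 1
    try:
        X = condition_dummies(subject_ratings["condition"], order)
        fit = fit_proportional_odds(y, X)
        chi2, dfree, _ = wald_omnibus(fit)
        return SensitivityIndex(subject_id, chi2, dfree, True)
    except (SeparationError, NumericalError, ValidationError) as exc:
        return SensitivityIndex(subject_id, np.nan, df_dummies, False, str(exc))


def sensitivity_indices(
    ratings: pd.DataFrame, category: str | None = "speech"
) -> pd.DataFrame:
    """Per-subject sensitivity indices for one stimulus category."""
    df = ratings if category is None else ratings[ratings["category"] == category]
    if df.empty:
        raise ValidationError(f"no rows for category {category!r}")
    rows = []
    for sid, sub in df.groupby("subject_id", sort=True):
        idx = subject_sensitivity(sub, sid)
        rows.append(
            {
                "subject_id": sid,
                "wald_chi2": idx.wald_chi2,
                "df": idx.df,
                "valid": idx.valid,
                "message": idx.message,
            }
        )
    return pd.DataFrame(rows)


def split_half_reliability(ratings: pd.DataFrame) -> pd.DataFrame:
    """Odd/even-trial split-half reliability per category and condition.

    Within each (category, condition) cell, trials are split by presentation
    order (odd = 1st, 3rd, ... in ``trial_index`` order); the per-subject
    half-means are correlated across subjects (Pearson) and corrected to
    full length with the Spearman-Brown formula 2r/(1+r).
    """
    rows = []
    for (cat, cond), cell in ratings.groupby(["category", "condition"], sort=True):
        halves = []
        for sid, sub in cell.groupby("subject_id", sort=True):
            vals = sub.sort_values("trial_index")["rating"].to_numpy(dtype=float)
            halves.append((sid, vals[0::2].mean(), vals[1::2].mean()))
        h = pd.DataFrame(halves, columns=["subject_id", "odd_mean", "even_mean"])
        valid = len(h) >= 3 and h["odd_mean"].std() > 0 and h["even_mean"].std() > 0
        if valid:
            r = float(np.corrcoef(h["odd_mean"], h["even_mean"])[0, 1])
            sb = 2 * r / (1 + r) if r > -1 else np.nan
        else:
            r, sb = np.nan, np.nan
        rows.append(
            {
                "category": cat,
                "condition": cond,
                "n_subjects": len(h),
                "pearson_r": r,
                "split_half": sb,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows)
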