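"""Discrimination and brain-behavior evaluation of severity scores.

ROC/AUC compares how well the multivariate M score and each tract's
univariate |Z| separate patients from controls; Spearman correlations
(with Benjamini-Hochberg FDR over the univariate family) relate the
scores to the cognitive composite, with a bisquare robust fit line for
display.  The orientation convention throughout: higher score = more
patient-like, and the cognitive composite is signed so that higher =
poorer performance, so a positive rho means more injury goes with worse
cognition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .io import CONTROL, PATIENT, ResultTable

#: below this n the Spearman p-value is computed by exact permutation
EXACT_PERMUTATION_N = 10


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class CorrelationResult:
    variable_name: str
    rho: float
    p_value: float
    q_value: float | None = None


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and tie-corrected AUC (higher score = more patient-like).

    The AUC equals the Mann-Whitney statistic
    P(score_patient > score_control) + 0.5 * P(equal).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if g == PATIENT else 0 for g in labels])
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be nonempty")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    # Mann-Whitney form (identical to trapezoidal AUC, stated explicitly)
    u = stats.mannwhitneyu(scores[y == 1], scores[y == 0], alternative="two-sided")
    auc = u.statistic / (y.sum() * (len(y) - y.sum()))
    return RocCurve(thr, fpr, tpr, float(auc))


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    n = len(xr)
    xs = (xr - xr.mean()) / xr.std()
    ys = (yr - yr.mean()) / yr.std()
    count = 0
    total = factorial(n)
    for perm in permutations(range(n)):
        r = float(xs @ ys[list(perm)]) / n
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman(x, y, name: str = "", exact: bool | None = None) -> CorrelationResult:
    """Spearman rank correlation with two-sided p-value.

    Ranks use average ties.  For n below 10 the p-value is an exact
    permutation tail; otherwise the t-approximation (adequate at the
    sample sizes this package targets).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    if exact is None:
        exact = len(x) < EXACT_PERMUTATION_N
    if exact:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        p = _exact_spearman_p(xr, yr, float(rho))
    return CorrelationResult(name, float(rho), float(min(p, 1.0)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def robust_line(x, y, max_iter: int = 100, tol: float = 1e-8):
    """Bisquare (Tukey biweight, c = 4.685) robust line fit by IRLS.

    Scale is the MAD of residuals (/0.6745).  Returns
    ``(slope, intercept, converged)``; on non-convergence the last
    iterate is returned with ``converged=False`` and a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: degenerate design")
    X = sm.add_constant(x)
    rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    fit = rlm.fit(maxiter=max_iter, tol=tol, scale_est="mad")
    converged = bool(getattr(fit, "converged", True))
    if not converged:
        import warnings

        warnings.warn("bisquare IRLS did not converge; returning last iterate")
    return float(fit.params[1]), float(fit.params[0]), converged


def evaluate_discrimination(score_df: pd.DataFrame, tracts) -> ResultTable:
    """One AUC per tract's |Z| plus the multivariate M AUC.

    ``score_df`` is the table from :func:`tractnorm.distances.results_frame`
    with a ``group`` column.  Also reports the best univariate tract and
    whether AUC(M) exceeds it.
    """
    if "group" not in score_df.columns:
        raise ValueError("score table must carry a 'group' column")
    labels = score_df["group"]
    rows = []
    for t in tracts:
        curve = roc_auc(score_df[f"z_{t}"], labels)
        rows.append({"measure": t, "kind": "univariate_z", "auc": curve.auc})
    m_auc = roc_auc(score_df["m_median"], labels).auc
    rows.append({"measure": "M", "kind": "multivariate", "auc": m_auc})
    df = pd.DataFrame(rows).set_index("measure")
    uni = df[df["kind"] == "univariate_z"]["auc"]
    best_tract = uni.idxmax()
    meta = {
        "best_univariate_tract": best_tract,
        "best_univariate_auc": f"{uni.max():.6f}",
        "multivariate_auc": f"{m_auc:.6f}",
        "multivariate_exceeds_best_univariate": bool(m_auc > uni.max()),
    }
    return ResultTable(df, meta)


def evaluate_correlations(
    score_df: pd.DataFrame, composite: pd.Series, tracts
) -> ResultTable:
    """Spearman of M and each tract |Z| against the cognitive composite.

    Computed over patients with a composite score.  The 22-tract
    univariate family is BH-FDR adjusted; the single M correlation is
    reported unadjusted (one planned comparison), its q column left
    missing.
    """
    patients = score_df[score_df["group"] == PATIENT]
    common = patients.index.intersection(composite.dropna().index)
    if len(common) < 4:
        raise ValueError("need >=4 patients with composite scores")
    comp = composite.loc[common].to_numpy(dtype=float)
    uni = [
        spearman(patients.loc[common, f"z_{t}"].to_numpy(), comp, name=t)
        for t in tracts
    ]
    q = bh_fdr([c.p_value for c in uni])
    uni = [replace(c, q_value=float(qv)) for c, qv in zip(uni, q)]
    m_corr = spearman(patients.loc[common, "m_median"].to_numpy(), comp, name="M")
    rows = [
        {"variable": c.variable_name, "kind": "univariate_z",
         "rho": c.rho, "p_value": c.p_value, "q_value": c.q_value}
        for c in uni
    ]
    rows.append(
        {"variable": "M", "kind": "multivariate", "rho": m_corr.rho,
         "p_value": m_corr.p_value, "q_value": np.nan}
    )
    df = pd.DataFrame(rows).set_index("variable")
    meta = {
        "n_patients": len(common),
        "m_rho": f"{m_corr.rho:.6f}",
        "m_p_value": f"{m_corr.p_value:.6f}",
        "fdr_family": "univariate tracts only; M reported unadjusted",
    }
    return ResultTable(df, meta)
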