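"""Consolidated neurocognitive score: Box-Cox then PCA first component.

Raw test scores from a neuropsychological battery are combined into a
single outcome: tests whose |z-skewness| or |z-kurtosis| exceeds 1.96
are first shifted to positivity and Box-Cox transformed (PCA is
unsuitable for strongly skewed data), all tests are standardized, and
the first principal component of the standardized matrix is the
composite, oriented so that a higher score means poorer performance.
Box-Cox is strictly monotone for every lambda, so rank-based analyses
downstream are unaffected by the transform itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

#: two-sided normal critical value flagging skew/kurtosis
Z_CRITICAL = 1.96

PATIENTS_ONLY = "patients_only"
ALL_SUBJECTS = "all_subjects"


def z_moments(x) -> tuple[float, float]:
    """Standardized sample skewness and excess kurtosis.

    Skewness is the adjusted Fisher-Pearson statistic divided by its
    standard error sqrt(6n(n-1)/((n-2)(n+1)(n+3))); kurtosis is excess
    kurtosis divided by 2*SE_skew*sqrt((n^2-1)/((n-3)(n+5))).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("need n >= 8 for moment z-scores")
    if np.ptp(x) == 0:
        raise ValueError("constant input: moments undefined")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, bias=False)  # excess, adjusted
    se_skew = np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    se_kurt = 2.0 * se_skew * np.sqrt((n**2 - 1) / ((n - 3) * (n + 5)))
    return float(g1 / se_skew), float(g2 / se_kurt)


def box_cox(x, lmbda: float | None = None) -> tuple[np.ndarray, float]:
    """Box-Cox power transform of strictly positive data.

    y = (x^lambda - 1)/lambda for lambda != 0, log(x) at lambda = 0.
    When ``lmbda`` is None it is chosen by profile maximum likelihood:
    a coarse grid over [-5, 5] followed by bounded refinement around the
    grid optimum.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    if lmbda is None:
        grid = np.linspace(-5.0, 5.0, 201)
        ll = np.array([stats.boxcox_llf(l, x) for l in grid])
        i = int(np.argmax(ll))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda l: -stats.boxcox_llf(l, x), bounds=(lo, hi), method="bounded"
        )
        lmbda = float(res.x)
    y = stats.boxcox(x, lmbda=lmbda)
    return np.asarray(y, dtype=float), float(lmbda)


@dataclass
class CognitiveSummary:
    """Per-test transform audit and per-subject composite scores."""

    transforms: pd.DataFrame  # per test: z_skewness, z_kurtosis, lambda, shift
    pc1_scores: pd.Series  # per subject, zero-mean over fitted subjects
    variance_explained_pc1: float
    orientation_flipped: bool
    fit_subjects: list = field(default_factory=list)


def build_composite(
    cognition: pd.DataFrame,
    fit_population: str = PATIENTS_ONLY,
    groups: pd.Series | None = None,
) -> CognitiveSummary:
    """Build the PC1 cognitive composite from raw test scores.

    Parameters
    ----------
    cognition
        Subjects x tests frame of raw scores, oriented so that higher
        raw scores indicate poorer performance (error counts, times).
        Missing scores are allowed; subjects with any missing test are
        excluded from the fit, all-missing tests are dropped.
    fit_population
        ``"patients_only"`` (default; the composite is the patients'
        outcome variable) or ``"all_subjects"``; requires ``groups``
        for the former.
    """
    df = cognition.copy()
    dropped = [c for c in df.columns if df[c].isna().all()]
    if dropped:
        import warnings

        warnings.warn(f"dropping all-missing cognitive tests: {dropped}")
        df = df.drop(columns=dropped)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 usable cognitive tests")
    if fit_population == PATIENTS_ONLY:
        if groups is None:
            raise ValueError("groups required for patients_only fit")
        df = df.loc[groups.loc[df.index] == "patient"]
    elif fit_population != ALL_SUBJECTS:
        raise ValueError(f"unknown fit_population {fit_population!r}")
    df = df.dropna()
    if len(df) < 5:
        raise ValueError("need >=5 subjects with complete scores")

    audit_rows = []
    transformed = {}
    for test in df.columns:
        x = df[test].to_numpy(dtype=float)
        zs, zk = z_moments(x)
        flagged = abs(zs) > Z_CRITICAL or abs(zk) > Z_CRITICAL
        shift = 0.0
        lam: float | str = "untransformed"
        if flagged:
            if x.min() <= 0:
                shift = 1.0 - x.min()
            y, lam = box_cox(x + shift)
        else:
            y = x
        audit_rows.append(
            {"test": test, "z_skewness": zs, "z_kurtosis": zk,
             "flagged": flagged, "lambda": lam, "shift": shift}
        )
        transformed[test] = y
    T = pd.DataFrame(transformed, index=df.index)

    # correlation-matrix PCA: standardize, then leading eigenvector
    Z = (T - T.mean()) / T.std(ddof=1)
    Zm = Z.to_numpy(dtype=float)
    n = Zm.shape[0]
    corr = (Zm.T @ Zm) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    v1 = evecs[:, -1]
    scores = Zm @ v1
    # orient so pc1 tracks the majority of (higher-is-worse) tests
    flipped = False
    if np.corrcoef(scores, Zm.mean(axis=1))[0, 1] < 0:
        scores = -scores
        v1 = -v1
        flipped = True
    ve = float(evals[-1] / evals.sum())
    return CognitiveSummary(
        transforms=pd.DataFrame(audit_rows).set_index("test"),
        pc1_scores=pd.Series(scores - scores.mean(), index=df.index, name="pc1"),
        variance_explained_pc1=ve,
        orientation_flipped=flipped,
        fit_subjects=list(df.index),
    )
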