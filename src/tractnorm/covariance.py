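"""Control-population model: mean, SDs and shrinkage covariance.

With 22 tracts estimated from 25-control subsamples the sample
covariance is near-singular and its off-diagonal entries are noisy, so
the covariance entering the Mahalanobis quadratic form is estimated
conservatively: the sample correlation matrix is shrunk toward the
identity with a data-driven Ledoit–Wolf-type intensity (the
Schäfer–Strimmer estimator for a diagonal target), then rescaled by the
sample variances.  This attenuates exactly the off-diagonal terms —
the potentially spurious small-sample correlations — while preserving
each tract's variance, and yields a positive-definite matrix even when
the dimension exceeds the sample size.

The optimal intensity for shrinking correlations r_ij toward zero is

    lambda* = sum_{i!=j} Var^(r_ij) / sum_{i!=j} r_ij^2,

clipped to [floor, 1], where Var^(r_ij) is the empirical variance of the
per-observation products of standardized scores.  A strictly positive
floor keeps the shrunk matrix positive definite by construction.

A plain sample-covariance mode exists for oracle tests and large-n use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

SHRINKAGE = "shrinkage"
SAMPLE = "sample"

#: strictly positive intensity floor guaranteeing positive definiteness
INTENSITY_FLOOR = 1e-12


class DegenerateVarianceError(ValueError):
    """A tract has zero variance across the fitted profiles."""


class SampleSizeError(ValueError):
    """Too few profiles to estimate a covariance."""


@dataclass(frozen=True)
class ControlModel:
    """Mean vector, per-tract SDs and (shrunk) covariance of control FA^r."""

    mu: np.ndarray
    cov: np.ndarray
    sd: np.ndarray
    shrink_intensity: float
    n_controls_used: int
    method: str = SHRINKAGE

    @property
    def n_tracts(self) -> int:
        return self.mu.shape[0]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            mu=self.mu,
            cov=self.cov,
            sd=self.sd,
            shrink_intensity=self.shrink_intensity,
            n_controls_used=self.n_controls_used,
            method=self.method,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ControlModel":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                z["mu"], z["cov"], z["sd"],
                float(z["shrink_intensity"]), int(z["n_controls_used"]),
                str(z["method"]),
            )


def _as_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, np.ndarray):
        return np.asarray(profiles, dtype=float)
    return np.vstack([np.asarray(p.fa_r, dtype=float) for p in profiles])


def fit_control_model(profiles, method: str = SHRINKAGE) -> ControlModel:
    """Estimate mu, per-tract SD and covariance from control profiles.

    Parameters
    ----------
    profiles
        List of :class:`~tractnorm.residualize.ResidualProfile` or an
        (n, p) array of residual rows.
    method
        ``"shrinkage"`` (default): correlation-shrinkage covariance,
        positive definite for any n >= 3.  ``"sample"``: textbook
        unbiased sample covariance, intended for oracle tests and
        large-n fits.
    """
    X = _as_matrix(profiles)
    if X.ndim != 2:
        raise ValueError("profiles must stack to a 2-D matrix")
    n, p = X.shape
    if n < 3:
        raise SampleSizeError(f"need >=3 profiles, got {n}")
    if p < 2:
        raise SampleSizeError(f"need >=2 tracts, got {p}")
    mu, sd, cov, lam = _fit_batch(X[None], method)
    return ControlModel(mu[0], cov[0], sd[0], float(lam[0]), n, method)


def _fit_batch(X: np.ndarray, method: str):
    """Vectorized model fit over a stack of subsamples.

    X has shape (B, n, p); returns (mu, sd, cov, lambda) with leading
    batch dimension.  The single-sample public fit is the B=1 case, so
    the batched permutation path is exactly equivalent by construction.
    """
    B, n, p = X.shape
    mu = X.mean(axis=1)
    xc = X - mu[:, None, :]
    var = (xc**2).sum(axis=1) / (n - 1)
    if np.any(var <= 0):
        b, t = np.argwhere(var <= 0)[0]
        raise DegenerateVarianceError(f"zero variance in tract index {t}")
    sd = np.sqrt(var)
    S = np.einsum("bki,bkj->bij", xc, xc) / (n - 1)
    if method == SAMPLE:
        return mu, sd, S, np.zeros(B)
    if method != SHRINKAGE:
        raise ValueError(f"unknown covariance method {method!r}")

    # Schafer-Strimmer intensity for shrinking correlations toward zero
    z = xc / sd[:, None, :]
    wbar = np.einsum("bki,bkj->bij", z, z) / n
    r = (n / (n - 1)) * wbar
    w2sum = np.einsum("bki,bkj->bij", z**2, z**2)
    var_r = (n / (n - 1) ** 3) * (w2sum - n * wbar**2)
    off = ~np.eye(p, dtype=bool)
    num = var_r[:, off].sum(axis=1)
    den = (r**2)[:, off].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(den > 0, num / den, 1.0)
    lam = np.clip(lam, INTENSITY_FLOOR, 1.0)

    r_shrunk = (1.0 - lam)[:, None, None] * r
    idx = np.arange(p)
    r_shrunk[:, idx, idx] = 1.0
    cov = r_shrunk * sd[:, :, None] * sd[:, None, :]
    return mu, sd, cov, lam


@dataclass(frozen=True)
class Precision:
    """Cholesky-based precision representation of a control covariance.

    Quadratic forms d' C^{-1} d are evaluated by triangular solves
    against the Cholesky factor rather than through an explicit inverse,
    which is the numerically stable route when C is ill-conditioned.
    """

    chol: np.ndarray  # lower-triangular L with C = L L'

    def whiten(self, d: np.ndarray) -> np.ndarray:
        """Solve L w = d; then ||w||^2 = d' C^{-1} d."""
        from scipy.linalg import solve_triangular

        return solve_triangular(self.chol, np.asarray(d, float), lower=True)

    def quad_form(self, d: np.ndarray) -> float:
        w = self.whiten(d)
        return float(w @ w)

    @property
    def inverse(self) -> np.ndarray:
        """Explicit C^{-1}; for audit, not for the scoring path."""
        from scipy.linalg import cho_solve

        p = self.chol.shape[0]
        return cho_solve((self.chol, True), np.eye(p))


def invert_model(model: ControlModel) -> Precision:
    """Factorize the model covariance for stable quadratic forms."""
    try:
        L = np.linalg.cholesky(model.cov)
    except np.linalg.LinAlgError as exc:
        eigvals = np.linalg.eigvalsh(model.cov)
        cond = eigvals[-1] / eigvals[0] if eigvals[0] != 0 else np.inf
        raise np.linalg.LinAlgError(
            "covariance is not positive definite "
            f"(min eigenvalue {eigvals[0]:.3e}, condition number {cond:.3e})"
        ) from exc
    return Precision(L)
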