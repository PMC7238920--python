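"""Multivariate M and univariate |Z| severity scores.

A subject's intrinsic injury load is summarized by the Mahalanobis
distance of their age-residualized FA profile s from the control
population,

    M = sqrt( (s - mu)' C^{-1} (s - mu) ),

with mu and C estimated from controls.  Because C is estimated from few
controls, scores are computed conservatively: for each subject a subset
of controls (default 25) is drawn at random, the control model (mu, sd,
C) refitted on that subset, M and the per-tract |Z| = |s_t - mu_t|/sd_t
evaluated against it, and the procedure repeated (default 1,000 times);
the subject's score is the median across repetitions.  A control being
scored is always held out of its own reference subsets.

Each subject gets an independent random stream derived from the master
seed and the subject id, so scores do not depend on cohort ordering.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance import SHRINKAGE, ControlModel, SampleSizeError, _fit_batch, invert_model
from .io import ResultTable
from .residualize import ResidualProfile

SUBSAMPLE_SD = "subsample"
POOL_SD = "pool"


@dataclass(frozen=True)
class DistanceResult:
    """Per-subject conservative severity scores.

    ``m_median`` is the median Mahalanobis distance across permuted
    control subsamples; ``z_median`` the per-tract median |Z|.
    ``held_out`` flags controls scored with themselves excluded from
    every reference subset.
    """

    subject_id: str
    m_median: float
    z_median: np.ndarray
    n_perm: int
    subset_size: int
    seed: int
    held_out: bool

    def __post_init__(self) -> None:
        if self.m_median < 0 or np.any(self.z_median < 0):
            raise ValueError("distances are nonnegative by construction")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def mahalanobis(s: ResidualProfile, model: ControlModel) -> float:
    """Mahalanobis distance of one residual profile from the model."""
    v = np.asarray(s.fa_r, dtype=float)
    if v.shape[0] != model.n_tracts:
        raise ValueError(
            f"profile has {v.shape[0]} tracts, model has {model.n_tracts}"
        )
    d = v - model.mu
    q = invert_model(model).quad_form(d)
    return float(np.sqrt(max(q, 0.0)))


def univariate_z(s: ResidualProfile, model: ControlModel) -> np.ndarray:
    """Per-tract |z| of one residual profile against the model."""
    v = np.asarray(s.fa_r, dtype=float)
    if v.shape[0] != model.n_tracts:
        raise ValueError(
            f"profile has {v.shape[0]} tracts, model has {model.n_tracts}"
        )
    return np.abs(v - model.mu) / model.sd


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    # stream keyed by (master seed, stable hash of subject id): cohort
    # order cannot affect any subject's draws
    tag = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def permuted_scores(
    subject: ResidualProfile,
    control_pool: list[ResidualProfile],
    subset_size: int = 25,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = SHRINKAGE,
    z_sd: str = SUBSAMPLE_SD,
) -> DistanceResult:
    """Score one subject against permuted control subsamples.

    The subject is removed from the pool first if present (leave-one-
    out).  For each of ``n_perm`` draws, ``subset_size`` controls are
    sampled without replacement, the control model refitted on them and
    M and |Z| evaluated; medians across draws are returned.  Fully
    reproducible given ``seed``.
    """
    pool = [p for p in control_pool if p.subject_id != subject.subject_id]
    held_out = len(pool) < len(control_pool)
    if subset_size > len(pool):
        raise SampleSizeError(
            f"subset_size {subset_size} exceeds available pool "
            f"({len(pool)} controls after hold-out)"
        )
    X = np.vstack([p.fa_r for p in pool])
    s = np.asarray(subject.fa_r, dtype=float)
    if s.shape[0] != X.shape[1]:
        raise ValueError("profile/pool tract dimension mismatch")

    rng = _subject_rng(seed, subject.subject_id)
    # without-replacement subsets via random-key argsort (vectorized)
    keys = rng.random((n_perm, X.shape[0]))
    subsets = np.argsort(keys, axis=1)[:, :subset_size]

    m, z = _scores_for_subsets(s, X, subsets, method)
    if z_sd == POOL_SD:
        pool_sd = X.std(axis=0, ddof=1)
        mu_b, _, _, _ = _fit_batch(X[subsets], method)
        z = np.abs(s[None, :] - mu_b) / pool_sd[None, :]
    elif z_sd != SUBSAMPLE_SD:
        raise ValueError(f"unknown z_sd option {z_sd!r}")

    return DistanceResult(
        subject_id=subject.subject_id,
        m_median=float(np.median(m)),
        z_median=np.median(z, axis=0),
        n_perm=n_perm,
        subset_size=subset_size,
        seed=int(seed),
        held_out=held_out,
    )


def _scores_for_subsets(s, X, subsets, method):
    """M and |Z| of profile ``s`` against each subset's refitted model."""
    mu_b, sd_b, cov_b, _ = _fit_batch(X[subsets], method)
    d = s[None, :] - mu_b
    sol = np.linalg.solve(cov_b, d[..., None])[..., 0]
    m2 = np.einsum("bi,bi->b", d, sol)
    m = np.sqrt(np.clip(m2, 0.0, None))
    z = np.abs(d) / sd_b
    return m, z


def score_cohort(
    profiles: list[ResidualProfile],
    groups: pd.Series | dict,
    subset_size: int = 25,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = SHRINKAGE,
    z_sd: str = SUBSAMPLE_SD,
) -> list[DistanceResult]:
    """Score every subject: patients against the control pool, each
    control against the remaining controls (leave-one-out).

    Requires at least ``subset_size + 1`` controls so hold-out scoring
    leaves a full subset.
    """
    get = groups.get if hasattr(groups, "get") else groups.__getitem__
    pool = [p for p in profiles if get(p.subject_id) == "control"]
    if len(pool) < subset_size + 1:
        raise SampleSizeError(
            f"need >= subset_size + 1 = {subset_size + 1} controls, "
            f"got {len(pool)}"
        )
    return [
        permuted_scores(p, pool, subset_size, n_perm, seed, method, z_sd)
        for p in profiles
    ]


def results_frame(results: list[DistanceResult], tracts, groups=None) -> pd.DataFrame:
    """Tabulate DistanceResults: m_median plus one |Z| column per tract."""
    idx = pd.Index([r.subject_id for r in results], name="subject_id")
    df = pd.DataFrame(index=idx)
    if groups is not None:
        get = groups.get if hasattr(groups, "get") else groups.__getitem__
        df["group"] = [get(sid) for sid in idx]
    df["m_median"] = [r.m_median for r in results]
    zmat = np.vstack([r.z_median for r in results])
    for j, t in enumerate(tracts):
        df[f"z_{t}"] = zmat[:, j]
    df["held_out"] = [r.held_out for r in results]
    return df


def results_table(results: list[DistanceResult], tracts, groups=None) -> ResultTable:
    meta = {}
    if results:
        meta = {
            "n_perm": results[0].n_perm,
            "subset_size": results[0].subset_size,
            "seed": results[0].seed,
        }
    return ResultTable(results_frame(results, tracts, groups), meta)
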