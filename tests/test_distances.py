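"""Mahalanobis / |Z| scoring and the permutation-subsampling estimator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tractnorm import mahalanobis, permuted_scores, score_cohort, univariate_z
from tractnorm.covariance import SAMPLE, ControlModel, SampleSizeError, fit_control_model
from tractnorm.distances import results_frame
from tractnorm.residualize import ResidualProfile


def _model(cov, mu=None):
    cov = np.asarray(cov, float)
    p = cov.shape[0]
    mu = np.zeros(p) if mu is None else np.asarray(mu, float)
    return ControlModel(mu=mu, cov=cov, sd=np.sqrt(np.diag(cov)),
                        shrink_intensity=0.0, n_controls_used=10, method=SAMPLE)


def _profile(vals, sid="s"):
    return ResidualProfile(sid, np.asarray(vals, float))


def test_euclidean_reduction_three_four_five():
    assert mahalanobis(_profile([3.0, 4.0]), _model(np.eye(2))) == pytest.approx(5.0)


def test_zero_at_the_centroid():
    mu = np.array([0.1, -0.2, 0.3])
    m = _model(np.eye(3), mu=mu)
    assert mahalanobis(_profile(mu), m) == 0.0
    np.testing.assert_array_equal(univariate_z(_profile(mu), m), np.zeros(3))


def test_correlated_2x2_closed_form():
    # d=(1,-1) against C=[[1,.8],[.8,1]]: d' C^-1 d = 10
    m = _model([[1.0, 0.8], [0.8, 1.0]])
    assert mahalanobis(_profile([1.0, -1.0]), m) == pytest.approx(np.sqrt(10.0), rel=1e-12)


def test_univariate_z_definition():
    m = _model(np.diag([4.0]))  # sd = 2
    assert univariate_z(_profile([4.0]), m)[0] == pytest.approx(2.0)


def test_dimension_mismatch_raises():
    with pytest.raises(ValueError, match="tracts"):
        mahalanobis(_profile([1.0, 2.0, 3.0]), _model(np.eye(2)))


def test_oracle_equivalence_dense_inverse(rng):
    """Sample-method M agrees with the brute-force dense-inverse
    quadratic form to 1e-10 relative on random low-dimensional data."""
    for _ in range(100):
        p = int(rng.integers(2, 7))
        n = int(rng.integers(p + 2, 30))
        X = rng.normal(size=(n, p))
        model = fit_control_model(X, method=SAMPLE)
        s = _profile(rng.normal(size=p))
        d = s.fa_r - model.mu
        brute = float(np.sqrt(d @ np.linalg.inv(model.cov) @ d))
        assert mahalanobis(s, model) == pytest.approx(brute, rel=1e-10)


@given(st.floats(min_value=1.0, max_value=50.0), st.floats(min_value=1.01, max_value=5.0))
def test_monotone_in_single_tract_deviation(base, factor):
    """With diagonal covariance, scaling one tract's deviation strictly
    increases M (others fixed)."""
    m = _model(np.diag([0.5, 2.0, 1.5]))
    lo = mahalanobis(_profile([base, 1.0, -1.0]), m)
    hi = mahalanobis(_profile([base * factor, 1.0, -1.0]), m)
    assert hi > lo


def _pool(rng, n=31, p=5):
    return [_profile(rng.normal(size=p), f"c{i}") for i in range(n)]


def test_no_resampling_reduction(rng):
    """n_perm=1 with the subset equal to the full pool reproduces the
    direct distances against a model fitted on the whole pool."""
    pool = _pool(rng)
    subj = _profile(rng.normal(size=5), "patient")
    res = permuted_scores(subj, pool, subset_size=31, n_perm=1, seed=3, method=SAMPLE)
    direct = fit_control_model(np.vstack([p.fa_r for p in pool]), method=SAMPLE)
    assert res.m_median == pytest.approx(mahalanobis(subj, direct), rel=1e-10)
    np.testing.assert_allclose(res.z_median, univariate_z(subj, direct), rtol=1e-10)
    assert not res.held_out


def test_same_seed_is_bit_identical(rng):
    pool = _pool(rng)
    subj = _profile(rng.normal(size=5), "patient")
    a = permuted_scores(subj, pool, 25, 50, seed=9)
    b = permuted_scores(subj, pool, 25, 50, seed=9)
    assert a.m_median == b.m_median
    np.testing.assert_array_equal(a.z_median, b.z_median)
    c = permuted_scores(subj, pool, 25, 50, seed=10)
    assert c.m_median != a.m_median


def test_identical_profiles_same_id_score_identically(rng):
    pool = _pool(rng)
    vals = rng.normal(size=5)
    a = permuted_scores(_profile(vals, "p1"), pool, 25, 50, seed=4)
    b = permuted_scores(_profile(vals.copy(), "p1"), pool, 25, 50, seed=4)
    assert a.m_median == b.m_median


def test_control_hold_out(rng):
    pool = _pool(rng)
    res = permuted_scores(pool[0], pool, subset_size=25, n_perm=20, seed=0)
    assert res.held_out
    with pytest.raises(SampleSizeError):
        permuted_scores(pool[0], pool, subset_size=31, n_perm=5, seed=0)


def test_score_cohort_shapes_and_holdout(rng):
    profiles = _pool(rng, 31) + [_profile(rng.normal(size=5), f"p{i}") for i in range(34)]
    groups = {p.subject_id: ("control" if p.subject_id.startswith("c") else "patient")
              for p in profiles}
    results = score_cohort(profiles, groups, subset_size=25, n_perm=20, seed=1)
    assert len(results) == 65
    held = [r.held_out for r in results]
    assert sum(held) == 31
    assert all(r.held_out == r.subject_id.startswith("c") for r in results)
    df = results_frame(results, [f"t{j}" for j in range(5)], groups)
    assert df.shape == (65, 1 + 1 + 5 + 1)
    with pytest.raises(SampleSizeError):
        score_cohort(profiles, groups, subset_size=31, n_perm=5, seed=1)


def test_subject_stream_independent_of_cohort_composition(rng):
    """A subject's score depends only on the master seed, its id and the
    control pool — not on which other subjects are scored alongside."""
    profiles = _pool(rng, 31) + [_profile(rng.normal(size=5), f"p{i}") for i in range(4)]
    groups = {p.subject_id: ("control" if p.subject_id.startswith("c") else "patient")
              for p in profiles}
    full = score_cohort(profiles, groups, 25, 30, seed=2)
    solo = permuted_scores(profiles[-1], profiles[:31], 25, 30, seed=2)
    match = [r for r in full if r.subject_id == solo.subject_id][0]
    assert match.m_median == solo.m_median
    np.testing.assert_array_equal(match.z_median, solo.z_median)


def test_null_patient_within_control_band():
    """A 'patient' drawn from the control distribution scores inside the
    central 99% band of held-out-control medians from a null simulation."""
    from tractnorm import SimulationConfig, null_reference

    cfg = SimulationConfig(
        n_controls=31, n_patients=0, n_tracts=5,
        affected_tracts_range=(0, 0), effect_size_range=(0.0, 0.0), seed=0,
    )
    null = null_reference(cfg, n_replicates=20, subset_size=25, n_perm=100, seed=77)
    rng = np.random.default_rng(5)
    L = np.linalg.cholesky(cfg.true_covariance())
    pool = [_profile(rng.normal(size=5) @ L.T, f"c{i}") for i in range(31)]
    fake_patient = _profile(rng.normal(size=5) @ L.T, "px")
    res = permuted_scores(fake_patient, pool, 25, 100, seed=42)
    assert null["quantiles"][0.005] < res.m_median < null["quantiles"][0.995]


def test_median_stabilizes_with_more_permutations(study_cohort):
    """Doubling permutations from 1,000 to 2,000 moves m_median < 2%."""
    from tractnorm import fit_age_model, residualize_cohort

    cohort, _ = study_cohort
    model = fit_age_model(cohort)
    profiles = residualize_cohort(cohort, model)
    pool = [p for p in profiles if cohort.groups[p.subject_id] == "control"]
    for subj in [p for p in profiles if p.subject_id.startswith("P")][:5]:
        a = permuted_scores(subj, pool, 25, 1000, seed=1)
        b = permuted_scores(subj, pool, 25, 2000, seed=1)
        assert abs(b.m_median - a.m_median) / a.m_median < 0.02
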