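"""ROC/AUC, Spearman, BH-FDR and robust-line evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tractnorm import bh_fdr, evaluate_discrimination, robust_line, roc_auc, spearman


def auc_pair_counting(scores, labels):
    """Brute-force Mann-Whitney pair counting oracle."""
    pats = [s for s, l in zip(scores, labels) if l == "patient"]
    ctrls = [s for s, l in zip(scores, labels) if l == "control"]
    total = 0.0
    for sp in pats:
        for sc in ctrls:
            total += 1.0 if sp > sc else (0.5 if sp == sc else 0.0)
    return total / (len(pats) * len(ctrls))


def test_auc_perfect_separation():
    curve = roc_auc([1, 2, 9, 10], ["control", "control", "patient", "patient"])
    assert curve.auc == 1.0
    assert curve.fpr[0] == 0 and curve.tpr[-1] == 1


def test_auc_all_tied():
    assert roc_auc([3, 3, 3, 3], ["control", "patient"] * 2).auc == 0.5


def test_auc_worked_example():
    # patients {2, 3}, controls {1, 2.5}: 3 of 4 pairs won
    curve = roc_auc([2, 3, 1, 2.5], ["patient", "patient", "control", "control"])
    assert curve.auc == pytest.approx(0.75)


def test_auc_matches_pair_counting_on_random_fixtures(rng):
    for _ in range(30):
        n = int(rng.integers(4, 25))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = ["patient" if b else "control" for b in rng.integers(0, 2, n)]
        if "patient" not in labels or "control" not in labels:
            continue
        assert roc_auc(scores, labels).auc == pytest.approx(
            auc_pair_counting(scores, labels), abs=1e-12
        )


def test_auc_orientation_symmetry(rng):
    scores = rng.normal(size=20)
    labels = ["patient"] * 8 + ["control"] * 12
    a = roc_auc(scores, labels).auc
    b = roc_auc(-scores, labels).auc
    assert a + b == pytest.approx(1.0)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([1, 2], ["control", "control"])


def test_spearman_monotone_and_antitone():
    x = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 7.0])
    assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
    assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)


def test_spearman_worked_example():
    # d^2 sum = 4: rho = 1 - 6*4/(5*24) = 0.8
    res = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
    assert res.rho == pytest.approx(0.8)


def test_spearman_exact_permutation_p_matches_enumeration():
    from itertools import permutations

    from scipy import stats

    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
    res = spearman(x, y)  # n=5 < 10: exact path
    rho_obs = stats.spearmanr(x, y).statistic
    count = sum(
        1 for perm in permutations(y)
        if abs(stats.spearmanr(x, perm).statistic) >= abs(rho_obs) - 1e-12
    )
    assert res.p_value == pytest.approx(count / 120)


def test_spearman_invariant_to_monotone_transforms(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    base = spearman(x, y)
    warped = spearman(np.exp(x / 2), y**3)
    assert warped.rho == pytest.approx(base.rho)
    assert warped.p_value == pytest.approx(base.p_value)


def test_spearman_errors():
    with pytest.raises(ValueError, match="constant"):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [1, 2, 3])


def bh_oracle(p):
    """Step-up rule: q_i = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = running
    return q


def test_bh_single_p():
    np.testing.assert_allclose(bh_fdr([0.03]), [0.03])


def test_bh_worked_example():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_equal_ps():
    np.testing.assert_allclose(bh_fdr([0.5] * 10), [0.5] * 10)


@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
def test_bh_matches_step_up_oracle_and_dominates_raw(p):
    q = bh_fdr(p)
    np.testing.assert_allclose(q, bh_oracle(p), rtol=1e-12)
    assert np.all(q >= np.asarray(p) - 1e-15)
    assert np.all(q <= 1.0)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.0, 0.5])
    with pytest.raises(ValueError):
        bh_fdr([1.5])


def test_robust_line_noiseless():
    x = np.linspace(0, 10, 15)
    slope, intercept, conv = robust_line(x, 2 * x + 1)
    assert slope == pytest.approx(2.0, rel=1e-6)
    assert intercept == pytest.approx(1.0, rel=1e-5)
    assert conv


def test_robust_line_resists_gross_outlier(rng):
    x = np.linspace(0, 10, 20)
    y = 2 * x + 1 + rng.normal(0, 0.05, 20)
    y[3] += 80.0
    slope, _, _ = robust_line(x, y)
    ols_slope = np.polyfit(x, y, 1)[0]
    assert abs(slope - 2.0) / 2.0 < 0.05
    assert abs(ols_slope - 2.0) > abs(slope - 2.0)


def test_robust_line_equals_ols_when_no_outliers(rng):
    # with all bisquare weights ~1 the IRLS solution is the OLS line
    x = np.linspace(0, 10, 30)
    y = 1.5 * x - 2 + rng.normal(0, 1e-6, 30)
    slope, intercept, _ = robust_line(x, y)
    b1, b0 = np.polyfit(x, y, 1)
    assert slope == pytest.approx(b1, rel=1e-4)
    assert intercept == pytest.approx(b0, abs=1e-4)


def test_robust_line_degenerate_x():
    with pytest.raises(ValueError, match="constant"):
        robust_line([2, 2, 2, 2], [1, 2, 3, 4])


def _null_scores(rng, n_tracts=6, n=40):
    df = pd.DataFrame(index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"))
    df["group"] = ["control"] * (n // 2) + ["patient"] * (n - n // 2)
    df["m_median"] = rng.normal(size=n) ** 2
    for t in range(n_tracts):
        df[f"z_t{t}"] = np.abs(rng.normal(size=n))
    return df


def test_discrimination_table_structure(scored_study):
    table = scored_study.discrimination()
    df = table.data
    assert len(df) == 23  # 22 univariate + 1 multivariate
    assert (df["kind"] == "univariate_z").sum() == 22
    assert df.loc["M", "kind"] == "multivariate"
    assert "best_univariate_tract" in table.metadata


def test_discrimination_null_cohort_near_chance(rng):
    df = _null_scores(rng)
    table = evaluate_discrimination(df, [f"t{t}" for t in range(6)])
    aucs = table.data["auc"].to_numpy()
    assert np.all(np.abs(aucs - 0.5) < 0.3)
    assert abs(aucs.mean() - 0.5) < 0.12


def test_discrimination_isolated_shift_saturates(rng):
    df = _null_scores(rng)
    df.loc[df["group"] == "patient", "z_t2"] += 50.0
    table = evaluate_discrimination(df, [f"t{t}" for t in range(6)])
    assert table.data.loc["t2", "auc"] == 1.0
    assert table.metadata["best_univariate_tract"] == "t2"
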