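"""Statistical-core tests: pooled covariance, canonical directions,
Hotelling inference, stepwise selection and centroid classification,
each against an independent oracle where one exists."""

import numpy as np
import pytest
from scipy import linalg, stats

from mdagwas.discrim import (
    CanonicalFunction,
    DiscriminantError,
    build_da_model,
    cda_fit,
    da_classify,
    hotelling_test,
    mahalanobis_d2,
    pooled_within_cov,
    sda_select,
    two_group_stats,
)


def _labels(n1, n2):
    return np.array(["LP"] * n1 + ["HP"] * n2)


def _gaussian_two_groups(rng, n1=20, n2=20, p=5, shift=2.0):
    X = rng.standard_normal((n1 + n2, p))
    X[n1:, 0] += shift
    return X, _labels(n1, n2)


# ---------------------------------------------------------------------------
# pooled within-group covariance


def test_pooled_cov_of_constant_groups_is_zero():
    X = np.array([[1.0, 2.0]] * 3 + [[5.0, 1.0]] * 3)
    W = pooled_within_cov(X, _labels(3, 3))
    assert np.allclose(W, 0)


def test_pooled_cov_matches_hand_computation():
    """4+4 points on a grid: each group has scatter diag(4, 4), so the
    pooled covariance is diag(8/6, 8/6)."""
    g1 = [[0, 0], [2, 0], [0, 2], [2, 2]]
    g2 = [[1, 0], [3, 0], [1, 2], [3, 2]]
    W = pooled_within_cov(np.array(g1 + g2, float), _labels(4, 4))
    assert np.allclose(W, np.diag([4.0 / 3.0, 4.0 / 3.0]))


def test_pooled_cov_equals_common_covariance_for_equal_groups(rng):
    S = np.array([[2.0, 0.5], [0.5, 1.0]])
    base = rng.multivariate_normal([0, 0], S, size=30)
    X = np.vstack([base, base + [10, 10]])  # identical within-group scatter
    W = pooled_within_cov(X, _labels(30, 30))
    assert np.allclose(W, np.cov(base, rowvar=False))


def test_group_smaller_than_two_is_an_error():
    with pytest.raises(DiscriminantError):
        pooled_within_cov(np.eye(3), np.array(["LP", "LP", "HP"]))


# ---------------------------------------------------------------------------
# canonical fit


def test_diagonal_within_matrix_gives_mean_difference_direction():
    """With exactly diagonal W and mean difference (1, 0), the canonical
    direction lies on the first axis and the second loading is zero."""
    E = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    X = np.vstack([E, E + [1.0, 0.0]])
    can = cda_fit(X, _labels(4, 4))
    assert can.raw_coef[1] == pytest.approx(0.0, abs=1e-12)
    assert can.cnc[1] == pytest.approx(0.0, abs=1e-12)
    assert can.raw_coef[0] > 0 and can.centroid_hp > can.centroid_lp


def test_canonical_scores_have_unit_within_variance(rng):
    X, labels = _gaussian_two_groups(rng)
    can = cda_fit(X, labels)
    W = pooled_within_cov(X, labels)
    assert can.raw_coef @ W @ can.raw_coef == pytest.approx(1.0)


def test_affine_invariance_of_the_discriminant(rng):
    """Any invertible linear remap of the variables leaves D2, the test,
    canonical scores and classifications unchanged."""
    X, labels = _gaussian_two_groups(rng, p=5)
    A = rng.standard_normal((5, 5)) + 5 * np.eye(5)
    XA = X @ A
    can, canA = cda_fit(X, labels), cda_fit(XA, labels)
    assert canA.d2 == pytest.approx(can.d2, rel=1e-8)
    t, tA = (
        hotelling_test(c.d2, c.n_lp, c.n_hp, c.rank) for c in (can, canA)
    )
    assert tA.p_value == pytest.approx(t.p_value, rel=1e-8)
    assert np.allclose(canA.scores(XA), can.scores(X), rtol=1e-6, atol=1e-8)
    la, _ = da_classify(build_da_model(can), X, labels)
    lb, _ = da_classify(build_da_model(canA), XA, labels)
    assert np.array_equal(la, lb)


def test_direction_matches_generalized_eigenproblem(rng):
    """Brute-force oracle: the discriminant direction is the leading
    eigenvector of W^-1 B."""
    X, labels = _gaussian_two_groups(rng, p=3, n1=20, n2=20)
    m_lp, m_hp, n_lp, n_hp, W, _, _ = two_group_stats(X, labels)
    gm = X.mean(axis=0)
    B = n_lp * np.outer(m_lp - gm, m_lp - gm) + n_hp * np.outer(m_hp - gm, m_hp - gm)
    vals, vecs = linalg.eig(np.linalg.inv(W) @ B)
    lead = np.real(vecs[:, np.argmax(np.real(vals))])
    can = cda_fit(X, labels)
    cos = abs(lead @ can.raw_coef) / (
        np.linalg.norm(lead) * np.linalg.norm(can.raw_coef)
    )
    assert cos >= 0.9999


def test_degenerate_identical_groups_error():
    X = np.ones((8, 3))
    with pytest.raises(DiscriminantError):
        cda_fit(X, _labels(4, 4))


# ---------------------------------------------------------------------------
# Mahalanobis distance and Hotelling test


def test_mahalanobis_basic_cases():
    assert mahalanobis_d2([1, 2], [1, 2], np.eye(2)) == 0.0
    assert mahalanobis_d2([0, 0], [3, 4], np.eye(2)) == pytest.approx(25.0)
    with pytest.raises(DiscriminantError):
        mahalanobis_d2([0, 0], [1, 1], np.eye(3))


def test_univariate_d2_reduces_to_t_statistic(rng):
    x = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 12)])
    labels = _labels(15, 12)
    m_lp, m_hp, n1, n2, W, _, _ = two_group_stats(x[:, None], labels)
    d2 = mahalanobis_d2(m_lp, m_hp, W)
    t, _ = stats.ttest_ind(x[15:], x[:15], equal_var=True)
    assert d2 == pytest.approx(t**2 * (1 / n1 + 1 / n2), rel=1e-10)


def test_hotelling_zero_distance_and_monotonicity():
    t0 = hotelling_test(0.0, 10, 10, 3)
    assert t0.t2 == 0 and t0.f_stat == 0 and t0.p_value == 1.0
    # doubling both group sizes with the same moments doubles T^2
    a = hotelling_test(1.7, 10, 12, 3)
    b = hotelling_test(1.7, 20, 24, 3)
    assert b.t2 == pytest.approx(2 * a.t2)


def test_hotelling_p1_equals_two_sample_t_test(rng):
    x = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.8, 1, 25)])
    labels = _labels(20, 25)
    can = cda_fit(x[:, None], labels)
    ht = hotelling_test(can.d2, can.n_lp, can.n_hp, 1)
    _, p_t = stats.ttest_ind(x[20:], x[:20], equal_var=True)
    assert ht.p_value == pytest.approx(p_t, abs=1e-10)


def test_hotelling_requires_error_degrees_of_freedom():
    with pytest.raises(DiscriminantError):
        hotelling_test(1.0, 3, 3, 5)


def test_rank_governs_effective_dimension_when_p_exceeds_n(rng):
    X, labels = _gaussian_two_groups(rng, n1=6, n2=6, p=30)
    can = cda_fit(X, labels)
    assert can.rank <= 10  # at most n - 2
    hotelling_test(can.d2, can.n_lp, can.n_hp, can.rank)  # must be testable


# ---------------------------------------------------------------------------
# stepwise selection


def _sda_oracle(X, labels, sle=0.15, sls=0.15, max_vars=None):
    """From-scratch stepwise Wilks-lambda selection: every subset statistic
    recomputed by direct solves, no incremental bookkeeping."""
    m_lp, m_hp, n1, n2, W, _, _ = two_group_stats(X, labels)
    n, p = X.shape
    diff = m_hp - m_lp
    c = n1 * n2 / (n * (n - 2))
    if max_vars is None:
        max_vars = n - 2

    def d2_of(subset):
        idx = list(subset)
        return float(
            diff[idx] @ np.linalg.solve(W[np.ix_(idx, idx)], diff[idx])
        )

    entered = []
    while True:
        changed = False
        k = len(entered)
        df2 = n - 2 - k
        if k < max_vars and df2 >= 1:
            best, best_f = None, -np.inf
            d2_cur = d2_of(entered) if entered else 0.0
            for j in range(p):
                if j in entered:
                    continue
                sub = entered + [j]
                if np.linalg.cond(W[np.ix_(sub, sub)]) > 1e8:
                    continue
                f = df2 * c * (d2_of(sub) - d2_cur) / (1 + c * d2_cur)
                if f > best_f:
                    best, best_f = j, f
            if best is not None and stats.f.sf(best_f, 1, df2) <= sle:
                entered.append(best)
                changed = True
        while entered:
            k = len(entered)
            df2r = n - 1 - k
            if df2r < 1:
                break
            d2_full = d2_of(entered)
            ps = []
            for j in entered:
                rest = [e for e in entered if e != j]
                d2r = d2_of(rest) if rest else 0.0
                f = df2r * c * (d2_full - d2r) / (1 + c * d2r)
                ps.append(stats.f.sf(f, 1, df2r))
            worst = int(np.argmax(ps))
            if ps[worst] <= sls:
                break
            entered.pop(worst)
            changed = True
        if not changed:
            break
    return entered


def test_perfectly_separating_variable_enters_first(rng):
    X = rng.standard_normal((40, 5))
    labels = _labels(20, 20)
    X[:, 2] = np.where(labels == "HP", 1.0, -1.0) + 0.01 * rng.standard_normal(40)
    sel = sda_select(X, labels)
    assert sel[0] == 2


def test_duplicated_column_never_joins_its_twin(rng):
    X = rng.standard_normal((30, 4))
    labels = _labels(15, 15)
    X[:, 0] += np.where(labels == "HP", 1.5, 0.0)
    X = np.hstack([X, X[:, [0]]])  # column 4 duplicates column 0
    sel = set(sda_select(X, labels).tolist())
    assert not ({0, 4} <= sel)


def test_stepwise_matches_brute_force_oracle(rng):
    """Entered sets agree with the from-scratch Wilks-lambda stepwise on
    random 6-variable fixtures."""
    for trial in range(5):
        X = rng.standard_normal((30, 6))
        labels = _labels(15, 15)
        X[:, 0] += np.where(labels == "HP", 1.2, 0.0)
        X[:, 3] += np.where(labels == "HP", 0.0, 0.8)
        got = sda_select(X, labels).tolist()
        assert got == _sda_oracle(X, labels)


def test_selection_size_never_exceeds_rank_bound(rng):
    X, labels = _gaussian_two_groups(rng, n1=8, n2=8, p=40)
    sel = sda_select(X, labels)
    assert len(sel) <= 14  # n1 + n2 - 2


def test_empty_selection_is_valid(rng):
    X = rng.standard_normal((24, 3))
    sel = sda_select(X, _labels(12, 12), sle=1e-9)
    assert len(sel) == 0


# ---------------------------------------------------------------------------
# discriminant classification


def _canfun(coef, c_lp, c_hp, n_lp, n_hp):
    return CanonicalFunction(
        raw_coef=np.asarray(coef, float), cnc=np.asarray(coef, float),
        centroid_lp=c_lp, centroid_hp=c_hp, n_lp=n_lp, n_hp=n_hp,
        lp_label="LP", hp_label="HP", d2=(c_hp - c_lp) ** 2, rank=len(coef),
    )


def test_cutoff_is_group_size_weighted_centroid_mean():
    assert build_da_model(_canfun([1.0], -1.0, 1.0, 10, 10)).cutoff == 0.0
    # n1=3 at centroid 0, n2=1 at centroid 4 -> (3*0 + 1*4)/4 = 1
    assert build_da_model(_canfun([1.0], 0.0, 4.0, 3, 1)).cutoff == 1.0


def test_individual_at_a_centroid_gets_that_group():
    model = build_da_model(_canfun([1.0], -1.0, 3.0, 5, 5))
    labels, _ = da_classify(model, np.array([[-1.0], [3.0], [1.0]]))
    assert labels.tolist() == ["LP", "HP", "HP"]  # tie at cutoff -> HP


def test_training_accuracy_is_perfect_for_well_separated_gaussians(rng):
    X, labels = _gaussian_two_groups(rng, n1=25, n2=25, p=4, shift=10.0)
    can = cda_fit(X, labels)
    assert can.d2 >= 25
    _, acc = da_classify(build_da_model(can), X, labels)
    assert acc == 1.0


def test_marker_count_mismatch_is_an_error(rng):
    X, labels = _gaussian_two_groups(rng)
    model = build_da_model(cda_fit(X, labels))
    with pytest.raises(DiscriminantError):
        da_classify(model, X[:, :3])
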