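import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mwdetect.evaluation import (default_dimension_grid, kfold_cv,
                                 learning_curve, mann_whitney_auc, nested_cv,
                                 roc_auc, stack_records)
from mwdetect.evaluation import test_vs_chance as vs_chance


def test_perfect_separation_gives_auc_one():
    assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == \
        pytest.approx(1.0)
    assert mann_whitney_auc([1, 2, 3, 10, 11, 12],
                            [0, 0, 0, 1, 1, 1]) == pytest.approx(1.0)


def test_identical_scores_give_auc_half():
    assert roc_auc([5.0] * 6, [0, 0, 0, 1, 1, 1]).auc == pytest.approx(0.5)
    assert mann_whitney_auc([5.0] * 6, [0, 0, 0, 1, 1, 1]) == \
        pytest.approx(0.5)


def test_worked_auc_example():
    # class 0: {0.1, 0.4}, class 1: {0.35, 0.8} -> 3/4 correct pairs
    scores = [0.1, 0.4, 0.35, 0.8]
    labels = [0, 0, 1, 1]
    assert roc_auc(scores, labels).auc == pytest.approx(0.75)
    assert mann_whitney_auc(scores, labels) == pytest.approx(0.75)


def test_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([1, 2], [1, 1])
    with pytest.raises(ValueError):
        mann_whitney_auc([1, 2], [0, 0])


@given(st.integers(min_value=0, max_value=10_000))
def test_auc_equals_brute_force_pairwise(seed):
    rng = np.random.default_rng(seed)
    scores = rng.standard_normal(14)
    labels = np.array([0] * 7 + [1] * 7)
    pos, neg = scores[labels == 1], scores[labels == 0]
    brute = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
    assert roc_auc(scores, labels).auc == pytest.approx(brute, abs=1e-12)
    assert mann_whitney_auc(scores, labels) == pytest.approx(brute,
                                                             abs=1e-12)


def _toy_Xy(n=40, n_features=25, effect=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_features, n)) \
        + 1j * rng.standard_normal((n_features, n))
    y = np.array([0, 1] * (n // 2))
    direction = rng.standard_normal(n_features)
    X[:, y == 1] += effect * direction[:, None]
    return X, y


def test_kfold_partitions_each_subject_once():
    X, y = _toy_Xy(n=20)
    decisions, roc = kfold_cv(X, y, d=2, k=10,
                              rng=np.random.default_rng(0))
    assert decisions.shape == (20,)
    assert np.all(np.isfinite(decisions))
    assert 0.0 <= roc.auc <= 1.0


def test_kfold_rejects_small_class():
    X, y = _toy_Xy(n=10)
    with pytest.raises(ValueError):
        kfold_cv(X, y, d=1, k=10, rng=np.random.default_rng(0))


def test_nested_cv_degenerate_grid_matches_kfold():
    X, y = _toy_Xy(n=30)
    rng_state = 7
    dec_k, roc_k = kfold_cv(X, y, d=3, k=10,
                            rng=np.random.default_rng(rng_state))
    res = nested_cv(X, y, dim_grid=[3], k_outer=10, k_inner=10,
                    rng=np.random.default_rng(rng_state))
    assert np.allclose(res.decisions, dec_k)
    assert res.auc == pytest.approx(roc_k.auc)
    assert res.chosen_dimensions == [3] * 10


def test_nested_cv_skips_infeasible_dimensions():
    X, y = _toy_Xy(n=24)
    with pytest.warns(UserWarning, match="skipped"):
        res = nested_cv(X, y, dim_grid=[1, 50], k_outer=10, k_inner=10,
                        rng=np.random.default_rng(0))
    assert set(res.chosen_dimensions) == {1}


def test_nested_cv_reproducible():
    X, y = _toy_Xy(n=30)
    a = nested_cv(X, y, rng=np.random.default_rng(42))
    b = nested_cv(X, y, rng=np.random.default_rng(42))
    assert np.array_equal(a.decisions, b.decisions)
    assert a.chosen_dimensions == b.chosen_dimensions


def test_default_dimension_grid_capped():
    assert default_dimension_grid(100) == [1, 2, 3, 5, 8, 12, 20]
    assert default_dimension_grid(10) == [1, 2, 3, 5, 8, 9]
    assert default_dimension_grid(2) == [1]


def test_t_test_null_center():
    sym = 0.5 + np.array([-0.02, -0.01, 0.0, 0.01, 0.02])
    _, p = vs_chance(sym)
    assert p == pytest.approx(0.5)


def test_t_test_zero_variance_branch():
    with pytest.warns(UserWarning, match="zero variance"):
        _, p = vs_chance([0.6] * 10)
    assert p == 0.0
    with pytest.warns(UserWarning):
        _, p = vs_chance([0.4] * 10)
    assert p == 1.0
    with pytest.warns(UserWarning):
        _, p = vs_chance([0.5] * 10)
    assert p == 0.5


def test_t_test_matches_textbook_computation():
    from scipy import stats
    aucs = np.array([0.55, 0.60, 0.58, 0.62, 0.57,
                     0.59, 0.61, 0.56, 0.63, 0.58])
    t = (aucs.mean() - 0.5) / (aucs.std(ddof=1) / np.sqrt(10))
    p_expected = stats.t.sf(t, df=9)
    _, p = vs_chance(aucs)
    assert p == pytest.approx(p_expected, rel=1e-10)


def test_t_test_needs_three_values():
    with pytest.raises(ValueError):
        vs_chance([0.6, 0.7])


def test_learning_curve_size_errors():
    X, y = _toy_Xy(n=30)
    with pytest.raises(ValueError):
        learning_curve(X, y, sizes=[40], repeats=2,
                       rng=np.random.default_rng(0))


def test_learning_curve_shapes_and_reproducibility(toy_cohort):
    X, y = stack_records(toy_cohort)
    a = learning_curve(X, y, sizes=[30, 60], repeats=3,
                       rng=np.random.default_rng(9))
    b = learning_curve(X, y, sizes=[30, 60], repeats=3,
                       rng=np.random.default_rng(9))
    assert a.aucs == b.aucs
    assert len(a.aucs[30]) == 3 and len(a.aucs[60]) == 3
    df = a.to_dataframe()
    assert set(df.columns) == {"size", "repeat", "auc"}
    assert len(df) == 6
    summary = a.summary()
    assert list(summary["size"]) == [30, 60]
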