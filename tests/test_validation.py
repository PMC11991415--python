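import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leafcal as lc
from leafcal.dataset import CalibrationDataset
from leafcal.errors import ConfigError, StratificationError
from leafcal.validation import (
    StratifiedGroupShuffleSplit,
    inner_lv_scan,
    learning_curve,
    nested_cv,
    quantile_bins,
    stratified_group_split,
)


# ---------------------------------------------------------------------------
# quantile bins
# ---------------------------------------------------------------------------

def test_hundred_leaves_make_ten_bins_of_ten(rng):
    bins = quantile_bins(rng.normal(size=100))
    assert np.bincount(bins).tolist() == [10] * 10


def test_bins_monotone_in_value():
    bins = quantile_bins(np.arange(1, 101, dtype=float))
    assert bins[0] == 0 and bins[-1] == 9
    assert (np.diff(bins) >= 0).all()


def test_tied_values_assigned_by_stable_order():
    values = np.zeros(20)
    b1 = quantile_bins(values, n_bins=4)
    b2 = quantile_bins(values, n_bins=4)
    np.testing.assert_array_equal(b1, b2)
    assert np.bincount(b1).tolist() == [5] * 4


@settings(deadline=None, derandomize=True, max_examples=30)
@given(n=st.integers(10, 200), n_bins=st.integers(2, 10),
       seed=st.integers(0, 999))
def test_bin_counts_differ_by_at_most_one(n, n_bins, seed):
    values = np.random.default_rng(seed).normal(size=n)
    counts = np.bincount(quantile_bins(values, n_bins), minlength=n_bins)
    assert counts.max() - counts.min() <= 1


def test_too_few_values_for_bins():
    with pytest.raises(StratificationError):
        quantile_bins(np.arange(5), n_bins=10)


# ---------------------------------------------------------------------------
# stratified group split
# ---------------------------------------------------------------------------

def test_twenty_of_hundred_held_out_two_per_bin(rng):
    leaves = np.arange(100)
    bins = quantile_bins(rng.normal(size=100))
    held, rest = stratified_group_split(leaves, bins, 20,
                                        np.random.default_rng(1))
    assert len(held) == 20 and len(rest) == 80
    assert np.intersect1d(held, rest).size == 0
    per_bin = np.bincount(bins[np.isin(leaves, held)], minlength=10)
    assert per_bin.tolist() == [2] * 10


def test_empty_holdout_and_determinism(rng):
    leaves = np.arange(50)
    bins = quantile_bins(rng.normal(size=50))
    held, rest = stratified_group_split(leaves, bins, 0,
                                        np.random.default_rng(0))
    assert held.size == 0 and rest.size == 50
    h1, _ = stratified_group_split(leaves, bins, 10, np.random.default_rng(7))
    h2, _ = stratified_group_split(leaves, bins, 10, np.random.default_rng(7))
    np.testing.assert_array_equal(h1, h2)
    h3, _ = stratified_group_split(leaves, bins, 10, np.random.default_rng(8))
    assert not np.array_equal(h1, h3)
    # per-bin counts identical across seeds even when the sets differ
    c1 = np.bincount(bins[np.isin(leaves, h1)], minlength=10)
    c3 = np.bincount(bins[np.isin(leaves, h3)], minlength=10)
    assert (np.abs(c1 - c3) <= 1).all()


def test_split_fails_when_a_bin_is_exhausted():
    leaves = np.arange(12)
    bins = np.array([0] * 11 + [1])        # bin 1 has a single leaf
    with pytest.raises(StratificationError):
        stratified_group_split(leaves, bins, 10, np.random.default_rng(0))


def test_splitter_keeps_groups_together(rng):
    groups = np.repeat(np.arange(40), 3)
    y = np.repeat(rng.normal(size=40), 3)
    X = rng.normal(size=(120, 4))
    splitter = StratifiedGroupShuffleSplit(n_splits=5, test_size=8,
                                           random_state=0)
    n_seen = 0
    for train, test in splitter.split(X, y, groups):
        n_seen += 1
        assert np.intersect1d(groups[train], groups[test]).size == 0
        assert len(np.unique(groups[test])) == 8
        assert len(train) + len(test) == 120
    assert n_seen == 5


# ---------------------------------------------------------------------------
# inner LV scan
# ---------------------------------------------------------------------------

def _linear_dataset(n=60, p=6, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(size=n) * noise
    return CalibrationDataset(
        X=X, leaf_codes=np.arange(n),
        leaf_labels=np.array([f"L{i}" for i in range(n)]), leaf_y=y)


def test_scan_over_single_k_chooses_that_k():
    ds = _linear_dataset()
    scan = inner_lv_scan(ds, np.arange(ds.n_leaves), [4], n_reps=3, seed=0)
    assert scan.chosen_lv == 4
    assert scan.lv_values.tolist() == [4]


def test_pure_noise_response_has_no_predictive_skill():
    rng = np.random.default_rng(3)
    ds = CalibrationDataset(
        X=rng.normal(size=(80, 6)), leaf_codes=np.arange(80),
        leaf_labels=np.array([f"L{i}" for i in range(80)]),
        leaf_y=rng.normal(size=80))
    scan = inner_lv_scan(ds, np.arange(80), range(1, 7), n_reps=20, seed=1)
    assert (scan.mean_r2 <= 2 * scan.sd_r2).all()


def test_scan_rejects_excessive_lv_range():
    ds = _linear_dataset(p=4)
    with pytest.raises(ConfigError):
        inner_lv_scan(ds, np.arange(ds.n_leaves), range(1, 9), seed=0)


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

def test_noise_free_linear_data_validate_perfectly():
    ds = _linear_dataset(n=120, p=6, noise=0.0, seed=4)
    res = nested_cv(ds, range(1, 7), outer_reps=3, inner_reps=3, seed=2)
    assert res.aggregates["validation_r2_mean"] == pytest.approx(1.0,
                                                                 abs=1e-6)
    assert res.aggregates["validation_mae_mean"] == pytest.approx(0.0,
                                                                  abs=1e-5)


def test_nested_cv_record_shape_and_reproducibility(mango_vis6):
    res1 = nested_cv(mango_vis6, range(1, 7), outer_reps=4, inner_reps=3,
                     seed=9)
    res2 = nested_cv(mango_vis6, range(1, 7), outer_reps=4, inner_reps=3,
                     seed=9)
    assert len(res1.records) == 4
    assert res1.records.equals(res2.records)
    assert set(res1.records["chosen_lv"]) <= set(range(1, 7))
    # aggregates recomputable from records
    assert res1.aggregates["validation_r2_mean"] == pytest.approx(
        res1.records["validation_r2"].mean())


def test_nested_cv_split_log_confirms_stratification(mango_vis6):
    res = nested_cv(mango_vis6, range(1, 7), outer_reps=5, inner_reps=2,
                    seed=0)
    for entry in res.split_log:
        counts = np.array(entry["validation_bin_counts"])
        assert counts.sum() == 20
        assert counts.max() - counts.min() <= 1
        assert len(set(entry["validation_leaves"])) == 20


def test_generalization_gap_is_small_on_smooth_profile(mango_vis6):
    res = nested_cv(mango_vis6, range(1, 7), outer_reps=10, inner_reps=5,
                    seed=17)
    gap = abs(res.aggregates["test_r2_mean"]
              - res.aggregates["validation_r2_mean"])
    assert gap < 0.05


# ---------------------------------------------------------------------------
# learning curves
# ---------------------------------------------------------------------------

def test_learning_curve_monotone_properties(mango_vis6):
    res = learning_curve(mango_vis6, n_lv=3, sizes=[8, 16, 32, 64],
                         reps=20, seed=5)
    # optimism: training error below test error at every size
    assert (res.train_mae_mean <= res.test_mae_mean + 1e-9).all()
    # consistency: more training data does not hurt
    assert res.test_mae_mean[-1] <= res.test_mae_mean[0]
    assert (res.to_frame()["n_train_leaves"].diff().dropna() > 0).all()


def test_learning_curve_rejects_oversized_training_pool(mango_vis6):
    with pytest.raises(ConfigError):
        learning_curve(mango_vis6, n_lv=3, sizes=[90], reps=2, seed=0)


def test_noise_free_learning_curve_reaches_zero_error():
    ds = _linear_dataset(n=80, p=4, noise=0.0, seed=8)
    res = learning_curve(ds, n_lv=4, sizes=[6, 12, 24], reps=5, seed=1)
    np.testing.assert_allclose(res.test_mae_mean, 0.0, atol=1e-7)


# ---------------------------------------------------------------------------
# chip comparison
# ---------------------------------------------------------------------------

def test_chip_comparison_outputs_all_subsets(mango_pop):
    ds = mango_pop.dataset("full18")
    tab = lc.chip_comparison(ds, n_lv=5, reps=4, seed=0)
    assert set(tab["subset"]) == {"combined", "A", "B", "C"}
    assert (tab["test_mae_mean"] > 0).all()


def test_chip_comparison_requires_chip_layout(mango_vis6):
    with pytest.raises(ConfigError):
        lc.chip_comparison(mango_vis6, reps=2, seed=0)
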