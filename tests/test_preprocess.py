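import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leafcal.preprocess as pp
from leafcal.errors import (
    DegenerateReferenceError,
    InsufficientDataError,
    ReplicateCountError,
)


# ---------------------------------------------------------------------------
# element-wise transforms
# ---------------------------------------------------------------------------

def test_reflectance_is_elementwise_ratio():
    np.testing.assert_allclose(
        pp.to_reflectance([50.0, 20.0], [100.0, 80.0]), [0.5, 0.25])
    np.testing.assert_allclose(
        pp.to_reflectance([100.0, 80.0], [100.0, 80.0]), [1.0, 1.0])


def test_reflectance_rejects_nonpositive_reference():
    with pytest.raises(DegenerateReferenceError):
        pp.to_reflectance([1.0, 2.0], [10.0, 0.0])


def test_absorbance_log_identities():
    np.testing.assert_allclose(pp.to_absorbance([1.0, 0.1]), [0.0, 1.0],
                               atol=1e-15)
    with pytest.raises(ValueError):
        pp.to_absorbance([0.0])


def test_reflectance_absorbance_round_trip(rng):
    r = rng.uniform(0.01, 1.5, size=200)
    back = 10.0 ** (-pp.to_absorbance(r))
    np.testing.assert_allclose(back, r, rtol=1e-12)


def test_total_chlorophyll_dmf_equation():
    assert pp.total_chlorophyll(0.0, 0.0) == 0.0
    assert pp.total_chlorophyll(1.0, 0.0) == pytest.approx(3.6486, abs=1e-9)
    assert pp.total_chlorophyll(0.5, 0.5) == pytest.approx(2.4579, abs=1e-9)
    with pytest.raises(ValueError):
        pp.total_chlorophyll(-0.1, 0.2)


def test_per_area_chlorophyll_scaling():
    assert pp.per_area_chlorophyll(10.0, 1.0, 1.0) == 10.0
    # linear in volume, inverse in area
    assert pp.per_area_chlorophyll(2.4579, 5.0, 3 * 0.28) == pytest.approx(
        2.4579 * 5.0 / 0.84, rel=1e-12)
    assert (pp.per_area_chlorophyll(3.0, 2.0, 1.0)
            == 2 * pp.per_area_chlorophyll(3.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        pp.per_area_chlorophyll(1.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Mahalanobis distances
# ---------------------------------------------------------------------------

def test_distance_of_sample_mean_is_zero(rng):
    m = rng.normal(size=4)
    v = rng.normal(size=(10, 4))
    X = np.vstack([m + v, m - v, m])     # sample mean is exactly m
    d = pp.mahalanobis_distances(X)
    assert d[-1] == pytest.approx(0.0, abs=1e-8)


def test_uncorrelated_standardized_distance_is_z_score_norm(rng):
    # 2-channel diagonal-covariance case: D^2 equals the sum of squared
    # z-scores computed with the explicitly inverted diagonal covariance
    X = rng.normal(size=(500, 2)) * [2.0, 0.5]
    d = pp.mahalanobis_distances(X)
    mu = X.mean(0)
    var = X.var(0, ddof=1)
    cov = np.cov(X.T)
    assert abs(cov[0, 1]) < 0.05  # nearly diagonal by construction
    Sinv = np.linalg.inv(np.diag(var) + (cov - np.diag(np.diag(cov))))
    d2_brute = np.einsum("ij,jk,ik->i", X - mu, Sinv, X - mu)
    np.testing.assert_allclose(d ** 2, d2_brute, rtol=1e-8)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(n=st.integers(10, 60), p=st.integers(2, 8), seed=st.integers(0, 10_000))
def test_squared_distances_sum_to_p_times_n_minus_1(n, p, seed):
    X = np.random.default_rng(seed).normal(size=(n, p))
    d = pp.mahalanobis_distances(X)
    assert np.sum(d ** 2) == pytest.approx(p * (n - 1), rel=1e-8)


def test_affine_invariance(rng):
    X = rng.normal(size=(80, 6))
    d0 = pp.mahalanobis_distances(X)
    A = rng.normal(size=(6, 6)) + 3 * np.eye(6)   # invertible w.h.p.
    assert np.linalg.matrix_rank(A) == 6
    d1 = pp.mahalanobis_distances(X @ A + rng.normal(size=6))
    np.testing.assert_allclose(d1, d0, atol=1e-8)


def test_too_few_spectra_raise():
    with pytest.raises(InsufficientDataError):
        pp.mahalanobis_distances(np.ones((2, 3)))


# ---------------------------------------------------------------------------
# replicate residues
# ---------------------------------------------------------------------------

def test_residue_is_difference_from_mean_of_others():
    X = np.array([[0.0, 0.0], [3.0, 3.0], [6.0, 6.0]])
    r = pp.replicate_residues(X, ["a", "a", "a"])
    np.testing.assert_allclose(r[0], [-4.5, -4.5])
    np.testing.assert_allclose(r.sum(axis=0), 0.0, atol=1e-12)


def test_identical_triplicate_gives_zero_residues():
    X = np.tile([1.0, 2.0, 3.0], (3, 1))
    r = pp.replicate_residues(X, ["a"] * 3)
    np.testing.assert_allclose(r, 0.0)


def test_wrong_replicate_count_names_the_leaf():
    X = np.ones((5, 2))
    with pytest.raises(ReplicateCountError, match="bad_leaf"):
        pp.replicate_residues(X, ["ok", "ok", "ok", "bad_leaf", "bad_leaf"])


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000), n_leaves=st.integers(1, 20))
def test_residues_of_each_leaf_sum_to_zero(seed, n_leaves):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(3 * n_leaves, 4))
    ids = np.repeat([f"L{i}" for i in range(n_leaves)], 3)
    r = pp.replicate_residues(X, ids)
    for i in range(n_leaves):
        np.testing.assert_allclose(r[ids == f"L{i}"].sum(axis=0), 0.0,
                                   atol=1e-9)


# ---------------------------------------------------------------------------
# 3-sigma flagging and reference screening
# ---------------------------------------------------------------------------

def test_equal_distances_produce_no_flags():
    assert not pp.flag_outliers_3sigma(np.full(50, 2.5)).any()


def test_flag_threshold_is_mean_plus_three_sd(rng):
    d = np.concatenate([rng.normal(10, 1, 200), [30.0]])
    flags = pp.flag_outliers_3sigma(d)
    thr = d.mean() + 3 * d.std(ddof=1)
    np.testing.assert_array_equal(flags, d > thr)
    assert flags[-1]


def _refs(disks, species="mango"):
    rows = []
    for i, d in enumerate(disks):
        rows.append({"leaf_id": f"L{i}", "species": species,
                     "disk1": d[0], "disk2": d[1], "disk3": d[2],
                     "mean_chl": np.mean(d)})
    return pd.DataFrame(rows)


def test_reference_screen_keeps_consistent_triplicates():
    refs = _refs([(40, 41, 42), (55, 54, 56), (30, 31, 29), (60, 61, 59)])
    out = pp.filter_reference_outliers(refs)
    assert not out[["excl1", "excl2", "excl3"]].to_numpy().any()


def test_reference_screen_excludes_deviant_disk():
    refs = _refs([(40, 41, 42), (55, 54, 56), (30, 31, 29), (60, 61, 90)])
    out = pp.filter_reference_outliers(refs)
    assert out.loc[3, "excl3"]
    assert out.loc[3, "mean_chl"] == pytest.approx(60.5)


def test_reference_screen_zero_variance_guard():
    # identical disks everywhere except one deviant: the floored pooled SD
    # still excludes it
    refs = _refs([(40, 40, 40), (50, 50, 50), (60, 60, 61)])
    out = pp.filter_reference_outliers(refs)
    assert out.loc[2, "excl3"]
    assert out.loc[2, "mean_chl"] == pytest.approx(60.0)


def test_reference_screen_errors_when_leaf_loses_all_disks():
    # two wildly disagreeing disks both fall beyond 3x the species spread
    refs = _refs([(40, 41, 42), (50, 51, 49), (np.nan, 10.0, 80.0)])
    with pytest.raises(InsufficientDataError):
        pp.filter_reference_outliers(refs)


# ---------------------------------------------------------------------------
# detector estimator
# ---------------------------------------------------------------------------

def test_detector_residue_mode_requires_groups(rng):
    X = rng.normal(size=(9, 3))
    det = pp.MahalanobisOutlierDetector(mode="residue")
    with pytest.raises(ValueError):
        det.fit(X)
    det.fit(X, groups=np.repeat(["a", "b", "c"], 3))
    assert det.labels_.shape == (9,)
    assert set(det.labels_) <= {-1, 1}


def test_detector_full_mode_flags_gross_outlier(rng):
    X = rng.normal(size=(60, 4))
    X[7] += 40.0
    det = pp.MahalanobisOutlierDetector(mode="full").fit(X)
    assert det.labels_[7] == -1


def test_detector_sklearn_param_interface():
    det = pp.MahalanobisOutlierDetector(mode="full", threshold_sigma=2.5)
    assert det.get_params() == {"mode": "full", "threshold_sigma": 2.5}
    det.set_params(mode="residue")
    assert det.mode == "residue"
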