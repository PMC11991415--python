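"""Group-stratified Monte-Carlo splitting, AIC LV selection, nested CV.

The evaluation protocol keeps every leaf's replicate spectra on one side
of every split (group integrity, preventing leakage through replicates)
and stratifies held-out sets over 10 quantile bins of leaf chlorophyll so
the response distribution matches across sets.

Model selection is double-nested: an outer Monte-Carlo loop holds out a
validation set of leaves (20 of 100 by default); on the remaining
training leaves an inner loop repeatedly splits 60/20, fits PLS for each
candidate LV count and scores leaf-level AIC on the inner test leaves;
the LV count minimizing the mean AIC (ties to the smaller k) is refit on
all training leaves and scored once on the untouched validation leaves.
With the default 50 outer and 20 inner repetitions the inner loop runs
1000 iterations per LV count.

A master seed deterministically spawns one child seed per outer
repetition (``SeedSequence(master).generate_state(reps) & 0x7FFFFFFF``),
so single repetitions are reproducible in isolation and full runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import PLSCalibrator, leaf_means, score
from .dataset import CalibrationDataset
from .errors import ConfigError, StratificationError
from .sensors import SensorLayout

__all__ = [
    "quantile_bins",
    "stratified_group_split",
    "StratifiedGroupShuffleSplit",
    "LVScanResult",
    "inner_lv_scan",
    "NestedCVResult",
    "nested_cv",
    "LearningCurveResult",
    "learning_curve",
    "chip_comparison",
    "default_lv_range",
]

# Numerical floor on RSS inside the scan so perfect fits select the
# smallest adequate k instead of producing -inf AIC.
_RSS_FLOOR = 1e-12


def default_lv_range(layout: SensorLayout) -> range:
    """Candidate LV counts: 1-6 for 6-channel layouts, 1-16 for 18."""
    return range(1, 7) if layout.n_channels <= 6 else range(1, 17)


# ---------------------------------------------------------------------------
# splitting primitives
# ---------------------------------------------------------------------------

def quantile_bins(values, n_bins: int = 10) -> np.ndarray:
    """Assign each value to one of ``n_bins`` near-equal-count quantile bins.

    Bin sizes differ by at most one; the bin index is monotone in the
    value, and ties are broken deterministically by stable input order.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < n_bins:
        raise StratificationError(f"need at least {n_bins} values, got {n}")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return ranks * n_bins // n


def stratified_group_split(leaves, bins, n_out: int,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Hold out ``n_out`` leaves sampled near-equally across bins.

    Every bin contributes ``n_out // n_bins`` leaves; the remainder is
    spread over a seeded random bin order, so per-bin held-out counts
    differ by at most one.  Returns ``(held_out, remaining)`` in original
    input order; the two sets are disjoint by construction.
    """
    leaves = np.asarray(leaves)
    bins = np.asarray(bins)
    if leaves.shape != bins.shape:
        raise ValueError("leaves and bins must align")
    if n_out < 0 or n_out > leaves.size:
        raise ConfigError(f"n_out={n_out} outside [0, {leaves.size}]")
    bin_labels = np.unique(bins)
    base, rem = divmod(n_out, bin_labels.size)
    quota = {int(b): base for b in bin_labels}
    for b in rng.permutation(bin_labels)[:rem]:
        quota[int(b)] += 1
    held_mask = np.zeros(leaves.size, dtype=bool)
    for b in bin_labels:
        members = np.flatnonzero(bins == b)
        q = quota[int(b)]
        if q > members.size:
            raise StratificationError(
                f"bin {b} has {members.size} leaves, cannot hold out {q}"
            )
        if q:
            held_mask[rng.choice(members, size=q, replace=False)] = True
    return leaves[held_mask], leaves[~held_mask]


class StratifiedGroupShuffleSplit:
    """Sklearn-compatible CV splitter with group integrity + y-stratification.

    Yields Monte-Carlo train/test splits of sample indices where all
    samples of a group (leaf) stay together and test groups sample the
    10 quantile bins of per-group mean ``y`` near-equally.

    Parameters
    ----------
    n_splits : number of Monte-Carlo repetitions.
    test_size : number of test groups (int) or fraction of groups (float).
    n_bins : quantile bins of per-group mean y.
    random_state : seed for the split sequence.
    """

    def __init__(self, n_splits: int = 10, test_size: float | int = 0.2,
                 n_bins: int = 10, random_state: int | None = None):
        self.n_splits = n_splits
        self.test_size = test_size
        self.n_bins = n_bins
        self.random_state = random_state

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def split(self, X, y, groups):
        if y is None or groups is None:
            raise ValueError("y and groups are required")
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        labels, codes = np.unique(groups, return_inverse=True)
        g_sum = np.bincount(codes, weights=y)
        g_y = g_sum / np.bincount(codes)
        bins = quantile_bins(g_y, self.n_bins)
        n_groups = labels.size
        n_test = (int(round(self.test_size * n_groups))
                  if isinstance(self.test_size, float) else int(self.test_size))
        rng = np.random.default_rng(self.random_state)
        all_codes = np.arange(n_groups)
        for _ in range(self.n_splits):
            test_g, train_g = stratified_group_split(all_codes, bins, n_test, rng)
            test_mask = np.isin(codes, test_g)
            yield np.flatnonzero(~test_mask), np.flatnonzero(test_mask)


def _assert_disjoint(train, test) -> None:
    overlap = np.intersect1d(train, test)
    if overlap.size:
        raise RuntimeError(f"leakage: leaves {overlap[:5]} in both sides of a split")


# ---------------------------------------------------------------------------
# inner scan
# ---------------------------------------------------------------------------

@dataclass
class LVScanResult:
    """Mean/SD AIC and leaf-level R2 per candidate LV count."""

    lv_values: np.ndarray
    mean_aic: np.ndarray
    sd_aic: np.ndarray
    mean_r2: np.ndarray
    sd_r2: np.ndarray
    mean_mae: np.ndarray
    sd_mae: np.ndarray
    chosen_lv: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_lv": self.lv_values, "mean_aic": self.mean_aic,
            "sd_aic": self.sd_aic, "mean_r2": self.mean_r2,
            "sd_r2": self.sd_r2, "mean_mae": self.mean_mae,
            "sd_mae": self.sd_mae,
        })


def _eval_leaf_level(X, codes, leaf_y, coef, intercept):
    preds = X @ coef + intercept
    labels, means = leaf_means(preds, codes)
    return score(leaf_y[labels], means)


def inner_lv_scan(ds: CalibrationDataset, leaves, lv_range, *,
                  n_test: int | None = None, n_reps: int = 20,
                  bins=None, rng: np.random.Generator | None = None,
                  seed: int | None = None) -> LVScanResult:
    """Scan candidate LV counts with repeated stratified inner splits.

    ``leaves`` are the training leaf codes; each repetition holds out
    ``n_test`` of them (default: a quarter, the study's 60/20 inner
    split), fits one PLS model per repetition at the largest k and
    evaluates the whole coefficient path on the inner-test leaves at
    leaf level.  ``chosen_lv`` minimizes the mean AIC, ties to smaller k.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    leaves = np.asarray(leaves)
    lv_values = np.array(sorted(set(int(k) for k in lv_range)))
    if lv_values.size == 0 or lv_values[0] < 1:
        raise ConfigError("lv_range must contain positive LV counts")
    if lv_values[-1] > ds.n_channels:
        raise ConfigError(
            f"lv_range max {lv_values[-1]} exceeds {ds.n_channels} channels")
    if n_test is None:
        n_test = max(1, int(round(0.25 * leaves.size)))
    if bins is None:
        bins = quantile_bins(ds.leaf_y[leaves])
    else:
        bins = np.asarray(bins)

    aics = np.empty((n_reps, lv_values.size))
    r2s = np.empty_like(aics)
    maes = np.empty_like(aics)
    k_max = int(lv_values[-1])
    for rep in range(n_reps):
        test_leaves, train_leaves = stratified_group_split(leaves, bins, n_test, rng)
        _assert_disjoint(train_leaves, test_leaves)
        tr = ds.row_mask(train_leaves)
        te = ds.row_mask(test_leaves)
        model = PLSCalibrator(n_components=k_max).fit(
            ds.X[tr], ds.leaf_y[ds.leaf_codes[tr]])
        path = model.coefficient_path(lv_values)
        X_te, codes_te = ds.X[te], ds.leaf_codes[te]
        n_eval = test_leaves.size
        for j, (coef, intercept) in enumerate(path):
            s = _eval_leaf_level(X_te, codes_te, ds.leaf_y, coef, intercept)
            rss = max(s.rss, _RSS_FLOOR)
            aics[rep, j] = n_eval * np.log(rss / n_eval) + 2.0 * lv_values[j]
            r2s[rep, j] = s.r2
            maes[rep, j] = s.mae
    mean_aic = aics.mean(axis=0)
    chosen = int(lv_values[int(np.argmin(mean_aic))])
    return LVScanResult(
        lv_values=lv_values,
        mean_aic=mean_aic, sd_aic=aics.std(axis=0, ddof=1),
        mean_r2=r2s.mean(axis=0), sd_r2=r2s.std(axis=0, ddof=1),
        mean_mae=maes.mean(axis=0), sd_mae=maes.std(axis=0, ddof=1),
        chosen_lv=chosen,
    )


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

@dataclass
class NestedCVResult:
    """Per-repetition nested-CV records with aggregate summaries."""

    records: pd.DataFrame
    aggregates: dict
    lv_range: tuple
    seed: int
    split_log: list = field(default_factory=list)

    def summary(self) -> dict:
        return dict(self.aggregates)


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    # documented spawning rule: 32-bit words of the master SeedSequence,
    # masked below 2^31 so they remain plain portable ints
    return (np.random.SeedSequence(seed).generate_state(n, np.uint32)
            & np.uint32(0x7FFFFFFF)).astype(np.int64)


def nested_cv(ds: CalibrationDataset, lv_range=None, *,
              outer_reps: int = 50, inner_reps: int = 20,
              n_validation: int | None = None, inner_test: int | None = None,
              n_bins: int = 10, seed: int = 0) -> NestedCVResult:
    """Double-nested Monte-Carlo cross-validation with AIC LV selection.

    Per outer repetition: hold out ``n_validation`` leaves (default 20%)
    stratified over the dataset-level quantile bins; run the inner LV
    scan on the remaining leaves; refit PLS at the chosen LV count on all
    of them; report leaf-level train/test/validation R2 and MAE.  Bin
    edges are computed once from all leaves and reused by every split.
    """
    if lv_range is None:
        if ds.layout is None:
            raise ConfigError("lv_range required when dataset has no layout")
        lv_range = default_lv_range(ds.layout)
    lv_values = sorted(set(int(k) for k in lv_range))
    n_leaves = ds.n_leaves
    if n_validation is None:
        n_validation = max(1, int(round(0.2 * n_leaves)))
    if n_validation >= n_leaves:
        raise ConfigError("n_validation must leave training leaves")
    bins = quantile_bins(ds.leaf_y, n_bins)
    all_leaves = np.arange(n_leaves)
    seeds = _rep_seeds(seed, outer_reps)

    records = []
    split_log = []
    for rep in range(outer_reps):
        rng = np.random.default_rng(seeds[rep])
        val_leaves, train_leaves = stratified_group_split(
            all_leaves, bins, n_validation, rng)
        _assert_disjoint(train_leaves, val_leaves)
        scan = inner_lv_scan(ds, train_leaves, lv_values,
                             n_test=inner_test, n_reps=inner_reps,
                             bins=bins[train_leaves], rng=rng)
        k = scan.chosen_lv
        tr = ds.row_mask(train_leaves)
        va = ds.row_mask(val_leaves)
        model = PLSCalibrator(n_components=k).fit(
            ds.X[tr], ds.leaf_y[ds.leaf_codes[tr]])
        s_train = _eval_leaf_level(ds.X[tr], ds.leaf_codes[tr], ds.leaf_y,
                                   model.coef_, model.intercept_)
        s_val = _eval_leaf_level(ds.X[va], ds.leaf_codes[va], ds.leaf_y,
                                 model.coef_, model.intercept_)
        j = lv_values.index(k)
        records.append({
            "rep": rep, "seed": int(seeds[rep]), "chosen_lv": k,
            "train_r2": s_train.r2, "train_mae": s_train.mae,
            "test_r2": scan.mean_r2[j], "test_mae": scan.mean_mae[j],
            "validation_r2": s_val.r2, "validation_mae": s_val.mae,
        })
        bc = np.bincount(bins[np.isin(all_leaves, val_leaves)],
                         minlength=bins.max() + 1)
        split_log.append({
            "rep": rep,
            "validation_leaves": tuple(ds.leaf_labels[val_leaves]),
            "validation_bin_counts": tuple(int(c) for c in bc),
        })
    records = pd.DataFrame(records)
    aggregates = {}
    for col in ("train_r2", "train_mae", "test_r2", "test_mae",
                "validation_r2", "validation_mae"):
        aggregates[f"{col}_mean"] = float(records[col].mean())
        aggregates[f"{col}_sd"] = float(records[col].std(ddof=1)) \
            if len(records) > 1 else 0.0
    counts = records["chosen_lv"].value_counts()
    aggregates["chosen_lv_mode"] = int(
        counts[counts == counts.max()].index.min())
    return NestedCVResult(records=records, aggregates=aggregates,
                          lv_range=tuple(lv_values), seed=seed,
                          split_log=split_log)


# ---------------------------------------------------------------------------
# learning curves
# ---------------------------------------------------------------------------

@dataclass
class LearningCurveResult:
    """Train/test MAE as a function of training-set size (in leaves)."""

    sizes: np.ndarray
    train_mae_mean: np.ndarray
    train_mae_sd: np.ndarray
    test_mae_mean: np.ndarray
    test_mae_sd: np.ndarray
    records: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_train_leaves": self.sizes,
            "train_mae_mean": self.train_mae_mean,
            "train_mae_sd": self.train_mae_sd,
            "test_mae_mean": self.test_mae_mean,
            "test_mae_sd": self.test_mae_sd,
        })


def learning_curve(ds: CalibrationDataset, n_lv: int, sizes, *,
                   reps: int = 20, n_test: int | None = None,
                   n_bins: int = 10, seed: int = 0) -> LearningCurveResult:
    """MAE versus number of training leaves at a fixed LV count.

    Each repetition draws one stratified test hold-out (shared across all
    sizes, isolating the training-size effect) and, for every size, a
    stratified training sample of that many leaves.
    """
    sizes = np.asarray(sorted(set(int(s) for s in sizes)))
    if sizes.size == 0 or sizes[0] < 2:
        raise ConfigError("sizes must contain counts >= 2")
    n_leaves = ds.n_leaves
    if n_test is None:
        n_test = max(1, int(round(0.2 * n_leaves)))
    if sizes[-1] > n_leaves - n_test:
        raise ConfigError(
            f"largest size {sizes[-1]} exceeds available training pool "
            f"({n_leaves - n_test} leaves)")
    bins = quantile_bins(ds.leaf_y, n_bins)
    all_leaves = np.arange(n_leaves)
    seeds = _rep_seeds(seed, reps)

    rows = []
    for rep in range(reps):
        rng = np.random.default_rng(seeds[rep])
        test_leaves, pool = stratified_group_split(all_leaves, bins, n_test, rng)
        te = ds.row_mask(test_leaves)
        for s in sizes:
            train_leaves, _ = stratified_group_split(pool, bins[pool], int(s), rng)
            _assert_disjoint(train_leaves, test_leaves)
            tr = ds.row_mask(train_leaves)
            model = PLSCalibrator(n_components=n_lv).fit(
                ds.X[tr], ds.leaf_y[ds.leaf_codes[tr]])
            s_tr = _eval_leaf_level(ds.X[tr], ds.leaf_codes[tr], ds.leaf_y,
                                    model.coef_, model.intercept_)
            s_te = _eval_leaf_level(ds.X[te], ds.leaf_codes[te], ds.leaf_y,
                                    model.coef_, model.intercept_)
            rows.append({"rep": rep, "n_train_leaves": int(s),
                         "train_mae": s_tr.mae, "test_mae": s_te.mae,
                         "train_r2": s_tr.r2, "test_r2": s_te.r2})
    records = pd.DataFrame(rows)
    g = records.groupby("n_train_leaves")
    return LearningCurveResult(
        sizes=sizes,
        train_mae_mean=g["train_mae"].mean().to_numpy(),
        train_mae_sd=g["train_mae"].std(ddof=1).to_numpy(),
        test_mae_mean=g["test_mae"].mean().to_numpy(),
        test_mae_sd=g["test_mae"].std(ddof=1).to_numpy(),
        records=records,
    )


# ---------------------------------------------------------------------------
# per-chip channel subsets
# ---------------------------------------------------------------------------

def chip_comparison(ds: CalibrationDataset, *, n_lv: int = 5, reps: int = 20,
                    n_test: int | None = None, n_bins: int = 10,
                    seed: int = 0) -> pd.DataFrame:
    """Test scores of each single-chip channel subset versus the full sensor.

    Fits PLS with a fixed LV count (default 5) on repeated stratified
    group splits, once per chip subset and once on all channels, sharing
    the same splits.  Returns a tidy table with one row per subset.
    """
    if ds.layout is None or not ds.layout.chip_ids:
        raise ConfigError("chip comparison needs a chip-mapped layout")
    subsets: dict[str, np.ndarray] = {"combined": np.ones(ds.n_channels, bool)}
    for cid in ds.layout.chip_ids:
        subsets[cid] = ds.layout.chip_mask(cid)
    n_leaves = ds.n_leaves
    if n_test is None:
        n_test = max(1, int(round(0.2 * n_leaves)))
    bins = quantile_bins(ds.leaf_y, n_bins)
    all_leaves = np.arange(n_leaves)
    seeds = _rep_seeds(seed, reps)

    rows = []
    for rep in range(reps):
        rng = np.random.default_rng(seeds[rep])
        test_leaves, train_leaves = stratified_group_split(
            all_leaves, bins, n_test, rng)
        _assert_disjoint(train_leaves, test_leaves)
        tr = ds.row_mask(train_leaves)
        te = ds.row_mask(test_leaves)
        for name, mask in subsets.items():
            model = PLSCalibrator(n_components=n_lv).fit(
                ds.X[tr][:, mask], ds.leaf_y[ds.leaf_codes[tr]])
            s = _eval_leaf_level(ds.X[te][:, mask], ds.leaf_codes[te],
                                 ds.leaf_y, model.coef_, model.intercept_)
            rows.append({"rep": rep, "subset": name,
                         "test_r2": s.r2, "test_mae": s.mae})
    records = pd.DataFrame(rows)
    g = records.groupby("subset", sort=False)
    return pd.DataFrame({
        "subset": list(g.groups),
        "n_lv": n_lv,
        "test_r2_mean": g["test_r2"].mean().to_numpy(),
        "test_r2_sd": g["test_r2"].std(ddof=1).to_numpy(),
        "test_mae_mean": g["test_mae"].mean().to_numpy(),
        "test_mae_sd": g["test_mae"].std(ddof=1).to_numpy(),
    })
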