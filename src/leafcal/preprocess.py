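"""Spectral normalization, reference chlorophyll, and outlier screening.

The raw sensor counts are normalized against a white reference,
``R = measured / reference``, and optionally converted to absorbance
``A = -log10(R)``.  Reference chlorophyll comes from triplicate leaf-disk
extractions in DMF: total chlorophyll (ug/mL) is

    0.18 * (20.27 * A647 + 7.04 * A664)

where the 0.18 factor absorbs path length and dilution, and per-area
chlorophyll (ug/cm2) is concentration * extract volume / disk area.

Erroneous spectra are screened with Mahalanobis distances.  Two modes
exist: ``full`` measures each spectrum against the population (which also
flags genuinely unusual leaves, e.g. young undeveloped ones), while
``residue`` measures each replicate against the mean of the other
replicates of the same leaf, isolating measurement error from real
leaf-to-leaf variation.  Flags use a 3-sigma cutoff on the distances,
computed independently per (sensor x species) dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, OutlierMixin

from .errors import (
    DegenerateReferenceError,
    InsufficientDataError,
    ReplicateCountError,
)
from .sensors import SensorLayout

__all__ = [
    "to_reflectance",
    "to_absorbance",
    "total_chlorophyll",
    "per_area_chlorophyll",
    "mahalanobis_distances",
    "replicate_residues",
    "flag_outliers_3sigma",
    "filter_reference_outliers",
    "normalize_spectra",
    "detect_spectral_outliers",
    "apply_outlier_flags",
    "MahalanobisOutlierDetector",
]

logger = logging.getLogger(__name__)

# Default disk-extraction geometry: 5 mL DMF per disk, 6 mm punch (~0.28 cm2).
EXTRACT_VOLUME_ML = 5.0
DISK_AREA_CM2 = 0.28

# Chlorophyll-in-DMF absorption model coefficients.
_CHL_PATH_DILUTION = 0.18
_CHL_COEF_647 = 20.27
_CHL_COEF_664 = 7.04


# ---------------------------------------------------------------------------
# element-wise transforms
# ---------------------------------------------------------------------------

def to_reflectance(measured, reference) -> np.ndarray:
    """Normalize raw counts against a white-reference reading, channel-wise."""
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if measured.shape[-1] != reference.shape[-1]:
        raise ValueError(
            f"measured has {measured.shape[-1]} channels, "
            f"reference has {reference.shape[-1]}"
        )
    if np.any(reference <= 0):
        bad = np.flatnonzero(np.atleast_1d(reference) <= 0)
        raise DegenerateReferenceError(
            f"white reference is <= 0 in channel index(es) {bad.tolist()}"
        )
    return measured / reference


def to_absorbance(reflectance) -> np.ndarray:
    """A = -log10(R); requires strictly positive reflectance."""
    reflectance = np.asarray(reflectance, dtype=float)
    if np.any(reflectance <= 0):
        raise ValueError("absorbance undefined for reflectance <= 0")
    return -np.log10(reflectance)


def total_chlorophyll(a647, a664):
    """Total chlorophyll concentration (ug/mL) from DMF-extract absorbances."""
    a647 = np.asarray(a647, dtype=float)
    a664 = np.asarray(a664, dtype=float)
    if np.any(a647 < 0) or np.any(a664 < 0):
        raise ValueError("absorbances must be >= 0")
    out = _CHL_PATH_DILUTION * (_CHL_COEF_647 * a647 + _CHL_COEF_664 * a664)
    return out if out.ndim else float(out)


def per_area_chlorophyll(concentration_ug_ml, extract_volume_ml, disk_area_cm2):
    """Convert extract concentration (ug/mL) to leaf-area density (ug/cm2)."""
    if extract_volume_ml <= 0 or disk_area_cm2 <= 0:
        raise ValueError("extract volume and disk area must be positive")
    out = np.asarray(concentration_ug_ml, dtype=float) * extract_volume_ml / disk_area_cm2
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Mahalanobis screening
# ---------------------------------------------------------------------------

def mahalanobis_distances(X, *, cond_threshold: float = 1e12) -> np.ndarray:
    """Mahalanobis distance of every row from the sample mean.

    Uses the sample covariance (n-1 denominator).  If the covariance is
    ill-conditioned (condition number beyond ``cond_threshold``, e.g. the
    highly correlated NIR bands on a small subset), a small ridge
    ``1e-8 * trace/p`` is added before inversion.  Returns D, the square
    root of the quadratic form, one value per row.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix of spectra")
    n, p = X.shape
    if n < 3:
        raise InsufficientDataError(f"need at least 3 spectra, got {n}")
    mu = X.mean(axis=0)
    Xc = X - mu
    S = (Xc.T @ Xc) / (n - 1)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > cond_threshold:
        S = S + (1e-8 * np.trace(S) / p) * np.eye(p)
    # solve instead of explicit inverse; S is symmetric PSD after ridging
    sol = linalg.solve(S, Xc.T, assume_a="pos")
    d2 = np.einsum("ij,ji->i", Xc, sol)
    return np.sqrt(np.clip(d2, 0.0, None))


def replicate_residues(X, leaf_ids) -> np.ndarray:
    """Per-replicate residue spectra: x_i minus the mean of the leaf's others.

    Rows must come in leaf triplicates (any order); the residues of a
    leaf sum to the zero vector.  Raises :class:`ReplicateCountError`
    naming the first leaf without exactly 3 replicates.
    """
    X = np.asarray(X, dtype=float)
    leaf_ids = np.asarray(leaf_ids)
    if X.shape[0] != leaf_ids.shape[0]:
        raise ValueError("X and leaf_ids must have matching length")
    residues = np.empty_like(X)
    labels, inverse, counts = np.unique(leaf_ids, return_inverse=True, return_counts=True)
    bad = np.flatnonzero(counts != 3)
    if bad.size:
        raise ReplicateCountError(
            f"leaf {labels[bad[0]]!r} has {counts[bad[0]]} replicates, expected 3"
        )
    sums = np.zeros((len(labels), X.shape[1]))
    np.add.at(sums, inverse, X)
    # mean of the other two: (sum - x_i) / 2; residue = x_i - that
    residues = X - (sums[inverse] - X) / 2.0
    return residues


def flag_outliers_3sigma(distances) -> np.ndarray:
    """Flag distances exceeding mean + 3 * sample SD of the distances."""
    d = np.asarray(distances, dtype=float)
    if d.size < 3:
        raise InsufficientDataError(f"need at least 3 distances, got {d.size}")
    threshold = d.mean() + 3.0 * d.std(ddof=1)
    return d > threshold


@dataclass(frozen=True)
class _FitResult:
    distances: np.ndarray
    flags: np.ndarray
    threshold: float


class MahalanobisOutlierDetector(BaseEstimator, OutlierMixin):
    """Sklearn-style spectral outlier screen.

    Parameters
    ----------
    mode : {"residue", "full"}
        ``full`` computes distances of raw spectra from the dataset mean;
        ``residue`` first forms per-replicate residues within each leaf
        (requires ``groups`` in :meth:`fit`), which ignores genuine
        leaf-to-leaf variation and targets measurement error only.
    threshold_sigma : float
        Flag rows with distance > mean + threshold_sigma * SD.

    Attributes (after fit)
    ----------------------
    distances_ : ndarray of shape (n,)
    labels_ : ndarray of shape (n,), -1 for outliers, +1 for inliers
    threshold_ : float
    """

    def __init__(self, mode: str = "residue", threshold_sigma: float = 3.0):
        self.mode = mode
        self.threshold_sigma = threshold_sigma

    def fit(self, X, y=None, *, groups=None):
        if self.mode not in ("residue", "full"):
            raise ValueError(f"mode must be 'residue' or 'full', got {self.mode!r}")
        X = np.asarray(X, dtype=float)
        if self.mode == "residue":
            if groups is None:
                raise ValueError("residue mode requires leaf groups")
            basis = replicate_residues(X, groups)
        else:
            basis = X
        d = mahalanobis_distances(basis)
        thr = d.mean() + self.threshold_sigma * d.std(ddof=1)
        self.distances_ = d
        self.threshold_ = float(thr)
        self.labels_ = np.where(d > thr, -1, 1)
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).labels_


# ---------------------------------------------------------------------------
# table-level orchestration
# ---------------------------------------------------------------------------

def normalize_spectra(spectra: pd.DataFrame, white_reference,
                      layout: SensorLayout) -> pd.DataFrame:
    """Replace raw channel counts by reflectance relative to the white reference.

    ``white_reference`` is the reference count vector for this layout
    (one session-level white reading).  Metadata columns pass through.
    """
    cols = layout.columns
    out = spectra.copy()
    out[cols] = to_reflectance(spectra[cols].to_numpy(float), white_reference)
    return out


def detect_spectral_outliers(reflectance: pd.DataFrame, layout: SensorLayout,
                             mode: str = "residue",
                             threshold_sigma: float = 3.0) -> pd.DataFrame:
    """Screen a reflectance table for outliers, independently per species.

    Returns a report with one row per replicate: ``leaf_id``, ``species``,
    ``sensor``, ``replicate``, ``distance``, ``flagged``, ``mode``.
    """
    reports = []
    for species, grp in reflectance.groupby("species", sort=True):
        det = MahalanobisOutlierDetector(mode=mode, threshold_sigma=threshold_sigma)
        det.fit(grp[layout.columns].to_numpy(float),
                groups=grp["leaf_id"].to_numpy())
        reports.append(pd.DataFrame({
            "leaf_id": grp["leaf_id"].to_numpy(),
            "species": species,
            "sensor": layout.name,
            "replicate": grp["replicate"].to_numpy(),
            "distance": det.distances_,
            "flagged": det.labels_ == -1,
            "mode": mode,
        }))
    report = pd.concat(reports, ignore_index=True)
    n_flagged = int(report["flagged"].sum())
    logger.info("outlier screen (%s, %s mode): %d of %d replicates flagged",
                layout.name, mode, n_flagged, len(report))
    return report


def apply_outlier_flags(reflectance: pd.DataFrame,
                        report: pd.DataFrame) -> pd.DataFrame:
    """Attach a boolean ``outlier`` column from a screening report."""
    key = ["leaf_id", "replicate"]
    flags = report.set_index(key)["flagged"]
    out = reflectance.copy()
    out["outlier"] = flags.reindex(
        pd.MultiIndex.from_frame(out[key])
    ).fillna(False).to_numpy(bool)
    return out


def filter_reference_outliers(references: pd.DataFrame, *,
                              sd_floor: float = 1e-6) -> pd.DataFrame:
    """Exclude deviant disks from triplicate reference measurements.

    Within each species, every disk's residual is taken from its leaf's
    disk median, and the within-leaf spread is estimated robustly as
    1.4826x the species-level median absolute residual (a MAD, floored
    at ``sd_floor`` ug/cm2 against zero-variance degeneracy).  Robust
    center and scale keep a gross disk error from masking itself by
    inflating the leaf mean and the pooled spread.  Disks beyond 3x the
    spread are excluded; leaf means are recomputed from the survivors,
    and a leaf losing all disks raises :class:`InsufficientDataError`.
    """
    disk_cols = ["disk1", "disk2", "disk3"]
    excl_cols = ["excl1", "excl2", "excl3"]
    out = references.copy()
    for c in excl_cols:
        if c not in out.columns:
            out[c] = False
    for species, grp in out.groupby("species", sort=True):
        disks = grp[disk_cols].to_numpy(float)            # (n_leaves, 3)
        usable = ~np.isnan(disks)
        counts = usable.sum(axis=1)
        if np.any(counts == 0):
            bad = grp.loc[counts == 0, "leaf_id"].iloc[0]
            raise InsufficientDataError(f"leaf {bad!r} has no usable disks")
        with np.errstate(invalid="ignore"):
            centers = np.nanmedian(disks, axis=1)
        resid = np.where(usable, disks - centers[:, None], 0.0)
        spread = 1.4826 * np.median(np.abs(resid[usable]))
        spread = max(spread, sd_floor)
        exclude = usable & (np.abs(resid) > 3.0 * spread)
        keep = usable & ~exclude
        n_keep = keep.sum(axis=1)
        if np.any(n_keep == 0):
            bad = grp.loc[n_keep == 0, "leaf_id"].iloc[0]
            raise InsufficientDataError(
                f"leaf {bad!r}: all disks excluded by the 3-sigma reference screen; "
                "drop the leaf explicitly upstream"
            )
        new_means = np.where(keep, disks, 0.0).sum(axis=1) / n_keep
        out.loc[grp.index, excl_cols] = exclude | ~usable
        out.loc[grp.index, "mean_chl"] = new_means
        n_excl = int(exclude.sum())
        if n_excl:
            logger.info("reference screen (%s): %d disk(s) excluded", species, n_excl)
    return out
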