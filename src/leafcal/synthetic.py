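"""Synthetic leaf populations with the statistical structure the pipeline assumes.

The generator emulates a calibration study on five species (banana,
jasmine, mango, rice, sugarcane), 100 leaves per species, three replicate
spectra per leaf on each sensor, and triplicate disk-extraction reference
measurements per leaf.

Chlorophyll-reflectance link
----------------------------
Leaf reflectance follows a Beer-Lambert-style form

    R(lambda) = R_bg(lambda) * exp(-kappa(lambda) * chl)

with the effective absorption kappa largest in the blue and red bands,
moderate in the green, and near zero in the NIR, so reflectance decreases
monotonically (and saturates) with chlorophyll in the absorbing bands
while the NIR plateau stays high.  Each leaf carries a multiplicative
texture factor; each replicate adds relative channel noise, and for
narrow-leaf species a per-replicate convex mixture with a flat 4% black
background emulates leaves that do not cover the optical path.  Replicate
noise is additive in relative-reflectance units (repositioning and
illumination error), with a small count-level shot-noise floor.  On the
18-channel layout, one multiplicative lognormal factor per chip per
replicate emulates the three apertures disagreeing on non-uniform
targets.  Raw counts are reflectance times a fixed per-layout reference
intensity curve.

Reference disks are drawn as chl + noise and converted to (A647, A664)
absorbance pairs that invert exactly through the DMF chlorophyll
equation, so with zero disk noise the reference pipeline reproduces the
true value to machine precision.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical arguments give byte-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as leafcal_io
from .dataset import CalibrationDataset
from .errors import ConfigError
from .preprocess import DISK_AREA_CM2, EXTRACT_VOLUME_ML
from .sensors import FULL18, NIR6, VIS6, SensorLayout

__all__ = [
    "SpeciesProfile",
    "SyntheticPopulation",
    "default_profiles",
    "simulate_population",
    "simulate_with_young_leaves",
    "inject_spectral_outliers",
    "simulate_factor_model",
    "reference_counts",
    "BACKGROUND_REFLECTANCE",
]

# Flat reflectance of the black measurement background.
BACKGROUND_REFLECTANCE = 0.04
# Chlorophyll-b/a absorbance ratio used when synthesizing (A647, A664) pairs.
_A647_OVER_A664 = 0.4

DEFAULT_LAYOUTS = (VIS6, NIR6, FULL18)


@dataclass(frozen=True)
class SpeciesProfile:
    """Noise and range parameters describing one species' leaf population.

    Parameters
    ----------
    name : species label.
    chl_range : (min, max) chlorophyll in ug/cm2, both positive.
    replicate_noise_sd : SD of per-replicate, per-channel noise in
        relative-reflectance units.
    leaf_texture_sd : per-leaf multiplicative (lognormal) reflectance spread.
    background_mix_max : max fraction of background reflectance mixed into a
        replicate; 0 for broad leaves that always cover the optical path.
    chip_artifact_sd : per-chip multiplicative (lognormal) error SD, applied
        to the 18-channel layout only.
    disk_noise_sd : SD of per-disk reference chlorophyll error, ug/cm2.
    """

    name: str
    chl_range: tuple[float, float]
    replicate_noise_sd: float
    leaf_texture_sd: float
    background_mix_max: float
    chip_artifact_sd: float
    disk_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.chl_range
        if not (0 < lo < hi):
            raise ConfigError(f"{self.name}: chl_range must satisfy 0 < min < max")
        if not 0 <= self.background_mix_max < 1:
            raise ConfigError(f"{self.name}: background_mix_max must be in [0, 1)")
        for attr in ("replicate_noise_sd", "leaf_texture_sd",
                     "chip_artifact_sd", "disk_noise_sd"):
            if getattr(self, attr) < 0:
                raise ConfigError(f"{self.name}: {attr} must be >= 0")


def default_profiles() -> dict[str, SpeciesProfile]:
    """The five study species.

    Broad smooth leaves (banana, mango) have the lowest replicate noise
    and no background mixing; jasmine is textured with the narrowest
    chlorophyll range; narrow-leaf rice and sugarcane mix in background
    reflectance and show the largest inter-chip aperture disagreement.
    """
    profiles = [
        SpeciesProfile("banana", (25.0, 80.0), 0.010, 0.03, 0.00, 0.005),
        SpeciesProfile("jasmine", (35.0, 65.0), 0.020, 0.06, 0.00, 0.020),
        SpeciesProfile("mango", (15.0, 90.0), 0.010, 0.04, 0.00, 0.005),
        SpeciesProfile("rice", (20.0, 70.0), 0.030, 0.05, 0.45, 0.100),
        SpeciesProfile("sugarcane", (20.0, 75.0), 0.025, 0.05, 0.25, 0.040),
    ]
    return {p.name: p for p in profiles}


# ---------------------------------------------------------------------------
# optical model
# ---------------------------------------------------------------------------

# Zero-chlorophyll leaf reflectance: moderate in the visible, high NIR
# plateau from the spongy mesophyll.
_WL = np.array([400, 450, 500, 550, 600, 650, 680, 700,
                720, 750, 800, 900, 950], dtype=float)
_R_BG = np.array([0.45, 0.48, 0.52, 0.55, 0.52, 0.50, 0.48, 0.55,
                  0.70, 0.82, 0.85, 0.84, 0.82])
# Effective absorption per ug/cm2: blue and red peaks, green dip, ~0 in NIR.
_KAPPA = np.array([0.028, 0.026, 0.012, 0.008, 0.010, 0.024, 0.030, 0.020,
                   0.006, 0.001, 0.0005, 0.0004, 0.0004])

# Illumination intensity at the white reference (arbitrary counts): a
# white LED with a blue peak, plus IR-LED support for the NIR layouts.
_I_WL = np.array([400, 450, 500, 550, 600, 650, 700, 760, 810, 860, 940, 960],
                 dtype=float)
_I_COUNTS = np.array([9000, 20000, 15000, 14000, 13000, 11000, 8000,
                      9000, 10000, 9000, 6000, 5000], dtype=float)


def _leaf_reflectance(chl: float, centers: np.ndarray,
                      nir_factor: float = 1.0) -> np.ndarray:
    """Mean reflectance of a leaf at the given channel centers."""
    r_bg = np.interp(centers, _WL, _R_BG)
    kappa = np.interp(centers, _WL, _KAPPA)
    r = r_bg * np.exp(-kappa * chl)
    if nir_factor != 1.0:
        r = np.where(centers >= 720.0, r * nir_factor, r)
    return r


def reference_counts(layout: SensorLayout) -> np.ndarray:
    """White-reference raw counts for a layout (fixed intensity curve)."""
    return np.interp(layout.centers, _I_WL, _I_COUNTS)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPopulation:
    """Simulated leaves, their reference measurements, and raw spectra.

    ``spectra`` maps layout name to a raw-count table in the spectra_io
    schema; ``white_reference`` maps layout name to the session reference
    counts; ``leaves`` records ground truth per leaf.
    """

    leaves: pd.DataFrame
    references: pd.DataFrame
    spectra: dict[str, pd.DataFrame]
    white_reference: dict[str, np.ndarray]
    layouts: dict[str, SensorLayout] = field(default_factory=dict)

    def to_dir(self, path) -> None:
        """Write all tables as CSV files under ``path``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.leaves.to_csv(path / "leaves.csv", index=False)
        leafcal_io.write_references(self.references, path / "references.csv")
        leafcal_io.write_white_reference(
            self.white_reference, self.layouts, path / "white_reference.csv")
        for name, df in self.spectra.items():
            leafcal_io.write_spectra(df, path / f"spectra_{name}.csv",
                                     self.layouts[name])

    def reflectance(self, layout_name: str) -> pd.DataFrame:
        """Convenience: spectra normalized by the white reference."""
        from .preprocess import normalize_spectra
        return normalize_spectra(self.spectra[layout_name],
                                 self.white_reference[layout_name],
                                 self.layouts[layout_name])

    def dataset(self, layout_name: str) -> CalibrationDataset:
        """Convenience: calibration dataset from reflectance + references."""
        return CalibrationDataset.from_frames(
            self.reflectance(layout_name), self.references,
            self.layouts[layout_name])


def _acquisition_meta(layout: SensorLayout) -> dict:
    # Acquisition settings mirror the study defaults: white LED at 12.5 mA,
    # 140 ms integration except the red/NIR-only device at 700 ms.
    if layout.name == "nir6":
        return {"led": "white", "integration_ms": 700, "current_ma": 12.5}
    led = "white+ir" if layout.name == "full18" else "white"
    return {"led": led, "integration_ms": 140, "current_ma": 12.5}


def _synthesize_references(leaf_ids, species, true_chl, disk_noise_sd, rng):
    rows = []
    denom = 0.18 * (20.27 * _A647_OVER_A664 + 7.04)
    for lid, sp, chl in zip(leaf_ids, species, true_chl):
        disks = chl + rng.normal(0.0, disk_noise_sd, size=3)
        disks = np.clip(disks, 0.1, None)
        conc = disks * DISK_AREA_CM2 / EXTRACT_VOLUME_ML
        a664 = conc / denom
        a647 = _A647_OVER_A664 * a664
        row = {"leaf_id": lid, "species": sp}
        for i in range(3):
            row[f"a647_{i + 1}"] = a647[i]
            row[f"a664_{i + 1}"] = a664[i]
            row[f"disk{i + 1}"] = disks[i]
            row[f"excl{i + 1}"] = False
        row["mean_chl"] = disks.mean()
        rows.append(row)
    return pd.DataFrame(rows)


def _simulate(profile: SpeciesProfile, n_leaves: int,
              layouts: tuple[SensorLayout, ...], rng: np.random.Generator,
              *, chl_values=None, nir_factors=None,
              leaf_prefix: str | None = None,
              shot_noise_scale: float = 1.0) -> SyntheticPopulation:
    if n_leaves < 1:
        raise ConfigError("n_leaves must be >= 1")
    layouts = tuple(layouts)
    prefix = leaf_prefix if leaf_prefix is not None else profile.name
    leaf_ids = np.array([f"{prefix}_{i:03d}" for i in range(n_leaves)])
    if chl_values is None:
        chl_values = rng.uniform(*profile.chl_range, size=n_leaves)
    else:
        chl_values = np.asarray(chl_values, dtype=float)
    if nir_factors is None:
        nir_factors = np.ones(n_leaves)
    texture = np.exp(rng.normal(0.0, profile.leaf_texture_sd, size=n_leaves))

    references = _synthesize_references(
        leaf_ids, [profile.name] * n_leaves, chl_values,
        profile.disk_noise_sd, rng)

    spectra: dict[str, pd.DataFrame] = {}
    white: dict[str, np.ndarray] = {}
    layout_map: dict[str, SensorLayout] = {}
    for layout in layouts:
        centers = layout.centers
        intensity = reference_counts(layout)
        meta = _acquisition_meta(layout)
        chip_masks = [layout.chip_mask(c) for c in layout.chip_ids]
        rows = []
        for i, lid in enumerate(leaf_ids):
            base = _leaf_reflectance(chl_values[i], centers,
                                     nir_factors[i]) * texture[i]
            for rep in (1, 2, 3):
                r = base
                if profile.background_mix_max > 0:
                    # On the multi-chip layout each aperture views its own
                    # patch of a narrow leaf, so the leaf/background mix
                    # differs per chip; single-aperture layouts share one mix.
                    if chip_masks:
                        r = r.copy()
                        for mask in chip_masks:
                            m = rng.uniform(0.0, profile.background_mix_max)
                            r[mask] = ((1.0 - m) * r[mask]
                                       + m * BACKGROUND_REFLECTANCE)
                    else:
                        m = rng.uniform(0.0, profile.background_mix_max)
                        r = (1.0 - m) * r + m * BACKGROUND_REFLECTANCE
                if chip_masks and profile.chip_artifact_sd > 0:
                    r = r.copy()
                    for mask in chip_masks:
                        r[mask] *= np.exp(
                            rng.normal(0.0, profile.chip_artifact_sd))
                if profile.replicate_noise_sd > 0:
                    # additive in relative-reflectance units: replicate error
                    # (repositioning, illumination) does not scale with the
                    # channel's reflectance level
                    r = r + rng.normal(
                        0.0, profile.replicate_noise_sd, size=len(centers))
                counts = np.clip(r * intensity, 0.0, None)
                if shot_noise_scale > 0:
                    counts = np.clip(
                        counts + shot_noise_scale * np.sqrt(counts)
                        * rng.normal(size=len(centers)), 0.0, None)
                row = {"leaf_id": lid, "species": profile.name,
                       "sensor": layout.name, "replicate": rep, **meta}
                row.update(dict(zip(layout.columns, counts)))
                rows.append(row)
        spectra[layout.name] = pd.DataFrame(rows)
        white[layout.name] = intensity
        layout_map[layout.name] = layout

    leaves = pd.DataFrame({
        "leaf_id": leaf_ids,
        "species": profile.name,
        "true_chl": chl_values,
        "is_young": nir_factors < 1.0,
    })
    return SyntheticPopulation(leaves=leaves, references=references,
                               spectra=spectra, white_reference=white,
                               layouts=layout_map)


def simulate_population(profile: SpeciesProfile, n_leaves: int = 100,
                        layouts: tuple[SensorLayout, ...] = DEFAULT_LAYOUTS,
                        seed: int = 0, *,
                        shot_noise_scale: float = 1.0) -> SyntheticPopulation:
    """Simulate one species' leaf population on the given sensor layouts.

    True chlorophyll is uniform over the profile's range; every leaf gets
    three replicate raw spectra per layout and three reference disks.
    ``shot_noise_scale`` scales the count-level (sqrt-intensity) detector
    noise; set it to 0 together with the profile SDs for a noise-free
    population.  The same seed reproduces the output exactly.
    """
    rng = np.random.default_rng(seed)
    return _simulate(profile, n_leaves, layouts, rng,
                     shot_noise_scale=shot_noise_scale)


def simulate_with_young_leaves(profile: SpeciesProfile, n_mature: int,
                               n_young: int,
                               layouts: tuple[SensorLayout, ...] = DEFAULT_LAYOUTS,
                               seed: int = 0, *,
                               young_chl: tuple[float, float] = (3.0, 8.0),
                               young_nir_factor: float = 0.6,
                               shot_noise_scale: float = 1.0
                               ) -> SyntheticPopulation:
    """A population containing undeveloped ("young") leaves.

    Young leaves sit off the mature chlorophyll-reflectance manifold:
    very low chlorophyll (high visible reflectance) combined with a
    reduced NIR plateau from an underdeveloped spongy mesophyll.  Their
    replicates are internally consistent, so a residue-based screen
    should not flag them while a full-spectrum screen does.  The returned
    ``leaves`` table marks them in the ``is_young`` column.
    """
    if n_mature < 1 or n_young < 0:
        raise ConfigError("need n_mature >= 1 and n_young >= 0")
    rng = np.random.default_rng(seed)
    n = n_mature + n_young
    chl = np.concatenate([
        rng.uniform(*profile.chl_range, size=n_mature),
        rng.uniform(*young_chl, size=n_young),
    ])
    nir = np.concatenate([np.ones(n_mature),
                          np.full(n_young, young_nir_factor)])
    return _simulate(profile, n, layouts, rng, chl_values=chl, nir_factors=nir,
                     shot_noise_scale=shot_noise_scale)


def inject_spectral_outliers(spectra: pd.DataFrame, layout: SensorLayout,
                             rate: float, magnitude: float, seed: int = 0
                             ) -> tuple[pd.DataFrame, list[tuple]]:
    """Corrupt a fraction of replicates for outlier-detection testing.

    ``round(rate * n)`` replicate rows are chosen without replacement and
    shifted by ``magnitude`` times the per-channel SD of the table, with
    a random sign per channel.  Returns the corrupted copy and the ground
    truth as a list of ``(leaf_id, sensor, replicate)`` tuples.
    """
    if spectra.empty:
        raise ConfigError("cannot inject outliers into an empty table")
    if not 0.0 <= rate <= 1.0:
        raise ConfigError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = spectra.copy()
    n = len(out)
    n_corrupt = int(round(rate * n))
    if n_corrupt == 0:
        return out, []
    idx = np.sort(rng.choice(n, size=n_corrupt, replace=False))
    cols = layout.columns
    channel_sd = out[cols].to_numpy(float).std(axis=0, ddof=1)
    truth = []
    for i in idx:
        signs = rng.choice([-1.0, 1.0], size=len(cols))
        out.iloc[i, out.columns.get_indexer(cols)] = np.clip(
            out.iloc[i][cols].to_numpy(float) + magnitude * channel_sd * signs,
            0.0, None)
        row = out.iloc[i]
        truth.append((row["leaf_id"], row["sensor"], int(row["replicate"])))
    return out, truth


def simulate_factor_model(n_leaves: int = 100, n_channels: int = 12,
                          n_factors: int = 3, noise_sd: float = 0.05,
                          y_noise_sd: float = 0.1, seed: int = 0
                          ) -> CalibrationDataset:
    """Data with a known latent dimensionality, for LV-recovery checks.

    ``X = T P + E`` with ``n_factors`` orthonormal loadings of decreasing
    scale, and ``y`` a linear combination of all factors plus noise.  One
    spectrum per leaf, so group splits reduce to plain splits.
    """
    rng = np.random.default_rng(seed)
    T = rng.normal(size=(n_leaves, n_factors))
    A = rng.normal(size=(n_channels, n_factors))
    P, _ = np.linalg.qr(A)                       # orthonormal columns
    scales = np.linspace(1.0, 0.6, n_factors)
    X = T @ (P * scales).T + rng.normal(0.0, noise_sd,
                                        size=(n_leaves, n_channels))
    q = np.linspace(3.0, 1.5, n_factors)
    y = T @ q + rng.normal(0.0, y_noise_sd, size=n_leaves)
    labels = np.array([f"leaf_{i:03d}" for i in range(n_leaves)])
    return CalibrationDataset(X=X, leaf_codes=np.arange(n_leaves),
                              leaf_labels=labels, leaf_y=y)
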