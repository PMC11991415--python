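"""CSV schemas for spectra, references, and white-reference tables.

All tables are comma-separated, UTF-8, dot-decimal, with a header row.

Spectra tables have one row per (leaf, sensor, replicate) with metadata
columns ``leaf_id, species, sensor, replicate, led, integration_ms,
current_ma`` followed by one ``ch_<center_nm>`` column per layout channel.
Reference tables have one row per leaf with triplicate disk chlorophyll
values (ug/cm2) and/or raw (A647, A664) absorbance pairs, exclusion flags
and the leaf mean.  White-reference tables are long-form
(sensor, channel, counts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import preprocess
from .errors import (
    ChannelCountError,
    MissingColumnError,
    NegativeCountError,
    SchemaError,
    UnknownSensorError,
)
from .sensors import SensorLayout

__all__ = [
    "SPECTRA_META_COLUMNS",
    "read_spectra",
    "write_spectra",
    "read_references",
    "write_references",
    "read_white_reference",
    "write_white_reference",
]

SPECTRA_META_COLUMNS = [
    "leaf_id", "species", "sensor", "replicate", "led",
    "integration_ms", "current_ma",
]

_REF_DISK_COLS = ["disk1", "disk2", "disk3"]
_REF_EXCL_COLS = ["excl1", "excl2", "excl3"]
_REF_ABS_COLS = [f"a{w}_{i}" for i in (1, 2, 3) for w in (647, 664)]


def _validate_spectra(df: pd.DataFrame, layout: SensorLayout) -> pd.DataFrame:
    missing = [c for c in SPECTRA_META_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"spectra table lacks column(s) {missing}")
    channel_cols = [c for c in df.columns if c.startswith("ch_")]
    if channel_cols != layout.columns:
        raise ChannelCountError(
            f"channel columns {channel_cols} do not match layout "
            f"{layout.name!r} ({layout.columns})"
        )
    bad_sensor = set(df["sensor"].unique()) - {layout.name}
    if bad_sensor:
        raise UnknownSensorError(
            f"spectra table names sensor(s) {sorted(bad_sensor)}, "
            f"expected {layout.name!r}"
        )
    counts = df[channel_cols].to_numpy(float)
    if np.any(~np.isfinite(counts)):
        raise SchemaError("spectra table contains non-finite counts")
    if np.any(counts < 0):
        raise NegativeCountError("spectra table contains negative counts")
    reps = df["replicate"].to_numpy()
    if not np.isin(reps, [1, 2, 3]).all():
        raise SchemaError("replicate must be 1, 2, or 3")
    df = df.copy()
    df["replicate"] = df["replicate"].astype(int)
    return df


def read_spectra(path, layout: SensorLayout) -> pd.DataFrame:
    """Read and validate a spectra table against ``layout``."""
    df = pd.read_csv(path)
    return _validate_spectra(df, layout)


def write_spectra(df: pd.DataFrame, path, layout: SensorLayout) -> None:
    """Validate and write a spectra table (row order preserved)."""
    df = _validate_spectra(df, layout)
    df.to_csv(path, index=False)


def read_references(path, *, extract_volume_ml: float = preprocess.EXTRACT_VOLUME_ML,
                    disk_area_cm2: float = preprocess.DISK_AREA_CM2) -> pd.DataFrame:
    """Read per-leaf reference chlorophyll.

    Accepts either per-disk chlorophyll columns (``disk1..3`` in ug/cm2)
    or raw absorbance pairs (``a647_i, a664_i``), from which disk values
    are derived via the DMF chlorophyll equation and the extraction
    geometry.  ``mean_chl`` is recomputed from non-excluded disks.
    """
    df = pd.read_csv(path)
    for c in ("leaf_id", "species"):
        if c not in df.columns:
            raise MissingColumnError(f"reference table lacks column {c!r}")
    df = df.copy()
    has_disks = all(c in df.columns for c in _REF_DISK_COLS)
    has_abs = all(c in df.columns for c in _REF_ABS_COLS)
    if not has_disks and not has_abs:
        raise MissingColumnError(
            "reference table needs disk1..3 or a647_i/a664_i columns"
        )
    if not has_disks:
        for i in (1, 2, 3):
            conc = preprocess.total_chlorophyll(df[f"a647_{i}"], df[f"a664_{i}"])
            df[f"disk{i}"] = preprocess.per_area_chlorophyll(
                conc, extract_volume_ml, disk_area_cm2
            )
    for c in _REF_EXCL_COLS:
        if c not in df.columns:
            df[c] = False
        df[c] = df[c].astype(bool)
    disks = df[_REF_DISK_COLS].to_numpy(float)
    excl = df[_REF_EXCL_COLS].to_numpy(bool)
    usable = ~excl & ~np.isnan(disks)
    n_usable = usable.sum(axis=1)
    if np.any(n_usable == 0):
        bad = df.loc[n_usable == 0, "leaf_id"].iloc[0]
        raise SchemaError(f"leaf {bad!r} has no usable reference disks")
    df["mean_chl"] = np.where(usable, disks, 0.0).sum(axis=1) / n_usable
    return df


def write_references(df: pd.DataFrame, path) -> None:
    for c in ("leaf_id", "species"):
        if c not in df.columns:
            raise MissingColumnError(f"reference table lacks column {c!r}")
    df.to_csv(path, index=False)


def write_white_reference(references: dict[str, np.ndarray],
                          layouts: dict[str, SensorLayout], path) -> None:
    """Write session white-reference counts, long-form (sensor, channel, counts)."""
    rows = []
    for name, counts in references.items():
        layout = layouts[name]
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != layout.n_channels:
            raise ChannelCountError(
                f"white reference for {name!r} has {counts.shape[0]} channels, "
                f"layout has {layout.n_channels}"
            )
        for col, v in zip(layout.columns, counts):
            rows.append({"sensor": name, "channel": col, "counts": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_white_reference(path, layouts: dict[str, SensorLayout]
                         ) -> dict[str, np.ndarray]:
    """Read white-reference counts; returns {sensor: counts ordered per layout}."""
    df = pd.read_csv(path)
    for c in ("sensor", "channel", "counts"):
        if c not in df.columns:
            raise MissingColumnError(f"white-reference table lacks column {c!r}")
    out: dict[str, np.ndarray] = {}
    for name, grp in df.groupby("sensor", sort=False):
        if name not in layouts:
            raise UnknownSensorError(f"white reference names unknown sensor {name!r}")
        layout = layouts[name]
        series = grp.set_index("channel")["counts"]
        missing = [c for c in layout.columns if c not in series.index]
        if missing or len(series) != layout.n_channels:
            raise ChannelCountError(
                f"white reference for {name!r} does not cover layout channels "
                f"(missing {missing})"
            )
        out[name] = series.loc[layout.columns].to_numpy(float)
    return out
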