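"""In-memory container pairing spectra with reference chlorophyll.

A :class:`CalibrationDataset` holds the reflectance matrix, an integer
leaf code per spectrum, and the per-leaf reference chlorophyll.  It is
the unit the resampling machinery operates on: splits act on leaf codes
(group integrity), fits act on spectra rows, and scores act on
leaf-averaged predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .sensors import SensorLayout

__all__ = ["CalibrationDataset"]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationDataset:
    """Spectra plus per-leaf reference values for one sensor (x species).

    Attributes
    ----------
    X : ndarray (n_spectra, n_channels)
        Reflectance (or absorbance) matrix.
    leaf_codes : ndarray (n_spectra,)
        Integer code of the leaf each row belongs to.
    leaf_labels : ndarray (n_leaves,)
        Leaf id per code.
    leaf_y : ndarray (n_leaves,)
        Reference chlorophyll (ug/cm2) per leaf code.
    layout : SensorLayout or None
    """

    X: np.ndarray
    leaf_codes: np.ndarray
    leaf_labels: np.ndarray
    leaf_y: np.ndarray
    layout: SensorLayout | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.leaf_codes = np.asarray(self.leaf_codes, dtype=int)
        self.leaf_y = np.asarray(self.leaf_y, dtype=float)
        if self.X.shape[0] != self.leaf_codes.shape[0]:
            raise SchemaError("X and leaf_codes must have matching length")
        if self.leaf_labels.shape[0] != self.leaf_y.shape[0]:
            raise SchemaError("leaf_labels and leaf_y must have matching length")

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    @property
    def n_leaves(self) -> int:
        return self.leaf_labels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def y_per_spectrum(self) -> np.ndarray:
        return self.leaf_y[self.leaf_codes]

    def row_mask(self, leaf_code_set) -> np.ndarray:
        """Boolean mask over spectra rows for a set of leaf codes."""
        return np.isin(self.leaf_codes, leaf_code_set)

    def subset_channels(self, mask: np.ndarray,
                        layout: SensorLayout | None = None) -> "CalibrationDataset":
        """Dataset restricted to a channel subset (e.g. one chip)."""
        return CalibrationDataset(
            X=self.X[:, mask], leaf_codes=self.leaf_codes,
            leaf_labels=self.leaf_labels, leaf_y=self.leaf_y,
            layout=layout, species=self.species,
        )

    @classmethod
    def from_frames(cls, reflectance: pd.DataFrame, references: pd.DataFrame,
                    layout: SensorLayout, *, drop_outliers: bool = True,
                    species: str | None = None) -> "CalibrationDataset":
        """Assemble a dataset from reflectance and reference tables.

        Rows flagged in an ``outlier`` column are dropped; leaves with no
        surviving replicates or no reference value are dropped with a
        logged warning.
        """
        df = reflectance
        if species is not None:
            df = df[df["species"] == species]
        if drop_outliers and "outlier" in df.columns:
            n_before = len(df)
            df = df[~df["outlier"].astype(bool)]
            if len(df) < n_before:
                logger.info("dropped %d flagged replicate(s)", n_before - len(df))
        ref = references.set_index("leaf_id")["mean_chl"]
        known = df["leaf_id"].isin(ref.index)
        if not known.all():
            missing = sorted(df.loc[~known, "leaf_id"].unique())
            logger.warning("dropping %d leaf(s) without reference values: %s",
                           len(missing), missing[:5])
            df = df[known]
        if df.empty:
            raise SchemaError("no spectra remain after filtering")
        labels, codes = np.unique(df["leaf_id"].to_numpy(), return_inverse=True)
        return cls(
            X=df[layout.columns].to_numpy(float),
            leaf_codes=codes,
            leaf_labels=labels,
            leaf_y=ref.loc[labels].to_numpy(float),
            layout=layout,
            species=species,
        )
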