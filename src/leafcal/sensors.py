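"""Channel layouts of the AMS multi-spectral sensor family.

Three layouts are modeled:

``vis6``
    Six visible channels (450-650 nm, FWHM 40 nm), AS7262-style.
``nir6``
    Six red/NIR channels (610-860 nm, FWHM 20 nm), AS7263-style.
``full18``
    Eighteen channels from 410 to 940 nm (FWHM 20 nm) spread over three
    6-channel chips, AS7265x-style.  Chip membership matters because the
    three chips sit behind separate apertures and can disagree on
    non-uniform targets; the chip map is configuration, not data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import yaml

from .errors import ConfigError, UnknownSensorError

__all__ = [
    "Channel",
    "SensorLayout",
    "VIS6",
    "NIR6",
    "FULL18",
    "LAYOUT_NAMES",
    "get_layout",
    "layouts_from_yaml",
]


@dataclass(frozen=True)
class Channel:
    """One spectral band: label, center wavelength, bandwidth, host chip."""

    label: str
    center_nm: float
    fwhm_nm: float
    chip_id: str | None = None


@dataclass(frozen=True)
class SensorLayout:
    """An ordered set of named channels with optional chip assignment.

    Invariants enforced at construction: centers strictly increasing;
    chip ids either absent everywhere or present everywhere; an
    18-channel layout with chips must have exactly 3 chips of 6
    channels each.
    """

    name: str
    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        centers = [c.center_nm for c in self.channels]
        if len(centers) < 1:
            raise ConfigError(f"layout {self.name!r} has no channels")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ConfigError(
                f"layout {self.name!r}: channel centers must be strictly increasing"
            )
        chip_ids = [c.chip_id for c in self.channels]
        has_chip = [cid is not None for cid in chip_ids]
        if any(has_chip) and not all(has_chip):
            raise ConfigError(
                f"layout {self.name!r}: chip ids must be set on all channels or none"
            )
        if all(has_chip) and len(self.channels) == 18:
            ids, counts = np.unique(chip_ids, return_counts=True)
            if len(ids) != 3 or any(counts != 6):
                raise ConfigError(
                    f"layout {self.name!r}: an 18-channel layout needs exactly "
                    f"3 chips of 6 channels each, got {dict(zip(ids, counts))}"
                )

    # -- derived views -------------------------------------------------

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center_nm for c in self.channels], dtype=float)

    @property
    def columns(self) -> list[str]:
        """CSV column names, one per channel (``ch_450`` ...)."""
        return [f"ch_{int(c.center_nm)}" for c in self.channels]

    @property
    def chip_ids(self) -> tuple[str, ...]:
        """Distinct chip ids in first-appearance order (empty if unchipped)."""
        seen: list[str] = []
        for c in self.channels:
            if c.chip_id is not None and c.chip_id not in seen:
                seen.append(c.chip_id)
        return tuple(seen)

    def chip_mask(self, chip_id: str) -> np.ndarray:
        """Boolean mask over channels belonging to ``chip_id``."""
        if chip_id not in self.chip_ids:
            raise ConfigError(
                f"layout {self.name!r} has no chip {chip_id!r}; "
                f"known chips: {list(self.chip_ids)}"
            )
        return np.array([c.chip_id == chip_id for c in self.channels])

    def chip_layout(self, chip_id: str) -> "SensorLayout":
        """A reduced layout containing only the channels of one chip."""
        mask = self.chip_mask(chip_id)
        sub = tuple(c for c, m in zip(self.channels, mask) if m)
        return SensorLayout(name=f"{self.name}:{chip_id}", channels=sub)


def _make(name: str, centers: Iterable[float], fwhm: float,
          chips: Iterable[str | None] | None = None) -> SensorLayout:
    centers = list(centers)
    chips = list(chips) if chips is not None else [None] * len(centers)
    channels = tuple(
        Channel(label=f"ch_{int(c)}", center_nm=float(c), fwhm_nm=fwhm, chip_id=cid)
        for c, cid in zip(centers, chips)
    )
    return SensorLayout(name=name, channels=channels)


VIS6 = _make("vis6", [450, 500, 550, 570, 600, 650], fwhm=40.0)
NIR6 = _make("nir6", [610, 680, 730, 760, 810, 860], fwhm=20.0)

# Default chip map for the 18-channel device.  Chip A holds the first six
# channels (closest to the illumination LED); chips B and C interleave the
# remaining twelve.  Device revisions differ in this mapping, so it is
# configurable via layouts_from_yaml; analyses record which map they used.
_FULL18_CENTERS = [410, 435, 460, 485, 510, 535, 560, 585, 610,
                   645, 680, 705, 730, 760, 810, 860, 900, 940]
_FULL18_CHIPS = {
    "A": {410, 435, 460, 485, 510, 535},
    "B": {560, 585, 645, 705, 900, 940},
    "C": {610, 680, 730, 760, 810, 860},
}
FULL18 = _make(
    "full18",
    _FULL18_CENTERS,
    fwhm=20.0,
    chips=[next(k for k, v in _FULL18_CHIPS.items() if c in v)
           for c in _FULL18_CENTERS],
)

_BUILTIN = {"vis6": VIS6, "nir6": NIR6, "full18": FULL18}
LAYOUT_NAMES = tuple(_BUILTIN)


def get_layout(name: str) -> SensorLayout:
    """Return a built-in layout by name (``vis6`` | ``nir6`` | ``full18``)."""
    try:
        return _BUILTIN[name]
    except KeyError:
        raise UnknownSensorError(
            f"unknown sensor layout {name!r}; known: {sorted(_BUILTIN)}"
        ) from None


def layouts_from_yaml(path) -> dict[str, SensorLayout]:
    """Load custom layouts (e.g. an alternative chip map) from a YAML file.

    Expected structure::

        full18:
          fwhm_nm: 20
          channels:
            - {center: 410, chip: A}
            - {center: 435, chip: A}
            ...
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"layout file {path} must map names to layouts")
    layouts: dict[str, SensorLayout] = {}
    for name, body in raw.items():
        try:
            fwhm = float(body["fwhm_nm"])
            entries = body["channels"]
            centers = [float(e["center"]) for e in entries]
            chips = [e.get("chip") for e in entries]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"layout {name!r} in {path}: {exc}") from exc
        layouts[name] = _make(name, centers, fwhm, chips)
    return layouts
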