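"""Canopy temperature statistics from thermal infrared rasters.

A transpiring canopy evaporatively cools below the ambient background;
drought closes stomata and lets leaf temperature rise toward (or past)
air temperature. Besides the canopy mean and minimum, the expansion of the
"low-temperature region" is quantified as the fraction of canopy pixels
below a threshold, by default defined relative to the scene background
(background median − 2 °C) so the statistic transfers across scenes with
different ambient temperatures; an absolute threshold is available for
calibrated cross-scene comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from ._exceptions import ParameterizationError, UndefinedFeatureError

__all__ = [
    "ThermalSummary",
    "canopy_stats",
    "segment_canopy_thermal",
    "read_thermal_csv",
    "write_thermal_csv",
]

#: Default offset (°C) below the background median defining "low temperature".
DEFAULT_REL_OFFSET_C = 2.0


@dataclass(frozen=True)
class ThermalSummary:
    """Canopy temperature summary for one thermal acquisition."""

    canopy_mean: float
    canopy_min: float
    low_temp_fraction: float
    threshold_used: float


def canopy_stats(
    temps: np.ndarray,
    mask: np.ndarray,
    rel_offset_c: float = DEFAULT_REL_OFFSET_C,
    abs_threshold_c: float | None = None,
) -> ThermalSummary:
    """Mean/min canopy temperature and low-temperature pixel fraction.

    ``low_temp_fraction`` is the fraction of canopy (masked) pixels strictly
    below the threshold. The threshold is ``abs_threshold_c`` when given,
    else background median − ``rel_offset_c``.
    """
    temps = np.asarray(temps, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if temps.shape != mask.shape:
        raise ParameterizationError("raster and mask shapes do not match")
    if not np.all(np.isfinite(temps)):
        raise ParameterizationError("raster contains non-finite temperatures")
    canopy = temps[mask]
    if canopy.size == 0:
        raise UndefinedFeatureError("canopy statistics undefined: empty mask")
    if abs_threshold_c is not None:
        threshold = float(abs_threshold_c)
    else:
        background = temps[~mask]
        if background.size == 0:
            raise ParameterizationError(
                "no background pixels; pass abs_threshold_c"
            )
        threshold = float(np.median(background)) - rel_offset_c
    return ThermalSummary(
        canopy_mean=float(canopy.mean()),
        canopy_min=float(canopy.min()),
        low_temp_fraction=float(np.mean(canopy < threshold)),
        threshold_used=threshold,
    )


def segment_canopy_thermal(temps: np.ndarray) -> np.ndarray:
    """Segment the canopy from a thermal raster alone.

    Thermal and visible cameras are not co-registered, so the thermal
    modality gets its own mask: an Otsu split of the temperature histogram,
    with the cooler class taken as canopy (the transpiring canopy is cooler
    than the surround).
    """
    temps = np.asarray(temps, dtype=float)
    if np.ptp(temps) == 0:
        raise UndefinedFeatureError("constant raster cannot be segmented")
    return temps < threshold_otsu(temps)


def write_thermal_csv(temps: np.ndarray, path: str | Path) -> None:
    """Write a raster as a headerless CSV grid of °C values."""
    np.savetxt(path, np.asarray(temps, dtype=float), delimiter=",", fmt="%.4f")


def read_thermal_csv(path: str | Path) -> np.ndarray:
    """Read a raster written by :func:`write_thermal_csv`."""
    return np.loadtxt(path, delimiter=",", dtype=float)
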