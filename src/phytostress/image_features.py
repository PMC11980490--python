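"""RGB histogram features of segmented plant images.

A visible-light image of a potted plant is background-subtracted and
segmented, and each color channel of the plant body is summarized by its
intensity histogram: the integral area (number of contributing pixels), the
barycenter (intensity-weighted mean, i.e. the histogram's center of mass on
the 0-255 axis) and the full width at half maximum of the dominant histogram
peak. The green-dominance statistic

    GD = G / (R + G + B)

with R, G, B the per-channel barycenters, is a scale-free proxy for leaf
greenness: chlorophyll loss under drought shifts weight from the green
channel toward red, lowering GD.

Intensity 0 is excluded from every feature: background subtraction zeroes
the background, so the zero bin mixes true background with genuinely black
foreground pixels and is discarded. This also explains why per-channel pixel
counts of the same plant can differ slightly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from skimage.morphology import remove_small_objects

from ._exceptions import ParameterizationError, UndefinedFeatureError

__all__ = [
    "CHANNELS",
    "ChannelHistogram",
    "ChannelFeatures",
    "GDResult",
    "FWHMResult",
    "ImageFeatureRow",
    "segment_plant",
    "channel_histogram",
    "integral_area",
    "barycenter",
    "fwhm",
    "green_dominance",
    "image_feature_row",
]

CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class ChannelHistogram:
    """Intensity histogram of one color channel over the plant mask."""

    counts: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (256,):
            raise ParameterizationError("histogram must have 256 bins")
        if np.any(counts < 0):
            raise ParameterizationError("histogram counts must be >= 0")
        object.__setattr__(self, "counts", counts)
        if self.channel not in CHANNELS:
            raise ParameterizationError(f"channel must be one of {CHANNELS}")


class FWHMResult(NamedTuple):
    """Full width at half maximum; ``one_sided`` flags a boundary peak whose
    width was doubled from the single available half-max crossing."""

    width: float
    one_sided: bool


@dataclass(frozen=True)
class ChannelFeatures:
    """Histogram summary of one channel (one third of a feature-table row)."""

    integral_area: int
    barycenter: float
    fwhm: float
    fwhm_one_sided: bool = False

    @property
    def defined(self) -> bool:
        return self.integral_area > 0


@dataclass(frozen=True)
class GDResult:
    """Green dominance, stored as a full-precision fraction in (0, 1)."""

    gd: float

    @property
    def percent(self) -> float:
        """GD as a percentage rounded to one decimal (table convention)."""
        return round(self.gd * 100.0, 1)


def segment_plant(
    image: np.ndarray,
    bg_level: int = 0,
    tol: int = 10,
    min_size: int = 16,
) -> np.ndarray:
    """Segment the plant body from a background-subtracted RGB image.

    A pixel belongs to the plant when the largest per-channel distance from
    ``bg_level`` exceeds ``tol``; connected components smaller than
    ``min_size`` pixels are then removed as noise. With ``tol=0`` every
    pixel differing from the background level is selected before the area
    filter. An empty mask is a legal result.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ParameterizationError("expected an H×W×3 RGB image")
    dist = np.abs(image.astype(np.int16) - int(bg_level)).max(axis=2)
    mask = dist > tol
    if min_size > 1:
        # remove components strictly smaller than min_size pixels
        mask = remove_small_objects(mask, max_size=min_size - 1)
    return mask


def channel_histogram(
    image: np.ndarray, mask: np.ndarray, channel: str
) -> ChannelHistogram:
    """Histogram of one channel's intensities over the masked pixels."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ParameterizationError("image and mask shapes do not match")
    ci = CHANNELS.index(channel)
    values = image[..., ci][mask]
    counts = np.bincount(values.ravel(), minlength=256)[:256]
    return ChannelHistogram(counts=counts, channel=channel)


def integral_area(h: ChannelHistogram) -> int:
    """Number of pixels contributing to the histogram (zero bin excluded)."""
    return int(h.counts[1:].sum())


def barycenter(h: ChannelHistogram) -> float:
    """Intensity-weighted mean of the histogram over intensities 1..255."""
    counts = h.counts[1:].astype(float)
    total = counts.sum()
    if total == 0:
        raise UndefinedFeatureError(
            f"barycenter undefined for empty {h.channel} histogram"
        )
    v = np.arange(1, 256, dtype=float)
    return float((v * counts).sum() / total)


def fwhm(h: ChannelHistogram, smooth_window: int = 5) -> FWHMResult:
    """Full width at half maximum of the dominant histogram peak.

    The counts over intensities 1..255 are smoothed with a centered moving
    average of ``smooth_window`` bins (real plant histograms are ragged;
    ``smooth_window=1`` disables smoothing), the global maximum is located
    (first bin on ties), and the nearest half-maximum crossings on either
    side of the peak are found by linear interpolation between adjacent
    bins. When a boundary peak has a crossing on only one side, that
    half-width is doubled and the result is flagged ``one_sided``.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ParameterizationError("smooth_window must be a positive odd int")
    counts = h.counts[1:].astype(float)
    if counts.sum() == 0:
        raise UndefinedFeatureError(
            f"FWHM undefined for empty {h.channel} histogram"
        )
    x = np.arange(1, 256, dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        s = np.convolve(counts, kernel, mode="same")
    else:
        s = counts
    peak = int(np.argmax(s))
    half = s[peak] / 2.0
    if half <= 0:
        raise UndefinedFeatureError("histogram peak has no positive maximum")

    left = _crossing(x, s, peak, half, side="left")
    right = _crossing(x, s, peak, half, side="right")
    if left is not None and right is not None:
        return FWHMResult(width=right - left, one_sided=False)
    if left is not None:
        return FWHMResult(width=2.0 * (x[peak] - left), one_sided=True)
    if right is not None:
        return FWHMResult(width=2.0 * (right - x[peak]), one_sided=True)
    raise UndefinedFeatureError("no half-maximum crossing on either side")


def _crossing(
    x: np.ndarray, s: np.ndarray, peak: int, half: float, side: str
) -> float | None:
    """Nearest half-max crossing on one side of the peak, interpolated."""
    if side == "left":
        below = np.nonzero(s[:peak] < half)[0]
        if below.size == 0:
            return None
        j = int(below[-1])  # last bin below half before the peak
        return x[j] + (half - s[j]) / (s[j + 1] - s[j])
    below = np.nonzero(s[peak + 1 :] < half)[0]
    if below.size == 0:
        return None
    j = int(below[0]) + peak + 1  # first bin below half after the peak
    return x[j - 1] + (s[j - 1] - half) / (s[j - 1] - s[j])


def green_dominance(r_bary: float, g_bary: float, b_bary: float) -> GDResult:
    """Green dominance GD = G / (R + G + B) from channel barycenters."""
    if min(r_bary, g_bary, b_bary) <= 0:
        raise UndefinedFeatureError("barycenters must all be positive")
    return GDResult(gd=g_bary / (r_bary + g_bary + b_bary))


@dataclass(frozen=True)
class ImageFeatureRow:
    """Per-channel histogram features plus green dominance for one image.

    ``gd`` is NaN when any channel is empty (undefined features are flagged
    rather than imputed).
    """

    channels: dict
    gd: float

    @property
    def complete(self) -> bool:
        return all(cf.defined for cf in self.channels.values()) and bool(
            np.isfinite(self.gd)
        )


def image_feature_row(
    image: np.ndarray, mask: np.ndarray, smooth_window: int = 5
) -> ImageFeatureRow:
    """Compute the full per-channel feature set and GD for one image."""
    features: dict[str, ChannelFeatures] = {}
    barys: dict[str, float] = {}
    for ch in CHANNELS:
        h = channel_histogram(image, mask, ch)
        area = integral_area(h)
        if area == 0:
            features[ch] = ChannelFeatures(
                integral_area=0, barycenter=float("nan"), fwhm=float("nan")
            )
            continue
        bary = barycenter(h)
        width = fwhm(h, smooth_window=smooth_window)
        features[ch] = ChannelFeatures(
            integral_area=area,
            barycenter=bary,
            fwhm=width.width,
            fwhm_one_sided=width.one_sided,
        )
        barys[ch] = bary
    if len(barys) == len(CHANNELS):
        gd = green_dominance(barys["R"], barys["G"], barys["B"]).gd
    else:
        gd = float("nan")
    return ImageFeatureRow(channels=features, gd=gd)
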