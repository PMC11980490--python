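"""Synthetic multi-modal acquisition generator.

Emulates the study's acquisitions for every (treatment, day) cell so the
whole analysis pipeline runs with no external data: visible-light plant
images (elliptical "leaf" blobs with per-channel Gaussian intensities on a
uniform background), thermal rasters (cool canopy blobs on a warm
background), electrical signals (a fast carrier plus a slow sub-5 Hz wave
plus white noise) and DPV voltammograms (Gaussian redox peaks on a linear
baseline). Generators are calibrated to the reference tables in
:mod:`phytostress.study` so downstream features reproduce the study's
trends, and are bitwise deterministic given their seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy.optimize import brentq
from scipy.stats import norm

from ._exceptions import ParameterizationError
from .dpv import Voltammogram
from .esignal import Signal
from .study import (
    RGB_CALIBRATION,
    SIGNAL_CALIBRATION,
    SLOW_AMP_FRACTION,
    THERMAL_BACKGROUND_C,
    THERMAL_CALIBRATION,
    StudyCondition,
    Treatment,
    study_grid,
)
from .thermal_features import write_thermal_csv

__all__ = [
    "GAUSSIAN_FWHM_OVER_SD",
    "ImageGenParams",
    "ESignalGenParams",
    "ThermalGenParams",
    "DPVGenParams",
    "generate_plant_image",
    "generate_esignal",
    "generate_thermal_image",
    "generate_dpv",
    "default_image_params",
    "default_esignal_params",
    "default_thermal_params",
    "default_dpv_params",
    "StudyConfig",
    "default_study_config",
    "generate_study",
]

#: FWHM of a Gaussian divided by its standard deviation, 2·sqrt(2·ln 2).
GAUSSIAN_FWHM_OVER_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))

# Native acquisition frames and the desk-scale frame (area ≈ native/10,
# same 1.6:1 aspect) used by default to keep image synthesis light.
FULL_FRAME = (1280, 800)
DESK_FRAME = (404, 252)
DESK_COUNT_DIVISOR = 10
THERMAL_FRAME = (256, 192)

#: DPV fingerprint defaults: three anonymous redox peaks (position V,
#: height µA, FWHM V) on a −2 µA/V baseline. Drought in untreated soil is
#: realized as peak broadening (×1.4 per two days, saturating at ×1.96 —
#: electrode fouling by viscous sap levels off) with small position jitter;
#: biochar as a higher concentration scale.
DPV_BASE_PEAKS = ((-0.5, 4.0, 0.10), (-0.75, 6.0, 0.10), (-1.0, 3.0, 0.10))
DPV_CONCENTRATION_SCALE = {
    Treatment.ORIGINAL: 1.0,
    Treatment.BIOCHAR2: 1.3,
    Treatment.BIOCHAR4: 1.6,
}
DPV_WIDTH_GROWTH_PER_2D = 1.4  # untreated soil only
DPV_WIDTH_GROWTH_CAP = 1.4**2
DPV_JITTER_SD_PER_2D = 0.003  # V, untreated soil only


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGenParams:
    """Parameters of one synthetic visible-light plant image.

    ``channel_means`` are the targets for the downstream per-channel
    histogram barycenters (0-255 scale); ``channel_sds`` the corresponding
    spreads (FWHM / 2.3548).
    """

    width: int = DESK_FRAME[0]
    height: int = DESK_FRAME[1]
    n_foreground: int = 40000
    channel_means: tuple[float, float, float] = (122.19, 155.78, 94.30)
    channel_sds: tuple[float, float, float] = (39.59, 35.93, 41.73)
    background_level: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterizationError("frame dimensions must be positive")
        if not 0 < self.n_foreground < self.width * self.height:
            raise ParameterizationError(
                f"n_foreground must be in (0, {self.width * self.height}), "
                f"got {self.n_foreground}"
            )
        if len(self.channel_means) != 3 or len(self.channel_sds) != 3:
            raise ParameterizationError("channel_means/sds must be triples")
        if any(not 0 <= m <= 255 for m in self.channel_means):
            raise ParameterizationError("channel_means must lie in [0, 255]")
        if any(sd <= 0 for sd in self.channel_sds):
            raise ParameterizationError("channel_sds must be positive")
        if not 0 <= self.background_level <= 255:
            raise ParameterizationError("background_level must lie in [0, 255]")


@dataclass(frozen=True)
class ESignalGenParams:
    """Parameters of one synthetic electrical signal.

    The deterministic part is a fast carrier sinusoid (default 50 Hz, the
    ~20 ms oscillation seen in the recordings) plus a slow wave at the
    plant's characteristic frequency (default 0.37 Hz), with
    ``slow_amp_fraction`` of the half peak-to-peak amplitude assigned to the
    slow wave. The default duration of 100 s puts 0.37 Hz exactly on a
    0.01 Hz Fourier bin. Defaults correspond to the most drought-stressed
    cell (untreated soil, day 6).
    """

    fs: float = 2000.0
    duration: float = 100.0
    carrier_freq: float = 50.0
    carrier_pp: float = 5.008
    slow_freq: float = 0.37
    slow_amp_fraction: float = 0.20
    noise_sd: float = 0.02
    seed: int = 1

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ParameterizationError("fs and duration must be positive")
        if self.carrier_freq <= 0 or self.fs <= 2 * self.carrier_freq:
            raise ParameterizationError("need fs > 2·carrier_freq > 0")
        if not 0 < self.slow_freq < 5:
            raise ParameterizationError("slow_freq must lie in (0, 5) Hz")
        cycles = self.duration * self.slow_freq
        if abs(cycles - round(cycles)) > 1e-9:
            raise ParameterizationError(
                "duration·slow_freq must be an integer (whole slow cycles)"
            )
        if not 0 <= self.slow_amp_fraction < 1:
            raise ParameterizationError("slow_amp_fraction must lie in [0, 1)")
        if self.carrier_pp < 0 or self.noise_sd < 0:
            raise ParameterizationError("amplitudes must be non-negative")


@dataclass(frozen=True)
class ThermalGenParams:
    """Parameters of one synthetic thermal raster (°C)."""

    width: int = THERMAL_FRAME[0]
    height: int = THERMAL_FRAME[1]
    canopy_mean: float = 26.0
    canopy_sd: float = 0.8
    background_mean: float = THERMAL_BACKGROUND_C
    n_canopy: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterizationError("frame dimensions must be positive")
        if not 0 < self.n_canopy < self.width * self.height:
            raise ParameterizationError("n_canopy must be in (0, width·height)")
        if self.canopy_mean >= self.background_mean:
            raise ParameterizationError(
                "transpiring canopy must be cooler than the background"
            )
        if self.canopy_sd < 0:
            raise ParameterizationError("canopy_sd must be non-negative")


@dataclass(frozen=True)
class DPVGenParams:
    """Parameters of one synthetic voltammogram.

    ``peaks`` are (position V, height µA, FWHM V) triples of phenomenological
    Gaussian redox peaks; peak currents scale linearly with
    ``concentration_scale`` (heights are proportional to electroactive
    substance concentrations).
    """

    v_start: float = 0.0
    v_end: float = -1.5
    v_step: float = 0.005
    peaks: tuple[tuple[float, float, float], ...] = DPV_BASE_PEAKS
    baseline_slope: float = -2.0
    concentration_scale: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_start <= self.v_end:
            raise ParameterizationError("scan must be negative-going: v_start > v_end")
        if self.v_step <= 0:
            raise ParameterizationError("v_step must be positive")
        for pos, height, width in self.peaks:
            if not self.v_end < pos < self.v_start:
                raise ParameterizationError(
                    f"peak position {pos} outside scan range"
                )
            if height <= 0 or width <= 0:
                raise ParameterizationError("peak heights/widths must be positive")
        if self.concentration_scale <= 0:
            raise ParameterizationError("concentration_scale must be positive")
        if self.noise_sd < 0:
            raise ParameterizationError("noise_sd must be non-negative")


# --------------------------------------------------------------------------
# Core generators
# --------------------------------------------------------------------------


def _blob_mask(
    width: int, height: int, n: int, rng: np.random.Generator, n_blobs: int = 4
) -> np.ndarray:
    """Foreground mask of exactly ``n`` pixels shaped as a union of ellipses.

    Each blob contributes a normalized elliptical distance field; the ``n``
    pixels with the smallest minimum field value are selected, so small
    counts give separate leaf-like blobs and large counts flood outward
    while the count stays exact.
    """
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    pot = np.full((height, width), np.inf)
    for _ in range(n_blobs):
        cx = rng.uniform(0.25, 0.75) * width
        cy = rng.uniform(0.25, 0.75) * height
        a = rng.uniform(0.12, 0.30) * width
        b = rng.uniform(0.12, 0.30) * height
        theta = rng.uniform(0.0, np.pi)
        dx, dy = xx - cx, yy - cy
        u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
        w = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
        pot = np.minimum(pot, u * u + w * w)
    order = np.argsort(pot, axis=None, kind="stable")
    flat = np.zeros(width * height, dtype=bool)
    flat[order[:n]] = True
    return flat.reshape(height, width)


def _calibrated_loc(mu: float, sigma: float) -> float:
    """Normal location whose retained 8-bit mean equals ``mu``.

    Draws are rounded into 0..255; pixels landing in bin 0 (draws below 0.5)
    are excluded by the downstream zero-bin convention, and draws above
    254.5 saturate at 255. Both effects bias the retained mean away from the
    raw normal location, so the location is solved (closed-form truncated
    moments, bracketed root find) to make the retained mean hit the target.
    """
    if sigma <= 0.5:
        return mu
    if not 1.0 <= mu <= 254.0:
        raise ParameterizationError("channel mean must lie in [1, 254]")
    lo, hi = 0.5, 254.5

    def retained_mean(loc: float) -> float:
        a = (lo - loc) / sigma
        b = (hi - loc) / sigma
        p_mid = norm.cdf(b) - norm.cdf(a)
        p_hi = norm.sf(b)
        num = loc * p_mid - sigma * (norm.pdf(b) - norm.pdf(a)) + 255.0 * p_hi
        return num / (p_mid + p_hi)

    return brentq(
        lambda loc: retained_mean(loc) - mu,
        mu - 8.0 * sigma - 1.0,
        mu + 8.0 * sigma + 1.0,
        xtol=1e-9,
    )


def generate_plant_image(params: ImageGenParams) -> tuple[np.ndarray, np.ndarray]:
    """Generate an 8-bit RGB plant image and its ground-truth mask.

    The foreground (a union of elliptical leaf blobs totalling exactly
    ``n_foreground`` pixels) gets per-channel intensities from a clipped,
    rounded normal calibrated so the zero-excluded channel barycenter
    recovers ``channel_means``; the background is uniform at
    ``background_level``. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(params.seed)
    mask = _blob_mask(params.width, params.height, params.n_foreground, rng)
    img = np.full(
        (params.height, params.width, 3), params.background_level, dtype=np.uint8
    )
    n = params.n_foreground
    for c in range(3):
        mu, sd = params.channel_means[c], params.channel_sds[c]
        if sd <= 0.5:
            values = np.full(n, np.clip(round(mu), 0, 255), dtype=np.uint8)
        else:
            draws = rng.normal(_calibrated_loc(mu, sd), sd, n)
            values = np.clip(np.rint(draws), 0, 255).astype(np.uint8)
        img[..., c][mask] = values
    return img, mask


def generate_esignal(params: ESignalGenParams) -> Signal:
    """Generate a synthetic plant electrical signal.

    x(t) = (pp/2)(1−f)·sin(2π f_c t) + (pp/2)f·sin(2π f_s t) + N(0, σ²)
    with pp the carrier peak-to-peak target, f the slow-wave amplitude
    fraction, f_c the carrier and f_s the slow frequency.
    """
    n = int(round(params.fs * params.duration))
    t = np.arange(n) / params.fs
    half = params.carrier_pp / 2.0
    x = half * (1.0 - params.slow_amp_fraction) * np.sin(
        2.0 * np.pi * params.carrier_freq * t
    )
    x += half * params.slow_amp_fraction * np.sin(2.0 * np.pi * params.slow_freq * t)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        x += rng.normal(0.0, params.noise_sd, n)
    return Signal(samples=x, fs=params.fs)


def generate_thermal_image(params: ThermalGenParams) -> tuple[np.ndarray, np.ndarray]:
    """Generate a thermal raster (°C, float) and its ground-truth canopy mask."""
    rng = np.random.default_rng(params.seed)
    mask = _blob_mask(params.width, params.height, params.n_canopy, rng)
    temps = np.full((params.height, params.width), params.background_mean, dtype=float)
    if params.canopy_sd > 0:
        temps[mask] = rng.normal(params.canopy_mean, params.canopy_sd, params.n_canopy)
    else:
        temps[mask] = params.canopy_mean
    return temps, mask


def generate_dpv(params: DPVGenParams) -> Voltammogram:
    """Generate a synthetic voltammogram on the 0 → −1.5 V grid.

    current(V) = slope·(V − v_start)
               + concentration_scale · Σ_k h_k·exp(−(V−p_k)²/(2σ_k²))
               + N(0, σ_noise²),   σ_k = FWHM_k / 2.3548.
    """
    n = int(round((params.v_start - params.v_end) / params.v_step)) + 1
    pot = params.v_start - params.v_step * np.arange(n)
    cur = params.baseline_slope * (pot - params.v_start)
    for pos, height, width in params.peaks:
        sd = width / GAUSSIAN_FWHM_OVER_SD
        cur = cur + params.concentration_scale * height * np.exp(
            -((pot - pos) ** 2) / (2.0 * sd * sd)
        )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        cur = cur + rng.normal(0.0, params.noise_sd, n)
    return Voltammogram(potential=pot, current=cur)


# --------------------------------------------------------------------------
# Per-cell default parameters (the study's calibration)
# --------------------------------------------------------------------------


def default_image_params(
    cond: StudyCondition,
    seed: int = 0,
    full_scale: bool = False,
    background_level: int = 0,
) -> ImageGenParams:
    """Calibrated image parameters for one grid cell.

    Barycenter/FWHM targets come from the cell's reference row; by default
    the frame is desk-scale (404×252) with foreground counts divided by 10.
    """
    cal = RGB_CALIBRATION[(cond.treatment, cond.day)]
    sds = tuple(f / GAUSSIAN_FWHM_OVER_SD for f in cal["fwhm"])
    if full_scale:
        width, height = FULL_FRAME
        n = cal["n_foreground"]
    else:
        width, height = DESK_FRAME
        n = round(cal["n_foreground"] / DESK_COUNT_DIVISOR)
    return ImageGenParams(
        width=width,
        height=height,
        n_foreground=n,
        channel_means=tuple(cal["barycenter"]),
        channel_sds=sds,
        background_level=background_level,
        seed=seed,
    )


def default_esignal_params(
    cond: StudyCondition | None = None,
    seed: int = 1,
    fs: float = 2000.0,
    duration: float = 100.0,
    noise_sd: float = 0.02,
) -> ESignalGenParams:
    """Calibrated signal parameters for one grid cell.

    The carrier peak-to-peak target is the cell's reference peak value; the
    slow-wave fraction grows with drought day. ``cond=None`` means the
    default (most stressed) cell: untreated soil, day 6.
    """
    if cond is None:
        cond = StudyCondition(Treatment.ORIGINAL, 6)
    cal = SIGNAL_CALIBRATION[(cond.treatment, cond.day)]
    return ESignalGenParams(
        fs=fs,
        duration=duration,
        carrier_pp=cal["peak_v"],
        slow_amp_fraction=SLOW_AMP_FRACTION[cond.day],
        noise_sd=noise_sd,
        seed=seed,
    )


def default_thermal_params(cond: StudyCondition, seed: int = 0) -> ThermalGenParams:
    """Calibrated thermal parameters for one grid cell.

    Canopy pixel count follows the cell's visible-image area fraction mapped
    onto the 256×192 thermal frame.
    """
    cal = THERMAL_CALIBRATION[(cond.treatment, cond.day)]
    n_vis = RGB_CALIBRATION[(cond.treatment, cond.day)]["n_foreground"]
    frame_px = THERMAL_FRAME[0] * THERMAL_FRAME[1]
    n_canopy = round(n_vis / (FULL_FRAME[0] * FULL_FRAME[1]) * frame_px)
    return ThermalGenParams(
        canopy_mean=cal["canopy_mean"],
        n_canopy=n_canopy,
        seed=seed,
    )


def default_dpv_params(cond: StudyCondition, seed: int = 0) -> DPVGenParams:
    """Calibrated DPV parameters for one grid cell.

    Untreated soil under drought broadens each peak by ×1.4 per two days
    (saturating at ×1.96) and jitters positions (electrolyte imbalance
    degrades the fingerprint); biochar raises the concentration scale
    (1.0 / 1.3 / 1.6).
    """
    widths_mult = 1.0
    jitter_sd = 0.0
    if cond.treatment is Treatment.ORIGINAL:
        widths_mult = min(
            DPV_WIDTH_GROWTH_PER_2D ** (cond.day / 2.0), DPV_WIDTH_GROWTH_CAP
        )
        jitter_sd = DPV_JITTER_SD_PER_2D * (cond.day / 2.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    peaks = []
    for pos, height, width in DPV_BASE_PEAKS:
        if jitter_sd > 0:
            pos = pos + rng.normal(0.0, jitter_sd)
        peaks.append((pos, height, width * widths_mult))
    return DPVGenParams(
        peaks=tuple(peaks),
        concentration_scale=DPV_CONCENTRATION_SCALE[cond.treatment],
        seed=seed,
    )


# --------------------------------------------------------------------------
# Full-study generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Per-cell generator parameters for the full 3×4 grid."""

    image: dict
    thermal: dict
    esignal: dict
    dpv: dict

    def cells(self) -> list[StudyCondition]:
        return sorted(self.image.keys(), key=lambda c: (c.treatment.value, c.day))


_MODALITY_CODES = {"visible": 1, "thermal": 2, "esignal": 3, "dpv": 4}


def _cell_seed(master_seed: int, cell_index: int, modality: str) -> int:
    """Stable sub-seed for one (cell, modality) from the master seed."""
    ss = np.random.SeedSequence(
        [int(master_seed), cell_index, _MODALITY_CODES[modality]]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def default_study_config(
    master_seed: int = 0,
    *,
    full_scale: bool = False,
    signal_fs: float = 2000.0,
    signal_duration: float = 100.0,
    signal_noise_sd: float = 0.02,
    image_background_level: int = 0,
) -> StudyConfig:
    """Default calibrated configuration for the whole study grid.

    ``signal_fs``/``signal_duration`` may be reduced for quick runs (the
    slow wave must still complete whole cycles).
    """
    if master_seed < 0:
        raise ParameterizationError("master_seed must be non-negative")
    image, thermal, esignal, dpv_cfg = {}, {}, {}, {}
    for i, cond in enumerate(study_grid()):
        image[cond] = default_image_params(
            cond,
            seed=_cell_seed(master_seed, i, "visible"),
            full_scale=full_scale,
            background_level=image_background_level,
        )
        thermal[cond] = default_thermal_params(
            cond, seed=_cell_seed(master_seed, i, "thermal")
        )
        esignal[cond] = default_esignal_params(
            cond,
            seed=_cell_seed(master_seed, i, "esignal"),
            fs=signal_fs,
            duration=signal_duration,
            noise_sd=signal_noise_sd,
        )
        dpv_cfg[cond] = default_dpv_params(
            cond, seed=_cell_seed(master_seed, i, "dpv")
        )
    return StudyConfig(image=image, thermal=thermal, esignal=esignal, dpv=dpv_cfg)


def generate_study(config: StudyConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write the full synthetic study to disk and return its manifest.

    Layout: ``visible/<cell>.png`` (+ ``_mask.png``), ``thermal/<cell>.csv``
    (+ ``.tif``), ``esignal/<cell>.csv``, ``dpv/<cell>.csv`` and a
    ``manifest.csv`` with columns treatment, day, modality, path, seed.
    Idempotent for a fixed configuration.
    """
    out = Path(out_dir)
    rows = []
    for sub in ("visible", "thermal", "esignal", "dpv"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    def record(cond: StudyCondition, modality: str, path: Path, seed: int) -> None:
        rows.append(
            {
                "treatment": cond.treatment.value,
                "day": cond.day,
                "modality": modality,
                "path": str(path.relative_to(out)),
                "seed": seed,
            }
        )

    for cond in config.cells():
        label = cond.label

        p = config.image[cond]
        img, mask = generate_plant_image(p)
        img_path = out / "visible" / f"{label}.png"
        mask_path = out / "visible" / f"{label}_mask.png"
        iio.imwrite(img_path, img)
        iio.imwrite(mask_path, (mask.astype(np.uint8) * 255))
        record(cond, "visible", img_path, p.seed)
        record(cond, "visible_mask", mask_path, p.seed)

        pt = config.thermal[cond]
        temps, _ = generate_thermal_image(pt)
        csv_path = out / "thermal" / f"{label}.csv"
        tif_path = out / "thermal" / f"{label}.tif"
        write_thermal_csv(temps, csv_path)
        tifffile.imwrite(tif_path, temps.astype(np.float32))
        record(cond, "thermal", csv_path, pt.seed)
        record(cond, "thermal_tiff", tif_path, pt.seed)

        pe = config.esignal[cond]
        sig = generate_esignal(pe)
        sig_path = out / "esignal" / f"{label}.csv"
        sig.to_csv(sig_path)
        record(cond, "esignal", sig_path, pe.seed)

        pd_params = config.dpv[cond]
        curve = generate_dpv(pd_params)
        dpv_path = out / "dpv" / f"{label}.csv"
        curve.to_csv(dpv_path)
        record(cond, "dpv", dpv_path, pd_params.seed)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
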