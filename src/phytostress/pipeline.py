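"""Study-level orchestration: per-modality analysis and the merged report.

Runs every analyzer over a study directory (as produced by
:func:`phytostress.synth.generate_study`, or real data following the same
manifest schema), joins the per-modality features on (treatment, day) and
summarizes per-treatment time trends as least-squares slopes versus drought
day. Missing modality files are flagged rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import dpv as dpv_mod
from . import image_features as imf
from . import thermal_features as thf
from ._exceptions import PhytostressError
from .esignal import Signal, amplitude_spectrum, characteristic_frequency, signal_stats
from .study import StudyCondition

log = logging.getLogger(__name__)

__all__ = ["StudyReport", "run_study", "trend_summary", "plot_study", "TREND_FEATURES"]

#: Features whose day-trends the report summarizes.
TREND_FEATURES = ("gd", "peak_v", "canopy_mean_C", "total_peak_current_uA")


@dataclass(frozen=True)
class StudyReport:
    """Joined feature table (one row per grid cell) and trend summary."""

    feature_table: pd.DataFrame
    trends: pd.DataFrame


def _analyze_visible(path: Path, mask_path: Path | None, use_truth_mask: bool,
                     bg_level: int, tol: int) -> dict:
    image = iio.imread(path)
    if use_truth_mask and mask_path is not None and mask_path.exists():
        mask = iio.imread(mask_path) > 0
    else:
        mask = imf.segment_plant(image, bg_level=bg_level, tol=tol)
    row = imf.image_feature_row(image, mask)
    out: dict = {"gd": row.gd}
    for ch, cf in row.channels.items():
        key = ch.lower()
        out[f"{key}_integral_area"] = cf.integral_area
        out[f"{key}_barycenter"] = cf.barycenter
        out[f"{key}_fwhm"] = cf.fwhm
    return out


def _analyze_thermal(path: Path, abs_threshold_c: float | None) -> dict:
    temps = thf.read_thermal_csv(path)
    mask = thf.segment_canopy_thermal(temps)
    summary = thf.canopy_stats(temps, mask, abs_threshold_c=abs_threshold_c)
    return {
        "canopy_mean_C": summary.canopy_mean,
        "canopy_min_C": summary.canopy_min,
        "low_temp_fraction": summary.low_temp_fraction,
    }


def _analyze_esignal(path: Path) -> dict:
    sig = Signal.from_csv(path)
    stats = signal_stats(sig)
    spec = amplitude_spectrum(sig, detrend=True)
    peak = characteristic_frequency(spec)
    return {
        "max_v": stats.max_v,
        "min_v": stats.min_v,
        "peak_v": stats.peak_v,
        "period_ms": stats.period_ms,
        "char_freq_hz": peak.freq if peak else float("nan"),
        "char_amp_V": peak.amp if peak else float("nan"),
    }


def _analyze_dpv(path: Path) -> dict:
    curve = dpv_mod.baseline_correct(dpv_mod.Voltammogram.from_csv(path))
    peaks = dpv_mod.detect_peaks(curve)
    report = dpv_mod.clarity(peaks)
    return {
        "n_dpv_peaks": report.n_peaks,
        "mean_resolution": report.mean_resolution,
        "overlap_flag": report.overlap_flag,
        "total_peak_current_uA": report.total_peak_current,
    }


_ANALYZERS = {
    "visible": _analyze_visible,
    "thermal": _analyze_thermal,
    "esignal": _analyze_esignal,
    "dpv": _analyze_dpv,
}

_NAN_COLUMNS = {
    "visible": (
        "gd", "r_integral_area", "r_barycenter", "r_fwhm",
        "g_integral_area", "g_barycenter", "g_fwhm",
        "b_integral_area", "b_barycenter", "b_fwhm",
    ),
    "thermal": ("canopy_mean_C", "canopy_min_C", "low_temp_fraction"),
    "esignal": ("max_v", "min_v", "peak_v", "period_ms", "char_freq_hz", "char_amp_V"),
    "dpv": ("n_dpv_peaks", "mean_resolution", "overlap_flag", "total_peak_current_uA"),
}


def run_study(
    data_dir: str | Path,
    out_dir: str | Path | None = None,
    *,
    strict: bool = False,
    use_truth_masks: bool = False,
    bg_level: int = 0,
    tol: int = 10,
    abs_threshold_c: float | None = None,
    plots: bool = False,
) -> StudyReport:
    """Analyze a study directory and build the merged report.

    Reads ``manifest.csv`` from ``data_dir``, runs all four analyzers per
    (treatment, day) cell, joins the results, computes trend slopes and —
    when ``out_dir`` is given — writes ``report.csv`` and ``trends.csv``.
    With ``strict=True`` a missing modality file raises; otherwise the gap
    is NaN-filled and the row flagged incomplete.
    """
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    rows = []
    for (treatment, day), group in manifest.groupby(["treatment", "day"], sort=True):
        cond = StudyCondition(treatment, int(day))
        row: dict = {"treatment": cond.treatment.value, "day": cond.day, "complete": True}
        paths = {m: data_dir / p for m, p in zip(group["modality"], group["path"])}
        for modality in ("visible", "thermal", "esignal", "dpv"):
            path = paths.get(modality)
            try:
                if path is None or not path.exists():
                    raise FileNotFoundError(
                        f"{cond.label}: missing {modality} file {path}"
                    )
                if modality == "visible":
                    out = _analyze_visible(
                        path, paths.get("visible_mask"), use_truth_masks, bg_level, tol
                    )
                elif modality == "thermal":
                    out = _analyze_thermal(path, abs_threshold_c)
                elif modality == "esignal":
                    out = _analyze_esignal(path)
                else:
                    out = _analyze_dpv(path)
            except (FileNotFoundError, PhytostressError) as exc:
                if strict:
                    raise
                log.warning("flagging incomplete cell %s: %s", cond.label, exc)
                out = {col: float("nan") for col in _NAN_COLUMNS[modality]}
                row["complete"] = False
            row.update(out)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(["treatment", "day"]).reset_index(drop=True)
    trends = trend_summary(table)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "report.csv", index=False)
        trends.to_csv(out / "trends.csv", index=False)
        if plots:
            plot_study(table, out / "trends.png")
    return StudyReport(feature_table=table, trends=trends)


def plot_study(table: pd.DataFrame, path: str | Path,
               features: tuple[str, ...] = TREND_FEATURES) -> None:
    """Plot each trend feature versus drought day, one line per treatment."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, feature in zip(axes.ravel(), features):
        for treatment, group in table.groupby("treatment", sort=True):
            ax.plot(group["day"], group[feature], marker="o", label=treatment)
        ax.set_title(feature)
        ax.set_xlabel("drought day")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def trend_summary(
    table: pd.DataFrame, features: tuple[str, ...] = TREND_FEATURES
) -> pd.DataFrame:
    """Per-treatment least-squares slope of each feature versus drought day.

    The reference study reports endpoint comparisons; a least-squares slope
    over all timepoints is the corresponding signed trend statistic.
    Treatments with fewer than two valid timepoints are flagged with a NaN
    slope.
    """
    rows = []
    for treatment, group in table.groupby("treatment", sort=True):
        for feature in features:
            if feature not in group.columns:
                continue
            sub = group[["day", feature]].dropna()
            if len(sub) >= 2:
                slope = float(
                    np.polyfit(sub["day"].to_numpy(float), sub[feature].to_numpy(float), 1)[0]
                )
                n = len(sub)
            else:
                slope, n = float("nan"), len(sub)
            rows.append(
                {"treatment": treatment, "feature": feature, "slope_per_day": slope, "n_days": n}
            )
    return pd.DataFrame(rows)
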