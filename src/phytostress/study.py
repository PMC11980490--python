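"""Study design: the treatment × drought-day grid and its calibration tables.

The experiment monitors clustered chili pepper plants under progressive
drought in three soil environments — untreated soil, soil amended with 2%
biochar, and soil amended with 4% biochar — with acquisitions every two days
(day 0, 2, 4, 6 of withheld watering). Each (treatment, day) cell is one
acquisition across four modalities: a visible-light image, a thermal raster,
an electrical-signal time series, and a differential pulse voltammogram.

The calibration tables below give, per cell, the target values the synthetic
generator is tuned to: visible-image foreground pixel counts, per-channel
histogram barycenters and full widths at half maximum; electrical-signal
extremes, peak-to-peak amplitude and oscillation period. They are reference
measurements from a pot experiment of this design and double as the
regression targets for the analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from ._exceptions import ParameterizationError

__all__ = [
    "Treatment",
    "DAYS",
    "StudyCondition",
    "study_grid",
    "RGB_CALIBRATION",
    "SIGNAL_CALIBRATION",
    "THERMAL_CALIBRATION",
    "THERMAL_BACKGROUND_C",
    "SLOW_AMP_FRACTION",
]


class Treatment(str, Enum):
    """Soil environment of a potted pepper plant."""

    ORIGINAL = "original"
    BIOCHAR2 = "biochar2"
    BIOCHAR4 = "biochar4"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Drought days at which acquisitions are made (watering withheld from day 0).
DAYS: tuple[int, ...] = (0, 2, 4, 6)


@dataclass(frozen=True, order=True)
class StudyCondition:
    """One (soil treatment, drought day) cell of the experimental grid."""

    treatment: Treatment
    day: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        if self.day not in DAYS:
            raise ParameterizationError(
                f"day must be one of {DAYS}, got {self.day!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.treatment.value}_day{self.day}"


def study_grid() -> list[StudyCondition]:
    """All 12 cells of the 3-treatment × 4-day grid, in canonical order."""
    return [StudyCondition(t, d) for t in Treatment for d in DAYS]


# --- Visible-image calibration -------------------------------------------
# Per cell: foreground pixel count (full 1280×800 scale), and per-channel
# (R, G, B) histogram barycenters and FWHMs on the 0-255 intensity axis.
# The per-channel pixel counts of the reference data differ by <0.1%
# (dark pixels falling into the excluded zero bin); the R-channel count is
# used as the cell's foreground count.
RGB_CALIBRATION: dict[tuple[Treatment, int], dict] = {
    (Treatment.ORIGINAL, 0): {
        "n_foreground": 915796,
        "barycenter": (122.18904, 155.77954, 94.29842),
        "fwhm": (93.23168, 84.60555, 98.2579),
    },
    (Treatment.ORIGINAL, 2): {
        "n_foreground": 887883,
        "barycenter": (138.79981, 169.83324, 105.1517),
        "fwhm": (115.00513, 96.89384, 109.34467),
    },
    (Treatment.ORIGINAL, 4): {
        "n_foreground": 637264,
        "barycenter": (144.67628, 173.1801, 111.03414),
        "fwhm": (108.57516, 91.77886, 103.68584),
    },
    (Treatment.ORIGINAL, 6): {
        "n_foreground": 245341,
        "barycenter": (161.17829, 183.06305, 119.85221),
        "fwhm": (95.70155, 89.72863, 95.01087),
    },
    (Treatment.BIOCHAR2, 0): {
        "n_foreground": 687753,
        "barycenter": (144.34983, 172.97689, 118.78648),
        "fwhm": (95.12128, 75.82036, 100.03365),
    },
    (Treatment.BIOCHAR2, 2): {
        "n_foreground": 816240,
        "barycenter": (144.50834, 174.13671, 103.79222),
        "fwhm": (121.39686, 109.73123, 101.04725),
    },
    (Treatment.BIOCHAR2, 4): {
        "n_foreground": 653911,
        "barycenter": (152.72323, 183.379, 108.74241),
        "fwhm": (110.62883, 103.20266, 88.57322),
    },
    (Treatment.BIOCHAR2, 6): {
        "n_foreground": 401992,
        "barycenter": (150.13314, 180.50439, 95.62488),
        "fwhm": (100.86988, 89.10542, 95.62488),
    },
    (Treatment.BIOCHAR4, 0): {
        "n_foreground": 700058,
        "barycenter": (121.14169, 148.35304, 96.80462),
        "fwhm": (79.02095, 65.32253, 80.70043),
    },
    (Treatment.BIOCHAR4, 2): {
        "n_foreground": 562509,
        "barycenter": (155.28203, 181.07274, 121.40066),
        "fwhm": (113.66721, 83.7965, 122.98113),
    },
    (Treatment.BIOCHAR4, 4): {
        "n_foreground": 516613,
        "barycenter": (151.06924, 179.01571, 107.52033),
        "fwhm": (104.62971, 88.87418, 98.9389),
    },
    (Treatment.BIOCHAR4, 6): {
        "n_foreground": 521343,
        "barycenter": (143.8908, 174.94072, 105.60115),
        "fwhm": (112.02855, 100.00407, 124.34274),
    },
}

# --- Electrical-signal calibration ---------------------------------------
# Per cell: signal maximum, minimum (V, post-amplification), peak-to-peak
# amplitude (V) and oscillation period (ms). peak_v is the generator's
# carrier peak-to-peak target.
SIGNAL_CALIBRATION: dict[tuple[Treatment, int], dict] = {
    (Treatment.ORIGINAL, 0): {"max_v": 1.063, "min_v": -1.193, "peak_v": 2.255, "period_ms": 19.714},
    (Treatment.ORIGINAL, 2): {"max_v": 1.648, "min_v": -1.560, "peak_v": 3.208, "period_ms": 20.000},
    (Treatment.ORIGINAL, 4): {"max_v": 1.744, "min_v": -1.744, "peak_v": 3.484, "period_ms": 20.000},
    (Treatment.ORIGINAL, 6): {"max_v": 2.396, "min_v": -2.612, "peak_v": 5.008, "period_ms": 20.000},
    (Treatment.BIOCHAR2, 0): {"max_v": 0.867, "min_v": -0.889, "peak_v": 1.756, "period_ms": 19.958},
    (Treatment.BIOCHAR2, 2): {"max_v": 1.361, "min_v": -1.415, "peak_v": 2.776, "period_ms": 20.000},
    (Treatment.BIOCHAR2, 4): {"max_v": 1.851, "min_v": -2.014, "peak_v": 3.865, "period_ms": 20.000},
    (Treatment.BIOCHAR2, 6): {"max_v": 1.633, "min_v": -1.633, "peak_v": 3.266, "period_ms": 20.000},
    (Treatment.BIOCHAR4, 0): {"max_v": 0.607, "min_v": -0.607, "peak_v": 1.214, "period_ms": 19.667},
    (Treatment.BIOCHAR4, 2): {"max_v": 1.143, "min_v": -1.198, "peak_v": 2.341, "period_ms": 20.000},
    (Treatment.BIOCHAR4, 4): {"max_v": 1.034, "min_v": -1.143, "peak_v": 2.178, "period_ms": 19.958},
    (Treatment.BIOCHAR4, 6): {"max_v": 1.470, "min_v": -1.579, "peak_v": 3.049, "period_ms": 20.000},
}

#: Fraction of the signal amplitude carried by the slow (0.37 Hz) component,
#: growing with drought severity so the sub-5 Hz spectral peak rises with day.
SLOW_AMP_FRACTION: dict[int, float] = {0: 0.05, 2: 0.10, 4: 0.15, 6: 0.20}

#: Ambient/background scene temperature for thermal rasters (°C).
THERMAL_BACKGROUND_C: float = 30.0

# --- Thermal calibration --------------------------------------------------
# Canopy mean temperatures (°C). Transpiring, well-watered canopies stay
# several °C below ambient; drought closes stomata and warms the canopy.
# Biochar retains soil water, so amended treatments stay cooler, and the
# canopy in untreated soil warms fastest. Values realize those orderings;
# absolute temperatures are nominal.
THERMAL_CALIBRATION: dict[tuple[Treatment, int], dict] = {
    (Treatment.ORIGINAL, 0): {"canopy_mean": 26.0},
    (Treatment.ORIGINAL, 2): {"canopy_mean": 27.0},
    (Treatment.ORIGINAL, 4): {"canopy_mean": 28.2},
    (Treatment.ORIGINAL, 6): {"canopy_mean": 29.2},
    (Treatment.BIOCHAR2, 0): {"canopy_mean": 25.5},
    (Treatment.BIOCHAR2, 2): {"canopy_mean": 26.2},
    (Treatment.BIOCHAR2, 4): {"canopy_mean": 26.9},
    (Treatment.BIOCHAR2, 6): {"canopy_mean": 27.6},
    (Treatment.BIOCHAR4, 0): {"canopy_mean": 25.0},
    (Treatment.BIOCHAR4, 2): {"canopy_mean": 25.4},
    (Treatment.BIOCHAR4, 4): {"canopy_mean": 25.8},
    (Treatment.BIOCHAR4, 6): {"canopy_mean": 26.2},
}
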