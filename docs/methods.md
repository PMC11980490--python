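# Methods

## Study design

The unit of analysis is a (soil treatment, drought day) cell: three
treatments (untreated soil, +2% biochar, +4% biochar by mass) crossed with
four acquisition days (0, 2, 4, 6 after watering is withheld). Each cell is
a single acquisition per modality; replicate-level statistics (significance
testing between treatments) are out of scope because the design carries one
curve/image per cell.

## Visible-image features

Background-subtracted images are segmented by thresholding the largest
per-channel distance from the background level (default level 0, tolerance
10 intensity units) followed by removal of connected components under 16
pixels. This is deliberately the simplest reproducible rule consistent with
a background-subtraction workflow; it recovers synthetic ground truth with
Jaccard ≥ 0.99 and is replaceable by an externally supplied mask.

Each channel histogram is summarized over intensities 1–255; **bin 0 is
excluded everywhere** because background subtraction zeroes the background,
making the zero bin a mixture of background and genuinely black pixels.
This convention is also what lets per-channel pixel counts of one plant
differ slightly (a channel with dark pixels loses them to bin 0).

* **Integral area**: Σ counts over bins 1–255.
* **Barycenter**: Σ v·counts[v] / Σ counts[v] — the histogram's center of
  mass, an intensity in [1, 255].
* **FWHM**: counts are smoothed with a centered 5-bin moving average (real
  histograms are ragged; a window of 1 disables smoothing), the global
  maximum located (first bin on ties, for determinism), and the nearest
  half-maximum crossings on each side found by linear interpolation. A
  boundary peak with only one crossing reports twice the one-sided
  half-width and is flagged. The 5-bin window adds (5²−1)/12 ≈ 2 to the
  variance of a Gaussian histogram, i.e. < 1% width inflation at the σ ≈
  30–45 typical here.
* **Green dominance** GD = G/(R+G+B) over channel barycenters, stored as a
  fraction and reported as a percentage rounded to one decimal.

## Thermal features

Thermal and visible cameras are not co-registered, so the thermal modality
segments independently: an Otsu split of the temperature histogram, cooler
class = canopy. Canopy mean and minimum are reported together with the
low-temperature fraction — the share of canopy pixels below a threshold.
The default threshold is *relative* (background median − 2 °C) so the
statistic is invariant to uniform scene temperature shifts; an absolute
threshold is available when scenes must be compared on a fixed scale.

## Electrical signals

Recordings are modeled as a fast carrier (default 50 Hz, the ~20 ms
oscillation visible in the time traces) superposed on a slow wave at the
plant's characteristic frequency (0.37 Hz) plus white noise.

* **Statistics**: max, min, peak-to-peak = max − min.
* **Period**: first local maximum of the biased, FFT-computed, normalized
  autocorrelation beyond lag 0 with value > 0.2, refined by quadratic
  interpolation over neighboring lags. Autocorrelation was chosen over
  zero-crossing counting because the slow-wave superposition shifts
  crossings but barely perturbs the first autocorrelation peak (the shift
  is ~the slow-wave slope divided by the carrier curvature, ≈ 10⁻⁴ lags at
  the defaults). The estimator is exact to one interpolated lag on
  noiseless sines from 10–100 Hz.
* **Spectrum**: one-sided amplitude 2|DFT|/N (DC and Nyquist unhalved), so
  a sinusoid of amplitude A on an exact bin reads A. No taper by default —
  the default 100 s duration holds whole cycles of both components — with a
  Hann option for real recordings.
* **Characteristic frequency**: spectrum argmax over 0 < f ≤ 5 Hz (DC
  excluded); at 100 s the frequency grid is 0.01 Hz so 0.37 Hz is an exact
  bin.

## DPV analysis

* **Baseline**: an ordinary line fit is pulled up by the peaks, so after
  each of two fits only the lowest-quartile-residual (baseline-dominated)
  points are kept and the line refit. Subtracting a line does not change
  residual rankings, so the operation is exactly idempotent. A linear
  (not polynomial) baseline keeps the step deterministic and is adequate
  over a 1.5 V window with Gaussian-like peaks.
* **Peaks**: local maxima with prominence ≥ 5% of the maximum current
  (relative, hence scale-free across concentrations). Width is the **FWHM
  relative to the corrected zero baseline**, interpolated on both flanks —
  not scipy's half-prominence contour, which is numerically unstable for
  overlapping peaks. When neighbors keep the curve above half height the
  width extends past them, which is precisely what drives the overlap
  metric.
* **Clarity**: chromatography-style resolution Rs =
  2Δposition/(width₁+width₂) per adjacent pair; mean Rs (NaN with < 2
  peaks), an overlap flag (any Rs < 1), and total peak current Σ heights
  (proportional to total electroactive-substance concentration).

## Synthetic-data generator

The generator's defaults *are* the study conditions; every downstream
calibration test runs against them.

* **Plant/canopy masks** — a union of a few random elliptical blobs,
  realized by ranking pixels on the minimum normalized elliptical distance
  and keeping exactly `n_foreground` of them: blob-shaped at low counts,
  flood-filled at high counts, always with an exact pixel count.
* **Image intensities** — per-channel normal draws rounded into 0–255.
  Because bin 0 is excluded downstream and draws above 254.5 saturate at
  255, the *retained* mean of a naive normal differs from its location by
  up to ~1.4 intensity units at the table's widest channels. The generator
  therefore solves (closed-form truncated-normal moments + bracketed root
  find) for the location whose retained mean equals the requested
  barycenter target; the sd is used as given. Recovered barycenter bias is
  then < 0.5 intensity units at 10⁵ foreground pixels.
* **Image frame** — desk scale by default: 404×252 (the native 1280×800
  scaled by √10) with foreground counts divided by 10, preserving the
  native fill fraction; `full_scale=True` restores 1280×800.
* **Signals** — x(t) = (pp/2)(1−f)·sin(2π·50t) + (pp/2)·f·sin(2π·0.37t) +
  N(0, 0.02²), with pp the cell's reference peak-to-peak value and the
  slow-wave fraction f growing with drought day (0.05/0.10/0.15/0.20, an
  invented schedule that makes the 0.37 Hz amplitude rise with stress).
  Duration 100 s at 2000 Hz so both components complete whole cycles.
  Measured peak-to-peak lands in [pp, 1.03·pp]: the two-tone maximum
  approaches pp from below over the 37 slow cycles, and noise extremes add
  ≲ 4.5σ per tail.
* **Thermal** — constant 30 °C background, canopy N(mean, 0.8 °C); canopy
  means per cell follow the orderings cooler-with-biochar and
  warming-with-drought (absolute values are nominal; none are published).
  Canopy pixel counts track the visible-image area fractions on the
  256×192 frame.
* **DPV** — three Gaussian peaks at −0.5/−0.75/−1.0 V, heights 4/6/3 µA,
  FWHM 0.10 V, on a −2 µA/V line with 0.05 µA noise, step 5 mV (301
  samples; no step potential is published). Biochar raises the
  concentration scale (1.0/1.3/1.6); drought in untreated soil broadens
  every peak ×1.4 per two days **saturating at ×1.96** with ±3 mV·(day/2)
  position jitter. The saturation is deliberate: unbounded broadening
  merges the fingerprint into a single detected hump by day 6, leaving no
  adjacent pair to flag, whereas saturated widths keep late-drought curves
  at distinct-but-overlapping peaks (Rs ≈ 0.45–0.8, flagged) across 100
  seeds while all biochar-4% curves stay clear (Rs ≈ 2.5).
* **Determinism** — every generator takes a seed; the study-level config
  derives per-(cell, modality) seeds from one master seed via seed
  sequences, and regenerating a study yields byte-identical CSV outputs.

### What the generator does *not* emulate

Leaf morphology and radiometric camera response (foregrounds are
statistical blobs, not plants); nonstationary/transient electrical events
(the signal model is stationary two-tone + noise, so passing tests show the
estimators are correct, not that real recordings are two-tone);
electrochemical kinetics (peaks are phenomenological Gaussians, so peak
*shape* physics is untested); thermal gradients and emissivity effects.
Reference peak-to-peak values are taken post-amplification; the analog gain
is unknown, so no tissue-level voltage scale is implied. The ~20 ms carrier
period coincides with mains frequency; the generator reproduces the
reported period without interpreting it.

## Problem sizes

Default signals are 2×10⁵ samples (100 s × 2000 Hz); the test suite's
end-to-end study runs at 400 Hz (duration unchanged, keeping the slow wave
on-bin), images at desk scale, and parameter-recovery tests at 10⁵
foreground pixels over 20 seeds. The reference-table endpoints (green
dominance) are exact arithmetic on three numbers each.

## Known limitations

* Segmentation assumes a uniform background near a known level; natural
  backgrounds need an external mask.
* The FWHM of a strongly multimodal histogram follows the *global* maximum
  only (nearest crossings), by design — the widest-region alternative was
  rejected as non-deterministic under count noise.
* Period estimation needs a dominant short-period component with
  autocorrelation > 0.2; broadband or drifting signals report "undefined"
  rather than a guess.
* One reference row (+2% biochar, day 6) prints identical B-channel
  barycenter and FWHM values (95.62488), an apparent transcription
  duplication in the source table; the row is kept verbatim in the
  calibration table but not used as a numeric anchor anywhere.
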