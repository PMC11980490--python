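"""Generator contracts: determinism, exact counts, calibration plumbing."""

import numpy as np
import pandas as pd
import pytest

from phytostress import (
    DPVGenParams,
    ESignalGenParams,
    ImageGenParams,
    ParameterizationError,
    ThermalGenParams,
    generate_dpv,
    generate_esignal,
    generate_plant_image,
    generate_study,
    generate_thermal_image,
)
from phytostress.study import SIGNAL_CALIBRATION, Treatment, study_grid
from phytostress.synth import default_study_config


SMALL_IMAGE = dict(width=120, height=80, n_foreground=2500)


class TestDeterminism:
    def test_image_bitwise_reproducible(self):
        p = ImageGenParams(**SMALL_IMAGE, seed=42)
        img1, mask1 = generate_plant_image(p)
        img2, mask2 = generate_plant_image(p)
        assert np.array_equal(img1, img2) and np.array_equal(mask1, mask2)

    def test_signal_thermal_dpv_reproducible(self):
        s1 = generate_esignal(ESignalGenParams(fs=400, seed=3))
        s2 = generate_esignal(ESignalGenParams(fs=400, seed=3))
        assert np.array_equal(s1.samples, s2.samples)
        t1, m1 = generate_thermal_image(ThermalGenParams(seed=3, n_canopy=5000))
        t2, m2 = generate_thermal_image(ThermalGenParams(seed=3, n_canopy=5000))
        assert np.array_equal(t1, t2) and np.array_equal(m1, m2)
        v1 = generate_dpv(DPVGenParams(seed=3))
        v2 = generate_dpv(DPVGenParams(seed=3))
        assert np.array_equal(v1.current, v2.current)

    def test_different_seeds_differ(self):
        a = generate_esignal(ESignalGenParams(fs=400, seed=1)).samples
        b = generate_esignal(ESignalGenParams(fs=400, seed=2)).samples
        assert not np.array_equal(a, b)


class TestCountConservation:
    @pytest.mark.parametrize("n", [17, 2500, 7000])
    def test_image_foreground_exact(self, n):
        _, mask = generate_plant_image(
            ImageGenParams(width=120, height=80, n_foreground=n, seed=0)
        )
        assert int(mask.sum()) == n

    def test_thermal_canopy_exact(self):
        _, mask = generate_thermal_image(ThermalGenParams(n_canopy=1000, seed=0))
        assert int(mask.sum()) == 1000


class TestValidation:
    def test_empty_foreground_rejected(self):
        with pytest.raises(ParameterizationError):
            ImageGenParams(width=120, height=80, n_foreground=0)

    def test_overfull_foreground_rejected(self):
        with pytest.raises(ParameterizationError):
            ImageGenParams(width=10, height=10, n_foreground=100)

    def test_signal_nyquist_rejected(self):
        with pytest.raises(ParameterizationError):
            ESignalGenParams(fs=80.0, carrier_freq=50.0)

    def test_partial_slow_cycle_rejected(self):
        with pytest.raises(ParameterizationError):
            ESignalGenParams(fs=400, duration=30.0, slow_freq=0.37)

    def test_warm_canopy_rejected(self):
        with pytest.raises(ParameterizationError):
            ThermalGenParams(canopy_mean=31.0, background_mean=30.0)

    def test_dpv_peak_outside_scan_rejected(self):
        with pytest.raises(ParameterizationError):
            DPVGenParams(peaks=((-2.0, 1.0, 0.1),))


class TestImageGeneration:
    def test_degenerate_variance_gives_constant_foreground(self):
        p = ImageGenParams(
            **SMALL_IMAGE,
            channel_means=(100.0, 100.0, 100.0),
            channel_sds=(0.01, 0.01, 0.01),
            seed=1,
        )
        img, mask = generate_plant_image(p)
        assert np.all(img[mask] == 100)
        assert np.all(img[~mask] == 0)


class TestSignalGeneration:
    def test_pure_sine_peak_to_peak_exact(self):
        p = ESignalGenParams(
            fs=2000, duration=1.0, carrier_pp=2.0, slow_freq=1.0,
            slow_amp_fraction=0.0, noise_sd=0.0,
        )
        x = generate_esignal(p).samples
        assert np.max(x) - np.min(x) == pytest.approx(2.0, abs=1e-9)

    def test_noise_inflates_extremes_by_at_most_three_percent(self):
        # default drought cell: carrier_pp target 5.008 V, noise sd 0.02 V
        sig = generate_esignal(ESignalGenParams(seed=1))
        pp = float(np.max(sig.samples) - np.min(sig.samples))
        assert 5.008 <= pp <= 5.008 * 1.03


class TestDPVGeneration:
    def test_no_peaks_no_noise_is_straight_line(self):
        from phytostress import baseline_correct, detect_peaks

        v = generate_dpv(DPVGenParams(peaks=(), noise_sd=0.0, seed=0))
        fit = np.polyfit(v.potential, v.current, 1)
        assert fit[0] == pytest.approx(-2.0, rel=1e-9)
        assert detect_peaks(baseline_correct(v)) == []

    def test_gaussian_maxima_located_within_one_step(self):
        from phytostress import baseline_correct, detect_peaks

        v = generate_dpv(
            DPVGenParams(peaks=((-0.4, 5.0, 0.1), (-0.9, 5.0, 0.1)), noise_sd=0.0)
        )
        peaks = detect_peaks(baseline_correct(v))
        assert [round(p.position, 3) for p in peaks] == [-0.4, -0.9]


class TestGenerateStudy:
    def test_counts_and_manifest(self, study_dir):
        manifest = pd.read_csv(study_dir / "manifest.csv")
        assert list(manifest.columns) == ["treatment", "day", "modality", "path", "seed"]
        per_modality = manifest["modality"].value_counts()
        for modality in ("visible", "visible_mask", "thermal", "esignal", "dpv"):
            assert per_modality[modality] == 12
        for rel in manifest["path"]:
            assert (study_dir / rel).exists()

    def test_same_master_seed_byte_identical_csv(self, tmp_path):
        cfg = default_study_config(master_seed=9, signal_fs=400.0)
        a, b = tmp_path / "a", tmp_path / "b"
        generate_study(cfg, a)
        generate_study(cfg, b)
        for rel in ("esignal/original_day6.csv", "dpv/biochar4_day0.csv",
                    "thermal/biochar2_day2.csv", "manifest.csv"):
            assert (a / rel).read_bytes() == (b / rel).read_bytes()

    def test_carrier_pp_table_matches_calibration(self):
        cfg = default_study_config(master_seed=0, signal_fs=400.0)
        for cond in study_grid():
            expected = SIGNAL_CALIBRATION[(cond.treatment, cond.day)]["peak_v"]
            assert cfg.esignal[cond].carrier_pp == expected
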