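"""Noise detection, baselining, line masking, band features, refinement,
dominant frequency.  Brute-force recomputations serve as oracles."""

import numpy as np
import pytest

from specscore import (
    EEGRecording,
    Hypnogram,
    Spectrogram,
    band_features,
    baseline_spectrogram,
    compute_spectrogram,
    default_bands,
    design_wavelets,
    detect_noise_epochs,
    dominant_frequency,
    generate_night,
    inject_artifacts,
    mask_line_noise,
    refine_band_peaks,
    StageScript,
)
from specscore.bands import BandDefinition, _detrend_local, _robust_z

FS = 250.0


def pink_recording(duration_s=600.0, seed=0, fs=FS):
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    x = np.fft.irfft(spec * f**-0.5, n)
    return EEGRecording(10 * (x / x.std())[None], fs, ["A"])


def fake_spectrogram(power, hop=0.5, f_lo=0.5, f_hi=40.0, baselined=False):
    freqs = np.logspace(np.log10(f_lo), np.log10(f_hi), power.shape[1])
    return Spectrogram(power=power.astype(float), hop=hop, freqs=freqs,
                       baselined=baselined)


class TestNoiseDetection:
    def test_scaled_segment_flagged(self, small_bank):
        """A x20 gain span is flagged; >99% of other bins stay unflagged."""
        rec = pink_recording(600.0, seed=1)
        noisy = inject_artifacts(rec, [(300.0, 30.0, 20.0)])
        spec = compute_spectrogram(noisy, "A", small_bank)
        mask = detect_noise_epochs(spec, noisy, "A", z_thresh=4.0)
        bins = np.arange(spec.n_times) * 0.5
        inside = (bins >= 302) & (bins < 328)   # interior of the artifact span
        outside = (bins < 295) | (bins >= 335)
        assert mask[inside].mean() > 0.9
        assert (~mask[outside]).mean() > 0.99
        # oracle: recompute the robust z of total power by brute force
        total_db = 10 * np.log10((10 ** (spec.power / 10)).sum(axis=1))
        resid = _detrend_local(total_db, int(600 / 0.5))
        med = np.median(resid)
        mad = np.median(np.abs(resid - med))
        z = (resid - med) / (1.4826 * mad)
        assert np.abs(z[inside]).min() > 4.0

    def test_stationary_signal_empty_mask(self, small_bank):
        rec = pink_recording(300.0, seed=2)
        spec = compute_spectrogram(rec, "A", small_bank)
        mask = detect_noise_epochs(spec, rec, "A")
        assert mask.mean() < 0.005

    def test_mask_invariant_to_global_scaling(self, small_bank):
        rec = pink_recording(400.0, seed=3)
        noisy = inject_artifacts(rec, [(100.0, 20.0, 15.0)])
        scaled = inject_artifacts(noisy, [(0.0, 400.0, 7.5)])   # whole-record gain
        m1 = detect_noise_epochs(compute_spectrogram(noisy, "A", small_bank), noisy, "A")
        m2 = detect_noise_epochs(compute_spectrogram(scaled, "A", small_bank), scaled, "A")
        assert np.array_equal(m1, m2)

    def test_constant_signal_warns_and_flags_nothing(self):
        power = np.full((100, 20), -30.0)
        spec = fake_spectrogram(power)
        with pytest.warns(UserWarning, match="MAD = 0"):
            mask = detect_noise_epochs(spec)
        assert not mask.any()

    def test_robust_z_none_on_constant(self):
        assert _robust_z(np.ones(50)) is None


class TestBaseline:
    def test_unmasked_column_means_zero(self):
        rng = np.random.default_rng(0)
        spec = fake_spectrogram(rng.normal(size=(200, 30)))
        mask = rng.random(200) < 0.1
        out = baseline_spectrogram(spec, mask)
        assert out.baselined
        assert np.abs(out.power[~mask].mean(axis=0)).max() < 1e-9

    def test_constant_in_time_becomes_zero(self):
        row = np.linspace(-5, 5, 30)
        spec = fake_spectrogram(np.tile(row, (50, 1)))
        out = baseline_spectrogram(spec)
        assert np.abs(out.power).max() < 1e-12

    def test_masked_artifact_matches_bruteforce(self):
        """Equals an oracle that drops masked columns before averaging."""
        rng = np.random.default_rng(4)
        power = rng.normal(size=(300, 25))
        power[100:120] += 40.0                      # injected artifact
        mask = np.zeros(300, bool)
        mask[100:120] = True
        out = baseline_spectrogram(fake_spectrogram(power), mask)
        oracle = power - power[~mask].mean(axis=0, keepdims=True)
        assert np.allclose(out.power, oracle, atol=1e-12)

    def test_double_baseline_and_all_masked_raise(self):
        spec = fake_spectrogram(np.zeros((50, 5)))
        out = baseline_spectrogram(spec)
        with pytest.raises(ValueError, match="already baselined"):
            baseline_spectrogram(out)
        with pytest.raises(ValueError, match="all time bins"):
            baseline_spectrogram(spec, np.ones(50, bool))


class TestLineMask:
    def make_ridge_spec(self):
        freqs_n = 60
        power = np.zeros((40, freqs_n))
        spec = fake_spectrogram(power, f_lo=1.0, f_hi=95.0, baselined=True)
        ridge = np.argmin(np.abs(spec.freqs - 60.0))
        spec.power[:, ridge] = 30.0
        return spec, ridge

    def test_ridge_removed_low_freqs_untouched(self):
        spec, ridge = self.make_ridge_spec()
        out = mask_line_noise(spec, (50.0, 70.0))
        assert np.abs(out.power[:, ridge]).max() < 1e-9
        below = spec.freqs < 50
        assert np.array_equal(out.power[:, below], spec.power[:, below])
        assert out.line_mask_band == (50.0, 70.0)

    def test_no_grid_rows_in_band_is_identity(self):
        spec = fake_spectrogram(np.random.default_rng(1).normal(size=(20, 10)),
                                f_lo=0.5, f_hi=30.0)
        out = mask_line_noise(spec, (50.0, 70.0))
        assert np.array_equal(out.power, spec.power)

    def test_wake_feature_ignores_line_ridge(self):
        """WAKE band excludes 50-70 Hz, so a 60 Hz ridge changes nothing."""
        spec, ridge = self.make_ridge_spec()
        clean = spec.copy()
        clean.power[:, ridge] = 0.0
        fa = band_features(spec, epoch_len=10.0)
        fb = band_features(clean, epoch_len=10.0)
        wake_col = 0
        assert np.allclose(fa.values[:, wake_col], fb.values[:, wake_col])


class TestBandFeatures:
    def test_default_band_edges(self):
        defs = default_bands()
        edges = {b.name: (b.lo, b.hi) for b in defs}
        assert edges == {
            "WAKE": (40.0, 95.0), "REM": (17.0, 26.0), "LIGHT": (11.0, 15.5),
            "HIDEEP": (1.0, 3.0), "LODEEP": (0.1, 1.0),
        }
        assert defs[0].exclusions == ((50.0, 70.0),)

    def test_zero_spectrogram_gives_zero_features(self, bank):
        spec = Spectrogram(power=np.zeros((120, bank.freqs.size)), hop=0.5,
                           freqs=bank.freqs, baselined=True)
        bs = band_features(spec, epoch_len=30.0)
        assert bs.n_epochs == 2
        assert np.allclose(bs.values, 0.0)

    def test_spindle_burst_maximises_light_feature(self, bank):
        """A 13 Hz burst over background makes LIGHT the largest feature."""
        rng = np.random.default_rng(5)
        spec = Spectrogram(power=rng.normal(0, 0.1, (60, bank.freqs.size)),
                           hop=0.5, freqs=bank.freqs, baselined=True)
        light_rows = (bank.freqs >= 12) & (bank.freqs <= 14)
        spec.power[:, light_rows] += 10.0
        bs = band_features(spec, epoch_len=30.0)
        assert np.all(np.argmax(bs.values, axis=1) == 2)

    def test_partial_epoch_dropped_and_empty_band_raises(self, bank):
        spec = Spectrogram(power=np.zeros((130, bank.freqs.size)), hop=0.5,
                           freqs=bank.freqs, baselined=True)
        assert band_features(spec, epoch_len=30.0).n_epochs == 2
        bad = [BandDefinition("WAKE", 97.0, 99.0)]
        with pytest.raises(ValueError, match="no grid frequencies"):
            band_features(spec, bad + default_bands()[1:], epoch_len=30.0)

    def test_mean_matches_bruteforce(self, bank):
        rng = np.random.default_rng(6)
        spec = Spectrogram(power=rng.normal(size=(120, bank.freqs.size)),
                           hop=0.5, freqs=bank.freqs, baselined=True)
        bs = band_features(spec, epoch_len=30.0)
        for b, bd in enumerate(bs.band_defs):
            rows = bd.row_indices(bank.freqs)
            for e in range(bs.n_epochs):
                expected = spec.power[e * 60:(e + 1) * 60][:, rows].mean()
                assert bs.values[e, b] == pytest.approx(expected, abs=1e-12)


class TestRefinement:
    def make_night_with_spindle(self, spindle_freq):
        script = StageScript(
            segments=[("WAKE", 90), ("LIGHT", 300), ("REM", 210)],
            fs=250.0, seed=9, spindle_freq=spindle_freq,
        )
        rec, truth = generate_night(script)
        spec = baseline_spectrogram(
            compute_spectrogram(rec, "SYN1", design_wavelets(0.5, 45.0, 80, 3, 15))
        )
        return spec, truth

    def test_rule_offsets_around_peaks(self):
        """LIGHT -> [p-1, p+1.5]; REM -> [p-2, p+2] around the found peaks."""
        spec, truth = self.make_night_with_spindle(13.0)
        defs = refine_band_peaks(spec, truth)
        by = {b.name: b for b in defs}
        p_s = by["LIGHT"].lo + 1.0
        assert by["LIGHT"].hi - by["LIGHT"].lo == pytest.approx(2.5)
        assert p_s == pytest.approx(13.0, abs=0.5)
        assert by["REM"].hi - by["REM"].lo == pytest.approx(4.0)
        assert (by["REM"].lo + by["REM"].hi) / 2 == pytest.approx(20.0, abs=1.0)

    def test_offcentre_spindles_recovered_and_feature_increases(self):
        """11.5 Hz spindles: refined band contains 11.5 Hz and the LIGHT
        feature in spindle epochs grows versus the default band."""
        spec, truth = self.make_night_with_spindle(11.5)
        defs = refine_band_peaks(spec, truth)
        by = {b.name: b for b in defs}
        assert by["LIGHT"].lo <= 11.5 <= by["LIGHT"].hi
        assert by["LIGHT"].lo == pytest.approx(10.5, abs=0.5)
        f_def = band_features(spec, default_bands(), epoch_len=30.0)
        f_ref = band_features(spec, defs, epoch_len=30.0)
        light_epochs = np.asarray(truth.stages) == "LIGHT"
        assert (
            f_ref.values[light_epochs, 2].mean() > f_def.values[light_epochs, 2].mean()
        )

    def test_missing_stage_leaves_band_unchanged(self):
        spec, truth = self.make_night_with_spindle(13.0)
        no_rem = Hypnogram(["LIGHT"] * truth.n_epochs, epoch_len=30.0)
        defs = refine_band_peaks(spec, no_rem)
        by = {b.name: b for b in defs}
        assert (by["REM"].lo, by["REM"].hi) == (17.0, 26.0)

    def test_idempotent_when_peak_centred(self):
        spec, truth = self.make_night_with_spindle(13.0)
        once = refine_band_peaks(spec, truth)
        twice = refine_band_peaks(spec, truth, once)
        assert [(b.lo, b.hi) for b in once] == [(b.lo, b.hi) for b in twice]


class TestDominantFrequency:
    def test_tone_segment_dominates(self, small_bank):
        """Where a strong 2 Hz rhythm is present it is the dominant frequency
        (relative to the whole-night baseline, which includes tone-free time)."""
        n = int(600 * FS)
        x = np.random.default_rng(2).normal(0, 1, n)
        t = np.arange(n) / FS
        x[n // 2:] += 40 * np.sin(2 * np.pi * 2.0 * t[n // 2:])
        spec = baseline_spectrogram(
            compute_spectrogram(EEGRecording(x[None], FS, ["A"]), "A", small_bank)
        )
        dom = dominant_frequency(spec, smooth_window=40.0)
        target = small_bank.freqs[np.argmin(np.abs(small_bank.freqs - 2.0))]
        second_half = dom.freq_at_max[spec.n_times // 2 + 100 : -100]
        assert (second_half == target).mean() > 0.95
        assert np.isin(dom.freq_at_max, small_bank.freqs).all()

    def test_tie_breaks_to_lower_frequency(self):
        power = np.zeros((20, 10))
        power[:, [3, 7]] = 5.0                      # two equal maxima
        spec = fake_spectrogram(power, baselined=True)
        dom = dominant_frequency(spec, smooth_window=0.5)
        assert np.all(dom.freq_at_max == spec.freqs[3])

    def test_single_bin_window_equals_unsmoothed_argmax(self):
        rng = np.random.default_rng(8)
        spec = fake_spectrogram(rng.normal(size=(50, 12)), baselined=True)
        dom = dominant_frequency(spec, smooth_window=0.5)    # one bin
        assert np.array_equal(dom.freq_at_max,
                              spec.freqs[np.argmax(spec.power, axis=1)])
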