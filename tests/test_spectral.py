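"""Unit and property tests for the sensor-level spectral chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import welch

from megnpt.spectral import (
    NormalizedPsd,
    PsdEstimate,
    Recording,
    SpectralConfig,
    band_relative_power,
    bandstop_filter,
    blackman_tukey_psd,
    individual_alpha_frequency,
    median_frequency,
    normalize_psd,
    segment_signal,
    spectral_entropy,
    summarize_recording,
)
from megnpt.synth import SignalSpec, simulate_recording


def _sine(freq, fs=200.0, seconds=60.0, n_ch=1):
    t = np.arange(int(seconds * fs)) / fs
    return Recording(np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1)), fs=fs)


def _psdn(freqs, mass):
    freqs = np.asarray(freqs, dtype=float)
    mass = np.asarray(mass, dtype=float)
    return NormalizedPsd(freqs=freqs, mass=mass / mass.sum())


class TestRecording:
    def test_rejects_non_finite_samples(self):
        bad = np.zeros((1, 100))
        bad[0, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            Recording(samples=bad, fs=200.0)

    def test_excluded_recording_may_carry_non_finite(self):
        bad = np.zeros((1, 100))
        bad[0, 3] = np.inf
        rec = Recording(samples=bad, fs=200.0, excluded=True, exclusion_reason="artifact")
        assert rec.excluded

    def test_rejects_bad_fs_and_shape(self):
        with pytest.raises(ValueError):
            Recording(samples=np.zeros((1, 10)), fs=0.0)
        with pytest.raises(ValueError):
            Recording(samples=np.zeros(10), fs=200.0)


class TestSegmentation:
    @pytest.mark.parametrize(
        "seconds, expected",
        [(300.0, 30), (25.0, 2), (10.0, 1)],
    )
    def test_floor_rule(self, seconds, expected):
        rec = Recording(np.zeros((1, int(seconds * 200))), fs=200.0)
        segs = segment_signal(rec, 10.0)
        assert len(segs) == expected
        assert all(s.n_samples == 2000 for s in segs)

    def test_segments_are_contiguous_from_zero(self):
        rec = Recording(np.arange(5000, dtype=float).reshape(1, -1), fs=200.0)
        segs = segment_signal(rec, 10.0)
        np.testing.assert_array_equal(segs[0].samples[0], np.arange(2000.0))
        np.testing.assert_array_equal(segs[1].samples[0], np.arange(2000.0, 4000.0))

    def test_too_short_recording_raises(self):
        rec = Recording(np.zeros((1, 1980)), fs=200.0)  # 9.9 s
        with pytest.raises(ValueError, match="too short"):
            segment_signal(rec, 10.0)

    def test_excluded_recording_refused(self):
        rec = Recording(np.zeros((1, 4000)), fs=200.0, excluded=True)
        with pytest.raises(ValueError, match="excluded"):
            segment_signal(rec, 10.0)


class TestBandstop:
    def test_50hz_sine_attenuated_30db(self):
        rec = _sine(50.0)
        out = bandstop_filter(rec, 50.0, 2.0)
        ratio = np.std(out.samples) / np.std(rec.samples)
        assert ratio < 0.032

    def test_10hz_sine_preserved(self):
        rec = _sine(10.0)
        out = bandstop_filter(rec, 50.0, 2.0)
        ratio = np.std(out.samples) / np.std(rec.samples)
        assert abs(ratio - 1.0) < 0.06

    def test_white_noise_notched_flat_elsewhere(self, white_noise_recording):
        out = bandstop_filter(white_noise_recording, 50.0, 2.0)
        f, p_in = welch(white_noise_recording.samples, fs=200.0, nperseg=2000)
        _, p_out = welch(out.samples, fs=200.0, nperseg=2000)
        p_in, p_out = p_in.mean(0), p_out.mean(0)
        at_50 = np.argmin(np.abs(f - 50.0))
        assert p_out[at_50] < 0.05 * p_in[at_50]
        away = (f > 5) & ((f < 45) | (f > 55)) & (f < 90)
        assert np.sum(p_out[away]) > 0.9 * np.sum(p_in[away])

    def test_notch_at_or_above_nyquist_raises(self):
        rec = _sine(10.0, fs=90.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandstop_filter(rec, 50.0, 2.0)


class TestBlackmanTukey:
    def test_white_noise_flat_and_parseval(self, white_noise_recording):
        psd = blackman_tukey_psd(white_noise_recording)
        df = psd.freqs[1] - psd.freqs[0]
        total = psd.power.sum(axis=1) * df
        assert np.allclose(total, 1.0, rtol=0.10)
        # flatness: in-band mean close to the 1/fs-per-Hz white level
        band = (psd.freqs > 5) & (psd.freqs < 95)
        level = psd.power[:, band].mean()
        assert abs(level - 1.0 / 100.0) / (1.0 / 100.0) < 0.10

    def test_sinusoid_peaks_at_grid_frequency(self):
        psd = blackman_tukey_psd(_sine(10.0))
        peak = psd.freqs[np.argmax(psd.power[0])]
        assert abs(peak - 10.0) <= psd.freqs[1] - psd.freqs[0]

    def test_zero_signal_gives_zero_spectrum_and_normalization_rejects(self):
        psd = blackman_tukey_psd(Recording(np.zeros((1, 2000)), fs=200.0))
        assert np.all(psd.power == 0)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_psd(psd)

    def test_grid_covers_80hz_and_is_uniform(self):
        psd = blackman_tukey_psd(Recording(np.random.default_rng(0).standard_normal((1, 2000)), fs=200.0))
        assert psd.freqs[-1] >= 80.0
        assert np.allclose(np.diff(psd.freqs), psd.freqs[1] - psd.freqs[0])

    def test_max_lag_longer_than_segment_raises(self):
        rec = Recording(np.zeros((1, 100)), fs=200.0)
        with pytest.raises(ValueError, match="max_lag"):
            blackman_tukey_psd(rec, max_lag_seconds=1.0)

    def test_oracle_equivalence_with_averaged_periodogram(self):
        """BT spectrum of white noise matches a non-overlapping averaged
        periodogram within 10% integrated relative error (20 seeds)."""
        bt_acc, or_acc = [], []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal((8, 12000))
            rec = Recording(x, fs=200.0)
            psd = blackman_tukey_psd(rec)
            bt_acc.append(psd.power.mean(0))
            fw, pw = welch(
                x, fs=200.0, window="boxcar", nperseg=2000, noverlap=0,
                detrend="constant",
            )
            or_acc.append(pw.mean(0))
        bt, oracle = np.mean(bt_acc, axis=0), np.mean(or_acc, axis=0)
        assert np.allclose(psd.freqs, fw)
        err = np.sum(np.abs(bt - oracle)) / np.sum(oracle)
        assert err < 0.10


class TestNormalize:
    def test_mass_sums_to_one(self, white_noise_recording):
        pn = normalize_psd(blackman_tukey_psd(white_noise_recording))
        assert abs(pn.mass.sum() - 1.0) < 1e-9
        assert pn.freqs[0] >= 1.0 and pn.freqs[-1] <= 70.0

    def test_uniform_psd_gives_uniform_mass(self):
        freqs = np.arange(0.0, 100.1, 0.5)
        psd = PsdEstimate(freqs=freqs, power=np.ones((3, freqs.size)))
        pn = normalize_psd(psd)
        assert np.allclose(pn.mass, pn.mass[0])

    def test_support_outside_band_raises(self):
        freqs = np.arange(0.0, 100.1, 0.5)
        power = np.zeros((1, freqs.size))
        power[0, np.argmin(np.abs(freqs - 80.0))] = 5.0
        with pytest.raises(ValueError, match="degenerate"):
            normalize_psd(PsdEstimate(freqs=freqs, power=power))

    def test_per_channel_variant_also_sums_to_one(self, white_noise_recording):
        pn = normalize_psd(blackman_tukey_psd(white_noise_recording), per_channel=True)
        assert abs(pn.mass.sum() - 1.0) < 1e-9


class TestMedianFrequency:
    def test_uniform_mass_gives_band_midpoint(self, uniform_psdn):
        assert median_frequency(uniform_psdn) == pytest.approx(35.5, abs=1e-9)

    def test_single_bin_mass(self):
        freqs = np.arange(1.0, 70.1, 1.0)
        mass = np.zeros(freqs.size)
        mass[np.argmin(np.abs(freqs - 10.0))] = 1.0
        assert median_frequency(_psdn(freqs, mass)) == 10.0

    def test_half_half_split_takes_smaller_frequency(self):
        freqs = np.arange(1.0, 70.1, 1.0)
        mass = np.zeros(freqs.size)
        mass[np.argmin(np.abs(freqs - 5.0))] = 0.5
        mass[np.argmin(np.abs(freqs - 20.0))] = 0.5
        assert median_frequency(_psdn(freqs, mass)) == 5.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mf_in_band_and_permutation_sensitive(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.arange(1.0, 70.1, 0.5)
        mass = rng.random(freqs.size) + 1e-12
        pn = _psdn(freqs, mass)
        assert 1.0 <= median_frequency(pn) <= 70.0
        # MF depends on where the mass sits: sorting the same masses toward
        # high frequencies must give a larger median than toward low ones
        asc = _psdn(freqs, np.sort(mass))
        desc = _psdn(freqs, np.sort(mass)[::-1])
        assert median_frequency(asc) > median_frequency(desc)


class TestIAF:
    def test_bump_recovered_with_peak_flag(self):
        spec = SignalSpec(alpha_center=10.0, alpha_relative_power=0.5, seed=3)
        summ = summarize_recording(simulate_recording(spec))
        assert summ.iaf == pytest.approx(10.0, abs=0.1)
        assert summ.iaf_peak_found

    def test_monotone_one_over_f_flags_edge(self):
        freqs = np.arange(1.0, 70.1, 0.5)
        pn = _psdn(freqs, 1.0 / freqs)
        iaf, found = individual_alpha_frequency(pn)
        assert iaf == 8.0
        assert not found

    def test_tie_breaks_to_lower_frequency(self):
        freqs = np.arange(1.0, 70.1, 1.0)
        mass = np.full(freqs.size, 1e-6)
        mass[np.argmin(np.abs(freqs - 9.0))] = 1.0
        mass[np.argmin(np.abs(freqs - 11.0))] = 1.0
        iaf, found = individual_alpha_frequency(_psdn(freqs, mass))
        assert iaf == 9.0
        assert found

    def test_band_outside_grid_raises(self):
        pn = _psdn(np.arange(20.0, 70.1, 1.0), np.ones(51))
        with pytest.raises(ValueError, match="alpha band"):
            individual_alpha_frequency(pn, band=(8.0, 12.0))


class TestSpectralEntropy:
    def test_uniform_mass_is_maximal(self, uniform_psdn):
        assert spectral_entropy(uniform_psdn) == pytest.approx(1.0, abs=1e-9)

    def test_single_bin_is_minimal(self):
        freqs = np.arange(1.0, 70.1, 1.0)
        mass = np.zeros(freqs.size)
        mass[10] = 1.0
        assert spectral_entropy(_psdn(freqs, mass)) == pytest.approx(0.0, abs=1e-9)

    def test_two_bin_split_closed_form(self):
        freqs = np.arange(1.0, 70.1, 1.0)
        n = freqs.size
        mass = np.zeros(n)
        mass[3] = mass[40] = 0.5
        expected = np.log(2.0) / np.log(n)
        assert spectral_entropy(_psdn(freqs, mass)) == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_se_in_unit_interval_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.arange(1.0, 70.1, 0.5)
        mass = rng.random(freqs.size) + 1e-12
        pn = _psdn(freqs, mass)
        se = spectral_entropy(pn)
        assert 0.0 <= se <= 1.0
        perm = rng.permutation(mass.size)
        se_perm = spectral_entropy(_psdn(freqs, mass[perm]))
        assert se_perm == pytest.approx(se, abs=1e-12)


class TestBandPower:
    def test_uniform_mass_proportional_to_band_width(self, uniform_psdn):
        rel = band_relative_power(uniform_psdn)
        # alpha spans 8-12 Hz inclusive on a 0.1 Hz grid: 41 of 691 bins
        assert rel["alpha"] == pytest.approx(41 / 691, abs=1e-9)
        assert sum(rel.values()) <= 1.0 + 1e-9

    def test_all_mass_at_10hz_is_pure_alpha(self):
        freqs = np.arange(1.0, 70.1, 1.0)
        mass = np.zeros(freqs.size)
        mass[np.argmin(np.abs(freqs - 10.0))] = 1.0
        rel = band_relative_power(_psdn(freqs, mass))
        assert rel["alpha"] == 1.0
        assert all(v == 0.0 for k, v in rel.items() if k != "alpha")

    def test_gamma_split_assignment(self):
        freqs = np.arange(1.0, 70.1, 1.0)
        mass = np.zeros(freqs.size)
        mass[np.argmin(np.abs(freqs - 30.0))] = 0.5
        mass[np.argmin(np.abs(freqs - 50.0))] = 0.5
        rel = band_relative_power(_psdn(freqs, mass))
        assert rel["low_gamma"] == 0.5
        assert rel["high_gamma"] == 0.5

    def test_band_outside_support_warns_zero(self):
        freqs = np.arange(1.0, 30.1, 1.0)
        with pytest.warns(UserWarning, match="outside"):
            rel = band_relative_power(_psdn(freqs, np.ones(freqs.size)),
                                      [("vhf", 100.0, 120.0)])
        assert rel["vhf"] == 0.0


class TestSummarize:
    def test_white_noise_limit(self):
        spec = SignalSpec(one_over_f_exponent=0.0, alpha_relative_power=0.0, seed=5)
        summ = summarize_recording(simulate_recording(spec))
        assert summ.se > 0.97
        assert abs(summ.mf - 35.5) < 3.0
        assert not summ.iaf_peak_found or 8 <= summ.iaf <= 12

    def test_low_frequency_boost_lowers_mf(self):
        base = SignalSpec(seed=9)
        boosted = SignalSpec(seed=9, low_band_boost=4.0)
        mf_base = summarize_recording(simulate_recording(base)).mf
        mf_boost = summarize_recording(simulate_recording(boosted)).mf
        assert mf_boost < mf_base

    def test_excluded_recording_gated_before_computation(self):
        rec = Recording(np.zeros((1, 12000)), fs=200.0, excluded=True,
                        exclusion_reason="artifact")
        with pytest.raises(ValueError, match="excluded"):
            summarize_recording(rec)

    def test_invariants_on_simulated_recording(self):
        summ = summarize_recording(simulate_recording(SignalSpec(seed=13)))
        assert 1.0 <= summ.mf <= 70.0
        assert 8.0 <= summ.iaf <= 12.0
        assert 0.0 <= summ.se <= 1.0
        assert all(0.0 <= v <= 1.0 for v in summ.band_relpower.values())
        assert sum(summ.band_relpower.values()) <= 1.0 + 1e-9
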