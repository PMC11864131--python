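import numpy as np
import pytest

from retmea.core import FieldTrace, SpikeTrain
from retmea.flicker import (
    Spectrum,
    acg_spectrum,
    call_electrode,
    call_unit,
    dark_baseline,
    following_fraction,
    lowpass_and_average,
    periodogram_power,
    spike_acg,
)
from tests.conftest import poisson_train

FS = 20_000.0


def sine_trace(freq, duration=2.0, amplitude=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return FieldTrace(1, amplitude * np.sin(2 * np.pi * freq * t), fs)


class TestLowpassAndAverage:
    def test_identical_repeats_average_to_filtered_trace(self):
        tr = sine_trace(5.0)
        avg1 = lowpass_and_average([tr])
        avg3 = lowpass_and_average([tr, tr, tr])
        np.testing.assert_allclose(avg3.samples_uv, avg1.samples_uv)

    def test_dc_offset_preserved(self):
        tr = FieldTrace(1, np.full(int(FS), 42.0), FS)
        avg = lowpass_and_average([tr])
        assert np.median(avg.samples_uv) == pytest.approx(42.0, rel=1e-6)

    def test_stopband_attenuation_and_passband_flatness(self):
        lo, hi = sine_trace(5.0), sine_trace(500.0)
        mixed = FieldTrace(1, lo.samples_uv + hi.samples_uv, FS)
        out = lowpass_and_average([mixed]).samples_uv[2000:-2000]
        spec = periodogram_power(out, FS)
        p5 = spec.power_at(5.0)
        p500 = spec.power_at(500.0)
        assert 10 * np.log10(p500 / p5) < -40     # >= 40 dB down
        ref = periodogram_power(lo.samples_uv[2000:-2000], FS).power_at(5.0)
        assert np.sqrt(p5 / ref) == pytest.approx(1.0, abs=0.01)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            lowpass_and_average([sine_trace(5, 1.0), sine_trace(5, 2.0)])


class TestPeriodogram:
    def test_pure_sinusoid_peaks_at_its_frequency(self):
        spec = periodogram_power(sine_trace(5.0, 2.0))
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(5.0)
        assert spec.resolution == pytest.approx(0.5)

    def test_zero_trace_has_zero_power(self):
        spec = periodogram_power(np.zeros(1000), 1000.0)
        assert np.all(spec.power == 0.0)

    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 3.0, 40_000)
        spec = periodogram_power(x, FS)
        total = np.sum(spec.power) * spec.resolution
        assert total == pytest.approx(np.mean(x ** 2), rel=0.01)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            periodogram_power(np.empty(0), FS)


class TestDarkBaseline:
    def test_zero_trace(self):
        m, s = dark_baseline(FieldTrace(1, np.zeros(int(FS)), FS))
        assert (m, s) == (0.0, 0.0)

    def test_band_artifact_raises_baseline(self):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1.0, int(FS))
        clean = dark_baseline(FieldTrace(1, noise, FS))
        t = np.arange(int(FS)) / FS
        artifact = noise + 5.0 * np.sin(2 * np.pi * 10.0 * t)
        dirty = dark_baseline(FieldTrace(1, artifact, FS))
        assert dirty[0] > clean[0] and dirty[1] > clean[1]

    def test_band_without_bins_rejected(self):
        spec = Spectrum(np.array([0.0, 100.0, 200.0]), np.ones(3))
        with pytest.raises(ValueError, match="band"):
            dark_baseline(spec, band=(30.0, 40.0))


class TestCallElectrode:
    def test_zero_trace_is_negative(self):
        spec = periodogram_power(np.zeros(int(2 * FS)), FS)
        call = call_electrode(spec, 5.0, (0.0, 0.0))
        assert not call.positive and call.power == 0.0

    def test_strong_tone_is_positive(self):
        spec = periodogram_power(sine_trace(5.0, 2.0, amplitude=50.0))
        call = call_electrode(spec, 5.0, (1e-6, 1e-6))
        assert call.positive
        assert call.threshold == pytest.approx(5e-6)

    def test_frequency_outside_range_rejected(self):
        spec = Spectrum(np.arange(0.0, 50.0, 0.5), np.ones(100))
        with pytest.raises(ValueError):
            call_electrode(spec, 200.0, (0.0, 0.0))


class TestSpikeAcg:
    def test_regular_train_peaks_at_multiples_of_period(self, regular_train):
        lags, counts = spike_acg(regular_train, (0.0, 10.0))
        rem = np.abs(lags) % 0.1
        near_multiple = np.minimum(rem, 0.1 - rem) <= 0.006
        assert counts[~near_multiple].sum() == 0
        assert counts.sum() > 0
        # periodicity: spectral peak of the ACG at 10 Hz
        spec = acg_spectrum(counts, 0.010)
        band = (spec.frequencies > 2)
        assert spec.frequencies[band][np.argmax(spec.power[band])] == \
            pytest.approx(10.0, abs=0.5)

    def test_symmetric_and_no_zero_lag_self_pairs(self, regular_train):
        lags, counts = spike_acg(regular_train, (0.0, 10.0))
        np.testing.assert_array_equal(counts, counts[::-1])
        assert counts[np.argmin(np.abs(lags))] == 0.0

    def test_single_spike_gives_empty_flagged_acg(self):
        lags, counts = spike_acg(SpikeTrain("u", 1, [1.0]), (0.0, 10.0))
        assert lags.size == 0 and counts.size == 0

    def test_poisson_train_acg_is_flat(self):
        tr = poisson_train(30.0, 50.0, seed=4)
        lags, counts = spike_acg(tr, (0.0, 50.0))
        inner = counts[np.abs(lags) > 0.015]
        assert inner.std() / inner.mean() < 0.15

    def test_pair_count_oracle(self):
        tr = SpikeTrain("u", 1, [0.0, 0.05, 0.4, 2.0])
        lags, counts = spike_acg(tr, (0.0, 3.0), bin_width=0.01, max_lag=1.0)
        # forward diffs < 1 s: 0.05, 0.4, 0.35; mirrored -> 6 entries
        assert counts.sum() == 6


class TestCallUnit:
    def test_empty_acg_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            call_unit(np.empty(0), 0.01, 5.0, (0.0, 0.0))

    def test_modulated_unit_positive_unmodulated_negative(self):
        rng = np.random.default_rng(7)
        t = []
        # 10-s spike train modulated at 5 Hz (on-phase bursts)
        for k in range(50):
            t.extend(k * 0.2 + np.sort(rng.uniform(0, 0.08, 6)))
        mod = SpikeTrain("m", 1, np.array(sorted(t)))
        dark = poisson_train(30.0, 10.0, seed=8)
        _, stim_counts = spike_acg(mod, (0.0, 10.0))
        _, dark_counts = spike_acg(dark, (0.0, 10.0))
        base = dark_baseline(acg_spectrum(dark_counts, 0.010))
        assert call_unit(stim_counts, 0.010, 5.0, base).positive
        _, d2 = spike_acg(poisson_train(30.0, 10.0, seed=9), (0.0, 10.0))
        assert not call_unit(d2, 0.010, 5.0, base).positive


class TestFollowingFraction:
    def _call(self, positive, retina="r1", freq=5.0, cond="c"):
        from retmea.flicker import FollowingCall
        return FollowingCall("t", "electrode", freq, 1.0, 0.0, 0.0,
                             positive, retina, cond)

    def test_all_positive_is_100(self):
        out = following_fraction([self._call(True)] * 4)
        assert out.percent_positive.iloc[0] == 100.0

    def test_3_of_10_is_30(self):
        calls = [self._call(True)] * 3 + [self._call(False)] * 7
        out = following_fraction(calls)
        assert out.percent_positive.iloc[0] == pytest.approx(30.0)

    def test_per_retina_fractions_preserved(self):
        calls = ([self._call(True, "rA")] + [self._call(False, "rA")] * 4
                 + [self._call(True, "rB")] * 2 + [self._call(False, "rB")] * 3)
        out = following_fraction(calls).set_index("retina")
        assert out.loc["rA", "percent_positive"] == pytest.approx(20.0)
        assert out.loc["rB", "percent_positive"] == pytest.approx(40.0)
        assert out.percent_positive.mean() == pytest.approx(30.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            following_fraction([])
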