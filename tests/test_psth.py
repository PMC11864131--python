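import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retmea.core import Epoch, SpikeTrain
from retmea.psth import (
    AnalysisConfig,
    PSTH,
    binomial_kernel,
    classify_unit,
    compute_psth,
    intensity_series,
    smooth_binomial,
    spontaneous_rate,
)
from tests.conftest import poisson_train

CFG = AnalysisConfig()


def make_psth(rates, bin_width=0.02, t0=-1.0, n_trials=1):
    edges = t0 + np.arange(len(rates) + 1) * bin_width
    return PSTH(edges, np.asarray(rates, float), n_trials)


class TestComputePsth:
    def test_counting_oracle_two_spikes(self, flash_epoch):
        st_ = SpikeTrain("u", 1, [flash_epoch.onset + 0.01,
                                  flash_epoch.onset + 0.03])
        psth = compute_psth(st_, [flash_epoch], (0.1, 0.1))
        nz = psth.rate[psth.rate > 0]
        assert list(nz) == [50.0, 50.0]
        idx = np.flatnonzero(psth.rate)
        assert psth.centers[idx[0]] == pytest.approx(0.01)
        assert psth.centers[idx[1]] == pytest.approx(0.03)

    def test_edge_aligned_with_onset(self, flash_epoch):
        psth = compute_psth(SpikeTrain("u", 1, []), [flash_epoch], (0.5, 1.0))
        assert np.isclose(psth.edges, 0.0).any()

    def test_empty_train_gives_zero_psth(self, flash_epoch):
        psth = compute_psth(SpikeTrain("u", 1, []), [flash_epoch], (1.0, 2.0))
        assert np.all(psth.rate == 0.0)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            compute_psth(SpikeTrain("u", 1, []), [], (1.0, 2.0))

    def test_homogeneous_rate_recovered(self):
        # 200 aligned trials of a 40-Hz Poisson process
        epochs = [Epoch("flash", 10.0 * k + 5.0, 10.0 * k + 7.0, 95.23)
                  for k in range(200)]
        tr = poisson_train(40.0, 2005.0, seed=11)
        psth = compute_psth(tr, epochs, (1.0, 2.5))
        assert psth.rate.mean() == pytest.approx(40.0, rel=0.05)
        # per-bin sampling error: SE = sqrt(rate / (trials * bw))
        assert np.all(np.abs(psth.rate - 40.0) < 5 * np.sqrt(40 / (200 * 0.02)))

    def test_mass_conservation(self, flash_epoch):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(flash_epoch.onset - 1, flash_epoch.onset + 2, 200))
        tr = SpikeTrain("u", 1, times)
        psth = compute_psth(tr, [flash_epoch], (1.0, 2.0))
        in_window = np.sum((times >= flash_epoch.onset + psth.edges[0])
                           & (times < flash_epoch.onset + psth.edges[-1]))
        assert np.sum(psth.rate) * 0.02 * 1 == pytest.approx(in_window)


class TestBinomialSmoothing:
    def test_impulse_response_is_binomial_kernel(self):
        rates = np.zeros(11)
        rates[5] = 16.0
        sm = smooth_binomial(make_psth(rates), 4)
        np.testing.assert_allclose(sm.rate[3:8], [1, 4, 6, 4, 1])

    def test_constant_psth_unchanged(self):
        sm = smooth_binomial(make_psth(np.full(20, 7.0)), 4)
        np.testing.assert_allclose(sm.rate, 7.0)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(5)
        rates = rng.uniform(0, 100, 37)
        sm = smooth_binomial(make_psth(rates), 4)
        padded = np.concatenate([rates[2:0:-1], rates, rates[-2:-4:-1]])
        kernel = np.array([1, 4, 6, 4, 1]) / 16.0
        expect = np.convolve(padded, kernel, mode="valid")
        np.testing.assert_allclose(sm.rate, expect, atol=1e-12)

    def test_kernel_orders(self):
        np.testing.assert_allclose(binomial_kernel(4),
                                   np.array([1, 4, 6, 4, 1]) / 16.0)
        np.testing.assert_allclose(binomial_kernel(0), [1.0])


class TestSpontaneous:
    def test_silent_unit(self):
        m, s = spontaneous_rate(SpikeTrain("u", 1, []), (0.0, 10.0))
        assert (m, s) == (0.0, 0.0)

    def test_regular_10hz_mean(self, regular_train):
        m, s = spontaneous_rate(regular_train, (0.0, 10.0))
        assert m == pytest.approx(10.0)

    def test_threshold_formula(self):
        from retmea.psth import threshold_from
        assert threshold_from(5.0, 1.0) == pytest.approx(9.0)

    def test_short_dark_interval_rejected(self, regular_train):
        with pytest.raises(ValueError, match="dark interval"):
            spontaneous_rate(regular_train, (0.0, 4.0))


class TestClassifyUnit:
    """Direct applications of the classification rules on hand-built PSTHs.

    The PSTH axis runs -1.0 s to +2.35 s around onset (flash 5-7 s, 2 s
    long); bin width 20 ms.
    """

    def _psth(self, peaks):  # peaks: {time_s: rate_hz}
        rates = np.zeros(168)
        edges = -1.0 + np.arange(169) * 0.02
        centers = 0.5 * (edges[:-1] + edges[1:])
        for t, r in peaks.items():
            rates[np.argmin(np.abs(centers - t))] = r
        return PSTH(edges, rates, 1, smoothed=True)

    def _classify(self, peaks, spont=0.0, sd=0.0, **kw):
        ep = Epoch("flash", 5.0, 7.0, 95.23)
        cfg = AnalysisConfig(**kw)
        return classify_unit(self._psth(peaks), ep, spont, sd, cfg, "u")

    def test_on_unit(self):
        c = self._classify({0.12: 40.0}, spont=5.0, sd=1.0)
        assert c.response_type == "ON"
        assert c.peak_rate == pytest.approx(35.0)
        assert c.latency == pytest.approx(0.12, abs=0.011)

    def test_on_off_unit(self):
        c = self._classify({0.1: 40.0, 2.1: 30.0}, spont=5.0, sd=1.0)
        assert c.response_type == "ON_OFF"

    def test_off_unit_latency_from_offset(self):
        c = self._classify({2.1: 30.0}, spont=5.0, sd=1.0)
        assert c.response_type == "OFF"
        assert c.latency == pytest.approx(0.1, abs=0.011)

    def test_low_signal_below_10hz(self):
        c = self._classify({0.1: 8.0}, spont=0.0, sd=0.5)
        assert c.response_type == "LOW_SIGNAL"

    def test_10hz_peak_is_not_low_signal(self):
        c = self._classify({0.1: 10.0}, spont=0.0, sd=0.5)
        assert c.response_type == "ON"

    def test_subthreshold_is_not_classified(self):
        c = self._classify({0.1: 8.0}, spont=5.0, sd=1.0)
        assert c.response_type == "NOT_CLASSIFIED"
        assert c.peak_rate == 0.0

    def test_peak_outside_windows_is_not_classified(self):
        # supra-threshold activity at +1.0 s (inside flash, outside ON window)
        # and at offset+0.4 s (outside OFF window)
        c = self._classify({1.0: 50.0, 2.4: 50.0}, spont=0.0, sd=0.1)
        assert c.response_type == "NOT_CLASSIFIED"

    def test_off_window_edges(self):
        assert self._classify({2.06: 30.0}).response_type == "OFF"
        assert self._classify({2.31: 30.0}).response_type == "NOT_CLASSIFIED"

    @given(mult=st.floats(min_value=4.0, max_value=12.0),
           peak=st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_raising_threshold_never_creates_a_responsive_class(self, mult, peak):
        ep = Epoch("flash", 5.0, 7.0, 95.23)
        psth = self._psth({0.1: peak})
        lo = classify_unit(psth, ep, 2.0, 1.0,
                           AnalysisConfig(threshold_sd=4.0), "u")
        hi = classify_unit(psth, ep, 2.0, 1.0,
                           AnalysisConfig(threshold_sd=mult), "u")
        responsive = {"ON", "OFF", "ON_OFF", "LOW_SIGNAL"}
        if lo.response_type == "NOT_CLASSIFIED":
            assert hi.response_type == "NOT_CLASSIFIED"
        if hi.response_type in responsive:
            assert lo.response_type in responsive


class TestIntensitySeries:
    def _c(self, intensity, rtype, on_peak):
        from retmea.psth import UnitClassification
        return UnitClassification("u", rtype, 1.0, 5.0, on_peak, 0.1,
                                  intensity, on_peak)

    def test_all_subthreshold_is_all_zero(self):
        cs = [self._c(i, "NOT_CLASSIFIED", 0.0) for i in (1.0, 10.0, 100.0)]
        assert intensity_series(cs, unit_type="ON") == \
            [(1.0, 0.0), (10.0, 0.0), (100.0, 0.0)]

    def test_zeros_exactly_at_subthreshold_intensities(self):
        cs = [self._c(1.0, "NOT_CLASSIFIED", 0.0), self._c(10.0, "ON", 20.0),
              self._c(100.0, "ON", 60.0)]
        assert intensity_series(cs) == [(1.0, 0.0), (10.0, 20.0), (100.0, 60.0)]

    def test_off_only_unit_is_excluded(self):
        cs = [self._c(1.0, "OFF", 0.0), self._c(10.0, "OFF", 0.0),
              self._c(100.0, "OFF", 0.0)]
        assert intensity_series(cs) == []

    def test_unit_type_defaults_to_highest_intensity(self):
        cs = [self._c(100.0, "ON", 50.0), self._c(1.0, "NOT_CLASSIFIED", 0.0)]
        assert intensity_series(cs) == [(1.0, 0.0), (100.0, 50.0)]
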