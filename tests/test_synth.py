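import dataclasses

import numpy as np
import pytest
from scipy.integrate import trapezoid

from retmea.core import ProtocolError
from retmea.synth import (
    ScenarioConfig,
    UnitPhenotype,
    firing_rate,
    make_graft_mask,
    make_protocol,
    rd1_cone_config,
    scenario_defaults,
    simulate_merg,
    simulate_recording,
    simulate_unit,
)


class TestMakeProtocol:
    def test_single_flash_runs_5_to_7_seconds(self):
        p = make_protocol("flash_series", [95.23])
        (ep,) = p.flash_epochs()
        assert (ep.onset, ep.offset) == (5.0, 7.0)
        assert p.duration >= 10.0

    def test_flicker_series_counts(self):
        p = make_protocol("flicker_series", [95.23],
                          frequencies=[5, 15, 20, 25], repeats=3)
        eps = p.flicker_epochs()
        assert len(eps) == 12
        for a, b in zip(eps, eps[1:]):
            assert b.onset >= a.offset

    def test_empty_intensity_list_gives_empty_valid_protocol(self):
        p = make_protocol("flash_series", [])
        assert len(p) == 0 and p.duration > 0

    def test_every_flash_has_at_least_5s_of_background(self):
        p = make_protocol("flash_series", [1.0, 10.0], repeats=2)
        t_prev = 0.0
        for ep in p.flash_epochs():
            assert ep.onset - t_prev >= 5.0
            assert ep.duration == pytest.approx(2.0)
            t_prev = ep.offset

    @pytest.mark.parametrize("bad", [[-1.0], [0.0]])
    def test_nonpositive_intensity_rejected(self, bad):
        with pytest.raises(ProtocolError):
            make_protocol("flash_series", bad)


class TestSimulateUnit:
    def test_spontaneous_only_count_matches_rate_integral(self):
        ph = UnitPhenotype("NONE", spont_rate=20.0, resp_amplitude_max=0.0,
                           refractory=0.0)
        p = make_protocol("flash_series", [])
        st = simulate_unit(ph, p, 100.0, seed=7)
        assert abs(st.n_spikes - 2000) < 3 * np.sqrt(2000)

    def test_rate_integral_property_over_seeds(self, flash_protocol):
        # mean count over many seeds within 4 SE of the rate integral
        ph = UnitPhenotype("ON", spont_rate=4.0, resp_amplitude_max=50.0,
                           true_i50=10.0, refractory=0.0)
        t = np.linspace(0, flash_protocol.duration, 200_001)
        expected = trapezoid(firing_rate(ph, flash_protocol, t), t)
        counts = [simulate_unit(ph, flash_protocol, flash_protocol.duration,
                                seed=s).n_spikes for s in range(100)]
        se = np.std(counts, ddof=1) / 10.0
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_zero_rate_gives_empty_train(self, dark_protocol):
        ph = UnitPhenotype("NONE", spont_rate=0.0, resp_amplitude_max=0.0)
        assert simulate_unit(ph, dark_protocol, 20.0, seed=0).n_spikes == 0

    def test_same_seed_is_bit_identical(self, flash_protocol):
        ph = UnitPhenotype("ON", spont_rate=5.0)
        a = simulate_unit(ph, flash_protocol, 10.0, seed=42)
        b = simulate_unit(ph, flash_protocol, 10.0, seed=42)
        np.testing.assert_array_equal(a.times, b.times)

    def test_refractory_period_is_enforced(self, flash_protocol):
        ph = UnitPhenotype("ON", spont_rate=80.0, resp_amplitude_max=100.0,
                           true_i50=10.0, refractory=0.002)
        st = simulate_unit(ph, flash_protocol, 10.0, seed=1)
        assert np.diff(st.times).min() >= 0.002

    def test_duration_shorter_than_protocol_rejected(self, flash_protocol):
        with pytest.raises(ValueError, match="duration"):
            simulate_unit(UnitPhenotype(), flash_protocol, 5.0, seed=0)

    def test_on_response_peaks_near_configured_latency(self, flash_protocol):
        ph = UnitPhenotype("ON", spont_rate=0.0, resp_amplitude_max=100.0,
                           true_i50=1.0, latency_base=0.2, latency_slope=0.0)
        ep = flash_protocol.flash_epochs()[0]
        t = np.linspace(ep.onset, ep.offset, 4001)
        r = firing_rate(ph, flash_protocol, t)
        assert t[np.argmax(r)] - ep.onset == pytest.approx(0.2, abs=0.005)
        assert r.max() == pytest.approx(100.0 * 1 / (1 + (1 / 95.23) ** 1.5),
                                        rel=1e-3)


class TestSimulateMerg:
    def test_noise_free_entrained_trace_is_periodic(self):
        p = make_protocol("flicker_series", [95.23], frequencies=[5.0], repeats=1)
        tr = simulate_merg(p, entrained=True, frequency=5.0, noise_sd=0.0, seed=0)
        ep = p.flicker_epochs()[0]
        fs = tr.sampling_rate
        seg = tr.samples_uv[int(ep.onset * fs):int(ep.offset * fs)]
        period = int(0.2 * fs)
        np.testing.assert_allclose(seg[:period * 9],
                                   np.tile(seg[:period], 9), atol=1e-9)
        assert seg.max() > 0

    def test_dark_segment_is_noise_only(self):
        p = make_protocol("flicker_series", [95.23], frequencies=[5.0], repeats=1)
        tr = simulate_merg(p, entrained=True, frequency=5.0, noise_sd=0.0, seed=0)
        fs = tr.sampling_rate
        assert np.all(tr.samples_uv[:int(4.9 * fs)] == 0.0)

    def test_noise_free_non_entrained_trace_is_zero(self, dark_protocol):
        tr = simulate_merg(dark_protocol, entrained=False, frequency=5.0,
                           noise_sd=0.0, seed=0)
        assert np.all(tr.samples_uv == 0.0)

    def test_frequency_above_analysis_band_rejected(self, dark_protocol):
        with pytest.raises(ValueError, match="100"):
            simulate_merg(dark_protocol, True, 120.0, 1.0, 0)


class TestGraftMask:
    def test_tiny_disk_is_a_few_pixels(self):
        m = make_graft_mask((21, 21), (10, 10), 1.0)
        assert 1 <= m.data.sum() <= 5

    def test_foreground_matches_brute_force_pixel_scan(self):
        m = make_graft_mask((41, 41), (20.0, 17.0), 6.2)
        count = sum(1 for r in range(41) for c in range(41)
                    if np.hypot(r - 20.0, c - 17.0) <= 6.2)
        assert int(m.data.sum()) == count

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(image_shape=(21, 21), center_px=(10, 10), radius_px=0), "radius"),
        (dict(image_shape=(21, 21), center_px=(30, 10), radius_px=2), "center"),
        (dict(image_shape=(21, 21), center_px=(10, 10), radius_px=25), "extent"),
    ])
    def test_preconditions(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            make_graft_mask(**kwargs)


class TestSimulateRecording:
    def test_rd1_default_has_no_responsive_units(self, flash_protocol):
        cfg = dataclasses.replace(scenario_defaults("RD1", seed=1),
                                  include_traces=False)
        _, gt = simulate_recording(cfg, flash_protocol)
        assert (gt.units.true_type == "NONE").all()

    def test_wt_has_one_train_and_trace_per_electrode(self, flash_protocol):
        cfg = scenario_defaults("WT", seed=1)
        rec, gt = simulate_recording(cfg, flash_protocol)
        assert len(rec.spike_trains) == 60
        assert len(rec.field_traces) == 60
        assert len(gt.units) == 60 and len(gt.electrodes) == 60

    def test_tp_rd1_responsive_units_lie_in_graft_areas(self, flash_protocol):
        cfg = dataclasses.replace(scenario_defaults("TP_RD1", seed=2),
                                  include_traces=False)
        rec, gt = simulate_recording(cfg, flash_protocol)
        merged = gt.units.merge(gt.electrodes[["electrode_id", "true_area"]],
                                on="electrode_id")
        resp = merged[merged.true_type.isin(["ON", "OFF", "ON_OFF", "LOW_SIGNAL"])]
        assert len(resp) > 0
        assert set(resp.true_area) <= {1, 2}

    def test_scenario_separation_rd1_spont_exceeds_wt(self, flash_protocol):
        wt_cfg = dataclasses.replace(scenario_defaults("WT", seed=5),
                                     include_traces=False)
        rd_cfg = dataclasses.replace(scenario_defaults("RD1", seed=6),
                                     include_traces=False)
        _, wt = simulate_recording(wt_cfg, flash_protocol)
        _, rd = simulate_recording(rd_cfg, flash_protocol)
        assert rd.units.spont_rate_hz.mean() > wt.units.spont_rate_hz.mean()

    def test_rd1_cone_i50_three_log_units_above_wt(self):
        wt = scenario_defaults("WT")
        rd = rd1_cone_config()
        assert rd.i50_log10_mean - wt.i50_log10_mean == pytest.approx(3.0)

    def test_type_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            ScenarioConfig("WT", type_mixture={"ON": 0.5, "NONE": 0.6})

    def test_identical_seed_identical_recording(self, flash_protocol):
        cfg = dataclasses.replace(scenario_defaults("WT", seed=9),
                                  include_traces=False)
        r1, _ = simulate_recording(cfg, flash_protocol)
        r2, _ = simulate_recording(cfg, flash_protocol)
        for a, b in zip(r1.spike_trains, r2.spike_trains):
            np.testing.assert_array_equal(a.times, b.times)
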