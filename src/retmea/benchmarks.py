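"""Self-calibration benchmarks: recovery, null-rate and contrast measurements.

Each function generates labeled synthetic data with the package's own
generator, runs the corresponding analysis route end to end, and returns
summary metrics.  They serve two purposes: quantifying how well the
analysis recovers known ground truth under the generator's default
conditions, and verifying the false-positive calibration of the mean+4SD
detection rules.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .core import FieldTrace, SpikeTrain
from .flicker import (
    acg_spectrum,
    call_electrode,
    call_unit,
    dark_baseline,
    lowpass_and_average,
    periodogram_power,
    spike_acg,
)
from .intensity import fit_intensity_response
from .pipeline import build_protocol, run_analyze
from .psth import AnalysisConfig, classify_unit, compute_psth, smooth_binomial, \
    spontaneous_rate
from .synth import (
    UnitPhenotype,
    make_protocol,
    rd1_cone_config,
    scenario_defaults,
    simulate_merg,
    simulate_recording,
    simulate_unit,
)

__all__ = [
    "high_snr_phenotypes",
    "classifier_recovery",
    "i50_recovery_noise_free",
    "i50_recovery_poisson",
    "flicker_null_rates",
    "flicker_sensitivity",
    "scenario_contrasts",
]

_REF_INTENSITY = 95.23


def high_snr_phenotypes(n: int, seed: int) -> list[UnitPhenotype]:
    """``n`` phenotypes cycling through all five classes, parameterized so
    each class is unambiguous at the 95.23 R*/rod/s reference flash:
    responsive units saturate well below it, low-signal units are silent in
    darkness with peaks below 10 Hz, and latencies sit mid-window."""
    rng = np.random.default_rng(seed)
    types = ("ON", "OFF", "ON_OFF", "LOW_SIGNAL", "NONE")
    out = []
    for i in range(n):
        t = types[i % len(types)]
        if t == "NONE":
            out.append(UnitPhenotype("NONE", spont_rate=rng.uniform(10, 30),
                                     resp_amplitude_max=0.0))
        elif t == "LOW_SIGNAL":
            out.append(UnitPhenotype("LOW_SIGNAL", spont_rate=0.0,
                                     resp_amplitude_max=rng.uniform(4.0, 6.5),
                                     true_i50=rng.uniform(2, 10), true_n=2.0,
                                     latency_base=rng.uniform(0.15, 0.3),
                                     latency_slope=-0.02))
        else:
            out.append(UnitPhenotype(t, spont_rate=rng.uniform(0.5, 2.0),
                                     resp_amplitude_max=rng.uniform(80, 120),
                                     true_i50=rng.uniform(2, 10),
                                     true_n=rng.uniform(1.5, 2.5),
                                     latency_base=rng.uniform(0.15, 0.3),
                                     latency_slope=-0.02))
    return out


def classifier_recovery(n_units: int = 200, seed: int = 0,
                        repeats: int = 20) -> dict:
    """Ground-truth type recovery on high-SNR units (percent correct).

    NONE ground truth counts as recovered when classified NOT_CLASSIFIED.
    """
    proto = build_protocol(flash_intensities=(_REF_INTENSITY,),
                           flash_repeats=repeats,
                           flicker_intensities=(), flicker_frequencies=())
    cfg = AnalysisConfig()
    eps = proto.flash_epochs()
    dark = (0.0, eps[0].onset)
    rng = np.random.default_rng(seed)
    correct = 0
    for i, ph in enumerate(high_snr_phenotypes(n_units, seed)):
        st = simulate_unit(ph, proto, proto.duration,
                           int(rng.integers(0, 2**31 - 1)), f"u{i}")
        sm, sd = spontaneous_rate(st, dark, cfg)
        psth = compute_psth(st, eps, (1.0, eps[0].duration + 0.35), cfg)
        c = classify_unit(smooth_binomial(psth, cfg.binomial_order), eps[0],
                          sm, sd, cfg)
        want = "NOT_CLASSIFIED" if ph.true_type == "NONE" else ph.true_type
        correct += c.response_type == want
    return {"accuracy_pct": 100.0 * correct / n_units, "n": n_units}


def i50_recovery_noise_free(seed: int = 0, n_cases: int = 20) -> dict:
    """Max |Δlog10 I50| when fitting exact Naka-Rushton points."""
    rng = np.random.default_rng(seed)
    errs = []
    for _ in range(n_cases):
        i50 = 10.0 ** rng.uniform(0.5, 3.0)
        n = rng.uniform(0.8, 3.0)
        rmax = rng.uniform(40, 120)
        I = np.geomspace(i50 / 300, i50 * 300, 7)
        R = rmax * I**n / (I**n + i50**n)
        fit = fit_intensity_response(list(zip(I, R)))
        errs.append(abs(np.log10(fit.i50 / i50)))
    return {"max_abs_log10_err": float(np.max(errs)), "n": n_cases}


def i50_recovery_poisson(n_seeds: int = 100, n_trials: int = 20,
                         seed: int = 0) -> dict:
    """Median |Δlog10 I50| when peak rates are estimated from Poisson spike
    counts in a 100-ms peak window over ``n_trials`` trials per intensity."""
    rng = np.random.default_rng(seed)
    window = 0.1
    errs = []
    for _ in range(n_seeds):
        i50 = 10.0 ** rng.uniform(1.0, 2.5)
        n = rng.uniform(1.0, 2.5)
        rmax = rng.uniform(50, 100)
        I = np.geomspace(1.0, 1e5, 6)
        rate = rmax * I**n / (I**n + i50**n)
        measured = rng.poisson(rate * window * n_trials) / (window * n_trials)
        fit = fit_intensity_response(list(zip(I, measured)))
        errs.append(abs(np.log10(fit.i50 / i50)))
    return {"median_abs_log10_err": float(np.median(errs)), "n": n_seeds}


def _flicker_protocol() -> tuple:
    proto = make_protocol("flicker_series", [_REF_INTENSITY],
                          frequencies=[5.0, 15.0, 20.0, 25.0], repeats=3)
    conditions: dict[float, list] = {}
    for e in proto.flicker_epochs():
        conditions.setdefault(float(e.frequency_hz), []).append(e)
    return proto, conditions


def flicker_null_rates(n_targets: int = 200, seed: int = 0,
                       noise_sd: float = 5.0) -> dict:
    """Per-frequency positive-call rate on noise-only electrodes and
    unmodulated Poisson units (percent, pooled over 5/15/20/25 Hz)."""
    proto, conditions = _flicker_protocol()
    rng = np.random.default_rng(seed)
    fs = 20_000.0

    e_pos = e_tot = 0
    for _ in range(n_targets):
        tr = simulate_merg(proto, entrained=False, frequency=5.0,
                           noise_sd=noise_sd,
                           seed=int(rng.integers(0, 2**31 - 1)))
        x = tr.samples_uv

        def seg(t0, t1):
            return FieldTrace(1, x[int(t0 * fs):int(t1 * fs)], fs)

        dark_avg = lowpass_and_average([seg(s, s + 1.0) for s in (1.0, 2.0, 3.0)])
        base = dark_baseline(dark_avg)
        for freq, eps in sorted(conditions.items()):
            avg = lowpass_and_average([seg(e.onset, e.offset) for e in eps])
            call = call_electrode(periodogram_power(avg), freq, base)
            e_pos += call.positive
            e_tot += 1

    u_pos = u_tot = 0
    for _ in range(n_targets):
        ph = UnitPhenotype("NONE", spont_rate=rng.uniform(10, 30))
        st = simulate_unit(ph, proto, proto.duration,
                           int(rng.integers(0, 2**31 - 1)))
        res = _unit_calls(st, conditions, proto)
        for freq, call in res.items():
            u_pos += call.positive
            u_tot += 1
    return {"electrode_null_pct": 100.0 * e_pos / e_tot,
            "unit_null_pct": 100.0 * u_pos / max(u_tot, 1),
            "n": n_targets}


def _unit_calls(st: SpikeTrain, conditions: dict, proto) -> dict:
    epoch_dur = next(iter(conditions.values()))[0].duration
    out = {}
    for freq, eps in sorted(conditions.items()):
        stim = None
        dark = None
        for k, e in enumerate(eps):
            _, c = spike_acg(st, (e.onset, e.offset))
            if c.size:
                stim = c if stim is None else stim + c
            _, cd = spike_acg(st, (e.onset - epoch_dur - 0.5,
                                   e.onset - 0.5))
            if cd.size:
                dark = cd if dark is None else dark + cd
        if stim is None or dark is None:
            continue
        base = dark_baseline(acg_spectrum(dark, 0.010))
        out[freq] = call_unit(stim, 0.010, freq, base)
    return out


def flicker_sensitivity(n_targets: int = 100, seed: int = 0,
                        modulation: float = 0.8, noise_sd: float = 5.0) -> dict:
    """Positive rate at the stimulated fundamental vs at the other
    protocol frequencies, for entrained mERGs and modulated units.

    Each electrode/unit is entrained at 5 Hz only; calls at 15/20/25 Hz are
    made on those epochs (where the target does not respond), so their
    positive rate estimates the off-target false-call rate.
    """
    proto, conditions = _flicker_protocol()
    rng = np.random.default_rng(seed)
    fs = 20_000.0
    fund = 5.0

    e_fund = e_off = e_off_tot = 0
    for _ in range(n_targets):
        tr = simulate_merg(proto, entrained=True, frequency=fund,
                           noise_sd=noise_sd,
                           seed=int(rng.integers(0, 2**31 - 1)))
        x = tr.samples_uv

        def seg(t0, t1):
            return FieldTrace(1, x[int(t0 * fs):int(t1 * fs)], fs)

        dark_avg = lowpass_and_average([seg(s, s + 1.0) for s in (1.0, 2.0, 3.0)])
        base = dark_baseline(dark_avg)
        for freq, eps in sorted(conditions.items()):
            avg = lowpass_and_average([seg(e.onset, e.offset) for e in eps])
            call = call_electrode(periodogram_power(avg), freq, base)
            if freq == fund:
                e_fund += call.positive
            else:
                e_off += call.positive
                e_off_tot += 1

    u_fund = u_off = u_off_tot = 0
    for _ in range(n_targets):
        ph = UnitPhenotype("ON", spont_rate=rng.uniform(2, 6),
                           resp_amplitude_max=rng.uniform(60, 100),
                           true_i50=5.0, true_n=2.0,
                           flicker_modulation={fund: modulation})
        st = simulate_unit(ph, proto, proto.duration,
                           int(rng.integers(0, 2**31 - 1)))
        for freq, call in _unit_calls(st, conditions, proto).items():
            if freq == fund:
                u_fund += call.positive
            else:
                u_off += call.positive
                u_off_tot += 1
    return {
        "electrode_fundamental_pct": 100.0 * e_fund / n_targets,
        "electrode_offtarget_pct": 100.0 * e_off / e_off_tot,
        "unit_fundamental_pct": 100.0 * u_fund / n_targets,
        "unit_offtarget_pct": 100.0 * u_off / max(u_off_tot, 1),
        "n": n_targets,
    }


def scenario_contrasts(seed: int = 0, flash_repeats: int = 3) -> dict:
    """Directional group contrasts on default scenarios.

    * rd1 vs WT mean spontaneous rate (analysis-side estimates),
    * TP-rd1 vs cone-only rd1 half-saturation shift (log10) + KS test,
    * WT vs TP-rd1 flicker-following fractions per frequency (electrodes).
    """
    flash = dict(flash_repeats=flash_repeats,
                 flicker_intensities=(), flicker_frequencies=())
    proto_flash = build_protocol(**flash)

    results = {}
    analyses = {}
    for name, cfg in (("WT", scenario_defaults("WT", seed)),
                      ("RD1", scenario_defaults("RD1", seed + 1)),
                      ("TP_RD1", scenario_defaults("TP_RD1", seed + 2)),
                      ("RD1_CONE", rd1_cone_config(seed + 3))):
        cfg = dataclasses.replace(cfg, include_traces=False)
        rec, gt = simulate_recording(cfg, proto_flash)
        analyses[name] = run_analyze(rec, retina=name)

    spont_wt = analyses["WT"].unit_summary["spont_hz"].mean()
    spont_rd1 = analyses["RD1"].unit_summary["spont_hz"].mean()
    results["wt_mean_spont_hz"] = float(spont_wt)
    results["rd1_mean_spont_hz"] = float(spont_rd1)

    i50_tp = np.log10(analyses["TP_RD1"].fits["i50"])
    i50_rd = np.log10(analyses["RD1_CONE"].fits["i50"])
    ks = stats.ks_2samp(i50_tp, i50_rd)
    results["i50_shift_log10"] = float(i50_rd.median() - i50_tp.median())
    results["i50_ks_statistic"] = float(ks.statistic)
    results["i50_ks_pvalue"] = float(ks.pvalue)
    results["n_fits_tp"] = int(len(i50_tp))
    results["n_fits_rd1_cone"] = int(len(i50_rd))

    proto_flick = build_protocol(flash_intensities=(),
                                 flicker_intensities=(_REF_INTENSITY,))
    following = {}
    graft_following = {}
    for name, cfg in (("WT", scenario_defaults("WT", seed + 10)),
                      ("TP_RD1", scenario_defaults("TP_RD1", seed + 11))):
        rec, gt = simulate_recording(cfg, proto_flick)
        res = run_analyze(rec, retina=name)
        f = res.fractions
        f = f[f.kind == "electrode"]
        following[name] = dict(zip(f.frequency_hz, f.percent_positive))
        # transplants are summarized over the grafted area (area 1) only
        calls = res.flicker_calls
        calls = calls[calls.kind == "electrode"].copy()
        calls["electrode_id"] = calls.target_id.str.lstrip("e").astype(int)
        calls = calls.merge(res.areas, on="electrode_id")
        graft = calls[calls.area <= 1] if (calls.area > 0).any() else calls
        g = graft.groupby("frequency_hz")["verdict"] \
            .apply(lambda v: 100.0 * (v == "positive").mean())
        graft_following[name] = dict(g)
        results[f"n_graft_electrodes_{name.lower()}"] = \
            int(graft.electrode_id.nunique())
    for freq in (5.0, 15.0, 20.0, 25.0):
        results[f"wt_following_pct_{freq:g}hz"] = following["WT"].get(freq, np.nan)
        results[f"tp_following_pct_{freq:g}hz"] = following["TP_RD1"].get(freq, np.nan)
        results[f"tp_graft_following_pct_{freq:g}hz"] = \
            graft_following["TP_RD1"].get(freq, np.nan)
    return results
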