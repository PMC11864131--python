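"""Synthetic MEA recordings with ground truth.

Emulates the three preparations the analysis is built for:

* ``WT`` — wild-type retina: ON/OFF/ON-OFF responsive units everywhere,
  low spontaneous rates, flicker-entrained field potentials at 5-25 Hz.
* ``RD1`` — end-stage degenerated retina: no light-responsive units by
  default, elevated spontaneous firing, no flicker entrainment.  A
  "young rd1" variant (:func:`rd1_cone_config`) keeps cone-driven
  responses that require roughly 1000-fold stronger light.
* ``TP_RD1`` — rd1 retina carrying a transplanted organoid sheet:
  responsive units and entrained field potentials confined to the graft
  footprint, rd1-like activity elsewhere, with flicker following that
  weakens above 5 Hz.

Spikes come from an inhomogeneous Poisson process (thinning) with an
absolute refractory period enforced by deletion; flash responses are
difference-of-exponentials transients whose peak follows the unit's own
Naka-Rushton curve and whose peak time shrinks with log intensity.  Field
traces are one damped monophasic wavelet per light pulse plus Gaussian
noise, sampled at 20 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    DEFAULT_SAMPLING_RATE,
    ElectrodeGrid,
    Epoch,
    FieldTrace,
    MaskImage,
    ProtocolError,
    Recording,
    SpikeTrain,
    StimulusProtocol,
    default_mea60,
)
from .intensity import NakaRushtonFit, naka_rushton

__all__ = [
    "UnitPhenotype",
    "ScenarioConfig",
    "GroundTruth",
    "make_protocol",
    "simulate_unit",
    "simulate_merg",
    "simulate_recording",
    "make_graft_mask",
    "scenario_defaults",
    "rd1_cone_config",
]

RESPONSIVE_TYPES = ("ON", "OFF", "ON_OFF")
ALL_TYPES = ("ON", "OFF", "ON_OFF", "LOW_SIGNAL", "NONE")


@dataclass(frozen=True)
class UnitPhenotype:
    """Ground-truth generative parameters of one simulated unit."""

    true_type: str = "ON"
    spont_rate: float = 5.0              # Hz
    resp_amplitude_max: float = 60.0     # Hz, saturating peak above baseline
    true_i50: float = 30.0               # R*/rod/s
    true_n: float = 1.5
    latency_base: float = 0.25           # s, time-to-peak at I = 1 R*/rod/s
    latency_slope: float = -0.04         # s per log10 intensity (latency shrinks)
    flicker_modulation: Mapping[float, float] = field(default_factory=dict)
    refractory: float = 0.001            # s

    def __post_init__(self) -> None:
        if self.true_type not in ALL_TYPES:
            raise ValueError(f"unknown unit type {self.true_type!r}")
        if self.spont_rate < 0 or self.resp_amplitude_max < 0 or self.refractory < 0:
            raise ValueError("rates and refractory must be non-negative")
        if self.true_i50 <= 0 or self.true_n <= 0:
            raise ValueError("true_i50 and true_n must be positive")
        if self.latency_slope > 0:
            raise ValueError("latency_slope must be <= 0 (latency shrinks with intensity)")
        for f, m in self.flicker_modulation.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"modulation depth at {f} Hz outside [0, 1]")

    def response_curve(self) -> NakaRushtonFit:
        return NakaRushtonFit(0.0, self.resp_amplitude_max, self.true_i50,
                              self.true_n, 0.0, True)

    def latency_at(self, intensity: float) -> float:
        """Time-to-peak, clipped away from zero so the transient stays causal."""
        return max(0.02, self.latency_base + self.latency_slope * np.log10(intensity))


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated preparation (WT / RD1 / TP_RD1)."""

    scenario: str
    n_units_per_electrode: int = 1
    spont_rate_range: tuple[float, float] = (1.0, 10.0)
    responsive_spont_range: tuple[float, float] = (0.5, 3.0)
    resp_amp_range: tuple[float, float] = (60.0, 120.0)
    low_signal_amp_range: tuple[float, float] = (4.0, 8.0)
    latency_base_range: tuple[float, float] = (0.12, 0.25)
    type_mixture: Mapping[str, float] = field(default_factory=dict)
    i50_log10_mean: float = 1.5
    i50_log10_sd: float = 0.35
    include_traces: bool = True
    graft_center_um: tuple[float, float] = (0.0, 0.0)
    graft_radius_um: float = 300.0
    graft_margin_um: float = 40.0
    merg_entrain_prob: Mapping[float, float] = field(default_factory=dict)
    unit_modulation: Mapping[float, float] = field(default_factory=dict)
    merg_amplitude_uv: float = 60.0
    merg_noise_sd_uv: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("WT", "RD1", "TP_RD1"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.type_mixture:
            s = sum(self.type_mixture.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"type_mixture must sum to 1 (got {s})")
        if self.scenario == "TP_RD1" and self.graft_radius_um <= 0:
            raise ValueError("TP_RD1 requires a positive graft radius")


def scenario_defaults(scenario: str, seed: int = 0) -> ScenarioConfig:
    """Default configuration for each preparation.

    Spontaneous-rate ranges encode the directional finding that rd1
    spontaneous firing exceeds WT; the type mixtures loosely follow the
    observed WT / graft-area proportions (ON-dominated, few OFF).
    """
    if scenario == "WT":
        return ScenarioConfig(
            "WT",
            spont_rate_range=(1.0, 10.0),
            type_mixture={"ON": 0.45, "OFF": 0.10, "ON_OFF": 0.25,
                          "LOW_SIGNAL": 0.10, "NONE": 0.10},
            i50_log10_mean=1.5, i50_log10_sd=0.35,
            merg_entrain_prob={5.0: 0.95, 15.0: 0.90, 20.0: 0.85, 25.0: 0.80},
            unit_modulation={5.0: 0.9, 15.0: 0.8, 20.0: 0.7, 25.0: 0.6},
            seed=seed,
        )
    if scenario == "RD1":
        return ScenarioConfig(
            "RD1",
            spont_rate_range=(12.0, 35.0),
            type_mixture={"NONE": 1.0},
            merg_entrain_prob={},
            unit_modulation={},
            seed=seed,
        )
    if scenario == "TP_RD1":
        return ScenarioConfig(
            "TP_RD1",
            spont_rate_range=(12.0, 35.0),   # rd1-like background outside graft
            type_mixture={"ON": 0.55, "OFF": 0.05, "ON_OFF": 0.15,
                          "LOW_SIGNAL": 0.15, "NONE": 0.10},
            i50_log10_mean=1.7, i50_log10_sd=0.40,
            latency_base_range=(0.22, 0.35),   # graft responses peak later than WT
            merg_entrain_prob={5.0: 0.55, 15.0: 0.20, 20.0: 0.10, 25.0: 0.05},
            unit_modulation={5.0: 0.6, 15.0: 0.0, 20.0: 0.0, 25.0: 0.0},
            seed=seed,
        )
    raise ValueError(f"unknown scenario {scenario!r}")


def rd1_cone_config(seed: int = 0) -> ScenarioConfig:
    """Young rd1 with residual cone responses: responds only to very strong
    light (half-saturation ~3 log units above WT)."""
    return replace(
        scenario_defaults("RD1", seed),
        type_mixture={"ON": 0.4, "ON_OFF": 0.1, "LOW_SIGNAL": 0.2, "NONE": 0.3},
        i50_log10_mean=4.5, i50_log10_sd=0.40,
        latency_base_range=(0.22, 0.35),
    )


@dataclass
class GroundTruth:
    """Generator-side labels: one row per unit and one per electrode."""

    units: pd.DataFrame       # unit_id, electrode_id, true_type, spont_rate, ...
    electrodes: pd.DataFrame  # electrode_id, true_area, entrained_<f>hz flags


# ---------------------------------------------------------------------------
# stimulus protocol construction


def make_protocol(
    kind: str,
    intensities: Sequence[float],
    background: float = 0.0,
    frequencies: Sequence[float] = (5.0, 15.0, 20.0, 25.0),
    repeats: int | None = None,
    flash_duration: float = 2.0,
    flicker_duration: float = 2.0,
    lead: float = 5.0,
    gap: float = 3.0,
) -> StimulusProtocol:
    """Build a flash or flicker stimulus series on a single time axis.

    ``flash_series``: each intensity x repeat gives one ``flash_duration``
    flash preceded by ``lead`` seconds of background (so the first flash
    runs 5-7 s, matching the standard 2-s flash protocol).

    ``flicker_series``: each intensity x frequency x repeat gives one
    ``flicker_duration`` square-wave flicker epoch; flicker series default
    to 3 repeats.
    """
    if kind not in ("flash_series", "flicker_series"):
        raise ProtocolError(f"unknown protocol kind {kind!r}")
    if any(i <= 0 for i in intensities):
        raise ProtocolError("intensities must be strictly positive")
    if repeats is None:
        repeats = 1 if kind == "flash_series" else 3
    if repeats < 1:
        raise ProtocolError("repeats must be >= 1")

    epochs: list[Epoch] = []
    t = 0.0
    if kind == "flash_series":
        for intensity in intensities:
            for rep in range(repeats):
                onset = t + lead
                epochs.append(Epoch("flash", onset, onset + flash_duration,
                                    intensity, background, None, rep))
                t = onset + flash_duration
    else:
        if any(f <= 0 for f in frequencies):
            raise ProtocolError("flicker frequencies must be positive")
        for intensity in intensities:
            for freq in frequencies:
                for rep in range(repeats):
                    onset = t + lead
                    epochs.append(Epoch("flicker", onset, onset + flicker_duration,
                                        intensity, background, freq, rep))
                    t = onset + flicker_duration
    duration = max(t + gap, 10.0)
    return StimulusProtocol(tuple(epochs), duration)


# ---------------------------------------------------------------------------
# spike simulation


def _doe_kernel(t: np.ndarray, peak_time: float, peak_rate: float) -> np.ndarray:
    """Difference-of-exponentials transient, normalized to peak ``peak_rate``
    at ``peak_time``.  Decay constant is 3x the rise constant, which puts
    the peak at ~1.648 tau_rise."""
    tau_r = peak_time / 1.6479184330021645   # = (3/2)*ln 3
    tau_d = 3.0 * tau_r
    g = np.where(t > 0, np.exp(-np.maximum(t, 0) / tau_d) - np.exp(-np.maximum(t, 0) / tau_r), 0.0)
    g_peak = np.exp(-peak_time / tau_d) - np.exp(-peak_time / tau_r)
    return peak_rate * g / g_peak


def firing_rate(phenotype: UnitPhenotype, protocol: StimulusProtocol,
                t: np.ndarray) -> np.ndarray:
    """Instantaneous firing rate lambda(t) in Hz for the generative model."""
    rate = np.full_like(t, phenotype.spont_rate, dtype=float)
    if phenotype.true_type == "NONE":
        return rate
    curve = phenotype.response_curve()
    for ep in protocol:
        if ep.kind == "flash":
            peak = float(naka_rushton(ep.intensity, curve))
            lat = phenotype.latency_at(ep.intensity)
            if phenotype.true_type in ("ON", "ON_OFF", "LOW_SIGNAL"):
                rate += _doe_kernel(t - ep.onset, lat, peak)
            if phenotype.true_type in ("OFF", "ON_OFF"):
                off_lat = float(np.clip(lat, 0.06, 0.28))
                rate += _doe_kernel(t - ep.offset, off_lat, peak)
        else:  # flicker: square-wave rate modulation at the stimulus frequency
            depth = float(phenotype.flicker_modulation.get(float(ep.frequency_hz), 0.0))
            if depth <= 0:
                continue
            peak = float(naka_rushton(ep.intensity, curve))
            inside = (t >= ep.onset) & (t < ep.offset)
            phase = (t - ep.onset) * ep.frequency_hz
            rate += inside * (phase % 1.0 < 0.5) * depth * peak
    return rate


def _rate_bound(phenotype: UnitPhenotype) -> float:
    # non-overlapping epochs; kernel tails can touch the next epoch, so
    # leave generous headroom above spont + saturating amplitude
    return phenotype.spont_rate + 2.1 * phenotype.resp_amplitude_max + 1.0


def simulate_unit(phenotype: UnitPhenotype, protocol: StimulusProtocol,
                  duration: float, seed: int, unit_id: str = "u0",
                  electrode_id: int = 1) -> SpikeTrain:
    """Draw one spike train by Poisson thinning of the phenotype's rate.

    The absolute refractory period is enforced after thinning by deleting
    any spike closer than ``phenotype.refractory`` to the previous kept
    spike.  Identical seed and inputs give identical spike times.
    """
    if duration < protocol.duration:
        raise ValueError("duration must cover the stimulus protocol")
    rng = np.random.default_rng(seed)
    lam_max = _rate_bound(phenotype)
    n = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n))
    u = rng.uniform(0.0, 1.0, n)
    if n:
        keep = u < firing_rate(phenotype, protocol, cand) / lam_max
        cand = cand[keep]
    if phenotype.refractory > 0 and cand.size:
        kept = [cand[0]]
        for s in cand[1:]:
            if s - kept[-1] >= phenotype.refractory:
                kept.append(s)
        cand = np.array(kept)
    return SpikeTrain(unit_id, electrode_id, cand)


# ---------------------------------------------------------------------------
# field-potential (micro-ERG) simulation


def _merg_wavelet(t: np.ndarray, tau: float = 0.02) -> np.ndarray:
    """Monophasic damped transient (b-wave-like), unit peak at t = tau."""
    x = np.maximum(t, 0.0) / tau
    return np.where(t > 0, x * np.exp(1.0 - x), 0.0)


def merg_signal(protocol: StimulusProtocol, entrained_freqs: Sequence[float],
                amplitude_uv: float = 60.0,
                sampling_rate: float = DEFAULT_SAMPLING_RATE) -> np.ndarray:
    """Noise-free field-potential signal: one damped transient per light
    pulse of every flicker epoch whose frequency is in ``entrained_freqs``."""
    n = int(round(protocol.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    sig = np.zeros(n)
    freqs = {float(f) for f in entrained_freqs}
    for ep in protocol.flicker_epochs():
        if float(ep.frequency_hz) not in freqs:
            continue
        period = 1.0 / ep.frequency_hz
        n_pulses = int(np.floor(ep.duration * ep.frequency_hz))
        # transient width shrinks with frequency so pulses stay resolved
        tau = min(0.02, 0.25 * period)
        for k in range(n_pulses):
            onset = ep.onset + k * period
            lo = int(onset * sampling_rate)
            hi = min(n, int((onset + 10 * tau) * sampling_rate))
            sig[lo:hi] += amplitude_uv * _merg_wavelet(t[lo:hi] - onset, tau)
    return sig


def simulate_merg(protocol: StimulusProtocol, entrained: bool, frequency: float,
                  noise_sd: float, seed: int, amplitude_uv: float = 60.0,
                  sampling_rate: float = DEFAULT_SAMPLING_RATE,
                  electrode_id: int = 1) -> FieldTrace:
    """Simulate one electrode's field trace for a single flicker frequency.

    Entrained traces respond to every flicker epoch at ``frequency``;
    non-entrained traces (and all dark segments) are Gaussian noise only.
    """
    if frequency >= 100.0:
        raise ValueError("flicker frequency must stay below the 100-Hz analysis band")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    sig = (merg_signal(protocol, [frequency], amplitude_uv, sampling_rate)
           if entrained else np.zeros(int(round(protocol.duration * sampling_rate))))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, sig.size)
    return FieldTrace(electrode_id, sig, sampling_rate)


# ---------------------------------------------------------------------------
# graft mask and whole-recording assembly


def make_graft_mask(image_shape: tuple[int, int], center_px: tuple[float, float],
                    radius_px: float, um_per_px: float = 20.0,
                    origin_um: tuple[float, float] = (0.0, 0.0)) -> MaskImage:
    """Binary disk emulating the graft's fluorescence footprint.

    ``center_px`` is (row, col).  Raises for non-positive radius, a center
    outside the image, or a radius at least the image extent.
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    rows, cols = image_shape
    r0, c0 = center_px
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError("center must lie inside the image")
    if radius_px >= max(rows, cols):
        raise ValueError("radius must be smaller than the image extent")
    rr, cc = np.ogrid[0:rows, 0:cols]
    data = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px ** 2
    return MaskImage(data, um_per_px, origin_um)


def _true_areas(mask: MaskImage, grid: ElectrodeGrid,
                levels: Sequence[int] = (1, 5, 10, 15)) -> np.ndarray:
    """Geometric ground-truth area labels from a chessboard distance
    transform of the mask background (independent of the iterated-dilation
    path used by the analysis)."""
    dist = ndimage.distance_transform_cdt(~mask.data, metric="chessboard")
    areas = np.empty(len(grid), dtype=int)
    for i, eid in enumerate(grid.ids):
        r, c = mask.um_to_pixel(grid.positions_um[i])
        d = dist[r, c]
        if d <= levels[0]:
            areas[i] = 1
        elif d <= levels[1]:
            areas[i] = 2
        elif d <= levels[2]:
            areas[i] = 3
        else:
            areas[i] = 4
    return areas


def _sample_phenotype(cfg: ScenarioConfig, rng: np.random.Generator,
                      responsive_site: bool,
                      flicker_entrained: dict[float, bool]) -> UnitPhenotype:
    if responsive_site and cfg.type_mixture:
        types = list(cfg.type_mixture)
        utype = rng.choice(types, p=[cfg.type_mixture[k] for k in types])
    else:
        utype = "NONE"
    if utype == "NONE":
        spont = rng.uniform(*cfg.spont_rate_range)
        return UnitPhenotype("NONE", spont_rate=spont, flicker_modulation={})
    # responsive units sit on functional (graft or WT) tissue: low baseline.
    # low-signal units are near-silent in the dark so the +4 SD threshold
    # (computed from 20-ms binned dark rates) stays below their small peak.
    if utype == "LOW_SIGNAL":
        spont = rng.uniform(0.0, 0.02)
        amp = rng.uniform(*cfg.low_signal_amp_range)
    else:
        spont = rng.uniform(*cfg.responsive_spont_range)
        amp = rng.uniform(*cfg.resp_amp_range)
    i50 = 10.0 ** rng.normal(cfg.i50_log10_mean, cfg.i50_log10_sd)
    n = rng.uniform(1.0, 2.5)
    lat_base = rng.uniform(*cfg.latency_base_range)
    lat_slope = -rng.uniform(0.02, 0.05)
    mod = {f: (cfg.unit_modulation.get(f, 0.0) if flicker_entrained.get(f, True) else 0.0)
           for f in cfg.unit_modulation}
    return UnitPhenotype(utype, spont, amp, i50, n, lat_base, lat_slope, mod)


def simulate_recording(config: ScenarioConfig,
                       protocol: StimulusProtocol) -> tuple[Recording, GroundTruth]:
    """Generate a complete labeled recording for one scenario.

    TP_RD1 places responsive phenotypes only on electrodes whose center
    lies within ``graft_margin_um`` of the graft disk and entrains field
    potentials there; RD1 has no responsive units and no entrainment; WT is
    responsive and entrained everywhere (probabilistically per frequency).
    """
    rng = np.random.default_rng(config.seed)
    grid = default_mea60()
    duration = protocol.duration

    mask = None
    dist_to_graft = np.zeros(len(grid))
    if config.scenario == "TP_RD1":
        um_per_px = 20.0
        half = 4.0 * grid.pitch_um + 3.0 * um_per_px * 5  # grid span + margin
        npx = int(2 * half / um_per_px) + 1
        origin = (-half, -half)
        cr, cc = ((config.graft_center_um[1] - origin[1]) / um_per_px,
                  (config.graft_center_um[0] - origin[0]) / um_per_px)
        mask = make_graft_mask((npx, npx), (cr, cc),
                               config.graft_radius_um / um_per_px,
                               um_per_px, origin)
        dist_to_graft = np.maximum(
            np.hypot(grid.positions_um[:, 0] - config.graft_center_um[0],
                     grid.positions_um[:, 1] - config.graft_center_um[1])
            - config.graft_radius_um, 0.0)

    protocol_freqs = sorted({float(e.frequency_hz) for e in protocol.flicker_epochs()})
    freqs = protocol_freqs or sorted(config.merg_entrain_prob)

    trains: list[SpikeTrain] = []
    traces: list[FieldTrace] = []
    unit_rows, elec_rows = [], []
    unit_idx = 0
    for i, eid in enumerate(grid.ids):
        if config.scenario == "WT":
            site_ok = True
        elif config.scenario == "RD1":
            site_ok = True  # mixture itself decides (default all NONE)
        else:
            site_ok = dist_to_graft[i] <= config.graft_margin_um

        entrained = {f: (site_ok and rng.uniform() < config.merg_entrain_prob.get(f, 0.0))
                     for f in freqs}
        if config.include_traces:
            sig_freqs = [f for f, flag in entrained.items() if flag]
            sig = merg_signal(protocol, sig_freqs, config.merg_amplitude_uv)
            if config.merg_noise_sd_uv > 0:
                sig = sig + rng.normal(0.0, config.merg_noise_sd_uv, sig.size)
            traces.append(FieldTrace(eid, sig.astype(np.float32)))

        for _ in range(config.n_units_per_electrode):
            ph = _sample_phenotype(config, rng, site_ok, entrained)
            uid = f"u{unit_idx:04d}"
            unit_idx += 1
            st = simulate_unit(ph, protocol, duration,
                               int(rng.integers(0, 2**31 - 1)), uid, eid)
            trains.append(st)
            unit_rows.append({
                "unit_id": uid, "electrode_id": eid, "true_type": ph.true_type,
                "spont_rate_hz": ph.spont_rate,
                "resp_amplitude_max_hz": ph.resp_amplitude_max,
                "true_i50": ph.true_i50, "true_n": ph.true_n,
                "latency_base_s": ph.latency_base,
                "latency_slope_s_per_log10": ph.latency_slope,
                **{f"modulation_{f:g}hz": ph.flicker_modulation.get(f, 0.0)
                   for f in freqs},
            })
        elec_rows.append({"electrode_id": eid,
                          **{f"entrained_{f:g}hz": bool(entrained[f]) for f in freqs}})

    edf = pd.DataFrame(elec_rows)
    if mask is not None:
        edf.insert(1, "true_area", _true_areas(mask, grid))
    else:
        edf.insert(1, "true_area", 0)

    rec = Recording(grid=grid, spike_trains=trains, field_traces=traces,
                    protocol=protocol, duration=duration, mask=mask,
                    metadata={"scenario": config.scenario, "seed": config.seed})
    return rec, GroundTruth(pd.DataFrame(unit_rows), edf)
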