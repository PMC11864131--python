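"""Peristimulus time histograms and flash-response classification.

The classification pipeline for each spike-sorted unit:

1. PSTH over flash trials, 20-ms bins, edges aligned to stimulus onset.
2. Smoothing with an order-4 binomial filter (weights 1,4,6,4,1 / 16).
3. Spontaneous mean and SD from 10 s of darkness (20-ms bins); response
   threshold = mean + 4 SD.
4. A unit is ON if a supra-threshold peak occurs within 500 ms after light
   onset, OFF if within 50-300 ms after offset, ON-OFF if both, LOW_SIGNAL
   if supra-threshold peaks exist but all stay below 10 Hz, and
   NOT_CLASSIFIED otherwise.  Reported peak rates are corrected by
   subtracting the dark mean (clipped at zero); ON latency is the
   time-to-peak from onset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence
import warnings

import numpy as np
from scipy.special import comb

from .core import Epoch, SpikeTrain

__all__ = [
    "AnalysisConfig",
    "PSTH",
    "UnitClassification",
    "compute_psth",
    "smooth_binomial",
    "spontaneous_rate",
    "classify_unit",
    "intensity_series",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Classification parameters (defaults are the standard procedure)."""

    bin_width: float = 0.020          # s
    binomial_order: int = 4
    threshold_sd: float = 4.0
    on_window: float = 0.5            # s after light onset
    off_window: tuple[float, float] = (0.05, 0.3)  # s after light offset
    low_signal_cutoff: float = 10.0   # Hz, on the raw supra-threshold peak
    spontaneous_window: float = 10.0  # s of darkness
    low_signal_on_raw_peak: bool = True  # assess <10 Hz before baseline subtraction

    def __post_init__(self) -> None:
        if min(self.bin_width, self.threshold_sd, self.on_window,
               self.low_signal_cutoff, self.spontaneous_window) <= 0:
            raise ValueError("analysis parameters must be positive")
        if not 0 <= self.off_window[0] < self.off_window[1]:
            raise ValueError("OFF window start must precede end")


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged firing rate on a peristimulus time axis.

    ``edges`` are relative to stimulus onset (edge 0 coincides with onset);
    ``rate[i]`` is the mean rate in ``[edges[i], edges[i+1])`` in Hz.
    """

    edges: np.ndarray
    rate: np.ndarray
    n_trials: int
    smoothed: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        r = np.asarray(self.rate, dtype=float)
        if e.size != r.size + 1:
            raise ValueError("need one more edge than rate bins")
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "rate", r)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass(frozen=True)
class UnitClassification:
    unit_id: str
    response_type: str                # ON | OFF | ON_OFF | LOW_SIGNAL | NOT_CLASSIFIED
    spont_rate: float                 # Hz, dark mean
    threshold: float                  # Hz, dark mean + 4 SD
    peak_rate: float                  # Hz, baseline-corrected, >= 0
    latency: float | None             # s from onset (ON/ON_OFF); from offset for OFF
    intensity: float | None = None    # flash intensity the classification used
    on_peak_rate: float = 0.0         # Hz, corrected ON-window peak (0 if subthreshold)


def compute_psth(train: SpikeTrain, epochs: Sequence[Epoch],
                 window: tuple[float, float], cfg: AnalysisConfig | None = None) -> PSTH:
    """Trial-aligned PSTH: spikes per bin / (trials x bin width).

    ``window`` is (seconds before onset, seconds after onset); the bin grid
    is anchored so one edge falls exactly at onset.
    """
    cfg = cfg or AnalysisConfig()
    if not epochs:
        raise ValueError("need at least one stimulus epoch")
    pre, post = float(window[0]), float(window[1])
    n_pre = int(np.ceil(pre / cfg.bin_width - 1e-9))
    n_post = int(np.ceil(post / cfg.bin_width - 1e-9))
    edges = (np.arange(-n_pre, n_post + 1)) * cfg.bin_width
    counts = np.zeros(edges.size - 1)
    for ep in epochs:
        rel = train.times - ep.onset
        sel = rel[(rel >= edges[0]) & (rel < edges[-1])]
        counts += np.histogram(sel, bins=edges)[0]
    rate = counts / (len(epochs) * cfg.bin_width)
    return PSTH(edges, rate, n_trials=len(epochs), smoothed=False)


def binomial_kernel(n: int) -> np.ndarray:
    """Normalized binomial smoothing kernel of order ``n`` (n+1 taps)."""
    if n < 0:
        raise ValueError("order must be >= 0")
    w = comb(n, np.arange(n + 1))
    return w / w.sum()


def smooth_binomial(psth: PSTH, n: int = 4) -> PSTH:
    """Binomial smoothing (order 4: 1,4,6,4,1 / 16) with reflect padding.

    Reflect padding keeps the total spike mass approximately conserved and
    avoids artificial dips at the window borders.
    """
    k = binomial_kernel(n)
    half = n // 2
    if psth.rate.size == 0 or n == 0:
        return replace(psth, smoothed=True)
    padded = np.pad(psth.rate, half, mode="reflect") if half else psth.rate
    sm = np.convolve(padded, k, mode="same")
    sm = sm[half:sm.size - half] if half else sm
    return replace(psth, rate=sm, smoothed=True)


def spontaneous_rate(train: SpikeTrain, dark_interval: tuple[float, float],
                     cfg: AnalysisConfig | None = None) -> tuple[float, float]:
    """Mean and SD of the dark firing rate over 20-ms bins.

    Uses the last ``cfg.spontaneous_window`` seconds of the given dark
    interval.  The response threshold is ``mean + cfg.threshold_sd * SD``.
    """
    cfg = cfg or AnalysisConfig()
    t0, t1 = dark_interval
    if t1 - t0 < cfg.spontaneous_window - 1e-9:
        raise ValueError(
            f"dark interval shorter than the {cfg.spontaneous_window}-s "
            "spontaneous window")
    t0 = t1 - cfg.spontaneous_window
    edges = t0 + np.arange(int(round(cfg.spontaneous_window / cfg.bin_width)) + 1) \
        * cfg.bin_width
    counts = np.histogram(train.times, bins=edges)[0]
    rates = counts / cfg.bin_width
    return float(rates.mean()), float(rates.std())


def threshold_from(spont_mean: float, spont_sd: float,
                   cfg: AnalysisConfig | None = None) -> float:
    cfg = cfg or AnalysisConfig()
    return spont_mean + cfg.threshold_sd * spont_sd


def _window_peak(psth: PSTH, lo: float, hi: float) -> tuple[float, float]:
    """(max rate, time of max) over bins whose center lies in [lo, hi)."""
    sel = (psth.centers >= lo) & (psth.centers < hi)
    if not sel.any():
        return 0.0, np.nan
    rates = psth.rate[sel]
    i = int(np.argmax(rates))
    return float(rates[i]), float(psth.centers[sel][i])


def classify_unit(psth: PSTH, epoch: Epoch, spont_mean: float, spont_sd: float,
                  cfg: AnalysisConfig | None = None,
                  unit_id: str = "") -> UnitClassification:
    """Apply the ON/OFF/ON-OFF/low-signal rules to a smoothed PSTH.

    ``psth`` must be onset-aligned and cover the ON window and the OFF
    window after ``epoch.offset``.  Precedence: supra-threshold detection
    first; then the low-signal test on the raw supra-threshold peak
    (config-switchable to the baseline-subtracted peak); then window-based
    typing.  Always returns a classification.
    """
    cfg = cfg or AnalysisConfig()
    thr = threshold_from(spont_mean, spont_sd, cfg)
    stim_dur = epoch.duration

    on_peak, on_t = _window_peak(psth, 0.0, cfg.on_window)
    off_peak, off_t = _window_peak(psth, stim_dur + cfg.off_window[0],
                                   stim_dur + cfg.off_window[1])
    on_pos = on_peak > thr
    off_pos = off_peak > thr

    def corrected(raw: float) -> float:
        return max(0.0, raw - spont_mean)

    on_corr = corrected(on_peak) if on_pos else 0.0

    if not on_pos and not off_pos:
        return UnitClassification(unit_id, "NOT_CLASSIFIED", spont_mean, thr,
                                  0.0, None, epoch.intensity, 0.0)

    supra = [p for p, pos in ((on_peak, on_pos), (off_peak, off_pos)) if pos]
    judged = supra if cfg.low_signal_on_raw_peak else [corrected(p) for p in supra]
    if max(judged) < cfg.low_signal_cutoff:
        best = max(supra)
        lat = on_t if (on_pos and on_peak >= off_peak) else off_t - stim_dur
        return UnitClassification(unit_id, "LOW_SIGNAL", spont_mean, thr,
                                  corrected(best), lat, epoch.intensity, on_corr)

    if on_pos and off_pos:
        return UnitClassification(unit_id, "ON_OFF", spont_mean, thr,
                                  corrected(max(on_peak, off_peak)), on_t,
                                  epoch.intensity, on_corr)
    if on_pos:
        return UnitClassification(unit_id, "ON", spont_mean, thr,
                                  corrected(on_peak), on_t, epoch.intensity,
                                  on_corr)
    return UnitClassification(unit_id, "OFF", spont_mean, thr,
                              corrected(off_peak), off_t - stim_dur,
                              epoch.intensity, 0.0)


def intensity_series(classifications: Sequence[UnitClassification],
                     unit_type: str | None = None) -> list[tuple[float, float]]:
    """Ordered (intensity, corrected ON peak rate) pairs for one unit.

    Only ON and ON-OFF units are admitted to the intensity-response
    analysis; ``unit_type`` defaults to the classification at the highest
    intensity.  Non-admitted units give an empty series.  At intensities
    where the unit stays subthreshold the response is recorded as 0 Hz;
    classifications without an intensity are omitted with a warning.
    """
    with_i = []
    for c in classifications:
        if c.intensity is None:
            warnings.warn(f"classification for {c.unit_id!r} lacks an intensity; "
                          "pair omitted", stacklevel=2)
        else:
            with_i.append(c)
    if not with_i:
        return []
    if unit_type is None:
        unit_type = max(with_i, key=lambda c: c.intensity).response_type
    if unit_type not in ("ON", "ON_OFF"):
        return []
    return sorted((c.intensity, c.on_peak_rate) for c in with_i)
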