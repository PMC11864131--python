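"""Flicker-following statistics for micro-ERGs and spike trains.

Electrode (mERG) route: 100-Hz zero-phase low-pass, average the (default
three) repeats of a stimulus condition, take the periodogram, and compare
the power at the stimulation frequency against a dark baseline — the mean
+ 4 SD of periodogram power over 0-30 Hz computed from a 1-s average
waveform in darkness.  Power above threshold makes the electrode
"positive" at that frequency.

Unit (spike) route: the spike-raster autocorrelogram within the stimulus
epochs, its periodogram, and the same mean + 4 SD rule with the baseline
taken from an equal-duration dark-segment autocorrelogram spectrum.

Following performance is summarized as the percentage of positive targets
per group x frequency x condition, keeping per-retina fractions so group
comparisons can use a Mann-Whitney U test across retinas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .core import FieldTrace, SpikeTrain

__all__ = [
    "Spectrum",
    "FollowingCall",
    "lowpass_and_average",
    "periodogram_power",
    "dark_baseline",
    "call_electrode",
    "spike_acg",
    "call_unit",
    "following_fraction",
]


@dataclass(frozen=True)
class Spectrum:
    frequencies: np.ndarray  # Hz, uniformly spaced from 0
    power: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))
        object.__setattr__(self, "power", np.asarray(self.power, float))

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def power_at(self, frequency: float) -> float:
        """Power in the bin nearest ``frequency`` (must be within 1 bin)."""
        i = int(np.argmin(np.abs(self.frequencies - frequency)))
        if abs(self.frequencies[i] - frequency) > self.resolution:
            raise ValueError(f"{frequency} Hz is outside the spectrum range")
        return float(self.power[i])


@dataclass(frozen=True)
class FollowingCall:
    target_id: str
    kind: str                 # "electrode" | "unit"
    frequency_hz: float
    power: float
    baseline_mean: float
    baseline_sd: float
    positive: bool
    retina: str = ""
    condition: str = ""

    @property
    def threshold(self) -> float:
        return self.baseline_mean + 4.0 * self.baseline_sd


def lowpass_and_average(traces: Sequence[FieldTrace], cutoff: float = 100.0,
                        order: int = 4) -> FieldTrace:
    """Zero-phase Butterworth low-pass at ``cutoff`` then pointwise mean.

    Filtering forward-backward avoids latency distortion of the mERG
    waveform.  All repeats must share length and sampling rate.
    """
    if not traces:
        raise ValueError("need at least one trace")
    n = traces[0].samples_uv.size
    fs = traces[0].sampling_rate
    if any(t.samples_uv.size != n or t.sampling_rate != fs for t in traces):
        raise ValueError("repeats must share length and sampling rate")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    stack = np.stack([signal.sosfiltfilt(sos, t.samples_uv.astype(float))
                      for t in traces])
    return FieldTrace(traces[0].electrode_id, stack.mean(axis=0), fs)


def periodogram_power(samples: np.ndarray | FieldTrace,
                      sampling_rate: float | None = None) -> Spectrum:
    """Single-taper (boxcar) periodogram; resolution = 1/duration."""
    if isinstance(samples, FieldTrace):
        sampling_rate = samples.sampling_rate
        samples = samples.samples_uv
    x = np.asarray(samples, float)
    if x.size == 0:
        raise ValueError("empty trace")
    f, p = signal.periodogram(x, fs=float(sampling_rate), window="boxcar",
                              detrend=False)
    return Spectrum(f, p)


def dark_baseline(dark_trace: FieldTrace | Spectrum,
                  band: tuple[float, float] = (0.0, 30.0)) -> tuple[float, float]:
    """Mean and SD of periodogram power over the 0-30 Hz band in darkness.

    Accepts the 1-s average dark waveform (or a precomputed spectrum).  The
    SD is taken across the frequency bins of the dark spectrum.
    """
    spec = dark_trace if isinstance(dark_trace, Spectrum) \
        else periodogram_power(dark_trace)
    sel = (spec.frequencies >= band[0]) & (spec.frequencies <= band[1])
    if not sel.any():
        raise ValueError("baseline band contains no frequency bins at this resolution")
    vals = spec.power[sel]
    return float(vals.mean()), float(vals.std())


def call_electrode(spectrum: Spectrum, stim_frequency: float,
                   baseline: tuple[float, float], target_id: str = "",
                   retina: str = "", condition: str = "") -> FollowingCall:
    """Positive iff power at the stimulation frequency exceeds mean + 4 SD.

    Power is read at the periodogram bin nearest the stimulation frequency;
    harmonics are deliberately not counted as following.
    """
    mean, sd = baseline
    p = spectrum.power_at(stim_frequency)
    return FollowingCall(target_id, "electrode", float(stim_frequency), p,
                         mean, sd, positive=p > mean + 4.0 * sd,
                         retina=retina, condition=condition)


def spike_acg(train: SpikeTrain, window: tuple[float, float],
              bin_width: float = 0.010, max_lag: float = 1.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """Spike-train autocorrelogram within ``window``.

    Returns (lag bin centers, counts): the histogram of all pairwise
    spike-time differences within ±``max_lag``, symmetric about zero, with
    zero-lag self-pairs excluded.  Fewer than 2 spikes give empty arrays
    (flagged by size 0).
    """
    if bin_width <= 0 or max_lag <= 0:
        raise ValueError("bin_width and max_lag must be positive")
    t = train.times[(train.times >= window[0]) & (train.times < window[1])]
    if t.size < 2:
        return np.empty(0), np.empty(0)
    n_bins = int(round(max_lag / bin_width))
    edges = (np.arange(-n_bins, n_bins + 1)) * bin_width
    counts = np.zeros(edges.size - 1)
    # windowed pair enumeration: only forward lags, mirrored afterwards
    for i, ti in enumerate(t[:-1]):
        diffs = t[i + 1:] - ti
        diffs = diffs[diffs < max_lag]
        if diffs.size == 0:
            continue
        counts += np.histogram(diffs, bins=edges)[0]
    counts += counts[::-1]  # add the negative lags by symmetry
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def call_unit(acg_counts: np.ndarray, acg_bin_width: float, stim_frequency: float,
              baseline: tuple[float, float], target_id: str = "",
              retina: str = "", condition: str = "") -> FollowingCall:
    """Apply the mean + 4 SD rule to the periodogram of an autocorrelogram.

    ``baseline`` should come from :func:`dark_baseline` on the spectrum of
    an equal-duration dark-segment autocorrelogram.
    """
    if acg_counts.size == 0:
        raise ValueError("empty autocorrelogram (fewer than 2 spikes)")
    spec = acg_spectrum(acg_counts, acg_bin_width)
    mean, sd = baseline
    p = spec.power_at(stim_frequency)
    return FollowingCall(target_id, "unit", float(stim_frequency), p, mean, sd,
                         positive=p > mean + 4.0 * sd,
                         retina=retina, condition=condition)


def acg_spectrum(acg_counts: np.ndarray, acg_bin_width: float) -> Spectrum:
    """Periodogram of an autocorrelogram sampled at 1/bin_width Hz."""
    if acg_counts.size == 0:
        raise ValueError("empty autocorrelogram")
    return periodogram_power(acg_counts, 1.0 / acg_bin_width)


def following_fraction(calls: Sequence[FollowingCall]) -> pd.DataFrame:
    """Percentage of positive calls per (retina, frequency, condition).

    Returns one row per retina x frequency x condition with columns
    ``n_positive``, ``n_total`` and ``percent_positive`` (100 x positive /
    total), so group-level statistics can operate on per-retina fractions.
    """
    if not calls:
        raise ValueError("no calls to aggregate")
    df = pd.DataFrame(
        [(c.retina, c.frequency_hz, c.condition, c.positive) for c in calls],
        columns=["retina", "frequency_hz", "condition", "positive"],
    )
    g = df.groupby(["retina", "frequency_hz", "condition"], dropna=False)
    out = g["positive"].agg(n_positive="sum", n_total="count").reset_index()
    out["percent_positive"] = 100.0 * out["n_positive"] / out["n_total"]
    return out
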