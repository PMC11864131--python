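"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles (plain loops, no
shared code paths with the library) so the implementation can be checked
against them.
"""

from __future__ import annotations

import numpy as np


def brute_classify(edges, rates, stim_duration, spont_mean, spont_sd,
                   on_window=0.5, off_window=(0.05, 0.3),
                   low_cutoff=10.0, sd_mult=4.0) -> str:
    """Literal re-implementation of the flash-response rules.

    A peak is the maximum smoothed rate among bins whose center falls in
    the search window; detection requires peak > spontaneous mean +
    ``sd_mult`` SD; supra-threshold peaks all below ``low_cutoff`` mean
    LOW_SIGNAL; otherwise the windows decide ON / OFF / ON_OFF.
    """
    threshold = spont_mean + sd_mult * spont_sd
    on_peak, off_peak = None, None
    for i in range(len(rates)):
        center = (edges[i] + edges[i + 1]) / 2.0
        if 0.0 <= center < on_window:
            if on_peak is None or rates[i] > on_peak:
                on_peak = rates[i]
        lo = stim_duration + off_window[0]
        hi = stim_duration + off_window[1]
        if lo <= center < hi:
            if off_peak is None or rates[i] > off_peak:
                off_peak = rates[i]
    on_pos = on_peak is not None and on_peak > threshold
    off_pos = off_peak is not None and off_peak > threshold
    if not on_pos and not off_pos:
        return "NOT_CLASSIFIED"
    supra = []
    if on_pos:
        supra.append(on_peak)
    if off_pos:
        supra.append(off_peak)
    if max(supra) < low_cutoff:
        return "LOW_SIGNAL"
    if on_pos and off_pos:
        return "ON_OFF"
    return "ON" if on_pos else "OFF"


def brute_shell_area(mask_data, pixel, levels=(1, 5, 10, 15)) -> int:
    """Area label from exhaustive Chebyshev distance to the mask foreground
    (the metric induced by a 3x3 square structuring element)."""
    seeds = np.argwhere(mask_data)
    r, c = pixel
    d = min(max(abs(int(sr) - r), abs(int(sc) - c)) for sr, sc in seeds)
    for k, lv in enumerate(levels):
        if d <= lv:
            return k + 1
    return 4


def random_psth(rng, n_pre=50, n_post=118, bin_width=0.02):
    """Randomized smoothed-PSTH fixture with occasional injected peaks."""
    edges = -n_pre * bin_width + np.arange(n_pre + n_post + 1) * bin_width
    rates = rng.uniform(0.0, 12.0, n_pre + n_post)
    centers = (edges[:-1] + edges[1:]) / 2.0
    for lo, hi in ((0.0, 0.5), (2.05, 2.3), (0.5, 2.0), (2.3, 2.36)):
        if rng.uniform() < 0.6:
            sel = np.flatnonzero((centers >= lo) & (centers < hi))
            if sel.size:
                rates[rng.choice(sel)] = rng.uniform(0.0, 80.0)
    spont_mean = rng.uniform(0.0, 10.0)
    spont_sd = rng.uniform(0.0, 4.0)
    return edges, rates, spont_mean, spont_sd
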