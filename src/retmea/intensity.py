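"""Naka-Rushton intensity-response fitting.

The saturating hyperbolic curve

    R(I) = Rmin + (Rmax - Rmin) * I^n / (I^n + I50^n)

maps flash intensity I (R*/rod/s) to the baseline-corrected peak firing
rate of an ON response.  ``I50`` is the intensity at the half-maximum
response and ``n`` the slope exponent.  Following the defining convention,
``Rmin``/``Rmax`` are fixed to the smallest/largest observed peak rates and
only ``I50`` and ``n`` are free; both are found by least squares
(multi-start Nelder-Mead over ``log10 I50`` and ``n``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "NakaRushtonFit",
    "naka_rushton",
    "fit_intensity_response",
    "half_saturation_summary",
]


@dataclass(frozen=True)
class NakaRushtonFit:
    rmin: float
    rmax: float
    i50: float
    n: float
    sse: float
    converged: bool

    def __post_init__(self) -> None:
        if self.rmin > self.rmax:
            raise ValueError("Rmin must not exceed Rmax")
        if self.i50 <= 0 or self.n <= 0:
            raise ValueError("I50 and n must be positive")

    def predict(self, intensity: float | np.ndarray) -> np.ndarray:
        return naka_rushton(intensity, self)


def naka_rushton(intensity, fit: NakaRushtonFit):
    """Evaluate the intensity-response curve at ``intensity`` (> 0)."""
    I = np.asarray(intensity, dtype=float)
    if np.any(I <= 0):
        raise ValueError("intensity must be positive (R*/rod/s)")
    # compute in log space for numerical safety at extreme n
    ratio = np.exp(fit.n * (np.log(I) - np.log(fit.i50)))
    return fit.rmin + (fit.rmax - fit.rmin) * ratio / (ratio + 1.0)


def _nr_rate(I: np.ndarray, rmin: float, rmax: float, log10_i50: float, n: float) -> np.ndarray:
    ratio = np.exp(n * np.log(10.0) * (np.log10(I) - log10_i50))
    return rmin + (rmax - rmin) * ratio / (ratio + 1.0)


def fit_intensity_response(
    series: Sequence[tuple[float, float]],
    n_bounds: tuple[float, float] = (1e-3, 10.0),
    log10_i50_margin: float = 2.0,
    n_starts: int = 7,
) -> NakaRushtonFit:
    """Least-squares fit of I50 and n to (intensity, peak rate) pairs.

    Rmin and Rmax are pinned to the smallest and largest observed peak
    rates.  The search runs over ``log10(I50)`` bounded by the stimulus
    range +/- ``log10_i50_margin`` log units and ``n`` in ``n_bounds``,
    from a coarse multi-start grid, so the result is deterministic.
    Subthreshold (0 Hz) points participate in the squared error.
    """
    arr = np.asarray(sorted(series), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (intensity, rate) pairs")
    I, R = arr[:, 0], arr[:, 1]
    if np.any(I <= 0):
        raise ValueError("intensity must be positive (R*/rod/s)")
    if len(np.unique(I)) < 3:
        raise ValueError("need at least 3 distinct intensities")

    rmin, rmax = float(R.min()), float(R.max())
    if rmax == rmin:
        # flat series: SSE is independent of (I50, n) -> degenerate
        return NakaRushtonFit(rmin, rmax, float(np.sqrt(I.min() * I.max())), 1.0,
                              0.0, converged=False)

    lo = np.log10(I.min()) - log10_i50_margin
    hi = np.log10(I.max()) + log10_i50_margin
    logI = np.log10(I)

    def sse(params) -> float:
        li50 = min(max(params[0], lo), hi)
        n = min(max(params[1], n_bounds[0]), n_bounds[1])
        ratio = np.exp(n * np.log(10.0) * (logI - li50))
        resid = rmin + (rmax - rmin) * ratio / (ratio + 1.0) - R
        return float(resid @ resid)

    # coarse deterministic grid, then Nelder-Mead polish from the best cells
    li_grid = np.linspace(lo, hi, max(n_starts, 5) * 5)
    n_grid = np.geomspace(max(n_bounds[0], 0.2), n_bounds[1], 12)
    ratio = np.exp(np.log(10.0) * n_grid[:, None, None]
                   * (logI[None, None, :] - li_grid[None, :, None]))
    pred = rmin + (rmax - rmin) * ratio / (ratio + 1.0)
    grid_sse = ((pred - R) ** 2).sum(axis=-1)
    order = np.argsort(grid_sse, axis=None)

    best = None
    for flat in order[:3]:
        ni, li = np.unravel_index(flat, grid_sse.shape)
        res = optimize.minimize(sse, x0=[li_grid[li], n_grid[ni]],
                                method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-10,
                                         "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    li50 = float(np.clip(best.x[0], lo, hi))
    n = float(np.clip(best.x[1], *n_bounds))
    return NakaRushtonFit(rmin, rmax, 10.0 ** li50, n, float(best.fun),
                          converged=bool(best.success))


def half_saturation_summary(fits_per_group: dict[str, Sequence[NakaRushtonFit]]) -> dict:
    """Per-group I50 distributions (log10 scale) and pairwise KS comparisons.

    Returns ``{"groups": {name: {"log10_i50": array, "cdf_x": ..., "cdf_y": ...}},
    "ks": {(a, b): (statistic, pvalue)}}``.  The two-sample
    Kolmogorov-Smirnov test is delegated to :func:`scipy.stats.ks_2samp`.
    """
    if len(fits_per_group) < 2:
        raise ValueError("need at least 2 groups")
    groups = {}
    for name, fits in fits_per_group.items():
        if len(fits) < 3:
            raise ValueError(f"group {name!r} needs at least 3 fits")
        vals = np.sort(np.log10([f.i50 for f in fits]))
        groups[name] = {
            "log10_i50": vals,
            "cdf_x": vals,
            "cdf_y": np.arange(1, vals.size + 1) / vals.size,
        }
    names = sorted(groups)
    ks = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            st = stats.ks_2samp(groups[a]["log10_i50"], groups[b]["log10_i50"])
            ks[(a, b)] = (float(st.statistic), float(st.pvalue))
    return {"groups": groups, "ks": ks}
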