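# Methods

This note documents the models, defaults and numerical choices behind
`retmea`, and what the synthetic-data validation does and does not show
about real recordings.

## Recording model and units

A recording is a 60-electrode planar MEA (8×8 grid minus corners, 200 µm
pitch, 30×30 µm electrodes), spike-sorted units referenced to their source
electrode, per-electrode field potentials sampled at 20 kHz, and a stimulus
protocol of non-overlapping flash/flicker epochs on the absolute
acquisition time axis (time 0 = acquisition start). Units are fixed
throughout: seconds, Hz, µm, µV, and photoisomerizations per rod per
second (R\*/rod/s) for light intensity. Spike sorting itself is out of
scope; the pipeline starts from sorted units and checks each one for a
refractory period — units with more than 2% of inter-spike intervals
under 1 ms are excluded and logged.

## Flash-response classification

PSTHs use 20-ms bins with one bin edge pinned to stimulus onset, rates
averaged across trials, then an order-4 binomial filter (1,4,6,4,1)/16.
Smoothing pads by reflection, which approximately conserves spike mass and
avoids edge dips; the raw (unsmoothed) PSTH conserves mass exactly.

The spontaneous mean and SD are computed over 20-ms bins of the last 10 s
of the longest dark interval. The detection threshold is mean + 4 SD.
The SD's bin basis is not uniquely determined by the procedure's usual
statement; binned (20-ms) dark rates were chosen and kept fixed. A
consequence worth knowing: for a unit firing at rate r in the dark, the
binned-rate SD is roughly 50·√(0.02·r) Hz, so the threshold is
conservative for tonically active units and near zero for units silent in
darkness. Low-signal cells (supra-threshold but < 10 Hz) are therefore
detectable mainly when they are nearly silent in the dark, which is how
the generator parameterizes them.

Rules, in precedence order: (1) find the maximum of the smoothed PSTH in
the ON window (0–500 ms after onset) and the OFF window (50–300 ms after
offset); a window "responds" if its peak exceeds the threshold. (2) If no
window responds → NOT_CLASSIFIED. (3) If every responding peak is below
10 Hz → LOW_SIGNAL; the cutoff is applied to the raw peak before baseline
subtraction (a config switch `low_signal_on_raw_peak=False` applies it
after, since the original wording does not fully pin this down). (4)
Otherwise ON / OFF / ON_OFF by which windows responded. Reported peak
rates subtract the dark mean and clip at zero. ON latency is the
time-to-peak from onset; OFF latency is measured from offset and not
surfaced in summary tables. "Peak" is the single window maximum — no
multi-peak logic, since flash responses are modeled (and described) as
unimodal transients.

## Intensity–response fitting

R(I) = Rmin + (Rmax − Rmin)·Iⁿ/(Iⁿ + I50ⁿ). Rmin and Rmax are the
smallest and largest observed peak rates — they are *not* free parameters
(a `fit_free_extremes`-style 4-parameter variant was deliberately not made
the default, matching the definitional reading; the series admission and
zero-convention below matter more in practice). Only log10(I50) and n are
optimized: sum of squared errors, coarse deterministic grid
(25+ log-spaced I50 cells × 12 n cells) followed by Nelder-Mead polish
from the three best cells, bounds log10(I50) within the stimulus range
± 2 log units and n ∈ (0, 10]. Subthreshold intensities contribute 0 Hz
to the series. Only units classified ON or ON-OFF enter the analysis; a
unit subthreshold at the 95.23 R\*/rod/s reference flash is admitted by
its type at the strongest flash, so insensitive (cone-remnant) cells can
still be fitted. A flat series returns a degenerate fit flagged
non-converged. Group I50 distributions are compared on the log10 scale
with `scipy.stats.ks_2samp`.

## Flicker-following detection

Electrode route: zero-phase 4th-order Butterworth low-pass at 100 Hz
(`sosfiltfilt`, so mERG latencies are not distorted), pointwise mean of
the (default three) repeats of a condition, boxcar periodogram
(`scipy.signal.periodogram`, density scaling, no detrend). The dark
baseline is the mean and SD of periodogram power over 0–30 Hz from the
1-s average dark waveform; SD is taken across frequency bins (an
across-seeds variant would need repeated dark segments the protocol may
not contain). A target is "positive" at frequency f iff the power in the
bin nearest f exceeds mean + 4 SD. Harmonics are never counted: only the
fundamental is tested.

Unit route: autocorrelogram of the spike raster within the stimulus
epochs (10-ms bins, ±1 s lags, zero-lag self-pairs excluded, symmetric),
then the periodogram of the autocorrelogram sampled at 100 Hz, with the
baseline from an equal-total-duration dark-segment autocorrelogram —
equal duration is enforced so the baseline and stimulus spectra share
their statistics. Units with fewer than two spikes in an epoch set are
excluded from the ratio and logged. Following performance is the
percentage of positive targets per frequency × condition, with
per-retina fractions kept so group comparisons use Mann–Whitney U across
retinas, not pooled counts.

Calibration: under the null (noise-only traces, unmodulated Poisson
units) the measured positive rate is ≈1% per frequency — consistent with
the ~e⁻⁵ tail of exponential periodogram power at mean+4·SD — and the
acceptance suite verifies ≤5% over 200 targets.

## Graft-area labeling

The graft footprint (binary fluorescence mask with µm/pixel metadata and
a pixel→µm affine placement) is dilated with a 3×3 square structuring
element — the Chebyshev metric in pixel space — for 1, 5, 10 and 15
iterations. The counts are read as iteration counts of that element, with
the physical scale set by the mask's pixel size (both configurable, since
the element and scale are not otherwise specified). Area 1 = within the
1-iteration shell (the graft and its border are both area 1), areas 2 and
3 = the 5- and 10-iteration shells, area 4 = the 15-iteration shell *and*
everything beyond (areas only go to 4, so 4 is the catch-all). Each
electrode maps by its center point to one mask pixel; no footprint
averaging (electrodes are 30 µm against a 200 µm pitch). Iterated
dilation is verified against an exhaustive Chebyshev-distance oracle.

## Synthetic-recording generator

Spikes are drawn from an inhomogeneous Poisson process by thinning, then
an absolute refractory period (default 1 ms) is enforced by deleting any
spike too close to its predecessor — this preserves Poisson statistics to
first order while guaranteeing ISIs pass QC. The firing rate is
spontaneous rate plus, per flash epoch, a difference-of-exponentials
transient (decay τ = 3× rise τ) at onset (ON-type components) and/or
offset (OFF components) whose peak equals the unit's own Naka–Rushton
value at that intensity and whose peak time is
latency_base + latency_slope·log10(I) (slope ≤ 0: latency shrinks with
intensity; clipped at 20 ms). During flicker the rate gains a square-wave
term (50% duty cycle, standard LED flicker practice) of amplitude
modulation-depth × Naka–Rushton peak.

Field traces are one damped monophasic wavelet (t/τ·e^(1−t/τ), τ = 20 ms
or a quarter period, whichever is smaller) per light pulse of every
entrained flicker epoch, plus white Gaussian noise (default 5 µV SD
against a 60 µV response amplitude), at 20 kHz. Non-entrained electrodes
and dark segments are noise only.

Scenario presets (defaults chosen once; the spontaneous-rate values are
assumptions, since no reference numbers are available, picked to be
physiologically plausible and to encode the directional finding that
degenerated retinas fire more in darkness):

| parameter | WT | rd1 | rd1-cone | TP-rd1 |
|---|---|---|---|---|
| non-responsive spont. rate | 1–10 Hz | 12–35 Hz | 12–35 Hz | 12–35 Hz |
| responsive spont. rate | 0.5–3 Hz | — | 0.5–3 Hz | 0.5–3 Hz |
| responsive mixture | ON .45/OFF .10/ON-OFF .25/LS .10/none .10 | all none | ON .4/ON-OFF .1/LS .2/none .3 | ON .55/OFF .05/ON-OFF .15/LS .15/none .10 |
| log10 I50 (mean ± SD) | 1.5 ± 0.35 | — | 4.5 ± 0.40 | 1.7 ± 0.40 |
| latency base | 0.12–0.25 s | — | 0.22–0.35 s | 0.22–0.35 s |
| mERG entrain prob. 5/15/20/25 Hz | .95/.90/.85/.80 | 0 | 0 | .55/.20/.10/.05 |
| unit modulation 5/15/20/25 Hz | .9/.8/.7/.6 | 0 | 0 | .6/0/0/0 |

In TP-rd1, responsive phenotypes are placed only on electrodes within
40 µm of the graft disk (default radius 300 µm, centered), so ground-truth
responsive units fall in areas 1–2; everything else is rd1-like.
Response-type mixtures loosely follow the observed WT and graft-area
proportions but are configuration, not claims. Low-signal units are
generated nearly silent in darkness (spont < 0.02 Hz, peaks 4–8 Hz) —
see the threshold discussion above for why that is the regime in which
the class is well defined.

Ground truth records every unit's phenotype, every electrode's
geometrically constructed area label (chessboard distance transform,
independent of the iterated-dilation code path) and per-frequency
entrainment flags.

What the generator does **not** emulate: rd1 oscillatory network activity,
photoreceptor biophysics and adaptation, spatially structured stimuli or
receptive fields, spike-sorting errors, electrode drift, correlated noise
across electrodes, or realistic fluorescence images (the mask is a binary
disk). Passing tests therefore show the analysis chain is correct and
calibrated under its stated assumptions — not that those assumptions hold
for any particular preparation.

## Problem sizes and determinism

Default validation sizes: classifier rule-equivalence on 1,000 randomized
PSTHs; type recovery on 200 high-SNR units with 20 flash trials; I50
recovery on 20 noise-free and 100 Poisson-noise series (20 trials per
intensity, 6 intensities); flicker calibration on 200 null and 100
entrained targets (3 repeats per condition); scenario contrasts on single
60-electrode recordings per group with 3 flash repeats. These sizes give
stable statistics while keeping the whole suite runnable on a laptop.
All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds reproduce recordings
bit-for-bit, including after serialization (fixed key order and float
formatting in the container writer).

## Known limitations

* The mean+4SD threshold's dependence on the dark-rate bin width means
  classification sensitivity varies with spontaneous rate; comparisons
  across groups with very different dark rates inherit that asymmetry.
* `Rmin`/`Rmax` pinned to observed extremes biases I50 slightly when the
  series does not reach saturation; the Poisson-noise recovery error
  (median ≈ 0.1 log10 units at default sizes) includes this effect.
* Area labels depend on the user-supplied mask-to-grid transform; no
  registration is estimated.
* The flicker statistic tests only the fundamental; responses that
  frequency-double (e.g. ON-OFF units under square-wave flicker) could be
  under-called by design.
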