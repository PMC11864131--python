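"""End-to-end orchestration: simulate -> analyze -> report.

Each stage is a plain function over library objects; the CLI wraps these
with config-file parsing and exit codes.  Analysis outputs are pandas
DataFrames written as CSV; a JSON run manifest snapshots the config, seed
and stage status so a run can be re-executed deterministically.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .areas import assign_areas
from .core import Recording, StimulusProtocol, Epoch
from .flicker import (
    FollowingCall,
    acg_spectrum,
    call_electrode,
    call_unit,
    dark_baseline,
    following_fraction,
    lowpass_and_average,
    periodogram_power,
    spike_acg,
)
from .intensity import fit_intensity_response
from .io import refractory_qc, validate_recording, write_recording
from .psth import (
    AnalysisConfig,
    classify_unit,
    compute_psth,
    intensity_series,
    smooth_binomial,
    spontaneous_rate,
)
from .synth import GroundTruth, ScenarioConfig, make_protocol, simulate_recording
from .core import FieldTrace

log = logging.getLogger("retmea")

__all__ = [
    "RunManifest",
    "AnalysisResult",
    "default_flash_intensities",
    "build_protocol",
    "run_simulate",
    "run_analyze",
    "run_report",
]

#: log-spaced flash series bracketing the canonical 95.23 R*/rod/s flash
DEFAULT_FLASH_INTENSITIES = (1.0, 10.0, 95.23, 1000.0, 10000.0, 100000.0)
DEFAULT_FLICKER_INTENSITY = 95.23
REFERENCE_FLASH_INTENSITY = 95.23
REFRACTORY_QC_CUTOFF = 0.02  # fraction of ISIs < 1 ms that excludes a unit


def default_flash_intensities() -> tuple[float, ...]:
    return DEFAULT_FLASH_INTENSITIES


@dataclass
class RunManifest:
    """Reproducibility record written next to each stage's outputs."""

    stage: str
    seed: int
    config: dict
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    status: str = "pending"
    started: str = ""
    finished: str = ""
    version: str = __version__

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def combine_protocols(first: StimulusProtocol,
                      second: StimulusProtocol) -> StimulusProtocol:
    """Concatenate two protocols on one time axis (second is shifted)."""
    shift = first.duration
    shifted = tuple(
        Epoch(e.kind, e.onset + shift, e.offset + shift, e.intensity,
              e.background, e.frequency_hz, e.repeat_index)
        for e in second
    )
    return StimulusProtocol(first.epochs + shifted, shift + second.duration)


def build_protocol(flash_intensities=DEFAULT_FLASH_INTENSITIES,
                   flash_repeats: int = 1,
                   flicker_intensities=(DEFAULT_FLICKER_INTENSITY,),
                   flicker_frequencies=(5.0, 15.0, 20.0, 25.0),
                   flicker_repeats: int = 3,
                   background: float = 0.0,
                   initial_dark: float = 12.0) -> StimulusProtocol:
    """Default combined protocol: >= 10 s of initial darkness (for the
    spontaneous-rate window), then a flash intensity series, then a flicker
    series, with >= 5 s of background before every epoch."""
    parts = [StimulusProtocol((), initial_dark)] if initial_dark > 0 else []
    if flash_intensities:
        parts.append(make_protocol("flash_series", list(flash_intensities),
                                   background, repeats=flash_repeats))
    if flicker_intensities and flicker_frequencies:
        parts.append(make_protocol("flicker_series", list(flicker_intensities),
                                   background, list(flicker_frequencies),
                                   repeats=flicker_repeats))
    if not parts:
        raise ValueError("protocol needs at least one stimulus block")
    proto = parts[0]
    for p in parts[1:]:
        proto = combine_protocols(proto, p)
    return proto


@dataclass
class AnalysisResult:
    """All per-recording analysis tables."""

    classifications: pd.DataFrame  # one row per unit x intensity
    unit_summary: pd.DataFrame     # one row per unit (reference-flash type, fit)
    fits: pd.DataFrame             # Naka-Rushton parameters per admitted unit
    flicker_calls: pd.DataFrame    # electrode + unit following calls
    fractions: pd.DataFrame        # percent positive per kind x freq x condition
    areas: pd.DataFrame            # electrode_id, area (0 when no mask)
    qc: pd.DataFrame               # unit_id, refractory violation fraction, excluded

    def write(self, out_dir: Path) -> list[str]:
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in ("classifications", "unit_summary", "fits",
                     "flicker_calls", "fractions", "areas", "qc"):
            p = out_dir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            written.append(str(p))
        return written


# ---------------------------------------------------------------------------
# simulate


def run_simulate(config: ScenarioConfig, protocol: StimulusProtocol | None,
                 out_dir: str | Path) -> tuple[Recording, GroundTruth]:
    """Generate a recording and write container + ground truth + manifest."""
    out = Path(out_dir)
    protocol = protocol or build_protocol()
    manifest = RunManifest("simulate", config.seed,
                           {"scenario": config.scenario,
                            "n_units_per_electrode": config.n_units_per_electrode},
                           started=_now())
    rec, gt = simulate_recording(config, protocol)
    write_recording(rec, out / "recording")
    gt.units.to_csv(out / "ground_truth_units.csv", index=False)
    gt.electrodes.to_csv(out / "ground_truth_electrodes.csv", index=False)
    manifest.outputs = [str(out / "recording"),
                        str(out / "ground_truth_units.csv"),
                        str(out / "ground_truth_electrodes.csv")]
    manifest.status, manifest.finished = "done", _now()
    manifest.write(out / "manifest_simulate.json")
    return rec, gt


# ---------------------------------------------------------------------------
# analyze


def _dark_interval(rec: Recording, min_len: float) -> tuple[float, float]:
    ivals = rec.protocol.dark_intervals(min_length=min_len)
    if not ivals:
        raise ValueError(f"no dark interval of >= {min_len} s in the protocol")
    return max(ivals, key=lambda ab: ab[1] - ab[0])


def _classify_all(rec: Recording, cfg: AnalysisConfig,
                  keep: set[str]) -> tuple[pd.DataFrame, dict[str, list]]:
    """Classify every kept unit at every flash intensity."""
    flash = rec.protocol.flash_epochs()
    by_intensity: dict[float, list] = {}
    for e in flash:
        by_intensity.setdefault(e.intensity, []).append(e)
    dark = _dark_interval(rec, cfg.spontaneous_window)

    rows, per_unit = [], {}
    for st in rec.spike_trains:
        if st.unit_id not in keep:
            continue
        sm, sd = spontaneous_rate(st, dark, cfg)
        per_unit[st.unit_id] = []
        for inten in sorted(by_intensity):
            eps = by_intensity[inten]
            stim_dur = eps[0].duration
            psth = compute_psth(st, eps, (1.0, stim_dur + cfg.off_window[1] + 0.05),
                                cfg)
            c = classify_unit(smooth_binomial(psth, cfg.binomial_order), eps[0],
                              sm, sd, cfg, unit_id=st.unit_id)
            per_unit[st.unit_id].append(c)
            rows.append({
                "unit_id": st.unit_id, "electrode_id": st.electrode_id,
                "intensity": inten, "type": c.response_type,
                "spont_hz": c.spont_rate, "threshold_hz": c.threshold,
                "peak_hz": c.peak_rate, "on_peak_hz": c.on_peak_rate,
                "latency_s": np.nan if c.latency is None else c.latency,
            })
    return pd.DataFrame(rows), per_unit


def _reference_type(classifs: list, reference: float) -> tuple[str, object]:
    """Unit type from the flash nearest (in log intensity) the reference."""
    c = min(classifs, key=lambda c: abs(np.log10(c.intensity / reference)))
    return c.response_type, c


def _electrode_flicker_calls(rec: Recording, retina: str) -> list[FollowingCall]:
    calls: list[FollowingCall] = []
    if not rec.field_traces:
        return calls
    fs = rec.field_traces[0].sampling_rate
    flick = rec.protocol.flicker_epochs()
    if not flick:
        return calls
    # three 1-s dark snippets from the longest dark interval -> baseline
    d0, d1 = _dark_interval(rec, 3.0)
    dark_starts = [d1 - 3.0, d1 - 2.0, d1 - 1.0]
    conditions: dict[tuple, list] = {}
    for e in flick:
        conditions.setdefault((e.intensity, e.background, e.frequency_hz),
                              []).append(e)
    for tr in rec.field_traces:
        def seg(t0: float, t1: float) -> FieldTrace:
            return FieldTrace(tr.electrode_id,
                              tr.samples_uv[int(t0 * fs):int(t1 * fs)], fs)
        dark_avg = lowpass_and_average([seg(s, s + 1.0) for s in dark_starts])
        base = dark_baseline(dark_avg)
        for (inten, bg, freq), eps in sorted(conditions.items()):
            avg = lowpass_and_average([seg(e.onset, e.offset) for e in eps])
            spec = periodogram_power(avg)
            calls.append(call_electrode(
                spec, freq, base, target_id=f"e{tr.electrode_id}",
                retina=retina, condition=f"{inten:g}@{bg:g}"))
    return calls


def _unit_flicker_calls(rec: Recording, keep: set[str],
                        retina: str) -> list[FollowingCall]:
    calls: list[FollowingCall] = []
    flick = rec.protocol.flicker_epochs()
    if not flick:
        return calls
    conditions: dict[tuple, list] = {}
    for e in flick:
        conditions.setdefault((e.intensity, e.background, e.frequency_hz),
                              []).append(e)
    epoch_dur = flick[0].duration
    d0, d1 = _dark_interval(rec, epoch_dur * 3)
    for st in rec.spike_trains:
        if st.unit_id not in keep:
            continue
        for (inten, bg, freq), eps in sorted(conditions.items()):
            stim_counts = None
            for e in eps:
                _, c = spike_acg(st, (e.onset, e.offset))
                if c.size:
                    stim_counts = c if stim_counts is None else stim_counts + c
            # dark ACG over segments matching the stimulus total duration
            dark_counts = None
            for k in range(len(eps)):
                t1 = d1 - k * epoch_dur
                _, c = spike_acg(st, (t1 - epoch_dur, t1))
                if c.size:
                    dark_counts = c if dark_counts is None else dark_counts + c
            if stim_counts is None or dark_counts is None:
                log.info("unit %s excluded from flicker ratio at %g Hz "
                         "(empty autocorrelogram)", st.unit_id, freq)
                continue
            base = dark_baseline(acg_spectrum(dark_counts, 0.010))
            calls.append(call_unit(stim_counts, 0.010, freq, base,
                                   target_id=st.unit_id, retina=retina,
                                   condition=f"{inten:g}@{bg:g}"))
    return calls


def run_analyze(rec: Recording, out_dir: str | Path | None = None,
                cfg: AnalysisConfig | None = None,
                retina: str = "r0") -> AnalysisResult:
    """Full analysis of one recording: QC, areas, classification, fits,
    flicker following.  Raises ValueError when the container is invalid."""
    cfg = cfg or AnalysisConfig()
    violations = validate_recording(rec)
    if violations:
        raise ValueError("invalid recording: " +
                         "; ".join(f"{v.kind}({v.target})" for v in violations))
    if not rec.spike_trains and not rec.field_traces:
        raise ValueError("empty recording: no units and no field traces")

    qc_rows = []
    keep: set[str] = set()
    for st in rec.spike_trains:
        frac = refractory_qc(st)
        excluded = frac > REFRACTORY_QC_CUTOFF
        if excluded:
            log.warning("unit %s excluded by refractory QC (%.3f)", st.unit_id, frac)
        else:
            keep.add(st.unit_id)
        qc_rows.append({"unit_id": st.unit_id, "refractory_fraction": frac,
                        "excluded": excluded})
    qc = pd.DataFrame(qc_rows)

    if rec.mask is not None:
        asg = assign_areas(rec.mask, rec.grid)
        areas = pd.DataFrame(sorted(asg.areas.items()),
                             columns=["electrode_id", "area"])
    else:
        areas = pd.DataFrame({"electrode_id": list(rec.grid.ids), "area": 0})
    area_of = dict(zip(areas["electrode_id"], areas["area"]))

    has_flash = bool(rec.protocol.flash_epochs())
    if has_flash and rec.spike_trains:
        classifications, per_unit = _classify_all(rec, cfg, keep)
    else:
        classifications, per_unit = pd.DataFrame(
            columns=["unit_id", "electrode_id", "intensity", "type", "spont_hz",
                     "threshold_hz", "peak_hz", "on_peak_hz", "latency_s"]), {}

    summary_rows, fit_rows = [], []
    for st in rec.spike_trains:
        if st.unit_id not in per_unit:
            continue
        classifs = per_unit[st.unit_id]
        utype, ref = _reference_type(classifs, REFERENCE_FLASH_INTENSITY)
        row = {"unit_id": st.unit_id, "electrode_id": st.electrode_id,
               "area": area_of.get(st.electrode_id, 0), "type": utype,
               "spont_hz": ref.spont_rate, "threshold_hz": ref.threshold,
               "peak_hz": ref.peak_rate,
               "latency_s": np.nan if ref.latency is None else ref.latency}
        # admission to the ON intensity-response series: a unit that is
        # subthreshold at the reference flash may still respond (ON/ON-OFF)
        # to stronger light, so fall back to the strongest flash's type
        series_type = utype
        if series_type not in ("ON", "ON_OFF"):
            series_type = max(classifs, key=lambda c: c.intensity).response_type
        series = intensity_series(classifs, unit_type=series_type)
        if len({i for i, _ in series}) >= 3 and any(r > 0 for _, r in series):
            fit = fit_intensity_response(series)
            fit_rows.append({"unit_id": st.unit_id, "rmin": fit.rmin,
                             "rmax": fit.rmax, "i50": fit.i50, "n": fit.n,
                             "sse": fit.sse, "converged": fit.converged,
                             "area": row["area"], "type": utype})
            row.update(i50=fit.i50, n=fit.n)
        summary_rows.append(row)
    unit_summary = pd.DataFrame(
        summary_rows,
        columns=["unit_id", "electrode_id", "area", "type", "spont_hz",
                 "threshold_hz", "peak_hz", "latency_s", "i50", "n"],
    ) if not summary_rows else pd.DataFrame(summary_rows)
    fits = pd.DataFrame(fit_rows, columns=["unit_id", "rmin", "rmax", "i50",
                                           "n", "sse", "converged", "area",
                                           "type"])

    e_calls = _electrode_flicker_calls(rec, retina)
    u_calls = _unit_flicker_calls(rec, keep, retina)
    flicker_calls = pd.DataFrame(
        [{"target_id": c.target_id, "kind": c.kind, "retina": c.retina,
          "frequency_hz": c.frequency_hz, "condition": c.condition,
          "power": c.power, "threshold": c.threshold,
          "verdict": "positive" if c.positive else "negative"}
         for c in e_calls + u_calls])

    frac_frames = []
    for kind, cs in (("electrode", e_calls), ("unit", u_calls)):
        if cs:
            f = following_fraction(cs)
            f.insert(0, "kind", kind)
            frac_frames.append(f)
    fractions = pd.concat(frac_frames, ignore_index=True) if frac_frames else \
        pd.DataFrame(columns=["kind", "retina", "frequency_hz", "condition",
                              "n_positive", "n_total", "percent_positive"])

    result = AnalysisResult(classifications, unit_summary, fits, flicker_calls,
                            fractions, areas, qc)
    if out_dir is not None:
        out = Path(out_dir)
        written = result.write(out)
        m = RunManifest("analyze", int(rec.metadata.get("seed", 0)),
                        {"retina": retina}, outputs=written,
                        status="done", started=_now(), finished=_now())
        m.write(out / "manifest_analyze.json")
    return result


# ---------------------------------------------------------------------------
# report


def run_report(groups: dict[str, list[AnalysisResult]],
               out_dir: str | Path | None = None,
               bonferroni: bool = False) -> dict[str, pd.DataFrame]:
    """Group comparison tables across >= 2 analyzed groups.

    * per-intensity latency and ON-peak comparisons (Mann-Whitney U),
    * I50 cumulative-distribution comparison (two-sample KS),
    * following-fraction comparison per kind x frequency x condition
      (Mann-Whitney U across per-retina fractions).

    Raw p-values are reported; a Bonferroni column is optional extra.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    names = sorted(groups)

    def _concat(attr: str, name: str) -> pd.DataFrame:
        frames = [getattr(r, attr) for r in groups[name]]
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    lat_rows, peak_rows = [], []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ca, cb = _concat("classifications", a), _concat("classifications", b)
            if len(ca) == 0 or len(cb) == 0:
                continue
            for inten in sorted(set(ca["intensity"]) & set(cb["intensity"])):
                for rows, col in ((lat_rows, "latency_s"), (peak_rows, "on_peak_hz")):
                    on_a = ca[(ca.intensity == inten) &
                              ca.type.isin(["ON", "ON_OFF"])][col].dropna()
                    on_b = cb[(cb.intensity == inten) &
                              cb.type.isin(["ON", "ON_OFF"])][col].dropna()
                    if len(on_a) and len(on_b):
                        u = stats.mannwhitneyu(on_a, on_b, alternative="two-sided")
                        rows.append({"group_a": a, "group_b": b,
                                     "intensity": inten, "n_a": len(on_a),
                                     "n_b": len(on_b),
                                     "median_a": float(on_a.median()),
                                     "median_b": float(on_b.median()),
                                     "statistic": float(u.statistic),
                                     "p_value": float(u.pvalue)})
                    else:
                        rows.append({"group_a": a, "group_b": b,
                                     "intensity": inten, "n_a": len(on_a),
                                     "n_b": len(on_b), "median_a": np.nan,
                                     "median_b": np.nan, "statistic": np.nan,
                                     "p_value": np.nan})

    ks_rows = []
    fits_by = {n: _concat("fits", n) for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            fa, fb = fits_by[a], fits_by[b]
            if len(fa) >= 3 and len(fb) >= 3:
                st = stats.ks_2samp(np.log10(fa["i50"]), np.log10(fb["i50"]))
                ks_rows.append({"group_a": a, "group_b": b, "n_a": len(fa),
                                "n_b": len(fb),
                                "median_log10_i50_a": float(np.log10(fa['i50']).median()),
                                "median_log10_i50_b": float(np.log10(fb['i50']).median()),
                                "ks_statistic": float(st.statistic),
                                "p_value": float(st.pvalue)})
            else:
                ks_rows.append({"group_a": a, "group_b": b, "n_a": len(fa),
                                "n_b": len(fb), "median_log10_i50_a": np.nan,
                                "median_log10_i50_b": np.nan,
                                "ks_statistic": np.nan, "p_value": np.nan})

    ff_rows = []
    frac_by = {n: _concat("fractions", n) for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            fa, fb = frac_by[a], frac_by[b]
            if len(fa) == 0 or len(fb) == 0:
                continue
            keys = ["kind", "frequency_hz", "condition"]
            common = set(map(tuple, fa[keys].drop_duplicates().values)) & \
                set(map(tuple, fb[keys].drop_duplicates().values))
            for kind, freq, cond in sorted(common):
                va = fa[(fa.kind == kind) & (fa.frequency_hz == freq) &
                        (fa.condition == cond)]["percent_positive"]
                vb = fb[(fb.kind == kind) & (fb.frequency_hz == freq) &
                        (fb.condition == cond)]["percent_positive"]
                if len(va) and len(vb):
                    if va.nunique() == 1 and vb.nunique() == 1 and \
                            va.iloc[0] == vb.iloc[0]:
                        u_stat, p = np.nan, 1.0
                    else:
                        u = stats.mannwhitneyu(va, vb, alternative="two-sided")
                        u_stat, p = float(u.statistic), float(u.pvalue)
                    ff_rows.append({"group_a": a, "group_b": b, "kind": kind,
                                    "frequency_hz": freq, "condition": cond,
                                    "mean_pct_a": float(va.mean()),
                                    "mean_pct_b": float(vb.mean()),
                                    "n_retinas_a": len(va), "n_retinas_b": len(vb),
                                    "statistic": u_stat, "p_value": p})

    tables = {
        "latency_comparison": pd.DataFrame(lat_rows),
        "peak_comparison": pd.DataFrame(peak_rows),
        "i50_ks": pd.DataFrame(ks_rows),
        "following_comparison": pd.DataFrame(ff_rows),
    }
    if bonferroni:
        for t in tables.values():
            if "p_value" in t.columns and len(t):
                m = t["p_value"].notna().sum()
                t["p_bonferroni"] = np.minimum(t["p_value"] * max(m, 1), 1.0)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, t in tables.items():
            t.to_csv(out / f"{name}.csv", index=False)
        RunManifest("report", 0, {"groups": names},
                    outputs=[str(out / f"{n}.csv") for n in tables],
                    status="done", started=_now(), finished=_now()
                    ).write(out / "manifest_report.json")
    return tables
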