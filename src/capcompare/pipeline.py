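"""End-to-end orchestration: simulate (or load) sessions, run the
preprocessing chain, the resting-state, blink and evoked analyses, and
assemble the gel-vs-dry comparison report.

Every computation lives in the topic modules; this module only wires them
together and defines the on-disk stage layout used by the CLI and the
analysis scripts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import evoked as evk
from . import preprocess as pre
from . import spectral as spc
from .montage import ElectrodeLayout, LayoutKind, builtin_layout, combined_layout
from .synthdata import (
    CapType,
    CohortResult,
    SegmentKind,
    SessionRecording,
    SimulationConfig,
    SubjectMetadata,
    simulate_cohort,
)

__all__ = [
    "PipelineConfig",
    "SessionAnalysis",
    "analyze_session",
    "analyze_cohort",
    "compare_cohort",
    "run_study",
    "mirror_cohort",
    "frontal_pair",
]

FRONTAL_PAIRS = {
    LayoutKind.TEN_TWENTY: ("Fp1", "Fp2"),
    LayoutKind.EQUIDISTANT: ("1L", "1R"),
}


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the analysis chain, grouped by stage."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: pre.FilterSpec = field(default_factory=pre.FilterSpec)
    badchan: pre.BadChannelParams = field(default_factory=pre.BadChannelParams)
    spline_order_m: int = 4
    spline_n_terms: int = 50
    spline_regularization: float = 1e-6
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    psd_window_s: float = 30.0
    vep_reject_ptp: float = 150.0
    peak_windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(evk.DEFAULT_PEAK_WINDOWS)
    )

    @classmethod
    def desk_scale(cls, n_subjects: int = 10, seed: int = 0, **sim_overrides) -> "PipelineConfig":
        """Desk-scale preset: short segments and a matching analysis window."""
        from .synthdata import short_config

        return cls(
            simulation=short_config(n_subjects=n_subjects, seed=seed, **sim_overrides),
            psd_window_s=10.0,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["bad_channel_prob"] = dict(d["simulation"]["bad_channel_prob"])
        d["simulation"]["impedance_params"] = {
            k: list(v) for k, v in d["simulation"]["impedance_params"].items()
        }
        d["peak_windows"] = {k: list(v) for k, v in d["peak_windows"].items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            sim = dict(d["simulation"])
            if "impedance_params" in sim:
                sim["impedance_params"] = {k: tuple(v) for k, v in sim["impedance_params"].items()}
            d["simulation"] = SimulationConfig(**sim)
        if "filters" in d:
            f = dict(d["filters"])
            if "band" in f:
                f["band"] = tuple(f["band"])
            d["filters"] = pre.FilterSpec(**f)
        if "badchan" in d:
            d["badchan"] = pre.BadChannelParams(**d["badchan"])
        if "peak_windows" in d:
            d["peak_windows"] = {k: tuple(v) for k, v in d["peak_windows"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def digest(self) -> str:
        return cmp.config_digest(self.to_dict())


@dataclass
class SessionAnalysis:
    """All derived outputs of one cap application."""

    subject_id: str
    cap_type: CapType
    layout_kind: LayoutKind
    ratings: dict  # segment kind -> list[ChannelRating]
    alpha_open: spc.BandPower
    alpha_closed: spc.BandPower
    psd_closed: spc.PsdResult
    blink_overlays: dict  # "2s"/"10s" -> EvokedWaveform (combined montage)
    vep_evoked: evk.EvokedWaveform
    vep_gfp: evk.GfpSeries
    vep_peaks: dict  # "N75"/"P100" -> ComponentPeak

    @property
    def alpha_power_scalar(self) -> float:
        """Across-channel mean alpha power with eyes closed (one per session)."""
        return float(self.alpha_closed.mean_power.mean())


def standard_combined() -> ElectrodeLayout:
    """The 128-site union of the two built-in 64-channel layouts."""
    return combined_layout(
        builtin_layout(LayoutKind.TEN_TWENTY), builtin_layout(LayoutKind.EQUIDISTANT)
    )


def frontal_pair(layout_kind: LayoutKind) -> tuple[str, str]:
    return FRONTAL_PAIRS[layout_kind]


def analyze_session(recording: SessionRecording, config: PipelineConfig) -> SessionAnalysis:
    """Run the full preprocessing + analysis chain on one session."""
    fs = recording.sampling_rate
    combined = standard_combined()
    filtered = pre.apply_filters(recording, config.filters)

    ratings: dict[str, list[pre.ChannelRating]] = {}
    combined_segments: dict[str, np.ndarray] = {}
    for seg in filtered.segments:
        data = filtered.segment_data(seg.kind)
        exclude = None
        offset = 0.0
        if seg.trigger_times and seg.kind is SegmentKind.BLINK:
            # center each cued blink in a single rating window and skip it
            exclude = [(t - seg.start - 0.3, t - seg.start + 0.3) for t in seg.trigger_times]
            first = seg.trigger_times[0] - seg.start
            offset = (first - config.badchan.window_s / 2.0) % config.badchan.window_s
        segment_ratings = pre.rate_channels(
            data, fs, labels=recording.layout.labels, params=config.badchan,
            exclude_spans=exclude, window_offset_s=offset,
        )
        ratings[seg.kind.value] = segment_ratings
        bad = [r.channel for r in segment_ratings if r.verdict is pre.Verdict.BAD]
        comb = pre.to_combined(
            data, recording.layout, bad, combined,
            order_m=config.spline_order_m,
            n_terms=config.spline_n_terms,
            regularization=config.spline_regularization,
        )
        combined_segments[seg.kind.value] = pre.common_average_reference(comb)

    # resting state: centered window -> Welch -> alpha band
    def _alpha(kind: SegmentKind) -> tuple[spc.PsdResult, spc.BandPower]:
        win = spc.extract_center_window(
            combined_segments[kind.value], fs, config.psd_window_s
        )
        psd = spc.welch_psd(win, fs, config.welch_window_s, config.welch_overlap)
        return psd, spc.alpha_band_power(psd)

    _, band_open = _alpha(SegmentKind.EYES_OPEN)
    psd_closed, band_closed = _alpha(SegmentKind.EYES_CLOSED)

    # blink overlays on the combined montage
    blink_seg = recording.segment(SegmentKind.BLINK)
    rel_triggers = [t - blink_seg.start for t in blink_seg.trigger_times]
    overlays = evk.blink_overlays(
        combined_segments[SegmentKind.BLINK.value], fs, rel_triggers
    )

    # visual evoked response
    vep_seg = recording.segment(SegmentKind.VEP)
    rel_vep = [t - vep_seg.start for t in vep_seg.trigger_times]
    epochs = evk.epoch(combined_segments[SegmentKind.VEP.value], fs, rel_vep)
    epochs = evk.reject_trials(epochs, config.vep_reject_ptp)
    vep_evoked = evk.average(epochs)
    vep_gfp = evk.gfp_t(vep_evoked)
    peaks = {p.name.value: p for p in evk.find_peaks(vep_gfp, dict(config.peak_windows))}

    return SessionAnalysis(
        subject_id=recording.subject_id,
        cap_type=recording.cap_type,
        layout_kind=recording.layout.kind,
        ratings=ratings,
        alpha_open=band_open,
        alpha_closed=band_closed,
        psd_closed=psd_closed,
        blink_overlays=overlays,
        vep_evoked=vep_evoked,
        vep_gfp=vep_gfp,
        vep_peaks=peaks,
    )


def analyze_cohort(
    cohort: CohortResult, config: PipelineConfig
) -> list[tuple[SessionAnalysis, SessionAnalysis]]:
    """Analyze every (gel, dry) session pair."""
    return [
        (analyze_session(gel, config), analyze_session(dry, config))
        for gel, dry in cohort.sessions
    ]


def _align_all(
    pairs: Sequence[tuple[SessionAnalysis, SessionAnalysis]]
) -> list[tuple[SessionAnalysis, SessionAnalysis]]:
    """Shift every session's evoked response to the grand-average N75 latency."""
    lats = [a.vep_peaks["N75"].latency for pair in pairs for a in pair]
    reference = float(np.mean(lats))
    out = []
    for pair in pairs:
        aligned_pair = []
        for a in pair:
            ev = evk.align_latency(a.vep_evoked, a.vep_peaks["N75"].latency, reference)
            gfp = evk.gfp_t(ev)
            aligned_pair.append(dataclasses.replace(a, vep_evoked=ev, vep_gfp=gfp))
        out.append(tuple(aligned_pair))
    return out


def compare_cohort(
    pairs: Sequence[tuple[SessionAnalysis, SessionAnalysis]],
    metadata: Sequence[SubjectMetadata],
    metadata_table: pd.DataFrame,
    config: PipelineConfig,
) -> cmp.StudyReport:
    """Build the full study report from per-session analyses and metadata."""
    if not pairs:
        raise cmp.IncompleteReportError("missing stage outputs: ['analyses']")
    pairs = _align_all(pairs)
    combined = standard_combined()

    # --- reliability ------------------------------------------------------
    rating_records = []
    for gel, dry in pairs:
        for a in (gel, dry):
            for seg_kind, ratings in a.ratings.items():
                for r in ratings:
                    rating_records.append(
                        (a.cap_type.value, a.layout_kind.value, seg_kind, r)
                    )
    reliability = cmp.channel_reliability(rating_records)
    rel_summary = reliability.group_summary()

    def _aggregations(cap: str) -> dict:
        sub = reliability.table[reliability.table["cap"] == cap]
        per_layout = sub.groupby("layout")["reliability"].mean()
        return {
            "over_channels": float(sub["reliability"].mean()),
            "over_layouts": float(per_layout.mean()),
            "over_ratings": float(sub["n_good"].sum() / sub["n_total"].sum()),
        }

    reliability_section = {
        "per_channel": reliability.table,
        "group_summary": rel_summary,
        "grand": {cap: _aggregations(cap) for cap in ("gel", "dry")},
    }

    # --- per-subject agreement metrics -----------------------------------
    rows = []
    for gel, dry in pairs:
        subj = gel.subject_id
        # blink overlay at the native frontal pair, 2-s window
        pair_gel = frontal_pair(gel.layout_kind)
        pair_dry = frontal_pair(dry.layout_kind)
        w_gel = _pair_mean(gel.blink_overlays["2s"], combined, pair_gel)
        w_dry = _pair_mean(dry.blink_overlays["2s"], combined, pair_dry)
        rows.append(_metric_row(subj, "blink_2s", gel.layout_kind, dry.layout_kind, w_gel, w_dry))
        # eyes-closed PSD over all combined channels
        rows.append(
            _metric_row(
                subj, "psd_eyes_closed", gel.layout_kind, dry.layout_kind,
                gel.psd_closed.power.ravel(), dry.psd_closed.power.ravel(),
            )
        )
        # VEP: all channels, and GFPt
        rows.append(
            _metric_row(
                subj, "vep_channels", gel.layout_kind, dry.layout_kind,
                gel.vep_evoked.mean.ravel(), dry.vep_evoked.mean.ravel(),
            )
        )
        rows.append(
            _metric_row(
                subj, "vep_gfp", gel.layout_kind, dry.layout_kind,
                gel.vep_gfp.gfp, dry.vep_gfp.gfp,
            )
        )
    metrics = pd.DataFrame(rows)
    metrics_summary = (
        metrics.groupby("metric")[["pearson_r", "rmsd"]].agg(["mean", "std"])
    )
    metrics_summary.columns = ["_".join(c) for c in metrics_summary.columns]
    metrics_summary = metrics_summary.reset_index()

    # --- distributional tests ---------------------------------------------
    samples = {
        "alpha_power": (
            [g.alpha_power_scalar for g, _ in pairs],
            [d.alpha_power_scalar for _, d in pairs],
        ),
        "n75_amplitude": (
            [g.vep_peaks["N75"].amplitude for g, _ in pairs],
            [d.vep_peaks["N75"].amplitude for _, d in pairs],
        ),
        "p100_amplitude": (
            [g.vep_peaks["P100"].amplitude for g, _ in pairs],
            [d.vep_peaks["P100"].amplitude for _, d in pairs],
        ),
        "n75_latency": (
            [g.vep_peaks["N75"].latency for g, _ in pairs],
            [d.vep_peaks["N75"].latency for _, d in pairs],
        ),
        "p100_latency": (
            [g.vep_peaks["P100"].latency for g, _ in pairs],
            [d.vep_peaks["P100"].latency for _, d in pairs],
        ),
    }
    test_results: dict[str, dict] = {}
    for name, (sample_gel, sample_dry) in samples.items():
        entry: dict = {}
        u = cmp.mann_whitney_u(np.array(sample_gel), np.array(sample_dry))
        entry["mann_whitney_u"] = {
            "statistic": u.statistic, "p_value": u.p_value, "decision": u.decision,
        }
        pooled = np.array(sample_gel + sample_dry)
        if pooled.size >= 8 and np.ptp(pooled) > 0:
            ks = cmp.ks_normality(pooled)
            entry["ks_normality"] = {
                "statistic": ks.statistic, "p_value": ks.p_value, "decision": ks.decision,
            }
        test_results[name] = entry

    # --- metadata / impedance ---------------------------------------------
    meta_summary = cmp.metadata_summary(metadata_table)
    impedance = cmp.impedance_summary(metadata)

    sections = {
        "metadata_summary": meta_summary,
        "reliability": reliability_section,
        "impedance": impedance,
        "comparison_metrics": metrics,
        "comparison_summary": metrics_summary,
        "test_results": test_results,
        "vep_grand_average": _vep_grand_average(pairs),
    }
    return cmp.build_report(sections, config.digest, config.simulation.seed)


def _pair_mean(overlay: evk.EvokedWaveform, combined: ElectrodeLayout,
               labels: tuple[str, str]) -> np.ndarray:
    idx = [combined.index_of(l) for l in labels]
    return overlay.mean[idx].mean(axis=0)


def _metric_row(subject, metric, kind_gel, kind_dry, x, y) -> dict:
    return {
        "subject": subject,
        "metric": metric,
        "layout_gel": kind_gel.value,
        "layout_dry": kind_dry.value,
        "pearson_r": cmp.pearson_r(x, y),
        "rmsd": cmp.rmsd(x, y),
    }


def _vep_grand_average(pairs) -> dict:
    """Grand-average GFPt peaks per cap, after latency alignment."""
    out = {}
    for cap, idx in (("gel", 0), ("dry", 1)):
        gfps = np.stack([pair[idx].vep_gfp.gfp for pair in pairs])
        times = pairs[0][idx].vep_gfp.times
        grand = evk.GfpSeries(gfp=gfps.mean(axis=0), times=times)
        peaks = evk.find_peaks(grand)
        out[cap] = {
            p.name.value: {"latency_ms": p.latency, "amplitude_uV": p.amplitude}
            for p in peaks
        }
    return out


def mirror_cohort(cohort: CohortResult) -> CohortResult:
    """Cohort in which every dry session is a relabeled copy of the gel one.

    Used by the end-to-end null check: with identical underlying data the
    comparison must return r = 1 and RMSD = 0 everywhere.
    """
    sessions = []
    metadata: list[SubjectMetadata] = []
    meta_by_key = {(m.subject_id, m.cap_type): m for m in cohort.metadata}
    for gel, _dry in cohort.sessions:
        dup = SessionRecording(
            subject_id=gel.subject_id,
            cap_type=CapType.DRY,
            layout=gel.layout,
            data=gel.data.copy(),
            sampling_rate=gel.sampling_rate,
            segments=gel.segments,
            true_bad_channels=gel.true_bad_channels,
        )
        sessions.append((gel, dup))
        m = meta_by_key[(gel.subject_id, CapType.GEL)]
        metadata.append(m)
        metadata.append(dataclasses.replace(m, cap_type=CapType.DRY))
    return CohortResult(config=cohort.config, sessions=sessions, metadata=metadata)


def run_study(config: PipelineConfig) -> tuple[CohortResult, list, cmp.StudyReport]:
    """Simulate, analyze and compare a full cohort under one configuration."""
    cohort = simulate_cohort(config.simulation)
    pairs = analyze_cohort(cohort, config)
    report = compare_cohort(pairs, cohort.metadata, cohort.metadata_table(), config)
    return cohort, pairs, report
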