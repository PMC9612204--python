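"""Synthetic paired gel/dry EEG sessions with the structure the pipeline assumes.

Each simulated session runs the four-part acquisition paradigm in order:
resting state with eyes open, resting state with eyes closed, cued eye blinks
on a fixed beep grid, and pattern-reversal visual stimulation. The generative
model is deliberately minimal but exercises every downstream analysis stage:

* background activity: per-channel pink (1/f) noise plus white sensor noise;
* alpha rhythm: an amplitude-modulated sinusoid, spatially weighted toward
  occipito-parietal sites and stronger with eyes closed;
* blinks: a stereotyped biphasic transient (~300 ms) at each beep trigger,
  weighted toward frontal sites;
* visual evoked response: a negative occipital lobe (N75) and a positive
  occipital lobe (P100), Gaussian-windowed in time, at each reversal trigger;
  each component's scalp pattern is standardized to unit spatial SD so the
  configured amplitude is the component's global field power in microvolts;
* bad channels: drawn independently per segment and replaced by isoelectric
  or high-amplitude-noise traces with equal probability;
* metadata: preparation/acquisition times, attention and comfort ratings and
  per-electrode impedances drawn per cap type, with dry impedances elevated
  centro-parietally.

All randomness flows from one master seed through named sub-streams, so
results are reproducible independent of execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .montage import ElectrodeLayout, LayoutKind, builtin_layout

__all__ = [
    "CapType",
    "SegmentKind",
    "SimulationConfig",
    "SegmentAnnotation",
    "SessionRecording",
    "SubjectMetadata",
    "simulate_session",
    "simulate_cohort",
    "CohortResult",
    "short_config",
    "write_edf",
    "read_edf",
]


class CapType(str, Enum):
    GEL = "gel"
    DRY = "dry"


class SegmentKind(str, Enum):
    EYES_OPEN = "eyes_open"
    EYES_CLOSED = "eyes_closed"
    BLINK = "blink"
    VEP = "vep"


_PARADIGM_ORDER = (
    SegmentKind.EYES_OPEN,
    SegmentKind.EYES_CLOSED,
    SegmentKind.BLINK,
    SegmentKind.VEP,
)

# Grand-average metadata distribution parameters per cap: (mean, sd) for
# preparation time, acquisition time (min), attention and comfort ratings at
# start/end of the acquisition phase.
METADATA_PARAMS: dict[CapType, dict[str, tuple[float, float]]] = {
    CapType.GEL: {
        "prep_time": (32.3, 13.8),
        "acquisition_time": (21.3, 9.3),
        "attention_start": (3.3, 1.6),
        "attention_end": (3.6, 1.9),
        "comfort_start": (2.4, 1.3),
        "comfort_end": (2.5, 1.4),
    },
    CapType.DRY: {
        "prep_time": (12.4, 6.5),
        "acquisition_time": (23.4, 8.3),
        "attention_start": (3.2, 1.6),
        "attention_end": (3.7, 1.9),
        "comfort_start": (3.6, 1.8),
        "comfort_end": (4.3, 2.2),
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Segment durations default to the study's average durations (whole
    seconds); amplitudes are in microvolts, times in seconds unless noted.
    The evoked component amplitudes are global-field-power amplitudes.
    """

    n_subjects: int = 10
    sampling_rate: float = 500.0
    seed: int = 0

    # resting-state rhythm
    alpha_freq: float = 10.0
    alpha_amp_closed: float = 10.0
    alpha_amp_open: float = 3.0

    # background noise
    noise_sd: float = 2.0
    pink_sd: float = 5.0
    pink_exponent: float = 1.0

    # blink paradigm
    blink_amp: float = 200.0
    blink_interval: float = 2.0
    blink_width: float = 0.06  # template lobe sigma, s (~300 ms total span)

    # visual stimulation
    n_vep_epochs: int = 150
    vep_interval: float = 1.3
    n75_latency: float = 72.0  # ms
    p100_latency: float = 120.0  # ms
    n75_amp: float = 7.38  # uV, GFP at peak
    p100_amp: float = 17.57  # uV, GFP at peak

    # segment durations, whole seconds
    duration_eyes_open: float = 184.0
    duration_eyes_closed: float = 183.0
    duration_blink: float = 67.0
    duration_vep: float = 205.0

    # data-quality model
    bad_channel_prob: Mapping[str, float] = field(
        default_factory=lambda: {"gel": 0.015, "dry": 0.19}
    )
    # per-cap log-normal impedance: (median kOhm, log-scale sigma)
    impedance_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"gel": (12.0, 0.9), "dry": (400.0, 0.75)}
    )
    attention_scale_max: float = 8.0  # Stanford sleepiness scale bound
    comfort_scale_max: float = 10.0

    def __post_init__(self) -> None:
        if self.sampling_rate < 200:
            raise ValueError("sampling_rate must be at least 200 Hz")
        for name in ("alpha_amp_closed", "alpha_amp_open", "noise_sd", "pink_sd",
                     "blink_amp", "n75_amp", "p100_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for cap, p in self.bad_channel_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"bad_channel_prob[{cap}] must be in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.blink_interval <= 0 or self.vep_interval <= 0:
            raise ValueError("trigger intervals must be positive")
        for name in ("duration_eyes_open", "duration_eyes_closed",
                     "duration_blink", "duration_vep"):
            d = getattr(self, name)
            if d <= 0 or abs(d - round(d)) > 1e-9:
                raise ValueError(f"{name} must be a positive whole number of seconds")

    def segment_duration(self, kind: SegmentKind) -> float:
        return {
            SegmentKind.EYES_OPEN: self.duration_eyes_open,
            SegmentKind.EYES_CLOSED: self.duration_eyes_closed,
            SegmentKind.BLINK: self.duration_blink,
            SegmentKind.VEP: self.duration_vep,
        }[kind]


def short_config(n_subjects: int = 10, seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale configuration: ten-fold shorter segments, fewer reversals."""
    params = dict(
        n_subjects=n_subjects,
        seed=seed,
        duration_eyes_open=18.0,
        duration_eyes_closed=18.0,
        duration_blink=12.0,
        duration_vep=21.0,
        n_vep_epochs=40,
        vep_interval=0.5,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass(frozen=True)
class SegmentAnnotation:
    kind: SegmentKind
    start: float  # s, from recording start
    duration: float  # s
    trigger_times: tuple[float, ...] = ()  # s, absolute

    def __post_init__(self) -> None:
        for t in self.trigger_times:
            if not (self.start - 1e-9 <= t <= self.start + self.duration + 1e-9):
                raise ValueError(f"trigger at {t} s outside segment bounds")


@dataclass
class SessionRecording:
    """One cap application: continuous multichannel data plus annotations."""

    subject_id: str
    cap_type: CapType
    layout: ElectrodeLayout
    data: np.ndarray  # channels x samples, uV
    sampling_rate: float
    segments: tuple[SegmentAnnotation, ...]
    # ground truth, simulation only: segment kind -> labels replaced
    true_bad_channels: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.layout):
            raise ValueError("data rows must correspond 1:1 to layout electrodes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        starts = [s.start for s in self.segments]
        if starts != sorted(starts):
            raise ValueError("segments must be in temporal order")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.start + a.duration > b.start + 1e-9:
                raise ValueError("segments overlap")

    def segment(self, kind: SegmentKind) -> SegmentAnnotation:
        for s in self.segments:
            if s.kind is kind:
                return s
        raise KeyError(f"no {kind.value} segment in session {self.subject_id}")

    def segment_data(self, kind: SegmentKind) -> np.ndarray:
        s = self.segment(kind)
        i0 = int(round(s.start * self.sampling_rate))
        i1 = int(round((s.start + s.duration) * self.sampling_rate))
        return self.data[:, i0:i1]


@dataclass(frozen=True)
class SubjectMetadata:
    subject_id: str
    cap_type: CapType
    prep_time: float  # min
    acquisition_time: float  # min
    attention_start: float
    attention_end: float
    comfort_start: float
    comfort_end: float
    impedance_start: Mapping[str, float]  # label -> kOhm
    impedance_end: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.prep_time < 0 or self.acquisition_time < 0:
            raise ValueError("times must be non-negative")
        for imp in (self.impedance_start, self.impedance_end):
            if any(v <= 0 for v in imp.values()):
                raise ValueError("impedances must be positive")


# ---------------------------------------------------------------------------
# Spatial weighting on the unit sphere
# ---------------------------------------------------------------------------

def _gaussian_weights(layout: ElectrodeLayout, center: np.ndarray, sigma_deg: float) -> np.ndarray:
    center = center / np.linalg.norm(center)
    ang = np.degrees(np.arccos(np.clip(layout.positions @ center, -1.0, 1.0)))
    return np.exp(-0.5 * (ang / sigma_deg) ** 2)


def _occipital_center() -> np.ndarray:
    # between Pz and Oz: 65 degrees back of the vertex on the midline
    lam = np.radians(65.0)
    return np.array([0.0, -np.sin(lam), np.cos(lam)])


def _frontal_center() -> np.ndarray:
    lam = np.radians(72.0)  # Fpz
    return np.array([0.0, np.sin(lam), np.cos(lam)])


def _centroparietal_center() -> np.ndarray:
    lam = np.radians(12.0)  # just behind the vertex
    return np.array([0.0, -np.sin(lam), np.cos(lam)])


def alpha_weights(layout: ElectrodeLayout) -> np.ndarray:
    """Occipito-parietal weighting of the alpha rhythm, max 1 near Oz/POz."""
    w = _gaussian_weights(layout, _occipital_center(), 35.0)
    return w / w.max()


def blink_weights(layout: ElectrodeLayout) -> np.ndarray:
    """Frontal weighting of the blink transient, max 1 near Fpz."""
    w = _gaussian_weights(layout, _frontal_center(), 30.0)
    return w / w.max()


def _standardized_pattern(layout: ElectrodeLayout, center: np.ndarray,
                          sigma_deg: float, sign: float) -> np.ndarray:
    """Scalp pattern with unit population SD across the layout."""
    w = sign * _gaussian_weights(layout, center, sigma_deg)
    return w / w.std()


def vep_patterns(layout: ElectrodeLayout) -> tuple[np.ndarray, np.ndarray]:
    """(N75, P100) scalp patterns, each standardized to unit spatial SD."""
    lam75 = np.radians(75.0)
    lam100 = np.radians(68.0)
    n75 = _standardized_pattern(
        layout, np.array([0.0, -np.sin(lam75), np.cos(lam75)]), 25.0, -1.0
    )
    p100 = _standardized_pattern(
        layout, np.array([0.0, -np.sin(lam100), np.cos(lam100)]), 35.0, +1.0
    )
    return n75, p100


# ---------------------------------------------------------------------------
# Temporal building blocks
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, unit-SD scaled."""
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    f_floor = 0.5  # flatten below 0.5 Hz to keep finite low-frequency power
    shaping[nonzero] = np.maximum(freqs[nonzero], f_floor) ** (-exponent / 2.0)
    shaping[0] = 0.0
    spec = np.fft.rfft(white, axis=1) * shaping[None, :]
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    out_sd = out.std(axis=1, keepdims=True)
    out_sd[out_sd == 0] = 1.0
    return sd * out / out_sd


def _slow_envelope(rng: np.random.Generator, n_samples: int, fs: float) -> np.ndarray:
    """Smooth positive amplitude modulation with mean ~1 (waxing/waning)."""
    n_nodes = max(int(n_samples / fs / 2) + 2, 4)  # ~0.5 Hz node spacing
    nodes = rng.standard_normal(n_nodes)
    x_nodes = np.linspace(0, n_samples - 1, n_nodes)
    mod = np.interp(np.arange(n_samples), x_nodes, nodes)
    env = 1.0 + 0.3 * mod
    return np.clip(env, 0.1, None)


def blink_template(fs: float, width: float) -> tuple[np.ndarray, int]:
    """Biphasic blink transient, unit positive peak; returns (kernel, peak index)."""
    half = int(round(3.0 * width * fs))
    t = np.arange(-half, half + 1) / fs
    g = (t / width) * np.exp(0.5 * (1.0 - (t / width) ** 2))
    return g, int(np.argmax(g))


def _gauss_lobe(t: np.ndarray, latency_s: float, sigma_s: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - latency_s) / sigma_s) ** 2)


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------

def _stream(master_seed: int, *context: object) -> np.random.Generator:
    """Named RNG sub-stream: context words are hashed into the seed sequence."""
    words = [master_seed & 0x7FFFFFFF]
    for item in context:
        words.append(zlib.crc32(str(item).encode()))
    return np.random.default_rng(np.random.SeedSequence(words))


def _segment_triggers(config: SimulationConfig, kind: SegmentKind, start: float) -> tuple[float, ...]:
    if kind is SegmentKind.BLINK:
        n = int(config.segment_duration(kind) // config.blink_interval)
        first = config.blink_interval / 2.0
        return tuple(start + first + k * config.blink_interval for k in range(n))
    if kind is SegmentKind.VEP:
        first = 0.5
        times = [start + first + k * config.vep_interval for k in range(config.n_vep_epochs)]
        end = start + config.segment_duration(kind)
        if times and times[-1] + 0.4 > end:
            raise ValueError(
                "vep segment too short for n_vep_epochs at the configured interval"
            )
        return tuple(times)
    return ()


def simulate_session(
    config: SimulationConfig,
    subject_id: str,
    cap_type: CapType | str,
    layout: ElectrodeLayout,
    seed: int | None = None,
) -> tuple[SessionRecording, SubjectMetadata]:
    """Generate one cap application (all four paradigm segments) plus metadata."""
    cap_type = CapType(cap_type)
    master = config.seed if seed is None else seed
    fs = config.sampling_rate
    n_ch = len(layout)

    segments: list[SegmentAnnotation] = []
    t0 = 0.0
    for kind in _PARADIGM_ORDER:
        dur = config.segment_duration(kind)
        segments.append(
            SegmentAnnotation(kind, t0, dur, _segment_triggers(config, kind, t0))
        )
        t0 += dur
    n_total = int(round(t0 * fs))
    t_axis = np.arange(n_total) / fs

    rng_bg = _stream(master, subject_id, cap_type.value, "background")
    data = _pink_noise(rng_bg, n_ch, n_total, fs, config.pink_exponent, config.pink_sd)
    data += config.noise_sd * rng_bg.standard_normal((n_ch, n_total))

    # alpha rhythm: occipito-parietal, stronger with eyes closed
    rng_alpha = _stream(master, subject_id, cap_type.value, "alpha")
    phase = rng_alpha.uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * config.alpha_freq * t_axis + phase)
    envelope = _slow_envelope(rng_alpha, n_total, fs)
    amp = np.full(n_total, config.alpha_amp_open)
    seg_ec = next(s for s in segments if s.kind is SegmentKind.EYES_CLOSED)
    i0 = int(round(seg_ec.start * fs))
    i1 = int(round((seg_ec.start + seg_ec.duration) * fs))
    amp[i0:i1] = config.alpha_amp_closed
    data += alpha_weights(layout)[:, None] * (amp * envelope * carrier)[None, :]

    # blink transients on the beep grid
    kernel, peak_idx = blink_template(fs, config.blink_width)
    w_blink = blink_weights(layout)
    blink_seg = next(s for s in segments if s.kind is SegmentKind.BLINK)
    drive = np.zeros(n_total)
    for t in blink_seg.trigger_times:
        center = int(round(t * fs))
        lo = center - peak_idx
        hi = lo + len(kernel)
        if lo >= 0 and hi <= n_total:
            drive[lo:hi] += kernel
    data += config.blink_amp * w_blink[:, None] * drive[None, :]

    # visual evoked components on the reversal grid
    n75_pat, p100_pat = vep_patterns(layout)
    vep_seg = next(s for s in segments if s.kind is SegmentKind.VEP)
    resp = np.zeros(n_total)
    resp75 = np.zeros(n_total)
    for t in vep_seg.trigger_times:
        i_start = int(round(t * fs))
        n_win = int(round(0.4 * fs))
        tt = np.arange(n_win) / fs
        lobe75 = _gauss_lobe(tt, config.n75_latency / 1000.0, 0.010)
        lobe100 = _gauss_lobe(tt, config.p100_latency / 1000.0, 0.010)
        resp75[i_start : i_start + n_win] += lobe75
        resp[i_start : i_start + n_win] += lobe100
    data += config.n75_amp * n75_pat[:, None] * resp75[None, :]
    data += config.p100_amp * p100_pat[:, None] * resp[None, :]

    # bad channels, independently per segment
    p_bad = float(config.bad_channel_prob[cap_type.value])
    true_bad: dict[str, tuple[str, ...]] = {}
    for seg in segments:
        rng_bad = _stream(master, subject_id, cap_type.value, "bad", seg.kind.value)
        flags = rng_bad.random(n_ch) < p_bad
        labels = tuple(lbl for lbl, f in zip(layout.labels, flags) if f)
        true_bad[seg.kind.value] = labels
        if not labels:
            continue
        j0 = int(round(seg.start * fs))
        j1 = int(round((seg.start + seg.duration) * fs))
        for lbl in labels:
            idx = layout.index_of(lbl)
            if rng_bad.random() < 0.5:  # isoelectric
                data[idx, j0:j1] = 0.01 * rng_bad.standard_normal(j1 - j0)
            else:  # saturated high-amplitude noise
                data[idx, j0:j1] = 300.0 * rng_bad.standard_normal(j1 - j0)

    metadata = _simulate_metadata(config, subject_id, cap_type, layout, master)
    recording = SessionRecording(
        subject_id=subject_id,
        cap_type=cap_type,
        layout=layout,
        data=data,
        sampling_rate=fs,
        segments=tuple(segments),
        true_bad_channels=true_bad,
    )
    return recording, metadata


def _simulate_metadata(
    config: SimulationConfig,
    subject_id: str,
    cap_type: CapType,
    layout: ElectrodeLayout,
    master: int,
) -> SubjectMetadata:
    rng = _stream(master, subject_id, cap_type.value, "metadata")
    p = METADATA_PARAMS[cap_type]

    def draw(key: str, lo: float, hi: float | None) -> float:
        mean, sd = p[key]
        v = rng.normal(mean, sd)
        return float(np.clip(v, lo, hi if hi is not None else np.inf))

    prep = draw("prep_time", 1.0, None)
    acq = draw("acquisition_time", 5.0, None)
    att_s = draw("attention_start", 1.0, config.attention_scale_max)
    att_e = draw("attention_end", 1.0, config.attention_scale_max)
    com_s = draw("comfort_start", 1.0, config.comfort_scale_max)
    com_e = draw("comfort_end", 1.0, config.comfort_scale_max)

    median, sigma = config.impedance_params[cap_type.value]
    base = median * np.exp(sigma * rng.standard_normal(len(layout)))
    if cap_type is CapType.DRY:
        boost = 1.0 + 1.5 * _gaussian_weights(layout, _centroparietal_center(), 30.0)
        base = base * boost
    drift = np.exp(rng.normal(0.05, 0.15, len(layout)))
    imp_start = dict(zip(layout.labels, base))
    imp_end = dict(zip(layout.labels, base * drift))
    return SubjectMetadata(
        subject_id=subject_id,
        cap_type=cap_type,
        prep_time=prep,
        acquisition_time=acq,
        attention_start=att_s,
        attention_end=att_e,
        comfort_start=com_s,
        comfort_end=com_e,
        impedance_start=imp_start,
        impedance_end=imp_end,
    )


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    config: SimulationConfig
    sessions: list[tuple[SessionRecording, SessionRecording]]  # (gel, dry) pairs
    metadata: list[SubjectMetadata]  # one per subject per cap

    def metadata_table(self) -> pd.DataFrame:
        rows = []
        for m in self.metadata:
            rows.append(
                {
                    "subject": m.subject_id,
                    "cap": m.cap_type.value,
                    "prep_time": m.prep_time,
                    "acquisition_time": m.acquisition_time,
                    "attention_start": m.attention_start,
                    "attention_end": m.attention_end,
                    "comfort_start": m.comfort_start,
                    "comfort_end": m.comfort_end,
                }
            )
        return pd.DataFrame(rows)


def _subject_layouts(index: int) -> tuple[LayoutKind, LayoutKind]:
    """Per-subject (gel, dry) layout assignment mirroring the study mixture:
    a minority of ten-twenty/ten-twenty pairs, some mixed gel ten-twenty with
    dry equidistant, and a majority of equidistant/equidistant pairs."""
    if index % 6 == 0:
        return LayoutKind.TEN_TWENTY, LayoutKind.TEN_TWENTY
    if index % 3 == 0:
        return LayoutKind.TEN_TWENTY, LayoutKind.EQUIDISTANT
    return LayoutKind.EQUIDISTANT, LayoutKind.EQUIDISTANT


def simulate_cohort(config: SimulationConfig) -> CohortResult:
    """Simulate one gel and one dry session per subject, plus metadata."""
    sessions: list[tuple[SessionRecording, SessionRecording]] = []
    metadata: list[SubjectMetadata] = []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:03d}"
        kind_gel, kind_dry = _subject_layouts(i)
        rec_g, meta_g = simulate_session(
            config, subject_id, CapType.GEL, builtin_layout(kind_gel)
        )
        rec_d, meta_d = simulate_session(
            config, subject_id, CapType.DRY, builtin_layout(kind_dry)
        )
        sessions.append((rec_g, rec_d))
        metadata.extend([meta_g, meta_d])
    return CohortResult(config=config, sessions=sessions, metadata=metadata)


# EDF round-trip lives in capcompare.edf; re-exported here as part of the
# generator's external interface.
from .edf import read_edf, write_edf  # noqa: E402
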