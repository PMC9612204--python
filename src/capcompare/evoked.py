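"""Evoked analysis: epoching, trial rejection, averaging, global field power
over time (GFPt), component peak detection, and latency alignment.

GFPt is the per-sample population standard deviation of the instantaneous
potential across all electrodes — a reference-free measure of momentary
scalp field strength. The N75 and P100 pattern-reversal components appear as
its first two post-stimulus peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .preprocess import InsufficientDataError

__all__ = [
    "EpochSet",
    "EvokedWaveform",
    "GfpSeries",
    "Component",
    "ComponentPeak",
    "PeakOrderError",
    "EmptyResultError",
    "SuspiciousShiftError",
    "VEP_WINDOW_MS",
    "DEFAULT_PEAK_WINDOWS",
    "epoch",
    "reject_trials",
    "average",
    "gfp_t",
    "find_peaks",
    "align_latency",
    "blink_overlays",
]

VEP_WINDOW_MS = (-100.0, 400.0)
DEFAULT_PEAK_WINDOWS = {"N75": (50.0, 100.0), "P100": (90.0, 170.0)}


class EmptyResultError(ValueError):
    """All trials were rejected."""


class PeakOrderError(ValueError):
    """Component peaks could not be resolved in physiological order."""

    def __init__(self, message: str, candidates: dict):
        super().__init__(message)
        self.candidates = candidates


class SuspiciousShiftError(ValueError):
    """Requested latency shift is implausibly large."""


class Component(str, Enum):
    N75 = "N75"
    P100 = "P100"


@dataclass(frozen=True)
class EpochSet:
    epochs: np.ndarray  # trials x channels x samples, uV
    times: np.ndarray  # ms relative to trigger
    rejected: tuple[int, ...] = ()
    n_dropped_bounds: int = 0  # triggers whose window fell outside the data

    @property
    def kept(self) -> np.ndarray:
        keep = [i for i in range(self.epochs.shape[0]) if i not in set(self.rejected)]
        return self.epochs[keep]


@dataclass(frozen=True)
class EvokedWaveform:
    mean: np.ndarray  # channels x samples, uV
    times: np.ndarray  # ms
    n_trials_used: int
    shift_ms: float = 0.0  # applied latency correction, provenance


@dataclass(frozen=True)
class GfpSeries:
    gfp: np.ndarray  # uV, >= 0
    times: np.ndarray  # ms


@dataclass(frozen=True)
class ComponentPeak:
    name: Component
    latency: float  # ms
    amplitude: float  # uV, GFPt value at the peak
    low_confidence: bool = False


def epoch(
    data: np.ndarray,
    sampling_rate: float,
    triggers: list[float],
    window_ms: tuple[float, float] = VEP_WINDOW_MS,
    baseline: bool = True,
) -> EpochSet:
    """Cut trigger-locked epochs with per-trial pre-stimulus baseline removal.

    Triggers whose window exceeds the data bounds are dropped (counted in
    ``n_dropped_bounds``).
    """
    data = np.asarray(data, dtype=float)
    n_samples = data.shape[-1]
    lo_ms, hi_ms = window_ms
    i_lo = int(round(lo_ms / 1000.0 * sampling_rate))
    i_hi = int(round(hi_ms / 1000.0 * sampling_rate))
    n_win = i_hi - i_lo
    times = (np.arange(i_lo, i_hi) / sampling_rate) * 1000.0

    trials = []
    dropped = 0
    for t in triggers:
        center = int(round(t * sampling_rate))
        a, b = center + i_lo, center + i_hi
        if a < 0 or b > n_samples:
            dropped += 1
            continue
        trials.append(data[:, a:b])
    if not trials:
        raise InsufficientDataError("no trigger window fits inside the recording")
    epochs = np.stack(trials)
    if baseline:
        pre = times < 0
        if pre.any():
            epochs = epochs - epochs[:, :, pre].mean(axis=2, keepdims=True)
    return EpochSet(epochs=epochs, times=times, n_dropped_bounds=dropped)


def reject_trials(epochs: EpochSet, ptp_threshold: float = 150.0) -> EpochSet:
    """Reject whole trials whose peak-to-peak exceeds the threshold anywhere."""
    if epochs.epochs.shape[0] < 1:
        raise InsufficientDataError("need at least one trial")
    ptp = epochs.epochs.max(axis=2) - epochs.epochs.min(axis=2)  # trials x channels
    bad = tuple(int(i) for i in np.nonzero((ptp > ptp_threshold).any(axis=1))[0])
    if len(bad) == epochs.epochs.shape[0]:
        raise EmptyResultError("all trials exceed the peak-to-peak threshold")
    return replace(epochs, rejected=bad)


def average(epochs: EpochSet) -> EvokedWaveform:
    """Arithmetic mean over kept trials."""
    kept = epochs.kept
    if kept.shape[0] < 1:
        raise EmptyResultError("no kept trials to average")
    return EvokedWaveform(mean=kept.mean(axis=0), times=epochs.times,
                          n_trials_used=int(kept.shape[0]))


def gfp_t(evoked: EvokedWaveform) -> GfpSeries:
    """Global field power: per-sample population SD across channels."""
    if evoked.mean.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return GfpSeries(gfp=evoked.mean.std(axis=0, ddof=0), times=evoked.times)


def find_peaks(
    gfp: GfpSeries,
    windows: dict[str, tuple[float, float]] | None = None,
) -> list[ComponentPeak]:
    """Locate the N75 and P100 peaks as GFP maxima in their search windows.

    Ties break to the earliest sample; a flat window is flagged low
    confidence. The P100 peak must fall after the N75 peak, otherwise a
    :class:`PeakOrderError` carrying both candidates is raised.
    """
    windows = windows or DEFAULT_PEAK_WINDOWS
    peaks: dict[str, ComponentPeak] = {}
    for name, (lo, hi) in windows.items():
        if lo < gfp.times[0] or hi > gfp.times[-1]:
            raise ValueError(f"{name} window {lo}-{hi} ms outside the time axis")
        mask = (gfp.times >= lo) & (gfp.times <= hi)
        seg = gfp.gfp[mask]
        k = int(np.argmax(seg))  # argmax takes the earliest on exact ties
        flat = bool(np.allclose(seg, seg[0]))
        peaks[name] = ComponentPeak(
            name=Component(name),
            latency=float(gfp.times[mask][0 if flat else k]),
            amplitude=float(seg[0 if flat else k]),
            low_confidence=flat,
        )
    if "N75" in peaks and "P100" in peaks:
        if peaks["P100"].latency <= peaks["N75"].latency:
            raise PeakOrderError(
                "P100 candidate does not follow N75 candidate",
                candidates={k: v for k, v in peaks.items()},
            )
    return [peaks[k] for k in windows]


def align_latency(
    evoked: EvokedWaveform, own_n75: float, reference_n75: float,
    max_shift_ms: float = 50.0,
) -> EvokedWaveform:
    """Shift the waveform so its N75 latency matches the reference.

    The shift (reference − own) is rounded to whole samples and applied with
    edge truncation: samples shifted in from outside the window are zero.
    """
    dt_ms = float(np.median(np.diff(evoked.times)))
    shift_ms = reference_n75 - own_n75
    if abs(shift_ms) > max_shift_ms:
        raise SuspiciousShiftError(
            f"latency shift {shift_ms:+.1f} ms exceeds {max_shift_ms} ms"
        )
    shift = int(round(shift_ms / dt_ms))
    if shift == 0:
        return replace(evoked, shift_ms=0.0)
    out = np.zeros_like(evoked.mean)
    if shift > 0:
        out[:, shift:] = evoked.mean[:, :-shift]
    else:
        out[:, :shift] = evoked.mean[:, -shift:]
    return replace(evoked, mean=out, shift_ms=shift * dt_ms)


def blink_overlays(
    segment_data: np.ndarray,
    sampling_rate: float,
    triggers_in_segment: list[float],
) -> dict[str, EvokedWaveform]:
    """Averaged blink overlays for 2-s (1 blink) and 10-s (5 blinks) trials.

    Trials are taken from the center of the stimulation sequence outward:
    2-s trials are centered on single triggers, 10-s trials span five
    consecutive triggers. No baseline correction is applied.
    """
    triggers = sorted(triggers_in_segment)
    if not triggers:
        raise InsufficientDataError("no blink triggers in segment")
    out: dict[str, EvokedWaveform] = {}

    short = epoch(segment_data, sampling_rate, triggers,
                  window_ms=(-1000.0, 1000.0), baseline=False)
    out["2s"] = average(short)

    if len(triggers) >= 5:
        mid = len(triggers) // 2
        centers = [triggers[i + 2] for i in range(0, len(triggers) - 4, 5)]
        if centers:
            long = epoch(segment_data, sampling_rate, centers,
                         window_ms=(-5000.0, 5000.0), baseline=False)
            out["10s"] = average(long)
    return out
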