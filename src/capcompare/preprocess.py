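"""Preprocessing chain: band-pass/notch filtering, automated channel rating,
spherical-spline interpolation to the combined 128-site montage, and common
average referencing.

The spline interpolator follows the classic spherical-spline formulation for
scalp potentials: the kernel is the Legendre series

    g(x) = (1/4pi) * sum_{n=1..N} (2n+1) / (n(n+1))**m * P_n(x)

evaluated at cosines of inter-electrode angles, with a constant-offset
constraint appended to the linear system. Interpolation is linear in the
data, so a single solve per electrode configuration yields a transfer matrix
that maps source potentials to any set of target sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal
from scipy.linalg import lu_factor, lu_solve
from scipy.special import eval_legendre

from .montage import ElectrodeLayout
from .synthdata import SessionRecording

__all__ = [
    "FilterSpec",
    "BadChannelParams",
    "ChannelRating",
    "Verdict",
    "RatingReason",
    "SplineModel",
    "InsufficientDataError",
    "InsufficientChannelsError",
    "apply_filters",
    "filter_array",
    "rate_channels",
    "fit_spline",
    "interpolate",
    "spline_transfer",
    "to_combined",
    "common_average_reference",
]


class InsufficientDataError(ValueError):
    """Not enough data for the requested operation."""


class InsufficientChannelsError(ValueError):
    """Too few usable channels to fit the interpolator."""


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Band-pass plus notch filter settings.

    ``band_slope`` is the asymptotic band-pass slope in dB/octave (24 dB/oct
    corresponds to a fourth-order Butterworth); the notch is realized as a
    Butterworth band-stop around ``notch_freq``.
    """

    band: tuple[float, float] = (1.0, 40.0)
    band_slope: float = 24.0
    notch_freq: float = 50.0
    notch_halfwidth: float = 1.0
    notch_order: int = 3

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if self.band_slope % 6 != 0 or self.band_slope <= 0:
            raise ValueError("band_slope must be a positive multiple of 6 dB/octave")

    @property
    def butter_order(self) -> int:
        return int(self.band_slope // 6)


def filter_array(data: np.ndarray, sampling_rate: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase band-pass + notch on a channels-by-samples array."""
    nyq = sampling_rate / 2.0
    low, high = spec.band
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz violates Nyquist ({nyq} Hz)")
    sos_bp = signal.butter(spec.butter_order, [low, high], btype="bandpass",
                           fs=sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos_bp, data, axis=-1)
    f0 = spec.notch_freq
    if 0 < f0 < nyq:
        sos_notch = signal.butter(
            spec.notch_order,
            [f0 - spec.notch_halfwidth, f0 + spec.notch_halfwidth],
            btype="bandstop", fs=sampling_rate, output="sos",
        )
        out = signal.sosfiltfilt(sos_notch, out, axis=-1)
    return out


def apply_filters(recording: SessionRecording, spec: FilterSpec | None = None) -> SessionRecording:
    """Return a copy of the recording with the filter chain applied."""
    spec = spec or FilterSpec()
    filtered = filter_array(recording.data, recording.sampling_rate, spec)
    return SessionRecording(
        subject_id=recording.subject_id,
        cap_type=recording.cap_type,
        layout=recording.layout,
        data=filtered,
        sampling_rate=recording.sampling_rate,
        segments=recording.segments,
        true_bad_channels=recording.true_bad_channels,
    )


# ---------------------------------------------------------------------------
# Channel rating
# ---------------------------------------------------------------------------

class Verdict(str, Enum):
    GOOD = "good"
    BAD = "bad"


class RatingReason(str, Enum):
    ARTIFACT = "artifact"
    ISOELECTRIC = "isoelectric"
    NONE = "none"


@dataclass(frozen=True)
class BadChannelParams:
    """Thresholds of the automated good/bad rating.

    A 1-second window fails as isoelectric when its SD is below
    ``iso_threshold`` and as artifactual when its peak-to-peak exceeds
    ``ptp_threshold`` or its SD exceeds ``sd_ratio`` times the across-channel
    median SD of that window. A channel is bad when at least ``bad_fraction``
    of its rated windows fail.
    """

    iso_threshold: float = 0.1  # uV
    ptp_threshold: float = 400.0  # uV
    sd_ratio: float = 8.0
    window_s: float = 1.0
    bad_fraction: float = 0.5


@dataclass(frozen=True)
class ChannelRating:
    channel: str
    verdict: Verdict
    reason: RatingReason
    bad_fraction: float


def rate_channels(
    segment_data: np.ndarray,
    sampling_rate: float,
    labels: list[str] | None = None,
    params: BadChannelParams | None = None,
    exclude_spans: list[tuple[float, float]] | None = None,
    window_offset_s: float = 0.0,
) -> list[ChannelRating]:
    """Rate each channel of one segment as good or bad.

    ``exclude_spans`` lists (start, stop) times in seconds, relative to the
    segment, whose overlapping windows are not rated — used to keep paradigm
    events (cued blinks) from counting as artifacts. ``window_offset_s``
    shifts the rating-window grid so such events can be centered in (and
    confined to) single windows.
    """
    params = params or BadChannelParams()
    data = np.asarray(segment_data, dtype=float)
    n_ch, n_samp = data.shape
    if labels is None:
        labels = [str(i) for i in range(n_ch)]
    win = int(round(params.window_s * sampling_rate))
    off = int(round(window_offset_s * sampling_rate)) % win
    n_win = (n_samp - off) // win
    if n_win < 2:
        raise InsufficientDataError("segment must contain at least 2 rating windows")

    rated = []
    for w in range(n_win):
        t_lo = window_offset_s + w * params.window_s
        t_hi = t_lo + params.window_s
        if exclude_spans and any(t_lo < b and a < t_hi for a, b in exclude_spans):
            continue
        rated.append(w)
    if len(rated) < 2:
        raise InsufficientDataError("fewer than 2 rateable windows after exclusions")

    iso_fail = np.zeros((n_ch, len(rated)), dtype=bool)
    art_fail = np.zeros((n_ch, len(rated)), dtype=bool)
    for j, w in enumerate(rated):
        chunk = data[:, off + w * win : off + (w + 1) * win]
        sd = chunk.std(axis=1)
        ptp = chunk.max(axis=1) - chunk.min(axis=1)
        iso_fail[:, j] = sd < params.iso_threshold
        med = np.median(sd)
        art_fail[:, j] = (ptp > params.ptp_threshold) | (
            (med > 0) & (sd > params.sd_ratio * med)
        )

    ratings = []
    for i, lbl in enumerate(labels):
        frac_iso = iso_fail[i].mean()
        frac_art = art_fail[i].mean()
        frac = (iso_fail[i] | art_fail[i]).mean()
        if frac >= params.bad_fraction:
            reason = RatingReason.ISOELECTRIC if frac_iso >= frac_art else RatingReason.ARTIFACT
            ratings.append(ChannelRating(lbl, Verdict.BAD, reason, float(frac)))
        else:
            ratings.append(ChannelRating(lbl, Verdict.GOOD, RatingReason.NONE, float(frac)))
    return ratings


# ---------------------------------------------------------------------------
# Spherical spline interpolation
# ---------------------------------------------------------------------------

@dataclass
class SplineModel:
    source_positions: np.ndarray  # (n, 3) unit vectors
    order_m: int = 4
    n_legendre_terms: int = 50
    regularization: float = 1e-6
    _lu: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.source_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 4:
            raise InsufficientChannelsError("need at least 4 source positions")
        if np.linalg.matrix_rank(pos) < 3:
            raise InsufficientChannelsError("source positions are coplanar through origin")
        if self.order_m < 2 or self.n_legendre_terms < 7 or self.regularization < 0:
            raise ValueError("invalid spline parameters")
        self.source_positions = pos
        n = pos.shape[0]
        g = _spline_kernel(np.clip(pos @ pos.T, -1.0, 1.0),
                           self.order_m, self.n_legendre_terms)
        g = g + self.regularization * np.eye(n)
        system = np.zeros((n + 1, n + 1))
        system[:n, :n] = g
        system[:n, n] = 1.0
        system[n, :n] = 1.0
        try:
            self._lu = lu_factor(system)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                f"singular spline system (cond ~ {np.linalg.cond(system):.3g})"
            ) from exc

    def solve(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Spline coefficients (c, offset) for values at the source sites.

        ``values`` may be (n,) or (n, t) for t time samples.
        """
        v = np.atleast_2d(np.asarray(values, dtype=float).T).T  # (n, t)
        n = self.source_positions.shape[0]
        if v.shape[0] != n:
            raise ValueError("values must match the number of source positions")
        rhs = np.zeros((n + 1, v.shape[1]))
        rhs[:n] = v
        sol = lu_solve(self._lu, rhs)
        return sol[:n], sol[n]


def _spline_kernel(x: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    coeffs = (2 * n + 1) / (n * (n + 1.0)) ** m
    out = np.zeros_like(np.asarray(x, dtype=float))
    for nn, c in zip(n, coeffs):
        out += c * eval_legendre(int(nn), x)
    return out / (4.0 * np.pi)


def fit_spline(
    source_positions: np.ndarray,
    order_m: int = 4,
    n_terms: int = 50,
    regularization: float = 1e-6,
) -> SplineModel:
    """Fit the spherical-spline system for a set of source sites."""
    return SplineModel(source_positions, order_m, n_terms, regularization)


def interpolate(model: SplineModel, values: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Interpolate source values to target sites (vector or time-resolved)."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    c, d = model.solve(values)
    g_ts = _spline_kernel(
        np.clip(targets @ model.source_positions.T, -1.0, 1.0),
        model.order_m, model.n_legendre_terms,
    )
    out = g_ts @ c + d[None, :]
    if np.ndim(values) == 1:
        return out[:, 0]
    return out


def spline_transfer(model: SplineModel, targets: np.ndarray) -> np.ndarray:
    """Transfer matrix T with T @ values == interpolate(model, values, targets)."""
    n = model.source_positions.shape[0]
    return interpolate(model, np.eye(n), np.atleast_2d(targets))


def to_combined(
    recording_data: np.ndarray,
    layout: ElectrodeLayout,
    bad: list[str],
    combined: ElectrodeLayout,
    order_m: int = 4,
    n_terms: int = 50,
    regularization: float = 1e-6,
) -> np.ndarray:
    """Interpolate a segment to the combined montage, excluding bad channels.

    The spline is fitted on good source electrodes only; native good channels
    pass through unchanged, every other combined site (including native bad
    channels) is interpolated.
    """
    data = np.asarray(recording_data, dtype=float)
    for lbl in bad:
        layout.index_of(lbl)  # raises on unknown label
    good_idx = [i for i, lbl in enumerate(layout.labels) if lbl not in set(bad)]
    if len(good_idx) < 16:
        raise InsufficientChannelsError(
            f"only {len(good_idx)} good channels; need at least 16"
        )
    good_labels = {layout.labels[i] for i in good_idx}
    model = fit_spline(layout.positions[good_idx], order_m, n_terms, regularization)
    transfer = spline_transfer(model, combined.positions)

    out = transfer @ data[good_idx]
    # exact pass-through for native good channels
    for j, lbl in enumerate(combined.labels):
        if lbl in good_labels:
            out[j] = data[layout.index_of(lbl)]
    return out


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous across-channel mean from every channel."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return data - data.mean(axis=0, keepdims=True)
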