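"""Resting-state spectral analysis: centered analysis windows, Welch power
spectral density, alpha-band mean power, and topographic mapping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import ElectrodeLayout
from .preprocess import InsufficientDataError, fit_spline, interpolate

__all__ = [
    "PsdResult",
    "BandPower",
    "extract_center_window",
    "welch_psd",
    "alpha_band_power",
    "topography",
]

ALPHA_BAND = (8.0, 13.0)  # Hz


@dataclass(frozen=True)
class PsdResult:
    freqs: np.ndarray  # Hz, ascending uniform grid
    power: np.ndarray  # channels x freqs, uV^2/Hz (one-sided density)
    window_length: float  # s
    overlap: float  # fraction


@dataclass(frozen=True)
class BandPower:
    band: tuple[float, float]
    mean_power: np.ndarray  # per channel, uV^2/Hz
    peak_freq: float  # Hz, argmax of channel-mean density within the band
    peak_power: float  # uV^2/Hz, channel-mean density at the peak


def extract_center_window(
    segment_data: np.ndarray, sampling_rate: float, duration: float = 30.0
) -> np.ndarray:
    """Contiguous window of ``duration`` seconds centered on the segment.

    When the leftover sample count is odd, the extra sample is left before
    the window.
    """
    data = np.asarray(segment_data)
    n_need = int(round(duration * sampling_rate))
    n_have = data.shape[-1]
    if n_have < n_need:
        raise InsufficientDataError(
            f"segment has {n_have} samples; {n_need} required for a "
            f"{duration:g}-s window"
        )
    extra = n_have - n_need
    start = extra - extra // 2  # odd leftover: extra sample goes before
    return data[..., start : start + n_need]


def welch_psd(
    data: np.ndarray,
    sampling_rate: float,
    window_length: float = 2.0,
    overlap: float = 0.5,
) -> PsdResult:
    """One-sided Welch density estimate with Hamming-tapered segments."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nperseg = int(round(window_length * sampling_rate))
    if data.shape[-1] < nperseg:
        raise InsufficientDataError("data shorter than one Welch window")
    freqs, power = signal.welch(
        data,
        fs=sampling_rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        scaling="density",
        detrend="constant",
        axis=-1,
    )
    return PsdResult(freqs=freqs, power=power, window_length=window_length, overlap=overlap)


def alpha_band_power(psd: PsdResult, band: tuple[float, float] = ALPHA_BAND) -> BandPower:
    """Per-channel mean density over the alpha band, plus the band peak.

    Bins whose center lies exactly on a band edge are included.
    """
    lo, hi = band
    if psd.freqs[0] > lo or psd.freqs[-1] < hi:
        raise ValueError(f"frequency grid does not cover the {band} Hz band")
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    band_power = psd.power[:, mask]
    mean_power = band_power.mean(axis=1)
    channel_mean = band_power.mean(axis=0)
    k = int(np.argmax(channel_mean))
    return BandPower(
        band=(lo, hi),
        mean_power=mean_power,
        peak_freq=float(psd.freqs[mask][k]),
        peak_power=float(channel_mean[k]),
    )


def _project_disk(positions: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection about the vertex: radius = polar angle."""
    theta = np.arccos(np.clip(positions[:, 2], -1.0, 1.0))
    horiz = np.linalg.norm(positions[:, :2], axis=1)
    safe = np.where(horiz > 1e-12, horiz, 1.0)
    return np.column_stack([theta * positions[:, 0] / safe, theta * positions[:, 1] / safe])


def topography(
    values: np.ndarray, layout: ElectrodeLayout, grid_n: int = 64
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate a per-channel scalar onto a head-disk grid.

    Returns (grid_x, grid_y, map) where ``map`` is ``grid_n x grid_n`` with
    NaN outside the head disk. Uses the spherical-spline interpolator on the
    back-projected grid directions.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("topography values must be finite")
    pos = layout.positions
    xy = _project_disk(pos)
    r_max = float(np.sqrt((xy ** 2).sum(axis=1)).max()) * 1.02

    axis = np.linspace(-r_max, r_max, grid_n)
    gx, gy = np.meshgrid(axis, axis)
    r = np.sqrt(gx ** 2 + gy ** 2)
    inside = r <= r_max

    # back-project disk points to the sphere: radius is the polar angle
    theta = np.minimum(r[inside], np.pi - 1e-9)
    safe_r = np.where(r[inside] > 1e-12, r[inside], 1.0)
    ux = np.where(r[inside] > 1e-12, gx[inside] / safe_r, 0.0)
    uy = np.where(r[inside] > 1e-12, gy[inside] / safe_r, 0.0)
    targets = np.column_stack(
        [np.sin(theta) * ux, np.sin(theta) * uy, np.cos(theta)]
    )
    model = fit_spline(pos)
    est = interpolate(model, values, targets)
    out = np.full(gx.shape, np.nan)
    out[inside] = est
    return gx, gy, out
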