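"""EDF+ export and import of session recordings.

The writer emits plain EDF+C: one data record per second, 16-bit samples with
per-channel physical scaling, and a TAL annotation channel carrying segment
boundaries (``seg:<kind>`` with duration) and stimulation triggers
(``trig:<kind>``). Reading goes through :func:`mne.io.read_raw_edf`, which
serves as an independent implementation of the format on the way back in.

Physical units are microvolts throughout; quantization error is bounded by
one digital step, i.e. (physical range)/65535 per channel.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf", "EdfFormatError"]

_DIG_MIN, _DIG_MAX = -32768, 32767


class EdfFormatError(IOError):
    """Unreadable or structurally invalid EDF file."""


def _fixed(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")
    if len(raw) > width:
        raw = raw[:width]
    return raw.ljust(width)


def _annotation_payloads(recording) -> dict[int, list[bytes]]:
    """Map record index -> TAL event strings for that second."""
    events: list[tuple[float, bytes]] = []
    for seg in recording.segments:
        tal = f"+{seg.start:.4f}\x15{seg.duration:.4f}\x14seg:{seg.kind.value}\x14"
        events.append((seg.start, tal.encode("ascii")))
        for t in seg.trigger_times:
            tal = f"+{t:.4f}\x14trig:{seg.kind.value}\x14"
            events.append((t, tal.encode("ascii")))
    out: dict[int, list[bytes]] = {}
    for onset, payload in events:
        out.setdefault(int(onset), []).append(payload)
    return out


def write_edf(recording, path: str | Path) -> None:
    """Write a session recording as EDF+C with annotations.

    The sampling rate must be a whole number of samples per second; the data
    are zero-padded to a whole number of 1-second records.
    """
    from .synthdata import SessionRecording  # local import to avoid a cycle

    assert isinstance(recording, SessionRecording)
    data = np.asarray(recording.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("EDF export requires finite sample values")
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_channels, n_samples = data.shape
    n_records = math.ceil(n_samples / fs)
    padded = np.zeros((n_channels, n_records * fs))
    padded[:, :n_samples] = data

    # Per-channel physical range; degenerate (flat) channels get a 1 uV span.
    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    flat = (pmax - pmin) < 1e-9
    pmax = np.where(flat, pmin + 1.0, pmax)
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.rint((padded - pmin[:, None]) * scale[:, None] + _DIG_MIN).astype("<i2")

    ann = _annotation_payloads(recording)
    ann_bytes = 0
    for rec_idx in range(n_records):
        need = len(f"+{rec_idx}\x14\x14\x00".encode()) + sum(
            len(p) for p in ann.get(rec_idx, [])
        )
        ann_bytes = max(ann_bytes, need)
    ann_samples = math.ceil((ann_bytes + 2) / 2)  # 2-byte samples, spare room

    ns = n_channels + 1
    header = bytearray()
    header += _fixed("0", 8)
    header += _fixed(f"{recording.subject_id} sex:X cap:{recording.cap_type.value}", 80)
    header += _fixed(f"Startdate 01-JAN-2000 {recording.layout.name}", 80)
    header += _fixed("01.01.00", 8)
    header += _fixed("00.00.00", 8)
    header += _fixed(str(256 * (ns + 1)), 8)
    header += _fixed("EDF+C", 44)
    header += _fixed(str(n_records), 8)
    header += _fixed("1", 8)  # record duration, seconds
    header += _fixed(str(ns), 4)

    labels = recording.layout.labels + ["EDF Annotations"]
    header += b"".join(_fixed(l, 16) for l in labels)
    header += b"".join(_fixed("", 80) for _ in range(ns))  # transducer
    header += b"".join(_fixed("uV", 8) for _ in range(n_channels)) + _fixed("", 8)
    header += b"".join(_fixed(f"{v:.7g}", 8) for v in pmin) + _fixed("-1", 8)
    header += b"".join(_fixed(f"{v:.7g}", 8) for v in pmax) + _fixed("1", 8)
    header += b"".join(_fixed(str(_DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_fixed(str(_DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_fixed("", 80) for _ in range(ns))  # prefiltering
    header += b"".join(_fixed(str(fs), 8) for _ in range(n_channels))
    header += _fixed(str(ann_samples), 8)
    header += b"".join(_fixed("", 32) for _ in range(ns))

    path = Path(path)
    with path.open("wb") as fh:
        fh.write(bytes(header))
        for rec_idx in range(n_records):
            block = digital[:, rec_idx * fs : (rec_idx + 1) * fs]
            fh.write(block.tobytes(order="C"))
            tal = f"+{rec_idx}\x14\x14\x00".encode()
            for payload in ann.get(rec_idx, []):
                tal += payload + b"\x00"
            fh.write(tal.ljust(ann_samples * 2, b"\x00"))


def read_edf(path: str | Path, layout=None):
    """Read an EDF file written by :func:`write_edf` back into a recording.

    Parameters
    ----------
    path
        EDF file path.
    layout
        Electrode layout to attach. If omitted, the built-in layout whose
        label set matches the EDF channel labels is used.
    """
    import mne

    from . import montage
    from .synthdata import CapType, SegmentAnnotation, SegmentKind, SessionRecording

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise EdfFormatError(f"{path}: not a readable EDF file ({exc})") from exc

    labels = list(raw.ch_names)
    if layout is None:
        for kind in (montage.LayoutKind.TEN_TWENTY, montage.LayoutKind.EQUIDISTANT):
            candidate = montage.builtin_layout(kind)
            if candidate.labels == labels:
                layout = candidate
                break
        else:
            raise EdfFormatError(
                f"{path}: channel labels match no built-in layout; pass layout="
            )
    elif layout.labels != labels:
        raise EdfFormatError(f"{path}: channel labels do not match the given layout")

    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned channels
    fs = float(raw.info["sfreq"])

    segments: list[SegmentAnnotation] = []
    triggers: dict[str, list[float]] = {}
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if desc.startswith("seg:"):
            segments.append(
                SegmentAnnotation(SegmentKind(desc[4:]), float(onset), float(duration), ())
            )
        elif desc.startswith("trig:"):
            triggers.setdefault(desc[5:], []).append(float(onset))
    segments.sort(key=lambda s: s.start)
    segments = [
        SegmentAnnotation(
            s.kind, s.start, s.duration,
            tuple(t for t in sorted(triggers.get(s.kind.value, []))
                  if s.start - 1e-6 <= t <= s.start + s.duration + 1e-6),
        )
        for s in segments
    ]
    if segments:
        end = segments[-1].start + segments[-1].duration
        n_keep = int(round(end * fs))
        if 0 < n_keep <= data.shape[1]:
            data = data[:, :n_keep]

    # mne tokenizes the EDF patient field; read it verbatim from the header
    subject_id = "unknown"
    cap_type = CapType.GEL
    with path.open("rb") as fh:
        fh.seek(8)
        patient_field = fh.read(80).decode("ascii", errors="replace").split()
    if patient_field:
        subject_id = patient_field[0]
    for token in patient_field[1:]:
        if token.startswith("cap:"):
            cap_type = CapType(token[4:])
    return SessionRecording(
        subject_id=subject_id,
        cap_type=cap_type,
        layout=layout,
        data=data,
        sampling_rate=fs,
        segments=tuple(segments),
        true_bad_channels={},
    )
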