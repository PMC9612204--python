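"""Electrode layouts on the unit sphere.

Two 64-channel layouts are supported: an extended ten-twenty (10-10 subset)
layout and an equidistant layout, plus their 128-site union used as the common
interpolation target. The head is modeled as a unit sphere; all geometry is
expressed in unit position vectors with +x toward the right preauricular
point, +y toward the nasion and +z toward the vertex.

Ten-twenty positions follow the idealized spherical construction: each row
(Fp, AF, F, ... O) sits on the meridian through both preauricular points that
crosses the midline at the row's 10%-step arc angle, and the lateral index
(z, 1/2, 3/4, 5/6, 7/8) places the electrode at 0/18/36/54/72 degrees along
that meridian toward the ear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "LayoutKind",
    "ElectrodePosition",
    "ElectrodeLayout",
    "LayoutError",
    "builtin_layout",
    "combined_layout",
    "load_layout",
    "save_layout",
    "angular_distance",
]

_UNIT_TOL = 1e-9
_MIN_SEPARATION_RAD = 1e-6


class LayoutError(ValueError):
    """Malformed or inconsistent electrode layout."""


class LayoutKind(str, Enum):
    TEN_TWENTY = "ten_twenty"
    EQUIDISTANT = "equidistant"
    COMBINED = "combined"


@dataclass(frozen=True)
class ElectrodePosition:
    """A labeled electrode site on the unit sphere."""

    label: str
    position: np.ndarray  # shape (3,), unit norm

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise LayoutError(f"{self.label}: position must be a 3-vector")
        norm = float(np.linalg.norm(pos))
        if abs(norm - 1.0) > _UNIT_TOL:
            raise LayoutError(f"{self.label}: position norm {norm!r} is not 1")
        if not self.label:
            raise LayoutError("electrode label must be non-empty")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class ElectrodeLayout:
    """Ordered, duplicate-free set of electrode sites."""

    name: str
    kind: LayoutKind
    electrodes: tuple[ElectrodePosition, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = [e.label for e in self.electrodes]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise LayoutError(f"duplicate electrode labels: {dup}")
        n = len(self.electrodes)
        expected = {LayoutKind.TEN_TWENTY: 64, LayoutKind.EQUIDISTANT: 64, LayoutKind.COMBINED: 128}
        if n != expected[self.kind]:
            raise LayoutError(f"{self.kind.value} layout must have {expected[self.kind]} electrodes, got {n}")
        pos = self.positions
        dots = np.clip(pos @ pos.T, -1.0, 1.0)
        ang = np.arccos(dots)
        np.fill_diagonal(ang, np.inf)
        if float(ang.min()) < _MIN_SEPARATION_RAD:
            i, j = np.unravel_index(int(np.argmin(ang)), ang.shape)
            raise LayoutError(
                f"electrodes {labels[i]} and {labels[j]} are closer than "
                f"{_MIN_SEPARATION_RAD} rad"
            )
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(labels)})

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.electrodes]

    @property
    def positions(self) -> np.ndarray:
        """Positions as an (n, 3) array, in layout order."""
        return np.array([e.position for e in self.electrodes])

    def __len__(self) -> int:
        return len(self.electrodes)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise LayoutError(f"no electrode labeled {label!r} in layout {self.name}") from None


def angular_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Great-circle angle in radians between two unit vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for v in (p, q):
        if v.shape != (3,) or abs(float(np.linalg.norm(v)) - 1.0) > 1e-6:
            raise ValueError("angular_distance requires unit 3-vectors")
    return float(np.arccos(np.clip(float(p @ q), -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Ten-twenty construction
# ---------------------------------------------------------------------------

# Midline arc angle per row, degrees forward (+) / backward (-) of the vertex.
_ROW_ANGLE_DEG = {
    "Fp": 72.0, "AF": 54.0, "F": 36.0, "FC": 18.0, "C": 0.0,
    "CP": -18.0, "P": -36.0, "PO": -54.0, "O": -72.0,
}

# 64 labels of the extended ten-twenty layout used here, row by row.
_TEN_TWENTY_LABELS = (
    "Fp1 Fpz Fp2 "
    "AF7 AF3 AFz AF4 AF8 "
    "F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 "
    "T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 "
    "P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO5 PO3 POz PO4 PO6 PO8 "
    "O1 Oz O2 Iz"
).split()

# Row aliases for labels whose prefix differs from their geometric row.
_ROW_ALIAS = {"FT": "FC", "T": "C", "TP": "CP"}


def _ten_twenty_angles(label: str) -> tuple[float, float]:
    """(midline angle, signed lateral angle) in degrees for a 10-10 label."""
    if label == "Iz":
        return -90.0, 0.0
    head = "".join(ch for ch in label if not (ch.isdigit() or ch == "z"))
    tail = label[len(head):]
    row = _ROW_ALIAS.get(head, head)
    lam = _ROW_ANGLE_DEG[row]
    if tail == "z":
        return lam, 0.0
    num = int(tail)
    if head in ("FT", "T", "TP") or (head in ("F", "P") and num in (7, 8)):
        beta = 72.0
    elif head in ("AF", "PO") and num in (7, 8):
        beta = 72.0
    else:
        beta = {1: 18.0, 2: 18.0, 3: 36.0, 4: 36.0, 5: 54.0, 6: 54.0, 7: 72.0, 8: 72.0}[num]
    side = -1.0 if num % 2 == 1 else 1.0  # odd = left (-x)
    return lam, side * beta


def _sphere_point(midline_deg: float, lateral_deg: float) -> np.ndarray:
    lam = math.radians(midline_deg)
    beta = math.radians(abs(lateral_deg))
    m = np.array([0.0, math.sin(lam), math.cos(lam)])  # midline crossing
    ear = np.array([math.copysign(1.0, lateral_deg) if lateral_deg else 1.0, 0.0, 0.0])
    p = math.cos(beta) * m + math.sin(beta) * ear
    return p / np.linalg.norm(p)


def _build_ten_twenty() -> ElectrodeLayout:
    electrodes = [
        ElectrodePosition(lbl, _sphere_point(*_ten_twenty_angles(lbl)))
        for lbl in _TEN_TWENTY_LABELS
    ]
    return ElectrodeLayout("ten_twenty_64", LayoutKind.TEN_TWENTY, tuple(electrodes))


# ---------------------------------------------------------------------------
# Equidistant construction
# ---------------------------------------------------------------------------

# Polar ring angles (degrees from the vertex) and site counts; counts are
# roughly proportional to ring circumference, summing to 64, and the half-step
# offset keeps every site clear of the ten-twenty positions in the union.
_EQ_RINGS = ((81.0, 19), (63.0, 18), (45.0, 14), (27.0, 9), (9.0, 4))


def _build_equidistant() -> ElectrodeLayout:
    # Sites at azimuths k*360/count per ring; pairs (+/-az) are labeled
    # front-to-back, outermost ring first; midline sites (front, and back for
    # even counts) get their own Z counter.
    electrodes: list[ElectrodePosition] = []
    pair_idx = 0
    mid_idx = 0
    for theta, count in _EQ_RINGS:
        mid_idx += 1
        electrodes.append(ElectrodePosition(f"{mid_idx}Z", _eq_point(theta, 0.0)))
        for k in range(1, (count - 1) // 2 + 1):
            az = k * 360.0 / count
            pair_idx += 1
            electrodes.append(ElectrodePosition(f"{pair_idx}L", _eq_point(theta, -az)))
            electrodes.append(ElectrodePosition(f"{pair_idx}R", _eq_point(theta, az)))
        if count % 2 == 0:
            mid_idx += 1
            electrodes.append(ElectrodePosition(f"{mid_idx}Z", _eq_point(theta, 180.0)))
    return ElectrodeLayout("equidistant_64", LayoutKind.EQUIDISTANT, tuple(electrodes))


def _eq_point(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    th = math.radians(polar_deg)
    az = math.radians(azimuth_deg)  # 0 = front (+y), positive toward the right
    return np.array([math.sin(th) * math.sin(az), math.sin(th) * math.cos(az), math.cos(th)])


_BUILTIN_CACHE: dict[LayoutKind, ElectrodeLayout] = {}


def builtin_layout(kind: LayoutKind | str) -> ElectrodeLayout:
    """Return one of the two built-in 64-channel layouts.

    Parameters
    ----------
    kind
        ``"ten_twenty"`` or ``"equidistant"``.
    """
    kind = LayoutKind(kind)
    if kind is LayoutKind.COMBINED:
        raise ValueError("use combined_layout() to build the 128-site union")
    if kind not in _BUILTIN_CACHE:
        _BUILTIN_CACHE[kind] = (
            _build_ten_twenty() if kind is LayoutKind.TEN_TWENTY else _build_equidistant()
        )
    return _BUILTIN_CACHE[kind]


def combined_layout(a: ElectrodeLayout, b: ElectrodeLayout) -> ElectrodeLayout:
    """Union of two layouts by label: a's electrodes, then b's novel ones.

    Electrodes sharing a label must agree in position to 1e-6 rad.
    """
    electrodes = list(a.electrodes)
    for e in b.electrodes:
        if e.label in a:
            other = a.electrodes[a.index_of(e.label)]
            if angular_distance(e.position, other.position) > 1e-6:
                raise LayoutError(
                    f"label {e.label!r} appears in both layouts at conflicting positions"
                )
            continue
        electrodes.append(e)
    n = len(electrodes)
    kind = LayoutKind.COMBINED if n == 128 else (a.kind if n == len(a) else LayoutKind.COMBINED)
    if n == len(a) and all(x.label == y.label for x, y in zip(electrodes, a.electrodes)):
        return a
    return ElectrodeLayout(f"{a.name}+{b.name}", kind, tuple(electrodes))


# ---------------------------------------------------------------------------
# BIDS-style electrodes.tsv I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["name", "x", "y", "z"]


def load_layout(path: str | Path, kind: LayoutKind | str | None = None,
                name: str | None = None) -> ElectrodeLayout:
    """Load a layout from a BIDS-style electrodes.tsv (columns name, x, y, z).

    Positions are renormalized to unit length; row order is preserved. The
    layout kind is inferred from the electrode count unless given.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_COLUMNS)] != _TSV_COLUMNS:
            raise LayoutError(f"{path}: expected columns {_TSV_COLUMNS}, got {header}")
        electrodes: list[ElectrodePosition] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise LayoutError(f"{path}:{lineno}: expected 4 tab-separated fields")
            label = parts[0]
            try:
                vec = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise LayoutError(f"{path}:{lineno}: non-numeric coordinate") from exc
            norm = float(np.linalg.norm(vec))
            if norm < 1e-12:
                raise LayoutError(f"{path}:{lineno}: zero-norm position for {label!r}")
            electrodes.append(ElectrodePosition(label, vec / norm))
    if kind is None:
        kind = LayoutKind.COMBINED if len(electrodes) == 128 else LayoutKind.TEN_TWENTY
        if len(electrodes) == 64 and electrodes and electrodes[0].label[0].isdigit():
            kind = LayoutKind.EQUIDISTANT
    return ElectrodeLayout(name or path.stem, LayoutKind(kind), tuple(electrodes))


def save_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    """Write a layout as electrodes.tsv with 9-significant-digit coordinates."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for e in layout.electrodes:
            x, y, z = (f"{v:.9g}" for v in e.position)
            fh.write(f"{e.label}\t{x}\t{y}\t{z}\n")


def nearest_neighbor_angles(layout: ElectrodeLayout) -> np.ndarray:
    """Per-electrode nearest-neighbor great-circle angle, radians."""
    pos = layout.positions
    ang = np.arccos(np.clip(pos @ pos.T, -1.0, 1.0))
    np.fill_diagonal(ang, np.inf)
    return ang.min(axis=1)
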