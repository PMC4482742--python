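"""Digitized 3D fascicle architectures: parsing, geometry, summaries.

Manually digitized muscle architectures describe every fascicle as an
ordered polyline of 20 points (x, y, z in mm) plus origin/insertion
landmarks per animal.  This module reads and writes the plain-text
dialects such data ships in, computes fascicle lengths (arc and chord)
and pennation angles against the muscle's line of action (mean origin ->
mean insertion), and produces per-muscle summary statistics
(count, mean +/- SD of fascicle length and pennation angle).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Fascicle",
    "FascicleSet",
    "ArchitectureSummary",
    "FascicleFormatError",
    "read_fascicle_dataset",
    "write_fascicle_dataset",
    "read_landmarks",
    "fascicle_length",
    "chord_length",
    "line_of_action",
    "pennation_angle",
    "segmentwise_pennation",
    "resample_polyline",
    "summarize",
]

POINTS_PER_FASCICLE = 20


class FascicleFormatError(ValueError):
    """A fascicle dataset file cannot be parsed or fails validation."""


@dataclass
class Fascicle:
    """One digitized fascicle: an ordered (n, 3) polyline in mm."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise FascicleFormatError("fascicle points must be an (n, 3) array")

    def validate(self, strict: bool = True) -> None:
        n = len(self.points)
        if strict and n != POINTS_PER_FASCICLE:
            raise FascicleFormatError(
                f"fascicle {self.label or '?'} has {n} points, expected {POINTS_PER_FASCICLE}")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise FascicleFormatError(f"fascicle {self.label or '?'} has coincident consecutive points")


@dataclass
class FascicleSet:
    """All fascicles of one muscle/animal plus landmarks and metadata."""

    fascicles: list[Fascicle]
    origins: np.ndarray | None = None     # (n, 3) mm
    insertions: np.ndarray | None = None  # (n, 3) mm
    animal: str = ""
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fascicles)


@dataclass(frozen=True)
class ArchitectureSummary:
    count: int
    length_mean: float      # mm, arc length
    length_sd: float
    pennation_mean: float   # degrees
    pennation_sd: float


# -- geometry -----------------------------------------------------------------

def fascicle_length(f: Fascicle) -> float:
    """Arc length of the polyline (sum of consecutive point distances), mm."""
    return float(np.linalg.norm(np.diff(f.points, axis=0), axis=1).sum())


def chord_length(f: Fascicle) -> float:
    """Straight-line first-to-last point distance, mm."""
    return float(np.linalg.norm(f.points[-1] - f.points[0]))


def line_of_action(s: FascicleSet) -> np.ndarray:
    """Unit vector from the mean origin landmark to the mean insertion."""
    if s.origins is None or s.insertions is None or not len(s.origins) or not len(s.insertions):
        raise ValueError("origin and insertion landmarks required for the line of action")
    d = np.mean(np.atleast_2d(s.insertions), axis=0) - np.mean(np.atleast_2d(s.origins), axis=0)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("origin and insertion landmarks coincide")
    return d / n


def _angle_deg(u: np.ndarray, axis: np.ndarray) -> float:
    c = abs(float(np.dot(u, axis)) / (np.linalg.norm(u) * np.linalg.norm(axis)))
    return math.degrees(math.acos(min(1.0, c)))


def pennation_angle(f: Fascicle, axis: np.ndarray) -> float:
    """Angle (deg, in [0, 90]) between the fascicle chord and the axis."""
    chord = f.points[-1] - f.points[0]
    if np.linalg.norm(chord) == 0:
        raise ValueError("zero-length chord")
    return _angle_deg(chord, np.asarray(axis, dtype=float))


def segmentwise_pennation(f: Fascicle, axis: np.ndarray) -> float:
    """Length-weighted mean of per-segment angles (deg) — sensitivity variant."""
    axis = np.asarray(axis, dtype=float)
    segs = np.diff(f.points, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    angles = np.array([_angle_deg(s, axis) for s in segs])
    return float(np.average(angles, weights=lens))


def resample_polyline(points: np.ndarray, n: int = POINTS_PER_FASCICLE) -> np.ndarray:
    """Resample a polyline to n points equally spaced in arc length."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        raise ValueError("cannot resample a degenerate polyline")
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, pts[:, k]) for k in range(3)])


def summarize(s: FascicleSet, axis: np.ndarray | None = None) -> ArchitectureSummary:
    """Count and mean +/- sample SD of arc lengths and pennation angles."""
    if not len(s):
        raise ValueError("empty fascicle set")
    if axis is None:
        axis = line_of_action(s)
    lengths = np.array([fascicle_length(f) for f in s.fascicles])
    angles = np.array([pennation_angle(f, axis) for f in s.fascicles])
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return ArchitectureSummary(
        count=len(s), length_mean=float(lengths.mean()), length_sd=sd(lengths),
        pennation_mean=float(angles.mean()), pennation_sd=sd(angles))


# -- plain-text dialect -------------------------------------------------------

_NUM = r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?"
_ROW_RE = re.compile(rf"^\s*({_NUM})[,;\s]+({_NUM})[,;\s]+({_NUM})\s*$")
_IDX_ROW_RE = re.compile(rf"^\s*(\d+)[,;\s]+({_NUM})[,;\s]+({_NUM})[,;\s]+({_NUM})\s*$")


def _parse_rows(lines: list[str]):
    """Classify data lines into (kind, payload); kind in {'xyz','ixyz','blank'}."""
    out = []
    for ln_no, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].rstrip("\n")
        if not line.strip():
            out.append((ln_no, "blank", None))
            continue
        m = _IDX_ROW_RE.match(line)
        if m:
            out.append((ln_no, "ixyz", (int(m.group(1)),
                                        tuple(float(m.group(k)) for k in (2, 3, 4)))))
            continue
        m = _ROW_RE.match(line)
        if m:
            out.append((ln_no, "xyz", tuple(float(m.group(k)) for k in (1, 2, 3))))
            continue
        raise FascicleFormatError(f"line {ln_no}: cannot parse {raw.strip()!r}")
    return out


def read_fascicle_dataset(
    path: str | Path, strict: bool = True, label: str = "", animal: str = "",
) -> FascicleSet:
    """Read a digitized-fascicle text file into a FascicleSet.

    Layout is auto-detected in this order: blank-line-separated point
    blocks; a single run of rows grouped into fixed blocks of 20; rows
    with a leading integer index column grouping points per fascicle.
    Fascicles with a wrong point count raise (with line numbers) in strict
    mode and are resampled to 20 points along the polyline otherwise.
    """
    path = Path(path)
    rows = _parse_rows(path.read_text().splitlines())
    data_rows = [(n, k, v) for n, k, v in rows if k != "blank"]
    if not data_rows:
        raise FascicleFormatError(f"{path}: no fascicle data found")
    kinds = {k for _, k, _ in data_rows}
    blocks: list[tuple[int, list]] = []  # (start line, points)

    if kinds == {"ixyz"}:
        current_idx, pts, start = None, [], None
        for n, _, (idx, xyz) in data_rows:
            if idx != current_idx:
                if pts:
                    blocks.append((start, pts))
                current_idx, pts, start = idx, [], n
            pts.append(xyz)
        blocks.append((start, pts))
    elif kinds == {"xyz"}:
        data_pos = [i for i, (_, k, _) in enumerate(rows) if k != "blank"]
        has_blank_sep = any(
            k == "blank" for (_, k, _) in rows[data_pos[0]:data_pos[-1]])
        if has_blank_sep:
            pts, start = [], None
            for n, k, v in rows:
                if k == "xyz":
                    if not pts:
                        start = n
                    pts.append(v)
                elif pts:
                    blocks.append((start, pts))
                    pts = []
            if pts:
                blocks.append((start, pts))
        else:
            if len(data_rows) % POINTS_PER_FASCICLE != 0:
                raise FascicleFormatError(
                    f"{path}: {len(data_rows)} rows not divisible into "
                    f"{POINTS_PER_FASCICLE}-point fascicles and no other layout detected")
            for i in range(0, len(data_rows), POINTS_PER_FASCICLE):
                chunk = data_rows[i:i + POINTS_PER_FASCICLE]
                blocks.append((chunk[0][0], [v for _, _, v in chunk]))
    else:
        raise FascicleFormatError(f"{path}: mixed row layouts, dialect undetectable")

    fascicles = []
    for fi, (start, pts) in enumerate(blocks):
        arr = np.asarray(pts, dtype=float)
        if len(arr) != POINTS_PER_FASCICLE:
            if strict:
                raise FascicleFormatError(
                    f"{path}: fascicle #{fi + 1} starting at line {start} has "
                    f"{len(arr)} points, expected {POINTS_PER_FASCICLE}")
            arr = resample_polyline(arr, POINTS_PER_FASCICLE)
        f = Fascicle(points=arr, label=label or path.stem)
        f.validate(strict=False)
        fascicles.append(f)
    if not fascicles:
        raise FascicleFormatError(f"{path}: no fascicles parsed")
    return FascicleSet(fascicles=fascicles, animal=animal)


def write_fascicle_dataset(s: FascicleSet, path: str | Path) -> None:
    """Write blank-line-separated 20-row blocks (round-trips bit-exactly
    through :func:`read_fascicle_dataset` at full float precision)."""
    lines = []
    for f in s.fascicles:
        for x, y, z in f.points:
            lines.append(f"{float(x)!r} {float(y)!r} {float(z)!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    """Read an origins/insertions file: lines of ``label x y z``.

    Returns a mapping from lower-cased label to an (n, 3) array; labels
    containing 'origin'/'insertion' can be passed straight into a
    FascicleSet.
    """
    out: dict[str, list] = {}
    for ln_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = re.split(r"[,;\s]+", line)
        if len(parts) < 4:
            raise FascicleFormatError(f"line {ln_no}: expected 'label x y z'")
        label = " ".join(parts[:-3]).lower()
        try:
            xyz = [float(v) for v in parts[-3:]]
        except ValueError as exc:
            raise FascicleFormatError(f"line {ln_no}: bad coordinates") from exc
        out.setdefault(label, []).append(xyz)
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}
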