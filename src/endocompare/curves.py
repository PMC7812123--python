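"""Labeled sulcal curves: the data model, file format, and label assignment.

A :class:`LabeledCurve` is an ordered 3D polyline in world millimetres with a
free-text sulcus label (e.g. ``"central"``, ``"lunate"``), a side, and a
strength (mean absolute principal curvature along the curve, 1/mm).  A
:class:`CurveSet` groups curves from one surface (brain hull or endocast).

Sulci on real surfaces are frequently incomplete or split into several
fragments, so many curves may legitimately share one label; all matching
statistics treat same-label fragments jointly.

The on-disk format is versioned JSON; round-trips are lossless (coordinates
to full float precision, labels exact).  Unknown extra fields are ignored
with a logged warning so the format can grow.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import min_distance_to_polylines, polyline_length

logger = logging.getLogger(__name__)

FORMAT_NAME = "endocompare-curves"
FORMAT_VERSION = 1

SIDES = ("left", "right", "midline", "unassigned")
UNLABELED = "unlabeled"

_KNOWN_CURVE_FIELDS = {"points", "label", "side", "strength"}


class CurveFileError(ValueError):
    """Raised when a curve file cannot be parsed; names the offending record."""


@dataclass
class LabeledCurve:
    """An ordered polyline on a surface with a sulcus label."""

    points: np.ndarray
    label: str = UNLABELED
    side: str = "unassigned"
    strength: float = 0.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("curve points must be an (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("a curve needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive curve points must be distinct")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def length(self) -> float:
        return polyline_length(self.points)

    def with_label(self, label: str, side: str | None = None) -> "LabeledCurve":
        return replace(self, label=label, side=self.side if side is None else side)


@dataclass
class CurveSet:
    """A collection of labeled curves from one surface."""

    curves: list[LabeledCurve] = field(default_factory=list)
    source: str = ""  # "brain-hull" | "endocast" | ""

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    def __getitem__(self, i: int) -> LabeledCurve:
        return self.curves[i]

    def labels(self, include_unlabeled: bool = False) -> list[str]:
        """Distinct labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.curves:
            if c.label == UNLABELED and not include_unlabeled:
                continue
            seen.setdefault(c.label, None)
        return list(seen)

    def with_label(self, label: str) -> list[LabeledCurve]:
        return [c for c in self.curves if c.label == label]


def load_vocabulary() -> list[str]:
    """Sulcus label vocabulary shipped with the package (one name per line)."""
    text = resources.files("endocompare.data").joinpath("sulcus_vocabulary.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def write_curves(curves: CurveSet, path: str | Path) -> None:
    doc = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "source": curves.source,
        "curves": [
            {
                "label": c.label,
                "side": c.side,
                "strength": float(c.strength),
                "points": c.points.tolist(),
            }
            for c in curves.curves
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_curves(path: str | Path) -> CurveSet:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise CurveFileError(f"{path}: not valid JSON ({e})") from e
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_NAME:
        raise CurveFileError(f"{path}: missing '{FORMAT_NAME}' format header")
    if doc.get("version") != FORMAT_VERSION:
        raise CurveFileError(f"{path}: unsupported version {doc.get('version')!r}")
    out = []
    for i, rec in enumerate(doc.get("curves", [])):
        if not isinstance(rec, dict) or "points" not in rec:
            raise CurveFileError(f"{path}: curve record {i} has no 'points'")
        extras = set(rec) - _KNOWN_CURVE_FIELDS
        if extras:
            logger.warning("%s: curve record %d: ignoring unknown fields %s", path, i, sorted(extras))
        try:
            out.append(
                LabeledCurve(
                    points=np.asarray(rec["points"], dtype=float),
                    label=rec.get("label", UNLABELED),
                    side=rec.get("side", "unassigned"),
                    strength=float(rec.get("strength", 0.0)),
                )
            )
        except (ValueError, TypeError) as e:
            raise CurveFileError(f"{path}: curve record {i} invalid: {e}") from e
    return CurveSet(curves=out, source=doc.get("source", ""))


def mean_distance_to_reference(curve: LabeledCurve, reference: LabeledCurve) -> float:
    """Mean over ``curve`` points of the distance to the ``reference`` polyline."""
    return float(np.mean(min_distance_to_polylines(curve.points, [reference.points])))


def _overlap_length(curve: LabeledCurve, reference: LabeledCurve, radius: float) -> float:
    """Arc length of ``curve`` lying within ``radius`` of ``reference``."""
    d = min_distance_to_polylines(curve.points, [reference.points])
    seg = np.linalg.norm(np.diff(curve.points, axis=0), axis=1)
    near = (d[:-1] <= radius) & (d[1:] <= radius)
    return float(seg[near].sum())


def label_by_reference(
    detected: CurveSet, reference: CurveSet, max_assign_dist: float
) -> CurveSet:
    """Assign each detected curve the label of its nearest reference curve.

    The nearest reference is the one minimising the mean closest-point
    distance from the detected curve's points to the reference polyline; the
    assignment is made only if that distance is at most ``max_assign_dist``
    (otherwise the curve stays ``"unlabeled"``).  Several detected fragments
    may end up sharing one label.  Ties are broken by larger overlap length
    with the detected curve, then lexicographically by label, so the result
    is deterministic and independent of input curve order.

    Curve geometry is never modified.
    """
    if len(reference) == 0:
        raise ValueError("reference curve set is empty")
    out = []
    for c in detected:
        best: tuple[float, float, str] | None = None  # (dist, -overlap, label)
        best_ref: LabeledCurve | None = None
        for ref in reference:
            d = mean_distance_to_reference(c, ref)
            key = (d, -_overlap_length(c, ref, max_assign_dist), ref.label)
            if best is None or key < best:
                best, best_ref = key, ref
        if best is not None and best[0] <= max_assign_dist and best_ref is not None:
            out.append(c.with_label(best_ref.label, side=best_ref.side))
        else:
            out.append(c.with_label(UNLABELED))
    return CurveSet(curves=out, source=detected.source)
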