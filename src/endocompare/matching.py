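"""Curve-matching statistics between an endocast and a deformed brain hull.

This module implements the study's quantitative core.  After the brain hull
has been registered to the endocast and its sulcal curves transported, each
endocast curve is compared to the same-label curves of the brain hull: the
curve distance is the mean, over the endocast curve's points, of the distance
to the closest point on any same-label brain curve (point-to-segment, so the
value does not depend on sampling density).  An endocast sulcus counts as
*found* in the brain when this mean distance is strictly less than a
threshold tau (default 10 mm — roughly the maximum distance between two
neighbouring sulci, so a larger distance would sooner indicate a different
sulcus than a displaced one).

The summary counts follow the conventional notation:

=======  ==========================================================
TC-E     total curves identified in the endocast
TC-B     total curves identified in the brain hull
NC-EB    endocast curves found in the brain hull (mean distance < tau)
NS-EB    endocast curves with no corresponding brain-hull curve
NS-E     distinct sulci (labels) identified in the endocast
NS-B     distinct sulci (labels) identified in the brain hull
=======  ==========================================================

Two scalar maps support visual interpretation: a distance map extrapolating
per-curve mean distances over the endocast surface, and a displacement map of
closest-point distances from the endocast to the deformed brain hull.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import UNLABELED, CurveSet, LabeledCurve
from .geometry import SurfaceDistanceQuery, min_distance_to_polylines

DEFAULT_TAU_MM = 10.0

COUNT_COLUMNS = ["TC-E", "NS-E", "TC-B", "NS-B", "NC-EB", "NS-EB"]


@dataclass
class CurveMatch:
    """Matching outcome for one endocast curve."""

    curve_id: int
    label: str
    mean_distance: float | None  # None when no same-label brain curve exists
    matched: bool


@dataclass
class MatchReport:
    """Per-curve distances and the six summary counts for one individual."""

    per_curve: list[CurveMatch]
    TC_E: int
    NS_E: int
    TC_B: int
    NS_B: int
    NC_EB: int
    NS_EB: int
    tau: float = DEFAULT_TAU_MM
    name: str = ""

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not (
            self.NC_EB <= self.TC_E
            and self.NC_EB + self.NS_EB <= self.TC_E
            and self.NS_E <= self.TC_E
            and self.NS_B <= self.TC_B
        ):
            raise ValueError("inconsistent match counts")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "TC-E": self.TC_E,
            "NS-E": self.NS_E,
            "TC-B": self.TC_B,
            "NS-B": self.NS_B,
            "NC-EB": self.NC_EB,
            "NS-EB": self.NS_EB,
        }

    @property
    def matched_fraction(self) -> float:
        """NC-EB / TC-E (0 when the endocast set is empty)."""
        return self.NC_EB / self.TC_E if self.TC_E else 0.0


@dataclass
class ScalarField:
    """Per-vertex scalar (mm) on a mesh, with a mask for 'not found' vertices."""

    values: np.ndarray
    mask: np.ndarray  # True where the value is defined

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have equal shape")
        v = self.values[self.mask]
        if v.size and (not np.all(np.isfinite(v)) or np.any(v < 0)):
            raise ValueError("unmasked values must be finite and non-negative")


def curve_distance(endo_curve: LabeledCurve, brain_curves: CurveSet | list[LabeledCurve]) -> float | None:
    """Mean distance from an endocast curve to same-label brain-hull curves.

    For each point of the endocast curve, take the distance to the closest
    point of *any* of the given brain curves (all fragments carrying the same
    label are used jointly); return the mean of those distances.  Returns
    ``None`` when ``brain_curves`` is empty.  The measure is directional:
    endocast -> brain.
    """
    curves = list(brain_curves)
    if any(c.label != endo_curve.label for c in curves):
        raise ValueError("brain curves must share the endocast curve's label")
    if not curves:
        return None
    d = min_distance_to_polylines(endo_curve.points, [c.points for c in curves])
    return float(d.mean())


def match_curves(
    endo: CurveSet, brain_deformed: CurveSet, tau: float = DEFAULT_TAU_MM
) -> MatchReport:
    """Apply the strict-tau matching criterion to every endocast curve.

    A curve is matched iff a same-label brain curve exists and the mean
    distance is strictly below ``tau`` (a distance of exactly ``tau`` is not
    a match).  Curves labeled ``"unlabeled"`` on either side never match and
    are counted only in the totals.
    """
    per_curve = []
    n_matched = 0
    for i, c in enumerate(endo):
        brain_same = brain_deformed.with_label(c.label) if c.label != UNLABELED else []
        d = curve_distance(c, brain_same)
        matched = d is not None and d < tau
        n_matched += matched
        per_curve.append(CurveMatch(curve_id=i, label=c.label, mean_distance=d, matched=matched))
    return MatchReport(
        per_curve=per_curve,
        TC_E=len(endo),
        NS_E=len(endo.labels()),
        TC_B=len(brain_deformed),
        NS_B=len(brain_deformed.labels()),
        NC_EB=n_matched,
        NS_EB=len(endo) - n_matched,
        tau=tau,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize(reports: list[MatchReport | dict]) -> pd.DataFrame:
    """Summary table: one row per individual, a mean row, and matched ratios.

    Accepts :class:`MatchReport` objects or plain dicts with the six count
    columns (so published per-individual counts can be fed in directly).
    The mean row is the arithmetic column mean rounded half-up to an integer,
    matching the convention of printing integer counts; ``ratio`` is
    NC-EB / TC-E per row, and its mean-row entry is the mean of the
    per-row ratios (not the ratio of the means).
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for i, r in enumerate(reports):
        counts = r.counts if isinstance(r, MatchReport) else {k: int(r[k]) for k in COUNT_COLUMNS}
        name = (r.name or f"I{i + 1}") if isinstance(r, MatchReport) else str(r.get("name", f"I{i + 1}"))
        rows.append({"specimen": name, **{k: counts[k] for k in COUNT_COLUMNS}})
    df = pd.DataFrame(rows)
    df["ratio"] = df["NC-EB"] / df["TC-E"]
    mean_row = {"specimen": "Mean"}
    for k in COUNT_COLUMNS:
        mean_row[k] = _round_half_up(df[k].mean())
    mean_row["ratio"] = float(df["ratio"].mean())
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def distance_field(
    endocast_mesh,
    report: MatchReport,
    endo_curves: CurveSet,
    influence_radius: float = DEFAULT_TAU_MM,
) -> ScalarField:
    """Extrapolate per-curve mean distances over the endocast surface.

    Each vertex within ``influence_radius`` of at least one *matched* curve
    receives an inverse-distance-weighted blend of the nearby curves' mean
    distances, so values never overshoot the input range.  Vertices whose
    nearest curve is unmatched are sentinel-masked ("sulcus not found"), as
    are vertices beyond the influence radius of every curve.
    """
    verts = np.asarray(endocast_mesh.vertices, dtype=float)
    n = len(verts)
    entries = [
        (m, min_distance_to_polylines(verts, [endo_curves[m.curve_id].points]))
        for m in report.per_curve
        if m.mean_distance is not None or not m.matched
    ]
    if not entries:
        return ScalarField(values=np.zeros(n), mask=np.zeros(n, dtype=bool))

    dists = np.stack([d for _, d in entries])  # (n_curves, n_verts)
    matched = np.array([m.matched for m, _ in entries])
    values = np.array([m.mean_distance if m.mean_distance is not None else np.inf for m, _ in entries])

    nearest = dists.argmin(axis=0)
    nearest_unmatched = ~matched[nearest]

    out = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    if matched.any():
        dm = dists[matched]  # (n_matched, n_verts)
        vm = values[matched]
        within = dm <= influence_radius
        eps = 1e-9
        w = np.where(within, 1.0 / (dm + eps), 0.0)
        wsum = w.sum(axis=0)
        ok = (wsum > 0) & ~nearest_unmatched
        out[ok] = (w[:, ok] * vm[:, None]).sum(axis=0) / wsum[ok]
        mask[ok] = True
    return ScalarField(values=np.where(mask, out, np.nan), mask=mask)


def displacement_map(
    deformed_brain_hull, endocast, render_clip: float = 5.0
) -> tuple[ScalarField, ScalarField]:
    """Closest-point distance from each endocast vertex to the deformed hull.

    Distances are exact point-to-triangle (not vertex-to-vertex).  Returns
    ``(raw, clipped)`` where ``clipped`` is min(raw, render_clip) for
    rendering on a fixed 0..render_clip colour scale.
    """
    q = SurfaceDistanceQuery(
        np.asarray(deformed_brain_hull.vertices, dtype=float),
        np.asarray(deformed_brain_hull.faces, dtype=np.int64),
    )
    _, d = q.query(np.asarray(endocast.vertices, dtype=float))
    mask = np.ones(len(d), dtype=bool)
    return (
        ScalarField(values=d, mask=mask),
        ScalarField(values=np.minimum(d, render_clip), mask=mask),
    )
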