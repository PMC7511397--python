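"""DNA bend-angle measurement by tangent (or secant) overlay.

The bend angle Theta at an arc position s0 on a traced DNA backbone is
defined as the deviation from straight: Theta = 180 deg - Phi, where Phi is
the angle between a tangent placed at arc s0 - q (oriented toward
decreasing arc) and a tangent at s0 + q (oriented toward increasing arc);
q is the query-point distance, which must extend past the protein radius
because the backbone under a bound protein is only extrapolated by the
skeleton. In secant mode the two lines instead connect P(s0 +/- q) with
P(s0); on a circular arc the secant angle at q equals the tangent angle at
q/2. Angles are unsigned, in [0, 180].
"""

from __future__ import annotations

import dataclasses
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .image_ops import ComponentStats
from .tracing import FilamentTrace

__all__ = ["AngleQuery", "ComplexSite", "bend_angle_at", "assign_proteins"]

ExclusionReason = Literal["none", "at_end", "too_close_pair", "off_dna",
                          "aggregate", "ambiguous"]


@dataclasses.dataclass
class AngleQuery:
    """Where and how tangents are placed around a measurement site.

    ``tangent_window_nm`` is the half-length of the chord used to estimate
    each tangent direction: a chord over +/- 2 nm averages out sub-node
    interpolation wiggle of the spline-stage trace without touching the
    signal (on a circular arc a symmetric chord has exactly the tangent
    direction of its midpoint, and a kink one query distance away is
    outside the window).
    """

    query_distance_nm: float = 8.0
    geometry: Literal["tangent", "secant"] = "tangent"
    tangent_window_nm: float = 2.0

    def __post_init__(self) -> None:
        if self.query_distance_nm <= 0:
            raise ValueError("query_distance_nm must be positive")
        if not 0 < self.tangent_window_nm <= self.query_distance_nm:
            raise ValueError("tangent_window_nm must be in "
                             "(0, query_distance_nm]")


@dataclasses.dataclass
class ComplexSite:
    """A protein peak assigned to an arc position on a trace."""

    trace_id: int
    arc_position_nm: float
    protein_centroid_nm: Tuple[float, float]
    distance_to_trace_nm: float
    bend_angle_deg: Optional[float] = None
    exclusion_reason: ExclusionReason = "none"


def _tangent(points: np.ndarray, i: int, half_window: int) -> np.ndarray:
    """Unit tangent at node i toward increasing arc (symmetric chord)."""
    lo = max(0, i - half_window)
    hi = min(points.shape[0] - 1, i + half_window)
    v = points[hi] - points[lo]
    return v / np.linalg.norm(v)


def bend_angle_at(trace: FilamentTrace, s0_nm: float,
                  query: AngleQuery = AngleQuery()) -> float:
    """Bend angle Theta = 180 - Phi (degrees) at arc position s0.

    The trace must be finely sampled (spline stage, ~0.1 nm) so tangents
    from adjacent nodes are smooth. Raises if the query window
    [s0 - q, s0 + q] leaves the trace; callers exclude end-bound sites.
    """
    q = query.query_distance_nm
    ds = trace.node_spacing_nm
    L = trace.contour_length_nm
    if s0_nm - q < 0 or s0_nm + q > L:
        raise ValueError("query window extends beyond the trace")
    pts = trace.points
    i0 = int(round(s0_nm / ds))
    im = int(round((s0_nm - q) / ds))
    ip = int(round((s0_nm + q) / ds))
    if query.geometry == "tangent":
        w = max(1, int(round(query.tangent_window_nm / ds)))
        u = -_tangent(pts, im, w)       # toward decreasing arc
        v = _tangent(pts, ip, w)        # toward increasing arc
    else:
        u = pts[im] - pts[i0]
        v = pts[ip] - pts[i0]
        u = u / np.linalg.norm(u)
        v = v / np.linalg.norm(v)
    phi = np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))
    return float(180.0 - phi)


def assign_proteins(peaks: Sequence[ComponentStats],
                    traces: Sequence[FilamentTrace],
                    protein_radius_nm: float, dna_radius_nm: float,
                    query: AngleQuery = AngleQuery(),
                    spacing_min_nm: float = 50.0,
                    tie_tolerance_nm: float = 0.1) -> List[ComplexSite]:
    """Assign protein peaks to DNA traces and measure their bend angles.

    A peak is DNA-bound when its distance to the nearest trace point is at
    most protein_radius + dna_radius (the sum of the two radii). Exclusions
    are recorded, never raised: `off_dna` (too far from any trace),
    `ambiguous` (equidistant from two traces within ``tie_tolerance_nm``),
    `at_end` (closer than the query distance to a trace end, where no
    tangent pair exists), and `too_close_pair` (two bound proteins on one
    trace nearer than ``spacing_min_nm``; both are dropped to avoid
    interference between neighbouring bends).
    """
    if protein_radius_nm <= 0 or dna_radius_nm <= 0:
        raise ValueError("radii must be positive")
    cutoff = protein_radius_nm + dna_radius_nm
    trees = [cKDTree(t.points) for t in traces]
    sites: List[ComplexSite] = []
    for pk in peaks:
        c = np.asarray(pk.centroid_nm)
        if not trees:
            sites.append(ComplexSite(-1, np.nan, tuple(c), np.inf,
                                     exclusion_reason="off_dna"))
            continue
        dists, idxs = zip(*(tr.query(c) for tr in trees))
        order = np.argsort(dists)
        best = int(order[0])
        d_best = float(dists[best])
        site = ComplexSite(
            trace_id=traces[best].trace_id,
            arc_position_nm=float(idxs[best] * traces[best].node_spacing_nm),
            protein_centroid_nm=(float(c[0]), float(c[1])),
            distance_to_trace_nm=d_best)
        if d_best > cutoff:
            site.exclusion_reason = "off_dna"
        elif (len(order) > 1
              and float(dists[int(order[1])]) - d_best < tie_tolerance_nm
              and float(dists[int(order[1])]) <= cutoff):
            site.exclusion_reason = "ambiguous"
        else:
            L = traces[best].contour_length_nm
            s = site.arc_position_nm
            if s < query.query_distance_nm or s > L - query.query_distance_nm:
                site.exclusion_reason = "at_end"
        sites.append(site)

    # 50 nm spacing rule: drop both members of any close bound pair
    by_trace: dict = {}
    for site in sites:
        if site.exclusion_reason == "none":
            by_trace.setdefault(site.trace_id, []).append(site)
    for group in by_trace.values():
        group.sort(key=lambda s: s.arc_position_nm)
        close = set()
        for a, b in zip(group, group[1:]):
            if b.arc_position_nm - a.arc_position_nm < spacing_min_nm:
                close.update((id(a), id(b)))
        for site in group:
            if id(site) in close:
                site.exclusion_reason = "too_close_pair"

    trace_by_id = {t.trace_id: t for t in traces}
    for site in sites:
        if site.exclusion_reason == "none":
            site.bend_angle_deg = bend_angle_at(
                trace_by_id[site.trace_id], site.arc_position_nm, query)
    return sites
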