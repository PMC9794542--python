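"""Deployment validation metrics.

The deployed configuration of a stent is scored ring by ring: a
periodic cubic spline is fitted through the apexes of each ring, the
area enclosed by the spline (the ring opening area, OA) is evaluated in
the ring's best-fit plane, and per-ring OA percentage errors against a
reference configuration are summarised as mean +- sd [min; max].  Strut
alignment is scored with the maximum distance between corresponding
strut polylines, and the overall deployed length along the vessel
centerline completes the picture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .contact import polyline_project
from .geometry import BeamMesh, RingSpec, ring_apex_nodes

__all__ = [
    "RingApexSet",
    "OAResult",
    "extract_apexes",
    "opening_area",
    "oa_percent_error",
    "max_strut_distance",
    "deployed_length",
]


@dataclass
class RingApexSet:
    """Ordered apex points of one stent ring (one closed contour)."""

    ring_id: int
    points: np.ndarray            # (n, 3), ordered by angle
    source: str = "simulation"    # "simulation" | "reference"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if len(self.points) < 4:
            raise ValueError("an apex set needs at least 4 points")


@dataclass
class OAResult:
    """Per-ring opening areas and error statistics (absolute % errors)."""

    ring_ids: List[int]
    areas: np.ndarray             # mm^2
    reference_areas: np.ndarray   # mm^2
    percent_errors: np.ndarray    # absolute values

    @property
    def summary(self) -> Dict[str, float]:
        e = self.percent_errors
        return {
            "mean": float(e.mean()), "sd": float(e.std(ddof=0)),
            "min": float(e.min()), "max": float(e.max()),
            "oa_mean": float(self.areas.mean()),
            "oa_sd": float(self.areas.std(ddof=0)),
            "oa_min": float(self.areas.min()),
            "oa_max": float(self.areas.max()),
        }


def _best_fit_plane(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """PCA plane: returns (centroid, orthonormal in-plane basis (2, 3))."""
    c = points.mean(axis=0)
    u, s, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt[:2]


def _order_by_angle(points: np.ndarray) -> np.ndarray:
    c, basis = _best_fit_plane(points)
    xy = (points - c) @ basis.T
    ang = np.arctan2(xy[:, 1], xy[:, 0])
    return np.argsort(ang)


def extract_apexes(stent: BeamMesh, positions: np.ndarray, ring_id: int,
                   spec: RingSpec, side: str = "proximal",
                   thin_samples: int = 16) -> RingApexSet:
    """Apex points of a deployed ring.

    Apexes are taken at the nodes meshed as local axial extrema of the
    wire (node identity is preserved by the Lagrangian mesh, so the
    undeformed extrema remain the apexes after deployment).  The thin
    ring, a plane circle, is sampled uniformly instead.
    """
    if spec.kind == "thin":
        idx = stent.ring_nodes(ring_id)
        step = max(1, len(idx) // thin_samples)
        pts = positions[idx[::step]]
    else:
        nodes = ring_apex_nodes(stent, ring_id, spec, side=side)
        pts = positions[nodes]
    order = _order_by_angle(pts)
    return RingApexSet(ring_id, pts[order])


def opening_area(apexes: RingApexSet, n_resample: int = 1000) -> float:
    """Area enclosed by a periodic cubic spline through the apexes [mm^2].

    The apex points are projected on their PCA best-fit plane, a
    periodic cubic spline is fitted through them (chord-length
    parametrised) and the enclosed area is evaluated with Green's
    theorem on an ``n_resample``-point polygon.
    """
    pts = apexes.points
    c, basis = _best_fit_plane(pts)
    xy = (pts - c) @ basis.T
    closed = np.vstack([xy, xy[:1]])
    t = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(closed, axis=0), axis=1))])
    if t[-1] <= 0:
        raise ValueError("degenerate apex set")
    sp = CubicSpline(t, closed, bc_type="periodic")
    tt = np.linspace(0.0, t[-1], n_resample, endpoint=False)
    p = sp(tt)
    x, y = p[:, 0], p[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    area = float(abs(area))
    if area <= 0:
        raise ValueError("self-intersecting or degenerate apex spline")
    return area


def oa_percent_error(sim: Sequence[RingApexSet],
                     ref: Sequence[RingApexSet]) -> OAResult:
    """Per-ring |OA_sim - OA_ref| / OA_ref x 100 with summary statistics."""
    ref_by_id = {a.ring_id: a for a in ref}
    ids, a_sim, a_ref = [], [], []
    for a in sim:
        if a.ring_id not in ref_by_id:
            raise ValueError(f"reference misses ring {a.ring_id}")
        ids.append(a.ring_id)
        a_sim.append(opening_area(a))
        a_ref.append(opening_area(ref_by_id[a.ring_id]))
    a_sim = np.array(a_sim)
    a_ref = np.array(a_ref)
    err = np.abs(a_sim - a_ref) / a_ref * 100.0
    return OAResult(ids, a_sim, a_ref, err)


def max_strut_distance(sim_polyline: np.ndarray,
                       ref_polyline: np.ndarray) -> float:
    """One-sided Hausdorff distance between strut polylines [mm].

    Maximum over simulation vertices of the distance to the nearest
    point of the reference polyline (segments included).
    """
    sim_polyline = np.asarray(sim_polyline, float)
    ref_polyline = np.asarray(ref_polyline, float)
    if len(sim_polyline) == 0 or len(ref_polyline) == 0:
        raise ValueError("empty polyline")
    if len(ref_polyline) == 1:
        d = np.linalg.norm(sim_polyline - ref_polyline[0], axis=1)
        return float(d.max())
    closest, _, _ = polyline_project(ref_polyline, sim_polyline)
    return float(np.max(np.linalg.norm(sim_polyline - closest, axis=1)))


def deployed_length(stent: BeamMesh, positions: np.ndarray,
                    centerline: Optional[np.ndarray] = None) -> float:
    """Axial extent of the deployed stent [mm].

    With a centerline, the extent is measured in arc length between the
    most proximal and most distal stent node projections (>= the chord
    for a curved vessel); otherwise plain z extent.
    """
    if centerline is None:
        z = positions[:, 2]
        return float(z.max() - z.min())
    _, _, s = polyline_project(np.asarray(centerline, float), positions)
    return float(s.max() - s.min())
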