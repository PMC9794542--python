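"""Penalty contact with rigid analytic surfaces and beam self-contact.

Surfaces are rigid planes and tubes (inner/outer) with prescribed
motion over pseudo-time; deformable nodes are pushed out of penetration
by a linear penalty force and resisted tangentially by Coulomb friction
with an elastic-predictor / slip-return (anchor) scheme.  The crimping
bench is modelled exactly as in the simulated experiment: 12 rigid
planes tangent to the commanded cylinder at 30 degree increments, the
radial force being the sum of the 12 plane contributions.

Beam wires additionally carry a sphere-swept segment-segment
self-contact at the wire radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .fe_core import DynamicState, StructuralModel

__all__ = [
    "ContactRecord",
    "RigidPlane",
    "Crimper",
    "Tube",
    "BeamSelfContact",
    "ContactSet",
    "total_radial_force",
    "polyline_arclength",
    "polyline_project",
]


@dataclass
class ContactRecord:
    """Resultant of one surface for one evaluation."""

    name: str
    normal_force: float                   # resultant normal force [N]
    penetration: np.ndarray               # per contacting node [mm]
    n_active: int


def total_radial_force(records: Sequence[ContactRecord]) -> float:
    """Global radial force of a 12-plane crimper: sum of plane forces."""
    if len(records) != 12:
        raise ValueError(f"expected 12 plane records, got {len(records)}")
    return float(sum(r.normal_force for r in records))


# ---------------------------------------------------------------------------
# centerline helpers
# ---------------------------------------------------------------------------

def polyline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_project(points: np.ndarray, x: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest points on a polyline for query points ``x``.

    Returns (closest, tangent, arclength) arrays; vectorised over both
    query points and segments.
    """
    a = points[:-1]                       # (S, 3)
    d = np.diff(points, axis=0)           # (S, 3)
    L2 = np.sum(d * d, axis=1)
    w = x[:, None, :] - a[None, :, :]     # (N, S, 3)
    t = np.clip(np.einsum("nsk,sk->ns", w, d) / L2, 0.0, 1.0)
    proj = a[None] + t[..., None] * d[None]
    dist2 = np.sum((x[:, None, :] - proj) ** 2, axis=2)
    best = np.argmin(dist2, axis=1)
    n = np.arange(len(x))
    closest = proj[n, best]
    tangent = d[best] / np.sqrt(L2[best])[:, None]
    s0 = polyline_arclength(points)
    s = s0[best] + t[n, best] * np.sqrt(L2[best])
    return closest, tangent, s


# ---------------------------------------------------------------------------
# rigid surfaces
# ---------------------------------------------------------------------------

class _FrictionState:
    """Per-node tangential anchors of the stick-slip return mapping."""

    def __init__(self, n_nodes: int) -> None:
        self.anchor = np.zeros((n_nodes, 3))
        self.active = np.zeros(n_nodes, bool)


class RigidPlane:
    """Half-space contact: nodes are kept on the inner side of the plane.

    ``normal`` points from the admissible region towards the plane; a
    node with (x . normal) + r_node > offset(t) penetrates.  ``motion``
    maps pseudo-time to the plane offset along the normal [mm].
    """

    def __init__(self, normal: np.ndarray, motion: Callable[[float], float],
                 penalty_stiffness, mu: float = 0.0, name: str = "plane",
                 nodes: Optional[np.ndarray] = None) -> None:
        self.normal = np.asarray(normal, float)
        self.normal /= np.linalg.norm(self.normal)
        self.motion = motion
        self.k = penalty_stiffness
        if np.any(np.asarray(penalty_stiffness) <= 0):
            raise ValueError("penalty_stiffness must be positive")
        self.mu = mu
        self.name = name
        self.nodes = nodes          # optional node subset
        self._fric: Optional[_FrictionState] = None
        self.record: Optional[ContactRecord] = None

    def forces(self, x: np.ndarray, node_radius: np.ndarray, t: float
               ) -> Tuple[np.ndarray, float]:
        n_all = len(x)
        if self._fric is None:
            self._fric = _FrictionState(n_all)
        idx = self.nodes if self.nodes is not None else slice(None)
        xs = x[idx]
        r = node_radius[idx]
        off = self.motion(t)
        g = xs @ self.normal + r - off          # penetration where > 0
        pen = np.maximum(g, 0.0)
        k = self.k[idx] if isinstance(self.k, np.ndarray) else self.k
        fn = k * pen
        f = np.zeros((n_all, 3))
        fs = -fn[:, None] * self.normal
        dissip = 0.0
        if self.mu > 0.0:
            fs_t, dissip = _stick_slip(
                xs, pen > 0, fn, np.broadcast_to(self.normal, xs.shape),
                k if isinstance(k, np.ndarray) else np.full(len(xs), k),
                self.mu, self._fric, idx, n_all)
            fs = fs + fs_t
        f[idx] = fs
        self.record = ContactRecord(self.name, float(fn.sum()),
                                    pen[pen > 0], int(np.sum(pen > 0)))
        return f, dissip


def _stick_slip(xs, active, fn, normal, k, mu, fric: _FrictionState,
                idx, n_all) -> Tuple[np.ndarray, float]:
    """Elastic-predictor/slip-return Coulomb friction on a node subset."""
    sub = np.nonzero(active)[0]            # indices into the subset view
    if isinstance(idx, slice):
        g_sub = sub                        # global node ids
    else:
        g_sub = np.asarray(idx)[active]

    # (re)set anchors for nodes that just (re)entered contact
    fresh = ~fric.active[g_sub]
    fric.anchor[g_sub[fresh]] = xs[sub[fresh]]
    fric.active[:] = False
    fric.active[g_sub] = True

    ft = np.zeros_like(xs)
    dissip = 0.0
    if len(sub):
        dx = xs[sub] - fric.anchor[g_sub]
        nrm = normal[sub]
        dx_t = dx - np.sum(dx * nrm, axis=1, keepdims=True) * nrm
        kk = k[sub] if isinstance(k, np.ndarray) else k
        trial = -kk[:, None] * dx_t if np.ndim(kk) else -kk * dx_t
        tmag = np.linalg.norm(trial, axis=1)
        fmax = mu * fn[sub]
        slip = tmag > fmax
        if np.any(slip):
            scale = fmax[slip] / tmag[slip]
            slip_dist = np.linalg.norm(dx_t[slip], axis=1) * (1.0 - scale)
            dissip = float(np.sum(fmax[slip] * slip_dist))
            trial[slip] *= scale[:, None]
            # drag anchors along the slip direction
            fric.anchor[g_sub[slip]] = xs[sub[slip]] + \
                trial[slip] / (kk[slip][:, None] if np.ndim(kk) else kk)
        ft[sub] = trial
    return ft, dissip


class Crimper:
    """Blockwise-style iris crimper: 12 rigid planes at 30 degree steps.

    ``diameter_motion(t)`` commands the iris diameter; each plane is
    tangent to the commanded cylinder and translates radially, so the
    distance between opposite planes equals the commanded diameter
    exactly.  All 12 planes are evaluated in one vectorised pass;
    friction anchors are kept per node and plane.
    """

    N_PLANES = 12

    def __init__(self, diameter_motion: Callable[[float], float],
                 penalty_stiffness, mu: float = 0.3,
                 nodes: Optional[np.ndarray] = None) -> None:
        self.diameter_motion = diameter_motion
        ang = np.arange(self.N_PLANES) * 2.0 * np.pi / self.N_PLANES
        self.normals = np.column_stack([np.cos(ang), np.sin(ang),
                                        np.zeros_like(ang)])
        self.k = penalty_stiffness
        self.mu = mu
        self.nodes = nodes
        self._anchor: Optional[np.ndarray] = None   # (n, 12, 3)
        self._active: Optional[np.ndarray] = None
        self.records: List[ContactRecord] = []

    def forces(self, x: np.ndarray, node_radius: np.ndarray, t: float
               ) -> Tuple[np.ndarray, float]:
        idx = self.nodes if self.nodes is not None else slice(None)
        xs = x[idx]
        r = node_radius[idx]
        n = len(xs)
        if self._anchor is None or len(self._anchor) != n:
            self._anchor = np.zeros((n, self.N_PLANES, 3))
            self._active = np.zeros((n, self.N_PLANES), bool)
        R = self.diameter_motion(t) / 2.0
        proj = xs @ self.normals.T                       # (n, 12)
        pen = np.maximum(proj + r[:, None] - R, 0.0)
        k = self.k[idx] if isinstance(self.k, np.ndarray) else \
            np.full(n, float(self.k))
        fn = k[:, None] * pen                            # (n, 12)
        fs = -(fn[:, :, None] * self.normals[None])      # (n, 12, 3)
        dissip = 0.0
        if self.mu > 0.0:
            active = pen > 0.0
            fresh = active & ~self._active
            if np.any(fresh):
                self._anchor[fresh] = np.broadcast_to(
                    xs[:, None, :], self._anchor.shape)[fresh]
            self._active = active
            dxv = xs[:, None, :] - self._anchor
            dxt = dxv - (np.einsum("npk,pk->np", dxv, self.normals)[..., None]
                         * self.normals[None])
            trial = -k[:, None, None] * dxt
            tmag = np.linalg.norm(trial, axis=2)
            fmax = self.mu * fn
            slip = active & (tmag > fmax)
            if np.any(slip):
                scale = fmax[slip] / tmag[slip]
                slip_dist = (tmag[slip] / np.repeat(
                    k[:, None], self.N_PLANES, 1)[slip]) * (1.0 - scale)
                dissip = float(np.sum(fmax[slip] * slip_dist))
                trial[slip] *= scale[:, None]
                self._anchor[slip] = (
                    np.broadcast_to(xs[:, None, :], dxv.shape)[slip]
                    + trial[slip] / np.repeat(
                        k[:, None], self.N_PLANES, 1)[slip][:, None])
            trial[~active] = 0.0
            fs = fs + trial
        f = np.zeros((len(x), 3))
        f[idx] = fs.sum(axis=1)
        self.records = [
            ContactRecord(f"plane_{i:02d}", float(fn[:, i].sum()),
                          pen[pen[:, i] > 0, i], int(np.sum(pen[:, i] > 0)))
            for i in range(self.N_PLANES)
        ]
        return f, dissip

    @property
    def radial_force(self) -> float:
        return total_radial_force(self.records)


class Tube:
    """Rigid tube along a centerline polyline (catheter, sheath, vessel).

    ``kind`` = "tube_inner": nodes are confined inside the tube (the
    usual catheter/vessel case); "tube_outer": nodes are kept outside.
    ``active_window(t) -> (s0, s1)`` optionally restricts the contact to
    a centerline arc-length interval (a retracting sheath exposes
    s < s0).  ``radius_motion(t)`` optionally commands the radius.
    """

    def __init__(self, centerline: np.ndarray, radius: float,
                 penalty_stiffness, kind: str = "tube_inner",
                 mu: float = 0.0, name: str = "tube",
                 radius_motion: Optional[Callable[[float], float]] = None,
                 active_window: Optional[Callable[[float], Tuple[float, float]]] = None,
                 nodes: Optional[np.ndarray] = None,
                 broadphase_every: int = 20,
                 broadphase_margin: float = 2.0) -> None:
        if radius <= 0:
            raise ValueError("tube radius must be positive")
        if kind not in ("tube_inner", "tube_outer"):
            raise ValueError(f"unknown tube kind {kind!r}")
        self.centerline = np.asarray(centerline, float)
        self.radius = radius
        self.kind = kind
        self.k = penalty_stiffness
        self.mu = mu
        self.name = name
        self.radius_motion = radius_motion
        self.active_window = active_window
        self.nodes = nodes
        #: full node-to-polyline projections are done every
        #: ``broadphase_every`` evaluations; in between only the nodes
        #: within ``broadphase_margin`` mm of the wall are projected
        self.broadphase_every = broadphase_every
        self.broadphase_margin = broadphase_margin
        self._count = 0
        self._cand: Optional[np.ndarray] = None
        self._fric: Optional[_FrictionState] = None
        self.record: Optional[ContactRecord] = None

    def forces(self, x: np.ndarray, node_radius: np.ndarray, t: float
               ) -> Tuple[np.ndarray, float]:
        n_all = len(x)
        if self._fric is None:
            self._fric = _FrictionState(n_all)
        base = self.nodes if self.nodes is not None else np.arange(n_all)
        R = self.radius if self.radius_motion is None else self.radius_motion(t)
        full = (self._cand is None
                or self._count % self.broadphase_every == 0)
        self._count += 1
        idx = base if full else self._cand
        xs = x[idx]
        r = node_radius[idx]
        closest, tangent, s = polyline_project(self.centerline, xs)
        if full:
            rho_f = xs - closest
            rho_f -= np.sum(rho_f * tangent, axis=1, keepdims=True) * tangent
            dist_f = np.linalg.norm(rho_f, axis=1)
            if self.kind == "tube_inner":
                gap = (R - r) - dist_f
            else:
                gap = dist_f - (R + r)
            near = gap < self.broadphase_margin
            self._cand = np.asarray(idx)[near]
            # nodes that left the neighbourhood lose their friction anchor
            keep = np.zeros(n_all, bool)
            keep[self._cand] = True
            self._fric.active &= keep
        rho = xs - closest
        rho -= np.sum(rho * tangent, axis=1, keepdims=True) * tangent
        dist = np.linalg.norm(rho, axis=1)
        safe = np.maximum(dist, 1e-9)
        nrad = rho / safe[:, None]          # outward radial unit vector
        if self.kind == "tube_inner":
            g = dist + r - R                # penetration into the wall
            normal = nrad                   # push back towards the axis
        else:
            g = (R + r) - dist
            normal = -nrad
        if self.active_window is not None:
            s0, s1 = self.active_window(t)
            g = np.where((s >= s0) & (s <= s1), g, -1.0)
        pen = np.maximum(g, 0.0)
        k = self.k[idx] if isinstance(self.k, np.ndarray) else self.k
        fn = k * pen
        f = np.zeros((n_all, 3))
        fs = -fn[:, None] * normal
        dissip = 0.0
        if self.mu > 0.0:
            ft, dissip = _stick_slip(
                xs, pen > 0, fn, normal,
                k if isinstance(k, np.ndarray) else np.full(len(xs), k),
                self.mu, self._fric, idx, n_all)
            fs = fs + ft
        f[idx] = fs
        self.record = ContactRecord(self.name, float(fn.sum()),
                                    pen[pen > 0], int(np.sum(pen > 0)))
        return f, dissip


# ---------------------------------------------------------------------------
# beam self-contact
# ---------------------------------------------------------------------------

def _segment_pair_distance(p1, q1, p2, q2):
    """Closest-approach vectors of segment pairs (vectorised).

    Returns (delta, dist) with delta pointing from segment 2 to 1.
    Clamped classic segment-segment algorithm.
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.sum(d1 * d1, axis=1)
    e = np.sum(d2 * d2, axis=1)
    fz = np.sum(d2 * r, axis=1)
    c = np.sum(d1 * r, axis=1)
    b = np.sum(d1 * d2, axis=1)
    den = a * e - b * b
    s = np.where(den > 1e-12, (b * fz - c * e) / np.where(den > 1e-12, den, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    tt = np.where(e > 1e-12, (b * s + fz) / np.where(e > 1e-12, e, 1.0), 0.0)
    tt = np.clip(tt, 0.0, 1.0)
    s = np.where(a > 1e-12, np.clip((b * tt - c) / np.where(a > 1e-12, a, 1.0),
                                    0.0, 1.0), 0.0)
    c1 = p1 + s[:, None] * d1
    c2 = p2 + tt[:, None] * d2
    delta = c1 - c2
    return delta, np.linalg.norm(delta, axis=1), s, tt


class BeamSelfContact:
    """Sphere-swept segment-segment penalty between stent wire elements.

    Candidate pairs are rebuilt every ``rebuild_every`` evaluations with
    a midpoint KD-tree; adjacent elements (sharing a node) are excluded.
    """

    def __init__(self, model: StructuralModel, penalty_stiffness,
                 cutoff_factor: float = 3.0, rebuild_every: int = 25) -> None:
        self.model = model
        self.k = penalty_stiffness
        self.cutoff_factor = cutoff_factor
        self.rebuild_every = rebuild_every
        self._count = 0
        self._pairs: Optional[np.ndarray] = None

    def _rebuild(self, x: np.ndarray) -> None:
        m = self.model
        mid = 0.5 * (x[m.conn[:, 0]] + x[m.conn[:, 1]])
        half = 0.5 * np.linalg.norm(x[m.conn[:, 1]] - x[m.conn[:, 0]], axis=1)
        cutoff = float(np.max(2.0 * m.sec_r) * self.cutoff_factor
                       + 2.0 * np.max(half))
        tree = cKDTree(mid)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs):
            c = m.conn
            i, j = pairs[:, 0], pairs[:, 1]
            share = ((c[i, 0][:, None] == c[j][:, None, :]).any(axis=(1, 2)) |
                     (c[i, 1][:, None] == c[j][:, None, :]).any(axis=(1, 2)))
            pairs = pairs[~share]
        self._pairs = pairs

    def forces(self, x: np.ndarray, node_radius: np.ndarray, t: float
               ) -> Tuple[np.ndarray, float]:
        m = self.model
        if self._count % self.rebuild_every == 0 or self._pairs is None:
            self._rebuild(x)
        self._count += 1
        f = np.zeros_like(x)
        if self._pairs is None or len(self._pairs) == 0:
            return f, 0.0
        i, j = self._pairs[:, 0], self._pairs[:, 1]
        c = m.conn
        delta, dist, s, tt = _segment_pair_distance(
            x[c[i, 0]], x[c[i, 1]], x[c[j, 0]], x[c[j, 1]])
        rsum = m.sec_r[i] + m.sec_r[j]
        pen = rsum - dist
        hit = pen > 0
        if not np.any(hit):
            return f, 0.0
        i, j, s, tt = i[hit], j[hit], s[hit], tt[hit]
        nvec = delta[hit] / np.maximum(dist[hit], 1e-9)[:, None]
        fmag = (self.k if np.isscalar(self.k) else
                np.minimum(self.k[c[i, 0]], self.k[c[j, 0]])) * pen[hit]
        fv = fmag[:, None] * nvec
        np.add.at(f, c[i, 0], (1.0 - s)[:, None] * fv)
        np.add.at(f, c[i, 1], s[:, None] * fv)
        np.add.at(f, c[j, 0], -(1.0 - tt)[:, None] * fv)
        np.add.at(f, c[j, 1], -tt[:, None] * fv)
        return f, 0.0

    def min_distance(self, x: np.ndarray) -> float:
        """Minimum wire-centerline distance over candidate pairs [mm]."""
        self._rebuild(x)
        if self._pairs is None or len(self._pairs) == 0:
            return np.inf
        m = self.model
        i, j = self._pairs[:, 0], self._pairs[:, 1]
        c = m.conn
        _, dist, _, _ = _segment_pair_distance(
            x[c[i, 0]], x[c[i, 1]], x[c[j, 0]], x[c[j, 1]])
        return float(dist.min())


# ---------------------------------------------------------------------------
# contact set
# ---------------------------------------------------------------------------

class ContactSet:
    """Bundle of contact objects evaluated together by the solver."""

    def __init__(self, model: StructuralModel,
                 surfaces: Sequence = (),
                 self_contact: Optional[BeamSelfContact] = None) -> None:
        self.model = model
        self.surfaces = list(surfaces)
        self.self_contact = self_contact
        self.node_radius = contact_node_radius(model)

    def __call__(self, state: DynamicState) -> Tuple[np.ndarray, float]:
        f = np.zeros_like(state.x)
        dissip = 0.0
        for s in self.surfaces:
            fs, ds = s.forces(state.x, self.node_radius, state.time)
            f += fs
            dissip += ds
        if self.self_contact is not None:
            fs, ds = self.self_contact.forces(state.x, self.node_radius,
                                              state.time)
            f += fs
            dissip += ds
        return f, dissip


def contact_node_radius(model: StructuralModel) -> np.ndarray:
    """Per-node contact offset: wire radius for stent nodes, half the
    fabric thickness for graft nodes."""
    r = np.zeros(model.n_nodes)
    if model.n_beams:
        for jj in (0, 1):
            np.maximum.at(r, model.conn[:, jj], model.sec_r)
    if model.n_tris:
        half_t = 0.5 * model.graft_material.thickness
        np.maximum.at(r, model.tri.ravel(),
                      np.full(model.tri.size, half_t))
    return r


def default_penalty_stiffness(model: StructuralModel,
                              factor: float = 0.1) -> np.ndarray:
    """Stable per-node penalty: factor x m_node / dt^2 [N/mm]."""
    return factor * model.mass / model.dt ** 2
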