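"""Parametric stent-ring, graft and device geometry and meshing.

The stent of a Valiant-type thoracic endograft is a stack of sinusoidal
zig-zag Nitinol rings (8-peaks and 5-peaks, 0.5 mm wire) plus a thin
circular proximal ring (0.2 mm wire), sutured to a cylindrical PET graft
(0.1 mm thick).  Rings are meshed with 2-node beam elements, the graft
with 3-node membrane triangles; sutures are merged-node connections.

Conventions: units mm; device axis = +z with the proximal end at high z;
the angular origin of every ring sits at its first (proximal) apex.

The ring centerline is the sinusoid  z(theta) = z0 + (h/2) cos(n theta)
on the cylinder of the requested diameter, with crown height h.  Crown
heights were not published for the commercial device; the defaults below
are fixed by requiring that at 1 mm element size the 30 mm 8-peaks ring
meshes to 240 elements and the 5-peaks ring to 160 (the published
convergent mesh sizes), which pins the free geometric parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "RingSpec",
    "DeviceSpec",
    "BeamMesh",
    "MembraneMesh",
    "CROWN_HEIGHT_8PEAKS",
    "CROWN_HEIGHT_5PEAKS",
    "make_ring",
    "make_device",
    "measure_diameter",
    "ring_wire_length",
    "crown_height_for_wire_length",
    "device_preset",
]

# Crown heights [mm] solved from the published convergent mesh counts
# (240 elements for the 30 mm 8-peaks ring, 160 for the 5-peaks ring,
# both at 1 mm average element size); see crown_height_for_wire_length.
CROWN_HEIGHT_8PEAKS = 13.34717260964607
CROWN_HEIGHT_5PEAKS = 12.231730180300252

#: fallback circumferential divisions of the graft grid (a multiple of
#: both 16 and 10 so apex angles of 8- and 5-peaks rings are grid lines)
_GRAFT_NDIV = 80


class InvalidSpecError(ValueError):
    """Raised for geometrically inconsistent ring/device specifications."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingSpec:
    kind: str  # "peaks8" | "peaks5" | "thin"
    nominal_diameter: float
    crown_height: float = 0.0
    wire_diameter: float = 0.5
    n_peaks: int = 8
    target_element_size: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("peaks8", "peaks5", "thin"):
            raise InvalidSpecError(f"unknown ring kind {self.kind!r}")
        if self.nominal_diameter <= 0:
            raise InvalidSpecError("nominal_diameter must be positive")
        if self.wire_diameter <= 0:
            raise InvalidSpecError("wire_diameter must be positive")
        if self.target_element_size <= 0:
            raise InvalidSpecError("target_element_size must be positive")
        if self.kind != "thin":
            if self.n_peaks not in (5, 8):
                raise InvalidSpecError("n_peaks must be 5 or 8 for peaks rings")
            if not (0.0 < self.crown_height < self.nominal_diameter):
                raise InvalidSpecError(
                    "crown_height must be positive and below the diameter")

    @staticmethod
    def peaks8(diameter: float, crown_height: float = CROWN_HEIGHT_8PEAKS,
               element_size: float = 1.0) -> "RingSpec":
        return RingSpec("peaks8", diameter, crown_height, 0.5, 8, element_size)

    @staticmethod
    def peaks5(diameter: float, crown_height: float = CROWN_HEIGHT_5PEAKS,
               element_size: float = 1.0) -> "RingSpec":
        return RingSpec("peaks5", diameter, crown_height, 0.5, 5, element_size)

    @staticmethod
    def thin(diameter: float, element_size: float = 1.0) -> "RingSpec":
        return RingSpec("thin", diameter, 0.0, 0.2, 8, element_size)


@dataclass(frozen=True)
class DeviceSpec:
    """Assembled stent-graft: rings at axial positions plus graft cylinder.

    ``rings`` lists (RingSpec, axial_position of ring mid-plane); the
    graft spans z in [0, graft_length].  In a Free-Flo configuration the
    most proximal peaks ring is bare (not sutured, above the graft).
    ``prestress_ratio`` is the relative excess of the stress-free ring
    diameter over the sutured one (0.17 for the modelled device).
    """

    rings: Tuple[Tuple[RingSpec, float], ...]
    graft_diameter: float
    graft_length: float
    graft_thickness: float = 0.1
    configuration: str = "ClosedWeb"  # "ClosedWeb" | "FreeFlo"
    prestress_ratio: float = 0.17

    def __post_init__(self) -> None:
        if self.graft_length <= 0 or self.graft_diameter <= 0:
            raise InvalidSpecError("graft dimensions must be positive")
        if self.prestress_ratio < 0:
            raise InvalidSpecError("prestress_ratio must be >= 0")
        if self.configuration not in ("ClosedWeb", "FreeFlo"):
            raise InvalidSpecError(f"unknown configuration {self.configuration!r}")
        spans = []
        for spec, z in self.rings:
            h = spec.crown_height if spec.kind != "thin" else 0.0
            spans.append((z - h / 2.0, z + h / 2.0))
        for (a0, a1), (b0, b1) in zip(sorted(spans), sorted(spans)[1:]):
            if b0 < a1 - 1e-9:
                raise InvalidSpecError("rings overlap axially")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

@dataclass
class BeamMesh:
    """Stent wire discretisation: 2-node beam elements on ring loops."""

    node_coords: np.ndarray          # (N, 3)
    elements: np.ndarray             # (E, 2) int
    section_radius: np.ndarray       # (E,)
    part_id: np.ndarray              # (E,) int  (= ring index within device)
    node_ring_id: np.ndarray         # (N,) int

    def __post_init__(self) -> None:
        n = len(self.node_coords)
        if self.elements.size and (self.elements.min() < 0
                                   or self.elements.max() >= n):
            raise InvalidSpecError("element references a missing node")
        d = self.node_coords[self.elements[:, 1]] - \
            self.node_coords[self.elements[:, 0]]
        if self.elements.size and np.any(np.linalg.norm(d, axis=1) < 1e-12):
            raise InvalidSpecError("zero-length beam element")

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def ring_ids(self) -> np.ndarray:
        return np.unique(self.part_id)

    def ring_nodes(self, ring_id: int) -> np.ndarray:
        return np.nonzero(self.node_ring_id == ring_id)[0]

    def ring_elements(self, ring_id: int) -> np.ndarray:
        return np.nonzero(self.part_id == ring_id)[0]


@dataclass
class MembraneMesh:
    """Graft discretisation: 3-node membrane triangles on a cylinder."""

    node_coords: np.ndarray          # (N, 3)
    triangles: np.ndarray            # (T, 3) int
    thickness: float
    suture_map: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    # (S, 2) int: (graft node, stent node) pairs to be merged at assembly

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)


# ---------------------------------------------------------------------------
# ring generation
# ---------------------------------------------------------------------------

def ring_wire_length(diameter: float, n_peaks: int, crown_height: float) -> float:
    """Arc length of the sinusoidal ring centerline [mm]."""
    R = diameter / 2.0
    amp = n_peaks * crown_height / 2.0

    def ds(t):
        return np.sqrt(R * R + amp * amp * np.sin(n_peaks * t) ** 2)

    return quad(ds, 0.0, 2.0 * np.pi, limit=200)[0]


def crown_height_for_wire_length(diameter: float, n_peaks: int,
                                 target_length: float) -> float:
    """Crown height h such that the ring wire length equals the target."""
    return brentq(
        lambda h: ring_wire_length(diameter, n_peaks, h) - target_length,
        1e-3, diameter)


def _peaks_element_count(spec: RingSpec) -> int:
    L = ring_wire_length(spec.nominal_diameter, spec.n_peaks, spec.crown_height)
    m = 2 * spec.n_peaks
    return m * max(1, round(L / (m * spec.target_element_size)))


def make_ring(spec: RingSpec, *, center_z: float = 0.0,
              diameter: Optional[float] = None,
              n_elements: Optional[int] = None,
              ring_id: int = 0) -> BeamMesh:
    """Mesh a single stent ring with 2-node beam elements.

    Peaks rings are closed sinusoidal zig-zag wires sampled on the
    cylinder of ``diameter`` (default: the nominal diameter); the element
    count is the wire length over the target size, rounded to an even
    multiple of ``n_peaks`` so apexes fall on nodes.  The thin ring is a
    plane circle.  Generation is deterministic.
    """
    D = spec.nominal_diameter if diameter is None else diameter
    if D <= 0:
        raise InvalidSpecError("diameter must be positive")
    R = D / 2.0
    if spec.kind == "thin":
        n_el = n_elements or max(8, round(np.pi * D / spec.target_element_size))
        theta = np.arange(n_el) * 2.0 * np.pi / n_el
        # deterministic sub-wire-radius axial ripple: seeds the wave
        # buckling a plane wire ring undergoes under hoop compression
        # (a perfectly circular mesh would crush axisymmetrically)
        z = center_z + 0.4 * spec.wire_diameter * np.cos(5.0 * theta)
    else:
        n_el = n_elements or _peaks_element_count(spec)
        theta = np.arange(n_el) * 2.0 * np.pi / n_el
        z = center_z + (spec.crown_height / 2.0) * np.cos(spec.n_peaks * theta)
    coords = np.column_stack([R * np.cos(theta), R * np.sin(theta), z])
    elems = np.column_stack([np.arange(n_el), (np.arange(n_el) + 1) % n_el])
    return BeamMesh(
        node_coords=coords,
        elements=elems.astype(int),
        section_radius=np.full(n_el, spec.wire_diameter / 2.0),
        part_id=np.full(n_el, ring_id, int),
        node_ring_id=np.full(n_el, ring_id, int),
    )


def measure_diameter(mesh: BeamMesh, ring_id: int) -> float:
    """Twice the mean radial node distance from the ring's own axis."""
    idx = mesh.ring_nodes(ring_id)
    if idx.size == 0:
        raise InvalidSpecError(f"ring {ring_id} has no nodes")
    xy = mesh.node_coords[idx, :2]
    c = xy.mean(axis=0)
    return 2.0 * float(np.mean(np.linalg.norm(xy - c, axis=1)))


def ring_apex_nodes(mesh: BeamMesh, ring_id: int, spec: RingSpec,
                    side: str = "both") -> np.ndarray:
    """Node indices at ring apexes (axial extrema of the wire).

    ``side``: "proximal" (peaks, high z), "distal" (valleys) or "both".
    """
    idx = mesh.ring_nodes(ring_id)
    if spec.kind == "thin":
        return idx
    z = mesh.node_coords[idx, 2]
    n = len(idx)
    prev_z = z[np.arange(-1, n - 1)]
    next_z = z[(np.arange(n) + 1) % n]
    if side == "proximal":
        mask = (z >= prev_z) & (z >= next_z)
    elif side == "distal":
        mask = (z <= prev_z) & (z <= next_z)
    else:
        mask = ((z >= prev_z) & (z >= next_z)) | ((z <= prev_z) & (z <= next_z))
    return idx[mask]


# ---------------------------------------------------------------------------
# device assembly
# ---------------------------------------------------------------------------

def _graft_ndiv(rings: Sequence[Tuple[RingSpec, float]], graft_diameter: float,
                element_size: float, bare_index) -> int:
    """Circumferential graft divisions.

    Must be a multiple of 2 n_peaks for every sutured peaks ring so all
    apex angles land on grid lines (16 for 8-peaks, 10 for 5-peaks,
    80 for a mix), rounded towards the target element size.
    ``rings`` is the proximal-first sorted list matching ``bare_index``.
    """
    base = 1
    for i, (rs, _z) in enumerate(rings):
        if rs.kind == "thin" or i == bare_index:
            continue
        base = int(np.lcm(base, 2 * rs.n_peaks))
    if base == 1:
        base = 16
    k = max(1, round(np.pi * graft_diameter / (base * element_size)))
    return base * k


def _graft_mesh(spec: DeviceSpec, suture_planes: Sequence[float],
                element_size: float, nc: int
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Structured cylinder mesh whose grid contains all suture planes.

    Returns (coords, triangles, zgrid); the circumferential grid has
    ``nc`` divisions so every apex angle is a grid line.
    """
    req = sorted({0.0, spec.graft_length,
                  *[z for z in suture_planes
                    if 1e-9 < z < spec.graft_length - 1e-9]})
    zs: List[float] = []
    for a, b in zip(req, req[1:]):
        n = max(1, round((b - a) / element_size))
        zs.extend(np.linspace(a, b, n, endpoint=False))
    zs.append(spec.graft_length)
    zgrid = np.array(zs)
    theta = np.arange(nc) * 2.0 * np.pi / nc
    R = spec.graft_diameter / 2.0
    tt, zz = np.meshgrid(theta, zgrid)
    coords = np.column_stack([R * np.cos(tt).ravel(), R * np.sin(tt).ravel(),
                              zz.ravel()])
    nz = len(zgrid)
    tris = []
    for i in range(nz - 1):
        j = np.arange(nc)
        jp = (j + 1) % nc
        a = i * nc + j
        b = i * nc + jp
        c = (i + 1) * nc + j
        d = (i + 1) * nc + jp
        tris.append(np.column_stack([a, b, d]))
        tris.append(np.column_stack([a, d, c]))
    return coords, np.vstack(tris).astype(int), zgrid


def make_device(spec: DeviceSpec) -> Tuple[BeamMesh, MembraneMesh]:
    """Assemble the stent-graft: rings (at stress-free diameter) + graft.

    Rings are generated at their stress-free diameter, nominal x
    (1 + prestress_ratio); the graft cylinder sits at the sutured
    (graft) diameter.  The suture map pairs graft nodes with ring apex
    nodes at identical (theta, z) grid positions, so that once the rings
    are mapped radially to the sutured diameter the paired nodes
    coincide exactly.  In a Free-Flo device the most proximal peaks ring
    is left bare.
    """
    if not spec.rings:
        raise InvalidSpecError("device needs at least one ring")
    order = np.argsort([-z for _, z in spec.rings])  # proximal first
    rings = [spec.rings[i] for i in order]

    bare_index: Optional[int] = None
    if spec.configuration == "FreeFlo":
        for i, (rs, _z) in enumerate(rings):
            if rs.kind != "thin":
                bare_index = i
                break
        if bare_index is None:
            raise InvalidSpecError("FreeFlo device has no peaks ring")

    factor = 1.0 + spec.prestress_ratio
    beam_coords, beam_elems, beam_rad = [], [], []
    beam_part, beam_nring = [], []
    offset = 0
    apex_info = []  # (ring_index, apex theta/z pairs in sutured config)
    el_size = min(rs.target_element_size for rs, _ in rings)
    ndiv = _graft_ndiv(rings, spec.graft_diameter, el_size, bare_index)

    for i, (rs, zc) in enumerate(rings):
        if rs.kind == "thin":
            # the thin sealing ring is sewn flush at the sutured
            # diameter; the pre-stress applies to the peaks springs only
            n_el = ndiv
            d_mesh = rs.nominal_diameter
        else:
            n_el = _peaks_element_count(rs)
            d_mesh = rs.nominal_diameter * factor
        ring = make_ring(rs, center_z=zc, diameter=d_mesh,
                         n_elements=n_el, ring_id=i)
        beam_coords.append(ring.node_coords)
        beam_elems.append(ring.elements + offset)
        beam_rad.append(ring.section_radius)
        beam_part.append(ring.part_id)
        beam_nring.append(ring.node_ring_id)

        if i != bare_index:
            # suture locations on the (theta, z) grid of the graft
            if rs.kind == "thin":
                loc = np.arange(n_el)
                zpl = np.full(n_el, zc)
            else:
                loc = np.arange(0, n_el, n_el // (2 * rs.n_peaks))
                zpl = zc + (rs.crown_height / 2.0) * np.cos(
                    rs.n_peaks * loc * 2.0 * np.pi / n_el)
            theta = loc * 2.0 * np.pi / n_el
            apex_info.append((i, offset + loc, theta, zpl))
        offset += n_el

    stent = BeamMesh(
        node_coords=np.vstack(beam_coords),
        elements=np.vstack(beam_elems),
        section_radius=np.concatenate(beam_rad),
        part_id=np.concatenate(beam_part),
        node_ring_id=np.concatenate(beam_nring),
    )

    planes = np.concatenate([zp for _, _, _, zp in apex_info]) \
        if apex_info else np.empty(0)
    gcoords, gtris, zgrid = _graft_mesh(spec, planes, el_size, ndiv)

    nc = ndiv
    pairs = []
    for _i, stent_nodes, theta, zpl in apex_info:
        jz = np.searchsorted(zgrid, np.clip(zpl, 0.0, spec.graft_length))
        jz = np.clip(jz, 0, len(zgrid) - 1)
        # snap to the nearest grid plane (apex planes are grid members
        # when inside the graft span)
        below = np.clip(jz - 1, 0, len(zgrid) - 1)
        use_below = np.abs(zgrid[below] - zpl) < np.abs(zgrid[jz] - zpl)
        jz = np.where(use_below, below, jz)
        jt = np.rint(theta / (2.0 * np.pi / nc)).astype(int) % nc
        gnodes = jz * nc + jt
        inside = (zpl > -1e-9) & (zpl < spec.graft_length + 1e-9)
        pairs.append(np.column_stack([gnodes[inside], stent_nodes[inside]]))
    suture_map = np.vstack(pairs) if pairs else np.empty((0, 2), int)

    # snap paired graft nodes onto their stent partners (mapped to the
    # graft radius) so suture pairs coincide exactly in the sutured
    # configuration; for peaks rings this is an identity, for the thin
    # ring it carries the buckling-seed ripple into the graft grid
    if len(suture_map):
        sp = stent.node_coords[suture_map[:, 1]].copy()
        rad = np.linalg.norm(sp[:, :2], axis=1)
        ring_of = stent.node_ring_id[suture_map[:, 1]]
        scale = np.ones(len(sp))
        for i, (rs, _z) in enumerate(rings):
            m = ring_of == i
            if not np.any(m):
                continue
            scale[m] = (spec.graft_diameter / 2.0) / np.mean(rad[m])
        sp[:, :2] *= scale[:, None]
        gcoords[suture_map[:, 0]] = sp

    graft = MembraneMesh(
        node_coords=gcoords,
        triangles=gtris,
        thickness=spec.graft_thickness,
        suture_map=suture_map,
    )
    return stent, graft


# ---------------------------------------------------------------------------
# device presets
# ---------------------------------------------------------------------------

def _body_positions(z_top: float, z_bot: float, n: int) -> np.ndarray:
    return np.linspace(z_top, z_bot, n)


def device_preset(name: str, element_size: float = 1.0) -> DeviceSpec:
    """Published device geometries.

    * ``device_a`` -- 30 x 30 x 150 Closed-Web straight
    * ``device_b`` -- 46 x 46 x 150 Free-Flo straight
    * ``device_c`` -- 34 x 34 x 200 Free-Flo straight (11 rings)

    Ring counts and axial pitches were not published; the presets place
    a proximal thin ring plus sinusoidal body rings at uniform pitch
    (and, for device C, 11 rings total matching the published strut
    numbering 1..11, proximal free-flo ring first).
    """
    key = name.lower().replace("-", "_")
    if key in ("device_a", "a"):
        D, L = 30.0, 150.0
        h8, h5 = CROWN_HEIGHT_8PEAKS, CROWN_HEIGHT_5PEAKS
        rings = [(RingSpec.peaks8(D, h8, element_size), L - h8 / 2 - 1.0),
                 (RingSpec.thin(D, element_size), L - h8 - 3.0)]
        body = _body_positions(L - h8 - 5.0 - h5 / 2, h5 / 2 + 1.0, 7)
        rings += [(RingSpec.peaks5(D, h5, element_size), z) for z in body]
        return DeviceSpec(tuple(rings), D, L, configuration="ClosedWeb")
    if key in ("device_b", "b"):
        D, L = 46.0, 150.0
        h8 = crown_height_for_wire_length(D, 8, 8 * 2 * 17.0)
        h5 = crown_height_for_wire_length(D, 5, 5 * 2 * 19.0)
        rings = [(RingSpec("peaks8", D, h8, 0.5, 8, element_size), L + h8 / 2 + 1.0),
                 (RingSpec.thin(D, element_size), L - 2.0)]
        body = _body_positions(L - 5.0 - h5 / 2, h5 / 2 + 1.0, 6)
        rings += [(RingSpec("peaks5", D, h5, 0.5, 5, element_size), z) for z in body]
        return DeviceSpec(tuple(rings), D, L, configuration="FreeFlo")
    if key in ("device_c", "c"):
        D, L = 34.0, 200.0
        h8 = crown_height_for_wire_length(D, 8, 8 * 2 * 15.5)
        h5 = crown_height_for_wire_length(D, 5, 5 * 2 * 16.5)
        rings = [(RingSpec("peaks8", D, h8, 0.5, 8, element_size), L + h8 / 2 + 1.0),
                 (RingSpec.thin(D, element_size), L - 2.0)]
        body = _body_positions(L - 5.0 - h5 / 2, h5 / 2 + 1.0, 9)
        rings += [(RingSpec("peaks5", D, h5, 0.5, 5, element_size), z) for z in body]
        return DeviceSpec(tuple(rings), D, L, configuration="FreeFlo")
    raise InvalidSpecError(f"unknown device preset {name!r}")
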