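"""Explicit-dynamics structural kernel.

Corotational two-node Euler--Bernoulli fibre beams (2 x 2 Gauss points in
the circular cross-section, two Gauss points along the length), total-
Lagrangian constant-strain membrane triangles, lumped masses with
optional mass scaling, mass-proportional damping and central-difference
time stepping.  Quasi-static solutions are obtained by dynamic
relaxation: boundary motion is prescribed over a pseudo-time and the
system is stepped until the kinetic energy decays.

Unit system: mm / N / MPa / tonne / s (consistent for explicit FE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constitutive import (FabricParams, NitinolParams, SMAState,
                           fabric_update, sma_update)
from .geometry import BeamMesh, MembraneMesh

__all__ = [
    "SolverConfig",
    "DynamicState",
    "StructuralModel",
    "DivergenceError",
    "FatalDeformationError",
    "NonConvergenceError",
    "beam_internal_forces",
    "membrane_internal_forces",
    "relax_to_equilibrium",
]

#: standard NiTi / PET densities [tonne/mm^3]
DENSITY_NITI = 6.45e-9
DENSITY_PET = 1.4e-9


class DivergenceError(RuntimeError):
    """Explicit integration blew up (energy growth / non-finite state)."""


class FatalDeformationError(RuntimeError):
    """Element deformation beyond the configured fatal threshold."""


class NonConvergenceError(RuntimeError):
    """Dynamic relaxation did not reach the kinetic-energy tolerance."""


@dataclass
class SolverConfig:
    """Explicit solver settings.

    ``dt_target`` is the stable timestep enforced through mass scaling
    (default 1e-6 s = 0.001 ms).  Damping is mass-proportional, with
    separate factors for stent and graft parts (defaults 1 and 0.1 1/s;
    deployment protocols raise the graft damping to 0.5).
    """

    dt_target: float = 1e-6
    damping_stent: float = 1.0
    damping_graft: float = 0.1
    ke_tol: float = 1e-3
    max_steps: int = 2_000_000
    mass_scaling: bool = True
    density_stent: float = DENSITY_NITI
    density_graft: float = DENSITY_PET
    fatal_strain: float = 0.40      # fibre / principal strain threshold
    fatal_area_ratio: float = 0.02  # membrane Jacobian collapse threshold
    #: steps the fatal-strain threshold must be exceeded continuously
    #: before the run is declared failed (explicit transients spike)
    fatal_patience: int = 300
    #: compressive membrane stress [MPa] above which crushing counts as
    #: deformation failure (slack / compliant membranes fold harmlessly)
    membrane_stress_floor: float = 5.0
    #: outright compressive-stress limit [MPa]: a thin membrane driven
    #: this deep into post-buckling compression (PET yields near
    #: 60-80 MPa) is a collapsing run even if folding keeps the
    #: in-plane strain moderate
    membrane_stress_limit: float = 100.0
    energy_blowup_factor: float = 1e4
    #: per-step multiplicative damping of angular velocities; suppresses
    #: the zero-stiffness spin mechanism of straight wire runs and the
    #: weak follower-moment flutter of the corotational formulation
    rot_damp: float = 0.2
    #: per-step multiplicative damping of translational velocities;
    #: protocols with frictional contact use ~0.01 to settle stick-slip
    lin_damp: float = 0.0

    def __post_init__(self) -> None:
        if self.dt_target <= 0:
            raise ValueError("dt_target must be positive")
        if self.damping_stent < 0 or self.damping_graft < 0:
            raise ValueError("damping must be non-negative")
        if self.ke_tol <= 0:
            raise ValueError("ke_tol must be positive")


# ---------------------------------------------------------------------------
# quaternion helpers (w-first, vectorised)
# ---------------------------------------------------------------------------

def _qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = (a[..., i] for i in range(4))
    w2, x2, y2, z2 = (b[..., i] for i in range(4))
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def _qconj(q: np.ndarray) -> np.ndarray:
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def _qapply(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    # rotate v by q: v + 2 u x (u x v + w v) with u = q_vec
    u = q[..., 1:]
    w = q[..., :1]
    c = np.cross(u, v)
    return v + 2.0 * np.cross(u, c + w * v)


def _q_from_rotvec(r: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(r, axis=-1, keepdims=True)
    half = 0.5 * angle
    small = angle < 1e-12
    k = np.where(small, 0.5, np.sin(half) / np.where(small, 1.0, angle))
    return np.concatenate([np.cos(half), k * r], axis=-1)


def _rotvec_from_q(q: np.ndarray) -> np.ndarray:
    w = np.clip(q[..., :1], -1.0, 1.0)
    u = q[..., 1:]
    n = np.linalg.norm(u, axis=-1, keepdims=True)
    angle = 2.0 * np.arctan2(n, np.abs(w))
    sgn = np.where(w < 0.0, -1.0, 1.0)
    small = n < 1e-12
    k = np.where(small, 2.0 * sgn, sgn * angle / np.where(small, 1.0, n))
    return k * u


def _q_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a to unit vector b."""
    w = 1.0 + np.sum(a * b, axis=-1, keepdims=True)
    xyz = np.cross(a, b)
    q = np.concatenate([w, xyz], axis=-1)
    # antiparallel fallback: rotate pi about any perpendicular axis
    bad = w[..., 0] < 1e-8
    if np.any(bad):
        perp = np.cross(a[bad], np.array([1.0, 0.0, 0.0]))
        n = np.linalg.norm(perp, axis=-1, keepdims=True)
        alt = np.cross(a[bad], np.array([0.0, 1.0, 0.0]))
        perp = np.where(n > 1e-6, perp, alt)
        perp /= np.linalg.norm(perp, axis=-1, keepdims=True)
        q[bad] = np.concatenate([np.zeros_like(n), perp], axis=-1)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def _q_cols(q: np.ndarray):
    """Columns of the rotation matrix of q (images of ex, ey, ez)."""
    w, x, y, z = (q[..., i] for i in range(4))
    c1 = np.stack([1 - 2 * (y * y + z * z), 2 * (x * y + w * z),
                   2 * (x * z - w * y)], axis=-1)
    c2 = np.stack([2 * (x * y - w * z), 1 - 2 * (x * x + z * z),
                   2 * (y * z + w * x)], axis=-1)
    c3 = np.stack([2 * (x * z + w * y), 2 * (y * z - w * x),
                   1 - 2 * (x * x + y * y)], axis=-1)
    return c1, c2, c3


def _frame_quaternion(axis: np.ndarray) -> np.ndarray:
    """Quaternion whose rotation maps ex to ``axis`` (unit vectors)."""
    ex = np.zeros_like(axis)
    ex[..., 0] = 1.0
    return _q_between(ex, axis)


# ---------------------------------------------------------------------------
# dynamic state
# ---------------------------------------------------------------------------

@dataclass
class DynamicState:
    """Nodal kinematics plus material history and energy bookkeeping."""

    x: np.ndarray                 # (N, 3) positions
    v: np.ndarray                 # (N, 3) velocities
    q: np.ndarray                 # (N, 4) node triads (quaternions)
    w: np.ndarray                 # (N, 3) angular velocities
    sma: Optional[SMAState]       # per-fibre history (beam SMA parts)
    time: float = 0.0
    kinetic_energy: float = 0.0
    internal_energy: float = 0.0
    contact_energy: float = 0.0
    external_work: float = 0.0
    damping_energy: float = 0.0
    friction_energy: float = 0.0
    peak_kinetic_energy: float = 0.0
    max_fibre_strain: float = 0.0
    max_membrane_strain: float = 0.0
    min_area_ratio: float = 1.0
    min_membrane_stress: float = 0.0     # most compressive principal [MPa]
    f_net: Optional[np.ndarray] = None   # last net nodal force (no damping)
    f_int_prev: Optional[np.ndarray] = None   # trapezoidal work correction
    fc_prev: Optional[np.ndarray] = None
    dx_prev: Optional[np.ndarray] = None
    mom_prev: Optional[np.ndarray] = None
    dth_prev: Optional[np.ndarray] = None
    force_scale: float = 0.0             # running peak of the force scale
    contact_force_max: float = 0.0       # instantaneous |f_contact| peak
    ext_force_max: float = 0.0
    int_force_max: float = 0.0

    def copy(self) -> "DynamicState":
        return DynamicState(
            x=self.x.copy(), v=self.v.copy(), q=self.q.copy(),
            w=self.w.copy(),
            sma=self.sma.copy() if self.sma is not None else None,
            time=self.time,
            kinetic_energy=self.kinetic_energy,
            internal_energy=self.internal_energy,
            contact_energy=self.contact_energy,
            external_work=self.external_work,
            damping_energy=self.damping_energy,
            friction_energy=self.friction_energy,
            peak_kinetic_energy=self.peak_kinetic_energy,
            max_fibre_strain=self.max_fibre_strain,
            max_membrane_strain=self.max_membrane_strain,
            min_area_ratio=self.min_area_ratio,
            min_membrane_stress=self.min_membrane_stress,
            f_net=None if self.f_net is None else self.f_net.copy(),
            force_scale=self.force_scale,
            contact_force_max=self.contact_force_max,
            ext_force_max=self.ext_force_max,
            int_force_max=self.int_force_max,
        )


# ---------------------------------------------------------------------------
# structural model
# ---------------------------------------------------------------------------

#: 2-point Gauss rule on [0, 1]
_GAUSS_X = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
#: 2 x 2 section fibres of a circular cross-section at (+-R/2, +-R/2);
#: with weight A/4 each this integrates both A and I = pi R^4 / 4 exactly.
_FIBRE_Y = np.array([0.5, 0.5, -0.5, -0.5])
_FIBRE_Z = np.array([0.5, -0.5, 0.5, -0.5])


class StructuralModel:
    """Assembled beam + membrane model with merged suture nodes.

    Parameters
    ----------
    stent : BeamMesh or None
    graft : MembraneMesh or None
        When both are given and ``merge_sutures`` is True, each graft
        node listed in the suture map shares the degrees of freedom of
        its stent partner (merged-node suture).
    beam_material : NitinolParams | ("linear", E, nu)
        Fibre law of the stent wire.
    graft_material : FabricParams
        Graft law; a linear-elastic graft is a FabricParams with
        ``compressive_stiffness_factor=1``.
    """

    def __init__(self, stent: Optional[BeamMesh] = None,
                 graft: Optional[MembraneMesh] = None, *,
                 beam_material=None,
                 graft_material: Optional[FabricParams] = None,
                 cfg: Optional[SolverConfig] = None,
                 merge_sutures: bool = True) -> None:
        self.cfg = cfg or SolverConfig()
        self.stent = stent
        self.graft = graft
        self.beam_material = beam_material
        self.graft_material = graft_material

        coords: List[np.ndarray] = []
        n_stent = stent.n_nodes if stent is not None else 0
        if stent is not None:
            coords.append(stent.node_coords)

        self.graft_node_map = np.empty(0, int)
        if graft is not None:
            gmap = np.arange(graft.n_nodes) + n_stent
            if merge_sutures and stent is not None and len(graft.suture_map):
                merged = dict(zip(graft.suture_map[:, 0].tolist(),
                                  graft.suture_map[:, 1].tolist()))
                keep = np.array([i for i in range(graft.n_nodes)
                                 if i not in merged], int)
                new_idx = np.full(graft.n_nodes, -1, int)
                new_idx[keep] = n_stent + np.arange(len(keep))
                for g, s in merged.items():
                    new_idx[g] = s
                gmap = new_idx
                coords.append(graft.node_coords[keep])
            else:
                coords.append(graft.node_coords)
            self.graft_node_map = gmap
            self.tri = gmap[graft.triangles]
        else:
            self.tri = np.empty((0, 3), int)

        self.X = np.vstack(coords) if coords else np.empty((0, 3))
        self.n_nodes = len(self.X)
        self.n_stent_nodes = n_stent
        self._fatal_count = 0

        self._setup_beams()
        self._setup_membranes()
        self._setup_mass()

    # -- beams ------------------------------------------------------------
    def _setup_beams(self) -> None:
        if self.stent is None or len(self.stent.elements) == 0:
            self.n_beams = 0
            return
        st = self.stent
        self.conn = st.elements
        d = self.X[self.conn[:, 1]] - self.X[self.conn[:, 0]]
        self.L0 = np.linalg.norm(d, axis=1)
        axis = d / self.L0[:, None]
        self.qE0 = _frame_quaternion(axis)
        self.sec_r = st.section_radius
        self.A = np.pi * self.sec_r ** 2
        self.I = np.pi * self.sec_r ** 4 / 4.0
        self.J = 2.0 * self.I
        self.n_beams = len(self.conn)
        mat = self.beam_material
        if isinstance(mat, NitinolParams):
            self.beam_E_ref = mat.E_A
            self.beam_G = mat.G_A
            self.beam_is_sma = True
        else:
            _, E, nu = mat
            self.beam_E_ref = E
            self.beam_G = E / (2.0 * (1.0 + nu))
            self.beam_is_sma = False
        # fibre offsets (E, 4)
        self.fib_y = self.sec_r[:, None] * _FIBRE_Y
        self.fib_z = self.sec_r[:, None] * _FIBRE_Z

    # -- membranes --------------------------------------------------------
    def _setup_membranes(self) -> None:
        """Reference membrane geometry.

        The graft reference is the pristine graft cylinder (its own mesh
        coordinates), NOT the merged assembly positions: a suture node
        shares its degrees of freedom with the stent, but the fabric is
        unstrained when the graft is a cylinder at the sutured diameter.
        """
        self.n_tris = len(self.tri)
        if self.n_tris == 0:
            return
        p = self.graft.node_coords[self.graft.triangles]
        e1 = p[:, 1] - p[:, 0]
        e2 = p[:, 2] - p[:, 0]
        n = np.cross(e1, e2)
        self.A0 = 0.5 * np.linalg.norm(n, axis=1)
        if np.any(self.A0 < 1e-12):
            raise ValueError("degenerate graft triangle")
        # reference in-plane basis and 2x2 edge matrix inverse
        b1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        nn = n / np.linalg.norm(n, axis=1, keepdims=True)
        b2 = np.cross(nn, b1)
        E11 = np.sum(e1 * b1, axis=1)
        E21 = np.zeros_like(E11)
        E12 = np.sum(e2 * b1, axis=1)
        E22 = np.sum(e2 * b2, axis=1)
        det = E11 * E22 - E12 * E21
        self.Dinv = np.empty((self.n_tris, 2, 2))
        self.Dinv[:, 0, 0] = E22 / det
        self.Dinv[:, 0, 1] = -E12 / det
        self.Dinv[:, 1, 0] = -E21 / det
        self.Dinv[:, 1, 1] = E11 / det

    # -- mass and mass scaling -------------------------------------------
    def _setup_mass(self) -> None:
        cfg = self.cfg
        m = np.zeros(self.n_nodes)
        inert = np.zeros(self.n_nodes)
        k_tr = np.zeros(self.n_nodes)
        k_rot = np.zeros(self.n_nodes)
        if self.n_beams:
            mel = cfg.density_stent * self.A * self.L0
            np.add.at(m, self.conn[:, 0], 0.5 * mel)
            np.add.at(m, self.conn[:, 1], 0.5 * mel)
            iel = 0.5 * mel * (self.L0 ** 2 / 12.0 + self.sec_r ** 2 / 4.0)
            np.add.at(inert, self.conn[:, 0], iel)
            np.add.at(inert, self.conn[:, 1], iel)
            E = self.beam_E_ref
            kt = E * self.A / self.L0 + 12.0 * E * self.I / self.L0 ** 3
            kr = 4.0 * E * self.I / self.L0 + self.beam_G * self.J / self.L0
            for j in (0, 1):
                np.add.at(k_tr, self.conn[:, j], kt)
                np.add.at(k_rot, self.conn[:, j], kr)
        if self.n_tris:
            gm = self.graft_material
            mel = cfg.density_graft * self.A0 * gm.thickness
            for j in range(3):
                np.add.at(m, self.tri[:, j], mel / 3.0)
            Ep = gm.E_long / (1.0 - gm.nu ** 2)
            p = self.graft.node_coords[self.graft.triangles]
            lmax = np.max(np.linalg.norm(
                p - p[:, [1, 2, 0]], axis=2), axis=1)
            ktri = Ep * gm.thickness * lmax ** 2 / (2.0 * self.A0)
            for j in range(3):
                np.add.at(k_tr, self.tri[:, j], ktri)

        self.m_phys = m.copy()
        if cfg.mass_scaling:
            dt = cfg.dt_target
            m_req = 2.0 * k_tr * dt * dt
            i_req = 16.0 * k_rot * dt * dt
            m = np.maximum(m, m_req)
            inert = np.maximum(inert, i_req)
            self.dt = dt
        else:
            with np.errstate(divide="ignore"):
                wmax2 = np.max(np.where(m > 0, 2.0 * k_tr / np.maximum(m, 1e-30), 0.0))
            self.dt = 0.9 * 2.0 / np.sqrt(max(wmax2, 1e-30))
        m = np.where(m > 0, m, 1e-12)
        inert = np.where(inert > 0, inert, 1e-12)
        self.mass = m
        self.inertia = inert
        tot_phys = self.m_phys.sum()
        self.added_mass_fraction = (
            (m.sum() - tot_phys) / tot_phys if tot_phys > 0 else 0.0)

        # per-node damping: stent vs graft parts
        d = np.full(self.n_nodes, cfg.damping_graft)
        if self.n_stent_nodes:
            d[: self.n_stent_nodes] = cfg.damping_stent
        self.damping = d

    # -- initial state -----------------------------------------------------
    def initial_state(self) -> DynamicState:
        sma = None
        if self.n_beams and self.beam_is_sma:
            sma = SMAState.zeros((self.n_beams, 2, 4))
        q = np.zeros((self.n_nodes, 4))
        q[:, 0] = 1.0
        return DynamicState(
            x=self.X.copy(), v=np.zeros((self.n_nodes, 3)),
            q=q, w=np.zeros((self.n_nodes, 3)), sma=sma)

    # -- internal forces ---------------------------------------------------
    def beam_forces(self, state: DynamicState, commit: bool = True
                    ) -> Tuple[np.ndarray, np.ndarray]:
        """Internal forces/moments of all beam elements.

        Returns (f, mom): (N,3) force and moment arrays such that the
        equations of motion read  m a = f_ext - f.
        """
        f = np.zeros((self.n_nodes, 3))
        mom = np.zeros((self.n_nodes, 3))
        if self.n_beams == 0:
            return f, mom
        c0 = self.conn[:, 0]
        c1 = self.conn[:, 1]
        x1 = state.x[c0]
        x2 = state.x[c1]
        d = x2 - x1
        l = np.linalg.norm(d, axis=1)
        if np.any(l < 1e-12):
            raise DivergenceError("zero-length beam element")
        t = d / l[:, None]
        eps0 = (l - self.L0) / self.L0

        q1 = state.q[c0]
        q2 = state.q[c1]
        rrel = _rotvec_from_q(_qmul(_qconj(q1), q2))
        qm = _qmul(q1, _q_from_rotvec(0.5 * rrel))
        qmE = _qmul(qm, self.qE0)
        a1, _, _ = _q_cols(qmE)
        q_al = _q_between(a1, t)
        q_e = _qmul(q_al, qmE)
        qe_inv = _qconj(q_e)
        th1 = _rotvec_from_q(_qmul(qe_inv, _qmul(q1, self.qE0)))
        th2 = _rotvec_from_q(_qmul(qe_inv, _qmul(q2, self.qE0)))

        L0 = self.L0
        # curvature shape functions at the 2 Gauss points, v(x) cubic with
        # v(0)=v(L)=0, v'(0)=th1, v'(L)=th2:  v'' = B1 th1 + B2 th2
        xg = _GAUSS_X[None, :] * L0[:, None]        # (E, 2)
        B1 = -4.0 / L0[:, None] + 6.0 * xg / L0[:, None] ** 2
        B2 = -2.0 / L0[:, None] + 6.0 * xg / L0[:, None] ** 2
        kv = B1 * th1[:, 2:3] + B2 * th2[:, 2:3]    # v'' (bend about e3)
        kw = -(B1 * th1[:, 1:2] + B2 * th2[:, 1:2])  # w'' (bend about e2)

        # fibre strains (E, 2, 4)
        epsf = (eps0[:, None, None]
                - self.fib_y[:, None, :] * kv[:, :, None]
                - self.fib_z[:, None, :] * kw[:, :, None])
        if self.beam_is_sma:
            if commit:
                sig, state.sma = sma_update(epsf, state.sma, self.beam_material)
            else:
                sig, _ = sma_update(epsf, state.sma.copy(), self.beam_material)
        else:
            sig = self.beam_E_ref * epsf
        state.max_fibre_strain = float(np.max(np.abs(epsf))) \
            if epsf.size else 0.0

        wf = (self.A / 4.0)[:, None, None]
        Nx = np.sum(wf * sig, axis=2)                       # (E, 2)
        Mv = np.sum(wf * sig * (-self.fib_y[:, None, :]), axis=2)
        Mw = np.sum(wf * sig * (-self.fib_z[:, None, :]), axis=2)

        P = 0.5 * (Nx[:, 0] + Nx[:, 1])                     # axial force
        wg = 0.5 * L0                                       # Gauss weight
        Mz1 = wg * (Mv[:, 0] * B1[:, 0] + Mv[:, 1] * B1[:, 1])
        Mz2 = wg * (Mv[:, 0] * B2[:, 0] + Mv[:, 1] * B2[:, 1])
        My1 = -wg * (Mw[:, 0] * B1[:, 0] + Mw[:, 1] * B1[:, 1])
        My2 = -wg * (Mw[:, 0] * B2[:, 0] + Mw[:, 1] * B2[:, 1])
        Tq = self.beam_G * self.J * (th2[:, 0] - th1[:, 0]) / L0

        # element frame axes
        e1, e2, e3 = _q_cols(q_e)

        sumMz = (Mz1 + Mz2) / l
        sumMy = (My1 + My2) / l
        f2 = P[:, None] * t - sumMz[:, None] * e2 + sumMy[:, None] * e3
        m1 = -Tq[:, None] * e1 + My1[:, None] * e2 + Mz1[:, None] * e3
        m2 = Tq[:, None] * e1 + My2[:, None] * e2 + Mz2[:, None] * e3
        nn = self.n_nodes
        for comp in range(3):
            f[:, comp] += (np.bincount(c1, f2[:, comp], nn)
                           - np.bincount(c0, f2[:, comp], nn))
            mom[:, comp] += (np.bincount(c0, m1[:, comp], nn)
                             + np.bincount(c1, m2[:, comp], nn))
        return f, mom

    def membrane_forces(self, state: DynamicState) -> np.ndarray:
        """Total-Lagrangian CST membrane internal forces (N,3)."""
        f = np.zeros((self.n_nodes, 3))
        if self.n_tris == 0:
            return f
        p = state.x[self.tri]                      # (T, 3, 3)
        g1 = p[:, 1] - p[:, 0]
        g2 = p[:, 2] - p[:, 0]
        # deformation gradient F (3x2) = [g1 g2] @ Dinv
        F = np.empty((self.n_tris, 3, 2))
        F[:, :, 0] = g1 * self.Dinv[:, 0, 0, None] + g2 * self.Dinv[:, 1, 0, None]
        F[:, :, 1] = g1 * self.Dinv[:, 0, 1, None] + g2 * self.Dinv[:, 1, 1, None]
        C = np.einsum("tki,tkj->tij", F, F)
        E = 0.5 * (C - np.eye(2))
        gm = self.graft_material
        S = fabric_update(E, gm)                   # (T, 2, 2)

        # deformation monitoring, in engineering stretch measures.
        # Tensile principal stretch is always scored.  Compressive crush
        # (1 - lambda_2) and area collapse count only where the membrane
        # carries significant compressive stress: a fabric (or a very
        # compliant membrane) folds and wrinkles harmlessly, while
        # crushing a structurally engaged membrane is the hallmark of a
        # collapsing run.
        tr = E[..., 0, 0] + E[..., 1, 1]
        dd = 0.5 * (E[..., 0, 0] - E[..., 1, 1])
        rad = np.sqrt(dd * dd + E[..., 0, 1] ** 2)
        lam1 = np.sqrt(np.maximum(1.0 + 2.0 * (0.5 * tr + rad), 0.0))
        lam2 = np.sqrt(np.maximum(1.0 + 2.0 * (0.5 * tr - rad), 0.0))
        strain_score = float(np.max(lam1)) - 1.0
        s_tr = S[..., 0, 0] + S[..., 1, 1]
        s_dd = 0.5 * (S[..., 0, 0] - S[..., 1, 1])
        s_rad = np.sqrt(s_dd * s_dd + S[..., 0, 1] ** 2)
        s2 = 0.5 * s_tr - s_rad
        loaded = s2 < -self.cfg.membrane_stress_floor
        state.min_area_ratio = 1.0
        if np.any(loaded):
            strain_score = max(strain_score,
                               float(np.max(1.0 - lam2[loaded], initial=0.0)))
            detC = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
            state.min_area_ratio = float(np.sqrt(
                max(np.min(detC[loaded]), 0.0)))
        state.max_membrane_strain = strain_score
        state.min_membrane_stress = float(np.min(s2)) if s2.size else 0.0

        P = np.einsum("tki,tij->tkj", F, S)        # 1st PK (3x2)
        s = (self.A0 * gm.thickness)[:, None]
        # shape gradients in reference coords: G1 = Dinv[0], G2 = Dinv[1]
        f1 = s * (P[:, :, 0] * self.Dinv[:, 0, 0, None]
                  + P[:, :, 1] * self.Dinv[:, 0, 1, None])
        f2 = s * (P[:, :, 0] * self.Dinv[:, 1, 0, None]
                  + P[:, :, 1] * self.Dinv[:, 1, 1, None])
        np.add.at(f, self.tri[:, 1], f1)
        np.add.at(f, self.tri[:, 2], f2)
        np.add.at(f, self.tri[:, 0], -f1 - f2)
        return f

    def internal_forces(self, state: DynamicState, commit: bool = True
                        ) -> Tuple[np.ndarray, np.ndarray]:
        fb, mom = self.beam_forces(state, commit=commit)
        fm = self.membrane_forces(state)
        return fb + fm, mom

    # -- time integration --------------------------------------------------
    def step(self, state: DynamicState, *,
             f_ext: Optional[np.ndarray] = None,
             contact: Optional[Callable] = None,
             prescribed: Optional[Callable] = None,
             check_fatal: bool = False) -> DynamicState:
        """One central-difference step (in place); returns ``state``.

        ``contact(state) -> (forces, dissipation)`` adds contact forces;
        ``prescribed(state, t_new, dt)`` must return (idx, x_target) for
        displacement-driven nodes; their velocity is set consistently.
        """
        cfg = self.cfg
        dt = self.dt
        x_old = state.x
        f_int, mom_int = self.internal_forces(state, commit=True)
        f = -f_int
        if f_ext is not None:
            f = f + f_ext
        fric = 0.0
        if contact is not None:
            fc, fric = contact(state)
            f = f + fc
        state.f_net = f
        # second-order (trapezoidal) correction of last step's work terms
        if state.dx_prev is not None:
            if state.f_int_prev is not None:
                state.internal_energy += 0.5 * float(
                    np.sum((f_int - state.f_int_prev) * state.dx_prev))
            if contact is not None and state.fc_prev is not None:
                state.contact_energy += 0.5 * float(
                    np.sum((fc - state.fc_prev) * state.dx_prev))
        if state.dth_prev is not None and state.mom_prev is not None:
            state.internal_energy += 0.5 * float(
                np.sum((mom_int - state.mom_prev) * state.dth_prev))
        state.f_int_prev = f_int
        state.fc_prev = fc if contact is not None else None
        state.mom_prev = mom_int
        # instantaneous force magnitudes for equilibrium residual scales
        state.contact_force_max = (
            float(np.max(np.linalg.norm(fc, axis=1)))
            if contact is not None else 0.0)
        state.ext_force_max = (
            float(np.max(np.linalg.norm(f_ext, axis=1)))
            if f_ext is not None else 0.0)
        state.int_force_max = (
            float(np.max(np.abs(f_int))) if (self.n_beams or self.n_tris)
            else 0.0)
        scale = (state.contact_force_max or state.ext_force_max
                 or state.int_force_max)
        state.force_scale = max(state.force_scale, scale)
        m = self.mass[:, None]
        dmp = self.damping[:, None]
        # trapezoidal mass-proportional damping
        c = 0.5 * dmp * dt
        v_new = ((1.0 - c) * state.v + dt * f / m) / (1.0 + c)
        w_new = ((1.0 - c) * state.w + dt * (-mom_int) / self.inertia[:, None]) \
            / (1.0 + c)
        ke_before = 0.5 * (float(np.sum(self.mass * np.sum(v_new ** 2, axis=1)))
                           + float(np.sum(self.inertia * np.sum(w_new ** 2, axis=1))))
        w_new = w_new * (1.0 - cfg.rot_damp)
        if cfg.lin_damp:
            v_new = v_new * (1.0 - cfg.lin_damp)

        t_new = state.time + dt
        if prescribed is not None:
            res = prescribed(state, t_new, dt)
            idx, x_t = res[0], res[1]
            rot_idx = res[2] if len(res) > 2 else None
            if idx is not None and len(idx):
                v_new[idx] = (x_t - x_old[idx]) / dt
            if rot_idx is not None and len(rot_idx):
                w_new[rot_idx] = 0.0

        dx = v_new * dt
        state.x = x_old + dx
        state.v = v_new
        state.w = w_new
        dq = _q_from_rotvec(w_new * dt)
        state.q = _qmul(dq, state.q)
        state.q /= np.linalg.norm(state.q, axis=-1, keepdims=True)
        state.time = t_new

        # energy bookkeeping (midpoint increments)
        ke = 0.5 * float(np.sum(self.mass * np.sum(v_new * v_new, axis=1))
                         + np.sum(self.inertia * np.sum(w_new * w_new, axis=1)))
        state.kinetic_energy = ke
        state.peak_kinetic_energy = max(state.peak_kinetic_energy, ke)
        state.internal_energy += float(np.sum(f_int * dx))
        dth = w_new * dt
        state.internal_energy += float(np.sum(mom_int * dth))
        if contact is not None:
            state.contact_energy += float(np.sum(fc * dx))
        state.dx_prev = dx
        state.dth_prev = dth
        state.damping_energy += float(np.sum(dmp * m * v_new * v_new) * dt)
        state.damping_energy += max(ke_before - ke, 0.0)  # lin/rot drag
        state.friction_energy += float(fric)
        if f_ext is not None:
            state.external_work += float(np.sum(f_ext * dx))

        if not np.isfinite(ke) or ke > cfg.energy_blowup_factor * max(
                1e-12, abs(state.internal_energy) + 1.0):
            raise DivergenceError(f"kinetic energy blow-up at t={t_new:g}")
        if check_fatal:
            over = (state.max_fibre_strain > cfg.fatal_strain
                    or state.max_membrane_strain > cfg.fatal_strain
                    or (self.n_tris and state.min_area_ratio
                        < cfg.fatal_area_ratio)
                    or (self.n_tris and state.min_membrane_stress
                        < -cfg.membrane_stress_limit))
            hard = (state.max_fibre_strain > 2.0 * cfg.fatal_strain
                    or state.max_membrane_strain > 2.0 * cfg.fatal_strain)
            self._fatal_count = self._fatal_count + 1 if over else 0
            if hard or self._fatal_count > cfg.fatal_patience:
                raise FatalDeformationError(
                    f"fatal deformation at t={t_new:g}: "
                    f"fibre strain {state.max_fibre_strain:.3f}, "
                    f"membrane strain {state.max_membrane_strain:.3f}, "
                    f"area ratio {state.min_area_ratio:.3f}")
        return state


def relax_to_equilibrium(model: StructuralModel, state: DynamicState, *,
                         contact: Optional[Callable] = None,
                         prescribed: Optional[Callable] = None,
                         f_ext: Optional[np.ndarray] = None,
                         ke_tol: Optional[float] = None,
                         force_tol: float = 1e-3,
                         force_floor: float = 0.0,
                         max_steps: Optional[int] = None,
                         min_steps: int = 50,
                         kinetic_damping: bool = True,
                         stride: int = 50,
                         check_fatal: bool = False) -> DynamicState:
    """Dynamic relaxation to quasi-static equilibrium.

    Prescribed motions are held at their current targets.  With
    ``kinetic_damping`` (default) the kinetic energy is monitored every
    ``stride`` steps and all velocities are zeroed when it has passed a
    peak; the stride keeps high-frequency wiggles from masking the slow
    travel modes.  At each reset the out-of-balance force of the free
    nodes is compared with the peak applied force of this relaxation,
    and the run terminates when the relative residual drops below
    ``force_tol``.  Without kinetic damping the viscous per-step drag of
    the config does the settling (the stable choice with frictional
    contact) and the same residual criterion is checked periodically.
    Raises NonConvergenceError when ``max_steps`` is exhausted first.
    """
    cfg = model.cfg
    tol = ke_tol if ke_tol is not None else cfg.ke_tol
    nmax = max_steps if max_steps is not None else cfg.max_steps
    peak = 0.0
    ke_prev = 0.0
    # residual reference: the peak out-of-balance force on free nodes
    # observed during this relaxation (decays to ~0 at equilibrium)
    scale = 0.0
    free = np.ones(model.n_nodes, bool)

    def _residual_ok(i: int) -> bool:
        nonlocal scale
        if prescribed is not None:
            idx = prescribed(state, state.time, model.dt)[0]
            free[:] = True
            if idx is not None:
                free[idx] = False
        resid = float(np.max(np.abs(state.f_net[free]))) \
            if np.any(free) else 0.0
        scale = max(scale, resid, state.contact_force_max,
                    state.ext_force_max)
        if i < min_steps:
            return False
        return resid <= max(force_tol * scale, force_floor)

    check_every = max(min_steps, 100)
    # kinetic damping supplies its own dissipation; the per-step viscous
    # drag would throttle the free travel it relies on
    saved_lin = cfg.lin_damp
    if kinetic_damping:
        cfg.lin_damp = 0.0
    try:
        return _relax_loop(model, state, nmax, kinetic_damping, stride,
                           _residual_ok, f_ext, contact, prescribed,
                           check_fatal, min_steps, ke_tol, tol, check_every)
    finally:
        cfg.lin_damp = saved_lin


def _relax_loop(model, state, nmax, kinetic_damping, stride, _residual_ok,
                f_ext, contact, prescribed, check_fatal, min_steps,
                ke_tol, tol, check_every):
    peak = 0.0
    ke_prev = 0.0
    for i in range(nmax):
        model.step(state, f_ext=f_ext, contact=contact,
                   prescribed=prescribed, check_fatal=check_fatal)
        ke = state.kinetic_energy
        peak = max(peak, ke)
        if kinetic_damping:
            if (i + 1) % stride == 0:
                ok = _residual_ok(i)
                if ke < ke_prev:  # passed a peak: kill the velocities
                    state.damping_energy += ke
                    state.v[:] = 0.0
                    state.w[:] = 0.0
                    ke = 0.0
                    if ok:
                        return state
                ke_prev = ke
        else:
            # viscous settling (the stable choice with friction)
            if (i + 1) % check_every == 0 and _residual_ok(i):
                return state
            if ke_tol is not None and i >= min_steps and peak > 0 \
                    and ke < tol * peak:
                return state
    raise NonConvergenceError(
        f"dynamic relaxation did not converge in {nmax} steps "
        f"(residual {float(np.max(np.abs(state.f_net))):.3e})")


# ---------------------------------------------------------------------------
# free-function wrappers (operate on meshes without a solver loop)
# ---------------------------------------------------------------------------

def beam_internal_forces(mesh: BeamMesh, displacements: np.ndarray,
                         material) -> np.ndarray:
    """Beam internal nodal forces for given nodal displacements.

    Rotational DOFs are relaxed to the chord orientation (nodes follow
    the wire), which makes this a convenience check for translation-only
    load cases; the full solver carries explicit nodal triads.
    """
    model = StructuralModel(stent=mesh, beam_material=material)
    st = model.initial_state()
    st.x = mesh.node_coords + displacements
    f, _ = model.beam_forces(st, commit=False)
    return f


def membrane_internal_forces(mesh: MembraneMesh, displacements: np.ndarray,
                             params: FabricParams) -> np.ndarray:
    """Membrane internal nodal forces for given nodal displacements."""
    model = StructuralModel(graft=mesh, graft_material=params,
                            merge_sutures=False)
    st = model.initial_state()
    st.x = mesh.node_coords + displacements
    return model.membrane_forces(st)
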