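"""Material laws for stent-graft simulation.

Three laws are provided:

* a history-dependent uniaxial superelastic Nitinol model of the
  Auricchio--Taylor type, with flat forward/reverse transformation
  plateaus, used for the stent wire fibres;
* a plane-stress fabric law for the PET graft in which compressive
  principal stresses are suppressed (woven fabric carries no compression);
* linear-elastic variants used by the verification matrix.

Units are mm / N / MPa / tonne / s throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "NitinolParams",
    "SMAState",
    "FabricParams",
    "VALIANT_CAPTIVIA_TABLE2",
    "KLEINSTREUER_2008",
    "DEFAULT_FABRIC",
    "sma_update",
    "fabric_update",
    "linear_elastic_update",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NitinolParams:
    """Parameters of the uniaxial superelastic law.

    Attributes
    ----------
    E_A, E_M : float
        Austenite / martensite Young's moduli [MPa].
    nu : float
        Poisson's ratio, shared by both phases (enters only through the
        elastic torsion modulus of the wire).
    sig_SL, sig_EL : float
        Start / end stress of the forward (austenite -> martensite)
        transformation plateau in tension [MPa].
    sig_SU, sig_EU : float
        Start / end stress of the reverse transformation plateau on
        unloading [MPa].
    eps_L : float
        Maximum transformation (recoverable inelastic) strain [-].
    alpha : float
        Tension/compression asymmetry; compressive transformation onsets
        are scaled by (1 + alpha).
    """

    E_A: float = 57500.0
    E_M: float = 47800.0
    nu: float = 0.3
    sig_SL: float = 550.0
    sig_EL: float = 620.0
    sig_SU: float = 450.0
    sig_EU: float = 250.0
    eps_L: float = 0.063
    alpha: float = 0.0279

    def __post_init__(self) -> None:
        if not (self.E_A > 0 and self.E_M > 0):
            raise ValueError("moduli must be positive")
        if not (self.sig_EL > self.sig_SL > self.sig_SU > self.sig_EU > 0):
            raise ValueError(
                "transformation stresses must satisfy "
                "sig_EL > sig_SL > sig_SU > sig_EU > 0"
            )
        if not (0.0 < self.eps_L < 0.15):
            raise ValueError("eps_L must lie in (0, 0.15)")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not (0.0 < self.nu < 0.5):
            raise ValueError("nu must lie in (0, 0.5)")

    @property
    def G_A(self) -> float:
        """Austenite shear modulus [MPa] (elastic torsion of the wire)."""
        return self.E_A / (2.0 * (1.0 + self.nu))


#: Calibrated Valiant Captivia ring parameter preset.
VALIANT_CAPTIVIA_TABLE2 = NitinolParams()

#: Literature starting point for Nitinol calibration
#: (Kleinstreuer et al. 2008, J. Biomech. 41:2370-2378, stent-graft NiTi).
KLEINSTREUER_2008 = NitinolParams(
    E_A=51700.0,
    E_M=47800.0,
    nu=0.3,
    sig_SL=600.0,
    sig_EL=670.0,
    sig_SU=288.0,
    sig_EU=254.0,
    eps_L=0.063,
    alpha=0.0,
)


@dataclass(frozen=True)
class FabricParams:
    """Plane-stress graft fabric parameters.

    ``compressive_stiffness_factor`` scales compressive principal
    stresses: 0 reproduces a true fabric (no resistance to compression,
    wrinkling-like behaviour), 1 recovers classical isotropic
    plane-stress elasticity.
    """

    E_long: float = 1080.0  # MPa, longitudinal modulus of the woven PET
    nu: float = 0.35
    thickness: float = 0.1  # mm
    compressive_stiffness_factor: float = 0.0

    def __post_init__(self) -> None:
        if self.E_long <= 0:
            raise ValueError("E_long must be positive")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if not (0.0 <= self.compressive_stiffness_factor <= 1.0):
            raise ValueError("compressive_stiffness_factor must be in [0, 1]")


DEFAULT_FABRIC = FabricParams()


# ---------------------------------------------------------------------------
# superelastic state and update
# ---------------------------------------------------------------------------

@dataclass
class SMAState:
    """Vectorised history state of the superelastic law.

    All fields are ndarrays of a common shape (one entry per material
    point / beam fibre).  ``sgn`` is the sign of the stress that drove
    the current transformation (+1 tension, -1 compression); it is
    meaningful only while ``xi > 0``.
    """

    xi: np.ndarray
    eps: np.ndarray
    sig: np.ndarray
    sgn: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "SMAState":
        return cls(
            xi=np.zeros(shape),
            eps=np.zeros(shape),
            sig=np.zeros(shape),
            sgn=np.ones(shape),
        )

    def copy(self) -> "SMAState":
        return SMAState(self.xi.copy(), self.eps.copy(),
                        self.sig.copy(), self.sgn.copy())


def _reuss_compliance(xi: np.ndarray, p: NitinolParams) -> np.ndarray:
    """Phase-mixture compliance 1/E(xi) (Reuss / series mixing)."""
    return (1.0 - xi) / p.E_A + xi / p.E_M


def _plateau_solve(eps_hat, a, b, scale, xi_like, p):
    """Solve for xi on a transformation plateau.

    On the plateau the (signed-projected) stress is ``scale*(a + b*xi)``
    and the strain decomposition reads

        eps_hat = sig_hat / E(xi) + xi * eps_L

    which with Reuss mixing is quadratic in xi.  Returns the relevant
    real root (unclamped); callers clamp to [0, 1].
    """
    cA = 1.0 / p.E_A
    dc = 1.0 / p.E_M - cA
    A2 = scale * b * dc
    A1 = scale * (a * dc + b * cA) + p.eps_L
    A0 = scale * a * cA - eps_hat
    # A2 is tiny when E_A ~ E_M; fall back to the linear solution there.
    lin = -A0 / A1
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = A1 * A1 - 4.0 * A2 * A0
        disc = np.maximum(disc, 0.0)
        sq = np.sqrt(disc)
        # root continuous with the A2 -> 0 limit: use the "-" branch of
        # the numerically stable form q = -(A1 + sign(A1) sq)/2
        q = -(A1 + np.sign(A1) * sq) / 2.0
        r1 = np.where(A2 != 0.0, q / np.where(A2 != 0.0, A2, 1.0), lin)
        r2 = np.where(q != 0.0, A0 / np.where(q == 0.0, 1.0, q), lin)
    # pick the root lying in (or nearest to) [0, 1]
    mid = 0.5
    pick = np.abs(r1 - mid) <= np.abs(r2 - mid)
    return np.where(np.abs(A2) < 1e-16 * np.abs(A1), lin,
                    np.where(pick, r1, r2))


def sma_update(eps_new, state: SMAState, p: NitinolParams
               ) -> Tuple[np.ndarray, SMAState]:
    """Advance the superelastic law to the total strain ``eps_new``.

    The law is rate-independent and history-dependent: within a
    monotonic segment the result does not depend on the increment size.
    Returns the stress array and the committed new state.

    Branch structure (tension; compression mirrors with onsets scaled
    by ``1 + alpha``):

    * elastic with the phase-mixture modulus E(xi);
    * forward plateau from ``sig_SL`` to ``sig_EL`` accumulating the
      transformation strain ``xi * eps_L`` (xi: 0 -> 1);
    * martensite branch at ``E_M`` beyond full transformation;
    * reverse plateau from ``sig_SU`` down to ``sig_EU`` on unloading,
      recovering the transformation strain (xi -> 0).
    """
    eps_new = np.asarray(eps_new, dtype=float)
    if np.any(~np.isfinite(eps_new)):
        raise ValueError("non-finite strain passed to sma_update")
    if eps_new.shape != state.xi.shape:
        eps_new = np.broadcast_to(eps_new, state.xi.shape).astype(float)

    xi0 = state.xi
    # active transformation sign: frozen while xi > 0, else follows strain
    sgn = np.where(xi0 > 0.0, state.sgn, np.where(eps_new < 0.0, -1.0, 1.0))
    scale = np.where(sgn < 0.0, 1.0 + p.alpha, 1.0)

    comp0 = _reuss_compliance(xi0, p)
    sig_tr = (eps_new - sgn * xi0 * p.eps_L) / comp0
    d_tr = sgn * sig_tr  # stress projected on the transformation direction
    eps_hat = sgn * eps_new

    fwd_surface = scale * (p.sig_SL + (p.sig_EL - p.sig_SL) * xi0)
    rev_surface = scale * (p.sig_EU + (p.sig_SU - p.sig_EU) * xi0)

    b_fwd = p.sig_EL - p.sig_SL
    b_rev = p.sig_SU - p.sig_EU

    forward = (d_tr > fwd_surface + 1e-12) & (xi0 < 1.0)
    reverse = (d_tr < rev_surface - 1e-12) & (xi0 > 0.0)

    xi = xi0.copy()
    sig = sig_tr.copy()

    if np.any(forward):
        xf = _plateau_solve(eps_hat, p.sig_SL, b_fwd, scale, xi0, p)
        xf = np.clip(xf, xi0, 1.0)
        sigf = np.where(
            xf >= 1.0,
            sgn * (eps_hat - p.eps_L) * p.E_M,
            sgn * scale * (p.sig_SL + b_fwd * xf),
        )
        xi = np.where(forward, xf, xi)
        sig = np.where(forward, sigf, sig)

    if np.any(reverse):
        xr = _plateau_solve(eps_hat, p.sig_EU, b_rev, scale, xi0, p)
        xr = np.clip(xr, 0.0, xi0)
        sigr = np.where(
            xr <= 0.0,
            eps_new * p.E_A,
            sgn * scale * (p.sig_EU + b_rev * xr),
        )
        xi = np.where(reverse, xr, xi)
        sig = np.where(reverse, sigr, sig)

    new = SMAState(xi=xi, eps=eps_new.copy(), sig=sig,
                   sgn=np.where(xi > 0.0, sgn, np.sign(eps_new) + (eps_new == 0)))
    return sig, new


# ---------------------------------------------------------------------------
# fabric and linear laws
# ---------------------------------------------------------------------------

def _principal_2x2(strain: np.ndarray):
    """Closed-form eigen-decomposition of symmetric 2x2 tensors.

    Returns (e1, e2, c, s) with e1 >= e2 and the rotation
    (cos, sin) of the first principal direction.
    """
    exx = strain[..., 0, 0]
    eyy = strain[..., 1, 1]
    exy = 0.5 * (strain[..., 0, 1] + strain[..., 1, 0])
    tr = 0.5 * (exx + eyy)
    dd = 0.5 * (exx - eyy)
    rad = np.sqrt(dd * dd + exy * exy)
    e1 = tr + rad
    e2 = tr - rad
    theta = 0.5 * np.arctan2(2.0 * exy, exx - eyy)
    return e1, e2, np.cos(theta), np.sin(theta)


def fabric_update(membrane_strain: np.ndarray, p: FabricParams = DEFAULT_FABRIC
                  ) -> np.ndarray:
    """Plane-stress fabric response to an in-plane strain tensor.

    ``membrane_strain`` has shape (..., 2, 2).  The isotropic
    plane-stress stress is evaluated in the principal strain frame and
    any compressive principal stress is multiplied by
    ``compressive_stiffness_factor`` before rotating back.  Returns the
    Cauchy stress tensor [MPa], shape (..., 2, 2).  Multiply by the
    fabric thickness for stress resultants [N/mm].
    """
    strain = np.asarray(membrane_strain, dtype=float)
    if np.any(~np.isfinite(strain)):
        raise ValueError("non-finite strain passed to fabric_update")
    e1, e2, c, s = _principal_2x2(strain)
    k = p.E_long / (1.0 - p.nu ** 2)
    s1 = k * (e1 + p.nu * e2)
    s2 = k * (e2 + p.nu * e1)
    f = p.compressive_stiffness_factor
    s1 = np.where(s1 < 0.0, f * s1, s1)
    s2 = np.where(s2 < 0.0, f * s2, s2)
    # rotate back: R diag(s1,s2) R^T
    cc, ss, cs = c * c, s * s, c * s
    out = np.empty(strain.shape, dtype=float)
    out[..., 0, 0] = s1 * cc + s2 * ss
    out[..., 1, 1] = s1 * ss + s2 * cc
    out[..., 0, 1] = (s1 - s2) * cs
    out[..., 1, 0] = out[..., 0, 1]
    return out


def linear_elastic_update(eps, E: float):
    """History-free linear elasticity, sig = E * eps."""
    if E <= 0:
        raise ValueError("E must be positive")
    return E * np.asarray(eps, dtype=float)
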