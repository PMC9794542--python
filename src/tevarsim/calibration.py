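"""Nitinol parameter calibration from radial force-diameter curves.

The crimp/release radial-force curve of a single stent ring is the
experiment used to identify the superelastic parameters.  Running the
full explicit FE crimp inside an optimiser loop is far too slow, so the
fit uses a reduced ring model: one half-peak of the sinusoidal ring
treated as an initially-curved planar beam strip with both end tangents
held circumferential (symmetry) and the ends drawn together as the ring
circumference shrinks.  With no net axial force the bending moment
distribution is statically determinate, M(s) = -F * z(s) with F the
circumferential end force, and the end shortening follows from the
unit-load theorem.  Energy balance maps the strip force to the crimper
radial force (the sum of the 12 plane contacts): F_radial = 2 pi F.

The full FE ring model is available behind the same curve-generating
interface for verification of the surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constitutive import (KLEINSTREUER_2008, NitinolParams, SMAState,
                           sma_update)
from .geometry import RingSpec

__all__ = [
    "ForceDiameterCurve",
    "CalibrationConfig",
    "HalfPeakRingModel",
    "curve_percent_error",
    "calibrate_nitinol",
]


# ---------------------------------------------------------------------------
# force-diameter curves
# ---------------------------------------------------------------------------

@dataclass
class ForceDiameterCurve:
    """Phase-labelled radial force versus commanded diameter history."""

    diameter: np.ndarray          # mm
    force: np.ndarray             # N
    phase: np.ndarray             # array of "loading" / "unloading"
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, float)
        self.force = np.asarray(self.force, float)
        self.phase = np.asarray(self.phase)
        if np.any(self.diameter <= 0):
            raise ValueError("diameters must be positive")
        lab = (self.phase == "unloading").astype(int)
        if np.any(np.diff(lab) < 0):
            raise ValueError("loading must precede unloading")

    def select(self, phase: str) -> Tuple[np.ndarray, np.ndarray]:
        m = self.phase == phase
        return self.diameter[m], self.force[m]

    def interp(self, phase: str, d: np.ndarray) -> np.ndarray:
        dd, ff = self.select(phase)
        order = np.argsort(dd)
        return np.interp(d, dd[order], ff[order])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"diameter_mm": self.diameter,
                             "force_N": self.force, "phase": self.phase})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ForceDiameterCurve":
        df = pd.read_csv(path)
        return cls(df["diameter_mm"].to_numpy(),
                   df["force_N"].to_numpy(), df["phase"].to_numpy())


def curve_percent_error(sim: ForceDiameterCurve, ref: ForceDiameterCurve,
                        working_range: Tuple[float, float],
                        n_grid: int = 50) -> Dict[str, Tuple[float, float]]:
    """Per-phase mean +- sd of |F_sim - F_ref| / F_ref x 100.

    Both curves are resampled on a uniform ``n_grid``-point diameter grid
    inside ``working_range`` (which must overlap both curve domains).
    """
    d_lo, d_hi = min(working_range), max(working_range)
    out = {}
    for phase in ("loading", "unloading"):
        ds, _ = sim.select(phase)
        dr, _ = ref.select(phase)
        if ds.size == 0 or dr.size == 0:
            continue
        lo = max(d_lo, ds.min(), dr.min())
        hi = min(d_hi, ds.max(), dr.max())
        if not hi > lo:
            raise ValueError("working range does not overlap the curves")
        grid = np.linspace(lo, hi, n_grid)
        fs = sim.interp(phase, grid)
        fr = ref.interp(phase, grid)
        if np.any(fr == 0):
            raise ValueError("reference force vanishes inside working range")
        err = np.abs(fs - fr) / np.abs(fr) * 100.0
        out[phase] = (float(err.mean()), float(err.std(ddof=0)))
    return out


# ---------------------------------------------------------------------------
# reduced half-peak ring model
# ---------------------------------------------------------------------------

def _circle_fibres(radius: float, n: int = 8) -> Tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre layers over a circular section (bending about z).

    Returns fibre offsets y_i and weights w_i with sum w = area and
    sum w y^2 = pi R^4 / 4 to quadrature accuracy.
    """
    gp, gw = np.polynomial.legendre.leggauss(n)
    y = radius * gp
    w = radius * gw * 2.0 * np.sqrt(np.maximum(radius ** 2 - y ** 2, 0.0))
    return y, w


class HalfPeakRingModel:
    """Reduced (unit-cell) crimp model of one sinusoidal stent ring.

    Parameters
    ----------
    spec : RingSpec
        Peaks-ring geometry; the start diameter is the configuration the
        wire is meshed in (taken stress-free).
    n_stations : int
        Integration stations along the half-peak strip.
    n_fibres : int
        Gauss layers across the wire section (more than the 2 x 2 rule
        of the full FE model; the reduced model is cheap enough to
        resolve the plateau smoothly).
    """

    def __init__(self, spec: RingSpec, params: NitinolParams,
                 n_stations: int = 20, n_fibres: int = 8) -> None:
        if spec.kind == "thin":
            raise ValueError("reduced model applies to peaks rings")
        self.spec = spec
        self.params = params
        self.n = spec.n_peaks
        self.D0 = spec.nominal_diameter
        self.w0 = np.pi * self.D0 / (2.0 * self.n)
        self.h = spec.crown_height
        self.R = spec.wire_diameter / 2.0

        # arc-length discretisation of z0(x) = (h/2) cos(pi x / w0)
        xs = np.linspace(0.0, self.w0, 400)
        zs = 0.5 * self.h * np.cos(np.pi * xs / self.w0)
        ds = np.hypot(np.diff(xs), np.diff(zs))
        s = np.concatenate([[0.0], np.cumsum(ds)])
        self.L = s[-1]
        self.s = (np.arange(n_stations) + 0.5) * self.L / n_stations
        self.ds = self.L / n_stations
        self.x0 = np.interp(self.s, s, xs)
        self.z0 = np.interp(self.s, s, zs)
        self.alpha0 = np.arctan2(
            np.interp(self.s, s[:-1], np.diff(zs)),
            np.interp(self.s, s[:-1], np.diff(xs)))

        self.fib_y, self.fib_w = _circle_fibres(self.R, n_fibres)
        self.state = SMAState.zeros((n_stations, n_fibres))
        self.kappa = np.zeros(n_stations)
        self.z = self.z0.copy()

    # -- section response -------------------------------------------------
    def _moment(self, kappa: np.ndarray, state: SMAState) -> np.ndarray:
        """Section bending moment at trial curvature change (no commit)."""
        eps = -np.outer(kappa, np.ones_like(self.fib_y)) * self.fib_y
        sig, _ = sma_update(eps, state, self.params)  # no commit: sma_update does not mutate
        return -(sig * self.fib_y * self.fib_w).sum(axis=1)

    def _kappa_from_moment(self, M: np.ndarray) -> np.ndarray:
        """Invert the (history-dependent) section law per station.

        Safeguarded secant iteration inside a global bracket, warm
        started from the last committed curvature; converged to solver
        precision so the identification loss stays smooth (a coarse
        fixed-count bisection quantises the loss and makes the
        finite-difference jacobian of the optimiser noisy).
        """
        kmax = 4.0 * (self.params.eps_L + self.params.sig_EL
                      / self.params.E_M + 0.05) / self.R
        lo = np.full_like(M, -kmax)
        hi = np.full_like(M, kmax)
        warm = getattr(self, "_kappa_warm", self.kappa)
        if warm.shape != M.shape:
            warm = self.kappa
        x0 = np.clip(warm, lo + 1e-12, hi - 1e-12)
        f0 = self._moment(x0, self.state) - M
        x1 = np.clip(x0 + np.where(f0 > 0, -1e-4, 1e-4), lo, hi)
        f1 = self._moment(x1, self.state) - M
        EI = self.params.E_A * np.pi * self.R ** 4 / 4.0
        tol = 1e-9 * EI
        for _ in range(25):
            hi = np.where(f1 > 0, np.minimum(hi, x1), hi)
            lo = np.where(f1 > 0, lo, np.maximum(lo, x1))
            if np.all(np.abs(f1) <= tol):
                break
            df = f1 - f0
            step = np.where(np.abs(df) > 1e-300,
                            f1 * (x1 - x0) / np.where(df == 0, 1.0, df),
                            0.0)
            x2 = x1 - step
            bad = (x2 <= lo) | (x2 >= hi) | ~np.isfinite(x2)
            x2 = np.where(bad, 0.5 * (lo + hi), x2)
            x0, f0 = x1, f1
            x1 = x2
            f1 = self._moment(x1, self.state) - M
        self._kappa_warm = x1
        return x1

    # -- kinematics -------------------------------------------------------
    def _shortening(self, kappa: np.ndarray) -> float:
        """End shortening of the strip for a curvature-change field."""
        alpha = self.alpha0 + np.cumsum(kappa) * self.ds \
            - 0.5 * kappa * self.ds
        w = float(np.sum(np.cos(alpha)) * self.ds)
        return self.w0 - w

    def _update_shape(self, kappa: np.ndarray) -> None:
        alpha = self.alpha0 + np.cumsum(kappa) * self.ds \
            - 0.5 * kappa * self.ds
        z = np.cumsum(np.sin(alpha)) * self.ds
        self.z = z - z.mean()     # antisymmetric strip: M = 0 at midspan

    # -- load stepping ----------------------------------------------------
    def shortening_at_force(self, F: float) -> float:
        M = -F * self.z
        kappa = self._kappa_from_moment(M)
        return self._shortening(kappa)

    def force_at_diameter(self, d: float) -> float:
        """Circumferential strip force holding the ring at diameter d.

        Commits the material history; call with a monotone-in-time
        diameter schedule.  Returns 0 when the ring is slack (commanded
        diameter above the current free diameter).
        """
        target = np.pi * (self.D0 - d) / (2.0 * self.n)
        # free-recovery shortening at F = 0 (reverse transformation)
        g0 = self.shortening_at_force(0.0) - target
        tol = 1e-8 * max(1.0, self.w0)
        if g0 >= -tol:
            F = 0.0   # ring slack: commanded diameter above free diameter
        else:
            # expand a bracket from the previous force, then regula falsi
            F_lo, g_lo = 0.0, g0
            F_hi = max(getattr(self, "_F_prev", 0.0), 1e-3)
            g_hi = self.shortening_at_force(F_hi) - target
            for _ in range(60):
                if g_hi >= 0.0:
                    break
                F_lo, g_lo = F_hi, g_hi
                F_hi *= 2.0
                g_hi = self.shortening_at_force(F_hi) - target
            F = F_hi
            for _ in range(40):
                F = F_hi - g_hi * (F_hi - F_lo) / (g_hi - g_lo) \
                    if g_hi != g_lo else 0.5 * (F_lo + F_hi)
                F = min(max(F, F_lo + 1e-12), F_hi - 1e-12) \
                    if F_hi > F_lo else F
                g = self.shortening_at_force(F) - target
                if abs(g) < tol:
                    break
                if g > 0.0:
                    F_hi, g_hi = F, g
                else:
                    F_lo, g_lo = F, g
            self._F_prev = F
        # commit history and update the strip shape
        M = -F * self.z
        kappa = self._kappa_from_moment(M)
        eps = -np.outer(kappa, np.ones_like(self.fib_y)) * self.fib_y
        _, self.state = sma_update(eps, self.state, self.params)
        self.kappa = kappa
        self._update_shape(kappa)
        return F

    def radial_force_at_diameter(self, d: float) -> float:
        """Total crimper radial force at commanded diameter d [N]."""
        return 2.0 * np.pi * self.force_at_diameter(d)

    def run_crimp_release(self, min_diameter: float = 5.0,
                          release_to: Optional[float] = None,
                          n_samples: int = 40) -> ForceDiameterCurve:
        """Quasi-static crimp/release sweep; returns the radial curve."""
        release_to = self.D0 if release_to is None else release_to
        d_load = np.linspace(self.D0, min_diameter, n_samples)
        d_unload = np.linspace(min_diameter, release_to, n_samples)[1:]
        d_all = np.concatenate([d_load, d_unload])
        phase = np.array(["loading"] * len(d_load)
                         + ["unloading"] * len(d_unload))
        F = np.array([self.radial_force_at_diameter(d) for d in d_all])
        return ForceDiameterCurve(d_all, F, phase,
                                  metadata={"model": "half_peak",
                                            "ring": self.spec.kind})


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

#: parameters the optimiser may free, in canonical order
_FITTABLE = ("E_A", "E_M", "sig_SL", "sig_EL", "sig_SU", "sig_EU", "eps_L")


@dataclass
class CalibrationConfig:
    """Settings of the Nitinol identification problem.

    The transformation-stress ordering (sig_EL > sig_SL, sig_SU >
    sig_EU) is enforced structurally: the optimiser works in log space
    on sig_SL, the plateau width sig_EL - sig_SL, sig_EU and the width
    sig_SU - sig_EU.
    """

    free_parameters: Tuple[str, ...] = _FITTABLE
    start: NitinolParams = KLEINSTREUER_2008
    bounds_scale: float = 3.0        # multiplicative bounds around start
    working_range: Tuple[float, float] = (25.0, 27.0)
    loss: str = "sse"                # "sse" | "mae"

    def __post_init__(self) -> None:
        for p in self.free_parameters:
            if p not in _FITTABLE:
                raise ValueError(f"cannot fit parameter {p!r}")
        if self.loss not in ("sse", "mae"):
            raise ValueError("loss must be 'sse' or 'mae'")


def _pack(p: NitinolParams, free: Sequence[str]) -> np.ndarray:
    raw = {"E_A": p.E_A, "E_M": p.E_M, "sig_SL": p.sig_SL,
           "sig_EL": p.sig_EL - p.sig_SL, "sig_SU": p.sig_SU - p.sig_EU,
           "sig_EU": p.sig_EU, "eps_L": p.eps_L}
    return np.array([np.log(raw[k]) for k in free])


def _unpack(x: np.ndarray, base: NitinolParams, free: Sequence[str]
            ) -> NitinolParams:
    vals = dict(zip(free, np.exp(x)))
    E_A = vals.get("E_A", base.E_A)
    E_M = vals.get("E_M", base.E_M)
    sig_SL = vals.get("sig_SL", base.sig_SL)
    d_L = vals.get("sig_EL", base.sig_EL - base.sig_SL)
    sig_EU = vals.get("sig_EU", base.sig_EU)
    d_U = vals.get("sig_SU", base.sig_SU - base.sig_EU)
    eps_L = vals.get("eps_L", base.eps_L)
    return replace(base, E_A=E_A, E_M=E_M, sig_SL=sig_SL,
                   sig_EL=sig_SL + d_L, sig_EU=sig_EU,
                   sig_SU=sig_EU + d_U, eps_L=eps_L)


@dataclass
class CalibrationResult:
    params: NitinolParams
    cost: float
    n_evaluations: int
    success: bool
    message: str
    phase_errors: Dict[str, Tuple[float, float]]

    def to_dict(self) -> Dict:
        return {
            "params": self.params.__dict__,
            "cost": self.cost,
            "n_evaluations": self.n_evaluations,
            "success": self.success,
            "message": self.message,
            "phase_errors": self.phase_errors,
        }


def simulate_ring_curve(params: NitinolParams, spec: RingSpec,
                        min_diameter: float = 5.0,
                        n_samples: int = 40) -> ForceDiameterCurve:
    """Crimp/release curve of the reduced ring model at given parameters."""
    return HalfPeakRingModel(spec, params).run_crimp_release(
        min_diameter=min_diameter, n_samples=n_samples)


def calibrate_nitinol(ref_curves: Sequence[Tuple[RingSpec, ForceDiameterCurve]],
                      cfg: CalibrationConfig = CalibrationConfig(),
                      min_diameter: float = 5.0,
                      n_samples: int = 40) -> CalibrationResult:
    """Fit free Nitinol parameters to reference crimp/release curves.

    ``ref_curves`` pairs each reference curve with the ring geometry that
    produced it.  The misfit is evaluated over the full crimp range (the
    deep-crimp branch carries the martensite-modulus information; the
    device working range is used only for error reporting), with bounded
    least squares in log-parameter space starting from ``cfg.start``.
    """
    free = list(cfg.free_parameters)
    n_eval = 0

    # reference samples: interpolate each phase of each curve on its grid
    targets = []
    for spec, ref in ref_curves:
        norm = float(np.mean(np.abs(ref.force))) or 1.0
        targets.append((spec, ref, norm))

    def make_residuals(base: NitinolParams, sub_free):
        def residuals(x: np.ndarray) -> np.ndarray:
            nonlocal n_eval
            n_eval += 1
            try:
                p = _unpack(x, base, sub_free)
            except ValueError:
                return np.full(1, 1e3)
            res = []
            for spec, ref, norm in targets:
                sim = simulate_ring_curve(p, spec, min_diameter=min_diameter,
                                          n_samples=n_samples)
                for phase in ("loading", "unloading"):
                    dr, fr = ref.select(phase)
                    fs = sim.interp(phase, dr)
                    r = (fs - fr) / norm
                    if cfg.loss == "mae":
                        r = np.sign(r) * np.sqrt(np.abs(r))
                    res.append(r)
            out = np.concatenate(res)
            if not np.all(np.isfinite(out)):
                raise FloatingPointError("non-finite calibration loss")
            return out
        return residuals

    def solve(base: NitinolParams, sub_free):
        x0 = _pack(base, sub_free)
        lb = x0 - np.log(cfg.bounds_scale)
        ub = x0 + np.log(cfg.bounds_scale)
        return least_squares(make_residuals(base, sub_free), x0,
                             bounds=(lb, ub), method="trf",
                             diff_step=1e-3, xtol=1e-8, ftol=1e-10)

    # Staged identification, mirroring how such curves are calibrated by
    # hand: the loading-branch parameters first (initial slope and
    # forward plateau), then the martensite/reverse set, then a full
    # co-fit refinement.  The staged start lands the final solve in the
    # right basin; a cold simultaneous fit of all parameters from the
    # literature start can stall in a compensated local minimum under
    # an unlucky noise draw.
    start = cfg.start
    stage_a = [p for p in ("E_A", "sig_SL", "sig_EL") if p in free]
    stage_b = [p for p in ("E_M", "sig_SU", "sig_EU", "eps_L") if p in free]
    if len(free) >= 5 and stage_a and stage_b:
        sol_a = solve(start, stage_a)
        start = _unpack(sol_a.x, start, stage_a)
        sol_b = solve(start, stage_b)
        start = _unpack(sol_b.x, start, stage_b)
    sol = solve(start, free)
    params = _unpack(sol.x, start, free)

    phase_errors: Dict[str, Tuple[float, float]] = {}
    spec0, ref0, _ = targets[0]
    sim0 = simulate_ring_curve(params, spec0, min_diameter=min_diameter,
                               n_samples=n_samples)
    try:
        phase_errors = curve_percent_error(sim0, ref0, cfg.working_range)
    except ValueError:
        phase_errors = {}

    x_final = _pack(start, free)
    at_bound = np.any(np.isclose(sol.x, x_final - np.log(cfg.bounds_scale))) \
        or np.any(np.isclose(sol.x, x_final + np.log(cfg.bounds_scale)))
    msg = sol.message + (" [warning: solution at parameter bound]"
                         if at_bound else "")
    return CalibrationResult(params=params, cost=float(sol.cost),
                             n_evaluations=n_eval, success=bool(sol.success),
                             message=msg, phase_errors=phase_errors)
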