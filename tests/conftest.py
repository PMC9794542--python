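"""Shared fixtures.

The expensive simulations (full-FE ring crimp, calibration recovery,
verification matrix) are session-scoped so every test that needs them
shares a single run.
"""

import time
import warnings

import numpy as np
import pytest

import tevarsim as tv
from tevarsim.calibration import (CalibrationConfig, calibrate_nitinol,
                                  simulate_ring_curve)
from tevarsim.fe_core import SolverConfig, StructuralModel
from tevarsim.geometry import RingSpec, make_ring
from tevarsim.protocols import (CrimpProtocol, DeploymentProtocol,
                                run_crimp_release, run_verification_matrix)
from tevarsim.toolkit import SynthConfig, gen_synthetic_curve


@pytest.fixture(scope="session")
def table2():
    return tv.VALIANT_CAPTIVIA_TABLE2


@pytest.fixture(scope="session")
def ring_crimp_fe():
    """Full explicit-FE crimp/release of the 30 mm 8-peaks ring.

    Frictionless planes: the axisymmetric reference case used for the
    plane-force symmetry, energy-balance and full-recovery checks.
    Returns (curve, model, state, crimper_records, wall_time).
    """
    spec = RingSpec.peaks8(30.0)
    mesh = make_ring(spec)
    model = StructuralModel(stent=mesh, beam_material=tv.VALIANT_CAPTIVIA_TABLE2,
                            cfg=SolverConfig(lin_damp=0.005))
    state = model.initial_state()
    t0 = time.time()
    curve = run_crimp_release(
        model, state,
        CrimpProtocol(start_diameter=30.0, min_diameter=5.0, release_to=31.0,
                      mu=0.0, sample_spacing=4.0, move_rate=0.004,
                      settle_max_steps=9000),
    )
    wall = time.time() - t0
    return {"curve": curve, "model": model, "state": state,
            "mesh": mesh, "wall_time": wall}


@pytest.fixture(scope="session")
def cantilever_20():
    """Linear 20-element cantilever solved to equilibrium (shared)."""
    from test_fe_core import solve_cantilever
    n, P, L, R = 20, 0.01, 10.0, 0.25
    st, model = solve_cantilever(n, P, L, R)
    return {"state": st, "P": P, "L": L, "R": R}


@pytest.fixture(scope="session")
def calibration_recovery():
    """Nitinol parameter recovery from a noisy synthetic ring curve.

    Moduli and plateau stresses co-fitted; the transformation strain is
    held at its literature value (weakly identified by a ring crimp).
    """
    spec = RingSpec.peaks8(30.0)
    synth = SynthConfig(seed=1, noise_sd_rel=0.01, n_samples=32)
    noisy = gen_synthetic_curve(tv.VALIANT_CAPTIVIA_TABLE2, spec, synth)
    cfg = CalibrationConfig(free_parameters=(
        "E_A", "E_M", "sig_SL", "sig_EL", "sig_SU", "sig_EU"))
    res = calibrate_nitinol([(spec, noisy)], cfg, n_samples=32)
    return res


@pytest.fixture(scope="session")
def verification_matrix():
    """The eight verification deployments on the desk-scale device."""
    warnings.simplefilter("ignore")
    spec = tv.desk_device_spec(element_size=3.0)
    proto = DeploymentProtocol(
        method="tracking", centerline=tv.desk_centerline(),
        catheter_radius=0.25 * spec.graft_diameter,
        vessel_radius=0.44 * spec.graft_diameter,
        crimp_steps=3000, track_steps=3000,
        release_steps=6000, settle_steps=5000)
    rows = run_verification_matrix(
        spec, proto,
        prestress_kwargs=dict(move_steps=2500, settle_max_steps=30000))
    return {"rows": rows, "spec": spec, "proto": proto}
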