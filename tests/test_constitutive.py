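"""Superelastic Nitinol law and graft fabric law."""

import numpy as np
import pytest

from tevarsim.constitutive import (DEFAULT_FABRIC, FabricParams,
                                   NitinolParams, SMAState,
                                   VALIANT_CAPTIVIA_TABLE2, fabric_update,
                                   linear_elastic_update, sma_update)


def sweep(eps_path, p=VALIANT_CAPTIVIA_TABLE2, state=None):
    """Drive a single material point along a strain path."""
    st = state or SMAState.zeros(())
    sig = np.empty(len(eps_path))
    xi = np.empty(len(eps_path))
    for i, e in enumerate(eps_path):
        s, st = sma_update(e, st, p)
        sig[i] = s
        xi[i] = st.xi
    return sig, xi, st


class TestSuperelasticLaw:
    p = VALIANT_CAPTIVIA_TABLE2

    def test_virgin_state_zero(self):
        sig, st = sma_update(0.0, SMAState.zeros(()), self.p)
        assert sig == 0.0 and st.xi == 0.0

    def test_forward_plateau_onset(self):
        """Transformation starts at sig_SL = 550 MPa, eps = sig_SL/E_A."""
        path = np.arange(0.0, 0.012, 1e-5)
        sig, xi, _ = sweep(path)
        k = np.argmax(xi > 0)
        assert sig[k] == pytest.approx(550.0, abs=1.0)
        assert path[k] == pytest.approx(550.0 / 57500.0, rel=1e-2)

    def test_forward_plateau_end_and_transformation_strain(self):
        path = np.arange(0.0, 0.12, 1e-5)
        sig, xi, _ = sweep(path)
        k0 = np.argmax(xi > 0)
        k1 = np.argmax(xi >= 1.0)
        assert sig[k1] == pytest.approx(620.0, abs=1.0)
        # plateau strain span minus the elastic strain accrued across it
        elastic = 620.0 / 47800.0 - 550.0 / 57500.0
        assert (path[k1] - path[k0]) - elastic == pytest.approx(
            0.063, abs=1e-4)

    def test_reverse_plateau_stresses(self):
        up = np.arange(0.0, 0.086, 1e-5)
        down = up[::-1][1:]
        sig_u, xi_u, st = sweep(up)
        assert xi_u[-1] == 1.0
        sig_d, xi_d, _ = sweep(down, state=st)
        started = np.argmax(xi_d < 1.0)
        finished = len(xi_d) - 1 - np.argmax(xi_d[::-1] > 0.0)
        assert sig_d[started] == pytest.approx(450.0, abs=1.0)
        assert sig_d[finished] == pytest.approx(250.0, abs=1.0)

    def test_full_recovery_on_unloading(self):
        path = np.concatenate([np.linspace(0, 0.09, 500),
                               np.linspace(0.09, 0, 500)])
        sig, xi, st = sweep(path)
        assert sig[-1] == pytest.approx(0.0, abs=1e-9)
        assert st.xi == pytest.approx(0.0, abs=1e-12)

    def test_hysteresis_loop_area_positive_and_closed(self):
        path = np.concatenate([np.linspace(0, 0.08, 400),
                               np.linspace(0.08, 0, 400)])
        sig, _, _ = sweep(path)
        area = np.trapezoid(sig, path)   # signed loop integral
        assert area > 1.0                # dissipated energy density, MPa
        assert sig[-1] == pytest.approx(0.0, abs=1e-9)

    def test_inner_loop_unloads_with_mixture_modulus(self):
        """Partial unloading inside the plateau is elastic at E(xi)."""
        p = self.p
        up = np.linspace(0, 0.04, 400)
        sig, xi, st = sweep(up)
        xi0 = st.xi
        assert 0.0 < xi0 < 1.0
        d = 1e-4
        sig2, st2 = sma_update(0.04 - d, st, p)
        E_mix = 1.0 / ((1 - xi0) / p.E_A + xi0 / p.E_M)
        assert (sig[-1] - sig2) / d == pytest.approx(E_mix, rel=1e-6)

    def test_rate_independence(self):
        """Halving the increment size leaves the stress path unchanged."""
        coarse = np.linspace(0, 0.08, 200)
        fine = np.linspace(0, 0.08, 400)
        s1, _, _ = sweep(coarse)
        s2, _, _ = sweep(fine)
        assert abs(s1[-1] - s2[-1]) < 1e-9

    def test_monotonic_loading_is_monotone_in_stress(self):
        rng = np.random.default_rng(0)
        path = np.cumsum(rng.uniform(0, 5e-4, 300))
        sig, _, _ = sweep(path)
        assert np.all(np.diff(sig) >= -1e-12)

    def test_compression_onset_scaled_by_alpha(self):
        path = -np.arange(0.0, 0.015, 1e-5)
        sig, xi, _ = sweep(path)
        k = np.argmax(xi > 0)
        assert sig[k] == pytest.approx(-550.0 * (1 + 0.0279), abs=1.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            NitinolParams(sig_SL=700.0, sig_EL=620.0)
        with pytest.raises(ValueError):
            NitinolParams(eps_L=0.5)
        with pytest.raises(ValueError):
            sma_update(np.nan, SMAState.zeros(()), self.p)


class TestFabricLaw:
    def test_uniaxial_tension(self):
        """Uniaxial plane stress at 1% strain gives 10.8 MPa."""
        p = DEFAULT_FABRIC
        e = 0.01
        strain = np.array([[e, 0.0], [0.0, -p.nu * e]])
        sig = fabric_update(strain, p)
        assert sig[0, 0] == pytest.approx(1080.0 * e, rel=1e-12)
        assert sig[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_equibiaxial_compression_carries_nothing(self):
        strain = -0.05 * np.eye(2)
        assert np.all(fabric_update(strain, DEFAULT_FABRIC) == 0.0)

    def test_factor_one_recovers_plane_stress(self):
        p = FabricParams(compressive_stiffness_factor=1.0)
        strain = np.array([[-0.02, 0.007], [0.007, 0.01]])
        sig = fabric_update(strain, p)
        k = p.E_long / (1 - p.nu ** 2)
        exx, eyy, exy = strain[0, 0], strain[1, 1], strain[0, 1]
        ref = np.array([[k * (exx + p.nu * eyy), k * (1 - p.nu) * exy],
                        [k * (1 - p.nu) * exy, k * (eyy + p.nu * exx)]])
        assert np.allclose(sig, ref, rtol=1e-10)

    def test_principal_stresses_never_negative_at_factor_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(scale=0.05, size=(2, 2))
            strain = 0.5 * (a + a.T)
            sig = fabric_update(strain, DEFAULT_FABRIC)
            ev = np.linalg.eigvalsh(sig)
            assert np.all(ev >= -1e-10)


@pytest.mark.parametrize("eps,E,expected", [
    (0.01, 57500.0, 575.0),
    (0.0, 57500.0, 0.0),
    (0.1, 1.84, 0.184),
])
def test_linear_elastic_update(eps, E, expected):
    assert linear_elastic_update(eps, E) == pytest.approx(expected, rel=1e-12)
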