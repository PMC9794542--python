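"""Synthetic generators, file I/O and the command-line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import tevarsim as tv
from tevarsim.calibration import ForceDiameterCurve
from tevarsim.geometry import RingSpec, make_ring
from tevarsim.toolkit import (SynthConfig, cli, desk_centerline,
                              desk_device_spec, gen_pseudo_segmentation,
                              gen_synthetic_curve, nitinol_preset,
                              read_centerline_csv, write_centerline_csv,
                              write_vtk_mesh)
from tevarsim.vv_metrics import oa_percent_error


class TestSyntheticCurve:
    spec = RingSpec.peaks8(30.0)

    def test_zero_noise_is_the_model_curve(self):
        from tevarsim.calibration import simulate_ring_curve
        clean = simulate_ring_curve(tv.VALIANT_CAPTIVIA_TABLE2, self.spec,
                                    n_samples=10)
        synth = gen_synthetic_curve(tv.VALIANT_CAPTIVIA_TABLE2, self.spec,
                                    SynthConfig(seed=3, noise_sd_rel=0.0,
                                                n_samples=10))
        assert np.allclose(clean.force, synth.force, rtol=1e-12)

    def test_same_seed_reproducible(self):
        cfg = SynthConfig(seed=7, noise_sd_rel=0.02, n_samples=10)
        a = gen_synthetic_curve(tv.VALIANT_CAPTIVIA_TABLE2, self.spec, cfg)
        b = gen_synthetic_curve(tv.VALIANT_CAPTIVIA_TABLE2, self.spec, cfg)
        assert np.array_equal(a.force, b.force)

    def test_noise_magnitude_half_normal(self):
        """Mean |relative deviation| of N(0, 0.01) noise is about 0.8%."""
        cfg = SynthConfig(seed=1, noise_sd_rel=0.01, n_samples=400)
        noisy = gen_synthetic_curve(tv.VALIANT_CAPTIVIA_TABLE2, self.spec, cfg)
        from tevarsim.calibration import simulate_ring_curve
        clean = simulate_ring_curve(tv.VALIANT_CAPTIVIA_TABLE2, self.spec,
                                    n_samples=400)
        ok = clean.force > 0.5
        rel = np.abs(noisy.force[ok] / clean.force[ok] - 1.0)
        assert rel.mean() == pytest.approx(0.01 * np.sqrt(2 / np.pi),
                                           rel=0.15)


class TestPseudoSegmentation:
    def _deployed_stand_in(self):
        spec = RingSpec.peaks8(30.0)
        mesh = make_ring(spec)
        return mesh, mesh.node_coords, {0: spec}

    def test_zero_perturbation_zero_oa_error(self):
        mesh, x, specs = self._deployed_stand_in()
        apexes, struts = gen_pseudo_segmentation(
            mesh, x, specs, SynthConfig(seed=1, perturbation_sd=0.0))
        from tevarsim.vv_metrics import extract_apexes
        sim = [extract_apexes(mesh, x, 0, specs[0])]
        res = oa_percent_error(sim, apexes)
        assert res.percent_errors[0] == pytest.approx(0.0, abs=1e-9)

    def test_small_perturbation_small_oa_error(self):
        """0.2 mm noise on a 30 mm ring: OA is first-order insensitive."""
        mesh, x, specs = self._deployed_stand_in()
        from tevarsim.vv_metrics import extract_apexes
        sim = [extract_apexes(mesh, x, 0, specs[0])]
        errs = []
        for seed in range(40):
            apexes, _ = gen_pseudo_segmentation(
                mesh, x, specs, SynthConfig(seed=seed, perturbation_sd=0.2))
            errs.append(oa_percent_error(sim, apexes).percent_errors[0])
        assert np.mean(np.array(errs) < 3.0) > 0.9

    def test_fixed_seed_reproducible(self):
        mesh, x, specs = self._deployed_stand_in()
        cfg = SynthConfig(seed=5, perturbation_sd=0.1)
        a1, s1 = gen_pseudo_segmentation(mesh, x, specs, cfg)
        a2, s2 = gen_pseudo_segmentation(mesh, x, specs, cfg)
        assert np.array_equal(a1[0].points, a2[0].points)
        assert np.array_equal(s1[0], s2[0])


class TestIO:
    def test_centerline_csv_roundtrip(self, tmp_path):
        line = desk_centerline()
        path = tmp_path / "line.csv"
        write_centerline_csv(path, line)
        back = read_centerline_csv(path)
        assert np.allclose(line, back, rtol=1e-12, atol=0)

    def test_vtk_writer_smoke(self, tmp_path):
        mesh = make_ring(RingSpec.peaks8(30.0))
        path = tmp_path / "ring.vtk"
        write_vtk_mesh(path, mesh.node_coords, lines=mesh.elements,
                       point_data={"ring": np.zeros(mesh.n_nodes)})
        text = path.read_text()
        assert "POINTS 240 double" in text
        assert "CELL_TYPES 240" in text

    def test_nitinol_presets(self):
        p = nitinol_preset("valiant_captivia_table2")
        assert p.E_A == 57500.0
        with pytest.raises(KeyError):
            nitinol_preset("nope")


class TestCLI:
    def test_synth_command(self, tmp_path):
        out = tmp_path / "curve.csv"
        result = CliRunner().invoke(cli, ["synth", "--seed", "2",
                                          "--out", str(out)])
        assert result.exit_code == 0, result.output
        curve = ForceDiameterCurve.from_csv(out)
        assert set(curve.phase) == {"loading", "unloading"}

    def test_generate_command(self, tmp_path):
        out = tmp_path / "dev.vtk"
        result = CliRunner().invoke(
            cli, ["generate", "--device", "desk", "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert out.exists()

    def test_metrics_command_zero_error(self, tmp_path):
        import pandas as pd
        th = np.arange(8) * 2 * np.pi / 8
        pts = pd.DataFrame({
            "ring_id": np.zeros(8, int),
            "x": 10 * np.cos(th), "y": 10 * np.sin(th), "z": np.zeros(8)})
        sim = tmp_path / "sim.csv"
        ref = tmp_path / "ref.csv"
        pts.to_csv(sim, index=False)
        pts.to_csv(ref, index=False)
        out = tmp_path / "report.json"
        result = CliRunner().invoke(cli, ["metrics", "--sim", str(sim),
                                          "--ref", str(ref),
                                          "--out", str(out)])
        assert result.exit_code == 0, result.output
        report = json.loads(out.read_text())
        assert report["summary"]["mean"] == pytest.approx(0.0, abs=1e-9)

    def test_bad_device_errors(self, tmp_path):
        result = CliRunner().invoke(
            cli, ["generate", "--device", "not_a_device",
                  "--out", str(tmp_path / "x.vtk")])
        assert result.exit_code != 0
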