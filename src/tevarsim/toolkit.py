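"""Synthetic data generation, file I/O and the command-line interface.

No experimental bench data or CT segmentations are distributed with the
package; the generators here produce the stand-ins used by the tests
and the reproduction scripts: noisy radial-force curves emulating the
crimp bench, and perturbed apex/strut point clouds emulating a
segmented CT scan of the deployed stent.  Both are seeded and fully
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import click
import numpy as np
import pandas as pd

from .calibration import (CalibrationConfig, ForceDiameterCurve,
                          calibrate_nitinol, curve_percent_error,
                          simulate_ring_curve)
from .constitutive import (DEFAULT_FABRIC, KLEINSTREUER_2008, NitinolParams,
                           VALIANT_CAPTIVIA_TABLE2, FabricParams)
from .fe_core import SolverConfig
from .geometry import (BeamMesh, DeviceSpec, MembraneMesh, RingSpec,
                       crown_height_for_wire_length, device_preset,
                       make_device, make_ring)
from .vv_metrics import RingApexSet, extract_apexes

__all__ = [
    "SynthConfig",
    "gen_synthetic_curve",
    "gen_pseudo_segmentation",
    "desk_device_spec",
    "desk_centerline",
    "nitinol_preset",
    "write_vtk_mesh",
    "write_stl",
    "read_centerline_csv",
    "write_centerline_csv",
    "cli",
]


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthConfig:
    """Reproducible noise settings for synthetic reference data."""

    seed: int = 1
    noise_sd_rel: float = 0.01      # multiplicative force noise
    perturbation_sd: float = 0.1    # mm, geometric noise
    n_samples: int = 32

    def __post_init__(self) -> None:
        if self.noise_sd_rel < 0 or self.perturbation_sd < 0:
            raise ValueError("noise levels must be non-negative")


def gen_synthetic_curve(params: NitinolParams, spec: RingSpec,
                        synth: SynthConfig,
                        min_diameter: float = 5.0) -> ForceDiameterCurve:
    """Synthetic crimp-bench curve: ring model + multiplicative noise.

    Runs the reduced ring model at ``params`` and multiplies each force
    sample by (1 + noise_sd_rel * N(0,1)) with the given seed; phase
    labels are preserved.
    """
    curve = simulate_ring_curve(params, spec, min_diameter=min_diameter,
                                n_samples=synth.n_samples)
    rng = np.random.default_rng(synth.seed)
    noise = 1.0 + synth.noise_sd_rel * rng.standard_normal(len(curve.force))
    return ForceDiameterCurve(curve.diameter, curve.force * noise,
                              curve.phase,
                              metadata={**curve.metadata,
                                        "noise_sd_rel": synth.noise_sd_rel,
                                        "seed": synth.seed})


def gen_pseudo_segmentation(stent: BeamMesh, positions: np.ndarray,
                            ring_specs: Dict[int, RingSpec],
                            synth: SynthConfig
                            ) -> Tuple[List[RingApexSet], Dict[int, np.ndarray]]:
    """Pseudo CT segmentation of a deployed stent.

    Returns perturbed per-ring apex sets and perturbed strut polylines
    (the closed wire loop of every ring), each point displaced by
    isotropic Gaussian noise of sd ``perturbation_sd`` mm.
    """
    rng = np.random.default_rng(synth.seed)
    apexes: List[RingApexSet] = []
    struts: Dict[int, np.ndarray] = {}
    for ring_id, spec in ring_specs.items():
        a = extract_apexes(stent, positions, ring_id, spec)
        pts = a.points + synth.perturbation_sd * rng.standard_normal(
            a.points.shape)
        apexes.append(RingApexSet(ring_id, pts, source="reference"))
        loop_nodes = stent.ring_nodes(ring_id)
        loop = positions[loop_nodes]
        struts[ring_id] = loop + synth.perturbation_sd * \
            rng.standard_normal(loop.shape)
    return apexes, struts


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def nitinol_preset(name: str) -> NitinolParams:
    """Named Nitinol parameter sets."""
    presets = {
        "valiant_captivia_table2": VALIANT_CAPTIVIA_TABLE2,
        "kleinstreuer_2008": KLEINSTREUER_2008,
    }
    try:
        return presets[name.lower()]
    except KeyError:
        raise KeyError(f"unknown Nitinol preset {name!r}; "
                       f"available: {sorted(presets)}")


def desk_device_spec(diameter: float = 20.0, graft_length: float = 40.0,
                     element_size: float = 2.5) -> DeviceSpec:
    """Small Free-Flo device for desk-scale deployment studies.

    A bare proximal 8-peaks ring (tip-captured) and three covered
    8-peaks body rings on a short graft; the same architecture as the
    full device at roughly half scale so a deployment run stays
    tractable on one CPU.  The wire is thinned to 0.35 mm so peak crimp
    strains on the small-diameter rings stay in the range the full-size
    device experiences, and the thin sealing ring is omitted (resolving
    its hoop-compression wave buckling needs a finer mesh than desk
    scale affords).
    """
    h = crown_height_for_wire_length(diameter, 8, 16 * 8.0)
    ring8 = RingSpec("peaks8", diameter, h, 0.35, 8, element_size)
    L = graft_length
    rings = (
        (ring8, L + h / 2 + 1.0),            # bare free-flo ring
        (ring8, L - 2.0 - h / 2),
        (ring8, L / 2.0 - 1.0),
        (ring8, h / 2 + 2.0),
    )
    return DeviceSpec(rings, diameter, L, configuration="FreeFlo")


def desk_centerline(straight: float = 70.0, bend_radius: float = 60.0,
                    bend_angle_deg: float = 35.0, n: int = 40) -> np.ndarray:
    """Vessel centerline: straight entry along +z with a planar bend.

    Starts at the origin so a device meshed around the z axis sits
    coaxially on the first section.
    """
    t = np.linspace(0.0, 1.0, n)
    z = straight * t
    line1 = np.column_stack([np.zeros(n), np.zeros(n), z])
    ang = np.deg2rad(bend_angle_deg) * np.linspace(0.0, 1.0, n)[1:]
    cx = bend_radius
    arc = np.column_stack([cx - bend_radius * np.cos(ang),
                           np.zeros(len(ang)),
                           straight + bend_radius * np.sin(ang)])
    return np.vstack([line1, arc])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_vtk_mesh(path, points: np.ndarray,
                   lines: Optional[np.ndarray] = None,
                   triangles: Optional[np.ndarray] = None,
                   point_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Minimal legacy-VTK ASCII writer (polylines and/or triangles)."""
    points = np.asarray(points, float)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ntevarsim mesh\nASCII\n"
                "DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(points)} double\n")
        for p in points:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        cells = []
        types = []
        if lines is not None:
            for a, b in np.asarray(lines, int):
                cells.append((2, a, b))
                types.append(3)      # VTK_LINE
        if triangles is not None:
            for a, b, c in np.asarray(triangles, int):
                cells.append((3, a, b, c))
                types.append(5)      # VTK_TRIANGLE
        total = sum(c[0] + 1 for c in cells)
        f.write(f"CELLS {len(cells)} {total}\n")
        for c in cells:
            f.write(" ".join(str(v) for v in c) + "\n")
        f.write(f"CELL_TYPES {len(cells)}\n")
        for tp in types:
            f.write(f"{tp}\n")
        if point_data:
            f.write(f"POINT_DATA {len(points)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, float)
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    f.write(f"{v:.9g}\n")


def write_stl(path, points: np.ndarray, triangles: np.ndarray) -> None:
    """Export a triangle surface as (binary) STL via trimesh."""
    import trimesh
    trimesh.Trimesh(vertices=points, faces=triangles,
                    process=False).export(path)


def read_stl(path) -> Tuple[np.ndarray, np.ndarray]:
    """Read a triangle surface (vessel wall) from STL."""
    import trimesh
    m = trimesh.load_mesh(path)
    return np.asarray(m.vertices, float), np.asarray(m.faces, int)


def write_centerline_csv(path, points: np.ndarray) -> None:
    pd.DataFrame(np.asarray(points, float),
                 columns=["x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)


def read_centerline_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy(float)


def _ring_spec_from_json(d: Dict) -> RingSpec:
    return RingSpec(d["kind"], d["nominal_diameter"],
                    d.get("crown_height", 0.0),
                    d.get("wire_diameter", 0.5), d.get("n_peaks", 8),
                    d.get("target_element_size", 1.0))


def device_spec_from_json(d) -> DeviceSpec:
    """DeviceSpec from a JSON dict or a preset name string."""
    if isinstance(d, str):
        return device_preset(d)
    rings = tuple((_ring_spec_from_json(r), float(z)) for r, z in d["rings"])
    return DeviceSpec(rings, d["graft_diameter"], d["graft_length"],
                      d.get("graft_thickness", 0.1),
                      d.get("configuration", "ClosedWeb"),
                      d.get("prestress_ratio", 0.17))


# ---------------------------------------------------------------------------
# command-line interface
# ---------------------------------------------------------------------------

@click.group()
def cli() -> None:
    """tevarsim: desk-scale stent-graft crimp and deployment simulation."""


@cli.command()
@click.option("--device", default="device_a", help="preset name or JSON file")
@click.option("--out", type=click.Path(), required=True,
              help="output VTK file for the assembled device")
def generate(device: str, out: str) -> None:
    """Mesh a device and export it as legacy VTK."""
    spec = _load_device(device)
    stent, graft = make_device(spec)
    n0 = len(stent.node_coords)
    pts = np.vstack([stent.node_coords, graft.node_coords])
    write_vtk_mesh(out, pts, lines=stent.elements,
                   triangles=graft.triangles + n0)
    click.echo(f"device: {len(stent.elements)} beam elements, "
               f"{len(graft.triangles)} membrane elements, "
               f"{len(graft.suture_map)} sutures -> {out}")


@cli.command()
@click.option("--ring", default="peaks8", type=click.Choice(["peaks8", "peaks5"]))
@click.option("--diameter", default=30.0)
@click.option("--min-diameter", default=5.0)
@click.option("--out", type=click.Path(), required=True)
@click.option("--full-fe/--reduced", default=False,
              help="full explicit FE crimp vs the reduced ring model")
def crimp(ring: str, diameter: float, min_diameter: float, out: str,
          full_fe: bool) -> None:
    """Crimp/release a single ring and write the radial-force curve CSV."""
    spec = RingSpec.peaks8(diameter) if ring == "peaks8" \
        else RingSpec.peaks5(diameter)
    if full_fe:
        from .fe_core import SolverConfig, StructuralModel
        from .protocols import CrimpProtocol, run_crimp_release
        mesh = make_ring(spec)
        model = StructuralModel(stent=mesh,
                                beam_material=VALIANT_CAPTIVIA_TABLE2,
                                cfg=SolverConfig(lin_damp=0.01))
        curve = run_crimp_release(model, model.initial_state(),
                                  CrimpProtocol(start_diameter=diameter,
                                                min_diameter=min_diameter))
    else:
        curve = simulate_ring_curve(VALIANT_CAPTIVIA_TABLE2, spec,
                                    min_diameter=min_diameter)
    curve.to_csv(out)
    click.echo(f"{len(curve.force)} samples -> {out}")


@cli.command()
@click.option("--device", default="device_a")
@click.option("--out", type=click.Path(), required=True)
def prestress(device: str, out: str) -> None:
    """Pre-stress a device and export the equilibrated state as VTK."""
    from .protocols import apply_prestress, build_device_model
    spec = _load_device(device)
    model, stent, graft = build_device_model(
        spec, cfg=SolverConfig(lin_damp=0.01))
    state = apply_prestress(model, spec)
    write_vtk_mesh(out, state.x, lines=model.conn if model.n_beams else None,
                   triangles=model.tri if model.n_tris else None)
    click.echo(f"pre-stressed device -> {out} "
               f"(added mass fraction {model.added_mass_fraction:.1f})")


@cli.command()
@click.option("--device", default="desk")
@click.option("--method", default="tracking",
              type=click.Choice(["tracking", "virtual_catheter",
                                 "virtual_catheter_modified"]))
@click.option("--out-prefix", type=click.Path(), required=True)
def deploy(device: str, method: str, out_prefix: str) -> None:
    """Deploy a device into the desk-scale curved vessel."""
    from .protocols import (DeploymentProtocol, apply_prestress,
                            build_device_model, run_deployment)
    spec = desk_device_spec() if device == "desk" else _load_device(device)
    model, stent, _ = build_device_model(spec, cfg=SolverConfig(lin_damp=0.01))
    state = apply_prestress(model, spec)
    proto = DeploymentProtocol(
        method=method, centerline=desk_centerline(),
        catheter_radius=0.25 * spec.graft_diameter,
        vessel_radius=0.44 * spec.graft_diameter)
    res = run_deployment(model, state, spec, proto,
                         progress=lambda s: click.echo(f"  stage: {s}"))
    click.echo(f"outcome: {res.outcome}" +
               (f" ({res.error})" if res.error else ""))
    for name, st in res.stages.items():
        write_vtk_mesh(f"{out_prefix}_{name}.vtk", st.x,
                       lines=model.conn if model.n_beams else None,
                       triangles=model.tri if model.n_tris else None)


@cli.command()
@click.option("--ref", type=click.Path(exists=True), required=True,
              help="reference curve CSV (diameter_mm, force_N, phase)")
@click.option("--ring", default="peaks8", type=click.Choice(["peaks8", "peaks5"]))
@click.option("--diameter", default=30.0)
@click.option("--out", type=click.Path(), required=True)
def calibrate(ref: str, ring: str, diameter: float, out: str) -> None:
    """Fit Nitinol parameters to a reference curve; write a JSON report."""
    spec = RingSpec.peaks8(diameter) if ring == "peaks8" \
        else RingSpec.peaks5(diameter)
    curve = ForceDiameterCurve.from_csv(ref)
    res = calibrate_nitinol([(spec, curve)])
    Path(out).write_text(json.dumps(res.to_dict(), indent=2))
    click.echo(f"E_A = {res.params.E_A:.0f} MPa, "
               f"E_M = {res.params.E_M:.0f} MPa -> {out}")


@cli.command()
@click.option("--sim", type=click.Path(exists=True), required=True,
              help="simulated apex CSV (ring_id, x, y, z)")
@click.option("--ref", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
def metrics(sim: str, ref: str, out: str) -> None:
    """Opening-area error report between two apex point files."""
    from .vv_metrics import oa_percent_error
    sims = _read_apex_csv(sim, "simulation")
    refs = _read_apex_csv(ref, "reference")
    res = oa_percent_error(sims, refs)
    report = {"per_ring": {str(r): {"oa": float(a), "oa_ref": float(b),
                                    "error_pct": float(e)}
                           for r, a, b, e in zip(res.ring_ids, res.areas,
                                                 res.reference_areas,
                                                 res.percent_errors)},
              "summary": res.summary}
    Path(out).write_text(json.dumps(report, indent=2))
    click.echo(f"OA error {res.summary['mean']:.2f}% +- "
               f"{res.summary['sd']:.2f}% -> {out}")


@cli.command("verify-matrix")
@click.option("--out", type=click.Path(), required=True)
@click.option("--release-steps", default=8000)
def verify_matrix(out: str, release_steps: int) -> None:
    """Run the 8-simulation verification matrix on the desk device."""
    from .protocols import (DeploymentProtocol, run_verification_matrix)
    spec = desk_device_spec()
    proto = DeploymentProtocol(
        method="tracking", centerline=desk_centerline(),
        catheter_radius=0.25 * spec.graft_diameter,
        vessel_radius=0.44 * spec.graft_diameter,
        release_steps=release_steps)
    rows = run_verification_matrix(
        spec, proto, cfg=SolverConfig(lin_damp=0.01),
        progress=lambda s: click.echo(f"  {s}"))
    pd.DataFrame([{"id": r["id"], "label": r["label"],
                   "outcome": r["outcome"]} for r in rows]).to_csv(
        out, index=False)
    click.echo(f"matrix outcomes -> {out}")


@cli.command()
@click.option("--seed", default=1)
@click.option("--noise", default=0.01)
@click.option("--out", type=click.Path(), required=True)
def synth(seed: int, noise: float, out: str) -> None:
    """Generate a synthetic noisy crimp-bench curve CSV."""
    curve = gen_synthetic_curve(VALIANT_CAPTIVIA_TABLE2,
                                RingSpec.peaks8(30.0),
                                SynthConfig(seed=seed, noise_sd_rel=noise))
    curve.to_csv(out)
    click.echo(f"synthetic curve ({len(curve.force)} samples) -> {out}")


def _load_device(device: str) -> DeviceSpec:
    if device.endswith(".json"):
        return device_spec_from_json(json.loads(Path(device).read_text()))
    if device == "desk":
        return desk_device_spec()
    return device_preset(device)


def _read_apex_csv(path, source) -> List[RingApexSet]:
    df = pd.read_csv(path)
    out = []
    for rid, grp in df.groupby("ring_id"):
        out.append(RingApexSet(int(rid),
                               grp[["x", "y", "z"]].to_numpy(float),
                               source=source))
    return out


if __name__ == "__main__":
    cli()
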