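# Methods

## Superelastic Nitinol law

The stent wire is modelled with a uniaxial superelastic law of the
Auricchio–Taylor family, driven in strain.  The state is the martensite
fraction ξ ∈ [0, 1] plus the sign of the transformation.  Loading from
the virgin state is elastic at E_A up to σ_SL; the forward plateau runs
linearly from σ_SL to σ_EL while ξ grows and the transformation strain
ξ·ε_L accumulates; beyond full transformation the response is elastic at
E_M.  Unloading is elastic until σ_SU, then the reverse plateau from
σ_SU to σ_EU recovers the transformation strain, closing the hysteresis
loop exactly at the origin (full superelastic recovery).  Between
plateaus the modulus is the Reuss (series) phase mixture
1/E(ξ) = (1−ξ)/E_A + ξ/E_M; the Reuss/Voigt choice is not determined by
the plateau data, Reuss is the common choice.  On each plateau the pair
(σ, ξ) is obtained in closed form from the strain (a quadratic, because
of the mixture rule).  Tension–compression asymmetry enters only as a
scaling of the compressive transformation onsets by (1 + α); this is
sufficient for wire fibres in bending.  The law is rate-independent by
construction: within a monotonic segment the update depends only on the
total strain, not the increment subdivision.  Temperature does not
appear; the parameter set is an isothermal calibration at body
temperature.

Default parameters (preset `valiant_captivia_table2`): E_A = 57 500,
E_M = 47 800 MPa, ν = 0.3, σ_SL = 550, σ_EL = 620, σ_SU = 450,
σ_EU = 250 MPa, ε_L = 0.063, α = 0.0279.  The calibration starting
point (`kleinstreuer_2008`) carries the widely used literature values
for stent-graft Nitinol.

## Graft fabric law

The graft is woven PET, 0.1 mm thick, modelled as an isotropic
plane-stress membrane (E = 1080 MPa, ν = 0.35) evaluated in the
principal strain frame, with compressive principal stresses multiplied
by a `compressive_stiffness_factor` (default 0: a true fabric offers no
resistance to compression and wrinkles freely; 1 recovers classical
plane-stress elasticity, the form used by the literature-comparison
variants at E = 1.84 MPa and 1.84 GPa).

## Geometry

Peaks rings are sinusoids z(θ) = (h/2)·cos(nθ) on a cylinder; the thin
proximal sealing ring is a plane circle of 0.2 mm wire.  Crown heights
h were not published for the commercial device; they are fixed by
requiring that the 30 mm 8-peaks and 5-peaks rings mesh to the
published convergent element counts (240 and 160) at 1 mm element size,
which pins the single free geometric parameter (h = 13.35 mm and
12.23 mm).  Ring axial positions in the device presets are uniform-pitch
choices; they were also not published.

Devices are assembled with the peaks rings meshed at their stress-free
diameter (sutured × 1.17) and the graft as a structured cylinder whose
grid contains every suture location, so suture pairs coincide exactly
in the sutured configuration.  Sutures are merged nodes (shared degrees
of freedom) at the ring apexes, and at every node of the thin ring.
The thin sealing ring is meshed flush at the sutured diameter: a plane
circular wire cannot carry the 17 % hoop pre-compression that the
zig-zag springs store, and is sewn tight in the real device.  The thin
ring also carries a deterministic axial ripple of 0.4 wire diameters:
under crimp a perfect circle would crush axisymmetrically, while the
rippled ring buckles into the physical wave pattern.

The membrane reference configuration is the pristine graft cylinder,
not the assembled position of the suture nodes: the fabric is
unstrained when the graft is a cylinder at the sutured diameter.

## Explicit kernel and dynamic relaxation

Beams are corotational two-node Euler–Bernoulli fibre elements.  The
element frame follows the mean nodal triad aligned to the chord; local
end rotations feed a cubic bending field sampled at two Gauss points
along the length, and the circular cross-section is integrated at the
2×2 Gauss fibre positions (±R/2, ±R/2) with weights A/4, which
reproduce both the area and the bending inertia exactly.  Torsion is
elastic at G = E_A/(2(1+ν)).  Membranes are total-Lagrangian
constant-strain triangles (Green strain), exactly objective.

Time integration is central difference with lumped masses.  Mass
scaling inflates nodal masses/inertias to m ≥ 2·k·dt² (rotary: 16·k·dt²)
for the target timestep dt = 1e-6 s, and the added-mass fraction is
reported on the model.  Mass-proportional damping (1 s⁻¹ stent,
0.1–0.5 s⁻¹ graft) follows the simulated procedure; because the scaled
masses make those factors negligible per step, quasi-static equilibria
are driven by dynamic relaxation instead:

* *kinetic damping* — velocities are zeroed when the kinetic energy
  passes a peak, checked on a 50-step stride (checking every step
  mistakes high-frequency wiggle for peaks and freezes slow travel
  modes);
* *viscous settling* — a per-step multiplicative velocity drag
  (`lin_damp`, typically 0.5–1 %), the stable choice in the presence of
  stick-slip friction, whose anchor updates interact badly with
  velocity resets;
* a small per-step rotational drag (`rot_damp` = 0.2) suppresses the
  zero-stiffness spin mode of straight wires and a weak follower-moment
  flutter of the corotational formulation.

Convergence is declared on the out-of-balance force of the free nodes,
relative to the peak applied (contact/external) force or peak imbalance
of that relaxation, with an absolute floor; the equilibrium residuals
of the protocol stages are ≤ 1 % of the driving forces.

Energy bookkeeping accumulates translational and rotational internal
work, contact work, damping losses (including kinetic-damping resets
and the per-step drags) and friction dissipation, with a trapezoidal
(second-order) work integration; a frictionless crimp/release cycle
closes the balance to within 2 %.

A note on crimper symmetry: an 8-peaks ring between 12 planes shares
only the 90-degree rotation group, so per-plane forces are equal in
groups of four 90-degree-separated planes (to a few tenths of a percent
at moderate crimp), not across all twelve; at deep crimp the wire folds
into a three-dimensional pattern and the remaining symmetry breaks too.

## Contact

Node-to-surface penalty contact with per-node stiffness
0.1·m_node/dt² (stable by construction against the scaled masses).
Friction uses an elastic-predictor/slip-return tangential anchor with
the same stiffness.  The crimper is 12 rigid planes tangent to the
commanded cylinder at 30° increments, evaluated in one vectorised pass;
the radial force is the sum of the 12 plane normal forces.  Tubes
(catheter, sheath, vessel) are polyline centerlines with a radius, an
optional arc-length active window (a retracting sheath) and a cached
broad-phase candidate set.  Wire self-contact is sphere-swept
segment–segment penalty with a KD-tree candidate rebuild.  Friction
coefficients follow the modelled procedure: 0.3 stent–plane, 0.1
graft–plane, 0.1 device–catheter in crimp, frictionless tracking, 0.1
device–vessel in deployment.

## Protocols

*Crimp/release* is stop-and-go: the crimper moves at 0.002 mm/step
between sample diameters and the assembly is relaxed at every sample,
so each force is an equilibrium point; phase labels give the loading
and unloading branches.

*Pre-stress* prescribes the radial map of the peaks rings from the
stress-free to the sutured diameter (superelastic history accumulates),
the merged sutures carry the recoil into the graft, and the assembly is
relaxed in two rounds (the second round restarts the residual scale so
the gentle recoil of a bare Free-Flo ring converges as well as the loud
graft modes).

*Tracking deployment* crimps the device into the catheter with a
shrinking coaxial tube, transports the crimped configuration along
parallel-transport frames of the centerline (rotational DOFs stay free
so the wire follows the bend), then retracts the sheath window
proximal-to-distal while the bare-ring apexes stay pinned to the tip
(tip capture) and are released last, followed by a settle against the
vessel.

*Virtual catheter* (the literature comparator) has no tracking phase:
the whole assembly is kinematically transported to the landing zone,
the stent is morphed radially to the catheter radius inside a shrinking
coaxial tube, and the device is released either at once or gradually
(modified variant).

*Fatal deformation*: a deployment run is scored Negative when, for more
than 300 consecutive steps (or 2× instantly), a beam fibre strain
exceeds 40 %, a membrane tensile principal strain exceeds 40 %, a
membrane carrying more than 5 MPa of compressive stress is crushed past
40 %, or a compression-carrying membrane's area ratio collapses below
2 %.  The patience window separates genuine collapse from the strain
spikes every explicit transient produces; the 5 MPa stress floor
distinguishes structurally engaged membranes from slack or very
compliant ones, which fold harmlessly.  These thresholds operationalise
"crashed run" for a solver whose automatic mass scaling cannot crash
the way a fixed-timestep solver does.

## Reduced ring model and calibration

The calibration loop cannot afford a full explicit crimp per objective
evaluation.  The reduced model treats one half-peak of the sinusoidal
ring as an initially-curved planar beam strip: symmetry keeps both end
tangents circumferential, no net ring-axial force acts, and the bending
moment is statically determinate, M(s) = −F·z(s), with z the strip
height profile and F the circumferential end force.  Sections (8 Gauss
layers across the wire) are inverted for curvature with the full
history-dependent law; the deformed shape is reconstructed by
integrating the slope, and the commanded diameter fixes the end
shortening, solved for F by bracketed regula falsi.  Energy balance
maps the strip force to the crimper radial force: F_radial = 2π·F.
The strip shape is updated explicitly between load steps (a lagged
geometric nonlinearity, adequate at the 40-sample schedules used).
The reduced model omits the discrete plane contacts, friction and
torsion of the full FE crimp; against a frictionless full-FE crimp its
loading branch agrees to within about 3-15% across the crimp range
(with the one-wire-diameter offset between the commanded crimper
diameter and the wire centerline accounted for).  Self-consistent
parameter recovery (generate and fit with the same model) does not
depend on that gap.

Identification is bounded least squares in log-parameter space; the
plateau ordering (σ_EL > σ_SL, σ_SU > σ_EU) is enforced structurally by
fitting widths instead of end stresses.  Fits with five or more free
parameters are staged — loading-branch parameters first (initial slope
and forward plateau), then the reverse/martensite set, then a full
co-fit — which lands the final solve in the right basin; a cold
simultaneous fit from the literature start can stall in a compensated
local minimum under an unlucky noise draw.  The misfit uses the full
crimp range, while device working-range errors (the 25–27 mm band for
a 30 mm device) are used for reporting, resampled on a uniform 50-point
diameter grid per phase (the reporting grid is a documented choice).

A known identifiability limit: a single ring crimp to 5 mm barely
drives the wire fibres past full transformation, so the martensite
modulus enters the curve mostly through the phase-mixture slope and is
weakly identified — its noise-displaced optimum can move by 10–20 %
under a 1 % multiplicative noise realisation.  The recovery experiment
therefore co-fits the moduli with the four plateau stresses and holds
the transformation strain at its literature (datasheet) value, removing
the dominant compensation direction; even so, the recovered E_M scatter
across noise realisations remains of order ten percent.

## Validation metrics

Ring opening area: the proximal apexes of each ring (the meshed axial
extrema; apex node identity survives deployment) are projected on their
PCA best-fit plane, a chord-length-parametrised periodic cubic spline
is fitted, and the enclosed area is evaluated by Green's theorem on a
1000-point resampling.  OA percentage errors are absolute values,
summarised as mean ± sd [min; max].  Strut alignment is the one-sided
Hausdorff distance from simulation vertices to the reference polyline.
Deployed length is the arc-length extent of the stent node projections
on the vessel centerline.

## Synthetic data

`gen_synthetic_curve` emulates the crimp bench: the reduced ring model
plus multiplicative Gaussian force noise (default sd 1 %, the scatter
scale of a repeatable radial-force bench).  `gen_pseudo_segmentation`
emulates a CT segmentation of the deployed stent: apex sets and strut
polylines perturbed by isotropic Gaussian noise (default sd 0.1 mm, of
the order of a CT voxel).  Both are seeded and byte-reproducible.  What
they do not emulate: systematic bench compliance errors, segmentation
bias near metal artefacts, and graft invisibility in CT; conclusions
about real acquisitions are correspondingly limited.

## Desk-scale study conditions

The deployment studies run on a reduced Free-Flo device (20 mm rings,
40 mm graft, a bare tip-captured ring plus three covered rings,
2.5–3 mm elements) in a 17.6 mm curved rigid vessel with a 60 mm-radius
bend, rather than the 34 × 34 × 200 device in a full aorta.  The wire
is thinned to 0.35 mm so peak crimp strains stay in the range the
full-size device experiences, and the thin sealing ring is omitted
(resolving its crimp wave-buckling needs a finer mesh than desk scale
affords).  Single-ring work (crimping, calibration, mesh counts) uses
the full-size 30 mm rings throughout.

## Known limitations

Hughes–Liu beams are replaced by corotational Euler–Bernoulli fibre
beams with the same section rule; torsion stays elastic.  The graft has
no bending stiffness.  The reduced ring model is planar (no torsion,
no plane contacts).  Deployment accuracy at desk scale is qualitative:
coarse sutures leave ±2 % apex-diameter offsets after pre-stress, and
stage schedules are counted in solver steps, not a physical retraction
speed.  The vessel is rigid; guidewires, blood pressure and patient
anatomies are out of scope.
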