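# Methods

## Model overview

The physical picture: retinal arterioles (72–185 µm) carry pressurized
blood; their walls and the surrounding retina are soft elastic tissue.
Two loads act during abusive head trauma — the ophthalmic blood
pressure (raised from 63 to 79.6 mmHg by the hypertensive trauma
response; ophthalmic = 0.68 × brachial systolic) and the inertial body
force of shaking, F = ρ·r·sign(ω)·ω² per unit volume, where r is the
chest-to-eye distance and ω(t) the head's angular velocity. The
question is whether either load alone, or only their combination,
raises the wall stress past the increase that ruptured vessels in an ex
vivo porcine perfusion experiment.

The model is a thin en-face 2D section of the fundus with three
domains: blood (b), vessel wall (w) and retina/choroid (r). Flow and
deformation are coupled one way — the converged fluid stress is applied
as a traction on the wall — iterated loads stay in the small-strain
regime (µm displacements on a 100 µm structure), so geometric
nonlinearity is neglected and superposition holds.

## Geometry and meshing

The original study traced vessel outlines from a fundus photograph;
those tracings are not published, so the geometry here is a parametric
synthetic stand-in built from tapering straight segments: a trunk
(default 120 µm — inside the plausibility band, and chosen so that the
pump flow of 100 µl/min split over six fundus arteries gives the
observed 2.46 cm/s settling velocity through a circular lumen of that
diameter) bifurcating into two branches, one of which bifurcates again,
yielding outlets of 20, 16 and 18 µm; a constant-thickness wall shell
(15 µm) and a retina box of 600 × 420 µm. Child branches start on the
parent's end-cap plane with a configurable lateral split so the
junction is tiled rather than double-covered, and the single bend is
filleted by a short half-angle chord — vessels do not kink, and a sharp
lumen corner would put a stress singularity under POI3. All absolute
stress values are geometry-dependent; only structural properties
(linearity, orderings, conservation) are treated as transferable.

Probe points (POIs) are placed deterministically on the wall
mid-thickness line: POI1 and POI2 at the carina (flow-divider apex) of
the two bifurcations, POI3 on the outer side of the maximum-curvature
bend, POI4 on the parent wall across the widest junction.

Meshing snaps a structured triangular background grid onto the lumen
and outer-wall curves (snap tolerance 0.45 cells, with inversion
repair) and classifies triangles by centroid. This is deterministic,
exactly scale-equivariant, conforming, and conserves each domain's
polygon area to better than 1% at the default 4 µm resolution. Meshes
are emitted in SI metres; configuration is in µm.

## Fluid solver

Blood is generalized Newtonian with the power law μ = K·γ̇ᵉ,
K = 28.52 mPa·s at γ̇ = 1 s⁻¹ and e = −0.385. The source states no
units for K; mPa·s is adopted because it yields ~4.8 mPa·s at 100 s⁻¹,
physiologic for whole blood, whereas Pa·s would be off by 10³. The
shear rate γ̇ = √(2ε:ε) is clamped to [1, 10⁴] s⁻¹, the standard
regularization of the power-law singularity at γ̇ → 0.

At these scales (100 µm, cm/s) the Reynolds number is ≪ 1, so inertia
is dropped: steady Stokes flow with Picard iteration on the viscosity
field (relative L2 change < 10⁻⁶; with e = 0 the loop converges in one
iteration and reduces to plain Stokes). Discretization is Taylor–Hood
(P2 velocity / P1 pressure) on the blood submesh. Port pressures enter
as natural boundary tractions −p·n with the tangential velocity
component pinned to zero, which makes σ_nn = −p hold exactly and the
plane-Poiseuille solution representable to machine precision; port
velocities are parabolic Dirichlet profiles over the meshed port chord;
interface edges are no-slip. Global mass balance is monitored and stays
below 0.1% of throughflow. Wall traction (−pI + 2με)·n is evaluated on
the blood side at each interface-edge midpoint.

## Solid solver

Plane strain is used (the section is embedded in the globe, which
resists out-of-plane stretch): ε_zz = 0 and σ_zz = ν(σ_xx + σ_yy)
enters the von Mises stress. P2 elements on wall + retina with the
published material table (retina: ρ 1098 kg/m³, ν 0.49, E 90 kPa; wall:
ρ 1147, ν 0.17, E 192 kPa; blood density 1057 kg/m³). Loads are the
interface traction, plus (during shaking) the body force with each
domain's density — applied to fluid and solid alike. The outer box
boundary is clamped: the section is excised from continuous tissue.
Volumetric strain is the trace of the small-strain tensor.

Verification oracles: plane-Poiseuille velocity and wall shear
(machine-exact by construction), the Lamé thick-walled-cylinder hoop
stress (within 2% on a coarse annulus), a uniform-stress patch test
(exact), zero-load ⇒ zero-field, exact superposition, and invariance
under a 90° frame rotation.

## POI sampling

Stress at a probe point is reported as the mean of the pointwise P2
stress over a fixed 17-point disc (radius 0.4 wall thicknesses, center
plus two rings of 8, restricted to the probe's domain); displacement is
pointwise. The disc average is a through-thickness-representative
value: the point stress at mid-thickness of a 15 µm wall sits on a
steep gradient and converges slowly, while the disc value moves by less
than 2% when the mesh edge length is halved. The carina-tip
displacement (POI1) remains the least-converged quantity — the flow
divider is a thin compliant sliver — and no test asserts its refinement
behavior.

## Scenarios and the shaking sweep

Boundary values are taken as printed: settling {inlet 2.46 cm/s,
outlets 28.61 mmHg}, rh {14.73 cm/s, 39.46 mmHg}, baseline {63 mmHg,
outlet velocities 2.13/1.77/1.93 cm/s}, tbi {79.6 mmHg, same outlets},
shaking and aht add the angular-motion body load to the 63 and
79.6 mmHg states. (The source text calls 14.73 cm/s "50% more" than
2.46 cm/s — a 6× ratio; both printed numbers are exposed as
configuration and the inconsistency is not resolved here.)

The shaking profile is ω(t) = A·sin(2πft) with f = 3 Hz and
A = peak/(2πf); only the peak angular acceleration (1068.3 rad/s², the
strongest value measured on shaken anthropomorphic dummies) is
quotable, so the sinusoid is a modeling choice. The sweep is
quasi-static — 50 samples over 1 s by default, t = 0 included — because
no transient structural data are published and the loading timescale
(3 Hz) is far below the tissue's elastic wave timescale at this size.
The body-force direction is chosen, per the "worst direction"
prescription, as the member of a 16-angle fan maximizing mean POI von
Mises at peak load; the chest-to-eye distance r defaults to 0.2 m
(not stated in the source; configurable).

Because the solid is linear and the body-force perturbation of the
flow is small relative to the boundary-driven flow, the sweep is
evaluated by superposing the base solution with two unit body-load
responses computed at the frozen base viscosity field. A test compares
this engine against full nonlinear re-solves at every step and finds
agreement well below 1%. Sweep metrics are reduced to per-POI maximum
and average; volumetric-strain statistics are taken on magnitudes with
the compressive sign restored.

In this synthetic geometry the pressurized wall is predominantly in
tension, so POI volumetric strains come out positive, where the
published tables report compression — a geometry- and
constraint-dependent sign that the reporting layer sidesteps by
comparing strain magnitudes.

## Ex vivo statistics

Trace analysis mirrors the wet-lab protocol. The line loss between
transducer and cannulation point is a least-squares line through
open-tube (flow, pressure) recordings, subtracted from each trace
(clipped at 0). Event detection works on a 2 s moving-average smooth:
the perfusion (clot-breakthrough) pressure is the vertex of a local
quadratic fit around the first prominent peak; the settling pressure is
the mean over the longest window with |dP/dt| < 0.2 mmHg/s lasting
≥ 20 s after the peak (trimmed by the smoothing window); the RH
pressure is the smoothed value at the first annotated rupture
timestamp (video-derived in the experiment; annotations stand in).

Tests: one-tailed two-sample pooled-variance t-tests at α = 0.05 —
pooled because equal variance across groups was separately verified;
a paired form is not possible since group sizes differ (17 perfused
eyes, 8 with choroid perfusion, rupture observed in a subset).
Normality is Anderson–Darling (statsmodels `normal_ad`), equal variance
is Levene; with numerically identical groups Levene's statistic
degenerates and p = 1 is returned by convention. The published t and p
values are not reproducible from the printed summaries (per-group n and
pairing are unstated); only the mean difference 10.84 mmHg is
recomputed.

## Synthetic data

Generators are pure functions of a seed-bearing spec. Per-eye pressures
are normal draws at the printed moments — perfusion (39.89, 15.73),
settling (28.61, 15.40), choroid (32.14, 14.11), RH (39.45, 11.43)
mmHg, 17 eyes, choroid in 8 — truncated at zero, with settling
resampled to not exceed the eye's perfusion pressure and RH resampled
to exceed settling (rupture happens on the post-plateau ramp); the
conditioning slightly biases the conditional marginals, which no test
asserts against. Choroid pressures are generated independently: no
dependence structure is published. Traces are piecewise — ramp, rounded
quadratic peak cap (2 s half-width) at the perfusion pressure, drop,
60 s plateau, then a 0.3 mmHg/s ramp with the rupture annotation where
it crosses the eye's RH pressure — plus the ground-truth line loss and
Gaussian noise (SD 0.5 mmHg). The ramp rate sits above the plateau
slope threshold so detection can separate the two regimes.

What the generators do not emulate: pulsatility, pump servo dynamics,
drift, clot re-formation, inter-eye correlation, or any imaging
channel. Passing round-trip tests therefore demonstrates internal
consistency of the detection pipeline at realistic noise, not
performance on raw laboratory traces.

## Reporting and the rupture rule

For each model the percent change over its reference (rh over settling;
tbi/shaking/aht over baseline) is computed per metric and POI, swept
scenarios contributing their maxima; row averages are means of the four
per-POI changes (validated: this convention reproduces the printed 48%
and 34% displacement averages exactly). Volumetric strain is compared
on magnitudes. Rounding is half-away-from-zero and happens only at
presentation; exceed flags compare raw floats. A model predicts RH iff
it exceeds the ex vivo change for at least one metric at one POI. On
the printed tables, only the combined AHT loading exceeds (strain and
displacement at all four POIs, von Mises at POI2).

Recomputing the printed comparison table from the printed POI tables
reproduces every von Mises cell exactly after rounding; a few
displacement and strain cells differ by 1–2 points (the study rounded
those from unrounded internals, and the printed strains carry only two
significant figures), and the ex vivo von Mises average recomputes to
39% (the source prints both 40% and 39% for this quantity; 40% is not
reproducible under any tested convention). Applied to the freshly
computed synthetic-geometry scenarios the rule yields no exceeding
cells: this geometry's pressure response is stronger and its shaking
response weaker than the traced original, which is exactly why absolute
FEA values are out of scope and the published verdict is reproduced
from the printed tables.

## Problem sizes and numerical choices

Default runs use the 4 µm mesh (31.5k triangles; Stokes ≈ 35k dofs,
elasticity ≈ 100k dofs), direct sparse factorization (COLAMD ordering
for the indefinite Stokes saddle, minimum-degree for the SPD
stiffness). Picard tolerance 10⁻⁶ (relative viscosity change), mass
balance tolerance 10⁻³, POI disc radius 0.4 t. The mesh-refinement
study halves 5 µm to 2.5 µm with a Newtonian fluid, which isolates the
discretization question from the rheology loop. The five-step,
four-angle variant of the sweep is used where the superposition engine
is cross-checked against full re-solves.

## Known limitations

- 2D en-face plane-strain idealization: no globe curvature, no
  vitreoretinal traction, no out-of-plane flow.
- One-way coupling and quasi-static sweeps; adequate at µm
  deformations and 3 Hz loading, untested beyond.
- The parametric geometry is a stand-in: absolute stresses, the strain
  sign, and the computed-scenario verdicts are geometry-specific.
- Linear elastic tissue; no hyperelasticity, viscoelasticity, damage or
  failure mechanics beyond the percent-increase threshold rule.
- The power-law rheology units and clamp, the sinusoidal shaking
  waveform, r = 0.2 m, and the anchoring choice are documented
  reconstructions where the source is silent.
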