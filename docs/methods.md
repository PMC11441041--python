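# Methods

`mvteer` simulates mitral valve closure and transcatheter edge-to-edge
repair (TEER) with a desk-scale finite-element membrane model. This note
documents the model, its assumptions, the synthetic study conditions, the
numerical choices, and what the test suite does and does not demonstrate.

## The valve data model

The valve is a triangulated mid-surface of the two leaflets in a local
Cartesian frame: origin at the annulus centroid, axial axis the best-fit
annulus-plane normal pointing toward the atrium, septal-lateral axis from
the anterior toward the posterior annulus, all units millimetres. The mesh
is one continuous band around the annulus (the leaflets are anatomically
continuous at the commissures), with per-triangle anterior/posterior
labels, an ordered closed annulus loop, per-leaflet free-edge chains,
per-vertex thickness (default 1.0 mm uniform), and two papillary tips
registered in end-diastole and early systole.

Radial slicing cuts the valve with planes containing the axial axis,
18 planes at 10° by default. The plane family is offset by half the
spacing (5°, 15°, ..., 175°) so that no plane is tangent to a commissural
leaflet boundary; each plane yields one anterior and one posterior trace,
ordered annulus → free edge. Reconstruction lofts the traces, ordered by
their angular position, back into a closed band; on the synthetic family
the round-trip mean surface distance is well below one mesh edge.

## Synthetic study conditions

Patient 3D-TEE segmentations equivalent to the imaging this model is
normally built from are not distributable, so the generator is the study
condition. Defaults, chosen once on anatomical grounds:

| parameter | default | rationale |
|---|---|---|
| annulus AP x CC diameter | 30 x 36 mm | normal adult mitral annulus |
| saddle height (peak-to-peak) | 4 mm | classic saddle annulus |
| anterior / posterior leaflet height | 24 / 14 mm | normal leaflet lengths |
| funnel tilt of the open leaflets | 15° from axial | keeps papillary-tip-to-free-edge distance nearly constant between open and closed states, as marginal chordae are in vivo |
| leaflet thickness | 1.0 mm uniform | the convergence yardstick of the calibration |
| mesh target edge | 1.5 mm (generator default) | membrane resolution; the test suite and acceptance script run at 2.5-4 mm to keep wall time in minutes — a deliberate problem-size choice, the physics is unchanged |
| papillary tips | below the commissures at 0.5 x CC radius laterally, depth 0.85 x max semi-axis + 2 mm | tips roughly equidistant from the open and closed free-edge positions |

The functional-regurgitation phenotype combines annular dilation
(`dilation_factor`, default study value 1.5) with papillary tethering
(`tethering_displacement`, study value (0, -3, -8) mm applied to both tips,
laterally mirrored). Tethering displaces the tip *anchors* while chordal
rest lengths stay tied to the untethered reference position — the
ventricular-remodeling mechanism: displaced papillary muscles load intact
chordae and restrict the leaflets. Without this separation the displacement
would be silently absorbed into the generated rest lengths and produce no
restriction. Under systolic load the default regurgitant valve leaves a
central coaptation gap of ≈1 cm² (severe secondary MR); the healthy
default (dilation 1, no tether) closes completely with ≈5 mm coaptation
height.

What the generator does *not* emulate: speckle/dropout imaging noise,
leaflet scallops (P1-P3 clefts), thickness variation, calcification,
chordal heterogeneity (marginal vs strut), and annular dynamics. Passing
tests therefore demonstrate the correctness and internal consistency of
the simulation chain on a clean geometry, not predictive accuracy on
patient data.

## Leaflet constitutive law

Leaflets are Fung-type anisotropic hyperelastic membranes:

    W = (c/2) (exp(Q) - 1) + (1/D) ((J² - 1)/2 - ln J),   Q = ε : b : ε

with ε the in-plane Green strain with shear suppressed (membrane shear
stress taken negligible), so the fourth-order b reduces to in-plane
orthotropic coefficients. Defaults c = 0.2 kPa, b_ff = 25, b_ss = 10,
b_fs = 5, fibers circumferential (annulus-parallel); these are
representative literature-style soft-tissue values and fully configurable.
Incompressibility is enforced kinematically (thickness = t₀/areal stretch,
J = 1, the volumetric term vanishes); the finite-D penalty form is
evaluated directly where the volumetric term itself is under test. A small
quadratic shear term (dimensionless coefficient `shear_stabilization`,
default 5, energy 2 c k ε₁₂²) removes the zero-energy in-plane shearing
mode that the shear-free law otherwise leaves unresisted; it is part of the
element energy, so stresses remain the exact energy gradient.

At 13.3 kPa (≈100 mmHg) these parameters give areal stretches of ~1.4-1.7:
the leaflets are very compliant and billow atrially. This is a property of
the chosen constants, not a numerical artifact; all geometric defaults
above were selected to coapt (healthy) or leak (dilated/tethered) *at*
these material constants.

## Chordae

12 chordae per papillary muscle, each a trunk splitting at 80% of the
tip-to-margin distance into 2 branches inserting on the free margin;
each tip serves its ipsilateral commissural half of both leaflets, with
insertions spaced evenly by arc length. Cables are linear tension-only
springs on engineering strain (default 6 N per unit strain per segment),
continuous at slack onset. Branch junctions are extra solver degrees of
freedom (massless at equilibrium). Pre-stretch λ₀ rescales rest lengths so
the as-generated configuration carries stretch λ₀.

## Quasi-static solver

Explicit dynamic relaxation with kinetic damping: fictitious nodal masses
are scaled from a per-node tangent-stiffness estimate and refreshed as a
decaying ratchet (they rise immediately with the tangent — the Fung law
stiffens by orders of magnitude over a solve — and bleed transient
inflation off at 5% per check so later creep phases are not stuck with
shock-sized masses); all velocities are zeroed when kinetic energy peaks;
a light viscous decay (1% per step, escalated 5x in the second half of the
step budget) breaks contact/slack-chord limit cycles; and nodes whose
force direction flips on a 2-3-step period — far below the natural
relaxation period, the signature of a local mode the global estimate
missed — get their individual mass boosted 1.5x per detection with slow
decay. Per-step displacement is capped at 25% of the smallest element
altitude. Collapsed elements (areal stretch → 0) get clamped strains so
the restoring stress stays finite; the exponential is continued linearly
(C¹) beyond Q = 12, where membrane tension already dwarfs the
transvalvular load, so the stress slope stays bounded through extreme
transients (physiological states, Q of order 1-10, are untouched). None
of these guards is active at a converged physiological state, so
equilibria are equilibria of the true forces. Convergence: max
out-of-balance nodal force < 1e-3 N, checked *before* integrating, so a
run started from a converged state terminates without motion.

Loads and constraints: follower pressure (13.3 kPa systole, -0.5 kPa
diastole, textbook transvalvular values — the element force is exactly
p·A·n lumped to nodes), annulus nodes fixed, papillary tips fixed at the
phase-appropriate registration, node-to-triangle penalty contact between
the leaflets (gap = leaflet thickness, penalty 2 N/mm; a node's force is
the penetration-weighted average over its overlapping opposing triangles,
which is smooth in the active set and reduces to penalty x (gap - d) for
a single pair; pairs within two graph rings are excluded — the band is
continuous at the commissures — and candidates refresh every 10 steps
from a centroid KD-tree).

The solver is verified against the classical approximate closed form for a
pressurized clamped circular membrane, w₀ ≈ 0.662 a (p a / E t)^(1/3),
in the isotropic small-exponent limit of the material (agreement ~1-3%,
tolerance 10%, mesh-halving consistency 5%).

## Inverse calibration of the closed shape

Following the corrective-pressure approach for matching an image-derived
closed surface: each element carries a pressure increment updated as
p_new = p_old + δ·α·‖d‖ with d the centroid-to-target shortest vector
(exact vertex/edge/face projection), δ = sign(d·n) (+1 at d·n = 0), and α
constant over the domain (default 0.25 kPa/mm; larger values can
overshoot — the loop aborts with a diagnostic if the mean distance grows
five iterations running). Convergence when the area-weighted mean distance
falls below the average leaflet thickness. Chordal pre-stretch is tuned
first by a bounded golden-section search (shared λ₀ applied per chorda,
bounds [1.0, 1.15], never below 1) on the mean free-edge distance to the
target. On a manufactured target (hidden smooth corrective field, λ₀ =
1.05) the chain recovers λ₀ within ±0.01 and the closed shape to ≪ 1 mm.

## Virtual clip implantation

The clip is a rigid kinematic constraint, not a deformable device mesh.

1. **Grasp selection**: on each leaflet, vertices within geodesic depth
   grip_fraction x arm_length of the free edge (multi-source Dijkstra on
   the mesh edge graph) and within half a device width of the requested
   coaptation coordinate (0 = anterolateral, 1 = posteromedial commissure).
2. **Kinematic closing**: band nodes are displacement-driven (smoothstep
   ramp, 800 steps) onto two parallel near-axial clamp planes one leaflet
   thickness apart. The clamp planes sit on the annulus-to-annulus chord at
   the point dividing it in proportion to the *ungrasped* leaflet lengths,
   so neither leaflet is forced to overstretch; the clip settles toward the
   shorter (restricted) posterior leaflet, as it does clinically. Pairwise
   midpoint targets were rejected: with a 70% grasp of a 9-12 mm arm on a
   14 mm posterior leaflet they demand >600% strain next to the fixed
   annulus.
3. **Rigid tie + re-simulation**: the closed bands become a 6-DOF rigid
   body integrated by the same relaxation (net force/torque, kinetic
   damping), and systole/diastole are re-run with the constraint active.
   Contact is disabled for clip-tied nodes (the constraint already encodes
   the clamp). Multiple clips are independent rigid bodies with disjoint
   bands.

Device catalog from the manufacturer family: NTW 9x6, XT 12x4, XTW 12x6 mm;
NT 9x4 is the fourth arm/width combination, flagged extrapolated. Grasp
fraction defaults to 70% of the arm length. The closed-clip residual
tissue gap allowance is 4 mm (two leaflets plus the device body). An
optional uniform annular-reduction factor (default 1.0 = none) emulates
post-clip annular remodeling.

## Orifice quantification

Orifices are delineated on the en-face projection (down the axial axis,
as in multi-planar reconstruction): annulus polygon minus the union of
projected leaflet triangles leaves the open channels; a morphological
opening of radius 0.75 x gap_threshold removes channels narrower than
1.5 x gap_threshold (two coapted mid-surfaces of thickness-t leaflets sit
~t apart, so the coaptation seam projects as a ~t-wide sliver). The default
gap_threshold is the mean leaflet thickness. Components below 2 mm² are
discarded as numerical slivers. Each surviving component is lifted to a 3-D
loop at the height of the nearest free-edge vertices; areas use the
vector-area formula (equal to the planar polygon area for planar loops) in
cm². The same construction serves systole (residual ERO, summed over
multiple jets) and diastole (MVA; a clip's tissue bridge splits the channel
into a double or triple orifice). Coaptation height is measured per radial
slice as the axial extent of trace points within 1.5 x thickness of the
opposite leaflet, averaged over coapting slices.

The reported ERO is the anatomic orifice area of the converged closed
state; no flow convergence (PISA) or pressure gradient is computed. On the
regurgitant study valve the ERO varies by under 5% as the gap threshold
sweeps 0.5-1.5 leaflet thicknesses (the dominant orifice is much wider
than any threshold in that range).

## Pipeline, determinism, problem sizes

The pipeline (synthesize/load → chordae → optional calibration → pre-clip
systole/diastole → clip → post-clip systole/diastole → metrics) persists
every stage artifact (legacy-VTK meshes, JSON) and resumes from persisted
stages when re-run with an identical configuration hash. Everything is
deterministic given the seed: identical seeds give bitwise-identical
geometries and byte-identical metrics JSON.

Default problem sizes: the study valve at 2.5 mm edges (~800 nodes,
~1500 elements) closes in 3-10 k relaxation steps (tens of seconds to a
few minutes per solve); the calibration loops run a 3.5 mm-edge valve. The
full default pipeline (one NTW clip) completes in well under 15 minutes on
one CPU.

## Known limitations

- Quasi-static only: no fluid-structure interaction, no dynamic cycling,
  no pressure gradient (MPG) — transvalvular pressures are prescribed.
- The annulus is rigid (optional uniform reduction factor aside); real
  TEER acutely reduces the AP diameter.
- ERO is anatomic, not effective (no flow contraction coefficient).
- The clip model ignores arm bending, gripper mechanics, and leaflet
  insertion-depth optimisation.
- The shear-free Fung reduction plus stabilisation under-resists in-plane
  shear; commissural folding is therefore softer than in a full
  anisotropic shell model.
- Membrane elements carry no bending stiffness; wrinkling is resolved only
  at mesh scale.
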