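# Methods

This package studies how cell geometry destabilizes protein polarization in
budding yeast by simulating reaction–diffusion master equation (RDME) models
of Cdc42 and polarisome dynamics on tip-shaped three-dimensional geometries.
This note records the modelling choices, the numerical scheme, the parameter
provenance, and what the desk-scale test suite does and does not establish.

## The RDME and the sampler

The cell volume is partitioned into K vertex-centred dual voxels of an
unstructured tetrahedral mesh. The state is a K×S matrix of molecule counts.
Reactions (mass action, molecularity ≤ 2) fire within voxels; in keeping with
the biology of yeast polarity all model reactions are restricted to membrane
voxels, where they may consume the cytosolic copies resident in the same
voxel. Diffusion is a Markov jump process between adjacent voxels: cytosolic
species hop on the tetrahedral adjacency, membrane species on the
boundary-edge adjacency.

Propensity conventions for a voxel with dual volume V_i and membrane area
A_i: zeroth order k·V_i (k·A_i for membrane-only reactions); unimolecular
k·x; heterodimeric k·x₁·x₂/Ω and homodimeric k·x(x−1)/Ω with Ω = V_i for a
cytosol–cytosol pair and Ω = A_i for membrane–membrane and mixed
membrane–cytosol pairs. Units are fixed package-wide (μm, s, molecules);
bimolecular constants are volumetric (μm³/s) or areal (μm²/s) accordingly,
with a helper for converting from per-molar units.

Realizations are drawn with the Next Subvolume Method: each voxel keeps its
next-event time in an indexed binary min-heap; within the chosen voxel the
event is selected Direct-Method style; after a reaction only the host
voxel's clock is rebuilt, after a jump both endpoints'. Clock ties have
probability zero and are not specially ordered. Identical inputs and seed
give bitwise-identical trajectories; per-realization seeds derive from
(base seed, realization index) through `numpy.random.SeedSequence`. A
deliberately naive Direct-Method SSA with full propensity recomputation
serves as an independent oracle, and both samplers are validated against a
matrix-exponential solution of the master equation on a three-voxel fixture.

## Diffusion jump coefficients

Jump coefficients come from the P1 finite-element stiffness matrix of the
Laplacian (volume elements for cytosolic species, boundary triangles with
cotangent weights for membrane species), with lumped mass V_i or A_i:
d_sij = D_s·max(0, −L_ij)/m_i. Because the assembled stiffness is exactly
symmetric, V_i·d_ij = V_j·d_ji holds to machine precision on every unclipped
edge, which makes the uniform state an exact stationary distribution
(occupancy ∝ V_i, respectively A_i).

Positive off-diagonal stiffness entries (obtuse elements) are clipped to
zero without rebalancing, and the clipped edge-weight fraction is reported.
A known limitation: point-insertion Delaunay meshing cannot drive this
fraction arbitrarily low — even a perfect BCC lattice block clips ≈3% of its
edge weight purely from boundary truncation, and the generated tip
geometries carry 5–15%. Meshes above 15% are rejected and a quality warning
fires above 5%. The practical consequence is a slight slow-down of
mesoscopic diffusion near the boundary; diffusion accuracy is therefore
verified independently (nearest-neighbour chain rate = D/h² within 1%,
tracer mean-squared displacement = 6Dt within 10%, exact stationarity).

## Geometries

Cell shapes are axisymmetric implicit surfaces: a smooth union (log-sum-exp
blend with a neck-smoothing length) of the spherical body and a
spherocylinder along −x whose apex models the mating-projection tip. The
five canonical shapes — sphere, slight deform, two projection stages, long
projection — are this package's parametrization of the successive stages of
projection growth; the published shapes came from a cell-wall mechanics
solver that is out of scope here, so only the qualitative shape classes and
the ≤15% volume-deviation constraint are binding. Dimensions (body radius
2 μm): slight deform L=0.8, a=0.55; projection stages L=1.3, a=0.6 and
L=3.0, a=0.5; long projection L=4.5, a=0.5 (L = apex height above the
sphere surface, a = tube radius; smoothing 0.3–0.35 μm). These were chosen
for volume fidelity and mesh quality, and the stage-2 tube is long enough
that tip escape is resolvable above the finite-copy cap-wander floor
(~3 μm over 1000 s at the reference copy numbers) — the same
separation-of-scales requirement the full-scale study satisfies through
cap size versus projection length.

Meshing: quasi-uniform surface rings (counts forced to multiples of 4, so
every mesh has an exact discrete 4-fold symmetry about the x-axis), a
congruent inward boundary layer, a BCC interior lattice, Delaunay
tetrahedralization with outside-culling, ODT smoothing of the interior, and
an exact re-symmetrization every iteration. Zero-volume slivers from
cospherical ring points are retained for a watertight boundary but carry no
volume and are skipped by the FEM assembly. Dual volumes use barycentric
lumping (V_tet/4 per vertex, A_tri/3 per boundary vertex), so ΣV_i and ΣA_i
are exact partitions. Surface geodesics are Dijkstra shortest paths along
boundary edges; on a sphere the edge-path distance to the antipode is
0.99–1.00 of πr (inscribed chords slightly undercut the great circle).

The tip frame places the origin at the volume centroid on the symmetry
axis (the published convention only fixes "an origin on the x-axis") and
the tip direction along −x, so a cap exactly at the tip reads
(θ, φ) = (90°, 180°).

## The three reaction networks and their parameters

The supplementary parameter tables of the source study were not available
to this implementation, so the three networks were reconstructed from the
models they were adapted from and calibrated once on the base r = 2 μm
sphere. Calibration happened during model construction; the acceptance
checks were frozen afterwards. Copy numbers are deliberately below
wild-type abundances (hundreds rather than thousands) so that stochastic
ensembles fit a single CPU; the rate constants were chosen to place each
model in the qualitative regime the study describes at those copy numbers.

**Mechanistic Cdc42 model.** A GTPase-cycle module: cytosolic Cdc42-GDP
attaches/detaches; a uniform Gbg (pheromone) input provides basal
activation; a cytosolic GEF complex is recruited by active Cdc42 and
cooperatively by membrane GEF (GEFc + GEFm → 2 GEFm), and activates
cytosolic Cdc42 in its voxel; hydrolysis returns Cdc42 to the membrane GDP
form; Cla4 is recruited by active Cdc42 and ejects the GEF (weak negative
feedback). The quadratic GEF self-recruitment supplies the cooperativity a
birth-death network with molecularity ≤ 2 needs for winner-take-all
competition; cytosolic Cdc42 and GEF are the shared substrates whose
depletion enforces a single cap. Cdc42/GEF/Cla4 totals are conserved
moieties. At the reference copy numbers (350/60/30) the model polarizes
from random starts within a few hundred seconds and holds a single compact
cap whose 50%-mass geodesic radius on the sphere is ≈1.2 μm — the recorded
default cap radius for polarized initial conditions.

**Simplified model.** The minimal positive-feedback network: attach,
detach, and recruitment of cytosolic by membrane-bound Cdc42. The
first-order attachment propensity is rescaled per mesh by the inverse
volume fraction of membrane voxels so that the effective well-mixed
attachment rate equals k_on on any mesh; the stationary membrane fraction
at k_fb = 0 is then exactly k_on/(k_on+k_off) regardless of geometry. At
the reference density the model shows transient clusters that form and
dissolve; at 1% of it the membrane is essentially empty (the density
switch).

**Polarisome model.** Bni1 is recruited by active Cdc42 (rate B_on, the
spec's tunable of interest), by membrane Spa2 (positive feedback), and by
a weak spontaneous attachment path that lets the polarisome nucleate
anywhere; membrane Bni1 nucleates actin cables (unconserved species with
first-order decay); cables deliver cytosolic Spa2. In frozen-field mode
the active-Cdc42 profile enters the B_on propensity as a static per-voxel
multiplier and never changes. The coupled model unions the mechanistic and
polarisome networks, with actin cables additionally delivering cytosolic
Cdc42-GDP to the membrane (vesicle-transport feedback).

## Desk-scale study conditions

Default problem sizes, chosen once as this package's reference conditions:
mesh edge 0.5 μm on the r = 2 μm geometries (K ≈ 450–550 voxels; 0.8 μm on
the r = 4 μm sphere), cytoplasmic diffusion D_c = 10 μm²/s (within the
range the study explored; the high-diffusion D_c = 50 μm²/s variant is the
E8 catalog experiment), membrane diffusion 0.01 μm²/s, 1000 s horizons for
cap-drift experiments (600 s in the heaviest test-suite ensembles, where
the geometry effect is already fully expressed), and 10–50 realizations
per condition. The experiment catalog (E1–E8) mirrors the full in-silico
study design and accepts a scale factor for further shrinking.

## What the tests show — and what they do not

The test suite establishes, at desk scale: exactness of the sampler
(master-equation and cross-sampler agreement), correctness of the
mesoscopic diffusion (chain rate, MSD, stationarity, reciprocity), exact
moiety conservation, the simplified model's closed form and density
switch, the geometry effect on the mechanistic model (tip-polarized caps
end significantly farther from the tip on a short projection than on a
sphere; the cap leaves the ±10° tip region within a few hundred seconds;
on the long projection the cap remains inside the tube in the majority of
realizations), azimuthal symmetry of spontaneous polarization on the
sphere, the frozen-Cdc42 polarisome contrast (a hundred-fold B_on boost
pins Spa2 to the tip), and multi-site polarization on the large sphere at
constant density.

Known limitations of the desk-scale conditions:

* With hundreds rather than thousands of molecules the polarization cap
  wanders diffusively, so a sphere cap does not stay within ±10° of its
  starting point for 1000 s the way the full-scale model's does; the
  geometry effect is therefore quantified *relatively* (rank-sum between
  geometries), exactly as fluctuating ensembles require.
* The simplified model's long-run cluster statistics on projections show
  tube *enrichment* rather than the tip depletion seen at full scale: at
  reduced copy numbers recruitment is diffusion-limited and detached
  molecules in the quasi-one-dimensional tube rebind locally (a recurrence
  effect), which outweighs the catchment-starvation mechanism that
  dominates in the reaction-limited, high-copy regime. No desk-scale test
  asserts the depletion direction.
* Clipped stiffness edges slightly slow diffusion near curved boundaries
  (see above); all quantitative diffusion checks pass within their stated
  tolerances nonetheless.

Numerical details: sampling is on a fixed time grid with state carried
between events; cached propensities are fully recomputed every 5×10⁶
events to bound floating-point drift; simulations abort on non-finite
propensities or negative counts; cluster counting uses a threshold of 2×
the mean surface density and a 5-voxel minimum (the published criterion is
unstated; both knobs are exposed); time averages discard a 10% burn-in by
default; the cap centre uses all membrane signal and is flagged ill-defined
when the resultant length falls below 0.05; the polarization index
multiplies the membrane fraction by the Rayleigh-corrected resultant
length √max(0, R²−1/n).
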