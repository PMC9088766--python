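# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Structural model and I/O

A structure is a flat, ordered list of atoms addressed by the triple
(chain, residue number, atom name); residue numbering is taken verbatim
from the input and never renumbered, because every residue referenced in
the analyses (Ser42, Arg38/65/93, Ser144, Tyr157) is meaningful only in the
authors' numbering.  PDB parsing is strict (Biopython, `PERMISSIVE=0`):
alternate locations resolve to the highest-occupancy copy, insertion codes
are rejected rather than silently renumbered, and duplicate atom triples are
integrity errors.  Trajectories carry no box or periodicity — all analyses
here use intra-complex distances far below any box dimension, so minimum
image handling would add surface without changing a single number.  The XYZ
dialect (count line, comment, `element x y z` in Å) is supported as the
simplest portable multi-frame format; it carries no atom identity, so
analyses that address atoms by name (competence, H-bonds, reaction
coordinate) should use multi-model PDB.

Umbrella-window files are two header lines (`center`, `force_constant`)
followed by one ξ sample per line; peak lists are CSV
(`residue,shift_H_ppm,shift_N_ppm,intensity`) plus a manifest CSV
(`point,ratio,file`).  All writers round-trip within 1e-6.

## Pose triage

* Thresholds (−90 kJ/mol, 9 Å) are **strict** inequalities; a pose exactly
  at a threshold is excluded.
* The stability criterion compares every sample of the final 4 ns window
  against the **window mean** with a 15% relative tolerance.  An alternative
  reading — deviation from the window's first value — is available via
  `stability_reference="first_value"`; the two differ only for drifting
  series.  The criterion is scale-invariant by construction.
* Cα RMSD uses the least-squares orthogonal superposition (Kabsch via SVD,
  through `scipy.spatial.transform.Rotation.align_vectors`); the test suite
  checks it against an independent brute-force minimizer over rotation
  vectors.
* Clustering is average-linkage on the pairwise Cα-RMSD matrix, cut to the
  requested number of clusters, with medoid representatives (minimal summed
  RMSD to members).  No clustering algorithm is canonical for this task;
  average linkage with medoids was chosen because it is deterministic,
  metric-agnostic, and needs no coordinate averaging (which would distort
  chirality).  Ties break to the lowest frame index.
* The Ser42 Oγ–to–arginine-patch distance pools the guanidinium atoms
  (Cζ, Nη1, Nη2, Nε) of all listed arginines into one mass-weighted centre
  of mass; a per-residue option reports individual distances instead.
* Docking interaction energies are consumed, never computed: the scoring
  engine is an external tool whose output tables are inputs here.

## Stereochemistry and reaction competence

* **Chirality** is assigned from caller-supplied substituent priorities (no
  CIP engine — the substrate's priorities are fixed and known, so a general
  implementation would be disproportionate).  The label is read from the
  sign of n·v₄ where n is the right-handed normal of the priority-1→2→3
  plane and v₄ the vector to the lowest-priority substituent: positive means
  the 1→2→3 cycle appears clockwise to a viewer opposite substituent 4,
  i.e. R.  Configurations with |n·v₄| below 1e-6 (scaled) are degenerate.
* **Prochiral face**: with carbonyl substituent priorities O9 > C8 > C10,
  the hydride's side of the carbonyl plane is the sign of
  (H−C9)·[(O9−C9)×(C8−C9)]; the negative side is the Re face and Re-face
  attack is pro-S (yields the S-alcohol).  The test suite cross-checks this
  against the independently computed R/S label of the tetrahedral product.
* **Ring conformers** use Cremer–Pople puckering coordinates: chair when the
  total amplitude Q ≥ 0.1 Å and θ within 30° of 0°/180° (up/down by the sign
  of q₃); axial when the substituent bond makes < 45° with the ring normal
  (folded to [0°, 90°]).  Non-chair geometry is a label, not an error.
* **Competence criteria** default to hydride–C9 ≤ 3.0 Å, Tyr-Oη–O9 ≤ 3.5 Å,
  Ser-Oγ–O9 ≤ 3.5 Å and a required pro-S face.  These are standard
  near-attack-conformation contact distances; they are deliberately
  configuration-exposed, and no test or headline number depends on the
  specific defaults — only on recovery of planted labels under whatever
  criteria generated them.
* **ΔG = −RT ln f** is reported as a positive cost (the published values are
  positive magnitudes from fractions < 1).  R = 1.98720425864×10⁻³
  kcal·mol⁻¹·K⁻¹; the default temperature is 303 K, matching the simulation
  thermostat.  At one decimal place the conversion is insensitive to the
  298-vs-303 K "room temperature" ambiguity, and the suite asserts both.
* **Jackknife** error bars leave out one *replica* at a time (frames within
  a replica are autocorrelated, so frame-level resampling would understate
  the error): se = sd(θ_i) · √((m−1)²/m) for m replicas, equivalently the
  standard jackknife standard error of the pooled fraction.  ΔG is flagged
  undefined (None) when no frame is competent.

## Hydrogen bonds

Geometric criterion: donor–acceptor ≤ 3.5 Å and donor–H–acceptor ≥ 135°
for some hydrogen on the donor — standard practice values, both exposed.
Water bridges are single-water only: one water simultaneously
hydrogen-bonded (either role) to both sides in the same frame; two-water
chains never count.  Occupancy is a plain per-frame fraction; direct and
bridged contacts are tallied separately and may co-occur in one frame.

## CSP analysis

δ_AV = {0.5[Δδ(¹H)² + (0.2Δδ(¹⁵N))²]}^½ with bins none (≤ 0.02 ppm),
yellow (≤ 0.04), orange (< 0.06), red (≥ 0.06).  The boundary points 0.02
and 0.04 ppm are assigned to the lower bin (the published intervals are
open at both ends, so a convention is required; the conservative one was
chosen).  Peaks are matched across titration points by residue number
(assigned lists); a greedy nearest-neighbour mode with a 0.05 ppm maximum
jump in scaled (¹H, 0.2·¹⁵N) coordinates exists for unassigned lists.
CSPs are reported apo (first list) → final point, with per-point values
also available.  A residue is flagged exchange-broadened when it disappears
before the final point with its last observed intensity below 50% of its
initial value; the 50% threshold is a package convention, as intensity-loss
criteria are not standardized.  Prolines (no backbone N–H) are emitted with
an explicit `missing` marker rather than a bin.

## Umbrella sampling and WHAM

* Reaction coordinate ξ = d(H⁻, donor carbon) − d(H⁻, acceptor C9):
  negative in the reactant state, positive in the product.
* **Bias convention**: w(ξ) = ½k(ξ−c)², k in kcal·mol⁻¹·Å⁻².  Inputs scored
  as k(ξ−c)² (no ½) must be doubled before use; conventions differ between
  MD codes and are rarely stated, so this one is fixed and documented here.
* WHAM iterates the window shifts f_i directly (in log space via
  `logsumexp`), with defaults bin width 0.02 Å, tolerance 1e-6 kcal/mol on
  the shifts, 10⁵ iterations maximum, and optional simple mixing for
  oscillatory cases.  Unvisited bins are dropped from the output grid; the
  unbiased probability is normalized to 1 before −RT ln; the PMF minimum is
  set to zero.  Non-overlap between adjacent windows' sample ranges warns
  (the profile may be disconnected); non-convergence raises with the
  residual.
* No autocorrelation correction is applied by default — the synthetic
  sampler draws independent points, so window counts are true sample sizes.
  For correlated (e.g. MD) data the Metropolis generator and an
  effective-sample-size treatment would be required before trusting error
  estimates; the PMF point estimate itself is unaffected.
* The window ladder helper builds centers `start, start+Δ, …` inclusive of
  the endpoint when commensurate (e.g. −1.8…1.8 at 0.1 Å gives 37 windows);
  a non-commensurate endpoint is dropped with a warning.

## Synthetic data: what it emulates, and what it does not

* **Competence trajectories** emit a minimal 14-atom roster (nicotinamide
  donor carbon and hydride; substrate C7–C11 and O9; Tyr157 Oη/Hη; Ser144
  Oγ/Hγ; Ser42 Cβ; Arg38 Cζ).  Exactly round(n·fraction) frames satisfy all
  criteria *before* noise: competent frames place every contact at 90% of
  its cutoff (the 10% margin keeps zero-noise labels exact), hydride on the
  Re face; incompetent frames violate one criterion — hydride distance, Tyr
  or Ser contact at 150% of the cutoff, or a face flip — chosen per frame
  from the seeded stream.  Isotropic Gaussian noise of the requested σ is
  then added to every coordinate.  The generator does not emulate solvent,
  force-field energetics, periodic images, or correlated frame-to-frame
  dynamics; recovery tests therefore certify the classifier and statistics,
  not the conformational sampling of real MD.
* **Umbrella windows** are drawn *exactly* (independent draws) from the
  biased Boltzmann density by rejection against a piecewise-constant
  envelope on a fine grid.  A bias-Gaussian proposal would be arbitrarily
  inefficient where the underlying potential is steep (the biased density
  shifts far from the bias centre), so the envelope tracks the actual
  density; acceptance stays near one everywhere.  A random-walk Metropolis
  option (default burn-in 500 steps, step size √(RT/k)) exists for realism;
  its samples are correlated.  Supported potentials: harmonic, quartic
  double well a(ξ²−b²)² (analytic barrier a·b⁴ at ξ=0), and a clamped
  piecewise-linear table.
* **Titrations** follow the fast-exchange limit: observed shift = free
  shift + f_bound·Δδ_sat, with f_bound the single-site quadratic-binding
  solution for totals implied by the KR/ACP ratio and the ACP concentration
  (defaults 0.5 mM ACP, Kd 0.5 mM — a weak, transient complex; no measured
  affinity exists for this pair, so the Kd is a free synthetic parameter).
  The default ratio ladder prepends an apo point (ratio 0) to the eight
  experimental ratios 0.08–2.34, providing the reference spectrum.
  Broadened residues lose intensity by a factor (default 0.5) per point and
  drop out below 10% of the initial intensity.  Slow/intermediate exchange,
  peak overlap and assignment errors are not emulated.
* **Pose tables** mix two (energy, distance) Gaussian clusters — binder-like
  (−120 kJ/mol, 5 Å) and non-binder (−50 kJ/mol, 12 Å), σ = (10, 1) — with
  ground-truth labels retained for filter tests.
* All generators are deterministic given their seed (bit-identical repeats).

## Problem sizes

The shipped analyses and checks run at 8 replicas × 1000 frames for the
competence statistics, 37 umbrella windows × 5000 independent samples for
WHAM, and 160-pose tables — sizes at which every stochastic recovery lands
well inside its statistical tolerance (3 binomial standard errors;
0.2 kcal/mol on the WHAM barrier) while a complete run stays in the
seconds-to-minutes range on a single core.

## Known limitations

* No CIP priority engine; chirality needs caller-supplied priorities.
* Water bridges are single-water by definition; longer chains are invisible.
* WHAM error bars (block bootstrap over windows) are not implemented; the
  suite bounds errors by analytic-recovery tests instead.
* The PDB writer emits minimal fixed-column records (no occupancy/altloc
  round-trip, single-character chain ids).
* The synthetic competence geometry fixes the anchor atoms (Ser42 Cβ,
  Arg38 Cζ) away from the active-site atoms; it is not a physical model of
  the ACP–KR interface, only a carrier for plantable labels and distances.
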