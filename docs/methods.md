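# Methods

This note documents the models, conventions and numerical choices
behind `mdgate`, and what the synthetic-data tests do and do not show.

## Coordinate and data model

Atoms carry PDB-convention names, elements, author residue numbers
(never renumbered), chain IDs and positions in Å. Trajectories are
ordered frames of positions with per-frame orthorhombic boxes and
times in ps. Internal indexing is 0-based; all user-facing residue
numbers are the 1-based author numbers of the input structure. Domain
definitions default to the SLC26A9 subdomain spans in that numbering:
core 45–150 ∪ 158–198 ∪ 313–428, gate 199–312 ∪ 429–499, STAS
5–26 ∪ 500–567 ∪ 653–741, TM = core ∪ gate.

PDB and DCD/XTC/TRR I/O is delegated to MDAnalysis behind the package's
own containers; multi-model PDB is the guaranteed plain-text trajectory
fallback. A line-level pre-validation pass runs before parsing so that
malformed ATOM records are reported with their line number; insertion
codes are rejected (out of scope for author-numbered selections).
Masses come from a standard element table; a `unit` flag switches
center-of-mass calls to centroid semantics. Superposition is Kabsch
(SVD with determinant correction), validated in the tests against an
independent rotation-search minimizer.

## Occupancy grids and the binding classifier

The volume covered by the periodic box (or user bounds) is discretized
into cubic cells, default spacing 1.0 Å. A cell's probability is the
fraction of frames with **at least one** tracked ion in the cell; at
1 Å³ double occupancy by anions is sterically negligible, so this
coincides with the per-ion reading. An expected-count tally (every
ion–frame assignment) is kept alongside and checked in the tests
against the conservation identity Σ_cells counts = ions × frames.

When an alignment selection is given, each frame is first superposed
onto the reference coordinates (topology by default) so the map lives
in the protein-aligned frame; this matches showing densities on an
average structure. Whether to fix the grid in the box frame or the
protein frame is genuinely open; protein-aligned is this package's
choice, and unaligned binning (with periodic wrapping into the primary
cell) is what you get when no alignment selection is passed. Ions
falling outside the grid are counted in no cell and reported in a
warning.

μ and σ are the mean and *population* standard deviation of the cell
probabilities over **all** cells, including protein-excluded volume.
The binding site is a sphere of radius 5 × 1.7 Å (carbon van der
Waals) = 8.5 Å centred on the midpoint of the Cα atoms of residues 128
and 391 of a chain. A chain is called bound when the maximum cell
probability among cells whose *centers* lie in the sphere is strictly
greater than μ + kσ, default k = 50. Strict inequality means equality
is not binding; cell-center membership keeps the classifier
deterministic at the grid's own resolution. The classifier is monotone
in k by construction.

The per-frame binding time series counts ions within 9 Å
(minimum-image) of **both** anchor Cα atoms.

Concentration conversion: under a Poisson occupancy model the expected
μ and σ are equal, so a probability of μ + kσ corresponds to
bulk × (1 + k) — 7.65 M for k = 50 at 0.15 M bulk. For Bernoulli-like
rare occupancy the empirical σ generally differs from μ (σ ≈
√(μ(1−μ)/n) per-cell sampling noise dominates), so classification
always uses the empirical σ; the σ = μ convention enters only this
documented conversion.

## Free-energy landscapes

ΔG_i = −RT ln(n_i/n_min) with R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹ and
T defaulting to the 303.15 K thermostat setting. The logarithm is the
natural logarithm (Boltzmann-inversion convention). n_i counts frames
in cell i where the objective event occurred; n_min is the smallest
nonzero count, pinning ΔG = 0 at the rarest visited cell, so every
defined value is ≤ 0 and ΔG is strictly decreasing in n_i. Cells with
n_i = 0 are masked — never 0, never imputed. A diagnostic warns when
n_min ≠ 1 (the convention that the grid interval be fine enough for the
rarest cell to be singly visited) and suggests refining the interval.

Binning is half-open [lo, hi), anchored at the data minimum for
distance axes (default interval 0.25 Å) and at −180° for periodic
dihedral axes (default 1°, full (−180°, 180°] circle, binned modulo
360°). Dihedral landscapes therefore always contain the probe cells;
distance landscapes raise an error for probes outside the sampled
range.

The dual-mode classifier evaluates ΔG at the cell *containing* each
probe point — no interpolation, matching a 1°-resolution cell-based
landscape; probes on a cell boundary belong to the half-open cell on
their right. Defaults: probes (−60°, 15°), (−60°, −45°), (−90°, −15°)
in (φ, ψ) and threshold −0.9 kcal/mol, strict inequality; a masked
probe cell fails. The classifier is monotone in the threshold.

## Geometry

* **Core–gate distance**: per-frame Euclidean Cα–Cα distance between
  residues 362 (core tip) and 201 (gate tip) of one chain.
* **Dimer frame**: z is the membrane normal (box +z by default,
  overridable), x the component ⊥ z of the vector from chain B's TM
  center of mass to chain A's, y = z × x, origin the midpoint of the
  two TM COMs. Construction errors out when the inter-chain axis is
  parallel to z. The STAS COM trace reports per-frame STAS
  centers of mass in this frame; its y column is the histogrammed
  lateral coordinate.
* **Dihedrals**: IUPAC convention, φ = C(i−1)–N–CA–C, ψ =
  N–CA–C–N(i+1), signed, (−180°, 180°], cross-checked against
  MDAnalysis' implementation.
* **Kink angle**: per flank of the hinge residue, the helix axis is
  estimated from the Cα windows [i−6, i−1] and [i+1, i+6] (half-window
  exposed as a parameter; ≥ 4 Cα required per side) as the common
  normal of the Cα second differences d_j = p_{j−1} + p_{j+1} − 2p_j
  (smallest-singular-vector fit), oriented N→C. For an ideal helix the
  second differences are exactly perpendicular to the axis, so the
  estimator is unbiased on short arcs — unlike a raw principal-
  component fit, which on a 6-residue window of a *straight* ideal
  helix is tilted ~3.5° and would fabricate a ~7° kink. The kink is the
  angle between the two flank axes, in [0°, 180°].
* **Salt bridges**: basic side-chain nitrogens (NZ, NH1, NH2, NE)
  versus acidic side-chain oxygens (OD1, OD2, OE1, OE2), minimum-image
  N–O distance strictly below 4.0 Å (the common structural-biology
  convention; exposed as a parameter), deduplicated to the closest pair
  per residue pair. Residue 709 is addressed by chain and number only;
  its identity is taken from the input structure, not assumed.
* **RMSD profiles**: per-frame best-fit RMSD of a selection to a
  reference frame after superposing on that same selection.

## Synthetic generators

Each generator is kinematic (no forces, no membrane, no physical
realism) and bit-reproducible given its config and seed, with a single
private RNG stream and a ground-truth sidecar so tests never re-derive
truth from the data under test.

* **Ion well**: n ions random-walk in a periodic box; one tracked ion
  follows a two-state bound/unbound Markov chain with stationary bound
  probability p_bind, sitting uniformly within the well radius
  (default 0.4 Å, inside one 1 Å cell centred on a cell center) when
  bound. The default switching rate of 1.0/frame makes the states
  i.i.d., so realized occupancy obeys the binomial law the recovery
  tests assume; smaller rates give autocorrelated (telegraph-like)
  kinetics. Two static anchor Cα atoms whose midpoint is the well
  center make the site constructor and time-series counter work
  directly. Defaults (40 Å box, 5 ions, p_bind 0.30, 2000 frames) are
  the recovery-test study conditions.
* **Dihedral modes**: crankshaft samples along the slope −1 line
  through the vertex (−90°, −15°); non-crankshaft along the slope +1
  line; dual is their mixture, populating all three probe cells; the
  single-branch sets are the negative controls. Branch spread 20°
  (keeps ±180° wrap-around negligible), scatter 5°.
* **Kinked helix**: N/CA/C backbone chained by NeRF from ideal bond
  lengths/angles at (φ, ψ) = (−57°, −47°) — which reproduces the
  canonical ~1.5 Å rise, ~100° twist, ~2.3 Å Cα radius — with the
  chain beyond the hinge rotated by the configured kink angle about a
  perpendicular axis through the hinge Cα, plus optional Gaussian
  jitter.
* **Telegraph salt bridge**: a two-atom pair switching between 2.8 Å
  and 8.0 Å with a configured duty cycle.
* **Dimer toy**: per chain, a TM and a STAS blob of Gaussian-scattered
  CA pseudo-atoms with exactly-centred clouds (the configured centers
  are the true centroids), residue numbers inside the default domain
  spans, and an optional per-frame drift of chain A's STAS blob.

Because the generators are kinematic, passing recovery tests shows the
*estimators* are correct and well-calibrated at the stated sample
sizes; it says nothing about force fields, sampling convergence or the
biology of any particular transporter. Real trajectories additionally
contain correlated frames, anisotropic wells, identity exchange between
ions and non-orthorhombic boxes in some setups — of these, only frame
correlation and orthorhombic periodicity are exercised here.

## Problem sizes and determinism

The test and acceptance runs use desk-scale sizes chosen so each
statistical check has comfortable power: 2000 frames for occupancy
recovery (binomial 99% CI half-width ≈ 0.026 at p = 0.30), 10⁵ draws
for Boltzmann recovery (max error tolerance 0.15 kcal/mol; observed
≈ 0.02–0.09), 10⁵ samples for the dual-mode sets, 5000 frames for the
telegraph duty cycle. All stochastic quantities flow from explicit
seeds; `scripts/acceptance.py` derives every sub-seed from its
`--seed` argument.

## Known limitations

* Minimum-image distances assume orthorhombic boxes; triclinic cells
  are not reduced.
* The occupancy grid does not smooth, symmetrize across chains, or
  partial-volume-weight cells at the site boundary.
* No reweighting or WHAM/MBAR; landscapes are raw Boltzmann inversions
  of event counts, with no error bars beyond the sampling-consistency
  test.
* Loop modelling, system construction and MD itself are out of scope;
  coordinates are analyzed as given.
* The real experimental structure of the transporter is not bundled;
  structure-dependent checks in the tests run on a synthetic stand-in
  fragment built to the published initial geometry (22 Å core–gate
  separation), which verifies the measurement pipeline, not the
  experimental coordinates.
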