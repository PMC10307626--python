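# Methods

This note documents the models, numerical choices and limitations behind
each module, in the order a study would use them.

## Screw symmetry: generation and estimation

A filament is an orbit of a protomer under a screw operator with rise d
(Å/subunit), twist τ (deg/subunit), axis direction â and axis point p.
Estimation inverts generation without any iterative refinement: for each
consecutive subunit pair the rigid transform is obtained by a Kabsch
least-squares superposition of Cα coordinates (scipy's
`Rotation.align_vectors`), then decomposed into screw form. The rotation
axis and angle come from the rotation vector; the rise is the translation
component along the axis; the axis point solves (I − R)p = t − d·â by
least squares, whose minimum-norm solution is the unique point normal to
the axis. Per-pair estimates are combined by the arithmetic mean (rise,
axis, point) and the circular mean (twist). Sign convention: the axis is
oriented so the rise is positive, and the twist then follows the
right-hand rule; a left-handed filament such as the 20.95 Å / −1.05°
reference case keeps its negative twist under this convention.

Degeneracies are explicit errors rather than silent results: an identity
transform has no axis; a pure 180° rotation leaves the axis orientation
ambiguous; a pure translation is returned as rise = |t|, twist = 0. The
round trip build→estimate is exact to ~1e-13 on clean coordinates, far
inside the 1e-6 tolerance asserted by the tests. Model coordinates are
held in float64 throughout; the biotite atom arrays used for file I/O
mirror them at float32, which is why estimation always reads the float64
store.

One bookkeeping point about cumulative rotation: for an n-subunit
filament the rotation between the first and last subunit accumulates
(n − 1) twist steps, matching the (n − 1)·d axial span of the centroids;
applying the screw operator n times accumulates n steps. The tests check
both quantities separately.

## Ring closure

The pore model places subunit i at angle 2πi/n on a circle of radius
R = n·d/2π in the plane normal to the membrane normal (z), with the
protomer's filament-propagation axis turned tangential and its centroid
on the circle, so consecutive centroids are spaced exactly d along the
arc. The intrinsic per-subunit twist of the filament is *dropped* on
closure — the subunits are rearranged, not screw-propagated — and the
accumulated residual (n·τ, wrapped to ±180°) is reported as a
closure-mismatch diagnostic in `extras['residual_twist_deg']`. For the
45-mer at τ = −1.05° this residual is −47.25°. Preserving the twist
instead would require an out-of-plane supercoil that the planar pore
geometry cannot accommodate.

## Antiparallel double filament

The second filament is the first rotated 180° about the axis
perpendicular to both the filament axis and the hydrophobic-face normal,
then offset along that normal. This choice simultaneously makes the two
propagation axes antiparallel and turns the copy's hydrophobic face back
towards the original — the packing observed for the detergent-solubilised
polymer. The face normal defaults to the one computed by the
amphipathicity module; any interatomic contact closer than 1.5 Å raises a
clash error naming the worst pair. No energy minimisation is attempted.

## Coevolution contact mapping

d_intra is measured on the reference subunit; because generated subunits
are rigid copies it is subunit-independent, which is asserted to 1e-6
(`rigid_tol=None` relaxes this for deposited models whose chains differ
slightly). d_inter_min minimises over *all* ordered subunit pairs, not
only adjacent ones — the minimum over neighbours is subsumed and the
definition stays topology-agnostic. Classification: pairs whose smaller
distance exceeds the cutoff (12 Å between Cα atoms by default) are
excluded; otherwise a pair is inter-dominant only if d_inter_min is
*strictly* shorter than d_intra, so exact ties count as intramolecular.
The screen keeps the top 100 pairs with score > 0.5 by default. Table
reading deduplicates unordered pairs keeping the maximum score and
supports an index offset for alignment-column to author numbering.

## Amphipathic surface analysis

Residue positions are side-chain centroids (all non-backbone heavy
atoms; Cα for glycine or Cα-only models) — the belt is a side-chain
property. The face split is a single planar cut through the filament
axis found by a 1° azimuthal grid search maximising the difference in
mean hydrophobicity between the two half-planes; a best split below 1e-6
separation (e.g. a homopolymer) is flagged degenerate rather than
asserted. The default scale is Kyte–Doolittle with the Wimley–White
interface scale selectable; no claim is made that either matches the
rendering package behind published lipophilicity surfaces. Belt height
is the axial extent of hydrophobic-face residues with hydrophobicity at
or above a threshold (default 1.8, the Kyte–Doolittle value that admits
alanine and everything stronger), after trimming the top and bottom 2.5%
of z-values to guard against single-residue outliers; the trim is
configurable to zero for exact constructions, and height is monotone
non-increasing in the threshold.

The hydrophobic moment subtracts the mean hydrophobicity before the
Eisenberg sum, μ_H = |Σ (H_k − ⟨H⟩) e^{ikδ}|/N. The raw sum is available
(`center=False`), but the centred form is the default because it makes
μ_H exactly zero for homopolymers of any length, whereas the raw sum
vanishes only when N·δ is a multiple of 360°; the two agree on the
amphipathic-vs-uniform ordering that the moment is used for.

## SMLM morphometrics

DBSCAN (scikit-learn) with Euclidean 2-D distances; a point is core when
at least `min_pts` points, itself included, lie within `eps`. Border
points join the cluster that first expands onto them in the
index-ordered depth-first traversal, which the brute-force O(n²) oracle
in the test suite reproduces exactly, giving label-for-label parity.
Defaults eps = 50 nm, min_pts = 10 are package defaults chosen for
15 nm-precision data, not values taken from any publication.
Localization precision is not used to weight points.

The gyration tensor is the population (divisor N) second-moment matrix
about the cluster centroid. Ecc = √(λ₁/λ₂) ≥ 1 was chosen over the
alternative √(1 − λ₂/λ₁) ∈ [0, 1) because it reads directly as an axis
ratio; the alternative is available as `ClusterStats.ecc_alt()`. A
collinear cluster (λ₂ = 0, or a ratio beyond 1e12) reports an infinite
sentinel and a degenerate flag instead of overflowing.

Condition comparisons use the equal-variance two-sided Student t on
per-experiment medians; the experiment, not the localization, is the
unit of replication because localizations of one cell are strongly
correlated (blinking, shared clusters). Zero pooled variance is resolved
by the limit: equal means give t = 0, p = 1, unequal give |t| = ∞,
p = 0.

## Assay quantifications

All formulas are linear rescalings; out-of-range percentages are flagged,
never clamped, so pipetting or control failures stay visible. Phase
plateaus of the dithionite-quench trace are estimated as the median of
the final 20% of each phase — the recording runs "until plateau", so the
tail median is robust to both transient decay and point noise; using the
endpoint value instead changes the result by well under the assay noise.
A sealed symmetric liposome loses half its signal on dithionite addition
(only the outer leaflet is accessible), which the formula maps to 0%
permeability; full quench maps to 100%. The DRAQ7 onset uses the strict
inequality (F_t − F_i)/F_i > 1; a trace touching exactly twice its
initial intensity has not yet crossed. The inhomogeneity normalization is
the difference D_t − D_i, whose first value is exactly zero.

## Synthetic-data generators

Every generator is a deterministic function of its spec, which carries
the seed (numpy `default_rng`; no global state), and returns the ground
truth needed to score the downstream analysis.

*Protomer*: four ideal α-helices (1.5 Å rise/residue, 100°/residue,
2.3 Å radius) on parallel axes with alternating direction, spanning the
NINJ1 annotation (α1 44–55, α2 58–74, α3 79–103, α4 114–138, modelled
span 39–141), Cα-only, loops linearly interpolated. Residues pointing
towards +x are leucine — a planted hydrophobic face — and the rest
alternate lysine/glutamate. This fixture has exact helical geometry and
no side chains; it validates geometry and face logic, not packing or
rotamer behaviour.

*Localization fields*: untreated fields contain many single-site dots and
a few small round clusters; pyroptotic fields contain large
branched-filamentous clusters built from persistent, softly
self-avoiding branching walks (step 20 nm, branch probability 0.02 per
step, 1000 nm contour scale, giving 0.5–5 µm extents). Blinking is a
geometric number of localizations per site with Gaussian jitter at the
localization precision (15 nm) — a minimal over-counting model with no
photophysics, PSF or drift; the walks reproduce scale and anisotropy,
not the biology of filament growth. Condition comparisons in the tests
use 5 replicate fields per condition: with ~2× median-Rg effects and
between-field coefficients of variation around 0.2–0.3, five replicates
give the Student t-test comfortable power at α = 0.01, which three do
not reliably provide.

*EC tables*: candidate residue pairs are binned by the classifier's own
geometric criterion evaluated on exact coordinates, then sampled per
category with scores uniform in (0.55, 0.95), so recovery is expected to
be perfect by construction — the test is of the pipeline's bookkeeping,
not of a noisy inference.

*Quench traces*: three phases (180 s baseline, 500 s after dithionite,
60 s after Triton) with exponential transitions (τ = 30 s and 5 s) and
optional Gaussian noise as a fraction of the initial level; the planted
permeability is the formula applied to the noiseless levels.

## Problem sizes and runtime

The default test and analysis runs use 20–45-subunit filaments of a
103-residue Cα protomer, 5-subunit assemblies for pair classification,
localization fields of 20×20 µm with a few thousand points, and traces
sampled at 1 Hz — sizes chosen so every stage's statistics are stable
while the whole suite completes in seconds.

## Known limitations

- No density maps, model refinement, energetics or clash minimisation
  beyond the hard-sphere check; the ring and double-filament models are
  geometric constructions.
- Face assignment is a single planar cut; a filament with a twisted or
  patchy hydrophobic stripe would need a helical boundary model.
- EC inference itself (alignments, coupling scores) is out of scope;
  only its output table is consumed.
- Localization fitting, drift correction and the spatial-inhomogeneity
  statistic itself are upstream of this package; only their outputs are
  processed.
- Passing tests on the synthetic generators demonstrate correctness of
  the computations and their invariances, not performance on real
  micrographs, alignments or plate data.
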