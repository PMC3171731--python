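# Methods

This note documents the model assumptions, the default parameters and why
they were chosen, what the synthetic data generator does and does not
emulate, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

Binding-site prediction is cast as binary classification of *exposed*
residues: residues whose relative solvent accessibility (rSASA) reaches a
threshold. Buried residues are never scored — they are assumed unable to
participate in an interface without a conformational change, which the
model does not attempt to capture. Interface labels for training come
from bound complexes (heavy-atom inter-chain distance criterion), while
features are computed on isolated chains, mimicking the realistic setting
where the unbound structure is the prediction input and no complex-derived
information leaks into features.

The classifier is a pair of random forests. The first scores residues
from per-residue features and environment descriptors; the second adds
summaries of the first forest's scores over the same neighbourhood. The
rationale is geometric: true interfaces form contiguous surface patches,
so a residue's class is strongly informed by its neighbours' scores, and
feeding those back lets the model suppress isolated false positives and
fill in missed patch members. The second step can only be trained
honestly on first-step scores that are not resubstitution-inflated, so
during fitting the first-step scores for the training rows are produced
by an internal cross-validation split **by structure** (never by
residue): each structure's rows, and therefore also every neighbour of
every row, are scored by a forest that never saw that structure.

## Environment definitions

* **Voronoi (default).** All heavy atoms are tessellated; residues are
  neighbours when their atoms' cells share a facet; contact strengths
  are facet-count fractions, `c_ij = N_ij / N_i`. Facet adjacency is
  computed through the Delaunay triangulation (its exact dual), which
  exposes hull-adjacent facets that a Voronoi ridge enumeration can merge
  away. Surface cells are unbounded, so by default the structure is
  surrounded by a shell of 256 pseudo-solvent sites at 10 Å beyond its
  extent; facets against shell sites are discarded. The shell bounds
  surface cells without inventing residue–residue contacts, at the cost
  of removing a few spurious long-range surface adjacencies; it can be
  disabled, in which case the neighbour relation is exactly Delaunay
  adjacency of the heavy atoms (the configuration verified against the
  brute-force empty-circumsphere oracle). An optional facet distance
  filter (off by default; ~8 Å is reasonable) additionally drops atom-pair
  facets spanning surface clefts.
* **Sphere.** Neighbours within a Euclidean radius (default 15 Å) of the
  residue's heavy-atom centroid (configurable to Cα); uniform weights.
* **Window.** The up-to-8 sequence flanking residues (default length 9),
  truncated at termini; uniform weights. Window environments may include
  buried residues, so residue features are computed for all residues even
  though only exposed ones are classified; score feedback in window mode
  aggregates over the scored (exposed) neighbours with renormalised
  weights.
* **None.** Every residue is isolated; no environment blocks enter the
  design matrix.

The exposed-only restriction applies to the structural modes (Voronoi,
sphere) *after* facet counting — buried atoms still shape the
tessellation — but not to the window, which is sequence-defined.

## Feature groups

The per-feature inventory is a registry of pluggable providers; the
defaults are chosen to be fully self-contained (no external servers,
databases, or binaries):

* **Structure (`s`).** rSASA from an in-package Shrake–Rupley
  implementation over heavy atoms (Fibonacci sphere sampling, probe
  1.4 Å, 144 points by default), normalised by the residue type's
  theoretical Gly-X-Gly maximum (Tien et al. 2013) and clipped to [0, 1];
  a 3-state secondary-structure one-hot from an internal
  hydrogen-bond-pattern assignment (DSSP-style electrostatic model with a
  rebuilt amide hydrogen; i→i+4 bonds mark helices, non-local bonds mark
  strands, helix wins; a deliberate simplification of full DSSP state
  logic); and the 20-way residue-type one-hot.
* **Energy (`e`).** A desolvation proxy (Kyte–Doolittle hydropathy ×
  rSASA) and a residue contact pseudo-energy: the sum over residues
  within 8 Å (centroid distance) of an embedded additive pair potential,
  `e(l,k) = -(kd_l + kd_k)/9`, i.e. hydrophobic–hydrophobic contacts are
  favourable. This additive form is the standard first-order
  approximation to knowledge-based contact potentials and keeps the table
  self-derived rather than copied.
* **Conservation (`c`).** Per-column Shannon entropy (bits) and relative
  entropy versus Robinson–Robinson background frequencies, from an
  aligned FASTA whose first row must equal the chain sequence after gap
  removal (columns map to residues by ungapped index; any mismatch is an
  error, never silently realigned). Without an MSA the group is disabled
  — absent columns, never zero-imputed.
* **B-factor (`b`).** Mean heavy-atom B-factor, z-scored within each
  chain (zero-variance chains give zeros).

The EDM is flattened to its upper triangle including the diagonal (210
columns); the symmetric lower half would duplicate columns. Residues with
no neighbours get zero environment blocks plus an explicit isolated
indicator, and their environmental score and Mms fall back to their own
score — this keeps every exposed residue in the prediction universe
without NaN rows.

## Defaults and tunable parameters

| Parameter | Default | Notes |
|---|---|---|
| exposure threshold (rSASA) | 0.05 | defines the prediction universe; configurable |
| interface cutoff | 5 Å | heavy-atom inter-chain distance for labels; configurable |
| SASA probe / points | 1.4 Å / 144 | see numerical notes below |
| sphere radius | 15 Å | the radius at which sphere environments perform best in the 5–20 Å range |
| window length | 9 | classic sliding-window size |
| forest size | 500 trees | √p feature subsampling, unlimited depth |
| class weighting | balanced subsample | exposed non-interface residues heavily outnumber interface ones |
| inner OOF folds | 5 | capped at the number of training structures |
| decision threshold | 0.5 | for R/P/MCC/Q2/F1 reporting; AUC is threshold-free |

Every forest is seeded from `random_state` (mandatory for reproducible
training); the two steps use consecutive derived seeds so their trees are
decorrelated. Model bundles serialise the fitted forests together with
the feature registry, environment configuration and seed; prediction
refuses structurally incompatible registries rather than reordering
columns.

## Synthetic data: what it emulates, and what it does not

`vorsite.synthetic` builds two-chain complexes from ideal α-helix
backbones (N/CA/C/O plus one Cβ-like pseudo-atom; rise 1.5 Å, 100°/turn)
or cubic-lattice pseudo-residues. The chains are docked by a
deterministic bisection on the separation of their axes until the
requested fraction of residues (default 0.25) lies within 5 Å of the
partner; the construction is exactly two-fold symmetric, so both chains
bury the same number of residues. Each fixture gets a seeded random
azimuthal phase and a small coordinate jitter (σ = 0.15 Å), applied to
the shared template so the symmetry is preserved; without them all
fixtures would share one geometry and a learner could memorise the
residue-index-to-label pattern across structures, corrupting null
experiments. Coordinates are quantised to PDB precision before labelling
so emitted labels agree exactly with labels recomputed from the file.

The planted class signal flows through the observable inputs that real
interfaces bias: interface residues draw their types from an
exponentially tilted distribution (hydrophobic tilt for the energy group,
aromatic tilt for the structure group's type one-hot; defaults 1.5 tilt
units each), their B-factors are shifted down (default 8 Å²,
i.e. interface residues are better ordered), and their MSA columns mutate
at a reduced rate (default 80% reduction from the 0.45 background rate
over 50 rows, i.e. interfaces are conserved). With all strengths zero the
emitted data carry no label information — the null condition.

What passing tests on these fixtures show: that the geometry machinery,
descriptor algebra, training protocol and evaluation are correct, that
genuine multi-group signal is recovered and absent signal is not
hallucinated, and that score feedback and Voronoi environments do not
hurt. What they do not show: performance on real proteins. Real
interfaces couple geometry and chemistry (shape complementarity,
rotamers, realistic SASA distributions, alignment phylogeny) in ways the
generator deliberately does not model, and the planted effect sizes are
not calibrated to any empirical dataset.

## Numerical choices

* **SASA sampling.** Fibonacci sphere sampling is deterministic but
  converges slowly on residues with fragmented accessible surface:
  against a 3840-point reference, per-residue error is within ~7% at the
  144-point default and ~2% at 960 points. The default favours speed —
  a few percent of rSASA noise is immaterial to the forests — and the
  point count is a parameter wherever accuracy matters.
* **Altloc resolution** keeps the highest-occupancy conformer, ties
  broken by altloc identifier; only the first model of multi-model files
  is read (or an error, by policy).
* **Degenerate geometry** (coplanar point sets without the solvent
  shell) raises a geometry error naming the structure rather than
  producing a partial tessellation.
* **Ties and zero marginals.** MCC is defined as 0 when any confusion
  marginal is 0; precision is reported as 0 with an explicit
  `precision_defined=False` flag when nothing is predicted positive. AUC
  uses the tie-midrank convention (constant scores give 0.5). Displayed
  metrics are truncated — not rounded — to two decimals; full precision
  is kept internally.
* **Bootstrap AUC comparison** resamples residues with replacement
  within each class (both classes therefore survive every replicate),
  recomputes both AUCs on the shared resample, and reports a two-sided
  p-value (floored at 1/n_boot) and a 95% percentile interval; 2000
  replicates by default, fully determined by the seed.
* **Fold assignment** everywhere is by structure, and the evaluation
  helpers additionally accept group ids so that the two chains of one
  complex — whose interfaces mirror each other — never straddle a
  train/test split.

## Problem sizes in the harness

The test suite and the acceptance script run on desk-scale instances
chosen as the package's own defaults for quick, single-CPU verification:
5–6 complexes of 30 residues per chain (two chains each), forests of
80–100 trees with 3 inner folds, 10 repeats for null experiments and 5
for configuration comparisons, and 30–60-point clouds for the geometric
oracles. The library defaults (500 trees, 5 folds) remain what a real
training run would use.

## Known limitations

* No mmCIF input, biological-assembly reconstruction, hydrogen placement
  or NMR ensemble handling; single-model PDB only.
* The secondary-structure assignment is a simplified two-pattern
  classifier, not full DSSP; an external DSSP could be slotted in as an
  alternative provider.
* The contact pseudo-energy is a hydrophobicity-derived surrogate, not a
  fitted statistical potential.
* Scores are not calibrated probabilities; threshold-based metrics use
  0.5 unless configured otherwise.
* The Mms summary implements one reasonable reading of the weighted
  max/min score statistics (weighted max, weighted min, raw max, raw
  min); it is isolated in a single function so an alternative definition
  can be swapped without touching the rest of the pipeline.
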