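# Methods

`protqa` estimates the accuracy of a single protein structure model,
per residue and globally, without access to the experimental structure.
It combines three kinds of evidence — knowledge-based statistical
potentials, agreement with sequence-based predictors, and distance
constraints derived from homologous experimental structures — and fuses
them with small feed-forward neural networks that tolerate missing
inputs.  This note documents the model, its parameters and the design
choices that were genuinely open.

## Target value: lDDT

The quantity being predicted is the local Distance Difference Test.
For every heavy-atom pair of the reference structure within the
inclusion radius (15 Å, atoms in different residues) and every deviation
threshold (0.5, 1, 2, 4 Å), one check is counted; it is conserved when
the model reproduces the reference distance within the threshold.  A
residue's score pools the checks touching its atoms; the global score
pools all checks (deliberately *not* the mean of per-residue values, so
that residues with few contacts do not dominate and missing residues are
penalised coherently).  Atoms absent from the model fail their checks;
atoms present only in the model are ignored.  Contacts are defined on
reference distances only.  Stereochemistry-aware extensions of lDDT are
out of scope.  Residues with lDDT strictly above 0.6 are classified
"correctly modelled" in all ROC analyses.

## Statistical potentials

Six inverse-Boltzmann terms, each trained by counting observations in a
corpus of structures and comparing type-conditional with type-pooled
distributions:

e(bin | type) = −log[(f_obs(bin|type) + σ·f_ref(bin)) / ((1+σ)·f_ref(bin))]

with pseudo-count weight σ = 0.02 (Sippl-style sparse-data handling);
types never observed fall back to the reference (zero energy).  The
terms and their binning:

| term | descriptor | bins |
|---|---|---|
| all_atom | heavy-atom pair distance, 167 atom types | 0.5 Å on [0, 20) |
| cb_interaction | Cβ–Cβ distance (Cβ inferred from backbone for Gly) | 0.5 Å on [0, 20) |
| reduced | Cα distance × angle between backbone direction vectors | 1 Å on [0, 15) × 30° |
| packing | neighbour count per atom within 10 Å | counts 0–32, clamped |
| cb_packing | neighbour count over Cβ representatives | counts 0–32, clamped |
| torsion | central φ/ψ of a residue triplet | 30°×30°, 5³ triplet groups |

Interaction terms use a sequence-separation threshold |i−j| ≥ 5,
suppressing local secondary-structure signal (helical i,i+4 contacts are
excluded).  The reduced-representation direction vector is the
normalised bisector of the unit vectors Cα→N reversed and Cα→C reversed
(i.e. u ∝ (Cα−N)/|…| + (Cα−C)/|…|); its pair geometry is binned on
(distance, inter-vector angle).  The torsion grouping assigns each
position to one of five classes — glycine, proline, pre-proline,
hydrophobic (AVLIMFWC), polar — and keys the φ/ψ table by the triplet of
classes.  All per-residue outputs are sign-flipped so that higher is
better, matching the orientation of every other feature.

## Local agreement features

* **Secondary structure** is assigned internally with a DSSP-equivalent
  algorithm: amide hydrogens are reconstructed from the preceding
  carbonyl, hydrogen bonds use the Kabsch–Sander electrostatic energy
  with the −0.5 kcal/mol cutoff, and the 8 states G/H/I/E/B/T/S/C follow
  the turn/bridge patterns (β-bulge refinements are not reproduced).
  The agreement feature is a trained log-odds score
  S(d, p, c) = log[p(d,p,c)/(p(d)·p(p,c))] between the observed state d
  and the predicted 3-state p at confidence c ∈ 0–9, with Laplace
  pseudo-count 1.
* **Solvent accessibility** is Shrake–Rupley SASA (probe 1.4 Å, via
  biotite), scaled by per-residue theoretical maxima (Tien et al.) to a
  relative accessibility in [0, 1].  The two-state agreement feature
  compares the burial class (buried iff relative accessibility < 0.25,
  the boundary counting as exposed) with an ACCpro-style prediction.
* **Clash score**: hard-sphere overlap with radii C 1.6, N 1.3, O 1.3,
  S 1.7 Å; penalty 0 above R_ij, 10 below 0.8254·R_ij, linear between,
  summed per residue and sign-flipped.  Pairs between sequence-adjacent
  residues are excluded — this covers the covalent peptide bond and its
  1-3 neighbours with a single uniform rule.
* **N**: number of other residues with Cα within 15 Å.

All per-residue traces except N (and the constraint features below)
undergo spherical smoothing: smoothed_i = Σ_j w_ij v_j / Σ_j w_ij with
w_ij = exp(−d_ij²/2σ²) over valid residues j (σ = 5 Å, Cα distances, the
centre residue included with weight 1).  Smoothing interpolates values
spatially, but a residue whose raw value is undefined keeps an *invalid*
feature: validity drives network dispatch and must not be manufactured
by interpolation.

## Distance constraints

Homologous templates aligned to the target (A3M convention: lowercase =
insertion, skipped) contribute Gaussian constraints for every template
Cα–Cα distance μ_ijk < 15 Å:

    g_ijk(d) = exp[−½ (d − μ_ijk)²]        (unit width, as printed)
    h_ijc(d) = (1/n_ijc) Σ_{k∈c} g_ijk(d)
    s_ij(d)  = Σ_c w_c h_ijc(d),  w_c ∝ exp(γ·SS_c),  γ = 70

Weights are normalised over the clusters actually covering the pair.
Templates are clustered by average-linkage agglomeration on
1 − pairwise sequence similarity, cut at similarity 0.8.  The
normalised similarity of an aligned column is the BLOSUM62 score
affinely rescaled so that the matrix minimum maps to 0 and the
self-score (mean of the two diagonal entries) to 1; sequence-level
similarity is the mean over aligned columns.  This keeps SS_c in [0, 1]
so that exp(γ·SS_c) behaves as intended.  The per-residue score averages
s_ij(d_ij) over all partners j with model Cα within 15 Å that carry
constraints; no sequence-separation filter is applied here.  Seven
reliability features accompany the score: average number of covering
clusters, average max-over-clusters similarity and identity, average
variance of the pooled constraint distances, the number of evaluated
pairs, the total number of pairs within 15 Å, and their ratio.  The
variance feature pools all observed distances across the covering
clusters of a pair, the closest literal reading of "variance of all
observed distances in any of the underlying clusters".

## Neural-network fusion

Each residue yields up to 47 features: 11 single-model values (6
potentials, 2 agreement terms, relative accessibility, clash, N), 8
constraint features, 8 full-model averages of the potential/agreement
terms and a 20-dimensional amino-acid one-hot.  Four blocks can be
missing — torsion (chain termini), SS-agreement (no secondary-structure
prediction), ACC-agreement (no accessibility prediction) and the
constraint block (no templates) — giving 2⁴ = 16 feature groups.  The
full-model torsion average is treated as mandatory: it exists whenever
the chain has ≥ 3 residues, even at termini.  A scorer holds one network
per group, topology [n, 20, 20, 20, 1] with ReLU hidden layers and a
linear output clamped to [0, 1] (clamping keeps the printed topology
literal; a sigmoid would change it).  Training: z-scored inputs,
mean-squared-error loss, RMSprop (lr 10⁻³, decay 0.9), 100 epochs,
batch 400, He-uniform initialisation, all driven by a single seed.
Rows whose validity is a superset of a group's blocks participate in
that group's training with the group's feature subset; groups with
fewer than 400 usable rows are not trained and dispatch at prediction
time to the richest trained subset group.  Cross-validation always
splits on modelling targets, never on models or residues, and a blend
utility mixes two datasets row-wise for mixed-corpus training.  The
wider hyperparameter grid (loss absolute/mse, adam/rmsprop, epochs,
batch sizes, alternative topologies) is representable in the estimator
parameters; the default is the single configuration above.

## Global score and expected error

The global score is the mean of valid per-residue predictions.  Because
the method scores a model "as is" while lDDT penalises missing
residues, a coverage pre-factor (fraction of target-sequence residues
present in the model, matched in order) gives the normalised variant.
The expected error at model length l is the RMS of absolute
global-score errors over reference models with length within l ± 40;
an empty window widens symmetrically until ≥ 30 points are covered.
The reference pairs come from the package's own cross-validation
predictions on synthetic data.

## Evaluation

ROC AUC is computed with the rank statistic (tie-averaged); the pooled
overall AUC measures absolute calibration, the mean per-model AUC
within-model discrimination.  Models whose residues all fall in one
class — or whose predictions are constant, as with the naive baseline
that broadcasts a model-level score to every residue — define no
ranking and are excluded from the per-model mean.  The naive baseline
demonstrates that between-model quality variation alone inflates the
pooled AUC, which is why both views are reported.

## Synthetic data

The generator emulates every input the pipeline consumes.  Natives are
built from ideal backbone internal coordinates (N–Cα 1.458, Cα–C 1.525,
C–N 1.329 Å; angles 111.2/116.2/121.7°; ω = 180°) with torsions from
the layout: helix (−57, −47) ± 3°, strand (−139, 135) ± 3°, coil drawn
from five Ramachandran basins ± 15°.  Layouts interleave helix/strand
segments with coil linkers.  Chains are rejection-resampled until no
heavy-atom pair at sequence separation ≥ 2 comes within its hard-sphere
contact distance (R_ij + 0.05 Å), so every native has clash score
exactly zero; a fixed 3.5 Å blanket cutoff would be unusable here, as
genuine helical O(i)–N(i+4) hydrogen bonds sit near 3.1 Å.  Models are
copies with i.i.d. Gaussian coordinate noise (and optional segment
deletions for partial coverage); templates are noise-perturbed,
truncated, point-mutated copies written as PDB files with a consistent
A3M; predictor files derive from the native's own secondary structure
and burial, corrupted at a configurable error rate with confidence
anticorrelated with corruption.

The standard study corpus is 30 targets (length 35–55, seed 7), 8
models each with noise amplitudes spanning 0–3 Å, 4 templates per
target (noise 0.3–1.5 Å, coverage 0.7–1.0, identity 0.35–0.9),
predictor error rate 0.15.  Statistical potentials train on 150
additional clash-free natives plus the corpus natives.  These sizes
keep the full pipeline — generation, training, cross-validation —
within a few minutes on one CPU while covering all 16 feature groups.

What the synthetic data does *not* emulate: side chains beyond Cβ,
realistic decoy energetics (noise is isotropic, not physically
plausible), template phylogenetics, or the error structure of real
secondary-structure predictors.  Passing tests therefore demonstrate
the correctness of the implemented equations and the trainability of
the fusion network, not benchmark-level performance on real models.

## Numerical choices and degenerate inputs

* All distance cutoffs are strict `<` comparisons (a template distance
  of exactly 15 Å contributes no constraint).
* Cluster weights use a max-shifted exponential (stable softmax),
  mathematically identical to the normalised exp(γ·SS_c).
* Residues with no contributing observations for a term are invalid
  (NaN), not zero; mandatory-feature gaps are imputed with the model
  average of that feature so the row stays dispatchable.
* A single-residue chain gets secondary-structure state C, a computed
  accessibility, and invalid torsion/interaction features.
* Ties in template clustering are broken by sorting templates by id
  before clustering; training counts are integers, so table training is
  exactly order-independent.
* Alternate locations resolve to the highest-occupancy copy at parse
  time; hydrogens and heteroatoms are discarded; only one chain is
  assessed per run.

## Known limitations

* The DSSP-equivalent assignment omits β-bulge handling; isolated
  strands (no sheet partner) are assigned C/B rather than E, which is
  self-consistent between the generator and the scorer but differs
  from full DSSP on real sheets.
* The 167-type atom alphabet is only sparsely populated by the
  synthetic corpus (backbone + Cβ); unseen types score zero by the
  reference fallback.  On real structures the full alphabet trains.
* The coverage pre-factor uses greedy in-order sequence matching, which
  can overcount coverage for highly repetitive sequences.
* Trained weights are corpus-specific; no pre-trained parameters ship
  with the package.
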