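# protqa

Per-residue and global quality estimation for protein structure models.

Given a single 3D model (PDB format), `protqa` predicts how accurate
each residue is — on the scale of the local Distance Difference Test
(lDDT, in [0, 1]) — without access to the experimental structure.  It
is aimed at structural biologists and method developers who need to
decide whether a homology model is good enough for its intended use, or
which parts of it to trust.

## The score

Three kinds of evidence are combined per residue:

1. **Statistical potentials of mean force** — six inverse-Boltzmann
   terms (all-atom and Cβ pairwise interactions, a reduced
   Cα + direction representation, two packing terms, a φ/ψ torsion
   term) trained from a structure corpus as
   `e(bin|type) = −log[(f_obs + σ f_ref) / ((1+σ) f_ref)]`.
2. **Agreement terms** — consistency of the model's DSSP-style
   secondary structure and burial with sequence-based predictions
   (PSIPRED / ACCpro style files), a clash score and local packing
   density.
3. **Distance constraints (DisCo)** — homologous experimental
   structures are mapped onto the target sequence; every template
   Cα–Cα distance μ below 15 Å becomes a Gaussian constraint
   `g(d) = exp[−½(d−μ)²]`.  Constraints are grouped by sequence-
   similarity clusters, cluster scoring functions `h_c` are averaged
   member constraints, and the pairwise score
   `s_ij(d) = Σ_c w_c h_c(d)` weighs clusters by
   `w_c ∝ exp(γ·SS_c)` (γ = 70, SS_c = mean normalised similarity to
   the target).  A residue's DisCo score averages `s_ij` over its
   neighbours within 15 Å.

A set of 16 small feed-forward networks (topology [n, 20, 20, 20, 1],
one per combination of available feature blocks) maps the up-to-47
features of each residue to a predicted lDDT; missing inputs (no
templates found, chain termini, no predictor files) select the matching
network instead of breaking the prediction.  The global score is the
mean of the per-residue predictions, optionally multiplied by target
coverage, with a length-dependent expected error.

## Worked example

Everything below runs on synthetic data generated by the package
itself — no downloads.

```bash
# 1. generate a small fixture tree (natives, models, templates,
#    alignments, predictor files)
protqa make-fixtures --out fixtures --seed 3 --targets 2

# 2. train all components (potential tables, agreement table, networks)
protqa train-nn --fixtures fixtures --out checkpoints --seed 3 \
    --corpus-size 20

# 3. score one model end to end
protqa score \
    --model fixtures/models/target_1742692732/target_1742692732_m4.pdb \
    --checkpoints checkpoints \
    --alignments fixtures/alignments/target_1742692732.a3m \
    --template-dir fixtures/templates/target_1742692732 \
    --ss2 fixtures/predictions/target_1742692732.ss2 \
    --acc fixtures/predictions/target_1742692732.acc \
    --reference fixtures/natives/target_1742692732.pdb \
    --out scored
```

The last command prints

```
global score: 0.4665 (coverage 1.00)
```

and writes `scored.json`, `scored.tsv` (per-residue table) and
`scored.pdb` (predictions ×100 in the B-factor column, 99.99 for
invalid residues).  Here the model was the native perturbed with 1.7 Å
coordinate noise; the true per-residue lDDT against the reference,
included in `scored.json` because `--reference` was given, averages
0.49 — the predicted 0.47 tracks it from evidence alone.  Omitting
`--alignments`/`--template-dir` re-scores the model in single-model
mode (`"mode": "QMEAN-like"` in the JSON): predictions remain for every
residue, computed by the constraint-free network.

The same machinery is available as a library:

```python
from protqa import SyntheticScenario, compute_lddt
from protqa.synth import make_native, make_models

native = make_native(SyntheticScenario(seed=7, length=45))
model = make_models(native, [1.0], seed=1)[0]
print(compute_lddt(model, native).global_score)   # 0.673
```

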