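# protfit

Supervised prediction of quantitative protein mutation effects from
**ensemble sequence representations**: per-residue "global" embeddings
from multiple protein sequence models, fused with per-mutant "local"
evolutionary-coupling features resolved from CCMPred output, mapped to
deep-mutational-scanning (DMS) fitness by ridge regression and evaluated
by Spearman rank correlation ρ.

It is aimed at protein-engineering and variant-effect researchers who
have, per protein: a wild-type sequence, a ProteinGym-style substitution
table (`A1P:G2K`-notation mutants with scores), CCMPred couplings from a
homolog MSA, and optionally precomputed per-residue embedding matrices
from external language models.

## The model

For a mutant with residues x₁…x_L:

- each embedder contributes an L×D global matrix, pooled (default: mean
  over positions) to a fixed-length block;
- the coupling model contributes the local vector
  `values[i] = Σ_{j≠i} e_ij(x_i, x_j)`, where e_ij(a,b) are the
  Markov-random-field pair potentials estimated by CCMPred;
- blocks are concatenated (or projected and summed) into one
  representation per mutant, and ridge regression
  `(Xᶜ′Xᶜ + αI) w = Xᶜ′yᶜ` maps it to fitness, with α chosen by inner
  cross-validated Spearman.

One model is fitted per protein.  An ablation harness re-runs the
identical cross-validation on feature-block subsets (the default grid is
six scenarios: each global block alone or ensembled, with and without
the local block) to attribute predictive gain.

Because real studies need large language-model inference and CCMPred
runs, the package includes a first-class synthetic-study generator with
known ground truth (random wild types, unique mutants, sparse coupling
tensors, block-structured embeddings, and fitness as a noisy weighted
sum of chosen feature blocks plus the coupling term); see
`docs/methods.md`.

## Worked example

```python
from protfit import GeneratorConfig, MutationEffectModel
from protfit.synthetic import gen_dataset

study = gen_dataset(GeneratorConfig(seed=0))   # L=120, 500 mutants
model = MutationEffectModel.from_dataset(
    study.dataset, study.embedders, study.coupling_model
)
res = model.fit(seed=0)
print(res.summary())
```

```
Mutation Effect Ridge Regression Results
==========================================================
Dataset:                    synthetic_L120_n500_seed0
No. observations:           500
Representation width:       184
Feature blocks:             plm_a, plm_b, local
Fusion strategy:            concat
Alpha (refit):              31.6228
CV protocol:                kfold (seed 0)
Spearman rho (CV mean):     0.9244
Spearman rho (CV sd):       0.0114
In-sample Spearman rho:     0.9669
----------------------------------------------------------
Per-fold held-out Spearman rho:
  fold 0: rho=+0.9209  alpha=31.6228  n_train=400  n_test=100
  ...
```

The representation is 184 columns (two 32-dim pooled embedding blocks
plus the 120-dim local block); held-out ρ ≈ 0.92 is what the study's
noise level (noise_sd = 0.3 of the signal sd) permits.  Ablation on the
same folds attributes the gain:

```python
table, _ = model.ablate(seed=0)
print(table[["subset", "mean_rho"]].to_string(index=False))
```

```
           subset  mean_rho
            plm_a  0.554544
            plm_b  0.546376
      plm_a+plm_b  0.787879
      plm_a+local  0.723068
      plm_b+local  0.675238
plm_a+plm_b+local  0.924428
```

Ensembling the two complementary global blocks beats either alone, and
adding the local block helps further — the qualitative behaviour the
method is built around.

The same workflow runs from the shell on study bundles
(`protfit simulate / featurize / train / evaluate / ablate`; see
`protfit --help`).

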