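# Methods

## The modeling problem

A deep mutational scan (DMS) measures a quantitative fitness score for
hundreds to thousands of substitution variants of one wild-type protein.
The supervised task is, per protein: given a variant's amino-acid
sequence, predict its score well enough to *rank* variants correctly —
protein engineering cares about which mutants are better, not about the
assay's absolute units.  The evaluation metric throughout is therefore
Spearman rank correlation ρ between predicted and measured scores on
held-out variants.

The package predicts from an **ensemble sequence representation** built
from two kinds of features:

- **Global features.** A per-residue embedder maps a length-L sequence to
  an L×D matrix (one feature row per residue).  In production use these
  matrices come from large pre-trained protein language models run
  elsewhere and loaded from an embedding store; the package itself ships
  deterministic reference embedders (one-hot, D=20; physico-chemical
  properties, D=5) and a synthetic embedder family with controllable
  information content.  Several embedders can be combined, on the premise
  that models trained on different corpora capture complementary
  information.
- **Local features.** A Markov-random-field coupling model estimated from
  a homolog MSA (CCMPred output) provides pairwise potentials
  e_ij(a, b) over 21 residue states (20 amino acids + gap).  For a mutant
  with residues x₁…x_L the local feature vector is the per-position
  coupling sum

      values[i] = Σ_{j≠i} e_ij(x_i, x_j),

  a length-L, mutant-specific summary of how well each residue's actual
  identity fits its evolutionary context.  The full pairwise profile
  [e_ij(x_i,x_j)]_{ij} (length L², flattened) is available as an
  alternative behind `local_mode="pairwise"`.  When only CCMPred's L×L
  summary matrix is available, the fallback row-sum features are
  sequence-independent and a warning says that mutant specificity is
  lost.

Each global L×D matrix is pooled to a fixed-length vector per mutant —
default: the positional mean, which is robust across protein lengths;
row-major flattening and mutated-position extraction are provided for
ablation.  Pooled global blocks and the local block are then fused.  Two
fusion strategies exist because both appear plausible readings of how
such ensembles are assembled:

- `concat` (default): column-wise concatenation with recorded block
  spans, which is what the ablation harness needs to slice blocks back
  out; and
- `project_sum`: each block is multiplied by a seeded random
  orthonormal-column projection to a common dimension and the projections
  are summed.  A random projection (rather than PCA) keeps the mapping
  deterministic, cheap and fit-free; PCA would entangle the mapping with
  the training rows.

The regressor is ridge regression on the fused representation, solved on
column-centered data via the normal equations (Xᶜ′Xᶜ + αI)w = Xᶜ′yᶜ;
α = 0 falls back to the minimum-norm least-squares solution, so ordinary
linear regression is the α = 0 special case.  One model is fitted per
protein; no cross-protein transfer is attempted.

## Evaluation protocol

Default: 5-fold cross-validation over mutants (seeded, shuffled), with an
80/20 holdout available.  Within each outer training fold:

1. columns are z-scored on training rows (constant columns map to zero);
2. α is selected from a 13-point log grid 10⁻³…10³ by an inner seeded
   k-fold CV maximizing mean validation Spearman (ties → smallest α);
3. the model is fitted at α* and scored by Spearman on the held-out rows.

Held-out rows never influence scaling, α selection or fitting; a test
exists that poisons holdout rows and checks the training-side results are
bit-identical.  Selection uses Spearman rather than MSE because it is the
deployment metric.  A fold whose predictions are constant has undefined
rank correlation; such folds are scored ρ = 0 (with a warning), since a
constant predictor carries no ranking information — this also makes a
completely uninformative feature set evaluate to ρ ≈ 0 rather than
erroring.  `spearman()` itself returns NaN for constant inputs.

The ablation harness re-runs the identical protocol (same seed, hence
identical folds) on subsets of feature blocks and reports per-fold paired
differences against the full configuration.  The default grid for two
global blocks g₁, g₂ and the local block is the six scenarios
{g₁, g₂, g₁+g₂} × {with, without local}.

## Synthetic studies

Real inputs (ProteinGym-style DMS tables, CCMPred runs on deep MSAs,
language-model embeddings) cannot be regenerated at desk scale, so the
generator emulates each of them with known ground truth:

- **Wild type / mutants**: uniform random sequence; unique substitution
  mutants with order uniform on 1..max_order, positions sampled without
  replacement, 1-based ProteinGym notation.
- **Couplings**: each position pair is active with probability
  `coupling_sparsity`; active pairs get dense 21×21 Gaussian blocks,
  mirrored so e_ij(a,b) = e_ji(b,a).  Bundles write both the raw
  potential dialect and a summary matrix (Frobenius norm of each 20×20
  amino-acid block, gap excluded — a standard coupling-strength summary).
- **Embedders**: frozen Gaussian lookup tables per (position, residue).
  A declared fraction of dimensions is informative (depends on residue
  identity); the rest depend on position only and carry no mutant
  information.  Two embedders with different seeds span uncorrelated
  informative subspaces, emulating complementary language models.
- **Fitness**: y = Σ_b w_b·(block signal) + w_local·(coupling sum) + ε,
  where each component is z-scored across mutants before weighting (so
  `signal_split` weights are comparable), w_b are frozen standard-normal
  draws stored in the ground truth, and ε ~ N(0, noise_sd·sd(signal)).
  Parameterizing noise relative to the signal sd makes the expected ρ
  scale-free.

Defaults are pinned to the low end of the envelope of published
substitution-DMS collections (lengths 86–881 aa, 298–6370 mutants per
dataset) so a full study runs in seconds on one CPU: L=120, n=500,
max_order=2, two global blocks of D=32 with 50% informative dimensions,
coupling sparsity 0.05, noise_sd=0.3, and signal split 35/35/30 across
the two global blocks and the local term.  The 30% local share makes the
local-feature ablation meaningful by construction.

Everything derives deterministically from the config seed (child stages
use fixed seed offsets); on-disk bundles are bitwise-reproducible
(HDF5 written without timestamps) and carry a sha256 manifest.

**What passing these simulations does and does not show.**  The generator
is linear-Gaussian in its pooled features and its epistasis is exactly
the pairwise coupling term, so ridge is well-specified by construction;
synthetic ρ values (≈0.92 at default noise) say nothing about absolute
accuracy on real proteins, where embeddings are not linearly sufficient
and assay noise is not Gaussian.  What the simulations do establish is
that the machinery is correct and leak-free: exact agreement of the core
numerics with independent oracles, recovery of a recoverable signal,
a flat permutation null, and the two qualitative ablation effects
(ensembling complementary blocks helps; adding an informative local
block helps on identical folds).

## Numerical and design choices

- Mutation positions are 1-based externally, 0-based internally;
  conversion is confined to parsers.  Non-canonical residues are rejected
  in mutation strings, tolerated in wild-type/MSA sequences with
  embedder-specific unknown handling (one-hot → zero row; physchem →
  column means; couplings → gap state), all logged.
- The CCMPred residue-state order "ARNDCQEGHILKMFPSTWYV-" is the fixed
  default alphabet; raw-file pair headers are 0-based with a flag for
  1-based dialects.  An asymmetric summary matrix is symmetrized as
  (C+C′)/2 with a warning.
- Local-feature resolution accumulates the per-position sum left-to-right
  so results are bit-identical to a naive double loop (numpy's pairwise
  summation differs at 1 ulp).
- Domain-level coupling models (MSA covering a sub-span) are supported
  via an integer offset; mutants entirely outside the covered span get
  zero local features with a logged count.
- `project_sum` fixes projection signs via the QR R-diagonal so the
  projection is unique across LAPACK implementations; each block's
  projection is seeded from (seed, crc32(block name)), making fusion
  order-invariant and stable under renaming-free refactors.
- Alpha-selection folds with fewer than 2 validation points are skipped
  with a warning; if all folds are skipped the selection errors out.

## Limitations

- Substitutions only; indel variants are out of scope.
- The package does not run CCMPred or any language model; it consumes
  their outputs (or synthetic stand-ins).
- The summary-matrix local-feature fallback is sequence-independent and
  therefore useless for ranking mutants that share a wild type; it exists
  so summary-only CCMPred output still flows through the pipeline.
- Spearman selection inside CV is noisy for very small datasets
  (n below a few hundred); the α grid's endpoints are then chosen often,
  which is visible in the per-fold α diagnostics.
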