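# Methods

## Problem setting

Synergy screens label a *triplet* — two drugs tested together in a cancer
cell line — with a real-valued synergy score (e.g. S_mean or Loewe)
measuring the deviation of the combined effect from an additivity
reference. Regression models for these scores are routinely evaluated
with random triplet splits, which leak drug pairs, drugs, and cell lines
between training and test and can inflate apparent performance. They are
also rarely subjected to ablations that ask *where* the predictive signal
comes from. This package implements the evaluation loop needed to ask
those questions rigorously: leakage-controlled splits with verifiable
contracts, a configurable encoder–decoder regression stack, and three
ablation instruments, all exercisable hermetically on synthetic data with
known signal structure.

## Model stack

A model is declared as *feature (preprocessor | encoder)* plus an MLP
decoder. Drug and cell-line feature vectors (one-hot identifiers,
MACCS/Morgan fingerprints, binary target profiles, gene expression,
precomputed embeddings) feed the decoder directly; two learnable encoders
handle structured inputs:

- **GCN** over the heavy-atom molecular graph, layers
  `H' = σ(D̃^{-1/2} Ã D̃^{-1/2} H W)` with `Ã = A + I` and
  `D̃_ii = Σ_j Ã_ij`, followed by coordinatewise (global max) pooling over
  atoms. Atom features are a standard descriptor (element, degree, formal
  charge, aromaticity, hydrogen count, ring flag); the featurizer is
  pluggable.
- **Transformer** over tokenized SMILES, `[CLS] + tokens + [SEP]`, with
  sinusoidal or learnable positional encodings (a configuration choice);
  the final-layer `[CLS]` representation is the drug embedding. A
  character-level vocabulary ships in-repo; a byte-pair subword vocabulary
  can be supplied as a file, with greedy longest-match tokenization and a
  character-split fallback.

A feature uses a preprocessor or an encoder, never both: preprocessors
emit plain vectors, encoders consume structured payloads. The decoder
concatenates `[emb_a ; emb_b ; emb_cell]` and regresses the score under
mean squared error. Because concatenation is order-sensitive and nothing
in the problem distinguishes drug A from drug B, training by default
augments each triplet with both drug orders; a canonical-order-only mode
is available. The checkpoint with the best validation MSE is kept.
Training pulls scores through an access-audited wrapper and asserts on
exit that no test index was ever read.

All learnable components run on a small NumPy reverse-mode autodiff core
(`_nn.py`) with Adam; gradients are pinned by finite-difference tests.
Given a seed, training is fully deterministic.

### Preprocessors

- **Autoencoder**: reconstruction MLP (default hidden width 256 →
  latent) on sparse binary features; the best-reconstruction checkpoint
  defines a pure encode transform.
- **Random walk with restart (RWR)**: a drug's binary target profile,
  normalized to a probability vector, is diffused over the PPI network by
  iterating `p ← c·p0 + (1−c)·W·p` with column-stochastic `W` to a fixed
  point (restart probability default 0.5, a standard mid-range value for
  network propagation; configurable). STRING-style confidence scores are
  binarized at a cutoff (default 900, "highest confidence") before
  normalization; raw-weight propagation is available. Zero-degree nodes
  get a self-loop so restart mass is conserved; the iterate is checked
  against the closed-form solve `p = c(I − (1−c)W)^{-1} p0` in tests.
  Drugs with no target inside the network are omitted and fall out
  downstream via feature-availability filtering.

## Dataset preparation

The cleaning pipeline mirrors the standard preparation of a
combination-screen export: drop mono-therapy rows; map drug names to
compound identifiers, excluding unmapped names and names resolving to
multiple identifiers with different structures (salt forms); collapse
replicates to a consensus mean, discarding groups whose sample standard
deviation (n−1 denominator; threshold 0.1 by default) indicates
replicate disagreement — singleton groups pass, since the filter targets
inconsistency; keep only triplets with full feature coverage; and drop
cell lines carrying less than 5% of the triplets. The coverage filter is
a single pass against the pre-filter total (boundary inclusive), applied
after feature subsetting by default since representation is defined
relative to the data a model sees; both the order and an
iterate-to-fixed-point mode are configurable.

## Splits and leakage contracts

Four strategies: leave-triplet, leave-drug-pair, leave-drug,
leave-cell-line. Sampling is grouped (triplets / unordered pairs / drugs
/ cell lines), with groups shuffled by the seed and assigned greedily to
the partition with the largest remaining deficit (ties favor test, then
validation). Realized fractions therefore deviate from the request by at
most the largest group's share; on very small tables the validation
partition may be empty, and a repair step guarantees train and test are
not. Default fractions 0.7/0.1/0.2. Leave-drug assigns triplets joining
a training drug with a held-out drug to test ("at least one unseen");
strict mode requires both drugs unseen and drops mixed triplets.
Validation obeys the same contract against train as test does; contracts
between validation and test are not enforced. `verify_leakage` re-derives
every contract from the raw triplets, so splits are auditable
independently of how they were built.

## Ablation instruments

- **One-hot baseline**: identifier one-hot for drugs and cell lines with
  the MLP decoder — no biological information.
- **Feature shuffling**: payloads reassigned across entities by a uniform
  random permutation (fixed points allowed, matching uniform selection; a
  derangement mode exists). The payload multiset is conserved; the model
  is retrained on the shuffled assignment.
- **Network randomization** of the per-cell-line signed synergy networks,
  positive and negative edges treated separately:
  - *degree-preserving*: Maslov–Sneppen double-edge swaps (10·|E|
    attempts by default), rejecting self-loops and duplicate pairs —
    including pairs occupied by the other sign, so the result stays
    simple; weights of each sign are reassigned at random.
  - *strength-preserving*: simulated annealing from a degree-preserving
    start, moves = {double-edge swap (both reconnections, weights
    following their first endpoint), weight swap}, energy
    `E = Σ_v (s_orig(v) − s_cur(v))²` per sign. Initial temperature from
    the dispersion of sampled single-move ΔE, geometric cooling (0.9),
    stop on temperature floor or stagnation, followed by a deterministic
    first-improvement sweep over all edge pairs and two restarts on small
    subgraphs. The reported objective trace is the running best and is
    non-increasing. After this rewiring a pair may carry one positive and
    one negative edge (flagged `multi_edge_allowed`); when such a pair is
    folded back into a training table the two weights are summed, since a
    table holds one score per key.
  - *weight permutation*: edges kept, weights permuted within sign.
- Training variants replace only the training partition; validation and
  test triplets and scores are always the originals, and a rewired
  training edge that collides with an evaluation key is dropped rather
  than overwriting it.

## Evaluation protocol

RMSE and Pearson correlation per run; per-model medians and interquartile
ranges over five independent runs. Pairwise comparisons use the
Mann–Whitney U test — exact null distribution for small untied samples
(five runs per model sits squarely in the exact regime), normal
approximation with average ranks and tie-corrected variance otherwise —
with Benjamini–Hochberg step-up adjustment across an explicit comparison
family; families of more than two groups use Kruskal–Wallis.

## Synthetic benchmark

The generator emits every input the framework reads (triplet table,
SMILES, target table, expression matrix, PPI edge list) under three
signal modes:

- `strength_driven`: `score(i,j,c) = a_i^c + a_j^c + ε` with per-cell-line
  propensities `a^c ~ N(0, 10²)` — additive in drug identity, carrying no
  information in any feature. This is the regime in which the only
  learnable structure is each drug's synergy-score distribution (the
  topological shortcut).
- `feature_driven`: additive, bilinear-interaction, and cell-line terms in
  latent drug vectors `x_i` and cell vectors `z_c` (dimension 8), scaled
  4 / 4 / 4 so the pairwise bilinear term dominates the signal variance.
  The latents are embedded into the emitted feature tables by a fixed
  noisy linear map, so features genuinely carry the signal, and the
  interaction term cannot be recovered for unseen pairs by memorizing
  per-drug effects.
- `noise_only`: `score = ε`.

Noise is `ε ~ N(0, 5²)` by default; propensity and noise scales were
chosen once to give score spreads loosely comparable to S_mean-style
synergy values. Defaults: 30 drugs, 5 cell lines, 50% pair density
(~1 090 triplets) — small enough for minute-scale CPU runs, large enough
for stable split and ablation behavior. SMILES come from a shipped
library of 134 real small molecules and are deliberately unrelated to
the planted signal in `strength_driven` mode. A replicate emitter and a
planted-conflict generator (replicate pairs with sample SD above the 0.1
filter threshold) exercise the cleaning pipeline end to end.

What the generator does *not* emulate: dose–response surfaces, real
synergy biology, batch effects across studies, heavy-tailed score
distributions, or chemically meaningful structure–activity coupling.
Passing diagnostics therefore show that the evaluation machinery behaves
as designed — that leakage contracts hold, that shortcut learning is
detectable, that rewiring preserves what it claims — not that any model
would perform comparably on real screens.

## Diagnostic workflows

Three workflows (five seeds each, compact MLP: hidden 64→32, 150
epochs, Adam 3e-3, batch 128) reproduce the qualitative ablation
findings:

1. on feature-driven data, shuffling drug features costs a large test-PCC
   drop, while on strength-driven data it is immaterial (features are
   mere identifiers);
2. on strength-driven data, the one-hot baseline trained on
   strength-preserving rewired networks retains most of its original test
   PCC, while degree-preserving rewiring and weight permutation retain
   less;
3. on strength-driven data, leave-drug test PCC collapses relative to
   leave-drug-pair (unseen drugs have unlearned propensities).

## Numerical choices and limitations

- Strength-annealing tolerance: relative strength error
  `Σ(Δs)²/Σs²` below 1% on 30-node networks under the default budget;
  the greedy refinement sweep ends at a local optimum of the move set.
- RWR convergence: L1 tolerance 1e-10, iteration cap 10 000.
- MACCS keys: the toolkit emits 167 bits with index 0 always unset; the
  166-key vector drops it.
- Ties in the split greedy are broken toward test, then validation, for
  determinism; identifiers are opaque strings ordered lexicographically.
- Backend nondeterminism is absent by construction (pure NumPy), so
  seed-for-seed runs are bit-reproducible.
- The transformer path is sized for correctness, not throughput; at
  paper-scale vocabulary and depth a GPU framework would be the right
  tool.
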