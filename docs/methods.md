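# Methods

`circdrug` predicts circRNA–drug-sensitivity associations from a binary
association matrix **A** (N circRNAs × M drugs), circRNA host-gene sequences
and drug structures. This note records the model, its assumptions, the
numerical choices, and what the synthetic benchmark does and does not show.

## Problem setting

`A[i, j] = 1` records a statistically significant link between circRNA *i*'s
expression and cell-line sensitivity to drug *j*; `0` means *unobserved*, not
*absent*. The task is link prediction on this sparse bipartite graph
(reference curated benchmark: 271 × 218 with 4134 positives, density ≈ 0.07).

## Similarity networks

Three networks per entity side, all symmetric, in [0, 1], unit diagonal:

* **Drug structure** — Tanimoto coefficient of binary topological
  fingerprints (2048-bit path-based by default, computed from SMILES with
  RDKit). A pair of all-zero fingerprints is defined to have similarity 0 —
  no shared-substructure evidence.
* **circRNA sequence** — normalized Levenshtein "ratio" of host-gene
  sequences: with substitution cost 2, `sim = (|a|+|b| − D₂)/(|a|+|b|) =
  2·LCS/(|a|+|b|)`. Computed by a numba LCS dynamic program. The plain
  unit-cost variant is available via `convention="unit"`.
* **Gaussian interaction profile (GIP)** — `K_ij = exp(−ω‖IP_i − IP_j‖²)`
  over binary association profiles (rows of A for circRNAs, columns for
  drugs), with bandwidth `ω = ω′ / mean_i ‖IP_i‖²` and `ω′ = 1`.
* **Information entropy** — each drug carries probability
  `p = colsum(A)/AN` and entropy weight `−p·log₂p`; a circRNA's set entropy
  F is the summed weight of its associated drugs, and
  `sim(A,B) = 2·F(I_A ∩ I_B)/(F(I_A)+F(I_B))` (0 when the denominator
  vanishes; diagonal forced to 1; symmetric construction for drugs). Log
  base 2, `0·log 0 := 0`.

## Network fusion (cross-diffusion)

Per side, the three networks are integrated nonlinearly:

1. **Full normalization**: off-diagonal `P_ij = W_ij / (2·Σ_{k≠i} W_ik)`,
   diagonal pinned at 1/2 — every row sums to exactly 1.
2. **KNN affinity**: each row keeps its K largest off-diagonal entries
   (self excluded, ties broken toward the smaller index) renormalized to a
   row-stochastic transition matrix S. Default `K = floor(n/10)` (27 and 21
   at benchmark dimensions).
3. **Cross-diffusion**: `P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ`, renormalized
   after every step; the KNN matrices are computed once and held fixed.
   Stops when the max relative Frobenius change < 1e-6 or after 20
   iterations (random 30×30 inputs converge in ~8).
4. The mean of the three final iterates is symmetrized:
   `SM′ = (SM + SMᵀ)/2`.

**Degenerate rows.** An entity sharing no associations with any other has an
all-zero off-diagonal entropy row, which step 1 cannot normalize.
`normalize_full` raises in that case; the pipeline first applies
`repair_isolated_rows`, which gives such rows a tiny uniform affinity (at the
scale of the smallest informative entry) — an uninformative prior for an
uninformative entity.

## Feature extraction

Three embedding families, each 128-dimensional by default:

* **Sparse autoencoder (drugs).** Input per drug: its fused-similarity row
  concatenated with its association profile (width M+N; 489 at benchmark
  dims), clipped to [0, 1]. Encoder widths 400/350/256/128, mirrored
  decoder; rectifier hiddens; logistic output trained with binary cross
  entropy (per-drug sum over features, averaged over the batch). The
  sparsity term `α · mean_j (x̄_j − β)²` pulls each coding unit's batch-mean
  activation toward the target β = 0.05 with weight α = 1e-3. Adam, lr 1e-3,
  50 epochs, batch 128. The coding-layer activations are the embeddings.
  (The literal "weight tensor" reading of the sparsity penalty is available
  behind `literal_weight_penalty=True`.)
* **Multi-head graph-attention autoencoder (circRNAs).** Node features are
  the block matrix `[[SM′, A], [Aᵀ, 0]]`; edges are association pairs,
  each circRNA's top-`floor(N/10)` fused-similarity neighbours
  (symmetrized), and self-loops; the drug–drug block has no edges. Two
  attention layers: 3 heads × 64 concatenated (192 wide, ELU), then
  3 heads × 128 averaged (identity). Attention scores
  `LeakyReLU(a·[h_i‖h_j])` (slope 0.2) are softmaxed over each node's
  neighbourhood. Training reconstructs the adjacency with an inner-product
  decoder `σ(ZZᵀ)` under BCE; Adam with decoupled weight decay 5e-3 and a
  one-cycle schedule peaking at 1e-3; 300 epochs. The first N rows of Z are
  the circRNA embeddings.
* **Masked NMF (both sides).** Minimize
  `‖W ⊙ (C − UV)‖²_F + λ₁‖U‖²_F + λ₂‖V‖²_F` with `C = W = A`,
  λ₁ = λ₂ = 0.01, rank k = 128, via multiplicative updates with a constant
  `(λ/2)` denominator term and an `eps = 1e-9` guard; exactly 500
  iterations, Uniform(0,1) initialization. Because a constant additive
  denominator is the multiplicative-update treatment of an **L1** penalty,
  the recorded `objective_history` is the quantity the updates provably
  descend — `‖W⊙(C−UV)‖² + λ₁·ΣU + λ₂·ΣV` — which is non-increasing; the
  Frobenius-penalized objective is exposed separately (`nmf_objective`) and
  can drift upward by ~1e-4 near convergence. With λ = 0 the two coincide.
  The rank is capped at `min(k, N, M)` when the dataset is smaller than the
  default rank.

## Pair features, classifier, evaluation

A pair (i, j) is represented by `[gat_i ⊙ sae_j ‖ U_i ⊙ V_j]` — two
element-wise-product blocks, 256 dims by default. Ablations: removing a
module drops its block; when one member of a product pair is removed the
surviving embedding enters raw (`del_mga` → `[sae_j ‖ U_i⊙V_j]`,
`del_sae` → `[gat_i ‖ U_i⊙V_j]`, `del_nmf` → `[gat_i⊙sae_j]`). The MLP
input layer is sized from the realized feature width.

Balanced 1:1 sampling keeps all positives plus an equal number of uniform
negatives (without replacement, never colliding with a positive), drawn once
before fold splitting. The classifier is a fully connected net
(input, 128, 64, 1), rectifier hiddens, logistic output, BCE, Adam lr 1e-3,
100 epochs, batch 32; confusion-based metrics use threshold 0.5.

Cross-validation shuffles the balanced sample into k folds (sizes differing
by ≤ 1). Two protocols:

* `paper_faithful` (default) — similarity networks and embeddings are
  computed once from the complete A; only the MLP is refitted per fold. This
  reproduces the protocol as originally described but lets test-fold
  positives inform the association-derived inputs (GIP, entropy, NMF target,
  GAT edges).
* `strict` — those inputs are recomputed per fold with the test-fold
  positives zeroed; slower, leak-free. Provided because the faithful
  protocol's optimism should be measurable, not silent.

AUC is the trapezoidal area under the ROC curve over all distinct score
thresholds (ties pooled); AUPR likewise over the precision–recall curve with
the curve anchored at recall 0 using the first observed precision. Both are
cross-checked in the test suite against quadratic-time oracles and
scikit-learn.

Candidate ranking scores all (circRNA, drug) pairs for a chosen drug,
optionally excluding known positives, ties broken by circRNA id. The
novel-drug protocol zeroes the drug's column and retrains before ranking.

## Numerical infrastructure

All neural components run on an in-repo reverse-mode autodiff engine over
numpy float64 (`circdrug.autograd`), with Adam and the one-cycle schedule in
`circdrug.nn`. Double precision plus explicit seeding makes every training
run bit-reproducible; gradients are validated against central finite
differences, and the masked softmax and logit-BCE are implemented with the
usual max-shift / log1p stabilizations. Every source of randomness flows
through an explicitly passed seed (sub-seeds are derived per role via
`SeedSequence`); there is no global random state.

## Synthetic benchmark

The generator plants one cluster assignment per side (round-robin), draws a
per-cluster ancestor sequence/fingerprint, mutates each member per position
at `mutation_rate` (default 0.05), links cluster pairs with probability
`link_density` (0.15) and fills A with Bernoulli(p_hi = 0.4) inside linked
blocks and Bernoulli(p_lo = 0.02) outside. Expected density
`0.15·0.4 + 0.85·0.02 ≈ 0.077`, matching the curated benchmark's ≈ 0.07.
Defaults (150 × 120, 8 clusters) keep a full 5-fold run plus ablations to a
few minutes on one CPU; the reference benchmark scale (271 × 218) is
generated the same way when wanted.

What it emulates: sparsity, cluster-correlated sequences/fingerprints, and
low-rank block structure tying similarities to associations. What it does
not: realistic sequence length and composition, realistic chemistry (member
fingerprints are bit-flips, not molecules), heavy-tailed degree
distributions, or any biology of drug mechanism. Passing the end-to-end
tests therefore shows the pipeline recovers planted multi-source structure —
not that it attains the curated benchmark's published performance, which
requires the external dataset.

## Known limitations

* The paper-faithful CV protocol is optimistic by construction (see above).
* Entropy similarity is undefined for entities without associations; the
  uniform-affinity repair is a pragmatic, not principled, choice.
* Multiplicative-update NMF with W = A constrains only observed positives;
  everything else is shaped by regularization alone.
* Trained GAT embeddings are not permutation-equivariant under a fixed seed
  because the node features are themselves node-indexed (the attention layer
  is equivariant; the initialization is not relative to column order).
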