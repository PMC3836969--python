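# Methods

This note records the modelling and numerical choices behind dtikit, the
defaults and why they were chosen, and what the synthetic benchmark does and
does not demonstrate.

## Problem setting

Given a binary gold standard of drug–target pairs, predict the probability
of interaction for the unknown pairs. Absent pairs are treated as negatives
during training and evaluation (the standard closed-world convention for
this problem; genuinely unknown true interactions therefore depress measured
AUC slightly). Identifiers are opaque strings; no cross-database synonym
resolution is attempted.

## Drug kernels

**Tanimoto / signature.** Tanimoto operates on binary fingerprint bit-sets;
the 0/0 case for two empty fingerprints is defined as similarity 0 with a
warning. The signature kernel is the Gram matrix of count vectors, PSD by
construction; cosine normalization is the default, with zero vectors mapped
to 0 off-diagonal (diagonal 1).

**Side effects.** The similarity is a weighted Dice coefficient. Two
down-weights multiply per side effect *s*: a frequency penalty
`1/ln(e + f_s)` (smooth, equals 1 at f=0, ~0.76 at f=1) and a correlation
penalty `1/|cluster(s)|`. Clusters come from average-linkage agglomerative
clustering of side effects on the Jaccard similarity of their carrier-drug
sets, cut where between-cluster similarity drops below `corr_threshold`
(default 0.7). Rationale: a block of mutually redundant side effects should
count roughly once, not |block| times, and ubiquitous side effects carry
little information. Dice rather than raw overlap keeps the measure in [0,1]
and symmetric. Drugs with empty profiles get 0 similarity to everything
(diagonal 1). The clustering cut and the exact penalty shapes are design
choices; both are configurable.

**DDI.** Three variants over the undirected DDI graph: adjacency
("direct"), inverse unweighted shortest-path distance 1/d (BFS; unreachable
pairs scored 0 rather than removed, so arbitrary graphs are accepted — the
CLI's `--drop-unreachable` restricts to the largest connected component for
the stricter convention), and the diffusion kernel `exp(βH)` with
`H = A − D`. H annihilates the constant vector, so every row of the kernel
sums to 1 (a conserved diffusion), and `exp(βH)` is symmetric PSD. β
defaults to 0.5, the middle of the useful range in practice; larger β mixes
longer paths more strongly. The matrix exponential is scipy's
scaling-and-squaring; tests pin it against an independent truncated-series
oracle. All drug kernels define self-similarity as 1.

Distances are not capped: the empirical observation that real DDI networks
have diameter ≈ 6 is a property of those data, not a rule of the method.

## Protein kernels

**Sequence.** Smith–Waterman local alignment with a linear gap model and
defaults (match, mismatch, gap) = (+2, −1, −1); the defaults keep scores
hand-checkable at desk scale, and BLOSUM62 with affine gaps is available
through `AlignmentParams`. The kernel entry is the
`SW(i,j)/√(SW(i,i)·SW(j,j))` normalization, giving a unit diagonal and
entries in [0,1]. Normalized SW is not guaranteed PSD; the PSD correction is
applied before SVM use.

**EC hierarchy.** Score = number of shared leading EC fields + 1 ∈ [1,5],
optionally divided by 5. Unknown fields ('-') terminate the comparable
prefix. The kernel is a sum of prefix-indicator Gram matrices plus a
constant, hence PSD. Proteins lacking EC numbers must be filtered by the
caller — the operation refuses to invent a neutral value.

## Kernel algebra

PSD correction shifts the diagonal once by |λ_min| + δ (δ = 1e-8) when the
minimum eigenvalue is negative — the fixed point of the "keep adding small
identity multiples" procedure, reached in a single eigen-solve, and
idempotent. Fusion is a fixed-weight non-negative sum (weights default to
1); learning the weights by semidefinite programming is out of scope. The
pairwise (tensor-product) kernel K((c,p),(c′,p′)) = K_drug(c,c′)·K_prot(p,p′)
is exposed as a block generator over groups of 15 proteins by default, so
the full pair-space Gram matrix never has to be materialized at once.

## KL1LR

Features per evaluated drug and kernel: mean similarity to positive-labelled
training drugs and to negative-labelled ones, excluding the drug itself —
without self-exclusion the unit diagonal of the kernel would leak each
training example's own label into its feature. Features are interleaved
(x⁺₁, x⁻₁, …, x⁺_m, x⁻_m); the objective is `−loglik + λΣ|β_j|` with the
intercept unpenalized (standard for L1 logistic models).

Solver: the nonsmooth problem is rewritten as the smooth split β = β⁺ − β⁻
with non-negativity bounds and solved by L-BFGS-B, then polished by
proximal-gradient steps until the max KKT violation of the original problem
is ≤ 1e-8 (contract: ≤ 1e-6). The problem is convex with a handful of
coefficients (2 per kernel + intercept), so the fit is deterministic and
takes milliseconds. λ defaults to 0.04; the sweep helper provides 13
log-spaced values in [0.01, 0.3]. At very large λ the fit collapses to the
null model with intercept = logit(prevalence), which tests verify.

## SVM route

A precomputed-kernel C-SVC (scikit-learn) trained on the train×train kernel
block; held-out drugs are scored through their kernel rows against the
training set. Decision values are mapped to probabilities by a Platt sigmoid
fitted on the training decision values with Platt's smoothed targets
((N⁺+1)/(N⁺+2) and 1/(N⁻+2)), which stays finite on separable data and —
unlike the library's built-in probability estimates, which randomize an
internal cross-validation — is deterministic. C defaults to 1; the sweep
helper provides 18 log-spaced values in [0.1, 100].

## Bipartite local model

For a pair (d, p): the drug-side model for p is trained on drugs excluding
d; the protein-side model for d on proteins excluding p. The two
probabilities are aggregated by geometric mean √(p₁p₂) by default —
symmetric, bounded by its inputs, zero-absorbing (a pair scored impossible
by either side stays at the bottom); arithmetic mean and max are available.
Entities with degenerate labels (fewer than two positives or two negatives
in the training set) are skipped and logged, never imputed; when only one
side of a pair is computable, that side's probability is used as-is.

## Cross-validation protocol

Drugs are partitioned into k balanced folds (sizes differ by ≤1), repeated
with fresh random partitions; defaults k = 5, 5 repeats. Within a run, all
per-protein models share the fold split; held-out pair scores are pooled
across proteins into a single AUC per run ("global accuracy") — per-protein
AUC averaging would up-weight proteins with few drugs. The reported figure
is the mean of the k·repeats AUCs. AUC uses the Mann–Whitney midrank
convention (ties count ½), computed from rank sums and verified against
brute-force concordance counting. Degenerate proteins are excluded per run
and logged; a run with no usable protein raises rather than fabricating a
number.

## Synthetic data generator

One latent assignment of drugs and proteins to `n_modules` modules drives
every modality, emulating the empirical coupling between DDI, chemical and
side-effect similarity observed in real drug data:

| knob | default | meaning |
| --- | --- | --- |
| n_drugs, n_proteins, n_modules | 150, 60, 5 | problem size |
| p_in / p_out | 0.9 / 0.02 | DTI edge prob., same/different module |
| q_in / q_out | 0.6 / 0.02 | DDI edge prob., same/different module |
| se_pool_size, se_per_drug, se_noise | 100, 8, 0.2 | side-effect pools and swap noise |
| fp_width, fp_module_bits, fp_flip_prob | 128, 24, 0.45 | fingerprint template and per-bit flip |
| seq_length, seq_mut_prob | 120, 0.05 | sequence length and per-site mutation |

The default ("signal") condition couples the DDI network strongly to the
modules and the fingerprints only weakly: at flip probability q the per-bit
correlation with the module template scales as (1−2q)², i.e. 0.01 at 0.45 —
near-noise by design, so the DDI kernel is the informative one. The
`chem-strong` preset reverses this (flip 0.05, q_in 0.05); `null` removes
module structure from the DTI edges entirely. Every random draw flows from a
single seeded generator, so a config reproduces its dataset bit-for-bit.

What the generator does *not* emulate: scale-free degree structure of real
DDI networks, overlapping pharmacological classes, correlated side-effect
co-reporting biases, realistic protein family phylogenies, or database
incompleteness. Passing the synthetic benchmark therefore shows the
machinery is correct and that planted signal of the stated strength is
recovered — not that any particular real database will yield a given AUC.

## Numerical conventions and degenerate inputs

- Symmetry tolerance for kernels: 1e-9 (read-back averages K and Kᵀ).
- Ranking ties broken lexicographically by (drug, protein) id, so rankings
  are stable across runs.
- Empty rank bins report "undefined", not 0.
- Matrix TSVs round-trip at ≥12 significant digits (`%.17g`).
- Result JSON is written with sorted keys and no timestamps; two runs of the
  same config are byte-identical.

## Problem sizes used in tests

The test and acceptance workloads run the full 5×5 protocol at the default
150×60 generator size (about a minute per CV pair on one core) and use
10–30-entity instances for oracle comparisons (Floyd–Warshall, truncated
series, brute-force concordance), chosen so every oracle is exhaustive yet
the whole suite stays comfortably fast on a laptop.

## Known limitations

- The closed-world negative assumption biases probabilities downward for
  under-annotated drugs/proteins.
- Normalized SW similarity can be indefinite; SVM use requires the PSD
  shift, which slightly inflates self-similarity.
- KL1LR features collapse each kernel to two summary statistics per drug;
  signal orthogonal to the positive/negative mean structure is invisible
  to it.
- The CV protocol splits over drugs only; it estimates accuracy for new
  drugs against known proteins, not for entirely novel proteins.
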