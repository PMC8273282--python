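# Methods

## Data model

The network couples five entity types — lncRNA, miRNA, gene, cancer, and
prognosis — through seven binary relation blocks: lncRNA–miRNA, lncRNA–gene,
lncRNA–cancer (the target), miRNA–gene, miRNA–cancer, gene–cancer, and
gene–prognosis. Each block R_ij is a dense 0/1 matrix whose axes are fixed
entity catalogs; unobserved pairs are encoded 0 and treated as negatives
throughout (there is no missing-value mask), which matches how the
cross-validation defines its negative class. Gene–prognosis scores arrive as
reals in [0, 1] and are binarized at a strict cutoff: an entry becomes 1 iff
its score exceeds 0.5, so a gene exactly at the cutoff is not counted as
prognosis-correlated.

Prognosis is modeled as its own three-entry catalog whose columns are keyed
one-to-one to the cancer catalog. This is an interpretation: the
gene–prognosis block has one column per cancer, and restricting the network
to a single cancer (`restrict_to_cancer`) therefore slices prognosis-indexed
axes in lockstep with cancer-indexed ones while leaving purely molecular
blocks untouched. Restriction is idempotent, and per-cancer models share all
molecular side information.

Identifiers, not indices, are the external currency: edge lists are
`source_id<TAB>target_id[<TAB>weight]` TSV files and catalogs one identifier
per line, with 0-based indexing purely internal. Duplicate edges collapse to
a single entry with a logged warning (public interaction databases commonly
contain them); duplicate catalog identifiers are an error.

## Objective and solver

The fused objective is

    min_{G≥0,S,w}  Σ_ij w_ij ||R_ij − G_i S_ij G_j^T||_F² + α Σ_ij w_ij²,
    subject to w ≥ 0, Σ w_ij = 1,

with one nonnegative factor G_i (n_i × k_i) per entity type shared across
its incident blocks, an unconstrained core S_ij per block, and simplex
weights w. α defaults to 1e5: at that strength the weights stay near uniform
(1/7 ≈ 0.143 for the full seven-block network) and act as a mild
down-weighting of poorly reconstructed blocks rather than a hard selection.
Smaller α concentrates weight on the easiest blocks; in the limit α → 0 all
mass goes to the single block with the smallest residual.

**Weight step.** Given residuals H_ij, the optimal simplex weights have the
closed form w_ij = max(γ − H_ij, 0)/(2α). γ is found exactly by
water-filling: sort H ascending and take the largest active-set size m for
which γ_m = (2α + Σ_{r≤m} H_(r))/m strictly exceeds H_(m); inactive
relations get weight exactly 0. Two numerical details matter: H is first
shifted by its minimum (the solution is invariant to a common shift, and the
shift avoids cancellation when residuals are large but nearly equal), and
the result is renormalized so Σw = 1 holds to machine precision. Weights are
re-initialized to uniform at the start of every fit so repeated fits (e.g.
cross-validation folds) are independent.

**Factor steps.** Each sweep first re-solves every core exactly,
S_ij = G_i⁺ R_ij (G_j⁺)ᵀ via pseudoinverse, then updates each G_i as the
exact nonnegative least-squares minimizer of its incident weighted residual:
with cores and the other factors fixed, the problem separates over the rows
of G_i, each row a small NNLS against the horizontally stacked
(√w_ij-scaled) incident blocks. Exact coordinate minimization was chosen
over multiplicative gradient-ratio updates after direct comparison: on an
exactly low-rank graph the multiplicative rule stalls on plateaus two to
three orders of magnitude above the attainable residual, while NNLS descent
reaches the noiseless optimum in a few dozen sweeps. A guard still recomputes
each factor update's incident cost and rejects any step a numerical edge
case would make worse, so the recorded objective trace is non-increasing by
construction — a contract the tests audit at 1e-8 relative slack.

**Initialization.** G_i starts as the elementwise absolute value of the top
k_i left singular vectors of the horizontal concatenation of all blocks
incident to type i (blocks transposed where i is the column type), floored
at ε = 1e-12; cores then start at their least-squares values. The absolute
value reconciles the SVD basis with nonnegativity but leaves the data column
space when singular vectors have mixed signs, so the *initial* residual on
planted low-rank data is small (a few percent of the data norm) but not
zero; driving it to the noiseless optimum is the solver's job, and the
recovery tests assert exactly that division of labor. The full SVD is used
so ranks up to the axis size remain available through the orthonormal
completion. The solver is deterministic; the seed in `FitConfig` labels the
run and is recorded in every report.

**Ranks and stopping.** Ranks are per-entity-type (k1…k5 in the
five-feature network). A requested rank above its axis size is clamped to
the axis size with a warning rather than rejected, so coarse search grids
remain runnable on small axes. Iteration stops when the relative objective
change drops below `tol` (default 1e-6) or after `max_iter` (default 200)
sweeps. Because the α-term (~1.4e4 at α = 1e5) dominates the objective's
magnitude, the default tolerance can stop the sweep while the residual part
is still improving; the exact-recovery experiment therefore runs at
tol = 1e-9, which is a solver-convergence setting, not a change to any
asserted bound.

**Scores.** Predicted scores are the raw entries of the reconstruction
G_i S_ij G_jᵀ, with no rescaling — decision thresholds are therefore
dataset-specific and are always re-derived by the max-MCC scan on the data
at hand.

## Evaluation protocol

Every cell of the target block is a labelled example (observed association
= positive, unobserved = negative). `make_folds` partitions cells into K
stratified folds (per-label fold sizes differ by at most one; both classes
must hold ≥ K cells). Fold granularity is pairs, not lncRNAs: the target is
a pair score, and in per-cancer mode the two notions coincide. For each fold
the test positives are zeroed in a training copy of the target (test
negatives are already zero — nothing else can leak), the model is refit from
scratch, and the held-out cells are scored from the reconstruction.

AUC is the rank-based Mann–Whitney statistic with mid-rank tie handling,
equal to P(score⁺ > score⁻) + ½·P(tie). The headline statistic is the mean
of per-fold AUCs. Confusion metrics (MCC, accuracy, precision, sensitivity,
specificity) call a pair positive iff its score strictly exceeds the
threshold, with MCC defined as 0 whenever a denominator factor vanishes. The
max-MCC threshold scan evaluates midpoints between consecutive distinct
sorted scores plus below-minimum and above-maximum sentinels — every
achievable confusion matrix is visited — and ties resolve to the lowest
threshold. Per-fold metrics use each fold's own best-MCC cutoff; the
reported decision threshold comes from the pooled out-of-fold scores
(pooling is the default because one threshold per model is what a
candidate-calling step consumes; per-fold thresholds are also emitted).

Rank search is coordinate descent: the first axis scans its grid with all
other ranks fixed, is frozen at its best value, then the next axis scans.
The default grid pattern for a searched axis starts at 10 and steps by 100
up to the axis size, and ties break toward the smaller rank — both choices
logged. Ablation drops one named side block at a time (never the target),
re-runs cross-validation with the identical fold assignment, and reports
mean-AUC and best-MCC deltas against the full-graph baseline. An entity type
orphaned by an ablation (prognosis, when gene–prognosis is dropped) leaves
the graph together with its catalog.

## Synthetic generator

The generator emulates the corpus topology at desk scale: 200 lncRNAs, 150
miRNAs, 300 genes, 3 cancers, 3 prognosis columns, joined by the same seven
blocks. Latent nonnegative factors (gamma magnitudes under a Bernoulli(0.5)
sparsity mask; true ranks 5/5/5/3/3, the cancer-side ranks capped by their
axis size) are shared across blocks, and each block is the latent product
under a block-specific nonnegative core, binarized at the quantile matching
its density target. Densities mirror the curated corpus's regime — target
0.10, cancer-indexed side blocks 0.18–0.30, molecular blocks 0.01–0.05 —
chosen so stratified 10-fold CV retains several positives per fold.
Prognosis shares the cancer latent factor, making the gene–prognosis block
an informative proxy for gene–cancer structure.

Noise flips each cell independently at a configurable rate (default 0), and
a holdout fraction (default 0.2) of target positives is removed into a truth
list; those cells are zero in the emitted target, so recovery AUC measures
genuine generalization, not memorization. One block (default lncRNA–miRNA)
is designated *informative*: side blocks touching the target's row type that
are neither the target nor the informative block are rebuilt from decoy row
factors, making the informative block the main conduit tying target rows to
the rest of the network — this is what gives relation ablation a planted
effect to detect. In exact mode (`binarize=False`) decoys are disabled and
the real-valued latent products are emitted scaled to [0, 1], so the graph
is jointly and exactly low rank; this is the regime the solver-recovery
tests require, and it permits neither noise nor holdout.

What the generator does **not** emulate: real relation matrices are not
generated by a shared low-rank process plus independent flips — database
curation induces correlated, degree-biased missingness; entity degrees are
far more skewed; and block densities at corpus scale differ by orders of
magnitude across blocks. Passing the synthetic suite therefore demonstrates
that the solver, masking, and protocols behave as designed under a known
ground truth — not that any particular AUC will transfer to curated data.

## Null calibration

A single label permutation of a 200 × 3 target is *not* an adequate null: the
60 shuffled positives cluster by chance within rows, and with only three
columns that clustering systematically shifts a single draw's CV AUC by up
to ±0.08 in either direction. The calibration therefore averages the mean
CV AUC over five fixed-seed label permutations, which concentrates at 0.5
within ±0.05 at the default scale. This is the standard permutation-test
logic: the null distribution, not one sample from it, is what must center at
chance.

## Problem sizes and determinism

Default experiment sizes — 650 entities, seven blocks, 10 folds, ≤ 200
sweeps — keep a full cross-validation around seven seconds and the complete
acceptance computation under a minute on one CPU core. All randomness
(generation, fold assignment, permutations) flows from explicit integer
seeds; reports embed the seed and a hash of the resolved configuration, and
two runs from the same configuration are byte-identical.

## Known limitations

- Dense in-memory blocks: at full corpus scale (16,410 genes) the
  miRNA–gene block alone is ~360 MB as float64; a sparse backend would be
  needed well beyond desk scale.
- Alternating minimization guarantees monotone descent, not global
  optimality; different ranks or data can land in different local optima
  (scores, not the protocol, change).
- Raw reconstruction scores are not calibrated probabilities; thresholds
  must be re-derived per dataset via the max-MCC scan.
- The weight mechanism with α = 1e5 is intentionally gentle; it reorders
  block importance only when residuals differ by amounts comparable to α.
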