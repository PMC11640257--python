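# Methods

## The problem

Two-class expression studies (classically microarray, equally bulk RNA-seq
counts after preprocessing) sit in the "large p, small n" regime: tens of
samples against thousands to tens of thousands of genes, most of which carry
no class information. Classifiers trained on the full matrix overfit, and
the genes a model leans on are of direct biological interest, so the
selection itself is a deliverable. `mipsa` implements a two-stage
filter/wrapper selector: a mutual-information (MI) filter cuts the candidate
pool to a tractable size, then a binary particle swarm optimizer (PSO)
searches subsets of that pool against a cross-validated support vector
machine (SVM), trading error against subset size.

## Stage 1 — mutual-information filter

Each gene's expression vector X is discretized and scored by the plug-in
(histogram) mutual information with the binary label Y, in bits:

    I(X; Y) = H(Y) - H(Y | X)

with H the plug-in Shannon entropy over observed frequencies and the
0·log 0 = 0 convention. Genes are ranked by descending MI (ties broken
lexicographically by gene id, so rankings are identical across platforms),
the top k are kept, and a greedy redundancy pass then walks the survivors
in rank order and drops any gene whose absolute Pearson correlation with an
already-retained gene reaches the redundancy threshold. Because the pass
runs after the top-k cut, the surviving pool may hold fewer than k genes;
there is no backfilling.

Parameter defaults:

| parameter | default | units / range | rationale |
|---|---|---|---|
| `k` | 100 | genes | pool size handed to the wrapper stage |
| `n_bins` | 10 | equal-frequency bins | see below |
| `redundancy_threshold` | 0.90 | abs. Pearson r | drop near-duplicates, keep the higher-MI member |

Discretization is equal-frequency (quantile) binning. Two reasons: it is
robust to the heavy-tailed, skewed distributions typical of expression
values, and it makes the score invariant under any strictly monotone
transform of a gene (quantile order is preserved), so raw, log-scaled and
z-scored matrices produce the same ranking — the package therefore takes
expression values as given and does not prescribe a normalization. The
plug-in estimator on n ≈ 60 samples with 10 bins is biased upward for every
gene equally; since only the ranking matters in stage 1, the bias is
harmless. No k-NN/KSG estimators are provided.

A constant gene yields a single bin and scores exactly 0. All scores
satisfy 0 ≤ I ≤ min(H(X_binned), H(Y)); the test suite asserts this bound
on every generated gene and checks the entropy-decomposition route against
a direct joint-distribution computation to 1e-12.

## Stage 2 — binary PSO with an SVM-wrapped fitness

Particles are bit-vectors over the D pooled genes (1 = included) with a
real velocity per bit. Updates are the canonical binary-PSO rules: velocity

    v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x),   clamped to ±v_max

with fresh per-component uniform draws r1, r2, and a stochastic position
resampling through the sigmoid transfer, bit = 1 iff u < 1/(1+e^(−v)).
Personal/global bests replace the incumbent only on strict improvement, so
the global-best trace is non-increasing by construction. The minimized
fitness is

    f(x) = α·Error(x) + β·|x|/D

where Error(x) is the cross-validated misclassification rate of the wrapped
SVM restricted to the included genes.

Defaults: 30 particles, 100 iterations, w = 1.0, c1 = c2 = 2.0, v_max = 6,
initial inclusion probability 0.1, stall window 20 iterations, α = 0.9,
β = 0.1. The inertia choice deserves a note: in binary PSO the position is
*resampled* every iteration, so a damped velocity (w around 0.7) reaches a
pull/decay equilibrium near |v| ≈ 1.2 well inside the clamp — a settled-off
bit still flips on with probability ≈ 0.23 per iteration and the swarm
never converges to compact subsets. With w = 1 velocities accumulate to
saturation at ±v_max (flip probability 0.0025) and agreed bits freeze.
Measured on a planted 10-of-50 Hamming objective, w = 0.7/c = 1.5 stalls at
Hamming distance 4–6 from the optimum while w = 1/c = 2 recovers it exactly
on every seed tried; the package therefore ships the original
binary-PSO parameterization as default, with everything configurable.

Other numerical choices:

- **All-zero repair.** A particle that resamples to the empty subset has no
  defined classifier error; one uniformly chosen bit is switched on.
- **Inner error estimator.** Stratified 5-fold CV by default. Leave-one-out
  per particle per iteration is quadratically more expensive and is
  reserved for final reporting, where it is the evaluation standard for
  tiny-n studies; `error_estimator="loocv"` restores it inside the search,
  and `"holdout"` gives a single stratified 80/20 split.
- **Fitness caching.** Results are memoized by bit pattern; particles
  revisit subsets constantly, and caching changes no result, only runtime.
- **Stopping.** max_iter iterations, or stall_iters consecutive iterations
  without global-best improvement.
- **`target_size`.** Optional hard repair to exactly that many included
  genes (keeping the highest-velocity bits), for protocols that report
  accuracy at fixed subset sizes.
- **Error quantization.** On n samples the CV error moves in steps of 1/n,
  while removing one gene saves β/D (0.001 at the defaults). Any
  zero-error subset therefore strictly dominates all larger ones, and the
  search converges to minimal zero-error subsets — see the discussion of
  recovery below.

## Classification and evaluation

The SVM (linear kernel by default, C = 1, with polynomial and RBF kernels
as configuration) is delegated to scikit-learn's solver; the package owns
fold hygiene: when standardization is on (default), per-gene mean/SD are
fitted on the training portion of each fold only and applied to both sides,
and the test suite asserts the corresponding shift-invariance/variance
properties. Single-class training folds — possible in k-fold on tiny or
heavily imbalanced data — are skipped with a warning and the accuracy
denominator adjusts.

Final reporting uses leave-one-out cross-validation: n folds, accuracy =
correct/total, aggregated into a confusion matrix (positive class =
label 1, "cancer") from which accuracy, precision, sensitivity and F-score
are computed, with zero-denominator metrics reported as 0 and flagged. ROC
and precision–recall point sets come from a threshold sweep over the
held-out decision scores; AUC is the trapezoid area, which equals the
Mann–Whitney concordance probability (asserted to 1e-12 against brute-force
pairwise counting).

The pipeline repeats the PSO stage `n_runs` times with child seeds
base_seed + run index, evaluates each run's subset by LOOCV, and reports
the best run's subset together with best/average/worst accuracy over runs
(ties on accuracy keep the earliest run). Everything is a pure function of
(data, configuration, seed); two identical invocations produce
byte-identical output files.

## Synthetic data: what it emulates and what it does not

The generator draws Gaussian per-gene expression: a standard-normal
baseline mean per gene, within-class SD `noise_sd`, and for the
`n_informative` planted genes a between-class mean shift of
`effect_size`·`noise_sd` (per-gene Cohen's d). Labels are
Bernoulli(`class_balance`). An optional correlated block adds noisy copies
of planted genes (parent–child correlation ≈ 0.98 in expectation) to give
redundancy removal real work. Planted genes are scattered over seeded
random column positions so positional bugs cannot pass recovery tests.

Default conditions — 60 samples × 200 genes, 10 informative, effect size
2.0, balanced classes, unit noise — are the calibrated test-bed: large
enough that the MI filter separates signal from noise reliably (the planted
genes' mean MI clears the 95th percentile of noise-gene MI in 50/50
calibration seeds), small enough that the full pipeline runs in minutes on
one CPU. At effect size 0 planted genes are statistically indistinguishable
from noise, which the suite verifies by rank-sum test.

What the generator does **not** emulate: probe/batch effects, heteroscedastic
or count-distributed noise, correlated noise structure beyond the explicit
block, or gene–gene interaction signal (every planted gene is marginally
informative). Passing recovery tests therefore demonstrates correctness of
the machinery under a clean additive-shift model, not performance on real
microarray data.

## Recovery behaviour and a known limitation

Under the default conditions the two-stage pipeline returns compact subsets
(4–7 genes) with best-run LOOCV accuracy ≥ 0.95, far above equal-size
random subsets drawn from the filtered pool (≈ 0.75 mean). Note what
compactness implies: with d = 2 per planted gene, three or four of them
already achieve zero cross-validated error, and since any zero-error subset
strictly dominates larger ones under β > 0, a *well-converging* optimizer
will not keep all ten planted genes — the selected subset typically
contains 3–5 of them, while the union across repeated runs covers most of
the planted set. If the goal is enumerating all informative genes rather
than a minimal predictive panel, run with β = 0 and a fixed
`target_size`, or aggregate subsets across runs; a minimal-panel selector
is by design not an exhaustive biomarker screen. Related caveat: because
the wrapper compares thousands of subsets on the same folds, the inner CV
error of the winner is optimistically biased; the reported LOOCV accuracy
is computed on the same dataset and shares that selection bias, as it does
in any wrapper study without an external validation cohort.

## Problem sizes used in the automated checks

The test-bed exercises the estimator oracles at n ≤ 30 samples (200 random
instances), the bound properties on 1,000 generated genes, the optimizer on
a 50-bit planted objective, filter recovery over 50 generator seeds, and
the full pipeline at the default 60 × 200 conditions with 5 runs — sizes
chosen so the complete suite runs in a few minutes on a single CPU while
every stage is still measured under its calibrated conditions.
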