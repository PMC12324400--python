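# Methods

## Model and procedure

The package treats a bulk expression profile as a vector of log-scale
values (e.g. log2 TPM) over genes whose biologically meaningful states
are binary: each gene is either "high" or "low" in a given sample, and
the continuous measurement scatters around one of two modes. Under
that assumption three operations define the whole pipeline.

**Step regression and thresholds.** For one gene across samples, the
values are sorted ascending and a single-step function is fitted by
evaluating every breakpoint k in 1..n−1: the fitted value is the mean
of the left segment up to k and the mean of the right segment after
it, and the chosen k minimizes the residual sum of squares. The
high/low threshold SThr is the midpoint of the two segment means —
symmetric, deterministic, and independent of sample ordering. On a
time series the same fit is applied in the given order and the
breakpoint itself is the quantity of interest. Fit quality is an
F-like ratio of explained to residual variance,

    F = [ Σᵢ (X̂ᵢ − X̄)² / (m − 1) ] / [ Σᵢ (Xᵢ − X̂ᵢ)² / (n − m) ],

with m the degrees of freedom consumed by the adaptive fit. We use
m = 3 (two segment means plus one breakpoint); m is configurable
because other conventions exist for the adaptive term. A zero residual
is reported as a perfect-fit flag rather than an infinite F.

**Normalization and composite scores.** Each gene is rescaled as
z = (expr − SThr)/(3·sd), where sd is the gene's sample standard
deviation. z = 0 at the binarization boundary and |z| = 1 three
standard deviations away, so genes with very different dynamic ranges
contribute comparably. A cluster's composite score for a sample is the
sum of z over the cluster's genes, with Down-direction genes negated
so that a larger score always means more of the cluster's state; for
the common case of a single-direction cluster this is exactly the
plain sum. Composite scores are comparable between groups within one
dataset but not across signatures of different sizes or across
independently normalized datasets.

**Per-gene selection.** A gene's classification strength for a binary
contrast is its rank ROC-AUC: the probability that a random
positive-class sample carries a larger value than a random
negative-class sample, with ties counted ½. We compute it in the
Mann–Whitney rank form, which is exact under ties (an ROC-curve
trapezoid integral can return 0.5 − ε on fully tied data and flip the
inferred direction arbitrarily, which is why we do not use one). Genes
with raw AUC < 0.5 discriminate in the opposite orientation and are
reported as Down with AUC 1 − raw, so reported values lie in
[0.5, 1]. Confusion-matrix metrics use the gene's own threshold as the
decision rule (high call = positive for Up genes, inverted for Down).
Refinement keeps genes with AUC strictly greater than the cutoff
(default 0.70) and maps source clusters to refined clusters; the
default map sends the reactive cluster R to the inflammatory refined
cluster and the tolerant clusters T1/T2 to the non-inflammatory one,
and any unmapped source cluster keeps its own name. No
multiple-testing adjustment is applied during selection; instead a
label-permutation null (`permutation_null_counts`) estimates how many
genes would pass the cutoff by chance, exploiting the fact that
thresholds and normalization do not depend on the labels.

## Parameters

| parameter | default | units / scale | rationale |
|---|---|---|---|
| m (F-statistic df) | 3 | — | one-step fit: two means + one breakpoint |
| margin (intermediate zone half-width) | 0.5 | log2 expression | conventional for this algorithm family; 0 disables the zone (ties at SThr go low) |
| auc_cutoff | 0.70 | AUC | strict `>`; configurable |
| flag_missing_fraction | 0.5 | fraction of cluster genes | samples missing more are flagged, not silently scored |
| correlation method | Pearson | — | rank (Spearman) exposed as an option |
| significance convention | p ≤ 0.05 | — | reported unadjusted |

Numerical choices: SSE ties in the step fit break toward the smallest
breakpoint; degenerate genes (no step strictly below the constant-fit
SSE, e.g. constant expression) carry the median as SThr, a degenerate
marker, and are excluded from selection; zero-variance genes are
dropped from normalization rather than divided; the accuracy of a
composite score comes from an exhaustive sweep over observed score
thresholds (rule: score > t), with ties broken toward the lower
threshold, so accuracy never falls below the larger class prevalence.

## Synthetic cohorts

The generator emulates a two-group (healthy vs disease) bulk cohort in
which the pipeline's binarizability assumption holds by construction:
every value is drawn from a low or high Gaussian mode (defaults
μ_lo = 4, μ_hi = 8 log2 units, noise sd 0.7, 15 samples per group —
sized so that default runs finish in seconds while group AUCs are
estimated from a realistic cohort size). Signature genes differ
between groups in their high-mode probability; the `effect` parameter
is the separation of those probabilities (P(high|disease) =
0.5 + effect/2 for an Up gene, mirrored for Down), so effect 0 is an
exact null and effect 1 a complete separation. Background genes use
p = 0.5 in both groups. All randomness flows from a single seed.

What the generator does *not* emulate: count-level noise
(negative-binomial overdispersion), batch effects, correlated gene
modules, library-size artifacts, or intermediate/mixed-polarization
samples. Passing tests therefore certify the algorithmic contracts —
exact step fits, exact AUCs, calibrated nulls, correct end-to-end
recovery when the assumptions hold — not robustness to the messiness
of real cohorts. On real data the binarizability assumption can fail
for unimodal genes (they surface as near-degenerate fits with inflated
thresholds), and signature refinement inherits whatever confounding
the group labels carry.

## Design choices

- The per-gene "classifier" is the gene's own thresholded, normalized
  expression — the only classifier consistent with defining AUC by
  sample ranking and accuracy at the StepMiner threshold. No
  cross-validation is layered on top; selection scope is the per-gene
  AUC rule.
- Two-level fits only; two-step (up-down-up) StepMiner variants and
  Boolean-implication discovery between gene pairs are out of scope.
- Cross-cluster weighting of composite scores is not implemented; all
  genes in a cluster carry equal weight.
- Gene identifiers match case-sensitively with no alias resolution; a
  case-folding option exists but is off by default because it is not a
  substitute for cross-species symbol mapping.
- Welch's t, Pearson/Spearman correlation and the t/normal
  distributions come from scipy; the step fit, thresholding,
  normalization, composite scoring, rank AUC and permutation null are
  implemented here.

## Problem sizes

The test suite and the acceptance script run on synthetic inputs with
200–220 genes and 20–30 samples, 200 label permutations for the null
band, 500–1,000 randomized fixtures for the oracle-equivalence checks,
and 200 Monte-Carlo replicates for breakpoint-recovery calibration.
These sizes make the oracle comparisons exhaustive (every breakpoint,
every sample pair) while keeping a full run to a few seconds.
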