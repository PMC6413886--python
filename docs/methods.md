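# Methods

This note documents the statistical models behind each screen, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical and design choices
made where the design was genuinely open.

## Activity states and covariates

Gene activity is discretized per cancer type: within each type, a gene is
*underactive* (−1) in samples strictly below its 33rd percentile,
*overactive* (+1) strictly above its 67th, *normal* (0) otherwise.
Quantiles use linear interpolation; values equal to a threshold, constant
genes, and missing entries all map to the normal state, and cancer types
with fewer than 10 samples (configurable) are set all-normal with a
warning.  These conventions make the calls conservative at boundaries and
deterministic under ties.

For a pair (V, R) the *rescued* state is V underactive with R overactive
(DU) or underactive (DD); *non-rescued* is V underactive without the
rescue; everything else is *other*.  The three states partition samples.

The genomic instability index of a sample is the fraction of genes whose
absolute SCNA log-ratio strictly exceeds 1.  Continuous covariates entering
any regression are inverse-normal transformed with Blom offsets,
Φ⁻¹((r − 3/8)/(n + 1/4)), ties averaged; binary indicators are left as is.

## Screen 1 — conditional essentiality (cell lines)

Fitness readouts y (shRNA essentiality or drug log-IC50, oriented so higher
= more growth) are quantile-normalized to N(0,1) and regressed on the
partner gene's continuous molecular level g with cancer type as a random
intercept: y ~ g + (1 | cancer_type).  The model is fitted by maximum
likelihood with the variance ratio θ = σ²ᵤ/σ²ₑ profiled out, reducing each
fit to a bounded 1-D optimization (the marginal covariance is
block-diagonal with blocks σ²ₑ(I + θJ), so GLS needs only per-group sums).
The fixed-effect p-value is a 1-df likelihood-ratio test against the
intercept-plus-random-effect null; both models use ML because REML
likelihoods are not comparable across fixed-effect structures.  With a
single cancer type the fit degrades exactly to OLS, and the OLS t-test
p-value is reported.  The fitter is validated against statsmodels MixedLM
in the test suite; the dedicated implementation exists because the screen
evaluates tens of thousands of tiny models per run and per-model object
construction dominates the runtime of general-purpose mixed-model code.

DU gates: condition (i) slope > 0 (V-knockdown fitness rises with R),
condition (ii) slope > 0 (R-knockdown fitness falls with V).  DD gates:
condition (i) slope < 0; condition (ii) is a one-sided Wilcoxon rank-sum
comparing V-knockdown fitness between R-low and R-high cell-line tertiles
(no separate linear model is printed for this condition in the screening
tradition; the rank test is the natural two-sample analogue).  A
wrong-signed effect sets the gated p to 1 regardless of magnitude.

P-values are Fisher-combined across panels (X = −2Σln p against χ² with 2k
df; non-positive inputs clamped to 1e-300 with a warning), BH-adjusted per
(condition, modality) family, and a pair passes at FDR < 0.2 if both
conditions clear in mRNA *or* in SCNA.  The OR rule reflects that screen
collections are often missing SCNA for many genes, so an AND rule would
discard well-supported pairs for data-availability reasons.

## Screen 2 — survival of the fittest (tumor co-occurrence)

With N samples, n₂ = #(V underactive), n₁ = #(R in the state required by
the tested pair state), and k the joint count, enrichment of the rescued
state is P(X ≥ k) and depletion of the non-rescued state P(X ≤ k) for
X ~ Hypergeometric(N, n₁, n₂).  States called per cancer type are pooled
into one cohort-level table (the pooled margins inherit the per-type
control).  BH runs separately per (state, modality) family; a pair passes
at FDR < 0.05 only if rescued-enrichment AND non-rescued-depletion hold in
mRNA AND SCNA.  Note that with fixed margins the two one-tailed tests are
complementary (k_non = n₂ − k_res), so the conjunction is effectively a
single strongly-directional requirement per modality — both are still
computed and reported, as each carries its own count bookkeeping.

## Screen 3 — stratified Cox survival screen

For each pair, state and modality the hazard model is

    h_g(t) = h_0g(t) exp(β₁ I + β₂ g(V) + β₃ g(R) + β₄ age + β₅ GII + β₆ TP)

with strata g over the full cross of cancer type × race × sex; strata with
fewer than 10 observed events are merged into one pooled stratum so every
baseline hazard is identifiable.  Ties use the Efron approximation
(lifelines default).  β₁'s significance is a 1-df LRT against the same
model without the indicator; the Wald p is recorded alongside.  Additional
tumor-purity estimates, when provided, enter as further covariates
(mean-imputed if partially missing, dropped with a warning if entirely
missing).  Non-converged fits count as non-significant (p = 1) rather than
being dropped, keeping FDR denominators stable.  The pass rule is the
four-way conjunction: rescued-state β₁ > 0 and non-rescued-state β₁ < 0,
each at BH FDR < 0.05, in both modalities.  Each state is fitted with its
own indicator rather than as the complement of the other, since the two
states are strict subsets of "V underactive", not complements of each
other.

## Screen 4 — phylogenetic similarity

The gene × species conservation-score matrix (87 species in the reference
setting) is factorized with NMF (multiplicative updates, 500 iterations,
tolerance 1e-6, rank 20 by default, seeded and deterministic); each gene's
L2-normalized membership row summarizes its evolutionary pattern, and pair
similarity is the Euclidean distance between rows.  The pass threshold is
the 5% quantile of a background of 10,000 seeded random gene pairs, with a
cap at the top-5% most-similar pairs.  In a full pipeline run distances are
computed for *all* candidate pairs and the cap is taken over that tested
universe; the survivors of the clinical screen are then intersected with
the passing set.  Capping at 5% of the (few) step-3 survivors instead would
make the final step's yield depend on how aggressive the earlier screens
were, which contradicts the filter's role as an absolute similarity
criterion.  Genes absent from the profile matrix fail the screen
(conservative; configurable).

## Interaction score, modes, and controls

Per screen, the representative p-value of a pair is the worst (largest) of
that screen's required sub-tests — the screen's gate is a conjunction, so
its weakest link is its evidence level.  Representative p-values of all
pairs tested by a screen are rank-normalized to [0, 1] (0 = most
significant, ties averaged) and summed over the four screens; lower
interaction scores mean stronger rescue evidence.  In ICB
(immune-checkpoint) mode the in-vitro screen is dropped — its cell-line
panels lack an immune compartment — and the three-screen sum is rescaled by
4/3 to stay on the [0, 4] range.

Control networks: `shuffle_network` permutes rescuer endpoints across edges
(degree sequence preserved; no self-pairs; no edge keeps its original
rescuer; seeded), and `random_degree_matched_network` relabels every node
with a random gene from a larger universe, preserving the degree structure
exactly.

## Drug response and synergy

The drug–tumor SR score C is the fraction of a drug's targets' DU rescuers
(union over targets, set semantics; agonist-annotated targets excluded at
map construction) whose tertile state is +1 in mRNA *or* SCNA — the OR is
chosen for sensitivity and is configurable to mRNA-only.  C is associated
with post-treatment survival via a stratified Cox model (covariates C, age,
GII, all inverse-normal transformed; strata cancer type × sex × race),
compared between RECIST responders (CR/PR) and non-responders (PD/SD) with
a one-sided rank-sum test, and summarized as a rank-based AUC for
predicting non-response, flipped to 1−AUC when the separation runs in the
unexpected direction.  Patients treated with the drug under analysis are
excluded from network inference to avoid circularity.

Bliss synergy for the sparse 1×5 design: for each dose/replicate point,
Ratio(X) = count(combo)/count(primary alone) and Ratio(Y) = count(rescuer
inhibitor alone)/count(untreated); synergism = Ratio(Y)/Ratio(X).  The
primary-alone and untreated denominators use the mean of their replicates.
A rescuer's synergism is the median over its 10 points, significance a
two-sided rank-sum of Ratio(Y) vs Ratio(X), BH across all grids in a
screen; calls are synergistic above 1.25 and antagonistic below 0.75 at
FDR < 0.05.  Zero combination counts are capped at synergism 100 with a
flag rather than propagating infinities; grids with fewer than 6 valid
points are called "neither" with a quality flag.

## Synthetic-data generator

The generator is a pure function of (parameters, seed) and plants exactly
the structure the screens assume.  Reference desk-scale conditions: 1,000
samples, 500 genes, 3 cancer types, 20 DU + 10 DD planted pairs,
rescued-state joint-frequency inflation 2.0, rescued/non-rescued log-hazard
+0.7/−0.7, in-vitro effect 0.8 SD of fitness per SD of partner level,
mRNA–SCNA correlation 0.5, ~30% independent censoring, per-type exponential
baselines with median survival around 500–1,000 days.  The hazard effects
are planted on *both* states because the clinical screen's gate is a
conjunction: a generator that only raised rescued-state hazard would fail
its own non-rescued condition.

Planted states share one latent per-sample "rescue program": block 1
(frequency inflation/9) is the rescued state of every planted pair, block 2
(1/3 − inflation/9) the non-rescued state; within blocks, states are drawn
so every gene's tertile marginals stay exactly at 1/3, and the survival
effect applies once per sample to the blocks.  This mimics a pathway-level
rescue program shared by the planted pairs.  The alternative — independent
per-pair states with multiplicative hazards — leaves each tested pair with
~29 omitted binary hazard terms (per-sample log-hazard sd ≈ 2.2), and Cox
non-collapsibility under that much unobserved heterogeneity attenuates
every pair's marginal contrast to roughly half its conditional value,
so the generator would not deliver the effect size it claims to plant.
Continuous values for planted genes are drawn from the same per-type
distributions as background genes and reordered within type so the planted
states occupy the correct tertile bands — activity calling recovers the
planted states up to boundary noise.

What the generator does *not* emulate: real gene–gene co-expression
structure, batch and platform effects, SCNA segment correlation along
chromosomes, informative censoring, cancer-type-specific rescue biology,
and measurement error models of shRNA screens.  Passing tests therefore
demonstrate that the statistical machinery recovers the assumed structure
at the stated effect sizes — not that those effect sizes or structures
match any particular real cohort.

## Problem sizes used in the checks

The test and acceptance suites size their simulations for a single CPU:
the end-to-end run uses the full default bundle with 5,000 candidate
pairs; Cox parameter recovery uses 50 replicates at n = 1,000; mixed-model
recovery 50 replicates at n = 50; null calibrations use 500 replicates at
n = 400 (Cox, SoF) and n = 100 (mixed model), sizes at which the 1-df
asymptotic reference distributions are accurate; Bliss calibration uses
500 null grids and 200 grids per power setting.

## Known limitations

* The hypergeometric screen treats samples as exchangeable after per-type
  state calling; it does not model per-type sample-size imbalance beyond
  that.
* The mixed model assumes a single random intercept; random slopes per
  cancer type are not supported.
* Non-rescued depletion and rescued enrichment are complementary given the
  margins (see above); they are reported as two tests for bookkeeping but
  are not independent evidence.
* The phylogenetic screen's NMF rank (20) is a heuristic for ~500-gene
  universes; very small gene universes should lower it.
* UD/UU rescue polarities are not implemented.
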