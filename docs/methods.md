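# Methods

## Statistical model

All group contrasts are nonparametric. For feature X in groups A
(control) and B (case), the test is the two-sided Mann–Whitney U with
tie correction (exact null enumeration when |A|·|B| ≤ 400 and the
pooled sample is tie-free, the continuity-corrected normal
approximation otherwise; an all-tied sample is defined to have p = 1).
The effect size is Cliff's delta,

    δ(A, B) = P(x_B > x_A) − P(x_B < x_A),

computed from midranks in O(n log n), equal to 2·AUC − 1 where AUC is
the two-sample concordance probability with half credit for ties. The
sign convention throughout is *positive = higher in the later disease
stage* (the second-named group of a comparison).

Multiple testing uses Benjamini–Hochberg step-up q-values. The family
is one group comparison within one feature kind (taxa, modules, serum
metabolites, urine metabolites); whether microbiome and metabolome
features should share one family is not decidable from the protocol we
follow, so the per-kind default is exposed (`pooled_family=True` pools
everything). Significance means q ≤ 0.1; the threshold is a
configuration value, and the boundary is inclusive.

Continuous/ordinal/dosage covariate associations use tie-aware Spearman
correlation with the t-approximation for p; a constant vector leaves
rho undefined and is treated as non-significant.

## Deconfounding decision procedure

For each feature × comparison, with A the binary disease status (1 =
the more diseased group) and candidate covariates B₁…B_k:

1. If X is not significantly associated with A (BH q > 0.1):
   NOT_SIGNIFICANT; no covariate verdict is assigned.
2. If no covariate is significantly associated with X: **NC**.
3. For every significantly associated covariate B, the forward nested
   test compares OLS fits of X on {A, B} vs {B}. The LR statistic
   n·log(RSS₀/RSS₁) is referred to χ² with df = number of added
   independent design columns. If p < 0.05 for all B: **CD**.
4. For each B where the forward test fails, the reverse test compares
   {A, B} vs {A}. If any reverse test passes: **CONFOUNDED**, naming
   those covariates.
5. Otherwise: **LD** — disease and covariate are mutually irreducible.

Choices made here, and why:

* X is rank-transformed before the OLS fits. The first pipeline step is
  rank-based, abundance data are heavy-tailed and zero-inflated, and
  rank LRTs keep the two steps on the same scale; `rank_transform=False`
  restores raw-scale fits.
* The LRT level is raw 0.05 per covariate, with no multiplicity
  correction across covariates — each covariate is its own hypothesis
  about one feature, and correcting would make the CD label depend on
  how many irrelevant covariates were supplied.
* Covariates are tested one at a time, not in a joint model; the
  procedure is a screen for pairwise reducibility, not a causal model.
* A covariate exactly collinear with status (e.g. a drug prescribed to
  every case and no control) makes both LRTs df = 0, which is defined
  as p = 1: such a pair can never be called CD, and ends LD when both
  are naively significant. This is the designed behaviour — perfectly
  collinear treatment is epistemically indistinguishable from disease.
* Subjects with missing covariate values are dropped per covariate
  test; covariates constant within a comparison are dropped with a
  warning.

## Stage categorization

Stage 1 is HC vs MMC and HC vs UMMC; stage 2 is MMC vs IHD and UMMC vs
IHD; HC vs IHD spans both. A comparison *fires* for a feature when its
q passes the threshold **and** its deconfounding verdict is eligible —
{NC, CD} by default. LD is excluded by default because a feature whose
disease signal cannot be separated from a drug's does not meet the
"cannot be confounded by any tested host variable" bar; admitting LD is
a single flag, since the lax cases are deconfounded in the weak sense.

Rules, in precedence order (the two-stage patterns also satisfy the
single-stage definitions, so they are evaluated first):

1. both stages fire, same delta sign → **ESCF**;
2. both stages fire, opposite signs → **DSCF**;
3. only stage 2 fires → **IHDF** (HC:IHD support is implied but not
   required);
4. only stage 1 fires → **DMF**; HC:IHD firing alone, with no stage-2
   support, also routes to DMF (a shift present the whole way from HC
   but invisible between MMC and IHD is a dysmetabolism-onset signal);
5. otherwise unclassified.

When both comparisons of a stage fire with conflicting signs, the
smaller q defines the stage's direction (q ties break toward the larger
|delta|). A stage delta of exactly zero satisfies neither the
same-sign nor the opposite-sign rule and leaves the feature
unclassified. The |δ| > 0.1 threshold that appears in report rendering
is display-only and is never read during categorization.

Subtype analyses (ACS, CIHD, HF) substitute the subtype's subjects for
IHD in the stage-2 and spanning comparisons and reuse the global
control groups unchanged; with the whole IHD group as the "subtype" the
result is identical to the standard run, which is tested.

## Quantitative profiling

* **Load correction**: row i is multiplied by load_i / mean(load); the
  factors average to exactly 1, so the grand scale is preserved while
  between-subject cell-count differences re-enter the compositional
  profile. Subjects without a load are excluded with a warning (or a
  hard error on request).
* **Rarefaction** is one multivariate hypergeometric draw (sampling
  without replacement); a sample below depth raises a flaggable error.
  Tests run at depths of tens of reads to 10⁴; the production-scale
  depth for shotgun data is 10⁷ reads and is just a parameter.
* **Gene richness** is the mean, over 10 independent rarefactions, of
  the number of genes with a nonzero rarefied count.
* **MGS abundance** is the mean abundance of the marker-gene panel
  (canonically the 50 centroid genes) iff *strictly more than* 10% of
  them are positive, else 0 — 5 of 50 positive is not called.
* **Module profile**: variant coverage = fraction of steps with ≥ 1
  detected ortholog; module coverage = max over variants; presence
  requires coverage > 0.66, so the common 2/3 boundary passes. Module
  abundance is the median over the max-coverage variant's steps of the
  per-step abundance. The protocol does not define per-step
  aggregation when a step has several detected alternatives: the
  default sums them (alternatives are substitutable capacity);
  `step_aggregation="max"` takes the dominant one. Undetected steps
  contribute 0 to the median.

## O-PLS-DA

Features are mean-centered and unit-variance scaled (Pareto scaling by
flag); constant columns are dropped. Each orthogonal component removes
from X the direction of maximal variance orthogonal to the class
contrast; a single predictive PLS component is then fitted. Predictive
scores are exactly orthogonal to every orthogonal-component score by
construction (asserted to < 1e-8 in tests). One orthogonal component is
the default — the protocol does not state component counts, and one is
the smallest model that distinguishes O-PLS-DA from plain PLS-DA;
`n_orth` is exposed, with `n_orth=0` giving PLS-DA.

Panel evaluation uses stratified 70/30 splits (the reference protocol
says random splits; stratification prevents class-empty test sets at
small n and is the documented deviation), 1,000 iterations by default
(100 in the bundled analyses and tests), with identical split indices
across panels per iteration so panel differences are paired. External
validation aligns columns by feature ID, imputes missing features at
the training mean (zero after centering), and refuses < 50% overlap.

## Synthetic cohort generator

The generator defines the study conditions for every benchmark. The
source protocol provides no generative model, so all distributional
choices are explicit stand-ins:

* **Design**: group sizes default to 275/222/372/372 (HC/UMMC/MMC/IHD),
  with IHD split 112/158/102 into ACS/CIHD/HF; tests use smaller sizes.
* **Taxon/module features** are zero-inflated negative-binomial counts
  (dispersion r = 1, structural-zero probability 0.25, per-feature base
  mean log-normal around ~100 counts).
* **Metabolite features** are log-normal intensities (σ_log = 1),
  alternately tagged serum/urine.
* **Archetypes** shift the log-mean by group: dmf = 0/1/1/1 (in
  HC/UMMC/MMC/IHD units of the calibrated shift d), ihdf = 0/0/0/1,
  escf = 0/1/1/2, dscf = 0/1/1/0, drug_driven follows the subject's
  drug indicator instead of the group. Directions are random per
  feature.
* **Effect calibration**: d is solved so that the Cliff's delta between
  the shifted and unshifted populations equals the requested effect —
  in closed form for log-normals (δ = 2Φ(d/(σ√2)) − 1), and by
  bisection on an exact pmf integration for ZINB counts. Structural
  zeros bound the attainable |δ| at roughly (1 − π)·(1 + π) minus the
  nonzero tie mass (≈ 0.57 at π = 0.25); unreachable targets fall back
  to the boundary shift, which matters only for targets ≥ ~0.6 on
  count features.
* **Drugs** are Bernoulli per subject with group-conditional
  probabilities (defaults: statin 0/0/0.6/0.9 across HC/UMMC/MMC/IHD,
  beta-blocker 0/0/0.3/0.8, metformin 0/0/0.45/0.5, aspirin
  0.02/0.05/0.15/0.9, PPI 0.1/0.15/0.3/0.4) — realistic prescription
  gradients that make drug-disease collinearity tunable.
* **Host covariates**: age and BMI normal with group-shifted means,
  smoking ordinal 0/1/2; microbial load log-normal with group-dependent
  mean (highest in HC, lowest in UMMC, partly restored in treated IHD).
* **Seeding**: feature-level structure (archetype assignment,
  directions, base abundances) and subject-level sampling draw from
  separate substreams of the spec seed, so `subject_seed` resamples a
  fresh cohort from the *same* population — used to emulate external
  validation cohorts. A fixed spec is byte-identical across runs.

What passing tests on this generator do **not** show: robustness to
compositionality constraints (features are independent given group),
batch/center effects, covariate measurement error, nonlinear
dose-response, longitudinal structure, or real pharmacokinetics. The
generator exists to verify the decision logic and its operating
characteristics, not to simulate biology.

## Benchmark sizes and numerical notes

Bundled benchmarks use n = 300/group, 250–600 features, and 100 split
iterations — sizes at which the planted effects give near-asymptotic
operating characteristics while the full suite runs in seconds. LRTs
guard degenerate fits (df ≤ 0 or a perfectly fitting reduced model →
p = 1); BH propagates NaN p-values without ranking them; all file
output rounds to 12 significant digits, which is the documented
round-trip precision.

## Known limitations

* The deconfounding screen is a reducibility argument, not causal
  inference; LD cases are genuinely undecidable within it.
* Rank-transformed LRTs are an approximation to a fully nonparametric
  nested test; their null is slightly conservative under heavy ties.
* Categorization trusts the five canonical comparisons; cohorts missing
  a group cannot be staged.
* The O-PLS-DA implementation fits one predictive component only, which
  is sufficient for binary discrimination but not for multiclass
  extensions.
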