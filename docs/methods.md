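# Methods

## Scope and model

`mirax` operationalizes a multi-layer argument for miRNA-mediated
repression in tumors and its prognostic value. The unit of analysis is an
*axis*: one miRNA with a direction of dysregulation (tumor vs normal) and
the set of predicted targets whose own dysregulation runs the opposite
way. Evidence is accumulated in four layers — differential expression,
cross-cohort consensus with inverse-direction target filtering, per-sample
target-set activity coherence, and survival modeling with locked external
transfer — each implemented as an independent module with explicit
contracts.

## Differential expression

Counts are filtered at linear CPM ≥ 1 in at least *m* samples, with *m*
defaulting to the size of the smaller group (standard edgeR-style
guidance; group-specific features survive). Between-sample scaling uses
TMM: reference = sample whose 75th-percentile CPM is closest to the mean
upper quartile; M-values trimmed 30% each side, A-values 5%; weights are
inverse delta-method variances; factors are rescaled to geometric mean 1.
Log-CPM uses a prior count of 0.5: `log2((c + 0.5)/(lib + 1) * 1e6)`.
Microarray-style inputs (`scale="log2"`) bypass filtering/TMM entirely.

The moderated t-test shrinks per-gene variances toward a prior:
`s̃²_g = (d0·s0² + d·s²_g)/(d0 + d)`, with `(d0, s0²)` from matching the
mean and variance of `log s²_g` via the digamma/trigamma identities of
log-chi-square variables (trigamma inverted by Newton iteration). The
statistic is referred to a t distribution on `d0 + d` df. Setting `d0=0`
recovers the ordinary t exactly; `d0=inf` uses the prior variance alone.
The paired design is analyzed as a one-sample moderated t on
within-patient tumor−normal differences over complete pairs — exact for
complete pairs and simpler than a mixed-model correlation approximation;
this is a deliberate substitution for the blocking-factor approach and is
noted in output metadata. Genes with zero variance are excluded before
prior estimation. Direction sets require BH q ≤ 0.05 *and*
|log2FC| ≥ 1 (mRNA) or ≥ log2 1.5 (miRNA); the lower miRNA gate reflects
the narrower dynamic range of miRNA expression.

BH adjustment is the step-up `q_(i) = min_{j≥i} m·p_(j)/j` capped at 1
(delegated to statsmodels).

## Consensus and axes

Meta-DEGs are per-direction intersections across cohorts, with the
threshold applied in each cohort (the stricter of the two readings of
"concordant"; logged in output). miRNA consensus requires the same
direction in *every* design/cohort; conflicting directions exclude the
miRNA silently (counted in the log). Predicted targets must appear in
both prediction resources; the inverse-direction filter then keeps, for an
up-miRNA, only targets in the consensus-down set (and symmetrically). The
result is exported as a bipartite edge list and GraphML.

Over-representation uses the upper-tail hypergeometric
`p = P[X ≥ k], X ~ HG(N, K, n)` over a CPM-filtered universe, terms
clipped to the universe and bounded to 3–500 members, BH across tested
terms. Both FDR < 0.05 and unadjusted p < 0.05 tiers are reported because
small query sets rarely survive correction. Symbol harmonization is
uppercase plus an optional alias map — deterministic and pluggable rather
than a frozen HGNC snapshot.

## Activity and coherence

Within tumors, duplicate symbols are collapsed by the per-sample median,
rows are z-scored with the sample SD (n−1; the `scale()` convention), and
an axis's activity is the unweighted mean z over its supported targets
present in the matrix (≥ 2 by default; single-target axes only by
explicit flag, since a 1-gene "set" is just that gene). Coherence is
mid-rank Spearman between miRNA log-CPM and activity over the
sample-ID intersection; p-values use the t approximation
`t = ρ√((n−2)/(1−ρ²))` for n ≥ 10 and the exact permutation distribution
below that; BH runs across the tested axes only. Quartile summaries order
samples by decreasing activity with a stable sample-ID tie-break.

## Survival modeling

The axis matrix holds exactly 8 molecular features (4 miRNA log-CPM
abundances, 4 activities) with per-feature training means/SDs stored at
assembly; only complete cases (features + time/event + age/sex/stage)
enter, and the drop tally is logged.

The penalized Cox fit minimizes
`-(1/n)·log PL(β) + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` with Breslow tie handling,
by IRLS with cyclic coordinate descent in covariance form (sufficient
statistics are p×p per IRLS step), soft-thresholding for the L1 part,
step-halving to keep the penalized objective monotone, and warm starts
along a λ path of log-spaced values from λ_max down four decades. λ_max is
the smallest λ with an all-zero solution (glmnet's α ↦ max(α, 0.001)
convention makes it finite for ridge). Divergence (‖β‖∞ > 30, monotone
likelihood) truncates the path at the last stable solution. At λ = 0 the
solver reduces to unpenalized Newton-type iteration and matches an
independent BFGS optimum of the Breslow partial likelihood to 1e-6.
Univariable fits (screen, High/Low contrasts) use lifelines with Efron
ties; the tie-rule split (Breslow inside the penalized fit, Efron for
univariable) is recorded in the model JSON.

Nested CV: one event-stratified outer 5-fold split shared by the
clinical / axes / combined specifications; standardization recomputed
inside each training fold only; (α, λ) tuned per training fold by inner
5-fold CV on the partial-likelihood deviance (ll(all) − ll(train) form);
held-out performance is Harrell's c-index. The function default α grid is
{0, 0.1, …, 1.0} with a 100-step λ path; the pipeline's run configuration
defaults to the coarser {0, 0.25, 0.5, 0.75, 1.0} × 50 steps, which keeps
a full synthetic run near two minutes without changing conclusions — pass
`alpha_grid`/`n_lambda` to restore the dense grid. The final model is fit
on all complete cases at the modal CV-selected α (smallest on ties), with
λ re-chosen by inner CV; its coefficients and standardization are frozen
into a JSON model.

Harrell's c-index counts pairs (i, j) with `t_i < t_j` and an event at
`t_i` (tied times not comparable); higher risk on the shorter time is
concordant, tied risks credit 0.5. Confidence intervals are percentile
bootstrap over samples (1000 resamples by default).

Locked external validation computes
`risk_i = Σ_j β_j (x_ij − μ_j^train)/σ_j^train` with no refitting. When
the validation cohort carries only a subset of model features (here: the
four miRNA abundances), scoring restricts to that subset with an explicit
warning — this feature-subset mode is the package's resolution of
transferring an 8-coefficient model through a 4-feature cohort. The
High/Low cutpoint comes from 5-fold CV inside the validation cohort: per
fold the training portion's risk quantiles 0.2–0.8 (step 0.05) are scanned
for the maximal log-rank statistic, and the final cutpoint is the mean of
fold optima (one reasonable instantiation of a CV cutpoint; the exact rule
is not canonical). Because the predictor is linear with frozen scale,
adding any per-feature constants to the validation matrix shifts all risks
equally: rankings, c-index and the High/Low partition are invariant, which
is asserted in tests.

The survival screen median-dichotomizes each gene (values equal to the
median go to Low — deterministic), runs KM + log-rank + a univariable Cox
HR on the High indicator, adjusts the log-rank p-values by BH across
genes, and shortlists at q ≤ 0.01. KM display tables are truncated at 120
months with numbers-at-risk at 24-month ticks.

## Synthetic data generator

The generator emulates a paired bulk tumor/normal study and defines the
package's standard study conditions; all defaults were fixed once, from
the design targets below, and are not tuned per test.

Counts are negative-binomial (`var = μ + φμ²`, φ = 0.15) around gene-wise
baselines `a_g ~ N(5, 1.8)` (log2, miRNAs `N(7, 1.5)`), converted to
library-scaled means at depths uniform in 0.8–1.2 M. Latent biological
noise is log-normal (gene SD 0.6, miRNA SD 1.0); matched tumor/normal
pairs share 40% of that latent variance (`patient_shared_fraction`), which
is what gives the paired design its power advantage. Planted DE
magnitudes are `|N(lfc_mean=2, lfc_scale=0.25)|` with direction by gene;
the four axis archetypes get ∓1.5 log2 shifts (one down "tumor
suppressor", three up "oncomiRs"). Each archetype has 12 true targets
drawn from the opposite-direction DE genes and decoy predicted targets
from the null genes; both prediction sources contain all true targets, a
shared decoy block, and source-specific extras, so the two-source
intersection is informative. Repression acts in tumors only: each true
target's latent log2 mean includes `−0.15 × z̃_m` where `z̃_m` is the
regulator's standardized latent deviation — sized so the observed Spearman
coherence is ≈ −0.40 at 120 tumors.

Survival is exponential with hazard
`λ_0 exp(β·x + clinical)`, `λ_0 = log 2 / 24` months, where `x` are the 8
standardized latent axis features (abundance z's and their negatives as
activities) and `β` defaults to (0.52, −0.46, 0.46, 0.40, −0.40, 0.35,
0.35, 0.29) — sized for an oracle c-index ≈ 0.75 in discovery and ≈ 0.70
for the miRNA-only validation predictor. Clinical covariates (age
N(60,10), sex Bernoulli(½), stage categorical I–IV) carry small hazards
(0.3/decade-SD, 0.3/stage) so the clinical-only specification beats
chance. Censoring is independent exponential calibrated to ≈ 35%, with
administrative censoring at 240 months.

The validation cohort redraws tumors under the same law, adds per-miRNA
batch offsets (a scalar `batch_shift` is the SD of per-feature log2
offsets — a *uniform* offset would cancel exactly under library-size
normalization), and generates survival from the miRNA part of β only; it
carries miRNA counts and survival, nothing else. Replicate discovery
cohorts reuse the gene-level truth but redraw the background (non-axis)
miRNA effects, modeling cohort-specific platform artifacts; the axis
archetypes are the only miRNAs guaranteed to replicate across designs.

A separate 25-gene screen panel ties hazards directly to gene expression
(7 effect genes at 1.0/SD, one adverse and six protective, n = 400) so the
univariable screen's power (≥ 0.95 per gene at BH FDR ≤ 0.01) can be
exercised independently of the indirect coupling in the main cohorts. The
panel size accounts for the attenuation of each gene's *marginal* hazard
ratio by the joint frailty of the other six effect genes: observed
median-split HRs are ~0.5–0.6 rather than the conditional exp(±1.6).

What the generator does *not* emulate: platform-specific microarray noise,
isoform/arm-level miRNA annotation, gene–gene correlation beyond the
planted regulator coupling, informative censoring, or missingness
mechanisms beyond missing-at-random stage. Passing recovery tests
therefore demonstrates the statistical machinery under a faithful but
idealized generative model, not performance on any real cohort.

A note on pairing and the unpaired test: because matched tumor/normal
samples share 40% of their latent variance, the unpaired two-sample
statistic is mildly conservative on partially paired cohorts (measured
null rejection ≈ 0.041 at nominal 0.05 with 40% pairing). Its type-I
calibration is therefore verified on fully unpaired null designs, where it
is exact; on paired data the paired design is the calibrated analysis.

## Numerical choices and degenerate inputs

- Row z-scores drop zero-variance rows with a warning; activities are set
  semantics (duplicate listings and target order cannot matter).
- Spearman p is NA (with reason) when either vector is constant.
- Empty inverse-filter results are valid axes with empty sets, warned.
- Zero library sizes, all-zero samples, missing model features and zero
  training SDs raise errors naming the offender.
- Coordinate-descent tolerances: 1e-10 on coefficients for single fits,
  1e-6 along CV paths (the KKT check tolerance); IRLS capped at 200 steps
  with step-halving.
- All randomness (simulation, folds, k-means restarts, bootstrap,
  cutpoint CV) descends from one top-level seed recorded in every output;
  reruns are checksum-identical.

## Problem sizes used by the test suite

The suite exercises the study conditions at sizes chosen for tight,
well-powered checks: DE recovery at 50 vs 50 with |log2FC| = 2 planted;
coherence and survival at the default 120 tumors; null calibration over
20 replicates (DE type-I, 200 decoy axes, null CV c-index); and the
screen panel at n = 200. The end-to-end determinism check runs a reduced
cohort (500 genes, 60 tumors) through every stage twice.

## Known limitations

- The paired analysis assumes complete pairs; unpaired samples are simply
  ignored in that design rather than recovered through a correlation
  structure.
- The cutpoint-selection rule inside validation CV is one defensible
  choice among several; cutpoints are reported so alternatives can be
  compared.
- The elastic-net path does not implement strong-rule screening; with 8–11
  features it is unnecessary.
- Breslow ties inside the penalized fit vs Efron in univariable fits is a
  documented asymmetry; with continuous simulated times the two coincide.
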