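# Methods

## The model behind the pipeline

The package operationalizes one idea: a single stromal transcriptional
program, marked by an anchor gene expressed in cancer-associated
fibroblasts, simultaneously (i) induces a module of co-expressed genes
visible in bulk expression across independent cohorts and (ii) worsens
survival. The derivation chain — per-cohort correlation screen, FDR
control, cross-cohort intersection, signature scoring, cutpoint-based
stratification, Cox modelling, subtype transfer, and an invasiveness
filter against pre-malignant tissue — treats each of those claims as a
testable computation.

## Statistical procedures

**Correlation screen.** Pearson r of every gene against the anchor row;
two-sided p from the exact t transform `t = r·√((n−2)/(1−r²))` on n−2 df;
Benjamini–Hochberg step-up q within cohort over all screened (collapsed,
non-constant) genes. Selection uses strict inequalities `r > r_min`,
`q < q_max`; the default is one-sided positive (`sided="absolute"` is
available). Genes with zero variance are excluded and counted; genes
missing from any cohort simply cannot enter the intersection.

**Probe collapsing.** Many-to-one probe→gene maps; a gene's row is the
arithmetic mean of its probe rows per sample. Unmapped probes are dropped
with a logged count. Missing expression values are never imputed: rows
containing them are dropped at read time, keeping matrices finite.

**Differential expression.** `log2fc` is the difference of group means on
a log2-scale matrix. `welch` is the unequal-variance t-test with
Welch–Satterthwaite df. `moderated` (default) shrinks the pooled per-gene
variance toward a scaled inverse-chi-square prior whose parameters
(d₀, s₀²) are moment-matched on the log sample variances — the digamma/
trigamma identities of the classical empirical-Bayes microarray moderation;
the trigamma inverse is a Newton iteration. When the log-variance spread
does not exceed the chi-square expectation, d₀ = ∞ and all genes share
s₀². A variance floor of 1e−8 guards degenerate genes (flagged in the
log). Agreement with the reference R implementation (limma::eBayes) is
verified in the test suite to ~1e-6 relative on t. DGE filters are strict:
`|log2FC| > 1`, `q < 0.05`. The invasiveness signature is the exact
three-way intersection up-vs-premalignant ∩ up-vs-normal ∩ anchor
signature, in sorted gene order.

**Scoring.** Signature score = unweighted mean of row-z-scores (ddof=1)
over the signature genes present; the aggregation is a documented
convention — the heatmap-scaled expression the field displays implies a
z-scale, and the unweighted mean keeps the score invariant under gene-wise
affine transforms. Marker-population scores follow the MCP-counter rule:
arithmetic mean of *raw* log expression per population — comparable across
samples within a population, not across populations. Over-representation
uses the upper-tail hypergeometric p with BH across annotation sets
(default flag at q < 0.01); the universe defaults to the analyzed matrix's
genes.

**Survival machinery.** Kaplan–Meier, the log-rank test and the entire
maxstat search are native implementations (the cutpoint search is defined
by exhaustive agreement with the log-rank test, so the two must share one
code path). KM confidence bands use Greenwood variance on the log(−log)
scale; the median is the smallest event time with S(t) ≤ 0.5 and its CI
inverts the pointwise bands (Brookmeyer–Crowley). The log-rank statistic
accumulates `U = Σ(d1i − n1i·di/ni)` and the hypergeometric variance over
distinct event times. Maximally selected cutpoints consider midpoints
between consecutive distinct score values leaving at least
`ceil(minprop·n)` samples per side (minprop = 0.1, the reference maxstat
default); the observed statistics reuse the log-rank accumulation verbatim
(bit-exact against enumeration), while the permutation null — p =
(1 + #{perm max ≥ observed max})/(1 + n_perm), seeded — runs through a
vectorized cumulative-sum kernel over the same per-event-time constants.
The permutation p is the primary (and only) selection p-value; the
Lausen–Schumacher improved-Bonferroni approximation is not implemented.
Ties at the maximum resolve to the smallest cutpoint. Quantile
dichotomization uses the linear-interpolation empirical quantile with
strictly-greater "high" labels, so threshold ties fall low. Cox models
delegate to lifelines (Efron tie handling, Wald CIs); zero-variance and
collinear designs are rejected before fitting; the univariate screen
refits jointly all covariates with univariate p < 0.05.

**Subtypes.** Per-subtype signatures come from one-versus-all moderated
DGE ranked by ascending p, then descending |t|, then gene id (the stable
residual tie-break); the centroid is the subtype's mean profile over its
own signature genes, and assignment correlates each sample with each
centroid on that centroid's own gene space (argmax; ties go to the
lexicographically first subtype and are flagged; samples with no defined
correlation are "unassigned"). Clustering is a single hierarchical pass —
average linkage on 1 − Pearson between samples — cut into k branches that
are relabeled deterministically by ascending mean of a supplied score, a
reproducible stand-in for manual branch annotation. Consensus-style
resampling is deliberately out of scope.

## Synthetic data: what it emulates and what it does not

`generate_cohort` implements a single-latent-factor model: per sample
f ~ N(0,1); anchor row λₐ·f + ε, module rows λ_m·f + ε, background rows
pure ε with ε ~ N(0, σ²); survival is exponential with hazard
h₀·exp(β·f), censored by an independent Uniform(0, censor_max). This is
the minimal structure producing a cross-cohort-consistent correlated
module plus a survival signal from one common cause. Closed forms follow:
the anchor–module correlation is λₐλ_m/√((λₐ²+σ²)(λ_m²+σ²)), which the
tests verify by simulation. Defaults are one realistic resected-PDAC
cohort: n = 250 samples, 5000 genes, a 24-gene module, λ = 0.8 against
σ = 1 (true anchor–module r = 0.39), β = 0.5, h₀ = ln2/20 per month
(median OS 20 months at factor 0), 60-month censoring window. Expression
and survival draw from independent child streams of the root seed, so
changing the censoring horizon never perturbs expression.

The PanIN-style generator plants genes up-shifted in carcinoma with a
controllable overlap between the vs-premalignant and vs-normal contrasts
(genes exclusive to one contrast are also elevated in the other reference
group, so the complementary contrast is null for them). The subtype
generator imprints signed ±effect patterns on disjoint gene blocks shared
across cohorts — patterns rather than level shifts, because a
correlation-based centroid classifier is blind to uniform offsets. The
cutpoint generator plants a hazard step (default HR 2.5) at a known score
quantile.

None of the generators model batch effects, probe saturation, library-size
artifacts, non-proportional hazards, or cohort-specific platform bias.
Passing recovery tests therefore shows the machinery is correct under the
stated model, not that the biological findings would replicate on new
cohorts; the original cohort-level results (specific thresholds, medians,
hazard ratios) depend on access-controlled data and are out of scope.

## Numerical and design choices

* Gene identifiers are stripped/uppercased at every entry point before any
  set operation; cross-platform reconciliation is symbol-level.
* BH is exactly the step-up definition (suffix minimum of m·p(j)/j, capped
  at 1); p-values are clipped into (0,1] at the float-tiny bound before
  adjustment.
* The bundled demo pipeline and the acceptance script screen at
  r > 0.3 in all three simulated cohorts: under the generator's closed
  form the planted module sits at r = 0.39, so 0.3 is the threshold that
  separates module from background at the default loadings.
* Degenerate inputs fail loudly and early: constant anchors, all-constant
  matrices, empty universes, single-group log-rank, zero-information
  splits, negative times, non-binary events, collinear Cox designs.
* An empty cross-cohort intersection is a clean terminal pipeline state,
  not an exception.
* Problem sizes in the test suite (cohorts of 60–250 samples, 300–5000
  genes, 50–200 simulation replicates, 200-permutation nulls) are chosen
  so the full statistical battery — enumeration oracles, KS calibration
  checks, coverage simulations — completes in about two minutes.

## Known limitations

* The moderation prior assumes a common scaled inverse-chi-square across
  genes; heavy-tailed variance distributions would call for the robust
  variant, which is not implemented.
* Maxstat returns a single best cutpoint; no confidence region for the
  cutpoint location is provided.
* Cox modelling is right-censoring-only, no time-varying covariates or
  competing risks; RFS-style endpoints are handled by relabeling columns.
* The GMT reader accepts only the tab-separated Broad dialect.
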