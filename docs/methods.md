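# Methods

## The differential-correlation model

The unit of analysis is an (RNA, miRNA) expression pair. Over the n
normal samples of a cancer type the pair has a baseline Pearson
correlation PCC_n; appending a single tumour sample and recomputing
gives PCC_{n+1}, and the tumour sample's differential correlation is
ΔPCC = PCC_{n+1} − PCC_n. Because the normal cohort is fixed, ΔPCC is a
per-sample feature: two tumour samples perturb the same pair by
different amounts, which is what makes single-sample (patient-level)
analysis possible. ΔPCC is bounded in [−2, 2] and is zero exactly when
the appended sample sits at the normal mean of both features.

Correlations are computed on the expression scales as provided (TPM for
RNA, CPM for miRNA) with no log transform. CPM uses per-sample library
size equal to the column sum of the count matrix. Features with zero
variance across normal samples are removed before any correlation is
formed (the filter criterion is exact: min equals max over normals), so
the denominators below are always positive and no epsilon guard is
needed.

## The incremental update and its exactness

The engine reduces the normal cohort once to sufficient statistics —
per-feature means and sums of squared deviations (SS), and the per-pair
covariance numerator (CN) — and absorbs each tumour point (x, y) in
closed form:

    PCC_{n+1} = [CN + f (x − X̄)(y − Ȳ)] /
                sqrt(SS_X + f (x − X̄)²) / sqrt(SS_Y + f (y − Ȳ)²),

with f = n/(n+1). The factor f is required for exactness in the
numerator as well as the denominators: the single-point increment of the
centered cross-product is (n/(n+1))(x − X̄)(y − Ȳ) once the means are
updated. A circulating form of this update carries f only in the
denominators; we implement the exact update by default and expose the
uncorrected-numerator variant behind `as_printed=True` purely for
comparison. On a four-point example (normals (1,1), (2,2), (3,3);
tumour (4,0)) the exact update reproduces the brute-force PCC₄ = −0.2
while the uncorrected variant yields −0.4.

Exactness is enforced by a dual-route check: the definitional path
(`pcc_matrix`, two full Pearson computations) is kept as an independent
oracle, and tests require agreement within 1e-10 absolute across random
cohorts of 20–200 RNAs × 10–50 miRNAs × 5–60 normals × up to 20 tumour
samples. Observed disagreement is at the 1e-15 level, i.e. double-
precision rounding; the 1e-10 tolerance leaves headroom for poorly
conditioned inputs. Computed correlations are clipped to [−1, 1] to
absorb last-ulp excursions.

The retained state is O(k + #features), independent of n: after
`precompute_normal_stats` the normal expression matrices can be
discarded, and computing ΔPCC for any number of tumour samples touches
only the state. Feature order is frozen lexicographically in the state
so the flattened RNA-major pair index is reproducible. The on-disk
store chunks the pair dimension (default 10⁶ pairs per chunk) to bound
memory at full scale, with a JSON manifest recording offsets and
round-trip-exact float serialization.

## Site-specific screening

For each metastatic site, tumour samples *with metastasis information*
are partitioned into site-positive and site-negative groups (a sample
with several recorded sites is positive for each; samples with
metastasis information but no recorded site are site-negative
everywhere). ΔPCC is not normally distributed, so group differences are
assessed with the two-sided Mann–Whitney U test. Following the source
method's rationale, raw p < 0.001 defines significance and no
multiple-testing correction is applied — a stringent raw threshold keeps
rare sites with small cohorts in play, and the report carries the
number of tests performed so users can post-correct if desired. Sites
with fewer than 5 positive samples are skipped entirely; a site-negative
group below 5 triggers a warning but not a skip (the source method
states no minimum for that group).

Test variant: exact enumeration when the pooled sample is ≤ 12 with no
ties; otherwise the normal approximation with midranks, tie correction
and continuity correction (scipy's implementation behind the module
surface). The switch point keeps the p-value exact where the 5-sample
minimum makes approximation poorest. A pooled sample that is entirely
constant carries no rank information and is reported as p = 1.

Ranking among significant pairs is deterministic: ascending p, then
descending |median difference of ΔPCC|, then ids. The top-k (default
100) pairs form the exported site network. Per-site unique pairs are
those significant at no other site of the same cancer type;
cross-cancer intersections use exclusive (UpSet) semantics, so the
combination counts sum to the size of the union.

## Survival analysis

For a chosen pair and site, each cohort (site-positive and
site-negative) is stratified at its **own** median ΔPCC — the dual-plot
design shows each cohort with its own two strata, and the median of a
site cohort is the natural split point within it. Values exactly at the
median join the low stratum (a fixed convention; the alternative
assignment changes group sizes by at most the number of tied samples
and is documented rather than configurable). Strata are compared with
the standard two-group log-rank test (lifelines), p from χ²(1); a
label-permutation mode exists for very small cohorts. Cohorts with
fewer than two usable samples, an unsplittable (constant) ΔPCC vector,
or zero events are reported as not evaluable rather than raising.
Kaplan–Meier curves are the product-limit estimates at the distinct
event times; censored times reduce the risk set without adding factors.
The survival endpoint is whatever (time, event) columns the clinical
table provides; the column mapping is configuration.

## Preprocessing conventions

RNA-seq and miRNA-seq aliquots are paired at the vial level of
TCGA-style barcodes (first four hyphen-delimited fields); plain ids
fall back to exact-string equality so synthetic cohorts need no
barcodes. When a vial has several portions, non-FFPE portions are
preferred; among the eligible portions (all of them, when every portion
is FFPE or of unknown status) the lexicographically earliest portion id
wins, making the choice order-independent. Unmatched samples are
reported and logged, never silently dropped. Cancer-type eligibility
requires follow-up site information, ≥ 10 normal samples, and ≥ 5
samples at some metastatic site. Site names are cleaned (case-fold,
trim, collapse internal whitespace) but not ontology-mapped; diagnosis
and follow-up site records are unioned per sample.

## The synthetic cohort generator

The generator emulates the statistical structure the screening method
assumes, not TCGA biology. Each feature has a latent standard-Gaussian
value per sample; designated (RNA_j, miR_j) pairs share latent
correlation `baseline_corr` (default 0.5). Latents map to observed
expression through exp(0.5·z + 2), giving non-negative, right-skewed,
TPM/CPM-like values; the modest log-scale SD of 0.5 keeps the
observed-scale Pearson correlation close to the latent target (at a
latent 0.9 the lognormal attenuation is ≈ 0.01), which is verified
empirically in tests. Defaults — 30 normals, 40 tumour samples, two
sites of 10 positives each, 30 × 20 features — describe a small cohort
that clears every screening threshold while keeping the full pipeline
interactive.

A planted site effect displaces the pair's two values in opposite
directions (RNA up, miRNA down, by `shift` latent SDs) in site-positive
samples only; with the default positive baseline correlation this
drives the pair's ΔPCC consistently negative there, with magnitude
growing in `shift`. The displacement necessarily also perturbs the
planted features' other pairs (one row and one column of the pair
matrix), so precision against the truth ledger is informative but not
expected to be 1 at small shifts.

Survival times are exponential. Within the prognostic pair's designated
site cohort, the low-ΔPCC stratum of that cohort's own median split
(the same convention the analysis uses) has its hazard multiplied by
`hazard_ratio`; every other patient carries the base hazard (median
survival 1000 days), so the site-negative cohort is a true survival
null. The default hazard ratio is 6: by the Peto approximation the
log-rank z-mean is (HR−1)/(HR+1)·√d, and with 60 patients per cohort at
event rate 0.7 (d ≈ 42) this gives ≈ 98% power at two-sided α = 0.01 —
a planted effect strong enough that failing to recover it indicates a
defect rather than sampling noise. (The more common ln(HR)·√(d/4)
approximation overstates power for hazard ratios this large.)
Censoring is exponential with per-sample rate λ·c/(1−c), which makes
the expected censored fraction exactly `censor_rate` (default 0.3, i.e.
event rate 0.7) in every stratum. All randomness flows from a single
integer seed; identical specs produce bit-identical cohorts.

What passing tests on these cohorts does **not** show: robustness to
library-size heterogeneity, batch effects, miRNA-target biology,
non-lognormal marginals, or informative censoring — none of which the
generator emulates.

## Calibration checks and their design

Type-I calibration composes many independent replicate cohorts (100
cohorts × 1000 pairs = 10⁵ pair-tests) rather than one large cohort:
pair tests within a cohort share features and a single group split, so
they are positively dependent, and replication restores the
independence that a binomial reference band assumes. Group sizes are
40/40; the attained level of the continuity-corrected normal
approximation at nominal α = 0.001 was computed exactly (dynamic
programming over the null U distribution) as 8.1 × 10⁻⁴ — the test is
conservative at this tail, which the acceptance band accounts for.
Null log-rank uniformity is checked by Kolmogorov–Smirnov distance over
2000 replicates of two 30-patient exponential groups with 30%
censoring.

## Numerical and degenerate-input conventions

- Zero-variance features: error at precompute, not silent exclusion —
  filtering is the preprocessing step's responsibility.
- ΔPCC tensors validate finiteness and the [−2, 2] bound on
  construction.
- Stores reject out-of-order chunk writes and missing chunks on read.
- CPM re-normalization of CPM input is accepted and is a no-op, making
  the operation idempotent.
- TSV floats are serialized with `repr` (shortest round-trip form) and
  parsed with round-trip precision, so write→read is bit-exact and
  reruns with the same seed are byte-identical.

## Known limitations

- Dense all-pairs computation: no restriction to predicted miRNA-target
  pairs; at full scale the chunked store bounds memory but not compute.
- Pearson correlation assumes linear association on the given scales;
  strongly nonlinear RNA–miRNA relationships are invisible to ΔPCC.
- The screening p-values are raw by design; at genome scale users
  should post-correct using the reported test counts.
- FFPE status must be supplied as a flag; it is not inferred from
  metadata.
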