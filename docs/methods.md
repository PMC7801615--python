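# Methods

`compdecon` analyzes paired (treated vs vehicle) bulk RNA-seq from colon
organoids through the lens of cell composition: it builds a cell-type
signature from labeled single-cell counts, regresses each bulk mixture on that
signature to obtain per-sample cell-type scores, tests composition shifts
between arms, and fits negative-binomial models that either adjust for
composition or test cell-type-specific treatment responses. This note records
the model, the parameters that matter, and the choices made where the design
was genuinely open.

## Single-cell reference processing

Cells are kept when they have strictly more than 250 detected genes and a
mitochondrial count fraction strictly below 15% (both boundaries strict; a
cell at exactly 15% is removed). The mitochondrial fraction is computed on
raw counts — the conventional choice; normalized values would give the same
ordering in practice. The default label policy removes populations that
cannot be separated reliably in a linear basis (M cells, mature goblet and
colonocyte, colonocyte progenitors, cycling and secretory TA) and merges the
immature-colonocyte and remaining TA subpopulations, leaving six populations:
stem, TA, immature colonocyte, immature goblet, enteroendocrine, tuft.
"TPM" for droplet-style single-cell counts is implemented as counts-per-million
(no length correction — there is no defensible length model for 3'-tag data).

## Signature construction

For each cell type a one-vs-rest Welch t-test on log2(CPM+1) yields per-gene
p-values; Benjamini–Hochberg q-values are computed within each cell type's
family. Candidate markers are genes with q < 0.001 and positive fold change
(log2 of pseudocounted CPM means), ranked by log2FC descending, then p
ascending, then gene id — a fully deterministic ordering. Genes whose maximum
per-type mean CPM falls below 0.15 are removed first (an expression floor;
the only reading of a single scalar cutoff that is consistent across types).
For every per-type count G in [100, 600] the union of each type's top-G
candidates defines a basis of per-type mean CPM; the basis minimizing the
2-norm condition number wins (smallest G on ties; G is capped at a type's
candidate count with a warning). A low condition number means well-separated,
numerically invertible cell-type columns — exactly what the downstream
regression needs. Cell subsampling (`sampling_fraction`, default 1.0) is
seeded; quantile normalization is disabled by design and requesting it raises.

A note on selection metrics: because markers of *other* types are also
BH-rejected (their two-sided p-values are tiny), the effective step-up
threshold for true null genes approaches the q cutoff itself, so the raw
candidate lists occasionally admit a near-zero-fold-change false positive.
Such genes rank last and are dropped by the chosen top-G, so selection
quality should be judged as the two stages are used: recall on the candidate
lists, precision on the selected basis.

## Deconvolution

Each mixture (one bulk TPM column restricted to signature genes, at least 10
shared) is z-scored by its own moments; the signature is z-scored by its
global moments, shared across samples so scores are comparable between
samples. A linear-kernel nu-support-vector regression is fitted for
nu ∈ {0.25, 0.5, 0.75} and the fit with the smallest reconstruction RMSE is
kept; negative coefficients are clamped to zero and normalized to relative
fractions. Non-negative least squares on the raw linear problem provides the
deterministic convex oracle — on noiseless mixtures NNLS is exact to 1e-6 and
the SVR agrees within ±0.02, which is the wedge that validates the SVR path.

Permutation p-values shuffle the mixture across genes and re-fit at the
winning nu: p = (1 + #{permuted r ≥ observed}) / (n + 1). They are a
per-sample goodness-of-fit diagnostic, consumed by nothing downstream, so the
pipeline default is 0 permutations; the operation itself is exact and seeded.

Absolute scores rescale fractions by
median(mixture TPM over signature genes) / median(signature entries), so a
sample that expresses the signature weakly gets a low total score — the
property that lets the two arms differ in total cellularity signal. Scaled
scores are absolute scores centered and scaled (unit variance, ddof 1) per
cell type *within each analysis stratum* (all / left / right / by sex),
mirroring the rule that stratified analyses are self-contained. Raw totals
enter the total-score test without further normalization.

## Composition tests

Per cell type, the per-subject differences d_i = score(control) −
score(treated) feed a paired t-test with a 95% t-interval. The sign
convention is control − treated throughout: a cell type expanded by treatment
has a negative mean difference. With fewer than 3 pairs the test refuses to
run; zero-variance differences return an exact tie (p = 1) with a warning.

## Differential expression

Counts are normalized by median-of-ratios size factors (genes observed in all
samples only). Three designs share one NB GLM engine (log link, log size
factors as offset, IRLS to relative tolerance 1e-8, at most 100 iterations):

1. unadjusted: `~ pair + treatment`, Wald test on treatment;
2. adjusted: `~ pair + scaled scores (all six) + treatment`, Wald on
   treatment; if the score block makes the design rank deficient, score
   covariates are dropped greedily by variance-inflation factor and reported;
3. interaction, one cell type k at a time: full `~ pair + score_k + treatment
   + treatment:score_k` vs reduced without the interaction, statistic
   2·(Δ log-likelihood) referred to chi-square with 1 df.

Dispersions are per-gene Cox–Reid adjusted profile maximum likelihood given
Poisson-fitted means (the CR term compensates the many pair-indicator
nuisance parameters), with a method-of-moments fallback and a 1e-8 floor, and
are then moderated toward the experiment-wide median log-dispersion. The
moderation weight is the robust (MAD-based) between-gene spread in excess of
the expected sampling noise trigamma(df_res/2): when the observed spread is
pure estimation noise the estimates pool, while genuine between-gene
differences survive. Without moderation, ~31 residual degrees of freedom
leave enough noise in individual dispersions that chance under-estimates
inflate the far tail of the p-values and with it the realized FDR; with it,
the null type-I error at p < 0.05 sits near 0.05–0.06 (the small residue is
the finite-sample behaviour of the chi-square reference with ~37 parameters
on 68 samples, which is retained deliberately as the standard reference).

BH correction (step-up, hand-implemented and oracle-tested) is applied per
results table at alpha 0.1; genes with all-zero counts or non-convergent fits
are excluded from the family and logged. When interaction tables exist for
several cell types, per-gene collation keeps the row with the smallest p
(ties: smaller q, then lexicographic cell-type name), preserving the full
per-type tables.

## Enrichment

The overlap grid counts up/down DEGs (by coefficient sign) intersecting each
marker list at the nominal p < 0.05 and the FDR level. Enrichment is the
one-sided (greater) hypergeometric tail with the universe equal to the genes
actually tested in that DE run — enrichment against untested genes would
inflate odds ratios. The sample odds ratio is (a·d)/(b·c), +inf when b·c = 0
with a·d > 0.

## Synthetic data: what it emulates and what it does not

The generator draws six cell-type expression profiles with log-normal
baselines (σ = 1.2) and disjoint marker sets elevated by `marker_log2fc`
(default 3, i.e. 8-fold); mitochondrial genes share one profile across types
(~4.5% of counts). Single-cell libraries are log-normal around 2×10⁴ counts;
a configurable fraction of cells is planted to fail QC (tiny libraries or
20–50% mitochondrial load). Bulk samples are paired: one Dirichlet
composition per subject (default concentration (1.6, 2.8, 1.6, 1.2, 0.4,
0.4): TA-dominant, rare enteroendocrine/tuft), shared by both arms, with the
treated arm's log-proportions shifted additively and renormalized — a
compositional shift that stays in the simplex for any effect size. The
default shift expands TA and depletes the immature absorptive/secretory
lineages; right-colon subjects receive the shift scaled by
`location_modifier` (default 0.4), giving the left colon the stronger
response. Planted cell-type-specific effects multiply a treated sample's
expression of chosen well-expressed non-marker genes by
2^(log2FC × proportion of the target type) — exactly the signal shape the
interaction LRT is built to detect. All counts (single-cell and bulk) are
negative binomial with a shared dispersion (default 0.02 for the paired bulk
design, where pair indicators absorb between-subject variation); TPM is
computed from counts.

Not modeled: doublets, ambient RNA, batch effects, gene length variation,
library-preparation composition biases, and any within-arm correlation beyond
the shared subject composition. Passing tests therefore demonstrate that the
estimators recover the planted statistical structure, not that they are
robust to every artifact of real single-cell or bulk data.

## Numerical choices and degenerate inputs

IRLS initializes from a least-squares fit of log(y + 0.5) − offset, clips the
linear predictor to ±30, and declares convergence on relative log-likelihood
change < 1e-8. Rank-deficient designs are rejected (the adjusted model drops
score covariates first). Condition numbers declare rank deficiency (+inf)
when σ_min ≤ σ_max × 1e-12. Constant genes get p = 1 by convention in the
marker test; zero-count cells are dropped with a warning before CPM; an
all-nonpositive coefficient vector in deconvolution returns uniform fractions
with a warning. Every stochastic step takes an explicit seed, and the
pipeline derives per-stage seeds from the run seed by hashing the stage name,
so stages re-run independently and byte-identically.

## Validation studies and their problem sizes

`scripts/acceptance.py` (and the mirror tests in `tests/test_acceptance.py`)
re-runs eight studies at desk scale, chosen so the full battery completes in
a few minutes: noiseless-mixture oracle agreement; fraction recovery on 20
paired mixtures under log-normal (sd 0.1) noise; signature selection quality
with 150 planted markers per type at 200 cells/type, including an independent
brute-force condition-number sweep; null calibration of the interaction LRT
on ≥2000 gene-tests at 34 pairs; recovery of 100 planted TA-specific effects
(log2FC 1.5); detection of a 0.3-SD TA composition shift over 100 replicates
(via the NNLS estimator, the deterministic solver, with the location modifier
set to 1 so every subject carries the stated effect); exact-oracle agreement
for BH and the hypergeometric tail; and the marker-overlap direction pattern
(TA up, immature lineages down, left > right).

## Known limitations

- The effect recovery study's per-gene power is governed by ln2 · log2FC ·
  sd(p_TA); the realized spread of the composition draw at 34 subjects varies
  between runs and moves all planted genes' power together, so its recall
  fluctuates noticeably between seeds even though ranking (AUROC) is stable.
- The chi-square reference for the 1-df LRT is mildly anticonservative with
  ~37 parameters on 68 samples (type-I ≈ 0.06 at nominal 0.05); this is the
  standard reference for this model family and is kept.
- Absolute scores are a median-ratio approximation of "overall signature
  expression"; their essential property — totals can differ between arms —
  holds, but the scale is not calibrated to cell counts.
- The paired t-interval is a symmetric t-interval; no attempt is made to
  reproduce any asymmetric interval construction.
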