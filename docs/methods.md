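# Methods

This note documents the models, statistics and numerical conventions
implemented in `stromabalance`, the choices made where the design was
genuinely open, and what the synthetic validation does and does not show.

## Tissue-mixture model

A bulk prostate sample is modelled as a convex mixture of three latent
tissue expression profiles — cancer, stroma and benign epithelium — on a
log2 scale.  Mixing happens in linear space: if `f = (f_c, f_s, f_e)` are
the tissue fractions of a sample and `x_t` the latent log2 profile of
tissue `t`, the sample's expression of gene `g` is

    y_g = log2( f_c·2^{x_cg} + f_s·2^{x_sg} + f_e·2^{x_eg} ) + ε + b,

with `ε ~ N(0, noise_sd²)` i.i.d. per gene and sample and `b` a constant
cohort baseline offset.  Linear-space mixing is the physically correct
model for bulk RNA: transcripts from different tissue compartments add as
molecule counts, not as log intensities.

Cancer samples mix all three tissues; normal samples have a cancer fraction
of exactly zero.  Tissue fractions are Dirichlet-distributed with
class-specific means; the stroma means (0.25 for cancer, 0.50 for normal by
default) encode the documented sampling bias of higher stroma content in
normal samples, which is the confounder the whole pipeline is built to
counter.  The Dirichlet concentration (default 10) sets the realistic
sample-to-sample spread of tissue composition (stroma-fraction SD ≈ 0.13).

### Planted gene classes

- `stroma_up` / `stroma_down`: the stroma profile is shifted ±2 log2 units
  (a strong but realistic marker-gene effect, ~4-fold per pure tissue).
- `cancer_de_down`: the confounded pattern — epithelium +1, cancer 0,
  stroma −2.  The true cancer-vs-epithelium effect is a 2-fold decrease.
- `cancer_de_up`: the mirrored pattern — epithelium −1, cancer 0,
  stroma +0.5.

The stroma gaps of the cancer_de classes are chosen so that, at the default
tissue-fraction means, the stroma gradient approximately cancels the true
cancer-vs-epithelium difference in the pooled cancer-vs-normal contrast:
for the down class the normal-group mean is
`0.5·2^{-2} + 0.5·2^{1} = 1.125` times the base level and the cancer-group
mean `0.45 + 0.25·2^{-2} + 0.30·2^{1} = 1.1125` — a residual difference of
about 0.015 log2 units, i.e. essentially invisible at any realistic sample
size.  These genes are therefore genuinely hidden in an unstratified
analysis and only become detectable when the compared groups are matched in
stroma content.  This is the planted analogue of the rate-limiting
cholesterol-synthesis enzyme's behaviour that motivates the method: a gene
high in epithelium, intermediate in cancer and low in stroma flips from
"not significant" (unstratified) to "strongly down in cancer" (balanced)
to "up in cancer" (unbalanced, where it really measures cancer vs stroma).

Noise (`noise_sd = 0.5` log2 units) and effect sizes were fixed a priori so
that planted effects are detectable at ~100 samples per cohort; no
published effect-size or noise magnitudes exist for this tissue system, so
these are calibration choices of the generator, not literature values.

The default five-cohort study suite shares one draw of latent profiles and
planted classes across cohorts (the same biology measured five times) while
drawing samples, noise and cohort baseline offsets independently; the first
two cohorts are sized 116 cancer / 40 normal and keep their histopathology
(emulating a fully reviewed prostatectomy series), the other three are
100/50 with histopathology blanked.  Cohort baseline offsets default to a
±1 log2 spread.

### What the generator does not model

Reactive stroma as a distinct fourth tissue, precancerous epithelial
aberrations, probe-level microarray structure, platform-specific dynamic
ranges, and gene–gene correlation beyond that induced by shared tissue
fractions.  Passing recovery tests on this generator shows the pipeline's
statistics behave as designed under the stated mixture model; it does not
show that real prostate cohorts satisfy that model.

## Differential expression

The per-gene test is the two-sided Mann–Whitney–Wilcoxon rank-sum test
throughout — per cohort and in the meta-analysis — so the whole stack is
rank-based and invariant to any strictly monotone per-sample (scoring) or
per-cohort (meta) transform of expression.  Groups of ≥ 8 samples each use
the tie-corrected normal approximation without continuity correction;
smaller layouts are tested exactly by enumerating all assignments of
samples to groups, which handles ties correctly (the two-sided exact p is
the fraction of assignments whose U deviates from the null mean at least as
much as observed).  Enumeration is capped at 200,000 combinations — e.g. a
3 vs 100 layout would enumerate ~10^5 but 5 vs 100 would not — beyond which
the normal approximation is used.  Constant genes report p = 1 and
direction "up" by convention.  The direction is the sign of the
rank-biserial shift of the cancer group; `log_fold_change` is the
difference of class means on the stored log-like scale (reported
descriptively; the test itself uses ranks only).

Significance ranks (1 = best) break p-value ties lexicographically by gene
id, making every ranking deterministic.

Benjamini–Hochberg q-values support an `m_total` larger than the number of
genes tested, implementing the conservative convention of correcting every
display at the full cross-cohort gene-identifier count; the default is each
analysis's own gene count (per-cohort) or the union gene count (pipeline).

### Probe collapse

For multi-probe platforms, one probe per gene is retained by one of three
strategies: most significant average p-value rank over several analyses
(e.g. unstratified, balanced, unbalanced), the same with a single analysis,
or highest mean expression.  "Best average rank" is interpreted as the
numerically smallest mean rank position (rank 1 = most significant); ties
break by probe id.

## Stroma gene-set derivation

Genes are ranked by `p_score = p_unbal / p_bal²` ascending (best candidates
first).  p-values enter uncorrected — the score compares raw evidence
between two equally powered contrasts, and FDR correction would apply the
same monotone transform to both.  The stroma direction of a gene is the
direction of its unbalanced shift toward the high-stroma group (the normal
samples in the standard design), the contrast that maximizes stroma signal
by construction.  Up- and down-regulated genes are ranked separately and
the top N per direction retained, after removing any caller-supplied
exclusion list (e.g. a pathway under study, to preclude circularity).
Genes more significant in the balanced than the unbalanced contrast are not
filtered, only down-ranked by the formula.

## Single-sample enrichment score

The classic unweighted Kolmogorov–Smirnov running sum (enrichment weight
exponent 0): genes ranked by descending expression within the sample (ties
broken by gene id), set members step +1/|S|, non-members −1/(N−|S|), and
the score is the running sum's signed maximum absolute deviation (first
such position on exact ties).  The unweighted variant depends on
within-sample ranks only, which maximizes comparability across microarray
and RNA-seq platforms; expression-weighted variants would couple the score
to each platform's intensity scale.

A sample's raw stroma score combines both directional sets as
ES(up) − ES(down).  Scores are computed at a ladder of gene-set sizes
(100, 150, …, 500, 1000 for full-scale cohorts; 20, 30, …, 100, 200 for the
2000-gene synthetic suite, the same ladder scaled to the smaller universe
and 200-gene sets), each size is affinely normalized to 0–100 over the
cohort's samples, and the per-size scores are averaged.  Normalization is
strictly per scoring call (one cohort): cohorts differ in baseline
enrichment, so no absolute cross-cohort stroma percentage is defined — the
score supports relative within-cohort ordering, which is all stratification
needs.  Degenerate cases (a single sample, or constant raw scores at some
size) normalize to 50 with a warning.

All scoring runs on the gene universe shared by every participating cohort,
so that a gene measured in only some cohorts cannot tilt the scores.

Calibration to histopathology is ordinary least squares of the pathologist
stroma percentage on the score (that orientation turns a score into a
predicted percentage); reported are slope, intercept, Pearson r and the
mean absolute deviation of fitted vs observed percentages, with predictions
clipped to [0, 100].

## Stratification

Within each class, samples are sorted by stroma value (histopathology
percentage or enrichment score — any strictly increasing transform yields
identical assignments).  The top-stroma half of the cancers joins the
bottom-stroma half of the normals to form the balanced dataset; the
complementary halves form the unbalanced dataset.  Equal group sizes in the
two datasets keep their statistical power identical, which is what makes
p-values comparable gene by gene.  With an odd class count the median
sample is dropped rather than assigned arbitrarily; stroma ties break by
sample id.  A `fraction` parameter (default 0.5, i.e. halves) allows
smaller symmetric tails with the middle excluded.  Cohorts lacking normal
samples are split at the class median into high/low-stroma groups instead,
with no differential contrast constructed.

## Meta-analysis

Per cohort, each gene's values are rank-normalized to 0–100 (average ranks
on ties, rank 1 → 0, rank n → 100) and mean-centered.  Weighted centering
subtracts the unweighted average of the cancer and normal class means,
½·mean_cancer + ½·mean_normal.  The stated purpose of the weighting is to
remove mean-value biases caused by the large class imbalance (up to ~10:1
cancer:normal in the inventory cohorts), and the equal-weight average of
class means is the form that removes this bias exactly: duplicating samples
of one class leaves every other sample's centered value unchanged.  Plain
grand-mean centering is provided for mixes that include cancer-only
cohorts.

The merged matrix holds the gene union; each gene's pooled Mann–Whitney
test uses exactly the cohorts that measured it (genes covered by no
contrast cohort are dropped with a warning).  Contrasts reuse each cohort's
stratification verbatim; no re-balancing happens after the merge.  A
single pooled test on the merged centered scores is used rather than
per-cohort tests with p-value combination.

## Validation statistics

Gene-set overlap between two top-N lists is |A∩B|/N × 100 (denominator N,
symmetric for equal-size lists).  The random baseline draws N-gene subsets
uniformly from each cohort's own measured-gene universe (mirroring
platform-specific gene lists) and averages the overlap over 50 draws by
default; with a shared universe of size M its expectation is the
hypergeometric N/M × 100.  Recovery reports give per planted class the
recall and precision at top-k and the mean significance rank.

## Pipeline determinism and sizes

All randomness flows from a single configuration seed (per-step generators
are spawned from it); result tables carry the configuration hash as a
header comment, floats are written at fixed precision, and re-running an
identical configuration reproduces byte-identical outputs.

The synthetic study sizes used by the test suite and the acceptance script
— 2000 genes, five cohorts of 116/40, 116/40, 100/50, 100/50, 100/50
samples, 200-gene stroma sets, the scaled 10-size scoring ladder — keep a
full end-to-end run around ten seconds while leaving every planted effect
comfortably detectable; they are the package's standard desk-scale study
conditions.

## Known limitations

- The three-tissue model ignores reactive stroma; on real data the
  balanced contrast may partly reflect reactive-vs-normal stroma
  differences.
- Stroma scores are relative within a cohort; no absolute stroma
  percentage is transferable across cohorts without per-cohort
  calibration against histopathology.
- The Mann–Whitney test carries no covariate adjustment (e.g. tumor grade);
  grade balance must be audited separately.
- The exact-test branch is limited to small layouts; moderate layouts with
  heavy ties rely on the tie-corrected normal approximation.
- Missing expression values are not supported; imputation (or gene
  filtering) is the caller's responsibility upstream.
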