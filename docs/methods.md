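# Methods

## Scope and design

`reciprome` chains five analysis stages — digital-count normalization and
permutation screening, 2^−ΔΔCt qPCR statistics, promoter TFBS distance
filtering, cross-dataset reciprocal miRNA→target integration, and
preranked gene-set enrichment — behind one library API, one thin CLI and
one pipeline function. All stages consume plain-text tables (CSV/TSV/GMT)
and can be driven either by user files or by the built-in synthetic
generator that emulates the underlying five-arm monocyte study.

## Count normalization and screening (`reciprome.nanostring`)

Per-sample scale factors are the geometric mean of that sample's
positive-control counts divided by the across-sample geometric mean of
those values, so the factors multiply to 1 (anchoring convention);
endogenous counts are divided by the factor. The positive-control summary
is the geometric mean — the usual digital-counter convention; mean-based
scaling is a one-line change. Background is per-sample
`mean + 2·SD` of the normalized negative controls; a probe is *detected*
when it exceeds background in every sample of at least one group
(fraction and grouping configurable). With 731 probes and the default
abundance distribution this yields ≈398 detected probes.

Fold changes are ratios of group means of normalized values with a
pseudocount (default 0.5) guarding zero means; screens use *strict*
inequalities (`> 3` or `< 1/3`), so a ratio of exactly 3 does not pass.
The permutation test uses the difference of group means of
`log2(value + pseudocount)`; when the number of distinct label
assignments C(n_A+n_B, n_A) is within the permutation budget the test
enumerates all of them (p = tail fraction, observed labeling included,
so p ≥ 1/#assignments), otherwise it Monte-Carlo samples with the
add-one correction (1 + hits)/(1 + n_perm). At the study's profiling
size (3 vs 3) exact enumeration gives 20 assignments and a two-sided
p floor of 0.1 — a nominal cutoff of 0.003 can never fire at that n, so
the headline screens are fold-based, with p-values reported alongside.

## Relative qPCR quantification (`reciprome.qpcr`)

Technical replicates are averaged (arithmetic mean on the Ct scale)
before ΔCt = mean Ct(target) − mean Ct(reference); ΔΔCt is the
difference of group-mean ΔCt and fold = 2^−ΔΔCt, giving the exact
identities fold(ΔΔCt=0)=1, fold(ΔΔCt=−2)=4 and
fold(A,B)·fold(B,A)=1. Group tests run on per-sample ΔCt — the
conventional scale for relative qPCR, since folds are log-normal —
using pooled-variance Student t by default (Welch by flag) and one-way
ANOVA with Bonferroni-corrected pairwise t-tests for multi-arm designs.
Bonferroni thresholds are exact α/m internally and rounded to 4 decimals
only for display (0.05/3 → 0.0167). Two constant equal groups return
p = 1 rather than an error. No amplification-efficiency correction is
applied (pure 2^−ΔΔCt).

## Promoter filtering (`reciprome.promoter`)

Sites are signed distances from the TSS, upstream negative (unsigned
upstream exports accepted by flag; BED-like intervals plus a TSS table
convert internally, 0-based half-open). A site qualifies iff
`min ≤ |d| ≤ max` on the upstream side; the minimum distance encodes the
"too close to the TSS to be functional" exclusion. No numeric bound for
that rule exists in the source annotations, so the default window
(100–10,000 bp) is a documented, configurable choice. Reason codes:
`in_window` (regulated), `too_close` (a site exists inside the exclusion
zone and none qualifies), `no_site` (no site of that TF, or sites only
beyond the window / downstream). Classification is order-independent and
widening the window never removes a positive call.

## Reciprocal integration (`reciprome.integration`)

Fold-change encodings differ between export dialects; readers normalize
`ratio`, `signed` (−2.5 = 2.5-fold down) and `magnitude + direction`
forms to ratio form internally. Qualification is probe-level and
reporting gene-level (any-probe rule). `common_downregulated` is
inclusive (`≥ 2-fold` down in both datasets, matching the wording of the
filter it implements) while `high_magnitude_subset` is strict
(`> 10-fold` in both). Reciprocal targets must be validated targets of at
least `min_coregulators` of the lead miRNAs **and** up-regulated in both
datasets. The lead list is configurable and may include both arms of a
hairpin: the screen detects the −5p arm of miR-199a while the validated
co-regulated targets attach to the −3p arm, so the integration default
uses (miR-199a-3p, miR-320a, miR-598).

## Enrichment (`reciprome.enrichment`)

The running-sum statistic follows the weighted Kolmogorov–Smirnov form:
walking a descending ranked list, hits add `|score|^p` normalized by the
total hit weight and misses subtract `1/(N−k)`; ES is the signed maximum
deviation (computed in O(k) from hit positions; the full walk is also
returned for inspection, and positive extremes win exact ties). `p = 0`
reduces to the classic unweighted KS statistic; the default is `p = 1`.

Null distributions use gene-label permutation preserving set size — the
expression datasets behind the ranking are pooled (one array per
condition), so phenotype permutation is impossible by construction.
Sets with C(N, k) within the permutation budget are enumerated
exhaustively; larger sets share one label shuffle per iteration.
NES = ES / mean(|null ES| of the matching sign); nominal p is the
same-sign null tail; FDR q follows the standard same-sign pooled-null
ratio convention, clipped to [0, 1]. Overrepresentation is the one-sided
hypergeometric tail against a user universe with Benjamini–Hochberg
adjustment across sets (significant: adjusted p < 0.05).

## Synthetic data (`reciprome.synthetic`)

The generator reproduces the *statistical structure* the analysis
assumes, not the biology of any particular cohort:

* **Counts**: negative binomial with variance `m + d·m²`. The default
  dispersion `d = 0.005` (CV ≈ 8–10 % at typical abundances) models
  measurement-scale noise around fixed group means. Real inter-individual
  biological variability is substantially larger and is deliberately
  *not* emulated — passing recovery tests therefore demonstrate correctness
  of the estimators, not field-realistic power at n = 3.
  `d = 0` is the deterministic limit (`count = round(mean)`) used by the
  exact planted-truth recovery property; integer rounding is then the
  only residual distortion (≲0.5 % at the default abundance floor).
* **Scale factors**: log-normal, σ = 0.15, recovered by the
  positive-control normalization; a 6-probe positive ladder
  (32…32,768 counts) and 8 negative controls with mean 2 mirror the
  usual cartridge layout.
* **Planted effects** multiply the numerator group's mean before noise,
  so fold-change recovery is well defined; planted features' baselines
  are floored at `baseline_mean` (default 300) so recovery is not
  Poisson-limited.
* **Ct tables**: additive Gaussian replicate noise (σ = 0.25 cycles,
  typical Taqman triplicate scatter) plus a per-sample RNA-input offset
  that cancels in ΔCt; a planted fold f shifts the numerator group's
  target Ct by −log2 f.
* **Frozen study conditions** (`aat_*` factories): five groups, n = 3
  per group for profiling and n = 4 for qPCR; 731 probes with ≈398
  detectable; leads planted at 40×/17×/12× (profiling) and
  22×/28×/16× with a 5× negative control (qPCR); 21 features beyond
  3-fold ZZ vs MM and 11 (7 down) Day 2 vs Day 0; 334 common ≥2-fold
  down genes, 294 NF-κB-annotated, 8 above 10-fold in both datasets;
  EIF4H/HNRNPU as the only two-lead reciprocal targets; promoter sites
  in-window for the three leads and at −45 bp (too close) for miR-30a-5p.

The paper-scale problem sizes are kept as-is (731 probes, ~2,350 genes,
50 gene sets) because they run in seconds; permutation budgets default to
10,000 (screen; collapses to exact enumeration at 3 vs 3) and 500 (GSEA).
Fold-recovery checks average over 30–40 replicate simulated cohorts so
they measure estimator calibration rather than one cohort's sampling
noise.

## Numerical choices and degenerate inputs

* Screen ordering: |log2 FC| descending, ties lexicographic by probe id.
* A sample whose positive controls are all zero raises a normalization
  error naming the sample; zero negative controls give background 0 and
  every nonzero probe detected.
* Permutation tie handling uses a relative tolerance so permutations
  exactly tying the observed statistic count toward the tail.
* Hit weights that are all zero (all-zero scores in a set) fall back to
  unweighted increments instead of dividing by zero; a degenerate null
  (no same-sign null ES) raises rather than silently returning NES = ∞.
* All generators and permutation routines take explicit seeds; identical
  seed + config ⇒ bit-identical outputs (the pipeline report embeds the
  config hash and seed for provenance).

## Known limitations

* The generator does not model probe cross-hybridization, array spatial
  artifacts, amplification-efficiency differences, or inter-individual
  biological variance; conclusions about real-cohort power cannot be
  drawn from it.
* The promoter stage consumes upstream TFBS predictions; it performs no
  motif scanning of its own.
* FDR q follows one (the most common) of several published permutation-
  FDR variants; values are comparable across runs of this package but
  not bit-comparable with other implementations.
* With pooled expression designs the gene-label permutation null is the
  only option; it is known to be anti-conservative relative to phenotype
  permutation for correlated gene sets.
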