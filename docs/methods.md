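# Methods

`kranzsep` implements the analytical machinery needed to work with
imperfectly separated bundle-sheath (BS) and mesophyll (M) samples from C4
leaves: estimating true tissue distributions from marker-anchored mixtures,
diagnosing RNA-degradation (3' bias) artifacts when comparing separation
studies, and harmonizing tissue-specificity calls across studies.  A
synthetic-data generator with full ground truth stands in for sequencing
data, so every stage is testable end to end.

## The mixture-plus-degradation model

Each sample is modelled as a two-tissue mixture with BS purity π: a gene
with pure-tissue expressions (μ_BS, μ_M) contributes
e = π·μ_BS + (1−π)·μ_M to the sample's RNA pool.

Degradation is modelled positionally.  Sequencing libraries retain the 3'
ends of degrading transcripts, so expected coverage at fractional distance
t from the 3' end is proportional to exp(−d·s_g·t), where d ≥ 0 is the
sample's degradation severity and s_g ≥ 0 the gene's degradation
sensitivity.  Averaging over positions gives the retention factor

    R(d·s_g) = (1 − exp(−d·s_g)) / (d·s_g),    R(0) = 1,

the fraction of the gene's signal surviving degradation.  Expected counts
are lib_size · e·R / Σ(e·R); the renormalization is what makes degradation
a *relative* artifact: in a degraded sample, insensitive genes appear
up-shifted because sensitive genes lost signal.  Counts are negative
binomial with var = μ + φμ² (gamma–Poisson construction; φ = 0 is Poisson).
Degradation acts only through R — no fragment-length model — which keeps
every downstream quantity in closed form for oracle tests.

Coverage profiles are stored 0-based, 5'→3', with t = 0 at the 3'-most
base; bedGraph export uses 0-based half-open intervals and minus-strand
genes are flipped on ingestion so the metric is biological-end-relative.

## Marker-based deconvolution

Within one developmental slice, all analyte values (enzyme activities,
metabolite signals) are converted to fraction-of-total across the
enrichment fractions.  The M-marker profile (PEPC activity) and BS-marker
profile (NADP-ME activity) proxy the tissue amounts in each fraction.  For
a target analyte T the OLS slope of ln(T/M) on ln(BS/M) estimates the
fraction of T residing in pure BS; the null of no tissue preference is
slope = 0.5, tested two-sided with t = (b − 0.5)/SE on n−2 df.  Pure
abundances are reconstructed as b·2ā and (1−b)·2ā where ā is the analyte's
mean abundance over all fractions and replicates of the slice; b is clamped
to [0, 1] for this reconstruction only (never for the test), with a flag.

Choices where the procedure is underdetermined:

* all fraction × replicate points of a slice are pooled into one regression
  (maximizes df); a replicate-means mode (one point per fraction) is
  available via `pooled=False`;
* natural log, intercept included — the intercept absorbs scale error
  between the target's and the markers' normalizations;
* the estimator is exact at the endpoints (a marker deconvolved against
  the marker pair returns exactly 0 or 1) and is a first-order
  approximation for interior mixtures; empirically the bias is < 0.01 for
  purities spanning 0.25–0.8 and vanishes as the purity range narrows.

The log-ratio regression is a linearization, not a nonlinear fit of
T = αB + (1−α)M; the test suite checks it against a grid-search nonlinear
oracle.

## 3'-bias metrics

The per-gene metric is mean coverage over the 3'-most `window` bases
(default 100 nt) divided by mean coverage over the whole transcript:
1 for uniform coverage, up to L/window when all signal sits in the last
window.  Transcripts shorter than 2·window, or without coverage, are
excluded — the numerator and denominator would otherwise overlap almost
completely.  The per-sample summary is the median over the 1000 most
expressed genes of that sample (both knobs configurable, following the
common definition of this QC metric); gene-set profiles report median and
IQR per set per sample with the whole universe as an always-present
background row.  For the exponential coverage model the metric has the
closed form (∫₀^w e^{−kt}dt / w)/(∫₀¹ e^{−kt}dt) with k = d·s_g, strictly
increasing in k — the quadrature oracle used by the tests.

## Differential expression

Two engines, matched to the two separation regimes:

**Conditional NB exact-style test** (well-separated groups).  Counts are
scaled to the mean library size (total-count scaling; the synthetic data
carry no composition bias, so no TMM) and rounded; group sums are NB with
mean n·μ and dispersion φ/n; conditioning on the total gives a discrete
split distribution, and the two-sided p sums all splits at most as probable
as the one observed.  φ = 0 reduces to the binomial split of a Poisson
total.  The common dispersion is a method-of-moments estimate,
φ = max(0, mean over genes of (s² − μ)/μ²), from group-centered normalized
counts (genes with mean below 1 are skipped as numerically unstable); when
no group is replicated the caller must supply φ — mirroring the practice of
reusing a dispersion estimated elsewhere.  Rounding after library scaling
makes the test exact only at equal library sizes; at realistic imbalance
the approximation error is far below the discreteness granularity.  Null
simulations at known φ give rejection rates within a point of nominal;
running with an *underestimated* φ is anti-conservative (tested), which is
exactly the failure mode that motivates reusing a common dispersion.

**Purity-adjusted linear unmixing** (imperfectly enriched fractions).  Per
gene, library-normalized expression y_r is regressed on the two-column
design [π_r, 1−π_r], estimating the pure-tissue expressions (B, M)
directly; the contrast B − M is t-tested on n−2 df with the residual
variance.  Negative pure estimates are clipped to 0 for fold-change
reporting only.  Log fold changes use a pseudo-count of 0.5 (mean-library
count scale) so they are finite at zeros.  With perfect separation
(π ∈ {0,1}) the estimator reduces exactly to group means.  Under
cross-contamination, naive group ratios are attenuated to
(πF + 1−π)/((1−π)F + π) for a true ratio F; the unmixing removes this
attenuation exactly in expectation.  The price is variance: the contrast is
inflated by ≈ 1/(2π−1) relative to the naive contrast, so under the null
the adjusted fold changes are *noisier* (≈2.5× at π = 0.7/0.3) while the
t-based p-values remain calibrated, because estimate and standard error are
amplified alike.  This estimator is a transparent stand-in with the same
intent as published contamination-tolerant DE methods; it accepts
externally computed purities (e.g. from deconvolving the marker
transcripts).

## Cross-study harmonization and artifact diagnostics

Log2 fold changes (BS over M, throughout) from different studies are
aligned by inner join on shared genes and quantile normalized: each
column's sorted values are replaced by the across-column mean of order
statistics, ties receiving the mean of the reference values their ranks
span.  Within-column ranks are preserved exactly.  Tissue TPM pairs are
back-calculated from the normalized fold change ℓ and the stage mean TPM m
as (2m·2^ℓ/(1+2^ℓ), 2m/(1+2^ℓ)) — the unique pair whose arithmetic mean is
m and log2 ratio is ℓ; mean-TPM is therefore defined as the arithmetic mean
of the two tissue TPMs, the only convention under which the
back-calculation is self-consistent.

Conflict sets collect genes called tissue-specific in opposite directions
by two studies at designated stage pairs (set 1: BS in study A, M in study
B; set 2 the mirror), with per-gene provenance.  Significance defaults to
FDR < α; a per-test p < α mode exists for global-null designs (below).
Degradation-sensitive genes are detected by contrasting a harshly
separated sample set against matched unseparated tissue; genes
significantly lower in the separated samples form the `down` list.
Ortholog agreement reports, for a directed gene set, the fraction of mapped
orthologs whose fold change in another study has the same sign — sign only,
regardless of significance in the second study, matching how cross-species
panels plot all measured orthologs (a significance-requiring mode exists
for the developmental-switch analysis).  Overlap and enrichment questions
use the two-sided Fisher exact test with conditional-MLE odds ratios; BH
FDR is attached across the tested categories of one query.  Hierarchical
clustering of fully normalized log2 TPM keeps genes with min > 0 and
max > 50 TPM, uses 1 − r distances (Pearson for genes, Spearman for
samples) and average linkage (configurable; the distance choice is the
meaningful one), and serializes both trees as Newick.

Developmental-switch support: genes significant at both stages of study A
are classified consistent (same sign) or switching (opposite); support
means the same signed pattern in study B at the matched stages; the
class × support table is Fisher-tested.

## The synthetic demonstration experiment

`run_demo` (CLI: `kranzsep demo`) builds one gene population — expression
lognormal around 100 units, identical in both tissues for every non-marker
gene; lengths lognormal in [400, 4000] nt; degradation sensitivity 0 for
75% of genes and Gamma(3, 0.6) for the rest, making sensitivity sparse the
way degradation-affected gene lists are reported to be — and sequences it
through three protocol templates:

| template   | groups (π)           | degradation d        | emulates                         |
|------------|----------------------|----------------------|----------------------------------|
| mech       | BS 0.95 / M 0.05     | BS 0.3, M 2.0        | mechanical/enzymatic separation, M degrades more |
| lmd        | BS 1.0 / M 0.0       | 3.0 both             | laser micro-dissection, heavy symmetric degradation |
| filtration | 0.7 / 0.5 / 0.3      | 0.2 everywhere       | serial filtration: low purity, high integrity |

plus an unseparated control (π = 0.5, d = 0.2).  Defaults: 2000 genes,
4 replicates per group, library size 1e6 (mean count ≈ 500), φ = 0.05 —
sizes chosen so the full experiment runs in seconds on one core while every
effect of interest is many standard errors wide.  The mech and lmd studies
are analyzed with the NB test (dispersion estimated from their own
replicates), the filtration study with purity-adjusted unmixing using the
design purities — mirroring how a low-enrichment study needs the
contamination-tolerant analysis.

Because the shared truth contains no tissue-specific expression, the
filtration arm is a global null and BH yields (correctly) essentially no
FDR-level discoveries there; conflict sets for the demonstration are
therefore built on per-test p < α, where the flip structure the experiment
is designed to expose is visible.  The experiment then shows, by
computation: conflict set 1 (BS in mech, M in filtration) is strongly
enriched for top-quartile-sensitivity genes and carries elevated 3' bias
relative to the genomic background in every sample of both studies;
conflict set 2 shows no such enrichment; the separated-vs-unseparated
contrast recovers the top-decile sensitive genes essentially completely
with near-zero false recovery; and a second-species replicate of the mech
protocol reproduces conflict set 1's directions — degradation sensitivity
masquerading as conserved tissue specificity.

What the generator does **not** emulate: isoforms, GC or positional
mappability bias, fragment-length effects, composition bias between
libraries, correlated gene modules, or real biological tissue specificity.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not performance on any particular real dataset.

## Numerical conventions and edge cases

* TPM columns sum to 1e6 by construction; an all-zero sample is an error
  naming the sample; an all-zero gene has TPM 0, not NA.
* Fraction-of-total groups must contain a positive value; output sums to 1
  and re-application is the identity.
* Metabolite normalization divides by the ribitol peak and fresh weight,
  then by the per-replicate mean over all analytes (so values are relative
  to the dominant metabolites; the per-replicate mean of the output is 1).
* The 3-SD replicate-exclusion rule computes percentage-in-BS as
  BS_e/(BS_e+M_e) per replicate (the intermediate fraction carries no
  information about the BS/M axis) with the candidate included in mean and
  SD; with n replicates the largest attainable z is (n−1)/√n, so the rule
  cannot fire for n ≤ 10 — it is a gross-outlier guard for well-replicated
  analytes, and SD = 0 groups exclude nothing.  The low-signal threshold
  defaults to the 5% quantile of per-analyte maxima (no absolute scale is
  meaningful after the relative normalization); an absolute threshold is
  accepted.
* Deconvolution errors out on non-positive profile values (log-ratios
  undefined) and on a constant BS/M marker ratio ("markers not
  separated"); a zero regression SE yields the degenerate convention
  p = 0 (b ≠ 0.5) / p = 1 (b = 0.5).
* Two-sided exact-test p-values sum all outcomes with probability at most
  that of the observed one (with a 1e-9 relative tie tolerance); the NB
  conditional test normalizes the split distribution in probability space,
  stable for the supports that arise at these library sizes.
* Every table is plain text (TSV/CSV/bedGraph/Newick/JSON), `.` is the NA
  token, and all writers use fixed float formatting so a fixed seed
  reproduces every artifact byte for byte; the run manifest records
  parameters and output hashes and contains no timestamps.

## Known limitations

* The conditional NB test is exact only under equal (post-scaling) library
  sizes and a correctly specified common dispersion; tagwise or trended
  dispersions are out of scope.
* The unmixing estimator assumes purities are known and constant per
  sample; errors-in-purities propagate into fold changes by roughly the
  relative error of 1/(π_BS − π_M).
* The deconvolution slope is a linearization; for extreme targets measured
  over very wide purity ranges the small interior bias is visible (< 0.01
  under the tested designs).
* Quantile normalization with heavy ties can leave sorted columns unequal
  at the tied values; fold-change distributions are continuous in practice.
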