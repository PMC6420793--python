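# Methods

## The experimental design being modelled

A knockdown/rescue experiment depletes the endogenous fusion transcription
factor with shRNA (`iEF`), then re-expresses a construct of interest on that
background.  Each replicate batch contains one sample per condition: the
depleted control, an undepleted control (`iLuc`), and one sample per rescue
construct.  Every transcriptional profile is a contrast against `iEF`; the
`iLuc` vs `iEF` contrast defines the endogenous signature.  A gene is
*rescued* by a construct when it is significantly regulated (BH-adjusted
*p* < 0.05, no fold-change cutoff) in both the endogenous and the
construct's contrast; it is *paradoxical* when both are significant but the
directions disagree.  *Rescue strength* is the Pearson correlation and OLS
slope (with intercept, reported but not interpreted) of construct log2FC on
endogenous log2FC over co-significant genes.

## Count model and differential expression

Counts are modelled negative-binomially with mean–dispersion
parameterization, Var = μ + αμ².  Per contrast we fit, per gene, a log-link
GLM with an intercept and a condition indicator, with log size factors as
offsets, by IRLS (max 50 iterations, deviance tolerance 1e-8; |log2FC|
bounded at 10 so one-group-all-zero genes stay finite without biasing
estimable effects; non-convergent genes are flagged with *p* = NA).  Size
factors are median-of-ratios over genes positive in all samples, rescaled
to geometric mean one.  BH correction is applied per contrast over testable
genes.

**Dispersion.**  The gene-wise method-of-moments estimate equates the
pooled within-condition variance of normalized counts with
μ·mean(1/s_j) + αμ².  At two to five samples per condition this estimate is
far too noisy to plug into a Wald test, so it is moderated per gene toward
the mean dispersion of genes of similar expression (20 quantile bins; the
bin mean of the unclipped estimator is nearly unbiased).  The moderation
weight is empirical-Bayes: the χ²-theory sampling variance of the gene-wise
estimate, Var ≈ (2/df)·(shot/μ² + α)², against the biological spread of
dispersions around the trend.  That spread is expressed as a multiple *c*
of the trend and estimated by moments, but floored at *c*² = 0.25
(dispersion sd = half the trend): when the design cannot identify the
spread, underestimating it is precisely what inflates Wald tails, so the
uninformative case defaults to the conservative side.  The gene-wise
estimate never receives more than 70% of the weight.  Final values are
floored at 1e-8 (all-zero genes are flagged).

**Wald tail.**  A plug-in Wald statistic treats the estimated dispersion as
known; with few residual degrees of freedom the resulting extreme tails are
badly anti-conservative (in all-null simulations, minimum p-values of
1e-8–1e-10 and BH rejections in every run).  The estimated standard error
is a noisy version of the true one, making the statistic a normal scale
mixture — i.e. t-like — so p-values are taken from a per-gene t reference
with effective degrees of freedom ν = 2 / Var(log se²), where Var(log se²)
derives from the dispersion posterior variance and se² ∝ (1/μ + α).  ν is
clipped to [3, 1e6] and converges to the normal reference as dispersion
uncertainty vanishes.  With this reference, twenty all-null simulations of
5,000 genes produce no BH discoveries at *padj* < 0.05 and pooled raw
p-values with KS distance ≈ 0.02 from uniform.  One dispersion set is
estimated per experiment from all conditions' within-group residuals and
shared across contrasts.

## Preprocessing

Genes averaging under one count per sample (total < number of samples) are
removed; "per sample" is read as a rate, since requiring every individual
sample to reach one count would discard most genes in sparse designs.
Batch adjustment operates on log2(normalized count + 1): per gene the data
are standardized against a model holding batch means and condition
covariates (so condition effects are preserved and re-added), batch
locations get a normal prior and batch scales an inverse-gamma prior with
moment-matched hyperparameters, solved by fixed-point iteration (tolerance
1e-6, max 100 iterations; non-parametric variant not implemented).
Degenerate cases are handled exactly: one batch returns the input; a
noise-free location shift is removed completely; hyperprior moments of zero
spread fall back to unshrunk estimates.  Because the downstream DE stage is
a count model, the adjusted matrix is back-transformed to integer
pseudo-counts round(max(2^x − 1, 0)); the un-rounded matrix is kept for
clustering and PCA.  Whether to run the count model on adjusted
pseudo-counts is a genuinely open design point; the adjust-then-test
composition is known to be mildly anti-conservative, which the conservative
dispersion handling above offsets (measured endogenous-contrast false
discovery proportion ≈ 0.04 at study scale).

## Response elements

The microsatellite caller finds maximal runs of consecutive GGAA units on
the plus strand (TTCC runs reported as minus-strand elements), merges runs
separated by at most `max_gap` = 4 non-motif bases, and drops elements with
fewer than `min_repeats` = 4 total units; `max_consecutive` is the longest
constituent run.  These two thresholds are explicit stand-ins — the
localization literature the element taxonomy comes from does not publish a
portable definition — and are exposed in `ScanParams`.  The ETS scanner
matches an IUPAC consensus (default ACMGGAARY) on both strands, reporting
all overlapping matches.  Coordinates are 0-based half-open internally and
BED on disk.

Distance is unsigned, element edge to TSS, zero when the TSS lies inside
the element; the half-open `end` serves as the downstream edge.  A gene
significantly regulated in the endogenous profile takes the class of its
nearest microsatellite within 500 kb (promoter-like strictly under 5 kb,
enhancer-like otherwise — a tie at exactly 5 kb is enhancer-like), crossed
with its direction of regulation; lacking one, an ETS motif (then any other
factor-bound element supplied as BED) overlapping the strand-aware window
[TSS − 5 kb, TSS + 1 kb] makes it a direct target.  All other genes are
`none`; the classification is a partition.  Feature distributions between
element groups (max consecutive units, total units, binding enrichment —
the last consumed as an annotation, never computed) are compared with the
two-sided Mann–Whitney U test, asymptotic with tie correction and no
continuity correction.

## Overlap testing and summaries

Two-fold gene sets use strict inequalities (|FC| > 2 and *padj* < 0.05).
Overlaps are tested with the Pearson chi-square (1 df, no continuity
correction) on the 2×2 membership table over an explicit universe — the
genes surviving the count filter and testable in both contrasts — because
the test's value depends entirely on that choice.  Fidelity fractions are
computed over endogenously regulated genes only (rescue-only genes
excluded).  Variable genes are ranked by across-sample variance with
lexicographic tie-breaks; gene clustering is complete-linkage on
z-scored log2 expression (Euclidean; correlation distance available); PCA
centers genes, takes scores from the SVD, and fixes each component's sign
so its largest-magnitude loading is positive.

## The synthetic-data generator

The generator is first-class, tested code.  Per gene it draws a log2
baseline from N(7.5, 1.3) (median ≈ 180 normalized counts, a moderately
deep bulk library) and an NB dispersion from LogNormal(ln 0.005, 0.4) — low
biological variability, as expected for replicate batches of an isogenic
cell line.  A configurable fraction of genes (defaults 0.15 activated, 0.20
repressed) carries an endogenous effect with |log2FC| ~ N(3.5, 0.8),
matching the large effect sizes of direct fusion targets.  Construct
defaults mirror the wildtype / partially-active / dead panel: rescue
fractions 0.75 / 0.40 / 0.02 with attenuations 0.8 / 0.5 / 0.1, and a 30%
paradoxical fraction for the partial construct; rescued genes get
construct log2FC = ±attenuation × endogenous log2FC (sign flipped for
paradoxical genes).  Rescued and paradoxical gene counts are exact
(rounded) per element-class stratum.  Batch structure: additive per-batch
per-gene log2 shifts (sd 0.4), multiplicative per-batch dispersion
inflation (ln-sd 0.25), and per-sample library scaling LogNormal(0, 0.2) so
size-factor estimation is non-trivial.  One root seed spawns named
sub-streams (plan, counts, annotation) in a fixed order, so identical
configurations are byte-identical and the truth table agrees between the
count and annotation simulators.

The annotation simulator writes three chromosomes: microsatellite genes own
private 100-kb blocks (so each gene's nearest microsatellite is provably
its own under the 500-kb association radius), ETS genes sit on a
microsatellite-free chromosome with one motif instance inside each gene's
strand-aware window, and all remaining genes pack densely on an
element-free chromosome.  Planted elements are one or two GGAA (or TTCC)
runs with guard bases chosen so no motif can form across an element
boundary; every background GGAA/TTCC unit outside planted footprints is
destroyed by iterative mutation (which also removes accidental ETS matches,
since each ACMGGAARY instance contains a GGAA).  Scanning the emitted FASTA
therefore recovers exactly the planted elements — the round-trip is an
oracle in the test suite.

**What the generator does not emulate:** read-level structure (alignment,
counting, GC or length bias), isoforms, outlier samples, correlated genes,
dispersion–mean trends beyond a constant, and real microsatellite length
distributions.  Passing recovery tests therefore validates the analysis
logic and its statistical calibration under the stated model, not
performance on any particular real dataset.

## Problem sizes and numerical choices

Recovery checks run ten replicate simulations of 6,000 genes × 15 samples;
null calibration uses twenty simulations of 5,000 genes; the clustering
oracle uses n ≤ 12 items against an O(n³) reference.  The attenuation
slope of the near-dead construct (rescue fraction 0.02, attenuation 0.1) is
fit on co-significant genes pooled across the ten simulations, because a
single experiment yields fewer than the three genes needed for a line —
mirroring how weak constructs produce small, unstable fitted slopes in
practice.  Pearson *r* and the OLS slope are computed from centered sums of
products so that identical inputs return exactly 1.0 (for doubles,
sqrt(x·x) = |x| in round-to-nearest).  The chi-square overlap statistic is
the closed-form N(ad − bc)² / (row × column products), undefined (NA with a
reason) on degenerate margins.

## Known limitations

- The adjust-then-test composition shares information between batch
  adjustment and testing; calibration was verified on the generator's
  conditions, not proven generally.
- The t-reference effective df relies on a delta-method approximation of
  Var(log se²); it is conservative rather than exact.
- The microsatellite call definition (min repeats, merge gap) is a
  documented stand-in; results stratified by element class inherit it.
- Whether a microsatellite's distance should be measured edge-to-TSS,
  midpoint-to-TSS, or summit-to-TSS is unsettled; edge-to-TSS is used.
- Non-parametric batch priors, fold-change shrinkage, independent
  filtering, and outlier-count replacement are intentionally out of scope.
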