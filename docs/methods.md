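# Methods

This note documents the statistical procedures implemented in `tfact`, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not establish.

## Scientific setting

In acute leukemia cohorts, a transcription factor that is normally silent
in a lineage can be aberrantly activated in a small subset of patients —
for instance a GATA-family factor in B-lineage acute lymphoblastic leukemia
(B-ALL), where it is ordinarily off in the lymphoid compartment.  The
pipeline detects such samples as per-subtype expression outliers,
characterizes the downstream transcriptional program, nominates direct
targets through promoter motif evidence plus co-expression, and scores
whether the activation is *cis*-driven (a same-allele genomic lesion) or
*trans*-driven (e.g. a fusion protein), using allele-specific expression
and structural-variant/TAD geometry.

## Normalization and the expressed-gene filter

FPKM is computed directly from the count matrix:
`fpkm[g,s] = counts[g,s] · 1e9 / (exonic_length[g] · library_size[s])`,
with the library size taken as the in-matrix column sum.  Using in-matrix
totals keeps the normalization reproducible from the counts file alone; no
between-sample factors (TMM, median-of-ratios) are applied.  A
protein-coding gene is *expressed* when FPKM exceeds 1 (strictly) in at
least 30% of samples (fraction inclusive); only expressed genes enter
differential expression.

## Outlier-activation calling

Within each molecular subtype with ≥ 3 samples, a sample is an outlier for
the focal gene when its FPKM strictly exceeds `mean + k·sd` (k = 3, sd with
the n−1 denominator).  Calling per subtype absorbs baseline differences
between subtypes.  The mean and sd include the candidate sample — the
conservative choice, since a true outlier inflates its own threshold; a
leave-one-out variant is available (`leave_one_out=True`).  Two structural
consequences are worth knowing: a single point in a subtype of n samples
can reach at most `z = (n−1)/√n`, so the rule cannot fire for n ≤ 10; and
with several outliers in one subtype the flagged set depends on the ratio
of their magnitudes, so a spike much smaller than its sibling can fall
below the inflated threshold.  Downstream analysis keeps only subtypes with
≥ 1 outlier, splitting their samples into outlier and normal groups;
everything else is excluded.

## Differential expression

Per expressed gene, a log-link negative-binomial GLM:
`y ~ NB(mu, alpha)`, `log mu = offset + X beta`, offset = log library size,
design = intercept + group indicator + one-hot subtype (largest subtype as
reference; batch appended the same way when present, never as a separate
correction step).  Dispersion is estimated per gene by method of moments —
the Pearson χ² statistic of a Poisson fit is matched to its residual
degrees of freedom by a monotone bisection in `alpha`, floored at 1e-8 —
with no empirical-Bayes shrinkage.  Coefficients come from batched IRLS
(working weights `mu/(1+alpha·mu)`, 60 iterations, convergence at 1e-8 on
the coefficient sup-norm; non-converged genes are flagged and given p = 1).

The group coefficient is tested with a Wald statistic referred to a
**t distribution with n − p degrees of freedom** rather than a normal.
With moment-estimated dispersions the normal reference is measurably
anticonservative at realistic group sizes (empirical type-I ≈ 0.066 at
nominal 0.05 with 2×20 samples); the t reference — the standard choice for
quasi-likelihood-style NB fits — restores calibration and converges to the
normal as n grows.  This is the one place the implementation departs from
the plainest reading of "Wald z".

DEGs are called at |fold change| > 1.5 (on the model coefficient, no
shrinkage) and raw p < 0.05, both strict; no FDR correction is applied to
DEG calling (Benjamini–Hochberg q-values are available in the
over-representation output).  Marker-panel enrichment uses Fisher's exact
test on the 2×2 panel × DEG table over the expressed universe (one-sided
hypergeometric upper tail by default; the two-sided minimum-likelihood p is
also reported).  Generic gene-set over-representation is a hypergeometric
upper tail per set with BH q-values — a deliberate, simpler stand-in for
web-service enrichment tools.

## Promoter motif scanning

Peak-to-TSS profiling measures, for each ChIP peak (midpoint, or summit
when given), the signed distance to the nearest protein-coding TSS
(TSS = `start` on +, `end − 1` on −); the headline fraction is the share
of peaks within ±100 bp among those within ±2 kb.  This motivates scanning
the TSS ±100 bp window.

Promoter windows are `[TSS − 100, TSS + 100)` on the reference strand,
reverse-complemented for minus-strand genes; windows truncated by contig
edges are dropped with a warning.  The PWM (MEME minimal format; 0.1
pseudocount per cell; uniform background by default, optionally estimated
from the promoter set) is scored as log2 odds.  Each window score is
converted to an **exact p-value**: the probability under an i.i.d.
background that a random window scores at least as high, computed by
dynamic-programming convolution of the per-column score distributions on an
integer grid of 1/1000 log2-odds unit.  The scanner scores windows with the
same integerized matrix, so the lookup is exact for the scores it reports;
discretization perturbs a width-w score by at most w/2 grid steps
(≤ 0.004 log2-odds units at w = 8), far below the p < 1e-4 decision
boundary.  Both strands are scanned by default.  Note that p-values are
discrete: for a sharply peaked width-8 matrix the only attainable p below
1e-4 is the consensus itself (4⁻⁸ ≈ 1.5e-5), so chance hits occur at rate
4⁻⁸ per window — about 6 per thousand 200-bp promoters per strand pair.

Targets are nominated as motif-positive DEGs, each annotated with its best
hit and the Pearson correlation between TF and candidate on log2(FPKM+1)
(variance stabilization for skewed FPKM) across the in-scope samples, with
the correlation p from the t transform with n−2 df.  A zero-variance
candidate is reported with r = 0, p = 1 and a warning rather than aborting
the batch.

## Cis evidence

ASE: per heterozygous marker with coverage ≥ 10, a two-sided exact binomial
test of the reference fraction against 0.5; the gene is called ASE when
more than half of its covered markers are individually significant at 0.05
*and* share the skew direction.  This is deliberately the simplest
defensible statistic — no phasing, no mapping-bias correction, no
regulatory-element modelling.

A copy-number segment is a focal deletion when log2 ratio ≤ −0.4
(inclusive); an accompanying LOH segment mean ≥ 0.2 strengthens the call.
The LOH score is treated as an opaque annotation with a configurable cut
(its precise semantic — likely mean B-allele-frequency deviation — is not
standardized).  Both cuts comfortably pass a lesion printed at (−0.75,
0.32).  TAD boundaries are the interval endpoints of the domain containing
the gene's TSS and of the two adjacent domains, each widened by ±5 kb
(Hi-C resolution scale); disruption requires the deletion to intersect a
widened boundary and to lie within 500 kb of the TSS.  The final verdict is
`cis-candidate` only when outlier expression, an ASE call, and a disrupted
boundary co-occur; anything less is `insufficient`.

## Synthetic cohort

The generator emits every input the pipeline reads, with ground truth.
Defaults state the cohort the pipeline is meant to handle: 629
subtype-annotated samples in 11 subtypes (the seven largest, 584 samples,
carry 13 planted outliers as 5/2/2/1/1/1/1), 12,000 genes (1,000
noncoding; 10,560 coding genes in the expressed regime so that ≈ 10,500
pass the filter), NB counts with per-gene lognormal dispersions (median
0.08), per-gene subtype offsets (0.1 log2 sd), lognormal library sizes
(3e7, CV 0.2), and log-uniform exonic lengths (200 bp – 20 kb) so FPKM and
counts decouple.  The expressed-regime mean (log2 FPKM 3.7) is set so that
the implied total `sum(fpkm·length) ≈ 1e9`, making the intended FPKM scale
agree with what the pipeline recomputes from in-matrix library sizes; the
small test preset shifts this mean up to compensate for its 22× smaller
gene count.

The focal TF has background FPKM 0.3 (dispersion 0.05) and is multiplied
by an activation fold of 30 in outlier samples.  The fold — rather than a
background-SD offset — is the spike parameter because, with the spike
included in the subtype mean/sd and NB realization noise (CV ≈ 0.23 at the
spiked mean), an 8-SD spike leaves only ~1.4σ of margin in single-outlier
subtypes; 30× matches the magnitude such outliers show in real cohorts
(FPKM ~5–50 against a median of ~0.3) and is comfortably identifiable.
Planted targets (33 up, 13 down) are drawn from mid-range expressed genes
with folds uniform on [1.5, 4], applied only in outlier samples — genes
planted near the 1.5 threshold are *expected* to be missed occasionally,
which is why recovery criteria are stated as ≥ 12/13 outliers and ≥ 90% of
up-targets, not exact recovery.

The regulome is a random ~6 Mb multi-contig genome with TSSs on a 400 bp
grid (so promoter windows never overlap), an exact consensus (`AGATAAGA`,
a GATA-family-like motif) planted inside the promoter windows of all
planted targets plus random fillers (313 motif genes total), 1,000 peaks
at Normal(0, 50 bp) around random TSSs plus 200 distal decoys, and the cis
scenario: beta-binomial allele counts (fraction 0.95, 6 markers of depth
30), a 101 kb deletion starting 285 kb downstream of the TF's TSS, and a
400 kb TAD grid with a boundary inside the deletion.

What green tests establish: the estimators are calibrated (NB type-I error
and rank-sum rejection inside binomial 99% bands), the exact algorithms
match exhaustive enumeration oracles, and the pipeline recovers planted
structure at realistic effect sizes.  What they do not establish: behaviour
under real-data pathologies absent from the generator — GC/length bias,
batch artifacts beyond an optional additive offset, correlated genes,
mapping bias in allele counts, or subtype misannotation.

## Numerical notes

- IRLS linear predictors are clipped to ±30 before exponentiation; a 1e-10
  ridge keeps near-singular normal equations solvable (affected genes are
  still reported non-converged if they fail the tolerance).
- The exact rank-sum null is enumerated only for n_a+n_b ≤ 12 without ties;
  otherwise the normal approximation with tie and continuity corrections is
  used.  All-tied data returns p = 1.
- Fisher's two-sided p uses the minimum-likelihood rule (sum of
  margin-fixed tables with point probability ≤ observed); zero margins
  give p = 1 and an undefined odds ratio.
- All coordinates are 0-based half-open throughout (BED convention);
  deletion-to-TSS distance is 0 when the deletion overlaps the gene span.
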