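# Methods

## Measurement model and ratio arithmetic

A pyrosequencing assay for an exonic reporter SNP (rSNP) reports, per
sample and technical replicate, the two alleles as percentages of
incorporated nucleotides on the 0–100 scale. The allelic transcript ratio
is `r = pct1/pct2` with the numerator allele fixed per assay in
configuration — orientation is never inferred from data, so ratios are
comparable across samples and studies. Percentages of exactly 0 or 100 are
rejected as failed assays rather than clamped: a true heterozygote cannot
express 0% of one allele at pyrosequencing depth, so such read-outs signal
genotyping or assay failure. The two percentages of a read-out must sum to
100 ± 0.5 (instrument exports round to 0.1).

Nucleotide-incorporation bias is estimated per gene/assay as the arithmetic
mean of raw allelic ratios in heterozygous gDNA, where a 1:1 molar ratio is
expected, pooling breeds by default (a per-breed option exists). Each
replicate's raw ratio is divided by this bias and the normalized replicate
ratios are then arithmetically averaged per sample (replicate SD reported;
0 for singletons). Normalizing before averaging makes the per-sample value
directly comparable to the classification thresholds; averaging the raw
percentages first and ratio-ing afterwards is an equivalent-in-expectation
alternative that the API allows by passing a single pre-averaged
measurement.

Classification against the 60:40 band uses strict inequalities: ASE towards
allele 1 iff `r > 1.5`, towards allele 2 iff `r < lower`, balanced
otherwise (threshold values themselves are balanced). The default lower
threshold is exactly `2/3` — the 40:60 proportion, conventionally printed
as 0.667 — rather than the rounded literal 0.667, so that relabelling the
alleles (`r → 1/r`) mirrors every call exactly; with a rounded lower bound
a sliver of ratios in (2/3, 0.667) would break that symmetry. Imbalance
magnitude is neutralized as `max(r, 1/r)`, whose log10 is `|log10 r|`.

## Group tests

The cDNA-vs-gDNA deviation per breed × tissue is a two-sample, two-tailed
Welch (unequal-variance) t-test on `log10 r`, cDNA samples against gDNA
samples — not a one-sample test against zero, since the gDNA group has its
own sampling noise and its mean is reported alongside. For genes with
bi-directional ASE both groups are neutralized before the log transform
(per-gene flag), otherwise signed logs are compared. Zero-variance-in-both
groups raises an explicit degenerate-variance error instead of returning
NaN; in the aggregate summary table that case is reported "ns" (identical
constant groups carry no evidence). Significance codes use strict
thresholds, most stringent applicable: `***` p<0.001, `**` p<0.01, `*`
p<0.05. No multiple-testing correction is applied by default (per-cell raw
p are reported); Benjamini–Hochberg is available behind a flag.

Quantitative analysis is restricted to (gene, breed) groups with at least
10 rSNP heterozygotes (`min_het`, configurable); excluded groups are logged
with their heterozygote count.

Directionality per gene × breed × tissue is counted from individual calls:
one-directional if only one allele is ever over-expressed, bi-directional
if both occur, none if no sample passes the threshold. One-directional ASE
points to a cis element in linkage disequilibrium with the gene;
bi-directional ASE to an unlinked regulatory variant.

## Phase-corrected variant association

For a candidate regulatory SNP, each candidate heterozygote's signed
`log10 r` is re-oriented so the numerator haplotype always carries the same
candidate allele: the sign is flipped when the candidate alt allele is cis
to assay allele 1 (phase `cis_alt`). Sign flip and taking the reciprocal of
the ratio are the same operation on the log scale; the flip is used. Under
this convention a candidate alt allele that up-regulates its haplotype
produces a consistently *negative* corrected mean in heterozygotes — the
sign is pure orientation convention and carries no inferential weight; the
test is two-sided. Candidate heterozygotes are compared with pooled
homozygotes (who cannot exhibit a candidate-driven imbalance and centre on
zero) by Welch's test, within rSNP heterozygotes only. Phase is an input
column for real data — the package never infers haplotypes; a heterozygote
entering the test without phase is an error (the pipeline routes such rows
to the exclusion log).

## CpG methylation comparison

Control samples are balanced calls whose normalized ratio lies within
1 ± 0.15 (band configurable), sorted by distance from 1 so the caller can
truncate to a target group size. Per CpG site the ASE and control groups
are compared with the classic pooled equal-variance Student t-test — read
as deliberately distinct from the unequal-variance test used for the ratio
comparisons — with Welch behind a flag; at equal group sizes and equal
sample variances the two coincide. Sites with fewer than two values in a
group are flagged not-tested rather than dropped. Records failing the
bisulfite conversion control are excluded (and counted). Coordinates are
1-based inclusive everywhere; the BED export of tested sites converts to
0-based half-open. No per-island multiplicity correction by default, BH
behind the same flag as above.

ASE-group membership for methylation comes from the ASE calls of the same
tissue (first configured assay); the module never re-thresholds. Groups are
not breed-matched by default; a config filter can restrict breeds.

## Synthetic cohorts

The generator encodes the assumed measurement process. A heterozygote's
haplotypes are expressed at odds `f` (the cis fold); the assay bias `b`
multiplies allelic odds in both materials, giving expected allele-1
fractions `b/(1+b)` in gDNA and `b·f/(1+b·f)` in cDNA. Each replicate draws
the measured fraction from a Beta distribution with that mean and
concentration κ (bounded, realistic for percentage read-outs; a
Gaussian-on-logit alternative was considered and rejected as adding a
second unbounded parameter for no observable difference at the precisions
involved). Replicates are independent; there is no animal-level technical
random effect by default. Exported percentages are rounded to 0.1 like
instrument output and always sum to 100; ground truth (per-animal fold,
over-expressed allele, phase, expected fractions, per-assay bias, per-site
methylation means) is emitted at full precision.

Defaults, chosen once as study conditions: breed sizes 51/35/38/21 (the
four-breed cohort design), rSNP heterozygote fraction 0.45, bias b = 1.1,
two replicates, κ = 1000 (replicate SD ≈ 1.4 percentage points at 50:50 —
the replicate variance of the instrument is a free parameter, so every
validation states the κ it used), and a log-normal cis-fold spread with
σ(log10) = 0.12, which puts roughly 15–25% of fat-tissue samples past the
60:40 threshold — the intended prevalence regime, documented as a
calibration of the scenario, not a reproduction claim. Fold distributions:
point mass (nulls and fixed effects), log-normal (smooth bi-directional
spread), and a symmetric two-point mixture (fold `f` with random direction
in a fraction of animals).

The candidate SNP is drawn per haplotype jointly with a causal variant at
correlation `r = sqrt(r²)` via standard two-locus haplotype frequencies
(`D = r·sqrt(p₁q₁p₂q₂)`, Fréchet bounds enforced); at r² = 1 with matched
frequencies the candidate is the driver, at r² = 0 it is unlinked — the
null of the association test. Methylation values are normal per site,
truncated to [0, 100] (truncation is negligible at the simulated means),
with ASE-group means shifted at designated sites.

Determinism: one sequential RNG in fixed generation order, so identical
config + seed give byte-identical exports; grid scenarios derive per-cell
seeds from a `SeedSequence` spawn of the base seed.

## Validation design and problem sizes

The statistical contracts are checked by seeded Monte-Carlo suites sized to
keep the full run in tens of seconds while leaving the acceptance bands
3-standard-error wide or more: type-I error of the cDNA-vs-gDNA test at
n = 14 per group over 2000 replicates (band 0.05 ± 0.015); association null
at 10 vs 10 over 2000 replicates with power at r² = 1 over 400; cis-fold
recovery (1.5/2.0/3.0) from 30 heterozygotes within 5%; bias recovery
(b = 1.25) from 500 gDNA samples within 2%; methylation +3-point shift
(sd 1, n = 10 vs 10) as smallest-p site in ≥95% of 500 replicates and a
per-site null rate 0.05 ± 0.02 over 1000. The null type-I check runs with
neutralization off — the exactly exchangeable case; with neutralization the
folded log ratios remain identically distributed across groups and the
level is preserved to Monte-Carlo accuracy.

## What passing tests do and do not show

The generator reproduces the *statistical* structure the analysis assumes:
bounded multiplicative noise, a shared assay bias across materials,
independent replicates, Hardy-Weinberg-like genotype draws, and normal
methylation noise. It does not emulate PCR allelic drop-out, DNA
contamination of cDNA, shared-run batch effects, pedigree structure within
breeds, or correlation of methylation across neighbouring CpGs. Passing
suites therefore validate the arithmetic, the error rates and the recovery
properties of the pipeline under its own model — not the accuracy of
pyrosequencing itself on real tissue.

## Known limitations

* Phase for real data must be supplied; there is no haplotype inference.
* The methylation module assumes percent-5-mC inputs; it does not call
  methylation from reads.
* The summary table anchors each breed row on its own gDNA group by
  default; whether gDNA should pool across breeds is data-dependent and
  left as a switch.
* Multi-allelic VCF records are rejected rather than decomposed.
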