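# Methods

This note records the statistical conventions, defaults and design choices
behind each stage of the pipeline, and what the synthetic-data generator
does and does not emulate.

## Call-set model and filtering

The central object is a sites × samples matrix of diploid genotype calls
(hom-ref / het / hom-alt / missing) over biallelic SNPs, with per-genotype
depth (DP) and Phred genotype quality (GQ) and per-site INFO annotations.
Multiallelic and non-SNP records are excluded at ingestion and counted;
heterozygous indels are outside the model.

Site filters follow GATK hard-filter semantics: a site is retained only if
it passes **all** rules — QUAL ≥ 50, summed depth within
[50, round(1.5 × mean depth)], QD ≥ 2.0, FS ≤ 40.0, MQ ≥ 40,
HaplotypeScore ≤ 13.0, MQRankSum ≥ −12.5, ReadPosRankSum ≥ −8.0.  A
*missing* INFO annotation never fails a site: rank-sum annotations only
exist at sites with heterozygous calls, so absence is uninformative.  For
reporting, each removal is attributed to the first failing rule in the
fixed order (qual, depth-low, depth-high, QD, FS, MQ, HaplotypeScore,
MQRankSum, ReadPosRankSum); attribution is presentational, retention is
conjunctive.  The coverage bound is computed from the full input set; when
re-filtering an already-filtered call-set the bounds from the original
pass should be supplied (`apply_site_filters(..., bounds=...)`), which is
what makes filtering idempotent — recomputing 1.5 × mean on a truncated
set would drift.

Genotype filters mask calls with DP < 8 or GQ < 24 (GQ 24 bounds the
call-error probability at 10^(−2.4) ≈ 0.4 %).  Call-rate selection keeps
sites called in ≥ 6 counted samples; clone duplicates are excluded from the
count via an explicit list — clone *detection* is not attempted.

## Heterozygosity

Individual heterozygosity is `H_I = S_HET / (S_TOT − S_N/A)`.  `S_TOT`
(positions meeting per-sample ≥ 8x and across-sample coverage bounds)
depends on per-base coverage that a variant-only call-set cannot supply, so
it is an explicit input — from a callable mask, an external count, or the
simulator's truth table.  `S_N/A` counts call-set variants whose genotype
in the sample is missing despite the position being callable; a site that
is heterozygous but fails the per-sample depth contributes to `S_N/A`, not
`S_HET`.  No multiple-substitution correction is applied to `H_I` (the
correction lives in the coding module, which is why corrected synonymous
heterozygosity can exceed genome-wide `H_I`).

Sites are exonic if they overlap any CDS or 5'/3' UTR interval of any gene
model; everything else is non-exonic.  The partition is exhaustive and
disjoint, so exonic + non-exonic counts reproduce the genome-wide ones.

Window heterozygosity `H_W` is the number of heterozygous calls divided by
all non-missing calls at SNP positions in a window.  Windows are 1-based
inclusive `[start, start+size−1]`, anchored at base 1, advanced by the
step; windows extending past the contig end are dropped (not truncated) so
per-window denominators stay comparable.  Defaults: 100 kb windows, 10 kb
step, and `min_snps = 10` — windows with fewer SNPs are reported but
flagged and excluded from genome-wide means/SDs and the outlier scan,
since near-empty windows would otherwise dominate the variance.

## Nucleotide diversity and Tajima's D

Per-site π for `k` alternate alleles among `n` called chromosomes is
`k(n−k)/C(n,2)`; per-site `n` is always twice the non-missing genotype
count at that site.  Windowed π divides summed per-site values by the
callable base count — the full window size by default, or the masked base
count when a callable BED is given.

Tajima's D uses the standard coefficients (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂)
evaluated at a per-window effective chromosome count
`n_D = floor(mean per-site called chromosomes over the window's SNPs)`;
requiring a single `n` across a window would discard data under scattered
missingness, and per-site π keeps its own `n` regardless.  `D` is reported
as missing (not 0) when `S = 0`, the variance term is non-positive, or
`n_D < 4`; downstream means and SDs skip missing windows.

These are genotype-call-based estimators.  Genotype-likelihood machinery
(ANGSD-style) would integrate over call uncertainty and filter at the base
level; with hard calls from ~10x data the absolute π level is not
comparable to likelihood-based estimates, which is why correctness here
rests on internal oracles and synthetic recovery rather than on matching
any published data-derived mean.

## Outlier regions and enrichment

Window statistics are standardised with the **sample** SD (n−1) over
non-flagged, non-missing windows (conventional for genome scans).  An
outlier region is a maximal run of ≥ 4 consecutive windows with |z| > 3 and
a common sign; overlapping sliding windows are consecutive when their
starts differ by exactly one step on the same contig, and a flagged or
missing window, a contig boundary, or a sign change breaks the run.  Runs
never mix directions (high and low regions are tabulated separately).
The region span is the union of member windows.

Genes overlap a region at ≥ 1 bp.  Enrichment is the upper-tail
hypergeometric probability P(X ≥ k) per term over a user-supplied flat
gene→term map, adjusted with Benjamini–Yekutieli across tested terms
(terms with zero list hits are skipped); GO-graph ancestor propagation is
out of scope — feed a pre-propagated map if that is wanted.  The default
report cutoff is adjusted p < 0.01.

## Coding selection (H_A/H_S)

Each sample's two alleles over a gene are built by substituting its SNP
genotypes into the reference spliced CDS (reverse-complemented for minus
strand; the leading phase bases are trimmed): hom-alt substitutes both
alleles, het substitutes allele B only, missing leaves the reference base.
Putting all alternates on one pseudo-haplotype is safe because difference
counting averages over within-codon substitution pathways, making per-codon
results phase-insensitive, and inter-codon phase never enters NG86-style
counting.

Site counts follow NG86: each codon position contributes f/3 synonymous
sites, f being the fraction of its three possible changes that preserve
the amino acid; changes creating stop codons count as nonsynonymous.
Codons with ambiguity codes or reference-frame internal stops are skipped
and counted; a terminal stop codon is excluded, so syn + nonsyn sites equal
the analysed CDS length (spliced length − 3 for a stop-terminated gene).
Codon pairs differing at 2–3 positions average over all substitution
orderings with equal weight; pathways through intermediate stop codons are
excluded whenever an alternative exists.  Proportions are corrected for
multiple substitutions with the Jukes–Cantor transform
`h = −(3/4)ln(1 − 4p/3)` (undefined at p ≥ 3/4, flagged).  This NG86 + JC
combination is deterministic and testable; model-averaging Ka/Ks schemes
blend substitution models whose composite behaviour cannot be pinned down
for verification.

Per-gene records require ≥ 5 heterozygous CDS sites (`min_het`), below
which a ratio is mostly noise.  Genome-wide `H_A`/`H_S` concatenates 100
randomly chosen genes per replicate (pooling count numerators and
denominators before correcting) over 1,000 seeded replicates and reports
per-sample means.  The permutation median test draws same-size gene sets
without replacement from the universe of genes with ≥ 5 het sites in ≥ 1
sample (gene ratio = mean over qualifying samples) and reports both
one-sided p-values (`p_ge`, `p_le`), since a gene set may be extreme in
either direction.  The exact Wilcoxon signed-rank test drops zero
differences, assigns average ranks to ties, enumerates all 2ⁿ sign vectors
(n ≤ 20) and returns `2·min(P(W≤w), P(W≥w))` capped at 1.

## Distances and clustering

The half-weight Hamming distance scores het vs either homozygote 0.5 and
opposite homozygotes 1.0 per site (identical states, including het–het,
score 0), summed over mutually non-missing sites and normalised per pair
(pairwise deletion).  It is not guaranteed to satisfy the triangle
inequality and is used as a dissimilarity, not a metric.  The homozygous
p-distance is the mismatch fraction over a homozygous-only call-set and is
exported as PHYLIP/NEXUS matrices for external phylogenetic-network
software; an optional concatenated pseudo-alignment FASTA (missing → N) is
equivalent under pairwise deletion.  Clustering is scipy agglomerative
linkage — complete by default (the common default of heatmap-style
clustering wrappers), configurable — with samples sorted lexicographically
first so tie-breaking is deterministic, and Newick export with branch
lengths as height differences.

## mtDNA

From per-position A/C/G/T read counts: positions below depth 10 are
skipped; a minor-allele fraction ≥ 0.2 calls heteroplasmy; otherwise a
major allele differing from the reference is a fixed SNP.  The numeric
thresholds replace by-eye browser inspection and make classification
monotone in the threshold.  NUMT contamination can mimic heteroplasmy and
is not modelled; calls deserve inspection.  The copy-number proxy is the
ratio of mean mitochondrial to mean nuclear per-site coverage, reported to
the unit place.  Synonymous/nonsynonymous annotation of mtDNA variants
reuses the coding machinery with a configurable code table (invertebrate
mitochondrial codes differ from the standard code).

## Synthetic data generator

The generator emulates the statistical structure of a 10-sample panel of
clonally propagated anemone genomes — it is a controllable test harness,
not a population-genetic simulator of record (no coalescent, no
recombination, no read-level simulation).

Genotypes are drawn directly from per-site allele counts on 16 chromosomes
(8 unique genets; two samples are clone copies).  The site-frequency
spectrum is a mixture: with probability 0.67 a "rare" site with alt count
i drawn ∝ i^−2.3 assigned to random chromosomes, and with probability 0.33
a cluster-private site (one of three clusters chosen by size; members'
chromosomes carry the alternate with probability 0.85).  The cluster-
private sites create the between-cluster distances that clustering must
recover and mimic a panel with few shared derived polymorphisms.

Two published panel features are jointly impossible under Hardy–Weinberg
genotype assignment: a mean heterozygous-call fraction of 0.37 at SNP
sites and a negative genome-wide Tajima's D.  With random allele-to-genet
assignment the expected het fraction equals expected per-site π, and π
above 1/a₁ (0.30 at n = 16) forces D > 0.  The generator therefore models
**heterozygote excess** — the expected state of a clonally reproducing,
rarely outcrossing animal — via allele-count-preserving hom/hom → het/het
swaps (`het_boost`): each swap raises the het count by two without touching
the allele count, so π, θ_W and D are exactly invariant while H_W rises.
The defaults (rare_gamma 2.3, share_prob 0.33, het_boost 1.0) were
calibrated once so the realised panel shows mean H_W ≈ 0.37 and mean D ≈
−0.4; a `neutral` SFS mode (weights ∝ 1/i, no sharing) yields mean D ≈ 0
for estimator validation.

Planted regions span 200 kb (≥ 4 overlapping 100 kb windows by
construction): *balancing* regions draw intermediate counts
(1 + Binomial(14, 0.5)) at 1.2× density, elevating H_W, π and D;
*sweep* regions carry singletons only at 0.15× density, depressing all
three.  Region lengths are kept small relative to the 6 Mb genome so the
planted windows do not inflate the genome-wide SD enough to hide the
low-diversity tail (π is bounded below by zero, so sweep detection is the
SD-sensitive side).

Coding genes (140 by default; 450–960 bp CDS, 1–3 exons, both strands,
valid ORFs) are placed outside planted regions.  Each gene gets a ratio
class — background 0.22, low 0.07, high 0.64 — and its SNPs are split
between synonymous and nonsynonymous changes with the synonymous share
f_s = S/(S + R·A) (S, A the gene's NG86 site totals) so the expected
realised ratio matches the class; at most one SNP per codon keeps planted
classes clean, and alternates never create stop codons.  Realised class
medians sit near the planted values with an upward bias on the high class
(ratio-of-noisy-counts effect at ~16 SNPs per gene); the classes remain
cleanly separable, which is what the permutation test checks.

Observed genotypes add, in order: hom↔het error flips at rate 0.006 per
call (clone copies flip independently, giving expected clone discordance
2e(1−e) ≈ 1.2 %), missingness at 0.03, negative-binomial depth (per-sample
means 13–20, dispersion 8) and GQ ≈ 3·DP + N(0, 10) clipped to [0, 99] so
the DP/GQ filters mask a realistic ~10 % of calls.  Alternate alleles
favour the transition partner with probability 0.58, reproducing a
transition-dominated spectrum.  Two percent of sites are planted to
violate one hard-filter rule each (chosen uniformly), exercising every
removal path.

`callable_total` in the truth table plays the role of the externally
derived per-sample callable-position count: it is set to
`n_het·pass_rate/target + n_sites·(1 − pass_rate)` (pass rate measured on
the emitted DP/GQ/missingness, planted-bad sites excluded), which makes
the H_I estimator unbiased for the per-sample targets (0.37–0.58 %) under
the same genotype masking that thins the heterozygous calls.  Targets that
would require more callable positions than the genome holds raise a
configuration error.

mtDNA tables place one fixed SNP in one sample and one shared heteroplasmic
site (45 % minor fraction) in a clone pair over a 3 kb mitochondrial
reference, with per-sample coverage at configured mtDNA:nuclear ratios
(10–42, mean ≈ 19).

**What passing tests show, and don't.**  The generator produces exact
biallelic genotypes with independent sites: there is no linkage
disequilibrium, no allele-frequency drift along chromosomes, no mapping
artefacts, no depth–genotype correlation, and INFO annotations are drawn
independently of the genotypes.  Recovery results therefore validate the
estimators and the scanning logic, not robustness to correlated errors in
real alignments.

## Problem sizes and numerics

Default simulated scale is 2 × 3 Mb contigs, ~14,000 SNPs, 140 genes —
chosen so a full pipeline run (simulation through coding counts) completes
in seconds on one CPU while every window statistic still rests on ~200
SNPs per 100 kb window and 582 windows.  The test suite and the acceptance
script both run at this scale.  Tolerances: planted-rate recoveries are
checked within 3 binomial standard errors at their realised problem sizes;
closed-form identities at 1e-9 or tighter; permutation p-values at the
resolution of 10,000 draws.  Degenerate inputs (empty call-sets, constant
tracks, zero variance, saturated proportions p ≥ 3/4, all-zero difference
vectors) raise explicit errors or return flagged missing values rather
than silently producing numbers.
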