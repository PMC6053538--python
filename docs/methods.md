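# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, and what the synthetic data does and does not emulate.

## The synthetic stand

**Species divergence.** Two partially diverged species share an ancestral
allele frequency per site, drawn uniform on [0.05, 0.95]; each species'
frequency is a Balding–Nichols Beta draw with mean p and variance
F·p(1−p), F being the nominal Fst (default 0.07, a realistic value for a
pair of hybridizing sister tree species). This is the simplest generator
with a tunable Fst whose realized per-locus distribution is L-shaped at
low divergence — most loci barely differentiated, a thin tail of strongly
differentiated ones — which is exactly the regime the two-cluster
assignment and the per-locus Fst scan must cope with. The pooled
(ratio-of-sums) Weir–Cockerham estimator over many loci recovers the
nominal F (verified to ±0.01 at 20,000 loci in the tests). Frequencies
are never clipped away from 0/1 except by the Beta draw itself.

**Pedigree.** Founders are unrelated and non-inbred. Families are
requested per species by category — parent–offspring, full-sib, half-sib
(one shared parent, two unrelated mates), and selfed — and each family
consumes fresh founders, so the produced pairs carry exactly the
classical expectations 0.5 / 0.5 / 0.25 / 1 with no side relationships.
"Admixed" founders draw one haplotype from each species.

**Genotypes** come from Mendelian gene dropping: founder haplotypes are
Bernoulli draws from the species frequency (Hardy–Weinberg), and each
offspring allele is a copy of one uniformly chosen parental allele per
locus. Allele copies can carry founder-origin tags, which makes the
conservation property (every allele traces to a founder) directly
testable.

**Read counts.** Depth is negative-binomial with mean 95× (typical of a
capture assay at this multiplexing level) and dispersion k = 3, i.e.
variance μ + μ²/k — capture runs show large between-run and between-site
depth variation, and the dispersion is a config knob. A 2% per-cell
dropout models failed capture and creates realistic missingness once the
depth ≥ 10 calling rule is applied. Given the genotype, each read is the
alternate allele with probability ε (hom-ref), ½ (het) or 1−ε (hom-alt);
ε defaults to 0.005.

**Fitness.** Offspring counts are Poisson with
log E[F] = α + β₁X + γI, where X is a latent environment factor
expressed through five correlated Gaussian covariates (loadings 0.8–0.4;
the first principal axis of the covariates recovers X) and I is true
inbreeding. Defaults α = 2.0 (mean ≈ 7 offspring for an average
outbred tree, consistent with a parentage analysis of a few thousand
seedlings over a few hundred adults), γ = −3.6 (the magnitude reported
for reproductive-success inbreeding depression in the motivating stand).
Stem circumference is Gaussian with an age covariate (felling age uniform
on 78–102 years) and its own inbreeding coefficient (default −30 cm per
unit inbreeding, noise SD 20 cm).

**Toy genome.** Scaffolds (default 4–5, last one flagged unanchored, so
the unanchored-scaffold site filter has something to remove) carry random
sequence whose GC content varies by ~1 kb block (Beta(6,6)), so the
30–60% GC filter genuinely removes a tail of candidates. Genes
(600–6,000 bp, 1–4 exons, exon-first/exon-last structure) are placed
non-overlapping; transposable elements are intervals filled with one of
three family sequences pasted into the scaffold, so the genome is
genuinely repetitive where the TE track says it is and the repeat filter
has real work to do.

**What the simulation does not emulate:** linkage (sites segregate
independently, so LD pruning on simulated data only removes the pedigree-
induced correlation), mapping artifacts and allelic dropout bias,
indels/multi-allelic sites, selection, and spatial structure. Passing
tests therefore validate the estimators and the cascade logic under the
stated sampling models, not robustness to real-data artifacts.

## Capture-target design

Genes shorter than 1.5 kb yield one 150 bp exonic target (centered in
the longest exon); longer genes are split into thirds and yield one
exonic target in one extreme third and one intron–exon junction target
(150 bp centered on a boundary) in the other, preferring exon-first /
junction-last and swapping when only the mirror arrangement fits. A
single-exon long gene has no junction; it falls back to a second exonic
target in the opposite third (logged). Genes whose exons cannot hold
150 bp are reported and skipped. Target categories are classified by the
realized footprint (fully exonic / fully intronic / spanning), so
"intron" targets can arise from clipped junction placements.

Intergenic targets: one 150 bp candidate at the start of each 100 kb
window that contains no previously selected target, shifted downstream in
150 bp steps while it overlaps a TE; a window exhausted by TEs yields
nothing. Gene overlap is deliberately not a shift trigger — only TEs are.

Filters: GC in [0.30, 0.60] with both bounds inclusive (the prose rule
"between 30 and 60%" is ambiguous; inclusive is chosen and tested at the
boundaries). Repetitiveness is counted as approximate full-length
matches at ≥ 90% identity on either strand, found by non-overlapping
exact 15-mer seeding and verified by Hamming distance; a target is kept
with fewer than 10 hits. This is a self-contained surrogate for an
aligner-based count: a true match is found whenever at least one of its
ten seed k-mers is mutation-free, which holds for any match with at most
nine mismatches and for essentially all random placements of up to 15.
The exhaustive sliding-window scan is the test oracle.

Probes are 120 bp: length arithmetic dictates one centered probe for a
150 bp target (two non-overlapping 120-mers need ≥ 240 bp) and two
end-anchored probes for targets of at least 240 bp. All coordinates are
0-based half-open internally; BED is written natively, GFF3 converted on
read; everything is reported on the forward strand (GC and matching are
strand-symmetric).

## Calling and the filtering cascade

A cell needs depth ≥ 10 (the replicate-analysis phrasing "depth ≥ 10" is
taken over the looser "more than 10×" appearing elsewhere); the
within-individual alternate-read fraction then calls −1 below 30%, +1
above 70%, heterozygote otherwise, with the 30% boundary itself calling
heterozygote (inclusive, tested). A site is a SNP only if at least one
individual is heterozygous — read literally, a site where the two
homozygote classes are both present but no het exists is *not* a SNP;
this literal reading is implemented and tested. Cascade order: calling →
polymorphism → sample missingness (> 20% removed) → site call rate
(< 95% removed) and unanchored scaffolds. Branch-specific filters (HWE,
LD, maf) are applied by the analyses that need them. Every stage removes
calls, never edits them (tested).

The HWE exact test conditions on allele counts and sums the
probabilities of all heterozygote counts no more probable than the one
observed (log-gamma arithmetic, normalized by log-sum-exp); it agrees
with an exact-rational full enumeration to 1e−9 relative and is
uniform-conservative under a simulated null. Adjusted p-values come from
Benjamini–Hochberg step-up; markers are retained when adjusted p > 0.05.

LD pruning: genotypic r² (squared Pearson correlation of the −1/0/+1
codes over pairwise-complete individuals — phase is not simulated, so the
composite genotypic correlation replaces the haplotype r² a phased-data
tool would use). Greedy left-to-right scan: a marker is dropped when its
r² with any kept marker among the previous 50 exceeds 0.4; the earlier
marker of an offending pair always survives, which makes the result
deterministic and order-stable. Spacing mode keeps markers greedily with
≥ 1,000 bp gaps. Population maf tiers use strict "exceeds": a site at
maf exactly 0.01 fails the 0.01 tier.

## Relatedness and inbreeding

The G denominator's centering term "2(pᵢ ± 0.5)" is implemented as
2(pᵢ − 0.5): with codes in {−1, 0, +1} only the minus sign centers the
genotype to mean zero under Hardy–Weinberg. pᵢ is the frequency of the
+1-coded allele (not folded to minor), keeping centering
orientation-consistent. Missing genotypes are imputed to the locus mean
2pᵢ − 1 (zero after centering) by default; a pairwise-complete mode
rescales each pair's cross-product instead. Frequencies are estimated
in-sample by default — as a real study must — which is what produces the
documented downward bias of realized relatedness in samples containing
relatives; a known-truth frequency mode exists for simulation studies.
G is computed per species for species-level analyses (pooling the two
species inflates within-species relatedness through the Wahlund effect;
the per-species convention follows the study design the package
emulates), and jointly when a single-population analysis is wanted —
the downstream fitness regression uses the joint-G inbreeding.

The tabular method builds A in generation order: Aᵢᵢ = 1 + ½A(sire, dam),
Aᵢⱼ = ½(A(j, sire) + A(j, dam)); it matches an independent top-down
kinship recursion on every tested pedigree.

## Structure and assignment

Per-locus Fst is the Weir–Cockerham (1984) two-population
variance-components estimator (a, b, c) from genotype counts, with
mean/median over defined loci and the pooled ratio-of-sums estimator
reported separately (the pooled form is the calibrated one; the mean of
per-locus ratios is biased downward, and the median is far below the
mean under the L-shaped distribution).

Species assignment uses a maximum-likelihood two-cluster admixture
model — each allele copy originates from cluster A with the individual's
ancestry q and is the alternate allele with the cluster's frequency —
fitted by EM with SQUAREM extrapolation (plain EM needs thousands of
iterations to saturate q near the boundaries; the extrapolated step is
accepted only when it does not decrease the likelihood, so the trace
stays monotone). Ancestry is initialized from the leading principal axis
of the centered dosage matrix, min-max scaled into (0, 1). Convergence:
relative log-likelihood change below 1e−8. Cluster labels are anchored
to the individual with the highest initial q. A flat-likelihood flag
marks unidentifiable q: the two-cluster fit must beat the one-cluster
(pooled-frequency) model by more than its extra parameter count
(an AIC-style likelihood-ratio rule), else q is meaningless. Thresholds
q ≥ 0.9 / q ≤ 0.1 (inclusive) label purebreds; everything between is
admixed. Only K = 2 is supported; the model is a deliberately light
surrogate for a full variational-Bayes structure program, adequate
because downstream analysis consumes q only through coarse thresholds.
The marker set fed to the EM is the 1,000 bp spacing-pruned,
HWE-passing set.

## Inbreeding–fitness regression

Reproductive success: Poisson GLM with log link (statsmodels IRLS,
deviance tolerance 1e−8, max 100 iterations) of offspring counts on the
first principal axis of the five standardized environmental covariates
and on genomic inbreeding. Covariates are centered so the intercept is
the phenotypic mean; centering provably leaves slopes, standard errors
and p-values unchanged (asserted numerically in the tests). Growth:
ordinary least squares with felling age as an additional covariate.
p-values are two-sided Wald z (Poisson) and t (linear). The PC1 sign is
fixed by making the first variable's loading non-negative. Degenerate
inputs (all-zero counts, constant covariates, rank-deficient designs)
raise errors rather than returning garbage.

## Problem sizes and numerical choices

The default pipeline run uses 2,000 markers, ~125 trees and a 400 kb
toy genome, completing in seconds. The parameter-recovery suite uses
100 stands of 287 trees (140 founders per species plus the family
structure above — matching the size of the motivating stand) at 10,000
markers, where the in-sample-frequency bias is ≈ −0.02 per category; the
marker-count contrast (82 vs 10,000) reproduces the variance inflation
seen with legacy marker panels. GLM recovery uses n = 150 per replicate,
200 replicates for CI coverage and 1,000 for the type-I error rate
(200 replicates would leave ≈ ±0.015 Monte-Carlo noise on a 0.05 rate,
too coarse to verify a [0.03, 0.07] band). Ties and degeneracies: the
GC bounds are inclusive; the heterozygote calling boundary is inclusive;
maf tiers are strict; the LD pruner keeps the earlier marker; the EM
falls back to the plain double-EM step whenever extrapolation would
reduce the likelihood.

## Known limitations

- No linkage in the simulator, so r²-window pruning is exercised mainly
  by duplicated/correlated columns and pedigree structure.
- The admixture surrogate supports K = 2 only and reports no credible
  intervals on q.
- The repeat counter is Hamming-based (no indels); an aligner would
  count gapped matches slightly differently.
- Replicate "different alleles" can only arise through differing
  alternate alleles, which the diallelic simulator never produces; the
  report supports them through optional per-site allele strings.
- The VCF writer emits minimal GT-only records; it is not a general VCF
  emitter.
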