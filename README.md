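# standkin

Capture-based genotyping and genomic relatedness for mixed forest stands,
end to end and fully simulated: **standkin** reimplements, as a tested
pipeline with a synthetic-data generator, the analysis chain used to
genotype a mixed stand of two hybridizing sister tree species (pedunculate
and sessile oak are the motivating case) by targeted sequence capture —
from probe design on an annotated genome, through SNP calling and
filtering, to marker-based relatedness, inbreeding, species assignment,
and inbreeding–fitness regression.

It is aimed at population geneticists who want to prototype or validate a
capture-based relatedness study before (or instead of) touching real
sequencing data: every input the pipeline consumes can be generated with
known ground truth, so pedigree expectations, estimator bias, and power
are all checkable.

## What it computes

**Genomic relatedness (VanRaden form).** With genotypes coded −1/0/+1 in
an *n* × *m* matrix **M** and per-locus allele frequencies *pᵢ* for the
+1-coded allele,

    G = (M − P)(M − P)′ / (2 Σᵢ pᵢ(1 − pᵢ)),

where column *i* of **P** is 2(pᵢ − ½). A non-inbred individual matching
population frequencies has G₍ᵢᵢ₎ = 1, so genomic inbreeding is
**F = Gᵢᵢ − 1**. Pedigree expectations come from the tabular additive
relationship matrix **A** (parent–offspring and full sibs 0.5, half sibs
0.25, parent vs selfed offspring 1).

**Around it**, the package provides: Balding–Nichols two-species allele
frequencies with a tunable Fst; Mendelian gene dropping through arbitrary
pedigrees; overdispersed read-depth simulation; the SNP calling rule
(depth ≥ 10, within-individual allele-read fraction 30%) and filtering
cascade (polymorphism, 20% sample missingness, 95% site call rate,
unanchored-scaffold removal, exact Hardy–Weinberg test with
Benjamini–Hochberg FDR, LD pruning by r² window or base-pair spacing,
population-maf tiers); capture-target selection and 120-bp probe tiling
with GC and repetitiveness filters; enrichment/reproducibility QC;
per-locus Weir–Cockerham Fst; a two-cluster admixture EM with the q ≥ 0.9
/ q ≤ 0.1 purebred thresholds; and Poisson / linear inbreeding-depression
regressions.

## Worked example

Simulate a two-species stand with known families, sequence it, call and
filter SNPs, and compare realized to expected relatedness:

```python
import numpy as np
import standkin as sk

families = {"A": {"full_sib": 1, "selfed": 1}, "B": {"half_sib": 1}}
ped = sk.build_pedigree(60, 60, families, seed=1)
freqs = sk.simulate_species_freqs(5000, fst=0.07, seed=2)
geno = sk.drop_genotypes(ped, freqs, seed=3)
reads = sk.simulate_read_counts(geno, mean_depth=95, seed=4)
called, stages = sk.filtering.apply_filter_cascade(reads)
print(stages.to_string(index=False))

sp = ped.table["species"].to_numpy() == "A"
samples = [s for s, k in zip(called.samples, sp) if k]
G = sk.grm(called.codes[np.asarray(sp)])
print(sk.compare_realized_expected(G, samples, ped).to_string(index=False))
```

Output:

```
                 stage  samples  sites
                called      125   5000
           polymorphic      125   4996
    sample_missingness      125   4996
site_callrate_anchored      125   4797
               category  n_pairs  expected  mean_realized  var_realized  mean_deviation
               full_sib        1       0.5       0.436944      0.000000       -0.063056
       parent_offspring        4       0.5       0.422140      0.000102       -0.077860
selfed_parent_offspring        1       1.0       0.932901      0.000000       -0.067099
```

The cascade report shows what each filter removed (4,797 of 5,000
simulated sites survive calling, polymorphism, missingness and call-rate
filters). The comparison table reads: the full-sib pair's realized
relatedness is 0.437 against the pedigree expectation 0.5, and every
category sits slightly *below* expectation — the well-known downward bias
of marker-based relatedness when allele frequencies are estimated from a
sample that itself contains relatives. The selfed offspring's parent
shows the characteristic coefficient near 1.

The same analysis chain runs as a CLI over on-disk FASTA / GFF3 / BED /
VCF / TSV artifacts:

```sh
standkin run-all --seed 1 --out myrun        # or: simulate, design, qc,
standkin design --out myrun                  # filter, relate, structure,
standkin fitness --out myrun                 # fitness, individually
```

Each run writes a `manifest.json` with per-artifact checksums; the same
configuration and seed reproduce it byte for byte.

## Layout

| module | contents |
| --- | --- |
| `standkin.simulate` | species frequencies, pedigree, gene dropping, read counts, fitness, toy genome |
| `standkin.targets` | capture-target selection, GC/repeat filters, probe tiling, accounting |
| `standkin.qc` | on-target/breadth/depth metrics, replicate and cross-platform concordance |
| `standkin.filtering` | genotype calling, filtering cascade, HWE exact test, FDR, LD pruning |
| `standkin.relatedness` | VanRaden G, genomic inbreeding, tabular A, realized-vs-expected |
| `standkin.structure` | Weir–Cockerham per-locus Fst, two-cluster admixture EM, q thresholds |
| `standkin.fitness` | environment PCA, Poisson and linear inbreeding-depression regressions |
| `standkin.pipeline` / `standkin.cli` | configuration-driven orchestration and the `standkin` command |

See `docs/methods.md` for the models, parameter choices, and limitations.
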