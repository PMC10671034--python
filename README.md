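# qtlallele

Dissecting a quantitative trait in an inbred landrace panel into a
**QTL-allele system**: many loci, each with multiple haplotype alleles, whose
joint constitution describes every accession in the population — and what
breeders could build from it by recombination.

The package was written for the analysis of insect antixenosis (non-preference
resistance) in a selfing crop panel scored with the damaged leaf percentage
(DLP, 0–100%) across multiple environments, but every stage is generic for a
percentage-scale trait in a homozygous diversity panel.

## What it computes

1. **Plot phenotypes** — a plot's trait value is the CV-weighted average of
   repeated observations: weights `P_i = CV_i / ΣCV_i` over observation times,
   `PM = Σ P_i Y_i`. Variance components come from the expected mean squares
   of the balanced accession × environment × replicate ANOVA, with
   broad-sense heritability `h² = σ²g / (σ²g + σ²ge/n + σ²e/(nr))`.
2. **SNPLDB markers** — after SNP QC (missing and heterozygosity ≤ 20%,
   MAF ≥ 1%), adjacent SNPs with all-pairs D′ > 0.7 are merged into LD-block
   markers whose observed haplotypes act as multiple alleles (rare haplotypes
   below 1% pooled). A marker-sharing similarity matrix supplies eigenvector
   covariates for population structure.
3. **Restricted two-stage multi-locus scan** — single-marker F-tests
   preselect markers (p ≤ 0.05); forward-selection/backward-deletion stepwise
   regression then builds a multi-locus model whose cumulative contribution
   is capped by the trait heritability, followed by the same procedure for
   marker × environment (QEI) terms. Per-locus contributions are Type-III
   partial R² (percent of phenotypic SS); allele effects are least-squares
   estimates under a per-locus sum-to-zero constraint (negative = lower DLP =
   more resistant). Loci with R² ≥ 1% are large-contribution (LC), the rest
   small-contribution (SC).
4. **QTL-allele matrix** — loci × accessions table of carried-allele effects,
   plus per-accession sums and sign counts.
5. **Cross prediction** — for every parent pair, 2000 fully inbred progenies
   are simulated from the matrix under a linkage model (Haldane map from
   1 cM/Mb, inbred-line recombination `R = 2r/(1+2r)`) or independent
   assortment; the 25th percentile of progeny DLP is the predicted cross
   value, and recombination potentials are the gaps between population
   mean/minimum and the best P25.
6. **Resistance-group differentiation** — accessions split 20/60/20 into
   susceptible (SV), moderately resistant (MRV) and resistant (RV) groups;
   an allele is *increased* in a group when absent from the reference group
   but present in the derived one, *decreased* in the converse case.
7. **Candidate genes** — genes within 50 kb of an associated marker whose
   internal SNPs associate with the marker haplotypes by contingency
   chi-square at p ≤ 0.05, tallied over eight biological-process categories.

A synthetic-data module generates populations with exactly this structure
(founder-genealogy LD blocks, planted multi-allelic QTLs, G×E and residual
noise calibrated to a target heritability) so the whole pipeline is testable
end to end, and the package ships the published summary tables it validates
against as CSV fixtures.

## Worked example

```bash
qtlallele simulate --out demo --seed 7 --accessions 150 --chromosomes 6 \
    --snps-per-chromosome 40 --qtls 4
# simulated 150 accessions, 240 SNPs, 4 QTLs; realized h2 = 0.767

qtlallele run-all --genotypes demo/genotypes.vcf \
    --phenotypes demo/phenotypes.csv --genes demo/genes.gff3 \
    --out demo/results --seed 7
# h2 = 0.767; 4 loci detected (4 main, 0 QEI); outputs in demo/results
# recombination potential: average 2.96, max improvement 16.99, max transgression -3.31
```

The detected-locus table (`demo/results/qtl_table.csv`) names loci by
chromosome and physical rank and reports allele number, significance and
contribution per locus:

```
qtl,marker,chromosome,position,an,main_neglog10p,main_r2,qei_neglog10p,qei_r2,class
q-DLP-01-1,ldb_1_132733,1,132733,4,19.2,11.39,,,LC
q-DLP-02-1,ldb_2_2097852,2,2097852,4,16.8,9.89,,,LC
q-DLP-03-1,ldb_3_1025861,3,1025861,4,16.1,9.43,,,LC
q-DLP-06-1,ldb_6_1823060,6,1823060,4,17.8,10.47,,,LC
```

All four planted QTLs are recovered as multi-allelic LC loci. The
recombination-potential line says the best predicted cross's 25th-percentile
progeny DLP sits 16.99 points below the population mean; the negative
transgression (−3.31) means no cross beats the single best accession in this
small four-locus demo. The output directory also holds the QTL-allele
matrix, all cross predictions, the SV/MRV/RV allele-change table and the
candidate-gene list, plus a `manifest.json` recording every parameter and
seed.

The same stages are available as library functions
(`qtlallele.simulate_population`, `qtlallele.two_stage_scan`,
`qtlallele.predict_all_crosses`, ...) and as further subcommands
(`qc`, `snpldb`, `allele-change`).

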