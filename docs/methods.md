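# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions, and the design decisions behind `qtlallele`.

## Phenotype model

A plot (one accession in one replicate of one environment) is scored
repeatedly as damage accumulates; the plot value is the weighted average
`PM = Σ P_i Y_i` with `P_i = CV_i / ΣCV_i`, where `CV_i` is the coefficient
of variation of observation time `i` **across accessions within one
(environment, replicate) set**. The rationale for this weighting is that an
observation time at which accessions differ more (relative to its mean
severity) is more informative about genetic differences. Computing CVs per
replicate rather than pooled per environment is a choice this package makes
because each replicate is scored as a unit in the field protocol; with a
shared damage trajectory the two conventions give identical weights.
Degenerate all-zero CVs fall back to equal weights with a warning.

Variance components are method-of-moments estimates from the balanced
two-way expected mean squares:

    MS_g  = σ²e + r σ²ge + n r σ²g
    MS_ge = σ²e + r σ²ge
    MS_e  = σ²e

with `n` environments and `r` replicates; genotype F is tested against the
G×E stratum (against residual in a single environment). Negative estimates
are truncated at zero and flagged — standard EMS practice. Broad-sense
heritability on an accession-mean basis is
`h² = σ²g / (σ²g + σ²ge/n + σ²e/(nr))` (multi-environment) or
`σ²g / (σ²g + σ²e/r)` (single environment). GCV and error CV are `σg/μ` and
`σe/μ` in percent. REML/mixed models are deliberately out of scope; the EMS
route is the procedure the pipeline mirrors, and `statsmodels` serves as an
independent cross-check in the test suite, not as the implementation.
Duncan's new multiple range test is implemented from the studentized-range
distribution with protection levels `α_p = 1 − (1−α)^(p−1)`; Tukey HSD can
be obtained by fixing the protection level, but Duncan is the default
reported letter set.

## SNPLDB markers

Inbred encoding: heterozygous calls (≤ 20% by QC) are set missing, so
haplotypes are read directly from homozygotes instead of EM phasing; the
residual missing calls are mode-imputed per SNP before block construction.
QC removes SNPs with missing rate > 20%, heterozygosity > 20% or MAF < 1%.

D′ between two biallelic SNPs is `|p_AB − p_A p_B| / D_max` with the
standard D_max, computed on pairwise-complete homozygous observations.
Blocks are built by greedy left-to-right merging within a chromosome: the
next SNP joins the current block iff its D′ with **every** block member
exceeds 0.7 and the block span stays within a 200 kb cap. The source
procedure states only the D′ > 0.7 criterion; the all-pairs rule and the
span cap are this package's documented substitutes (the cap prevents
chromosome-scale blocks in strongly drifted populations). Haplotypes over a
block's SNPs are the marker's alleles; haplotypes below 1% frequency are
pooled into a single `rare` allele so every accession keeps a call, and
markers left monomorphic are dropped.

Genetic similarity between accessions is the share of markers identical in
state. Structure covariates are the top-k (default 10) eigenvectors of the
double-centered similarity matrix — the principal-coordinate convention, so
the leading eigenvector captures the strongest population split rather than
the constant direction, and the covariates are orthogonal to the intercept.

## Two-stage multi-locus scan

Observations are accession × environment cell means. Stage 1 fits, per
marker, environment + structure covariates + the multi-allelic marker term
and F-tests the marker; markers with p ≤ 0.05 (unadjusted, configurable)
are preselected. Stage 2 runs forward selection / backward deletion over
the preselected marker terms: the forward step adds the candidate with the
smallest partial-F p-value if it clears the entry threshold **and** the
cumulative model R² stays within the heritability cap (the trait's own h²
estimate); the backward step removes any term whose partial-F p-value
exceeds the stay threshold. After the main-effect model stabilizes,
marker × environment interaction terms are scanned the same way over all
preselected markers, so a locus may carry a main effect, an interaction
effect, or both. Ties in forward selection break by smaller p, then smaller
chromosome/position; collinear duplicates never enter because their partial
contribution is zero.

Significance control: the default mode is experimentwise Bonferroni with
the stage-1 family size (the number of markers screened) as the divisor.
Scaling by the *preselected* count does not control the family-wise error —
preselection is itself a selection on the same F-tests, and simulations
under the null then report a spurious locus in most runs — so this package
uses the full family. An "unadjusted 0.05" mode mirrors the plainest
reading of the stated threshold. Under the default mode, 20 null
simulations yield zero scans with a reported locus (nominal ≤ ~5%).

Per-locus contribution is the Type-III partial sum of squares over the
total phenotypic sum of squares with environment main effects removed,
reported in percent; R² ≥ 1% classifies a locus as large-contribution (LC,
boundary inclusive). Allele effects are the least-squares coefficients
re-expressed under an unweighted sum-to-zero constraint per locus; the
model intercept μ is the grand mean of the cell means. Negative allele
effects lower the trait (for a damage percentage: increase resistance).

## QTL-allele matrix and cross prediction

The matrix holds, per main-effect locus and accession, the effect of the
carried allele; rare-collapsed alleles carry their estimated joint effect
so the matrix is complete. `μ + column sum` approximates an accession's
genotypic value.

Cross prediction simulates fully inbred progenies: per chromosome, a
progeny's haplotype is a Markov mosaic of the two parents — the first locus
comes from either parent with probability ½, each next locus switches
parental origin with probability `R` (linkage model) or ½ (independent
assortment). No genetic map is available, so physical positions convert at
1 cM/Mb, distances map to per-meiosis recombination fractions through the
Haldane function, and `R = 2r/(1+2r)` encodes the extra effective
recombination of repeated selfing. Progeny are generated directly at
fixation (one recombinant gamete, doubled): the F∞ marginal distribution is
all the percentile summary needs. Values are pure genotypic values
(μ + summed effects), with no residual noise, matching the notion of a
predicted genotypic cross value. Percentiles use linear interpolation
(type 7). Per-cross seeds derive from SHA-256 of the master seed and the
sorted parent ids, making results independent of evaluation order; parent
order within a pair is canonicalized for the same reason. Because the map
is a stand-in, linkage-model outputs at real scale are indicative, not
reproductions.

Recombination potentials: `mean − mean(P25)` (average),
`mean − min(P25)` (maximum improvement), `min − min(P25)` (maximum
transgression), all on the trait's percent scale.

## Resistance groups and allele changes

Accessions rank ascending by trait value; the lowest ⌊0.2N⌋ form RV, the
highest ⌊0.2N⌋ SV, the remainder MRV (ties break by accession id). Between
a reference and a derived group an allele is *increased* iff its frequency
is zero in the reference and positive in the derived group, *decreased* in
the converse case, *inherent* otherwise. This presence/absence rule — not
any graded frequency shift — is the only rule that reproduces the published
changed-allele marginals from the published frequency table, which is the
module's core regression test. The union comparison ("MRV and RV vs SV")
marks an allele changed when either pairwise comparison against SV does;
increased and decreased cannot collide there because both compare against
the same reference. Sign-by-direction counts (increased-negative,
decreased-positive) are tallied among gene-annotated alleles.

## Candidate genes

Genes whose 1-based inclusive span intersects the closed window
[marker start − 50 kb, marker end + 50 kb] are candidates; the window is
measured from the marker's member-SNP span, not its midpoint. Each SNP
inside a candidate gene is tested against the marker's haplotype alleles by
contingency chi-square without continuity correction (low expected counts
are flagged); a gene is retained when its most significant SNP reaches
p ≤ 0.05. No multiple-testing correction is applied across genes by
default (a Bonferroni mode exists but is off). The eight GO
biological-process categories are input labels carried through to tallies,
not derived from the GO graph.

## Synthetic-data generator

The generator emulates the study design the analysis assumes, at reduced
scale so everything runs in seconds on one CPU:

- **Defaults**: 370 accessions, 20 chromosomes × 50 SNPs over 2.5 Mb,
  LD blocks of exponential mean span 150 kb with 4 founder haplotypes,
  10 QTLs with 2–4 alleles, RMS allele effect 3.5 DLP points, 3
  environments × 3 replicates, heritability target 0.77 with 40% of the
  non-genetic deficit assigned to G×E, population mean 44.5%.
- **LD**: founder haplotypes per block come from a random founder genealogy
  — each SNP mutates once on one clade — so within-block SNP pairs show at
  most three gamete types and D′ is exactly 1, the structure an LD-block
  marker assumes; between blocks founder draws are independent. Founder
  frequencies are Dirichlet; optional subpopulations draw divergent
  frequency vectors to plant detectable structure.
- **QTLs** are designated blocks whose founders are collapsed into k allele
  classes; eligibility requires common founder classes (≥ 5% each),
  pairwise-distinct frequent-founder haplotypes, member SNPs safe from the
  MAF filter, and a span within the block builder's cap — i.e. planted loci
  are in principle taggable, so recovery failures indict the method, not
  the plant. Allele effects are drawn normal, centered (unweighted mean
  zero), and rescaled to a fixed RMS so no planted locus is degenerate by
  the luck of the draw.
- **Noise calibration**: with realized genotypic variance σ²g and target
  h², the deficit D = σ²g(1/h² − 1) is split into σ²ge = n·f·D and
  σ²e = n·r·(1−f)·D (f = G×E fraction). Draws are standardized to exact
  sample moments, which keeps the realized (ANOVA-estimated) h² within a
  few points of target at the default design size; a target unreachable
  from zero genotypic variance raises a configuration error.
- **Observation expansion**: plot values expand into per-time observations
  `Y_t = m_t + s_t·Z` with prescribed per-time CVs and a rising severity
  pattern, normalized so the CV-weighted average recovers the plot value
  *exactly* (the round-trip identity is a test); a common shrink factor on
  the dispersions keeps observations inside [0, 100] — weights are
  invariant to it, extreme sets compress slightly toward their mean.
- **Gene models**: planted candidate genes cover a member SNP of a QTL
  block (so their SNPs co-segregate with the QTL haplotypes); background
  genes are placed ≥ 200 kb from every QTL. Categories I–VIII are drawn
  uniformly.
- **Seeds**: one master seed; components (genotypes, effects, phenotypes,
  observations, genes) use `SeedSequence(master_seed, spawn_key=(k,))`
  children, so identical seeds give byte-identical outputs and components
  can be regenerated independently.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: admixture or continuous population
structure beyond discrete founder subpopulations, LD decay within blocks
and across block boundaries, genotyping error beyond simple missing/het
corruption, dominance and epistasis, non-Gaussian residuals, and
environment-specific variance heterogeneity. Parameter-recovery results at
the default scale quantify internal consistency of the pipeline, not field
performance.

## Problem sizes in tests and validation

The validation suite uses 20 seeded replicates of a 400-accession, 10-QTL,
h² = 0.75 population (~1000 SNPs each) for power and effect-recovery
checks — detection counts a true QTL when a retained main-effect locus lies
within 300 kb (one to two LD blocks), and effect recovery is the Pearson
correlation between true and estimated per-accession locus contributions
pooled over detected loci, which avoids arbitrary allele-label matching.
Null error control uses 20 scans of 200-accession pure-noise populations.
The acceptance script uses 10 replicates of each. These sizes are the
package's chosen validation design; all complete in well under a minute
each on one CPU.

## Known limitations

- Stage-1 preselection at unadjusted 0.05 is a stated stand-in for the
  original procedure's unprinted liberal criterion (~50% retention).
- The EMS ANOVA assumes (near-)balance; strongly unbalanced trials would
  need REML, which is out of scope.
- The 1 cM/Mb map is uniform; real recombination landscapes are not, so
  linkage-model cross predictions at real scale are approximate by design.
- The greedy block algorithm is order-dependent at boundaries; the block
  recovery test bounds, but does not eliminate, boundary disagreement.
- Duncan letters use the harmonic mean of group sizes in unbalanced data.
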