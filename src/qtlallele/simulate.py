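"""Synthetic genotype/phenotype/annotation generator.

Emulates, at a configurable reduced scale, a selfing landrace diversity
panel scored for a percentage trait in a multi-environment replicated
trial: ~370 fully homozygous accessions over 20 chromosomes, SNPs organised
in founder-haplotype LD blocks, a set of multi-allelic QTLs whose alleles
are the haplotypes of designated blocks, fixed environment effects,
genotype-by-environment deviations and plot residuals calibrated so the
broad-sense heritability of the simulated trial hits a target (default
0.77).

LD structure uses a block-copy model: each chromosome is partitioned into
segments of exponentially distributed physical length, each segment carries
a few founder haplotypes, and every accession copies one founder per
segment. Within a segment D' is (near) 1 between informative SNP pairs;
between segments SNPs are independent.

Seeds: one master seed; per-component child seeds come from
``numpy.random.SeedSequence(master_seed, spawn_key=(k,))`` with a fixed
component index k, so each piece can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from qtlallele.phenotype import anova_components, heritability
from qtlallele.snpldb import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ConfigurationError",
    "simulate_population",
    "simulate_dlp_observations",
    "simulate_gene_annotation",
]

# child-seed component indices (stable public scheme)
_SEED_GENOTYPES = 0
_SEED_EFFECTS = 1
_SEED_PHENOTYPE = 2
_SEED_OBSERVATIONS = 3
_SEED_GENES = 4


class ConfigurationError(ValueError):
    """A simulation request that cannot be satisfied as specified."""


@dataclass
class SimulationConfig:
    """Study-design constants of the emulated trial.

    Defaults mirror the design being emulated: 370 accessions from a
    landrace panel, 20 chromosomes, three environments with three
    replicates, heritability target 0.77 and a population mean of 44.5 on
    the 0-100 percent scale. Genome size and SNP density are reduced-scale
    stand-ins (2.5 Mb chromosomes, 50 SNPs each, ~150 kb LD blocks) so the
    full pipeline runs in seconds.
    """

    n_accessions: int = 370
    n_chromosomes: int = 20
    snps_per_chromosome: int = 50
    chromosome_length: int = 2_500_000
    ld_block_mean_span: int = 150_000
    founders_per_block: int = 4
    n_true_qtls: int = 10
    alleles_per_qtl: tuple[int, int] = (2, 4)
    qtl_block_max_span: int = 200_000
    effect_scale: float = 3.5
    heritability_target: float = 0.77
    n_environments: int = 3
    n_replicates: int = 3
    gxe_variance_fraction: float = 0.4
    env_effect_scale: float = 3.0
    population_mean: float = 44.5
    n_subpopulations: int = 1
    subpop_divergence: float = 2.0
    master_seed: int = 20230

    def __post_init__(self):
        counts = {
            "n_accessions": self.n_accessions,
            "n_chromosomes": self.n_chromosomes,
            "snps_per_chromosome": self.snps_per_chromosome,
            "chromosome_length": self.chromosome_length,
            "ld_block_mean_span": self.ld_block_mean_span,
            "founders_per_block": self.founders_per_block,
            "n_environments": self.n_environments,
            "n_replicates": self.n_replicates,
            "n_subpopulations": self.n_subpopulations,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        if self.n_true_qtls < 0:
            raise ConfigurationError("n_true_qtls must be >= 0")
        if not 0 < self.heritability_target <= 1:
            raise ConfigurationError("heritability_target must be in (0, 1]")
        if not 0 <= self.gxe_variance_fraction <= 1:
            raise ConfigurationError("gxe_variance_fraction must be in [0, 1]")
        lo, hi = self.alleles_per_qtl
        if lo < 2 or hi < lo:
            raise ConfigurationError("alleles_per_qtl must be a range with min >= 2")

    def child_rng(self, component: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.master_seed, spawn_key=(component,))
        )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated population, for parameter recovery."""

    qtl_positions: list[tuple]  # (chromosome, bp) per QTL
    qtl_snp_ids: list[list[str]]  # member SNPs of each QTL block
    allele_assignment: np.ndarray  # n_qtls x n_accessions allele index
    allele_effects: list[np.ndarray]  # per QTL, mean-zero over alleles
    genotypic_values: np.ndarray  # mu + summed allele effects per accession
    env_effects: np.ndarray
    sigma2_ge: float
    sigma2_e: float
    realized_h2: float
    block_id_per_snp: np.ndarray  # generator block membership, all SNPs
    subpopulation: np.ndarray


def _founder_haplotypes(n_f: int, n_snp: int, rng) -> np.ndarray:
    """Founder haplotypes from a random founder genealogy.

    Each SNP's derived allele is carried by one clade of a random binary
    tree over the founders (a single mutation, no recurrence), so any two
    SNPs in the block show at most three of the four gamete types and
    within-block D' is 1 — the haplotype structure an LD block assumes.
    """
    groups: list[frozenset] = [frozenset([i]) for i in range(n_f)]
    clades: list[frozenset] = list(groups)
    while len(groups) > 1:
        i, j = rng.choice(len(groups), size=2, replace=False)
        merged = groups[i] | groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(merged)
        if len(groups) > 1:
            clades.append(merged)
    founders = np.zeros((n_f, n_snp), dtype=np.int8)
    for s in range(n_snp):
        clade = clades[rng.integers(len(clades))]
        founders[list(clade), s] = 1
    return founders


def _partition_blocks(pos: np.ndarray, mean_span: float, rng) -> list[np.ndarray]:
    """Cut a chromosome's SNP indices into exponential-length segments."""
    blocks, current = [], [0]
    limit = pos[0] + rng.exponential(mean_span)
    for k in range(1, pos.size):
        if pos[k] <= limit:
            current.append(k)
        else:
            blocks.append(np.array(current))
            current = [k]
            limit = pos[k] + rng.exponential(mean_span)
    blocks.append(np.array(current))
    return blocks


def simulate_population(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate genotypes, plot phenotypes and their ground truth.

    Returns the homozygous genotype matrix, a tidy plot table
    (``accession, environment, replicate, value``) whose values are already
    on the weighted plot scale, and the :class:`SyntheticTruth`.
    """
    rng_g = config.child_rng(_SEED_GENOTYPES)
    n_acc = config.n_accessions

    accessions = [f"A{i + 1:04d}" for i in range(n_acc)]
    subpop = np.arange(n_acc) % config.n_subpopulations

    snp_rows = []
    hap_cols = []  # per-SNP founder allele column (0/1), n_acc
    block_records = []  # (chrom, snp_index list, founder assignment)
    block_id_per_snp = []
    snp_counter = 0
    block_counter = 0
    for c in range(1, config.n_chromosomes + 1):
        pos = np.sort(
            rng_g.choice(
                np.arange(1, config.chromosome_length + 1),
                size=config.snps_per_chromosome,
                replace=False,
            )
        )
        blocks = _partition_blocks(pos.astype(float), config.ld_block_mean_span, rng_g)
        for blk in blocks:
            n_snp = blk.size
            n_f = config.founders_per_block
            founders = _founder_haplotypes(n_f, n_snp, rng_g)
            # founder frequencies; subpopulations draw their own frequency
            # vectors, more divergent at lower Dirichlet concentration
            conc = 2.0 if config.n_subpopulations == 1 else 2.0 / config.subpop_divergence
            assign = np.empty(n_acc, dtype=np.int32)
            for s in range(config.n_subpopulations):
                freqs = rng_g.dirichlet(np.full(n_f, conc))
                members = np.where(subpop == s)[0]
                assign[members] = rng_g.choice(n_f, size=members.size, p=freqs)
            block_records.append(
                (c, list(range(snp_counter, snp_counter + n_snp)), assign, founders)
            )
            block_id_per_snp.extend([block_counter] * n_snp)
            block_counter += 1
            for j in range(n_snp):
                snp_rows.append(
                    {"id": f"snp_{c:02d}_{pos[blk[j]]}", "chrom": c, "pos": int(pos[blk[j]])}
                )
                hap_cols.append(founders[assign, j])
            snp_counter += n_snp

    snps = pd.DataFrame(snp_rows)
    haps = np.column_stack(hap_cols)  # n_acc x n_snps, founder alleles 0/1
    codes = (haps * 2).astype(np.int8)
    genotypes = GenotypeMatrix(codes, accessions, snps)

    # --- plant QTLs on blocks with enough realized founder classes
    rng_e = config.child_rng(_SEED_EFFECTS)
    lo, hi = config.alleles_per_qtl

    def _eligible(rec) -> bool:
        # a planted locus must stay taggable by the block's haplotypes:
        # enough common founder classes, every frequent founder carrying a
        # distinct haplotype, member SNPs safe from the MAF filter, and a
        # span a block builder with a standard cap will not fragment
        _, snp_idx, founder_assign, founders = rec
        present, counts = np.unique(founder_assign, return_counts=True)
        frequent = present[counts / n_acc >= 0.05]
        if frequent.size < lo:
            return False
        hap_strings = {tuple(founders[fk]) for fk in frequent}
        if len(hap_strings) < frequent.size:
            return False
        span = int(snps_span(snp_idx))
        if span > config.qtl_block_max_span:
            return False
        sub = codes[:, snp_idx]
        p_alt = (sub == 2).mean(axis=0)
        return bool(np.all(np.minimum(p_alt, 1 - p_alt) >= 0.05))

    def snps_span(snp_idx) -> int:
        pos = snps.loc[snp_idx, "pos"]
        return int(pos.max() - pos.min())

    eligible = [(i, rec) for i, rec in enumerate(block_records) if _eligible(rec)]
    if config.n_true_qtls > len(eligible):
        raise ConfigurationError(
            f"requested {config.n_true_qtls} QTLs but only {len(eligible)} "
            "blocks have enough distinct haplotypes"
        )
    chosen = rng_e.choice(len(eligible), size=config.n_true_qtls, replace=False)
    chosen = sorted(chosen)

    qtl_positions, qtl_snp_ids, effects_per_qtl = [], [], []
    assignment = np.zeros((config.n_true_qtls, n_acc), dtype=np.int32)
    genotypic = np.full(n_acc, config.population_mean, dtype=float)
    for q, pick in enumerate(chosen):
        _, (chrom, snp_idx, founder_assign, _founders) = eligible[pick]
        founders_present = np.unique(founder_assign)
        k_target = int(rng_e.integers(lo, hi + 1))
        k = min(k_target, founders_present.size)
        # collapse founders into k allele classes
        classes = rng_e.permutation(founders_present.size) % k
        class_of = dict(zip(founders_present, classes))
        alleles = np.array([class_of[f] for f in founder_assign], dtype=np.int32)
        eff = rng_e.normal(0.0, 1.0, size=k)
        eff -= eff.mean()  # unweighted mean-zero constraint per locus
        rms = float(np.sqrt(np.mean(eff**2)))
        if rms > 0:
            # effect_scale is the RMS allele effect of every planted locus,
            # so no QTL is degenerate by the luck of the draw
            eff *= config.effect_scale / rms
        assignment[q] = alleles
        effects_per_qtl.append(eff)
        genotypic += eff[alleles]
        qtl_positions.append((chrom, int(snps.loc[snp_idx, "pos"].iloc[0])))
        qtl_snp_ids.append(list(snps.loc[snp_idx, "id"]))

    # --- noise calibration from the realized genotypic variance
    rng_p = config.child_rng(_SEED_PHENOTYPE)
    n_env, n_rep = config.n_environments, config.n_replicates
    sigma2_g = float(np.var(genotypic, ddof=1))
    h2 = config.heritability_target
    if sigma2_g == 0.0:
        if h2 > 0.05:
            raise ConfigurationError(
                "no genotypic variance (n_true_qtls=0 or single-class QTLs) "
                f"but heritability_target={h2}; unreachable"
            )
        base = max(config.effect_scale, 1.0) ** 2
        sigma2_ge = n_env * config.gxe_variance_fraction * base
        sigma2_e = n_env * n_rep * (1 - config.gxe_variance_fraction) * base
    else:
        deficit = sigma2_g * (1.0 / h2 - 1.0)
        sigma2_ge = n_env * config.gxe_variance_fraction * deficit
        sigma2_e = n_env * n_rep * (1 - config.gxe_variance_fraction) * deficit

    env_names = [f"E{j + 1}" for j in range(n_env)]
    env_eff = rng_p.normal(0.0, config.env_effect_scale, size=n_env)
    env_eff -= env_eff.mean()
    if n_env == 1:
        env_eff[:] = 0.0

    def _standardized(shape, sd, rng):
        """Noise with sample mean 0 and sample variance exactly sd**2."""
        if sd == 0:
            return np.zeros(shape)
        z = rng.normal(size=shape)
        z -= z.mean()
        s = z.std(ddof=1)
        return z * (sd / s) if s > 0 else z

    ge = _standardized((n_acc, n_env), np.sqrt(sigma2_ge), rng_p) if n_env > 1 else np.zeros((n_acc, 1))
    rows = []
    for j, env in enumerate(env_names):
        resid = _standardized((n_acc, n_rep), np.sqrt(sigma2_e), rng_p)
        for rep in range(n_rep):
            vals = genotypic + env_eff[j] + ge[:, j] + resid[:, rep]
            rows.append(
                pd.DataFrame(
                    {
                        "accession": accessions,
                        "environment": env,
                        "replicate": rep + 1,
                        "value": vals,
                    }
                )
            )
    phenotypes = pd.concat(rows, ignore_index=True)

    if config.n_true_qtls > 0 and (n_rep > 1 or n_env > 1):
        vc = anova_components(phenotypes)
        realized = heritability(vc, multi_env=n_env > 1)
    else:
        realized = 0.0

    truth = SyntheticTruth(
        qtl_positions=qtl_positions,
        qtl_snp_ids=qtl_snp_ids,
        allele_assignment=assignment,
        allele_effects=effects_per_qtl,
        genotypic_values=genotypic,
        env_effects=env_eff,
        sigma2_ge=float(sigma2_ge) if n_env > 1 else 0.0,
        sigma2_e=float(sigma2_e),
        realized_h2=float(realized),
        block_id_per_snp=np.array(block_id_per_snp),
        subpopulation=subpop,
    )
    return genotypes, phenotypes, truth


def simulate_dlp_observations(
    plot_values: pd.DataFrame,
    n_times: int = 3,
    cv_targets: np.ndarray | None = None,
    stage_pattern: np.ndarray | None = None,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Expand plot values into per-time observations with distinct CVs.

    Per (environment, replicate) set, observation time t gets values
    ``Y_t = m_t + s_t * Z`` where Z is the standardized plot value across
    accessions; the time means follow ``stage_pattern`` (feeding damage
    grows over the scoring window) and the time CVs follow ``cv_targets``
    (early scores vary relatively more). The constants are normalized so
    that the CV-weighted average recovers the input plot value exactly,
    giving a round-trip identity with
    :func:`qtlallele.phenotype.plot_values_from_observations`.

    The intended plot value is carried in column ``intended``.
    """
    if n_times < 2:
        raise ValueError("need at least two observation times")
    if cv_targets is None:
        cv_targets = np.linspace(0.35, 0.15, n_times)
    cv_targets = np.asarray(cv_targets, dtype=float)
    if stage_pattern is None:
        stage_pattern = np.linspace(0.6, 1.4, n_times)
    stage_pattern = np.asarray(stage_pattern, dtype=float)
    if cv_targets.size != n_times or stage_pattern.size != n_times:
        raise ValueError("cv_targets/stage_pattern must have n_times entries")

    p = cv_targets / cv_targets.sum()
    out = []
    for (env, rep), grp in plot_values.groupby(["environment", "replicate"], sort=True):
        pm = grp["value"].to_numpy(dtype=float)
        mean = pm.mean()
        sd = pm.std(ddof=1) if pm.size > 1 else 0.0
        intended = pm
        if sd == 0:
            y = np.tile(pm[:, None], (1, n_times))
        else:
            z = (pm - mean) / sd
            m = mean * stage_pattern / float(p @ stage_pattern)
            c = sd / float(p @ (cv_targets * m))
            s = c * cv_targets * m
            # keep every observation inside [0, 100]: shrink all s_t by a
            # common factor (weights are invariant to it); the intended plot
            # value compresses toward the set mean by the same factor
            z_max, z_min = z.max(), z.min()
            gamma = 1.0
            for t in range(n_times):
                if z_max > 0:
                    gamma = min(gamma, (100.0 - m[t]) / (s[t] * z_max))
                if z_min < 0:
                    gamma = min(gamma, (0.0 - m[t]) / (s[t] * z_min))
            gamma = max(gamma, 0.0)
            s = s * gamma
            # gamma bounds y analytically; the clip only removes roundoff
            y = np.clip(m[None, :] + np.outer(z, s), 0.0, 100.0)
            intended = mean + gamma * sd * z
        for t in range(n_times):
            out.append(
                pd.DataFrame(
                    {
                        "accession": grp["accession"].to_numpy(),
                        "environment": env,
                        "replicate": rep,
                        "time": t + 1,
                        "value": y[:, t],
                        "intended": intended,
                    }
                )
            )
    return pd.concat(out, ignore_index=True)


def simulate_gene_annotation(
    truth: SyntheticTruth,
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    genes_per_qtl: int = 2,
    n_background: int = 30,
    gene_span: int = 4_000,
) -> pd.DataFrame:
    """Gene models near (and away from) the true QTLs, with GO categories.

    Each true QTL receives up to ``genes_per_qtl`` genes whose spans cover a
    member SNP of the QTL block (so SNPs inside the gene co-segregate with
    the QTL haplotype); background genes are placed away from every QTL.
    Categories are drawn from the eight-way biological-process scheme
    I..VIII. Coordinates are 1-based inclusive.
    """
    rng = config.child_rng(_SEED_GENES)
    categories = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    records = []
    snp_by_id = genotypes.snps.set_index("id")
    gid = 1
    for q, snp_ids in enumerate(truth.qtl_snp_ids):
        take = min(genes_per_qtl, len(snp_ids))
        picked = rng.choice(len(snp_ids), size=take, replace=False)
        for s in picked:
            row = snp_by_id.loc[snp_ids[s]]
            start = max(1, int(row["pos"]) - gene_span // 2)
            records.append(
                {
                    "gene": f"Gene{gid:04d}",
                    "chrom": row["chrom"],
                    "start": start,
                    "end": start + gene_span - 1,
                    "category": categories[rng.integers(0, len(categories))],
                    "near_qtl": truth.qtl_positions[q][0:2],
                }
            )
            gid += 1
    qtl_by_chrom: dict = {}
    for chrom, pos in truth.qtl_positions:
        qtl_by_chrom.setdefault(chrom, []).append(pos)
    tries = 0
    while n_background > 0 and tries < 50 * n_background:
        tries += 1
        chrom = int(rng.integers(1, config.n_chromosomes + 1))
        start = int(rng.integers(1, max(2, config.chromosome_length - gene_span)))
        end = start + gene_span - 1
        if any(abs(p - start) < 200_000 for p in qtl_by_chrom.get(chrom, [])):
            continue
        records.append(
            {
                "gene": f"Gene{gid:04d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "category": categories[rng.integers(0, len(categories))],
                "near_qtl": None,
            }
        )
        gid += 1
        n_background -= 1
    return pd.DataFrame(records)
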