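"""File formats, run configuration and the end-to-end pipeline.

Genotypes travel as VCF (homozygous diploid calls for inbred lines) or as a
plain accession x SNP CSV whose column headers encode ``id|chrom|pos`` and
whose cells are {0, 2, NA} (homozygous codes; 1 marks a heterozygous call).
Phenotypes are tidy CSV (accession, environment, replicate[, time], value);
gene models are GFF3-formatted with a ``category`` attribute.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from qtlallele import allele_matrix as am
from qtlallele import association, crosses, genes as genes_mod, groups as groups_mod
from qtlallele import phenotype as phen
from qtlallele import snpldb as snpldb_mod
from qtlallele.snpldb import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "read_genes",
    "write_genes",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults."""

    genotype_path: str | None = None
    genotype_format: str = "vcf"
    phenotype_path: str | None = None
    gene_path: str | None = None
    output_dir: str = "qtlallele_out"

    max_missing: float = 0.20
    max_het: float = 0.20
    min_maf: float = 0.01
    d_threshold: float = 0.70
    max_block_span: int = 200_000
    rare_haplotype_freq: float = 0.01
    n_structure_covariates: int = 10

    preselect_alpha: float = 0.05
    enter_alpha: float = 0.05
    remove_alpha: float = 0.05
    correction: str = "bonferroni"
    use_heritability_cap: bool = True
    trait: str = "DLP"

    map_rate_cm_per_mb: float = 1.0
    cross_model: str = "linkage"
    n_progeny: int = 2000
    group_proportions: tuple[float, float, float] = (0.2, 0.6, 0.2)
    gene_window: int = 50_000
    gene_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("max_missing", "max_het", "min_maf", "preselect_alpha",
                     "enter_alpha", "remove_alpha", "gene_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_maf > 0.5:
            raise ValueError(f"min_maf={self.min_maf} exceeds 0.5; no SNP can pass")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if self.cross_model not in ("linkage", "independent"):
            raise ValueError("cross_model must be 'linkage' or 'independent'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "group_proportions" in data:
            data["group_proportions"] = tuple(data["group_proportions"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_proportions"] = list(d["group_proportions"])
        return d


# ---------------------------------------------------------------------------
# genotype formats

_VCF_CODE = {(0, 0): 0, (1, 1): 2, (0, 1): 1, (1, 0): 1}


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the package CSV dialect."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "csv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows, cols = [], []
    for i, variant in enumerate(vcf):
        gts = variant.genotype.array()
        codes = np.full(len(accessions), MISSING, dtype=np.int8)
        for s in range(len(accessions)):
            a, b = int(gts[s, 0]), int(gts[s, 1])
            if a < 0 or b < 0:
                continue
            codes[s] = _VCF_CODE.get((a, b), 1)
        rows.append({"id": variant.ID or f"snp{i}", "chrom": _as_chrom(variant.CHROM),
                     "pos": variant.POS})
        cols.append(codes)
    if not rows:
        raise ValueError(f"{path}: no variant records")
    return GenotypeMatrix(np.column_stack(cols), accessions, pd.DataFrame(rows))


def _as_chrom(c):
    try:
        return int(str(c).lstrip("chr"))
    except ValueError:
        return c


def _read_csv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    snp_rows = []
    for col in df.columns:
        parts = col.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"{path}: column {col!r} is not 'id|chrom|pos'"
            )
        snp_rows.append({"id": parts[0], "chrom": _as_chrom(parts[1]), "pos": int(parts[2])})
    codes = np.full(df.shape, MISSING, dtype=np.int8)
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            v = values[i, j]
            if pd.isna(v):
                continue
            if v not in (0, 1, 2):
                raise ValueError(
                    f"{path}: unknown allele code {v!r} at accession "
                    f"{df.index[i]!r}, SNP {df.columns[j]!r}"
                )
            codes[i, j] = int(v)
    return GenotypeMatrix(codes, list(df.index.astype(str)), pd.DataFrame(snp_rows))


def write_genotypes(g: GenotypeMatrix, path, fmt: str = "vcf") -> None:
    path = Path(path)
    if fmt == "vcf":
        _write_vcf(g, path)
    elif fmt == "csv":
        cols = [f"{r.id}|{r.chrom}|{r.pos}" for r in g.snps.itertuples()]
        df = pd.DataFrame(g.codes, index=g.accessions, columns=cols)
        df = df.astype(object).mask(df == MISSING, other=pd.NA)
        df.to_csv(path, index_label="accession")
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    gt_of = {0: "0/0", 2: "1/1", 1: "0/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=qtlallele\n")
        for chrom in pd.unique(g.snps["chrom"]):
            length = int(g.snps.loc[g.snps["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.accessions) + "\n")
        for j, snp in enumerate(g.snps.itertuples()):
            gts = "\t".join(gt_of[int(c)] for c in g.codes[:, j])
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.id}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"accession", "environment", "replicate", "value"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: phenotype CSV lacks columns {sorted(missing)}")
    return df


def write_genes(genes: pd.DataFrame, path) -> None:
    """GFF3 gene rows with ID and category attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            attrs = f"ID={row.gene};category={row.category}"
            fh.write(
                f"{row.chrom}\tqtlallele\tgene\t{row.start}\t{row.end}\t.\t+\t.\t{attrs}\n"
            )


def read_genes(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF columns, got {len(parts)}")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene": attrs.get("ID", f"gene{ln}"),
                    "chrom": _as_chrom(parts[0]),
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "category": attrs.get("category"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(
    config: RunConfig,
    genotypes: GenotypeMatrix | None = None,
    phenotypes: pd.DataFrame | None = None,
    gene_table: pd.DataFrame | None = None,
) -> dict:
    """Execute the full analysis and write table outputs plus a manifest.

    Inputs may be passed in memory or read from the configured paths. The
    result bundle maps stage names to their in-memory products.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("load")
        if genotypes is None:
            if not config.genotype_path:
                raise ValueError("no genotype input")
            genotypes = read_genotypes(config.genotype_path, config.genotype_format)
        if phenotypes is None:
            if not config.phenotype_path:
                raise ValueError("no phenotype input")
            phenotypes = read_phenotypes(config.phenotype_path)
        if gene_table is None and config.gene_path:
            gene_table = read_genes(config.gene_path)

        stage("phenotype_stats")
        if "time" in phenotypes.columns and phenotypes["time"].nunique() > 1:
            plots = phen.plot_values_from_observations(phenotypes)
        else:
            plots = phenotypes[["accession", "environment", "replicate", "value"]]
        vc = phen.anova_components(plots)
        h2 = phen.heritability(vc, multi_env=vc.n_env > 1)
        acc_means = plots.groupby("accession")["value"].mean()
        summary = phen.descriptive_stats(acc_means, vc=vc)

        stage("snpldb")
        filtered, qc_report = snpldb_mod.qc_filter(
            genotypes, config.max_missing, config.max_het, config.min_maf
        )
        markers = snpldb_mod.build_blocks(
            filtered, config.d_threshold, config.max_block_span,
            config.rare_haplotype_freq,
        )
        sim = snpldb_mod.similarity_matrix(markers)
        k = min(config.n_structure_covariates, len(filtered.accessions) - 1)
        covariates = snpldb_mod.structure_covariates(sim, k)

        stage("association")
        settings = association.ScanSettings(
            preselect_alpha=config.preselect_alpha,
            enter_alpha=config.enter_alpha,
            remove_alpha=config.remove_alpha,
            heritability_cap=h2 if config.use_heritability_cap else None,
            correction=config.correction,
        )
        scan = association.two_stage_scan(
            markers, plots, filtered.accessions, covariates, settings,
            trait=config.trait,
        )

        bundle = {
            "variance_components": vc,
            "heritability": h2,
            "summary": summary,
            "qc_report": qc_report,
            "markers": markers,
            "scan": scan,
        }

        main_qtls = [q for q in scan.qtls if q.has_main]
        if main_qtls:
            stage("allele_matrix")
            markers_by_id = {m.id: m for m in markers}
            matrix = am.build_matrix(
                scan.qtls, markers_by_id, filtered.accessions, scan.intercept
            )
            bundle["matrix"] = matrix

            stage("cross_prediction")
            gmap = crosses.GeneticMap.from_positions(
                matrix.positions, config.map_rate_cm_per_mb
            )
            predictions = crosses.predict_all_crosses(
                matrix, gmap, config.cross_model, config.n_progeny, config.seed
            )
            pop_mean = float(acc_means.mean())
            pop_min = float(acc_means.min())
            potential = crosses.recombination_potential(
                pop_mean, pop_min, predictions["p25"].to_numpy()
            )
            bundle["predictions"] = predictions
            bundle["potential"] = potential
            bundle["optimal"] = crosses.optimal_crosses(predictions, pop_min)

            stage("group_differentiation")
            grp = groups_mod.assign_groups(acc_means, config.group_proportions)
            freqs = groups_mod.group_allele_frequencies(matrix.allele_calls, grp)
            effect_of = {
                (l, a): matrix.effects_by_locus[l][matrix.alleles_by_locus[l].index(a)]
                for l in matrix.loci
                for a in matrix.alleles_by_locus[l]
            }
            freqs["effect"] = [
                effect_of[(q, a)] for q, a in zip(freqs["qtl"], freqs["allele"])
            ]
            records = groups_mod.classify_records(freqs)
            bundle["groups"] = grp
            bundle["allele_changes"] = records
            bundle["change_summary"] = groups_mod.change_summary(records)

            if gene_table is not None and not gene_table.empty:
                stage("gene_annotation")
                qtl_names = {q.marker_id: q.name for q in scan.qtls}
                qtl_markers = [markers_by_id[q.marker_id] for q in scan.qtls]
                candidates = genes_mod.annotate_qtls(
                    qtl_markers, filtered, gene_table,
                    config.gene_window, config.gene_alpha, qtl_names=qtl_names,
                )
                bundle["candidates"] = candidates
                bundle["category_tally"] = genes_mod.category_tally(
                    candidates.drop_duplicates("gene")
                    if not candidates.empty else candidates
                )
                bundle["gene_integration"] = groups_mod.integrate_genes(
                    records.merge(
                        candidates[["qtl", "gene", "category"]].drop_duplicates("qtl"),
                        on="qtl", how="left",
                    )
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    _write_outputs(bundle, config, out)
    return bundle


def _write_outputs(bundle: dict, config: RunConfig, out: Path) -> None:
    header = f"# qtlallele v0.1.0 seed={config.seed}\n"

    def save(df: pd.DataFrame, name: str, **kw):
        p = out / name
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh, **kw)

    vc = bundle["variance_components"]
    save(
        pd.DataFrame(
            [{
                "sigma2_g": vc.sigma2_g, "sigma2_ge": vc.sigma2_ge,
                "sigma2_e": vc.sigma2_e, "h2": bundle["heritability"],
                "gcv": vc.gcv, "cv": vc.cv, "mu": vc.mu,
                "f_genotype": vc.f_genotype, "f_ge": vc.f_ge,
            }]
        ),
        "variance_components.csv", index=False,
    )
    save(bundle["scan"].to_frame(), "qtl_table.csv", index=False)
    if bundle["scan"].stage1 is not None:
        save(bundle["scan"].stage1, "stage1_pvalues.csv", index=False)
    save(snpldb_mod.markers_to_frame(bundle["markers"]), "snpldb_markers.csv", index=False)
    if "matrix" in bundle:
        save(bundle["matrix"].effects, "qtl_allele_matrix.csv")
        save(bundle["matrix"].allele_calls, "qtl_allele_calls.csv")
    if "predictions" in bundle:
        save(bundle["predictions"], "cross_predictions.csv", index=False)
        save(bundle["optimal"].head(20), "optimal_crosses.csv", index=False)
    if "allele_changes" in bundle:
        save(bundle["allele_changes"], "allele_changes.csv", index=False)
        save(bundle["change_summary"], "change_summary.csv")
    if "candidates" in bundle:
        save(bundle["candidates"], "candidate_genes.csv", index=False)

    manifest = {
        "package": "qtlallele",
        "version": "0.1.0",
        "parameters": config.to_dict(),
        "seed": config.seed,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    if "potential" in bundle:
        manifest["recombination_potential"] = bundle["potential"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
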