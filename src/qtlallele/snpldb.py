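"""SNP quality control and multi-allelic SNPLDB marker construction.

An SNPLDB marker is a run of adjacent SNPs in strong linkage disequilibrium
(all pairwise D' above a threshold, default 0.7) whose observed haplotypes
serve as the alleles of a single multi-allelic marker. In a selfing species
the accessions are (nearly) fully homozygous, so haplotypes are read
directly from the homozygous genotype codes; residual heterozygous calls
are set missing during QC and residual missing codes are mode-imputed per
SNP before block construction.

Genotype codes: 0 = homozygous reference, 2 = homozygous alternate,
1 = heterozygous, -1 = missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "SnpldbMarker",
    "QcReport",
    "qc_filter",
    "mode_impute",
    "pairwise_dprime",
    "build_blocks",
    "haplotype_alleles",
    "similarity_matrix",
    "structure_covariates",
]


@dataclass
class GenotypeMatrix:
    """Accession x SNP genotype codes with SNP metadata.

    ``codes`` is an int8 array of shape (n_accessions, n_snps); ``snps`` has
    columns ``id, chrom, pos`` with positions strictly increasing within a
    chromosome (1-based).
    """

    codes: np.ndarray
    accessions: list[str]
    snps: pd.DataFrame

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.accessions), len(self.snps)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.snps)} SNPs"
            )
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_rate(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=0)

    def het_rate(self) -> np.ndarray:
        return (self.codes == 1).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP from homozygous calls only."""
        alt = (self.codes == 2).sum(axis=0)
        ref = (self.codes == 0).sum(axis=0)
        total = alt + ref
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
        return np.minimum(p, 1 - p)


@dataclass
class QcReport:
    n_input: int
    n_removed_missing: int
    n_removed_het: int
    n_removed_maf: int
    n_kept: int


@dataclass
class SnpldbMarker:
    """An LD-block marker whose alleles are haplotypes with frequencies."""

    id: str
    chrom: object
    start: int
    end: int
    snp_ids: list[str]
    alleles: list[str]
    frequencies: np.ndarray
    allele_index: np.ndarray  # per-accession index into ``alleles``
    rare_collapsed: bool = False

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def span(self) -> int:
        return self.end - self.start


def qc_filter(
    g: GenotypeMatrix,
    max_missing: float = 0.20,
    max_het: float = 0.20,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing missing-rate, heterozygosity or MAF thresholds.

    Heterozygous calls are recoded missing first (inbred encoding), so the
    missing-rate criterion sees the combined missing + heterozygous load.
    """
    for name, v in (("max_missing", max_missing), ("max_het", max_het), ("min_maf", min_maf)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    het = g.het_rate()
    codes = g.codes.copy()
    codes[codes == 1] = MISSING
    g2 = GenotypeMatrix(codes, g.accessions, g.snps)

    bad_het = het > max_het
    bad_miss = g2.missing_rate() > max_missing
    maf = g2.maf()
    bad_maf = ~(maf >= min_maf)  # NaN (monomorphic/all-missing) counts as failing

    keep = ~(bad_het | bad_miss | bad_maf)
    if not keep.any():
        raise ValueError("all SNPs removed by QC")
    report = QcReport(
        n_input=g.n_snps,
        n_removed_missing=int(bad_miss.sum()),
        n_removed_het=int(bad_het.sum()),
        n_removed_maf=int(bad_maf.sum()),
        n_kept=int(keep.sum()),
    )
    filtered = GenotypeMatrix(
        codes[:, keep], g.accessions, g.snps.loc[keep].reset_index(drop=True)
    )
    logger.info(
        "QC: kept %d/%d SNPs (missing %d, het %d, maf %d flagged)",
        report.n_kept, report.n_input, report.n_removed_missing,
        report.n_removed_het, report.n_removed_maf,
    )
    return filtered, report


def mode_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Fill missing codes with the per-SNP modal homozygous code."""
    codes = g.codes.copy()
    for j in range(codes.shape[1]):
        col = codes[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        alt = int((col == 2).sum())
        ref = int((col == 0).sum())
        codes[miss, j] = 2 if alt > ref else 0
    return GenotypeMatrix(codes, g.accessions, g.snps)


def pairwise_dprime(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized linkage disequilibrium D' between two biallelic SNPs.

    Haplotypes are read from homozygous inbred genotypes on pairwise-complete
    accessions. Returns D' in [0, 1]; raises on monomorphic columns or fewer
    than two complete observations.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    ok = (a != MISSING) & (b != MISSING) & (a != 1) & (b != 1)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 complete haplotype observations")
    ha = a[ok] == 2
    hb = b[ok] == 2
    p_a = ha.mean()
    p_b = hb.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("monomorphic column; D' undefined")
    p_ab = (ha & hb).mean()
    d = p_ab - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max == 0:
        return 0.0
    return float(abs(d) / d_max)


def _dprime_or_nan(a, b) -> float:
    try:
        return pairwise_dprime(a, b)
    except ValueError:
        return float("nan")


def build_blocks(
    g: GenotypeMatrix,
    d_threshold: float = 0.7,
    max_span: int = 200_000,
    min_freq: float = 0.01,
    impute: bool = True,
) -> list[SnpldbMarker]:
    """Partition SNPs into SNPLDB markers by greedy adjacent merging.

    Walking left to right within each chromosome, the next SNP joins the
    current block iff its pairwise D' with *every* block member exceeds
    ``d_threshold`` and the block span stays within ``max_span`` bp.
    Unmerged SNPs become singleton biallelic markers. Markers left with a
    single allele after rare-haplotype collapsing are dropped (logged).
    Every retained SNP belongs to exactly one marker.
    """
    if impute:
        g = mode_impute(g)
    markers: list[SnpldbMarker] = []
    for chrom, grp in g.snps.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        block: list[int] = []
        blocks: list[list[int]] = []
        for k, j in enumerate(idx):
            if not block:
                block = [j]
                continue
            start_pos = g.snps.loc[block[0], "pos"]
            fits_span = (pos[k] - start_pos) <= max_span
            in_ld = fits_span and all(
                (dp := _dprime_or_nan(g.codes[:, m], g.codes[:, j])) > d_threshold
                and not np.isnan(dp)
                for m in block
            )
            if in_ld:
                block.append(j)
            else:
                blocks.append(block)
                block = [j]
        if block:
            blocks.append(block)
        for b in blocks:
            marker = haplotype_alleles(g, b, min_freq=min_freq)
            if marker is None:
                continue
            markers.append(marker)
    for i, m in enumerate(markers, start=1):
        m.id = f"ldb_{m.chrom}_{m.start}"
    return markers


def haplotype_alleles(
    g: GenotypeMatrix, snp_indices: list[int], min_freq: float = 0.01
) -> SnpldbMarker | None:
    """Define a marker's alleles as the haplotypes over its member SNPs.

    Haplotypes rarer than ``min_freq`` are merged into a single ``rare``
    allele class. Returns None (and logs) when only one allele remains.
    """
    sub = g.codes[:, snp_indices]
    if (sub == MISSING).any():
        raise ValueError("missing genotypes in block; impute first")
    hap_strings = np.array(["".join("1" if c == 2 else "0" for c in row) for row in sub])
    labels, counts = np.unique(hap_strings, return_counts=True)
    freqs = counts / counts.sum()

    common = freqs >= min_freq
    alleles = list(labels[common])
    rare_collapsed = bool((~common).any())
    if rare_collapsed:
        # every accession keeps an allele call, so rare haplotypes are
        # pooled into one class even when their total stays below min_freq
        alleles.append("rare")
    lookup = {a: i for i, a in enumerate(alleles)}
    allele_index = np.array(
        [lookup.get(h, lookup.get("rare")) for h in hap_strings], dtype=np.int32
    )
    n_all = len(alleles)
    freq_out = np.bincount(allele_index, minlength=n_all) / allele_index.size

    if n_all < 2:
        logger.info("marker at %s dropped: single allele", snp_indices)
        return None

    meta = g.snps.loc[snp_indices]
    return SnpldbMarker(
        id=f"ldb_{meta['chrom'].iloc[0]}_{meta['pos'].iloc[0]}",
        chrom=meta["chrom"].iloc[0],
        start=int(meta["pos"].min()),
        end=int(meta["pos"].max()),
        snp_ids=list(meta["id"]),
        alleles=alleles,
        frequencies=freq_out,
        allele_index=allele_index,
        rare_collapsed=rare_collapsed,
    )


def similarity_matrix(markers: list[SnpldbMarker]) -> np.ndarray:
    """Genetic similarity: share of markers identical in state per pair."""
    if not markers:
        raise ValueError("no markers")
    a = np.stack([m.allele_index for m in markers])  # markers x accessions
    n = a.shape[1]
    sim = np.zeros((n, n))
    chunk = 500
    for k in range(0, a.shape[0], chunk):
        blk = a[k : k + chunk]
        sim += (blk[:, :, None] == blk[:, None, :]).sum(axis=0)
    sim /= a.shape[0]
    return sim


def structure_covariates(sim: np.ndarray, k: int = 10) -> np.ndarray:
    """Top-k eigenvectors of the similarity matrix as structure covariates.

    The matrix is double-centered first (principal-coordinate convention),
    so the leading eigenvector captures the strongest population split
    rather than the constant grand-mean direction, and the covariates are
    orthogonal to a regression intercept.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = sim.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_accessions={n}")
    centered = sim - sim.mean(axis=0, keepdims=True)
    centered -= centered.mean(axis=1, keepdims=True)
    vals, vecs = np.linalg.eigh(centered)
    order = np.argsort(vals)[::-1]
    return vecs[:, order[:k]]


def markers_to_frame(markers: list[SnpldbMarker]) -> pd.DataFrame:
    """Flat marker summary (one row per marker) for TSV export."""
    return pd.DataFrame(
        {
            "id": [m.id for m in markers],
            "chrom": [m.chrom for m in markers],
            "start": [m.start for m in markers],
            "end": [m.end for m in markers],
            "n_snps": [len(m.snp_ids) for m in markers],
            "n_alleles": [m.n_alleles for m in markers],
            "alleles": ["|".join(m.alleles) for m in markers],
            "frequencies": ["|".join(f"{f:.6g}" for f in m.frequencies) for m in markers],
            "rare_collapsed": [m.rare_collapsed for m in markers],
        }
    )
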