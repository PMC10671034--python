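"""Candidate-gene inference around associated SNPLDB markers.

Genes whose spans fall within a flanking window (default 50 kb, closed
intervals measured from the marker's member-SNP span) of an associated
marker are tested for association between the marker's haplotype alleles
and the genotypes of SNPs inside the gene, with a plain contingency
chi-square (no continuity correction). A gene is retained when its most
significant SNP reaches the significance level (default 0.05, no
multiple-testing correction by default). Each gene carries one of eight
biological-process category labels (I..VIII); the labels are inputs, not
derived from the GO graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from qtlallele.snpldb import MISSING, GenotypeMatrix, SnpldbMarker

logger = logging.getLogger(__name__)

CATEGORIES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

__all__ = [
    "GeneIndex",
    "genes_near_marker",
    "snp_gene_association",
    "select_candidates",
    "annotate_qtls",
    "category_tally",
]


class GeneIndex:
    """Per-chromosome interval index over a gene table.

    The gene table needs columns ``gene, chrom, start, end`` (1-based
    inclusive) and optionally ``category``.
    """

    def __init__(self, genes: pd.DataFrame):
        self.genes = genes.reset_index(drop=True)
        self.trees: dict = {}
        for chrom, grp in self.genes.groupby("chrom", sort=False):
            tree = IntervalTree()
            for i, row in grp.iterrows():
                # +1: IntervalTree is half-open, coordinates are inclusive
                tree[row["start"] : row["end"] + 1] = i
            self.trees[chrom] = tree

    def query(self, chrom, start: int, end: int) -> pd.DataFrame:
        tree = self.trees.get(chrom)
        if tree is None:
            return self.genes.iloc[0:0]
        hits = sorted(iv.data for iv in tree[start : end + 1])
        return self.genes.iloc[hits]


def genes_near_marker(
    genes: pd.DataFrame | GeneIndex, marker: SnpldbMarker, window: int = 50_000
) -> pd.DataFrame:
    """Genes intersecting [marker.start - window, marker.end + window].

    Closed-interval semantics: a gene exactly ``window`` bp away is still a
    candidate. A chromosome mismatch is simply a non-overlap.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    lo = max(1, marker.start - window)
    hi = marker.end + window
    return index.query(marker.chrom, lo, hi)


def snp_gene_association(
    marker_alleles: np.ndarray, snp_genotypes: np.ndarray
) -> tuple[float, float, bool]:
    """Contingency chi-square between marker alleles and SNP genotypes.

    Missing entries (< 0) are dropped pairwise. Returns (chi2, p,
    low_expected) where ``low_expected`` flags any expected cell below 5.
    Raises on a degenerate (single-class) table.
    """
    a = np.asarray(marker_alleles)
    g = np.asarray(snp_genotypes)
    ok = (a >= 0) & (g != MISSING)
    a, g = a[ok], g[ok]
    if a.size == 0:
        raise ValueError("no complete observations")
    table = pd.crosstab(a, g).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (one class)")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    low = bool((expected < 5).any())
    if low:
        logger.debug("expected cell count < 5 in chi-square table")
    return float(chi2), float(p), low


def select_candidates(tested: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Genes whose most significant linked SNP reaches p <= alpha."""
    if tested.empty:
        return tested
    best = (
        tested.sort_values("p", kind="mergesort")
        .groupby("gene", as_index=False)
        .first()
    )
    return best[best["p"] <= alpha].reset_index(drop=True)


def annotate_qtls(
    qtl_markers: list[SnpldbMarker],
    genotypes: GenotypeMatrix,
    gene_table: pd.DataFrame,
    window: int = 50_000,
    alpha: float = 0.05,
    bonferroni: bool = False,
    qtl_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full candidate-gene procedure for a set of associated markers.

    For each marker: collect genes within the window, test each SNP inside
    each gene against the marker alleles, keep genes whose best SNP is
    significant. Returns one row per retained (qtl, gene) pair with the
    best chi-square statistic and p-value.
    """
    if gene_table.empty:
        return pd.DataFrame(
            columns=["qtl", "marker", "gene", "category", "chi2", "p", "n_snps", "low_expected"]
        )
    index = GeneIndex(gene_table)
    snp_pos = genotypes.snps
    rows = []
    for marker in qtl_markers:
        near = genes_near_marker(index, marker, window)
        if near.empty:
            continue
        tested = []
        for _, gene in near.iterrows():
            inside = snp_pos[
                (snp_pos["chrom"] == gene["chrom"])
                & (snp_pos["pos"] >= gene["start"])
                & (snp_pos["pos"] <= gene["end"])
            ]
            best = None
            n_ok = 0
            for j in inside.index:
                try:
                    chi2, p, low = snp_gene_association(
                        marker.allele_index, genotypes.codes[:, j]
                    )
                except ValueError:
                    continue
                n_ok += 1
                if best is None or p < best[1]:
                    best = (chi2, p, low)
            if best is not None:
                tested.append(
                    {
                        "qtl": (qtl_names or {}).get(marker.id, marker.id),
                        "marker": marker.id,
                        "gene": gene["gene"],
                        "category": gene.get("category"),
                        "chi2": best[0],
                        "p": best[1],
                        "low_expected": best[2],
                        "n_snps": n_ok,
                    }
                )
        if not tested:
            continue
        tested = pd.DataFrame(tested)
        a = alpha / len(tested) if bonferroni else alpha
        rows.append(select_candidates(tested, alpha=a))
    if not rows:
        return pd.DataFrame(
            columns=["qtl", "marker", "gene", "category", "chi2", "p", "n_snps", "low_expected"]
        )
    return pd.concat(rows, ignore_index=True)


def category_tally(genes: pd.DataFrame, column: str = "category") -> dict:
    """Gene counts per category I..VIII (unknown labels raise)."""
    counts = dict.fromkeys(CATEGORIES, 0)
    labeled = genes[genes[column].notna()] if not genes.empty else genes
    for label in labeled[column] if not genes.empty else []:
        if label not in counts:
            raise ValueError(f"unknown category label {label!r}")
        counts[label] += 1
    return counts
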