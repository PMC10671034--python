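"""The loci x accessions QTL-allele effect matrix.

Each cell holds the estimated effect of the allele an accession carries at
a detected main-effect locus; together with the population intercept the
column sums approximate each accession's genotypic value, giving a compact
description of the genetic structure of the whole panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from qtlallele.association import QtlRecord
from qtlallele.snpldb import SnpldbMarker

__all__ = ["QtlAlleleMatrix", "build_matrix", "accession_summary", "submatrix"]


@dataclass
class QtlAlleleMatrix:
    """Effects (loci x accessions), allele labels, and the intercept mu."""

    effects: pd.DataFrame  # loci rows, accession columns, float effects
    allele_calls: pd.DataFrame  # same shape, allele label strings
    effects_by_locus: dict  # locus -> np.ndarray of allele effects
    alleles_by_locus: dict  # locus -> list of allele labels
    positions: pd.DataFrame  # locus, chrom, pos
    mu: float

    @property
    def loci(self) -> list[str]:
        return list(self.effects.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.effects.columns)


def build_matrix(
    qtls: list[QtlRecord],
    markers_by_id: dict[str, SnpldbMarker],
    accessions: list[str],
    mu: float,
) -> QtlAlleleMatrix:
    """Assemble the matrix from main-effect loci and their marker calls."""
    main = [q for q in qtls if q.has_main and q.allele_effects is not None]
    if not main:
        raise ValueError("no main-effect loci to assemble")
    eff_rows, call_rows, pos_rows = [], [], []
    effects_by_locus, alleles_by_locus = {}, {}
    for q in main:
        marker = markers_by_id[q.marker_id]
        idx = marker.allele_index
        if idx.shape[0] != len(accessions):
            raise ValueError(
                f"marker {marker.id} has calls for {idx.shape[0]} accessions, "
                f"expected {len(accessions)}"
            )
        label_of = {a: i for i, a in enumerate(q.alleles)}
        # map marker allele index -> estimated-effect slot
        eff = np.full(len(marker.alleles), np.nan)
        for slot, lab in enumerate(q.alleles):
            eff[marker.alleles.index(lab)] = q.allele_effects[slot]
        cells = eff[idx]
        if np.isnan(cells).any():
            missing_acc = accessions[int(np.argmax(np.isnan(cells)))]
            raise ValueError(
                f"accession {missing_acc} carries an allele with no estimated "
                f"effect at locus {q.name}"
            )
        eff_rows.append(cells)
        call_rows.append([marker.alleles[a] for a in idx])
        pos_rows.append({"locus": q.name, "chrom": q.chrom, "pos": q.start})
        effects_by_locus[q.name] = q.allele_effects
        alleles_by_locus[q.name] = list(q.alleles)
    names = [q.name for q in main]
    return QtlAlleleMatrix(
        effects=pd.DataFrame(eff_rows, index=names, columns=accessions),
        allele_calls=pd.DataFrame(call_rows, index=names, columns=accessions),
        effects_by_locus=effects_by_locus,
        alleles_by_locus=alleles_by_locus,
        positions=pd.DataFrame(pos_rows).set_index("locus"),
        mu=float(mu),
    )


def accession_summary(m: QtlAlleleMatrix, accession: str) -> tuple[float, int, int]:
    """(sum of effects, count of negative, count of positive) for one column."""
    if accession not in m.effects.columns:
        raise KeyError(f"unknown accession {accession!r}")
    col = m.effects[accession].to_numpy()
    return float(col.sum()), int((col < 0).sum()), int((col > 0).sum())


def submatrix(m: QtlAlleleMatrix, accessions) -> QtlAlleleMatrix:
    """Column selection preserving locus order."""
    accessions = list(accessions)
    if not accessions:
        raise ValueError("empty accession subset")
    unknown = [a for a in accessions if a not in m.effects.columns]
    if unknown:
        raise KeyError(f"unknown accessions: {unknown}")
    return QtlAlleleMatrix(
        effects=m.effects[accessions],
        allele_calls=m.allele_calls[accessions],
        effects_by_locus=m.effects_by_locus,
        alleles_by_locus=m.alleles_by_locus,
        positions=m.positions,
        mu=m.mu,
    )
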