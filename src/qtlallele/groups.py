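"""Allele differentiation across phenotype-defined resistance groups.

Accessions are split by trait quantile into susceptible (SV, worst 20%),
moderately resistant (MRV, middle 60%) and resistant (RV, best 20%) groups
— for a damage percentage, higher values are more susceptible. Comparing a
derived group against a reference group, an allele is *increased* when it
is absent from the reference but present in the derived group, *decreased*
when present in the reference but absent from the derived group, and
*inherent* otherwise. This presence/absence rule, applied per allele per
locus, summarizes how the allele constitution shifts as resistance
improves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResistanceGroups",
    "assign_groups",
    "group_allele_frequencies",
    "classify_change",
    "classify_records",
    "change_summary",
    "integrate_genes",
]

COMPARISONS = (
    ("mrv_vs_sv", "freq_sv", "freq_mrv"),
    ("rv_vs_mrv", "freq_mrv", "freq_rv"),
    ("rv_vs_sv", "freq_sv", "freq_rv"),
)


@dataclass
class ResistanceGroups:
    labels: pd.Series  # accession -> {SV, MRV, RV}
    ranges: pd.DataFrame  # per group: n, min, max of the trait

    def members(self, group: str) -> list[str]:
        return list(self.labels.index[self.labels == group])


def assign_groups(
    phenotypes: pd.Series, proportions: tuple[float, float, float] = (0.2, 0.6, 0.2)
) -> ResistanceGroups:
    """Quantile split into RV (lowest), MRV, SV (highest) by trait value.

    ``proportions`` are the (SV, MRV, RV) shares and must sum to 1. With N
    accessions the RV and SV groups take floor(share * N) members each from
    the two ends of the ascending ranking; ties break by accession id.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    n = len(phenotypes)
    if n < 5:
        raise ValueError("need at least 5 accessions")
    p_sv, _, p_rv = proportions
    order = phenotypes.reset_index()
    order.columns = ["accession", "value"]
    order = order.sort_values(["value", "accession"], kind="mergesort")
    n_rv = int(np.floor(p_rv * n))
    n_sv = int(np.floor(p_sv * n))
    labels = np.array(["MRV"] * n, dtype=object)
    labels[:n_rv] = "RV"
    labels[n - n_sv:] = "SV"
    lab = pd.Series(labels, index=order["accession"].to_numpy(), name="group")
    ranges = (
        pd.DataFrame({"group": lab, "value": phenotypes.reindex(lab.index)})
        .groupby("group")["value"]
        .agg(["size", "min", "max"])
        .rename(columns={"size": "n"})
    )
    return ResistanceGroups(labels=lab, ranges=ranges)


def group_allele_frequencies(
    allele_calls: pd.DataFrame, groups: ResistanceGroups
) -> pd.DataFrame:
    """Percent carrier frequencies per allele in each group.

    ``allele_calls`` is loci x accessions (allele labels). Returns a long
    frame with columns ``qtl, allele, freq_entire, freq_sv, freq_mrv,
    freq_rv, freq_mrv_rv`` on the percent scale.
    """
    sets = {
        "entire": list(allele_calls.columns),
        "sv": groups.members("SV"),
        "mrv": groups.members("MRV"),
        "rv": groups.members("RV"),
    }
    sets["mrv_rv"] = sets["mrv"] + sets["rv"]
    for name in ("sv", "mrv", "rv"):
        if not sets[name]:
            raise ValueError(f"empty group {name.upper()}")
    rows = []
    for locus, calls in allele_calls.iterrows():
        for allele in pd.unique(calls.to_numpy()):
            row = {"qtl": locus, "allele": allele}
            for key, members in sets.items():
                sub = calls[members]
                row[f"freq_{key}"] = 100.0 * float((sub == allele).mean())
            rows.append(row)
    return pd.DataFrame(rows)


def classify_change(freq_reference: float, freq_derived: float) -> str:
    """Presence rule: increased / decreased / inherent between two groups."""
    if freq_reference < 0 or freq_derived < 0:
        raise ValueError("frequencies must be non-negative")
    if freq_reference == 0 and freq_derived > 0:
        return "increased"
    if freq_reference > 0 and freq_derived == 0:
        return "decreased"
    return "inherent"


def classify_records(freqs: pd.DataFrame) -> pd.DataFrame:
    """Add the three pairwise classifications plus the union column.

    The union ("MRV and RV compared to SV") marks an allele increased when
    it is increased in either MRV-vs-SV or RV-vs-SV, and likewise for
    decreased; the two cannot co-occur because both compare against SV.
    """
    out = freqs.copy()
    for name, ref, der in COMPARISONS:
        out[f"class_{name}"] = [
            classify_change(r, d) for r, d in zip(out[ref], out[der])
        ]
    inc = (out["class_mrv_vs_sv"] == "increased") | (out["class_rv_vs_sv"] == "increased")
    dec = (out["class_mrv_vs_sv"] == "decreased") | (out["class_rv_vs_sv"] == "decreased")
    out["class_union"] = np.select([inc, dec], ["increased", "decreased"], "inherent")
    return out


def _count(sub: pd.DataFrame) -> dict:
    return {
        "alleles": len(sub),
        "negative": int((sub["effect"] < 0).sum()),
        "positive": int((sub["effect"] > 0).sum()),
        "loci": sub["qtl"].nunique(),
    }


def change_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison changed/increased/decreased counts with sign splits.

    ``records`` must carry ``qtl, effect`` and the classification columns
    from :func:`classify_records` (added on the fly when absent). Rows:
    the three pairwise comparisons plus the union against SV.
    """
    if "class_mrv_vs_sv" not in records.columns:
        records = classify_records(records)
    rows = []
    for name, _, _ in COMPARISONS:
        cls = records[f"class_{name}"]
        inc = records[cls == "increased"]
        dec = records[cls == "decreased"]
        chg = records[cls != "inherent"]
        rows.append(
            {
                "comparison": name,
                "changed_alleles": len(chg),
                "changed_loci": chg["qtl"].nunique(),
                "increased_alleles": len(inc),
                "increased_negative": int((inc["effect"] < 0).sum()),
                "increased_positive": int((inc["effect"] > 0).sum()),
                "increased_loci": inc["qtl"].nunique(),
                "decreased_alleles": len(dec),
                "decreased_negative": int((dec["effect"] < 0).sum()),
                "decreased_positive": int((dec["effect"] > 0).sum()),
                "decreased_loci": dec["qtl"].nunique(),
            }
        )
    cls = records["class_union"]
    inc = records[cls == "increased"]
    dec = records[cls == "decreased"]
    chg = records[cls != "inherent"]
    rows.append(
        {
            "comparison": "union_vs_sv",
            "changed_alleles": len(chg),
            "changed_loci": chg["qtl"].nunique(),
            "increased_alleles": len(inc),
            "increased_negative": int((inc["effect"] < 0).sum()),
            "increased_positive": int((inc["effect"] > 0).sum()),
            "increased_loci": inc["qtl"].nunique(),
            "decreased_alleles": len(dec),
            "decreased_negative": int((dec["effect"] < 0).sum()),
            "decreased_positive": int((dec["effect"] > 0).sum()),
            "decreased_loci": dec["qtl"].nunique(),
        }
    )
    return pd.DataFrame(rows).set_index("comparison")


def integrate_genes(records: pd.DataFrame, gene_table: pd.DataFrame | None = None) -> dict:
    """Join changed alleles with gene annotations and tally the outcome.

    When ``records`` already carries ``gene``/``category`` columns (as the
    packaged change table does) no join is needed; otherwise ``gene_table``
    must map ``qtl`` to ``gene`` and ``category``. Sign-by-direction counts
    (increased-negative, decreased-positive) are reported among the
    gene-annotated alleles, which is where candidate mechanisms can be
    named.
    """
    rec = records if "class_union" in records.columns else classify_records(records)
    if "gene" not in rec.columns:
        if gene_table is None:
            rec = rec.assign(gene=None, category=None)
        else:
            cols = ["qtl", "gene"] + (["category"] if "category" in gene_table else [])
            rec = rec.merge(gene_table[cols].drop_duplicates("qtl"), on="qtl", how="left")
    changed = rec[rec["class_union"] != "inherent"]
    with_gene = changed[changed["gene"].notna()]
    inc_neg = with_gene[
        (with_gene["class_union"] == "increased") & (with_gene["effect"] < 0)
    ]
    dec_pos = with_gene[
        (with_gene["class_union"] == "decreased") & (with_gene["effect"] > 0)
    ]
    out = {
        "changed_alleles": len(changed),
        "changed_qtls": changed["qtl"].nunique(),
        "annotated_genes": with_gene["gene"].nunique(),
        "annotated_alleles": len(with_gene),
        "increased_negative_alleles": len(inc_neg),
        "increased_negative_loci": inc_neg["qtl"].nunique(),
        "decreased_positive_alleles": len(dec_pos),
        "decreased_positive_loci": dec_pos["qtl"].nunique(),
    }
    if "category" in with_gene.columns:
        out["gene_categories"] = (
            with_gene.drop_duplicates("gene")["category"].value_counts().to_dict()
        )
        out["allele_categories"] = with_gene["category"].value_counts().to_dict()
    return out
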