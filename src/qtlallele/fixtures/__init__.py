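"""Packaged reference tables.

Five small CSV tables ship with the package and back the regression tests:
per-QTL scan summaries (``table2_qtls``), candidate genes with GO categories
(``table5_genes``), increased/decreased alleles across resistance groups
(``table7_changes``), population descriptive statistics (``table1_summary``)
and the cross-prediction summary (``table3_summary``).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FIXTURES = {
    "table1_summary": "table1_summary.csv",
    "table2_qtls": "table2_qtls.csv",
    "table3_summary": "table3_summary.csv",
    "table5_genes": "table5_genes.csv",
    "table7_changes": "table7_changes.csv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables by name.

    Parameters
    ----------
    name
        One of ``table1_summary``, ``table2_qtls``, ``table3_summary``,
        ``table5_genes``, ``table7_changes``.
    """
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    ref = resources.files("qtlallele.fixtures").joinpath(fname)
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if name == "table7_changes":
        # genes apply to every allele row of an annotated locus
        df["gene"] = df["gene"].where(df["gene"].notna(), None)
    return df
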