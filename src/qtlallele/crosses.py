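"""In-silico cross prediction from the QTL-allele matrix.

For every unordered parent pair, fully inbred progenies are simulated from
the parents' locus alleles: each progeny inherits, per chromosome, a mosaic
of the two parental haplotypes generated by a Markov chain whose switch
probability between adjacent loci is the inbred-line recombination fraction
R = 2r/(1+2r) (linkage model) or 1/2 (independent assortment). Progeny are
homozygous by construction — a single recombinant gamete doubled — which
reproduces the F-infinity marginal distribution that percentile summaries
need. The per-meiosis fraction r comes from a physical-to-genetic
conversion (default 1 cM/Mb) through the Haldane map function.

The 25th percentile of a cross's progeny values serves as its predicted
cross value; crosses whose P25 undercuts the observed population minimum
are transgressive, and the gap between population mean/minimum and the best
P25 quantifies the panel's recombination potential.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from qtlallele.allele_matrix import QtlAlleleMatrix

__all__ = [
    "GeneticMap",
    "physical_to_genetic",
    "haldane_r",
    "ril_recomb_fraction",
    "simulate_cross",
    "cross_percentiles",
    "predict_all_crosses",
    "optimal_crosses",
    "recombination_potential",
    "group_summary",
]


def physical_to_genetic(positions_bp, rate_cm_per_mb: float = 1.0) -> np.ndarray:
    """Genetic positions cM = bp * rate / 1e6 (uniform recombination rate)."""
    if rate_cm_per_mb <= 0:
        raise ValueError("rate must be positive")
    return np.asarray(positions_bp, dtype=float) * rate_cm_per_mb / 1e6


def haldane_r(d_cm) -> np.ndarray:
    """Haldane map function: recombination fraction from distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_recomb_fraction(r) -> np.ndarray:
    """Selfed-inbred-line recombination fraction R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("per-meiosis r must lie in [0, 0.5]")
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass
class GeneticMap:
    """Per-locus map with adjacent-locus inbred recombination fractions.

    ``loci`` has columns ``locus, chrom, pos, cm``; ``R`` has one entry per
    locus: the switch probability from the previous locus on the same
    chromosome (0.5 marks a chromosome start, i.e. free recombination).
    """

    loci: pd.DataFrame
    R: np.ndarray

    @classmethod
    def from_positions(
        cls, positions: pd.DataFrame, rate_cm_per_mb: float = 1.0
    ) -> "GeneticMap":
        """Build from a ``locus, chrom, pos`` frame (sorted by chrom, pos)."""
        df = positions.reset_index()
        if "locus" not in df.columns:
            df = df.rename(columns={df.columns[0]: "locus"})
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        df["cm"] = physical_to_genetic(df["pos"].to_numpy(), rate_cm_per_mb)
        R = np.full(len(df), 0.5)
        for _, grp in df.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            d = np.diff(grp["cm"].to_numpy())
            R[idx[1:]] = ril_recomb_fraction(haldane_r(d))
        return cls(loci=df, R=R)


def _progeny_origins(
    R: np.ndarray, n_progeny: int, rng: np.random.Generator, model: str
) -> np.ndarray:
    """0/1 parental-origin matrix (progeny x loci) from the Markov chain."""
    n_loci = R.size
    switch_p = np.full(n_loci, 0.5) if model == "independent" else R.copy()
    switch_p[0] = 0.5  # first locus drawn from either parent equally
    u = rng.random((n_progeny, n_loci))
    switches = (u < switch_p[None, :]).astype(np.int8)
    # first column is the origin itself; later columns flip the origin
    return np.cumsum(switches, axis=1) % 2


def simulate_cross(
    parent1_calls: np.ndarray,
    parent2_calls: np.ndarray,
    gmap: GeneticMap,
    effects_by_locus: dict,
    mu: float,
    n_progeny: int = 2000,
    model: str = "linkage",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulated progeny genotypic values for one cross.

    ``parent*_calls`` are per-locus allele indices in the order of
    ``gmap.loci``; loci where the parents share an allele are fixed in all
    progeny. Values are mu plus the summed allele effects (pure genotypic
    values, no residual noise).
    """
    if model not in ("linkage", "independent"):
        raise ValueError("model must be 'linkage' or 'independent'")
    rng = rng or np.random.default_rng()
    p1 = np.asarray(parent1_calls)
    p2 = np.asarray(parent2_calls)
    n_loci = len(gmap.loci)
    if p1.size != n_loci or p2.size != n_loci:
        raise ValueError("parent allele calls do not match the map's locus count")

    eff1 = np.array(
        [effects_by_locus[l][p1[k]] for k, l in enumerate(gmap.loci["locus"])]
    )
    eff2 = np.array(
        [effects_by_locus[l][p2[k]] for k, l in enumerate(gmap.loci["locus"])]
    )
    seg = p1 != p2
    fixed_sum = float(eff1[~seg].sum())
    if not seg.any():
        return np.full(n_progeny, mu + fixed_sum)

    values = np.full(n_progeny, mu + fixed_sum)
    for chrom, grp in gmap.loci.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        idx_seg = idx[seg[idx]]
        if idx_seg.size == 0:
            continue
        # restrict the chain to segregating loci; switch probability between
        # consecutive segregating loci compounds the skipped intervals via
        # the chain itself, so simulate on the full chromosome then subset
        origins = _progeny_origins(gmap.R[idx], n_progeny, rng, model)
        sub = origins[:, np.searchsorted(idx, idx_seg)]
        values += np.where(sub == 0, eff1[idx_seg][None, :], eff2[idx_seg][None, :]).sum(axis=1)
    return values


def cross_percentiles(values) -> dict:
    """Type-7 (linear interpolation) percentile summary of progeny values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty progeny sample")
    p20, p25, p50, p75 = np.percentile(v, [20, 25, 50, 75])
    return {
        "mean": float(v.mean()),
        "p20": float(p20),
        "p25": float(p25),
        "p50": float(p50),
        "p75": float(p75),
    }


def _cross_seed(master_seed: int, a: str, b: str) -> int:
    """Order-independent deterministic child seed for one parent pair."""
    lo, hi = sorted([str(a), str(b)])
    digest = hashlib.sha256(f"{master_seed}:{lo}:{hi}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def predict_all_crosses(
    matrix: QtlAlleleMatrix,
    gmap: GeneticMap | None = None,
    model: str = "linkage",
    n_progeny: int = 2000,
    master_seed: int = 0,
    rate_cm_per_mb: float = 1.0,
) -> pd.DataFrame:
    """Percentile predictions for all N(N-1)/2 unordered parent pairs.

    Per-cross seeds derive from the master seed and the sorted parent ids,
    so results do not depend on evaluation order.
    """
    accs = matrix.accessions
    if len(accs) < 2:
        raise ValueError("need at least two accessions")
    if gmap is None:
        gmap = GeneticMap.from_positions(matrix.positions, rate_cm_per_mb)
    order = gmap.loci["locus"].tolist()
    calls_idx = np.stack(
        [
            np.array(
                [matrix.alleles_by_locus[l].index(matrix.allele_calls.at[l, a]) for l in order]
            )
            for a in accs
        ]
    )
    rows = []
    for i, j in combinations(range(len(accs)), 2):
        # canonical parent order, so results do not depend on column order
        if accs[j] < accs[i]:
            i, j = j, i
        seed = _cross_seed(master_seed, accs[i], accs[j])
        vals = simulate_cross(
            calls_idx[i], calls_idx[j], gmap, matrix.effects_by_locus,
            matrix.mu, n_progeny, model, np.random.default_rng(seed),
        )
        pct = cross_percentiles(vals)
        rows.append({"parent1": accs[i], "parent2": accs[j], "model": model, **pct})
    return pd.DataFrame(rows)


def optimal_crosses(predictions: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Crosses whose P25 beats the observed population minimum, best first."""
    sel = predictions[predictions["p25"] < threshold]
    return sel.sort_values("p25", kind="mergesort").reset_index(drop=True)


def recombination_potential(
    population_mean: float,
    population_min: float,
    p25=None,
    *,
    p25_mean: float | None = None,
    p25_min: float | None = None,
) -> dict:
    """Average/maximum-improvement/maximum-transgression potentials.

    Either pass the array of per-cross P25 values, or their precomputed
    mean and minimum.
    """
    if p25 is not None:
        arr = np.asarray(p25, dtype=float)
        if arr.size == 0:
            raise ValueError("no predictions")
        p25_mean = float(arr.mean())
        p25_min = float(arr.min())
    if p25_mean is None or p25_min is None:
        raise ValueError("provide p25 values or p25_mean and p25_min")
    return {
        "average": population_mean - p25_mean,
        "max_improvement": population_mean - p25_min,
        "max_transgression": population_min - p25_min,
    }


def group_summary(
    predictions: pd.DataFrame, groups: pd.Series, observed_min: pd.Series | None = None
) -> pd.DataFrame:
    """Within/between-group P25 summaries (mean, min, max, optimal count)."""
    g = groups.to_dict()
    df = predictions.copy()
    df["g1"] = df["parent1"].map(g)
    df["g2"] = df["parent2"].map(g)
    df["pair"] = np.where(df["g1"] == df["g2"], df["g1"].astype(str), "between")
    rows = []
    for label, grp in df.groupby("pair"):
        row = {
            "group": label,
            "n_crosses": len(grp),
            "mean_p25": grp["p25"].mean(),
            "min_p25": grp["p25"].min(),
            "max_p25": grp["p25"].max(),
        }
        if observed_min is not None:
            thr = (
                observed_min.min() if label == "between" else observed_min.get(label, np.nan)
            )
            row["n_optimal"] = int((grp["p25"] < thr).sum())
        rows.append(row)
    return pd.DataFrame(rows)
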