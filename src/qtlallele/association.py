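"""Restricted two-stage multi-locus association scan.

Stage 1 screens every multi-allelic SNPLDB marker with a single-marker
F-test in a fixed-effect model containing the environment term and
population-structure eigenvector covariates. Stage 2 runs stepwise
regression (forward selection, backward deletion) over the preselected
markers under a multi-locus linear model, with the cumulative marker
contribution capped by the trait heritability (the "restriction"): adding
markers stops once the model would explain more phenotypic variance than is
heritable. After the main-effect model stabilizes, marker-by-environment
interaction terms are scanned the same way, so a locus may carry a main
effect, an interaction effect, or both.

Per-locus contributions are Type-III partial sums of squares over the total
phenotypic sum of squares (environment main effects removed), reported in
percent; allele effects are least-squares estimates under an unweighted
sum-to-zero constraint per locus, so a negative effect lowers the trait
(for a damage percentage: increases resistance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from qtlallele.snpldb import SnpldbMarker

logger = logging.getLogger(__name__)

__all__ = [
    "ScanSettings",
    "QtlRecord",
    "ScanResult",
    "stage1_scan",
    "stage2_stepwise",
    "two_stage_scan",
    "classify_contribution",
    "name_qtl",
]


@dataclass
class ScanSettings:
    """Thresholds of the two-stage scan."""

    preselect_alpha: float = 0.05
    enter_alpha: float = 0.05
    remove_alpha: float = 0.05
    heritability_cap: float | None = None  # fraction; None = no restriction
    correction: str = "bonferroni"  # or "none"
    max_iterations: int = 100

    def __post_init__(self):
        for name in ("preselect_alpha", "enter_alpha", "remove_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")


@dataclass
class QtlRecord:
    """One detected locus with its per-allele effects and contributions."""

    name: str
    marker_id: str
    chrom: object
    start: int
    end: int
    allele_number: int
    alleles: list[str]
    allele_effects: np.ndarray | None  # sum-to-zero; None for QEI-only loci
    main_neglog10p: float | None
    main_r2: float | None  # percent of phenotypic SS
    qei_neglog10p: float | None
    qei_r2: float | None

    @property
    def contribution_class(self) -> str | None:
        r2 = max(filter(None, [self.main_r2 or 0.0, self.qei_r2 or 0.0]), default=0.0)
        return classify_contribution(r2)

    @property
    def has_main(self) -> bool:
        return self.main_r2 is not None

    @property
    def has_qei(self) -> bool:
        return self.qei_r2 is not None


@dataclass
class ScanResult:
    qtls: list[QtlRecord]
    intercept: float
    settings: ScanSettings
    n_preselected: int
    n_markers: int
    stage1: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q in self.qtls:
            rows.append(
                {
                    "qtl": q.name,
                    "marker": q.marker_id,
                    "chromosome": q.chrom,
                    "position": q.start,
                    "an": q.allele_number,
                    "main_neglog10p": q.main_neglog10p,
                    "main_r2": q.main_r2,
                    "qei_neglog10p": q.qei_neglog10p,
                    "qei_r2": q.qei_r2,
                    "class": q.contribution_class,
                }
            )
        return pd.DataFrame(rows)


def classify_contribution(r2_percent: float) -> str:
    """Large (LC) vs small (SC) contribution at the 1-percent boundary."""
    if r2_percent < 0:
        raise ValueError("R2 must be non-negative")
    return "LC" if r2_percent >= 1.0 else "SC"


def name_qtl(trait: str, chromosome: int, rank_on_chromosome: int) -> str:
    """Locus name `q-<TRAIT>-<chrom:02d>-<rank>`, rank by physical position."""
    return f"q-{trait}-{int(chromosome):02d}-{rank_on_chromosome}"


# ---------------------------------------------------------------------------
# design-matrix helpers


class _Design:
    """Observation-level design pieces shared by both stages.

    Observations are accession x environment cell means (replicates
    averaged). The base design holds intercept, environment dummies and
    structure covariates. Marker terms are allele-indicator groups
    (first allele dropped); interaction terms are allele x environment
    indicator products.
    """

    def __init__(self, phenotype: pd.DataFrame, accessions: list[str], covariates=None):
        cell = (
            phenotype.groupby(["accession", "environment"], sort=True)["value"]
            .mean()
            .reset_index()
        )
        known = set(accessions)
        cell = cell[cell["accession"].isin(known)]
        self.acc_index = {a: i for i, a in enumerate(accessions)}
        self.obs_acc = cell["accession"].map(self.acc_index).to_numpy()
        envs = sorted(cell["environment"].unique())
        env_idx = {e: i for i, e in enumerate(envs)}
        self.obs_env = cell["environment"].map(env_idx).to_numpy()
        self.n_env = len(envs)
        self.y = cell["value"].to_numpy(dtype=float)
        n_obs = self.y.size

        cols = [np.ones(n_obs)]
        for j in range(1, self.n_env):
            cols.append((self.obs_env == j).astype(float))
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            for j in range(cov.shape[1]):
                cols.append(cov[self.obs_acc, j])
        self.base = np.column_stack(cols)

        # total phenotypic SS with environment main effects removed
        env_means = np.array([self.y[self.obs_env == j].mean() for j in range(self.n_env)])
        centered = self.y - env_means[self.obs_env]
        self.tss = float(centered @ centered)
        self.grand_mean = float(self.y.mean())

    def marker_columns(self, marker: SnpldbMarker) -> np.ndarray | None:
        """Allele indicator columns (drop-first) for alleles present."""
        obs_allele = marker.allele_index[self.obs_acc]
        present = np.unique(obs_allele)
        if present.size < 2:
            return None
        cols = [(obs_allele == a).astype(float) for a in present[1:]]
        return np.column_stack(cols)

    def qei_columns(self, marker: SnpldbMarker) -> np.ndarray | None:
        mc = self.marker_columns(marker)
        if mc is None or self.n_env < 2:
            return None
        cols = []
        for j in range(1, self.n_env):
            ind = (self.obs_env == j).astype(float)
            cols.append(mc * ind[:, None])
        return np.column_stack(cols)


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and model rank from least squares."""
    beta, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    rss = float(np.sum((y - fitted) ** 2))
    return rss, int(rank)


def _partial_f(x_base: np.ndarray, x_extra: np.ndarray, y: np.ndarray):
    """Partial F-test of adding `x_extra` to `x_base`."""
    rss0, rank0 = _rss(x_base, y)
    full = np.column_stack([x_base, x_extra])
    rss1, rank1 = _rss(full, y)
    df1 = rank1 - rank0
    df2 = y.size - rank1
    if df1 <= 0 or df2 <= 0 or rss1 <= 0:
        return 0.0, 1.0, rss0 - rss1, df1
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p, rss0 - rss1, df1


def stage1_scan(
    markers: list[SnpldbMarker],
    phenotype: pd.DataFrame,
    accessions: list[str],
    covariates=None,
    preselect_alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-marker F-tests; returns all markers with preselection flags.

    The returned frame is ordered by p-value and has columns
    ``marker, chrom, start, p, preselected``.
    """
    design = _Design(phenotype, accessions, covariates)
    rows = []
    for m in markers:
        cols = design.marker_columns(m)
        if cols is None:
            logger.info("marker %s skipped in stage 1: single allele class", m.id)
            continue
        f, p, _, df1 = _partial_f(design.base, cols, design.y)
        rows.append({"marker": m.id, "chrom": m.chrom, "start": m.start, "f": f, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(columns=["marker", "chrom", "start", "f", "p", "preselected"])
        return out
    out = out.sort_values(["p", "chrom", "start"], kind="mergesort").reset_index(drop=True)
    out["preselected"] = out["p"] <= preselect_alpha
    return out


def _stepwise(
    design: _Design,
    candidates: list[SnpldbMarker],
    col_fn,
    base: np.ndarray,
    settings: ScanSettings,
    alpha_scale: float,
    cap_rss_floor: float | None,
) -> list[SnpldbMarker]:
    """Generic forward/backward selection over marker term groups.

    ``cap_rss_floor`` is the smallest residual sum of squares the model may
    reach under the heritability restriction (None disables the cap).
    """
    selected: list[SnpldbMarker] = []
    cols_of = {}
    for m in candidates:
        c = col_fn(m)
        if c is not None:
            cols_of[m.id] = c
    cand = [m for m in candidates if m.id in cols_of]
    enter = settings.enter_alpha * alpha_scale
    remove = settings.remove_alpha * alpha_scale

    for _ in range(settings.max_iterations):
        changed = False
        # forward step
        current = np.column_stack([base] + [cols_of[m.id] for m in selected]) if selected else base
        best = None
        for m in cand:
            if any(s.id == m.id for s in selected):
                continue
            f, p, ssdrop, df1 = _partial_f(current, cols_of[m.id], design.y)
            if df1 <= 0:
                continue
            key = (p, _chrom_sort_key(m.chrom), m.start)
            if p <= enter and (best is None or key < best[0]):
                best = (key, m)
        if best is not None:
            m = best[1]
            with_m = np.column_stack([current, cols_of[m.id]])
            rss_new, _ = _rss(with_m, design.y)
            if cap_rss_floor is None or rss_new >= cap_rss_floor:
                selected.append(m)
                changed = True
            # else: the restriction blocks this and every weaker candidate
        # backward step
        dropped = True
        while dropped and selected:
            dropped = False
            for m in list(selected):
                others = [s for s in selected if s.id != m.id]
                x0 = np.column_stack([base] + [cols_of[s.id] for s in others]) if others else base
                f, p, _, df1 = _partial_f(x0, cols_of[m.id], design.y)
                if p > remove:
                    selected.remove(m)
                    dropped = True
                    changed = True
                    break
        if not changed:
            break
    else:
        raise RuntimeError(
            f"stepwise selection did not converge in {settings.max_iterations} iterations"
        )
    return selected


def _chrom_sort_key(chrom) -> tuple:
    try:
        return (0, int(chrom))
    except (TypeError, ValueError):
        return (1, str(chrom))


def stage2_stepwise(
    preselected: list[SnpldbMarker],
    phenotype: pd.DataFrame,
    accessions: list[str],
    covariates=None,
    settings: ScanSettings | None = None,
    trait: str = "DLP",
    n_family: int | None = None,
) -> ScanResult:
    """Stepwise multi-locus model over preselected markers, then QEI terms.

    ``n_family`` is the size of the experimentwise test family for the
    Bonferroni mode — the number of markers screened in stage 1, not just
    those preselected (preselection is itself a selection on the same
    tests, so scaling by the preselected count would not control the
    family-wise error). Defaults to the preselected count when stage 2 is
    run stand-alone.
    """
    settings = settings or ScanSettings()
    if not preselected:
        raise ValueError("empty preselection")
    design = _Design(phenotype, accessions, covariates)
    m = n_family if n_family is not None else len(preselected)
    alpha_scale = 1.0 / m if settings.correction == "bonferroni" else 1.0

    cap_floor = None
    rss_base, _ = _rss(design.base, design.y)
    if settings.heritability_cap is not None:
        cap_floor = rss_base - settings.heritability_cap * design.tss

    main_sel = _stepwise(
        design, preselected, design.marker_columns, design.base, settings,
        alpha_scale, cap_floor,
    )

    main_cols = {m.id: design.marker_columns(m) for m in main_sel}
    base_with_main = (
        np.column_stack([design.base] + list(main_cols.values())) if main_sel else design.base
    )
    qei_sel: list[SnpldbMarker] = []
    if design.n_env > 1:
        rss_main, _ = _rss(base_with_main, design.y)
        cap_floor_qei = None
        if settings.heritability_cap is not None:
            cap_floor_qei = rss_base - settings.heritability_cap * design.tss
        qei_sel = _stepwise(
            design, preselected, design.qei_columns, base_with_main, settings,
            alpha_scale, cap_floor_qei,
        )

    return _summarize(design, main_sel, qei_sel, settings, trait,
                      n_preselected=len(preselected))


def _summarize(
    design: _Design,
    main_sel: list[SnpldbMarker],
    qei_sel: list[SnpldbMarker],
    settings: ScanSettings,
    trait: str,
    n_preselected: int,
) -> ScanResult:
    """Type-III contributions, allele effects and locus naming."""
    main_cols = {m.id: design.marker_columns(m) for m in main_sel}
    qei_cols = {m.id: design.qei_columns(m) for m in qei_sel}
    blocks = (
        [design.base]
        + [main_cols[m.id] for m in main_sel]
        + [qei_cols[m.id] for m in qei_sel]
    )
    full = np.column_stack(blocks)
    rss_full, rank_full = _rss(full, design.y)
    df_resid = design.y.size - rank_full

    def term_stats(term_cols: np.ndarray) -> tuple[float, float]:
        """Type-III partial SS of one term in the full model."""
        keep = [b for b in blocks if b is not term_cols]
        x0 = np.column_stack(keep)
        rss0, rank0 = _rss(x0, design.y)
        ss = rss0 - rss_full
        df1 = rank_full - rank0
        if df1 <= 0 or df_resid <= 0 or rss_full <= 0:
            return float("inf"), ss
        f = (ss / df1) / (rss_full / df_resid)
        p = float(stats.f.sf(f, df1, df_resid))
        neglog = float(-np.log10(max(p, 1e-300)))
        return neglog, ss

    # allele effects from the full fit (drop-first coding -> sum-to-zero)
    beta, *_ = np.linalg.lstsq(full, design.y, rcond=None)
    offsets = np.cumsum([0] + [b.shape[1] for b in blocks])

    records: dict[str, dict] = {}
    for i, m in enumerate(main_sel):
        cols = main_cols[m.id]
        neglog, ss = term_stats(cols)
        sl = slice(offsets[1 + i], offsets[1 + i] + cols.shape[1])
        obs_allele = m.allele_index[design.obs_acc]
        present = np.unique(obs_allele)
        raw = np.concatenate([[0.0], beta[sl]])
        eff = raw - raw.mean()
        records[m.id] = {
            "marker": m,
            "alleles": [m.alleles[a] for a in present],
            "allele_effects": eff,
            "main_neglog10p": neglog,
            "main_r2": 100.0 * ss / design.tss if design.tss > 0 else float("nan"),
            "qei_neglog10p": None,
            "qei_r2": None,
        }
    for i, m in enumerate(qei_sel):
        cols = qei_cols[m.id]
        neglog, ss = term_stats(cols)
        rec = records.get(m.id)
        if rec is None:
            obs_allele = m.allele_index[design.obs_acc]
            present = np.unique(obs_allele)
            rec = records[m.id] = {
                "marker": m,
                "alleles": [m.alleles[a] for a in present],
                "allele_effects": None,
                "main_neglog10p": None,
                "main_r2": None,
                "qei_neglog10p": None,
                "qei_r2": None,
            }
        rec["qei_neglog10p"] = neglog
        rec["qei_r2"] = 100.0 * ss / design.tss if design.tss > 0 else float("nan")

    ordered = sorted(
        records.values(),
        key=lambda r: (_chrom_sort_key(r["marker"].chrom), r["marker"].start),
    )
    qtls = []
    rank: dict = {}
    for rec in ordered:
        m = rec["marker"]
        rank[m.chrom] = rank.get(m.chrom, 0) + 1
        qtls.append(
            QtlRecord(
                name=name_qtl(trait, m.chrom, rank[m.chrom]),
                marker_id=m.id,
                chrom=m.chrom,
                start=m.start,
                end=m.end,
                allele_number=len(rec["alleles"]),
                alleles=rec["alleles"],
                allele_effects=rec["allele_effects"],
                main_neglog10p=rec["main_neglog10p"],
                main_r2=rec["main_r2"],
                qei_neglog10p=rec["qei_neglog10p"],
                qei_r2=rec["qei_r2"],
            )
        )
    return ScanResult(
        qtls=qtls,
        intercept=design.grand_mean,
        settings=settings,
        n_preselected=n_preselected,
        n_markers=len(records),
    )


def two_stage_scan(
    markers: list[SnpldbMarker],
    phenotype: pd.DataFrame,
    accessions: list[str],
    covariates=None,
    settings: ScanSettings | None = None,
    trait: str = "DLP",
) -> ScanResult:
    """Full restricted two-stage scan: preselection then stepwise model."""
    settings = settings or ScanSettings()
    s1 = stage1_scan(
        markers, phenotype, accessions, covariates,
        preselect_alpha=settings.preselect_alpha,
    )
    by_id = {m.id: m for m in markers}
    order = [by_id[mid] for mid in s1.loc[s1["preselected"], "marker"]]
    if not order:
        return ScanResult(
            qtls=[], intercept=float(phenotype["value"].mean()),
            settings=settings, n_preselected=0, n_markers=0, stage1=s1,
        )
    result = stage2_stepwise(
        order, phenotype, accessions, covariates, settings, trait=trait,
        n_family=len(s1),
    )
    result.stage1 = s1
    return result
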