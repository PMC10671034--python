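"""Phenotype statistics: CV-weighted plot values, ANOVA, heritability.

The plot-level phenotype (here the damaged-leaf percentage, DLP, of a plot
scored repeatedly as insect feeding progresses) is a weighted average of the
per-time observations, where each observation time is weighted by its
coefficient of variation across accessions: time points that discriminate
accessions more strongly get more weight.

Variance components for the accession x environment x replicate layout are
method-of-moments estimates from the expected mean squares of the balanced
two-way ANOVA:

    MS_g  = sigma2_e + r*sigma2_ge + n*r*sigma2_g
    MS_ge = sigma2_e + r*sigma2_ge
    MS_e  = sigma2_e

with broad-sense heritability on an accession-mean basis

    h2 = sigma2_g / (sigma2_g + sigma2_ge/n + sigma2_e/(n*r))    (multi-env)
    h2 = sigma2_g / (sigma2_g + sigma2_e/r)                      (single-env)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "observation_weights",
    "plot_dlp",
    "plot_values_from_observations",
    "anova_components",
    "heritability",
    "descriptive_stats",
    "duncan_letters",
]


def observation_weights(cv_values) -> np.ndarray:
    """Weights P_i = CV_i / sum(CV) for the per-time observations.

    All-zero CVs are a degenerate case (no time point discriminates the
    accessions); equal weights are returned with a warning.
    """
    cv = np.asarray(cv_values, dtype=float)
    if cv.ndim != 1 or cv.size < 2:
        raise ValueError("need CVs for at least two observation times")
    if np.any(cv < 0):
        raise ValueError("CVs must be non-negative")
    total = cv.sum()
    if total == 0:
        warnings.warn("all CVs are zero; falling back to equal weights")
        return np.full(cv.size, 1.0 / cv.size)
    return cv / total


def plot_dlp(y_values, weights) -> float:
    """Weighted plot value PM = sum(P_i * Y_i)."""
    y = np.asarray(y_values, dtype=float)
    p = np.asarray(weights, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"lengths differ: {y.shape} observations, {p.shape} weights")
    return float(np.dot(p, y))


def plot_values_from_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated observations into one CV-weighted value per plot.

    ``obs`` is tidy with columns ``accession, environment, replicate, time,
    value``. The CV of each observation time is computed across accessions
    within each (environment, replicate) set, giving per-plot weights; the
    result has one ``value`` row per (accession, environment, replicate).
    """
    required = {"accession", "environment", "replicate", "time", "value"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observation table lacks columns: {sorted(missing)}")
    out = []
    for (env, rep), grp in obs.groupby(["environment", "replicate"], sort=True):
        wide = grp.pivot_table(index="accession", columns="time", values="value")
        if wide.isna().any().any():
            raise ValueError(f"unbalanced observation times in {env!r} rep {rep!r}")
        means = wide.mean(axis=0)
        sds = wide.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(means.to_numpy() != 0, sds.to_numpy() / means.to_numpy(), 0.0)
        p = observation_weights(cv) if cv.sum() > 0 else np.full(cv.size, 1.0 / cv.size)
        pm = wide.to_numpy() @ p
        out.append(
            pd.DataFrame(
                {
                    "accession": wide.index,
                    "environment": env,
                    "replicate": rep,
                    "value": pm,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


@dataclass
class VarianceComponents:
    """Method-of-moments variance components of the two-way layout."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    r: float
    n_env: int
    mu: float
    f_genotype: float = float("nan")
    p_genotype: float = float("nan")
    f_ge: float = float("nan")
    p_ge: float = float("nan")
    truncated: tuple[str, ...] = field(default_factory=tuple)

    @property
    def h2(self) -> float:
        return heritability(self, multi_env=self.n_env > 1)

    @property
    def gcv(self) -> float:
        """Genotypic coefficient of variation sigma_g / mu, percent."""
        return float(100.0 * np.sqrt(self.sigma2_g) / self.mu) if self.mu else float("nan")

    @property
    def cv(self) -> float:
        """Error coefficient of variation sqrt(sigma2_e) / mu, percent."""
        return float(100.0 * np.sqrt(self.sigma2_e) / self.mu) if self.mu else float("nan")


def anova_components(table: pd.DataFrame) -> VarianceComponents:
    """Estimate (sigma2_g, sigma2_ge, sigma2_e) from a balanced plot table.

    ``table`` has columns ``accession, environment, replicate, value``.
    Negative method-of-moments estimates are truncated at zero and recorded
    in ``truncated``. The genotype F statistic is tested against the G x E
    stratum in the multi-environment layout and against the residual in a
    single environment.
    """
    required = {"accession", "environment", "value"}
    if missing := required - set(table.columns):
        raise ValueError(f"plot table lacks columns: {sorted(missing)}")
    y = table["value"].to_numpy(dtype=float)
    n_obs = y.size
    if n_obs == 0:
        raise ValueError("empty plot table")
    g_levels = table["accession"].nunique()
    e_levels = table["environment"].nunique()
    r = n_obs / (g_levels * e_levels)

    grand = y.mean()
    c = n_obs * grand**2
    ss_total = float(np.sum(y**2) - c)

    tg = table.groupby("accession", sort=False)["value"].agg(["sum", "count"])
    ss_g = float(np.sum(tg["sum"] ** 2 / tg["count"]) - c)
    te = table.groupby("environment", sort=False)["value"].agg(["sum", "count"])
    ss_env = float(np.sum(te["sum"] ** 2 / te["count"]) - c)
    tge = table.groupby(["accession", "environment"], sort=False)["value"].agg(["sum", "count"])
    ss_cells = float(np.sum(tge["sum"] ** 2 / tge["count"]) - c)
    ss_ge = ss_cells - ss_g - ss_env
    ss_err = ss_total - ss_cells

    df_g = g_levels - 1
    df_ge = (g_levels - 1) * (e_levels - 1)
    df_err = n_obs - g_levels * e_levels

    ms_g = ss_g / df_g if df_g > 0 else float("nan")
    ms_ge = ss_ge / df_ge if df_ge > 0 else float("nan")
    ms_err = ss_err / df_err if df_err > 0 else float("nan")

    def safe_f(num: float, den: float) -> float:
        """F ratio with degenerate strata reported as inf (signal, no noise)
        or nan (nothing to test)."""
        if not np.isfinite(num) or not np.isfinite(den) or num == 0:
            return float("nan")
        if den == 0:
            return float("inf")
        return num / den

    truncated = []
    if e_levels > 1:
        sigma2_e = ms_err if df_err > 0 else 0.0
        sigma2_ge = (ms_ge - sigma2_e) / r if df_err > 0 else ms_ge / r
        sigma2_g = (ms_g - (ms_ge if df_ge > 0 else sigma2_e)) / (e_levels * r)
        f_g, denom_df = (safe_f(ms_g, ms_ge), df_ge) if df_ge > 0 else (
            safe_f(ms_g, ms_err), df_err)
        f_ge = safe_f(ms_ge, ms_err) if df_err > 0 else float("nan")
        p_ge = float(stats.f.sf(f_ge, df_ge, df_err)) if not np.isnan(f_ge) else float("nan")
    else:
        sigma2_e = ms_err if df_err > 0 else 0.0
        sigma2_ge = 0.0
        sigma2_g = (ms_g - sigma2_e) / r
        f_g, denom_df = safe_f(ms_g, ms_err), df_err
        f_ge, p_ge = float("nan"), float("nan")

    p_g = float(stats.f.sf(f_g, df_g, denom_df)) if not np.isnan(f_g) else float("nan")

    for name, val in (("sigma2_g", sigma2_g), ("sigma2_ge", sigma2_ge), ("sigma2_e", sigma2_e)):
        if val < 0:
            truncated.append(name)
    sigma2_g = max(sigma2_g, 0.0)
    sigma2_ge = max(sigma2_ge, 0.0)
    sigma2_e = max(sigma2_e, 0.0)

    return VarianceComponents(
        sigma2_g=float(sigma2_g),
        sigma2_ge=float(sigma2_ge),
        sigma2_e=float(sigma2_e),
        r=float(r),
        n_env=int(e_levels),
        mu=float(grand),
        f_genotype=float(f_g) if np.isfinite(f_g) else float("nan"),
        p_genotype=p_g,
        f_ge=float(f_ge) if np.isfinite(f_ge) else float("nan"),
        p_ge=p_ge,
        truncated=tuple(truncated),
    )


def heritability(vc: VarianceComponents, multi_env: bool = True) -> float:
    """Broad-sense heritability on an accession-mean basis, in [0, 1]."""
    if multi_env:
        denom = vc.sigma2_g + vc.sigma2_ge / vc.n_env + vc.sigma2_e / (vc.n_env * vc.r)
    else:
        denom = vc.sigma2_g + vc.sigma2_e / vc.r
    if denom == 0:
        raise ZeroDivisionError("all variance components are zero")
    return float(vc.sigma2_g / denom)


def _bin_counts(values: np.ndarray, width: float = 5.0) -> pd.Series:
    """Frequency counts in classes of `width` percent, keyed by midpoint."""
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi == lo:
        hi = lo + width
    edges = np.arange(lo, hi + width, width)
    counts, _ = np.histogram(values, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2
    return pd.Series(counts, index=mids, name="count")


def descriptive_stats(
    values: pd.Series,
    groups: pd.Series | None = None,
    vc: VarianceComponents | None = None,
    bin_width: float = 5.0,
) -> dict:
    """Descriptive summary of per-accession phenotype means.

    Returns mean/min/max, 5-percent-class frequency counts, and, when group
    labels are given, a one-way F-test among groups with Duncan
    multiple-range letters on the group means. GCV and error CV are taken
    from ``vc`` when provided.
    """
    v = values.dropna()
    if v.empty:
        raise ValueError("no values")
    arr = v.to_numpy(dtype=float)
    out = {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "bins": _bin_counts(arr, width=bin_width),
    }
    if vc is not None:
        out["gcv"] = vc.gcv
        out["cv"] = vc.cv
        out["h2"] = vc.h2
    if groups is not None:
        groups = groups.reindex(v.index)
        samples = [grp.to_numpy(dtype=float) for _, grp in v.groupby(groups)]
        if any(len(s) == 0 for s in samples):
            raise ValueError("empty group")
        if len(samples) > 1:
            f, p = stats.f_oneway(*samples)
            out["group_f"] = float(f)
            out["group_p"] = float(p)
            out["letters"] = duncan_letters(v, groups)
        g = v.groupby(groups)
        out["group_table"] = pd.DataFrame(
            {"n": g.size(), "mean": g.mean(), "min": g.min(), "max": g.max()}
        )
    return out


def duncan_letters(values: pd.Series, groups: pd.Series, alpha: float = 0.05) -> pd.Series:
    """Duncan's new multiple range test letters for group means.

    Uses protection levels ``alpha_p = 1 - (1 - alpha)**(p - 1)`` with the
    studentized range distribution; groups sharing a letter do not differ at
    the protected level. The harmonic mean of group sizes stands in for a
    common n in unbalanced data.
    """
    df = pd.DataFrame({"y": values, "g": groups}).dropna()
    means = df.groupby("g")["y"].mean().sort_values(ascending=False)
    sizes = df.groupby("g")["y"].size().reindex(means.index)
    k = len(means)
    if k < 2:
        return pd.Series(["a"] * k, index=means.index)
    n_err = len(df) - k
    sse = float(((df["y"] - df.groupby("g")["y"].transform("mean")) ** 2).sum())
    mse = sse / n_err if n_err > 0 else 0.0
    n_h = stats.hmean(sizes.to_numpy())
    se = np.sqrt(mse / n_h)

    def crit(p_span: int) -> float:
        a_p = 1 - (1 - alpha) ** (p_span - 1)
        return float(stats.studentized_range.ppf(1 - a_p, p_span, n_err)) * se

    m = means.to_numpy()
    # significance of each ordered pair span
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            sig[i, j] = (m[i] - m[j]) > crit(j - i + 1)

    # maximal non-significant stretches become letters
    stretches = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[i, j + 1]:
            j += 1
        if not any(a <= i and j <= b for a, b in stretches):
            stretches.append((i, j))
    letters = ["" for _ in range(k)]
    for idx, (a, b) in enumerate(stretches):
        ch = chr(ord("a") + idx)
        for i in range(a, b + 1):
            letters[i] += ch
    return pd.Series(letters, index=means.index, name="letters")
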