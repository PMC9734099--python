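"""Preliminary per-sample QC and presence filtering.

Covers the exploratory stage of the pipeline: per-sample identified-protein
counts, a Kolmogorov–Smirnov normality screen of those counts followed by a
one-sided Grubbs test for a suspiciously low sample, per-protein per-group
presence fractions, the 50 %-presence analysis-set selection, three-way Venn
partitions of protein identification, and PCA scores of the sample intensity
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import GROUPS

VENN_REGIONS = ("M", "S", "C", "MS", "MC", "SC", "MSC")


@dataclass
class PresenceSummary:
    """Per-group identification totals and per-protein presence fractions.

    Attributes
    ----------
    totals : per-group number of proteins detected in >= 1 sample of the group.
    mean_sd : per-group (mean, sd) of per-sample identified-protein counts.
    fractions : DataFrame proteins x groups of detected-sample fractions.
    group_sizes : samples per group.
    """

    totals: dict[str, int]
    mean_sd: dict[str, tuple[float, float]]
    fractions: pd.DataFrame
    group_sizes: dict[str, int]


def per_sample_counts(q: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    """Number of proteins quantified (non-missing) in each sample."""
    counts = q[samples["sample_id"].tolist()].notna().sum(axis=0)
    counts.name = "n_identified"
    return counts


def ks_normality(counts) -> tuple[float, float]:
    """One-sample KS test against a normal law with the sample's mean and SD.

    Note the parameters are estimated from the same data, which makes the
    plain KS p-value conservative; see :func:`lilliefors_normality` for the
    corrected variant.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    res = stats.kstest(x, "norm", args=(x.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def lilliefors_normality(counts) -> tuple[float, float]:
    """Lilliefors-corrected KS normality test (parameters estimated)."""
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(counts, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance")
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


def grubbs_min_outlier(
    counts, alpha: float = 0.05, *, two_sided: bool = False
) -> tuple[int | None, float, float]:
    """Grubbs test for a single low outlier.

    Returns ``(index_of_minimum_or_None, G, G_critical)``. The statistic is
    G = (mean - min) / SD; the critical value is
    ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper alpha/n
    (alpha/(2n) when two_sided) quantile of Student's t at n-2 df. The
    minimum is flagged iff G > G_critical.
    """
    x = np.asarray(counts, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    g = (x.mean() - x.min()) / sd
    tail = alpha / (2 * n) if two_sided else alpha / n
    t = stats.t.ppf(1 - tail, n - 2)
    g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
    idx = int(np.argmin(x)) if g > g_crit else None
    return idx, float(g), float(g_crit)


def presence_fractions(q: pd.DataFrame, samples: pd.DataFrame) -> PresenceSummary:
    """Per-protein per-group presence fractions and group summaries."""
    counts = per_sample_counts(q, samples)
    fractions = pd.DataFrame(index=q.index, columns=list(GROUPS), dtype=float)
    totals: dict[str, int] = {}
    mean_sd: dict[str, tuple[float, float]] = {}
    sizes: dict[str, int] = {}
    for g in GROUPS:
        cols = samples.loc[samples["group"] == g, "sample_id"].tolist()
        sizes[g] = len(cols)
        detected = q[cols].notna()
        fractions[g] = detected.mean(axis=1) if cols else 0.0
        totals[g] = int(detected.any(axis=1).sum()) if cols else 0
        gc = counts[cols]
        mean_sd[g] = (float(gc.mean()), float(gc.std(ddof=1))) if cols else (0.0, 0.0)
    return PresenceSummary(totals, mean_sd, fractions, sizes)


def select_analysis_set(
    summary: PresenceSummary | pd.DataFrame, threshold: float = 0.5
) -> list:
    """Proteins present in at least ``threshold`` of samples of >= 1 group."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    frac = summary.fractions if isinstance(summary, PresenceSummary) else summary
    keep = (frac >= threshold).any(axis=1)
    return frac.index[keep].tolist()


def venn_partition(
    q: pd.DataFrame, samples: pd.DataFrame, mode: str = "all_identified"
) -> dict[str, int]:
    """Counts of the 7 regions of the M/S/C identification Venn diagram.

    ``all_identified``: a protein is "in" a group when detected in >= 1 of its
    samples. ``per_group_50``: in a group when detected in >= 50 % of its
    samples. ``any_group_50``: universe restricted to the 50 %-presence
    analysis set, then membership by >= 1 sample per group.
    """
    summary = presence_fractions(q, samples)
    frac = summary.fractions
    sizes = summary.group_sizes
    if any(sizes[g] == 0 for g in GROUPS):
        raise ValueError("all three groups must be non-empty")
    if mode == "all_identified":
        member = frac > 0
        universe = member.any(axis=1)
    elif mode == "per_group_50":
        member = frac >= 0.5
        universe = member.any(axis=1)
    elif mode == "any_group_50":
        universe = frac.index.isin(select_analysis_set(summary))
        member = (frac > 0) & universe[:, None]
        universe = pd.Series(universe, index=frac.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    counts = {r: 0 for r in VENN_REGIONS}
    for in_m, in_s, in_c in member.loc[universe].itertuples(index=False):
        region = "".join(
            g for g, flag in zip(GROUPS, (in_m, in_s, in_c)) if flag
        )
        if region:
            counts[region] += 1
    return counts


def table_one(q: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Identification summary across the three presence modes.

    For each mode (all identified proteins; proteins present in >= 50 % of the
    given group; the >= 50 %-in-any-group analysis set) the per-group total
    number of proteins and the mean +/- SD of per-sample identified counts.
    """
    summary = presence_fractions(q, samples)
    analysis = select_analysis_set(summary)
    rows = []
    for mode in ("all_identified", "per_group_50", "any_group_50"):
        if mode == "all_identified":
            sub = q
            member = summary.fractions > 0
        elif mode == "per_group_50":
            sub = q
            member = summary.fractions >= 0.5
        else:
            sub = q.loc[analysis]
            member = summary.fractions.loc[analysis] > 0
        for g in GROUPS:
            cols = samples.loc[samples["group"] == g, "sample_id"].tolist()
            counts = sub[cols].notna().sum(axis=0)
            rows.append(
                {
                    "mode": mode,
                    "group": g,
                    "total_identified": int(member[g].sum()),
                    "mean_per_sample": float(counts.mean()),
                    "sd_per_sample": float(counts.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)


def pca_scores(
    q: pd.DataFrame, n_components: int = 2, *, scale: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA scores of the per-sample protein intensity vectors.

    Samples are rows. Missing cells enter as 0 (no imputation), each protein
    is centered and optionally unit-variance scaled, and scores come from the
    SVD of the centered matrix. Component signs follow the convention that
    each component's largest-magnitude loading is positive. Returns
    ``(scores, explained_variance_ratio)``.
    """
    X = q.to_numpy(dtype=float).T  # samples x proteins
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = np.nan_to_num(X, nan=0.0)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, s.size)
    # sign convention: largest-|loading| positive per component
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u[:, :k] * s[:k]
    var = s**2
    evr = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    out = pd.DataFrame(
        scores, index=q.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return out, evr
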