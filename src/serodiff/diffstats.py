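"""Differential protein abundance testing with aggregated FDR control.

Per protein and contrast (M vs S, M vs C, M vs SC, S vs C) a two-sided
two-sample t-test is run over the observed (non-missing) quantification
values, with the fold change reported as the binary logarithm of the ratio of
group means. Multiple testing is corrected by a Benjamini–Hochberg step-up
whose total test count is fixed a priori at 3 x (analysis-set size) — each
protein is tested against at most three other sample sets — rather than at
the number of p-values actually produced. The three M-centric contrasts form
one pooled family; S vs C is corrected in its own family with the same total.

The paired acute-vs-survivor comparison subtracts, per subject, the acute
(M_pair) value from the follow-up (S_pair) value and t-tests the differences
against zero, with plain BH across the tested proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import group_samples, paired_samples

STANDARD_CONTRASTS = (("M", "S"), ("M", "C"), ("M", "SC"), ("S", "C"))
M_CENTRIC = ("M_vs_S", "M_vs_C", "M_vs_SC")

#: Number of contrasts a protein is tested in within the aggregated family.
BH_CONTRAST_MULTIPLIER = 3


@dataclass
class ContrastSpec:
    """A two-group comparison: test-group samples vs reference samples."""

    name: str
    test_samples: list[str] = field(default_factory=list)
    ref_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.test_samples or not self.ref_samples:
            raise ValueError(f"contrast {self.name}: both sides must be non-empty")
        if set(self.test_samples) & set(self.ref_samples):
            raise ValueError(f"contrast {self.name}: sides overlap")


def contrast_from_groups(samples: pd.DataFrame, test: str, ref: str) -> ContrastSpec:
    """Build a contrast from group labels; 'SC' pools S and C sample-wise."""
    return ContrastSpec(
        name=f"{test}_vs_{ref}",
        test_samples=group_samples(samples, test),
        ref_samples=group_samples(samples, ref),
    )


def standard_contrasts(samples: pd.DataFrame) -> list[ContrastSpec]:
    return [contrast_from_groups(samples, t, r) for t, r in STANDARD_CONTRASTS]


def two_sample_t(
    test_values, ref_values, variant: str = "student"
) -> tuple[float, float]:
    """Two-sided two-sample t-test (test minus reference).

    ``student`` pools the variances (n1+n2-2 df); ``welch`` uses the
    Satterthwaite approximation.
    """
    x = np.asarray(test_values, dtype=float)
    y = np.asarray(ref_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per side")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def log2_fold_change(mean_test: float, mean_ref: float) -> float:
    """Binary log of the ratio of group mean quantification values."""
    if mean_test <= 0 or mean_ref <= 0:
        raise ValueError("fold change requires positive group means")
    return float(np.log2(mean_test / mean_ref))


def run_contrast(
    q: pd.DataFrame,
    spec: ContrastSpec,
    alpha: float = 0.05,
    *,
    variant: str = "student",
    min_obs: int = 2,
    zeros_as_values: bool = False,
) -> pd.DataFrame:
    """Per-protein t-tests and fold changes for one contrast.

    Means, SDs and tests use observed (non-missing) values only unless
    ``zeros_as_values`` replaces missing cells by 0 (sensitivity mode).
    Proteins with fewer than ``min_obs`` observations on either side are kept
    in the output with ``tested=False`` and NaN statistics. The ``q`` column
    is NaN here and filled by :func:`aggregate_bh` / :func:`run_differential`.
    """
    X = q[spec.test_samples].to_numpy(dtype=float)
    Y = q[spec.ref_samples].to_numpy(dtype=float)
    if zeros_as_values:
        X = np.nan_to_num(X, nan=0.0)
        Y = np.nan_to_num(Y, nan=0.0)

    n_test = np.sum(~np.isnan(X), axis=1)
    n_ref = np.sum(~np.isnan(Y), axis=1)
    mean_test = _nanmean(X, n_test)
    mean_ref = _nanmean(Y, n_ref)
    sd_test = _nanstd(X)
    sd_ref = _nanstd(Y)

    tested = (n_test >= max(min_obs, 2)) & (n_ref >= max(min_obs, 2))
    # at least one side must carry variance for the statistic to exist
    tested &= (sd_test > 0) | (sd_ref > 0)

    t = np.full(len(q), np.nan)
    p = np.full(len(q), np.nan)
    if tested.any():
        res = stats.ttest_ind(
            X[tested],
            Y[tested],
            axis=1,
            equal_var=(variant == "student"),
            nan_policy="omit",
        )
        t[tested] = res.statistic
        p[tested] = res.pvalue

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(
            (mean_test > 0) & (mean_ref > 0), np.log2(mean_test / mean_ref), np.nan
        )

    out = pd.DataFrame(
        {
            "contrast": spec.name,
            "n_test": n_test,
            "n_ref": n_ref,
            "mean_test": mean_test,
            "mean_ref": mean_ref,
            "sd_test": sd_test,
            "sd_ref": sd_ref,
            "t": t,
            "p": p,
            "q": np.nan,
            "log2fc": log2fc,
            "tested": tested,
        },
        index=q.index,
    )
    out.attrs["alpha"] = alpha
    return out


def _nanmean(A: np.ndarray, n: np.ndarray) -> np.ndarray:
    return np.where(n > 0, np.nansum(A, axis=1) / np.maximum(n, 1), np.nan)


def _nanstd(A: np.ndarray) -> np.ndarray:
    n = np.sum(~np.isnan(A), axis=1)
    out = np.full(A.shape[0], np.nan)
    ok = n >= 2
    if ok.any():
        with np.errstate(invalid="ignore"):
            out[ok] = np.nanstd(A[ok], axis=1, ddof=1)
    return out


def aggregate_bh(pvalues, m_total: int) -> np.ndarray:
    """BH step-up with a fixed total test count ``m_total``.

    The supplied p-values (possibly pooled over several contrasts) are sorted
    and adjusted as q_(i) = min_{j>=i} p_(j) * m_total / j, capped at 1.
    ``m_total`` must be at least the number of supplied p-values; with
    equality this reduces to the textbook BH adjustment.
    """
    p = np.asarray(pvalues, dtype=float)
    k = p.size
    if m_total < k:
        raise ValueError(f"m_total={m_total} smaller than number of p-values ({k})")
    if k == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m_total / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q


def run_differential(
    q: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    *,
    variant: str = "student",
    m_total: int | None = None,
    min_obs: int = 2,
) -> dict[str, pd.DataFrame]:
    """All four standard contrasts with aggregated BH correction.

    ``m_total`` defaults to 3 x (number of proteins in the matrix). The three
    M-centric contrasts share one pooled BH family of size ``m_total``;
    S vs C forms its own family corrected with the same total. Adds ``q`` and
    ``significant`` (q <= alpha) to every contrast table.
    """
    if m_total is None:
        m_total = BH_CONTRAST_MULTIPLIER * len(q)
    results = {
        spec.name: run_contrast(q, spec, alpha, variant=variant, min_obs=min_obs)
        for spec in standard_contrasts(samples)
    }
    _fill_q([results[name] for name in M_CENTRIC], m_total)
    _fill_q([results["S_vs_C"]], m_total)
    for df in results.values():
        df["significant"] = df["q"] <= alpha
    return results


def _fill_q(family: Sequence[pd.DataFrame], m_total: int) -> None:
    ps = np.concatenate([df.loc[df["tested"], "p"].to_numpy() for df in family])
    qs = aggregate_bh(ps, m_total)
    start = 0
    for df in family:
        mask = df["tested"].to_numpy()
        n = int(mask.sum())
        df.loc[mask, "q"] = qs[start : start + n]
        start += n


def significant_sets(
    results: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> dict[str, set]:
    """Per-contrast significant-protein sets and the named intersections.

    ``M_intersection`` = M_vs_S ∩ M_vs_C ∩ M_vs_SC (proteins separating the
    acute group from every other set); ``threeway`` = M_vs_S ∩ M_vs_C ∩
    S_vs_C (changed between any two groups).
    """
    sets = {
        name: set(df.index[(df["q"] <= alpha).fillna(False)])
        for name, df in results.items()
    }
    if all(n in sets for n in M_CENTRIC):
        sets["M_intersection"] = (
            sets["M_vs_S"] & sets["M_vs_C"] & sets["M_vs_SC"]
        )
    if all(n in sets for n in ("M_vs_S", "M_vs_C", "S_vs_C")):
        sets["threeway"] = sets["M_vs_S"] & sets["M_vs_C"] & sets["S_vs_C"]
    return sets


def paired_contrast(
    q: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    *,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Paired follow-up-minus-acute test over the S_pair/M_pair subjects.

    For each protein the per-pair differences (S sample minus M sample, both
    observed) are tested against zero with a two-sided one-sample t-test;
    plain BH runs across the tested proteins. Proteins with fewer than
    ``min_pairs`` usable pairs or zero-variance differences are reported with
    ``tested=False``.
    """
    pairs = paired_samples(samples)
    if pairs.empty:
        raise ValueError("sample sheet defines no pairs")
    S = q[pairs["s_sample"].tolist()].to_numpy(dtype=float)
    M = q[pairs["m_sample"].tolist()].to_numpy(dtype=float)
    D = S - M  # NaN when either member missing

    n_used = np.sum(~np.isnan(D), axis=1)
    mean_diff = _nanmean(D, n_used)
    sd_diff = _nanstd(D)
    tested = (n_used >= min_pairs) & (sd_diff > 0)

    t = np.full(len(q), np.nan)
    p = np.full(len(q), np.nan)
    if tested.any():
        res = stats.ttest_1samp(D[tested], 0.0, axis=1, nan_policy="omit")
        t[tested] = res.statistic
        p[tested] = res.pvalue

    qvals = np.full(len(q), np.nan)
    if tested.any():
        qvals[tested] = multipletests(p[tested], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "n_pairs_used": n_used,
            "mean_diff": mean_diff,
            "t": t,
            "p": p,
            "q": qvals,
            "direction_m": np.where(
                np.isnan(mean_diff), "", np.where(mean_diff > 0, "down", "up")
            ),
            "tested": tested,
        },
        index=q.index,
    )
    out["significant"] = out["q"] <= alpha
    return out
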