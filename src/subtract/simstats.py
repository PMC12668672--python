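"""Tract-similarity and group-comparison statistics.

Pairwise subject similarity is the Pearson correlation between normalised
path distributions after thresholding at 0.5% of valid streamlines, averaged
across tracts per subject pair. Group distributions of these averages (e.g.
monozygotic twins vs unrelated pairs) are compared with two-sided
Mann-Whitney U tests, Bonferroni-corrected across the pairwise group
comparisons.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import PathDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityTable",
    "tract_pearson",
    "pairwise_similarity",
    "mann_whitney_u",
    "bonferroni",
    "rank_to_group_average",
]

SIMILARITY_THRESHOLD = 0.005  # fraction of valid streamlines
EXACT_LIMIT = 12  # enumeration bound for the exact Mann-Whitney mode


def tract_pearson(
    pd_a: PathDistribution, pd_b: PathDistribution, threshold: float = SIMILARITY_THRESHOLD
) -> float:
    """Pearson r between two thresholded path distributions.

    Values below ``threshold`` are zeroed in each map; the correlation is
    computed over voxels non-zero in at least one map. Returns NaN (flagged
    missing) when fewer than 3 such voxels exist or either map is constant
    on them.
    """
    if pd_a.grid != pd_b.grid:
        raise ValueError("path distributions are on different grids")
    if not (pd_a.normalised and pd_b.normalised):
        raise ValueError("path distributions must be normalised")
    a = pd_a.values.ravel().copy()
    b = pd_b.values.ravel().copy()
    a[a < threshold] = 0.0
    b[b < threshold] = 0.0
    support = (a > 0) | (b > 0)
    if support.sum() < 3:
        return float("nan")
    a, b = a[support], b[support]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SimilarityTable:
    """Per-pair mean/sd of across-tract correlations plus the per-tract values."""

    table: pd.DataFrame  # columns: subject_a, subject_b, group, mean_r, sd_r, n_tracts
    per_tract: pd.DataFrame  # one column per tract, one row per pair

    def group_means(self) -> pd.Series:
        return self.table.groupby("group")["mean_r"].mean()


def pairwise_similarity(
    cohort: dict[str, dict[str, PathDistribution]],
    pairs: list[tuple],
    threshold: float = SIMILARITY_THRESHOLD,
) -> SimilarityTable:
    """Per-tract Pearson r for each subject pair, then mean and sd across
    tracts. ``pairs`` entries are (subject_a, subject_b) or
    (subject_a, subject_b, group_label). Missing (NaN) tracts are excluded
    from the per-pair mean and logged.
    """
    if not pairs:
        raise ValueError("empty pair list")
    tract_lists = {tuple(sorted(tr)) for tr in (cohort[s].keys() for s in cohort)}
    if len(tract_lists) != 1:
        raise ValueError("all subjects must share the same tract list")
    tracts = sorted(next(iter(tract_lists)))

    rows, per_tract_rows = [], []
    n_missing = 0
    for pair in pairs:
        a, b = pair[0], pair[1]
        group = pair[2] if len(pair) > 2 else ""
        rs = {t: tract_pearson(cohort[a][t], cohort[b][t], threshold) for t in tracts}
        vals = np.array([rs[t] for t in tracts], dtype=float)
        ok = ~np.isnan(vals)
        n_missing += int((~ok).sum())
        rows.append(
            {
                "subject_a": a,
                "subject_b": b,
                "group": group,
                "mean_r": float(vals[ok].mean()) if ok.any() else float("nan"),
                "sd_r": float(vals[ok].std(ddof=0)) if ok.any() else float("nan"),
                "n_tracts": int(ok.sum()),
            }
        )
        per_tract_rows.append(rs)
    if n_missing:
        logger.warning("pairwise_similarity: %d missing tract correlations excluded", n_missing)
    return SimilarityTable(table=pd.DataFrame(rows), per_tract=pd.DataFrame(per_tract_rows))


def _u_statistic(ranks_x: np.ndarray, n: int) -> float:
    return float(ranks_x.sum() - n * (n + 1) / 2.0)


def mann_whitney_u(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    ``exact`` enumerates all C(n+m, n) group assignments of the pooled
    (mid-)ranks — feasible for n+m <= 12; ``normal-approx`` uses the
    tie-corrected large-sample normal form with continuity correction;
    ``auto`` picks exact when feasible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n], n)

    if mode == "auto":
        mode = "exact" if n + m <= EXACT_LIMIT else "normal-approx"
    if mode == "exact":
        if n + m > EXACT_LIMIT:
            raise ValueError(f"exact mode limited to n+m <= {EXACT_LIMIT}")
        us = np.array(
            [
                _u_statistic(ranks[list(comb)], n)
                for comb in itertools.combinations(range(n + m), n)
            ]
        )
        n_le = np.count_nonzero(us <= u_obs + 1e-12)
        n_ge = np.count_nonzero(us >= u_obs - 1e-12)
        p = min(1.0, 2.0 * min(n_le, n_ge) / us.size)
        return u_obs, p
    if mode == "normal-approx":
        mu = n * m / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum()
        nm = n + m
        sigma2 = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1)))
        if sigma2 <= 0:
            return u_obs, 1.0
        z = (u_obs - mu - math.copysign(0.5, u_obs - mu)) / math.sqrt(sigma2)
        if abs(u_obs - mu) < 0.5:
            z = 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        return u_obs, min(1.0, p)
    raise ValueError(f"unknown mode {mode!r}")


def bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Significance flags under the Bonferroni-adjusted threshold alpha/n."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    thr = alpha / p.size
    return p < thr, thr


def rank_to_group_average(
    cohort: dict[str, dict[str, PathDistribution]],
    group_average: dict[str, PathDistribution],
    percentiles=(10, 50, 90),
    threshold: float = SIMILARITY_THRESHOLD,
) -> dict[float, str]:
    """Subjects at the requested percentiles of mean-over-tracts correlation
    to the group average (nearest-rank rule; ties -> lowest subject id)."""
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects")
    scores = {}
    for subj, tracts in cohort.items():
        rs = [
            tract_pearson(tracts[t], group_average[t], threshold) for t in group_average
        ]
        rs = [r for r in rs if not math.isnan(r)]
        if not rs:
            raise ValueError(f"subject {subj!r} has no defined correlations")
        scores[subj] = float(np.mean(rs))
    ordered = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    nsub = len(ordered)
    out = {}
    for p in percentiles:
        rank = max(1, math.ceil(p / 100.0 * nsub))  # nearest-rank
        r_val = ordered[rank - 1][1]
        tied = [s for s, v in ordered if v == r_val]
        out[p] = min(tied)
    return out
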