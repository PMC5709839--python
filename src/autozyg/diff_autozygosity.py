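"""Differential autozygosity between two groups of individuals.

Window-wise one-sided Wilcoxon rank-sum statistics compare per-individual
wLOD scores between two groups, and significance is assessed against a
genome-wide max-statistic permutation null: each permutation of the group
labels records the maximum statistic across all windows, and a window's
adjusted P-value is the (add-one) proportion of permutation maxima at or
above its observed statistic.  Overlapping qualifying windows are joined
into enriched regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .wlod_engine import WindowScoreMatrix


def _flatten(scores: WindowScoreMatrix):
    """(n_ind, W) score matrix plus per-window (chrom, start_bp, end_bp)."""
    mats, meta = [], []
    for chrom in scores.chroms:
        m = scores.scores[chrom]
        start, end = scores.window_bounds(chrom)
        mats.append(m.T)
        meta.append(pd.DataFrame({"chrom": chrom, "start_bp": start,
                                  "end_bp": end}))
    return np.hstack(mats), pd.concat(meta, ignore_index=True)


def _group_indices(scores: WindowScoreMatrix, groups: dict[str, str]):
    labels = sorted({g for g in groups.values()})
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a_label, b_label = labels
    idx = {s: i for i, s in enumerate(scores.individual_ids)}
    a = np.asarray([idx[s] for s, g in groups.items() if g == a_label and s in idx])
    b = np.asarray([idx[s] for s, g in groups.items() if g == b_label and s in idx])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 scored members")
    return a_label, b_label, np.sort(a), np.sort(b)


def rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided rank-sum statistic (sum of x's mid-ranks in the pooled
    sample); large values support 'x stochastically greater than y'."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    return float(ranks[:len(x)].sum())


def window_contrast(scores: WindowScoreMatrix, groups: dict[str, str],
                    direction: str = "A>B") -> np.ndarray:
    """Per-window rank-sum statistic for one direction.

    ``direction`` "A>B" sums the first (alphabetical) group's ranks,
    "B>A" the second's.  Ties are mid-ranked.
    """
    a_label, b_label, a, b = _group_indices(scores, groups)
    mat, _ = _flatten(scores)
    sub = mat[np.concatenate([a, b])]
    ranks = rankdata(sub, axis=0)
    if direction == "A>B":
        return ranks[:len(a)].sum(axis=0)
    if direction == "B>A":
        return ranks[len(a):].sum(axis=0)
    raise ValueError("direction must be 'A>B' or 'B>A'")


@dataclass
class PermutationResult:
    """Observed statistics, permutation maxima and adjusted P-values."""

    windows: pd.DataFrame          # chrom, start_bp, end_bp
    stat_a_gt_b: np.ndarray
    stat_b_gt_a: np.ndarray
    perm_max_a: np.ndarray         # per permutation genome-wide maxima
    perm_max_b: np.ndarray
    p_a_gt_b: np.ndarray
    p_b_gt_a: np.ndarray
    n_permutations: int
    seed: int
    a_label: str
    b_label: str


def permutation_null(scores: WindowScoreMatrix, groups: dict[str, str],
                     n_perm: int = 1000, seed: int = 0) -> PermutationResult:
    """Genome-wide max-statistic permutation null for both directions.

    Permutations shuffle group labels (preserving group sizes) among the
    labelled individuals; per-window ranks are computed once since label
    permutation leaves them unchanged.  Adjusted P-values use the add-one
    convention ``(1 + #{max >= observed}) / (n_perm + 1)`` so P is never 0
    and ties count against significance.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse P-value "
                      "grid", stacklevel=2)
    a_label, b_label, a, b = _group_indices(scores, groups)
    mat, windows = _flatten(scores)
    sub = mat[np.concatenate([a, b])]
    n_a, n_tot = len(a), len(a) + len(b)
    ranks = rankdata(sub, axis=0)
    obs_a = ranks[:n_a].sum(axis=0)
    obs_b = ranks[n_a:].sum(axis=0)
    total = ranks.sum(axis=0)

    rng = np.random.default_rng(seed)
    max_a = np.empty(n_perm)
    max_b = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n_tot)
        sa = ranks[perm[:n_a]].sum(axis=0)
        max_a[p] = sa.max()
        max_b[p] = (total - sa).max()
    p_a = (1 + (max_a[:, None] >= obs_a[None, :]).sum(axis=0)) / (n_perm + 1)
    p_b = (1 + (max_b[:, None] >= obs_b[None, :]).sum(axis=0)) / (n_perm + 1)
    return PermutationResult(windows, obs_a, obs_b, max_a, max_b, p_a, p_b,
                             n_perm, seed, a_label, b_label)


def call_enriched_regions(result: PermutationResult,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Join overlapping windows with P_perm <= alpha into regions.

    Returns one row per region per direction with chromosome, bp bounds,
    window count and minimum P_perm.
    """
    out = []
    for direction, pvals in (("A>B", result.p_a_gt_b), ("B>A", result.p_b_gt_a)):
        q = result.windows.assign(p=pvals)
        q = q[q["p"] <= alpha].sort_values(["chrom", "start_bp"])
        for chrom, sub in q.groupby("chrom", sort=False):
            cur_s = cur_e = None
            n_win, min_p = 0, np.inf
            for row in sub.itertuples():
                if cur_s is None or row.start_bp > cur_e:
                    if cur_s is not None:
                        out.append({"direction": direction, "chrom": chrom,
                                    "start_bp": int(cur_s), "end_bp": int(cur_e),
                                    "length_bp": int(cur_e - cur_s),
                                    "n_windows": n_win, "min_p_perm": min_p})
                    cur_s, cur_e, n_win, min_p = row.start_bp, row.end_bp, 0, np.inf
                cur_e = max(cur_e, row.end_bp)
                n_win += 1
                min_p = min(min_p, row.p)
            if cur_s is not None:
                out.append({"direction": direction, "chrom": chrom,
                            "start_bp": int(cur_s), "end_bp": int(cur_e),
                            "length_bp": int(cur_e - cur_s),
                            "n_windows": n_win, "min_p_perm": min_p})
    return pd.DataFrame(out, columns=["direction", "chrom", "start_bp",
                                      "end_bp", "length_bp", "n_windows",
                                      "min_p_perm"])
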