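"""Genome-wide score-distribution analysis.

The pooled per-window score distribution of a sample is summarised with a
Gaussian kernel density estimate.  A bimodal distribution separates a
non-autozygous (left) mode from an autozygous (right) mode; the score at
the density minimum between them is the natural autozygosity threshold.
In populations practising both endogamy and consanguinity a third mode
can split the autozygous mass in two, and the minimum between the two
autozygous modes separates endogamy-like from consanguinity-like windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from statsmodels.nonparametric.kde import KDEUnivariate

from .wlod_engine import ModelParams, WindowScoreMatrix, scan_wlod

logger = logging.getLogger(__name__)

#: subsample threshold: above this many windows per individual, threshold
#: estimation pools a random subset of 20 individuals
MEMORY_GUARD_WINDOWS = 5_000_000


@dataclass
class ScoreDistributionSummary:
    """KDE summary of a pooled window-score distribution."""

    grid: np.ndarray
    density: np.ndarray
    modes: np.ndarray            # modal score locations, ascending
    mode_densities: np.ndarray
    minima: np.ndarray           # density-minimum scores between adjacent modes
    modality: str                # unimodal | bimodal | trimodal | multimodal
    intermodal_distance: float | None
    threshold: float | None      # minimum between modes 1 and 2
    inter_autozygous_minimum: float | None  # minimum between modes 2 and 3

    @property
    def n_modes(self) -> int:
        return len(self.modes)


def _merge_unclear_modes(grid, dens, peaks, valley_frac):
    """Merge adjacent peaks that are not separated by a clear valley.

    Two adjacent peaks belong to the same mode when the density minimum
    between them exceeds ``valley_frac`` times the lower of the two peak
    densities; each merged group is represented by its highest peak.
    """
    if len(peaks) <= 1:
        return np.asarray(peaks)
    groups = [[peaks[0]]]
    for a, b in zip(peaks[:-1], peaks[1:]):
        valley = dens[a:b + 1].min()
        if valley > valley_frac * min(dens[a], dens[b]):
            groups[-1].append(b)
        else:
            groups.append([b])
    return np.asarray([g[int(np.argmax(dens[g]))] for g in groups])


def pool_and_kde(scores, individuals=None, bandwidth: str = "silverman",
                 gridsize: int = 4096, prominence_frac: float = 0.01,
                 valley_frac: float = 0.5,
                 subsample_seed: int = 0) -> ScoreDistributionSummary:
    """Gaussian KDE of pooled window scores with mode/minimum detection.

    Parameters
    ----------
    scores
        A :class:`WindowScoreMatrix` or a 1-D array of pooled scores.
    individuals
        Optional index array restricting the pooled individuals.  Fewer
        than 10 individuals triggers a warning (threshold estimates become
        unstable below that).
    prominence_frac
        Local maxima are retained as modes only when their prominence is
        at least this fraction of the global density maximum, which
        suppresses spurious modes from KDE ripple.
    valley_frac
        Adjacent retained peaks whose separating density minimum exceeds
        this fraction of the lower peak are merged into one mode — a
        formalisation of the 'clear' multimodality judged visually in
        practice.
    """
    if isinstance(scores, WindowScoreMatrix):
        n_ind = len(scores.individual_ids)
        idx = np.arange(n_ind) if individuals is None else np.asarray(individuals)
        if len(idx) < 10:
            warnings.warn("fewer than 10 individuals: score threshold may be "
                          "unstable", stacklevel=2)
        per_ind = scores.n_windows()
        if per_ind > MEMORY_GUARD_WINDOWS and len(idx) > 20:
            rng = np.random.default_rng(subsample_seed)
            idx = rng.choice(idx, size=20, replace=False)
        pooled = scores.pooled(idx)
    else:
        pooled = np.asarray(scores, dtype=np.float64).ravel()
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size < 2:
        raise ValueError("need at least 2 window scores for a KDE")

    kde = KDEUnivariate(pooled)
    kde.fit(kernel="gau", bw=bandwidth, fft=True, gridsize=gridsize)
    grid = np.asarray(kde.support)
    dens = np.asarray(kde.density)

    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    # a mode at a grid boundary has no turning point; include boundary maxima
    if dens.size > 1 and dens[0] > dens[1] and dens[0] >= prominence_frac * dens.max():
        peaks = np.concatenate([[0], peaks])
    peaks = _merge_unclear_modes(grid, dens, peaks, valley_frac)
    modes = grid[peaks]
    mode_dens = dens[peaks]

    minima = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        j = a + int(np.argmin(dens[a:b + 1]))
        minima.append(grid[j])
    minima = np.asarray(minima)

    n = len(modes)
    modality = {0: "unimodal", 1: "unimodal", 2: "bimodal", 3: "trimodal"}.get(
        n, "multimodal")
    threshold = float(minima[0]) if n >= 2 else None
    inter_auto = float(minima[1]) if n >= 3 else None
    inter_dist = float(modes[1] - modes[0]) if n >= 2 else None
    return ScoreDistributionSummary(grid, dens, modes, mode_dens, minima,
                                    modality, inter_dist, threshold, inter_auto)


def select_window_size(panel, freqs, ld, gmap, params: ModelParams,
                       k_grid, mode: str = "roa",
                       kde_kwargs: dict | None = None):
    """Scan a window-size grid and pick K from the pooled distributions.

    In ``"roa"`` mode returns the largest K whose pooled distribution has
    at least two modes (the ROA-calling convention); in ``"contrast"``
    mode the K maximising the intermodal distance between non-autozygous
    and autozygous modal scores (used for group contrasts).  Returns
    ``(chosen_k_or_None, per_k_summary_frame, summaries_dict)``.
    """
    if mode not in ("roa", "contrast"):
        raise ValueError("mode must be 'roa' or 'contrast'")
    kde_kwargs = kde_kwargs or {}
    rows, summaries = [], {}
    for K in sorted(k_grid):
        p = ModelParams(epsilon=params.epsilon, mu=params.mu,
                        m_generations=params.m_generations, window_k=int(K))
        sm = scan_wlod(panel, freqs, ld, gmap, p)
        if sm.n_windows() < 2:
            continue
        summary = pool_and_kde(sm, **kde_kwargs)
        summaries[int(K)] = summary
        rows.append({"K": int(K), "modality": summary.modality,
                     "n_modes": summary.n_modes,
                     "threshold": summary.threshold,
                     "intermodal_distance": summary.intermodal_distance})
    table = pd.DataFrame(rows)
    chosen = None
    if len(table):
        multi = table[table["n_modes"] >= 2]
        if len(multi):
            if mode == "roa":
                chosen = int(multi["K"].max())
            else:
                chosen = int(multi.loc[multi["intermodal_distance"].idxmax(), "K"])
    if chosen is None:
        logger.info("no window size produced a multimodal score distribution")
    return chosen, table, summaries


def rule_of_thumb(snv_per_bp: float) -> tuple[int, float]:
    """Guideline window size and overlap fraction at SNV density ``D``.

    Fitted against simulated optima: ``K = 16.400 ln(D) + 218.020`` and
    ``fraction = 0.0736 ln(D) + 0.8063``.  K is rounded to the nearest
    integer and clamped to >= 20; the fraction is clamped to [0, 0.5]
    (the fitted lines go negative at extreme densities).
    """
    if snv_per_bp <= 0:
        raise ValueError("SNV density must be positive")
    ln_d = np.log(snv_per_bp)
    k = int(round(16.400 * ln_d + 218.020))
    frac = float(np.clip(0.0736 * ln_d + 0.8063, 0.0, 0.5))
    return max(k, 20), frac


def decompose_trimodal(scores: WindowScoreMatrix,
                       summary: ScoreDistributionSummary,
                       roas) -> pd.DataFrame:
    """Per-ROA proportion of autozygous windows in the right-most mode.

    For each ROA (built from windows above ``summary.threshold``), the
    proportion of its above-threshold windows scoring above the minimum
    between the two autozygous modes.  ROA with proportion > 0.8 are
    labelled consanguinity-like, < 0.1 endogamy-like, otherwise mixed.
    """
    if summary.inter_autozygous_minimum is None:
        raise ValueError("summary is not trimodal")
    thr = summary.threshold
    mid = summary.inter_autozygous_minimum
    K = scores.window_k
    rows = []
    for row in roas.df.itertuples():
        mat = scores.scores[row.chrom]
        i = scores.individual_ids.index(row.individual)
        nw = mat.shape[0]
        lo = max(0, int(row.first_snp) - K + 1)
        hi = min(nw - 1, int(row.last_snp))
        win = mat[lo:hi + 1, i]
        auto = win[win > thr]
        prop = float((auto > mid).mean()) if auto.size else np.nan
        if np.isnan(prop):
            label = "undetermined"
        elif prop > 0.8:
            label = "consanguinity-like"
        elif prop < 0.1:
            label = "endogamy-like"
        else:
            label = "mixed"
        rows.append({"individual": row.individual, "chrom": row.chrom,
                     "start_bp": row.start_bp, "end_bp": row.end_bp,
                     "proportion_right_mode": prop, "origin_label": label})
    return pd.DataFrame(rows)
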