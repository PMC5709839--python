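"""ROA assembly, classification, baseline caller and evaluation.

A SNP enters an ROA when the fraction of its covering windows that score
above threshold exceeds the overlap fraction; maximal runs of such SNPs
form the ROA.  Near chromosome ends the denominator is the number of
windows that actually exist, so edge SNPs remain reachable at high
fractions.  At overlap fraction 0 the rule reduces to the plain union of
above-threshold windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .data_io import GeneticMap, GenotypePanel, HET, MISSING
from .wlod_engine import WindowScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class ROASet:
    """Called ROA intervals (one row per ROA per individual).

    ``df`` columns: individual, chrom, start_bp, end_bp, length_bp,
    start_cm, end_cm, length_cm, n_windows, mean_score, first_snp,
    last_snp, class_label (0 = unclassified, else 1..G with G the longest
    class).
    """

    df: pd.DataFrame
    window_k: int | None = None
    threshold: float | None = None

    COLUMNS = ["individual", "chrom", "start_bp", "end_bp", "length_bp",
               "start_cm", "end_cm", "length_cm", "n_windows", "mean_score",
               "first_snp", "last_snp", "class_label"]

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls, window_k=None, threshold=None) -> "ROASet":
        return cls(pd.DataFrame(columns=cls.COLUMNS), window_k, threshold)

    def for_individual(self, individual: str) -> pd.DataFrame:
        return self.df[self.df["individual"] == individual]


def _runs(mask: np.ndarray):
    """Start/end (inclusive) indices of maximal True runs."""
    if not mask.any():
        return np.empty(0, int), np.empty(0, int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(mask) - 1]])
    return starts, ends


def assemble_roa(scores: WindowScoreMatrix, threshold: float,
                 overlap_fraction: float,
                 gmap: GeneticMap | None = None) -> ROASet:
    """Assemble ROA from above-threshold windows with a coverage rule.

    A SNP is in-ROA iff (number of above-threshold windows containing it)
    / (number of existing windows containing it) > ``overlap_fraction``.
    ROA boundaries are the first/last in-ROA SNP positions.
    """
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    K = scores.window_k
    rows = []
    for chrom in scores.chroms:
        mat = scores.scores[chrom]
        pos = scores.positions[chrom]
        gpos = None
        if scores.gpos is not None and chrom in scores.gpos:
            gpos = scores.gpos[chrom]
        elif gmap is not None and chrom in gmap.tables:
            gpos = gmap.interpolate(chrom, pos)
        nw, n_ind = mat.shape
        S = len(pos)
        t = np.arange(S)
        lo = np.maximum(0, t - K + 1)
        hi = np.minimum(t, nw - 1)
        n_exist = (hi - lo + 1).astype(np.float64)
        for i in range(n_ind):
            above = mat[:, i] > threshold
            if not above.any():
                continue
            ca = np.concatenate([[0], np.cumsum(above)])
            cs = np.concatenate([[0.0], np.cumsum(np.where(above, mat[:, i], 0.0))])
            cov = ca[hi + 1] - ca[lo]
            in_roa = cov > overlap_fraction * n_exist
            starts, ends = _runs(in_roa)
            for t0, t1 in zip(starts, ends):
                wlo = max(0, t0 - K + 1)
                whi = min(nw - 1, t1)
                n_win = int(ca[whi + 1] - ca[wlo])
                mean_score = (cs[whi + 1] - cs[wlo]) / n_win if n_win else np.nan
                start_cm = end_cm = length_cm = np.nan
                if gpos is not None:
                    start_cm = gpos[t0] * 100.0
                    end_cm = gpos[t1] * 100.0
                    length_cm = end_cm - start_cm
                rows.append({
                    "individual": scores.individual_ids[i], "chrom": chrom,
                    "start_bp": int(pos[t0]), "end_bp": int(pos[t1]),
                    "length_bp": int(pos[t1] - pos[t0]),
                    "start_cm": start_cm, "end_cm": end_cm,
                    "length_cm": length_cm, "n_windows": n_win,
                    "mean_score": mean_score, "first_snp": int(t0),
                    "last_snp": int(t1), "class_label": 0,
                })
    df = pd.DataFrame(rows, columns=ROASet.COLUMNS)
    return ROASet(df, window_k=K, threshold=threshold)


def naive_count_roh(panel: GenotypePanel, window_k: int = 50,
                    max_het_frac: float = 0.02, max_missing_frac: float = 0.05,
                    overlap_fraction: float = 0.0,
                    gmap: GeneticMap | None = None) -> ROASet:
    """Genotype-counting ROH baseline.

    A window is autozygous when it holds at most ``max_het_frac * K``
    heterozygous and ``max_missing_frac * K`` missing genotypes (boundary
    inclusive); assembly is identical to :func:`assemble_roa`.
    """
    scores, positions = {}, {}
    for chrom in panel.chroms:
        g = panel.genotypes[chrom]
        S = len(panel.positions[chrom])
        if S < window_k:
            continue
        het = np.concatenate([np.zeros((1, g.shape[1])),
                              np.cumsum(g == HET, axis=0)])
        mis = np.concatenate([np.zeros((1, g.shape[1])),
                              np.cumsum(g == MISSING, axis=0)])
        n_het = het[window_k:] - het[:-window_k]
        n_mis = mis[window_k:] - mis[:-window_k]
        ok = (n_het <= max_het_frac * window_k) & (n_mis <= max_missing_frac * window_k)
        scores[chrom] = ok.astype(np.float64)
        positions[chrom] = panel.positions[chrom]
    sm = WindowScoreMatrix(window_k, scores, positions,
                           list(panel.individual_ids), kind="naive")
    return assemble_roa(sm, 0.5, overlap_fraction, gmap=gmap)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Gaussian-mixture fit over ROA lengths."""

    g: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    bic: dict[int, float]            # sklearn convention: lower is better
    skipped: dict[int, str] = field(default_factory=dict)
    length_scale: str = "genetic"


def classify_roa_gmm(roas: ROASet, candidate_g=range(1, 11),
                     length_scale: str = "genetic", seed: int = 0) -> tuple[MixtureFit, ROASet]:
    """Classify ROA by length with a Gaussian mixture model.

    Fits an EM Gaussian mixture (free weights, means, variances) to the
    genetic-map lengths (cM; ``length_scale="physical"`` uses bp) for each
    candidate component count G, selects G by BIC, orders components by
    increasing mean (so label G marks the longest class) and assigns each
    ROA its maximum-posterior class.
    """
    if length_scale == "genetic":
        x = roas.df["length_cm"].to_numpy(dtype=np.float64)
    elif length_scale == "physical":
        x = roas.df["length_bp"].to_numpy(dtype=np.float64)
    else:
        raise ValueError("length_scale must be 'genetic' or 'physical'")
    if not np.all(np.isfinite(x)):
        raise ValueError("ROA lengths contain non-finite values "
                         "(classification on genetic length needs a map)")
    n_ind = roas.df["individual"].nunique()
    if n_ind < 25:
        warnings.warn("fewer than 25 individuals: GMM classification may be "
                      "unstable", stacklevel=2)
    x = x.reshape(-1, 1)
    fits, bic, skipped = {}, {}, {}
    for g in candidate_g:
        if len(x) < 2 * g:
            skipped[g] = f"only {len(x)} ROA for G={g}"
            continue
        gm = GaussianMixture(n_components=g, covariance_type="full",
                             n_init=10, random_state=seed, reg_covar=1e-6)
        gm.fit(x)
        fits[g] = gm
        bic[g] = float(gm.bic(x))
    if not fits:
        raise ValueError("no candidate G could be fitted")
    best_g = min(bic, key=bic.get)
    gm = fits[best_g]
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    variances = gm.covariances_.reshape(best_g, -1)[:, 0][order]
    weights = gm.weights_[order]
    post = gm.predict_proba(x)[:, order]
    labels = post.argmax(axis=1) + 1  # 1..G ascending mean
    out = ROASet(roas.df.copy(), roas.window_k, roas.threshold)
    out.df["class_label"] = labels
    fit = MixtureFit(best_g, weights, means, variances, bic, skipped, length_scale)
    return fit, out


# ---------------------------------------------------------------------------
# evaluation against simulated truth
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Agreement between inferred ROA and true autozygous segments."""

    power: float               # overlapped true length / total true length
    false_discovery: float     # non-overlapping inferred length / total inferred
    ratios: np.ndarray         # per detected true segment: union inferred / true
    mean_ratio: float          # unweighted mean of per-segment ratios
    lw_ratio: float            # length-weighted: sum(union inferred)/sum(true)
    n_false_positive: int      # inferred ROA overlapping no true segment
    n_false_negative: int      # true segments with no qualifying overlap
    n_detected: int
    total_true_bp: float
    total_inferred_bp: float


def _overlap_len(a_start, a_end, b_start, b_end) -> float:
    """Total overlap between two sorted disjoint interval sets [start, end)."""
    total = 0.0
    i = j = 0
    while i < len(a_start) and j < len(b_start):
        lo = max(a_start[i], b_start[j])
        hi = min(a_end[i], b_end[j])
        if hi > lo:
            total += hi - lo
        if a_end[i] < b_end[j]:
            i += 1
        else:
            j += 1
    return total


def evaluate_against_truth(inferred: ROASet, truth,
                           min_true_length: float = 0.0,
                           min_overlap_bp: float = 1.0) -> EvalReport:
    """Interval-arithmetic comparison of inferred ROA with true segments.

    Power is the total length of true segments (longer than
    ``min_true_length``) overlapped by inferred ROA divided by their total
    length; the false-discovery rate always uses all true segments.  A
    true segment is detected when overlapped by at least
    ``min_overlap_bp``; its ratio is the union length of inferred ROA
    overlapping it divided by its own length.
    """
    tdf = truth.df
    idf = inferred.df
    tot_true = 0.0
    tot_true_cov = 0.0
    tot_inf = float((idf["end_bp"] - idf["start_bp"]).sum())
    tot_inf_cov = 0.0
    ratios, n_fp, n_fn, n_det = [], 0, 0, 0
    det_true_len = det_inf_len = 0.0
    individuals = set(tdf["individual"]) | set(idf["individual"])
    for ind in individuals:
        t = tdf[tdf["individual"] == ind].sort_values("start_bp")
        inf = idf[idf["individual"] == ind].sort_values("start_bp")
        ts, te = t["start_bp"].to_numpy(float), t["end_bp"].to_numpy(float)
        is_, ie = inf["start_bp"].to_numpy(float), inf["end_bp"].to_numpy(float)
        keep = (te - ts) > min_true_length
        tot_true += (te[keep] - ts[keep]).sum()
        tot_true_cov += _overlap_len(ts[keep], te[keep], is_, ie)
        tot_inf_cov += _overlap_len(is_, ie, ts, te)
        # per-segment detection / ratio and FP/FN counts
        for s0, e0 in zip(ts, te):
            sel = (ie > s0) & (is_ < e0)
            ov = _overlap_len(np.array([s0]), np.array([e0]), is_[sel], ie[sel])
            if ov >= min_overlap_bp:
                n_det += 1
                # union length of the inferred ROA overlapping this segment
                u_s, u_e = is_[sel], ie[sel]
                union = float((u_e - u_s).sum())  # inferred ROA are disjoint
                ratios.append(union / (e0 - s0))
                det_true_len += e0 - s0
                det_inf_len += union
            else:
                n_fn += 1
        for s0, e0 in zip(is_, ie):
            if _overlap_len(np.array([s0]), np.array([e0]), ts, te) <= 0:
                n_fp += 1
    power = tot_true_cov / tot_true if tot_true > 0 else np.nan
    fdr = 1.0 - tot_inf_cov / tot_inf if tot_inf > 0 else np.nan
    ratios = np.asarray(ratios, dtype=np.float64)
    lw = det_inf_len / det_true_len if det_true_len > 0 else np.nan
    return EvalReport(power, fdr, ratios,
                      float(ratios.mean()) if ratios.size else np.nan,
                      lw, n_fp, n_fn, n_det, tot_true, tot_inf)


# ---------------------------------------------------------------------------
# optimal-parameter search
# ---------------------------------------------------------------------------

def select_optimal(surface: pd.DataFrame, ratio_tol: float = 0.05):
    """Smallest (K, fraction) with zero mean false positives and a
    length-weighted inferred/true ratio within ``ratio_tol`` of one.

    The length-weighted ratio (total inferred length over detected true
    segments divided by their total true length) is used rather than the
    unweighted per-segment mean, which is dominated by very short true
    segments swept up by window-scale calls.  Returns
    ``(K, fraction, qualified)``; when nothing qualifies, the best-effort
    cell (fewest false positives, then ratio closest to one) is returned
    with ``qualified=False``.
    """
    if not len(surface):
        return None, None, False
    ok = surface[(surface["fp_count"] == 0)
                 & ((surface["lw_ratio"] - 1.0).abs() <= ratio_tol)]
    if len(ok):
        row = ok.sort_values(["K", "fraction"]).iloc[0]
        return int(row["K"]), float(row["fraction"]), True
    row = surface.assign(_d=(surface["lw_ratio"] - 1.0).abs()) \
                 .sort_values(["fp_count", "_d", "K", "fraction"]).iloc[0]
    return int(row["K"]), float(row["fraction"]), False


def optimal_parameter_search(scan_fn, truth, k_grid, fraction_grid,
                             threshold_fn, ratio_tol: float = 0.05,
                             gmap: GeneticMap | None = None):
    """Grid evaluation of window size and overlap fraction against truth.

    ``scan_fn(K)`` must return a :class:`WindowScoreMatrix` and
    ``threshold_fn(scores)`` a score threshold (or None when the pooled
    distribution is not multimodal, in which case the K is skipped).
    Returns ``(K*, fraction*, surface)`` where the surface holds power,
    false-discovery rate, mean ratio and FP/FN counts per grid cell.
    """
    if truth is not None and not len(truth.df):
        logger.info("empty truth set: optimal search is degenerate")
        return None, None, pd.DataFrame()
    rows = []
    for K in sorted(k_grid):
        sm = scan_fn(int(K))
        if sm.n_windows() == 0:
            continue
        thr = threshold_fn(sm)
        if thr is None:
            continue
        for f in sorted(fraction_grid):
            roas = assemble_roa(sm, thr, float(f), gmap=gmap)
            rep = evaluate_against_truth(roas, truth)
            rows.append({"K": int(K), "fraction": float(f),
                         "threshold": thr, "power": rep.power,
                         "fdr": rep.false_discovery,
                         "mean_ratio": rep.mean_ratio,
                         "lw_ratio": rep.lw_ratio,
                         "fp_count": rep.n_false_positive,
                         "fn_count": rep.n_false_negative})
    surface = pd.DataFrame(rows)
    k_star, f_star, ok = select_optimal(surface, ratio_tol)
    if not ok:
        logger.info("no (K, fraction) met the zero-FP/unit-ratio criteria; "
                    "best-effort pair returned")
    return k_star, f_star, surface
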