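"""Sliding-window autozygosity likelihood scores (LOD and wLOD).

Per-SNP model
-------------
At a biallelic site with reference-allele frequency ``f_A`` and combined
genotyping-error/mutation rate ``eps``, the genotype likelihoods under
autozygosity (X = 1) and non-autozygosity (X = 0) are

====  ==============================  ===========
G     Pr(G | X = 1)                   Pr(G | X = 0)
====  ==============================  ===========
AA    (1 - eps) f_A + eps f_A^2       f_A^2
AB    2 eps f_A f_B                   2 f_A f_B
BB    (1 - eps) f_B + eps f_B^2       f_B^2
miss  1                               1
====  ==============================  ===========

so a heterozygote contributes ``log10(eps)`` and a missing genotype zero.
The quadratic term in the homozygote rows makes each column sum to one
over {AA, AB, BB} for every ``f_A`` and ``eps``.

The LOD score of a window is the plain sum of per-SNP log10 ratios; the
wLOD score multiplies each SNP's ratio by three weights before summation:
an LD redundancy weight ``1 / sum_l r2(k,l)`` (window-relative, bounded in
[1/K, 1]), and the probabilities of no recombination
``exp(-2 M (g_k - g_{k-1}))`` and no mutation
``exp(-2 M mu (p_k - p_{k-1}))`` in the gap to the preceding genotyped SNP
on the chromosome.  The first SNP of a chromosome has gap weights 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .data_io import GeneticMap, GenotypePanel, HET, HOM_REF, HOM_ALT, MISSING
from .popgen_stats import BandedR2, FrequencyTable

logger = logging.getLogger(__name__)


@dataclass
class ModelParams:
    """Tunable parameters of the wLOD model.

    epsilon : combined genotyping-error and mutation rate, in (0, 1)
    mu : per-base per-generation mutation rate
    m_generations : expected minimum meioses to the MRCA of the two
        haplotypes (tunes the recombination/mutation gap weights)
    window_k : window size in SNPs
    slide_step : window advance in SNPs (1; each SNP sits in K windows)
    """

    epsilon: float = 4.71e-4
    mu: float = 1.18e-8
    m_generations: float = 7.0
    window_k: int = 100
    slide_step: int = 1

    def __post_init__(self):
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError("epsilon must be in (0,1)")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.m_generations < 1:
            raise ValueError("m_generations must be >= 1")
        if self.window_k < 2:
            raise ValueError("window_k must be >= 2")
        if self.slide_step != 1:
            raise ValueError("only slide_step=1 is supported")


@dataclass
class WindowScoreMatrix:
    """Per-window, per-individual scores with window -> SNP provenance.

    ``scores[chrom]`` has shape ``(n_windows, n_individuals)``; window
    ``s`` spans SNP indices ``[s, s + K)`` of ``positions[chrom]``.
    """

    window_k: int
    scores: dict[str, np.ndarray]
    positions: dict[str, np.ndarray]
    individual_ids: list[str]
    kind: str = "wlod"
    gpos: dict[str, np.ndarray] | None = None
    slide_step: int = 1

    @property
    def chroms(self) -> list[str]:
        return list(self.scores)

    def n_windows(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return self.scores[chrom].shape[0]
        return sum(m.shape[0] for m in self.scores.values())

    def window_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(first bp, last bp) of each window on ``chrom``."""
        pos = self.positions[chrom]
        nw = self.scores[chrom].shape[0]
        return pos[:nw], pos[self.window_k - 1:self.window_k - 1 + nw]

    def pooled(self, individuals: np.ndarray | None = None) -> np.ndarray:
        parts = []
        for m in self.scores.values():
            parts.append(m if individuals is None else m[:, individuals])
        return np.concatenate([p.ravel() for p in parts])


# ---------------------------------------------------------------------------
# per-SNP terms
# ---------------------------------------------------------------------------

def genotype_llr(genotype: int, f_a: float, epsilon: float) -> float:
    """log10 Pr(G|X=1)/Pr(G|X=0) for one genotype (scalar reference form).

    Carriers of an allele with frequency 0 (the zero-frequency resampling
    rule) and missing genotypes return 0.
    """
    if genotype == MISSING or not np.isfinite(f_a):
        return 0.0
    f_b = 1.0 - f_a
    if genotype == HET:
        if f_a <= 0.0 or f_b <= 0.0:
            return 0.0
        return float(np.log10(epsilon))
    if genotype == HOM_REF:
        if f_a <= 0.0:
            return 0.0
        return float(np.log10((1.0 - epsilon) / f_a + epsilon))
    if genotype == HOM_ALT:
        if f_b <= 0.0:
            return 0.0
        return float(np.log10((1.0 - epsilon) / f_b + epsilon))
    raise ValueError(f"invalid genotype code {genotype}")


def site_llr_matrix(panel: GenotypePanel, chrom: str, freqs: FrequencyTable,
                    params: ModelParams) -> np.ndarray:
    """Vectorised ``(S, N)`` matrix of per-genotype log10 likelihood ratios.

    Uses the per-genotype error matrix when the panel carries one, else the
    global ``params.epsilon``.  Sites flagged by the zero-frequency rule
    contribute 0 for carriers of the zero-frequency allele; sites with
    unavailable frequency contribute 0 for everyone.
    """
    g = panel.genotypes[chrom]
    f = freqs.f_ref[chrom][:, None]
    if panel.per_genotype_error is not None:
        eps = panel.per_genotype_error[chrom]
        eps = np.where(np.isfinite(eps), eps, params.epsilon)
    else:
        eps = np.full((1, 1), params.epsilon)
    out = np.zeros(g.shape, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        ref_term = np.log10((1.0 - eps) / f + eps)
        alt_term = np.log10((1.0 - eps) / (1.0 - f) + eps)
        het_term = np.log10(eps) * np.ones_like(f)
    np.copyto(out, np.broadcast_to(ref_term, g.shape), where=(g == HOM_REF))
    np.copyto(out, np.broadcast_to(alt_term, g.shape), where=(g == HOM_ALT))
    np.copyto(out, np.broadcast_to(het_term, g.shape), where=(g == HET))
    # zero-frequency / unavailable-frequency rules
    carries_ref = (g == HOM_REF) | (g == HET)
    carries_alt = (g == HOM_ALT) | (g == HET)
    ref_dead = (freqs.ref_zero[chrom] | (freqs.f_ref[chrom] <= 0.0))[:, None]
    alt_dead = (freqs.alt_zero[chrom] | (freqs.f_ref[chrom] >= 1.0))[:, None]
    out[carries_ref & ref_dead] = 0.0
    out[carries_alt & alt_dead] = 0.0
    out[:, :][~np.isfinite(freqs.f_ref[chrom])[:, None] & np.ones_like(g, bool)] = 0.0
    out[g == MISSING] = 0.0
    out[~np.isfinite(out)] = 0.0
    return out


def recomb_weight(g_prev, g_k, m_generations):
    """Pr(no recombination in [g_prev, g_k]) = exp(-2 M (g_k - g_prev))."""
    dg = np.asarray(g_k, dtype=np.float64) - np.asarray(g_prev, dtype=np.float64)
    if np.any(dg < -1e-12):
        raise ValueError("g_k must be >= g_prev")
    return np.exp(-2.0 * m_generations * np.maximum(dg, 0.0))


def mutation_weight(p_prev, p_k, mu, m_generations):
    """Pr(no mutation in [p_prev, p_k]) = exp(-2 M mu (p_k - p_prev))."""
    dp = np.asarray(p_k, dtype=np.float64) - np.asarray(p_prev, dtype=np.float64)
    return np.exp(-2.0 * m_generations * mu * np.maximum(dp, 0.0))


def gap_weights(positions: np.ndarray, gpos: np.ndarray,
                params: ModelParams) -> np.ndarray:
    """Per-site recombination x mutation gap weights along one chromosome.

    Site k is weighted by the gap to the preceding genotyped site
    (window-independent); the first site has weight 1.
    """
    w = np.ones(len(positions), dtype=np.float64)
    if len(positions) > 1:
        rw = recomb_weight(gpos[:-1], gpos[1:], params.m_generations)
        mw = mutation_weight(positions[:-1], positions[1:], params.mu,
                             params.m_generations)
        w[1:] = rw * mw
    return w


# ---------------------------------------------------------------------------
# window scans
# ---------------------------------------------------------------------------

def _sliding_sums(a: np.ndarray, K: int) -> np.ndarray:
    cs = np.vstack([np.zeros((1, a.shape[1])), np.cumsum(a, axis=0)])
    return cs[K:] - cs[:-K]


def scan_lod(panel: GenotypePanel, freqs: FrequencyTable,
             params: ModelParams) -> WindowScoreMatrix:
    """Unweighted LOD scan: windowed sums of per-SNP log10 ratios."""
    scores, positions = {}, {}
    K = params.window_k
    for chrom in panel.chroms:
        S = len(panel.positions[chrom])
        if S < K:
            logger.info("chromosome %s has %d < K=%d SNPs; no windows", chrom, S, K)
            continue
        llr = site_llr_matrix(panel, chrom, freqs, params)
        scores[chrom] = _sliding_sums(llr, K)
        positions[chrom] = panel.positions[chrom]
    return WindowScoreMatrix(K, scores, positions, list(panel.individual_ids),
                             kind="lod")


@njit(cache=False)
def _wlod_kernel(a, band, K):  # pragma: no cover - exercised via scan_wlod
    S, N = a.shape
    nw = S - K + 1
    out = np.zeros((nw, N))
    denom = np.empty(K)
    kmin = 1.0 / K
    for j in range(K):
        t = 1.0
        for l in range(K):
            if l < j:
                t += band[l, j - l - 1]
            elif l > j:
                t += band[j, l - j - 1]
        denom[j] = t
    for s in range(nw):
        if s > 0:
            for j in range(K - 1):
                k = s + j
                denom[j] = denom[j + 1] - band[s - 1, k - s] + band[k, s + K - 2 - k]
            k2 = s + K - 1
            t = 1.0
            for l in range(s, k2):
                t += band[l, k2 - l - 1]
            denom[K - 1] = t
        for j in range(K):
            w = 1.0 / denom[j]
            if w < kmin:
                w = kmin
            elif w > 1.0:
                w = 1.0
            k = s + j
            for i in range(N):
                out[s, i] += a[k, i] * w
    return out


def scan_wlod(panel: GenotypePanel, freqs: FrequencyTable, ld: BandedR2,
              gmap: GeneticMap, params: ModelParams) -> WindowScoreMatrix:
    """Weighted LOD scan over all sliding windows of ``params.window_k`` SNPs.

    Each SNP's log10 ratio (positive or negative, including the log10(eps)
    heterozygote penalty) is multiplied by its LD, recombination and
    mutation weights before summation.  Windows never span chromosomes;
    chromosomes with fewer than K SNPs produce no windows.
    """
    K = params.window_k
    scores, positions, gpos_out = {}, {}, {}
    for chrom in panel.chroms:
        S = len(panel.positions[chrom])
        if S < K:
            logger.info("chromosome %s has %d < K=%d SNPs; no windows", chrom, S, K)
            continue
        if ld.bandwidth < K - 1:
            raise ValueError(
                f"banded r2 store bandwidth {ld.bandwidth} < K-1 = {K - 1}")
        pos = panel.positions[chrom]
        gpos = gmap.interpolate(chrom, pos)
        llr = site_llr_matrix(panel, chrom, freqs, params)
        a = llr * gap_weights(pos, gpos, params)[:, None]
        scores[chrom] = _wlod_kernel(np.ascontiguousarray(a),
                                     np.ascontiguousarray(ld.band[chrom]), K)
        positions[chrom] = pos
        gpos_out[chrom] = gpos
    return WindowScoreMatrix(K, scores, positions, list(panel.individual_ids),
                             kind="wlod", gpos=gpos_out)
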