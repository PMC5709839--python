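"""Population-level inputs to the wLOD estimator.

Allele frequencies are estimated with a resampling scheme (100 alleles
drawn with replacement per site) so that frequency resolution is uniform
across populations of different sample sizes.  Pairwise linkage
disequilibrium (r^2) is likewise estimated from a fixed-size subsample of
individuals, and stored in a banded structure covering only site pairs
that can co-occur in a window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import GenotypePanel, HET, HOM_REF, HOM_ALT, MISSING

logger = logging.getLogger(__name__)


@dataclass
class FrequencyTable:
    """Resampled reference-allele frequencies per site.

    ``f_ref`` holds the frequency of the reference (A) allele; the
    alternate (B) frequency is its complement.  ``ref_zero``/``alt_zero``
    flag sites where an allele observed in the population sample received
    a resampled count of zero; carriers of a flagged allele are treated as
    missing by the likelihood engine.  NaN marks sites with no genotyped
    individual.
    """

    f_ref: dict[str, np.ndarray]
    ref_zero: dict[str, np.ndarray]
    alt_zero: dict[str, np.ndarray]
    resample_size: int
    seed: int

    def f_alt(self, chrom: str) -> np.ndarray:
        return 1.0 - self.f_ref[chrom]


def estimate_allele_freqs_resampled(panel: GenotypePanel,
                                    population: str | None = None,
                                    resample_size: int = 100,
                                    seed: int = 0) -> FrequencyTable:
    """Estimate per-site allele frequencies from ``resample_size`` alleles.

    Drawing ``resample_size`` alleles with replacement from the observed
    (non-missing) alleles is equivalent to a binomial draw at the observed
    frequency, which is how it is implemented.  Frequencies are therefore
    exact multiples of ``1/resample_size`` and deterministic given the seed.
    """
    if resample_size < 1:
        raise ValueError("resample_size must be >= 1")
    rng = np.random.default_rng(seed)
    idx = panel.individuals_of_population(population)
    f_ref, ref_zero, alt_zero = {}, {}, {}
    for chrom in panel.chroms:
        g = panel.genotypes[chrom][:, idx]
        n_hom_ref = (g == HOM_REF).sum(axis=1)
        n_het = (g == HET).sum(axis=1)
        n_hom_alt = (g == HOM_ALT).sum(axis=1)
        ref_count = 2 * n_hom_ref + n_het
        alt_count = 2 * n_hom_alt + n_het
        total = ref_count + alt_count
        with np.errstate(invalid="ignore", divide="ignore"):
            f_obs = np.where(total > 0, ref_count / np.maximum(total, 1), np.nan)
        counts = rng.binomial(resample_size, np.nan_to_num(f_obs))
        f = counts / float(resample_size)
        f = np.where(total > 0, f, np.nan)
        f_ref[chrom] = f
        ref_zero[chrom] = (ref_count > 0) & (counts == 0) & (total > 0)
        alt_zero[chrom] = (alt_count > 0) & (counts == resample_size) & (total > 0)
    return FrequencyTable(f_ref, ref_zero, alt_zero, resample_size, seed)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either side is monomorphic."""
    x = x.astype(np.float64)
    y = y.astype(np.float64)
    xc = x - x.mean()
    yc = y - y.mean()
    vx = (xc * xc).sum()
    vy = (yc * yc).sum()
    if vx <= 0 or vy <= 0:
        return 0.0
    r = (xc * yc).sum() / np.sqrt(vx * vy)
    return float(r * r)


def _ld_matrix_for(panel: GenotypePanel, chrom: str, idx: np.ndarray) -> np.ndarray:
    """Site-by-carrier matrix used for LD: haplotype alleles when phase is
    available, genotype dosages (missing -> site mean) otherwise."""
    if panel.haplotypes is not None:
        cols = np.empty(2 * len(idx), dtype=np.int64)
        cols[0::2] = 2 * idx
        cols[1::2] = 2 * idx + 1
        return panel.haplotypes[chrom][:, cols].astype(np.float64)
    g = panel.genotypes[chrom][:, idx].astype(np.float64)
    g[g == MISSING] = np.nan
    n_obs = (~np.isnan(g)).sum(axis=1)
    means = np.where(n_obs > 0, np.nansum(g, axis=1) / np.maximum(n_obs, 1), 0.0)
    ii, jj = np.nonzero(np.isnan(g))
    g[ii, jj] = means[ii]
    return g


def estimate_r2_resampled(panel: GenotypePanel, chrom: str,
                          site_pair: tuple[int, int],
                          population: str | None = None,
                          resample_individuals: int = 55,
                          seed: int = 0) -> float:
    """Pairwise r^2 between two sites from a resampled individual subset.

    ``resample_individuals`` individuals are drawn without replacement
    (all individuals are used when the population is no larger than the
    subsample).  With phased data r^2 is the squared correlation of
    haplotype allele indicators; otherwise the squared genotype-dosage
    (composite LD) correlation.  If either site is monomorphic in the
    subsample, r^2 is defined as 0.
    """
    rng = np.random.default_rng(seed)
    idx = panel.individuals_of_population(population)
    if len(idx) > resample_individuals:
        idx = np.sort(rng.choice(idx, size=resample_individuals, replace=False))
    x = _ld_matrix_for(panel, chrom, idx)
    i, j = site_pair
    return _pair_r2(x[i], x[j])


@dataclass
class BandedR2:
    """Banded pairwise r^2 store: ``band[chrom][k, d-1]`` is r^2 between
    sites ``k`` and ``k+d`` (d = 1..bandwidth).  Only pairs that can share
    a window are stored; the full SxS matrix is never materialised."""

    band: dict[str, np.ndarray]
    bandwidth: int
    seed: int

    def block(self, chrom: str, start: int, K: int) -> np.ndarray:
        """Dense symmetric KxK r^2 block for window [start, start+K)."""
        if K - 1 > self.bandwidth:
            raise ValueError("window exceeds banded r2 bandwidth")
        b = self.band[chrom]
        out = np.eye(K)
        for j in range(K):
            for l in range(j + 1, K):
                out[j, l] = out[l, j] = b[start + j, l - j - 1]
        return out


def estimate_banded_r2(panel: GenotypePanel, bandwidth: int,
                       population: str | None = None,
                       resample_individuals: int = 55,
                       seed: int = 0,
                       per_pair_resampling: bool | None = None) -> BandedR2:
    """Estimate r^2 for all site pairs within ``bandwidth`` positions.

    When the population holds more individuals than
    ``resample_individuals`` and ``per_pair_resampling`` is enabled
    (the default in that situation), each pair receives its own
    without-replacement subsample; otherwise the computation is vectorised
    over all pairs at a given offset using every individual.
    """
    rng = np.random.default_rng(seed)
    idx_all = panel.individuals_of_population(population)
    resample = len(idx_all) > resample_individuals
    if per_pair_resampling is None:
        per_pair_resampling = resample
    band = {}
    for chrom in panel.chroms:
        x_full = _ld_matrix_for(panel, chrom, idx_all)
        S = x_full.shape[0]
        out = np.zeros((S, bandwidth), dtype=np.float64)
        for d in range(1, bandwidth + 1):
            if S - d <= 0:
                break
            a = x_full[:-d]
            b = x_full[d:]
            if resample and per_pair_resampling:
                n_pairs = S - d
                m = resample_individuals
                # per-pair column subsets; phase doubles the column count
                if panel.haplotypes is not None:
                    ind_pick = np.stack([
                        rng.choice(len(idx_all), size=m, replace=False)
                        for _ in range(n_pairs)], axis=1)
                    cols = np.empty((2 * m, n_pairs), dtype=np.int64)
                    cols[0::2] = 2 * ind_pick
                    cols[1::2] = 2 * ind_pick + 1
                else:
                    cols = np.stack([
                        rng.choice(len(idx_all), size=m, replace=False)
                        for _ in range(n_pairs)], axis=1)
                rows = np.arange(n_pairs)[None, :]
                a = a[rows, cols].T
                b = b[rows, cols].T
            ac = a - a.mean(axis=1, keepdims=True)
            bc = b - b.mean(axis=1, keepdims=True)
            va = (ac * ac).sum(axis=1)
            vb = (bc * bc).sum(axis=1)
            cov = (ac * bc).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where((va > 0) & (vb > 0),
                              (cov * cov) / np.maximum(va * vb, 1e-300), 0.0)
            out[:S - d, d - 1] = np.clip(r2, 0.0, 1.0)
        band[chrom] = out
    return BandedR2(band, bandwidth, seed)


def window_ld_weights(r2_block: np.ndarray) -> np.ndarray:
    """LD weights for one window: ``w_k = 1 / sum_l r2(k, l)``.

    ``r2_block`` must be symmetric with unit diagonal; the self-term in
    the denominator keeps every weight inside ``[1/K, 1]`` (clipped after
    floating-point evaluation).
    """
    r2_block = np.asarray(r2_block, dtype=np.float64)
    K = r2_block.shape[0]
    if r2_block.shape != (K, K):
        raise ValueError("r2 block must be square")
    if not np.allclose(r2_block, r2_block.T, atol=1e-8):
        raise ValueError("r2 block must be symmetric")
    if not np.allclose(np.diag(r2_block), 1.0, atol=1e-8):
        raise ValueError("r2 block diagonal must be 1")
    w = 1.0 / r2_block.sum(axis=1)
    return np.clip(w, 1.0 / K, 1.0)
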