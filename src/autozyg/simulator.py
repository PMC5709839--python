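"""Forward-time diploid simulator with true-autozygosity tracking.

A single chromosome is simulated under a non-uniform recombination map:
a backbone of sorted uniform genetic positions is laid down every Mb,
predetermined polymorphic SNVs receive genetic positions within their
backbone interval, and every remaining base pair maps onto the construct
by interpolation.  Each generation, offspring draw two distinct parents
uniformly; gametes recombine at Poisson crossovers (genetic positions
uniform on the map) and acquire Poisson de novo mutations at uniformly
chosen base pairs.  Haplotypes are tracked as mosaics of founder
haplotype copies, so true autozygous segments — where the maternal and
paternal chromosome descend from the same founder haplotype copy — are
read off exactly, with segment ends at crossover breakpoints.

Two demographic scenarios are preconfigured: (1) a small partially
isolated population (N_e = 75, 150 generations, one migrant per
generation) and (2) a medium closed population (N_e = 500, 100
generations).  Recombination and mutation rates are scaled (x10 by
default) during the simulation to boost diversity, mimicking a longer
history at the nominal rates; analyses of the output use the unscaled
map and mutation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GeneticMap, GenotypePanel

logger = logging.getLogger(__name__)

_SCENARIOS = {
    1: dict(n_predetermined=725_000, n_e=75, n_generations=150,
            migrants_per_generation=1),
    2: dict(n_predetermined=650_000, n_e=500, n_generations=100,
            migrants_per_generation=0),
}


@dataclass
class SimulationConfig:
    """Simulation parameters.

    Defaults reproduce the full-size study conditions: a 250 Mb
    chromosome (g_max = 3.25 Morgans at theta = 1.3 cM/Mb), mu =
    1.18e-8 per bp per generation, rates scaled x10 during the run,
    ~750k polymorphic SNVs, genotyping errors at 0.001, and 50 analysed
    individuals sampled from the final generation.  For desk-scale runs
    shrink ``g_max_morgans`` and ``n_predetermined`` proportionally —
    SNV density, inbreeding depth and map ruggedness are all preserved.
    """

    scenario: int = 1
    g_max_morgans: float = 3.25
    theta_cm_per_mb: float = 1.3
    mu: float = 1.18e-8
    rate_scale: float = 10.0
    n_predetermined: int | None = None
    n_e: int | None = None
    n_generations: int | None = None
    migrants_per_generation: int | None = None
    error_rate: float = 0.001
    sample_n: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in _SCENARIOS:
            raise ValueError("scenario must be 1 or 2")
        for key, val in _SCENARIOS[self.scenario].items():
            if getattr(self, key) is None:
                setattr(self, key, val)
        if min(self.g_max_morgans, self.theta_cm_per_mb, self.mu,
               self.rate_scale) <= 0:
            raise ValueError("rates and lengths must be positive")
        if self.scenario == 2 and self.migrants_per_generation:
            raise ValueError("scenario 2 is a closed population (no migrants)")
        if self.sample_n > self.n_e:
            raise ValueError("cannot sample more individuals than N_e")

    @property
    def chrom_length_bp(self) -> int:
        return int(round(self.g_max_morgans * 100.0 / self.theta_cm_per_mb)) * 1_000_000

    @property
    def n_megabases(self) -> int:
        return self.chrom_length_bp // 1_000_000


class _Hap:
    """A haplotype as a founder mosaic plus carried mutations.

    ``breaks`` are segment right edges (bp, last equals the chromosome
    length), ``ids`` the founder haplotype copy per segment, ``muts`` the
    sorted bp positions of carried de novo mutations.
    """

    __slots__ = ("breaks", "ids", "muts")

    def __init__(self, breaks, ids, muts):
        self.breaks = breaks
        self.ids = ids
        self.muts = muts


@dataclass
class PedigreeRecord:
    """Per-generation parentage and per-meiosis event counts.

    ``parents[t][i]`` are the two parent indices (generation t) of
    individual ``i`` in generation t+1; -1 marks a migrant founder.
    """

    parents: np.ndarray          # (G, N, 2) int32
    migrant: np.ndarray          # (G, N) bool
    crossover_counts: np.ndarray
    mutation_counts: np.ndarray

    def to_tsv(self, path) -> None:
        G, N, _ = self.parents.shape
        rows = [{"generation": t + 1, "individual": i,
                 "parent1": int(self.parents[t, i, 0]),
                 "parent2": int(self.parents[t, i, 1]),
                 "migrant": bool(self.migrant[t, i])}
                for t in range(G) for i in range(N)]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class TrueIBDSegmentSet:
    """True autozygous segments of the sampled individuals.

    ``df`` columns: individual, chrom, start_bp, end_bp, length_bp
    (half-open [start, end) intervals whose ends coincide with crossover
    breakpoints or chromosome ends).  ``mrca_depth`` holds the
    pedigree-derived number of generations to the parents' most recent
    common ancestor per sampled individual (NaN when none exists within
    the simulated pedigree).
    """

    df: pd.DataFrame
    mrca_depth: pd.DataFrame

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.df.itertuples():
                fh.write(f"{row.chrom}\t{row.start_bp}\t{row.end_bp}\t"
                         f"{row.individual}\n")


@dataclass
class SimulationResult:
    panel: GenotypePanel
    gmap: GeneticMap
    truth: TrueIBDSegmentSet
    pedigree: PedigreeRecord
    config: SimulationConfig
    n_error_flips: int = 0

    @property
    def de_novo_mask(self) -> np.ndarray:
        return self.panel.site_flags["1"]["de_novo"]

    def de_novo_fraction(self) -> float:
        m = self.de_novo_mask
        return float(m.mean()) if len(m) else np.nan

    def maf_below(self, cutoff: float = 0.05) -> float:
        """Fraction of polymorphic sites with minor allele frequency below
        ``cutoff`` among the sampled individuals."""
        g = self.panel.genotypes["1"].astype(np.int64)
        alt = (g * (g > 0)).sum(axis=1)  # MISSING is absent in simulator output
        f = alt / (2.0 * self.panel.n_individuals)
        maf = np.minimum(f, 1.0 - f)
        return float((maf < cutoff).mean()) if len(maf) else np.nan


# ---------------------------------------------------------------------------
# map construction
# ---------------------------------------------------------------------------

def build_map_backbone(config: SimulationConfig, rng=None):
    """Build the non-uniform genetic map and predetermined SNV positions.

    Returns ``(map_bp, map_g, snv_bp, snv_g)`` where the map arrays merge
    the Mb backbone with the predetermined SNV nodes (so interpolating a
    predetermined SNV recovers its assigned genetic position exactly).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.chrom_length_bp
    n_mb = config.n_megabases
    g_max = config.g_max_morgans
    bb_bp = np.concatenate([[1], (np.arange(1, n_mb + 1) * 1_000_000)]).astype(np.int64)
    interior = np.sort(rng.uniform(0.0, g_max, size=max(n_mb - 1, 0)))
    bb_g = np.concatenate([[0.0], interior, [g_max]])

    n = config.n_predetermined
    snv_bp = _distinct_positions(rng, n, L, forbid=set(bb_bp.tolist()))
    snv_bp.sort()
    # assign genetic positions within each backbone interval, kept sorted
    snv_g = np.empty(n, dtype=np.float64)
    iv = np.searchsorted(bb_bp, snv_bp, side="right") - 1
    iv = np.clip(iv, 0, n_mb - 1)
    for t in np.unique(iv):
        sel = iv == t
        snv_g[sel] = np.sort(rng.uniform(bb_g[t], bb_g[t + 1], size=sel.sum()))

    map_bp = np.concatenate([bb_bp, snv_bp])
    map_g = np.concatenate([bb_g, snv_g])
    order = np.argsort(map_bp)
    return map_bp[order], np.maximum.accumulate(map_g[order]), snv_bp, snv_g


def _distinct_positions(rng, n, L, forbid=None):
    """n distinct integers in [1, L], avoiding ``forbid``."""
    forbid = forbid or set()
    out: list[int] = []
    seen = set(forbid)
    while len(out) < n:
        cand = rng.integers(1, L + 1, size=n - len(out))
        for c in cand.tolist():
            if c not in seen:
                seen.add(c)
                out.append(c)
    return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _make_gamete(hap_a: _Hap, hap_b: _Hap, L, map_bp, map_g, g_max,
                 xover_mean, mut_mean, rng, used_positions):
    n_x = rng.poisson(xover_mean)
    xg = np.sort(rng.uniform(0.0, g_max, size=n_x))
    xbp = np.unique(np.clip(np.rint(np.interp(xg, map_g, map_bp)), 1, L - 1)
                    .astype(np.int64))
    start = int(rng.integers(2))
    srcs = (hap_a, hap_b)

    if len(xbp) == 0:
        src = srcs[start]
        breaks, ids = src.breaks.copy(), src.ids.copy()
        inherited = src.muts.copy()
    else:
        bounds = np.concatenate([[0], xbp, [L]])
        pieces_b, pieces_i = [], []
        for t in range(len(bounds) - 1):
            lo, hi = bounds[t], bounds[t + 1]
            src = srcs[(start + t) % 2]
            j0 = np.searchsorted(src.breaks, lo, side="right")
            j1 = np.searchsorted(src.breaks, hi, side="left")
            pieces_b.append(np.concatenate([src.breaks[j0:j1], [hi]]))
            pieces_i.append(src.ids[j0:j1 + 1])
        breaks = np.concatenate(pieces_b).astype(np.int64)
        ids = np.concatenate(pieces_i)
        keep = np.empty(len(ids), dtype=bool)
        keep[-1] = True
        keep[:-1] = ids[1:] != ids[:-1]
        breaks, ids = breaks[keep], ids[keep]
        par_a = (start + np.searchsorted(xbp, hap_a.muts, side="left")) % 2 == 0
        par_b = (start + np.searchsorted(xbp, hap_b.muts, side="left")) % 2 == 1
        inherited = np.union1d(hap_a.muts[par_a], hap_b.muts[par_b])

    n_new = rng.poisson(mut_mean)
    if n_new:
        new = _distinct_positions(rng, n_new, L, forbid=used_positions)
        used_positions.update(new.tolist())
        muts = np.union1d(inherited, new)
    else:
        muts = inherited
    return _Hap(breaks, ids, muts), len(xbp), n_new


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def run_forward(config: SimulationConfig) -> SimulationResult:
    """Run the forward simulation and build the analysed dataset.

    Returns the genotype panel of ``sample_n`` final-generation
    individuals at all polymorphic sites (predetermined plus de novo,
    monomorphic sites removed), the genetic map, the true autozygous
    segments and the pedigree record.  Genotyping errors are *not* yet
    injected (see :func:`inject_errors`).
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length_bp
    g_max = config.g_max_morgans
    map_bp, map_g, snv_bp, snv_g = build_map_backbone(config, rng)
    n_pre = config.n_predetermined
    founder_freq = rng.uniform(0.05, 0.95, size=n_pre)

    founder_rows: list[np.ndarray] = []

    def new_founder_hap() -> int:
        founder_rows.append((rng.random(n_pre) < founder_freq).astype(np.int8))
        return len(founder_rows) - 1

    n_e, n_gen = config.n_e, config.n_generations
    full = np.array([L], dtype=np.int64)
    empty = np.empty(0, dtype=np.int64)
    pop = []
    for _ in range(n_e):
        pop.append((_Hap(full.copy(), np.array([new_founder_hap()]), empty),
                    _Hap(full.copy(), np.array([new_founder_hap()]), empty)))

    xover_mean = g_max * config.rate_scale
    mut_mean = config.mu * config.rate_scale * L
    used_positions: set[int] = set(snv_bp.tolist())

    parents = np.zeros((n_gen, n_e, 2), dtype=np.int32)
    migrant = np.zeros((n_gen, n_e), dtype=bool)
    xover_counts, mut_counts = [], []

    for t in range(n_gen):
        nxt = []
        for i in range(n_e):
            p1 = int(rng.integers(n_e))
            p2 = int(rng.integers(n_e - 1))
            if p2 >= p1:
                p2 += 1  # selfing excluded
            parents[t, i] = (p1, p2)
            g1, nx1, nm1 = _make_gamete(*pop[p1], L, map_bp, map_g, g_max,
                                        xover_mean, mut_mean, rng, used_positions)
            g2, nx2, nm2 = _make_gamete(*pop[p2], L, map_bp, map_g, g_max,
                                        xover_mean, mut_mean, rng, used_positions)
            xover_counts += [nx1, nx2]
            mut_counts += [nm1, nm2]
            nxt.append((g1, g2))
        if config.migrants_per_generation:
            for _ in range(config.migrants_per_generation):
                j = int(rng.integers(n_e))
                nxt[j] = (_Hap(full.copy(), np.array([new_founder_hap()]), empty),
                          _Hap(full.copy(), np.array([new_founder_hap()]), empty))
                parents[t, j] = (-1, -1)
                migrant[t, j] = True
        pop = nxt

    sampled = np.sort(rng.choice(n_e, size=config.sample_n, replace=False))
    founder = np.vstack(founder_rows)

    panel, de_novo_mask = _build_panel(config, pop, sampled, snv_bp, snv_g,
                                       founder)
    gmap = GeneticMap({"1": (map_bp, map_g)})
    truth = _true_segments(pop, sampled, panel.individual_ids, L)
    pedigree = PedigreeRecord(parents, migrant,
                              np.asarray(xover_counts), np.asarray(mut_counts))
    truth.mrca_depth = _mrca_depths(pedigree, sampled, panel.individual_ids)
    return SimulationResult(panel, gmap, truth, pedigree, config)


def _build_panel(config, pop, sampled, snv_bp, snv_g, founder):
    n = len(sampled)
    haps = [h for i in sampled for h in pop[i]]
    mut_union = np.unique(np.concatenate([h.muts for h in haps])) \
        if any(len(h.muts) for h in haps) else np.empty(0, dtype=np.int64)

    n_pre, n_mut = len(snv_bp), len(mut_union)
    alleles = np.empty((n_pre + n_mut, 2 * n), dtype=np.int8)
    for c, h in enumerate(haps):
        lo = 0
        for breaks_end, fid in zip(h.breaks, h.ids):
            hi = np.searchsorted(snv_bp, breaks_end, side="right")
            alleles[lo:hi, c] = founder[fid, lo:hi]
            lo = hi
        if n_mut:
            carried = np.zeros(n_mut, dtype=np.int8)
            j = np.searchsorted(mut_union, h.muts)
            carried[j] = 1
            alleles[n_pre:, c] = carried

    pos = np.concatenate([snv_bp, mut_union])
    de_novo = np.concatenate([np.zeros(n_pre, bool), np.ones(n_mut, bool)])
    order = np.argsort(pos)
    pos, de_novo, alleles = pos[order], de_novo[order], alleles[order]

    geno = (alleles[:, 0::2] + alleles[:, 1::2]).astype(np.int8)
    poly = ~((geno == 0).all(axis=1) | (geno == 2).all(axis=1))
    pos, de_novo = pos[poly], de_novo[poly]
    geno, alleles = geno[poly], alleles[poly]

    ids = [f"sim{i:03d}" for i in range(n)]
    panel = GenotypePanel(ids, {"1": pos}, {"1": geno},
                          haplotypes={"1": alleles},
                          site_flags={"1": {"de_novo": de_novo}})
    return panel, de_novo


def _true_segments(pop, sampled, ids, L) -> TrueIBDSegmentSet:
    rows = []
    for name, i in zip(ids, sampled):
        ha, hb = pop[i]
        allb = np.union1d(ha.breaks, hb.breaks)
        ia = ha.ids[np.searchsorted(ha.breaks, allb, side="left")]
        ib = hb.ids[np.searchsorted(hb.breaks, allb, side="left")]
        eq = ia == ib
        if not eq.any():
            continue
        lefts = np.concatenate([[0], allb[:-1]])
        starts, ends = [], []
        for k in range(len(allb)):
            if eq[k]:
                if starts and ends[-1] == lefts[k]:
                    ends[-1] = allb[k]
                else:
                    starts.append(lefts[k])
                    ends.append(allb[k])
        for s, e in zip(starts, ends):
            rows.append({"individual": name, "chrom": "1",
                         "start_bp": int(s), "end_bp": int(e),
                         "length_bp": int(e - s)})
    df = pd.DataFrame(rows, columns=["individual", "chrom", "start_bp",
                                     "end_bp", "length_bp"])
    return TrueIBDSegmentSet(df, pd.DataFrame())


def _mrca_depths(pedigree: PedigreeRecord, sampled, ids) -> pd.DataFrame:
    """Generations back from the parents to their most recent common
    ancestor, found by breadth-first search up the recorded pedigree."""
    G = pedigree.parents.shape[0]
    rows = []
    for name, i in zip(ids, sampled):
        p1, p2 = pedigree.parents[G - 1, i]
        if p1 < 0:
            rows.append({"individual": name, "mrca_depth": np.nan})
            continue
        side_a, side_b = {int(p1)}, {int(p2)}
        depth = np.nan
        for d in range(1, G):
            t = G - 1 - d  # parent generation index into parents[t]
            if t < 0:
                break
            side_a = {int(q) for m in side_a for q in pedigree.parents[t, m]
                      if q >= 0}
            side_b = {int(q) for m in side_b for q in pedigree.parents[t, m]
                      if q >= 0}
            if side_a & side_b:
                depth = d
                break
            if not side_a or not side_b:
                break
        rows.append({"individual": name, "mrca_depth": depth})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def inject_errors(panel: GenotypePanel, rate: float = 0.001,
                  seed: int = 0) -> tuple[GenotypePanel, int]:
    """Flip each non-missing genotype to a uniformly chosen different
    state with probability ``rate``.  Returns the new panel and the flip
    count."""
    rng = np.random.default_rng(seed)
    out = panel.subset_sites(panel.chroms[0], np.arange(len(panel.positions[panel.chroms[0]])))
    n_flips = 0
    for chrom in out.chroms:
        g = out.genotypes[chrom]
        flip = (rng.random(g.shape) < rate) & (g != -1)
        shift = rng.integers(1, 3, size=g.shape).astype(np.int8)
        g[flip] = (g[flip] + shift[flip]) % 3
        n_flips += int(flip.sum())
    return out, n_flips


def thin_to_density(panel: GenotypePanel, target_snv_count: int,
                    seed: int = 0) -> GenotypePanel:
    """Uniform random subsample (without replacement) of polymorphic sites
    down to ``target_snv_count``, order preserved."""
    chrom = panel.chroms[0]
    S = len(panel.positions[chrom])
    if target_snv_count >= S:
        return panel.subset_sites(chrom, np.arange(S))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(S, size=target_snv_count, replace=False))
    return panel.subset_sites(chrom, idx)
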