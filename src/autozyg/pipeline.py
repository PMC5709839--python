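"""End-to-end orchestration: ROA calling, simulation benchmarks, contrasts.

These functions tie the modules together the way the command-line
interface uses them, and are also the entry points for reproducing the
simulation benchmarks (power / false discovery of wLOD, LOD and the
naive counting baseline against simulated truth).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import score_modes
from .data_io import GeneticMap, GenotypePanel
from .diff_autozygosity import call_enriched_regions, permutation_null
from .popgen_stats import (estimate_allele_freqs_resampled,
                           estimate_banded_r2)
from .roa_caller import (ROASet, assemble_roa, classify_roa_gmm,
                         evaluate_against_truth, naive_count_roh,
                         optimal_parameter_search)
from .score_modes import pool_and_kde, rule_of_thumb
from .simulator import (SimulationConfig, SimulationResult, inject_errors,
                        run_forward, thin_to_density)
from .wlod_engine import ModelParams, scan_lod, scan_wlod

logger = logging.getLogger(__name__)

#: benchmark analysis grids (window size in SNPs, overlap fraction)
DEFAULT_K_GRID = (50, 70, 90, 110, 130)
DEFAULT_FRACTION_GRID = tuple(np.round(np.arange(0.0, 0.51, 0.05), 2))

#: thinned-density targets at the full 250 Mb chromosome scale
DENSITY_TARGETS = {"125k": 125_000, "80k": 80_000, "50k": 50_000,
                   "18k": 18_000}

#: pedigree-derived M used when analysing benchmark data
BENCHMARK_M = {1: 3.0, 2: 4.0}


def scaled_scenario_config(scenario: int, scale: float = 1.0,
                           seed: int = 0, **overrides) -> SimulationConfig:
    """Scenario config with chromosome length and SNV count scaled
    together (density-preserving)."""
    base = SimulationConfig(scenario=scenario, seed=seed)
    g_max = base.g_max_morgans * scale
    n_pre = int(round(base.n_predetermined * scale))
    kwargs = dict(scenario=scenario, g_max_morgans=g_max,
                  n_predetermined=n_pre, seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def simulate_benchmark_dataset(config: SimulationConfig) -> SimulationResult:
    """Forward simulation plus genotyping-error injection."""
    sim = run_forward(config)
    panel, n_flips = inject_errors(sim.panel, config.error_rate,
                                   seed=config.seed + 1)
    sim.panel = panel
    sim.n_error_flips = n_flips
    return sim


# ---------------------------------------------------------------------------
# single-panel analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    method: str
    window_k: int | None
    overlap_fraction: float | None
    threshold: float | None
    roas: ROASet | None
    surface: pd.DataFrame | None
    power: float
    power_gt_1mb: float
    false_discovery: float
    mean_ratio: float
    n_false_positive: int
    n_false_negative: int


def _threshold_of(sm, **kde_kwargs):
    try:
        summary = pool_and_kde(sm, **kde_kwargs)
    except ValueError:
        return None
    return summary.threshold


def analyze_against_truth(panel: GenotypePanel, gmap: GeneticMap, truth,
                          method: str = "wlod",
                          params: ModelParams | None = None,
                          k_grid=DEFAULT_K_GRID,
                          fraction_grid=DEFAULT_FRACTION_GRID,
                          fixed_k: int | None = None,
                          fixed_fraction: float | None = None,
                          freq_resample: int = 100,
                          ld_resample: int = 55,
                          seed: int = 0,
                          long_roa_bp: float = 1_000_000) -> AnalysisResult:
    """Call ROA with one method and score the calls against truth.

    With ``fixed_k``/``fixed_fraction`` unset, the optimal
    (window size, overlap fraction) pair is searched on the grid (the
    smallest pair with zero false-positive ROA and mean length ratio
    within 5% of one).  ``method`` is "wlod", "lod" or "naive".
    """
    params = params or ModelParams(epsilon=1e-3, m_generations=3.0)
    if method == "naive":
        roas = naive_count_roh(panel, gmap=gmap)
        rep = evaluate_against_truth(roas, truth)
        rep_long = evaluate_against_truth(roas, truth, min_true_length=long_roa_bp)
        return AnalysisResult("naive", 50, 0.0, None, roas, None, rep.power,
                              rep_long.power, rep.false_discovery,
                              rep.mean_ratio, rep.n_false_positive,
                              rep.n_false_negative)

    freqs = estimate_allele_freqs_resampled(panel, resample_size=freq_resample,
                                            seed=seed)
    band = None
    if method == "wlod":
        k_max = max(k_grid) if fixed_k is None else fixed_k
        band = estimate_banded_r2(panel, bandwidth=k_max - 1,
                                  resample_individuals=ld_resample, seed=seed)

    cache: dict[int, object] = {}

    def scan_fn(K: int):
        if K not in cache:
            p = ModelParams(epsilon=params.epsilon, mu=params.mu,
                            m_generations=params.m_generations, window_k=K)
            if method == "wlod":
                cache[K] = scan_wlod(panel, freqs, band, gmap, p)
            else:
                cache[K] = scan_lod(panel, freqs, p)
        return cache[K]

    surface = None
    if fixed_k is None or fixed_fraction is None:
        k_star, f_star, surface = optimal_parameter_search(
            scan_fn, truth, k_grid, fraction_grid, _threshold_of, gmap=gmap)
        if fixed_k is not None:
            k_star = fixed_k
        if fixed_fraction is not None:
            f_star = fixed_fraction
    else:
        k_star, f_star = fixed_k, fixed_fraction
    if k_star is None:
        return AnalysisResult(method, None, None, None, None, surface,
                              np.nan, np.nan, np.nan, np.nan, -1, -1)
    sm = scan_fn(int(k_star))
    thr = _threshold_of(sm)
    if thr is None:
        return AnalysisResult(method, int(k_star), f_star, None, None, surface,
                              np.nan, np.nan, np.nan, np.nan, -1, -1)
    roas = assemble_roa(sm, thr, float(f_star), gmap=gmap)
    rep = evaluate_against_truth(roas, truth)
    rep_long = evaluate_against_truth(roas, truth, min_true_length=long_roa_bp)
    return AnalysisResult(method, int(k_star), float(f_star), thr, roas,
                          surface, rep.power, rep_long.power,
                          rep.false_discovery, rep.mean_ratio,
                          rep.n_false_positive, rep.n_false_negative)


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------

def run_scenario_benchmark(scenario: int = 1, scale: float = 1.0,
                           n_replicates: int = 3,
                           densities=("125k", "80k", "50k", "18k"),
                           include_full: bool = True,
                           methods=("wlod",),
                           k_grid=DEFAULT_K_GRID,
                           fraction_grid=DEFAULT_FRACTION_GRID,
                           seed: int = 0) -> pd.DataFrame:
    """Replicates x densities x methods benchmark grid.

    Each replicate simulates the scenario (optionally scaled down in
    chromosome length at constant SNV density), injects genotyping
    errors, thins to each density target, calls ROA with each method at
    its per-replicate optimal parameters, and scores power / false
    discovery against the true autozygous segments.  Returns a tidy
    DataFrame with one row per (replicate, density, method).
    """
    rows = []
    for r in range(n_replicates):
        rep_seed = int(seed + 1000 * r)
        cfg = scaled_scenario_config(scenario, scale=scale, seed=rep_seed)
        sim = simulate_benchmark_dataset(cfg)
        params = ModelParams(epsilon=cfg.error_rate,
                             m_generations=BENCHMARK_M[scenario])
        mrca = float(np.nanmean(sim.truth.mrca_depth["mrca_depth"]))
        base_stats = dict(replicate=r, scenario=scenario,
                          n_snv=sim.panel.n_sites,
                          de_novo_pct=100 * sim.de_novo_fraction(),
                          maf_lt5_pct=100 * sim.maf_below(0.05),
                          mean_mrca_depth=mrca)

        density_panels = {}
        if include_full:
            density_panels["full"] = sim.panel
        for label in densities:
            target = int(round(DENSITY_TARGETS[label] * scale))
            density_panels[label] = thin_to_density(sim.panel, target,
                                                    seed=rep_seed + 7)
        for label, panel_d in density_panels.items():
            for method in methods:
                res = analyze_against_truth(panel_d, sim.gmap, sim.truth,
                                            method=method, params=params,
                                            k_grid=k_grid,
                                            fraction_grid=fraction_grid,
                                            seed=rep_seed + 13)
                rows.append({**base_stats, "density": label,
                             "n_snv_density": panel_d.n_sites,
                             "method": method, "K": res.window_k,
                             "fraction": res.overlap_fraction,
                             "threshold": res.threshold,
                             "power_pct": 100 * res.power,
                             "power_gt_1mb_pct": 100 * res.power_gt_1mb,
                             "fdr": res.false_discovery,
                             "mean_ratio": res.mean_ratio,
                             "fp_count": res.n_false_positive,
                             "fn_count": res.n_false_negative})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROA calling on real panels
# ---------------------------------------------------------------------------

def call_roas(panel: GenotypePanel, gmap: GeneticMap,
              params: ModelParams | None = None,
              window_k: int | None = None,
              overlap_fraction: float | None = None,
              threshold: float | None = None,
              population: str | None = None,
              classify: bool = True,
              candidate_g=range(1, 11),
              seed: int = 0):
    """Frequencies -> LD -> wLOD scan -> threshold -> assembly -> classes.

    When ``window_k``/``overlap_fraction`` are not given they come from
    the density rule of thumb; the threshold defaults to the KDE density
    minimum of the pooled score distribution.  Returns a dict with the
    ROASet and all intermediate summaries.
    """
    params = params or ModelParams()
    density = panel.n_sites / float(sum(
        p[-1] - p[0] + 1 for p in panel.positions.values() if len(p)))
    rot_k, rot_frac = rule_of_thumb(density)
    if window_k is None:
        window_k = rot_k
    if overlap_fraction is None:
        overlap_fraction = rot_frac
    params = ModelParams(epsilon=params.epsilon, mu=params.mu,
                         m_generations=params.m_generations,
                         window_k=int(window_k))
    freqs = estimate_allele_freqs_resampled(panel, population=population,
                                            seed=seed)
    band = estimate_banded_r2(panel, bandwidth=int(window_k) - 1,
                              population=population, seed=seed)
    sm = scan_wlod(panel, freqs, band, gmap, params)
    summary = pool_and_kde(sm)
    if threshold is None:
        threshold = summary.threshold
    if threshold is None:
        raise ValueError("pooled score distribution is unimodal; supply an "
                         "explicit threshold or change the window size")
    roas = assemble_roa(sm, threshold, overlap_fraction, gmap=gmap)
    fit = None
    if classify and len(roas):
        try:
            fit, roas = classify_roa_gmm(roas, candidate_g=candidate_g,
                                         seed=seed)
        except ValueError as exc:
            logger.info("classification skipped: %s", exc)
    return {"roas": roas, "scores": sm, "summary": summary,
            "threshold": threshold, "window_k": int(window_k),
            "overlap_fraction": float(overlap_fraction),
            "mixture_fit": fit, "density_snv_per_bp": density,
            "rule_of_thumb": (rot_k, rot_frac)}


def contrast_groups(panel: GenotypePanel, gmap: GeneticMap,
                    groups: dict[str, str],
                    params: ModelParams | None = None,
                    window_k: int | None = None,
                    k_grid=None, n_perm: int = 1000,
                    alpha: float = 0.05, seed: int = 0):
    """Window-wise group contrast with the max-statistic permutation null.

    The window size defaults to the intermodal-distance-maximising K over
    ``k_grid`` (contrast mode of window-size selection).
    """
    params = params or ModelParams()
    freqs = estimate_allele_freqs_resampled(panel, seed=seed)
    if window_k is None:
        if k_grid is None:
            raise ValueError("supply window_k or k_grid")
        band = estimate_banded_r2(panel, bandwidth=max(k_grid) - 1, seed=seed)
        window_k, table, _ = score_modes.select_window_size(
            panel, freqs, band, gmap, params, k_grid, mode="contrast")
        if window_k is None:
            raise ValueError("no window size gave a multimodal distribution")
    else:
        band = estimate_banded_r2(panel, bandwidth=int(window_k) - 1, seed=seed)
    p = ModelParams(epsilon=params.epsilon, mu=params.mu,
                    m_generations=params.m_generations, window_k=int(window_k))
    sm = scan_wlod(panel, freqs, band, gmap, p)
    result = permutation_null(sm, groups, n_perm=n_perm, seed=seed)
    regions = call_enriched_regions(result, alpha=alpha)
    return {"result": result, "regions": regions, "window_k": int(window_k),
            "scores": sm}
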