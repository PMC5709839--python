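import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autozyg.data_io import GeneticMap, GenotypePanel, HET, HOM_ALT, HOM_REF, MISSING
from autozyg.popgen_stats import (estimate_allele_freqs_resampled,
                                  estimate_banded_r2)
from autozyg.wlod_engine import (ModelParams, gap_weights, genotype_llr,
                                 mutation_weight, recomb_weight, scan_lod,
                                 scan_wlod, site_llr_matrix)


class TestGenotypeLikelihoods:
    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(f=st.floats(0.0, 1.0), eps=st.floats(1e-8, 1 - 1e-8))
    def test_likelihood_normalisation(self, f, eps):
        """Pr over {AA, AB, BB} sums to 1 under both hypotheses."""
        fb = 1.0 - f
        auto = (1 - eps) * f + eps * f ** 2 + 2 * eps * f * fb \
            + (1 - eps) * fb + eps * fb ** 2
        non = f ** 2 + 2 * f * fb + fb ** 2
        assert auto == pytest.approx(1.0, abs=1e-12)
        assert non == pytest.approx(1.0, abs=1e-12)

    def test_heterozygote_penalty_is_log_epsilon(self):
        for f in (0.1, 0.5, 0.9):
            assert genotype_llr(HET, f, 1e-3) == pytest.approx(-3.0)

    def test_missing_genotype_zero(self):
        assert genotype_llr(MISSING, 0.5, 1e-3) == 0.0

    def test_homozygote_direct_value(self):
        # AA with f_A = 0.5, eps -> 0: log10(0.5 / 0.25)
        assert genotype_llr(HOM_REF, 0.5, 1e-12) == pytest.approx(
            np.log10(2.0), abs=1e-6)

    def test_fixed_allele_zero(self):
        assert genotype_llr(HOM_REF, 1.0, 1e-3) == pytest.approx(0.0)

    def test_zero_frequency_carrier_treated_missing(self):
        assert genotype_llr(HOM_ALT, 1.0, 1e-3) == 0.0
        assert genotype_llr(HET, 1.0, 1e-3) == 0.0
        assert genotype_llr(HET, 0.0, 1e-3) == 0.0


class TestGapWeights:
    def test_zero_distance_unity(self):
        assert recomb_weight(0.1, 0.1, 7) == pytest.approx(1.0)
        assert mutation_weight(100, 100, 1.18e-8, 7) == pytest.approx(1.0)

    def test_half_weight_closed_form(self):
        # M = 7, delta g = ln2 / 14 Morgan halves the weight
        assert recomb_weight(0.0, np.log(2) / 14, 7) == pytest.approx(0.5)

    def test_mutation_weight_first_order(self):
        w = mutation_weight(0, 1, 1.18e-8, 7)
        assert w == pytest.approx(1 - 2 * 7 * 1.18e-8, rel=1e-6)

    def test_monotone_decreasing(self):
        assert recomb_weight(0, 0.02, 7) < recomb_weight(0, 0.01, 7)
        assert recomb_weight(0, 0.01, 9) < recomb_weight(0, 0.01, 7)
        w1 = recomb_weight(0, 0.01, 7) * mutation_weight(0, 1e6, 1.18e-8, 7)
        w2 = recomb_weight(0, 0.01, 7) * mutation_weight(0, 2e6, 1.18e-8, 7)
        assert w2 < w1

    def test_first_site_has_unit_weight(self, toy_panel, toy_map):
        params = ModelParams(epsilon=1e-3, window_k=5)
        pos = toy_panel.positions["1"]
        w = gap_weights(pos, toy_map.interpolate("1", pos), params)
        assert w[0] == 1.0 and np.all(w[1:] < 1.0)


def _brute_wlod(panel, freqs, band, gmap, params):
    """Independent direct evaluation of the weighted window score."""
    K = params.window_k
    pos = panel.positions["1"]
    g = panel.genotypes["1"]
    gpos = gmap.interpolate("1", pos)
    f = freqs.f_ref["1"]
    S, N = g.shape
    out = np.zeros((S - K + 1, N))

    def r2(i, j):
        if i == j:
            return 1.0
        i, j = min(i, j), max(i, j)
        return band.band["1"][i, j - i - 1]

    for s in range(S - K + 1):
        for j in range(K):
            k = s + j
            denom = sum(r2(k, l) for l in range(s, s + K))
            w = min(max(1.0 / denom, 1.0 / K), 1.0)
            if k > 0:
                w *= np.exp(-2 * params.m_generations * (gpos[k] - gpos[k - 1]))
                w *= np.exp(-2 * params.m_generations * params.mu
                            * (pos[k] - pos[k - 1]))
            for i in range(N):
                ll = genotype_llr(int(g[k, i]), f[k], params.epsilon)
                if freqs.ref_zero["1"][k] and g[k, i] in (HOM_REF, HET):
                    ll = 0.0
                if freqs.alt_zero["1"][k] and g[k, i] in (HOM_ALT, HET):
                    ll = 0.0
                out[s, i] += ll * w
    return out


class TestScans:
    def test_wlod_matches_brute_force(self, toy_panel, toy_map):
        freqs = estimate_allele_freqs_resampled(toy_panel, seed=3)
        band = estimate_banded_r2(toy_panel, bandwidth=6, seed=4)
        params = ModelParams(epsilon=1e-3, m_generations=3, window_k=7)
        sm = scan_wlod(toy_panel, freqs, band, toy_map, params)
        brute = _brute_wlod(toy_panel, freqs, band, toy_map, params)
        np.testing.assert_allclose(sm.scores["1"], brute, atol=1e-10)

    def test_wlod_equals_lod_under_unit_weights(self, toy_panel):
        freqs = estimate_allele_freqs_resampled(toy_panel, seed=3)
        band = estimate_banded_r2(toy_panel, bandwidth=6, seed=4)
        for c in band.band:
            band.band[c][:] = 0.0
        flat_map = GeneticMap({"1": (np.array([1, 10_000_000]),
                                     np.array([0.0, 0.0]))})
        params = ModelParams(epsilon=1e-3, mu=1e-30, m_generations=1,
                             window_k=7)
        sw = scan_wlod(toy_panel, freqs, band, flat_map, params)
        sl = scan_lod(toy_panel, freqs, params)
        np.testing.assert_allclose(sw.scores["1"], sl.scores["1"], atol=1e-12)

    def test_duplicated_snp_pair_contributes_half(self, toy_map):
        # 5-SNP window where sites 1 and 2 are perfect copies: each gets
        # LD weight 1/2 and together they contribute one site's worth
        hap = np.zeros((5, 8), dtype=np.int8)
        hap[1] = hap[2] = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=np.int8)
        geno = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
        pos = np.array([10, 20, 30, 40, 50], dtype=np.int64)
        panel = GenotypePanel([f"i{j}" for j in range(4)], {"1": pos},
                              {"1": geno}, haplotypes={"1": hap})
        freqs = estimate_allele_freqs_resampled(panel, seed=0)
        band = estimate_banded_r2(panel, bandwidth=4, seed=0)
        flat_map = GeneticMap({"1": (np.array([1, 100]), np.array([0.0, 0.0]))})
        params = ModelParams(epsilon=1e-3, mu=1e-30, m_generations=1,
                             window_k=5)
        sm = scan_wlod(panel, freqs, band, flat_map, params)
        brute = _brute_wlod(panel, freqs, band, flat_map, params)
        np.testing.assert_allclose(sm.scores["1"], brute, atol=1e-10)
        # the duplicated pair's weights are exactly 1/2
        from autozyg.popgen_stats import window_ld_weights
        w = window_ld_weights(band.block("1", 0, 5))
        assert w[1] == pytest.approx(0.5) and w[2] == pytest.approx(0.5)

    def test_all_missing_panel_scores_zero(self, toy_map):
        geno = np.full((10, 4), MISSING, dtype=np.int8)
        pos = (np.arange(10, dtype=np.int64) + 1) * 100
        panel = GenotypePanel([f"i{j}" for j in range(4)], {"1": pos},
                              {"1": geno})
        freqs = estimate_allele_freqs_resampled(panel, seed=0)
        band = estimate_banded_r2(panel, bandwidth=4, seed=0)
        params = ModelParams(epsilon=1e-3, window_k=5)
        sm = scan_wlod(panel, freqs, band, toy_map, params)
        np.testing.assert_array_equal(sm.scores["1"], 0.0)

    def test_monotone_heterozygote_penalty(self, toy_panel, toy_map):
        """Replacing one homozygote with a heterozygote never increases a
        window's score."""
        freqs = estimate_allele_freqs_resampled(toy_panel, seed=3)
        band = estimate_banded_r2(toy_panel, bandwidth=6, seed=4)
        params = ModelParams(epsilon=1e-3, m_generations=3, window_k=7)
        base = scan_wlod(toy_panel, freqs, band, toy_map, params).scores["1"]
        g = toy_panel.genotypes["1"]
        hom = np.argwhere(g == HOM_REF)
        k, i = hom[len(hom) // 2]
        mod = toy_panel.subset_sites("1", np.arange(g.shape[0]))
        mod.genotypes["1"][k, i] = HET
        after = scan_wlod(mod, freqs, band, toy_map, params).scores["1"]
        assert np.all(after[:, i] <= base[:, i] + 1e-12)

    def test_short_chromosome_yields_no_windows(self, toy_panel, toy_map):
        freqs = estimate_allele_freqs_resampled(toy_panel, seed=3)
        band = estimate_banded_r2(toy_panel, bandwidth=6, seed=4)
        params = ModelParams(epsilon=1e-3, window_k=26)  # S = 25 < K
        sm = scan_wlod(toy_panel, freqs, band, toy_map, params)
        assert sm.n_windows() == 0

    def test_per_genotype_error_overrides_global(self, toy_panel):
        eps = np.full(toy_panel.genotypes["1"].shape, 1e-2)
        toy_panel.per_genotype_error = {"1": eps}
        freqs = estimate_allele_freqs_resampled(toy_panel, seed=3)
        params = ModelParams(epsilon=1e-6, window_k=5)
        llr = site_llr_matrix(toy_panel, "1", freqs, params)
        het = toy_panel.genotypes["1"] == HET
        np.testing.assert_allclose(llr[het], -2.0)

    def test_window_count_and_sliding_step(self, toy_panel, toy_map):
        freqs = estimate_allele_freqs_resampled(toy_panel, seed=3)
        params = ModelParams(epsilon=1e-3, window_k=10)
        sm = scan_lod(toy_panel, freqs, params)
        assert sm.scores["1"].shape[0] == 25 - 10 + 1
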