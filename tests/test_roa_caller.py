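import numpy as np
import pandas as pd
import pytest

from autozyg.data_io import GeneticMap, GenotypePanel, HET, MISSING
from autozyg.roa_caller import (ROASet, assemble_roa, classify_roa_gmm,
                                evaluate_against_truth, naive_count_roh,
                                select_optimal)
from autozyg.simulator import TrueIBDSegmentSet
from autozyg.wlod_engine import WindowScoreMatrix


def _score_matrix(scores_by_ind, K, spacing=1000):
    scores = np.asarray(scores_by_ind, dtype=float).T  # (nw, n_ind)
    S = scores.shape[0] + K - 1
    pos = (np.arange(S, dtype=np.int64) + 1) * spacing
    ids = [f"i{j}" for j in range(scores.shape[1])]
    return WindowScoreMatrix(K, {"1": scores}, {"1": pos}, ids, kind="wlod")


def _brute_assemble(scores, threshold, fraction, K):
    """Per-SNP coverage counting done the obvious slow way."""
    above = scores > threshold
    nw = len(scores)
    S = nw + K - 1
    in_roa = np.zeros(S, bool)
    for t in range(S):
        wins = [s for s in range(max(0, t - K + 1), min(t, nw - 1) + 1)]
        n_above = sum(above[s] for s in wins)
        in_roa[t] = n_above > fraction * len(wins)
    return in_roa


class TestAssembleROA:
    def test_matches_brute_force_on_random_toys(self, rng):
        for trial in range(20):
            K = int(rng.integers(2, 9))
            nw = int(rng.integers(K, 60))
            scores = rng.normal(0, 1, nw)
            thr = float(rng.normal(0, 0.5))
            frac = float(rng.uniform(0, 0.6))
            sm = _score_matrix([scores], K)
            roas = assemble_roa(sm, thr, min(frac, 0.99))
            expected = _brute_assemble(scores, thr, min(frac, 0.99), K)
            got = np.zeros(nw + K - 1, bool)
            for row in roas.df.itertuples():
                got[row.first_snp:row.last_snp + 1] = True
            np.testing.assert_array_equal(got, expected)

    def test_fraction_zero_is_union_join(self):
        sm = _score_matrix([[1, 1, 1, 1, 1, 1]], K=4)
        roas = assemble_roa(sm, 0.0, 0.0)
        assert len(roas) == 1
        row = roas.df.iloc[0]
        assert row.first_snp == 0 and row.last_snp == 8

    def test_isolated_window_with_fraction(self):
        # an isolated above-threshold window of K = 8 SNPs at the
        # chromosome start: only the leading SNPs, covered by few existing
        # windows, exceed the 25% coverage fraction
        K = 8
        scores = np.zeros(20)
        scores[0] = 5.0
        sm = _score_matrix([scores], K)
        roas = assemble_roa(sm, 1.0, 0.25)
        expected = _brute_assemble(scores, 1.0, 0.25, K)
        got = np.zeros(20 + K - 1, bool)
        for row in roas.df.itertuples():
            got[row.first_snp:row.last_snp + 1] = True
        np.testing.assert_array_equal(got, expected)
        assert 0 < got.sum() < K  # leading SNPs only
        # in mid-chromosome the same isolated window is diluted away
        scores2 = np.zeros(20)
        scores2[10] = 5.0
        assert len(assemble_roa(_score_matrix([scores2], K), 1.0, 0.25)) == 0

    def test_no_above_threshold_windows(self):
        sm = _score_matrix([[-1, -2, -3]], K=2)
        assert len(assemble_roa(sm, 0.0, 0.0)) == 0

    def test_fraction_anti_monotone(self, rng):
        scores = rng.normal(0, 1, 80)
        sm = _score_matrix([scores], K=6)
        prev = None
        for f in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            total = assemble_roa(sm, 0.0, f).df["length_bp"].sum()
            if prev is not None:
                assert total <= prev
            prev = total

    def test_threshold_anti_monotone(self, rng):
        scores = rng.normal(0, 1, 80)
        sm = _score_matrix([scores], K=6)
        prev = None
        for thr in (-1.0, -0.5, 0.0, 0.5, 1.0):
            total = assemble_roa(sm, thr, 0.1).df["length_bp"].sum()
            if prev is not None:
                assert total <= prev
            prev = total

    def test_invalid_fraction_raises(self):
        sm = _score_matrix([[1.0, 2.0]], K=2)
        with pytest.raises(ValueError):
            assemble_roa(sm, 0.0, 1.0)

    def test_genetic_lengths_from_map(self):
        sm = _score_matrix([[5.0] * 10], K=3)
        gmap = GeneticMap({"1": (np.array([1, 20_000]), np.array([0.0, 0.02]))})
        roas = assemble_roa(sm, 0.0, 0.0, gmap=gmap)
        row = roas.df.iloc[0]
        assert row.length_cm == pytest.approx(
            (row.end_bp - row.start_bp) / (20_000 - 1) * 2, rel=1e-6)


class TestNaiveCounting:
    def _panel(self, geno):
        geno = np.asarray(geno, dtype=np.int8)[:, None]
        pos = (np.arange(len(geno), dtype=np.int64) + 1) * 100
        return GenotypePanel(["i0"], {"1": pos}, {"1": geno})

    def test_all_homozygous_single_roh(self):
        panel = self._panel(np.zeros(120))
        roas = naive_count_roh(panel, window_k=50)
        assert len(roas) == 1
        assert roas.df.iloc[0].first_snp == 0
        assert roas.df.iloc[0].last_snp == 119

    def test_het_boundary_inclusive(self):
        # 1 het in 50 SNPs (2%) passes; 2 hets (4%) fail
        g = np.zeros(50)
        g[25] = HET
        assert len(naive_count_roh(self._panel(g), window_k=50)) == 1
        g[26] = HET
        assert len(naive_count_roh(self._panel(g), window_k=50)) == 0

    def test_missing_allowance(self):
        g = np.zeros(50)
        g[:2] = MISSING
        assert len(naive_count_roh(self._panel(g), window_k=50)) == 1
        g[:3] = MISSING
        assert len(naive_count_roh(self._panel(g), window_k=50)) == 0


class TestGMMClassification:
    def test_two_component_recovery(self, rng):
        n = 2000
        lengths = np.concatenate([rng.normal(0.1, 0.02, n // 2),
                                  rng.normal(5.0, 0.5, n // 2)])
        df = pd.DataFrame({
            "individual": [f"i{j % 30}" for j in range(n)], "chrom": "1",
            "start_bp": 0, "end_bp": 1, "length_bp": 1, "start_cm": 0.0,
            "end_cm": lengths, "length_cm": lengths, "n_windows": 1,
            "mean_score": 1.0, "first_snp": 0, "last_snp": 1,
            "class_label": 0})
        fit, labelled = classify_roa_gmm(ROASet(df), seed=0)
        assert fit.g == 2
        assert fit.means[0] == pytest.approx(0.1, rel=0.1)
        assert fit.means[1] == pytest.approx(5.0, rel=0.1)
        # classes ordered by mean: long ROA carry the larger label
        long_labels = labelled.df.loc[labelled.df.length_cm > 2, "class_label"]
        assert (long_labels == 2).all()

    def test_single_cluster_prefers_one_component(self, rng):
        lengths = rng.normal(1.0, 0.05, 400)
        df = pd.DataFrame({
            "individual": [f"i{j % 30}" for j in range(400)], "chrom": "1",
            "start_bp": 0, "end_bp": 1, "length_bp": 1, "start_cm": 0.0,
            "end_cm": lengths, "length_cm": lengths, "n_windows": 1,
            "mean_score": 1.0, "first_snp": 0, "last_snp": 1,
            "class_label": 0})
        fit, _ = classify_roa_gmm(ROASet(df), candidate_g=range(1, 4), seed=0)
        assert fit.g == 1

    def test_determinism_given_seed(self, rng):
        lengths = np.concatenate([rng.normal(0.5, 0.1, 100),
                                  rng.normal(4.0, 0.5, 100)])
        df = pd.DataFrame({
            "individual": [f"i{j % 30}" for j in range(200)], "chrom": "1",
            "start_bp": 0, "end_bp": 1, "length_bp": 1, "start_cm": 0.0,
            "end_cm": lengths, "length_cm": lengths, "n_windows": 1,
            "mean_score": 1.0, "first_snp": 0, "last_snp": 1,
            "class_label": 0})
        _, a = classify_roa_gmm(ROASet(df), seed=5)
        _, b = classify_roa_gmm(ROASet(df), seed=5)
        assert (a.df["class_label"] == b.df["class_label"]).all()

    def test_small_g_skipped_when_too_few_roa(self, rng):
        lengths = rng.normal(1.0, 0.1, 6)
        df = pd.DataFrame({
            "individual": [f"i{j}" for j in range(6)], "chrom": "1",
            "start_bp": 0, "end_bp": 1, "length_bp": 1, "start_cm": 0.0,
            "end_cm": lengths, "length_cm": lengths, "n_windows": 1,
            "mean_score": 1.0, "first_snp": 0, "last_snp": 1,
            "class_label": 0})
        with pytest.warns(UserWarning):
            fit, _ = classify_roa_gmm(ROASet(df), candidate_g=range(1, 11),
                                      seed=0)
        assert 4 in fit.skipped and 1 in fit.bic


def _truth(rows):
    df = pd.DataFrame(rows, columns=["individual", "chrom", "start_bp",
                                     "end_bp", "length_bp"])
    return TrueIBDSegmentSet(df, pd.DataFrame())


def _inferred(rows):
    recs = []
    for ind, s, e in rows:
        recs.append({"individual": ind, "chrom": "1", "start_bp": s,
                     "end_bp": e, "length_bp": e - s, "start_cm": 0.0,
                     "end_cm": 0.0, "length_cm": 0.0, "n_windows": 1,
                     "mean_score": 1.0, "first_snp": 0, "last_snp": 1,
                     "class_label": 0})
    return ROASet(pd.DataFrame(recs, columns=ROASet.COLUMNS))


class TestEvaluation:
    def test_identical_calls_perfect(self):
        truth = _truth([("i0", "1", 100, 1100, 1000)])
        inferred = _inferred([("i0", 100, 1100)])
        rep = evaluate_against_truth(inferred, truth)
        assert rep.power == 1.0 and rep.false_discovery == 0.0
        assert rep.mean_ratio == pytest.approx(1.0)

    def test_half_coverage(self):
        truth = _truth([("i0", "1", 0, 1000, 1000)])
        inferred = _inferred([("i0", 0, 500)])
        rep = evaluate_against_truth(inferred, truth)
        assert rep.power == 0.5 and rep.false_discovery == 0.0
        assert rep.mean_ratio == pytest.approx(0.5)

    def test_ten_percent_extension_both_sides(self):
        truth = _truth([("i0", "1", 1000, 2000, 1000)])
        inferred = _inferred([("i0", 900, 2100)])
        rep = evaluate_against_truth(inferred, truth)
        assert rep.power == 1.0
        assert rep.false_discovery == pytest.approx(0.2 / 1.2)
        assert rep.mean_ratio == pytest.approx(1.2)

    def test_fp_fn_counts(self):
        truth = _truth([("i0", "1", 0, 1000, 1000),
                        ("i0", "1", 5000, 6000, 1000)])
        inferred = _inferred([("i0", 0, 1000), ("i0", 9000, 9500)])
        rep = evaluate_against_truth(inferred, truth)
        assert rep.n_false_positive == 1 and rep.n_false_negative == 1
        assert rep.n_detected == 1

    def test_min_true_length_restriction(self):
        truth = _truth([("i0", "1", 0, 100, 100),
                        ("i0", "1", 5000, 7000, 2000)])
        inferred = _inferred([("i0", 5000, 7000)])
        rep = evaluate_against_truth(inferred, truth, min_true_length=1000)
        assert rep.power == 1.0


class TestOptimalSelection:
    def test_smallest_qualifying_pair(self):
        surface = pd.DataFrame([
            {"K": 70, "fraction": 0.1, "fp_count": 0, "lw_ratio": 1.01,
             "mean_ratio": 1.01},
            {"K": 50, "fraction": 0.2, "fp_count": 0, "lw_ratio": 0.99,
             "mean_ratio": 0.99},
            {"K": 50, "fraction": 0.1, "fp_count": 1, "lw_ratio": 1.00,
             "mean_ratio": 1.00},
        ])
        k, f, ok = select_optimal(surface)
        assert (k, f, ok) == (50, 0.2, True)

    def test_best_effort_when_nothing_qualifies(self):
        surface = pd.DataFrame([
            {"K": 50, "fraction": 0.0, "fp_count": 2, "lw_ratio": 1.5,
             "mean_ratio": 1.5},
            {"K": 70, "fraction": 0.1, "fp_count": 1, "lw_ratio": 1.4,
             "mean_ratio": 1.4},
        ])
        k, f, ok = select_optimal(surface)
        assert (k, f, ok) == (70, 0.1, False)

    def test_empty_surface(self):
        assert select_optimal(pd.DataFrame()) == (None, None, False)
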