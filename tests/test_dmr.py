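"""Window normalisation, logistic LRT, BH-FDR and DMR-set statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epinipt as e
from epinipt.dmr import WindowFeatures


def make_features(norm_cov, norm_frac=None, lin_cov=None):
    norm_cov = np.asarray(norm_cov, dtype=float)
    n, w = norm_cov.shape
    if norm_frac is None:
        norm_frac = np.ones_like(norm_cov)
    if lin_cov is None:
        lin_cov = 2.0**norm_cov
    return WindowFeatures(
        chrom=np.array(["chr21a"] * w),
        start=np.arange(w) * 100,
        end=np.arange(w) * 100 + 100,
        n_cg=np.ones(w, dtype=int),
        norm_cov=norm_cov,
        norm_frac=np.asarray(norm_frac, dtype=float),
        lin_cov=np.asarray(lin_cov, dtype=float),
        sample_ids=[f"s{i}" for i in range(n)],
    )


class TestNormalise:
    def test_hand_arithmetic_with_pseudocount(self, toy_sites):
        from conftest import toy_matrix
        m = toy_matrix([[3, 0, 0, 0, 800, 200]], toy_sites)
        ws = e.window_stats(m, width=100)
        cs = e.chrom_stats(m)
        feats = e.normalize_window_features(ws, cs, "chrB")
        w0 = np.flatnonzero((feats.chrom == "chrA") & (feats.start == 0))[0]
        assert feats.norm_cov[0, w0] == pytest.approx(
            np.log2(4) - np.log2(1000), abs=1e-12)
        # window fraction 0.5 over reference fraction 1.0
        assert feats.norm_frac[0, w0] == pytest.approx(0.5)

    def test_zero_reference_total_names_sample(self, toy_sites):
        from conftest import toy_matrix
        m = toy_matrix([[3, 0, 0, 0, 0, 0]], toy_sites, ids=["lowcov"])
        ws = e.window_stats(m, width=100)
        cs = e.chrom_stats(m)
        with pytest.raises(ValueError, match="lowcov"):
            e.normalize_window_features(ws, cs, "chrB")

    def test_doubling_counts_keeps_features_finite(self, toy_sites):
        from conftest import toy_matrix
        m = toy_matrix([[3, 1, 0, 0, 800, 200]], toy_sites)
        m2 = toy_matrix([[6, 2, 0, 0, 1600, 400]], toy_sites)
        f1 = e.normalize_window_features(e.window_stats(m, 100),
                                         e.chrom_stats(m), "chrB")
        f2 = e.normalize_window_features(e.window_stats(m2, 100),
                                         e.chrom_stats(m2), "chrB")
        assert np.all(np.isfinite(f2.norm_cov))
        assert np.allclose(f1.norm_frac, f2.norm_frac)


class TestLRT:
    def test_constant_windows_give_lrt_zero_p_one(self):
        f = make_features(np.ones((8, 3)))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
        tab = e.dmr_lrt(f, y)
        assert np.allclose(tab["lrt"], 0.0, atol=1e-6)
        assert np.allclose(tab["p"], 1.0, atol=1e-6)

    def test_matches_statsmodels_logit_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        n, w = 30, 60
        f = make_features(rng.standard_normal((n, w)),
                          norm_frac=rng.standard_normal((n, w)) + 2)
        y = np.zeros(n, dtype=bool)
        y[rng.choice(n, 15, replace=False)] = True
        tab = e.dmr_lrt(f, y)
        ll_null = sm.Logit(y.astype(float), np.ones((n, 1))).fit(disp=0).llf
        for j in range(0, w, 7):
            x = sm.add_constant(np.column_stack([f.norm_cov[:, j],
                                                 f.norm_frac[:, j]]))
            fit = sm.Logit(y.astype(float), x).fit(disp=0, maxiter=300,
                                                   method="newton")
            assert tab["lrt"].iloc[j] == pytest.approx(
                2 * (fit.llf - ll_null), abs=1e-6)

    def test_covariates_shared_by_both_models(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(12)
        n, w = 26, 20
        f = make_features(rng.standard_normal((n, w)),
                          norm_frac=rng.standard_normal((n, w)))
        y = np.zeros(n, dtype=bool)
        y[rng.choice(n, 13, replace=False)] = True
        cov = pd.DataFrame({
            "fetal_sex": rng.choice(["XX", "XY"], n),
            "ff": rng.uniform(0.06, 0.10, n),
        })
        tab = e.dmr_lrt(f, y, covariates=cov)
        sex = (cov["fetal_sex"] == "XY").to_numpy(float)
        zn = np.column_stack([np.ones(n), sex, cov["ff"]])
        ll_null = sm.Logit(y.astype(float), zn).fit(disp=0, maxiter=300,
                                                    method="newton").llf
        j = 5
        x = np.column_stack([np.ones(n), f.norm_cov[:, j], f.norm_frac[:, j],
                             cov["ff"], sex])
        # column order differs but the likelihood does not
        fit = sm.Logit(y.astype(float), x).fit(disp=0, maxiter=300,
                                               method="newton")
        if tab["converged"].iloc[j] and tab["used_sex"].iloc[j]:
            assert tab["lrt"].iloc[j] == pytest.approx(
                2 * (fit.llf - ll_null), abs=1e-5)

    def test_too_few_samples_per_class_rejected(self):
        f = make_features(np.random.default_rng(0).random((5, 4)))
        with pytest.raises(ValueError):
            e.dmr_lrt(f, np.array([0, 0, 0, 1, 1], dtype=bool))

    def test_log_fold_change_zero_for_equal_group_means(self):
        base = np.tile(np.array([[1.0, 2.0, 3.0]]), (8, 1))
        f = make_features(base, norm_frac=base, lin_cov=base)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
        tab = e.dmr_lrt(f, y)
        assert np.allclose(tab["logFC_cov"], 0.0, atol=1e-12)
        assert np.allclose(tab["logFC_frac"], 0.0, atol=1e-12)


class TestBH:
    def test_hand_computation(self):
        q = e.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p_passthrough(self):
        assert e.bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.all(e.bh_fdr(np.ones(5)) == 1.0)

    def test_nan_passthrough(self):
        q = e.bh_fdr(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            e.bh_fdr(np.array([0.5, 1.5]))

    def test_matches_step_up_enumeration_oracle(self):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank_from_top in range(m, 0, -1):
                i = order[rank_from_top - 1]
                val = min(prev, p[i] * m / rank_from_top)
                q[i] = val
                prev = val
            return q
        rng = np.random.default_rng(13)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(e.bh_fdr(p), oracle(p), atol=1e-12)

    def test_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(14)
        p = rng.random(500)
        assert np.allclose(e.bh_fdr(p),
                           mt.multipletests(p, method="fdr_bh")[1], atol=1e-12)


def fisher_oracle(n11, n10, n01, n00):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, c1, n = n11 + n10, n11 + n01, n11 + n10 + n01 + n00
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: stats.hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    obs = probs[n11]
    return sum(v for v in probs.values() if v <= obs * (1 + 1e-9))


class TestOverlap:
    def test_hand_table_odds_ratio(self):
        universe = list(range(100))
        a = set(range(15))                    # a=10 overlap, b=5 A-only
        b = set(range(10)) | set(range(15, 17))
        res = e.intersect_dmr_sets(a, b, universe)
        assert res.table == (10, 5, 2, 83)
        assert res.odds_ratio == pytest.approx(83.0)
        assert res.p == pytest.approx(fisher_oracle(10, 5, 2, 83), rel=1e-9)

    def test_identical_half_split_is_haldane_corrected(self):
        universe = list(range(40))
        a = set(range(20))
        res = e.intersect_dmr_sets(a, a, universe)
        assert res.haldane_corrected
        assert np.isfinite(res.odds_ratio)

    def test_independent_sets_median_or_near_one(self):
        rng = np.random.default_rng(15)
        universe = list(range(5000))
        ors = []
        for _ in range(100):
            a = set(rng.choice(5000, 500, replace=False).tolist())
            b = set(rng.choice(5000, 500, replace=False).tolist())
            ors.append(e.intersect_dmr_sets(a, b, universe).odds_ratio)
        assert 0.8 < np.median(ors) < 1.25

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            e.intersect_dmr_sets(set(), set(), [])


class TestEffectAndPosition:
    def test_proportional_effects_fully_concordant(self):
        d = np.array([0.5, -1.0, 2.0, 0.1, -0.3])
        assert e.dmr_effect_concordance(d, 2 * d)[0] == pytest.approx(1.0)
        assert e.dmr_effect_concordance(d, -d)[0] == pytest.approx(-1.0)

    def test_independent_effects_near_zero(self):
        rng = np.random.default_rng(16)
        hits = sum(
            abs(e.dmr_effect_concordance(rng.standard_normal(500),
                                         rng.standard_normal(500))[0]) < 0.15
            for _ in range(40)
        )
        assert hits >= 36                      # ~95% of null replicates

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            e.dmr_effect_concordance(np.ones(5), np.arange(5))

    def test_ks_identical_sets(self):
        pos = np.arange(10, dtype=float)
        d, p = e.dmr_positional_ks(pos, pos)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_ks_disjoint_supports(self):
        rng = np.random.default_rng(17)
        d, p = e.dmr_positional_ks(rng.uniform(0, 0.5, 100),
                                   rng.uniform(0.5, 1.0, 100))
        assert d > 0.99 and p < 1e-10

    def test_ks_matches_bruteforce_ecdf_oracle(self):
        def oracle(a, b):
            grid = np.sort(np.concatenate([a, b]))
            fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
            fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
            return np.max(np.abs(fa - fb))
        rng = np.random.default_rng(18)
        for _ in range(20):
            a = rng.standard_normal(rng.integers(5, 50))
            b = rng.standard_normal(rng.integers(5, 50)) + 0.3
            d, _ = e.dmr_positional_ks(a, b)
            assert d == pytest.approx(oracle(a, b), abs=1e-12)

    def test_ks_needs_five_positions(self):
        with pytest.raises(ValueError):
            e.dmr_positional_ks(np.arange(3), np.arange(10))


class TestPerDMRClassifier:
    def test_perfectly_separating_window_scores_auc_one(self):
        rng = np.random.default_rng(19)
        n = 12
        y = np.array([0] * 6 + [1] * 6, dtype=bool)
        sep = np.concatenate([rng.normal(0, 0.1, 6), rng.normal(3, 0.1, 6)])
        f = make_features(sep[:, None], norm_frac=rng.random((n, 1)))
        assert e.per_dmr_cv_auc(f, y)[0] == 1.0

    def test_label_independent_window_near_chance(self):
        rng = np.random.default_rng(20)
        n = 14
        x = rng.standard_normal((n, 1))
        f = make_features(x, norm_frac=rng.standard_normal((n, 1)))
        aucs = []
        for _ in range(50):
            y = np.zeros(n, dtype=bool)
            y[rng.choice(n, 7, replace=False)] = True
            aucs.append(e.per_dmr_cv_auc(f, y)[0])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_rejected(self):
        f = make_features(np.random.default_rng(0).random((6, 2)))
        with pytest.raises(ValueError):
            e.per_dmr_cv_auc(f, np.ones(6, dtype=bool))
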