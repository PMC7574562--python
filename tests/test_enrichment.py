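"""Top-signal window selection and Fisher enrichment at CG resolution."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epinipt as e
from epinipt.coverage import SiteIndex

from conftest import toy_matrix


@pytest.fixture
def grid_sites():
    """One chromosome, one CG in each of 10 kb-wide windows."""
    return SiteIndex(
        chrom_names=["chrA"],
        chrom_lengths=np.array([10_000]),
        chrom_id=np.zeros(10, dtype=np.int32),
        pos=np.arange(10, dtype=np.int64) * 1000 + 500,
    )


class TestTopWindows:
    def test_single_loaded_window_is_sole_top(self, grid_sites):
        counts = np.zeros((1, 10), dtype=int)
        counts[0, 3] = 50
        tops = e.top_signal_windows(toy_matrix(counts, grid_sites), ["g"],
                                    width=1000, quantile=0.10)["g"]
        sel = tops[tops["top"]]
        assert len(sel) == 1 and sel["start"].iloc[0] == 3000

    def test_uniform_coverage_selects_all_with_degenerate_flag(self, grid_sites):
        counts = np.full((1, 10), 5, dtype=int)
        with pytest.warns(UserWarning, match="ties"):
            tops = e.top_signal_windows(toy_matrix(counts, grid_sites), ["g"],
                                        width=1000, quantile=0.10)["g"]
        assert tops["top"].all()
        assert tops.attrs["degenerate"]

    def test_quantile_zero_and_one_degenerate_predictably(self, grid_sites):
        counts = np.arange(10, dtype=int)[None, :]
        m = toy_matrix(counts, grid_sites)
        none = e.top_signal_windows(m, ["g"], width=1000, quantile=0.0)["g"]
        assert not none["top"].any()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            allw = e.top_signal_windows(m, ["g"], width=1000, quantile=1.0)["g"]
        assert allw["top"].all()

    def test_planted_high_signal_windows_recovered(self, small_genome):
        """CGI-concentrated uCG capture puts CGI windows among the top 10%."""
        cfg = e.CohortConfig(assay="uCG", n_npc=5, n_healthy=0, n_t21=0,
                             n_cvs=0, depth_human_reads=20e6)
        matrix, meta, _ = e.simulate_cohort(small_genome, cfg, seed=41)
        tops = e.top_signal_windows(matrix, [m.group for m in meta])["NPC"]
        from epinipt.synthetic_data import _in_intervals
        cgi = small_genome.annotations["CGI"]
        is_cgi = np.zeros(len(tops), dtype=bool)
        for chrom, grp in tops.groupby("chrom"):
            is_cgi[grp.index] = _in_intervals(grp["start"].to_numpy() + 500,
                                              cgi[chrom])
        # CGI windows are 10x CG-dense and 5x boosted: nearly all selected
        assert tops.loc[is_cgi, "top"].mean() >= 0.95


def fisher_oracle(n11, n10, n01, n00):
    r1, c1, n = n11 + n10, n11 + n01, n11 + n10 + n01 + n00
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: stats.hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    obs = probs[n11]
    return sum(v for v in probs.values() if v <= obs * (1 + 1e-9))


def test_fisher_p_equals_hypergeometric_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(30):
        t = rng.integers(0, 50, size=4)
        table = [[int(t[0]), int(t[1])], [int(t[2]), int(t[3])]]
        _, p = stats.fisher_exact(table)
        assert p == pytest.approx(fisher_oracle(*t), rel=1e-8, abs=1e-12)


class TestSiteEnrichment:
    def test_annotation_identical_to_top_windows_is_degenerate(self, grid_sites):
        counts = np.zeros((1, 10), dtype=int)
        counts[0, 3] = 50
        tops = e.top_signal_windows(toy_matrix(counts, grid_sites), ["g"],
                                    width=1000, quantile=0.10)["g"]
        res = e.site_enrichment(tops, {"chrA": np.array([[3000, 4000]])},
                                grid_sites, "match")
        assert res.haldane_corrected
        assert res.odds_ratio > 1
        assert res.overlap_fraction == 1.0

    def test_independent_annotation_median_or_near_one(self, grid_sites):
        rng = np.random.default_rng(43)
        sites = SiteIndex(["chrA"], np.array([100_000]),
                          np.zeros(100, dtype=np.int32),
                          np.arange(100, dtype=np.int64) * 1000 + 500)
        ors = []
        for _ in range(100):
            counts = rng.poisson(5, size=(1, 100))
            tops = e.top_signal_windows(toy_matrix(counts, sites), ["g"],
                                        width=1000, quantile=0.30)["g"]
            starts = np.sort(rng.choice(100, 30, replace=False)) * 1000
            iv = np.column_stack([starts, starts + 1000])
            ors.append(e.site_enrichment(tops, {"chrA": iv}, sites).odds_ratio)
        assert 0.7 < np.median(ors) < 1.4

    def test_annotation_off_catalog_warns(self, grid_sites):
        counts = np.ones((1, 10), dtype=int)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tops = e.top_signal_windows(toy_matrix(counts, grid_sites), ["g"],
                                        width=1000)["g"]
        with pytest.warns(UserWarning, match="no chromosomes"):
            res = e.site_enrichment(tops, {"chrZ": np.array([[0, 10]])},
                                    grid_sites)
        assert res.degenerate

    def test_cgi_enrichment_direction_on_synthetic_ucg(self, small_genome):
        """Unmethylated-CG signal concentrates in CG islands, not introns."""
        cfg = e.CohortConfig(assay="uCG", n_npc=5, n_healthy=0, n_t21=0,
                             n_cvs=0, depth_human_reads=20e6)
        matrix, meta, _ = e.simulate_cohort(small_genome, cfg, seed=44)
        tops = e.top_signal_windows(matrix, [m.group for m in meta])["NPC"]
        or_cgi = e.site_enrichment(tops, small_genome.annotations["CGI"],
                                   small_genome.sites, "CGI").odds_ratio
        or_intron = e.site_enrichment(tops, small_genome.annotations["intron"],
                                      small_genome.sites, "intron").odds_ratio
        assert or_cgi > 1.0
        assert or_cgi > or_intron


class TestProbeEnrichment:
    def test_no_mqtl_probe_in_dmrs_gives_zero_overlap(self):
        probes = pd.DataFrame({"chrom": ["chrA"] * 4,
                               "pos": [10, 20, 5000, 6000],
                               "is_mqtl": [True, True, False, False]})
        res = e.probe_dmr_enrichment(probes, {"chrA": np.array([[4000, 7000]])})
        assert res.table[0] == 0
        assert res.overlap_fraction == 0.0

    def test_uniform_probes_match_dmr_coverage_fraction(self):
        rng = np.random.default_rng(45)
        fracs = []
        for r in range(30):
            probes = pd.DataFrame({
                "chrom": "chrA",
                "pos": rng.integers(0, 1_000_000, 2000),
                "is_mqtl": rng.random(2000) < 0.5,
            })
            starts = np.sort(rng.choice(1000, 10, replace=False)) * 1000
            dmrs = {"chrA": np.column_stack([starts, starts + 1000])}
            res = e.probe_dmr_enrichment(probes, dmrs)
            # fraction of probes inside DMRs ~ 1% of the chromosome
            fracs.append((res.table[0] + res.table[2]) / 2000)
        assert np.mean(fracs) == pytest.approx(0.01, abs=0.002)

    def test_independent_mqtls_not_enriched(self, small_genome):
        """mQTL flags planted independently of DMRs: Fisher p > 0.05 in the
        vast majority of replicates."""
        rng = np.random.default_rng(46)
        nonsig = 0
        reps = 20
        for r in range(reps):
            probes = small_genome.mqtl_probes.copy()
            probes["is_mqtl"] = rng.random(len(probes)) < 0.2
            starts = np.sort(rng.choice(19_000, 150, replace=False)) * 100
            dmrs = {"chr21a": np.column_stack([starts, starts + 100])}
            nonsig += e.probe_dmr_enrichment(probes, dmrs).p > 0.05
        assert nonsig >= int(0.8 * reps)

    def test_no_probes_on_dmr_chromosome_rejected(self):
        probes = pd.DataFrame({"chrom": ["chrB"], "pos": [1], "is_mqtl": [True]})
        with pytest.raises(ValueError):
            e.probe_dmr_enrichment(probes, {"chrA": np.array([[0, 10]])})

    def test_marginals_sum_to_universe(self, small_genome):
        probes = small_genome.mqtl_probes
        dmrs = {"chr21a": np.array([[0, 50_000]])}
        res = e.probe_dmr_enrichment(probes, dmrs)
        assert sum(res.table) == len(probes)
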