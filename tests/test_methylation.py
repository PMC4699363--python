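"""Methylation scoring, binomial testing and clustering tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from tadscape import methylation as M


def exact_binom_two_sided(x, n, p0):
    """Independent oracle: direct tail summation over outcomes."""
    pmf = [special.comb(n, k, exact=True) * p0**k * (1 - p0) ** (n - k)
           for k in range(n + 1)]
    lower = sum(pmf[: x + 1])
    upper = sum(pmf[x:])
    return min(1.0, 2.0 * min(lower, upper))


class TestScore:
    def test_extremes_and_midpoint(self):
        assert M.methylation_score(0, 50) == 100.0
        assert M.methylation_score(50, 0) == 0.0
        assert M.methylation_score(7, 7) == pytest.approx(50.0)

    def test_monotone_decreasing_in_hpaii(self):
        scores = M.methylation_score(np.arange(0, 60), np.full(60, 20))
        assert (np.diff(scores) < 0).all()

    def test_unassayable_site_is_nan(self):
        assert np.isnan(M.methylation_score(0, 0))

    def test_depth_normalization(self):
        # doubled HpaII depth halves the normalized count
        assert M.methylation_score(20, 10, hpaii_depth=2.0) == pytest.approx(50.0)


class TestBinomialTest:
    @pytest.mark.parametrize("x,n,p0", [
        (5, 10, 0.5), (30, 30, 0.5), (0, 40, 0.5), (17, 60, 0.3), (2, 9, 0.7)])
    def test_matches_summation_oracle(self, x, n, p0):
        got = float(M.binom_two_sided(x, n, p0))
        assert got == pytest.approx(exact_binom_two_sided(x, n, p0), abs=1e-12)

    def test_oracle_sweep_large_n(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(1, 1000))
            x = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            assert float(M.binom_two_sided(x, n, p0)) == pytest.approx(
                exact_binom_two_sided(x, n, p0), abs=1e-12)

    def test_balanced_site_not_significant(self):
        t = pd.DataFrame({"hpaii_wt": [5], "hpaii_tko": [5],
                          "mspi_wt": [10], "mspi_tko": [10]})
        res = M.test_differential_methylation(t, depth_wt=1, depth_tko=1)
        assert res["p"].iloc[0] == pytest.approx(1.0)
        assert res["direction"].iloc[0] == "none"

    def test_extreme_sites_called_with_exact_tail(self):
        t = pd.DataFrame({"hpaii_wt": [0, 40], "hpaii_tko": [30, 0],
                          "mspi_wt": [10, 10], "mspi_tko": [10, 10]})
        res = M.test_differential_methylation(t, depth_wt=1, depth_tko=1)
        assert res["p"].iloc[0] == pytest.approx(2 * 0.5**30)
        assert res["direction"].iloc[0] == "hypo"  # TKO excess HpaII = demethylated
        assert res["p"].iloc[1] == pytest.approx(2 * 0.5**40)
        assert res["direction"].iloc[1] == "hyper"

    def test_direction_antisymmetric_under_condition_swap(self, rng):
        n = 300
        t = pd.DataFrame({
            "hpaii_wt": rng.poisson(20, n), "hpaii_tko": rng.poisson(35, n),
            "mspi_wt": rng.poisson(20, n), "mspi_tko": rng.poisson(20, n)})
        res = M.test_differential_methylation(t, depth_wt=1, depth_tko=1)
        swapped = t.rename(columns={"hpaii_wt": "hpaii_tko", "hpaii_tko": "hpaii_wt",
                                    "mspi_wt": "mspi_tko", "mspi_tko": "mspi_wt"})
        res_sw = M.test_differential_methylation(swapped, depth_wt=1, depth_tko=1)
        flip = {"hypo": "hyper", "hyper": "hypo", "none": "none"}
        assert (res_sw["direction"] == res["direction"].map(flip)).all()
        np.testing.assert_allclose(res_sw["p"], res["p"], atol=1e-12)

    def test_zero_total_gets_sentinel(self):
        t = pd.DataFrame({"hpaii_wt": [0], "hpaii_tko": [0],
                          "mspi_wt": [10], "mspi_tko": [10]})
        res = M.test_differential_methylation(t, depth_wt=1, depth_tko=1)
        assert np.isnan(res["p"].iloc[0]) and res["direction"].iloc[0] == "none"


class TestStringent:
    def test_threshold_logic(self):
        t = pd.DataFrame({"p": [1e-7, 1e-7, 1e-3],
                          "score_wt": [80.0, 55.0, 90.0],
                          "score_tko": [40.0, 50.0, 20.0]})
        out = M.classify_stringent(t, delta_threshold=25)
        assert out["stringent"].tolist() == [True, False, False]

    def test_planted_confusion_matrix(self, dataset, default_params):
        res = M.test_differential_methylation(dataset.methylation)
        res = M.classify_stringent(res)
        truth = res["truth"]
        sens = (res["stringent"] & (truth != "null")).sum() / (truth != "null").sum()
        fp = (res["stringent"] & (truth == "null")).sum() / (truth == "null").sum()
        assert sens >= 0.9
        assert fp <= 5e-4  # counts are mildly overdispersed vs the test's model

    def test_confusion_matrix_poisson_counts(self):
        # under the test's own count model the stringent false-positive
        # rate stays at the p-threshold scale
        from tadscape.simulate import SimulationParams, make_genome, simulate_methylation
        p = SimulationParams(seed=29, meth_dispersion=1e9)
        res = M.classify_stringent(M.test_differential_methylation(
            simulate_methylation(make_genome(p), p)))
        truth = res["truth"]
        fp = (res["stringent"] & (truth == "null")).sum() / (truth == "null").sum()
        assert fp <= 1e-4
        sens = (res["stringent"] & (truth != "null")).sum() / (truth != "null").sum()
        assert sens >= 0.9


class TestWindowCluster:
    def _sites(self, chrom, positions):
        return pd.DataFrame({"chrom": chrom, "start": positions,
                             "end": np.asarray(positions) + 2})

    def test_no_dmr_gives_p_one(self):
        assayable = self._sites("chr1", np.arange(0, 100_000, 100))
        res = M.window_cluster_test(assayable.iloc[0:0], assayable, draws=50)
        assert res.observed == 0 and res.p_value == 1.0

    def test_single_window_cluster(self):
        assayable = self._sites("chr1", np.arange(0, 1_000_000, 100))
        dmr = self._sites("chr1", [100, 200, 300, 400, 500])
        res = M.window_cluster_test(dmr, assayable, window=20_000,
                                    min_sites=5, draws=20)
        assert res.observed == 1

    def test_clustered_sites_give_minimal_p(self):
        rng = np.random.default_rng(4)
        assayable = self._sites("chr1", np.sort(rng.choice(10_000_000, 20_000,
                                                           replace=False)))
        # all "DMRs" packed into 1% of the span
        inside = assayable[assayable["start"] < 100_000].head(200)
        res = M.window_cluster_test(inside, assayable, window=20_000,
                                    min_sites=5, draws=200, seed=1)
        assert res.p_value == pytest.approx(1 / 201)

    def test_p_invariant_to_chromosome_order(self):
        rng = np.random.default_rng(5)
        a1 = self._sites("chr1", np.sort(rng.choice(10**6, 500, replace=False)))
        a2 = self._sites("chr2", np.sort(rng.choice(10**6, 500, replace=False)))
        assayable = pd.concat([a1, a2], ignore_index=True)
        dmr = assayable.iloc[::10]
        p_fwd = M.window_cluster_test(dmr, assayable, draws=100, seed=7).p_value
        rev = pd.concat([a2, a1], ignore_index=True)
        p_rev = M.window_cluster_test(dmr.iloc[::-1], rev, draws=100, seed=7).p_value
        assert p_fwd == p_rev

    def test_more_dmrs_than_assayable_rejected(self):
        a = self._sites("chr1", [10, 20])
        with pytest.raises(ValueError):
            M.window_cluster_test(pd.concat([a, a, a]), a)


class TestStateComposition:
    def test_pure_enhancer_sites(self):
        states = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 1000],
                               "end": [1000, 2000],
                               "name": ["enhancer", "promoter"]})
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [10, 500, 900],
                              "end": [12, 502, 902]})
        comp = M.state_composition(sites, states)
        assert comp.loc["enhancer", "sites"] == 1.0

    def test_uniform_sites_match_coverage(self, genome, rng):
        n = 20_000
        pos = rng.integers(0, genome.chromosomes[0][1], n)
        sites = pd.DataFrame({"chrom": "chr1", "start": pos, "end": pos + 2})
        comp = M.state_composition(sites, genome.states)
        st = genome.states.query("chrom == 'chr1'")
        cover = (st["end"] - st["start"]).groupby(st["name"]).sum()
        cover = cover / cover.sum()
        for state, frac in cover.items():
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(comp.loc[state, "sites"] - frac) < 4 * se

    def test_empty_sites_rejected(self, genome):
        with pytest.raises(ValueError):
            M.state_composition(genome.states.iloc[0:0], genome.states)

    def test_outside_sites_counted_as_other(self):
        states = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                               "name": ["promoter"]})
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [502]})
        with pytest.warns(UserWarning, match="outside"):
            comp = M.state_composition(sites, states)
        assert comp.loc["other", "sites"] == 1.0
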