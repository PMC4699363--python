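"""Contact-matrix building, balancing, compartments and domain scores."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tadscape import hic as H


def symmetric_random(n, rng, lam=20):
    m = rng.poisson(lam, (n, n)).astype(float)
    return np.triu(m) + np.triu(m, 1).T


class TestBinContacts:
    def test_single_pair_and_conservation(self):
        pairs = pd.DataFrame({"chrom1": ["chr1"], "pos1": [50_000],
                              "chrom2": ["chr1"], "pos2": [150_000]})
        res = H.bin_contacts(pairs, {"chr1": 300_000}, bin_size=100_000)
        m = res.matrices["chr1"].matrix
        assert m[0, 1] == 1 and m[1, 0] == 1
        assert m.sum() == 2  # one off-diagonal pair counted symmetrically

    def test_cis_trans_ratio(self):
        pairs = pd.DataFrame({
            "chrom1": ["chr1", "chr1", "chr1", "chr1"],
            "pos1": [0, 10, 20, 30],
            "chrom2": ["chr1", "chr1", "chr1", "chr2"],
            "pos2": [100, 200, 300, 400]})
        res = H.bin_contacts(pairs, {"chr1": 10_000, "chr2": 10_000}, 1000)
        assert res.cis_fraction == pytest.approx(0.75)

    def test_out_of_bounds_rejected(self):
        pairs = pd.DataFrame({"chrom1": ["chr1"], "pos1": [999_999],
                              "chrom2": ["chr1"], "pos2": [5]})
        with pytest.raises(ValueError, match="pair 1"):
            H.bin_contacts(pairs, {"chr1": 100_000}, 10_000)


class TestBalance:
    def test_uniform_matrix_fixed_point(self):
        cm = H.ContactMatrix("chr1", 10, np.full((30, 30), 4.0))
        bal = H.balance(cm)
        ratio = bal.matrix / bal.matrix[0, 0]
        np.testing.assert_allclose(ratio, 1.0, atol=1e-9)

    def test_row_sums_equalized(self, rng):
        cm = H.ContactMatrix("chr1", 10, symmetric_random(40, rng))
        bal = H.balance(cm, tol=1e-8)
        s = bal.matrix.sum(axis=1)[~bal.mask]
        assert s.max() / s.min() <= 1 + 1e-6

    def test_matches_independent_sinkhorn_oracle(self):
        m = np.array([[4.0, 2, 1, 3], [2, 6, 2, 1],
                      [1, 2, 8, 2], [3, 1, 2, 5]])
        bal = H.balance(H.ContactMatrix("chr1", 10, m), tol=1e-12)
        # oracle: explicit alternating row/column scaling to row sums 1
        x = m.copy()
        for _ in range(10_000):
            r = x.sum(axis=1)
            x = x / np.sqrt(np.outer(r, r))
        np.testing.assert_allclose(bal.matrix, x, atol=1e-8)

    def test_symmetry_preserved(self, rng):
        bal = H.balance(H.ContactMatrix("chr1", 10, symmetric_random(25, rng)))
        np.testing.assert_allclose(bal.matrix, bal.matrix.T, atol=1e-9)

    def test_low_coverage_bins_masked(self, rng):
        m = symmetric_random(30, rng)
        m[3, :] = 0.0
        m[:, 3] = 0.0
        m[3, 3] = 0.1
        bal = H.balance(H.ContactMatrix("chr1", 10, m))
        assert bal.mask[3]
        assert (bal.matrix[3, :] == 0).all()


class TestDecay:
    def test_uniform_matrix_constant_expected(self):
        cm = H.ContactMatrix("chr1", 10, np.full((20, 20), 3.0))
        exp = H.expected_by_distance(cm)
        assert (exp["expected"] == 3.0).all()

    def test_fraction_curve_sums_to_one(self, rng):
        cm = H.ContactMatrix("chr1", 10, symmetric_random(50, rng))
        assert H.contact_fraction_curve(cm)["fraction"].sum() == pytest.approx(1.0)

    def test_planted_exponent_recovered(self, dataset, default_params):
        m = dataset.hic["wt"]["chr1"]
        cm = H.ContactMatrix("chr1", default_params.hic_bin_size, m)
        alpha = H.fit_decay_exponent(cm, d_max=100)
        assert alpha == pytest.approx(default_params.decay_exponent, rel=0.1)


class TestCompartments:
    def _planted(self, seed=0, strength=0.5):
        from tadscape.simulate import SimulationParams, make_genome, simulate_hic
        p = SimulationParams(seed=seed, compartment_strength=strength)
        g = make_genome(p)
        cm = H.ContactMatrix("chr1", p.hic_bin_size,
                             simulate_hic(g, p, "wt")["chr1"])
        bal = H.balance(cm)
        dens = np.zeros(cm.n_bins)
        sub = g.genes.query("chrom == 'chr1'")
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy() // p.hic_bin_size
        np.add.at(dens, mids, 1)
        planted = g.compartments.query("chrom == 'chr1'") \
            .sort_values("bin")["label"].to_numpy()
        return bal, dens, planted

    def test_planted_blocks_recovered(self):
        bal, dens, planted = self._planted(seed=23, strength=0.5)
        track = H.compartment_pc1(bal, dens)
        live = track.labels != ""
        assert (track.labels[live] == planted[live]).mean() >= 0.95

    def test_zero_strength_uninformative(self):
        bal, dens, planted = self._planted(seed=24, strength=0.0)
        track = H.compartment_pc1(bal, dens)
        live = track.labels != ""
        signed = np.where(planted[live] == "A", 1.0, -1.0)
        assert abs(np.corrcoef(track.pc1[live], signed)[0, 1]) < 0.3

    def test_orientation_flip_only_changes_labels(self):
        bal, dens, _ = self._planted(seed=23, strength=0.5)
        t1 = H.compartment_pc1(bal, dens)
        t2 = H.compartment_pc1(bal, -dens)
        live = t1.labels != ""
        np.testing.assert_allclose(np.abs(t1.pc1[live]), np.abs(t2.pc1[live]),
                                   atol=1e-12)
        flip = {"A": "B", "B": "A"}
        assert all(t2.labels[live][i] == flip[t1.labels[live][i]]
                   for i in range(int(live.sum())))

    def test_scale_invariance(self):
        bal, dens, _ = self._planted(seed=23, strength=0.5)
        scaled = H.ContactMatrix(bal.chrom, bal.bin_size, bal.matrix * 7.5,
                                 balanced=True, mask=bal.mask)
        t1, t2 = H.compartment_pc1(bal, dens), H.compartment_pc1(scaled, dens)
        live = t1.labels != ""
        np.testing.assert_allclose(t1.pc1[live], t2.pc1[live], atol=1e-9)


class TestPeScan:
    def test_window_shape_and_null(self, rng):
        cm = H.ContactMatrix("chr1", 10, symmetric_random(120, rng, lam=50))
        res = H.pe_scan(cm, np.array([20, 50, 80, 105]), flank=5)
        assert res.aggregate.shape == (11, 11)
        assert res.center_enrichment == pytest.approx(1.0, abs=0.2)

    def test_planted_anchor_affinity_recovered(self):
        from tadscape.simulate import simulate_anchor_matrix
        mat, anchors = simulate_anchor_matrix(seed=31, enrichment=2.0)
        bal = H.balance(H.ContactMatrix("chr1", 100_000, mat))
        res = H.pe_scan(bal, anchors, flank=5, min_sep=20, max_sep=280)
        assert res.center_enrichment == pytest.approx(2.0, rel=0.15)

    def test_no_eligible_pairs_sentinel(self, rng):
        cm = H.ContactMatrix("chr1", 10, symmetric_random(60, rng))
        assert H.pe_scan(cm, np.array([10, 12]), flank=2, min_sep=20) is None

    def test_anchor_spacing_precondition(self, rng):
        cm = H.ContactMatrix("chr1", 10, symmetric_random(60, rng))
        with pytest.raises(ValueError):
            H.pe_scan(cm, np.array([10, 40]), flank=5, min_sep=5)


class TestDomainScore:
    def test_block_diagonal_zero_inter(self):
        m = np.zeros((10, 10))
        m[2:5, 2:5] = 6.0
        cm = H.ContactMatrix("chr1", 10, m)
        rec = H.domain_score(cm, 20, 50, "t")
        intra = 6.0 * 6  # upper triangle of a 3x3 block
        assert rec.inter == 0.0
        assert rec.score == (intra + 1) / 1

    def test_uniform_closed_form(self):
        c, n_tad, n_chrom = 3.0, 4, 12
        cm = H.ContactMatrix("chr1", 10, np.full((n_chrom, n_chrom), c))
        rec = H.domain_score(cm, 0, 40, "t")
        assert rec.intra == c * n_tad * (n_tad + 1) / 2
        assert rec.inter == c * n_tad * (n_chrom - n_tad)
        assert rec.score == (rec.intra + 1) / (rec.inter + 1)

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(5):
            m = symmetric_random(30, rng)
            cm = H.ContactMatrix("chr1", 10, m)
            b0, b1 = 8, 17
            rec = H.domain_score(cm, b0 * 10, b1 * 10, "t")
            intra = sum(m[i, j] for i in range(b0, b1)
                        for j in range(i, b1))
            inter = sum(m[i, j] for i in range(b0, b1)
                        for j in range(30) if not b0 <= j < b1)
            assert rec.intra == pytest.approx(intra)
            assert rec.inter == pytest.approx(inter)

    def test_sub_bin_tad_skipped(self):
        cm = H.ContactMatrix("chr1", 10, np.ones((10, 10)))
        with pytest.warns(UserWarning, match="skipped"):
            assert H.domain_score(cm, 5, 12, "tiny") is None


class TestCompareDomainScores:
    def _records(self, scores, cond):
        return pd.DataFrame({"tad_id": [f"t{i}" for i in range(len(scores))],
                             "score": scores, "condition": cond})

    def test_identical_scores(self, rng):
        s = rng.uniform(1, 3, 50)
        res = H.compare_domain_scores(self._records(s, "wt"), self._records(s, "tko"))
        assert (res.deltas["delta"] == 0).all()
        assert res.p_value > 0.9

    def test_mismatched_tads_rejected(self):
        a = self._records([1.0, 2.0], "wt")
        b = self._records([1.0, 2.0, 3.0], "tko")
        with pytest.raises(ValueError, match="differ"):
            H.compare_domain_scores(a, b)

    def test_wilcoxon_matches_enumeration_oracle(self):
        # exact null distribution of the rank-sum by full enumeration, n,m <= 10
        wt = [1.2, 3.4, 2.2, 5.0, 4.1]
        tko = [0.9, 1.0, 2.0, 1.1]
        res = H.compare_domain_scores(
            self._records(wt, "wt").iloc[:4], self._records(tko, "tko"))
        x, y = wt[:4], tko
        pooled = x + y
        ranks = stats.rankdata(pooled)
        w_obs = ranks[: len(x)].sum()
        exp = ranks.mean() * len(x)
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(pooled)), len(x)):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - exp) >= abs(w_obs - exp) - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total, abs=0.02)

    def test_planted_shift_detected(self, dataset, genome, default_params):
        cms = {c: {k: H.ContactMatrix(k, default_params.hic_bin_size, v)
                   for k, v in dataset.hic[c].items()} for c in ("wt", "tko")}
        sc = {c: H.domain_scores(cms[c], genome.tads, c) for c in ("wt", "tko")}
        res = H.compare_domain_scores(sc["wt"], sc["tko"])
        assert res.p_value < 0.01
        assert res.deltas["delta"].median() < 0
        assert res.fraction_decreased > 0.5


class TestDeltaQuintiles:
    def test_planted_coupling_detected(self, dataset, genome, default_params):
        from tadscape import tads as T
        cms = {c: {k: H.ContactMatrix(k, default_params.hic_bin_size, v)
                   for k, v in dataset.hic[c].items()} for c in ("wt", "tko")}
        sc = {c: H.domain_scores(cms[c], genome.tads, c) for c in ("wt", "tko")}
        comp = H.compare_domain_scores(sc["wt"], sc["tko"])
        meth = dataset.methylation
        changes = {
            "meth": T.assign_sites_to_tads(meth[meth["truth"] != "null"], genome.tads),
            "dhs": T.assign_sites_to_tads(
                dataset.signal["dhs"][dataset.signal["dhs"]["truth"] != "none"],
                genome.tads)}
        out = H.delta_score_quintiles(genome.tads, comp.deltas, changes)
        tab = out["delta_score"]
        allc = tab[tab["feature"] == "all_changes"].set_index("bin")
        # altered TADs lose insulation (most negative delta -> bin 1)
        assert allc["pct"].idxmax() == 1
        assert allc["chisq_p"].iloc[0] < 0.01

    def test_uniform_changes_flat(self, small_tads, rng):
        deltas = pd.DataFrame({"tad_id": small_tads["tad_id"],
                               "delta": rng.normal(size=10)})
        counts = pd.Series(np.full(10, 40.0), index=small_tads.index)
        out = H.delta_score_quintiles(small_tads, deltas, {"x": counts})
        tab = out["delta_score"]
        assert (tab[tab["feature"] == "all_changes"]["pct"] == 20).all()

    def test_per_feature_rows_sum_to_100(self, small_tads, rng):
        deltas = pd.DataFrame({"tad_id": small_tads["tad_id"],
                               "delta": rng.normal(size=10)})
        counts = {"a": pd.Series(rng.poisson(5, 10).astype(float) + 1,
                                 index=small_tads.index),
                  "b": pd.Series(rng.poisson(3, 10).astype(float) + 1,
                                 index=small_tads.index)}
        out = H.delta_score_quintiles(small_tads, deltas, counts)
        for feat, grp in out["delta_score"].groupby("feature"):
            assert grp["pct"].sum() == pytest.approx(100, abs=1e-9)
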