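"""Weir-Cockerham F_ST, D_xy, windowed pi, and cluster ranking."""

import numpy as np
import pandas as pd
import pytest

from ldgraph import (
    GenotypeMatrix,
    PopPair,
    site_fst,
    weighted_fst,
    site_dxy,
    site_pi,
    windowed_stats,
    cluster_fst_ranking,
    cluster_sample_pca,
    MISSING,
)
from oracles import wc84_from_genotypes, pairwise_pi_bruteforce


def _gm(values, pops, pos=None, chroms=None):
    values = np.asarray(values, dtype=np.int8)
    n, p = values.shape
    sites = pd.DataFrame(
        {
            "chrom": chroms if chroms is not None else ["chr1"] * p,
            "pos": pos if pos is not None else np.arange(1, p + 1) * 10,
            "id": [f"s{i}" for i in range(p)],
            "ref": ["A"] * p,
            "alt": ["T"] * p,
            "qual": [50.0] * p,
            "n_alt": [1] * p,
        }
    )
    samples = [f"i{k}" for k in range(n)]
    return GenotypeMatrix(
        values=values,
        sample_ids=samples,
        pop_of_sample=dict(zip(samples, pops)),
        sites=sites,
    )


def _random_two_pop(seed, n_sites=20, n1=8, n2=12, missing=0.1):
    rng = np.random.default_rng(seed)
    vals = np.empty((n1 + n2, n_sites), dtype=np.int8)
    for j in range(n_sites):
        p1, p2 = rng.uniform(0.1, 0.9, 2)
        vals[:n1, j] = rng.binomial(2, p1, n1)
        vals[n1:, j] = rng.binomial(2, p2, n2)
    mask = rng.random(vals.shape) < missing
    vals[mask] = MISSING
    return _gm(vals, ["A"] * n1 + ["B"] * n2)


PAIR = PopPair("A", "B")


class TestSiteFst:
    def test_fixed_difference_is_one(self):
        vals = [[0] * 3] * 10 + [[2] * 3] * 10
        gm = _gm(vals, ["A"] * 10 + ["B"] * 10)
        out = site_fst(gm, PAIR)
        assert np.allclose(out["fst"], 1.0)

    def test_identical_populations_nonpositive(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.4, 10).astype(np.int8)
        vals = np.column_stack([col, col])
        gm = _gm(np.vstack([vals, vals]), ["A"] * 10 + ["B"] * 10)
        out = site_fst(gm, PAIR)
        assert (out["fst"].dropna() <= 1e-12).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wc84_transcription(self, seed):
        """Vectorized estimator equals the scalar 1984 component transcription to 1e-10."""
        gm = _random_two_pop(seed)
        out = site_fst(gm, PAIR)
        rows_a = gm.sample_indices_of_pop("A")
        rows_b = gm.sample_indices_of_pop("B")
        for _, row in out.iterrows():
            j = int(row["site"])
            a, b, c = wc84_from_genotypes(gm.values[rows_a, j], gm.values[rows_b, j])
            assert row["a"] == pytest.approx(a, abs=1e-10)
            assert row["d"] == pytest.approx(a + b + c, abs=1e-10)
            if a + b + c != 0:
                assert row["fst"] == pytest.approx(a / (a + b + c), abs=1e-10)

    def test_specified_count_configuration(self):
        # pop A: 6 hom-ref, 4 het; pop B: 2 hom-ref, 8 hom-alt
        vals = [[0]] * 6 + [[1]] * 4 + [[0]] * 2 + [[2]] * 8
        gm = _gm(vals, ["A"] * 10 + ["B"] * 10)
        out = site_fst(gm, PAIR)
        a, b, c = wc84_from_genotypes(
            np.array([0] * 6 + [1] * 4), np.array([0] * 2 + [2] * 8)
        )
        assert out["fst"].iloc[0] == pytest.approx(a / (a + b + c), abs=1e-10)

    def test_allele_relabel_invariance(self):
        gm = _random_two_pop(7, missing=0.0)
        flipped = _gm(2 - gm.values, [gm.pop_of_sample[s] for s in gm.sample_ids])
        f1 = site_fst(gm, PAIR)["fst"].to_numpy()
        f2 = site_fst(flipped, PAIR)["fst"].to_numpy()
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_small_side_rejected(self):
        gm = _gm([[0], [1], [2]], ["A", "B", "B"])
        with pytest.raises(ValueError):
            site_fst(gm, PAIR)


class TestWeightedFst:
    def test_single_site_equals_site_value(self):
        gm = _random_two_pop(1)
        out = site_fst(gm, PAIR)
        one = out.iloc[[0]]
        assert weighted_fst(one) == pytest.approx(one["fst"].iloc[0])

    def test_all_fixed_sites_give_one(self):
        vals = [[0] * 4] * 6 + [[2] * 4] * 6
        gm = _gm(vals, ["A"] * 6 + ["B"] * 6)
        assert weighted_fst(site_fst(gm, PAIR)) == pytest.approx(1.0)

    def test_ratio_of_sums_matches_oracle(self):
        gm = _random_two_pop(2, n_sites=10)
        out = site_fst(gm, PAIR)
        rows_a = gm.sample_indices_of_pop("A")
        rows_b = gm.sample_indices_of_pop("B")
        num = den = 0.0
        for j in out["site"]:
            a, b, c = wc84_from_genotypes(gm.values[rows_a, j], gm.values[rows_b, j])
            num += a
            den += a + b + c
        assert weighted_fst(out) == pytest.approx(num / den, abs=1e-10)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            weighted_fst(pd.DataFrame(columns=["a", "d"]))


class TestDxy:
    def test_fixed_alternate(self):
        vals = [[0]] * 5 + [[2]] * 5
        gm = _gm(vals, ["A"] * 5 + ["B"] * 5)
        assert site_dxy(gm, PAIR)["dxy"].iloc[0] == pytest.approx(1.0)

    def test_identical_monomorphic(self):
        gm = _gm([[0]] * 10, ["A"] * 5 + ["B"] * 5)
        assert site_dxy(gm, PAIR)["dxy"].iloc[0] == pytest.approx(0.0)

    def test_half_half(self):
        # p_a = p_b = 0.5 -> 0.5; brute force over inter-population allele draws
        vals = [[0]] * 2 + [[2]] * 2 + [[1]] * 4
        gm = _gm(vals, ["A"] * 4 + ["B"] * 4)
        d = site_dxy(gm, PAIR)["dxy"].iloc[0]
        alleles_a = [0, 0, 0, 0, 1, 1, 1, 1][:8]
        a_side = [0] * 4 + [1] * 4
        b_side = [0, 1] * 4
        brute = np.mean([[int(x != y) for y in b_side] for x in a_side])
        assert d == pytest.approx(brute) == pytest.approx(0.5)

    def test_symmetric_in_sides(self):
        gm = _random_two_pop(3)
        d1 = site_dxy(gm, PopPair("A", "B"))["dxy"].to_numpy()
        d2 = site_dxy(gm, PopPair("B", "A"))["dxy"].to_numpy()
        np.testing.assert_allclose(d1, d2, atol=1e-14)


class TestPiAndWindows:
    def test_monomorphic_pi_zero(self):
        gm = _gm([[0, 2]] * 6, ["A"] * 3 + ["B"] * 3)
        pi = site_pi(gm)
        assert np.allclose(pi["pi"], 0.0)

    def test_site_pi_matches_bruteforce(self):
        gm = _random_two_pop(4, n_sites=12)
        pi = site_pi(gm)
        for _, row in pi.iterrows():
            brute = pairwise_pi_bruteforce(gm.values[:, int(row["site"])])
            assert row["pi"] == pytest.approx(brute, abs=1e-10)

    def test_window_tiling_and_snp_bounds(self):
        # 3 windows of 1000 bp; counts 3, 2, 1
        pos = [10, 500, 900, 1100, 1900, 2500]
        gm = _gm(np.array([[0, 1, 2, 0, 1, 2]] * 6), ["A"] * 3 + ["B"] * 3, pos=pos)
        comp = site_fst(gm, PAIR)
        pi = site_pi(gm)
        persite = comp.merge(pi[["site", "pi"]], on="site")
        allw = windowed_stats(persite, window_bp=1000, apply_snp_bounds=False)
        assert allw["n_snps"].tolist() == [3, 2, 1]
        assert allw["start"].tolist() == [1, 1001, 2001]
        assert allw["n_snps"].sum() == len(comp)
        kept = windowed_stats(persite, window_bp=1000, min_snps=2, max_snps=2)
        assert kept["n_snps"].tolist() == [2]

    def test_window_pi_normalized_by_window_length(self):
        gm = _random_two_pop(5, n_sites=8, missing=0.0)
        pi = site_pi(gm)
        w = windowed_stats(pi, window_bp=1000, apply_snp_bounds=False)
        total = sum(
            pairwise_pi_bruteforce(gm.values[:, j]) for j in range(gm.n_snps)
        )
        assert w["pi"].iloc[0] == pytest.approx(total / 1000, abs=1e-10)

    def test_bad_window_size(self):
        with pytest.raises(ValueError):
            windowed_stats(pd.DataFrame({"chrom": [], "pos": []}), window_bp=0)


class TestClusterRanking:
    def test_single_cluster_equals_baseline_not_flagged(self):
        gm = _random_two_pop(6)
        comp = site_fst(gm, PAIR)
        table, baseline = cluster_fst_ranking(comp, np.ones(gm.n_snps, dtype=int))
        assert table["weighted_fst"].iloc[0] == pytest.approx(baseline)
        assert not table["above_baseline"].iloc[0]

    def test_differentiated_cluster_flagged(self):
        rng = np.random.default_rng(8)
        n = 40
        base = rng.binomial(2, 0.5, (n, 30)).astype(np.int8)
        # plant strong divergence in the first 10 sites
        base[: n // 2, :10] = rng.binomial(2, 0.05, (n // 2, 10))
        base[n // 2 :, :10] = rng.binomial(2, 0.95, (n // 2, 10))
        gm = _gm(base, ["A"] * (n // 2) + ["B"] * (n // 2))
        assign = np.array([1] * 10 + [2] * 20)
        comp = site_fst(gm, PAIR)
        table, baseline = cluster_fst_ranking(comp, assign)
        row = table[table["cluster_id"] == 1].iloc[0]
        assert row["above_baseline"]
        assert table["cluster_id"].iloc[0] == 1  # sorted by descending weighted F_ST

    def test_tie_broken_by_cluster_id(self):
        gm = _random_two_pop(9, n_sites=4, missing=0.0)
        # duplicate the 4 sites so clusters 1 and 2 see identical site sets
        vals = np.hstack([gm.values, gm.values])
        gm2 = _gm(vals, [gm.pop_of_sample[s] for s in gm.sample_ids])
        assign = np.array([1] * 4 + [2] * 4)
        comp = site_fst(gm2, PAIR)
        table, _ = cluster_fst_ranking(comp, assign, with_mannwhitney=False)
        assert table["weighted_fst"].iloc[0] == pytest.approx(table["weighted_fst"].iloc[1])
        assert table["cluster_id"].tolist()[:2] == [1, 2]

    def test_unscorable_cluster_flagged_missing(self):
        gm = _random_two_pop(10, n_sites=4, missing=0.0)
        vals = gm.values.copy()
        vals[:, 3] = MISSING
        gm2 = _gm(vals, [gm.pop_of_sample[s] for s in gm.sample_ids])
        assign = np.array([1, 1, 1, 2])
        table, _ = cluster_fst_ranking(site_fst(gm2, PAIR), assign)
        row = table[table["cluster_id"] == 2].iloc[0]
        assert row["missing"]
        assert np.isnan(row["weighted_fst"])


class TestClusterSamplePca:
    def test_fixed_difference_separates_groups(self):
        vals = [[0] * 5] * 8 + [[2] * 5] * 8
        gm = _gm(vals, ["A"] * 8 + ["B"] * 8)
        scores, expl = cluster_sample_pca(gm, np.ones(5, dtype=int), 1)
        pc1 = scores[:, 0]
        assert np.std(pc1[:8]) == pytest.approx(0.0, abs=1e-9)
        assert np.std(pc1[8:]) == pytest.approx(0.0, abs=1e-9)
        assert abs(pc1[0] - pc1[8]) > 1.0

    def test_duplicated_samples_identical_scores(self):
        gm = _random_two_pop(11, n_sites=6, missing=0.0)
        vals = np.vstack([gm.values, gm.values[:1]])
        gm2 = _gm(vals, [gm.pop_of_sample[s] for s in gm.sample_ids] + ["A"])
        scores, _ = cluster_sample_pca(gm2, np.ones(6, dtype=int), 1)
        np.testing.assert_allclose(scores[0], scores[-1], atol=1e-9)

    def test_degenerate_cluster_errors(self):
        gm = _gm([[0, 1]] * 6, ["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValueError, match="cluster 1"):
            cluster_sample_pca(gm, np.array([1, 2]), 1)


def test_fst_calibrated_on_balding_nichols():
    """Mean per-site F_ST over simulated sites is within 3 SE of the divergence parameter."""
    from ldgraph import SimConfig, ChromSpec, simulate_genotypes

    means = []
    for seed in range(3):
        cfg = SimConfig(
            n_per_pop=50,
            chroms=[ChromSpec("chr1", 1_000_000, 600)],
            background_fst=0.1,
            missing_rate=0.0,
            seed=seed,
        )
        gm, _ = simulate_genotypes(cfg)
        out = site_fst(gm, PopPair("pop1", "pop2"))
        means.append(out["fst"].dropna().mean())
    grand = np.mean(means)
    se = np.std(means, ddof=1) / np.sqrt(len(means)) + 1e-3
    assert abs(grand - 0.1) < max(3 * se, 0.03)
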