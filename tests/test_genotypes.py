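"""VCF input, genotype coding, and the hard site/genotype filters."""

import numpy as np
import pandas as pd
import pytest

from ldgraph import (
    GenotypeMatrix,
    FilterCriteria,
    apply_filters,
    read_vcf,
    write_clusters,
    read_clusters,
    simulate_genotypes,
    SimConfig,
    ChromSpec,
    write_vcf,
    write_pop_map,
    MISSING,
)


class TestReadVcf:
    def test_gt_codes_and_missing(self, toy_vcf):
        vcf, pops = toy_vcf
        gm = read_vcf(vcf, pops)
        # pos 100: 0/1 and 1/1 -> [1, 2]
        j = gm.sites.index[gm.sites["pos"] == 100][0]
        assert gm.values[:, j].tolist() == [1, 2]
        # pos 200: ./. -> missing
        j = gm.sites.index[gm.sites["pos"] == 200][0]
        assert gm.values[0, j] == MISSING
        assert gm.values[1, j] == 0

    def test_indel_kept_separately(self, toy_vcf):
        vcf, pops = toy_vcf
        gm = read_vcf(vcf, pops)
        assert 300 not in set(gm.sites["pos"])
        assert gm.indels is not None
        assert (gm.indels["pos"] == 300).any()

    def test_multiallelic_parsed_with_n_alt(self, toy_vcf):
        vcf, pops = toy_vcf
        gm = read_vcf(vcf, pops)
        row = gm.sites[gm.sites["pos"] == 400].iloc[0]
        assert row["n_alt"] == 2

    def test_unknown_sample_errors(self, toy_vcf, tmp_path):
        vcf, _ = toy_vcf
        bad = tmp_path / "bad_pops.tsv"
        bad.write_text("sample_id\tpopulation\ns1\tA\n")
        with pytest.raises(ValueError, match="s2"):
            read_vcf(vcf, bad)

    def test_non_diploid_errors(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t10\t.\tA\tT\t50\tPASS\t.\tGT\t1\n"
        )
        path = tmp_path / "hap.vcf"
        path.write_text(text)
        with pytest.raises(ValueError, match="chr1:10"):
            read_vcf(path, {"s1": "A"})

    def test_roundtrip_through_simulator_vcf(self, tmp_path):
        cfg = SimConfig(chroms=[ChromSpec("chr1", 100_000, 40)], seed=9)
        gm, _ = simulate_genotypes(cfg)
        write_vcf(gm, tmp_path / "sim.vcf")
        write_pop_map(gm, tmp_path / "pops.tsv")
        back = read_vcf(tmp_path / "sim.vcf", tmp_path / "pops.tsv")
        np.testing.assert_array_equal(back.values, gm.values)
        np.testing.assert_array_equal(back.depth, gm.depth)
        assert back.sample_ids == gm.sample_ids
        np.testing.assert_allclose(
            back.sites["qual"].to_numpy(), gm.sites["qual"].to_numpy(), atol=1e-6
        )


def _matrix(values, pos=None, qual=None, depth=None, pops=("A", "A", "B", "B"), indels=None):
    values = np.asarray(values, dtype=np.int8)
    n, p = values.shape
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * p,
            "pos": pos if pos is not None else np.arange(1, p + 1) * 100,
            "id": [f"s{i}" for i in range(p)],
            "ref": ["A"] * p,
            "alt": ["T"] * p,
            "qual": qual if qual is not None else [50.0] * p,
            "n_alt": [1] * p,
        }
    )
    samples = [f"i{k}" for k in range(n)]
    return GenotypeMatrix(
        values=values,
        sample_ids=samples,
        pop_of_sample=dict(zip(samples, pops[:n])),
        sites=sites,
        depth=np.asarray(depth, dtype=np.int32) if depth is not None else None,
        indels=pd.DataFrame(indels, columns=["chrom", "pos"]) if indels else None,
    )


class TestApplyFilters:
    def test_maf_threshold(self):
        # alt freq 1/16 = 0.0625 kept at 0.05; 0/16 dropped
        gm = _matrix([[1, 0], [0, 0], [0, 0], [0, 0]], pops="AABB")
        crit = FilterCriteria(min_maf=0.05, min_qual=0, indel_distance_bp=0)
        out, rep = apply_filters(gm, crit)
        assert out.n_snps == 1
        assert rep.removed_maf == 1

    def test_maf_uses_post_masking_frequencies(self):
        # freq 0.5 before masking; after masking the het carrier, freq 0 -> dropped
        gm = _matrix(
            [[1], [1], [1], [1]],
            depth=[[1], [1], [1], [1]],
        )
        out, rep = apply_filters(gm, FilterCriteria(min_qual=0))
        assert rep.masked_genotypes_depth == 4
        assert out.n_snps == 0

    def test_depth_masking_bounds(self):
        gm = _matrix(
            [[1, 1], [1, 1], [1, 1], [1, 1]],
            depth=[[1, 10], [25, 10], [10, 10], [10, 10]],
        )
        crit = FilterCriteria(
            min_maf=0, min_qual=0, max_missing_overall=1.0, max_missing_per_pop=1.0
        )
        out, rep = apply_filters(gm, crit)
        assert rep.masked_genotypes_depth == 2  # DP=1 and DP=25
        assert out.values[0, 0] == MISSING
        assert out.values[1, 0] == MISSING

    def test_qual_threshold(self):
        gm = _matrix([[1, 1], [0, 0], [1, 1], [0, 0]], qual=[24.0, 25.0])
        out, rep = apply_filters(gm, FilterCriteria(min_maf=0))
        assert rep.removed_qual == 1
        assert set(out.sites["qual"]) == {25.0}

    def test_missingness_overall_and_per_pop(self):
        vals = [
            [MISSING, MISSING],
            [MISSING, 1],
            [0, 0],
            [1, 1],
        ]
        gm = _matrix(vals)
        crit = FilterCriteria(
            min_maf=0, min_qual=0, max_missing_overall=0.5, max_missing_per_pop=0.5
        )
        # site 0: 50% overall but 100% within pop A -> dropped
        out, rep = apply_filters(gm, crit)
        assert rep.removed_missingness == 1
        assert out.n_snps == 1

    def test_indel_proximity(self):
        gm = _matrix(
            [[1, 1], [0, 1], [1, 0], [0, 0]],
            pos=[100, 500],
            indels=[("chr1", 108)],
        )
        out, rep = apply_filters(gm, FilterCriteria(min_maf=0, min_qual=0))
        assert rep.removed_indel_proximity == 1
        assert out.sites["pos"].tolist() == [500]

    def test_multiallelic_dropped(self):
        gm = _matrix([[1, 1], [0, 1], [1, 0], [0, 0]])
        gm.sites.loc[0, "n_alt"] = 2
        out, rep = apply_filters(gm, FilterCriteria(min_maf=0, min_qual=0))
        assert rep.removed_multiallelic == 1
        assert out.n_snps == 1

    def test_idempotent(self, small_blocks_dataset):
        gm, _, _ = small_blocks_dataset
        crit = FilterCriteria()
        once, rep1 = apply_filters(gm, crit)
        twice, rep2 = apply_filters(once, crit)
        np.testing.assert_array_equal(once.values, twice.values)
        assert rep2.sites_out == rep2.sites_in

    def test_post_filter_invariants(self, small_blocks_dataset):
        """Recomputed MAF and missing fractions respect the thresholds at every retained site."""
        gm, _, _ = small_blocks_dataset
        crit = FilterCriteria()
        out, _ = apply_filters(gm, crit)
        assert (out.maf() >= crit.min_maf).all()
        assert (out.missing_fraction() <= crit.max_missing_overall).all()
        for pop in out.populations:
            rows = out.sample_indices_of_pop(pop)
            frac = (out.values[rows] == MISSING).mean(axis=0)
            assert (frac <= crit.max_missing_per_pop).all()

    def test_empty_matrix_warns(self):
        gm = _matrix([[0], [0], [0], [0]])
        with pytest.warns(UserWarning, match="all sites removed"):
            out, rep = apply_filters(gm, FilterCriteria())
        assert out.n_snps == 0
        assert rep.sites_out == 0


class TestCriteriaValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"min_maf": 1.5},
            {"min_gt_depth": 30, "max_gt_depth": 20},
            {"indel_distance_bp": -1},
        ],
    )
    def test_invalid_criteria_rejected(self, kw):
        with pytest.raises(ValueError):
            FilterCriteria(**kw)


class TestClusterIO:
    def test_roundtrip(self, tmp_path, small_blocks_dataset):
        gm, _, _ = small_blocks_dataset
        chrom = np.arange(gm.n_snps) % 7 + 1
        genome = np.arange(gm.n_snps) % 3 + 1
        path = tmp_path / "clusters.tsv"
        write_clusters(gm, path, chrom, genome)
        back = read_clusters(path)
        assert back["chrom_cluster"].tolist() == chrom.tolist()
        assert back["genome_cluster"].tolist() == genome.tolist()
        assert back["pos"].tolist() == gm.sites["pos"].tolist()

    def test_single_cluster_and_empty(self, tmp_path):
        gm = _matrix([[0, 1], [1, 0], [1, 1], [0, 0]])
        df = write_clusters(gm, tmp_path / "one.tsv", np.ones(2, dtype=int))
        assert set(df["chrom_cluster"]) == {1}
        empty = gm.take_sites([])
        df2 = write_clusters(empty, tmp_path / "empty.tsv", np.zeros(0, dtype=int))
        assert len(df2) == 0
        assert read_clusters(tmp_path / "empty.tsv").shape[0] == 0

    def test_length_mismatch_errors(self, tmp_path):
        gm = _matrix([[0, 1], [1, 0], [1, 1], [0, 0]])
        with pytest.raises(IndexError):
            write_clusters(gm, tmp_path / "bad.tsv", np.ones(5, dtype=int))
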