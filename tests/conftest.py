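import numpy as np
import pytest

from ldgraph import SimConfig, ChromSpec, BlockSpec, simulate_genotypes


@pytest.fixture(scope="session")
def small_blocks_dataset():
    """60 samples, 1 chromosome x 120 SNPs with one neutral and one differentiated block."""
    cfg = SimConfig(
        chroms=[ChromSpec("chr1", 1_000_000, 120)],
        blocks=[
            BlockSpec("chr1", 10, 20, divergence_fst=0.3),
            BlockSpec("chr1", 60, 20),
        ],
        seed=42,
    )
    gm, truth = simulate_genotypes(cfg)
    return gm, truth, cfg


@pytest.fixture
def toy_vcf(tmp_path):
    """Hand-written VCF exercising GT codes, missing data, multiallelics and indels."""
    text = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT:DP\t0/1:10\t1/1:12
chr1\t200\t.\tG\tC\t50\tPASS\t.\tGT:DP\t./.:0\t0/0:9
chr1\t300\t.\tA\tAT\t50\tPASS\t.\tGT:DP\t0/1:10\t0/0:11
chr1\t305\t.\tC\tG\t50\tPASS\t.\tGT:DP\t0/1:10\t0/1:8
chr1\t400\t.\tA\tT,G\t50\tPASS\t.\tGT:DP\t0/1:10\t1/2:9
chr1\t500\t.\tT\tA\t50\tPASS\t.\tGT:DP\t1/1:15\t0/1:7
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    pop_path = tmp_path / "pops.tsv"
    pop_path.write_text("sample_id\tpopulation\ns1\tA\ns2\tB\n")
    return path, pop_path
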