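# ldgraph — unsupervised LD graph learning for population genomics

`ldgraph` identifies groups of SNPs that carry a shared genetic-differentiation
signal, directly from a multi-sample VCF, without any outlier test or
environmental covariate. It is aimed at population-genomic studies of
non-model organisms — for example, resequencing panels of a few dozen diploid
individuals from populations spanning an environmental gradient — where the
question is *which sets of loci move together*, not just which single site has
an extreme statistic.

## The method

The core idea is to estimate a sparse **linkage-disequilibrium (LD) graph**
over SNPs by neighborhood selection, cluster it into LD blocks, and rank the
blocks by population differentiation. It runs in two stages:

1. **Chromosome-wise LD graph.** Each SNP *j* on a chromosome (genotypes
   coded *x<sub>ij</sub>* = 0, 1, 2) is treated as a categorical response and
   regressed on all other SNPs of that chromosome with an L1-penalized
   multinomial logistic regression. The shrinkage λ is chosen by an
   information criterion along a geometric 100-point grid from λ<sub>max</sub>
   down to 0.01 λ<sub>max</sub>. SNP *l* is a neighbor of *j* when its
   coefficient block is nonzero (Σ<sub>k</sub> β<sub>kl</sub>² > 0). Per-SNP
   neighbor sets are symmetrized into an undirected, unweighted adjacency
   matrix *A* (default: mutual selection required), and walktrap community
   detection (short random walks, agglomerative merging, maximum-modularity
   cut) partitions the graph into LD blocks.
2. **Genome-wide cluster graph.** Each block is reduced to the leading
   principal components that cumulatively explain 80% of its genetic
   variance. The first PC of every block is regressed on all PCs of all other
   blocks under a group-LASSO penalty with one group per block, again with
   criterion-selected shrinkage; selected blocks become edges of a
   block-level graph, and walktrap on that graph yields genome-wide SNP
   clusters.

Clusters are then ranked by **weighted Weir–Cockerham F<sub>ST</sub>**
(ratio of summed variance components, Σa / Σ(a+b+c)) between two population
groups, against the genome-wide baseline; per-site F<sub>ST</sub>,
D<sub>xy</sub>, windowed π (non-overlapping 100-kb windows, 15–205 SNPs per
window) and per-cluster sample PCA are provided alongside.

A seedable synthetic-genotype generator (Balding–Nichols background +
haplotype-pool LD blocks with controllable within-block r² and between-group
divergence) makes the whole method testable without external data.

## Worked example

```python
from ldgraph import (SimConfig, ChromSpec, BlockSpec, simulate_genotypes,
                     GenomeWideLDBlocks, evaluate_recovery,
                     PopPair, site_fst, cluster_fst_ranking)

cfg = SimConfig(
    chroms=[ChromSpec("chr1", 1_000_000, 150), ChromSpec("chr2", 1_000_000, 150)],
    blocks=[BlockSpec("chr1", 40, 30, divergence_fst=0.3)],   # one adaptive block
    background_fst=0.02,
    seed=3,
)
gm, truth = simulate_genotypes(cfg)

model = GenomeWideLDBlocks().fit(gm.values, chromosomes=gm.sites["chrom"].to_numpy())
print(evaluate_recovery(truth, model.labels_)["ari_background_singletons"])

comp = site_fst(gm, PopPair("pop1", "pop2"))
table, baseline = cluster_fst_ranking(comp, model.labels_)
print(f"genome-wide weighted FST = {baseline:.4f}")
print(table.head(3)[["cluster_id", "n_snps", "weighted_fst", "above_baseline"]])
```

Output:

```
0.9885237910639099
genome-wide weighted FST = 0.0899
   cluster_id  n_snps  weighted_fst  above_baseline
0          41      30      0.447802            True
1         209       1      0.275248            True
2          39       1      0.233455            True
```

The planted 30-SNP block is recovered intact as genome-wide cluster 41
(adjusted Rand index 0.99 against the planted truth) and tops the
F<sub>ST</sub> ranking at 0.448, well above the genome-wide baseline of
0.090 — the clusters just below it are single background SNPs with extreme
site estimates, which is exactly why ranking whole multi-SNP clusters rather
than single sites is informative.

The same pipeline runs from the shell:

```bash
ldgraph simulate --seed 3 --out sim/
ldgraph run-all sim/genotypes.vcf sim/pop_map.tsv --out run/ \
        --pop-a pop1 --pop-b pop2 --truth sim/truth.tsv
```

which writes the cluster table (`clusters.tsv`), graphs (GraphML/edge lists),
per-site/window/cluster differentiation tables, recovery metrics and the
resolved configuration into `run/`.

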