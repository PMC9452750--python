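# Methods

## Model and procedure

### Genotype model and filtering

Genotypes are diploid biallelic dosages *x<sub>ij</sub>* ∈ {0, 1, 2}
(hom-ref, het, hom-alt) with an explicit missing code. VCF input is read
through cyvcf2; indel records are retained only as positions for the
proximity filter. Hard filters are applied in a fixed order so the
per-criterion removal counts are reproducible: (1) SNPs within 10 bp of an
indel on the same chromosome (|ΔPOS|, both coordinates 1-based); (2)
biallelic sites only (multiallelic records dropped, not split); (3)
genotypes with FORMAT/DP outside [2, 20] masked to missing (absent DP counts
as 0); (4) sites with > 50% missing genotypes overall or within any
population dropped; (5) site QUAL < 25 dropped (missing QUAL passes); (6)
minor allele frequency < 0.05 dropped, with MAF computed on non-missing
alleles *after* depth masking — masking changes allele counts, so computing
MAF first would let sites slip below the threshold unnoticed. Filtering is
idempotent by construction.

### Stage 1: chromosome-wise neighborhood selection

For each SNP *j* on a chromosome, the class indicator of *x<sub>ij</sub>* is
regressed on all other SNPs of the chromosome by L1-penalized multinomial
(softmax) logistic regression. Details:

* Missing predictor cells are mean-imputed per SNP; rows where the *target*
  is missing are dropped (the class indicator must be observed). Constant
  columns are excluded and become isolated graph nodes. Targets with one
  observed genotype class are skipped; two observed classes use the binomial
  special case of the same solver.
* Predictors are standardized (mean 0, variance 1) inside each regression so
  λ is comparable across SNPs; only the zero/nonzero coefficient pattern is
  consumed.
* The solver is FISTA with groupwise-exact soft-thresholding, sequential
  strong-rule screening and full KKT verification, warm-started along a
  geometric grid of 100 λ values from λ<sub>max</sub> (smallest λ with the
  all-zero solution) to 0.01 λ<sub>max</sub>. The intercepts are unpenalized.
  Solutions agree with scikit-learn's saga L1 solver to the support and to
  ~10⁻⁴ in coefficients (tested).
* λ is selected by an information criterion evaluated at the penalized
  solution: score = κ·df − 2·loglik, with df the number of **selected
  predictors** (the multinomial df convention used by glmnet's report) and
  κ = 2 (`criterion="aic"`), log n (`"bic"`, the stage-1 default) or
  log n + 2γ log p (`"ebic"`, γ = 0.5, with p the candidate count).
* SNP *l* joins the neighbor set of *j* when Σ<sub>k</sub> β<sub>kl</sub>² > 0
  at the selected λ. Edges require **mutual** selection by default
  (`symmetrize="and"`); an `"or"` rule is available.

Why these defaults and not the plain penalized-likelihood AIC with
entry-counted df: in the n ≈ 60–100, p ≈ 200–1000 regime of the intended
data, the fixed AIC price of 2 per coefficient is far below the likelihood
gain available from the maximum of hundreds of chance correlations, so
AIC-over-the-path selects tens of spurious neighbors per SNP and the "null"
graph on truly independent SNPs comes out ~10% dense (we confirmed the same
behavior in glmnet). BIC prices a predictor at log n, which rejects chance
maxima while keeping genuinely linked SNPs, whose likelihood gain is an
order of magnitude larger. Counting selected *variables* rather than
coefficient entries matters because the LASSO spreads mass across groups of
highly collinear SNPs — an LD block entering the path as 19 near-duplicates
is one effective predictor, not 57 parameters. Mutual selection ("and")
suppresses the remaining one-directional chance edges: a background SNP may
select its best chance correlate out of a thousand candidates, but the
correlate's own regression almost never selects it back, whereas SNPs in a
real block select each other. Without this rule, walktrap absorbs every
pendant false edge into a block community and recovery degrades sharply.

Walktrap (4 random-walk steps, maximum-modularity cut; igraph's C
implementation) partitions the graph into LD blocks. Isolated nodes become
singleton clusters; walktrap runs on the non-isolated subgraph since random
walks are undefined on degree-0 vertices. The per-SNP regressions are
independent, so the graph is identical for any execution order or worker
count.

### Stage 2: genome-wide cluster graph

Each chromosome-wise cluster is reduced by PCA of its mean-imputed,
standardized genotype submatrix; the minimal set of leading PCs whose
cumulative explained variance reaches 80% (`var_threshold`) is retained.
Each PC's loading vector is oriented so that its largest-magnitude loading
is positive, removing sign ambiguity from determinism checks. A one-SNP
cluster contributes its standardized column.

The first PC of each cluster *j* is regressed on all retained PCs of all
other clusters under a group-LASSO penalty, one group per cluster,
unweighted by group size as specified (a √m<sub>l</sub> weight is available
via `weight_by_group_size`). The solver is block proximal gradient (FISTA)
with a groupwise soft-threshold prox, groupwise strong-rule screening and
KKT checks, converging when the relative objective change falls below 10⁻⁸
(cap 10,000 iterations). Predictor PCs are standardized to unit variance so
groups with different PC counts are comparable.

Shrinkage selection uses a Mallows-Cp-type score RSS/σ₀² + κ·df with σ₀²
the response variance (null-model RSS/n). The naive Gaussian
AIC = n log(RSS/n) + 2 df is unusable here: with more candidate PCs than
samples the path reaches near-interpolation, where log(RSS/n) → −∞ swamps
any penalty and the criterion always picks the saturated fit. Normalizing
by the *null* variance keeps the score bounded below by the penalty. The
stage-2 default is the extended-BIC κ (γ = 0.5), correcting for the number
of candidate clusters scanned; selections are symmetrized with the **or**
rule, because the group LASSO picks a minimal representative among collinear
cluster fragments (one fragment of a split block selects the core, the core
does not select every fragment back) and a mutual rule would disconnect
them.

Genome-wide clusters are the **connected components** of the block graph by
default (`genome_clustering="components"`; walktrap is available as an
option). The reasoning: a block-level edge has survived two rounds of
penalized selection — it is strong evidence of shared signal, not a noisy
candidate — and the selection graph over a set of near-collinear fragments
is a sparse representative skeleton (hub-and-spoke or chain shaped), whose
tree-like parts a maximum-modularity cut severs even when every pairwise
first-PC correlation exceeds 0.95. Components merge all fragments of a
split block without, in our checks, pulling in any background cluster.
Every SNP inherits its block's genome-wide id, so the genome-wide
clustering is a coarsening of the chromosome-wise one — blocks merge,
never split. The two stages thus play complementary roles: stage 1 is
deliberately conservative (clean cores, some fragments), stage 2 re-links
fragments through their near-collinear PCs.

### Differentiation statistics

* **F<sub>ST</sub>**: Weir & Cockerham (1984) two-level variance components
  a, b, c computed from per-side sample sizes, allele frequencies and
  observed heterozygosity on non-missing genotypes. Per-site estimate
  a/(a+b+c) (negative values retained); "weighted" F<sub>ST</sub> over any
  site set is Σa / Σ(a+b+c). A side of the comparison may be one population
  or a pooled group of populations. Sites need at least one non-missing
  genotype on each side and three overall to be scored; monomorphic sites
  keep zero components and a NaN ratio.
* **D<sub>xy</sub>** = p<sub>a</sub>(1−p<sub>b</sub>) + p<sub>b</sub>(1−p<sub>a</sub>),
  the expected difference between one allele drawn from each side.
* **π** per site = 2p(1−p)·2n/(2n−1) on observed allele counts — equal to
  the mean pairwise difference among the 2n observed alleles.
* **Windows**: non-overlapping, tiling each chromosome from position 1 in
  half-open steps of 100 kb; windows with fewer than 15 or more than 205
  SNPs are excluded. Windowed F<sub>ST</sub> is the ratio of summed
  components; D<sub>xy</sub> the mean over scored variant sites (per-site,
  not per-bp — note this differs from a per-bp normalization when comparing
  across window SNP densities); π the per-site sum divided by the window
  length in bp.
* **Cluster ranking**: weighted F<sub>ST</sub> per genome-wide cluster,
  flagged when strictly above the genome-wide baseline, sorted descending
  with ties broken by cluster id. A two-sided Mann–Whitney p-value of the
  cluster's per-site values against all other sites is attached as a
  convenience screen, not a calibrated test. Per-cluster sample PCA (PC1/2
  scores) supports visual checks of group separation.

### Synthetic data

The generator emulates the structure the method assumes, with one integer
seed driving everything:

* **Background SNPs** are mutually independent given population allele
  frequencies: ancestral frequency ~ Uniform(0.05, 0.5), per-population
  frequencies from the Balding–Nichols beta model at `background_fst`
  (default 0.02), genotypes Binomial(2, p). This defines the null graph for
  sparsity checks.
* **LD blocks** use a haplotype-pool model: a pool of `n_haplotypes`
  (default 4) haplotypes derived from two complementary lineages with
  per-site mutation noise ε = (1 − r²<sub>target</sub><sup>1/4</sup>)/2, so
  the expected pairwise within-block r² ≈ the target (default 0.9). Each
  individual draws two haplotypes; the ancestral alt-lineage frequency is
  drawn from Uniform(0.35, 0.65). For a *differentiated* block the group
  lineage frequencies are planted deterministically at
  q<sub>anc</sub> ± √(F·q<sub>anc</sub>(1−q<sub>anc</sub>)) (sign
  randomized, alternating across groups), which realizes a two-group
  parametric F<sub>ST</sub> equal to `divergence_fst` in expectation at
  every block site. A random per-group draw (e.g. Balding–Nichols) would
  leave the *realized* divergence of a single block anywhere between 0 and
  fixation — a planted "differentiated" block could then be undetectable
  by construction, which defeats the purpose of planting it.
* **Metadata**: uniform genotype missingness (default 5%),
  negative-binomial per-genotype depth (mean 10, dispersion 5), Gaussian
  site QUAL (60 ± 15, truncated at 0), evenly spaced positions. Output as
  VCF 4.2 (GT:DP, QUAL), truth TSV and config JSON; identical configs give
  byte-identical files.

What this generator does **not** emulate: recombination-map-driven LD decay
(blocks have sharp edges), demographic history, linked selection, batch or
sequencing-error structure, and correlated missingness. Passing tests
demonstrate that the estimator recovers the planted structure under this
idealized model at realistic sample sizes — not that it will reach the same
accuracy on real resequencing data, where block boundaries are soft and
background LD is nonzero.

Recovery is scored by adjusted Rand index against the planted partition,
reported under both background conventions (each background SNP its own
class — the stricter convention used in the acceptance checks — and
background as a single class), plus per-block recall/precision (a block is
"recovered" when one inferred cluster holds ≥ 80% of its SNPs and they make
up ≥ 50% of that cluster).

## Problem sizes used in the checks

End-to-end recovery runs 2 chromosomes × 500 SNPs with ten 20-SNP blocks at
n = 60 (10 seeds in the test suite, 5 in the acceptance script);
differentiated-block detection 2 × 150 SNPs with one 30-SNP block at
divergence 0.3; null sparsity n = 100, p = 200 (missingness 0 — the null is
a pure design matrix); walktrap reference agreement 25 random graphs of ≤ 50
nodes against R igraph's `cluster_walktrap` via Rscript.

## Numerical choices

* λ grids: 100 geometric points, `lambda_min_ratio` 0.01, both stages.
* Multinomial FISTA: tolerance 10⁻⁵ on the relative objective (checked
  every 10 iterations, adaptive restart), cap 1000 iterations per λ;
  Lipschitz constants from power iteration on the restricted design,
  cached while the active set is unchanged. Group LASSO: tolerance 10⁻⁸,
  cap 10,000.
* Path truncation: a λ path stops early once the fit saturates
  (loglik ≈ 0 / RSS ≈ 0) or the selected-predictor count exceeds a bound
  under which no later grid point can beat the already-seen optimum for the
  active criterion (κ·df alone exceeds the null score). This changes no
  selection, only runtime.
* Exact zeros come from the proximal step; a 10⁻¹⁰ guard absorbs
  floating-point residue at the λ<sub>max</sub> boundary.
* Degenerate inputs: empty chromosomes, single-class targets, zero-variance
  clusters and zero denominators are skipped or flagged rather than raised,
  except where the contract demands an error (unknown samples, non-diploid
  genotypes, id mismatches, degenerate PCA clusters).
* Determinism: no stage consumes random numbers at fit time; walktrap and
  all solvers are deterministic, PCA signs are fixed, and per-chromosome
  parallel results are reduced in chromosome order, so outputs are
  byte-identical across runs and worker counts. The simulator is
  bit-reproducible from its seed.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `n_lambda`, `lambda_min_ratio` | 100, 0.01 | shrinkage grid (both stages) |
| `criterion`, `df_mode` | `bic`, `variables` | stage-1 λ selection |
| `symmetrize` | `and` | stage-1 edge rule |
| `genome_criterion`, `ebic_gamma` | `ebic`, 0.5 | stage-2 λ selection |
| `genome_symmetrize` | `or` | stage-2 edge rule |
| `genome_clustering` | `components` | stage-2 cut: graph components or walktrap |
| `aic_direction` | `min` | flip to `max` to maximize the criterion |
| `walktrap_steps` | 4 | random-walk length |
| `var_threshold` | 0.8 | cumulative PC variance retained per block |
| `weight_by_group_size` | off | √m group-penalty weights |
| window `window_bp`, `min_snps`, `max_snps` | 100 000, 15, 205 | windowed statistics |
| filters | 10 bp, DP [2, 20], 50%, QUAL 25, MAF 0.05 | hard filters |

## Known limitations

* The information-criterion defaults were chosen for the n ≪ p regime; with
  thousands of samples, AIC-flavored selection becomes reasonable again and
  is available via the `criterion` switches.
* Very large LD blocks (block size approaching n) lose per-SNP likelihood
  headroom against the BIC price and may fragment at stage 1; stage 2
  usually re-links the fragments, but recovery of blocks much larger than
  the sample size is not guaranteed.
* Walktrap's maximum-modularity cut severs single bridge edges between
  internally dense communities — the reason the stage-2 default is
  connected components. With `genome_clustering="walktrap"`, a signal split
  across chromosomes merges reliably only when each chromosome contributes
  one clean cluster.
* Weighted F<sub>ST</sub> pools the populations within each group side;
  hierarchical (population-within-group) variance components are not
  modeled.
* The windowed D<sub>xy</sub> is a mean over analyzed variant sites;
  comparing it across regions with different SNP densities requires care.
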