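"""Genome-wide LD network over chromosome-wise clusters.

Each chromosome-wise LD block is reduced to the leading principal
components that cumulatively explain a fraction (default 80%) of its
genetic variance. Treating each block as a unit, the first PC of every
block is regressed on all PCs of all other blocks under a group-LASSO
penalty (one group per block, shrinkage chosen by Gaussian AIC); blocks
with a nonzero group become graph neighbors, the per-block selections are
OR-symmetrized, and walktrap on the block graph yields genome-wide SNP
clusters (each SNP inherits the genome-wide id of its block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator, ClusterMixin

from ._solvers import group_lasso_path
from .chrom_graph import ChromosomeLDBlocks, encode_missing
from .graph import LDGraph, Clustering, walktrap_cluster, relabel_dense

logger = logging.getLogger(__name__)


@dataclass
class ClusterPCSet:
    """Retained principal components of one chromosome-wise cluster.

    ``scores`` is (n_samples, m) with m the smallest number of leading PCs
    whose cumulative explained variance reaches the threshold; columns are
    centered, orthogonal, and sign-fixed (largest-|loading| entry positive).
    """

    cluster_id: int
    scores: np.ndarray
    explained: np.ndarray
    m: int


def _pca_scores(Xsub):
    """Centered/standardized PCA of a genotype submatrix; returns (scores, explained fractions)."""
    mu = Xsub.mean(axis=0)
    sd = Xsub.std(axis=0)
    keep = sd > 0.0
    if not keep.any():
        return None
    Z = (Xsub[:, keep] - mu[keep]) / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # sign convention: largest-magnitude loading of each PC is positive
    for k in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, i] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = S**2
    total = var.sum()
    if total == 0.0:
        return None
    return U * S, var / total


def compute_cluster_pcs(gm, clustering, var_threshold: float = 0.8):
    """PC-reduce every cluster of a chromosome-wise clustering.

    ``gm`` may be a GenotypeMatrix or a raw (n_samples, n_snps) array;
    missing cells are mean-imputed and columns standardized before the
    eigendecomposition. Clusters whose SNPs are all constant are dropped
    (with a warning) — they carry no variance to link.
    """
    from .genotypes import GenotypeMatrix

    if not 0.0 < var_threshold <= 1.0:
        raise ValueError("var_threshold must be in (0, 1]")
    X = gm.values if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    X = encode_missing(X)
    obs = ~np.isnan(X)
    col_mean = np.where(obs.any(axis=0), np.nanmean(X, axis=0), 0.0)
    X = np.where(obs, X, col_mean[None, :])
    assignment = clustering.assignment if isinstance(clustering, Clustering) else np.asarray(clustering)
    out = []
    for cid in np.unique(assignment):
        cols = np.flatnonzero(assignment == cid)
        res = _pca_scores(X[:, cols])
        if res is None:
            logger.warning("cluster %d is entirely zero-variance; dropped from genome stage", cid)
            continue
        scores, frac = res
        cum = np.cumsum(frac)
        m = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
        m = min(m, scores.shape[1])
        out.append(ClusterPCSet(cluster_id=int(cid), scores=scores[:, :m], explained=frac[:m], m=m))
    return out


@dataclass
class GroupLassoFit:
    """Group-LASSO linkage of one cluster to all others at the AIC-optimal shrinkage."""

    target_cluster: int
    group_norm2: dict  # other-cluster id -> sum_k alpha_lk^2
    selected_clusters: set
    lambda_selected: float
    aic: float
    df: int


def _gaussian_kappa(n, criterion, n_candidates, ebic_gamma):
    if criterion == "aic":
        return 2.0
    if criterion == "bic":
        return float(np.log(max(n, 2)))
    if criterion == "ebic":
        p_cand = n_candidates if n_candidates else 2
        return float(np.log(max(n, 2)) + 2.0 * ebic_gamma * np.log(max(p_cand, 2)))
    raise ValueError(f"unknown criterion {criterion!r}")


def gaussian_information_criterion(path, n, criterion="ebic", n_candidates=None, ebic_gamma=0.5):
    """Selection score for the Gaussian group-LASSO path.

    Mallows-Cp form RSS/sigma0^2 + kappa df with sigma0^2 the response
    variance (the null-model RSS/n) and kappa = 2 ('aic'), log n ('bic'),
    or log(n) + 2 gamma log(p) ('ebic', the extended-BIC correction for
    the p candidate predictors searched over). Normalizing by the null variance instead of the per-lambda
    RSS keeps the score bounded below by the penalty, so near-interpolating
    solutions (always reachable when the PC count exceeds n) cannot drag
    the criterion to -infinity.
    """
    rss0 = path["rss"][0]
    sigma0 = rss0 / n if rss0 > 0 else 1.0
    kappa = _gaussian_kappa(
        n, criterion, n_candidates if n_candidates else path["coef"].shape[1], ebic_gamma
    )
    return path["rss"] / sigma0 + kappa * path["df"]


def fit_cluster_group_lasso(
    pcsets,
    j,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    criterion: str = "ebic",
    ebic_gamma: float = 0.5,
    aic_direction: str = "min",
    weight_by_group_size: bool = False,
) -> GroupLassoFit:
    """Regress cluster ``j``'s first PC on all PCs of all other clusters.

    One penalty group per other cluster; predictors are standardized to
    unit variance so groups with different PC counts are comparable. The
    shrinkage is chosen by :func:`gaussian_information_criterion`. With
    ``weight_by_group_size`` the penalty of group l is scaled by sqrt(m_l)
    (off by default: unweighted penalty).
    """
    byid = {ps.cluster_id: ps for ps in pcsets}
    if j not in byid:
        raise KeyError(f"cluster {j} has no PC set")
    others = [ps for ps in pcsets if ps.cluster_id != j]
    empty = GroupLassoFit(
        target_cluster=j,
        group_norm2={},
        selected_clusters=set(),
        lambda_selected=np.nan,
        aic=np.nan,
        df=0,
    )
    if not others:
        return empty
    z = byid[j].scores[:, 0]
    n = z.shape[0]
    cols, groups, wmap = [], [], {}
    for ps in others:
        S = ps.scores
        sd = S.std(axis=0)
        ok = sd > 0.0
        if not ok.any():
            continue
        cols.append((S[:, ok] - S[:, ok].mean(axis=0)) / sd[ok])
        groups.extend([ps.cluster_id] * int(ok.sum()))
        wmap[ps.cluster_id] = np.sqrt(float(ok.sum())) if weight_by_group_size else 1.0
    if not cols:
        return empty
    Z = np.hstack(cols)
    if z.std() == 0.0:
        return empty
    kappa = _gaussian_kappa(n, criterion, Z.shape[1], ebic_gamma)
    path = group_lasso_path(
        Z,
        z,
        np.asarray(groups),
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        group_weights=np.array([wmap[g] for g in sorted(wmap)])
        if weight_by_group_size
        else None,
        dfmax=min(n, int(2.0 * n / kappa) + 2),
    )
    ic = gaussian_information_criterion(
        path, n, criterion, n_candidates=Z.shape[1], ebic_gamma=ebic_gamma
    )
    best = int(np.argmin(ic)) if aic_direction == "min" else int(np.argmax(ic))
    gnorm = dict(zip(path["group_ids"].tolist(), path["groupnorm2"][best]))
    selected = {g for g, v in gnorm.items() if v > 0.0}
    return GroupLassoFit(
        target_cluster=j,
        group_norm2=gnorm,
        selected_clusters=selected,
        lambda_selected=float(path["lambdas"][best]),
        aic=float(ic[best]),
        df=int(path["df"][best]),
    )


def _stack_pcsets(pcsets, weight_by_group_size=False):
    """Standardized PC predictor matrix over all clusters, with group labels."""
    cols, groups, wmap = [], [], {}
    for ps in pcsets:
        S = ps.scores
        sd = S.std(axis=0)
        ok = sd > 0.0
        if not ok.any():
            continue
        cols.append((S[:, ok] - S[:, ok].mean(axis=0)) / sd[ok])
        groups.extend([ps.cluster_id] * int(ok.sum()))
        wmap[ps.cluster_id] = np.sqrt(float(ok.sum())) if weight_by_group_size else 1.0
    if not cols:
        return None, None, None
    return np.hstack(cols), np.asarray(groups), wmap


def build_genomewide_graph(
    pcsets,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    criterion: str = "ebic",
    ebic_gamma: float = 0.5,
    symmetrize: str = "or",
    aic_direction: str = "min",
    weight_by_group_size: bool = False,
    return_fits: bool = False,
):
    """One node per chromosome-wise cluster; symmetrized group-LASSO edges.

    ``symmetrize='and'`` requires mutual selection; ``'or'`` keeps an edge
    when either cluster's regression selects the other.
    """
    ids = [ps.cluster_id for ps in pcsets]
    index_of = {cid: i for i, cid in enumerate(ids)}
    Zall, gall, wmap = _stack_pcsets(pcsets, weight_by_group_size)
    fits = []
    for ps in pcsets:
        cid = ps.cluster_id
        empty = GroupLassoFit(
            target_cluster=cid,
            group_norm2={},
            selected_clusters=set(),
            lambda_selected=np.nan,
            aic=np.nan,
            df=0,
        )
        if Zall is None:
            fits.append(empty)
            continue
        mask = gall != cid
        if not mask.any() or ps.scores[:, 0].std() == 0.0:
            fits.append(empty)
            continue
        Z = Zall[:, mask]
        groups = gall[mask]
        z = ps.scores[:, 0]
        kappa = _gaussian_kappa(len(z), criterion, Z.shape[1], ebic_gamma)
        # a model with kappa*df > the null score n can never win; stop the
        # path shortly after that point (factor 2 slack)
        dfmax = min(len(z), int(2.0 * len(z) / kappa) + 2)
        path = group_lasso_path(
            Z,
            z,
            groups,
            n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
            group_weights=np.array([wmap[g] for g in sorted(set(groups.tolist()))])
            if weight_by_group_size
            else None,
            dfmax=dfmax,
        )
        ic = gaussian_information_criterion(
            path, len(z), criterion, n_candidates=Z.shape[1], ebic_gamma=ebic_gamma
        )
        best = int(np.argmin(ic)) if aic_direction == "min" else int(np.argmax(ic))
        gnorm = dict(zip(path["group_ids"].tolist(), path["groupnorm2"][best]))
        fits.append(
            GroupLassoFit(
                target_cluster=cid,
                group_norm2=gnorm,
                selected_clusters={g for g, v in gnorm.items() if v > 0.0},
                lambda_selected=float(path["lambdas"][best]),
                aic=float(ic[best]),
                df=int(path["df"][best]),
            )
        )
    sel = {f.target_cluster: f.selected_clusters for f in fits}
    edges = set()
    for f in fits:
        a = index_of[f.target_cluster]
        for other in f.selected_clusters:
            if symmetrize == "or" or f.target_cluster in sel.get(other, set()):
                b = index_of[other]
                edges.add((min(a, b), max(a, b)))
    g = LDGraph(n_nodes=len(ids), edges=edges, node_labels=ids)
    if return_fits:
        return g, fits
    return g


def cluster_genomewide(
    g: LDGraph,
    chrom_clustering: Clustering,
    steps: int = 4,
    method: str = "components",
) -> Clustering:
    """Re-cluster the block graph; SNPs inherit their block's genome-wide id.

    ``method='components'`` (default) merges every connected component of
    the block graph into one genome-wide cluster: a block-level edge has
    already survived two rounds of penalized selection, so it is strong
    evidence of shared signal, and the block graph over near-collinear
    fragments is a sparse representative skeleton whose tree-like parts a
    maximum-modularity cut would sever. ``method='walktrap'`` applies the
    same community detection as the chromosome stage instead.

    Either way the result is a coarsening of the chromosome-wise
    clustering: blocks are merged, never split.
    """
    node_ids = g.node_labels
    if node_ids is None:
        raise ValueError("cluster graph must carry cluster ids as node labels")
    node_ids = [int(x) for x in node_ids]
    present = set(node_ids)
    chrom_ids = set(np.unique(chrom_clustering.assignment).tolist())
    if not present.issubset(chrom_ids):
        raise ValueError("cluster graph nodes do not match chromosome-wise cluster ids")
    if method == "components":
        memb = np.asarray(g.to_igraph().connected_components().membership)
        assignment = memb + 1
        comm = Clustering(assignment=assignment, level="genome")
    elif method == "walktrap":
        comm = walktrap_cluster(g, steps=steps, level="genome")
    else:
        raise ValueError("method must be 'components' or 'walktrap'")
    genome_of_cluster = {cid: comm.assignment[i] for i, cid in enumerate(node_ids)}
    # clusters dropped at the PC stage (all-constant) keep their own singleton id
    nxt = comm.n_clusters
    for cid in sorted(chrom_ids - present):
        nxt += 1
        genome_of_cluster[cid] = nxt
    snp_assign = np.array(
        [genome_of_cluster[int(c)] for c in chrom_clustering.assignment], dtype=int
    )
    return Clustering(assignment=snp_assign, level="genome")


class GenomeWideLDBlocks(ClusterMixin, BaseEstimator):
    """Two-stage LD graph learning: chromosome-wise blocks, then genome-wide clusters.

    Stage 1 runs :class:`ChromosomeLDBlocks` independently per chromosome
    (parallelizable; results identical for any worker count). Stage 2
    PC-reduces every block, links blocks genome-wide by group LASSO, and
    re-clusters with walktrap.

    Parameters
    ----------
    var_threshold : float, default=0.8
        Cumulative explained-variance fraction retained per block.
    criterion, symmetrize
        Stage-1 (per-SNP) shrinkage criterion and edge rule: BIC with
        mutual ('and') selection keeps collinear LD blocks densely
        connected while chance selections, which are rarely mutual, are
        dropped.
    genome_criterion, genome_symmetrize, genome_clustering, ebic_gamma
        Stage-2 (per-cluster) controls. Cluster-level selections are
        sparse within groups of collinear blocks (the group LASSO picks a
        minimal representative subset), so an 'or' rule is needed to keep
        split blocks linked; the extended-BIC penalty
        (log n + 2 gamma log p per coefficient) compensates for the many
        candidate clusters searched over.
    weight_by_group_size : bool, default=False
        Scale each block's penalty by sqrt(#PCs) instead of the unweighted
        penalty.
    n_jobs : int, default=1
        Parallelism over chromosomes (stage 1 only).
    Remaining parameters mirror :class:`ChromosomeLDBlocks`.

    Attributes
    ----------
    chrom_labels_ : ndarray
        Chromosome-wise cluster id per SNP, unique across chromosomes,
        dense from 1.
    labels_ : ndarray
        Genome-wide cluster id per SNP.
    cluster_graph_ : LDGraph
        The block-level graph.
    chrom_graphs_ : dict chrom -> LDGraph
    pcsets_ : list of ClusterPCSet
    """

    def __init__(
        self,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        criterion: str = "bic",
        df_mode: str = "variables",
        symmetrize: str = "and",
        genome_criterion: str = "ebic",
        genome_symmetrize: str = "or",
        genome_clustering: str = "components",
        ebic_gamma: float = 0.5,
        aic_direction: str = "min",
        walktrap_steps: int = 4,
        var_threshold: float = 0.8,
        weight_by_group_size: bool = False,
        tol: float = 1e-5,
        max_iter: int = 1000,
        n_jobs: int = 1,
    ):
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.criterion = criterion
        self.df_mode = df_mode
        self.symmetrize = symmetrize
        self.genome_criterion = genome_criterion
        self.genome_symmetrize = genome_symmetrize
        self.genome_clustering = genome_clustering
        self.ebic_gamma = ebic_gamma
        self.aic_direction = aic_direction
        self.walktrap_steps = walktrap_steps
        self.var_threshold = var_threshold
        self.weight_by_group_size = weight_by_group_size
        self.tol = tol
        self.max_iter = max_iter
        self.n_jobs = n_jobs

    def fit(self, X, y=None, chromosomes=None):
        """Fit on an (n_samples, n_snps) genotype array.

        ``chromosomes`` assigns each SNP column to a chromosome (defaults
        to a single chromosome).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x snps)")
        n, p = X.shape
        self.n_features_in_ = p
        if chromosomes is None:
            chromosomes = np.zeros(p, dtype=int)
        chromosomes = np.asarray(chromosomes)
        if chromosomes.shape[0] != p:
            raise ValueError("chromosomes length != number of SNP columns")
        chrom_order = list(dict.fromkeys(chromosomes.tolist()))

        def _one(ch):
            cols = np.flatnonzero(chromosomes == ch)
            est = ChromosomeLDBlocks(
                n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
                criterion=self.criterion,
                df_mode=self.df_mode,
                symmetrize=self.symmetrize,
                aic_direction=self.aic_direction,
                walktrap_steps=self.walktrap_steps,
                tol=self.tol,
                max_iter=self.max_iter,
            ).fit(X[:, cols])
            return ch, cols, est

        results = Parallel(n_jobs=self.n_jobs)(delayed(_one)(ch) for ch in chrom_order)
        # deterministic reduction in chromosome order regardless of worker count
        results = {ch: (cols, est) for ch, cols, est in results}
        chrom_labels = np.zeros(p, dtype=int)
        self.chrom_graphs_ = {}
        offset = 0
        for ch in chrom_order:
            cols, est = results[ch]
            chrom_labels[cols] = est.labels_ + offset
            offset = int(chrom_labels.max())
            self.chrom_graphs_[ch] = est.graph_
        self.chrom_labels_ = relabel_dense(chrom_labels)
        self.chrom_clustering_ = Clustering(self.chrom_labels_, level="chromosome")
        self.pcsets_ = compute_cluster_pcs(X, self.chrom_clustering_, self.var_threshold)
        self.cluster_graph_, self.group_fits_ = build_genomewide_graph(
            self.pcsets_,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            criterion=self.genome_criterion,
            ebic_gamma=self.ebic_gamma,
            symmetrize=self.genome_symmetrize,
            aic_direction=self.aic_direction,
            weight_by_group_size=self.weight_by_group_size,
            return_fits=True,
        )
        self.genome_clustering_ = cluster_genomewide(
            self.cluster_graph_,
            self.chrom_clustering_,
            steps=self.walktrap_steps,
            method=self.genome_clustering,
        )
        self.labels_ = self.genome_clustering_.assignment
        return self

    def fit_predict(self, X, y=None, **kw):
        return self.fit(X, y, **kw).labels_
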