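"""Population-differentiation statistics: Weir-Cockerham F_ST, D_xy, pi.

Implements the Weir & Cockerham (1984) two-level variance-components
estimator of F_ST from genotype counts (including the heterozygosity term),
absolute divergence D_xy, and nucleotide diversity pi, per site and in
non-overlapping windows, plus per-cluster weighted-F_ST ranking against the
genome-wide baseline and per-cluster sample PCA.

Conventions follow the common VCF-toolchain output: "weighted" F_ST is the
ratio of summed numerators to summed denominators; windowed pi divides the
summed per-site pi by the window length in bp; windowed D_xy averages over
the variant sites analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genotypes import MISSING, GenotypeMatrix
from .graph import Clustering


@dataclass
class PopPair:
    """Two disjoint sides of a comparison; each side is a population label or a group of labels."""

    pop_a: object
    pop_b: object

    def side_indices(self, gm: GenotypeMatrix):
        ia = gm.sample_indices_of_pop(self.pop_a)
        ib = gm.sample_indices_of_pop(self.pop_b)
        if set(ia) & set(ib):
            raise ValueError("the two sides of a PopPair must be disjoint")
        if len(ia) < 2 or len(ib) < 2:
            raise ValueError("each side of a PopPair needs >= 2 samples")
        return ia, ib


def _side_counts(values, rows):
    """Per-site (n non-missing, alt freq, het freq) for a sample subset."""
    sub = values[rows]
    obs = sub != MISSING
    n = obs.sum(axis=0).astype(float)
    alt = np.where(obs, sub, 0).sum(axis=0)
    het = ((sub == 1) & obs).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def site_fst(gm: GenotypeMatrix, pair: PopPair) -> pd.DataFrame:
    """Per-site Weir-Cockerham (1984) theta with its variance components.

    Returns a DataFrame with columns ``site`` (column index in ``gm``),
    ``chrom``, ``pos``, ``fst``, ``a`` (numerator) and ``d`` (denominator
    a+b+c). Sites scorable on fewer than two total genotypes, or with
    either side entirely missing, are absent. Monomorphic sites keep a
    NaN ratio with zero components (they add nothing to weighted sums).
    Negative estimates are retained.
    """
    ia, ib = pair.side_indices(gm)
    n1, p1, h1 = _side_counts(gm.values, ia)
    n2, p2, h2 = _side_counts(gm.values, ib)
    scorable = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)

    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        fst = np.where(denom != 0.0, a / denom, np.nan)

    idx = np.flatnonzero(scorable)
    return pd.DataFrame(
        {
            "site": idx,
            "chrom": gm.sites["chrom"].to_numpy()[idx],
            "pos": gm.sites["pos"].to_numpy()[idx],
            "fst": fst[idx],
            "a": a[idx],
            "d": denom[idx],
        }
    )


def weighted_fst(components: pd.DataFrame) -> float:
    """Ratio-of-sums F_ST over a site set: sum(a) / sum(a+b+c)."""
    if len(components) == 0:
        raise ValueError("weighted_fst needs at least one scorable site")
    num = float(components["a"].sum())
    den = float(components["d"].sum())
    if den == 0.0:
        warnings.warn("zero total denominator; weighted F_ST undefined", stacklevel=2)
        return float("nan")
    return num / den


def site_dxy(gm: GenotypeMatrix, pair: PopPair) -> pd.DataFrame:
    """Per-site absolute divergence d_xy = p_a(1-p_b) + p_b(1-p_a)."""
    ia, ib = pair.side_indices(gm)
    n1, p1, _ = _side_counts(gm.values, ia)
    n2, p2, _ = _side_counts(gm.values, ib)
    scorable = (n1 >= 1) & (n2 >= 1)
    dxy = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    idx = np.flatnonzero(scorable)
    return pd.DataFrame(
        {
            "site": idx,
            "chrom": gm.sites["chrom"].to_numpy()[idx],
            "pos": gm.sites["pos"].to_numpy()[idx],
            "dxy": dxy[idx],
        }
    )


def site_pi(gm: GenotypeMatrix, samples=None) -> pd.DataFrame:
    """Per-site nucleotide diversity 2p(1-p) * 2n/(2n-1) on non-missing alleles.

    ``samples`` restricts to a population label (or list); default all
    samples. Equals the mean pairwise allele difference among the 2n
    observed alleles.
    """
    rows = (
        np.arange(gm.n_samples) if samples is None else gm.sample_indices_of_pop(samples)
    )
    n, p, _ = _side_counts(gm.values, rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n > 0.5, 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0), np.nan)
    idx = np.flatnonzero(n >= 1)
    return pd.DataFrame(
        {
            "site": idx,
            "chrom": gm.sites["chrom"].to_numpy()[idx],
            "pos": gm.sites["pos"].to_numpy()[idx],
            "pi": pi[idx],
        }
    )


def windowed_stats(
    sites: pd.DataFrame,
    window_bp: int = 100_000,
    min_snps: int = 15,
    max_snps: int = 205,
    apply_snp_bounds: bool = True,
) -> pd.DataFrame:
    """Aggregate per-site statistics in non-overlapping windows.

    Windows tile each chromosome from position 1 in steps of ``window_bp``
    (half-open [start, start+window_bp)). Within a window, F_ST is the
    ratio of summed components, D_xy the mean over scored sites, and pi the
    summed per-site pi divided by the window length in bp. Windows whose
    SNP count falls outside [min_snps, max_snps] are excluded (disable with
    ``apply_snp_bounds=False``).

    ``sites`` must have chrom and pos plus any of the columns a/d (F_ST
    components), dxy, pi.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    recs = []
    for chrom, sub in sites.groupby("chrom", sort=True):
        widx = (sub["pos"].to_numpy() - 1) // window_bp
        for w in np.unique(widx):
            block = sub[widx == w]
            rec = {
                "chrom": chrom,
                "start": int(w) * window_bp + 1,
                "stop": (int(w) + 1) * window_bp,
                "n_snps": len(block),
            }
            if {"a", "d"}.issubset(block.columns):
                den = block["d"].sum()
                rec["weighted_fst"] = block["a"].sum() / den if den != 0 else np.nan
            if "dxy" in block.columns:
                rec["mean_dxy"] = float(block["dxy"].mean())
            if "pi" in block.columns:
                rec["pi"] = float(np.nansum(block["pi"].to_numpy())) / window_bp
            recs.append(rec)
    out = pd.DataFrame(recs)
    if apply_snp_bounds and len(out):
        out = out[(out["n_snps"] >= min_snps) & (out["n_snps"] <= max_snps)]
    return out.reset_index(drop=True)


def cluster_fst_ranking(
    components: pd.DataFrame,
    clustering,
    with_mannwhitney: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Weighted F_ST per cluster, flagged against the genome-wide baseline.

    ``components`` is the output of :func:`site_fst` (its ``site`` column
    indexes the clustering assignment). Returns (table, baseline) with the
    table sorted by descending weighted F_ST, ties broken by cluster id;
    clusters without scorable sites get NaN. ``above_baseline`` uses strict
    >. The optional two-sided Mann-Whitney p-value compares a cluster's
    per-site F_ST values against all other sites (a convenience screen, not
    a calibrated test).
    """
    assignment = (
        clustering.assignment if isinstance(clustering, Clustering) else np.asarray(clustering)
    )
    baseline = weighted_fst(components)
    cl = assignment[components["site"].to_numpy()]
    recs = []
    all_fst = components["fst"].to_numpy()
    for cid in np.unique(assignment):
        mask = cl == cid
        block = components[mask]
        if len(block) == 0 or block["d"].sum() == 0:
            recs.append(
                {
                    "cluster_id": int(cid),
                    "n_snps": int((assignment == cid).sum()),
                    "n_scored": len(block),
                    "weighted_fst": np.nan,
                    "above_baseline": False,
                    "missing": True,
                }
            )
            continue
        wf = block["a"].sum() / block["d"].sum()
        rec = {
            "cluster_id": int(cid),
            "n_snps": int((assignment == cid).sum()),
            "n_scored": len(block),
            "weighted_fst": wf,
            "above_baseline": bool(wf > baseline),
            "missing": False,
        }
        if with_mannwhitney:
            x = block["fst"].dropna().to_numpy()
            y = all_fst[~mask]
            y = y[~np.isnan(y)]
            if len(x) and len(y):
                rec["mannwhitney_p"] = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
            else:
                rec["mannwhitney_p"] = np.nan
        recs.append(rec)
    table = pd.DataFrame(recs).sort_values(
        ["weighted_fst", "cluster_id"], ascending=[False, True], na_position="last"
    )
    return table.reset_index(drop=True), baseline


def cluster_sample_pca(gm, clustering, cluster_id):
    """PCA of samples on one cluster's mean-imputed standardized genotypes.

    Returns (scores (n_samples, 2), explained fractions (2,)). Requires at
    least two polymorphic SNPs in the cluster.
    """
    from .genome_graph import _pca_scores
    from .chrom_graph import encode_missing

    assignment = (
        clustering.assignment if isinstance(clustering, Clustering) else np.asarray(clustering)
    )
    X = gm.values if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    cols = np.flatnonzero(assignment == cluster_id)
    Xf = encode_missing(X[:, cols])
    obs = ~np.isnan(Xf)
    col_mean = np.where(obs.any(axis=0), np.nanmean(Xf, axis=0), 0.0)
    Xf = np.where(obs, Xf, col_mean[None, :])
    poly = Xf.std(axis=0) > 0
    if poly.sum() < 2:
        raise ValueError(f"cluster {cluster_id} has fewer than 2 polymorphic SNPs")
    res = _pca_scores(Xf)
    scores, frac = res
    k = min(2, scores.shape[1])
    out = np.zeros((scores.shape[0], 2))
    out[:, :k] = scores[:, :k]
    expl = np.zeros(2)
    expl[:k] = frac[:k]
    return out, expl
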