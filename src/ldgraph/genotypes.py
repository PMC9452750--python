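"""Genotype containers, VCF input, and site/genotype filtering.

Genotypes are coded ``0`` (hom-ref), ``1`` (het), ``2`` (hom-alt) with ``-1``
for missing, in an ``n_samples x n_snps`` integer matrix. Per-genotype
sequencing depth (FORMAT/DP) and site QUAL are carried alongside so the
standard hard filters (depth masking, missingness, QUAL, MAF, indel
proximity, biallelic-only) can be applied after reading.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "qual", "n_alt"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic-SNP genotype matrix with site and sample metadata.

    Attributes
    ----------
    values : ndarray of int8, shape (n_samples, n_snps)
        Genotype codes {0, 1, 2} with -1 for missing.
    sample_ids : list of str
    pop_of_sample : dict
        Maps every sample id to its population label.
    sites : pandas.DataFrame
        Columns chrom, pos (1-based), id, ref, alt, qual, n_alt; sorted by
        (chrom, pos) and unique.
    depth : ndarray of int32 or None
        Per-genotype DP; -1 where absent.
    indels : pandas.DataFrame or None
        Positions (chrom, pos) of indel records retained for the proximity
        filter only.
    """

    values: np.ndarray
    sample_ids: list
    pop_of_sample: dict
    sites: pd.DataFrame
    depth: np.ndarray | None = None
    indels: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x snps)")
        bad = ~np.isin(self.values, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2} or missing (-1)")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("values rows != number of samples")
        if self.values.shape[1] != len(self.sites):
            raise ValueError("values columns != number of sites")
        missing_pop = [s for s in self.sample_ids if s not in self.pop_of_sample]
        if missing_pop:
            raise ValueError(f"samples without population label: {missing_pop}")
        self.sites = self.sites.reset_index(drop=True)
        key = list(zip(self.sites["chrom"], self.sites["pos"]))
        if sorted(set(key)) != key:
            raise ValueError("sites must be sorted by (chrom, pos) and unique")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.sites["chrom"]))

    @property
    def populations(self) -> list:
        return sorted(set(self.pop_of_sample[s] for s in self.sample_ids))

    def sample_indices_of_pop(self, pops) -> np.ndarray:
        """Row indices of samples whose population is in ``pops`` (label or list)."""
        if isinstance(pops, str):
            pops = [pops]
        pops = set(pops)
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.pop_of_sample[s] in pops],
            dtype=int,
        )

    def chrom_site_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.sites["chrom"] == chrom).to_numpy())

    def take_sites(self, idx) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            pop_of_sample=dict(self.pop_of_sample),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, idx],
            indels=None if self.indels is None else self.indels.copy(),
        )

    def alt_freq(self) -> np.ndarray:
        """Per-site alternate-allele frequency on non-missing genotypes (NaN if none)."""
        obs = self.values != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.values, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (self.values == MISSING).mean(axis=0)


@dataclass
class FilterCriteria:
    """Hard-filter thresholds applied by :func:`apply_filters`.

    Defaults are the conventional whole-genome resequencing values: drop
    SNPs within 10 bp of an indel, keep biallelic sites only, mask genotypes
    with depth outside [2, 20], drop sites with >50% missing data overall or
    within any population, require site QUAL >= 25 and MAF >= 0.05.
    """

    min_maf: float = 0.05
    max_missing_overall: float = 0.5
    max_missing_per_pop: float = 0.5
    min_gt_depth: int = 2
    max_gt_depth: int = 20
    min_qual: float = 25.0
    indel_distance_bp: int = 10
    biallelic_only: bool = True

    def __post_init__(self):
        for f in ("min_maf", "max_missing_overall", "max_missing_per_pop"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if self.min_gt_depth > self.max_gt_depth:
            raise ValueError("min_gt_depth must be <= max_gt_depth")
        if self.indel_distance_bp < 0:
            raise ValueError("indel_distance_bp must be >= 0")


@dataclass
class FilterReport:
    """Per-criterion removal/masking counts from one :func:`apply_filters` run."""

    sites_in: int = 0
    sites_out: int = 0
    removed_indel_proximity: int = 0
    removed_multiallelic: int = 0
    masked_genotypes_depth: int = 0
    removed_missingness: int = 0
    removed_qual: int = 0
    removed_maf: int = 0

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def read_pop_map(path) -> dict:
    """Read a sample->population TSV with columns ``sample_id``, ``population``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"}.issubset(df.columns):
        # headerless two-column fallback
        df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"], dtype=str)
    return dict(zip(df["sample_id"], df["population"]))


def read_vcf(path, pop_map) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Diploid GT fields map to 0/1/2 by alternate-allele count; any GT allele
    of '.' maps to missing. Indel records are not genotyped but their
    positions are retained for the indel-proximity filter. Multiallelic SNPs
    are kept (with ``n_alt`` recorded) so the biallelic filter can count
    them.

    Parameters
    ----------
    path
        VCF 4.x file, plain or bgzipped.
    pop_map
        Either a path to a TSV (columns sample_id, population) or a dict.
    """
    from cyvcf2 import VCF

    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in pop_map]
    if unknown:
        raise ValueError(f"VCF samples missing from population map: {unknown}")

    rows_gt, rows_dp, site_recs, indel_recs = [], [], [], []
    for var in vcf:
        alts = var.ALT or []
        is_indel = len(var.REF) != 1 or any(len(a) != 1 for a in alts) or not alts
        if is_indel:
            indel_recs.append((var.CHROM, var.POS))
            continue
        gts = var.genotypes
        codes = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid genotype for sample {samples[i]} at "
                    f"{var.CHROM}:{var.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                codes[i] = MISSING
            else:
                codes[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        dp = np.full(len(samples), -1, dtype=np.int32)
        try:
            raw = var.format("DP")
        except Exception:
            raw = None
        if raw is not None:
            raw = np.asarray(raw).reshape(len(samples), -1)[:, 0]
            ok = raw >= 0
            dp[ok] = raw[ok]
        rows_gt.append(codes)
        rows_dp.append(dp)
        site_recs.append(
            (
                var.CHROM,
                var.POS,
                var.ID or ".",
                var.REF,
                ",".join(alts),
                float(var.QUAL) if var.QUAL is not None else np.nan,
                len(alts),
            )
        )
    vcf.close()

    if site_recs:
        sites = pd.DataFrame(site_recs, columns=SITE_COLUMNS)
        values = np.stack(rows_gt, axis=1)
        depth = np.stack(rows_dp, axis=1)
    else:
        sites = pd.DataFrame(columns=SITE_COLUMNS)
        values = np.zeros((len(samples), 0), dtype=np.int8)
        depth = np.zeros((len(samples), 0), dtype=np.int32)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy())) if len(sites) else []
    if len(sites):
        sites = sites.iloc[order].reset_index(drop=True)
        values = values[:, order]
        depth = depth[:, order]
    indels = pd.DataFrame(indel_recs, columns=["chrom", "pos"]) if indel_recs else None
    return GenotypeMatrix(
        values=values,
        sample_ids=samples,
        pop_of_sample={s: pop_map[s] for s in samples},
        sites=sites,
        depth=depth,
        indels=indels,
    )


def apply_filters(gm: GenotypeMatrix, crit: FilterCriteria | None = None):
    """Apply hard filters in a fixed order; returns (filtered matrix, report).

    Order: (1) indel proximity, (2) biallelic-only, (3) genotype depth
    masking, (4) missingness (overall and per-population), (5) site QUAL,
    (6) MAF on non-missing alleles after masking. The fixed order makes the
    per-criterion counts reproducible.
    """
    if crit is None:
        crit = FilterCriteria()
    report = FilterReport(sites_in=gm.n_snps)
    keep = np.ones(gm.n_snps, dtype=bool)
    values = gm.values.copy()
    sites = gm.sites

    # (1) indel proximity
    if crit.indel_distance_bp >= 0 and gm.indels is not None and len(gm.indels):
        for chrom, sub in gm.indels.groupby("chrom"):
            on_chrom = (sites["chrom"] == chrom).to_numpy()
            if not on_chrom.any():
                continue
            pos = sites.loc[on_chrom, "pos"].to_numpy()
            ipos = np.sort(sub["pos"].to_numpy())
            j = np.searchsorted(ipos, pos)
            dist = np.full(pos.shape, np.iinfo(np.int64).max)
            has_right = j < len(ipos)
            dist[has_right] = np.abs(ipos[np.minimum(j, len(ipos) - 1)] - pos)[has_right]
            has_left = j > 0
            dist[has_left] = np.minimum(
                dist[has_left], np.abs(pos - ipos[np.maximum(j - 1, 0)])[has_left]
            )
            near = dist <= crit.indel_distance_bp
            idx = np.flatnonzero(on_chrom)[near]
            report.removed_indel_proximity += int(keep[idx].sum())
            keep[idx] = False
    elif gm.indels is None or not len(gm.indels or []):
        logger.info("no indel records present; indel-proximity filter is a no-op")

    # (2) biallelic only
    if crit.biallelic_only and "n_alt" in sites.columns and len(sites):
        multi = (sites["n_alt"].to_numpy() != 1) & keep
        report.removed_multiallelic = int(multi.sum())
        keep &= ~multi

    # (3) depth masking
    if gm.depth is not None and gm.n_snps:
        dp = gm.depth
        bad = (values != MISSING) & (
            (dp < crit.min_gt_depth) | (dp > crit.max_gt_depth)
        )
        bad[:, ~keep] = False
        report.masked_genotypes_depth = int(bad.sum())
        values[bad] = MISSING

    # (4) missingness
    if gm.n_snps:
        miss = values == MISSING
        frac_all = miss.mean(axis=0)
        drop = frac_all > crit.max_missing_overall
        for pop in gm.populations:
            rows = gm.sample_indices_of_pop(pop)
            if len(rows):
                drop |= miss[rows].mean(axis=0) > crit.max_missing_per_pop
        drop &= keep
        report.removed_missingness = int(drop.sum())
        keep &= ~drop

    # (5) QUAL
    if "qual" in sites.columns and len(sites):
        qual = sites["qual"].to_numpy(dtype=float)
        bad_q = (qual < crit.min_qual) & ~np.isnan(qual) & keep
        report.removed_qual = int(bad_q.sum())
        keep &= ~bad_q

    # (6) MAF after masking
    if gm.n_snps:
        obs = values != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, values, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
        maf = np.minimum(p, 1.0 - p)
        low = (np.isnan(maf) | (maf < crit.min_maf)) & keep
        report.removed_maf = int(low.sum())
        keep &= ~low

    idx = np.flatnonzero(keep)
    report.sites_out = len(idx)
    out = GenotypeMatrix(
        values=values[:, idx],
        sample_ids=list(gm.sample_ids),
        pop_of_sample=dict(gm.pop_of_sample),
        sites=sites.iloc[idx].reset_index(drop=True),
        depth=None if gm.depth is None else gm.depth[:, idx],
        indels=None if gm.indels is None else gm.indels.copy(),
    )
    if report.sites_out == 0:
        warnings.warn("all sites removed by filtering", stacklevel=2)
    return out, report


def write_clusters(gm: GenotypeMatrix, path, chrom_clusters, genome_clusters=None):
    """Write one row per SNP: chrom, pos, id, chromosome-wise and genome-wide cluster ids.

    Row order equals site order; round-trips through :func:`read_clusters`.
    """
    chrom_clusters = np.asarray(chrom_clusters)
    if chrom_clusters.shape[0] != gm.n_snps:
        raise IndexError("cluster assignment length != number of SNPs")
    if genome_clusters is None:
        genome_clusters = chrom_clusters
    genome_clusters = np.asarray(genome_clusters)
    if genome_clusters.shape[0] != gm.n_snps:
        raise IndexError("genome-wide assignment length != number of SNPs")
    df = pd.DataFrame(
        {
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "id": gm.sites["id"],
            "chrom_cluster": chrom_clusters,
            "genome_cluster": genome_clusters,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_clusters(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
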