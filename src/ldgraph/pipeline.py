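"""End-to-end orchestration: filter -> LD graphs -> clusters -> differentiation.

Thin layer over the library used by the command-line interface. All outputs
are plain text (TSV/JSON/GraphML) and deterministic for a fixed input and
configuration, regardless of worker count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (
    GenotypeMatrix,
    FilterCriteria,
    apply_filters,
    read_vcf,
    write_clusters,
)
from .genome_graph import GenomeWideLDBlocks
from .chrom_graph import fit_log_table
from .differentiation import (
    PopPair,
    site_fst,
    site_dxy,
    site_pi,
    windowed_stats,
    cluster_fst_ranking,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of a full run; echoed as JSON next to the outputs."""

    filters: FilterCriteria = field(default_factory=FilterCriteria)
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    criterion: str = "bic"
    df_mode: str = "variables"
    symmetrize: str = "and"
    genome_criterion: str = "ebic"
    genome_symmetrize: str = "or"
    genome_clustering: str = "components"
    ebic_gamma: float = 0.5
    aic_direction: str = "min"
    walktrap_steps: int = 4
    var_threshold: float = 0.8
    weight_by_group_size: bool = False
    window_bp: int = 100_000
    min_snps: int = 15
    max_snps: int = 205
    pop_a: list = field(default_factory=list)
    pop_b: list = field(default_factory=list)
    threads: int = 1
    seed: int = 0

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


def run_all(gm: GenotypeMatrix, outdir, config: RunConfig | None = None, truth=None) -> dict:
    """Execute the whole method on a genotype matrix and write all artifacts.

    Stages: hard filtering, per-chromosome LD graph + walktrap blocks,
    genome-wide PC/group-LASSO graph + re-clustering, differentiation
    statistics between the configured sides, and (if planted truth is
    given) recovery metrics. Returns a summary dict.
    """
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_json(outdir / "resolved_config.json")

    filtered, report = apply_filters(gm, cfg.filters)
    report.to_json(outdir / "filter_report.json")
    logger.info("filtering: %d -> %d sites", report.sites_in, report.sites_out)

    chroms = filtered.sites["chrom"].to_numpy()
    model = GenomeWideLDBlocks(
        n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio,
        criterion=cfg.criterion,
        df_mode=cfg.df_mode,
        symmetrize=cfg.symmetrize,
        genome_criterion=cfg.genome_criterion,
        genome_symmetrize=cfg.genome_symmetrize,
        genome_clustering=cfg.genome_clustering,
        ebic_gamma=cfg.ebic_gamma,
        aic_direction=cfg.aic_direction,
        walktrap_steps=cfg.walktrap_steps,
        var_threshold=cfg.var_threshold,
        weight_by_group_size=cfg.weight_by_group_size,
        n_jobs=cfg.threads,
    )
    model.fit(filtered.values, chromosomes=chroms)

    write_clusters(filtered, outdir / "clusters.tsv", model.chrom_labels_, model.labels_)
    model.cluster_graph_.write_graphml(outdir / "cluster_graph.graphml")
    for ch, g in model.chrom_graphs_.items():
        g.write_edgelist(outdir / f"edges_{ch}.tsv")

    summary = {
        "sites_in": report.sites_in,
        "sites_out": report.sites_out,
        "n_chrom_clusters": int(model.chrom_labels_.max()) if len(model.chrom_labels_) else 0,
        "n_genome_clusters": int(model.labels_.max()) if len(model.labels_) else 0,
    }

    if cfg.pop_a and cfg.pop_b:
        pair = PopPair(cfg.pop_a, cfg.pop_b)
        comp = site_fst(filtered, pair)
        dxy = site_dxy(filtered, pair)
        pi = site_pi(filtered)
        persite = comp.merge(dxy[["site", "dxy"]], on="site", how="left").merge(
            pi[["site", "pi"]], on="site", how="left"
        )
        persite.to_csv(outdir / "per_site_stats.tsv", sep="\t", index=False)
        windows = windowed_stats(
            persite, cfg.window_bp, cfg.min_snps, cfg.max_snps
        )
        windows.to_csv(outdir / "per_window_stats.tsv", sep="\t", index=False)
        ranking, baseline = cluster_fst_ranking(comp, model.labels_)
        ranking.insert(1, "genome_baseline", baseline)
        ranking.to_csv(outdir / "cluster_ranking.tsv", sep="\t", index=False)
        summary["genome_weighted_fst"] = baseline
        summary["n_clusters_above_baseline"] = int(ranking["above_baseline"].sum())

    if truth is not None:
        from .simulate import evaluate_recovery, SimTruth

        flagged = None
        if cfg.pop_a and cfg.pop_b:
            flagged = ranking.loc[ranking["above_baseline"], "cluster_id"].tolist()
        # filtering may have dropped sites: restrict the planted truth to the
        # retained (chrom, pos) set before scoring
        if len(truth.block_of_snp) != filtered.n_snps:
            if len(truth.block_of_snp) != gm.n_snps:
                raise ValueError(
                    "truth covers neither the input nor the filtered SNP set"
                )
            key_in = list(zip(gm.sites["chrom"], gm.sites["pos"]))
            pos_of = {k: i for i, k in enumerate(key_in)}
            idx = [
                pos_of[k]
                for k in zip(filtered.sites["chrom"], filtered.sites["pos"])
            ]
            truth = SimTruth(
                block_of_snp=np.asarray(truth.block_of_snp)[idx],
                differentiated_blocks=set(truth.differentiated_blocks),
                ancestral_freqs=np.asarray(truth.ancestral_freqs)[idx]
                if len(np.asarray(truth.ancestral_freqs))
                else truth.ancestral_freqs,
                pop_freqs=truth.pop_freqs.iloc[idx].reset_index(drop=True)
                if len(truth.pop_freqs)
                else truth.pop_freqs,
            )
        metrics = evaluate_recovery(truth, model.labels_, flagged_clusters=flagged)
        with open(outdir / "recovery_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, default=str)
        summary["recovery"] = {
            k: metrics[k] for k in metrics if k.startswith("ari") or k == "n_blocks_recovered"
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    summary["model"] = model
    return summary


def run_all_vcf(vcf_path, pop_map, outdir, config: RunConfig | None = None, truth=None):
    gm = read_vcf(vcf_path, pop_map)
    return run_all(gm, outdir, config=config, truth=truth)
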