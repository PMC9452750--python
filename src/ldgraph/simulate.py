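"""Synthetic structured diploid genotypes with planted LD blocks.

The generator emulates the data a two-stage LD clustering method sees:

* background SNPs are mutually independent given population allele
  frequencies, drawn from the Balding-Nichols beta model around a uniform
  ancestral frequency (``background_fst`` controls drift);
* planted LD blocks come from a haplotype-pool model: a pool of block
  haplotypes derived from two lineages (all-reference vs all-alternate)
  with per-site mutation noise tuned so the realized mean within-block r^2
  approximates a target; each diploid individual draws two haplotypes.
  A *differentiated* block diverges its lineage frequency between
  environment groups by a Balding-Nichols draw with ``divergence_fst``; a
  neutral block shares one lineage frequency everywhere;
* uniform genotype missingness, negative-binomial per-genotype depth and
  truncated-normal site QUAL provide the metadata the hard filters need.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .genotypes import GenotypeMatrix, MISSING


@dataclass
class ChromSpec:
    name: str
    length_bp: int
    n_snps: int


@dataclass
class BlockSpec:
    """A planted LD block occupying ``n_snps`` consecutive SNP slots on ``chrom``.

    ``divergence_fst`` of None means a neutral (shared) block; a value in
    [0, 1) plants between-group differentiation of that magnitude at every
    block site.
    """

    chrom: str
    start_snp: int
    n_snps: int
    n_haplotypes: int = 4
    r2_target: float = 0.9
    divergence_fst: float | None = None


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a modest resequencing design: two populations of 30
    diploids in contrasting environment groups, two 1-Mb chromosomes of 500
    SNPs each, low background differentiation (F_ST 0.02), MAF spectrum
    uniform on [0.05, 0.5], 5% missing genotypes, negative-binomial depth
    around 10x and QUAL around 60.
    """

    n_per_pop: int = 30
    pops: dict = field(default_factory=lambda: {"pop1": "high", "pop2": "mid"})
    chroms: list = field(
        default_factory=lambda: [ChromSpec("chr1", 1_000_000, 500), ChromSpec("chr2", 1_000_000, 500)]
    )
    blocks: list = field(default_factory=list)
    background_fst: float = 0.02
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.05
    depth_mean: float = 10.0
    depth_dispersion: float = 5.0
    qual_mean: float = 60.0
    qual_sd: float = 15.0
    seed: int = 0

    def __post_init__(self):
        self.chroms = [c if isinstance(c, ChromSpec) else ChromSpec(*c) for c in self.chroms]
        self.blocks = [b if isinstance(b, BlockSpec) else BlockSpec(**b) for b in self.blocks]
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not 0.0 <= self.background_fst < 1.0:
            raise ValueError("background_fst must be in [0, 1)")
        occupied: dict = {}
        for b in self.blocks:
            if b.divergence_fst is not None and not 0.0 <= b.divergence_fst < 1.0:
                raise ValueError("divergence_fst must be in [0, 1)")
            spec = next((c for c in self.chroms if c.name == b.chrom), None)
            if spec is None:
                raise ValueError(f"block on unknown chromosome {b.chrom}")
            if b.start_snp + b.n_snps > spec.n_snps:
                raise ValueError(f"block exceeds SNP count of chromosome {b.chrom}")
            span = set(range(b.start_snp, b.start_snp + b.n_snps))
            if span & occupied.get(b.chrom, set()):
                raise ValueError(f"overlapping blocks on chromosome {b.chrom}")
            occupied.setdefault(b.chrom, set()).update(span)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        s = json.dumps(d, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["chroms"] = [ChromSpec(*c) if isinstance(c, (list, tuple)) else ChromSpec(**c) for c in d["chroms"]]
        d["blocks"] = [BlockSpec(**b) for b in d.get("blocks", [])]
        d["maf_range"] = tuple(d.get("maf_range", (0.05, 0.5)))
        return cls(**d)


@dataclass
class SimTruth:
    """Planted structure: block membership per SNP and which blocks are differentiated."""

    block_of_snp: np.ndarray  # -1 for background
    differentiated_blocks: set
    ancestral_freqs: np.ndarray
    pop_freqs: pd.DataFrame  # one column per population

    def to_tsv(self, path, sites: pd.DataFrame):
        df = pd.DataFrame(
            {
                "chrom": sites["chrom"],
                "pos": sites["pos"],
                "block": self.block_of_snp,
                "differentiated": [
                    int(b in self.differentiated_blocks) if b >= 0 else 0
                    for b in self.block_of_snp
                ],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def _balding_nichols(rng, p_anc, fst, size):
    """Per-population frequency draw around p_anc with differentiation fst."""
    if fst <= 0.0:
        return np.full(size, p_anc)
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b, size=size), 1e-6, 1.0 - 1e-6)


def _positions(length_bp, n_snps):
    pos = np.round(np.linspace(1, length_bp, n_snps + 2)[1:-1]).astype(int)
    return np.maximum.accumulate(np.maximum(pos, np.arange(n_snps) + 1))


def simulate_genotypes(cfg: SimConfig, vcf_path=None, truth_path=None):
    """Draw one dataset; returns (GenotypeMatrix, SimTruth) and optionally writes VCF/truth.

    See the module docstring for the generative model. With ``vcf_path``
    set, a VCF 4.2 with GT:DP fields and site QUAL is written (plain text);
    the written file is byte-identical for identical configs.
    """
    rng = np.random.default_rng(cfg.seed)
    pop_labels = list(cfg.pops)
    groups = list(dict.fromkeys(cfg.pops.values()))
    sample_ids, pop_of_sample = [], {}
    for pop in pop_labels:
        for i in range(cfg.n_per_pop):
            sid = f"{pop}_{i + 1:02d}"
            sample_ids.append(sid)
            pop_of_sample[sid] = pop
    n = len(sample_ids)
    rows_of_pop = {
        pop: np.array([i for i, s in enumerate(sample_ids) if pop_of_sample[s] == pop])
        for pop in pop_labels
    }

    site_recs = []
    cols = []
    block_of_snp = []
    anc_freqs = []
    pop_freq_rows = []
    differentiated = set()

    for chrom in cfg.chroms:
        pos = _positions(chrom.length_bp, chrom.n_snps)
        blocks_here = sorted(
            (b for b in cfg.blocks if b.chrom == chrom.name), key=lambda b: b.start_snp
        )
        block_id_of = np.full(chrom.n_snps, -1, dtype=int)
        for b in blocks_here:
            bid = cfg.blocks.index(b)
            block_id_of[b.start_snp : b.start_snp + b.n_snps] = bid

        G = np.empty((n, chrom.n_snps), dtype=np.int8)
        site_anc = np.empty(chrom.n_snps)
        site_pop_freq = np.empty((chrom.n_snps, len(pop_labels)))

        # background sites (columnwise independent given pop frequencies)
        bg = np.flatnonzero(block_id_of < 0)
        p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=len(bg))
        for k, s in enumerate(bg):
            site_anc[s] = p_anc[k]
            for pi, pop in enumerate(pop_labels):
                pp = _balding_nichols(rng, p_anc[k], cfg.background_fst, 1)[0]
                site_pop_freq[s, pi] = pp
                G[rows_of_pop[pop], s] = rng.binomial(2, pp, size=len(rows_of_pop[pop]))

        # planted blocks via the haplotype-pool model
        for b in blocks_here:
            bid = cfg.blocks.index(b)
            span = np.arange(b.start_snp, b.start_snp + b.n_snps)
            eps = (1.0 - b.r2_target**0.25) / 2.0
            H = max(2, b.n_haplotypes)
            lineage = (np.arange(H) >= H / 2).astype(int)  # half ref-lineage, half alt-lineage
            base = np.repeat(lineage[:, None], b.n_snps, axis=1)
            flips = rng.random((H, b.n_snps)) < eps
            pool = np.where(flips, 1 - base, base)  # (H, block sites)

            q_anc = rng.uniform(0.35, 0.65)
            if b.divergence_fst is not None:
                # plant the divergence deterministically: a symmetric split
                # q_anc +/- sqrt(F q(1-q)) realizes a two-group parametric
                # F_ST of exactly `divergence_fst` in expectation, rather
                # than a random draw whose realized divergence could be
                # anywhere from 0 to fixation
                differentiated.add(bid)
                delta = np.sqrt(b.divergence_fst * q_anc * (1.0 - q_anc))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                q_group = {
                    g: float(np.clip(q_anc + (sign if gi % 2 == 0 else -sign) * delta, 0.02, 0.98))
                    for gi, g in enumerate(groups)
                }
            else:
                q_group = {g: q_anc for g in groups}
            for pi, pop in enumerate(pop_labels):
                q = q_group[cfg.pops[pop]]
                rows = rows_of_pop[pop]
                hap_idx = np.empty((len(rows), 2), dtype=int)
                for copy in range(2):
                    lin = rng.random(len(rows)) < q  # True -> alt lineage
                    choice = rng.integers(0, H // 2, size=len(rows))
                    hap_idx[:, copy] = np.where(lin, H // 2 + choice % (H - H // 2), choice)
                geno = pool[hap_idx[:, 0]] + pool[hap_idx[:, 1]]
                G[np.ix_(rows, span)] = geno.astype(np.int8)
                site_pop_freq[span, pi] = q * pool[H // 2 :].mean(axis=0) + (
                    1 - q
                ) * pool[: H // 2].mean(axis=0)
            site_anc[span] = q_anc

        for k in range(chrom.n_snps):
            site_recs.append((chrom.name, int(pos[k]), f"{chrom.name}_{pos[k]}", "A", "T"))
        cols.append(G)
        block_of_snp.append(block_id_of)
        anc_freqs.append(site_anc)
        pop_freq_rows.append(site_pop_freq)

    values = np.hstack(cols)
    p_total = values.shape[1]

    # missingness, depth, QUAL
    miss = rng.random(values.shape) < cfg.missing_rate
    values = np.where(miss, MISSING, values).astype(np.int8)
    k = cfg.depth_dispersion
    depth = rng.negative_binomial(k, k / (k + cfg.depth_mean), size=values.shape).astype(np.int32)
    qual = np.maximum(rng.normal(cfg.qual_mean, cfg.qual_sd, size=p_total), 0.0)

    sites = pd.DataFrame(site_recs, columns=["chrom", "pos", "id", "ref", "alt"])
    sites["qual"] = np.round(qual, 2)
    sites["n_alt"] = 1

    gm = GenotypeMatrix(
        values=values,
        sample_ids=sample_ids,
        pop_of_sample=pop_of_sample,
        sites=sites,
        depth=depth,
        indels=None,
    )
    truth = SimTruth(
        block_of_snp=np.concatenate(block_of_snp),
        differentiated_blocks=differentiated,
        ancestral_freqs=np.concatenate(anc_freqs),
        pop_freqs=pd.DataFrame(np.vstack(pop_freq_rows), columns=pop_labels),
    )
    if vcf_path is not None:
        write_vcf(gm, vcf_path)
    if truth_path is not None:
        truth.to_tsv(truth_path, gm.sites)
    return gm, truth


def write_vcf(gm: GenotypeMatrix, path):
    """Write a minimal VCF 4.2 with GT:DP per sample and site QUAL."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for chrom in gm.chroms:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.sample_ids)
    )
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j in range(gm.n_snps):
        row = gm.sites.iloc[j]
        qual = row.get("qual", np.nan)
        qual_s = "." if pd.isna(qual) else f"{float(qual):g}"
        fields = [
            str(row["chrom"]),
            str(int(row["pos"])),
            str(row["id"]),
            str(row["ref"]),
            str(row["alt"]),
            qual_s,
            "PASS",
            ".",
            "GT:DP",
        ]
        for i in range(gm.n_samples):
            dp = gm.depth[i, j] if gm.depth is not None else "."
            fields.append(f"{gt_str[int(gm.values[i, j])]}:{dp}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_pop_map(gm: GenotypeMatrix, path):
    pd.DataFrame(
        {"sample_id": gm.sample_ids, "population": [gm.pop_of_sample[s] for s in gm.sample_ids]}
    ).to_csv(path, sep="\t", index=False)


def truth_labels(truth: SimTruth, background: str = "singletons") -> np.ndarray:
    """Planted partition as integer labels.

    ``background='singletons'`` gives every non-block SNP its own label;
    ``background='one-class'`` lumps them into a single class.
    """
    b = truth.block_of_snp
    labels = np.empty(len(b), dtype=int)
    nb = int(b.max()) + 1 if len(b) and b.max() >= 0 else 0
    nxt = nb
    for i, v in enumerate(b):
        if v >= 0:
            labels[i] = v
        elif background == "one-class":
            labels[i] = nb
        else:
            labels[i] = nxt
            nxt += 1
    return labels


def evaluate_recovery(truth: SimTruth, inferred, flagged_clusters=None) -> dict:
    """Score an inferred SNP clustering against the planted structure.

    Reports the adjusted Rand index under both background conventions, a
    per-block recovery flag (some inferred cluster contains >= 80% of the
    block's SNPs and those SNPs make up >= 50% of that cluster), block
    precision/recall, and — given a list of flagged cluster ids — the
    detection rate of differentiated blocks.
    """
    inferred = (
        inferred.assignment if hasattr(inferred, "assignment") else np.asarray(inferred)
    )
    if len(inferred) != len(truth.block_of_snp):
        raise ValueError("inferred clustering and truth cover different SNP universes")
    out = {
        "ari_background_singletons": float(
            adjusted_rand_score(truth_labels(truth, "singletons"), inferred)
        ),
        "ari_background_one_class": float(
            adjusted_rand_score(truth_labels(truth, "one-class"), inferred)
        ),
    }
    blocks = {}
    n_recovered = 0
    block_ids = sorted(set(truth.block_of_snp[truth.block_of_snp >= 0].tolist()))
    for bid in block_ids:
        members = np.flatnonzero(truth.block_of_snp == bid)
        ids, counts = np.unique(inferred[members], return_counts=True)
        best = int(ids[np.argmax(counts)])
        in_best = int(counts.max())
        cluster_size = int((inferred == best).sum())
        recall = in_best / len(members)
        precision = in_best / cluster_size
        recovered = recall >= 0.8 and precision >= 0.5
        n_recovered += recovered
        blocks[bid] = {
            "host_cluster": best,
            "recall": recall,
            "precision": precision,
            "recovered": bool(recovered),
        }
    out["blocks"] = blocks
    out["n_blocks_recovered"] = n_recovered
    if flagged_clusters is not None and truth.differentiated_blocks:
        flagged = set(int(c) for c in flagged_clusters)
        hits = sum(
            1
            for bid in truth.differentiated_blocks
            if blocks.get(bid, {}).get("host_cluster") in flagged
        )
        out["differentiated_detection_rate"] = hits / len(truth.differentiated_blocks)
    return out
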