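"""Synthetic polysome-CAGE dataset generator with ground truth.

Builds a toy genome with annotated gene models, plants canonical and
alternative TSSs (ORF-retaining in the 5' UTR, ORF-truncating in CDS or
intron), balanced bidirectional enhancers, and planted promoter motifs;
then emits per-base CTSS count tracks for every condition x replicate x
fraction with negative-binomial noise.  Polysome partitioning follows a
multinomial whose translated-vs-free log-odds are penalized by 5' UTR
length and upstream-AUG count and multiplied down for CNY cap-proximal
trinucleotides, so the downstream recovery analyses have a known truth.

All randomness flows from ``SimulationConfig.seed``: the same config
yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CtssTrack, write_ctss_bed
from .seq import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 80
    n_multi_tss_genes: int = 24
    n_enhancers: int = 12
    frac_truncating_atss: float = 0.5
    replicates_per_condition: int = 2
    nb_dispersion: float = 0.05
    cny_te_multiplier: float = 0.25
    dtu_logfc: float = 1.5
    sharp_frac: float = 0.5
    genome_length: int = 1_200_000
    # secondary structure of the simulation
    frac_unbalanced_enhancers: float = 0.25  # decoys with a 0.8/0.2 arm split
    frac_intronic_enhancers: float = 0.5
    dtu_frac: float = 0.5  # fraction of multi-TSS genes given the condition shift
    de_frac: float = 0.2  # fraction of uni-TSS genes with a gene-wide shift
    de_logfc: float = 2.0
    mean_cluster_tags: float = 2000.0
    enhancer_arm_tags: float = 120.0
    te_intercept: float = 6.5  # translated-vs-free log odds before penalties
    light_share: float = 0.45  # Light's share of the translated signal
    enhancer_logit: float = -1.5  # eRNAs sit mostly in the Free fraction
    planted_motif: str = "TGACGTCATC"
    motif_fg_rate: float = 0.4
    motif_bg_rate: float = 0.05
    profile_condition: str = "TCL1"

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "replicates_per_condition": self.replicates_per_condition,
            "genome_length": self.genome_length,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1 (got {value})")
        if not 0 <= self.n_multi_tss_genes <= self.n_genes:
            raise ValueError("n_multi_tss_genes must lie in [0, n_genes]")
        for name in ("frac_truncating_atss", "sharp_frac", "dtu_frac", "de_frac",
                     "frac_unbalanced_enhancers", "frac_intronic_enhancers",
                     "motif_fg_rate", "motif_bg_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1]")
        if self.cny_te_multiplier <= 0:
            raise ValueError("cny_te_multiplier must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_enhancers < 0:
            raise ValueError("n_enhancers must be >= 0")


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # genomic gene span, 0-based half-open
    length: int
    utr5_len: int
    exons_t: list  # transcript-space [(s, e)]
    cds_t: list
    introns_t: list
    alt_t: int | None = None  # alternative TSS, transcript coordinate
    alt_class: str | None = None  # fiveUTR | CDS | intron
    orf_effect: str | None = None
    gene_log2fc: float = 0.0
    atss_log2fc: float = 0.0
    alt_rel: float = 1.0  # alt cluster mean relative to canonical
    alt_leader_len: int = 0  # effective 5' leader of a truncating isoform
    alt_leader_uaug: int = 0
    base_mean: float = 0.0
    n_uaug: int = 0
    motif_planted: bool = False
    utr_seq: str = ""

    @property
    def end(self) -> int:
        return self.start + self.length

    def t2g(self, t: int) -> int:
        """Transcript coordinate -> genomic position."""
        if self.strand == "+":
            return self.start + t
        return self.start + self.length - 1 - t

    def interval_g(self, s: int, e: int) -> tuple[int, int]:
        """Transcript-space [s, e) -> genomic half-open interval."""
        if self.strand == "+":
            return self.start + s, self.start + e
        return self.start + self.length - e, self.start + self.length - s

    @property
    def tss(self) -> int:
        return self.t2g(0)

    @property
    def alt_peak(self) -> int | None:
        return None if self.alt_t is None else self.t2g(self.alt_t)


@dataclass
class SimEnhancer:
    enhancer_id: str
    chrom: str
    midpoint: int
    minus_peak: int
    plus_peak: int
    location: str  # intergenic | intronic
    linked_gene: str
    balanced: bool
    minus_share: float  # expected minus-arm share d
    arm_mean: float  # total of both arms / 2
    cond_log2fc: float


@dataclass
class Reference:
    config: SimulationConfig
    chrom: str
    genome: np.ndarray = field(repr=False)  # S1 byte array, mutably built
    genes: list = field(default_factory=list)
    enhancers: list = field(default_factory=list)

    def sequence(self) -> str:
        return self.genome.tobytes().decode()

    def genome_dict(self) -> dict:
        return {self.chrom: self.sequence()}


@dataclass
class SyntheticDataset:
    reference: Reference
    tracks: list
    sample_sheet: pd.DataFrame
    gene_truth: pd.DataFrame
    enhancer_truth: pd.DataFrame
    ctss_truth: pd.DataFrame


def _make_gene(rng, gene_id, chrom, strand, start) -> SimGene:
    u = int(rng.integers(140, 401))
    c1 = int(rng.integers(200, 401))
    i1 = int(rng.integers(600, 1401))
    c2 = int(rng.integers(300, 601))
    i2 = int(rng.integers(300, 801))
    c3 = int(rng.integers(200, 401))
    c3 -= (c1 + c2 + c3) % 3
    utr3 = 150
    exons_t = [
        (0, u + c1),
        (u + c1 + i1, u + c1 + i1 + c2),
        (u + c1 + i1 + c2 + i2, u + c1 + i1 + c2 + i2 + c3 + utr3),
    ]
    cds_t = [
        (u, u + c1),
        (u + c1 + i1, u + c1 + i1 + c2),
        (u + c1 + i1 + c2 + i2, u + c1 + i1 + c2 + i2 + c3),
    ]
    introns_t = [(u + c1, u + c1 + i1), (u + c1 + i1 + c2, u + c1 + i1 + c2 + i2)]
    length = exons_t[-1][1]
    return SimGene(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        length=length,
        utr5_len=u,
        exons_t=exons_t,
        cds_t=cds_t,
        introns_t=introns_t,
    )


def _write_subseq(genome: np.ndarray, gene: SimGene, t: int, seq: str) -> None:
    """Write ``seq`` at transcript coordinate ``t`` in transcript orientation."""
    if gene.strand == "+":
        g = gene.start + t
        genome[g : g + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")
    else:
        g_end = gene.start + gene.length - t  # exclusive
        rc = revcomp(seq)
        genome[g_end - len(seq) : g_end] = np.frombuffer(rc.encode(), dtype="S1")


def _read_subseq(genome: np.ndarray, gene: SimGene, t0: int, t1: int) -> str:
    s, e = gene.interval_g(t0, t1)
    raw = genome[s:e].tobytes().decode()
    return raw if gene.strand == "+" else revcomp(raw)


def generate_reference(config: SimulationConfig) -> Reference:
    """Toy genome + gene models, with alternative TSSs and motifs planted.

    Raises a sizing error when ``genome_length`` cannot hold ``n_genes``
    with the required intergenic spacing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    genome = rng.choice(_BASES, size=config.genome_length)

    genes: list[SimGene] = []
    cursor = 3000
    for i in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _make_gene(rng, f"G{i:04d}", chrom, strand, cursor)
        genes.append(gene)
        cursor = gene.end + int(rng.integers(4000, 9001))
    if cursor + 3000 > config.genome_length:
        raise ValueError(
            f"genome_length={config.genome_length} too small for "
            f"{config.n_genes} genes (need ~{cursor + 3000})"
        )

    # multi-TSS designation and ORF effect of the alternative TSS
    order = rng.permutation(config.n_genes)
    multi_idx = list(order[: config.n_multi_tss_genes])
    n_trunc = int(round(config.frac_truncating_atss * len(multi_idx)))
    for j, gi in enumerate(multi_idx):
        gene = genes[gi]
        gene.alt_rel = float(rng.uniform(0.35, 0.85))
        if j < n_trunc:
            gene.orf_effect = "truncating"
            # truncated isoforms start inside the gene body; their effective
            # 5' leaders vary widely, so both High- and Low-TE calls occur
            gene.alt_leader_len = int(rng.integers(50, 601))
            gene.alt_leader_uaug = int(rng.poisson(1.2))
            if rng.random() < 0.5:
                s, e = gene.introns_t[0]
                gene.alt_t = (s + e) // 2
                gene.alt_class = "intron"
            else:
                s, e = gene.cds_t[1]
                gene.alt_t = s + (e - s) // 3
                gene.alt_class = "CDS"
        else:
            gene.orf_effect = "retaining"
            gene.alt_t = max(110, int(0.8 * gene.utr5_len))
            gene.alt_class = "fiveUTR"

    # condition effects: promoter shifts on a subset of multi-TSS genes,
    # gene-wide DE on a subset of uni-TSS genes (alternating sign)
    n_dtu = int(round(config.dtu_frac * len(multi_idx)))
    dtu_idx = list(rng.permutation(multi_idx)[:n_dtu])
    for gi in dtu_idx:
        genes[gi].atss_log2fc = config.dtu_logfc
    uni_idx = [i for i in range(config.n_genes) if i not in set(multi_idx)]
    n_de = int(round(config.de_frac * len(uni_idx)))
    for k, gi in enumerate(rng.permutation(uni_idx)[:n_de]):
        genes[gi].gene_log2fc = config.de_logfc * (1 if k % 2 == 0 else -1)

    # expression levels
    for gene in genes:
        gene.base_mean = float(
            np.exp(rng.normal(np.log(config.mean_cluster_tags), 0.6))
        )

    # start codons and planted promoter motifs
    for gene in genes:
        _write_subseq(genome, gene, gene.utr5_len, "ATG")
        fg = gene.atss_log2fc != 0 and gene.alt_t is not None
        rate = config.motif_fg_rate if fg else config.motif_bg_rate
        if config.planted_motif and rng.random() < rate:
            anchor_t = gene.alt_t if fg else 0
            offset = int(rng.integers(150, 700))
            t = anchor_t - offset
            g0, _ = gene.interval_g(t, t + len(config.planted_motif))
            if g0 >= 0:
                _write_subseq(genome, gene, t, config.planted_motif)
                gene.motif_planted = True

    # realized 5' UTR content (after all sequence edits)
    for gene in genes:
        gene.utr_seq = _read_subseq(genome, gene, 0, gene.utr5_len)
        gene.n_uaug = sum(
            1
            for i in range(len(gene.utr_seq) - 2)
            if gene.utr_seq[i : i + 3] == "ATG"
        )

    enhancers = _place_enhancers(config, rng, chrom, genes)
    return Reference(config=config, chrom=chrom, genome=genome, genes=genes,
                     enhancers=enhancers)


def _place_enhancers(config, rng, chrom, genes) -> list[SimEnhancer]:
    if config.n_enhancers == 0:
        return []
    n_unbal = int(round(config.frac_unbalanced_enhancers * config.n_enhancers))
    n_intronic = int(round(config.frac_intronic_enhancers * config.n_enhancers))
    # intronic hosts: second intron, away from the truncating alternative TSS
    hosts = [g for g in genes if g.introns_t[1][1] - g.introns_t[1][0] >= 500]
    gaps = []
    prev_end = None
    for g in sorted(genes, key=lambda g: g.start):
        if prev_end is not None and g.start - prev_end >= 2400:
            gaps.append((prev_end + 1000, g.start - 1000))
        prev_end = g.end
    enhancers = []
    host_order = rng.permutation(len(hosts))
    gap_order = rng.permutation(len(gaps))
    hi = gi = 0
    for k in range(config.n_enhancers):
        intronic = k < n_intronic and hi < len(hosts)
        if intronic:
            host = hosts[host_order[hi % len(host_order)]]
            hi += 1
            s, e = host.interval_g(*host.introns_t[1])
            mid = (s + e) // 2
            location, linked = "intronic", host.gene_id
        else:
            if not gaps:
                raise ValueError("no intergenic gap wide enough for an enhancer")
            lo, hi_gap = gaps[gap_order[gi % len(gap_order)]]
            gi += 1
            mid = (lo + hi_gap) // 2
            location = "intergenic"
            linked = min(genes, key=lambda g: abs(g.tss - mid)).gene_id
        balanced = k >= n_unbal
        minus_share = 0.5 if balanced else 0.8
        linked_gene = next(g for g in genes if g.gene_id == linked)
        enhancers.append(
            SimEnhancer(
                enhancer_id=f"E{k:03d}",
                chrom=chrom,
                midpoint=mid,
                minus_peak=mid - 90,
                plus_peak=mid + 90,
                location=location,
                linked_gene=linked,
                balanced=balanced,
                minus_share=minus_share,
                arm_mean=config.enhancer_arm_tags,
                cond_log2fc=linked_gene.gene_log2fc + linked_gene.atss_log2fc * 0.5,
            )
        )
    return enhancers


def _cluster_profile(rng, peak: int, sharp: bool) -> tuple[np.ndarray, np.ndarray]:
    """CTSS positions and normalized weights around a planted peak."""
    n = int(rng.integers(1, 11)) if sharp else int(rng.integers(11, 61))
    center = n // 2
    offsets = np.arange(n) - center
    tau = n / 3.0 + 1.0
    w = np.exp(-np.abs(offsets) / tau)
    # make the centre strictly maximal so the planted peak is recovered
    w[center] *= 1.5
    w /= w.sum()
    return peak + offsets, w


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_ctss_tracks(config: SimulationConfig, reference: Reference) -> SyntheticDataset:
    """Sample per-base CTSS tracks for every condition/replicate/fraction.

    In the noise-free expectation layer, Free+Light+Heavy means sum to the
    Total mean at every CTSS; NB sampling is applied independently per
    sample around those means.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    genome = reference.genome
    chrom = reference.chrom
    seq = reference.sequence()
    genome_d = {chrom: seq}

    from .startseq import extract_start_kmer

    conditions = ("WT", "TCL1")
    reps = range(1, cfg.replicates_per_condition + 1)
    fractions = ("Total", "Free", "Light", "Heavy")
    samples = [
        (f"{c}_rep{r}_{f}", c, r, f) for c in conditions for r in reps for f in fractions
    ]

    # ---- expectation layer ------------------------------------------------
    rows = []  # per-CTSS truth rows
    unit_latent: dict = {}  # (unit_key, cond, rep) -> latent multiplier
    linked_units = {}
    for enh in reference.enhancers:
        linked_units.setdefault(enh.linked_gene, []).append(enh.enhancer_id)

    def latent_for(unit_key, cond, rep):
        return unit_latent.get((unit_key, cond, rep), 1.0)

    # shared latent activity between an enhancer and its linked gene
    for enh in reference.enhancers:
        for cond in conditions:
            for rep in reps:
                l = float(np.exp(rng.normal(0.0, 0.5)))
                unit_latent[(enh.enhancer_id, cond, rep)] = l
                unit_latent[(enh.linked_gene, cond, rep)] = l

    def add_cluster(kind, unit_id, gene, positions, weights, strand, mean, log2fc,
                    utr_at, uaug_at, logit_fn, latent_key):
        for pos, w in zip(positions, weights):
            tri = extract_start_kmer(genome_d, chrom, int(pos), strand, 3)
            if tri is None:
                continue
            is_cny = tri[0] == "C" and tri[2] in "CT"
            utr_len = utr_at(int(pos)) if utr_at else 0
            n_uaug = uaug_at(int(pos)) if uaug_at else 0
            eta = logit_fn(utr_len, n_uaug) + (
                math.log(cfg.cny_te_multiplier) if is_cny else 0.0
            )
            p_poly = _sigmoid(eta)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "strand": strand,
                    "kind": kind,
                    "unit_id": unit_id,
                    "gene_id": gene,
                    "mean_total": mean * w,
                    "log2fc": log2fc,
                    "trinucleotide": tri,
                    "is_cny": is_cny,
                    "utr_len": utr_len,
                    "n_uaug": n_uaug,
                    "eta": eta,
                    "expected_te": math.exp(eta),
                    "p_free": 1.0 - p_poly,
                    "p_light": p_poly * cfg.light_share,
                    "p_heavy": p_poly * (1.0 - cfg.light_share),
                    "latent_key": latent_key,
                }
            )

    for gene in reference.genes:
        sharp = rng.random() < cfg.sharp_frac
        positions, weights = _cluster_profile(rng, gene.tss, sharp)
        u = gene.utr5_len

        def t_of(pos, gene=gene):
            return pos - gene.start if gene.strand == "+" else gene.start + gene.length - 1 - pos

        def utr_at(pos, gene=gene):
            return max(5, gene.utr5_len - t_of(pos, gene))

        def uaug_at(pos, gene=gene):
            t = t_of(pos, gene)
            return sum(
                1
                for i in range(max(t, 0), len(gene.utr_seq) - 2)
                if gene.utr_seq[i : i + 3] == "ATG"
            )

        genic_logit = lambda utr, nu: cfg.te_intercept - math.log(max(utr, 1)) - 0.5 * nu
        add_cluster(
            "canonical", f"{gene.gene_id}_can", gene.gene_id, positions, weights,
            gene.strand, gene.base_mean, gene.gene_log2fc, utr_at, uaug_at,
            genic_logit, gene.gene_id,
        )
        if gene.alt_t is not None:
            alt_sharp = rng.random() < cfg.sharp_frac
            alt_positions, alt_weights = _cluster_profile(rng, gene.alt_peak, alt_sharp)
            alt_mean = gene.base_mean * gene.alt_rel
            alt_fc = gene.gene_log2fc + gene.atss_log2fc
            if gene.orf_effect == "retaining":
                add_cluster(
                    "alt", f"{gene.gene_id}_alt", gene.gene_id, alt_positions,
                    alt_weights, gene.strand, alt_mean, alt_fc, utr_at, uaug_at,
                    genic_logit, gene.gene_id,
                )
            else:
                leader_len = gene.alt_leader_len
                leader_uaug = gene.alt_leader_uaug
                add_cluster(
                    "alt", f"{gene.gene_id}_alt", gene.gene_id, alt_positions,
                    alt_weights, gene.strand, alt_mean, alt_fc,
                    lambda pos, L=leader_len: L, lambda pos, U=leader_uaug: U,
                    genic_logit, gene.gene_id,
                )

    for enh in reference.enhancers:
        total = 2.0 * enh.arm_mean
        for strand, peak, share in (
            ("-", enh.minus_peak, enh.minus_share),
            ("+", enh.plus_peak, 1.0 - enh.minus_share),
        ):
            positions, weights = _cluster_profile(rng, peak, sharp=True)
            add_cluster(
                f"enh_{'minus' if strand == '-' else 'plus'}",
                enh.enhancer_id, enh.linked_gene, positions, weights, strand,
                total * share, enh.cond_log2fc,
                None, None, lambda utr, nu: cfg.enhancer_logit, enh.enhancer_id,
            )

    layer = pd.DataFrame(rows)

    # ---- NB sampling ------------------------------------------------------
    n_nb = 1.0 / cfg.nb_dispersion
    frac_prob_cols = {"Total": None, "Free": "p_free", "Light": "p_light", "Heavy": "p_heavy"}
    tracks = []
    sheet_rows = []
    mean_total = layer["mean_total"].to_numpy()
    fc_mult = 2.0 ** layer["log2fc"].to_numpy()
    latent_keys = layer["latent_key"].to_numpy()
    for sample_id, cond, rep, frac in samples:
        lat = np.array([latent_for(k, cond, rep) for k in latent_keys])
        mean = mean_total * lat
        if cond == "TCL1":
            mean = mean * fc_mult
        col = frac_prob_cols[frac]
        if col is not None:
            mean = mean * layer[col].to_numpy()
        p = n_nb / (n_nb + np.maximum(mean, 1e-12))
        counts = rng.negative_binomial(n_nb, p)
        counts = np.where(mean <= 0, 0, counts)
        keep = counts > 0
        data = pd.DataFrame(
            {
                "chrom": layer["chrom"][keep].to_numpy(),
                "pos": layer["pos"][keep].to_numpy(),
                "strand": layer["strand"][keep].to_numpy(),
                "count": counts[keep],
            }
        )
        data = (
            data.groupby(["chrom", "pos", "strand"], as_index=False)["count"].sum()
        )
        tracks.append(CtssTrack(sample_id, cond, rep, frac, data).sorted())
        sheet_rows.append(
            {
                "sample_id": sample_id,
                "condition": cond,
                "replicate": rep,
                "fraction": frac,
                "path": f"ctss/{sample_id}.bed",
            }
        )

    gene_truth = _gene_truth_table(reference, layer, cfg)
    enhancer_truth = _enhancer_truth_table(reference)
    ctss_truth = layer.drop(columns=["latent_key"])
    return SyntheticDataset(
        reference=reference,
        tracks=tracks,
        sample_sheet=pd.DataFrame(sheet_rows),
        gene_truth=gene_truth,
        enhancer_truth=enhancer_truth,
        ctss_truth=ctss_truth,
    )


def _gene_truth_table(reference, layer, cfg) -> pd.DataFrame:
    # expected polysome-fraction TPM ratio alt/canonical in the profiled condition
    poly = layer.assign(
        poly_mean=layer["mean_total"]
        * (layer["p_light"] + layer["p_heavy"])
        * 2.0 ** (layer["log2fc"] if cfg.profile_condition == "TCL1" else 0.0)
    )
    poly_by_unit = poly.groupby("unit_id")["poly_mean"].sum()
    rows = []
    for gene in reference.genes:
        can = poly_by_unit.get(f"{gene.gene_id}_can", float("nan"))
        alt = poly_by_unit.get(f"{gene.gene_id}_alt", float("nan"))
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "strand": gene.strand,
                "canonical_peak": gene.tss,
                "start_codon_t": gene.utr5_len,
                "utr5_len": gene.utr5_len,
                "n_uaug": gene.n_uaug,
                "alt_peak": gene.alt_peak if gene.alt_t is not None else -1,
                "alt_class": gene.alt_class or "",
                "orf_effect": gene.orf_effect or "",
                "alt_rel": gene.alt_rel if gene.alt_t is not None else float("nan"),
                "alt_leader_len": (
                    gene.alt_leader_len
                    if gene.orf_effect == "truncating"
                    else (gene.utr5_len - gene.alt_t if gene.alt_t is not None else -1)
                ),
                "alt_leader_uaug": (
                    gene.alt_leader_uaug
                    if gene.orf_effect == "truncating"
                    else (
                        sum(
                            1
                            for i in range(gene.alt_t, len(gene.utr_seq) - 2)
                            if gene.utr_seq[i : i + 3] == "ATG"
                        )
                        if gene.alt_t is not None
                        else -1
                    )
                ),
                "gene_log2fc": gene.gene_log2fc,
                "atss_log2fc": gene.atss_log2fc,
                "motif_planted": gene.motif_planted,
                "expected_alt_polysome_ratio": alt / can
                if gene.alt_t is not None
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _enhancer_truth_table(reference) -> pd.DataFrame:
    rows = [
        {
            "enhancer_id": e.enhancer_id,
            "chrom": e.chrom,
            "midpoint": e.midpoint,
            "minus_peak": e.minus_peak,
            "plus_peak": e.plus_peak,
            "location": e.location,
            "linked_gene": e.linked_gene,
            "balanced": e.balanced,
            "minus_share": e.minus_share,
            "arm_mean": e.arm_mean,
            "cond_log2fc": e.cond_log2fc,
        }
        for e in reference.enhancers
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "enhancer_id", "chrom", "midpoint", "minus_peak", "plus_peak",
            "location", "linked_gene", "balanced", "minus_share", "arm_mean",
            "cond_log2fc",
        ],
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Reference + tracks + truth in one call."""
    return generate_ctss_tracks(config, generate_reference(config))


# ---------------------------------------------------------------------------
# on-disk serialization

def write_fasta(reference: Reference, path) -> None:
    seq = reference.sequence()
    with open(path, "w") as fh:
        fh.write(f">{reference.chrom}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_gtf(reference: Reference, path) -> None:
    """Annotation of canonical transcripts only (1-based closed intervals).

    Alternative TSSs are deliberately absent: they are cryptic starts the
    analysis should discover, not annotation.
    """
    with open(path, "w") as fh:
        for gene in sorted(reference.genes, key=lambda g: g.start):
            tx = f"{gene.gene_id}.1"
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx}";'
            def line(feature, s, e):
                fh.write(
                    f"{gene.chrom}\tpolycage_sim\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\t{attrs}\n"
                )
            line("gene", gene.start, gene.end)
            line("transcript", gene.start, gene.end)
            for s_t, e_t in gene.exons_t:
                s, e = gene.interval_g(s_t, e_t)
                line("exon", s, e)
            for s_t, e_t in gene.cds_t:
                s, e = gene.interval_g(s_t, e_t)
                line("CDS", s, e)


def motif_consensus_set(config: SimulationConfig) -> dict:
    """Planted motif plus seeded decoy consensi (synthetic motif panel)."""
    rng = np.random.default_rng(config.seed + 2)
    motifs = {"PLANTED.1 planted_motif": config.planted_motif}
    for i in range(4):
        length = int(rng.integers(8, 13))
        decoy = "".join(rng.choice(list("ACGT"), size=length))
        motifs[f"DECOY.{i + 1} decoy_{i + 1}"] = decoy
    return motifs


def write_motif_file(config: SimulationConfig, path) -> None:
    """JASPAR-format motif set: the planted motif plus decoys (synthetic)."""
    with open(path, "w") as fh:
        for header, consensus in motif_consensus_set(config).items():
            fh.write(f">{header}\n")
            for base in "ACGT":
                row = ["18" if b == base else "2" for b in consensus]
                fh.write(f"{base}  [ {'  '.join(f'{v:>3}' for v in row)} ]\n")


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write FASTA, GTF, per-sample BED6 tracks, truth TSVs and config JSON."""
    os.makedirs(outdir, exist_ok=True)
    ctss_dir = os.path.join(outdir, "ctss")
    os.makedirs(ctss_dir, exist_ok=True)
    ref = dataset.reference
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "gtf": os.path.join(outdir, "annotation.gtf"),
        "sample_sheet": os.path.join(outdir, "sample_sheet.tsv"),
        "motifs": os.path.join(outdir, "motifs.jaspar"),
        "gene_truth": os.path.join(outdir, "truth_genes.tsv"),
        "enhancer_truth": os.path.join(outdir, "truth_enhancers.tsv"),
        "ctss_truth": os.path.join(outdir, "truth_ctss.tsv"),
        "config": os.path.join(outdir, "config.json"),
    }
    write_fasta(ref, paths["genome"])
    write_gtf(ref, paths["gtf"])
    write_motif_file(ref.config, paths["motifs"])
    for track in dataset.tracks:
        write_ctss_bed(track, os.path.join(ctss_dir, f"{track.sample_id}.bed"))
    dataset.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    dataset.gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)
    dataset.enhancer_truth.to_csv(paths["enhancer_truth"], sep="\t", index=False)
    dataset.ctss_truth.to_csv(paths["ctss_truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(ref.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def simulate_motif_windows(
    n_fg: int,
    n_bg: int,
    motif: str,
    fg_rate: float,
    bg_rate: float,
    length: int = 600,
    seed: int = 0,
):
    """Sequence-only synthetic promoter sets with a motif planted at known
    rates; returns (fg_windows, bg_windows, planted_fg_ids, planted_bg_ids)."""
    rng = np.random.default_rng(seed)

    def make(n, rate, prefix):
        windows, planted = {}, set()
        for i in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            name = f"{prefix}{i:04d}"
            if rng.random() < rate:
                at = int(rng.integers(0, length - len(motif)))
                seq = seq[:at] + motif + seq[at + len(motif):]
                planted.add(name)
            windows[name] = seq
        return windows, planted

    fg, fg_planted = make(n_fg, fg_rate, "FG")
    bg, bg_planted = make(n_bg, bg_rate, "BG")
    return fg, bg, fg_planted, bg_planted
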