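"""Gene-structure annotation of tag clusters and alternative-TSS calling.

Each cluster peak is assigned one gene-structure category (promoter >
5' UTR > CDS > exon > intron, then antisense, then intergenic).  Within a
gene, clusters contributing at least 10% of total gene expression form the
multi-TSS set; the canonical TSS is the retained cluster at the annotated
promoter (falling back to the highest-expressed one) and every other
retained cluster is an alternative TSS, classified as ORF-retaining or
ORF-truncating by its position relative to the annotated start codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seq import fetch, revcomp

CATEGORY_ORDER = ["promoter", "fiveUTR", "CDS", "exon", "intron", "antisense", "intergenic"]


@dataclass
class TranscriptModel:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list  # [(start, end)] 0-based half-open, genomically sorted
    cds: list  # [(start, end)] genomically sorted; empty for noncoding

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Genomic position of the transcript's 5'-most base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def start_codon_pos(self) -> int | None:
        """Genomic position of the first base of the annotated start codon."""
        if not self.cds:
            return None
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1] - 1

    def exonic_positions(self):
        """All exonic genomic positions in transcript (5'->3') order."""
        pos = [p for s, e in self.exons for p in range(s, e)]
        return pos if self.strand == "+" else pos[::-1]


@dataclass
class GeneStructureCall:
    cluster_id: str
    gene_id: str | None
    tx_id: str | None
    category: str
    distance_to_annotated_tss: int | None  # signed, transcript orientation


def load_annotation(gtf_path) -> list[TranscriptModel]:
    """Load transcript models from a GTF (1-based closed, converted on read)."""
    import pyranges as pr

    df = pr.read_gtf(gtf_path).df
    models = []
    for tx_id, grp in df[df["Feature"].isin(["exon", "CDS"])].groupby("transcript_id"):
        exons = sorted(
            (int(r.Start), int(r.End))
            for r in grp[grp["Feature"] == "exon"].itertuples()
        )
        cds = sorted(
            (int(r.Start), int(r.End))
            for r in grp[grp["Feature"] == "CDS"].itertuples()
        )
        if not exons:
            continue
        first = grp.iloc[0]
        models.append(
            TranscriptModel(
                tx_id=tx_id,
                gene_id=str(first["gene_id"]),
                chrom=str(first["Chromosome"]),
                strand=str(first["Strand"]),
                exons=exons,
                cds=cds,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.tx_id))
    return models


def _categorize_against(tx: TranscriptModel, peak: int, promoter_pad: int) -> str | None:
    """Category of a same-strand peak against one transcript, or None."""
    if abs(peak - tx.tss) <= promoter_pad:
        return "promoter"
    if not (tx.start <= peak < tx.end):
        return None
    in_exon = any(s <= peak < e for s, e in tx.exons)
    if not in_exon:
        return "intron"
    if tx.cds:
        sc = tx.start_codon_pos
        upstream_of_cds = peak < sc if tx.strand == "+" else peak > sc
        if upstream_of_cds:
            return "fiveUTR"
        if any(s <= peak < e for s, e in tx.cds):
            return "CDS"
    return "exon"


def assign_genomic_category(
    cluster,
    transcripts: list[TranscriptModel],
    promoter_pad: int = 100,
) -> GeneStructureCall:
    """Assign one gene-structure category to a cluster peak.

    Same-strand transcripts are tested with precedence promoter > fiveUTR >
    CDS > exon > intron; failing those, opposite-strand overlap gives
    antisense, and anything else is intergenic.  The assignment only
    depends on the set of transcripts, never on their input order.
    """
    rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    best: tuple | None = None
    for tx in transcripts:
        if tx.chrom != cluster.chrom or tx.strand != cluster.strand:
            continue
        cat = _categorize_against(tx, cluster.peak, promoter_pad)
        if cat is None:
            continue
        signed = (cluster.peak - tx.tss) * (1 if tx.strand == "+" else -1)
        key = (rank[cat], abs(signed), tx.tx_id)
        if best is None or key < best[0]:
            best = (key, cat, tx, signed)
    if best is not None:
        _, cat, tx, signed = best
        return GeneStructureCall(cluster.cluster_id, tx.gene_id, tx.tx_id, cat, signed)
    for tx in transcripts:
        if tx.chrom != cluster.chrom or tx.strand == cluster.strand:
            continue
        if tx.start <= cluster.peak < tx.end:
            return GeneStructureCall(cluster.cluster_id, tx.gene_id, tx.tx_id, "antisense", None)
    return GeneStructureCall(cluster.cluster_id, None, None, "intergenic", None)


def annotate_clusters(
    clusters: list, transcripts: list[TranscriptModel], promoter_pad: int = 100
) -> pd.DataFrame:
    calls = [assign_genomic_category(cl, transcripts, promoter_pad) for cl in clusters]
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in calls],
            "gene_id": [c.gene_id for c in calls],
            "tx_id": [c.tx_id for c in calls],
            "category": [c.category for c in calls],
            "distance_to_annotated_tss": [c.distance_to_annotated_tss for c in calls],
        }
    )


@dataclass
class GeneTssSet:
    gene_id: str
    canonical_cluster_id: str
    alternative_cluster_ids: list
    shares: dict  # cluster_id -> share of gene expression (retained clusters)


def designate_canonical_and_alternatives(
    clusters: list,
    annotations: pd.DataFrame,
    min_share: float = 0.10,
) -> dict[str, GeneTssSet]:
    """Per-gene canonical / alternative TSS designation under the 10% rule.

    Clusters contributing less than ``min_share`` of the gene's pooled
    expression are discarded from the multi-TSS analysis.  The canonical
    TSS is the retained cluster annotated as promoter (highest-expressed
    if several); a gene with no promoter-category cluster falls back to
    the highest-expressed retained cluster, ties broken by the transcript-
     5'-most peak and then cluster id, so shuffled input order never
    changes the call.
    """
    by_id = {cl.cluster_id: cl for cl in clusters}
    genic = annotations[
        annotations["gene_id"].notna()
        & ~annotations["category"].isin(["antisense", "intergenic"])
    ]
    out: dict[str, GeneTssSet] = {}
    for gene_id, grp in genic.groupby("gene_id"):
        members = [by_id[cid] for cid in grp["cluster_id"] if cid in by_id]
        total = sum(cl.pooled_tpm for cl in members)
        if total <= 0:
            continue
        retained = [cl for cl in members if cl.pooled_tpm / total >= min_share]
        if not retained:
            continue
        cats = dict(zip(grp["cluster_id"], grp["category"]))
        strand = retained[0].strand
        five_prime_key = (lambda cl: cl.peak) if strand == "+" else (lambda cl: -cl.peak)

        def sort_key(cl):
            return (-cl.pooled_tpm, five_prime_key(cl), cl.cluster_id)

        promoter_clusters = [cl for cl in retained if cats.get(cl.cluster_id) == "promoter"]
        pool = promoter_clusters if promoter_clusters else retained
        canonical = min(pool, key=sort_key)
        alternatives = sorted(
            (cl.cluster_id for cl in retained if cl.cluster_id != canonical.cluster_id)
        )
        out[gene_id] = GeneTssSet(
            gene_id=gene_id,
            canonical_cluster_id=canonical.cluster_id,
            alternative_cluster_ids=alternatives,
            shares={cl.cluster_id: cl.pooled_tpm / total for cl in retained},
        )
    return out


def classify_orf_effect(peak: int, tx: TranscriptModel) -> str:
    """ORF-retaining vs -truncating call for an alternative TSS peak.

    Retaining iff the peak lies strictly upstream (transcript orientation)
    of the annotated start codon; a peak at or downstream of the start
    codon's first base truncates (or N-terminally modifies) the ORF.
    """
    sc = tx.start_codon_pos
    if sc is None:
        raise ValueError(f"{tx.tx_id} has no annotated CDS; noncoding genes excluded")
    downstream = peak >= sc if tx.strand == "+" else peak <= sc
    return "truncating" if downstream else "retaining"


def count_uaug_and_utr_length(peak: int, tx: TranscriptModel, genome) -> tuple[int, int]:
    """Spliced 5' UTR length and upstream-AUG count for a retaining TSS.

    The 5' UTR runs from the TSS peak to the base before the annotated
    start codon along the transcript's exonic path; peaks upstream of the
    annotated transcript start extend it with unspliced genomic sequence.
    AUGs are counted in all frames, overlapping occurrences allowed.
    """
    sc = tx.start_codon_pos
    if sc is None:
        raise ValueError(f"{tx.tx_id} has no annotated CDS")
    if classify_orf_effect(peak, tx) == "truncating":
        raise ValueError("5' UTR undefined: peak downstream of start codon")
    path = tx.exonic_positions()
    sc_idx = path.index(sc)
    if peak in path[:sc_idx]:
        utr_positions = path[path.index(peak): sc_idx]
    else:
        # peak upstream of the annotated transcript: unspliced extension
        if tx.strand == "+":
            upstream = list(range(peak, tx.start))
        else:
            upstream = list(range(tx.end, peak + 1))[::-1]
        utr_positions = upstream + path[:sc_idx]
    bases = []
    for p in utr_positions:
        base = fetch(genome, tx.chrom, p, p + 1)
        bases.append(base if tx.strand == "+" else revcomp(base))
    utr = "".join(bases)
    n_uaug = sum(1 for i in range(len(utr) - 2) if utr[i : i + 3] == "ATG")
    return len(utr), n_uaug


def build_atss_table(
    clusters: list,
    annotations: pd.DataFrame,
    gene_sets: dict[str, GeneTssSet],
    transcripts: list[TranscriptModel],
) -> pd.DataFrame:
    """One row per (gene, alternative TSS) with its ORF-effect class."""
    by_id = {cl.cluster_id: cl for cl in clusters}
    tx_by_gene: dict = {}
    for tx in transcripts:
        tx_by_gene.setdefault(tx.gene_id, tx)
    rows = []
    for gene_id, gs in sorted(gene_sets.items()):
        tx = tx_by_gene.get(gene_id)
        if tx is None or not tx.cds:
            continue
        for alt_id in gs.alternative_cluster_ids:
            alt = by_id[alt_id]
            rows.append(
                {
                    "gene_id": gene_id,
                    "canonical_cluster_id": gs.canonical_cluster_id,
                    "alt_cluster_id": alt_id,
                    "orf_effect": classify_orf_effect(alt.peak, tx),
                    "alt_share": gs.shares[alt_id],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "canonical_cluster_id", "alt_cluster_id", "orf_effect", "alt_share"],
    )
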