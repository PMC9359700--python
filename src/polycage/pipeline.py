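"""End-to-end orchestration: simulate/load -> clusters -> enhancers ->
DE/DTU -> annotation -> translation -> start-sequence -> motifs -> report.

The pipeline mirrors the analysis order of a polysome-CAGE study: promoter
and enhancer calling on pooled Total-RNA signal, differential expression
and differential TSS usage between conditions, per-isoform translation
efficiency from the polysome fractions of the profiled condition, and
cap-proximal sequence / TF-motif characterization of the shifted
promoters.  Every tabular output is written atomically (temp + rename).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann
from . import clustering as clus
from . import core
from . import diffexp
from . import enhancers as enh
from . import motifs as mot
from . import simulate as sim
from . import startseq
from . import translation as tra

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "polycage_run"
    seed: int = 0
    # either simulate in place ...
    simulation: sim.SimulationConfig | None = None
    # ... or load an existing dataset from disk
    sample_sheet: str | None = None
    genome: str | None = None
    gtf: str | None = None
    motif_file: str | None = None
    # stage parameters
    slice_threshold: float = 0.1
    merge_dist: int = 20
    min_cluster_tpm: float = 1.0
    enhancer_window: int = 400
    balance_threshold: float = 0.95
    link_max_dist: int = 50_000
    promoter_pad: int = 100
    min_share: float = 0.10
    alpha: float = 0.05
    te_pseudocount: float = 1.0
    te_fold: float = 2.0
    truncation_threshold: float = 0.5
    kmer_min_support: int = 50
    motif_rel_threshold: float = 0.85
    profile_condition: str = "TCL1"
    # stage toggles
    run_enhancers: bool = True
    run_diffexp: bool = True
    run_translation: bool = True
    run_startseq: bool = True
    run_motifs: bool = True


@dataclass
class RunResult:
    config: RunConfig
    clusters: list
    cluster_annotations: pd.DataFrame
    gene_sets: dict
    atss_table: pd.DataFrame
    enhancer_calls: list = field(default_factory=list)
    enhancer_links: list = field(default_factory=list)
    erna_fractions: dict = field(default_factory=dict)
    de_results: pd.DataFrame | None = None
    dtu_results: pd.DataFrame | None = None
    te_table: pd.DataFrame | None = None
    truncation_table: pd.DataFrame | None = None
    occupancy: pd.DataFrame | None = None
    ctss_te: pd.DataFrame | None = None
    kmer_summary_k1: pd.DataFrame | None = None
    kmer_summary_k3: pd.DataFrame | None = None
    start_frequencies: pd.Series | None = None
    enrichment: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def atomic_write_table(df: pd.DataFrame, path: str, **kwargs) -> None:
    """Write a TSV via a temp file + rename so readers never see a torn file."""
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, sep="\t", **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _samples(sheet: pd.DataFrame, fraction=None, condition=None) -> list[str]:
    sel = pd.Series(True, index=sheet.index)
    if fraction is not None:
        sel &= sheet["fraction"] == fraction
    if condition is not None:
        sel &= sheet["condition"] == condition
    return list(sheet.loc[sel, "sample_id"])


def _cluster_fraction_tpm(clusters, sample_ids) -> dict:
    """cluster_id -> replicate-mean TPM over the given samples."""
    out = {}
    for cl in clusters:
        vals = [cl.tpm.get(s, 0.0) for s in sample_ids]
        out[cl.cluster_id] = float(np.mean(vals)) if vals else 0.0
    return out


def load_inputs(config: RunConfig):
    """Resolve the run's dataset: simulate in-memory or read from disk."""
    if config.simulation is not None:
        dataset = sim.simulate_dataset(config.simulation)
        genome = dataset.reference.genome_dict()
        transcripts = _transcripts_from_reference(dataset.reference)
        sheet = dataset.sample_sheet
        tracks = dataset.tracks
        motif_path = None
        return tracks, sheet, genome, transcripts, motif_path, dataset
    if not (config.sample_sheet and config.genome and config.gtf):
        raise ValueError("RunConfig needs either a simulation or dataset paths")
    import pyfaidx

    sheet = core.read_sample_sheet(config.sample_sheet)
    tracks = core.load_tracks(sheet, base_dir=os.path.dirname(config.sample_sheet))
    genome = pyfaidx.Fasta(config.genome)
    transcripts = ann.load_annotation(config.gtf)
    return tracks, sheet, genome, transcripts, config.motif_file, None


def _transcripts_from_reference(reference) -> list:
    """Annotation models straight from the simulator (bypasses GTF I/O)."""
    models = []
    for g in reference.genes:
        exons = sorted(g.interval_g(s, e) for s, e in g.exons_t)
        cds = sorted(g.interval_g(s, e) for s, e in g.cds_t)
        models.append(
            ann.TranscriptModel(
                tx_id=f"{g.gene_id}.1",
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                exons=exons,
                cds=cds,
            )
        )
    return models


def run_all(config: RunConfig, write: bool = True) -> RunResult:
    """Run every enabled stage; a stage failure aborts with the stage named
    while earlier outputs stay on disk."""
    t0 = time.time()
    stage = "load"
    try:
        tracks, sheet, genome, transcripts, motif_path, dataset = load_inputs(config)
        if write:
            os.makedirs(config.outdir, exist_ok=True)
            _write_resolved_config(config)

        stage = "normalize"
        tpm_tracks = [core.tpm_normalize(t) for t in tracks]
        by_key = {(t.condition, t.replicate, t.fraction): t for t in tracks}
        poly_tracks = []
        for (cond, rep) in sorted({(t.condition, t.replicate) for t in tracks}):
            light = by_key.get((cond, rep, "Light"))
            heavy = by_key.get((cond, rep, "Heavy"))
            if light is not None and heavy is not None:
                poly_tracks.append(core.merge_fractions(light, heavy))
        all_tracks = tracks + poly_tracks
        sheet_all = pd.concat(
            [
                sheet,
                pd.DataFrame(
                    [
                        {
                            "sample_id": t.sample_id,
                            "condition": t.condition,
                            "replicate": t.replicate,
                            "fraction": "Polysomes",
                            "path": "",
                        }
                        for t in poly_tracks
                    ]
                ),
            ],
            ignore_index=True,
        )

        stage = "clustering"
        total_ids = _samples(sheet, fraction="Total")
        pooled_total = core.pool_tracks(
            [t for t in tpm_tracks if t.sample_id in total_ids]
        )
        clusters = clus.slice_reduce_cluster(
            pooled_total,
            tracks=all_tracks,
            slice_threshold=config.slice_threshold,
            merge_dist=config.merge_dist,
        )
        logger.info("clustering: %d clusters", len(clusters))

        enhancer_calls: list = []
        enhancer_links: list = []
        if config.run_enhancers:
            stage = "enhancers"
            candidates = enh.detect_bidirectional_candidates(
                pooled_total,
                window=config.enhancer_window,
                tracks=[t for t in tracks if t.fraction == "Total"],
                balance_threshold=config.balance_threshold,
            )
            enhancer_calls = candidates
            called_windows = {}
            for e in candidates:
                if e.called:
                    called_windows.setdefault(e.chrom, []).append((e.start, e.end))
            # an enhancer window claims its positions: drop TSS clusters inside
            def in_enhancer(cl):
                return any(
                    s <= cl.peak < e
                    for s, e in called_windows.get(cl.chrom, ())
                )
            erna_clusters = [cl for cl in clusters if in_enhancer(cl)]
            clusters = [cl for cl in clusters if not in_enhancer(cl)]
            logger.info(
                "enhancers: %d candidates, %d called",
                len(candidates),
                sum(e.called for e in candidates),
            )
        else:
            erna_clusters = []

        stage = "expression_filter"
        cond_of = dict(
            zip(sheet["sample_id"], sheet["condition"])
        )
        clusters = clus.filter_low_expression(
            clusters,
            {s: cond_of[s] for s in total_ids},
            min_tpm=config.min_cluster_tpm,
        )
        logger.info("expression filter: %d clusters kept", len(clusters))

        stage = "annotation"
        annotations = ann.annotate_clusters(clusters, transcripts, config.promoter_pad)
        # eRNA fractions are computed over all clusters before enhancer removal
        all_for_categories = clusters + erna_clusters
        annotations_all = ann.annotate_clusters(
            all_for_categories, transcripts, config.promoter_pad
        )
        erna_fractions = enh.classify_intergenic_intronic_ernas(
            annotations_all, enhancer_calls, all_for_categories
        )
        gene_sets = ann.designate_canonical_and_alternatives(
            clusters, annotations, min_share=config.min_share
        )
        atss_table = ann.build_atss_table(clusters, annotations, gene_sets, transcripts)

        de_results = None
        dtu_results = None
        conditions_total = pd.Series(
            {s: cond_of[s] for s in total_ids}
        )
        if config.run_diffexp:
            stage = "diffexp"
            counts = clus.count_matrix(clusters)[total_ids]
            settings = diffexp.DeSettings(alpha=config.alpha)
            de_results = diffexp.de_test(counts, conditions_total, settings=settings)
            cluster_gene = {}
            for gene_id, gs in gene_sets.items():
                for cid in [gs.canonical_cluster_id, *gs.alternative_cluster_ids]:
                    cluster_gene[cid] = gene_id
            dtu_results = diffexp.dtu_test(
                counts, pd.Series(cluster_gene), conditions_total, settings=settings
            )

        te_table = None
        truncation_table = None
        occupancy = None
        if config.run_translation:
            stage = "translation"
            pc_cond = config.profile_condition
            free_tpm = _cluster_fraction_tpm(clusters, _samples(sheet_all, "Free", pc_cond))
            light_tpm = _cluster_fraction_tpm(clusters, _samples(sheet_all, "Light", pc_cond))
            heavy_tpm = _cluster_fraction_tpm(clusters, _samples(sheet_all, "Heavy", pc_cond))
            te_records = tra.compute_te(
                free_tpm, light_tpm, heavy_tpm, pseudocount=config.te_pseudocount
            )
            te_by_id = {r.cluster_id: r for r in te_records}
            rows = []
            for gene_id, gs in sorted(gene_sets.items()):
                can = te_by_id.get(gs.canonical_cluster_id)
                if can is None:
                    continue
                for alt_id in gs.alternative_cluster_ids:
                    alt = te_by_id.get(alt_id)
                    if alt is None:
                        continue
                    rows.append(
                        {
                            "gene_id": gene_id,
                            "canonical_cluster_id": can.cluster_id,
                            "alt_cluster_id": alt.cluster_id,
                            "te_canonical": can.te,
                            "te_alt": alt.te,
                            "te_class": tra.classify_differential_te(
                                alt.te, can.te, fold=config.te_fold
                            ),
                        }
                    )
            te_table = pd.DataFrame(
                rows,
                columns=[
                    "gene_id", "canonical_cluster_id", "alt_cluster_id",
                    "te_canonical", "te_alt", "te_class",
                ],
            )

            poly_ids = _samples(sheet_all, "Polysomes", pc_cond)
            poly_tpm = _cluster_fraction_tpm(clusters, poly_ids)
            de_fc = (
                de_results["log2_fc"] if de_results is not None else pd.Series(dtype=float)
            )
            trows = []
            truncating = atss_table[atss_table["orf_effect"] == "truncating"]
            for r in truncating.itertuples(index=False):
                impact = tra.truncation_impact(
                    r.gene_id,
                    r.canonical_cluster_id,
                    r.alt_cluster_id,
                    poly_tpm.get(r.alt_cluster_id, 0.0),
                    poly_tpm.get(r.canonical_cluster_id, 0.0),
                    threshold=config.truncation_threshold,
                )
                alt_total = _cluster_fraction_tpm(
                    [c for c in clusters if c.cluster_id == r.alt_cluster_id],
                    _samples(sheet_all, "Total", pc_cond),
                ).get(r.alt_cluster_id, 0.0)
                can_total = _cluster_fraction_tpm(
                    [c for c in clusters if c.cluster_id == r.canonical_cluster_id],
                    _samples(sheet_all, "Total", pc_cond),
                ).get(r.canonical_cluster_id, 0.0)
                within_ratio = np.log2(
                    (alt_total + config.te_pseudocount)
                    / (can_total + config.te_pseudocount)
                )
                cond_fc = float(de_fc.get(r.alt_cluster_id, 0.0))
                trows.append(
                    {
                        "gene_id": impact.gene_id,
                        "canonical_cluster_id": impact.canonical_cluster_id,
                        "alt_cluster_id": impact.alt_cluster_id,
                        "polysome_ratio": impact.polysome_ratio,
                        "impact": impact.impact,
                        "condition_log2_fc": cond_fc,
                        "alt_vs_canonical_log2": within_ratio,
                        "inclusive_log2_fc": tra.inclusive_log_fc(cond_fc, within_ratio),
                        "flagged": impact.flagged,
                    }
                )
            truncation_table = pd.DataFrame(
                trows,
                columns=[
                    "gene_id", "canonical_cluster_id", "alt_cluster_id",
                    "polysome_ratio", "impact", "condition_log2_fc",
                    "alt_vs_canonical_log2", "inclusive_log2_fc", "flagged",
                ],
            )

            cat_of = dict(zip(annotations_all["cluster_id"], annotations_all["category"]))
            occ_rows = {}
            for frac in ("Free", "Light", "Heavy"):
                ids = _samples(sheet_all, frac, pc_cond)
                vals = _cluster_fraction_tpm(all_for_categories, ids)
                for cl in all_for_categories:
                    cat = cat_of.get(cl.cluster_id, "intergenic")
                    occ_rows.setdefault(cat, {}).setdefault(frac, 0.0)
                    occ_rows[cat][frac] += vals.get(cl.cluster_id, 0.0)
            occupancy = tra.fraction_occupancy_by_category(
                pd.DataFrame(occ_rows).T.fillna(0.0)
            )

        ctss_te = None
        kmer1 = kmer3 = None
        start_freqs = None
        if config.run_startseq:
            stage = "startseq"
            pc_cond = config.profile_condition

            def pooled_fraction(frac):
                ids = _samples(sheet, frac, pc_cond)
                return core.pool_tracks(
                    [t for t in tpm_tracks if t.sample_id in ids]
                )

            ctss_te = tra.ctss_te_table(
                pooled_fraction("Free"),
                pooled_fraction("Light"),
                pooled_fraction("Heavy"),
                pseudocount=config.te_pseudocount,
            )
            ctss_te = startseq.attach_start_kmers(ctss_te, genome, k=3)
            ctss_te["is_cny"] = [startseq.classify_cny(k) for k in ctss_te["kmer"]]
            kmer3 = startseq.te_by_start_kmer(
                ctss_te, k=3, min_support=config.kmer_min_support
            )
            kmer1 = startseq.te_by_start_kmer(
                ctss_te, k=1, min_support=config.kmer_min_support
            )
            weights = ctss_te["free"] + ctss_te["polysome"]
            start_freqs = startseq.start_nt_frequencies(ctss_te["kmer"], weights)

        enrichment = None
        if config.run_motifs and (motif_path or dataset is not None):
            stage = "motifs"
            if motif_path is not None:
                pfms = mot.read_jaspar_pfm(motif_path)
            else:
                pfms = []
                for header, consensus in sim.motif_consensus_set(
                    dataset.reference.config
                ).items():
                    counts = np.full((4, len(consensus)), 2.0)
                    for j, base in enumerate(consensus):
                        counts["ACGT".index(base), j] = 18.0
                    motif_id, name = header.split(" ", 1)
                    pfms.append(mot.Pfm(motif_id, name, counts))
            by_id = {cl.cluster_id: cl for cl in clusters}
            if dtu_results is not None and len(dtu_results):
                alt_ids = set(atss_table["alt_cluster_id"])
                sig_up = dtu_results[
                    (dtu_results["fdr"] < config.alpha)
                    & (dtu_results["direction"] == "up")
                    & dtu_results["cluster_id"].isin(alt_ids)
                ]["cluster_id"]
                fg_clusters = [by_id[c] for c in sig_up if c in by_id]
            else:
                fg_clusters = []
            fg_genes = {
                annotations.set_index("cluster_id")["gene_id"].get(cl.cluster_id)
                for cl in fg_clusters
            }
            bg_clusters = [
                by_id[cid]
                for cid in annotations.loc[
                    annotations["category"] == "promoter", "cluster_id"
                ]
                if cid in by_id
                and annotations.set_index("cluster_id")["gene_id"].get(cid)
                not in fg_genes
            ]
            if fg_clusters and bg_clusters:
                fg_windows = mot.promoter_windows(fg_clusters, genome)
                bg_windows = mot.promoter_windows(bg_clusters, genome)
                fg_mat = mot.occurrence_matrix(
                    fg_windows, pfms, rel_threshold=config.motif_rel_threshold
                )
                bg_mat = mot.occurrence_matrix(
                    bg_windows, pfms, rel_threshold=config.motif_rel_threshold
                )
                enrichment = mot.enrichment_fisher(fg_mat, bg_mat, alpha=config.alpha)

        stage = "report"
        summary = _summarize(
            clusters, annotations_all, erna_fractions, gene_sets, de_results,
            dtu_results, te_table, truncation_table, kmer1, enrichment, config,
            atss_table,
        )
        result = RunResult(
            config=config,
            clusters=clusters,
            cluster_annotations=annotations,
            gene_sets=gene_sets,
            atss_table=atss_table,
            enhancer_calls=enhancer_calls,
            enhancer_links=enhancer_links,
            erna_fractions=erna_fractions,
            de_results=de_results,
            dtu_results=dtu_results,
            te_table=te_table,
            truncation_table=truncation_table,
            occupancy=occupancy,
            ctss_te=ctss_te,
            kmer_summary_k1=kmer1,
            kmer_summary_k3=kmer3,
            start_frequencies=start_freqs,
            enrichment=enrichment,
            summary=summary,
        )
        if write:
            _write_outputs(result)
        logger.info("run_all finished in %.1f s", time.time() - t0)
        return result
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def _summarize(clusters, annotations_all, erna_fractions, gene_sets, de, dtu,
               te_table, truncation_table, kmer1, enrichment, config,
               atss_table=None) -> dict:
    summary: dict = {
        "n_clusters": len(clusters),
        "category_counts": annotations_all["category"].value_counts().to_dict(),
        "erna_fraction_intron": erna_fractions.get("intron", 0.0),
        "erna_fraction_intergenic": erna_fractions.get("intergenic", 0.0),
        "n_genes_detected": int(annotations_all["gene_id"].nunique()),
        "n_multi_tss_genes": sum(
            1 for gs in gene_sets.values() if gs.alternative_cluster_ids
        ),
    }
    n_genes_with_tss = len(gene_sets)
    summary["multi_tss_gene_fraction"] = (
        summary["n_multi_tss_genes"] / n_genes_with_tss if n_genes_with_tss else 0.0
    )
    if de is not None:
        summary["de_up"] = int((de["status"] == "up").sum())
        summary["de_down"] = int((de["status"] == "down").sum())
    if dtu is not None and len(dtu):
        sig = dtu[dtu["fdr"] < config.alpha]
        if atss_table is not None and len(atss_table):
            # promoter-shift events are counted at the alternative TSS
            sig = sig[sig["cluster_id"].isin(set(atss_table["alt_cluster_id"]))]
        summary["dtu_up"] = int((sig["direction"] == "up").sum())
        summary["dtu_down"] = int((sig["direction"] == "down").sum())
    if te_table is not None and len(te_table):
        vc = te_table["te_class"].value_counts()
        summary["te_diff_high"] = int(vc.get("diff_high", 0))
        summary["te_diff_low"] = int(vc.get("diff_low", 0))
        summary["te_neutral"] = int(vc.get("neutral", 0))
    if truncation_table is not None and len(truncation_table):
        vc = truncation_table["impact"].value_counts()
        summary["truncation_substantial"] = int(vc.get("substantial", 0))
        summary["truncation_sparse"] = int(vc.get("sparse", 0))
    if kmer1 is not None and len(kmer1):
        summary["median_te_by_first_nt"] = dict(
            zip(kmer1["kmer"], kmer1["median_te"].round(4))
        )
    if enrichment is not None:
        summary["n_enriched_motifs"] = int(enrichment["enriched"].sum())
    return summary


def _write_resolved_config(config: RunConfig) -> None:
    resolved = dataclasses.asdict(config)
    path = os.path.join(config.outdir, "run_config.json")
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    os.replace(tmp, path)


def _write_outputs(result: RunResult) -> None:
    out = result.config.outdir
    os.makedirs(out, exist_ok=True)
    atomic_write_table(
        clus.clusters_to_frame(result.clusters), os.path.join(out, "clusters.tsv"),
        index=False,
    )
    atomic_write_table(
        clus.count_matrix(result.clusters), os.path.join(out, "cluster_counts.tsv")
    )
    atomic_write_table(
        result.cluster_annotations, os.path.join(out, "cluster_annotation.tsv"),
        index=False,
    )
    atomic_write_table(result.atss_table, os.path.join(out, "atss.tsv"), index=False)
    if result.enhancer_calls:
        atomic_write_table(
            enh.enhancers_to_frame(result.enhancer_calls),
            os.path.join(out, "enhancers.tsv"),
            index=False,
        )
    if result.de_results is not None:
        atomic_write_table(result.de_results, os.path.join(out, "de_results.tsv"))
    if result.dtu_results is not None:
        atomic_write_table(
            result.dtu_results, os.path.join(out, "dtu_results.tsv"), index=False
        )
    if result.te_table is not None:
        atomic_write_table(result.te_table, os.path.join(out, "te_pairs.tsv"), index=False)
    if result.truncation_table is not None:
        atomic_write_table(
            result.truncation_table, os.path.join(out, "truncation_impact.tsv"),
            index=False,
        )
    if result.occupancy is not None:
        atomic_write_table(result.occupancy, os.path.join(out, "fraction_occupancy.tsv"))
    if result.kmer_summary_k3 is not None:
        atomic_write_table(
            result.kmer_summary_k3, os.path.join(out, "te_by_trinucleotide.tsv"),
            index=False,
        )
    if result.enrichment is not None:
        atomic_write_table(
            result.enrichment, os.path.join(out, "motif_enrichment.tsv"), index=False
        )
    path = os.path.join(out, "summary.json")
    fd, tmp = tempfile.mkstemp(dir=out, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    os.replace(tmp, path)
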