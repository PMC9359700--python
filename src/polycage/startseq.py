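"""Cap-proximal sequence analysis: start k-mers, CNY class, LOGO matrices.

CAGE pins the first transcribed base of every transcript, so the genomic
sequence at a CTSS is the transcript's exact 5' end.  This module
extracts strand-aware start k-mers, summarizes TE by first
nucleotide/di-/trinucleotide, classifies the translation-inhibitory CNY
start class (C, anything, pyrimidine), and builds positional nucleotide
frequency matrices for promoter windows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .seq import fetch, revcomp

logger = logging.getLogger(__name__)

_VALID = set("ACGT")


def extract_start_kmer(genome, chrom: str, pos: int, strand: str, k: int) -> str | None:
    """First ``k`` transcribed bases of a CTSS, in transcript orientation.

    Plus strand reads genome[pos .. pos+k); minus strand reverse-
    complements genome[pos-k+1 .. pos].  Returns None (to be skipped and
    counted by the caller) when the window leaves the chromosome or
    contains a non-ACGT base.
    """
    try:
        if strand == "+":
            kmer = fetch(genome, chrom, pos, pos + k)
        elif strand == "-":
            kmer = revcomp(fetch(genome, chrom, pos - k + 1, pos + 1))
        else:
            raise ValueError(f"invalid strand {strand!r}")
    except IndexError:
        return None
    if set(kmer) - _VALID:
        return None
    return kmer


def attach_start_kmers(ctss: pd.DataFrame, genome, k: int) -> pd.DataFrame:
    """Add a ``kmer`` column to a per-CTSS table (chrom/pos/strand/...).

    Rows whose k-mer cannot be extracted are dropped; the number skipped
    is logged.
    """
    kmers = [
        extract_start_kmer(genome, c, int(p), s, k)
        for c, p, s in zip(ctss["chrom"], ctss["pos"], ctss["strand"])
    ]
    out = ctss.copy()
    out["kmer"] = kmers
    skipped = out["kmer"].isna().sum()
    if skipped:
        logger.info("skipped %d CTSSs without a valid %d-mer", skipped, k)
    return out.dropna(subset=["kmer"]).reset_index(drop=True)


def start_nt_frequencies(
    kmers: pd.Series | list,
    weights=None,
) -> pd.Series:
    """Share of starts per first nucleotide, TPM-weighted when weights given."""
    kmers = pd.Series(kmers)
    if len(kmers) == 0:
        raise ValueError("no start records")
    first = kmers.str[0]
    if weights is None:
        freqs = first.value_counts(normalize=True)
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=first.index)
        freqs = w.groupby(first).sum() / w.sum()
    return freqs.reindex(list("ACGT"), fill_value=0.0)


def te_by_start_kmer(
    records: pd.DataFrame,
    k: int | None = None,
    min_support: int = 50,
) -> pd.DataFrame:
    """Distribution summaries of TE per start k-mer.

    ``records`` needs ``kmer`` and ``te`` columns (per-CTSS); ``k``
    truncates the stored k-mers to a shorter prefix, so k=1 summaries are
    the support-weighted marginal of k=3 groups.  K-mers observed fewer
    than ``min_support`` times are omitted.
    """
    df = records.copy()
    if k is not None:
        df["kmer"] = df["kmer"].str[:k]
    rows = []
    for kmer, grp in df.groupby("kmer", sort=True):
        if len(grp) < min_support:
            continue
        te = grp["te"].to_numpy(dtype=float)
        q5, q25, q75, q95 = np.percentile(te, [5, 25, 75, 95])
        rows.append(
            {
                "kmer": kmer,
                "n_ctss": len(grp),
                "total_tpm": float(grp["free"].sum() + grp["polysome"].sum())
                if {"free", "polysome"} <= set(grp.columns)
                else float("nan"),
                "median_te": float(np.median(te)),
                "q5": q5,
                "q25": q25,
                "q75": q75,
                "q95": q95,
            }
        )
    return pd.DataFrame(
        rows, columns=["kmer", "n_ctss", "total_tpm", "median_te", "q5", "q25", "q75", "q95"]
    )


def classify_cny(trinucleotide: str) -> bool:
    """True for the CNY start class: C first, pyrimidine (C/T) third.

    CNY-initiating transcripts show strongly reduced translation
    efficiency, echoing the 5' TOP-like repression seen under metabolic
    stress.
    """
    if len(trinucleotide) != 3 or set(trinucleotide) - _VALID:
        raise ValueError(f"invalid trinucleotide {trinucleotide!r}")
    return trinucleotide[0] == "C" and trinucleotide[2] in "CT"


def positional_frequency_matrix(sequences: list[str]) -> pd.DataFrame:
    """Per-position nucleotide frequencies of equal-length, strand-oriented
    windows (e.g. -40..+30 around TSS peaks); columns sum to 1.

    The output is LOGO-ready: positions x {A, C, G, T}.
    """
    if not sequences:
        raise ValueError("no sequences")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("windows must be equal length")
    arr = np.frombuffer("".join(s.upper() for s in sequences).encode(), dtype="S1")
    arr = arr.reshape(len(sequences), length)
    out = {}
    for base in "ACGT":
        out[base] = (arr == base.encode()).mean(axis=0)
    mat = pd.DataFrame(out)
    # renormalize columns over ACGT in case of ambiguity codes
    totals = mat.sum(axis=1)
    mat = mat.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    mat.index.name = "position"
    return mat


def tss_windows(clusters, genome, upstream: int = 40, downstream: int = 30) -> list[str]:
    """Strand-oriented sequence windows around cluster peaks.

    The window covers ``upstream`` bases before the peak and
    ``downstream`` bases after it, peak included (length upstream +
    downstream + 1); minus-strand windows are reverse-complemented so +1
    is always the transcribed start.
    """
    seqs = []
    for cl in clusters:
        if cl.strand == "+":
            start, end = cl.peak - upstream, cl.peak + downstream + 1
        else:
            start, end = cl.peak - downstream, cl.peak + upstream + 1
        try:
            s = fetch(genome, cl.chrom, start, end)
        except IndexError:
            continue
        seqs.append(s if cl.strand == "+" else revcomp(s))
    return seqs
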