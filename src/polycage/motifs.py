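"""TF-binding-site scanning and enrichment around promoters and enhancers.

Position frequency matrices (JASPAR text format) are converted to log-odds
PWMs, scanned over promoter windows (-1000..+100 around cluster peaks, both
strands), and motif presence is tested for foreground-vs-background
enrichment with a one-sided Fisher exact test and BH FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seq import revcomp

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class Pfm:
    motif_id: str
    name: str
    counts: np.ndarray  # 4 x L, rows A, C, G, T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: PFM must have 4 rows")
        if self.counts.shape[1] < 1:
            raise ValueError(f"{self.motif_id}: empty motif")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.motif_id}: empty PFM column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class MotifOccurrence:
    promoter_id: str
    motif_id: str
    present: bool
    best_relative_score: float
    strand: str | None = None
    offset: int | None = None
    flagged: bool = False  # window shorter than the motif


def read_jaspar_pfm(path) -> list[Pfm]:
    """Parse a JASPAR text file (">ID NAME" plus four labelled count rows).

    Row labels are honored regardless of their order in the file; a
    missing or length-mismatched row raises a parse error naming the
    motif.
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
            records = list(parsed)
        except Exception as exc:
            raise ValueError(f"failed to parse JASPAR file {path}: {exc}") from exc
    pfms = []
    for m in records:
        motif_id = m.matrix_id or m.name
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        lengths = {len(m.counts[b]) for b in _BASES}
        if len(lengths) != 1:
            raise ValueError(f"motif {motif_id}: unequal row lengths")
        if counts.shape[1] < 4:
            raise ValueError(f"motif {motif_id}: shorter than 4 columns")
        pfms.append(Pfm(motif_id=motif_id, name=m.name or motif_id, counts=counts))
    return pfms


def pfm_to_pwm(
    pfm: Pfm,
    pseudocount: float = 0.8,
    background: dict | None = None,
) -> np.ndarray:
    """Log-odds PWM: log2((count + pc*bg) / (colsum + pc) / bg).

    Uniform background by default; a column matching the background gives
    all-zero log-odds.
    """
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.array([background[b] for b in _BASES], dtype=float)
    if (bg <= 0).any():
        raise ValueError("background frequencies must be positive")
    colsum = pfm.counts.sum(axis=0)
    prob = (pfm.counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    return np.log2(prob / bg[:, None])


def _encode(seq: str) -> np.ndarray:
    """Sequence as row indices into the PWM; non-ACGT becomes -1."""
    idx = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype="S1") == b.encode()] = i
    return idx


def _best_score(seq: str, pwm: np.ndarray) -> tuple[float, int] | None:
    L = pwm.shape[1]
    if len(seq) < L:
        return None
    idx = _encode(seq.upper())
    n = len(seq) - L + 1
    offsets = np.arange(L)
    windows = idx[np.arange(n)[:, None] + offsets]
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return None
    scores = np.full(n, -np.inf)
    w = windows[valid]
    scores[valid] = pwm[w, offsets].sum(axis=1)
    best = int(np.argmax(scores))
    return float(scores[best]), best


def scan_window(
    sequence: str,
    pwm: np.ndarray,
    motif_id: str = "",
    promoter_id: str = "",
    rel_threshold: float = 0.85,
) -> MotifOccurrence:
    """Best-match scan of one window on both strands.

    The raw best score is rescaled to (score - min) / (max - min) where
    min/max are the PWM's worst and best attainable scores, so a window
    containing the consensus scores exactly 1.  Presence requires the
    relative score to reach ``rel_threshold``.  A window shorter than the
    motif is reported absent and flagged.
    """
    lo = float(pwm.min(axis=0).sum())
    hi = float(pwm.max(axis=0).sum())
    span = hi - lo
    best: tuple[float, int, str] | None = None
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        res = _best_score(seq, pwm)
        if res is None:
            continue
        score, offset = res
        if best is None or score > best[0]:
            best = (score, offset, strand)
    if best is None:
        return MotifOccurrence(promoter_id, motif_id, False, float("nan"), flagged=True)
    score, offset, strand = best
    rel = (score - lo) / span if span > 0 else 1.0
    return MotifOccurrence(
        promoter_id, motif_id, rel >= rel_threshold, rel, strand=strand, offset=offset
    )


def occurrence_matrix(
    windows: dict,
    pfms: list[Pfm],
    rel_threshold: float = 0.85,
    pseudocount: float = 0.8,
) -> pd.DataFrame:
    """Promoters x motifs boolean presence matrix.

    ``windows`` maps promoter_id -> sequence.  Scanning is deterministic
    and independent of promoter order.
    """
    pwms = {p.motif_id: pfm_to_pwm(p, pseudocount=pseudocount) for p in pfms}
    data = {}
    for motif_id, pwm in pwms.items():
        data[motif_id] = {
            pid: scan_window(seq, pwm, motif_id, pid, rel_threshold).present
            for pid, seq in windows.items()
        }
    mat = pd.DataFrame(data).reindex(sorted(windows)).sort_index(axis=1)
    mat.index.name = "promoter_id"
    return mat


def enrichment_fisher(
    foreground: pd.DataFrame,
    background: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test per motif.

    ``foreground`` and ``background`` are presence matrices over disjoint
    promoter sets with identical motif columns.  The odds ratio uses the
    Haldane 0.5 correction when any cell is zero; FDR is BH across
    motifs.
    """
    if foreground.shape[0] == 0:
        raise ValueError("empty foreground set")
    if list(foreground.columns) != list(background.columns):
        raise ValueError("foreground/background motif columns differ")
    overlap = set(foreground.index) & set(background.index)
    if overlap:
        raise ValueError(f"background must exclude foreground ({len(overlap)} shared)")
    rows = []
    for motif in foreground.columns:
        a = int(foreground[motif].sum())
        b = int(foreground.shape[0] - a)
        c = int(background[motif].sum())
        d = int(background.shape[0] - c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append(
            {"motif_id": motif, "a": a, "b": b, "c": c, "d": d, "odds_ratio": odds, "p_value": p}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["enriched"] = out["fdr"] < alpha
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def occurrence_pca(percent_matrix: pd.DataFrame):
    """PCA of a group x motif occurrence-percentage matrix (>=3 groups)."""
    from .diffexp import sample_pca

    if percent_matrix.shape[0] < 3:
        raise ValueError("occurrence PCA needs at least three groups")
    return sample_pca(percent_matrix, log_transform=False)


def promoter_windows(
    clusters,
    genome,
    upstream: int = 1000,
    downstream: int = 100,
) -> dict:
    """Strand-aware promoter windows (-upstream..+downstream) around peaks.

    Enhancer windows use the midpoint the same way, on the plus strand.
    Windows truncated by chromosome ends keep whatever sequence exists.
    """
    out = {}
    for cl in clusters:
        anchor = getattr(cl, "peak", None)
        if anchor is None:
            anchor = cl.midpoint
        strand = getattr(cl, "strand", "+")
        name = getattr(cl, "cluster_id", None) or getattr(cl, "enhancer_id")
        length = len(genome[cl.chrom])
        if strand == "+":
            start, end = max(0, anchor - upstream), min(length, anchor + downstream + 1)
            seq = genome[cl.chrom][start:end]
            seq = seq if isinstance(seq, str) else seq.seq
        else:
            start, end = max(0, anchor - downstream), min(length, anchor + upstream + 1)
            seq = genome[cl.chrom][start:end]
            seq = seq if isinstance(seq, str) else seq.seq
            seq = revcomp(seq)
        out[name] = seq.upper()
    return out
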