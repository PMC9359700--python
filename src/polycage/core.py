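"""Data model and I/O for strand-specific CTSS count tracks.

A CTSS (CAGE-derived transcription start site) is a single genomic base
carrying the number of capped 5' ends observed there, per sample and per
strand.  Tracks are stored sparsely as a DataFrame with one row per
non-zero base.  All internal coordinates are 0-based half-open, matching
BED; GTF input is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("WT", "TCL1")
FRACTIONS = ("Total", "Free", "Light", "Heavy", "Polysomes")

_TRACK_COLUMNS = ["chrom", "pos", "strand", "count"]


class CtssParseError(ValueError):
    """Raised when a CTSS BED file violates the one-record-per-base dialect."""


@dataclass
class CtssTrack:
    """Per-sample, per-strand sparse map of position -> raw tag count."""

    sample_id: str
    condition: str
    replicate: int
    fraction: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}")
        d = self.data
        missing = [c for c in _TRACK_COLUMNS if c not in d.columns]
        if missing:
            raise ValueError(f"track data missing columns {missing}")
        if (d["count"] < 0).any():
            raise ValueError("negative CTSS counts")
        bad = set(d["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"invalid strand value(s) {bad}")

    @property
    def library_size(self) -> float:
        return float(self.data["count"].sum())

    def sorted(self) -> "CtssTrack":
        d = (
            self.data.sort_values(["chrom", "strand", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        return replace(self, data=d)


@dataclass
class TpmTrack:
    """Same shape as :class:`CtssTrack`, values in tags-per-million."""

    sample_id: str
    condition: str
    replicate: int
    fraction: str
    data: pd.DataFrame = field(repr=False)  # columns chrom, pos, strand, tpm


def read_ctss_bed(
    path,
    sample_id: str,
    condition: str,
    replicate: int,
    fraction: str,
) -> CtssTrack:
    """Read a BED6 CTSS file: one record per base, score = raw tag count.

    Records at the same (chrom, strand, position) are summed.  A record
    whose interval is not exactly one base, whose strand is not +/-, or
    whose score is negative or non-integer raises :class:`CtssParseError`
    naming the offending line.
    """
    chroms, poss, strands, counts = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise CtssParseError(f"{path}:{lineno}: expected 6 BED fields")
            chrom, start, end, _name, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
                score_i = int(score)
            except ValueError as exc:
                raise CtssParseError(f"{path}:{lineno}: non-integer field") from exc
            if end_i - start_i != 1:
                raise CtssParseError(
                    f"{path}:{lineno}: CTSS records must span exactly one base"
                )
            if strand not in ("+", "-"):
                raise CtssParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            if score_i < 0:
                raise CtssParseError(f"{path}:{lineno}: negative score")
            chroms.append(chrom)
            poss.append(start_i)
            strands.append(strand)
            counts.append(score_i)
    data = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "strand": strands, "count": counts}
    )
    data = (
        data.groupby(["chrom", "pos", "strand"], as_index=False)["count"]
        .sum()
        .loc[:, _TRACK_COLUMNS]
    )
    return CtssTrack(sample_id, condition, replicate, fraction, data).sorted()


def write_ctss_bed(track: CtssTrack, path) -> None:
    """Write a track in the canonical BED6 CTSS dialect (lossless round-trip)."""
    d = track.sorted().data
    with open(path, "w") as fh:
        for chrom, pos, strand, count in d.itertuples(index=False):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t{int(count)}\t{strand}\n")


def write_bedgraph(track, outdir, prefix: str | None = None) -> list:
    """Export one bedGraph per strand for genome-browser inspection."""
    import os

    prefix = prefix or track.sample_id
    value_col = "tpm" if "tpm" in track.data.columns else "count"
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        sub = track.data[track.data["strand"] == strand]
        sub = sub.sort_values(["chrom", "pos"], kind="mergesort")
        path = os.path.join(outdir, f"{prefix}.{tag}.bedgraph")
        with open(path, "w") as fh:
            for chrom, pos, val in sub[["chrom", "pos", value_col]].itertuples(
                index=False
            ):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{val:g}\n")
        paths.append(path)
    return paths


def tpm_normalize(track: CtssTrack | TpmTrack) -> TpmTrack:
    """Scale counts to tags-per-million of the track's own library size.

    Normalizing an already-normalized track is a no-op (idempotence up to
    scale): TPM values sum to 1e6, so rescaling reproduces them.
    """
    value_col = "tpm" if isinstance(track, TpmTrack) else "count"
    total = float(track.data[value_col].sum())
    if total <= 0:
        raise ValueError(f"empty track {track.sample_id}: cannot TPM-normalize")
    d = track.data[["chrom", "pos", "strand"]].copy()
    d["tpm"] = track.data[value_col].astype(float) * 1e6 / total
    return TpmTrack(track.sample_id, track.condition, track.replicate, track.fraction, d)


def merge_fractions(light: CtssTrack, heavy: CtssTrack) -> CtssTrack:
    """Position-wise sum of the Light and Heavy polysome fractions.

    The result carries the derived fraction label "Polysomes", representing
    all translated transcripts; it is never read from disk, which keeps a
    sample sheet from double-counting tags.
    """
    if (light.condition, light.replicate) != (heavy.condition, heavy.replicate):
        raise ValueError(
            "cannot merge fractions across samples: "
            f"{light.sample_id} vs {heavy.sample_id}"
        )
    if {light.fraction, heavy.fraction} != {"Light", "Heavy"}:
        raise ValueError("merge_fractions expects one Light and one Heavy track")
    merged = (
        pd.concat([light.data, heavy.data], ignore_index=True)
        .groupby(["chrom", "pos", "strand"], as_index=False)["count"]
        .sum()
        .loc[:, _TRACK_COLUMNS]
    )
    sample_id = f"{light.condition}_rep{light.replicate}_Polysomes"
    return CtssTrack(
        sample_id, light.condition, light.replicate, "Polysomes", merged
    ).sorted()


def pool_tracks(tracks: list) -> pd.DataFrame:
    """Sum several tracks position-wise; returns chrom/pos/strand/value."""
    if not tracks:
        raise ValueError("no tracks to pool")
    frames = []
    for t in tracks:
        col = "tpm" if "tpm" in t.data.columns else "count"
        d = t.data[["chrom", "pos", "strand"]].copy()
        d["value"] = t.data[col].astype(float)
        frames.append(d)
    pooled = (
        pd.concat(frames, ignore_index=True)
        .groupby(["chrom", "pos", "strand"], as_index=False)["value"]
        .sum()
        .sort_values(["chrom", "strand", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return pooled


def replicate_correlation(expression: pd.DataFrame, log: bool = True) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples on a cluster x sample table.

    Values are log2(x+1)-transformed by default.  A zero-variance sample
    yields NaN in its row/column (flagged with a warning) rather than a
    silent 0.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = np.log2(expression.to_numpy(dtype=float) + 1.0) if log else (
        expression.to_numpy(dtype=float)
    )
    sd = mat.std(axis=0)
    if (sd == 0).any():
        bad = list(expression.columns[sd == 0])
        logger.warning("zero-variance sample(s) %s: correlation undefined", bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat, rowvar=False)
    return pd.DataFrame(corr, index=expression.columns, columns=expression.columns)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV sample sheet: sample_id, condition, replicate, fraction, path."""
    sheet = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "condition", "replicate", "fraction", "path"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    key = sheet[["condition", "replicate", "fraction"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValueError("duplicate (condition, replicate, fraction) in sample sheet")
    return sheet


def load_tracks(sheet: pd.DataFrame, base_dir=None) -> list:
    """Load every track referenced by a sample sheet."""
    import os

    tracks = []
    for row in sheet.itertuples(index=False):
        path = row.path
        if base_dir is not None and not os.path.isabs(path):
            path = os.path.join(base_dir, path)
        tracks.append(
            read_ctss_bed(
                path, row.sample_id, row.condition, int(row.replicate), row.fraction
            )
        )
    return tracks
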