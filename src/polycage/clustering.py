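"""Unidirectional tag clustering of pooled CTSS signal.

Closely spaced CTSSs on one strand are grouped into tag clusters (TCs) by
the slice-reduce rule: positions whose pooled TPM clears a slice threshold
are kept, and kept positions within a merge distance of each other on the
same strand are reduced into one cluster.  Each cluster gets a peak (the
modal CTSS), a 10-90% interquartile width, a sharp/broad shape class, and
per-sample aggregated counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TagCluster:
    """A promoter-level unit: contiguous block of CTSSs on one strand."""

    cluster_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span of kept CTSSs
    end: int
    peak: int
    pooled_tpm: float
    iqr_start: int
    iqr_end: int
    width_iqr: int
    shape: str  # sharp | broad | wide
    counts: dict = field(default_factory=dict)  # sample_id -> raw count
    tpm: dict = field(default_factory=dict)  # sample_id -> TPM

    def __post_init__(self) -> None:
        if not (self.start <= self.iqr_start <= self.peak <= self.iqr_end < self.end):
            raise ValueError(
                f"{self.cluster_id}: peak/IQR outside cluster span "
                f"({self.start}, {self.iqr_start}, {self.peak}, {self.iqr_end}, {self.end})"
            )
        if self.width_iqr != self.iqr_end - self.iqr_start + 1:
            raise ValueError(f"{self.cluster_id}: inconsistent IQR width")


def compute_iqr_width(
    positions: np.ndarray,
    values: np.ndarray,
    lower: float = 0.10,
    upper: float = 0.90,
) -> tuple[int, int, int]:
    """Span holding the central 10-90% of a cluster's pooled signal.

    ``iqr_start`` is the smallest position whose cumulative pooled fraction
    reaches ``lower``; ``iqr_end`` the smallest reaching ``upper``.  Width is
    ``iqr_end - iqr_start + 1`` so a single-CTSS cluster has width 1.
    """
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError("zero-signal cluster has no IQR width")
    order = np.argsort(positions, kind="mergesort")
    positions, values = positions[order], values[order]
    cum = np.cumsum(values) / total
    # guard against float round-off at the top of the cumulative curve
    cum[-1] = 1.0
    i_lo = int(np.searchsorted(cum, lower, side="left"))
    i_hi = int(np.searchsorted(cum, upper, side="left"))
    iqr_start, iqr_end = int(positions[i_lo]), int(positions[i_hi])
    return iqr_start, iqr_end, iqr_end - iqr_start + 1


def classify_shape(width_iqr: int) -> str:
    """Sharp promoters are 1-10 bases wide, broad 11-100; wider clusters
    are labelled "wide" and excluded from shape-stratified analyses."""
    if width_iqr < 1:
        raise ValueError("IQR width must be >= 1")
    if width_iqr <= 10:
        return "sharp"
    if width_iqr <= 100:
        return "broad"
    return "wide"


def slice_reduce_cluster(
    pooled: pd.DataFrame,
    tracks: list | None = None,
    slice_threshold: float = 0.1,
    merge_dist: int = 20,
    prefix: str = "TC",
) -> list[TagCluster]:
    """Slice-reduce clustering of a pooled TPM track.

    Parameters
    ----------
    pooled
        chrom/pos/strand/value table of summed per-sample TPM.
    tracks
        Optional raw-count :class:`~polycage.core.CtssTrack` list; when
        given, each cluster aggregates per-sample raw counts and TPM over
        its span.
    slice_threshold
        Minimum pooled TPM for a CTSS to be kept ("slice").
    merge_dist
        Kept CTSSs at most this many bases apart on the same strand join
        one cluster ("reduce"); opposite strands never merge.
    """
    if merge_dist < 0:
        raise ValueError("merge_dist must be non-negative")
    kept = pooled[pooled["value"] >= slice_threshold]
    clusters: list[TagCluster] = []
    idx = 0
    for (chrom, strand), grp in kept.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy()
        val = grp["value"].to_numpy(dtype=float)
        order = np.argsort(pos, kind="mergesort")
        pos, val = pos[order], val[order]
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > merge_dist) + 1
        for seg_pos, seg_val in zip(np.split(pos, breaks), np.split(val, breaks)):
            peak = int(seg_pos[np.argmax(seg_val)])  # leftmost maximal CTSS
            iqr_start, iqr_end, width = compute_iqr_width(seg_pos, seg_val)
            clusters.append(
                TagCluster(
                    cluster_id=f"{prefix}{idx:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=int(seg_pos[0]),
                    end=int(seg_pos[-1]) + 1,
                    peak=peak,
                    pooled_tpm=float(seg_val.sum()),
                    iqr_start=iqr_start,
                    iqr_end=iqr_end,
                    width_iqr=width,
                    shape=classify_shape(width),
                )
            )
            idx += 1
    if tracks is not None:
        aggregate_cluster_counts(clusters, tracks)
    return clusters


def aggregate_cluster_counts(clusters: list[TagCluster], tracks: list) -> None:
    """Fill per-sample raw counts and TPM for each cluster span (in place)."""
    for track in tracks:
        lib = track.library_size
        d = track.data
        by_key = {k: g for k, g in d.groupby(["chrom", "strand"], sort=False)}
        for cl in clusters:
            g = by_key.get((cl.chrom, cl.strand))
            if g is None:
                total = 0
            else:
                sel = (g["pos"] >= cl.start) & (g["pos"] < cl.end)
                total = int(g.loc[sel, "count"].sum())
            cl.counts[track.sample_id] = total
            cl.tpm[track.sample_id] = total * 1e6 / lib if lib > 0 else float("nan")


def filter_low_expression(
    clusters: list[TagCluster],
    sample_conditions: dict,
    min_tpm: float = 1.0,
    fraction_samples: set | None = None,
) -> list[TagCluster]:
    """Drop very lowly expressed clusters.

    A cluster is retained iff there is at least one condition in which
    every replicate reaches ``min_tpm`` — this keeps condition-specific
    promoters that are silent in the other group.

    ``sample_conditions`` maps sample_id -> condition; only samples present
    in that mapping (typically the Total-RNA libraries) are considered.
    """
    by_condition: dict = {}
    for sid, cond in sample_conditions.items():
        if fraction_samples is not None and sid not in fraction_samples:
            continue
        by_condition.setdefault(cond, []).append(sid)
    if not by_condition:
        raise ValueError("no samples to filter on")
    kept = []
    for cl in clusters:
        for cond, sids in by_condition.items():
            if all(cl.tpm.get(s, 0.0) >= min_tpm for s in sids):
                kept.append(cl)
                break
    return kept


def clusters_to_frame(clusters: list[TagCluster]) -> pd.DataFrame:
    """Flat table of cluster attributes (one row per cluster)."""
    rows = []
    for cl in clusters:
        row = {
            "cluster_id": cl.cluster_id,
            "chrom": cl.chrom,
            "strand": cl.strand,
            "start": cl.start,
            "end": cl.end,
            "peak": cl.peak,
            "pooled_tpm": cl.pooled_tpm,
            "iqr_start": cl.iqr_start,
            "iqr_end": cl.iqr_end,
            "width_iqr": cl.width_iqr,
            "shape": cl.shape,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def count_matrix(clusters: list[TagCluster], value: str = "counts") -> pd.DataFrame:
    """Clusters x samples matrix of raw counts or TPM."""
    if value not in ("counts", "tpm"):
        raise ValueError("value must be 'counts' or 'tpm'")
    rows = {cl.cluster_id: getattr(cl, value) for cl in clusters}
    mat = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    mat.index.name = "cluster_id"
    return mat.sort_index(axis=1)
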