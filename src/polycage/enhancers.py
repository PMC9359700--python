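"""Bidirectional (enhancer RNA) candidate calling and TSS linking.

Active enhancers transcribe short capped RNAs divergently from both
strands at balanced levels.  Candidates are windows with minus-strand
signal upstream and plus-strand signal downstream of a signal-weighted
midpoint; balance is scored with the Bhattacharyya coefficient and
candidates at or above a 0.95 threshold are called.  Called enhancers are
linked to TSS clusters within 50 kbp whose expression is positively
correlated across samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnhancerCall:
    enhancer_id: str
    chrom: str
    midpoint: int
    start: int
    end: int
    minus_arm_tpm: float  # upstream arm, minus strand
    plus_arm_tpm: float  # downstream arm, plus strand
    balance: float
    called: bool
    counts: dict = field(default_factory=dict)  # sample -> raw count, arms summed
    tpm: dict = field(default_factory=dict)


@dataclass
class EnhancerLink:
    enhancer_id: str
    cluster_id: str
    distance: int
    pearson_r: float
    p_value: float


def balance_score(minus_arm: float, plus_arm: float) -> float:
    """Bhattacharyya coefficient between the observed arm split and a
    perfectly balanced one.

    With d = D/(D+U) and u = U/(D+U), the score is sqrt(0.5*d) +
    sqrt(0.5*u): exactly 1 iff both arms carry half the signal, and
    sqrt(0.5) ~ 0.707 at the fully one-sided limit.
    """
    total = minus_arm + plus_arm
    if total <= 0:
        raise ValueError("balance_score undefined for zero total signal")
    d = minus_arm / total
    u = plus_arm / total
    return math.sqrt(0.5 * d) + math.sqrt(0.5 * u)


def detect_bidirectional_candidates(
    pooled: pd.DataFrame,
    window: int = 400,
    tracks: list | None = None,
    balance_threshold: float = 0.95,
    prefix: str = "ENH",
) -> list[EnhancerCall]:
    """Find divergently transcribed candidate windows in pooled signal.

    All CTSSs (both strands) within ``window`` of each other form a locus;
    each locus is reduced to a window of ``window`` bp centred on its
    signal-weighted midpoint m.  The minus arm is minus-strand signal in
    [m - window/2, m), the plus arm plus-strand signal in [m, m + window/2).
    A candidate requires both arms > 0, which excludes unidirectional
    promoters and convergent configurations.  Candidates with balance >=
    ``balance_threshold`` are flagged as called enhancers.
    """
    half = window // 2
    calls: list[EnhancerCall] = []
    idx = 0
    for chrom, grp in pooled.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        val = grp["value"].to_numpy(dtype=float)
        strand = grp["strand"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > window) + 1
        for sl in np.split(np.arange(len(pos)), breaks):
            p, v, s = pos[sl], val[sl], strand[sl]
            mid = int(round(np.average(p, weights=v)))
            lo, hi = mid - half, mid + half
            minus_sel = (s == "-") & (p >= lo) & (p < mid)
            plus_sel = (s == "+") & (p >= mid) & (p < hi)
            minus_arm = float(v[minus_sel].sum())
            plus_arm = float(v[plus_sel].sum())
            if minus_arm <= 0 or plus_arm <= 0:
                continue
            bal = balance_score(minus_arm, plus_arm)
            calls.append(
                EnhancerCall(
                    enhancer_id=f"{prefix}{idx:04d}",
                    chrom=chrom,
                    midpoint=mid,
                    start=lo,
                    end=hi,
                    minus_arm_tpm=minus_arm,
                    plus_arm_tpm=plus_arm,
                    balance=bal,
                    called=bal >= balance_threshold,
                )
            )
            idx += 1
    if tracks is not None:
        _aggregate_enhancer_counts(calls, tracks)
    return calls


def _aggregate_enhancer_counts(calls: list[EnhancerCall], tracks: list) -> None:
    """Per-sample expression of each candidate: both arms summed."""
    for track in tracks:
        lib = track.library_size
        d = track.data
        for call in calls:
            sel = (
                (d["chrom"] == call.chrom)
                & (
                    ((d["strand"] == "-") & (d["pos"] >= call.start) & (d["pos"] < call.midpoint))
                    | ((d["strand"] == "+") & (d["pos"] >= call.midpoint) & (d["pos"] < call.end))
                )
            )
            total = int(d.loc[sel, "count"].sum())
            call.counts[track.sample_id] = total
            call.tpm[track.sample_id] = total * 1e6 / lib if lib > 0 else float("nan")


def link_enhancers_to_tss(
    enhancers: list[EnhancerCall],
    clusters: list,
    sample_ids: list[str],
    max_dist: int = 50_000,
    alpha: float = 0.05,
    require_called: bool = True,
) -> list[EnhancerLink]:
    """Predict enhancer-TSS interactions by distance and correlation.

    A link requires midpoint-to-peak distance <= ``max_dist``, Pearson
    r > 0 on log2(TPM+1) across the given samples, and a two-sided
    correlation p-value below ``alpha``.  At least three shared samples
    are needed for the p-value to be defined.
    """
    if len(sample_ids) < 3:
        raise ValueError("correlation p-value undefined with fewer than 3 samples")
    links: list[EnhancerLink] = []
    for enh in enhancers:
        if require_called and not enh.called:
            continue
        e_expr = np.log2(np.array([enh.tpm.get(s, 0.0) for s in sample_ids]) + 1.0)
        for cl in clusters:
            if cl.chrom != enh.chrom:
                continue
            distance = abs(cl.peak - enh.midpoint)
            if distance > max_dist:
                continue
            c_expr = np.log2(
                np.array([cl.tpm.get(s, 0.0) for s in sample_ids]) + 1.0
            )
            if e_expr.std() == 0 or c_expr.std() == 0:
                continue
            r, p = stats.pearsonr(e_expr, c_expr)
            if r > 0 and p < alpha:
                links.append(
                    EnhancerLink(enh.enhancer_id, cl.cluster_id, distance, float(r), float(p))
                )
    return links


def classify_intergenic_intronic_ernas(
    category_calls: pd.DataFrame,
    enhancers: list[EnhancerCall],
    clusters: list,
) -> dict:
    """Fraction of intronic and intergenic TSS clusters that are eRNAs.

    A cluster counts as eRNA-derived when its peak falls inside a called
    enhancer window.  ``category_calls`` must hold cluster_id and category
    columns (from the annotation stage).
    """
    windows: dict = {}
    for enh in enhancers:
        if enh.called:
            windows.setdefault(enh.chrom, []).append((enh.start, enh.end))
    peak_of = {cl.cluster_id: (cl.chrom, cl.peak) for cl in clusters}
    out = {}
    for category in ("intron", "intergenic"):
        ids = category_calls.loc[category_calls["category"] == category, "cluster_id"]
        n = len(ids)
        if n == 0:
            out[category] = 0.0
            continue
        hits = 0
        for cid in ids:
            chrom, peak = peak_of[cid]
            for start, end in windows.get(chrom, ()):
                if start <= peak < end:
                    hits += 1
                    break
        out[category] = hits / n
    return out


def enhancers_to_frame(calls: list[EnhancerCall]) -> pd.DataFrame:
    rows = [
        {
            "enhancer_id": e.enhancer_id,
            "chrom": e.chrom,
            "midpoint": e.midpoint,
            "start": e.start,
            "end": e.end,
            "minus_arm_tpm": e.minus_arm_tpm,
            "plus_arm_tpm": e.plus_arm_tpm,
            "balance": e.balance,
            "called": e.called,
        }
        for e in calls
    ]
    return pd.DataFrame(rows)
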