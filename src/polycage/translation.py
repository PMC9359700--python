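"""Per-TSS translation efficiency from polysome-fraction CAGE signal.

Polysome profiling splits a transcript pool into Free (untranslated),
Light (few ribosomes) and Heavy (many ribosomes) fractions.  Translation
efficiency (TE) of a TSS is the ratio of its signal in the translated
fractions (Heavy + Light = "Polysomes") to the Free fraction, computed on
per-fraction TPM so sequencing-depth differences between fractions
cancel.  Canonical/alternative TSS pairs are compared with a twofold rule
(Differential High/Low-TE), and ORF-truncating alternative TSSs are
scored for how much translated signal they carry relative to their
gene's canonical TSS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TeRecord:
    cluster_id: str
    free_tpm: float
    light_tpm: float
    heavy_tpm: float
    te: float

    @property
    def polysome_tpm(self) -> float:
        return self.light_tpm + self.heavy_tpm


@dataclass
class TruncationImpact:
    gene_id: str
    canonical_cluster_id: str
    alt_cluster_id: str
    polysome_ratio: float
    impact: str  # substantial | sparse
    inclusive_log2_fc: float | None = None
    flagged: bool = False


def compute_te(
    free_tpm: dict,
    light_tpm: dict,
    heavy_tpm: dict,
    pseudocount: float = 1.0,
    min_total_tpm: float = 1.0,
) -> list[TeRecord]:
    """TE per cluster: (polysome TPM + eps) / (free TPM + eps).

    Input dicts map cluster_id -> TPM per fraction (replicate-averaged).
    Clusters whose TPM summed over the three fractions falls below
    ``min_total_tpm`` are excluded.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ids = sorted(set(free_tpm) | set(light_tpm) | set(heavy_tpm))
    records = []
    for cid in ids:
        f = float(free_tpm.get(cid, 0.0))
        l = float(light_tpm.get(cid, 0.0))
        h = float(heavy_tpm.get(cid, 0.0))
        if f + l + h < min_total_tpm:
            continue
        te = (l + h + pseudocount) / (f + pseudocount)
        records.append(TeRecord(cid, f, l, h, te))
    return records


def classify_differential_te(te_alt: float, te_canonical: float, fold: float = 2.0) -> str:
    """Twofold rule for paired isoforms: the alternative is diff_high when
    its TE is at least ``fold`` times the canonical's, diff_low when at
    most 1/``fold`` of it, else neutral.  Swapping the pair's roles maps
    diff_high <-> diff_low."""
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if te_alt >= fold * te_canonical:
        return "diff_high"
    if te_alt <= te_canonical / fold:
        return "diff_low"
    return "neutral"


def truncation_impact(
    gene_id: str,
    canonical_cluster_id: str,
    alt_cluster_id: str,
    alt_polysome_tpm: float,
    canonical_polysome_tpm: float,
    threshold: float = 0.5,
) -> TruncationImpact:
    """Substantial vs sparse ORF truncation.

    A truncating alternative TSS whose polysome-fraction signal reaches
    ``threshold`` (50%) of the canonical TSS's is considered to
    substantially displace the full-length protein.  A canonical TSS with
    zero polysome signal yields an infinite ratio, called substantial and
    flagged.
    """
    if canonical_polysome_tpm == 0:
        return TruncationImpact(
            gene_id,
            canonical_cluster_id,
            alt_cluster_id,
            math.inf,
            "substantial",
            flagged=True,
        )
    ratio = alt_polysome_tpm / canonical_polysome_tpm
    impact = "substantial" if ratio >= threshold else "sparse"
    return TruncationImpact(gene_id, canonical_cluster_id, alt_cluster_id, ratio, impact)


def inclusive_log_fc(condition_log2_fc: float, alt_vs_canonical_log2: float) -> float:
    """Combined promoter-shift magnitude.

    Adds the alternative TSS's condition log2 FC to its within-condition
    log2 ratio over the canonical TSS; both addends are reported alongside
    so alternative summaries can be recomputed.
    """
    return condition_log2_fc + alt_vs_canonical_log2


def fraction_occupancy_by_category(
    category_tpm: pd.DataFrame,
) -> pd.DataFrame:
    """Per-category share of signal in each polysome fraction.

    ``category_tpm`` is a categories x fractions (Free/Light/Heavy) table
    of summed TPM; rows are normalized to 1.
    """
    mat = category_tpm.astype(float)
    totals = mat.sum(axis=1)
    shares = mat.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return shares


def ctss_te_table(
    free_tpm: pd.DataFrame,
    light_tpm: pd.DataFrame,
    heavy_tpm: pd.DataFrame,
    pseudocount: float = 1.0,
    min_tpm: float = 1.0,
) -> pd.DataFrame:
    """Per-CTSS TE at single-base resolution.

    Inputs are pooled TPM tables (chrom/pos/strand/value) for each
    fraction.  Only CTSSs with at least ``min_tpm`` pooled TPM in both
    the Free and the combined polysome signal are retained, mirroring the
    per-cluster expression filter at base resolution.
    """
    key = ["chrom", "pos", "strand"]

    def prep(df, name):
        return df.rename(columns={"value": name}).set_index(key)[[name]]

    merged = (
        prep(free_tpm, "free")
        .join(prep(light_tpm, "light"), how="outer")
        .join(prep(heavy_tpm, "heavy"), how="outer")
        .fillna(0.0)
        .reset_index()
    )
    merged["polysome"] = merged["light"] + merged["heavy"]
    merged = merged[(merged["free"] >= min_tpm) & (merged["polysome"] >= min_tpm)]
    merged = merged.reset_index(drop=True)
    merged["te"] = (merged["polysome"] + pseudocount) / (merged["free"] + pseudocount)
    return merged
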