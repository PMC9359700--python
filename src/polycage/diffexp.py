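"""Negative-binomial differential expression and differential TSS usage.

Counts are modelled as NB(mean, dispersion) with per-unit dispersions
estimated by method of moments and shrunk toward the common dispersion.
Condition effects are tested with a Wald statistic on the log fold change
between group means (after median-of-ratios library-size normalization),
with Benjamini-Hochberg FDR control.  Differential TSS usage (DTU)
contrasts each TSS of a multi-TSS gene against the rest of its gene, so
gene-wide expression changes cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors (total-count fallback).

    The reference is the per-unit geometric mean over samples; units with
    a zero anywhere drop out.  When no unit survives, factors fall back to
    relative total counts.
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    usable = np.isfinite(log_mat).all(axis=1)
    if usable.sum() >= 1:
        log_ref = log_mat[usable].mean(axis=1)
        factors = np.exp(np.median(log_mat[usable] - log_ref[:, None], axis=0))
    else:
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    conditions: dict | pd.Series,
    shrink_weight: float = 0.7,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-unit NB dispersions, shrunk toward the common dispersion.

    Within each condition the method-of-moments estimate is
    (var - mean) / mean^2 on normalized counts; per-unit values are the
    replicate-weighted average over conditions, then blended with the
    common (median) dispersion: (1 - w) * unit + w * common.  Estimates
    never drop below ``floor`` (identical replicates give the floor).
    """
    conditions = pd.Series(conditions)
    groups = {c: list(conditions[conditions == c].index) for c in conditions.unique()}
    if any(len(s) < 2 for s in groups.values()):
        raise ValueError("dispersion estimation needs >=2 replicates per condition")
    sf = size_factors(counts)
    norm = counts / sf
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for samples in groups.values():
        sub = norm[samples].to_numpy(dtype=float)
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (var - mu) / mu**2
        d = np.where(np.isfinite(d), d, 0.0)
        num += d * len(samples)
        den += len(samples)
    unit = np.maximum(num / den, floor)
    expressed = counts.sum(axis=1).to_numpy() > 0
    common = float(np.median(unit[expressed])) if expressed.any() else floor
    shrunk = np.maximum((1.0 - shrink_weight) * unit + shrink_weight * common, floor)
    return pd.Series(shrunk, index=counts.index, name="dispersion")


@dataclass
class DeSettings:
    alpha: float = 0.05
    shrink_weight: float = 0.7
    pseudocount: float = 0.5  # added to group means in the log fold change
    prior_df: float = 4.0  # extra df credited to the moderated dispersion


def _group_stats(norm: pd.DataFrame, samples: list, dispersion: np.ndarray):
    sub = norm[samples].to_numpy(dtype=float)
    mu = sub.mean(axis=1)
    n = sub.shape[1]
    var_mean = (mu + dispersion * mu**2) / n
    return mu, var_mean


def _wald(mu_a, var_a, mu_b, var_b, pseudocount: float, df: float):
    """log2 FC (b over a) and two-sided moderated-t p from the delta method.

    With two replicates per group the plain normal reference is
    anti-conservative, so the Wald statistic is referred to a t
    distribution whose df combine the residual df with a prior df
    credited to the dispersion moderation (limma-style).
    """
    mu_a_p = mu_a + pseudocount
    mu_b_p = mu_b + pseudocount
    log2_fc = np.log2(mu_b_p / mu_a_p)
    se2 = var_a / mu_a_p**2 + var_b / mu_b_p**2  # variance of ln ratio
    se_log2 = np.sqrt(se2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2_fc / se_log2
    z = np.where(se_log2 == 0, 0.0, z)
    p = 2.0 * stats.t.sf(np.abs(z), df)
    return log2_fc, p


def de_test(
    counts: pd.DataFrame,
    conditions: dict | pd.Series,
    reference: str = "WT",
    settings: DeSettings | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test per unit (cluster or gene).

    Returns a table with log2_fc (treatment over ``reference``), p_value,
    fdr and an up/down/unchanged status at the FDR cutoff.  All-zero
    units are excluded (logged), mirroring independent filtering.
    """
    settings = settings or DeSettings()
    conditions = pd.Series(conditions)
    levels = [c for c in conditions.unique()]
    if len(levels) != 2 or reference not in levels:
        raise ValueError(f"need exactly two conditions including {reference!r}")
    treatment = next(c for c in levels if c != reference)

    nonzero = counts.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("excluding %d all-zero units from DE", int((~nonzero).sum()))
    counts = counts.loc[nonzero]
    sf = size_factors(counts)
    norm = counts / sf
    disp = estimate_dispersions(
        counts, conditions, shrink_weight=settings.shrink_weight
    ).to_numpy()
    ref_samples = list(conditions[conditions == reference].index)
    trt_samples = list(conditions[conditions == treatment].index)
    mu_r, var_r = _group_stats(norm, ref_samples, disp)
    mu_t, var_t = _group_stats(norm, trt_samples, disp)
    df = len(ref_samples) + len(trt_samples) - 2 + settings.prior_df
    log2_fc, p = _wald(mu_r, var_r, mu_t, var_t, settings.pseudocount, df)
    fdr = multipletests(p, method="fdr_bh")[1]
    status = np.where(
        (fdr < settings.alpha) & (log2_fc > 0),
        "up",
        np.where((fdr < settings.alpha) & (log2_fc < 0), "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "unit_id": counts.index,
            "log2_fc": log2_fc,
            "p_value": p,
            "fdr": fdr,
            "status": status,
        }
    ).set_index("unit_id")


def dtu_test(
    counts: pd.DataFrame,
    cluster_genes: dict | pd.Series,
    conditions: dict | pd.Series,
    reference: str = "WT",
    settings: DeSettings | None = None,
) -> pd.DataFrame:
    """Differential TSS usage within multi-TSS genes.

    For each TSS cluster the condition log2 FC is contrasted with the FC
    of the rest of its gene (the gene's other retained clusters summed),
    which makes the statistic invariant to gene-wide expression shifts.
    The reported ``atss_log2_fc`` is the cluster FC minus the gene-total
    FC, matching the promoter-shift effect size; p-values come from a
    Wald test on the cluster-vs-rest contrast and are BH-adjusted over
    all tested TSSs.  Genes with fewer than two clusters are skipped.
    """
    settings = settings or DeSettings()
    conditions = pd.Series(conditions)
    cluster_genes = pd.Series(cluster_genes)
    levels = list(conditions.unique())
    treatment = next(c for c in levels if c != reference)
    sf = size_factors(counts)
    norm = counts / sf
    ref_samples = list(conditions[conditions == reference].index)
    trt_samples = list(conditions[conditions == treatment].index)
    disp = estimate_dispersions(counts, conditions, shrink_weight=settings.shrink_weight)

    rows = []
    for gene_id, members in cluster_genes.groupby(cluster_genes):
        ids = [cid for cid in members.index if cid in counts.index]
        if len(ids) < 2:
            continue
        gene_norm = norm.loc[ids]
        gene_counts = counts.loc[ids]
        gene_disp = float(disp.loc[ids].mean())
        total = gene_norm.sum(axis=0)
        for cid in ids:
            rest = total - gene_norm.loc[cid]
            own = gene_norm.loc[cid]

            def grp(series, samples):
                vals = series[samples].to_numpy(dtype=float)
                mu = vals.mean()
                var = (mu + gene_disp * mu**2) / len(samples)
                return mu, var

            mu_or, var_or = grp(own, ref_samples)
            mu_ot, var_ot = grp(own, trt_samples)
            mu_rr, var_rr = grp(rest, ref_samples)
            mu_rt, var_rt = grp(rest, trt_samples)
            pc = settings.pseudocount
            own_fc = np.log2((mu_ot + pc) / (mu_or + pc))
            rest_fc = np.log2((mu_rt + pc) / (mu_rr + pc))
            stat = own_fc - rest_fc
            se2 = (
                var_or / (mu_or + pc) ** 2
                + var_ot / (mu_ot + pc) ** 2
                + var_rr / (mu_rr + pc) ** 2
                + var_rt / (mu_rt + pc) ** 2
            )
            se_log2 = np.sqrt(se2) / np.log(2)
            z = 0.0 if se_log2 == 0 else stat / se_log2
            df = len(ref_samples) + len(trt_samples) - 2 + settings.prior_df
            p = 2.0 * stats.t.sf(abs(z), df)
            # effect size relative to the gene total, as reported
            mu_gr = total[ref_samples].mean()
            mu_gt = total[trt_samples].mean()
            gene_fc = np.log2((mu_gt + pc) / (mu_gr + pc))
            rows.append(
                {
                    "gene_id": gene_id,
                    "cluster_id": cid,
                    "atss_log2_fc": own_fc - gene_fc,
                    "shift_stat": stat,
                    "p_value": p,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "cluster_id", "atss_log2_fc", "shift_stat", "p_value", "fdr", "direction"]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["direction"] = np.where(out["atss_log2_fc"] >= 0, "up", "down")
    return out


def sample_pca(matrix: pd.DataFrame, log_transform: bool = True):
    """PCA of a samples x features matrix via SVD of the centered data.

    With ``log_transform`` the matrix is first log2(x+1)-transformed, the
    variance-stabilization used for sample-level QC.  Returns (coordinates
    DataFrame with PC columns, variance-explained fractions).
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    X = matrix.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("constant matrix: PCA undefined")
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = U * S
    var_explained = S**2 / (S**2).sum()
    k = min(X.shape)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords[:, :k], index=matrix.index, columns=cols),
        pd.Series(var_explained[:k], index=cols, name="variance_explained"),
    )
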