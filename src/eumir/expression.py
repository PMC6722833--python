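"""Quantification and differential expression between LR and HR.

Abundance unit is TPM = mapped read count / total reads x 10^6 (the
small-RNA convention; miRNA lengths differ too little for a length
correction to matter).  Differential expression is a negative-binomial
Wald test on median-of-ratios normalized counts with a method-of-
moments dispersion estimate floored at 0.01, Benjamini-Hochberg FDR
across features, and calls at |log2FC| >= 1 and FDR <= 0.05.  HR is
the numerator of every fold change.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from eumir.config import ExpressionConfig


def tpm(mapped_count: float, total_reads: float) -> float:
    """Transcripts per million: mapped_count / total_reads x 10^6."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if not 0 <= mapped_count <= total_reads:
        raise ValueError("need 0 <= mapped_count <= total_reads")
    return mapped_count / total_reads * 1_000_000


def tpm_matrix(counts: pd.DataFrame, totals: dict[str, float]) -> pd.DataFrame:
    """Per-sample TPM for a feature x sample count table."""
    out = counts.astype(float).copy()
    for col in out.columns:
        total = totals[col]
        if total <= 0:
            raise ValueError(f"total reads for {col} must be > 0")
        out[col] = out[col] / total * 1_000_000
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over features positive in all samples.

    Falls back to library-size ratios when no feature is everywhere
    positive (tiny or pathological tables).
    """
    arr = counts.to_numpy(dtype=float)
    ok = np.all(arr > 0, axis=1)
    if ok.sum() == 0:
        libsize = arr.sum(axis=0)
        sf = libsize / np.exp(np.mean(np.log(libsize[libsize > 0])))
        return pd.Series(sf, index=counts.columns)
    logs = np.log(arr[ok])
    geo = np.exp(logs.mean(axis=1))
    sf = np.median(arr[ok] / geo[:, None], axis=0)
    return pd.Series(sf, index=counts.columns)


def differential_expression(counts: pd.DataFrame,
                            conditions: dict[str, str] | Sequence[str],
                            config: Optional[ExpressionConfig] = None,
                            ) -> pd.DataFrame:
    """NB Wald test per feature, HR vs LR.

    ``counts`` is a non-negative integer feature x sample table;
    ``conditions`` maps sample -> "LR"/"HR" (or a sequence in column
    order).  Returns one row per feature with baseMean per condition,
    log2FC, p, FDR and the direction call.
    """
    cfg = config or ExpressionConfig()
    if isinstance(conditions, dict):
        cond = np.array([conditions[c] for c in counts.columns])
    else:
        cond = np.asarray(list(conditions))
    if set(cond) - {"LR", "HR"}:
        raise ValueError("conditions must be LR or HR")
    is_hr = cond == "HR"
    if is_hr.sum() < 2 or (~is_hr).sum() < 2:
        raise ValueError("need >= 2 replicates per condition")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")

    sf = size_factors(counts).to_numpy()
    norm = arr / sf
    xh, xl = norm[:, is_hr], norm[:, ~is_hr]
    nh, nl = is_hr.sum(), (~is_hr).sum()
    mu_h, mu_l = xh.mean(axis=1), xl.mean(axis=1)
    pc = cfg.pseudocount
    lfc = np.log2((mu_h + pc) / (mu_l + pc))

    # method-of-moments dispersion, pooled within conditions
    ss = ((xh - mu_h[:, None]) ** 2).sum(1) + ((xl - mu_l[:, None]) ** 2).sum(1)
    s2 = ss / (nh + nl - 2)
    mu = (mu_h + mu_l) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    alpha = np.where(np.isfinite(alpha), alpha, cfg.dispersion_floor)
    alpha = np.maximum(alpha, cfg.dispersion_floor)

    var_h = (mu_h + alpha * mu_h**2) / nh
    var_l = (mu_l + alpha * mu_l**2) / nl
    se = np.sqrt(var_h / (mu_h + pc) ** 2 + var_l / (mu_l + pc) ** 2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pvals = 2 * stats.norm.sf(np.abs(z))

    allzero = arr.sum(axis=1) == 0
    pvals[allzero] = 1.0
    lfc[allzero] = 0.0
    fdr = multipletests(pvals, method="fdr_bh")[1]

    call = np.full(len(lfc), "ns", dtype=object)
    call[(lfc >= cfg.lfc_threshold) & (fdr <= cfg.fdr_threshold)] = "up"
    call[(lfc <= -cfg.lfc_threshold) & (fdr <= cfg.fdr_threshold)] = "down"
    return pd.DataFrame({
        "feature": counts.index,
        "baseMean_LR": mu_l,
        "baseMean_HR": mu_h,
        "log2FC": lfc,
        "p": pvals,
        "FDR": fdr,
        "call": call,
    }).set_index("feature")


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-score ((x - mean) / sd, sd with n-1); constant rows -> 0."""
    if matrix.shape[1] < 2:
        raise ValueError("each row needs >= 2 samples")
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
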