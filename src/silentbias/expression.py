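"""Expression normalisation, decile stratification, and regressions.

TPM uses the raw transcript length: TPM_i = 1e6 (c_i/L_i) / sum_j (c_j/L_j)
per cell, so it sums to one million. Slopes come from ordinary least
squares; significance from Spearman rank correlation, Benjamini-Hochberg
corrected within the batch each analysis defines. Log-TPM regressions use
base-10 logs and drop zero-TPM transcripts rather than add a pseudocount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_ALPHA = 0.05


@dataclass
class RegressionResult:
    """OLS slope with Spearman significance for one predictor/response pair."""

    slope: float
    intercept: float
    spearman_rho: float
    p_value: float
    q_value: float = math.nan
    n: int = 0

    @property
    def significant(self) -> bool:
        return (not math.isnan(self.q_value)) and self.q_value < SIGNIFICANCE_ALPHA


def tpm(read_counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Transcripts per million from raw counts and raw lengths (one cell)."""
    counts = np.asarray(read_counts, dtype=float)
    lens = np.asarray(lengths, dtype=float)
    if counts.shape != lens.shape:
        raise ValueError("counts and lengths must align")
    if np.any(counts < 0) or np.any(lens <= 0):
        raise ValueError("counts must be >= 0 and lengths > 0")
    rates = counts / lens
    total = rates.sum()
    if total == 0:
        raise ValueError("all-zero read counts: TPM undefined")
    return 1e6 * rates / total


def decile_bins(tpm_values: Sequence[float]) -> np.ndarray:
    """Decile label (0 = lowest .. 9 = highest) per transcript, per cell.

    Ranking uses minimum ranks so tied values share the lower bin. Requires
    at least 10 transcripts with positive TPM.
    """
    x = np.asarray(tpm_values, dtype=float)
    if np.sum(x > 0) < 10:
        raise ValueError("need >= 10 transcripts with TPM > 0 for deciles")
    ranks = stats.rankdata(x, method="min") - 1  # 0-based
    bins = np.minimum((ranks * 10 // len(x)).astype(int), 9)
    return bins


def decile_masks(bins: np.ndarray) -> Dict[str, np.ndarray]:
    return {
        "bottom1": bins == 0,
        "top1": bins == 9,
        "bottom2": bins <= 1,
        "top2": bins >= 8,
        "all": np.ones_like(bins, dtype=bool),
    }


def _regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a regression")
    if np.allclose(x, x[0]):
        return RegressionResult(math.nan, math.nan, math.nan, math.nan, n=n)
    if np.allclose(y, y[0]):
        # Constant response: slope 0 by convention, rank correlation undefined.
        return RegressionResult(0.0, float(y[0]), math.nan, math.nan, n=n)
    fit = stats.linregress(x, y)
    rho, p = stats.spearmanr(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        spearman_rho=float(rho),
        p_value=float(p),
        n=n,
    )


def metric_vs_log_tpm(
    metric: Sequence[float], tpm_values: Sequence[float]
) -> RegressionResult:
    """OLS of a per-transcript metric on log10(TPM), Spearman significance.

    Rows with TPM <= 0 or non-finite metric values are dropped.
    """
    m = np.asarray(metric, dtype=float)
    t = np.asarray(tpm_values, dtype=float)
    keep = np.isfinite(m) & np.isfinite(t) & (t > 0)
    m, t = m[keep], t[keep]
    return _regress(np.log10(t), m)


def neutrality_plot(
    gc12_values: Sequence[float],
    gc4_values: Sequence[float],
    mask: Optional[Sequence[bool]] = None,
) -> RegressionResult:
    """Slope of per-transcript GC12 on GC4 over an expression subset.

    Slope 1 is the pure-substitution-bias expectation; selection and
    functional constraint on amino acids drive it toward 0.
    """
    y = np.asarray(gc12_values, dtype=float)
    x = np.asarray(gc4_values, dtype=float)
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        x, y = x[sel], y[sel]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.allclose(x, x[0] if len(x) else 0.0):
        return RegressionResult(math.nan, math.nan, math.nan, math.nan, n=len(x))
    return _regress(x, y)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN p stays NaN)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, math.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def attach_bh(results: Mapping[str, RegressionResult]) -> Dict[str, RegressionResult]:
    """BH-correct a batch of regressions in place of their q-values."""
    keys = list(results)
    q = bh_adjust([results[k].p_value for k in keys])
    out = {}
    for k, qv in zip(keys, q):
        r = results[k]
        out[k] = RegressionResult(
            r.slope, r.intercept, r.spearman_rho, r.p_value, float(qv), r.n
        )
    return out


def cross_taxon_aa_slopes(
    aa_freq_by_taxon: pd.DataFrame,
    mean_gc4_by_taxon: Mapping[str, float],
) -> Dict[str, RegressionResult]:
    """Per-amino-acid regression of mean usage on mean GC4 across taxa.

    ``aa_freq_by_taxon`` is taxa x amino acids (one row per cell, typically
    restricted to an expression-decile gene set). Requires >= 5 taxa; the
    batch is BH-corrected across amino acids.
    """
    taxa = list(aa_freq_by_taxon.index)
    if len(taxa) < 5:
        raise ValueError("need >= 5 taxa for cross-taxon amino-acid slopes")
    x = np.array([mean_gc4_by_taxon[t] for t in taxa], dtype=float)
    results = {}
    for aa in aa_freq_by_taxon.columns:
        y = aa_freq_by_taxon[aa].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        if keep.sum() < 5:
            results[aa] = RegressionResult(math.nan, math.nan, math.nan, math.nan, n=int(keep.sum()))
            continue
        results[aa] = _regress(x[keep], y[keep])
    return attach_bh(results)
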