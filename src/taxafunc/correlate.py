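"""Host-gene vs microbe Spearman correlation with clustered output order.

The top differentially expressed host genes (smallest FDR, expressed as
TPM) are correlated against differentially abundant microbes (percent
abundance) across the shared samples. Rho uses average ranks for ties and
the p-value the t-distribution approximation. Hierarchical clustering
(average linkage on 1 - Pearson correlation between rows/columns of the
rho grid) yields deterministic row and column leaf orders for heatmap
rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import rankdata, t as t_dist

from .types import ValidationError


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame  # genes x species
    pvalue: pd.DataFrame
    pvalue_bh: pd.DataFrame
    n_samples: int


def select_top_genes(deg_table: pd.DataFrame, n: int = 100) -> pd.Index:
    """The n genes with the smallest FDR (ties broken by p, then id)."""
    ranked = deg_table.sort_values(
        ["fdr", "pvalue"], kind="mergesort"
    )
    return ranked.index[:n]


def select_da_microbes(
    da_table: pd.DataFrame,
    percent: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    min_percent: float = 0.01,
) -> pd.Index:
    """Microbes passing the DA FDR cutoff and, at the correlation stage,
    a stricter abundance floor (percent >= ``min_percent`` somewhere)."""
    sig = da_table.index[da_table["fdr"] < fdr_cutoff]
    abundant = percent.index[(percent >= min_percent).any(axis=1)]
    return sig.intersection(abundant)


def spearman_matrix(
    gene_tpm: pd.DataFrame,
    microbe_pct: pd.DataFrame,
) -> CorrelationMatrix:
    """Average-rank Spearman rho and t-approximation p for every
    gene x microbe pair over the shared samples.

    Constant vectors leave rho undefined (NaN), reported as missing.
    """
    shared = [s for s in gene_tpm.columns if s in microbe_pct.columns]
    if len(shared) < 4:
        raise ValidationError(
            f"need >=4 shared samples for correlation, found {len(shared)}"
        )
    g = gene_tpm[shared].to_numpy(dtype=float)
    m = microbe_pct[shared].to_numpy(dtype=float)
    n = len(shared)

    g_ranks = np.apply_along_axis(rankdata, 1, g)
    m_ranks = np.apply_along_axis(rankdata, 1, m)

    def standardize(x: np.ndarray) -> np.ndarray:
        centered = x - x.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = centered / sd
        out[~np.isfinite(out)] = np.nan
        return out

    gz = standardize(g_ranks)
    mz = standardize(m_ranks)
    rho = gz @ mz.T / n
    rho = np.clip(rho, -1.0, 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    pval = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    pval[np.abs(rho) >= 1.0] = 0.0
    pval[np.isnan(rho)] = np.nan

    rho_df = pd.DataFrame(rho, index=gene_tpm.index, columns=microbe_pct.index)
    p_df = pd.DataFrame(pval, index=gene_tpm.index, columns=microbe_pct.index)

    flat = p_df.to_numpy().ravel()
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        from .diff_stats import bh_adjust

        adj[ok] = bh_adjust(flat[ok])
    p_bh = pd.DataFrame(
        adj.reshape(p_df.shape), index=p_df.index, columns=p_df.columns
    )
    return CorrelationMatrix(rho=rho_df, pvalue=p_df, pvalue_bh=p_bh, n_samples=n)


def _corr_distance(block: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson correlation distance between rows."""
    centered = block - block.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = centered / sd
    corr = np.clip(z @ z.T / block.shape[1], -1.0, 1.0)
    dist = 1.0 - corr
    iu = np.triu_indices_from(dist, k=1)
    return np.maximum(dist[iu], 0.0)


def cluster_order(
    matrix: CorrelationMatrix, method: str = "average"
) -> tuple[list, list]:
    """Deterministic row (gene) and column (species) leaf orders from
    agglomerative clustering of the rho grid.

    Missing rho cells (constant inputs) are imputed as 0 for distance
    purposes only, with a warning; ties are broken by sorting features by
    id before clustering.
    """
    rho = matrix.rho.sort_index().sort_index(axis=1)
    if rho.shape[0] < 2 or rho.shape[1] < 2:
        raise ValidationError("clustering needs >=2 rows and >=2 columns")
    values = rho.to_numpy(dtype=float)
    if np.isnan(values).any():
        warnings.warn(
            "missing rho cells imputed as 0 for clustering distances",
            stacklevel=2,
        )
        values = np.nan_to_num(values, nan=0.0)
    row_link = linkage(_corr_distance(values), method=method)
    col_link = linkage(_corr_distance(values.T), method=method)
    row_order = [rho.index[i] for i in leaves_list(row_link)]
    col_order = [rho.columns[i] for i in leaves_list(col_link)]
    return row_order, col_order
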