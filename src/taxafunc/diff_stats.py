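"""Count-based differential statistics shared by microbes and host genes.

The model: feature counts in sample j of group g are negative binomial
with mean mu_g * N_j (N_j the effective library size) and a common
dispersion phi shared across features (variance mu + phi*mu^2; phi = 0
recovers Poisson). Samples are first brought to a common effective library
size, then a two-sided exact test conditions on each feature's total count
and sums the probabilities of all splits as or less likely than the one
observed. With phi = 0 and equal group sizes the conditional distribution
is exactly binomial, which is what the test-suite oracle enumerates.

Also here: the expression filter applied before testing, TMM normalization
factors, Benjamini-Hochberg adjustment, TPM conversion, and preranked GSEA
with a gene-label permutation null.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .types import GeneCountTable, GeneSetCollection, ValidationError

DEFAULT_FDR = 0.05


# ---------------------------------------------------------------------------
# expression filter


def filter_features(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    min_count: float = 1,
) -> pd.Index:
    """Features with count >= ``min_count`` in at least n samples, where n
    is the smallest group size.

    A simplified raw-count version of the usual CPM-based expression
    filter; ``min_count`` defaults to 1.
    """
    if counts.shape[1] < 2:
        raise ValidationError("need >=2 samples to filter by expression")
    sizes = pd.Series(groups).value_counts()
    n = int(sizes.min())
    keep = (counts >= min_count).sum(axis=1) >= n
    retained = counts.index[keep]
    if len(retained) == 0:
        raise ValidationError(
            "all features removed by the expression filter; lower min_count"
        )
    return retained


# ---------------------------------------------------------------------------
# TMM normalization


def _quantile_factor(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.array(
        [np.quantile(counts[:, j], p) / lib[j] for j in range(counts.shape[1])]
    )


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the one whose upper-quartile/library ratio is
    closest to the mean of those ratios. For each sample, gene-wise log2
    ratios (M) and average log2 abundances (A) against the reference are
    computed on genes positive in both; the extreme 30% of M and 5% of A
    are trimmed and the factor is 2 to the precision-weighted mean of the
    remaining M values.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValidationError("every sample needs a positive library size")
    f75 = _quantile_factor(y, lib)
    if np.median(f75) < 1e-20:
        ref = int(np.argmax(np.sqrt(y).sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    yr = y[:, ref]
    for j in range(y.shape[1]):
        factors[j] = _tmm_pair(y[:, j], yr, lib[j], lib[ref], logratio_trim, sum_trim, weighted)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
    weighted: bool,
) -> float:
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos], ref[pos]
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if weighted:
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(m[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def _rank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x)


# ---------------------------------------------------------------------------
# negative-binomial exact test


@dataclass
class ExactTestResult:
    """Per-feature differential result plus the fitted common dispersion."""

    table: pd.DataFrame  # columns: log2FC, mean_abundance, pvalue, fdr
    dispersion: float
    comparison: tuple[str, str]


def _conditional_log_weights(total: int, r1: float | None, r2: float | None,
                             n1: int, n2: int) -> np.ndarray:
    """Unnormalized log P(y1 = y | y1 + y2 = total) under equal per-sample
    means; ``r1``/``r2`` are group NB sizes (n_g / phi), None means phi=0
    (the Poisson/binomial limit)."""
    y = np.arange(total + 1)
    if r1 is None:  # phi == 0: Binomial(total, n1/(n1+n2))
        p = n1 / (n1 + n2)
        return (
            gammaln(total + 1)
            - gammaln(y + 1)
            - gammaln(total - y + 1)
            + y * np.log(p)
            + (total - y) * np.log1p(-p)
        )
    return (
        gammaln(y + r1) - gammaln(y + 1)
        + gammaln(total - y + r2) - gammaln(total - y + 1)
    )


def exact_nb_pvalue(
    s1: int, s2: int, n1: int, n2: int, dispersion: float
) -> float:
    """Two-sided exact p for group sums (s1, s2) of (n1, n2) equalized
    samples under common dispersion: the probability, conditional on the
    total, of all splits whose probability does not exceed the observed
    split's."""
    total = s1 + s2
    if total == 0:
        return 1.0
    if dispersion > 0:
        r1, r2 = n1 / dispersion, n2 / dispersion
    else:
        r1 = r2 = None
    logw = _conditional_log_weights(total, r1, r2, n1, n2)
    logw = logw - logsumexp(logw)
    obs = logw[s1]
    # tolerance mirrors R's binom.test relative-error guard on ties
    keep = logw <= obs + 1e-7
    return float(min(1.0, np.exp(logsumexp(logw[keep]))))


def _equalize(counts: pd.DataFrame, eff_lib: pd.Series) -> pd.DataFrame:
    common = np.exp(np.mean(np.log(eff_lib)))
    return counts.mul(common / eff_lib, axis=1)


def estimate_common_dispersion(
    pseudo: pd.DataFrame, groups: Mapping[str, str]
) -> float:
    """Common dispersion by conditional maximum likelihood on equalized
    counts: within each group, the likelihood of the per-sample counts
    conditional on their sum depends on phi alone."""
    y = np.round(pseudo.to_numpy(dtype=float)).astype(np.int64)
    labels = pd.Series(groups).reindex(pseudo.columns)
    blocks = [
        y[:, (labels == g).to_numpy()] for g in labels.unique()
    ]

    def neg_cll(log_phi: float) -> float:
        phi = np.exp(log_phi)
        r = 1.0 / phi
        ll = 0.0
        for block in blocks:
            n = block.shape[1]
            if n < 2:
                continue
            t = block.sum(axis=1)
            ll += np.sum(gammaln(block + r)) - block.size * gammaln(r)
            ll += np.sum(gammaln(n * r) - gammaln(t + n * r))
        return -ll

    res = minimize_scalar(neg_cll, bounds=(-10.0, 3.0), method="bounded")
    phi = float(np.exp(res.x))
    # near-Poisson data pushes the optimum to the lower bound
    if res.x < -9.5:
        phi = 0.0
    return phi


def nb_exact_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    factors: pd.Series | None = None,
    dispersion: float | None = None,
    prior_count: float = 0.125,
) -> ExactTestResult:
    """Two-group exact differential test on count data.

    ``groups`` maps sample -> label and must contain exactly two labels;
    for more groups run :func:`pairwise_exact_tests`. Counts are scaled to
    a common effective library size (library x TMM factor); the common
    dispersion is estimated by conditional maximum likelihood when not
    supplied. log2 fold change is group1 over group2 on equalized means
    with a small prior count.
    """
    labels = pd.Series({s: groups[s] for s in counts.columns})
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValidationError(
            f"exact test needs exactly two groups, got {uniq}; "
            "use pairwise_exact_tests for multi-group designs"
        )
    g1, g2 = uniq
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValidationError("sample with zero library size")
    if factors is None:
        factors = tmm_factors(counts)
    eff_lib = lib * factors.reindex(counts.columns)
    pseudo = _equalize(counts, eff_lib)
    if dispersion is None:
        dispersion = estimate_common_dispersion(pseudo, groups)

    cols1 = labels.index[labels == g1]
    cols2 = labels.index[labels == g2]
    n1, n2 = len(cols1), len(cols2)
    s1 = np.round(pseudo[cols1].sum(axis=1)).astype(np.int64)
    s2 = np.round(pseudo[cols2].sum(axis=1)).astype(np.int64)

    pvals = np.array(
        [
            exact_nb_pvalue(int(a), int(b), n1, n2, dispersion)
            for a, b in zip(s1, s2)
        ]
    )
    m1 = pseudo[cols1].mean(axis=1)
    m2 = pseudo[cols2].mean(axis=1)
    log2fc = np.log2((m1 + prior_count) / (m2 + prior_count))
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "mean_abundance": pseudo.mean(axis=1),
            "pvalue": pvals,
            "fdr": bh_adjust(pvals),
        },
        index=counts.index,
    )
    return ExactTestResult(table=table, dispersion=float(dispersion), comparison=(g1, g2))


def pairwise_exact_tests(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    **kwargs,
) -> dict[tuple[str, str], ExactTestResult]:
    """All pairwise two-group exact tests for k-group designs.

    A feature counts as significant *for* group i when it is significant
    versus every other group (checked downstream via
    :func:`significant_in_group`)."""
    labels = pd.Series({s: groups[s] for s in counts.columns})
    uniq = list(dict.fromkeys(labels))
    out = {}
    for i, g1 in enumerate(uniq):
        for g2 in uniq[i + 1 :]:
            cols = labels.index[labels.isin([g1, g2])]
            sub_groups = {s: labels[s] for s in cols}
            out[(g1, g2)] = nb_exact_test(counts[cols], sub_groups, **kwargs)
    return out


def significant_in_group(
    results: Mapping[tuple[str, str], ExactTestResult],
    group: str,
    fdr: float = DEFAULT_FDR,
) -> pd.Index:
    """Features significantly *up* in ``group`` versus every other group."""
    keep: pd.Index | None = None
    for (g1, g2), res in results.items():
        if group not in (g1, g2):
            continue
        sign = 1.0 if group == g1 else -1.0
        hits = res.table.index[
            (res.table["fdr"] < fdr) & (sign * res.table["log2FC"] > 0)
        ]
        keep = hits if keep is None else keep.intersection(hits)
    if keep is None:
        raise ValidationError(f"group {group!r} not present in any comparison")
    return keep


# ---------------------------------------------------------------------------
# BH adjustment


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# TPM


def tpm(table: GeneCountTable) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6 per
    sample."""
    rates = table.counts.div(table.lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"samples with zero total expression: {list(totals.index[zero])}",
            stacklevel=2,
        )
    return 1e6 * rates.div(totals.mask(zero, 1), axis=1)


# ---------------------------------------------------------------------------
# preranked GSEA


def _running_es(
    hit_mask: np.ndarray, weights: np.ndarray, return_peak: bool = False
):
    """Signed maximum deviation of the weighted KS running sum.

    ``weights`` are |score|^p for every position in ranked order; hits
    step up by weight/sum(hit weights), misses step down uniformly."""
    nr = weights[hit_mask].sum()
    n_miss = hit_mask.size - hit_mask.sum()
    steps = np.where(hit_mask, weights / nr, -1.0 / n_miss)
    run = np.cumsum(steps)
    peak = int(np.argmax(np.abs(run)))
    es = float(run[peak])
    if return_peak:
        return es, peak
    return es


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
    min_size: int = 2,
) -> pd.DataFrame:
    """Preranked gene set enrichment with a gene-label permutation null.

    ``ranked`` maps gene -> score (any order; sorted descending here).
    ES is the signed maximum deviation of the weighted running sum; NES
    divides ES by the mean |null ES| of matching sign; the permutation p
    is two-sided within sign; BH adjusts across tested sets. Sets fully
    covering or disjoint from the list (or smaller than ``min_size``
    in-list) are skipped with a reason.
    """
    if ranked.index.duplicated().any():
        raise ValidationError("ranked list has duplicate gene ids")
    ranked = ranked.sort_values(ascending=False, kind="mergesort")
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    weights = np.abs(scores) ** weight
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    skipped = []
    for name, gset in sets.items():
        idx = np.array(sorted(pos[g] for g in gset.genes if g in pos), dtype=int)
        k = idx.size
        if k < min_size or k == 0:
            skipped.append((name, "too few genes in ranked list"))
            continue
        if k == genes.size:
            skipped.append((name, "set covers the entire ranked list"))
            continue
        hit_mask = np.zeros(genes.size, dtype=bool)
        hit_mask[idx] = True
        es, peak = _running_es(hit_mask, weights, return_peak=True)

        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_idx = rng.choice(genes.size, size=k, replace=False)
            mask = np.zeros(genes.size, dtype=bool)
            mask[perm_idx] = True
            null[b] = _running_es(mask, weights)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size == 0:
            nes = np.nan
            pval = 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same_sign))
            pval = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (same_sign.size + 1)

        if es >= 0:
            leading = [g for g in genes[: peak + 1] if hit_mask[pos[g]]]
        else:
            leading = [g for g in genes[peak:] if hit_mask[pos[g]]]
        rows.append(
            {
                "set": name,
                "size": int(k),
                "es": es,
                "nes": nes,
                "pvalue": float(pval),
                "leading_edge": ",".join(leading),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set", "size", "es", "nes", "pvalue", "leading_edge"]
    )
    if not out.empty:
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    else:
        out["padj"] = pd.Series(dtype=float)
    out.attrs["skipped"] = skipped
    return out.set_index("set")
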