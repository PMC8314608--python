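"""Target co-expression, hypergeometric gene-set enrichment, perturbation
signature intersection, and pairwise gene correlation with a linear trend.

Enrichment uses the one-sided (upper-tail) hypergeometric test per set with
Benjamini-Hochberg adjustment across sets by default (Bonferroni by flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "correlate_with_target",
    "select_coexpressed",
    "hypergeometric_enrichment",
    "intersect_signatures",
    "PairwiseCorrelation",
    "pairwise_correlation",
]


def _tumor_frame(expr) -> pd.DataFrame:
    if isinstance(expr, ExpressionMatrix):
        return expr.tumor_values()
    return expr


def correlate_with_target(target_gene: str, expr) -> pd.DataFrame:
    """Pearson r of every gene against the target across tumor samples.

    ``expr`` may be an ExpressionMatrix (tumor samples are used) or a plain
    genes x samples DataFrame.  Genes with zero variance have undefined r and
    are excluded (count logged and recorded in ``attrs``); the target's
    self-correlation is 1 by construction.
    """
    values = _tumor_frame(expr)
    if target_gene not in values.index:
        raise ValueError(f"target gene '{target_gene}' not in expression matrix")
    n = values.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for correlation")
    X = values.to_numpy(dtype=float)
    t = values.loc[target_gene].to_numpy(dtype=float)
    t_c = t - t.mean()
    t_norm = np.sqrt((t_c ** 2).sum())
    if t_norm == 0:
        raise ValueError("target gene has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    defined = norms > 0
    r = np.full(X.shape[0], np.nan)
    r[defined] = (Xc[defined] @ t_c) / (norms[defined] * t_norm)
    r = np.clip(r, -1.0, 1.0)
    n_dropped = int((~defined).sum())
    if n_dropped:
        log.info("correlate_with_target: excluded %d zero-variance genes", n_dropped)
    out = pd.DataFrame({"r_pearson": r[defined], "n_samples": n},
                       index=values.index[defined].copy())
    out.attrs["target"] = target_gene
    out.attrs["n_zero_variance_excluded"] = n_dropped
    return out


def select_coexpressed(corr: pd.DataFrame, min_abs_r: float = 0.5):
    """Split genes with |r| strictly greater than the cutoff into positively
    and negatively co-expressed sets; the target itself is excluded."""
    target = corr.attrs.get("target")
    mask = corr["r_pearson"].abs() > min_abs_r
    if target is not None:
        mask &= corr.index != target
    hits = corr[mask]
    positive = sorted(hits.index[hits["r_pearson"] > 0].tolist())
    negative = sorted(hits.index[hits["r_pearson"] < 0].tolist())
    return positive, negative


def hypergeometric_enrichment(query, collection, universe,
                              correction: str = "benjamini_hochberg") -> pd.DataFrame:
    """One-sided hypergeometric (Fisher upper-tail) enrichment of a query
    gene set against a gene-set collection.

    Sets are intersected with the universe before testing; the query must be
    a subset of the universe.  ``correction`` is ``benjamini_hochberg``
    (default) or ``bonferroni`` across sets.  Rows are sorted by adjusted
    then raw p, ties by set id.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    if query - universe:
        raise ValueError("query genes must be a subset of the universe")
    if correction not in ("benjamini_hochberg", "bonferroni"):
        raise ValueError("correction must be 'benjamini_hochberg' or 'bonferroni'")

    N, n = len(universe), len(query)
    rows = []
    for gs in collection:
        members = set(gs.members) & universe
        K = len(members)
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append((gs.set_id, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["set_id", "overlap", "set_size",
                                     "query_size", "universe_size", "p_value"])
    if len(df):
        method = "fdr_bh" if correction == "benjamini_hochberg" else "bonferroni"
        df["adjusted_p"] = multipletests(df["p_value"].to_numpy(), method=method)[1]
    else:
        df["adjusted_p"] = []
    return df.sort_values(["adjusted_p", "p_value", "set_id"],
                          kind="mergesort").reset_index(drop=True)


def _norm_signature(sig: pd.DataFrame, min_abs_effect: float) -> pd.DataFrame:
    sig = sig.set_index("gene_id") if "gene_id" in sig.columns else sig
    if "effect" not in sig.columns:
        raise ValueError("signature table needs an 'effect' column")
    if not np.isfinite(sig["effect"].to_numpy(dtype=float)).all():
        raise ValueError("signature effects must be finite")
    if "significant" not in sig.columns:
        sig = sig.assign(significant=sig["effect"].abs() >= min_abs_effect)
    return sig


def intersect_signatures(sig_a: pd.DataFrame, sig_b: pd.DataFrame,
                         min_abs_effect: float = 1.0):
    """Concordantly regulated genes of two perturbation signatures.

    up = significant in both with positive effect in both; down = significant
    in both with negative effect in both; discordant genes are excluded.
    When a table lacks a ``significant`` flag, |effect| >= ``min_abs_effect``
    (default 1 log2 unit) is used.  Returns (up, down, combined_count).
    """
    a = _norm_signature(sig_a, min_abs_effect)
    b = _norm_signature(sig_b, min_abs_effect)
    shared = a.index.intersection(b.index)
    ea, eb = a.loc[shared, "effect"], b.loc[shared, "effect"]
    sig_both = a.loc[shared, "significant"].astype(bool) & b.loc[shared, "significant"].astype(bool)
    up = sorted(shared[sig_both & (ea > 0) & (eb > 0)].tolist())
    down = sorted(shared[sig_both & (ea < 0) & (eb < 0)].tolist())
    return up, down, len(up) + len(down)


@dataclass
class PairwiseCorrelation:
    r: float
    p_value: float      # two-tailed t-test, df = n - 2
    slope: float
    intercept: float
    n: int


def pairwise_correlation(gene_a: str, gene_b: str, expr) -> PairwiseCorrelation:
    """Pearson r between two genes with its two-tailed t-test p-value and the
    simple least-squares trend line of b on a."""
    values = _tumor_frame(expr)
    for g in (gene_a, gene_b):
        if g not in values.index:
            raise ValueError(f"gene '{g}' not in expression matrix")
    x = values.loc[gene_a].to_numpy(dtype=float)
    y = values.loc[gene_b].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance gene; correlation undefined")
    res = stats.linregress(x, y)
    return PairwiseCorrelation(float(res.rvalue), float(res.pvalue),
                               float(res.slope), float(res.intercept), x.size)
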