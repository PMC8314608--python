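"""Stage 1 of the funnel: tumor-over-normal log2 fold increase and the
overexpression cutoff.

The screen is a pure fold-change funnel (no moderated statistics): per gene,
the mean log2 expression of tumors minus a normal-compendium reference, with
genes at or above the cutoff (default 2 log2 units) nominated as candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["log2_fold_increase", "filter_overexpressed"]

NORMAL_AGGREGATIONS = ("per_tissue_mean", "pooled")


def log2_fold_increase(expr: ExpressionMatrix,
                       normal_aggregation: str = "per_tissue_mean") -> pd.DataFrame:
    """Per-gene log2 fold increase of tumors over the normal compendium.

    Parameters
    ----------
    expr
        Log2 expression with tumor/normal classes and tissue labels.
    normal_aggregation
        ``"pooled"`` — mean over all normal samples; ``"per_tissue_mean"``
        (default) — mean of per-tissue means, weighting each normal tissue
        type equally regardless of how many samples it contributed.

    Returns
    -------
    DataFrame indexed by gene_id with columns ``log2_fold_increase``,
    ``tumor_mean`` and ``normal_reference`` (fold = tumor_mean -
    normal_reference exactly).
    """
    if normal_aggregation not in NORMAL_AGGREGATIONS:
        raise ValueError(f"normal_aggregation must be one of {NORMAL_AGGREGATIONS}")
    tumors = expr.tumor_values()
    normals = expr.normal_values()
    if tumors.shape[1] == 0:
        raise ValueError("no tumor samples in expression matrix")
    if normals.shape[1] == 0:
        raise ValueError("no normal samples in expression matrix")
    if tumors.isna().any().any() or normals.isna().any().any():
        bad = expr.values.index[expr.values.isna().any(axis=1)].tolist()
        raise ValueError(f"missing expression values for genes: {bad[:5]}")

    tumor_mean = tumors.mean(axis=1)
    if normal_aggregation == "pooled":
        normal_ref = normals.mean(axis=1)
    else:
        tissues = expr.tissue[normals.columns]
        normal_ref = normals.T.groupby(tissues).mean().mean(axis=0)
    fc = tumor_mean - normal_ref
    return pd.DataFrame(
        {"log2_fold_increase": fc, "tumor_mean": tumor_mean,
         "normal_reference": normal_ref},
        index=expr.values.index.copy())


def filter_overexpressed(fc: pd.DataFrame, min_log2_fold: float = 2.0) -> list[str]:
    """Candidate genes with fold increase >= cutoff (inclusive), sorted by
    descending fold; ties broken lexicographically by gene id."""
    if fc.empty:
        raise ValueError("fold-change table is empty")
    hits = fc[fc["log2_fold_increase"] >= min_log2_fold]
    order = sorted(hits.index, key=lambda g: (-hits.at[g, "log2_fold_increase"], g))
    return list(order)
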