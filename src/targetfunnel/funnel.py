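"""Stage 3 and orchestration: druggability filtering of survival-screen hits
and assembly of the ranked target-candidate table (the overexpression ->
survival -> druggability funnel shape)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalCohort
from .expression import filter_overexpressed, log2_fold_increase
from .survival import run_survival_screen

log = logging.getLogger(__name__)

__all__ = ["FunnelConfig", "apply_druggability_filter", "run_full_screen"]

_FLAGS = ("enzymatic_function", "specific_inhibitor_available",
          "pk_data_available", "tested_in_disease")


@dataclass(frozen=True)
class FunnelConfig:
    """Stage parameters of the full screen.

    min_log2_fold: stage-1 overexpression cutoff (log2 units, inclusive).
    normal_aggregation: normal-compendium reference ('per_tissue_mean'|'pooled').
    percentile: fixed stratification quantile (float) or a scan grid.
    alpha: FWER level for the Bonferroni-adjusted survival screen.
    """

    min_log2_fold: float = 2.0
    normal_aggregation: str = "per_tissue_mean"
    percentile: object = 0.78
    alpha: float = 0.05


def _annotation_row(annotations: pd.DataFrame, gene: str) -> dict:
    if gene in annotations.index:
        return {f: bool(annotations.at[gene, f]) for f in _FLAGS}
    return {f: False for f in _FLAGS}


def apply_druggability_filter(hits, annotations: pd.DataFrame) -> list[str]:
    """Keep hit genes that are enzymatically druggable: enzymatic function AND
    specific inhibitor available AND PK data available AND NOT already tested
    in the disease.  Hits without an annotation record are treated as
    all-false (not druggable) and logged.

    ``hits`` may be the survival-screen DataFrame (its passing genes are
    used) or a plain iterable of gene ids.
    """
    if isinstance(hits, pd.DataFrame):
        genes = hits.loc[hits["passes"], "gene_id"].tolist()
    else:
        genes = list(hits)
    missing = [g for g in genes if g not in annotations.index]
    if missing:
        log.warning("druggability filter: no annotation for %s; treated as "
                    "not druggable", missing[:10])
    kept = []
    for g in genes:
        rec = _annotation_row(annotations, g)
        if (rec["enzymatic_function"] and rec["specific_inhibitor_available"]
                and rec["pk_data_available"] and not rec["tested_in_disease"]):
            kept.append(g)
    return kept


def run_full_screen(expr: ExpressionMatrix, cohort: SurvivalCohort,
                    annotations: pd.DataFrame,
                    config: FunnelConfig = FunnelConfig()):
    """Execute the three-stage funnel and assemble the candidate table.

    Returns ``(targets, funnel_summary)``: ``targets`` has one row per
    stage-1 candidate with fold change, survival-screen results, druggability
    flags, the furthest funnel stage reached and (for stage-3 genes) a unique
    rank by adjusted p ascending, then fold increase descending, then gene
    id; ``funnel_summary`` lists the candidate count per stage.
    """
    fc = log2_fold_increase(expr, config.normal_aggregation)
    stage1 = filter_overexpressed(fc, config.min_log2_fold)

    if stage1:
        screen = run_survival_screen(stage1, cohort, percentile=config.percentile,
                                     alpha=config.alpha)
    else:
        screen = pd.DataFrame(columns=["gene_id", "tested", "cutoff_percentile",
                                       "raw_p", "adjusted_p", "direction", "passes"])
    stage2 = screen.loc[screen["passes"], "gene_id"].tolist()
    stage3 = apply_druggability_filter(stage2, annotations)

    screen_by_gene = screen.set_index("gene_id") if len(screen) else screen
    rows = []
    for g in stage1:
        srow = screen_by_gene.loc[g] if g in getattr(screen_by_gene, "index", []) else None
        rec = _annotation_row(annotations, g)
        stage_reached = 3 if g in stage3 else (2 if g in stage2 else 1)
        rows.append({
            "gene_id": g,
            "log2_fold_increase": float(fc.at[g, "log2_fold_increase"]),
            "tested": bool(srow["tested"]) if srow is not None else False,
            "cutoff_percentile": float(srow["cutoff_percentile"]) if srow is not None else np.nan,
            "raw_p": float(srow["raw_p"]) if srow is not None else np.nan,
            "adjusted_p": float(srow["adjusted_p"]) if srow is not None else np.nan,
            "direction": srow["direction"] if srow is not None else None,
            **rec,
            "funnel_stage_reached": stage_reached,
        })
    targets = pd.DataFrame(rows, columns=[
        "gene_id", "log2_fold_increase", "tested", "cutoff_percentile", "raw_p",
        "adjusted_p", "direction", *_FLAGS, "funnel_stage_reached"])
    targets["rank"] = pd.array([pd.NA] * len(targets), dtype="Int64")
    if stage3:
        final = targets[targets["funnel_stage_reached"] == 3].sort_values(
            ["adjusted_p", "log2_fold_increase", "gene_id"],
            ascending=[True, False, True], kind="mergesort")
        targets.loc[final.index, "rank"] = np.arange(1, len(final) + 1)
    targets = targets.sort_values(
        ["funnel_stage_reached", "adjusted_p", "log2_fold_increase", "gene_id"],
        ascending=[False, True, False, True], kind="mergesort").reset_index(drop=True)

    funnel_summary = pd.DataFrame(
        {"stage": [1, 2, 3],
         "description": ["overexpressed (log2 fold >= cutoff)",
                         "negative survival association (Bonferroni)",
                         "druggable, untested in disease"],
         "count": [len(stage1), len(stage2), len(stage3)]})
    targets.attrs["m_tested"] = screen.attrs.get("m_tested", 0)
    return targets, funnel_summary
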