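"""Canonical synthetic study conditions used by the analysis drivers, the
acceptance checks and the calibration simulations.

These fix, once, the desk-scale designs the generators emulate: a 200-gene
tumor/normal compendium with one fully planted target (overexpressed by 3
log2 units, prognostic with hazard ratio 3 dichotomized at the 78th
percentile, enzymatically druggable and untested) plus overexpressed-only and
prognostic-only distractors; a matched survival cohort sized for >99%
log-rank power at that effect; dose-response plates mirroring a sensitive /
intermediate / insensitive cell-type panel and an acquired-resistance pair;
and two-drug grids with controllable Bliss deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .funnel import FunnelConfig
from .synth import (CohortSpec, CompendiumSpec, PlateSpec,
                    generate_druggability_annotations,
                    generate_expression_compendium, generate_survival_cohort)

__all__ = [
    "PLANTED_TARGET", "OX_ONLY", "PROG_ONLY",
    "funnel_scenario", "null_screen_scenario",
    "plate_panel", "resistance_pair", "synergy_plates",
]

PLANTED_TARGET = "RRM2L"                     # the one gene planted at all 3 stages
OX_ONLY = tuple(f"OX{i}" for i in range(1, 6))      # overexpressed, not prognostic
PROG_ONLY = tuple(f"PR{i}" for i in range(1, 4))    # prognostic, not overexpressed

N_GENES = 200
N_PATIENTS = 250
TISSUES = tuple((f"tissue{i:02d}", 15) for i in range(1, 11))
DELTA_LOG2 = 3.0
LOG_HR = math.log(3.0)
CUT_Q = 0.78
BASE_HAZARD = 0.1        # events per month
CENS_RATE = 0.02         # independent censoring per month
MAX_FOLLOWUP = 120.0     # months


def funnel_scenario(seed: int):
    """Compendium + cohort + annotations with the planted funnel truth.

    Returns (expr, cohort, annotations, config, truth) where ``truth`` maps
    stage names to the gene sets planted for them.
    """
    planted_ox = [(PLANTED_TARGET, DELTA_LOG2)] + [(g, DELTA_LOG2) for g in OX_ONLY]
    planted_ox += [(g, 0.0) for g in PROG_ONLY]   # named but not overexpressed
    cspec = CompendiumSpec(
        n_genes=N_GENES, n_tumor=N_PATIENTS, tissues=TISSUES,
        baseline_mean=7.0, baseline_sd=1.0,
        planted_overexpressed=tuple(planted_ox), seed=seed)
    expr = generate_expression_compendium(cspec)

    prognostic = [(PLANTED_TARGET, LOG_HR, CUT_Q)] + [(g, LOG_HR, CUT_Q) for g in PROG_ONLY]
    sspec = CohortSpec(
        n_patients=N_PATIENTS, baseline_hazard=BASE_HAZARD,
        planted_prognostic=tuple(prognostic),
        censoring_rate=CENS_RATE, max_followup=MAX_FOLLOWUP,
        seed=seed + 10_000)
    cohort = generate_survival_cohort(expr, sspec)

    annotations = generate_druggability_annotations(
        expr.gene_ids, {PLANTED_TARGET}, seed=seed + 20_000)
    config = FunnelConfig(min_log2_fold=2.0, percentile=CUT_Q, alpha=0.05)
    truth = {"stage1": {PLANTED_TARGET, *OX_ONLY},
             "stage2": {PLANTED_TARGET},
             "stage3": {PLANTED_TARGET}}
    return expr, cohort, annotations, config, truth


def null_screen_scenario(seed: int, n_genes: int = 200, n_patients: int = 100):
    """Global-null compendium + cohort (no planted effects) for FWER
    calibration of the survival screen."""
    cspec = CompendiumSpec(
        n_genes=n_genes, n_tumor=n_patients,
        tissues=(("tissueA", 10), ("tissueB", 10)),
        baseline_mean=7.0, baseline_sd=1.0, seed=seed)
    expr = generate_expression_compendium(cspec)
    sspec = CohortSpec(n_patients=n_patients, baseline_hazard=BASE_HAZARD,
                       censoring_rate=CENS_RATE, max_followup=MAX_FOLLOWUP,
                       seed=seed + 10_000)
    cohort = generate_survival_cohort(expr, sspec)
    return expr, cohort


_DOSES_LOW = tuple(0.01 * 2 ** k for k in range(10))     # 0.01 .. 5.12 uM
_DOSES_HIGH = tuple(1.0 * 2 ** k for k in range(10))     # 1 .. 512 uM


def plate_panel(seed: int, noise_sd: float = 0.02):
    """Single-agent plates for a sensitive (EC50 0.35 uM), intermediate
    (1.63 uM) and insensitive (101.63 uM) cell type."""
    return {
        "sensitive": PlateSpec(0.0, 1.0, 0.35, 1.5, _DOSES_LOW, 3, noise_sd, seed),
        "intermediate": PlateSpec(0.0, 1.0, 1.63, 1.5, _DOSES_LOW, 3, noise_sd, seed + 1),
        "insensitive": PlateSpec(0.0, 1.0, 101.63, 1.5, _DOSES_HIGH, 3, noise_sd, seed + 2),
    }


def resistance_pair(seed: int, fold: float = 2000.0, noise_sd: float = 0.02):
    """Parental vs acquired-resistance plates with a planted IC50 shift."""
    parental_ec50 = 0.05
    doses_res = tuple(parental_ec50 * fold * 2.0 ** k for k in range(-5, 5))
    return {
        "parental": PlateSpec(0.0, 1.0, parental_ec50, 1.5, _DOSES_LOW, 3,
                              noise_sd, seed),
        "resistant": PlateSpec(0.0, 1.0, parental_ec50 * fold, 1.5, doses_res, 3,
                               noise_sd, seed + 1),
    }


def synergy_plates(seed: int = 0):
    """Two single-agent curves (hill 1, EC50 1 uM) with a dose range spanning
    ec50/8 .. 2*ec50, so a +0.15 Bliss deviation stays essentially unclipped
    on the combination grid."""
    doses = (0.125, 0.25, 0.5, 1.0, 2.0)
    a = PlateSpec(0.0, 1.0, 1.0, 1.0, doses, 1, 0.0, seed)
    b = PlateSpec(0.0, 1.0, 1.0, 1.0, doses, 1, 0.0, seed + 1)
    return a, b
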