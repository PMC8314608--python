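"""Synthetic-data generators for every input the screening pipeline consumes.

The generators emulate, at desk scale, the statistical structure the analysis
assumes: a tumor/normal log2 expression compendium with planted overexpressed
genes, survival cohorts whose hazard depends on planted genes' dichotomized
expression, immunoreactive scores (IRS) coupled to outcome, 4PL-shaped
single-agent plates, and two-drug grids with a controllable deviation from
Bliss independence.  Every generator is bit-reproducible given its spec and
seed; there is no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import NORMAL, TUMOR, CombinationGrid, ExpressionMatrix, GeneSet, SurvivalCohort
from .pharm import four_pl

__all__ = [
    "CompendiumSpec",
    "CohortSpec",
    "PlateSpec",
    "generate_expression_compendium",
    "generate_survival_cohort",
    "generate_irs_scores",
    "generate_dose_response_plate",
    "generate_combination_grid",
    "generate_druggability_annotations",
    "generate_gene_set_collection",
]


@dataclass(frozen=True)
class CompendiumSpec:
    """Design of a tumor + multi-tissue normal log2 expression compendium.

    ``planted_overexpressed`` lists (gene_id, delta_log2) pairs; those genes
    are named as given and their tumor samples are shifted up by delta_log2
    log2 units.  Filler genes are auto-named G0001, G0002, ...
    """

    n_genes: int
    n_tumor: int
    tissues: tuple[tuple[str, int], ...]
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    planted_overexpressed: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_tumor < 1:
            raise ValueError("n_genes and n_tumor must be positive")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        if not self.tissues:
            raise ValueError("at least one normal tissue is required")
        names = [t for t, _ in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("tissue names must be unique")
        if any(n < 1 for _, n in self.tissues):
            raise ValueError("every tissue needs >= 1 sample")
        planted_ids = [g for g, _ in self.planted_overexpressed]
        if len(set(planted_ids)) != len(planted_ids):
            raise ValueError("duplicate planted gene_id")
        if len(planted_ids) > self.n_genes:
            raise ValueError("more planted genes than n_genes")
        if any(not np.isfinite(d) for _, d in self.planted_overexpressed):
            raise ValueError("delta_log2 must be finite")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a survival cohort tied to a compendium's tumor samples.

    Event times are exponential with hazard
    ``baseline_hazard * exp(sum log_HR * [expression > per-gene quantile])``;
    censoring is independent exponential at ``censoring_rate`` plus
    administrative censoring at ``max_followup``.
    """

    n_patients: int
    baseline_hazard: float
    planted_prognostic: tuple[tuple[str, float, float], ...] = ()
    censoring_rate: float = 0.0
    max_followup: float = float("inf")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.max_followup <= 0:
            raise ValueError("max_followup must be > 0")
        for gene, _, q in self.planted_prognostic:
            if not (0.0 < q < 1.0):
                raise ValueError(f"stratification quantile for {gene} outside (0, 1)")


@dataclass(frozen=True)
class PlateSpec:
    """True 4PL viability curve plus plate noise for a single-agent assay."""

    true_bottom: float
    true_top: float
    true_ec50: float
    true_hill: float
    doses: tuple[float, ...]
    replicates: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_bottom < self.true_top:
            raise ValueError("true_bottom must be < true_top")
        if not (0.0 <= self.true_bottom and self.true_top <= 1.0):
            raise ValueError("asymptotes must lie in [0, 1]")
        if self.true_ec50 <= 0 or self.true_hill <= 0:
            raise ValueError("true_ec50 and true_hill must be positive")
        d = np.asarray(self.doses, dtype=float)
        if d.size < 1 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly positive and sorted ascending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_expression_compendium(spec: CompendiumSpec) -> ExpressionMatrix:
    """Gaussian log2 compendium with planted tumor overexpression.

    Planted gene ids occupy the first rows (in the order given); remaining
    rows are filler genes.  Tumor samples are T001..; each normal sample id is
    ``<tissue>_<k>``.
    """
    rng = np.random.default_rng(spec.seed)
    planted = dict(spec.planted_overexpressed)
    gene_ids = list(planted)
    k = 1
    while len(gene_ids) < spec.n_genes:
        gid = f"G{k:04d}"
        if gid not in planted:
            gene_ids.append(gid)
        k += 1

    tumor_ids = [f"T{i:03d}" for i in range(1, spec.n_tumor + 1)]
    normal_ids, tissue_of = [], {}
    for tissue, n in spec.tissues:
        for i in range(1, n + 1):
            sid = f"{tissue}_{i:02d}"
            normal_ids.append(sid)
            tissue_of[sid] = tissue
    sample_ids = tumor_ids + normal_ids

    values = rng.normal(spec.baseline_mean, spec.baseline_sd,
                        size=(spec.n_genes, len(sample_ids)))
    for row, gid in enumerate(gene_ids):
        if gid in planted:
            values[row, : spec.n_tumor] += planted[gid]

    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=sample_ids)
    sample_class = pd.Series(
        [TUMOR] * spec.n_tumor + [NORMAL] * len(normal_ids), index=sample_ids)
    tissue = pd.Series(
        [TUMOR] * spec.n_tumor + [tissue_of[s] for s in normal_ids], index=sample_ids)
    return ExpressionMatrix(df, sample_class, tissue)


def generate_survival_cohort(expr: ExpressionMatrix, spec: CohortSpec) -> SurvivalCohort:
    """Exponential event times with step-function covariate effects.

    The cohort's patients are the compendium's tumor samples (matched
    expression and survival); ``spec.n_patients`` must equal their number.
    The per-gene cutoff is the planted quantile of expression across tumors.
    The latent pre-censoring event time is kept in a ``true_event_time``
    column for downstream generators; writers only emit time/event.
    """
    tumors = list(expr.tumor_samples)
    if spec.n_patients != len(tumors):
        raise ValueError(
            f"spec.n_patients={spec.n_patients} but compendium has {len(tumors)} tumors")
    tumor_expr = expr.tumor_values()
    log_hr = np.zeros(len(tumors))
    for gene, lhr, q in spec.planted_prognostic:
        if gene not in tumor_expr.index:
            raise ValueError(f"planted prognostic gene '{gene}' not in expression matrix")
        vals = tumor_expr.loc[gene].to_numpy(dtype=float)
        cutoff = np.quantile(vals, q)
        log_hr = log_hr + lhr * (vals > cutoff)

    rng = np.random.default_rng(spec.seed)
    hazard = spec.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, size=len(tumors))
    else:
        t_cens = np.full(len(tumors), np.inf)
    t_cens = np.minimum(t_cens, spec.max_followup)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    table = pd.DataFrame(
        {"time": time, "event": event, "true_event_time": t_event},
        index=pd.Index(tumors, name="patient_id"))
    return SurvivalCohort(table, expression=tumor_expr.copy())


def generate_irs_scores(cohort: SurvivalCohort, association_strength: float,
                        seed: int = 0) -> pd.DataFrame:
    """Immunoreactive scores IRS = intensity (0-3) x proportion (0-4).

    A latent risk score (standardized negative log latent event time, falling
    back to observed time if the cohort lacks ``true_event_time``) is mixed
    with unit Gaussian noise at weight ``association_strength`` and binned by
    cohort quartiles/quintiles into the two factor scores, so higher
    association couples high IRS to shorter event times and strength 0 gives
    IRS independent of outcome.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(seed)
    t = (cohort.table["true_event_time"].to_numpy(dtype=float)
         if "true_event_time" in cohort.table.columns else cohort.times)
    risk = -np.log(t)
    sd = risk.std()
    risk = (risk - risk.mean()) / (sd if sd > 0 else 1.0)

    lat_i = association_strength * risk + rng.normal(size=len(cohort))
    lat_p = association_strength * risk + rng.normal(size=len(cohort))
    intensity = np.searchsorted(np.quantile(lat_i, [0.25, 0.5, 0.75]), lat_i,
                                side="left")
    proportion = np.searchsorted(np.quantile(lat_p, [0.2, 0.4, 0.6, 0.8]), lat_p,
                                 side="left")
    return pd.DataFrame(
        {"intensity": intensity, "proportion": proportion,
         "irs": intensity * proportion},
        index=cohort.table.index.copy())


def generate_dose_response_plate(spec: PlateSpec) -> pd.DataFrame:
    """Plate table (dose, replicate, response): 4PL viability plus Gaussian
    noise, clipped to [0, 1.05] to allow slight super-control readings."""
    rng = np.random.default_rng(spec.seed)
    doses = np.repeat(np.asarray(spec.doses, dtype=float), spec.replicates)
    reps = np.tile(np.arange(1, spec.replicates + 1), len(spec.doses))
    y = four_pl(doses, spec.true_bottom, spec.true_top, spec.true_ec50, spec.true_hill)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    y = np.clip(y, 0.0, 1.05)
    return pd.DataFrame({"dose": doses, "replicate": reps, "response": y})


def _inhibition_from_spec(doses: np.ndarray, spec: PlateSpec) -> np.ndarray:
    """Fraction affected implied by the spec's viability curve, normalized to
    the untreated control (= true_top)."""
    v = four_pl(doses, spec.true_bottom, spec.true_top, spec.true_ec50, spec.true_hill)
    return 1.0 - v / spec.true_top


def generate_combination_grid(curve_a: PlateSpec, curve_b: PlateSpec,
                              bliss_deviation: float, seed: int = 0,
                              noise_sd: float = 0.0) -> CombinationGrid:
    """Two-drug inhibition grid with a uniform injected Bliss deviation.

    Interior cells are ``y_a + y_b - y_a*y_b + bliss_deviation`` (clipped to
    [0, 1]); margins (dose-0 row/column) carry the exact single-agent values.
    Optional Gaussian noise (driven by ``seed``) is off by default.
    """
    if not (-0.5 <= bliss_deviation <= 0.5):
        raise ValueError("bliss_deviation must lie in [-0.5, 0.5]")
    da = np.concatenate([[0.0], np.asarray(curve_a.doses, dtype=float)])
    db = np.concatenate([[0.0], np.asarray(curve_b.doses, dtype=float)])
    ya = np.concatenate([[0.0], _inhibition_from_spec(da[1:], curve_a)])
    yb = np.concatenate([[0.0], _inhibition_from_spec(db[1:], curve_b)])
    grid = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    grid[1:, 1:] += bliss_deviation
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise_sd, size=grid.shape)
        grid[0, 0] = 0.0
    return CombinationGrid(da, db, np.clip(grid, 0.0, 1.0))


def generate_druggability_annotations(gene_ids, planted_druggable, seed: int = 0) -> pd.DataFrame:
    """Boolean druggability annotations per gene.

    Planted genes satisfy the downstream filter exactly (enzymatic function,
    specific inhibitor and PK data available, not yet tested in the disease).
    Non-planted genes draw random flags, and any random draw that would pass
    the filter is marked ``tested_in_disease`` so the planted set is the exact
    druggable truth set.
    """
    gene_ids = list(gene_ids)
    planted = set(planted_druggable)
    unknown = planted - set(gene_ids)
    if unknown:
        raise ValueError(f"planted druggable genes not in universe: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    enz = rng.random(n) < 0.3
    inh = rng.random(n) < 0.3
    pk = rng.random(n) < 0.5
    tested = rng.random(n) < 0.1
    df = pd.DataFrame(
        {"enzymatic_function": enz, "specific_inhibitor_available": inh,
         "pk_data_available": pk, "tested_in_disease": tested},
        index=pd.Index(gene_ids, name="gene_id"))
    would_pass = enz & inh & pk & ~tested
    df.loc[would_pass, "tested_in_disease"] = True
    is_planted = df.index.isin(planted)
    df.loc[is_planted, ["enzymatic_function", "specific_inhibitor_available",
                        "pk_data_available"]] = True
    df.loc[is_planted, "tested_in_disease"] = False
    return df


def generate_gene_set_collection(gene_ids, n_sets: int, set_size_range,
                                 planted_set_around=(), seed: int = 0) -> list[GeneSet]:
    """Random gene sets plus (optionally) one set enriched for a gene list.

    The planted set contains all of ``planted_set_around`` padded with random
    other genes up to the lower end of ``set_size_range`` if needed; it is
    appended last with id ``PLANTED``.
    """
    gene_ids = list(gene_ids)
    lo, hi = set_size_range
    if not (1 <= lo <= hi <= len(gene_ids)):
        raise ValueError("set_size_range must satisfy 1 <= lo <= hi <= universe size")
    if n_sets < 0:
        raise ValueError("n_sets must be >= 0")
    planted = list(dict.fromkeys(planted_set_around))
    if set(planted) - set(gene_ids):
        raise ValueError("planted_set_around genes must be in the universe")
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(sorted(rng.choice(gene_ids, size=size, replace=False)))
        sets.append(GeneSet(f"RAND{i:04d}", "random gene set", members))
    if planted:
        members = list(planted)
        pool = [g for g in gene_ids if g not in set(planted)]
        while len(members) < lo and pool:
            pick = pool[int(rng.integers(len(pool)))]
            members.append(pick)
            pool.remove(pick)
        sets.append(GeneSet("PLANTED", "planted enriched set", tuple(members)))
    return sets
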