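"""Plain-TSV readers/writers, GMT gene sets, report writing and pipeline
configuration.

TSV with a header row is the single tabular dialect (tab-separated, decimal
point, no locale commas).  Every writer's output is accepted by its reader.
Logging goes to stderr; result files never mix logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import SAMPLE_CLASSES, CombinationGrid, ExpressionMatrix, GeneSet, SurvivalCohort

log = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_sample_metadata_tsv", "write_sample_metadata_tsv",
    "load_expression_matrix", "save_expression_matrix",
    "read_survival_tsv", "write_survival_tsv",
    "read_plate_tsv", "write_plate_tsv",
    "read_grid_tsv", "write_grid_tsv",
    "read_gmt", "write_gmt",
    "write_report", "PipelineConfig", "load_config",
]

_FLOAT_FMT = "%.10g"


def _read_tsv(path, required_cols) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str,
                         keep_default_na=False, na_values=[])
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _to_float(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        try:
            df[c] = df[c].astype(float)
        except ValueError:
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: non-numeric value in column '{c}' at line {bad + 2}"
            ) from None
    return df


# -- expression -------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples log2 matrix: header row of sample ids, first column
    ``gene_id``.  Duplicate ids, ragged rows and non-numeric cells reject
    with the offending gene/line."""
    path = Path(path)
    df = _read_tsv(path, [])
    gene_col = df.columns[0]
    genes = df[gene_col]
    dup = genes[genes.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate gene id(s): {dup[:5]}")
    if len(set(df.columns[1:])) != len(df.columns) - 1:
        raise ValueError(f"{path}: duplicate sample ids in header")
    if len(df.columns) < 2:
        raise ValueError(f"{path}: no sample columns")
    out = df.set_index(gene_col)
    out.index.name = "gene_id"
    for i, (gene, row) in enumerate(out.iterrows()):
        vals = pd.to_numeric(row, errors="coerce")
        if vals.isna().any():
            raise ValueError(
                f"{path}: non-numeric or missing value for gene '{gene}' (line {i + 2})")
    return out.astype(float)


def write_expression_tsv(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)


def read_sample_metadata_tsv(path) -> pd.DataFrame:
    """Sample metadata: columns sample_id, class (tumor|normal), tissue."""
    path = Path(path)
    df = _read_tsv(path, ["sample_id", "class", "tissue"])
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample id(s): {dup[:5]}")
    bad = sorted(set(df["class"]) - SAMPLE_CLASSES)
    if bad:
        line = df.index[df["class"].isin(bad)][0] + 2
        raise ValueError(f"{path}: invalid sample class {bad[:3]} (line {line})")
    return df.set_index("sample_id")


def write_sample_metadata_tsv(expr: ExpressionMatrix, path) -> None:
    pd.DataFrame({"class": expr.sample_class, "tissue": expr.tissue}) \
        .to_csv(path, sep="\t", index_label="sample_id")


def load_expression_matrix(expr_path, meta_path) -> ExpressionMatrix:
    values = read_expression_tsv(expr_path)
    meta = read_sample_metadata_tsv(meta_path)
    return ExpressionMatrix(values, meta["class"], meta["tissue"])


def save_expression_matrix(expr: ExpressionMatrix, expr_path, meta_path) -> None:
    write_expression_tsv(expr.values, expr_path)
    write_sample_metadata_tsv(expr, meta_path)


# -- survival ---------------------------------------------------------------

def read_survival_tsv(path) -> SurvivalCohort:
    """Survival table: patient_id, time (> 0), event in {0, 1}."""
    path = Path(path)
    df = _read_tsv(path, ["patient_id", "time", "event"])
    df = _to_float(df, ["time"], path)
    bad = ~df["event"].isin(["0", "1"])
    if bad.any():
        line = df.index[bad][0] + 2
        raise ValueError(f"{path}: event values must be 0 or 1 (line {line})")
    table = pd.DataFrame(
        {"time": df["time"].to_numpy(),
         "event": df["event"].astype(int).astype(bool).to_numpy()},
        index=pd.Index(df["patient_id"], name="patient_id"))
    return SurvivalCohort(table)


def write_survival_tsv(cohort: SurvivalCohort, path) -> None:
    out = pd.DataFrame({"time": cohort.table["time"],
                        "event": cohort.table["event"].astype(int)})
    out.to_csv(path, sep="\t", index_label="patient_id", float_format=_FLOAT_FMT)


# -- plates and grids -------------------------------------------------------

def read_plate_tsv(path) -> pd.DataFrame:
    """Dose-response plate: dose, replicate, response (viability fraction)."""
    path = Path(path)
    df = _read_tsv(path, ["dose", "replicate", "response"])
    df = _to_float(df, ["dose", "replicate", "response"], path)
    if (df["dose"] <= 0).any():
        raise ValueError(f"{path}: doses must be strictly positive")
    return df.reset_index(drop=True)


def write_plate_tsv(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_grid_tsv(path) -> CombinationGrid:
    """Long-format combination grid: dose_a, dose_b, inhibition; must tile a
    full dose_a x dose_b grid including the dose-0 margins."""
    path = Path(path)
    df = _read_tsv(path, ["dose_a", "dose_b", "inhibition"])
    df = _to_float(df, ["dose_a", "dose_b", "inhibition"], path)
    pivot = df.pivot_table(index="dose_a", columns="dose_b", values="inhibition")
    if pivot.isna().any().any():
        raise ValueError(f"{path}: grid is not a complete dose_a x dose_b matrix")
    return CombinationGrid(pivot.index.to_numpy(), pivot.columns.to_numpy(),
                           pivot.to_numpy())


def write_grid_tsv(grid: CombinationGrid, path) -> None:
    rows = [(a, b, grid.inhibition[i, j])
            for i, a in enumerate(grid.doses_a)
            for j, b in enumerate(grid.doses_b)]
    pd.DataFrame(rows, columns=["dose_a", "dose_b", "inhibition"]) \
        .to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# -- gene sets --------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """GMT: one set per line, tab-separated set_id, description, members..."""
    path = Path(path)
    sets, seen = [], set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has < 3 fields")
            set_id, desc, *members = fields
            if set_id in seen:
                raise ValueError(f"{path}: duplicate set id '{set_id}' (line {lineno})")
            seen.add(set_id)
            sets.append(GeneSet(set_id, desc, tuple(members)))
    if not sets:
        raise ValueError(f"{path}: no data rows")
    return sets


def write_gmt(collection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.description, *gs.members]) + "\n")


# -- reports ----------------------------------------------------------------

def write_report(outdir, tables: dict) -> list[str]:
    """Write each named table as ``<name>.tsv`` plus a MANIFEST.tsv listing
    file names and row counts; returns the (sorted, deterministic) file list."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        fname = f"{name}.tsv"
        tables[name].to_csv(outdir / fname, sep="\t", index=False,
                            float_format=_FLOAT_FMT)
        written.append(fname)
    manifest = pd.DataFrame({"file": written,
                             "n_rows": [len(tables[Path(f).stem]) for f in written]})
    manifest.to_csv(outdir / "MANIFEST.tsv", sep="\t", index=False)
    return written + ["MANIFEST.tsv"]


# -- configuration ----------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and stage parameters of a full pipeline run (YAML-backed)."""

    expression: str = ""
    metadata: str = ""
    survival: str = ""
    annotations: str = ""
    outdir: str = "results"
    min_log2_fold: float = 2.0
    normal_aggregation: str = "per_tissue_mean"
    percentile: object = 0.78
    alpha: float = 0.05
    min_abs_r: float = 0.5
    correction: str = "benjamini_hochberg"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_abs_r < 0 or self.min_abs_r >= 1:
            raise ValueError("min_abs_r must lie in [0, 1)")


def load_config(path, **overrides) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)
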