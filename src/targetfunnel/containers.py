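"""Core in-memory containers shared across the pipeline.

Expression values are log2-scale throughout; linear-scale input is out of
contract. Containers validate their invariants on construction so that every
downstream stage can assume clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
SAMPLE_CLASSES = frozenset({TUMOR, NORMAL})


def _check_unique(index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample class/tissue labels.

    ``values`` is a DataFrame indexed by gene_id with sample_id columns;
    ``sample_class`` ('tumor'/'normal') and ``tissue`` are Series indexed by
    sample_id and must cover every column of ``values``.
    """

    values: pd.DataFrame
    sample_class: pd.Series
    tissue: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            bad = self.values.index[
                ~np.isfinite(self.values.to_numpy(dtype=float)).all(axis=1)
            ].tolist()
            raise ValueError(f"non-finite expression values for genes: {bad[:5]}")
        for name, series in (("sample_class", self.sample_class), ("tissue", self.tissue)):
            missing = self.values.columns.difference(series.index)
            if len(missing):
                raise ValueError(f"{name} missing for samples: {missing.tolist()[:5]}")
        self.sample_class = self.sample_class.reindex(self.values.columns)
        self.tissue = self.tissue.reindex(self.values.columns)
        unknown = set(self.sample_class.unique()) - SAMPLE_CLASSES
        if unknown:
            raise ValueError(f"unknown sample classes: {sorted(unknown)}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def tumor_samples(self) -> pd.Index:
        return self.values.columns[self.sample_class.to_numpy() == TUMOR]

    @property
    def normal_samples(self) -> pd.Index:
        return self.values.columns[self.sample_class.to_numpy() == NORMAL]

    def tumor_values(self) -> pd.DataFrame:
        return self.values[self.tumor_samples]

    def normal_values(self) -> pd.DataFrame:
        return self.values[self.normal_samples]


@dataclass
class SurvivalCohort:
    """Per-patient follow-up with optional expression and IRS covariates.

    ``table`` is indexed by patient_id with columns ``time`` (> 0) and
    ``event`` (bool; True = death observed). The generator may attach a
    latent ``true_event_time`` column (pre-censoring event time); readers and
    writers only contract on time/event. ``expression`` is genes x patients.
    """

    table: pd.DataFrame
    expression: pd.DataFrame | None = None
    irs: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "patient ids")
        for col in ("time", "event"):
            if col not in self.table.columns:
                raise ValueError(f"survival table missing column '{col}'")
        times = self.table["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("follow-up times must be finite and > 0")
        self.table = self.table.assign(event=self.table["event"].astype(bool))
        if self.expression is not None:
            missing = self.table.index.difference(self.expression.columns)
            if len(missing):
                raise ValueError(
                    f"expression missing for patients: {missing.tolist()[:5]}"
                )
            _check_unique(self.expression.index, "gene ids")
        if self.irs is not None:
            irs = self.irs.reindex(self.table.index)
            vals = irs.to_numpy(dtype=float)
            if np.any(np.isnan(vals)) or np.any((vals < 0) | (vals > 12)):
                raise ValueError("IRS values must cover all patients and lie in 0-12")
            self.irs = irs.astype(int)

    @property
    def patient_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=bool)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CombinationGrid:
    """Two-drug dose matrix of observed inhibition fractions.

    ``inhibition[i, j]`` is the fraction affected at (doses_a[i], doses_b[j]).
    Both dose vectors must include 0 so the margins carry the single-agent
    curves; the (0, 0) cell is the untreated control.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if d.ndim != 1 or d.size < 2:
                raise ValueError(f"{name} must be a 1-d vector with >= 2 doses")
            if d[0] != 0.0:
                raise ValueError(f"{name} must start with the dose-0 margin")
            if np.any(np.diff(d) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.inhibition.shape != (self.doses_a.size, self.doses_b.size):
            raise ValueError("inhibition shape must be (len(doses_a), len(doses_b))")
        if np.any(~np.isfinite(self.inhibition)):
            raise ValueError("inhibition values must be finite")
        if np.any((self.inhibition < 0) | (self.inhibition > 1)):
            raise ValueError("inhibition fractions must lie in [0, 1]")

    def transpose(self) -> "CombinationGrid":
        return CombinationGrid(self.doses_b.copy(), self.doses_a.copy(), self.inhibition.T.copy())


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT semantics: id, free-text description, members)."""

    set_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set '{self.set_id}' is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set '{self.set_id}' has duplicate members")
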