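"""Tabular I/O and schema validation for the pipeline's CSV interfaces.

All tables are comma-separated UTF-8 with a header row; scientific notation
is accepted on read. Validation reports issues with row/column context
rather than raising on first error, so malformed files are diagnosable in
one pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CQ_COLUMNS
from .fitness import COMPETITION_COLUMNS
from .fluctuation import FLUCTUATION_COLUMNS, FluctuationDataset
from .spectrum import MUTATION_COLUMNS

__all__ = [
    "SCHEMAS",
    "ValidationIssue",
    "validate_table",
    "read_fluctuation_csv",
    "write_fluctuation_csv",
]

SCHEMAS = {
    "fluctuation": FLUCTUATION_COLUMNS,
    "competition": COMPETITION_COLUMNS,
    "cq": CQ_COLUMNS,
    "mutation": MUTATION_COLUMNS,
}

_NUMERIC = {
    "fluctuation": [
        "n_initial",
        "n_final",
        "plated_fraction_selective",
        "candidate_colonies",
        "n_sequenced",
        "n_confirmed_target",
        "n_confirmed_other",
    ],
    "competition": [
        "counts_focal_t0",
        "counts_ref_t0",
        "counts_focal_t",
        "counts_ref_t",
        "generations",
    ],
    "cq": ["biological_rep", "technical_rep", "cq_target", "cq_reference"],
    "mutation": ["gene_position"],
}


@dataclass
class ValidationIssue:
    row: int | None  # 0-based data row; None for table-level issues
    column: str | None
    message: str

    def __str__(self) -> str:
        where = []
        if self.row is not None:
            where.append(f"row {self.row}")
        if self.column is not None:
            where.append(f"column {self.column!r}")
        prefix = " ".join(where)
        return f"{prefix}: {self.message}" if prefix else self.message


def _rows_where(mask: pd.Series) -> list[int]:
    return [int(i) for i in np.flatnonzero(np.asarray(mask))]


def validate_table(source, schema_name: str) -> list[ValidationIssue]:
    """Validate a CSV file (or DataFrame) against a named table schema.

    Checks column presence, numeric parsability, and the schema's own
    invariants (count orderings, value ranges). Returns a machine-readable
    issue list; an empty list means the table is well formed.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    if isinstance(source, pd.DataFrame):
        table = source
    else:
        table = pd.read_csv(source)
    issues: list[ValidationIssue] = []
    for col in SCHEMAS[schema_name]:
        if col not in table.columns:
            issues.append(ValidationIssue(None, col, "missing column"))
    if issues:
        return issues
    for col in _NUMERIC[schema_name]:
        coerced = pd.to_numeric(table[col], errors="coerce")
        for row in _rows_where(coerced.isna() & table[col].notna()):
            issues.append(ValidationIssue(row, col, "not numeric"))
        table = table.assign(**{col: coerced})
    if issues:
        return issues

    if schema_name == "fluctuation":
        for row in _rows_where(table["n_final"] <= 0):
            issues.append(ValidationIssue(row, "n_final", "must be positive"))
        eps = table["plated_fraction_selective"]
        for row in _rows_where((eps <= 0) | (eps > 1)):
            issues.append(
                ValidationIssue(row, "plated_fraction_selective", "must be in (0, 1]")
            )
        confirmed = table["n_confirmed_target"] + table["n_confirmed_other"]
        for row in _rows_where(confirmed > table["n_sequenced"]):
            issues.append(
                ValidationIssue(
                    row, "n_confirmed_target", "confirmed exceeds n_sequenced"
                )
            )
        nonzero = table["candidate_colonies"] > 0
        for row in _rows_where(
            nonzero & (table["n_sequenced"] > table["candidate_colonies"])
        ):
            issues.append(
                ValidationIssue(row, "n_sequenced", "exceeds candidate_colonies")
            )
        for row in _rows_where(table["candidate_colonies"] < 0):
            issues.append(ValidationIssue(row, "candidate_colonies", "negative count"))
    elif schema_name == "competition":
        for col in _NUMERIC["competition"][:4]:
            for row in _rows_where(table[col] < 0):
                issues.append(ValidationIssue(row, col, "negative count"))
        for row in _rows_where(table["generations"] <= 0):
            issues.append(ValidationIssue(row, "generations", "must be positive"))
    elif schema_name == "cq":
        for col in ("cq_target", "cq_reference"):
            bad = ~np.isfinite(table[col].to_numpy(float)) | (table[col] <= 0)
            for row in _rows_where(pd.Series(bad)):
                issues.append(ValidationIssue(row, col, "must be finite and positive"))
    elif schema_name == "mutation":
        for row in _rows_where(table["gene_position"] < 1):
            issues.append(ValidationIssue(row, "gene_position", "must be >= 1"))
        points = table["mutation_class"] == "point"
        for row in _rows_where(points & (table["ref_base"] == table["alt_base"])):
            issues.append(
                ValidationIssue(row, "alt_base", "point mutation must change the base")
            )
    return issues


def read_fluctuation_csv(path) -> FluctuationDataset:
    """Read a fluctuation CSV, validating it on the way in."""
    issues = validate_table(path, "fluctuation")
    if issues:
        detail = "; ".join(str(i) for i in issues[:5])
        raise ValueError(f"invalid fluctuation table {path}: {detail}")
    table = pd.read_csv(Path(path))
    genotype = str(table["genotype"].iloc[0])
    return FluctuationDataset(genotype=genotype, table=table)


def write_fluctuation_csv(dataset: FluctuationDataset, path) -> None:
    """Write a fluctuation dataset as CSV (ground-truth sidecar separate)."""
    dataset.table.to_csv(Path(path), index=False)
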