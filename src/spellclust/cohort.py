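"""Cohort tables of longitudinal binary wheeze indicators.

A cohort is a wide table: one row per subject, one column per follow-up
epoch, each cell recording current wheeze (1), no wheeze (0) or missing.
Epochs are harmonized follow-up windows (e.g. infancy 0.5-1 yr) shared
across cohorts; the :class:`EpochGrid` carries their labels, age ranges and
the numeric encoding used for age-valued derived variables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import CohortFormatError, ValidationError

__all__ = [
    "EpochGrid",
    "WheezeRecord",
    "CohortTable",
    "DEFAULT_GRID",
    "read_cohort_csv",
    "write_cohort_csv",
    "filter_by_observed",
]

#: Missing cells are emitted as this token and recognised on input
#: alongside the empty string.
MISSING_TOKEN = "NA"


@dataclass(frozen=True)
class EpochGrid:
    """Ordered follow-up epochs with an age encoding.

    Parameters
    ----------
    labels
        Epoch names, e.g. ``("infancy", ..., "adolescence")``.
    age_ranges
        ``(low, high)`` age bounds in years per epoch; strictly increasing
        and non-overlapping.
    encoding_mode
        ``"ordinal"`` encodes epochs as 1..T (equal spacing, order only);
        ``"midpoint"`` uses the midpoint age of each range in years.
    """

    labels: tuple[str, ...]
    age_ranges: tuple[tuple[float, float], ...]
    encoding_mode: str = "ordinal"

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValidationError("an epoch grid needs at least 2 epochs")
        if len(self.age_ranges) != len(self.labels):
            raise ValidationError("labels and age_ranges must align")
        for lo, hi in self.age_ranges:
            if not lo < hi:
                raise ValidationError(f"degenerate age range ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(self.age_ranges, self.age_ranges[1:]):
            if not hi < lo2:
                raise ValidationError("age ranges must be increasing and non-overlapping")
        if self.encoding_mode not in ("ordinal", "midpoint"):
            raise ValidationError(f"unknown encoding_mode {self.encoding_mode!r}")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def encoded_ages(self) -> np.ndarray:
        """Numeric value per epoch under the chosen encoding; strictly increasing."""
        if self.encoding_mode == "ordinal":
            return np.arange(1, self.n_epochs + 1, dtype=float)
        return np.array([(lo + hi) / 2.0 for lo, hi in self.age_ranges])

    def with_encoding(self, encoding_mode: str) -> "EpochGrid":
        return replace(self, encoding_mode=encoding_mode)


#: The pooled five-epoch grid: infancy (0.5-1 yr), early childhood (2-3 yr),
#: preschool to early school (4-5 yr), middle childhood (8-10 yr) and
#: adolescence (14-18 yr).
DEFAULT_GRID = EpochGrid(
    labels=(
        "infancy",
        "early_childhood",
        "preschool",
        "mid_childhood",
        "adolescence",
    ),
    age_ranges=((0.5, 1.0), (2.0, 3.0), (4.0, 5.0), (8.0, 10.0), (14.0, 18.0)),
)


@dataclass(frozen=True)
class WheezeRecord:
    """One subject's wheeze indicators over the grid (NaN = missing)."""

    subject_id: str
    observed: tuple[float, ...]

    def __post_init__(self) -> None:
        for v in self.observed:
            if not (np.isnan(v) or v in (0.0, 1.0)):
                raise ValidationError(
                    f"subject {self.subject_id}: value {v!r} outside {{0, 1, missing}}"
                )


@dataclass
class CohortTable:
    """Wide cohort table: ``data`` is (n_subjects, T) float with NaN for missing."""

    grid: EpochGrid
    subject_ids: list[str]
    data: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape != (len(self.subject_ids), self.grid.n_epochs):
            raise ValidationError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.subject_ids)} subjects x {self.grid.n_epochs} epochs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            dupes = pd.Series(self.subject_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate subject ids: {dupes}")
        vals = self.data[~np.isnan(self.data)]
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError("cohort values must be 0, 1 or missing")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_epochs(self) -> int:
        return self.grid.n_epochs

    def observed_counts(self) -> np.ndarray:
        """Number of non-missing epochs per subject."""
        return (~np.isnan(self.data)).sum(axis=1)

    def complete_mask(self) -> np.ndarray:
        """Boolean mask of subjects with no missing epoch."""
        return ~np.isnan(self.data).any(axis=1)

    def records(self) -> list[WheezeRecord]:
        return [
            WheezeRecord(sid, tuple(row))
            for sid, row in zip(self.subject_ids, self.data)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"w{t + 1}" for t in range(self.n_epochs)]
        df = pd.DataFrame(self.data, columns=cols)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def copy(self) -> "CohortTable":
        return CohortTable(self.grid, list(self.subject_ids), self.data.copy(), self.name)


def _parse_cell(raw: str, row: int, column: str, missing_tokens: tuple[str, ...]) -> float:
    token = raw.strip()
    if token in missing_tokens:
        return np.nan
    if token == "0":
        return 0.0
    if token == "1":
        return 1.0
    raise CohortFormatError(
        f"row {row}, column {column!r}: cannot parse {raw!r} as 0/1/missing"
    )


def read_cohort_csv(
    path,
    grid: EpochGrid = DEFAULT_GRID,
    missing_tokens: tuple[str, ...] = (MISSING_TOKEN, ""),
    name: str = "",
) -> CohortTable:
    """Read a wide cohort CSV (``subject_id, w1..wT``) against a grid.

    Cells must parse to 0, 1 or a configured missing token; anything else
    raises :class:`CohortFormatError` naming the offending row and column.
    """
    T = grid.n_epochs
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: empty file, expected a header row")
        if len(header) != T + 1:
            raise CohortFormatError(
                f"{path}: expected 1 id column + {T} epoch columns, got {len(header)}"
            )
        epoch_cols = header[1:]
        ids: list[str] = []
        rows: list[list[float]] = []
        for i, rec in enumerate(reader, start=1):
            if len(rec) != T + 1:
                raise CohortFormatError(f"row {i}: expected {T + 1} fields, got {len(rec)}")
            ids.append(rec[0])
            rows.append(
                [_parse_cell(v, i, c, missing_tokens) for v, c in zip(rec[1:], epoch_cols)]
            )
    data = np.array(rows, dtype=float) if rows else np.empty((0, T))
    return CohortTable(grid=grid, subject_ids=ids, data=data, name=name or str(path))


def write_cohort_csv(table: CohortTable, path) -> str:
    """Write a cohort table; missing cells are emitted as ``NA``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id"] + [f"w{t + 1}" for t in range(table.n_epochs)])
        for sid, row in zip(table.subject_ids, table.data):
            writer.writerow(
                [sid] + [MISSING_TOKEN if np.isnan(v) else str(int(v)) for v in row]
            )
    return str(path)


def filter_by_observed(
    table: CohortTable, min_observed: int = 0, require_complete: bool = False
) -> CohortTable:
    """Keep subjects with enough observed epochs, preserving order.

    With ``require_complete`` only fully observed subjects are kept (the
    complete-case analysis set); otherwise subjects with at least
    ``min_observed`` non-missing epochs are kept (e.g. the at-least-two-
    observations set that feeds the multiple-imputation pipeline).
    """
    if not 0 <= min_observed <= table.n_epochs:
        raise ValidationError(f"min_observed must be in [0, {table.n_epochs}]")
    if require_complete:
        keep = table.complete_mask()
    else:
        keep = table.observed_counts() >= min_observed
    return CohortTable(
        grid=table.grid,
        subject_ids=[s for s, k in zip(table.subject_ids, keep) if k],
        data=table.data[keep],
        name=table.name,
    )
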