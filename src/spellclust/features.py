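"""Spell variables derived from complete binary wheeze sequences.

A *spell* is a maximal run of consecutive epochs with reported wheeze. Each
complete sequence is transformed into six variables:

1. age of the first wheeze episode,
2. age of the last recorded episode,
3. total number of wheeze records,
4. duration of the longest spell (consecutive records),
5. total number of separate spells,
6. spell type: 0 = no wheeze, 1 = a single spell, 2 = intermittent
   (at least two non-consecutive spells of any length).

Ages use the grid's encoding (ordinal epoch index or midpoint years); a
subject who never wheezes has no first/last age, recorded as missing rather
than a sentinel value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import DEFAULT_GRID, CohortTable, EpochGrid
from .exceptions import CoverageError, ValidationError

__all__ = [
    "SpellFeatureVector",
    "FeatureTable",
    "FEATURE_COLUMNS",
    "derive_features",
    "derive_feature_table",
    "enumerate_sequences",
    "sequence_audit",
]

FEATURE_COLUMNS = (
    "first_age",
    "last_age",
    "n_records",
    "longest_spell",
    "n_spells",
    "spell_type",
)


@dataclass(frozen=True)
class SpellFeatureVector:
    """The six spell variables for one subject (ages NaN for never-wheezers)."""

    first_age: float
    last_age: float
    n_records: int
    longest_spell: int
    n_spells: int
    spell_type: int

    def as_tuple(self) -> tuple:
        return (
            self.first_age,
            self.last_age,
            self.n_records,
            self.longest_spell,
            self.n_spells,
            self.spell_type,
        )


def _spell_lengths(seq: np.ndarray) -> list[int]:
    lengths, run = [], 0
    for v in seq:
        if v == 1:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths


def derive_features(sequence: Sequence[float], grid: EpochGrid = DEFAULT_GRID) -> SpellFeatureVector:
    """Derive the six spell variables from one complete binary sequence.

    Pure and deterministic: identical sequences always yield identical
    vectors, which is what makes spell-based cluster assignment consistent
    across subjects sharing a wheeze pattern.
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.shape != (grid.n_epochs,):
        raise ValidationError(f"sequence length {seq.size} != {grid.n_epochs} epochs")
    if np.isnan(seq).any():
        raise ValidationError("sequence has missing entries; impute before deriving features")
    if not np.isin(seq, (0.0, 1.0)).all():
        raise ValidationError("sequence values must be 0 or 1")

    ages = grid.encoded_ages
    idx = np.flatnonzero(seq == 1.0)
    lengths = _spell_lengths(seq)
    n_spells = len(lengths)
    return SpellFeatureVector(
        first_age=float(ages[idx[0]]) if idx.size else np.nan,
        last_age=float(ages[idx[-1]]) if idx.size else np.nan,
        n_records=int(idx.size),
        longest_spell=max(lengths) if lengths else 0,
        n_spells=n_spells,
        spell_type=0 if n_spells == 0 else (1 if n_spells == 1 else 2),
    )


@dataclass
class FeatureTable:
    """Spell features for a cohort; ``data`` columns follow FEATURE_COLUMNS."""

    subject_ids: list[str]
    data: pd.DataFrame
    grid: EpochGrid

    def __post_init__(self) -> None:
        if tuple(self.data.columns) != FEATURE_COLUMNS:
            raise ValidationError(f"feature columns must be {FEATURE_COLUMNS}")
        if len(self.data) != len(self.subject_ids):
            raise ValidationError("subject_ids and data misaligned")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def vectors(self) -> list[SpellFeatureVector]:
        return [SpellFeatureVector(*row) for row in self.data.itertuples(index=False)]


def derive_feature_table(table: CohortTable) -> FeatureTable:
    """Derive features for every subject of a complete cohort table."""
    if not table.complete_mask().all():
        raise ValidationError(
            "cohort has missing entries; run imputation or complete-case filtering first"
        )
    rows = [derive_features(row, table.grid).as_tuple() for row in table.data]
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    return FeatureTable(subject_ids=list(table.subject_ids), data=df, grid=table.grid)


def enumerate_sequences(T: int) -> list[tuple[int, ...]]:
    """All 2^T complete binary sequences of length T, lexicographically."""
    if T < 1:
        raise ValidationError("T must be >= 1")
    return list(itertools.product((0, 1), repeat=T))


def sequence_audit(
    assigner: Callable[[list[tuple[int, ...]]], Sequence],
    T: int,
    repeats: int = 2,
) -> tuple[pd.DataFrame, bool]:
    """Audit whether an assigner maps each sequence to a single cluster.

    ``assigner`` receives a batch of complete sequences (each of the 2^T
    sequences appears ``repeats`` times) and returns one cluster label per
    entry. The consistency flag is True iff every occurrence of a sequence
    received the same label — guaranteed for any deterministic function of
    the sequence (e.g. spell features + nearest medoid), but violated by
    per-subject stochastic allocation.
    """
    seqs = enumerate_sequences(T)
    batch = [s for s in seqs for _ in range(repeats)]
    labels = list(assigner(batch))
    if len(labels) != len(batch) or any(l is None for l in labels):
        raise CoverageError(
            f"assigner must return one label per sequence ({len(batch)} expected)"
        )
    rows = []
    consistent = True
    for j, s in enumerate(seqs):
        got = labels[j * repeats : (j + 1) * repeats]
        uniform = len(set(got)) == 1
        consistent &= uniform
        rows.append(
            {
                "sequence": "".join(str(v) for v in s),
                "cluster": got[0],
                "consistent": uniform,
            }
        )
    return pd.DataFrame(rows), bool(consistent)
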