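"""Long-format best-worst response data: containers, validation, I/O.

Each answered choice scenario contributes one record: the respondent, the
block (choice set) answered, and the items picked as most and least
influential.  The maximum-difference likelihood operates on ordered
(best, worst) pairs, so :func:`expand_pairs` enumerates, per record, the
k(k-1) candidate ordered pairs of the block and flags the chosen one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .design import BWSDesign, DesignError

__all__ = [
    "ChoiceRecord",
    "ChoiceDataset",
    "PairExpansion",
    "ChoiceDataError",
    "read_choices",
    "write_choices",
    "expand_pairs",
]

CSV_COLUMNS = ("respondent", "block", "best", "worst")


class ChoiceDataError(ValueError):
    """Raised for malformed or inconsistent response data."""


@dataclass(frozen=True)
class ChoiceRecord:
    """One answered scenario: ``block_id`` is 1-based, matching design CSVs."""

    respondent_id: str
    block_id: int
    best: str
    worst: str


@dataclass(frozen=True)
class ChoiceDataset:
    """Validated responses tied to the design they were collected under."""

    design: BWSDesign
    records: tuple[ChoiceRecord, ...]

    def __init__(self, design: BWSDesign, records: Iterable[ChoiceRecord]):
        records = tuple(records)
        seen: set[tuple[str, int]] = set()
        for idx, rec in enumerate(records):
            _validate_record(design, rec, where=f"record {idx}")
            key = (rec.respondent_id, rec.block_id)
            if key in seen:
                raise ChoiceDataError(
                    f"record {idx}: duplicate (respondent, block) = {key}")
            seen.add(key)
        object.__setattr__(self, "design", design)
        object.__setattr__(self, "records", records)

    @property
    def n_tasks(self) -> int:
        return len(self.records)

    @property
    def n_respondents(self) -> int:
        return len({r.respondent_id for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.respondent_id, r.block_id, r.best, r.worst) for r in self.records],
            columns=list(CSV_COLUMNS),
        )


@dataclass(frozen=True)
class PairExpansion:
    """Per record: chosen (best, worst) index pair and the block's full
    candidate ordered-pair space (k(k-1) pairs per record)."""

    design: BWSDesign
    chosen: tuple[tuple[int, int], ...]       # item indices
    block_of: tuple[int, ...]                 # 0-based block index per record

    def candidates(self, rec: int) -> list[tuple[int, int]]:
        blk = self.design.blocks[self.block_of[rec]]
        return [(a, b) for a in blk for b in blk if a != b]

    @property
    def n_records(self) -> int:
        return len(self.chosen)


def _validate_record(design: BWSDesign, rec: ChoiceRecord, where: str) -> None:
    if not 1 <= rec.block_id <= design.b:
        raise ChoiceDataError(
            f"{where}: unknown block id {rec.block_id} (design has "
            f"{design.b} blocks numbered 1..{design.b})")
    if rec.best == rec.worst:
        raise ChoiceDataError(
            f"{where}: best and worst are both {rec.best!r}")
    block_items = set(design.block_labels(rec.block_id - 1))
    for role, label in (("best", rec.best), ("worst", rec.worst)):
        try:
            design.item_set.index(label)
        except DesignError:
            raise ChoiceDataError(
                f"{where}: unknown item label {label!r}") from None
        if label not in block_items:
            raise ChoiceDataError(
                f"{where}: {role} item {label!r} is not in block {rec.block_id}")


def read_choices(path, design: BWSDesign) -> ChoiceDataset:
    """Read a ``respondent,block,best,worst`` CSV, validating every row.

    Errors name the offending file row (header = row 1).
    """
    df = pd.read_csv(path, dtype={"respondent": str, "best": str, "worst": str})
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ChoiceDataError(f"responses CSV missing columns: {sorted(missing)}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False)):
        rec = ChoiceRecord(str(row.respondent), int(row.block),
                           str(row.best), str(row.worst))
        _validate_record(design, rec, where=f"row {pos + 2}")
        records.append(rec)
    return ChoiceDataset(design, records)


def write_choices(dataset: ChoiceDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def expand_pairs(dataset: ChoiceDataset) -> PairExpansion:
    """Expand each record into its ordered best-worst pair space."""
    items = dataset.design.item_set
    chosen = []
    block_of = []
    for rec in dataset.records:
        chosen.append((items.index(rec.best), items.index(rec.worst)))
        block_of.append(rec.block_id - 1)
    return PairExpansion(dataset.design, tuple(chosen), tuple(block_of))
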