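"""Expression dataset model: sequences, outcomes, and A/C/N categorisation.

A cell-free expression experiment scores every target protein into one of
three mutually exclusive categories:

* ``A`` — soluble product above the yield threshold (default 0.1 mg per ml
  of extract),
* ``C`` — expressed at full length but insoluble (or soluble below
  threshold),
* ``N`` — not expressed, or expressed at a lower-than-expected molecular
  size (truncated products cannot attain native structure and are scored
  as non-expressed).

This module owns sequence validation, the categorisation rule, and the
FASTA/TSV round trip for whole datasets.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "STANDARD_RESIDUES",
    "SequenceError",
    "DatasetError",
    "AminoAcidSequence",
    "ExpressionCategory",
    "ExpressionOutcome",
    "CategorizationConfig",
    "ExpressionRecord",
    "ExpressionDataset",
    "validate_sequence",
    "assign_category",
    "read_dataset",
    "write_dataset",
]


class SequenceError(ValueError):
    """Raised for empty sequences or non-standard residue codes."""


class DatasetError(ValueError):
    """Raised for malformed outcome tables or id mismatches."""


@dataclass(frozen=True)
class AminoAcidSequence:
    """A validated protein sequence over the 20 standard one-letter codes."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def validate_sequence(id: str, raw: str) -> AminoAcidSequence:
    """Canonicalise *raw* to uppercase and reject non-standard residues.

    Ambiguity codes (B, Z, X), selenocysteine (U), stops (``*``) and gap
    characters are rejected rather than silently mapped: the downstream
    feature scales are undefined for them.  The error names the 1-based
    offending position.
    """
    if not id:
        raise SequenceError("sequence id must be non-empty")
    residues = "".join(raw.split()).upper()
    if not residues:
        raise SequenceError(f"{id}: empty sequence")
    for pos, ch in enumerate(residues, start=1):
        if ch not in STANDARD_RESIDUES:
            raise SequenceError(
                f"{id}: non-standard residue {ch!r} at position {pos}"
            )
    return AminoAcidSequence(id=id, residues=residues)


class ExpressionCategory(str, enum.Enum):
    """Mutually exclusive expression score."""

    SOLUBLE = "A"
    INSOLUBLE = "C"
    NON_EXPRESSED = "N"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ExpressionOutcome:
    """Raw experimental outcome for one target.

    soluble_yield is in mg of product per ml of extract.  A non-expressed
    target must not report a yield at or above the soluble threshold.
    """

    expressed: bool
    soluble_yield: float
    full_length: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.soluble_yield) or self.soluble_yield < 0:
            raise DatasetError(
                f"soluble_yield must be finite and >= 0, got {self.soluble_yield}"
            )


@dataclass(frozen=True)
class CategorizationConfig:
    """Threshold separating soluble (A) from below-detection yields."""

    yield_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (self.yield_threshold > 0):
            raise DatasetError("yield_threshold must be strictly positive")


DEFAULT_CATEGORIZATION = CategorizationConfig()


def assign_category(
    outcome: ExpressionOutcome,
    cfg: CategorizationConfig = DEFAULT_CATEGORIZATION,
) -> ExpressionCategory:
    """Score an outcome as A, C or N.

    A: expressed, full length, soluble yield strictly above the threshold.
    C: expressed, full length, soluble yield at or below the threshold
    (a yield of exactly the threshold is C — the soluble class requires
    *more than* the threshold).
    N: not expressed, or truncated (below expected molecular size).
    """
    if not outcome.expressed and outcome.soluble_yield >= cfg.yield_threshold:
        raise DatasetError(
            "non-expressed outcome reports soluble yield at or above threshold"
        )
    if not outcome.expressed or not outcome.full_length:
        return ExpressionCategory.NON_EXPRESSED
    if outcome.soluble_yield > cfg.yield_threshold:
        return ExpressionCategory.SOLUBLE
    return ExpressionCategory.INSOLUBLE


@dataclass(frozen=True)
class ExpressionRecord:
    """One sequence with its (optional) outcome and assigned category."""

    sequence: AminoAcidSequence
    category: ExpressionCategory
    outcome: Optional[ExpressionOutcome] = None

    @property
    def id(self) -> str:
        return self.sequence.id


@dataclass
class ExpressionDataset:
    """Ordered collection of expression records with unique ids."""

    records: list[ExpressionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise DatasetError("dataset must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DatasetError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExpressionRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def sequences(self) -> list[AminoAcidSequence]:
        return [rec.sequence for rec in self.records]

    def categories(self) -> list[str]:
        return [rec.category.value for rec in self.records]

    def category_counts(self) -> dict[str, int]:
        counts = {"A": 0, "C": 0, "N": 0}
        for rec in self.records:
            counts[rec.category.value] += 1
        return counts


_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n"}


def _parse_flag(token: str, line_no: int, column: str) -> bool:
    low = token.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise DatasetError(f"line {line_no}: bad boolean {token!r} in column {column}")


def _read_outcome_table(
    path: Path,
) -> tuple[dict[str, ExpressionOutcome], dict[str, ExpressionCategory]]:
    """Parse the outcome TSV.

    Two schemas are accepted: ``id, expressed, soluble_yield, full_length``
    (outcomes, category derived) or ``id, category`` (pre-assigned scores
    taken verbatim).
    """
    outcomes: dict[str, ExpressionOutcome] = {}
    categories: dict[str, ExpressionCategory] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetError(f"{path}: empty outcome table") from None
        header = [h.strip().lower() for h in header]
        if header == ["id", "expressed", "soluble_yield", "full_length"]:
            schema = "outcome"
        elif header == ["id", "category"]:
            schema = "category"
        else:
            raise DatasetError(
                f"{path}: unrecognised header {header!r}; expected "
                "'id expressed soluble_yield full_length' or 'id category'"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if schema == "outcome":
                if len(row) != 4:
                    raise DatasetError(
                        f"line {line_no}: expected 4 columns, got {len(row)}"
                    )
                rec_id = row[0].strip()
                try:
                    yield_val = float(row[2])
                except ValueError:
                    raise DatasetError(
                        f"line {line_no}: non-numeric soluble_yield {row[2]!r}"
                    ) from None
                outcome = ExpressionOutcome(
                    expressed=_parse_flag(row[1], line_no, "expressed"),
                    soluble_yield=yield_val,
                    full_length=_parse_flag(row[3], line_no, "full_length"),
                )
                if rec_id in outcomes:
                    raise DatasetError(f"line {line_no}: duplicate id {rec_id!r}")
                outcomes[rec_id] = outcome
            else:
                if len(row) != 2:
                    raise DatasetError(
                        f"line {line_no}: expected 2 columns, got {len(row)}"
                    )
                rec_id = row[0].strip()
                token = row[1].strip().upper()
                if token not in ("A", "C", "N"):
                    raise DatasetError(
                        f"line {line_no}: unknown category {row[1]!r}"
                    )
                if rec_id in categories:
                    raise DatasetError(f"line {line_no}: duplicate id {rec_id!r}")
                categories[rec_id] = ExpressionCategory(token)
    return outcomes, categories


def read_dataset(
    fasta_path: str | Path,
    outcomes_path: str | Path,
    cfg: CategorizationConfig = DEFAULT_CATEGORIZATION,
    drop_invalid: bool = False,
) -> ExpressionDataset:
    """Join a FASTA file with its outcome table into a dataset.

    Record order follows the FASTA file.  Every FASTA id must have an
    outcome row and vice versa; orphans on either side raise a
    :class:`DatasetError` listing them.  With ``drop_invalid`` sequences
    failing validation are skipped (with their outcome rows) instead of
    aborting the load.
    """
    fasta_path = Path(fasta_path)
    outcomes_path = Path(outcomes_path)
    outcomes, categories = _read_outcome_table(outcomes_path)
    by_outcome = outcomes if outcomes else categories

    sequences: list[AminoAcidSequence] = []
    seen: set[str] = set()
    dropped: list[str] = []
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        if entry.id in seen:
            raise DatasetError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        try:
            sequences.append(validate_sequence(entry.id, str(entry.seq)))
        except SequenceError:
            if drop_invalid:
                dropped.append(entry.id)
                continue
            raise
    if not sequences:
        raise DatasetError(f"{fasta_path}: no usable FASTA entries")

    fasta_ids = {s.id for s in sequences}
    missing_outcomes = [s.id for s in sequences if s.id not in by_outcome]
    orphan_rows = [i for i in by_outcome if i not in fasta_ids and i not in dropped]
    if missing_outcomes or orphan_rows:
        raise DatasetError(
            "id mismatch between FASTA and outcome table; "
            f"FASTA ids without outcome: {missing_outcomes[:10]}; "
            f"outcome rows without FASTA: {orphan_rows[:10]}"
        )

    records = []
    for seq in sequences:
        if outcomes:
            outcome = outcomes[seq.id]
            records.append(
                ExpressionRecord(
                    sequence=seq,
                    outcome=outcome,
                    category=assign_category(outcome, cfg),
                )
            )
        else:
            records.append(
                ExpressionRecord(sequence=seq, category=categories[seq.id])
            )
    return ExpressionDataset(records=records)


def write_dataset(
    dataset: ExpressionDataset,
    fasta_path: str | Path,
    outcomes_path: str | Path,
) -> None:
    """Write the FASTA + outcome TSV pair (inverse of :func:`read_dataset`)."""
    entries = [
        SeqRecord(Seq(rec.sequence.residues), id=rec.id, description="")
        for rec in dataset
    ]
    SeqIO.write(entries, str(fasta_path), "fasta")
    with open(outcomes_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if all(rec.outcome is not None for rec in dataset):
            writer.writerow(["id", "expressed", "soluble_yield", "full_length"])
            for rec in dataset:
                out = rec.outcome
                assert out is not None
                writer.writerow(
                    [
                        rec.id,
                        int(out.expressed),
                        f"{out.soluble_yield:.6g}",
                        int(out.full_length),
                    ]
                )
        else:
            writer.writerow(["id", "category"])
            for rec in dataset:
                writer.writerow([rec.id, rec.category.value])


def export_summary(dataset: ExpressionDataset, path: str | Path) -> None:
    """Export ``id, length, category`` per record."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "length", "category"])
        for rec in dataset:
            writer.writerow([rec.id, len(rec.sequence), rec.category.value])
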