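"""Reading, validating, deduplicating and splitting multi-round SELEX pools.

A pool is an ordered collection of candidate aptamer sequences with
``R<round>#<clone>`` identifiers, as produced by listing the most frequent
clones of each selection round.  The module enforces the study's data-set
conventions: ~40-nt sequences, cross-round duplicates resolved in favour of
the highest (most selected) round, and removal of records whose predicted
secondary structure has no base pairs.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .folding import SecondaryStructure

logger = logging.getLogger(__name__)

#: Nominal sequence length and tolerance ("40 bases with a tolerance of two").
NOMINAL_LENGTH = 40
LENGTH_TOLERANCE = 2

_ID_RE = re.compile(r"^R(\d+)#(\S+)$")
_VALID = set("ACGT")


class PoolError(ValueError):
    """Raised for malformed pool files or invalid records."""


@dataclass(frozen=True)
class SequenceRecord:
    """One candidate aptamer: selection round, clone identifier, DNA string."""

    round_index: int
    clone_id: str
    sequence: str

    @property
    def key(self) -> str:
        """Canonical identifier, e.g. ``R10#86``."""
        return f"R{self.round_index}#{self.clone_id}"


@dataclass
class Pool:
    """Ordered collection of :class:`SequenceRecord`."""

    records: list[SequenceRecord] = field(default_factory=list)

    @property
    def rounds_present(self) -> set[int]:
        return {r.round_index for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_round(self, round_index: int) -> list[SequenceRecord]:
        return [r for r in self.records if r.round_index == round_index]


@dataclass
class LabeledSet:
    """Records with class labels: 1 = low affinity (round 1), 2 = high (round 10)."""

    records: list[SequenceRecord]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise PoolError("records and labels differ in length")
        bad = set(self.labels) - {1, 2}
        if bad:
            raise PoolError(f"labels must be 1 or 2, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)


def _validate_sequence(raw: str, where: str, strict_length: bool = True) -> str:
    seq = raw.strip().upper()
    if "U" in seq:
        logger.warning("%s: U transliterated to T (DNA pool)", where)
        seq = seq.replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise PoolError(f"{where}: non-ACGT character(s) {sorted(bad)}")
    if strict_length and abs(len(seq) - NOMINAL_LENGTH) > LENGTH_TOLERANCE:
        raise PoolError(
            f"{where}: length {len(seq)} outside "
            f"{NOMINAL_LENGTH}±{LENGTH_TOLERANCE} (disable strict_length to allow)"
        )
    return seq


def _parse_id(token: str, where: str) -> tuple[int, str]:
    m = _ID_RE.match(token.strip())
    if not m:
        raise PoolError(f"{where}: malformed identifier {token!r} (expected R<round>#<clone>)")
    return int(m.group(1)), m.group(2)


def parse_pool(path: str | Path, format: str = "fasta", strict_length: bool = True) -> Pool:
    """Read a pool file into a :class:`Pool`, preserving input order.

    Parameters
    ----------
    path:
        FASTA file with ``>R<round>#<clone>`` headers, or a 2-column TSV
        (identifier, sequence; a header row is tolerated).
    format:
        ``"fasta"`` (canonical) or ``"tsv"``.
    strict_length:
        Enforce the 40±2-nt length rule (default on).
    """
    path = Path(path)
    if not path.exists():
        raise PoolError(f"pool file not found: {path}")
    records: list[SequenceRecord] = []
    if format == "fasta":
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
            where = f"{path.name} record {i} ({rec.id})"
            rnd, clone = _parse_id(rec.id, where)
            seq = _validate_sequence(str(rec.seq), where, strict_length)
            records.append(SequenceRecord(rnd, clone, seq))
    elif format == "tsv":
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or row[0].startswith("#"):
                    continue
                if i == 1 and not _ID_RE.match(row[0].strip()):
                    continue  # header row
                if len(row) < 2:
                    raise PoolError(f"{path.name} line {i}: expected 2 columns")
                where = f"{path.name} line {i}"
                rnd, clone = _parse_id(row[0], where)
                seq = _validate_sequence(row[1], where, strict_length)
                records.append(SequenceRecord(rnd, clone, seq))
    else:
        raise PoolError(f"unknown pool format {format!r}")
    return Pool(records)


def filter_pool(pool: Pool, structures: Mapping[str, "SecondaryStructure"]) -> Pool:
    """Apply the data-set filters; returns a new pool, input unchanged.

    1. A sequence string occurring in several rounds is kept only in the
       highest round (the most evolved copy).  Within one round, the first
       occurrence is kept and later copies are dropped with a warning.
    2. Records whose minimum-free-energy structure has zero base pairs
       ("no pair structure") are removed.

    ``structures`` maps ``record.key`` to the record's folded structure.
    """
    missing = [r.key for r in pool.records if r.key not in structures]
    if missing:
        raise PoolError(f"missing structure for record(s): {missing[:5]}")

    # pass 1: highest round per sequence string
    best_round: dict[str, int] = {}
    for rec in pool.records:
        if rec.sequence not in best_round or rec.round_index > best_round[rec.sequence]:
            best_round[rec.sequence] = rec.round_index

    kept: list[SequenceRecord] = []
    seen_in_round: set[tuple[str, int]] = set()
    for rec in pool.records:
        if rec.round_index != best_round[rec.sequence]:
            logger.info("dropping %s: sequence recurs in round %d", rec.key, best_round[rec.sequence])
            continue
        mark = (rec.sequence, rec.round_index)
        if mark in seen_in_round:
            logger.warning("dropping %s: duplicate within round %d", rec.key, rec.round_index)
            continue
        seen_in_round.add(mark)
        if not structures[rec.key].pairs:
            logger.info("dropping %s: no pair structure", rec.key)
            continue
        kept.append(rec)
    return Pool(kept)


def split_train_test(pool: Pool) -> tuple[LabeledSet, Pool]:
    """Split a filtered pool into the labeled training set and the test pool.

    Training set: rounds 1 and 10, with labels 1 (low affinity) and 2 (high
    affinity).  Test pool: rounds 2–9, unlabeled.
    """
    rounds = pool.rounds_present
    if 1 not in rounds or 10 not in rounds:
        raise PoolError(f"pool must contain rounds 1 and 10 (has {sorted(rounds)})")
    train_records, labels, test_records = [], [], []
    for rec in pool.records:
        if rec.round_index == 1:
            train_records.append(rec)
            labels.append(1)
        elif rec.round_index == 10:
            train_records.append(rec)
            labels.append(2)
        else:
            test_records.append(rec)
    return LabeledSet(train_records, labels), Pool(test_records)


def write_pool_csv(pool: Pool, path: str | Path) -> None:
    """Export a pool as CSV with round/clone/sequence columns."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "round", "clone", "sequence"])
        for rec in pool.records:
            w.writerow([rec.key, rec.round_index, rec.clone_id, rec.sequence])


def write_pool_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.key}\n{rec.sequence}\n")
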