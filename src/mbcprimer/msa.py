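"""Multiple-sequence-alignment input and preprocessing.

The scanner works on an aligned FASTA whose records are split into a
*target* set (taxa the primers should amplify) and an *exclusion* set
(typically the host, which must not be amplified).  Before scanning, the
alignment is normalized (uppercase, U→T, "." → "-"), terminal gap runs are
masked so partial database records are not mistaken for genuine indels, and
columns dominated by gaps or ambiguous bases are trimmed.  A coordinate map
from the trimmed alignment back to the original columns is kept so reported
sites can be located in the user's input.

Column statistics are coverage-aware: positions inside a record's terminal
gap run are excluded from both numerator and denominator of the per-column
badness fraction, so partial sequences cannot delete genuinely conserved
columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentShapeError, ConfigurationError, MbcError, ParseError

logger = logging.getLogger(__name__)

GAP = "-"
TARGET = "target"
EXCLUSION = "exclusion"

_GAP_BYTE = ord(GAP)
_ACGT_BYTES = frozenset(b"ACGT")


@dataclass
class AlignedRecord:
    """One aligned sequence with its set label and terminal-gap mask.

    ``terminal_mask`` is the (first, last) non-gap column pair (inclusive);
    ``None`` until computed, and stays ``None`` for an all-gap record.
    """

    id: str
    residues: str
    set_label: str
    terminal_mask: tuple[int, int] | None = None

    def covers(self, start: int, end: int | None = None) -> bool:
        """True if the record's non-terminal region spans column ``start``
        (or the half-open window ``[start, end)``)."""
        if self.terminal_mask is None:
            return False
        first, last = self.terminal_mask
        if end is None:
            return first <= start <= last
        return first <= start and end - 1 <= last


@dataclass
class Alignment:
    """An ordered set of aligned records split into target/exclusion sets."""

    records: list[AlignedRecord]
    n_columns: int

    @property
    def n_target(self) -> int:
        return sum(1 for r in self.records if r.set_label == TARGET)

    @property
    def n_exclusion(self) -> int:
        return sum(1 for r in self.records if r.set_label == EXCLUSION)

    def __len__(self) -> int:
        return len(self.records)

    def _matrix(self) -> np.ndarray:
        """Byte matrix view of the residues, shape (n_records, n_columns)."""
        buf = "".join(r.residues for r in self.records).encode("ascii")
        return np.frombuffer(buf, dtype=np.uint8).reshape(len(self.records), self.n_columns)


@dataclass
class TrimmedAlignment:
    """Alignment after column trimming, with the trimmed→original column map."""

    alignment: Alignment
    kept_columns: list[int]
    max_frac: float = 0.20

    @property
    def n_columns(self) -> int:
        return self.alignment.n_columns


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T").replace(".", GAP)


def _resolve_target_ids(
    ids: Sequence[str], target_spec: int | str | Path | Iterable[str]
) -> set[str]:
    if isinstance(target_spec, bool):
        raise ConfigurationError("target_spec must be an int, path, or id collection")
    if isinstance(target_spec, int):
        if not 1 <= target_spec < len(ids):
            raise ConfigurationError(
                f"target_spec={target_spec} must leave both a nonempty target and "
                f"exclusion set among {len(ids)} records"
            )
        return set(ids[:target_spec])
    if isinstance(target_spec, (str, Path)) and Path(target_spec).exists():
        wanted = {
            line.strip() for line in Path(target_spec).read_text().splitlines() if line.strip()
        }
    else:
        wanted = {str(x) for x in target_spec} if not isinstance(target_spec, str) else {target_spec}
    unknown = wanted - set(ids)
    if unknown:
        raise ConfigurationError(f"target ids not present in alignment: {sorted(unknown)[:5]}")
    if not wanted or len(wanted) >= len(ids):
        raise ConfigurationError("target set must be a nonempty proper subset of the records")
    return wanted


def read_alignment(path: str | Path, target_spec: int | str | Path | Iterable[str]) -> Alignment:
    """Read an aligned FASTA and label each record target or exclusion.

    ``target_spec`` is either an integer N ("the first N records are
    targets"), the path of a file listing target record ids one per line,
    or a collection of ids.  Residues are uppercased, U is normalized to T
    and "." to "-"; record order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises ValueError on malformed input
        raise ParseError(f"could not parse {path} as FASTA: {exc}") from exc
    if not raw:
        raise ParseError(f"no FASTA records found in {path}")
    lengths = {len(rec.seq) for rec in raw}
    if len(lengths) != 1:
        raise AlignmentShapeError(
            f"aligned records must share one length; found lengths {sorted(lengths)}"
        )
    ids = [rec.id for rec in raw]
    target_ids = _resolve_target_ids(ids, target_spec)
    records = [
        AlignedRecord(
            id=rec.id,
            residues=_normalize(str(rec.seq)),
            set_label=TARGET if rec.id in target_ids else EXCLUSION,
        )
        for rec in raw
    ]
    return Alignment(records=records, n_columns=lengths.pop())


def mask_terminal_gaps(alignment: Alignment) -> Alignment:
    """Set each record's terminal mask to its (first, last) non-gap column.

    All-gap records get an empty mask (``None``) and a warning; they are
    excluded from every downstream column statistic and window count.
    """
    for rec in alignment.records:
        stripped = rec.residues.strip(GAP)
        if not stripped:
            rec.terminal_mask = None
            logger.warning("record %s is all gaps; it will be ignored", rec.id)
            continue
        first = len(rec.residues) - len(rec.residues.lstrip(GAP))
        last = first + len(stripped) - 1
        rec.terminal_mask = (first, last)
    return alignment


def _ensure_masks(alignment: Alignment) -> None:
    # None is both the "unset" and the "all-gap" value; recomputing is
    # idempotent and cheap, so recompute whenever a None could mean unset.
    if any(r.terminal_mask is None and r.residues.strip(GAP) for r in alignment.records):
        mask_terminal_gaps(alignment)


def _badness_vector(alignment: Alignment) -> np.ndarray:
    """Per-column fraction of internal gaps + ambiguous bases among the
    records whose terminal mask covers the column; 1.0 where nothing covers."""
    mat = alignment._matrix()
    n_rec, n_col = mat.shape
    cols = np.arange(n_col)
    covered = np.zeros((n_rec, n_col), dtype=bool)
    for i, rec in enumerate(alignment.records):
        if rec.terminal_mask is not None:
            first, last = rec.terminal_mask
            covered[i] = (cols >= first) & (cols <= last)
    is_good = (
        (mat == ord("A")) | (mat == ord("C")) | (mat == ord("G")) | (mat == ord("T"))
    )
    cov_counts = covered.sum(axis=0)
    bad_counts = (covered & ~is_good).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(cov_counts > 0, bad_counts / np.maximum(cov_counts, 1), 1.0)
    return frac


def column_badness(alignment: Alignment, column: int) -> float:
    """Fraction of covering records that carry an internal gap or ambiguous
    (non-ACGT) base at ``column``.  Terminal-masked records neither count as
    bad nor enter the denominator; a column no record covers scores 1.0."""
    if not 0 <= column < alignment.n_columns:
        raise IndexError(f"column {column} out of range")
    _ensure_masks(alignment)
    covering = [r for r in alignment.records if r.covers(column)]
    if not covering:
        logger.warning("column %d covered by no record; treated as fully bad", column)
        return 1.0
    bad = sum(1 for r in covering if r.residues[column] not in "ACGT")
    return bad / len(covering)


def trim_columns(alignment: Alignment, max_frac: float = 0.20) -> TrimmedAlignment:
    """Remove columns whose gap+ambiguity fraction exceeds ``max_frac``.

    The threshold is strict (badness > max_frac is removed; exactly equal is
    kept).  Raises if nothing survives.
    """
    _ensure_masks(alignment)
    frac = _badness_vector(alignment)
    kept = np.flatnonzero(frac <= max_frac)
    if kept.size == 0:
        raise MbcError("alignment too gappy: every column exceeds the trim threshold")
    mat = alignment._matrix()[:, kept]
    records = [
        AlignedRecord(id=rec.id, residues=mat[i].tobytes().decode("ascii"), set_label=rec.set_label)
        for i, rec in enumerate(alignment.records)
    ]
    trimmed = Alignment(records=records, n_columns=int(kept.size))
    mask_terminal_gaps(trimmed)
    n_removed = alignment.n_columns - kept.size
    if n_removed:
        logger.info("trimmed %d of %d columns (badness > %.2f)", n_removed, alignment.n_columns, max_frac)
    return TrimmedAlignment(alignment=trimmed, kept_columns=[int(c) for c in kept], max_frac=max_frac)


def to_original_position(trimmed: TrimmedAlignment, pos: int) -> int:
    """Map a trimmed 0-based column back to its original 0-based column."""
    if not 0 <= pos < len(trimmed.kept_columns):
        raise IndexError(f"trimmed position {pos} out of range")
    return trimmed.kept_columns[pos]


def write_trimmed(
    trimmed: TrimmedAlignment, fasta_path: str | Path, map_path: str | Path | None = None
) -> None:
    """Write the trimmed alignment as FASTA and, optionally, a two-column
    TSV mapping trimmed → original 1-based columns."""
    with open(fasta_path, "w") as fh:
        for rec in trimmed.alignment.records:
            fh.write(f">{rec.id}\n{rec.residues}\n")
    if map_path is not None:
        with open(map_path, "w") as fh:
            fh.write("trimmed_column\toriginal_column\n")
            for t, o in enumerate(trimmed.kept_columns):
                fh.write(f"{t + 1}\t{o + 1}\n")
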