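"""Readers and writers for the sequence formats the pipeline touches.

Internal convention, used by every module in this package: sequences are
uppercase RNA (``U``, never ``T``) once :func:`normalize_rna` has been
applied, and all internal coordinates are 0-based, half-open. User-facing
reports (TSV outputs, CLI messages) use 1-based inclusive coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTUN")

logger = logging.getLogger(__name__)


class SequenceFormatError(ValueError):
    """Raised for malformed FASTQ/FASTA input or alphabet violations."""


@dataclass(frozen=True)
class Read:
    """A single sequencing read (quality values are never used)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceFormatError(f"read {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class NamedSequence:
    """A reference sequence with a role in the pipeline.

    ``kind`` is one of ``ncRNA``, ``UTR`` or ``miRNA``.
    """

    id: str
    sequence: str
    kind: str = "ncRNA"


def normalize_rna(sequence: str) -> str:
    """Uppercase and convert to the RNA alphabet (T -> U).

    DNA and RNA spellings of the same molecule normalize to the same
    string; the function is idempotent.
    """
    return sequence.upper().replace("T", "U")


def _check_alphabet(sequence: str, label: str) -> None:
    bad = set(sequence) - ALPHABET
    if bad:
        raise SequenceFormatError(
            f"sequence {label!r} contains characters outside A/C/G/T/U/N: "
            f"{''.join(sorted(bad))}"
        )


def read_fastq(path: str | Path, *, drop_n: bool = True,
               stats: dict | None = None) -> list[Read]:
    """Parse strict 4-line-record FASTQ into :class:`Read` objects.

    Quality lines are discarded and sequences are uppercased (but not
    RNA-normalized; downstream stages call :func:`normalize_rna`).
    Reads containing ``N`` are dropped with a logged count when
    ``drop_n`` is true, because every downstream step relies on exact
    string identity. If ``stats`` is given, ``stats["discarded_n"]`` is
    set to the number of dropped reads.

    Raises :class:`SequenceFormatError` naming the offending line number
    for records that do not follow the 4-line layout.
    """
    path = Path(path)
    reads: list[Read] = []
    n_dropped = 0
    with path.open() as fh:
        lines = fh.read().splitlines()
    # trailing blank lines are tolerated
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise SequenceFormatError(
            f"{path}: truncated FASTQ, {len(lines)} lines is not a multiple of 4 "
            f"(record starting at line {len(lines) - len(lines) % 4 + 1} is incomplete)"
        )
    for rec_start in range(0, len(lines), 4):
        header, seq, sep, _qual = lines[rec_start:rec_start + 4]
        if not header.startswith("@"):
            raise SequenceFormatError(
                f"{path}: line {rec_start + 1}: expected '@' header, got {header[:30]!r}"
            )
        if not sep.startswith("+"):
            raise SequenceFormatError(
                f"{path}: line {rec_start + 3}: expected '+' separator, got {sep[:30]!r}"
            )
        read_id = header[1:].split()[0] if header[1:].split() else header[1:]
        seq = seq.upper()
        _check_alphabet(seq, read_id)
        if drop_n and "N" in seq:
            n_dropped += 1
            continue
        reads.append(Read(id=read_id, sequence=seq))
    if n_dropped:
        logger.info("%s: dropped %d read(s) containing N", path, n_dropped)
    if stats is not None:
        stats["discarded_n"] = n_dropped
    return reads


def read_plain(path: str | Path, *, drop_n: bool = True,
               stats: dict | None = None) -> list[Read]:
    """Read one sequence per line (ids are synthesized as ``seq<N>``)."""
    path = Path(path)
    reads: list[Read] = []
    n_dropped = 0
    with path.open() as fh:
        for i, line in enumerate(fh, start=1):
            seq = line.strip().upper()
            if not seq:
                continue
            _check_alphabet(seq, f"line {i}")
            if drop_n and "N" in seq:
                n_dropped += 1
                continue
            reads.append(Read(id=f"seq{i}", sequence=seq))
    if n_dropped:
        logger.info("%s: dropped %d sequence(s) containing N", path, n_dropped)
    if stats is not None:
        stats["discarded_n"] = n_dropped
    return reads


def read_fasta(path: str | Path, kind: str = "ncRNA") -> list[NamedSequence]:
    """Parse FASTA into :class:`NamedSequence` objects.

    Ids are the first whitespace-delimited token of each header; multi-line
    sequences are concatenated. Duplicate ids and alphabet violations raise
    :class:`SequenceFormatError`.
    """
    path = Path(path)
    records: list[NamedSequence] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise SequenceFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        _check_alphabet(seq, rec.id)
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(NamedSequence(id=rec.id, sequence=seq, kind=kind))
    dups = sorted(i for i, c in seen.items() if c > 1)
    if dups:
        raise SequenceFormatError(f"{path}: duplicate ids: {', '.join(dups)}")
    return records


def write_fasta(sequences: Iterable[NamedSequence], path: str | Path) -> None:
    """Write sequences as FASTA (sequence spelling is echoed verbatim)."""
    recs = [SeqRecord(Seq(s.sequence), id=s.id, description="") for s in sequences]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(records: Sequence[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> None:
    """Write (id, sequence) pairs as 4-line FASTQ with constant quality."""
    with Path(path).open("w") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
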