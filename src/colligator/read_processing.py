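"""Read cleanup: 3' adapter removal, trailing-A trimming, length filtering.

Small-RNA library reads are sequenced past the insert into the ligated 3'
adapter, so the insert boundary is located by finding the adapter's 5' end
inside the read. The pipeline order is fixed: adapter removal, then poly-A
trimming, then the insert-length filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .sequence_io import Read, normalize_rna

#: Illumina small-RNA 3' adapter (DNA spelling as supplied by the vendor).
ILLUMINA_3P_ADAPTER = "TCTCGTATGCCGTCTTCTGCTTGAAA"


class TrimConfigError(ValueError):
    """Invalid trimming configuration."""


@dataclass(frozen=True)
class TrimConfig:
    """Parameters of the read-cleanup stage.

    adapter
        3' adapter sequence (any spelling; normalized to RNA internally).
    min_adapter_prefix
        Minimum number of adapter bases that must match (default 6).
    max_polya
        Cap on trailing A's removed after the adapter (default 4).
    min_len / max_len
        Retained insert length range, inclusive (defaults 16 and 29).
    """

    adapter: str = ILLUMINA_3P_ADAPTER
    min_adapter_prefix: int = 6
    max_polya: int = 4
    min_len: int = 16
    max_len: int = 29

    def __post_init__(self) -> None:
        if not (1 <= self.min_adapter_prefix <= len(self.adapter)):
            raise TrimConfigError(
                f"min_adapter_prefix={self.min_adapter_prefix} must be in "
                f"[1, {len(self.adapter)}] (adapter length)"
            )
        if self.min_len > self.max_len:
            raise TrimConfigError(f"min_len {self.min_len} > max_len {self.max_len}")
        if self.max_polya < 0:
            raise TrimConfigError("max_polya must be >= 0")

    @property
    def adapter_rna(self) -> str:
        return normalize_rna(self.adapter)


@dataclass(frozen=True)
class TrimmedRead:
    """A read after adapter and poly-A trimming.

    ``insert`` is a prefix of the normalized source read;
    ``adapter_start`` is the 0-based position of the adapter match
    (``None`` if no adapter was found).
    """

    source_id: str
    insert: str
    adapter_found: bool
    adapter_start: int | None
    polya_removed: int


@dataclass
class TrimStats:
    """Read-accounting for one library; conserves the input count."""

    reads_in: int = 0
    retained: int = 0
    discarded_no_adapter: int = 0
    discarded_length: int = 0
    discarded_n: int = 0

    def conserved(self) -> bool:
        return self.reads_in == (self.retained + self.discarded_no_adapter
                                 + self.discarded_length + self.discarded_n)


def find_adapter(sequence: str, adapter: str, min_prefix: int) -> int | None:
    """Locate the leftmost 3'-anchored adapter match.

    A match at position ``i`` requires that a prefix of ``adapter`` of
    length >= ``min_prefix`` matches exactly and extends either to the
    read's 3' end or over the full adapter. The anchoring rule prevents a
    spurious mid-read 6-mer from truncating the insert. Returns the match
    position or ``None``.
    """
    if min_prefix > len(adapter):
        raise TrimConfigError(
            f"min_adapter_prefix {min_prefix} exceeds adapter length {len(adapter)}"
        )
    n = len(sequence)
    for i in range(n - min_prefix + 1):
        m = min(len(adapter), n - i)
        if sequence[i:i + m] == adapter[:m]:
            return i
    return None


def trim_adapter(read: Read, config: TrimConfig) -> TrimmedRead:
    """Remove the 3' adapter from a read.

    The read is RNA-normalized first. When no qualifying adapter match
    exists the returned record has ``adapter_found=False`` and the full
    normalized read as ``insert``; the pipeline decides whether such
    unanchored reads are kept (default: discarded, because the insert's 3'
    boundary is then unknown).
    """
    seq = normalize_rna(read.sequence)
    pos = find_adapter(seq, config.adapter_rna, config.min_adapter_prefix)
    if pos is None:
        return TrimmedRead(read.id, seq, False, None, 0)
    return TrimmedRead(read.id, seq[:pos], True, pos, 0)


def trim_polya(insert: str, max_polya: int) -> tuple[str, int]:
    """Remove up to ``max_polya`` trailing A's from an insert."""
    removed = 0
    while removed < max_polya and insert.endswith("A"):
        insert = insert[:-1]
        removed += 1
    return insert, removed


def length_filter(insert: str, config: TrimConfig) -> bool:
    """True iff the insert length is within [min_len, max_len]."""
    return config.min_len <= len(insert) <= config.max_len


def trim_pipeline(reads: Iterable[Read], config: TrimConfig | None = None, *,
                  keep_unanchored: bool = False,
                  discarded_n: int = 0) -> tuple[list[TrimmedRead], TrimStats]:
    """Run adapter removal, poly-A trimming and the length filter.

    ``discarded_n`` lets the caller fold reads already dropped at parse
    time (N-containing) into the conservation accounting. Returns the
    retained trimmed reads and a :class:`TrimStats` whose categories sum
    to ``reads_in``.
    """
    config = config or TrimConfig()
    stats = TrimStats(reads_in=discarded_n, discarded_n=discarded_n)
    retained: list[TrimmedRead] = []
    for read in reads:
        stats.reads_in += 1
        tr = trim_adapter(read, config)
        if not tr.adapter_found and not keep_unanchored:
            stats.discarded_no_adapter += 1
            continue
        insert, n_a = trim_polya(tr.insert, config.max_polya)
        if not length_filter(insert, config):
            stats.discarded_length += 1
            continue
        stats.retained += 1
        retained.append(TrimmedRead(tr.source_id, insert, tr.adapter_found,
                                    tr.adapter_start, n_a))
    return retained, stats
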