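"""Collapse trimmed inserts to exact-copy counts and extract core sequences.

A *core* is an exact subsequence of at least ``min_core_len`` bases shared
by a cluster of abundant insert sequences, reported with the summed
instance count of its members. Clustering is a deterministic greedy on
shared exact substrings: at each round the longest substring shared by at
least two remaining sequences seeds a cluster that absorbs every sequence
containing it; sequences sharing nothing long enough become singleton
cores. Ties are broken by higher total instance count of the containing
set, then lexicographically — the result is independent of input order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence


class CoreConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CountedSequence:
    """A distinct insert string with the number of exact copies observed."""

    sequence: str
    count: int


@dataclass(frozen=True)
class CoreSequence:
    """A shared exact subsequence with its member cluster.

    invariant: every member contains ``sequence`` as an exact substring
    and ``instance_count`` is the sum of member counts.
    """

    sequence: str
    instance_count: int
    members: tuple[CountedSequence, ...]
    core_id: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


def collapse_exact(inserts: Iterable[str]) -> list[CountedSequence]:
    """One :class:`CountedSequence` per distinct string; counts sum to the input size."""
    counts = Counter(inserts)
    return [CountedSequence(seq, n)
            for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def abundance_filter(counted: Iterable[CountedSequence],
                     min_copies: int = 3) -> list[CountedSequence]:
    """Keep sequences observed at least ``min_copies`` times (exact copies)."""
    return [c for c in counted if c.count >= min_copies]


def _substrings_of_length(seq: str, length: int) -> set[str]:
    return {seq[i:i + length] for i in range(len(seq) - length + 1)}


def _longest_shared(seqs: Sequence[str], min_len: int) -> tuple[int, dict[str, set[int]]]:
    """Longest substring length shared by >= 2 of ``seqs``, with the
    substrings of that length mapped to the indices containing them.

    Returns ``(0, {})`` when no substring of >= ``min_len`` is shared.
    Sequence lengths here are <= 29 nt, so plain enumeration is fine.
    """
    max_len = max((len(s) for s in seqs), default=0)
    for length in range(max_len, min_len - 1, -1):
        containers: dict[str, set[int]] = {}
        for idx, s in enumerate(seqs):
            for sub in _substrings_of_length(s, length):
                containers.setdefault(sub, set()).add(idx)
        shared = {sub: idxs for sub, idxs in containers.items() if len(idxs) >= 2}
        if shared:
            return length, shared
    return 0, {}


def _longest_common_all(seqs: Sequence[str], min_len: int) -> str | None:
    """Lexicographically smallest among the longest substrings common to
    every sequence in ``seqs`` (``None`` if shorter than ``min_len``)."""
    shortest = min(seqs, key=len)
    for length in range(len(shortest), min_len - 1, -1):
        hits = sorted(sub for sub in _substrings_of_length(shortest, length)
                      if all(sub in s for s in seqs))
        if hits:
            return hits[0]
    return None


def extract_cores(counted: Sequence[CountedSequence],
                  min_core_len: int = 16) -> list[CoreSequence]:
    """Partition abundance-filtered sequences into cores.

    Every input sequence becomes a member of exactly one core; the sum of
    core instance counts equals the sum of input counts. Cores are sorted
    by instance count descending, then lexicographically, and labelled
    ``core1``, ``core2``, ...
    """
    if min_core_len < 1:
        raise CoreConfigError(f"min_core_len must be >= 1, got {min_core_len}")
    # canonical pool order makes the procedure order-insensitive
    pool = sorted(counted, key=lambda c: (-c.count, c.sequence))
    cores: list[CoreSequence] = []
    while pool:
        seqs = [c.sequence for c in pool]
        length, shared = _longest_shared(seqs, min_core_len)
        if length == 0:
            # nothing shared: each remaining sequence is its own core
            for c in pool:
                cores.append(CoreSequence(c.sequence, c.count, (c,)))
            break
        # among equally long shared substrings prefer the highest total
        # count of containers, then the lexicographically smallest string
        def score(item: tuple[str, set[int]]) -> tuple[int, str]:
            sub, idxs = item
            return (-sum(pool[i].count for i in idxs), sub)

        seed, idxs = min(shared.items(), key=score)
        members = tuple(pool[i] for i in sorted(idxs))
        # the final core is the longest substring common to ALL members;
        # it has the same length as the seed (the seed is common to all,
        # and nothing longer is shared by even two sequences)
        core_str = _longest_common_all([m.sequence for m in members], min_core_len)
        assert core_str is not None and len(core_str) >= length
        cores.append(CoreSequence(core_str, sum(m.count for m in members), members))
        remaining = set(range(len(pool))) - idxs
        pool = [pool[i] for i in sorted(remaining)]
    cores.sort(key=lambda c: (-c.instance_count, c.sequence))
    return [CoreSequence(c.sequence, c.instance_count, c.members, f"core{i + 1}")
            for i, c in enumerate(cores)]
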