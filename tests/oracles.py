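"""Brute-force reference implementations used only as test oracles.

These deliberately take the dumbest correct route (full enumeration over
all placements/substrings) so that they share no code path with the
package implementations they check.
"""

from __future__ import annotations

from colligator.core_discovery import CountedSequence

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

_RC = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}


def brute_rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def brute_hairpins(seq: str, min_stem_pairs: int, min_loop: int = 3,
                   max_loop: int = 30) -> set[tuple[int, int, int, int]]:
    """All maximal perfect stem-loops as (start, end, loop_start, loop_len).

    Enumerates every (start, end, loop_start) triple, checks the whole
    stem pairs wholesale, then filters for outward and inward maximality.
    """
    n = len(seq)
    found: set[tuple[int, int, int, int]] = set()
    for start in range(n):
        for end in range(start + 1, n + 1):
            span = end - start
            for stem in range(min_stem_pairs, span // 2 + 1):
                loop_len = span - 2 * stem
                if not (min_loop <= loop_len <= max_loop):
                    continue
                if not all((seq[start + t], seq[end - 1 - t]) in _PAIRS
                           for t in range(stem)):
                    continue
                loop_start = start + stem
                # outward maximality
                if start > 0 and end < n and (seq[start - 1], seq[end]) in _PAIRS:
                    continue
                # inward maximality (canonical loop)
                if (loop_len - 2 >= min_loop
                        and (seq[loop_start], seq[loop_start + loop_len - 1]) in _PAIRS):
                    continue
                found.add((start, end, loop_start, loop_len))
    return found


def brute_target_sites(core: str, utr: str,
                       min_len: int = 7) -> set[tuple[int, int, int, int]]:
    """All maximal reverse-complement blocks as
    (utr_start, utr_end, core_start, core_end)."""
    r = brute_rc(core)
    c_len, u_len = len(r), len(utr)
    out: set[tuple[int, int, int, int]] = set()
    for m in range(min_len, min(c_len, u_len) + 1):
        for p in range(c_len - m + 1):
            for u in range(u_len - m + 1):
                if r[p:p + m] != utr[u:u + m]:
                    continue
                if p > 0 and u > 0 and r[p - 1] == utr[u - 1]:
                    continue  # extendable left
                if p + m < c_len and u + m < u_len and r[p + m] == utr[u + m]:
                    continue  # extendable right
                out.add((u, u + m, c_len - p - m, c_len - p))
    return out


def _all_substrings(seq: str, length: int) -> set[str]:
    return {seq[i:i + length] for i in range(len(seq) - length + 1)}


def brute_cores(counted: list[CountedSequence],
                min_core_len: int) -> list[tuple[str, int, frozenset[str]]]:
    """Greedy core extraction by exhaustive shared-substring enumeration.

    At each round, every substring (of any remaining sequence) contained
    in at least two remaining sequences is scored by (length, total count
    of containers, lexicographic); the winner forms a cluster of all its
    containers. When nothing of >= min_core_len is shared, the remaining
    sequences become singleton cores. Returns (core, total_count,
    member set) tuples, sorted like the implementation.
    """
    pool = list(counted)
    clusters: list[tuple[str, int, frozenset[str]]] = []
    while pool:
        candidates: dict[str, set[int]] = {}
        best_len = 0
        for length in range(max(len(c.sequence) for c in pool), min_core_len - 1, -1):
            for idx, c in enumerate(pool):
                for sub in _all_substrings(c.sequence, length):
                    holders = {i for i, o in enumerate(pool) if sub in o.sequence}
                    if len(holders) >= 2:
                        candidates[sub] = holders
            if candidates:
                best_len = length
                break
        if best_len == 0:
            for c in pool:
                clusters.append((c.sequence, c.count, frozenset({c.sequence})))
            break
        winner = min(candidates.items(),
                     key=lambda kv: (-sum(pool[i].count for i in kv[1]), kv[0]))
        sub, holders = winner
        members = [pool[i] for i in sorted(holders)]
        # lexicographically smallest longest substring common to all members
        shortest = min((m.sequence for m in members), key=len)
        core = None
        for length in range(len(shortest), min_core_len - 1, -1):
            common = sorted(s for s in _all_substrings(shortest, length)
                            if all(s in m.sequence for m in members))
            if common:
                core = common[0]
                break
        clusters.append((core, sum(m.count for m in members),
                         frozenset(m.sequence for m in members)))
        pool = [pool[i] for i in range(len(pool)) if i not in holders]
    clusters.sort(key=lambda t: (-t[1], t[0]))
    return clusters
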