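"""Permutation negative control for core abundance.

An abundant core could in principle be a sequencing artifact. The control
generates distinct random permutations of the core's bases (same
composition, scrambled order) and searches for them among the raw reads.
Under a uniform-random base model the probability that *none* of K random
k-mers appears anywhere in M random L-mers has the closed product form

    p_none = (1 - 4^-k) ^ (K * M * (L - k + 1)),

an independence approximation over all pattern/position pairs (overlap
dependence is ignored). A Monte-Carlo estimator validates the
approximation at reduced scale.
"""

from __future__ import annotations

import math
import random
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import Read


class PermutationError(ValueError):
    pass


@dataclass(frozen=True)
class PermutationNullResult:
    """Outcome of the permutation control for one core."""

    core: str
    n_permutations: int      # K
    n_reads: int             # M
    read_length: int         # L
    core_length: int         # k
    n_found: int             # permutations observed in >= 1 read
    p_none_analytic: float


@dataclass(frozen=True)
class MonteCarloEstimate:
    p_hat: float
    std_error: float
    n_trials: int


def count_distinct_permutations(sequence: str) -> int:
    """Number of distinct orderings of the multiset of bases."""
    n = math.factorial(len(sequence))
    for c in Counter(sequence).values():
        n //= math.factorial(c)
    return n


def generate_distinct_permutations(core: str, k: int, rng_seed: int) -> list[str]:
    """Draw ``k`` distinct random permutations of ``core``'s bases.

    The identity ordering (the core itself) is excluded — the permutations
    stand in contrast to the observed core. Raises
    :class:`PermutationError` when fewer than ``k`` non-identity orderings
    exist, reporting the available maximum. Reproducible given the seed.
    """
    available = count_distinct_permutations(core) - 1
    if k > available:
        raise PermutationError(
            f"requested {k} distinct permutations of {core!r} but only "
            f"{available} non-identity orderings exist"
        )
    rng = random.Random(rng_seed)
    bases = list(core)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < k:
        rng.shuffle(bases)
        perm = "".join(bases)
        if perm == core or perm in seen:
            continue
        seen.add(perm)
        out.append(perm)
    return out


def search_patterns_in_reads(patterns: Sequence[str],
                             reads: Iterable[Read]) -> dict[str, int]:
    """For each pattern, the number of reads containing it as an exact substring.

    Patterns are grouped by length and looked up through each read's
    k-mer sets, so the cost is O(total read bases), not O(patterns x reads).
    """
    by_len: dict[int, set[str]] = {}
    for p in patterns:
        by_len.setdefault(len(p), set()).add(p)
    counts: dict[str, int] = {p: 0 for p in patterns}
    for read in reads:
        seq = read.sequence
        for length, pset in by_len.items():
            if length > len(seq):
                continue
            hits = {seq[i:i + length] for i in range(len(seq) - length + 1)} & pset
            for h in hits:
                counts[h] += 1
    return counts


def p_none(K: int, M: int, L: int, k: int) -> float:
    """Closed-form probability that none of K random k-mers occurs in M random L-mers.

    Computed as ``exp(K*M*(L-k+1) * log1p(-4**-k))`` for numerical
    stability at large exponents. ``K = 0`` returns exactly 1.0.
    """
    if k > L:
        raise PermutationError(f"pattern length k={k} exceeds read length L={L}")
    if min(M, L, k) < 1 or K < 0:
        raise PermutationError("K must be >= 0 and M, L, k positive")
    if K == 0:
        return 1.0
    exponent = K * M * (L - k + 1)
    return math.exp(exponent * math.log1p(-(4.0 ** -k)))


def p_none_monte_carlo(K: int, M: int, L: int, k: int, n_trials: int,
                       rng_seed: int) -> MonteCarloEstimate:
    """Monte-Carlo estimate of :func:`p_none` with binomial standard error.

    Each trial draws K random k-mers and M random L-mers (uniform bases)
    and records whether no pattern occurs in any read. Sequences are
    encoded as base-4 integers so the per-trial scan is vectorized.
    Requires ``k <= 15`` so k-mer codes fit comfortably in int64.
    """
    if k > L:
        raise PermutationError(f"pattern length k={k} exceeds read length L={L}")
    if k > 15:
        raise PermutationError("Monte-Carlo supports k <= 15 (integer k-mer codes)")
    if K == 0:
        return MonteCarloEstimate(1.0, 0.0, n_trials)
    rng = np.random.default_rng(rng_seed)
    n_codes = 4 ** k
    n_positions = L - k + 1
    none_count = 0
    for _ in range(n_trials):
        patterns = rng.integers(0, n_codes, size=K)
        reads = rng.integers(0, 4, size=(M, L))
        codes = np.zeros((M, n_positions), dtype=np.int64)
        for j in range(k):
            codes = codes * 4 + reads[:, j:j + n_positions]
        if not np.isin(codes, patterns).any():
            none_count += 1
    p_hat = none_count / n_trials
    se = math.sqrt(max(p_hat * (1 - p_hat), 1.0 / n_trials) / n_trials)
    return MonteCarloEstimate(p_hat, se, n_trials)


def run_permutation_test(core: str, reads: Sequence[Read], n_permutations: int,
                         rng_seed: int,
                         read_length: int | None = None) -> PermutationNullResult:
    """Full control: permute, search, and evaluate the closed form.

    ``read_length`` defaults to the maximum observed read length (the
    closed form treats every read as an independent L-mer).
    """
    perms = generate_distinct_permutations(core, n_permutations, rng_seed)
    counts = search_patterns_in_reads(perms, reads)
    n_found = sum(1 for c in counts.values() if c > 0)
    L = read_length if read_length is not None else max(
        (len(r.sequence) for r in reads), default=len(core))
    return PermutationNullResult(
        core=core,
        n_permutations=n_permutations,
        n_reads=len(reads),
        read_length=L,
        core_length=len(core),
        n_found=n_found,
        p_none_analytic=p_none(n_permutations, max(len(reads), 1), L, len(core)),
    )
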