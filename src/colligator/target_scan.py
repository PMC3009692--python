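"""Reverse-complement target scanning of 3'UTRs and miRNA seed checks.

A candidate regulatory small RNA binds a 3'UTR where a block of the UTR
is the exact reverse complement of a block of the RNA (no wobble, no
mismatches — the evidence sought is exact complementarity, not a
thermodynamic context score). Sites are *maximal*: extendable matches are
extended, contained matches suppressed.

The seed check asks whether any 7-nt window of the core coincides with
the seed (mature positions 2-8) of a known miRNA; an empty result means
targeting by the core would not be redundant with the supplied miRNA set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .core_discovery import CoreSequence
from .sequence_io import NamedSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSite:
    """A maximal exact reverse-complement block between a core and a UTR.

    Coordinates are 0-based half-open; ``matched_block`` is the UTR-side
    string, equal to ``reverse_complement(core[core_start:core_end])``.
    """

    core_id: str
    utr_id: str
    utr_start: int
    utr_end: int
    core_start: int
    core_end: int
    match_len: int
    matched_block: str


@dataclass(frozen=True)
class SeedRecord:
    """A mature miRNA and its seed (nucleotides 2-8, 1-based inclusive)."""

    mirna_id: str
    mature_sequence: str

    @property
    def seed(self) -> str:
        return self.mature_sequence[1:8]


def reverse_complement(seq: str) -> str:
    """Reverse complement in the RNA alphabet (A<->U, C<->G, N->N)."""
    return str(Seq(seq).reverse_complement_rna())


def kmer_windows(core: str, k: int = 7) -> list[tuple[int, str]]:
    """All length-``k`` windows of the core in 5'->3' order as (start, kmer).

    A core shorter than ``k`` yields an empty list with a warning.
    """
    if k > len(core):
        logger.warning("k=%d exceeds core length %d; no windows", k, len(core))
        return []
    return [(i, core[i:i + k]) for i in range(len(core) - k + 1)]


def find_target_sites(core: CoreSequence | str, utr: NamedSequence,
                      min_site_len: int = 7) -> list[TargetSite]:
    """All maximal exact reverse-complement blocks of length >= ``min_site_len``.

    Implemented as maximal-run detection along every alignment diagonal
    between ``reverse_complement(core)`` and the UTR (sequence lengths
    here make this exact O(|core| * |UTR|) scan entirely adequate).
    """
    if isinstance(core, CoreSequence):
        core_id, core_seq = core.core_id or core.sequence, core.sequence
    else:
        core_id, core_seq = core, core
    rc = reverse_complement(core_seq)
    u = utr.sequence
    c_len, u_len = len(rc), len(u)
    sites: list[TargetSite] = []
    # diagonal d aligns rc[p] with u[p + d]
    for d in range(-(c_len - 1), u_len):
        p = max(0, -d)
        p_hi = min(c_len, u_len - d)
        while p < p_hi:
            if rc[p] == u[p + d]:
                run_start = p
                while p < p_hi and rc[p] == u[p + d]:
                    p += 1
                m = p - run_start
                if m >= min_site_len:
                    # map rc positions back onto the core
                    core_start = c_len - p
                    core_end = c_len - run_start
                    sites.append(TargetSite(
                        core_id=core_id, utr_id=utr.id,
                        utr_start=run_start + d, utr_end=p + d,
                        core_start=core_start, core_end=core_end,
                        match_len=m, matched_block=u[run_start + d:p + d]))
            else:
                p += 1
    sites.sort(key=lambda s: (-s.match_len, s.utr_start, s.core_start))
    return sites


def load_seeds(path: str | Path) -> list[SeedRecord]:
    """Read a mature-miRNA TSV (mirna_id, mature_sequence).

    Records with a mature sequence shorter than 8 nt cannot define a
    2-8 seed and are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["mirna_id", "mature_sequence"], comment="#")
    records: list[SeedRecord] = []
    for row in df.itertuples(index=False):
        mature = str(row.mature_sequence).upper().replace("T", "U")
        if len(mature) < 8:
            logger.warning("skipping %s: mature sequence %r shorter than 8 nt",
                           row.mirna_id, mature)
            continue
        records.append(SeedRecord(str(row.mirna_id), mature))
    return records


def seed_overlap(core: str, seeds: Iterable[SeedRecord],
                 k: int = 7) -> list[tuple[int, str, str]]:
    """Exact matches between the core's k-mer windows and miRNA seeds.

    Returns (window start, window k-mer, mirna_id) triples; one triple
    per (window, miRNA) equality.
    """
    by_seed: dict[str, list[str]] = {}
    for rec in seeds:
        if len(rec.mature_sequence) < 8:
            logger.warning("skipping %s: mature sequence shorter than 8 nt",
                           rec.mirna_id)
            continue
        by_seed.setdefault(rec.seed, []).append(rec.mirna_id)
    hits: list[tuple[int, str, str]] = []
    for start, window in kmer_windows(core, k):
        for mirna_id in by_seed.get(window, []):
            hits.append((start, window, mirna_id))
    return hits
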