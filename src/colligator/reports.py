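"""TSV report writers/readers shared by the CLI stages.

Internal coordinates are 0-based half-open; every column written here is
1-based inclusive. Readers invert the conversion so a written table
round-trips to the same in-memory objects.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_discovery import CoreSequence, CountedSequence
from .hairpin_analysis import Hairpin
from .read_processing import TrimmedRead
from .target_scan import TargetSite


def trimmed_to_frame(trimmed: Iterable[TrimmedRead]) -> pd.DataFrame:
    return pd.DataFrame([
        {"source_id": t.source_id, "insert": t.insert,
         "adapter_found": t.adapter_found,
         "adapter_start": (t.adapter_start + 1) if t.adapter_start is not None else 0,
         "polya_removed": t.polya_removed}
        for t in trimmed])


def frame_to_inserts(df: pd.DataFrame) -> list[str]:
    return [str(s) for s in df["insert"]]


def cores_to_frame(cores: Iterable[CoreSequence]) -> pd.DataFrame:
    return pd.DataFrame([
        {"core_id": c.core_id, "core_sequence": c.sequence,
         "core_length": len(c.sequence), "instance_count": c.instance_count,
         "n_members": len(c.members),
         "member_sequences": ";".join(f"{m.sequence}:{m.count}" for m in c.members)}
        for c in cores])


def frame_to_cores(df: pd.DataFrame) -> list[CoreSequence]:
    cores = []
    for row in df.itertuples(index=False):
        members = tuple(CountedSequence(*(lambda s, n: (s, int(n)))(*m.split(":")))
                        for m in str(row.member_sequences).split(";") if m)
        cores.append(CoreSequence(row.core_sequence, int(row.instance_count),
                                  members, row.core_id))
    return cores


def hairpins_to_frame(hairpins: Iterable[Hairpin]) -> pd.DataFrame:
    rows = []
    for h in hairpins:
        rows.append({
            "parent_id": h.parent_id, "start": h.start + 1, "end": h.end,
            "L": h.L, "loop_start": h.loop_start + 1, "loop_len": h.loop_len,
            "n_stem_pairs": h.n_stem_pairs, "gc_pair_count": h.gc_pair_count,
            "gc_nt_count": h.gc_nt_count,
            "dG": None if h.dG is None else round(h.dG, 4),
            "energy_source": h.energy_source,
            "stability_ratio": None if h.stability_ratio is None
            else round(h.stability_ratio, 4),
            "mfei": None if h.mfei is None else round(h.mfei, 4),
            "sequence": h.sequence, "structure": h.dot_bracket,
        })
    return pd.DataFrame(rows)


def frame_to_hairpins(df: pd.DataFrame) -> list[Hairpin]:
    """Rebuild hairpins from a report; stem pairs are recovered from the
    dot-bracket (perfect stems: k-th '(' pairs k-th-from-last ')')."""
    out = []
    for row in df.itertuples(index=False):
        start = int(row.start) - 1
        seq, db = str(row.sequence), str(row.structure)
        opens = [i for i, ch in enumerate(db) if ch == "("]
        closes = [i for i, ch in enumerate(db) if ch == ")"]
        pairs = tuple((start + i, start + j, seq[i] + seq[j])
                      for i, j in zip(opens, reversed(closes)))
        out.append(Hairpin(
            parent_id=str(row.parent_id), start=start, end=int(row.end),
            loop_start=int(row.loop_start) - 1, loop_len=int(row.loop_len),
            stem_pairs=pairs, sequence=seq,
            dG=float(row.dG), energy_source=str(row.energy_source)))
    return out


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame([
        {"core_id": s.core_id, "utr_id": s.utr_id,
         "utr_start": s.utr_start + 1, "utr_end": s.utr_end,
         "core_start": s.core_start + 1, "core_end": s.core_end,
         "match_len": s.match_len, "matched_block": s.matched_block}
        for s in sites])


def frame_to_sites(df: pd.DataFrame) -> list[TargetSite]:
    return [TargetSite(str(r.core_id), str(r.utr_id),
                       int(r.utr_start) - 1, int(r.utr_end),
                       int(r.core_start) - 1, int(r.core_end),
                       int(r.match_len), str(r.matched_block))
            for r in df.itertuples(index=False)]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
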