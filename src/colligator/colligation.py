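"""The triple-colligation join.

Three independent evidence streams are linked: (1) an abundant core
sequence from the sequencing reads, (2) a stable hairpin in an ncRNA
whose stem/loop contains that core, and (3) an exact reverse-complement
site for the core in the 3'UTR of a protein that is complexed with the
same ncRNA in a ribonucleoprotein particle. A record is emitted only when
all three predicates hold; each emitted record re-verifies its predicates
from the raw sequences as a defensive recheck.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_discovery import CoreSequence
from .hairpin_analysis import Hairpin
from .target_scan import TargetSite, reverse_complement


class ColligationError(ValueError):
    pass


@dataclass(frozen=True)
class RnpLink:
    """ncRNA <-> protein membership in an annotated RNP complex."""

    ncrna_id: str
    protein_gene_id: str
    complex_name: str = ""


@dataclass(frozen=True)
class ColligationThresholds:
    overlap_min: float = 0.8     # fraction of core bases inside the hairpin span
    min_ratio: float = 0.30      # stability ratio floor, kcal/mol/nt
    min_site_len: int = 7        # shortest UTR site accepted


@dataclass(frozen=True)
class CoreHairpinOverlap:
    fraction: float
    side: str | None  # "5'-side" | "loop" | "3'-side" | "mixed" | None


@dataclass(frozen=True)
class ColligationRecord:
    core_id: str
    core_sequence: str
    ncrna_id: str
    hairpin_start: int
    hairpin_end: int
    stability_ratio: float
    mfei: float | None
    overlap_fraction: float
    side: str | None
    protein_gene_id: str
    complex_name: str
    utr_id: str
    utr_start: int
    utr_end: int
    match_len: int
    core_in_stem: bool
    ratio_pass: bool
    site_pass: bool


def load_rnp_links(path: str | Path) -> list[RnpLink]:
    """Read an RNP membership TSV (ncrna_id, protein_gene_id, complex_name)."""
    df = pd.read_csv(path, sep="\t")
    required = {"ncrna_id", "protein_gene_id"}
    if not required.issubset(df.columns):
        raise ColligationError(f"{path}: missing columns {required - set(df.columns)}")
    links = [RnpLink(str(r.ncrna_id), str(r.protein_gene_id),
                     str(getattr(r, "complex_name", "")))
             for r in df.itertuples(index=False)]
    pairs = [(l.ncrna_id, l.protein_gene_id) for l in links]
    if len(pairs) != len(set(pairs)):
        raise ColligationError(f"{path}: duplicate (ncrna_id, protein_gene_id) pairs")
    return links


def locate_core_in_hairpin(core: CoreSequence | str, hairpin: Hairpin,
                           parent_seq: str) -> CoreHairpinOverlap:
    """Fraction of core bases inside the hairpin span, with a side call.

    The core is located in the parent by exact substring search (the
    occurrence maximizing overlap wins, leftmost on ties). The side
    annotation is by majority of overlapped bases over the hairpin's
    5'-side / loop / 3'-side regions; an exact tie is called "mixed".
    """
    core_seq = core.sequence if isinstance(core, CoreSequence) else core
    occurrences = []
    i = parent_seq.find(core_seq)
    while i != -1:
        occurrences.append(i)
        i = parent_seq.find(core_seq, i + 1)
    if not occurrences:
        return CoreHairpinOverlap(0.0, None)

    def overlap_at(pos: int) -> int:
        return max(0, min(pos + len(core_seq), hairpin.end) - max(pos, hairpin.start))

    best = max(occurrences, key=lambda pos: (overlap_at(pos), -pos))
    ov = overlap_at(best)
    if ov == 0:
        return CoreHairpinOverlap(0.0, None)
    loop_end = hairpin.loop_start + hairpin.loop_len
    regions = {
        "5'-side": (hairpin.start, hairpin.loop_start),
        "loop": (hairpin.loop_start, loop_end),
        "3'-side": (loop_end, hairpin.end),
    }
    counts = {name: max(0, min(best + len(core_seq), hi) - max(best, lo))
              for name, (lo, hi) in regions.items()}
    top = max(counts.values())
    winners = [name for name, c in counts.items() if c == top]
    side = winners[0] if len(winners) == 1 else "mixed"
    return CoreHairpinOverlap(ov / len(core_seq), side)


def colligate(cores: Sequence[CoreSequence], hairpins: Sequence[Hairpin],
              sites: Sequence[TargetSite], rnp_links: Sequence[RnpLink],
              parent_seqs: dict[str, str],
              thresholds: ColligationThresholds | None = None,
              utr_seqs: dict[str, str] | None = None) -> list[ColligationRecord]:
    """Three-way inner join of cores, hairpins, and UTR sites via RNP links.

    ``parent_seqs`` maps ncRNA id -> sequence (needed to locate cores in
    hairpins); ``utr_seqs``, when given, enables the site recheck against
    the raw UTR string. UTR ids are expected to equal the protein gene
    ids of the RNP table. One record per (core, hairpin, site) triple,
    sorted by (stability_ratio, match_len) descending.
    """
    th = thresholds or ColligationThresholds()
    links_by_ncrna: dict[str, list[RnpLink]] = {}
    for link in rnp_links:
        links_by_ncrna.setdefault(link.ncrna_id, []).append(link)
    sites_by_key: dict[tuple[str, str], list[TargetSite]] = {}
    for s in sites:
        sites_by_key.setdefault((s.core_id, s.utr_id), []).append(s)

    records: list[ColligationRecord] = []
    for h in hairpins:
        if h.parent_id not in parent_seqs:
            raise ColligationError(f"no sequence for ncRNA {h.parent_id!r}")
        if h.dG is None:
            raise ColligationError(f"hairpin {h.parent_id}:{h.start}-{h.end} lacks dG")
        ratio_pass = h.stability_ratio >= th.min_ratio
        if not ratio_pass:
            continue
        for core in cores:
            ov = locate_core_in_hairpin(core, h, parent_seqs[h.parent_id])
            if ov.fraction < th.overlap_min:
                continue
            for link in links_by_ncrna.get(h.parent_id, []):
                for site in sites_by_key.get((core.core_id, link.protein_gene_id), []):
                    if site.match_len < th.min_site_len:
                        continue
                    _recheck(core, h, site, parent_seqs[h.parent_id],
                             None if utr_seqs is None else utr_seqs.get(site.utr_id))
                    records.append(ColligationRecord(
                        core_id=core.core_id, core_sequence=core.sequence,
                        ncrna_id=h.parent_id,
                        hairpin_start=h.start, hairpin_end=h.end,
                        stability_ratio=h.stability_ratio, mfei=h.mfei,
                        overlap_fraction=ov.fraction, side=ov.side,
                        protein_gene_id=link.protein_gene_id,
                        complex_name=link.complex_name,
                        utr_id=site.utr_id, utr_start=site.utr_start,
                        utr_end=site.utr_end, match_len=site.match_len,
                        core_in_stem=True, ratio_pass=True, site_pass=True))
    records.sort(key=lambda r: (-r.stability_ratio, -r.match_len,
                                r.core_id, r.utr_start))
    return records


def _recheck(core: CoreSequence, h: Hairpin, site: TargetSite,
             parent_seq: str, utr_seq: str | None) -> None:
    """Defensive re-verification of the three predicates from raw inputs."""
    if core.sequence not in parent_seq:
        raise ColligationError(
            f"recheck failed: core {core.core_id} absent from {h.parent_id}")
    if h.dG is not None and abs(-h.dG / h.L - h.stability_ratio) > 1e-9:
        raise ColligationError("recheck failed: inconsistent stability ratio")
    expected = reverse_complement(core.sequence[site.core_start:site.core_end])
    if expected != site.matched_block:
        raise ColligationError(
            f"recheck failed: site block mismatch for {core.core_id}/{site.utr_id}")
    if utr_seq is not None and utr_seq[site.utr_start:site.utr_end] != site.matched_block:
        raise ColligationError(
            f"recheck failed: UTR {site.utr_id} does not carry the matched block")


def records_to_frame(records: Iterable[ColligationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = r.__dict__.copy()
        # user-facing 1-based inclusive coordinates; 4-decimal rounding
        d["hairpin_start"] += 1
        d["utr_start"] += 1
        for key in ("stability_ratio", "mfei", "overlap_fraction"):
            if d[key] is not None:
                d[key] = round(d[key], 4)
        rows.append(d)
    return pd.DataFrame(rows)
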