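"""End-to-end orchestration: trim -> cores -> hairpins -> targets -> colligate."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .colligation import (ColligationRecord, ColligationThresholds, RnpLink,
                          colligate)
from .core_discovery import CoreSequence, abundance_filter, collapse_exact, extract_cores
from .hairpin_analysis import EnergyParameters, Hairpin, scan_ncrna
from .read_processing import TrimConfig, TrimStats, trim_pipeline
from .sequence_io import NamedSequence, Read
from .target_scan import TargetSite, find_target_sites


@dataclass
class PipelineResult:
    trim_stats: TrimStats
    cores: list[CoreSequence]
    hairpins: list[Hairpin]
    sites: list[TargetSite]
    records: list[ColligationRecord]


def run_pipeline(reads: Sequence[Read], ncrnas: Sequence[NamedSequence],
                 utrs: Sequence[NamedSequence], rnp_links: Sequence[RnpLink],
                 *, trim_config: TrimConfig | None = None,
                 min_copies: int = 3, min_core_len: int = 16,
                 window: int = 50, step: int = 5, min_span: int = 25,
                 min_ratio: float = 0.30, min_site_len: int = 7,
                 thresholds: ColligationThresholds | None = None,
                 energy_params: EnergyParameters | None = None,
                 discarded_n: int = 0) -> PipelineResult:
    """Run the full analysis on in-memory inputs and return every stage's output."""
    trimmed, stats = trim_pipeline(reads, trim_config, discarded_n=discarded_n)
    counted = abundance_filter(collapse_exact(t.insert for t in trimmed), min_copies)
    cores = extract_cores(counted, min_core_len)

    hairpins: list[Hairpin] = []
    for nc in ncrnas:
        hairpins.extend(scan_ncrna(nc, window=window, step=step, min_span=min_span,
                                   min_ratio=min_ratio, params=energy_params))

    sites: list[TargetSite] = []
    for core in cores:
        for utr in utrs:
            sites.extend(find_target_sites(core, utr, min_site_len))

    parent_seqs = {nc.id: nc.sequence for nc in ncrnas}
    utr_seqs = {u.id: u.sequence for u in utrs}
    th = thresholds or ColligationThresholds(min_ratio=min_ratio,
                                             min_site_len=min_site_len)
    records = colligate(cores, hairpins, sites, rnp_links, parent_seqs,
                        thresholds=th, utr_seqs=utr_seqs)
    return PipelineResult(stats, cores, hairpins, sites, records)
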