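"""Synthetic library, ncRNA and 3'UTR generators with truth tables.

The generators emulate the statistical structure the analysis assumes:

* 35-base small-RNA reads consisting of an insert (a planted core,
  optionally with one or two random flanking bases), zero to four
  trailing A's, and the Illumina 3' adapter, truncated to the read
  length; background reads are uniform-random and rejection-sampled to
  contain no planted core.
* a 164-nt ncRNA with the canonical reconstruction of the planted core's
  hairpin embedded at a recorded offset, in a background rejection-
  sampled so no *other* hairpin passes the default screen; and
* a 3'UTR carrying exact reverse complements of configured core
  intervals (defaults: an 11-nt and a 9-nt block) at recorded offsets,
  in a background free of other complementary blocks of >= 7 nt.

Every generator is a pure function of the configuration (including its
seed): identical configurations produce byte-identical outputs. Truth
tables are first-class outputs — tests assert against them, never
against re-derived expectations.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .colligation import RnpLink
from .hairpin_analysis import reconstruct_hairpin, scan_ncrna
from .read_processing import ILLUMINA_3P_ADAPTER
from .sequence_io import NamedSequence, normalize_rna, write_fasta, write_fastq
from .target_scan import find_target_sites, reverse_complement

#: the 16-nt core the defaults plant (RNA spelling)
S_CORE = "UUCGCGCUUUCCCCUG"

_DNA_BASES = "ACGT"
_RNA_BASES = "ACGU"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generators, with desk-scale defaults.

    ``planted_sites`` are 0-based half-open intervals *of the core* whose
    reverse complements are embedded in the UTR.
    """

    rng_seed: int = 17
    n_reads: int = 10_000
    read_len: int = 35
    adapter: str = ILLUMINA_3P_ADAPTER
    planted_cores: tuple[tuple[str, int], ...] = ((S_CORE, 300),)
    polya_distribution: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    max_flank: int = 2
    ncrna_len: int = 164
    ncrna_id: str = "RNU1_like"
    planted_hairpin_core: str | None = S_CORE
    hairpin_loop_len: int = 4
    utr_len: int = 400
    utr_id: str = "SFRS1_like"
    planted_sites: tuple[tuple[int, int], ...] = ((5, 16), (0, 9))
    complex_name: str = "U1_snRNP_like"
    max_retries: int = 500

    def __post_init__(self) -> None:
        planted_total = sum(n for _s, n in self.planted_cores)
        if any(n < 1 for _s, n in self.planted_cores):
            raise SimulationError("planted abundances must be >= 1")
        if planted_total > self.n_reads:
            raise SimulationError(
                f"planted reads ({planted_total}) exceed n_reads ({self.n_reads})")
        probs = self.polya_distribution
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise SimulationError("polya_distribution must be probabilities summing to 1")
        max_insert = max((len(s) for s, _n in self.planted_cores), default=0) + self.max_flank
        max_polya = len(probs) - 1
        if self.planted_cores and max_insert + max_polya + 6 > self.read_len:
            raise SimulationError(
                f"insert ({max_insert}) + poly-A ({max_polya}) + 6 adapter bases "
                f"exceed read_len {self.read_len}")
        for s, _n in self.planted_cores:
            if normalize_rna(s).endswith("A"):
                raise SimulationError(
                    f"planted core {s!r} ends in A; poly-A trimming would erode it "
                    "and the truth table could not be exact")
        for cs, ce in self.planted_sites:
            ref = self.planted_hairpin_core or (
                self.planted_cores[0][0] if self.planted_cores else "")
            if not (0 <= cs < ce <= len(ref)):
                raise SimulationError(f"planted site interval ({cs},{ce}) outside core")

    @property
    def background_read_fraction(self) -> float:
        return 1.0 - sum(n for _s, n in self.planted_cores) / self.n_reads


def _random_seq(rng: random.Random, n: int, bases: str) -> str:
    return "".join(rng.choice(bases) for _ in range(n))


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def simulate_reads(config: SimulationConfig) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate the read library; returns (records, truth table).

    Records are (read_id, DNA sequence) pairs ready for FASTQ output;
    the truth table lists every read with its planted insert (RNA) and
    source core (empty for background reads).
    """
    rng = random.Random(f"{config.rng_seed}-reads")
    adapter = _to_dna(config.adapter)
    polya_sizes = list(range(len(config.polya_distribution)))
    records: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    def emit(insert_rna: str, core: str) -> None:
        n_a = rng.choices(polya_sizes, weights=config.polya_distribution)[0]
        read = (_to_dna(insert_rna) + "A" * n_a + adapter)[:config.read_len]
        read_id = f"read{len(records) + 1:06d}"
        records.append((read_id, read))
        truth_rows.append({"read_id": read_id, "insert": insert_rna,
                           "core": core, "polya": n_a})

    for core, abundance in config.planted_cores:
        core = normalize_rna(core)
        variants: list[tuple[str, int]] = []
        if abundance >= 15 and config.max_flank > 0:
            # a few exact-copy variants sharing the core, each abundant
            # enough to survive the >= 3 copies filter
            n_flank = abundance // 5
            flank5 = _random_seq(rng, rng.randint(1, config.max_flank), _RNA_BASES)
            flank3 = ("".join(rng.choice("CGU")  # avoid trailing A (poly-A erosion)
                              for _ in range(rng.randint(1, config.max_flank))))
            variants = [(core, abundance - 2 * n_flank),
                        (flank5 + core, n_flank),
                        (core + flank3, n_flank)]
        else:
            variants = [(core, abundance)]
        for insert, n in variants:
            for _ in range(n):
                emit(insert, core)

    planted_dna = [_to_dna(normalize_rna(s)) for s, _n in config.planted_cores]
    n_background = config.n_reads - sum(n for _s, n in config.planted_cores)
    for _ in range(n_background):
        while True:
            read = _random_seq(rng, config.read_len, _DNA_BASES)
            if not any(p in read for p in planted_dna):
                break
        read_id = f"read{len(records) + 1:06d}"
        records.append((read_id, read))
        truth_rows.append({"read_id": read_id, "insert": "", "core": "", "polya": 0})
    return records, pd.DataFrame(truth_rows)


def simulate_ncrna(config: SimulationConfig) -> tuple[NamedSequence, pd.DataFrame]:
    """Generate the ncRNA with (or without) the planted hairpin.

    The background is rejection-sampled until the default hairpin screen
    (window 50, step 5, span >= 25, ratio >= 0.30) reports exactly the
    planted span as its only (hence top-ranked) hairpin — or, when no
    core is planted, nothing at all.
    """
    rng = random.Random(f"{config.rng_seed}-ncrna")
    if config.planted_hairpin_core is None:
        for _ in range(config.max_retries):
            seq = _random_seq(rng, config.ncrna_len, _RNA_BASES)
            ncrna = NamedSequence(config.ncrna_id, seq, "ncRNA")
            if not scan_ncrna(ncrna):
                return ncrna, pd.DataFrame(
                    columns=["ncrna_id", "start", "end", "hairpin_sequence"])
        raise SimulationError(
            "could not sample a hairpin-free background; use a shorter "
            "sequence or looser screening criteria")
    hp = reconstruct_hairpin(normalize_rna(config.planted_hairpin_core),
                             config.hairpin_loop_len)
    if hp.L > config.ncrna_len:
        raise SimulationError(f"ncrna_len {config.ncrna_len} < hairpin length {hp.L}")
    for _ in range(config.max_retries):
        offset = rng.randrange(0, config.ncrna_len - hp.L + 1)
        bg = _random_seq(rng, config.ncrna_len - hp.L, _RNA_BASES)
        seq = bg[:offset] + hp.sequence + bg[offset:]
        ncrna = NamedSequence(config.ncrna_id, seq, "ncRNA")
        found = scan_ncrna(ncrna)
        if len(found) == 1 and (found[0].start, found[0].end) == (offset, offset + hp.L):
            truth = pd.DataFrame([{"ncrna_id": config.ncrna_id, "start": offset,
                                   "end": offset + hp.L,
                                   "hairpin_sequence": hp.sequence}])
            return ncrna, truth
    raise SimulationError(
        "rejection sampling exhausted: the planted hairpin kept gaining "
        "competitors or junction extensions; increase ncrna_len or max_retries")


def simulate_utr(config: SimulationConfig) -> tuple[NamedSequence, pd.DataFrame]:
    """Generate the UTR with planted reverse-complement blocks of the core."""
    rng = random.Random(f"{config.rng_seed}-utr")
    ref = config.planted_hairpin_core or (
        config.planted_cores[0][0] if config.planted_cores else None)
    if ref is None and config.planted_sites:
        raise SimulationError("planted_sites given but no core to derive blocks from")
    core = normalize_rna(ref) if ref else ""
    blocks = [(cs, ce, reverse_complement(core[cs:ce]))
              for cs, ce in config.planted_sites]
    min_needed = sum(len(b) for *_i, b in blocks) + 10 * (len(blocks) + 1)
    if config.utr_len < min_needed:
        raise SimulationError(f"utr_len {config.utr_len} too short; need >= {min_needed}")
    for _ in range(config.max_retries):
        seq = list(_random_seq(rng, config.utr_len, _RNA_BASES))
        offsets: list[int] = []
        cursor = 5
        for i, (_cs, _ce, block) in enumerate(blocks):
            remaining = sum(len(b) for *_x, b in blocks[i + 1:]) + 5 * (len(blocks) - i)
            off = rng.randrange(cursor, config.utr_len - len(block) - remaining + 1)
            seq[off:off + len(block)] = block
            offsets.append(off)
            cursor = off + len(block) + 5
        utr = NamedSequence(config.utr_id, "".join(seq), "UTR")
        if not blocks:
            if core and find_target_sites(core, utr):
                continue
            return utr, pd.DataFrame(columns=["utr_id", "utr_start", "utr_end",
                                              "core_start", "core_end", "length"])
        found = find_target_sites(core, utr)
        expected = {(off, off + len(b), cs, ce)
                    for off, (cs, ce, b) in zip(offsets, blocks)}
        got = {(s.utr_start, s.utr_end, s.core_start, s.core_end) for s in found}
        if got == expected:
            truth = pd.DataFrame([
                {"utr_id": config.utr_id, "utr_start": off,
                 "utr_end": off + len(b), "core_start": cs, "core_end": ce,
                 "length": len(b)}
                for off, (cs, ce, b) in zip(offsets, blocks)])
            return utr, truth
    raise SimulationError(
        "rejection sampling exhausted: background kept producing spurious or "
        "extended complementary blocks; increase utr_len or max_retries")


def simulate_rnp_links(config: SimulationConfig) -> list[RnpLink]:
    return [RnpLink(config.ncrna_id, config.utr_id, config.complex_name)]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    reads: list[tuple[str, str]]
    read_truth: pd.DataFrame
    ncrna: NamedSequence
    ncrna_truth: pd.DataFrame
    utr: NamedSequence
    utr_truth: pd.DataFrame
    rnp_links: list[RnpLink]


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate all pipeline inputs for one configuration."""
    config = config or SimulationConfig()
    reads, read_truth = simulate_reads(config)
    ncrna, ncrna_truth = simulate_ncrna(config)
    utr, utr_truth = simulate_utr(config)
    return SyntheticDataset(config, reads, read_truth, ncrna, ncrna_truth,
                            utr, utr_truth, simulate_rnp_links(config))


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write reads.fastq, ncrna.fa, utrs.fa, rnp_links.tsv and truth/*.tsv."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.fastq",
        "ncrna": outdir / "ncrna.fa",
        "utrs": outdir / "utrs.fa",
        "rnp_links": outdir / "rnp_links.tsv",
    }
    write_fastq(ds.reads, paths["reads"])
    write_fasta([ds.ncrna], paths["ncrna"])
    write_fasta([ds.utr], paths["utrs"])
    pd.DataFrame([l.__dict__ for l in ds.rnp_links]).to_csv(
        paths["rnp_links"], sep="\t", index=False)
    for name, df in [("reads", ds.read_truth), ("ncrna", ds.ncrna_truth),
                     ("utr", ds.utr_truth)]:
        df.to_csv(outdir / "truth" / f"{name}.tsv", sep="\t", index=False)
    return paths
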