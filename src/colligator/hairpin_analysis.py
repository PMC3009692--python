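"""Stem-loop enumeration, free-energy scoring, and hairpin reconstruction.

The model is deliberately restricted to *perfect* stem-loops: a run of
consecutive base pairs (Watson-Crick plus G-U wobble) closed by a
single-stranded loop, with no bulges, internal loops or multiloops. Free
energies are a nearest-neighbour sum — stacking terms over adjacent stem
pairs, a hairpin-loop initiation penalty, and a tetraloop bonus for a few
unusually stable loops — using a shipped, versioned parameter table.
Users who need energies from a full folding engine can override them per
hairpin span via :func:`load_external_energies`.

Two screening statistics are computed per hairpin of length L and free
energy dG:

* stability ratio = -dG / L  (kcal/mol per nucleotide), and
* MFEI = -dG / (number of G and C nucleotides in the hairpin),

the minimal-folding-free-energy-index style score used to screen
miRNA-precursor-like hairpins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

try:  # Python >= 3.9
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

from .sequence_io import NamedSequence

#: allowed stem pairs: Watson-Crick plus G-U wobble
PAIRABLE = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                      ("G", "U"), ("U", "G")})
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_RT = 0.616          # kcal/mol at 37 C
_JS_COEFF = 1.75     # Jacobson-Stockmayer loop-size extrapolation


class HairpinConfigError(ValueError):
    pass


class EnergyModelError(ValueError):
    pass


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


@dataclass
class Hairpin:
    """A perfect stem-loop within a parent sequence.

    All coordinates are 0-based half-open positions *in the parent*.
    ``stem_pairs`` is ordered outer -> inner as ``(i, j, pair_type)``
    tuples, e.g. ``(12, 39, "GC")``. ``sequence`` is the hairpin's span.
    """

    parent_id: str
    start: int
    end: int
    loop_start: int
    loop_len: int
    stem_pairs: tuple[tuple[int, int, str], ...]
    sequence: str
    dG: float | None = None
    energy_source: str = "internal-model"

    @property
    def L(self) -> int:
        return self.end - self.start

    @property
    def n_stem_pairs(self) -> int:
        return len(self.stem_pairs)

    @property
    def gc_pair_count(self) -> int:
        """Number of stem pairs of type G-C or C-G."""
        return sum(1 for *_ij, t in self.stem_pairs if t in ("GC", "CG"))

    @property
    def gc_nt_count(self) -> int:
        """Number of G and C nucleotides over the full hairpin span."""
        return sum(1 for b in self.sequence if b in "GC")

    @property
    def loop_sequence(self) -> str:
        off = self.loop_start - self.start
        return self.sequence[off:off + self.loop_len]

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * self.L
        for i, j, _t in self.stem_pairs:
            chars[i - self.start] = "("
            chars[j - self.start] = ")"
        return "".join(chars)

    @property
    def stability_ratio(self) -> float | None:
        return None if self.dG is None else -self.dG / self.L

    @property
    def mfei(self) -> float | None:
        if self.dG is None or self.gc_nt_count == 0:
            return None
        return -self.dG / self.gc_nt_count


@dataclass(frozen=True)
class HairpinScore:
    """The two screening statistics; ``ratio * L == mfei * gc_nt_count == -dG``."""

    stability_ratio: float
    mfei: float | None
    gc_nt_count: int


@dataclass(frozen=True)
class EnergyParameters:
    stack: dict
    loop_init: dict
    tetraloop_bonus: dict
    version: str

    def stack_energy(self, outer: tuple[str, str], inner: tuple[str, str]) -> float:
        key = f"{outer[0]}{inner[0]}/{outer[1]}{inner[1]}"
        if key in self.stack:
            return self.stack[key]
        rotated = f"{inner[1]}{outer[1]}/{inner[0]}{outer[0]}"
        if rotated in self.stack:
            return self.stack[rotated]
        raise EnergyModelError(f"no stacking energy for {key} (or rotated {rotated})")

    def loop_penalty(self, loop_len: int) -> float:
        if loop_len in self.loop_init:
            return self.loop_init[loop_len]
        largest = max(self.loop_init)
        if loop_len < min(self.loop_init):
            raise EnergyModelError(f"no initiation term for loop size {loop_len}")
        return self.loop_init[largest] + _JS_COEFF * _RT * math.log(loop_len / largest)


def load_energy_parameters(path: str | Path | None = None) -> EnergyParameters:
    """Load the shipped (or a user-supplied) nearest-neighbour table."""
    if path is None:
        data = yaml.safe_load(
            (_pkg_files("colligator") / "data" / "nn_energies.yaml").read_text())
    else:
        data = yaml.safe_load(Path(path).read_text())
    return EnergyParameters(stack=dict(data["stack"]),
                            loop_init={int(k): float(v) for k, v in data["loop_init"].items()},
                            tetraloop_bonus=dict(data.get("tetraloop_bonus", {})),
                            version=str(data.get("version", "unversioned")))


_DEFAULT_PARAMS: EnergyParameters | None = None


def default_energy_parameters() -> EnergyParameters:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_energy_parameters()
    return _DEFAULT_PARAMS


def _pair_type(a: str, b: str) -> str:
    return a + b


def _canonical_hairpin(seq: str, loop_start: int, loop_len: int, min_loop: int,
                       lo: int = 0, hi: int | None = None,
                       parent_id: str = "seq") -> Hairpin | None:
    """Extend a candidate loop placement outward to its maximal stem.

    Returns ``None`` for non-canonical placements: either the loop's end
    bases could pair (the structure belongs to a smaller loop) or no pair
    forms at all. Extension is bounded by ``[lo, hi)``.
    """
    hi = len(seq) if hi is None else hi
    if loop_len - 2 >= min_loop and can_pair(seq[loop_start], seq[loop_start + loop_len - 1]):
        return None
    i = loop_start - 1
    j = loop_start + loop_len
    pairs: list[tuple[int, int, str]] = []
    while i >= lo and j < hi and can_pair(seq[i], seq[j]):
        pairs.append((i, j, _pair_type(seq[i], seq[j])))
        i -= 1
        j += 1
    if not pairs:
        return None
    pairs.reverse()  # outer -> inner
    start, end = pairs[0][0], pairs[0][1] + 1
    return Hairpin(parent_id=parent_id, start=start, end=end,
                   loop_start=loop_start, loop_len=loop_len,
                   stem_pairs=tuple(pairs), sequence=seq[start:end])


def enumerate_hairpins(seq: str, min_stem_pairs: int, min_loop: int = 3,
                       max_loop: int = 30, parent_id: str = "seq") -> list[Hairpin]:
    """All maximal perfect stem-loops of a sequence (no energies yet).

    For every loop placement the stem is extended outward until a
    mismatch or the sequence end; hairpins with fewer than
    ``min_stem_pairs`` pairs are dropped. Maximality holds both outward
    (the while-loop runs to failure) and inward (placements whose loop
    ends could themselves pair are skipped as non-canonical duplicates).
    """
    if min_loop < 3:
        raise HairpinConfigError(f"min_loop must be >= 3 (got {min_loop}): "
                                 "shorter loops are sterically impossible")
    if min_stem_pairs < 1:
        raise HairpinConfigError("min_stem_pairs must be >= 1")
    out: list[Hairpin] = []
    seen: set[tuple[int, int, int, int]] = set()
    for loop_start in range(1, len(seq)):
        for loop_len in range(min_loop, max_loop + 1):
            if loop_start + loop_len >= len(seq):
                break
            h = _canonical_hairpin(seq, loop_start, loop_len, min_loop,
                                   parent_id=parent_id)
            if h is None or h.n_stem_pairs < min_stem_pairs:
                continue
            key = (h.start, h.end, h.loop_start, h.loop_len)
            if key not in seen:
                seen.add(key)
                out.append(h)
    out.sort(key=lambda h: (h.start, h.end, h.loop_start))
    return out


def hairpin_energy(h: Hairpin, params: EnergyParameters | None = None) -> float:
    """Nearest-neighbour free energy of a perfect stem-loop, kcal/mol.

    dG = sum of stacking terms over adjacent stem pairs
       + hairpin-loop initiation for the loop size
       + tetraloop bonus when the closing pair + loop matches the table.
    """
    params = params or default_energy_parameters()
    seq = h.sequence
    off = h.start

    def bases(pair: tuple[int, int, str]) -> tuple[str, str]:
        i, j, _t = pair
        return seq[i - off], seq[j - off]

    dg = params.loop_penalty(h.loop_len)
    for outer, inner in zip(h.stem_pairs, h.stem_pairs[1:]):
        dg += params.stack_energy(bases(outer), bases(inner))
    if h.loop_len == 4 and h.stem_pairs:
        c5, c3 = bases(h.stem_pairs[-1])  # closing (innermost) pair
        bonus = params.tetraloop_bonus.get(f"{c5}{h.loop_sequence}{c3}")
        if bonus is not None:
            dg += bonus
    return dg


def score_hairpin(h: Hairpin) -> HairpinScore:
    """Stability ratio and MFEI of an energy-annotated hairpin.

    MFEI is reported as ``None`` when the hairpin contains no G or C
    nucleotide; the hairpin itself is still usable via the ratio.
    """
    if h.dG is None:
        raise EnergyModelError("hairpin has no dG; run hairpin_energy first")
    mfei = None if h.gc_nt_count == 0 else -h.dG / h.gc_nt_count
    return HairpinScore(stability_ratio=-h.dG / h.L, mfei=mfei,
                        gc_nt_count=h.gc_nt_count)


def load_external_energies(path: str | Path) -> dict[tuple[str, int, int], float]:
    """Read externally computed energies (TSV: parent_id, start, end, dG).

    Input coordinates are 1-based inclusive (the user-facing convention);
    the returned keys are internal 0-based half-open spans.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["parent_id", "start", "end", "dG"],
                     dtype={"parent_id": str}, comment="#")
    table: dict[tuple[str, int, int], float] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end, dg = int(row.start), int(row.end), float(row.dG)
        except (TypeError, ValueError) as exc:
            raise EnergyModelError(f"{path}: line {row_no}: malformed row ({exc})")
        if end <= start:
            raise EnergyModelError(f"{path}: line {row_no}: end {end} <= start {start}")
        table[(row.parent_id, start - 1, end)] = dg
    return table


def scan_ncrna(seq: NamedSequence, window: int = 50, step: int = 5,
               min_span: int = 25, min_ratio: float = 0.30,
               min_loop: int = 3, max_loop: int = 30,
               min_stem_pairs: int = 2,
               params: EnergyParameters | None = None,
               external_energies: dict[tuple[str, int, int], float] | None = None,
               ) -> list[Hairpin]:
    """Sliding-window hairpin screen of one ncRNA.

    Candidate loop placements are taken inside ``window``-nt windows every
    ``step`` nt (one full-length window for short sequences); each stem is
    then re-extended in the full sequence, so window edges never clip a
    stem and duplicated spans across overlapping windows collapse.
    Hairpins are kept when span >= ``min_span`` and stability ratio >=
    ``min_ratio``, energy-annotated (external table overriding the
    internal model per span), and sorted by ratio descending.
    """
    params = params or default_energy_parameters()
    s = seq.sequence
    n = len(s)
    if n <= window:
        starts = [0]
    else:
        starts = list(range(0, n - window + 1, step))
        if starts[-1] != n - window:
            starts.append(n - window)
    seen: set[tuple[int, int, int, int]] = set()
    kept: list[Hairpin] = []
    for w in starts:
        w_end = min(n, w + window)
        for loop_start in range(w + 1, w_end):
            for loop_len in range(min_loop, max_loop + 1):
                if loop_start + loop_len >= w_end:
                    break
                h = _canonical_hairpin(s, loop_start, loop_len, min_loop,
                                       parent_id=seq.id)
                if h is None or h.n_stem_pairs < min_stem_pairs:
                    continue
                key = (h.start, h.end, h.loop_start, h.loop_len)
                if key in seen:
                    continue
                seen.add(key)
                if h.L < min_span:
                    continue
                ext = (external_energies or {}).get((seq.id, h.start, h.end))
                if ext is not None:
                    h.dG = ext
                    h.energy_source = "external-table"
                else:
                    h.dG = hairpin_energy(h, params)
                if h.stability_ratio >= min_ratio:
                    kept.append(h)
    kept.sort(key=lambda h: (-h.stability_ratio, h.start, h.end))
    return kept


def reconstruct_hairpin(core: str, loop_len: int = 4,
                        parent_id: str = "reconstructed") -> Hairpin:
    """Build the canonical hairpin that presents ``core`` as loop + 3' side.

    The core's first ``loop_len`` bases become the loop and the remainder
    the 3' side of the stem; the 5' side is the strict Watson-Crick
    reverse complement of the 3' side (no wobble), prepended. The result
    is a perfect stem-loop of length ``2*(len(core)-loop_len) + loop_len``.
    """
    if len(core) <= loop_len:
        raise HairpinConfigError(
            f"core length {len(core)} must exceed loop_len {loop_len}")
    loop = core[:loop_len]
    three_side = core[loop_len:]
    try:
        five_side = "".join(_WC[b] for b in reversed(three_side))
    except KeyError as exc:
        raise HairpinConfigError(f"cannot Watson-Crick-complement base {exc}")
    seq = five_side + loop + three_side
    stem_len = len(three_side)
    pairs = tuple((i, len(seq) - 1 - i, _pair_type(seq[i], seq[len(seq) - 1 - i]))
                  for i in range(stem_len))
    return Hairpin(parent_id=parent_id, start=0, end=len(seq),
                   loop_start=stem_len, loop_len=loop_len,
                   stem_pairs=pairs, sequence=seq)
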