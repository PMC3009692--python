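# Methods

This note records the models behind each stage, the defaults and why
they were chosen, and what the synthetic data does and does not emulate.

## Read cleanup

Small-RNA libraries sequence through the insert into the ligated 3'
adapter, so the insert boundary is the adapter's 5' end. A match is the
leftmost position where ≥ `min_adapter_prefix` (default 6) bases of the
adapter match exactly **and** the match runs to the read's 3' end or
covers the whole adapter. The anchoring condition prevents a chance
mid-read 6-mer from truncating an insert; in 35-base reads real adapters
are 3'-anchored by construction. Reads with no qualifying match are
discarded by default (`--keep-unanchored` reverses this): without the
adapter the insert's 3' boundary is unknown, and every downstream step
depends on exact string identity. Up to four trailing A's are then
removed (a hard cap, configurable), and inserts of 16–29 nt are kept.
Accounting is conservative by construction:
`reads_in = retained + discarded_no_adapter + discarded_length + discarded_N`,
with N-containing reads dropped at parse time.

Re-running the cleanup on its own retained output is a no-op under the
generator's conditions (planted inserts do not end in A); an insert whose
genuine 3' base is A followed by a sequenced poly-A tail longer than the
cap is indistinguishable from a shorter insert with a longer tail, and no
trimmer can recover that distinction.

## Core discovery

Inserts are collapsed to exact-copy counts; only sequences with ≥ 3
copies enter clustering. A core is an exact substring of ≥ 16 nt shared
by its cluster. Clustering is greedy and fully deterministic: at each
round, among all substrings of ≥ `min_core_len` contained in at least
two remaining sequences, take the longest (ties: highest total count of
containing sequences, then lexicographic), absorb every sequence
containing it, report the longest substring common to all absorbed
members, and repeat; sequences sharing nothing long enough become
singleton cores. A multiple-alignment-based grouping would do a similar
job but is not reproducible across aligner versions; the exact-substring
greedy is oracle-checkable (the test suite compares it against exhaustive
subset enumeration on small inputs) and independent of input order.

## Permutation null

The control asks whether scrambled versions of a core are as absent as
random chance predicts. `p_none(K, M, L, k) = (1 − 4^−k)^(K·M·(L−k+1))`
treats every (pattern, read, offset) triple as independent, ignoring
overlap dependence between nearby offsets; the Monte-Carlo estimator
(integer-encoded k-mers, vectorised) confirms the approximation within
three binomial standard errors at parameter settings where the expected
hit count is order 1. Distinct permutations are drawn by
shuffle-with-rejection against a seen-set, excluding the identity;
requesting more permutations than the multiset of bases admits is an
error that reports the available maximum. Probabilities are reported to
4 decimal places.

## Hairpin model

Only perfect stem-loops are modelled: consecutive pairs (Watson-Crick
plus G·U wobble) closed by a loop of 3–30 nt (defaults; loops < 3 nt are
sterically impossible). A full dynamic-programming folder would also
report bulged and branched structures, but the structures of interest
here are clean stems, and a restricted model is exactly enumerable: the
enumerator is tested for set equality against a brute-force oracle over
all (span, loop) placements. Reported hairpins are maximal — not
extendable outward, and the loop's end bases cannot themselves pair.

Energies are a nearest-neighbour sum: stacking terms over adjacent stem
pairs, a hairpin-loop initiation penalty (tabulated for sizes 3–9,
Jacobson–Stockmayer `+1.75·RT·ln(n/9)` beyond), and a bonus for a few
unusually stable tetraloops. The shipped table (`data/nn_energies.yaml`,
versioned) uses the standard Turner 2004 values for Watson-Crick stacks
and approximate values for wobble stacks and loop terms. Consequences:

* absolute dG values differ from full folding engines, so published
  per-hairpin scores are treated as *ordering* claims (the stable
  hairpin should outrank its siblings), not point targets;
* users needing engine-accurate energies can supply a per-span TSV
  (`load_external_energies`, 1-based inclusive coordinates) that
  overrides the internal model and marks `energy_source`.

Two scores per hairpin of length L: stability ratio −dG/L and MFEI
−dG/(G+C nucleotide count). They satisfy `ratio·L = MFEI·gc_nt_count`
(both equal −dG); the GC *pair* count of the stem is a separate field —
the reconstruction of the 16-nt core `UUCGCGCUUUCCCCUG` with a 4-nt loop
gives a 28-nt hairpin with 12 stem pairs of which 8 are C-G.

The sliding-window screen (window 50, step 5) limits where candidate
loops are sought, but each stem is re-extended in the full parent
sequence before reporting; otherwise window edges clip stems and emit
truncated duplicates. With the default window/step and loop bounds every
placement falls inside some window, so the screen's output is
window-invariant; the windows matter only when substituting an external
engine that must be fed bounded subsequences.

`reconstruct_hairpin` builds the canonical hairpin presenting a core as
loop + 3' stem side: the first `loop_len` bases become the loop and the
strict Watson-Crick reverse complement of the remainder is prepended as
the 5' side (the stem is described by its C-G bond count, implying
canonical pairs; wobble is allowed in *enumeration* but not in the
*construction*).

## Target scan

Sites are maximal exact reverse-complement blocks between core and UTR,
found by maximal-run detection along every alignment diagonal — an exact
O(|core|·|UTR|) scan, verified against an all-substrings oracle. The
default minimum site length is 7 (one seed length); longer matches such
as 9- or 11-nt blocks are *outputs*, not thresholds. No G·U wobble is
accepted on the target side. The seed-redundancy check compares the
core's 7-mer windows with seeds defined as mature miRNA positions 2–8
(1-based); matures shorter than 8 nt are skipped with a warning.

## Colligation

The join emits a record per (core, hairpin, site) triple when: the core
overlaps the hairpin span by ≥ `overlap_min` (default 0.8 — the
motivating core lies fully inside its hairpin, and the slack tolerates
ragged core ends); the hairpin's stability ratio is ≥ 0.30; and the site
is ≥ 7 nt in the 3'UTR of a protein RNP-linked to the hairpin's ncRNA
(UTR FASTA ids must equal the protein gene ids of the RNP table). The
side annotation is by majority of overlapped bases over 5'-side / loop /
3'-side, with exact ties reported as "mixed". Every emitted record
re-verifies its three predicates from the raw sequences. No significance
is attached to the join itself: there is no agreed null model for triple
co-occurrence, so thresholds are exposed rather than asserted.

## Synthetic data

The generators produce desk-scale inputs with the structural features
the pipeline assumes:

* **Reads** (default 10,000 per library): 35-base reads built as
  insert + 0–4 trailing A's (uniform over 0–4) + adapter, truncated to
  35 nt. The default plants the 16-nt core at 300 copies — 180 bare and
  two 60-copy flanked variants, so core clustering is actually
  exercised — against a uniform-random background rejection-sampled to
  contain no planted core. Planted cores may not end in A (the poly-A
  trimmer would erode them and the truth table could not be exact).
* **ncRNA** (default 164 nt): the reconstructed 28-nt hairpin embedded
  at a random recorded offset; the background is rejection-sampled until
  the default screen reports exactly the planted span (junction bases
  often extend the planted stem by chance — such draws are rejected).
* **3'UTR** (default 400 nt): reverse complements of core intervals
  [6,16] and [1,9] (1-based; an 11-nt and a 9-nt block) at recorded
  offsets, in a background rejection-sampled to contain no other
  complementary block of ≥ 7 nt.

Every generator is a pure function of its configuration, so identical
configs give byte-identical files. What the simulation does **not**
emulate: sequencing error, quality-score structure, realistic abundance
distributions (real libraries span counts from 3 to > 100,000),
expression differences between samples, or genomic multi-mapping.
Passing the planted-truth tests therefore demonstrates correctness of
the pipeline's logic under its own assumptions, not performance on real
libraries — in real data cores are ragged, hairpins compete, and the
rejection-sampled "no competitor" guarantee does not hold.

## Numerical and engineering choices

* Internal coordinates 0-based half-open everywhere; every user-facing
  table 1-based inclusive. Internal alphabet is RNA (T→U on input).
* Floating-point reports rounded to 4 decimals; internal computation at
  full double precision.
* Sorting tie-breaks are always total (count, then lexicographic or
  coordinates), so all outputs are reproducible bit-for-bit.
* Problem sizes in the test suite (10,000-read libraries, 100 ncRNA
  replicates, 500/200 oracle instances) keep the whole suite around ten
  seconds while still covering every code path; all generators scale to
  larger configurations if heavier validation is wanted.

## Known limitations

* The hairpin energy model ignores bulges, internal loops, multiloops,
  dangling ends and coaxial stacking; a hairpin interrupted by a 1-nt
  bulge is reported as two shorter stems or missed entirely.
* The adapter matcher is exact; a single sequencing error in the first
  six adapter bases loses the read.
* Core clustering is exact-substring based; SNP- or error-bearing copies
  of a core form separate members and may fall below the copy threshold.
* `p_none` assumes uniform base composition; biological reads are far
  from uniform (the closed form is a stated approximation, not a claim
  about real libraries).
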