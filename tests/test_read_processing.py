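import random

import pytest
from hypothesis import given, strategies as st

from colligator.read_processing import (TrimConfig, TrimConfigError, find_adapter,
                                        length_filter, trim_adapter, trim_pipeline,
                                        trim_polya)
from colligator.sequence_io import Read, normalize_rna

S_DNA = "TTCGCGCTTTCCCCTG"
ADAPTER = "TCTCGTATGCCGTCTTCTGCTTGAAA"


def brute_find_adapter(seq: str, adapter: str, min_prefix: int) -> int | None:
    """Scan every (position, prefix length) pair; leftmost anchored hit wins."""
    for i in range(len(seq)):
        for plen in range(min_prefix, len(adapter) + 1):
            if i + plen > len(seq):
                break
            if seq[i:i + plen] == adapter[:plen] and (
                    i + plen == len(seq) or plen == len(adapter)):
                return i
    return None


class TestTrimAdapter:
    def test_core_plus_adapter_prefix(self):
        read = Read("r", S_DNA + ADAPTER[:19])  # 16 + 19 = 35 bases
        tr = trim_adapter(read, TrimConfig())
        assert tr.adapter_found
        assert tr.insert == normalize_rna(S_DNA)
        assert tr.adapter_start == 16

    def test_no_adapter_is_flagged(self):
        tr = trim_adapter(Read("r", "ACGT" * 8), TrimConfig())
        assert not tr.adapter_found and tr.adapter_start is None

    def test_exact_six_base_prefix_at_read_end(self):
        read = Read("r", "ACGTACGTACGTACGT" + ADAPTER[:6])
        tr = trim_adapter(read, TrimConfig())
        assert tr.adapter_found and tr.insert == "ACGUACGUACGUACGU"

    def test_mid_read_six_mer_does_not_truncate(self):
        # the adapter 6-mer occurs mid-read but neither runs to the read
        # end nor covers the whole adapter, so it is not an adapter hit
        seq = ADAPTER[:6] + "GGGGGGGGGG" + ADAPTER[:8]
        pos = find_adapter(normalize_rna(seq), normalize_rna(ADAPTER), 6)
        assert pos == 16

    def test_matches_brute_force_scan(self):
        rng = random.Random(42)
        adapter = normalize_rna(ADAPTER)
        for _ in range(300):
            n = rng.randint(10, 40)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            if rng.random() < 0.5:  # often splice in a real adapter tail
                cut = rng.randint(0, n)
                seq = seq[:cut] + adapter[:n - cut]
            assert find_adapter(seq, adapter, 6) == brute_find_adapter(seq, adapter, 6)

    def test_min_prefix_longer_than_adapter_rejected(self):
        with pytest.raises(TrimConfigError):
            TrimConfig(adapter="ACGT", min_adapter_prefix=5)


class TestPolyA:
    @pytest.mark.parametrize("insert,cap,expected", [
        ("ACGUAA", 4, ("ACGU", 2)),
        ("ACGUAAAAA", 4, ("ACGUA", 4)),  # cap leaves the fifth A in place
        ("ACGU", 4, ("ACGU", 0)),
        ("AAAA", 2, ("AA", 2)),
    ])
    def test_examples(self, insert, cap, expected):
        assert trim_polya(insert, cap) == expected

    @given(st.text(alphabet="ACGU", max_size=30), st.integers(0, 6))
    def test_never_removes_more_than_cap_or_non_a(self, insert, cap):
        trimmed, n = trim_polya(insert, cap)
        assert n <= cap
        assert trimmed + "A" * n == insert


class TestLengthFilter:
    @pytest.mark.parametrize("length,keep", [(15, False), (16, True), (29, True), (30, False)])
    def test_boundaries(self, length, keep):
        assert length_filter("A" * length, TrimConfig()) is keep


class TestPipeline:
    def test_count_conservation_and_idempotence(self, default_reads):
        retained, stats = trim_pipeline(default_reads, TrimConfig())
        assert stats.conserved()
        assert stats.retained == len(retained)
        # retained inserts are fixed points: no adapter hit, no trailing A
        # beyond the already-applied cap, length in range
        config = TrimConfig()
        for tr in retained:
            again = trim_adapter(Read(tr.source_id, tr.insert), config)
            assert not again.adapter_found
            insert2, n_a = trim_polya(tr.insert, config.max_polya)
            assert insert2 == tr.insert and n_a == 0
            assert length_filter(tr.insert, config)

    def test_keep_unanchored_passes_reads_through(self):
        reads = [Read("r", "ACGTACGTACGTACGTACGT")]  # 20 nt, no adapter
        retained, stats = trim_pipeline(reads, TrimConfig(), keep_unanchored=True)
        assert stats.retained == 1 and retained[0].insert == "ACGUACGUACGUACGUACGU"

    def test_parse_time_n_discards_enter_conservation(self, default_reads):
        _retained, stats = trim_pipeline(default_reads[:100], discarded_n=7)
        assert stats.reads_in == 107 and stats.discarded_n == 7
        assert stats.conserved()
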