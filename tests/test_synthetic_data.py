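import pytest

from colligator.read_processing import ILLUMINA_3P_ADAPTER
from colligator.synthetic_data import (S_CORE, SimulationConfig, SimulationError,
                                       simulate_dataset, simulate_ncrna,
                                       simulate_reads, simulate_utr, write_dataset)


class TestConfigValidation:
    def test_insert_plus_adapter_must_fit(self):
        with pytest.raises(SimulationError, match="adapter bases"):
            SimulationConfig(planted_cores=(("ACGU" * 7, 10),))  # 28 + 4 + 6 > 35

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="summing to 1"):
            SimulationConfig(polya_distribution=(0.5, 0.6))

    def test_core_ending_in_a_rejected(self):
        with pytest.raises(SimulationError, match="ends in A"):
            SimulationConfig(planted_cores=(("UUCGCGCUUUCCCCUA", 10),))

    def test_planted_exceeding_total_rejected(self):
        with pytest.raises(SimulationError, match="exceed n_reads"):
            SimulationConfig(n_reads=100, planted_cores=((S_CORE, 200),))


class TestReads:
    def test_bare_core_reads_are_core_plus_adapter_prefix(self):
        config = SimulationConfig(n_reads=5, planted_cores=((S_CORE, 5),),
                                  polya_distribution=(1.0,), max_flank=0)
        records, truth = simulate_reads(config)
        expected = ("TTCGCGCTTTCCCCTG" + ILLUMINA_3P_ADAPTER)[:35]
        assert len(records) == 5
        assert all(seq == expected for _i, seq in records)
        assert list(truth["insert"]) == [S_CORE] * 5

    def test_empty_library(self):
        config = SimulationConfig(n_reads=0, planted_cores=())
        records, truth = simulate_reads(config)
        assert records == [] and truth.empty

    def test_background_never_contains_a_planted_core(self):
        records, truth = simulate_reads(SimulationConfig(rng_seed=3))
        background = [seq for (rid, seq), core in zip(records, truth.core)
                      if core == ""]
        assert background
        assert all("TTCGCGCTTTCCCCTG" not in seq for seq in background)

    def test_truth_counts_match_configuration(self):
        config = SimulationConfig(rng_seed=8)
        _records, truth = simulate_reads(config)
        assert (truth.core == S_CORE).sum() == config.planted_cores[0][1]
        assert len(truth) == config.n_reads


class TestNcrna:
    def test_planted_hairpin_at_recorded_offset(self):
        config = SimulationConfig(rng_seed=31)
        ncrna, truth = simulate_ncrna(config)
        row = truth.iloc[0]
        assert len(ncrna.sequence) == config.ncrna_len
        assert ncrna.sequence[row.start:row.end] == row.hairpin_sequence
        assert S_CORE in row.hairpin_sequence

    def test_background_only_has_no_qualifying_hairpin(self):
        from colligator.hairpin_analysis import scan_ncrna
        config = SimulationConfig(rng_seed=31, planted_hairpin_core=None)
        ncrna, truth = simulate_ncrna(config)
        assert truth.empty and scan_ncrna(ncrna) == []


class TestUtr:
    def test_planted_blocks_at_recorded_offsets(self):
        from colligator.target_scan import reverse_complement
        config = SimulationConfig(rng_seed=41)
        utr, truth = simulate_utr(config)
        assert len(utr.sequence) == config.utr_len
        for row in truth.itertuples(index=False):
            block = utr.sequence[row.utr_start:row.utr_end]
            assert block == reverse_complement(S_CORE[row.core_start:row.core_end])

    def test_no_planted_blocks_no_sites(self):
        from colligator.target_scan import find_target_sites
        config = SimulationConfig(rng_seed=41, planted_sites=())
        utr, truth = simulate_utr(config)
        assert truth.empty and find_target_sites(S_CORE, utr) == []


class TestDeterminism:
    def test_identical_config_gives_byte_identical_outputs(self, tmp_path):
        config = SimulationConfig(rng_seed=77, n_reads=500,
                                  planted_cores=((S_CORE, 50),))
        for d in ("a", "b"):
            write_dataset(simulate_dataset(config), tmp_path / d)
        for rel in ["reads.fastq", "ncrna.fa", "utrs.fa", "rnp_links.tsv",
                    "truth/reads.tsv", "truth/ncrna.tsv", "truth/utr.tsv"]:
            assert (tmp_path / "a" / rel).read_bytes() == \
                   (tmp_path / "b" / rel).read_bytes(), rel

    def test_different_seeds_differ(self):
        a, _ = simulate_reads(SimulationConfig(rng_seed=1, n_reads=50,
                                               planted_cores=()))
        b, _ = simulate_reads(SimulationConfig(rng_seed=2, n_reads=50,
                                               planted_cores=()))
        assert a != b
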