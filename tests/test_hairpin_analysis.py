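import random
import subprocess

import pytest
import yaml

from colligator.hairpin_analysis import (EnergyModelError, Hairpin,
                                         HairpinConfigError, default_energy_parameters,
                                         enumerate_hairpins, hairpin_energy,
                                         load_external_energies,
                                         load_energy_parameters,
                                         reconstruct_hairpin, scan_ncrna,
                                         score_hairpin)
from colligator.sequence_io import NamedSequence
from colligator.synthetic_data import SimulationConfig, simulate_ncrna
from oracles import brute_hairpins

S = "UUCGCGCUUUCCCCUG"


def _keys(hairpins):
    return {(h.start, h.end, h.loop_start, h.loop_len) for h in hairpins}


class TestEnumerate:
    def test_perfect_gc_stem(self):
        hps = enumerate_hairpins("GGGAAAACCC", min_stem_pairs=3)
        assert len(hps) == 1
        h = hps[0]
        assert h.n_stem_pairs == 3 and h.loop_sequence == "AAAA"
        assert h.gc_pair_count == 3 and (h.start, h.end) == (0, 10)
        assert h.dot_bracket == "(((....)))"

    def test_unpairable_sequence(self):
        assert enumerate_hairpins("A" * 10, min_stem_pairs=1) == []

    def test_min_loop_below_three_rejected(self):
        with pytest.raises(HairpinConfigError):
            enumerate_hairpins("GGGAAAACCC", 1, min_loop=2)

    def test_matches_brute_force_on_random_sequences(self):
        rng = random.Random(1234)
        for _ in range(100):
            n = rng.randint(8, 20)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            got = _keys(enumerate_hairpins(seq, min_stem_pairs=2))
            assert got == brute_hairpins(seq, min_stem_pairs=2), seq


class TestEnergy:
    def test_hand_summed_against_shipped_table(self):
        import importlib.resources as res
        raw = yaml.safe_load(
            (res.files("colligator") / "data" / "nn_energies.yaml").read_text())
        h = enumerate_hairpins("GGGAAAACCC", min_stem_pairs=3)[0]
        # two GG/CC stacks plus the 4-loop initiation; loop GAAAAC has no bonus
        expected = 2 * raw["stack"]["GG/CC"] + raw["loop_init"][4]
        assert hairpin_energy(h) == pytest.approx(expected)

    def test_single_pair_is_loop_initiation_only(self):
        h = enumerate_hairpins("GAAAC", min_stem_pairs=1)[0]
        assert h.n_stem_pairs == 1
        params = default_energy_parameters()
        assert hairpin_energy(h) == pytest.approx(
            params.loop_penalty(3) if h.loop_len == 3 else params.loop_penalty(h.loop_len))

    def test_deterministic(self):
        h = enumerate_hairpins("GGGAAAACCC", 3)[0]
        assert hairpin_energy(h) == hairpin_energy(h)

    def test_large_loop_extrapolation_monotone(self):
        params = default_energy_parameters()
        assert params.loop_penalty(30) > params.loop_penalty(9)

    def test_gc_extension_never_raises_dg(self):
        params = default_energy_parameters()
        prev = None
        for n_gc in range(2, 8):
            core = "UUCG" + "C" * n_gc
            h = reconstruct_hairpin(core)
            dg = hairpin_energy(h, params)
            if prev is not None:
                assert dg <= prev
            prev = dg


class TestScore:
    def test_ratio_at_threshold_arithmetic(self):
        h = reconstruct_hairpin(S)
        h.dG = -8.4
        score = score_hairpin(h)
        assert score.stability_ratio == pytest.approx(8.4 / 28)

    def test_mfei_arithmetic_and_identity(self):
        h = reconstruct_hairpin(S)
        h.dG = -9.0
        s = score_hairpin(h)
        assert s.mfei == pytest.approx(9.0 / h.gc_nt_count)
        assert s.stability_ratio * h.L == pytest.approx(s.mfei * s.gc_nt_count)

    def test_mfei_missing_without_gc(self):
        h = reconstruct_hairpin("AAAAUUUU")
        h.dG = -2.0
        s = score_hairpin(h)
        assert s.mfei is None and s.stability_ratio == pytest.approx(2.0 / 12)


class TestReconstruct:
    def test_s_yields_the_28nt_hairpin(self):
        h = reconstruct_hairpin(S, 4)
        assert h.L == 28
        assert h.n_stem_pairs == 12
        assert h.gc_pair_count == 8
        assert h.loop_sequence == S[:4]
        assert h.sequence.endswith(S[4:])

    def test_au_only_core(self):
        h = reconstruct_hairpin("AAAAUUUU", 4)
        assert h.L == 12 and h.n_stem_pairs == 4 and h.gc_pair_count == 0

    def test_round_trip_through_enumerator(self):
        h = reconstruct_hairpin(S, 4)
        found = enumerate_hairpins(h.sequence, min_stem_pairs=h.n_stem_pairs)
        assert (h.start, h.end, h.loop_start, h.loop_len) in _keys(found)

    def test_core_not_longer_than_loop_rejected(self):
        with pytest.raises(HairpinConfigError):
            reconstruct_hairpin("ACGU", 4)


class TestScan:
    def test_planted_hairpin_recovered_and_top_ranked(self):
        config = SimulationConfig(rng_seed=101)
        ncrna, truth = simulate_ncrna(config)
        hits = scan_ncrna(ncrna)
        row = truth.iloc[0]
        assert hits and (hits[0].start, hits[0].end) == (row.start, row.end)

    def test_all_a_sequence_empty(self):
        assert scan_ncrna(NamedSequence("x", "A" * 164)) == []

    def test_window_larger_than_sequence(self):
        seq = NamedSequence("x", reconstruct_hairpin(S).sequence)
        assert len(scan_ncrna(seq, window=500)) == len(scan_ncrna(seq, window=50))

    def test_scored_hairpins_satisfy_identity(self):
        config = SimulationConfig(rng_seed=55)
        ncrna, _ = simulate_ncrna(config)
        for h in scan_ncrna(ncrna):
            if h.mfei is not None:
                assert h.stability_ratio * h.L == pytest.approx(h.mfei * h.gc_nt_count)


class TestExternalEnergies:
    def test_override_marks_source(self, tmp_path):
        config = SimulationConfig(rng_seed=101)
        ncrna, truth = simulate_ncrna(config)
        row = truth.iloc[0]
        table_path = tmp_path / "dg.tsv"
        # user-facing coordinates are 1-based inclusive
        table_path.write_text(f"{ncrna.id}\t{row.start + 1}\t{row.end}\t-16.5\n")
        ext = load_external_energies(table_path)
        hits = scan_ncrna(ncrna, external_energies=ext)
        top = hits[0]
        assert top.energy_source == "external-table"
        assert top.dG == pytest.approx(-16.5)

    def test_empty_file_means_no_overrides(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert load_external_energies(p) == {}

    def test_reversed_span_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("x\t10\t5\t-1.0\n")
        with pytest.raises(EnergyModelError, match="line 1"):
            load_external_energies(p)


class TestViennaCrossCheck:
    def test_reconstructed_hairpin_folds_as_a_single_stem_loop(self, tmp_path):
        """Independent check with RNAfold: the reconstruction of S folds
        into one hairpin whose paired region covers our predicted stem."""
        h = reconstruct_hairpin(S, 4)
        out = subprocess.run(["RNAfold", "--noPS"], input=h.sequence + "\n",
                             capture_output=True, text=True, check=True,
                             cwd=tmp_path)
        structure = out.stdout.splitlines()[1].split()[0]
        assert structure.count("(") >= 10
        # a single stem-loop: all '(' precede all ')'
        assert structure.rindex("(") < structure.index(")")
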