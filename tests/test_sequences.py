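"""Sequence parsing, repeat notation, and benchmark fixture integrity."""

import pytest

from imogfold import (
    HPSequence,
    SequenceParseError,
    benchmark,
    builtin_benchmarks,
    expand_notation,
    parse_hp_string,
    read_sequence_file,
)


class TestExpandNotation:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("(010)_2", "010010"),
            ("(010)_2_", "010010"),
            ("(1)_7", "1111111"),
            ("(010)2", "010010"),  # underscore-free dialect
            ("0110", "0110"),
            ("", ""),
        ],
    )
    def test_expansion(self, raw, expected):
        assert expand_notation(raw) == expected

    def test_mixed_literals_and_groups(self):
        out = expand_notation("1(100)_2_1(001)_5_1")
        assert out == "1" + "100" * 2 + "1" + "001" * 5 + "1"
        assert len(out) == 24

    def test_output_length_is_sum_of_parts(self):
        # length = literals + sum(group length * repeat)
        out = expand_notation("01(10)_3_1(0)_4_")
        assert len(out) == 2 + 2 * 3 + 1 + 1 * 4
        assert set(out) <= {"0", "1"}

    @pytest.mark.parametrize(
        "raw",
        [
            "(010_2",        # unbalanced open
            "010)_2",        # unbalanced close
            "(010)",         # missing repeat count
            "((01)_2)_3",    # nested
            "(0a0)_2",       # non-binary symbol in group
            "01x",           # non-binary symbol outside
            "()_3",          # empty group
        ],
    )
    def test_malformed_notation_rejected_with_position(self, raw):
        with pytest.raises(SequenceParseError) as err:
            expand_notation(raw)
        assert "position" in str(err.value)


class TestParseHPString:
    def test_letters(self):
        seq = parse_hp_string("HHPPHPHPHPHPHP")
        assert seq.n == 14
        assert seq.hydrophobic_indices == (1, 2, 5, 7, 9, 11, 13)

    def test_binary_default_convention_maps_one_to_h(self):
        seq = parse_hp_string("110101010101")
        assert str(seq) == "HHPHPHPHPHPH"
        assert len(seq.hydrophobic_indices) == 7

    def test_inverse_convention(self):
        seq = parse_hp_string("10", one_is="P")
        assert str(seq) == "PH"

    def test_lowercase_letters_accepted(self):
        assert str(parse_hp_string("hph")) == "HPH"

    @pytest.mark.parametrize("bad", ["", "  ", "H1P0", "HXP", "2010"])
    def test_rejects_empty_mixed_and_unknown(self, bad):
        with pytest.raises(SequenceParseError):
            parse_hp_string(bad)

    def test_hpsequence_rejects_bad_residues(self):
        with pytest.raises(SequenceParseError):
            HPSequence("HPX")


class TestBenchmarks:
    def test_table_sizes(self):
        assert len(builtin_benchmarks(1)) == 8
        assert len(builtin_benchmarks(2)) == 20

    def test_every_entry_expands_to_its_stated_length(self):
        # the transcription lock: notation, expansion and stated length agree
        for table in (1, 2):
            for entry in builtin_benchmarks(table):
                assert entry.sequence.n == entry.stated_length, (
                    f"table {table} entry {entry.index}"
                )

    def test_stated_energies_are_nonpositive_or_absent(self):
        for table in (1, 2):
            for entry in builtin_benchmarks(table):
                assert entry.stated_best_energy is None or entry.stated_best_energy < 0

    def test_table1_first_entry(self):
        entry = benchmark(1, 1)
        assert entry.stated_length == 20
        assert entry.stated_best_energy == -15

    def test_table1_long_rows_have_no_printed_energy(self):
        assert benchmark(1, 7).stated_best_energy is None
        assert benchmark(1, 8).stated_best_energy is None

    def test_table2_last_entry(self):
        entry = benchmark(2, 20)
        assert entry.stated_length == 37
        assert entry.stated_best_energy == -29

    def test_table2_entry7_is_all_hydrophobic(self):
        entry = benchmark(2, 7)
        assert str(entry.sequence) == "H" * 17
        assert entry.stated_best_energy == -17

    def test_bad_table_rejected(self):
        with pytest.raises(ValueError):
            builtin_benchmarks(3)


class TestSequenceFiles:
    def test_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "seqs.tsv"
        p.write_text("a\tHPHH\nb\t1(10)_2_\n# comment\n\nHPPH\n")
        seqs = read_sequence_file(p)
        assert [str(s) for s in seqs] == ["HPHH", "HHPHP", "HPPH"]
        assert seqs[0].label == "a"
        assert seqs[2].label == ""  # bare line without a label column

    def test_fasta(self, tmp_path):
        p = tmp_path / "seqs.fa"
        p.write_text(">s1 demo\nHPH\nPH\n>s2\nHH\n")
        seqs = read_sequence_file(p)
        assert [str(s) for s in seqs] == ["HPHPH", "HH"]
        assert seqs[0].label == "s1"

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("x\tHPQ\n")
        with pytest.raises(SequenceParseError) as err:
            read_sequence_file(p)
        assert "bad.tsv:1" in str(err.value)
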