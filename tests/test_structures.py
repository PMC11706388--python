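"""Dot-bracket parsing, pseudoknot detection and region decomposition."""

import pytest

from treepoly import (
    decompose,
    detect_pseudoknots,
    parse_dot_bracket,
    read_structure_file,
    strip_pseudoknots,
)
from treepoly.structures import ParseError, PseudoknotError, SecondaryStructure, write_dbn
from treepoly.synthetic import GeneratorParams, random_structure


class TestParsing:
    @pytest.mark.parametrize(
        "db,n_pairs,length",
        [
            (".", 0, 1),
            ("((...))", 2, 7),
            ("", 0, 0),
            ("(((...)))..((..))", 5, 17),
        ],
    )
    def test_pair_count_and_length(self, db, n_pairs, length):
        ss = parse_dot_bracket(db)
        assert len(ss.pairs) == n_pairs
        assert ss.length == length

    def test_simple_stack_matching(self):
        assert parse_dot_bracket("((...))").pairs == {(1, 7), (2, 6)}

    def test_positions_are_one_based(self):
        assert parse_dot_bracket("(.)").pairs == {(1, 3)}

    @pytest.mark.parametrize("db,pos", [("((.)", 1), (".))", 2), ("(].", 2)])
    def test_unbalanced_brackets_name_position(self, db, pos):
        with pytest.raises(ParseError, match=f"position {pos}"):
            parse_dot_bracket(db)

    def test_sequence_length_mismatch(self):
        with pytest.raises(ParseError, match="length"):
            parse_dot_bracket("((...))", "ACG")

    def test_sequence_t_converted_to_u(self):
        ss = parse_dot_bracket("....", "ACGT")
        assert ss.sequence == "ACGU"

    def test_extended_brackets_give_crossing_pairs(self):
        ss = parse_dot_bracket("((.[[..)).]]")
        assert detect_pseudoknots(ss)


class TestPseudoknots:
    def test_nested_structure_has_none(self):
        assert detect_pseudoknots(parse_dot_bracket("((...))")) == []

    def test_crossing_pair_detected(self):
        ss = SecondaryStructure(length=8, pairs=frozenset({(1, 5), (3, 8)}))
        assert detect_pseudoknots(ss) == [((1, 5), (3, 8))]

    def test_generator_structures_are_knot_free(self, random_structures):
        for ss in random_structures:
            assert detect_pseudoknots(ss) == []

    def test_strip_removes_later_opening_pair(self):
        ss = SecondaryStructure(length=8, pairs=frozenset({(1, 5), (3, 8)}))
        stripped = strip_pseudoknots(ss)
        assert stripped.pairs == {(1, 5)}

    def test_decompose_rejects_crossings(self):
        ss = SecondaryStructure(length=8, pairs=frozenset({(1, 5), (3, 8)}))
        with pytest.raises(PseudoknotError):
            decompose(ss)


class TestWorkedExampleDecomposition:
    """Every feature of the 41-nt worked example."""

    def test_length_and_pairs(self, worked_example):
        db, expected = worked_example
        ss = parse_dot_bracket(db)
        assert ss.length == expected["length"] == 41
        assert len(ss.pairs) == expected["n_pairs"] == 11

    def test_stem_sizes(self, worked_decomp):
        assert sorted(worked_decomp.stem_sizes()) == [2, 2, 2, 2, 3]

    def test_loop_sizes(self, worked_decomp):
        sizes = {k: sorted(v) for k, v in worked_decomp.loop_sizes().items()}
        assert sizes == {
            "opening": [3],
            "interior": [2],
            "multiloop": [6],
            "hairpin": [3, 4],
            "bulge": [1],
        }

    def test_loop_groups(self, worked_decomp):
        groups = {}
        for lp in worked_decomp.loops:
            groups.setdefault(lp.kind, []).append(sorted(lp.group_sizes))
        assert sorted(groups["opening"][0]) == [1, 2]
        assert groups["interior"][0] == [1, 1]
        assert sorted(groups["multiloop"][0]) == [1, 1, 4]
        assert groups["bulge"][0] == [1]
        assert sorted(g[0] for g in groups["hairpin"]) == [3, 4]

    def test_branch_linearity(self, worked_decomp):
        # the two hairpin-bearing branches below the multiloop are linear;
        # branches containing the multiloop are not
        kinds = {b.stem: b.is_linear for b in worked_decomp.branches}
        linear_flags = sorted(kinds.values())
        assert linear_flags.count(False) == 2  # outer stem and interior-loop stem
        assert linear_flags.count(True) == 3


class TestDecompositionInvariants:
    def test_conservation_identity(self, random_structures):
        for ss in random_structures:
            d = decompose(ss)
            assert 2 * sum(d.stem_sizes()) + sum(lp.size for lp in d.loops) == ss.length

    def test_loops_equal_stems_plus_one(self, random_structures):
        for ss in random_structures:
            d = decompose(ss)
            assert len(d.loops) == len(d.stems) + 1

    def test_every_nucleotide_assigned_once(self, random_structures):
        for ss in random_structures:
            d = decompose(ss)
            assigned = []
            for st in d.stems:
                for i, j in st.pairs:
                    assigned.extend((i, j))
            for lp in d.loops:
                assigned.extend(lp.unpaired_positions)
            assert sorted(assigned) == list(range(1, ss.length + 1))

    def test_mirror_symmetry_preserves_loop_kinds(self, random_structures):
        for ss in random_structures[:20]:
            db = ss.to_dot_bracket()
            mirror = db[::-1].translate(str.maketrans("()", ")("))
            d1, d2 = decompose(ss), decompose(parse_dot_bracket(mirror))
            assert {k: sorted(v) for k, v in d1.loop_sizes().items()} == {
                k: sorted(v) for k, v in d2.loop_sizes().items()
            }
            assert sorted(d1.stem_sizes()) == sorted(d2.stem_sizes())

    def test_zero_pair_structure_is_single_opening(self):
        d = decompose(parse_dot_bracket("....."))
        assert len(d.loops) == 1
        assert d.opening.kind == "opening"
        assert d.opening.size == 5
        assert d.opening.group_sizes == [5]

    def test_lonely_pair_is_a_stem(self):
        d = decompose(parse_dot_bracket("(...)"))
        assert d.stem_sizes() == [1]
        assert d.stems[0].n_stem_regions == 0


class TestFileIO:
    def test_dbn_roundtrip_preserves_pairs(self, tmp_path, random_structures):
        records = [(f"s{i}", ss) for i, ss in enumerate(random_structures[:50])]
        path = tmp_path / "batch.dbn"
        write_dbn(records, path)
        back = read_structure_file(path, format="dbn")
        assert len(back) == 50
        for (rid, orig), (rid2, loaded) in zip(records, back):
            assert rid == rid2
            assert orig.pairs == loaded.pairs

    def test_two_record_dbn(self, tmp_path):
        path = tmp_path / "two.dbn"
        path.write_text(">a\nACGUACG\n((...))\n>b\n.....\n")
        recs = read_structure_file(path)
        assert [(r, s.length) for r, s in recs] == [("a", 7), ("b", 5)]

    def test_bprna_st_reader_skips_annotations(self, tmp_path):
        path = tmp_path / "rec.st"
        path.write_text(
            "#Name: bpRNA_TEST_1\n#Length: 7\n"
            "ACGUACG\n((...))\nSSHHHSS\nNNNNNNN\n"
        )
        recs = read_structure_file(path, format="bpRNA_st")
        assert recs[0][0] == "bpRNA_TEST_1"
        assert recs[0][1].pairs == {(1, 7), (2, 6)}

    def test_st_record_with_pseudoknot_is_flagged(self, tmp_path):
        path = tmp_path / "pk.st"
        path.write_text("#Name: pk\nACGUACGUACGU\n((.[[..)).]]\n")
        (rid, ss), = read_structure_file(path, format="bpRNA_st")
        assert detect_pseudoknots(ss)

    def test_malformed_record_names_it(self, tmp_path):
        path = tmp_path / "bad.dbn"
        path.write_text(">broken\n((..\n")
        with pytest.raises(ParseError, match="broken"):
            read_structure_file(path)
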