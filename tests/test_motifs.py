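"""Stem/loop decomposition, instance generation, fixtures, and the oracle."""

import numpy as np
import pytest

from rnaloopkit.motifs import (
    Stem,
    brute_force_decompose,
    decompose_loops,
    find_stems,
    generate_random_structure,
    junction_features,
    make_instances,
)
from rnaloopkit.structio import SecondaryStructure, parse_dotbracket


def loop_signature(loops):
    return sorted(
        (L.loop_class, tuple(sorted(L.strand_lengths)))
        for L in loops
    )


class TestFindStems:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("((...))", [((1, 7), (2, 6))]),
            ("(.((...)).)", [((1, 11),), ((3, 9), (4, 8))]),
            (
                "((..((...))..((...))..))",
                [((1, 24), (2, 23)), ((5, 11), (6, 10)), ((14, 20), (15, 19))],
            ),
        ],
    )
    def test_examples(self, db, expected):
        assert [s.pairs for s in find_stems(parse_dotbracket(db))] == expected

    def test_non_nested_rejected(self):
        ss = SecondaryStructure(10, frozenset({(1, 6), (4, 9)}))
        with pytest.raises(ValueError, match="pseudoknot"):
            find_stems(ss)

    def test_lone_pair_is_a_stem(self):
        stems = find_stems(parse_dotbracket("(...)"))
        assert stems == [Stem(((1, 5),))]


class TestDecompose:
    def test_three_way_junction(self, junction_example):
        loops = decompose_loops(junction_example)
        junctions = [L for L in loops if L.loop_class == "junction"]
        assert len(junctions) == 1
        (j,) = junctions
        assert j.closing_pair == (2, 23)
        assert j.child_pairs == ((5, 11), (14, 20))
        assert j.strand_lengths == (2, 2, 2)
        hairpins = [L for L in loops if L.loop_class == "hairpin"]
        assert [h.strand_lengths for h in hairpins] == [(3,), (3,)]

    def test_internal_loop(self):
        loops = decompose_loops(parse_dotbracket("((..((...))..))"))
        internal = [L for L in loops if L.loop_class == "internal"]
        assert len(internal) == 1 and internal[0].strand_lengths == (2, 2)

    def test_bulge_is_internal_order_two(self):
        loops = decompose_loops(parse_dotbracket("((.((...))))"))
        internal = [L for L in loops if L.loop_class == "internal"]
        assert len(internal) == 1
        assert internal[0].order == 2
        assert internal[0].strand_lengths == (1, 0)

    def test_exterior_never_junction(self):
        loops = decompose_loops(parse_dotbracket("(...)..(...)..(...)"))
        exterior = [L for L in loops if L.loop_class == "exterior"]
        assert len(exterior) == 1
        assert exterior[0].order == 3  # three top-level stems, still exterior
        assert all(L.loop_class != "junction" for L in loops)

    def test_empty_structure_exterior_only(self):
        loops = decompose_loops(parse_dotbracket("...."))
        assert [L.loop_class for L in loops] == ["exterior"]
        assert brute_force_decompose(parse_dotbracket("....")) is not None

    def test_position_conservation(self, random_structures):
        for ss in random_structures(60, seed=13):
            loops = decompose_loops(ss)
            stem_positions = set()
            for L in loops:
                if L.enclosing_stem is not None:
                    stem_positions |= L.enclosing_stem.positions
            strand_total = sum(
                len(L.strand_positions) for L in loops
            )
            assert len(stem_positions) + strand_total == ss.length
            # no position in two strands
            all_strand = [p for L in loops for p in L.strand_positions]
            assert len(all_strand) == len(set(all_strand))

    def test_matches_brute_force(self, random_structures):
        for ss in random_structures(120, seed=17):
            assert loop_signature(decompose_loops(ss)) == loop_signature(
                brute_force_decompose(ss)
            )

    def test_loop_count_identity(self, random_structures):
        # every stem's inner face closes exactly one loop, so the number of
        # closed loops of order >= 2 is #stems - #hairpins
        for ss in random_structures(40, seed=19):
            loops = decompose_loops(ss)
            stems = find_stems(ss)
            hairpins = sum(L.loop_class == "hairpin" for L in loops)
            multi = sum(
                L.closing_pair is not None and L.order >= 2 for L in loops
            )
            assert multi == len(stems) - hairpins


class TestJunctionFeatures:
    def test_three_way_counts(self, junction_example):
        (j,) = [L for L in decompose_loops(junction_example) if L.order == 3]
        assert junction_features(j) == (2, 2, 2)

    def test_asymmetric_strands(self):
        # 3-way junction with strand lengths (0, 5, 1)
        ss = parse_dotbracket("((...).....(...).)")
        (j,) = [L for L in decompose_loops(ss) if L.loop_class == "junction"]
        assert junction_features(j) == (0, 5, 1)

    def test_feature_sum_is_loop_unpaired_total(self, random_structures):
        for ss in random_structures(30, seed=23):
            for L in decompose_loops(ss):
                if L.closing_pair is None:
                    continue
                feats = junction_features(L, any_order=True)
                assert len(feats) == L.order
                assert sum(feats) == len(L.strand_positions)

    def test_hairpin_rejected_without_generalization(self):
        (h,) = [
            L
            for L in decompose_loops(parse_dotbracket("((...))"))
            if L.loop_class == "hairpin"
        ]
        with pytest.raises(ValueError, match="3-way"):
            junction_features(h)

    def test_exterior_rejected(self):
        (ext,) = [
            L
            for L in decompose_loops(parse_dotbracket("..(...).."))
            if L.loop_class == "exterior"
        ]
        with pytest.raises(ValueError, match="exterior"):
            junction_features(ext, any_order=True)


class TestMakeInstances:
    def test_junction_instances(self, junction_example):
        (j,) = [L for L in decompose_loops(junction_example) if L.order == 3]
        inst = make_instances(j, junction_example, cap_length=3)
        assert inst.len_loop == 12
        assert inst.len_loop_stems == 18
        assert inst.len_full == 24
        assert inst.loop_stems_db == "((..((...))..((...))..))"
        assert inst.loop_db == "(..(...)..(...)..)"
        assert parse_dotbracket(inst.loop_db).is_nested

    def test_internal_loop_instances(self):
        ss0 = parse_dotbracket("((..((...))..))")
        ss = SecondaryStructure(15, ss0.pairs, "GGAAGGAAACCAACC")
        (internal,) = [L for L in decompose_loops(ss) if L.loop_class == "internal"]
        inst = make_instances(internal, ss, cap_length=3)
        assert inst.len_loop_stems == 12
        # the excised hairpin had exactly 3 nt, so the cap reproduces it
        assert inst.loop_stems_db == "((..((...))..))"
        assert inst.loop_stems_seq == "GGAAGGNNNCCAACC"

    def test_hairpin_rejected(self, junction_example):
        h = [L for L in decompose_loops(junction_example) if L.loop_class == "hairpin"]
        with pytest.raises(ValueError, match="order"):
            make_instances(h[0], junction_example)

    def test_all_instances_reparse_with_consistent_lengths(self, random_structures):
        for ss in random_structures(40, seed=29):
            for L in decompose_loops(ss):
                if L.closing_pair is None or L.order < 2:
                    continue
                inst = make_instances(L, ss)
                for seq, db in [
                    (inst.loop_seq, inst.loop_db),
                    (inst.loop_stems_seq, inst.loop_stems_db),
                    (inst.full_seq, inst.full_db),
                ]:
                    assert len(seq) == len(db)
                    assert parse_dotbracket(db).is_nested
                assert inst.len_loop <= inst.len_loop_stems <= inst.len_full
                assert inst.len_full == ss.length

    def test_cap_zero_as_is_mode(self, junction_example):
        (j,) = [L for L in decompose_loops(junction_example) if L.order == 3]
        inst = make_instances(j, junction_example, cap_length=0)
        assert len(inst.loop_db) == inst.len_loop == 12


class TestGenerator:
    def test_seed_determinism(self):
        a = generate_random_structure(30, seed=1)
        b = generate_random_structure(30, seed=1)
        assert a.pairs == b.pairs and a.sequence == b.sequence

    def test_no_branching_weight_means_hairpin_chains(self):
        ss = generate_random_structure(
            120, branching_weights={0: 0.3, 1: 0.7}, seed=4
        )
        assert all(L.loop_class != "junction" for L in decompose_loops(ss))

    def test_infeasible_forced_pairing_rejected(self):
        with pytest.raises(ValueError, match="feasible"):
            generate_random_structure(3, branching_weights={1: 1.0}, seed=0)

    def test_invariants_and_min_hairpin(self, random_structures):
        for ss in random_structures(100, min_len=20, max_len=200, seed=31):
            assert ss.is_nested
            assert set(ss.sequence) <= set("ACGU")
            for L in decompose_loops(ss):
                if L.loop_class == "hairpin":
                    assert L.strand_lengths[0] >= 3

    def test_paired_bases_complementary(self):
        ss = generate_random_structure(80, seed=8)
        for i, j in ss.pairs:
            assert ss.sequence[i - 1] + ss.sequence[j - 1] in {
                "AU", "UA", "GC", "CG", "GU", "UG",
            }
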