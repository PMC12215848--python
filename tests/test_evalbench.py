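"""Benchmark metrics: F1, tree-edit distance, Wilcoxon, failure handling."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rnaloopkit.evalbench import (
    FAILED,
    CandidateEnergetics,
    aggregate_with_failures,
    bp_f1,
    fold_wrapper,
    normalize_distance,
    pdist_wrapper,
    rnadistance_wrapper,
    select_candidate,
    target_probability,
    tree_edit_distance,
    wilcoxon_matrix,
    wilcoxon_pvalue,
)
from rnaloopkit.motifs import generate_random_structure
from rnaloopkit.structio import SecondaryStructure, parse_dotbracket


def render(ss):
    chars = ["."] * ss.length
    for i, j in ss.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


class TestBpF1:
    def test_partial_match(self):
        target = SecondaryStructure(7, frozenset({(1, 7), (2, 6)}))
        predicted = SecondaryStructure(7, frozenset({(1, 7)}))
        precision, recall, f1 = bp_f1(target, predicted)
        assert (precision, recall) == (1.0, 0.5)
        assert f1 == pytest.approx(2 / 3)

    def test_identical_and_disjoint(self):
        a = parse_dotbracket("((...))")
        assert bp_f1(a, a)[2] == 1.0
        b = SecondaryStructure(7, frozenset({(3, 5)}))
        assert bp_f1(a, b)[2] == 0.0

    def test_both_empty_convention(self):
        empty = SecondaryStructure(5, frozenset())
        assert bp_f1(empty, empty) == (1.0, 1.0, 1.0)
        assert bp_f1(parse_dotbracket("(...)"), empty)[2] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            bp_f1(parse_dotbracket("..."), parse_dotbracket(".."))

    def test_swapping_arguments_swaps_precision_recall(self, random_structures):
        structures = random_structures(10, min_len=30, max_len=60, seed=41)
        for a in structures[:5]:
            b = SecondaryStructure(a.length, frozenset(sorted(a.pairs)[:: 2]))
            pa, ra, fa = bp_f1(a, b)
            pb, rb, fb = bp_f1(b, a)
            assert (pa, ra) == (rb, pb) and fa == pytest.approx(fb)

    def test_matches_set_arithmetic_oracle(self, random_structures):
        for a, b in itertools.pairwise(random_structures(20, min_len=20, max_len=50, seed=43)):
            b = SecondaryStructure(a.length, frozenset(p for p in b.pairs if p[1] <= a.length))
            tp = len(a.pairs & b.pairs)
            p, r, f1 = bp_f1(a, b)
            if b.pairs:
                assert p == tp / len(b.pairs)
            if a.pairs:
                assert r == tp / len(a.pairs)


class TestTreeEdit:
    def test_identity_is_zero(self, random_structures):
        for ss in random_structures(10, min_len=10, max_len=40, seed=47):
            assert tree_edit_distance(ss, ss) == 0.0

    def test_single_base_indel(self):
        assert tree_edit_distance(parse_dotbracket("."), parse_dotbracket("")) == 1.0

    def test_reference_binary_agreement_on_examples(self):
        # values fixed by the RNAdistance program on these inputs
        cases = [("((...))", ".(...)."), ("(...)", "....."), ("((...))", "(...)")]
        expected = [4.0, 4.0, 2.0]
        for (a, b), want in zip(cases, expected):
            assert tree_edit_distance(parse_dotbracket(a), parse_dotbracket(b)) == want

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(53)
        structures = [
            generate_random_structure(int(rng.integers(15, 45)), seed=int(rng.integers(2**31)))
            for _ in range(12)
        ]
        for a, b in itertools.combinations(structures[:8], 2):
            assert tree_edit_distance(a, b) == tree_edit_distance(b, a)
        for a, b, c in itertools.combinations(structures, 3):
            dab = tree_edit_distance(a, b)
            dbc = tree_edit_distance(b, c)
            dac = tree_edit_distance(a, c)
            assert dac <= dab + dbc + 1e-9

    def test_non_nested_rejected(self):
        pk = SecondaryStructure(10, frozenset({(1, 6), (4, 9)}))
        with pytest.raises(ValueError, match="nested"):
            tree_edit_distance(pk, pk)

    def test_matches_rnadistance_binary(self):
        rng = np.random.default_rng(59)
        for _ in range(15):
            n = int(rng.integers(15, 70))
            a = generate_random_structure(n, seed=int(rng.integers(2**31)))
            b = generate_random_structure(n, seed=int(rng.integers(2**31)))
            assert tree_edit_distance(a, b) == rnadistance_wrapper(render(a), render(b))


class TestNormalize:
    def test_division(self):
        assert normalize_distance(14, 100) == pytest.approx(0.14)
        assert normalize_distance(0, 33) == 0.0
        assert normalize_distance(28, 100) == 2 * normalize_distance(14, 100)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            normalize_distance(1.0, 0)


class TestAggregate:
    def test_distance_failures_become_infinity(self):
        vals, _ = aggregate_with_failures({"A": [1.2, FAILED]}, "rnadistance")
        assert vals["A"][0] == 1.2 and math.isinf(vals["A"][1])

    def test_f1_failures_become_zero(self):
        vals, _ = aggregate_with_failures({"A": [0.9, FAILED]}, "f1")
        assert list(vals["A"]) == [0.9, 0.0]

    def test_common_subset(self):
        _, common = aggregate_with_failures(
            {"A": [1.0, 2.0, FAILED], "B": [FAILED, 1.0, 1.0]}, "rnapdist"
        )
        assert list(common) == [False, True, False]

    def test_finite_values_untouched_and_count_conserved(self):
        values = [0.1, FAILED, 0.3, None, 0.5]
        vals, _ = aggregate_with_failures({"A": values}, "rnadistance")
        assert len(vals["A"]) == len(values)
        assert list(vals["A"][[0, 2, 4]]) == [0.1, 0.3, 0.5]

    def test_unknown_metric(self):
        with pytest.raises(ValueError, match="unknown"):
            aggregate_with_failures({"A": [1]}, "mcc")


class TestWilcoxon:
    def test_exact_strict_dominance_five_pairs(self):
        p = wilcoxon_pvalue([1, 2, 3, 4, 5], [2, 3, 4, 5, 6], "less")
        assert p == pytest.approx(1 / 32)

    def test_identical_vectors(self):
        assert wilcoxon_pvalue([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_matches_scipy_exact_when_untied(self):
        rng = np.random.default_rng(61)
        for _ in range(25):
            n = int(rng.integers(6, 11))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            for alt in ("less", "greater"):
                ours = wilcoxon_pvalue(a, b, alt)
                ref = stats.wilcoxon(a, b, alternative=alt, method="exact").pvalue
                assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_exhaustive_enumeration_with_ties(self):
        rng = np.random.default_rng(67)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            d = rng.integers(-3, 4, size=n).astype(float)
            d = d[d != 0]
            if d.size == 0:
                continue
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            count = 0
            total = 0
            for signs in itertools.product([1, -1], repeat=d.size):
                w = sum(r for r, s in zip(ranks, signs) if s > 0)
                total += 1
                if w <= w_obs:
                    count += 1
            ours = wilcoxon_pvalue(d, np.zeros_like(d), "less")
            assert ours == pytest.approx(count / total)

    def test_failures_lose_by_rank(self):
        a = [math.inf] * 6
        b = [1.0, 2.0, 0.5, 3.0, 1.5, 2.5]
        assert wilcoxon_pvalue(a, b, "less") == 1.0
        assert wilcoxon_pvalue(b, a, "less") == pytest.approx(1 / 64)

    def test_matrix_directions(self):
        vectors = {"good": [1, 2, 3, 4, 5], "bad": [2, 3, 4, 5, 6]}
        m = wilcoxon_matrix(vectors, "lower")
        df = m.to_dataframe()
        assert df.loc["good", "bad"] == pytest.approx(1 / 32)
        assert df.loc["bad", "good"] == 1.0
        assert df.loc["good", "good"] == 1.0
        m2 = wilcoxon_matrix(vectors, "higher")
        assert m2.to_dataframe().loc["bad", "good"] == pytest.approx(1 / 32)

    def test_always_failing_tool_never_significantly_better(self):
        rng = np.random.default_rng(71)
        finite = {f"t{k}": rng.uniform(0, 5, size=20).tolist() for k in range(3)}
        finite["dead"] = [FAILED] * 20
        vals, _ = aggregate_with_failures(finite, "rnadistance")
        m = wilcoxon_matrix(vals, "lower").to_dataframe()
        assert (m.loc["dead"].drop("dead") > 0.95).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_matrix({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4]}, "lower")


class TestCandidates:
    def test_probability_closed_forms(self):
        assert target_probability(-5.0, -5.0) == 1.0
        rt = 0.61633
        assert target_probability(-5.0 + rt * math.log(2), -5.0, rt) == pytest.approx(0.5)

    def test_selection_rule(self):
        def cand(psum, mfe, seq):
            # one target with energy chosen to give the desired probability
            e = -10.0 - 0.61633 * math.log(psum)
            return CandidateEnergetics(seq, mfe, -10.0, (e,))

        chosen = select_candidate([cand(0.8, -12, "a"), cand(0.8, -15, "b"), cand(0.5, -20, "c")])
        assert chosen.sequence == "b"

    def test_empty_list(self):
        with pytest.raises(ValueError):
            select_candidate([])


class TestViennaWrappers:
    def test_fold_smoke(self):
        ss, mfe, ee = fold_wrapper("GGGAAACCC")
        assert len(ss.pairs) >= 1
        assert ee <= mfe <= 0

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            fold_wrapper("")

    def test_pdist_self_is_zero(self):
        assert pdist_wrapper("GGGAAACCC", "GGGAAACCC") == 0.0
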