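"""The P and Q recursions, coefficient sums, tensors and interpretability."""

import random

import numpy as np
import pytest

from treepoly import (
    build_tree,
    canonical_form,
    coefficient_sum,
    decompose,
    evaluate,
    parse_dot_bracket,
    poly_P,
    poly_Q,
    to_coeff_tensor,
    tree_polynomial,
)
from treepoly.polynomials import Polynomial
from treepoly.trees import ARTIFICIAL_GROUP, LOOP, UNPAIRED_LEAF, RootedTree


def path_tree(n_edges: int) -> RootedTree:
    t = RootedTree()
    v = 0
    for _ in range(n_edges):
        v = t.add_vertex(v, LOOP)
    return t


class TestPolyP:
    def test_single_leaf_is_x(self):
        assert poly_P(RootedTree()).terms == {(1, 0): 1}

    @pytest.mark.parametrize("ell", [1, 2, 3, 7])
    def test_path_of_ell_edges_is_x_plus_ell_y(self, ell):
        assert poly_P(path_tree(ell)).terms == {(1, 0): 1, (0, 1): ell}

    def test_worked_example_type1_polynomial(self, worked_decomp):
        p = poly_P(build_tree(worked_decomp, 1))
        assert p.terms == {(2, 0): 1, (1, 1): 1, (0, 1): 3}  # x^2 + xy + 3y

    def test_child_order_invariance(self, worked_decomp):
        t = build_tree(worked_decomp, 4)
        rng = random.Random(7)
        shuffled = RootedTree(
            classes=list(t.classes),
            children=[list(c) for c in t.children],
            tree_type=t.tree_type,
        )
        for c in shuffled.children:
            rng.shuffle(c)
        assert poly_P(t) == poly_P(shuffled)
        assert poly_Q(t) == poly_Q(shuffled)


class TestPolyQ:
    def test_artificial_vertex_with_k_leaves_gives_xk_plus_z(self):
        for k in (1, 2, 5):
            t = RootedTree(classes=[ARTIFICIAL_GROUP], children=[[]])
            for _ in range(k):
                t.add_vertex(0, UNPAIRED_LEAF)
            q = poly_Q(t)
            assert q.terms == {(k, 0, 0): 1, (0, 0, 1): 1}

    def test_interior_loop_vertex_with_two_singleton_groups(self):
        # loop vertex with two artificial children of one leaf each:
        # y + (x + z)^2
        t = RootedTree()
        for _ in range(2):
            g = t.add_vertex(0, ARTIFICIAL_GROUP)
            t.add_vertex(g, UNPAIRED_LEAF)
        q = poly_Q(t)
        assert q.terms == {
            (0, 1, 0): 1,
            (2, 0, 0): 1,
            (1, 0, 1): 2,
            (0, 0, 2): 1,
        }

    def test_q_reduces_to_p_under_z_to_y(self, random_structures):
        for ss in random_structures:
            d = decompose(ss)
            for k in (2, 4):
                t = build_tree(d, k)
                assert poly_Q(t).substitute_z_with_y() == poly_P(t)

    def test_q_equals_p_without_artificial_vertices(self, worked_decomp):
        t = build_tree(worked_decomp, 3)
        assert poly_Q(t).eliminate_z() == poly_P(t)

    def test_type_pairing(self, worked_decomp):
        assert tree_polynomial(build_tree(worked_decomp, 2)).nvars == 3
        assert tree_polynomial(build_tree(worked_decomp, 1)).nvars == 2


class TestCoefficientSumAndEvaluate:
    def test_x_sums_to_one(self):
        assert coefficient_sum(Polynomial(2, {(1, 0): 1})) == 1

    def test_worked_example_sum_is_five(self, worked_decomp):
        assert coefficient_sum(poly_P(build_tree(worked_decomp, 1))) == 5

    def test_sum_equals_evaluation_at_ones(self, random_structures):
        for ss in random_structures:
            d = decompose(ss)
            for k in (1, 2, 3, 4):
                p = tree_polynomial(build_tree(d, k))
                z = 1 if p.nvars == 3 else None
                assert coefficient_sum(p) == evaluate(p, 1, 1, z)

    def test_evaluate_spot_value(self):
        p = Polynomial(2, {(1, 0): 1, (0, 1): 2})  # x + 2y
        assert evaluate(p, 1, 1) == 3


class TestInterpretability:
    def test_x_degree_is_leaf_count(self, random_structures):
        for ss in random_structures[:30]:
            d = decompose(ss)
            for k in (1, 2, 5):
                t = build_tree(d, k)
                p = tree_polynomial(t)
                assert p.var_degree("x") == len(t.leaves())

    def test_z_degree_is_total_loop_groups(self, random_structures):
        for ss in random_structures[:30]:
            d = decompose(ss)
            for k in (2, 4):
                q = poly_Q(build_tree(d, k))
                assert q.var_degree("z") == d.total_loop_groups()

    def test_linear_y_coefficient_counts_loops(self, worked_decomp, random_structures):
        def linear_y_at_z1(q):
            return sum(c for (i, j, _), c in q.terms.items() if i == 0 and j == 1)

        assert linear_y_at_z1(poly_Q(build_tree(worked_decomp, 2))) == 6
        assert linear_y_at_z1(poly_Q(build_tree(worked_decomp, 4))) == 12  # + stem regions
        for ss in random_structures[:15]:
            d = decompose(ss)
            assert linear_y_at_z1(poly_Q(build_tree(d, 2))) == len(d.loops)
            assert linear_y_at_z1(poly_Q(build_tree(d, 4))) == len(
                d.loops
            ) + d.total_stem_regions()


class TestBubbleGrowth:
    """Bubbles in linear branches drive coefficient sums up geometrically."""

    @staticmethod
    def branch_db(bubbles: int) -> str:
        core = "((...))"
        for _ in range(bubbles):
            core = "((" + "." + core + "))"  # one bulge per wrap
        return core

    def test_inserting_a_bubble_strictly_increases_type1_sum(self):
        sums = []
        for b in range(6):
            d = decompose(parse_dot_bracket(self.branch_db(b)))
            sums.append(coefficient_sum(poly_P(build_tree(d, 1))))
        assert all(s2 > s1 for s1, s2 in zip(sums, sums[1:]))

    def test_multibranch_sum_grows_geometrically(self):
        # b linear branches of ell bubbles each hanging off one multiloop:
        # each branch contributes the factor x + ell*y (a path of ell edges),
        # so the multiloop gets y + (x + ell*y)^b and the root one more y;
        # at x = y = 1 the coefficient sum is 2 + (ell + 1)^b
        for ell in (1, 2, 3):
            branch = self.branch_db(ell)
            for b in (2, 3, 4):
                db = "(" + ".".join([branch] * b) + ")"
                d = decompose(parse_dot_bracket(db))
                s = coefficient_sum(poly_P(build_tree(d, 1)))
                assert s == 2 + (ell + 1) ** b

    def test_growth_is_at_least_geometric_in_bubbles(self):
        base = None
        for ell in range(1, 6):
            db = "(" + ".".join([self.branch_db(ell)] * 3) + ")"
            d = decompose(parse_dot_bracket(db))
            s = coefficient_sum(poly_P(build_tree(d, 1)))
            if base is not None:
                assert s / base > 1.5  # ratio grows with each added bubble layer
            base = s


class TestTensor:
    def test_x_plus_2y_tensor(self):
        p = Polynomial(2, {(1, 0): 1, (0, 1): 2})
        t = to_coeff_tensor(p)
        assert t.shape == (2, 2)
        assert t[1, 0] == 1 and t[0, 1] == 2 and t[0, 0] == 0

    def test_roundtrip_and_total(self, random_structures):
        for ss in random_structures[:20]:
            d = decompose(ss)
            p = tree_polynomial(build_tree(d, 2))
            t = to_coeff_tensor(p)
            assert Polynomial.from_coeff_tensor(t) == p
            assert int(t.sum()) == coefficient_sum(p)

    def test_serialization_roundtrip(self, worked_decomp):
        p = tree_polynomial(build_tree(worked_decomp, 4))
        assert Polynomial.from_json(p.to_json()) == p
        assert p.to_coordinate_text().startswith("%")


class TestCompletenessSmall:
    def test_p_distinguishes_small_trees(self):
        """P equal <=> canonical form equal over all rooted trees on <= 7 vertices."""
        from conftest import all_rooted_trees, tuple_to_tree

        by_p: dict = {}
        by_canon: dict = {}
        trees = [t for n in range(1, 8) for t in all_rooted_trees(n)]
        for enc in trees:
            t = tuple_to_tree(enc)
            by_p.setdefault(poly_P(t), []).append(enc)
            by_canon.setdefault(canonical_form(t), []).append(enc)
        assert len(by_p) == len(trees) == len(by_canon)
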