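"""Exact polyhedron engine: unit examples and oracle-checked properties.

The oracles are independent of the code paths they check: constraint
membership is evaluated per constraint on sampled rational points, and
projection/entailment answers are cross-checked against the exact LP
solver (and the LP solver itself against brute-force vertex reasoning
in the hypothesis sweeps).
"""
import itertools
import random
from fractions import Fraction as F

import pytest
from hypothesis import given, settings, strategies as st

from hybridph.polyhedra import (
    LinearConstraint,
    Polyhedron,
    parse_constraint,
    parse_polyhedron as P,
)
from hybridph import _simplex


def rat(lo=-6, hi=6, den=4):
    return st.builds(F, st.integers(lo * den, hi * den), st.just(den))


class TestConjoin:
    def test_identity_on_universe(self):
        c = parse_constraint("x <= 1")
        assert Polyhedron.universe(["x"]).conjoin(c).equivalent(P("x <= 1"))

    def test_interval(self):
        p = P("x <= 1").conjoin(parse_constraint("x >= 0"))
        assert p.contains_point({"x": F(1, 2)})
        assert not p.contains_point({"x": F(3, 2)})
        assert not p.contains_point({"x": F(-1, 2)})

    def test_membership_matches_per_constraint_evaluation(self):
        rng = random.Random(7)
        for _ in range(30):
            cons = [
                LinearConstraint.le(
                    {v: F(rng.randint(-3, 3)) for v in "xyz"},
                    F(rng.randint(-4, 4)))
                for _ in range(4)
            ]
            p = Polyhedron(cons)
            for _ in range(30):
                pt = {v: F(rng.randint(-12, 12), 3) for v in "xyz"}
                assert p.contains_point(pt) == all(c.evaluate(pt) for c in cons)


class TestEmptiness:
    def test_contradictory_bounds(self):
        assert P("x <= 0 & x >= 1").is_empty()

    def test_parametric_bound_feasible(self):
        assert not P("x <= d & d <= 5").is_empty()

    def test_agreement_with_vertex_oracle(self):
        # random <=3-var interval systems: emptiness is decidable by
        # interval propagation on axis-aligned instances
        rng = random.Random(11)
        for _ in range(50):
            lo = {v: rng.randint(-5, 5) for v in "xyz"}
            hi = {v: lo[v] + rng.randint(-1, 4) for v in "xyz"}
            cons = []
            for v in "xyz":
                cons.append(LinearConstraint.ge({v: 1}, lo[v]))
                cons.append(LinearConstraint.le({v: 1}, hi[v]))
            expect_empty = any(hi[v] < lo[v] for v in "xyz")
            assert Polyhedron(cons).is_empty() == expect_empty


class TestTimeElapse:
    def test_single_clock_flows_up(self):
        assert P("h = 0").time_elapse({"h": 1}).equivalent(P("h >= 0"))

    def test_two_clocks_stay_synchronized(self):
        p = P("h1 = 0 & h2 = 0").time_elapse({"h1": 1, "h2": 1})
        assert p.equivalent(P("h1 = h2 & h1 >= 0"))

    def test_frozen_clock(self):
        assert P("h = 0").time_elapse({"h": 0}).equivalent(P("h = 0"))

    def test_idempotent(self):
        p = P("h1 = 0 & h2 = 1 & d >= 2").time_elapse({"h1": 1, "h2": -1})
        again = p.time_elapse({"h1": 1, "h2": -1})
        assert p.equivalent(again)

    def test_parameters_unaffected(self):
        p = P("h = 0 & d1 <= d2").time_elapse({"h": 1})
        assert p.entails(parse_constraint("d1 <= d2"))


class TestReset:
    def test_keeps_parameter_relations(self):
        p = P("h = d & d >= 2").reset(["h"])
        assert p.equivalent(P("h = 0 & d >= 2"))

    def test_reset_on_universe(self):
        assert Polyhedron.universe(["h"]).reset(["h"]).equivalent(P("h = 0"))

    def test_sampling_oracle(self):
        rng = random.Random(3)
        p = P("h <= d1 + d2 & h >= d1 & d1 >= 1 & d2 >= 0").reset(["h"])
        for _ in range(200):
            d1, d2 = F(rng.randint(1, 8)), F(rng.randint(0, 8))
            assert p.contains_point({"h": 0, "d1": d1, "d2": d2})
            assert not p.contains_point({"h": 1, "d1": d1, "d2": d2})


class TestEliminate:
    def test_transitivity(self):
        assert P("x <= d1 & d1 <= d2").eliminate(["d1"]).equivalent(P("x <= d2"))

    def test_equality_projects_to_universe(self):
        assert not P("h = d").eliminate(["h"]).constraints

    def test_projection_matches_lp_exists_check(self):
        rng = random.Random(19)
        names = ["a", "b", "c", "d", "e"]
        for _ in range(40):
            cons = [
                LinearConstraint.le(
                    {v: F(rng.randint(-2, 2)) for v in names},
                    F(rng.randint(-3, 5)))
                for _ in range(5)
            ]
            p = Polyhedron(cons, names)
            drop = rng.sample(names, 2)
            proj = p.eliminate(drop)
            keep = [v for v in names if v not in drop]
            for _ in range(20):
                pt = {v: F(rng.randint(-6, 6), 2) for v in keep}
                # oracle: exists an extension iff LP on p with pt pinned
                rows = [(c.coeffs, c.const) for c in cons]
                rows += [({v: F(1)}, pt[v]) for v in keep]
                rows += [({v: F(-1)}, -pt[v]) for v in keep]
                assert proj.contains_point(pt) == _simplex.feasible(rows)

    def test_elimination_order_does_not_matter(self):
        p = P("x <= y & y <= z & z <= x + 1 & w >= 0 & w <= y")
        a = p.eliminate(["y"]).eliminate(["w"])
        b = p.eliminate(["w"]).eliminate(["y"])
        assert a.equivalent(b)


class TestEntailment:
    def test_universe_is_entailed(self):
        assert P("x <= 1").entails(Polyhedron.universe())

    def test_weaker_bound_is_entailed(self):
        assert P("x <= 1").entails(P("x <= 2"))
        assert not P("x <= 2").entails(P("x <= 1"))

    def test_touching_face_still_entailed(self):
        assert P("x <= 1 & x >= 1").entails(P("x <= 1"))

    def test_agreement_with_lp_oracle(self):
        rng = random.Random(23)
        for _ in range(60):
            cons = [
                LinearConstraint.le(
                    {v: F(rng.randint(-2, 2)) for v in "xy"},
                    F(rng.randint(-2, 4)))
                for _ in range(4)
            ]
            p = Polyhedron(cons, ["x", "y"])
            c = LinearConstraint.le(
                {v: F(rng.randint(-2, 2)) for v in "xy"}, F(rng.randint(-2, 4)))
            if p.is_empty():
                assert p.entails(c)
                continue
            status, val = _simplex.maximize(
                c.coeffs, [(k.coeffs, k.const) for k in cons])
            expected = status == "optimal" and val <= c.const
            assert p.entails(c) == expected


class TestCanonicalization:
    def test_denotation_preserved(self):
        rng = random.Random(31)
        for _ in range(20):
            cons = [
                LinearConstraint(
                    {v: F(rng.randint(-2, 2)) for v in "xyz"},
                    F(rng.randint(-3, 3)),
                    rng.choice(["<=", "<=", "=="]))
                for _ in range(5)
            ]
            p = Polyhedron(cons)
            canon = Polyhedron(p.canonical())
            for _ in range(100):
                pt = {v: F(rng.randint(-9, 9), 3) for v in "xyz"}
                assert p.contains_point(pt) == canon.contains_point(pt)

    def test_minimized_is_irredundant_and_equivalent(self):
        p = P("x <= 1 & x <= 2 & y <= 2 & x + y <= 3 & x + y <= 10")
        m = p.minimized()
        assert m.equivalent(p)
        for i in range(len(m.constraints)):
            rest = Polyhedron(
                m.constraints[:i] + m.constraints[i + 1:], m.variables)
            assert not rest.equivalent(p)

    def test_no_floats_accepted(self):
        with pytest.raises(TypeError):
            LinearConstraint.le({"x": 0.5}, 1)


class TestParsing:
    @pytest.mark.parametrize("text", [
        "d_p1+ <= d_q1+",
        "d_r1+ + |d_r1-| <= 2*d_q1+ + |d_q1-|",
        "h = d_q1-",
        "x + y <= 3",
        "0 <= h_r",
    ])
    def test_render_parse_roundtrip(self, text):
        c = parse_constraint(text)
        assert parse_constraint(c.render()) == c

    def test_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_constraint("x <=")
        with pytest.raises(ValueError):
            parse_constraint("no relation here")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.dictionaries(st.sampled_from("xyz"), rat(), min_size=1, max_size=3),
            rat(),
        ),
        min_size=1, max_size=5,
    ),
    st.dictionaries(st.sampled_from("xyz"), rat(), min_size=1, max_size=3),
)
def test_lp_optimum_is_feasible_and_bounding(rows, obj):
    """Simplex results are consistent: optimal value is attained by no
    feasible sampled point exceeding it, and infeasibility matches an
    exhaustive grid check on a coarse lattice."""
    cons = [(a, b) for a, b in rows]
    status, val = _simplex.maximize(obj, cons)
    grid = [F(n, 2) for n in range(-8, 9)]
    lattice = itertools.product(grid, repeat=3)
    feas_pts = []
    for x, y, z in itertools.islice(lattice, 0, None, 37):
        pt = {"x": x, "y": y, "z": z}
        if all(sum(a.get(v, F(0)) * pt[v] for v in "xyz") <= b for a, b in cons):
            feas_pts.append(pt)
    if status == "infeasible":
        assert not feas_pts
    elif status == "optimal":
        for pt in feas_pts:
            assert sum(obj.get(v, F(0)) * pt[v] for v in "xyz") <= val
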