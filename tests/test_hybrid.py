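"""Hybrid automata: construction, composition, symbolic reachability,
delay constraints and concrete simulation."""
from fractions import Fraction as F

import pytest

from hybridph import random_brn
from hybridph.automata import build_an, reachable
from hybridph.hybrid import (
    DEGRADATION,
    PRODUCTION,
    BioLHANetwork,
    DelayParameter,
    ReachOverflow,
    build_lha,
    build_network,
    concrete_simulate,
    delay_constraints,
    parametric_reach,
    parse_delay_constraint,
    reach_path,
)
from hybridph.polyhedra import parse_constraint

TABLE_PATH = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1), (1, 0, 0)]


class TestBuildLha:
    def test_single_threshold_gene_layout(self, oscillator_an):
        q = build_lha("q", oscillator_an)
        assert q.clocks == ("h_q",)
        assert q.max_level == 1
        guards = {(e.origin, e.parameter.name, tuple(sorted(map(str, e.condition))))
                  for e in q.edges}
        assert guards == {
            (0, "d_q1+", ("r0",)),
            (1, "d_q1-", ("r1",)),
        }
        # invariants: rising bound below the production delay, falling
        # bound above the (negative) degradation delay
        assert [c.render() for c in q.invariants[0]] == ["h_q <= d_q1+"]
        assert [c.render() for c in q.invariants[1]] == ["d_q1- <= h_q"]
        assert q.rates[0] == {"h_q": 1} and q.rates[1] == {"h_q": -1}

    def test_multilevel_gene_gets_two_clocks(self, phage_an):
        cI = build_lha("cI", phage_an)
        assert cI.clocks == ("h_cI", "hn_cI")
        assert {p.name for p in cI.parameters} == {
            "d_cI1+", "d_cI2+", "d_cI1-", "d_cI2-"}
        # both clocks run at intermediate levels
        assert cI.rates[1] == {"h_cI": 1, "hn_cI": -1}
        # the top level only degrades
        assert cI.rates[2] == {"h_cI": 0, "hn_cI": -1}

    def test_N_upregulation_cells(self, phage_an):
        N = build_lha("N", phage_an)
        rises = [e for e in N.edges if e.destination == 1]
        conds = {tuple(sorted(map(str, e.condition))) for e in rises}
        assert conds == {("cI0", "cro0"), ("cI0", "cro1")}

    def test_constant_gene_single_location_no_clocks(self):
        from hybridph.brn import Gene, Interaction, InteractionGraph

        g = InteractionGraph(
            [Gene("a", 1), Gene("b", 1)],
            [Interaction("b", "a", 1, "+")])
        an = build_an(g)
        b = build_lha("b", an)
        assert b.clocks == () and b.edges == ()


class TestCompose:
    def test_network_shape(self, phage_net):
        assert phage_net.gene_order == ("cI", "cro", "cII", "N")
        assert len(phage_net.clocks) == 6          # 2+2+1+1
        assert len(phage_net.parameters) == 14     # 4+6+2+2
        # product location space: 3*4*2*2
        total = 1
        for c in phage_net.components:
            total *= c.max_level + 1
        assert total == 48

    def test_single_automaton_composes_to_itself(self, oscillator_an):
        q = build_lha("q", oscillator_an)
        net = BioLHANetwork((q,))
        assert net.components == (q,)

    def test_clock_collision_rejected(self, oscillator_an):
        q = build_lha("q", oscillator_an)
        with pytest.raises(ValueError, match="duplicate|collision"):
            BioLHANetwork((q, q))


class TestParametricReach:
    def test_initial_state_has_zero_clocks(self, oscillator_net):
        res = parametric_reach(oscillator_net, (0, 0, 0), subsume="location")
        init = res.states[0]
        pt = {v: F(0) for v in init.polyhedron.variables}
        assert init.polyhedron.contains_point(pt)

    def test_table_path_is_traversed(self, oscillator_net):
        res = parametric_reach(oscillator_net, (0, 0, 0), subsume="location")
        discrete = res.discrete_states()
        for state in TABLE_PATH:
            assert state in discrete

    def test_discrete_projection_within_an_reach(self, oscillator_an, oscillator_net):
        res = parametric_reach(oscillator_net, (0, 0, 0), subsume="location")
        assert res.discrete_states() <= set(reachable(oscillator_an, (0, 0, 0)).nodes)

    def test_projection_equals_an_reach_on_random_models(self):
        for seed in (0, 1, 2, 3, 4, 7, 9):
            an = build_an(random_brn(seed, n_genes=3, max_levels=2))
            net = build_network(an)
            init = tuple(0 for _ in an.genes)
            res = parametric_reach(net, init, subsume="location")
            assert res.discrete_states() == set(reachable(an, init).nodes)

    def test_exact_fixpoint_overflows_on_sustained_oscillation(self, oscillator_net):
        """The q/r oscillator accumulates clock-offset relations without
        bound, so the exact fixpoint hits its ceiling (the engine must
        report this rather than loop silently)."""
        with pytest.raises(ReachOverflow) as exc:
            parametric_reach(oscillator_net, (0, 0, 0), max_symbolic_states=60)
        assert len(exc.value.partial.states) == 60

    def test_exact_fixpoint_closes_without_cycles(self, cascade_an):
        # p -> q -> r cascade has no oscillation: the exact fixpoint closes
        net = build_network(cascade_an)
        res = parametric_reach(net, (0, 0, 0), max_symbolic_states=200)
        assert res.complete
        assert (1, 1, 1) in res.discrete_states()

    def test_time_blocked_states_are_flagged(self, cascade_an):
        net = build_network(cascade_an)
        res = parametric_reach(net, (0, 0, 0), max_symbolic_states=200)
        final = [s for s in res.states if s.location == (1, 1, 1)]
        # at <1,1,1> r cannot fall (p and q high) but q's degradation
        # deadline keeps ticking: the branch is retained, time-blocked
        assert final and all(s.time_blocked for s in final)


class TestDelayConstraints:
    def test_first_hop_ordering(self, oscillator_net):
        dc = delay_constraints(oscillator_net, TABLE_PATH[:2])
        assert dc.entails("d_p1+ <= d_q1+")
        assert dc.entails("d_p1+ <= d_r1+")

    def test_full_cycle_polyhedron(self, oscillator_net):
        dc = delay_constraints(oscillator_net, TABLE_PATH)
        for printed in [
            "d_p1+ <= d_q1+",
            "d_p1+ <= d_r1+",
            "d_p1+ <= d_q1+ + |d_q1-|",
            "d_r1+ <= d_q1+ + |d_q1-|",
            "d_q1+ + |d_q1-| <= d_r1+ + |d_r1-|",
            "d_r1+ + |d_r1-| <= 2*d_q1+ + |d_q1-|",
        ]:
            assert dc.entails(printed), printed

    def test_unrealizable_path_reports_empty(self, oscillator_net):
        # r cannot rise before q does
        dc = delay_constraints(oscillator_net, [(0, 0, 0), (0, 0, 1)])
        assert dc.empty

    def test_display_uses_magnitudes(self, oscillator_net):
        dc = delay_constraints(oscillator_net, TABLE_PATH)
        text = dc.render()
        assert "|d_q1-|" in text and "d_q1-" not in text.replace("|d_q1-|", "")

    def test_parse_delay_constraint_maps_magnitudes(self):
        c = parse_delay_constraint("d_r1+ <= d_q1+ + |d_q1-|")
        # |d_q1-| = -d_q1- internally
        assert c.coeffs["d_q1-"] == F(1)
        assert c.coeffs["d_r1+"] == F(1)
        assert c.coeffs["d_q1+"] == F(-1)


def _table_gamma(inside=True):
    """A valuation satisfying (or violating, when inside=False) the
    printed cycle constraints."""
    if inside:
        return {"d_p1+": F(1), "d_q1+": F(2), "d_q1-": F(-1),
                "d_r1+": F(3), "d_r1-": F(-2)}
    # violates d_p1+ <= d_q1+: q fires before p can
    return {"d_p1+": F(4), "d_q1+": F(2), "d_q1-": F(-1),
            "d_r1+": F(3), "d_r1-": F(-2)}


class TestConcreteSimulation:
    def test_satisfying_valuation_follows_the_printed_path(self, oscillator_net):
        traces = concrete_simulate(oscillator_net, _table_gamma(True), (0, 0, 0),
                                   horizon=6)
        assert len(traces) == 1
        path = traces[0].discrete_path()
        assert path[:6] == TABLE_PATH

    def test_violating_valuation_deviates_at_first_hop(self, oscillator_net):
        traces = concrete_simulate(oscillator_net, _table_gamma(False), (0, 0, 0),
                                   horizon=6)
        path = traces[0].discrete_path()
        assert path[1] != TABLE_PATH[1]
        assert path[1] == (0, 1, 0)    # q wins the race instead of p

    def test_zero_horizon(self, oscillator_net):
        traces = concrete_simulate(oscillator_net, _table_gamma(True), (0, 0, 0),
                                   horizon=0)
        assert traces[0].discrete_path() == [(0, 0, 0)]
        assert traces[0].horizon_reached

    def test_dwell_matches_parameters(self, oscillator_net):
        tr = concrete_simulate(oscillator_net, _table_gamma(True), (0, 0, 0),
                               horizon=6)[0]
        times = [s.entry_time for s in tr.steps]
        # p at 1, q at 2, r at 3, q falls at 3, r falls at 5
        assert times[:6] == [F(0), F(1), F(2), F(3), F(3), F(5)]

    def test_sign_checking(self, oscillator_net):
        bad = _table_gamma(True)
        bad["d_q1-"] = F(1)
        with pytest.raises(ValueError, match="<= 0"):
            concrete_simulate(oscillator_net, bad, (0, 0, 0), horizon=1)


class TestDelayParameterNaming:
    def test_names_and_display(self):
        up = DelayParameter("cro", 2, PRODUCTION)
        down = DelayParameter("cro", 2, DEGRADATION)
        assert up.name == "d_cro2+" and up.display == "d_cro2+"
        assert down.name == "d_cro2-" and down.display == "|d_cro2-|"

    def test_one_parameter_per_level_change(self, phage_net):
        cro = phage_net.component("cro")
        assert sorted(p.name for p in cro.parameters) == [
            "d_cro1+", "d_cro1-", "d_cro2+", "d_cro2-", "d_cro3+", "d_cro3-"]
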