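"""Parametric hybrid automata for timed gene networks.

Each gene becomes a linear hybrid automaton whose locations are its
discrete levels.  Crossing from level i to i+1 takes a *production
delay* d_g(i+1)+ >= 0, measured by a clock of rate +1; dropping from
level j to j-1 takes a *degradation delay* d_gj- <= 0, measured by a
clock of rate -1 (the delay parameter is carried negative internally
and displayed as |d_gj-|, its magnitude).  Guards are clock equalities
(h = d) conjoined with the switch condition over the other genes'
levels; location invariants bound the running clocks by the very same
parameters, so a delay that comes due *must* either fire its
transition or stop time (a *time-blocked* branch, retained and
flagged).  Every clock of a gene is reset exactly on that gene's own
jumps, so clocks accumulate across other genes' moves — this is what
produces summed terms such as 2*d_q1+ + |d_q1-| in cyclic paths.

Genes with a single intermediate threshold use one clock that rises
toward the production delay at level 0 and falls toward the
degradation delay at level 1; genes with three or more levels carry a
production clock and a degradation clock running simultaneously.

The network composition is asynchronous: one component jumps at a
time, reading the other components' discrete levels through shared
level variables.  :func:`parametric_reach` computes the symbolic
forward reach set — pairs of a location vector and an exact rational
polyhedron over clocks and delay parameters — and
:func:`delay_constraints` projects a state or path onto the delay
parameters alone.
"""
from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .automata import AutomataNetwork, GlobalState, LocalState, LocalTransition
from .polyhedra import LinearConstraint, Polyhedron, parse_constraint

Rat = Fraction

PRODUCTION = "production"
DEGRADATION = "degradation"


@dataclass(frozen=True, order=True)
class DelayParameter:
    """One delay per (gene, level change, direction).

    ``level`` is the upper level of the change: rising i -> i+1 uses
    d_g(i+1)+ and falling j -> j-1 uses d_gj-.  Production delays are
    constrained >= 0, degradation delays <= 0 (displayed |d-|).
    """

    gene: str
    level: int
    direction: str

    def __post_init__(self):
        if self.direction not in (PRODUCTION, DEGRADATION):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.level < 1:
            raise ValueError("delay level must be >= 1")

    @property
    def name(self) -> str:
        sign = "+" if self.direction == PRODUCTION else "-"
        return f"d_{self.gene}{self.level}{sign}"

    @property
    def display(self) -> str:
        return self.name if self.direction == PRODUCTION else f"|{self.name}|"

    def __str__(self):
        return self.display


@dataclass(frozen=True)
class LHAEdge:
    origin: int
    destination: int
    #: switch condition over *other* genes' levels
    condition: frozenset[LocalState]
    clock: str
    parameter: DelayParameter
    #: the underlying discrete transition
    transition: LocalTransition

    @property
    def guard(self) -> LinearConstraint:
        return LinearConstraint.eq({self.clock: 1, self.parameter.name: -1}, 0)


@dataclass
class BioLHA:
    """Hybrid automaton of one gene."""

    gene: str
    max_level: int
    initial: int
    clocks: tuple[str, ...]
    parameters: tuple[DelayParameter, ...]
    edges: tuple[LHAEdge, ...]
    #: level -> list of invariant constraints
    invariants: dict[int, tuple[LinearConstraint, ...]]
    #: level -> clock -> rate in {-1, 0, +1}
    rates: dict[int, dict[str, int]]

    def edges_from(self, level: int) -> tuple[LHAEdge, ...]:
        return tuple(e for e in self.edges if e.origin == level)


def production_clock(gene: str) -> str:
    return f"h_{gene}"


def degradation_clock(gene: str, two_clocks: bool) -> str:
    return f"hn_{gene}" if two_clocks else f"h_{gene}"


def build_lha(gene: str, an: AutomataNetwork, initial: int = 0) -> BioLHA:
    """Lift one gene of an automata network to a parametric hybrid
    automaton.

    Single-threshold genes (max level 1) use one clock whose rate is +1
    while the gene can rise and -1 while it can fall; multi-level genes
    use a production clock and a degradation clock running
    simultaneously.  Every edge resets all of the gene's clocks.  Each
    location's invariant bounds each running clock by the parameter of
    the corresponding outgoing edge.
    """
    if gene not in an.genes:
        raise KeyError(f"unknown gene {gene!r}")
    l = an.genes[gene]
    trans = an.transitions_of(gene)
    if not trans:
        return BioLHA(gene, l, initial, (), (), (), {k: () for k in range(l + 1)},
                      {k: {} for k in range(l + 1)})
    two = l >= 2
    hp = production_clock(gene)
    hd = degradation_clock(gene, two)
    clocks = (hp, hd) if two else (hp,)
    params: dict[str, DelayParameter] = {}
    edges: list[LHAEdge] = []
    for t in trans:
        rising = t.destination.level > t.origin.level
        if rising:
            p = DelayParameter(gene, t.destination.level, PRODUCTION)
            clk = hp
        else:
            p = DelayParameter(gene, t.origin.level, DEGRADATION)
            clk = hd
        params[p.name] = p
        edges.append(LHAEdge(t.origin.level, t.destination.level,
                             t.condition, clk, p, t))
    invariants: dict[int, tuple[LinearConstraint, ...]] = {}
    rates: dict[int, dict[str, int]] = {}
    for k in range(l + 1):
        here = [e for e in edges if e.origin == k]
        rate = {c: 0 for c in clocks}
        inv: list[LinearConstraint] = []
        rise = next((e for e in here if e.destination > k), None)
        fall = next((e for e in here if e.destination < k), None)
        if rise is not None:
            rate[rise.clock] = +1
            inv.append(LinearConstraint.le(
                {rise.clock: 1, rise.parameter.name: -1}, 0))   # h <= d+
        if fall is not None:
            rate[fall.clock] = -1
            inv.append(LinearConstraint.ge(
                {fall.clock: 1, fall.parameter.name: -1}, 0))   # h >= d-
        invariants[k] = tuple(inv)
        rates[k] = rate
    return BioLHA(gene, l, initial,
                  clocks, tuple(sorted(params.values())), tuple(edges),
                  invariants, rates)


@dataclass
class BioLHANetwork:
    """Asynchronous product of per-gene hybrid automata sharing discrete
    level variables."""

    components: tuple[BioLHA, ...]

    def __post_init__(self):
        names = [c.gene for c in self.components]
        if len(names) != len(set(names)):
            raise ValueError("duplicate component genes")
        clocks = [h for c in self.components for h in c.clocks]
        if len(clocks) != len(set(clocks)):
            raise ValueError("clock name collision between components")
        params = [p.name for c in self.components for p in c.parameters]
        if len(params) != len(set(params)):
            raise ValueError("parameter name collision between components")

    @property
    def gene_order(self) -> tuple[str, ...]:
        return tuple(c.gene for c in self.components)

    @property
    def clocks(self) -> tuple[str, ...]:
        return tuple(h for c in self.components for h in c.clocks)

    @property
    def parameters(self) -> tuple[DelayParameter, ...]:
        return tuple(p for c in self.components for p in c.parameters)

    def index(self, gene: str) -> int:
        return self.gene_order.index(gene)

    def component(self, gene: str) -> BioLHA:
        return self.components[self.index(gene)]

    def check_state(self, state: Sequence[int]) -> GlobalState:
        state = tuple(state)
        if len(state) != len(self.components):
            raise ValueError("state arity mismatch")
        for c, v in zip(self.components, state):
            if not 0 <= v <= c.max_level:
                raise ValueError(f"level {v} of {c.gene} outside 0..{c.max_level}")
        return state

    def rates_at(self, loc: GlobalState) -> dict[str, int]:
        rates: dict[str, int] = {}
        for c, lvl in zip(self.components, loc):
            rates.update(c.rates[lvl])
        return rates

    def invariants_at(self, loc: GlobalState) -> list[LinearConstraint]:
        out: list[LinearConstraint] = []
        for c, lvl in zip(self.components, loc):
            out.extend(c.invariants[lvl])
        return out

    def condition_holds(self, loc: GlobalState, condition: frozenset[LocalState]
                        ) -> bool:
        return all(loc[self.index(ls.gene)] == ls.level for ls in condition)

    def initial_constraint(self) -> Polyhedron:
        """All clocks at zero; production delays >= 0, degradation <= 0."""
        cons: list[LinearConstraint] = [
            LinearConstraint.eq({h: 1}, 0) for h in self.clocks
        ]
        for p in self.parameters:
            if p.direction == PRODUCTION:
                cons.append(LinearConstraint.ge({p.name: 1}, 0))
            else:
                cons.append(LinearConstraint.le({p.name: 1}, 0))
        return Polyhedron(cons, self.variables())

    def variables(self) -> tuple[str, ...]:
        return tuple(self.clocks) + tuple(p.name for p in self.parameters)


def compose(lhas: Iterable[BioLHA]) -> BioLHANetwork:
    return BioLHANetwork(tuple(lhas))


def build_network(an: AutomataNetwork,
                  initial: Sequence[int] | None = None) -> BioLHANetwork:
    init = tuple(initial) if initial is not None else (0,) * len(an.genes)
    return compose(
        build_lha(g, an, initial=i) for g, i in zip(an.gene_order, init)
    )


# ---------------------------------------------------------------------------
# symbolic reachability

@dataclass
class SymbolicState:
    location: GlobalState
    polyhedron: Polyhedron
    index: int
    time_blocked: bool = False
    #: indices of (source state, fired edge) pairs reaching this state
    incoming: list[tuple[int, LHAEdge]] = field(default_factory=list)


@dataclass
class ReachResult:
    states: list[SymbolicState]
    edges: list[tuple[int, LHAEdge, int]]
    complete: bool

    def discrete_states(self) -> set[GlobalState]:
        return {s.location for s in self.states}

    def states_at(self, loc: GlobalState) -> list[SymbolicState]:
        return [s for s in self.states if s.location == loc]


class ReachOverflow(RuntimeError):
    def __init__(self, message, partial: ReachResult):
        super().__init__(message)
        self.partial = partial


def _post(net: BioLHANetwork, loc: GlobalState, poly: Polyhedron
          ) -> Polyhedron | None:
    """Close a region under its location's invariants and time flow."""
    for inv in net.invariants_at(loc):
        poly = poly.conjoin(inv)
    if poly.is_empty():
        return None
    rates = net.rates_at(loc)
    if any(r != 0 for r in rates.values()):
        poly = poly.time_elapse(rates)
        for inv in net.invariants_at(loc):
            poly = poly.conjoin(inv)
        if poly.is_empty():
            return None
    return Polyhedron(poly.canonical(), poly.variables)


def parametric_reach(net: BioLHANetwork, init: Sequence[int],
                     init_constraint: Polyhedron | None = None,
                     max_symbolic_states: int = 4000,
                     subsume: str = "polyhedron") -> ReachResult:
    """Least fixpoint of time elapse and discrete jumps, breadth first.

    With ``subsume="polyhedron"`` a candidate region is discarded when an
    already-stored region at the same location entails it.  This is the
    exact fixpoint, but around sustained oscillations the clock-offset
    relations accumulate unboundedly and no finite fixpoint exists
    (parametric reachability is undecidable in general); the ceiling
    then raises :class:`ReachOverflow` carrying the partial result.

    With ``subsume="location"`` at most one region is kept per discrete
    location.  Because the delay domains are closed at zero, every
    region produced by this construction contains the all-zero
    valuation (clocks 0, all delays 0), at which every invariant holds
    and every due guard is satisfied; hence any region at a location
    enables exactly the discretely enabled edges, location-level
    subsumption terminates, and the set of visited location vectors is
    exactly the discrete projection of the full symbolic reach set.
    Use this mode to count reachable discrete states.

    States where a delay comes due but no switch condition holds are
    *time-blocked*: they are retained and flagged, and simply have no
    outgoing symbolic edge.
    """
    if subsume not in ("polyhedron", "location"):
        raise ValueError(f"unknown subsumption mode {subsume!r}")
    loc0 = net.check_state(init)
    poly0 = init_constraint if init_constraint is not None else net.initial_constraint()
    start = _post(net, loc0, poly0)
    if start is None:
        raise ValueError("initial constraint violates the initial invariants")
    states: list[SymbolicState] = [SymbolicState(loc0, start, 0)]
    edges: list[tuple[int, LHAEdge, int]] = []
    by_loc: dict[GlobalState, list[int]] = {loc0: [0]}
    queue: deque[int] = deque([0])
    while queue:
        i = queue.popleft()
        src = states[i]
        fired = False
        for gi, comp in enumerate(net.components):
            for e in comp.edges_from(src.location[gi]):
                if not net.condition_holds(src.location, e.condition):
                    continue
                q = src.polyhedron.conjoin(e.guard)
                if q.is_empty():
                    continue
                fired = True
                q = q.reset(comp.clocks)
                loc2 = src.location[:gi] + (e.destination,) + src.location[gi + 1:]
                q2 = _post(net, loc2, q)
                if q2 is None:
                    continue
                target = None
                if subsume == "location":
                    stored = by_loc.get(loc2, ())
                    target = stored[0] if stored else None
                else:
                    for j in by_loc.get(loc2, ()):
                        if q2.entails(states[j].polyhedron):
                            target = j
                            break
                if target is None:
                    if len(states) >= max_symbolic_states:
                        raise ReachOverflow(
                            f"symbolic state ceiling {max_symbolic_states} reached",
                            ReachResult(states, edges, complete=False),
                        )
                    target = len(states)
                    states.append(SymbolicState(loc2, q2, target))
                    by_loc.setdefault(loc2, []).append(target)
                    queue.append(target)
                states[target].incoming.append((i, e))
                edges.append((i, e, target))
        if not fired and net.invariants_at(src.location):
            src.time_blocked = True
    return ReachResult(states, edges, complete=True)


def reach_path(net: BioLHANetwork, path: Sequence[Sequence[int]],
               init_constraint: Polyhedron | None = None
               ) -> list[Polyhedron]:
    """Re-run reachability restricted to a given discrete state sequence.

    Returns the (possibly several, if parallel edges realize a hop)
    regions of the final state; empty list when the path is not
    realizable.
    """
    path = [net.check_state(s) for s in path]
    if not path:
        raise ValueError("empty path")
    poly0 = init_constraint if init_constraint is not None else net.initial_constraint()
    start = _post(net, path[0], poly0)
    if start is None:
        return []
    current: list[Polyhedron] = [start]
    for loc, loc2 in zip(path, path[1:]):
        diff = [k for k in range(len(loc)) if loc[k] != loc2[k]]
        if len(diff) != 1:
            raise ValueError(
                f"path hop {loc} -> {loc2} must change exactly one gene"
            )
        gi = diff[0]
        comp = net.components[gi]
        nxt: list[Polyhedron] = []
        for e in comp.edges_from(loc[gi]):
            if e.destination != loc2[gi]:
                continue
            if not net.condition_holds(loc, e.condition):
                continue
            for p in current:
                q = p.conjoin(e.guard)
                if q.is_empty():
                    continue
                q = q.reset(comp.clocks)
                q2 = _post(net, loc2, q)
                if q2 is not None:
                    nxt.append(q2)
        if not nxt:
            return []
        current = nxt
    return current


@dataclass
class DelayConstraints:
    """Delay-parameter projection of a symbolic state or path.

    ``disjuncts`` is a finite union of parameter polyhedra (usually a
    single one); entailment holds when *every* disjunct satisfies the
    constraint, i.e. the constraint is necessary for the behaviour.
    """

    disjuncts: tuple[Polyhedron, ...]
    parameters: tuple[DelayParameter, ...]

    @property
    def empty(self) -> bool:
        return all(p.is_empty() for p in self.disjuncts) if self.disjuncts else True

    def entails(self, constraint: LinearConstraint | str) -> bool:
        c = (parse_delay_constraint(constraint)
             if isinstance(constraint, str) else constraint)
        if not self.disjuncts:
            return True
        return all(p.entails(c) for p in self.disjuncts)

    def display_rename(self) -> dict[str, str]:
        return {p.name: p.display for p in self.parameters
                if p.direction == DEGRADATION}

    def _display_poly(self, p: Polyhedron) -> Polyhedron:
        """Rewrite degradation parameters to their magnitudes |d-| = -d-."""
        flip = {p_.name for p_ in self.parameters
                if p_.direction == DEGRADATION}
        cons = []
        for c in p.canonical():
            coeffs = {
                (f"|{v}|" if v in flip else v): (-k if v in flip else k)
                for v, k in c.coeffs.items()
            }
            cons.append(LinearConstraint(coeffs, c.const, c.relation))
        return Polyhedron(cons)

    def render(self) -> str:
        parts = []
        for p in self.disjuncts:
            parts.append(self._display_poly(p.minimized()).render())
        return " | ".join(parts) if parts else "false"

    def to_json(self) -> dict:
        return {
            "parameters": [p.display for p in self.parameters],
            "disjuncts": [self._display_poly(p.minimized()).to_json()
                          for p in self.disjuncts],
        }


def parse_delay_constraint(text: str) -> LinearConstraint:
    """Parse a printed-style delay constraint, mapping displayed
    magnitudes |d_g1-| back to the internal negative parameters."""
    c = parse_constraint(text)
    coeffs: dict[str, Fraction] = {}
    for v, k in c.coeffs.items():
        if v.startswith("|") and v.endswith("|"):
            coeffs[v[1:-1]] = coeffs.get(v[1:-1], Rat(0)) - k
        else:
            coeffs[v] = coeffs.get(v, Rat(0)) + k
    return LinearConstraint(coeffs, c.const, c.relation)


def delay_constraints(net: BioLHANetwork,
                      source: "SymbolicState | Sequence[Sequence[int]]",
                      init_constraint: Polyhedron | None = None
                      ) -> DelayConstraints:
    """Delay-parameter constraints of a symbolic state or discrete path.

    Clocks are eliminated exactly; the result ranges over delay
    parameters only.  For a path, reachability is re-run restricted to
    that discrete sequence; an unrealizable path yields an explicitly
    empty result.
    """
    if isinstance(source, SymbolicState):
        polys = [source.polyhedron]
    else:
        polys = reach_path(net, source, init_constraint)
    clocks = set(net.clocks)
    out, seen = [], set()
    for p in polys:
        q = p.eliminate(clocks & p.variables).minimized()
        if q.is_empty():
            continue
        key = frozenset(c.key() for c in q.canonical())
        if key in seen or any(q.equivalent(prev) for prev in out):
            continue
        seen.add(key)
        out.append(q)
    return DelayConstraints(tuple(out), net.parameters)


# ---------------------------------------------------------------------------
# concrete timed simulation

@dataclass
class TimedStep:
    state: GlobalState
    entry_time: Fraction
    dwell: Fraction | None
    fired: LHAEdge | None


@dataclass
class ConcreteTimedTrace:
    steps: list[TimedStep]
    gamma: dict[str, Fraction]
    blocked: bool = False
    horizon_reached: bool = False

    def discrete_path(self) -> list[GlobalState]:
        return [s.state for s in self.steps]


def concrete_simulate(net: BioLHANetwork, gamma: Mapping[str, object],
                      init: Sequence[int], horizon,
                      max_events: int = 200,
                      max_branches: int = 16) -> list[ConcreteTimedTrace]:
    """Deterministic earliest-deadline runs under a parameter valuation.

    In each composite location the next event is the earliest clock
    deadline; if its switch condition holds the edge fires (all
    interleavings are explored when several deadlines coincide), and if
    no due edge can fire the run is time-blocked.  Returns the list of
    distinct runs (singleton unless deadlines tie).
    """
    horizon = Rat(horizon)
    loc0 = net.check_state(init)
    g: dict[str, Fraction] = {}
    for p in net.parameters:
        if p.name not in gamma:
            raise ValueError(f"missing parameter {p.display}")
        v = Rat(gamma[p.name])
        if p.direction == PRODUCTION and v < 0:
            raise ValueError(f"{p.display} must be >= 0")
        if p.direction == DEGRADATION and v > 0:
            raise ValueError(f"{p.name} must be <= 0 (it is displayed |d-|)")
        g[p.name] = v
    traces: list[ConcreteTimedTrace] = []

    def run(loc, clocks, now, steps, events):
        if len(traces) >= max_branches:
            return
        # deadlines: per running clock with an invariant bound
        deadlines: list[tuple[Fraction, int, LHAEdge]] = []
        for gi, comp in enumerate(net.components):
            lvl = loc[gi]
            for e in comp.edges_from(lvl):
                rate = comp.rates[lvl].get(e.clock, 0)
                if rate == 0:
                    continue
                h = clocks[e.clock]
                dt = (g[e.parameter.name] - h) * rate   # works for +-1
                if dt < 0:
                    continue
                deadlines.append((dt, gi, e))
        if not deadlines:
            traces.append(ConcreteTimedTrace(steps, dict(g)))
            return
        dt_min = min(d for d, _, _ in deadlines)
        if now + dt_min > horizon or events >= max_events:
            traces.append(ConcreteTimedTrace(
                steps, dict(g), horizon_reached=True))
            return
        new_clocks = dict(clocks)
        for gi, comp in enumerate(net.components):
            for h, rate in comp.rates[loc[gi]].items():
                new_clocks[h] = new_clocks[h] + rate * dt_min
        now2 = now + dt_min
        due = [(gi, e) for d, gi, e in deadlines if d == dt_min]
        firable = [
            (gi, e) for gi, e in due if net.condition_holds(loc, e.condition)
        ]
        if not firable:
            traces.append(ConcreteTimedTrace(
                steps + [TimedStep(loc, now2, None, None)],
                dict(g), blocked=True))
            return
        for gi, e in firable:
            comp = net.components[gi]
            clocks3 = dict(new_clocks)
            for h in comp.clocks:
                clocks3[h] = Rat(0)
            loc3 = loc[:gi] + (e.destination,) + loc[gi + 1:]
            run(loc3, clocks3, now2,
                steps + [TimedStep(loc3, now2, None, e)], events + 1)

    clocks0 = {h: Rat(0) for h in net.clocks}
    run(loc0, clocks0,
        Rat(0), [TimedStep(loc0, Rat(0), None, None)], 0)
    return traces
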