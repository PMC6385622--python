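"""Automata networks: discrete semantics of a regulatory network.

Every gene is a finite automaton whose local states are its discrete
levels; a *local transition* moves one gene between adjacent levels and
is conditioned on a set of other genes' local states (at most one per
gene).  A *global state* picks one level per gene.  The default
execution is asynchronous — one local transition per step, which is the
semantics of all published state-transition graphs for these models —
while generalized steps (any set of transitions touching distinct
genes) are available behind a flag.

The builder derives the transition set from the interaction graph: for
each gene and adjacent level pair, activation conditions produce rises
and inhibition conditions produce falls, with conditions taken from a
minimal cube cover of the gene's regulation formula and expanded into
explicit one-local-state-per-regulator combinations.  Self-regulation
is absorbed into the origin level: a cube constraining the gene itself
applies only to transitions whose origin level satisfies it.
"""
from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

from .brn import InteractionGraph
from .regulation import cube_switch_condition, prime_cover

GlobalState = tuple[int, ...]


@dataclass(frozen=True, order=True)
class LocalState:
    gene: str
    level: int

    def __str__(self):
        return f"{self.gene}{self.level}"


@dataclass(frozen=True)
class LocalTransition:
    """``origin --condition--> destination`` within one gene's automaton."""

    origin: LocalState
    condition: frozenset[LocalState]
    destination: LocalState

    def __post_init__(self):
        if self.origin.gene != self.destination.gene:
            raise ValueError("local transition must stay within one automaton")
        if abs(self.origin.level - self.destination.level) != 1:
            raise ValueError("local transitions connect adjacent levels only")
        genes = [ls.gene for ls in self.condition]
        if len(genes) != len(set(genes)):
            raise ValueError("condition holds at most one local state per gene")
        if self.origin.gene in genes:
            raise ValueError("condition must not mention the transition's own gene")

    @property
    def gene(self) -> str:
        return self.origin.gene

    def __str__(self):
        cond = ",".join(str(ls) for ls in sorted(self.condition))
        return f"{self.origin} -{{{cond}}}-> {self.destination}"


Step = tuple[LocalTransition, ...]
Trace = tuple[Step, ...]


class AutomataNetwork:
    """(genes, local state sets, local transitions)."""

    def __init__(self, genes: Mapping[str, int],
                 transitions: Iterable[LocalTransition]):
        #: gene name -> max level, in declaration order
        self.genes: dict[str, int] = dict(genes)
        self.transitions: tuple[LocalTransition, ...] = tuple(transitions)
        for t in self.transitions:
            for ls in (t.origin, t.destination, *t.condition):
                if ls.gene not in self.genes:
                    raise ValueError(f"transition mentions undeclared gene {ls.gene!r}")
                if not 0 <= ls.level <= self.genes[ls.gene]:
                    raise ValueError(f"local state {ls} outside the gene's levels")

    @property
    def gene_order(self) -> tuple[str, ...]:
        return tuple(self.genes)

    def index(self, gene: str) -> int:
        return self.gene_order.index(gene)

    def state_count(self) -> int:
        n = 1
        for l in self.genes.values():
            n *= l + 1
        return n

    def all_states(self) -> Iterator[GlobalState]:
        return itertools.product(*(range(l + 1) for l in self.genes.values()))

    def check_state(self, state: Sequence[int]) -> GlobalState:
        state = tuple(state)
        if len(state) != len(self.genes):
            raise ValueError(f"state arity {len(state)} != {len(self.genes)} genes")
        for (g, l), v in zip(self.genes.items(), state):
            if not 0 <= v <= l:
                raise ValueError(f"level {v} of {g} outside 0..{l}")
        return state

    def render_state(self, state: Sequence[int]) -> str:
        return "<" + ",".join(str(v) for v in state) + ">"

    def transitions_of(self, gene: str) -> tuple[LocalTransition, ...]:
        return tuple(t for t in self.transitions if t.gene == gene)

    def local_value(self, state: Sequence[int], gene: str) -> int:
        return state[self.index(gene)]


# ---------------------------------------------------------------------------
# construction from an interaction graph

def build_an(graph: InteractionGraph) -> AutomataNetwork:
    """Derive the automata network of an interaction graph.

    Regulated genes get one transition per (adjacent level pair,
    condition combination); input-flagged genes get unconditioned
    transitions in their flagged direction; unregulated unflagged genes
    are constant.
    """
    problems = graph.validate()
    if problems:
        raise ValueError("invalid interaction graph:\n" + "\n".join(problems))
    genes = {g.name: g.max_level for g in graph.genes.values()}
    max_levels = dict(genes)
    out: list[LocalTransition] = []
    for name, gene in graph.genes.items():
        l = gene.max_level
        if gene.input is not None:
            for k in range(l):
                if gene.input in ("rise", "both"):
                    out.append(LocalTransition(
                        LocalState(name, k), frozenset(), LocalState(name, k + 1)))
                if gene.input in ("fall", "both"):
                    out.append(LocalTransition(
                        LocalState(name, k + 1), frozenset(), LocalState(name, k)))
            continue
        rf = graph.logic.get(name)
        if rf is None:
            continue    # constant gene
        thresholds = graph.thresholds_for(name)
        rise_cubes = prime_cover(rf, True)
        fall_cubes = prime_cover(rf, False)
        if not rise_cubes or not fall_cubes:
            raise ValueError(
                f"regulation formula of {name} is constant; the gene could "
                f"never both rise and fall (declare it an input instead)"
            )
        for cubes, delta in ((rise_cubes, +1), (fall_cubes, -1)):
            for k in range(l):
                origin = k if delta == +1 else k + 1
                dest = origin + delta
                seen: set[frozenset[LocalState]] = set()
                for cube in cubes:
                    cube = dict(cube)
                    if name in cube:
                        t = thresholds[name]
                        ok = origin >= t if cube.pop(name) else origin < t
                        if not ok:
                            continue
                    sc = cube_switch_condition(cube, thresholds, max_levels)
                    for combo in sc.denotation():
                        cond = frozenset(LocalState(r, v) for r, v in combo)
                        if cond in seen:
                            continue
                        seen.add(cond)
                        out.append(LocalTransition(
                            LocalState(name, origin), cond, LocalState(name, dest)))
    return AutomataNetwork(genes, out)


# ---------------------------------------------------------------------------
# semantics

def playable(an: AutomataNetwork, state: Sequence[int],
             transition: LocalTransition) -> bool:
    """A transition is playable when its origin is active and every local
    state of its condition holds in the global state."""
    state = tuple(state)
    if state[an.index(transition.gene)] != transition.origin.level:
        return False
    return all(state[an.index(ls.gene)] == ls.level for ls in transition.condition)


def playable_transitions(an: AutomataNetwork, state: Sequence[int]
                         ) -> list[LocalTransition]:
    return [t for t in an.transitions if playable(an, state, t)]


def apply_step(an: AutomataNetwork, state: Sequence[int], step: Step
               ) -> GlobalState:
    genes = [t.gene for t in step]
    if len(genes) != len(set(genes)):
        raise ValueError("a step may change each gene at most once")
    new = list(state)
    for t in step:
        if not playable(an, state, t):
            raise ValueError(f"transition {t} is not playable in {tuple(state)}")
        new[an.index(t.gene)] = t.destination.level
    return tuple(new)


def successors(an: AutomataNetwork, state: Sequence[int],
               semantics: str = "async") -> dict[GlobalState, list[Step]]:
    """Successor states with the steps that realize them.

    ``async``: one playable transition per step.  ``step``: every
    non-empty set of playable transitions touching distinct genes.
    """
    state = an.check_state(state)
    pl = playable_transitions(an, state)
    result: dict[GlobalState, list[Step]] = {}
    if semantics == "async":
        steps: Iterable[Step] = ((t,) for t in pl)
    elif semantics == "step":
        def gen() -> Iterator[Step]:
            for r in range(1, len(pl) + 1):
                for sub in itertools.combinations(pl, r):
                    genes = [t.gene for t in sub]
                    if len(genes) == len(set(genes)):
                        yield sub
        steps = gen()
    else:
        raise ValueError(f"unknown semantics {semantics!r}")
    for step in steps:
        result.setdefault(apply_step(an, state, step), []).append(step)
    return result


def reachable(an: AutomataNetwork, init: Sequence[int],
              semantics: str = "async") -> nx.DiGraph:
    """Breadth-first state transition graph from ``init``.

    Nodes are global states (tuples); each edge carries the realizing
    steps under attribute ``steps``.  Exploration order is deterministic:
    genes in declaration order, transitions in their declared order.
    """
    init = an.check_state(init)
    g = nx.DiGraph()
    g.add_node(init)
    queue = deque([init])
    while queue:
        state = queue.popleft()
        for succ, steps in successors(an, state, semantics).items():
            if succ not in g:
                g.add_node(succ)
                queue.append(succ)
            g.add_edge(state, succ, steps=tuple(steps))
    return g


def stable_states(an: AutomataNetwork, max_states: int = 200_000
                  ) -> list[GlobalState]:
    """All global states with no playable transition, by exhaustive
    enumeration of the product space (desk scale)."""
    n = an.state_count()
    if n > max_states:
        raise ValueError(
            f"state space has {n} states, above the enumeration bound "
            f"{max_states}; raise max_states to force the computation"
        )
    return [s for s in an.all_states() if not playable_transitions(an, s)]


def matches_goal(an: AutomataNetwork, state: Sequence[int],
                 goal: Iterable[LocalState] | LocalState) -> bool:
    goals = (goal,) if isinstance(goal, LocalState) else tuple(goal)
    return all(state[an.index(g.gene)] == g.level for g in goals)


def find_trace(an: AutomataNetwork, init: Sequence[int],
               goal: Iterable[LocalState] | LocalState,
               semantics: str = "async") -> Trace | None:
    """A shortest trace whose final state contains the goal, or None."""
    init = an.check_state(init)
    if matches_goal(an, init, goal):
        return ()
    parent: dict[GlobalState, tuple[GlobalState, Step]] = {}
    queue = deque([init])
    seen = {init}
    while queue:
        state = queue.popleft()
        for succ, steps in successors(an, state, semantics).items():
            if succ in seen:
                continue
            seen.add(succ)
            parent[succ] = (state, steps[0])
            if matches_goal(an, succ, goal):
                trace: list[Step] = []
                cur = succ
                while cur != init:
                    prev, step = parent[cur]
                    trace.append(step)
                    cur = prev
                return tuple(reversed(trace))
            queue.append(succ)
    return None


def replay(an: AutomataNetwork, init: Sequence[int], trace: Trace
           ) -> GlobalState:
    """Apply a trace step by step; raises if any step is unplayable."""
    state = an.check_state(init)
    for step in trace:
        state = apply_step(an, state, step)
    return state
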