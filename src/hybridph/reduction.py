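"""Goal-oriented reduction and cutsets, by exact enumeration.

A *goal* is a (partial) state to be reached from a given initial state.
*Minimal traces* are the acyclic runs to the goal — no global state is
visited twice — and the goal-oriented reduction keeps exactly the local
transitions occurring in some minimal trace.  A *cutset* is a set of
local states hit by every minimal trace (through the condition or the
origin of one of its transitions): disabling every transition that uses
a cutset member makes the goal unreachable, which is the formal version
of a combined knock-out proposal.

Everything here enumerates explicitly and is meant for desk-scale
models (a few thousand global states); large networks need dedicated
abstraction-based tooling, which is out of scope.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .automata import (
    AutomataNetwork,
    GlobalState,
    LocalState,
    Trace,
    apply_step,
    matches_goal,
    playable,
    successors,
)


@dataclass(frozen=True)
class Goal:
    """Target local state(s) to reach from ``init``."""

    targets: tuple[LocalState, ...]
    init: GlobalState

    def __post_init__(self):
        if not self.targets:
            raise ValueError("a goal needs at least one target local state")


@dataclass(frozen=True)
class Cutset:
    members: frozenset[LocalState]
    minimal: bool = True
    #: members that are part of the initial state (a knock-out of the
    #: starting condition rather than of an intermediate step)
    in_initial_state: frozenset[LocalState] = frozenset()

    def __str__(self):
        return "{" + ", ".join(str(m) for m in sorted(self.members)) + "}"


@dataclass
class MinimalTraces:
    traces: tuple[Trace, ...]
    truncated: bool = False


class TruncationError(RuntimeError):
    """Raised when trace enumeration hit its length bound; the partial
    result is carried on the exception."""

    def __init__(self, message, partial: MinimalTraces):
        super().__init__(message)
        self.partial = partial


def minimal_traces(an: AutomataNetwork, goal: Goal,
                   bound: int | None = None) -> MinimalTraces:
    """All acyclic traces from the goal's initial state to a state
    containing the goal, in deterministic (depth-first, declared
    transition order) order.

    Traces stop at the first goal-containing state; ``bound`` caps the
    trace length and sets ``truncated`` when some search branch was cut
    short while the goal was still reachable from it.
    """
    init = an.check_state(goal.init)
    if bound is not None and bound < 0:
        raise ValueError("bound must be >= 0")
    out: list[Trace] = []
    truncated = False

    def dfs(state: GlobalState, visited: set[GlobalState], prefix: list):
        nonlocal truncated
        if matches_goal(an, state, goal.targets):
            out.append(tuple(prefix))
            return
        if bound is not None and len(prefix) >= bound:
            if _goal_reachable(an, state, goal.targets, forbidden=visited):
                truncated = True
            return
        for t in an.transitions:
            if not playable(an, state, t):
                continue
            nxt = apply_step(an, state, (t,))
            if nxt in visited:
                continue
            visited.add(nxt)
            prefix.append((t,))
            dfs(nxt, visited, prefix)
            prefix.pop()
            visited.remove(nxt)

    dfs(init, {init}, [])
    return MinimalTraces(tuple(out), truncated)


def _goal_reachable(an, state, targets, forbidden=frozenset()) -> bool:
    from collections import deque

    if matches_goal(an, state, targets):
        return True
    seen = {state} | set(forbidden)
    queue = deque([state])
    while queue:
        s = queue.popleft()
        for nxt in successors(an, s):
            if nxt in seen:
                continue
            if matches_goal(an, nxt, targets):
                return True
            seen.add(nxt)
            queue.append(nxt)
    return False


def goal_reduce(an: AutomataNetwork, goal: Goal,
                bound: int | None = None) -> AutomataNetwork:
    """Keep exactly the transitions occurring in some minimal trace.

    The reduced network preserves goal reachability (the minimal traces
    themselves survive); its transition set is a subset of the original.
    """
    mt = minimal_traces(an, goal, bound)
    kept = {t for trace in mt.traces for step in trace for t in step}
    reduced = AutomataNetwork(
        an.genes, [t for t in an.transitions if t in kept]
    )
    if mt.truncated:
        raise TruncationError(
            "minimal-trace enumeration hit its bound; reduction is partial",
            MinimalTraces(mt.traces, True),
        )
    return reduced


def _involved(trace: Trace) -> frozenset[LocalState]:
    """Local states a trace involves: conditions and origins of its
    transitions (destinations excluded: disabling a process prevents it
    from enabling or performing hits, not from being produced)."""
    states: set[LocalState] = set()
    for step in trace:
        for t in step:
            states.add(t.origin)
            states |= t.condition
    return frozenset(states)


def disable(an: AutomataNetwork, members: Iterable[LocalState]
            ) -> AutomataNetwork:
    """Remove every transition whose condition or origin intersects the
    given local states."""
    members = frozenset(members)
    return AutomataNetwork(
        an.genes,
        [
            t for t in an.transitions
            if t.origin not in members and not (t.condition & members)
        ],
    )


@dataclass
class CutsetReport:
    cutsets: tuple[Cutset, ...]
    #: goal was unreachable to begin with: nothing to cut
    already_cut: bool = False
    truncated: bool = False


def cutsets(an: AutomataNetwork, goal: Goal, kmax: int,
            bound: int | None = None) -> CutsetReport:
    """Minimal cutsets of size <= kmax for the goal.

    Candidates are the minimal hitting sets of the per-trace involved
    local-state sets; every candidate is then verified by disabling its
    members and re-checking reachability, and only verified cutsets are
    returned (with subset-minimality enforced against each other).
    Goal-specification local states are never proposed.
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    mt = minimal_traces(an, goal, bound)
    if not mt.traces:
        return CutsetReport((), already_cut=True, truncated=mt.truncated)
    goal_states = set(goal.targets)
    involved = [frozenset(s for s in _involved(tr) if s not in goal_states)
                for tr in mt.traces]
    if any(not s for s in involved):
        # some trace involves nothing cuttable (e.g. the empty trace)
        return CutsetReport((), already_cut=False, truncated=mt.truncated)
    init_states = {
        LocalState(g, lvl) for g, lvl in zip(an.gene_order, goal.init)
    }
    candidates = sorted(frozenset().union(*involved))
    found: list[Cutset] = []
    for k in range(1, kmax + 1):
        for combo in itertools.combinations(candidates, k):
            members = frozenset(combo)
            if any(c.members <= members for c in found):
                continue    # not minimal
            if not all(members & s for s in involved):
                continue    # not a hitting set
            if _goal_reachable(disable(an, members), goal.init, goal.targets):
                continue    # hitting the enumerated traces was not enough
            found.append(Cutset(
                members,
                minimal=True,
                in_initial_state=members & init_states,
            ))
    return CutsetReport(tuple(found), truncated=mt.truncated)
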