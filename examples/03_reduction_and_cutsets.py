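"""Goal-oriented reduction and cutsets on the cooperative toy model.

The goal is the activation of r from <p,q,r> = <1,0,0>.  The reduction
keeps only the transitions used by minimal (acyclic) traces to the
goal; the cutsets are local states whose knock-out provably severs
every route to the goal — the formal version of a therapeutic-target
proposal.
"""
from hybridph import build_an, load_fixture
from hybridph.automata import LocalState
from hybridph.reduction import Goal, cutsets, goal_reduce, minimal_traces

an = build_an(load_fixture("toy-cascade"))
goal = Goal((LocalState("r", 1),), (1, 0, 0))

mt = minimal_traces(an, goal)
print(f"{len(mt.traces)} minimal trace(s) to r=1:")
for trace in mt.traces:
    print("  " + " :: ".join(str(t) for step in trace for t in step))

reduced = goal_reduce(an, goal)
print(f"\nreduction keeps {len(reduced.transitions)} of "
      f"{len(an.transitions)} transitions:")
for t in reduced.transitions:
    print("  ", t)

report = cutsets(an, goal, kmax=1)
print("\nverified minimal cutsets (size 1):")
for c in report.cutsets:
    note = "  [knocks out part of the initial state]" if c.in_initial_state else ""
    print(f"  {c}{note}")
print("disabling any one of these local states makes r=1 unreachable.")
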