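"""Derive the automata network of the toy oscillator and explore its
discrete dynamics: transitions, state graph, stable states, traces.

p and q activate r; r inhibits q.  With p held high the q/r pair forms
a negative feedback loop and the system cycles through four states.
"""
from hybridph import build_an, find_trace, load_fixture, reachable, stable_states
from hybridph.automata import LocalState

an = build_an(load_fixture("toy-oscillator"))
print("local transitions:")
for t in an.transitions:
    print("  ", t)

stg = reachable(an, (1, 0, 0))
print(f"\nfrom <1,0,0>: {stg.number_of_nodes()} states, "
      f"{stg.number_of_edges()} edges (a pure 4-cycle)")
for a, b in stg.edges:
    print(f"  {an.render_state(a)} -> {an.render_state(b)}")

print("\nstable states (no playable transition):",
      [an.render_state(s) for s in stable_states(an)] or "none — the input "
      "transition of p keeps every resting state alive")

trace = find_trace(an, (1, 0, 0), LocalState("r", 1))
print("\nshortest trace to r=1:")
for step in trace:
    print("  ", " ; ".join(str(t) for t in step))
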