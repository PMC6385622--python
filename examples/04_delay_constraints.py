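"""Delay-constraint synthesis on the toy oscillator.

Each gene's rise takes a production delay d+ and each fall a
degradation delay (displayed |d-|).  For the cyclic discrete path of
the oscillator, the clock-eliminated polyhedron characterizes exactly
which delay orderings realize that path; a concrete simulation at a
satisfying valuation reproduces it, and a violating valuation deviates
at the first race it loses.
"""
from fractions import Fraction as F

from hybridph import build_an, build_network, concrete_simulate, \
    delay_constraints, load_fixture

an = build_an(load_fixture("toy-oscillator"))
net = build_network(an)
path = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1), (1, 0, 0)]

dc = delay_constraints(net, path)
print("path:", " -> ".join(an.render_state(s) for s in path))
print("delay constraints:")
for line in dc.render().split(" & "):
    print("   ", line)

good = {"d_p1+": F(1), "d_q1+": F(2), "d_q1-": F(-1),
        "d_r1+": F(3), "d_r1-": F(-2)}
tr = concrete_simulate(net, good, (0, 0, 0), horizon=6)[0]
print("\nsimulation at d_p1+=1, d_q1+=2, |d_q1-|=1, d_r1+=3, |d_r1-|=2:")
for step in tr.steps:
    print(f"   t={step.entry_time}: {an.render_state(step.state)}")
print("-> follows the path above; p wins the first race because d_p1+ is")
print("   the smallest pending delay, and each later hop fires at its")
print("   accumulated deadline.")

bad = dict(good, **{"d_p1+": F(4)})
tr = concrete_simulate(net, bad, (0, 0, 0), horizon=6)[0]
print(f"\nwith d_p1+=4 instead (violating d_p1+ <= d_q1+), the second "
      f"state is {an.render_state(tr.steps[1].state)}: q fires first and "
      f"the path deviates.")
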