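# hybridph — hybrid process hitting for gene regulatory networks

Logical (Thomas-style) models of gene regulatory networks describe each
gene by a handful of discrete expression levels and each regulation by a
signed threshold: gene *p* activates or inhibits gene *q* once *p* is at
or above its threshold.  Such models answer *whether* a behaviour is
possible, but not *when*: switching a level up takes a production delay
d⁺ and switching it down a degradation delay (written |d⁻|), and it is
the ordering of these delays — not just the wiring — that decides which
of several competing fates a network commits to.

`hybridph` closes that gap for desk-scale networks.  From an interaction
graph with boolean regulation logic it

1. derives the **automata network** of permissible local transitions
   (one automaton per gene; conditions come from a minimal cube cover of
   the regulation formula over the regulators' threshold cells),
2. analyses the **discrete dynamics**: state transition graphs, stable
   states, shortest traces, minimal (acyclic) traces, goal-oriented
   reduction and verified knock-out **cutsets**,
3. lifts every gene to a **parametric linear hybrid automaton**: one
   clock per direction of change (rate +1 toward d⁺ ≥ 0, rate −1 toward
   d⁻ ≤ 0), guards `h = d` conjoined with the switch condition, and
   location invariants that make every due delay fire or stop time, and
4. runs exact **symbolic polyhedral reachability** (rational
   Fourier–Motzkin projection plus an exact rational simplex — no
   floating point anywhere) to synthesize, per reachable state or per
   discrete path, the **constraints on the delays** that realize it.

The audience is systems biologists and formal-methods researchers who
work with logical models of small regulatory circuits (signalling
switches, phage decision circuits, cell-cycle entry modules) and want
timing conditions, not just reachability verdicts.

## Worked example

Three genes: *p* and *q* activate *r* cooperatively, *r* inhibits *q*,
and *p* drifts up as an input.  `examples/04_delay_constraints.py`
computes the delay constraints of the oscillator's cyclic path and
validates them by concrete simulation:

```
path: <0,0,0> -> <1,0,0> -> <1,1,0> -> <1,1,1> -> <1,0,1> -> <1,0,0>
delay constraints:
    0 <= d_p1+
    d_p1+ <= d_q1+
    d_q1+ <= d_r1+
    d_r1+ <= d_q1+ + |d_q1-|
    d_q1+ + |d_q1-| <= d_r1+ + |d_r1-|
    d_r1+ + |d_r1-| <= 2*d_q1+ + |d_q1-|

simulation at d_p1+=1, d_q1+=2, |d_q1-|=1, d_r1+=3, |d_r1-|=2:
   t=0: <0,0,0>
   t=1: <1,0,0>
   t=2: <1,1,0>
   t=3: <1,1,1>
   t=3: <1,0,1>
   t=5: <1,0,0>
```

Reading the numbers: *p* must rise before *q*'s production comes due
(`d_p1+ <= d_q1+`) or the path's first hop is lost to *q*; *r*'s rise
must beat *q*'s full up-down cycle (`d_r1+ <= d_q1+ + |d_q1-|`); and the
final inequality, with its `2*d_q1+` term, exists because clocks reset
only on their own gene's jumps, so *q*'s second production window
accumulates across the other genes' moves.  The valuation
(1, 2, 1, 3, 2) satisfies the polyhedron and the earliest-deadline
simulation reproduces the discrete path at exactly those times;
raising `d_p1+` to 4 violates the first inequality and the simulated
run deviates to `<0,1,0>` at its first event.

The same machinery applied to the packaged four-gene bacteriophage λ
model (`examples/05_phage_lambda.py`) visits 42 of the 48 product
states and prints the delay orderings that commit the phage to
lysogeny (cI reaching its top level: the cascade fires N, then cII,
then cI twice, all before cro's first production) or to lysis (cro
outrunning N, cII and cI).

## Command line

Every analysis is also reachable from a thin CLI:

```
hybridph stg -m toy-oscillator --init 1,0,0
hybridph hybrid -m phage-lambda --init 0,0,0,0 --count-states
hybridph constraints -m toy-oscillator --init 0,0,0 --path "0,0,0;1,0,0;1,1,0"
hybridph cutsets -m toy-cascade --init 1,0,0 --goal r=1
hybridph export-hytech -m phage-lambda -o phage.hy
```

Models are packaged fixture names (`toy-cascade`, `toy-oscillator`,
`phage-lambda`) or BRN-JSON files (schema in
`src/hybridph/schema/brn.schema.json`); SBML-qual documents restricted
to AND/OR/NOT threshold logic can be imported with
`hybridph.import_sbml_qual`.

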