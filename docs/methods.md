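# Methods

## The model class

A regulatory network is an interaction graph: genes with discrete
levels 0..l (l ≥ 1) and signed threshold edges p →(t,s) q, meaning p
influences q once its level reaches t (activating for s = +, inhibiting
for s = −).  Each regulated gene carries a boolean regulation formula
over its regulators; the atom `p` reads "p at or above its threshold
toward this target".  The *effective levels* of an edge are the source
levels at which the influence is exerted ({t..l} for activators,
{0..t−1} for inhibitors); the two polarities always partition {0..l}.

### Discrete semantics

Each gene is an automaton over its levels.  For every adjacent level
pair, the satisfying cells of the regulation formula (over {low,
high}ⁿ regulator configurations) generate rises and the falsifying
cells generate falls.  Conditions are emitted from a **minimal
prime-implicant cube cover** of the formula, then expanded into
explicit one-local-state-per-regulator combinations; for the common
pure-conjunction logic this yields one joint condition for the rise
and one single-literal condition per regulator for the falls, which is
how published transition lists for these models are written.  The raw
2ⁿ minterm partition remains available (`regulation.expand_formula`)
and is what the two-regulator case-table cross-checks use.
Self-regulation is absorbed into the origin level: a cube constraining
the gene itself applies only to transitions whose origin satisfies it
(e.g. a self-limiting gene falls from its top level unconditionally,
because the origin itself witnesses the inhibition).

The default execution is asynchronous (one local transition per step),
which is the semantics of every published state graph for this model
family; generalized steps (any set of transitions touching distinct
genes) are available behind `semantics="step"`.  Transitions connect
adjacent levels only.

Unregulated genes are constant unless flagged as *inputs* with a
trajectory (`rise`, `fall` or `both`), in which case they move
unconditionally in the flagged direction.  The default for the toy
fixtures is `rise`: an input signal that turns on once and stays on.
Both behaviours (input held at its starting level vs. drifting) are
therefore expressible; neither is hard-wired.

### Timed semantics

Every gene becomes a parametric linear hybrid automaton:

* one **production delay** d_g,i+ ≥ 0 per rise i−1 → i and one
  **degradation delay** d_g,i− ≤ 0 per fall i → i−1 (kept negative
  internally, displayed as the magnitude |d−|; delays are distinct per
  level change, because the time to cross different thresholds of the
  same gene is in general different);
* genes with a single threshold use one clock with rate +1 at the
  bottom level and −1 at the top; genes with more levels carry a
  production clock (rate +1) and a degradation clock (rate −1) running
  simultaneously wherever the corresponding move exists (a clock with
  no enabled move at a level is frozen);
* each edge's guard is the switch condition over the other genes'
  levels conjoined with the clock equality h = d; each location's
  invariant bounds every running clock by the parameter of its
  outgoing edge (h ≤ d⁺ for production, h ≥ d⁻ for degradation);
* **all of a gene's clocks reset exactly on that gene's own jumps** —
  never on other genes' jumps.  Clock values therefore accumulate
  across the rest of the network's activity, which is what produces
  summed and multiplied terms (2·d_q1+ + |d_q1−|) in cyclic paths.

Urgency: because the invariant bound and the guard use the same
parameter, a due delay must either fire its transition or stop time.
When a deadline is reached and no switch condition holds, the branch
is **time-blocked**: it is retained in the reach set and flagged, not
silently dropped.  (A region may be blocked for part of its parameter
space and live for the rest; the flag is computed per symbolic state,
not per valuation — a known coarseness.)

The network composition is asynchronous: one component jumps at a
time; the others' levels are read through shared discrete variables.
The initial constraint sets every clock to zero and imposes only the
sign domain on the delays.

## Symbolic reachability

A symbolic state is a pair (location vector, polyhedron over clocks
and delay parameters).  The post operator conjoins the location's
invariants, lets time elapse under the location's rate vector
(projection of an auxiliary t ≥ 0), re-conjoins the invariants, and
then fires each enabled edge (guard conjunction, emptiness check,
reset of the jumping gene's clocks, target invariants, elapse).
Exploration is breadth-first and deterministic (genes in declaration
order, transitions in derivation order).

Two subsumption modes:

* `subsume="polyhedron"` — a candidate region is dropped iff an
  existing region at the same location entails it.  This is the exact
  fixpoint.  Around sustained oscillations it does not terminate: each
  lap of a cycle ties the clocks together through an offset relation
  whose coefficients grow with the lap count, so the regions are
  pairwise incomparable forever (parametric reachability is
  undecidable in general).  A configurable ceiling turns divergence
  into an explicit overflow error carrying the partial result.
* `subsume="location"` — at most one region is kept per location.
  This terminates and computes the **exact discrete projection** of
  the full reach set, by the following observation: every region this
  construction produces contains the all-zero point (clocks 0, all
  delays 0), since the initial region does and conjunction with
  guards/invariants, resets and elapse all preserve it.  At that point
  every due guard is satisfied, so a region enables an edge iff the
  edge's switch condition holds discretely — any region at a location
  yields the same discrete successors.  This mode is what state
  counting uses.

Per-path constraint extraction (`delay_constraints` on a discrete
state sequence) re-runs the post operator restricted to the given
hops — always finitely — then eliminates the clocks exactly and
returns an irredundant parameter polyhedron (one exact LP test per
constraint).  Parallel edges realizing the same hop yield a finite
union; equivalent disjuncts are merged.  An unrealizable path yields
an explicitly empty result.

## Numerical core

All polyhedral arithmetic is exact over `fractions.Fraction`; the
module contains no floating point.  Constraints are non-strict (≤, =)
only — the closed grammar every printed delay constraint in this model
family uses — in H-representation, with no generator form and no
convex-hull widening.  Equalities are removed by Gaussian
substitution; inequalities by Fourier–Motzkin combination with
syntactic pruning after every elimination step.  Feasibility,
entailment and redundancy removal use a dictionary-form simplex with
Bland's rule over the same rationals (sparse rows; problems here have
at most a few dozen variables).  Entailment checks try a syntactic
dominance fast path before falling back to one LP per constraint.

Concrete simulation (`concrete_simulate`) implements the
earliest-deadline run of the timed semantics at a rational valuation:
the next event is the smallest remaining deadline; coinciding
deadlines branch into all interleavings (bounded by `max_branches`);
a due deadline whose switch condition fails ends the run with a
blocked marker.  Dwell times equal the firing parameter's magnitude by
construction, which the tests assert.

## Fixtures and the generator

Three models ship with the package: the two three-gene toys (a
cooperative cascade and the p/q/r oscillator) and the four-gene
bacteriophage λ immunity circuit (cI 0–2, cro 0–3, cII, N) with logic
cI: `!cro & cII`, cro/N: `!cI & !cro`, cII: `!cI & !cro & N`.  One
threshold deserves a note: cro represses cI at threshold 3, the value
of the source model of record for this circuit.  Some published
re-drawings show that threshold as 1; under that reading only 35 of
the 48 product states are reachable from ⟨0,0,0,0⟩ and the lysogenic
path could never be timed against cro's first rise, both contradicting
the circuit's documented behaviour (42 reachable states; lysogeny as a
race of cI's two productions against d_cro1+), so the fixture follows
the source model.  The fixture docstring repeats this note.

`generate.random_brn` emits seeded random models for the property
sweeps: 3–4 genes, levels 1–2, sparse signed edges (density 0.35–0.4),
default conjunction logic, occasional rising inputs.  These sizes
match the desk scale the discrete engines target, and the brute-force
oracles stay exhaustive there.  What the generator does *not* emulate:
measurement noise, unknown logic, or any quantitative rate data —
passing the sweeps shows the engines are exact on the model class, not
that a fitted model of real data is correct.

## Problem sizes

The packaged analyses are small by design: the λ network composes to
48 product locations over 6 clocks and 14 delay parameters; its
location-mode reach closes in 42 symbolic states in about a second,
and each fate path projects in well under a second.  The discrete
engines enumerate exhaustively and are guarded by an explicit bound
(default 200 000 product states) rather than silently scaling.

## Known limitations

* The exact polyhedral fixpoint diverges on oscillating networks (see
  above); only the location-subsumed projection is guaranteed to
  terminate.  No widening/extrapolation is implemented, by choice of
  exactness.
* Time-blocking is flagged per symbolic state, not split per parameter
  region.
* Cutsets interpret "involving" a local state as appearing in a
  transition's condition or origin (destinations excluded): disabling
  a process prevents it from enabling or performing moves.  Cutset
  members inside the initial state are legal but flagged, since they
  knock out the starting condition itself.
* The goal-oriented reduction enumerates acyclic traces explicitly and
  is meant for desk-scale models (roughly ≤ 12 genes / a few thousand
  states), not for the abstraction-based scaling of dedicated static
  analyzers.
* SBML-qual import covers AND/OR/NOT over single-threshold literals
  with declared input signs; richer MathML is rejected with a pointed
  error rather than guessed at.
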