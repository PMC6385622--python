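"""Exact rational linear programming (dictionary simplex, Bland's rule).

Private numerical substrate for the polyhedron engine.  All arithmetic is
over :class:`fractions.Fraction`; there is no floating point here.  The
problems solved are tiny (tens of variables and constraints), so a plain
dictionary-form simplex with anti-cycling pivoting is both simple and fast
enough; rows are kept as sparse dicts because switch-condition and clock
constraints mention only a handful of variables each.
"""
from __future__ import annotations

from fractions import Fraction
from typing import Mapping, Sequence

Zero = Fraction(0)

OPTIMAL = "optimal"
UNBOUNDED = "unbounded"
INFEASIBLE = "infeasible"


def maximize(
    objective: Mapping[str, Fraction],
    constraints: Sequence[tuple[Mapping[str, Fraction], Fraction]],
) -> tuple[str, Fraction | None]:
    """Maximize ``objective . x`` subject to ``a . x <= b`` for each (a, b).

    Variables are free (unrestricted in sign).  Returns ``(status, value)``
    with status one of OPTIMAL / UNBOUNDED / INFEASIBLE; ``value`` is the
    exact optimum for OPTIMAL and None otherwise.
    """
    dic = _Dictionary(constraints)
    if not dic.make_feasible():
        return INFEASIBLE, None
    if dic.optimize(objective):
        return OPTIMAL, dic.objective_value()
    return UNBOUNDED, None


def feasible(
    constraints: Sequence[tuple[Mapping[str, Fraction], Fraction]],
) -> bool:
    """True iff some rational point satisfies every ``a . x <= b``."""
    return _Dictionary(constraints).make_feasible()


class _Dictionary:
    """Simplex dictionary over split variables.

    Each free variable v is represented as v = pos(v) - neg(v) with both
    parts nonnegative; each constraint contributes a nonnegative slack.
    Basic variables are expressed as ``const + sum coef * nonbasic`` with
    the invariant const >= 0 once feasible.
    """

    def __init__(self, constraints):
        names = sorted({v for a, _ in constraints for v in a})
        self.col: dict[str, int] = {}
        nxt = 0
        for v in names:                      # pos/neg split, stable ids
            self.col[v] = nxt
            nxt += 2
        self.nvars = nxt
        self.rows: dict[int, tuple[Fraction, dict[int, Fraction]]] = {}
        for i, (a, b) in enumerate(constraints):
            terms: dict[int, Fraction] = {}
            for v, c in a.items():
                if c == 0:
                    continue
                j = self.col[v]
                terms[j] = terms.get(j, Zero) - c        # slack = b - a.x
                terms[j + 1] = terms.get(j + 1, Zero) + c
            self.rows[self.nvars + i] = (Fraction(b), terms)
        self.obj: tuple[Fraction, dict[int, Fraction]] = (Zero, {})

    # -- pivoting ---------------------------------------------------------
    def _pivot(self, leave: int, enter: int) -> None:
        const, terms = self.rows.pop(leave)
        coef = terms.pop(enter)
        # leave = const + coef*enter + rest  =>  enter = (leave - const - rest)/coef
        inv = Fraction(-1, 1) / coef
        e_const = const * inv
        e_terms = {j: c * inv for j, c in terms.items()}
        e_terms[leave] = -inv
        self.rows[enter] = (e_const, e_terms)

        def subst(pair):
            c0, t = pair
            ce = t.pop(enter, None)
            if ce is None or ce == 0:
                return (c0, t)
            c0 = c0 + ce * e_const
            for j, c in e_terms.items():
                nv = t.get(j, Zero) + ce * c
                if nv == 0:
                    t.pop(j, None)
                else:
                    t[j] = nv
            return (c0, t)

        for b in list(self.rows):
            if b != enter:
                self.rows[b] = subst(self.rows[b])
        self.obj = subst(self.obj)

    def _bland_step(self) -> bool | None:
        """One simplex step on the current objective.

        Returns True when optimal, None when a pivot was made, False when
        unbounded.
        """
        _, oterms = self.obj
        enter = None
        for j in sorted(oterms):
            if oterms[j] > 0:
                enter = j
                break
        if enter is None:
            return True
        leave, best = None, None
        for b in sorted(self.rows):
            const, terms = self.rows[b]
            c = terms.get(enter, Zero)
            if c < 0:
                ratio = const / (-c)
                if best is None or ratio < best:
                    best, leave = ratio, b
        if leave is None:
            return False
        self._pivot(leave, enter)
        return None

    def _run(self) -> bool:
        while True:
            r = self._bland_step()
            if r is not None:
                return r

    # -- phases -----------------------------------------------------------
    def make_feasible(self) -> bool:
        """Phase one: drive all basic constants nonnegative."""
        if all(const >= 0 for const, _ in self.rows.values()):
            return True
        art = self.nvars + len(self.rows) + 1    # auxiliary x0
        for b in list(self.rows):
            const, terms = self.rows[b]
            terms[art] = Fraction(1)
            self.rows[b] = (const, terms)
        self.obj = (Zero, {art: Fraction(-1)})   # maximize -x0
        # special first pivot: most negative row enters x0 into the basis
        leave = min(self.rows, key=lambda b: (self.rows[b][0], b))
        self._pivot(leave, art)
        self._run()                              # bounded by construction
        const, terms = self.obj
        if const != 0:
            return False
        if art in self.rows:                     # degenerate: x0 basic at 0
            _, t = self.rows[art]
            enter = next((j for j in sorted(t) if t[j] != 0), None)
            if enter is None:
                del self.rows[art]
            else:
                self._pivot(art, enter)
        for b in list(self.rows):                # scrub x0 from rows
            c0, t = self.rows[b]
            t.pop(art, None)
            self.rows[b] = (c0, t)
        self.obj = (Zero, {})
        return True

    def optimize(self, objective: Mapping[str, Fraction]) -> bool:
        """Phase two on an already-feasible dictionary; True iff bounded."""
        terms: dict[int, Fraction] = {}
        for v, c in objective.items():
            if c == 0 or v not in self.col:
                continue
            j = self.col[v]
            terms[j] = terms.get(j, Zero) + c
            terms[j + 1] = terms.get(j + 1, Zero) - c
        const = Zero
        for v, c in objective.items():
            if v not in self.col and c != 0:
                # variable absent from every constraint: unbounded direction
                return False
        obj = (const, dict(terms))
        # rewrite through current basis
        for b, (bc, bt) in self.rows.items():
            c0, t = obj
            cb = t.pop(b, None)
            if cb is None or cb == 0:
                obj = (c0, t)
                continue
            c0 += cb * bc
            for j, c in bt.items():
                nv = t.get(j, Zero) + cb * c
                if nv == 0:
                    t.pop(j, None)
                else:
                    t[j] = nv
            obj = (c0, t)
        self.obj = obj
        return self._run()

    def objective_value(self) -> Fraction:
        return self.obj[0]
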