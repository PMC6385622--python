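"""Exact rational polyhedra over clocks and delay parameters.

This module is the computational substrate for parametric reachability of
hybrid gene-network models.  A :class:`Polyhedron` is a finite conjunction
of *non-strict* rational linear constraints (``<=`` and ``==`` only) over
named variables — clock variables, delay parameters and short-lived
auxiliaries.  The operations are the ones a symbolic reachability engine
needs:

* :meth:`Polyhedron.conjoin` — intersection,
* :meth:`Polyhedron.is_empty` — exact feasibility (rational simplex),
* :meth:`Polyhedron.time_elapse` — flow under clock rates in {-1, 0, +1},
* :meth:`Polyhedron.reset` — clock reset to zero,
* :meth:`Polyhedron.eliminate` — exact existential projection
  (Gaussian substitution for equalities, Fourier–Motzkin for
  inequalities),
* :meth:`Polyhedron.entails` / :meth:`Polyhedron.equivalent` — inclusion
  and equality of denotations, used for fixpoint detection.

All arithmetic is exact (``fractions.Fraction``); no floating point is
used anywhere in this module.  Polyhedra are closed by construction:
strict inequalities are outside the constraint grammar.
"""
from __future__ import annotations

import re
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Sequence

from . import _simplex

Rat = Fraction


def _rat(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        raise TypeError("floating point is not allowed in the polyhedron engine")
    return Fraction(x)


class LinearConstraint:
    """``sum(coeffs[v] * v) REL const`` with REL in {``<=``, ``==``}.

    Zero coefficients are dropped on construction.  A constraint with no
    remaining variables is a trivial truth or falsehood, exposed through
    :meth:`is_tautology` / :meth:`is_contradiction`.
    """

    __slots__ = ("coeffs", "const", "relation")

    def __init__(self, coeffs: Mapping[str, object], const, relation: str = "<="):
        if relation not in ("<=", "=="):
            raise ValueError(f"unsupported relation {relation!r}; grammar is non-strict")
        self.coeffs: dict[str, Fraction] = {
            v: _rat(c) for v, c in coeffs.items() if _rat(c) != 0
        }
        self.const = _rat(const)
        self.relation = relation

    # -- constructors -----------------------------------------------------
    @classmethod
    def le(cls, coeffs, const) -> "LinearConstraint":
        return cls(coeffs, const, "<=")

    @classmethod
    def ge(cls, coeffs, const) -> "LinearConstraint":
        """``sum >= const`` stored as the negated ``<=`` form."""
        return cls({v: -_rat(c) for v, c in coeffs.items()}, -_rat(const), "<=")

    @classmethod
    def eq(cls, coeffs, const) -> "LinearConstraint":
        return cls(coeffs, const, "==")

    # -- predicates -------------------------------------------------------
    def is_tautology(self) -> bool:
        if self.coeffs:
            return False
        return self.const >= 0 if self.relation == "<=" else self.const == 0

    def is_contradiction(self) -> bool:
        if self.coeffs:
            return False
        return self.const < 0 if self.relation == "<=" else self.const != 0

    def variables(self) -> frozenset[str]:
        return frozenset(self.coeffs)

    def evaluate(self, point: Mapping[str, object]) -> bool:
        lhs = sum((c * _rat(point.get(v, 0)) for v, c in self.coeffs.items()), Rat(0))
        return lhs <= self.const if self.relation == "<=" else lhs == self.const

    # -- algebra ----------------------------------------------------------
    def substitute(self, var: str, expr: Mapping[str, Fraction], const: Fraction
                   ) -> "LinearConstraint":
        """Replace ``var`` by the affine expression ``expr . x + const``."""
        c = self.coeffs.get(var)
        if c is None:
            return self
        coeffs = dict(self.coeffs)
        del coeffs[var]
        for v, e in expr.items():
            coeffs[v] = coeffs.get(v, Rat(0)) + c * e
        return LinearConstraint(coeffs, self.const - c * const, self.relation)

    def scaled(self, k: Fraction) -> "LinearConstraint":
        if k <= 0 and self.relation == "<=":
            raise ValueError("inequalities may only be scaled by positive factors")
        return LinearConstraint(
            {v: c * k for v, c in self.coeffs.items()}, self.const * k, self.relation
        )

    def normalized(self) -> "LinearConstraint":
        """Scale to coprime integer coefficients (orientation-preserving)."""
        if not self.coeffs:
            if self.relation == "==":
                return LinearConstraint({}, 0 if self.const == 0 else 1, "==")
            return LinearConstraint({}, 0 if self.const >= 0 else -1, "<=")
        from math import gcd, lcm

        den = lcm(*(c.denominator for c in self.coeffs.values()), self.const.denominator)
        num = gcd(*(abs(c.numerator * den // c.denominator) for c in self.coeffs.values()))
        k = Fraction(den, num or 1)
        if self.relation == "==":
            lead = self.coeffs[min(self.coeffs)]
            if lead < 0:
                return LinearConstraint(
                    {v: -c * k for v, c in self.coeffs.items()}, -self.const * k, "=="
                )
        return self.scaled(k)

    def key(self):
        n = self.normalized()
        return (n.relation, tuple(sorted(n.coeffs.items())), n.const)

    def functional_key(self):
        """Hashable key for the left-hand side only (same normalization)."""
        n = self.normalized()
        return (n.relation, tuple(sorted(n.coeffs.items())))

    def __eq__(self, other):
        return isinstance(other, LinearConstraint) and self.key() == other.key()

    def __hash__(self):
        return hash(self.key())

    def __repr__(self):
        return f"LinearConstraint({self.render()!r})"

    def render(self, rename: Mapping[str, str] | None = None) -> str:
        """Human-readable form, e.g. ``d_p1+ + |d_q1-| <= 2*d_r1+``."""
        def name(v):
            return rename.get(v, v) if rename else v

        pos, neg = [], []
        for v in sorted(self.coeffs):
            c = self.coeffs[v]
            (pos if c > 0 else neg).append((abs(c), name(v)))

        def side(terms, const):
            parts = [f"{t[1]}" if t[0] == 1 else f"{t[0]}*{t[1]}" for t in terms]
            text = " + ".join(parts)
            if const != 0 or not parts:
                if not parts:
                    text = str(const)
                elif const > 0:
                    text += f" + {const}"
                else:
                    text += f" - {-const}"
            return text

        rel = "<=" if self.relation == "<=" else "="
        # move negative-coefficient terms to the right-hand side
        return f"{side(pos, 0) if pos else '0'} {rel} {side(neg, self.const)}"


TRUE = LinearConstraint({}, 0, "<=")


class Polyhedron:
    """A conjunction of non-strict linear constraints (H-representation).

    Instances are treated as immutable; every operation returns a new
    polyhedron.  ``variables`` records the declared dimension set, which
    may exceed the variables actually constrained.
    """

    __slots__ = ("variables", "constraints", "_canonical", "_empty")

    def __init__(self, constraints: Iterable[LinearConstraint] = (),
                 variables: Iterable[str] = ()):
        self.constraints: tuple[LinearConstraint, ...] = tuple(constraints)
        names = set(variables)
        for c in self.constraints:
            names |= c.variables()
        self.variables: frozenset[str] = frozenset(names)
        self._canonical: tuple[LinearConstraint, ...] | None = None
        self._empty: bool | None = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def universe(cls, variables: Iterable[str] = ()) -> "Polyhedron":
        return cls((), variables)

    @classmethod
    def empty(cls, variables: Iterable[str] = ()) -> "Polyhedron":
        return cls((LinearConstraint({}, -1, "<="),), variables)

    @classmethod
    def from_constraints(cls, constraints, variables=()) -> "Polyhedron":
        return cls(constraints, variables)

    # -- basic queries ----------------------------------------------------
    def contains_point(self, point: Mapping[str, object]) -> bool:
        return all(c.evaluate(point) for c in self.constraints)

    def _ineq_rows(self, constraints=None):
        """Constraints as simplex rows (equalities become two inequalities)."""
        rows = []
        for c in (self.constraints if constraints is None else constraints):
            rows.append((c.coeffs, c.const))
            if c.relation == "==":
                rows.append(({v: -k for v, k in c.coeffs.items()}, -c.const))
        return rows

    def is_empty(self) -> bool:
        if self._empty is None:
            if any(c.is_contradiction() for c in self.constraints):
                self._empty = True
            else:
                self._empty = not _simplex.feasible(self._ineq_rows())
        return self._empty

    # -- lattice operations ----------------------------------------------
    def conjoin(self, other) -> "Polyhedron":
        """Intersection with a constraint or another polyhedron."""
        if isinstance(other, LinearConstraint):
            extra: tuple[LinearConstraint, ...] = (other,)
            variables = self.variables | other.variables()
        elif isinstance(other, Polyhedron):
            extra = other.constraints
            variables = self.variables | other.variables
        else:
            raise TypeError(f"cannot conjoin {type(other).__name__}")
        return Polyhedron(self.constraints + extra, variables)

    # -- canonical form ---------------------------------------------------
    def canonical(self) -> tuple[LinearConstraint, ...]:
        """Duplicate-free constraint list with syntactic dominance removed.

        Equalities are Gauss-reduced and substituted through the
        inequalities; the result entails and is entailed by the raw list.
        Full LP-based redundancy removal is available via :meth:`minimized`.
        """
        if self._canonical is not None:
            return self._canonical
        eqs, ineqs = self._solved_form()
        if eqs is None:
            self._canonical = (LinearConstraint({}, -1, "<="),)
            return self._canonical
        out: list[LinearConstraint] = [
            LinearConstraint(dict(expr, **{v: Fraction(-1)}), -const, "==").normalized()
            for v, (expr, const) in sorted(eqs.items())
        ]
        out.extend(_prune(ineqs))
        self._canonical = tuple(out)
        return self._canonical

    def _solved_form(self):
        """(eq_substitutions, reduced inequalities) or (None, None) if an
        immediate contradiction is found syntactically.

        eq_substitutions maps var -> (expr, const) meaning var = expr.x+const,
        triangular in variable order.
        """
        subs: dict[str, tuple[dict[str, Fraction], Fraction]] = {}
        ineqs: list[LinearConstraint] = []
        pending = list(self.constraints)
        for c in pending:
            for v in sorted(set(c.coeffs) & set(subs)):
                expr, const = subs[v]
                c = c.substitute(v, expr, const)
            if c.relation == "<=":
                if c.is_contradiction():
                    return None, None
                if not c.is_tautology():
                    ineqs.append(c)
                continue
            if c.is_contradiction():
                return None, None
            if c.is_tautology():
                continue
            # solve for the first variable present
            v = min(c.coeffs)
            cv = c.coeffs[v]
            expr = {u: -k / cv for u, k in c.coeffs.items() if u != v}
            const = c.const / cv
            # keep existing substitutions triangular
            for u, (uexpr, uconst) in list(subs.items()):
                if v in uexpr:
                    k = uexpr.pop(v)
                    for w, e in expr.items():
                        uexpr[w] = uexpr.get(w, Rat(0)) + k * e
                        if uexpr[w] == 0:
                            del uexpr[w]
                    subs[u] = (uexpr, uconst + k * const)
            subs[v] = (expr, const)
            ineqs = [i.substitute(v, expr, const) for i in ineqs]
            bad = [i for i in ineqs if i.is_contradiction()]
            if bad:
                return None, None
            ineqs = [i for i in ineqs if not i.is_tautology()]
        return subs, ineqs

    # -- projection -------------------------------------------------------
    def eliminate(self, vars: Iterable[str]) -> "Polyhedron":
        """Exact existential projection onto the remaining variables.

        Variables pinned by an equality are removed by substitution;
        the rest by Fourier–Motzkin combination of lower and upper
        bounds, pruning duplicates after every step.
        """
        drop = set(vars)
        unknown = drop - self.variables
        if unknown:
            raise KeyError(f"cannot eliminate undeclared variables {sorted(unknown)}")
        if self.is_empty():
            return Polyhedron.empty(self.variables - drop)
        work = list(self.canonical())
        for v in sorted(drop):
            work = _eliminate_one(work, v)
            if work is None:
                return Polyhedron.empty(self.variables - drop)
        return Polyhedron(work, self.variables - drop)

    def time_elapse(self, rates: Mapping[str, int]) -> "Polyhedron":
        """Flow forward in time under per-clock rates in {-1, 0, +1}.

        Result: { x' | exists x in self, t >= 0 : x'_h = x_h + rate_h * t,
        and x'_v = x_v for unrated variables }.  Implemented by
        substituting h -> h - rate_h * t, adding t >= 0, and eliminating
        the auxiliary t.
        """
        for h, r in rates.items():
            if r not in (-1, 0, 1):
                raise ValueError(f"rate of {h} must be -1, 0 or +1, got {r}")
        aux = "__elapse"
        out = []
        for c in self.constraints:
            for h, r in rates.items():
                if r != 0 and h in c.coeffs:
                    c = c.substitute(h, {h: Rat(1), aux: Rat(-r)}, Rat(0))
            out.append(c)
        out.append(LinearConstraint({aux: Rat(-1)}, 0, "<="))  # t >= 0
        return Polyhedron(out, self.variables | {aux}).eliminate([aux])

    def reset(self, clocks: Iterable[str]) -> "Polyhedron":
        """Set each clock to zero, forgetting its previous value."""
        clocks = list(clocks)
        p = self.eliminate(clocks)
        zero = [LinearConstraint({h: Rat(1)}, 0, "==") for h in clocks]
        return Polyhedron(p.constraints + tuple(zero), self.variables)

    # -- entailment -------------------------------------------------------
    def entails(self, other: "Polyhedron | LinearConstraint") -> bool:
        """True iff every point of self satisfies ``other``."""
        targets = (other,) if isinstance(other, LinearConstraint) else other.constraints
        if self.is_empty():
            return True
        mine = {c.key() for c in self.constraints} | {c.key() for c in self.canonical()}
        rows = None
        for c in targets:
            if c.is_tautology() or c.key() in mine:
                continue
            if rows is None:
                rows = self._ineq_rows(self.canonical())
            if not _entailed_by_rows(rows, c):
                return False
        return True

    def equivalent(self, other: "Polyhedron") -> bool:
        return self.entails(other) and other.entails(self)

    # -- presentation -----------------------------------------------------
    def minimized(self) -> "Polyhedron":
        """Irredundant constraint list (one exact LP test per constraint)."""
        if self.is_empty():
            return Polyhedron.empty(self.variables)
        kept = list(self.canonical())
        i = 0
        while i < len(kept):
            c = kept[i]
            if c.relation == "==":
                i += 1
                continue
            rest = kept[:i] + kept[i + 1:]
            if Polyhedron(rest, self.variables).entails(c):
                kept = rest
            else:
                i += 1
        return Polyhedron(kept, self.variables)

    def render(self, rename: Mapping[str, str] | None = None) -> str:
        cons = self.canonical()
        if not cons:
            return "true"
        if self.is_empty():
            return "false"
        return " & ".join(c.render(rename) for c in cons)

    def to_json(self) -> dict:
        return {
            "variables": sorted(self.variables),
            "constraints": [
                {
                    "coeffs": {v: str(c) for v, c in sorted(k.coeffs.items())},
                    "const": str(k.const),
                    "relation": k.relation,
                }
                for k in self.canonical()
            ],
        }

    def __repr__(self):
        return f"Polyhedron({self.render()})"


# ---------------------------------------------------------------------------
# internals

def _eliminate_one(constraints: list[LinearConstraint], var: str):
    """One Fourier–Motzkin / substitution step.  None means empty."""
    eq = next((c for c in constraints if c.relation == "==" and var in c.coeffs), None)
    if eq is not None:
        cv = eq.coeffs[var]
        expr = {u: -k / cv for u, k in eq.coeffs.items() if u != var}
        const = eq.const / cv
        out = []
        for c in constraints:
            if c is eq:
                continue
            c = c.substitute(var, expr, const)
            if c.is_contradiction():
                return None
            if not c.is_tautology():
                out.append(c)
        return _prune(out)

    lowers, uppers, rest = [], [], []
    for c in constraints:
        a = c.coeffs.get(var)
        if a is None:
            rest.append(c)
        elif a > 0:
            uppers.append(c)   # a*var <= const - rest
        else:
            lowers.append(c)
    for lo in lowers:
        for up in uppers:
            # combine: scale to cancel var
            al, au = lo.coeffs[var], up.coeffs[var]
            comb = LinearConstraint(
                {
                    v: lo.coeffs.get(v, Rat(0)) * au - up.coeffs.get(v, Rat(0)) * al
                    for v in set(lo.coeffs) | set(up.coeffs)
                },
                lo.const * au - up.const * al,
                "<=",
            )
            if comb.is_contradiction():
                return None
            if not comb.is_tautology():
                rest.append(comb)
    return _prune(rest)


def _prune(constraints: Sequence[LinearConstraint]) -> list[LinearConstraint]:
    """Cheap syntactic pruning: dedup, drop dominated same-functional rows."""
    best: dict[tuple, LinearConstraint] = {}
    eqs: dict[tuple, LinearConstraint] = {}
    order: list[tuple] = []
    for c in constraints:
        if c.is_tautology():
            continue
        n = c.normalized()
        fk = n.functional_key()
        if n.relation == "==":
            if fk not in eqs:
                eqs[fk] = n
                order.append(("eq", fk))
            continue
        cur = best.get(fk)
        if cur is None:
            best[fk] = n
            order.append(("le", fk))
        elif n.const < cur.const:
            best[fk] = n
    out = []
    for kind, fk in order:
        out.append(eqs[fk] if kind == "eq" else best[fk])
    return out


def _entailed_by_rows(rows, c: LinearConstraint) -> bool:
    """Is ``c`` implied by the (feasible) system ``rows``?  Exact LP check."""
    status, val = _simplex.maximize(c.coeffs, rows)
    if status == _simplex.INFEASIBLE:
        return True
    if status == _simplex.UNBOUNDED or val > c.const:
        return False
    if c.relation == "==":
        status, val = _simplex.maximize({v: -k for v, k in c.coeffs.items()}, rows)
        if status != _simplex.OPTIMAL or val > -c.const:
            return False
    return True


# ---------------------------------------------------------------------------
# constraint syntax
#
#   constraint := sum REL sum
#   sum        := term (("+" | "-") term)*
#   term       := [coef "*"] atom | coef
#   atom       := identifier, optionally ending in "+" or "-", optionally
#                 wrapped in |...| (used for displayed degradation delays)
#   REL        := "<=" | ">=" | "="
#
# Rational coefficients are written like 3 or 3/2.

_TOKEN = re.compile(
    r"\s*(?:(?P<rel><=|>=|==?)|(?P<num>\d+(?:/\d+)?)"
    r"|(?P<var>\|[^|]+\||[A-Za-z_][A-Za-z0-9_]*(?:(?<=[0-9])[+-])?)"
    r"|(?P<op>[+*-]))"
)


def parse_constraint(text: str) -> LinearConstraint:
    """Parse one constraint in the rendering syntax, e.g. ``h <= d_p1+``."""
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ValueError(f"cannot tokenize constraint at: {text[pos:]!r}")
            break
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))

    def parse_sum(toks):
        coeffs: dict[str, Fraction] = {}
        const = Rat(0)
        sign = Rat(1)
        i = 0
        expect_term = True
        while i < len(toks):
            kind, tok = toks[i]
            if kind == "op" and tok in "+-" and not expect_term:
                sign = Rat(1) if tok == "+" else Rat(-1)
                expect_term = True
                i += 1
                continue
            if kind == "op" and tok == "-" and expect_term:
                sign = -sign
                i += 1
                continue
            if kind == "num":
                coef = Fraction(tok)
                if i + 1 < len(toks) and toks[i + 1] == ("op", "*"):
                    if i + 2 >= len(toks) or toks[i + 2][0] != "var":
                        raise ValueError("expected variable after '*'")
                    v = toks[i + 2][1]
                    coeffs[v] = coeffs.get(v, Rat(0)) + sign * coef
                    i += 3
                elif i + 1 < len(toks) and toks[i + 1][0] == "var":
                    v = toks[i + 1][1]
                    coeffs[v] = coeffs.get(v, Rat(0)) + sign * coef
                    i += 2
                else:
                    const += sign * coef
                    i += 1
            elif kind == "var":
                coeffs[tok] = coeffs.get(tok, Rat(0)) + sign
                i += 1
            else:
                raise ValueError(f"unexpected token {tok!r}")
            sign = Rat(1)
            expect_term = False
        return coeffs, const

    split = next((i for i, (k, _) in enumerate(tokens) if k == "rel"), None)
    if split is None:
        raise ValueError(f"no relation in constraint: {text!r}")
    if split == 0 or split == len(tokens) - 1:
        raise ValueError(f"relation needs both sides: {text!r}")
    rel = tokens[split][1]
    lc, lconst = parse_sum(tokens[:split])
    rc, rconst = parse_sum(tokens[split + 1:])
    coeffs = dict(lc)
    for v, c in rc.items():
        coeffs[v] = coeffs.get(v, Rat(0)) - c
    const = rconst - lconst
    if rel == ">=":
        return LinearConstraint.ge(coeffs, const)
    if rel in ("=", "=="):
        return LinearConstraint.eq(coeffs, const)
    return LinearConstraint.le(coeffs, const)


def parse_polyhedron(text: str, variables: Iterable[str] = ()) -> Polyhedron:
    """Parse an ``&``-separated conjunction of constraints."""
    text = text.strip()
    if not text or text == "true":
        return Polyhedron.universe(variables)
    return Polyhedron(
        [parse_constraint(part) for part in text.split("&")], variables
    )
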