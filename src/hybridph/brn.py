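"""Interaction graphs of biological regulatory networks.

A regulatory network is a directed graph of genes (or other species)
whose edges carry a discrete threshold and a sign: gene ``p`` activates
(``+``) or inhibits (``-``) gene ``q`` once its level is at or above the
threshold.  Each regulated gene additionally carries a boolean
*regulation formula* over its regulators, describing how their joint
presence drives the gene up or down; the atom ``p`` reads "p is at or
above its threshold toward this target", ``!p`` reads "below".

Levels are 0-based: a gene with ``max_level`` l has l+1 discrete levels
{0..l}.  An unregulated gene is constant unless it carries an *input
trajectory* flag (``rise``, ``fall`` or ``both``), in which case it
drifts freely between adjacent levels in the flagged direction(s).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

INPUT_TRAJECTORIES = ("rise", "fall", "both")


@dataclass(frozen=True)
class Gene:
    name: str
    max_level: int = 1
    #: None for regulated/constant genes; one of INPUT_TRAJECTORIES for
    #: input genes that evolve unconditionally.
    input: str | None = None

    def __post_init__(self):
        if self.max_level < 1:
            raise ValueError(f"gene {self.name!r}: max_level must be >= 1")
        if self.input is not None and self.input not in INPUT_TRAJECTORIES:
            raise ValueError(
                f"gene {self.name!r}: input must be one of {INPUT_TRAJECTORIES}"
            )

    @property
    def levels(self) -> range:
        return range(self.max_level + 1)


@dataclass(frozen=True)
class Interaction:
    """A signed threshold edge ``source --(threshold, sign)--> target``."""

    source: str
    target: str
    threshold: int
    sign: str

    def __post_init__(self):
        if self.sign not in ("+", "-"):
            raise ValueError(f"interaction sign must be '+' or '-', got {self.sign!r}")
        if self.threshold < 1:
            raise ValueError("interaction threshold must be >= 1")


def effective_levels(interaction: Interaction, source_max: int, polarity: str
                     ) -> frozenset[int]:
    """Levels of the source at which it exerts (``+``) or withholds (``-``)
    its influence on the target.

    For an activation at threshold t the exerting levels are {t..l}; for
    an inhibition they are {0..t-1}; polarity ``-`` is the complement
    within {0..l}.
    """
    if polarity not in ("+", "-"):
        raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")
    t, l = interaction.threshold, source_max
    if not 1 <= t <= l:
        raise ValueError(
            f"threshold {t} of {interaction.source}->{interaction.target} "
            f"outside 1..{l}"
        )
    high = frozenset(range(t, l + 1))
    low = frozenset(range(0, t))
    exerting = high if interaction.sign == "+" else low
    return exerting if polarity == "+" else frozenset(range(l + 1)) - exerting


# ---------------------------------------------------------------------------
# boolean regulation formulas (atoms & ! | and parentheses)

class Formula:
    """AST node; subclasses: Atom, Not, And, Or."""

    def atoms(self) -> frozenset[str]:
        raise NotImplementedError

    def evaluate(self, assignment: Mapping[str, bool]) -> bool:
        raise NotImplementedError

    def __repr__(self):
        return f"{type(self).__name__}({self!s})"


@dataclass(frozen=True, repr=False)
class Atom(Formula):
    name: str

    def atoms(self):
        return frozenset({self.name})

    def evaluate(self, a):
        return bool(a[self.name])

    def __str__(self):
        return self.name


@dataclass(frozen=True, repr=False)
class Not(Formula):
    arg: Formula

    def atoms(self):
        return self.arg.atoms()

    def evaluate(self, a):
        return not self.arg.evaluate(a)

    def __str__(self):
        s = str(self.arg)
        return f"!{s}" if isinstance(self.arg, Atom) else f"!({s})"


@dataclass(frozen=True, repr=False)
class And(Formula):
    args: tuple[Formula, ...]

    def atoms(self):
        return frozenset().union(*(f.atoms() for f in self.args))

    def evaluate(self, a):
        return all(f.evaluate(a) for f in self.args)

    def __str__(self):
        return " & ".join(
            f"({f})" if isinstance(f, Or) else str(f) for f in self.args
        )


@dataclass(frozen=True, repr=False)
class Or(Formula):
    args: tuple[Formula, ...]

    def atoms(self):
        return frozenset().union(*(f.atoms() for f in self.args))

    def evaluate(self, a):
        return any(f.evaluate(a) for f in self.args)

    def __str__(self):
        return " | ".join(str(f) for f in self.args)


def parse_formula(text: str) -> Formula:
    """Parse ``!``, ``&``, ``|`` and parentheses over gene-name atoms.

    Precedence (tightest first): ``!``, ``&``, ``|``.
    """
    import re

    tokens = re.findall(r"[A-Za-z_][A-Za-z0-9_]*|[!&|()]", text)
    if "".join(tokens).replace(" ", "") != text.replace(" ", ""):
        raise ValueError(f"cannot tokenize formula: {text!r}")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take(expected=None):
        nonlocal pos
        tok = peek()
        if tok is None or (expected is not None and tok != expected):
            raise ValueError(f"formula syntax error near token {pos} in {text!r}")
        pos += 1
        return tok

    def parse_or():
        args = [parse_and()]
        while peek() == "|":
            take()
            args.append(parse_and())
        return args[0] if len(args) == 1 else Or(tuple(args))

    def parse_and():
        args = [parse_not()]
        while peek() == "&":
            take()
            args.append(parse_not())
        return args[0] if len(args) == 1 else And(tuple(args))

    def parse_not():
        if peek() == "!":
            take()
            return Not(parse_not())
        if peek() == "(":
            take()
            f = parse_or()
            take(")")
            return f
        tok = take()
        if not tok[0].isalpha() and tok[0] != "_":
            raise ValueError(f"expected atom, got {tok!r} in {text!r}")
        return Atom(tok)

    f = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in formula {text!r}")
    return f


@dataclass(frozen=True)
class RegulationFormula:
    """Boolean regulation logic of one target gene."""

    target: str
    formula: Formula

    @property
    def regulators(self) -> frozenset[str]:
        return self.formula.atoms()

    def evaluate(self, above_threshold: Mapping[str, bool]) -> bool:
        return self.formula.evaluate(above_threshold)

    def __str__(self):
        return str(self.formula)


def default_formula(target: str, interactions: Sequence[Interaction]
                    ) -> RegulationFormula:
    """Conjunction of signed literals: ``p`` for activators, ``!p`` for
    inhibitors, in source order of the given interactions."""
    lits: list[Formula] = []
    for i in interactions:
        if i.target != target:
            continue
        lits.append(Atom(i.source) if i.sign == "+" else Not(Atom(i.source)))
    if not lits:
        raise ValueError(f"gene {target!r} has no regulators")
    return RegulationFormula(target, lits[0] if len(lits) == 1 else And(tuple(lits)))


# ---------------------------------------------------------------------------

class InteractionGraph:
    """Genes, signed threshold interactions and per-gene regulation logic.

    Gene order is significant: global states, reports and generated
    automata all follow declaration order.
    """

    def __init__(self, genes: Iterable[Gene],
                 interactions: Iterable[Interaction] = (),
                 logic: Mapping[str, RegulationFormula | str] | None = None):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.name in self.genes:
                raise ValueError(f"duplicate gene {g.name!r}")
            self.genes[g.name] = g
        self.interactions: list[Interaction] = list(interactions)
        self.logic: dict[str, RegulationFormula] = {}
        for target, f in (logic or {}).items():
            if isinstance(f, str):
                f = RegulationFormula(target, parse_formula(f))
            self.logic[target] = f
        # regulated genes without explicit logic get the default conjunction
        for name in self.genes:
            if name not in self.logic and self.regulators(name):
                self.logic[name] = default_formula(name, self.interactions)

    # -- queries ----------------------------------------------------------
    @property
    def gene_order(self) -> tuple[str, ...]:
        return tuple(self.genes)

    def regulators(self, target: str) -> tuple[Interaction, ...]:
        return tuple(i for i in self.interactions if i.target == target)

    def interaction(self, source: str, target: str) -> Interaction | None:
        for i in self.interactions:
            if i.source == source and i.target == target:
                return i
        return None

    def thresholds_for(self, target: str) -> dict[str, int]:
        return {i.source: i.threshold for i in self.regulators(target)}

    # -- validation -------------------------------------------------------
    def validate(self) -> list[str]:
        """All invariant violations, each naming the offending element.

        An empty list means the graph is well formed.  Violations are
        returned rather than raised so that partially-built models can be
        inspected.
        """
        problems: list[str] = []
        seen_pairs: set[tuple[str, str]] = set()
        for i in self.interactions:
            pair = (i.source, i.target)
            if pair in seen_pairs:
                problems.append(f"duplicate interaction {i.source}->{i.target}")
            seen_pairs.add(pair)
            for end in pair:
                if end not in self.genes:
                    problems.append(
                        f"interaction {i.source}->{i.target}: undeclared gene {end!r}"
                    )
            src = self.genes.get(i.source)
            if src is not None and not 1 <= i.threshold <= src.max_level:
                problems.append(
                    f"interaction {i.source}->{i.target}: threshold {i.threshold} "
                    f"outside 1..{src.max_level}"
                )
        for target, rf in self.logic.items():
            if target not in self.genes:
                problems.append(f"regulation formula for undeclared gene {target!r}")
                continue
            declared = {i.source for i in self.regulators(target)}
            for atom in sorted(rf.regulators - declared):
                problems.append(
                    f"logic of {target}: atom {atom!r} is not a declared regulator"
                )
            for missing in sorted(declared - rf.regulators):
                problems.append(
                    f"logic of {target}: regulator {missing!r} does not appear"
                )
        for name, g in self.genes.items():
            if self.regulators(name) and g.input is not None:
                problems.append(
                    f"gene {name}: flagged as input but has declared regulators"
                )
        return problems

    def check(self) -> "InteractionGraph":
        problems = self.validate()
        if problems:
            raise ValueError("invalid interaction graph:\n" + "\n".join(problems))
        return self
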