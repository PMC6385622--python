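"""Regulation conditions, hit parts and switch conditions.

A gene's rise or fall is driven by its regulators' joint position
relative to their thresholds.  Abstractly every regulator is either low
(``L``: below its threshold toward the target) or high (``H``: at or
above it), so the joint configurations of n regulators are the 2^n cells
of {L,H}^n.  The cells satisfying the target's regulation formula are
*activation* conditions (the gene tends up), the falsifying cells are
*inhibition* conditions (the gene tends down); for the classic
two-regulator logical functions this recovers the familiar
one-activation / three-inhibition case table.

A *switch condition* makes a cell concrete: each L/H coordinate becomes
a closed interval of discrete levels ({0..t-1} or {t..l}), whose
expansion enumerates the exact regulator-level combinations enabling a
transition of the target automaton.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

from .brn import RegulationFormula

LOW, HIGH = "L", "H"


@dataclass(frozen=True)
class HitPart:
    """Abstract regulator cell of a hit: regulators in fixed order with
    one L/H letter each.  ``kind`` is "single" for one regulator and
    "pair" for the cooperative two-regulator case."""

    regulators: tuple[str, ...]
    cell: str   # e.g. "L", "H", "LL", "LH", ...

    def __post_init__(self):
        if len(self.regulators) != len(self.cell) or not self.cell:
            raise ValueError("cell arity must match the number of regulators")
        if any(ch not in (LOW, HIGH) for ch in self.cell):
            raise ValueError(f"cell letters must be L/H, got {self.cell!r}")

    @property
    def kind(self) -> str:
        return {1: "single", 2: "pair"}.get(len(self.cell), "n-ary")

    def __str__(self):
        if len(self.regulators) == 1:
            return f"{self.regulators[0]}_{self.cell}"
        return "".join(self.regulators) + "_" + self.cell


@dataclass(frozen=True)
class RegulationCase:
    """Case-table row for a cooperative hit by two regulators: the single
    activation cell and the three inhibition cells."""

    signs: tuple[str, str]
    activation: HitPart
    inhibition: tuple[HitPart, ...]

    def __post_init__(self):
        cells = {self.activation.cell} | {h.cell for h in self.inhibition}
        if cells != {"LL", "LH", "HL", "HH"}:
            raise ValueError("activation + inhibition must partition the four cells")


@dataclass(frozen=True)
class SwitchCondition:
    """Closed integer level interval per regulator; its denotation is the
    set of explicit level combinations obtained by expanding each
    interval."""

    intervals: tuple[tuple[str, int, int], ...]   # (regulator, lo, hi)

    def __post_init__(self):
        for reg, lo, hi in self.intervals:
            if lo > hi:
                raise ValueError(f"empty interval for {reg}: [{lo}, {hi}]")

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {r: (lo, hi) for r, lo, hi in self.intervals}

    def denotation(self) -> Iterator[tuple[tuple[str, int], ...]]:
        """Explicit regulator-level combinations, in lexicographic order."""
        ranges = [
            [(reg, lvl) for lvl in range(lo, hi + 1)]
            for reg, lo, hi in self.intervals
        ]
        return (tuple(combo) for combo in itertools.product(*ranges))

    def __str__(self):
        parts = []
        for reg, lo, hi in self.intervals:
            parts.append(f"{reg}={lo}" if lo == hi else f"{reg}={lo}..{hi}")
        return "{" + ", ".join(parts) + "}"


def single_conditions(sign: str) -> tuple[str, str]:
    """(activation cell, inhibition cell) for an individual hit.

    An inhibitor activates its target while low and inhibits while high;
    an activator the other way round.
    """
    if sign == "-":
        return LOW, HIGH
    if sign == "+":
        return HIGH, LOW
    raise ValueError(f"sign must be '+' or '-', got {sign!r}")


def pair_conditions(regulators: tuple[str, str], s_p: str, s_q: str
                    ) -> RegulationCase:
    """Case table for a cooperative hit by two regulators under the AND
    of their signed literals: the activation cell takes L where the sign
    is '-' and H where it is '+', the other three cells inhibit."""
    act = single_conditions(s_p)[0] + single_conditions(s_q)[0]
    inh = tuple(
        HitPart(regulators, a + b)
        for a in (LOW, HIGH)
        for b in (LOW, HIGH)
        if a + b != act
    )
    return RegulationCase((s_p, s_q), HitPart(regulators, act), inh)


def switch_condition(cell: HitPart, thresholds: Mapping[str, int],
                     max_levels: Mapping[str, int]) -> SwitchCondition:
    """Concretize a cell: L becomes {0..t-1}, H becomes {t..l}."""
    intervals = []
    for reg, letter in zip(cell.regulators, cell.cell):
        t = thresholds[reg]
        l = max_levels[reg]
        if not 1 <= t <= l:
            raise ValueError(f"threshold {t} of {reg} outside 1..{l}")
        intervals.append((reg, 0, t - 1) if letter == LOW else (reg, t, l))
    return SwitchCondition(tuple(intervals))


def expand_formula(rf: RegulationFormula, thresholds: Mapping[str, int],
                   max_levels: Mapping[str, int], *,
                   allow_constant: bool = False,
                   ) -> tuple[list[tuple[HitPart, SwitchCondition]],
                              list[tuple[HitPart, SwitchCondition]]]:
    """Minterm expansion of a regulation formula over n regulators.

    Returns (activation, inhibition): the cells of {L,H}^n satisfying
    (resp. falsifying) the formula, each paired with its switch
    condition.  The two lists partition all 2^n cells.  A formula that
    can never rise or never fall its target is rejected unless
    ``allow_constant`` is set: such a gene could not both rise and fall.
    """
    regs = tuple(sorted(rf.regulators))
    activation, inhibition = [], []
    for bits in itertools.product((False, True), repeat=len(regs)):
        cell = HitPart(regs, "".join(HIGH if b else LOW for b in bits))
        sc = switch_condition(cell, thresholds, max_levels)
        bucket = activation if rf.evaluate(dict(zip(regs, bits))) else inhibition
        bucket.append((cell, sc))
    if not allow_constant and (not activation or not inhibition):
        kind = "tautology" if not inhibition else "contradiction"
        raise ValueError(
            f"regulation formula of {rf.target} is a {kind}; the gene could "
            f"never both rise and fall (declare it an input instead)"
        )
    return activation, inhibition


def prime_cover(rf: RegulationFormula, value: bool
                ) -> list[dict[str, bool]]:
    """Minimal prime-implicant cube cover of {cells : formula == value}.

    Each cube is a partial assignment regulator -> True(H)/False(L);
    unmentioned regulators are free.  Quine–McCluskey merging followed
    by a deterministic greedy cover (essential cubes first).  This is
    what turns e.g. the falsification of a pure conjunction into one
    single-literal condition per regulator, matching the compact
    transition lists used for published models.
    """
    regs = tuple(sorted(rf.regulators))
    minterms = [
        bits
        for bits in itertools.product((False, True), repeat=len(regs))
        if rf.evaluate(dict(zip(regs, bits))) == value
    ]
    if not minterms:
        return []
    # cubes as tuples over {False, True, None}; None = free coordinate
    cubes = {tuple(m) for m in minterms}
    primes: set[tuple] = set()
    while cubes:
        merged_into: set[tuple] = set()
        used: set[tuple] = set()
        for a, b in itertools.combinations(sorted(cubes, key=str), 2):
            diff = [i for i in range(len(regs)) if a[i] != b[i]]
            if len(diff) == 1 and None not in (a[diff[0]], b[diff[0]]):
                m = tuple(None if i == diff[0] else a[i] for i in range(len(regs)))
                merged_into.add(m)
                used.add(a)
                used.add(b)
        primes |= cubes - used
        cubes = merged_into
    primes_list = sorted(primes, key=str)

    def covers(cube, m):
        return all(c is None or c == v for c, v in zip(cube, m))

    remaining = set(minterms)
    cover: list[tuple] = []
    # essential primes
    for m in sorted(remaining):
        hits = [c for c in primes_list if covers(c, m)]
        if len(hits) == 1 and hits[0] not in cover:
            cover.append(hits[0])
    for c in cover:
        remaining -= {m for m in remaining if covers(c, m)}
    # greedy for the rest
    while remaining:
        best = max(
            primes_list,
            key=lambda c: (sum(covers(c, m) for m in remaining), str(c)),
        )
        cover.append(best)
        remaining -= {m for m in remaining if covers(best, m)}
    return [
        {regs[i]: cube[i] for i in range(len(regs)) if cube[i] is not None}
        for cube in cover
    ]


def cube_switch_condition(cube: Mapping[str, bool],
                          thresholds: Mapping[str, int],
                          max_levels: Mapping[str, int]) -> SwitchCondition:
    """Switch condition of a cube (partial cell): only the regulators the
    cube mentions are constrained."""
    intervals = []
    for reg in sorted(cube):
        t, l = thresholds[reg], max_levels[reg]
        if not 1 <= t <= l:
            raise ValueError(f"threshold {t} of {reg} outside 1..{l}")
        intervals.append((reg, t, l) if cube[reg] else (reg, 0, t - 1))
    return SwitchCondition(tuple(intervals))


def case_table(rf: RegulationFormula, thresholds: Mapping[str, int],
               max_levels: Mapping[str, int]) -> str:
    """Readable case table (activation / inhibition cells with their
    effective level intervals) for debugging and the CLI."""
    act, inh = expand_formula(rf, thresholds, max_levels, allow_constant=True)
    lines = [f"regulation of {rf.target}: {rf}"]
    for label, rows in (("activation", act), ("inhibition", inh)):
        for cell, sc in rows:
            lines.append(f"  {label:<10} {str(cell):<14} {sc}")
    return "\n".join(lines)
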