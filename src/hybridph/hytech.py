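"""Export and import of hybrid networks in a HyTech-style dialect.

One ``automaton`` block per gene, with the classic keywords: ``loc``
(location), ``while`` (invariant), ``wait`` (clock rates), ``when``
(guard), ``do`` (resets and level-variable update), ``goto``.  Clock
and delay names are flattened to the tool's identifier alphabet:
production delay d_g<i>+ becomes ``dpg<i>``, degradation delay d_g<i>-
becomes ``dng<i>``, clocks h_g / hn_g become ``hg`` / ``hng``.  A
degradation clock runs at rate -1 from zero toward its (negative)
delay parameter, so its invariant is a *lower* bound (``hng>=dng1``).

The importer accepts exactly this dialect and rebuilds an equivalent
network; exporting the imported network reproduces the text verbatim,
which the round-trip tests rely on.
"""
from __future__ import annotations

import re
from typing import Iterable

from .automata import LocalState, LocalTransition
from .hybrid import (
    DEGRADATION,
    PRODUCTION,
    BioLHA,
    BioLHANetwork,
    DelayParameter,
    LHAEdge,
)
from .polyhedra import LinearConstraint


def _flat_clock(h: str) -> str:
    return h.replace("_", "")


def _flat_param(p: DelayParameter) -> str:
    prefix = "dp" if p.direction == PRODUCTION else "dn"
    return f"{prefix}{p.gene}{p.level}"


def export_hytech(net: BioLHANetwork, name: str = "model") -> str:
    """Render the network as HyTech-style text with a forward-reach
    analysis section."""
    clocks = [_flat_clock(h) for h in net.clocks]
    params = [_flat_param(p) for p in net.parameters]
    lines = [f"-- {name}: hybrid gene network", "var"]
    if clocks:
        lines.append("    " + ", ".join(clocks) + ": clock;")
    if params:
        lines.append("    " + ", ".join(params) + ": parameter;")
    lines.append("    " + ", ".join(net.gene_order) + ": discrete;")
    lines.append("")
    for comp in net.components:
        lines.extend(_export_component(net, comp))
        lines.append("")
    lines.append("-- analysis")
    init_parts = [f"loc[gene{c.gene}]={c.gene}{c.initial}" for c in net.components]
    init_parts += [f"{c.gene}={c.initial}" for c in net.components]
    init_parts += [f"{_flat_clock(h)}=0" for h in net.clocks]
    lines.append("init := " + " & ".join(init_parts) + ";")
    lines.append("reach forward from init endreach;")
    return "\n".join(lines) + "\n"


def _export_component(net: BioLHANetwork, comp: BioLHA) -> list[str]:
    lines = [f"automaton gene{comp.gene}", "synclabs: ;"]
    init_clocks = "".join(f" & {_flat_clock(h)}=0" for h in comp.clocks)
    lines.append(
        f"initially {comp.gene}{comp.initial} & {comp.gene}={comp.initial}"
        f"{init_clocks};")
    pmap = {p.name: _flat_param(p) for p in comp.parameters}
    for lvl in range(comp.max_level + 1):
        inv = " & ".join(
            _render_invariant(c, comp, pmap) for c in comp.invariants[lvl]
        ) or "True"
        rates = ", ".join(
            f"d{_flat_clock(h)}={comp.rates[lvl].get(h, 0)}" for h in comp.clocks
        )
        lines.append(f"loc {comp.gene}{lvl}: while {inv} wait {{{rates}}}")
        for e in comp.edges_from(lvl):
            cond = [
                f"{ls.gene}={ls.level}"
                for ls in sorted(e.condition,
                                 key=lambda ls: net.gene_order.index(ls.gene))
            ]
            cond.append(f"{_flat_clock(e.clock)}={pmap[e.parameter.name]}")
            resets = [f"{_flat_clock(h)}'=0" for h in comp.clocks]
            resets.append(f"{comp.gene}'={e.destination}")
            lines.append(
                f"    when {' & '.join(cond)} do {{{', '.join(resets)}}} "
                f"goto {comp.gene}{e.destination};")
    lines.append(f"end --gene{comp.gene}")
    return lines


def _render_invariant(c: LinearConstraint, comp: BioLHA, pmap) -> str:
    # invariants are h - d <= 0 (production) or d - h <= 0 (degradation)
    items = sorted(c.coeffs.items())
    clock = next(v for v, k in items if not v.startswith("d_"))
    param = next(v for v, k in items if v.startswith("d_"))
    rel = "<=" if c.coeffs[clock] > 0 else ">="
    return f"{_flat_clock(clock)}{rel}{pmap[param]}"


# ---------------------------------------------------------------------------
# parsing

_AUTOMATON = re.compile(r"^automaton gene(\S+)$")
_INITIALLY = re.compile(r"^initially (\S+?)(\d+) &")
_LOC = re.compile(r"^loc (\S+?)(\d+): while (.+) wait \{(.*)\}$")
_WHEN = re.compile(r"^when (.+) do \{(.*)\} goto (\S+?)(\d+);$")


class HytechParseError(ValueError):
    pass


def parse_hytech(text: str) -> BioLHANetwork:
    """Rebuild a network from text produced by :func:`export_hytech`."""
    lines = [ln.strip() for ln in text.splitlines()]
    genes: list[str] = []
    clocks: list[str] = []
    params: list[str] = []
    for ln in lines:
        if ln.endswith(": clock;"):
            clocks = [t.strip() for t in ln[: -len(": clock;")].split(",")]
        elif ln.endswith(": parameter;"):
            params = [t.strip() for t in ln[: -len(": parameter;")].split(",")]
        elif ln.endswith(": discrete;"):
            genes = [t.strip() for t in ln[: -len(": discrete;")].split(",")]
    if not genes:
        raise HytechParseError("no discrete gene variables declared")

    def unflatten_param(flat: str) -> DelayParameter:
        direction = PRODUCTION if flat.startswith("dp") else DEGRADATION
        body = flat[2:]
        for g in sorted(genes, key=len, reverse=True):
            if body.startswith(g) and body[len(g):].isdigit():
                return DelayParameter(g, int(body[len(g):]), direction)
        raise HytechParseError(f"cannot resolve parameter {flat!r}")

    def unflatten_clock(flat: str, gene: str) -> str:
        if flat == f"hn{gene}":
            return f"hn_{gene}"
        if flat == f"h{gene}":
            return f"h_{gene}"
        raise HytechParseError(f"clock {flat!r} does not belong to gene {gene!r}")

    components: list[BioLHA] = []
    i = 0
    while i < len(lines):
        m = _AUTOMATON.match(lines[i])
        if not m:
            i += 1
            continue
        gene = m.group(1)
        i += 1
        initial = 0
        comp_clocks: list[str] = []
        edges: list[LHAEdge] = []
        invariants: dict[int, tuple[LinearConstraint, ...]] = {}
        rates: dict[int, dict[str, int]] = {}
        pset: dict[str, DelayParameter] = {}
        current_level: int | None = None
        while i < len(lines) and not lines[i].startswith("end "):
            ln = lines[i]
            mi = _INITIALLY.match(ln)
            if mi:
                initial = int(mi.group(2))
                comp_clocks = [
                    unflatten_clock(part.split("=")[0].strip(), gene)
                    for part in ln.rstrip(";").split("&")[2:]
                ]
            ml = _LOC.match(ln)
            if ml:
                current_level = int(ml.group(2))
                inv_text, wait_text = ml.group(3), ml.group(4)
                invs = []
                if inv_text != "True":
                    for part in inv_text.split("&"):
                        part = part.strip()
                        op = "<=" if "<=" in part else ">="
                        clk, par = part.split(op)
                        p = unflatten_param(par.strip())
                        pset[p.name] = p
                        h = unflatten_clock(clk.strip(), gene)
                        if op == "<=":
                            invs.append(LinearConstraint.le({h: 1, p.name: -1}, 0))
                        else:
                            invs.append(LinearConstraint.ge({h: 1, p.name: -1}, 0))
                invariants[current_level] = tuple(invs)
                rate = {}
                for part in filter(None, (t.strip() for t in wait_text.split(","))):
                    lhs, val = part.split("=")
                    rate[unflatten_clock(lhs.strip()[1:], gene)] = int(val)
                rates[current_level] = rate
            mw = _WHEN.match(ln)
            if mw:
                if current_level is None:
                    raise HytechParseError(f"'when' before any 'loc': {ln!r}")
                cond_parts = [t.strip() for t in mw.group(1).split("&")]
                clk_part = cond_parts[-1]
                clk_flat, par_flat = clk_part.split("=")
                p = unflatten_param(par_flat.strip())
                pset[p.name] = p
                h = unflatten_clock(clk_flat.strip(), gene)
                condition = set()
                for part in cond_parts[:-1]:
                    name, lvl = part.split("=")
                    condition.add(LocalState(name.strip(), int(lvl)))
                dest = int(mw.group(4))
                t = LocalTransition(
                    LocalState(gene, current_level), frozenset(condition),
                    LocalState(gene, dest))
                edges.append(LHAEdge(current_level, dest, frozenset(condition),
                                     h, p, t))
            i += 1
        max_level = max(invariants) if invariants else 0
        for lvl in range(max_level + 1):
            invariants.setdefault(lvl, ())
            rates.setdefault(lvl, {h: 0 for h in comp_clocks})
        components.append(BioLHA(
            gene, max_level, initial, tuple(comp_clocks),
            tuple(sorted(pset.values())), tuple(edges), invariants, rates))
        i += 1
    order = {g: k for k, g in enumerate(genes)}
    components.sort(key=lambda c: order.get(c.gene, len(order)))
    return BioLHANetwork(tuple(components))
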