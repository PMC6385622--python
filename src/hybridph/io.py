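"""File formats: BRN-JSON, PINT-style .an, DOT, SBML-qual import, run
configurations.

The native model format is BRN-JSON::

    {
      "genes": [{"name": "p", "max_level": 1, "input": "rise"}, ...],
      "interactions": [
        {"source": "p", "target": "q", "threshold": 1, "sign": "+"}, ...],
      "logic": {"q": "p", "r": "p & q"}
    }

``input`` is optional (one of rise/fall/both) and marks an unregulated
gene that drifts freely; ``logic`` entries are boolean formulas over
regulator names (``!``, ``&``, ``|``, parentheses).  A machine-readable
schema ships in ``hybridph/schema/brn.schema.json``.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .automata import AutomataNetwork, LocalState, LocalTransition
from .brn import Gene, Interaction, InteractionGraph, parse_formula


class SchemaError(ValueError):
    """A BRN-JSON document violates the format; the message names the
    offending field."""


# ---------------------------------------------------------------------------
# BRN-JSON

def graph_to_dict(graph: InteractionGraph) -> dict:
    genes = []
    for g in graph.genes.values():
        entry: dict[str, Any] = {"name": g.name, "max_level": g.max_level}
        if g.input is not None:
            entry["input"] = g.input
        genes.append(entry)
    return {
        "genes": genes,
        "interactions": [
            {"source": i.source, "target": i.target,
             "threshold": i.threshold, "sign": i.sign}
            for i in graph.interactions
        ],
        "logic": {t: str(f) for t, f in graph.logic.items()},
    }


def graph_from_dict(doc: Mapping) -> InteractionGraph:
    _check_document(doc)
    genes = [
        Gene(g["name"], g["max_level"], g.get("input"))
        for g in doc["genes"]
    ]
    interactions = [
        Interaction(i["source"], i["target"], i["threshold"], i["sign"])
        for i in doc["interactions"]
    ]
    return InteractionGraph(genes, interactions, doc.get("logic") or {})


def _check_document(doc) -> None:
    if not isinstance(doc, Mapping):
        raise SchemaError("document: expected a JSON object")
    for key in ("genes", "interactions"):
        if key not in doc:
            raise SchemaError(f"document: missing required field {key!r}")
    if not isinstance(doc["genes"], Sequence) or isinstance(doc["genes"], str):
        raise SchemaError("genes: expected an array")
    for n, g in enumerate(doc["genes"]):
        where = f"genes[{n}]"
        if not isinstance(g, Mapping):
            raise SchemaError(f"{where}: expected an object")
        if "name" not in g or not isinstance(g["name"], str) or not g["name"]:
            raise SchemaError(f"{where}: missing or invalid 'name'")
        if "max_level" not in g or not isinstance(g["max_level"], int) \
                or isinstance(g["max_level"], bool) or g["max_level"] < 1:
            raise SchemaError(f"{where} ({g.get('name')}): 'max_level' must be an integer >= 1")
        if "input" in g and g["input"] not in ("rise", "fall", "both", None):
            raise SchemaError(f"{where} ({g['name']}): 'input' must be rise/fall/both")
    if not isinstance(doc["interactions"], Sequence) or isinstance(doc["interactions"], str):
        raise SchemaError("interactions: expected an array")
    for n, i in enumerate(doc["interactions"]):
        where = f"interactions[{n}]"
        if not isinstance(i, Mapping):
            raise SchemaError(f"{where}: expected an object")
        for fieldname in ("source", "target", "threshold", "sign"):
            if fieldname not in i:
                raise SchemaError(f"{where}: missing required field {fieldname!r}")
        if i["sign"] not in ("+", "-"):
            raise SchemaError(f"{where}: 'sign' must be '+' or '-'")
        if not isinstance(i["threshold"], int) or isinstance(i["threshold"], bool) \
                or i["threshold"] < 1:
            raise SchemaError(f"{where}: 'threshold' must be an integer >= 1")
    logic = doc.get("logic", {})
    if logic is not None and not isinstance(logic, Mapping):
        raise SchemaError("logic: expected an object mapping gene -> formula")
    for target, f in (logic or {}).items():
        if not isinstance(f, str):
            raise SchemaError(f"logic[{target}]: expected a formula string")
        try:
            parse_formula(f)
        except ValueError as ex:
            raise SchemaError(f"logic[{target}]: {ex}") from ex


def load_brn(path) -> InteractionGraph:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as ex:
            raise SchemaError(f"{path}: not valid JSON ({ex})") from ex
    return graph_from_dict(doc)


def save_brn(graph: InteractionGraph, path) -> None:
    with open(path, "w") as fh:
        json.dump(graph_to_dict(graph), fh, indent=2, sort_keys=False)
        fh.write("\n")


# ---------------------------------------------------------------------------
# PINT-style .an dialect
#
#   "g" [0..l]
#   "g" i -> j when "a"=x and "b"=y

def export_an(an: AutomataNetwork) -> str:
    lines = []
    for g, l in an.genes.items():
        lines.append(f'"{g}" [0..{l}]')
    lines.append("")
    for t in an.transitions:
        cond = " and ".join(
            f'"{ls.gene}"={ls.level}' for ls in sorted(t.condition)
        )
        line = f'"{t.gene}" {t.origin.level} -> {t.destination.level}'
        if cond:
            line += f" when {cond}"
        lines.append(line)
    return "\n".join(lines) + "\n"


def import_an(text: str) -> AutomataNetwork:
    import re

    genes: dict[str, int] = {}
    transitions: list[LocalTransition] = []
    decl = re.compile(r'^"([^"]+)"\s*\[0\.\.(\d+)\]$')
    trans = re.compile(
        r'^"([^"]+)"\s+(\d+)\s*->\s*(\d+)(?:\s+when\s+(.*))?$')
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = decl.match(line)
        if m:
            genes[m.group(1)] = int(m.group(2))
            continue
        m = trans.match(line)
        if m:
            g, i, j, cond = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
            condition = set()
            if cond:
                for part in cond.split(" and "):
                    cm = re.match(r'^\s*"([^"]+)"\s*=\s*(\d+)\s*$', part)
                    if not cm:
                        raise ValueError(f".an line {ln}: bad condition {part!r}")
                    condition.add(LocalState(cm.group(1), int(cm.group(2))))
            transitions.append(LocalTransition(
                LocalState(g, i), frozenset(condition), LocalState(g, j)))
            continue
        raise ValueError(f".an line {ln}: cannot parse {raw!r}")
    return AutomataNetwork(genes, transitions)


# ---------------------------------------------------------------------------
# DOT / edge-list export of state transition graphs

def stg_to_dot(stg, an: AutomataNetwork) -> str:
    lines = ["digraph stg {", '  node [shape=box, fontname="monospace"];']
    for node in stg.nodes:
        lines.append(f'  "{an.render_state(node)}";')
    for a, b in stg.edges:
        lines.append(f'  "{an.render_state(a)}" -> "{an.render_state(b)}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def stg_to_json(stg, an: AutomataNetwork) -> dict:
    return {
        "genes": list(an.genes),
        "states": [list(s) for s in stg.nodes],
        "edges": [
            {"from": list(a), "to": list(b),
             "transitions": [str(t) for step in d.get("steps", ()) for t in step]}
            for a, b, d in stg.edges(data=True)
        ],
    }


# ---------------------------------------------------------------------------
# SBML-qual import (restricted to AND/OR/NOT over threshold literals)

class UnsupportedSbmlError(ValueError):
    """The document uses constructs outside the supported fragment; the
    message points at the offending element."""


_QUAL = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATH = "http://www.w3.org/1998/Math/MathML"


def import_sbml_qual(path) -> InteractionGraph:
    """Read a qualitative-models SBML document into an interaction graph.

    Supported fragment: qualitativeSpecies with maxLevel; transitions
    whose inputs carry sign and thresholdLevel; function terms that are
    AND/OR/NOT combinations of threshold comparisons (geq/lt against
    the input's declared threshold, or eq against 0 / maxLevel for
    boolean species).  Anything else raises UnsupportedSbmlError naming
    the element and line.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()

    def q(tag):
        return f"{{{_QUAL}}}{tag}"

    species = {}
    order: list[str] = []
    for sp in root.iter(q("qualitativeSpecies")):
        sid = sp.get(q("id")) or sp.get("id")
        if sid is None:
            raise UnsupportedSbmlError(
                f"qualitativeSpecies without id (line {sp.sourceline})")
        max_level = sp.get(q("maxLevel")) or sp.get("maxLevel") or "1"
        species[sid] = int(max_level)
        order.append(sid)

    interactions: list[Interaction] = []
    logic: dict[str, str] = {}
    for tr in root.iter(q("transition")):
        inputs: dict[str, tuple[int, str]] = {}
        for inp in tr.iter(q("input")):
            src = inp.get(q("qualitativeSpecies")) or inp.get("qualitativeSpecies")
            sign = inp.get(q("sign")) or inp.get("sign")
            thr = inp.get(q("thresholdLevel")) or inp.get("thresholdLevel") or "1"
            if sign not in ("positive", "negative"):
                raise UnsupportedSbmlError(
                    f"input of {src!r} needs sign positive/negative "
                    f"(line {inp.sourceline})")
            inputs[src] = (int(thr), "+" if sign == "positive" else "-")
        outputs = [
            (o.get(q("qualitativeSpecies")) or o.get("qualitativeSpecies"))
            for o in tr.iter(q("output"))
        ]
        if len(outputs) != 1:
            raise UnsupportedSbmlError(
                f"transition needs exactly one output (line {tr.sourceline})")
        target = outputs[0]
        for src, (thr, sign) in inputs.items():
            interactions.append(Interaction(src, target, thr, sign))
        formula = _qual_formula(tr, inputs, species)
        if formula is not None:
            logic[target] = formula

    genes = [Gene(s, species[s]) for s in order]
    return InteractionGraph(genes, interactions, logic)


def _qual_formula(tr, inputs, species) -> str | None:
    from lxml import etree

    terms = list(tr.iter(f"{{{_QUAL}}}functionTerm"))
    active = [t for t in terms
              if int(t.get(f"{{{_QUAL}}}resultLevel") or t.get("resultLevel") or 0) > 0]
    if not active:
        return None
    if len(active) > 1:
        raise UnsupportedSbmlError(
            f"multiple non-zero function terms (line {active[1].sourceline}); "
            f"only single-threshold logic is supported")
    math = active[0].find(f"{{{_MATH}}}math")
    if math is None or len(math) != 1:
        raise UnsupportedSbmlError(
            f"functionTerm without a single math child (line {active[0].sourceline})")
    return _mathml_to_formula(math[0], inputs, species)


def _mathml_to_formula(node, inputs, species) -> str:
    tag = node.tag.split("}")[-1]
    if tag != "apply" or len(node) == 0:
        raise UnsupportedSbmlError(
            f"unsupported math element <{tag}> (line {node.sourceline})")
    op = node[0].tag.split("}")[-1]
    args = list(node)[1:]
    if op in ("and", "or"):
        parts = [_mathml_to_formula(a, inputs, species) for a in args]
        joiner = " & " if op == "and" else " | "
        return "(" + joiner.join(parts) + ")"
    if op == "not":
        if len(args) != 1:
            raise UnsupportedSbmlError(f"<not> needs one argument (line {node.sourceline})")
        return f"!({_mathml_to_formula(args[0], inputs, species)})"
    if op in ("geq", "lt", "leq", "gt", "eq"):
        if len(args) != 2 or args[0].tag.split("}")[-1] != "ci" \
                or args[1].tag.split("}")[-1] != "cn":
            raise UnsupportedSbmlError(
                f"comparison must be species vs integer (line {node.sourceline})")
        name = args[0].text.strip()
        value = int(float(args[1].text.strip()))
        if name not in inputs:
            raise UnsupportedSbmlError(
                f"species {name!r} compared but not an input (line {node.sourceline})")
        threshold = inputs[name][0]
        above = {"geq": value, "gt": value + 1,
                 "leq": None, "lt": None, "eq": None}[op]
        if op in ("geq", "gt"):
            if above != threshold:
                raise UnsupportedSbmlError(
                    f"comparison of {name} at {value} does not match its "
                    f"declared threshold {threshold} (line {node.sourceline})")
            return name
        if op in ("leq", "lt"):
            below = value + 1 if op == "leq" else value
            if below != threshold:
                raise UnsupportedSbmlError(
                    f"comparison of {name} at {value} does not match its "
                    f"declared threshold {threshold} (line {node.sourceline})")
            return f"!{name}"
        # eq: only meaningful for boolean species
        if species.get(name) == 1 and value in (0, 1) and threshold == 1:
            return name if value == 1 else f"!{name}"
        raise UnsupportedSbmlError(
            f"eq comparison on multi-level species {name} (line {node.sourceline})")
    raise UnsupportedSbmlError(
        f"unsupported operator <{op}> (line {node.sourceline})")


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    model: str = ""
    semantics: str = "async"
    initial_state: list[int] = field(default_factory=list)
    goal: str | None = None
    kmax: int = 3
    max_symbolic_states: int = 4000
    seed: int = 0
    output: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise SchemaError(f"run config: unknown fields {sorted(unknown)}")
        return cls(**doc)
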