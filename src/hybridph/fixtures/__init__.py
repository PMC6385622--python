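"""Packaged example models.

* ``toy-cascade`` — three genes p, q, r: p activates q, and p and q
  jointly (AND) activate r.  p is an unconditioned rising input.  The
  classic minimal example of a cooperative hit.
* ``toy-oscillator`` — three genes where p and q activate r cooperatively
  and r inhibits q, closing a negative loop that makes q and r
  oscillate while p stays high.  p is an unconditioned rising input.
* ``phage-lambda`` — the four-gene bacteriophage λ immunity network
  (cI with levels 0-2, cro 0-3, cII and N boolean) after Thieffry &
  Thomas (1995): the lysis/lysogeny decision circuit.  Regulation
  logic: cI needs cII and the absence of cro; cro and N need the
  absence of both cI and cro (cro self-limits at its top level); cII
  additionally needs N.  Note on thresholds: cro represses cI at
  threshold 3 (the source model's value).  Published re-drawings of
  this network sometimes show that threshold as 1, but only the
  threshold-3 reading reproduces the model's documented behaviour
  (42 of 48 states reachable from the all-zero state, and lysogeny
  timing raced against cro's first rise).

Every fixture passes ``InteractionGraph.validate``.
"""
from __future__ import annotations

import json
from importlib import resources

from ..brn import InteractionGraph
from ..io import graph_from_dict

FIXTURES = ("toy-cascade", "toy-oscillator", "phage-lambda")


def fixture_names() -> tuple[str, ...]:
    return FIXTURES


def load_fixture(name: str) -> InteractionGraph:
    """Load a packaged model by name (see FIXTURES)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    text = resources.files(__package__).joinpath(f"{name}.json").read_text()
    return graph_from_dict(json.loads(text))
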