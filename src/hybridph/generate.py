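"""Seeded random interaction graphs for property testing.

The generator emits small multi-level networks of the kind the desk
analyses target: a handful of genes (default 3-4), levels 1-2, sparse
signed threshold edges, and the default conjunction logic on every
regulated gene.  It is deterministic per seed and every output passes
validation, so property tests can sweep seeds and compare the discrete
engines against brute force.
"""
from __future__ import annotations

import random

from .brn import Gene, Interaction, InteractionGraph


def random_brn(seed: int, n_genes: int = 3, max_levels: int = 2,
               density: float = 0.4, input_probability: float = 0.3
               ) -> InteractionGraph:
    """Deterministic random model.

    Each ordered gene pair (self-loops excluded) gets an interaction
    with probability ``density``, with a uniform threshold in
    1..source_max and a uniform sign.  Regulated genes use the default
    conjunction of signed literals; unregulated genes become rising
    inputs with probability ``input_probability`` and stay constant
    otherwise.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    rng = random.Random(seed)
    names = [f"g{i}" for i in range(1, n_genes + 1)]
    levels = {n: rng.randint(1, max_levels) for n in names}
    interactions = []
    for src in names:
        for tgt in names:
            if src == tgt:
                continue
            if rng.random() < density:
                interactions.append(Interaction(
                    src, tgt,
                    rng.randint(1, levels[src]),
                    rng.choice("+-"),
                ))
    regulated = {i.target for i in interactions}
    genes = []
    for n in names:
        if n in regulated:
            genes.append(Gene(n, levels[n]))
        elif rng.random() < input_probability:
            genes.append(Gene(n, levels[n], input="rise"))
        else:
            genes.append(Gene(n, levels[n]))
    return InteractionGraph(genes, interactions)
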