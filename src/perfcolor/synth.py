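"""Bundled toy network and synthetic-data generators.

``toy_graph`` ships a small 9-node, 11-edge signed network whose behavior
under every stage of the pipeline is known in closed form: the consistency
reduction merges {D, E, F}, the co-regulator reduction merges {B, C}, the
edge-balance reduction cancels the opposite-signed I->G pair and isolates I,
exactly two mutually-reversed optimal colorings remain, and the component
partition is {A, B, C, D, E, F : +; G, H : -} plus the singleton {I}.  The
edge list is a reconstruction constrained by those narrated behaviors.

``random_signed_graph`` and ``synthetic_profiles`` provide seeded generators
for property tests and recovery experiments: random simple signed digraphs,
and discrete observation sets drawn from a component configuration with
independent sign-flip noise.
"""

from __future__ import annotations

from fractions import Fraction
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from .coloring import DOWN, UP, flip_color
from .components import Component
from .network import SignedGraph, read_signed_graph
from .similarity import DiscretizedProfile

__all__ = [
    "toy_graph",
    "toy_observations",
    "random_signed_graph",
    "synthetic_profiles",
]


def toy_graph() -> SignedGraph:
    """The bundled 9-node / 11-edge toy network (all weights 1)."""
    ref = resources.files("perfcolor") / "data" / "toy_graph.tsv"
    with resources.as_file(ref) as path:
        return read_signed_graph(path)


def toy_observations() -> DiscretizedProfile:
    """The worked observation set {D: up, E: up, G: up}."""
    return DiscretizedProfile({"D": UP, "E": UP, "G": UP}, sample_id="toy")


def random_signed_graph(
    n_nodes: int,
    n_edges: int,
    p_inhibition: float = 0.3,
    weight_range: tuple[int, int] = (1, 1),
    seed=0,
) -> SignedGraph:
    """Uniform simple signed digraph without self-loops; pure in its seed."""
    if not 0 <= p_inhibition <= 1:
        raise ValueError("p_inhibition must be in [0, 1]")
    max_edges = n_nodes * (n_nodes - 1)
    if n_edges > max_edges:
        raise ValueError(
            f"{n_edges} edges infeasible for {n_nodes} nodes (max {max_edges})"
        )
    lo, hi = weight_range
    if lo < 1 or hi < lo:
        raise ValueError("weight_range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_nodes - 1, 0)))
    nodes = [f"n{i:0{width}d}" for i in range(n_nodes)]
    g = SignedGraph(nodes)
    slots = rng.choice(max_edges, size=n_edges, replace=False) if n_edges else []
    for slot in slots:
        i, rest = divmod(int(slot), n_nodes - 1)
        j = rest if rest < i else rest + 1
        sign = -1 if rng.random() < p_inhibition else 1
        weight = Fraction(int(rng.integers(lo, hi + 1)))
        g.add_edge(nodes[i], nodes[j], sign, weight)
    return g


def synthetic_profiles(
    components: Sequence[Component],
    chosen_config: Optional[Mapping[str, int]] = None,
    flip_noise: float = 0.0,
    unobserved_rate: float = 0.0,
    n_samples: int = 1,
    seed=0,
) -> list[DiscretizedProfile]:
    """Draw observation sets from component configurations.

    Each sample observes each member node independently with probability
    ``1 - unobserved_rate``; an observed sign equals the chosen configuration's
    sign, flipped independently with probability ``flip_noise``.
    ``chosen_config`` maps component id -> 1 or 2 (default 1 for all).
    """
    if not 0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must be in [0, 0.5)")
    if not 0 <= unobserved_rate < 1:
        raise ValueError("unobserved_rate must be in [0, 1)")
    chosen_config = chosen_config or {}
    rng = np.random.default_rng(seed)
    truth: dict[str, str] = {}
    for comp in components:
        which = chosen_config.get(comp.id, 1)
        if which not in (1, 2):
            raise ValueError(f"configuration choice must be 1 or 2, got {which}")
        truth.update(comp.config1 if which == 1 else comp.config2)
    nodes = sorted(truth)
    profiles = []
    for k in range(n_samples):
        obs: dict[str, str] = {}
        for node in nodes:
            if rng.random() < unobserved_rate:
                continue
            sign = truth[node]
            if rng.random() < flip_noise:
                sign = flip_color(sign)
            obs[node] = sign
        profiles.append(DiscretizedProfile(obs, sample_id=f"s{k:03d}"))
    return profiles
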