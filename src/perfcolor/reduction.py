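"""Solution-space reductions: merge provably color-correlated nodes.

Three behavior-preserving rewrites shrink a signed graph before enumeration:

1. *Consistency* — a target with a single incoming edge must, in any optimal
   coloring that explains it, follow its unique predecessor (equal color for
   activation, opposite for inhibition); the pair is merged into one
   subcomponent-node carrying relative signs.
2. *Co-regulators* — two predecessor-free nodes whose only outgoing edge goes
   to the same single successor always align so that both explain that
   successor in an optimum; they merge with relative sign equal to the product
   of their edge signs.
3. *Edge balance* — between an ordered pair of subcomponent-nodes, same-sign
   parallel weights are summed and an opposite-sign pair ``(w1, w2)`` is
   replaced by ``(w1 - min, w2 - min)``; zero-weight edges are deleted.  A
   target losing a balanced pair is permanently consistent (one of the pair
   always explained it) and permanently imperfect (the other always failed),
   recorded as a :class:`~perfcolor.coloring.TargetFlag` carrying the
   cancelled weight so objectives of original and reduced graphs agree
   exactly.  Subcomponents left without incident edges become isolated,
   color-independent components of their own.

Safety guards (this package's own refinements, needed for the reductions to
preserve the *complete* optimal model set on arbitrary graphs, not only on
graphs admitting a fully consistent coloring):

- the consistency merge is applied only when neither endpoint lies on a
  directed cycle of the current reduced graph (on a conflict cycle the
  single-incoming constraint may be the cheapest one to sacrifice, so forcing
  it can change the optimum);
- a flagged target is never consistency-merged (it is permanently imperfect,
  so the pattern's premise does not hold);
- a co-regulator candidate must have exactly one, single-signed, edge to the
  shared successor (a node with a balanced +/- pair is genuinely free and is
  handled by the edge-balance rule instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Iterable, Mapping, Optional

import networkx as nx

from .coloring import (DOWN, UP, ModelSet, ObjectiveVector, TargetFlag,
                       flip_color)
from .network import SignedGraph

__all__ = [
    "Subcomponent",
    "ReducedGraph",
    "reduce_consistency",
    "reduce_coregulators",
    "reduce_edge_balance",
    "reduce_all",
    "expand_coloring",
    "expand_model_set",
]


@dataclass(frozen=True)
class Subcomponent:
    """A merged set of color-correlated nodes with fixed relative signs."""

    representative: str
    members: Mapping[str, int]  # member -> sign of correlation with representative

    def __post_init__(self):
        if self.members.get(self.representative) != 1:
            raise ValueError(
                f"representative {self.representative!r} must be a member with "
                f"relative sign +1"
            )

    def expand(self, color: str) -> dict[str, str]:
        """Color every member from the representative's color."""
        return {m: (color if s == 1 else flip_color(color))
                for m, s in self.members.items()}


@dataclass
class ReducedGraph:
    """A signed graph over subcomponent representatives, plus bookkeeping."""

    graph: SignedGraph                       # over all representatives
    subcomponents: dict[str, Subcomponent]   # rep -> subcomponent (all of them)
    flags: dict[str, TargetFlag] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    @property
    def isolated(self) -> dict[str, Subcomponent]:
        """Subcomponents with no incident edge (color-independent)."""
        used = self.graph.incident_nodes()
        return {r: s for r, s in self.subcomponents.items() if r not in used}

    @property
    def connected(self) -> dict[str, Subcomponent]:
        used = self.graph.incident_nodes()
        return {r: s for r, s in self.subcomponents.items() if r in used}

    def core_graph(self) -> SignedGraph:
        """The reduced graph restricted to subcomponents that kept edges."""
        return self.graph.subgraph(self.connected)

    def original_nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for sc in self.subcomponents.values():
            out.update(sc.members)
        return frozenset(out)

    def relative_sign(self, node: str) -> tuple[str, int]:
        """(representative, sign of ``node`` relative to it)."""
        for rep, sc in self.subcomponents.items():
            if node in sc.members:
                return rep, sc.members[node]
        raise KeyError(node)


# ---------------------------------------------------------------------------
# mutable working state
# ---------------------------------------------------------------------------

class _State:
    def __init__(self, graph: SignedGraph):
        graph.validate_for_coloring()
        self.edges: dict[tuple[str, str, int], Fraction] = {
            (e.source, e.target, e.sign): e.weight for e in graph.edges
        }
        self.members: dict[str, dict[str, int]] = {
            n: {n: 1} for n in graph.nodes
        }
        self.flags: dict[str, TargetFlag] = {}
        self.log: list[str] = []

    # -- queries ------------------------------------------------------------

    def in_edges(self, node: str):
        return [(s, t, g, w) for (s, t, g), w in self.edges.items() if t == node]

    def out_edges(self, node: str):
        return [(s, t, g, w) for (s, t, g), w in self.edges.items() if s == node]

    def cyclic_nodes(self) -> frozenset[str]:
        """Representatives lying on a directed cycle."""
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        g.add_edges_from((s, t) for (s, t, _) in self.edges)
        out: set[str] = set()
        for scc in nx.strongly_connected_components(g):
            if len(scc) > 1:
                out.update(scc)
        return frozenset(out)

    # -- mutation -----------------------------------------------------------

    def add_edge(self, s: str, t: str, sign: int, w: Fraction) -> None:
        key = (s, t, sign)
        self.edges[key] = self.edges.get(key, Fraction(0)) + w

    def merge(self, child: str, into: str, rel: int, consume: bool) -> None:
        """Fold subcomponent ``child`` into ``into`` with relative sign ``rel``.

        ``consume`` drops edges between the pair (the consistency pattern's
        satisfied incoming edge); the caller guarantees no other edges run
        between them.
        """
        assert child != into
        for m, s in self.members.pop(child).items():
            self.members[into][m] = rel * s
        for (s, t, g), w in list(self.edges.items()):
            if s != child and t != child:
                continue
            del self.edges[(s, t, g)]
            if s == child and t == child:  # cannot happen (no self-loops)
                continue
            if child in (s, t) and into in (s, t):
                if not consume:
                    raise AssertionError("unexpected internal edge in merge")
                continue
            if s == child:
                self.add_edge(into, t, g * rel, w)
            else:
                self.add_edge(s, into, g * rel, w)

    def to_reduced(self) -> ReducedGraph:
        g = SignedGraph(self.members)
        for (s, t, sign), w in self.edges.items():
            g.add_edge(s, t, sign, w)
        subs = {
            rep: Subcomponent(rep, dict(members))
            for rep, members in self.members.items()
        }
        return ReducedGraph(g, subs, dict(self.flags), list(self.log))


def _from_reduced(rg: ReducedGraph) -> _State:
    st = _State(rg.graph)
    st.members = {r: dict(s.members) for r, s in rg.subcomponents.items()}
    st.flags = dict(rg.flags)
    st.log = list(rg.provenance)
    return st


def _wrap(graph_or_rg) -> _State:
    if isinstance(graph_or_rg, ReducedGraph):
        return _from_reduced(graph_or_rg)
    return _State(graph_or_rg)


# ---------------------------------------------------------------------------
# the three rewrites
# ---------------------------------------------------------------------------

def _consistency_pass(st: _State) -> bool:
    changed = False
    while True:
        cyclic = st.cyclic_nodes()
        hit = None
        for t in sorted(st.members):
            if t in cyclic:
                continue
            flag = st.flags.get(t)
            if flag is not None and flag.always_consistent_imperfect:
                continue
            incoming = st.in_edges(t)
            if len(incoming) != 1:
                continue
            p, _, sign, _ = incoming[0]
            if p == t or p in cyclic:
                continue
            if any(s == t and tt == p for (s, tt, _g) in st.edges):
                continue  # back-edge would become a self-loop
            hit = (t, p, sign)
            break
        if hit is None:
            return changed
        t, p, sign = hit
        st.merge(t, p, sign, consume=True)
        st.log.append(f"consistency: merged {t} into {p} (rel {sign:+d})")
        changed = True


def _coregulator_pass(st: _State) -> bool:
    changed = False
    while True:
        hit = None
        for z in sorted({t for (_, t, _) in st.edges}):
            cands = []
            for p in sorted({s for (s, t, _) in st.edges if t == z}):
                if st.in_edges(p):
                    continue
                out = st.out_edges(p)
                if len(out) == 1 and out[0][1] == z:
                    cands.append((p, out[0][2]))
            if len(cands) >= 2:
                hit = (cands[0], cands[1])
                break
        if hit is None:
            return changed
        (x, sx), (y, sy) = hit
        st.merge(y, x, sx * sy, consume=False)
        st.log.append(f"co-regulators: merged {y} into {x} (rel {sx * sy:+d})")
        changed = True


def _balance_pass(st: _State) -> bool:
    changed = False
    pairs = sorted({(s, t) for (s, t, _) in st.edges})
    for s, t in pairs:
        wp = st.edges.get((s, t, 1))
        wm = st.edges.get((s, t, -1))
        if wp is None or wm is None:
            continue
        m = min(wp, wm)
        for sign, w in ((1, wp), (-1, wm)):
            if w - m == 0:
                del st.edges[(s, t, sign)]
            else:
                st.edges[(s, t, sign)] = w - m
        old = st.flags.get(t, TargetFlag(True, Fraction(0)))
        st.flags[t] = TargetFlag(True, old.residual_weight + m)
        st.log.append(f"edge balance: cancelled {m} between {s} and {t}; flagged {t}")
        changed = True
    return changed


def reduce_consistency(rg) -> ReducedGraph:
    """Apply the single-incoming-edge merge to fixpoint."""
    st = _wrap(rg)
    _consistency_pass(st)
    return st.to_reduced()


def reduce_coregulators(rg) -> ReducedGraph:
    """Apply the shared-unique-successor merge to fixpoint."""
    st = _wrap(rg)
    _coregulator_pass(st)
    return st.to_reduced()


def reduce_edge_balance(rg) -> ReducedGraph:
    """Sum same-sign parallel weights and cancel opposite-sign pairs."""
    st = _wrap(rg)
    _balance_pass(st)
    return st.to_reduced()


def reduce_all(graph: SignedGraph, rerun_after_balance: bool = False) -> ReducedGraph:
    """Run the three reductions successively: consistency, co-regulators,
    edge balance (each internally to fixpoint).

    The successive order is deliberate: a co-regulator merge can expose a
    fresh single-incoming-edge pattern on the very subcomponent it feeds, and
    folding that in would collapse the co-regulator pair and its successor
    into one subcomponent.  That extra merge is sound but coarser than the
    subcomponent structure the successive order produces, so it is not taken.
    ``rerun_after_balance`` re-enters the whole sequence after a balance pass
    that deleted edges (possibly exposing new patterns); it is off by default
    for the same reason.
    """
    st = _wrap(graph)
    while True:
        _consistency_pass(st)
        _coregulator_pass(st)
        if not _balance_pass(st) or not rerun_after_balance:
            break
    return st.to_reduced()


# ---------------------------------------------------------------------------
# expansion back to original nodes
# ---------------------------------------------------------------------------

def expand_coloring(rg: ReducedGraph, coloring: Mapping[str, str]) -> dict[str, str]:
    """Map a coloring of subcomponent representatives to the original nodes."""
    out: dict[str, str] = {}
    for rep, sc in rg.subcomponents.items():
        if rep not in coloring:
            raise ValueError(f"no color assigned to subcomponent {rep!r}")
        out.update(sc.expand(coloring[rep]))
    return out


def expand_model_set(rg: ReducedGraph, models: ModelSet) -> ModelSet:
    """Expand reduced-graph models to original-node models.

    Representatives absent from the model colorings (isolated subcomponents
    when enumeration ran on the core graph only) are color-independent and are
    completed with both colors, multiplying the model count accordingly.
    """
    dicts = models.as_dicts()
    covered = set(dicts[0]) if dicts else set()
    free_reps = sorted(set(rg.subcomponents) - covered)
    expanded = []
    for m in dicts:
        for combo in product((UP, DOWN), repeat=len(free_reps)):
            full = dict(m)
            full.update(zip(free_reps, combo))
            expanded.append(expand_coloring(rg, full))
    return ModelSet.from_dicts(expanded, models.objective, models.fixed)
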