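"""Perfect-coloring evaluation and exhaustive lexicographic optimization.

A *coloring* assigns every node a qualitative state shift ``up`` or ``down``
(the change between two cellular conditions).  A target node is *consistent*
when at least one incoming edge explains its color (activation copies the
predecessor's sign, inhibition flips it), and *imperfect* when at least one
incoming edge fails to explain it.  Colorings are ranked by the lexicographic
objective

    (number of inconsistent targets,
     number of imperfect targets,
     total weight of imperfect regulators)

and a *perfect coloring* is any coloring attaining the minimum.  Because the
rules are sign-symmetric, the objective is invariant under a global flip, so
the optimal set without node fixing is flip-closed.

Three backends enumerate the complete optimal set: a vectorized ``bruteforce``
scan of all 2^n colorings, a ``branchbound`` depth-first search with a
lexicographic lower bound (exhaustive: it collects *all* optima, not a single
witness), and an ``asp`` backend that grounds and solves the equivalent logic
program with clingo when that solver is installed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .network import SignedGraph, target_nodes

__all__ = [
    "UP",
    "DOWN",
    "flip_color",
    "flip_coloring",
    "TargetFlag",
    "TargetStatus",
    "ObjectiveVector",
    "ModelSet",
    "BackendUnavailableError",
    "EnumerationCapError",
    "explains",
    "evaluate_coloring",
    "enumerate_optimal",
    "emit_asp_program",
]

UP = "up"
DOWN = "down"

_BACKENDS = ("bruteforce", "branchbound", "asp")


def flip_color(color: str) -> str:
    return DOWN if color == UP else UP


def flip_coloring(coloring: Mapping[str, str]) -> dict[str, str]:
    return {n: flip_color(c) for n, c in coloring.items()}


class BackendUnavailableError(RuntimeError):
    """The requested solver backend is not installed."""


class EnumerationCapError(RuntimeError):
    """The graph exceeds the configured brute-force size cap."""


@dataclass(frozen=True)
class TargetFlag:
    """Residual bookkeeping attached to a target by the edge-balance reduction.

    A target that received a balanced pair of opposite-sign edges from one
    source is *always* consistent (one of the pair explains it whatever the
    colors) and *always* imperfect (the other fails); the cancelled weight
    ``residual_weight`` keeps the third objective identical between original
    and reduced graphs.
    """

    always_consistent_imperfect: bool = True
    residual_weight: Fraction = Fraction(0)


@dataclass(frozen=True)
class TargetStatus:
    node: str
    consistent: bool
    imperfect: bool
    imperfect_regulators: tuple[tuple[str, int, Fraction], ...]


@dataclass(frozen=True, order=True)
class ObjectiveVector:
    """Lexicographic objective; dataclass field order gives the priority."""

    n_inconsistent: int
    n_imperfect: int
    imperfect_weight: Fraction

    def as_tuple(self) -> tuple[int, int, Fraction]:
        return (self.n_inconsistent, self.n_imperfect, self.imperfect_weight)


def _freeze(coloring: Mapping[str, str]) -> tuple[tuple[str, str], ...]:
    return tuple(sorted(coloring.items()))


@dataclass(frozen=True)
class ModelSet:
    """The complete set of optimal colorings sharing one objective."""

    colorings: frozenset[tuple[tuple[str, str], ...]]
    objective: ObjectiveVector
    fixed: Optional[tuple[str, str]] = None

    @classmethod
    def from_dicts(cls, colorings: Iterable[Mapping[str, str]],
                   objective: ObjectiveVector,
                   fixed: Optional[tuple[str, str]] = None) -> "ModelSet":
        return cls(frozenset(_freeze(c) for c in colorings), objective, fixed)

    def as_dicts(self) -> list[dict[str, str]]:
        return [dict(c) for c in sorted(self.colorings)]

    def __len__(self) -> int:
        return len(self.colorings)

    def __contains__(self, coloring: Mapping[str, str]) -> bool:
        return _freeze(coloring) in self.colorings

    def is_flip_closed(self) -> bool:
        return all(_freeze(flip_coloring(dict(c))) in self.colorings
                   for c in self.colorings)

    def free_nodes(self) -> frozenset[str]:
        """Nodes taking both colors across the model set."""
        free = set()
        models = self.as_dicts()
        if not models:
            return frozenset()
        ref = models[0]
        for m in models[1:]:
            free.update(n for n, c in m.items() if c != ref[n])
        return frozenset(free)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def explains(pred_sign: str, edge_sign: int, target_sign: str) -> bool:
    """Does a predecessor with color ``pred_sign`` explain the target's color?

    Activation (+1) requires equal colors, inhibition (-1) opposite colors.
    """
    if edge_sign == 1:
        return pred_sign == target_sign
    return pred_sign != target_sign


def evaluate_coloring(
    graph: SignedGraph,
    coloring: Mapping[str, str],
    flags: Optional[Mapping[str, TargetFlag]] = None,
) -> tuple[ObjectiveVector, dict[str, TargetStatus]]:
    """Score one coloring: objective vector plus per-target status.

    ``flags`` carries the always-consistent/always-imperfect annotations and
    residual weights produced by the edge-balance reduction; a flagged node
    counts as one imperfect (never inconsistent) target and contributes its
    residual weight even if it no longer has incoming edges.
    """
    flags = flags or {}
    missing = graph.nodes - set(coloring)
    if missing:
        raise ValueError(f"coloring is missing nodes: {sorted(missing)}")
    statuses: dict[str, TargetStatus] = {}
    n_inc = 0
    n_imp = 0
    weight = Fraction(0)
    flagged_seen: set[str] = set()
    for t in sorted(target_nodes(graph)):
        incoming = graph.in_edges(t)
        bad = tuple(
            (e.source, e.sign, e.weight)
            for e in incoming
            if not explains(coloring[e.source], e.sign, coloring[t])
        )
        flag = flags.get(t)
        flagged = flag is not None and flag.always_consistent_imperfect
        consistent = flagged or len(bad) < len(incoming)
        imperfect = flagged or len(bad) > 0
        if not consistent:
            n_inc += 1
        if imperfect:
            n_imp += 1
        w = sum((b[2] for b in bad), Fraction(0))
        if flag is not None:
            w += flag.residual_weight
            flagged_seen.add(t)
        weight += w
        statuses[t] = TargetStatus(t, consistent, imperfect, bad)
    # flagged nodes that lost every incoming edge (isolated by the balance
    # reduction) still count as always-consistent, always-imperfect targets
    for t, flag in flags.items():
        if t in flagged_seen:
            continue
        if flag.always_consistent_imperfect:
            n_imp += 1
        weight += flag.residual_weight
        statuses[t] = TargetStatus(t, True, flag.always_consistent_imperfect, ())
    return ObjectiveVector(n_inc, n_imp, weight), statuses


# ---------------------------------------------------------------------------
# shared integer scaffolding for the enumeration backends
# ---------------------------------------------------------------------------

def _weight_scale(graph: SignedGraph, flags: Mapping[str, TargetFlag]) -> int:
    """Common denominator turning all weights into exact integers."""
    denoms = [e.weight.denominator for e in graph.edges]
    denoms += [f.residual_weight.denominator for f in flags.values()]
    scale = 1
    for d in denoms:
        scale = scale * d // math.gcd(scale, d)
    return scale


def _flag_constants(graph: SignedGraph, flags: Mapping[str, TargetFlag],
                    scale: int) -> tuple[int, int]:
    """(extra imperfect count, scaled residual weight) from isolated flagged nodes."""
    targets = target_nodes(graph)
    extra_imp = 0
    extra_w = 0
    for t, f in flags.items():
        if t in targets:
            continue  # handled inline with the target's own edges
        if f.always_consistent_imperfect:
            extra_imp += 1
        extra_w += int(f.residual_weight * scale)
    return extra_imp, extra_w


# ---------------------------------------------------------------------------
# brute-force backend (vectorized over all 2^n colorings)
# ---------------------------------------------------------------------------

def _bruteforce(graph: SignedGraph, fixed, flags, cap: int) -> ModelSet:
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n > cap:
        raise EnumerationCapError(
            f"brute-force enumeration refused: {n} nodes exceeds cap {cap}; "
            f"raise the cap explicitly or use the branchbound backend"
        )
    idx = {node: i for i, node in enumerate(nodes)}
    m = 1 << n
    # cols[i, j] = True iff node j is 'up' in coloring i
    cols = ((np.arange(m, dtype=np.int64)[:, None] >> np.arange(n)) & 1).astype(bool)
    scale = _weight_scale(graph, flags)
    targets = sorted(target_nodes(graph))
    n_inc = np.zeros(m, dtype=np.int64)
    n_imp = np.zeros(m, dtype=np.int64)
    wsum = np.zeros(m, dtype=np.int64)
    for t in targets:
        ti = idx[t]
        any_explain = np.zeros(m, dtype=bool)
        fail_w = np.zeros(m, dtype=np.int64)
        for e in graph.in_edges(t):
            same = cols[:, idx[e.source]] == cols[:, ti]
            expl = same if e.sign == 1 else ~same
            any_explain |= expl
            fail_w += np.where(expl, 0, int(e.weight * scale))
        flag = flags.get(t)
        flagged = flag is not None and flag.always_consistent_imperfect
        if flagged:
            consistent = np.ones(m, dtype=bool)
            imperfect = np.ones(m, dtype=bool)
        else:
            consistent = any_explain
            imperfect = fail_w > 0
        if flag is not None:
            fail_w = fail_w + int(flag.residual_weight * scale)
        n_inc += ~consistent
        n_imp += imperfect.astype(np.int64)
        wsum += fail_w
    extra_imp, extra_w = _flag_constants(graph, flags, scale)
    n_imp += extra_imp
    wsum += extra_w
    keep = np.ones(m, dtype=bool)
    if fixed is not None:
        node, color = fixed
        keep &= cols[:, idx[node]] == (color == UP)
    if not keep.any():
        raise ValueError("fixed assignment excludes every coloring")
    best = keep.copy()
    for arr in (n_inc, n_imp, wsum):
        best &= arr == arr[best].min()
    objective = ObjectiveVector(
        int(n_inc[best][0]), int(n_imp[best][0]),
        Fraction(int(wsum[best][0]), scale),
    )
    colorings = []
    for i in np.flatnonzero(best):
        colorings.append({node: (UP if cols[i, j] else DOWN)
                          for j, node in enumerate(nodes)})
    return ModelSet.from_dicts(colorings, objective, fixed)


# ---------------------------------------------------------------------------
# branch-and-bound backend (exhaustive optimal-set collection)
# ---------------------------------------------------------------------------

def _branchbound(graph: SignedGraph, fixed, flags) -> ModelSet:
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    scale = _weight_scale(graph, flags)
    targets = sorted(target_nodes(graph))
    # a target's status is decided once it and all its predecessors are colored
    decided_at: dict[int, list[str]] = {d: [] for d in range(n)}
    for t in targets:
        last = max([idx[t]] + [idx[e.source] for e in graph.in_edges(t)])
        decided_at[last].append(t)
    in_edges = {t: [(idx[e.source], e.sign, int(e.weight * scale))
                    for e in graph.in_edges(t)] for t in targets}
    flag_info = {}
    for t in targets:
        f = flags.get(t)
        flag_info[t] = (f is not None and f.always_consistent_imperfect,
                        int(f.residual_weight * scale) if f is not None else 0)
    extra_imp, extra_w = _flag_constants(graph, flags, scale)
    fixed_idx = idx[fixed[0]] if fixed is not None else -1
    fixed_up = fixed is not None and fixed[1] == UP

    best: list = [None]  # best (inc, imp, w) found so far
    optima: list[tuple[bool, ...]] = []
    assign = [False] * n

    def score_decided(depth: int, inc: int, imp: int, w: int):
        for t in decided_at[depth]:
            t_up = assign[idx[t]]
            any_expl = False
            fail = 0
            for si, sign, sw in in_edges[t]:
                expl = (assign[si] == t_up) if sign == 1 else (assign[si] != t_up)
                if expl:
                    any_expl = True
                else:
                    fail += sw
            flagged, residual = flag_info[t]
            if not (any_expl or flagged):
                inc += 1
            if fail > 0 or flagged:
                imp += 1
            w += fail + residual
        return inc, imp, w

    def dfs(depth: int, inc: int, imp: int, w: int) -> None:
        if best[0] is not None and (inc, imp, w) > best[0]:
            return
        if depth == n:
            key = (inc, imp, w)
            if best[0] is None or key < best[0]:
                best[0] = key
                optima.clear()
            if key == best[0]:
                optima.append(tuple(assign))
            return
        choices = (fixed_up,) if depth == fixed_idx else (False, True)
        for up in choices:
            assign[depth] = up
            dfs(depth + 1, *score_decided(depth, inc, imp, w))

    dfs(0, 0, extra_imp, extra_w)
    inc, imp, w = best[0]
    objective = ObjectiveVector(inc, imp, Fraction(w, scale))
    colorings = [{node: (UP if bits[j] else DOWN) for j, node in enumerate(nodes)}
                 for bits in optima]
    return ModelSet.from_dicts(colorings, objective, fixed)


# ---------------------------------------------------------------------------
# ASP backend
# ---------------------------------------------------------------------------

def _asp_quote(node: str) -> str:
    return '"' + node.replace("\\", "\\\\").replace('"', '\\"') + '"'


def emit_asp_program(
    graph: SignedGraph,
    fixed: Optional[tuple[str, str]] = None,
    flags: Optional[Mapping[str, TargetFlag]] = None,
) -> str:
    """Render the coloring logic as an ASP-Core-2 / gringo program.

    Grounding and solving the text with an external solver (clingo) under
    optimal answer-set enumeration yields the same model set as
    :func:`enumerate_optimal`.  Weights are integer-scaled (ASP weights must
    be integers); the scale factor is recorded in a comment.
    """
    flags = flags or {}
    scale = _weight_scale(graph, flags)
    lines = [f"% weight scale: {scale}"]
    for e in graph.edges:
        lines.append(
            f"edge({_asp_quote(e.source)},{_asp_quote(e.target)},{e.sign},"
            f"{int(e.weight * scale)})."
        )
    for node in sorted(graph.nodes - graph.incident_nodes()):
        lines.append(f"node({_asp_quote(node)}).")
    for t, f in sorted(flags.items()):
        if f.always_consistent_imperfect:
            lines.append(f"flagged({_asp_quote(t)}).")
        if f.residual_weight:
            lines.append(f"residual({_asp_quote(t)},{int(f.residual_weight * scale)}).")
    lines += [
        "node(X) :- edge(X,_,_,_).",
        "node(X) :- edge(_,X,_,_).",
        "target(X) :- edge(_,X,_,_).",
        "sign(up). sign(down).",
        "1 { color(X,S) : sign(S) } 1 :- node(X).",
        "consistent(T) :- target(T), edge(S,T,1,_), color(S,C), color(T,C).",
        "consistent(T) :- target(T), edge(S,T,-1,_), color(S,C1), color(T,C2), C1 != C2.",
        "consistent(T) :- target(T), flagged(T).",
        "imperfect_reg(S,T,W) :- edge(S,T,1,W), color(S,C1), color(T,C2), C1 != C2.",
        "imperfect_reg(S,T,W) :- edge(S,T,-1,W), color(S,C), color(T,C).",
        "inconsistent(T) :- target(T), not consistent(T).",
        "imperfect(T) :- imperfect_reg(_,T,_), not flagged(T).",
        "imperfect(T) :- flagged(T).",
        "#minimize { 1@3,T : inconsistent(T) }.",
        "#minimize { 1@2,T : imperfect(T) }.",
        "#minimize { W@1,S,T : imperfect_reg(S,T,W) }.",
        "#minimize { W@1,r,T : residual(T,W) }.",
        "#show color/2.",
    ]
    if fixed is not None:
        lines.append(f"color({_asp_quote(fixed[0])},{fixed[1]}).")
    return "\n".join(lines) + "\n"


def _asp_solve(graph: SignedGraph, fixed, flags) -> ModelSet:
    try:
        import clingo  # type: ignore
    except ImportError as exc:
        raise BackendUnavailableError(
            "the 'asp' backend requires the clingo Python package, which is "
            "not installed; use backend='bruteforce' or 'branchbound'"
        ) from exc
    program = emit_asp_program(graph, fixed, flags)
    ctl = clingo.Control(["--opt-mode=optN", "0"])
    ctl.add("base", [], program)
    ctl.ground([("base", [])])
    scale = _weight_scale(graph, flags or {})
    models: list[dict[str, str]] = []
    costs: list = []

    def on_model(model):
        if not model.optimality_proven:
            return
        coloring = {}
        for atom in model.symbols(shown=True):
            if atom.name == "color":
                coloring[atom.arguments[0].string] = str(atom.arguments[1])
        costs[:] = [model.cost]
        models.append(coloring)

    ctl.solve(on_model=on_model)
    inc, imp, w = (costs[0] + [0, 0, 0])[:3] if costs else (0, 0, 0)
    objective = ObjectiveVector(inc, imp, Fraction(w, scale))
    return ModelSet.from_dicts(models, objective, fixed)


# ---------------------------------------------------------------------------
# public driver
# ---------------------------------------------------------------------------

def enumerate_optimal(
    graph: SignedGraph,
    fixed: Optional[tuple[str, str]] = None,
    flags: Optional[Mapping[str, TargetFlag]] = None,
    backend: str = "bruteforce",
    cap: int = 20,
) -> ModelSet:
    """Enumerate *all* colorings attaining the lexicographic optimum.

    Parameters
    ----------
    graph:
        The signed graph to color (validated against self-loops).
    fixed:
        Optional ``(node, color)`` pinning one node; halves the search space
        and breaks the global flip symmetry.
    flags:
        Edge-balance bookkeeping (see :class:`TargetFlag`).
    backend:
        ``bruteforce`` (vectorized, capped at ``cap`` nodes), ``branchbound``
        (exhaustive DFS), or ``asp`` (requires clingo).
    """
    if backend not in _BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; choose from {_BACKENDS}")
    graph.validate_for_coloring()
    flags = flags or {}
    if fixed is not None:
        node, color = fixed
        if node not in graph.nodes:
            raise ValueError(f"fixed node {node!r} not in graph")
        if color not in (UP, DOWN):
            raise ValueError(f"fixed color must be 'up' or 'down', got {color!r}")
    if graph.n_nodes() == 0:
        return ModelSet.from_dicts([{}], ObjectiveVector(0, 0, Fraction(0)), fixed)
    if backend == "bruteforce":
        return _bruteforce(graph, fixed, flags, cap)
    if backend == "branchbound":
        return _branchbound(graph, fixed, flags)
    return _asp_solve(graph, fixed, flags)
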