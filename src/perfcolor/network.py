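"""Signed influence-graph data model and edge-list / expression-matrix I/O.

The central object is :class:`SignedGraph`: a directed graph whose edges carry
an activation (+1) or inhibition (-1) sign and a strictly positive weight.
Node identifiers are case-sensitive opaque strings.  Weights are kept as exact
:class:`fractions.Fraction` values so that the edge-balance subtraction used by
the graph reductions is exact and free of floating-point ties.

Canonical form: at most one edge per ``(source, target, sign)`` triple;
parallel same-sign edges are merged by summing their weights.  Two edges of
*opposite* sign between the same ordered node pair are legal and meaningful
(they are what the edge-balance reduction cancels).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "Edge",
    "SignedGraph",
    "GraphParseError",
    "GraphValidationError",
    "read_signed_graph",
    "read_signed_graph_with_isolates",
    "write_signed_graph",
    "target_nodes",
    "read_expression_matrix",
    "read_sample_groups",
]

#: accepted spellings of the activation / inhibition sign in edge-list files
_SIGN_TOKENS = {
    "1": 1, "+1": 1, "+": 1, "activation": 1, "activates": 1,
    "-1": -1, "-": -1, "inhibition": -1, "inhibits": -1,
}


class GraphParseError(ValueError):
    """Raised for malformed edge-list rows (carries the offending line number)."""


class GraphValidationError(ValueError):
    """Raised when a structurally parsed graph violates a model invariant."""


@dataclass(frozen=True)
class Edge:
    """A signed, weighted regulatory interaction ``source -> target``."""

    source: str
    target: str
    sign: int
    weight: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise GraphValidationError(f"edge sign must be +1 or -1, got {self.sign!r}")
        if not isinstance(self.weight, Fraction):
            object.__setattr__(self, "weight", _as_fraction(self.weight))
        if self.weight <= 0:
            raise GraphValidationError(
                f"edge {self.source}->{self.target} has nonpositive weight {self.weight}"
            )


def _as_fraction(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        # decimal round-trip keeps '0.1' exact instead of binary-float noise
        return Fraction(repr(value))
    return Fraction(value)


class SignedGraph:
    """Directed signed weighted graph in canonical form.

    Internally a mapping ``(source, target, sign) -> weight``; adding an edge
    that already exists with the same sign sums the weights.
    """

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[Edge] = ()):
        self._nodes: set[str] = set(nodes)
        self._edges: dict[tuple[str, str, int], Fraction] = {}
        for e in edges:
            self.add_edge(e.source, e.target, e.sign, e.weight)

    # -- construction -------------------------------------------------------

    def add_node(self, node: str) -> None:
        self._nodes.add(str(node))

    def add_edge(self, source: str, target: str, sign: int, weight=Fraction(1)) -> None:
        e = Edge(str(source), str(target), int(sign), _as_fraction(weight))
        self._nodes.add(e.source)
        self._nodes.add(e.target)
        key = (e.source, e.target, e.sign)
        self._edges[key] = self._edges.get(key, Fraction(0)) + e.weight

    def copy(self) -> "SignedGraph":
        g = SignedGraph(self._nodes)
        g._edges = dict(self._edges)
        return g

    # -- queries -------------------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._nodes)

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(
            Edge(s, t, sign, w) for (s, t, sign), w in sorted(self._edges.items())
        )

    def n_nodes(self) -> int:
        return len(self._nodes)

    def n_edges(self) -> int:
        return len(self._edges)

    def in_edges(self, node: str) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.target == node)

    def out_edges(self, node: str) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.source == node)

    def incident_nodes(self) -> frozenset[str]:
        """Nodes with at least one incident edge."""
        used: set[str] = set()
        for s, t, _ in self._edges:
            used.add(s)
            used.add(t)
        return frozenset(used)

    def has_self_loop(self) -> bool:
        return any(s == t for s, t, _ in self._edges)

    def validate_for_coloring(self) -> None:
        """Reject graphs whose coloring semantics are undefined (self-loops)."""
        loops = sorted({s for s, t, _ in self._edges if s == t})
        if loops:
            raise GraphValidationError(
                f"self-regulation has no defined coloring semantics; self-loop(s) at: "
                + ", ".join(loops)
            )

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self._nodes)
        for (s, t, sign), w in self._edges.items():
            g.add_edge(s, t, sign=sign, weight=w)
        return g

    def subgraph(self, nodes: Iterable[str]) -> "SignedGraph":
        keep = set(nodes)
        g = SignedGraph(keep)
        for (s, t, sign), w in self._edges.items():
            if s in keep and t in keep:
                g.add_edge(s, t, sign, w)
        return g

    # -- equality / display ---------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignedGraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self):  # pragma: no cover - mutable container
        raise TypeError("SignedGraph is mutable and unhashable")

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._nodes))

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def __repr__(self) -> str:
        return f"SignedGraph(n_nodes={self.n_nodes()}, n_edges={self.n_edges()})"


def target_nodes(graph: SignedGraph) -> frozenset[str]:
    """Nodes with at least one predecessor (in-degree >= 1).

    Only these nodes are constrained by the coloring logic; source nodes are
    free variables.
    """
    return frozenset(t for _, t, _ in graph._edges)


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def _parse_sign(token: str, lineno: int) -> int:
    try:
        return _SIGN_TOKENS[token.strip().lower()]
    except KeyError:
        raise GraphParseError(
            f"line {lineno}: unrecognized sign token {token!r} "
            f"(accepted: {sorted(_SIGN_TOKENS)})"
        ) from None


def read_signed_graph(path, dialect: str = "auto") -> SignedGraph:
    """Read a signed edge list.

    Format: TSV with columns ``source<TAB>sign<TAB>target[<TAB>weight]``;
    lines starting with ``#`` are comments.  A missing weight column means
    weight 1.  SIF-style files where the sign is carried by the relation token
    (``activates`` / ``inhibits``) are accepted by the same reader.

    Parameters
    ----------
    path:
        File location (or a file-like object).
    dialect:
        ``"three-column"`` (no weight), ``"four-column"`` (explicit weight) or
        ``"auto"`` (per-row: 3 fields -> weight 1, 4 fields -> 4th is weight).
    """
    if dialect not in ("auto", "three-column", "four-column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    g = SignedGraph()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) == 3:
            if dialect == "four-column":
                raise GraphParseError(f"line {lineno}: expected 4 columns, got 3")
            src, sign_tok, tgt = fields
            weight = Fraction(1)
        elif len(fields) == 4:
            if dialect == "three-column":
                raise GraphParseError(f"line {lineno}: expected 3 columns, got 4")
            src, sign_tok, tgt, wtok = fields
            try:
                weight = Fraction(wtok)
            except (ValueError, ZeroDivisionError):
                raise GraphParseError(
                    f"line {lineno}: cannot parse weight {wtok!r}"
                ) from None
        else:
            raise GraphParseError(
                f"line {lineno}: expected 3 or 4 tab-separated columns, got {len(fields)}"
            )
        sign = _parse_sign(sign_tok, lineno)
        if weight <= 0:
            raise GraphValidationError(
                f"line {lineno}: weight must be > 0, got {weight}"
            )
        g.add_edge(src, tgt, sign, weight)
    return g


def write_signed_graph(graph: SignedGraph, path) -> None:
    """Write the canonical four-column TSV edge list (round-trips losslessly)."""
    buf = io.StringIO()
    buf.write("#source\tsign\ttarget\tweight\n")
    for e in graph.edges:
        buf.write(f"{e.source}\t{e.sign:+d}\t{e.target}\t{e.weight}\n")
    # isolated nodes carried as comment directives so round-trip preserves them
    for node in sorted(graph.nodes - graph.incident_nodes()):
        buf.write(f"#node\t{node}\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


def read_signed_graph_with_isolates(path, dialect: str = "auto") -> SignedGraph:
    """Like :func:`read_signed_graph`, also honoring ``#node`` directives."""
    if hasattr(path, "read"):
        text = path.read()
        lines = text.splitlines()
        g = read_signed_graph(io.StringIO(text), dialect)
    else:
        lines = Path(path).read_text().splitlines()
        g = read_signed_graph(path, dialect)
    for raw in lines:
        fields = raw.strip().split("\t")
        if len(fields) == 2 and fields[0] == "#node":
            g.add_node(fields[1])
    return g


# ---------------------------------------------------------------------------
# expression-matrix I/O
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene id) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise GraphValidationError("expression matrix has duplicate gene ids")
    return df


def read_sample_groups(path) -> dict[str, str]:
    """Read a two-column TSV mapping sample id -> group label (case/control)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                     comment="#", dtype=str)
    return dict(zip(df["sample"], df["group"]))
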