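"""Component identification from enumerated optimal colorings.

Across the complete set of optimal colorings, two nodes are *positively
correlated* when they are never colored oppositely, *negatively correlated*
when they are never colored alike, and *independent* when both combinations
occur.  Positive/negative correlation is transitive over the complete model
set, so its closure partitions the nodes into *components*: maximal sets of
mutually determined nodes.  A component admits exactly two configurations,
each the global flip of the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .coloring import DOWN, UP, ModelSet, flip_color

__all__ = [
    "CorrelationClass",
    "Component",
    "correlation_matrix",
    "identify_components",
]

POSITIVE = "positive"
NEGATIVE = "negative"
INDEPENDENT = "independent"


@dataclass(frozen=True)
class CorrelationClass:
    """Classification of one unordered node pair across all optimal models."""

    pair: tuple[str, str]
    cls: str                 # positive / negative / independent
    counts: tuple[int, int]  # (same-sign occurrences, opposite-sign occurrences)


@dataclass(frozen=True)
class Component:
    """A maximal color-correlated node set with its two configurations."""

    id: str
    members: Mapping[str, int]  # node -> relative sign within the component

    @property
    def config1(self) -> dict[str, str]:
        """Canonical configuration: lexicographically smallest member is up."""
        ref = min(self.members)
        ref_sign = self.members[ref]
        return {m: (UP if s == ref_sign else DOWN) for m, s in self.members.items()}

    @property
    def config2(self) -> dict[str, str]:
        return {m: flip_color(c) for m, c in self.config1.items()}

    def __len__(self) -> int:
        return len(self.members)


def _model_matrix(models: ModelSet) -> tuple[list[str], np.ndarray]:
    dicts = models.as_dicts()
    if not dicts:
        raise ValueError("model set is empty")
    nodes = sorted(dicts[0])
    mat = np.array([[m[n] == UP for n in nodes] for m in dicts], dtype=bool)
    return nodes, mat


def correlation_matrix(models: ModelSet) -> dict[tuple[str, str], CorrelationClass]:
    """Classify every unordered node pair over the complete model set.

    The diagonal (self-pairs) is excluded.
    """
    nodes, mat = _model_matrix(models)
    n_models = mat.shape[0]
    out: dict[tuple[str, str], CorrelationClass] = {}
    for i, x in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            y = nodes[j]
            a = int(np.count_nonzero(mat[:, i] == mat[:, j]))
            b = n_models - a
            if b == 0:
                cls = POSITIVE
            elif a == 0:
                cls = NEGATIVE
            else:
                cls = INDEPENDENT
            out[(x, y)] = CorrelationClass((x, y), cls, (a, b))
    return out


class _SignedUnionFind:
    """Union-find carrying the sign of each node relative to its root."""

    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}
        self.sign = {x: 1 for x in items}

    def find(self, x: str) -> tuple[str, int]:
        if self.parent[x] == x:
            return x, 1
        root, s = self.find(self.parent[x])
        self.parent[x] = root
        self.sign[x] *= s
        return root, self.sign[x]

    def union(self, x: str, y: str, rel: int) -> None:
        rx, sx = self.find(x)
        ry, sy = self.find(y)
        if rx == ry:
            if sx * sy != rel:
                raise AssertionError(
                    f"inconsistent relative signs between {x} and {y}"
                )
            return
        # attach the lexicographically larger root under the smaller one
        if rx > ry:
            rx, ry, sx, sy = ry, rx, sy, sx
            x, y = y, x
        self.parent[ry] = rx
        self.sign[ry] = sx * rel * sy

    def groups(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for x in self.parent:
            root, s = self.find(x)
            out.setdefault(root, {})[x] = s
        return out


def identify_components(
    models: ModelSet,
    reduced: Optional["ReducedGraph"] = None,
) -> list[Component]:
    """Partition nodes into components from the complete optimal model set.

    When ``reduced`` (a :class:`~perfcolor.reduction.ReducedGraph`) is given,
    the model colorings are over subcomponent representatives; components are
    expanded back to original nodes via the subcomponent relative signs, and
    every isolated subcomponent becomes its own component.  Components are
    labeled ``C1, C2, ...`` in decreasing size order (ties broken by smallest
    member id).
    """
    corr = correlation_matrix(models)
    nodes = sorted(models.as_dicts()[0])
    uf = _SignedUnionFind(nodes)
    for (x, y), cc in corr.items():
        if cc.cls == POSITIVE:
            uf.union(x, y, 1)
        elif cc.cls == NEGATIVE:
            uf.union(x, y, -1)
    member_maps: list[dict[str, int]] = []
    for root, grp in uf.groups().items():
        if reduced is None:
            member_maps.append(grp)
        else:
            expanded: dict[str, int] = {}
            for rep, rel in grp.items():
                for m, s in reduced.subcomponents[rep].members.items():
                    expanded[m] = rel * s
            member_maps.append(expanded)
    if reduced is not None:
        covered = set(nodes)
        for rep, sc in sorted(reduced.subcomponents.items()):
            if rep not in covered:
                member_maps.append(dict(sc.members))
    # every node must land in exactly one component
    seen: set[str] = set()
    for mm in member_maps:
        dup = seen & set(mm)
        if dup:
            raise AssertionError(f"nodes in two components: {sorted(dup)}")
        seen.update(mm)
    member_maps.sort(key=lambda mm: (-len(mm), min(mm)))
    return [Component(f"C{i + 1}", mm) for i, mm in enumerate(member_maps)]
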