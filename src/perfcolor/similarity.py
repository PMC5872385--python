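"""Fold-change discretization and the maximal-similarity (MS) statistic.

An expression profile is discretized against control means with a fold
threshold f (default 1.2): a gene is ``up`` when value >= f * mean, ``down``
when value <= mean / f, and unobserved inside the band.  For a component with
configurations C1 and C2 (mutual flips), the maximal similarity of an
observation set restricted to the component is

    MS = max(|obs ∩ C1|, |obs ∩ C2|) / |obs|

which always lies in [1/2, 1] because the two intersection counts partition
the observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional

import pandas as pd

from .coloring import DOWN, UP
from .components import Component

__all__ = [
    "DiscretizedProfile",
    "MSRecord",
    "discretize",
    "discretize_matrix",
    "maximal_similarity",
]


@dataclass(frozen=True)
class DiscretizedProfile:
    """Partial up/down observation map derived from one expression profile."""

    observations: Mapping[str, str]
    sample_id: str = "obs"
    fold: float = 1.2
    n_skipped: int = 0  # genes dropped for nonpositive control mean

    def __post_init__(self):
        bad = {v for v in self.observations.values()} - {UP, DOWN}
        if bad:
            raise ValueError(f"observation values must be up/down, got {bad}")

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class MSRecord:
    component_id: str
    sample_id: str
    n_observed: int
    ms: Optional[Fraction]  # None when the component is unobserved
    sim_c1: int = 0
    sim_c2: int = 0

    @property
    def defined(self) -> bool:
        return self.ms is not None


def discretize(
    profile: Mapping[str, float],
    control_means: Mapping[str, float],
    fold: float = 1.2,
    sample_id: str = "obs",
    log_scale: bool = False,
) -> DiscretizedProfile:
    """Threshold one profile against control means.

    Boundary values are inclusive (>= f*mean is up, <= mean/f is down), making
    the discretizer monotone in the measured value.  ``log_scale`` treats the
    inputs as log2 values and compares by +/- log2(fold) instead of ratios.
    """
    if fold <= 1:
        raise ValueError(f"fold threshold must be > 1, got {fold}")
    obs: dict[str, str] = {}
    skipped = 0
    for gene, value in profile.items():
        if gene not in control_means:
            continue
        mean = control_means[gene]
        if log_scale:
            delta = math.log2(fold)
            if value >= mean + delta:
                obs[gene] = UP
            elif value <= mean - delta:
                obs[gene] = DOWN
            continue
        if mean <= 0:
            skipped += 1
            continue
        if value >= fold * mean:
            obs[gene] = UP
        elif value <= mean / fold:
            obs[gene] = DOWN
    return DiscretizedProfile(obs, sample_id, fold, skipped)


def discretize_matrix(
    matrix: pd.DataFrame,
    control_samples: list[str],
    fold: float = 1.2,
    samples: Optional[list[str]] = None,
    log_scale: bool = False,
) -> list[DiscretizedProfile]:
    """Discretize each (non-control, unless listed) sample of a genes x samples matrix."""
    missing = [s for s in control_samples if s not in matrix.columns]
    if missing:
        raise ValueError(f"control samples not in matrix: {missing}")
    means = matrix[control_samples].mean(axis=1).to_dict()
    if samples is None:
        samples = [c for c in matrix.columns if c not in control_samples]
    return [
        discretize(matrix[s].to_dict(), means, fold, sample_id=s,
                   log_scale=log_scale)
        for s in samples
    ]


def maximal_similarity(component: Component, obs: DiscretizedProfile) -> MSRecord:
    """MS of one observation set against one component's two configurations."""
    config1 = component.config1
    inside = {n: c for n, c in obs.observations.items() if n in config1}
    n = len(inside)
    if n == 0:
        return MSRecord(component.id, obs.sample_id, 0, None)
    k = sum(1 for node, c in inside.items() if c == config1[node])
    return MSRecord(
        component.id, obs.sample_id, n,
        Fraction(max(k, n - k), n), sim_c1=k, sim_c2=n - k,
    )
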