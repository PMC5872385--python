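"""Randomization-based validation and case/control specificity of MS scores.

Two questions are asked of every component:

*validation* — are the real profiles more similar to the component's
configurations than sign-scrambled versions of the same profiles?  For each
real profile a number of randomized profiles (default 5) is generated by
permuting the observed up/down labels over the observed nodes (conserving the
up/down counts); the real MS values are compared to the pooled shuffled MS
values with Welch's unequal-variance t-test.

*specificity* — do case profiles score differently from control profiles on
this component?  Welch's t-test between the two groups' MS values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .components import Component
from .similarity import DiscretizedProfile, maximal_similarity

__all__ = [
    "ValidationReport",
    "DegenerateSamplesError",
    "shuffle_signs",
    "welch_t",
    "validate_components",
]


class DegenerateSamplesError(ValueError):
    """Welch's t-test is undefined (sample too small or both variances zero)."""


@dataclass(frozen=True)
class ValidationReport:
    component_id: str
    n_nodes: int
    validation_p: Optional[float]
    specificity_p: Optional[float]
    n_random_sets: int
    seed: int
    n_observed_profiles: int = 0

    @property
    def applicable(self) -> bool:
        return self.n_observed_profiles > 0


def shuffle_signs(obs: DiscretizedProfile, seed) -> DiscretizedProfile:
    """Permute the observed up/down labels uniformly over the observed nodes.

    The observed node set and the multiset of labels are conserved; only the
    assignment of labels to nodes is randomized.  ``seed`` may be an int or a
    numpy Generator.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(obs.observations)
    labels = [obs.observations[n] for n in nodes]
    perm = rng.permutation(len(nodes))
    shuffled = {nodes[i]: labels[perm[i]] for i in range(len(nodes))}
    return DiscretizedProfile(shuffled, obs.sample_id + ":shuffled", obs.fold)


def welch_t(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t statistic and two-sided p-value.

    Uses the Welch–Satterthwaite degrees of freedom.  Raises
    :class:`DegenerateSamplesError` when either sample has fewer than two
    values or both samples have zero variance.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 2 or len(ys) < 2:
        raise DegenerateSamplesError(
            f"need >= 2 values per sample, got {len(xs)} and {len(ys)}"
        )
    if xs.var(ddof=1) == 0 and ys.var(ddof=1) == 0:
        raise DegenerateSamplesError("both samples have zero variance")
    t, p = stats.ttest_ind(xs, ys, equal_var=False)
    return float(t), float(p)


def validate_components(
    components: Sequence[Component],
    profiles: Sequence[DiscretizedProfile],
    groups: Optional[Mapping[str, str]] = None,
    case_label: str = "case",
    control_label: str = "control",
    n_random: int = 5,
    seed: int = 0,
) -> list[ValidationReport]:
    """Per-component validation (vs shuffles) and specificity (case vs control).

    ``groups`` maps sample id -> group label; when absent, specificity is not
    computed.  All randomness derives from ``seed``.  A component observed in
    no profile is reported as not applicable (both p-values None).
    """
    if len(profiles) < 2:
        raise ValueError("validation requires at least 2 profiles")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    root = np.random.default_rng(seed)
    reports: list[ValidationReport] = []
    for comp in components:
        rng = np.random.default_rng(root.integers(2 ** 31))
        real: list[float] = []
        shuffled: list[float] = []
        by_group: dict[str, list[float]] = {}
        n_obs_profiles = 0
        for prof in profiles:
            rec = maximal_similarity(comp, prof)
            if not rec.defined:
                continue
            n_obs_profiles += 1
            ms = float(rec.ms)
            real.append(ms)
            if groups is not None and prof.sample_id in groups:
                by_group.setdefault(groups[prof.sample_id], []).append(ms)
            for _ in range(n_random):
                srec = maximal_similarity(comp, shuffle_signs(prof, rng))
                shuffled.append(float(srec.ms))
        validation_p = None
        specificity_p = None
        if n_obs_profiles > 0:
            try:
                validation_p = welch_t(real, shuffled)[1]
            except DegenerateSamplesError:
                pass
            if groups is not None:
                xs = by_group.get(case_label, [])
                ys = by_group.get(control_label, [])
                try:
                    specificity_p = welch_t(xs, ys)[1]
                except DegenerateSamplesError:
                    pass
        reports.append(ValidationReport(
            comp.id, len(comp), validation_p, specificity_p,
            n_random, seed, n_obs_profiles,
        ))
    return reports
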