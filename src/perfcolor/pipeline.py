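"""End-to-end workflow: reduce -> color -> components -> score -> validate.

The coloring stages are data-independent: the model set and component
partition are computed from the network alone, and only afterwards are the
discretized expression profiles confronted with the components.  Supplying or
omitting expression inputs therefore never changes the coloring outputs.

Node fixing: the solution space is flip-symmetric, so enumeration pins the
lexicographically smallest representative of the largest weakly connected part
of the reduced core graph to ``down``, halving the search; the full model set
is restored by flip completion before component correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional

import networkx as nx

from . import __version__
from .coloring import (ModelSet, ObjectiveVector, enumerate_optimal,
                       flip_coloring)
from .components import Component, identify_components
from .network import (SignedGraph, read_expression_matrix, read_sample_groups,
                      read_signed_graph, target_nodes, write_signed_graph)
from .reduction import ReducedGraph, reduce_all
from .similarity import DiscretizedProfile, MSRecord, discretize_matrix, \
    maximal_similarity
from .validation import ValidationReport, validate_components

__all__ = ["RunConfig", "PipelineResult", "color_graph", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run (defaults match the method)."""

    graph_path: Optional[str] = None
    expression_path: Optional[str] = None
    groups_path: Optional[str] = None
    observations_path: Optional[str] = None
    control_label: str = "control"
    case_label: str = "case"
    fold: float = 1.2
    n_random: int = 5
    seed: int = 0
    backend: str = "bruteforce"
    fix_node: bool = True
    bruteforce_cap: int = 20
    rerun_after_balance: bool = False
    out_dir: Optional[str] = None


@dataclass
class PipelineResult:
    reduced: ReducedGraph
    models: ModelSet
    components: list[Component]
    ms_records: list[MSRecord] = field(default_factory=list)
    validation: list[ValidationReport] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _pick_fixed(core: SignedGraph) -> Optional[tuple[str, str]]:
    """Smallest representative of the largest weakly connected part, down."""
    if core.n_nodes() == 0:
        return None
    und = nx.Graph()
    und.add_nodes_from(core.nodes)
    und.add_edges_from((e.source, e.target) for e in core.edges)
    parts = sorted(nx.connected_components(und), key=lambda p: (-len(p), min(p)))
    return (min(parts[0]), "down")


def color_graph(
    graph: SignedGraph,
    backend: str = "bruteforce",
    fix_node: bool = True,
    bruteforce_cap: int = 20,
    rerun_after_balance: bool = False,
) -> tuple[ReducedGraph, ModelSet]:
    """Reduce the graph and enumerate the complete optimal model set.

    Enumeration runs on the reduced core graph (isolated subcomponents are
    color-independent and excluded); when ``fix_node`` is set, one node is
    pinned and the flip-completed set is returned, so the result is identical
    to unfixed enumeration.
    """
    rg = reduce_all(graph, rerun_after_balance=rerun_after_balance)
    core = rg.core_graph()
    fixed = _pick_fixed(core) if fix_node else None
    models = enumerate_optimal(core, fixed=fixed, flags=rg.flags,
                               backend=backend, cap=bruteforce_cap)
    if fixed is not None:
        completed = models.as_dicts() + [flip_coloring(m) for m in models.as_dicts()]
        models = ModelSet.from_dicts(completed, models.objective, fixed=None)
    return rg, models


def _load_profiles(config: RunConfig) -> tuple[list[DiscretizedProfile], Optional[dict]]:
    profiles: list[DiscretizedProfile] = []
    groups = None
    if config.observations_path:
        import pandas as pd
        df = pd.read_csv(config.observations_path, sep="\t", header=None,
                         comment="#", dtype=str)
        if df.shape[1] == 2:
            df.columns = ["node", "sign"]
            df["sample"] = "obs"
        else:
            df.columns = ["sample", "node", "sign"][: df.shape[1]]
        for sample, grp in df.groupby("sample", sort=True):
            obs = dict(zip(grp["node"], grp["sign"]))
            profiles.append(DiscretizedProfile(obs, sample_id=str(sample),
                                               fold=config.fold))
    elif config.expression_path:
        if not config.groups_path:
            raise ValueError("expression input requires a sample-groups file")
        groups = read_sample_groups(config.groups_path)
        controls = [s for s, g in groups.items() if g == config.control_label]
        if not controls:
            raise ValueError(
                f"no samples labeled {config.control_label!r} in groups file"
            )
        matrix = read_expression_matrix(config.expression_path)
        samples = [c for c in matrix.columns if c in groups]
        profiles = discretize_matrix(matrix, controls, config.fold,
                                     samples=samples)
    return profiles, groups


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and (optionally) write run artifacts to out_dir."""
    if config.graph_path:
        graph = read_signed_graph(config.graph_path)
    else:
        from .synth import toy_graph
        graph = toy_graph()
    graph.validate_for_coloring()
    rg, models = color_graph(
        graph, backend=config.backend, fix_node=config.fix_node,
        bruteforce_cap=config.bruteforce_cap,
        rerun_after_balance=config.rerun_after_balance,
    )
    components = identify_components(models, rg)
    profiles, groups = _load_profiles(config)
    ms_records: list[MSRecord] = []
    for comp in components:
        for prof in profiles:
            ms_records.append(maximal_similarity(comp, prof))
    reports: list[ValidationReport] = []
    if len(profiles) >= 2:
        reports = validate_components(
            components, profiles, groups=groups,
            case_label=config.case_label, control_label=config.control_label,
            n_random=config.n_random, seed=config.seed,
        )
    obj = models.objective
    summary = {
        "version": __version__,
        "seed": config.seed,
        "backend": config.backend,
        "fold": config.fold,
        "n_random": config.n_random,
        "graph": {
            "n_nodes": graph.n_nodes(),
            "n_targets": len(target_nodes(graph)),
            "n_edges": graph.n_edges(),
        },
        "reduced": {
            "n_subcomponents": len(rg.subcomponents),
            "n_connected": len(rg.connected),
            "n_isolated": len(rg.isolated),
            "n_edges": rg.graph.n_edges(),
        },
        "optimum": {
            "n_models": len(models),
            "n_inconsistent": obj.n_inconsistent,
            "n_imperfect": obj.n_imperfect,
            "imperfect_weight": str(obj.imperfect_weight),
        },
        "components": [
            {"id": c.id, "n_nodes": len(c)} for c in components
        ],
        "n_profiles": len(profiles),
    }
    result = PipelineResult(rg, models, components, ms_records, reports, summary)
    if config.out_dir:
        _write_artifacts(result, graph, Path(config.out_dir))
    return result


def _write_artifacts(result: PipelineResult, graph: SignedGraph,
                     out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_signed_graph(result.reduced.graph, out / "reduced_graph.tsv")
    with open(out / "membership.tsv", "w") as fh:
        fh.write("#member\trepresentative\trelative_sign\n")
        for rep, sc in sorted(result.reduced.subcomponents.items()):
            for m, s in sorted(sc.members.items()):
                fh.write(f"{m}\t{rep}\t{s:+d}\n")
    with open(out / "flags.tsv", "w") as fh:
        fh.write("#target\talways_consistent_imperfect\tresidual_weight\n")
        for t, f in sorted(result.reduced.flags.items()):
            fh.write(f"{t}\t{int(f.always_consistent_imperfect)}\t"
                     f"{f.residual_weight}\n")
    dicts = result.models.as_dicts()
    nodes = sorted(dicts[0]) if dicts else []
    with open(out / "models.tsv", "w") as fh:
        fh.write("\t".join(nodes) + "\n")
        for m in dicts:
            fh.write("\t".join(m[n] for n in nodes) + "\n")
    with open(out / "components.tsv", "w") as fh:
        fh.write("#component\tmember\trelative_sign\n")
        for c in result.components:
            for m, s in sorted(c.members.items()):
                fh.write(f"{c.id}\t{m}\t{s:+d}\n")
    with open(out / "ms.tsv", "w") as fh:
        fh.write("#component\tsample\tn_observed\tms\n")
        for r in result.ms_records:
            ms = "NA" if r.ms is None else str(r.ms)
            fh.write(f"{r.component_id}\t{r.sample_id}\t{r.n_observed}\t{ms}\n")
    with open(out / "validation.tsv", "w") as fh:
        fh.write("#component\tn_nodes\tvalidation_p\tspecificity_p\n")
        for r in result.validation:
            vp = "NA" if r.validation_p is None else f"{r.validation_p:.6g}"
            sp = "NA" if r.specificity_p is None else f"{r.specificity_p:.6g}"
            fh.write(f"{r.component_id}\t{r.n_nodes}\t{vp}\t{sp}\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
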