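"""End-to-end convenience wrapper: sequences -> Co-occurrence Clusters.

Chains the individual stages with their default settings; each stage remains
available separately for finer control.
"""

from __future__ import annotations

from dataclasses import dataclass

from .apc import AlignedPatternCluster, ApcConstraints, cluster_patterns
from .clustering import (
    ClusteringResult,
    kmedoids_cluster,
    mst_hierarchical_cluster,
    select_best_cluster,
    spectral_cluster,
)
from .cooccur import CoOccurrenceGraph, build_graph
from .io_seq import SequenceSet
from .patterns import DiscoveryConfig, PatternSet, discover_patterns
from .structure3d import StructureMapping, StructureModel, map_apcs


@dataclass
class PipelineResult:
    patterns: PatternSet
    apcs: list[AlignedPatternCluster]
    graph: CoOccurrenceGraph | None
    clustering: ClusteringResult | None
    best_cluster: int | None
    mapping: StructureMapping | None = None


def run_pipeline(seqs: SequenceSet,
                 discovery: DiscoveryConfig | None = None,
                 constraints: ApcConstraints | None = None,
                 algorithm: str = "spectral",
                 k: int | None = None,
                 seed: int = 1,
                 edge_min: float = 0.0,
                 structure: StructureModel | None = None,
                 chain: str | None = None) -> PipelineResult:
    """Run discovery, APC construction, co-occurrence clustering and,
    optionally, 3D validation of the best cluster's APCs."""
    patterns = discover_patterns(seqs, discovery)
    if len(patterns) == 0:
        return PipelineResult(patterns, [], None, None, None)
    apcs = cluster_patterns(patterns, constraints)
    if len(apcs) < 2:
        return PipelineResult(patterns, apcs, None, None, None)
    graph = build_graph(apcs, edge_min=edge_min)
    if algorithm == "spectral":
        result = spectral_cluster(graph, k, seed=seed)
    elif algorithm == "kmedoids":
        result = kmedoids_cluster(graph, k)
    elif algorithm == "mst":
        if k is None:
            raise ValueError("mst clustering requires an explicit k")
        result = mst_hierarchical_cluster(graph, k)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    best: int | None = None
    if result.algorithm == "spectral":
        try:
            best = select_best_cluster(result)
        except ValueError:
            best = None
    mapping = None
    if structure is not None:
        chosen = [c for c in apcs
                  if best is None or result.assignment[c.id] == best]
        mapping = map_apcs(chosen, structure, chain=chain)
    return PipelineResult(patterns, apcs, graph, result, best, mapping)
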