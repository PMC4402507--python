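"""Network search: which deregulated genes does each mutation *explain*?

A deregulated gene is explained by a mutated gene when a path of at most L
edges connects them through deregulated genes only, never transiting a hub
(intermediate node of degree > D).  The mutated source itself need not be
deregulated (a truncating mutation need not alter its own transcript), and
hub exclusion applies to transit nodes only, so hub genes can themselves be
explained endpoints.  Both conventions can be tightened via flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .deregulation import DeregulationProfile
from .io_model import GeneNetwork, ParameterSet

logger = logging.getLogger(__name__)


@dataclass
class ExplainedMap:
    """Per-sample association of mutated genes to the deregulated genes they explain."""

    sample: str
    assoc: dict[str, set[str]] = field(default_factory=dict)
    #: one shortest qualifying path per (mutated, explained) pair, as a gene
    #: list starting at the mutated gene
    path_witness: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def explained_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.assoc.values():
            out |= genes
        return out


def _bfs_explained(
    network: GeneNetwork,
    source: str,
    dereg: set[str],
    L: int,
    D: int,
    exclude_hub_endpoints: bool,
) -> tuple[set[str], dict[tuple[str, str], list[str]]]:
    """Layered BFS from one mutated source over the deregulated subgraph.

    Traversal may only continue through deregulated nodes of degree <= D;
    deterministic lexicographic neighbor order fixes the witness paths.
    """
    graph = network.graph
    degree = graph.degree
    parent: dict[str, str] = {}
    visited = {source}
    frontier = [source]
    explained: set[str] = set()
    # a mutated gene that is itself deregulated is explained by the
    # zero-length path (e.g. an amplification driving its own transcript)
    if source in dereg and not (exclude_hub_endpoints and degree(source) > D):
        explained.add(source)
    depth = 0
    while frontier and depth < L:
        depth += 1
        nxt: list[str] = []
        for u in frontier:
            for v in sorted(graph.neighbors(u)):
                if v in visited or v not in dereg:
                    continue
                visited.add(v)
                parent[v] = u
                if not (exclude_hub_endpoints and degree(v) > D):
                    explained.add(v)
                # transit beyond v requires v to be a non-hub
                if degree(v) <= D:
                    nxt.append(v)
        frontier = nxt
    witnesses: dict[tuple[str, str], list[str]] = {}
    for g in explained:
        path = [g]
        while path[-1] != source:
            path.append(parent[path[-1]])
        witnesses[(source, g)] = path[::-1]
    return explained, witnesses


def explained_genes(
    network: GeneNetwork,
    profile: DeregulationProfile,
    mutated: set[str],
    params: ParameterSet,
    strict_length: bool = False,
    exclude_hub_endpoints: bool = False,
) -> ExplainedMap:
    """Compute the explained map of one sample.

    ``strict_length=True`` reads the path bound as < L edges instead of the
    default <= L.  Mutated genes absent from the network are skipped.
    """
    if params.L < 1 or params.D < 1:
        raise ValueError("L and D must be positive")
    L = params.L - 1 if strict_length else params.L
    dereg = profile.genes & network.nodes
    emap = ExplainedMap(sample=profile.sample)
    skipped = [m for m in mutated if m not in network]
    if skipped:
        logger.debug("sample %s: %d mutated gene(s) not in network", profile.sample, len(skipped))
    for m in sorted(mutated):
        if m not in network:
            continue
        expl, wit = _bfs_explained(network, m, dereg, L, params.D, exclude_hub_endpoints)
        if expl:
            emap.assoc[m] = expl
            for key, path in wit.items():
                if key[1] in expl:
                    emap.path_witness[key] = path
    return emap


def explained_frequency(maps: list[ExplainedMap]) -> dict[str, float]:
    """Fraction of cohort samples in which each gene is explained by >= 1 mutation."""
    if not maps:
        raise ValueError("at least one sample required")
    n = len(maps)
    counts: dict[str, int] = {}
    for emap in maps:
        for g in emap.explained_genes():
            counts[g] = counts.get(g, 0) + 1
    return {g: c / n for g, c in counts.items()}


def mean_pairwise_distance(network: GeneNetwork, genes: set[str]) -> float:
    """Mean shortest-path distance over all connected unordered pairs of ``genes``."""
    members = sorted(g for g in genes if g in network)
    if len(members) < 2:
        raise ValueError("need at least 2 genes present in the network")
    total = 0.0
    n_pairs = 0
    n_skipped = 0
    for i, a in enumerate(members):
        lengths = nx.single_source_shortest_path_length(network.graph, a)
        for b in members[i + 1 :]:
            if b in lengths:
                total += lengths[b]
                n_pairs += 1
            else:
                n_skipped += 1
    if n_skipped:
        logger.info("mean_pairwise_distance: skipped %d disconnected pair(s)", n_skipped)
    if n_pairs == 0:
        raise ValueError("all gene pairs are disconnected")
    return total / n_pairs


def association_table(maps: list[ExplainedMap]):
    """Long-format (sample, mutated_gene, explained_gene, path_length) table."""
    import pandas as pd

    rows = []
    for emap in maps:
        for m in sorted(emap.assoc):
            for g in sorted(emap.assoc[m]):
                rows.append((emap.sample, m, g, len(emap.path_witness[(m, g)]) - 1))
    return pd.DataFrame(rows, columns=["sample", "mutated_gene", "explained_gene", "path_length"])
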