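"""Seed-expansion identification of protein complexes over interval networks.

For each temporal-interval network (swept in ascending interval length),
unassigned nodes seed clusters in descending weighted-degree order.  A
cluster repeatedly admits the best admissible frontier node -- a node with
at least one r-reliable interval edge into the cluster for which the joint
colocalization, joint coexpression and expanding-cluster conditions all
hold -- until no frontier node qualifies.  Clusters from all intervals are
merged into a catalog with exact member-set deduplication and interval
provenance.

All ordering rules (seed order, frontier order, one admission per
iteration) exist to make the output deterministic; they are this
implementation's choices, not externally mandated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .config import RunConfig, Thresholds
from .conditions import (
    SemanticSimilarity,
    expanding_condition,
    expression_window,
    joint_coexpression,
    joint_localization,
)
from .dynnet import (
    ActivityMatrix,
    IntervalNetwork,
    NormalizedExpression,
    ScoredNetwork,
    build_temporal_series,
    collapse_cycles,
    compute_activity,
    iter_intervals_ascending,
    merge_interval_networks,
    normalize_expression,
)
from .io_formats import ComplexList, ExpressionTable, OntologyDag

logger = logging.getLogger(__name__)

__all__ = ["ProteinCluster", "ComplexCatalog", "identify_in_network", "run_icjointle"]


@dataclass(frozen=True)
class ProteinCluster:
    members: frozenset[str]
    seed: str
    interval: tuple[int, int]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ComplexCatalog:
    """Identified complexes with per-complex source-interval provenance."""

    members: list[frozenset[str]] = field(default_factory=list)
    provenance: list[tuple[tuple[int, int], ...]] = field(default_factory=list)
    n_raw: int = 0  # cluster count before deduplication

    def __post_init__(self) -> None:
        self._index: dict[frozenset[str], int] = {
            s: k for k, s in enumerate(self.members)
        }

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def merge(self, clusters: list[ProteinCluster], dedup: str = "exact") -> None:
        for cluster in clusters:
            self.n_raw += 1
            if dedup == "exact":
                k = self._index.get(cluster.members)
                if k is not None:
                    if cluster.interval not in self.provenance[k]:
                        self.provenance[k] = self.provenance[k] + (cluster.interval,)
                    continue
                self._index[cluster.members] = len(self.members)
            self.members.append(cluster.members)
            self.provenance.append((cluster.interval,))

    def to_complex_list(self) -> ComplexList:
        return ComplexList(list(self.members), list(self.provenance))


def identify_in_network(
    inet: IntervalNetwork,
    T: int,
    gep: NormalizedExpression,
    localization: Mapping[str, np.ndarray],
    sims: Mapping[str, SemanticSimilarity],
    thresholds: Thresholds,
    config: RunConfig = RunConfig(),
) -> list[ProteinCluster]:
    """Grow clusters in one interval network; see the module docstring."""
    window = expression_window(inet.t_low, inet.t_high, T)
    adjacency: dict[str, dict[str, int]] = {}
    for (i, j), s in inet.edges.items():
        adjacency.setdefault(i, {})[j] = s
        adjacency.setdefault(j, {})[i] = s
    # seed order: descending weighted degree, ties by ID
    seeds = sorted(
        adjacency, key=lambda n: (-sum(adjacency[n].values()), n)
    )
    assigned: set[str] = set()
    clusters: list[ProteinCluster] = []

    def admissible(pc: set[str], u: str) -> bool:
        tentative = pc | {u}
        jl = joint_localization(
            tentative, localization, strict=config.strict_localization
        )
        if not jl.holds:
            return False
        _, coexpressed = joint_coexpression(
            tentative, gep, window, thresholds.gamma,
            denominator=config.jq_denominator,
        )
        if not coexpressed:
            return False
        ec, _ = expanding_condition(pc, u, sims, thresholds, inet.score)
        return ec

    for seed in seeds:
        if seed in assigned:
            continue
        pc: set[str] = {seed}
        while True:
            frontier: dict[str, int] = {}
            for member in pc:
                for neighbor, s in adjacency[member].items():
                    if neighbor in pc or neighbor in assigned or s < thresholds.r:
                        continue
                    if s > frontier.get(neighbor, 0):
                        frontier[neighbor] = s
            admitted = None
            for u in sorted(frontier, key=lambda n: (-frontier[n], n)):
                if admissible(pc, u):
                    admitted = u
                    break
            if admitted is None:
                break
            pc.add(admitted)
        if len(pc) >= config.min_size:
            clusters.append(
                ProteinCluster(frozenset(pc), seed, (inet.t_low, inet.t_high))
            )
            assigned |= pc
    return clusters


def run_icjointle(
    network: ScoredNetwork,
    expression: ExpressionTable,
    localization: Mapping[str, np.ndarray],
    ontologies: Mapping[str, OntologyDag],
    annotations: Mapping[str, Mapping[str, frozenset[str]]],
    thresholds: Thresholds,
    config: RunConfig = RunConfig(),
    max_interval_length: int | None = None,
) -> ComplexCatalog:
    """Run the full pipeline: expression preprocessing, interval-network
    construction, per-interval identification and catalog assembly."""
    raw = collapse_cycles(expression, config.n_cycles)
    gep = normalize_expression(raw)
    act = compute_activity(gep, thresholds.phi)
    series = build_temporal_series(network, act)
    intervals = merge_interval_networks(series, max_interval_length)
    sims = {
        ont: SemanticSimilarity(dag, annotations.get(ont, {}))
        for ont, dag in ontologies.items()
    }
    catalog = ComplexCatalog()
    T = act.n_times
    for inet in iter_intervals_ascending(intervals):
        if not inet.edges:
            continue
        clusters = identify_in_network(
            inet, T, gep, localization, sims, thresholds, config
        )
        if clusters:
            logger.debug(
                "interval [%d, %d]: %d cluster(s)",
                inet.t_low, inet.t_high, len(clusters),
            )
        catalog.merge(clusters, dedup=config.dedup)
    logger.info(
        "identified %d complex(es) from %d raw cluster(s) across %d interval(s)",
        len(catalog), catalog.n_raw, len(intervals),
    )
    return catalog
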