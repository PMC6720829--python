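"""Construction of weighted static, temporal and temporal-interval networks.

The weighted static network carries integer reliability scores on the
1-999 scale.  Per-time-point temporal networks keep an edge only between
proteins active at that time point; temporal-interval networks intersect
the temporal networks over a closed interval, each surviving edge scored
by its minimum over the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .io_formats import ExpressionTable, InteractionRecord

__all__ = [
    "ScoredNetwork",
    "NormalizedExpression",
    "ActivityMatrix",
    "TemporalNetworkSeries",
    "IntervalNetwork",
    "weight_network",
    "collapse_cycles",
    "normalize_expression",
    "compute_activity",
    "build_temporal_series",
    "merge_interval_networks",
]

Edge = tuple[str, str]


def _canonical(i: str, j: str) -> Edge:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class ScoredNetwork:
    """Undirected protein graph with integer edge reliability scores.

    An edge exists iff its score is positive; absent pairs score 0.
    """

    nodes: tuple[str, ...]
    edges: dict[Edge, int]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (i, j), s in self.edges.items():
            if i >= j:
                raise ValueError(f"non-canonical edge ({i}, {j})")
            if i not in node_set or j not in node_set:
                raise ValueError(f"edge ({i}, {j}) references unknown node")
            if not 1 <= s <= 999:
                raise ValueError(f"edge ({i}, {j}) score {s} outside [1, 999]")

    def score(self, i: str, j: str) -> int:
        if i == j:
            return 0
        return self.edges.get(_canonical(i, j), 0)

    @property
    def adjacency(self) -> dict[str, dict[str, int]]:
        cached = self.__dict__.get("_adjacency")
        if cached is None:
            cached = {n: {} for n in self.nodes}
            for (i, j), s in self.edges.items():
                cached[i][j] = s
                cached[j][i] = s
            object.__setattr__(self, "_adjacency", cached)
        return cached

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class NormalizedExpression:
    """Per-gene expression patterns rescaled to [0, 1] per row.

    Degenerate (constant) genes are all-zero, hence inactive for any
    positive active threshold.
    """

    genes: tuple[str, ...]
    gep: np.ndarray  # (n_genes, T) in [0, 1]

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {g: k for k, g in enumerate(self.genes)})

    @property
    def n_times(self) -> int:
        return int(self.gep.shape[1])

    def vector(self, gene: str) -> np.ndarray | None:
        k = self._index.get(gene)
        return None if k is None else self.gep[k]


@dataclass(frozen=True)
class ActivityMatrix:
    """0/1 activity per gene and time point at threshold ``phi``."""

    genes: tuple[str, ...]
    active: np.ndarray  # (n_genes, T) bool
    phi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {g: k for k, g in enumerate(self.genes)})

    @property
    def n_times(self) -> int:
        return int(self.active.shape[1])

    def is_active(self, gene: str, t: int) -> bool:
        """Activity of ``gene`` at 1-based time ``t``; absentees are inactive."""
        k = self._index.get(gene)
        return bool(self.active[k, t - 1]) if k is not None else False


@dataclass(frozen=True)
class TemporalNetworkSeries:
    """Edge-score maps of the temporal networks at t = 1..T."""

    nodes: tuple[str, ...]
    maps: tuple[dict[Edge, int], ...]

    @property
    def n_times(self) -> int:
        return len(self.maps)


@dataclass(frozen=True)
class IntervalNetwork:
    """Edge scores of a temporal-interval network over [t_low, t_high]."""

    t_low: int
    t_high: int
    edges: dict[Edge, int]

    def __post_init__(self) -> None:
        if not 1 <= self.t_low <= self.t_high:
            raise ValueError("need 1 <= t_low <= t_high")

    @property
    def length(self) -> int:
        return self.t_high - self.t_low + 1

    def score(self, i: str, j: str) -> int:
        if i == j:
            return 0
        return self.edges.get(_canonical(i, j), 0)

    @property
    def present_nodes(self) -> tuple[str, ...]:
        seen: set[str] = set()
        for i, j in self.edges:
            seen.add(i)
            seen.add(j)
        return tuple(sorted(seen))


def weight_network(
    base_edges: Iterable[InteractionRecord | Edge],
    scored_edges: Iterable[InteractionRecord] = (),
    drop_unscored: bool = False,
) -> ScoredNetwork:
    """Weight a base edge set with reliability scores from a scored list.

    Base edges with a score in ``scored_edges`` take that score; base edges
    without one take weight 1 (or are dropped when ``drop_unscored``).
    Scored pairs absent from the base are ignored.
    """
    scores: dict[Edge, int] = {}
    for rec in scored_edges:
        if rec.score is not None:
            prev = scores.get(rec.pair, 0)
            scores[rec.pair] = max(prev, rec.score)
    edges: dict[Edge, int] = {}
    nodes: set[str] = set()
    for item in base_edges:
        if isinstance(item, InteractionRecord):
            pair = item.pair
            own = item.score
        else:
            i, j = item
            if i == j:
                continue
            pair = _canonical(i, j)
            own = None
        s = scores.get(pair, own)
        if s is None:
            if drop_unscored:
                continue
            s = 1
        edges[pair] = max(edges.get(pair, 0), s)
        nodes.update(pair)
    if not edges:
        raise ValueError("empty base edge set")
    return ScoredNetwork(tuple(sorted(nodes)), edges)


def collapse_cycles(raw: ExpressionTable, n_cycles: int) -> ExpressionTable:
    """Average a multi-cycle profile down to one cycle.

    With C cycles and ``T_raw`` columns, output time point i is the mean of
    input columns i, i+P, ..., i+(C-1)*P where P = T_raw / C.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if n_cycles == 1:
        return raw
    if raw.n_times % n_cycles != 0:
        raise ValueError(
            f"{raw.n_times} columns not divisible by {n_cycles} cycles"
        )
    period = raw.n_times // n_cycles
    stacked = raw.values.reshape(len(raw.genes), n_cycles, period)
    return ExpressionTable(raw.genes, stacked.mean(axis=1))


def normalize_expression(raw: ExpressionTable) -> NormalizedExpression:
    """Min-max rescale each gene's row to [0, 1]; constant rows become 0."""
    values = raw.values
    vmin = values.min(axis=1, keepdims=True)
    vmax = values.max(axis=1, keepdims=True)
    span = vmax - vmin
    with np.errstate(invalid="ignore", divide="ignore"):
        gep = np.where(span > 0, (values - vmin) / np.where(span > 0, span, 1.0), 0.0)
    return NormalizedExpression(raw.genes, gep)


def compute_activity(gep: NormalizedExpression, phi: float) -> ActivityMatrix:
    """Threshold normalized expression: active iff gep >= phi (inclusive)."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")
    return ActivityMatrix(gep.genes, gep.gep >= phi, phi)


def build_temporal_series(
    net: ScoredNetwork, act: ActivityMatrix
) -> TemporalNetworkSeries:
    """Restrict the static network to co-active endpoints per time point.

    Proteins without expression data are never active, so all their edges
    vanish at every time point.
    """
    T = act.n_times
    if T == 0:
        raise ValueError("activity matrix has no time points")
    index = {g: k for k, g in enumerate(act.genes)}
    # per-node activity row (None = absent from expression data)
    rows = {n: (act.active[index[n]] if n in index else None) for n in net.nodes}
    maps: list[dict[Edge, int]] = []
    for t in range(T):
        da: dict[Edge, int] = {}
        for edge, s in net.edges.items():
            ri, rj = rows[edge[0]], rows[edge[1]]
            if ri is not None and rj is not None and ri[t] and rj[t]:
                da[edge] = s
        maps.append(da)
    return TemporalNetworkSeries(net.nodes, tuple(maps))


def merge_interval_networks(
    series: TemporalNetworkSeries, max_length: int | None = None
) -> dict[tuple[int, int], IntervalNetwork]:
    """Build every temporal-interval network up to ``max_length``.

    Bottom-up recurrence in ascending interval length: the length-1 diagonal
    equals the temporal networks, and each longer interval is the key-wise
    intersection of its two sub-intervals with element-wise minimum scores.
    Returns T*(T+1)/2 networks (including the diagonal) when ``max_length``
    is None.
    """
    T = series.n_times
    if T < 1:
        raise ValueError("series has no time points")
    top = T if max_length is None else min(max_length, T)
    out: dict[tuple[int, int], IntervalNetwork] = {}
    prev_band: list[dict[Edge, int]] = [dict(m) for m in series.maps]
    for t in range(1, T + 1):
        out[(t, t)] = IntervalNetwork(t, t, prev_band[t - 1])
    for length in range(2, top + 1):
        band: list[dict[Edge, int]] = []
        for t_low in range(1, T - length + 2):
            left = prev_band[t_low - 1]   # [t_low, t_low+length-2]
            right = prev_band[t_low]      # [t_low+1, t_low+length-1]
            if len(right) < len(left):
                left, right = right, left
            merged = {
                e: min(s, right[e]) for e, s in left.items() if e in right
            }
            band.append(merged)
            out[(t_low, t_low + length - 1)] = IntervalNetwork(
                t_low, t_low + length - 1, merged
            )
        prev_band = band
    return out


def iter_intervals_ascending(
    intervals: Mapping[tuple[int, int], IntervalNetwork]
) -> Iterator[IntervalNetwork]:
    """Yield interval networks in ascending length, then ascending t_low."""
    for key in sorted(intervals, key=lambda k: (k[1] - k[0], k[0])):
        yield intervals[key]
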