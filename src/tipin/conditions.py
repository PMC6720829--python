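"""The three admission conditions for growing a protein cluster.

* joint colocalization: all members share at least one of the 22
  subcellular categories (AND of 0/1 localization vectors);
* joint coexpression: the windowed mean of the product of the members'
  normalized expression profiles reaches a threshold;
* expanding cluster: the candidate is semantically similar to every
  reliably-linked cluster member in at least two of the three GO
  ontologies (CC/MF/BP).

The GO similarity of two terms is ``exp(-c1*l) * tanh(c2*h) * tanh(c3*d)``
with c1=0.2, c2=0.3, c3=30, where ``l`` sums the shortest paths from the
maximum-information common ancestor (mica) to the two terms and ``h``/``d``
are the mica's depth and information content.  IC is the
descendant-annotation-frequency kind: ``-ln(n_term / n_corpus)`` with
``n_term`` counting proteins annotated to the term or any descendant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np

from .config import Thresholds
from .dynnet import NormalizedExpression
from .io_formats import N_LOCALIZATION_CATEGORIES, OntologyDag

__all__ = [
    "JointLocalization",
    "JointExpression",
    "TermInformation",
    "joint_localization",
    "expression_window",
    "joint_coexpression",
    "term_information",
    "SemanticSimilarity",
    "cluster_min_similarity",
    "expanding_condition",
]

DEFAULT_C1 = 0.2
DEFAULT_C2 = 0.3
DEFAULT_C3 = 30.0

ScoreFn = Callable[[str, str], int]


@dataclass(frozen=True)
class JointLocalization:
    jlv: np.ndarray  # 22-element 0/1 vector (AND over members)
    jc: int          # number of shared categories

    @property
    def holds(self) -> bool:
        """The joint colocalization condition: JC > 0."""
        return self.jc > 0


@dataclass(frozen=True)
class JointExpression:
    window: tuple[int, int]   # inclusive 1-based span
    profile: np.ndarray       # product profile over the window
    jq: float                 # windowed quantity


def joint_localization(
    ps: Iterable[str],
    localization: Mapping[str, np.ndarray],
    strict: bool = False,
) -> JointLocalization:
    """AND the members' localization vectors and count shared categories.

    Proteins absent from the table count as localized everywhere by
    default; ``strict=True`` treats them as localized nowhere.
    """
    members = list(ps)
    if not members:
        raise ValueError("empty protein set")
    jlv = np.ones(N_LOCALIZATION_CATEGORIES, dtype=np.uint8)
    absent_default = 0 if strict else 1
    for p in members:
        vec = localization.get(p)
        if vec is None:
            if absent_default == 0:
                jlv[:] = 0
        else:
            jlv &= vec.astype(np.uint8)
    return JointLocalization(jlv, int(jlv.sum()))


def expression_window(t_low: int, t_high: int, T: int) -> tuple[int, int]:
    """The coexpression window for interval [t_low, t_high]: two extra time
    points on each side, clipped at the horizon (l+4 points away from the
    boundaries)."""
    if not 1 <= t_low <= t_high <= T:
        raise ValueError(f"need 1 <= t_low <= t_high <= T, got ({t_low}, {t_high}, {T})")
    lo = 1 if t_low < 3 else t_low - 2
    hi = T if t_high > T - 2 else t_high + 2
    return lo, hi


def joint_coexpression(
    gs: Iterable[str],
    gep: NormalizedExpression,
    window: tuple[int, int],
    gamma: float,
    denominator: str = "window",
) -> tuple[JointExpression, bool]:
    """Product profile of the members over the window and its mean.

    ``denominator="window"`` averages over the window length (default);
    ``"T"`` divides the window sum by the full horizon instead, matching
    the un-windowed formula.  A gene with no expression vector makes the
    condition fail outright.
    """
    genes = list(gs)
    if not genes:
        raise ValueError("empty gene set")
    lo, hi = window
    if not 1 <= lo <= hi <= gep.n_times:
        raise ValueError(f"window {window} outside horizon T={gep.n_times}")
    profile = np.ones(hi - lo + 1, dtype=float)
    for g in genes:
        vec = gep.vector(g)
        if vec is None:
            je = JointExpression((lo, hi), np.zeros(hi - lo + 1), 0.0)
            return je, False
        profile = profile * vec[lo - 1 : hi]
    denom = (hi - lo + 1) if denominator == "window" else gep.n_times
    jq = float(profile.sum() / denom)
    return JointExpression((lo, hi), profile, jq), jq >= gamma


# ---------------------------------------------------------------------------
# GO-based functional similarity


@dataclass(frozen=True)
class TermInformation:
    """Per-term depth and information content for one ontology."""

    depth: dict[str, int]          # longest root-to-term path, in edges
    ic: dict[str, float]           # -ln(n_term / n_corpus); absent if n_term = 0
    n_corpus: int
    c1: float = DEFAULT_C1
    c2: float = DEFAULT_C2
    c3: float = DEFAULT_C3


def term_information(
    dag: OntologyDag,
    annotations: Mapping[str, frozenset[str]],
    c1: float = DEFAULT_C1,
    c2: float = DEFAULT_C2,
    c3: float = DEFAULT_C3,
) -> TermInformation:
    """Compute per-term depth and descendant-frequency information content.

    The corpus is every protein with at least one annotation in this
    ontology; a term's count includes proteins annotated to any descendant.
    Terms with zero count carry no IC and similarities involving them are 0.
    """
    depth: dict[str, int] = {}
    for term in dag.topo_order:
        parents = dag.parents[term]
        depth[term] = 0 if not parents else 1 + max(depth[p] for p in parents)

    annotated: dict[str, set[str]] = {t: set() for t in dag.parents}
    corpus: set[str] = set()
    for protein, terms in annotations.items():
        usable = [t for t in terms if t in dag.parents]
        if not usable:
            continue
        corpus.add(protein)
        for t in usable:
            annotated[t].add(protein)
    # propagate counts up the DAG (children before parents)
    for term in reversed(dag.topo_order):
        for parent in dag.parents[term]:
            annotated[parent] |= annotated[term]

    n_corpus = len(corpus)
    ic: dict[str, float] = {}
    for term, prots in annotated.items():
        if prots and n_corpus:
            ic[term] = -math.log(len(prots) / n_corpus)
    return TermInformation(depth, ic, n_corpus, c1, c2, c3)


def _similarity_from_mica(l: int, h: int, d: float, ti: TermInformation) -> float:
    return (
        math.exp(-ti.c1 * l) * math.tanh(ti.c2 * h) * math.tanh(ti.c3 * d)
    )


class SemanticSimilarity:
    """Cached term- and protein-level semantic similarity for one ontology."""

    def __init__(
        self,
        dag: OntologyDag,
        annotations: Mapping[str, frozenset[str]],
        c1: float = DEFAULT_C1,
        c2: float = DEFAULT_C2,
        c3: float = DEFAULT_C3,
    ) -> None:
        self.dag = dag
        self.annotations = {
            p: frozenset(t for t in ts if t in dag.parents)
            for p, ts in annotations.items()
        }
        self.info = term_information(dag, annotations, c1, c2, c3)
        # per term: {ancestor-or-self: shortest path length in edges}
        self._updist: dict[str, dict[str, int]] = {}
        for term in self.dag.topo_order:
            dist = {term: 0}
            for parent in self.dag.parents[term]:
                for anc, dd in self._updist[parent].items():
                    cand = dd + 1
                    if cand < dist.get(anc, cand + 1):
                        dist[anc] = cand
            self._updist[term] = dist
        self._term_cache: dict[tuple[str, str], float] = {}
        self._protein_cache: dict[tuple[str, str], float] = {}

    def term_similarity(self, go1: str, go2: str) -> float:
        """Similarity of two terms of this ontology; symmetric, in [0, 1)."""
        if go1 not in self.dag.parents or go2 not in self.dag.parents:
            raise KeyError(f"term not in {self.dag.ontology} DAG")
        key = (go1, go2) if go1 <= go2 else (go2, go1)
        cached = self._term_cache.get(key)
        if cached is not None:
            return cached
        value = self._term_similarity(go1, go2)
        self._term_cache[key] = value
        return value

    def _term_similarity(self, go1: str, go2: str) -> float:
        ic = self.info.ic
        if go1 not in ic or go2 not in ic:
            return 0.0  # zero-corpus term: IC undefined
        d1, d2 = self._updist[go1], self._updist[go2]
        common = d1.keys() & d2.keys()
        if not common:
            return 0.0
        # mica: maximal IC, ties broken by depth then ID for determinism
        mica = max(
            common,
            key=lambda t: (ic.get(t, -math.inf), self.info.depth[t], t),
        )
        if mica not in ic:
            return 0.0
        l = d1[mica] + d2[mica]
        return _similarity_from_mica(l, self.info.depth[mica], ic[mica], self.info)

    def termset_similarity(self, go: str, st: Iterable[str]) -> float:
        """Best similarity of ``go`` against a term set (0 if the set is empty)."""
        best = 0.0
        for other in st:
            s = self.term_similarity(go, other)
            if s > best:
                best = s
        return best

    def protein_similarity(self, p1: str, p2: str) -> float:
        """Average best-match similarity over both proteins' annotating sets.

        0 if either protein has no terms in this ontology; symmetric.
        """
        key = (p1, p2) if p1 <= p2 else (p2, p1)
        cached = self._protein_cache.get(key)
        if cached is not None:
            return cached
        st1 = self.annotations.get(p1, frozenset())
        st2 = self.annotations.get(p2, frozenset())
        if not st1 or not st2:
            value = 0.0
        else:
            total = sum(self.termset_similarity(g, st2) for g in st1)
            total += sum(self.termset_similarity(g, st1) for g in st2)
            value = total / (len(st1) + len(st2))
        self._protein_cache[key] = value
        return value


def cluster_min_similarity(
    pc: Iterable[str],
    u: str,
    sim: SemanticSimilarity,
    score: ScoreFn,
    r: int,
) -> float:
    """Minimum similarity of ``u`` to reliably-linked cluster members.

    Only members with an r-reliable link to ``u`` enter the minimum; if no
    member qualifies the value is 0 (the condition fails).
    """
    values = [
        sim.protein_similarity(u, v) for v in pc if v != u and score(u, v) >= r
    ]
    return min(values) if values else 0.0


def expanding_condition(
    pc: Iterable[str],
    u: str,
    sims: Mapping[str, SemanticSimilarity],
    thresholds: Thresholds,
    score: ScoreFn,
) -> tuple[bool, dict[str, bool]]:
    """The 2-of-3 admission rule on CC/MF/BP minimal similarities.

    Returns the overall verdict plus the per-ontology flags
    (CC >= sigma, MF >= omega, BP >= theta).
    """
    members = list(pc)
    flags: dict[str, bool] = {}
    for ont, threshold in (
        ("CC", thresholds.sigma),
        ("MF", thresholds.omega),
        ("BP", thresholds.theta),
    ):
        sim = sims.get(ont)
        if sim is None:
            flags[ont] = False
            continue
        value = cluster_min_similarity(members, u, sim, score, thresholds.r)
        flags[ont] = value >= threshold
    n_true = sum(flags.values())
    return n_true >= 2, flags
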