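"""Synthetic input bundles with planted ground-truth complexes.

The generator emits an internally consistent bundle -- scored network,
time-course expression, localization table, toy three-namespace ontology,
annotations and the planted complex list -- such that, at noise level 0,
every planted complex is recoverable by the identification pipeline on its
planted interval and nothing else is: within-complex edges score at or
above the recommended reliability threshold, background edges strictly
below it, planted members are active exactly on their interval, members
share a localization category and a complex-specific deep GO term in all
three ontologies, and background genes are expression-degenerate (hence
never active).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

from .config import RunConfig, Thresholds
from .conditions import (
    SemanticSimilarity,
    expression_window,
    joint_coexpression,
    joint_localization,
)
from .dynnet import ScoredNetwork, normalize_expression, weight_network
from .io_formats import (
    N_LOCALIZATION_CATEGORIES,
    ComplexList,
    ExpressionTable,
    InteractionRecord,
    OntologyDag,
    read_annotations,
    read_complexes,
    read_expression,
    read_localization,
    read_ontology,
    read_scored_interactions,
    write_annotations,
    write_complexes,
    write_expression,
    write_interactions,
    write_localization,
    write_ontology,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "write_bundle", "read_bundle"]

ONTOLOGIES = ("BP", "MF", "CC")


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_background: int = 30
    n_complexes: int = 10
    size_range: tuple[int, int] = (3, 5)
    T: int = 8
    interval_length_range: tuple[int, int] = (2, 4)
    complex_score_range: tuple[int, int] = (950, 999)
    background_density: float = 0.05
    background_score_range: tuple[int, int] = (1, 500)
    noise: float = 0.0
    loc_extra_prob: float = 0.2
    onto_depth: int = 5
    base_level: float = 1.0
    active_level: float = 10.0

    def __post_init__(self) -> None:
        if self.n_complexes < 0 or self.n_background < 0:
            raise ValueError("counts must be non-negative")
        if self.size_range[0] < 2 or self.size_range[0] > self.size_range[1]:
            raise ValueError("size_range must be (lo, hi) with 2 <= lo <= hi")
        if self.T < 2:
            raise ValueError("need T >= 2 (members must be inactive somewhere)")
        lo, hi = self.interval_length_range
        if not 1 <= lo <= hi:
            raise ValueError("bad interval_length_range")
        if not 1 <= self.complex_score_range[0] <= self.complex_score_range[1] <= 999:
            raise ValueError("complex scores must lie in [1, 999]")
        if not 1 <= self.background_score_range[0] <= self.background_score_range[1] <= 999:
            raise ValueError("background scores must lie in [1, 999]")
        if self.background_score_range[1] >= self.complex_score_range[0]:
            raise ValueError(
                "background scores must stay below the within-complex range "
                "(keeps background links below the reliability threshold)"
            )
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")
        if self.onto_depth < 1:
            raise ValueError("onto_depth must be >= 1")
        if self.active_level <= self.base_level:
            raise ValueError("active_level must exceed base_level")

    @property
    def recommended_thresholds(self) -> Thresholds:
        # similarity of a shared depth-D term with itself is
        # tanh(0.3 * D) * tanh(30 * d); leave 10% slack on the depth factor
        sim_floor = 0.9 * math.tanh(0.3 * self.onto_depth)
        return Thresholds(
            r=self.complex_score_range[0],
            sigma=round(sim_floor, 3),
            omega=round(sim_floor, 3),
            theta=round(sim_floor, 3),
            gamma=0.01,
            phi=0.5,
        )


@dataclass
class GroundTruth:
    spec: SyntheticSpec
    proteins: tuple[str, ...]
    complexes: list[frozenset[str]]
    intervals: list[tuple[int, int]]
    network: ScoredNetwork
    expression: ExpressionTable
    localization: dict[str, np.ndarray]
    ontologies: dict[str, OntologyDag]
    annotations: dict[str, dict[str, frozenset[str]]]
    thresholds: Thresholds

    def planted_complex_list(self) -> ComplexList:
        return ComplexList(list(self.complexes), [(iv,) for iv in self.intervals])


def generate(spec: SyntheticSpec) -> GroundTruth:
    """Generate a bundle; deterministic given ``spec.seed``.

    At noise level 0 the result is verified against the planted invariants
    (see :func:`verify_ground_truth`); violation is a bug, not noise.
    """
    rng = np.random.default_rng(spec.seed)

    sizes = [
        int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
        for _ in range(spec.n_complexes)
    ]
    n_proteins = sum(sizes) + spec.n_background
    if n_proteins < 2:
        raise ValueError("infeasible spec: fewer than two proteins")
    proteins = tuple(f"P{k:04d}" for k in range(1, n_proteins + 1))

    complexes: list[frozenset[str]] = []
    cursor = 0
    for size in sizes:
        complexes.append(frozenset(proteins[cursor : cursor + size]))
        cursor += size
    background = proteins[cursor:]
    member_of = {p: c for c, members in enumerate(complexes) for p in members}

    # planted intervals: never the whole horizon, so members have an
    # inactive time point and normalization keeps their profile non-degenerate
    max_len = min(spec.interval_length_range[1], spec.T - 1)
    min_len = min(spec.interval_length_range[0], max_len)
    intervals: list[tuple[int, int]] = []
    for _ in range(spec.n_complexes):
        length = int(rng.integers(min_len, max_len + 1))
        t_low = int(rng.integers(1, spec.T - length + 2))
        intervals.append((t_low, t_low + length - 1))

    # edges
    records: list[InteractionRecord] = []
    lo_c, hi_c = spec.complex_score_range
    for members in complexes:
        for a, b in combinations(sorted(members), 2):
            records.append(
                InteractionRecord(a, b, int(rng.integers(lo_c, hi_c + 1)))
            )
    lo_b, hi_b = spec.background_score_range
    for a, b in combinations(proteins, 2):
        if member_of.get(a) is not None and member_of.get(a) == member_of.get(b):
            continue
        if rng.random() < spec.background_density:
            records.append(
                InteractionRecord(a, b, int(rng.integers(lo_b, hi_b + 1)))
            )
    if not records:
        # degenerate but legal spec (no complexes, density 0): keep the
        # network non-empty so downstream constructors accept it
        records.append(InteractionRecord(proteins[0], proteins[1], lo_b))
    network = weight_network(records)

    # expression: members step up to active_level on their interval;
    # background genes are flat (degenerate -> never active)
    values = np.full((n_proteins, spec.T), spec.base_level, dtype=float)
    for c, members in enumerate(complexes):
        t_low, t_high = intervals[c]
        for p in members:
            values[proteins.index(p), t_low - 1 : t_high] = spec.active_level
    if spec.noise > 0:
        scale = spec.noise * (spec.active_level - spec.base_level)
        values = values + rng.normal(0.0, scale, size=values.shape)
    expression = ExpressionTable(proteins, values)

    # localization: one shared category per complex plus random extras
    localization: dict[str, np.ndarray] = {}
    for k, p in enumerate(proteins):
        vec = (rng.random(N_LOCALIZATION_CATEGORIES) < spec.loc_extra_prob).astype(
            np.uint8
        )
        localization[p] = vec
    for c, members in enumerate(complexes):
        shared = c % N_LOCALIZATION_CATEGORIES
        for p in members:
            localization[p][shared] = 1

    ontologies, annotations = _build_ontologies(spec, complexes, background)

    gt = GroundTruth(
        spec=spec,
        proteins=proteins,
        complexes=complexes,
        intervals=intervals,
        network=network,
        expression=expression,
        localization=localization,
        ontologies=ontologies,
        annotations=annotations,
        thresholds=spec.recommended_thresholds,
    )
    if spec.noise == 0:
        verify_ground_truth(gt)
    return gt


def _build_ontologies(spec, complexes, background):
    """One toy DAG per namespace: a root, a shallow generic term for
    background proteins, and a depth-``onto_depth`` chain per complex whose
    leaf annotates exactly that complex's members."""
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    ontologies: dict[str, OntologyDag] = {}
    annotations: dict[str, dict[str, frozenset[str]]] = {}
    for ont in ONTOLOGIES:
        root = next_id()
        generic = next_id()
        parents: dict[str, set[str]] = {root: set(), generic: {root}}
        names = {root: f"{ont} root", generic: f"{ont} generic"}
        protein_terms: dict[str, frozenset[str]] = {}
        for c, members in enumerate(complexes):
            parent = root
            term = parent
            for level in range(spec.onto_depth):
                term = next_id()
                parents[term] = {parent}
                names[term] = f"{ont} complex {c} level {level + 1}"
                parent = term
            for p in members:
                protein_terms[p] = frozenset({term})
        for p in background:
            protein_terms[p] = frozenset({generic})
        ontologies[ont] = OntologyDag(ont, parents, names)
        annotations[ont] = protein_terms
    return ontologies, annotations


def verify_ground_truth(gt: GroundTruth, config: RunConfig = RunConfig()) -> None:
    """Post-check the planted invariants; raises ``ValueError`` on failure."""
    th = gt.thresholds
    gep = normalize_expression(gt.expression)
    sims = {
        ont: SemanticSimilarity(dag, gt.annotations[ont])
        for ont, dag in gt.ontologies.items()
    }
    # background edges must not reach the reliability threshold
    member_of = {p: c for c, members in enumerate(gt.complexes) for p in members}
    for (a, b), s in gt.network.edges.items():
        same = member_of.get(a) is not None and member_of.get(a) == member_of.get(b)
        if not same and s >= th.r:
            raise ValueError(f"background edge ({a}, {b}) reaches r={th.r}")
    for c, members in enumerate(gt.complexes):
        jl = joint_localization(members, gt.localization,
                                strict=config.strict_localization)
        if not jl.holds:
            raise ValueError(f"planted complex {c} is not jointly colocalized")
        window = expression_window(*gt.intervals[c], gt.expression.n_times)
        _, ok = joint_coexpression(members, gep, window, th.gamma,
                                   denominator=config.jq_denominator)
        if not ok:
            raise ValueError(f"planted complex {c} fails joint coexpression")
        for a, b in combinations(sorted(members), 2):
            n_similar = sum(
                sims[ont].protein_similarity(a, b) >= threshold
                for ont, threshold in (
                    ("CC", th.sigma), ("MF", th.omega), ("BP", th.theta),
                )
            )
            if n_similar < 2:
                raise ValueError(
                    f"planted pair ({a}, {b}) similar in only {n_similar} ontology(ies)"
                )


def write_bundle(gt: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write every bundle piece via the io_formats writers plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "expression": out / "expression.tsv",
        "localization": out / "localization.tsv",
        "ontology": out / "ontology.obo",
        "annotations": out / "annotations.gaf",
        "complexes": out / "complexes.txt",
        "manifest": out / "manifest.yaml",
    }
    write_interactions(sorted(
        InteractionRecord(a, b, s) for (a, b), s in gt.network.edges.items()
    ), paths["network"])
    write_expression(gt.expression, paths["expression"])
    write_localization(gt.localization, paths["localization"])
    write_ontology(gt.ontologies, paths["ontology"])
    write_annotations(gt.annotations, paths["annotations"])
    write_complexes(gt.planted_complex_list(), paths["complexes"])
    manifest = {
        "generator": "tipin.synthetic",
        "rng": "numpy.random.default_rng (PCG64)",
        "spec": asdict(gt.spec),
        "thresholds": asdict(gt.thresholds),
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def read_bundle(bundle_dir: str | Path) -> dict:
    """Re-read a written bundle into in-memory types (round-trip support)."""
    d = Path(bundle_dir)
    records = read_scored_interactions(d / "network.tsv")
    ontologies = read_ontology(d / "ontology.obo")
    with open(d / "manifest.yaml", "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    return {
        "network": weight_network(records),
        "expression": read_expression(d / "expression.tsv"),
        "localization": read_localization(d / "localization.tsv"),
        "ontologies": ontologies,
        "annotations": read_annotations(d / "annotations.gaf", ontologies),
        "complexes": read_complexes(d / "complexes.txt"),
        "manifest": manifest,
        "thresholds": Thresholds(**manifest["thresholds"]),
    }
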