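"""Readers and writers for every external file format the pipeline touches.

All other modules consume the in-memory types defined here; no other module
opens files.  Formats are deliberately plain text: whitespace-delimited edge
lists and matrices, a CYC2008-style complex list, OBO 1.2 ontologies and
GAF 2.x annotation tables.

Parsing is strict: malformed input raises :class:`FormatError` naming the
offending line, and recoverable irregularities (self-loops, singleton
complexes, annotations to unknown terms) are dropped with a logged count.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "InteractionRecord",
    "ExpressionTable",
    "ComplexList",
    "OntologyDag",
    "LOCALIZATION_CATEGORIES",
    "read_scored_interactions",
    "read_unscored_interactions",
    "write_interactions",
    "read_expression",
    "write_expression",
    "read_localization",
    "write_localization",
    "read_complexes",
    "write_complexes",
    "read_ontology",
    "write_ontology",
    "read_annotations",
    "write_annotations",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


#: The 22 yeast subcellular localization categories, in canonical order.
#: Index i of a localization vector refers to ``LOCALIZATION_CATEGORIES[i]``.
LOCALIZATION_CATEGORIES: tuple[str, ...] = (
    "mitochondrion",
    "vacuole",
    "spindle pole",
    "cell periphery",
    "punctate composite",
    "vacuolar membrane",
    "ER",
    "nuclear periphery",
    "endosome",
    "bud neck",
    "microtubule",
    "Golgi",
    "late Golgi",
    "peroxisome",
    "actin",
    "nucleolus",
    "cytoplasm",
    "ER to Golgi",
    "early Golgi",
    "lipid particle",
    "nucleus",
    "bud",
)

N_LOCALIZATION_CATEGORIES = len(LOCALIZATION_CATEGORIES)

SCORE_MIN = 1
SCORE_MAX = 999

# GAF aspect letter -> ontology key used throughout the package.
_ASPECT_TO_ONTOLOGY = {"P": "BP", "F": "MF", "C": "CC"}
_ONTOLOGY_TO_ASPECT = {v: k for k, v in _ASPECT_TO_ONTOLOGY.items()}
_NAMESPACE_TO_ONTOLOGY = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
_ONTOLOGY_TO_NAMESPACE = {v: k for k, v in _NAMESPACE_TO_ONTOLOGY.items()}


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """A canonicalized undirected interaction, optionally scored.

    ``protein_a < protein_b`` lexicographically; ``score`` is an integer in
    [1, 999] or ``None`` for unscored pair lists.
    """

    protein_a: str
    protein_b: str
    score: int | None = None

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction: {self.protein_a}")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class ExpressionTable:
    """Raw gene expression, genes x time points."""

    genes: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_times), float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.genes) != values.shape[0]:
            raise ValueError("gene list and value matrix disagree on row count")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene IDs")
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("non-finite expression values")

    @property
    def n_times(self) -> int:
        return int(self.values.shape[1])

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]


@dataclass
class ComplexList:
    """An ordered collection of protein sets, optionally with provenance.

    ``provenance[k]`` is a tuple of ``(t_low, t_high)`` source intervals for
    ``members[k]`` (empty when unknown).
    """

    members: list[frozenset[str]] = field(default_factory=list)
    provenance: list[tuple[tuple[int, int], ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [() for _ in self.members]
        if len(self.provenance) != len(self.members):
            raise ValueError("provenance length mismatch")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


class OntologyDag:
    """A single-namespace GO DAG: terms with ``is_a`` parents.

    Construction validates acyclicity and exposes the derived structures
    similarity computations need: children, roots and a topological order
    (roots first).
    """

    def __init__(
        self,
        ontology: str,
        parents: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
    ) -> None:
        if not parents:
            raise FormatError(f"empty ontology: {ontology}")
        self.ontology = ontology
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(p) for t, p in parents.items()
        }
        # parents referenced but not declared are an input error
        for term, ps in self.parents.items():
            missing = ps - self.parents.keys()
            if missing:
                raise FormatError(
                    f"term {term} has undeclared parent(s): {sorted(missing)}"
                )
        self.names: dict[str, str] = dict(names or {})
        self.children: dict[str, set[str]] = {t: set() for t in self.parents}
        for term, ps in self.parents.items():
            for p in ps:
                self.children[p].add(term)
        self.roots: tuple[str, ...] = tuple(
            sorted(t for t, ps in self.parents.items() if not ps)
        )
        self.topo_order: tuple[str, ...] = self._toposort()

    def _toposort(self) -> tuple[str, ...]:
        # Kahn's algorithm from the roots; leftovers mean a cycle.
        n_pending = {t: len(ps) for t, ps in self.parents.items()}
        frontier = sorted(t for t, n in n_pending.items() if n == 0)
        order: list[str] = []
        while frontier:
            term = frontier.pop()
            order.append(term)
            for child in sorted(self.children[term]):
                n_pending[child] -= 1
                if n_pending[child] == 0:
                    frontier.append(child)
        if len(order) != len(self.parents):
            cyclic = sorted(t for t, n in n_pending.items() if n > 0)
            raise FormatError(f"cycle in ontology {self.ontology}: {cyclic[:5]}")
        return tuple(order)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def __len__(self) -> int:
        return len(self.parents)


# ---------------------------------------------------------------------------
# line-level helpers


def _data_lines(path: str | Path):
    """Yield (line_number, stripped_line) skipping blanks and '#' comments."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _parse_interaction_lines(path, scored: bool, score_range):
    lo, hi = score_range
    best: dict[tuple[str, str], int | None] = OrderedDict()
    n_self = 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2 or (scored and len(tokens) > 3) or (not scored and len(tokens) > 2):
            raise FormatError(f"{path}:{lineno}: malformed interaction line: {line!r}")
        a, b = tokens[0], tokens[1]
        score: int | None = None
        if scored and len(tokens) == 3:
            try:
                score = int(tokens[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer score {tokens[2]!r}"
                ) from exc
            if not lo <= score <= hi:
                raise FormatError(
                    f"{path}:{lineno}: score {score} outside [{lo}, {hi}]"
                )
        if a == b:
            n_self += 1
            continue
        pair = (a, b) if a < b else (b, a)
        prev = best.get(pair, _ABSENT)
        if prev is _ABSENT:
            best[pair] = score
        else:
            # duplicate policy: keep the maximum score; a scored duplicate
            # beats an unscored one
            if prev is None:
                best[pair] = score if score is not None else None
            elif score is not None and score > prev:
                best[pair] = score
    if n_self:
        logger.info("%s: dropped %d self-interaction(s)", path, n_self)
    return [InteractionRecord(a, b, s) for (a, b), s in sorted(best.items())]


_ABSENT = object()


def read_scored_interactions(
    path: str | Path, score_range: tuple[int, int] = (SCORE_MIN, SCORE_MAX)
) -> list[InteractionRecord]:
    """Read a 2/3-column edge list with optional integer reliability scores.

    Pairs are canonicalized (sorted endpoints), duplicates resolved by
    keeping the maximum score, and self-pairs dropped with a logged count.
    Output is sorted by pair, so it is independent of input line order.
    """
    return _parse_interaction_lines(path, scored=True, score_range=score_range)


def read_unscored_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read a 2-column pair list (BioGrid/DIP style, no scores)."""
    return _parse_interaction_lines(path, scored=False, score_range=(SCORE_MIN, SCORE_MAX))


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if rec.score is None:
                fh.write(f"{rec.protein_a}\t{rec.protein_b}\n")
            else:
                fh.write(f"{rec.protein_a}\t{rec.protein_b}\t{rec.score}\n")


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a gene x time-point expression matrix.

    First column is the gene ID, remaining columns are numeric.  An optional
    header line (all value fields non-numeric) is tolerated and skipped.
    Ragged rows, non-numeric cells and duplicate gene IDs are errors.
    """
    genes: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    n_cols: int | None = None
    first = True
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise FormatError(f"{path}:{lineno}: expected gene ID plus values")
        gene, cells = tokens[0], tokens[1:]
        if first:
            first = False
            if all(not _is_number(c) for c in cells):
                continue  # header line
        try:
            values = [float(c) for c in cells]
        except ValueError:
            bad = next(c for c in cells if not _is_number(c))
            raise FormatError(f"{path}:{lineno}: non-numeric cell {bad!r}") from None
        if n_cols is None:
            n_cols = len(values)
        elif len(values) != n_cols:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(values)} columns, expected {n_cols})"
            )
        if gene in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene!r}")
        seen.add(gene)
        genes.append(gene)
        rows.append(values)
    if not genes:
        raise FormatError(f"{path}: no genes")
    return ExpressionTable(tuple(genes), np.array(rows, dtype=float))


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene, row in zip(table.genes, table.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_localization(
    path: str | Path,
    categories: Sequence[str] = LOCALIZATION_CATEGORIES,
) -> dict[str, np.ndarray]:
    """Read a protein -> subcellular-category table into 0/1 vectors.

    Each row is a protein ID followed by category names.  Tab-delimited rows
    may carry category names containing spaces; in whitespace-delimited rows
    underscores stand in for spaces (``spindle_pole``).  A protein listed on
    several rows gets the union (OR) of its vectors.  Unknown categories are
    a hard error naming the offending token.
    """
    index = {name: i for i, name in enumerate(categories)}
    table: dict[str, np.ndarray] = {}
    for lineno, line in _data_lines(path):
        if "\t" in line:
            tokens = [t.strip() for t in line.split("\t") if t.strip()]
        else:
            tokens = line.split()
        if not tokens:
            continue
        protein, cats = tokens[0], tokens[1:]
        vec = table.setdefault(protein, np.zeros(len(categories), dtype=np.uint8))
        for cat in cats:
            name = cat.replace("_", " ")
            if name not in index:
                raise FormatError(
                    f"{path}:{lineno}: unknown localization category {cat!r}"
                )
            vec[index[name]] = 1
    return table


def write_localization(
    table: Mapping[str, np.ndarray],
    path: str | Path,
    categories: Sequence[str] = LOCALIZATION_CATEGORIES,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for protein in sorted(table):
            vec = table[protein]
            names = [categories[i].replace(" ", "_") for i in np.flatnonzero(vec)]
            fh.write("\t".join([protein] + names) + "\n")


def read_complexes(path: str | Path, dedupe: bool = False) -> ComplexList:
    """Read a one-complex-per-line, whitespace-separated protein list.

    Lines starting with ``# interval=`` immediately before a complex carry
    its source-interval provenance.  Singleton lines are dropped with a
    warning.  ``dedupe=True`` enforces the catalog invariant (first
    occurrence wins, provenance merged).
    """
    members: list[frozenset[str]] = []
    provenance: list[tuple[tuple[int, int], ...]] = []
    pending: tuple[tuple[int, int], ...] = ()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("interval="):
                    pending = _parse_intervals(body[len("interval="):], path, lineno)
                continue
            proteins = frozenset(line.split())
            if len(proteins) < 2:
                logger.warning("%s:%d: dropped singleton complex line", path, lineno)
                pending = ()
                continue
            members.append(proteins)
            provenance.append(pending)
            pending = ()
    result = ComplexList(members, provenance)
    if dedupe:
        result = _dedupe_complexes(result)
    return result


def _parse_intervals(text: str, path, lineno) -> tuple[tuple[int, int], ...]:
    out = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            lo, hi = chunk.split("-")
            out.append((int(lo), int(hi)))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad interval {chunk!r}") from exc
    return tuple(out)


def _dedupe_complexes(cl: ComplexList) -> ComplexList:
    seen: dict[frozenset[str], int] = {}
    members: list[frozenset[str]] = []
    provenance: list[tuple[tuple[int, int], ...]] = []
    for s, prov in zip(cl.members, cl.provenance):
        if s in seen:
            provenance[seen[s]] = provenance[seen[s]] + prov
        else:
            seen[s] = len(members)
            members.append(s)
            provenance.append(prov)
    return ComplexList(members, provenance)


def write_complexes(complexes: ComplexList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s, prov in zip(complexes.members, complexes.provenance):
            if prov:
                fh.write(
                    "# interval=" + ",".join(f"{lo}-{hi}" for lo, hi in prov) + "\n"
                )
            fh.write(" ".join(sorted(s)) + "\n")


# ---------------------------------------------------------------------------
# OBO / GAF


def read_ontology(path: str | Path) -> dict[str, OntologyDag]:
    """Parse an OBO 1.2 file into one DAG per GO namespace (BP/MF/CC).

    Obsolete terms are excluded; ``is_a`` edges crossing namespaces or
    pointing at unknown terms are dropped with a logged count; each
    namespace graph is verified acyclic.
    """
    terms: dict[str, dict] = {}
    current: dict | None = None
    in_term = False
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                if current is not None and current["id"]:
                    terms[current["id"]] = current
                in_term = line == "[Term]"
                current = {"id": None, "name": "", "namespace": None,
                           "is_a": [], "obsolete": False} if in_term else None
                continue
            if not in_term or not line or ":" not in line:
                continue
            key, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            key = key.strip()
            if key == "id":
                current["id"] = value
            elif key == "name":
                current["name"] = value
            elif key == "namespace":
                current["namespace"] = value
            elif key == "is_a":
                current["is_a"].append(value)
            elif key == "is_obsolete" and value.lower() == "true":
                current["obsolete"] = True
    if current is not None and current["id"]:
        terms[current["id"]] = current

    live = {tid: t for tid, t in terms.items() if not t["obsolete"] and t["id"]}
    if not live:
        raise FormatError(f"{path}: empty ontology")
    by_ns: dict[str, dict[str, set[str]]] = {}
    names: dict[str, dict[str, str]] = {}
    n_dropped_edges = 0
    for tid, t in live.items():
        ns = t["namespace"]
        ont = _NAMESPACE_TO_ONTOLOGY.get(ns, ns or "unknown")
        by_ns.setdefault(ont, {})[tid] = set()
        names.setdefault(ont, {})[tid] = t["name"]
    for tid, t in live.items():
        ns = t["namespace"]
        ont = _NAMESPACE_TO_ONTOLOGY.get(ns, ns or "unknown")
        for parent in t["is_a"]:
            if parent in by_ns[ont]:
                by_ns[ont][tid].add(parent)
            else:
                n_dropped_edges += 1
    if n_dropped_edges:
        logger.info("%s: dropped %d cross-namespace/unknown is_a edge(s)",
                    path, n_dropped_edges)
    return {
        ont: OntologyDag(ont, parents, names[ont]) for ont, parents in by_ns.items()
    }


def write_ontology(dags: Mapping[str, OntologyDag], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for ont in sorted(dags):
            dag = dags[ont]
            namespace = _ONTOLOGY_TO_NAMESPACE.get(ont, ont)
            for term in dag.topo_order:
                fh.write("\n[Term]\n")
                fh.write(f"id: {term}\n")
                fh.write(f"name: {dag.names.get(term, term)}\n")
                fh.write(f"namespace: {namespace}\n")
                for parent in sorted(dag.parents[term]):
                    fh.write(f"is_a: {parent}\n")


def read_annotations(
    path: str | Path,
    dags: Mapping[str, OntologyDag],
    exclude_evidence: Iterable[str] = (),
) -> dict[str, dict[str, frozenset[str]]]:
    """Parse a GAF 2.x table into per-ontology protein -> term sets.

    Rows whose GO term is absent from the given DAGs (unknown or obsolete)
    are dropped with a logged count, as are NOT-qualified rows and rows
    whose evidence code is in ``exclude_evidence``.
    """
    excluded = set(exclude_evidence)
    out: dict[str, dict[str, set[str]]] = {ont: {} for ont in ("BP", "MF", "CC")}
    n_dropped = 0
    for lineno, line in _data_lines_gaf(path):
        cols = line.split("\t")
        if len(cols) < 9:
            raise FormatError(f"{path}:{lineno}: GAF row has {len(cols)} columns")
        protein = cols[1].strip()
        qualifier = cols[3].strip()
        go_id = cols[4].strip()
        evidence = cols[6].strip()
        aspect = cols[8].strip()
        if aspect not in _ASPECT_TO_ONTOLOGY:
            raise FormatError(f"{path}:{lineno}: unknown aspect {aspect!r}")
        if "NOT" in qualifier.split("|"):
            continue
        if evidence in excluded:
            continue
        ont = _ASPECT_TO_ONTOLOGY[aspect]
        dag = dags.get(ont)
        if dag is None or go_id not in dag:
            n_dropped += 1
            continue
        out[ont].setdefault(protein, set()).add(go_id)
    if n_dropped:
        logger.info("%s: dropped %d annotation(s) to unknown/obsolete terms",
                    path, n_dropped)
    return {
        ont: {p: frozenset(ts) for p, ts in prots.items()}
        for ont, prots in out.items()
    }


def _data_lines_gaf(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            yield lineno, line


def write_annotations(
    annotations: Mapping[str, Mapping[str, frozenset[str]]],
    path: str | Path,
    db: str = "TIPIN",
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n")
        for ont in sorted(annotations):
            aspect = _ONTOLOGY_TO_ASPECT[ont]
            for protein in sorted(annotations[ont]):
                for term in sorted(annotations[ont][protein]):
                    cols = [
                        db, protein, protein, "", term, f"{db}:ref", "IEA",
                        "", aspect, "", "", "protein", "taxon:4932",
                        "20190821", db,
                    ]
                    fh.write("\t".join(cols) + "\n")
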