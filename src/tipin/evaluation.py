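"""Matching metrics and enrichment analysis for predicted complex catalogs.

Matching metrics compare an identified catalog IC against a reference
catalog KC through the overlap score ``OS = |intersection|^2 / (|ic|*|kc|)``:
precision/recall/f-measure at an overlap threshold, the fraction of matched
references (Frac), the maximum matching ratio (MMR), the clustering-wise
sensitivity/PPV/accuracy, the composite ``FAM = Frac + Acc + MMR``, and the
exact-match count #PM (OS = 1).  Enrichment uses the upper hypergeometric
tail per GO term, a complex being significant when any term's p-value
drops below the level psi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

__all__ = [
    "MatchReport",
    "EnrichmentSummary",
    "overlap_score",
    "match_report",
    "fam_score",
    "relative_geometric_mean",
    "enrichment_pvalue",
    "overexpression_score",
]


def overlap_score(ic: frozenset[str] | set[str], kc: frozenset[str] | set[str]) -> float:
    """``|ic & kc|^2 / (|ic| * |kc|)``; 1 iff the sets are identical."""
    if not ic or not kc:
        raise ValueError("overlap score of an empty set is undefined")
    inter = len(set(ic) & set(kc))
    return inter * inter / (len(ic) * len(kc))


@dataclass(frozen=True)
class MatchReport:
    lam: float
    n_identified: int
    n_known: int
    mic: int
    mkc: int
    n_pm: int
    prec: float
    rec: float
    fm: float
    frac: float
    mmr: float
    mmr_one_to_one: float
    sn: float
    ppv: float
    acc: float
    fam: float
    overlap_counts: np.ndarray  # t_ij, known x identified
    known_sizes: np.ndarray

    @property
    def pm_times_fam(self) -> float:
        return self.n_pm * self.fam


def match_report(
    ic: Sequence[frozenset[str] | set[str]],
    kc: Sequence[frozenset[str] | set[str]],
    lam: float = 0.2,
    mmr_mode: str = "per_known_best",
) -> MatchReport:
    """Compute the full metric suite of IC against KC.

    ``mmr_mode`` selects which MMR populates the report's ``mmr`` field:
    ``"per_known_best"`` (mean over known complexes of the best overlap
    score, the default) or ``"matching"`` (maximum-weight one-to-one
    matching).  Both values are always computed and carried in the report.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"lambda must be in (0, 1], got {lam}")
    if not ic or not kc:
        raise ValueError("both catalogs must be non-empty")
    if mmr_mode not in ("per_known_best", "matching"):
        raise ValueError(f"unknown mmr_mode {mmr_mode!r}")
    ics = [frozenset(c) for c in ic]
    kcs = [frozenset(c) for c in kc]
    n, m = len(kcs), len(ics)
    os_matrix = np.zeros((n, m))
    t = np.zeros((n, m), dtype=np.int64)
    for i, known in enumerate(kcs):
        for j, pred in enumerate(ics):
            inter = len(known & pred)
            t[i, j] = inter
            os_matrix[i, j] = inter * inter / (len(known) * len(pred))

    matched_ic = os_matrix.max(axis=0) >= lam
    matched_kc = os_matrix.max(axis=1) >= lam
    mic = int(matched_ic.sum())
    mkc = int(matched_kc.sum())
    prec = mic / m
    rec = mkc / n
    fm = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    frac = rec

    mmr_best = float(os_matrix.max(axis=1).mean())
    row, col = linear_sum_assignment(os_matrix, maximize=True)
    mmr_matched = float(os_matrix[row, col].sum() / n)
    mmr = mmr_best if mmr_mode == "per_known_best" else mmr_matched

    known_sizes = np.array([len(c) for c in kcs], dtype=np.int64)
    sn = float(t.max(axis=1).sum() / known_sizes.sum())
    t_total = int(t.sum())
    ppv = 0.0 if t_total == 0 else float(t.max(axis=0).sum() / t_total)
    acc = math.sqrt(sn * ppv)

    n_pm = sum(1 for pred in ics if any(pred == known for known in kcs))
    fam = fam_score(frac, acc, mmr)
    return MatchReport(
        lam=lam, n_identified=m, n_known=n, mic=mic, mkc=mkc, n_pm=n_pm,
        prec=prec, rec=rec, fm=fm, frac=frac,
        mmr=mmr, mmr_one_to_one=mmr_matched,
        sn=sn, ppv=ppv, acc=acc, fam=fam,
        overlap_counts=t, known_sizes=known_sizes,
    )


def fam_score(frac: float, acc: float, mmr: float) -> float:
    """The comprehensive matching score: Frac + Acc + MMR."""
    return frac + acc + mmr


def relative_geometric_mean(pm1: float, fam1: float, pm2: float, fam2: float) -> float:
    """Geometric mean of the relative #PM and FAM performances:
    ``sqrt((pm1*fam1) / (pm2*fam2))``."""
    if pm2 * fam2 <= 0:
        raise ValueError("reference #PM * FAM must be positive")
    return math.sqrt((pm1 * fam1) / (pm2 * fam2))


def enrichment_pvalue(N: int, K: int, n_s: int, k_s: int) -> float:
    """Upper hypergeometric tail: P(X >= k_s) drawing n_s from N with K marked."""
    if not (0 <= K <= N and 0 <= n_s <= N and 0 <= k_s <= min(K, n_s)):
        raise ValueError(
            f"impossible configuration N={N}, K={K}, n_s={n_s}, k_s={k_s}"
        )
    if k_s == 0:
        return 1.0
    return float(hypergeom.sf(k_s - 1, N, K, n_s))


@dataclass(frozen=True)
class EnrichmentSummary:
    n_complexes: int
    n_significant: int
    psi: float
    score: float                  # n_significant / n_complexes
    p_values: tuple[float, ...]   # per-complex minimum over tested terms


def overexpression_score(
    complexes: Sequence[frozenset[str] | set[str]],
    annotations: Mapping[str, frozenset[str]],
    background: Iterable[str],
    psi: float = 0.01,
) -> EnrichmentSummary:
    """Fraction of complexes significantly enriched for some annotated term.

    ``annotations`` maps protein -> term set (one ontology); ``background``
    is the protein universe of the evaluated network.  A complex's p-value
    is the minimum over the terms annotating its members (no multiple-
    testing correction); it is significant when that p-value is < psi.
    """
    if not complexes:
        raise ValueError("empty catalog")
    universe = set(background)
    N = len(universe)
    term_members: dict[str, set[str]] = {}
    for protein, terms in annotations.items():
        if protein not in universe:
            continue
        for term in terms:
            term_members.setdefault(term, set()).add(protein)

    p_values: list[float] = []
    n_significant = 0
    for complex_ in complexes:
        members = set(complex_) & universe
        n_s = len(members)
        best = 1.0
        if n_s:
            tested: set[str] = set()
            for protein in members:
                tested |= annotations.get(protein, frozenset())
            for term in tested:
                marked = term_members.get(term, set())
                K = len(marked)
                k_s = len(members & marked)
                p = enrichment_pvalue(N, K, n_s, k_s)
                if p < best:
                    best = p
        p_values.append(best)
        if best < psi:
            n_significant += 1
    return EnrichmentSummary(
        n_complexes=len(complexes),
        n_significant=n_significant,
        psi=psi,
        score=n_significant / len(complexes),
        p_values=tuple(p_values),
    )
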