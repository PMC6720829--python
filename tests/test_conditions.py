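import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tipin.config import Thresholds
from tipin.conditions import (
    SemanticSimilarity,
    _similarity_from_mica,
    cluster_min_similarity,
    expanding_condition,
    expression_window,
    joint_coexpression,
    joint_localization,
    term_information,
)
from tipin.dynnet import NormalizedExpression
from tipin.io_formats import OntologyDag


def vec(*ones):
    v = np.zeros(22, dtype=np.uint8)
    for i in ones:
        v[i] = 1
    return v


class TestJointLocalization:
    def test_hand_and(self):
        loc = {"P1": vec(0, 1), "P2": vec(0)}
        jl = joint_localization(["P1", "P2"], loc)
        assert jl.jc == 1 and jl.jlv[0] == 1 and jl.jlv[1] == 0

    def test_singleton_identity(self):
        loc = {"P1": vec(2, 5, 7)}
        jl = joint_localization(["P1"], loc)
        np.testing.assert_array_equal(jl.jlv, loc["P1"])

    def test_disjoint_fails(self):
        loc = {"P1": vec(0), "P2": vec(1)}
        assert not joint_localization(["P1", "P2"], loc).holds

    def test_missing_protein_default_everywhere(self):
        loc = {"P1": vec(3)}
        assert joint_localization(["P1", "P_absent"], loc).jc == 1

    def test_missing_protein_strict(self):
        loc = {"P1": vec(3)}
        assert joint_localization(["P1", "P_absent"], loc, strict=True).jc == 0

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            joint_localization([], {})

    @given(st.integers(0, 21), st.lists(st.integers(0, 21), max_size=8))
    def test_anti_monotone(self, extra_bit, bits):
        loc = {"A": vec(*bits), "B": vec(*(bits or [0])), "C": vec(extra_bit)}
        jc_small = joint_localization(["A", "B"], loc).jc
        jc_large = joint_localization(["A", "B", "C"], loc).jc
        assert jc_large <= jc_small


class TestExpressionWindow:
    @pytest.mark.parametrize(
        "t_low,t_high,T,expected",
        [
            (5, 9, 12, (3, 11)),
            (1, 3, 12, (1, 5)),
            (2, 3, 12, (1, 5)),
            (10, 12, 12, (8, 12)),
            (3, 10, 12, (1, 12)),
            (1, 1, 1, (1, 1)),
        ],
    )
    def test_cases(self, t_low, t_high, T, expected):
        assert expression_window(t_low, t_high, T) == expected

    def test_window_covers_l_plus_4_away_from_borders(self):
        lo, hi = expression_window(5, 9, 12)
        assert hi - lo + 1 == (9 - 5 + 1) + 4

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            expression_window(4, 3, 12)


def make_gep(rows):
    genes = tuple(rows)
    return NormalizedExpression(genes, np.array([rows[g] for g in genes], float))


class TestJointCoexpression:
    def test_all_ones(self):
        gep = make_gep({"G1": [1.0] * 6})
        je, ok = joint_coexpression(["G1"], gep, (1, 6), gamma=1.0)
        assert je.jq == pytest.approx(1.0) and ok

    def test_zero_profile(self):
        gep = make_gep({"G1": [1.0] * 6, "G2": [0.0] * 6})
        je, ok = joint_coexpression(["G1", "G2"], gep, (1, 6), gamma=0.01)
        assert je.jq == 0.0 and not ok

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_half_product(self, k):
        gep = make_gep({f"G{i}": [0.5] * 4 for i in range(k)})
        je, _ = joint_coexpression(list(gep.genes), gep, (1, 4), gamma=0.0)
        assert je.jq == pytest.approx(0.5**k)

    def test_denominator_T(self):
        gep = make_gep({"G1": [1.0, 1.0, 0.0, 0.0]})
        je_w, _ = joint_coexpression(["G1"], gep, (1, 2), 0.0, denominator="window")
        je_t, _ = joint_coexpression(["G1"], gep, (1, 2), 0.0, denominator="T")
        assert je_w.jq == pytest.approx(1.0)
        assert je_t.jq == pytest.approx(0.5)

    def test_missing_gene_fails(self):
        gep = make_gep({"G1": [1.0] * 4})
        _, ok = joint_coexpression(["G1", "GX"], gep, (1, 4), gamma=0.0)
        assert not ok

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            joint_coexpression([], make_gep({"G1": [1.0]}), (1, 1), 0.0)

    @given(st.integers(1, 5), st.floats(0.0, 1.0))
    def test_anti_monotone(self, k, value):
        rows = {f"G{i}": [0.8, 0.6, 0.9] for i in range(k)}
        rows["GX"] = [value] * 3
        gep = make_gep(rows)
        smaller = [f"G{i}" for i in range(k)]
        je1, _ = joint_coexpression(smaller, gep, (1, 3), 0.0)
        je2, _ = joint_coexpression(smaller + ["GX"], gep, (1, 3), 0.0)
        assert je2.jq <= je1.jq + 1e-15


class TestTermInformation:
    def test_root_depth_and_ic(self, chain_dag, chain_annotations):
        info = term_information(chain_dag, chain_annotations)
        assert info.depth["GO:0000001"] == 0
        assert info.ic["GO:0000001"] == pytest.approx(0.0)

    def test_leaf_hand_values(self, chain_dag, chain_annotations):
        info = term_information(chain_dag, chain_annotations)
        assert info.depth["GO:0000003"] == 2
        assert info.ic["GO:0000003"] == pytest.approx(-math.log(0.2))

    def test_ic_non_increasing_towards_root(self, chain_dag, chain_annotations):
        info = term_information(chain_dag, chain_annotations)
        for term, parents in chain_dag.parents.items():
            for p in parents:
                if term in info.ic and p in info.ic:
                    assert info.ic[p] <= info.ic[term] + 1e-12

    def test_zero_count_term_has_no_ic(self):
        dag = OntologyDag("BP", {"R": set(), "A": {"R"}, "B": {"R"}})
        info = term_information(dag, {"P1": frozenset({"A"})})
        assert "B" not in info.ic


class TestTermSimilarity:
    def test_self_similarity_hand_value(self, chain_dag, chain_annotations):
        sim = SemanticSimilarity(chain_dag, chain_annotations)
        d = -math.log(0.2)
        expected = math.tanh(0.3 * 2) * math.tanh(30 * d)  # l = 0
        assert sim.term_similarity("GO:0000003", "GO:0000003") == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.53705, abs=1e-4)

    def test_root_mica_zero(self):
        dag = OntologyDag("BP", {"R": set(), "A": {"R"}, "B": {"R"}})
        ann = {"P1": frozenset({"A"}), "P2": frozenset({"B"})}
        sim = SemanticSimilarity(dag, ann)
        assert sim.term_similarity("A", "B") == 0.0  # h(root) = 0

    def test_symmetry(self, chain_dag, chain_annotations):
        sim = SemanticSimilarity(chain_dag, chain_annotations)
        a = sim.term_similarity("GO:0000002", "GO:0000003")
        b = sim.term_similarity("GO:0000003", "GO:0000002")
        assert a == b

    def test_path_length_discount(self, chain_dag, chain_annotations):
        sim = SemanticSimilarity(chain_dag, chain_annotations)
        # mica(X, Y) = X (same IC as Y, shallower): l = 0 + 1
        d = -math.log(0.2)
        expected = math.exp(-0.2 * 1) * math.tanh(0.3 * 1) * math.tanh(30 * d)
        assert sim.term_similarity("GO:0000002", "GO:0000003") == pytest.approx(
            expected, abs=1e-12
        )

    def test_range(self, chain_dag, chain_annotations):
        sim = SemanticSimilarity(chain_dag, chain_annotations)
        for a in chain_dag.parents:
            for b in chain_dag.parents:
                assert 0.0 <= sim.term_similarity(a, b) < 1.0

    @given(
        st.integers(0, 8),
        st.integers(0, 10),
        st.floats(0.0, 10.0),
    )
    def test_tanh_identity(self, l, h, d):
        """The implementation's tanh factors equal the explicit exponential
        quotient form to within 1e-12."""
        from tipin.conditions import TermInformation

        ti = TermInformation({}, {}, 0)
        c1, c2, c3 = ti.c1, ti.c2, ti.c3
        explicit = (
            math.exp(-c1 * l)
            * ((math.exp(c2 * h) - math.exp(-c2 * h))
               / (math.exp(c2 * h) + math.exp(-c2 * h)))
            * ((math.exp(c3 * d) - math.exp(-c3 * d))
               / (math.exp(c3 * d) + math.exp(-c3 * d))
               if c3 * d < 350 else 1.0)
        )
        assert _similarity_from_mica(l, h, d, ti) == pytest.approx(
            explicit, abs=1e-12
        )


class TestTermsetAndProteinSimilarity:
    def test_termset_max(self, chain_dag, chain_annotations):
        sim = SemanticSimilarity(chain_dag, chain_annotations)
        st_terms = {"GO:0000002", "GO:0000003"}
        expected = max(
            sim.term_similarity("GO:0000003", t) for t in st_terms
        )
        assert sim.termset_similarity("GO:0000003", st_terms) == expected

    def test_termset_empty_is_zero(self, chain_dag, chain_annotations):
        sim = SemanticSimilarity(chain_dag, chain_annotations)
        assert sim.termset_similarity("GO:0000003", []) == 0.0

    def test_identical_single_term_sets(self, chain_dag, chain_annotations):
        sim = SemanticSimilarity(chain_dag, chain_annotations)
        assert sim.protein_similarity("L0", "L1") == sim.term_similarity(
            "GO:0000003", "GO:0000003"
        )

    def test_distinct_single_terms(self, chain_dag):
        ann = {"PA": frozenset({"GO:0000002"}), "PB": frozenset({"GO:0000003"}),
               **{f"Q{i}": frozenset({"GO:0000003"}) for i in range(3)}}
        sim = SemanticSimilarity(chain_dag, ann)
        assert sim.protein_similarity("PA", "PB") == pytest.approx(
            sim.term_similarity("GO:0000002", "GO:0000003")
        )

    def test_unannotated_protein_zero(self, chain_dag, chain_annotations):
        sim = SemanticSimilarity(chain_dag, chain_annotations)
        assert sim.protein_similarity("L0", "nobody") == 0.0

    def test_symmetry(self, chain_dag, chain_annotations):
        sim = SemanticSimilarity(chain_dag, chain_annotations)
        assert sim.protein_similarity("L0", "R1") == sim.protein_similarity(
            "R1", "L0"
        )


class _StubSim(SemanticSimilarity):
    """Similarity engine with a fixed protein-pair lookup table."""

    def __init__(self, table):
        self._table = table  # no super().__init__: pure stub

    def protein_similarity(self, p1, p2):
        key = (p1, p2) if p1 <= p2 else (p2, p1)
        return self._table.get(key, 0.0)


class TestClusterMinSimilarity:
    def score_fn(self, scores):
        def f(u, v):
            key = (u, v) if u <= v else (v, u)
            return scores.get(key, 0)
        return f

    def test_min_over_reliable(self):
        sim = _StubSim({("u", "v1"): 0.8, ("u", "v2"): 0.6})
        score = self.score_fn({("u", "v1"): 999, ("u", "v2"): 999})
        assert cluster_min_similarity(["v1", "v2"], "u", sim, score, 999) == 0.6

    def test_unreliable_member_excluded(self):
        sim = _StubSim({("u", "v1"): 0.8, ("u", "v2"): 0.6})
        score = self.score_fn({("u", "v1"): 999, ("u", "v2"): 10})
        assert cluster_min_similarity(["v1", "v2"], "u", sim, score, 999) == 0.8

    def test_empty_reliable_set_zero(self):
        sim = _StubSim({("u", "v1"): 0.8})
        score = self.score_fn({})
        assert cluster_min_similarity(["v1"], "u", sim, score, 999) == 0.0

    def test_non_increasing_under_growth(self):
        sim = _StubSim({("u", "v1"): 0.8, ("u", "v2"): 0.6, ("u", "v3"): 0.4})
        score = self.score_fn(
            {("u", "v1"): 999, ("u", "v2"): 999, ("u", "v3"): 999}
        )
        values = [
            cluster_min_similarity(pc, "u", sim, score, 999)
            for pc in (["v1"], ["v1", "v2"], ["v1", "v2", "v3"])
        ]
        assert values == sorted(values, reverse=True)


class TestExpandingCondition:
    def make(self, cc, mf, bp):
        sims = {
            "CC": _StubSim({("u", "v"): cc}),
            "MF": _StubSim({("u", "v"): mf}),
            "BP": _StubSim({("u", "v"): bp}),
        }
        th = Thresholds(r=900, sigma=0.7, omega=0.6, theta=0.1)
        score = lambda a, b: 999
        return expanding_condition(["v"], "u", sims, th, score)

    def test_all_three_true(self):
        ec, flags = self.make(0.9, 0.9, 0.9)
        assert ec and all(flags.values())

    def test_exactly_one_true(self):
        ec, flags = self.make(0.9, 0.1, 0.05)
        assert not ec and sum(flags.values()) == 1

    def test_two_of_three(self):
        ec, flags = self.make(0.8, 0.7, 0.0)
        assert ec and flags["CC"] and flags["MF"] and not flags["BP"]

    def test_inclusive_thresholds(self):
        ec, flags = self.make(0.7, 0.6, 0.0)
        assert ec  # comparisons are >=
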