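"""Disease semantic similarity: worked examples, limits, and a brute-force oracle."""

import math

import numpy as np
import pytest

import tlsea as T
from tlsea.dag_semantics import OntologyError, ancestor_closure, semantic_profile

from conftest import random_dag


class TestLoadOntology:
    def test_two_child_star(self):
        onto = T.load_ontology([("R", "A"), ("R", "B")])
        assert onto.roots == {"R"}
        assert len(onto.terms) == 3

    def test_cycle_is_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            T.load_ontology([("R", "A"), ("A", "R")])

    def test_diamond_gives_two_parents(self, diamond_ontology):
        assert diamond_ontology.parents_of("C") == {"A", "B"}

    def test_duplicate_edges_deduplicated(self):
        onto = T.load_ontology([("R", "A"), ("R", "A")])
        assert len(onto.parent_edges) == 1

    def test_empty_term_rejected(self):
        with pytest.raises(OntologyError):
            T.load_ontology([("R", " ")])


class TestAncestorClosure:
    def test_diamond_full_closure(self, diamond_ontology):
        view = ancestor_closure(diamond_ontology, "C")
        assert view.ancestors == {"C", "A", "B", "R"}
        assert len(view.edges) == 4

    def test_root_is_its_own_closure(self, diamond_ontology):
        view = ancestor_closure(diamond_ontology, "R")
        assert view.ancestors == {"R"}
        assert view.edges == frozenset()

    def test_chain_transitive_closure(self):
        onto = T.load_ontology([("R", "A"), ("A", "C")])
        assert ancestor_closure(onto, "C").ancestors == {"C", "A", "R"}

    def test_unknown_disease(self, diamond_ontology):
        with pytest.raises(OntologyError):
            ancestor_closure(diamond_ontology, "nope")


class TestTermStats:
    def test_star_full_universe(self, star_ontology):
        stats = T.term_stats(star_ontology, {"R", "A", "B"})
        assert stats.dag_counts["R"] == 3
        assert stats.dag_counts["A"] == 1
        assert stats.total_diseases == 3
        assert stats.max_count == 3

    def test_single_root_universe(self, star_ontology):
        stats = T.term_stats(star_ontology, {"R"})
        assert stats.dag_counts == {"R": 1}
        assert stats.total_diseases == 1

    def test_leaves_only_universe(self, star_ontology):
        stats = T.term_stats(star_ontology, {"A", "B"})
        assert stats.dag_counts["R"] == 2
        assert stats.total_diseases == 2

    def test_empty_universe_rejected(self, star_ontology):
        with pytest.raises(OntologyError):
            T.term_stats(star_ontology, set())


class TestSemanticProfile:
    def test_chain_decay(self):
        onto = T.load_ontology([("R", "A")])
        prof = semantic_profile(ancestor_closure(onto, "A"), "LNCSIM1", delta=0.5)
        assert prof.contributions == {"A": 1.0, "R": 0.5}
        assert prof.total == 1.5

    def test_root_base_case(self, star_ontology):
        prof = semantic_profile(ancestor_closure(star_ontology, "R"), "LNCSIM1")
        assert prof.contributions == {"R": 1.0}

    def test_idssim_star_example(self, star_ontology):
        stats = T.term_stats(star_ontology, {"R", "A", "B"})
        prof = semantic_profile(ancestor_closure(star_ontology, "A"), "IDSSIM",
                                delta=0.5, stats=stats)
        # P(R) = (3 - 3)/3 = 0, so the root contributes (0.5 + 0) * 1
        assert prof.contributions == pytest.approx({"A": 1.0, "R": 0.5})
        assert prof.total == pytest.approx(1.5)

    def test_lncsim2_information_content(self, star_ontology):
        stats = T.term_stats(star_ontology, {"R", "A", "B"})
        prof = semantic_profile(ancestor_closure(star_ontology, "A"), "LNCSIM2",
                                stats=stats)
        assert prof.contributions["A"] == pytest.approx(-math.log(1 / 3))
        assert prof.contributions["R"] == pytest.approx(0.0)

    def test_contribution_clipping_toggle(self):
        # deep chain, leaf-only universe: P(t) large for shared ancestors
        onto = T.load_ontology([("R", "A"), ("A", "B"), ("B", "C")])
        stats = T.term_stats(onto, {"C", "R"})
        clipped = semantic_profile(ancestor_closure(onto, "C"), "IDSSIM",
                                   stats=stats, clip=True)
        raw = semantic_profile(ancestor_closure(onto, "C"), "IDSSIM",
                               stats=stats, clip=False)
        assert max(clipped.contributions.values()) <= 1.0
        assert max(raw.contributions.values()) >= max(clipped.contributions.values())

    def test_missing_stats_is_error(self, star_ontology):
        with pytest.raises(ValueError):
            semantic_profile(ancestor_closure(star_ontology, "A"), "IDSSIM")


class TestDss:
    def test_identical_profiles_similarity_one(self, star_ontology):
        prof = semantic_profile(ancestor_closure(star_ontology, "A"), "LNCSIM1")
        assert T.dss(prof, prof) == pytest.approx(1.0)

    def test_disjoint_ancestors_zero(self):
        onto = T.load_ontology([("R1", "A"), ("R2", "B")])
        pa = semantic_profile(ancestor_closure(onto, "A"), "LNCSIM1")
        pb = semantic_profile(ancestor_closure(onto, "B"), "LNCSIM1")
        assert T.dss(pa, pb) == 0.0

    def test_star_idssim_one_third(self, star_ontology):
        stats = T.term_stats(star_ontology, {"R", "A", "B"})
        pa = semantic_profile(ancestor_closure(star_ontology, "A"), "IDSSIM", stats=stats)
        pb = semantic_profile(ancestor_closure(star_ontology, "B"), "IDSSIM", stats=stats)
        assert T.dss(pa, pb) == pytest.approx(1 / 3)

    def test_scheme_mismatch_rejected(self, star_ontology):
        stats = T.term_stats(star_ontology, {"R", "A", "B"})
        pa = semantic_profile(ancestor_closure(star_ontology, "A"), "LNCSIM1")
        pb = semantic_profile(ancestor_closure(star_ontology, "B"), "IDSSIM", stats=stats)
        with pytest.raises(ValueError):
            T.dss(pa, pb)


def brute_force_dss(onto, universe, scheme, delta, a, b):
    """Independent oracle: direct recursive formulas, no DP or matrices."""
    stats = T.term_stats(onto, universe) if scheme != "LNCSIM1" else None

    def contrib(disease, t, view):
        if scheme == "LNCSIM2":
            return -math.log(stats.dag_counts[t] / stats.total_diseases)
        if t == disease:
            return 1.0
        factor = delta if scheme == "LNCSIM1" else delta + stats.p(t)
        children = [c for p, c in view.edges if p == t]
        val = max(factor * contrib(disease, c, view) for c in children)
        return min(val, 1.0)

    va, vb = ancestor_closure(onto, a), ancestor_closure(onto, b)
    ca = {t: contrib(a, t, va) for t in va.ancestors}
    cb = {t: contrib(b, t, vb) for t in vb.ancestors}
    shared = va.ancestors & vb.ancestors
    denom = sum(ca.values()) + sum(cb.values())
    return sum(ca[t] + cb[t] for t in shared) / denom


@pytest.mark.parametrize("scheme", ["LNCSIM1", "IDSSIM", "LNCSIM2"])
@pytest.mark.parametrize("rng_seed", [0, 1, 2])
def test_dss_matrix_matches_brute_force_oracle(scheme, rng_seed):
    """Matrix construction equals an independent recursive recomputation."""
    rng = np.random.default_rng(rng_seed)
    edges, terms = random_dag(rng, n_terms=int(rng.integers(5, 13)))
    onto = T.load_ontology(edges)
    universe = sorted(onto.terms)
    matrix = T.dss_matrix(onto, universe, scheme=scheme, delta=0.5)
    for i, a in enumerate(matrix.diseases):
        for j, b in enumerate(matrix.diseases):
            if i < j:
                expected = brute_force_dss(onto, universe, scheme, 0.5, a, b)
                assert matrix.values[i, j] == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("scheme", ["LNCSIM1", "IDSSIM", "LNCSIM2"])
def test_dss_matrix_symmetric_bounded_unit_diagonal(scheme):
    rng = np.random.default_rng(3)
    edges, _ = random_dag(rng, 10)
    onto = T.load_ontology(edges)
    matrix = T.dss_matrix(onto, sorted(onto.terms), scheme=scheme)
    assert np.allclose(matrix.values, matrix.values.T)
    assert (matrix.values >= 0).all() and (matrix.values <= 1 + 1e-12).all()
    if scheme in ("LNCSIM1", "IDSSIM"):
        assert np.allclose(np.diag(matrix.values), 1.0)


def test_lncsim1_contribution_bounded_by_delta_power():
    """A term at depth k from the disease contributes at most delta^k."""
    onto = T.load_ontology([("R", "A"), ("A", "B"), ("B", "C"), ("R", "C")])
    prof = semantic_profile(ancestor_closure(onto, "C"), "LNCSIM1", delta=0.4)
    depth = {"C": 0, "B": 1, "A": 2, "R": 1}  # min undirected depth via R->C edge
    for t, c in prof.contributions.items():
        assert c <= 0.4 ** depth[t] + 1e-12


def test_idssim_reduces_to_lncsim1_when_p_zero():
    """With every term in every DAG, P(t)=0 and the two recursions coincide."""
    onto = T.load_ontology([("R", "A"), ("A", "B")])
    stats = T.term_stats(onto, {"B"})  # single-disease universe: all counts = max
    view = ancestor_closure(onto, "B")
    p1 = semantic_profile(view, "LNCSIM1", delta=0.5)
    p3 = semantic_profile(view, "IDSSIM", delta=0.5, stats=stats)
    assert p1.contributions == pytest.approx(p3.contributions)


def test_diseases_absent_from_ontology_are_dropped(star_ontology, caplog):
    matrix = T.dss_matrix(star_ontology, ["A", "B", "UNKNOWN"])
    assert matrix.diseases == ["A", "B"]
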