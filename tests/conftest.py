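import numpy as np
import pytest

import tlsea as T


@pytest.fixture
def diamond_ontology():
    """R -> A, R -> B, A -> C, B -> C."""
    return T.load_ontology([("R", "A"), ("R", "B"), ("A", "C"), ("B", "C")])


@pytest.fixture
def star_ontology():
    """R -> A, R -> B."""
    return T.load_ontology([("R", "A"), ("R", "B")])


@pytest.fixture(scope="session")
def fixture_spec():
    return T.FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def fixture_bundle(fixture_spec):
    """Full synthetic input bundle for one seed, built once per session."""
    spec = fixture_spec
    return {
        "spec": spec,
        "ontology": T.make_ontology(spec),
        "mirna_assoc": T.make_associations(spec, "mirna"),
        "disease_assoc": T.make_associations(spec, "disease"),
        "mirna_sim": T.make_mirna_similarity(spec),
        "expression": T.make_expression(spec),
        "scenario": T.case_study_scenario(spec),
    }


@pytest.fixture(scope="session")
def fixture_library(fixture_bundle):
    return T.make_gmt(fixture_bundle["spec"], fixture_bundle["disease_assoc"])


@pytest.fixture(scope="session")
def fixture_network(fixture_bundle):
    """Fused Pearson association network for the session fixture."""
    b = fixture_bundle
    return T.build_association_network(
        b["mirna_assoc"], b["mirna_sim"], b["disease_assoc"], b["ontology"])


def random_dag(rng: np.random.Generator, n_terms: int):
    """Random rooted DAG edge list: term i>0 picks 1-2 parents among earlier."""
    terms = [f"T{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        k = 1 if i == 1 else int(rng.integers(1, 3))
        for p in rng.choice(i, size=min(k, i), replace=False):
            edges.append((terms[int(p)], terms[i]))
    return edges, terms
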