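"""Disease–disease semantic similarity over a MeSH-like ontology DAG.

A disease ``A`` is represented by its *disease DAG*: the subgraph of the
ontology induced by ``A`` and all of its ancestor terms.  Each ancestor
term ``t`` contributes a semantic value to ``A`` under one of three
schemes:

``LNCSIM1``
    Recursive decay: ``SV(A) = 1`` at the disease itself, and each step
    up the hierarchy multiplies by a constant contribution factor
    ``delta`` (taking the max over the term's children on paths toward
    ``A``).

``LNCSIM2``
    Information content: a term contributes ``-log(DAGs(t)/D)`` where
    ``DAGs(t)`` is the number of disease DAGs in a chosen universe that
    contain ``t`` and ``D`` is the universe size.  Rare (specific) terms
    contribute more; a term present in every DAG contributes 0.

``IDSSIM``
    Combines both: the recursion of LNCSIM1 with a per-term factor
    ``delta + P(t)``, where ``P(t) = (max_k DAGs(k) - DAGs(t)) / D`` is
    the information-content correction.

The semantic similarity of diseases ``A`` and ``B`` is the contribution
mass on their shared ancestors, normalised by the total semantic values:

    DSS(A, B) = sum_{t in T_A ∩ T_B} (SV_A(t) + SV_B(t)) / (SV(A) + SV(B))
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMES = ("LNCSIM1", "LNCSIM2", "IDSSIM")


class OntologyError(ValueError):
    """Raised for structural problems in an ontology (cycles, unknown terms)."""


@dataclass(frozen=True)
class DiseaseOntology:
    """A validated, acyclic parent→child term hierarchy."""

    terms: frozenset[str]
    parent_edges: frozenset[tuple[str, str]]

    @property
    def roots(self) -> frozenset[str]:
        children = {c for _, c in self.parent_edges}
        return frozenset(t for t in self.terms if t not in children)

    def parents_of(self, term: str) -> set[str]:
        return {p for p, c in self.parent_edges if c == term}

    def as_digraph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.parent_edges)
        return g


@dataclass(frozen=True)
class DiseaseDAGView:
    """A disease plus its ancestor closure: ``T_A`` and the induced edges ``E_A``."""

    disease: str
    ancestors: frozenset[str]
    edges: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class TermStats:
    """Per-term DAG membership counts over a disease universe.

    ``dag_counts[t]`` is the number of diseases in ``universe`` whose
    ancestor closure contains ``t``; ``total_diseases`` is ``D``.
    """

    dag_counts: Mapping[str, int]
    total_diseases: int
    universe: frozenset[str]

    @property
    def max_count(self) -> int:
        return max(self.dag_counts.values())

    def p(self, term: str) -> float:
        """Information-content contribution factor P(t)."""
        if term not in self.dag_counts:
            raise OntologyError(f"term {term!r} appears in no disease DAG of the universe")
        return (self.max_count - self.dag_counts[term]) / self.total_diseases


@dataclass(frozen=True)
class SemanticProfile:
    """Per-term semantic contributions of one disease's DAG, plus their sum."""

    disease: str
    contributions: Mapping[str, float]
    scheme: str
    delta: float

    @property
    def total(self) -> float:
        return float(sum(self.contributions.values()))


@dataclass
class DSSMatrix:
    """Symmetric disease×disease semantic-similarity matrix."""

    diseases: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self._index = {d: i for i, d in enumerate(self.diseases)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def __contains__(self, disease: str) -> bool:
        return disease in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.diseases, columns=self.diseases)


def load_ontology(pairs: Iterable[tuple[str, str]]) -> DiseaseOntology:
    """Build and validate an ontology from (parent, child) rows.

    Duplicate edges are dropped with a warning; a cycle is a hard error.
    """
    edges: set[tuple[str, str]] = set()
    n_rows = 0
    for parent, child in pairs:
        n_rows += 1
        parent, child = str(parent).strip(), str(child).strip()
        if not parent or not child:
            raise OntologyError(f"empty term in row {n_rows}: ({parent!r}, {child!r})")
        edges.add((parent, child))
    if len(edges) < n_rows:
        logger.warning("dropped %d duplicate ontology edges", n_rows - len(edges))
    terms = {t for e in edges for t in e}
    g = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyError(f"ontology contains a cycle through edge {cycle[0][:2]}")
    return DiseaseOntology(terms=frozenset(terms), parent_edges=frozenset(edges))


def ancestor_closure(onto: DiseaseOntology, disease: str) -> DiseaseDAGView:
    """The disease DAG: the disease, its transitive parents, and induced edges."""
    if disease not in onto.terms:
        raise OntologyError(f"unknown disease term {disease!r}")
    g = onto.as_digraph()
    anc = nx.ancestors(g, disease) | {disease}
    edges = {(p, c) for p, c in onto.parent_edges if p in anc and c in anc}
    return DiseaseDAGView(disease=disease, ancestors=frozenset(anc), edges=frozenset(edges))


def term_stats(onto: DiseaseOntology, disease_universe: Iterable[str]) -> TermStats:
    """Count, for every term, how many universe diseases' DAGs contain it."""
    universe = frozenset(disease_universe)
    if not universe:
        raise OntologyError("empty disease universe")
    missing = universe - onto.terms
    if missing:
        raise OntologyError(f"universe diseases not in ontology: {sorted(missing)}")
    counts: dict[str, int] = {}
    for disease in universe:
        for t in ancestor_closure(onto, disease).ancestors:
            counts[t] = counts.get(t, 0) + 1
    return TermStats(dag_counts=counts, total_diseases=len(universe), universe=universe)


def _contribution_order(view: DiseaseDAGView) -> list[str]:
    # Process A first, then terms whose in-view children are all done
    # (reverse topological order w.r.t. parent→child edges).
    g = nx.DiGraph()
    g.add_nodes_from(view.ancestors)
    g.add_edges_from(view.edges)
    return list(reversed(list(nx.topological_sort(g))))


def semantic_profile(
    view: DiseaseDAGView,
    scheme: str,
    delta: float = 0.5,
    stats: TermStats | None = None,
    clip: bool = True,
) -> SemanticProfile:
    """Per-term semantic contributions for one disease under a scheme.

    ``stats`` is required for LNCSIM2 and IDSSIM.  ``clip`` caps any
    recursive contribution at 1.0 (relevant to IDSSIM, where the factor
    ``delta + P(t)`` may exceed 1); set ``clip=False`` to disable.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    if scheme in ("LNCSIM2", "IDSSIM") and stats is None:
        raise ValueError(f"scheme {scheme} requires term statistics")

    contrib: dict[str, float] = {}
    if scheme == "LNCSIM2":
        assert stats is not None
        for t in view.ancestors:
            if t not in stats.dag_counts:
                raise OntologyError(f"term {t!r} missing from DAG counts")
            contrib[t] = -math.log(stats.dag_counts[t] / stats.total_diseases)
        return SemanticProfile(view.disease, contrib, scheme, delta)

    children_in_view: dict[str, list[str]] = {t: [] for t in view.ancestors}
    for p, c in view.edges:
        children_in_view[p].append(c)
    for t in _contribution_order(view):
        if t == view.disease:
            contrib[t] = 1.0
            continue
        factor = delta
        if scheme == "IDSSIM":
            assert stats is not None
            factor = delta + stats.p(t)
        value = max(factor * contrib[c] for c in children_in_view[t])
        if clip and value > 1.0:
            value = 1.0
        contrib[t] = value
    return SemanticProfile(view.disease, contrib, scheme, delta)


def dss(prof_a: SemanticProfile, prof_b: SemanticProfile) -> float:
    """Semantic similarity: shared-ancestor contribution mass over total mass."""
    if prof_a.scheme != prof_b.scheme or prof_a.delta != prof_b.delta:
        raise ValueError("profiles computed under different schemes or deltas")
    denom = prof_a.total + prof_b.total
    if denom <= 0:
        raise ValueError(
            f"degenerate profiles: SV({prof_a.disease}) + SV({prof_b.disease}) = 0"
        )
    shared = set(prof_a.contributions) & set(prof_b.contributions)
    num = sum(prof_a.contributions[t] + prof_b.contributions[t] for t in shared)
    return num / denom


def dss_matrix(
    onto: DiseaseOntology,
    universe: Sequence[str],
    scheme: str = "IDSSIM",
    delta: float = 0.5,
    clip: bool = True,
) -> DSSMatrix:
    """Pairwise semantic similarity over a disease universe.

    Diseases absent from the ontology are dropped with a warning rather
    than aborting the whole computation.
    """
    present = [d for d in universe if d in onto.terms]
    dropped = [d for d in universe if d not in onto.terms]
    if dropped:
        logger.warning("dropping %d diseases absent from the ontology: %s",
                       len(dropped), dropped)
    if not present:
        raise OntologyError("no universe disease is present in the ontology")
    stats = term_stats(onto, present) if scheme in ("LNCSIM2", "IDSSIM") else None
    profiles = [
        semantic_profile(ancestor_closure(onto, d), scheme, delta, stats, clip)
        for d in present
    ]
    n = len(present)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dss(profiles[i], profiles[j])
        if scheme == "LNCSIM2":
            values[i, i] = dss(profiles[i], profiles[i]) if profiles[i].total > 0 else 1.0
    return DSSMatrix(diseases=list(present), values=values)
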