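"""The three lncRNA functional-similarity networks.

Three complementary notions of lncRNA similarity are built here:

1. *miRNA-target based*: two lncRNAs sharing target miRNAs (or targeting
   functionally similar miRNAs) are similar.  Each lncRNA pair is encoded
   as a pair of feature vectors over the merged target list — a binary
   membership part plus a miRNA-similarity part — and scored by cosine
   similarity.
2. *Disease-association based*: lncRNAs associated with semantically
   similar diseases are similar; a best-match average over the two
   disease sets using the disease semantic-similarity matrix.
3. *Expression based*: Spearman rank correlation of tissue expression
   profiles (average ranks on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dag_semantics import DSSMatrix

logger = logging.getLogger(__name__)


class SimilarityError(ValueError):
    pass


@dataclass
class AssociationTable:
    """Bipartite lncRNA–partner associations (partner = miRNA or disease)."""

    lnc_index: dict[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        idx: dict[str, set[str]] = {}
        seen: set[tuple[str, str]] = set()
        dupes = 0
        for lnc, partner in pairs:
            lnc, partner = str(lnc).strip(), str(partner).strip()
            if not lnc or not partner:
                raise SimilarityError(f"empty identifier in pair ({lnc!r}, {partner!r})")
            if (lnc, partner) in seen:
                dupes += 1
                continue
            seen.add((lnc, partner))
            idx.setdefault(lnc, set()).add(partner)
        if dupes:
            logger.warning("dropped %d duplicate association pairs", dupes)
        if not idx:
            raise SimilarityError("empty association table")
        return cls(lnc_index={k: frozenset(v) for k, v in idx.items()})

    @property
    def lncrnas(self) -> list[str]:
        return sorted(self.lnc_index)

    @property
    def partner_index(self) -> dict[str, frozenset[str]]:
        rev: dict[str, set[str]] = {}
        for lnc, partners in self.lnc_index.items():
            for p in partners:
                rev.setdefault(p, set()).add(lnc)
        return {k: frozenset(v) for k, v in rev.items()}

    def partners(self, lnc: str) -> frozenset[str]:
        try:
            return self.lnc_index[lnc]
        except KeyError:
            raise SimilarityError(f"unknown lncRNA {lnc!r}") from None


@dataclass
class SimilarityMatrix:
    """Symmetric labelled similarity matrix with a declared value range."""

    labels: list[str]
    values: np.ndarray
    range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self._index = {l: i for i, l in enumerate(self.labels)}

    def get(self, a: str, b: str, default: float | None = None) -> float:
        if a == b:
            return 1.0  # self-similarity, even if the matrix omits the diagonal
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            if default is not None:
                return default
            raise SimilarityError(f"label missing from similarity matrix: {a!r} or {b!r}")
        return float(self.values[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class LncFeatureVectorPair:
    """Feature encoding of an lncRNA pair over the merged target-miRNA list.

    ``v1 = concat(v1_binary, v1_sim)``: membership of each merged miRNA in
    lnc1's target set, then the max similarity of each merged miRNA to
    lnc1's target set (1.0 on its own targets by self-similarity).
    """

    merged_mirnas: list[str]
    v1_binary: np.ndarray
    v2_binary: np.ndarray
    v1_sim: np.ndarray
    v2_sim: np.ndarray

    @property
    def v1(self) -> np.ndarray:
        return np.concatenate([self.v1_binary, self.v1_sim])

    @property
    def v2(self) -> np.ndarray:
        return np.concatenate([self.v2_binary, self.v2_sim])


def _max_sim_to_set(mirna: str, target_set: frozenset[str],
                    mirna_sim: SimilarityMatrix, aggregator: str) -> float:
    vals = [mirna_sim.get(mirna, t, default=0.0) for t in target_set]
    return float(max(vals)) if aggregator == "max" else float(np.mean(vals))


def mirna_feature_pair(
    lnc1: str,
    lnc2: str,
    assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    aggregator: str = "max",
) -> LncFeatureVectorPair:
    """Encode an lncRNA pair over the sorted union of their target miRNAs."""
    if aggregator not in ("max", "mean"):
        raise ValueError(f"aggregator must be 'max' or 'mean', got {aggregator!r}")
    set_a, set_b = assoc.partners(lnc1), assoc.partners(lnc2)
    if not set_a or not set_b:
        raise SimilarityError(f"lncRNA with empty target set: {lnc1!r} or {lnc2!r}")
    merged = sorted(set_a | set_b)
    v1_bin = np.array([1.0 if m in set_a else 0.0 for m in merged])
    v2_bin = np.array([1.0 if m in set_b else 0.0 for m in merged])
    v1_sim = np.array([_max_sim_to_set(m, set_a, mirna_sim, aggregator) for m in merged])
    v2_sim = np.array([_max_sim_to_set(m, set_b, mirna_sim, aggregator) for m in merged])
    return LncFeatureVectorPair(merged, v1_bin, v2_bin, v1_sim, v2_sim)


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise SimilarityError(f"vector length mismatch: {v1.shape} vs {v2.shape}")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise SimilarityError("zero-norm feature vector (degenerate lncRNA)")
    return float(v1 @ v2 / (n1 * n2))


def sim_network_mirna(
    assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    aggregator: str = "max",
) -> SimilarityMatrix:
    """Pairwise miRNA-target-based functional similarity over all lncRNAs."""
    lncs = assoc.lncrnas
    n = len(lncs)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            pair = mirna_feature_pair(lncs[i], lncs[j], assoc, mirna_sim, aggregator)
            values[i, j] = values[j, i] = cosine_similarity(pair.v1, pair.v2)
    return SimilarityMatrix(labels=lncs, values=values, range=(0.0, 1.0))


def disease_set_similarity(d: str, dg: frozenset[str] | set[str], dss: DSSMatrix) -> float:
    """Best semantic match between a disease and a disease set."""
    if not dg:
        raise SimilarityError("empty disease set")
    return max(dss.get(d, other) for other in dg)


def fs_disease(u: str, v: str, assoc: AssociationTable, dss: DSSMatrix) -> float:
    """Functional similarity from disease associations.

    FS(u, v) = (S_{u→v} + S_{v→u}) / (|DG_u| + |DG_v|), where each
    directed term sums the best semantic match of every disease of one
    lncRNA against the other lncRNA's disease set.
    """
    dg_u, dg_v = assoc.partners(u), assoc.partners(v)
    s_uv = sum(disease_set_similarity(d, dg_v, dss) for d in dg_u)
    s_vu = sum(disease_set_similarity(d, dg_u, dss) for d in dg_v)
    return (s_uv + s_vu) / (len(dg_u) + len(dg_v))


def sim_network_disease(assoc: AssociationTable, dss: DSSMatrix) -> SimilarityMatrix:
    """Pairwise disease-association-based functional similarity."""
    dropped = sorted({d for partners in assoc.lnc_index.values()
                      for d in partners if d not in dss})
    if dropped:
        logger.warning("dropping %d diseases absent from the DSS matrix: %s",
                       len(dropped), dropped)
        kept = {lnc: frozenset(d for d in partners if d in dss)
                for lnc, partners in assoc.lnc_index.items()}
        empty = sorted(l for l, p in kept.items() if not p)
        if empty:
            logger.warning("dropping %d lncRNAs left with no known disease: %s",
                           len(empty), empty)
        assoc = AssociationTable(lnc_index={l: p for l, p in kept.items() if p})
        if not assoc.lnc_index:
            raise SimilarityError("no lncRNA retains a disease known to the DSS matrix")
    lncs = assoc.lncrnas
    n = len(lncs)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fs_disease(lncs[i], lncs[j], assoc, dss)
    return SimilarityMatrix(labels=lncs, values=values, range=(0.0, 1.0))


@dataclass
class ExpressionMatrix:
    """lncRNA × tissue expression levels (nonnegative, finite)."""

    lncrnas: list[str]
    tissues: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise SimilarityError("expression matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lncrnas, columns=self.tissues)


def sim_network_expression(expr: ExpressionMatrix) -> SimilarityMatrix:
    """Spearman rank correlation between lncRNA expression profiles.

    Constant profiles have undefined rank correlation; their rows and
    columns are set to NaN (except the unit diagonal) with a warning.
    """
    x = expr.values
    if x.shape[1] < 2:
        raise SimilarityError("need at least 2 tissues for rank correlation")
    constant = np.ptp(x, axis=1) == 0
    if constant.any():
        logger.warning("constant expression profiles (similarity undefined): %s",
                       [l for l, c in zip(expr.lncrnas, constant) if c])
    ranks = sps.rankdata(x, axis=1)  # average ranks on ties
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.corrcoef(ranks)
    values = np.asarray(values, dtype=float)
    values[constant, :] = np.nan
    values[:, constant] = np.nan
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels=list(expr.lncrnas), values=values, range=(-1.0, 1.0))
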