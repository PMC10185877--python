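"""Over-representation analysis of lncRNA lists against disease lncRNA sets.

The query list (original or RWR-expanded) is intersected with each
disease lncRNA set of a library; the overlap is scored with the
one-sided upper-tail hypergeometric test (equivalent to a one-sided
Fisher exact test),

    p = P(X >= hits),   X ~ Hypergeom(|U|, |S|, |L ∩ U|)

with Benjamini–Hochberg adjustment across sets.  Each set also carries a
*hit rate*: the percentage of its members present in the query list.
The report keeps rows with raw p below a cutoff (0.01 by default),
sorted ascending by p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .fusion_rwr import AssocNetwork, ExpansionResult, RWRConfig, expand_list

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSetLibrary:
    """Named lncRNA sets plus a background universe.

    If no explicit universe is given, the union of all sets is used.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if not self.sets:
            raise EnrichmentError("empty gene-set library")
        union = frozenset().union(*self.sets.values())
        if not self.universe:
            self.universe = union
        empty = [name for name, s in self.sets.items() if not s]
        if empty:
            raise EnrichmentError(f"empty sets in library: {empty}")
        stray = union - self.universe
        if stray:
            raise EnrichmentError(
                f"{len(stray)} set members outside the declared universe, "
                f"e.g. {sorted(stray)[:5]}")


@dataclass
class EnrichmentRow:
    set_name: str
    set_size: int
    list_size: int          # |L ∩ U|, the effective number of draws
    hits: int
    universe_size: int
    p_value: float
    adj_p: float
    hit_rate: float         # 100 * hits / set_size, in percent


def hypergeom_upper_tail(hits: int, universe: int, set_size: int, draws: int) -> float:
    """P(X >= hits) for X ~ Hypergeom(universe, set_size, draws)."""
    return float(sps.hypergeom.sf(hits - 1, universe, set_size, draws))


def hit_rate(gene_set: Iterable[str], query_list: Iterable[str]) -> float:
    """Percentage of a set's members present in the query list (2 decimals)."""
    s = set(gene_set)
    if not s:
        raise EnrichmentError("empty gene set")
    return round(100.0 * len(s & set(query_list)) / len(s), 2)


def ora_hypergeom(query_list: Iterable[str], library: GeneSetLibrary,
                  test: str = "hypergeom") -> list[EnrichmentRow]:
    """Per-set over-representation statistics for a query list.

    Symbols outside the universe are dropped from the draws (with a
    logged count); ``test`` selects the upper-tail hypergeometric
    (default), one-sided Fisher (identical p), or binomial approximation.
    """
    if test not in ("hypergeom", "fisher", "binomial"):
        raise ValueError(f"unknown test {test!r}")
    query = set(query_list)
    effective = query & library.universe
    outside = len(query) - len(effective)
    if outside:
        logger.warning("dropped %d query symbols outside the universe", outside)
    if not effective:
        raise EnrichmentError("no query symbol is in the background universe")

    u, draws = len(library.universe), len(effective)
    rows = []
    for name in sorted(library.sets):
        members = library.sets[name]
        hits = len(members & effective)
        if test == "binomial":
            p = float(sps.binom.sf(hits - 1, draws, len(members) / u))
        elif test == "fisher":
            table = [[hits, len(members) - hits],
                     [draws - hits, u - len(members) - (draws - hits)]]
            p = float(sps.fisher_exact(table, alternative="greater")[1])
        else:
            p = hypergeom_upper_tail(hits, u, len(members), draws)
        rows.append(EnrichmentRow(
            set_name=name, set_size=len(members), list_size=draws, hits=hits,
            universe_size=u, p_value=p, adj_p=np.nan,
            hit_rate=hit_rate(members, effective)))
    adj = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
    for row, a in zip(rows, adj):
        row.adj_p = float(a)
    return rows


def filter_report(rows: Iterable[EnrichmentRow], p_cutoff: float = 0.01,
                  top_k: int | None = None) -> list[EnrichmentRow]:
    """Rows with raw p strictly below the cutoff, ascending by (p, name)."""
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must be in (0, 1]")
    kept = sorted((r for r in rows if r.p_value < p_cutoff),
                  key=lambda r: (r.p_value, r.set_name))
    return kept[:top_k] if top_k is not None else kept


def rows_to_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class PairedReport:
    """Enrichment of the original vs the RWR-expanded lncRNA list."""

    expansion: ExpansionResult
    original: list[EnrichmentRow]
    expanded: list[EnrichmentRow]
    membership: pd.DataFrame  # per set member: hit/not-hit in each list

    def set_comparison(self, set_name: str) -> pd.DataFrame:
        return self.membership[self.membership["set_name"] == set_name]


def run_tlsea(seed_list: Iterable[str], network: AssocNetwork,
              library: GeneSetLibrary, rwr_config: RWRConfig | None = None,
              test: str = "hypergeom") -> PairedReport:
    """End-to-end analysis: expand the list, then run ORA on both lists.

    With ``rwr_config.sim_coef=None`` no expansion happens and the two
    reports coincide.
    """
    rwr_config = rwr_config or RWRConfig()
    expansion = expand_list(network, set(seed_list), rwr_config)
    original_list = set(expansion.seeds_used)
    expanded_list = set(expansion.expanded_list)
    original = ora_hypergeom(original_list, library, test)
    expanded = ora_hypergeom(expanded_list, library, test)
    records = []
    for name in sorted(library.sets):
        for member in sorted(library.sets[name]):
            records.append({
                "set_name": name,
                "member": member,
                "in_original": member in original_list,
                "in_expanded": member in expanded_list,
            })
    membership = pd.DataFrame(records)
    return PairedReport(expansion=expansion, original=original,
                        expanded=expanded, membership=membership)
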