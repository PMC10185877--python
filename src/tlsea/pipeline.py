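"""End-to-end orchestration: raw tables → fused network → paired ORA report.

This is the programmatic equivalent of the ``tlsea run`` subcommand: it
chains disease semantic similarity, the two lncRNA similarity networks,
SDNE embedding of each, the average-merge of embeddings, the Pearson
association network, RWR expansion of the user's list, and the paired
over-representation report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .dag_semantics import DiseaseOntology, dss_matrix
from .lnc_similarity import (AssociationTable, SimilarityMatrix,
                             sim_network_disease, sim_network_mirna)
from .sdne import SDNEConfig, WeightedGraph, merge_embeddings, sdne_embed
from .fusion_rwr import AssocNetwork, RWRConfig, pearson_network
from .enrichment import GeneSetLibrary, PairedReport, run_tlsea

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scheme: str = "IDSSIM"
    delta: float = 0.5
    sdne: SDNEConfig = field(default_factory=SDNEConfig)
    rwr: RWRConfig = field(default_factory=RWRConfig)
    ora_test: str = "hypergeom"
    p_cutoff: float = 0.01


def build_association_network(
    mirna_assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    disease_assoc: AssociationTable,
    ontology: DiseaseOntology,
    config: PipelineConfig | None = None,
) -> AssocNetwork:
    """Similarity networks → SDNE embeddings → merge → Pearson network."""
    config = config or PipelineConfig()
    diseases = sorted({d for p in disease_assoc.lnc_index.values() for d in p})
    dss = dss_matrix(ontology, diseases, scheme=config.scheme, delta=config.delta)

    sim_m = sim_network_mirna(mirna_assoc, mirna_sim)
    sim_d = sim_network_disease(disease_assoc, dss)
    logger.info("similarity networks: %d lncRNAs (miRNA-based), %d (disease-based)",
                len(sim_m.labels), len(sim_d.labels))

    emb_m = sdne_embed(WeightedGraph.from_similarity(sim_m.labels, sim_m.values),
                       config.sdne)
    emb_d = sdne_embed(WeightedGraph.from_similarity(sim_d.labels, sim_d.values),
                       config.sdne)
    merged = merge_embeddings(emb_m, emb_d)
    return pearson_network(merged)


def run_pipeline(
    seed_list: Iterable[str],
    mirna_assoc: AssociationTable,
    mirna_sim: SimilarityMatrix,
    disease_assoc: AssociationTable,
    ontology: DiseaseOntology,
    library: GeneSetLibrary,
    config: PipelineConfig | None = None,
) -> PairedReport:
    config = config or PipelineConfig()
    network = build_association_network(mirna_assoc, mirna_sim, disease_assoc,
                                        ontology, config)
    return run_tlsea(seed_list, network, library, config.rwr, config.ora_test)
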