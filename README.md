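# tlsea — lncRNA set enrichment analysis with network fusion

Conventional over-representation analysis (ORA) of a long non-coding RNA
(lncRNA) list treats every gene in isolation: associations *between* the
lncRNAs — shared target miRNAs, shared disease involvement, co-expression —
carry no weight. `tlsea` implements a network-topology approach for lncRNA
set enrichment: it fuses heterogeneous lncRNA association evidence into a
single lncRNA–lncRNA network, uses that network to *expand* the user's list
with closely connected lncRNAs via random walk with restart, and only then
runs ORA against a disease lncRNA-set library. On lists with genuine network
structure the expanded list is typically far more significantly enriched in
the relevant disease sets than the original list.

The pipeline, stage by stage:

1. **Disease semantic similarity.** Each disease `A` in a MeSH-like ontology
   is represented by its DAG (the disease plus all ancestors). A term `t`
   contributes a semantic value `SV_A(t)`; under the information-content
   scheme the recursion is
   `SV_A(t) = max over children t' of (Δ + P(t)) · SV_A(t')` with
   `SV_A(A) = 1`, where `P(t) = (max_k DAGs(k) − DAGs(t))/D` up-weights rare
   terms. Similarity of two diseases is the contribution mass on shared
   ancestors: `DSS(A,B) = Σ_{t∈T_A∩T_B} (SV_A(t)+SV_B(t)) / (SV(A)+SV(B))`.
   The simpler constant-decay (`LNCSIM1`) and pure information-content
   (`LNCSIM2`) schemes are also provided.
2. **lncRNA functional similarity.** Three networks: (i) from lncRNA–miRNA
   associations — each lncRNA pair is encoded over the merged target-miRNA
   list as a binary membership part plus a miRNA-similarity part and scored
   by cosine similarity; (ii) from lncRNA–disease associations — a
   best-match average `FS(u,v) = (S_{u→v}+S_{v→u})/(|DG_u|+|DG_v|)` over the
   disease semantic-similarity matrix; (iii) from tissue expression profiles
   via Spearman rank correlation.
3. **Graph embedding and fusion.** The miRNA- and disease-based networks are
   each embedded into 64-dimensional vectors by a structural deep network
   embedding (SDNE) autoencoder preserving first-order (Laplacian penalty)
   and second-order (β-weighted reconstruction) proximity. The two
   embeddings are merged — elementwise mean where an lncRNA appears in both,
   plain copy otherwise — and pairwise Pearson correlation ρ of the merged
   rows defines the lncRNA–lncRNA association network.
4. **List expansion.** Edges with ρ above a user-chosen similarity
   coefficient are kept; a random walk with restart
   `p ← (1−r)·W p + r·p₀` from the user's seed lncRNAs is iterated to
   convergence; every node with non-vanishing stationary probability joins
   the expanded list. A similarity coefficient of `None` disables expansion.
5. **Enrichment.** Both lists are scored against a GMT disease library with
   the upper-tail hypergeometric test (BH-adjusted), reported with per-set
   hit counts and hit rates (`100·|S∩L|/|S|`).

Because the curated source databases are large downloads, the package ships
a synthetic-fixture generator (`tlsea.synthetic`) that emulates all input
shapes with planted lncRNA modules, so the whole pipeline is testable
offline.

## Worked example

```python
import tlsea as T

spec = T.FixtureSpec(seed=7)                     # 3 modules x 8 lncRNAs
onto = T.make_ontology(spec)
mirna_assoc = T.make_associations(spec, "mirna")
disease_assoc = T.make_associations(spec, "disease")
library = T.make_gmt(spec, disease_assoc)
bundle = T.case_study_scenario(spec)             # seeds = half of module 1

net = T.build_association_network(mirna_assoc, T.make_mirna_similarity(spec),
                                  disease_assoc, onto)
report = T.run_tlsea(bundle.seeds, net, library,
                     T.RWRConfig(sim_coef=T.tuned_sim_coef(net)))
```

Printing the planted module's disease sets before and after expansion
(`examples/04_expansion_and_enrichment.py`) gives:

```
recovered 4/4 held-out module members

disease set    p (original)   p (expanded)             hit rate %
D001                  0.179        0.00132      40.00 -> 100.00
D002                 0.0353       0.000208      50.00 -> 100.00
D003                 0.0593       2.31e-05      42.86 -> 100.00
D004                 0.0909       0.000175      37.50 -> 87.50
```

The walk recovered the held-out half of the seeded module, so every disease
set anchored in that module roughly doubles its hit rate and drops its
p-value by two to three orders of magnitude — the behaviour list expansion
is designed to produce.

The same workflow is available as a CLI
(`tlsea simulate|dss|sim-mirna|sim-disease|sim-expr|embed|merge|network|expand|enrich|run`);
see `examples/05_full_pipeline_cli.py`.

## Layout

- `src/tlsea/` — library (`dag_semantics`, `lnc_similarity`, `sdne`,
  `fusion_rwr`, `enrichment`, `synthetic`, `pipeline`, `io`, `cli`).
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model details, parameter choices, limitations.
- `tests/` — pytest suite including property-based invariants.
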