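# Methods

## Model and assumptions

The pipeline rests on three assumptions about lncRNA biology: lncRNAs
sharing target miRNAs tend to share function; lncRNAs associated with
semantically similar diseases tend to share function; and functionally
related lncRNAs are co-expressed across tissues. Each assumption yields a
similarity network, the first two are fused through graph embedding into a
single lncRNA–lncRNA association network, and that network is used to
expand a user's lncRNA list before over-representation analysis (ORA).
Expression similarity is computed and exported but does not enter the
fusion by default: the fused network is defined over the union of the
miRNA- and disease-annotated lncRNAs, and co-expression evidence is noisier
and partially redundant with them. It can be embedded and merged explicitly
by the caller if desired.

### Disease semantic similarity

A disease `A` is its ancestor DAG `(T_A, E_A)` in a parent–child ontology.
Three contribution schemes are implemented:

- `LNCSIM1`: `SV_A(A)=1`, otherwise `SV_A(t) = max_{t'∈C(t)} Δ·SV_A(t')`,
  children taken within the DAG view. Δ defaults to 0.5, the conventional
  semantic contribution factor.
- `LNCSIM2`: `SV_A(t) = −log(DAGs(t)/D)` over a disease universe of size
  `D`. The log base is natural; the choice is immaterial for similarity
  because the base cancels between numerator and denominator.
- `IDSSIM` (default): the `LNCSIM1` recursion with per-term factor
  `Δ + P(t)`, `P(t) = (max_k DAGs(k) − DAGs(t))/D`.

`DSS(A,B) = Σ_{t∈T_A∩T_B}(SV_A(t)+SV_B(t)) / (SV(A)+SV(B))`.

Numerical choices: contributions are computed by dynamic programming in
reverse-topological order of the DAG view (children before parents), so
each term is evaluated once. Because `Δ + P(t)` can exceed 1 when `P(t) >
1 − Δ`, a contribution can exceed the disease's own self-contribution; by
default each per-term contribution is clipped at 1.0, which keeps `DSS`
inside `[0, 1]`. The clip is a package choice, exposed as `clip=False`.
The counting universe for `DAGs(t)`/`D` is a parameter: by default the
diseases actually being compared, since the package cannot assume a global
vocabulary. Terms never appearing in any universe DAG have no defined
information content; referencing them under `LNCSIM2`/`IDSSIM` is an error
rather than `−log 0`. Diseases missing from the ontology are dropped from
matrix construction with a warning.

### lncRNA similarity networks

*miRNA-based.* For a pair of lncRNAs with target sets `A` and `B`, features
are indexed over the sorted merged target list (length `n`): a 0/1
membership part, and a similarity part whose entry for miRNA `m` is the
maximum miRNA–miRNA similarity between `m` and the lncRNA's own target set
(1 on its own targets by self-similarity). Each lncRNA's feature vector is
the concatenation (length `2n`) and the pair is scored by cosine
similarity. Indexing both similarity parts over the merged list is the only
construction that makes the two vectors equal-length while preserving the
intended semantics ("how functionally close is each relevant miRNA to this
lncRNA's targets"); it also guarantees similarity 1 for identical target
sets. The max aggregator mirrors the best-match rule of the disease-side
formulas; a mean aggregator is available. miRNA self-similarity is assumed
1 even if the input matrix omits it; missing cross-pairs count as 0.

*Disease-based.* `S(d, DG) = max_{d'∈DG} DSS(d, d')`;
`FS(u,v) = (Σ_{d∈DG_u} S(d,DG_v) + Σ_{d∈DG_v} S(d,DG_u)) /
(|DG_u|+|DG_v|)`. Equal disease sets give FS = 1.

*Expression.* Spearman rank correlation with average ranks on ties
(standard definition). Constant profiles have undefined rank correlation
and are reported as missing, not zero.

### SDNE embedding

The autoencoder takes each node's dense similarity row (diagonal zeroed) as
input. Loss: `‖(X̂−X)⊙B‖²_F + 2α·tr(YᵀLY) + ν·Σ‖W‖²`, with `B_ij = β`
where `x_ij > 0` else 1, `L` the graph Laplacian and `Y` the code layer.
Architecture `n → 128 → 64 → 128 → n`, tanh on hidden layers, linear code
and output. Training is full-batch Adam with analytically derived
gradients. Defaults: `dim = 64` (the dimension found most informative for
this task), `α = 10⁻²`, `β = 5`, `ν = 10⁻⁴`, 200 epochs, learning rate
10⁻², seed 42 — the loss-weight values sit in the ranges of the original
SDNE literature; only the dimension is fixed by the method itself. The
dense similarity matrix is used directly as weighted adjacency (no
sparsification by default; a threshold hook exists). Node labels are
canonically sorted before parameter initialisation, so the embedding is
exactly invariant to input node order and bit-reproducible for a fixed
seed under single-threaded BLAS.

Merging averages the two code vectors of an lncRNA present in both
networks and copies the vector otherwise. Averaging mixes two
independently trained latent frames; this is implemented exactly as
specified by the method, and a per-network standardisation hook was
deliberately left out of the default path after it degraded module
contrast on the synthetic fixture.

### Fusion network, thresholding, RWR

Edge weights are Pearson correlations of merged embedding rows (diagonal
excluded). Thresholding keeps edges with `ρ > sim_coef` *strictly*;
negative correlations never survive a numeric threshold, and
`sim_coef=None` disables expansion entirely (only the original list is
analysed). The walk iterates `p ← (1−r)·Ŵp + r·p₀` with `Ŵ` the
column-normalised thresholded weights, `p₀` uniform over the seeds found
in the network, restart probability `r = 0.7` (common network-propagation
default; all structural properties hold for any `r ∈ (0,1]`), L1 tolerance
10⁻¹⁰, at most 1000 iterations. Dangling columns teleport their mass to
`p₀`, preserving stochasticity. "Probability not 0" is implemented as
`p > 10⁻¹²` to absorb floating-point noise; on small graphs this equals
reachability from the seeds in the thresholded graph. Seeds absent from
the network are reported, not fatal.

### Enrichment

ORA uses the one-sided upper-tail hypergeometric test (equivalent to
one-sided Fisher; Fisher and a binomial approximation are selectable). The
background universe defaults to the union of the library's sets,
configurable to an explicit list. Query symbols outside the universe are
dropped from the draws with a logged count. Raw p-values drive the report
filter (`p < 0.01` by default, strict), mirroring how such reports are
conventionally read; BH-adjusted values are always included alongside. Hit
rates are percentages of a set's members present in the effective query
list, displayed round-half-even to 2 decimals with full precision kept
internally.

## Synthetic fixtures

The generators emulate the shapes of the curated inputs with planted
structure: lncRNAs come in modules (default 3 × 8); each module owns a
pool of miRNAs (40 total) and of diseases (12 total); an lncRNA carries
each own-pool partner with probability 0.8 and each foreign partner with
probability 0.05; the disease ontology places each pool under its own
branch of a common root, so pool mates are semantically close; the
miRNA–miRNA similarity matrix is block-structured (0.6 within pools, 0.1
across, jittered, clipped to [0,1]); expression adds per-lncRNA noise to a
module-specific gamma-distributed tissue profile over 8 tissues. One
integer seed drives independent substreams per generator, making every
artefact a pure function of `(spec, seed)`. The sizes keep the full
pipeline under a few seconds per run.

The case-study scenario seeds the walk with half of module 1 and expects
the other half back. Because the correlation scale of the fused network on
a 24-node fixture is data-dependent (unlike the absolute 0.9 a user picks
on real data), the scenario's expansion threshold is the 85th percentile
of the off-diagonal edge weights: with three equal modules ~30% of pairs
are within-module, so the top 15% of edges are dominated by them.

What passing these tests shows — and does not. The fixture plants exactly
the kind of modular, mutually consistent evidence the method assumes, at a
scale where SDNE has an easy job. Success demonstrates that every stage
preserves planted structure and that the pipeline's machinery (similarity
→ embedding → fusion → walk → ORA) composes correctly; it does not
demonstrate recovery on real databases, where evidence is sparser, modules
overlap, name normalisation matters, and the two association networks
cover different lncRNA subsets. Occasionally a single stray cross-module
edge survives the threshold and the reachability rule then pulls in a
whole second module, diluting the draws and weakening the planted set's
p-value despite a higher hit rate — the same failure mode a too-low
similarity coefficient produces on real data.

## Known limitations

- The SDNE trainer is full-batch and dense; it targets networks of up to a
  few thousand nodes, not genome-scale graphs.
- Averaging embeddings from two independently trained autoencoders has no
  alignment guarantee between latent frames; it follows the method's merge
  rule as stated.
- Name normalisation is limited to whitespace trimming and optional
  case-folding; callers must supply consistently named symbols.
- The expression-based network is exposed but unfused by default (see
  above).
- Whether expansion reduces a set's p-value is a data property, not a
  theorem; it is verified empirically on the planted fixture only.
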