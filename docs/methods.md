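# Methods

## Problem and model

`kfpm` ranks the proteins of a protein–protein interaction (PPI) network by
predicted essentiality. The premise, well established for *S. cerevisiae*,
is twofold: essential proteins tend to be better connected
(centrality–lethality), and purely topological predictors saturate because
PPI data are incomplete and noisy. The method therefore fuses network
topology with three per-protein biological signals — evolutionary
conservation, co-expression with interaction partners, and subcellular
localisation — and lets the fused scores diffuse over a two-layer
protein–domain network, so that a protein is also credited for sitting in
domains (and neighbourhoods) shared with other high-scoring proteins.

### Network construction

With proteins `p_1..p_N` and domains `d_1..d_M`:

* **Weighted PPI block.** For each PPI edge (u, v),
  `WPP(u,v) = |NG(u) ∩ NG(v)|² / ((|NG(u)|+1)(|NG(v)|+1))`, with `NG` the
  PPI neighbourhood; 0 for non-edges and the diagonal. Squaring the
  common-neighbour count emphasises edges inside dense modules. The
  exponent is configurable (`wpp_exponent`, default 2) because the
  alternative reading (exponent 1, a plain normalised overlap) is also a
  sensible scheme; the default is the stronger module-weighting form.
* **Protein–domain block.** `WPD(u,v) = 1` iff protein u carries domain v
  (membership restricted to PPI nodes).
* **Domain–domain block.** For distinct non-empty domains,
  `WDD(u,v) = |N(d_u) ∩ N(d_v)| / (|N(d_u)| · |N(d_v)|)` over their PPI
  protein sets; a cosine-style `1/√(n_u n_v)` denominator is available
  (`wdd_sqrt_denominator`). Diagonals are forced to 0: these networks carry
  no self-edges, and a self-overlap term would otherwise dominate every
  row.
* **Assembly.** `NWPD = [[WPP, WPD], [WPDᵀ, WDD]]`, an (N+M)×(N+M)
  symmetric adjacency, proteins first.

All matrices are scipy.sparse CSR; node order is first-appearance order of
the input files, and every matrix indexes against it.

### Features and CRITIC fusion

* Orthology: `BIO_I(u) = I(u) / max_v I(v)` — orthology counts max-scaled
  to [0, 1].
* Co-expression: `BIO_Exp(u) = Σ_{v ∈ NG(u)} PCC(u, v)` — the sum of
  sample Pearson correlations (1/(n−1) convention) between expression
  profiles of u and its PPI neighbours. A missing or constant profile
  contributes correlation 0 (the σ = 0 case is defined as 0, not NaN).
* Subcellular localisation: compartment i has enrichment
  `Eve(i) = N(i) / (Σ_j N(j) / N_sub)` — its protein count over the mean
  compartment count, counted over PPI proteins against the declared label
  universe — and `BIO_sub(u)` sums `Eve(i)` over u's compartments.

The three columns are fused with CRITIC (Criteria Importance Through
Intercriteria Correlation): weight `W_j ∝ C_j = σ_j Σ_i (1 − |r_ij|)`,
contrast (column SD) times conflict (summed absolute-correlation
complement). Because CRITIC presumes commensurable criteria and `BIO_Exp`
is unbounded while the other two live near [0, 1], each column is min–max
scaled to [0, 1] both before the weight computation and before the
weighted sum `BIO(u) = Σ_j W_j · BF_j(u)` (`critic_raw` disables scaling
for comparison). A constant column has zero contrast and hence weight 0;
if every C_j vanishes the weights fall back to uniform 1/3 with a warning.

### Topology score and initial scores

`TOP(u) = Σ_{v ∈ NG(u)} |NG(u) ∩ NG(v)| / |NG(u)|` — the mean shared-
neighbour count of u with its neighbours — computed on the unweighted
support of the assembled network (`NWPD > 0`), so domain co-membership
contributes shared neighbours. Note the support convention: a PPI edge
whose WPP weight is 0 (no common neighbour) is absent from the support.
`top_on_ppi_only` restricts the neighbourhood to the PPI block.

Initial scores: `S0(p_u) = θ·BIO(p_u) + (1−θ)·TOP(p_u)` with θ = 0.7 by
default; each domain receives the sum of its member proteins' scores,
max-normalised over domains so the best domain scores 1. The domain
normalisation runs over the M domains (the alternative — normalising a
domain score by a maximum taken over proteins — is dimensionally
meaningless).

### Transition matrix and propagation

Each block W is dampened to `W / (1 + max W)²` (global maximum of the
block; a per-entry maximum would make the expression vacuous), then
row-normalised within the block and biased by the target's initial score:
`entry(u,v) = [X(u,v)/Σ_j X(u,j)] · S0(v)`. The four biased blocks form
NDPM. The S0 bias destroys row-stochasticity, so by default every nonzero
row of the assembled NDPM is renormalised to sum to 1 (±1e−12), making the
iteration a proper random walk with restart; `row_renorm=False` iterates
the literal biased matrix instead (it still converges — the spectral
radius only shrinks — but scores lose their probabilistic reading).

Scores iterate as `S(t+1) = α · NDPMᵀ · S(t) + (1−α) · S0` with S0
normalised to sum 1, α = 0.5 by default, stopping when
`‖S(t+1) − S(t)‖² < ε` (ε = 1e−6, cap 1000 iterations; exceeding the cap
raises an error carrying the last residual). The transpose orientation
makes a node's new score aggregate incoming probability mass; with
row-stochastic NDPM the map is an α-contraction, so convergence is
guaranteed and the fixed point equals the closed form
`(1−α)(I − α·NDPMᵀ)⁻¹ S0` — an equivalence the tests verify to 1e−8
against a dense solve on systems with N+M ≤ 50. Final protein scores are
ranked descending, ties broken by protein ID ascending; domain nodes are
discarded.

## Parameters

| parameter | default | meaning |
|---|---|---|
| θ (`theta`) | 0.7 | biology-vs-topology blend in S0 |
| α (`alpha`) | 0.5 | propagation-vs-restart blend |
| ε (`eps`) | 1e−6 | squared-update stopping threshold |
| `max_iter` | 1000 | iteration cap |
| `wpp_exponent` | 2 | exponent on common-neighbour counts in WPP |
| `dampen_exponent` | 2 | exponent on (1 + max W) in dampening |

θ = 0.7 and α = 0.5 are the settings at which the method performs best in
published parameter sweeps; ε has no reported reference value, and 1e−6 on
the *squared* update is tight enough that rank order is stable well before
the cap (typical runs converge in well under 20 iterations).

## Evaluation

Top-k% accuracy uses a half-up nearest-integer cutoff `m = round(k/100·N)`
— the rounding that reproduces the benchmark top-1% set sizes 51/5,093,
37/3,672 and 19/1,855 — and reports `100·|top-m ∩ essential|/m` to two
decimals. The jackknife curve is the cumulative count of true essentials
among the top r ranked proteins. ROC/PR curves and trapezoidal AUC come
from scikit-learn over the score ordering (ties grouped by threshold);
the suite cross-checks the AUC against a Mann–Whitney pairwise-comparison
count. Pairwise method comparison reports top-n intersection and the
percentage of essentials in each exclusive set, with an explicit emptiness
flag instead of 0/0.

## Synthetic data

The generator plants a fraction of essential proteins and gives them the
asymmetries the method exploits:

* **Graph:** preferential attachment (3 edges per incoming node → mean
  degree ≈ 6, the order of curated yeast interactomes) where an existing
  node's attachment weight is `(degree+1)·(1 + hub_bonus·essential)`;
  `hub_bonus = 1` yields roughly twice the mean degree for essentials,
  matching the strength of the centrality–lethality effect.
* **Expression:** length-36 profiles; essentials load on one shared latent
  factor with loading 0.8 (expected essential–essential PCC ≈ 0.64, strong
  co-expression), background profiles are white noise.
* **Orthology:** Poisson counts, mean 12 for essentials vs 2 for
  background — conserved vs sparsely conserved on an InParanoid-like
  scale.
* **Subcellular:** 11 compartments; essentials draw 80% of their 1–3
  labels from 3 designated compartments.
* **Domains:** 60 domains of mean size 8 sampling members with 3× weight
  on essentials, producing essential-dense domains.

A seed fixes every output bit-for-bit. `null_config()` switches every
asymmetry off, giving an exchangeable null under which top-k accuracy sits
at the base essential rate — the suite checks both regimes. The generator
deliberately does **not** reproduce real interactome degree distributions,
assortativity, expression periodicity, or annotation sparsity (>95% but
incomplete expression coverage in curated data); passing recovery tests
shows the pipeline extracts planted multi-channel signal, not that its
accuracy on real yeast data matches published figures, which depend on the
curated database extracts.

## Numerical choices and degenerate inputs

* Pearson correlation with any zero-variance vector is 0 by definition
  here; consequently proteins without expression data simply contribute
  nothing.
* Proteins missing from an auxiliary table score 0 on that feature;
  auxiliary entries for proteins outside the PPI node set are ignored.
* Isolated nodes produce all-zero matrix rows end to end (never NaN) and
  finish with the minimum restart mass.
* All-zero domain scores, an all-zero feature column, or an all-identical
  feature table degrade gracefully (zeros, zero weight, uniform weights)
  with logged warnings.
* Ranking files print 6-decimal scores; reading one back re-applies the
  ID-ascending tie rule within equal printed scores.

## Test and acceptance problem sizes

Unit and property tests run on graphs of up to ~30 nodes where brute-force
set-intersection and dense linear-solve oracles are exact; pipeline-level
tests use bundles of 150–500 proteins with 15–60 domains and 10–20 seeds,
sizes at which the planted-signal statistics are stable while the full
suite stays fast. `scripts/acceptance.py` measures the pipeline on ten
500-protein strong-signal bundles.

## Known limitations

* The two documented formula variants (`wpp_exponent`, row renormalisation)
  cannot be settled from the published description; defaults follow the
  readings argued above, and both paths are implemented and tested.
* Accuracy figures on synthetic bundles are not comparable to figures
  obtained on curated yeast datasets; the package does not ship or
  download those datasets (users supply pre-extracted TSVs).
* Competing centrality methods are not re-implemented; external rankings
  can be compared via `ranking_difference` and the evaluate CLI.
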