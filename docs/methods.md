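# Methods

## Random walk with restart

The association score of gene *i* is the *i*-th entry of the stationary
vector of *p*ₜ₊₁ = (1 − γ)*W p*ₜ + γ*p₀*, where *W* is the
column-normalised adjacency matrix of a simple undirected gene network and
*p₀* puts mass 1/|S| on each seed gene. The model assumes the network is
binary and unweighted (edge = functional interaction), that association is
symmetric along edges, and that restart mass keeps the walk localised
around the seeds; γ trades off locality (γ → 1) against diffusion
(γ → 0).

* **γ (restart probability).** Default 0.5, a mandatory, recorded
  parameter. There is no canonical value; 0.5 balances seed locality and
  network exploration, and every output records the value used.
* **Convergence.** The iteration stops when the L1 norm of
  *p*ₜ₊₁ − *p*ₜ falls below `tol` (default 1e−10, configurable), with a
  hard cap of 10 000 iterations; non-convergence raises an error carrying
  the last residual. A per-entry threshold of 10⁻³⁰ is below
  double-precision resolution, so the residual is defined on the norm.
* **Isolated nodes.** Degree-0 nodes have all-zero transition columns
  (flagged at normalisation); mass reaching them leaves only through the
  restart term, so they score 0 unless seeded.
* **Geometry of the solution.** The iteration converges to
  γ(I − (1 − γ)W)⁻¹p₀; the dense direct solve is implemented separately
  (`solve_rwr_linear`) and serves as an internal cross-check, not as the
  production path (the iterative solver scales to large sparse networks).

## Centrality baselines

Degree is the count of distinct neighbours. Betweenness sums, over each
unordered pair {s, t} in the same component with s ≠ t ≠ i, the fraction
of shortest s–t paths through *i* (endpoints excluded; counting each pair
once rather than twice rescales all values by a constant and changes no
ranking). Eigenvector centrality is the principal eigenvector of the
adjacency matrix of the largest connected component, computed by power
iteration on A + I — the shift leaves the eigenvector unchanged but breaks
the ±λ oscillation on bipartite graphs — from a fixed all-ones start for
determinism, max-normalised to 1; nodes outside the component get 0.

## Ranking

Genes are ranked by descending score with average ranks on ties;
percentile(g) = 100·rank(g)/n ∈ (0, 100]. For top-k selections, boundary
ties are broken lexicographically by gene identifier so results are
reproducible across platforms.

## GSEA

The preranked enrichment score is the classic weighted Kolmogorov–Smirnov
running-sum extremum: hits advance by |score|^w (normalised to total 1,
default weight w = 1), misses retreat by 1/(N − N_h). The null is a
gene-label permutation (random same-size subsets of the universe):
phenotype permutation is undefined for a ranking, and the responder
cohorts this targets are small, so gene-label permutation is used for the
two-group analysis as well; output metadata records the scheme. The
nominal p-value is sign-conditional with add-one smoothing,
(1 + #{same-sign permuted ES at least as extreme}) / (1 + #{same-sign
permuted ES}) — a mixture of the two sign-conditional uniforms, hence
calibrated under the null — and NES divides the ES by the mean |permuted
ES| of the same sign. Gene sets with ranked-universe overlap outside
[5, 2000] are skipped and logged. The two-group ranking metric is the
signal-to-noise ratio with each group SD floored at 0.2·|group mean| (0.2
when the mean is zero); log2 fold-change is available by flag.

## Truncated product combination

For the two p-values (association, deregulation), w = Π pᵢ^I(pᵢ ≤ τ) with
τ = 0.01 by default. For w < 1 the null probability conditions on the
number k of components at or below τ:

Pr(W ≤ w) = Σₖ₌₁² C(2,k)(1−τ)^{2−k}·[ w·Σₛ₌₀^{k−1}(k ln τ − ln w)ˢ/s!
if w ≤ τᵏ, else τᵏ ]

and Pr(W ≤ 1) = 1 when no component passes τ. Two checks pin the
implementation: at τ = 1 it collapses to Fisher's two-test closed form
w(1 − ln w), and Monte Carlo over uniform pairs reproduces it to within
sampling error. Note the combined p has an atom at 1 of mass (1 − τ)² and
continuous support (0, 1 − (1 − τ)²]; with τ = 0.01 no combined p between
≈0.02 and 1 can occur, which is the intended behaviour of the truncation
(calibration checks therefore use significance levels within the
continuous support, or a larger τ).

## ssGSEA and the MIAS

For one sample, genes are ordered by decreasing expression; the raw score
sums, over all positions, the difference between the in-signature ECDF
weighted by (expression rank)^α and the uniform out-of-signature ECDF.
Weights use within-sample ranks, not expression values, so any monotone
transformation of a sample's profile leaves its raw score unchanged —
which makes the score robust to per-sample normalisation differences
across platforms. α defaults to 0.25; normalisation divides the raw
scores by their cohort range (max − min), giving the NES that is the MIAS.
Cohort-range normalisation means MIAS values are comparable within, not
across, scored cohorts. Scoring can be restricted to a supplied common
gene universe (the cross-platform intersection) and errors if fewer than
50% (configurable) of the signature genes are measurable.

## Signature selection and integration

Immune correlations default to Spearman (expression is heavy-tailed and
every downstream use is rank-based; Pearson by flag), computed after
quantile normalisation when the input is counts/TPM and on the given
values for pre-normalised input; the path taken is recorded. The
immune-positive/negative selections intersect the top 10% of the
association ranking with correlation ≥ +0.2 / ≤ −0.2. The signature takes
the `n_signature` = 100 smallest MR_g = √(r1_g·r2_g). Copy-number states
use strict thresholds (log2 ratio > 0.5 gain, < −0.5 loss, boundaries
neutral); "recurrently altered" defaults to ≥ 3 altered samples per
alteration type (no canonical value exists; 3 excludes singletons and
doubletons while keeping cohort-scale recurrences). Drug–target mapping
joins only against the immune-negative set: those genes mark immune
suppression when highly expressed, so their inhibitors are the candidate
combination partners. Predictor integration rank-products two per-sample
scores (both oriented higher = responder).

## Synthetic data: what it emulates and what it does not

* `simulate_network` (defaults n = 1000 nodes, Barabási–Albert attachment
  m = 3, planted module of 50 with internal edge probability 0.6, 5 seed
  genes inside the module) emulates the scale-free degree structure of
  curated interactomes and a functionally coherent seed pathway. Defaults
  are desk-scale: large enough that the top decile (100 genes) is a
  meaningful target for the 45 non-seed module genes, small enough that a
  run takes well under a second.
* `simulate_expression_cohort` (2000 genes × 300 samples, 5% immune-
  positive and 5% immune-negative genes at target correlation 0.5)
  emulates a TCGA-like training cohort: a standard-normal latent immune
  axis z per sample, signal genes a·z + noise with a = ρ/√(1 − ρ²), all on
  a log scale exponentiated to nonnegative values (log-normal expression;
  downstream analysis is rank-based and real pipelines quantile-normalise,
  so only the ranks matter). ρ = 0.5 places planted genes clearly above
  the |ρ| ≥ 0.2 selection threshold while leaving null genes mostly below
  it at n = 300–500.
* `simulate_response_cohort` (30 responders / 30 non-responders, effect
  1.5 SD on the signature genes) emulates a treated melanoma cohort at the
  size of a single published dataset. The 1.5 SD planted effect is an
  idealisation chosen to test the machinery at high power; the 0 SD
  condition tests the null.
* `simulate_full_study` wires the three together on one 1500-gene
  universe: a 200-gene module containing the seeds, of which 100 non-seed
  genes are also immune-positive (the true signature), plus 100
  immune-positive and 100 immune-negative genes outside the module. By
  construction neither network proximity nor immune correlation alone
  identifies the true signature — only the rank-product of both does —
  which is what the evidence-ablation comparison exercises (the ablation
  runs use a 1.0 SD effect so the full model is off the AUC ceiling;
  20 replicates).

None of the generators model dropout, batch effects, tumour purity,
cell-type composition, mutational processes or realistic pathway overlap.
Passing the recovery tests therefore shows the pipeline is correct and
well-calibrated under its own assumptions, not that the signature
generalises to real cohorts.

## Numerical and interface choices

* Node order is lexicographic everywhere a matrix is built; all
  permutation-based statistics take an explicit seed and are reproducible
  bit-for-bit.
* Preranked ES with all-zero hit weights (possible at weight 1 when all
  hit scores are 0) falls back to equal hit weights rather than 0/0.
* The Mann–Whitney p is exact by enumeration for combined n ≤ 20 without
  ties, otherwise the normal approximation with tie correction; the route
  is recorded in the result. One-sided direction conventions are stated
  in every result object.
* Gene identifiers are opaque case-sensitive strings; no symbol mapping
  is attempted. TSV dialect: tab-delimited UTF-8, '.' decimal, '#'
  comments. Every CLI run writes a JSON manifest (parameters, input
  checksums, version) sufficient to reproduce it.
* The default seed gene set is {HLA-A, HLA-B, HLA-C, PDCD1, CD274},
  fully configurable; well-known MHC I accessory genes such as TAP1 and
  B2M are deliberately not seeds so that recovering them remains a
  prediction, not an input.

## Known limitations

* Unweighted, undirected networks only; confidence scores on edges are
  ignored by design.
* Gene-label permutation underestimates inter-gene correlation relative
  to phenotype permutation; nominal p-values from the deregulation
  analysis are calibrated under the independence null only.
* No multiple-testing correction across gene sets (nominal p-values are
  reported, matching the combination step's input contract).
* ESTIMATE-style immune scores, RECIST adjudication and segment-to-gene
  copy-number conversion are consumed as inputs, never computed.
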