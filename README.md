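# netmias

Network guilt-by-association prediction of genes and pathways associated
with response to anti-PD-1 immunotherapy, and the **MIAS** (MHC I
association immunoscore) per-patient response predictor.

## The problem and who this is for

Tumours evade T-cell killing by disrupting MHC class I antigen
presentation, and response to PD-1/PD-L1 checkpoint blockade depends on
genes functionally coupled to that pathway. `netmias` is for computational
biologists who want to (a) prioritise genes by network proximity to the MHC
I pathway in a molecular interaction network, (b) identify pathways that
are both network-associated with MHC I and deregulated between responders
and non-responders, and (c) build and apply a transcriptomic response
signature for patients treated with anti-PD-1.

## The method

**Association scores.** Given an undirected gene network with
column-normalised adjacency matrix *W* and a seed set (by default the MHC I
heavy chains HLA-A/B/C plus *PDCD1* and *CD274*) carrying uniform initial
mass *p₀*, a random walk with restart is iterated to stationarity:

> *p*ₜ₊₁ = (1 − γ) *W p*ₜ + γ *p₀*

with restart probability γ (default 0.5). The stationary probabilities are
the per-gene **MHC I association scores**; degree, betweenness and
eigenvector centrality are provided as baselines.

**Pathway association.** For each gene set, a preranked GSEA enrichment
score over the association ranking (association analysis) and a
two-group GSEA over responder/non-responder expression ranked by
signal-to-noise ratio (deregulation analysis) give two p-values, combined
by the truncated product method: *w* = Π pᵢ^I(pᵢ ≤ τ) with τ = 0.01,
referred to its analytic null distribution.

**The MIAS signature and score.** In an expression cohort with per-sample
immune-infiltration scores (e.g. ESTIMATE, consumed as input), every
gene gets an immune correlation. With *r1* = association rank and *r2* =
immune-correlation rank, the rank-product merge

> MR_g = (r1_g × r2_g)^{1/2}

selects the 100 genes with smallest MR as the signature. A sample's MIAS
is the ssGSEA normalised enrichment score of the signature in its
expression profile; higher MIAS predicts response (CR/PR vs SD/PD).
Evaluation uses ROC/AUC, the one-sided Wilcoxon–Mann–Whitney test,
one-sided hypergeometric overlap, and Spearman rank agreement.

Because the original network, TCGA and patient cohorts are external data,
the package ships generators that plant known ground truth: a scale-free
network with a dense seed-proximal module, an expression cohort with a
latent immune axis, and a response cohort with a signature effect. See
`docs/methods.md` for model details and limitations.

## Worked example

```python
import netmias as nm

study = nm.simulate_full_study(rng_seed=1)      # planted ground truth
assoc = nm.random_walk_with_restart(
    nm.column_normalize(study["network"]), study["seeds"], gamma=0.5)
ranked = nm.rank_and_percentile(assoc.scores)
print(ranked.table.head(3).to_string(index=False))

corr = nm.immune_correlation(study["expression"], study["immune"])
sig = nm.select_mias_signature(ranked, corr, n_signature=100)
print("recovered:", len(set(sig.genes) & set(study["true_signature"])))

mias = nm.mias_score(study["cohort_expression"], sig)
y = (study["labels"]["response"] == "response").astype(int)
roc = nm.roc_auc(mias.loc[y.index].values, y.values)
mwu = nm.mann_whitney_one_sided(mias[y == 1].values, mias[y == 0].values)
print(f"MIAS AUC = {roc.auc:.3f}   one-sided Wilcoxon p = {mwu.p_value:.2e}")
```

prints

```
  gene    score  rank  percentile
G01490 0.102547   1.0    0.066667
G01431 0.102472   2.0    0.133333
G00429 0.102165   3.0    0.200000
recovered: 71
MIAS AUC = 1.000   one-sided Wilcoxon p = 1.51e-11
```

The top-ranked genes are members of the planted seed-proximal module
(high stationary probability ⇒ network-proximal to the seeds); 71 of the
100 selected signature genes are truly planted; and the MIAS separates the
simulated responders from non-responders essentially perfectly at the
planted 1.5 SD effect.

The same stages run from the shell via the `netmias` umbrella command
(`associate`, `centrality`, `gsea`, `combine-p`, `ssgsea`, `select`,
`mias`, `evaluate`, `overlap`, `drugs`, `simulate`, `run`); every run
writes a JSON manifest with parameters and input checksums.

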