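"""Gene-set enrichment statistics and p-value combination.

Three enrichment flavours feed the pipeline:

* *association* GSEA — a preranked analysis over the gene list ordered by
  network association score, asking whether a pathway's members crowd the
  top (or bottom) of that ranking;
* *deregulation* GSEA — a two-group analysis over an expression cohort
  (responders vs non-responders), ranking genes by signal-to-noise ratio and
  reusing the preranked machinery;
* single-sample GSEA (ssGSEA) — a per-sample enrichment score of a fixed
  signature, used to turn the 100-gene signature into the per-patient MIAS.

The association and deregulation p-values for a pathway are combined with
the truncated product method: the product of the p-values not exceeding a
truncation threshold tau, referred to its analytic null distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...]

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene-set names in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p_value: float
    n_perm: int
    overlap: int
    metadata: dict = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class CombinedPValue:
    """Truncated-product combination of two p-values.

    ``w`` is the product of the components at or below ``tau`` (1 if none
    pass), and ``probability`` is Pr(W <= w) under independent uniforms.
    """

    w: float
    tau: float
    probability: float
    components: tuple[float, float]


# ---------------------------------------------------------------------------
# Preranked (weighted Kolmogorov–Smirnov) enrichment
# ---------------------------------------------------------------------------

def _ordered_scores(ranked) -> tuple[np.ndarray, np.ndarray]:
    """Descending score order with lexicographic tie-break; returns
    (gene array, score array)."""
    tbl = ranked.table
    return tbl["gene"].to_numpy(), tbl["score"].to_numpy(dtype=float)


def _running_sum_es(hit_mask: np.ndarray, scores: np.ndarray,
                    weight_exponent: float) -> float:
    """Signed extremum of the weighted KS running sum for one hit mask."""
    n = hit_mask.size
    n_h = int(hit_mask.sum())
    if n_h == 0 or n_h == n:
        raise ValueError("gene set must hit a strict subset of the universe")
    w = np.abs(scores) ** weight_exponent
    hit_w = w * hit_mask
    denom = hit_w.sum()
    if denom == 0:  # all hit scores are zero: fall back to equal hit weights
        hit_w = hit_mask.astype(float)
        denom = float(n_h)
    inc = hit_w / denom - (~hit_mask.astype(bool)).astype(float) / (n - n_h)
    run = np.cumsum(inc)
    return float(run[np.argmax(np.abs(run))])


def preranked_es(ranked, gene_set: GeneSet, weight_exponent: float = 1.0) -> float:
    """Enrichment score of ``gene_set`` against a ranked gene list.

    Hits step the running sum up by |score|^weight_exponent (normalised so
    the hit increments total 1); misses step it down by 1/(N - N_hits).  The
    ES is the signed extremum of the running sum.
    """
    genes, scores = _ordered_scores(ranked)
    hit = np.isin(genes, list(gene_set.genes))
    if not hit.any():
        raise ValueError(f"gene set {gene_set.name!r} absent from universe")
    if hit.all():
        raise ValueError("ranked universe must be strictly larger than the overlap")
    return _running_sum_es(hit, scores, weight_exponent)


def _batch_permuted_es(scores: np.ndarray, k: int, n_perm: int,
                       weight_exponent: float, rng: np.random.Generator
                       ) -> np.ndarray:
    """ES of ``n_perm`` random k-subsets of the universe (gene-label
    permutation null), vectorised across permutations."""
    n = scores.size
    w = np.abs(scores) ** weight_exponent
    hit = np.zeros((n_perm, n), dtype=bool)
    for row in range(n_perm):  # loop only over perms; cumsum is vectorised
        hit[row, rng.choice(n, size=k, replace=False)] = True
    hit_w = hit * w
    denom = hit_w.sum(axis=1, keepdims=True)
    zero = denom.ravel() == 0
    if zero.any():
        hit_w[zero] = hit[zero].astype(float)
        denom = hit_w.sum(axis=1, keepdims=True)
    inc = hit_w / denom - (~hit) / (n - k)
    run = np.cumsum(inc, axis=1)
    pick = np.argmax(np.abs(run), axis=1)
    return run[np.arange(n_perm), pick]


def _nominal_p_and_nes(es: float, perm_es: np.ndarray) -> tuple[float, float]:
    """Sign-conditional nominal p with add-one smoothing, and NES.

    p = (1 + #{perm ES of the same sign, at least as extreme})
        / (1 + #{perm ES of the same sign});
    NES = ES / mean |same-sign perm ES| (falls back to mean |perm ES| when
    no permutation lands on the observed side).
    """
    same = perm_es >= 0 if es >= 0 else perm_es < 0
    n_same = int(same.sum())
    extreme = int((np.abs(perm_es[same]) >= abs(es)).sum())
    p = (1 + extreme) / (1 + n_same)
    ref = np.abs(perm_es[same]).mean() if n_same else np.abs(perm_es).mean()
    nes = es / ref if ref > 0 else np.nan
    return p, float(nes)


def gsea_association(ranked, sets: GeneSetCollection, n_perm: int = 1000,
                     rng_seed: int = 0, weight_exponent: float = 1.0,
                     min_size: int = 5, max_size: int = 2000
                     ) -> list[EnrichmentResult]:
    """Preranked GSEA of each gene set against an association ranking.

    The null is a gene-label permutation: ``n_perm`` random same-size
    subsets of the ranked universe.  Results are reproducible bit-for-bit
    for a fixed ``rng_seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    genes, scores = _ordered_scores(ranked)
    universe = set(genes)
    rng = np.random.default_rng(rng_seed)
    results = []
    for gs in sets:
        overlap = gs.genes & universe
        if not (min_size <= len(overlap) <= max_size):
            logger.info("skipping %s: overlap %d outside [%d, %d]",
                        gs.name, len(overlap), min_size, max_size)
            continue
        hit = np.isin(genes, list(overlap))
        es = _running_sum_es(hit, scores, weight_exponent)
        perm = _batch_permuted_es(scores, len(overlap), n_perm,
                                  weight_exponent, rng)
        p, nes = _nominal_p_and_nes(es, perm)
        results.append(EnrichmentResult(
            name=gs.name, es=es, nes=nes, p_value=p, n_perm=n_perm,
            overlap=len(overlap),
            metadata={"permutation": "gene_label",
                      "weight_exponent": weight_exponent},
        ))
    return results


# ---------------------------------------------------------------------------
# Two-group (deregulation) enrichment
# ---------------------------------------------------------------------------

def signal_to_noise(expr: pd.DataFrame, groups: pd.Series,
                    sd_floor_frac: float = 0.2) -> pd.Series:
    """Per-gene signal-to-noise ratio between two sample groups.

    (mean_1 - mean_0) / (sd_1 + sd_0), with each group SD floored at
    ``sd_floor_frac`` * |group mean| (and at ``sd_floor_frac`` when the mean
    is zero) — the classic GSEA variance stabilisation.
    """
    g = groups.reindex(expr.columns)
    m1 = expr.loc[:, g.values.astype(bool)]
    m0 = expr.loc[:, ~g.values.astype(bool)]
    if m1.shape[1] < 3 or m0.shape[1] < 3:
        raise ValueError("each group needs at least 3 samples")

    def _floored_sd(m):
        sd = m.std(axis=1, ddof=1)
        mean = m.mean(axis=1)
        floor = sd_floor_frac * mean.abs()
        floor[floor == 0] = sd_floor_frac
        return np.maximum(sd, floor), mean

    s1, mu1 = _floored_sd(m1)
    s0, mu0 = _floored_sd(m0)
    denom = s1 + s0
    if (denom == 0).all():
        raise ValueError("degenerate groups: zero variance in all genes")
    return (mu1 - mu0) / denom


def gsea_deregulation(expr: pd.DataFrame, groups: pd.Series,
                      sets: GeneSetCollection, n_perm: int = 1000,
                      rng_seed: int = 0, weight_exponent: float = 1.0,
                      ranking_metric: str = "snr",
                      min_size: int = 5, max_size: int = 2000
                      ) -> list[EnrichmentResult]:
    """GSEA of gene sets against a two-group expression contrast.

    Genes are ranked by signal-to-noise ratio (or log2 fold-change with
    ``ranking_metric='lfc'``), then the preranked machinery is applied with
    a gene-label permutation null.
    """
    from .network import rank_and_percentile

    if ranking_metric == "snr":
        metric = signal_to_noise(expr, groups)
    elif ranking_metric == "lfc":
        g = groups.reindex(expr.columns).values.astype(bool)
        metric = np.log2(expr.loc[:, g].mean(axis=1) + 1) - np.log2(
            expr.loc[:, ~g].mean(axis=1) + 1)
    else:
        raise ValueError(f"unknown ranking metric {ranking_metric!r}")
    ranked = rank_and_percentile(metric)
    out = gsea_association(ranked, sets, n_perm=n_perm, rng_seed=rng_seed,
                           weight_exponent=weight_exponent,
                           min_size=min_size, max_size=max_size)
    return [EnrichmentResult(
        name=r.name, es=r.es, nes=r.nes, p_value=r.p_value, n_perm=r.n_perm,
        overlap=r.overlap,
        metadata={**r.metadata, "ranking_metric": ranking_metric},
    ) for r in out]


# ---------------------------------------------------------------------------
# Truncated product combination
# ---------------------------------------------------------------------------

def truncated_product(p_assoc: float, p_dereg: float,
                      tau: float = 0.01) -> CombinedPValue:
    """Combine two p-values by the truncated product method.

    w is the product of the components not exceeding tau (w = 1 when neither
    passes, with Pr defined as 1).  For w < 1 the null probability
    conditions on k, the number of components below tau (L = 2 tests):

        Pr(W <= w) = sum_{k=1}^{2} C(2,k) (1-tau)^{2-k} *
                     [ w * sum_{s=0}^{k-1} (k ln tau - ln w)^s / s!
                                                  if w <= tau^k,
                       tau^k                      otherwise ]
    """
    ps = (p_assoc, p_dereg)
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    w = 1.0
    for p in ps:
        if p <= tau:
            w *= p
    if w == 1.0:
        return CombinedPValue(w=1.0, tau=tau, probability=1.0, components=ps)
    prob = 0.0
    ln_w = math.log(w)
    ln_tau = math.log(tau)
    for k in (1, 2):
        if w <= tau ** k:
            inner = w * sum((k * ln_tau - ln_w) ** s / math.factorial(s)
                            for s in range(k))
        else:
            inner = tau ** k
        prob += math.comb(2, k) * (1 - tau) ** (2 - k) * inner
    return CombinedPValue(w=w, tau=tau, probability=min(prob, 1.0),
                          components=ps)


# ---------------------------------------------------------------------------
# Single-sample GSEA
# ---------------------------------------------------------------------------

def _ssgsea_raw_es(expr_col: np.ndarray, hit: np.ndarray, alpha: float) -> float:
    """Raw ssGSEA enrichment of one sample: the summed gap between the
    rank-weighted in-set ECDF and the uniform out-of-set ECDF."""
    n = expr_col.size
    # rank n = highest expression; average ranks keep ties order-invariant
    ranks = rankdata(expr_col, method="average")
    order = np.lexsort((np.arange(n), -ranks))  # descending expression
    hit_ord = hit[order]
    w = ranks[order] ** alpha
    in_w = np.where(hit_ord, w, 0.0)
    p_in = np.cumsum(in_w) / in_w.sum()
    p_out = np.cumsum(~hit_ord) / (n - hit_ord.sum())
    return float(np.sum(p_in - p_out))


def ssgsea_scores(expr: pd.DataFrame, signature: GeneSet,
                  alpha: float = 0.25) -> pd.Series:
    """Per-sample normalised ssGSEA enrichment of a signature.

    Raw per-sample scores use rank weights (so any monotone transform of a
    sample's expression leaves its raw ES unchanged); normalisation divides
    by the cohort range (max - min) of the raw scores, giving the NES used
    as the MIAS.
    """
    hit = expr.index.isin(signature.genes)
    if not hit.any():
        raise ValueError(f"signature {signature.name!r} absent from matrix")
    if expr.shape[1] < 2:
        raise ValueError("cohort normalisation needs at least 2 samples")
    vals = expr.to_numpy(dtype=float)
    raw = np.array([_ssgsea_raw_es(vals[:, j], hit, alpha)
                    for j in range(vals.shape[1])])
    spread = raw.max() - raw.min()
    nes = raw / spread if spread > 0 else np.zeros_like(raw)
    return pd.Series(nes, index=expr.columns, name="NES")
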