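"""Immune-correlation filtering, the rank-product MIAS signature, and
per-sample MIAS scoring.

The signature-selection step merges two lines of evidence for every gene:
its rank in the network association prediction (r1, 1 = most associated
with the MHC I seed pathway) and its rank by correlation of expression with
an externally computed immune-infiltration score (r2, 1 = most positively
correlated).  The merged rank-product score

    MR_g = sqrt(r1_g * r2_g)

selects the signature: the ``n_signature`` (default 100) genes with the
smallest MR.  A sample's MIAS is then the ssGSEA normalised enrichment
score of that signature in the sample's expression profile; higher MIAS
predicts response to anti-PD-1 therapy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .enrichment import GeneSet, ssgsea_scores
from .network import RankedList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImmuneCorrelationProfile:
    """Per-gene correlation of expression with the immune score.

    Zero-variance genes carry NaN and are listed in ``missing_genes``.
    """

    correlations: pd.Series
    method: str
    missing_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ImmuneGeneSelection:
    positive_genes: frozenset[str]
    negative_genes: frozenset[str]
    top_fraction: float
    corr_threshold: float


@dataclass(frozen=True)
class MiasSignature:
    """Rank-product signature: genes sorted ascending by merged rank MR."""

    table: pd.DataFrame = field(repr=False)  # gene, r1, r2, mr (sorted by mr)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.table["gene"])

    def as_gene_set(self, name: str = "MIAS_signature") -> GeneSet:
        return GeneSet(name=name, description="rank-product signature",
                       genes=frozenset(self.genes))


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Convert raw read counts to transcripts per million.

    TPM_gs = 1e6 * (c_gs / len_g) / sum_g (c_gs / len_g); every sample
    column sums to 1e6.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {sorted(missing)}")
    lengths = gene_lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    return 1e6 * rate / rate.sum(axis=0)


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise samples to a common (mean-of-sorted) distribution."""
    ranks = expr.rank(axis=0, method="average")
    sorted_mean = np.sort(expr.to_numpy(dtype=float), axis=0).mean(axis=1)
    # average ranks map onto the reference by linear interpolation
    positions = np.arange(1, expr.shape[0] + 1)
    out = np.empty_like(expr.to_numpy(dtype=float))
    for j in range(expr.shape[1]):
        out[:, j] = np.interp(ranks.iloc[:, j].to_numpy(), positions, sorted_mean)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def immune_correlation(expr: pd.DataFrame, immune: pd.Series,
                       method: str = "spearman",
                       normalize: bool | None = None,
                       unit: str = "TPM") -> ImmuneCorrelationProfile:
    """Correlate each gene's expression with the immune-infiltration score.

    ``normalize=None`` quantile-normalises counts/TPM input and leaves
    pre-normalised matrices untouched.  Genes with zero expression variance
    are flagged missing (NaN correlation).
    """
    shared = expr.columns.intersection(immune.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    x = expr.loc[:, shared]
    if normalize is None:
        normalize = unit in ("counts", "TPM")
    if normalize:
        x = quantile_normalize(x)
    y = immune.loc[shared].to_numpy(dtype=float)
    xv = x.to_numpy(dtype=float)
    if method == "spearman":
        xv = np.apply_along_axis(rankdata, 1, xv)
        y = rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    xc = xv - xv.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc @ yc) / (sx * sy)
    corr = pd.Series(corr, index=expr.index)
    missing = tuple(corr.index[corr.isna()])
    if missing:
        logger.info("%d zero-variance gene(s) flagged missing", len(missing))
    return ImmuneCorrelationProfile(correlations=corr, method=method,
                                    missing_genes=missing)


def _top_fraction_genes(assoc: RankedList, top_fraction: float) -> list[str]:
    n_top = int(np.floor(len(assoc.table) * top_fraction))
    # table is already sorted by rank then gene id (deterministic ties)
    return list(assoc.table["gene"].iloc[:n_top])


def select_immune_genes(assoc: RankedList, corr: ImmuneCorrelationProfile,
                        top_fraction: float = 0.10,
                        corr_threshold: float = 0.2) -> ImmuneGeneSelection:
    """Immune-positive/negative genes: top association decile intersected
    with |immune correlation| >= threshold (sign split)."""
    universe = set(assoc.genes) & set(corr.correlations.index)
    if not universe:
        raise ValueError("association ranking and correlation profile share no genes")
    top = [g for g in _top_fraction_genes(assoc, top_fraction) if g in universe]
    c = corr.correlations
    pos = frozenset(g for g in top if c[g] >= corr_threshold)
    neg = frozenset(g for g in top if c[g] <= -corr_threshold)
    if not pos and not neg:
        logger.info("no gene passed |corr| >= %.3g in the top fraction",
                    corr_threshold)
    return ImmuneGeneSelection(positive_genes=pos, negative_genes=neg,
                               top_fraction=top_fraction,
                               corr_threshold=corr_threshold)


def select_mias_signature(assoc: RankedList, corr: ImmuneCorrelationProfile,
                          n_signature: int = 100) -> MiasSignature:
    """Rank-product signature selection (MR_g = sqrt(r1_g * r2_g)).

    r1: association rank (1 = most associated); r2: rank by immune
    correlation descending (1 = most positive).  Boundary ties are broken
    lexicographically by gene id.
    """
    shared = assoc.scores.index.intersection(corr.correlations.index)
    shared = pd.Index([g for g in shared
                       if not np.isnan(corr.correlations[g])])
    if len(shared) < n_signature:
        raise ValueError(
            f"shared universe ({len(shared)}) smaller than signature size "
            f"({n_signature})")
    r1 = pd.Series(rankdata(-assoc.scores.loc[shared].to_numpy(),
                            method="average"), index=shared)
    r2 = pd.Series(rankdata(-corr.correlations.loc[shared].to_numpy(),
                            method="average"), index=shared)
    mr = np.sqrt(r1 * r2)
    tbl = pd.DataFrame({"gene": shared, "r1": r1.values, "r2": r2.values,
                        "mr": mr.values})
    tbl = tbl.sort_values(["mr", "gene"], kind="mergesort").head(n_signature)
    return MiasSignature(table=tbl.reset_index(drop=True))


def ablated_signature(assoc: RankedList, corr: ImmuneCorrelationProfile,
                      scenario: str, n_signature: int = 100,
                      rng: np.random.Generator | None = None) -> MiasSignature:
    """Signature under one of the four evidence scenarios.

    ``full`` uses both rank sources; ``no_immune`` randomises the immune
    correlations (network association only); ``no_network`` randomises the
    association scores (immune correlation only); ``random`` randomises
    both.  Randomised components are drawn with ``rng``.
    """
    if scenario not in {"full", "no_immune", "no_network", "random"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = rng or np.random.default_rng()
    a_scores = assoc.scores.copy()
    c_series = corr.correlations.copy()
    if scenario in ("no_network", "random"):
        a_scores[:] = rng.permutation(a_scores.values)
    if scenario in ("no_immune", "random"):
        c_series[:] = rng.permutation(c_series.values)
    from .network import rank_and_percentile

    return select_mias_signature(
        rank_and_percentile(a_scores),
        ImmuneCorrelationProfile(correlations=c_series, method=corr.method),
        n_signature=n_signature)


def mias_score(expr: pd.DataFrame, signature: MiasSignature,
               alpha: float = 0.25, min_overlap_frac: float = 0.5,
               universe: list[str] | None = None) -> pd.Series:
    """Per-sample MIAS: ssGSEA NES of the signature genes.

    ``universe`` optionally restricts scoring to genes shared by all
    platforms under comparison.  Errors if fewer than
    ``min_overlap_frac`` of the signature genes are measurable.
    """
    x = expr.loc[expr.index.intersection(universe)] if universe is not None else expr
    overlap = len(set(signature.genes) & set(x.index))
    if overlap < min_overlap_frac * len(signature.genes):
        raise ValueError(
            f"signature overlap too small: {overlap}/{len(signature.genes)} "
            f"genes present (need >= {min_overlap_frac:.0%})")
    scores = ssgsea_scores(x, signature.as_gene_set(), alpha=alpha)
    return scores.rename("MIAS")


def integrate_predictions(scores_a: pd.Series, scores_b: pd.Series) -> pd.DataFrame:
    """Rank-product merge of two per-sample predictors.

    Both inputs must be oriented higher = more likely responder; the output
    ``rank_product`` is sqrt(rank_a * rank_b) with rank 1 = highest score,
    so smaller values mean more likely responder.  ``merged_score`` negates
    it so that higher = responder, for AUC-style evaluation.
    """
    shared = scores_a.index.intersection(scores_b.index)
    if len(shared) < 2:
        raise ValueError("predictors share fewer than 2 samples")
    ra = rankdata(-scores_a.loc[shared].to_numpy(), method="average")
    rb = rankdata(-scores_b.loc[shared].to_numpy(), method="average")
    rp = np.sqrt(ra * rb)
    return pd.DataFrame({"rank_a": ra, "rank_b": rb, "rank_product": rp,
                         "merged_score": -rp}, index=shared)


def call_cnv_states(cnv: pd.DataFrame) -> pd.DataFrame:
    """Discretise gene-level log2 copy-number ratios.

    Strictly > 0.5 is a gain, strictly < -0.5 a loss, everything else
    (boundaries included) neutral.
    """
    vals = cnv.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("copy-number table contains non-finite values")
    states = np.where(vals > 0.5, "gain", np.where(vals < -0.5, "loss", "neutral"))
    return pd.DataFrame(states, index=cnv.index, columns=cnv.columns)


def recurrent_alterations(selection: ImmuneGeneSelection,
                          mutations: pd.DataFrame,
                          cnv_states: pd.DataFrame,
                          corr: ImmuneCorrelationProfile | None = None,
                          min_samples: int = 3) -> pd.DataFrame:
    """Selected genes recurrently altered across samples.

    One row per (gene, alteration type) with >= ``min_samples`` altered
    samples; alteration types are Mut (mutation records), Amp (CNV gains)
    and Del (CNV losses).  ``mutations`` needs columns (gene, sample).
    """
    selected = sorted(selection.positive_genes | selection.negative_genes)
    rows = []
    mut_counts = (mutations.drop_duplicates()
                  .groupby("gene")["sample"].nunique()
                  if len(mutations) else pd.Series(dtype=int))
    for gene in selected:
        direction = ("positive" if gene in selection.positive_genes
                     else "negative")
        counts = {"Mut": int(mut_counts.get(gene, 0))}
        if gene in cnv_states.index:
            row = cnv_states.loc[gene]
            counts["Amp"] = int((row == "gain").sum())
            counts["Del"] = int((row == "loss").sum())
        else:
            counts["Amp"] = counts["Del"] = 0
        for alt, n in counts.items():
            if n >= min_samples:
                rows.append({
                    "gene": gene, "alteration": alt, "n_samples": n,
                    "immune_correlation_direction": direction,
                    "immune_correlation": (
                        float(corr.correlations.get(gene, np.nan))
                        if corr is not None else np.nan),
                })
    return pd.DataFrame(rows, columns=["gene", "alteration", "n_samples",
                                       "immune_correlation_direction",
                                       "immune_correlation"])


def map_drug_targets(selection: ImmuneGeneSelection,
                     drug_targets: pd.DataFrame,
                     assoc: RankedList | None = None,
                     corr: ImmuneCorrelationProfile | None = None
                     ) -> pd.DataFrame:
    """Join drug–target pairs against the immune-negative gene set.

    High expression of immune-negative associated genes marks immune
    suppression, so their inhibitors are the therapeutic candidates; the
    output annotates each hit with the gene's association percentile and
    immune correlation when available.  ``drug_targets`` needs columns
    (drug, target).
    """
    unknown = set(drug_targets["target"]) - (
        set(assoc.genes) if assoc is not None else set(drug_targets["target"]))
    if unknown:
        logger.info("%d drug target(s) not in the ranked universe (kept)",
                    len(unknown))
    hits = drug_targets[drug_targets["target"].isin(selection.negative_genes)]
    rows = []
    for _, rec in hits.iterrows():
        g = rec["target"]
        rows.append({
            "compound": rec["drug"], "target_gene": g,
            "immune_correlation": (float(corr.correlations.get(g, np.nan))
                                   if corr is not None else np.nan),
            "association_percentile": (float(assoc.percentiles.get(g, np.nan))
                                       if assoc is not None else np.nan),
        })
    return pd.DataFrame(rows, columns=["compound", "target_gene",
                                       "immune_correlation",
                                       "association_percentile"])
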