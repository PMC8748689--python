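"""The umbrella pipeline: association → enrichment → selection → MIAS →
evaluation, with per-stage TSV outputs and a JSON run manifest."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import enrichment, evaluation, integration, io, network

logger = logging.getLogger(__name__)

DEFAULTS = {
    "gamma": 0.5, "tol": 1e-10, "tau": 0.01, "top_fraction": 0.10,
    "corr_threshold": 0.2, "n_signature": 100, "n_perm": 1000,
    "rng_seed": 0, "alpha": 0.25, "corr_method": "spearman",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _params(config: dict) -> dict:
    p = dict(DEFAULTS)
    for k in DEFAULTS:
        if k in config:
            p[k] = type(DEFAULTS[k])(config[k])
    return p


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the stages named by ``config`` and write outputs to ``out_dir``.

    Required inputs: ``network`` and ``seeds`` file paths.  Optional:
    ``gene_sets`` (GMT), ``expression`` + ``immune`` (selection/signature),
    ``cohort_expression`` (MIAS scoring; falls back to ``expression``),
    ``labels`` (evaluation).  Stages whose inputs are absent are skipped
    with a notice; any stage error aborts with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = _params(config)

    # --- stage: associate -------------------------------------------------
    try:
        net = io.read_edge_list(config["network"])
        seeds = io.read_seeds(config["seeds"])
        w = network.column_normalize(net)
        assoc = network.random_walk_with_restart(
            w, seeds, gamma=p["gamma"], tol=p["tol"])
        ranked = network.rank_and_percentile(assoc.scores)
        ranked.table.to_csv(out / "association.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        raise PipelineError("associate", exc) from exc

    # --- stage: gsea + combine (optional) ---------------------------------
    if config.get("gene_sets"):
        try:
            sets = io.parse_gmt(config["gene_sets"])
            res_assoc = enrichment.gsea_association(
                ranked, sets, n_perm=p["n_perm"], rng_seed=p["rng_seed"])
            rows = []
            dereg_by_name = {}
            if config.get("cohort_expression") and config.get("labels"):
                cexpr = io.parse_matrix(config["cohort_expression"])
                lab = io.read_two_column(
                    config["labels"], names=("sample", "response", "timing"))
                groups = pd.Series(
                    (lab["response"] == "response").values,
                    index=lab["sample"].values)
                res_dereg = enrichment.gsea_deregulation(
                    cexpr, groups, sets, n_perm=p["n_perm"],
                    rng_seed=p["rng_seed"])
                dereg_by_name = {r.name: r for r in res_dereg}
            for r in res_assoc:
                d = dereg_by_name.get(r.name)
                combined = (enrichment.truncated_product(
                    r.p_value, d.p_value, tau=p["tau"]).probability
                    if d else float("nan"))
                rows.append({"set": r.name, "size": r.overlap, "es": r.es,
                             "nes": r.nes, "p_assoc": r.p_value,
                             "p_dereg": d.p_value if d else float("nan"),
                             "combined_p": combined})
            pd.DataFrame(rows).to_csv(out / "pathways.tsv", sep="\t",
                                      index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("gsea", exc) from exc
    else:
        logger.info("no gene_sets configured; skipping gsea/combine stage")

    # --- stages: select + signature + mias + evaluate ---------------------
    if not (config.get("expression") and config.get("immune")):
        logger.info("no expression/immune inputs; skipping stages c-e")
        io.write_manifest(out, "run", p,
                          {k: config.get(k) for k in
                           ("network", "seeds", "gene_sets")})
        return out

    try:
        expr = io.parse_matrix(config["expression"])
        imm_tbl = io.read_two_column(config["immune"], names=("sample", "score"))
        immune = pd.Series(imm_tbl["score"].astype(float).values,
                           index=imm_tbl["sample"].values)
        corr = integration.immune_correlation(expr, immune,
                                              method=p["corr_method"])
        selection = integration.select_immune_genes(
            ranked, corr, top_fraction=p["top_fraction"],
            corr_threshold=p["corr_threshold"])
        pd.DataFrame({"gene": sorted(selection.positive_genes)}).to_csv(
            out / "immune_positive.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": sorted(selection.negative_genes)}).to_csv(
            out / "immune_negative.tsv", sep="\t", index=False)
        signature = integration.select_mias_signature(
            ranked, corr, n_signature=p["n_signature"])
        signature.table.to_csv(out / "signature.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("select", exc) from exc

    try:
        score_expr = (io.parse_matrix(config["cohort_expression"])
                      if config.get("cohort_expression") else expr)
        mias = integration.mias_score(score_expr, signature, alpha=p["alpha"])
        mias.rename_axis("sample").to_frame().to_csv(out / "mias.tsv", sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("mias", exc) from exc

    if config.get("labels"):
        try:
            lab = io.read_two_column(config["labels"],
                                     names=("sample", "response", "timing"))
            lab = lab.set_index("sample").loc[mias.index]
            y = (lab["response"] == "response").astype(int)
            roc = evaluation.roc_auc(mias.values, y.values)
            mwu = evaluation.mann_whitney_one_sided(
                mias[y == 1].values, mias[y == 0].values)
            pd.DataFrame([{"auc": roc.auc, "wilcoxon_u": mwu.u,
                           "wilcoxon_p_one_sided": mwu.p_value,
                           "wilcoxon_method": mwu.method,
                           "n_response": int(y.sum()),
                           "n_non_response": int((1 - y).sum())}]).to_csv(
                out / "evaluation.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("evaluate", exc) from exc
    else:
        logger.info("no labels configured; skipping evaluation stage")

    io.write_manifest(out, "run", p, {
        k: config.get(k) for k in
        ("network", "seeds", "gene_sets", "expression", "immune",
         "cohort_expression", "labels")})
    return out
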