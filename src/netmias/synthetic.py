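"""Synthetic fixtures with planted ground truth for every pipeline stage.

Real inputs to the method — a curated interaction network, a TCGA-scale
expression cohort with immune-infiltration scores, and anti-PD-1-treated
patient cohorts — are emulated here by three generators:

* :func:`simulate_network` — a preferential-attachment backbone (scale-free,
  like curated interactomes) with a densely wired planted module that
  contains the seed genes, so network proximity to the seeds has a known
  answer;
* :func:`simulate_expression_cohort` — log-normal expression driven by a
  latent per-sample immune axis, with designated immune-positive /
  immune-negative gene blocks at a target correlation;
* :func:`simulate_response_cohort` — responders carry an expression shift
  on a known signature; everything else is exchangeable between groups.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import GeneNetwork, SeedSet, build_network


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by a generator."""

    rng_seed: int
    module_genes: tuple[str, ...] = ()
    seed_genes: tuple[str, ...] = ()
    signature_genes: tuple[str, ...] = ()
    immune_positive: tuple[str, ...] = ()
    immune_negative: tuple[str, ...] = ()
    responders: tuple[str, ...] = ()
    effect_sd: float = 0.0
    params: dict = field(default_factory=dict, repr=False)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_network(n_nodes: int = 1000, attach_m: int = 3,
                     module_size: int = 50, seeds_in_module: int = 5,
                     module_p: float = 0.6, rng_seed: int = 0
                     ) -> tuple[GeneNetwork, SeedSet, SyntheticTruth]:
    """Scale-free backbone with a densely interconnected planted module.

    The module's internal edge probability (default 0.6) far exceeds the
    backbone density, so a restart walk from the in-module seed genes should
    concentrate on the module.
    """
    if module_size >= n_nodes:
        raise ValueError("module_size must be smaller than n_nodes")
    if attach_m < 1:
        raise ValueError("attach_m must be >= 1")
    if seeds_in_module > module_size:
        raise ValueError("more seeds than module genes")
    rng = np.random.default_rng(rng_seed)
    genes = _gene_ids(n_nodes)
    backbone = nx.barabasi_albert_graph(n_nodes, attach_m,
                                        seed=int(rng.integers(2**31)))
    edges = [(genes[a], genes[b]) for a, b in backbone.edges()]
    module_idx = rng.choice(n_nodes, size=module_size, replace=False)
    module = [genes[i] for i in module_idx]
    for i in range(module_size):
        for j in range(i + 1, module_size):
            if rng.random() < module_p:
                edges.append((module[i], module[j]))
    net = build_network(edges)
    seed_genes = tuple(module[:seeds_in_module])
    truth = SyntheticTruth(
        rng_seed=rng_seed, module_genes=tuple(module), seed_genes=seed_genes,
        params={"n_nodes": n_nodes, "attach_m": attach_m,
                "module_size": module_size, "module_p": module_p})
    return net, SeedSet(genes=seed_genes), truth


def simulate_expression_cohort(n_genes: int = 2000, n_samples: int = 300,
                               frac_immune_pos: float = 0.05,
                               frac_immune_neg: float = 0.05,
                               rho_target: float = 0.5, rng_seed: int = 0,
                               gene_ids: list[str] | None = None,
                               immune_pos_genes: list[str] | None = None,
                               immune_neg_genes: list[str] | None = None,
                               ) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Expression cohort with a latent immune axis.

    A per-sample latent immune score z ~ N(0, 1) drives designated
    immune-positive genes (population correlation ~= +rho_target on the log
    scale) and immune-negative genes (~= -rho_target); remaining genes are
    independent noise.  Expression is exponentiated (base 2) so the matrix
    is nonnegative, emulating normalised abundance.
    """
    if not 0.0 < rho_target < 1.0:
        raise ValueError("rho_target must be in (0, 1)")
    if frac_immune_pos + frac_immune_neg >= 1.0:
        raise ValueError("immune gene fractions must sum to < 1")
    rng = np.random.default_rng(rng_seed)
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    n_genes = len(genes)
    if immune_pos_genes is None or immune_neg_genes is None:
        n_pos = int(round(frac_immune_pos * n_genes))
        n_neg = int(round(frac_immune_neg * n_genes))
        perm = rng.permutation(n_genes)
        immune_pos_genes = [genes[i] for i in perm[:n_pos]]
        immune_neg_genes = [genes[i] for i in perm[n_pos:n_pos + n_neg]]
    samples = [f"S{j:04d}" for j in range(n_samples)]
    z = rng.standard_normal(n_samples)
    # loading a on unit noise gives corr(az + e, z) = a / sqrt(a^2 + 1)
    a = rho_target / np.sqrt(1.0 - rho_target ** 2)
    base = rng.normal(6.0, 1.0, size=n_genes)
    noise = rng.standard_normal((n_genes, n_samples))
    sign = np.zeros(n_genes)
    pos_set, neg_set = set(immune_pos_genes), set(immune_neg_genes)
    for i, g in enumerate(genes):
        if g in pos_set:
            sign[i] = 1.0
        elif g in neg_set:
            sign[i] = -1.0
    log_expr = base[:, None] + a * sign[:, None] * z[None, :] + noise
    expr = pd.DataFrame(2.0 ** log_expr, index=genes, columns=samples)
    immune = pd.Series(z, index=samples, name="immune_score")
    truth = SyntheticTruth(
        rng_seed=rng_seed, immune_positive=tuple(immune_pos_genes),
        immune_negative=tuple(immune_neg_genes),
        params={"rho_target": rho_target, "n_samples": n_samples})
    return expr, immune, truth


def simulate_response_cohort(signature_genes, n_resp: int = 30,
                             n_nonresp: int = 30, effect_sd: float = 1.5,
                             rng_seed: int = 0,
                             gene_ids: list[str] | None = None,
                             n_genes: int = 2000,
                             ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Responder/non-responder cohort with a planted signature effect.

    Signature genes are shifted up by ``effect_sd`` log-scale standard
    deviations in responders; all other genes are exchangeable between the
    groups.  Labels come as a DataFrame (response, timing) indexed by
    sample.
    """
    if effect_sd < 0:
        raise ValueError("effect_sd must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    sig = [g for g in signature_genes if g in set(genes)]
    n = n_resp + n_nonresp
    samples = [f"P{j:04d}" for j in range(n)]
    responders = samples[:n_resp]
    base = rng.normal(6.0, 1.0, size=len(genes))
    log_expr = base[:, None] + rng.standard_normal((len(genes), n))
    sig_rows = [i for i, g in enumerate(genes) if g in set(sig)]
    log_expr[np.ix_(sig_rows, range(n_resp))] += effect_sd
    expr = pd.DataFrame(2.0 ** log_expr, index=genes, columns=samples)
    labels = pd.DataFrame(
        {"response": ["response"] * n_resp + ["non-response"] * n_nonresp,
         "timing": ["pre"] * n},
        index=pd.Index(samples, name="sample"))
    truth = SyntheticTruth(
        rng_seed=rng_seed, signature_genes=tuple(sig),
        responders=tuple(responders), effect_sd=effect_sd,
        params={"n_resp": n_resp, "n_nonresp": n_nonresp})
    return expr, labels, truth


def simulate_full_study(rng_seed: int = 0, n_nodes: int = 1500,
                        attach_m: int = 3, module_size: int = 200,
                        seeds_in_module: int = 5, n_true_signature: int = 100,
                        n_immune_pos_outside: int = 100,
                        n_immune_neg: int = 100, n_samples: int = 300,
                        rho_target: float = 0.5, n_resp: int = 30,
                        n_nonresp: int = 30, effect_sd: float = 1.5) -> dict:
    """Compose the three generators into one coherent study.

    The gene universe is the network's node set.  Immune-positive genes are
    ``n_true_signature`` non-seed planted-module genes plus
    ``n_immune_pos_outside`` genes outside the module, so neither network
    proximity nor immune correlation alone pinpoints the true signature —
    only their combination does.  The response effect is planted on the
    module ∩ immune-positive intersection (the true signature).
    """
    rng = np.random.default_rng(rng_seed)
    sub = rng.integers(2**31, size=3)
    net, seeds, net_truth = simulate_network(
        n_nodes=n_nodes, attach_m=attach_m, module_size=module_size,
        seeds_in_module=seeds_in_module, rng_seed=int(sub[0]))
    genes = list(net.nodes)
    non_seed_module = [g for g in net_truth.module_genes
                       if g not in net_truth.seed_genes]
    pick = rng.choice(len(non_seed_module), size=n_true_signature,
                      replace=False)
    true_signature = sorted(non_seed_module[i] for i in pick)
    outside = sorted(set(genes) - set(net_truth.module_genes))
    pick_out = rng.choice(len(outside), size=n_immune_pos_outside + n_immune_neg,
                          replace=False)
    immune_pos = true_signature + [outside[i]
                                   for i in pick_out[:n_immune_pos_outside]]
    immune_neg = [outside[i] for i in pick_out[n_immune_pos_outside:]]
    expr, immune, expr_truth = simulate_expression_cohort(
        n_samples=n_samples, rho_target=rho_target, rng_seed=int(sub[1]),
        gene_ids=genes, immune_pos_genes=immune_pos,
        immune_neg_genes=immune_neg)
    cohort_expr, labels, cohort_truth = simulate_response_cohort(
        true_signature, n_resp=n_resp, n_nonresp=n_nonresp,
        effect_sd=effect_sd, rng_seed=int(sub[2]), gene_ids=genes)
    return {
        "network": net, "seeds": seeds, "network_truth": net_truth,
        "expression": expr, "immune": immune, "expression_truth": expr_truth,
        "cohort_expression": cohort_expr, "labels": labels,
        "cohort_truth": cohort_truth,
        "true_signature": tuple(true_signature),
    }
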