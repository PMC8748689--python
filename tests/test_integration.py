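"""TPM conversion, immune correlation, gene selection, MIAS, CNV/mutation
filters and drug-target mapping."""

import numpy as np
import pandas as pd
import pytest

import netmias as nm
from netmias.integration import ablated_signature, recurrent_alterations

from conftest import toy_ranked


class TestCountsToTpm:
    def test_single_gene(self):
        counts = pd.DataFrame({"s1": [57.0]}, index=["g1"])
        tpm = nm.counts_to_tpm(counts, pd.Series({"g1": 1500.0}))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_counts_and_lengths_split_evenly(self):
        counts = pd.DataFrame({"s1": [10.0, 10.0]}, index=["g1", "g2"])
        tpm = nm.counts_to_tpm(counts, pd.Series({"g1": 2000.0, "g2": 2000.0}))
        assert np.allclose(tpm["s1"].values, 5e5)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(80)]
        counts = pd.DataFrame(rng.integers(0, 5000, size=(80, 6)).astype(float),
                              index=genes, columns=[f"s{j}" for j in range(6)])
        lengths = pd.Series(rng.integers(200, 9000, size=80).astype(float),
                            index=genes)
        tpm = nm.counts_to_tpm(counts, lengths)
        assert np.allclose(tpm.sum(axis=0).values, 1e6, rtol=1e-6)
        # scaling a library leaves its TPM unchanged
        tpm2 = nm.counts_to_tpm(counts * 3, lengths)
        assert np.allclose(tpm.values, tpm2.values, rtol=1e-12)

    def test_missing_length_lists_genes(self):
        counts = pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="g2"):
            nm.counts_to_tpm(counts, pd.Series({"g1": 100.0}))


class TestImmuneCorrelation:
    def test_perfect_positive_and_negative(self):
        imm = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        expr = pd.DataFrame(
            {"a": [1, 16], "b": [2, 9], "c": [3, 4], "d": [4, 1]},
            index=["up", "down"], dtype=float)
        prof = nm.immune_correlation(expr, imm, normalize=False)
        assert prof.correlations["up"] == pytest.approx(1.0)
        # strictly decreasing transform: rho = -1 under rank correlation
        assert prof.correlations["down"] == pytest.approx(-1.0)

    def test_recovers_known_rho(self):
        rng = np.random.default_rng(3)
        n = 500
        z = rng.standard_normal(n)
        rho = 0.6
        a = rho / np.sqrt(1 - rho ** 2)
        expr = pd.DataFrame(a * z + rng.standard_normal((40, n)),
                            index=[f"g{i}" for i in range(40)],
                            columns=[f"s{j}" for j in range(n)])
        imm = pd.Series(z, index=expr.columns)
        prof = nm.immune_correlation(expr, imm, normalize=False)
        assert abs(prof.correlations.mean() - rho) < 0.1

    def test_zero_variance_gene_flagged(self):
        imm = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        expr = pd.DataFrame({"a": [1, 5], "b": [2, 5], "c": [3, 5]},
                            index=["ok", "flat"], dtype=float)
        prof = nm.immune_correlation(expr, imm, normalize=False)
        assert prof.missing_genes == ("flat",)
        assert np.isnan(prof.correlations["flat"])

    def test_too_few_shared_samples(self):
        imm = pd.Series([1.0, 2.0], index=["a", "b"])
        expr = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["g"])
        with pytest.raises(ValueError, match="3 shared"):
            nm.immune_correlation(expr, imm)


def _selection_fixture(n=100, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n)]
    assoc = toy_ranked(dict(zip(genes, rng.standard_normal(n))))
    corr = nm.ImmuneCorrelationProfile(
        correlations=pd.Series(rng.uniform(-0.6, 0.6, size=n), index=genes),
        method="spearman")
    return assoc, corr


class TestSelectImmuneGenes:
    def test_direct_filter(self):
        genes = [f"g{i:02d}" for i in range(100)]
        assoc = toy_ranked({g: 100 - i for i, g in enumerate(genes)})
        corr_vals = pd.Series(0.0, index=genes)
        corr_vals[genes[0:3]] = [0.3, 0.25, 0.2]   # top decile, positive
        corr_vals[genes[3:5]] = [-0.2, -0.4]       # top decile, negative
        corr_vals[genes[50]] = 0.9                 # outside the top decile
        sel = nm.select_immune_genes(
            assoc, nm.ImmuneCorrelationProfile(corr_vals, "spearman"))
        assert sel.positive_genes == frozenset(genes[0:3])
        assert sel.negative_genes == frozenset(genes[3:5])

    def test_empty_selection_is_valid(self):
        assoc, _ = _selection_fixture()
        corr = nm.ImmuneCorrelationProfile(
            pd.Series(0.0, index=assoc.scores.index), "spearman")
        sel = nm.select_immune_genes(assoc, corr)
        assert not sel.positive_genes and not sel.negative_genes

    def test_matches_brute_force_two_predicate_filter(self):
        assoc, corr = _selection_fixture(n=200, seed=4)
        sel = nm.select_immune_genes(assoc, corr, top_fraction=0.1,
                                     corr_threshold=0.2)
        top = set(assoc.table["gene"].iloc[:20])
        c = corr.correlations
        assert sel.positive_genes == frozenset(
            g for g in top if c[g] >= 0.2)
        assert sel.negative_genes == frozenset(
            g for g in top if c[g] <= -0.2)
        assert not (sel.positive_genes & sel.negative_genes)


class TestMiasSignature:
    def test_rank_product_arithmetic(self):
        # MR = sqrt(r1 * r2); sqrt(4*9) = 6
        assert np.sqrt(4 * 9) == 6.0
        assoc, corr = _selection_fixture(n=50, seed=1)
        sig = nm.select_mias_signature(assoc, corr, n_signature=10)
        tbl = sig.table
        assert np.allclose(tbl["mr"], np.sqrt(tbl["r1"] * tbl["r2"]))
        assert (tbl["mr"].diff().dropna() >= 0).all()

    def test_best_gene_always_selected(self):
        genes = [f"g{i}" for i in range(30)]
        assoc = toy_ranked({g: 30 - i for i, g in enumerate(genes)})
        corr = nm.ImmuneCorrelationProfile(
            pd.Series(np.linspace(0.9, -0.9, 30), index=genes), "spearman")
        sig = nm.select_mias_signature(assoc, corr, n_signature=5)
        assert sig.table.iloc[0]["gene"] == "g0"
        assert sig.table.iloc[0]["mr"] == 1.0

    def test_matches_brute_force_mr_sort(self):
        assoc, corr = _selection_fixture(n=150, seed=7)
        sig = nm.select_mias_signature(assoc, corr, n_signature=40)
        from scipy.stats import rankdata
        genes = list(assoc.scores.index)
        r1 = rankdata(-assoc.scores[genes].values)
        r2 = rankdata(-corr.correlations[genes].values)
        mr = np.sqrt(r1 * r2)
        expected = [g for _, g in sorted(zip(mr, genes))][:40]
        assert sorted(sig.genes) == sorted(expected)

    def test_row_order_invariance(self):
        assoc, corr = _selection_fixture(n=80, seed=9)
        sig1 = nm.select_mias_signature(assoc, corr, n_signature=20)
        shuffled = nm.ImmuneCorrelationProfile(
            corr.correlations.sample(frac=1.0, random_state=0), "spearman")
        sig2 = nm.select_mias_signature(assoc, shuffled, n_signature=20)
        assert sig1.genes == sig2.genes

    def test_universe_too_small(self):
        assoc, corr = _selection_fixture(n=20)
        with pytest.raises(ValueError, match="smaller than signature"):
            nm.select_mias_signature(assoc, corr, n_signature=100)


class TestMiasScore:
    def test_planted_signature_separates_responders(self):
        genes = [f"G{i:05d}" for i in range(1000)]
        sig_genes = genes[:100]
        expr, labels, _ = nm.simulate_response_cohort(
            sig_genes, n_resp=30, n_nonresp=30, effect_sd=1.5, rng_seed=0,
            gene_ids=genes)
        sig = nm.MiasSignature(table=pd.DataFrame(
            {"gene": sig_genes, "r1": 1.0, "r2": 1.0, "mr": 1.0}))
        mias = nm.mias_score(expr, sig)
        y = (labels["response"] == "response").astype(int)
        assert nm.roc_auc(mias[y.index].values, y.values).auc >= 0.9

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        expr = pd.DataFrame(rng.uniform(1, 100, size=(200, 5)), index=genes,
                            columns=[f"s{j}" for j in range(5)])
        sig = nm.MiasSignature(table=pd.DataFrame(
            {"gene": genes[:120], "r1": 1.0, "r2": 1.0, "mr": 1.0}))
        m1 = nm.mias_score(expr, sig)
        m2 = nm.mias_score(expr.sample(frac=1.0, random_state=3), sig)
        assert np.allclose(m1.values, m2.values, atol=1e-12)

    def test_insufficient_overlap_reports_counts(self):
        expr = pd.DataFrame(np.ones((5, 3)),
                            index=[f"g{i}" for i in range(5)],
                            columns=list("abc"))
        sig = nm.MiasSignature(table=pd.DataFrame(
            {"gene": [f"x{i}" for i in range(99)] + ["g0"],
             "r1": 1.0, "r2": 1.0, "mr": 1.0}))
        with pytest.raises(ValueError, match="1/100"):
            nm.mias_score(expr, sig)

    def test_universe_restriction(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(100)]
        expr = pd.DataFrame(rng.uniform(1, 10, size=(100, 4)), index=genes,
                            columns=list("wxyz"))
        sig = nm.MiasSignature(table=pd.DataFrame(
            {"gene": genes[:20], "r1": 1.0, "r2": 1.0, "mr": 1.0}))
        full = nm.mias_score(expr, sig)
        shared = nm.mias_score(expr, sig, universe=genes[:60])
        assert len(full) == len(shared) == 4
        assert not np.allclose(full.values, shared.values)


class TestAblatedSignature:
    def test_full_equals_plain_selection(self):
        assoc, corr = _selection_fixture(n=120, seed=2)
        rng = np.random.default_rng(0)
        sig_a = ablated_signature(assoc, corr, "full", 30, rng)
        sig_b = nm.select_mias_signature(assoc, corr, 30)
        assert sig_a.genes == sig_b.genes

    def test_unknown_scenario_rejected(self):
        assoc, corr = _selection_fixture()
        with pytest.raises(ValueError, match="scenario"):
            ablated_signature(assoc, corr, "bogus")


class TestIntegratePredictions:
    def test_agreeing_best_sample(self):
        a = pd.Series({"s1": 9.0, "s2": 5.0, "s3": 1.0})
        merged = nm.integrate_predictions(a, a * 2)
        assert merged.loc["s1", "rank_product"] == 1.0
        assert merged["merged_score"].idxmax() == "s1"

    def test_identical_predictors_preserve_order(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.standard_normal(20),
                      index=[f"s{i}" for i in range(20)])
        merged = nm.integrate_predictions(a, a.copy())
        assert (merged["merged_score"].rank(ascending=False).values
                == merged["rank_a"]).all()

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(5)
        idx = [f"s{i}" for i in range(15)]
        a = pd.Series(rng.standard_normal(15), index=idx)
        b = pd.Series(rng.standard_normal(15), index=idx)
        from scipy.stats import rankdata
        merged = nm.integrate_predictions(a, b)
        expected = np.sqrt(rankdata(-a.values) * rankdata(-b.values))
        assert np.allclose(merged.loc[idx, "rank_product"].values, expected)

    def test_disjoint_samples_rejected(self):
        with pytest.raises(ValueError, match="share"):
            nm.integrate_predictions(pd.Series({"a": 1.0}),
                                     pd.Series({"b": 2.0}))


class TestCnvAndAlterations:
    def test_threshold_rule(self):
        cnv = pd.DataFrame([[-0.6, -0.5, 0.0, 0.5, 0.6]], index=["g1"],
                           columns=[f"s{i}" for i in range(5)])
        states = nm.call_cnv_states(cnv)
        assert list(states.loc["g1"]) == ["loss", "neutral", "neutral",
                                          "neutral", "gain"]

    def test_every_entry_in_exactly_one_state(self):
        rng = np.random.default_rng(0)
        cnv = pd.DataFrame(rng.normal(0, 1, size=(30, 10)),
                           index=[f"g{i}" for i in range(30)],
                           columns=[f"s{j}" for j in range(10)])
        states = nm.call_cnv_states(cnv)
        assert states.isin(["gain", "neutral", "loss"]).all().all()

    def test_recurrent_alteration_counting(self):
        sel = nm.ImmuneGeneSelection(
            positive_genes=frozenset({"gp"}), negative_genes=frozenset({"gn"}),
            top_fraction=0.1, corr_threshold=0.2)
        mut = pd.DataFrame({"gene": ["gn"] * 5 + ["gp"] * 2,
                            "sample": [f"s{i}" for i in range(5)] + ["s0", "s1"]})
        cnv = pd.DataFrame(
            [[0.7, 0.8, 0.9, 0.0, 0.0], [0.0] * 5],
            index=["gp", "gn"], columns=[f"s{i}" for i in range(5)])
        tbl = recurrent_alterations(sel, mut, nm.call_cnv_states(cnv),
                                    min_samples=3)
        rows = {(r.gene, r.alteration): r.n_samples
                for r in tbl.itertuples()}
        assert rows == {("gn", "Mut"): 5, ("gp", "Amp"): 3}

    def test_matches_brute_force_count_filter(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(20)]
        samples = [f"s{j}" for j in range(12)]
        sel = nm.ImmuneGeneSelection(
            positive_genes=frozenset(genes[:10]), negative_genes=frozenset(),
            top_fraction=0.1, corr_threshold=0.2)
        mut = pd.DataFrame(
            {"gene": rng.choice(genes, 60), "sample": rng.choice(samples, 60)})
        cnv = pd.DataFrame(rng.normal(0, 0.5, size=(20, 12)), index=genes,
                           columns=samples)
        states = nm.call_cnv_states(cnv)
        tbl = recurrent_alterations(sel, mut, states, min_samples=3)
        for r in tbl.itertuples():
            if r.alteration == "Mut":
                n = mut[mut.gene == r.gene].drop_duplicates()["sample"].nunique()
            else:
                tag = "gain" if r.alteration == "Amp" else "loss"
                n = int((states.loc[r.gene] == tag).sum())
            assert r.n_samples == n >= 3


class TestMapDrugTargets:
    def _selection(self):
        return nm.ImmuneGeneSelection(
            positive_genes=frozenset({"POS1"}),
            negative_genes=frozenset({"NEG1", "NEG2"}),
            top_fraction=0.1, corr_threshold=0.2)

    def test_hit_on_negative_set(self):
        drugs = pd.DataFrame({"drug": ["dA"], "target": ["NEG1"]})
        tbl = nm.map_drug_targets(self._selection(), drugs)
        assert len(tbl) == 1 and tbl.iloc[0]["compound"] == "dA"

    def test_positive_only_target_excluded(self):
        drugs = pd.DataFrame({"drug": ["dB"], "target": ["POS1"]})
        assert nm.map_drug_targets(self._selection(), drugs).empty

    def test_matches_relational_join(self):
        rng = np.random.default_rng(0)
        targets = [f"NEG{i}" for i in range(3)] + [f"X{i}" for i in range(7)]
        sel = nm.ImmuneGeneSelection(
            positive_genes=frozenset(), top_fraction=0.1, corr_threshold=0.2,
            negative_genes=frozenset(t for t in targets if t.startswith("NEG")))
        drugs = pd.DataFrame({"drug": rng.choice(["d1", "d2", "d3"], 30),
                              "target": rng.choice(targets, 30)})
        tbl = nm.map_drug_targets(sel, drugs)
        expected = drugs[drugs.target.isin(sel.negative_genes)]
        assert len(tbl) == len(expected)
        assert set(zip(tbl.compound, tbl.target_gene)) == set(
            zip(expected.drug, expected.target))


class TestQuantileNormalize:
    def test_columns_share_distribution(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.lognormal(3, 1, size=(50, 4)),
                            index=[f"g{i}" for i in range(50)],
                            columns=list("abcd"))
        qn = nm.quantile_normalize(expr)
        ref = np.sort(qn["a"].values)
        for c in "bcd":
            assert np.allclose(np.sort(qn[c].values), ref)
        # ranks within each sample are preserved
        for c in "abcd":
            assert (qn[c].rank() == expr[c].rank()).all()
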