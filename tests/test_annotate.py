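import itertools

import numpy as np
import pandas as pd
import pytest

from conetwork import annotate, workflow
from conetwork.annotate import (
    closest_partner_summary,
    correlation_pvalue,
    crosstab_overlap,
    guilt_by_association,
    list_enrichment,
    run_stratified,
    trait_correlation,
)
from conetwork.moddetect import GREY
from conetwork.netbuild import NetworkConfig
from conetwork.simdata import SimConfig, generate_dataset
from oracles import fisher_exact_enumerate, hypergeom_upper_tail, t_pvalue_quadrature


def _labels(assignments):
    return pd.Series(assignments)


class TestListEnrichment:
    def test_zero_overlap_p_one(self):
        labels = _labels({f"g{i}": "blue" if i < 5 else GREY for i in range(20)})
        lists = {"L": {f"g{i}" for i in range(10, 15)}}
        out = list_enrichment(labels, lists)
        assert out.loc[0, "overlap"] == 0
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_full_overlap_exact_p(self):
        # universe 20, list 5, module 5, overlap 5 -> 1 / C(20,5)
        labels = _labels({f"g{i}": "blue" if i < 5 else GREY for i in range(20)})
        lists = {"L": {f"g{i}" for i in range(5)}}
        out = list_enrichment(labels, lists)
        assert out.loc[0, "p_raw"] == pytest.approx(1 / 15504, rel=1e-10)

    @pytest.mark.parametrize("n_universe", [10, 20, 30])
    def test_matches_enumeration_oracle(self, n_universe):
        for n_list in (1, 3, n_universe // 2):
            for n_module in (2, 5, n_universe // 2):
                genes = [f"g{i}" for i in range(n_universe)]
                labels = _labels(
                    {g: ("blue" if i < n_module else GREY) for i, g in enumerate(genes)}
                )
                for shift in range(0, n_universe - n_list + 1, 7):
                    lists = {"L": set(genes[shift : shift + n_list])}
                    out = list_enrichment(labels, lists)
                    k = out.loc[0, "overlap"]
                    expected = hypergeom_upper_tail(k, n_universe, n_list, n_module)
                    assert out.loc[0, "p_raw"] == pytest.approx(expected, rel=1e-9)

    def test_bonferroni_over_module_list_pairs(self, small_ds, small_result):
        out = list_enrichment(small_result.labels, small_ds.marker_lists)
        n_tests = len(out)
        assert np.allclose(
            out["p_bonferroni"], np.minimum(1.0, out["p_raw"] * n_tests)
        )
        assert (out["p_bonferroni"] >= out["p_raw"] - 1e-15).all()

    def test_planted_lists_hit_their_modules(self, small_ds, small_result):
        out = list_enrichment(small_result.labels, small_ds.marker_lists)
        best = out.loc[out.groupby("list_name")["p_raw"].idxmin()]
        # each planted marker list is most enriched in the module holding it
        for _, row in best.iterrows():
            assert row["p_bonferroni"] < 0.05

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            list_enrichment(pd.Series(dtype=object), {}, universe=set())


class TestTraitCorrelation:
    def test_r_zero_gives_p_one(self):
        assert correlation_pvalue(0.0, 20) == pytest.approx(1.0)

    def test_perfect_correlation_p_zero(self):
        assert correlation_pvalue(1.0, 20) == 0.0
        assert correlation_pvalue(-1.0, 20) == 0.0

    def test_matches_quadrature_oracle(self):
        for r, n in [(0.5, 20), (0.1, 50), (0.9, 10), (-0.37, 100)]:
            assert correlation_pvalue(r, n) == pytest.approx(
                t_pvalue_quadrature(r, n), abs=1e-8
            )

    def test_p_decreasing_in_abs_r_and_n(self):
        ps = [correlation_pvalue(r, 30) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        ps = [correlation_pvalue(0.4, n) for n in (10, 30, 100, 300)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_trait_equal_to_me(self, small_result):
        mes = small_result.eigengenes
        traits = pd.DataFrame({"t": mes.iloc[:, 0]}, index=mes.index)
        out = trait_correlation(mes, traits)
        row = out[out["module"] == mes.columns[0]].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] == 0.0

    def test_planted_trait_recovered(self):
        ds = generate_dataset(
            SimConfig(n_samples=500, n_modules=3, genes_per_module=40,
                      n_background_genes=60, trait_loading=0.6, seed=21)
        )
        res = workflow.run_pipeline(ds.expression, None, None, NetworkConfig())
        out = trait_correlation(res.eigengenes, ds.traits)
        sub = out[out["trait"] == "trait1"].sort_values("p")
        top = sub.iloc[0]
        planted = ds.truth.gene_module[ds.truth.gene_module == 1].index
        expected_module = res.labels.loc[planted].mode()[0]
        assert top["module"] == expected_module
        assert abs(abs(top["r"]) - 0.6) < 0.08
        assert top["significant"]

    def test_missing_values_pairwise_complete(self, small_ds, small_result):
        traits = small_ds.traits.copy()
        traits.iloc[:30, 0] = np.nan
        out = trait_correlation(small_result.eigengenes, traits)
        n1 = out[out["trait"] == "trait1"]["n_used"].unique()
        assert set(n1) == {len(traits) - 30}

    def test_constant_trait_dropped(self, small_result, caplog):
        traits = pd.DataFrame(
            {"flat": 1.0}, index=small_result.eigengenes.index
        )
        with caplog.at_level("WARNING"):
            out = trait_correlation(small_result.eigengenes, traits)
        assert len(out) == 0


class TestCrosstab:
    def test_self_crosstab_diagonal_p(self):
        labels = _labels(
            {f"g{i}": ("blue" if i < 30 else "brown") for i in range(100)}
        )
        out = crosstab_overlap(labels, labels)
        diag = out[(out["module_a"] == "blue") & (out["module_b"] == "blue")].iloc[0]
        expected = fisher_exact_enumerate([[30, 0], [0, 70]])
        assert diag["p"] == pytest.approx(expected, rel=1e-9)

    def test_diagonal_dominates_rows(self, small_result):
        out = crosstab_overlap(small_result.labels, small_result.labels)
        for mod in out["module_a"].unique():
            row = out[out["module_a"] == mod]
            diag_p = row[row["module_b"] == mod]["p"].iloc[0]
            assert (diag_p <= row["p"] + 1e-15).all()

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        n, n_seeds, alpha = 100, 200, 0.05
        hits = total = 0
        genes = [f"g{i}" for i in range(n)]
        for _ in range(n_seeds):
            la = pd.Series(rng.permutation(["blue"] * 50 + ["brown"] * 50), index=genes)
            lb = pd.Series(rng.permutation(["red"] * 50 + ["green"] * 50), index=genes)
            out = crosstab_overlap(la, lb)
            hits += int((out["p"] < alpha).sum())
            total += len(out)
        rate = hits / total
        assert 0.01 <= rate <= 0.12

    def test_matches_enumeration_oracle_small(self):
        genes = [f"g{i}" for i in range(20)]
        la = _labels({g: ("blue" if i < 8 else "brown") for i, g in enumerate(genes)})
        lb = _labels({g: ("red" if i % 3 == 0 else "green") for i, g in enumerate(genes)})
        out = crosstab_overlap(la, lb)
        for _, row in out.iterrows():
            k = row["overlap"]
            table = [
                [k, row["size_a"] - k],
                [row["size_b"] - k, 20 - row["size_a"] - row["size_b"] + k],
            ]
            assert row["p"] == pytest.approx(
                fisher_exact_enumerate(table), rel=1e-9
            )

    def test_disjoint_universe_raises(self):
        la = _labels({"g1": "blue"})
        lb = _labels({"g2": "blue"})
        with pytest.raises(ValueError):
            crosstab_overlap(la, lb)


class TestGuiltByAssociation:
    def test_cutoff_rule(self, small_ds, small_result):
        membership = small_result.membership
        functions = {m: f"fn_{m}" for m in small_result.eigengenes.columns}
        predicted, summary = guilt_by_association(
            membership, small_ds.annotation, functions
        )
        assert (predicted["MM"].abs() > 0.20).all()
        own = membership.own_mm
        missed = [
            g for g in membership.mm.index
            if membership.assigned[g] in functions and abs(own[g]) > 0.20
        ]
        assert set(predicted["gene_id"]) == set(missed)

    def test_unlabeled_module_emits_nothing(self, small_ds, small_result):
        predicted, _ = guilt_by_association(
            small_result.membership, small_ds.annotation, {}
        )
        assert len(predicted) == 0

    def test_planted_lncrnas_get_predictions(self):
        ds = generate_dataset(
            SimConfig(n_samples=300, n_modules=3, genes_per_module=60,
                      n_background_genes=30, weight_range=(0.5, 0.9),
                      lncrna_fraction=0.3, seed=30)
        )
        res = workflow.run_pipeline(ds.expression, None, None, NetworkConfig())
        functions = {m: "immune" for m in res.eigengenes.columns}
        predicted, summary = guilt_by_association(
            res.membership, ds.annotation, functions
        )
        lnc_in_modules = [
            g
            for g in ds.annotation.index[ds.annotation["biotype"] == "lncRNA"]
            if ds.truth.gene_module[g] > 0
        ]
        predicted_lnc = set(predicted[predicted["biotype"] == "lncRNA"]["gene_id"])
        frac = len(predicted_lnc & set(lnc_in_modules)) / len(lnc_in_modules)
        assert frac >= 0.9
        # biotype summary is consistent
        lnc_row = summary[summary["biotype"] == "lncRNA"].iloc[0]
        assert lnc_row["predicted"] == len(predicted_lnc)
        assert lnc_row["hubs"] <= lnc_row["predicted"] <= lnc_row["total"]


class TestClosestPartner:
    def test_two_gene_module_mutual(self, small_ds, small_result):
        adj = small_result.adjacency.iloc[:4, :4].copy()
        labels = pd.Series(["blue", "blue", GREY, GREY], index=adj.index)
        membership = small_result.membership
        partners, _, _ = closest_partner_summary(
            adj, labels, membership, small_ds.annotation
        )
        g0, g1 = adj.index[0], adj.index[1]
        assert partners.loc[g0, "partner"] == g1
        assert partners.loc[g1, "partner"] == g0

    def test_partner_maximizes_adjacency_brute_force(self, small_ds, small_result):
        partners, _, _ = closest_partner_summary(
            small_result.adjacency, small_result.labels,
            small_result.membership, small_ds.annotation,
        )
        adj = small_result.adjacency
        labels = small_result.labels
        for g in list(adj.index)[::13]:
            row = partners.loc[g]
            if row["singleton"]:
                continue
            mates = [x for x in adj.index if labels[x] == labels[g] and x != g]
            best = max(mates, key=lambda x: (adj.loc[g, x], x))
            assert adj.loc[g, row["partner"]] == pytest.approx(adj.loc[g, best])

    def test_singleton_flagged(self, small_ds, small_result):
        adj = small_result.adjacency.iloc[:3, :3]
        labels = pd.Series(["blue", GREY, GREY], index=adj.index)
        partners, _, _ = closest_partner_summary(
            adj, labels, small_result.membership, small_ds.annotation
        )
        assert partners.loc[adj.index[0], "singleton"]

    def test_default_floor_is_75th_percentile(self, small_ds, small_result):
        partners, full, filtered = closest_partner_summary(
            small_result.adjacency, small_result.labels,
            small_result.membership, small_ds.annotation,
        )
        floor = float(np.quantile(partners["adjacency"].dropna(), 0.75))
        _, _, filtered2 = closest_partner_summary(
            small_result.adjacency, small_result.labels,
            small_result.membership, small_ds.annotation,
            adjacency_floor=floor,
        )
        assert filtered.equals(filtered2)


class TestStratified:
    def test_full_stratum_equals_pooled(self, small_ds, small_result):
        sample_filter = pd.Series(True, index=small_ds.expression.columns)
        result, crosstab = run_stratified(
            small_ds.expression, None, None, sample_filter,
            NetworkConfig(mode="signed"),
            pooled_labels=small_result.labels,
            pooled_membership=small_result.membership,
        )
        assert result.labels.equals(small_result.labels)
        # self-overlap: each module's best partner is itself, highly significant
        for mod in result.eigengenes.columns:
            sub = crosstab[crosstab["module_a"] == mod]
            assert sub.loc[sub["p"].idxmin(), "module_b"] == mod

    def test_random_halves_overlap(self):
        ds = generate_dataset(
            SimConfig(n_samples=400, n_modules=3, genes_per_module=40,
                      n_background_genes=60, weight_range=(0.7, 0.9), seed=17)
        )
        cfg = NetworkConfig(mode="signed")
        pooled = workflow.run_pipeline(ds.expression, None, None, cfg)
        samples = list(ds.expression.columns)
        half = pd.Series(
            [i < 200 for i in range(400)], index=samples
        )
        res_a, ct = run_stratified(
            ds.expression, None, None, half, cfg,
            pooled_labels=pooled.labels, pooled_membership=pooled.membership,
        )
        n_tests = len(ct)
        for m in range(1, 4):
            planted = ds.truth.gene_module[ds.truth.gene_module == m].index
            mod_a = res_a.labels.loc[planted].mode()[0]
            if mod_a == GREY:
                continue
            sub = ct[ct["module_a"] == mod_a]
            assert (sub["p"].min() * n_tests) < 0.05

    def test_small_stratum_raises(self, small_ds):
        tiny = pd.Series(False, index=small_ds.expression.columns)
        tiny.iloc[:5] = True
        with pytest.raises(ValueError, match="stratum"):
            run_stratified(small_ds.expression, None, None, tiny, NetworkConfig())
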