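import itertools

import numpy as np
import pandas as pd
import pytest

import mirtarnet as mt

from conftest import make_network


def _de_table(entries):
    """entries: {feature: (lfc, fdr)}"""
    frame = pd.DataFrame.from_dict(entries, orient="index", columns=["lfc", "fdr"])
    frame["tested"] = True
    return frame


class TestCandidatePairs:
    def _db(self, rows):
        return mt.TargetPairDB(
            pd.DataFrame(rows, columns=["mirna", "gene", "source", "evidence"])
        )

    def test_nonsignificant_gene_excluded(self):
        de_m = _de_table({"m1": (1.0, 0.01)})
        de_g = _de_table({"g1": (-1.0, 0.2)})
        db = self._db([["m1", "g1", "srcA", "predicted"]])
        assert len(mt.candidate_pairs(de_m, de_g, db)) == 0

    def test_sources_union_and_validated_flag(self):
        de_m = _de_table({"m1": (1.0, 0.01)})
        de_g = _de_table({"g1": (-1.0, 0.01)})
        db = self._db(
            [["m1", "g1", "srcA", "predicted"], ["m1", "g1", "srcB", "validated"]]
        )
        out = mt.candidate_pairs(de_m, de_g, db)
        assert len(out) == 1
        assert out.loc[0, "sources"] == frozenset({"srcA", "srcB"})
        assert bool(out.loc[0, "validated"])

    def test_enumeration_of_de_restricted_pairs(self):
        de_m = _de_table({f"m{i}": (1.0, 0.01) for i in (1, 2, 3)})
        de_g = _de_table({f"g{i}": (-1.0, 0.01) for i in (1, 2, 3, 4)})
        rows = [
            ["m1", "g1", "srcA", "predicted"],
            ["m1", "g2", "srcA", "predicted"],
            ["m2", "g3", "srcA", "predicted"],
            ["m3", "g4", "srcA", "predicted"],
            ["m3", "g1", "srcA", "predicted"],
            ["m9", "g1", "srcA", "predicted"],  # miRNA not DE
        ]
        out = mt.candidate_pairs(de_m, de_g, self._db(rows))
        assert len(out) == 5

    def test_empty_de_sets_give_empty_list(self, caplog):
        de_m = _de_table({"m1": (1.0, 0.5)})
        de_g = _de_table({"g1": (-1.0, 0.01)})
        db = self._db([["m1", "g1", "srcA", "predicted"]])
        out = mt.candidate_pairs(de_m, de_g, db)
        assert out.empty

    def test_shared_feature_ids_rejected(self):
        de_m = _de_table({"x1": (1.0, 0.01)})
        de_g = _de_table({"x1": (-1.0, 0.01)})
        db = self._db([["x1", "x1", "srcA", "predicted"]])
        with pytest.raises(ValueError, match="shared across layers"):
            mt.candidate_pairs(de_m, de_g, db)


class TestPearsonWithP:
    def test_antipodal_vectors(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = mt.pearson_with_p(x, -x)
        assert np.isclose(r, -1.0)
        assert p < 1e-10

    def test_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        r, p = mt.pearson_with_p(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert np.isclose(r, r_hand, atol=1e-12)
        from scipy import stats

        t = r_hand * np.sqrt((len(x) - 2) / (1 - r_hand**2))
        assert np.isclose(p, 2 * stats.t.sf(abs(t), len(x) - 2), atol=1e-12)

    def test_p_matches_permutation_reference(self):
        rng = np.random.default_rng(21)
        for _ in range(4):
            x = rng.normal(size=8)
            y = 0.7 * x + rng.normal(size=8)
            r, p = mt.pearson_with_p(x, y)
            perm_r = []
            for _ in range(10000):
                perm_r.append(abs(np.corrcoef(x, rng.permutation(y))[0, 1]))
            perm_p = (np.sum(np.asarray(perm_r) >= abs(r)) + 1) / 10001
            se = np.sqrt(perm_p * (1 - perm_p) / 10000)
            assert abs(p - perm_p) < max(4 * se, 0.01)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mt.pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            mt.pearson_with_p([1.0, 2.0], [3.0, 4.0])


class TestBuildNetwork:
    def _setup(self):
        rng = np.random.default_rng(30)
        samples = [f"s{i}" for i in range(11)]
        x = rng.normal(5, 1, 11)
        rm = pd.DataFrame([x], index=["m1"], columns=samples)
        rg = pd.DataFrame(
            [-x + rng.normal(0, 0.3, 11), rng.normal(5, 1, 11)],
            index=["g1", "g2"], columns=samples,
        )
        candidates = pd.DataFrame(
            {
                "mirna": ["m1", "m1"],
                "gene": ["g1", "g2"],
                "sources": [frozenset({"srcA"})] * 2,
                "validated": [True, False],
            }
        )
        return candidates, rm, rg

    def test_strong_anticorrelation_admitted_noise_rejected(self):
        candidates, rm, rg = self._setup()
        net = mt.build_network(candidates, rm, rg)
        assert set(zip(net.edges.mirna, net.edges.gene)) == {("m1", "g1")}
        assert bool(net.edges.loc[0, "validated"])

    def test_thresholds_are_strict_inequalities(self):
        candidates, rm, rg = self._setup()
        r, p = mt.pearson_with_p(rm.loc["m1"], rg.loc["g1"])
        at_r = mt.build_network(candidates, rm, rg, r_threshold=r)
        assert ("m1", "g1") not in set(zip(at_r.edges.mirna, at_r.edges.gene))
        at_p = mt.build_network(candidates, rm, rg, p_threshold=p)
        assert ("m1", "g1") not in set(zip(at_p.edges.mirna, at_p.edges.gene))
        below = mt.build_network(
            candidates, rm, rg, r_threshold=r + 1e-9, p_threshold=p + 1e-9
        )
        assert ("m1", "g1") in set(zip(below.edges.mirna, below.edges.gene))

    def test_sample_intersection_too_small_rejected(self):
        candidates, rm, rg = self._setup()
        with pytest.raises(ValueError, match="shared samples"):
            mt.build_network(candidates, rm, rg[rg.columns[:2]])

    def test_stored_edge_statistics_recomputable(self, small_network, small_cohort):
        """Every admitted edge's (r, p) must reproduce exactly from the
        expression matrices it was computed on."""
        mirna_ds, mrna_ds, _ = small_cohort
        rm = mt.rlog_transform(mirna_ds)
        rg = mt.rlog_transform(mrna_ds)
        shared = [s for s in rm.columns if s in set(rg.columns)]
        assert small_network.n_edges > 0
        for row in small_network.edges.itertuples(index=False):
            r, p = mt.pearson_with_p(
                rm.loc[row.mirna, shared], rg.loc[row.gene, shared]
            )
            assert abs(r - row.pearson_r) < 1e-10
            assert abs(p - row.p_value) < 1e-10

    def test_null_layers_rarely_pass_filter(self):
        """Independent layers at n = 12: < 2% of candidate pairs survive."""
        cfg = mt.SimulationConfig(
            seed=31, n_control=6, n_case=6, n_mirna=40, n_gene=100,
            n_true_pairs=0, repression_slope=0.0, de_fraction_mirna=0.0,
            de_fraction_gene=0.0, marker_effect=0.0,
            composition_shift={"control": (5.0, 5.0), "case": (5.0, 5.0)},
            rna_subset=None,
        )
        mirna_ds, mrna_ds, _ = mt.simulate_dataset(cfg)
        rm = mt.rlog_transform(mirna_ds)
        rg = mt.rlog_transform(mrna_ds)
        rng = np.random.default_rng(0)
        passed = 0
        n_pairs = 2000
        for _ in range(n_pairs):
            r, p = mt.pearson_with_p(
                rm.loc[rng.choice(rm.index)], rg.loc[rng.choice(rg.index)]
            )
            passed += (r < -0.7) and (p < 0.05)
        assert passed / n_pairs <= 0.02


class TestNetworkSummary:
    def test_targeted_percentages_match_printed_ratios(self):
        """866 of 2209 down genes targeted -> 39%; 478 of 1660 up -> 29%."""
        down = {f"d{i}": (-1.0, 0.01) for i in range(2209)}
        up = {f"u{i}": (1.0, 0.01) for i in range(1660)}
        de_gene = _de_table(down | up)
        edges = [("m1", f"d{i}", -0.8, 0.01, False) for i in range(866)]
        edges += [("m1", f"u{i}", -0.8, 0.01, False) for i in range(478)]
        summary = mt.network_summary(make_network(edges), de_gene)
        assert summary["pct_down_targeted"] == 39
        assert summary["pct_up_targeted"] == 29

    def test_empty_network_zero_percentages(self):
        de_gene = _de_table({"g1": (-1.0, 0.01)})
        summary = mt.network_summary(make_network([]), de_gene)
        assert summary["pct_down_targeted"] == 0
        assert summary["n_edges"] == 0


class TestDegreeCorrelationTest:
    def test_all_single_degree_missing_p(self):
        net = make_network(
            [("m1", "g1", -0.8, 0.01, False), ("m2", "g2", -0.9, 0.01, False)]
        )
        report = mt.degree_correlation_test(net)
        assert report.mwu_p is None and report.median_multi is None

    def test_identical_distributions_p_one(self):
        edges = []
        for i, r in enumerate((-0.8, -0.75, -0.9)):
            edges.append((f"m1", f"s{i}", r, 0.01, False))     # degree-1 genes
            edges.append((f"m1", f"d{i}", r, 0.01, False))     # degree-2 genes
            edges.append((f"m2", f"d{i}", r, 0.01, False))
        net = make_network(edges)
        report = mt.degree_correlation_test(net)
        assert report.mwu_p == pytest.approx(1.0)

    def test_u_statistic_matches_exhaustive_enumeration(self):
        multi_r = [-0.85, -0.80, -0.78]
        single_r = [-0.76, -0.74, -0.72]
        edges = []
        for i, r in enumerate(single_r):
            edges.append(("m1", f"s{i}", r, 0.01, False))
        for i, r in enumerate(multi_r):
            edges.append(("m1", f"d{i}", r, 0.01, False))
            edges.append(("m2", f"d{i}", r, 0.01, False))
        net = make_network(edges)
        report = mt.degree_correlation_test(net)

        # oracle: exact two-sided p by enumerating all group assignments
        pooled = multi_r + single_r
        u_obs = sum(
            (a < b) + 0.5 * (a == b)
            for a in multi_r for b in single_r
        )
        n1 = len(multi_r)
        us = []
        for combo in itertools.combinations(range(len(pooled)), n1):
            group = [pooled[i] for i in combo]
            rest = [pooled[i] for i in range(len(pooled)) if i not in combo]
            us.append(sum((a < b) + 0.5 * (a == b) for a in group for b in rest))
        us = np.asarray(us)
        mean_u = n1 * (len(pooled) - n1) / 2
        p_exact = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
        assert report.mwu_p == pytest.approx(p_exact, abs=1e-9)


class TestPrioritizeTargets:
    def test_printed_ratio_168_of_492(self):
        edges = []
        for i in range(492):
            validated = i < 168
            edges.append((f"mA", f"g{i}", -0.8, 0.01, validated))
            edges.append((f"mB", f"g{i}", -0.8, 0.01, False))
        out = mt.prioritize_targets(make_network(edges))
        assert len(out.tier_a) == 492
        assert len(out.tier_b) == 168
        assert out.pct_validated == 34

    def test_degree_and_validation_rules(self):
        net = make_network(
            [
                ("m1", "gA", -0.8, 0.01, False),
                ("m2", "gA", -0.8, 0.01, False),   # degree 2, unvalidated
                ("m1", "gB", -0.9, 0.01, True),    # degree 1, validated
            ]
        )
        out = mt.prioritize_targets(net)
        assert out.tier_a == ["gA"]
        assert out.tier_b == []


class TestOverlapPrioritizedGenes:
    def test_disjoint_list_empty_subnetwork(self):
        net = make_network([("m1", "g1", -0.8, 0.01, False)])
        report = mt.overlap_prioritized_genes(net, ["x1", "x2"], {"x1", "g1"})
        assert report.n_in_network == 0
        assert report.subnetwork.n_edges == 0

    def test_full_list_covers_network_genes(self):
        net = make_network(
            [("m1", "g1", -0.8, 0.01, False), ("m2", "g2", -0.9, 0.01, True)]
        )
        report = mt.overlap_prioritized_genes(net, ["g1", "g2"], {"g1", "g2"})
        assert report.n_in_network == 2

    def test_induced_subnetwork_exact(self):
        edges = [(f"m{i % 3}", f"g{i}", -0.8, 0.01, i % 2 == 0) for i in range(10)]
        net = make_network(edges)
        listed = ["g0", "g4", "g7", "zz1", "zz2", "zz3", "zz4", "zz5", "zz6", "zz7"]
        report = mt.overlap_prioritized_genes(net, listed, set(f"g{i}" for i in range(10)))
        assert report.genes_in_network == ["g0", "g4", "g7"]
        assert set(report.subnetwork.genes) == {"g0", "g4", "g7"}
        assert report.subnetwork.n_edges == 3
        assert report.n_expressed == 3
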