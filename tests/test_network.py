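"""Sponge-network construction: correlations, hypergeometric test, filters."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spongenet as sp
from spongenet import diffexpr as dx, network as nw


class TestCorrelations:
    def test_perfect_antimonotone(self):
        assert nw.rank_correlation(range(1, 7), list(range(6, 0, -1))) == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        x = np.arange(1.0, 7.0)
        assert nw.rank_correlation(x, x**2) == pytest.approx(1.0)

    def test_tied_ranks_hand_computed(self):
        # ranks x: 1, 2.5, 2.5, 4; ranks y: 2.5, 4, 2.5, 1
        # centered products: 0, 0, 0, -2.25 -> r = -2.25/4.5 = -0.5
        assert nw.rank_correlation([1, 2, 2, 3], [3, 4, 3, 1]) == pytest.approx(-0.5, abs=1e-12)
        # fully anti-monotone with symmetric ties -> -1
        assert nw.rank_correlation([1, 2, 2, 3], [4, 3, 3, 1]) == pytest.approx(-1.0, abs=1e-12)

    def test_pearson_affine(self):
        x = np.array([0.0, 1.0, 5.0, 2.0])
        assert nw.pearson_correlation(x, x) == pytest.approx(1.0)
        assert nw.pearson_correlation(x, -2 * x + 7) == pytest.approx(-1.0)

    def test_pearson_three_point_hand_value(self):
        # cov/(sd sd) = 3/sqrt(2*14/3) = sqrt(27/28)
        expected = math.sqrt(27.0 / 28.0)
        assert nw.pearson_correlation([1, 2, 3], [1, 2, 4]) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        assert math.isnan(nw.rank_correlation([1, 1, 1], [1, 2, 3]))
        assert math.isnan(nw.pearson_correlation([1, 2, 3], [5, 5, 5]))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            nw.rank_correlation([1, 2], [3, 4])


def hypergeom_upper_tail_oracle(k, K, n, N):
    """Brute-force enumeration of all C(N, n) draws."""
    population = [1] * K + [0] * (N - K)
    total = hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


class TestSpongeTest:
    def test_zero_overlap_is_certain(self):
        assert nw.sponge_test(0, 3, 4, 10) == 1.0

    def test_forced_overlap_is_certain(self):
        assert nw.sponge_test(2, 2, 2, 2) == 1.0

    def test_enumerated_example(self):
        # N=10, K=4, n=5: 66 of the 252 draws contain >= 3 successes.
        assert nw.sponge_test(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-15)

    def test_matches_enumeration_for_small_universes(self):
        for N in range(2, 9):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(0, min(K, n) + 1):
                        assert nw.sponge_test(k, K, n, N) == pytest.approx(
                            hypergeom_upper_tail_oracle(k, K, n, N), abs=1e-12
                        )

    def test_matches_scipy_survival_function(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            N = int(rng.integers(2, 500))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert nw.sponge_test(k, K, n, N) == pytest.approx(
                stats.hypergeom.sf(k - 1, N, K, n), rel=1e-9
            )

    def test_non_increasing_in_k(self):
        vals = [nw.sponge_test(k, 6, 7, 15) for k in range(0, 7)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            nw.sponge_test(3, 2, 5, 10)
        with pytest.raises(ValueError):
            nw.sponge_test(1, 5, 5, 4)
        with pytest.raises(ValueError):
            nw.sponge_test(0, 0, 3, 10)


def _pair_matrices(vectors_a, vectors_b, prefix_a="MIR", prefix_b="LNC"):
    cols = [f"NHS_M{i+1}" for i in range(3)] + [f"HS_M{i+1}" for i in range(3)]
    design = [sp.SampleDesign(c, c.split("_")[0], "mammary") for c in cols]
    a = pd.DataFrame(vectors_a, index=[f"{prefix_a}{i}" for i in range(len(vectors_a))], columns=cols)
    b = pd.DataFrame(vectors_b, index=[f"{prefix_b}{i}" for i in range(len(vectors_b))], columns=cols)
    return a, b, design


class TestNegativePairFilter:
    def test_strictness_membership_and_de_gating(self):
        up = [1, 2, 3, 4, 5, 6]
        down = [6, 5, 4, 3, 2, 1]
        # vector engineered to give SCC exactly -0.7 with `up`:
        # ranks (1..6) vs (2,4,1,6,3,5) reversed... use a direct construction:
        mir, lnc, design = _pair_matrices([up], [down, up], prefix_b="LNC")
        targets = pd.DataFrame(
            {
                "mirna_id": ["MIR0", "MIR0"],
                "target_id": ["LNC0", "LNC1"],
                "target_class": ["lncRNA", "lncRNA"],
            }
        )
        got = nw.select_negative_target_pairs(
            mir, lnc, targets, {"MIR0"}, {"LNC0", "LNC1"}, -0.7, "lncRNA"
        )
        assert list(got["target_id"]) == ["LNC0"]
        assert got["scc"].iloc[0] == pytest.approx(-1.0)
        # not DE -> excluded even at SCC == -1
        got = nw.select_negative_target_pairs(mir, lnc, targets, {"MIR0"}, set(), -0.7, "lncRNA")
        assert got.empty
        # absent from the target table -> excluded
        got = nw.select_negative_target_pairs(
            mir, lnc, targets.iloc[1:], {"MIR0"}, {"LNC0", "LNC1"}, -0.7, "lncRNA"
        )
        assert list(got["target_id"]) == []

    def test_boundary_scc_excluded(self):
        # y chosen so Spearman(x, y) is exactly -0.7: d_i^2 sums to 59.5
        # impossible with integers; instead verify the strict rule at the
        # threshold by passing scc_thresh equal to the realized SCC.
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5][::-1]
        scc = nw.rank_correlation(x, y)
        mir, lnc, design = _pair_matrices([x], [y])
        targets = pd.DataFrame(
            {"mirna_id": ["MIR0"], "target_id": ["LNC0"], "target_class": ["lncRNA"]}
        )
        got = nw.select_negative_target_pairs(mir, lnc, targets, {"MIR0"}, {"LNC0"}, scc, "lncRNA")
        assert got.empty  # SCC == threshold is not < threshold

    def test_sample_column_mismatch_rejected(self):
        mir, lnc, _ = _pair_matrices([[1, 2, 3, 4, 5, 6]], [[6, 5, 4, 3, 2, 1]])
        with pytest.raises(ValueError, match="sample columns"):
            nw.select_negative_target_pairs(
                mir, lnc[list(lnc.columns[::-1])], pd.DataFrame(columns=["mirna_id", "target_id", "target_class"]), set(), set()
            )


class TestCandidatePairs:
    def test_requires_shared_mirna_and_strict_pcc(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        lnc, mrna, _ = _pair_matrices([x], [x, -x + 10], prefix_a="LNC", prefix_b="MRNA")
        neg_lnc = pd.DataFrame({"mirna_id": ["MIR0"], "target_id": ["LNC0"], "scc": [-1.0]})
        neg_mrna = pd.DataFrame({"mirna_id": ["MIR0"], "target_id": ["MRNA0"], "scc": [-1.0]})
        got = nw.candidate_sponge_pairs(lnc, mrna, neg_lnc, neg_mrna, 0.9)
        assert list(got["lnc_id"]) == ["LNC0"]
        assert got["shared_mirnas"].iloc[0] == frozenset({"MIR0"})
        # PCC exactly at the threshold is excluded
        got = nw.candidate_sponge_pairs(lnc, mrna, neg_lnc, neg_mrna, 1.0)
        assert got.empty
        # no shared miRNA -> excluded even at PCC 1.0
        neg_mrna2 = pd.DataFrame({"mirna_id": ["MIR9"], "target_id": ["MRNA0"], "scc": [-1.0]})
        got = nw.candidate_sponge_pairs(lnc, mrna, neg_lnc, neg_mrna2, 0.9)
        assert got.empty


def _build_from_bundle(bundle, **kwargs):
    params, truth, design, lnc, mir, mrna = bundle
    tabs = [dx.de_table(m, design) for m in (lnc, mir, mrna)]
    net = nw.build_network(lnc, mir, mrna, design, truth.target_table, *tabs, **kwargs)
    return truth, net


class TestBuildNetwork:
    def test_zero_noise_exact_recovery(self, zero_noise_bundle):
        truth, net = _build_from_bundle(zero_noise_bundle, universe_policy="table")
        assert nw.sponge_pairs(net) == truth.true_sponge_pairs()
        # supporting negative edges present for every sponge edge
        for u, v, d in net.edges(data=True):
            if d["edge_type"] != "lnc_mrna":
                continue
            lnc_id, mrna_id = (u, v) if net.nodes[u]["node_type"] == "lncRNA" else (v, u)
            for mir_id in d["shared_mirnas"].split(";"):
                assert net.has_edge(mir_id, lnc_id) and net.has_edge(mir_id, mrna_id)

    def test_alpha_zero_gives_no_sponge_edges(self, zero_noise_bundle):
        truth, net = _build_from_bundle(
            zero_noise_bundle,
            thresholds=nw.NetworkThresholds(alpha=0.0),
            universe_policy="table",
        )
        assert nw.sponge_pairs(net) == set()

    def test_empty_de_sets_give_empty_network(self, zero_noise_bundle):
        params, truth, design, lnc, mir, mrna = zero_noise_bundle
        tabs = [dx.de_table(m, design) for m in (lnc, mir, mrna)]
        empty = tabs[1].copy()
        empty["is_de"] = False
        net = nw.build_network(lnc, mir, mrna, design, truth.target_table,
                               tabs[0], empty, tabs[2])
        assert net.number_of_nodes() == 0

    def test_hand_crafted_toy_one_passing_one_failing(self):
        # Six samples; triplet A passes all filters, triplet B fails PCC.
        cols = [f"NHS_M{i+1}" for i in range(3)] + [f"HS_M{i+1}" for i in range(3)]
        design = [sp.SampleDesign(c, c.split("_")[0], "mammary") for c in cols]
        mir_a = np.array([1.0, 2.0, 3.0, 20.0, 30.0, 40.0])
        mir_b = np.array([2.0, 4.0, 8.0, 30.0, 40.0, 60.0])
        lnc_a = 100.0 / mir_a          # anti-monotone with mir_a
        mrna_a = 200.0 / mir_a         # anti-monotone, PCC(lnc_a, mrna_a) = 1
        lnc_b = 100.0 / mir_b
        mrna_b = np.array([50.0, 8.0, 35.0, 2.0, 1.5, 1.0])  # anti-monotone but crooked
        assert nw.pearson_correlation(lnc_b, mrna_b) < 0.9
        lnc = pd.DataFrame([lnc_a, lnc_b], index=["LA", "LB"], columns=cols)
        mir = pd.DataFrame([mir_a, mir_b], index=["MA", "MB"], columns=cols)
        mrna = pd.DataFrame([mrna_a, mrna_b], index=["RA", "RB"], columns=cols)
        targets = pd.DataFrame(
            {
                "mirna_id": ["MA", "MA", "MB", "MB"] + ["MX"] * 2,
                "target_id": ["LA", "RA", "LB", "RB", "LA", "RB"],
                "target_class": ["lncRNA", "mRNA", "lncRNA", "mRNA", "lncRNA", "mRNA"],
            }
        )
        de = pd.DataFrame({"is_de": True}, index=["LA", "LB", "MA", "MB", "RA", "RB", "MX"])
        # alpha=1 disables the sharing test: this toy isolates the two
        # correlation filters (a 3-miRNA universe cannot reach p < 0.05).
        net = nw.build_network(lnc, mir, mrna, design, targets, de, de, de,
                               thresholds=nw.NetworkThresholds(alpha=1.0),
                               universe_policy="table")
        assert nw.sponge_pairs(net) == {("LA", "RA")}

    def test_invariant_to_row_order_and_consistent_sample_permutation(self, zero_noise_bundle):
        params, truth, design, lnc, mir, mrna = zero_noise_bundle
        tabs = [dx.de_table(m, design) for m in (lnc, mir, mrna)]
        net1 = nw.build_network(lnc, mir, mrna, design, truth.target_table, *tabs,
                                universe_policy="table")
        rng = np.random.default_rng(0)
        perm_design = list(design)
        rng.shuffle(perm_design)
        shuffled = [m.sample(frac=1, random_state=4) for m in (lnc, mir, mrna)]
        tbl = truth.target_table.sample(frac=1, random_state=5, ignore_index=True)
        net2 = nw.build_network(*shuffled, perm_design, tbl, *tabs, universe_policy="table")
        assert nw.sponge_pairs(net1) == nw.sponge_pairs(net2)
        assert set(net1.nodes) == set(net2.nodes)

    @pytest.mark.parametrize(
        "tighter",
        [
            dict(thresholds=nw.NetworkThresholds(scc=-0.8)),
            dict(thresholds=nw.NetworkThresholds(pcc=0.95)),
            dict(thresholds=nw.NetworkThresholds(alpha=0.01)),
        ],
    )
    def test_tightening_any_threshold_never_adds_edges(self, default_bundle,
                                                       default_de_tables, tighter):
        params, truth, design, lnc, mir, mrna = default_bundle
        base = nw.build_network(lnc, mir, mrna, design, truth.target_table,
                                *default_de_tables)
        tight = nw.build_network(lnc, mir, mrna, design, truth.target_table,
                                 *default_de_tables, **tighter)
        assert nw.sponge_pairs(tight) <= nw.sponge_pairs(base)

    def test_stochastic_recovery_on_planted_truth(self, default_bundle, default_de_tables):
        params, truth, design, lnc, mir, mrna = default_bundle
        net = nw.build_network(lnc, mir, mrna, design, truth.target_table,
                               *default_de_tables)
        found = nw.sponge_pairs(net)
        tp = len(found & truth.true_sponge_pairs())
        assert tp / max(len(found), 1) >= 0.8
        assert tp / len(truth.true_sponge_pairs()) >= 0.8


class TestSubnetworkAndSummary:
    def _toy_net(self):
        net = None
        cols = [f"NHS_M{i+1}" for i in range(3)] + [f"HS_M{i+1}" for i in range(3)]
        design = [sp.SampleDesign(c, c.split("_")[0], "mammary") for c in cols]
        mir_a = np.array([1.0, 2.0, 3.0, 20.0, 30.0, 40.0])
        lnc = pd.DataFrame([100 / mir_a, 50 / mir_a], index=["L1", "L2"], columns=cols)
        mir = pd.DataFrame([mir_a], index=["M1"], columns=cols)
        mrna = pd.DataFrame([200 / mir_a, 70 / mir_a], index=["R1", "R2"], columns=cols)
        # M2 is a decoy annotation that widens the miRNA universe to 2,
        # keeping the (forced) sharing p at 0.5 < 1 under alpha=1.
        targets = pd.DataFrame(
            {
                "mirna_id": ["M1"] * 4 + ["M2"],
                "target_id": ["L1", "L2", "R1", "R2", "L1"],
                "target_class": ["lncRNA", "lncRNA", "mRNA", "mRNA", "lncRNA"],
            }
        )
        de = pd.DataFrame({"is_de": True}, index=["L1", "L2", "M1", "M2", "R1", "R2"])
        return nw.build_network(lnc, mir, mrna, design, targets, de, de, de,
                                thresholds=nw.NetworkThresholds(alpha=1.0),
                                universe_policy="table")

    def test_extract_by_gene_set(self):
        net = self._toy_net()
        assert len(nw.sponge_pairs(net)) == 4
        sub = nw.extract_subnetwork(net, nw.GeneSet("hub", frozenset({"R1"})))
        assert nw.sponge_pairs(sub) == {("L1", "R1"), ("L2", "R1")}
        disjoint = nw.extract_subnetwork(net, nw.GeneSet("none", frozenset({"ZZZ"})))
        assert disjoint.number_of_nodes() == 0
        everything = nw.extract_subnetwork(net, nw.GeneSet("all", frozenset({"R1", "R2"})))
        assert nw.sponge_pairs(everything) == nw.sponge_pairs(net)

    def test_summary_counts(self):
        net = self._toy_net()
        s = nw.network_summary(net)
        assert s["n_lnc_mrna_pairs"] == 4
        assert s["nodes_by_type"] == {"lncRNA": 2, "miRNA": 1, "mRNA": 2}
        assert s["per_mrna"]["R1"] == {"n_lncRNAs": 2, "n_miRNAs": 1}

    def test_empty_summary(self):
        import networkx as nx

        s = nw.network_summary(nx.Graph())
        assert s["n_lnc_mrna_pairs"] == 0
        assert s["per_mrna"] == {}

    def test_zero_noise_pair_count_matches_truth(self, zero_noise_bundle):
        truth, net = _build_from_bundle(zero_noise_bundle, universe_policy="table")
        assert nw.network_summary(net)["n_lnc_mrna_pairs"] == len(truth.triplets)


def ora_enumeration_oracle(hits, members, universe):
    """Exact p by enumerating all equally-likely hit sets of the same size."""
    universe = sorted(universe)
    k_obs = len(hits & members)
    total = count = 0
    for draw in itertools.combinations(universe, len(hits)):
        total += 1
        if len(set(draw) & members) >= k_obs:
            count += 1
    return count / total


class TestOraEnrichment:
    def test_hits_equal_universe(self):
        sets = [nw.GeneSet("s", frozenset({"a", "b"}))]
        out = nw.ora_enrichment({"a", "b", "c"}, sets, {"a", "b", "c"})
        assert out.loc[0, "k"] == 2
        assert out.loc[0, "pvalue"] == 1.0

    def test_delegation_to_sponge_test(self):
        hits = {"a", "b", "c"}
        universe = hits | {"d", "e", "f"}
        out = nw.ora_enrichment(hits, [nw.GeneSet("s", frozenset(hits))], universe)
        assert out.loc[0, "pvalue"] == pytest.approx(nw.sponge_test(3, 3, 3, 6))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        universe = set("abcdefghij")
        for _ in range(20):
            hits = set(rng.choice(sorted(universe), size=4, replace=False))
            members = frozenset(rng.choice(sorted(universe), size=5, replace=False))
            out = nw.ora_enrichment(hits, [nw.GeneSet("s", members)], universe)
            assert out.loc[0, "pvalue"] == pytest.approx(
                ora_enumeration_oracle(hits, set(members), universe), abs=1e-12
            )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            nw.ora_enrichment(set(), [nw.GeneSet("s", frozenset("ab"))], set())
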