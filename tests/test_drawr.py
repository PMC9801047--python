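"""Two-stage walk, pruning, permutation calibration, end-to-end runner."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from splicefi import (
    FIParams,
    QueryConfig,
    crossval_diagnostic,
    permutation_test,
    prune_to_subnetwork,
    run_fi,
    rwr,
    stage1,
    stage2,
)
from splicefi.drawr import empirical_pvalues

from conftest import dense_rwr_oracle, random_network


class TestRWR:
    def test_two_node_ring_closed_form(self):
        T = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        res = rwr(T, np.array([1.0, 0.0]), c=0.7, tol=1e-12, max_iter=500)
        # pi = c (I - (1-c)T)^-1 v = (0.7/0.91, 0.21/0.91)
        assert res.pi == pytest.approx([0.7 / 0.91, 0.21 / 0.91], abs=1e-10)
        assert res.converged

    def test_uniform_restart_on_vertex_transitive_graph(self):
        n = 6  # ring graph: uniform restart must give the uniform vector
        M = np.zeros((n, n))
        for i in range(n):
            M[i, (i + 1) % n] = M[(i + 1) % n, i] = 1.0
        T = sp.csr_matrix(M / M.sum(axis=0))
        res = rwr(T, np.full(n, 1 / n), c=0.7, tol=1e-12)
        assert res.pi == pytest.approx(np.full(n, 1 / n), abs=1e-10)

    def test_iterative_matches_linear_solve_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            net = random_network(rng, n_g=12, n_a=6, n_p=3)
            T = net.transition()
            v = np.zeros(net.n)
            v[: max(1, net.n // 4)] = 1.0 / max(1, net.n // 4)
            res = rwr(T, v, c=0.7, tol=1e-10, max_iter=2000)
            oracle = dense_rwr_oracle(T, v, 0.7)
            assert np.abs(res.pi - oracle).max() < 1e-8

    def test_fixed_point_identity_and_mass(self):
        rng = np.random.default_rng(7)
        net = random_network(rng)
        T = net.transition()
        v = np.zeros(net.n)
        v[0] = 1.0
        res = rwr(T, v, c=0.7, tol=1e-12, max_iter=2000)
        assert res.pi.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.abs(0.3 * (T @ res.pi) + 0.7 * v - res.pi).max() < 1e-9

    def test_contraction_rate(self):
        rng = np.random.default_rng(9)
        net = random_network(rng)
        T = net.transition()
        v = np.zeros(net.n)
        v[0] = 1.0
        c = 0.7
        pi = np.full(net.n, 1 / net.n)
        prev_err = None
        for _ in range(10):
            pi = (1 - c) * (T @ pi) + c * v
            err = np.abs(pi - dense_rwr_oracle(T, v, c)).sum()
            if prev_err is not None and prev_err > 1e-14:
                assert err <= (1 - c) * prev_err + 1e-12
            prev_err = err

    def test_bad_inputs(self):
        T = sp.csr_matrix(np.array([[0.5, 1.0], [0.2, 0.0]]))  # not stochastic
        with pytest.raises(ValueError):
            rwr(T, np.array([1.0, 0.0]))
        T2 = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            rwr(T2, np.array([1.0, 0.0]), c=1.5)

    def test_nonconvergence_flagged_not_raised(self):
        T = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        res = rwr(T, np.array([1.0, 0.0]), c=0.7, tol=1e-15, max_iter=3)
        assert not res.converged and res.iterations == 3


class TestStage1:
    def test_query_equal_background_gives_zero_scores(self, toy_net):
        genes = list(toy_net.node_ids[toy_net.gene_mask])
        r = stage1(toy_net, genes, QueryConfig(tol=1e-12))
        assert np.abs(r.table["score"].to_numpy()).max() < 1e-10

    def test_feature_adjacent_to_query_outranks_twin(self, toy_net):
        cfg = QueryConfig(tol=1e-12)
        r = stage1(toy_net, ["g0", "g1"], cfg)
        feats = r.feature_ranking().set_index("node_id")
        assert (
            feats.loc["SE:gx:chr1:+:1-2:3-4", "score"]
            > feats.loc["SE:gy:chr1:+:5-6:7-8", "score"]
        )
        assert feats.loc["pwA", "score"] > feats.loc["pwB", "score"]
        # cross-check stationary vectors against the dense linear solve
        T = toy_net.transition()
        vq = np.zeros(toy_net.n)
        for g in ("g0", "g1"):
            vq[toy_net.index_of(g)] = 0.5
        oracle = dense_rwr_oracle(T, vq, 0.7)
        got = r.table.set_index("node_id")["statP_Q"]
        assert np.abs(got[toy_net.node_ids].to_numpy() - oracle).max() < 1e-8

    def test_scores_independent_of_query_order(self, toy_net):
        a = stage1(toy_net, ["g0", "g1"], QueryConfig(tol=1e-12)).table
        b = stage1(toy_net, ["g1", "g0"], QueryConfig(tol=1e-12)).table
        pd.testing.assert_frame_equal(a, b)

    def test_query_outside_network_errors(self, toy_net):
        with pytest.raises(ValueError):
            stage1(toy_net, ["not_a_gene"])


class TestPrune:
    def test_full_feature_count_is_noop(self, toy_net):
        r = stage1(toy_net, ["g0"], QueryConfig(tol=1e-12))
        sub = prune_to_subnetwork(toy_net, r, num_feats=4)
        assert sub.n == toy_net.n

    def test_single_feature_survives(self):
        # two events with distinct stage-1 scores: only the top one is kept
        from splicefi import assemble_adjacency

        ga = sp.coo_matrix(
            (np.array([0.9, 0.3]), (np.array([0, 1]), np.array([0, 1]))), shape=(2, 2)
        )
        net = assemble_adjacency(
            ["g0", "g1"], ["e_strong", "e_weak"], [],
            [("g0", "g1", 0.5)], ga, sp.coo_matrix((2, 0)),
        )
        r = stage1(net, ["g0"], QueryConfig(tol=1e-12))
        sub = prune_to_subnetwork(net, r, num_feats=1)
        assert list(sub.node_ids[sub.feature_mask]) == ["e_strong"]

    def test_boundary_ties_all_kept(self, toy_net):
        r = stage1(toy_net, ["g0", "g1"], QueryConfig(tol=1e-12))
        tied = r.table.copy()
        tied.loc[tied["kind"] != "gene", "score"] = 0.25  # force a 4-way tie
        from splicefi.drawr import StageRanking

        sub = prune_to_subnetwork(toy_net, StageRanking(tied), num_feats=2)
        assert int(sub.feature_mask.sum()) == 4


class TestStage2:
    def test_equals_stage1_without_pruning(self, toy_net):
        cfg = QueryConfig(tol=1e-12)
        s1 = stage1(toy_net, ["g0", "g1"], cfg)
        s2 = stage2(toy_net, ["g0", "g1"], cfg)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_statp_sums_to_one(self, toy_net):
        cfg = QueryConfig(tol=1e-12)
        sub = prune_to_subnetwork(
            toy_net, stage1(toy_net, ["g0", "g1"], cfg), num_feats=2
        )
        s2 = stage2(sub, ["g0", "g1"], cfg)
        assert s2.table["statP_Q"].sum() == pytest.approx(1.0, abs=1e-9)
        assert s2.table["statP_B"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_top_stage1_feature_retained_in_stage2(self):
        rng = np.random.default_rng(2024)
        cfg = QueryConfig(tol=1e-12)
        for _ in range(20):
            net = random_network(rng, n_g=10, n_a=6, n_p=2)
            genes = list(net.node_ids[net.gene_mask])
            q = list(rng.choice(genes, size=3, replace=False))
            s1 = stage1(net, q, cfg)
            top1 = s1.feature_ranking()["node_id"].iloc[0]
            k = min(4, int(net.feature_mask.sum()))
            sub = prune_to_subnetwork(net, s1, num_feats=k)
            s2 = stage2(sub, q, cfg)
            kept = set(s2.feature_ranking()["node_id"].head(k))
            assert top1 in kept


class TestPermutation:
    def test_indicator_fraction_by_hand(self):
        null = np.array([[0.1, 0.2, 0.3, 0.4]])
        assert empirical_pvalues(null, np.array([0.25]))[0] == pytest.approx(0.5)
        assert empirical_pvalues(null, np.array([0.9]))[0] == 0.0

    def test_monte_carlo_matches_exact_enumeration(self):
        # 6-gene network, |Q| = 2: all C(6,2) = 15 null queries enumerable
        rng = np.random.default_rng(123)
        net = random_network(rng, n_g=6, n_a=3, n_p=1)
        genes = list(net.node_ids[net.gene_mask])
        assert len(genes) == 6
        cfg = QueryConfig(tol=1e-12, restart=0.7)
        query = genes[:2]
        s2 = stage2(net, query, cfg)
        obs = s2.gene_scores()

        T = net.transition()
        gene_idx = np.nonzero(net.gene_mask)[0]
        exact_null = []
        for pair in itertools.combinations(gene_idx, 2):
            v = np.zeros(net.n)
            v[list(pair)] = 0.5
            exact_null.append(dense_rwr_oracle(T, v, 0.7)[net.gene_mask])
        exact_null = np.array(exact_null).T  # genes x 15
        # the actual query is one of the 15 draws and ties the observed
        # value exactly; strict comparison of a tie depends on rounding,
        # so the enumerated tail is the interval [P(>), P(>=)]
        vq = np.zeros(net.n)
        vq[[net.index_of(g) for g in query]] = 0.5
        pi_hat_exact = dense_rwr_oracle(T, vq, 0.7)[net.gene_mask]
        lower = (exact_null > pi_hat_exact[:, None] + 1e-9).mean(axis=1)
        tie = (np.abs(exact_null - pi_hat_exact[:, None]) <= 1e-9).mean(axis=1)
        upper = lower + tie

        n_perm = 1000
        perm = permutation_test(net, query, obs, n_perm=n_perm, seed=5, cfg=cfg)
        mc_p = perm.table.set_index("gene_id").loc[genes, "perm_p"].to_numpy()
        se_lo = np.sqrt(lower * (1 - lower) / n_perm)
        se_hi = np.sqrt(upper * (1 - upper) / n_perm)
        assert np.all(mc_p >= lower - 3 * se_lo - 1e-9)
        assert np.all(mc_p <= upper + 3 * se_hi + 1e-9)

    def test_reproducible_given_seed(self, toy_net):
        cfg = QueryConfig(tol=1e-10)
        s2 = stage2(toy_net, ["g0"], cfg)
        a = permutation_test(toy_net, ["g0"], s2.gene_scores(), n_perm=50, seed=9, cfg=cfg)
        b = permutation_test(toy_net, ["g0"], s2.gene_scores(), n_perm=50, seed=9, cfg=cfg)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestCrossval:
    def test_folds_partition_query(self, toy_net):
        aucs = crossval_diagnostic(toy_net, ["g0", "g1", "g2"], num_folds=3, seed=0)
        assert len(aucs) == 3

    def test_too_few_query_genes_errors(self, toy_net):
        with pytest.raises(ValueError):
            crossval_diagnostic(toy_net, ["g0"], num_folds=5)

    def test_star_fixture_retrieves_held_out_neighbors(self):
        # hub gene connected to all query genes; held-out genes are the
        # hub's neighbors and must outrank the detached background genes
        from splicefi import assemble_adjacency

        n = 18
        genes = [f"g{i}" for i in range(n)]
        gg = [(f"g{i}", "g0", 0.9) for i in range(1, 5)]
        gg += [(f"g{i}", f"g{i + 1}", 0.9) for i in range(5, n - 1)]
        ga = sp.coo_matrix(
            (np.ones(n) * 0.5, (np.arange(n), np.zeros(n, int))), shape=(n, 1)
        )
        net = assemble_adjacency(genes, ["e0"], [], gg, ga, sp.coo_matrix((n, 0)))
        aucs = crossval_diagnostic(
            net, ["g1", "g2", "g3", "g4"], num_folds=4, seed=0,
            cfg=QueryConfig(tol=1e-12),
        )
        # each held-out spoke outranks every detached gene (the hub alone
        # may sit above it)
        assert np.mean(aucs) > 0.9


class TestRunFI:
    def test_end_to_end_deterministic(self, small_dataset, tmp_path):
        ds = small_dataset
        params = FIParams()
        params.query_cfg.n_perm = 30
        params.query_cfg.num_feats = 50
        params.query_cfg.seed = 3
        outs = []
        for rep in range(2):
            res = run_fi(
                ds.expression, ds.psi, ds.gene_sets, ds.ref_edges, ds.query, params
            )
            p = tmp_path / f"as_{rep}.tsv"
            res.as_table.to_csv(p, sep="\t", index=False)
            res.gene_table.to_csv(tmp_path / f"gene_{rep}.tsv", sep="\t", index=False)
            outs.append(res)
        assert (tmp_path / "as_0.tsv").read_bytes() == (tmp_path / "as_1.tsv").read_bytes()
        assert (tmp_path / "gene_0.tsv").read_bytes() == (tmp_path / "gene_1.tsv").read_bytes()
        assert set(outs[0].manifest) >= {"network", "walk", "n_nodes_subnet"}

    def test_no_gene_as_edges_still_completes(self, small_dataset):
        ds = small_dataset
        params = FIParams()
        params.network.cor_threshold = 0.9999  # no edge can strictly exceed this
        params.query_cfg.n_perm = 0
        res = run_fi(
            ds.expression, ds.psi, ds.gene_sets, ds.ref_edges, ds.query, params
        )
        assert res.as_table.empty
        assert not res.gene_table.empty

    def test_planted_events_dominate_ranking(self, small_dataset):
        ds = small_dataset
        params = FIParams()
        params.query_cfg.n_perm = 0
        res = run_fi(
            ds.expression, ds.psi, ds.gene_sets, ds.ref_edges, ds.query, params
        )
        truth = dict(zip(ds.event_truth["event_id"], ds.event_truth["planted"]))
        top20 = res.as_table.head(20)["event_id"]
        assert np.mean([truth[e] for e in top20]) > 0.9
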