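"""Simulator and leave-one-out evaluation harness."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from meplace import simeval
from meplace.placement import PlacementOptions
from meplace.seqio import AlignedQuery, Topology
from meplace.simeval import (
    NoisyRead,
    SimConfig,
    SimulatedDataset,
    apply_read_noise,
    discrete_gamma_rates,
    extract_read,
    leave_one_out_eval,
    simulate_alignment,
    simulate_dataset,
    simulate_tree,
)


def _cfg(**kw):
    base = dict(n_taxa=10, seq_len=300, seed=1, read_lengths=(100, 300))
    base.update(kw)
    return SimConfig(**base)


class TestSimulateTree:
    def test_minimal_tree_has_five_edges(self):
        topo = simulate_tree(_cfg(n_taxa=4), np.random.default_rng(0))
        assert topo.n_leaves == 4
        assert topo.n_edges == 5

    def test_collapsed_rate_interval_is_clocklike(self):
        cfg = _cfg(n_taxa=12, rate_low=0.22, rate_high=0.22)
        topo = simulate_tree(cfg, np.random.default_rng(3))
        # with a constant rate the tree is exactly clock-like: every leaf's
        # farthest partner lies across the clock root, so the maximum path
        # from each leaf equals twice the clock depth — a constant
        labels, D = topo.leaf_path_distance_matrix()
        far = D.max(axis=1)
        assert np.allclose(far, far[0], rtol=1e-9)

    def test_mean_branch_length_is_calibrated(self):
        for seed in range(3):
            topo = simulate_tree(_cfg(n_taxa=40), np.random.default_rng(seed))
            m = topo.edge_lengths().mean()
            assert 0.03 <= m <= 0.07
            assert m == pytest.approx(0.05)

    def test_labels_unique_and_deterministic(self):
        t1 = simulate_tree(_cfg(n_taxa=15), np.random.default_rng(9))
        t2 = simulate_tree(_cfg(n_taxa=15), np.random.default_rng(9))
        assert t1.newick() == t2.newick()
        assert len(set(t1.leaf_labels)) == 15


class TestSimulateAlignment:
    def test_zero_length_branch_copies_parent(self):
        # two leaves joined by zero-length edges must be identical
        spec = (
            None,
            None,
            [
                ("a", 0.0, []),
                ("b", 0.0, []),
                (None, 0.5, [("c", 0.3, []), ("d", 0.3, [])]),
            ],
        )
        topo = Topology.from_spec(spec)
        aln = simulate_alignment(topo, _cfg(n_taxa=4), np.random.default_rng(1))
        assert aln.seqs[aln.index_of("a")] == aln.seqs[aln.index_of("b")]

    def test_jc_pairwise_divergence_matches_closed_form(self):
        # two taxa at known distance; JC expectation p = 3/4 (1 - e^{-4d/3})
        d = 0.3
        spec = (
            None,
            None,
            [("a", d / 2, []), ("b", d / 2, []), (None, 2.0, [("c", 0.1, []), ("e", 0.1, [])])],
        )
        topo = Topology.from_spec(spec)
        cfg = SimConfig(
            n_taxa=4, seq_len=2000, seed=0, read_lengths=(100,),
            gamma_alpha=1e6, p_invariant=0.0,
        )
        aln = simulate_alignment(topo, cfg, np.random.default_rng(11))
        sa = aln.seqs[aln.index_of("a")]
        sb = aln.seqs[aln.index_of("b")]
        p_obs = np.mean([x != y for x, y in zip(sa, sb)])
        p_exp = 0.75 * (1 - np.exp(-4 * d / 3))
        se = np.sqrt(p_exp * (1 - p_exp) / 2000)
        assert abs(p_obs - p_exp) < 3 * se

    def test_gamma_heterogeneity_increases_site_variance(self):
        rng_seed = 5
        topo = simulate_tree(_cfg(n_taxa=20), np.random.default_rng(2))
        cfg_het = _cfg(n_taxa=20, seq_len=1000, gamma_alpha=0.7, p_invariant=0.0)
        cfg_hom = _cfg(n_taxa=20, seq_len=1000, gamma_alpha=1e6, p_invariant=0.0)
        var = {}
        for name, cfg in (("het", cfg_het), ("hom", cfg_hom)):
            aln = simulate_alignment(topo, cfg, np.random.default_rng(rng_seed))
            codes = aln.codes()
            # per-column mismatch fraction over all sequence pairs
            col_div = np.array(
                [
                    np.mean(codes[:, c][:, None] != codes[:, c][None, :])
                    for c in range(codes.shape[1])
                ]
            )
            var[name] = col_div.var()
        assert var["het"] > var["hom"]

    def test_discrete_gamma_rates_average_to_one(self):
        r = discrete_gamma_rates(0.7, 5)
        assert r.shape == (5,)
        assert np.all(np.diff(r) > 0)
        assert r.mean() == pytest.approx(1.0, abs=1e-9)


class TestExtractRead:
    def test_full_length_returns_whole_sequence(self):
        seq = "ACGT" * 25
        q = extract_read(seq, 100, np.random.default_rng(0))
        assert q.seq == seq
        assert list(q.cols) == list(range(100))

    def test_block_is_contiguous(self):
        seq = "ACGT" * 500
        q = extract_read(seq, 125, np.random.default_rng(1))
        assert q.n_covered == 125
        assert (np.diff(q.cols) == 1).all()

    def test_too_long_read_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            extract_read("ACGT", 5, np.random.default_rng(0))

    def test_start_position_is_uniform(self):
        seq = "A" * 500
        rng = np.random.default_rng(42)
        starts = [extract_read(seq, 100, rng).cols[0] for _ in range(1000)]
        # 401 possible starts; KS against the continuous uniform
        res = stats.kstest(np.array(starts) / 400.0, "uniform")
        assert res.pvalue > 0.001


class TestReadNoise:
    def _read(self, L=2000, seed=0):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), L))
        return AlignedQuery("r", np.arange(L), seq)

    def test_zero_rates_are_identity(self):
        q = self._read(200)
        noisy = apply_read_noise(q, np.random.default_rng(0), sub=0, dup=0, delete=0)
        assert noisy.seq == q.seq
        assert (noisy.col_map == q.cols).all()

    def test_certain_substitution_changes_every_base(self):
        q = self._read(200)
        noisy = apply_read_noise(q, np.random.default_rng(0), sub=1, dup=0, delete=0)
        assert len(noisy.seq) == 200
        assert all(a != b for a, b in zip(noisy.seq, q.seq))

    def test_expected_length_is_preserved_at_default_rates(self):
        # deletions remove 1%, duplications add 1%: E[len] = L
        q = self._read(2000)
        rng = np.random.default_rng(7)
        lens = [len(apply_read_noise(q, rng).seq) for _ in range(300)]
        # per-read variance: Var = L(p_del(1-p_del) + p_dup(1-p_dup))
        se = np.sqrt(2000 * 2 * 0.01 * 0.99 / 300)
        assert abs(np.mean(lens) - 2000) < 3 * se

    def test_aligned_view_drops_stutter_and_gaps_deletions(self):
        q = AlignedQuery("r", np.arange(4), "ACGT")
        noisy = NoisyRead("r", "AACGT", np.array([0, -1, 1, 2, 3]))
        back = noisy.aligned_query()
        assert back.seq == "ACGT"
        assert list(back.cols) == [0, 1, 2, 3]

    def test_stutter_survives_deletion_of_template(self):
        # force dup and del together on every base: copies remain, originals go
        q = self._read(100)
        noisy = apply_read_noise(q, np.random.default_rng(1), sub=0, dup=1, delete=1)
        assert len(noisy.seq) == 100
        assert (noisy.col_map == -1).all()


class TestMetrics:
    def test_quartet_node_separation(self):
        from meplace.seqio import parse_newick_string

        topo = parse_newick_string("((a:1,b:1):1,(c:1,d:1):1);")
        ea = topo.find_edge_by_split({"a"})
        ec = topo.find_edge_by_split({"c"})
        assert simeval.node_separation(topo, ea, ea) == 0
        assert simeval.node_separation(topo, ea, ec) == 2

    def test_unknown_edge_rejected(self):
        from meplace.seqio import parse_newick_string

        topo = parse_newick_string("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(KeyError):
            simeval.node_separation(topo, 0, 99)


class TestLeaveOneOut:
    def test_wellseparated_fullength_is_perfect(self):
        # hand-built 10-leaf tree with every branch >= 0.05 subs/site
        rng = np.random.default_rng(4)
        from _helpers import random_topology

        topo = random_topology(10, rng, lo=0.06, hi=0.15)
        cfg = SimConfig(
            n_taxa=10, seq_len=1200, seed=3, read_lengths=(1200,),
        )
        aln = simulate_alignment(topo, cfg, np.random.default_rng(8))
        ds = SimulatedDataset(topo, aln, cfg)
        rep = leave_one_out_eval(cfg, mode="loo", noise=False, dataset=ds)
        assert rep.summary()["f_c"].iloc[0] == 1.0

    def test_truth_bookkeeping_self_consistency(self):
        # pruning x and re-inserting x's own additive distance row must
        # recover the merged truth edge exactly
        from _helpers import additive_matrix, random_topology
        from meplace import me_core

        rng = np.random.default_rng(6)
        topo = random_topology(9, rng, lo=0.05, hi=0.2)
        order, D = additive_matrix(topo)
        for x in order[:4]:
            k = order.index(x)
            pruned, truth = topo.prune_leaf(x)
            keep = [i for i in range(len(order)) if i != k]
            scan = me_core.insertion_scan(
                pruned, D[np.ix_(keep, keep)], D[k, keep],
                [order[i] for i in keep],
            )
            assert scan.best()[0] == truth

    def test_histogram_totals_match_query_count(self):
        cfg = _cfg(n_taxa=12, seq_len=300, read_lengths=(150, 300))
        rep = leave_one_out_eval(cfg, mode="loo", noise=True)
        assert sum(rep.sn_histogram().values()) == len(rep.records)
        assert ((rep.records["s_n"] == 0) == rep.records["correct"]).all()

    def test_known_mode_beats_leave_one_out(self):
        cfg = SimConfig(n_taxa=40, seq_len=600, seed=11, read_lengths=(200,))
        ds = simulate_dataset(cfg)
        loo = leave_one_out_eval(cfg, mode="loo", noise=True, dataset=ds)
        known = leave_one_out_eval(cfg, mode="known", noise=True, dataset=ds)
        assert (
            known.summary()["f_c"].iloc[0] > loo.summary()["f_c"].iloc[0]
        )

    def test_bootstrap_column_collected(self):
        cfg = _cfg(n_taxa=10, seq_len=300, read_lengths=(300,))
        rep = leave_one_out_eval(
            cfg,
            options=PlacementOptions(bootstrap=10, seed=1),
            mode="loo",
            noise=False,
        )
        assert rep.records["support"].between(0, 1).all()


class TestConfigIO:
    def test_toml_roundtrip(self, tmp_path):
        cfg = _cfg(n_taxa=25, noise_sub=0.02)
        p = tmp_path / "sim.toml"
        cfg.to_file(p)
        back = SimConfig.from_file(p)
        assert back == cfg

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "sim.toml"
        p.write_text("bogus = 3\n")
        with pytest.raises(ValueError, match="bogus"):
            SimConfig.from_file(p)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            _cfg(noise_sub=1.5)
        with pytest.raises(ValueError):
            _cfg(read_lengths=(4000,))
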