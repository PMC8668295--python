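"""Topographic connectivity generation: placement, pools, degrees, modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgnet import (
    ConnectionRule,
    connectivity_summary,
    generate_network,
    place_cells,
    read_edge_list,
    select_targets,
    write_edge_list,
)
from dgnet.exceptions import ConfigurationError, GenerationError, ParseError
from dgnet.topology import DEFAULT_COUNTS, HEALTHY_RULES, scaled_rules


class TestPlaceCells:
    def test_default_counts_layout(self):
        pops = place_cells(DEFAULT_COUNTS)
        assert sum(p.count for p in pops.values()) == 527
        gc = pops["GC"]
        assert np.allclose(gc.axis_positions, (np.arange(500) + 0.5) / 500)
        assert gc.offset == 0 and pops["MC"].offset == 500

    def test_single_cell_sits_at_midpoint(self):
        pops = place_cells({"GC": 1, "MC": 1, "BC": 1, "HIPP": 1})
        for p in pops.values():
            assert p.axis_positions.tolist() == [0.5]

    def test_two_cells_quartile_positions(self):
        pops = place_cells({"GC": 10, "MC": 2, "BC": 1, "HIPP": 1})
        assert pops["MC"].axis_positions.tolist() == [0.25, 0.75]

    @pytest.mark.parametrize("bad", [{"GC": 0, "MC": 1, "BC": 1, "HIPP": 1},
                                     {"GC": -3, "MC": 1, "BC": 1, "HIPP": 1},
                                     {"GC": 5, "MC": 1, "BC": 1}])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            place_cells(bad)

    def test_positions_strictly_increasing(self):
        pops = place_cells({"GC": 37, "MC": 4, "BC": 2, "HIPP": 9})
        for p in pops.values():
            assert np.all(np.diff(p.axis_positions) > 0)


def brute_force_pool(rule, pre_pos, post_pop, pre_gid):
    """Independent nearest-neighbour derivation of the eligible target set."""
    d = np.abs(post_pop.axis_positions - pre_pos)
    order = sorted(range(post_pop.count), key=lambda i: (d[i], i))
    pool = order[: min(rule.pool_size, post_pop.count)]
    eligible = pool[rule.center_exclusion:]
    gids = [i + post_pop.offset for i in eligible]
    if not rule.allow_self and pre_gid in gids:
        gids.remove(pre_gid)
    return set(gids)


class TestSelectTargets:
    def test_toy_pool_matches_exhaustive_nearest_neighbours(self):
        pops = place_cells({"GC": 10, "MC": 1, "BC": 1, "HIPP": 1})
        rule = ConnectionRule("MC", "GC", divergence=4, pool_size=4)
        rng = np.random.default_rng(0)
        targets = select_targets(rule, pops["MC"].offset, pops, rng)
        # with divergence == pool size the whole pool is returned
        assert set(targets) == brute_force_pool(rule, 0.5, pops["GC"], pops["MC"].offset)
        assert set(targets) == {3, 4, 5, 6}

    def test_zero_divergence_yields_no_targets(self):
        pops = place_cells(DEFAULT_COUNTS)
        rule = ConnectionRule("MC", "GC", divergence=0, pool_size=10)
        assert len(select_targets(rule, 500, pops, np.random.default_rng(0))) == 0

    def test_mc_to_gc_rule_returns_exactly_200_targets(self):
        pops = place_cells(DEFAULT_COUNTS)
        rule = ConnectionRule("MC", "GC", divergence=200, pool_size=350, center_exclusion=50)
        rng = np.random.default_rng(3)
        for mc in pops["MC"].global_ids():
            targets = select_targets(rule, int(mc), pops, rng)
            assert len(targets) == 200
            assert len(set(targets.tolist())) == 200

    def test_targets_respect_pool_and_center_exclusion(self):
        pops = place_cells(DEFAULT_COUNTS)
        rng = np.random.default_rng(7)
        for rule in HEALTHY_RULES:
            pre_pop = pops[rule.pre_type]
            for pre in (pre_pop.offset, pre_pop.offset + pre_pop.count // 2,
                        pre_pop.offset + pre_pop.count - 1):
                eligible = brute_force_pool(
                    rule, pre_pop.axis_positions[pre - pre_pop.offset],
                    pops[rule.post_type], pre)
                targets = set(select_targets(rule, pre, pops, rng).tolist())
                assert targets <= eligible, rule.name

    def test_infeasible_rule_names_the_rule(self):
        pops = place_cells({"GC": 10, "MC": 2, "BC": 1, "HIPP": 1})
        rule = ConnectionRule("MC", "MC", divergence=2, pool_size=2)
        with pytest.raises(GenerationError, match="MC->MC"):
            select_targets(rule, pops["MC"].offset, pops, np.random.default_rng(0))

    @pytest.mark.parametrize("div,pool,excl", [(5, 4, 0), (3, 4, 2), (1, 3, 3)])
    def test_invalid_rule_parameters_rejected(self, div, pool, excl):
        with pytest.raises(ConfigurationError):
            ConnectionRule("MC", "GC", divergence=div, pool_size=pool,
                           center_exclusion=excl).validate()

    @given(n_post=st.integers(5, 40), pool=st.integers(2, 10),
           excl=st.integers(0, 3), seed=st.integers(0, 100))
    @settings(max_examples=40, deadline=None)
    def test_out_degree_always_equals_divergence(self, n_post, pool, excl, seed):
        pool = min(pool, n_post)
        excl = min(excl, pool - 1)
        div = pool - excl
        pops = place_cells({"GC": n_post, "MC": 3, "BC": 1, "HIPP": 1})
        rule = ConnectionRule("MC", "GC", divergence=div, pool_size=pool,
                              center_exclusion=excl)
        rng = np.random.default_rng(seed)
        for mc in pops["MC"].global_ids():
            targets = select_targets(rule, int(mc), pops, rng)
            assert len(targets) == div
            assert len(np.unique(targets)) == div


class TestGenerateNetwork:
    def test_healthy_has_no_recurrent_gc_and_active_mossy_cells(self, healthy_network):
        net = healthy_network
        assert net.edge_count("GC", "GC") == 0
        assert net.edge_count("BC", "HIPP") == 0
        out = net.edges.pre_id.value_counts()
        for mc in net.populations["MC"].global_ids():
            assert out.get(mc, 0) > 0

    def test_total_contact_count_is_rule_sum(self, healthy_network):
        expected = sum(
            r.divergence * DEFAULT_COUNTS[r.pre_type] for r in HEALTHY_RULES
        )
        assert len(healthy_network.edges) == expected == 7228

    def test_sprouting_adds_exactly_degree_times_gc_edges(self):
        net = generate_network(mode="pathological", seed=4, sprouting_degree=2, mc_loss=0)
        assert net.edge_count("GC", "GC") == 1000
        sprouted = net.edges[(net.edges.pre_type == "GC") & (net.edges.post_type == "GC")]
        assert not (sprouted.pre_id == sprouted.post_id).any()

    def test_mossy_cell_loss_removes_all_their_edges(self):
        net = generate_network(mode="pathological", seed=4, sprouting_degree=2, mc_loss=5)
        mc_ids = set(net.populations["MC"].global_ids().tolist())
        touched = set(net.edges.pre_id) | set(net.edges.post_id)
        assert len(mc_ids - touched) == 5

    def test_same_seed_reproduces_identical_edge_list(self):
        a = generate_network(seed=11)
        b = generate_network(seed=11)
        assert a.edges.equals(b.edges)

    def test_seed_changes_edges_but_not_degree_statistics(self):
        a = generate_network(seed=1)
        b = generate_network(seed=2)
        assert not a.edges.equals(b.edges)
        sa = connectivity_summary(a)
        sb = connectivity_summary(b)
        assert np.allclose(sa.divergence_mean, sb.divergence_mean)
        assert np.allclose(sa.convergence_mean, sb.convergence_mean)
        assert (sa.edge_count == sb.edge_count).all()

    def test_healthy_mode_rejects_recurrent_gc_rule(self):
        rules = HEALTHY_RULES + (ConnectionRule("GC", "GC", 2, 100),)
        with pytest.raises(ConfigurationError):
            generate_network(mode="healthy", seed=0, rules=rules)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_network(mode="sclerotic", seed=0)


class TestConnectivitySummary:
    def test_convergence_equals_edge_conservation_for_every_rule(self, healthy_network):
        summary = connectivity_summary(healthy_network)
        for rule in HEALTHY_RULES:
            row = summary.loc[(rule.pre_type, rule.post_type)]
            expected = (DEFAULT_COUNTS[rule.pre_type] * rule.divergence
                        / DEFAULT_COUNTS[rule.post_type])
            assert row.convergence_mean == pytest.approx(expected, abs=1e-12)
            assert row.divergence_mean == pytest.approx(rule.divergence, abs=1e-12)

    def test_empty_network_summary_is_all_zero(self):
        net = generate_network(counts={"GC": 2, "MC": 1, "BC": 1, "HIPP": 1}, rules=())
        assert connectivity_summary(net).empty


class TestEdgeListIO:
    def test_round_trip_preserves_edges(self, tmp_path, healthy_network):
        path = tmp_path / "edges.tsv"
        write_edge_list(healthy_network, path)
        back = read_edge_list(path, counts=DEFAULT_COUNTS)
        a = healthy_network.edges[["pre_id", "post_id"]].sort_values(
            ["pre_id", "post_id"]).reset_index(drop=True)
        b = back.edges[["pre_id", "post_id"]].sort_values(
            ["pre_id", "post_id"]).reset_index(drop=True)
        assert a.equals(b)

    def test_malformed_cell_id_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("pre_id\tpost_id\tpre_type\tpost_type\nXX7\tGC0\tGC\tGC\n")
        with pytest.raises(ParseError, match="line 2"):
            read_edge_list(path)


class TestScaledRules:
    def test_mini_rule_set_generates_with_exact_degrees(self):
        counts = {"GC": 20, "MC": 3, "BC": 2, "HIPP": 2}
        net = generate_network(counts=counts, seed=0, rules=scaled_rules(counts))
        out = net.edges.groupby(["pre_type", "pre_id"]).size()
        for rule in net.rules:
            sub = net.edges[(net.edges.pre_type == rule.pre_type)
                            & (net.edges.post_type == rule.post_type)]
            per_pre = sub.groupby("pre_id").size()
            assert (per_pre == rule.divergence).all()
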