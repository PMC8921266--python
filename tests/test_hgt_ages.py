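"""HGT event weighting rules, age distributions, box summaries, overlaps."""

import numpy as np
import pytest

from poomkit.chronogram_io import GeologicalWindow, read_dated_trees
from poomkit.hgt_ages import (
    HGTError,
    HGTEvent,
    HGTMapping,
    LeafOnlyEventError,
    WeightedAgeDistribution,
    event_bounds,
    filter_by_support,
    read_hgt_table,
    recipient_weights,
    summarize_box,
    weighted_age_distribution,
    window_overlap,
    write_hgt_table,
)


def event(mappings, event_id="E1", support=1.0):
    return HGTEvent(event_id=event_id, mappings=mappings, support=support)


class TestRecipientWeights:
    def test_single_internal_recipient(self):
        rw = recipient_weights(event([HGTMapping("X", "A|B", 100)]))
        assert rw.weights == (("A|B", 1.0),)
        assert not rw.leaf_only

    def test_multiple_internal_fraction_weights(self):
        rw = recipient_weights(
            event([HGTMapping("X", "A|B", 60), HGTMapping("X", "C|D", 40)])
        )
        assert dict(rw.weights) == pytest.approx({"A|B": 0.6, "C|D": 0.4})

    def test_leaf_recipients_deleted_and_renormalized(self):
        rw = recipient_weights(
            event([HGTMapping("X", "A", 50), HGTMapping("X", "C|D", 50)])
        )
        assert dict(rw.weights) == pytest.approx({"C|D": 1.0})

    def test_leaf_only_flagged_not_errored(self):
        rw = recipient_weights(event([HGTMapping("X", "A", 100)]))
        assert rw.leaf_only and rw.weights == ()

    def test_invariant_under_count_scaling(self):
        maps = [HGTMapping("X", "A|B", 3), HGTMapping("X", "C|D", 7)]
        scaled = [HGTMapping("X", "A|B", 30), HGTMapping("X", "C|D", 70)]
        assert recipient_weights(event(maps)).weights == recipient_weights(
            event(scaled)
        ).weights


class TestWeightedAgeDistribution:
    def test_point_mass_on_identical_trees(self, identical_ensemble):
        dist = weighted_age_distribution(
            event([HGTMapping("X", "A|B", 100)]), identical_ensemble
        )
        assert dist.mean() == pytest.approx(100.0)
        assert np.allclose(dist.ages, 100.0)
        assert dist.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_brute_force_enumeration_two_recipients(self):
        # two trees with different CD ages; weights 0.6/0.4 over 2 trees
        trees = (
            "((A:100,B:100):150,(C:200,D:200):50);\n"
            "((A:110,B:110):140,(C:180,D:180):70);\n"
        )
        ens = read_dated_trees(trees, burn_in=0.0)
        e = event([HGTMapping("X", "A|B", 60), HGTMapping("X", "C|D", 40)])
        dist = weighted_age_distribution(e, ens)
        assert sorted(dist.weights) == pytest.approx([0.2, 0.2, 0.3, 0.3])
        expected = 0.6 * np.mean([100.0, 110.0]) + 0.4 * np.mean([200.0, 180.0])
        assert dist.mean() == pytest.approx(expected)

    def test_leaf_only_event_raises(self, identical_ensemble):
        with pytest.raises(LeafOnlyEventError):
            weighted_age_distribution(
                event([HGTMapping("X", "A", 100)]), identical_ensemble
            )

    def test_unresolvable_specifier_names_event(self, identical_ensemble):
        with pytest.raises(HGTError, match="E1.*A|Z"):
            weighted_age_distribution(
                event([HGTMapping("X", "A|Z", 100)]), identical_ensemble
            )

    def test_weights_normalized(self, jittered_ensemble):
        from poomkit.synthetic_data import make_hgt_table

        events, _ = make_hgt_table(jittered_ensemble, n_events=10, leaf_mix=0.3, seed=7)
        for e in events:
            dist = weighted_age_distribution(e, jittered_ensemble)
            assert dist.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestEventBounds:
    def test_single_tree_point_masses(self, single_tree_ensemble):
        b = event_bounds(
            event([HGTMapping("X", "C|D", 100)]), single_tree_ensemble
        )
        assert b.younger.mean() == pytest.approx(200.0)
        assert b.older.mean() == pytest.approx(250.0)

    def test_root_recipient_rejected(self, single_tree_ensemble):
        with pytest.raises(HGTError, match="root"):
            event_bounds(
                event([HGTMapping("X", "A|B|C|D", 100)]), single_tree_ensemble
            )

    def test_older_mean_at_least_younger_mean(self, jittered_ensemble):
        from poomkit.synthetic_data import make_hgt_table

        events, _ = make_hgt_table(jittered_ensemble, n_events=10, leaf_mix=0.2, seed=8)
        for e in events:
            b = event_bounds(e, jittered_ensemble)
            assert b.older.mean() >= b.younger.mean()

    def test_bound_means_recover_generating_ages(self, yule_tree):
        from poomkit.synthetic_data import make_posterior_ensemble

        cv = 0.05
        ens = make_posterior_ensemble(yule_tree, n_trees=100, age_jitter_cv=cv, seed=9)
        # pick a non-root internal clade well separated from its neighbours
        # (near-ties are compressed by the ordering constraint)
        def separated(n):
            age = yule_tree.age_of(n)
            gap_c = age - max(yule_tree.age_of(c) for c in n.child_nodes())
            gap_p = yule_tree.age_of(n.parent_node) - age
            return min(gap_c, gap_p) > 3 * cv * yule_tree.age_of(n.parent_node)

        node = next(
            n for n in yule_tree.tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and separated(n)
        )
        spec = "|".join(sorted(l.taxon.label for l in node.leaf_iter()))
        b = event_bounds(event([HGTMapping("X", spec, 100)]), ens)
        mc_tol = 4 * 0.05 / np.sqrt(100)  # ~4 standard errors of the jitter
        assert b.younger.mean() == pytest.approx(yule_tree.age_of(node), rel=mc_tol)
        assert b.older.mean() == pytest.approx(
            yule_tree.age_of(node.parent_node), rel=mc_tol
        )


class TestSummarizeBox:
    def test_point_mass(self):
        d = WeightedAgeDistribution(np.array([2000.0]), np.array([1.0]))
        box = summarize_box(d)
        assert (box.mean, box.p2_5, box.p25, box.p75, box.p97_5) == (2000.0,) * 5

    def test_equal_weight_mean(self):
        d = WeightedAgeDistribution(np.array([1.0, 2.0, 3.0, 4.0]), np.full(4, 0.25))
        assert summarize_box(d).mean == pytest.approx(2.5)

    def test_percentiles_match_normal_quantiles(self, rng):
        from scipy import stats

        draws = np.abs(rng.normal(2000.0, 100.0, size=4000))
        d = WeightedAgeDistribution(draws, np.full(draws.size, 1.0 / draws.size))
        box = summarize_box(d)
        for q, val in ((2.5, box.p2_5), (25, box.p25), (75, box.p75), (97.5, box.p97_5)):
            theo = stats.norm.ppf(q / 100.0, 2000.0, 100.0)
            assert val == pytest.approx(theo, abs=12.0)  # ~sampling error at n=4000

    def test_cumulative_weight_definition(self):
        # first age whose cumulative weight reaches q
        d = WeightedAgeDistribution(
            np.array([10.0, 20.0, 30.0]), np.array([0.25, 0.5, 0.25])
        )
        assert d.percentile(25) == 10.0
        assert d.percentile(26) == 20.0
        assert d.percentile(75) == 20.0
        assert d.percentile(76) == 30.0


class TestWindowOverlap:
    def test_interval_endpoint_inside_window(self, single_tree_ensemble):
        # branch interval [1830-style younger, 2350-style older] vs GOE window:
        # the older endpoint falls inside the window, so overlap is certain
        b = event_bounds(event([HGTMapping("X", "C|D", 100)]), single_tree_ensemble)
        # here bounds are [200, 250]; window [240, 210] overlaps
        w = GeologicalWindow("W", 240.0, 210.0)
        assert window_overlap(b, w) == pytest.approx(1.0)

    def test_window_older_than_all_samples(self, single_tree_ensemble):
        b = event_bounds(event([HGTMapping("X", "C|D", 100)]), single_tree_ensemble)
        w = GeologicalWindow("old", 1000.0, 900.0)
        assert window_overlap(b, w) == 0.0

    def test_matches_brute_force_enumeration(self, jittered_ensemble):
        from poomkit.synthetic_data import make_hgt_table

        events, _ = make_hgt_table(jittered_ensemble, n_events=5, leaf_mix=0.0, seed=10)
        b = event_bounds(events[0], jittered_ensemble)
        med = float(np.median(b.younger.ages))
        w = GeologicalWindow("mid", med + 50.0, max(med - 50.0, 0.0))
        brute = sum(
            wt
            for o, y, wt in zip(b.older.ages, b.younger.ages, b.younger.weights)
            if y <= w.older and o >= w.younger
        )
        assert window_overlap(b, w) == pytest.approx(brute, abs=1e-12)

    def test_monotone_in_window_width(self, jittered_ensemble):
        from poomkit.synthetic_data import make_hgt_table

        events, _ = make_hgt_table(jittered_ensemble, n_events=3, leaf_mix=0.0, seed=11)
        b = event_bounds(events[0], jittered_ensemble)
        center = float(np.mean(b.younger.ages))
        prev = 0.0
        for half in (1.0, 10.0, 100.0, 1000.0):
            w = GeologicalWindow("w", center + half, max(center - half, 0.0))
            cur = window_overlap(b, w)
            assert cur >= prev - 1e-12
            prev = cur

    def test_marginal_mode_factorizes(self, jittered_ensemble):
        from poomkit.synthetic_data import make_hgt_table

        events, _ = make_hgt_table(jittered_ensemble, n_events=3, leaf_mix=0.0, seed=12)
        b = event_bounds(events[0], jittered_ensemble)
        med = float(np.median(b.younger.ages))
        w = GeologicalWindow("mid", med + 30.0, max(med - 30.0, 0.0))
        p_o = b.older.weights[b.older.ages >= w.younger].sum()
        p_y = b.younger.weights[b.younger.ages <= w.older].sum()
        assert window_overlap(b, w, mode="marginal") == pytest.approx(p_o * p_y)


class TestTableIO:
    def test_round_trip(self, tmp_path):
        events = [
            event([HGTMapping("D1", "A|B", 60), HGTMapping("D2", "C", 40)], "E1"),
            event([HGTMapping("D3", "C|D", 90)], "E2", support=0.9),
        ]
        path = tmp_path / "events.tsv"
        write_hgt_table(events, path)
        back = read_hgt_table(path)
        assert [e.event_id for e in back] == ["E1", "E2"]
        assert back[0].mappings == events[0].mappings
        assert back[1].support == pytest.approx(0.9)

    def test_support_filter_default_080(self):
        evs = [
            event([HGTMapping("X", "A|B", 100)], "hi", support=0.85),
            event([HGTMapping("X", "A|B", 100)], "lo", support=0.79),
        ]
        assert [e.event_id for e in filter_by_support(evs)] == ["hi"]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("event_id\tdonor\n")
        with pytest.raises(HGTError, match="missing column"):
            read_hgt_table(path)
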