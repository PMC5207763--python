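import itertools

import numpy as np
import pytest
from scipy.stats import binom

from genecycle.events import (
    PRE_ROOT,
    GeneEventRecord,
    LifeStage,
    build_event_record,
    classify_life_stage,
    event_rate_ratio,
    infer_gain_branch,
    infer_loss_branches,
    loss_propensity,
    tabulate_branch_events,
)
from genecycle.phylo import LineageConfig, parse_newick, resolve_lineage

from dollo_oracle import all_rooted_topologies, oracle_min_losses, topology_to_newick


def presence_for(tree, present):
    return {s: s in present for s in tree.leaf_names}


class TestInferGain:
    def test_outgroup_carrier_means_oldest(self, toy_tree, toy_lineage):
        gain, age = infer_gain_branch(
            presence_for(toy_tree, {"F", "C"}), toy_tree, toy_lineage
        )
        assert (gain, age) == (PRE_ROOT, "oldest")

    def test_ingroup_gain_at_carrier_mrca(self, toy_tree, toy_lineage):
        # {F, A} sit below the K.waltii-style threshold (node X): recent gain
        gain, age = infer_gain_branch(
            presence_for(toy_tree, {"F", "A"}), toy_tree, toy_lineage
        )
        assert gain == "X"
        assert age == "recent_gain"

    def test_focal_only_is_focal_specific(self, toy_tree, toy_lineage):
        gain, age = infer_gain_branch(presence_for(toy_tree, {"F"}), toy_tree, toy_lineage)
        assert (gain, age) == ("F", "focal_specific")

    def test_absent_focal_rejected(self, toy_tree, toy_lineage):
        with pytest.raises(ValueError, match="focal"):
            infer_gain_branch(presence_for(toy_tree, {"A"}), toy_tree, toy_lineage)


class TestInferLosses:
    def test_core_gene_has_no_losses(self, toy_tree, toy_lineage):
        p = presence_for(toy_tree, set(toy_tree.leaf_names))
        assert infer_loss_branches(p, toy_tree, PRE_ROOT, toy_lineage) == frozenset()

    def test_maximal_absent_clade_is_single_event(self):
        t = parse_newick("((F:1,(L1:1,L2:1)M:1)I:1,(D1:1,D2:1)O:1)R;", focal="F")
        lin = resolve_lineage(t, LineageConfig(focal="F", outgroup=frozenset({"D1", "D2"})))
        p = presence_for(t, {"F", "D1", "D2"})
        losses = infer_loss_branches(p, t, PRE_ROOT, lin)
        assert losses == {"M"}

    def test_single_absent_leaf_is_terminal_loss(self, toy_tree, toy_lineage):
        p = presence_for(toy_tree, set(toy_tree.leaf_names) - {"A"})
        assert infer_loss_branches(p, toy_tree, PRE_ROOT, toy_lineage) == {"A"}

    def test_outgroup_only_absence_ignored(self, toy_tree, toy_lineage):
        # C and D form an outgroup clade: their absence is not a counted loss
        p = presence_for(toy_tree, {"F", "A", "B"})
        assert infer_loss_branches(p, toy_tree, PRE_ROOT, toy_lineage) == frozenset()


class TestClassify:
    def test_oldest_without_losses_is_core(self, toy_tree, toy_lineage):
        rec = GeneEventRecord("g", PRE_ROOT, "oldest")
        assert classify_life_stage(rec, toy_tree, toy_lineage) is LifeStage.CORE

    def test_sister_species_loss_is_local(self, toy_tree, toy_lineage):
        rec = build_event_record(
            "g", presence_for(toy_tree, {"F", "B", "C", "D"}), toy_tree, toy_lineage
        )
        assert rec.loss_branches == {"A"}
        assert classify_life_stage(rec, toy_tree, toy_lineage) is LifeStage.LOCAL_LOSS

    def test_deep_loss_is_distant(self):
        t = parse_newick(
            "((((F:1,A:1)X:1,B:1)W:1,E:1)Y:1,(C:1,D:1)Z:1)R;", focal="F"
        )
        lin = resolve_lineage(t, LineageConfig(focal="F", local_threshold="X"))
        rec = build_event_record(
            "g", presence_for(t, {"F", "A", "E", "C", "D"}), t, lin
        )
        assert rec.loss_branches == {"B"}  # splits from the focal path above X
        assert classify_life_stage(rec, t, lin) is LifeStage.DISTANT_LOSS

    def test_losses_on_gained_genes_ignored_for_staging(self, toy_tree, toy_lineage):
        rec = GeneEventRecord("g", "Y", "ancient_gain", frozenset({"A"}))
        assert classify_life_stage(rec, toy_tree, toy_lineage) is LifeStage.ANCIENT_GAIN

    def test_every_record_gets_exactly_one_label(self, toy_tree, toy_lineage):
        leaves = set(toy_tree.leaf_names)
        n = 0
        for r in range(len(leaves)):
            for others in itertools.combinations(leaves - {"F"}, r):
                rec = build_event_record(
                    "g", presence_for(toy_tree, {"F", *others}), toy_tree, toy_lineage
                )
                assert isinstance(classify_life_stage(rec, toy_tree, toy_lineage), LifeStage)
                n += 1
        assert n == 2 ** (len(leaves) - 1)


class TestTabulate:
    def test_empty_input_all_zero(self, toy_tree):
        table = tabulate_branch_events([], toy_tree)
        assert table["gain_count"].sum() == 0
        assert table["loss_count"].sum() == 0

    def test_hand_placed_events(self, toy_tree):
        recs = [
            GeneEventRecord("g1", PRE_ROOT, "oldest", frozenset({"A", "B"})),
            GeneEventRecord("g2", "X", "recent_gain"),
            GeneEventRecord("g3", PRE_ROOT, "oldest", frozenset({"A"})),
        ]
        table = tabulate_branch_events(recs, toy_tree)
        assert table.loc["A", "loss_count"] == 2
        assert table.loc["B", "loss_count"] == 1
        assert table.loc["X", "gain_count"] == 1
        assert table.loc[PRE_ROOT, "gain_count"] == 2
        # bookkeeping identity: branch sums equal per-gene sums
        assert table["loss_count"].sum() == sum(len(r.loss_branches) for r in recs)
        assert table["gain_count"].sum() == len(recs)

    def test_unknown_branch_rejected(self, toy_tree):
        from genecycle.phylo import TreeError

        with pytest.raises(TreeError, match="unknown branch"):
            tabulate_branch_events(
                [GeneEventRecord("g", "nope", "oldest")], toy_tree
            )


class TestLossPropensity:
    def test_worked_five_leaf_example(self, toy_tree, toy_lineage):
        # toy tree: off-path non-outgroup branch lengths are A=1 only
        # (B, C, D and their stems form the outgroup); one loss on A -> 1/1
        rec = GeneEventRecord("g", PRE_ROOT, "oldest", frozenset({"A"}))
        assert loss_propensity(rec, toy_tree, toy_lineage) == pytest.approx(1.0)

    def test_core_gene_zero_over_full_length(self):
        t = parse_newick("((F:1,(L1:1,L2:2)M:1)I:1,(D1:1,D2:1)O:1)R;", focal="F")
        lin = resolve_lineage(t, LineageConfig(focal="F", outgroup=frozenset({"D1", "D2"})))
        rec = GeneEventRecord("g", PRE_ROOT, "oldest")
        # opportunity: branches M, L1, L2 = 1 + 1 + 2
        assert loss_propensity(rec, t, lin) == 0.0
        rec2 = GeneEventRecord("g", PRE_ROOT, "oldest", frozenset({"M"}))
        # loss branch M counts, its descendants L1/L2 do not: 1 event / 1
        assert loss_propensity(rec2, t, lin) == pytest.approx(1.0)
        rec3 = GeneEventRecord("g", PRE_ROOT, "oldest", frozenset({"L1"}))
        assert loss_propensity(rec3, t, lin) == pytest.approx(1 / 4)

    def test_invariant_under_uniform_rescaling(self):
        newick = "((F:{s},(L1:{s},L2:{s})M:{s})I:{s},(D1:{s},D2:{s})O:{s})R;"
        vals = []
        for scale in (1.0, 7.5):
            t = parse_newick(newick.replace("{s}", str(scale)), focal="F")
            lin = resolve_lineage(
                t, LineageConfig(focal="F", outgroup=frozenset({"D1", "D2"}))
            )
            rec = GeneEventRecord("g", PRE_ROOT, "oldest", frozenset({"L1"}))
            vals.append(loss_propensity(rec, t, lin) * scale)
        assert vals[0] == pytest.approx(vals[1])


class TestEventRateRatio:
    def test_symmetric_counts_give_unit_ratio(self):
        res = event_rate_ratio(10, 2.0, 10, 2.0)
        assert res.effect == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fourfold(self):
        assert event_rate_ratio(40, 2.0, 10, 2.0).effect == pytest.approx(4.0)

    def test_binomial_tail_matches_enumeration(self):
        res = event_rate_ratio(8, 1.0, 2, 4.0)
        assert res.effect == pytest.approx(16.0)
        # two-sided exact binomial, p0 = 0.2, n = 10, k = 8
        pmf = [binom.pmf(k, 10, 0.2) for k in range(11)]
        expected = sum(p for p in pmf if p <= pmf[8] * (1 + 1e-9))
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_degenerate_inputs(self):
        assert np.isinf(event_rate_ratio(3, 1.0, 0, 1.0).effect)
        with pytest.raises(ValueError):
            event_rate_ratio(0, 1.0, 0, 1.0)


class TestDolloMinimality:
    """Quick oracle-equivalence spot check (exhaustive sweep in acceptance)."""

    @pytest.mark.parametrize("n_leaves", [3, 4])
    def test_inferred_events_are_minimal(self, n_leaves):
        labels = ["F"] + [f"s{i}" for i in range(1, n_leaves)]
        for topo in all_rooted_topologies(labels):
            tree = parse_newick(topology_to_newick(topo), focal="F")
            lin = resolve_lineage(tree, LineageConfig(focal="F", outgroup=frozenset()))
            others = [l for l in labels if l != "F"]
            for r in range(len(others) + 1):
                for present in itertools.combinations(others, r):
                    presence = presence_for(tree, {"F", *present})
                    gain, _ = infer_gain_branch(presence, tree, lin)
                    losses = infer_loss_branches(presence, tree, gain, lin)
                    assert len(losses) == oracle_min_losses(tree, presence)
                    # reconstruction is consistent with the leaf pattern
                    start = tree.root.id if gain == PRE_ROOT else gain
                    covered = set(tree.clade_leaves(start))
                    for b in losses:
                        covered -= tree.clade_leaves(b)
                    assert covered == {s for s, v in presence.items() if v}
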