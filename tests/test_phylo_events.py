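"""Fitch parsimony, site mapping, context exposures and event inference."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from euplofs.phylo_events import (
    build_event_table,
    count_contexts,
    event_probabilities,
    fitch_states,
    infer_events,
    map_columns,
    ratio_test,
    reconstruct_ancestors,
)
from euplofs.seqcore import TreeTable, read_tree


def tree4():
    return TreeTable(read_tree("((A:1,B:1):1,(C:1,D:1):1);"))


def fitch_bruteforce(tree_table, leaf_states):
    """Minimum number of changes over all ancestral 0/1 assignments."""
    internal = [n for n in tree_table.nodes if not n.is_leaf]
    best = None
    for combo in itertools.product([0, 1], repeat=len(internal)):
        states = {n.index: s for n, s in zip(internal, combo)}
        for n in tree_table.nodes:
            if n.is_leaf and n.name in leaf_states:
                states[n.index] = leaf_states[n.name]
        changes = 0
        ok = True
        for n in tree_table.branches():
            if n.index not in states or n.parent not in states:
                ok = False
                break
            changes += states[n.index] != states[n.parent]
        if ok and (best is None or changes < best):
            best = changes
    return best


def all_labeled_trees(leaves):
    """Every rooted binary topology over the given leaf labels (newick)."""
    if len(leaves) == 1:
        return [leaves[0]]
    out = []
    first = leaves[0]
    rest = leaves[1:]
    for k in range(len(rest)):
        for left_rest in itertools.combinations(rest, k):
            left = (first,) + left_rest
            right = tuple(x for x in rest if x not in left_rest)
            if not right:
                continue
            for lt in all_labeled_trees(list(left)):
                for rt in all_labeled_trees(list(right)):
                    out.append(f"({lt}:1,{rt}:1)")
    return out


class TestFitch:
    def test_single_gain_on_clade_stem(self):
        states, score = fitch_states(tree4(), {"A": 1, "B": 1, "C": 0, "D": 0})
        assert score == 1
        assert states["N1"] == 0  # root tie resolves to absence
        assert states["N2"] == 1  # (A,B) ancestor

    def test_all_present_no_changes(self):
        states, score = fitch_states(tree4(), {"A": 1, "B": 1, "C": 1, "D": 1})
        assert score == 0
        assert all(v == 1 for v in states.values())

    def test_terminal_gain(self):
        states, score = fitch_states(tree4(), {"A": 1, "B": 0, "C": 0, "D": 0})
        assert score == 1
        assert states["A"] == 1 and states["N2"] == 0 and states["N1"] == 0

    def test_missing_leaves_are_pruned(self):
        states, score = fitch_states(tree4(), {"A": 1, "C": 0})
        assert score == 1
        assert "B" not in states

    def test_fewer_than_two_scored_leaves_rejected(self):
        with pytest.raises(ValueError):
            fitch_states(tree4(), {"A": 1})

    @pytest.mark.parametrize("n_leaves", [2, 3, 4])
    def test_score_equals_bruteforce_small_trees_exhaustive(self, n_leaves):
        labels = list("ABCDEF"[:n_leaves])
        for newick in all_labeled_trees(labels):
            tt = TreeTable(read_tree(newick + ";"))
            for pattern in itertools.product([0, 1], repeat=n_leaves):
                leaf_states = dict(zip(labels, pattern))
                _, score = fitch_states(tt, leaf_states)
                assert score == fitch_bruteforce(tt, leaf_states)


class TestCountContexts:
    def test_single_aaa_context(self):
        # codons AAA|AAA|TTT: only the first boundary is followed by A,A
        K, F = count_contexts(["AAA", "AAA", "TTT"])
        assert K == {"AAA": 1}
        assert F == {}

    def test_no_a_purine_junctions(self):
        K, F = count_contexts(["TTT", "CCC", "GGG"])
        assert K == {}

    def test_existing_site_is_exposure_for_loss_not_gain(self):
        K, F = count_contexts(["AAA", "AAG", "TTT"], fs={1: 1})
        assert F == {"AAA": 1}
        assert K == {}


class TestMapColumns:
    def make_alignment(self):
        # 2 junction columns (one +1 FS in A and B, absent in C), flanks clean
        base = "GATGATGATGCTGCTGCTGATGCTGATGATGGCAATGGTGGTGCTGCTGATGATG"
        a = base[:30] + "T" + "AGG" + base[34:]
        c = base[:30] + "-" + "AGG" + base[34:]
        aln = {"A": a, "B": a, "C": c}
        fs = pd.DataFrame(
            [
                {"species": "A", "transcript_id": "A|OG", "pos": 35, "shift": 1, "context": base[27:30]},
                {"species": "B", "transcript_id": "B|OG", "pos": 35, "shift": 1, "context": base[27:30]},
            ]
        )
        seqs = {
            "A|OG": "GATTA" + a.replace("-", ""),
            "B|OG": "GATTA" + a.replace("-", ""),
            "C|OG": "AA" + c.replace("-", ""),
        }
        return aln, fs, seqs

    def test_states_and_flank(self):
        aln, fs, seqs = self.make_alignment()
        sites = map_columns(aln, fs, seqs, "OG")
        assert len(sites) == 1
        site = sites[0]
        assert site.column == 30
        assert site.flank_ok
        assert site.states == {"A": 1, "B": 1, "C": 0}

    def test_gap_near_stop_disables_flank(self):
        aln, fs, seqs = self.make_alignment()
        # introduce a second indel column 3 columns away from the stop
        for k in list(aln):
            row = aln[k]
            aln[k] = row[:27] + ("-" if k == "C" else row[27]) + row[28:]
        seqs["C|OG"] = "AA" + aln["C"].replace("-", "")
        sites = map_columns(aln, fs, seqs, "OG")
        assert sites and not sites[0].flank_ok


class TestInferEvents:
    def test_single_gain_event_table(self):
        tt = tree4()
        from euplofs.phylo_events import SiteColumn

        site = SiteColumn(
            orthogroup_id="OG",
            column=30,
            shift=1,
            context="AAA",
            states={"A": 1, "B": 1, "C": 0, "D": 0},
            flank_ok=True,
        )
        events = infer_events(tt, [site])
        assert len(events) == 1
        assert events.iloc[0].kind == "gain"
        assert events.iloc[0].branch == "N2"
        assert events.iloc[0].context == "AAA"

    def test_flank_failed_sites_skipped(self):
        tt = tree4()
        from euplofs.phylo_events import SiteColumn

        site = SiteColumn("OG", 30, 1, "AAA", {"A": 1, "B": 0, "C": 0, "D": 0}, False)
        assert infer_events(tt, [site]).empty


class TestEventProbabilities:
    def make_table(self, n_gain=3, n_loss=2, K=300.0, F=20.0):
        tt = tree4()
        events = pd.DataFrame(
            [
                {"orthogroup_id": "OG", "branch": "A", "context": "AAA", "kind": "gain", "shift": 1}
            ]
            * n_gain
            + [
                {"orthogroup_id": "OG", "branch": "B", "context": "AAA", "kind": "loss", "shift": 1}
            ]
            * n_loss
        )
        # constant exposures on every branch: weighted mean equals the value
        exposures = pd.DataFrame(
            [
                {"orthogroup_id": "OG", "branch": n.name, "context": "AAA", "K": K, "F": F}
                for n in tt.branches()
            ]
        )
        return build_event_table(tt, events, exposures)

    def test_ratios(self):
        ev = self.make_table(n_gain=3, n_loss=2, K=300, F=20)
        p = ev.probabilities("AAA")
        assert p["p_gain"] == pytest.approx(0.01)
        assert p["p_loss"] == pytest.approx(0.1)
        assert not p["p_gain_is_bound"]

    def test_zero_losses_become_flagged_bound(self):
        ev = self.make_table(n_gain=3, n_loss=0, K=300, F=20)
        p = ev.probabilities("AAA")
        assert p["p_loss"] == pytest.approx(1 / 20)
        assert p["p_loss_is_bound"]

    def test_pooled_table_contains_contexts_and_pooled(self):
        ev = self.make_table()
        df = event_probabilities(ev)
        assert set(df.context) == {"AAA", "pooled"}


class TestRatioTest:
    def test_zero_events_p_one(self):
        ev = TestEventProbabilities().make_table(n_gain=1, n_loss=0)
        ev.events = ev.events.iloc[0:0]
        out = ratio_test(ev, "AAA", rounds=100, rng=np.random.default_rng(0))
        assert out["p_value"] == 1.0

    def test_null_calibration(self):
        # events allocated proportionally to exposures: p-value ~ 0.5
        ev = TestEventProbabilities().make_table(n_gain=30, n_loss=2, K=300, F=20)
        out = ratio_test(ev, "AAA", rounds=20_000, rng=np.random.default_rng(1))
        assert 0.3 < out["p_value"] < 0.8

    def test_strong_loss_excess_is_significant(self):
        # the study-scale configuration: 39 gains vs 4 losses with K/F = 74;
        # binomial tail oracle: P[losses >= 4 | n=43, p_loss_target = F/(K+F)]
        K, F = 74.0 * 20, 20.0
        ev = TestEventProbabilities().make_table(n_gain=39, n_loss=4, K=K, F=F)
        out = ratio_test(ev, "AAA", rounds=20_000, rng=np.random.default_rng(2))
        w = F / (K + F)
        tail = sum(
            math.comb(43, k) * w**k * (1 - w) ** (43 - k) for k in range(4, 44)
        )
        assert out["p_value"] < 0.05
        assert out["p_value"] == pytest.approx(tail, abs=0.02)


class TestReconstructAncestors:
    def test_recovers_shared_state_and_junction(self):
        tt = tree4()
        # all leaves share codons GAT|AAA|GAG; A and B carry a +1 T before
        # codon 2 (one indel column)
        row_fs = "GATAAA" + "T" + "GAG"
        row_no = "GATAAA" + "-" + "GAG"
        aln = {"A": row_fs, "B": row_fs, "C": row_no, "D": row_no}
        anc = reconstruct_ancestors(tt, aln)
        codons, fs = anc["N2"]  # (A,B) ancestor
        assert codons == ["GAT", "AAA", "GAG"]
        assert fs == {2: 1}
        codons_root, fs_root = anc["N1"]
        assert codons_root == ["GAT", "AAA", "GAG"]
        assert fs_root == {}  # root tie resolves toward absence of the insert
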