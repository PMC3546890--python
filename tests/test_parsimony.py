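"""Ancestral reconstruction: Sankoff DP, MPR sets, unambiguous events,
all anchored to exhaustive enumeration and an independent Fitch oracle."""

import numpy as np
import pytest

from conftest import build_tree, node, random_binary_tree, random_column
from thermopath.core_io import AA_INDEX, AMINO_ACIDS, DataError, OrthologAlignment
from thermopath import parsimony as pars


def events_from_labelings(labelings, leaf_states, tree):
    """Oracle: derive unambiguous branch events from the exhaustive list of
    minimum-cost labelings."""
    events = {}
    for parent, child in tree.branches():
        child_node = tree.nodes[child]
        pairs = set()
        if child_node.is_leaf:
            s = leaf_states[child]
            if s in ("-", "X"):
                continue  # free leaf state: a no-change labeling always exists
            for lab in labelings:
                pairs.add((lab[parent], s))
        else:
            for lab in labelings:
                pairs.add((lab[parent], lab[child]))
        if len(pairs) == 1:
            (x, y) = next(iter(pairs))
            if x != y:
                events[(parent, child)] = (x, y)
    return events


def events_from_recon(alignment, tree, preset):
    return {
        (e.parent_node, e.child_node): (e.from_aa, e.to_aa)
        for e in pars.unambiguous_events(alignment, tree, preset)
    }


def fitch_count(leaf_states, tree):
    """Independent Fitch pass count for unit costs, fully observed leaves."""
    changes = 0

    def walk(n):
        nonlocal changes
        if n.is_leaf:
            return {leaf_states[n.name]}
        left, right = (walk(c) for c in n.children)
        both = left & right
        if both:
            return both
        changes += 1
        return left | right

    walk(tree.root)
    return changes


class TestCostMatrices:
    def test_unit_costs(self):
        c = pars.unit_cost_matrix().costs
        assert c.shape == (20, 20)
        assert np.all(np.diag(c) == 0)
        assert np.all(c[~np.eye(20, dtype=bool)] == 1)

    def test_genetic_code_costs_symmetric_with_known_entries(self):
        c = pars.genetic_code_cost_matrix().costs
        assert np.allclose(c, c.T)
        # lysine AAA -> arginine AGA is one nucleotide change
        assert c[AA_INDEX["K"], AA_INDEX["R"]] == 1
        # phenylalanine TTY -> lysine AAR needs all three positions
        assert c[AA_INDEX["F"], AA_INDEX["K"]] == 3
        assert c.max() == 3 and c[~np.eye(20, dtype=bool)].min() == 1


class TestSankoffExamples:
    def test_four_leaf_split_scores_one_unique_labeling(self, four_leaf_tree):
        # A,B form a cherry so the single K->R change can only sit on the
        # branch into their ancestor: enumeration yields one labeling
        states = {"A": "R", "B": "R", "C": "K", "D": "K"}
        rec = pars.sankoff_reconstruct(states, four_leaf_tree, "unit")
        assert rec.parsimony_score == 1
        labelings = pars.enumerate_mp_labelings(states, four_leaf_tree, "unit")
        assert labelings == [{"Q": "R", "P": "K", "root": "K"}]
        aln = OrthologAlignment("g", dict(states))
        events = pars.unambiguous_events(aln, four_leaf_tree, "unit")
        assert [(e.parent_node, e.child_node, e.from_aa, e.to_aa) for e in events] == \
            [("P", "Q", "K", "R")]

    def test_four_leaf_alternating_column_is_ambiguous(self, four_leaf_tree):
        # R/K alternate across the tree: three minimum-cost labelings place
        # the two changes on different branches, so nothing is unambiguous
        states = {"A": "R", "B": "K", "C": "R", "D": "K"}
        rec = pars.sankoff_reconstruct(states, four_leaf_tree, "unit")
        assert rec.parsimony_score == 2
        labelings = pars.enumerate_mp_labelings(states, four_leaf_tree, "unit")
        assert len(labelings) == 3
        aln = OrthologAlignment("g", dict(states))
        assert pars.unambiguous_events(aln, four_leaf_tree, "unit") == []

    def test_five_leaf_unique_labeling_single_event(self, five_leaf_tree):
        states = {"A": "R", "B": "R", "C": "K", "D": "K", "E": "K"}
        rec = pars.sankoff_reconstruct(states, five_leaf_tree, "unit")
        assert rec.parsimony_score == 1
        labelings = pars.enumerate_mp_labelings(states, five_leaf_tree, "unit")
        assert len(labelings) == 1
        assert labelings[0] == {"root": "K", "P": "K", "Q": "R", "R": "K"}
        aln = OrthologAlignment("g", dict(states))
        events = pars.unambiguous_events(aln, five_leaf_tree, "unit")
        assert len(events) == 1
        e = events[0]
        assert (e.parent_node, e.child_node) == ("P", "Q")
        assert (e.from_aa, e.to_aa) == ("K", "R")
        assert e.column == 1

    def test_identical_leaves_score_zero_single_labeling(self, five_leaf_tree):
        states = dict.fromkeys("ABCDE", "Q")
        rec = pars.sankoff_reconstruct(states, five_leaf_tree, "unit")
        assert rec.parsimony_score == 0
        assert all(s == frozenset("Q") for s in rec.node_state_sets.values())
        assert len(pars.enumerate_mp_labelings(states, five_leaf_tree, "unit")) == 1
        aln = OrthologAlignment("g", dict(states))
        assert pars.unambiguous_events(aln, five_leaf_tree, "unit") == []

    def test_all_missing_column_skipped(self, four_leaf_tree):
        states = dict.fromkeys("ABCD", "-")
        rec = pars.sankoff_reconstruct(states, four_leaf_tree, "unit")
        assert rec.skipped
        assert pars.enumerate_mp_labelings(states, four_leaf_tree, "unit") == []

    def test_enumeration_limit(self, four_leaf_tree):
        states = {"A": "R", "B": "R", "C": "K", "D": "K"}
        with pytest.raises(DataError, match="limit"):
            pars.enumerate_mp_labelings(states, four_leaf_tree, "unit", limit=2)


class TestOracleEquivalence:
    @pytest.mark.parametrize("preset", ["unit", "genetic_code"])
    def test_random_instances_match_enumeration(self, preset):
        """Sankoff score, MPR sets and unambiguous events all agree with
        exhaustive enumeration over minimum-cost labelings."""
        rng = np.random.default_rng(101 if preset == "unit" else 202)
        for _ in range(60):
            tree = random_binary_tree(int(rng.integers(4, 9)), rng)
            states = random_column(tree, rng)
            labelings = pars.enumerate_mp_labelings(states, tree, preset)
            rec = pars.sankoff_reconstruct(states, tree, preset)
            if not labelings:
                assert rec.skipped
                continue
            costs = [pars.labeling_cost(l, states, tree, preset) for l in labelings]
            assert abs(min(costs) - rec.parsimony_score) < 1e-9
            assert max(costs) - min(costs) < 1e-9
            for name in tree.internal_names():
                assert frozenset(l[name] for l in labelings) == rec.node_state_sets[name]
            aln = OrthologAlignment("g", dict(states))
            assert events_from_recon(aln, tree, preset) == \
                events_from_labelings(labelings, states, tree)

    def test_unit_cost_equals_fitch(self):
        rng = np.random.default_rng(303)
        for _ in range(200):
            tree = random_binary_tree(int(rng.integers(4, 9)), rng)
            states = random_column(tree, rng, p_missing=0.0)
            rec = pars.sankoff_reconstruct(states, tree, "unit")
            assert rec.parsimony_score == fitch_count(states, tree)

    def test_duplicating_a_leaf_never_decreases_score(self):
        """Attaching a new leaf with the same state as an existing leaf
        keeps the parsimony score and every unambiguous event direction."""
        rng = np.random.default_rng(404)
        for _ in range(40):
            n_leaves = int(rng.integers(4, 7))
            topo_seed = int(rng.integers(2**31))
            tree = random_binary_tree(n_leaves, np.random.default_rng(topo_seed))
            states = random_column(tree, rng, p_missing=0.0)
            base = pars.sankoff_reconstruct(states, tree, "unit")
            base_events = events_from_recon(
                OrthologAlignment("g", dict(states)), tree, "unit"
            )

            # duplicate a random leaf as its own sister
            target = tree.leaf_names()[int(rng.integers(n_leaves))]
            grown = random_binary_tree(n_leaves, np.random.default_rng(topo_seed))
            leaf = grown.nodes[target]
            parent = leaf.parent
            mid = type(leaf)("MID")
            twin = type(leaf)("TWIN")
            parent.children[parent.children.index(leaf)] = mid
            mid.parent = parent
            mid.add_child(leaf)
            mid.add_child(twin)
            grown = build_tree(grown.root)
            grown_states = dict(states, TWIN=states[target])
            grown_rec = pars.sankoff_reconstruct(grown_states, grown, "unit")
            assert grown_rec.parsimony_score >= base.parsimony_score
            grown_events = events_from_recon(
                OrthologAlignment("g", dict(grown_states)), grown, "unit"
            )
            for branch, (x, y) in base_events.items():
                if branch in grown_events:
                    assert grown_events[branch] == (x, y)


class TestEventCounting:
    def test_counts_partition_events(self, five_leaf_tree):
        events = [
            pars.SubstitutionEvent("g", 1, "P", "Q", "K", "R"),
            pars.SubstitutionEvent("g", 2, "P", "Q", "K", "R"),
            pars.SubstitutionEvent("g", 3, "P", "Q", "K", "R"),
            pars.SubstitutionEvent("g", 4, "root", "R", "A", "G"),
        ]
        by_branch = pars.count_events(events, five_leaf_tree, "branch")
        assert by_branch["P->Q"].get("K", "R") == 3
        assert by_branch["root->R"].get("A", "G") == 1
        assert sum(m.total for m in by_branch.values()) == 4
        by_label = pars.count_events(events, five_leaf_tree, "label")
        assert sum(m.total for m in by_label.values()) == 4

    def test_empty_event_list_all_zero(self, five_leaf_tree):
        by_branch = pars.count_events([], five_leaf_tree, "branch")
        assert len(by_branch) == len(five_leaf_tree.branches())
        assert all(m.total == 0 for m in by_branch.values())

    def test_unknown_branch_rejected(self, five_leaf_tree):
        bad = [pars.SubstitutionEvent("g", 1, "nope", "Q", "K", "R")]
        with pytest.raises(DataError, match="unknown branch"):
            pars.count_events(bad, five_leaf_tree, "branch")

    def test_determinism(self, five_leaf_tree):
        aln = OrthologAlignment(
            "g",
            {"A": "RKWGA", "B": "RKWGC", "C": "KKWGA", "D": "KRWGA", "E": "KRW-A"},
        )
        first = pars.unambiguous_events(aln, five_leaf_tree, "unit")
        second = pars.unambiguous_events(aln, five_leaf_tree, "unit")
        assert first == second
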