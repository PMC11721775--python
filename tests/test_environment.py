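"""Environment dynamics: valency, structural alerts, rewards, traversal."""

import numpy as np
import pytest

from molrl.environment import (
    Action,
    ActionError,
    REJECTION_PENALTY,
    RING_CLOSURE_REWARD,
    apply_action,
    enumerate_actions,
    initial_state,
    is_terminal,
    next_focus,
    substructure_violation,
    valency_ok,
)
from molrl.mol_graph import MolGraph, parse_smiles, to_canonical


def linear_state(mode, elements=("C", "C", "C")):
    """A freshly built chain state with atoms added in order."""
    st = initial_state(mode)
    for el in elements[1:]:
        st, out = apply_action(st, Action(end=el, order=1)
                               if mode != "gcpn"
                               else Action(focus=st.graph.n_atoms - 1, end=el, order=1))
        assert out.accepted
    return st


class TestValency:
    def test_saturated_carbon_rejects_any_bond(self):
        g = parse_smiles("C(C)(C)(C)C")  # central C with four single bonds
        assert not valency_ok(g, 0, "C", 1)

    def test_fresh_carbon_triple_bond_to_nitrogen(self):
        g = parse_smiles("C")
        assert valency_ok(g, 0, "N", 3)

    def test_carbonyl_oxygen_full(self):
        g = parse_smiles("C=O")  # O already uses both valences
        assert not valency_ok(g, 1, "C", 1)

    def test_bad_indices_raise(self):
        g = parse_smiles("CC")
        with pytest.raises(ActionError):
            valency_ok(g, 5, 0, 1)
        with pytest.raises(ActionError):
            valency_ok(g, 0, 9, 1)


class TestSubstructureViolations:
    @pytest.mark.parametrize("smiles, code", [
        ("C=C=C", "a"),          # cumulated alkene
        ("COOC", "a"),           # peroxide
        ("C1=CC1", "b"),         # double bond in 3-ring
        ("C1=CCC1", "b"),        # double bond in 4-ring
        ("C1CCCCCCC1", "d"),     # 8-membered ring
        ("CC(=O)Oc1ccccc1C(=O)O", None),  # aspirin passes its own filters
        ("c1ccccc1", None),
        ("O=S(=O)(N)c1ccccc1", None),     # sulfonamide is not a cumulated alkene
        ("C1CC2CCC1CC2", None),  # bridged but non-aromatic
    ])
    def test_classes(self, smiles, code):
        assert substructure_violation(parse_smiles(smiles)) == code

    def test_bridged_aromatic_flags_class_c(self):
        # benzene ring bridged by an extra sp3 strap across para positions
        g = parse_smiles("c1ccccc1")
        g.add_atom("C")
        g.add_atom("C")
        g.add_bond(0, 6, 1)
        g.add_bond(6, 7, 1)
        g.add_bond(7, 2, 1)  # bridge shares 3 atoms with the aromatic ring
        assert substructure_violation(g) == "c"


class TestApplyAction:
    def test_ring_closure_reward(self):
        st = linear_state("dfm", ("C",) * 6)
        # close the six-membered ring: focus is atom 5, end atom 0
        st, out = apply_action(st, Action(end=0, order=1))
        assert out.accepted
        assert out.step_reward == RING_CLOSURE_REWARD

    def test_peroxide_rejected_leaves_graph_unchanged(self):
        st = linear_state("dfm", ("C", "O"))
        before = to_canonical(st.graph)
        st, out = apply_action(st, Action(end="O", order=1))
        assert not out.accepted
        assert out.step_reward == REJECTION_PENALTY
        assert out.violation == "a"
        assert to_canonical(st.graph) == before
        assert st.rejected_count == 1

    def test_chain_growth_zero_reward(self):
        st = linear_state("dfm", ("C", "C"))
        st, out = apply_action(st, Action(end="C", order=1))
        assert out.accepted and out.step_reward == 0.0

    def test_step_count_increments_on_rejection(self):
        st = linear_state("dfm", ("C", "O"))
        n = st.step_count
        st, _ = apply_action(st, Action(end="O", order=1))
        assert st.step_count == n + 1

    def test_malformed_actions_raise(self):
        st = initial_state("dfm")
        with pytest.raises(ActionError):
            apply_action(st, Action(stop=True))
        st2 = initial_state("gcpn")
        with pytest.raises(ActionError):
            apply_action(st2, Action(finish=True))
        with pytest.raises(ActionError):
            apply_action(st2, Action(end="C", order=1))  # missing focus


class TestFocusDiscipline:
    def test_stack_vs_queue(self):
        dfm = linear_state("dfm")
        bfm = linear_state("bfm")
        assert next_focus(dfm) == 2  # most recently added
        assert next_focus(bfm) == 0  # earliest unfinished

    def test_done_when_all_marked(self):
        st = initial_state("dfm")
        st, out = apply_action(st, Action(finish=True))
        assert next_focus(st) is None
        assert out.terminal and is_terminal(st)

    def test_gcpn_stop_terminates(self):
        st = initial_state("gcpn")
        st, out = apply_action(st, Action(stop=True))
        assert out.terminal and is_terminal(st)

    def test_step_cap_terminates(self):
        st = initial_state("dfm", max_steps=3)
        for _ in range(3):
            st, _ = apply_action(st, Action(end="C", order=1))
        assert is_terminal(st)

    def test_dfm_not_terminal_with_unfinished_atom(self):
        st = linear_state("dfm", ("C", "C"))
        st, _ = apply_action(st, Action(finish=True))
        assert not is_terminal(st)


def _is_traversal_order(graph: MolGraph, mode: str) -> bool:
    """Independent validator: atom indices 0..n-1 (addition order) form a
    valid DFS (stack) or BFS (queue) discovery order of the final graph."""
    n = graph.n_atoms
    adj = {i: set() for i in range(n)}
    for (i, j) in graph.bonds:
        adj[i].add(j)
        adj[j].add(i)
    container = [0]
    visited = {0}
    for v in range(1, n):
        while container:
            u = container[-1] if mode == "dfm" else container[0]
            unvisited = adj[u] - visited
            if unvisited:
                if v not in unvisited:
                    return False
                break
            container.pop() if mode == "dfm" else container.pop(0)
        else:
            return False
        visited.add(v)
        container.append(v)
    return True


class TestEnvironmentSoundness:
    @pytest.mark.parametrize("mode", ["gcpn", "dfm", "bfm"])
    def test_random_episodes_always_valid(self, mode):
        """Any action sequence yields a sanitizable, alert-free molecule."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            st = initial_state(mode, max_steps=40)
            reward_sum, rings, rejections = 0.0, 0, 0
            while not is_terminal(st):
                acts = enumerate_actions(st)
                st, out = apply_action(st, acts[int(rng.integers(len(acts)))],
                                       inplace=True)
                reward_sum += out.step_reward
                if out.accepted and out.step_reward > 0:
                    rings += 1
                if not out.accepted:
                    rejections += 1
            assert to_canonical(st.graph)  # sanitizes
            assert substructure_violation(st.graph) is None
            assert reward_sum == pytest.approx(
                RING_CLOSURE_REWARD * rings + REJECTION_PENALTY * rejections)
            assert st.rejected_count == rejections

    @pytest.mark.parametrize("mode", ["dfm", "bfm"])
    def test_focus_sequence_is_valid_traversal_order(self, mode):
        rng = np.random.default_rng(7)
        for _ in range(10):
            st = initial_state(mode, max_steps=40)
            while not is_terminal(st):
                acts = enumerate_actions(st)
                st, _ = apply_action(st, acts[int(rng.integers(len(acts)))],
                                     inplace=True)
            assert _is_traversal_order(st.graph, mode)

    def test_traversal_validator_against_networkx(self):
        """The validator itself agrees with reference graph traversals."""
        import networkx as nx
        G = nx.Graph([(0, 1), (0, 2), (1, 3), (2, 3), (3, 4), (1, 5)])
        dfs = list(nx.dfs_preorder_nodes(G, 0))
        bfs = [v for v in nx.bfs_tree(G, 0)]

        def relabelled(order):
            g = MolGraph()
            pos = {v: i for i, v in enumerate(order)}
            for _ in order:
                g.add_atom("C")
            for (u, v) in G.edges:
                g.add_bond(pos[u], pos[v], 1)
            return g

        assert _is_traversal_order(relabelled(dfs), "dfm")
        assert _is_traversal_order(relabelled(bfs), "bfm")
        # an order that is neither DFS nor BFS of this graph
        bad = [0, 4, 1, 2, 3, 5]
        assert not _is_traversal_order(relabelled(bad), "dfm")
        assert not _is_traversal_order(relabelled(bad), "bfm")
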