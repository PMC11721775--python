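"""Policy network: embeddings, action probabilities, gradients, checkpoints."""

import numpy as np
import pytest

import molrl.autodiff as ad
from molrl.environment import Action, apply_action, initial_state
from molrl.mol_graph import MolGraph, parse_smiles
from molrl.policy_net import (
    ActionDistribution,
    PolicyConfig,
    action_distribution,
    embed_graph,
    featurize_state,
    init_params,
    load_checkpoint,
    save_checkpoint,
    value_estimate,
)


def make_state(smiles: str, mode: str = "dfm"):
    """A generation state holding an existing molecule mid-episode."""
    from molrl.expert_pretrain import traversal_trajectory
    g = parse_smiles(smiles)
    pairs = traversal_trajectory(g, mode if mode != "gcpn" else "dfm",
                                 start=0, rng=np.random.default_rng(0))
    if mode == "gcpn":
        st = initial_state("gcpn")
        for state, action in pairs:
            if action.finish:
                continue
            from molrl.environment import next_focus
            st, out = apply_action(
                st, Action(focus=next_focus(state), end=action.end,
                           order=action.order), inplace=True)
            assert out.accepted
        return st
    # stop mid-trajectory so the state is active
    st = pairs[len(pairs) // 2][0].copy()
    return st


class TestEmbedding:
    def test_single_atom_identity_weights(self):
        """With Ã = D̃ = I the embedding is the thrice-rectified projection."""
        params = init_params(0)
        for m in range(3):
            for i in range(3):
                params[f"gcn{m}_w{i}"] = ad.parameter(np.eye(64) / 3)
        g = parse_smiles("C")
        h = embed_graph(g, params)
        from molrl.mol_graph import encode_atoms
        h0 = encode_atoms(g) @ params["embed"].data
        expected = h0
        for _ in range(3):
            expected = np.maximum(expected / 3, 0) * 3  # 3 slices x ReLU(h W/3)
        assert np.allclose(h, expected)

    def test_zero_weights_zero_embeddings(self):
        params = init_params(0)
        for m in range(3):
            for i in range(3):
                params[f"gcn{m}_w{i}"] = ad.parameter(np.zeros((64, 64)))
        assert np.allclose(embed_graph(parse_smiles("CCO"), params), 0.0)

    def test_permutation_equivariance(self, params):
        g = parse_smiles("CC(=O)Oc1ccccc1C(=O)O")
        h = embed_graph(g, params)
        perm = np.random.default_rng(3).permutation(g.n_atoms)
        inv = {int(p): i for i, p in enumerate(perm)}
        g2 = MolGraph()
        for p in perm:
            g2.add_atom(g.elements[p])
        for (i, j), o in g.bonds.items():
            g2.add_bond(inv[i], inv[j], o)
        h2 = embed_graph(g2, params)
        assert np.allclose(h2, h[perm], atol=1e-10)


class TestActionDistribution:
    @pytest.mark.parametrize("mode", ["dfm", "bfm", "gcpn"])
    def test_composite_probabilities_sum_to_one(self, params, mode):
        st = make_state("CCOc1ccccc1", mode)
        dist = action_distribution(st, params)
        probs = [p for _, p in dist.all_actions()]
        assert sum(probs) == pytest.approx(1.0, abs=1e-9)
        assert all(p >= 0 for p in probs)

    def test_finished_atoms_get_zero_end_probability(self, params):
        st = make_state("CCCCO", "dfm")
        st.finished_set.add(0)
        dist = action_distribution(st, params)
        assert all(a.end != 0 for a, p in dist.all_actions() if p > 0)

    def test_finish_gate_partitions_mass(self, params):
        st = make_state("CCO", "dfm")
        dist = action_distribution(st, params)
        acts = dist.all_actions()
        p_finish = sum(p for a, p in acts if a.finish)
        p_bonds = sum(p for a, p in acts if not a.finish)
        assert p_finish + p_bonds == pytest.approx(1.0, abs=1e-9)
        assert p_bonds == pytest.approx(
            1.0 - np.exp(dist.gate_logp.data[1]), abs=1e-9)

    def test_log_prob_matches_enumeration(self, params):
        st = make_state("CCN", "dfm")
        dist = action_distribution(st, params)
        for action, p in dist.all_actions():
            assert np.exp(dist.log_prob(action).item()) == pytest.approx(p, abs=1e-10)

    def test_sampling_reproducible(self, params):
        st = make_state("CCO", "dfm")
        dist = action_distribution(st, params)
        a1 = [dist.sample(np.random.default_rng(5)) for _ in range(10)]
        a2 = [dist.sample(np.random.default_rng(5)) for _ in range(10)]
        assert a1 == a2

    def test_empirical_frequencies_match_probabilities(self, params):
        st = make_state("CC", "dfm")
        dist = action_distribution(st, params)
        acts = dist.all_actions()
        rng = np.random.default_rng(0)
        n = 20_000
        counts = {a: 0 for a, _ in acts}
        for _ in range(n):
            counts[dist.sample(rng)] += 1
        for a, p in acts:
            if p < 1e-4:
                continue
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(counts[a] / n - p) < 4 * sigma + 1e-4

    def test_greedy_decoding_deterministic(self, params):
        st = make_state("CCO", "dfm")
        dist = action_distribution(st, params)
        rng = np.random.default_rng(0)
        assert dist.sample(rng, greedy=True) == dist.sample(rng, greedy=True)


class TestValueHead:
    def test_zero_head_weights_give_zero(self, params):
        p = dict(params)
        p["value_w2"] = ad.parameter(np.zeros((64, 1)))
        p["value_b2"] = ad.parameter(np.zeros(1))
        assert value_estimate(parse_smiles("CCO"), p) == 0.0

    def test_permutation_invariance(self, params):
        a = value_estimate(parse_smiles("CCOc1ccccc1"), params)
        b = value_estimate(parse_smiles("c1ccccc1OCC"), params)
        assert a == pytest.approx(b, abs=1e-10)

    def test_finite_on_corpus(self, params, corpus):
        for g in corpus[:10]:
            assert np.isfinite(value_estimate(g, params))


class TestGradients:
    def _finite_difference_check(self, params, tensors, loss_fn, h=1e-6):
        loss = loss_fn()
        for p in params.values():
            p.zero_grad()
        loss.backward()
        rng = np.random.default_rng(0)
        for name in tensors:
            t = params[name]
            assert t.grad is not None, name
            flat = t.data.reshape(-1)
            gflat = t.grad.reshape(-1)
            idxs = rng.choice(flat.size, size=min(5, flat.size), replace=False)
            for k in idxs:
                orig = flat[k]
                flat[k] = orig + h
                up = loss_fn().item()
                flat[k] = orig - h
                dn = loss_fn().item()
                flat[k] = orig
                num = (up - dn) / (2 * h)
                denom = max(abs(num), abs(gflat[k]), 1e-8)
                assert abs(num - gflat[k]) / denom < 1e-4, (name, k)

    def test_log_prob_gradients_match_finite_differences(self, params):
        st = make_state("CCO", "dfm")
        feats = featurize_state(st)
        dist0 = ActionDistribution(feats, params)
        # highest-probability bond action, so every head participates
        action = max((ap for ap in dist0.all_actions() if not ap[0].finish),
                     key=lambda ap: ap[1])[0]

        def loss_fn():
            return -ActionDistribution(feats, params).log_prob(action)

        self._finite_difference_check(
            params,
            ["embed", "gcn0_w0", "gcn2_w0", "finish_w1", "end_w1", "bond_w2",
             "element_embed"],
            loss_fn)

    def test_value_gradients_match_finite_differences(self, params):
        g = parse_smiles("CCN")

        def loss_fn():
            from molrl.policy_net import value_tensor
            return ad.square(value_tensor(g, params) - 1.7)

        self._finite_difference_check(params, ["value_w1", "value_w2", "embed"],
                                      loss_fn)


class TestCheckpoints:
    def test_round_trip_bit_exact(self, params, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, params)
        loaded = load_checkpoint(path)
        assert set(loaded) == set(params)
        for k in params:
            assert np.array_equal(loaded[k].data, params[k].data)

    def test_config_hash_mismatch_rejected(self, params, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, params, PolicyConfig())
        with pytest.raises(ValueError, match="hash"):
            load_checkpoint(path, PolicyConfig(pooling="sum"))
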