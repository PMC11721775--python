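"""Graph-convolutional policy and value networks.

Atom features (N×20) are embedded into a 64-dimensional latent space
and passed through three graph-convolution modules.  Each module holds
one 64×64 weight matrix per bond-order slice; per-slice convolutions
use the symmetrically normalized self-loop-augmented adjacency, are
rectified and summed:

    h^l = Σ_i ReLU( D̃_i^{-1/2} Ã_i D̃_i^{-1/2} h^{l-1} W_i^l )

Action selection is factored into sub-tasks whose probabilities
multiply into the composite action probability

    P(a) = (1 - I_finish) Π_j P(a_j)  +  I_finish P(finish),

where in gcpn mode the gate is the STOP decision and an extra sub-task
picks the focus atom, while in dfm/bfm mode the focus atom is dictated
by the traversal and the gate is the finish-mark decision.  Atoms
marked finished are masked out of the end-atom sub-task.  Fresh-atom
end slots are scored from learned per-element embeddings; pair scoring
concatenates focus and candidate embeddings through a two-layer
perceptron.  The graph-level context for gating, focus and value heads
is the mean-pooled node embedding ("sum" pooling is switchable).

A value head maps the same pooled embedding to a scalar expected-reward
estimate used as the PPO baseline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .environment import (
    Action,
    ActionError,
    GenerationState,
    end_candidates,
    legal_orders,
    next_focus,
)
from .mol_graph import (
    MolGraph,
    N_ATOM_FEATURES,
    VOCABULARY,
    bond_slices,
    encode_atoms,
)

EMBED_DIM = 64
N_GCN_MODULES = 3
N_SLICES = 3
HEAD_HIDDEN = 64


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class PolicyConfig:
    embed_dim: int = EMBED_DIM
    n_modules: int = N_GCN_MODULES
    head_hidden: int = HEAD_HIDDEN
    pooling: str = "mean"  # or "sum"

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def init_params(seed: int = 0, config: PolicyConfig = PolicyConfig()) -> dict[str, Tensor]:
    """Seed-controlled uniform Glorot-style initialization of all tensors."""
    rng = np.random.default_rng(seed)
    d, h = config.embed_dim, config.head_hidden
    p: dict[str, Tensor] = {"embed": ad.glorot(rng, N_ATOM_FEATURES, d)}
    for m in range(config.n_modules):
        for i in range(N_SLICES):
            p[f"gcn{m}_w{i}"] = ad.glorot(rng, d, d)
    for name, n_in, n_out in [
        ("stop", d, 2),          # gcpn: continue / stop
        ("finish", 2 * d, 2),    # dfm/bfm: continue / finish (focus ⊕ context)
        ("focus", 2 * d, 1),     # gcpn focus scoring (atom ⊕ context)
        ("end", 2 * d, 1),       # end-atom pair scoring (focus ⊕ candidate)
        ("bond", 2 * d, 3),      # bond-order head (focus ⊕ candidate)
        ("value", d, 1),
    ]:
        p[f"{name}_w1"] = ad.glorot(rng, n_in, h)
        p[f"{name}_b1"] = ad.parameter(np.zeros(h))
        p[f"{name}_w2"] = ad.glorot(rng, h, n_out)
        p[f"{name}_b2"] = ad.parameter(np.zeros(n_out))
    p["element_embed"] = ad.glorot(rng, len(VOCABULARY), d)
    return p


def save_checkpoint(path, params: dict[str, Tensor],
                    config: PolicyConfig = PolicyConfig()) -> None:
    """Versioned archive of named parameter tensors plus a config hash."""
    arrays = {k: v.data for k, v in params.items()}
    np.savez(path, __config_hash__=np.frombuffer(
        config.hash().encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, config: PolicyConfig = PolicyConfig()) -> dict[str, Tensor]:
    archive = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
    stored = bytes(archive["__config_hash__"]).decode()
    if stored != config.hash():
        raise ValueError(f"checkpoint config hash {stored} does not match {config.hash()}")
    return {k: ad.parameter(archive[k]) for k in archive.files if k != "__config_hash__"}


# ---------------------------------------------------------------------------
# State featurization (decoupled so PPO can snapshot and replay states)
# ---------------------------------------------------------------------------

@dataclass
class StateFeatures:
    """Everything the networks need to know about one RL state."""

    mode: str
    X: np.ndarray
    slices: list[np.ndarray]
    n_atoms: int
    terminal_allowed: bool = True
    # dfm / bfm
    focus: Optional[int] = None
    candidates: list = field(default_factory=list)
    order_mask: Optional[np.ndarray] = None
    # gcpn
    focus_mask: Optional[np.ndarray] = None
    per_focus: list = field(default_factory=list)


def _candidate_block(state: GenerationState, focus: int):
    cands = end_candidates(state, focus)
    mask = np.zeros((len(cands), 3), dtype=bool)
    for c, cand in enumerate(cands):
        for o in legal_orders(state.graph, focus, cand):
            mask[c, o - 1] = True
    return cands, mask


def featurize_state(state: GenerationState) -> StateFeatures:
    X = encode_atoms(state.graph)
    slices = bond_slices(state.graph).normalized
    feats = StateFeatures(mode=state.mode, X=X, slices=slices,
                          n_atoms=state.graph.n_atoms)
    if state.mode in ("dfm", "bfm"):
        feats.focus = next_focus(state)
        if feats.focus is not None:
            feats.candidates, feats.order_mask = _candidate_block(state, feats.focus)
    else:
        feats.focus_mask = np.zeros(state.graph.n_atoms, dtype=bool)
        for f in range(state.graph.n_atoms):
            cands, mask = _candidate_block(state, f)
            feats.per_focus.append((cands, mask))
            feats.focus_mask[f] = bool(mask.any())
    return feats


# ---------------------------------------------------------------------------
# Forward passes
# ---------------------------------------------------------------------------

def embed_features(feats: StateFeatures, params: dict[str, Tensor],
                   config: PolicyConfig = PolicyConfig()) -> tuple[Tensor, Tensor]:
    """Node embeddings (N×64) and pooled graph context (1×64)."""
    h = Tensor(feats.X) @ params["embed"]
    n = feats.X.shape[0]
    # bond-free slices are identity after normalization; skip their matmul
    trivial = [np.count_nonzero(s) <= n for s in feats.slices]
    for m in range(config.n_modules):
        acc = None
        for i in range(N_SLICES):
            prop = h if trivial[i] else Tensor(feats.slices[i]) @ h
            conv = ad.relu(prop @ params[f"gcn{m}_w{i}"])
            acc = conv if acc is None else acc + conv
        h = acc
    ctx = h.mean(axis=0) if config.pooling == "mean" else h.sum(axis=0)
    return h, ctx


def embed_graph(g: MolGraph, params: dict[str, Tensor],
                config: PolicyConfig = PolicyConfig()) -> np.ndarray:
    """Convenience wrapper: node embeddings for a bare molecular graph."""
    feats = StateFeatures(mode="gcpn", X=encode_atoms(g),
                          slices=bond_slices(g).normalized, n_atoms=g.n_atoms)
    h, _ = embed_features(feats, params, config)
    return h.data


def _mlp(params: dict[str, Tensor], prefix: str, x: Tensor) -> Tensor:
    h = ad.relu(x @ params[f"{prefix}_w1"] + params[f"{prefix}_b1"])
    return h @ params[f"{prefix}_w2"] + params[f"{prefix}_b2"]


def _row(t: Tensor, idx: int) -> Tensor:
    return ad.take_rows(t, [idx])


def value_estimate(g_or_feats, params: dict[str, Tensor],
                   config: PolicyConfig = PolicyConfig()) -> float:
    """Scalar expected-reward estimate from the pooled graph embedding."""
    t = value_tensor(g_or_feats, params, config)
    return t.item()


def value_tensor(g_or_feats, params: dict[str, Tensor],
                 config: PolicyConfig = PolicyConfig()) -> Tensor:
    if isinstance(g_or_feats, MolGraph):
        feats = StateFeatures(mode="gcpn", X=encode_atoms(g_or_feats),
                              slices=bond_slices(g_or_feats).normalized,
                              n_atoms=g_or_feats.n_atoms)
    else:
        feats = g_or_feats
    _, ctx = embed_features(feats, params, config)
    out = _mlp(params, "value", _row_vector(ctx))
    return out.sum()


def _row_vector(v: Tensor) -> Tensor:
    """View a (d,) tensor as a (1, d) matrix for matmul heads."""
    return v if v.data.ndim == 2 else _reshape_1xd(v)


def _reshape_1xd(v: Tensor) -> Tensor:
    d = v.data.shape[0]
    return Tensor(v.data.reshape(1, d), parents=[(v, lambda g: g.reshape(d))])


# ---------------------------------------------------------------------------
# Action distribution
# ---------------------------------------------------------------------------

class ActionDistribution:
    """Factored distribution over legal actions for one state.

    Sub-task log-probabilities are autodiff tensors, so ``log_prob`` of
    a taken action is differentiable with respect to the parameters.
    """

    def __init__(self, feats: StateFeatures, params: dict[str, Tensor],
                 config: PolicyConfig = PolicyConfig()):
        self.feats = feats
        self.params = params
        self.config = config
        self.H, self.ctx = embed_features(feats, params, config)
        self._focus_cache: dict[int, tuple] = {}
        if feats.mode in ("dfm", "bfm"):
            self._build_traversal()
        else:
            self._build_gcpn()

    # -- shared helpers ----------------------------------------------

    def _pair_logits(self, focus: int, cands: Sequence, prefix: str) -> Tensor:
        """Score (focus, candidate) pairs through a two-layer perceptron."""
        exist = [c for c in cands if isinstance(c, int)]
        fresh = [VOCABULARY.index(c) for c in cands if isinstance(c, str)]
        blocks = []
        if exist:
            blocks.append(ad.take_rows(self.H, exist))
        if fresh:
            blocks.append(ad.take_rows(self.params["element_embed"], fresh))
        cand_mat = blocks[0] if len(blocks) == 1 else ad.concat(blocks, axis=0)
        focus_mat = ad.take_rows(self.H, [focus] * len(cands))
        return _mlp(self.params, prefix, ad.concat([focus_mat, cand_mat], axis=1))

    def _gate_block(self, focus: Optional[int]):
        """End/bond sub-task log-probs for a given focus atom."""
        if focus in self._focus_cache:
            return self._focus_cache[focus]
        if self.feats.mode in ("dfm", "bfm"):
            cands, mask = self.feats.candidates, self.feats.order_mask
        else:
            cands, mask = self.feats.per_focus[focus]
        if len(cands) == 0 or not mask.any():
            block = (cands, mask, None, None)
            self._focus_cache[focus] = block
            return block
        end_scores = self._pair_logits(focus, cands, "end").sum(axis=1)
        end_logp = ad.log_softmax(end_scores, mask=mask.any(axis=1))
        bond_scores = self._pair_logits(focus, cands, "bond")
        bond_logp = ad.log_softmax(bond_scores, mask=mask)
        block = (cands, mask, end_logp, bond_logp)
        self._focus_cache[focus] = block
        return block

    # -- mode-specific construction ----------------------------------

    def _build_traversal(self):
        feats = self.feats
        if feats.focus is None:
            raise ActionError("cannot build a distribution for a terminal state")
        can_bond = feats.order_mask is not None and bool(feats.order_mask.any())
        focus_emb = _row(self.H, feats.focus)
        gate_in = ad.concat([focus_emb, _row_vector(self.ctx)], axis=1)
        gate_scores = _mlp(self.params, "finish", gate_in).sum(axis=0)
        gate_mask = np.array([can_bond, True])  # [continue, finish]
        self.gate_logp = ad.log_softmax(gate_scores, mask=gate_mask)

    def _build_gcpn(self):
        feats = self.feats
        can_bond = bool(feats.focus_mask.any())
        gate_scores = _mlp(self.params, "stop", _row_vector(self.ctx)).sum(axis=0)
        gate_mask = np.array([can_bond, True])  # [continue, stop]
        self.gate_logp = ad.log_softmax(gate_scores, mask=gate_mask)
        if can_bond:
            n = feats.n_atoms
            ctx_mat = Tensor(np.ones((n, 1))) @ _row_vector(self.ctx)
            focus_in = ad.concat([self.H, ctx_mat], axis=1)
            scores = _mlp(self.params, "focus", focus_in).sum(axis=1)
            self.focus_logp = ad.log_softmax(scores, mask=feats.focus_mask)
        else:
            self.focus_logp = None

    # -- public API ----------------------------------------------------

    def value(self) -> Tensor:
        """Value-baseline estimate sharing this distribution's embeddings."""
        return _mlp(self.params, "value", _row_vector(self.ctx)).sum()

    def log_prob(self, action: Action) -> Tensor:
        """Differentiable log of the composite action probability."""
        if action.stop or action.finish:
            return ad.gather(self.gate_logp, 1)
        logp = ad.gather(self.gate_logp, 0)
        if self.feats.mode == "gcpn":
            if action.focus is None:
                raise ActionError("gcpn bond action needs a focus index")
            logp = logp + ad.gather(self.focus_logp, action.focus)
            focus = action.focus
        else:
            focus = self.feats.focus
        cands, mask, end_logp, bond_logp = self._gate_block(focus)
        try:
            c = cands.index(action.end)
        except ValueError:
            raise ActionError(f"action end {action.end!r} is not a candidate")
        if end_logp is None or not mask[c, action.order - 1]:
            return Tensor(-np.inf)
        logp = logp + ad.gather(end_logp, c)
        row = ad.take_rows(bond_logp, [c]).sum(axis=0)
        return logp + ad.gather(row, action.order - 1)

    def all_actions(self) -> list[tuple[Action, float]]:
        """Enumerate every legal action with its composite probability."""
        out: list[tuple[Action, float]] = []
        gate = np.exp(self.gate_logp.data)
        if self.feats.mode == "gcpn":
            out.append((Action(stop=True), float(gate[1])))
            if self.focus_logp is not None:
                pf = np.exp(self.focus_logp.data)
                for f in range(self.feats.n_atoms):
                    if not self.feats.focus_mask[f]:
                        continue
                    out.extend(self._enumerate_block(f, gate[0] * pf[f]))
        else:
            out.append((Action(finish=True), float(gate[1])))
            if self.feats.focus is not None:
                out.extend(self._enumerate_block(self.feats.focus, gate[0]))
        return out

    def _enumerate_block(self, focus: int, base_p: float):
        cands, mask, end_logp, bond_logp = self._gate_block(focus)
        out = []
        if end_logp is None:
            return out
        pe = np.exp(end_logp.data)
        pb = np.exp(bond_logp.data)
        kwargs = {"focus": focus} if self.feats.mode == "gcpn" else {}
        for c, cand in enumerate(cands):
            for o in (1, 2, 3):
                if mask[c, o - 1]:
                    out.append((Action(end=cand, order=o, **kwargs),
                                float(base_p * pe[c] * pb[c, o - 1])))
        return out

    def sample(self, rng: np.random.Generator, greedy: bool = False) -> Action:
        """Draw an action sub-task by sub-task (or argmax-decode)."""
        gate = np.exp(self.gate_logp.data)
        pick = (lambda p: int(np.argmax(p))) if greedy \
            else (lambda p: int(rng.choice(len(p), p=p / p.sum())))
        if pick(gate) == 1:
            return Action(stop=True) if self.feats.mode == "gcpn" else Action(finish=True)
        if self.feats.mode == "gcpn":
            focus = pick(np.exp(self.focus_logp.data))
        else:
            focus = self.feats.focus
        cands, mask, end_logp, bond_logp = self._gate_block(focus)
        c = pick(np.exp(end_logp.data))
        o = 1 + pick(np.exp(bond_logp.data[c]))
        kwargs = {"focus": focus} if self.feats.mode == "gcpn" else {}
        return Action(end=cands[c], order=o, **kwargs)


def action_distribution(state: GenerationState, params: dict[str, Tensor],
                        config: PolicyConfig = PolicyConfig()) -> ActionDistribution:
    return ActionDistribution(featurize_state(state), params, config)


def sample_action(dist: ActionDistribution, rng: np.random.Generator,
                  greedy: bool = False) -> Action:
    return dist.sample(rng, greedy=greedy)


def log_prob(dist: ActionDistribution, action: Action) -> Tensor:
    return dist.log_prob(action)
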