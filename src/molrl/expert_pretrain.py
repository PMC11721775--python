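"""Expert (imitation) pre-training of the generative agents.

Training molecules are turned into expert state/action pairs:

* dfm / bfm — the molecule is rebuilt through the environment by
  traversing its graph depth- or breadth-first from a random start
  atom; every replayed step yields one (state, action) pair, and the
  focus-atom order obeys the environment's own stack/queue discipline.
  An atom is marked finished once all of its target-graph bonds have
  been added.
* gcpn — a random connected partial graph G′ of the molecule G is the
  state; every single-bond extension of G′ within G is an expert
  action (STOP when G′ = G).

The pre-training objective is the mean negative log composite action
probability over expert pairs, minimized with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .environment import (
    Action,
    GenerationState,
    apply_action,
    initial_state,
    next_focus,
)
from .mol_graph import MolGraph, sssr_ring_sizes
from .policy_net import (
    ActionDistribution,
    PolicyConfig,
    featurize_state,
    init_params,
)

MAX_RING = 8


class TrajectoryError(RuntimeError):
    """Replay produced a rejected action — trajectory/environment mismatch."""


def filter_training_set(mols: Sequence[MolGraph]) -> list[MolGraph]:
    """Drop molecules containing any SSSR ring of eight or more members."""
    return [g for g in mols if all(s < MAX_RING for s in sssr_ring_sizes(g))]


# ---------------------------------------------------------------------------
# Traversal trajectories (dfm / bfm)
# ---------------------------------------------------------------------------

def _ring_size(added: set[tuple[int, int]], u: int, v: int) -> int:
    """Size of the ring that closing bond u-v would create in the partial
    graph whose edge set is ``added`` (shortest u-v path length + 1)."""
    adj: dict[int, list[int]] = {}
    for (a, b) in added:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    frontier = [u]
    dist = {u: 0}
    while frontier:
        nxt = []
        for x in frontier:
            for y in adj.get(x, ()):  # pragma: no branch
                if y not in dist:
                    dist[y] = dist[x] + 1
                    if y == v:
                        return dist[y] + 1
                    nxt.append(y)
        frontier = nxt
    return 10 ** 9  # disconnected in the partial graph (cannot happen)


def traversal_trajectory(
    g: MolGraph,
    mode: str,
    start: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_steps: int = 10_000,
) -> list[tuple[GenerationState, Action]]:
    """Expert (state, action) pairs rebuilding ``g`` under dfm/bfm focus rules.

    The neighbor visit order is randomized per step by ``rng``.  The
    returned pairs replay through the environment with zero rejections
    and reconstruct a graph isomorphic to ``g``.
    """
    if not g.is_connected():
        raise TrajectoryError("training molecule graph is disconnected")
    rng = rng or np.random.default_rng()
    if start is None:
        start = int(rng.integers(g.n_atoms))

    # adjacency of the target graph with bond orders
    adj: dict[int, dict[int, int]] = {i: {} for i in range(g.n_atoms)}
    for (i, j), o in g.bonds.items():
        adj[i][j] = o
        adj[j][i] = o

    st = initial_state(mode, max_steps=max_steps, start_element=g.elements[start])
    env_to_g = {0: start}
    g_to_env = {start: 0}
    added: set[tuple[int, int]] = set()
    pairs: list[tuple[GenerationState, Action]] = []

    def emit(action: Action):
        nonlocal st
        pairs.append((st.copy(), action))
        st, outcome = apply_action(st, action, inplace=True)
        if not outcome.accepted:
            raise TrajectoryError(
                f"expert action rejected ({outcome.violation}) while replaying")

    while True:
        focus_env = next_focus(st)
        if focus_env is None:
            break
        focus_g = env_to_g[focus_env]
        pending = [v for v in adj[focus_g]
                   if (min(focus_g, v), max(focus_g, v)) not in added]
        if not pending:
            emit(Action(finish=True))
            continue
        # Close available rings before extending, smallest resulting ring
        # first: postponing a closure (or closing the wrong bond first) in
        # a fused system transiently creates an over-large perimeter ring
        # that the environment would reject.
        closures = [v for v in pending if v in g_to_env]
        if closures:
            sizes = [_ring_size(added, focus_g, v) for v in closures]
            best = min(sizes)
            pending = [v for v, s in zip(closures, sizes) if s == best]
        v = pending[int(rng.integers(len(pending)))]
        order = adj[focus_g][v]
        added.add((min(focus_g, v), max(focus_g, v)))
        if v in g_to_env:
            emit(Action(end=g_to_env[v], order=order))
        else:
            emit(Action(end=g.elements[v], order=order))
            new_env = st.graph.n_atoms - 1
            env_to_g[new_env] = v
            g_to_env[v] = new_env
    return pairs


# ---------------------------------------------------------------------------
# Subgraph states (gcpn)
# ---------------------------------------------------------------------------

def subgraph_trajectory(
    g: MolGraph,
    rng: Optional[np.random.Generator] = None,
    max_steps: int = 10_000,
) -> tuple[GenerationState, list[Action]]:
    """A random connected partial graph of ``g`` and its expert actions.

    The partial graph G′ grows by random-walk edge additions from a
    uniform start vertex up to a uniformly drawn edge count.  The expert
    action set contains every single-bond extension of G′ within ``g``
    (both focus orientations for bonds between two existing atoms), or
    STOP when G′ equals ``g``.
    """
    if not g.is_connected():
        raise TrajectoryError("molecule graph is disconnected")
    rng = rng or np.random.default_rng()
    start = int(rng.integers(g.n_atoms))
    n_target = int(rng.integers(0, len(g.bonds) + 1))

    st = initial_state("gcpn", max_steps=max_steps, start_element=g.elements[start])
    env_to_g = {0: start}
    g_to_env = {start: 0}
    added: set[tuple[int, int]] = set()

    def frontier() -> list[tuple[int, int]]:
        out = []
        for (i, j) in g.bonds:
            if (i, j) in added:
                continue
            if i in g_to_env or j in g_to_env:
                out.append((i, j))
        return out

    for _ in range(n_target):
        edges = frontier()
        if not edges:
            break
        i, j = edges[int(rng.integers(len(edges)))]
        order = g.bonds[(i, j)]
        if i in g_to_env and j in g_to_env:
            action = Action(focus=g_to_env[i], end=g_to_env[j], order=order)
        else:
            known, fresh = (i, j) if i in g_to_env else (j, i)
            action = Action(focus=g_to_env[known], end=g.elements[fresh], order=order)
        st, outcome = apply_action(st, action, inplace=True)
        if not outcome.accepted:
            raise TrajectoryError(
                f"subgraph-growth action rejected ({outcome.violation})")
        added.add((i, j))
        for idx in (i, j):
            if idx not in g_to_env:
                new_env = st.graph.n_atoms - 1
                g_to_env[idx] = new_env
                env_to_g[new_env] = idx

    expert: list[Action] = []
    for (i, j) in frontier():
        order = g.bonds[(i, j)]
        if i in g_to_env and j in g_to_env:
            expert.append(Action(focus=g_to_env[i], end=g_to_env[j], order=order))
            expert.append(Action(focus=g_to_env[j], end=g_to_env[i], order=order))
        else:
            known, fresh = (i, j) if i in g_to_env else (j, i)
            expert.append(Action(focus=g_to_env[known], end=g.elements[fresh],
                                 order=order))
    if not expert:
        expert.append(Action(stop=True))
    return st, expert


# ---------------------------------------------------------------------------
# Loss and training loop
# ---------------------------------------------------------------------------

def expert_loss(params: dict[str, Tensor],
                batch: Sequence[tuple[GenerationState, Action]],
                config: PolicyConfig = PolicyConfig()) -> Tensor:
    """Mean negative log composite probability of the expert actions."""
    if not batch:
        raise ValueError("empty expert batch")
    terms = []
    for state, action in batch:
        dist = ActionDistribution(featurize_state(state), params, config)
        lp = dist.log_prob(action)
        if not np.isfinite(lp.data):
            raise TrajectoryError(f"expert action {action} illegal in its state")
        terms.append(lp)
    return -ad.stack_scalars(terms).mean()


@dataclass
class PretrainConfig:
    mode: str = "dfm"
    steps: int = 5_000           # desk-scale default; the reference setting
    batch_size: int = 32         # in the source work is ~1e6 steps
    lr: float = 1e-4
    seed: int = 0
    policy: PolicyConfig = field(default_factory=PolicyConfig)


def pretrain(
    molecules: Sequence[MolGraph],
    config: PretrainConfig = PretrainConfig(),
    params: Optional[dict[str, Tensor]] = None,
    callback=None,
) -> tuple[dict[str, Tensor], list[tuple[int, float]]]:
    """Behavior-clone the policy on expert pairs from ``molecules``.

    Returns the trained parameters and a per-step loss log.
    """
    mols = filter_training_set(molecules)
    if not mols:
        raise ValueError("no training molecules left after ring filtering")
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_params(config.seed, config.policy)
    opt = ad.Adam(params, lr=config.lr)
    log: list[tuple[int, float]] = []

    buffer: list[tuple[GenerationState, Action]] = []
    for step in range(config.steps):
        while len(buffer) < config.batch_size:
            g = mols[int(rng.integers(len(mols)))]
            try:
                if config.mode in ("dfm", "bfm"):
                    buffer.extend(traversal_trajectory(g, config.mode, rng=rng))
                else:
                    state, expert = subgraph_trajectory(g, rng=rng)
                    action = expert[int(rng.integers(len(expert)))]
                    buffer.append((state, action))
            except TrajectoryError:
                continue  # molecule incompatible with environment rules
        idx = rng.permutation(len(buffer))[: config.batch_size]
        batch = [buffer[i] for i in idx]
        buffer = [b for k, b in enumerate(buffer) if k not in set(idx)]
        loss = expert_loss(params, batch, config.policy)
        opt.zero_grad()
        loss.backward()
        opt.step()
        log.append((step, loss.item()))
        if callback is not None:
            callback(step, loss.item())
    return params, log
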