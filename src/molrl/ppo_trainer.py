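"""Proximal Policy Optimization loop for the molecular generators.

Each roll-out round collects a batch of episodes under the current
policy θ^k, scores the terminal molecules with the multi-objective
reward engine, and maintains the diversity memory stack.  Returns are
standard discounted reward-to-go with the final reward attached to the
terminal step:

    G_t = Σ_{u ≥ t} γ^{u-t} r_u ,   r_u = step reward (+ R_final at T).

Advantages subtract a learnable value baseline, A_t = G_t - b(s_t), and
the clipped surrogate objective

    L = -Σ_t min( ρ_t A_t , clip(ρ_t, 1-ε, 1+ε) A_t ),  ρ_t = P_θ/P_θk,

is minimized jointly with a squared-error value-regression term.
Defaults: γ = 0.98, ε = 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .environment import (
    Action,
    GenerationState,
    apply_action,
    initial_state,
    is_terminal,
)
from .mol_graph import MolGraph, to_canonical
from .policy_net import (
    ActionDistribution,
    PolicyConfig,
    StateFeatures,
    featurize_state,
    value_tensor,
)
from .reward_engine import (
    AffinityPredictor,
    MemoryStack,
    PropertyBounds,
    RewardBreakdown,
    DEFAULT_ALPHA,
    final_reward,
    update_memory,
)


@dataclass
class PPOConfig:
    gamma: float = 0.98
    clip_eps: float = 0.1
    epochs: int = 4
    minibatch: int = 64
    lr: float = 1e-4
    episodes_per_round: int = 50
    rounds: int = 30
    max_steps: int = 100
    mode: str = "dfm"
    seed: int = 0
    value_loss_weight: float = 0.5
    normalize_advantages: bool = False
    entropy_bonus: float = 0.0
    bounds: PropertyBounds = field(default_factory=PropertyBounds)
    alpha: tuple[float, float, float] = DEFAULT_ALPHA
    policy: PolicyConfig = field(default_factory=PolicyConfig)

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("discount gamma must lie in (0, 1]")
        if self.clip_eps <= 0:
            raise ValueError("clip epsilon must be positive")


@dataclass
class Episode:
    """One trajectory: frozen state features, actions, behavior log-probs,
    step rewards, and (after scoring) returns and advantages."""

    features: list[StateFeatures]
    actions: list[Action]
    behavior_logp: np.ndarray
    step_rewards: np.ndarray
    final_graph: MolGraph
    completed: bool  # terminated by policy choice, not by the step cap
    breakdown: Optional[RewardBreakdown] = None
    returns: Optional[np.ndarray] = None
    advantages: Optional[np.ndarray] = None

    @property
    def rewards(self) -> np.ndarray:
        """Per-step rewards with R_final folded into the terminal step."""
        r = self.step_rewards.astype(float).copy()
        if self.breakdown is not None and r.size:
            r[-1] += self.breakdown.r_final
        return r


def discounted_returns(rewards: Sequence[float], gamma: float) -> np.ndarray:
    """Reward-to-go: G_t = Σ_{u≥t} γ^(u-t) r_u."""
    out = np.zeros(len(rewards))
    acc = 0.0
    for t in range(len(rewards) - 1, -1, -1):
        acc = rewards[t] + gamma * acc
        out[t] = acc
    return out


def advantages(returns: np.ndarray, values: np.ndarray,
               normalize: bool = False) -> np.ndarray:
    """A_t = G_t - b(s_t), with optional batch normalization."""
    if len(returns) != len(values):
        raise ValueError("returns and values length mismatch")
    adv = np.asarray(returns, dtype=float) - np.asarray(values, dtype=float)
    if normalize and adv.size > 1:
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)
    return adv


# ---------------------------------------------------------------------------
# Roll-out collection
# ---------------------------------------------------------------------------

def collect_episode(params: dict[str, Tensor], config: PPOConfig,
                    rng: np.random.Generator) -> Episode:
    st = initial_state(config.mode, max_steps=config.max_steps)
    features, actions, logps, rewards = [], [], [], []
    with ad.no_grad():
        while not is_terminal(st):
            feats = featurize_state(st)
            dist = ActionDistribution(feats, params, config.policy)
            action = dist.sample(rng)
            logp = dist.log_prob(action).item()
            st, outcome = apply_action(st, action, inplace=True)
            features.append(feats)
            actions.append(action)
            logps.append(logp)
            rewards.append(outcome.step_reward)
    completed = st.step_count < config.max_steps
    return Episode(
        features=features,
        actions=actions,
        behavior_logp=np.array(logps),
        step_rewards=np.array(rewards),
        final_graph=st.graph.copy(),
        completed=completed,
    )


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def ppo_loss(params: dict[str, Tensor],
             steps: Sequence[tuple[StateFeatures, Action, float, float, float]],
             config: PPOConfig) -> Tensor:
    """Clipped-surrogate policy loss plus value regression on a step batch.

    Each step is (features, action, behavior_logp, return, advantage).
    """
    policy_terms, value_terms = [], []
    for feats, action, logp_old, ret, adv in steps:
        dist = ActionDistribution(feats, params, config.policy)
        logp = dist.log_prob(action)
        ratio = ad.exp(logp - logp_old)
        clipped = ad.clip(ratio, 1.0 - config.clip_eps, 1.0 + config.clip_eps)
        policy_terms.append(ad.minimum(ratio * adv, clipped * adv))
        value_terms.append(ad.square(dist.value() - ret))
        if config.entropy_bonus:
            # single-sample entropy estimator: E_a[-log p(a)]
            policy_terms.append((-logp) * config.entropy_bonus)
    loss = -ad.stack_scalars(policy_terms).sum()
    loss = loss + config.value_loss_weight * ad.stack_scalars(value_terms).sum()
    return loss


# ---------------------------------------------------------------------------
# Round report and training loop
# ---------------------------------------------------------------------------

@dataclass
class RoundReport:
    round_index: int
    n_molecules: int
    mean_r_final: float
    mean_unpenalized: float
    mean_p_complexity: float
    mean_p_property: float
    mean_p_similarity: float
    mean_r_qed: float
    mean_r_sa: float
    mean_r_aff: float
    mean_episode_reward: float
    rejection_rate: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def train_round(
    params: dict[str, Tensor],
    predictor: AffinityPredictor,
    config: PPOConfig,
    round_index: int,
    stack: MemoryStack,
    rng: np.random.Generator,
    opt: Optional[ad.Adam] = None,
) -> tuple[dict[str, Tensor], RoundReport, list[Episode]]:
    """One round: collect episodes, score, update memory, run PPO epochs."""
    episodes = [collect_episode(params, config, rng)
                for _ in range(config.episodes_per_round)]

    for ep in episodes:
        ep.breakdown = final_reward(
            ep.final_graph, predictor, config.bounds, stack,
            round_index, config.alpha,
        )
        ep.returns = discounted_returns(ep.rewards, config.gamma)
        with ad.no_grad():
            values = np.array([value_tensor(f, params, config.policy).item()
                               for f in ep.features])
        ep.advantages = advantages(ep.returns, values,
                                   config.normalize_advantages)

    update_memory(stack, [ep.final_graph for ep in episodes],
                  [ep.breakdown for ep in episodes], round_index)

    steps = [
        (f, a, lp, ret, adv)
        for ep in episodes
        for f, a, lp, ret, adv in zip(
            ep.features, ep.actions, ep.behavior_logp, ep.returns, ep.advantages)
    ]
    if opt is None:
        opt = ad.Adam(params, lr=config.lr)
    order = np.arange(len(steps))
    for _ in range(config.epochs):
        rng.shuffle(order)
        for lo in range(0, len(order), config.minibatch):
            batch = [steps[i] for i in order[lo: lo + config.minibatch]]
            loss = ppo_loss(params, batch, config)
            opt.zero_grad()
            loss.backward()
            opt.step()

    bds = [ep.breakdown for ep in episodes]
    n_steps = sum(len(ep.actions) for ep in episodes)
    n_rejected = sum(int((ep.step_rewards < 0).sum()) for ep in episodes)
    report = RoundReport(
        round_index=round_index,
        n_molecules=len(episodes),
        mean_r_final=float(np.mean([b.r_final for b in bds])),
        mean_unpenalized=float(np.mean([b.reward_sum for b in bds])),
        mean_p_complexity=float(np.mean([b.p_complexity for b in bds])),
        mean_p_property=float(np.mean([b.p_property for b in bds])),
        mean_p_similarity=float(np.mean([b.p_similarity for b in bds])),
        mean_r_qed=float(np.mean([b.r_qed for b in bds])),
        mean_r_sa=float(np.mean([b.r_sa for b in bds])),
        mean_r_aff=float(np.mean([b.r_aff for b in bds])),
        mean_episode_reward=float(np.mean(
            [ep.rewards.sum() for ep in episodes])),
        rejection_rate=n_rejected / max(n_steps, 1),
    )
    return params, report, episodes


def train(
    params: dict[str, Tensor],
    predictor: AffinityPredictor,
    config: PPOConfig,
    callback: Optional[Callable[[RoundReport], None]] = None,
) -> tuple[dict[str, Tensor], list[RoundReport], list[Episode]]:
    """Full training run: ``config.rounds`` rounds with a shared memory stack.

    Returns final parameters, per-round reports, and all scored episodes.
    """
    rng = np.random.default_rng(config.seed)
    stack = MemoryStack()
    opt = ad.Adam(params, lr=config.lr)
    reports: list[RoundReport] = []
    all_episodes: list[Episode] = []
    for r in range(config.rounds):
        params, report, episodes = train_round(
            params, predictor, config, r, stack, rng, opt)
        reports.append(report)
        all_episodes.extend(episodes)
        if callback is not None:
            callback(report)
    return params, reports, all_episodes
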