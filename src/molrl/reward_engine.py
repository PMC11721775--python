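"""Multi-objective reward: property scaling, penalties, memory stack.

A terminal molecule is scored on three properties — drug-likeness
(QED), synthetic accessibility (SAScore, lower is better) and predicted
binding affinity (pK units, via a pluggable predictor).  Each raw value
is mapped to [0, 1] by a linear ramp between a lower and an upper bound;
the final reward is the weighted sum of the three property rewards
multiplied by three penalty factors:

* complexity — a descending ramp in heavy-atom count (1 at ≤10 atoms,
  0 at ≥40), halved for molecules with more than two potential
  stereocenters, countering the size bias of learned affinity scores;
* property  — ∏ min(1, R/0.2), zeroing the reward when any single
  property is very poor;
* similarity — a diversity pressure computed against a memory stack of
  recent high-scoring molecules (halogens ignored throughout).

R_final = (Σ_i α_i R_i) · ∏_j P_j.
"""

from __future__ import annotations

import math
import os
import sys
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from rdkit.Chem import QED as _QED

from .mol_graph import (
    MolGraph,
    Fingerprint,
    count_chiral_centers,
    ecfp4,
    heavy_atom_count,
    strip_halogens,
    tanimoto,
    to_canonical,
)

# The Ertl-Schuffenhauer synthetic-accessibility scorer ships with RDKit
# as a contrib module; make it importable.
from rdkit.Chem import RDConfig as _RDConfig

_SA_DIR = os.path.join(_RDConfig.RDContribDir, "SA_Score")
if _SA_DIR not in sys.path:
    sys.path.append(_SA_DIR)
import sascorer as _sascorer  # noqa: E402

#: MolGraph -> predicted binding affinity in -log (pK) units.
AffinityPredictor = Callable[[MolGraph], float]


class RewardError(ValueError):
    pass


@dataclass(frozen=True)
class Bounds:
    """Per-property scaling bounds.  ``low > high`` means the property
    is inverted (smaller raw values are better, e.g. SAScore)."""

    low: float
    high: float

    def __post_init__(self):
        if self.low == self.high:
            raise RewardError("degenerate bounds: low == high")


@dataclass(frozen=True)
class PropertyBounds:
    qed: Bounds = Bounds(0.2, 0.8)
    sa: Bounds = Bounds(3.5, 2.0)  # inverted: lower SAScore is better
    affinity: Bounds = Bounds(5.5, 8.5)  # pK units


#: Default property weights α (unweighted sum).
DEFAULT_ALPHA: tuple[float, float, float] = (1.0, 1.0, 1.0)

#: Complexity-penalty heavy-atom bounds and stereocenter factor.
COMPLEXITY_BOUNDS = (10, 40)
CHIRAL_FACTOR = 0.5
CHIRAL_LIMIT = 2

#: Memory-stack windows (in roll-out rounds) and admission threshold.
TANIMOTO_WINDOW = 10
MAPPING_AGE = 20
ADMISSION_FRACTION = 0.7


# ---------------------------------------------------------------------------
# Property scaling and scorers
# ---------------------------------------------------------------------------

def scale_property(value: float, bounds: Bounds) -> float:
    """Linear ramp of a raw property value onto [0, 1].

    Returns 1 at/beyond the upper bound, 0 at/below the lower bound and
    interpolates linearly in between.  Inverted bounds (``low > high``)
    mirror the ramp so that smaller raw values score higher.
    """
    if not math.isfinite(value):
        raise RewardError(f"non-finite property value {value!r}")
    lo, hi = bounds.low, bounds.high
    t = (value - lo) / (hi - lo)
    return min(1.0, max(0.0, t))


def qed_score(g: MolGraph) -> float:
    """Quantitative estimate of drug-likeness, in (0, 1)."""
    return float(_QED.qed(g.to_rdkit()))


def sa_score(g: MolGraph) -> float:
    """Ertl-Schuffenhauer synthetic-accessibility score, in [1, 10]."""
    return float(_sascorer.calculateScore(g.to_rdkit()))


# ---------------------------------------------------------------------------
# Penalties
# ---------------------------------------------------------------------------

def complexity_penalty(n_heavy: int, n_chiral: int) -> float:
    """Size/stereo penalty factor in [0, 1].

    Descending ramp in heavy-atom count: 1.0 up to 10 atoms, 0.0 from
    40 atoms, linear in between; multiplied by 0.5 when the molecule has
    more than two potential stereocenters.
    """
    if n_heavy < 1:
        raise RewardError("complexity penalty needs at least one heavy atom")
    lo, hi = COMPLEXITY_BOUNDS
    p = min(1.0, max(0.0, (hi - n_heavy) / (hi - lo)))
    if n_chiral > CHIRAL_LIMIT:
        p *= CHIRAL_FACTOR
    return p


def property_penalty(rewards: Sequence[float]) -> float:
    """∏ min(1, R/0.2): collapses the reward when any property is poor."""
    p = 1.0
    for r in rewards:
        p *= min(1.0, r / 0.2)
    return p


# ---------------------------------------------------------------------------
# Memory stack (diversity pressure)
# ---------------------------------------------------------------------------

@dataclass
class StackEntry:
    round_index: int
    canonical: str  # halogen-stripped canonical form
    fingerprint: Fingerprint  # halogen-stripped ECFP4
    reward_sum: float


@dataclass
class MemoryStack:
    """Archive of favorable molecules, round-stamped.

    Entries from the preceding :data:`TANIMOTO_WINDOW` rounds form the
    Tanimoto pool; canonical forms older than :data:`MAPPING_AGE` rounds
    form the mapping archive (exact-match lookup).  The two windows are
    disjoint; the mapping archive is FIFO-capped.
    """

    entries: list[StackEntry] = field(default_factory=list)
    mapping_archive: "dict[str, int]" = field(default_factory=dict)
    archive_capacity: int = 1_000_000
    nbits: int = 2048

    def tanimoto_pool(self, round_index: int) -> list[StackEntry]:
        return [e for e in self.entries if e.round_index >= round_index - TANIMOTO_WINDOW]

    def in_mapping_archive(self, canonical: str, round_index: int) -> bool:
        r = self.mapping_archive.get(canonical)
        return r is not None and r < round_index - MAPPING_AGE

    def admit(self, g: MolGraph, reward_sum: float, round_index: int) -> None:
        stripped = strip_halogens(g)
        self.entries.append(
            StackEntry(
                round_index=round_index,
                canonical=to_canonical(stripped),
                fingerprint=ecfp4(stripped, self.nbits),
                reward_sum=reward_sum,
            )
        )

    def _age_out(self, round_index: int) -> None:
        keep: list[StackEntry] = []
        for e in self.entries:
            if e.round_index < round_index - TANIMOTO_WINDOW:
                if e.canonical not in self.mapping_archive:
                    self.mapping_archive[e.canonical] = e.round_index
            else:
                keep.append(e)
        self.entries = keep
        while len(self.mapping_archive) > self.archive_capacity:
            self.mapping_archive.pop(next(iter(self.mapping_archive)))


def similarity_penalty(g: MolGraph, stack: MemoryStack, round_index: int) -> float:
    """Diversity penalty factor in [0, 1] (Tanimoto on halogen-stripped ECFP4).

    0.0 on an exact mapping-archive hit (a molecule re-generated more
    than 20 rounds later) or when the maximal Tanimoto similarity to the
    recent pool reaches 0.7; 1.0 at or below 0.4; linear ramp between.
    An empty stack imposes no penalty.
    """
    stripped = strip_halogens(g)
    return similarity_penalty_from_fingerprint(
        ecfp4(stripped, stack.nbits), to_canonical(stripped), stack, round_index)


def similarity_penalty_from_fingerprint(fp: Fingerprint, canonical: str,
                                        stack: MemoryStack,
                                        round_index: int) -> float:
    """Similarity penalty for an already halogen-stripped fingerprint."""
    if stack.in_mapping_archive(canonical, round_index):
        return 0.0
    pool = stack.tanimoto_pool(round_index)
    if not pool:
        return 1.0
    t = max(tanimoto(fp, e.fingerprint) for e in pool)
    return _similarity_ramp(t)


def _similarity_ramp(t: float) -> float:
    if t >= 0.7:
        return 0.0
    if t <= 0.4:
        return 1.0
    return 1.0 - (t - 0.4) / 0.3


def update_memory(stack: MemoryStack, molecules: Sequence[MolGraph],
                  breakdowns: Sequence["RewardBreakdown"], round_index: int) -> MemoryStack:
    """End-of-round bookkeeping: admit favorable molecules, age out old ones.

    A molecule is admitted when its unpenalized reward Σ α_i R_i exceeds
    70% of the attainable maximum Σ α_i.
    """
    for g, bd in zip(molecules, breakdowns):
        if bd.reward_sum > ADMISSION_FRACTION * sum(bd.alpha):
            stack.admit(g, bd.reward_sum, round_index)
    stack._age_out(round_index + 1)
    return stack


# ---------------------------------------------------------------------------
# Final reward
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RewardBreakdown:
    """Per-property rewards, penalty factors and the final scalar."""

    qed: float
    sa: float
    affinity: float
    r_qed: float
    r_sa: float
    r_aff: float
    p_complexity: float
    p_property: float
    p_similarity: float
    alpha: tuple[float, float, float]
    r_final: float

    @property
    def reward_sum(self) -> float:
        """Unpenalized weighted property-reward sum Σ α_i R_i."""
        a = self.alpha
        return a[0] * self.r_qed + a[1] * self.r_sa + a[2] * self.r_aff


def final_reward(
    g: MolGraph,
    predictor: AffinityPredictor,
    bounds: PropertyBounds = PropertyBounds(),
    stack: Optional[MemoryStack] = None,
    round_index: int = 0,
    alpha: tuple[float, float, float] = DEFAULT_ALPHA,
) -> RewardBreakdown:
    """Score a terminal molecule: R_final = (Σ α_i R_i) · ∏ P_j."""
    qed = qed_score(g)
    sa = sa_score(g)
    try:
        aff = float(predictor(g))
    except Exception as exc:
        raise RewardError(f"affinity predictor failed on {to_canonical(g)}: {exc}") from exc
    if not math.isfinite(aff):
        raise RewardError(f"non-finite affinity for {to_canonical(g)}")

    r_qed = scale_property(qed, bounds.qed)
    r_sa = scale_property(sa, bounds.sa)
    r_aff = scale_property(aff, bounds.affinity)

    p_complex = complexity_penalty(heavy_atom_count(g), count_chiral_centers(g))
    p_prop = property_penalty((r_qed, r_sa, r_aff))
    p_sim = 1.0 if stack is None else similarity_penalty(g, stack, round_index)

    reward_sum = alpha[0] * r_qed + alpha[1] * r_sa + alpha[2] * r_aff
    return RewardBreakdown(
        qed=qed, sa=sa, affinity=aff,
        r_qed=r_qed, r_sa=r_sa, r_aff=r_aff,
        p_complexity=p_complex, p_property=p_prop, p_similarity=p_sim,
        alpha=alpha,
        r_final=reward_sum * p_complex * p_prop * p_sim,
    )
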