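"""State-transition dynamics for stepwise molecular graph construction.

The environment executes agent actions (add a bond, optionally creating a
fresh atom; mark the focus atom finished; or stop), enforcing a valency
rule and four structural-alert classes after every action:

  (a) cumulated double bonds and O–O (peroxyl) bonds,
  (b) double or triple bonds inside three- or four-membered rings,
  (c) bridged ring systems involving an aromatic ring,
  (d) rings with eight or more members (SSSR).

Actions failing a check are *rejected*: the working graph is left
untouched and a -0.2 step reward is returned.  Accepted bond actions
that close a ring earn +0.02; everything else earns 0.  Because the
working graph only ever mutates through accepted actions, every
terminal graph is chemically valid by construction — this is the
mechanism behind 100% sanitizer validity of generated batches.

Three agent modes share the dynamics and differ in focus handling:

* ``gcpn``  — the agent picks the focus atom itself and may STOP;
* ``dfm``   — focus follows a depth-first (stack) discipline;
* ``bfm``   — focus follows a breadth-first (queue) discipline.

In dfm/bfm the stop decision is replaced by marking the focus atom
"finished"; the episode ends when every atom is marked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Union

from rdkit import Chem

from .mol_graph import (
    HALOGENS,
    MAX_VALENCE,
    VOCABULARY,
    MolGraph,
    MolGraphError,
)

Mode = Literal["gcpn", "dfm", "bfm"]

#: Step-reward constants.
RING_CLOSURE_REWARD = 0.02
REJECTION_PENALTY = -0.2

#: Default per-episode action cap.
DEFAULT_STEP_CAP = 100

#: Editable SMARTS alerts for violation class (a).  Classes (b) and (d)
#: are ring-size rules evaluated on the SSSR and class (c) requires ring
#: analysis with perceived aromaticity; neither is SMARTS-expressible in
#: a robust way, so they are implemented in code below.
ALERT_SMARTS: dict[str, str] = {
    # cumulated double bonds (allene/ketene-like); hypervalent S and P
    # centers are excluded so that sulfones/sulfonamides and phosphates,
    # ubiquitous in drug-like space, do not trip the alert
    "cumulated": "[*]=[!#16;!#15]=[*]",
    "peroxide": "[#8]~[#8]",
}

_COMPILED = {name: Chem.MolFromSmarts(s) for name, s in ALERT_SMARTS.items()}


class ActionError(ValueError):
    """Malformed action (bad indices/fields) — distinct from chemical rejection."""


@dataclass(frozen=True)
class Action:
    """An agent move.

    gcpn mode: either ``stop`` or a bond action ``(focus, end, order)``.
    dfm/bfm mode: either ``finish`` (mark the focus atom) or a bond
    action ``(end, order)`` from the environment-dictated focus atom.
    ``end`` is an existing atom index (int) or an element symbol (str)
    for a fresh atom appended and bonded in the same action.
    """

    stop: bool = False
    finish: bool = False
    focus: Optional[int] = None
    end: Union[int, str, None] = None
    order: Optional[int] = None


@dataclass(frozen=True)
class StepOutcome:
    accepted: bool
    step_reward: float
    terminal: bool
    violation: Optional[str] = None  # 'valency' or 'a'..'d'


@dataclass
class GenerationState:
    """RL state: a partial molecule plus traversal bookkeeping."""

    graph: MolGraph
    mode: Mode
    visit_order: list[int] = field(default_factory=list)
    finished_set: set[int] = field(default_factory=set)
    step_count: int = 0
    rejected_count: int = 0
    stopped: bool = False
    max_steps: int = DEFAULT_STEP_CAP
    focus_history: list[int] = field(default_factory=list)

    def copy(self) -> "GenerationState":
        return GenerationState(
            graph=self.graph.copy(),
            mode=self.mode,
            visit_order=list(self.visit_order),
            finished_set=set(self.finished_set),
            step_count=self.step_count,
            rejected_count=self.rejected_count,
            stopped=self.stopped,
            max_steps=self.max_steps,
            focus_history=list(self.focus_history),
        )


def initial_state(mode: Mode, max_steps: int = DEFAULT_STEP_CAP,
                  start_element: str = "C") -> GenerationState:
    """A fresh episode: a single starting atom (carbon by default)."""
    g = MolGraph()
    g.add_atom(start_element)
    return GenerationState(graph=g, mode=mode, visit_order=[0], max_steps=max_steps)


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

def valency_ok(g: MolGraph, focus: int, end: Union[int, str], order: int) -> bool:
    """True iff adding the bond keeps Σ bond orders ≤ max valence at both ends."""
    if not (0 <= focus < g.n_atoms):
        raise ActionError(f"focus index {focus} out of range")
    if order not in (1, 2, 3):
        return False
    if g.valence_used(focus) + order > MAX_VALENCE[g.elements[focus]]:
        return False
    if isinstance(end, str):
        if end not in MAX_VALENCE:
            raise ActionError(f"unknown element {end!r}")
        return order <= MAX_VALENCE[end]
    if not (0 <= end < g.n_atoms):
        raise ActionError(f"end index {end} out of range")
    if end == focus or g.has_bond(focus, end):
        return False
    return g.valence_used(end) + order <= MAX_VALENCE[g.elements[end]]


def substructure_violation(g: MolGraph) -> Optional[str]:
    """First matching structural-alert class 'a'..'d', or None.

    Checks run in order a → d.  Class (a) uses SMARTS patterns from
    :data:`ALERT_SMARTS`; (b) and (d) use kekulé bond orders within the
    SSSR; (c) re-perceives aromaticity and flags ring pairs sharing
    three or more atoms when one of them is aromatic.
    """
    if not g.bonds:
        return None
    mol_k = g.to_rdkit(sanitize=False)
    Chem.GetSymmSSSR(mol_k)
    rings = [tuple(r) for r in mol_k.GetRingInfo().AtomRings()]
    mol_s = g.to_rdkit(sanitize=True)

    # (a) cumulated double bonds / peroxyl bonds
    for patt in _COMPILED.values():
        if mol_s.HasSubstructMatch(patt):
            return "a"

    # (b) double/triple bonds in 3- or 4-membered rings
    for ring in rings:
        if len(ring) in (3, 4):
            for k in range(len(ring)):
                i, j = ring[k], ring[(k + 1) % len(ring)]
                key = (i, j) if i < j else (j, i)
                if g.bonds.get(key, 0) >= 2:
                    return "b"

    # (c) bridged ring systems involving an aromatic ring
    if len(rings) >= 2:
        aromatic = []
        ri = mol_s.GetRingInfo()
        for ring in ri.AtomRings():
            aromatic.append(all(mol_s.GetAtomWithIdx(i).GetIsAromatic() for i in ring))
        ring_sets = [set(r) for r in ri.AtomRings()]
        for x in range(len(ring_sets)):
            for y in range(x + 1, len(ring_sets)):
                if len(ring_sets[x] & ring_sets[y]) >= 3 and (aromatic[x] or aromatic[y]):
                    return "c"

    # (d) large rings (eight or more members in the SSSR)
    for ring in rings:
        if len(ring) >= 8:
            return "d"
    return None


# ---------------------------------------------------------------------------
# Focus / termination
# ---------------------------------------------------------------------------

def next_focus(state: GenerationState) -> Optional[int]:
    """Traversal-dictated focus atom, or None when all atoms are finished.

    dfm uses stack discipline (most recently added unfinished atom),
    bfm uses queue discipline (earliest unfinished atom).
    """
    if state.mode not in ("dfm", "bfm"):
        raise ActionError(f"next_focus undefined for mode {state.mode!r}")
    if not state.visit_order:
        return None
    return state.visit_order[-1] if state.mode == "dfm" else state.visit_order[0]


def is_terminal(state: GenerationState) -> bool:
    if state.step_count >= state.max_steps:
        return True
    if state.mode == "gcpn":
        return state.stopped
    return not state.visit_order


# ---------------------------------------------------------------------------
# Action legality (valency mask) and execution
# ---------------------------------------------------------------------------

def end_candidates(state: GenerationState, focus: int) -> list[Union[int, str]]:
    """End-atom candidates: eligible existing atoms plus fresh element slots.

    In dfm/bfm, atoms already marked finished are excluded.
    """
    g = state.graph
    out: list[Union[int, str]] = []
    for i in range(g.n_atoms):
        if i == focus or g.has_bond(focus, i):
            continue
        if state.mode in ("dfm", "bfm") and i in state.finished_set:
            continue
        out.append(i)
    out.extend(VOCABULARY)
    return out


def legal_orders(g: MolGraph, focus: int, end: Union[int, str]) -> list[int]:
    return [o for o in (1, 2, 3) if valency_ok(g, focus, end, o)]


def enumerate_actions(state: GenerationState) -> list[Action]:
    """All actions legal under the valency mask (structural alerts are
    enforced at execution time, not masked)."""
    actions: list[Action] = []
    if state.mode == "gcpn":
        actions.append(Action(stop=True))
        for focus in range(state.graph.n_atoms):
            for end in end_candidates(state, focus):
                for order in legal_orders(state.graph, focus, end):
                    actions.append(Action(focus=focus, end=end, order=order))
    else:
        actions.append(Action(finish=True))
        focus = next_focus(state)
        if focus is not None:
            for end in end_candidates(state, focus):
                for order in legal_orders(state.graph, focus, end):
                    actions.append(Action(focus=focus, end=end, order=order))
    return actions


def apply_action(state: GenerationState, action: Action,
                 inplace: bool = False) -> tuple[GenerationState, StepOutcome]:
    """Execute one action: mutate bookkeeping, or accept/reject a bond.

    Rejected actions leave the graph untouched and cost -0.2; accepted
    ring-closing bonds earn +0.02; every call advances ``step_count``.
    """
    if is_terminal(state):
        raise ActionError("episode is terminal")
    st = state if inplace else state.copy()
    st.step_count += 1

    if st.mode == "gcpn":
        if action.finish:
            raise ActionError("finish-mark is undefined in gcpn mode")
        if action.stop:
            st.stopped = True
            return st, StepOutcome(True, 0.0, True)
        focus = action.focus
        if focus is None:
            raise ActionError("bond action needs a focus atom in gcpn mode")
    else:
        if action.stop:
            raise ActionError("STOP is undefined in dfm/bfm mode")
        focus = next_focus(st)
        if action.finish:
            if focus is None:
                raise ActionError("no focus atom left to mark finished")
            st.finished_set.add(focus)
            if st.mode == "dfm":
                st.visit_order.pop()
            else:
                st.visit_order.pop(0)
            return st, StepOutcome(True, 0.0, is_terminal(st))
        if action.focus is not None and action.focus != focus:
            raise ActionError(
                f"action focus {action.focus} contradicts traversal focus {focus}"
            )

    if action.end is None or action.order is None:
        raise ActionError("bond action needs end and order")
    if isinstance(action.end, int) and st.mode in ("dfm", "bfm") \
            and action.end in st.finished_set:
        raise ActionError(f"end atom {action.end} is marked finished")

    # Valency gate on the current graph.
    if not valency_ok(st.graph, focus, action.end, action.order):
        st.rejected_count += 1
        return st, StepOutcome(False, REJECTION_PENALTY, is_terminal(st), "valency")

    # Build the hypothetical post-action graph, then run alert patterns.
    trial = st.graph.copy()
    if isinstance(action.end, str):
        end_idx = trial.add_atom(action.end)
        closes_ring = False
    else:
        end_idx = action.end
        closes_ring = True  # the working graph is connected, so any
        # bond between existing atoms closes a cycle
    trial.add_bond(focus, end_idx, action.order)
    violation = substructure_violation(trial)
    if violation is not None:
        st.rejected_count += 1
        return st, StepOutcome(False, REJECTION_PENALTY, is_terminal(st), violation)

    st.graph = trial
    st.focus_history.append(focus)
    if isinstance(action.end, str):
        st.visit_order.append(end_idx)
    reward = RING_CLOSURE_REWARD if closes_ring else 0.0
    return st, StepOutcome(True, reward, is_terminal(st))
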