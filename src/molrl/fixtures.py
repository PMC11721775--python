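"""Synthetic inputs that make every component testable offline.

* a hand-curated corpus of ~50 drug-like molecules (aspirin included),
  all of which pass the training-set ring filter and the environment's
  structural-alert checks;
* a uniform-random-policy molecule sampler exercising the environment's
  validity guarantee;
* a deterministic surrogate binding-affinity predictor standing in for
  an external graph-neural-network scorer — it reproduces the size bias
  of learned affinity models (larger molecules score higher) plus a
  hash-derived pseudo-pharmacophore term, bounded in (4, 9) pK;
* concrete aspirin construction trajectories for each agent mode.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np

from .environment import (
    Action,
    GenerationState,
    apply_action,
    enumerate_actions,
    initial_state,
    is_terminal,
    next_focus,
)
from .expert_pretrain import traversal_trajectory
from .mol_graph import MolGraph, parse_smiles, strip_halogens, to_canonical

ASPIRIN_SMILES = "CC(=O)Oc1ccccc1C(=O)O"

#: Curated drug-like corpus (neutral molecules over the C/N/O/S/P/halogen
#: vocabulary; every entry passes the structural-alert and ring filters).
FIXTURE_SMILES: tuple[str, ...] = (
    ASPIRIN_SMILES,
    "CC(=O)Nc1ccc(O)cc1",                      # paracetamol
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",              # ibuprofen
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",            # naproxen
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",              # caffeine
    "Cn1c(=O)c2[nH]cnc2n(C)c1=O",              # theophylline
    "CN1CCCC1c1cccnc1",                        # nicotine
    "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O",       # diazepam
    "CN(C)CCOC(c1ccccc1)c1ccccc1",             # diphenhydramine
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",          # atenolol
    "CC(C)NCC(O)COc1cccc2ccccc12",             # propranolol
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",           # salbutamol
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",   # warfarin
    "O=c1ccc2ccccc2o1",                        # coumarin
    "COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1",   # quinine
    "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",  # celecoxib
    "O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1",       # phenytoin
    "NC(=O)N1c2ccccc2C=Cc2ccccc21",            # carbamazepine
    "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1",      # fluoxetine
    "CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21",      # sertraline
    "CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21", # citalopram
    "COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1",        # venlafaxine
    "COc1cccc(C2(O)CCCCC2CN(C)C)c1",           # tramadol
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",              # lidocaine
    "CCN(CC)CCOC(=O)c1ccc(N)cc1",              # procaine
    "CCOC(=O)c1ccc(N)cc1",                     # benzocaine
    "CNC1(c2ccccc2Cl)CCCCC1=O",                # ketamine
    "Cc1nccn1CC1CCc2c(C1=O)c1ccccc1n2C",       # ondansetron
    "CNS(=O)(=O)Cc1ccc2[nH]cc(CCN(C)C)c2c1",   # sumatriptan
    "Cc1ccc(-c2nc3ccc(C)cn3c2CC(=O)N(C)C)cc1", # zolpidem
    "COc1ccc2[nH]cc(CCNC(=O)C)c2c1",           # melatonin
    "NCCc1c[nH]c2ccc(O)cc12",                  # serotonin
    "NCCc1ccc(O)c(O)c1",                       # dopamine
    "NCCc1c[nH]cn1",                           # histamine
    "Cc1ncc(CCO)n1C",                          # metronidazole core
    "Cc1nc[nH]c1CSCCNC(=N)NC#N",               # cimetidine
    "CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1",          # chlorpheniramine
    "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC",         # trimethoprim
    "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1",         # sulfamethoxazole
    "O=C(O)C=Cc1ccc(O)c(O)c1",                 # caffeic acid
    "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1",  # indomethacin
    "CN(C)CCC=C1c2ccccc2CCc2ccccc21",          # amitriptyline
    "CN(C)CCCN1c2ccccc2CCc2ccccc21",           # imipramine
    "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1",     # haloperidol
    "O=C(CCCN1CCN(c2ncccn2)CC1)NC1CCCCC1",     # buspirone analog
    "CN(C)C(=N)NC(=N)N",                       # metformin
    "O=c1[nH]cnc2[nH]ncc12",                   # allopurinol
    "CCc1nc(N)nc(N)c1-c1ccc(Cl)cc1",           # pyrimethamine
    "CC(N)COc1c(C)cccc1C",                     # mexiletine
    "CNCC(O)c1cccc(O)c1",                      # phenylephrine
    "CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1",         # tolbutamide
    "O=c1[nH]c2cc(Cl)ccc2o1",                  # chlorzoxazone
    "CC(=O)Nc1ccc(OCC(O)CNC(C)C)cc1",          # practolol
)


def fixture_corpus() -> list[str]:
    """The curated drug-like SMILES corpus (aspirin first)."""
    return list(FIXTURE_SMILES)


def fixture_graphs() -> list[MolGraph]:
    return [parse_smiles(s) for s in FIXTURE_SMILES]


# ---------------------------------------------------------------------------
# Random-policy sampler
# ---------------------------------------------------------------------------

def random_policy_sample(
    n: int, mode: str = "dfm", seed: int = 0, max_steps: int = 100,
) -> tuple[list[MolGraph], list[bool]]:
    """Generate ``n`` molecules by uniform-random legal actions.

    Actions are drawn uniformly from the valency-legal action set;
    structural-alert rejections are handled by the environment.  Returns
    the terminal graphs and per-episode completion flags (terminated by
    choice rather than by the step cap).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    graphs, completed = [], []
    for _ in range(n):
        st = initial_state(mode, max_steps=max_steps)
        while not is_terminal(st):
            actions = enumerate_actions(st)
            st, _ = apply_action(st, actions[int(rng.integers(len(actions)))],
                                 inplace=True)
        graphs.append(st.graph.copy())
        completed.append(st.step_count < max_steps)
    return graphs, completed


# ---------------------------------------------------------------------------
# Surrogate affinity predictor
# ---------------------------------------------------------------------------

def _pharmacophore_term(g: MolGraph) -> float:
    """Hash-derived pseudo-pharmacophore score in [-1, 1], deterministic
    per canonical (halogen-stripped) structure."""
    key = to_canonical(strip_halogens(g)) if g.n_atoms else ""
    digest = hashlib.md5(key.encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2 ** 63 - 1.0


def surrogate_affinity(g: MolGraph) -> float:
    """Deterministic stand-in binding-affinity predictor (pK units).

    4 + 5·σ(0.08·(n_heavy − 20) + 0.3·z(g)) with σ the logistic
    function: bounded in (4, 9), strictly increasing in molecule size
    at fixed pseudo-pharmacophore term z — emulating the size bias of
    learned affinity scorers.
    """
    x = 0.08 * (g.n_atoms - 20) + 0.3 * _pharmacophore_term(g)
    return 4.0 + 5.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# Aspirin construction trajectories
# ---------------------------------------------------------------------------

def aspirin_trajectory(mode: str) -> list[tuple[GenerationState, Action]]:
    """A concrete legal action list replaying to aspirin under ``mode``.

    Construction starts from the acetyl methyl carbon, so the benzene
    ring is entered, walked and closed before the second exocyclic
    branch completes (a depth-first construction order).
    """
    asp = parse_smiles(ASPIRIN_SMILES)
    if mode in ("dfm", "bfm"):
        return traversal_trajectory(asp, mode, start=0, rng=np.random.default_rng(7))
    if mode != "gcpn":
        raise ValueError(f"unknown mode {mode!r}")
    # Replay the depth-first edge order as explicit-focus gcpn actions.
    dfm_pairs = traversal_trajectory(asp, "dfm", start=0, rng=np.random.default_rng(7))
    st = initial_state("gcpn")
    pairs: list[tuple[GenerationState, Action]] = []
    for state, action in dfm_pairs:
        if action.finish:
            continue
        gcpn_action = Action(focus=next_focus(state), end=action.end,
                             order=action.order)
        pairs.append((st.copy(), gcpn_action))
        st, outcome = apply_action(st, gcpn_action, inplace=True)
        assert outcome.accepted
    pairs.append((st.copy(), Action(stop=True)))
    return pairs


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_fixtures(out_dir) -> None:
    """Write the corpus SMILES and a replayable aspirin action log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "corpus.smi").write_text("\n".join(FIXTURE_SMILES) + "\n")
    with open(out / "aspirin_trajectory.jsonl", "w") as fh:
        for mode in ("gcpn", "dfm", "bfm"):
            for _, action in aspirin_trajectory(mode):
                fh.write(json.dumps({
                    "mode": mode, "stop": action.stop, "finish": action.finish,
                    "focus": action.focus, "end": action.end,
                    "order": action.order}) + "\n")
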