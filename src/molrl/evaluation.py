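"""Generative-model metrics and de novo hit assessment.

Batch metrics follow the standard fractions

    validity   = valid graphs / generated graphs
    uniqueness = unique valid graphs / valid graphs
    novelty    = unique valid graphs not in the training set / unique valid graphs

computed both on molecules and on their Bemis–Murcko scaffolds, plus

* pattern validity — fraction of valid graphs free of structural-alert
  substructures, and
* completeness — fraction of episodes terminated by the policy's own
  choice (all atoms finish-marked, or STOP) rather than by the step
  cap.  Breadth-first generation is prone to leaving rings unclosed and
  episodes unfinished, which this column surfaces.

Hit filtering applies the strict thresholds QED > 0.6, SAScore < 3.0
and predicted affinity > 7.0 (pK); binder matching counts generated
molecules with an ECFP4 Tanimoto similarity above 0.6 to any reference
binder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .environment import substructure_violation
from .mol_graph import MolGraph, ecfp4, murcko_scaffold, tanimoto, to_canonical


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class MetricRecord:
    n_generated: int
    rdkit_validity: float
    pattern_validity: float
    completeness: Optional[float]
    uniqueness: float
    scaffold_uniqueness: float
    novelty: float
    scaffold_novelty: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _scaffold_key(g: MolGraph) -> str:
    # acyclic molecules share the single empty-scaffold class
    return to_canonical(murcko_scaffold(g))


def validity_metrics(
    generated: Sequence[MolGraph],
    training_set: Sequence[MolGraph] = (),
    completed: Optional[Sequence[bool]] = None,
) -> MetricRecord:
    """Compute the full metric record for a generated batch."""
    if not generated:
        raise EvaluationError("empty generated batch")
    valid: list[MolGraph] = []
    canon: list[str] = []
    n_pattern_ok = 0
    for g in generated:
        try:
            smi = to_canonical(g)
        except Exception:
            continue
        valid.append(g)
        canon.append(smi)
        if substructure_violation(g) is None:
            n_pattern_ok += 1

    n = len(generated)
    rdkit_validity = len(valid) / n
    pattern_validity = n_pattern_ok / n
    completeness = None
    if completed is not None:
        if len(completed) != n:
            raise EvaluationError("completed flags do not match batch size")
        completeness = sum(bool(c) for c in completed) / n

    train_canon = {to_canonical(g) for g in training_set}
    unique = sorted(set(canon))
    uniqueness = len(unique) / len(valid) if valid else 0.0
    novel = [s for s in unique if s not in train_canon]
    novelty = len(novel) / len(unique) if unique else 0.0

    scaff = [_scaffold_key(g) for g in valid]
    train_scaff = {_scaffold_key(g) for g in training_set}
    unique_scaff = sorted(set(scaff))
    scaffold_uniqueness = len(unique_scaff) / len(scaff) if scaff else 0.0
    novel_scaff = [s for s in unique_scaff if s not in train_scaff]
    scaffold_novelty = len(novel_scaff) / len(unique_scaff) if unique_scaff else 0.0

    return MetricRecord(
        n_generated=n,
        rdkit_validity=rdkit_validity,
        pattern_validity=pattern_validity,
        completeness=completeness,
        uniqueness=uniqueness,
        scaffold_uniqueness=scaffold_uniqueness,
        novelty=novelty,
        scaffold_novelty=scaffold_novelty,
    )


# ---------------------------------------------------------------------------
# Hit assessment
# ---------------------------------------------------------------------------

#: Default hit-filter thresholds (all strict inequalities).
HIT_THRESHOLDS = {"qed_min": 0.6, "sa_max": 3.0, "affinity_min": 7.0}


def hit_filter(records, qed_min: float = HIT_THRESHOLDS["qed_min"],
               sa_max: float = HIT_THRESHOLDS["sa_max"],
               affinity_min: float = HIT_THRESHOLDS["affinity_min"]) -> pd.DataFrame:
    """Keep records with QED > qed_min, SAScore < sa_max, affinity > affinity_min."""
    df = pd.DataFrame(records)
    if len(df) == 0:
        return df
    for col in ("qed", "sa", "affinity"):
        if col not in df.columns:
            raise EvaluationError(f"records lack required field {col!r}")
    keep = (df["qed"] > qed_min) & (df["sa"] < sa_max) & (df["affinity"] > affinity_min)
    return df[keep].reset_index(drop=True)


def binder_similarity_count(
    generated: Sequence[MolGraph],
    references: Sequence[MolGraph],
    threshold: float = 0.6,
    nbits: int = 2048,
) -> tuple[int, list[tuple[int, int, float]]]:
    """Generated molecules similar (Tanimoto > threshold) to any reference.

    Returns the count of such generated molecules and every matched
    (generated index, reference index, similarity) pair for inspection.
    """
    gen_fps = [ecfp4(g, nbits) for g in generated]
    ref_fps = [ecfp4(r, nbits) for r in references]
    pairs: list[tuple[int, int, float]] = []
    matched: set[int] = set()
    for i, gf in enumerate(gen_fps):
        for j, rf in enumerate(ref_fps):
            sim = tanimoto(gf, rf)
            if sim > threshold:
                pairs.append((i, j, sim))
                matched.add(i)
    return len(matched), pairs
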