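"""Filter generated molecules to hits and match them against binders.

Hit criteria (all strict): QED > 0.6, SAScore < 3.0, predicted affinity
> 7.0 pK.  Binder matching counts generated molecules with an ECFP4
Tanimoto similarity above 0.6 to any reference.
"""

from molrl import (
    binder_similarity_count,
    fixture_graphs,
    hit_filter,
    qed_score,
    sa_score,
    to_canonical,
)
from molrl.fixtures import surrogate_affinity

corpus = fixture_graphs()
records = [{"smiles": to_canonical(g), "qed": qed_score(g), "sa": sa_score(g),
            "affinity": surrogate_affinity(g)} for g in corpus]
hits = hit_filter(records)
print(f"{len(hits)} of {len(records)} corpus molecules pass the hit filter")
if len(hits):
    print(hits[["smiles", "qed", "sa", "affinity"]].head().to_string(index=False))

# treat the first ten corpus members as "known binders"
count, pairs = binder_similarity_count(corpus[10:], corpus[:10], threshold=0.6)
print(f"\n{count} of {len(corpus) - 10} other molecules are similar "
      f"(Tanimoto > 0.6) to a reference binder; {len(pairs)} matched pair(s)")
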