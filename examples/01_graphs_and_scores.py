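"""Parse a molecule, inspect its graph features, and score its rewards.

The reward breakdown shows the three scaled property rewards (QED,
SAScore, predicted affinity), the three penalty factors, and the final
scalar R_final = (R_qed + R_sa + R_aff) · P_complexity · P_property · P_similarity.
"""

from molrl import (
    bond_slices,
    encode_atoms,
    final_reward,
    parse_smiles,
    surrogate_affinity,
    to_canonical,
)

aspirin = parse_smiles("CC(=O)Oc1ccccc1C(=O)O")
print("canonical:", to_canonical(aspirin))
print("heavy atoms:", aspirin.n_atoms, "bonds:", len(aspirin.bonds))

X = encode_atoms(aspirin)
print("atom feature matrix:", X.shape, "(element + degree + ring-size bits)")
slices = bond_slices(aspirin)
print("bond-order slices carry",
      [int(r.sum() // 2) for r in slices.raw], "edges (single/double/triple)")

bd = final_reward(aspirin, surrogate_affinity)
print(f"\nQED {bd.qed:.3f}  SAScore {bd.sa:.2f}  affinity {bd.affinity:.2f} pK")
print(f"scaled rewards: R_qed {bd.r_qed:.3f}  R_sa {bd.r_sa:.3f}  R_aff {bd.r_aff:.3f}")
print(f"penalties: complexity {bd.p_complexity:.3f}  property {bd.p_property:.3f} "
      f" similarity {bd.p_similarity:.3f}")
print(f"final reward: {bd.r_final:.3f}  (max 3.0 with unit weights)")
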