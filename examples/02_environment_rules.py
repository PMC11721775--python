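"""Step through the generation environment and trigger its chemical rules.

Every agent action is checked against a valency table and four
structural-alert classes; rejected actions leave the molecule unchanged
and cost -0.2, while ring-closing bonds earn +0.02.
"""

from molrl import Action, apply_action, initial_state, to_canonical

# grow a hexane chain in depth-first mode, then close the ring
st = initial_state("dfm")
for _ in range(5):
    st, out = apply_action(st, Action(end="C", order=1))
    print(f"add C   -> accepted={out.accepted} reward={out.step_reward:+.2f} "
          f"molecule={to_canonical(st.graph)}")

st, out = apply_action(st, Action(end=0, order=1))  # bond back to atom 0
print(f"close ring -> accepted={out.accepted} reward={out.step_reward:+.2f} "
      f"molecule={to_canonical(st.graph)}  (+0.02 ring bonus)")

# now try to violate the rules: an O-O (peroxyl) bond
st, out = apply_action(st, Action(finish=True))
st, out = apply_action(st, Action(end="O", order=1))
st, out = apply_action(st, Action(end="O", order=1))
print(f"\nattempt O-O bond -> accepted={out.accepted} "
      f"violation class={out.violation!r} reward={out.step_reward:+.2f}")
print("molecule unchanged:", to_canonical(st.graph))
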