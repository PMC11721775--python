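# Methods

This note documents the modelling choices, defaults and limitations of
`molrl`, in the spirit of a model-description appendix.

## State, action and dynamics

A generation state is a partial heavy-atom molecular graph with kekulé
bond orders plus traversal bookkeeping (focus pointer, finished marks,
step counter). Episodes start from a single carbon atom. An action either
adds a bond — to an existing atom (closing a ring) or to a fresh atom
appended and bonded in the same move — or terminates: STOP in gcpn mode,
a finish-mark on the focus atom in dfm/bfm mode. Fresh-atom slots exist
for each element of the vocabulary (C, N, O, S, F, Cl, Br, I, P — the
drug-like heavy-atom set).

Internally graphs are kekulized; the three adjacency slices are bond
orders 1/2/3 with aromatic systems represented by their kekulé orders,
since a bond-order partition admits no aromatic slice. Aromaticity is
re-perceived (RDKit sanitization) for scoring, canonicalization and the
structural-alert checks. Everything is two-dimensional: no conformers,
stereo-annotations, charges, isotopes or explicit hydrogens.

**Valency rule.** A bond is legal iff the summed bond orders at both
endpoints stay within C 4, N 3, O 2, S 6, P 5, halogens 1. The agent's
action masks encode this rule, so sampled actions are always
valency-legal; the structural alerts below are enforced at execution
time instead (a rejection costs −0.2 and is itself a learning signal).

**Structural alerts.** After each action the hypothetical post-action
graph is screened, in order:

* (a) cumulated double bonds, SMARTS `[*]=[!#16;!#15]=[*]` — hypervalent
  S/P centers are excluded so sulfones, sulfonamides and phosphates
  (ubiquitous drug-like chemistry) do not trip the alert — and any O–O
  bond (`[#8]~[#8]`, generalizing peroxides);
* (b) double or triple bonds inside 3- or 4-membered SSSR rings
  (evaluated on kekulé orders);
* (c) bridged ring systems involving an aromatic ring: two SSSR rings
  sharing ≥ 3 atoms with either ring aromatic after re-perception (not
  robustly SMARTS-expressible, hence code);
* (d) any SSSR ring with ≥ 8 members.

The class-(a) SMARTS live in an editable module-level table
(`environment.ALERT_SMARTS`). They are best-effort defaults: reasonable
people can disagree about hetero-cumulenes (isocyanates, azides); the
shipped pattern flags them, and projects needing different chemistry can
override the table.

**Rejection semantics.** A rejected action never mutates the working
graph and does not end the episode; the agent may retry (the −0.2 penalty
is the deterrent). Episodes are capped at 100 actions by default — a
40-heavy-atom molecule needs at most ~80 bond actions even with rings —
and a capped dfm/bfm episode is scored like any other (its molecule is
valid by construction, merely unfinished by choice; the `completed` flag
records this).

**Ring-closure detection** is connectivity-based: the working graph stays
connected, so any accepted bond between two existing atoms closes a
cycle and earns the +0.02 bonus.

## Policy and value networks

Atom features (20 = 9 element + 6 degree + 5 ring-size bits; the printed
total fixes only the sum, this split is the natural reading) are
linearly embedded to 64 dimensions and refined by three GCN modules,
each summing per-slice rectified convolutions with symmetric
normalization. The graph-level context is the mean-pooled node embedding
(sum pooling is a config switch). Heads are two-layer perceptrons
(hidden 64): a gate head (STOP or finish), a focus head (gcpn only), a
pair-scoring end-atom head on concatenated (focus, candidate)
embeddings — fresh-atom slots scored from learned per-element
embeddings — and a 3-way bond-order head. The value head maps the pooled
context to a scalar.

Composite action probabilities multiply the sub-task probabilities, with
the gate distributing mass between terminating and bonding; masks
(illegal valences, finished atoms) zero probabilities before
normalization, so the distribution always sums to 1 over the legal set.
Gradients flow through a small in-package reverse-mode autodiff over
float64 numpy; analytic gradients match central finite differences to
1e-4 relative in the tests. Initialization is uniform Glorot-style,
seed-controlled; sampling temperature is 1 during training with greedy
argmax decoding available.

## Expert pre-training

Training molecules are filtered to drop any containing an SSSR ring of
≥ 8 members. For dfm/bfm, each molecule is converted to an expert
trajectory by traversing its graph from a random start atom with the
environment's own focus discipline; neighbor visit order is randomized
per step. Ring-closing bonds are emitted as soon as they become
available at the focus, smallest resulting ring first — postponing a
closure in a fused system would transiently create an over-large
perimeter ring that the environment rejects, and this ordering is what
makes replay soundness (zero rejections on every corpus molecule for
every seed) hold. An atom is finish-marked once all its target-graph
bonds exist. For gcpn, a random connected partial graph (random-walk
edge growth from a uniform start, uniform edge-count target) is the
state and every single-bond extension within the target is an expert
action (both focus orientations for internal bonds; STOP when the graph
is complete). The loss is the mean negative log composite probability of
expert actions, minimized with Adam (desk default: 5,000 steps, batch
32, lr 1e-4; the reference setting for this family of models is on the
order of 10^6 steps).

## PPO

Returns are discounted reward-to-go with the final reward attached to
the terminal step (γ = 0.98); advantages subtract the value baseline
(optional batch normalization, off by default). The clipped surrogate
(ε = 0.1) is minimized jointly with a 0.5-weighted squared-error value
regression; 4 epochs of minibatch-64 Adam (lr 1e-4) per round by
default. Epoch count, learning rate, episode cap and round sizes are all
config — the epochs/minibatch/lr defaults are conventional, not
prescribed by the model. No entropy bonus by default; the flag uses the
single-sample estimator E[−log p(a)], whose value (not its gradient
estimator) is the policy entropy. Parallel roll-out is a contract
(independent per-worker episode streams, deterministic merge), not a
mechanism; the implementation is single-process.

## Memory stack and similarity penalty

Molecules whose unpenalized reward Σ α_i R_i exceeds 70% of the
attainable maximum are admitted to the stack at the end of their round,
halogen-stripped (so analogues differing only in halogen decoration are
treated as identical). Entries from the preceding 10 rounds form the
Tanimoto pool (2048-bit ECFP4); entries older than 20 rounds migrate to
a FIFO-capped (10^6) exact-match mapping archive. The two windows are
disjoint — entries aged 11–20 rounds are dormant — a deliberate
resolution of an underdetermined boundary. The penalty is 0 on a mapping
hit or at Tanimoto ≥ 0.7, 1 at ≤ 0.4, linear between.

## Complexity penalty direction

The size penalty is a *descending* ramp: 1.0 at ≤ 10 heavy atoms, 0.0 at
≥ 40. Its stated purpose is to counter the size bias of learned affinity
predictors (larger molecules score higher), which an ascending ramp
would amplify rather than counter; the descending ramp creates the
intended mid-size optimum once combined with the size-increasing
affinity reward. The direction is a config switch for experiments.

## Surrogate affinity predictor

The external GNN affinity scorer is out of scope and abstracted behind
`AffinityPredictor = Callable[[MolGraph], float]` (pK units). The
shipped surrogate is deliberately synthetic:

```
pK(g) = 4 + 5 σ(0.08 (n_heavy − 20) + 0.3 z(g))
```

with z a hash-derived pseudo-pharmacophore term in [−1, 1], deterministic
per halogen-stripped canonical form. It is bounded in (4, 9), strictly
increasing in size at fixed z (reproducing the documented size bias),
and its constants were chosen so that random-policy molecules mapped
through the 5.5/8.5 bounds land at R_aff ≈ 0.2–0.5 — non-degenerate, with
headroom for RL improvement. It emulates nothing about real binding.

## Synthetic fixtures: what they do and do not show

The fixture corpus is 53 hand-curated, neutral, real drug molecules
(aspirin included) spanning both sides of the QED = 0.6 hit threshold and
passing every environment rule. It exercises parsing, featurization,
trajectories, scoring and metrics offline, but it is ~4 orders of
magnitude smaller than a real training corpus: pre-training on it shows
convergence behaviour, not chemistry coverage. Likewise the desk-scale
learning smoke test (pretrain 400 steps; 3 seeds × 30 rounds × 50
episodes, 32-step cap, 1 PPO epoch, lr 1e-3 — sized to minutes on one
CPU) demonstrates that the reward machinery produces a learnable signal;
it says nothing about the chemical quality reachable at production
scale, where runs of hundreds of rounds × thousands of episodes with a
trained GNN scorer are the relevant regime.

## Numerical and degenerate-input choices

* Property scaling: inverted bounds (low > high) mirror the ramp;
  `low == high` is rejected at construction. Non-finite property values
  raise.
* Tanimoto of two all-zero fingerprints is defined as 1.0 (identical
  empty environments).
* Acyclic molecules have an empty Murcko scaffold; all empty scaffolds
  pool into a single scaffold class in the metrics.
* Potential stereocenters (assigned + unassigned) are counted, since
  generated graphs carry no stereo annotations.
* "Completeness" of a batch = fraction of episodes terminated by the
  policy's own choice (all atoms finished / STOP) rather than by the
  step cap. This operationalizes an otherwise informal notion and
  surfaces the breadth-first mode's tendency to terminate prematurely or
  leave rings unclosed.
* Checkpoints are versioned npz archives keyed by a config hash;
  load/save round-trips bit-exact.
* All randomness flows from explicit integer seeds; identical seed +
  config reproduces pretraining losses, generated molecules and round
  reports exactly (single-process).

## Known limitations

* No charged species, tautomers, stereochemistry or 3-D structure.
* The alert patterns are pragmatic defaults, not a curated med-chem
  alert library (no PAINS, no reactivity alerts).
* The autodiff is adequate for these network sizes but makes no claim to
  framework performance; production-scale training would swap in a GPU
  framework behind the same module interfaces.
* The gcpn expert-state sampler grows subgraphs by random walks — it
  covers all sizes but is not uniform over connected subgraphs (exact
  uniformity is neither needed nor attempted).
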