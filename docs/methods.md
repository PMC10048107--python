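# Methods

This note records the model, the conventions the implementation fixes where
more than one reading was possible, and what the synthetic experiments do
and do not establish.

## State and action space

A molecule under construction is an **ordered** graph: a list of heavy atoms
(element symbol, formal charge ∈ {−1, 0, +1}) plus undirected bonds of order
1–3. Aromatic input is kekulized on parsing and re-perceived on canonical
SMILES emission, so the action vocabulary never needs an "aromatic" bond.
Hydrogens are implicit throughout. Stereochemistry, isotopes and
multi-fragment SMILES are out of scope.

Three action kinds grow a graph: ADD (new atom bonded to an existing node;
the first atom of an empty graph attaches to nothing), CONNECT (ring-closing
bond between the most recently added node and an earlier one) and TERMINATE.
Action application is value-semantic and validates index ranges, duplicate
edges and valence caps; a per-(element, charge) cap table handles the common
organic cases (N⁺ 4, O⁻ 1, S up to 6, …) while RDKit sanitization remains
the final validity authority.

## Canonical deconstruction routes

Training targets come from a deterministic deconstruction of each training
molecule: nodes are visited breadth-first from the atom with the lowest
RDKit canonical rank, neighbor order broken by canonical rank; each visit
emits one ADD (bonded to the earliest-visited neighbor), extra bonds into
the visited set emit CONNECTs in visit order, and the route ends with
TERMINATE. Route length is therefore nodes + ring closures + 1, and
replaying the route reproduces the relabeled graph exactly. Any
deterministic rule would do; canonical-rank-seeded BFS keeps routes
reproducible across machines and matches the convention of the
graph-generation literature this model family descends from.

## Network

- Node features: one-hot element ⊕ one-hot charge ⊕ one-hot construction
  position. The positional channel is deliberate: route targets address
  nodes by construction index, and a purely permutation-equivariant encoder
  gives chemically equivalent nodes (e.g. both ends of a symmetric chain)
  identical embeddings, leaving an irreducible cross-entropy floor. Because
  the decoder's state genuinely is an ordered graph, position is part of the
  state, and with it single-molecule overfitting reaches near-zero loss.
- Message passing: per-bond-order SELU MLPs (depth = "GGNN depth", width =
  "GGNN width") map neighbor states to messages (size 100 by default),
  summed over neighbors and fed with the node state to a GRU update;
  3 rounds by default. "Hidden dimension" (250) is the node state size.
- Readout: gated sum over nodes — sigmoid(MLP_gate([h, x])) ⊙ MLP_out([h, x])
  — yielding the graph embedding.
- Heads: per-node SELU MLPs (depth 4, width 500 by default) emit ADD and
  CONNECT logits per node slot; graph-level MLPs emit the first-atom block
  and the terminate logit. All logits concatenate into one vector, an
  additive mask (−10³⁰) removes inapplicable actions (slots beyond the
  current size, first-atom block on non-empty graphs, CONNECT with fewer
  than two nodes, ADD at the node cap), and one softmax yields the APD.

KL divergence against the one-hot route target reduces to the cross-entropy
of the correct action; predicted probabilities are floored at 1e−12.

Default hyperparameters (the config file's defaults) are the full-scale
reference settings: Adam at 1e−4, multiplicative decay 0.99 every 10 steps
clamped to [1e−4, 1] relative, batch size 20 molecules, uniform fan-in
weight initialization, zero dropout and weight decay, node cap 13. One
optimizer step consumes one batch of molecules, with the loss averaged over
all their route steps. Route blocks are serialized as JSON-lines files
holding at most `block_size` (1000) route steps each.

The tensor engine is a minimal NumPy reverse-mode autodiff (topologically
sorted tape; broadcast-aware arithmetic, matmul, concat/pad, SELU, sigmoid,
tanh, stable log-softmax), with gradients finite-difference-checked in the
test suite.

## Sampling

Molecules grow from the empty graph by sampling the masked APD. Growth ends
on TERMINATE (properly terminated), on an inapplicable action such as a
valence violation (molecule marked invalid — this is accounting, not an
error, so validity percentages are meaningful), or on a step cap of
2·max_nodes + 16 (not properly terminated). ADD actions are masked out once
the graph holds max_nodes atoms, mirroring the route targets of
maximum-size training molecules. The sequence log-probability accumulates
the sampled actions' log masses.

## Rewards and exclusions

- **SAScore** follows the published fragment-contribution formulation:
  count-weighted mean contribution of Morgan radius-2 fragments, minus
  complexity penalties (size n^1.005 − n; log10 spiro, bridgehead and
  macrocycle terms), plus the fingerprint-density symmetry correction,
  affinely mapped and clamped to [1, 10] with logarithmic smoothing above 8.
  The stereo penalty is identically zero here (stereochemistry out of
  scope). With the published contribution table the implementation matches
  the independent reference scorer to 1e−8 on stereo-free molecules (tested).
- **NPScore**: sum of fragment contributions over unique fragments divided
  by heavy-atom count, log-compressed beyond ±4, clamped to [−5, 5];
  likewise cross-checked against the independent reference scorer.
- Contribution tables are pluggable two-column text files. The test fixtures
  calibrate a small table from the fixture set's own fragment frequencies
  (log count relative to the mean count, clipped to ±3) — the same
  frequency logic as the published calibrations, at desk scale. Unseen
  fragments default to −4 (SA) and 0 (NP), matching the published defaults.
- Reward maps: r_SA = (10 − SA)/9 ("inversely proportional" read as the
  bounded affine map, not 1/SA), r_NP = (NP + 5)/10 (the NP→reward map is
  not specified anywhere authoritative; the affine map mirrors r_SA), and
  the size reward is the indicator of 0 < nodes ≤ max_nodes, with the cap
  tied to the sampler's node cap.
- Final score: arithmetic mean of the three rewards — the only reading of
  "equal weight" that keeps scores in [0, 1]. Invalid, unterminated and
  duplicate molecules (same canonical SMILES, first kept, within the scored
  batch only) are excluded with score 0.

## Reinforcement learning

The squared-gap molecule loss
[log P(B|A) − (log P(B|ℙ) + σ·S(B))]² places the square over the whole
bracket (the augmented-likelihood family): minimization pulls the agent's
likelihood of high-scoring sequences above the reference's. σ = 20 and
α = 0.5 by default. The batch loss normalizes both the current-batch and
remembered-batch terms by the current batch size N.

Memory semantics: the best batch is the one with the highest mean final
score so far, stored with its action sequences, scores, and the snapshot of
the agent **before** the optimizer step that followed it (the parameters
that generated it). The remembered term re-scores those sequences under the
current agent against that snapshot as reference; on the first batch the
memory is the current batch with the frozen prior as its reference. The
reference model ℙ stays frozen at the chosen generative epoch throughout.
Epoch numbering continues across stages (generative 1…E, RL E+1…), and
snapshot selection minimizes UC-JSD with ties broken by higher PV, then
higher PU, then lower epoch.

Sequence likelihoods of sampled molecules are recomputed by replaying the
taken actions; a trailing inapplicable action (the move that invalidated a
molecule) is kept in the likelihood — the agent chose it — but never
applied.

## Evaluation metrics

Over a sampled set: PV = valid/total; PPT = properly-terminated/total;
PVPT = valid∧terminated / terminated; PU = unique canonical SMILES among
valid / valid (the validity-restricted denominator is the only one under
which a fully valid set with 10% repeats reads PV = 1.00, PU = 0.90).
νav averages heavy-atom counts and εav averages per-graph 2·edges/nodes,
both over valid molecules.

UC-JSD histograms the training, validation and sampled per-molecule NLL
lists on 64 shared bins spanning the pooled range (each normalized with an
additive 1e−12 floor) and returns H(mean) − mean(H) in nats — 0 for
identical lists, ln 3 for disjoint supports. Bin count and log base are
conventions fixed here for reproducibility; the metric is cited by name
only in the literature that uses it.

Score-range tables bin non-excluded molecules into unit bins ([1,2)…[9,10]
for SA, [−5,−4)…[4,5] for NP, top bin closed) as percentages summing to 100.

## Synthetic data

The fixture generator emulates a flavor database's shape: random trees over
C/N/O/S (72/10/15/3%) with occasional double bonds and one optional small
ring, 5–15 heavy atoms (mean ≈ 10 nodes, ≈ 1.85 edges per node), heteroatoms
kept non-adjacent, 1–5 descriptor labels per molecule drawn from a Zipf-like
table with "sweet" most frequent. It does **not** emulate real flavor
chemistry: no aromatic rings, esters/lactones in realistic proportions, or
descriptor–structure correlation. Tests passing on fixtures therefore
establish the correctness of the machinery (routes, losses, metrics,
reward plumbing), not chemical quality of generated molecules on real data.

## Desk-scale experiment sizes and numerical choices

The behavioural experiments use reduced sizes chosen as the package's
standard desk-scale conditions: a hidden-32/depth-2 network overfit on one
molecule for 300 steps at learning rate 5e−3 (the full-scale default 1e−4
is meant for long runs); a hidden-16 network trained 40 epochs on 10
molecules as the RL prior, fine-tuned 50 batches at 1e−3. Split sizes are
round(n·fraction) for test and validation with the remainder to train;
shuffling is a seeded uniform permutation (the split is not stratified).
Duplicate molecules merge at curation by unioning descriptor sets.

Batch mean scores over 20 molecules are quantized at 0.05, so trend
assertions on RL score climbing use non-overlapping 10-batch window means
with a one-quantum tolerance plus a required overall gain, rather than
strict monotonicity of a sliding average, which sampling noise would
violate even for a cleanly improving agent.

## Known limitations

- NumPy execution: full-scale settings (hidden 250, 1000 + 500 epochs on a
  ~900-molecule database) are architecturally supported but impractical
  without accelerator hardware; the package targets desk-scale studies.
- The positional node feature ties the encoder to construction order;
  isomorphic graphs with different node orders get different APDs by design.
- Cross-batch duplicate memory is not kept; PU and the duplicate exclusion
  are per-batch notions.
- The element vocabulary is read from the training set at preprocessing
  time; sampling can never emit an element outside it.
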