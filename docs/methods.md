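# Methods

## Problem setting

Neural decoding maps population neural activity (here, calcium-imaging
traces) to behavior labels. Overparameterized MLP/CNN decoders reach high
accuracy but are too slow for real-time, closed-loop use, so they are
*structurally pruned*: whole nodes (MLP) or filters (CNN) — *removal units*
— are deleted together with every weight that depends on them, and the
survivor is briefly retrained (fine-tuned). Pruning proceeds under two
constraints:

* a **minimum unit-count vector (MUCV, mu)** — a per-hidden-layer floor on
  surviving units; input features and output logits are never removal units;
* an **accuracy-drop tolerance T**: with `OriValAcc` the validation accuracy
  of the unpruned model, any step whose retrained validation accuracy falls
  below `ValAcc_min = OriValAcc * T` is rejected. Default `T = 0.985`.

## The multi-phase phenomenon and the jump mechanism

Greedy random-selection pruning (GRS) removes one unit at a time, retraining
and validating after every removal; the retraining dominates the cost and
scales badly with model size. Empirically the pruning trajectory has two
regimes: a **far phase** (structures still close to the overparameterized
model) where accuracy is almost insensitive to removals — redundant units
let retraining relocate the informative forward paths — and a **near phase**
(structures close to the minimal form) where single removals can destroy
accuracy irrecoverably.

Jump-GRS (JGRS) exploits this by lowering the retraining frequency where it
is safe. Define the **pruning midpoint** of a layer with `u` units and floor
`mu` as `max(floor((u - mu)/2), 1)`, and the **compression rate (CR)** as
the number of removal units eliminated between successive retrain+validate
events. The three JGRS stages are:

| stage          | action per retrain+validate                    | CR              |
|----------------|------------------------------------------------|-----------------|
| far subphase 1 | cut every layer's midpoint in one sweep        | sum of midpoints|
| far subphase 2 | one midpoint-cut candidate per layer, keep best| one midpoint    |
| near phase     | one single-unit candidate per layer, keep best | 1               |

Each stage loops until its first rejected step (or the MUCV), and each stage
is run for a configurable number of *attempts* (default 3 each), chaining on
the evolving model, to damp unlucky random cuts. `ValAcc_min` is computed
once from the input model and shared by all stages. In far subphase 1 a
16-unit layer with floor 2 walks 16 -> 9 -> 6 -> 4 -> 3 -> 2, i.e. the
whole far regime costs five retrains per layer-sweep instead of fourteen.

Counter form of the speedup: wall-clock time depends on hardware, so the
package also counts `fine_tune` invocations; on pinned-accuracy data (below)
JGRS uses ~17x fewer retrain calls than pure near-phase GRS for the
16x16x16 -> 2x2x2 task.

## Baselines

* **grs_near_phase** — the near-phase scheme run from the start: per-layer
  single-unit random candidates, greedy argmax on validation accuracy (ties
  break to the lowest layer index), until rejection or MUCV. The candidate
  structure (one random candidate per layer per round) mirrors far subphase
  2 at CR = 1; this is a documented approximation of the original GRS, whose
  exact intra-layer candidate count is not fully specified in the sources
  available to us.
* **rrs_prune_trace** — random inter-layer order, random intra-layer unit:
  at each step one single-unit candidate per layer is fine-tuned and
  validated `evals_per_structure` (default 3) times and averaged; the walk
  continues from a uniformly random candidate (carrying that candidate's
  first fine-tuned weights) until the MUCV. With tolerance 0.5 it
  effectively never stops early, which is what makes it a sensitivity probe
  rather than a pruning method.
* **nwm_prune** — natural (input-to-output) layer order, weight-magnitude
  selection: each round removes the half of the current layer's units with
  the smallest L1 incoming-weight norm (floor when odd, clamped to the
  MUCV), then fine-tunes and validates; the first rejected round stops the
  whole process. Biases are excluded from the magnitude score. Note that
  with a strict tolerance and few fine-tune epochs NWM's aggressive halving
  (CR = 8 on a 16-unit layer) is often rejected on its very first round on
  noisy decoding data — the comparison script reports this honestly as 100%
  of the initial size.

## Model substrate

No deep-learning framework is used; the substrate is a small, fully seeded
numpy implementation:

* Dense and valid-padding stride-1 conv layers (optional non-overlapping max
  pooling, ties share gradient), ReLU or tanh activations, linear softmax
  output, cross-entropy loss, mini-batch Adam (default lr 0.01, batch 128).
* Initialization: He-normal for ReLU layers, Glorot-uniform for tanh and the
  output layer; zero biases.
* **Exact surgery.** The forward pass accumulates contributions one input
  unit (or one kernel tap) at a time in a fixed order. Consequently a hidden
  unit whose outgoing weights are all zero contributes an exact +-0.0 at
  each accumulation, and deleting it leaves the logits *bitwise* unchanged —
  the core correctness oracle for `remove_units`, including the
  conv-to-dense flattening boundary (row-major (h, w, c) flattening; a
  removed filter deletes every flattened position it feeds). Gradients use
  ordinary vectorized linear algebra; they carry no bitwise contract.
* **Cost conventions.** `param_count` counts every stored weight and bias.
  `flop_count` counts a dense layer as `(2*fan_in - 1)*units` multiply-adds
  plus `units` bias additions, and a conv layer as
  `(2*kh*kw*in_channels - 1) + 1` per output position and filter; pooling
  and activations are excluded. These conventions are internal and are
  validated against brute-force recomputation, not against any external
  table.
* Training hyperparameters are not part of the pruning method; they live in
  `TrainConfig` (defaults: 30 epochs initial training, 2 fine-tune epochs).
  Fine-tuning warm-starts from the surviving weights — re-initialization
  would discard the redundancy argument that justifies the far phase.

## Synthetic data

Real calcium-imaging decoding data of this kind is distributed on request
only, so the package generates seeded surrogates that target the documented
schema and learnability, not physiological realism:

* **MSN-like traces** (`generate_msn_like`): 3000 samples at 10 Hz, `beta`
  neurons (default 114; the real recordings range 53-273 per subject). The
  behavior label is a two-state Markov chain with mean run length
  `label_persistence` (default 20 samples = 2 s bouts, since fine-motion
  bouts are contiguous in time). Informative neurons (default ~20% of
  `beta`) emit Poisson events at a state-dependent rate (defaults 0.2 Hz
  idle / 2.0 Hz active); events pass through a single-exponential calcium
  kernel (AR(1) filter, tau = 1 s — a GCaMP-like decay) plus Gaussian noise
  (sd 0.1). Uninformative neurons fire at the mean rate throughout. The
  defaults give a moderately hard, clearly decodable task (validation
  accuracy ~0.9 for a 16x16x16 MLP). What this does *not* model: spike
  correlations, drifting baselines, motion artifacts, speed as a continuous
  regressor.
* **Embedding-like vectors** (`generate_embedding_like`): 1600 balanced
  80-dimensional vectors in two unit-variance Gaussian clusters separated by
  `separation` (default 6) along a random direction; Bayes accuracy is
  `Phi(separation/2)`. With separation 10 the task is *pinned*: every
  retrained substructure scores 1.0, which isolates the algorithms'
  counter/bookkeeping behavior from data noise. The pinned batteries in the
  tests and the acceptance script use exactly this setting.
* **Planted subnetwork** (`generate_planted_subnetwork`): labels are the
  median-thresholded score `sum_k |w_k . x|` over 4 random directions in
  20-d standard-normal features. Each term needs a pair of first-layer ReLU
  units, and the score has no dominant linear component, so a width-2 first
  layer is a hard representational ceiling. This is the probe for the
  far/near-phase phenomenon: the RRS trace stays flat near the
  overparameterized side and drops sharply (typically 0.1-0.4 in mean
  validation accuracy) by the final, near-minimal step. An earlier tanh
  -teacher design was discarded because its strong linear component let
  2x2x2 students keep full accuracy and no drop appeared.
* **Splits**: uniform random 8:1:1; validation and test get `floor(n/10)`
  each, train the remainder (3000 -> 2400/300/300).

## Design choices where the design was open

* Attempts chain sequentially on the evolving model (not best-of restarts);
  a `--best-of` CLI option repeats whole runs and keeps the best result as
  the mitigation for early-stop trials. A per-phase retry default of 3 is
  used throughout.
* Greedy argmax is taken before the tolerance check; the selected candidate
  may then be rejected, ending the stage.
* Far subphase 1 restarts each sweep from the last *accepted* model, so a
  rejected sweep leaves no residue.
* RNG discipline: one master seed per run; child integer seeds (< 2^31) are
  drawn from it for each attempt's unit selection and each fine-tune's batch
  shuffling, so runs are exactly reproducible while attempts stay honestly
  random.
* Comparison metrics are signed ((G - J)/O form), so negative minima remain
  visible; summary means are clamped into [min, max] to absorb float
  summation rounding. Runtime is recorded but the portable speed measure is
  the fine-tune call counter.
* The trace CSV contains no wall-clock column; identical config + seed gives
  byte-identical traces. Runtime lives in the JSON summary only.

## Problem sizes and limitations

Default experiment sizes (60-neuron, 3000-sample datasets, 16x16x16 models,
batteries of 5-20 seeds) were chosen so a full comparison runs in minutes on
one CPU core; the algorithms themselves are size-agnostic, and an example
larger spec is provided under `examples/`. Known limitations: no recurrent
or attention architectures; no unstructured (weight-level) sparsity; no
automated MUCV search; accuracy is the only fitness signal (no calibration
or class-imbalance handling); the numpy substrate is not optimized for
GPU-scale models.
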