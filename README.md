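# jumpgrs — multi-phase structured pruning for compact neural-decoding models

Real-time neural decoding (e.g. classifying behavior from calcium-imaging
traces of dozens to hundreds of neurons) needs compact classifiers, but
compact models trained from scratch underperform. Structured pruning fixes
this: start from an overparameterized MLP/CNN, repeatedly delete whole
nodes/filters (*removal units*) and fine-tune, subject to a per-layer floor
on surviving units (the **MUCV**, mu) and an accuracy-drop tolerance
(`ValAcc_min = OriValAcc * T`, default `T = 0.985`).

Greedy random-selection pruning (**GRS**) retrains after *every* removal and
is prohibitively slow for large models. This package implements **Jump-GRS
(JGRS)**, which exploits the two-phase structure of the pruning trajectory:
far from the minimal structure, accuracy is insensitive to removals, so
retraining can be "jumped" across whole batches of cuts. With
`midpoint(lambda) = max(floor((u_lambda - mu_lambda)/2), 1)`, JGRS runs
three stages of decreasing compression rate (units cut per retrain):

1. **far subphase 1** — cut every layer's midpoint in one sweep, then one
   fine-tune + validation (CR = sum of midpoints);
2. **far subphase 2** — one midpoint-cut candidate per layer, fine-tune
   each, greedily keep the best (CR = one midpoint);
3. **near phase** — the GRS scheme itself: single-unit candidates per layer,
   greedy selection (CR = 1).

Each stage loops until its first rejected step (or the MUCV) and is retried
a configurable number of attempts (default 3). Baselines included:
`grs_near_phase` (pure GRS), `nwm_prune` (layer-by-layer weight-magnitude
halving) and `rrs_prune_trace` (random walk used to expose the far/near
phase phenomenon). Everything runs on a seeded, dependency-light numpy
substrate with exact structural surgery, plus synthetic generators that
emulate calcium-trace and graph-embedding decoding datasets. See
`docs/methods.md` for the full model and design notes.

## Worked example

```bash
jumpgrs prune --method jgrs --synthetic msn --beta 60 --seed 0 --out-dir demo
```

trains a 16x16x16 MLP on a synthetic 60-neuron calcium decoding dataset
(3000 samples, 8:1:1 split) and prunes it toward mu = 2x2x2:

```
original model: val_acc=0.8933 params=1554 flops=3008
[far1] cut=21 val_acc=0.8367 accepted=False -> 9x9x9
[far2] cut=7 val_acc=0.9067 accepted=True -> 16x16x9
[far2] cut=3 val_acc=0.8933 accepted=True -> 16x16x6
...
[near] cut=1 val_acc=0.8900 accepted=True -> 8x2x2
[near] cut=1 val_acc=0.8533 accepted=False -> 6x2x2
pruned: val_acc=0.8900 test_acc=0.8933 params=455 flops=884
```

Reading the log: each line is one retrain+validate event; `cut` is its
compression rate (21 = 7+7+7, a whole far-1 sweep; this noisy dataset
rejects it, so the far-2 stage takes over with per-layer midpoint cuts, and
the near phase finishes unit by unit). The run ends at structure 7x2x2 with
71% of parameters removed (455/1554) and validation accuracy 0.8900 >=
0.985 * 0.8933 — the tolerance contract. `demo/` contains the per-step
`trace.csv` (byte-identical across reruns with the same seed), a
`summary.json` with counts and retrain counters, and the pruned model.

Other entry points: `jumpgrs compare` (JGRS vs GRS vs NWM over a battery of
datasets, with the signed AL/FCI/PCI difference metrics and Time_ratio),
`jumpgrs phase-trace` (the 42-step RRS sensitivity trace on
planted-subnetwork data, showing the flat far phase and the late accuracy
drop), and `jumpgrs generate-data` (write the synthetic datasets to CSV).

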