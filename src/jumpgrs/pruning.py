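"""Multi-phase structured pruning: JGRS and its baselines.

The jump-GRS (JGRS) algorithm prunes a trained MLP/CNN in three stages whose
*compression rate* (CR — removal units eliminated between successive
retrain+validate events) shrinks as the model approaches its minimal
structure:

======================  ==========================================
stage                   CR
======================  ==========================================
far subphase 1          sum of per-layer pruning midpoints
far subphase 2          the processed layer's pruning midpoint
near phase (GRS)        1
======================  ==========================================

The *pruning midpoint* of a layer with ``u`` units and floor ``mu`` is
``max(floor((u - mu)/2), 1)``.  Far subphase 1 jumps across retraining by
cutting every layer's midpoint in one sweep before a single fine-tune and
validation.  Far subphase 2 builds one midpoint-cut candidate per layer,
fine-tunes each, and greedily keeps the best.  The near phase is the same
greedy candidate scheme with single-unit cuts — the retraining-intensive
regime of the original GRS algorithm.  A step is accepted only while
validation accuracy stays at or above ``val_acc_min = OriValAcc * T`` where
``T`` is the accuracy-drop tolerance.

Baselines: ``grs_near_phase`` (pure GRS, CR=1 throughout), ``rrs_prune_trace``
(random inter-layer order / random selection, used to expose the far/near
phase phenomenon), and ``nwm_prune`` (natural layer order, weight-magnitude
selection, halving each layer per round).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    COUNTERS,
    LabeledDataset,
    StructureError,
    TrainConfig,
    TrainedModel,
    ConfigurationError,
    fine_tune,
    flop_count,
    param_count,
    remove_units,
    unit_counts,
    validate,
)

__all__ = [
    "PruningConfig",
    "PruneStep",
    "PruneTrace",
    "PruneResult",
    "ToleranceContext",
    "pruning_midpoint",
    "stage_compression_rate",
    "random_cut_units",
    "far_subphase_1",
    "far_subphase_2",
    "grs_near_phase",
    "jgrs",
    "rrs_prune_trace",
    "nwm_prune",
]

DEFAULT_TOLERANCE = 0.985
DEFAULT_ATTEMPTS = (3, 3, 3)


@dataclass(frozen=True)
class PruningConfig:
    """Controls one JGRS run: the minimum unit-count vector (MUCV) ``mucv``,
    the accuracy-drop tolerance, per-stage attempt counts, the master seed,
    and the retraining hyperparameters."""

    mucv: tuple[int, ...]
    tolerance: float = DEFAULT_TOLERANCE
    attempts: tuple[int, int, int] = DEFAULT_ATTEMPTS
    seed: int = 0
    train_cfg: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        object.__setattr__(self, "mucv", tuple(int(m) for m in self.mucv))
        object.__setattr__(self, "attempts", tuple(int(a) for a in self.attempts))
        if any(m < 1 for m in self.mucv):
            raise ConfigurationError("every MUCV entry must be >= 1")
        if not 0.0 < self.tolerance <= 1.0:
            raise ConfigurationError("tolerance must lie in (0, 1]")
        if len(self.attempts) != 3 or any(a < 0 for a in self.attempts):
            raise ConfigurationError("attempts is a triple of non-negative counts")


@dataclass(frozen=True)
class ToleranceContext:
    """Accuracy floor derived once from the unpruned model:
    ``val_acc_min = ori_val_acc * tolerance``."""

    ori_val_acc: float
    val_acc_min: float


@dataclass
class PruneStep:
    stage: str                      # far1 | far2 | near | rrs | nwm
    cuts: tuple                     # ((layer, (unit indices…)), …)
    cr: int                         # removal units since previous retrain+validate
    retrained: bool
    val_acc: float
    accepted: bool
    structure: tuple                # hidden unit counts of the candidate


@dataclass
class PruneTrace:
    steps: list = field(default_factory=list)
    fine_tune_calls: int = 0
    validate_calls: int = 0
    runtime: float = 0.0

    def extend(self, other: "PruneTrace") -> None:
        self.steps.extend(other.steps)
        self.fine_tune_calls += other.fine_tune_calls
        self.validate_calls += other.validate_calls
        self.runtime += other.runtime

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.steps):
            rows.append({
                "step": i,
                "stage": s.stage,
                "layers_cut": ";".join(str(l) for l, _ in s.cuts),
                "units_cut": ";".join(
                    ",".join(str(u) for u in units) for _, units in s.cuts),
                "cr": s.cr,
                "retrained": s.retrained,
                "val_acc": s.val_acc,
                "accepted": s.accepted,
                "structure": "x".join(str(u) for u in s.structure),
            })
        return pd.DataFrame(
            rows, columns=["step", "stage", "layers_cut", "units_cut", "cr",
                           "retrained", "val_acc", "accepted", "structure"])


@dataclass
class PruneResult:
    model: TrainedModel
    accuracy: float
    n_flops: int
    n_params: int
    trace: PruneTrace


def _result(model: TrainedModel, acc: float, trace: PruneTrace) -> PruneResult:
    return PruneResult(model=model, accuracy=acc, n_flops=flop_count(model),
                       n_params=param_count(model), trace=trace)


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2 ** 31))


# ---------------------------------------------------------------------------
# CR algebra
# ---------------------------------------------------------------------------

def pruning_midpoint(unit_count: int, mu: int) -> int:
    """Half the distance from the current unit count down to the floor mu,
    clamped below at 1: ``max(floor((unit_count - mu)/2), 1)``."""
    if unit_count < 1 or mu < 1:
        raise ValueError("unit_count and mu must be >= 1")
    return max((unit_count - mu) // 2, 1)


def _prunable(counts, mucv) -> list[int]:
    return [i for i, (u, m) in enumerate(zip(counts, mucv)) if u > m]


def stage_compression_rate(stage: str, model: TrainedModel,
                           mucv, layer: int | None = None) -> int:
    """CR of one retrain+validate event in the given stage."""
    counts = unit_counts(model)
    if stage == "far1":
        return sum(pruning_midpoint(counts[i], mucv[i]) for i in _prunable(counts, mucv))
    if stage == "far2":
        if layer is None:
            raise ValueError("far2 CR is per-layer; pass layer")
        return pruning_midpoint(counts[layer], mucv[layer])
    if stage == "near":
        return 1
    raise ValueError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------
# randomized surgery
# ---------------------------------------------------------------------------

def random_cut_units(model: TrainedModel, layer: int, n: int,
                     rng: np.random.Generator) -> TrainedModel:
    """Remove ``n`` uniformly sampled (without replacement) units from one
    hidden layer.  At least one unit must survive."""
    uc = unit_counts(model)[layer]
    if n > uc - 1:
        raise StructureError(f"cannot cut {n} of {uc} units")
    idx = rng.choice(uc, size=n, replace=False)
    return remove_units(model, layer, idx)


def _random_cut_traced(model, layer, n, rng):
    uc = unit_counts(model)[layer]
    if n > uc - 1:
        raise StructureError(f"cannot cut {n} of {uc} units")
    idx = np.sort(rng.choice(uc, size=n, replace=False))
    return remove_units(model, layer, idx), tuple(int(i) for i in idx)


# ---------------------------------------------------------------------------
# far subphase 1 — one sweep cuts every layer's midpoint, then one retrain
# ---------------------------------------------------------------------------

def far_subphase_1(model: TrainedModel, train_data: LabeledDataset,
                   val_data: LabeledDataset, mucv, val_acc_min: float,
                   rng: np.random.Generator,
                   train_cfg: TrainConfig | None = None) -> PruneResult:
    train_cfg = train_cfg or TrainConfig()
    t0 = time.perf_counter()
    trace = PruneTrace()
    ori = validate(model, val_data)
    trace.validate_calls += 1
    m_start = model
    last_acc = ori
    val_acc = ori
    while val_acc >= val_acc_min:
        ims = m_start  # sweep always restarts from the last accepted model
        min_struct = True
        cuts = []
        cr = 0
        for li in _prunable(unit_counts(m_start), mucv):
            min_struct = False
            d = pruning_midpoint(unit_counts(ims)[li], mucv[li])
            ims, idx = _random_cut_traced(ims, li, d, rng)
            cuts.append((li, idx))
            cr += d
        if min_struct:
            val_acc = 0.0
            continue
        ims = fine_tune(ims, train_data, train_cfg, seed=_child_seed(rng))
        val_acc = validate(ims, val_data)
        trace.fine_tune_calls += 1
        trace.validate_calls += 1
        accepted = val_acc >= val_acc_min
        trace.steps.append(PruneStep(
            stage="far1", cuts=tuple(cuts), cr=cr, retrained=True,
            val_acc=val_acc, accepted=accepted,
            structure=tuple(unit_counts(ims))))
        if accepted:
            last_acc = val_acc
            m_start = ims
    trace.runtime = time.perf_counter() - t0
    return _result(m_start, last_acc, trace)


# ---------------------------------------------------------------------------
# far subphase 2 / near phase — per-layer candidates, greedy selection
# ---------------------------------------------------------------------------

def _greedy_rounds(stage: str, model, train_data, val_data, mucv, val_acc_min,
                   rng, train_cfg, cut_size) -> PruneResult:
    """Shared control flow of far subphase 2 (midpoint cuts) and the near
    phase (single-unit cuts): build one candidate per prunable layer,
    fine-tune and validate each, keep the best while it clears the floor.
    Ties break toward the lowest layer index."""
    t0 = time.perf_counter()
    trace = PruneTrace()
    ori = validate(model, val_data)
    trace.validate_calls += 1
    m_start = model
    last_acc = ori
    max_acc = ori
    while max_acc >= val_acc_min:
        candidates = []
        for li in _prunable(unit_counts(m_start), mucv):
            d = cut_size(unit_counts(m_start)[li], mucv[li])
            cand, idx = _random_cut_traced(m_start, li, d, rng)
            cand = fine_tune(cand, train_data, train_cfg, seed=_child_seed(rng))
            acc = validate(cand, val_data)
            trace.fine_tune_calls += 1
            trace.validate_calls += 1
            candidates.append((li, idx, d, cand, acc))
        if not candidates:
            max_acc = 0.0
            continue
        accs = [c[4] for c in candidates]
        best = int(np.argmax(accs))  # first index wins ties
        li, idx, d, cand, max_acc = candidates[best]
        accepted = max_acc >= val_acc_min
        trace.steps.append(PruneStep(
            stage=stage, cuts=((li, idx),), cr=d, retrained=True,
            val_acc=max_acc, accepted=accepted,
            structure=tuple(unit_counts(cand))))
        if accepted:
            last_acc = max_acc
            m_start = cand
    trace.runtime = time.perf_counter() - t0
    return _result(m_start, last_acc, trace)


def far_subphase_2(model, train_data, val_data, mucv, val_acc_min, rng,
                   train_cfg: TrainConfig | None = None) -> PruneResult:
    return _greedy_rounds("far2", model, train_data, val_data, mucv,
                          val_acc_min, rng, train_cfg or TrainConfig(),
                          cut_size=pruning_midpoint)


def grs_near_phase(model, train_data, val_data, mucv, val_acc_min, rng,
                   train_cfg: TrainConfig | None = None) -> PruneResult:
    """The retraining-intensive GRS scheme: randomized single-unit
    candidates per layer, greedy selection, CR = 1."""
    return _greedy_rounds("near", model, train_data, val_data, mucv,
                          val_acc_min, rng, train_cfg or TrainConfig(),
                          cut_size=lambda u, m: 1)


# ---------------------------------------------------------------------------
# the JGRS driver
# ---------------------------------------------------------------------------

def jgrs(model: TrainedModel, train_data: LabeledDataset,
         val_data: LabeledDataset, cfg: PruningConfig) -> PruneResult:
    """Run the three JGRS stages in sequence, each for its configured number
    of attempts, chaining every attempt on the current pruned model.

    The accuracy floor ``val_acc_min = validate(M) * tolerance`` is computed
    once from the input model and shared by every stage.
    """
    if len(cfg.mucv) != model.spec.n_hidden:
        raise ConfigurationError("MUCV length must match the hidden layer count")
    rng = np.random.default_rng(cfg.seed)
    t0 = time.perf_counter()
    trace = PruneTrace()
    acc0 = validate(model, val_data)
    trace.validate_calls += 1
    val_acc_min = acc0 * cfg.tolerance
    cur, acc = model, acc0
    stages = (far_subphase_1, far_subphase_2, grs_near_phase)
    for stage_fn, n_attempts in zip(stages, cfg.attempts):
        for _ in range(n_attempts):
            res = stage_fn(cur, train_data, val_data, cfg.mucv, val_acc_min,
                           np.random.default_rng(_child_seed(rng)), cfg.train_cfg)
            cur, acc = res.model, res.accuracy
            trace.extend(res.trace)
    trace.runtime = time.perf_counter() - t0
    return _result(cur, acc, trace)


def tolerance_context(model: TrainedModel, val_data: LabeledDataset,
                      tolerance: float) -> ToleranceContext:
    ori = validate(model, val_data)
    return ToleranceContext(ori_val_acc=ori, val_acc_min=ori * tolerance)


# ---------------------------------------------------------------------------
# RRS — the sensitivity probe exposing the far/near phase phenomenon
# ---------------------------------------------------------------------------

@dataclass
class RRSStep:
    step: int
    structure: tuple            # hidden unit counts before this removal
    candidate_layers: tuple
    candidate_val_accs: tuple   # per-candidate mean over evals_per_structure
    mean_val_acc: float
    mean_test_acc: float | None
    chosen_layer: int


def rrs_prune_trace(model, train_data, val_data, mucv, tolerance: float = 0.5,
                    rng: np.random.Generator | None = None,
                    evals_per_structure: int = 3,
                    train_cfg: TrainConfig | None = None,
                    test_data: LabeledDataset | None = None) -> list[RRSStep]:
    """Random inter-layer order / random intra-layer selection walk.

    At every step one single-unit-removal candidate is built per prunable
    layer; each candidate is fine-tuned and validated ``evals_per_structure``
    times (averaged to damp retraining randomness).  The walk then continues
    from a uniformly random candidate until the MUCV is reached, or until the
    chosen candidate's mean accuracy falls below ``OriValAcc * tolerance``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    train_cfg = train_cfg or TrainConfig()
    ori = validate(model, val_data)
    val_acc_min = ori * tolerance
    cur = model
    steps: list[RRSStep] = []
    step = 0
    while _prunable(unit_counts(cur), mucv):
        cands = []
        for li in _prunable(unit_counts(cur), mucv):
            cand, _ = _random_cut_traced(cur, li, 1, rng)
            vaccs, taccs, tuned = [], [], None
            for _ in range(evals_per_structure):
                ft = fine_tune(cand, train_data, train_cfg, seed=_child_seed(rng))
                tuned = tuned if tuned is not None else ft
                vaccs.append(validate(ft, val_data))
                if test_data is not None:
                    taccs.append(validate(ft, test_data))
            cands.append((li, tuned, float(np.mean(vaccs)),
                          float(np.mean(taccs)) if taccs else None))
        chosen = int(rng.integers(len(cands)))
        li, tuned, vacc, _ = cands[chosen]
        steps.append(RRSStep(
            step=step,
            structure=tuple(unit_counts(cur)),
            candidate_layers=tuple(c[0] for c in cands),
            candidate_val_accs=tuple(c[2] for c in cands),
            mean_val_acc=float(np.mean([c[2] for c in cands])),
            mean_test_acc=(float(np.mean([c[3] for c in cands]))
                           if test_data is not None else None),
            chosen_layer=li,
        ))
        cur = tuned  # continue from the chosen candidate's fine-tuned weights
        step += 1
        if vacc < val_acc_min:
            break
    return steps


def rrs_trace_to_dataframe(steps: list[RRSStep]) -> pd.DataFrame:
    return pd.DataFrame([{
        "step": s.step,
        "structure": "x".join(str(u) for u in s.structure),
        "mean_val_acc": s.mean_val_acc,
        "mean_test_acc": s.mean_test_acc,
        "chosen_layer": s.chosen_layer,
    } for s in steps])


# ---------------------------------------------------------------------------
# NWM — natural layer order, weight-magnitude halving
# ---------------------------------------------------------------------------

def _incoming_l1(model: TrainedModel, layer: int) -> np.ndarray:
    W = model.weights[layer]["W"]
    if model.spec.hidden_layers[layer].layer_kind == "dense":
        return np.abs(W).sum(axis=0)
    return np.abs(W).sum(axis=(0, 1, 2))


def nwm_prune(model, train_data, val_data, mucv, val_acc_min,
              train_cfg: TrainConfig | None = None,
              rng: np.random.Generator | None = None) -> PruneResult:
    """Magnitude baseline: visit hidden layers input-to-output; each round
    removes the half of the layer's units with smallest L1 incoming-weight
    norm (floor when odd, clamped to the MUCV floor), then fine-tunes and
    validates.  The whole process stops at the first rejected round."""
    train_cfg = train_cfg or TrainConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    t0 = time.perf_counter()
    trace = PruneTrace()
    ori = validate(model, val_data)
    trace.validate_calls += 1
    cur = model
    last_acc = ori
    for li in range(model.spec.n_hidden):
        while True:
            uc = unit_counts(cur)[li]
            n_cut = min(uc // 2, uc - mucv[li])
            if n_cut < 1:
                break
            order = np.argsort(_incoming_l1(cur, li), kind="stable")
            idx = tuple(int(i) for i in np.sort(order[:n_cut]))
            cand = remove_units(cur, li, idx)
            cand = fine_tune(cand, train_data, train_cfg, seed=_child_seed(rng))
            acc = validate(cand, val_data)
            trace.fine_tune_calls += 1
            trace.validate_calls += 1
            accepted = acc >= val_acc_min
            trace.steps.append(PruneStep(
                stage="nwm", cuts=((li, idx),), cr=n_cut, retrained=True,
                val_acc=acc, accepted=accepted,
                structure=tuple(unit_counts(cand))))
            if not accepted:
                trace.runtime = time.perf_counter() - t0
                return _result(cur, last_acc, trace)
            cur, last_acc = cand, acc
    trace.runtime = time.perf_counter() - t0
    return _result(cur, last_acc, trace)
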