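"""JGRS stages, baselines, and their bookkeeping contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jumpgrs as jg
from jumpgrs.pruning import rrs_trace_to_dataframe

from conftest import FAST_CFG, make_pinned_split


# ---------------------------------------------------------------------------
# midpoint / CR algebra
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("uc,mu,expected", [
    (16, 2, 7), (3, 2, 1), (2, 2, 1), (273, 2, 135), (9, 2, 3),
])
def test_pruning_midpoint_values(uc, mu, expected):
    assert jg.pruning_midpoint(uc, mu) == expected


@given(st.integers(1, 500), st.integers(1, 500))
@settings(max_examples=200, deadline=None)
def test_pruning_midpoint_properties(uc, mu):
    m = jg.pruning_midpoint(uc, mu)
    assert m >= 1
    # never overshoots: cutting m units keeps at least mu units when uc > mu+1
    if uc > mu + 1:
        assert uc - m >= mu


def test_stage_compression_rates(pinned_model):
    mucv = (2, 2, 2)
    assert jg.stage_compression_rate("far1", pinned_model, mucv) == 21
    assert jg.stage_compression_rate("near", pinned_model, mucv) == 1
    nine = jg.remove_units(pinned_model, 1, range(7))  # 16 -> 9 units
    assert jg.stage_compression_rate("far2", nine, mucv, layer=1) == 3
    with pytest.raises(ValueError):
        jg.stage_compression_rate("far2", pinned_model, mucv)


# ---------------------------------------------------------------------------
# randomized surgery
# ---------------------------------------------------------------------------

def test_random_cut_units_seeded_and_bounded():
    model = jg.build_model(jg.mlp_spec(6, [8, 8]), 0)
    a = jg.random_cut_units(model, 0, 3, np.random.default_rng(5))
    b = jg.random_cut_units(model, 0, 3, np.random.default_rng(5))
    assert jg.unit_counts(a) == [5, 8]
    for wa, wb in zip(a.weights, b.weights):
        assert np.array_equal(wa["W"], wb["W"])
    with pytest.raises(jg.StructureError):
        jg.random_cut_units(model, 0, 8, np.random.default_rng(0))


def test_random_cut_is_uniform():
    """Over 10000 single-unit cuts from a 4-unit layer, each unit should be
    selected ~2500 times (binomial tolerance)."""
    model = jg.build_model(jg.mlp_spec(3, [4]), 0)
    model.weights[0]["b"][:] = np.arange(4.0)  # tag units via their biases
    rng = np.random.default_rng(123)
    counts = np.zeros(4, dtype=int)
    for _ in range(10_000):
        cut = jg.random_cut_units(model, 0, 1, rng)
        removed = set(range(4)) - set(int(b) for b in cut.weights[0]["b"])
        counts[removed.pop()] += 1
    assert counts.sum() == 10_000
    assert np.all(np.abs(counts - 2500) <= 150)


# ---------------------------------------------------------------------------
# far subphase 1
# ---------------------------------------------------------------------------

def test_far1_pinned_width_sequence(pinned_model, pinned_split):
    """With accuracy pinned at 1.0, the sweep widths follow the midpoint
    recursion 16 -> 9 -> 6 -> 4 -> 3 -> 2, one fine-tune per sweep."""
    train_d, val_d, _ = pinned_split
    res = jg.far_subphase_1(pinned_model, train_d, val_d, (2, 2, 2), 0.985,
                            np.random.default_rng(0), FAST_CFG)
    widths = [s.structure for s in res.trace.steps]
    assert widths == [(9, 9, 9), (6, 6, 6), (4, 4, 4), (3, 3, 3), (2, 2, 2)]
    assert all(s.accepted for s in res.trace.steps)
    assert [s.cr for s in res.trace.steps] == [21, 9, 6, 3, 3]
    assert res.trace.fine_tune_calls == len(res.trace.steps) == 5
    assert jg.unit_counts(res.model) == [2, 2, 2]
    assert res.accuracy >= 0.985


def test_far1_rejected_sweep_returns_input(msn_model, msn_split):
    """An unreachable accuracy floor plus no retraining rejects the first
    sweep, so the input model comes back untouched with its own accuracy."""
    train_d, val_d, _ = msn_split
    cfg = jg.TrainConfig(epochs=5, fine_tune_epochs=0, seed=0)
    ori = jg.validate(msn_model, val_d)
    res = jg.far_subphase_1(msn_model, train_d, val_d, (2, 2, 2), ori,
                            np.random.default_rng(3), cfg)
    if res.trace.steps and not res.trace.steps[0].accepted:
        assert jg.unit_counts(res.model) == [16, 16, 16]
        assert res.accuracy == ori
        for wa, wb in zip(res.model.weights, msn_model.weights):
            assert np.array_equal(wa["W"], wb["W"])


# ---------------------------------------------------------------------------
# far subphase 2 and the near phase
# ---------------------------------------------------------------------------

def test_far2_at_minimum_structure_is_identity(pinned_model, pinned_split):
    train_d, val_d, _ = pinned_split
    mucv = tuple(jg.unit_counts(pinned_model))  # already minimal
    res = jg.far_subphase_2(pinned_model, train_d, val_d, mucv, 0.5,
                            np.random.default_rng(0), FAST_CFG)
    assert res.model.spec == pinned_model.spec
    assert res.trace.fine_tune_calls == 0
    assert res.accuracy == 1.0


def test_far2_pinned_reduces_one_layer_per_round(pinned_model, pinned_split):
    train_d, val_d, _ = pinned_split
    res = jg.far_subphase_2(pinned_model, train_d, val_d, (2, 2, 2), 0.985,
                            np.random.default_rng(0), FAST_CFG)
    prev = [16, 16, 16]
    retrains = 0
    for step in res.trace.steps:
        if not step.accepted:
            break
        (layer, idx), = step.cuts
        expected_cut = jg.pruning_midpoint(prev[layer], 2)
        assert len(idx) == expected_cut == step.cr
        retrains += sum(1 for u, m in zip(prev, (2, 2, 2)) if u > m)
        prev[layer] -= expected_cut
        assert list(step.structure) == prev
    assert jg.unit_counts(res.model) == [2, 2, 2]
    assert res.trace.fine_tune_calls >= retrains


def test_near_phase_single_unit_steps(pinned_split):
    train_d, val_d, _ = pinned_split
    spec = jg.mlp_spec(20, [3, 2, 2], activation="tanh")
    model = jg.train(jg.build_model(spec, 0), train_d, FAST_CFG)
    res = jg.grs_near_phase(model, train_d, val_d, (2, 2, 2), 0.985,
                            np.random.default_rng(0), FAST_CFG)
    accepted = [s for s in res.trace.steps if s.accepted]
    assert len(accepted) == 1 and accepted[0].cr == 1
    assert jg.unit_counts(res.model) == [2, 2, 2]


def test_near_phase_decrements_by_one(pinned_model, pinned_split):
    train_d, val_d, _ = pinned_split
    res = jg.grs_near_phase(pinned_model, train_d, val_d, (10, 10, 10), 0.985,
                            np.random.default_rng(0), FAST_CFG)
    total = 48
    for step in res.trace.steps:
        if step.accepted:
            total -= 1
            assert sum(step.structure) == total


# ---------------------------------------------------------------------------
# the JGRS driver
# ---------------------------------------------------------------------------

def test_jgrs_zero_attempts_is_identity(msn_model, msn_split):
    train_d, val_d, _ = msn_split
    ori = jg.validate(msn_model, val_d)
    cfg = jg.PruningConfig(mucv=(2, 2, 2), attempts=(0, 0, 0), seed=0,
                           train_cfg=FAST_CFG)
    res = jg.jgrs(msn_model, train_d, val_d, cfg)
    assert res.model.spec == msn_model.spec
    assert res.accuracy == ori
    assert res.trace.fine_tune_calls == 0


def test_jgrs_mucv_length_checked(msn_model, msn_split):
    train_d, val_d, _ = msn_split
    with pytest.raises(jg.ConfigurationError):
        jg.jgrs(msn_model, train_d, val_d,
                jg.PruningConfig(mucv=(2, 2), train_cfg=FAST_CFG))


def test_jgrs_contracts_on_decoding_data(msn_model, msn_split):
    """MUCV floor and tolerance floor hold on calcium-like decoding data."""
    train_d, val_d, _ = msn_split
    ori = jg.validate(msn_model, val_d)
    for seed in range(3):
        cfg = jg.PruningConfig(mucv=(2, 2, 2), seed=seed, train_cfg=FAST_CFG)
        res = jg.jgrs(msn_model, train_d, val_d, cfg)
        assert all(u >= 2 for u in jg.unit_counts(res.model))
        if any(s.accepted for s in res.trace.steps):
            assert res.accuracy >= ori * 0.985
        # accepted structures shrink monotonically
        sizes = [sum(s.structure) for s in res.trace.steps if s.accepted]
        assert sizes == sorted(sizes, reverse=True)


def test_jgrs_runs_on_cnn(pinned_split):
    """The full pipeline also operates on conv models (filters as removal
    units), driving them to the MUCV on pinned data."""
    train_d, val_d, _ = pinned_split
    spec = jg.ModelSpec(
        kind="cnn", input_shape=(1, 5, 4),
        hidden_layers=(jg.LayerSpec("conv", 4, kernel=(2, 2), activation="tanh"),
                       jg.LayerSpec("dense", 6, activation="tanh")),
        num_classes=2)
    imgs = jg.LabeledDataset(train_d.X.reshape(-1, 1, 5, 4), train_d.y)
    val = jg.LabeledDataset(val_d.X.reshape(-1, 1, 5, 4), val_d.y)
    model = jg.train(jg.build_model(spec, 0), imgs, FAST_CFG)
    res = jg.jgrs(model, imgs, val, jg.PruningConfig(
        mucv=(2, 2), seed=0, train_cfg=FAST_CFG))
    assert all(u >= m for u, m in zip(jg.unit_counts(res.model), (2, 2)))
    assert res.n_params < jg.param_count(model)


# ---------------------------------------------------------------------------
# RRS
# ---------------------------------------------------------------------------

def test_rrs_trace_walks_to_mucv():
    train_d, val_d, test_d = make_pinned_split(n=400, dim=8, seed=2)
    model = jg.train(jg.build_model(jg.mlp_spec(8, [4, 4], activation="tanh"), 0),
                     train_d, FAST_CFG)
    steps = jg.rrs_prune_trace(model, train_d, val_d, (2, 2), tolerance=0.5,
                               rng=np.random.default_rng(0),
                               evals_per_structure=2, train_cfg=FAST_CFG,
                               test_data=test_d)
    assert len(steps) == 4  # (4-2) + (4-2) single-unit removals
    assert steps[0].structure == (4, 4)
    df = rrs_trace_to_dataframe(steps)
    assert df["mean_val_acc"].between(0, 1).all()
    assert df["mean_test_acc"].between(0, 1).all()


# ---------------------------------------------------------------------------
# NWM
# ---------------------------------------------------------------------------

def test_nwm_halves_layers_in_order(pinned_model, pinned_split):
    train_d, val_d, _ = pinned_split
    res = jg.nwm_prune(pinned_model, train_d, val_d, (2, 2, 2), 0.985,
                       FAST_CFG, np.random.default_rng(0))
    layer0 = [s.structure[0] for s in res.trace.steps if s.cuts[0][0] == 0]
    assert layer0[:3] == [8, 4, 2]  # halving rounds 16 -> 8 -> 4 -> 2
    first = res.trace.steps[0]
    assert first.structure == (8, 16, 16) and first.cr == 8
    if all(s.accepted for s in res.trace.steps):
        assert jg.unit_counts(res.model) == [2, 2, 2]


def test_nwm_cuts_smallest_magnitude_units(msn_split):
    train_d, val_d, _ = msn_split
    model = jg.build_model(jg.mlp_spec(60, [16, 16]), 0)
    model.weights[0]["W"][:, 5] = 0.0  # unit 5 has zero incoming weights
    res = jg.nwm_prune(model, train_d, val_d, (2, 2), 0.0,
                       jg.TrainConfig(epochs=1, fine_tune_epochs=0, seed=0),
                       np.random.default_rng(0))
    (layer, idx), = res.trace.steps[0].cuts
    assert layer == 0 and 5 in idx and len(idx) == 8
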