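import numpy as np
import pytest

import jumpgrs as jg

FAST_CFG = jg.TrainConfig(epochs=30, fine_tune_epochs=2, seed=0)


@pytest.fixture
def fast_cfg():
    return FAST_CFG


def make_pinned_split(n=1000, dim=20, separation=10.0, seed=0):
    """A trivially learnable two-cluster task: any reasonable decoder scores
    1.0 on it, which pins validation accuracy during pruning."""
    data = jg.generate_embedding_like(n=n, dim=dim, separation=separation,
                                      seed=seed).to_labeled()
    sp = jg.split_8_1_1(data.n, seed=seed)
    return data.subset(sp.train), data.subset(sp.validation), data.subset(sp.test)


@pytest.fixture(scope="session")
def pinned_split():
    return make_pinned_split()


@pytest.fixture(scope="session")
def pinned_model(pinned_split):
    """A 16x16x16 tanh MLP trained to 1.0 validation accuracy."""
    train_d, val_d, _ = pinned_split
    spec = jg.mlp_spec(20, [16, 16, 16], activation="tanh")
    model = jg.train(jg.build_model(spec, seed=0), train_d, FAST_CFG)
    assert jg.validate(model, val_d) == 1.0
    return model


@pytest.fixture(scope="session")
def msn_split():
    params = jg.MSNGenParams(beta=60, n_informative=12, seed=0)
    data = jg.generate_msn_like(params).to_labeled()
    sp = jg.split_8_1_1(data.n, seed=0)
    return data.subset(sp.train), data.subset(sp.validation), data.subset(sp.test)


@pytest.fixture(scope="session")
def msn_model(msn_split):
    train_d, _, _ = msn_split
    spec = jg.mlp_spec(60, [16, 16, 16])
    return jg.train(jg.build_model(spec, seed=0), train_d, FAST_CFG)


def make_cnn_spec(dense=(6,), num_classes=3):
    return jg.ModelSpec(
        kind="cnn",
        input_shape=(2, 8, 8),
        hidden_layers=(
            jg.LayerSpec("conv", 4, kernel=(3, 3), pool=2),
            jg.LayerSpec("conv", 5, kernel=(2, 2)),
            *(jg.LayerSpec("dense", u) for u in dense),
        ),
        num_classes=num_classes,
    )


@pytest.fixture
def cnn_model():
    return jg.build_model(make_cnn_spec(), seed=7)


def random_spec(rng: np.random.Generator) -> jg.ModelSpec:
    """A random valid MLP or CNN spec for count/surgery oracles."""
    if rng.random() < 0.5:
        hidden = [int(rng.integers(1, 20)) for _ in range(rng.integers(1, 4))]
        return jg.mlp_spec(int(rng.integers(1, 40)), hidden,
                           num_classes=int(rng.integers(2, 5)))
    h = w = int(rng.integers(6, 12))
    c = int(rng.integers(1, 4))
    layers = []
    cur = h
    for _ in range(int(rng.integers(1, 3))):
        k = int(rng.integers(1, min(4, cur) + 1))
        pool = int(rng.integers(1, 3))
        out = cur - k + 1
        if out // pool < 1:
            pool = 1
        layers.append(jg.LayerSpec("conv", int(rng.integers(1, 7)), kernel=(k, k),
                                   pool=pool if pool > 1 else None))
        cur = (cur - k + 1) // pool
    for _ in range(int(rng.integers(0, 3))):
        layers.append(jg.LayerSpec("dense", int(rng.integers(1, 16))))
    return jg.ModelSpec(kind="cnn", input_shape=(c, h, w),
                        hidden_layers=tuple(layers),
                        num_classes=int(rng.integers(2, 5)))
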