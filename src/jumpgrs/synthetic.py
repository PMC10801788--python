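"""Synthetic datasets with the statistical structure of calcium-imaging
decoding inputs.

Three generators, all seeded and deterministic:

* :func:`generate_msn_like` — population calcium traces (3000 samples at
  10 Hz by default, ``beta`` neurons) with a binary behavior label that has
  temporal persistence.  A subset of *informative* neurons fires Poisson
  calcium events at a state-dependent rate; events are convolved with a
  single-exponential decay kernel (the simplest standard transient model)
  and Gaussian noise is added.  Uninformative neurons are state-independent.
* :func:`generate_embedding_like` — balanced binary-labeled embedding
  vectors (1600 x 80 by default): two spherical Gaussian clusters at
  ``+/- separation/2`` along a random unit direction.
* :func:`generate_planted_subnetwork` — features labeled by a fixed random
  teacher MLP (median-thresholded logit, so classes are exactly balanced).
  Decoding accuracy on this data is capacity-dependent, which makes it the
  right probe for the far/near-phase sensitivity phenomenon.

:func:`split_8_1_1` partitions any of these into train/validation/test
index sets at the 8:1:1 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .model_core import ConfigurationError, DataError, LabeledDataset

__all__ = [
    "MSNGenParams",
    "MSNLikeDataset",
    "EmbeddingLikeDataset",
    "DataSplit",
    "generate_msn_like",
    "generate_embedding_like",
    "generate_planted_subnetwork",
    "split_8_1_1",
]


@dataclass(frozen=True)
class MSNGenParams:
    """Knobs of the calcium-trace generator.

    ``beta`` is the neuron count (the real recordings range over 53-273
    neurons per subject); ``n_informative`` of them couple to the behavior
    state.  ``event_rate_hz`` gives the informative neurons' Poisson event
    rate in each of the two behavior states; uninformative neurons fire at
    the mean of the two rates throughout.  ``transient_decay_s`` is the
    calcium decay time constant, ``label_persistence`` the mean run length
    (in samples) of each behavior state.
    """

    beta: int = 114
    n_informative: int = 22
    transient_decay_s: float = 1.0
    event_rate_hz: tuple[float, float] = (0.2, 2.0)
    noise_sd: float = 0.1
    label_persistence: float = 20.0
    n_samples: int = 3000
    sampling_rate_hz: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.beta < 1 or not 0 <= self.n_informative <= self.beta:
            raise ConfigurationError("need 0 <= n_informative <= beta, beta >= 1")
        if (self.transient_decay_s <= 0 or self.noise_sd < 0
                or self.label_persistence < 1 or min(self.event_rate_hz) < 0
                or self.n_samples < 1 or self.sampling_rate_hz <= 0):
            raise ConfigurationError("rates, decay and persistence must be positive")


@dataclass
class MSNLikeDataset:
    traces: np.ndarray          # (n_samples, n_neurons)
    labels: np.ndarray          # binary, temporal persistence
    sampling_rate_hz: float = 10.0

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[1]

    def to_labeled(self) -> LabeledDataset:
        return LabeledDataset(self.traces, self.labels)


@dataclass
class EmbeddingLikeDataset:
    vectors: np.ndarray         # (n_samples, dim)
    labels: np.ndarray          # exactly balanced binary

    def to_labeled(self) -> LabeledDataset:
        return LabeledDataset(self.vectors, self.labels)


@dataclass(frozen=True)
class DataSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def _markov_labels(n: int, persistence: float, rng: np.random.Generator) -> np.ndarray:
    """Two-state chain with mean run length ``persistence``."""
    p_flip = 1.0 / persistence
    flips = rng.random(n) < p_flip
    state = int(rng.integers(2))
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        if flips[i]:
            state = 1 - state
        labels[i] = state
    return labels


def generate_msn_like(params: MSNGenParams) -> MSNLikeDataset:
    """Simulate a population calcium-trace decoding dataset (see module
    docstring for the model)."""
    rng = np.random.default_rng(params.seed)
    n, beta = params.n_samples, params.beta
    fs = params.sampling_rate_hz
    labels = _markov_labels(n, params.label_persistence, rng)

    low, high = params.event_rate_hz
    rates = np.empty((n, beta))
    rates[:, : params.n_informative] = np.where(
        labels[:, None] == 1, high, low)
    rates[:, params.n_informative:] = 0.5 * (low + high)

    events = rng.poisson(rates / fs).astype(np.float64)
    # single-exponential calcium transient: AR(1) filter with decay per bin
    decay = np.exp(-1.0 / (params.transient_decay_s * fs))
    traces = lfilter([1.0], [1.0, -decay], events, axis=0)
    traces += rng.normal(0.0, params.noise_sd, size=traces.shape)
    return MSNLikeDataset(traces=traces, labels=labels, sampling_rate_hz=fs)


def generate_embedding_like(n: int = 1600, dim: int = 80,
                            separation: float = 6.0,
                            seed: int = 0) -> EmbeddingLikeDataset:
    """Two unit-variance Gaussian clusters whose centers sit ``separation``
    apart along a random direction; exactly ``n/2`` samples per class.
    The Bayes accuracy is ``Phi(separation/2)``."""
    if n % 2:
        raise ConfigurationError("n must be even for exact class balance")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=dim)
    u /= np.linalg.norm(u)
    labels = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, dim))
    X += np.where(labels[:, None] == 1, 0.5, -0.5) * separation * u
    perm = rng.permutation(n)
    return EmbeddingLikeDataset(vectors=X[perm], labels=labels[perm])


def generate_planted_subnetwork(n: int = 3000, dim: int = 20,
                                n_directions: int = 4,
                                seed: int = 0) -> LabeledDataset:
    """Standard-normal features labeled by a planted small network: the
    score ``sum_k |w_k . x|`` over ``n_directions`` random unit directions,
    thresholded at its median (so classes are exactly balanced up to one
    sample for odd n).

    Each ``|w_k . x|`` term is realizable by a pair of ReLU units, so the
    planted network needs ``2 * n_directions`` first-layer units.  The score
    has no dominant linear component, which makes decoding accuracy genuinely
    capacity-dependent: a first hidden layer of width 2 can represent only a
    single absolute-value direction, so heavily pruned models hit a
    representational ceiling no amount of retraining can cross.  This is the
    probe dataset for the far/near-phase sensitivity phenomenon.
    """
    if n_directions < 1 or dim < 1:
        raise ConfigurationError("dim and n_directions must be >= 1")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    W = rng.normal(size=(dim, n_directions))
    W /= np.linalg.norm(W, axis=0)
    score = np.abs(X @ W).sum(axis=1)
    y = (score > np.median(score)).astype(np.int64)
    return LabeledDataset(X, y)


def split_8_1_1(n_or_dataset, seed: int = 0) -> DataSplit:
    """Random disjoint train/validation/test split at 8:1:1.

    Validation and test each receive ``floor(n/10)`` samples; train takes
    the remainder.  Accepts a sample count or any object with ``n`` /
    ``labels`` / a first-axis length.
    """
    if isinstance(n_or_dataset, (int, np.integer)):
        n = int(n_or_dataset)
    elif hasattr(n_or_dataset, "n"):
        n = n_or_dataset.n
    elif hasattr(n_or_dataset, "labels"):
        n = len(n_or_dataset.labels)
    else:
        n = len(n_or_dataset)
    if n < 10:
        raise DataError("need at least 10 samples for an 8:1:1 split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = n // 10
    return DataSplit(train=np.sort(perm[2 * k:]),
                     validation=np.sort(perm[:k]),
                     test=np.sort(perm[k:2 * k]))
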