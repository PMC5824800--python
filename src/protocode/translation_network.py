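"""The protocell's 'black box' translation system.

A fully connected 3-6-11 feed-forward network with logistic activations on
the hidden and output layers (inputs are raw codon encodings) and a bias
weight into every hidden and output node. Trained by online gradient
descent on the per-sample squared error

    eps(n) = 1/2 * sum_j (d_j(n) - y_j(n))**2

with weight change -eta * dEps/dv_j * y_i, i.e. plain backpropagation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from typing import Sequence

import numpy as np

from ._kernels import sgd_train

__all__ = [
    "N_INPUT",
    "N_HIDDEN",
    "N_OUTPUT",
    "PerceptronTranslator",
    "init_network",
    "forward",
    "forward_batch",
    "sample_loss",
    "train_on_pairs",
]

N_INPUT, N_HIDDEN, N_OUTPUT = 3, 6, 11

#: Half-width of the zero-mean uniform with standard deviation 0.1.
_UNIFORM_HALF_WIDTH = 0.1 * math.sqrt(3.0)


@dataclass
class PerceptronTranslator:
    """Weights and biases of one protocell's translation network."""

    w_input_hidden: np.ndarray  # (3, 6)
    b_hidden: np.ndarray  # (6,)
    w_hidden_output: np.ndarray  # (6, 11)
    b_output: np.ndarray  # (11,)
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        self.w_input_hidden = np.ascontiguousarray(self.w_input_hidden, dtype=float)
        self.b_hidden = np.ascontiguousarray(self.b_hidden, dtype=float)
        self.w_hidden_output = np.ascontiguousarray(self.w_hidden_output, dtype=float)
        self.b_output = np.ascontiguousarray(self.b_output, dtype=float)
        shapes = (
            self.w_input_hidden.shape,
            self.b_hidden.shape,
            self.w_hidden_output.shape,
            self.b_output.shape,
        )
        expect = ((N_INPUT, N_HIDDEN), (N_HIDDEN,), (N_HIDDEN, N_OUTPUT), (N_OUTPUT,))
        if shapes != expect:
            raise ValueError(f"bad weight shapes {shapes}, expected {expect}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")

    def copy(self) -> "PerceptronTranslator":
        return PerceptronTranslator(
            self.w_input_hidden.copy(),
            self.b_hidden.copy(),
            self.w_hidden_output.copy(),
            self.b_output.copy(),
            self.learning_rate,
        )

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "w_input_hidden": self.w_input_hidden.tolist(),
                "b_hidden": self.b_hidden.tolist(),
                "w_hidden_output": self.w_hidden_output.tolist(),
                "b_output": self.b_output.tolist(),
                "learning_rate": self.learning_rate,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PerceptronTranslator":
        obj = json.loads(text)
        return cls(
            np.array(obj["w_input_hidden"]),
            np.array(obj["b_hidden"]),
            np.array(obj["w_hidden_output"]),
            np.array(obj["b_output"]),
            float(obj["learning_rate"]),
        )


def init_network(
    rng: np.random.Generator,
    learning_rate: float = 0.1,
    init: str = "uniform",
) -> PerceptronTranslator:
    """Random network with zero-mean weights of standard deviation 0.1.

    ``init='uniform'`` (default) draws from the uniform on
    [-0.1*sqrt(3), +0.1*sqrt(3)], the unique zero-mean uniform with sd 0.1;
    ``init='normal'`` draws from N(0, 0.1^2) instead.
    """
    if init == "uniform":
        draw = lambda size: rng.uniform(-_UNIFORM_HALF_WIDTH, _UNIFORM_HALF_WIDTH, size)
    elif init == "normal":
        draw = lambda size: rng.normal(0.0, 0.1, size)
    else:
        raise ValueError(f"unknown init scheme {init!r}")
    return PerceptronTranslator(
        w_input_hidden=draw((N_INPUT, N_HIDDEN)),
        b_hidden=draw(N_HIDDEN),
        w_hidden_output=draw((N_HIDDEN, N_OUTPUT)),
        b_output=draw(N_OUTPUT),
        learning_rate=learning_rate,
    )


def _logistic(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def forward(net: PerceptronTranslator, x: np.ndarray) -> np.ndarray:
    """Output 11-vector for one codon encoding; components in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (N_INPUT,):
        raise ValueError(f"input must be a 3-vector, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite network input")
    h = _logistic(x @ net.w_input_hidden + net.b_hidden)
    return _logistic(h @ net.w_hidden_output + net.b_output)


def forward_batch(net: PerceptronTranslator, X: np.ndarray) -> np.ndarray:
    """Vectorized forward pass over rows of ``X`` (n, 3) -> (n, 11)."""
    X = np.asarray(X, dtype=float)
    h = _logistic(X @ net.w_input_hidden + net.b_hidden)
    return _logistic(h @ net.w_hidden_output + net.b_output)


def sample_loss(net: PerceptronTranslator, x: np.ndarray, d: np.ndarray) -> float:
    """Per-sample squared error eps = 1/2 * sum_j (d_j - y_j)^2."""
    e = np.asarray(d, dtype=float) - forward(net, x)
    return 0.5 * float(e @ e)


def train_on_pairs(
    net: PerceptronTranslator,
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    epochs: int,
    rng: np.random.Generator,
) -> PerceptronTranslator:
    """Online backprop training, in place; returns ``net``.

    Runs ``epochs`` passes over ``pairs``; each pass presents the samples
    one at a time in a freshly shuffled order drawn from ``rng``, updating
    all weights and biases after every presentation.
    """
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    if epochs == 0:
        return net
    if not pairs:
        raise ValueError("pairs must be nonempty")
    X = np.ascontiguousarray([p[0] for p in pairs], dtype=float)
    D = np.ascontiguousarray([p[1] for p in pairs], dtype=float)
    if X.shape[1:] != (N_INPUT,) or D.shape[1:] != (N_OUTPUT,):
        raise ValueError(
            f"pair dimension mismatch: inputs {X.shape[1:]}, targets {D.shape[1:]}"
        )
    n = len(pairs)
    # one fresh permutation per epoch, flattened into a single sequence;
    # argsort of i.i.d. uniforms is a uniform random permutation per row
    order = np.ascontiguousarray(
        rng.random((epochs, n)).argsort(axis=1).ravel()
    )
    sgd_train(
        net.w_input_hidden,
        net.b_hidden,
        net.w_hidden_output,
        net.b_output,
        X,
        D,
        order,
        net.learning_rate,
    )
    return net
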