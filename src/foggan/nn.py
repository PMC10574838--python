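"""Dense feed-forward networks in numpy with reverse-mode gradients.

This module is the numerical core behind both the adversarial pair and the
utility classifier.  It provides exactly what those consumers need and no
more: fully-connected layers with ReLU hidden activations, a linear /
sigmoid / softmax head, inverted dropout, reverse-mode gradients for the
pre-activation of the head, and Adam.

Conventions
-----------
* Weight matrices are stored ``(fan_in, fan_out)``; a forward pass is
  ``X @ W + b``.
* ``TrainedNetwork.backward`` takes the gradient of the loss with respect
  to the final *pre-activation* (logits).  Loss functions that pair with a
  sigmoid or softmax head therefore hand back the usual ``p - t`` form,
  which is both simpler and numerically safer than differentiating through
  the output nonlinearity.
* Dropout is "inverted": activations are scaled by ``1/(1-rate)`` at train
  time so inference needs no rescaling and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkSpec",
    "TrainedNetwork",
    "Adam",
    "count_parameters",
    "layer_parameter_counts",
]

_HIDDEN_ACTIVATIONS = ("relu",)
_OUTPUT_ACTIVATIONS = ("linear", "sigmoid", "softmax")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: layer widths, activations, dropout placement.

    ``layer_widths`` lists every dense layer including the output head;
    ``dropout_after`` holds 0-based indices of layers whose activation is
    followed by dropout at rate ``dropout_rate`` during training.
    """

    input_dim: int
    layer_widths: tuple[int, ...]
    hidden_activation: str = "relu"
    output_activation: str = "linear"
    dropout_rate: float = 0.0
    dropout_after: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer_widths", tuple(int(w) for w in self.layer_widths))
        object.__setattr__(self, "dropout_after", tuple(int(i) for i in self.dropout_after))
        if self.input_dim < 1:
            raise ValueError(f"input_dim must be >= 1, got {self.input_dim}")
        if not self.layer_widths:
            raise ValueError("layer_widths may not be empty")
        if any(w < 1 for w in self.layer_widths):
            raise ValueError(f"all layer widths must be >= 1, got {self.layer_widths}")
        if self.hidden_activation not in _HIDDEN_ACTIVATIONS:
            raise ValueError(f"unsupported hidden activation {self.hidden_activation!r}")
        if self.output_activation not in _OUTPUT_ACTIVATIONS:
            raise ValueError(f"unsupported output activation {self.output_activation!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        n = len(self.layer_widths)
        if any(i < 0 or i >= n for i in self.dropout_after):
            raise ValueError("dropout_after indices out of range")

    @property
    def n_layers(self) -> int:
        return len(self.layer_widths)

    @property
    def output_dim(self) -> int:
        return self.layer_widths[-1]


def layer_parameter_counts(spec: NetworkSpec) -> list[int]:
    """Per-dense-layer parameter counts, ``(fan_in + 1) * fan_out``."""
    widths = (spec.input_dim, *spec.layer_widths)
    return [(w_in + 1) * w_out for w_in, w_out in zip(widths[:-1], widths[1:])]


def count_parameters(obj: "NetworkSpec | TrainedNetwork") -> int:
    """Total trainable parameters of a spec or an instantiated network."""
    spec = obj.spec if isinstance(obj, TrainedNetwork) else obj
    return sum(layer_parameter_counts(spec))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    shifted = z - z.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


class TrainedNetwork:
    """A realized multilayer perceptron: spec plus weights and biases.

    Hidden layers are He-initialized (suited to ReLU); the head uses a
    Glorot-style scale.  ``forward(training=True)`` caches intermediates so
    a subsequent ``backward`` can return parameter gradients and the
    gradient with respect to the input batch (needed to chain the
    discriminator into the generator update).
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = (spec.input_dim, *spec.layer_widths)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for li, (w_in, w_out) in enumerate(zip(widths[:-1], widths[1:])):
            last = li == spec.n_layers - 1
            scale = np.sqrt(1.0 / w_in) if last else np.sqrt(2.0 / w_in)
            self.weights.append(rng.normal(0.0, scale, size=(w_in, w_out)))
            self.biases.append(np.zeros(w_out))
        self._cache: dict | None = None

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Map a batch ``(n, input_dim)`` to ``(n, output_dim)``.

        With ``training=True`` dropout is active (an ``rng`` is then
        required if the spec declares any dropout) and intermediates are
        cached for :meth:`backward`.  Inference is deterministic.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected input of shape (n, {self.spec.input_dim}), got {X.shape}"
            )
        use_dropout = training and self.spec.dropout_rate > 0 and self.spec.dropout_after
        if use_dropout and rng is None:
            raise ValueError("training forward pass with dropout requires an rng")

        inputs: list[np.ndarray] = []     # layer inputs (post-dropout of previous)
        preacts: list[np.ndarray] = []    # z = a_prev @ W + b
        masks: dict[int, np.ndarray] = {}
        a = X
        n_layers = self.spec.n_layers
        keep = 1.0 - self.spec.dropout_rate
        for li in range(n_layers):
            inputs.append(a)
            z = a @ self.weights[li] + self.biases[li]
            preacts.append(z)
            if li < n_layers - 1:
                a = np.maximum(z, 0.0)
            elif self.spec.output_activation == "linear":
                a = z
            elif self.spec.output_activation == "sigmoid":
                a = _sigmoid(z)
            else:
                a = _softmax(z)
            if use_dropout and li in self.spec.dropout_after:
                mask = (rng.random(a.shape) < keep).astype(float) / keep
                masks[li] = mask
                a = a * mask
        if training:
            self._cache = {"inputs": inputs, "preacts": preacts, "masks": masks}
        return a

    # -- backward ----------------------------------------------------------

    def backward(
        self, dlogits: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Backpropagate from the head's pre-activation gradient.

        Returns ``(dWs, dbs, dX)``.  Requires a preceding
        ``forward(training=True)`` on the same batch.
        """
        if self._cache is None:
            raise RuntimeError("backward called without a cached training forward pass")
        inputs = self._cache["inputs"]
        preacts = self._cache["preacts"]
        masks = self._cache["masks"]
        n_layers = self.spec.n_layers

        dWs: list[np.ndarray] = [np.empty(0)] * n_layers
        dbs: list[np.ndarray] = [np.empty(0)] * n_layers
        # Dropout after the head rescales the loss path into the logits.
        dz = dlogits
        if (n_layers - 1) in masks:
            dz = dz * masks[n_layers - 1]
        for li in range(n_layers - 1, -1, -1):
            dWs[li] = inputs[li].T @ dz
            dbs[li] = dz.sum(axis=0)
            da = dz @ self.weights[li].T
            if li > 0:
                if (li - 1) in masks:
                    da = da * masks[li - 1]
                dz = da * (preacts[li - 1] > 0)
            else:
                dX = da
        self._cache = None
        return dWs, dbs, dX

    # -- persistence -------------------------------------------------------

    def parameter_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    def load_parameter_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i in range(self.spec.n_layers):
            W, b = arrays[f"W{i}"], arrays[f"b{i}"]
            if W.shape != self.weights[i].shape or b.shape != self.biases[i].shape:
                raise ValueError(f"parameter shape mismatch at layer {i}")
            self.weights[i] = np.asarray(W, dtype=float)
            self.biases[i] = np.asarray(b, dtype=float)


class Adam:
    """Adam optimizer over one :class:`TrainedNetwork`."""

    def __init__(
        self,
        net: TrainedNetwork,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._mW = [np.zeros_like(W) for W in net.weights]
        self._vW = [np.zeros_like(W) for W in net.weights]
        self._mb = [np.zeros_like(b) for b in net.biases]
        self._vb = [np.zeros_like(b) for b in net.biases]

    def step(self, dWs: Sequence[np.ndarray], dbs: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for i in range(len(self.net.weights)):
            for g, m, v, p in (
                (dWs[i], self._mW[i], self._vW[i], self.net.weights[i]),
                (dbs[i], self._mb[i], self._vb[i], self.net.biases[i]),
            ):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
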