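"""A small feedforward neural network with standard backpropagation.

Intended as a pluggable predictor inside optimization strategies (e.g.
mapping sequence features to an expression score). Logistic activations,
uniform(-0.5, 0.5) weight initialization, per-sample stochastic gradient
descent with optional momentum; everything is seeded and deterministic,
and a trained network round-trips bit-exactly through a plain-text map
file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeneDesignError


@dataclass(frozen=True)
class NetworkSpec:
    """Layer sizes (input, hidden..., output) and training hyperparameters."""

    layers: tuple[int, ...]
    activation: str = "logistic"
    learning_rate: float = 0.5
    momentum: float = 0.0
    epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layers) < 3:
            raise GeneDesignError("network needs at least one hidden layer")
        if any(n < 1 for n in self.layers):
            raise GeneDesignError("all layer sizes must be >= 1")
        if self.activation != "logistic":
            raise GeneDesignError(f"unsupported activation {self.activation!r}")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TrainedNetwork:
    """Weights, biases and the per-epoch mean-squared-error trace."""

    spec: NetworkSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    loss_trace: list[float] = field(default_factory=list)

    def predict(self, inputs) -> np.ndarray:
        """Forward pass; logistic outputs lie in (0, 1)."""
        a = np.asarray(inputs, dtype=float)
        squeeze = a.ndim == 1
        if squeeze:
            a = a[None, :]
        if a.shape[1] != self.spec.layers[0]:
            raise GeneDesignError(
                f"input width {a.shape[1]} != network input size {self.spec.layers[0]}"
            )
        for W, b in zip(self.weights, self.biases):
            a = _sigmoid(a @ W + b)
        return a[0] if squeeze else a

    def save(self, path) -> None:
        """Write the plain-text network map (full precision, reloadable)."""
        with open(path, "w") as fh:
            fh.write("genedesign-network-map 1\n")
            fh.write("layers\t" + "\t".join(map(str, self.spec.layers)) + "\n")
            fh.write(f"activation\t{self.spec.activation}\n")
            for li, (W, b) in enumerate(zip(self.weights, self.biases)):
                fh.write(f"layer\t{li}\n")
                for row in W:
                    fh.write("w\t" + "\t".join(repr(float(x)) for x in row) + "\n")
                fh.write("b\t" + "\t".join(repr(float(x)) for x in b) + "\n")

    @classmethod
    def load(cls, path) -> "TrainedNetwork":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        if not lines or not lines[0].startswith("genedesign-network-map"):
            raise GeneDesignError(f"{path}: not a network map file")
        layers = tuple(int(x) for x in lines[1].split("\t")[1:])
        activation = lines[2].split("\t")[1]
        spec = NetworkSpec(layers=layers, activation=activation)
        weights: list[np.ndarray] = []
        biases: list[np.ndarray] = []
        rows: list[list[float]] = []
        for ln in lines[3:]:
            parts = ln.split("\t")
            if parts[0] == "layer":
                rows = []
            elif parts[0] == "w":
                rows.append([float(x) for x in parts[1:]])
            elif parts[0] == "b":
                weights.append(np.array(rows, dtype=float))
                biases.append(np.array([float(x) for x in parts[1:]], dtype=float))
        net = cls(spec=spec, weights=weights, biases=biases)
        for i, (W, b) in enumerate(zip(net.weights, net.biases)):
            if W.shape != (layers[i], layers[i + 1]) or b.shape != (layers[i + 1],):
                raise GeneDesignError(f"{path}: inconsistent shapes at layer {i}")
        return net


def _init_network(spec: NetworkSpec) -> TrainedNetwork:
    rng = np.random.default_rng(spec.seed)
    weights = [
        rng.uniform(-0.5, 0.5, size=(spec.layers[i], spec.layers[i + 1]))
        for i in range(len(spec.layers) - 1)
    ]
    biases = [
        rng.uniform(-0.5, 0.5, size=spec.layers[i + 1])
        for i in range(len(spec.layers) - 1)
    ]
    return TrainedNetwork(spec=spec, weights=weights, biases=biases)


def _forward(net: TrainedNetwork, x: np.ndarray) -> list[np.ndarray]:
    activations = [x]
    a = x
    for W, b in zip(net.weights, net.biases):
        a = _sigmoid(a @ W + b)
        activations.append(a)
    return activations


def gradients(
    net: TrainedNetwork, inputs: np.ndarray, targets: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Full-batch backpropagation gradients of the mean squared error.

    Loss = mean over samples and outputs of (prediction - target)^2.
    """
    X = np.asarray(inputs, dtype=float)
    Y = np.asarray(targets, dtype=float)
    acts = _forward(net, X)
    n = X.shape[0] * Y.shape[1]
    delta = 2.0 * (acts[-1] - Y) / n * acts[-1] * (1.0 - acts[-1])
    gw: list[np.ndarray] = [None] * len(net.weights)
    gb: list[np.ndarray] = [None] * len(net.biases)
    for li in range(len(net.weights) - 1, -1, -1):
        gw[li] = acts[li].T @ delta
        gb[li] = delta.sum(axis=0)
        if li > 0:
            delta = (delta @ net.weights[li].T) * acts[li] * (1.0 - acts[li])
    return gw, gb


def mse(net: TrainedNetwork, inputs, targets) -> float:
    pred = net.predict(inputs)
    Y = np.asarray(targets, dtype=float)
    return float(np.mean((pred - Y) ** 2))


def train(spec: NetworkSpec, inputs, targets) -> TrainedNetwork:
    """Train with per-sample SGD + momentum in a fixed row order.

    Deterministic for a fixed spec seed. A zero epoch budget returns the
    freshly initialized network untouched.
    """
    X = np.asarray(inputs, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise GeneDesignError(
            f"shape mismatch: inputs {X.shape}, targets {Y.shape}"
        )
    if X.shape[1] != spec.layers[0] or Y.shape[1] != spec.layers[-1]:
        raise GeneDesignError(
            f"table widths {X.shape[1]}/{Y.shape[1]} do not match network "
            f"sizes {spec.layers[0]}/{spec.layers[-1]}"
        )
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise GeneDesignError("training tables must be finite")
    net = _init_network(spec)
    vel_w = [np.zeros_like(W) for W in net.weights]
    vel_b = [np.zeros_like(b) for b in net.biases]
    for _ in range(spec.epochs):
        for r in range(X.shape[0]):
            x = X[r : r + 1]
            y = Y[r : r + 1]
            acts = _forward(net, x)
            delta = 2.0 * (acts[-1] - y) / y.size * acts[-1] * (1.0 - acts[-1])
            for li in range(len(net.weights) - 1, -1, -1):
                gw = acts[li].T @ delta
                gb = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ net.weights[li].T) * acts[li] * (1.0 - acts[li])
                vel_w[li] = spec.momentum * vel_w[li] - spec.learning_rate * gw
                vel_b[li] = spec.momentum * vel_b[li] - spec.learning_rate * gb
                net.weights[li] = net.weights[li] + vel_w[li]
                net.biases[li] = net.biases[li] + vel_b[li]
        net.loss_trace.append(mse(net, X, Y))
    return net


def predict(net: TrainedNetwork, inputs) -> np.ndarray:
    return net.predict(inputs)
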