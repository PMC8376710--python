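"""The customized convolutional classifier for connectome grids.

Because adjacency in a connectome matrix carries no spatial meaning, the
network departs from image CNNs in two ways: every convolutional layer uses a
filter size of 1 (each grid cell is transformed independently across
channels) and max-pooling is omitted entirely, so feature maps keep the full
60x60 extent through all four convolutional stages (8, 16, 16 and 32
channels).  The final feature maps are flattened and processed by three fully
connected layers (4096, 4096 and 2 units by default); the two outputs are
softmax class probabilities with teacher vectors [1, 0] (control) and [0, 1]
(patient).

Training minimizes softmax cross-entropy with AdaGrad (accumulator started at
zero) on minibatches of 15 for 20 epochs, after 6-fold augmentation of the
training inputs with zero-mean Gaussian noise (sd 0.002, 0.004, 0.006, 0.008,
0.010).  Rectified linear activations follow every convolutional and hidden
fully connected stage.  All arithmetic is float32 NumPy; forward, backward
and the optimizer are implemented here so that the attribution stage can read
exact activations and gradients at any convolutional layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import GRID_SIDE, ModelInput
from .errors import ConfigurationError, DataError, ValidationError

N_POSITIONS = GRID_SIDE * GRID_SIDE


@dataclass(frozen=True)
class ArchitectureSpec:
    """Shape of the customized CNN (1x1 filters, no pooling)."""

    conv_channels: tuple[int, ...] = (8, 16, 16, 32)
    conv_filter_size: int = 1
    pooling: None = None
    fc_units: tuple[int, ...] = (4096, 4096, 2)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.conv_filter_size != 1:
            raise ConfigurationError("conv_filter_size must be 1")
        if self.pooling is not None:
            raise ConfigurationError("pooling stages are not part of this architecture")
        if not self.fc_units or self.fc_units[-1] != 2:
            raise ConfigurationError("the last fully connected layer must have 2 units")
        if any(c < 1 for c in self.conv_channels) or any(u < 1 for u in self.fc_units):
            raise ConfigurationError("layer widths must be positive")
        if self.activation != "relu":
            raise ConfigurationError(f"unsupported activation: {self.activation!r}")


#: Paper-faithful architecture.
DEFAULT_ARCHITECTURE = ArchitectureSpec()
#: Same convolutional stack with narrow fully connected layers, for fast runs.
REDUCED_ARCHITECTURE = ArchitectureSpec(fc_units=(256, 256, 2))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the reference recipe)."""

    minibatch_size: int = 15
    learning_rate: float = 1e-3
    epochs: int = 20
    noise_sds: tuple[float, ...] = (0.002, 0.004, 0.006, 0.008, 0.010)
    seed: int = 0
    adagrad_eps: float = 1e-8

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise_sds):
            raise ConfigurationError("noise standard deviations must be non-negative")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.minibatch_size < 1:
            raise ConfigurationError("minibatch_size must be >= 1")


#: Scaled-down optimization used for the fast synthetic-cohort checks: no
#: noise augmentation and a larger step size to compensate for the much
#: smaller number of updates (see docs/methods.md).
FAST_TRAIN = TrainConfig(learning_rate=1e-2, noise_sds=())


class _Network:
    """Plain-NumPy network: 1x1 conv stack + fully connected head.

    Activations use a channels-last layout (batch, position, channel); the
    flatten order feeding the first fully connected layer is position-major
    (flat index = position * n_channels + channel).
    """

    def __init__(self, spec: ArchitectureSpec, n_positions: int = N_POSITIONS,
                 in_channels: int = 1, seed: int = 0) -> None:
        self.spec = spec
        self.n_positions = n_positions
        self.in_channels = in_channels
        self.seed = seed
        rng = np.random.default_rng(seed)

        def init(shape, fan_in):
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), shape).astype(np.float32)

        self.conv_W, self.conv_b = [], []
        prev = in_channels
        for c in spec.conv_channels:
            self.conv_W.append(init((c, prev), prev))
            self.conv_b.append(np.zeros(c, dtype=np.float32))
            prev = c
        self.flat_dim = n_positions * prev
        self.fc_W, self.fc_b = [], []
        prev = self.flat_dim
        for u in spec.fc_units:
            self.fc_W.append(init((u, prev), prev))
            self.fc_b.append(np.zeros(u, dtype=np.float32))
            prev = u

    # -- forward ----------------------------------------------------------

    def forward(self, X: np.ndarray, cache: bool = False):
        """X: (batch, n_positions * in_channels) float32 -> softmax probs.

        With ``cache=True`` also returns the intermediate pre/post-activation
        tensors needed for backprop and attribution.
        """
        B = X.shape[0]
        H = X.reshape(B, self.n_positions, self.in_channels).astype(np.float32, copy=False)
        conv_in, conv_pre = [], []
        for W, b in zip(self.conv_W, self.conv_b):
            conv_in.append(H)
            Z = H @ W.T + b
            conv_pre.append(Z)
            H = np.maximum(Z, 0.0)
        F = H.reshape(B, self.flat_dim)
        fc_in, fc_pre = [], []
        A = F
        for k, (W, b) in enumerate(zip(self.fc_W, self.fc_b)):
            fc_in.append(A)
            Z = A @ W.T + b
            fc_pre.append(Z)
            A = Z if k == len(self.fc_W) - 1 else np.maximum(Z, 0.0)
        logits = A
        logits64 = logits.astype(np.float64)
        logits64 -= logits64.max(axis=1, keepdims=True)
        e = np.exp(logits64)
        probs = e / e.sum(axis=1, keepdims=True)
        if not cache:
            return probs
        return probs, {"conv_in": conv_in, "conv_pre": conv_pre,
                       "fc_in": fc_in, "fc_pre": fc_pre, "logits": logits}

    # -- backward ---------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict:
        """Gradients of the loss for every parameter given d(loss)/d(logits)."""
        grads = {"fc_W": [None] * len(self.fc_W), "fc_b": [None] * len(self.fc_b),
                 "conv_W": [None] * len(self.conv_W), "conv_b": [None] * len(self.conv_b)}
        g = dlogits.astype(np.float32)
        for k in range(len(self.fc_W) - 1, -1, -1):
            if k != len(self.fc_W) - 1:
                g = g * (cache["fc_pre"][k] > 0)
            grads["fc_W"][k] = g.T @ cache["fc_in"][k]
            grads["fc_b"][k] = g.sum(axis=0)
            g = g @ self.fc_W[k]
        B = g.shape[0]
        g = g.reshape(B, self.n_positions, self.spec.conv_channels[-1])
        for k in range(len(self.conv_W) - 1, -1, -1):
            g = g * (cache["conv_pre"][k] > 0)
            grads["conv_W"][k] = np.tensordot(g, cache["conv_in"][k], axes=([0, 1], [0, 1]))
            grads["conv_b"][k] = g.sum(axis=(0, 1))
            if k > 0:
                g = g @ self.conv_W[k]
        return grads

    def conv_activations_and_gradient(self, x: np.ndarray, layer: int,
                                      target_class: int):
        """Post-ReLU activations of ``layer`` and the class-score gradient.

        Both have shape (n_positions, n_channels).  The score is the
        target-class logit minus the other class's logit: with two softmax
        outputs the class evidence is only defined relative to the
        alternative (the softmax output's gradient equals this difference's
        gradient up to a positive factor p(1-p)), and differencing removes a
        shared logit component that carries no class information.
        """
        if not (0 <= layer < len(self.conv_W)):
            raise ValidationError(f"no convolutional layer {layer}")
        probs, cache = self.forward(x.reshape(1, -1), cache=True)
        A = np.maximum(cache["conv_pre"][layer], 0.0)[0]
        g = np.full((1, 2), -1.0, dtype=np.float32)
        g[0, target_class] = 1.0
        for k in range(len(self.fc_W) - 1, -1, -1):
            if k != len(self.fc_W) - 1:
                g = g * (cache["fc_pre"][k] > 0)
            g = g @ self.fc_W[k]
        g = g.reshape(1, self.n_positions, self.spec.conv_channels[-1])
        for k in range(len(self.conv_W) - 1, layer, -1):
            g = g * (cache["conv_pre"][k] > 0)
            g = g @ self.conv_W[k]
        return A, g[0]

    # -- parameter access -------------------------------------------------

    def parameters(self):
        for name in ("conv_W", "conv_b", "fc_W", "fc_b"):
            for k, arr in enumerate(getattr(self, name)):
                yield name, k, arr


@dataclass
class TrainedClassifier:
    """Architecture description plus (possibly untrained) learned parameters."""

    spec: ArchitectureSpec
    net: _Network
    seed: int
    training_log: list[float] = field(default_factory=list)


def build_classifier(spec: ArchitectureSpec, seed: int = 0,
                     n_positions: int = N_POSITIONS,
                     in_channels: int = 1) -> TrainedClassifier:
    """Deterministically initialized, untrained classifier.

    Weights use a scaled-Gaussian fan-in scheme (sd = 1/sqrt(fan_in)), biases
    start at zero.
    """
    return TrainedClassifier(spec, _Network(spec, n_positions, in_channels, seed), seed)


def augment(x: ModelInput, noise_sds, rng: np.random.Generator) -> list[ModelInput]:
    """The original input plus one Gaussian-noise copy per sd (6-fold default).

    Noise is i.i.d. zero-mean per cell and added after max-normalization.
    """
    if any(sd < 0 for sd in noise_sds):
        raise ConfigurationError("noise standard deviations must be non-negative")
    out = [x]
    for sd in noise_sds:
        out.append(ModelInput(x.grid + rng.normal(0.0, sd, x.grid.shape),
                              x.source_subject, x.metric))
    return out


def _as_input_array(x) -> np.ndarray:
    if isinstance(x, ModelInput):
        return x.grid.reshape(-1)
    return np.asarray(x, dtype=float).reshape(-1)


def train(model: TrainedClassifier, samples, cfg: TrainConfig) -> TrainedClassifier:
    """Minibatch AdaGrad training on the augmented sample set.

    ``samples`` is a sequence of (ModelInput or flat array, 2-element teacher
    vector).  Runs exactly ``cfg.epochs`` epochs over the augmented set; the
    model is updated in place and returned with its per-epoch mean loss log.
    Same model seed and config seed give bit-identical results.
    """
    if not samples:
        raise DataError("empty training set")
    X0 = np.stack([_as_input_array(x) for x, _ in samples]).astype(np.float32)
    T0 = np.asarray([t for _, t in samples], dtype=np.float32)
    if T0.ndim != 2 or T0.shape[1] != 2:
        raise DataError("teacher vectors must have two elements")
    if np.unique(np.argmax(T0, axis=1)).size < 2:
        raise DataError("training set must contain both classes")

    rng = np.random.default_rng(cfg.seed)
    parts = [X0] + [X0 + rng.normal(0.0, sd, X0.shape).astype(np.float32)
                    for sd in cfg.noise_sds]
    X = np.concatenate(parts, axis=0)
    T = np.tile(T0, (len(parts), 1))
    n = X.shape[0]

    net = model.net
    state = {(name, k): np.zeros_like(arr) for name, k, arr in net.parameters()}
    tmp = {(name, k): np.empty_like(arr) for name, k, arr in net.parameters()}
    lr, eps = np.float32(cfg.learning_rate), np.float32(cfg.adagrad_eps)

    model.training_log = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.minibatch_size):
            idx = order[start:start + cfg.minibatch_size]
            xb, tb = X[idx], T[idx]
            probs, cache = net.forward(xb, cache=True)
            loss = -np.mean(np.sum(tb * np.log(np.maximum(probs, 1e-12)), axis=1))
            losses.append(float(loss))
            dlogits = (probs - tb) / xb.shape[0]
            grads = net.backward(cache, dlogits)
            for name, k, arr in net.parameters():
                g = grads[name][k]
                acc, buf = state[(name, k)], tmp[(name, k)]
                np.multiply(g, g, out=buf)
                acc += buf
                np.sqrt(acc, out=buf)
                buf += eps
                np.divide(g, buf, out=buf)
                buf *= lr
                arr -= buf
        model.training_log.append(float(np.mean(losses)))
    return model


def predict(model: TrainedClassifier, x) -> np.ndarray:
    """Softmax class probabilities (control, patient) for one input."""
    return model.net.forward(_as_input_array(x).reshape(1, -1))[0]


def predict_batch(model: TrainedClassifier, xs) -> np.ndarray:
    """(n, 2) class probabilities for a sequence of inputs."""
    X = np.stack([_as_input_array(x) for x in xs]).astype(np.float32)
    return model.net.forward(X)


def patient_score(model: TrainedClassifier, x) -> float:
    """Probability assigned to the patient class — the downstream ROC score."""
    return float(predict(model, x)[1])


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: TrainedClassifier, path) -> None:
    """Self-describing archive: architecture, seed, parameters, loss log."""
    meta = {
        "conv_channels": list(model.spec.conv_channels),
        "fc_units": list(model.spec.fc_units),
        "activation": model.spec.activation,
        "n_positions": model.net.n_positions,
        "in_channels": model.net.in_channels,
        "seed": model.seed,
        "training_log": model.training_log,
    }
    arrays = {f"{name}_{k}": arr for name, k, arr in model.net.parameters()}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> TrainedClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec = ArchitectureSpec(conv_channels=tuple(meta["conv_channels"]),
                                fc_units=tuple(meta["fc_units"]),
                                activation=meta["activation"])
        model = build_classifier(spec, meta["seed"], meta["n_positions"],
                                 meta["in_channels"])
        for name, k, arr in model.net.parameters():
            arr[...] = data[f"{name}_{k}"]
    model.training_log = list(meta["training_log"])
    return model
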