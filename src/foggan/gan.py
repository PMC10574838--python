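"""The adversarial generator/discriminator pair: build, train, sample.

The generator maps standard-normal noise to 9-channel accelerometer rows
through a deep fully-connected stack; the discriminator is a mirror-image
stack with 20% dropout after every hidden layer and a scalar sigmoid head
estimating Pr(sample is real).  Training alternates one discriminator and
one generator Adam step per minibatch of size ``m``:

* the discriminator ascends
  ``(1/m) sum_i [log D(x_i) + log(1 - D(G(z_i)))]``;
* the generator, in its literal mode, descends
  ``(1/m) sum_i log(1 - D(G(z_i)))``; the default "non_saturating" mode
  instead ascends ``(1/m) sum_i log D(G(z_i))`` — the same fixed point
  with usable gradients early in training, when the discriminator wins
  easily.

The published architecture tables fix the noise dimension at 8: the first
generator layer holds 13,824 = (8+1)*1536 parameters.  The printed
discriminator table repeats the generator's rows verbatim (including an
8-wide input and a 9-unit head), which cannot feed a scalar real/fake
probability; the functional discriminator here therefore takes the 9
features and ends in one sigmoid unit, while the printed layout remains
available as :func:`printed_discriminator_spec` for arithmetic checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_io import LabeledMatrix, Scaler
from .nn import Adam, NetworkSpec, TrainedNetwork, count_parameters

__all__ = [
    "GENERATOR_HIDDEN_WIDTHS",
    "DISCRIMINATOR_HIDDEN_WIDTHS",
    "NoiseSpec",
    "GanTrainConfig",
    "TrainingHistory",
    "GanDivergenceError",
    "build_generator",
    "build_discriminator",
    "printed_discriminator_spec",
    "train_foggan",
    "sample_synthetic",
    "save_checkpoint",
    "load_checkpoint",
]

GENERATOR_HIDDEN_WIDTHS = (1536, 1278, 1024, 512, 384, 256, 128, 64, 32, 16)
DISCRIMINATOR_HIDDEN_WIDTHS = (1536, 1278, 1024, 512, 384, 256, 128, 64, 32, 16)

_EPS = 1e-7  # probability clip in log losses


@dataclass(frozen=True)
class NoiseSpec:
    """Latent input of the generator: i.i.d. standard-normal of ``dimension``."""

    dimension: int = 8
    distribution: str = "standard_normal"

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("noise dimension must be >= 1")
        if self.distribution != "standard_normal":
            raise ValueError("only the standard_normal noise distribution is supported")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((n, self.dimension))


@dataclass(frozen=True)
class GanTrainConfig:
    """Adversarial training hyperparameters (defaults are the published run)."""

    epochs: int = 500
    batch_size: int = 50
    lr_discriminator: float = 0.001
    lr_generator: float = 0.01
    seed: int = 0
    generator_loss_mode: str = "non_saturating"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr_discriminator <= 0 or self.lr_generator <= 0:
            raise ValueError("learning rates must be positive")
        if self.generator_loss_mode not in ("literal", "non_saturating"):
            raise ValueError(
                f"unknown generator_loss_mode {self.generator_loss_mode!r}"
            )


@dataclass
class TrainingHistory:
    """Per-epoch mean generator and discriminator losses."""

    generator_loss: list[float] = field(default_factory=list)
    discriminator_loss: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.generator_loss)


class GanDivergenceError(RuntimeError):
    """Raised when a loss becomes non-finite during adversarial training."""


def build_generator(
    noise: NoiseSpec = NoiseSpec(),
    hidden_widths: tuple[int, ...] = GENERATOR_HIDDEN_WIDTHS,
    output_dim: int = 9,
    seed: int = 0,
) -> TrainedNetwork:
    """Instantiate the generator: ReLU hidden stack, linear ``output_dim`` head."""
    spec = NetworkSpec(
        input_dim=noise.dimension,
        layer_widths=(*hidden_widths, output_dim),
        output_activation="linear",
    )
    return TrainedNetwork(spec, seed=seed)


def build_discriminator(
    input_dim: int = 9,
    hidden_widths: tuple[int, ...] = DISCRIMINATOR_HIDDEN_WIDTHS,
    dropout_rate: float = 0.2,
    seed: int = 0,
) -> TrainedNetwork:
    """Instantiate the discriminator: dropout-regularized stack, sigmoid scalar head."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    spec = NetworkSpec(
        input_dim=input_dim,
        layer_widths=(*hidden_widths, 1),
        output_activation="sigmoid",
        dropout_rate=dropout_rate,
        dropout_after=tuple(range(len(hidden_widths))),
    )
    return TrainedNetwork(spec, seed=seed)


def printed_discriminator_spec() -> NetworkSpec:
    """The discriminator layout exactly as printed in the architecture table.

    Kept for parameter arithmetic only: its 8-wide input and 9-unit sigmoid
    head mirror the generator table row-for-row and cannot produce the
    scalar real/fake probability the value function needs.
    """
    return NetworkSpec(
        input_dim=8,
        layer_widths=(*DISCRIMINATOR_HIDDEN_WIDTHS, 9),
        output_activation="sigmoid",
        dropout_rate=0.2,
        dropout_after=tuple(range(len(DISCRIMINATOR_HIDDEN_WIDTHS))),
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_foggan(
    train: LabeledMatrix,
    cfg: GanTrainConfig = GanTrainConfig(),
    noise: NoiseSpec = NoiseSpec(),
    generator_hidden: tuple[int, ...] = GENERATOR_HIDDEN_WIDTHS,
    discriminator_hidden: tuple[int, ...] = DISCRIMINATOR_HIDDEN_WIDTHS,
) -> tuple[TrainedNetwork, TrainedNetwork, TrainingHistory]:
    """Adversarially train a generator on the features of ``train``.

    ``train`` should carry standardized features (the generator head is
    linear, so the data scale is whatever the scaler produced); labels are
    ignored — train one instance per class for labeled synthesis.  Fully
    reproducible for a fixed config seed.
    """
    X = np.asarray(train.X, dtype=float)
    n, d = X.shape
    if n == 0:
        raise ValueError("training matrix is empty")
    if cfg.batch_size > n:
        raise ValueError(f"batch_size {cfg.batch_size} exceeds training size {n}")

    ss = np.random.SeedSequence(cfg.seed)
    s_ginit, s_dinit, s_shuffle, s_noise, s_dropout = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)
    )
    G = build_generator(noise, generator_hidden, output_dim=d, seed=s_ginit)
    D = build_discriminator(d, discriminator_hidden, seed=s_dinit)
    opt_g = Adam(G, cfg.lr_generator)
    opt_d = Adam(D, cfg.lr_discriminator)
    rng_shuffle = np.random.default_rng(s_shuffle)
    rng_noise = np.random.default_rng(s_noise)
    rng_drop = np.random.default_rng(s_dropout)

    history = TrainingHistory()
    m = cfg.batch_size
    n_batches = n // m
    for epoch in range(cfg.epochs):
        order = rng_shuffle.permutation(n)
        d_losses = np.empty(n_batches)
        g_losses = np.empty(n_batches)
        for b in range(n_batches):
            real = X[order[b * m : (b + 1) * m]]

            # -- discriminator step: maximize log D(x) + log(1 - D(G(z)))
            z = noise.sample(m, rng_noise)
            fake = G.forward(z)  # detached: no G cache kept
            batch = np.vstack([real, fake])
            targets = np.concatenate([np.ones(m), np.zeros(m)])[:, None]
            p = D.forward(batch, training=True, rng=rng_drop)
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            d_loss = -float(
                np.mean(targets * np.log(pc) + (1 - targets) * np.log(1 - pc))
            )
            dlogits = (p - targets) / (2 * m)
            dWs, dbs, _ = D.backward(dlogits)
            opt_d.step(dWs, dbs)

            # -- generator step through a frozen discriminator
            z = noise.sample(m, rng_noise)
            fake = G.forward(z, training=True)
            p = D.forward(fake, training=True, rng=rng_drop)
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            if cfg.generator_loss_mode == "non_saturating":
                g_loss = -float(np.mean(np.log(pc)))
                dlogits = (p - 1.0) / m
            else:  # literal: descend mean log(1 - D(G(z)))
                g_loss = float(np.mean(np.log(1.0 - pc)))
                dlogits = -p / m
            _, _, dfake = D.backward(dlogits)
            dWs, dbs, _ = G.backward(dfake)
            opt_g.step(dWs, dbs)

            d_losses[b] = d_loss
            g_losses[b] = g_loss

        gl, dl = float(g_losses.mean()), float(d_losses.mean())
        if not (np.isfinite(gl) and np.isfinite(dl)):
            raise GanDivergenceError(
                f"non-finite loss at epoch {epoch + 1}: G={gl}, D={dl}"
            )
        history.generator_loss.append(gl)
        history.discriminator_loss.append(dl)
    return G, D, history


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _class_counts(n_total: int, class_mix: Mapping[int, float]) -> dict[int, int]:
    """Largest-remainder apportionment of ``n_total`` rows over classes."""
    if abs(sum(class_mix.values()) - 1.0) > 1e-6:
        raise ValueError("class_mix proportions must sum to 1")
    labels = sorted(class_mix)
    base = {c: int(np.floor(class_mix[c] * n_total)) for c in labels}
    rem = n_total - sum(base.values())
    frac = sorted(labels, key=lambda c: (class_mix[c] * n_total) % 1.0, reverse=True)
    for c in frac[:rem]:
        base[c] += 1
    return base


def sample_synthetic(
    generators: Mapping[int, TrainedNetwork],
    n_total: int,
    class_mix: Mapping[int, float],
    scaler: Scaler,
    seed: int,
    noise: NoiseSpec = NoiseSpec(),
) -> LabeledMatrix:
    """Draw labeled synthetic rows from per-class generators, in original units.

    ``class_mix`` maps labels to proportions (largest-remainder rounding
    makes counts sum exactly to ``n_total``); each class's generator
    produces rows in scaled space which are then inverse-standardized.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not scaler.fitted:
        raise ValueError("scaler must be fitted before sampling")
    missing = [c for c in class_mix if c not in generators]
    if missing:
        raise ValueError(f"missing generator for class(es) {missing}")

    counts = _class_counts(n_total, class_mix)
    ss = np.random.SeedSequence(seed)
    rngs = {
        c: np.random.default_rng(int(s.generate_state(1)[0] % 2**31))
        for c, s in zip(sorted(counts), ss.spawn(len(counts) + 1))
    }
    rng_shuffle = np.random.default_rng(int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))

    xs, ys = [], []
    for c in sorted(counts):
        k = counts[c]
        if k == 0:
            continue
        z = noise.sample(k, rngs[c])
        if z.shape[1] != generators[c].spec.input_dim:
            raise ValueError(
                f"noise dimension {z.shape[1]} does not match generator input "
                f"{generators[c].spec.input_dim} for class {c}"
            )
        xs.append(scaler.inverse_transform(generators[c].forward(z)))
        ys.append(np.full(k, c, dtype=np.int64))
    X = np.vstack(xs)
    y = np.concatenate(ys)
    order = rng_shuffle.permutation(len(y))
    return LabeledMatrix(X[order], y[order], scaled=False)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(net: TrainedNetwork, path: str) -> None:
    """Persist spec and parameters as a single ``.npz`` container."""
    spec = net.spec
    np.savez(
        path,
        input_dim=spec.input_dim,
        layer_widths=np.asarray(spec.layer_widths),
        hidden_activation=spec.hidden_activation,
        output_activation=spec.output_activation,
        dropout_rate=spec.dropout_rate,
        dropout_after=np.asarray(spec.dropout_after, dtype=np.int64),
        **net.parameter_arrays(),
    )


def load_checkpoint(path: str) -> TrainedNetwork:
    with np.load(path, allow_pickle=False) as data:
        spec = NetworkSpec(
            input_dim=int(data["input_dim"]),
            layer_widths=tuple(int(w) for w in data["layer_widths"]),
            hidden_activation=str(data["hidden_activation"]),
            output_activation=str(data["output_activation"]),
            dropout_rate=float(data["dropout_rate"]),
            dropout_after=tuple(int(i) for i in data["dropout_after"]),
        )
        net = TrainedNetwork(spec, seed=0)
        net.load_parameter_arrays({k: data[k] for k in data.files if k[0] in "Wb" and k[1:].isdigit()})
    return net
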