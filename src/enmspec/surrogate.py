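"""Convolutional surrogate mapping inverse-distance matrices to eigenvalues.

Architecture (defaults): three blocks of [5x5 conv with 32 kernels, stride 1,
size-preserving padding -> ReLU -> 2x2 average pool], a flatten, then dense
layers of 512 and 128 units with dropout before, between and after them, and
a 10-unit linear output.  For a 100x100 input the spatial sizes are
100 -> 50 -> 25 -> 12 (floor on the odd size), so the flattened feature
length is 12 * 12 * 32 = 4608.

Training minimizes the mean absolute percentage error with Adagrad
(learning rate 0.008, batch size 400, at most 100 epochs by default).  The
activation, padding and initialization choices are configuration-exposed;
the backend is the pure-NumPy kernel in :mod:`enmspec.nn`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import nn

INPUT_SIZE = 100


@dataclass(frozen=True)
class SurrogateConfig:
    """Architecture and training hyperparameters of the surrogate network."""

    input_size: int = INPUT_SIZE
    n_conv_blocks: int = 3
    kernels_per_block: int = 32
    kernel_size: int = 5
    dense_units: tuple[int, int] = (512, 128)
    n_outputs: int = 10
    dropout_rate: float = 0.25
    optimizer: str = "adagrad"
    learning_rate: float = 0.008
    batch_size: int = 400
    max_epochs: int = 100
    activation: str = "relu"
    seed: int = 0
    #: affine input normalization y = (x - shift) * scale, stored with the
    #: model so training and inference always agree; identity by default
    #: (the reference pipeline feeds raw descriptors)
    input_shift: float = 0.0
    input_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("input_size", "n_conv_blocks", "kernels_per_block",
                     "kernel_size", "n_outputs", "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.optimizer != "adagrad":
            raise ValueError("only the adagrad optimizer is supported")
        if self.activation != "relu":
            raise ValueError("only the relu activation is supported")
        # spatial size after the pooling cascade must stay positive
        if self.feature_size() <= 0:
            raise ValueError(
                f"input size {self.input_size} vanishes after "
                f"{self.n_conv_blocks} pooling stages"
            )
        object.__setattr__(self, "dense_units", tuple(self.dense_units))

    def spatial_sizes(self) -> list[int]:
        """Spatial extent after each conv block (floor division by 2)."""
        sizes = [self.input_size]
        for _ in range(self.n_conv_blocks):
            sizes.append(sizes[-1] // 2)
        return sizes

    def feature_size(self) -> int:
        """Flattened feature length entering the dense stack."""
        side = self.spatial_sizes()[-1]
        return side * side * self.kernels_per_block


@dataclass
class TrainedSurrogate:
    """A trained network plus its configuration and loss history."""

    config: SurrogateConfig
    model: nn.Sequential
    history: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["epoch", "train_mape", "eval_mape"])
    )

    def predict(self, inputs) -> np.ndarray:
        return predict(self, inputs)

    @property
    def n_parameters(self) -> int:
        return self.model.n_parameters()


def build_model(config: SurrogateConfig | None = None) -> nn.Sequential:
    """Instantiate the untrained network from a configuration.

    Weights are initialized Glorot-uniform from ``config.seed``; the output
    layer is linear (targets are positive but unbounded).
    """
    config = config or SurrogateConfig()
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    in_ch = 1
    for block in range(config.n_conv_blocks):
        layers.append(
            nn.Conv2D(
                in_ch,
                config.kernels_per_block,
                config.kernel_size,
                rng,
                needs_input_grad=block > 0,
            )
        )
        layers.append(nn.ReLU())
        layers.append(nn.AvgPool2())
        in_ch = config.kernels_per_block
    layers.append(nn.Flatten())
    features = config.feature_size()
    layers.append(nn.Dropout(config.dropout_rate))
    for units in config.dense_units:
        layers.append(nn.Dense(features, units, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(config.dropout_rate))
        features = units
    layers.append(nn.Dense(features, config.n_outputs, rng))
    return nn.Sequential(layers)


def _as_input_array(inputs, size: int) -> np.ndarray:
    """Coerce descriptors to a float32 (B, size, size, 1) batch."""
    from .descriptor import CoulombMatrix

    if isinstance(inputs, CoulombMatrix):
        inputs = [inputs]
    if isinstance(inputs, (list, tuple)) and inputs and isinstance(inputs[0], CoulombMatrix):
        x = np.stack([m.matrix for m in inputs])
    else:
        x = np.asarray(inputs, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 4 and x.shape[-1] == 1:
        x = x[..., 0]
    if x.ndim != 3 or x.shape[1] != size or x.shape[2] != size:
        raise ValueError(
            f"expected inputs of shape (B, {size}, {size}), got {x.shape}; "
            "the network accepts only its fixed training size"
        )
    return x[..., None].astype(nn.DTYPE)


def input_normalization(train_inputs) -> tuple[float, float]:
    """Affine normalization constants (shift, scale) fitted on a training set.

    Returns the global mean and inverse standard deviation over all entries;
    store them in ``SurrogateConfig(input_shift=..., input_scale=...)`` so
    inference applies the identical transform.
    """
    x = np.asarray(
        train_inputs if not hasattr(train_inputs[0], "matrix")
        else [m.matrix for m in train_inputs],
        dtype=float,
    )
    sd = float(x.std())
    return float(x.mean()), 1.0 / sd if sd > 0 else 1.0


def _normalized(x: np.ndarray, config: SurrogateConfig) -> np.ndarray:
    if config.input_shift == 0.0 and config.input_scale == 1.0:
        return x
    return ((x - config.input_shift) * config.input_scale).astype(nn.DTYPE)


def mape(true, predicted) -> float:
    """Mean absolute percentage error (percent), true values in the denominator."""
    return nn.mape(_as_target_array(true), np.asarray(predicted, dtype=float))


def _as_target_array(targets) -> np.ndarray:
    from .betagm import SpectrumTarget

    if isinstance(targets, SpectrumTarget):
        targets = [targets]
    if isinstance(targets, (list, tuple)) and targets and isinstance(targets[0], SpectrumTarget):
        return np.stack([t.eigenvalues for t in targets])
    return np.asarray(targets, dtype=float)


def train(
    model: nn.Sequential,
    train_inputs,
    train_targets,
    eval_inputs=None,
    eval_targets=None,
    config: SurrogateConfig | None = None,
    *,
    micro_batch: int = 25,
) -> TrainedSurrogate:
    """Train a network on (descriptor, spectrum) pairs.

    Minimizes MAPE with Adagrad at the configured batch size and epoch
    bound; batch shuffling and dropout are seeded from ``config.seed``.
    Gradients of batches larger than ``micro_batch`` are accumulated in
    micro-batches to bound the im2col working set.  Records train and eval
    MAPE per epoch and returns the final-epoch model.
    """
    config = config or SurrogateConfig()
    x = _normalized(_as_input_array(train_inputs, config.input_size), config)
    y = _as_target_array(train_targets).astype(nn.DTYPE)
    if len(x) == 0:
        raise ValueError("empty training set")
    if np.any(y <= 0):
        raise ValueError("training targets must be strictly positive")
    has_eval = eval_inputs is not None and eval_targets is not None
    if has_eval:
        xe = _normalized(_as_input_array(eval_inputs, config.input_size), config)
        ye = _as_target_array(eval_targets)

    rng = np.random.default_rng(config.seed + 1)
    model.set_dropout_rng(rng)
    opt = nn.Adagrad(model.parameters(), lr=config.learning_rate)
    records = []
    n = len(x)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            grads = [np.zeros_like(p) for p in model.parameters()]
            batch_loss = 0.0
            for mstart in range(0, len(idx), micro_batch):
                midx = idx[mstart : mstart + micro_batch]
                pred = model.forward(x[midx], train=True)
                loss, gout = nn.mape_loss_and_grad(y[midx], pred)
                # normalize micro-batch contributions by sample share
                share = len(midx) / len(idx)
                batch_loss += loss * share
                model.backward(gout * nn.DTYPE(share))
                for acc, g in zip(grads, model.gradients()):
                    acc += g
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: check target scale "
                    "and learning rate"
                )
            opt.step(grads)
            epoch_loss += batch_loss * len(idx)
        record = {"epoch": epoch, "train_mape": epoch_loss / n}
        if has_eval:
            record["eval_mape"] = nn.mape(ye, _forward_chunks(model, xe))
        records.append(record)
    history = pd.DataFrame(records)
    if "eval_mape" not in history.columns:
        history["eval_mape"] = np.nan
    return TrainedSurrogate(config=config, model=model, history=history)


def _forward_chunks(model: nn.Sequential, x: np.ndarray, chunk: int = 50) -> np.ndarray:
    out = [model.forward(x[i : i + chunk], train=False) for i in range(0, len(x), chunk)]
    return np.concatenate(out).astype(float)


def predict(surrogate: TrainedSurrogate, inputs) -> np.ndarray:
    """Deterministic forward pass (dropout off); returns (B, n_outputs)."""
    x = _normalized(
        _as_input_array(inputs, surrogate.config.input_size), surrogate.config
    )
    return _forward_chunks(surrogate.model, x)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_surrogate(surrogate: TrainedSurrogate, out_dir: str | Path) -> None:
    """Write config (JSON), weights (NPZ) and history (TSV) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(surrogate.config), indent=2))
    weights = {f"p{i}": p for i, p in enumerate(surrogate.model.parameters())}
    np.savez(out / "weights.npz", **weights)
    surrogate.history.to_csv(out / "history.tsv", sep="\t", index=False)


def load_surrogate(model_dir: str | Path) -> TrainedSurrogate:
    model_dir = Path(model_dir)
    cfg_dict = json.loads((model_dir / "config.json").read_text())
    cfg_dict["dense_units"] = tuple(cfg_dict["dense_units"])
    config = SurrogateConfig(**cfg_dict)
    model = build_model(config)
    with np.load(model_dir / "weights.npz") as data:
        params = model.parameters()
        if len(data.files) != len(params):
            raise ValueError("weight file does not match the architecture")
        for i, p in enumerate(params):
            p[...] = data[f"p{i}"]
    hist_path = model_dir / "history.tsv"
    history = (
        pd.read_csv(hist_path, sep="\t") if hist_path.exists() else pd.DataFrame()
    )
    return TrainedSurrogate(config=config, model=model, history=history)
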