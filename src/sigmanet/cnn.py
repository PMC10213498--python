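"""The dispersal CNN: architecture derivation, training, prediction.

The network has two input branches.  The genotype matrix (``m`` SNPs as the
sequence axis, the ``pad_to`` sample columns as channels) passes through
``floor(log10(m)) - 1`` convolution blocks — 1-D valid convolution with a
kernel spanning two SNPs and every column, stride 1, ReLU, then average
pooling of width 10 — whose filter counts start at 64 and grow by 44 per
block.  The result is flattened through three 128-unit ReLU dense layers,
concatenated with the sampling-width scalar, passed through one more
128-unit ReLU dense layer and a linear unit.  Targets are ``log(sigma)``;
prediction exponentiates the raw output, and the post hoc ``sqrt(3/2)``
correction converts a dispersal-kernel estimate (``sigma_f``) to effective
dispersal when the mating kernel has the same scale.

Training: mean squared error, Adam at initial learning rate 1e-3, batch
size 40, 20% validation holdout.  After ``patience/10`` epochs without
validation improvement the learning rate halves; training stops after
``patience`` epochs without improvement and the best-validation weights
are restored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from . import nnet
from .preprocess import GenotypeMatrix

__all__ = [
    "CNNSpec",
    "TrainingConfig",
    "TrainedModel",
    "build_architecture",
    "train",
    "predict_sigma",
    "correct_sigma",
    "SIGMA_CORRECTION",
]

#: Effective-dispersal correction factor, sqrt(3/2): the mean squared
#: per-axis displacement to a random parent is (3/2) sigma_f^2 when
#: sigma_f == sigma_m.
SIGMA_CORRECTION = float(np.sqrt(1.5))


@dataclass
class CNNSpec:
    """Deterministic architecture description derived from input dimensions."""

    m: int
    pad_to: int
    phased: bool
    num_conv_blocks: int
    filters: tuple[int, ...]
    conv_kernel: int = 2
    pool_width: int = 10
    dense_widths: tuple[int, ...] = (128, 128, 128)
    concat_dense_width: int = 128
    dropout: float = 0.0


@dataclass
class TrainingConfig:
    """Hyperparameters of the fitting schedule."""

    batch_size: int = 40
    learning_rate: float = 1e-3
    patience: int = 100
    validation_fraction: float = 0.2
    dropout: float = 0.0
    max_epochs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 10:
            raise ValueError("patience must be >= 10")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


def build_architecture(m: int, pad_to: int, phased: bool = False,
                       dropout: float = 0.0) -> CNNSpec:
    """Derive the architecture from the genotype-matrix dimensions.

    ``floor(log10(m)) - 1`` convolution blocks with filter counts
    ``64 + 44*k``; fewer than 100 SNPs would give no convolution block and
    raises.
    """
    if m < 100:
        raise ValueError("need m >= 100 SNPs (at least one convolution block)")
    blocks = int(np.floor(np.log10(m))) - 1
    filters = tuple(64 + 44 * k for k in range(blocks))
    # check the sequence axis survives the conv/pool stack
    length = m
    for _ in range(blocks):
        length = (length - 1) // 10
        if length < 1:
            raise ValueError("genotype matrix too short for the derived stack")
    return CNNSpec(m=int(m), pad_to=int(pad_to), phased=bool(phased),
                   num_conv_blocks=blocks, filters=filters, dropout=float(dropout))


class PlateauSchedule:
    """Patience bookkeeping for learning-rate halving and early stopping.

    The learning rate halves after ``patience // 10`` consecutive epochs
    without validation improvement (the counter resets on each halving);
    training stops after ``patience`` consecutive epochs without
    improvement.
    """

    def __init__(self, patience: int, lr: float):
        self.patience = patience
        self.lr_patience = max(1, patience // 10)
        self.lr = lr
        self.best = np.inf
        self._wait_lr = 0
        self._wait_stop = 0

    def update(self, val_loss: float) -> tuple[bool, bool]:
        """Returns ``(improved, stop)`` and adjusts ``self.lr`` in place."""
        if val_loss < self.best - 1e-9:
            self.best = val_loss
            self._wait_lr = 0
            self._wait_stop = 0
            return True, False
        self._wait_lr += 1
        self._wait_stop += 1
        if self._wait_stop >= self.patience:
            return False, True
        if self._wait_lr >= self.lr_patience:
            self.lr *= 0.5
            self._wait_lr = 0
        return False, False


class _Network:
    """Two-branch network materialised from a CNNSpec."""

    def __init__(self, spec: CNNSpec, rng: np.random.Generator):
        self.spec = spec
        layers: list[nnet.Layer] = []
        c_in = spec.pad_to
        length = spec.m
        for f in spec.filters:
            layers.append(nnet.Conv1D(c_in, f, spec.conv_kernel, rng))
            layers.append(nnet.ReLU())
            layers.append(nnet.AvgPool1D(spec.pool_width))
            length = (length - spec.conv_kernel + 1) // spec.pool_width
            c_in = f
        layers.append(nnet.Flatten())
        width = length * c_in
        for w in spec.dense_widths:
            layers.append(nnet.Dense(width, w, rng))
            layers.append(nnet.ReLU())
            if spec.dropout > 0:
                layers.append(nnet.Dropout(spec.dropout, rng))
            width = w
        self.genotype_branch = nnet.Sequential(layers)
        head: list[nnet.Layer] = [nnet.Dense(width + 1, spec.concat_dense_width, rng),
                                  nnet.ReLU()]
        if spec.dropout > 0:
            head.append(nnet.Dropout(spec.dropout, rng))
        head.append(nnet.Dense(spec.concat_dense_width, 1, rng, scale="glorot"))
        self.head = nnet.Sequential(head)

    def forward(self, geno, width, train=False):
        g = self.genotype_branch.forward(geno, train)
        self._gdim = g.shape[1]
        h = np.concatenate([g, width[:, None].astype(np.float32)], axis=1)
        return self.head.forward(h, train)[:, 0]

    def backward(self, gout):
        gh = self.head.backward(gout[:, None])
        self.genotype_branch.backward(gh[:, : self._gdim])

    @property
    def params(self):
        return self.genotype_branch.params + self.head.params

    @property
    def grads(self):
        return self.genotype_branch.grads + self.head.grads

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w


@dataclass
class TrainedModel:
    """Architecture, learned weights, training history and conventions."""

    spec: CNNSpec
    weights: list[np.ndarray]
    history: dict
    target_convention: str  # "log_sigma_f" or "log_effective_sigma"
    sigma_range: tuple[float, float]

    _net: Optional[_Network] = field(default=None, repr=False, compare=False)

    def network(self) -> _Network:
        if self._net is None:
            net = _Network(self.spec, np.random.default_rng(0))
            net.set_weights(self.weights)
            self._net = net
        return self._net

    def save(self, path: str) -> None:
        meta = {
            "spec": asdict(self.spec),
            "history": self.history,
            "target_convention": self.target_convention,
            "sigma_range": list(self.sigma_range),
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz",
                     allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            weights = [z[f"w{i}"] for i in range(len(z.files) - 1)]
        spec_d = meta["spec"]
        spec_d["filters"] = tuple(spec_d["filters"])
        spec_d["dense_widths"] = tuple(spec_d["dense_widths"])
        spec = CNNSpec(**spec_d)
        return cls(spec=spec, weights=weights, history=meta["history"],
                   target_convention=meta["target_convention"],
                   sigma_range=tuple(meta["sigma_range"]))


def _as_inputs(genotypes, widths):
    geno = np.asarray(genotypes, dtype=np.float32)
    if geno.ndim == 2:
        geno = geno[None]
    widths = np.atleast_1d(np.asarray(widths, dtype=np.float32))
    return geno, widths


def train(spec: CNNSpec,
          genotypes: np.ndarray,
          widths: np.ndarray,
          log_targets: np.ndarray,
          config: TrainingConfig,
          groups: Optional[np.ndarray] = None,
          target_convention: str = "log_sigma_f") -> TrainedModel:
    """Fit the CNN on (genotype matrix, width) -> log sigma pairs.

    ``genotypes`` is ``(N, m, pad_to)``; ``groups`` (e.g. the source
    simulation of each example) keeps all examples of one group on the same
    side of the 80/20 train/validation split, preventing leakage between
    samples drawn from the same simulation.
    """
    geno, widths = _as_inputs(genotypes, widths)
    y = np.asarray(log_targets, dtype=np.float32)
    N = geno.shape[0]
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite training targets")
    if N < 2 * config.batch_size:
        raise ValueError("need at least two batches of training data")
    rng = np.random.default_rng(config.seed)
    if spec.dropout != config.dropout:
        spec = CNNSpec(**{**asdict(spec), "dropout": config.dropout})
    net = _Network(spec, rng)

    # 80/20 split (by group when given)
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        val_groups = rng.choice(uniq, size=max(1, int(round(config.validation_fraction * uniq.size))),
                                replace=False)
        val_mask = np.isin(groups, val_groups)
    else:
        perm = rng.permutation(N)
        n_val = max(1, int(round(config.validation_fraction * N)))
        val_mask = np.zeros(N, dtype=bool)
        val_mask[perm[:n_val]] = True
    tr_idx = np.flatnonzero(~val_mask)
    va_idx = np.flatnonzero(val_mask)

    opt = nnet.Adam(net.params, lr=config.learning_rate)
    sched = PlateauSchedule(config.patience, config.learning_rate)
    best_weights = net.get_weights()
    history = {"train_loss": [], "val_loss": [], "lr": []}

    for _epoch in range(config.max_epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for s in range(0, order.size, config.batch_size):
            b = order[s: s + config.batch_size]
            out = net.forward(geno[b], widths[b], train=True)
            err = out - y[b]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss; aborting")
            net.backward((2.0 / b.size) * err.astype(np.float32))
            opt.step(net.grads)
            losses.append(loss)
        val_loss = _eval_loss(net, geno, widths, y, va_idx, config.batch_size)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        improved, stop = sched.update(val_loss)
        opt.lr = sched.lr
        if improved:
            best_weights = net.get_weights()
        if stop:
            break

    net.set_weights(best_weights)
    sig = np.exp(y)
    return TrainedModel(spec=spec, weights=best_weights, history=history,
                        target_convention=target_convention,
                        sigma_range=(float(sig.min()), float(sig.max())),
                        _net=net)


def _eval_loss(net, geno, widths, y, idx, batch_size):
    tot, cnt = 0.0, 0
    for s in range(0, idx.size, batch_size):
        b = idx[s: s + batch_size]
        out = net.forward(geno[b], widths[b], train=False)
        tot += float(np.sum((out - y[b]) ** 2))
        cnt += b.size
    return tot / max(cnt, 1)


def predict_sigma(model: TrainedModel, gm: GenotypeMatrix | np.ndarray,
                  width: float) -> float:
    """Point prediction: exp of the raw network output (strictly positive)."""
    values = gm.values if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    if values.shape != (model.spec.m, model.spec.pad_to):
        raise ValueError(
            f"genotype matrix shape {values.shape} does not match the model "
            f"(expected m={model.spec.m}, pad_to={model.spec.pad_to})")
    geno, w = _as_inputs(values, [width])
    out = model.network().forward(geno, w, train=False)
    return float(np.exp(out[0]))


def predict_sigma_batch(model: TrainedModel, genotypes: np.ndarray,
                        widths: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Vectorised :func:`predict_sigma` over ``(N, m, pad_to)`` inputs."""
    geno, w = _as_inputs(genotypes, widths)
    net = model.network()
    outs = []
    for s in range(0, geno.shape[0], batch_size):
        outs.append(net.forward(geno[s: s + batch_size], w[s: s + batch_size],
                                train=False))
    return np.exp(np.concatenate(outs))


def correct_sigma(sigma_f_pred: float | np.ndarray, enabled: bool = True):
    """Post hoc rescaling from sigma_f to effective dispersal: sqrt(3/2)x."""
    arr = np.asarray(sigma_f_pred, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("sigma must be positive")
    out = arr * (SIGMA_CORRECTION if enabled else 1.0)
    return float(out) if np.isscalar(sigma_f_pred) or arr.ndim == 0 else out
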