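"""Training loop, fold planning and cross-validation orchestration.

Training minimizes mean pixelwise categorical cross-entropy with Adam.  The
published recipe (learning rate 1e-4, batch size 16, 200 epochs) is the
default configuration; desk-scale experiments pass their own.  All shuffling
and initialization derive from explicit seeds, so runs are reproducible on a
fixed BLAS (floating-point reductions may differ across BLAS builds; that is
the only nondeterminism caveat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..osm import IndicatorStack
from .layers import cross_entropy_with_softmax
from .network import NetworkSpec, UNet, build_network


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters; defaults follow the published recipe."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 200
    optimizer: str = "adam"
    loss: str = "categorical-cross-entropy"
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class SegmentedMap:
    """Per-pixel class labels with the class-probability image retained."""

    labels: np.ndarray  # (ny, nx) int
    probabilities: np.ndarray | None = None  # (Nc, ny, nx)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.probabilities is not None:
            self.probabilities = np.asarray(self.probabilities, float)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def train(
    network: UNet,
    inputs: np.ndarray,
    targets: np.ndarray,
    cfg: TrainingConfig = TrainingConfig(),
) -> TrainingHistory:
    """Train in place; returns per-epoch loss history.

    ``inputs``: (N, Nf, H, W) normalized indicator stacks; ``targets``:
    (N, H, W) integer class maps.  A ``validation_fraction`` of the samples is
    held out (seeded split) for the validation curve only; set it to 0 to
    train on everything.  Raises on NaN loss with epoch/batch context.
    """
    inputs = np.ascontiguousarray(inputs, np.float32)
    targets = np.ascontiguousarray(targets, np.int64)
    if len(inputs) == 0:
        raise ValueError("empty dataset")
    if inputs.shape[0] != targets.shape[0] or inputs.shape[2:] != targets.shape[1:]:
        raise ValueError(
            f"inputs {inputs.shape} and targets {targets.shape} are inconsistent"
        )
    if targets.max() >= network.spec.output_classes:
        raise ValueError("target label exceeds the network's class count")

    rng = np.random.default_rng(cfg.seed)
    n = inputs.shape[0]
    n_val = int(round(cfg.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        raise ValueError("validation split left no training samples")

    opt = Adam(network.parameters, cfg.learning_rate)
    hist = TrainingHistory()
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        losses = []
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            network.zero_grad()
            logits = network.forward(inputs[batch])
            loss, dl = cross_entropy_with_softmax(logits, targets[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            network.backward(dl)
            opt.step(network.gradients)
            losses.append(loss)
        hist.train_loss.append(float(np.mean(losses)))
        if n_val:
            vlogits = network.forward(inputs[val_idx])
            vloss, _ = cross_entropy_with_softmax(vlogits, targets[val_idx])
            hist.val_loss.append(float(vloss))
    return hist


def predict(network: UNet, stack: IndicatorStack | np.ndarray) -> SegmentedMap:
    """Segment one indicator stack; argmax labels plus the probability image."""
    if isinstance(stack, IndicatorStack):
        if not stack.normalized:
            raise ValueError("indicator stack must be normalized before prediction")
        x = stack.images()[None]
    else:
        x = np.asarray(stack)
        if x.ndim == 3:
            x = x[None]
    probs = network.predict_proba(x)[0]
    return SegmentedMap(labels=probs.argmax(axis=0), probabilities=probs)


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint near-equal test splits covering every sample exactly once."""

    n_samples: int
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]  # (train, test) per fold

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_folds(n_samples: int, n_folds: int, seed: int) -> FoldPlan:
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_samples < n_folds:
        raise ValueError("need at least one sample per fold")
    perm = np.random.default_rng(seed).permutation(n_samples)
    tests = np.array_split(perm, n_folds)
    folds = []
    for te in tests:
        te_set = set(int(i) for i in te)
        tr = tuple(int(i) for i in range(n_samples) if i not in te_set)
        folds.append((tr, tuple(sorted(te_set))))
    return FoldPlan(n_samples, tuple(folds))


@dataclass
class CrossValidationResult:
    models: list[UNet]
    predictions: dict[int, SegmentedMap]  # sample index -> prediction
    plan: FoldPlan
    histories: list[TrainingHistory]


def run_cross_validation(
    inputs: np.ndarray,
    targets: np.ndarray,
    spec: NetworkSpec,
    cfg: TrainingConfig,
    n_folds: int = 10,
    seed: int = 0,
) -> CrossValidationResult:
    """Train one model per fold; every sample is predicted exactly once."""
    plan = make_folds(inputs.shape[0], n_folds, seed)
    models, histories, predictions = [], [], {}
    for fi, (tr, te) in enumerate(plan.folds):
        net = build_network(spec, seed=seed + fi)
        hist = train(net, inputs[list(tr)], targets[list(tr)], cfg)
        for idx in te:
            predictions[idx] = predict(net, inputs[idx])
        models.append(net)
        histories.append(hist)
    return CrossValidationResult(models, predictions, plan, histories)
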