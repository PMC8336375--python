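"""Supervised training loop for the spectrogram CNN (and toy models).

Protocol: Adam at 3e-4, learning rate divided by 10 after 25 epochs
(step schedule), batch size 16, 50 epochs, softmax cross-entropy over
the two-class output.  All of it is configurable through TrainConfig;
training is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .nn import Adam, Module
from .nn import tensor as T
from .nn.tensor import Tensor


class ClassBalanceError(ValueError):
    pass


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 50
    lr_initial: float = 3e-4
    lr_drop_factor: float = 10.0
    lr_drop_epoch: int = 25
    seed: int = 0

    def __post_init__(self):
        if self.batch_size <= 0 or self.lr_initial <= 0 or self.lr_drop_factor <= 0:
            raise ValueError("batch_size, lr_initial and lr_drop_factor must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.lr_drop_epoch <= 0:
            raise ValueError("lr_drop_epoch must be positive")
        # lr_drop_epoch >= epochs is allowed for short desk-scale runs:
        # the schedule simply never triggers.

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate in force during 0-indexed ``epoch``."""
        if epoch >= self.lr_drop_epoch:
            return self.lr_initial / self.lr_drop_factor
        return self.lr_initial

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainResult:
    model: Module
    loss_curve: list[float] = field(default_factory=list)   # mean loss per epoch
    lr_curve: list[float] = field(default_factory=list)

    def loss_curve_csv(self) -> str:
        lines = ["epoch,mean_loss,lr"]
        lines += [f"{i},{l!r},{lr!r}" for i, (l, lr) in
                  enumerate(zip(self.loss_curve, self.lr_curve))]
        return "\n".join(lines) + "\n"


AugmentFn = Callable[[np.ndarray, np.random.Generator], np.ndarray]


def train_model(model: Module, images: np.ndarray, labels: np.ndarray,
                tc: TrainConfig, augment_fn: AugmentFn | None = None) -> TrainResult:
    """Train ``model`` on (images, labels) under the configured protocol.

    ``images`` is any (N, ...) float array the model's forward accepts
    (the CNN takes (N, H, W) or (N, H, W, 1)); ``labels`` are 0/1 ints.
    ``augment_fn``, if given, perturbs each training batch in place of
    the raw images (evaluation data never passes through here).
    ``epochs = 0`` returns the model untouched with an empty loss curve.
    """
    images = np.asarray(images)
    labels = np.asarray(labels).astype(int)
    if images.shape[0] != labels.shape[0]:
        raise ValueError("images and labels disagree in length")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ClassBalanceError(
            f"training data contains only class {classes.tolist()}; need both classes")
    if images.ndim == 3:
        images = images[..., None]

    params = model.parameters()
    dtype = params[0].dtype if params else np.float32
    rng = np.random.default_rng(tc.seed)
    opt = Adam(params, lr=tc.lr_initial)
    result = TrainResult(model=model)
    n = images.shape[0]

    model.train()
    for epoch in range(tc.epochs):
        opt.lr = tc.lr_at_epoch(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            batch = images[idx]
            if augment_fn is not None:
                batch = augment_fn(batch, rng)
            model.zero_grad()
            logits = model(Tensor(np.ascontiguousarray(batch, dtype=dtype)))
            loss = T.softmax_cross_entropy(logits, labels[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        result.loss_curve.append(float(np.mean(losses)))
        result.lr_curve.append(opt.lr)
    model.eval()
    return result
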