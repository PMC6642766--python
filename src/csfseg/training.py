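"""Loss, learning-rate policy, augmentation and the 2D training loop.

Training pools the axial slices of all training exams into one 2D dataset
and minimizes the generalized dice loss with Adam under a 1cycle learning
rate policy: the rate warms up from ``max_lr / div_initial`` to ``max_lr``
over the first ``pct_start`` of steps and then cosine-anneals to
``max_lr / div_final`` while Adam's β₁ ("momentum") traverses
high → low → high in antiphase. Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import Adam, Tensor
from .model import SegmentationModel
from .preprocess import DEFAULT_WINDOW, preprocess_exam
from .volume_io import CTVolume, MaskVolume

__all__ = [
    "TrainConfig",
    "DESK_TRAIN",
    "OneCycleSchedule",
    "TrainHistory",
    "generalized_dice_loss",
    "one_cycle",
    "augment",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults are the full-scale recipe (Adam, lr 1e-4, 4 epochs, batch 10,
    weight decay 1e-7, 1cycle, generalized dice loss). ``DESK_TRAIN`` carries
    the desk-scale override used when training the small profile from
    scratch on CPU.
    """

    max_lr: float = 1e-4
    epochs: int = 4
    batch_size: int = 10
    weight_decay: float = 1e-7
    optimizer: str = "adam"
    schedule: str = "1cycle"
    loss: str = "generalized_dice"
    mixed_precision: bool = False
    augment: bool = True
    aug_flip_p: float = 0.5
    aug_rotate_deg: float = 10.0
    aug_zoom: tuple[float, float] = (0.9, 1.1)
    pct_start: float = 0.3
    div_initial: float = 25.0
    div_final: float = 1e4
    momentum_high: float = 0.95
    momentum_low: float = 0.85
    window: tuple[float, float] = DEFAULT_WINDOW
    seed: int = 0

    def __post_init__(self):
        if self.max_lr <= 0:
            raise ValueError("max_lr must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


#: desk-scale training override: from-scratch peak rate for the small profile
DESK_TRAIN = TrainConfig(max_lr=1e-2)


@dataclass(frozen=True)
class OneCycleSchedule:
    total_steps: int
    pct_start: float = 0.3
    div_initial: float = 25.0
    div_final: float = 1e4
    momentum_high: float = 0.95
    momentum_low: float = 0.85

    def __post_init__(self):
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        if not 0 < self.pct_start < 1:
            raise ValueError("pct_start must be in (0, 1)")

    @classmethod
    def from_config(cls, config: TrainConfig, total_steps: int) -> "OneCycleSchedule":
        return cls(
            total_steps=total_steps,
            pct_start=config.pct_start,
            div_initial=config.div_initial,
            div_final=config.div_final,
            momentum_high=config.momentum_high,
            momentum_low=config.momentum_low,
        )


def one_cycle(step: float, schedule: OneCycleSchedule, max_lr: float) -> tuple[float, float]:
    """Learning rate and momentum at ``step`` (0 ≤ step ≤ total_steps).

    Cosine warm-up to the single peak at ``pct_start·total_steps``, cosine
    anneal after it; momentum moves high → low → high in antiphase.
    """
    if not 0 <= step <= schedule.total_steps:
        raise ValueError(f"step {step} outside [0, {schedule.total_steps}]")
    t_peak = schedule.pct_start * schedule.total_steps
    lr0 = max_lr / schedule.div_initial
    lr_end = max_lr / schedule.div_final
    if step <= t_peak:
        s = step / t_peak if t_peak > 0 else 1.0
        w = (1 - math.cos(math.pi * s)) / 2
        lr = lr0 + (max_lr - lr0) * w
        mom = schedule.momentum_high + (schedule.momentum_low - schedule.momentum_high) * w
    else:
        s = (step - t_peak) / (schedule.total_steps - t_peak)
        w = (1 + math.cos(math.pi * s)) / 2
        lr = lr_end + (max_lr - lr_end) * w
        mom = schedule.momentum_low + (schedule.momentum_high - schedule.momentum_low) * (1 - w)
    return lr, mom


def generalized_dice_loss(probs, target, eps: float = 1e-7, validate: bool = True) -> Tensor:
    """Generalized dice loss in [0, 1].

    ``GDL = 1 − (2 Σ_l w_l Σ_n r_ln p_ln + ε) / (Σ_l w_l Σ_n (r_ln + p_ln) + ε)``
    with class weights ``w_l = 1 / ((Σ_n r_ln)² + ε)`` — inverse squared class
    volume, which rebalances the loss when CSF occupies a tiny fraction of
    the voxels. ``r`` is the one-hot target, ``p`` the predicted probability.
    Accepts ``(C, ...)`` or batched ``(B, C, ...)`` tensors (class axis 1
    when 4D); a perfect one-hot prediction gives exactly 0.
    """
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=np.float64))
    r = np.asarray(target.data if isinstance(target, Tensor) else target, dtype=np.float64)
    if p.shape != r.shape:
        raise ValueError(f"probs shape {p.shape} != target shape {r.shape}")
    class_axis = 1 if p.ndim >= 4 else 0
    if validate:
        if not np.isin(np.unique(r), (0.0, 1.0)).all() or not np.allclose(
            r.sum(axis=class_axis), 1.0
        ):
            raise ValueError("target must be one-hot along the class axis")
    n_classes = p.shape[class_axis]
    if class_axis != 0:
        p = p.swapaxes(0, class_axis)
        r = np.moveaxis(r, class_axis, 0)
    p = p.reshape(n_classes, -1)
    r = r.reshape(n_classes, -1)
    w = 1.0 / (r.sum(axis=1) ** 2 + eps)
    inter = (p * r).sum(axis=1)
    denom = p.sum(axis=1) + Tensor(r.sum(axis=1))
    num = 2.0 * (inter * w).sum() + eps
    den = (denom * w).sum() + eps
    return 1.0 - num / den


@dataclass
class TrainHistory:
    """Per-step training log."""

    step: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    momentum: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)

    def append(self, step: int, lr: float, momentum: float, loss: float) -> None:
        self.step.append(step)
        self.lr.append(lr)
        self.momentum.append(momentum)
        self.loss.append(loss)

    def epoch_mean_loss(self, steps_per_epoch: int) -> list[float]:
        losses = np.asarray(self.loss)
        return [
            float(losses[i : i + steps_per_epoch].mean())
            for i in range(0, len(losses), steps_per_epoch)
        ]


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Identical random geometric transform applied to an image/mask pair.

    Horizontal flip with probability ``aug_flip_p``, rotation within
    ``±aug_rotate_deg`` and isotropic zoom within ``aug_zoom``. The image is
    resampled bilinearly, the mask nearest-neighbour so it stays binary.
    """
    if not config.augment:
        return image, mask
    image = np.asarray(image)
    mask = np.asarray(mask)
    flip = rng.random() < config.aug_flip_p
    angle = rng.uniform(-config.aug_rotate_deg, config.aug_rotate_deg)
    zoom = rng.uniform(*config.aug_zoom)
    if flip:
        image = image[..., ::-1]
        mask = mask[..., ::-1]
    theta = math.radians(angle)
    # output→input map: rotate by θ and scale by 1/zoom about the center
    m = (np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
         / zoom)
    center = (np.asarray(mask.shape, dtype=float) - 1) / 2
    offset = center - m @ center
    channels = image if image.ndim == 3 else image[None]
    out = np.stack(
        [ndimage.affine_transform(c, m, offset=offset, order=1, mode="constant", cval=0.0)
         for c in channels]
    )
    out_img = out if image.ndim == 3 else out[0]
    out_mask = ndimage.affine_transform(
        mask.astype(np.float32), m, offset=offset, order=0, mode="constant", cval=0.0
    )
    return out_img.astype(image.dtype, copy=False), (out_mask > 0.5).astype(mask.dtype)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def train(
    model: SegmentationModel,
    exams: list[tuple[CTVolume, MaskVolume]],
    config: TrainConfig,
) -> tuple[SegmentationModel, TrainHistory]:
    """Train on the pooled 2D slices of ``exams``; returns per-step history.

    Slices from all exams are pooled and uniformly shuffled each epoch
    (seeded); total 1cycle steps = epochs × ⌈n_slices / batch_size⌉.
    """
    if not exams:
        raise ValueError("training requires at least one exam")
    if config.epochs < 1:
        raise ValueError("epochs must be >= 1")

    xs, ys = [], []
    for ct, mask in exams:
        if ct.shape != mask.shape:
            raise ValueError(f"exam {ct.exam_id}: volume/mask shape mismatch")
        xs.append(preprocess_exam(ct, *config.window))
        ys.append(mask.labels)
    X = np.concatenate(xs, axis=0).astype(np.float32)
    Y = np.concatenate(ys, axis=0)
    n = X.shape[0]

    rng = np.random.default_rng(config.seed)
    steps_per_epoch = math.ceil(n / config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    schedule = OneCycleSchedule.from_config(config, total_steps)
    opt = Adam(model.parameters(), weight_decay=config.weight_decay)
    history = TrainHistory()
    n_classes = model.config.n_classes

    model.train()
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx].copy()
            yb = Y[idx].copy()
            if config.augment:
                for i in range(len(idx)):
                    xb[i], yb[i] = augment(xb[i], yb[i], config, rng)
            if config.mixed_precision:
                xb = xb.astype(np.float16).astype(np.float32)
            lr, mom = one_cycle(step, schedule, config.max_lr)
            opt.lr, opt.beta1 = lr, mom
            probs = model(Tensor(xb))
            loss = generalized_dice_loss(probs, _one_hot(yb, n_classes), validate=False)
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(step, lr, mom, loss.item())
            step += 1
    return model, history
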