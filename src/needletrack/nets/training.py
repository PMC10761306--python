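"""Training recipe, checkpointing and inference for the segmentation nets.

The recipe mirrors the study configuration — AdamW, learning rate 0.001,
batch size 2, iteration-counted training with the lowest-validation-loss
checkpoint kept — at a desk-scale iteration budget.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._autograd import Tensor, no_grad
from .models import NetworkSpec, build_network

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "AdamW",
    "multi_bce_loss",
    "bce_loss",
    "train",
    "predict",
    "load_split_arrays",
]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    input_size: int = 256
    learning_rate: float = 0.001
    weight_decay: float = 0.01
    iterations: int = 20000
    batch_size: int = 2
    loss: str = "multi_bce"  # "multi_bce" for the nested-U variant, "bce" otherwise
    eval_every: int | None = None  # default: iterations // 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_size, self.iterations, self.batch_size) < 1:
            raise ValueError("input_size, iterations and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss not in ("multi_bce", "bce"):
            raise ValueError("loss must be 'multi_bce' or 'bce'")

    @property
    def validation_interval(self) -> int:
        return self.eval_every or max(self.iterations // 10, 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def bce_loss(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    """Pixel-mean binary cross-entropy on a probability map."""
    t = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=np.float32))
    if t.shape != pred.shape:
        raise ValueError(f"shape mismatch: prediction {pred.shape}, target {t.shape}")
    return -((t * pred.log()) + ((1.0 - t) * (1.0 - pred).log())).mean()


def multi_bce_loss(
    side_outputs: Sequence[Tensor],
    fused: Tensor | None,
    target: np.ndarray | Tensor,
) -> Tensor:
    """Equal-weight sum of pixel-mean BCE over every side output plus the fused map.

    With a single map and no fusion this reduces to plain BCE.
    """
    maps = list(side_outputs) + ([fused] if fused is not None else [])
    if not maps:
        raise ValueError("at least one output map is required")
    total = bce_loss(maps[0], target)
    for m in maps[1:]:
        total = total + bce_loss(m, target)
    return total


class AdamW(object):
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=0.001, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)


@dataclasses.dataclass
class Checkpoint:
    """Trained weights plus an echo of how they were produced."""

    state: dict[str, np.ndarray]
    spec: NetworkSpec
    config: TrainConfig
    best_val_loss: float
    iteration_of_best: int
    history: list[dict]

    def save(self, path: str | Path) -> None:
        header = json.dumps(
            {
                "spec": self.spec.to_dict(),
                "config": self.config.to_dict(),
                "best_val_loss": self.best_val_loss,
                "iteration_of_best": self.iteration_of_best,
                "history": self.history,
            }
        )
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **self.state)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            state = {k: z[k] for k in z.files if k != "__header__"}
        return cls(
            state=state,
            spec=NetworkSpec.from_dict(header["spec"]),
            config=TrainConfig(**header["config"]),
            best_val_loss=header["best_val_loss"],
            iteration_of_best=header["iteration_of_best"],
            history=header["history"],
        )

    def build_model(self):
        model = build_network(self.spec, seed=self.config.seed)
        model.load_state_dict(self.state)
        model.eval()
        return model

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


def _resize(img: np.ndarray, size: tuple[int, int], order: int) -> np.ndarray:
    if img.shape == size:
        return img.astype(np.float32)
    from skimage.transform import resize

    return resize(img, size, order=order, anti_aliasing=False, preserve_range=True).astype(
        np.float32
    )


def load_split_arrays(
    manifest: pd.DataFrame | str | Path, split: str, input_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Load one split of a dataset manifest into (images, masks) arrays.

    Returns float32 arrays shaped (n, input_size, input_size, 1); images are in
    [0, 1], masks are exactly 0/1. Rows flagged as empty-mask are skipped.
    """
    from ..imgform import load_image
    from ..pagt import BinaryNeedleMask

    df = manifest if isinstance(manifest, pd.DataFrame) else pd.read_csv(manifest)
    rows = df[df["split"] == split]
    if "flag_empty" in rows.columns:
        rows = rows[~rows["flag_empty"].astype(bool)]
    imgs, masks = [], []
    for _, row in rows.iterrows():
        img = _resize(load_image(row["path_us"]), (input_size, input_size), order=1)
        mask = _resize(
            BinaryNeedleMask.load(row["path_mask"]).pixels.astype(np.float32),
            (input_size, input_size),
            order=0,
        )
        imgs.append(img)
        masks.append(mask)
    if not imgs:
        return (
            np.zeros((0, input_size, input_size, 1), np.float32),
            np.zeros((0, input_size, input_size, 1), np.float32),
        )
    return np.stack(imgs)[..., None], (np.stack(masks)[..., None] > 0.5).astype(np.float32)


def _loss_for(model, x: np.ndarray, t: np.ndarray, loss_kind: str) -> Tensor:
    fused, sides = model(Tensor(x))
    if loss_kind == "multi_bce":
        return multi_bce_loss(sides, fused, t)
    return bce_loss(fused, t)


def _validation_loss(model, val_x, val_t, loss_kind: str, batch_size: int) -> float:
    model.eval()
    losses = []
    with no_grad():
        for lo in range(0, len(val_x), batch_size):
            batch = slice(lo, lo + batch_size)
            losses.append(float(_loss_for(model, val_x[batch], val_t[batch], loss_kind).data))
    model.train()
    return float(np.mean(losses))


def train(
    model,
    manifest: pd.DataFrame | str | Path,
    cfg: TrainConfig,
    log_path: str | Path | None = None,
    verbose: bool = False,
) -> Checkpoint:
    """Train a model on a dataset manifest and return the best checkpoint.

    Iterates ``cfg.iterations`` optimizer steps over shuffled training
    batches, evaluating the validation loss every ``cfg.validation_interval``
    steps; the weights with the lowest validation loss are kept.
    """
    train_x, train_t = load_split_arrays(manifest, "train", cfg.input_size)
    val_x, val_t = load_split_arrays(manifest, "val", cfg.input_size)
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError(
            f"manifest must provide non-empty train and val splits "
            f"(got {len(train_x)} train, {len(val_x)} val)"
        )

    rng = np.random.default_rng(cfg.seed)
    optimizer = AdamW(
        model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay
    )
    model.train()

    best_state: dict | None = None
    best_val = float("inf")
    best_iter = 0
    history: list[dict] = []
    order = rng.permutation(len(train_x))
    cursor = 0

    for iteration in range(1, cfg.iterations + 1):
        if cursor + cfg.batch_size > len(order):
            order = rng.permutation(len(train_x))
            cursor = 0
        idx = order[cursor : cursor + cfg.batch_size]
        cursor += cfg.batch_size

        loss = _loss_for(model, train_x[idx], train_t[idx], cfg.loss)
        loss_value = float(loss.data)
        if not np.isfinite(loss_value):
            raise RuntimeError(f"non-finite training loss at iteration {iteration}")
        model.zero_grad()
        loss.backward()
        optimizer.step()

        if iteration % cfg.validation_interval == 0 or iteration == cfg.iterations:
            val_loss = _validation_loss(model, val_x, val_t, cfg.loss, cfg.batch_size)
            if not np.isfinite(val_loss):
                raise RuntimeError(f"non-finite validation loss at iteration {iteration}")
            history.append(
                {"iteration": iteration, "train_loss": loss_value, "val_loss": val_loss}
            )
            if val_loss < best_val:
                best_val = val_loss
                best_iter = iteration
                best_state = model.state_dict()
            if verbose:
                print(f"iter {iteration}: train {loss_value:.4f} val {val_loss:.4f}")

    assert best_state is not None
    if log_path is not None:
        pd.DataFrame(history).to_csv(log_path, index=False)
    return Checkpoint(
        state=best_state,
        spec=model.spec,
        config=cfg,
        best_val_loss=best_val,
        iteration_of_best=best_iter,
        history=history,
    )


def predict(
    checkpoint_or_model,
    us_image,
    binarize_threshold: float = 0.5,
    input_size: int | None = None,
):
    """Run inference on one US image.

    Returns ``(mask, probability_map)`` where the probability map is mapped
    back to the input image geometry and the mask is ``prob >=
    binarize_threshold``.
    """
    from ..imgform import BScanImage
    from ..pagt import BinaryNeedleMask

    if isinstance(checkpoint_or_model, Checkpoint):
        model = checkpoint_or_model.build_model()
        input_size = input_size or checkpoint_or_model.config.input_size
    else:
        model = checkpoint_or_model
    values = us_image.values if isinstance(us_image, BScanImage) else np.asarray(us_image)
    if values.ndim != 2:
        raise ValueError("us_image must be 2-D")
    orig_shape = values.shape

    size = input_size or orig_shape[0]
    d = model.size_divisor
    size = max(d, ((size + d - 1) // d) * d)
    x = _resize(values.astype(np.float32), (size, size), order=1)[None, ..., None]

    model.eval()
    with no_grad():
        fused, _ = model(Tensor(x))
    prob = fused.data[0, :, :, 0].astype(np.float64)
    prob = _resize(prob, orig_shape, order=1).astype(np.float64)
    mask = BinaryNeedleMask(prob >= binarize_threshold)
    return mask, prob
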