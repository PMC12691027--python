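"""Training schedule, loop, and multi-seed orchestration.

The reference protocol: AdamW (weight decay 0.05), linear warm-up over
the first 3 epochs from lr_init/100, cosine annealing from 1e-3 down to
1e-5 across the remaining epochs, gradient clipping at global norm 1.0,
batch size 16, up to 100 epochs with early stopping after 15 epochs
without validation-mAP improvement, and the weights from the best
validation epoch retained.  Repeated runs use the seed triple
(42, 3407, 2025) and are aggregated as mean ± sd with a t-distribution
confidence interval.
"""

from __future__ import annotations

import copy
import csv
import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import losses as L
from .data import AugmentPolicy, augment
from .metrics import summarize, t_confidence_interval
from .model import STRIDES, DetectorModel, predict
from .nn import AdamW, clip_grad_norm
from .types import ImageRecord

DEFAULT_SEEDS = (42, 3407, 2025)


@dataclass
class TrainSchedule:
    epochs: int = 100
    batch_size: int = 16
    lr_init: float = 1e-3
    lr_final: float = 1e-5
    warmup_epochs: float = 3.0
    weight_decay: float = 0.05
    grad_clip_norm: float = 1.0
    early_stop_patience: int = 15
    seed: int = 42
    val_interval: int = 1
    eval_conf_threshold: float = 0.10

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr_init", "lr_final",
                     "warmup_epochs", "weight_decay", "grad_clip_norm",
                     "early_stop_patience"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")


def lr_at(schedule: TrainSchedule, epoch: float) -> float:
    """Learning rate at a (fractional) epoch.

    Linear ramp from lr_init/100 to lr_init over the warm-up epochs, then
    cosine decay to lr_final at the final epoch; monotone non-increasing
    after warm-up.
    """
    w = schedule.warmup_epochs
    if epoch < w:
        frac = epoch / w
        return schedule.lr_init * (0.01 + 0.99 * frac)
    span = max(schedule.epochs - w, 1e-9)
    t = min((epoch - w) / span, 1.0)
    return schedule.lr_final + 0.5 * (schedule.lr_init - schedule.lr_final) \
        * (1.0 + math.cos(math.pi * t))


def should_stop(val_history: Sequence[float], patience: int) -> bool:
    """True once the last ``patience`` validation scores failed to improve
    on the best score seen before them."""
    if len(val_history) <= patience:
        return False
    best = -math.inf
    since_best = 0
    for v in val_history:
        if v > best:
            best = v
            since_best = 0
        else:
            since_best += 1
    return since_best >= patience


def _records_to_arrays(records: Sequence[ImageRecord]
                       ) -> Tuple[np.ndarray, List[Tuple[np.ndarray, np.ndarray]]]:
    imgs = np.stack([r.pixels.transpose(2, 0, 1) for r in records]).astype(np.float32)
    size_h, size_w = records[0].pixels.shape[:2]
    gts = []
    for r in records:
        boxes = np.array([b.to_xyxy() for _, b in r.annotations],
                         dtype=np.float64).reshape(-1, 4)
        boxes[:, [0, 2]] *= size_w
        boxes[:, [1, 3]] *= size_h
        cls = np.array([c for c, _ in r.annotations], dtype=np.int64)
        gts.append((boxes, cls))
    return imgs, gts


def evaluate_records(model: DetectorModel, records: Sequence[ImageRecord],
                     conf_threshold: float = 0.10):
    """Run the detector over records and summarize against their labels."""
    dets = [predict(model, r.pixels, conf_threshold=conf_threshold,
                    iou_threshold=0.7) for r in records]
    gts = [list(r.annotations) for r in records]
    return summarize(dets, gts)


def train_model(model: DetectorModel,
                train_records: Sequence[ImageRecord],
                val_records: Sequence[ImageRecord],
                schedule: TrainSchedule,
                loss_weights: Optional[Dict[str, float]] = None,
                augment_policy: Optional[AugmentPolicy] = None,
                max_iterations: Optional[int] = None,
                verbose: bool = False) -> Tuple[DetectorModel, List[dict]]:
    """Train to the best-validation checkpoint with early stopping.

    Every source of randomness (batch order, on-the-fly augmentation)
    derives from ``schedule.seed``; the returned history has one row per
    epoch with the learning rate, loss components, and validation mAP.
    """
    if len(train_records) == 0 or len(val_records) == 0:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(schedule.seed)
    opt = AdamW(model.parameters(), lr=schedule.lr_init,
                weight_decay=schedule.weight_decay)
    strides = {l: STRIDES[l] for l in model.head_levels}
    history: List[dict] = []
    val_scores: List[float] = []
    best_state, best_score = None, -math.inf
    n = len(train_records)
    iters_per_epoch = max(1, math.ceil(n / schedule.batch_size))
    iteration = 0
    for epoch in range(schedule.epochs):
        order = rng.permutation(n)
        ep_losses = []
        for it in range(iters_per_epoch):
            idx = order[it * schedule.batch_size:(it + 1) * schedule.batch_size]
            if idx.size == 0:
                continue
            batch = [train_records[i] for i in idx]
            if augment_policy is not None:
                batch = [augment(r, rng, augment_policy) for r in batch]
            imgs, gts = _records_to_arrays(batch)
            opt.lr = lr_at(schedule, epoch + it / iters_per_epoch)
            outputs = model.forward(imgs)
            total, breakdown = L.detection_loss(
                outputs, gts, model.cfg.reg_max, strides,
                weights=loss_weights)
            model.zero_grad()
            total.backward()
            clip_grad_norm(model.parameters(), schedule.grad_clip_norm)
            opt.step()
            ep_losses.append(breakdown)
            iteration += 1
            if max_iterations is not None and iteration >= max_iterations:
                break
        mean = lambda k: float(np.mean([getattr(b, k) for b in ep_losses])) \
            if ep_losses else float("nan")
        row = {"epoch": epoch, "lr": opt.lr,
               "loss_box": mean("box"), "loss_cls": mean("cls"),
               "loss_dfl": mean("dfl"), "loss_total": mean("total"),
               "val_map50": float("nan"), "val_map50_95": float("nan")}
        last = (epoch == schedule.epochs - 1
                or (max_iterations is not None and iteration >= max_iterations))
        if epoch % schedule.val_interval == 0 or last:
            report = evaluate_records(model, val_records,
                                      schedule.eval_conf_threshold)
            row["val_map50"] = report.map50
            row["val_map50_95"] = report.map50_95
            val_scores.append(report.map50)
            if report.map50 > best_score:
                best_score = report.map50
                best_state = copy.deepcopy(model.state_dict())
        history.append(row)
        if verbose:
            print(f"epoch {epoch}: lr={row['lr']:.2e} "
                  f"loss={row['loss_total']:.3f} val_map50={row['val_map50']:.3f}")
        if last or should_stop(val_scores, schedule.early_stop_patience):
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def history_to_csv(history: List[dict], path) -> None:
    cols = ["epoch", "lr", "loss_box", "loss_cls", "loss_dfl", "loss_total",
            "val_map50", "val_map50_95"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for row in history:
            writer.writerow({k: row.get(k) for k in cols})


@dataclass
class SeedAggregate:
    values: List[float]
    mean: float = float("nan")
    sd: float = float("nan")
    ci_half_width: float = float("nan")
    level: float = 0.95

    def formatted(self) -> str:
        return f"{self.mean:.3f} ± {self.sd:.3f}"


def multi_seed_run(config: dict, seeds: Sequence[int] = DEFAULT_SEEDS,
                   runner: Optional[Callable[[dict, int], float]] = None,
                   level: float = 0.95) -> Tuple[Dict[int, float], SeedAggregate]:
    """Repeat a run per seed and aggregate mean ± sd with a t-interval.

    ``runner(config, seed)`` returns the headline metric of one run;
    with a single seed the aggregate is omitted with a warning.
    """
    import logging
    runner = runner or _default_runner
    per_seed = {int(s): float(runner(config, int(s))) for s in seeds}
    values = list(per_seed.values())
    agg = SeedAggregate(values=values, level=level)
    if len(values) < 2:
        logging.getLogger(__name__).warning(
            "only one seed supplied; aggregate statistics omitted")
        return per_seed, agg
    mean, half = t_confidence_interval(values, level)
    agg.mean = mean
    agg.sd = float(np.std(values, ddof=1))
    agg.ci_half_width = half
    return per_seed, agg


def _default_runner(config: dict, seed: int) -> float:
    """Small end-to-end run: synthesize, train briefly, report val mAP50."""
    from .config import ModelConfig
    from .model import build_model
    from .scenes import SceneSpec, generate_dataset

    model_cfg = dict(config.get("model", {}))
    model_cfg["seed"] = seed
    sched_kwargs = dict(config.get("schedule", {}))
    sched_kwargs.pop("seeds", None)
    sched_kwargs["seed"] = seed
    schedule = TrainSchedule(**sched_kwargs)
    n_images = int(config.get("n_images", 48))
    spec = SceneSpec(canvas_size=model_cfg.get("input_size", 96))
    records, _ = generate_dataset(n_images, spec, seed)
    n_val = max(1, n_images // 5)
    train_recs, val_recs = records[n_val:], records[:n_val]
    model = build_model(ModelConfig(**model_cfg))
    model, history = train_model(model, train_recs, val_recs, schedule)
    best = max(h["val_map50"] for h in history
               if not math.isnan(h["val_map50"]))
    return best
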