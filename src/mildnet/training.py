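"""Training loop, cross-validation, grid search, saliency and significance tests.

Defaults follow the grid-search optimum used throughout: Adam (first
moment decay 0.9) at learning rate 1e-3 with reduce-on-plateau
scheduling (factor 0.1, patience 10, driven by validation loss), batch
size 4, 100 epochs, binary cross-entropy with logits as the loss. The
protocol is 70/30 image-level train/test splitting with 5-fold cross
validation inside the training portion; each fold's model is evaluated
on the one fixed test set and the per-metric mean ± std across the five
models is the final score.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from skimage.transform import resize

from . import nn
from .data import AugmentationConfig, Augmenter, ImageSample, SplitPlan
from .metrics import MetricsReport, binarize, score_pair
from .networks import ArchitectureConfig, NetworkModel, build_network, predict_mask
from .nn.autograd import Tensor, _stable_sigmoid
from .nn.optim import OPTIMIZERS, SCHEDULERS, ReduceLROnPlateau


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    momentum: float = 0.9  # Adam first-moment decay / SGD momentum
    scheduler: str = "reduce_on_plateau"
    batch_size: int = 4
    epochs: int = 100
    seed: int = 0
    augmentation: bool = False
    augmentation_config: AugmentationConfig | None = None
    max_steps: int | None = None  # optional hard cap on gradient steps
    target_train_dc: float | None = None  # optional early stop once reached
    plateau_factor: float = 0.1
    plateau_patience: int = 10

    def __post_init__(self):
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.scheduler not in SCHEDULERS:
            raise ValueError(f"unknown scheduler {self.scheduler!r}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


@dataclass
class RunHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_dc: list[float] = field(default_factory=list)
    val_dc: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = math.inf
    best_state: dict | None = None


def _to_batch(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([s.image.transpose(2, 0, 1) for s in samples])
    masks = np.stack([s.mask for s in samples])[:, None].astype(float)
    return imgs, masks


def _batch_dice(prob: np.ndarray, target: np.ndarray) -> float:
    pred = prob >= 0.5
    tgt = target >= 0.5
    inter = (pred & tgt).sum()
    total = pred.sum() + tgt.sum()
    return 1.0 if total == 0 else 2.0 * inter / total


def _make_optimizer(model: NetworkModel, config: TrainingConfig):
    cls = OPTIMIZERS[config.optimizer]
    if config.optimizer == "sgd":
        return cls(model.parameters(), lr=config.learning_rate, momentum=config.momentum)
    if config.optimizer == "adam":
        return cls(model.parameters(), lr=config.learning_rate, beta1=config.momentum)
    return cls(model.parameters(), lr=config.learning_rate, momentum=config.momentum)


def _make_scheduler(optimizer, config: TrainingConfig):
    if config.scheduler == "reduce_on_plateau":
        return ReduceLROnPlateau(optimizer, factor=config.plateau_factor,
                                 patience=config.plateau_patience)
    return SCHEDULERS[config.scheduler](optimizer)


def train_model(model: NetworkModel, train_samples: list[ImageSample],
                val_samples: list[ImageSample], config: TrainingConfig,
                ) -> tuple[NetworkModel, RunHistory]:
    """Optimize BCE-with-logits; fully deterministic under ``config.seed``."""
    if not train_samples:
        raise TrainingError("empty training set")
    if not val_samples:
        raise TrainingError("empty validation set")

    rng = np.random.default_rng(config.seed)
    augmenter = None
    if config.augmentation:
        aug_cfg = config.augmentation_config or AugmentationConfig()
        augmenter = Augmenter(aug_cfg, int(rng.integers(2 ** 31)))

    optimizer = _make_optimizer(model, config)
    scheduler = _make_scheduler(optimizer, config)
    history = RunHistory()
    steps_done = 0
    n = len(train_samples)

    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses, epoch_dcs = [], []
        for start in range(0, n, config.batch_size):
            batch = [train_samples[i] for i in order[start:start + config.batch_size]]
            if augmenter is not None:
                batch = [augmenter(s) for s in batch]
            x, y = _to_batch(batch)
            logits = model(Tensor(x))
            loss = nn.bce_with_logits(logits, y)
            loss_val = loss.item()
            if not math.isfinite(loss_val):
                raise TrainingError(
                    f"non-finite loss {loss_val} at epoch {epoch}, step {steps_done}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss_val)
            prob = _stable_sigmoid(logits.data)
            epoch_dcs.append(_batch_dice(prob, y))
            steps_done += 1
            if config.max_steps is not None and steps_done >= config.max_steps:
                break

        val_loss, val_dc = _validate(model, val_samples, config.batch_size)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.train_dc.append(float(np.mean(epoch_dcs)))
        history.val_loss.append(val_loss)
        history.val_dc.append(val_dc)
        history.lr_trace.append(optimizer.lr)
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            history.best_state = model.state_dict()
        scheduler.step(val_loss)
        if config.max_steps is not None and steps_done >= config.max_steps:
            break
        if (config.target_train_dc is not None
                and history.train_dc[-1] >= config.target_train_dc):
            break

    return model, history


def _validate(model: NetworkModel, samples: list[ImageSample],
              batch_size: int) -> tuple[float, float]:
    model.eval()
    losses, dcs = [], []
    with nn.no_grad():
        for start in range(0, len(samples), batch_size):
            x, y = _to_batch(samples[start:start + batch_size])
            logits = model(Tensor(x))
            losses.append(nn.bce_with_logits(logits, y).item())
            prob = _stable_sigmoid(logits.data)
            dcs.append(_batch_dice(prob, y))
    return float(np.mean(losses)), float(np.mean(dcs))


def evaluate_model(model: NetworkModel, samples: list[ImageSample],
                   batch_size: int = 4) -> MetricsReport:
    """Predict, binarize at 0.5, and score DC/IoU/HD per sample."""
    if not samples:
        raise TrainingError("empty evaluation set")
    rows = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        x, _ = _to_batch(chunk)
        prob = predict_mask(model, x)
        for s, p in zip(chunk, prob):
            rows.append(score_pair(s.id, s.mask, binarize(p[0])))
    return MetricsReport(per_sample=rows)


# ----------------------------------------------------------------------
# cross validation

@dataclass
class CVResult:
    per_round: list[MetricsReport]
    histories: list[RunHistory]
    validation_folds: list[int]

    def metric_values(self, metric: str) -> list[float]:
        """Per-round test-set means of one metric ('dc' | 'iou' | 'hd')."""
        return [r.aggregate[metric][0] for r in self.per_round]

    @property
    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for metric in ("dc", "iou", "hd"):
            vals = np.array(self.metric_values(metric))
            out[metric] = (float(vals.mean()), float(vals.std(ddof=0)))
        return out


def run_cross_validation(samples: list[ImageSample], plan: SplitPlan,
                         arch: ArchitectureConfig, config: TrainingConfig,
                         rounds: int | None = None) -> CVResult:
    """Train one model per CV round and evaluate each on the fixed test set.

    Round k uses fold k as validation and the remaining folds for
    training; ``rounds`` (default: plan.folds) allows a degenerate
    shorter protocol for smoke testing.
    """
    by_id = {s.id: s for s in samples}
    missing = set(plan.assignments) - set(by_id)
    if missing:
        raise TrainingError(f"plan ids missing from dataset: {sorted(missing)[:5]} ...")
    test = [by_id[i] for i in plan.test_ids]
    n_rounds = plan.folds if rounds is None else rounds

    reports, histories, val_folds = [], [], []
    for k in range(1, n_rounds + 1):
        train = [by_id[i] for i in plan.train_ids(validation_fold=k)]
        val = [by_id[i] for i in plan.validation_ids(validation_fold=k)]
        model = build_network(arch, seed=config.seed + k)
        model, history = train_model(model, train, val,
                                     replace(config, seed=config.seed + k))
        if history.best_state is not None:
            model.load_state_dict(history.best_state)
        reports.append(evaluate_model(model, test, batch_size=config.batch_size))
        histories.append(history)
        val_folds.append(k)
    return CVResult(per_round=reports, histories=histories, validation_folds=val_folds)


# ----------------------------------------------------------------------
# grid search

ARCH_KEYS = {"variant", "depth", "initial_filters", "levels", "dilation_rates", "fusion"}


def grid_search(samples: list[ImageSample], plan: SplitPlan,
                base_arch: ArchitectureConfig, base_config: TrainingConfig,
                space: dict[str, list], budget: int | None = None,
                rounds: int = 1) -> list[dict]:
    """Enumerate the Cartesian product of ``space`` and rank by validation DC.

    Keys in ``space`` override fields of the architecture config (depth,
    levels, dilation_rates, ...) or the training config (optimizer,
    learning_rate, batch_size, scheduler, momentum). Returns the
    evaluated points sorted by score, best first; ties keep insertion
    order.
    """
    if not space:
        raise ValueError("empty search space")
    for key, candidates in space.items():
        if not candidates:
            raise ValueError(f"empty candidate list for {key!r}")
    keys = list(space)
    results = []
    for idx, values in enumerate(itertools.product(*(space[k] for k in keys))):
        if budget is not None and idx >= budget:
            break
        point = dict(zip(keys, values))
        arch = replace(base_arch, **{k: v for k, v in point.items() if k in ARCH_KEYS})
        cfg = replace(base_config,
                      **{k: v for k, v in point.items() if k not in ARCH_KEYS})
        cv = run_cross_validation(samples, plan, arch, cfg, rounds=rounds)
        score = float(np.mean([max(h.val_dc) for h in cv.histories]))
        results.append({"point": point, "score": score, "order": idx})
    results.sort(key=lambda r: (-r["score"], r["order"]))
    return results


# ----------------------------------------------------------------------
# saliency

def saliency_map(model: NetworkModel, image) -> np.ndarray:
    """Input-gradient saliency averaged over decoder stages.

    For each decoder stage the gradient of the stage's mean activation
    with respect to the input is reduced to a per-pixel magnitude (max
    of |grad| over input channels), bilinearly up-sampled to the input
    size, averaged across stages and max-normalized to [0, 1].
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.ndim == 3:
        x_arr = img.transpose(2, 0, 1)[None]
    else:
        x_arr = img
    h, w = x_arr.shape[2], x_arr.shape[3]

    was_training = model.training
    model.eval()
    try:
        n_stages = len(model.decoder)
        maps = []
        for stage in range(n_stages):
            x = Tensor(x_arr, requires_grad=True)
            _, acts = model(x, collect_decoder=True)
            nn.mean(acts[stage]).backward()
            g = np.abs(x.grad[0]).max(axis=0)  # max over input channels
            if g.shape != (h, w):  # pragma: no cover - decoder stages keep input size
                g = resize(g, (h, w), order=1, preserve_range=True)
            maps.append(g)
    finally:
        model.train(was_training)

    combined = np.mean(maps, axis=0)
    peak = combined.max()
    if peak > 0:
        combined = combined / peak
    return combined


# ----------------------------------------------------------------------
# significance testing

def compare_models_ttest(iou_a, iou_b, alpha: float = 0.05
                         ) -> tuple[float, float, bool]:
    """Paired two-sided t-test on per-fold IoU values.

    Returns (t statistic, p value, significant flag with p <= alpha).
    Zero-variance differences: p = 1 when the mean difference is zero,
    otherwise p = 0 (a constant nonzero shift across all folds).
    """
    a = np.asarray(iou_a, dtype=float)
    b = np.asarray(iou_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("need at least two paired values")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0, False
        t = math.inf if d.mean() > 0 else -math.inf
        return t, 0.0, True
    res = stats.ttest_rel(a, b)
    t, p = float(res.statistic), float(res.pvalue)
    return t, p, p <= alpha
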