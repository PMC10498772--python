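"""Training loop, evaluation, and the ablation harness.

Training minimizes the soft Dice loss with Adam.  Defaults follow the
reference protocol for this architecture: batch size 16, 300 epochs,
learning rate 1e-5, Adam second-moment decay (beta2) 0.999 with the
standard beta1 = 0.9, DropBlock rate 0.1, evaluation threshold 0.5.
Validation loss is monitored every epoch and the checkpoint is saved
whenever it reaches a new minimum, so the retained weights are the
argmin of the validation-loss curve (which typically dips and then
rises as the model overfits), not the final epoch.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, soft_dice_loss
from .metrics import confusion_counts, dice_coefficient, evaluate_all, iou, \
    sensitivity, specificity
from .network import ModelConfig, PDCNet, build_model, save_checkpoint

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "Adam",
    "BestCheckpointSelector",
    "train",
    "evaluate",
    "run_ablation",
    "format_ablation_table",
]


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 300
    learning_rate: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999  # the protocol's "momentum 0.999"
    eps: float = 1e-8
    dropout_rate: float = 0.1
    threshold: float = 0.5
    loss_smooth: float = 1e-6
    seed: int = 0
    device: str = "cpu"
    max_steps: int | None = None  # optional hard cap on optimizer steps
    patience: int | None = None  # early stopping; off by default

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params, lr=1e-5, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class BestCheckpointSelector:
    """Tracks the running argmin of the validation loss.

    ``update`` returns True exactly when the supplied loss is a new
    strict minimum, i.e. when the caller should persist weights.
    """

    def __init__(self):
        self.best_loss = np.inf
        self.best_epoch = None

    def update(self, epoch: int, val_loss: float) -> bool:
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            return True
        return False


@dataclass
class TrainingHistory:
    records: list = field(default_factory=list)  # one dict per epoch
    best_epoch: int | None = None
    best_val_loss: float = np.inf
    steps: int = 0

    def append(self, **kwargs):
        self.records.append(kwargs)

    def column(self, key):
        return [r[key] for r in self.records]

    def write_csv(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cols = ["epoch", "train_loss", "val_loss", "sens", "spec", "dice", "iou"]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for r in self.records:
                w.writerow([r[c] for c in cols])


def _check_split(data, name):
    if name not in data:
        raise ValueError(f"dataset is missing the '{name}' split")
    x, y = data[name]
    if len(x) == 0:
        raise ValueError(f"'{name}' split is empty")
    return np.asarray(x, dtype=np.float64), np.asarray(y)


def _batch_loss_and_grads(model, xb, yb, eps):
    prob = model(Tensor(xb))
    loss = soft_dice_loss(prob, yb[:, None, :, :], eps=eps)
    loss.backward()
    return float(loss.data)


def validation_loss(model, x, y, eps=1e-6, batch_size=16):
    """Mean per-image Dice loss over a split, evaluation mode."""
    was_training = model.training
    model.eval()
    losses = []
    try:
        for s in range(0, len(x), batch_size):
            xb, yb = x[s:s + batch_size], y[s:s + batch_size]
            prob = model(Tensor(xb))
            loss = soft_dice_loss(prob, yb[:, None, :, :], eps=eps)
            losses.append(float(loss.data) * len(xb))
    finally:
        model.train(was_training)
    return sum(losses) / len(x)


def train(model: PDCNet, data: dict, tc: TrainConfig,
          checkpoint_path=None, history_csv=None, verbose=False):
    """Optimize the model on data['train'], monitoring data['val'].

    data maps split names to (images (N,1,H,W), masks (N,H,W)) pairs.
    Returns (TrainingHistory, best_state_dict).  When ``checkpoint_path``
    is given, weights are also persisted there at every new validation-
    loss minimum.
    """
    x_tr, y_tr = _check_split(data, "train")
    x_va, y_va = _check_split(data, "val")

    rng = np.random.default_rng(tc.seed)
    opt = Adam(model.parameters(), lr=tc.learning_rate,
               beta1=tc.beta1, beta2=tc.beta2, eps=tc.eps)
    selector = BestCheckpointSelector()
    history = TrainingHistory()
    best_state = model.state_dict()
    steps = 0
    done = False

    for epoch in range(tc.epochs):
        model.train()
        order = rng.permutation(len(x_tr))
        epoch_losses = []
        for s in range(0, len(order), tc.batch_size):
            idx = order[s:s + tc.batch_size]
            opt.zero_grad()
            loss = _batch_loss_and_grads(model, x_tr[idx], y_tr[idx], tc.loss_smooth)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss {loss} at epoch {epoch} step {steps}; "
                    "try a lower learning rate")
            opt.step()
            epoch_losses.append(loss)
            steps += 1
            if tc.max_steps is not None and steps >= tc.max_steps:
                done = True
                break

        val_loss = validation_loss(model, x_va, y_va, eps=tc.loss_smooth,
                                   batch_size=tc.batch_size)
        val_metrics = evaluate(model, x_va, y_va, threshold=tc.threshold)
        history.append(epoch=epoch,
                       train_loss=float(np.mean(epoch_losses)),
                       val_loss=val_loss,
                       sens=val_metrics["sensitivity"],
                       spec=val_metrics["specificity"],
                       dice=val_metrics["dice"],
                       iou=val_metrics["iou"])
        if selector.update(epoch, val_loss):
            best_state = model.state_dict()
            if checkpoint_path is not None:
                save_checkpoint(checkpoint_path, model,
                                extra={"epoch": epoch, "val_loss": val_loss})
        if verbose:
            print(f"epoch {epoch:4d}  train {np.mean(epoch_losses):.4f}  "
                  f"val {val_loss:.4f}  dice {val_metrics['dice']:.4f}")
        if done:
            break
        if tc.patience is not None and selector.best_epoch is not None \
                and epoch - selector.best_epoch >= tc.patience:
            break

    history.best_epoch = selector.best_epoch
    history.best_val_loss = selector.best_loss
    history.steps = steps
    if history_csv is not None:
        history.write_csv(history_csv)
    return history, best_state


def evaluate(model: PDCNet, images, masks, threshold: float = 0.5,
             standard_sensitivity: bool = False) -> dict:
    """Mean per-image metrics over a split, plus pooled-count variants.

    Per-image averaging treats every image equally; pooling the
    confusion counts over the whole split weights images by lesion size.
    The two differ whenever confusion proportions vary across images, so
    both are reported.
    """
    x = np.asarray(images, dtype=np.float64)
    y = np.asarray(masks)
    prob = model.predict(x)
    per_image = {"sensitivity": [], "specificity": [], "dice": [], "iou": []}
    pooled = None
    import warnings as _warnings
    for i in range(len(x)):
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            rep = evaluate_all(prob[i], y[i], threshold=threshold,
                               standard_sensitivity=standard_sensitivity)
        for k in per_image:
            per_image[k].append(getattr(rep, k))
        c = rep.counts
        pooled = c if pooled is None else type(c)(
            tp=pooled.tp + c.tp, tn=pooled.tn + c.tn,
            fp=pooled.fp + c.fp, fn=pooled.fn + c.fn)
    out = {k: float(np.mean(v)) for k, v in per_image.items()}
    out.update({
        "pooled_sensitivity": sensitivity(pooled, standard=standard_sensitivity),
        "pooled_specificity": specificity(pooled),
        "pooled_dice": dice_coefficient(pooled),
        "pooled_iou": iou(pooled),
        "n_images": len(x),
    })
    return out


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

DEFAULT_ABLATION = (
    {"variant": "no_pdcm", "use_residual": False},
    {"variant": "no_pdcm", "use_residual": True},
    {"variant": "pdcm_previous", "use_residual": False},
    {"variant": "pdcm_previous", "use_residual": True},
)


def run_ablation(variants, data, tc: TrainConfig, base_cfg: ModelConfig,
                 eval_split: str = "test", verbose=False):
    """Train each architectural variant with identical seed and data and
    evaluate on the held-out split.  Returns one row dict per variant."""
    rows = []
    for spec_row in variants:
        cfg = ModelConfig(**{**_cfg_dict(base_cfg), **spec_row})
        model = build_model(cfg)
        history, best_state = train(model, data, tc, verbose=verbose)
        model.load_state_dict(best_state)
        x_ev, y_ev = _check_split(data, eval_split)
        metrics = evaluate(model, x_ev, y_ev, threshold=tc.threshold)
        rows.append({
            "variant": cfg.variant,
            "use_residual": cfg.use_residual,
            "sensitivity": metrics["sensitivity"],
            "specificity": metrics["specificity"],
            "dice": metrics["dice"],
            "iou": metrics["iou"],
            "best_epoch": history.best_epoch,
        })
    return rows


def _cfg_dict(cfg: ModelConfig):
    from dataclasses import asdict
    return asdict(cfg)


_LABELS = {
    ("no_pdcm", False): "No Residual + No PDCM",
    ("no_pdcm", True): "Residual + No PDCM",
    ("pdcm_no_previous", False): "No Residual + PDCM without previous branch",
    ("pdcm_no_previous", True): "Residual + PDCM without previous branch",
    ("pdcm_previous", False): "No Residual + PDCM with previous branch",
    ("pdcm_previous", True): "Residual + PDCM with previous branch",
}


def format_ablation_table(rows) -> str:
    """Render ablation rows as an aligned text table (4-decimal cells)."""
    header = f"{'':50s}\tSensitivity\tSpecificity\tDice\tIoU"
    lines = [header]
    for r in rows:
        label = _LABELS[(r["variant"], r["use_residual"])]
        lines.append(f"{label:50s}\t{r['sensitivity']:.4f}\t{r['specificity']:.4f}"
                     f"\t{r['dice']:.4f}\t{r['iou']:.4f}")
    return "\n".join(lines) + "\n"
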