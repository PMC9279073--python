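"""Training loop, binary cross-entropy loss, and Acc/Sen/Spe evaluation.

The network head has 3 output channels; the binary vessel label is replicated
across them, per-channel sigmoid binary cross-entropy is averaged, and the
inference vessel probability is the mean of the per-channel sigmoids.  The
published schedule: Adam, initial learning rate 1e-3 multiplied by 0.9 after
every epoch, batch size 128, 100 epochs.  Metrics are counted inside the FOV
mask when one is available (switchable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .backbone import VesselFusionNet
from .data_io import ImagePair, binarize, extract_patches, random_augment, \
    stitch_predictions
from .layers import Adam

BCE_EPS = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    initial_lr: float = 1e-3
    lr_decay: float = 0.9  # per-epoch learning-rate multiplier
    seed: int = 0
    device: str = "cpu"
    patches_per_image: int = 500
    patch_size: int = 64
    augment: bool = True
    val_stride: int = 32
    threshold: float = 0.5
    use_fov: bool = True

    def validate(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


@dataclass
class MetricReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    counts: ConfusionCounts
    per_image: list[tuple[str, ConfusionCounts, Metrics]] = field(
        default_factory=list)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_loss(pred, target):
    """Mean binary cross-entropy over every element.

    ``pred`` holds probabilities (clamped to [1e-7, 1-1e-7]); ``target`` binary
    labels, broadcastable to ``pred``.  Accepts arrays (returns a float) or
    autograd tensors (returns a scalar tensor for backprop).
    """
    if isinstance(pred, Tensor):
        tdata = target.data if isinstance(target, Tensor) else \
            np.asarray(target, dtype=pred.data.dtype)
        try:
            tdata = np.broadcast_to(tdata, pred.shape)
        except ValueError:
            raise ValueError(
                f"shape mismatch: pred {pred.shape} vs target {tdata.shape}")
        target = Tensor(np.ascontiguousarray(tdata))
        p = ag.clip(pred, BCE_EPS, 1.0 - BCE_EPS)
        ll = target * ag.log(p) + (1.0 - target) * ag.log(1.0 - p)
        return -ag.mean(ll)
    pred = np.asarray(pred, dtype=np.float64)
    target_b = np.broadcast_to(np.asarray(target, dtype=np.float64), pred.shape)
    p = np.clip(pred, BCE_EPS, 1.0 - BCE_EPS)
    return float(-(target_b * np.log(p) + (1 - target_b) * np.log(1 - p)).mean())


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_counts(pred_mask: np.ndarray, true_mask: np.ndarray,
                     fov: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel tallies with vessel as the positive class."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(
            f"shape mismatch {pred_mask.shape} vs {true_mask.shape}")
    for name, m in (("pred", pred_mask), ("true", true_mask)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    if fov is not None:
        sel = np.asarray(fov).astype(bool)
        pred_mask, true_mask = pred_mask[sel], true_mask[sel]
    p = pred_mask.astype(bool)
    t = true_mask.astype(bool)
    return ConfusionCounts(
        tp=int((p & t).sum()), tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()), fn=int((~p & t).sum()))


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity and specificity from pixel tallies.

    A metric whose denominator is zero is reported as None (undefined),
    never as 0/0; all-zero counts are rejected.
    """
    if c.total == 0:
        raise ValueError("metrics undefined for all-zero counts")

    def ratio(num, den):
        return num / den if den > 0 else None

    return Metrics(
        accuracy=ratio(c.tp + c.tn, c.total),
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp))


def evaluate_pairs(preds: dict[str, np.ndarray], pairs: list[ImagePair],
                   threshold: float = 0.5, use_fov: bool = True) -> MetricReport:
    """Per-image and micro-aggregated metrics for predicted probability maps."""
    per_image = []
    total = ConfusionCounts()
    for pair in pairs:
        if pair.source_id not in preds:
            raise ValueError(f"no prediction for image {pair.source_id!r}")
        pred = binarize(preds[pair.source_id], threshold)
        c = confusion_counts(pred, pair.mask,
                             pair.fov if use_fov else None)
        per_image.append((pair.source_id, c, metrics(c)))
        total = total + c
    agg = metrics(total)
    return MetricReport(accuracy=agg.accuracy, sensitivity=agg.sensitivity,
                        specificity=agg.specificity, counts=total,
                        per_image=per_image)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_probability(model: VesselFusionNet, pair_or_image,
                        patch_size: int = 64, stride: int = 32,
                        batch_size: int = 64) -> np.ndarray:
    """Grid-tiled, overlap-averaged full-image vessel probability map."""
    image = pair_or_image.image if isinstance(pair_or_image, ImagePair) \
        else np.asarray(pair_or_image)
    h, w = image.shape[:2]
    dummy = ImagePair(image=image, mask=np.zeros((h, w), dtype=np.uint8))
    ps = extract_patches(dummy, size=patch_size, strategy="grid",
                         n_or_stride=stride)
    x = np.stack([p.image.transpose(2, 0, 1) for p in ps]).astype(np.float32)
    origins = [(p.row, p.col) for p in ps]
    model.eval()
    probs = []
    with ag.no_grad():
        for i in range(0, len(x), batch_size):
            out, _ = model.forward(Tensor(x[i:i + batch_size]),
                                   record_taps=False)
            p = _sigmoid_np(out.data).mean(axis=1)  # channel-mean probability
            probs.append(p)
    tiles = list(zip(np.concatenate(probs), origins))
    prob_map, coverage = stitch_predictions(tiles, (h, w))
    if not coverage.all():
        raise ValueError("tiling left uncovered pixels")
    return prob_map


def _sigmoid_np(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def build_patch_arrays(pairs: list[ImagePair], tc: TrainConfig
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Sample and augment training patches from full images (seeded)."""
    rng = np.random.default_rng(tc.seed)
    xs, ys = [], []
    for i, pair in enumerate(pairs):
        ps = extract_patches(pair, size=tc.patch_size, strategy="random",
                             n_or_stride=tc.patches_per_image,
                             seed=tc.seed + 1000 * (i + 1))
        for p in ps:
            img, msk = p.image, p.mask
            if tc.augment:
                img, msk = random_augment(img, msk, rng)
            xs.append(img.transpose(2, 0, 1))
            ys.append(msk)
    x = np.asarray(np.stack(xs), dtype=np.float32)
    y = np.asarray(np.stack(ys), dtype=np.float32)
    return x, y


def train(model: VesselFusionNet, train_pairs: list[ImagePair],
          val_pairs: list[ImagePair], tc: TrainConfig
          ) -> tuple[VesselFusionNet, list[dict]]:
    """Seeded mini-batch optimization with per-epoch validation.

    Returns the model carrying the best-validation-accuracy weights and a
    history of per-epoch records (train loss, learning rate, validation
    Acc/Sen/Spe when validation pairs are given).
    """
    tc.validate()
    if not train_pairs:
        raise ValueError("empty training set")
    x, y = build_patch_arrays(train_pairs, tc)
    rng = np.random.default_rng(tc.seed + 7)
    opt = Adam(model.parameters(), lr=tc.initial_lr)
    lr = tc.initial_lr
    history: list[dict] = []
    best_acc = -1.0
    best_state = None
    for epoch in range(tc.epochs):
        model.train()
        perm = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), tc.batch_size):
            idx = perm[i:i + tc.batch_size]
            xb = Tensor(x[idx])
            yb = Tensor(y[idx][:, None])  # broadcast across the 3 channels
            out, _ = model.forward(xb, record_taps=False)
            prob = ag.sigmoid(out)
            loss = bce_loss(prob, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss {loss.data} at epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            opt.lr = lr
            opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch + 1, "train_loss": float(np.mean(losses)),
                  "lr": lr}
        lr *= tc.lr_decay
        if val_pairs:
            report = validate(model, val_pairs, tc)
            record.update(val_accuracy=report.accuracy,
                          val_sensitivity=report.sensitivity,
                          val_specificity=report.specificity)
            acc = report.accuracy if report.accuracy is not None else -1.0
            if acc > best_acc:
                best_acc = acc
                best_state = model.state_dict()
                record["best"] = True
        history.append(record)
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def validate(model: VesselFusionNet, pairs: list[ImagePair],
             tc: TrainConfig) -> MetricReport:
    preds = {p.source_id: predict_probability(
        model, p, patch_size=tc.patch_size, stride=tc.val_stride)
        for p in pairs}
    return evaluate_pairs(preds, pairs, threshold=tc.threshold,
                          use_fov=tc.use_fov)
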