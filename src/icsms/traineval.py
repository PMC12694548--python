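"""Training loop, evaluation metrics, lambda sweep and fold aggregation.

Training follows the dual-optimizer contract of the joint objective: Adam
(lr 1e-4) on every network weight, and the canonical mini-batch center
update (plain SGD, rate alpha) on the class-center matrix.  All randomness
(shuffling, augmentation, dropout, init) derives from one config seed, so a
fixed seed reproduces a run bit-for-bit.

Metrics are computed from the multiclass confusion matrix (rows = truth):
headline accuracy is trace/total; precision, recall and F1 are computed
one-vs-rest per class and macro-averaged, all reported in percent.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .backbone import GrapeLeafNet
from .datapipe import (AugmentConfig, DatasetManifest, NormalizeConfig,
                       load_image, resize_normalize)
from .losses import (ClassCenters, DEFAULT_CENTER_LR, DEFAULT_LAMBDA,
                     LAMBDA_SWEEP, center_loss, cross_entropy, joint_loss)
from .nn.core import Tensor
from .nn.layers import Module
from .nn.optim import Adam


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 200
    lr: float = 1e-4
    lam: float = DEFAULT_LAMBDA
    center_lr: float = DEFAULT_CENTER_LR
    seed: int = 0
    image_size: int = 224
    augment: AugmentConfig | None = AugmentConfig()
    stop_at_val_accuracy: float | None = None   # early exit for smoke tests
    normalize: NormalizeConfig = dataclasses.field(default_factory=NormalizeConfig)

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.lr <= 0:
            raise ValueError("batch size, epochs and lr must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


@dataclasses.dataclass
class ArrayDataset:
    """In-memory split dataset: raw HWC images in [0, 1] plus labels."""

    images: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]

    def split(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        return self.images[name], self.labels[name]

    @classmethod
    def from_manifest(cls, manifest: DatasetManifest,
                      images: np.ndarray | None = None,
                      splits: tuple[str, ...] = ("train", "val", "test")
                      ) -> "ArrayDataset":
        """Materialize splits; ``images`` (aligned with the manifest rows)
        avoids disk IO, otherwise images are loaded from manifest paths."""
        imgs, labs = {}, {}
        for s in splits:
            df = manifest.df[manifest.df["split"] == s]
            if images is not None:
                imgs[s] = images[df.index.to_numpy()]
            else:
                imgs[s] = np.stack([load_image(p) for p in df["path"]])
            labs[s] = df["label"].to_numpy(dtype=np.int64)
        return cls(imgs, labs)

    @classmethod
    def from_fold(cls, manifest: DatasetManifest, fold: int,
                  images: np.ndarray | None = None) -> "ArrayDataset":
        """Cross-validation view: the given fold is the test set, the rest
        trains (no separate validation split in CV mode)."""
        imgs, labs = {}, {}
        for s, df in (("train", manifest.fold_subset(fold, "train")),
                      ("test", manifest.fold_subset(fold, "test"))):
            if images is not None:
                imgs[s] = images[df.index.to_numpy()]
            else:
                imgs[s] = np.stack([load_image(p) for p in df["path"]])
            labs[s] = df["label"].to_numpy(dtype=np.int64)
        imgs["val"], labs["val"] = imgs["test"], labs["test"]
        return cls(imgs, labs)


@dataclasses.dataclass
class MetricsReport:
    confusion: np.ndarray            # (C, C), rows = truth
    accuracy: float                  # percent
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: pd.DataFrame          # TP/FP/FN/TN + per-class P/R/F1

    @classmethod
    def from_confusion(cls, confusion: np.ndarray) -> "MetricsReport":
        cm = np.asarray(confusion, dtype=np.int64)
        if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
            raise ValueError("confusion matrix must be square")
        total = cm.sum()
        if total == 0:
            raise ValueError("empty confusion matrix")
        tp = np.diag(cm).astype(float)
        fp = cm.sum(axis=0) - tp
        fn = cm.sum(axis=1) - tp
        tn = total - tp - fp - fn
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
            rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
            f1 = np.where(prec + rec > 0,
                          2 * prec * rec / (prec + rec), 0.0)
        per_class = pd.DataFrame({
            "TP": tp.astype(int), "FP": fp.astype(int),
            "FN": fn.astype(int), "TN": tn.astype(int),
            "precision": prec * 100, "recall": rec * 100, "f1": f1 * 100})
        return cls(confusion=cm,
                   accuracy=float(tp.sum() / total * 100),
                   macro_precision=float(prec.mean() * 100),
                   macro_recall=float(rec.mean() * 100),
                   macro_f1=float(f1.mean() * 100),
                   per_class=per_class)

    def summary(self) -> dict[str, float]:
        return {"accuracy": self.accuracy,
                "precision": self.macro_precision,
                "recall": self.macro_recall, "f1": self.macro_f1}


@dataclasses.dataclass
class FoldResult:
    reports: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]


# ------------------------------------------------------------- training

def _prep_batch(raw: np.ndarray, config: TrainConfig,
                rng: np.random.Generator | None) -> np.ndarray:
    """Augment (train only) and resize/normalize a batch of HWC images."""
    out = np.empty((raw.shape[0], 3, config.image_size, config.image_size),
                   dtype=np.float32)
    for i, img in enumerate(raw):
        if rng is not None and config.augment is not None:
            from .datapipe import augment as _augment
            img = _augment(img, config.augment, rng)
        out[i] = resize_normalize(img, config.image_size, config.normalize)
    return out


def _forward_loss(model: Module, x: np.ndarray, y: np.ndarray,
                  config: TrainConfig, centers: ClassCenters | None):
    if isinstance(model, GrapeLeafNet) and model.center_proj is not None \
            and config.lam > 0:
        logits, _, cfeat = model.forward_with_features(Tensor(x))
        ce = cross_entropy(logits, y)
        cl = center_loss(cfeat, y, centers)
        return joint_loss(ce, cl, config.lam), ce, cl, logits, cfeat
    logits = model(Tensor(x))
    ce = cross_entropy(logits, y)
    return ce, ce, None, logits, None


def train_model(model: Module, data: ArrayDataset, config: TrainConfig
                ) -> tuple[Module, pd.DataFrame]:
    """Train; returns the model (best-val weights restored) and the history.

    History columns: epoch, loss, ce, center, val_accuracy.  Aborts with a
    diagnostic on a non-finite loss.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    joint = isinstance(model, GrapeLeafNet) and model.center_proj is not None \
        and config.lam > 0
    centers = None
    if joint:
        centers = ClassCenters(model.config.num_classes, model.center_dim,
                               storage=model.centers)
        # the center matrix is driven by its own SGD rule, not by Adam
        opt = Adam([p for p in model.parameters()
                    if p is not model.centers], lr=config.lr)
    x_train, y_train = data.split("train")
    history = []
    best_acc, best_state = -1.0, None
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(x_train))
        ep_loss = ep_ce = ep_cl = 0.0
        nb = 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            x = _prep_batch(x_train[sel], config, rng)
            y = y_train[sel]
            loss, ce, cl, _, cfeat = _forward_loss(model, x, y, config,
                                                   centers)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(lambda={config.lam}, lr={config.lr})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            if joint:
                centers.update(cfeat.data, y, config.center_lr)
            ep_loss += float(loss.data)
            ep_ce += float(ce.data)
            ep_cl += float(cl.data) if cl is not None else 0.0
            nb += 1
        val = evaluate(model, data, "val", config)
        history.append({"epoch": epoch, "loss": ep_loss / nb,
                        "ce": ep_ce / nb, "center": ep_cl / nb,
                        "val_accuracy": val.accuracy})
        if val.accuracy > best_acc:
            best_acc = val.accuracy
            best_state = model.state_dict()
        if config.stop_at_val_accuracy is not None \
                and val.accuracy >= config.stop_at_val_accuracy:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def predict(model: Module, images: np.ndarray, config: TrainConfig,
            batch_size: int = 64) -> np.ndarray:
    """Deterministic eval-mode class predictions for raw HWC images."""
    model.eval()
    preds = []
    for start in range(0, len(images), batch_size):
        x = _prep_batch(images[start:start + batch_size], config, rng=None)
        logits = model(Tensor(x))
        preds.append(logits.data.argmax(axis=1))
    return np.concatenate(preds)


def evaluate(model: Module, data: ArrayDataset, split: str,
             config: TrainConfig) -> MetricsReport:
    images, labels = data.split(split)
    if len(images) == 0:
        raise ValueError(f"split {split!r} is empty")
    preds = predict(model, images, config)
    c = int(max(labels.max(), preds.max())) + 1
    if isinstance(model, GrapeLeafNet):
        c = model.config.num_classes
    cm = np.zeros((c, c), dtype=np.int64)
    np.add.at(cm, (labels, preds), 1)
    return MetricsReport.from_confusion(cm)


def validation_loss(model: Module, data: ArrayDataset,
                    config: TrainConfig) -> float:
    """Mean cross-entropy on the validation split (eval mode)."""
    model.eval()
    images, labels = data.split("val")
    total, n = 0.0, 0
    for start in range(0, len(images), config.batch_size):
        x = _prep_batch(images[start:start + config.batch_size], config, None)
        y = labels[start:start + config.batch_size]
        ce = cross_entropy(model(Tensor(x)), y)
        total += float(ce.data) * len(y)
        n += len(y)
    return total / n


# ------------------------------------------------------- sweep / folds

def lambda_sweep(model_factory, data: ArrayDataset, config: TrainConfig,
                 lambdas: tuple[float, ...] = LAMBDA_SWEEP) -> pd.DataFrame:
    """Train one model per lambda under a shared seed; Table-2-shaped report."""
    if not lambdas:
        raise ValueError("lambda set must be non-empty")
    rows = []
    for lam in lambdas:
        cfg = dataclasses.replace(config, lam=lam)
        model = model_factory()
        model, _ = train_model(model, data, cfg)
        rep = evaluate(model, data, "test" if "test" in data.images else "val",
                       cfg)
        rows.append({"lambda": lam, **rep.summary(),
                     "loss": validation_loss(model, data, cfg)})
    return pd.DataFrame(rows)


def aggregate_folds(reports: list[MetricsReport]) -> FoldResult:
    """Mean and sample SD (denominator k-1) of each metric over folds."""
    if len(reports) < 2:
        raise ValueError("fold aggregation needs >= 2 folds")
    table = pd.DataFrame([r.summary() for r in reports])
    return FoldResult(reports=reports,
                      mean=table.mean().to_dict(),
                      sd=table.std(ddof=1).to_dict())


def cross_validate(model_factory, manifest: DatasetManifest,
                   images: np.ndarray, config: TrainConfig,
                   k: int = 5) -> FoldResult:
    from .datapipe import make_folds
    manifest = make_folds(manifest, k=k, seed=config.seed)
    reports = []
    for fold in range(k):
        data = ArrayDataset.from_fold(manifest, fold, images)
        model = model_factory()
        model, _ = train_model(model, data, config)
        reports.append(evaluate(model, data, "test", config))
    return aggregate_folds(reports)


def mean_intra_class_distance(features: np.ndarray,
                              labels: np.ndarray) -> float:
    """Mean distance of each sample's feature to its class centroid."""
    features = np.asarray(features, dtype=np.float64)
    dists = []
    for j in np.unique(labels):
        sel = features[labels == j]
        dists.append(np.linalg.norm(sel - sel.mean(axis=0), axis=1).mean())
    return float(np.mean(dists))


def extract_features(model: GrapeLeafNet, images: np.ndarray,
                     config: TrainConfig, batch_size: int = 64) -> np.ndarray:
    """Pooled penultimate (576-d) features in eval mode."""
    model.eval()
    feats = []
    for start in range(0, len(images), batch_size):
        x = _prep_batch(images[start:start + batch_size], config, rng=None)
        _, pooled, _ = model.forward_with_features(Tensor(x))
        feats.append(pooled.data)
    return np.concatenate(feats)
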