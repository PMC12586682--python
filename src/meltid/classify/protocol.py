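"""Supervised identification protocol on rendered curve images.

The pipeline mirrors standard small-dataset practice: drop species with too
few samples, split 60/20/20 stratified by species (splits operate on run ids,
so the three image kinds of one reaction never straddle splits), grid-search
learning rate and weight decay with 20-epoch training cycles, select the
configuration with the highest optimal validation accuracy (the best
validation accuracy seen within a cycle), retrain on train+validation, and
evaluate once on the untouched test split with support-weighted metrics and
mean softmax confidence.  A combined-representation model concatenates the
latent features of three independently trained per-kind networks under a
single linear head.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .nn import AdamW, SmallCNN, cross_entropy_grad, softmax

__all__ = [
    "TrainConfig", "ClassifierReport", "PredictionResult",
    "filter_min_samples", "stratified_split", "load_arrays",
    "train_classifier", "grid_search", "retrain_full",
    "evaluate", "predict", "FusedModel", "fuse_models", "get_backbone",
]

SPLITS = ("train", "val", "test", "unseen")


@dataclasses.dataclass
class TrainConfig:
    """Training hyper-parameters and the search grid."""

    backbone: str = "smallcnn"
    epochs: int = 20
    learning_rates: tuple[float, ...] = (1e-3, 1e-4)
    weight_decays: tuple[float, ...] = (0.0, 1e-4)
    batch_size: int = 8
    seed: int = 0
    deterministic: bool = True
    input_size: int = 64

    def __post_init__(self) -> None:
        if not self.learning_rates or not self.weight_decays:
            raise ValueError("hyper-parameter grid must be non-empty")


@dataclasses.dataclass
class ClassifierReport:
    """Test-set evaluation: support-weighted metrics plus mean confidence."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    avg_confidence: float
    confusion_matrix: np.ndarray
    classes: list[str]
    per_class: pd.DataFrame
    n_test: int

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "avg_confidence": self.avg_confidence, "n_test": self.n_test,
                "classes": self.classes,
                "confusion_matrix": self.confusion_matrix.tolist()}


@dataclasses.dataclass
class PredictionResult:
    """One sample's ranked class probabilities and open-set flag."""

    run_id: str
    classes: list[str]
    probabilities: np.ndarray
    threshold: float = 0.9
    true_label: str | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be non-negative and sum to 1")
        self.probabilities = p

    @property
    def top_class(self) -> str:
        return self.classes[int(self.probabilities.argmax())]

    @property
    def confidence(self) -> float:
        return float(self.probabilities.max())

    @property
    def flag(self) -> str:
        return "untested" if self.confidence < self.threshold else "tested"


# ---- dataset shaping --------------------------------------------------------

def filter_min_samples(counts: dict[str, int],
                       min_n: int = 5) -> tuple[set[str], set[str], int]:
    """Retain species with >= ``min_n`` runs; report the removal tally."""
    if not counts:
        raise ValueError("counts must be non-empty")
    retained = {s for s, n in counts.items() if n >= min_n}
    excluded = set(counts) - retained
    if not retained:
        raise ValueError(f"no species has >= {min_n} samples")
    removed = sum(counts[s] for s in excluded)
    return retained, excluded, removed


def _largest_remainder(n: int, fractions: tuple[float, float, float]) -> list[int]:
    ideal = [n * f for f in fractions]
    alloc = [int(np.floor(v + 1e-9)) for v in ideal]
    rem = n - sum(alloc)
    order = sorted(range(3), key=lambda i: (-(ideal[i] - alloc[i]), i))
    for i in range(rem):
        alloc[order[i % 3]] += 1
    return alloc


def stratified_split(manifest: pd.DataFrame,
                     fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0) -> pd.DataFrame:
    """Assign train/val/test splits per species by run id.

    Per-class counts follow largest-remainder rounding of the fractions, with
    validation and test each guaranteed at least one run (a 5-run class splits
    3/1/1).  Assignment is deterministic given the seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    df = manifest.copy()
    runs = df[["run_id", "species_label"]].drop_duplicates("run_id")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for species in sorted(runs["species_label"].unique()):
        ids = sorted(runs.loc[runs["species_label"] == species, "run_id"])
        if len(ids) < 5:
            raise ValueError(
                f"species {species!r} reaches splitting with {len(ids)} < 5 runs")
        n_tr, n_va, n_te = _largest_remainder(len(ids), fractions)
        while n_va < 1:
            n_tr -= 1; n_va += 1
        while n_te < 1:
            n_tr -= 1; n_te += 1
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        for rid in shuffled[:n_tr]:
            assignment[rid] = "train"
        for rid in shuffled[n_tr:n_tr + n_va]:
            assignment[rid] = "val"
        for rid in shuffled[n_tr + n_va:]:
            assignment[rid] = "test"
    df["split"] = df["run_id"].map(assignment)
    return df


# ---- image loading ----------------------------------------------------------

_IMAGE_CACHE: dict[tuple[str, int], np.ndarray] = {}


def _load_image(path: str, input_size: int) -> np.ndarray:
    key = (path, input_size)
    if key not in _IMAGE_CACHE:
        img = Image.open(path).convert("L").resize((input_size, input_size),
                                                   Image.BILINEAR)
        # dark-on-light plots -> invert so the curve carries the signal mass
        arr = 1.0 - np.asarray(img, dtype=np.float32) / 255.0
        _IMAGE_CACHE[key] = arr[None, :, :]
    return _IMAGE_CACHE[key]


def load_arrays(manifest: pd.DataFrame, kind: str, split: str | list[str],
                classes: list[str] | None = None, input_size: int = 64,
                ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Images of one kind for one or more splits -> (X, y, run_ids, classes)."""
    splits = [split] if isinstance(split, str) else list(split)
    sub = manifest[(manifest["kind"] == kind) & (manifest["split"].isin(splits))]
    sub = sub.sort_values("run_id")
    if sub.empty:
        raise ValueError(f"no images for kind={kind!r}, split={splits}")
    if classes is None:
        classes = sorted(sub["species_label"].unique())
    index = {c: i for i, c in enumerate(classes)}
    X = np.stack([_load_image(p, input_size) for p in sub["image_path"]])
    y = np.array([index.get(lbl, -1) for lbl in sub["species_label"]])
    return X, y, list(sub["run_id"]), classes


# ---- training ---------------------------------------------------------------

def get_backbone(name: str, n_classes: int, input_size: int, seed: int,
                 class_names: list[str]):
    """Instantiate a backbone by name.

    ``smallcnn`` is the native CPU-sized default.  ``resnet18``/``resnet50``/
    ``vit`` are optional plug-ins requiring torch/torchvision at run time.
    """
    if name == "smallcnn":
        return SmallCNN(n_classes, input_size, seed, class_names)
    if name in ("resnet18", "resnet50", "vit"):
        try:
            import torch  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                f"backbone {name!r} requires the optional torch/torchvision "
                "dependency; install it or use backbone='smallcnn'") from exc
        raise NotImplementedError(
            f"torch backbone {name!r} adapter not wired in this build")
    raise ValueError(f"unknown backbone {name!r}")


def _accuracy(model: SmallCNN, X: np.ndarray, y: np.ndarray) -> float:
    probs = model.predict_proba(X)
    return float((probs.argmax(axis=1) == y).mean())


def _run_epochs(model: SmallCNN, Xtr, ytr, Xval, yval, lr, wd, config,
                audit: list | None = None, train_run_ids=None) -> list[dict]:
    opt = AdamW(model, lr=lr, weight_decay=wd)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(ytr))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            probs = softmax(model.forward(Xtr[idx]))
            loss, glog = cross_entropy_grad(probs, ytr[idx])
            model.backward(glog)
            opt.step()
            losses.append(loss)
            if audit is not None and train_run_ids is not None:
                audit.append([train_run_ids[j] for j in idx])
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if Xval is not None:
            row["val_accuracy"] = _accuracy(model, Xval, yval)
        history.append(row)
    return history


def train_classifier(manifest: pd.DataFrame, kind: str, config: TrainConfig,
                     lr: float | None = None, wd: float | None = None,
                     ) -> tuple[SmallCNN, list[dict], float]:
    """Train one backbone on the train split, validating each epoch.

    Returns the model, the per-epoch history (train loss, validation
    accuracy) and the optimal validation accuracy — the maximum validation
    accuracy observed across the training cycle.
    """
    lr = config.learning_rates[0] if lr is None else lr
    wd = config.weight_decays[0] if wd is None else wd
    Xtr, ytr, tr_ids, classes = load_arrays(manifest, kind, "train",
                                            input_size=config.input_size)
    Xva, yva, _, _ = load_arrays(manifest, kind, "val", classes,
                                 config.input_size)
    if np.any(ytr < 0) or np.any(yva < 0):
        raise ValueError("validation split contains a class absent from train")
    model = get_backbone(config.backbone, len(classes), config.input_size,
                         config.seed, classes)
    model.train_run_ids = sorted(set(tr_ids))
    history = _run_epochs(model, Xtr, ytr, Xva, yva, lr, wd, config)
    optimal_val_accuracy = max(h["val_accuracy"] for h in history)
    return model, history, optimal_val_accuracy


def grid_search(manifest: pd.DataFrame, kind: str, config: TrainConfig,
                ) -> tuple[tuple[float, float], pd.DataFrame]:
    """Exhaustive (learning rate, weight decay) search.

    The winning cell maximizes optimal validation accuracy; ties break toward
    the lower learning rate, then the lower weight decay.  The full table is
    returned for audit.
    """
    rows = []
    for lr, wd in itertools.product(config.learning_rates, config.weight_decays):
        _, _, opt_acc = train_classifier(manifest, kind, config, lr, wd)
        rows.append({"learning_rate": lr, "weight_decay": wd,
                     "optimal_val_accuracy": opt_acc})
    table = pd.DataFrame(rows)
    return select_best(table), table


def select_best(table: pd.DataFrame) -> tuple[float, float]:
    """Argmax of the grid table; ties break toward lower lr, then lower wd."""
    best = table.sort_values(
        ["optimal_val_accuracy", "learning_rate", "weight_decay"],
        ascending=[False, True, True]).iloc[0]
    return float(best["learning_rate"]), float(best["weight_decay"])


def retrain_full(manifest: pd.DataFrame, kind: str, config: TrainConfig,
                 best: tuple[float, float],
                 audit: list | None = None) -> SmallCNN:
    """Retrain on train+val with the selected hyper-parameters.

    The test split is never loaded here; ``audit``, when given, collects the
    run ids of every training batch so leakage is assertable after the fact.
    """
    lr, wd = best
    X, y, run_ids, classes = load_arrays(manifest, kind, ["train", "val"],
                                         input_size=config.input_size)
    model = get_backbone(config.backbone, len(classes), config.input_size,
                         config.seed, classes)
    model.train_run_ids = sorted(set(run_ids))
    _run_epochs(model, X, y, None, None, lr, wd, config,
                audit=audit, train_run_ids=run_ids)
    return model


# ---- evaluation -------------------------------------------------------------

def evaluate(model: SmallCNN, manifest: pd.DataFrame, kind: str,
             split: str = "test", input_size: int | None = None,
             ) -> ClassifierReport:
    """Support-weighted metrics plus average softmax confidence on a split."""
    classes = model.class_names
    X, y, _, _ = load_arrays(manifest, kind, split, classes,
                             input_size or model.input_size)
    if X.shape[0] == 0:
        raise ValueError(f"empty {split!r} split")
    probs = model.predict_proba(X)
    return report_from_probs(probs, y, classes)


def report_from_probs(probs: np.ndarray, y_true: np.ndarray,
                      classes: list[str]) -> ClassifierReport:
    y_pred = probs.argmax(axis=1)
    labels = np.arange(len(classes))
    accuracy = float((y_pred == y_true).mean())
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0)
    p_c, r_c, f_c, s_c = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0)
    per_class = pd.DataFrame({"species": classes, "precision": p_c,
                              "recall": r_c, "f1": f_c, "support": s_c})
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    return ClassifierReport(
        accuracy=accuracy, precision=float(precision), recall=float(recall),
        f1=float(f1), avg_confidence=float(probs.max(axis=1).mean()),
        confusion_matrix=cm, classes=list(classes), per_class=per_class,
        n_test=len(y_true))


def predict(model: SmallCNN, manifest: pd.DataFrame, kind: str,
            split: str | list[str], threshold: float = 0.9) -> list[PredictionResult]:
    """Per-sample predictions with confidence and the open-set flag."""
    X, y, run_ids, _ = load_arrays(manifest, kind, split, model.class_names,
                                   model.input_size)
    probs = model.predict_proba(X)
    sub = manifest[(manifest["kind"] == kind)].set_index("run_id")
    out = []
    for i, rid in enumerate(run_ids):
        true = str(sub.loc[rid, "species_label"]) if rid in sub.index else None
        out.append(PredictionResult(run_id=rid, classes=model.class_names,
                                    probabilities=probs[i], threshold=threshold,
                                    true_label=true))
    return out


# ---- fusion -----------------------------------------------------------------

class FusedModel:
    """Concatenated latent features from three per-kind models + linear head.

    Only the head is trained; the backbones are frozen feature extractors.
    A fused prediction for one run consumes all three of its images.
    """

    def __init__(self, models: dict[str, SmallCNN], seed: int = 0):
        if len(models) != 3:
            raise ValueError("fusion expects exactly three per-kind models")
        first = next(iter(models.values()))
        for m in models.values():
            if m.class_names != first.class_names:
                raise ValueError("per-kind models disagree on the class list")
        self.models = dict(models)
        self.kinds = list(models)
        self.class_names = first.class_names
        self.input_dim = sum(m.latent_dim for m in models.values())
        rng = np.random.default_rng(seed)
        self.W = rng.normal(0.0, np.sqrt(2.0 / self.input_dim),
                            size=(self.input_dim, len(self.class_names))
                            ).astype(np.float32)
        self.b = np.zeros(len(self.class_names), dtype=np.float32)

    def features(self, manifest: pd.DataFrame, split: str | list[str],
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        feats, y_ref, ids_ref = [], None, None
        for kind in self.kinds:
            model = self.models[kind]
            X, y, run_ids, _ = load_arrays(manifest, kind, split,
                                           self.class_names, model.input_size)
            if ids_ref is None:
                ids_ref, y_ref = run_ids, y
            elif run_ids != ids_ref:
                missing = set(ids_ref) ^ set(run_ids)
                raise ValueError(f"runs missing a {kind!r} image: {sorted(missing)[:5]}")
            feats.append(np.concatenate(
                [model.latent(X[i:i + 64]) for i in range(0, len(X), 64)]))
        return np.concatenate(feats, axis=1), y_ref, ids_ref

    def fit_head(self, manifest: pd.DataFrame, split="train",
                 lr: float = 1e-2, weight_decay: float = 0.0,
                 epochs: int = 100, seed: int = 0) -> None:
        F, y, _ = self.features(manifest, split)
        rng = np.random.default_rng(seed)
        m = np.zeros_like(self.W); v = np.zeros_like(self.W)
        mb = np.zeros_like(self.b); vb = np.zeros_like(self.b)
        t = 0
        for _ in range(epochs):
            order = rng.permutation(len(y))
            for i in range(0, len(order), 64):
                idx = order[i:i + 64]
                probs = softmax(F[idx] @ self.W + self.b)
                _, g = cross_entropy_grad(probs, y[idx])
                gW = F[idx].T @ g
                gb = g.sum(axis=0)
                t += 1
                for arr, grad, mm, vv in ((self.W, gW, m, v), (self.b, gb, mb, vb)):
                    mm *= 0.9; mm += 0.1 * grad
                    vv *= 0.999; vv += 0.001 * grad * grad
                    mhat = mm / (1 - 0.9 ** t)
                    vhat = vv / (1 - 0.999 ** t)
                    if arr is self.W and weight_decay:
                        arr *= 1.0 - lr * weight_decay
                    arr -= (lr * mhat / (np.sqrt(vhat) + 1e-8)).astype(np.float32)

    def predict_proba(self, manifest: pd.DataFrame, split: str | list[str],
                      ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        F, y, run_ids = self.features(manifest, split)
        return softmax(F @ self.W + self.b), y, run_ids


def fuse_models(models: dict[str, SmallCNN], manifest: pd.DataFrame,
                fit_split: str | list[str] = ("train", "val"),
                seed: int = 0) -> FusedModel:
    """Build and fit a combined-representation model over three kinds."""
    fused = FusedModel(models, seed=seed)
    fused.fit_head(manifest, split=list(fit_split) if not isinstance(fit_split, str)
                   else fit_split, seed=seed)
    return fused
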