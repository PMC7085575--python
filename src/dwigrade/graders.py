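"""Zone-level graders learned from data.

Two families:

* Feature-based graders — logistic regression, random forest, and an RBF
  support-vector machine fitted on the 96-dimensional radiomic sequences,
  with per-class weights {negative: 1, positive: 150} to counter the rare
  positive grade, and feature standardization fit on the training split.
* A compact convolutional sequencer trained end-to-end on 32x32 zone
  patches with Adam and the same class-weighted cross-entropy, early
  stopping on a held-out patient-level validation split.

Modality-specific training defaults: ADC uses batch 219, learning rate
2e-4, patience 50; the high-b modality uses batch 163, learning rate 2e-3,
patience 16. The shipped ADC sequencer design is deliberately smaller than
the high-b design (3 vs 5 conv blocks) — the lower-complexity modality
needs the lower-capacity sequencer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._nn import AdamState, ConvNet, weighted_softmax_loss

__all__ = [
    "SequencerDesign", "TrainingConfig", "GraderModel",
    "ADC_DESIGN", "CHB_DESIGN", "ADC_TRAINING", "CHB_TRAINING",
    "weighted_cross_entropy", "train_zone_x", "train_dr", "predict_proba",
    "save_model", "load_model",
]

CLASS_WEIGHTS = {0: 1.0, 1: 150.0}


@dataclass(frozen=True)
class SequencerDesign:
    """Declarative conv-sequencer design: 3x3 convs, optional maxpools,
    terminal global-average pool + dense 2-way probability head."""

    layer_spec: tuple[tuple, ...]
    modality_tag: str = "ADC"

    def __post_init__(self) -> None:
        kinds = {e[0] for e in self.layer_spec}
        if not kinds <= {"conv", "maxpool"}:
            raise ValueError("layer_spec entries must be conv or maxpool")
        if not any(e[0] == "conv" for e in self.layer_spec):
            raise ValueError("design needs at least one conv layer")

    def build(self, rng: np.random.Generator) -> ConvNet:
        return ConvNet(self.layer_spec, rng, in_channels=1)

    def n_parameters(self) -> int:
        return self.build(np.random.default_rng(0)).n_parameters()


ADC_DESIGN = SequencerDesign(
    layer_spec=(("conv", 8), ("maxpool",), ("conv", 16), ("maxpool",),
                ("conv", 32)),
    modality_tag="ADC")

CHB_DESIGN = SequencerDesign(
    layer_spec=(("conv", 8), ("conv", 8), ("maxpool",), ("conv", 16),
                ("conv", 16), ("maxpool",), ("conv", 32)),
    modality_tag="CHB")


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 219
    learning_rate: float = 2e-4
    patience: int = 50
    class_weights: tuple[float, float] = (1.0, 150.0)   # (negative, positive)
    max_epochs: int = 100
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.learning_rate <= 0 or self.patience < 1:
            raise ValueError("invalid training configuration")


ADC_TRAINING = TrainingConfig(batch_size=219, learning_rate=2e-4, patience=50)
CHB_TRAINING = TrainingConfig(batch_size=163, learning_rate=2e-3, patience=16)


@dataclass
class GraderModel:
    """Fitted grader. ``kind`` in {lr, rf, svm, dr}; feature-based kinds
    consume radiomic sequences, ``dr`` consumes normalized 32x32 patches."""

    kind: str
    estimator: object = None            # sklearn pipeline or ConvNet
    fitted: bool = False
    design: Optional[SequencerDesign] = None
    training: Optional[TrainingConfig] = None
    history: Optional[list] = None      # (epoch, train_loss, val_loss)
    norm_scale: float = 1.0             # dr input scaling (1 / modality max)


def weighted_cross_entropy(labels, probs, weights=(1.0, 150.0),
                           eps: float = 1e-12) -> float:
    """Mean over samples of the class-weighted binary cross-entropy.

    Each sample's term -[y log p + (1-y) log(1-p)] is scaled by the weight
    of its class; the sum is divided by the number of samples.
    """
    y = np.asarray(labels, dtype=float).ravel()
    p = np.asarray(probs, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError("labels and probs length mismatch")
    if isinstance(weights, dict):
        weights = (weights[0], weights[1])
    p = np.clip(p, eps, 1.0 - eps)
    w = np.where(y == 1, weights[1], weights[0])
    terms = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float((w * terms).sum() / len(y))


def _require_both_classes(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one example of each class")
    return y


def train_zone_x(sequences, labels, kind: str, seed: int = 0) -> GraderModel:
    """Fit a feature-based grader on a (n, 96) radiomic-sequence table."""
    X = np.asarray(sequences, dtype=float)
    y = _require_both_classes(labels)
    if kind == "lr":
        est = LogisticRegression(max_iter=5000, class_weight=CLASS_WEIGHTS)
    elif kind == "rf":
        est = RandomForestClassifier(n_estimators=200, class_weight=CLASS_WEIGHTS,
                                     random_state=seed, n_jobs=1)
    elif kind == "svm":
        # Platt-calibrated decision values give the probability output
        est = CalibratedClassifierCV(
            SVC(kernel="rbf", class_weight=CLASS_WEIGHTS, random_state=seed),
            ensemble=False)
    else:
        raise ValueError(f"unknown feature-based grader kind {kind!r}")
    pipe = Pipeline([("scale", StandardScaler()), ("clf", est)])
    pipe.fit(X, y)
    return GraderModel(kind=kind, estimator=pipe, fitted=True)


def _patient_val_split(patient_ids, labels, val_fraction, rng):
    """Seeded patient-level split keeping ~val_fraction of patients out."""
    pids = np.asarray(patient_ids)
    uniq = np.unique(pids)
    if len(uniq) < 2:
        raise ValueError("no validation split available: need >= 2 patients")
    perm = rng.permutation(uniq)
    n_val = max(1, int(round(val_fraction * len(uniq))))
    val_pids = set(perm[:n_val].tolist())
    val_mask = np.isin(pids, list(val_pids))
    if val_mask.all() or not val_mask.any():
        raise ValueError("no validation split available")
    return ~val_mask, val_mask


def train_dr(patches, labels, design: SequencerDesign = ADC_DESIGN,
             config: TrainingConfig = ADC_TRAINING,
             patient_ids: Optional[Sequence] = None,
             norm_scale: float = 1.0) -> GraderModel:
    """Train the convolutional sequencer on a (n, 32, 32) patch stack.

    ``norm_scale`` multiplies intensities before training (typically one
    over the modality maximum so inputs lie in [0, 1]). Early stopping
    monitors class-weighted cross-entropy on a held-out validation split —
    patient-level when ``patient_ids`` is given, sample-level otherwise.
    """
    X = np.asarray(patches, dtype=float) * norm_scale
    if X.ndim != 3 or X.shape[1:] != (32, 32):
        raise ValueError("patches must be a (n, 32, 32) stack")
    y = _require_both_classes(labels)
    rng = np.random.default_rng(config.seed)

    if patient_ids is not None:
        tr, va = _patient_val_split(patient_ids, y, config.val_fraction, rng)
    else:
        perm = rng.permutation(len(y))
        n_val = max(1, int(round(config.val_fraction * len(y))))
        va = np.zeros(len(y), dtype=bool)
        va[perm[:n_val]] = True
        tr = ~va
    if not va.any() or not tr.any():
        raise ValueError("no validation split available")
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training split is single-class")

    Xtr, ytr = X[tr][..., None], y[tr]
    Xva, yva = X[va][..., None], y[va]

    net = design.build(rng)
    opt = AdamState(net.parameters(), lr=config.learning_rate)
    best_val, best_state, best_epoch = np.inf, net.get_state(), -1
    history = []
    n = len(ytr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        train_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            cache: list = []
            logits = net.forward(Xtr[idx], cache)
            loss, dlogits = weighted_softmax_loss(logits, ytr[idx],
                                                  config.class_weights)
            grads = net.backward(dlogits, cache)
            opt.step(net.parameters(), grads)
            train_loss += loss
            n_batches += 1
        val_logits = net.forward(Xva)
        val_loss, _ = weighted_softmax_loss(val_logits, yva, config.class_weights)
        history.append((epoch, train_loss / n_batches, val_loss))
        if val_loss < best_val - 1e-9:
            best_val, best_state, best_epoch = val_loss, net.get_state(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    net.set_state(best_state)
    return GraderModel(kind="dr", estimator=net, fitted=True, design=design,
                       training=config, history=history, norm_scale=norm_scale)


def predict_proba(model: GraderModel, inputs) -> np.ndarray:
    """Positive-class probability for each input row/patch."""
    if not model.fitted:
        raise RuntimeError("model is not fitted")
    X = np.asarray(inputs, dtype=float)
    if model.kind == "dr":
        X = (X * model.norm_scale)[..., None]
        probs = []
        for start in range(0, len(X), 512):
            logits = model.estimator.forward(X[start:start + 512])
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z)
            probs.append((ez / ez.sum(axis=1, keepdims=True))[:, 1])
        return np.concatenate(probs)
    return model.estimator.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# dr checkpointing: one .npz archive with a JSON config snapshot inside.

def save_model(model: GraderModel, path: str | Path) -> None:
    if model.kind != "dr":
        raise ValueError("only dr models use the archive format")
    meta = {
        "layer_spec": [list(e) for e in model.design.layer_spec],
        "modality_tag": model.design.modality_tag,
        "training": {k: getattr(model.training, k) for k in
                     ("batch_size", "learning_rate", "patience",
                      "class_weights", "max_epochs", "val_fraction", "seed")},
        "norm_scale": model.norm_scale,
        "history": model.history,
    }
    arrays = {f"p{i}": p for i, p in enumerate(model.estimator.parameters())}
    np.savez(Path(path), meta=json.dumps(meta, default=list), **arrays)


def load_model(path: str | Path) -> GraderModel:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        design = SequencerDesign(
            layer_spec=tuple(tuple(e) for e in meta["layer_spec"]),
            modality_tag=meta["modality_tag"])
        tcfg = dict(meta["training"])
        tcfg["class_weights"] = tuple(tcfg["class_weights"])
        training = TrainingConfig(**tcfg)
        net = design.build(np.random.default_rng(0))
        net.set_state([data[f"p{i}"] for i in range(len(net.parameters()))])
    return GraderModel(kind="dr", estimator=net, fitted=True, design=design,
                       training=training, history=meta["history"],
                       norm_scale=meta["norm_scale"])
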