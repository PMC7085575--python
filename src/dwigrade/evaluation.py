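"""ROC analysis, threshold selection, and patient-level cross-validation.

The grading threshold for each strategy is chosen on the ROC curve by
maximizing the weighted Youden objective

    J(theta) = 2 * [ w * (1 - fpr(theta)) + (1 - w) * tpr(theta) ]

with w = 0.5 recovering the plain (1 - fpr) + tpr criterion. Candidate
thresholds are midpoints between consecutive unique scores, so a separable
score distribution yields the midpoint of the separating gap; ties are
broken toward higher specificity, then toward the higher threshold. A
sample is graded positive iff its score >= theta.

Cross-validation is stratified at the patient level: patients with and
without verified cancer are shuffled separately (seeded) and dealt
round-robin into k folds, so every zone of a patient lands in the same fold
(no leakage) and each fold keeps its share of positive patients. A
101-patient roster at k = 5 yields groups of {21, 20, 20, 20, 20}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc, roc_curve as _sk_roc_curve

from .graders import (ADC_DESIGN, ADC_TRAINING, CHB_DESIGN, CHB_TRAINING,
                      predict_proba, train_dr, train_zone_x)
from .heuristic import HeuristicConfig, adc_zone_probability, chb_zone_probability
from .pipeline import cohort_patches, featurize_patches, patch_stack
from .radiomics import feature_names
from .zoning import ADC_FILL, ZonePatch

__all__ = ["ROCResult", "FoldAssignment", "StrategyReport", "roc_curve",
           "optimal_threshold", "sens_spec_at", "stratified_patient_folds",
           "cross_validate", "STRATEGIES", "plot_reports"]

STRATEGIES = ("heuristic", "lr", "rf", "svm", "dr")


@dataclass
class ROCResult:
    thresholds: np.ndarray   # descending; leading sentinel above max score
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class FoldAssignment:
    fold_of_patient: dict
    k: int

    def fold_patients(self, fold: int) -> list:
        return [p for p, f in self.fold_of_patient.items() if f == fold]


@dataclass
class StrategyReport:
    strategy: str
    modality: str
    fold_auc: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    fold_threshold: list[float]

    def _ms(self, xs):
        a = np.asarray(xs, dtype=float)
        return float(a.mean()), float(a.std())

    def summary(self) -> dict:
        out = {"strategy": self.strategy, "modality": self.modality,
               "k": len(self.fold_auc)}
        for name, xs in (("auc", self.fold_auc),
                         ("sensitivity", self.fold_sensitivity),
                         ("specificity", self.fold_specificity)):
            m, s = self._ms(xs)
            out[f"{name}_mean"], out[f"{name}_sd"] = m, s
            out[f"{name}_folds"] = list(map(float, xs))
        out["thresholds"] = list(map(float, self.fold_threshold))
        return out


def roc_curve(scores, labels) -> ROCResult:
    """ROC over all unique-score thresholds; AUC by trapezoid rule."""
    y = np.asarray(labels).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr,
                     auc=float(_trapezoid_auc(fpr, tpr)))


def optimal_threshold(roc: ROCResult, weight: float = 0.5) -> float:
    """Threshold maximizing 2[w(1-fpr) + (1-w)tpr]; see module docstring."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    j = 2.0 * (weight * (1.0 - roc.fpr) + (1.0 - weight) * roc.tpr)
    # tie-breaks: higher specificity (lower fpr), then higher threshold
    order = np.lexsort((-roc.thresholds, roc.fpr, -j))
    i = int(order[0])
    t = roc.thresholds
    if i == 0:                      # "no positives": just above the max score
        return float(t[1] + 1.0)
    if i == len(t) - 1:             # "all scores positive"
        return float(t[i])
    return float((t[i] + t[i + 1]) / 2.0)


def sens_spec_at(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) grading positive iff score >= threshold."""
    y = np.asarray(labels).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("sensitivity/specificity require both classes")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    return tp / (tp + fn), tn / (tn + fp)


def stratified_patient_folds(patient_ids: Sequence, patient_positive_flags: Sequence,
                             k: int = 5, seed: int = 0) -> FoldAssignment:
    """Two-stratum round-robin deal of patients into k folds (seeded)."""
    pids = list(patient_ids)
    flags = [bool(f) for f in patient_positive_flags]
    if k > len(pids):
        raise ValueError("k exceeds number of patients")
    if len(set(pids)) != len(pids):
        raise ValueError("duplicate patient ids")
    rng = np.random.default_rng(seed)
    pos = [p for p, f in zip(pids, flags) if f]
    neg = [p for p, f in zip(pids, flags) if not f]
    if 0 < len(pos) < k:
        warnings.warn(f"only {len(pos)} positive patients for {k} folds; "
                      "some folds will lack positives", stacklevel=2)
    assignment = {}
    for stratum in (pos, neg):
        shuffled = [stratum[i] for i in rng.permutation(len(stratum))]
        for j, p in enumerate(shuffled):
            assignment[p] = j % k
    return FoldAssignment(fold_of_patient=assignment, k=k)


# ---------------------------------------------------------------------------
# cross-validated strategy comparison

def _heuristic_scores(patches: list[ZonePatch], modality: str,
                      config: HeuristicConfig) -> np.ndarray:
    fn = adc_zone_probability if modality == "ADC" else chb_zone_probability
    return np.array([fn(p.zone_values, config) for p in patches])


def _fold_scores(strategy, modality, train_p, test_p, features, seed,
                 dr_design, dr_training):
    """Fit on the training patches (if the strategy learns) and score the
    held-out patches."""
    if strategy == "heuristic":
        if modality == "ADC":
            cfg = HeuristicConfig(m_adc=ADC_FILL)
        else:
            m = max(float(np.max(p.zone_values)) for p in train_p)
            cfg = HeuristicConfig(m_chb=max(m, 1e-12))
        return _heuristic_scores(test_p, modality, cfg)
    y_tr = np.array([p.label for p in train_p], dtype=int)
    if strategy in ("lr", "rf", "svm"):
        cols = list(feature_names())
        X_tr = features.loc[[id(p) for p in train_p], cols].to_numpy()
        X_te = features.loc[[id(p) for p in test_p], cols].to_numpy()
        model = train_zone_x(X_tr, y_tr, kind=strategy, seed=seed)
        return predict_proba(model, X_te)
    if strategy == "dr":
        scale = 1.0 / ADC_FILL if modality == "ADC" else \
            1.0 / max(max(float(p.pixels.max()) for p in train_p), 1e-12)
        model = train_dr(patch_stack(train_p), y_tr, design=dr_design,
                         config=dr_training,
                         patient_ids=[p.patient_id for p in train_p],
                         norm_scale=scale)
        return predict_proba(model, patch_stack(test_p))
    raise ValueError(f"unknown strategy {strategy!r}")


def cross_validate(cohort, strategy: str, modality: str = "ADC", k: int = 5,
                   seed: int = 0, weight: float = 0.5,
                   dr_design=None, dr_training=None,
                   patches: Optional[list[ZonePatch]] = None,
                   features=None) -> StrategyReport:
    """Stratified patient-level k-fold evaluation of one grading strategy.

    Per fold the grader is fitted on the other k-1 folds (a no-op for the
    heuristic beyond its dataset-derived normalizer), the held-out zones
    are scored, the grading threshold is selected on the held-out ROC, and
    AUC / sensitivity / specificity are recorded. Precomputed ``patches``
    and ``features`` may be passed to share work across strategies.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if patches is None:
        patches = cohort_patches(cohort, modality)
    labels = np.array([p.label for p in patches], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("cohort must contain both classes")
    if strategy in ("lr", "rf", "svm") and features is None:
        features = featurize_patches(patches)
    if features is not None:
        features = features.copy()
        features.index = [id(p) for p in patches]
    if dr_design is None:
        dr_design = ADC_DESIGN if modality == "ADC" else CHB_DESIGN
    if dr_training is None:
        dr_training = ADC_TRAINING if modality == "ADC" else CHB_TRAINING

    # stratify on verified tumour presence (any positive zone), so every
    # fold receives its share of evaluable positive patients
    case_flag = {c.patient_id: sum(c.labels.values()) > 0 for c in cohort}
    folds = stratified_patient_folds(list(case_flag), list(case_flag.values()),
                                     k=k, seed=seed)
    report = StrategyReport(strategy=strategy, modality=modality,
                            fold_auc=[], fold_sensitivity=[],
                            fold_specificity=[], fold_threshold=[])
    for fold in range(k):
        test_pids = set(folds.fold_patients(fold))
        test_p = [p for p in patches if p.patient_id in test_pids]
        train_p = [p for p in patches if p.patient_id not in test_pids]
        scores = _fold_scores(strategy, modality, train_p, test_p, features,
                              seed, dr_design, dr_training)
        y_te = np.array([p.label for p in test_p], dtype=int)
        roc = roc_curve(scores, y_te)
        theta = optimal_threshold(roc, weight=weight)
        sens, spec = sens_spec_at(scores, y_te, theta)
        report.fold_auc.append(roc.auc)
        report.fold_sensitivity.append(sens)
        report.fold_specificity.append(spec)
        report.fold_threshold.append(theta)
    return report


def plot_reports(reports: Sequence[StrategyReport], path) -> None:
    """Bar plot (mean with sd error bars) of AUC/sensitivity/specificity."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ("auc", "sensitivity", "specificity")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, metric in zip(axes, metrics):
        names = [r.strategy for r in reports]
        means = [r.summary()[f"{metric}_mean"] for r in reports]
        sds = [r.summary()[f"{metric}_sd"] for r in reports]
        ax.bar(names, means, yerr=sds, capsize=3)
        ax.set_title(metric)
        ax.set_ylim(0, 1.05)
    fig.suptitle(f"{reports[0].modality} zone grading, {len(reports[0].fold_auc)}-fold")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
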