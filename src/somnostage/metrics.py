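"""Epoch-by-epoch agreement metrics between two hypnograms.

All scores are computed from a 5×5 confusion matrix over the canonical
stage order (rows = reference, columns = prediction), restricted to epochs
scored in *both* hypnograms:

- accuracy: fraction of epochs on the diagonal;
- Cohen's kappa: chance-corrected agreement, (p_o − p_e)/(1 − p_e) with
  p_e from the row/column marginals;
- Matthews correlation coefficient (multiclass R_K form), robust to stage
  imbalance;
- per-stage F1 (harmonic mean of one-vs-rest precision and sensitivity) and
  macro-F1 over the stages present.

Stratified accuracies split epochs by (a) proximity to a reference stage
transition — an epoch counts as "transition" if a stage change occurs
within ±1.5 min of it — and (b) classifier confidence above/below 0.80.
Among misclassified epochs, the second-choice accuracy is the fraction
where the classifier's runner-up stage was the correct one.

Holm's step-down adjustment is provided for families of paired tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import STAGES, Hypnogram, StageProbabilities

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion",
    "agreement_scores",
    "stage_f1",
    "transition_mask",
    "transition_fraction",
    "stratified_report",
    "holm_adjust",
]


@dataclass
class ConfusionMatrix:
    """5×5 stage confusion counts; rows = reference, columns = prediction."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(STAGES), len(STAGES)):
            raise ValueError(f"confusion matrix must be {len(STAGES)}x{len(STAGES)}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _joint_mask(ref: Hypnogram, pred: Hypnogram) -> np.ndarray:
    if len(ref) != len(pred):
        raise ValueError(f"hypnogram lengths differ: {len(ref)} vs {len(pred)}")
    mask = ref.scored_mask & pred.scored_mask
    if not mask.any():
        raise ValueError("no jointly scored epochs")
    return mask


def confusion(ref: Hypnogram, pred: Hypnogram) -> ConfusionMatrix:
    """Confusion counts over jointly scored epochs."""
    mask = _joint_mask(ref, pred)
    r = ref.indices[mask]
    p = pred.indices[mask]
    k = len(STAGES)
    counts = np.bincount(r * k + p, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts=counts)


def agreement_scores(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, Cohen's kappa, and MCC from a confusion matrix."""
    c = cm.counts.astype(np.float64)
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    diag = np.trace(c)
    acc = diag / n
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    pe = float(rows @ cols) / n**2
    if abs(1.0 - pe) < 1e-15:
        kappa = 1.0 if abs(acc - 1.0) < 1e-15 else 0.0
    else:
        kappa = (acc - pe) / (1.0 - pe)
    # multiclass MCC (R_K statistic)
    cov_xy = diag * n - float(rows @ cols)
    cov_xx = n**2 - float(rows @ rows)
    cov_yy = n**2 - float(cols @ cols)
    denom = np.sqrt(cov_xx * cov_yy)
    mcc = cov_xy / denom if denom > 0 else 0.0
    return {"accuracy": float(acc), "kappa": float(kappa), "mcc": float(mcc)}


def stage_f1(cm: ConfusionMatrix) -> tuple[dict[str, float], float]:
    """One-vs-rest F1 per stage plus the macro average over stages present.

    Stages absent from both reference and prediction are excluded from the
    macro mean (their F1 is undefined, reported as NaN).
    """
    c = cm.counts.astype(np.float64)
    if c.sum() == 0:
        raise ValueError("empty confusion matrix")
    per: dict[str, float] = {}
    present: list[float] = []
    for i, s in enumerate(STAGES):
        tp = c[i, i]
        ref_n = c[i, :].sum()
        pred_n = c[:, i].sum()
        if ref_n == 0 and pred_n == 0:
            per[s] = float("nan")
            continue
        denom = ref_n + pred_n
        f1 = 2 * tp / denom if denom > 0 else 0.0
        per[s] = float(f1)
        present.append(float(f1))
    return per, float(np.mean(present))


def transition_mask(hyp: Hypnogram, window_min: float = 3.0) -> np.ndarray:
    """Flag epochs lying within ±window/2 of a reference stage transition.

    With the default 3-min window and 30-s epochs, a boundary between epochs
    i and i+1 flags epochs i−2 … i+3 (1.5 min of influence on each side).
    Unscored epochs neither create nor interrupt transitions.
    """
    half_epochs = window_min * 60.0 / 2.0 / hyp.epoch_len_s
    if abs(half_epochs - round(half_epochs)) > 1e-9 or half_epochs < 1:
        raise ValueError(
            f"window ({window_min} min) must be a positive multiple of twice the "
            f"epoch length ({hyp.epoch_len_s} s)"
        )
    h = int(round(half_epochs))
    codes = hyp.indices
    scored_idx = np.flatnonzero(codes >= 0)
    out = np.zeros(len(hyp), dtype=bool)
    sc = codes[scored_idx]
    boundaries = scored_idx[:-1][sc[:-1] != sc[1:]]  # boundary b sits between b and b+1
    for b in boundaries:
        # boundary b flags epochs b-h+1 … b+h: h epochs on each side of the change
        out[max(0, b - h + 1) : b + h + 1] = True
    return out


def transition_fraction(hyp: Hypnogram) -> float:
    """Fraction of consecutive scored epoch pairs whose stages differ."""
    codes = hyp.indices[hyp.scored_mask]
    if len(codes) < 2:
        return 0.0
    return float(np.mean(codes[:-1] != codes[1:]))


@dataclass
class EvaluationReport:
    """Full epoch-by-epoch evaluation of a predicted hypnogram."""

    confusion: ConfusionMatrix
    accuracy: float
    kappa: float
    mcc: float
    f1_per_stage: dict[str, float]
    f1_macro: float
    stage_proportions_ref: dict[str, float]
    stage_proportions_pred: dict[str, float]
    transition_accuracy: float | None = None
    stable_accuracy: float | None = None
    highconf_accuracy: float | None = None
    lowconf_accuracy: float | None = None
    second_choice_accuracy: float | None = None
    conf_threshold: float = 0.80
    n_epochs: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n_epochs": self.n_epochs,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "mcc": self.mcc,
            "f1_per_stage": self.f1_per_stage,
            "f1_macro": self.f1_macro,
            "stage_proportions_ref": self.stage_proportions_ref,
            "stage_proportions_pred": self.stage_proportions_pred,
            "transition_accuracy": self.transition_accuracy,
            "stable_accuracy": self.stable_accuracy,
            "highconf_accuracy": self.highconf_accuracy,
            "lowconf_accuracy": self.lowconf_accuracy,
            "second_choice_accuracy": self.second_choice_accuracy,
            "conf_threshold": self.conf_threshold,
            "confusion": self.confusion.counts.tolist(),
        }
        d.update(self.extras)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [
            f"epochs evaluated : {self.n_epochs}",
            f"accuracy         : {self.accuracy:.4f}",
            f"Cohen's kappa    : {self.kappa:.4f}",
            f"MCC              : {self.mcc:.4f}",
            f"macro F1         : {self.f1_macro:.4f}",
            "per-stage F1     : "
            + "  ".join(f"{s}={self.f1_per_stage[s]:.3f}" for s in STAGES),
            "confusion (rows=ref, cols=pred, order " + "/".join(STAGES) + "):",
        ]
        for row in self.confusion.counts:
            lines.append("  " + " ".join(f"{v:6d}" for v in row))
        if self.transition_accuracy is not None:
            lines.append(
                f"transition vs stable accuracy: {self.transition_accuracy:.4f} vs "
                f"{self.stable_accuracy:.4f}"
            )
        if self.highconf_accuracy is not None:
            lines.append(
                f"confidence ≥{self.conf_threshold:.2f} vs below: "
                f"{self.highconf_accuracy:.4f} vs {self.lowconf_accuracy:.4f}"
            )
        if self.second_choice_accuracy is not None:
            lines.append(f"second-choice accuracy on errors: {self.second_choice_accuracy:.4f}")
        return "\n".join(lines)


def _masked_accuracy(correct: np.ndarray, mask: np.ndarray) -> float | None:
    if not mask.any():
        return None
    return float(np.mean(correct[mask]))


def stratified_report(
    ref: Hypnogram,
    pred: Hypnogram,
    probs: StageProbabilities | None = None,
    conf_threshold: float = 0.80,
    transition_window_min: float = 3.0,
) -> EvaluationReport:
    """Complete evaluation report, optionally stratified by confidence.

    Transition/stable accuracies always use the *reference* hypnogram's
    transitions. Confidence stratification and second-choice accuracy
    require the predicted stage probabilities.
    """
    if not (0.0 < conf_threshold < 1.0):
        raise ValueError(f"conf_threshold must be in (0, 1), got {conf_threshold}")
    if probs is not None and len(probs) != len(pred):
        raise ValueError("probability rows do not match hypnogram length")
    cm = confusion(ref, pred)
    scores = agreement_scores(cm)
    f1s, f1_macro = stage_f1(cm)
    joint = _joint_mask(ref, pred)
    correct_all = (ref.indices == pred.indices) & joint
    correct = correct_all[joint]

    rows = cm.counts.sum(axis=1) / cm.total
    cols = cm.counts.sum(axis=0) / cm.total
    report = EvaluationReport(
        confusion=cm,
        accuracy=scores["accuracy"],
        kappa=scores["kappa"],
        mcc=scores["mcc"],
        f1_per_stage=f1s,
        f1_macro=f1_macro,
        stage_proportions_ref={s: float(rows[i]) for i, s in enumerate(STAGES)},
        stage_proportions_pred={s: float(cols[i]) for i, s in enumerate(STAGES)},
        conf_threshold=conf_threshold,
        n_epochs=cm.total,
    )

    trans = transition_mask(ref, transition_window_min)[joint]
    report.transition_accuracy = _masked_accuracy(correct, trans)
    report.stable_accuracy = _masked_accuracy(correct, ~trans)

    if probs is not None:
        conf = probs.confidence[joint]
        high = conf >= conf_threshold
        report.highconf_accuracy = _masked_accuracy(correct, high)
        report.lowconf_accuracy = _masked_accuracy(correct, ~high)
        errors = ~correct
        if errors.any():
            runner = probs.runner_up_stages()[joint][errors]
            truth = ref.stages[joint][errors]
            report.second_choice_accuracy = float(np.mean(runner == truth))
    return report


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down multiple-comparison adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj_sorted = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
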