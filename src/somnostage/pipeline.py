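"""Night-level orchestration: signals → features → staging → evaluation.

The canonical chain for one night is

    resample(100 Hz) → bandpass(0.4–30 Hz) → 30-s epochs
    → per-epoch features → smoothing / per-night z-scoring / covariates
    → classifier → hypnogram + per-epoch stage probabilities.

Per-night normalization happens *inside* :func:`night_features`, so feature
matrices from different nights can be concatenated directly for training.

:func:`synthetic_benchmark` runs the whole pipeline on generated nights —
train on one set, evaluate held-out nights — and is the package's built-in
end-to-end check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .context import SmoothingConfig, assemble
from .core import UNSCORED, Hypnogram, Recording, StageProbabilities
from .features import DEFAULT_BANDS, extract_features
from .model import Hyperparameters, TrainedModel, fit, predict_proba
from .preprocess import DEFAULT_BAND, TARGET_RATE, bandpass, epoch, resample
from .synthetic import HypnogramModel, StageSignalModel, generate_night

__all__ = [
    "night_features",
    "stage_recording",
    "train_nights",
    "synthetic_benchmark",
    "BenchmarkResult",
]

logger = logging.getLogger(__name__)


def night_features(
    rec: Recording,
    meta: dict | None = None,
    target_rate: float = TARGET_RATE,
    band: tuple[float, float] = DEFAULT_BAND,
    epoch_len_s: float = 30.0,
    smoothing: SmoothingConfig | None = None,
) -> pd.DataFrame:
    """Full assembled feature matrix for one recording (one row per epoch)."""
    rec = resample(rec, target_rate)
    rec = bandpass(rec, *band)
    channels = epoch(rec, epoch_len_s)
    raw = extract_features(channels, DEFAULT_BANDS)
    return assemble(raw, smoothing or SmoothingConfig(), meta)


def stage_recording(
    rec: Recording,
    model: TrainedModel,
    meta: dict | None = None,
    epoch_len_s: float = 30.0,
) -> tuple[Hypnogram, StageProbabilities]:
    """Predict a hypnogram and per-epoch stage probabilities for a recording."""
    feats = night_features(rec, meta=meta, epoch_len_s=epoch_len_s)
    probs = predict_proba(model, feats)
    hyp = Hypnogram(stages=probs.argmax_stages(), epoch_len_s=epoch_len_s)
    return hyp, probs


def train_nights(
    nights: list[tuple[Recording, Hypnogram]],
    hp: Hyperparameters | None = None,
    metas: list[dict | None] | None = None,
) -> TrainedModel:
    """Train the classifier on several (recording, hypnogram) nights."""
    if not nights:
        raise ValueError("need at least one training night")
    metas = metas or [None] * len(nights)
    feats, labels = [], []
    for (rec, hyp), meta in zip(nights, metas):
        f = night_features(rec, meta=meta)
        if len(f) != len(hyp):
            n = min(len(f), len(hyp))
            f, hyp = f.iloc[:n], Hypnogram(hyp.stages[:n], epoch_len_s=hyp.epoch_len_s)
        feats.append(f)
        labels.append(hyp.stages)
    x = pd.concat(feats, ignore_index=True)
    y = Hypnogram(stages=np.concatenate(labels))
    return fit(x, y, hp)


@dataclass
class BenchmarkResult:
    """Held-out evaluation of a synthetic-night experiment."""

    model: TrainedModel
    reports: list[_metrics.EvaluationReport]

    def median(self, attr: str) -> float:
        vals = [getattr(r, attr) for r in self.reports if getattr(r, attr) is not None]
        return float(np.median(vals))

    def pooled(self) -> _metrics.EvaluationReport:
        """Single report over all held-out epochs pooled together."""
        cm = _metrics.ConfusionMatrix(sum(r.confusion.counts for r in self.reports))
        scores = _metrics.agreement_scores(cm)
        f1s, f1_macro = _metrics.stage_f1(cm)
        rows = cm.counts.sum(axis=1) / cm.total
        cols = cm.counts.sum(axis=0) / cm.total
        from .core import STAGES

        return _metrics.EvaluationReport(
            confusion=cm,
            accuracy=scores["accuracy"],
            kappa=scores["kappa"],
            mcc=scores["mcc"],
            f1_per_stage=f1s,
            f1_macro=f1_macro,
            stage_proportions_ref={s: float(rows[i]) for i, s in enumerate(STAGES)},
            stage_proportions_pred={s: float(cols[i]) for i, s in enumerate(STAGES)},
            n_epochs=cm.total,
        )


def synthetic_benchmark(
    n_train: int = 20,
    n_test: int = 5,
    seed: int = 1,
    hp: Hyperparameters | None = None,
    hm: HypnogramModel | None = None,
    sm: StageSignalModel | None = None,
) -> BenchmarkResult:
    """Train on ``n_train`` synthetic nights, evaluate on ``n_test`` held-out ones.

    All nights derive from the single master ``seed``; training and test
    nights use disjoint substreams. Each held-out night gets a full
    stratified evaluation report against its generative hypnogram.
    """
    ss = np.random.SeedSequence(seed)
    night_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_train + n_test)]
    logger.info("generating %d training nights", n_train)
    train = [generate_night(s, hm, sm) for s in night_seeds[:n_train]]
    model = train_nights(train, hp=hp)
    reports = []
    logger.info("evaluating %d held-out nights", n_test)
    for s in night_seeds[n_train:]:
        rec, truth = generate_night(s, hm, sm)
        pred, probs = stage_recording(rec, model)
        reports.append(_metrics.stratified_report(truth, pred, probs))
    return BenchmarkResult(model=model, reports=reports)
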