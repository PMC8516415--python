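"""Temporal context: rolling smoothing, per-night normalization, covariates.

Human scorers use the surrounding minutes when staging an epoch. The final
feature matrix therefore contains, for every raw feature, two smoothed and
per-night z-scored duplicates:

``*_c7min_norm``
    a 7.5-min centered triangular-weighted rolling average (15 epochs, the
    weight vector ramps linearly from 1/8 to 1 at the current epoch and back),
``*_p2min_norm``
    the unweighted mean of the last 2 min (4 epochs) strictly before the
    current epoch.

Smoothing never looks outside the night: at the edges the centered window
truncates to in-range epochs and renormalizes its weights; the past window
falls back to the current epoch's value at epoch 0. The raw per-epoch
columns are kept untouched to retain temporal specificity and absolute µV
scale. Z-scoring is within-night (each subject is their own reference,
absorbing inter-individual EEG amplitude differences).

Two covariates can be appended: ``time_elapsed`` (0 at the first epoch, 1 at
the last — sleep-stage composition is strongly asymmetric across the night)
and, optionally, the subject's age (years) and sex (1 = male, 0 = female).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SmoothingConfig",
    "triangular_weights",
    "smooth_features",
    "znorm_night",
    "assemble",
    "SMOOTH_SUFFIXES",
]

SMOOTH_SUFFIXES: tuple[str, str] = ("_c7min_norm", "_p2min_norm")


def triangular_weights(n: int) -> np.ndarray:
    """Symmetric triangular weight vector of odd length ``n``, peak 1 at center.

    Weights ramp linearly in steps of ``1/((n+1)/2)``; for n = 15 this is
    [0.125, 0.25, ..., 1.0, ..., 0.25, 0.125].
    """
    if n < 1 or n % 2 == 0:
        raise ValueError(f"window length must be odd and >= 1, got {n}")
    half = (n + 1) // 2
    ramp = np.arange(1, half + 1) / half
    return np.concatenate([ramp, ramp[-2::-1]])


@dataclass
class SmoothingConfig:
    """Rolling-window parameters (defaults: 7.5 min centered, 2 min past)."""

    centered_len_epochs: int = 15
    past_len_epochs: int = 4
    centered_weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.centered_weights is None:
            self.centered_weights = triangular_weights(self.centered_len_epochs)
        self.centered_weights = np.asarray(self.centered_weights, dtype=np.float64)
        if len(self.centered_weights) != self.centered_len_epochs:
            raise ValueError("centered_weights length must equal centered_len_epochs")

    @classmethod
    def from_minutes(
        cls, centered_minutes: float = 7.5, past_minutes: float = 2.0, epoch_len_s: float = 30.0
    ) -> "SmoothingConfig":
        return cls(
            centered_len_epochs=int(round(centered_minutes * 60 / epoch_len_s)),
            past_len_epochs=int(round(past_minutes * 60 / epoch_len_s)),
        )


def _smooth_centered(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    # weighted average with weights renormalized over in-range epochs
    num = ndimage.convolve1d(x, weights, axis=0, mode="constant", cval=0.0)
    den = ndimage.convolve1d(np.ones(x.shape[0]), weights, mode="constant", cval=0.0)
    return num / den[:, None]


def _smooth_past(x: np.ndarray, past_len: int) -> np.ndarray:
    n = x.shape[0]
    csum = np.concatenate([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)], axis=0)
    out = np.empty_like(x)
    for e in range(n):
        lo = max(0, e - past_len)
        if e == 0:
            out[0] = x[0]  # no history yet: fall back to the current epoch
        else:
            out[e] = (csum[e] - csum[lo]) / (e - lo)
    return out


def smooth_features(
    ft: pd.DataFrame, mode: str, cfg: SmoothingConfig | None = None
) -> pd.DataFrame:
    """Apply one of the two rolling smoothings to every column.

    ``mode`` is ``"centered_triangular"`` or ``"past_mean"``. Output has the
    same shape and column names as the input.
    """
    cfg = cfg or SmoothingConfig()
    x = ft.to_numpy(dtype=np.float64)
    if x.shape[0] < 1:
        raise ValueError("need at least one epoch")
    if mode == "centered_triangular":
        out = _smooth_centered(x, cfg.centered_weights)
    elif mode == "past_mean":
        out = _smooth_past(x, cfg.past_len_epochs)
    else:
        raise ValueError(f"unknown smoothing mode {mode!r}")
    return pd.DataFrame(out, columns=ft.columns, index=ft.index)


def znorm_night(ft: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column across the night (zero-variance columns → zeros)."""
    if ft.shape[0] < 2:
        raise ValueError("per-night z-scoring needs at least two epochs")
    x = ft.to_numpy(dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(out, columns=ft.columns, index=ft.index)


def assemble(
    ft_raw: pd.DataFrame,
    cfg: SmoothingConfig | None = None,
    meta: dict | None = None,
) -> pd.DataFrame:
    """Build the final per-night feature matrix.

    Columns, in deterministic order: the raw features, their centered-smoothed
    then z-scored duplicates (``_c7min_norm``), their past-smoothed then
    z-scored duplicates (``_p2min_norm``), ``time_elapsed``, and — when
    ``meta`` is given — constant ``age`` and ``sex`` columns.
    """
    cfg = cfg or SmoothingConfig()
    n = ft_raw.shape[0]
    if n < 2:
        raise ValueError("need at least two epochs to assemble a night")
    centered = znorm_night(smooth_features(ft_raw, "centered_triangular", cfg))
    past = znorm_night(smooth_features(ft_raw, "past_mean", cfg))
    parts = {
        **{c: ft_raw[c].to_numpy() for c in ft_raw.columns},
        **{f"{c}{SMOOTH_SUFFIXES[0]}": centered[c].to_numpy() for c in ft_raw.columns},
        **{f"{c}{SMOOTH_SUFFIXES[1]}": past[c].to_numpy() for c in ft_raw.columns},
        "time_elapsed": np.arange(n) / (n - 1),
    }
    if meta is not None:
        for key in ("age", "sex"):
            if key not in meta:
                raise ValueError(f"metadata requested but field {key!r} missing")
            parts[key] = np.full(n, float(meta[key]))
    return pd.DataFrame(parts, index=ft_raw.index)
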