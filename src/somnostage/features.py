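"""Per-epoch feature extraction: time-domain descriptors and spectral powers.

Each 30-s epoch of each channel yields the same feature set:

time domain
    standard deviation, interquartile range, skewness, kurtosis, number of
    zero-crossings, Hjorth mobility and complexity, normalized permutation
    entropy, and two fractal dimensions (Petrosian and Higuchi, k_max = 10).

frequency domain
    relative spectral power in the six classical bands — slow (0.4–1 Hz),
    delta (1–4), theta (4–8), alpha (8–12), sigma (12–16), beta (16–30) —
    the log10 absolute broadband power, and four band ratios
    (delta/theta, delta/sigma, delta/beta, alpha/theta).

Spectra come from Welch's method with a 5-s Hamming window, 50 % overlap
(0.20 Hz frequency resolution at any rate) and *median* averaging across
segments, which limits the influence of transient artifacts.

Amplitude-dependent features (std, iqr, absolute power) assume input in µV.
All computations are vectorised across the epochs of a night; the
single-epoch entry points simply wrap one-row matrices.
"""

from __future__ import annotations

import math as _math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .preprocess import EpochedChannel

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "TIME_FEATURES",
    "SPECTRAL_FEATURES",
    "FEATURES_PER_CHANNEL",
    "time_domain_features",
    "spectral_features",
    "extract_features",
    "welch_resolution_hz",
]

_EPS = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.high):
            raise ValueError(f"band {self.name}: low must be < high")


#: The six contiguous bands partitioning the 0.4–30 Hz analysis range.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("slow", 0.4, 1.0),
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("sigma", 12.0, 16.0),
    BandDefinition("beta", 16.0, 30.0),
)

TIME_FEATURES: tuple[str, ...] = (
    "std",
    "iqr",
    "skew",
    "kurtosis",
    "nzc",
    "hjorth_mobility",
    "hjorth_complexity",
    "perm_entropy",
    "petrosian_fd",
    "higuchi_fd",
)

_RATIOS: tuple[tuple[str, str, str], ...] = (
    ("ratio_delta_theta", "delta", "theta"),
    ("ratio_delta_sigma", "delta", "sigma"),
    ("ratio_delta_beta", "delta", "beta"),
    ("ratio_alpha_theta", "alpha", "theta"),
)


def _spectral_names(bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> tuple[str, ...]:
    return tuple(f"relpow_{b.name}" for b in bands) + ("abspow_broadband",) + tuple(
        r[0] for r in _RATIOS
    )


SPECTRAL_FEATURES: tuple[str, ...] = _spectral_names()
FEATURES_PER_CHANNEL: int = len(TIME_FEATURES) + len(SPECTRAL_FEATURES)


def welch_resolution_hz(rate: float, window_s: float = 5.0) -> float:
    """Frequency-bin spacing of the Welch estimator (1 / window length)."""
    return rate / round(window_s * rate)


# ---------------------------------------------------------------------------
# Time-domain features (vectorised over rows)
# ---------------------------------------------------------------------------


def _forward_fill_sign(s: np.ndarray) -> np.ndarray:
    # exact zeros carry the previous sample's sign (leading zeros stay 0)
    idx = np.where(s != 0, np.arange(s.shape[1])[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    return np.take_along_axis(s, idx, axis=1)


def _zero_crossings(x: np.ndarray) -> np.ndarray:
    s = _forward_fill_sign(np.sign(x))
    return (s[:, 1:] * s[:, :-1] < 0).sum(axis=1).astype(np.float64)


def _hjorth(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vx = np.var(x, axis=1)
    d1 = np.diff(x, axis=1)
    d2 = np.diff(d1, axis=1)
    vd1 = np.var(d1, axis=1)
    vd2 = np.var(d2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mob = np.sqrt(np.where(vx > 0, vd1 / np.where(vx > 0, vx, 1.0), 0.0))
        mob_d = np.sqrt(np.where(vd1 > 0, vd2 / np.where(vd1 > 0, vd1, 1.0), 0.0))
        comp = np.where(mob > 0, mob_d / np.where(mob > 0, mob, 1.0), 0.0)
    return mob, comp


def _perm_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> np.ndarray:
    """Normalized permutation entropy (0 for monotone signals, →1 for noise)."""
    n, m = x.shape
    nvec = m - (order - 1) * delay
    emb = np.stack([x[:, i * delay : i * delay + nvec] for i in range(order)], axis=-1)
    ranks = np.argsort(emb, axis=-1, kind="stable")
    # encode each ordinal pattern as a base-`order` integer
    weights = order ** np.arange(order - 1, -1, -1)
    codes = (ranks * weights).sum(axis=-1)
    ncodes = order**order
    offset = (np.arange(n) * ncodes)[:, None]
    counts = np.bincount((codes + offset).ravel(), minlength=n * ncodes).reshape(n, ncodes)
    p = counts / nvec
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    return h / np.log(float(_math.factorial(order)))


def _petrosian_fd(x: np.ndarray) -> np.ndarray:
    n = x.shape[1]
    d = np.diff(x, axis=1)
    n_delta = _zero_crossings(d)
    logn = np.log10(n)
    return logn / (logn + np.log10(n / (n + 0.4 * n_delta)))


def _higuchi_fd(x: np.ndarray, kmax: int = 10) -> np.ndarray:
    n_rows, n = x.shape
    lk = np.empty((kmax, n_rows))
    for k in range(1, kmax + 1):
        lm = np.zeros(n_rows)
        for m0 in range(k):
            n_i = (n - m0 - 1) // k
            if n_i < 1:
                continue
            idx = m0 + k * np.arange(n_i + 1)
            seg = np.abs(np.diff(x[:, idx], axis=1)).sum(axis=1)
            lm += seg * (n - 1) / (n_i * k) / k
        lk[k - 1] = lm / k
    valid = np.all(lk > 0, axis=0)
    out = np.ones(n_rows)  # flat signal: curve length is scale-free, dimension 1
    if np.any(valid):
        logk = np.log(1.0 / np.arange(1, kmax + 1))
        a = np.vstack([logk, np.ones(kmax)]).T
        coef, *_ = np.linalg.lstsq(a, np.log(lk[:, valid]), rcond=None)
        out[valid] = coef[0]
    return out


def _time_domain_matrix(x: np.ndarray) -> dict[str, np.ndarray]:
    if x.shape[1] < 100:
        raise ValueError(f"epoch too short ({x.shape[1]} samples); need ≥ 100")
    degen = np.ptp(x, axis=1) == 0  # exactly flat epochs
    std = np.where(degen, 0.0, np.std(x, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = np.where(degen, 0.0, spstats.skew(x, axis=1, bias=True))
        kurt = np.where(degen, 0.0, spstats.kurtosis(x, axis=1, bias=True))
    mob, comp = _hjorth(x)
    mob = np.where(degen, 0.0, mob)
    comp = np.where(degen, 0.0, comp)
    pe = np.where(degen, 0.0, _perm_entropy(x))
    return {
        "std": std,
        "iqr": spstats.iqr(x, axis=1),
        "skew": skew,
        "kurtosis": kurt,
        "nzc": _zero_crossings(x),
        "hjorth_mobility": mob,
        "hjorth_complexity": comp,
        "perm_entropy": pe,
        "petrosian_fd": _petrosian_fd(x),
        "higuchi_fd": np.where(degen, 1.0, _higuchi_fd(x)),
    }


def time_domain_features(x: np.ndarray) -> dict[str, float]:
    """Time-domain feature set for a single epoch (≥ 100 samples)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a non-empty 1-D epoch signal")
    return {k: float(v[0]) for k, v in _time_domain_matrix(x[None, :]).items()}


# ---------------------------------------------------------------------------
# Frequency-domain features
# ---------------------------------------------------------------------------


def _band_masks(
    freqs: np.ndarray, bands: tuple[BandDefinition, ...]
) -> list[np.ndarray]:
    masks = []
    for i, b in enumerate(bands):
        lo = freqs >= b.low - 1e-9
        if i == len(bands) - 1:
            hi = freqs <= b.high + 1e-9  # last band closed at its upper edge
        else:
            hi = freqs < b.high - 1e-9
        masks.append(lo & hi)
    return masks


def _spectral_matrix(
    x: np.ndarray, rate: float, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> dict[str, np.ndarray]:
    nperseg = int(round(5.0 * rate))
    if x.shape[1] < nperseg:
        raise ValueError(
            f"epoch ({x.shape[1]} samples) shorter than one 5-s Welch segment ({nperseg})"
        )
    if rate < 2 * max(b.high for b in bands):
        raise ValueError(f"rate {rate} Hz too low for band edges up to {max(b.high for b in bands)} Hz")
    freqs, psd = sps.welch(
        x,
        fs=rate,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        average="median",
        axis=-1,
    )
    df = freqs[1] - freqs[0]
    masks = _band_masks(freqs, bands)
    band_pow = np.stack([psd[:, m].sum(axis=1) * df for m in masks], axis=1)
    total = band_pow.sum(axis=1)
    rel = band_pow / np.where(total > 0, total, 1.0)[:, None]
    out: dict[str, np.ndarray] = {
        f"relpow_{b.name}": rel[:, i] for i, b in enumerate(bands)
    }
    out["abspow_broadband"] = np.log10(total + _EPS)
    by_name = {b.name: i for i, b in enumerate(bands)}
    for rname, num, den in _RATIOS:
        if num in by_name and den in by_name:
            out[rname] = rel[:, by_name[num]] / (rel[:, by_name[den]] + _EPS)
    return out


def spectral_features(
    x: np.ndarray, rate: float, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> dict[str, float]:
    """Spectral feature set for a single epoch."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("expected a non-empty 1-D epoch signal")
    return {k: float(v[0]) for k, v in _spectral_matrix(x[None, :], rate, bands).items()}


# ---------------------------------------------------------------------------
# Per-night extraction
# ---------------------------------------------------------------------------


def extract_features(
    channels: list[EpochedChannel],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Raw (per-epoch, unsmoothed) feature table for one night.

    Columns are named ``{role}_{feature}`` in lower case, e.g. ``eeg_std`` or
    ``eog_relpow_delta``; identical feature sets are computed for every
    channel role. Rows align with epochs.
    """
    if not channels:
        raise ValueError("need at least one epoched channel")
    n_epochs = {c.n_epochs for c in channels}
    if len(n_epochs) != 1:
        raise ValueError(f"channels are not epoch-aligned: counts {sorted(n_epochs)}")
    cols: dict[str, np.ndarray] = {}
    for ch in channels:
        prefix = ch.role.lower()
        for name, vals in _time_domain_matrix(ch.epochs).items():
            cols[f"{prefix}_{name}"] = vals
        for name, vals in _spectral_matrix(ch.epochs, ch.rate, bands).items():
            cols[f"{prefix}_{name}"] = vals
    df = pd.DataFrame(cols)
    if not np.all(np.isfinite(df.to_numpy())):
        bad = df.columns[~np.isfinite(df.to_numpy()).all(axis=0)].tolist()
        raise ValueError(f"non-finite feature values in columns {bad}")
    return df
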