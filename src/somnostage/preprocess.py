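"""Signal conditioning: resampling, bandpass filtering, epoch segmentation.

The analysis chain mirrors standard practice in feature-based sleep staging:
every channel is brought to a common 100 Hz analysis rate (polyphase
resampling with an anti-alias FIR), bandpass-filtered 0.4–30 Hz with a
zero-phase linear-phase FIR, and cut into complete 30-s epochs (a trailing
partial epoch is dropped — scoring is only defined on whole epochs).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .core import Channel, Recording

__all__ = ["TARGET_RATE", "DEFAULT_BAND", "EpochedChannel", "resample", "bandpass", "epoch"]

#: Common analysis rate in Hz.
TARGET_RATE: float = 100.0

#: Default analysis band in Hz.
DEFAULT_BAND: tuple[float, float] = (0.4, 30.0)


@dataclass
class EpochedChannel:
    """One channel segmented into complete epochs (n_epochs × samples_per_epoch, µV)."""

    role: str
    epochs: np.ndarray
    rate: float
    epoch_len_s: float = 30.0

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 2:
            raise ValueError("epochs must be a 2-D matrix")
        expected = self.rate * self.epoch_len_s
        if abs(expected - round(expected)) > 1e-9 or self.epochs.shape[1] != int(round(expected)):
            raise ValueError(
                f"samples_per_epoch must equal rate*epoch_len_s = {expected}, "
                f"got {self.epochs.shape[1]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def resample(rec: Recording, target_rate: float = TARGET_RATE) -> Recording:
    """Downsample every channel to ``target_rate`` with anti-alias filtering.

    Upsampling is not supported: staging features were designed at 100 Hz
    and fabricating higher-frequency content would be misleading.
    """
    channels = []
    for c in rec.channels:
        if target_rate > c.rate + 1e-9:
            raise ValueError(
                f"channel {c.label}: cannot upsample {c.rate} Hz to {target_rate} Hz"
            )
        if abs(c.rate - target_rate) < 1e-9:
            channels.append(Channel(c.label, c.role, c.samples.copy(), c.rate))
            continue
        frac = Fraction(target_rate / c.rate).limit_denominator(1000)
        out = sps.resample_poly(c.samples, frac.numerator, frac.denominator, padtype="line")
        channels.append(Channel(c.label, c.role, out, target_rate))
    return Recording(channels=channels, start_time=rec.start_time)


def _bandpass_fir(rate: float, low: float, high: float) -> np.ndarray:
    # Hamming-window FIR; transition widths min(low, 2)/5 Hz at the two edges.
    trans_lo = min(low, 2.0)
    trans_hi = 5.0
    width = min(trans_lo, trans_hi)
    # length for a Hamming design: ~3.3 / (width / rate) taps, forced odd
    ntaps = int(np.ceil(3.3 * rate / width)) | 1
    return sps.firwin(ntaps, [low, high], pass_zero=False, window="hamming", fs=rate)


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # The Hamming FIR is symmetric (linear phase), so forward-backward
    # filtering equals two centered convolutions; FFT convolution keeps the
    # cost manageable for full-night signals. Odd reflection padding tames
    # edge transients, as in filtfilt.
    pad = min(3 * len(taps), len(x) - 1)
    left = 2 * x[0] - x[pad:0:-1]
    right = 2 * x[-1] - x[-2 : -pad - 2 : -1]
    xp = np.concatenate([left, x, right])
    for _ in range(2):
        xp = sps.fftconvolve(xp, taps, mode="same")
    return xp[pad : pad + len(x)]


def bandpass(rec: Recording, low: float = DEFAULT_BAND[0], high: float = DEFAULT_BAND[1]) -> Recording:
    """Zero-phase bandpass: linear-phase FIR applied forward and backward."""
    channels = []
    for c in rec.channels:
        nyq = c.rate / 2
        if not (0 < low < high < nyq):
            raise ValueError(
                f"band ({low}, {high}) Hz invalid for rate {c.rate} Hz (Nyquist {nyq})"
            )
        taps = _bandpass_fir(c.rate, low, high)
        if len(c.samples) <= len(taps):
            raise ValueError(
                f"channel {c.label}: signal too short ({len(c.samples)} samples) "
                f"for the {len(taps)}-tap filter"
            )
        out = _zero_phase_fir(c.samples, taps)
        channels.append(Channel(c.label, c.role, out, c.rate))
    return Recording(channels=channels, start_time=rec.start_time)


def epoch(rec: Recording, epoch_len_s: float = 30.0) -> list[EpochedChannel]:
    """Segment every channel into complete epochs; partial trailing epochs drop.

    All channels of a recording yield the same epoch count, aligned in time.
    """
    n_epochs = int(rec.duration_s // epoch_len_s)
    if n_epochs < 1:
        raise ValueError(
            f"recording too short ({rec.duration_s:.1f} s) for one {epoch_len_s:.0f}-s epoch"
        )
    out = []
    for c in rec.channels:
        spe = c.rate * epoch_len_s
        if abs(spe - round(spe)) > 1e-9:
            raise ValueError(f"rate {c.rate} Hz does not tile {epoch_len_s}-s epochs")
        spe = int(round(spe))
        mat = c.samples[: n_epochs * spe].reshape(n_epochs, spe)
        out.append(EpochedChannel(role=c.role, epochs=mat, rate=c.rate, epoch_len_s=epoch_len_s))
    return out
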