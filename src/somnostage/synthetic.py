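"""Reproducible synthetic PSG nights: hypnograms, signals, scorer panels.

The generator exists so the full staging pipeline can be exercised without
any clinical data. It emulates the two properties the classifier relies on:

1. *Hypnogram structure*: a first-order Markov chain over the five stages
   with strong self-transitions, started in Wake, plus a time-inhomogeneity
   factor that biases deep N3 sleep toward the first half of the night and
   REM toward the second half — the well-known overnight asymmetry.
2. *Stage-conditioned signals*: each 30-s epoch of each channel is colored
   Gaussian noise whose piecewise-flat spectrum matches a per-stage band
   profile over the six analysis bands (0.4–30 Hz), scaled to a per-stage
   RMS amplitude in µV with mild lognormal epoch-to-epoch jitter. Default
   profiles separate stages the way real sleep EEG does: delta-dominant N3,
   a sigma (spindle-band) bump in N2, alpha-rich Wake, low-amplitude
   mixed-frequency N1/REM, and an EMG amplitude drop in REM (atonia).

Synthetic scorer panels corrupt a ground-truth hypnogram independently per
scorer at a given error rate, drawing the wrong label from an
adjacent-stage kernel (scorers confuse N2 with N1/N3, not N3 with REM).

A single integer master seed derives all substreams, so a whole experiment
is reproducible from one number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import STAGES, STAGE_TO_INDEX, UNSCORED, Channel, Hypnogram, Recording
from .consensus import ScorerPanel
from .features import DEFAULT_BANDS, BandDefinition

__all__ = [
    "HypnogramModel",
    "StageSignalModel",
    "generate_hypnogram",
    "generate_psg",
    "generate_night",
    "generate_scorer_panel",
    "ADJACENT_STAGE_KERNEL",
]

#: Default per-stage, per-role relative band-power profiles over
#: (slow, delta, theta, alpha, sigma, beta) and RMS amplitudes in µV.
_EEG_PROFILES = {
    "W": ([0.05, 0.15, 0.15, 0.40, 0.10, 0.15], 30.0),
    "N1": ([0.10, 0.28, 0.32, 0.15, 0.05, 0.10], 25.0),
    "N2": ([0.15, 0.33, 0.22, 0.08, 0.17, 0.05], 35.0),
    "N3": ([0.20, 0.60, 0.10, 0.04, 0.03, 0.03], 55.0),
    "R": ([0.08, 0.22, 0.35, 0.15, 0.05, 0.15], 25.0),
}
_EOG_PROFILES = {
    "W": ([0.10, 0.20, 0.15, 0.30, 0.10, 0.15], 35.0),
    "N1": ([0.25, 0.35, 0.20, 0.10, 0.04, 0.06], 30.0),
    "N2": ([0.20, 0.35, 0.25, 0.08, 0.07, 0.05], 30.0),
    "N3": ([0.25, 0.50, 0.15, 0.04, 0.03, 0.03], 45.0),
    "R": ([0.40, 0.30, 0.15, 0.06, 0.03, 0.06], 40.0),
}
_EMG_FLAT = [0.05, 0.10, 0.15, 0.15, 0.15, 0.40]
_EMG_PROFILES = {
    "W": (_EMG_FLAT, 28.0),
    "N1": (_EMG_FLAT, 13.0),
    "N2": (_EMG_FLAT, 11.0),
    "N3": (_EMG_FLAT, 10.0),
    "R": (_EMG_FLAT, 5.0),  # REM atonia
}

#: Plausible mis-scoring targets per true stage.
ADJACENT_STAGE_KERNEL: dict[str, tuple[str, ...]] = {
    "W": ("N1",),
    "N1": ("W", "N2"),
    "N2": ("N1", "N3"),
    "N3": ("N2",),
    "R": ("N1", "W"),
}

#: Default stage transition matrix (rows/cols in canonical order).
_DEFAULT_TRANSITIONS = np.array(
    [
        [0.90, 0.07, 0.03, 0.00, 0.00],  # W
        [0.09, 0.62, 0.24, 0.00, 0.05],  # N1
        [0.02, 0.04, 0.85, 0.06, 0.03],  # N2
        [0.01, 0.01, 0.10, 0.88, 0.00],  # N3
        [0.02, 0.04, 0.04, 0.00, 0.90],  # R
    ]
)


@dataclass
class HypnogramModel:
    """Markov-chain model of a night's stage sequence."""

    transitions: np.ndarray = field(default_factory=lambda: _DEFAULT_TRANSITIONS.copy())
    initial: np.ndarray = field(default_factory=lambda: np.array([0.9, 0.1, 0.0, 0.0, 0.0]))
    n_epochs: int = 960  # 8 h of 30-s epochs
    #: Strength of the early-N3 / late-REM bias (0 = homogeneous chain).
    asymmetry: float = 0.4
    epoch_len_s: float = 30.0

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.initial = np.asarray(self.initial, dtype=np.float64)
        if self.transitions.shape != (5, 5) or np.any(self.transitions < 0):
            raise ValueError("transition matrix must be 5x5 nonnegative")
        if np.any(np.abs(self.transitions.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > 1e-9 or np.any(self.initial < 0):
            raise ValueError("initial distribution must be a probability vector")
        if self.n_epochs < 15:
            raise ValueError("night length must be at least 15 epochs")

    def stationary_distribution(self) -> np.ndarray:
        """Long-run stage distribution of the homogeneous base chain."""
        vals, vecs = np.linalg.eig(self.transitions.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()

    def transitions_at(self, frac: float) -> np.ndarray:
        """Row-stochastic matrix at normalized night time ``frac`` ∈ [0, 1]."""
        p = self.transitions.copy()
        bias = self.asymmetry * (1.0 - 2.0 * frac)  # >0 early, <0 late
        p[:, STAGE_TO_INDEX["N3"]] *= 1.0 + bias
        p[:, STAGE_TO_INDEX["R"]] *= 1.0 - bias
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class StageSignalModel:
    """Per-stage/per-role spectral profile and amplitude for signal synthesis."""

    #: role → stage → (band profile over DEFAULT_BANDS, RMS in µV)
    profiles: dict[str, dict[str, tuple[list[float], float]]] = field(
        default_factory=lambda: {"EEG": _EEG_PROFILES, "EOG": _EOG_PROFILES, "EMG": _EMG_PROFILES}
    )
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    #: σ of the lognormal per-epoch amplitude jitter (0 disables it).
    amplitude_jitter: float = 0.25
    #: σ of the lognormal per-epoch, per-band profile jitter — within-stage
    #: spectral variability that makes neighbouring stages overlap.
    band_jitter: float = 0.4
    #: Weight given to the neighbouring epochs' stage profiles; epochs at a
    #: stage boundary carry a spectral blend of both stages, as real
    #: transitions are gradual rather than instantaneous.
    transition_blend: float = 0.3

    def __post_init__(self) -> None:
        for role, stages in self.profiles.items():
            for stage, (prof, rms) in stages.items():
                prof = np.asarray(prof, dtype=np.float64)
                if len(prof) != len(self.bands) or np.any(prof < 0):
                    raise ValueError(f"{role}/{stage}: profile must be nonnegative per band")
                if abs(prof.sum() - 1.0) > 1e-6:
                    raise ValueError(f"{role}/{stage}: band profile must sum to 1")
                if rms <= 0:
                    raise ValueError(f"{role}/{stage}: RMS must be positive")


def generate_hypnogram(hm: HypnogramModel | None = None, seed: int = 0) -> Hypnogram:
    """Sample one night's stage sequence; deterministic per seed."""
    hm = hm or HypnogramModel()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = hm.n_epochs
    out = np.empty(n, dtype=np.int64)
    out[0] = rng.choice(5, p=hm.initial)
    for t in range(1, n):
        p = hm.transitions_at(t / (n - 1))
        out[t] = rng.choice(5, p=p[out[t - 1]])
    return Hypnogram(stages=np.asarray(STAGES)[out], epoch_len_s=hm.epoch_len_s)


_ROLE_LABELS = {"EEG": "C4-M1", "EOG": "EOG-L", "EMG": "EMG-Chin"}


def generate_psg(
    hyp: Hypnogram,
    sm: StageSignalModel | None = None,
    rate: float = 100.0,
    seed: int = 0,
) -> Recording:
    """Synthesize stage-conditioned EEG/EOG/EMG for a hypnogram.

    Every epoch's spectrum follows its stage's band profile; unscored epochs
    get Wake-like signal. Deterministic per seed.
    """
    sm = sm or StageSignalModel()
    if rate < 2 * max(b.high for b in sm.bands):
        raise ValueError(f"rate {rate} Hz below Nyquist for {max(b.high for b in sm.bands)} Hz bands")
    spe = int(round(rate * hyp.epoch_len_s))
    n = len(hyp)
    freqs = np.fft.rfftfreq(spe, d=1.0 / rate)
    stage_codes = np.array(
        [STAGE_TO_INDEX[s] for s in np.where(hyp.scored_mask, hyp.stages, "W")]
    )
    # bin→band index map for per-epoch gain construction
    band_idx = np.full(len(freqs), -1)
    band_nbins = np.zeros(len(sm.bands))
    for bi, b in enumerate(sm.bands):
        mask = (freqs >= b.low) & (freqs <= b.high) & (band_idx < 0)
        band_idx[mask] = bi
        band_nbins[bi] = max(mask.sum(), 1)
    inband = band_idx >= 0

    ss = np.random.SeedSequence(seed)
    channels = []
    for role, child in zip(("EEG", "EOG", "EMG"), ss.spawn(3)):
        rng = np.random.default_rng(child)
        prof_by_stage = np.stack(
            [np.asarray(sm.profiles[role][s][0], dtype=np.float64) for s in STAGES]
        )
        rms_by_stage = np.array([sm.profiles[role][s][1] for s in STAGES])
        profiles = prof_by_stage[stage_codes]  # (n, n_bands)
        rms = rms_by_stage[stage_codes].astype(np.float64)
        if sm.transition_blend > 0 and n > 1:
            # epochs bordering a stage change carry a blend of both stages
            mu = sm.transition_blend
            prev_ = np.r_[stage_codes[:1], stage_codes[:-1]]
            next_ = np.r_[stage_codes[1:], stage_codes[-1:]]
            profiles = (
                (1 - mu) * profiles
                + (mu / 2) * (prof_by_stage[prev_] + prof_by_stage[next_])
            )
            rms = (1 - mu) * rms + (mu / 2) * (rms_by_stage[prev_] + rms_by_stage[next_])
        if sm.band_jitter > 0:
            profiles = profiles * np.exp(
                rng.normal(0.0, sm.band_jitter, profiles.shape)
            )
            profiles /= profiles.sum(axis=1, keepdims=True)
        if sm.amplitude_jitter > 0:
            rms = rms * np.exp(rng.normal(0.0, sm.amplitude_jitter, n))

        gains = np.zeros((n, len(freqs)))
        gains[:, inband] = np.sqrt(
            profiles[:, band_idx[inband]] / band_nbins[band_idx[inband]]
        )
        white = rng.standard_normal((n, spe))
        shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * gains, n=spe, axis=1)
        sd = shaped.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        sig = shaped / sd * rms[:, None]
        channels.append(
            Channel(label=_ROLE_LABELS[role], role=role, samples=sig.ravel(), rate=rate)
        )
    return Recording(channels=channels)


def generate_night(
    seed: int,
    hm: HypnogramModel | None = None,
    sm: StageSignalModel | None = None,
    rate: float = 100.0,
) -> tuple[Recording, Hypnogram]:
    """One complete synthetic night (recording + ground-truth hypnogram)."""
    ss = np.random.SeedSequence(seed)
    hyp_seed, psg_seed = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    hyp = generate_hypnogram(hm, seed=hyp_seed)
    rec = generate_psg(hyp, sm, rate=rate, seed=psg_seed)
    return rec, hyp


def generate_scorer_panel(
    truth: Hypnogram,
    error_rate: float = 0.2,
    n_scorers: int = 5,
    seed: int = 0,
) -> ScorerPanel:
    """Corrupt the truth independently per scorer at ``error_rate`` per epoch.

    Wrong labels come from :data:`ADJACENT_STAGE_KERNEL`, so every corruption
    changes the stage. Unscored epochs stay unscored for every scorer.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    if n_scorers < 3:
        raise ValueError("a useful panel needs at least three scorers")
    ss = np.random.SeedSequence(seed)
    hyps = []
    for child in ss.spawn(n_scorers):
        rng = np.random.default_rng(child)
        stages = truth.stages.copy()
        flip = rng.random(len(truth)) < error_rate
        for e in np.flatnonzero(flip & truth.scored_mask):
            options = ADJACENT_STAGE_KERNEL[stages[e]]
            stages[e] = options[rng.integers(len(options))]
        stages[~truth.scored_mask] = UNSCORED
        hyps.append(Hypnogram(stages=stages, epoch_len_s=truth.epoch_len_s))
    return ScorerPanel(hypnograms=hyps)
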