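"""Core domain types: recordings, hypnograms, and the canonical stage alphabet.

Sleep is scored in 30-second epochs over the five AASM stages: Wake (W),
the three non-REM depths (N1, N2, N3) and REM sleep (R). Everything in this
package — probability matrices, confusion matrices, argmax tie-breaking —
uses the single canonical order ``["W", "N1", "N2", "N3", "R"]``.

Epochs that a scorer left unscored (movement time, unknown, lights on) carry
the sentinel :data:`UNSCORED`; they are kept in sequences so epoch indices
stay aligned with the recording, but are excluded from training and metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical stage order used for all matrices and tie-breaks.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")

#: Sentinel for epochs without a valid stage label.
UNSCORED: str = "UNS"

STAGE_TO_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Default epoch length in seconds (the AASM scoring unit).
EPOCH_LEN_S: float = 30.0


def stage_indices(stages: np.ndarray) -> np.ndarray:
    """Map an array of stage tokens to canonical integer codes (UNSCORED -> -1)."""
    out = np.full(len(stages), -1, dtype=np.int64)
    for name, idx in STAGE_TO_INDEX.items():
        out[np.asarray(stages) == name] = idx
    return out


@dataclass
class Channel:
    """One physiological signal trace in microvolts."""

    label: str
    role: str  # "EEG", "EOG", "EMG" or "other"
    samples: np.ndarray  # 1-D float array, µV
    rate: float  # Hz

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("channel samples must be 1-D")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Recording:
    """A multichannel PSG recording; channels may have different native rates."""

    channels: list[Channel]
    start_time: object | None = None

    def __post_init__(self) -> None:
        roles = [c.role for c in self.channels if c.role in ("EEG", "EOG", "EMG")]
        if len(roles) != len(set(roles)):
            raise ValueError("each of EEG/EOG/EMG may be assigned at most once")
        if self.channels:
            durs = [c.duration_s for c in self.channels]
            tol = max(1.0 / c.rate for c in self.channels)
            if max(durs) - min(durs) > tol:
                raise ValueError(
                    f"channels span unequal durations: {min(durs):.3f}s vs {max(durs):.3f}s"
                )

    @property
    def duration_s(self) -> float:
        return min(c.duration_s for c in self.channels)

    def get(self, role: str) -> Channel:
        for c in self.channels:
            if c.role == role:
                return c
        raise KeyError(f"no channel with role {role!r}; have {[c.role for c in self.channels]}")

    @property
    def roles(self) -> list[str]:
        return [c.role for c in self.channels if c.role in ("EEG", "EOG", "EMG")]


@dataclass
class Hypnogram:
    """Per-epoch stage sequence with a scored mask.

    ``stages`` holds canonical tokens (or :data:`UNSCORED`); ``scored_mask``
    is False exactly where the stage is the unscored sentinel.
    """

    stages: np.ndarray
    scored_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_len_s: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="<U3")
        if self.scored_mask is None:
            self.scored_mask = self.stages != UNSCORED
        self.scored_mask = np.asarray(self.scored_mask, dtype=bool)
        if len(self.stages) != len(self.scored_mask):
            raise ValueError("stages and scored_mask must have equal length")
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be positive")
        bad = set(np.unique(self.stages)) - set(STAGES) - {UNSCORED}
        if bad:
            raise ValueError(f"non-canonical stage tokens: {sorted(bad)}")
        # keep the sentinel and the mask consistent
        self.stages = np.where(self.scored_mask, self.stages, UNSCORED).astype("<U3")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def indices(self) -> np.ndarray:
        """Integer stage codes, -1 for unscored epochs."""
        return stage_indices(self.stages)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.stages == other.stages))
            and self.epoch_len_s == other.epoch_len_s
        )


@dataclass
class StageProbabilities:
    """Per-epoch stage probabilities over the canonical order; rows sum to 1."""

    probs: np.ndarray  # (n_epochs, 5)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(STAGES):
            raise ValueError(f"probs must be (n_epochs, {len(STAGES)})")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        rows = self.probs.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("each probability row must sum to 1")

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def confidence(self) -> np.ndarray:
        """Row maximum — the classifier's confidence at each epoch."""
        return self.probs.max(axis=1)

    def argmax_stages(self) -> np.ndarray:
        """Most probable stage per epoch; ties go to the earlier canonical stage."""
        return np.asarray(STAGES)[self.probs.argmax(axis=1)]

    def runner_up_stages(self) -> np.ndarray:
        """Second most probable stage per epoch (same tie-break)."""
        order = np.argsort(-self.probs, axis=1, kind="stable")
        return np.asarray(STAGES)[order[:, 1]]
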