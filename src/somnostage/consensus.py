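"""Consensus hypnograms from multiple human scorers.

Inter-scorer agreement on sleep staging is imperfect (especially for N1), so
reference hypnograms are often built by majority vote over several experts.
The consensus stage at an epoch is the most voted stage; when the vote ties,
the label of the *most reliable* scorer — the one with the highest average
pairwise agreement with all other scorers for that night — is used. For
evaluating an individual scorer without self-contamination, the
leave-one-out (N−1) consensus excludes that scorer and tie-breaks with the
most reliable of the remaining ones.

Epochs some scorers left unscored are voted among the scorers who did score
them; an epoch unscored by everyone stays unscored in the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import STAGES, UNSCORED, Hypnogram

__all__ = [
    "ScorerPanel",
    "pairwise_agreement",
    "most_reliable",
    "consensus_hypnogram",
    "loo_consensus",
]


@dataclass
class ScorerPanel:
    """Equal-length hypnograms from ≥ 2 independent scorers of one night."""

    hypnograms: list[Hypnogram]
    scorer_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.hypnograms) < 2:
            raise ValueError("a panel needs at least two scorers")
        lengths = {len(h) for h in self.hypnograms}
        if len(lengths) != 1:
            raise ValueError(f"scorers have unequal epoch counts: {sorted(lengths)}")
        epoch_lens = {h.epoch_len_s for h in self.hypnograms}
        if len(epoch_lens) != 1:
            raise ValueError("scorers have mismatched epoch lengths")
        if self.scorer_ids is None:
            self.scorer_ids = [f"scorer{i + 1}" for i in range(len(self.hypnograms))]
        if len(self.scorer_ids) != len(self.hypnograms):
            raise ValueError("scorer_ids length must match the number of hypnograms")

    @property
    def n_scorers(self) -> int:
        return len(self.hypnograms)

    def __len__(self) -> int:
        return len(self.hypnograms[0])


def pairwise_agreement(panel: ScorerPanel) -> np.ndarray:
    """Symmetric matrix of epoch-wise agreement proportions (diagonal 1).

    Entry (i, j) is the fraction of epochs scored by *both* i and j on which
    they assigned the same stage.
    """
    k = panel.n_scorers
    stages = np.stack([h.stages for h in panel.hypnograms])
    scored = np.stack([h.scored_mask for h in panel.hypnograms])
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            both = scored[i] & scored[j]
            if not both.any():
                raise ValueError(f"scorers {i} and {j} share no scored epochs")
            out[i, j] = out[j, i] = float(np.mean(stages[i][both] == stages[j][both]))
    return out


def most_reliable(panel: ScorerPanel) -> int:
    """Index of the scorer with the highest mean agreement with the others.

    Ties go to the lowest index. Requires ≥ 3 scorers so the mean over
    "all other scorers" is meaningful.
    """
    if panel.n_scorers < 3:
        raise ValueError("reliability ranking needs at least three scorers")
    agree = pairwise_agreement(panel)
    k = panel.n_scorers
    means = (agree.sum(axis=1) - 1.0) / (k - 1)  # exclude the diagonal
    # lowest index wins ties; tolerance guards float summation-order noise
    return int(np.flatnonzero(means >= means.max() - 1e-12)[0])


def consensus_hypnogram(panel: ScorerPanel) -> Hypnogram:
    """Per-epoch plurality stage, vote ties broken by the most reliable scorer.

    If the most reliable scorer's label is not among the tied top stages at
    an epoch (possible when they did not score it), the tie falls back to
    the earliest canonical stage among those tied.
    """
    ref_idx = most_reliable(panel)
    return _vote(panel.hypnograms, ref_idx, panel.hypnograms[0].epoch_len_s)


def loo_consensus(panel: ScorerPanel, excluded: int) -> Hypnogram:
    """Consensus of the N−1 scorers excluding ``excluded`` (needs ≥ 4 scorers)."""
    if panel.n_scorers < 4:
        raise ValueError("leave-one-out consensus needs at least four scorers")
    if not 0 <= excluded < panel.n_scorers:
        raise IndexError(f"scorer index {excluded} out of range")
    rest = [h for i, h in enumerate(panel.hypnograms) if i != excluded]
    ids = [s for i, s in enumerate(panel.scorer_ids) if i != excluded]
    return consensus_hypnogram(ScorerPanel(hypnograms=rest, scorer_ids=ids))


def _vote(hyps: list[Hypnogram], ref_idx: int, epoch_len_s: float) -> Hypnogram:
    n = len(hyps[0])
    codes = np.stack([h.indices for h in hyps])  # -1 = unscored
    out = np.full(n, UNSCORED, dtype="<U3")
    stage_arr = np.asarray(STAGES)
    for e in range(n):
        votes = codes[:, e]
        votes = votes[votes >= 0]
        if votes.size == 0:
            continue
        counts = np.bincount(votes, minlength=len(STAGES))
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1:
            out[e] = stage_arr[tied[0]]
        else:
            ref_vote = codes[ref_idx, e]
            if ref_vote in tied:
                out[e] = stage_arr[ref_vote]
            else:
                out[e] = stage_arr[tied[0]]
    return Hypnogram(stages=out, epoch_len_s=epoch_len_s)
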