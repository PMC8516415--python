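import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnostage.core import STAGES, UNSCORED, Hypnogram, StageProbabilities
from somnostage.metrics import (
    ConfusionMatrix,
    agreement_scores,
    confusion,
    holm_adjust,
    stage_f1,
    stratified_report,
    transition_fraction,
    transition_mask,
)

from conftest import random_hypnogram


def _hyp(stages):
    return Hypnogram(np.array(stages, dtype="<U3"))


class TestConfusion:
    def test_identity_is_diagonal(self):
        h = _hyp(["W", "N1", "N2", "N3", "R", "N2"])
        cm = confusion(h, h).counts
        assert np.all(cm == np.diag(np.diag(cm)))
        assert cm.sum() == 6

    def test_single_offdiagonal_cell(self):
        ref = _hyp(["N2"] * 7)
        pred = _hyp(["N3"] * 7)
        cm = confusion(ref, pred).counts
        assert cm[2, 3] == 7 and cm.sum() == 7

    def test_unscored_epochs_excluded(self):
        ref = _hyp(["W", UNSCORED, "N2"])
        pred = _hyp(["W", "N2", UNSCORED])
        assert confusion(ref, pred).total == 1

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ref = random_hypnogram(rng, 60, unscored_frac=0.1)
            pred = random_hypnogram(rng, 60, unscored_frac=0.1)
            cm = confusion(ref, pred).counts
            brute = np.zeros((5, 5), dtype=int)
            for r, p, mr, mp in zip(ref.indices, pred.indices, ref.scored_mask, pred.scored_mask):
                if mr and mp:
                    brute[r, p] += 1
            assert np.array_equal(cm, brute)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="lengths"):
            confusion(_hyp(["W"]), _hyp(["W", "W"]))


class TestAgreementScores:
    def test_perfect_agreement(self):
        cm = ConfusionMatrix(np.diag([10, 5, 20, 8, 7]))
        s = agreement_scores(cm)
        assert s == {"accuracy": 1.0, "kappa": 1.0, "mcc": 1.0}

    def test_two_class_closed_form(self):
        # [[40, 10], [5, 45]] embedded in the 5x5 frame:
        # acc = 0.85; pe = (50*45 + 50*55)/100^2 = 0.5 → kappa = 0.7;
        # mcc = (85*100 - 5000)/sqrt((100^2-5000)(100^2-5050)) = 0.703526...
        c = np.zeros((5, 5), dtype=int)
        c[0, 0], c[0, 1], c[1, 0], c[1, 1] = 40, 10, 5, 45
        s = agreement_scores(ConfusionMatrix(c))
        assert s["accuracy"] == pytest.approx(0.85)
        assert s["kappa"] == pytest.approx(0.70)
        assert s["mcc"] == pytest.approx(3500 / np.sqrt(5000 * 4950))

    def test_constant_prediction_has_zero_kappa(self):
        c = np.zeros((5, 5), dtype=int)
        c[:, 2] = [10, 10, 10, 10, 10]  # every stage predicted N2
        s = agreement_scores(ConfusionMatrix(c))
        assert s["kappa"] == pytest.approx(0.0)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError, match="empty"):
            agreement_scores(ConfusionMatrix(np.zeros((5, 5), dtype=int)))


class TestStageF1:
    def test_harmonic_mean_fixed_point(self):
        c = np.zeros((5, 5), dtype=int)
        c[0, 0], c[0, 1], c[1, 0], c[1, 1] = 1, 1, 1, 1  # P = R = 0.5 for W and N1
        per, _ = stage_f1(ConfusionMatrix(c))
        assert per["W"] == pytest.approx(0.5)
        assert per["N1"] == pytest.approx(0.5)

    def test_perfect_matrix(self):
        per, macro = stage_f1(ConfusionMatrix(np.diag([3, 3, 3, 3, 3])))
        assert all(per[s] == 1.0 for s in STAGES)
        assert macro == 1.0

    def test_absent_stages_excluded_from_macro(self):
        c = np.zeros((5, 5), dtype=int)
        c[0, 0] = 5
        c[2, 2] = 5
        per, macro = stage_f1(ConfusionMatrix(c))
        assert np.isnan(per["R"])
        assert macro == 1.0

    def test_formula_oracle(self):
        rng = np.random.default_rng(11)
        c = rng.integers(0, 20, (5, 5))
        per, _ = stage_f1(ConfusionMatrix(c))
        for i, s in enumerate(STAGES):
            tp = c[i, i]
            prec = tp / c[:, i].sum() if c[:, i].sum() else 0.0
            rec = tp / c[i, :].sum() if c[i, :].sum() else 0.0
            expect = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert per[s] == pytest.approx(expect)


class TestTransitionMask:
    def test_constant_hypnogram_all_false(self):
        assert not transition_mask(_hyp(["N2"] * 20)).any()

    def test_single_transition_flags_six_epochs(self):
        stages = ["N2"] * 10 + ["N3"] * 10  # boundary between epochs 9 and 10
        mask = transition_mask(_hyp(stages))
        expected = np.zeros(20, dtype=bool)
        expected[7:13] = True  # k-2 … k+3 with k = 9
        assert np.array_equal(mask, expected)

    def test_alternating_stages_saturate(self):
        assert transition_mask(_hyp(["W", "N1"] * 10)).all()

    def test_invalid_window_errors(self):
        with pytest.raises(ValueError, match="window"):
            transition_mask(_hyp(["W"] * 10), window_min=0.7)

    def test_transition_fraction_relabel_invariant(self):
        rng = np.random.default_rng(6)
        h = random_hypnogram(rng, 100)
        relabel = {s: t for s, t in zip(STAGES, np.roll(STAGES, 2))}
        h2 = _hyp([relabel[s] for s in h.stages])
        assert transition_fraction(h) == transition_fraction(h2)


class TestStratifiedReport:
    def _probs_for(self, pred: Hypnogram, conf: float) -> StageProbabilities:
        probs = np.full((len(pred), 5), (1 - conf) / 4)
        probs[np.arange(len(pred)), pred.indices] = conf
        return StageProbabilities(probs)

    def test_perfect_prediction(self):
        h = _hyp(["W"] * 5 + ["N2"] * 10 + ["N3"] * 5)
        rep = stratified_report(h, h, self._probs_for(h, 0.9))
        assert rep.accuracy == 1.0
        assert rep.transition_accuracy == 1.0
        assert rep.stable_accuracy == 1.0
        assert rep.highconf_accuracy == 1.0
        assert rep.lowconf_accuracy is None
        assert rep.second_choice_accuracy is None  # no errors to rank

    def test_second_choice_constructed_to_one(self):
        ref = _hyp(["N2", "N2", "N2", "N2"])
        pred = _hyp(["N3", "N2", "N2", "N2"])
        probs = np.array(
            [
                [0.05, 0.05, 0.35, 0.50, 0.05],  # wrong, runner-up N2 = correct
                [0.05, 0.05, 0.80, 0.05, 0.05],
                [0.05, 0.05, 0.80, 0.05, 0.05],
                [0.05, 0.05, 0.80, 0.05, 0.05],
            ]
        )
        rep = stratified_report(ref, pred, StageProbabilities(probs))
        assert rep.second_choice_accuracy == 1.0

    def test_stratified_counts_recombine(self):
        rng = np.random.default_rng(13)
        ref = random_hypnogram(rng, 200)
        pred = random_hypnogram(rng, 200)
        raw = rng.random((200, 5))
        probs = StageProbabilities(raw / raw.sum(1, keepdims=True))
        rep = stratified_report(ref, pred, probs)
        trans = transition_mask(ref)
        correct = ref.indices == pred.indices
        n_trans = trans.sum()
        n_stable = 200 - n_trans
        total_correct = correct.sum()
        assert rep.transition_accuracy * n_trans + rep.stable_accuracy * n_stable == pytest.approx(
            total_correct
        )
        conf = probs.confidence
        n_hi = (conf >= 0.8).sum()
        hi_term = 0.0 if rep.highconf_accuracy is None else rep.highconf_accuracy * n_hi
        lo_term = 0.0 if rep.lowconf_accuracy is None else rep.lowconf_accuracy * (200 - n_hi)
        assert hi_term + lo_term == pytest.approx(total_correct)

    def test_bad_threshold_errors(self):
        h = _hyp(["W", "N2"])
        with pytest.raises(ValueError, match="threshold"):
            stratified_report(h, h, conf_threshold=1.5)


class TestHolm:
    def test_hand_computed_pair(self):
        assert np.allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == pytest.approx([0.3])

    def test_monotonicity_enforced(self):
        # raw step-down products would be [0.03, 0.02]; Holm forces order
        assert np.allclose(holm_adjust([0.015, 0.02]), [0.03, 0.03])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=12)
    )
    @settings(max_examples=100, deadline=None)
    def test_adjusted_dominate_raw_and_preserve_order(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            holm_adjust([0.5, 1.2])
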