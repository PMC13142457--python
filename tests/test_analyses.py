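"""Figure-level decoding analyses on synthetic sessions."""

import numpy as np
import pytest

import phonoseq as pq
from phonoseq.analyses import pairwise_decoding_timecourse
from phonoseq.exceptions import DesignError, LabelError
from phonoseq.preprocess import EpochWindow
from conftest import make_session


class TestPairwiseDecoding:
    def test_noiseless_session_decodes_perfectly(self, noiseless_session):
        session, _, _ = noiseless_session
        for pos in (1, 2, 3):
            res = pq.pairwise_position_decoding(session, pos, n_boot=50)
            assert res.mean_auc == 1.0

    def test_silenced_position_falls_to_chance(self):
        session, _, _ = make_session(
            repeats=15, seed=1, gains=[1.0, 1.0, 1e-9]
        )
        res3 = pq.pairwise_position_decoding(session, 3, n_boot=50, seed=1)
        res1 = pq.pairwise_position_decoding(session, 1, n_boot=50, seed=1)
        res2 = pq.pairwise_position_decoding(session, 2, n_boot=50, seed=1)
        assert res3.mean_auc == pytest.approx(0.5, abs=0.05)
        assert res1.mean_auc > 0.9 and res2.mean_auc > 0.9
        assert res1.p_value < 0.001 and res3.p_value > 0.01

    def test_single_pair_equals_bare_binary_decoder(self, standard_session):
        session, _, _ = standard_session
        from phonoseq.lda import loo_binary_scores, rank_auc
        from phonoseq.preprocess import PREP_08, extract_windows
        from phonoseq.task import single_position_pairs
        pair = single_position_pairs(session.condition_set, 1)[0]
        sub = session.subset(session.trial_indices([pair[0].key,
                                                    pair[1].key]))
        res = pq.pairwise_position_decoding(sub, 1, n_boot=10)
        ext = extract_windows(sub, PREP_08)
        y = (sub.label_keys[ext.kept] == pair[1].key).astype(int)
        auc = rank_auc(loo_binary_scores(ext.matrix, y), y == 1)
        assert res.n_pairs == 1 and res.mean_auc == pytest.approx(auc)


@pytest.fixture(scope="module")
def matrix():
    session, _, _ = make_session(repeats=8, seed=2)
    small = {
        "cue": EpochWindow("cue_onset", 0.2, 0.8),
        "prep": EpochWindow("go_cue", -0.6, 0.0),
        "speech": EpochWindow("speech_onset", -0.1, 0.5),
    }
    return session, pq.cross_time_generalization(
        session, 2, epoch_windows=small, min_trials=100
    )


class TestCrossTime:
    def test_diagonal_equals_within_time_decoding(self, matrix):
        session, tg = matrix
        tc = pairwise_decoding_timecourse(
            session, 2, EpochWindow("cue_onset", 0.2, 0.8)
        )
        n = len(tc.times)
        assert np.allclose(np.diag(tg.auc)[:n], tc.mean_auc, atol=1e-12)

    def test_shared_code_generalizes_across_epochs(self, matrix):
        _, tg = matrix
        epochs = np.array([e for e, _ in tg.fit_times])
        cue = epochs == "cue"
        speech = epochs == "speech"
        off = tg.auc[np.ix_(cue, speech)].mean()
        diag = np.diag(tg.auc).mean()
        assert off > 0.75 and abs(off - diag) < 0.15

    def test_trial_mask_reported_not_applied(self, matrix):
        _, tg = matrix
        assert tg.mask.shape == (len(tg.fit_times),)
        assert np.all(np.isfinite(tg.auc))

    def test_epoch_private_code_does_not_transfer(self):
        session, _, _ = make_session(
            repeats=15, seed=3,
            epoch_gains={"cue": 0.0, "prep": 0.0, "speech": 0.0},
            epoch_private_scale=1.0,
        )
        small = {
            "cue": EpochWindow("cue_onset", 0.2, 0.8),
            "speech": EpochWindow("speech_onset", -0.1, 0.5),
        }
        tg = pq.cross_time_generalization(session, 1, epoch_windows=small,
                                          min_trials=100)
        epochs = np.array([e for e, _ in tg.fit_times])
        cue = epochs == "cue"
        speech = epochs == "speech"
        off = tg.auc[np.ix_(cue, speech)].mean()
        diag = np.diag(tg.auc).mean()
        assert off == pytest.approx(0.5, abs=0.05)
        assert diag > 0.8


class TestCrossEpoch:
    def test_cue_to_cue_matches_within_epoch_decoding(self):
        session, _, _ = make_session(repeats=10, seed=4)
        res = pq.cross_epoch_generalization(session, 1)
        # a decoder trained and tested on its own cue window must match the
        # plain pairwise decoder on that window
        win = EpochWindow("cue_onset",
                          res.peak_times["cue"] - 0.25,
                          res.peak_times["cue"] + 0.25)
        base = pq.pairwise_position_decoding(session, 1, window=win,
                                             n_boot=10)
        assert res.auc["cue"] == pytest.approx(base.mean_auc, abs=1e-9)


class TestCrossPosition:
    def test_identical_codes_transfer_fully(self):
        session, _, _ = make_session(repeats=10, seed=5, alignment=1.0,
                                     gains=[1.0, 1.0, 1.0])
        r = pq.cross_position_generalization(session, 2, 3, n_boot=50,
                                             seed=5)
        assert r.normalized_generalization == pytest.approx(1.0, abs=0.1)

    def test_orthogonal_codes_do_not_transfer(self):
        session, _, _ = make_session(repeats=10, seed=6, alignment=0.0)
        r = pq.cross_position_generalization(session, 2, 3, n_boot=50,
                                             seed=6)
        assert r.normalized_generalization == pytest.approx(0.0, abs=0.15)
        assert r.auc_within > 0.8

    def test_transfer_monotone_in_alignment(self):
        values = []
        for c in (0.0, 0.45, 0.9):
            session, _, _ = make_session(repeats=10, seed=7, alignment=c,
                                         gains=[1.0, 1.0, 1.0])
            r = pq.cross_position_generalization(session, 2, 3, n_boot=0,
                                                 seed=7)
            values.append(r.normalized_generalization)
        assert values[0] < values[1] < values[2]

    def test_normalization_invariant_to_feature_rescale(self):
        session, _, _ = make_session(repeats=6, seed=8)
        scaled = session.subset(np.arange(session.n_trials))
        scaled.features = scaled.features * 3.7
        a = pq.cross_position_generalization(session, 2, 3, n_boot=0, seed=8)
        b = pq.cross_position_generalization(scaled, 2, 3, n_boot=0, seed=8)
        assert a.normalized_generalization == \
            pytest.approx(b.normalized_generalization, abs=1e-9)


def lengths_session(**kw):
    spec = dict(design="lengths", lengths=(1, 2, 3))
    spec.update(kw.pop("generator", {}))
    from phonoseq.scenarios import generate_session
    return generate_session(spec, kw.pop("seed", 0))[0]


class TestSequenceLength:
    def test_strong_length_axis_decodes_nearly_perfectly(self):
        session = lengths_session(
            generator={"length_scale": 2.0, "repeats": 10}, seed=9)
        res = pq.sequence_length_decoding(session, n_perm=60, n_boot=0,
                                          seed=9)
        assert res.normalized_balanced_accuracy > 0.8
        assert res.p_value <= 1 / 60

    def test_absent_length_axis_is_chance(self):
        session = lengths_session(
            generator={"length_scale": 0.0, "repeats": 10}, seed=10)
        res = pq.sequence_length_decoding(session, n_perm=0, n_boot=0,
                                          seed=10)
        assert abs(res.normalized_balanced_accuracy) < 0.1

    def test_single_length_class_rejected(self, standard_session):
        session, _, _ = standard_session
        with pytest.raises(DesignError):
            pq.sequence_length_decoding(session, n_perm=0, n_boot=0)


def boundary_session(boundary_gain=1.0, boundary_scale=1.5, seed=0,
                     repeats=10):
    cset = pq.build_word_boundary_set(["K", "N"], 4, 2)
    cfg = pq.GeneratorConfig(seed=seed)
    code = pq.make_ground_truth_code(cfg, cset, boundary_gain=boundary_gain,
                                     boundary_scale=boundary_scale)
    plan = pq.make_trial_plan(cset, repeats=repeats, seed=seed)
    return pq.zscore_session(pq.simulate_session(code, plan, cfg))


class TestWordBoundary:
    def test_truncated_plan_loses_late_positions(self):
        session = boundary_session(boundary_gain=0.0, seed=11)
        res = pq.word_boundary_analysis(session, seed=11)
        assert res.boundary_auc > 0.9
        assert res.one_word_auc > 0.8
        assert res.two_word_auc == pytest.approx(0.5, abs=0.08)
        assert res.delta_p < 1e-4

    def test_identical_generative_laws_give_equal_contexts(self):
        session = boundary_session(boundary_gain=1.0, boundary_scale=0.0,
                                   seed=12)
        res = pq.word_boundary_analysis(session, seed=12)
        assert abs(res.delta_auc) < 0.06
        assert res.delta_p > 0.01
        assert res.boundary_auc == pytest.approx(0.5, abs=0.07)

    def test_non_boundary_set_rejected(self, standard_session):
        session, _, _ = standard_session
        with pytest.raises(DesignError):
            pq.word_boundary_analysis(session)


class TestLeakageSentinel:
    def test_label_shuffled_session_is_chance_everywhere(self):
        session, _, _ = make_session(repeats=15, seed=13)
        shuffled = pq.shuffle_labels(session, seed=13)
        res = pq.pairwise_position_decoding(shuffled, 2, n_boot=20, seed=0)
        assert res.mean_auc == pytest.approx(0.5, abs=0.05)
        gen = pq.cross_position_generalization(shuffled, 2, 3, n_boot=0)
        assert gen.auc_within == pytest.approx(0.5, abs=0.05)


class TestInputValidation:
    def test_inventory_mismatch_detected(self):
        cset = pq.build_full_factorial(["K", "N"], 1).union(
            pq.build_full_factorial(["K", "N"], 2))
        # restrict slot-2 tokens to K only: positions see different sets
        conds = [c for c in cset.conditions
                 if c.length_class == 1 or c.consonants[1] == "K"]
        sub = pq.ConditionSet(inventory=("K", "N"), conditions=tuple(conds))
        cfg = pq.GeneratorConfig(seed=0)
        code = pq.make_ground_truth_code(cfg, sub)
        plan = pq.make_trial_plan(sub, repeats=4, seed=0)
        session = pq.zscore_session(pq.simulate_session(code, plan, cfg))
        with pytest.raises(LabelError):
            pq.cross_position_generalization(session, 1, 2, n_boot=0)
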