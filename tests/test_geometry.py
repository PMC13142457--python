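"""Marginal means, displacement vectors, compositional prediction, planes."""

import numpy as np
import pytest

import phonoseq as pq
from phonoseq.exceptions import DesignError
from phonoseq.geometry import GroupSpec
from phonoseq.preprocess import PREP_06, extract_windows


def _points_and_labels(session, window=PREP_06):
    ext = extract_windows(session, window)
    return ext.matrix, [session.labels[i] for i in ext.kept]


class TestMarginalMeans:
    def test_no_wildcards_gives_per_condition_means(self, noiseless_session):
        session, code, _ = noiseless_session
        pts, labs = _points_and_labels(session)
        mm = pq.marginal_means(pts, labs, GroupSpec(slots=(1, 2, 3)))
        assert len(mm.means) == 27
        for key, mean in mm.means.items():
            tokens = dict((tag, val) for tag, val in key)
            lab = next(l for l in labs
                       if l.consonants == (tokens[1], tokens[2], tokens[3]))
            assert np.allclose(mean, code.feature_mean(lab, "prep"))

    def test_all_wildcards_gives_grand_mean(self, noiseless_session):
        session, _, _ = noiseless_session
        pts, labs = _points_and_labels(session)
        mm = pq.marginal_means(pts, labs, GroupSpec())
        assert len(mm.means) == 1
        assert np.allclose(list(mm.means.values())[0], pts.mean(axis=0))

    def test_marginal_mean_recovers_generative_term(self, noiseless_session):
        """Balanced design: mean of *ah*ahSH = baseline + g3*b3[SH]."""
        session, code, _ = noiseless_session
        pts, labs = _points_and_labels(session)
        mm = pq.marginal_means(pts, labs, GroupSpec(slots=(3,)))
        grand = pts.mean(axis=0)
        for key, mean in mm.means.items():
            tok = dict(key)[3]
            lat = code.position_gains[2] * code.phoneme_vectors[3][tok]
            expect = grand + np.concatenate([lat, lat])
            assert np.allclose(mean, expect, atol=1e-10)

    def test_pattern_rendering(self):
        spec = GroupSpec(slots=(3,))
        key = ((3, "SH"),)
        assert spec.pattern(key, 3) == "*ah*ahSH"


class TestDisplacements:
    def test_refined_equals_base_gives_zero_vectors(self, noiseless_session):
        session, _, _ = noiseless_session
        pts, labs = _points_and_labels(session)
        mm = pq.marginal_means(pts, labs, GroupSpec(slots=(3,)))
        disp = pq.displacement_vectors(mm, mm)
        assert all(np.allclose(v, 0) for v in disp.vectors.values())

    def test_zero_sum_within_base_group(self, noiseless_session):
        session, _, _ = noiseless_session
        pts, labs = _points_and_labels(session)
        base = pq.marginal_means(pts, labs, GroupSpec(slots=(3,)))
        refined = pq.marginal_means(pts, labs, GroupSpec(slots=(2, 3)))
        disp = pq.displacement_vectors(base, refined)
        per_base = {}
        for key, v in disp.vectors.items():
            bkey = disp.base_key(key)
            per_base[bkey] = per_base.get(bkey, 0) + v
        for total in per_base.values():
            assert np.abs(total).max() < 1e-10

    def test_like_phoneme_displacements_context_invariant(
            self, noiseless_session):
        """Compositional law: 2nd-position displacement identical across
        3rd-position contexts."""
        session, _, _ = noiseless_session
        pts, labs = _points_and_labels(session)
        base = pq.marginal_means(pts, labs, GroupSpec(slots=(3,)))
        refined = pq.marginal_means(pts, labs, GroupSpec(slots=(2, 3)))
        disp = pq.displacement_vectors(base, refined)
        by_phoneme = {}
        for key, v in disp.vectors.items():
            tok2 = dict(key)[2]
            by_phoneme.setdefault(tok2, []).append(v)
        for vs in by_phoneme.values():
            for v in vs[1:]:
                assert np.allclose(v, vs[0], atol=1e-10)

    def test_non_nested_groupings_rejected(self, noiseless_session):
        session, _, _ = noiseless_session
        pts, labs = _points_and_labels(session)
        a = pq.marginal_means(pts, labs, GroupSpec(slots=(2,)))
        b = pq.marginal_means(pts, labs, GroupSpec(slots=(3,)))
        with pytest.raises(DesignError):
            pq.displacement_vectors(a, b)


def lengths_session(style="compositional", seed=0, repeats=6, noiseless=True):
    cset = pq.build_length_series(["K", "N", "SH"], (1, 2, 3))
    kw = dict(trial_noise_sd=0.0, bin_noise_sd=0.0, drift_sd=0.0) \
        if noiseless else {}
    cfg = pq.GeneratorConfig(seed=seed, **kw)
    code = pq.make_ground_truth_code(cfg, cset, style=style,
                                     gains=[1.0, 1.0, 1.0])
    plan = pq.make_trial_plan(cset, repeats=repeats, seed=seed)
    return pq.simulate_session(code, plan, cfg), code


class TestCompositionalPredict:
    def test_noiseless_equal_gain_code_predicts_exactly(self):
        session, _ = lengths_session()
        pts, labs = _points_and_labels(session)
        rep = pq.compositional_predict(pts, labs, n_boot=0, n_perm=0)
        assert rep.r2_condition == pytest.approx(1.0, abs=1e-9)

    def test_self_donor_reduces_to_identity(self):
        session, _ = lengths_session()
        pts, labs = _points_and_labels(session)
        rep = pq.compositional_predict(pts, labs, n_boot=0, n_perm=0,
                                       donor_lengths="self")
        for c, mean in rep.class_means.items():
            assert np.allclose(rep.predictions[c], mean, atol=1e-10)

    def test_requires_two_length_classes(self, noiseless_session):
        session, _, _ = noiseless_session
        pts, labs = _points_and_labels(session)
        with pytest.raises(DesignError):
            pq.compositional_predict(pts, labs, n_boot=0, n_perm=0)

    def test_conjunctive_code_is_not_predictable(self):
        r2 = []
        for seed in range(4):
            session, _ = lengths_session(style="conjunctive", seed=seed,
                                         noiseless=False)
            session = pq.zscore_session(session)
            pts, labs = _points_and_labels(session)
            rep = pq.compositional_predict(pts, labs, n_boot=0, n_perm=0)
            r2.append(rep.r2_condition)
        assert np.mean(r2) <= 0.2

    def test_permutation_null_is_uncompositional(self):
        session, _ = lengths_session(noiseless=False, repeats=4)
        session = pq.zscore_session(session)
        pts, labs = _points_and_labels(session)
        rep = pq.compositional_predict(pts, labs, n_boot=0, n_perm=60,
                                       seed=0)
        assert rep.p_condition <= 0.05  # real structure beats the null


class TestPlane:
    def test_coplanar_points_fraction_one(self, rng):
        basis = rng.standard_normal((2, 6))
        pts = rng.standard_normal((9, 2)) @ basis
        assert pq.plane_variance_2d(pts) == pytest.approx(1.0)

    def test_three_equal_orthogonal_directions_fraction_two_thirds(self):
        pts = np.vstack([np.eye(3), -np.eye(3)])
        assert pq.plane_variance_2d(pts) == pytest.approx(2 / 3)

    def test_matches_covariance_eigendecomposition(self, rng):
        pts = rng.standard_normal((9, 5))
        got = pq.plane_variance_2d(pts)
        cov = np.cov((pts - pts.mean(axis=0)).T, bias=True)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert got == pytest.approx(evals[:2].sum() / evals.sum())

    def test_rotation_invariance(self, rng):
        pts = rng.standard_normal((12, 4))
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert pq.plane_variance_2d(pts @ q) == \
            pytest.approx(pq.plane_variance_2d(pts))

    def test_too_few_points_rejected(self):
        with pytest.raises(DesignError):
            pq.plane_variance_2d(np.zeros((2, 3)))


class TestCorrelationMatrix:
    def test_unit_diagonal(self):
        session, _ = lengths_session(noiseless=False, repeats=4)
        session = pq.zscore_session(session)
        m = pq.marginal_correlation_matrix(session, PREP_06)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)

    def test_orthogonal_positions_decorrelated_after_length_removal(self):
        cset = pq.build_length_series(["K", "N", "SH"], (2, 3))
        cfg = pq.GeneratorConfig(seed=5)
        code = pq.make_ground_truth_code(cfg, cset, alignment=0.0,
                                         gains=[1.0, 1.0, 1.0])
        plan = pq.make_trial_plan(cset, repeats=25, seed=5)
        session = pq.zscore_session(pq.simulate_session(code, plan, cfg))
        m = pq.marginal_correlation_matrix(session, PREP_06,
                                           subtract_length_means=True)
        like = []
        for tok in ("K", "N", "SH"):
            like.append(m.loc[(3, 2, tok), (3, 3, tok)])
        assert abs(np.mean(like)) < 0.25

    def test_length_offset_dominates_without_subtraction(self):
        cset = pq.build_length_series(["K", "N", "SH"], (2, 3))
        cfg = pq.GeneratorConfig(seed=6)
        code = pq.make_ground_truth_code(cfg, cset, length_scale=4.0,
                                         gains=[1.0, 1.0, 1.0])
        plan = pq.make_trial_plan(cset, repeats=12, seed=6)
        session = pq.zscore_session(pq.simulate_session(code, plan, cfg))
        raw = pq.marginal_correlation_matrix(session, PREP_06)
        sub = pq.marginal_correlation_matrix(session, PREP_06,
                                             subtract_length_means=True)
        within = [raw.loc[(3, p, a), (3, q, b)]
                  for p in (1, 2, 3) for q in (1, 2, 3)
                  for a in ("K", "N") for b in ("K", "N")
                  if (p, a) != (q, b)]
        within_sub = [sub.loc[(3, p, a), (3, q, b)]
                      for p in (1, 2, 3) for q in (1, 2, 3)
                      for a in ("K", "N") for b in ("K", "N")
                      if (p, a) != (q, b)]
        # shared positive length offset inflates raw correlations
        assert np.mean(within) > np.mean(within_sub) + 0.2
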