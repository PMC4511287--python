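"""The forward simulator: ground truth, BOLD generation, questionnaire and
respiration generators."""

import numpy as np
import pandas as pd
import pytest

from taskneg.protocol import build_design_matrix, rs_spec
from taskneg.synth import (
    SENSATION_ITEMS,
    THOUGHT_ITEMS,
    NoiseParams,
    SynthError,
    generate_questionnaire,
    generate_respiration,
    generate_subject_bold,
    make_ground_truth,
)


class TestMakeGroundTruth:
    def test_gating_has_no_positive_voxels(self):
        t = make_ground_truth("gating", fractions=(0.1, 0.2), seed=0)
        assert np.sum(t.labels == 1) == 0
        assert t.ideal_antagonism_index() == -1.0

    def test_balanced_antagonistic_index_zero(self):
        t = make_ground_truth("antagonistic", fractions=(0.1, 0.1), seed=0)
        assert t.ideal_antagonism_index() == 0.0

    def test_fraction_counts_exact(self):
        t = make_ground_truth("antagonistic", grid=(10, 10, 10),
                              fractions=(0.1, 0.1), seed=1)
        assert np.sum(t.labels == 1) == 100
        assert np.sum(t.labels == -1) == 100

    def test_region_masks_disjoint(self):
        t = make_ground_truth("antagonistic", seed=2)
        assert not np.any(t.regions["DMN-like"] & t.regions["language-like"])

    def test_amplitude_signs_enforced(self):
        with pytest.raises(SynthError):
            make_ground_truth("antagonistic", amplitudes=(-1.0, -1.0))

    def test_fractions_validated(self):
        with pytest.raises(SynthError):
            make_ground_truth("antagonistic", fractions=(0.6, 0.6))

    def test_random_placement_also_exact(self):
        t = make_ground_truth("antagonistic", grid=(10, 10, 10),
                              fractions=(0.05, 0.15), placement="random", seed=3)
        assert np.sum(t.labels == 1) == 50 and np.sum(t.labels == -1) == 150


class TestGenerateSubjectBold:
    def test_identical_seeds_bit_identical(self, rs_timeline, small_truth):
        nz = NoiseParams(seed=11)
        a, ma = generate_subject_bold(small_truth, rs_timeline, nz, "sub-01", "RS")
        b, mb = generate_subject_bold(small_truth, rs_timeline, nz, "sub-01", "RS")
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(ma, mb)

    def test_different_subjects_differ(self, rs_timeline, small_truth):
        nz = NoiseParams(seed=11)
        a, _ = generate_subject_bold(small_truth, rs_timeline, nz, "sub-01", "RS")
        b, _ = generate_subject_bold(small_truth, rs_timeline, nz, "sub-02", "RS")
        assert not np.array_equal(a.data, b.data)

    def test_emitted_motion_is_what_was_mixed_in(self, rs_timeline, small_truth):
        """Regressing the run on its own motion trace at a pure-noise voxel
        recovers the coupling (nonzero fit) while a zero-coupling run does
        not contain the trace."""
        coupled = NoiseParams(white_sd=0.0, drift_amplitude=0.0,
                              motion_amplitude=1.0, seed=12)
        run, motion = generate_subject_bold(small_truth, rs_timeline, coupled,
                                            "sub-01", "RS")
        null_vox = np.argwhere(small_truth.labels == 0)[0]
        y = run.data[tuple(null_vox)] - 1000.0
        X = motion[:, :3]
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert resid.var() < 1e-12 * y.var() + 1e-12

    def test_ar1_zero_white_noise_uncorrelated(self, rs_timeline):
        """Lag-1 autocorrelation of residual noise pooled over 1000 voxels at
        165 volumes stays within |r| < 0.05 when the AR coefficient is 0."""
        truth = make_ground_truth("antagonistic", grid=(10, 10, 10),
                                  fractions=(0.0, 0.0), amplitudes=(1.0, -1.0),
                                  seed=4)
        nz = NoiseParams(white_sd=1.0, ar1=0.0, drift_amplitude=0.0,
                         motion_amplitude=0.0, seed=13)
        run, _ = generate_subject_bold(truth, rs_timeline, nz, "sub-01", "RS")
        x = run.data.reshape(-1, run.n_volumes) - 1000.0
        x = x - x.mean(axis=1, keepdims=True)
        r = np.sum(x[:, :-1] * x[:, 1:]) / np.sum(x[:, :-1] ** 2)
        assert abs(r) < 0.05

    def test_ar1_positive_autocorrelation_near_coefficient(self, rs_timeline):
        truth = make_ground_truth("antagonistic", grid=(10, 10, 10),
                                  fractions=(0.0, 0.0), seed=4)
        nz = NoiseParams(white_sd=1.0, ar1=0.5, drift_amplitude=0.0,
                         motion_amplitude=0.0, seed=14)
        run, _ = generate_subject_bold(truth, rs_timeline, nz, "sub-01", "RS")
        x = run.data.reshape(-1, run.n_volumes) - 1000.0
        x = x - x.mean(axis=1, keepdims=True)
        r = np.sum(x[:, :-1] * x[:, 1:]) / np.sum(x[:, :-1] ** 2)
        assert r == pytest.approx(0.5, abs=0.05)

    def test_noise_sd_in_percent_of_baseline(self, rs_timeline):
        truth = make_ground_truth("antagonistic", grid=(10, 10, 10),
                                  fractions=(0.0, 0.0), seed=4)
        nz = NoiseParams(white_sd=2.0, ar1=0.0, drift_amplitude=0.0,
                         motion_amplitude=0.0, seed=15)
        run, _ = generate_subject_bold(truth, rs_timeline, nz, "sub-01", "RS")
        sd = (run.data - 1000.0).std()
        assert sd == pytest.approx(20.0, rel=0.02)  # 2% of baseline 1000


class TestGenerateQuestionnaire:
    def test_empty_cohort(self):
        t = generate_questionnaire(0)
        assert t.empty

    def test_shape_and_range(self):
        t = generate_questionnaire(10, seed=1)
        assert set(t.condition) == {"Rest", "RS"}
        assert t.rating.between(1, 5).all()
        assert len(t) == 10 * 17 * 2

    def test_determinism(self):
        a = generate_questionnaire(5, seed=2)
        b = generate_questionnaire(5, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_target_rest_correlation_recovered(self):
        """Observed Thoughts x Sensations r at Rest tracks the generator's
        target (-0.24, the anti-correlation at rest) across replicates."""
        from taskneg.behavior import category_correlation

        rs = []
        for s in range(40):
            t = generate_questionnaire(30, seed=100 + s)
            _, mean_r, _ = category_correlation(t, "Rest")
            rs.append(mean_r)
        rs = np.asarray(rs)
        ci = 1.96 * rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean() - (-0.24)) < max(ci, 0.03)

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(SynthError):
            generate_questionnaire(5, target_r={"Rest": -0.99, "RS": 0.0})

    def test_null_effect_type_one_rate_nominal(self):
        """With zero mean shifts the paired category t-test rejects at about
        the nominal 5% rate (200 cohorts, binomial tolerance)."""
        from taskneg.behavior import compare_conditions, score_questionnaire

        alpha, n_sim, rejections = 0.05, 200, 0
        for s in range(n_sim):
            t = generate_questionnaire(
                12, condition_effects={}, target_r={"Rest": -0.24, "RS": -0.24},
                seed=500 + s)
            scores = score_questionnaire(t)
            res = compare_conditions(scores, families=1)
            rejections += int(res.loc[res.measure == "Thoughts", "p"].iloc[0] < alpha)
        rate = rejections / n_sim
        se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rate - alpha) < 3 * se + 1e-9


class TestGenerateRespiration:
    def test_noiseless_period_four_pace_fifteen(self):
        from taskneg.behavior import extract_breath_params

        tr = generate_respiration(pace=15, depth=1.0, duration_s=120, fs=50,
                                  jitter_sd=0.0, seed=0)
        s = extract_breath_params(tr.time.to_numpy(), tr.flow.to_numpy())
        assert s.pace == pytest.approx(15.0, rel=0.01)
        assert s.inhale_duration == pytest.approx(2.0, rel=0.03)

    def test_depth_sets_inhale_peak(self):
        from taskneg.behavior import extract_breath_params

        tr = generate_respiration(pace=12, depth=2.5, duration_s=90, fs=50,
                                  jitter_sd=0.0, seed=0)
        s = extract_breath_params(tr.time.to_numpy(), tr.flow.to_numpy())
        assert s.inhale_peak == pytest.approx(2.5, rel=0.01)

    def test_inhale_integral_matches_closed_form_and_quadrature(self):
        """Half-sine of amplitude A and period T integrates to A*T/pi; the
        trapezoid estimate must agree within 1%."""
        from scipy.integrate import quad

        from taskneg.behavior import extract_breath_params

        A, T = 1.7, 4.0
        tr = generate_respiration(pace=60 / T, depth=A, duration_s=120, fs=100,
                                  jitter_sd=0.0, seed=0)
        s = extract_breath_params(tr.time.to_numpy(), tr.flow.to_numpy())
        closed = A * T / np.pi
        quadrature = quad(lambda t: A * np.sin(2 * np.pi * t / T), 0, T / 2)[0]
        assert closed == pytest.approx(quadrature, rel=1e-8)
        assert s.inhale_integral == pytest.approx(closed, rel=0.01)

    def test_jitter_makes_periods_vary(self):
        a = generate_respiration(jitter_sd=0.1, seed=5)
        from taskneg.behavior import extract_breath_params
        s = extract_breath_params(a.time.to_numpy(), a.flow.to_numpy())
        assert s.n_breaths > 10

    def test_bad_params_rejected(self):
        with pytest.raises(SynthError):
            generate_respiration(pace=0)
        with pytest.raises(SynthError):
            generate_respiration(fs=5)


def test_regime_separation_single_cohort(rs_timeline, default_noise):
    """End-to-end sanity at n=6: the gating cohort's mean antagonism index is
    far below the antagonistic cohort's."""
    from taskneg.distribution import antagonism_index, count_significant
    from taskneg.glm import contrast_t, fit_subject_glm
    from taskneg.preprocess import PreprocessParams, preprocess_run
    from taskneg.synth import generate_cohort

    means = {}
    for regime in ("antagonistic", "gating"):
        truth = make_ground_truth(regime, seed=1)
        A = []
        for sid, run, mot in generate_cohort(truth, rs_timeline, 6, default_noise,
                                             task_condition="RS"):
            clean = preprocess_run(run, PreprocessParams())
            fit = fit_subject_glm(clean, build_design_matrix(rs_timeline, motion=mot))
            n_pos, n_neg, *_ = count_significant(contrast_t(fit, "RS"))
            A.append(antagonism_index(n_pos, n_neg))
        means[regime] = np.mean(A)
    assert means["gating"] < -0.8 < -0.1 < means["antagonistic"] + 0.2
    assert means["gating"] < means["antagonistic"] - 0.5
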