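"""Metrics, corrections, the interpolation baseline and bad-channel logic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegcomplete.evaluation import (
    InterpolationWeights,
    amplitude_correct,
    baseline_correct,
    evaluate_completion,
    flag_bad_channel,
    interpolate_channel,
    mse,
    pearson_rho,
)
from eegcomplete.signal_io import Recording

RNG = np.random.default_rng(3)


class TestMSE:
    def test_identical_signals_give_zero(self):
        x = RNG.standard_normal(100)
        assert mse(x, x) == 0.0

    def test_unit_offset_gives_one(self):
        assert mse(np.zeros(2), np.ones(2)) == pytest.approx(1.0)

    def test_matches_definitional_loop(self):
        p, q = RNG.standard_normal(57), RNG.standard_normal(57)
        oracle = sum((a - b) ** 2 for a, b in zip(p, q)) / 57
        assert mse(p, q) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse(np.zeros(3), np.zeros(4))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mse(np.array([]), np.array([]))


class TestPearsonRho:
    def test_positive_affine_copy_gives_one(self):
        p = RNG.standard_normal(200)
        assert pearson_rho(p, 3.0 * p + 0.2) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        p = RNG.standard_normal(200)
        assert pearson_rho(p, -p) == pytest.approx(-1.0)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_rho(RNG.standard_normal(10), np.full(10, 0.3))

    @settings(deadline=None, max_examples=25)
    @given(
        a=st.floats(0.01, 100), b=st.floats(-10, 10),
        c=st.floats(0.01, 100), d=st.floats(-10, 10),
    )
    def test_invariant_under_positive_affine_transforms(self, a, b, c, d):
        p = RNG.standard_normal(64)
        q = RNG.standard_normal(64)
        base = pearson_rho(p, q)
        assert pearson_rho(a * p + b, c * q + d) == pytest.approx(base, abs=1e-6)


class TestCorrections:
    def test_baseline_removes_mean(self):
        x = RNG.standard_normal(500) + 0.7
        out = baseline_correct(x)
        assert abs(out.mean()) < 1e-12
        assert out.shape == x.shape

    def test_baseline_constant_becomes_zero(self):
        assert np.allclose(baseline_correct(np.full(10, 0.7)), 0.0)

    def test_baseline_idempotent(self):
        x = RNG.standard_normal(100)
        once = baseline_correct(x)
        assert np.allclose(baseline_correct(once), once)

    def test_baseline_preserves_rho(self):
        p, q = RNG.standard_normal(100), RNG.standard_normal(100)
        assert pearson_rho(baseline_correct(p), q) == pytest.approx(pearson_rho(p, q))

    def test_alpha_inverts_scaling(self):
        p = RNG.standard_normal(100)
        alpha, corrected = amplitude_correct(p, 2.0 * p)
        assert alpha == pytest.approx(0.5)
        assert np.allclose(corrected, p)

    def test_alpha_is_one_for_identical_signals(self):
        p = RNG.standard_normal(100)
        alpha, _ = amplitude_correct(p, p)
        assert alpha == pytest.approx(1.0)

    def test_alpha_equalizes_total_absolute_amplitude(self):
        p, q = RNG.standard_normal(100), RNG.standard_normal(100)
        _, corrected = amplitude_correct(p, q)
        assert np.abs(corrected).sum() == pytest.approx(np.abs(p).sum(), abs=1e-12)

    def test_alpha_preserves_rho(self):
        p, q = RNG.standard_normal(100), RNG.standard_normal(100)
        _, corrected = amplitude_correct(p, q)
        assert pearson_rho(p, corrected) == pytest.approx(pearson_rho(p, q))

    def test_all_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            amplitude_correct(RNG.standard_normal(10), np.zeros(10))


class TestInterpolation:
    def test_equidistant_inputs_get_equal_weights(self, layout):
        rec = Recording(RNG.random((22, 100)), 250.0, tuple(range(1, 23)), "normalized")
        signal, w = interpolate_channel(rec, layout, [1, 8, 12, 20], 10)
        assert np.allclose(w.weights, 0.25)
        assert np.allclose(signal, rec.select([1, 8, 12, 20]).mean(axis=0))

    def test_inverse_distance_hand_example(self):
        # distances (1, 1, 1, 2) -> weights (2/7, 2/7, 2/7, 1/7)
        w = InterpolationWeights(
            np.array([2, 2, 2, 1]) / 7.0, np.array([1.0, 1, 1, 2]), (1, 2, 3, 4)
        )
        inv = 1.0 / w.distances_cm
        assert np.allclose(w.weights, inv / inv.sum())

    def test_weights_sum_to_one_and_follow_distance_order(self, layout):
        rec = Recording(RNG.random((22, 50)), 250.0, tuple(range(1, 23)), "normalized")
        _, w = interpolate_channel(rec, layout, [2, 9, 13, 22], 10)
        assert w.weights.sum() == pytest.approx(1.0)
        assert np.all(np.argsort(-w.weights) == np.argsort(w.distances_cm))

    def test_permutation_equivariant(self, layout):
        rec = Recording(RNG.random((22, 50)), 250.0, tuple(range(1, 23)), "normalized")
        s1, w1 = interpolate_channel(rec, layout, [1, 8, 13, 22], 10)
        s2, w2 = interpolate_channel(rec, layout, [22, 13, 8, 1], 10)
        assert np.allclose(s1, s2)
        assert np.allclose(w1.weights, w2.weights[::-1])

    def test_target_among_inputs_rejected(self, layout):
        rec = Recording(RNG.random((22, 50)), 250.0, tuple(range(1, 23)), "normalized")
        with pytest.raises(ValueError):
            interpolate_channel(rec, layout, [10, 8, 12, 20], 10)

    def test_inconsistent_weights_rejected(self):
        with pytest.raises(ValueError):
            InterpolationWeights(np.array([0.5, 0.4]), np.array([1.0, 2.0]), (1, 2))
        with pytest.raises(ValueError, match="inversely ordered"):
            InterpolationWeights(np.array([0.3, 0.7]), np.array([1.0, 2.0]), (1, 2))


class TestFlagBadChannel:
    def test_faithful_channel_not_flagged(self):
        x = RNG.standard_normal(1000)
        flagged, diag = flag_bad_channel(x, x + 0.01 * RNG.standard_normal(1000))
        assert not flagged
        assert diag["rho"] > 0.99

    def test_independent_noise_flagged(self):
        rng = np.random.default_rng(42)
        structured = np.sin(np.linspace(0, 40 * np.pi, 2000))
        noise = rng.standard_normal(2000)
        flagged, diag = flag_bad_channel(noise, structured, rho_threshold=0.5)
        assert flagged
        assert abs(diag["rho"]) < 0.2

    def test_mse_escape_hatch(self):
        x = RNG.standard_normal(500)
        y = x + 5.0 * RNG.standard_normal(500)  # correlated but very noisy
        flagged, _ = flag_bad_channel(x, x, mse_reference=1e-6, mse_multiple=2.0)
        assert not flagged  # identical signals: zero MSE
        flagged, _ = flag_bad_channel(y, x, rho_threshold=0.01,
                                      mse_reference=1e-6, mse_multiple=2.0)
        assert flagged

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            flag_bad_channel(np.ones(10) + RNG.random(10), RNG.random(10), 1.2)


class TestTransferAcrossSubjects:
    def test_model_trained_on_one_subject_completes_others(self, mixture_experiment, layout):
        """A network fitted on one synthetic subject still completes Cz for
        subjects with different source configurations: the spatial smoothing
        it learns is largely subject-independent."""
        from eegcomplete.evaluation import transfer_evaluation
        from eegcomplete.signal_io import bandpass_filter, normalize
        from eegcomplete.synthetic import SyntheticConfig, generate_recording

        subjects = {}
        for name, seed in (("S2", 21), ("S3", 31)):
            raw, _ = generate_recording(
                layout, SyntheticConfig(duration_s=30, nonlinearity="mild", seed=seed)
            )
            rec, _ = normalize(bandpass_filter(raw))
            subjects[name] = (rec, rec.channel(10))
        table = transfer_evaluation(
            mixture_experiment["model"], subjects, mixture_experiment["inputs"], 10
        )
        assert list(table.columns) == ["subject", "target_channel", "mse", "rho"]
        assert len(table) == 2
        assert (table["rho"] > 0.8).all()
        assert (table["mse"] < 0.05).all()


class TestEdgeChannelAmplitude:
    def test_edge_completion_amplitude_error_exceeds_center_and_alpha_corrects(
        self, layout, mixture_experiment
    ):
        """Completing an edge electrode (channel 7) from the central input
        ring under-estimates amplitude more than completing the central Cz;
        the alpha rescale recovers part of the lost MSE."""
        from conftest import train_completion_on_synthetic

        edge = train_completion_on_synthetic(layout, [1, 8, 12, 20], 7, seed=11)
        plain = evaluate_completion(edge["truth"], edge["completed"], baseline=True)
        corrected = evaluate_completion(
            edge["truth"], edge["completed"], baseline=True, amplitude=True
        )
        center = evaluate_completion(
            mixture_experiment["truth"], mixture_experiment["completed"],
            baseline=True, amplitude=True,
        )
        assert abs(corrected.alpha - 1.0) > abs(center.alpha - 1.0)
        assert corrected.mse <= plain.mse
        assert plain.rho > 0.9


class TestEvaluateCompletion:
    def test_identity_gives_perfect_metrics(self):
        x = RNG.standard_normal(300)
        m = evaluate_completion(x, x, baseline=True, amplitude=True)
        assert m.mse == pytest.approx(0.0, abs=1e-20)
        assert m.rho == pytest.approx(1.0)
        assert m.alpha == pytest.approx(1.0)

    def test_baseline_correction_removes_pure_offset(self):
        x = RNG.standard_normal(300)
        m = evaluate_completion(x, x + 0.3, baseline=True)
        assert m.mse == pytest.approx(0.0, abs=1e-12)
        assert m.rho == pytest.approx(1.0)

    def test_amplitude_correction_removes_pure_rescale(self):
        x = RNG.standard_normal(300)
        m = evaluate_completion(x, 0.5 * x, amplitude=True)
        assert m.mse == pytest.approx(0.0, abs=1e-12)
        assert m.alpha == pytest.approx(2.0)

    def test_metric_bounds_enforced(self):
        from eegcomplete.evaluation import CompletionMetrics

        with pytest.raises(ValueError):
            CompletionMetrics(mse=-1.0, rho=0.5)
        with pytest.raises(ValueError):
            CompletionMetrics(mse=0.0, rho=1.5)
        with pytest.raises(ValueError):
            CompletionMetrics(mse=0.0, rho=0.5, alpha=0.0)
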