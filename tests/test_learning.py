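import numpy as np
import pytest

from superspike.core import ConfigurationError, NeuronParams
from superspike.kernels import KernelParams, TraceState, kernel_eval, trace_step
from superspike.learning import (
    ClassificationWindow,
    ErrorState,
    FeedbackSpec,
    RegularizerParams,
    SurrogateParams,
    SynapseMatrix,
    accumulate_update,
    apply_update,
    classification_error_step,
    eligibility_step,
    feedback_signals,
    hebbian_coincidence,
    output_error_step,
    regularizer_term,
    surrogate_derivative,
    update_rate_estimate,
)

DT = 0.1


class TestSurrogate:
    def test_peak_limits_and_closed_form(self, neuron):
        s = SurrogateParams(1.0)
        assert surrogate_derivative(neuron.threshold_mV, neuron, s) == 1.0
        assert surrogate_derivative(-1e9, neuron, s) == pytest.approx(0.0, abs=1e-12)
        # one beta-width below threshold: (1 + 1)^-2
        assert surrogate_derivative(neuron.threshold_mV - 1.0, neuron, s) == 0.25

    def test_strictly_increasing_below_threshold_and_positive(self, neuron):
        u = np.linspace(-90, neuron.threshold_mV, 400)
        g = surrogate_derivative(u, neuron, SurrogateParams(1.0))
        assert np.all(np.diff(g) > 0)
        assert np.all(g > 0)

    def test_bad_beta_rejected(self):
        with pytest.raises(ConfigurationError):
            SurrogateParams(0.0)


class TestHebbianEligibility:
    def test_silent_presynapse_gives_zero_column(self, neuron):
        pre = np.array([0.0, 0.5])
        h = hebbian_coincidence(pre, np.array([-55.0, -52.0]), neuron)
        assert np.all(h[0] == 0.0)
        assert np.all(h[1] > 0.0)

    def test_far_below_threshold_small_but_positive(self, neuron):
        h = hebbian_coincidence(np.array([1.0]), np.array([-90.0]), neuron)
        assert 0 < h[0, 0] < 1e-2

    def test_composes_kernel_and_surrogate_closed_forms(self, neuron, kernel):
        """One presyn spike 5 ms ago at threshold voltage: product is
        kernel(5 ms) * 1 exactly (delay compensation applied by the caller)."""
        tr = TraceState.zeros(1)
        trace_step(tr, np.ones(1), kernel, DT)
        n = int(round(5.0 / DT)) - 1
        for _ in range(n):
            trace_step(tr, np.zeros(1), kernel, DT)
        h = hebbian_coincidence(tr.slow, np.array([neuron.threshold_mV]), neuron)
        assert h[0, 0] == pytest.approx(kernel_eval(5.0, kernel), rel=1e-3)

    def test_unit_impulse_eligibility_traces_kernel(self, kernel):
        syn = SynapseMatrix(w=np.zeros((2, 2)))
        h = np.zeros((2, 2))
        h[1, 0] = 1.0
        eligibility_step(syn, h, kernel, DT)
        for n in range(1, 80):
            eligibility_step(syn, np.zeros((2, 2)), kernel, DT)
            t = (n + 1) * DT
            assert syn.elig.slow[1, 0] == pytest.approx(kernel_eval(t, kernel), rel=1e-9)
            # separability: untouched synapses stay exactly zero
            assert syn.elig.slow[0, 0] == 0.0 and syn.elig.slow[0, 1] == 0.0


class TestErrorSignals:
    def test_match_gives_zero_error(self, kernel, rng):
        err = ErrorState.zeros(1)
        spikes = (rng.random(500) < 0.01).astype(float)
        for s in spikes:
            output_error_step(err, np.array([s]), np.array([s]), kernel, DT)
            assert err.e[0] == 0.0

    def test_missed_and_extra_spikes_are_signed_kernel_transients(self, kernel):
        miss = ErrorState.zeros(1)
        extra = ErrorState.zeros(1)
        output_error_step(miss, np.zeros(1), np.ones(1), kernel, DT)
        output_error_step(extra, np.ones(1), np.zeros(1), kernel, DT)
        for n in range(1, 100):
            output_error_step(miss, np.zeros(1), np.zeros(1), kernel, DT)
            output_error_step(extra, np.zeros(1), np.zeros(1), kernel, DT)
            t = (n + 1) * DT
            assert miss.e[0] == pytest.approx(kernel_eval(t, kernel), rel=1e-9)
            assert extra.e[0] == pytest.approx(-kernel_eval(t, kernel), rel=1e-9)

    def test_classification_correct_in_window_no_error(self, kernel):
        err = ErrorState.zeros(2, mode="classification")
        win = ClassificationWindow(0.0, 25.0, correct_unit=0)
        classification_error_step(err, np.array([1.0, 0.0]), 5.0, win, kernel, DT)
        assert np.all(err.e == 0.0)
        assert win.hit

    def test_classification_wrong_spike_negative(self, kernel):
        err = ErrorState.zeros(2, mode="classification")
        win = ClassificationWindow(0.0, 25.0, correct_unit=0)
        classification_error_step(err, np.array([0.0, 1.0]), 5.0, win, kernel, DT)
        assert err.e[1] < 0 and err.e[0] == 0.0

    def test_classification_miss_positive_at_window_end(self, kernel):
        err = ErrorState.zeros(2, mode="classification")
        win = ClassificationWindow(0.0, 25.0, correct_unit=0)
        t = 0.0
        for step in range(400):
            classification_error_step(err, np.zeros(2), t, win, kernel, DT)
            if t < 25.0:
                assert np.all(err.e == 0.0)  # silence inside the window: no error yet
            t += DT
        assert err.e[0] > 0  # positive transient began exactly at the window end

    def test_spike_outside_any_window_negative(self, kernel):
        err = ErrorState.zeros(2, mode="classification")
        classification_error_step(err, np.array([1.0, 0.0]), 50.0, None, kernel, DT)
        assert err.e[0] < 0


class TestFeedback:
    def test_uniform_broadcasts_error_sum(self):
        spec = FeedbackSpec.create("uniform", 5, 2)
        fb = feedback_signals(np.array([0.3, -0.1]), np.zeros((5, 2)), spec)
        np.testing.assert_allclose(fb, 0.2)

    def test_symmetric_identity_passthrough(self):
        spec = FeedbackSpec.create("symmetric", 3, 3)
        e = np.array([1.0, -2.0, 0.5])
        np.testing.assert_array_equal(feedback_signals(e, np.eye(3), spec), e)

    def test_random_feedback_is_frozen_and_seeded(self):
        a = FeedbackSpec.create("random", 4, 2, seed=9)
        b = FeedbackSpec.create("random", 4, 2, seed=9)
        c = FeedbackSpec.create("random", 4, 2, seed=10)
        np.testing.assert_array_equal(a.B, b.B)
        assert not np.array_equal(a.B, c.B)

    def test_shape_mismatch_rejected(self):
        spec = FeedbackSpec.create("symmetric", 3, 2)
        with pytest.raises(ConfigurationError):
            feedback_signals(np.zeros(3), np.zeros((3, 2)), spec)


class TestUpdates:
    def test_zero_error_leaves_accumulator(self, kernel):
        syn = SynapseMatrix(w=np.zeros((2, 2)))
        syn.elig.slow[:] = 1.0
        accumulate_update(syn, np.zeros(2), DT)
        assert np.all(syn.m == 0.0)

    def test_positive_product_grows_monotonically(self):
        syn = SynapseMatrix(w=np.zeros((1, 1)))
        syn.elig.slow[:] = 0.5
        prev = 0.0
        for _ in range(10):
            accumulate_update(syn, np.array([1.0]), DT)
            assert syn.m[0, 0] > prev
            prev = syn.m[0, 0]

    def test_rectangular_error_times_eligibility_matches_integral(self, kernel):
        """Constant error over a known eligibility transient: the accumulator
        equals the analytic partial integral of the kernel (quadrature oracle)."""
        syn = SynapseMatrix(w=np.zeros((1, 1)))
        h = np.ones((1, 1))
        T = 40.0
        n = int(round(T / DT))
        delta = 0.7
        eligibility_step(syn, h, kernel, DT)
        accumulate_update(syn, np.array([delta]), DT)
        for _ in range(n - 1):
            eligibility_step(syn, np.zeros((1, 1)), kernel, DT)
            accumulate_update(syn, np.array([delta]), DT)
        tr, td = kernel.tau_rise_ms, kernel.tau_decay_ms
        integral_ms = kernel.normalization * (
            td * (1 - np.exp(-T / td)) - tr * (1 - np.exp(-T / tr))
        )
        assert syn.m[0, 0] == pytest.approx(delta * integral_ms / 1000.0, rel=2e-2)

    def test_apply_update_clips_and_resets(self):
        syn = SynapseMatrix(w=np.array([[0.09]]), w_min=-0.1, w_max=0.1)
        syn.m[:] = 1.0
        apply_update(syn, 1.0)
        assert syn.w[0, 0] == 0.1
        assert syn.m[0, 0] == 0.0
        syn.m[:] = 0.0
        apply_update(syn, 1.0)
        assert syn.w[0, 0] == 0.1  # m = 0 leaves weights unchanged

    def test_two_chunks_equal_one_without_clipping(self):
        m1, m2 = np.array([[0.3]]), np.array([[-0.1]])
        a = SynapseMatrix(w=np.zeros((1, 1)), w_min=-10, w_max=10)
        a.m = m1.copy()
        apply_update(a, 0.5)
        a.m = m2.copy()
        apply_update(a, 0.5)
        b = SynapseMatrix(w=np.zeros((1, 1)), w_min=-10, w_max=10)
        b.m = m1 + m2
        apply_update(b, 0.5)
        np.testing.assert_allclose(a.w, b.w, rtol=1e-12)

    def test_rule_locality(self, neuron):
        """The update of synapse (j, i) depends only on trace j, voltage i and
        feedback i — changing an unrelated presynaptic trace leaves it intact."""
        pre_a = np.array([0.4, 0.0, 0.2])
        pre_b = np.array([0.4, 0.9, 0.2])  # only trace 1 differs
        U = np.array([-55.0, -51.0])
        fb = np.array([0.3, -0.2])
        out = []
        for pre in (pre_a, pre_b):
            syn = SynapseMatrix(w=np.zeros((3, 2)))
            h = hebbian_coincidence(pre, U, neuron)
            eligibility_step(syn, h, KernelParams(), DT)
            accumulate_update(syn, fb, DT)
            out.append(syn.m)
        np.testing.assert_array_equal(out[0][[0, 2]], out[1][[0, 2]])
        assert not np.array_equal(out[0][1], out[1][1])


class TestRegularizer:
    def test_rho_zero_is_exact_zero(self):
        r = regularizer_term(np.ones((2, 2)), np.array([5.0, 1.0]), RegularizerParams(rho=0.0))
        assert np.all(r == 0.0)

    def test_silent_neuron_no_decay_for_positive_exponent(self):
        p = RegularizerParams(rho=1.0, exponent_a=2.0)
        r = regularizer_term(np.ones((2, 2)), np.array([0.0, 2.0]), p)
        assert np.all(r[:, 0] == 0.0) and np.all(r[:, 1] == 4.0)

    def test_exponent_zero_is_activity_independent(self):
        p = RegularizerParams(rho=0.5, exponent_a=0.0)
        r = regularizer_term(np.full((1, 3), 2.0), np.array([0.0, 5.0, 50.0]), p)
        np.testing.assert_allclose(r, 1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            RegularizerParams(rho=-1.0)
        with pytest.raises(ConfigurationError):
            RegularizerParams(exponent_a=-0.5)


class TestRateEstimate:
    def test_decays_to_zero_without_spikes(self):
        nu = np.array([8.0])
        for _ in range(100_000):
            nu = update_rate_estimate(nu, np.zeros(1), 1000.0, DT)
        assert nu[0] == pytest.approx(0.0, abs=1e-3)

    def test_regular_train_converges_to_rate_and_is_linear(self):
        nu10, nu20 = np.zeros(1), np.zeros(1)
        period = int(round(100.0 / DT))  # 10 Hz
        for step in range(600_000):  # 60 s
            s10 = 1.0 if step % period == 0 else 0.0
            s20 = 1.0 if step % (period // 2) == 0 else 0.0
            nu10 = update_rate_estimate(nu10, np.array([s10]), 1000.0, DT)
            nu20 = update_rate_estimate(nu20, np.array([s20]), 1000.0, DT)
        assert nu10[0] == pytest.approx(10.0, rel=0.05)
        assert nu20[0] == pytest.approx(2 * nu10[0], rel=0.05)
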