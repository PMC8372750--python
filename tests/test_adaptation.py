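"""Homeostatic and plasticity update rules: frozen examples, fixed
points, closed-loop convergence and boundedness."""

import numpy as np
import pytest

from pyramidal import (
    BCMParams,
    HebbParams,
    HomeostasisParams,
    HomeostasisState,
    PlasticityState,
    bcm_step,
    bias_step,
    gain_step,
    hebbian_step,
    running_average_step,
)
from pyramidal import _engine
from pyramidal.adaptation import init_plasticity_state


class TestRunningAverage:
    def test_fixed_point(self):
        assert running_average_step(0.7, 0.7, 5e-3) == pytest.approx(0.7, abs=1e-15)

    def test_single_step_value(self):
        # avg=0, sample=1 at the reference rate
        assert running_average_step(0.0, 1.0, 5e-3) == pytest.approx(0.005)

    def test_geometric_convergence_to_constant(self):
        mu = 5e-3
        avg, target = 3.0, -1.0
        for t in range(1, 6):
            avg = running_average_step(avg, target, mu)
            closed_form = target + (3.0 - target) * (1 - mu) ** t
            assert avg == pytest.approx(closed_form, rel=1e-12)

    def test_vector_shapes_and_errors(self):
        out = running_average_step(np.zeros(3), np.ones(3), 0.5)
        np.testing.assert_allclose(out, 0.5)
        with pytest.raises(ValueError):
            running_average_step(np.zeros(3), np.ones(2), 0.5)
        with pytest.raises(ValueError):
            running_average_step(0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            running_average_step(0.0, 1.0, 1.5)


class TestBiasStep:
    def test_fixed_point_at_target(self, homeo):
        s = HomeostasisState(b_p=0.2, b_d=-0.1)
        s2 = bias_step(s, homeo.I_p_target, homeo.I_d_target, homeo)
        assert s2.b_p == s.b_p and s2.b_d == s.b_d

    def test_single_step_value(self, homeo):
        s2 = bias_step(HomeostasisState(), 0.5, 0.0, homeo)
        assert s2.b_p == pytest.approx(5e-4)
        assert s2.b_d == 0.0

    def test_only_biases_touched(self, homeo):
        s = HomeostasisState(n_p=1.3, Itilde_p=0.4)
        s2 = bias_step(s, 1.0, 1.0, homeo)
        assert s2.n_p == s.n_p and s2.Itilde_p == s.Itilde_p

    def test_closed_loop_mean_reaches_target(self, homeo):
        """I = drive - b with constant drive: the realized current
        converges to the mean target (first-order linear feedback)."""
        s = HomeostasisState()
        drive = 0.8
        for _ in range(20_000):
            s = bias_step(s, drive - s.b_p, drive - s.b_d, homeo)
        assert drive - s.b_p == pytest.approx(homeo.I_p_target, abs=1e-6)


class TestGainStep:
    def test_fixed_point_at_variance_target(self, homeo):
        dev = np.sqrt(homeo.V_d_target)
        s = HomeostasisState(Itilde_d=0.0, Itilde_p=0.0)
        s2 = gain_step(s, np.sqrt(homeo.V_p_target), dev, homeo)
        assert s2.n_p == s.n_p and s2.n_d == s.n_d

    def test_single_step_value(self, homeo):
        # current equal to its running mean: full variance-target nudge
        s2 = gain_step(HomeostasisState(), 0.0, 0.0, homeo)
        assert s2.n_d == pytest.approx(1.0 + 2.5e-5)
        assert s2.n_p == pytest.approx(1.0 + 2.5e-5)

    def test_running_averages_advance(self, homeo):
        s2 = gain_step(HomeostasisState(), 1.0, -1.0, homeo)
        assert s2.Itilde_p == pytest.approx(homeo.mu_av * 1.0)
        assert s2.Itilde_d == pytest.approx(-homeo.mu_av * 1.0)

    def test_gain_clamped_nonnegative(self):
        p = HomeostasisParams(mu_n=0.5, V_p_target=0.01, V_d_target=0.01)
        s = HomeostasisState(n_p=0.1, n_d=0.1)
        s2 = gain_step(s, 5.0, 5.0, p)
        assert s2.n_p == 0.0 and s2.n_d == 0.0

    def test_closed_loop_variance_reaches_target(self, transfer, homeo):
        """Dual homeostasis driving I = n*x - b with zero-mean
        unit-variance drive: realized variance converges to the target
        within +-20%. Uses the frozen-weight training engine (N=1,
        w=1) so both current pathways see the same drive."""
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(100_000)
            traj = _engine.fused_train(
                x[:, None], x, np.ones(1),
                model="compartment", rule=None, transfer=transfer,
                homeo_params=homeo, plast_params=None,
                plastic=False, adapt=True,
            )
            var = traj.I_p[-10_000:].var()
            assert var == pytest.approx(homeo.V_p_target, rel=0.2)


class TestHebbianStep:
    params = HebbParams(mu_w=5e-5, epsilon=0.1, mu_av=5e-3)

    def test_pure_decay_when_pre_equals_average(self):
        w = np.array([0.5, -0.3])
        x = np.array([0.2, 0.9])
        st = PlasticityState(w=w, xtilde_p=x.copy(), ytilde=0.1)
        s2 = hebbian_step(st, x, 0.7, self.params)
        np.testing.assert_allclose(
            s2.w, w * (1 - self.params.mu_w * self.params.epsilon), rtol=1e-15
        )

    def test_single_step_value(self):
        # centered pre = centered post = 1, w = 0.5, reference rates
        st = PlasticityState(w=np.array([0.5]), xtilde_p=np.array([0.0]), ytilde=0.0)
        s2 = hebbian_step(st, np.array([1.0]), 1.0, self.params)
        assert s2.w[0] == pytest.approx(0.5000475, abs=1e-10)

    def test_weight_update_uses_prestep_averages(self):
        """The correlation term is evaluated with the trailing averages
        from before this sample is folded in."""
        st = PlasticityState(w=np.zeros(1), xtilde_p=np.array([0.0]), ytilde=0.0)
        s2 = hebbian_step(st, np.array([1.0]), 1.0, self.params)
        # pre-step averages are 0, so the drive is (1-0)(1-0) = 1
        assert s2.w[0] == pytest.approx(self.params.mu_w)
        # averages advanced afterwards
        assert s2.xtilde_p[0] == pytest.approx(self.params.mu_av)
        assert s2.ytilde == pytest.approx(self.params.mu_av)

    def test_shape_mismatch(self):
        st = PlasticityState(w=np.zeros(3), xtilde_p=np.zeros(3), ytilde=0.0)
        with pytest.raises(ValueError):
            hebbian_step(st, np.zeros(2), 0.5, self.params)

    def test_weights_stay_bounded(self, rng):
        """With x, y in [0,1] the drive is at most 1, so |w| can never
        escape |w0| + 1/epsilon."""
        st = init_plasticity_state(rng.normal(0, 1, 5), rng.uniform(0, 1, 5), 0.5)
        bound = np.abs(st.w).max() + 1.0 / self.params.epsilon
        p = HebbParams(mu_w=5e-3, epsilon=0.1, mu_av=5e-3)  # fast to stress the bound
        for _ in range(10_000):
            st = hebbian_step(st, rng.uniform(0, 1, 5), rng.uniform(0, 1), p)
            assert np.abs(st.w).max() <= bound


class TestBCMStep:
    fixed = BCMParams(threshold_mode="fixed", theta_M_fixed=0.65)
    sliding = BCMParams(threshold_mode="sliding")

    def test_pure_decay_at_threshold(self):
        w = np.array([0.4, -0.2])
        st = PlasticityState(w=w, xtilde_p=np.zeros(2), ytilde=0.0)
        s2 = bcm_step(st, np.array([1.0, 1.0]), 0.65, self.fixed)
        np.testing.assert_allclose(
            s2.w, w * (1 - self.fixed.mu_w * self.fixed.epsilon), rtol=1e-15
        )

    def test_single_step_value(self):
        # y=1, theta_M=(1+0.3)/2, x=1, w=0: dw = mu_w * 0.35
        st = PlasticityState(w=np.zeros(1), xtilde_p=np.zeros(1), ytilde=0.0)
        s2 = bcm_step(st, np.ones(1), 1.0, self.fixed)
        assert s2.w[0] == pytest.approx(1.75e-5, abs=1e-15)

    def test_silent_neuron_pure_decay(self):
        w = np.array([0.4, -0.2])
        st = PlasticityState(w=w, xtilde_p=np.zeros(2), ytilde=0.0)
        s2 = bcm_step(st, np.array([7.0, -3.0]), 0.0, self.fixed)
        np.testing.assert_allclose(
            s2.w, w * (1 - self.fixed.mu_w * self.fixed.epsilon), rtol=1e-15
        )

    def test_sliding_threshold_tracks_y_squared(self):
        st = PlasticityState(
            w=np.zeros(1), xtilde_p=np.zeros(1), ytilde=0.0, theta_M_sliding=0.2
        )
        s2 = bcm_step(st, np.ones(1), 0.8, self.sliding)
        assert s2.theta_M_sliding == pytest.approx(
            (1 - self.sliding.mu_av) * 0.2 + self.sliding.mu_av * 0.64
        )
        # the weight update used the pre-step threshold 0.2
        assert s2.w[0] == pytest.approx(self.sliding.mu_w * 0.8 * (0.8 - 0.2))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            BCMParams(threshold_mode="other")
        with pytest.raises(ValueError):
            HebbParams(mu_w=0.0)


def test_long_run_weights_bounded(transfer, homeo):
    """No unbounded weight trajectory over a million training steps of
    the full alignment dynamics (Hebbian, reference parameters)."""
    rng = np.random.default_rng(0)
    N = 10
    xp = rng.uniform(0, 1, (1_000_000, N))
    a = rng.standard_normal(N)
    a /= np.linalg.norm(a)
    traj = _engine.fused_train(
        xp, xp @ a, rng.standard_normal(N) / np.sqrt(N),
        model="compartment", rule="hebb", transfer=transfer,
        homeo_params=homeo, plast_params=HebbParams(),
    )
    assert np.abs(traj.plast.w).max() < 10.0 / HebbParams().epsilon
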