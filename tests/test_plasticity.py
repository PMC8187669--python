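"""Weight dynamics: STDP curve, current law, GDR gradient, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mrisnn as m
from mrisnn import plasticity
from mrisnn.errors import ContractError, DegenerateStateError


def surrogate_cost(w_obs, v, v_d, theta, v_norm):
    """J(W) = 1/2 || V_d - tanh(W V)/||V|| - theta/||V|| ||^2 (V held fixed)."""
    out = (np.tanh(w_obs @ v) + theta) / v_norm
    e = v_d - out
    return 0.5 * float(e @ e)


class TestStdpDelta:
    def setup_method(self):
        self.p = m.STDPParams()

    def test_zero_lag_gives_a_plus(self):
        assert plasticity.stdp_delta(0.0, self.p) == pytest.approx(2e-3)

    def test_minus_tau_gives_scaled_depression(self):
        p = m.STDPParams(tau_minus=50.0)
        assert plasticity.stdp_delta(-50.0, p) == pytest.approx(-2e-3 * np.exp(-1))

    def test_outside_window_is_zero(self):
        assert plasticity.stdp_delta(150.0, self.p) == 0.0
        assert plasticity.stdp_delta(-150.0, self.p) == 0.0

    def test_sign_discipline_and_bound_standard(self):
        dts = np.linspace(-100, 100, 2001)
        dw = plasticity.stdp_delta(dts, self.p)
        assert np.all(dw[dts >= 0] >= 0)
        assert np.all(dw[dts < 0] <= 0)
        assert np.max(np.abs(dw)) <= max(self.p.a_plus, self.p.a_minus)

    def test_monotone_decay_in_abs_dt(self):
        p = m.STDPParams(tau_plus=20.0, tau_minus=20.0)
        pos = plasticity.stdp_delta(np.linspace(0, 100, 500), p)
        neg = plasticity.stdp_delta(np.linspace(-100, 0, 500), p)
        assert np.all(np.diff(pos) <= 0)
        assert np.all(np.diff(np.abs(neg[::-1])) <= 0)

    def test_paper_sign_grows_as_printed(self):
        p = m.STDPParams(sign="paper", tau_plus=20.0, tau_minus=20.0)
        a = plasticity.stdp_delta(10.0, p)
        b = plasticity.stdp_delta(50.0, p)
        assert b > a > 0  # the literal exponent grows with dt

    def test_paper16_variant_potentiation_only(self):
        p = m.STDPParams(variant="paper16")
        assert plasticity.stdp_delta(-10.0, p) > 0
        assert plasticity.stdp_delta(10.0, p) == 0.0
        assert plasticity.stdp_delta(0.0, p) == pytest.approx(2e-3)


class TestObservedInputCurrent:
    def test_all_zero_inputs_give_zero(self):
        I = plasticity.observed_input_current(
            np.zeros((3, 5)), np.ones(5), np.zeros(5), np.zeros((3, 5)),
            np.zeros(3))
        np.testing.assert_array_equal(I, 0.0)

    def test_single_neighbor_weight_rate(self):
        # w = 0, dw/dt = k, v_j = 1 -> I = k (1 - tanh(0)^2) = k
        k = 0.37
        I = plasticity.observed_input_current(
            np.zeros((1, 1)), np.ones(1), np.zeros(1),
            np.array([[k]]), np.zeros(1))
        assert I[0] == pytest.approx(k)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(5)
        n_ob, n = 3, 5
        w = rng.normal(size=(n_ob, n))
        dw = rng.normal(size=(n_ob, n))
        v = rng.normal(size=n)
        dv = rng.normal(size=n)
        dth = rng.normal(size=n_ob)
        got = plasticity.observed_input_current(w, v, dv, dw, dth)
        for i in range(n_ob):
            acc = sum(w[i, j] * dv[j] + dw[i, j] * v[j] for j in range(n))
            gain = 1.0 - np.tanh(sum(w[i, j] * v[j] for j in range(n))) ** 2
            assert got[i] == pytest.approx(acc * gain + dth[i])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ContractError):
            plasticity.observed_input_current(
                np.zeros((2, 3)), np.zeros(4), np.zeros(4),
                np.zeros((2, 3)), np.zeros(2))


class TestGdrWeightUpdate:
    def test_zero_row_is_fixed_point_in_paper_mode(self):
        st_ = plasticity.TrainingState(e=np.array([0.5]), v_norm=2.0, ts=8.0)
        d = plasticity.gdr_weight_update(np.zeros((1, 4)), np.ones(4), st_,
                                         mode="paper")
        np.testing.assert_array_equal(d, 0.0)

    def test_zero_error_means_zero_update_both_modes(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(2, 5))
        v = rng.normal(size=5)
        st_ = plasticity.TrainingState(e=np.zeros(2), v_norm=1.5, ts=8.0)
        for mode in ("paper", "rederived"):
            d = plasticity.gdr_weight_update(w, v, st_, mode=mode)
            np.testing.assert_array_equal(d, 0.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_rederived_matches_finite_differences(self, trial):
        """Analytic update equals -eta * dJ/dW of the surrogate cost."""
        rng = np.random.default_rng(100 + trial)
        n_ob = rng.integers(1, 6)
        n = rng.integers(n_ob, 11)
        w = rng.normal(scale=0.3, size=(n_ob, n))
        v = rng.normal(size=n)
        v_d = rng.normal(size=n_ob)
        theta = rng.normal(scale=0.1, size=n_ob)
        v_norm = float(rng.uniform(0.5, 3.0))
        out = (np.tanh(w @ v) + theta) / v_norm
        e = v_d - out
        st_ = plasticity.TrainingState(e=e, v_norm=v_norm, ts=8.0)
        eta = 1.0
        delta = plasticity.gdr_weight_update(w, v, st_, mode="rederived",
                                             eta=eta)
        h = 1e-6
        for i in range(n_ob):
            for j in range(n):
                wp = w.copy(); wp[i, j] += h
                wm = w.copy(); wm[i, j] -= h
                g = (surrogate_cost(wp, v, v_d, theta, v_norm)
                     - surrogate_cost(wm, v, v_d, theta, v_norm)) / (2 * h)
                expect = -eta * g
                assert delta[i, j] == pytest.approx(expect, rel=1e-5, abs=1e-10)

    def test_degenerate_norm_raises(self):
        st_ = plasticity.TrainingState(e=np.ones(1), v_norm=0.0, ts=8.0)
        with pytest.raises(DegenerateStateError):
            plasticity.gdr_weight_update(np.ones((1, 2)), np.ones(2), st_)


class TestLeakage:
    def test_direct_division(self):
        st_ = plasticity.TrainingState(e=np.array([1.0, -1.0]), v_norm=2.0,
                                       ts=8.0)
        leak = plasticity.LeakageState(np.zeros(2))
        dth = plasticity.leakage_update(st_, leak)
        np.testing.assert_allclose(dth, [0.5, -0.5])

    def test_zero_error_no_change(self):
        st_ = plasticity.TrainingState(e=np.zeros(3), v_norm=1.0, ts=8.0)
        leak = plasticity.LeakageState(np.ones(3))
        plasticity.leakage_update(st_, leak)
        np.testing.assert_array_equal(leak.theta, 1.0)

    def test_accumulation_matches_scalar_sum(self):
        rng = np.random.default_rng(3)
        leak = plasticity.LeakageState(np.zeros(4))
        acc = np.zeros(4)
        for _ in range(50):
            e = rng.normal(size=4)
            vn = float(rng.uniform(0.5, 2.0))
            st_ = plasticity.TrainingState(e=e, v_norm=vn, ts=8.0)
            plasticity.leakage_update(st_, leak)
            acc += 8.0 * e / vn
        np.testing.assert_allclose(leak.theta, acc, rtol=1e-12)


class TestCombinedUpdate:
    def _build(self, seed=0):
        cloud = m.gen_head_cloud(200, seed=0)
        mont = m.gen_montage_1020(["Cz", "Pz", "Fz"])
        layout = m.place_neurons(cloud, mont, 40, seed=seed)
        graph = m.build_neighborhoods(layout, 70.0)
        W = m.init_weights(graph, layout, seed=seed)
        return layout, graph, W

    def test_no_spikes_no_error_leaves_w_unchanged(self):
        layout, graph, W = self._build()
        before = W.values.copy()
        st_ = plasticity.TrainingState(e=np.zeros(3), v_norm=1.0, ts=8.0)
        leak = plasticity.LeakageState(np.zeros(3))
        plasticity.combined_update(
            W, layout, st_, leak, m.STDPParams(), np.full(40, -65.0),
            np.full(40, np.nan), np.full(40, np.nan))
        np.testing.assert_array_equal(W.values, before)

    def test_single_hidden_spike_pair_touches_one_edge(self):
        layout, graph, W = self._build()
        hidden = np.flatnonzero(~layout.observed_mask)
        # pick two neighbouring excitatory hidden neurons
        pre = post = None
        for h in hidden:
            if layout.is_inhibitory[h]:
                continue
            nb = [j for j in graph.neighbors(h)
                  if j != h and j in hidden and not layout.is_inhibitory[j]]
            if nb:
                post, pre = h, nb[0]
                break
        assert post is not None
        before = W.values.copy()
        new_spike = np.full(40, np.nan)
        last_spike = np.full(40, np.nan)
        last_spike[pre] = 95.0
        new_spike[post] = 100.0  # pre 5 ms before post
        st_ = plasticity.TrainingState(e=np.zeros(3), v_norm=1.0, ts=8.0)
        leak = plasticity.LeakageState(np.zeros(3))
        plasticity.combined_update(W, layout, st_, leak, m.STDPParams(),
                                   np.full(40, -65.0), new_spike, last_spike)
        diff = W.values - before
        # forward synapse (pre -> post) potentiates; the reverse synapse of
        # the same pair depresses; nothing else moves
        assert diff[post, pre] > 0
        assert diff[pre, post] <= 0
        diff[post, pre] = 0.0
        diff[pre, post] = 0.0
        np.testing.assert_array_equal(diff, 0.0)

    def test_observed_row_changes_only_inside_neighborhood(self):
        layout, graph, W = self._build()
        before = W.values.copy()
        e = np.array([0.3, -0.2, 0.1])
        st_ = plasticity.TrainingState(e=e, v_norm=1.0, ts=8.0)
        leak = plasticity.LeakageState(np.zeros(3))
        rng = np.random.default_rng(0)
        v = rng.normal(scale=0.2, size=40)
        plasticity.combined_update(W, layout, st_, leak, m.STDPParams(), v,
                                   np.full(40, np.nan), np.full(40, np.nan))
        diff = W.values - before
        for i in layout.observed_ids:
            outside = ~graph.adjacency[i]
            np.testing.assert_array_equal(diff[i, outside], 0.0)
        hidden = ~layout.observed_mask
        np.testing.assert_array_equal(diff[hidden], 0.0)

    def test_structural_sparsity_never_grows(self):
        layout, graph, W = self._build()
        st_ = plasticity.TrainingState(e=np.array([1.0, 2.0, -1.0]),
                                       v_norm=1.0, ts=8.0)
        leak = plasticity.LeakageState(np.zeros(3))
        rng = np.random.default_rng(1)
        for _ in range(5):
            plasticity.combined_update(
                W, layout, st_, leak, m.STDPParams(),
                rng.normal(size=40), np.full(40, np.nan), np.full(40, np.nan))
        assert np.all(W.values[~W.mask] == 0.0)

    def test_inhibitory_columns_clamped_nonpositive(self):
        layout, graph, W = self._build()
        st_ = plasticity.TrainingState(e=np.array([5.0, 5.0, 5.0]),
                                       v_norm=1.0, ts=8.0)
        leak = plasticity.LeakageState(np.zeros(3))
        plasticity.combined_update(W, layout, st_, leak, m.STDPParams(),
                                   np.full(40, 1.0), np.full(40, np.nan),
                                   np.full(40, np.nan))
        inh = np.flatnonzero(layout.is_inhibitory)
        assert np.all(W.values[:, inh] <= 0.0)


class TestPruneStrongest:
    def _w(self, vals):
        mask = np.ones((3, 3), dtype=bool)
        return m.WeightMatrix(np.array(vals, dtype=float), mask)

    def test_keeps_larger_magnitude_direction(self):
        W = self._w([[0.0, 0.5, 0.0], [-0.7, 0.0, 0.0], [0.0, 0.0, 0.0]])
        out = plasticity.prune_strongest(W)
        assert out.values[0, 1] == 0.0
        assert out.values[1, 0] == -0.7

    def test_tie_keeps_lower_index_direction(self):
        W = self._w([[0.0, 0.4, 0.0], [0.4, 0.0, 0.0], [0.0, 0.0, 0.0]])
        out = plasticity.prune_strongest(W)
        assert out.values[0, 1] == 0.4
        assert out.values[1, 0] == 0.0

    def test_self_loops_untouched(self):
        W = self._w([[0.9, 0.1, 0.0], [0.2, -0.8, 0.0], [0.0, 0.0, 0.3]])
        out = plasticity.prune_strongest(W)
        assert out.values[0, 0] == 0.9
        assert out.values[1, 1] == -0.8
        assert out.values[2, 2] == 0.3

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_at_most_one_direction_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        mask = rng.random((n, n)) < 0.6
        mask |= mask.T
        np.fill_diagonal(mask, True)
        W = m.WeightMatrix(rng.normal(size=(n, n)) * mask, mask)
        once = plasticity.prune_strongest(W)
        for i in range(n):
            for j in range(i + 1, n):
                assert once.values[i, j] * once.values[j, i] == 0.0
        twice = plasticity.prune_strongest(once)
        np.testing.assert_array_equal(once.values, twice.values)
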