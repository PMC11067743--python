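"""Architecture, loss components, gradients and the training loop."""

import copy

import numpy as np
import pytest

from dedkin import (
    TrainConfig,
    decompose_series,
    forward_pass,
    general_mechanism,
    hidden_layer_size,
    init_state,
    relu1,
    sequential_mechanism,
    simulate,
    solve_concentrations,
    train,
)
from dedkin.kinetics_core import assemble_rate_matrix
from dedkin.network import (
    NetworkState,
    compute_losses,
    conversion_forward,
    loss_and_grads,
    projection_forward,
    rate_range_penalty,
)
from dedkin.svd_kinetics import RateBounds

T21 = np.geomspace(1e-6, 1.0, 21)
LOOSE = RateBounds(lower=np.array([1e-6]), upper=np.array([1e10]))


class TestHiddenLayerSize:
    def test_reference_dimensions(self):
        assert hidden_layer_size(63, 10) == 25

    def test_exceeds_output_width(self):
        for Q, R in [(63, 10), (42, 3), (84, 10)]:
            assert hidden_layer_size(Q, R) > R

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="hidden layer too small"):
            hidden_layer_size(6, 10)


class TestInitState:
    dims = {"M_sig": 3, "M": 3, "P": 21, "R": 10}

    def test_same_seed_bit_identical(self):
        a = init_state(self.dims, TrainConfig(seed=7))
        b = init_state(self.dims, TrainConfig(seed=7))
        for name, arr in a.params().items():
            assert np.array_equal(arr, b.params()[name])

    def test_different_seed_differs(self):
        a = init_state(self.dims, TrainConfig(seed=7))
        b = init_state(self.dims, TrainConfig(seed=8))
        assert not np.array_equal(a.W1, b.W1)

    def test_sample_std_matches_config(self):
        """>=1e5 draws: empirical STD within 1% of 0.02."""
        dims = {"M_sig": 3, "M": 3, "P": 700, "R": 10}   # W1 alone has 700*2100 entries
        state = init_state(dims, TrainConfig(seed=0))
        draws = np.concatenate([p.ravel() for p in state.params().values()])
        assert draws.size > 1e5
        assert np.std(draws) == pytest.approx(0.02, rel=0.01)
        assert np.mean(draws) == pytest.approx(0.0, abs=1e-3)

    def test_dimensions_follow_architecture(self):
        state = init_state(self.dims, TrainConfig(seed=1))
        assert state.A.shape == (3, 3)
        assert state.C_nn.shape == (3, 21)
        assert state.W1.shape == (25, 63) and state.b1.shape == (25,)
        assert state.W2.shape == (10, 25) and state.b2.shape == (10,)


class TestRelu1:
    @pytest.mark.parametrize("x,expected", [(0.5, 0.5), (-0.2, 0.0), (1.7, 1.0), (0.0, 0.0), (1.0, 1.0)])
    def test_clamp(self, x, expected):
        assert relu1(np.array([x]))[0] == expected


class TestProjectionForward:
    def test_identity_weights_return_lsvs(self):
        rng = np.random.default_rng(0)
        U = np.linalg.qr(rng.normal(size=(50, 3)))[0]
        state = init_state({"M_sig": 3, "M": 3, "P": 21, "R": 10}, TrainConfig(seed=0))
        state.A = np.eye(3)
        I, _ = projection_forward(U, state)
        assert np.array_equal(I, U)

    def test_zero_concentrations_give_zero_series(self):
        rng = np.random.default_rng(1)
        U = rng.normal(size=(50, 3))
        state = init_state({"M_sig": 3, "M": 3, "P": 21, "R": 10}, TrainConfig(seed=0))
        state.C_nn = np.zeros((3, 21))
        _, E_c1 = projection_forward(U, state)
        assert np.all(E_c1 == 0)

    def test_reference_shapes(self):
        rng = np.random.default_rng(2)
        U = rng.normal(size=(2291, 3))
        state = init_state({"M_sig": 3, "M": 3, "P": 21, "R": 10}, TrainConfig(seed=0))
        I, E_c1 = projection_forward(U, state)
        assert I.shape == (2291, 3) and E_c1.shape == (2291, 21)


class TestConversionForward:
    def test_zero_network_outputs_unit_rates(self):
        state = init_state({"M_sig": 3, "M": 3, "P": 21, "R": 10}, TrainConfig(seed=0))
        state.W1[:] = 0; state.b1[:] = 0; state.W2[:] = 0; state.b2[:] = 0
        k = conversion_forward(np.random.default_rng(0).uniform(size=(3, 21)), state)
        assert np.allclose(k, 1.0)
        assert k.shape == (10,)

    def test_rates_always_positive(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            state = init_state({"M_sig": 3, "M": 3, "P": 21, "R": 10}, TrainConfig(seed=seed, init_std=0.5))
            k = conversion_forward(rng.normal(size=(3, 21)), state)
            assert np.all(k > 0)


class TestLosses:
    def test_range_penalty_reference_values(self):
        """One rate in range -> 0; 2000 against an upper limit of 1000 -> 0.48."""
        bounds = RateBounds(lower=np.array([1e-6]), upper=np.array([1000.0]))
        assert rate_range_penalty(np.array([900.0]), bounds) == 0.0
        val = rate_range_penalty(np.array([2000.0]), bounds)
        assert round(val, 2) == 0.48
        assert val == pytest.approx(np.log(2.0) ** 2, rel=1e-12)

    def test_range_penalty_zero_iff_within_bounds_and_monotone(self):
        bounds = RateBounds(lower=np.array([10.0]), upper=np.array([1000.0]))
        inside = np.linspace(10, 1000, 7)
        assert all(rate_range_penalty(np.array([k]), bounds) == 0.0 for k in inside)
        above = [rate_range_penalty(np.array([k]), bounds) for k in (1001, 2000, 5000, 1e6)]
        assert all(b > a for a, b in zip(above, above[1:]))
        below = [rate_range_penalty(np.array([k]), bounds) for k in (9.9, 5, 1, 1e-3)]
        assert all(b > a for a, b in zip(below, below[1:]))

    def test_total_is_linear_combination(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(30, 5))
        C = rng.uniform(size=(3, 5))
        C_cde = np.vstack([C, 1 - C.sum(axis=0)])
        I = rng.normal(size=(30, 3))
        loss = compute_losses(E, E * 0.9, E * 1.1, C, C_cde, I, np.array([2000.0] * 10),
                              RateBounds(lower=np.array([1e-6]), upper=np.array([1000.0])),
                              amplifiers=(1.0, 1.0, 0.1, 1.0, 0.0))
        assert loss.total == pytest.approx(loss.L_E + loss.L_K + 0.1 * loss.L_C + loss.L_I, rel=1e-12)
        # component arithmetic: 2 + 3 + 0.1*5 + 7 = 12.5
        assert 1 * 2 + 1 * 3 + 0.1 * 5 + 1 * 7 == 12.5

    def test_perfect_self_consistency_leaves_only_rate_penalty(self):
        rng = np.random.default_rng(1)
        E = rng.normal(size=(30, 5))
        C = rng.uniform(size=(3, 5))
        C_cde = np.vstack([C, np.zeros(5)])
        I = rng.normal(size=(30, 3))
        bounds = RateBounds(lower=np.array([1e-6]), upper=np.array([1000.0]))
        in_range = compute_losses(E, E, E, C, C_cde, I, np.full(10, 500.0), bounds)
        assert in_range.total == 0.0
        out_of_range = compute_losses(E, E, E, C, C_cde, I, np.full(10, 2000.0), bounds)
        assert out_of_range.total == pytest.approx(out_of_range.c_K * 10 * np.log(2.0) ** 2, rel=1e-12)


class TestOptionalLossTerms:
    def test_dark_projection_column_penalized(self):
        """With the dark state carried in the projection, its map's squared
        mean feeds the loss and shrinks during training."""
        series, _ = simulate("S_S", n_voxels=150, noise_sigma=3.4e-5, seed=12)
        cfg = TrainConfig(max_iterations=0, seed=0, include_dark_in_projection=True)
        result = train(series, general_mechanism(), cfg)
        assert result.state.A.shape == (3, 4)
        assert result.loss.L_I > 0.0

    def test_map_dissimilarity_scores_parallel_maps(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(30, 5))
        C = rng.uniform(size=(3, 5))
        C_cde = np.vstack([C, np.zeros(5)])
        bounds = LOOSE
        base = rng.normal(size=30)
        I_par = np.column_stack([base, base * 2.0, rng.normal(size=30)])
        I_orth = np.linalg.qr(rng.normal(size=(30, 3)))[0]
        amps = (1.0, 1.0, 0.1, 1.0, 1.0)
        l_par = compute_losses(E, E, E, C, C_cde, I_par, np.ones(10), bounds, amplifiers=amps)
        l_orth = compute_losses(E, E, E, C, C_cde, I_orth, np.ones(10), bounds, amplifiers=amps)
        assert l_par.L_I > 0.9   # one cos^2 term is exactly 1
        assert l_orth.L_I < 1e-12


def _self_consistent_setup():
    """A state whose forward pass reproduces the data and the ODE exactly."""
    mech = sequential_mechanism()
    series, gt = simulate("S_S", n_voxels=300, noise_sigma=0.0, seed=8)
    svd = decompose_series(series, n_significant=3)
    U = svd.U_significant
    k_true = mech.rate_vector(gt.k_true)
    C_cde = solve_concentrations(assemble_rate_matrix(k_true, mech), np.array([1.0, 0, 0, 0]), T21).C
    state = init_state({"M_sig": 3, "M": 3, "P": 21, "R": mech.n_rates}, TrainConfig(seed=0))
    state.A = U.T @ gt.I_true
    state.C_nn = relu1(C_cde[:3])
    state.W1[:] = 0.0
    state.b1[:] = 1.0          # keep the hidden layer active
    state.W2[:] = 0.0
    state.b2 = np.log(k_true)
    return mech, series, U, state, gt


class TestForwardPass:
    def test_self_consistent_fixed_point(self):
        mech, series, U, state, gt = _self_consistent_setup()
        cfg = TrainConfig(seed=0)
        I, E_c1, k, C_cde, E_c2, loss = forward_pass(U, series.values, state, mech, cfg, T21)
        assert np.allclose(k, mech.rate_vector(gt.k_true), rtol=1e-12)
        assert loss.L_C == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(E_c1, E_c2, atol=1e-12)
        assert loss.L_E == pytest.approx(0.0, abs=1e-16)

    def test_initial_condition_enters_ode(self):
        mech, series, U, state, _ = _self_consistent_setup()
        _, _, _, C_cde, _, _ = forward_pass(U, series.values, state, mech, TrainConfig(seed=0), T21)
        # concentrations extrapolate to (1,0,0,0) at t -> 0
        early = solve_concentrations(
            assemble_rate_matrix(np.array(list(conversion_forward(state.C_nn, state))), mech),
            np.array([1.0, 0, 0, 0]), np.array([1e-12])).C[:, 0]
        assert np.allclose(early, [1.0, 0.0, 0.0, 0.0], atol=1e-6)

    def test_random_init_smoke_finite(self):
        series, _ = simulate("S_S", n_voxels=120, noise_sigma=3.4e-5, seed=9)
        svd = decompose_series(series, n_significant=3)
        mech = general_mechanism()
        for seed in range(10):
            cfg = TrainConfig(seed=seed)
            state = init_state({"M_sig": 3, "M": 3, "P": 21, "R": 10}, cfg)
            _, _, k, _, _, loss = forward_pass(svd.U_significant, series.values / svd.S[0],
                                               state, mech, cfg, T21 / 1e-3)
            assert np.isfinite(loss.total)
            _, grads, _ = loss_and_grads(state, svd.U_significant, series.values / svd.S[0],
                                         mech, T21 / 1e-3, LOOSE)
            assert all(np.all(np.isfinite(g)) for g in grads.values())


class TestGradients:
    @pytest.mark.parametrize("decoding", ["exp", "linear"])
    def test_directional_derivative_matches_finite_differences(self, decoding):
        rng = np.random.default_rng(0)
        N, P, M = 40, 21, 3
        mech = general_mechanism()
        E = rng.normal(0, 0.1, (N, P))
        U = np.linalg.svd(E, full_matrices=False)[0][:, :M]
        state = init_state({"M_sig": M, "M": M, "P": P, "R": 10}, TrainConfig(seed=1))
        state.C_nn = rng.uniform(0.05, 0.9, (M, P))
        state.b2 = np.linspace(-2.0, 2.0, 10)   # rates on both sides of the range
        bounds = RateBounds(lower=np.full(10, 0.5), upper=np.full(10, 1.5))
        ts = T21 / 1e-3
        loss, grads, _ = loss_and_grads(state, U, E, mech, ts, bounds, decoding=decoding)
        assert loss.L_K > 0  # both penalty branches should be exercised
        h = 1e-5
        for name, arr in state.params().items():
            d = rng.normal(size=arr.shape)
            d /= np.linalg.norm(d)
            plus = copy.deepcopy(state)
            getattr(plus, name)[...] += h * d
            minus = copy.deepcopy(state)
            getattr(minus, name)[...] -= h * d
            lp, _, _ = loss_and_grads(plus, U, E, mech, ts, bounds, decoding=decoding)
            lm, _, _ = loss_and_grads(minus, U, E, mech, ts, bounds, decoding=decoding)
            fd = (lp.total - lm.total) / (2 * h)
            an = float((grads[name] * d).sum())
            assert abs(fd - an) / max(abs(fd), abs(an), 1e-12) < 1e-4, name


@pytest.fixture(scope="module")
def short_run():
    series, gt = simulate("S_S", n_voxels=200, noise_sigma=3.4e-5, seed=10)
    cfg = TrainConfig(max_iterations=8000, seed=0, checkpoint_stride=1000)
    return train(series, general_mechanism(), cfg), series, gt


class TestTrainLoop:
    def test_zero_iterations_returns_initial_forward(self):
        series, _ = simulate("S_S", n_voxels=150, noise_sigma=3.4e-5, seed=10)
        result = train(series, general_mechanism(), TrainConfig(max_iterations=0, seed=0))
        assert result.run.loss_trace.shape == (1,)
        assert result.n_iterations == 0
        assert result.intermediates.shape == (150, 3)

    def test_loss_trace_moving_average_decreases(self, short_run):
        result, _, _ = short_run
        trace = result.run.loss_trace
        assert trace.shape == (8000,)
        windows = trace[2000:].reshape(-1, 1000).mean(axis=1)
        assert all(b <= a * 1.02 for a, b in zip(windows, windows[1:]))
        assert windows[-1] < windows[0]

    def test_checkpoints_follow_stride(self, short_run):
        result, _, _ = short_run
        assert list(result.run.checkpoint_iterations) == list(range(1000, 8001, 1000))
        assert len(result.run.intermediates_trace) == 8
        assert result.run.rates_trace.shape == (8, 10)

    def test_final_concentrations_on_dense_grid(self, short_run):
        result, series, _ = short_run
        assert result.run.concentrations_out.shape == (4, 400)
        assert np.allclose(result.run.concentrations_out.sum(axis=0), 1.0, atol=1e-6)
        assert result.run.concentration_times[0] == pytest.approx(series.times[0])
        assert result.run.concentration_times[-1] == pytest.approx(series.times[-1])

    def test_rates_reported_in_physical_units(self, short_run):
        result, _, _ = short_run
        assert set(result.rates) == set(general_mechanism().rate_order)
        assert all(v > 0 for v in result.rates.values())

    def test_tolerance_stop(self):
        series, _ = simulate("S_S", n_voxels=150, noise_sigma=3.4e-5, seed=10)
        cfg = TrainConfig(max_iterations=5000, seed=0, loss_tolerance=1e9, n_consecutive=50)
        result = train(series, general_mechanism(), cfg)
        assert result.converged
        assert result.n_iterations == 50

    def test_all_zero_input_rejected(self):
        from dedkin.ded_io import DEDMapSeries
        series = DEDMapSeries(voxel_index=np.arange(50), values=np.zeros((50, 21)), times=T21)
        with pytest.raises(ValueError, match="zero"):
            train(series, general_mechanism(), TrainConfig(max_iterations=10))

    def test_times_required(self):
        from dedkin.ded_io import DEDMapSeries
        rng = np.random.default_rng(0)
        series = DEDMapSeries(voxel_index=np.arange(50), values=rng.normal(size=(50, 21)))
        with pytest.raises(ValueError, match="times"):
            train(series, general_mechanism(), TrainConfig(max_iterations=10))
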