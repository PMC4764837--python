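import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consensusconf.model import (
    NetworkState,
    build_coupling,
    initial_state,
    ou_step,
    recurrent_current,
    simulate_trial,
    simulate_trials,
    step,
    transfer_rate,
)
from consensusconf.params import ModelParams
from consensusconf.readout import detect_votes, global_decision
from consensusconf.stimulus import LuminanceTransform, generate_flicker


class TestTransferRate:
    def test_removable_singularity_equals_inverse_curvature(self, params):
        i_at_threshold = params.fi_b / params.fi_a
        assert transfer_rate(i_at_threshold, params) == pytest.approx(
            1.0 / params.fi_d, rel=1e-9
        )

    def test_closed_form_value(self, params):
        # a=270, b=108, d=0.154, I=0.5 -> x=27, phi = 27/(1 - exp(-4.158))
        expected = 27.0 / (1.0 - np.exp(-0.154 * 27.0))
        assert transfer_rate(0.5, params) == pytest.approx(expected, rel=1e-12)
        assert transfer_rate(0.5, params) == pytest.approx(27.43, abs=0.005)

    def test_linear_asymptote(self, params):
        i = (params.fi_b + 1000.0) / params.fi_a
        assert transfer_rate(i, params) == pytest.approx(1000.0, rel=1e-6)

    def test_non_finite_current_rejected(self, params):
        with pytest.raises(ValueError, match="finite"):
            transfer_rate(np.nan, params)

    def test_very_negative_current_gives_zero_rate(self, params):
        assert transfer_rate(-100.0, params) == 0.0

    @given(
        st.floats(min_value=-2.0, max_value=2.0),
        st.floats(min_value=1e-6, max_value=1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_nonnegative_continuous(self, i, di):
        p = ModelParams()
        lo, hi = transfer_rate(i, p), transfer_rate(i + di, p)
        assert hi >= lo >= 0.0


class TestCoupling:
    def test_ic_zero_is_block_diagonal(self):
        p = ModelParams(n_modules=5, ic=0.0)
        w = build_coupling(p)
        for k in range(5):
            for l in range(5):
                block = w[k, :, l, :]
                if k == l:
                    np.testing.assert_allclose(
                        block,
                        [[p.w_same, p.w_diff], [p.w_diff, p.w_same]],
                    )
                else:
                    np.testing.assert_array_equal(block, 0.0)

    def test_full_coupling_is_uniform(self):
        p = ModelParams(n_modules=4, ic=1.0)
        w = build_coupling(p)
        # same weight to every module pair, independently of the module
        np.testing.assert_allclose(w[0, 0, 0, 0], p.w_same / 4)
        np.testing.assert_allclose(w[2, 0, 3, 0], p.w_same / 4)
        np.testing.assert_allclose(w[1, 0, 2, 1], p.w_diff / 4)
        assert np.ptp(w[:, 0, :, 0]) == 0.0

    @pytest.mark.parametrize("ic", [0.0, 0.17, 0.5, 0.99, 1.0])
    def test_row_sum_conserved_for_all_ic(self, ic):
        p = ModelParams(n_modules=7, ic=ic)
        w = build_coupling(p)
        # summed drive from population type i to (l, j) is ic-independent
        sums = w.sum(axis=0)  # (2, N, 2): sum over source modules k
        np.testing.assert_allclose(sums[0, :, 0], p.w_same, rtol=1e-12)
        np.testing.assert_allclose(sums[0, :, 1], p.w_diff, rtol=1e-12)
        np.testing.assert_allclose(sums[1, :, 1], p.w_same, rtol=1e-12)

    def test_structured_form_matches_tensor_contraction(self, rng):
        p = ModelParams(n_modules=6, ic=0.37)
        w = build_coupling(p)
        s = rng.uniform(0, 1, size=(6, 2))
        direct = np.einsum("kilj,ki->lj", w, s)
        np.testing.assert_allclose(recurrent_current(s, p), direct, rtol=1e-12)


class TestOuStep:
    def test_noiseless_decay_factor(self, rng):
        p = ModelParams(ou_var=0.0)
        eta = np.full((3, 2), 0.5)
        out = ou_step(eta, p, dt=0.005, rng=rng)
        np.testing.assert_allclose(out, 0.5 * np.exp(-0.005 / p.ou_tau))

    def test_stationary_variance_recovered(self, rng):
        # oracle: O-U stationary variance = ou_var
        p = ModelParams()
        n_chains, n_steps = 2000, 500
        eta = rng.normal(0.0, np.sqrt(p.ou_var), size=(n_chains, 2))
        samples = []
        for _ in range(n_steps):
            eta = ou_step(eta, p, p.dt, rng)
            samples.append(eta.copy())
        var = np.var(np.asarray(samples)[100:])
        assert var == pytest.approx(p.ou_var, rel=0.02)

    def test_autocorrelation_time(self, rng):
        # oracle: corr(eta_t, eta_{t+tau}) = exp(-1) at lag tau
        p = ModelParams()
        lag_steps = int(round(p.ou_tau / p.dt))
        n_chains, n_steps = 1000, 400
        eta = rng.normal(0.0, np.sqrt(p.ou_var), size=(n_chains, 1))
        hist = np.empty((n_steps, n_chains))
        for k in range(n_steps):
            eta = ou_step(eta, p, p.dt, rng)
            hist[k] = eta[:, 0]
        x = hist[: n_steps - lag_steps].ravel()
        y = hist[lag_steps:].ravel()
        corr = np.corrcoef(x, y)[0, 1]
        assert corr == pytest.approx(np.exp(-1.0), abs=0.02)

    def test_dt_must_be_positive(self, rng, params):
        with pytest.raises(ValueError):
            ou_step(np.zeros((2, 2)), params, dt=0.0, rng=rng)


class TestStep:
    def test_zero_input_zero_gating_stays_near_zero(self):
        # with no background current phi(0) is ~1e-6 Hz: s must stay ~0
        p = ModelParams(n_modules=3, i0=0.0, ou_var=0.0)
        w = build_coupling(p)
        state = NetworkState(
            s=np.zeros((3, 2)), r=np.zeros((3, 2)), eta=np.zeros((3, 2))
        )
        rng = np.random.default_rng(0)
        for _ in range(200):
            state = step(state, w, np.zeros((3, 2)), p, rng)
        assert np.all(state.s < 1e-5)

    def test_gating_relaxes_to_closed_form_fixed_point(self):
        # hold the rate constant by decoupling (w=0, noiseless, fixed i0);
        # oracle: s* = gamma * r * tau / (1 + gamma * r * tau)
        p = ModelParams(n_modules=1, w_same=0.0, w_diff=0.0, i0=0.5, ou_var=0.0)
        r_const = transfer_rate(0.5, p)
        expected = p.gamma * r_const * p.tau_nmda / (1 + p.gamma * r_const * p.tau_nmda)
        w = build_coupling(p)
        state = initial_state(p)
        rng = np.random.default_rng(0)
        for _ in range(3000):  # 1.5 s >> effective relaxation time
            state = step(state, w, np.zeros((1, 2)), p, rng)
        np.testing.assert_allclose(state.s, expected, rtol=1e-4)

    def test_gating_bounded_under_strong_input(self, rng):
        p = ModelParams(n_modules=4)
        w = build_coupling(p)
        state = initial_state(p)
        i_ext = np.full((4, 2), 1.0)  # unphysically strong drive
        for _ in range(500):
            state = step(state, w, i_ext, p, rng)
            assert np.all((state.s >= 0.0) & (state.s <= 1.0))


class TestSimulateTrial:
    def test_identical_seed_identical_result(self, small_params, transform, rng):
        stim = generate_flicker(60.0, 50.0, 5.0, 40.0, 2.0, 1, rng)
        out = []
        for _ in range(2):
            trace, res = simulate_trial(
                small_params, stim, transform, np.random.default_rng(7), max_t=2.0
            )
            out.append((trace, res))
        (t1, r1), (t2, r2) = out
        np.testing.assert_array_equal(t1.rates, t2.rates)
        assert r1.choice == r2.choice
        assert r1.rt == r2.rt
        assert r1.sigma_dv == r2.sigma_dv
        assert [v.vote_time for v in r1.votes] == [v.vote_time for v in r2.votes]

    def test_online_readout_matches_offline_trace_analysis(
        self, small_params, transform, rng
    ):
        # the engine's latched votes and majority decision must agree with
        # re-running the readout on the recorded trace
        stim = generate_flicker(62.0, 50.0, 5.0, 40.0, 2.5, 1, rng)
        trace, res = simulate_trial(
            small_params, stim, transform, np.random.default_rng(3), max_t=2.5
        )
        assert res.choice is not None
        votes = detect_votes(trace, small_params.lambda_thr)
        votes_by_module = {v.module: v for v in votes}
        # the engine stops tracking after the decision: every engine vote
        # must match the trace scan up to the decision time
        for v in res.votes:
            assert votes_by_module[v.module].option == v.option
            assert votes_by_module[v.module].vote_time == pytest.approx(v.vote_time)
        decision = global_decision(votes, small_params.n_modules)
        assert decision is not None
        choice, t = decision
        assert choice == res.choice
        assert t == pytest.approx(res.rt + stim.onset)

    def test_symmetric_stimulus_is_unbiased(self, transform):
        # zero discriminability: P(choose A) must be 0.5 within binomial CI
        from scipy import stats

        p = ModelParams(n_modules=9)
        rng = np.random.default_rng(11)
        n = 400
        from consensusconf.stimulus import generate_flicker_batch

        lum = generate_flicker_batch(n, 50.0, 50.0, 5.0, 40.0, 3.0, 1, rng)[:, :, :, 0]
        res = simulate_trials(p, transform, lum, 40.0, rng, onset=0.2, max_t=3.0)
        dec = res.decided
        k = int((res.choice[dec] == 0).sum())
        lo, hi = stats.binom.interval(0.99, int(dec.sum()), 0.5)
        assert lo <= k <= hi

    def test_batch_engine_matches_reference_step_loop(self, transform):
        # float64 batch of one trial vs the einsum-based reference stepper
        p = ModelParams(n_modules=5, ic=0.4, seed=0)
        rng = np.random.default_rng(17)
        stim = generate_flicker(58.0, 50.0, 5.0, 40.0, 0.4, 1, rng)
        res = simulate_trials(
            p,
            transform,
            stim.patch_luminance()[None],
            40.0,
            np.random.default_rng(5),
            onset=0.2,
            max_t=0.4,
            decide_at_majority=False,
            record=True,
            record_s=True,
            dtype=np.float64,
        )
        trace = res.extras["trace"]
        w = build_coupling(p)
        state = initial_state(p)
        rng_ref = np.random.default_rng(5)
        from consensusconf.stimulus import luminance_to_current

        i_frames = luminance_to_current(stim.patch_luminance(), transform)
        n_steps = trace.s_history.shape[0]
        for k in range(n_steps):
            t_now = k * p.dt
            if t_now >= 0.2 - 1e-12:
                frame = min(int((t_now - 0.2) / 0.04 + 1e-9), stim.n_frames - 1)
                i_ext = np.tile(i_frames[frame], (5, 1))
            else:
                i_ext = np.zeros((5, 2))
            state = step(state, w, i_ext, p, rng_ref)
            np.testing.assert_allclose(
                trace.s_history[k], state.s, rtol=0, atol=1e-9
            )

    def test_high_discriminability_is_nearly_always_correct(self, transform):
        from consensusconf.stimulus import generate_flicker_batch

        p = ModelParams(n_modules=9)
        rng = np.random.default_rng(2)
        lum = generate_flicker_batch(100, 70.0, 50.0, 5.0, 40.0, 2.0, 1, rng)[
            :, :, :, 0
        ]
        res = simulate_trials(p, transform, lum, 40.0, rng, onset=0.2, max_t=2.0)
        dec = res.decided
        assert np.mean(res.choice[dec] == 0) > 0.9

    def test_early_flag_set_for_pre_onset_decisions(self, transform):
        # an absurdly low vote threshold forces immediate votes
        p = ModelParams(n_modules=3, lambda_thr=0.5, readout_tau=0.0)
        rng = np.random.default_rng(0)
        stim = generate_flicker(55.0, 50.0, 0.0, 40.0, 1.0, 1, rng, onset=0.5)
        _, res = simulate_trial(p, stim, transform, rng, max_t=1.0)
        assert res.early
        assert res.rt < 0

    def test_dispersion_grows_with_readout_time_early_in_trial(self, transform):
        # forced readouts at increasing pre-commitment times: the
        # inter-module dispersion of an option's rates grows with time
        from consensusconf.stimulus import generate_flicker_batch

        p = ModelParams(n_modules=50)
        sigmas = []
        for dur in (0.15, 0.25, 0.35):
            rng = np.random.default_rng(23)
            lum = generate_flicker_batch(40, 55.0, 50.0, 5.0, 40.0, max(dur, 0.04), 1, rng)[
                :, :, :, 0
            ]
            res = simulate_trials(
                p,
                transform,
                lum,
                40.0,
                rng,
                onset=0.2,
                max_t=dur,
                forced_at=dur,
                decide_at_majority=False,
            )
            sigmas.append(float(np.nanmean(res.sigma_dv)))
        assert sigmas[0] < sigmas[1] < sigmas[2]
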