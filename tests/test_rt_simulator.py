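"""Agent-based run-and-tumble simulator: microscopic statistics and transport."""

import math

import numpy as np
import pytest

from chemorace.rt_simulator import (
    AgentState,
    Attractant,
    ChannelGeometry,
    Environment,
    RunTimeModulation,
    SensingModel,
    SimConfig,
    _sample_cos_scatter,
    measure_drift_velocity,
    simulate_race,
    simulate_tracks,
    step,
    tumble_rate,
    validate_against_theory,
)
from chemorace.theory_core import MotilityParams, ResponseKernel


def _null_sensing():
    return SensingModel(sensors=(("attr", ResponseKernel(0.0, 1.0, 0.0)),))


def _uniform_env(c=0.0):
    return Environment((Attractant.uniform("attr", c),))


class TestEnvironment:
    def test_linear_profile(self):
        a = Attractant.linear_channel("asp", 0.0, 1000.0, 4000.0)
        assert a.gradient == pytest.approx(0.25)
        assert a.concentration(2000.0) == pytest.approx(500.0)
        assert a.concentration(-100.0) == 0.0  # clipped at zero

    def test_background_adds(self):
        a = Attractant("ser", 0.0, 0.0, background=30.0)
        assert a.concentration(1234.0) == 30.0

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            Environment((Attractant.uniform("x", 1), Attractant.uniform("x", 2)))


class TestRunTimeModulation:
    def test_identity_without_driver(self):
        assert RunTimeModulation().m({"asp": np.array([5.0])}) == 1.0

    def test_anchors_reproduced_exactly(self):
        mod = RunTimeModulation("ser", ((1.0, 1.0), (3000.0, 2.1)))
        m = mod.m({"ser": np.array([1.0, 3000.0])})
        assert m[0] == pytest.approx(1.0)
        assert m[1] == pytest.approx(2.1)

    def test_log_linear_between_anchors(self):
        mod = RunTimeModulation("ser", ((1.0, 1.0), (100.0, 3.0)))
        # geometric midpoint of the anchors: arithmetic midpoint of the folds
        assert mod.m({"ser": np.array([10.0])})[0] == pytest.approx(2.0)

    def test_constant_extrapolation(self):
        mod = RunTimeModulation("ser", ((1.0, 1.2), (100.0, 2.0)))
        assert mod.m({"ser": np.array([1e-6])})[0] == pytest.approx(1.2)
        assert mod.m({"ser": np.array([1e6])})[0] == pytest.approx(2.0)

    def test_invalid_anchors(self):
        with pytest.raises(ValueError):
            RunTimeModulation("ser", ((1.0, -2.0),))
        with pytest.raises(ValueError):
            RunTimeModulation("ser", ((10.0, 1.0), (1.0, 2.0)))


class TestTumbleRate:
    def test_baseline_rate(self, motility, rng):
        env = _uniform_env(0.0)
        sens = _null_sensing()
        st = AgentState.fresh(np.zeros((4, 3)), env, sens, np.full(4, 15.0), rng)
        r = tumble_rate(st, env, sens, RunTimeModulation(), motility)
        assert np.allclose(r, 1.0 / motility.tau_r)

    def test_rate_clipped_at_zero(self, motility, rng):
        env = _uniform_env(10.0)
        # strongly non-adapted response saturates the pathway: Q > 1
        sens = SensingModel(sensors=(("attr", ResponseKernel(1.0, 1.0, 0.5)),))
        st = AgentState.fresh(np.zeros((3, 3)), env, sens, np.full(3, 15.0), rng)
        r = tumble_rate(st, env, sens, RunTimeModulation(), motility)
        assert np.all(r == 0.0)

    def test_steady_state_response_is_kernel_integral_times_c(self, motility, rng):
        # at uniform c the filter settles to Q = K0 * A * c
        K0, A, c = 0.4, 0.05, 10.0
        env = _uniform_env(c)
        sens = SensingModel(sensors=(("attr", ResponseKernel(K0, 1.0, A)),))
        st = AgentState.fresh(np.zeros((2, 3)), env, sens, np.full(2, 15.0), rng)
        from chemorace.rt_simulator import _filter_response

        q = _filter_response(st, sens, env.concentrations(st.pos[:, 0]))
        assert np.allclose(q, K0 * A * c, rtol=1e-12)
        # and the rate is reduced accordingly
        r = tumble_rate(st, env, sens, RunTimeModulation(), motility)
        assert np.allclose(r, (1 - K0 * A * c) / motility.tau_r)


class TestStep:
    def test_straight_line_without_noise_or_tumbles(self, rng):
        mot = MotilityParams(u=10.0, tau_r=1e12, D_rot=0.0, mean_cos_phi=0.0)
        env, sens = _uniform_env(), _null_sensing()
        st = AgentState.fresh(np.zeros((5, 3)), env, sens, np.full(5, 10.0), rng)
        d0 = st.dirs.copy()
        for _ in range(100):
            step(st, 0.01, env, sens, RunTimeModulation(), mot, rng)
        assert np.allclose(st.dirs, d0)
        assert np.allclose(np.linalg.norm(st.pos, axis=1), 10.0 * 1.0, rtol=1e-9)

    def test_direction_decorrelation_matches_rotational_diffusivity(self, rng):
        # <d(t).d(0)> = exp(-2 Drot t) without tumbling
        D_rot = 0.1
        mot = MotilityParams(u=15.0, tau_r=1e12, D_rot=D_rot, mean_cos_phi=0.0)
        env, sens = _uniform_env(), _null_sensing()
        n = 4000
        st = AgentState.fresh(np.zeros((n, 3)), env, sens, np.full(n, 15.0), rng)
        d0 = st.dirs.copy()
        dt, T = 0.01, 3.0
        for _ in range(int(T / dt)):
            step(st, dt, env, sens, RunTimeModulation(), mot, rng)
        c = np.sum(st.dirs * d0, axis=1)
        expected = math.exp(-2 * D_rot * T)
        se = c.std(ddof=1) / math.sqrt(n)
        assert abs(c.mean() - expected) < 3 * se

    def test_unit_norm_preserved(self, rng, motility):
        env, sens = _uniform_env(), _null_sensing()
        st = AgentState.fresh(np.zeros((200, 3)), env, sens, np.full(200, 15.0), rng)
        for _ in range(300):
            step(st, 0.02, env, sens, RunTimeModulation(), motility, rng)
        assert np.allclose(np.linalg.norm(st.dirs, axis=1), 1.0, atol=1e-9)

    def test_empirical_scatter_cosine(self, rng):
        # tumble persistence: <cos phi> = 0.3 over 10^4 draws
        c = _sample_cos_scatter(10000, 0.3, rng)
        assert np.all((c >= -1) & (c <= 1))
        assert abs(c.mean() - 0.3) < 3 * c.std(ddof=1) / 100.0
        assert abs(c.mean() - 0.3) < 0.02

    def test_scatter_requires_valid_mean(self, rng):
        with pytest.raises(ValueError):
            _sample_cos_scatter(10, 0.5, rng)


class TestSimulateTracks:
    def test_seeded_determinism(self, motility):
        env, sens = _uniform_env(), _null_sensing()
        cfg = SimConfig(T=5.0, n_agents=20, dt=0.02, seed=77)
        a = simulate_tracks(cfg, env, sens, RunTimeModulation(), motility)
        b = simulate_tracks(cfg, env, sens, RunTimeModulation(), motility)
        assert a.frames.equals(b.frames)

    def test_zero_gradient_mean_displacement(self, motility):
        env, sens = _uniform_env(), _null_sensing()
        cfg = SimConfig(T=40.0, n_agents=600, dt=0.02, seed=3)
        tracks = simulate_tracks(cfg, env, sens, RunTimeModulation(), motility)
        v, se = measure_drift_velocity(tracks)
        assert abs(v) < 3 * se

    def test_msd_matches_persistent_random_walk(self, motility):
        # long-time MSD/(6t) -> u^2/(3 sigma)
        env, sens = _uniform_env(), _null_sensing()
        cfg = SimConfig(T=60.0, n_agents=800, dt=0.02, seed=9)
        tracks = simulate_tracks(cfg, env, sens, RunTimeModulation(), motility)
        last = tracks.frames.groupby("track_id").tail(1)
        r2 = (last.x**2 + last.y**2 + last.z**2).to_numpy()
        D_emp = r2.mean() / (6 * 60.0)
        assert D_emp == pytest.approx(motility.diffusivity, rel=0.10)

    def test_modulated_mean_run_time(self, motility):
        # in homogeneous attractant the exponential run times stretch to tau_r*m
        fold = 2.0
        env = _uniform_env(50.0)
        sens = _null_sensing()
        mod = RunTimeModulation("attr", ((1.0, fold), (100.0, fold)))
        cfg = SimConfig(T=60.0, n_agents=400, dt=0.02, seed=21, frame_dt=60.0)
        # count tumbles via direction changes: run simulation with Drot=0 so
        # every direction change is a tumble
        mot = MotilityParams(motility.u, motility.tau_r, 0.0, motility.mean_cos_phi)
        from chemorace.rt_simulator import AgentState, step as _step

        rng = np.random.default_rng(21)
        st = AgentState.fresh(np.zeros((400, 3)), env, sens, np.full(400, 15.0), rng)
        tumbles = 0
        steps = int(60.0 / 0.02)
        for _ in range(steps):
            before = st.dirs.copy()
            _step(st, 0.02, env, sens, mod, mot, rng)
            tumbles += int(np.sum(np.any(before != st.dirs, axis=1)))
        total_time = 400 * 60.0
        tau_emp = total_time / tumbles
        expected = motility.tau_r * fold
        se = expected / math.sqrt(tumbles)
        assert abs(tau_emp - expected) < 3 * se

    def test_dt_stability_guard(self, motility):
        env, sens = _uniform_env(), _null_sensing()
        cfg = SimConfig(T=1.0, n_agents=2, dt=0.5, seed=0)
        with pytest.raises(ValueError):
            simulate_tracks(cfg, env, sens, RunTimeModulation(), motility)


@pytest.fixture(scope="module")
def short_race():
    from chemorace.synthetic_data import condition_preset

    preset = condition_preset("aspartate")
    cfg = SimConfig(T=600.0, n_agents=0, dt=0.02, seed=13, snapshot_dt=100.0)
    chan = ChannelGeometry()
    return simulate_race(
        cfg, chan, preset.environment, preset.sensing, preset.modulation,
        preset.motility, entry_density=0.5,
    ), chan


class TestSimulateRace:
    def test_counts_conserved(self, short_race):
        snap, _ = short_race
        c = snap.metadata["counts"]
        assert (
            c["injected"]
            == c["absorbed"] + c["returned_to_injection"] + c["in_channel_final"]
        )

    def test_positions_inside_channel(self, short_race):
        snap, chan = short_race
        for pos in snap.positions:
            assert np.all((pos >= 0) & (pos <= chan.L))

    def test_source_off_stays_empty(self, motility):
        env, sens = _uniform_env(), _null_sensing()
        cfg = SimConfig(T=50.0, n_agents=0, dt=0.02, seed=1, snapshot_dt=10.0)
        snap = simulate_race(
            cfg, ChannelGeometry(), env, sens, RunTimeModulation(), motility,
            entry_density=1.0, source_on=False,
        )
        assert all(len(p) == 0 for p in snap.positions)

    def test_seeded_determinism(self):
        from chemorace.synthetic_data import condition_preset

        preset = condition_preset("aspartate")
        cfg = SimConfig(T=120.0, n_agents=0, dt=0.02, seed=99, snapshot_dt=60.0)
        a = simulate_race(cfg, ChannelGeometry(), preset.environment,
                          preset.sensing, preset.modulation, preset.motility,
                          entry_density=0.3)
        b = simulate_race(cfg, ChannelGeometry(), preset.environment,
                          preset.sensing, preset.modulation, preset.motility,
                          entry_density=0.3)
        for pa, pb in zip(a.positions, b.positions):
            assert np.array_equal(pa, pb)


class TestDriftVsTheory:
    def test_zero_gradient_theory(self, motility, adapted_kernel):
        rep = validate_against_theory(
            motility, adapted_kernel, 0.0, n_agents=400, T=40.0, seed=5, c_mid=5.0
        )
        assert rep["v_theory"] == 0.0
        assert abs(rep["v_mc"]) < 3 * rep["se"]

    def test_linearity_in_gradient(self, motility, adapted_kernel):
        # doubling the gradient doubles the drift within Monte-Carlo error
        r1 = validate_against_theory(
            motility, adapted_kernel, 0.004, n_agents=2500, T=250.0, seed=6,
            c_mid=6.0,
        )
        r2 = validate_against_theory(
            motility, adapted_kernel, 0.008, n_agents=2500, T=250.0, seed=7,
            c_mid=9.0,
        )
        se = math.hypot(2 * r1["se"], r2["se"])
        assert abs(2 * r1["v_mc"] - r2["v_mc"]) < 3 * se

    def test_precondition_warning(self, motility):
        rep = validate_against_theory(
            motility, ResponseKernel(5.0, 1.0, 0.5), 0.1, n_agents=50, T=10.0,
            seed=8, c_mid=50.0,
        )
        assert rep["warnings"]
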