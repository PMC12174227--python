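"""Growth-rate arithmetic, integration accuracy, adaptation and extinctions."""

import numpy as np
import pytest

from invasim.config import IntegrationSettings, InvaderConfig
from invasim.dynamics import (SystemState, adaptive_rates, apply_extinctions,
                              integrate, integrate_native, invader_growth_rate,
                              native_growth_rates)
from invasim.invasion_setup import assemble_invaded_system

from conftest import build_community, isolated_invader_config


def make_system(comm, inv_cfg, seed=0, **coef):
    """Assemble then overwrite coefficients with exact hand-picked values."""
    sys_ = assemble_invaded_system(comm, inv_cfg, np.random.default_rng(seed))
    for name, val in coef.items():
        setattr(sys_, name, np.asarray(val, dtype=float))
    sys_.T_mut = float(sys_.b_kl.sum())
    return sys_


def rk4_oracle(rhs, y0, t_end, dt=1e-3):
    """Independent fixed-step classic Runge-Kutta integrator."""
    y = np.asarray(y0, dtype=float).copy()
    n = int(round(t_end / dt))
    t = 0.0
    for _ in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y


class TestGrowthRates:
    def test_logistic_reduction(self):
        comm = build_community([0.8], [0.3], [-0.5], d=0.6, x0=2.0)
        sys_ = make_system(comm, isolated_invader_config())
        st = SystemState(P=np.array([2.0]), M=np.array([1.0]),
                         H=np.array([1.0]), P_k=0.0)
        gP, gM, gH = native_growth_rates(st, sys_)
        assert gP[0] == pytest.approx(0.8 - 0.6 * 2.0)

    def test_plant_herbivore_arithmetic(self):
        # plant per-capita rate = r - d*P - C_ph*H with one herbivore link
        comm = build_community([1.0], [0.3], [-0.5], d=1.0,
                               C_ph=[[0.3]], C_hp=[[0.0]])
        sys_ = make_system(comm, isolated_invader_config())
        st = SystemState(P=np.array([2.0]), M=np.array([0.0]),
                         H=np.array([1.0]), P_k=0.0)
        gP, _, _ = native_growth_rates(st, sys_)
        assert gP[0] == pytest.approx(1.0 - 1.0 * 2.0 - 0.3)

    def test_absent_invader_recovers_native_rates(self, rng):
        comm = build_community([1.0, 0.9], [0.3], [-0.5],
                               A_pp=[[0, 0.2], [0.1, 0]], B_pm=[[0.1], [0.2]],
                               B_mp=[[0.1, 0.3]], C_ph=[[0.2], [0.1]],
                               C_hp=[[0.1, 0.2]])
        sys_ = make_system(comm, InvaderConfig(F1=1.0, F2=1.0, p_herb=1.0))
        st = SystemState(P=np.array([1.0, 2.0]), M=np.array([1.5]),
                         H=np.array([0.5]), P_k=0.0)
        gP, gM, gH = native_growth_rates(st, sys_)
        x = np.array([1.0, 2.0, 1.5, 0.5])
        expect = comm.r - comm.d * x + comm.interaction_matrix() @ x
        np.testing.assert_allclose(np.concatenate([gP, gM, gH]), expect)

    def test_invader_rate_arithmetic(self):
        # r_k=1, d_k=1, single mutualist M=2 with b=0.5, P_k=1 -> rate 1.0
        comm = build_community([1.0], [0.3], [-0.5])
        sys_ = make_system(comm, InvaderConfig(F1=1.0),
                           b_kl=[0.5], a_ki=[0.0], c_kh=[0.0])
        sys_.r_k, sys_.d_k = 1.0, 1.0
        st = SystemState(P=np.array([0.0]), M=np.array([2.0]),
                         H=np.array([0.0]), P_k=1.0)
        assert invader_growth_rate(st, sys_) == pytest.approx(1.0 - 1.0 + 0.5 * 2)

    def test_isolated_invader_is_logistic(self):
        comm = build_community([1.0], [0.3], [-0.5])
        sys_ = make_system(comm, isolated_invader_config())
        sys_.r_k, sys_.d_k = 1.2, 0.4
        st = SystemState(P=np.array([1.0]), M=np.array([1.0]),
                         H=np.array([1.0]), P_k=3.0)
        assert invader_growth_rate(st, sys_) == pytest.approx(1.2 - 0.4 * 3.0)

    def test_herbivore_link_strictly_decreases_rate(self):
        comm = build_community([1.0], [0.3], [-0.5])
        sys_ = make_system(comm, InvaderConfig(p_herb=1.0), c_kh=[0.2])
        st = SystemState(P=np.array([1.0]), M=np.array([1.0]),
                         H=np.array([0.7]), P_k=1.0)
        base = make_system(comm, isolated_invader_config())
        base.r_k, base.d_k = sys_.r_k, sys_.d_k
        assert invader_growth_rate(st, sys_) < invader_growth_rate(st, base)

    def test_nonfinite_state_rejected(self):
        comm = build_community([1.0], [0.3], [-0.5])
        sys_ = make_system(comm, isolated_invader_config())
        st = SystemState(P=np.array([np.inf]), M=np.array([1.0]),
                         H=np.array([1.0]), P_k=0.0)
        with pytest.raises(ValueError, match="non-finite"):
            native_growth_rates(st, sys_)


class TestAdaptiveRates:
    def test_zero_adaptation_rate(self):
        d = adaptive_rates(np.array([0.3, 0.7]), np.array([5.0, 1.0]), 0.0)
        np.testing.assert_array_equal(d, 0.0)

    def test_replicator_hand_check(self):
        # alpha=(0.5,0.5), M=(2,1), G=0.5, T=1: d_alpha = (+0.125, -0.125)
        d = adaptive_rates(np.array([0.5, 0.5]), np.array([2.0, 1.0]), 0.5)
        np.testing.assert_allclose(d, [0.125, -0.125])
        assert d.sum() == pytest.approx(0.0, abs=1e-15)

    def test_equal_densities_fixed_point(self):
        d = adaptive_rates(np.array([0.2, 0.8]), np.array([3.0, 3.0]), 0.5)
        np.testing.assert_allclose(d, 0.0, atol=1e-15)

    def test_off_link_entries_stay_zero(self):
        d = adaptive_rates(np.array([0.5, 0.0, 0.5]), np.array([2.0, 9.0, 1.0]), 0.5)
        assert d[1] == 0.0

    def test_share_of_densest_partner_grows(self):
        # constant M: integrate the replicator alone; the share of the
        # mutualist with maximal density must be non-decreasing
        M = np.array([2.0, 1.0, 0.5])
        alpha = np.array([0.1, 0.6, 0.3])
        T = alpha.sum()
        shares = [alpha[0] / T]
        dt = 0.01
        for _ in range(2000):
            alpha = alpha + dt * adaptive_rates(alpha, M, 0.5, total=T)
            shares.append(alpha[0] / alpha.sum())
        assert np.all(np.diff(shares) >= -1e-12)
        assert shares[-1] > 0.95  # replicator concentrates on the best partner


class TestIntegrate:
    def test_single_species_logistic_closed_form(self):
        comm = build_community([1.0], [0.5], [-0.5], x0=0.1, C_hp=[[2.0]])
        comm.r_P[0], comm.d_P[0] = 1.0, 0.5
        final = integrate_native(comm)
        assert final[0] == pytest.approx(2.0, abs=1e-6)

    def test_two_competitor_equilibrium(self):
        comm = build_community([1.0, 1.0], [0.5], [-0.5], x0=0.5,
                               A_pp=[[0, 0.5], [0.5, 0]], C_hp=[[1.0, 1.0]])
        final = integrate_native(comm)
        np.testing.assert_allclose(final[:2], 2 / 3, atol=1e-4)

    def test_adaptive_conservation_at_all_sampled_times(self):
        comm = build_community([1.0, 0.8], [0.3, -0.1], [-0.5], x0=1.0,
                               B_mp=[[0.2, 0.1], [0.1, 0.2]],
                               B_pm=[[0.1, 0.1], [0.1, 0.1]], C_hp=[[0.5, 0.5]])
        sys_ = make_system(comm, InvaderConfig(F1=1.0, adaptive=True),
                           b_kl=[0.3, 0.5])
        settings = IntegrationSettings(n_trajectory_points=50)
        res = integrate(sys_, settings)
        assert sys_.T_mut == pytest.approx(0.8)
        S = 5
        sums = res.trajectory[:, S + 1:].sum(axis=1)
        assert np.all(np.abs(sums - 0.8) < 1e-6)

    def test_g_zero_matches_non_adaptive_path(self):
        comm = build_community([1.0, 0.8], [0.3, -0.1], [-0.5], x0=1.0,
                               B_mp=[[0.2, 0.1], [0.1, 0.2]],
                               B_pm=[[0.1, 0.1], [0.1, 0.1]], C_hp=[[0.5, 0.5]])
        adapt = make_system(comm, InvaderConfig(F1=1.0, adaptive=True, G_k=0.0),
                            b_kl=[0.3, 0.5])
        fixed = make_system(comm, InvaderConfig(F1=1.0, adaptive=False),
                            b_kl=[0.3, 0.5])
        fixed.r_k, fixed.d_k, fixed.x0_k = adapt.r_k, adapt.d_k, adapt.x0_k
        fixed.b_lk = adapt.b_lk.copy()
        ra = integrate(adapt)
        rf = integrate(fixed)
        for attr in ("P", "M", "H"):
            np.testing.assert_allclose(getattr(ra.final, attr),
                                       getattr(rf.final, attr),
                                       rtol=1e-5, atol=1e-7)
        assert ra.final.P_k == pytest.approx(rf.final.P_k, rel=1e-5, abs=1e-7)

    def test_matches_rk4_oracle_on_small_systems(self):
        # three-species native chain: plant + obligate mutualist + herbivore
        comm = build_community([1.0], [-0.2], [-0.4], x0=1.5,
                               B_pm=[[0.3]], B_mp=[[0.6]],
                               C_ph=[[0.2]], C_hp=[[0.8]])
        t_end = 50.0
        final = integrate_native(comm, IntegrationSettings(t_end=t_end))

        W = comm.interaction_matrix()
        r, d = comm.r, comm.d
        oracle = rk4_oracle(lambda t, x: x * (r - d * x + W @ x),
                            comm.x0, t_end)
        np.testing.assert_allclose(final, oracle, rtol=1e-4)

    def test_invaded_system_matches_rk4_oracle(self):
        comm = build_community([1.0], [0.3], [-0.6], x0=1.0,
                               B_pm=[[0.2]], B_mp=[[0.3]],
                               C_ph=[[0.1]], C_hp=[[0.9]])
        sys_ = make_system(comm, InvaderConfig(F1=1.0, F2=1.0, p_herb=1.0),
                           b_kl=[0.4], b_lk=[0.2], a_ki=[0.3], a_ik=[0.5],
                           c_kh=[0.1], c_hk=[0.2])
        sys_.r_k, sys_.d_k, sys_.x0_k = 1.0, 1.0, 0.5
        t_end = 50.0
        res = integrate(sys_, IntegrationSettings(t_end=t_end))

        W = comm.interaction_matrix()
        r, d = comm.r, comm.d

        def rhs(t, y):
            x, Pk = y[:3], y[3]
            g = r - d * x + W @ x
            g[0] -= sys_.a_ik[0] * Pk
            g[1] += sys_.b_lk[0] * Pk
            g[2] += sys_.c_hk[0] * Pk
            gk = (sys_.r_k - sys_.d_k * Pk - sys_.a_ki @ x[:1]
                  + sys_.b_kl @ x[1:2] - sys_.c_kh @ x[2:3])
            return np.concatenate([x * g, [Pk * gk]])

        oracle = rk4_oracle(rhs, np.concatenate([comm.x0, [0.5]]), t_end)
        got = np.concatenate([res.final.P, res.final.M, res.final.H,
                              [res.final.P_k]])
        np.testing.assert_allclose(got, oracle, rtol=1e-4)

    def test_densities_never_negative_beyond_tolerance(self):
        comm = build_community([1.0], [0.4], [-0.9], x0=5.0)  # herbivore dies
        settings = IntegrationSettings(n_trajectory_points=200)
        sys_ = make_system(comm, isolated_invader_config())
        res = integrate(sys_, settings)
        assert res.trajectory[:, :4].min() > -settings.abs_tol
        assert res.final.H[0] >= 0.0


class TestExports:
    def test_trajectory_long_format_and_final_json(self):
        import json

        from invasim.dynamics import final_state_to_json, trajectory_to_frame

        comm = build_community([1.0, 0.8], [0.3, -0.1], [-0.5], x0=1.0,
                               B_mp=[[0.2, 0.1], [0.1, 0.2]],
                               B_pm=[[0.1, 0.1], [0.1, 0.1]], C_hp=[[0.5, 0.5]])
        sys_ = make_system(comm, InvaderConfig(F1=1.0, adaptive=True),
                           b_kl=[0.3, 0.5])
        res = integrate(sys_, IntegrationSettings(n_trajectory_points=10))
        df = trajectory_to_frame(res, sys_)
        assert list(df.columns) == ["time", "species_id", "guild", "density"]
        assert len(df) == 10 * 6  # 5 natives + invader at 10 sample times
        assert set(df["guild"]) == {"plant", "mutualist", "herbivore", "invader"}

        doc = json.loads(final_state_to_json(res.final))
        assert doc["alpha_total"] == pytest.approx(0.8, abs=1e-6)
        assert len(doc["survivors"]["plants"]) == 2
        assert isinstance(doc["invader_alive"], bool)

    def test_trajectory_requires_sampling(self):
        from invasim.dynamics import trajectory_to_frame

        comm = build_community([1.0], [0.3], [-0.5])
        sys_ = make_system(comm, isolated_invader_config())
        res = integrate(sys_)
        with pytest.raises(ValueError, match="n_trajectory_points"):
            trajectory_to_frame(res, sys_)


class TestApplyExtinctions:
    def test_all_alive(self):
        st = SystemState(P=np.ones(2), M=np.ones(2), H=np.ones(1), P_k=1.0)
        rep = apply_extinctions(st)
        assert rep.plants.all() and rep.mutualists.all() and rep.herbivores.all()
        assert rep.invader_alive

    def test_threshold_is_strict(self):
        st = SystemState(P=np.ones(1), M=np.ones(1), H=np.ones(1), P_k=1e-7)
        assert apply_extinctions(st, threshold=1e-6).invader_alive is False
        st.P_k = 1e-6
        assert apply_extinctions(st, threshold=1e-6).invader_alive is False

    def test_mixed_survivors(self):
        st = SystemState(P=np.array([1.0, 1e-8, 0.5]), M=np.ones(1),
                         H=np.ones(1), P_k=0.0)
        np.testing.assert_array_equal(apply_extinctions(st).plants,
                                      [True, False, True])
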