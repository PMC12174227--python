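"""Coupled population dynamics of the invaded multilayer community.

Native plants, mutualists and herbivores follow generalized Lotka-Volterra
equations with uniform intrinsic rates, separate intraspecific
density-dependence and half-normal interspecific coefficients; the invasive
plant adds competition on linked native plants, benefits linked mutualists and
feeds linked herbivores.  With adaptation switched on, the invader reallocates
its mutualistic benefit vector alpha by replicator dynamics

    d(alpha_l)/dt = G_k * alpha_l * (M_l - sum_l' (alpha_l'/T) M_l'),

the standard adaptive-foraging form in which a link's share grows when its
partner's density beats the share-weighted mean.  The total strength
sum(alpha) = T is conserved (it is an attracting invariant of this form), so
adaptation only redistributes, never creates, mutualistic benefit.

Integration uses an adaptive Dormand-Prince Runge-Kutta 4(5) scheme
(``scipy.integrate.solve_ivp`` method ``RK45``) to a fixed horizon; the
extinction threshold is applied to the final state only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .community_gen import NativeCommunity
from .config import IntegrationSettings
from .invasion_setup import InvadedSystem

__all__ = [
    "SystemState", "ExtinctionReport", "IntegrationError", "IntegrationResult",
    "native_growth_rates", "invader_growth_rate", "adaptive_rates",
    "integrate", "integrate_native", "apply_extinctions",
    "trajectory_to_frame", "final_state_to_json",
]


class IntegrationError(RuntimeError):
    """Solver failure or state blow-up; carries the divergence time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t={t_fail:g})")
        self.t_fail = t_fail


@dataclass
class SystemState:
    """Densities of the three native guilds, the invader, and (when adaptive)
    the invader's current mutualistic strength vector."""

    P: np.ndarray
    M: np.ndarray
    H: np.ndarray
    P_k: float
    alpha: np.ndarray | None = None

    def check_finite(self) -> None:
        vals = np.concatenate([self.P, self.M, self.H, [self.P_k]])
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite densities in system state")


@dataclass
class ExtinctionReport:
    """Survivor masks per guild and the invasion-success flag."""

    plants: np.ndarray
    mutualists: np.ndarray
    herbivores: np.ndarray
    invader_alive: bool


def native_growth_rates(state: SystemState, system: InvadedSystem,
                        _W: np.ndarray | None = None):
    """Per-capita growth rates (the bracketed terms) of all native species.

    Includes the invader contributions: extra competition on linked plants,
    extra benefit to linked mutualists (always the fixed coefficient — only
    the invader-side strength adapts) and extra food for linked herbivores.
    """
    state.check_finite()
    comm = system.comm
    sp, sm = comm.sizes.S_P, comm.sizes.S_M
    W = comm.interaction_matrix() if _W is None else _W
    x = np.concatenate([state.P, state.M, state.H])
    g = comm.r - comm.d * x + W @ x
    g[:sp] -= system.a_ik * state.P_k
    g[sp:sp + sm] += system.b_lk * state.P_k
    g[sp + sm:] += system.c_hk * state.P_k
    return g[:sp], g[sp:sp + sm], g[sp + sm:]


def invader_growth_rate(state: SystemState, system: InvadedSystem) -> float:
    """Per-capita growth rate of the invader.

    The mutualism term uses the current adaptive strength vector when one is
    present in the state, otherwise the fixed assembly coefficients.
    """
    state.check_finite()
    b = system.b_kl if state.alpha is None else state.alpha
    return float(system.r_k - system.d_k * state.P_k
                 - system.a_ki @ state.P + b @ state.M - system.c_kh @ state.H)


def adaptive_rates(alpha: np.ndarray, M: np.ndarray, G_k: float,
                   total: float | None = None) -> np.ndarray:
    """Replicator derivative of the invader's mutualistic strengths.

    The payoff of link l is the partner density M_l (the sensitivity of the
    invader's per-capita growth to alpha_l); the weighted mean uses the
    strength shares alpha/total.  Off-link (zero) entries stay at zero.
    """
    alpha = np.asarray(alpha, dtype=float)
    T = alpha.sum() if total is None else total
    if T <= 0 or G_k == 0:
        return np.zeros_like(alpha)
    mean_payoff = (alpha @ M) / T
    return G_k * alpha * (M - mean_payoff)


@dataclass
class IntegrationResult:
    final: SystemState
    t: np.ndarray                 # sampled times (at least the endpoint)
    trajectory: np.ndarray | None  # state samples, shape (len(t), n_state)
    n_state: int


def _native_rhs(comm: NativeCommunity):
    W = comm.interaction_matrix()
    r, d = comm.r, comm.d

    def rhs(t, x):
        return x * (r - d * x + W @ x)

    return rhs


def _check_clamp(y: np.ndarray, abs_tol: float, t_fail: float) -> np.ndarray:
    """Clamp small numerical negatives to zero; fail on real ones."""
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite state", t_fail)
    if np.min(y) < -abs_tol:
        raise IntegrationError(f"negative density {np.min(y):.3e}", t_fail)
    return np.clip(y, 0.0, None)


def integrate_native(comm: NativeCommunity,
                     settings: IntegrationSettings | None = None) -> np.ndarray:
    """Integrate the native-only system; returns the final stacked densities."""
    settings = settings or IntegrationSettings()
    settings.validate()
    sol = solve_ivp(_native_rhs(comm), (0.0, settings.t_end), comm.x0,
                    method="RK45", rtol=settings.rel_tol, atol=settings.abs_tol)
    if not sol.success:
        raise IntegrationError(f"native integration failed: {sol.message}",
                               sol.t[-1] if len(sol.t) else 0.0)
    return _check_clamp(sol.y[:, -1], settings.abs_tol, settings.t_end)


def integrate(system: InvadedSystem,
              settings: IntegrationSettings | None = None) -> IntegrationResult:
    """Integrate the invaded system to the horizon.

    The state is the stacked native densities, the invader density and — when
    the invader is adaptive and has at least one mutualist link — the adaptive
    strength vector, initialised at the assembly coefficients so that the
    conserved total equals the assembled total strength.
    """
    settings = settings or IntegrationSettings()
    settings.validate()
    comm = system.comm
    sp, sm, sh = comm.sizes.S_P, comm.sizes.S_M, comm.sizes.S_H
    S = sp + sm + sh
    adaptive = system.inv.adaptive and system.T_mut > 0

    W = comm.interaction_matrix()
    r, d = comm.r, comm.d
    a_ik, b_lk, c_hk = system.a_ik, system.b_lk, system.c_hk
    a_ki, b_kl, c_kh = system.a_ki, system.b_kl, system.c_kh
    r_k, d_k, G_k, T = system.r_k, system.d_k, system.inv.G_k, system.T_mut

    def rhs(t, y):
        x = y[:S]
        Pk = y[S]
        g = r - d * x + W @ x
        g[:sp] -= a_ik * Pk
        g[sp:sp + sm] += b_lk * Pk
        g[sp + sm:] += c_hk * Pk
        M = x[sp:sp + sm]
        if adaptive:
            alpha = y[S + 1:]
            mut = alpha @ M
            dalpha = G_k * alpha * (M - mut / T)
        else:
            mut = b_kl @ M
        gk = r_k - d_k * Pk - a_ki @ x[:sp] + mut - c_kh @ x[sp + sm:]
        out = np.empty_like(y)
        out[:S] = x * g
        out[S] = Pk * gk
        if adaptive:
            out[S + 1:] = dalpha
        return out

    y0 = np.concatenate([comm.x0, [system.x0_k]] + ([b_kl] if adaptive else []))
    t_eval = (np.linspace(0.0, settings.t_end, settings.n_trajectory_points)
              if settings.n_trajectory_points > 1 else None)
    sol = solve_ivp(rhs, (0.0, settings.t_end), y0, method="RK45",
                    rtol=settings.rel_tol, atol=settings.abs_tol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}",
                               sol.t[-1] if len(sol.t) else 0.0)

    yf = sol.y[:, -1].copy()
    yf[:S + 1] = _check_clamp(yf[:S + 1], settings.abs_tol, settings.t_end)
    final = SystemState(
        P=yf[:sp], M=yf[sp:sp + sm], H=yf[sp + sm:S], P_k=float(yf[S]),
        alpha=np.clip(yf[S + 1:], 0.0, None) if adaptive else None)
    traj = sol.y.T if t_eval is not None else None
    return IntegrationResult(final=final, t=sol.t, trajectory=traj,
                             n_state=len(y0))


def trajectory_to_frame(result: IntegrationResult, system: InvadedSystem):
    """Long-format trajectory table: time, species_id, guild, density.

    Requires a result integrated with ``n_trajectory_points > 1``.  Adaptive
    strength components are excluded (densities only).
    """
    import pandas as pd

    if result.trajectory is None:
        raise ValueError("no sampled trajectory; set n_trajectory_points")
    sp, sm, sh = (system.comm.sizes.S_P, system.comm.sizes.S_M,
                  system.comm.sizes.S_H)
    guilds = (["plant"] * sp + ["mutualist"] * sm + ["herbivore"] * sh
              + ["invader"])
    ids = ([f"P{i}" for i in range(sp)] + [f"M{i}" for i in range(sm)]
           + [f"H{i}" for i in range(sh)] + ["K"])
    n_dens = sp + sm + sh + 1
    rows = []
    for j, t in enumerate(result.t):
        for s in range(n_dens):
            rows.append((t, ids[s], guilds[s], result.trajectory[j, s]))
    return pd.DataFrame(rows, columns=["time", "species_id", "guild", "density"])


def final_state_to_json(final: SystemState, threshold: float = 1e-6) -> str:
    """Final-state JSON: densities, survivor masks, and the adaptive strength
    vector with its conserved total (null when not adaptive)."""
    import json

    report = apply_extinctions(final, threshold)
    doc = {
        "P": final.P.tolist(), "M": final.M.tolist(), "H": final.H.tolist(),
        "P_k": final.P_k,
        "alpha": None if final.alpha is None else final.alpha.tolist(),
        "alpha_total": None if final.alpha is None else float(final.alpha.sum()),
        "survivors": {"plants": report.plants.tolist(),
                      "mutualists": report.mutualists.tolist(),
                      "herbivores": report.herbivores.tolist()},
        "invader_alive": report.invader_alive,
    }
    return json.dumps(doc)


def apply_extinctions(final: SystemState, threshold: float = 1e-6
                      ) -> ExtinctionReport:
    """Threshold the final state: survivors are strictly above ``threshold``,
    and the invasion succeeds iff the invader itself is."""
    final.check_finite()
    return ExtinctionReport(
        plants=final.P > threshold,
        mutualists=final.M > threshold,
        herbivores=final.H > threshold,
        invader_alive=bool(final.P_k > threshold),
    )
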