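"""Phase-switched receding-horizon control on the Koopman linear predictor.

At each sampling instant the controller measures the ankle state, detects the
gait phase from the GRF, and minimizes over the active muscle's current
sequence the finite-horizon quadratic cost

    J = sum_{j=1..N} e_j' Q e_j + R u_{j-1}^2  +  e_N' S_sigma e_N

subject to the switched reduced predictor e+ = A_ee e + A_ed x_d + B_e u,
hard box bounds on the current, and soft (quadratic-penalty) angle-band and
terminal-set constraints.  The terminal weight S_sigma per phase solves the
discrete algebraic Riccati equation of that phase's error subsystem; the
associated LQR gain is the stabilizing terminal policy.

Q and R are specified on the degree scale (so degree-sized tracking errors
dominate mA-sized inputs) and converted to the internal radian units.  The
condensed input-only problem — a strictly convex piecewise-quadratic box
program of at most horizon_steps variables — is solved by projected Newton
(gradient projection with second-order scaling and active-set
identification); dense least-squares and exhaustive-grid oracles back it in
the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg

from . import plant as _plant
from .edmd import KoopmanModel, _normalize_phase
from .plant import (
    DEFAULT_GRF_TOLERANCE,
    DEG,
    AnklePlantParams,
    ReferenceTrajectory,
    Trajectory,
    phase_indicator,
)

__all__ = [
    "MPCProblem",
    "MPCSolution",
    "solve_dare",
    "dare_weights",
    "lifted_dare_diagnostics",
    "lqr_terminal_policy",
    "terminal_check",
    "build_horizon_schedule",
    "solve_horizon",
    "solve_mpc",
    "closed_loop",
    "value_decrease_run",
]

_D2 = _plant.RAD2DEG**2  # deg^2 per rad^2 weight conversion


@dataclass(frozen=True)
class MPCProblem:
    """Horizon, weights, and constraint sets of the gait MPC.

    Defaults: 20 steps at 200 Hz (a 0.1 s horizon), Q = diag(100, 1) on the
    (angle, velocity) tracking error in degrees, R = 0.01 per mA^2, stance
    current box 10-25 mA (plantarflexor) and swing box 10-20 mA
    (dorsiflexor), a +/-20 deg foot-clearance band enforced softly, and a
    soft DARE terminal set of radius epsilon.
    """

    horizon_steps: int = 20
    sample_rate: float = 200.0
    q_angle: float = 100.0        # deg^-2 weight on the angle error
    q_velocity: float = 1.0       # (deg/s)^-2 weight on the velocity error
    r_input: float = 0.01         # mA^-2 weight on the current
    u_bounds_stance: tuple = (10.0, 25.0)   # mA, plantarflexor
    u_bounds_swing: tuple = (10.0, 20.0)    # mA, dorsiflexor
    angle_band: float = 20.0 * DEG          # rad, soft |theta| box
    state_penalty: float = 1000.0           # deg^-2 weight on band violation
    terminal_epsilon: float = 1.0           # terminal-set radius in e'Se
    terminal_set_weight: float = 1e-3       # soft weight on (e'Se - eps)+^2
    max_iter: int = 200
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.horizon_steps < 1:
            raise ValueError("horizon_steps must be >= 1")
        if self.q_angle < 0 or self.q_velocity < 0 or self.r_input <= 0:
            raise ValueError("Q must be PSD and R strictly positive")
        for lo, hi in (self.u_bounds_stance, self.u_bounds_swing):
            if not lo < hi:
                raise ValueError("input box requires u_min < u_max")
            if lo < 0:
                raise ValueError("stimulation currents are nonnegative")
        if self.terminal_epsilon <= 0:
            raise ValueError("terminal_epsilon must be positive")

    @property
    def Q(self) -> np.ndarray:
        """Error weight in internal radian units."""
        return np.diag([self.q_angle * _D2, self.q_velocity * _D2])

    @property
    def R(self) -> float:
        return self.r_input

    @property
    def horizon_seconds(self) -> float:
        return self.horizon_steps / self.sample_rate

    def u_bounds(self, sigma: int) -> tuple:
        return self.u_bounds_stance if sigma == 0 else self.u_bounds_swing


@dataclass
class MPCSolution:
    u_opt: np.ndarray          # (N,) applied-muscle currents over the horizon
    z_pred: np.ndarray         # (N+1, 4) predicted [e; x_d]
    cost: float
    sigma_horizon: np.ndarray
    solver_status: str         # converged | max_iter | infeasible
    n_iter: int
    terminal_ok: bool


def solve_dare(A: np.ndarray, B: np.ndarray, Q: np.ndarray, R) -> np.ndarray:
    """Stabilizing solution of the discrete algebraic Riccati equation.

    Raises if the pair is not stabilizable or the Riccati residual exceeds
    1e-8 * ||S||.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.asarray(B, dtype=float).reshape(A.shape[0], -1)
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    try:
        S = scipy.linalg.solve_discrete_are(A, B, Q, R)
    except Exception as exc:  # scipy raises LinAlgError/ValueError variants
        raise RuntimeError(f"DARE solve failed (non-stabilizable pair?): {exc}") from exc
    gain_term = A.T @ S @ B @ np.linalg.solve(R + B.T @ S @ B, B.T @ S @ A)
    resid = np.linalg.norm(S - (A.T @ S @ A - gain_term + Q))
    if resid > 1e-8 * max(np.linalg.norm(S), 1.0):
        raise RuntimeError(f"DARE residual too large: {resid:.3e}")
    return S


def dare_weights(model: KoopmanModel, prob: MPCProblem) -> dict:
    """Per-phase terminal weights S_sigma on the 2-d error subsystem."""
    out = {}
    for ph in ("stance", "swing"):
        A_ee, _, B_e = model.error_blocks(ph)
        out[ph] = solve_dare(A_ee, B_e, prob.Q, prob.R)
    return out


def lifted_dare_diagnostics(model: KoopmanModel, prob: MPCProblem) -> dict:
    """Attempt the Riccati equation on the lifted blocks (K_xx, K_xu).

    The lifted pair is generically *not* stabilizable — the constant and
    reference-clock observables are marginal and uncontrollable — so this is
    reported as a diagnostic, never used by the controller.
    """
    Ce = model.C[:2]
    Q_lift = Ce.T @ prob.Q @ Ce
    out = {}
    for ph in ("stance", "swing"):
        try:
            S = solve_dare(model.K_xx[ph], model.K_xu[ph], Q_lift, prob.R)
            out[ph] = {"solved": True, "norm_S": float(np.linalg.norm(S))}
        except RuntimeError as exc:
            out[ph] = {"solved": False, "reason": str(exc)}
    return out


def lqr_terminal_policy(A: np.ndarray, B: np.ndarray, S: np.ndarray, R) -> np.ndarray:
    """LQR gain K of the terminal policy u = -K e for the DARE weight S."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.asarray(B, dtype=float).reshape(A.shape[0], -1)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    return np.linalg.solve(R + B.T @ S @ B, B.T @ S @ A)


def terminal_check(z, S, epsilon: float) -> bool:
    """True iff the quadratic form z'Sz lies inside (or on) the terminal set."""
    z = np.asarray(z, dtype=float).ravel()
    return bool(z @ np.atleast_2d(S) @ z <= epsilon)


def build_horizon_schedule(
    sigma_now: int,
    phase_clock: float,
    params: AnklePlantParams,
    horizon_steps: int,
    dt: float,
) -> np.ndarray:
    """Phase flags over the horizon from the cyclic stance/swing timetable.

    ``phase_clock`` is the time already spent in the current phase; scheduled
    transitions falling inside the horizon switch the flag mid-horizon.
    """
    if sigma_now not in (0, 1):
        raise ValueError("sigma_now must be 0 or 1")
    t0 = phase_clock if sigma_now == 0 else params.stance_duration + phase_clock
    times = t0 + dt * np.arange(horizon_steps)
    sigma, _ = _plant.cycle_phase(times, params)
    return sigma.astype(int)


def _condense(A_seq, B_seq, d_seq, e0):
    """Stack e_{j+1} = A_j e_j + B_j u_j + d_j into e = f + Gamma u.

    Returns the free response ``f`` (N, 2) and input map ``Gamma`` (N, 2, N).
    """
    N = len(A_seq)
    f = np.empty((N, 2))
    Gamma = np.zeros((N, 2, N))
    e = np.asarray(e0, dtype=float).ravel()[:2]
    for j in range(N):
        if j == 0:
            f[0] = A_seq[0] @ e + d_seq[0]
        else:
            f[j] = A_seq[j] @ f[j - 1] + d_seq[j]
            Gamma[j, :, :j] = A_seq[j] @ Gamma[j - 1, :, :j]
        Gamma[j, :, j] = B_seq[j]
    return f, Gamma


def solve_horizon(
    A_seq,
    B_seq,
    d_seq,
    e0,
    xd_seq,
    Q,
    R: float,
    S: np.ndarray,
    bounds,
    angle_band: float | None = None,
    state_penalty: float = 0.0,
    terminal_epsilon: float | None = None,
    terminal_set_weight: float = 0.0,
    u_init=None,
    max_iter: int = 200,
    tol: float = 1e-9,
):
    """Projected-gradient (Barzilai-Borwein) solve of the condensed problem.

    ``A_seq/B_seq/d_seq`` define the per-step affine error dynamics,
    ``xd_seq`` (N+1, >=1) the known reference used by the soft angle band,
    ``bounds`` the per-step (lo, hi) current box.  Returns
    (u, cost, status, n_iter).
    """
    N = len(A_seq)
    f, Gamma = _condense(A_seq, B_seq, d_seq, e0)
    # stage weight Q on each successor state; the final state carries the
    # Riccati cost-to-go S *instead of* Q — the DARE fixed point already
    # contains the stage weight, and only this split makes the finite-horizon
    # solution stationary (the receding-horizon tail-shift identity)
    W = [np.asarray(Q, dtype=float)] * N
    W[N - 1] = np.asarray(S, dtype=float)
    # quadratic part: H = sum Gamma_j' W_j Gamma_j + R I ; linear g = sum Gamma_j' W_j f_j
    H = R * np.eye(N)
    g = np.zeros(N)
    c0 = 0.0
    for j in range(N):
        WG = W[j] @ Gamma[j]
        H += Gamma[j].T @ WG
        g += Gamma[j].T @ (W[j] @ f[j])
        c0 += f[j] @ W[j] @ f[j]
    H = 0.5 * (H + H.T)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(lo > hi):
        raise ValueError("infeasible input box: u_min > u_max")
    G_ang = Gamma[:, 0, :]  # (N, N): angle-error rows
    xd_ang = np.asarray(xd_seq, dtype=float).reshape(len(xd_seq), -1)[1 : N + 1, 0]
    S_t = np.asarray(S, dtype=float)
    pen_w = state_penalty * _D2

    def eval_all(u, want_hess):
        Hu = H @ u
        cost = float(u @ Hu + 2.0 * g @ u + c0)
        grad = 2.0 * (Hu + g)
        hess = 2.0 * H if want_hess else None
        if angle_band is not None and pen_w > 0.0:
            theta = f[:, 0] + G_ang @ u + xd_ang
            v = np.maximum(theta - angle_band, 0.0) - np.maximum(-angle_band - theta, 0.0)
            active = v != 0.0
            if np.any(active):
                cost += pen_w * float(v @ v)
                grad += 2.0 * pen_w * (G_ang.T @ v)
                if want_hess:
                    Ga = G_ang[active]
                    hess = hess + 2.0 * pen_w * (Ga.T @ Ga)
        if terminal_set_weight > 0.0 and terminal_epsilon is not None:
            eN = f[N - 1] + Gamma[N - 1] @ u
            s = float(eN @ S_t @ eN) - terminal_epsilon
            if s > 0.0:
                J_s = 2.0 * (Gamma[N - 1].T @ (S_t @ eN))  # d s / d u
                cost += terminal_set_weight * s * s
                grad += 2.0 * terminal_set_weight * s * J_s
                if want_hess:
                    # Gauss-Newton curvature of the convex penalty
                    GSG = Gamma[N - 1].T @ S_t @ Gamma[N - 1]
                    hess = hess + 2.0 * terminal_set_weight * (
                        np.outer(J_s, J_s) + 2.0 * s * GSG
                    )
        return cost, grad, hess

    # projected Newton (gradient projection with second-order scaling and
    # active-set identification); the objective is strictly convex piecewise
    # quadratic, so each free-set Newton system is exact
    u = np.clip(u_init if u_init is not None else 0.5 * (lo + hi), lo, hi).astype(float)
    cost, grad, hess = eval_all(u, True)
    g_scale = 1.0 + np.linalg.norm(grad, np.inf)
    status, it = "max_iter", max_iter
    edge = 1e-10 * (1.0 + np.abs(hi - lo))
    for k in range(max_iter):
        at_lo = (u <= lo + edge) & (grad > 0.0)
        at_hi = (u >= hi - edge) & (grad < 0.0)
        free = ~(at_lo | at_hi)
        pg = np.where(free, grad, 0.0)
        if np.linalg.norm(pg, np.inf) <= tol * g_scale:
            status, it = "converged", k
            break
        d = np.zeros(N)
        idx = np.flatnonzero(free)
        Hf = hess[np.ix_(idx, idx)]
        try:
            d[idx] = -np.linalg.solve(Hf + 1e-12 * np.eye(len(idx)), grad[idx])
        except np.linalg.LinAlgError:
            d[idx] = -grad[idx] / (np.diag(hess)[idx] + 1e-12)
        # backtracking on the projected arc
        t = 1.0
        accepted = False
        for _ in range(40):
            u_try = np.clip(u + t * d, lo, hi)
            c_try, g_try, h_try = eval_all(u_try, True)
            if c_try <= cost + 1e-12 * (1.0 + abs(cost)) and np.any(u_try != u):
                u, cost, grad, hess = u_try, c_try, g_try, h_try
                accepted = True
                break
            t *= 0.5
        if not accepted:
            status, it = "converged", k  # no admissible decrease left
            break
    return u, cost, status, it


def solve_mpc(
    model: KoopmanModel,
    z0,
    ref_window,
    sigma_horizon,
    prob: MPCProblem,
    S_terminal: dict | None = None,
    u_init=None,
) -> MPCSolution:
    """One receding-horizon solve on the switched Koopman predictor.

    ``z0`` is the current augmented state (4-vector) or tracking error
    (2-vector); ``ref_window`` supplies the known reference [theta_d,
    thetadot_d] for steps 0..N (array (N+1, 2) or a ReferenceTrajectory
    slice); ``sigma_horizon`` the per-step phase flags.  Only the phase's own
    muscle is decision-active at each step; the returned currents apply to
    that muscle.
    """
    sigma = np.asarray(sigma_horizon)
    if not np.all(np.isin(sigma, (0, 1))):
        raise ValueError("sigma_horizon must be binary")
    N = len(sigma)
    if isinstance(ref_window, ReferenceTrajectory):
        xd = np.column_stack([ref_window.theta_d, ref_window.theta_dot_d])
    else:
        xd = np.asarray(ref_window, dtype=float).reshape(len(ref_window), -1)
    if xd.shape[0] < N + 1:
        raise ValueError(f"reference window must cover N + 1 = {N + 1} samples")
    z0 = np.asarray(z0, dtype=float).ravel()
    e0 = z0[:2]
    if S_terminal is None:
        S_terminal = dare_weights(model, prob)
    phase_of = {0: "stance", 1: "swing"}
    blocks = {ph: model.error_blocks(ph) for ph in ("stance", "swing")}
    A_seq, B_seq, d_seq, bounds = [], [], [], []
    for j in range(N):
        ph = phase_of[int(sigma[j])]
        A_ee, _, B_e = blocks[ph]
        A_seq.append(A_ee)
        B_seq.append(B_e[:, 0])
        # reference coupling derived from the known reference: the same fitted
        # matrix advances the physical state and the error, so
        # e+ = A_ee e + (A_ee xd_j - xd_{j+1}) + B u exactly for a known
        # reference.  The fitted A_ed block is identified only on the
        # training-reference manifold and is not used for control.
        d_seq.append(A_ee @ xd[j, :2] - xd[j + 1, :2])
        bounds.append(prob.u_bounds(int(sigma[j])))
    S = S_terminal[phase_of[int(sigma[-1])]]
    u, cost, status, it = solve_horizon(
        A_seq,
        B_seq,
        d_seq,
        e0,
        xd,
        prob.Q,
        prob.R,
        S,
        bounds,
        angle_band=prob.angle_band,
        state_penalty=prob.state_penalty,
        terminal_epsilon=prob.terminal_epsilon,
        terminal_set_weight=prob.terminal_set_weight,
        u_init=u_init,
        max_iter=prob.max_iter,
        tol=prob.tol,
    )
    # rebuild the predicted error trajectory from the returned inputs
    e_pred = np.empty((N + 1, 2))
    e_pred[0] = e0
    for j in range(N):
        e_pred[j + 1] = A_seq[j] @ e_pred[j] + B_seq[j] * u[j] + d_seq[j]
    z_pred = np.column_stack([e_pred, xd[: N + 1, :2]])
    return MPCSolution(
        u_opt=u,
        z_pred=z_pred,
        cost=float(cost),
        sigma_horizon=sigma.astype(int),
        solver_status=status,
        n_iter=it,
        terminal_ok=terminal_check(e_pred[-1], S, prob.terminal_epsilon),
    )


def closed_loop(
    model: KoopmanModel,
    params: AnklePlantParams,
    ref: ReferenceTrajectory,
    prob: MPCProblem,
    duration: float,
    x0=None,
    grf_tolerance: float = DEFAULT_GRF_TOLERANCE,
):
    """Receding-horizon loop against the nonlinear ankle plant.

    Per step: measure the state, detect the phase from the plant's GRF,
    solve the MPC (warm-started by the shifted previous solution), apply the
    first current of the active muscle to the plant, advance one sampling
    interval.  A solver failure holds the previous input (logged).  Returns
    the realized Trajectory and a per-step log DataFrame.
    """
    dt = 1.0 / prob.sample_rate
    steps = int(round(duration * prob.sample_rate))
    N = prob.horizon_steps
    if len(ref) < steps + N + 1:
        raise ValueError("reference must cover the run plus one horizon")
    S_term = dare_weights(model, prob)
    th, om = (float(ref.theta_d[0]), float(ref.theta_dot_d[0])) if x0 is None else (
        float(x0[0]),
        float(x0[1]),
    )
    theta = np.empty(steps)
    omega = np.empty(steps)
    u_pf = np.zeros(steps)
    u_df = np.zeros(steps)
    grf = np.empty(steps)
    sig = np.empty(steps, dtype=int)
    log = {k: [] for k in ("time", "sigma", "u_applied", "status", "cost", "iterations")}
    u_warm = None
    u_prev = 0.0
    for k in range(steps):
        t = k * dt
        grf_k = float(_plant.grf_at(t, params))
        sigma_now = 0 if grf_k > grf_tolerance else 1
        _, phase_clock = _plant.cycle_phase(t, params)
        sigma_h = build_horizon_schedule(
            int(_plant.cycle_phase(t, params)[0]), float(phase_clock), params, N, dt
        )
        sigma_h[0] = sigma_now
        e = np.array([th - ref.theta_d[k], om - ref.theta_dot_d[k]])
        xd_win = np.column_stack(
            [ref.theta_d[k : k + N + 1], ref.theta_dot_d[k : k + N + 1]]
        )
        try:
            sol = solve_mpc(
                model, e, xd_win, sigma_h, prob, S_terminal=S_term, u_init=u_warm
            )
            ok = np.all(np.isfinite(sol.u_opt))
        except (ValueError, RuntimeError):
            sol, ok = None, False
        if ok:
            u0 = float(sol.u_opt[0])
            u_warm = np.append(sol.u_opt[1:], sol.u_opt[-1])
            status, cost, iters = sol.solver_status, sol.cost, sol.n_iter
        else:
            u0, status, cost, iters = u_prev, "failed", np.nan, 0
        u_prev = u0
        if sigma_now == 0:
            u_pf[k] = u0
        else:
            u_df[k] = u0
        theta[k], omega[k], grf[k], sig[k] = th, om, grf_k, sigma_now
        log["time"].append(t)
        log["sigma"].append(sigma_now)
        log["u_applied"].append(u0)
        log["status"].append(status)
        log["cost"].append(cost)
        log["iterations"].append(iters)
        th, om = _plant.rk4_step(th, om, u_pf[k], u_df[k], t, dt, params)
    traj = Trajectory(
        np.arange(steps) * dt, theta, omega, u_pf, u_df, grf, phase_indicator(grf, grf_tolerance)
    )
    return traj, pd.DataFrame(log)


def value_decrease_run(
    model: KoopmanModel,
    prob: MPCProblem,
    phase,
    e0,
    n_steps: int = 500,
    clip: bool = False,
) -> pd.DataFrame:
    """Nominal closed loop under the terminal LQR policy; logs V_k and l_k.

    On the linear error subsystem with the DARE weight S the exact policy
    satisfies V_{k+1} = V_k - l(e_k, u_k) identically — the closed-loop
    stability criterion.  ``clip=True`` additionally projects the policy into
    the phase's current box (feasibility inside the terminal set only).
    """
    ph = _normalize_phase(phase)
    A_ee, _, B_e = model.error_blocks(ph)
    S = solve_dare(A_ee, B_e, prob.Q, prob.R)
    K = lqr_terminal_policy(A_ee, B_e, S, prob.R)
    lo, hi = prob.u_bounds(0 if ph == "stance" else 1)
    e = np.asarray(e0, dtype=float).ravel()[:2]
    rows = {"V": [], "l": [], "u": []}
    for _ in range(n_steps):
        u = float(-(K @ e)[0])
        if clip:
            u = min(max(u, lo), hi)
        rows["V"].append(float(e @ S @ e))
        rows["l"].append(float(e @ prob.Q @ e + prob.R * u * u))
        rows["u"].append(u)
        e = A_ee @ e + B_e[:, 0] * u
    rows["V"].append(float(e @ S @ e))
    df = pd.DataFrame({k: pd.Series(v) for k, v in rows.items()})
    return df
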