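"""Switched nonlinear ankle dynamics under functional electrical stimulation (FES).

The ankle is modelled as a single hinge joint driven by two antagonist muscle
groups — the plantarflexors (gastrocnemius, active in stance) and the
dorsiflexors (tibialis anterior, active in swing) — each recruited by a
transcutaneous current amplitude in mA.  The gait cycle switches between a
stance interval, where a ground-reaction-force (GRF) torque acts about the
joint, and a swing interval:

    J_sigma * thetadd + f(theta, thetad) = tau_pf(u_pf) + tau_df(u_df)
                                           + (1 - sigma) * r(theta) * F_grf(t)

with passive torque f = viscous*thetad + elastic*(theta - rest) + mgl*sin(theta),
a piecewise-linear saturating recruitment curve per muscle, and the phase flag
sigma = 0 in stance, 1 in swing.  Angles are radians and SI units throughout;
degrees appear only at file/CLI boundaries.  Dorsiflexion is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

DEG = np.pi / 180.0
RAD2DEG = 180.0 / np.pi

# GRF level (N) below which a sample is classified as swing, Eq.-style
# indicator rule: grf > tol  <=>  sigma = 0.
DEFAULT_GRF_TOLERANCE = 1.0

__all__ = [
    "AnklePlantParams",
    "Trajectory",
    "ReferenceTrajectory",
    "muscle_torque",
    "grf_force",
    "grf_at",
    "cycle_phase",
    "ankle_rhs",
    "simulate",
    "phase_indicator",
    "DEG",
    "RAD2DEG",
    "DEFAULT_GRF_TOLERANCE",
]


@dataclass(frozen=True)
class AnklePlantParams:
    """Physical and recruitment parameters of the switched ankle model.

    Defaults describe a damped second-order ankle-foot system at slow treadmill
    speed: natural frequency ~2.2–2.8 Hz, damping ratio ~0.55–0.7, FES torque
    reaching ~15 N·m at recruitment saturation, and a small net GRF moment
    (force applied close to the joint centre during supported slow walking).
    """

    inertia_stance: float = 0.08        # kg·m², J_P
    inertia_swing: float = 0.05         # kg·m², J_D
    viscous_coeff: float = 1.2          # N·m·s/rad
    elastic_coeff: float = 15.0         # N·m/rad
    elastic_rest_angle: float = 0.0     # rad
    gravity_torque_coeff: float = 1.0   # N·m (lumped m·g·l of the foot)
    recruit_threshold: float = 6.0      # mA, no torque below
    recruit_saturation: float = 45.0    # mA, full torque above
    recruit_max_torque: float = 15.0    # N·m per muscle at saturation
    grf_peak_force: float = 350.0       # N, peak of the stance half-sine
    grf_moment_arm_coeff: float = 0.002  # m, r(theta) = coeff * cos(theta)
    cycle_duration: float = 1.0         # s
    stance_fraction: float = 0.6        # dimensionless, in (0, 1)

    def __post_init__(self) -> None:
        positive = (
            "inertia_stance", "inertia_swing", "viscous_coeff", "elastic_coeff",
            "recruit_max_torque", "grf_peak_force", "cycle_duration",
        )
        for name in positive:
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.gravity_torque_coeff < 0.0:
            raise ValueError("gravity_torque_coeff must be nonnegative")
        if self.grf_moment_arm_coeff < 0.0:
            raise ValueError("grf_moment_arm_coeff must be nonnegative")
        if not self.recruit_threshold < self.recruit_saturation:
            raise ValueError("recruit_threshold must be < recruit_saturation")
        if self.recruit_threshold < 0.0:
            raise ValueError("recruit_threshold must be nonnegative")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")

    @property
    def stance_duration(self) -> float:
        return self.stance_fraction * self.cycle_duration

    @property
    def swing_duration(self) -> float:
        return (1.0 - self.stance_fraction) * self.cycle_duration


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled gait time series; the universal interchange record.

    Channels share one time grid.  ``sigma`` is the GRF-derived phase flag
    (0 stance, 1 swing).  Angles are radians internally; trajectory files on
    disk use degrees (see :mod:`koopgait.io`).
    """

    time: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    u_pf: np.ndarray
    u_df: np.ndarray
    grf: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("theta", "theta_dot", "u_pf", "u_df", "grf", "sigma"):
            if len(getattr(self, name)) != n:
                raise ValueError("all Trajectory channels must have one length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time must be strictly increasing with a constant step")
        if np.any(self.u_pf < 0) or np.any(self.u_df < 0):
            raise ValueError("stimulation currents must be nonnegative")
        if not np.all(np.isin(self.sigma, (0, 1))):
            raise ValueError("sigma must be binary")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else float("nan")


@dataclass(frozen=True)
class ReferenceTrajectory:
    """Desired ankle angle/velocity on the same grid as the controlled run.

    ``discontinuities`` marks sample indices where the velocity channel is not
    the derivative of the angle channel (unblended set-point steps).
    """

    time: np.ndarray
    theta_d: np.ndarray
    theta_dot_d: np.ndarray
    discontinuities: tuple = ()

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.theta_d) == len(self.theta_dot_d)):
            raise ValueError("reference channels must have one length")

    def __len__(self) -> int:
        return len(self.time)


def _recruitment(u, params: AnklePlantParams):
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("stimulation current must be nonnegative")
    lo, hi = params.recruit_threshold, params.recruit_saturation
    frac = np.clip((u - lo) / (hi - lo), 0.0, 1.0)
    return frac * params.recruit_max_torque


def muscle_torque(u, muscle: str, params: AnklePlantParams):
    """FES-evoked joint torque (N·m) from current ``u`` (mA).

    Piecewise-linear saturating recruitment: zero below ``recruit_threshold``,
    ``recruit_max_torque`` above ``recruit_saturation``, linear between.
    Plantarflexor torque is negative (plantarflexion), dorsiflexor positive.
    """
    tau = _recruitment(u, params)
    if muscle in ("pf", "P", "plantarflexor"):
        return -tau
    if muscle in ("df", "D", "dorsiflexor"):
        return tau
    raise ValueError(f"unknown muscle {muscle!r}")


def grf_force(t_in_stance, params: AnklePlantParams):
    """Vertical GRF template (N): a half-sine bump over the stance interval.

    Zero at both stance boundaries, peaking at ``grf_peak_force`` mid-stance;
    zero outside the stance interval.
    """
    t = np.asarray(t_in_stance, dtype=float)
    T = params.stance_duration
    inside = (t >= 0.0) & (t <= T)
    val = params.grf_peak_force * np.sin(np.pi * np.clip(t, 0.0, T) / T)
    out = np.where(inside, val, 0.0)
    return float(out) if np.isscalar(t_in_stance) else out


def cycle_phase(t, params: AnklePlantParams):
    """Scheduled phase at time(s) ``t``: (sigma, time since phase onset)."""
    tc = np.mod(np.asarray(t, dtype=float), params.cycle_duration)
    sigma = np.where(tc < params.stance_duration, 0, 1)
    t_in = np.where(sigma == 0, tc, tc - params.stance_duration)
    return sigma, t_in


def grf_at(t, params: AnklePlantParams):
    """GRF (N) at absolute time(s) ``t`` under the cyclic stance schedule."""
    sigma, t_in = cycle_phase(t, params)
    out = np.where(sigma == 0, grf_force(np.where(sigma == 0, t_in, 0.0), params), 0.0)
    return float(out) if np.isscalar(t) else out


def ankle_rhs(theta, theta_dot, u_pf, u_df, sigma, t_in_phase, params: AnklePlantParams):
    """Continuous-time right-hand side: returns (theta_dot, theta_ddot).

    The GRF torque r(theta)*F_grf acts only in stance (sigma = 0) and the
    inertia switches with the phase.
    """
    vals = np.asarray([theta, theta_dot, u_pf, u_df], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("ankle_rhs requires finite inputs")
    if sigma not in (0, 1):
        raise ValueError("sigma must be 0 (stance) or 1 (swing)")
    tau_m = muscle_torque(u_pf, "pf", params) + muscle_torque(u_df, "df", params)
    if sigma == 0:
        inertia = params.inertia_stance
        tau_ext = params.grf_moment_arm_coeff * np.cos(theta) * grf_force(t_in_phase, params)
    else:
        inertia = params.inertia_swing
        tau_ext = 0.0
    passive = (
        params.viscous_coeff * theta_dot
        + params.elastic_coeff * (theta - params.elastic_rest_angle)
        + params.gravity_torque_coeff * np.sin(theta)
    )
    return float(theta_dot), float((tau_m + tau_ext - passive) / inertia)


def rk4_step(th, om, u_pf, u_df, t, h, params: AnklePlantParams):
    """One classical Runge–Kutta step of size ``h`` with inputs held (ZOH).

    The phase flag is frozen at the step's start (zero-order hold on sigma,
    like the inputs) so every stage sees one smooth vector field; only the
    phase clock advances across stages.  With the sampling grid aligned to
    the stance/swing boundaries — the default 200 samples per cycle at a 0.6
    stance fraction — switches land exactly on step edges.
    """
    sigma, t_in = cycle_phase(t, params)
    sigma, t_in = int(sigma), float(t_in)

    def rhs(a, b, dt_off):
        return ankle_rhs(a, b, u_pf, u_df, sigma, t_in + dt_off, params)

    k1t, k1o = rhs(th, om, 0.0)
    k2t, k2o = rhs(th + 0.5 * h * k1t, om + 0.5 * h * k1o, 0.5 * h)
    k3t, k3o = rhs(th + 0.5 * h * k2t, om + 0.5 * h * k2o, 0.5 * h)
    k4t, k4o = rhs(th + h * k3t, om + h * k3o, h)
    return (
        th + h / 6.0 * (k1t + 2 * k2t + 2 * k3t + k4t),
        om + h / 6.0 * (k1o + 2 * k2o + 2 * k3o + k4o),
    )


def simulate(
    x0,
    u_pf_series,
    u_df_series,
    params: AnklePlantParams,
    sample_rate: float = 200.0,
    n_cycles: int | None = None,
    substeps: int = 1,
    grf_tolerance: float = DEFAULT_GRF_TOLERANCE,
) -> Trajectory:
    """Fixed-step RK4 simulation of the switched ankle under ZOH inputs.

    ``u_*_series`` give the current (mA) held over each sampling interval;
    their length sets the trajectory length, which must equal
    ``n_cycles * cycle_duration * sample_rate`` when ``n_cycles`` is given.
    The GRF and sigma channels come from the cyclic stance schedule, with
    sigma derived from the GRF by thresholding (heel-strike samples where the
    GRF template is exactly zero are therefore labelled swing).  ``substeps``
    refines the integrator grid without changing the output grid.
    """
    u_pf = np.asarray(u_pf_series, dtype=float)
    u_df = np.asarray(u_df_series, dtype=float)
    if u_pf.shape != u_df.shape or u_pf.ndim != 1:
        raise ValueError("input series must be 1-d and of equal length")
    n = len(u_pf)
    if n < 1:
        raise ValueError("need at least one sample")
    if n_cycles is not None:
        expected = int(round(n_cycles * params.cycle_duration * sample_rate))
        if n != expected:
            raise ValueError(
                f"input series length {n} does not match "
                f"{n_cycles} cycles x {params.cycle_duration} s at {sample_rate} Hz = {expected}"
            )
    dt = 1.0 / float(sample_rate)
    h = dt / int(substeps)
    time = np.arange(n) * dt
    theta = np.empty(n)
    omega = np.empty(n)
    th, om = float(x0[0]), float(x0[1])
    for k in range(n):
        theta[k] = th
        omega[k] = om
        if k == n - 1:
            break
        for s in range(substeps):
            th, om = rk4_step(th, om, u_pf[k], u_df[k], time[k] + s * h, h, params)
    grf = grf_at(time, params)
    sigma = phase_indicator(grf, grf_tolerance)
    return Trajectory(time, theta, omega, u_pf, u_df, grf, sigma)


def phase_indicator(grf_series, tolerance: float = DEFAULT_GRF_TOLERANCE) -> np.ndarray:
    """Gait-phase flag from the GRF: sigma = 0 where grf > tolerance, else 1."""
    grf = np.asarray(grf_series, dtype=float)
    if np.any(grf < 0):
        raise ValueError("GRF must be nonnegative")
    return np.where(grf > tolerance, 0, 1).astype(int)
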