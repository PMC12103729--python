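"""Synthetic gait-data protocol, reference trajectories, and evaluation studies.

The data generator emulates the system-identification protocol of the gait
experiments at desk scale: 150 gait cycles of 200 samples at 200 Hz (30,000
samples), initial angle drawn uniformly in [-20 deg, 25 deg], initial angular
velocity in [-2, 2] rad/s, and the active muscle's current ramped linearly
from 0 to 30 mA across its phase (a uniform-random-level mode over [0, 50] mA
is available behind a flag).  Stance and swing are covered by construction,
one snapshot set per phase.

Two study pipelines mirror the identification and control experiments:
``run_prediction_study`` (held-out multi-step RMSE per observable dictionary
and embedding length, against the 0.5 deg accuracy threshold) and
``run_closed_loop_study`` (tracking RMSE of the switched MPC on the nonlinear
plant at treadmill-speed analogues 0.1/0.2/0.3 m/s mapped to 4/3/2 s gait
cycles).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .edmd import KoopmanModel, fit_koopman, predict, prediction_rmse
from .lifting import augmented_states, make_dictionary
from .mpc import MPCProblem, closed_loop
from .plant import (
    DEG,
    RAD2DEG,
    AnklePlantParams,
    ReferenceTrajectory,
    Trajectory,
    simulate,
)

__all__ = [
    "DataGenConfig",
    "EvalReport",
    "SPEED_TO_CYCLE_DURATION",
    "generate_dataset",
    "make_reference",
    "split_dataset",
    "train_koopman",
    "evaluate_prediction",
    "run_prediction_study",
    "run_closed_loop_study",
    "config_hash",
]

#: Treadmill speeds (m/s) mapped to gait-cycle durations (s); an analogy to
#: the slow-walking protocol, not a biomechanical reproduction.
SPEED_TO_CYCLE_DURATION = {0.1: 4.0, 0.2: 3.0, 0.3: 2.0}

PREDICTION_RMSE_THRESHOLD_DEG = 0.5


@dataclass(frozen=True)
class DataGenConfig:
    """Configuration of the synthetic training-data protocol."""

    n_cycles: int = 150
    samples_per_cycle: int = 200
    sample_rate: float = 200.0
    theta0_range_deg: tuple = (-20.0, 25.0)
    thetadot0_range: tuple = (-2.0, 2.0)   # rad/s (printed range has no units)
    u_ramp_max: float = 30.0               # mA, deterministic per-phase ramp
    u_random_range: tuple = (0.0, 50.0)    # mA, alternative random-level mode
    input_mode: str = "ramp"               # "ramp" | "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.samples_per_cycle < 2:
            raise ValueError("counts must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for rng in (self.theta0_range_deg, self.thetadot0_range, self.u_random_range):
            if not rng[0] <= rng[1]:
                raise ValueError("ranges must be ordered (low, high)")
        if self.input_mode not in ("ramp", "random"):
            raise ValueError("input_mode must be 'ramp' or 'random'")
        if self.u_ramp_max < 0:
            raise ValueError("u_ramp_max must be nonnegative")

    @property
    def cycle_duration(self) -> float:
        return self.samples_per_cycle / self.sample_rate


def config_hash(obj) -> str:
    """Short stable hash of a configuration dataclass/dict, for report rows."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class EvalReport:
    """A study result: a tidy table tagged with its provenance."""

    table: pd.DataFrame
    seed: int | None
    config_hash: str
    notes: str = ""

    def summary(self) -> str:
        lines = [f"config={self.config_hash} seed={self.seed}"]
        if self.notes:
            lines.append(self.notes)
        lines.append(self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def generate_dataset(cfg: DataGenConfig, params: AnklePlantParams):
    """Simulate ``cfg.n_cycles`` independent gait cycles per the protocol.

    Each cycle starts from a freshly sampled initial state; the plantarflexor
    current ramps over the stance interval and the dorsiflexor over swing
    (or, in random mode, holds a per-phase uniform level).  Reproducible:
    one seed drives every draw.
    """
    params = replace(params, cycle_duration=cfg.cycle_duration)
    rng = np.random.default_rng(cfg.seed)
    spc = cfg.samples_per_cycle
    n_st = int(round(params.stance_fraction * spc))
    lo_th, hi_th = (v * DEG for v in cfg.theta0_range_deg)
    cycles = []
    for _ in range(cfg.n_cycles):
        theta0 = rng.uniform(lo_th, hi_th)
        omega0 = rng.uniform(*cfg.thetadot0_range)
        u_pf = np.zeros(spc)
        u_df = np.zeros(spc)
        if cfg.input_mode == "ramp":
            u_pf[:n_st] = np.linspace(0.0, cfg.u_ramp_max, n_st)
            u_df[n_st:] = np.linspace(0.0, cfg.u_ramp_max, spc - n_st)
        else:
            u_pf[:n_st] = rng.uniform(*cfg.u_random_range)
            u_df[n_st:] = rng.uniform(*cfg.u_random_range)
        cycles.append(
            simulate(
                (theta0, omega0),
                u_pf,
                u_df,
                params,
                sample_rate=cfg.sample_rate,
                n_cycles=1,
            )
        )
    return cycles


def make_reference(
    kind: str,
    params: AnklePlantParams,
    n_cycles: int = 1,
    sample_rate: float = 200.0,
    amplitude_deg: float = 10.0,
    setpoints_deg: tuple = (-15.0, 15.0),
    blend_fraction: float = 0.1,
    n_samples: int | None = None,
) -> ReferenceTrajectory:
    """Desired ankle trajectory aligned to the gait-cycle schedule.

    ``sinusoid``: one cycle-frequency sinusoid of the given amplitude with a
    consistent velocity channel.  ``gait_setpoints``: piecewise-constant
    plantarflexion target in stance and dorsiflexion target in swing,
    cosine-blended over a window of ``blend_fraction`` of the cycle centred
    on each transition (slow-walking transitions are assumed smooth); with a
    zero blend the profile is an exact step and the velocity channel is zero
    except at declared discontinuity indices.
    """
    T = params.cycle_duration
    n = n_samples if n_samples is not None else int(round(n_cycles * T * sample_rate))
    t = np.arange(n) / sample_rate
    if kind == "sinusoid":
        if abs(amplitude_deg) > 20.0:
            warnings.warn("sinusoid amplitude outside the +/-20 deg clearance band")
        A = amplitude_deg * DEG
        w = 2.0 * np.pi / T
        return ReferenceTrajectory(t, A * np.sin(w * t), A * w * np.cos(w * t))
    if kind != "gait_setpoints":
        raise ValueError("kind must be 'sinusoid' or 'gait_setpoints'")
    pf, df = (v * DEG for v in setpoints_deg)
    if max(abs(v) for v in setpoints_deg) > 20.0:
        warnings.warn("set-point outside the +/-20 deg clearance band")
    T_st = params.stance_duration
    tc = np.mod(t, T)
    if blend_fraction <= 0.0:
        theta_d = np.where(tc < T_st, pf, df)
        vel = np.zeros(n)
        jumps = np.flatnonzero(np.diff(theta_d) != 0.0) + 1
        return ReferenceTrajectory(t, theta_d, vel, discontinuities=tuple(jumps.tolist()))
    w = blend_fraction * T

    def blend(tau, a, b):
        # tau in [0, 1] across the window; C^1 cosine ramp a -> b
        return a + (b - a) * 0.5 * (1.0 - np.cos(np.pi * tau))

    def blend_vel(tau, a, b):
        return (b - a) * 0.5 * np.pi / w * np.sin(np.pi * tau)

    conds = [
        tc < 0.5 * w,                       # finishing the swing->stance blend
        tc > T - 0.5 * w,                   # starting it before heel strike
        np.abs(tc - T_st) <= 0.5 * w,       # stance->swing blend
        tc < T_st,
    ]
    tau0 = tc / w + 0.5
    tau1 = (tc - T) / w + 0.5
    tau2 = (tc - T_st) / w + 0.5
    theta_d = np.select(
        conds, [blend(tau0, df, pf), blend(tau1, df, pf), blend(tau2, pf, df), np.full(n, pf)], df
    )
    vel = np.select(
        conds,
        [blend_vel(tau0, df, pf), blend_vel(tau1, df, pf), blend_vel(tau2, pf, df), np.zeros(n)],
        0.0,
    )
    return ReferenceTrajectory(t, theta_d, vel)


def split_dataset(trajs, test_fraction: float = 0.2):
    """Hold out the last fraction of whole cycles for evaluation."""
    n_test = max(1, int(round(test_fraction * len(trajs))))
    if n_test >= len(trajs):
        raise ValueError("dataset too small to split")
    return trajs[:-n_test], trajs[-n_test:]


def train_koopman(
    dataset,
    params: AnklePlantParams,
    dictionary_name: str = "custom",
    embedding_length: int = 1,
    ref: ReferenceTrajectory | None = None,
    ridge: float = 1e-8,
    sample_rate: float = 200.0,
) -> KoopmanModel:
    """Fit the per-phase Koopman predictor on a cycle dataset."""
    if ref is None:
        ref = make_reference("sinusoid", params, n_cycles=1, sample_rate=sample_rate)
    d = make_dictionary(dictionary_name, embedding_length)
    return fit_koopman(dataset, ref, d, ridge=ridge)


def _phase_runs(sigma):
    """Consecutive same-phase index runs [(start, stop), ...) over a cycle."""
    sigma = np.asarray(sigma)
    bounds = np.flatnonzero(np.diff(sigma) != 0) + 1
    edges = np.concatenate([[0], bounds, [len(sigma)]])
    return list(zip(edges[:-1], edges[1:]))


def evaluate_prediction(
    model: KoopmanModel,
    traj: Trajectory,
    ref: ReferenceTrajectory,
    channel: str = "angle",
    reseed_at_transitions: bool | None = None,
) -> float:
    """Multi-step held-out RMSE over one gait cycle (degrees for angles).

    The lifted predictor is seeded with L true samples and rolled forward
    with the recorded currents and phase flags.  The rollout starts at the
    first phase segment long enough to host the embedding window — the
    heel-strike sample itself (GRF exactly zero at the contact instant) is
    labelled swing by the indicator rule and forms a degenerate one-sample
    segment on which neither phase operator is trained.

    With ``reseed_at_transitions`` (the default whenever L > 1, where a delay
    window straddling a switch is undefined) each phase segment is predicted
    from its own first true window; with L = 1 the default is one continuous
    rollout across the whole cycle.
    """
    L = model.dictionary.embedding_length
    if reseed_at_transitions is None:
        reseed_at_transitions = L > 1
    z = augmented_states(traj, ref, reference_dim=model.reference_dim)
    if len(traj) < L + 2:
        raise ValueError("cycle too short for this embedding length")
    runs = [(s, j) for s, j in _phase_runs(traj.sigma) if j - s >= L + 1]
    if not runs:
        raise ValueError("no phase segment long enough for this embedding length")
    preds, acts = [], []
    if reseed_at_transitions:
        for s, j in runs:
            p = predict(
                model,
                z[s : s + L],
                traj.u_pf[s + L - 1 : j - 1],
                traj.u_df[s + L - 1 : j - 1],
                traj.sigma[s + L - 1 : j - 1],
                mode="lifted",
            )
            preds.append(p[1:])
            acts.append(z[s + L : j])
    else:
        s = runs[0][0]
        p = predict(
            model,
            z[s : s + L],
            traj.u_pf[s + L - 1 : -1],
            traj.u_df[s + L - 1 : -1],
            traj.sigma[s + L - 1 : -1],
            mode="lifted",
        )
        preds.append(p[1:])
        acts.append(z[s + L :])
    return prediction_rmse(np.vstack(preds), np.vstack(acts), channel=channel)


def run_prediction_study(
    dataset,
    params: AnklePlantParams,
    dictionaries=("state", "custom"),
    embeddings=(1,),
    ref: ReferenceTrajectory | None = None,
    ridge: float = 1e-8,
    test_fraction: float = 0.2,
    threshold: float = PREDICTION_RMSE_THRESHOLD_DEG,
    seed: int | None = None,
) -> EvalReport:
    """Held-out multi-step RMSE per (dictionary, embedding length).

    Fits per-phase operators on the leading cycles, evaluates on the held-out
    tail, and flags whether each row meets the prediction-accuracy threshold
    (0.5 deg RMSE over a gait cycle).
    """
    if ref is None:
        ref = make_reference(
            "sinusoid", params, n_cycles=1, sample_rate=1.0 / dataset[0].dt
        )
    train, test = split_dataset(dataset, test_fraction)
    rows = []
    for name in dictionaries:
        for L in embeddings:
            d = make_dictionary(name, L)
            model = fit_koopman(train, ref, d, ridge=ridge)
            rmses = np.array([evaluate_prediction(model, tr, ref) for tr in test])
            rows.append(
                {
                    "dictionary": name,
                    "embedding_length": L,
                    "lifted_dim": d.lifted_dim,
                    "rmse_mean_deg": float(rmses.mean()),
                    "rmse_sd_deg": float(rmses.std(ddof=1)) if len(rmses) > 1 else 0.0,
                    "n_train_cycles": len(train),
                    "n_test_cycles": len(test),
                    "meets_threshold": bool(rmses.mean() <= threshold),
                }
            )
    cfg = {
        "dictionaries": list(dictionaries),
        "embeddings": list(embeddings),
        "ridge": ridge,
        "test_fraction": test_fraction,
        "threshold": threshold,
    }
    return EvalReport(pd.DataFrame(rows), seed, config_hash(cfg))


def run_closed_loop_study(
    model: KoopmanModel,
    params: AnklePlantParams,
    prob: MPCProblem,
    speeds=(0.1, 0.2, 0.3),
    n_cycles: int = 3,
    skip_cycles: int = 1,
    setpoints_deg: tuple = (-15.0, 15.0),
    blend_fraction: float = 0.1,
    seed: int | None = None,
) -> EvalReport:
    """Closed-loop tracking study at the treadmill-speed analogues.

    For each speed the switched MPC tracks the per-phase set-point profile on
    the nonlinear plant for ``n_cycles`` gait cycles; tracking RMSE is
    reported separately over the plantarflexion (stance-core) and
    dorsiflexion (swing-core) windows, mean +/- SD over the cycles after the
    first ``skip_cycles`` transient cycles, together with the solver-failure
    fraction and any input-box violations.
    """
    rows = []
    for speed in speeds:
        T = SPEED_TO_CYCLE_DURATION[speed]
        p = replace(params, cycle_duration=T)
        steps = int(round(n_cycles * T * prob.sample_rate))
        ref = make_reference(
            "gait_setpoints",
            p,
            sample_rate=prob.sample_rate,
            setpoints_deg=setpoints_deg,
            blend_fraction=blend_fraction,
            n_samples=steps + prob.horizon_steps + 2,
        )
        traj, log = closed_loop(model, p, ref, prob, duration=n_cycles * T)
        w = blend_fraction * T
        tc = np.mod(traj.time, T)
        cyc = (traj.time // T).astype(int)
        core_st = (tc >= w) & (tc <= p.stance_duration - 0.5 * w)
        core_sw = (tc >= p.stance_duration + 0.5 * w) & (tc <= T - 0.5 * w)
        err_deg = (traj.theta - ref.theta_d[: len(traj)]) * RAD2DEG
        pf_rmse, df_rmse = [], []
        for c in range(skip_cycles, n_cycles):
            m = cyc == c
            pf_rmse.append(float(np.sqrt(np.mean(err_deg[m & core_st] ** 2))))
            df_rmse.append(float(np.sqrt(np.mean(err_deg[m & core_sw] ** 2))))
        pf_rmse, df_rmse = np.array(pf_rmse), np.array(df_rmse)
        fail = float(np.mean(np.asarray(log["status"]) == "failed"))
        applied = log["u_applied"].to_numpy()
        sig = log["sigma"].to_numpy()
        viol = 0
        for s, (lo, hi) in ((0, prob.u_bounds_stance), (1, prob.u_bounds_swing)):
            m = sig == s
            viol += int(np.sum((applied[m] < lo - 1e-9) | (applied[m] > hi + 1e-9)))
        rows.append(
            {
                "speed_m_per_s": speed,
                "cycle_duration_s": T,
                "rmse_pf_mean_deg": float(pf_rmse.mean()),
                "rmse_pf_sd_deg": float(pf_rmse.std(ddof=1)) if len(pf_rmse) > 1 else 0.0,
                "rmse_df_mean_deg": float(df_rmse.mean()),
                "rmse_df_sd_deg": float(df_rmse.std(ddof=1)) if len(df_rmse) > 1 else 0.0,
                "solver_failure_rate": fail,
                "input_violations": viol,
                "flagged": bool(fail > 0.1),
            }
        )
    cfg = {
        "speeds": list(speeds),
        "n_cycles": n_cycles,
        "setpoints_deg": list(setpoints_deg),
        "blend_fraction": blend_fraction,
    }
    return EvalReport(pd.DataFrame(rows), seed, config_hash(cfg))
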