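"""Per-phase Koopman operator identification by extended DMD with control.

Snapshot pairs of lifted data, D_k = [Psi_x(x_k); u_k] and its one-step
successor D_{k+1}, are regressed phase-by-phase:

    K = F G+        with F = (1/M) sum D_{k+1} D_k',  G = (1/M) sum D_k D_k'

(equivalently the minimum-norm least-squares solution of K D_k ~ D_{k+1}).
The top blocks K_xx (P x P) and K_xu (P x m) give the lifted linear predictor;
the rows that would evolve the control observables are discarded.  A linear
recovery map C (n x P), fitted by least squares over both phases pooled, maps
lifted vectors back to the augmented state, and the reduced switched predictor

    z_{k+1} = A_sigma z_k + B_sigma u_k,   A = C K_xx C+,  B = C K_xu

is what the controller consumes.  C is not square, so its "inverse" is
realized as a right inverse restricted to the lifted data subspace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lifting import (
    ObservableDictionary,
    augmented_states,
    lift,
    lift_series,
    valid_pair_indices,
)
from .plant import RAD2DEG, ReferenceTrajectory, Trajectory

__all__ = [
    "SnapshotSet",
    "KoopmanModel",
    "EmptySnapshotError",
    "DegenerateFitError",
    "assemble_snapshots",
    "fit_operator",
    "fit_recovery",
    "reduce_model",
    "fit_koopman",
    "predict",
    "prediction_rmse",
]

STANCE, SWING = "stance", "swing"


class EmptySnapshotError(ValueError):
    """No same-phase snapshot pairs could be extracted."""


class DegenerateFitError(RuntimeError):
    """The snapshot matrices carry no signal (e.g. all zeros)."""


def _normalize_phase(phase) -> str:
    if phase in (STANCE, "P", 0):
        return STANCE
    if phase in (SWING, "D", 1):
        return SWING
    raise ValueError(f"unknown phase {phase!r}; use 'stance'/'P'/0 or 'swing'/'D'/1")


_PHASE_SIGMA = {STANCE: 0, SWING: 1}


@dataclass(frozen=True)
class SnapshotSet:
    """Aligned lifted snapshot pairs of one gait phase.

    Column j of ``D_k1`` is the lift of the immediate successor of column j of
    ``D_k``; ``states`` carries the raw augmented states z_k aligned to the
    ``D_k`` columns (used for the recovery fit).
    """

    D_k: np.ndarray     # (P + m, M)
    D_k1: np.ndarray    # (P + m, M)
    phase: str
    states: np.ndarray  # (n, M)
    input_dim: int = 1

    def __post_init__(self) -> None:
        if self.D_k.shape != self.D_k1.shape:
            raise ValueError("D_k and D_k1 must have identical shapes")
        if self.states.shape[1] != self.D_k.shape[1]:
            raise ValueError("states must align column-wise with D_k")

    @property
    def n_pairs(self) -> int:
        return self.D_k.shape[1]

    @property
    def lifted_dim(self) -> int:
        return self.D_k.shape[0] - self.input_dim


def assemble_snapshots(
    trajs,
    ref: ReferenceTrajectory,
    dictionary: ObservableDictionary,
    phase,
    reference_dim: int = 2,
) -> SnapshotSet:
    """Collect same-phase lifted snapshot pairs from one or more trajectories.

    The stance set draws the plantarflexor current, the swing set the
    dorsiflexor current, as the control observable (identity lifting on u).
    Pairs whose window or successor crosses a phase transition are dropped.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    phase = _normalize_phase(phase)
    sig_val = _PHASE_SIGMA[phase]
    L = dictionary.embedding_length
    cols_k, cols_k1, raw = [], [], []
    for traj in trajs:
        if len(traj) < L + 1:
            continue
        z = augmented_states(traj, ref, reference_dim=reference_dim)
        psi = lift_series(z, dictionary)  # column j <-> window ending at j+L-1
        u = traj.u_pf if phase == STANCE else traj.u_df
        ks = valid_pair_indices(traj.sigma, L, sig_val)
        if len(ks) == 0:
            continue
        j = ks - (L - 1)
        cols_k.append(np.vstack([psi[:, j], u[ks][None, :]]))
        cols_k1.append(np.vstack([psi[:, j + 1], u[ks + 1][None, :]]))
        raw.append(z[ks].T)
    if not cols_k:
        raise EmptySnapshotError(f"no {phase} snapshot pairs in the supplied trajectories")
    return SnapshotSet(
        D_k=np.hstack(cols_k),
        D_k1=np.hstack(cols_k1),
        phase=phase,
        states=np.hstack(raw),
        input_dim=1,
    )


def fit_operator(snaps: SnapshotSet, ridge: float = 0.0):
    """Least-squares Koopman operator fit; returns (K_xx, K_xu, diagnostics).

    With ``ridge=0`` the minimum-norm pseudoinverse solution K = F G+ is
    computed through LAPACK least squares on the snapshot matrices; a positive
    ``ridge`` solves the Tikhonov-regularized normal equations instead
    (useful for collinear observables such as theta and sin theta).
    The blocks that would evolve the control observables are discarded.
    """
    if snaps.n_pairs < 1:
        raise EmptySnapshotError("need at least one snapshot pair")
    Dk, Dk1 = snaps.D_k, snaps.D_k1
    if not Dk.any():
        raise DegenerateFitError(
            f"all-zero snapshot matrix ({snaps.phase}, {snaps.n_pairs} pairs)"
        )
    M = snaps.n_pairs
    G = (Dk @ Dk.T) / M
    if ridge > 0.0:
        F = (Dk1 @ Dk.T) / M
        K = np.linalg.solve(G + ridge * np.eye(G.shape[0]), F.T).T
    else:
        K = np.linalg.lstsq(Dk.T, Dk1.T, rcond=None)[0].T
    P = snaps.lifted_dim
    # residual over the retained state-observable rows only; the discarded
    # control-observable rows are not meant to be predictable
    resid = float(np.linalg.norm(Dk1[:P] - K[:P] @ Dk, "fro"))
    with np.errstate(all="ignore"):
        cond = float(np.linalg.cond(G))
    diagnostics = {
        "residual_fro": resid,
        "residual_per_pair": resid / np.sqrt(M),
        "cond_G": cond,
        "n_pairs": M,
    }
    return K[:P, :P], K[:P, P:], diagnostics


def fit_recovery(snaps, ridge: float = 0.0):
    """State-recovery map C minimizing ||C Psi - z||^2 over pooled snapshots.

    ``snaps`` may be one SnapshotSet or a list (both phases pooled — one C
    serves the whole gait cycle).  Returns (C, diagnostics); a rank-deficient
    lifted covariance triggers a warning and a regularized solve.
    """
    if isinstance(snaps, SnapshotSet):
        snaps = [snaps]
    Psi = np.hstack([s.D_k[: s.lifted_dim] for s in snaps])
    Z = np.hstack([s.states for s in snaps])
    M = Psi.shape[1]
    if M < 1:
        raise EmptySnapshotError("no snapshot columns for the recovery fit")
    rank = np.linalg.matrix_rank(Psi)
    if ridge <= 0.0 and rank < Psi.shape[0]:
        warnings.warn(
            f"rank-deficient lifted data (rank {rank} < P = {Psi.shape[0]}); "
            "using a regularized recovery solve",
            RuntimeWarning,
            stacklevel=2,
        )
        ridge = 1e-10
    if ridge > 0.0:
        G = (Psi @ Psi.T) / M
        F = (Z @ Psi.T) / M
        C = np.linalg.solve(G + ridge * np.eye(G.shape[0]), F.T).T
    else:
        C = np.linalg.lstsq(Psi.T, Z.T, rcond=None)[0].T
    resid = float(np.linalg.norm(C @ Psi - Z, "fro") / np.sqrt(M))
    return C, {"recovery_residual_per_sample": resid, "rank_Psi": int(rank), "n_columns": M}


def reduce_model(K_xx: np.ndarray, K_xu: np.ndarray, C: np.ndarray, lift_encoder=None):
    """Reduced switched predictor blocks: A = C K_xx C+, B = C K_xu.

    C is n x P (non-square), so its inverse is realized as a right inverse
    restricted to the lifted training subspace.  ``lift_encoder`` is that
    restriction: the P x n regression of the lifted training data on the raw
    states (supplied by :func:`fit_koopman`), which represents a state by the
    data-consistent lifted vector rather than the minimum-norm one — with
    nearly collinear observables (theta and sin theta at gait-scale angles)
    the two differ badly off the training manifold.  Without an encoder the
    plain Moore-Penrose pseudoinverse of C is used.  Ill-conditioned C is
    warned about, with the condition number attached.
    """
    cond = float(np.linalg.cond(C))
    if cond > 1e8:
        warnings.warn(
            f"recovery map is ill-conditioned (cond = {cond:.3g}); "
            "the reduced model may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    C_right_inv = np.linalg.pinv(C) if lift_encoder is None else lift_encoder
    A = C @ K_xx @ C_right_inv
    B = C @ K_xu
    return A, B


@dataclass
class KoopmanModel:
    """Per-phase lifted operators, shared recovery map, and reduced predictor."""

    dictionary: ObservableDictionary
    K_xx: dict
    K_xu: dict
    C: np.ndarray
    A_tilde: dict
    B_tilde: dict
    diagnostics: dict = field(default_factory=dict)
    reference_dim: int = 2

    @property
    def state_dim(self) -> int:
        return self.C.shape[0]

    @property
    def lifted_dim(self) -> int:
        return self.C.shape[1]

    def error_blocks(self, phase):
        """(A_ee, A_ed, B_e): the 2-d tracking-error subsystem of one phase.

        e+ = A_ee e + A_ed x_d + B_e u, with the reference coordinates x_d
        treated as known exogenous signals by the controller.
        """
        phase = _normalize_phase(phase)
        A, B = self.A_tilde[phase], self.B_tilde[phase]
        return A[:2, :2], A[:2, 2:], B[:2].reshape(2, -1)


def fit_koopman(
    trajs,
    ref: ReferenceTrajectory,
    dictionary: ObservableDictionary,
    ridge: float = 1e-8,
    reference_dim: int = 2,
) -> KoopmanModel:
    """Full identification pipeline: snapshots -> per-phase K -> pooled C -> (A, B).

    The small default ridge stabilizes the nearly collinear custom-library
    observables (theta and sin theta coincide to cubic order at gait-scale
    angles); pass ``ridge=0`` for exact pseudoinverse solutions.
    """
    snaps = {
        ph: assemble_snapshots(trajs, ref, dictionary, ph, reference_dim=reference_dim)
        for ph in (STANCE, SWING)
    }
    K_xx, K_xu, diag = {}, {}, {}
    for ph, s in snaps.items():
        K_xx[ph], K_xu[ph], d = fit_operator(s, ridge=ridge)
        diag[ph] = d
    C, rec_diag = fit_recovery(list(snaps.values()), ridge=ridge)
    diag["recovery"] = rec_diag
    # data-weighted lift encoder: regression of pooled lifted data on states,
    # the right-inverse of C restricted to the lifted training subspace
    Psi = np.hstack([s.D_k[: s.lifted_dim] for s in snaps.values()])
    Z = np.hstack([s.states for s in snaps.values()])
    W = np.linalg.lstsq(Z.T, Psi.T, rcond=None)[0].T
    diag["recovery"]["encoder_residual"] = float(
        np.linalg.norm(Psi - W @ Z, "fro") / np.sqrt(Psi.shape[1])
    )
    A_t, B_t = {}, {}
    for ph in (STANCE, SWING):
        A_t[ph], B_t[ph] = reduce_model(K_xx[ph], K_xu[ph], C, lift_encoder=W)
    return KoopmanModel(
        dictionary=dictionary,
        K_xx=K_xx,
        K_xu=K_xu,
        C=C,
        A_tilde=A_t,
        B_tilde=B_t,
        diagnostics=diag,
        reference_dim=reference_dim,
    )


def predict(
    model: KoopmanModel,
    z0_window,
    u_pf_series,
    u_df_series,
    sigma_series,
    mode: str = "lifted",
) -> np.ndarray:
    """Multi-step rollout of the switched predictor.

    ``z0_window`` holds the L most recent augmented states (oldest first);
    the series give the inputs and phase flags for each of the T steps.
    ``mode='lifted'`` rolls the P-dimensional observable vector and recovers
    states through C (the only mode defined for delay embeddings L > 1);
    ``mode='reduced'`` iterates z+ = A_sigma z + B_sigma u directly.
    Returns an array (T + 1, n) whose first row is the (recovered) initial
    state.
    """
    sigma = np.asarray(sigma_series)
    if not np.all(np.isin(sigma, (0, 1))):
        raise ValueError("sigma series must be binary")
    u_pf = np.asarray(u_pf_series, dtype=float)
    u_df = np.asarray(u_df_series, dtype=float)
    T = len(sigma)
    if len(u_pf) != T or len(u_df) != T:
        raise ValueError("input and sigma series must share one length")
    phase_of = {0: STANCE, 1: SWING}
    out = np.empty((T + 1, model.state_dim))
    if mode == "lifted":
        psi = lift(z0_window, model.dictionary)
        out[0] = model.C @ psi
        for k in range(T):
            ph = phase_of[int(sigma[k])]
            u = u_pf[k] if sigma[k] == 0 else u_df[k]
            psi = model.K_xx[ph] @ psi + (model.K_xu[ph] * u).ravel()
            out[k + 1] = model.C @ psi
    elif mode == "reduced":
        w = np.atleast_2d(np.asarray(z0_window, dtype=float))
        z = w[-1].copy()
        out[0] = z
        for k in range(T):
            ph = phase_of[int(sigma[k])]
            u = u_pf[k] if sigma[k] == 0 else u_df[k]
            z = model.A_tilde[ph] @ z + (model.B_tilde[ph] * u).ravel()
            out[k + 1] = z
    else:
        raise ValueError("mode must be 'lifted' or 'reduced'")
    return out


def prediction_rmse(pred, actual, channel: str = "angle") -> float:
    """Root-mean-square prediction error on one channel.

    For 2-d inputs the rows are augmented states [e_th, e_om, th_d, om_d] (or
    the 3-d variant) and the physical channel is reconstructed as error +
    reference; angle/velocity errors are reported in degrees(/s).  1-d inputs
    are compared as-is.  ``channel='state'`` gives the full-state 2-norm RMSE
    in native (radian) units.
    """
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError("prediction and reference series must have equal shapes")
    if p.ndim == 1:
        return float(np.sqrt(np.mean((p - a) ** 2)))
    if channel == "state":
        return float(np.sqrt(np.mean(np.sum((p - a) ** 2, axis=1))))
    if channel == "angle":
        idx = (0, 2) if p.shape[1] >= 3 else (0,)
    elif channel == "velocity":
        if p.shape[1] < 4:
            raise ValueError("velocity channel requires the 4-d augmented state")
        idx = (1, 3)
    else:
        raise ValueError("channel must be 'angle', 'velocity', or 'state'")
    diff = (p[:, list(idx)].sum(axis=1) - a[:, list(idx)].sum(axis=1)) * RAD2DEG
    return float(np.sqrt(np.mean(diff**2)))
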