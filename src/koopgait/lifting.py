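"""Observable dictionaries and the lifting map for Koopman/EDMD identification.

The nonlinear ankle state is lifted into a higher-dimensional space where the
dynamics evolve approximately linearly.  The state being lifted is the
*augmented* tracking state

    z = [e_theta, e_thetadot, theta_d, thetadot_d]        (default, n = 4)

i.e. the tracking error followed by the reference coordinates.  In descriptor
notation x1..x4 index these coordinates; the field-standard "custom" library
names its two position-like coordinates theta1 = x1 (error angle) and
theta2 = x3 (reference angle), with velocities thetadot1 = x2 and
thetadot2 = x4.

Delay embedding concatenates the basis evaluated on the L most recent states
(oldest to newest); a single constant observable, when enabled, is appended
last.  The same dictionary object serves both the stance and the swing fit so
the two phase operators share one lifted space.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .plant import Trajectory, ReferenceTrajectory

__all__ = [
    "ObservableDictionary",
    "make_dictionary",
    "lift",
    "lift_series",
    "embed",
    "valid_pair_indices",
    "augmented_states",
]

_RE_LIN = re.compile(r"^x(\d+)$")
_RE_SIN = re.compile(r"^sin\(x(\d+)\)$")
_RE_COS = re.compile(r"^cos\(x(\d+)\)$")
_RE_SQ = re.compile(r"^x(\d+)\^2$")
_RE_PROD = re.compile(r"^x(\d+)\*x(\d+)$")


def _compile_descriptor(desc: str, state_dim: int):
    """Turn one term descriptor into a vectorized evaluator over (..., n) arrays."""

    def _idx(match, pos=0):
        i = int(match.group(1 + pos)) - 1
        if not 0 <= i < state_dim:
            raise ValueError(f"descriptor {desc!r} indexes beyond state dimension {state_dim}")
        return i

    m = _RE_LIN.match(desc)
    if m:
        i = _idx(m)
        return lambda s: s[..., i]
    m = _RE_SIN.match(desc)
    if m:
        i = _idx(m)
        return lambda s: np.sin(s[..., i])
    m = _RE_COS.match(desc)
    if m:
        i = _idx(m)
        return lambda s: np.cos(s[..., i])
    m = _RE_SQ.match(desc)
    if m:
        i = _idx(m)
        return lambda s: s[..., i] ** 2
    m = _RE_PROD.match(desc)
    if m:
        i, j = _idx(m), int(m.group(2)) - 1
        if not 0 <= j < state_dim:
            raise ValueError(f"descriptor {desc!r} indexes beyond state dimension {state_dim}")
        return lambda s: s[..., i] * s[..., j]
    raise ValueError(f"unrecognized observable descriptor {desc!r}")


@dataclass(frozen=True)
class ObservableDictionary:
    """Ordered basis + embedding length defining the lifting map.

    ``descriptors`` lists the per-state scalar terms (the constant term is
    implicit via ``include_constant`` and always last in the lifted vector).
    ``lifted_dim`` is P = len(descriptors) * L (+1 for the constant).
    """

    name: str
    descriptors: tuple
    embedding_length: int
    state_dim: int
    include_constant: bool = True
    _funcs: tuple = field(init=False, repr=False, compare=False, default=())

    def __post_init__(self) -> None:
        if self.embedding_length < 1:
            raise ValueError("embedding_length must be >= 1")
        if self.state_dim < 1:
            raise ValueError("state_dim must be >= 1")
        funcs = tuple(_compile_descriptor(d, self.state_dim) for d in self.descriptors)
        object.__setattr__(self, "_funcs", funcs)

    @property
    def lifted_dim(self) -> int:
        return len(self.descriptors) * self.embedding_length + int(self.include_constant)


_CUSTOM_TERMS = (
    "x1", "x3", "x2", "x4",            # theta1, theta2, thetadot1, thetadot2
    "sin(x1)", "cos(x1)", "sin(x3)", "cos(x3)",
    "x1^2", "x3^2", "x1*x3", "x2*x4",
)


def make_dictionary(
    name: str,
    embedding_length: int = 1,
    state_dim: int = 4,
    include_constant: bool = True,
) -> ObservableDictionary:
    """Build one of the three named observable families.

    ``state``:  the raw augmented-state coordinates (identity lifting).
    ``custom``: the 12-term ankle library — linear terms theta1, theta2,
                thetadot1, thetadot2 plus sin/cos of the two position-like
                coordinates, their squares and product, and the velocity
                product — giving P = 13 with the constant at L = 1.
    ``trig``:   sin and cos of every state coordinate.
    """
    if name == "state":
        terms = tuple(f"x{i + 1}" for i in range(state_dim))
    elif name == "custom":
        if state_dim != 4:
            raise ValueError("the custom library requires the 4-d augmented state")
        terms = _CUSTOM_TERMS
    elif name == "trig":
        terms = tuple(
            t for i in range(state_dim) for t in (f"sin(x{i + 1})", f"cos(x{i + 1})")
        )
    else:
        raise ValueError(f"unknown dictionary name {name!r}; use state, custom, or trig")
    return ObservableDictionary(
        name=name,
        descriptors=terms,
        embedding_length=embedding_length,
        state_dim=state_dim,
        include_constant=include_constant,
    )


def lift_series(states: np.ndarray, dictionary: ObservableDictionary) -> np.ndarray:
    """Lift a whole state sequence.

    ``states`` has shape (N, n); the result has shape (P, N - L + 1) whose
    column j is the lifted vector of the window *ending* at sample j + L - 1.
    Delayed evaluations are stacked oldest-to-newest, constant term last.
    """
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[1] != dictionary.state_dim:
        raise ValueError(
            f"states must have shape (N, {dictionary.state_dim}); got {states.shape}"
        )
    N = states.shape[0]
    L = dictionary.embedding_length
    if N < L:
        raise ValueError(f"need at least L = {L} samples")
    feats = np.stack([f(states) for f in dictionary._funcs], axis=0)  # (nf, N)
    blocks = [feats[:, i : N - L + 1 + i] for i in range(L)]
    out = np.vstack(blocks)
    if dictionary.include_constant:
        out = np.vstack([out, np.ones((1, N - L + 1))])
    return out


def lift(state_window, dictionary: ObservableDictionary) -> np.ndarray:
    """Lift one window of L augmented states (oldest first) to a P-vector."""
    w = np.asarray(state_window, dtype=float)
    if w.ndim == 1:
        w = w[None, :]
    if w.shape != (dictionary.embedding_length, dictionary.state_dim):
        raise ValueError(
            f"window must have shape ({dictionary.embedding_length}, "
            f"{dictionary.state_dim}); got {w.shape}"
        )
    return lift_series(w, dictionary)[:, 0]


def valid_pair_indices(sigma, embedding_length: int, phase: int | None = None) -> np.ndarray:
    """Indices k whose window [k-L+1 .. k] and successor k+1 share one phase.

    Windows (and the predicted sample) straddling a stance/swing transition
    are excluded; with ``phase`` given, only that phase's indices are kept.
    """
    sig = np.asarray(sigma)
    L = int(embedding_length)
    n = len(sig)
    if n < L + 1:
        raise ValueError(f"trajectory shorter than L + 1 = {L + 1} samples")
    # run of L+1 equal flags ending at k+1
    same = np.ones(n, dtype=bool)  # same[j]: sig[j-1] == sig[j]
    same[1:] = sig[1:] == sig[:-1]
    run = np.empty(n, dtype=int)
    run[0] = 1
    for j in range(1, n):
        run[j] = run[j - 1] + 1 if same[j] else 1
    ks = np.flatnonzero(run[1:] >= L + 1)  # index into run at k+1
    if phase is not None:
        ks = ks[sig[ks] == phase]
    return ks


def embed(states: np.ndarray, sigma, dictionary: ObservableDictionary, phase: int | None = None):
    """Sliding windows of length L aligned so window k predicts sample k + 1.

    Returns ``(windows, ks)`` where ``windows[j] = states[ks[j]-L+1 .. ks[j]]``.
    """
    states = np.asarray(states, dtype=float)
    L = dictionary.embedding_length
    ks = valid_pair_indices(sigma, L, phase)
    windows = np.stack([states[k - L + 1 : k + 1] for k in ks]) if len(ks) else np.empty(
        (0, L, states.shape[1])
    )
    return windows, ks


def augmented_states(
    traj: Trajectory, ref: ReferenceTrajectory, reference_dim: int = 2
) -> np.ndarray:
    """Tracking-error + reference state sequence z_k from a run and its reference.

    With ``reference_dim=2`` (default) z = [e_theta, e_thetadot, theta_d,
    thetadot_d] in R^4; ``reference_dim=1`` keeps only the reference angle
    (the scalar-reference 3-d variant, usable with the ``state`` and ``trig``
    dictionaries).
    """
    if reference_dim not in (1, 2):
        raise ValueError("reference_dim must be 1 or 2")
    if len(ref) < len(traj):
        raise ValueError("reference shorter than trajectory")
    if len(traj) > 1 and not np.allclose(
        ref.time[: len(traj)], traj.time, rtol=1e-9, atol=1e-9
    ):
        raise ValueError("reference and trajectory are not on the same time grid")
    thd = ref.theta_d[: len(traj)]
    omd = ref.theta_dot_d[: len(traj)]
    cols = [traj.theta - thd, traj.theta_dot - omd, thd]
    if reference_dim == 2:
        cols.append(omd)
    return np.column_stack(cols)
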