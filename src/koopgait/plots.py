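"""Overlay figures for prediction and tracking studies (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .plant import RAD2DEG

__all__ = ["prediction_overlay", "tracking_overlay", "input_trace"]


def prediction_overlay(time, actual_theta, predicted_theta, path=None):
    """Actual vs predicted ankle angle over a gait cycle (degrees)."""
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(time, np.asarray(actual_theta) * RAD2DEG, "k-", label="actual")
    ax.plot(time, np.asarray(predicted_theta) * RAD2DEG, "r--", label="predicted")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ankle angle (deg)")
    ax.legend(loc="best")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def tracking_overlay(traj, ref, path=None):
    """Closed-loop tracked angle against the reference profile (degrees)."""
    fig, ax = plt.subplots(figsize=(7, 3))
    n = len(traj)
    ax.plot(traj.time, ref.theta_d[:n] * RAD2DEG, "g--", label="reference")
    ax.plot(traj.time, traj.theta * RAD2DEG, "b-", label="tracked")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ankle angle (deg)")
    ax.legend(loc="best")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def input_trace(traj, path=None):
    """Applied muscle currents and the phase flag over time."""
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(traj.time, traj.u_pf, label="plantarflexor (mA)")
    ax.plot(traj.time, traj.u_df, label="dorsiflexor (mA)")
    ax.fill_between(
        traj.time, 0, traj.sigma * np.max([traj.u_pf.max(), traj.u_df.max(), 1.0]),
        alpha=0.1, step="post", label="swing phase",
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("current (mA)")
    ax.legend(loc="best")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
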