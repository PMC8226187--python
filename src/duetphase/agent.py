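"""Kuramoto-model virtual duet partner.

A single phase oscillator θ with natural frequency attracted toward the
prescribed tempo (ω₀, the 12-note-cycle rate at 72 BPM) is coupled to the
live performer's estimated cycle phase plus the scheduled target offset Δ(t):

    θ̇ = ω + K·sin(θ_live + Δ − θ)
    ω̇ = γ·(ω₀ − ω) + K_f·sin(θ_live + Δ − θ)

Explicit Euler at dt = 10 ms.  With K = K_f = 0 the agent free-runs and its
tempo relaxes exponentially to 72 BPM; with coupling it phase-locks to the
live part whenever the residual detuning is within the locking range.  The
locked trajectory is then used to re-time (time-warp) a prerecorded bottom
part so that prerecorded note k sounds when θ crosses 2πk/12.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from pydantic import BaseModel, Field

from .errors import ControllerError, InsufficientDataError
from .performance import PATTERN_LENGTH, NoteStream

TWO_PI = 2.0 * np.pi
PER_ONSET = TWO_PI / PATTERN_LENGTH


class AgentParams(BaseModel):
    """Controller gains; defaults target the 72 BPM / 12-sixteenth cycle."""

    omega0: float = Field(TWO_PI * 0.6, gt=0)  # cycle rad/s at 72 BPM
    K: float = Field(0.5, ge=0)  # phase coupling, rad/s
    K_f: float | None = Field(None, ge=0)  # frequency coupling; None -> K/10
    gamma: float = Field(0.05, ge=0)  # tempo relaxation rate, 1/s
    dt: float = Field(0.01, gt=0, le=0.05)
    ioi_window: int = Field(12, ge=1)  # IOIs in the live-rate median

    @property
    def k_f(self) -> float:
        return self.K / 10.0 if self.K_f is None else self.K_f


@dataclass(frozen=True)
class AgentState:
    theta: float  # unwrapped cycle phase, rad
    omega: float  # cycle frequency, rad/s
    t: float


@dataclass(frozen=True)
class LivePhaseEstimate:
    theta_live: float
    last_onset_s: float
    onset_index: int
    rate: float  # rad/s used for extrapolation


@dataclass(frozen=True)
class AgentTrajectory:
    time_s: np.ndarray
    theta: np.ndarray
    omega: np.ndarray


def _recent_rate(onsets: np.ndarray, k: int, window: int) -> float:
    """Extrapolation rate from the median of the last ``window`` IOIs."""
    lo = max(0, k - window)
    ioi = np.median(np.diff(onsets[lo : k + 1]))
    return PER_ONSET / ioi


def track_live_phase(
    onsets: NoteStream, t: float, ioi_window: int = 12
) -> LivePhaseEstimate:
    """Causal cycle-phase estimate of the live performer at time ``t``.

    Phase equals 2πk/12 at onset k and advances linearly at the median-IOI
    rate in between, but never by more than one sixteenth (2π/12) beyond the
    last heard onset — the cap keeps the estimate non-decreasing when a long
    (jittered) gap would otherwise make the next onset snap the phase back.
    """
    times = onsets.onsets_s
    k = int(np.searchsorted(times, t, side="right")) - 1
    if k < 1:
        raise InsufficientDataError(
            f"need at least 2 onsets at or before t={t:.3f} s to track phase"
        )
    rate = _recent_rate(times, k, ioi_window)
    advance = min((t - times[k]) * rate, PER_ONSET)
    return LivePhaseEstimate(
        theta_live=PER_ONSET * k + advance,
        last_onset_s=float(times[k]),
        onset_index=k,
        rate=rate,
    )


def step_agent(
    state: AgentState,
    live: LivePhaseEstimate,
    dt: float,
    params: AgentParams,
    target_offset: float = 0.0,
) -> AgentState:
    """One explicit-Euler step of the coupled oscillator."""
    if not 0.0 < dt <= 0.05:
        raise ValueError(f"dt must be in (0, 0.05], got {dt}")
    err = np.sin(live.theta_live + target_offset - state.theta)
    theta = state.theta + state.omega * dt + params.K * err * dt
    omega = (
        state.omega
        + params.gamma * (params.omega0 - state.omega) * dt
        + params.k_f * err * dt
    )
    return AgentState(theta=theta, omega=omega, t=state.t + dt)


def run_free(
    params: AgentParams, duration_s: float, omega_init: float | None = None
) -> AgentTrajectory:
    """Uncoupled run: tempo relaxes exponentially toward ω₀."""
    n = int(round(duration_s / params.dt)) + 1
    t = np.arange(n) * params.dt
    omega = np.empty(n)
    theta = np.empty(n)
    omega[0] = params.omega0 if omega_init is None else omega_init
    theta[0] = 0.0
    for i in range(1, n):
        omega[i] = omega[i - 1] + params.gamma * (params.omega0 - omega[i - 1]) * params.dt
        theta[i] = theta[i - 1] + omega[i - 1] * params.dt
    return AgentTrajectory(t, theta, omega)


def run_closed_loop(
    live: NoteStream,
    target_offset_fn: Callable[[float], float],
    duration_s: float,
    params: AgentParams,
    theta_init: float = 0.0,
    omega_init: float | None = None,
) -> AgentTrajectory:
    """Integrate the agent against a live onset stream.

    Before two live onsets are available the agent free-runs; afterwards it is
    phase-coupled to the tracked live phase plus the scheduled offset.
    """
    dt = params.dt
    n = int(round(duration_s / dt)) + 1
    t_grid = np.arange(n) * dt
    theta = np.empty(n)
    omega = np.empty(n)
    theta[0] = theta_init
    omega[0] = params.omega0 if omega_init is None else omega_init

    times = live.onsets_s
    # precompute per-onset extrapolation rates
    rates = np.array(
        [_recent_rate(times, k, params.ioi_window) for k in range(1, len(times))]
    )
    k = -1  # index of last onset at or before current time
    for i in range(1, n):
        t = t_grid[i - 1]
        while k + 1 < len(times) and times[k + 1] <= t:
            k += 1
        if k >= 1:
            advance = min((t - times[k]) * rates[k - 1], PER_ONSET)
            theta_live = PER_ONSET * k + advance
            err = np.sin(theta_live + target_offset_fn(t) - theta[i - 1])
        else:
            err = 0.0
        theta[i] = theta[i - 1] + omega[i - 1] * dt + params.K * err * dt
        omega[i] = (
            omega[i - 1]
            + params.gamma * (params.omega0 - omega[i - 1]) * dt
            + params.k_f * err * dt
        )
    return AgentTrajectory(t_grid, theta, omega)


def render_agent_stream(
    traj: AgentTrajectory, prerecorded: NoteStream
) -> tuple[NoteStream, Callable[[np.ndarray], np.ndarray]]:
    """Re-time a prerecorded bottom part along the agent's phase trajectory.

    Prerecorded note k sounds at the wall time when the agent phase crosses
    2πk/12.  Also returns the monotone time-warp map (prerecorded time → wall
    time) for re-timing accompanying motion traces.
    """
    dtheta = np.diff(traj.theta)
    if np.any(dtheta < 0):
        raise ControllerError(
            "agent phase is non-monotone; cannot render a note stream"
        )
    theta_end = traj.theta[-1]
    n_notes = 0
    while (
        n_notes < len(prerecorded)
        and PER_ONSET * n_notes <= theta_end - 1e-12
    ):
        n_notes += 1
    targets = PER_ONSET * np.arange(n_notes)
    wall = np.interp(targets, traj.theta, traj.time_s)
    wall = np.maximum.accumulate(wall + np.arange(n_notes) * 1e-12)
    stream = NoteStream(
        onsets_s=wall,
        pitches=prerecorded.pitches[:n_notes],
        velocities=prerecorded.velocities[:n_notes],
        performer_id=prerecorded.performer_id + "-warped",
    )
    pre_phase = PER_ONSET * np.arange(len(prerecorded))

    def warp(times: np.ndarray) -> np.ndarray:
        """Map prerecorded time to wall time via the shared phase axis."""
        phase = np.interp(np.asarray(times, float), prerecorded.onsets_s, pre_phase)
        return np.interp(phase, traj.theta, traj.time_s)

    return stream, warp
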