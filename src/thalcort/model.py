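"""The thalamocortical ODE system and its fixed-step RK4 integrator.

Five coupled populations: cortical pyramidal cells (PY), fast (IN1) and
slow (IN2) cortical interneurons, thalamocortical relay cells (TC) and the
reticular nucleus (RE).  Cortical outputs pass through the steep sigmoid
``f(x) = 1 / (1 + nu**(-x))``; the thalamic subsystem is simplified with
the linear activation ``s(x) = alpha*x + beta``.  The governing equations:

    dPY/dt  = tau1 * (eps1 - PY + k1*f(PY) - k2*f(IN1) - k3*f(IN2) + k4*f(TC))
    dIN1/dt = tau2 * (eps2 - IN1 + k5*f(PY) - k6*f(IN2))
    dIN2/dt = tau3 * (eps3 - IN2 + k7*f(PY) - k8*f(IN1))
    dTC/dt  = tau4 * (eps4 - TC - k9*s(RE) + k10*f(PY))
    dRE/dt  = tau5 * (eps5 - RE - k11*s(RE) + k12*s(TC) + k13*f(PY))

Excitatory sources (PY, TC) enter with positive sign, inhibitory sources
(IN1, IN2, RE) with negative sign.  Integration is deliberately fixed-step
classical RK4 so that runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import (
    PARAM_VECTOR_NAMES,
    STATE_NAMES,
    ModelParameters,
    SimulationConfig,
)
from .protocol import StimulusProtocol

__all__ = [
    "sigmoid_activation",
    "linear_activation",
    "model_rhs",
    "simulate",
    "Trajectory",
    "IntegrationError",
]

# Exponent clip keeping nu**(-x) finite in double precision.
_EXP_CLIP = 700.0


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


def sigmoid_activation(x, nu):
    """Sigmoid firing-rate function ``1 / (1 + nu**(-x))``.

    Strictly increasing with range (0, 1); ``nu`` sets the steepness
    (the reference value 2.5e5 makes it nearly a step at 0).
    """
    if not nu > 1:
        raise ValueError("sigmoid steepness nu must exceed 1")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid input must be finite")
    z = np.clip(-x * math.log(nu), -_EXP_CLIP, _EXP_CLIP)
    out = 1.0 / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def linear_activation(x, alpha=2.8, beta=0.5):
    """Linear activation ``alpha*x + beta`` used for TC and RE."""
    x = np.asarray(x, dtype=float)
    out = alpha * x + beta
    return float(out) if out.ndim == 0 else out


@njit(cache=True, inline="always")
def _f(x, log_nu):
    z = -x * log_nu
    if z > _EXP_CLIP:
        z = _EXP_CLIP
    elif z < -_EXP_CLIP:
        z = -_EXP_CLIP
    return 1.0 / (1.0 + math.exp(z))


@njit(cache=True, inline="always")
def _rhs(y, p, log_nu, u_py, u_in1, out):
    alpha = p[24]
    beta = p[25]
    f_py = _f(y[0], log_nu)
    f_in1 = _f(y[1], log_nu)
    f_in2 = _f(y[2], log_nu)
    f_tc = _f(y[3], log_nu)
    s_tc = alpha * y[3] + beta
    s_re = alpha * y[4] + beta
    # p layout: eps1..5 | tau1..5 | k1..k13 | nu alpha beta
    out[0] = p[5] * (p[0] - y[0] + p[10] * f_py - p[11] * f_in1
                     - p[12] * f_in2 + p[13] * f_tc) + u_py
    out[1] = p[6] * (p[1] - y[1] + p[14] * f_py - p[15] * f_in2) + u_in1
    out[2] = p[7] * (p[2] - y[2] + p[16] * f_py - p[17] * f_in1)
    out[3] = p[8] * (p[3] - y[3] - p[18] * s_re + p[19] * f_py)
    out[4] = p[9] * (p[4] - y[4] - p[20] * s_re + p[21] * s_tc + p[22] * f_py)


@njit(cache=True)
def _integrate(y0, p, dt, n_steps,
               jump_steps, jump_py, jump_in1,
               pulse_on, pulse_off, pulse_py, pulse_in1,
               sched_idx, sched_vals):
    """Classical RK4 with state-jump and rectangular-pulse events.

    Returns (states, status): states has shape (n_steps+1, 5); status is
    -1 on success, else the index of the first non-finite step.
    """
    log_nu = math.log(p[23])
    ys = np.empty((n_steps + 1, 5))
    y = y0.copy()
    ys[0] = y
    k1v = np.empty(5)
    k2v = np.empty(5)
    k3v = np.empty(5)
    k4v = np.empty(5)
    ytmp = np.empty(5)
    pw = p.copy()
    n_jumps = jump_steps.shape[0]
    n_pulses = pulse_on.shape[0]
    jptr = 0
    for i in range(n_steps):
        # state-jump events fire at the first grid point >= event time
        while jptr < n_jumps and jump_steps[jptr] == i:
            y[0] += jump_py[jptr]
            y[1] += jump_in1[jptr]
            jptr += 1
        u_py = 0.0
        u_in1 = 0.0
        for q in range(n_pulses):
            if pulse_on[q] <= i < pulse_off[q]:
                u_py += pulse_py[q]
                u_in1 += pulse_in1[q]
        if sched_idx >= 0:
            v0 = sched_vals[i]
            v1 = sched_vals[i + 1]
            vm = 0.5 * (v0 + v1)
        else:
            v0 = v1 = vm = 0.0
        if sched_idx >= 0:
            pw[sched_idx] = v0
        _rhs(y, pw, log_nu, u_py, u_in1, k1v)
        if sched_idx >= 0:
            pw[sched_idx] = vm
        for j in range(5):
            ytmp[j] = y[j] + 0.5 * dt * k1v[j]
        _rhs(ytmp, pw, log_nu, u_py, u_in1, k2v)
        for j in range(5):
            ytmp[j] = y[j] + 0.5 * dt * k2v[j]
        _rhs(ytmp, pw, log_nu, u_py, u_in1, k3v)
        if sched_idx >= 0:
            pw[sched_idx] = v1
        for j in range(5):
            ytmp[j] = y[j] + dt * k3v[j]
        _rhs(ytmp, pw, log_nu, u_py, u_in1, k4v)
        ok = True
        for j in range(5):
            y[j] = y[j] + (dt / 6.0) * (k1v[j] + 2.0 * k2v[j]
                                        + 2.0 * k3v[j] + k4v[j])
            if not math.isfinite(y[j]):
                ok = False
        ys[i + 1] = y
        if not ok:
            return ys, i + 1
    # trailing jump exactly at the final grid point
    while jptr < n_jumps and jump_steps[jptr] == n_steps:
        ys[n_steps, 0] += jump_py[jptr]
        ys[n_steps, 1] += jump_in1[jptr]
        jptr += 1
    return ys, -1


def model_rhs(state, params: ModelParameters) -> np.ndarray:
    """Time-derivative of the five populations at ``state`` (no stimulus)."""
    y = np.asarray(state, dtype=float)
    if y.shape != (5,):
        raise ValueError("state must be a 5-vector (PY, IN1, IN2, TC, RE)")
    if not np.all(np.isfinite(y)):
        raise ValueError("state must be finite")
    out = np.empty(5)
    _rhs(y, params.to_vector(), math.log(params.nu), 0.0, 0.0, out)
    return out


@dataclass(frozen=True)
class Trajectory:
    """A simulated orbit: time grid, state matrix and the cortical mean
    observable (PY + IN1)/2 used for all analyses."""

    time: np.ndarray
    states: np.ndarray
    dt: float
    transient_discard: float = 0.0

    def __post_init__(self) -> None:
        if self.time.shape[0] != self.states.shape[0]:
            raise ValueError("time grid and state matrix lengths differ")

    @property
    def cortical_mean(self) -> np.ndarray:
        return 0.5 * (self.states[:, 0] + self.states[:, 1])

    def __getattr__(self, name: str):
        if name in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(name)]
        raise AttributeError(name)

    def window(self, t_start: float, t_end: float | None = None) -> np.ndarray:
        """Cortical-mean samples with time in [t_start, t_end]."""
        mask = self.time >= t_start
        if t_end is not None:
            mask &= self.time <= t_end
        return self.cortical_mean[mask]

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.time,
                **{n: self.states[:, i] for i, n in enumerate(STATE_NAMES)},
                "mean": self.cortical_mean,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        expected = ["t", *STATE_NAMES, "mean"]
        if list(df.columns) != expected:
            raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
        time = df["t"].to_numpy()
        dt = float(time[1] - time[0]) if len(time) > 1 else 0.0
        return cls(time=time, states=df[list(STATE_NAMES)].to_numpy(), dt=dt)


def _protocol_arrays(protocol: StimulusProtocol, dt: float, n_steps: int):
    jumps, pulses = [], []
    for ev in protocol.events:
        if ev.time < 0 or ev.time > n_steps * dt:
            raise ValueError(
                f"stimulus event at t={ev.time} outside the simulation window"
            )
        amp = ev.signed_amplitude
        d_py = amp if "PY" in ev.targets else 0.0
        d_in1 = amp if "IN1" in ev.targets else 0.0
        step = int(math.ceil(ev.time / dt - 1e-9))
        if ev.mode == "jump":
            jumps.append((step, d_py, d_in1))
        else:
            off = step + max(1, int(round(ev.duration / dt)))
            pulses.append((step, min(off, n_steps), d_py, d_in1))
    jumps.sort(key=lambda r: r[0])
    jump_steps = np.array([j[0] for j in jumps], dtype=np.int64)
    jump_py = np.array([j[1] for j in jumps], dtype=float)
    jump_in1 = np.array([j[2] for j in jumps], dtype=float)
    pulse_on = np.array([q[0] for q in pulses], dtype=np.int64)
    pulse_off = np.array([q[1] for q in pulses], dtype=np.int64)
    pulse_py = np.array([q[2] for q in pulses], dtype=float)
    pulse_in1 = np.array([q[3] for q in pulses], dtype=float)
    return jump_steps, jump_py, jump_in1, pulse_on, pulse_off, pulse_py, pulse_in1


def simulate(
    params: ModelParameters,
    config: SimulationConfig | None = None,
    protocol: StimulusProtocol | None = None,
) -> Trajectory:
    """Integrate the model with fixed-step RK4 under a stimulation protocol.

    Raises :class:`IntegrationError` if the state becomes non-finite,
    reporting the failing step and parameter set.
    """
    config = config or SimulationConfig()
    protocol = protocol or StimulusProtocol.none()
    n = config.n_steps
    dt = config.dt
    arrays = _protocol_arrays(protocol, dt, n)
    if config.schedule is not None:
        sched_idx = PARAM_VECTOR_NAMES.index(config.schedule.name)
        times = np.arange(n + 1) * dt
        sched_vals = config.schedule.values(times)
    else:
        sched_idx = -1
        sched_vals = np.zeros(1)
    states, status = _integrate(
        np.asarray(config.initial_state, dtype=float),
        params.to_vector(),
        dt,
        n,
        *arrays,
        sched_idx,
        sched_vals,
    )
    if status >= 0:
        raise IntegrationError(
            f"non-finite state at step {status} (t={status * dt:.3f} s) "
            f"with parameters {params}"
        )
    time = np.arange(n + 1) * dt
    return Trajectory(
        time=time,
        states=states,
        dt=dt,
        transient_discard=config.transient_discard,
    )
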