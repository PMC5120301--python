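"""Model parameters, initial state and simulation configuration.

The model is a five-population neural-field (neural mass) description of a
thalamocortical circuit: cortical pyramidal cells (PY), a fast GABA_A-like
interneuron population (IN1), a slow GABA_B-like interneuron population
(IN2), thalamocortical relay cells (TC) and the thalamic reticular nucleus
(RE).  All quantities are dimensionless population activities; time is in
seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Names of the five state variables, in storage order.
STATE_NAMES = ("PY", "IN1", "IN2", "TC", "RE")

#: Initial condition used throughout the dynamical analyses.  It sits close
#: to the background (low saturated) equilibrium at the reference coupling
#: (k4, k10) = (1, 3), on the non-seizure side of the separatrix in the
#: bistable regions.
DEFAULT_INITIAL_STATE = np.array([0.1724, 0.1787, 0.1803, -0.0818, 0.2775])

# Order of the flattened parameter vector consumed by the integration kernel.
PARAM_VECTOR_NAMES = (
    "eps1", "eps2", "eps3", "eps4", "eps5",
    "tau1", "tau2", "tau3", "tau4", "tau5",
    "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9",
    "k10", "k11", "k12", "k13",
    "nu", "alpha", "beta",
)


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the thalamocortical ODE system.

    Defaults are the reference parameter set of the modified Taylor model:
    additive input constants ``eps1..eps5``, time-scale multipliers
    ``tau1..tau5`` (the whole right-hand side of each population is scaled
    by its tau, so a small ``tau3`` makes IN2 slow), thirteen non-negative
    coupling strengths ``k1..k13``, the sigmoid steepness ``nu`` used for
    the cortical populations, and the slope/offset ``alpha``/``beta`` of
    the linear activation used for the thalamic populations.

    Couplings (source -> target):
      k1 PY->PY, k2 IN1->PY, k3 IN2->PY, k4 TC->PY, k5 PY->IN1,
      k6 IN2->IN1, k7 PY->IN2, k8 IN1->IN2, k9 RE->TC, k10 PY->TC,
      k11 RE->RE, k12 TC->RE, k13 PY->RE.
    """

    eps1: float = -0.35
    eps2: float = -3.4
    eps3: float = -4.4
    eps4: float = -2.0
    eps5: float = -5.0
    tau1: float = 26.0
    tau2: float = 26.0 * 1.25
    tau3: float = 26.0 * 0.005
    tau4: float = 26.0 * 0.1
    tau5: float = 26.0 * 0.1
    k1: float = 1.8
    k2: float = 1.5
    k3: float = 0.03
    k4: float = 1.0
    k5: float = 4.0
    k6: float = 0.03
    k7: float = 3.0
    k8: float = 1.5
    k9: float = 0.6
    k10: float = 3.0
    k11: float = 0.2
    k12: float = 10.5
    k13: float = 3.0
    nu: float = 2.5e5
    alpha: float = 2.8
    beta: float = 0.5

    def __post_init__(self) -> None:
        for i in range(1, 14):
            if getattr(self, f"k{i}") < 0:
                raise ValueError(f"k{i} must be non-negative")
        if not self.nu > 1:
            raise ValueError("sigmoid steepness nu must exceed 1")
        for i in range(1, 6):
            if not getattr(self, f"tau{i}") > 0:
                raise ValueError(f"tau{i} must be positive")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields overridden."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_vector(self) -> np.ndarray:
        """Flatten to the 26-element vector used by the RK4 kernel."""
        return np.array([getattr(self, n) for n in PARAM_VECTOR_NAMES])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ModelParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_VECTOR_NAMES),):
            raise ValueError(
                f"parameter vector must have length {len(PARAM_VECTOR_NAMES)}"
            )
        return cls(**dict(zip(PARAM_VECTOR_NAMES, vec)))


@dataclass(frozen=True)
class ParameterRamp:
    """Linear schedule for one parameter: value(t) interpolates start->end
    over [t_start, t_end], clamped outside."""

    name: str
    start_value: float
    end_value: float
    t_start: float = 0.0
    t_end: float = 200.0

    def __post_init__(self) -> None:
        if self.name not in PARAM_VECTOR_NAMES:
            raise ValueError(f"unknown parameter {self.name!r}")
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")

    def values(self, times: np.ndarray) -> np.ndarray:
        frac = np.clip((times - self.t_start) / (self.t_end - self.t_start), 0.0, 1.0)
        return self.start_value + frac * (self.end_value - self.start_value)


@dataclass(frozen=True)
class SimulationConfig:
    """Fixed-step integration settings.

    ``dt`` is the RK4 step (1 ms by default); ``duration`` the simulated
    time; ``transient_discard`` the leading interval dropped before any
    spectral or extrema analysis.
    """

    dt: float = 0.001
    duration: float = 20.0
    transient_discard: float = 5.0
    initial_state: np.ndarray = field(
        default_factory=lambda: DEFAULT_INITIAL_STATE.copy()
    )
    schedule: ParameterRamp | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.transient_discard < self.duration:
            raise ValueError("transient_discard must be smaller than duration")
        state = np.asarray(self.initial_state, dtype=float)
        if state.shape != (5,) or not np.all(np.isfinite(state)):
            raise ValueError("initial_state must be a finite 5-vector")
        object.__setattr__(self, "initial_state", state)

    def replace(self, **overrides) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))
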