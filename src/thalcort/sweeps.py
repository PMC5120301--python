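"""Parameter sweeps: 1-D bifurcation scans, 2-D state maps, double-pulse
protocols, threshold searches, and slow parameter ramps.

A swept "axis" is either a single parameter name (``"k4"``) or several
names tied to a common value (``"k3+k6"`` or ``("k3", "k6")``).  Tied axes
express joint modulation of one population's outputs: strengthening the
slow interneurons IN2 raises both of their couplings (k3 to PY and k6 to
IN1) together, and likewise the fast interneurons IN1 drive both k2 and k8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (
    ClassifierConfig,
    DEFAULT_CLASSIFIER,
    OscillationSummary,
    StateLabel,
    classify_state,
    summarize,
)
from .model import IntegrationError, Trajectory, simulate
from .params import ModelParameters, ParameterRamp, SimulationConfig
from .protocol import StimulusProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "apply_axis",
    "BifurcationScan",
    "StateMap",
    "PulsePlaneMap",
    "RampResult",
    "scan_1d",
    "state_map_2d",
    "double_pulse_outcome",
    "pulse_plane_map",
    "threshold_search",
    "ramp_simulation",
]

#: Default initiation magnitude and timing of the induce/abate protocol.
DEFAULT_PULSE_MAGNITUDE = 0.3
DEFAULT_T_INITIATION = 20.0
DEFAULT_T_TERMINATION = 35.0
DEFAULT_PULSED_DURATION = 50.0


def _axis_names(axis) -> tuple[str, ...]:
    if isinstance(axis, str):
        return tuple(axis.split("+"))
    return tuple(axis)


def apply_axis(params: ModelParameters, axis, value: float) -> ModelParameters:
    """Return parameters with every name of the axis set to ``value``."""
    return params.replace(**{n: float(value) for n in _axis_names(axis)})


def _axis_label(axis) -> str:
    return "+".join(_axis_names(axis))


def _analyze(traj: Trajectory, t_start: float, classifier: ClassifierConfig):
    window = traj.window(t_start)
    return classify_state(window, traj.dt, classifier, return_summary=True)


@dataclass
class BifurcationScan:
    """Per-grid-value extrema, dominant frequency and state label."""

    axis: str
    grid: np.ndarray
    labels: list[StateLabel]
    summaries: list[OscillationSummary]
    mode: str
    stimulus_condition: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, lab, s in zip(self.grid, self.labels, self.summaries):
            rows.append(
                {
                    self.axis: v,
                    "label": lab.value,
                    "dominant_frequency_hz": s.dominant_frequency_hz,
                    "amplitude": s.amplitude,
                    "mean_level": s.mean_level,
                    "max_of_maxima": s.maxima.max() if len(s.maxima) else np.nan,
                    "min_of_minima": s.minima.min() if len(s.minima) else np.nan,
                    "maxima_per_cycle": s.maxima_per_cycle,
                }
            )
        return pd.DataFrame(rows)


_EMPTY_SUMMARY = OscillationSummary(
    maxima=np.array([]),
    minima=np.array([]),
    amplitude=np.nan,
    dominant_frequency_hz=np.nan,
    maxima_per_cycle=0,
    n_maxima_clusters=0,
    mean_level=np.nan,
)


def scan_1d(
    params: ModelParameters,
    axis,
    grid,
    mode: str = "fixed",
    stimulus_condition: str = "none",
    config: SimulationConfig | None = None,
    pulse_magnitude: float = DEFAULT_PULSE_MAGNITUDE,
    classifier: ClassifierConfig | None = None,
) -> BifurcationScan:
    """Sweep one axis, simulating and classifying at every grid value.

    ``mode`` is ``fixed`` (same initial state everywhere),
    ``inherited-forward`` or ``inherited-backward`` (the end state of each
    run seeds the next, walking the grid up or down; forward/backward
    runs differ only inside bistable windows).  With
    ``stimulus_condition="with-initiation-pulse"`` each run lasts 50 s and
    receives an initiation perturbation at 20 s before analysis.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) > 1 and not (np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("grid must be strictly monotone")
    classifier = classifier or DEFAULT_CLASSIFIER
    if stimulus_condition == "with-initiation-pulse":
        base_cfg = config or SimulationConfig(
            duration=DEFAULT_PULSED_DURATION,
            transient_discard=DEFAULT_T_INITIATION + 5.0,
        )
        protocol = StimulusProtocol.single(DEFAULT_T_INITIATION, pulse_magnitude)
    elif stimulus_condition == "none":
        base_cfg = config or SimulationConfig()
        protocol = StimulusProtocol.none()
    else:
        raise ValueError(f"unknown stimulus_condition {stimulus_condition!r}")

    order = range(len(grid))
    if mode == "inherited-backward":
        order = range(len(grid) - 1, -1, -1)
    elif mode not in ("fixed", "inherited-forward"):
        raise ValueError(f"unknown scan mode {mode!r}")

    labels: list = [None] * len(grid)
    summaries: list = [None] * len(grid)
    state = base_cfg.initial_state
    for i in order:
        p_i = apply_axis(params, axis, grid[i])
        cfg = base_cfg if mode == "fixed" else base_cfg.replace(initial_state=state)
        try:
            traj = simulate(p_i, cfg, protocol)
        except IntegrationError as exc:
            logger.warning("scan cell %s=%g failed: %s", _axis_label(axis), grid[i], exc)
            labels[i] = StateLabel.FAILED
            summaries[i] = _EMPTY_SUMMARY
            continue
        if mode != "fixed":
            state = traj.final_state()
        labels[i], summaries[i] = _analyze(traj, cfg.transient_discard, classifier)
    return BifurcationScan(
        axis=_axis_label(axis),
        grid=grid,
        labels=labels,
        summaries=summaries,
        mode=mode,
        stimulus_condition=stimulus_condition,
    )


@dataclass
class StateMap:
    """Labels over a 2-D parameter grid.

    Cells whose unstimulated run is the low-saturated background but whose
    pulsed run shows SWD are labelled STIMULUS_INDUCED_SWD; cells already
    discharging without stimulation are SPONTANEOUS_SWD.
    """

    axis_x: str
    axis_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    labels: np.ndarray  # shape (len(grid_y), len(grid_x)), dtype=object
    frequencies: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iy, vy in enumerate(self.grid_y):
            for ix, vx in enumerate(self.grid_x):
                rows.append(
                    {
                        self.axis_x: vx,
                        self.axis_y: vy,
                        "label": self.labels[iy, ix].value,
                        "dominant_frequency_hz": self.frequencies[iy, ix],
                    }
                )
        return pd.DataFrame(rows)


def state_map_2d(
    params: ModelParameters,
    axes: tuple,
    grids: tuple,
    config: SimulationConfig | None = None,
    pulse_magnitude: float = DEFAULT_PULSE_MAGNITUDE,
    classifier: ClassifierConfig | None = None,
) -> StateMap:
    """Label every cell of a 2-D parameter plane.

    Each cell is first simulated without stimulation; background
    (SATURATED_LOW) cells are re-run with the initiation pulse to detect
    stimulus-induced SWD.
    """
    axis_x, axis_y = axes
    grid_x = np.asarray(grids[0], dtype=float)
    grid_y = np.asarray(grids[1], dtype=float)
    classifier = classifier or DEFAULT_CLASSIFIER
    base_cfg = config or SimulationConfig()
    labels = np.empty((len(grid_y), len(grid_x)), dtype=object)
    freqs = np.full((len(grid_y), len(grid_x)), np.nan)
    pulsed_cfg = SimulationConfig(
        dt=base_cfg.dt,
        duration=DEFAULT_PULSED_DURATION,
        transient_discard=DEFAULT_T_INITIATION + 5.0,
        initial_state=base_cfg.initial_state,
    )
    protocol = StimulusProtocol.single(DEFAULT_T_INITIATION, pulse_magnitude)
    for iy, vy in enumerate(grid_y):
        for ix, vx in enumerate(grid_x):
            p_cell = apply_axis(apply_axis(params, axis_x, vx), axis_y, vy)
            try:
                traj = simulate(p_cell, base_cfg)
            except IntegrationError as exc:
                logger.warning("map cell (%g, %g) failed: %s", vx, vy, exc)
                labels[iy, ix] = StateLabel.FAILED
                continue
            label, s = _analyze(traj, base_cfg.transient_discard, classifier)
            freqs[iy, ix] = s.dominant_frequency_hz
            if label is StateLabel.SWD:
                label = StateLabel.SPONTANEOUS_SWD
            elif label is StateLabel.SATURATED_LOW:
                try:
                    traj_p = simulate(p_cell, pulsed_cfg, protocol)
                except IntegrationError:
                    traj_p = None
                if traj_p is not None:
                    lab_p, s_p = _analyze(
                        traj_p, pulsed_cfg.transient_discard, classifier
                    )
                    if lab_p is StateLabel.SWD:
                        label = StateLabel.STIMULUS_INDUCED_SWD
                        freqs[iy, ix] = s_p.dominant_frequency_hz
            labels[iy, ix] = label
    return StateMap(
        axis_x=_axis_label(axis_x),
        axis_y=_axis_label(axis_y),
        grid_x=grid_x,
        grid_y=grid_y,
        labels=labels,
        frequencies=freqs,
    )


def double_pulse_outcome(
    params: ModelParameters,
    initiation: float,
    termination: float,
    t_initiation: float = DEFAULT_T_INITIATION,
    t_termination: float = DEFAULT_T_TERMINATION,
    duration: float = DEFAULT_PULSED_DURATION,
    classifier: ClassifierConfig | None = None,
    config: SimulationConfig | None = None,
) -> str:
    """Outcome of the two-pulse induce/abate protocol, one of A-D.

    A: neither pulse induces SWD.  B: the first pulse fails but the second
    initiates SWD.  C: SWD is induced and survives the second pulse.
    D: SWD is induced and the second pulse restores the background.
    Each verdict classifies the final 10 s of its window to skip the
    excitable transients that follow a pulse.
    """
    if not t_initiation < t_termination < duration:
        raise ValueError("need t_initiation < t_termination < duration")
    classifier = classifier or DEFAULT_CLASSIFIER
    cfg = (config or SimulationConfig()).replace(
        duration=duration, transient_discard=t_initiation
    )
    protocol = StimulusProtocol.double(
        initiation, termination, t_initiation, t_termination
    )
    traj = simulate(params, cfg, protocol)
    w1 = traj.window(max(t_initiation, t_termination - 10.0), t_termination)
    w2 = traj.window(duration - 10.0)
    swd1 = classify_state(w1, traj.dt, classifier) is StateLabel.SWD
    swd2 = classify_state(w2, traj.dt, classifier) is StateLabel.SWD
    if swd1:
        return "C" if swd2 else "D"
    return "B" if swd2 else "A"


@dataclass
class PulsePlaneMap:
    """Region label (A-D) per (initiation, termination) amplitude cell."""

    grid_initiation: np.ndarray
    grid_termination: np.ndarray
    regions: np.ndarray  # shape (len(grid_termination), len(grid_initiation))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it, T in enumerate(self.grid_termination):
            for ii, I in enumerate(self.grid_initiation):
                rows.append(
                    {"initiation": I, "termination": T, "region": self.regions[it, ii]}
                )
        return pd.DataFrame(rows)


def pulse_plane_map(
    params: ModelParameters,
    grid_initiation,
    grid_termination,
    **kwargs,
) -> PulsePlaneMap:
    """Evaluate :func:`double_pulse_outcome` over an amplitude plane."""
    gi = np.asarray(grid_initiation, dtype=float)
    gt = np.asarray(grid_termination, dtype=float)
    regions = np.empty((len(gt), len(gi)), dtype=object)
    for it, T in enumerate(gt):
        for ii, I in enumerate(gi):
            regions[it, ii] = double_pulse_outcome(params, I, T, **kwargs)
    return PulsePlaneMap(grid_initiation=gi, grid_termination=gt, regions=regions)


def threshold_search(
    predicate,
    low: float,
    high: float,
    resolution: float = 0.005,
) -> float:
    """Smallest magnitude in [low, high] at which ``predicate`` succeeds.

    Bisection between a failing and a succeeding endpoint, refined to
    ``resolution``.  If the predicate already succeeds at ``low`` that
    endpoint is returned; if it fails everywhere a ValueError reports both
    endpoint outcomes.
    """
    if not high > low:
        raise ValueError("need high > low")
    ok_low = bool(predicate(low))
    if ok_low:
        return low
    ok_high = bool(predicate(high))
    if not ok_high:
        raise ValueError(
            f"no bracket: predicate fails at both {low} (False) and {high} (False)"
        )
    while high - low > resolution:
        mid = 0.5 * (low + high)
        if predicate(mid):
            high = mid
        else:
            low = mid
    return high


def _debounced_runs(times, labels, min_run: int):
    """Contiguous runs of equal labels lasting at least ``min_run`` windows.

    UNCLASSIFIED windows and shorter runs are treated as transitional and
    dropped: single windows straddling a regime change often misclassify
    while the new attractor is still being approached.
    """
    runs = []
    for t, lab in zip(times, labels):
        if lab is StateLabel.UNCLASSIFIED:
            continue
        if runs and runs[-1][0] is lab:
            runs[-1][2] = t
            runs[-1][3] += 1
        else:
            runs.append([lab, t, t, 1])
    kept = [r for r in runs if r[3] >= min_run]
    merged = []
    for lab, t_first, t_last, n in kept:
        if merged and merged[-1][0] is lab:
            merged[-1][2] = t_last
        else:
            merged.append([lab, t_first, t_last])
    return merged


@dataclass
class RampResult:
    """Outcome of a slow linear parameter ramp."""

    ramp: ParameterRamp
    trajectory: Trajectory
    window_times: np.ndarray  # centres of the classified sliding windows
    window_labels: list[StateLabel]
    min_run: int = 5
    transitions: list[tuple[float, StateLabel, StateLabel]] = field(
        default_factory=list
    )

    def label_sequence(self) -> list[StateLabel]:
        """Distinct persistent regimes in order of appearance."""
        return [
            lab
            for lab, _, _ in _debounced_runs(
                self.window_times, self.window_labels, self.min_run
            )
        ]


def ramp_simulation(
    params: ModelParameters,
    ramp: ParameterRamp,
    protocol: StimulusProtocol | None = None,
    dt: float = 0.001,
    window: float = 5.0,
    step: float = 1.0,
    classifier: ClassifierConfig | None = None,
    min_run: int = 5,
) -> RampResult:
    """Simulate a time-varying parameter and track regime changes.

    One long run with the parameter following the linear schedule; a
    sliding window (default 5 s every 1 s) is classified and label-change
    timings are recorded.  Windows straddling a transition often come out
    UNCLASSIFIED; they are skipped when timing the transitions.
    """
    classifier = classifier or DEFAULT_CLASSIFIER
    cfg = SimulationConfig(
        dt=dt,
        duration=ramp.t_end,
        transient_discard=min(5.0, 0.5 * ramp.t_end),
        schedule=ramp,
    )
    traj = simulate(params, cfg, protocol)
    centres = []
    labels = []
    t0 = 0.0
    while t0 + window <= ramp.t_end + 1e-9:
        w = traj.window(t0, t0 + window)
        # remove the linear drift the moving parameter imposes on a
        # (quasi-)steady state, keeping the window mean for the
        # low/high saturation split
        x = np.arange(len(w))
        slope = np.polyfit(x, w, 1)[0]
        detrended = w - slope * (x - x.mean())
        labels.append(classify_state(detrended, dt, classifier))
        centres.append(t0 + 0.5 * window)
        t0 += step
    runs = _debounced_runs(centres, labels, min_run)
    transitions = [
        (0.5 * (runs[i - 1][2] + runs[i][1]), runs[i - 1][0], runs[i][0])
        for i in range(1, len(runs))
    ]
    return RampResult(
        ramp=ramp,
        trajectory=traj,
        window_times=np.asarray(centres),
        window_labels=labels,
        min_run=min_run,
        transitions=transitions,
    )
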