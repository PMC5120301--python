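"""Equilibrium continuation and bifurcation detection.

The toolkit characterises the organisation of the model's attractors along
one parameter: equilibrium branches with Jacobian spectra, Hopf points
(complex eigenpair crossing the imaginary axis), folds of limit cycles
(located by inherited-state simulation, without Floquet machinery), and
bistable intervals where the background equilibrium coexists with a
large-amplitude discharge cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .analysis import ClassifierConfig, DEFAULT_CLASSIFIER, StateLabel, classify_state
from .model import model_rhs, simulate
from .params import DEFAULT_INITIAL_STATE, ModelParameters, SimulationConfig
from .protocol import StimulusProtocol
from .sweeps import apply_axis, _axis_label

logger = logging.getLogger(__name__)

__all__ = [
    "find_equilibrium",
    "jacobian",
    "EquilibriumBranch",
    "equilibrium_branch",
    "BifurcationPoint",
    "locate_hopf",
    "locate_cycle_fold",
    "BistableInterval",
    "bistable_intervals",
    "settle_on_cycle",
]

_RESIDUAL_TOL = 1e-10
_NEWTON_MAX_ITER = 100


def jacobian(params: ModelParameters, state, method: str = "fd") -> np.ndarray:
    """5x5 Jacobian of the vector field at ``state``.

    ``method="fd"`` uses central finite differences with step
    ``1e-6 * (1 + |x_j|)``; ``method="analytic"`` differentiates the
    sigmoid/linear activations exactly (f' = ln(nu) f (1-f), s' = alpha).
    The two agree to ~1e-6 relative.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (5,) or not np.all(np.isfinite(y)):
        raise ValueError("state must be a finite 5-vector")
    if method == "fd":
        J = np.empty((5, 5))
        for j in range(5):
            h = 1e-6 * (1.0 + abs(y[j]))
            yp = y.copy()
            ym = y.copy()
            yp[j] += h
            ym[j] -= h
            J[:, j] = (model_rhs(yp, params) - model_rhs(ym, params)) / (2.0 * h)
        return J
    if method != "analytic":
        raise ValueError(f"unknown jacobian method {method!r}")
    p = params
    log_nu = math.log(p.nu)

    def fp(x):
        f = 1.0 / (1.0 + math.exp(min(max(-x * log_nu, -700.0), 700.0)))
        return log_nu * f * (1.0 - f)

    d_py, d_in1, d_in2, d_tc = fp(y[0]), fp(y[1]), fp(y[2]), fp(y[3])
    a = p.alpha
    J = np.array(
        [
            [p.tau1 * (-1 + p.k1 * d_py), -p.tau1 * p.k2 * d_in1,
             -p.tau1 * p.k3 * d_in2, p.tau1 * p.k4 * d_tc, 0.0],
            [p.tau2 * p.k5 * d_py, -p.tau2, -p.tau2 * p.k6 * d_in2, 0.0, 0.0],
            [p.tau3 * p.k7 * d_py, -p.tau3 * p.k8 * d_in1, -p.tau3, 0.0, 0.0],
            [p.tau4 * p.k10 * d_py, 0.0, 0.0, -p.tau4, -p.tau4 * p.k9 * a],
            [p.tau5 * p.k13 * d_py, 0.0, 0.0, p.tau5 * p.k12 * a,
             p.tau5 * (-1 - p.k11 * a)],
        ]
    )
    return J


def find_equilibrium(params: ModelParameters, guess=None) -> np.ndarray:
    """Damped Newton solve of ``model_rhs = 0`` from ``guess``.

    The step is halved while the residual max-norm would increase.
    Converges to residual < 1e-10 or raises after 100 iterations.
    """
    y = np.asarray(
        DEFAULT_INITIAL_STATE if guess is None else guess, dtype=float
    ).copy()
    if not np.all(np.isfinite(y)):
        raise ValueError("guess must be finite")
    res = model_rhs(y, params)
    res_norm = np.max(np.abs(res))
    for _ in range(_NEWTON_MAX_ITER):
        if res_norm < _RESIDUAL_TOL:
            return y
        J = jacobian(params, y, method="fd")
        try:
            delta = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular Jacobian during Newton solve: {exc}")
        lam = 1.0
        while lam > 1e-6:
            y_new = y + lam * delta
            res_new = model_rhs(y_new, params)
            new_norm = np.max(np.abs(res_new))
            if new_norm < res_norm or new_norm < _RESIDUAL_TOL:
                break
            lam *= 0.5
        y, res, res_norm = y_new, res_new, new_norm
    if res_norm < _RESIDUAL_TOL:
        return y
    raise ValueError(
        f"Newton did not converge in {_NEWTON_MAX_ITER} iterations "
        f"(last residual max-norm {res_norm:.3e})"
    )


@dataclass
class EquilibriumBranch:
    """Equilibrium curve along one axis with eigenvalue spectra."""

    axis: str
    grid: np.ndarray
    equilibria: np.ndarray  # (n, 5)
    eigenvalues: np.ndarray  # (n, 5) complex
    stable: np.ndarray  # (n,) bool

    def to_frame(self):
        import pandas as pd

        from .params import STATE_NAMES

        rows = []
        for i, v in enumerate(self.grid):
            row = {self.axis: v}
            row.update(
                {n: self.equilibria[i, j] for j, n in enumerate(STATE_NAMES)}
            )
            for j in range(5):
                row[f"eig{j+1}_re"] = self.eigenvalues[i, j].real
                row[f"eig{j+1}_im"] = self.eigenvalues[i, j].imag
            row["stable"] = bool(self.stable[i])
            rows.append(row)
        return pd.DataFrame(rows)


def equilibrium_branch(
    params: ModelParameters, axis, grid, guess=None
) -> EquilibriumBranch:
    """Pseudo-continuation: each solved equilibrium seeds the next value.

    On Newton divergence the branch is truncated with a warning.
    """
    grid = np.asarray(grid, dtype=float)
    eqs = []
    eigs = []
    y = DEFAULT_INITIAL_STATE if guess is None else np.asarray(guess, float)
    kept = []
    for v in grid:
        p_v = apply_axis(params, axis, v)
        try:
            y = find_equilibrium(p_v, y)
        except ValueError as exc:
            logger.warning(
                "branch truncated at %s=%g: %s", _axis_label(axis), v, exc
            )
            break
        ev = np.linalg.eigvals(jacobian(p_v, y, method="analytic"))
        eqs.append(y.copy())
        eigs.append(ev[np.argsort(-ev.real)])
        kept.append(v)
    eqs = np.asarray(eqs).reshape(-1, 5)
    eigs = np.asarray(eigs).reshape(-1, 5)
    stable = (
        eigs.real.max(axis=1) < 0 if len(eigs) else np.zeros(0, dtype=bool)
    )
    return EquilibriumBranch(
        axis=_axis_label(axis),
        grid=np.asarray(kept),
        equilibria=eqs,
        eigenvalues=eigs,
        stable=stable,
    )


@dataclass(frozen=True)
class BifurcationPoint:
    """A located codimension-one bifurcation."""

    kind: str  # HOPF_SUPER | HOPF_SUB | FOLD_OF_CYCLES
    parameter: str
    value: float
    bracket: tuple[float, float]
    diagnostics: dict


def _leading_complex_real(params, axis, value, guess):
    """(real part of the leading complex eigenpair, its eigenvalue, eq)."""
    p_v = apply_axis(params, axis, value)
    eq = find_equilibrium(p_v, guess)
    ev = np.linalg.eigvals(jacobian(p_v, eq, method="analytic"))
    complex_ev = ev[np.abs(ev.imag) > 1e-9]
    if len(complex_ev) == 0:
        # no oscillatory eigenpair at all: a crossing here cannot be a Hopf
        return None, ev[np.argmax(ev.real)], eq
    lead_c = complex_ev[np.argmax(complex_ev.real)]
    return lead_c.real, lead_c, eq


def locate_hopf(
    params: ModelParameters,
    axis,
    bracket: tuple[float, float],
    resolution: float = 0.002,
    classifier: ClassifierConfig | None = None,
    small_amplitude: float = 0.05,
) -> BifurcationPoint:
    """Bisect a sign change of the leading complex eigenpair's real part.

    The Hopf kind is decided by a probe simulation just past the crossing
    on the unstable side: a settled cycle of small amplitude indicates a
    supercritical branch, a jump to a large-amplitude attractor a
    subcritical one.
    """
    lo, hi = bracket
    r_lo, ev_lo, eq_lo = _leading_complex_real(params, axis, lo, None)
    r_hi, ev_hi, eq_hi = _leading_complex_real(params, axis, hi, eq_lo)
    if r_lo is None or r_hi is None:
        raise ValueError(
            f"leading eigenvalue is real inside the bracket (non-Hopf): "
            f"{ev_lo if r_lo is None else ev_hi}"
        )
    if np.sign(r_lo) == np.sign(r_hi):
        raise ValueError(
            f"no real-part sign change across bracket {bracket}: "
            f"{r_lo:.4g} and {r_hi:.4g}"
        )
    guess = eq_lo
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        r_mid, ev_mid, guess = _leading_complex_real(params, axis, mid, guess)
        if r_mid is None:
            raise ValueError("leading eigenvalue became real during bisection")
        if np.sign(r_mid) == np.sign(r_lo):
            lo, r_lo = mid, r_mid
        else:
            hi, r_hi = mid, r_mid
    crossing = 0.5 * (lo + hi)
    # probe just past the crossing on the unstable side
    unstable_side = hi if r_hi > 0 else lo
    probe_v = unstable_side + np.sign(unstable_side - crossing) * resolution
    p_probe = apply_axis(params, axis, probe_v)
    eq_probe = find_equilibrium(p_probe, guess)
    cfg = SimulationConfig(
        duration=30.0,
        transient_discard=20.0,
        initial_state=eq_probe + 1e-3,
    )
    traj = simulate(p_probe, cfg)
    amp = float(np.ptp(traj.window(20.0)))
    kind = "HOPF_SUPER" if amp < small_amplitude else "HOPF_SUB"
    ev_cross = ev_hi if r_hi > 0 else ev_lo
    return BifurcationPoint(
        kind=kind,
        parameter=_axis_label(axis),
        value=crossing,
        bracket=(lo, hi),
        diagnostics={
            "crossing_eigenvalue": complex(ev_cross),
            "probe_value": float(probe_v),
            "probe_amplitude": amp,
        },
    )


def settle_on_cycle(
    params: ModelParameters,
    axis,
    value: float,
    pulse_magnitude: float = 0.3,
    classifier: ClassifierConfig | None = None,
):
    """State on the large-amplitude cycle at an axis value, obtained by
    simulating from the default state with an initiation perturbation.
    Returns (final state, amplitude)."""
    p_v = apply_axis(params, axis, value)
    cfg = SimulationConfig(duration=50.0, transient_discard=40.0)
    traj = simulate(p_v, cfg, StimulusProtocol.single(20.0, pulse_magnitude))
    return traj.final_state(), float(np.ptp(traj.window(40.0)))


def _cycle_persists(params, axis, value, state, amp_tol, settle=30.0):
    p_v = apply_axis(params, axis, value)
    cfg = SimulationConfig(
        duration=settle, transient_discard=settle - 10.0, initial_state=state
    )
    traj = simulate(p_v, cfg)
    amp = float(np.ptp(traj.window(settle - 10.0)))
    return amp > amp_tol, traj.final_state(), amp


def locate_cycle_fold(
    params: ModelParameters,
    axis,
    bracket: tuple[float, float],
    resolution: float = 0.005,
    cycle_state=None,
    classifier: ClassifierConfig | None = None,
    max_step: float = 0.001,
) -> BifurcationPoint:
    """Bisect the parameter value at which a large-amplitude cycle ceases
    to exist, tracking the cycle by inheriting end states.

    The cycle must exist at exactly one bracket end (both ends are probed
    from cycle-inherited initial conditions).  Near the fold the cycle's
    basin shrinks, so the tracked state is never moved by more than
    ``max_step`` in the parameter per settle run: larger jumps can drop
    the inherited state outside the basin and report the fold early.
    Returns the first grid value on which no cycle is observed (the
    "ceases to exist" side of the final bracket), mirroring the
    smallest-succeeding-magnitude convention of threshold searches.
    """
    classifier = classifier or DEFAULT_CLASSIFIER
    amp_tol = classifier.amp_tol
    lo, hi = bracket

    # current position of the tracked cycle state along the axis
    def walk_to(state, v_from, v_to):
        """Move the cycle state from v_from to v_to in capped parameter
        steps; returns (alive, state at v_to or at death, amplitude)."""
        n_sub = max(1, int(math.ceil(abs(v_to - v_from) / max_step)))
        vs = np.linspace(v_from, v_to, n_sub + 1)[1:]
        amp = np.nan
        for v in vs:
            ok, state, amp = _cycle_persists(params, axis, v, state, amp_tol)
            if not ok:
                return False, state, amp
        return True, state, amp

    if cycle_state is None:
        state_lo, amp_lo = settle_on_cycle(params, axis, lo)
        state_hi, amp_hi = settle_on_cycle(params, axis, hi)
        exists_lo = amp_lo > amp_tol
        exists_hi = amp_hi > amp_tol
        if exists_lo == exists_hi:
            raise ValueError(
                f"cycle existence does not change across bracket {bracket} "
                f"(amplitudes {amp_lo:.3g} and {amp_hi:.3g})"
            )
        state = state_lo if exists_lo else state_hi
        cycle_at_lo = exists_lo
    else:
        state = np.asarray(cycle_state, dtype=float)
        ok_lo, state_lo, amp_lo = _cycle_persists(params, axis, lo, state, amp_tol)
        ok_hi, state_hi, amp_hi = _cycle_persists(params, axis, hi, state, amp_tol)
        if ok_lo == ok_hi:
            raise ValueError(
                f"cycle existence does not change across bracket {bracket} "
                f"(amplitudes {amp_lo:.3g} and {amp_hi:.3g})"
            )
        cycle_at_lo = ok_lo
        state = state_lo if ok_lo else state_hi
    v_state = lo if cycle_at_lo else hi
    amps = {}
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        ok, new_state, amp = walk_to(state, v_state, mid)
        amps[mid] = amp
        if ok:
            state, v_state = new_state, mid
            if cycle_at_lo:
                lo = mid
            else:
                hi = mid
        else:
            if cycle_at_lo:
                hi = mid
            else:
                lo = mid
    ceased_at = hi if cycle_at_lo else lo
    return BifurcationPoint(
        kind="FOLD_OF_CYCLES",
        parameter=_axis_label(axis),
        value=float(ceased_at),
        bracket=(lo, hi),
        diagnostics={"bracket_amplitudes": amps},
    )


@dataclass(frozen=True)
class BistableInterval:
    """Parameter interval on which two attractors coexist."""

    parameter: str
    lower: float
    upper: float
    attractors: tuple[str, str]


def bistable_intervals(
    params: ModelParameters,
    axis,
    grid,
    classifier: ClassifierConfig | None = None,
) -> list[BistableInterval]:
    """Intervals where the stable equilibrium coexists with a cycle.

    Per grid value the equilibrium branch provides one candidate attractor
    (where its eigenvalues all have negative real part) and bidirectional
    inherited-state sweeps track the oscillatory attractor; cells where
    both exist and classify differently are grouped into intervals, each
    verified by explicit coexistence at its midpoint.
    """
    classifier = classifier or DEFAULT_CLASSIFIER
    grid = np.asarray(grid, dtype=float)
    branch = equilibrium_branch(params, axis, grid)
    n = len(branch.grid)
    eq_label = []
    for i in range(n):
        lvl = 0.5 * (branch.equilibria[i, 0] + branch.equilibria[i, 1])
        eq_label.append(
            StateLabel.SATURATED_HIGH
            if lvl >= classifier.level_threshold
            else StateLabel.SATURATED_LOW
        )

    def inherited_cycle_labels(order):
        labels = [None] * n
        state = None
        for i in order:
            v = branch.grid[i]
            if state is None:
                state, amp = settle_on_cycle(params, axis, v)
                if amp <= classifier.amp_tol:
                    state = None
                    continue
            ok, new_state, amp = _cycle_persists(
                params, axis, v, state, classifier.amp_tol
            )
            if ok:
                state = new_state
                p_v = apply_axis(params, axis, v)
                cfg = SimulationConfig(
                    duration=30.0, transient_discard=20.0, initial_state=state
                )
                traj = simulate(p_v, cfg)
                labels[i] = classify_state(traj.window(20.0), traj.dt, classifier)
        return labels

    fwd = inherited_cycle_labels(range(n))
    bwd = inherited_cycle_labels(range(n - 1, -1, -1))
    cyc_label = [
        b if b is not None else f for f, b in zip(fwd, bwd)
    ]
    oscillatory = {StateLabel.TONIC, StateLabel.SWD, StateLabel.CLONIC}
    bistable = [
        branch.stable[i]
        and cyc_label[i] in oscillatory
        for i in range(n)
    ]
    intervals = []
    i = 0
    while i < n:
        if not bistable[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and bistable[j + 1]:
            j += 1
        mid = (i + j) // 2
        interval = BistableInterval(
            parameter=branch.axis,
            lower=float(branch.grid[i]),
            upper=float(branch.grid[j]),
            attractors=(eq_label[mid].value, cyc_label[mid].value),
        )
        if _verify_coexistence(params, axis, branch, mid, classifier):
            intervals.append(interval)
        else:  # pragma: no cover - defensive
            logger.warning("coexistence not confirmed at midpoint of %s", interval)
        i = j + 1
    return intervals


def _verify_coexistence(params, axis, branch, idx, classifier):
    """Two runs at an interior point, from the equilibrium vicinity and
    from a cycle-inherited state, must reach distinct labels."""
    v = branch.grid[idx]
    p_v = apply_axis(params, axis, v)
    cfg_eq = SimulationConfig(
        duration=30.0,
        transient_discard=20.0,
        initial_state=branch.equilibria[idx] + 1e-5,
    )
    lab_eq = classify_state(
        simulate(p_v, cfg_eq).window(20.0), cfg_eq.dt, classifier
    )
    state, amp = settle_on_cycle(params, axis, v)
    if amp <= classifier.amp_tol:
        # cycle not reachable by a pulse here; inherit from a neighbour
        for k in range(idx, len(branch.grid)):
            state, amp = settle_on_cycle(params, axis, branch.grid[k])
            if amp > classifier.amp_tol:
                ok, state, _ = _cycle_persists(
                    params, axis, v, state, classifier.amp_tol
                )
                if not ok:
                    return False
                break
        else:
            return False
    cfg_cy = SimulationConfig(
        duration=30.0, transient_discard=20.0, initial_state=state
    )
    lab_cy = classify_state(
        simulate(p_v, cfg_cy).window(20.0), cfg_cy.dt, classifier
    )
    return lab_eq is not lab_cy
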