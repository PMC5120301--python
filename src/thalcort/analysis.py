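"""Time-series analysis of the cortical mean: extrema, spectra, regime labels.

All analyses operate on the cortical-mean observable (PY + IN1)/2 of a
settled, post-transient window.  The discrete regimes of the model are:

* ``SATURATED_LOW`` / ``SATURATED_HIGH`` — steady (non-oscillatory) firing,
  split by mean activity level; the low state is the background/resting
  state.
* ``TONIC`` — low-amplitude, high-frequency (~15 Hz) oscillation.
* ``SWD`` — spike-wave discharge: ~3 Hz cycle with a sharp spike plus slow
  wave, i.e. at least two local maxima per period.
* ``CLONIC`` — simple slow-wave (~3 Hz) oscillation, one maximum per period.
* ``UNCLASSIFIED`` — oscillatory but outside every recognised band
  (reported with diagnostics, never silently forced into a class).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StateLabel",
    "ClassifierConfig",
    "OscillationSummary",
    "stable_extrema",
    "dominant_frequency",
    "summarize",
    "classify_state",
]


class StateLabel(str, enum.Enum):
    SATURATED_LOW = "SATURATED_LOW"
    SATURATED_HIGH = "SATURATED_HIGH"
    TONIC = "TONIC"
    SWD = "SWD"
    CLONIC = "CLONIC"
    UNCLASSIFIED = "UNCLASSIFIED"
    # map-level derived labels
    STIMULUS_INDUCED_SWD = "STIMULUS_INDUCED_SWD"
    SPONTANEOUS_SWD = "SPONTANEOUS_SWD"
    FAILED = "FAILED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds for :func:`classify_state`.

    ``amp_tol`` separates steady from oscillatory regimes (peak-to-peak).
    ``level_threshold`` splits low from high saturated firing on the mean
    cortical level: the background state sits near 0.18 and the saturated
    high state near 0.49-0.53, so the default cuts between them.
    ``tonic_freq_min`` separates ~15 Hz tonic from the ~3 Hz discharges;
    the intermediate band is empty in practice.  ``swd_band`` is the
    admissible dominant-frequency range for SWD/clonic rhythms.
    """

    amp_tol: float = 1e-3
    level_threshold: float = 0.33
    tonic_freq_min: float = 10.0
    swd_band: tuple[float, float] = (1.0, 5.0)
    cluster_tol: float = 0.05  # fraction of amplitude used to cluster maxima


DEFAULT_CLASSIFIER = ClassifierConfig()


@dataclass(frozen=True)
class OscillationSummary:
    """Stable extrema and spectral summary of one analysed window."""

    maxima: np.ndarray
    minima: np.ndarray
    amplitude: float
    dominant_frequency_hz: float
    maxima_per_cycle: int
    n_maxima_clusters: int
    mean_level: float


def stable_extrema(series, dt: float, transient_discard: float = 0.0):
    """Local maxima and minima of the post-transient window.

    Three-point comparison on the plateau-collapsed sequence: runs of equal
    consecutive samples count as a single point, so flat-topped extrema are
    reported once.  A constant series yields two empty arrays.
    """
    x = np.asarray(series, dtype=float)
    n_skip = int(round(transient_discard / dt)) if transient_discard else 0
    if n_skip >= len(x):
        raise ValueError("transient_discard longer than the series")
    x = x[n_skip:]
    if len(x) < 3:
        return np.array([]), np.array([])
    # collapse plateaus: keep the first sample of each run of equal values
    keep = np.concatenate(([True], np.diff(x) != 0.0))
    xc = x[keep]
    if len(xc) < 3:
        return np.array([]), np.array([])
    left, mid, right = xc[:-2], xc[1:-1], xc[2:]
    maxima = mid[(mid > left) & (mid > right)]
    minima = mid[(mid < left) & (mid < right)]
    return maxima, minima


def dominant_frequency(series, dt: float, power_floor: float = 1e-12) -> float:
    """Frequency (Hz) of the maximum of the FFT periodogram.

    The window is mean-subtracted and transformed without tapering; the
    spectral peak is searched over (0, Nyquist].  A spectrally flat
    (steady) window whose variance falls below ``power_floor`` returns 0.
    """
    x = np.asarray(series, dtype=float)
    if len(x) * dt < 1.0:
        raise ValueError("window must span at least 1 s for spectral analysis")
    x = x - x.mean()
    if np.var(x) < power_floor:
        return 0.0
    power = np.abs(np.fft.rfft(x)) ** 2
    power[0] = 0.0
    freqs = np.fft.rfftfreq(len(x), dt)
    return float(freqs[np.argmax(power)])


def _cluster_count(values: np.ndarray, tol: float) -> int:
    """Number of clusters among extrema values, splitting at gaps > tol."""
    if len(values) == 0:
        return 0
    v = np.sort(values)
    return int(1 + np.sum(np.diff(v) > tol))


def summarize(
    series, dt: float, config: ClassifierConfig | None = None
) -> OscillationSummary:
    """Extrema, amplitude, dominant frequency and waveform-shape counts."""
    config = config or DEFAULT_CLASSIFIER
    x = np.asarray(series, dtype=float)
    maxima, minima = stable_extrema(x, dt)
    if len(maxima) and len(minima):
        amplitude = float(maxima.max() - minima.min())
    else:
        amplitude = float(np.ptp(x))
    freq = dominant_frequency(x, dt)
    window_sec = len(x) * dt
    if freq > 0 and len(maxima):
        per_cycle = int(round(len(maxima) / (window_sec * freq)))
    else:
        per_cycle = 0
    clusters = _cluster_count(maxima, config.cluster_tol * max(amplitude, 1e-30))
    return OscillationSummary(
        maxima=maxima,
        minima=minima,
        amplitude=amplitude,
        dominant_frequency_hz=freq,
        maxima_per_cycle=per_cycle,
        n_maxima_clusters=clusters,
        mean_level=float(x.mean()),
    )


def classify_state(
    series,
    dt: float,
    config: ClassifierConfig | None = None,
    return_summary: bool = False,
):
    """Assign a discrete firing-state label to a stationary window.

    Decision rule: steady windows (amplitude below ``amp_tol``) are
    SATURATED_LOW or SATURATED_HIGH by mean level; oscillatory windows are
    TONIC above ``tonic_freq_min``, and inside ``swd_band`` they are SWD
    with >= 2 maxima per cycle or CLONIC with exactly one.  Anything else
    is UNCLASSIFIED.
    """
    config = config or DEFAULT_CLASSIFIER
    s = summarize(series, dt, config)
    if s.amplitude < config.amp_tol:
        label = (
            StateLabel.SATURATED_HIGH
            if s.mean_level >= config.level_threshold
            else StateLabel.SATURATED_LOW
        )
    elif s.dominant_frequency_hz >= config.tonic_freq_min:
        label = StateLabel.TONIC
    elif config.swd_band[0] <= s.dominant_frequency_hz <= config.swd_band[1]:
        if s.maxima_per_cycle >= 2:
            label = StateLabel.SWD
        elif s.maxima_per_cycle == 1:
            label = StateLabel.CLONIC
        else:
            label = StateLabel.UNCLASSIFIED
    else:
        label = StateLabel.UNCLASSIFIED
    if return_summary:
        return label, s
    return label


def summary_record(label: StateLabel, s: OscillationSummary) -> dict:
    """One flat record per analysed series, suitable for delimited output."""
    return {
        "label": label.value,
        "dominant_frequency_hz": s.dominant_frequency_hz,
        "amplitude": s.amplitude,
        "mean_level": s.mean_level,
        "n_maxima": len(s.maxima),
        "n_minima": len(s.minima),
        "maxima_per_cycle": s.maxima_per_cycle,
        "n_maxima_clusters": s.n_maxima_clusters,
    }
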