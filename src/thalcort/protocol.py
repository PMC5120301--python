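"""Stimulation protocols: timed perturbations of the cortical variables.

A stimulus acts on PY and/or IN1 only (the thalamic populations and IN2 are
never stimulated).  Two conventions are supported:

* ``jump`` (default): the event instantaneously displaces the state in
  phase space, adding ``direction * magnitude`` to the targeted variables
  at the first grid point at or after the event time.  This models a brief
  single-point perturbation such as a TMS pulse.
* ``pulse``: a rectangular current of the given duration is added to the
  targeted derivatives.

The direction is fixed negative by default; amplitude scans vary only the
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_TARGETS = ("PY", "IN1")


@dataclass(frozen=True)
class StimulusEvent:
    """One timed perturbation.

    ``magnitude`` is non-negative; the signed displacement applied is
    ``direction * magnitude``.  In ``jump`` mode ``duration`` is ignored.
    """

    time: float
    magnitude: float
    direction: float = -1.0
    mode: str = "jump"
    duration: float = 0.05
    targets: tuple[str, ...] = ("PY", "IN1")

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        if self.mode not in ("jump", "pulse"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        if self.mode == "pulse" and not self.duration > 0:
            raise ValueError("pulse duration must be positive")
        bad = set(self.targets) - set(VALID_TARGETS)
        if bad:
            raise ValueError(f"invalid stimulus target(s): {sorted(bad)}")

    @property
    def signed_amplitude(self) -> float:
        return self.direction * self.magnitude


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered sequence of stimulus events."""

    events: tuple[StimulusEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.time))
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)

    @classmethod
    def none(cls) -> "StimulusProtocol":
        return cls(())

    @classmethod
    def single(cls, time: float, magnitude: float, **kwargs) -> "StimulusProtocol":
        return cls((StimulusEvent(time=time, magnitude=magnitude, **kwargs),))

    @classmethod
    def double(
        cls,
        initiation: float,
        termination: float,
        t_initiation: float = 20.0,
        t_termination: float = 35.0,
        **kwargs,
    ) -> "StimulusProtocol":
        """The two-pulse induce/abate protocol: an initiation event followed
        by a termination event."""
        if not t_initiation < t_termination:
            raise ValueError("termination event must follow initiation event")
        return cls(
            (
                StimulusEvent(time=t_initiation, magnitude=initiation, **kwargs),
                StimulusEvent(time=t_termination, magnitude=termination, **kwargs),
            )
        )

    @classmethod
    def periodic(
        cls,
        period: float,
        initiation: float,
        termination: float,
        t_first: float = 20.0,
        termination_offset: float = 15.0,
        until: float = 100.0,
        **kwargs,
    ) -> "StimulusProtocol":
        """Alternating initiation/termination events: initiation at
        ``t_first + n*period`` and termination at
        ``t_first + termination_offset + n*period`` for all events before
        ``until``.  Repeated switching between seizure and background
        produces recurrent discharges."""
        if not 0 < termination_offset < period:
            raise ValueError("termination_offset must lie within one period")
        events = []
        t0 = t_first
        while t0 < until:
            events.append(StimulusEvent(time=t0, magnitude=initiation, **kwargs))
            t1 = t0 + termination_offset
            if t1 < until:
                events.append(StimulusEvent(time=t1, magnitude=termination, **kwargs))
            t0 += period
        return cls(tuple(events))
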