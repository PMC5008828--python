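"""Calcium and dopamine input trajectories.

The calcium input emulates 10 glutamate-triggered NMDAR calcium pulses at
10 Hz: each pulse is a difference of two exponentials (fast NMDAR-like rise
and decay), and the per-pulse amplitude is auto-scaled so the summed train
peaks at 5 uM over a 60 nM basal.  The dopamine input is a 1.5 uM, 1.0 s
transient over a 20 nM basal -- a plateau with short exponential edges so the
integrator never sees a true discontinuity.

The input interval is Dt = t_dopamine - t_calcium, measured start-to-start;
positive Dt means dopamine follows calcium.  Multi-trial protocols repeat the
(calcium, dopamine) pair every ITI seconds, the inter-trial interval being
measured calcium-onset to calcium-onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "CalciumTrain",
    "DopamineTransient",
    "TrialSchedule",
    "StimulusProtocol",
    "build_traces",
    "frequency_variant",
    "basal_protocol",
]

CA_BASAL = 0.060  # uM
DA_BASAL = 0.020  # uM


def _diff_exp_peak(rise_tau: float, decay_tau: float) -> float:
    """Peak value of exp(-t/decay) - exp(-t/rise) for unit amplitude."""
    if rise_tau >= decay_tau:
        raise ValueError("rise_tau must be < decay_tau")
    tpk = (
        rise_tau
        * decay_tau
        / (decay_tau - rise_tau)
        * math.log(decay_tau / rise_tau)
    )
    return math.exp(-tpk / decay_tau) - math.exp(-tpk / rise_tau)


@dataclass
class CalciumTrain:
    """A train of identical difference-of-exponential calcium pulses."""

    n_pulses: int = 10
    frequency: float = 10.0  # Hz
    peak: float = 5.0  # uM, max of the summed train
    basal: float = CA_BASAL  # uM
    rise_tau: float = 0.005  # s
    decay_tau: float = 0.030  # s
    onset: float = 0.0  # s, start of the first pulse (t_calcium)

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if not (self.peak > self.basal >= 0):
            raise ValueError("need peak > basal >= 0")
        if not (0 < self.rise_tau < self.decay_tau):
            raise ValueError("need 0 < rise_tau < decay_tau")

    @property
    def pulse_onsets(self) -> np.ndarray:
        return self.onset + np.arange(self.n_pulses) / self.frequency

    def pulse_amplitude(self) -> float:
        """Per-pulse scale such that the summed train peaks at ``peak``.

        Computed numerically on a fine grid so pulse overlap at high
        frequencies is accounted for exactly.
        """
        dt = min(self.rise_tau, 1.0 / self.frequency / 50.0) / 4.0
        t = np.arange(0.0, self.n_pulses / self.frequency + 8 * self.decay_tau, dt)
        unit = np.zeros_like(t)
        for t0 in np.arange(self.n_pulses) / self.frequency:
            tau = t - t0
            m = tau > 0
            unit[m] += np.exp(-tau[m] / self.decay_tau) - np.exp(
                -tau[m] / self.rise_tau
            )
        return (self.peak - self.basal) / float(unit.max())

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.basal)
        amp = self.pulse_amplitude()
        for t0 in self.pulse_onsets:
            tau = t - t0
            m = tau > 0
            out[m] += amp * (
                np.exp(-tau[m] / self.decay_tau) - np.exp(-tau[m] / self.rise_tau)
            )
        return out


@dataclass
class DopamineTransient:
    """A transient dopamine elevation: plateau with fast exponential edges."""

    amplitude: float = 1.5  # uM, plateau level above zero
    duration: float = 1.0  # s
    basal: float = DA_BASAL  # uM
    onset: float = 0.0  # s (t_dopamine)
    edge_tau: float = 0.010  # s

    def __post_init__(self) -> None:
        if not (self.amplitude > self.basal >= 0):
            raise ValueError("need amplitude > basal >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.basal)
        a = self.amplitude - self.basal
        tau = t - self.onset
        rising = (tau > 0) & (tau <= self.duration)
        out[rising] += a * (1.0 - np.exp(-tau[rising] / self.edge_tau))
        falling = tau > self.duration
        level = a * (1.0 - math.exp(-self.duration / self.edge_tau))
        out[falling] += level * np.exp(-(tau[falling] - self.duration) / self.edge_tau)
        return out


@dataclass
class TrialSchedule:
    """Trial timing: how many (calcium, dopamine) pairs, and when."""

    n_trials: int = 1
    iti: float = 100.0  # s, calcium-onset to calcium-onset
    delta_t: float = 1.0  # s, Dt = t_dopamine - t_calcium, per trial

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_trials > 1 and self.iti <= 0:
            raise ValueError("iti must be > 0 for multi-trial schedules")


@dataclass
class StimulusProtocol:
    """A full input protocol: calcium train, optional dopamine, trial plan."""

    calcium: CalciumTrain = field(default_factory=CalciumTrain)
    dopamine: Optional[DopamineTransient] = field(default_factory=DopamineTransient)
    schedule: TrialSchedule = field(default_factory=TrialSchedule)
    total_duration: float = 160.0  # s

    def __post_init__(self) -> None:
        if self.schedule.n_trials > 1:
            span = self._trial_span()
            if span > self.schedule.iti:
                raise ValueError(
                    f"trial inputs span {span:.2f}s which overlaps the next "
                    f"trial (ITI {self.schedule.iti}s)"
                )

    def _trial_span(self) -> float:
        span = self.calcium.n_pulses / self.calcium.frequency
        if self.dopamine is not None:
            span = max(
                span, self.schedule.delta_t + self.dopamine.duration
            )
        return span

    # -- onsets --------------------------------------------------------------
    def calcium_onsets(self) -> np.ndarray:
        """First-pulse onset of each trial's calcium train."""
        return self.calcium.onset + np.arange(self.schedule.n_trials) * self.schedule.iti

    def dopamine_onsets(self) -> np.ndarray:
        if self.dopamine is None:
            return np.empty(0)
        return self.calcium_onsets() + self.schedule.delta_t

    def all_pulse_onsets(self) -> np.ndarray:
        out = []
        for tc in self.calcium_onsets():
            out.extend(tc + np.arange(self.calcium.n_pulses) / self.calcium.frequency)
        return np.asarray(out)

    def breakpoints(self) -> np.ndarray:
        """Times the integrator must not step across (input onsets/offsets)."""
        pts = list(self.all_pulse_onsets())
        if self.dopamine is not None:
            for td in self.dopamine_onsets():
                pts.extend([td, td + self.dopamine.duration])
        pts = sorted(p for p in pts if 0.0 < p < self.total_duration)
        return np.asarray(pts)

    # -- evaluation ----------------------------------------------------------
    def calcium_at(self, t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.full(t.shape, self.calcium.basal)
        amp = self.calcium.pulse_amplitude()
        for t0 in self.all_pulse_onsets():
            tau = t - t0
            m = tau > 0
            out[m] += amp * (
                np.exp(-tau[m] / self.calcium.decay_tau)
                - np.exp(-tau[m] / self.calcium.rise_tau)
            )
        return out

    def dopamine_at(self, t: np.ndarray | float) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        basal = self.dopamine.basal if self.dopamine is not None else DA_BASAL
        out = np.full(t.shape, basal)
        if self.dopamine is None:
            return out
        for td in self.dopamine_onsets():
            pulse = replace(self.dopamine, onset=float(td))
            out += pulse(t) - basal
        return out

    def shifted(self, offset: float) -> "StimulusProtocol":
        """The same protocol translated in time by ``offset`` seconds."""
        cal = replace(self.calcium, onset=self.calcium.onset + offset)
        return replace(
            self, calcium=cal, total_duration=self.total_duration + offset
        )


def build_traces(
    protocol: StimulusProtocol, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the calcium and dopamine traces (uM) on a time grid."""
    grid = np.asarray(grid, dtype=float)
    onsets = protocol.calcium_onsets()
    if grid[-1] < onsets[-1]:
        raise ValueError(
            f"grid ends at {grid[-1]}s before the last trial onset {onsets[-1]}s"
        )
    return protocol.calcium_at(grid), protocol.dopamine_at(grid)


def frequency_variant(
    protocol: StimulusProtocol, new_frequency: float
) -> StimulusProtocol:
    """Same pulse shape and count, re-spaced at ``new_frequency`` Hz.

    The per-pulse amplitude is kept fixed at the reference protocol's value,
    so the summed peak concentration varies with pulse overlap (higher
    frequency -> more overlap -> higher peak), as for a fixed unitary calcium
    influx per upstream glutamate event.
    """
    if new_frequency <= 0:
        raise ValueError("new_frequency must be > 0")
    ref_amp = protocol.calcium.pulse_amplitude()
    cal = replace(protocol.calcium, frequency=new_frequency)
    # recompute the nominal peak so pulse_amplitude() returns ref_amp
    dt = min(cal.rise_tau, 1.0 / new_frequency / 50.0) / 4.0
    t = np.arange(0.0, cal.n_pulses / new_frequency + 8 * cal.decay_tau, dt)
    unit = np.zeros_like(t)
    for t0 in np.arange(cal.n_pulses) / new_frequency:
        tau = t - t0
        m = tau > 0
        unit[m] += np.exp(-tau[m] / cal.decay_tau) - np.exp(-tau[m] / cal.rise_tau)
    cal = replace(cal, peak=cal.basal + ref_amp * float(unit.max()))
    return replace(protocol, calcium=cal)


def basal_protocol(total_duration: float = 100.0) -> StimulusProtocol:
    """Inputs held at basal: calcium 60 nM, dopamine 20 nM, no transients.

    Implemented as a protocol whose pulse amplitudes vanish; the engine treats
    it like any other stimulus.
    """
    cal = CalciumTrain(n_pulses=1, peak=CA_BASAL + 1e-12, onset=0.0)
    return StimulusProtocol(
        calcium=cal,
        dopamine=None,
        schedule=TrialSchedule(n_trials=1),
        total_duration=total_duration,
    )
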