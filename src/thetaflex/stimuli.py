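"""Synthetic forcing signals: periodic and quasi-rhythmic pulse trains.

Pulses are smoothed square waves: an indicator of width w(s-1)/s convolved
with a Gaussian exp(-(s t / w)^2), where w is the pulse width (ms) and the
integer-ish shape parameter s controls squareness (s = 1 roughly normal,
s = 25 nearly square).  The convolution is evaluated in closed form via the
error function.  Trains are normalized so that the mean injected current
equals the requested gain (total integrated input of ``gain`` unit-seconds
per second of simulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field  # field: params default

import numpy as np
from scipy.special import erf

SUPPORT_FRACTION = 0.01  # pulse "on" where it exceeds 1% of its peak


class ResolutionError(ValueError):
    """Pulse narrower than two integration steps."""


@dataclass
class StimulusSignal:
    """A sampled applied-current trace plus pulse bookkeeping.

    ``supports`` lists the (onset, offset) ms intervals over which each pulse
    is appreciably nonzero; they anchor the piecewise-linear input phase.
    """

    trace: np.ndarray
    dt: float
    gain: float
    supports: list
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def duration(self) -> float:
        return self.trace.shape[0] * self.dt


def _pulse_profile(t, center, width, shape):
    """Closed-form indicator-convolved-Gaussian pulse, peak ~ sqrt(pi)*w/s."""
    half = 0.5 * width * (shape - 1.0) / shape
    a = shape / width
    return (math.sqrt(math.pi) / (2.0 * a)) * (
        erf(a * (t - center + half)) - erf(a * (t - center - half)))


def _add_pulse(trace, dt, center, width, shape):
    """Accumulate one pulse into ``trace``; returns its (a, b) support in ms."""
    half = 0.5 * width * (shape - 1.0) / shape
    margin = 5.0 * width / shape  # Gaussian tail
    i0 = max(0, int((center - half - margin) / dt))
    i1 = min(trace.shape[0], int((center + half + margin) / dt) + 2)
    if i1 <= i0:
        return None
    t = np.arange(i0, i1) * dt
    prof = _pulse_profile(t, center, width, shape)
    trace[i0:i1] += prof
    peak = prof.max()
    on = np.flatnonzero(prof > SUPPORT_FRACTION * peak)
    if on.size == 0:
        return None
    return ((i0 + on[0]) * dt, (i0 + on[-1]) * dt)


def _normalize(trace, gain):
    mean = trace.mean()
    if mean > 0:
        trace *= gain / mean
    return trace


def periodic_pulse_train(omega: float, duration: float, gain: float,
                         dt: float, d: float = 0.25,
                         shape: float = 25.0) -> StimulusSignal:
    """Periodic smoothed-square pulses at ``omega`` Hz, duty cycle ``d``.

    Pulse centers sit at t_i = 1000 i / omega ms; the pulse width is
    w = 1000 d / omega ms.
    """
    if omega <= 0:
        raise ValueError("frequency must be positive")
    if not 0 < d < 1:
        raise ValueError("duty cycle must lie in (0, 1)")
    width = 1000.0 * d / omega
    if width < 2 * dt:
        raise ResolutionError(f"pulse width {width:.4f} ms < 2 dt")
    n = int(round(duration / dt))
    trace = np.zeros(n)
    supports = []
    period = 1000.0 / omega
    i = 1
    while i * period <= duration:
        sup = _add_pulse(trace, dt, i * period, width, shape)
        if sup is not None:
            supports.append(sup)
        i += 1
    _normalize(trace, gain)
    return StimulusSignal(trace=trace, dt=dt, gain=gain, supports=supports,
                          params=dict(kind="periodic", omega=omega, d=d,
                                      shape=shape))


def single_pulse(onset: float, width: float, shape: float, dt: float,
                 n_steps: int) -> np.ndarray:
    """One unnormalized pulse whose support begins at ``onset`` ms."""
    trace = np.zeros(n_steps)
    _add_pulse(trace, dt, onset + 0.5 * width, width, shape)
    return trace


# -- quasi-rhythmic ("varied") pulse trains --------------------------------

@dataclass
class BandwidthRow:
    """One row of the varied-pulse parameter ladder.

    Per-pulse frequency, duty cycle, shape, and onset offset are drawn
    uniformly from [low, high] intervals that widen with the row index;
    ``bandwidth`` (f_high - f_low, Hz) names the row.  Offsets are seconds.
    """

    bandwidth: float
    f_low: float
    f_high: float
    d_low: float
    d_high: float
    s_low: float
    s_high: float
    o_low: float
    o_high: float

    def astuple(self):
        return (self.bandwidth, self.f_low, self.f_high, self.d_low,
                self.d_high, self.s_low, self.s_high, self.o_low, self.o_high)


N_BANDWIDTH_ROWS = 20


def bandwidth_row(k: int) -> BandwidthRow:
    """Row ``k`` (1..20) of the varied-pulse parameter ladder.

    The ladder interpolates linearly from a narrowband row (bandwidth 1 Hz,
    centered on 7 Hz, nearly periodic) to a broadband row (13.35 Hz, duty
    cycles 0.0125-0.775, offsets up to 1 s); shape bounds are rounded to
    integers.
    """
    if not 1 <= k <= N_BANDWIDTH_ROWS:
        raise ValueError(f"row index {k} outside 1..{N_BANDWIDTH_ROWS}")
    j = k - 1
    return BandwidthRow(
        bandwidth=1.0 + 0.65 * j,
        f_low=6.5 - 0.325 * j,
        f_high=7.5 + 0.325 * j,
        d_low=0.25 - 0.0125 * j,
        d_high=0.3 + 0.025 * j,
        s_low=round(10.0 - 9.0 * j / 19.0),
        s_high=round(40.0 + 10.0 * j / 19.0),
        o_low=0.0,
        o_high=0.05 * k,
    )


def row_for_bandwidth(bandwidth: float) -> int:
    """Row index whose bandwidth is closest to ``bandwidth`` Hz."""
    return int(round((bandwidth - 1.0) / 0.65)) + 1


def varied_pulse_train(row: BandwidthRow, duration: float, gain: float,
                       dt: float, seed: int = 0,
                       max_redraws: int = 100) -> StimulusSignal:
    """Quasi-rhythmic pulse train with per-pulse parameters drawn from ``row``.

    Nominal pulse times accumulate as t_i = sum_j 1000/omega_j; each pulse is
    shifted by its own offset draw.  Offsets producing overlapping supports
    are redrawn (the event count is recorded in ``params``).
    """
    if row.f_low > row.f_high or row.d_low > row.d_high:
        raise ValueError("invalid bandwidth row: lows exceed highs")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    trace = np.zeros(n)
    supports = []
    t_star = 0.0
    redraws = 0
    while True:
        omega = rng.uniform(row.f_low, row.f_high)
        t_star += 1000.0 / omega
        if t_star > duration:
            break
        d_i = rng.uniform(row.d_low, row.d_high)
        s_i = rng.uniform(row.s_low, row.s_high)
        width = 1000.0 * d_i / omega
        if width < 2 * dt:
            raise ResolutionError(f"pulse width {width:.4f} ms < 2 dt")
        for attempt in range(max_redraws + 1):
            o_i = rng.uniform(row.o_low, row.o_high) * 1000.0
            center = t_star + o_i
            a = center - 0.5 * width
            if not supports or a > supports[-1][1]:
                break
            redraws += 1
        else:
            continue  # could not place without overlap; drop the pulse
        sup = _add_pulse(trace, dt, center, width, s_i)
        if sup is not None and (not supports or sup[0] > supports[-1][1]):
            supports.append(sup)
    _normalize(trace, gain)
    return StimulusSignal(trace=trace, dt=dt, gain=gain, supports=supports,
                          params=dict(kind="varied", row=row.astuple(),
                                      redraws=redraws), seed=seed)


# default sweep grids for the periodic experiments
PERIODIC_FREQUENCIES = np.concatenate([[0.25], np.arange(0.5, 23.01, 0.5)])
PERIODIC_GAINS = np.round(np.arange(0.0, 4.01, 0.1), 10)
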