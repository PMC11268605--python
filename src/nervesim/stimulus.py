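"""Stimulation waveforms as asynchronous event lists.

A :class:`Stimulus` is a list of ``(time, value)`` events — times in
milliseconds, currents in microamperes — with an interpolation convention
describing how the signal is read between events:

``hold``
    zero-order hold: the value of the last event at or before *t*
    (pulses, square waves).
``linear``
    linear interpolation between bracketing events (sampled smooth
    waveforms such as kilohertz sines).

Before the first event every stimulus evaluates to zero; after the last
event the last value is held.  Stimuli combine algebraically on the union
of their time bases, so arbitrary waveforms (modulated kHz carriers,
pulse trains, ramps) are built by composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "Stimulus",
    "make_pulse",
    "make_sine",
    "make_square_wave",
    "make_ramp",
    "combine",
    "scale",
]


@dataclass
class Stimulus:
    """An asynchronous (time, value) event list.

    Parameters
    ----------
    times : array-like
        Event times in ms, strictly increasing.
    values : array-like
        Current at each event in µA; same length as ``times``.
    interpolation : {"hold", "linear"}
        Convention for reading the signal between events.
    """

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))
    interpolation: str = "hold"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidParameterError(
                "times and values must be 1-D arrays of equal length"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("event times must be strictly increasing")
        if self.interpolation not in ("hold", "linear"):
            raise InvalidParameterError(
                f"unknown interpolation {self.interpolation!r}"
            )

    def __len__(self):
        return self.times.size

    def evaluate(self, t):
        """Evaluate the stimulus at time(s) ``t`` (ms) → current (µA).

        Scalar in, scalar out; array in, array out.
        """
        t_arr = np.asarray(t, dtype=float)
        scalar = t_arr.ndim == 0
        t_arr = np.atleast_1d(t_arr)
        if self.times.size == 0:
            out = np.zeros_like(t_arr)
        elif self.interpolation == "hold":
            idx = np.searchsorted(self.times, t_arr, side="right") - 1
            out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 0.0)
        else:
            out = np.interp(t_arr, self.times, self.values,
                            left=0.0, right=self.values[-1])
            # np.interp holds the first value before times[0]; enforce 0 there
            out = np.where(t_arr < self.times[0], 0.0, out)
        return float(out[0]) if scalar else out

    __call__ = evaluate

    def charge(self):
        """Integral of the waveform over its support (µA·ms = nC)."""
        if self.times.size < 2:
            return 0.0
        dt = np.diff(self.times)
        if self.interpolation == "hold":
            return float(np.sum(self.values[:-1] * dt))
        return float(np.trapezoid(self.values, self.times))

    # -- algebra ---------------------------------------------------------
    def __add__(self, other):
        return combine(self, other, "add")

    def __sub__(self, other):
        return combine(self, other, "sub")

    def __mul__(self, other):
        if np.isscalar(other):
            return scale(self, other)
        return combine(self, other, "mul")

    def __rmul__(self, other):
        return self.__mul__(other)

    def __neg__(self):
        return scale(self, -1.0)

    # -- serialization ---------------------------------------------------
    def to_dict(self):
        return {
            "times": self.times.tolist(),
            "values": self.values.tolist(),
            "interpolation": self.interpolation,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["times"], dtype=float),
                   np.asarray(d["values"], dtype=float),
                   d.get("interpolation", "hold"))

    def to_json(self):
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s):
        return cls.from_dict(json.loads(s))


def make_pulse(start, amplitude, duration, kind="monophasic",
               anodic_ratio=1.0, interphase=0.0):
    """Rectangular stimulation pulse (zero-order hold).

    Monophasic: ``amplitude`` from ``start`` for ``duration`` ms, then 0.
    Biphasic: a cathodic phase of ``amplitude`` and ``duration`` followed
    (after ``interphase`` ms at 0) by a charge-balancing anodic phase of
    amplitude ``-amplitude/anodic_ratio`` and duration
    ``duration * anodic_ratio``.
    """
    if duration <= 0:
        raise InvalidParameterError("pulse duration must be positive")
    if kind == "monophasic":
        return Stimulus([start, start + duration], [amplitude, 0.0], "hold")
    if kind == "biphasic":
        if anodic_ratio <= 0:
            raise InvalidParameterError("anodic_ratio must be positive")
        if interphase < 0:
            raise InvalidParameterError("interphase must be non-negative")
        t1 = start + duration
        times = [start, t1]
        values = [amplitude, 0.0]
        t2 = t1 + interphase
        anodic_amp = -amplitude / anodic_ratio
        anodic_dur = duration * anodic_ratio
        if interphase > 0:
            times += [t2, t2 + anodic_dur]
            values += [anodic_amp, 0.0]
        else:
            times[-1:] = [t1, t1 + anodic_dur]
            values[-1:] = [anodic_amp, 0.0]
        return Stimulus(times, values, "hold")
    raise InvalidParameterError(f"unknown pulse kind {kind!r}")


def make_sine(start, freq, amplitude_pp, duration, dt_sample=None):
    """Sampled sine burst, ``(amplitude_pp/2)·sin(2π·freq·(t−start))``.

    ``freq`` is in kHz so that kHz-block waveforms are first-class.  The
    waveform is sampled every ``dt_sample`` ms (default 1/40 of a period)
    and linearly interpolated; ``dt_sample`` must resolve the carrier
    (i.e. be below the Nyquist interval ``1/(2 freq)``).
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if freq <= 0:
        raise InvalidParameterError("frequency must be positive")
    period = 1.0 / freq
    if dt_sample is None:
        dt_sample = period / 40.0
    if dt_sample >= period / 2.0:
        raise InvalidParameterError(
            f"dt_sample={dt_sample} ms does not resolve a {freq} kHz carrier "
            f"(Nyquist interval {period / 2.0} ms)")
    n = int(np.floor(duration / dt_sample)) + 1
    t = start + np.arange(n) * dt_sample
    if t[-1] < start + duration - 1e-12:
        t = np.append(t, start + duration)
    v = 0.5 * amplitude_pp * np.sin(2.0 * np.pi * freq * (t - start))
    # the burst ends at zero (the source switches off), so nothing is held
    v[-1] = 0.0
    return Stimulus(t, v, "linear")


def make_square_wave(start, freq, amplitude_pp, duration):
    """Square wave at ``freq`` kHz, peak-to-peak ``amplitude_pp`` (hold)."""
    if duration <= 0 or freq <= 0:
        raise InvalidParameterError("duration and frequency must be positive")
    half = 0.5 / freq
    edges = np.arange(start, start + duration, half)
    vals = np.where(np.arange(edges.size) % 2 == 0, 0.5, -0.5) * amplitude_pp
    times = np.append(edges, start + duration)
    values = np.append(vals, 0.0)
    return Stimulus(times, values, "hold")


def make_ramp(start, amplitude, duration, hold_end=False):
    """Linear ramp from 0 to ``amplitude`` over ``duration`` ms."""
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    if hold_end:
        return Stimulus([start, start + duration], [0.0, amplitude], "linear")
    eps = duration * 1e-9
    return Stimulus([start, start + duration, start + duration + eps],
                    [0.0, amplitude, 0.0], "linear")


_OPS = {"add": np.add, "sub": np.subtract, "mul": np.multiply}


def combine(a, b, op="add"):
    """Pointwise combination of two stimuli on the union of time bases.

    The result's events are the sorted union of both operands' events
    (duplicates merged); the value at each event is ``op`` applied to the
    operands evaluated there.  The result uses hold interpolation only if
    both operands do.
    """
    if op not in _OPS:
        raise InvalidParameterError(f"unknown op {op!r}")
    t = np.union1d(a.times, b.times)
    v = _OPS[op](a.evaluate(t), b.evaluate(t)) if t.size else np.empty(0)
    interp = "hold" if (a.interpolation == "hold" and
                        b.interpolation == "hold") else "linear"
    return Stimulus(t, np.atleast_1d(v), interp)


def scale(a, k):
    """Multiply every event value by the scalar ``k``."""
    return Stimulus(a.times.copy(), a.values * float(k), a.interpolation)
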