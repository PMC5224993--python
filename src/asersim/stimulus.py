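"""Stimulus protocols: piecewise-constant input I(t) with a stimulation epoch.

The ASER neuron is excited by *decreases* in NaCl concentration, so the
"downstep" level is the active (usually larger) input.  A protocol is an
ordered, contiguous list of half-open segments ``[t_start, t_end)`` covering
``[0, horizon]``, plus the boundaries of the stimulation epoch that gate the
inactivation variables ``y_i`` of the model.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidProtocolError

__all__ = [
    "Segment",
    "StimulusProtocol",
    "step_protocol",
    "flicker_protocol",
    "pseudorandom_protocol",
    "graded_step_protocols",
    "MM_PER_UNIT_INPUT",
]

#: Linear mapping between NaCl concentration change and dimensionless input:
#: a 50 mM downstep corresponds to I = 1.0.
MM_PER_UNIT_INPUT = 50.0

_EPS = 1e-9


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant piece of I(t) on the half-open [t_start, t_end)."""

    t_start: float
    t_end: float
    level: float


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant input I(t) plus stimulation-epoch boundaries.

    The epoch ``[epoch_start, epoch_end)`` is the interval during which the
    inactivation variables integrate (``dy_i/dt = -A x_i``); outside it they
    are held at zero.
    """

    segments: tuple[Segment, ...]
    epoch_start: float
    epoch_end: float
    name: str = field(default="custom", compare=False)

    def __post_init__(self):
        if not self.segments:
            raise InvalidProtocolError("protocol needs at least one segment")
        if self.segments[0].t_start != 0.0:
            raise InvalidProtocolError("segments must start at t = 0")
        prev_end = 0.0
        for seg in self.segments:
            if seg.t_end <= seg.t_start:
                raise InvalidProtocolError(f"empty or inverted segment {seg}")
            if abs(seg.t_start - prev_end) > _EPS:
                raise InvalidProtocolError(
                    f"gap or overlap at t = {seg.t_start:g} (previous end {prev_end:g})"
                )
            prev_end = seg.t_end
        if self.epoch_start > self.epoch_end:
            raise InvalidProtocolError("epoch_start must be <= epoch_end")

    @property
    def horizon(self) -> float:
        return self.segments[-1].t_end

    def breakpoints(self) -> np.ndarray:
        """Interior segment boundaries plus epoch bounds (sorted, unique)."""
        bps = [s.t_start for s in self.segments[1:]]
        bps += [self.epoch_start, self.epoch_end]
        bps = [b for b in bps if 0.0 < b < self.horizon]
        return np.unique(np.asarray(bps, dtype=float))

    def level_at(self, t: float) -> float:
        """I(t), right-continuous at breakpoints; t == horizon uses the last segment."""
        if t < 0.0 or t > self.horizon + _EPS:
            raise InvalidProtocolError(f"t = {t:g} outside protocol span")
        for seg in self.segments:
            if seg.t_start - _EPS <= t < seg.t_end - _EPS:
                return seg.level
        return self.segments[-1].level

    def levels_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        starts = np.array([s.t_start for s in self.segments])
        levels = np.array([s.level for s in self.segments])
        idx = np.clip(np.searchsorted(starts, t + _EPS) - 1, 0, len(levels) - 1)
        return levels[idx]

    def epoch_active(self, t: float) -> bool:
        return self.epoch_start - _EPS <= t < self.epoch_end - _EPS

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "epoch_start": self.epoch_start,
            "epoch_end": self.epoch_end,
            "segments": [[s.t_start, s.t_end, s.level] for s in self.segments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        segs = tuple(Segment(*map(float, row)) for row in d["segments"])
        return cls(
            segments=segs,
            epoch_start=float(d["epoch_start"]),
            epoch_end=float(d["epoch_end"]),
            name=str(d.get("name", "custom")),
        )


def _assemble(pieces: list[tuple[float, float, float]], horizon: float,
              epoch: tuple[float, float], name: str) -> StimulusProtocol:
    """Fill gaps with zero-level segments and merge into a protocol."""
    segs: list[Segment] = []
    cursor = 0.0
    for t0, t1, level in pieces:
        if t0 > cursor + _EPS:
            segs.append(Segment(cursor, t0, 0.0))
        else:
            t0 = cursor  # snap sub-epsilon gaps closed
        segs.append(Segment(t0, t1, level))
        cursor = t1
    if cursor < horizon - _EPS:
        segs.append(Segment(cursor, horizon, 0.0))
    return StimulusProtocol(tuple(segs), epoch[0], epoch[1], name=name)


def step_protocol(onset: float, duration: float, I_down: float = 1.0,
                  horizon: float = 120.0) -> StimulusProtocol:
    """Single concentration downstep: I = I_down on [onset, onset+duration).

    The canonical stimulus is a 60-s downstep from 50 mM to 0 mM NaCl at
    t = 10 s on a 120-s horizon, encoded as I = 1.0 during the step and 0
    elsewhere.
    """
    if duration <= 0:
        raise InvalidProtocolError("duration must be > 0")
    if onset < 0 or onset + duration > horizon + _EPS:
        raise InvalidProtocolError("step must lie inside [0, horizon]")
    offset = onset + duration
    return _assemble([(onset, offset, I_down)], horizon, (onset, offset), "step")


def flicker_protocol(onset: float, epoch_len: float, phase_len: float,
                     I_down: float, I_up: float, horizon: float) -> StimulusProtocol:
    """Fast alternation between two input levels (0.5 Hz head-swing regime).

    Within the epoch the input alternates I_down, I_up, I_down, ... in phases
    of ``phase_len`` seconds, starting with the downstep level; a trailing
    partial phase is truncated at the epoch end.  I = 0 outside the epoch.
    The whole alternation is a single stimulation epoch: the inactivation
    variables stay engaged across the brief upsteps.
    """
    if phase_len <= 0:
        raise InvalidProtocolError("phase_len must be > 0")
    if epoch_len <= 0 or onset < 0 or onset + epoch_len > horizon + _EPS:
        raise InvalidProtocolError("epoch must lie inside [0, horizon]")
    if I_down <= I_up:
        warnings.warn(
            "flicker with I_down <= I_up: inverted contrast (downstep should "
            "be the larger input for ASER)", stacklevel=2)
    pieces = []
    t = onset
    end = onset + epoch_len
    level_down = True
    while t < end - _EPS:
        t1 = min(t + phase_len, end)
        pieces.append((t, t1, I_down if level_down else I_up))
        level_down = not level_down
        t = t1
    return _assemble(pieces, horizon, (onset, end), "flicker")


def pseudorandom_protocol(onset: float, epoch_len: float, dwell: float,
                          I_down: float, I_up: float, seed: int,
                          horizon: float) -> StimulusProtocol:
    """Pseudorandom switching between two levels, Mersenne-Twister seeded.

    The epoch is divided into slots of ``dwell`` seconds; each slot is
    assigned I_down or I_up by bit 0 of a successive 32-bit MT19937 draw
    (bit set -> downstep).  Identical seeds give identical protocols.
    """
    if dwell <= 0:
        raise InvalidProtocolError("dwell must be > 0")
    if epoch_len <= 0 or onset < 0 or onset + epoch_len > horizon + _EPS:
        raise InvalidProtocolError("epoch must lie inside [0, horizon]")
    rng = random.Random(seed)  # CPython's MT19937; getrandbits(32) = genrand_int32
    pieces = []
    t = onset
    end = onset + epoch_len
    while t < end - _EPS:
        t1 = min(t + dwell, end)
        bit = rng.getrandbits(32) & 1
        pieces.append((t, t1, I_down if bit else I_up))
        t = t1
    return _assemble(pieces, horizon, (onset, end), "pseudorandom")


def graded_step_protocols(delta_mM_list, base_I: float = 1.0, onset: float = 10.0,
                          duration: float = 60.0, horizon: float = 120.0,
                          ) -> list[StimulusProtocol]:
    """Step protocols for graded NaCl downsteps, I proportional to the change.

    Input is mapped linearly from concentration change: a 50 mM downstep is
    ``base_I`` (default 1.0), so delta mM -> I = base_I * delta / 50.
    """
    protocols = []
    for delta in delta_mM_list:
        if not 0.0 < delta <= MM_PER_UNIT_INPUT:
            raise InvalidProtocolError(
                f"concentration change {delta} mM outside (0, {MM_PER_UNIT_INPUT:g}]")
        I_down = base_I * delta / MM_PER_UNIT_INPUT
        p = step_protocol(onset, duration, I_down=I_down, horizon=horizon)
        protocols.append(StimulusProtocol(p.segments, p.epoch_start, p.epoch_end,
                                          name=f"step_{delta:g}mM"))
    return protocols
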