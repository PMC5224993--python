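"""Three-unit ODE model of ASER calcium dynamics.

The neuron is split into dendrite, soma and axon.  Each unit i carries a
dimensionless activity x_i (calcium level above baseline) obeying a leaky
first-order equation, plus an inactivation variable y_i providing slow
negative feedback that shapes the delayed decay during a sustained downstep:

    tau_d dx_d/dt = -x_d + y_d + D (W_d x_s - x_d) + I(t)
    tau_s dx_s/dt = -x_s + Y_s y_s + D (x_d + x_a - x_s)
    tau_a dx_a/dt = -x_a + Y_a y_a + D (W_a x_s - x_a)
    dy_i/dt       = -A x_i           (only while the stimulation epoch is on)

The input I(t) enters the dendrite only.  D is a coupling constant for
calcium diffusion between units; W_d and W_a split the somatic efflux
between dendrite and axon as a function of the instantaneous signs and
magnitudes of x_d and x_a.  Outside the stimulation epoch every y_i is held
at exactly zero, which prevents post-stimulus hyperpolarization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._kernel import integrate_kernel
from .errors import IntegrationError, InvalidStateError
from .stimulus import StimulusProtocol

__all__ = [
    "ModelParameters",
    "NeuronState",
    "DiffusionWeights",
    "SimulatedTraces",
    "REFERENCE_PARAMETERS",
    "diffusion_weights",
    "derivatives",
    "integrate",
    "IntegrationPlan",
    "integrate_plan",
]

REGIONS = ("dendrite", "soma", "axon")

#: Default integrator settings: step-doubling absolute tolerance per state
#: variable, and the largest internal step in seconds.
DEFAULT_TOL = 1e-8
DEFAULT_MAX_STEP = 0.05
#: Default output sampling interval in seconds (10 samples/s, matching the
#: imaging frame rate the model was calibrated against).
DEFAULT_DT_OUT = 0.1

_EPS = 1e-9


@dataclass(frozen=True)
class ModelParameters:
    """Fixed time constants plus the four free parameters of the model.

    tau_d, tau_s, tau_a : unit membrane/indicator time constants, seconds.
        Defaults (1.4, 3.7, 1.2) were derived from imaging of the three
        regions and are treated as fixed.
    D   : dimensionless inter-unit coupling (calcium diffusion strength).
    Y_s, Y_a : magnitudes of the inactivation feedback in soma and axon
        (the dendrite's magnitude is fixed at 1 by the equations).
    A   : timescale of the inactivation variable; smaller = slower.
    """

    tau_d: float = 1.4
    tau_s: float = 3.7
    tau_a: float = 1.2
    D: float = 0.0
    Y_s: float = 0.0
    Y_a: float = 0.0
    A: float = 0.0

    def __post_init__(self):
        if min(self.tau_d, self.tau_s, self.tau_a) <= 0:
            raise InvalidStateError("time constants must be positive")
        if self.D < 0:
            raise InvalidStateError("coupling constant D must be >= 0")
        if self.A < 0:
            raise InvalidStateError("inactivation timescale A must be >= 0")

    def with_free(self, D: float, Y_s: float, Y_a: float, A: float) -> "ModelParameters":
        return replace(self, D=D, Y_s=Y_s, Y_a=Y_a, A=A)

    def free_dict(self) -> dict:
        return {"D": self.D, "Y_s": self.Y_s, "Y_a": self.Y_a, "A": self.A}

    def to_dict(self) -> dict:
        return {
            "tau_d": self.tau_d, "tau_s": self.tau_s, "tau_a": self.tau_a,
            **self.free_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in d.items()})


#: Genetic-algorithm fit of the model to ASER imaging of a 60-s downstep
#: (mean over repeated optimization runs): D = 7.1, Y_s = 0.3, Y_a = -0.2,
#: A = 0.03.  Used as the ground truth of the synthetic fixtures.
REFERENCE_PARAMETERS = ModelParameters(D=7.1, Y_s=0.3, Y_a=-0.2, A=0.03)


@dataclass(frozen=True)
class NeuronState:
    """The six dynamical variables; the model always starts from all zeros."""

    x_d: float = 0.0
    x_s: float = 0.0
    x_a: float = 0.0
    y_d: float = 0.0
    y_s: float = 0.0
    y_a: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x_d, self.x_s, self.x_a,
                         self.y_d, self.y_s, self.y_a])

    @classmethod
    def from_array(cls, a) -> "NeuronState":
        return cls(*map(float, a))


@dataclass(frozen=True)
class DiffusionWeights:
    """Split of somatic calcium efflux toward dendrite (W_d) and axon (W_a)."""

    W_d: float
    W_a: float


def diffusion_weights(x_d: float, x_a: float) -> DiffusionWeights:
    """Sign-case table for the somatic diffusion weights.

    The more active neurite receives the smaller share: for same-sign
    positive activities W_d = |x_a|/(|x_d|+|x_a|) and W_a = |x_d|/(|x_d|+|x_a|)
    (for same-sign negative activities the shares swap); opposite signs send
    the full share to the negative side, and a unit at exactly zero forfeits
    its share.  Comparisons are strict (>0, <0, =0).
    """
    if not (math.isfinite(x_d) and math.isfinite(x_a)):
        raise InvalidStateError("diffusion weights need finite activities")
    if x_d > 0.0 and x_a < 0.0:
        return DiffusionWeights(0.0, 1.0)
    if x_d < 0.0 and x_a > 0.0:
        return DiffusionWeights(1.0, 0.0)
    if x_d == 0.0 and x_a == 0.0:
        return DiffusionWeights(0.0, 0.0)
    if x_d == 0.0:
        return DiffusionWeights(0.0, 1.0)
    if x_a == 0.0:
        return DiffusionWeights(0.0, 1.0) if x_d > 0.0 else DiffusionWeights(1.0, 0.0)
    tot = abs(x_d) + abs(x_a)
    if x_d > 0.0:  # both strictly positive
        return DiffusionWeights(abs(x_a) / tot, abs(x_d) / tot)
    return DiffusionWeights(abs(x_d) / tot, abs(x_a) / tot)  # both negative


def derivatives(state: NeuronState, params: ModelParameters, I: float,
                stimulus_active: bool) -> NeuronState:
    """Time derivative of the state at input level I.

    Pure-Python reference of the compiled kernel's right-hand side; the
    weights are recomputed from the instantaneous (x_d, x_a).
    """
    w = diffusion_weights(state.x_d, state.x_a)
    p = params
    dx_d = (-state.x_d + state.y_d + p.D * (w.W_d * state.x_s - state.x_d) + I) / p.tau_d
    dx_s = (-state.x_s + p.Y_s * state.y_s
            + p.D * (state.x_d + state.x_a - state.x_s)) / p.tau_s
    dx_a = (-state.x_a + p.Y_a * state.y_a
            + p.D * (w.W_a * state.x_s - state.x_a)) / p.tau_a
    if stimulus_active:
        dy = (-p.A * state.x_d, -p.A * state.x_s, -p.A * state.x_a)
    else:
        dy = (0.0, 0.0, 0.0)
    return NeuronState(dx_d, dx_s, dx_a, *dy)


@dataclass(frozen=True)
class SimulatedTraces:
    """Model activities sampled on a uniform time grid."""

    time: np.ndarray
    x_d: np.ndarray
    x_s: np.ndarray
    x_a: np.ndarray
    y_d: np.ndarray | None = None
    y_s: np.ndarray | None = None
    y_a: np.ndarray | None = None

    def stacked(self) -> np.ndarray:
        """Activities as a (3, n) array ordered dendrite, soma, axon."""
        return np.vstack([self.x_d, self.x_s, self.x_a])

    def region(self, name: str) -> np.ndarray:
        return {"dendrite": self.x_d, "soma": self.x_s, "axon": self.x_a}[name]

    def as_frame(self, include_y: bool = False) -> pd.DataFrame:
        cols = {"time_s": self.time, "x_dendrite": self.x_d,
                "x_soma": self.x_s, "x_axon": self.x_a}
        if include_y and self.y_d is not None:
            cols.update({"y_dendrite": self.y_d, "y_soma": self.y_s,
                         "y_axon": self.y_a})
        return pd.DataFrame(cols)


class IntegrationPlan:
    """Pre-compiled event schedule for repeated integration of one protocol.

    Building the merged list of output sample times, protocol breakpoints and
    epoch gates once lets a parameter search call the compiled kernel tens of
    thousands of times with no per-call protocol handling.
    """

    def __init__(self, protocol: StimulusProtocol, t_end: float | None = None,
                 dt_out: float = DEFAULT_DT_OUT):
        if t_end is None:
            t_end = protocol.horizon
        if t_end <= 0 or dt_out <= 0:
            raise InvalidStateError("t_end and dt_out must be positive")
        if t_end > protocol.horizon + _EPS:
            raise InvalidStateError("protocol does not cover [0, t_end]")
        n_out = int(round(t_end / dt_out))
        if abs(n_out * dt_out - t_end) > 1e-6:
            raise InvalidStateError("t_end must be a multiple of dt_out")
        samples = np.arange(n_out + 1) * dt_out
        samples[-1] = t_end
        bps = protocol.breakpoints()
        bps = bps[bps < t_end - _EPS]
        # keep only breakpoints not already on the sample grid
        if bps.size:
            near = np.abs(bps[:, None] - samples[None, :]).min(axis=1)
            bps = bps[near > 1e-9]
        ev = np.sort(np.concatenate([samples, bps]))
        on_grid = np.isin(ev, samples)
        mids = (ev[:-1] + ev[1:]) / 2.0
        ev_I = np.append(protocol.levels_at(mids), 0.0)
        ev_active = np.append(
            np.array([protocol.epoch_active(m) for m in mids]), False)
        # hard reset of y at the epoch-end gate (active -> inactive transition)
        ev_reset = np.zeros(ev.size, dtype=np.bool_)
        if protocol.epoch_end <= t_end + _EPS:
            k = int(np.argmin(np.abs(ev - protocol.epoch_end)))
            if abs(ev[k] - protocol.epoch_end) < 1e-6:
                ev_reset[k] = True
        self.protocol = protocol
        self.t_end = float(t_end)
        self.dt_out = float(dt_out)
        self.n_samples = n_out + 1
        self.ev_t = ev
        self.ev_I = ev_I
        self.ev_active = ev_active
        self.ev_reset = ev_reset
        self.is_sample = on_grid
        self.sample_times = samples


def integrate_plan(plan: IntegrationPlan, params: ModelParameters,
                   tol: float = DEFAULT_TOL, max_step: float = DEFAULT_MAX_STEP,
                   ) -> np.ndarray:
    """Run the kernel over a pre-built plan; returns the (n, 6) state samples."""
    out = np.empty((plan.n_samples, 6))
    status, t_fail = integrate_kernel(
        plan.ev_t, plan.ev_I, plan.ev_active, plan.ev_reset, plan.is_sample,
        params.tau_d, params.tau_s, params.tau_a,
        params.D, params.Y_s, params.Y_a, params.A,
        tol, max_step, out)
    if status != 0:
        raise IntegrationError("adaptive step size underflow", t_fail)
    return out


def integrate(params: ModelParameters, protocol: StimulusProtocol,
              t_end: float | None = None, dt_out: float = DEFAULT_DT_OUT,
              tol: float = DEFAULT_TOL, max_step: float = DEFAULT_MAX_STEP,
              ) -> SimulatedTraces:
    """Integrate the model from the all-zero state over a stimulus protocol.

    Fourth-order Runge-Kutta with adaptive step-doubling error control
    (absolute tolerance ``tol`` per state variable, internal step capped at
    ``max_step``).  Output is sampled at 0, dt_out, ..., t_end inclusive;
    internal steps never straddle a protocol breakpoint, and the inactivation
    variables are reset to zero when the stimulation epoch ends.
    """
    plan = IntegrationPlan(protocol, t_end, dt_out)
    out = integrate_plan(plan, params, tol=tol, max_step=max_step)
    return SimulatedTraces(
        time=plan.sample_times.copy(),
        x_d=out[:, 0].copy(), x_s=out[:, 1].copy(), x_a=out[:, 2].copy(),
        y_d=out[:, 3].copy(), y_s=out[:, 4].copy(), y_a=out[:, 5].copy())
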