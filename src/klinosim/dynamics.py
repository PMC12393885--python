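"""Sensory transduction and continuous-time sigmoid neuron dynamics.

The two amphid sensory neurons are modeled as stateless transducers of the
recent salt-concentration history: a coarse-grained time derivative ``z``
compares the mean concentration over a recent window of duration ``N``
against the mean over the preceding window of duration ``M``, scaled by 100.
Its positive part drives the ON cell (ASEL), its negative part the OFF cell
(ASER).

The eight stateful neurons follow leaky sigmoid-unit dynamics

    tau_i dy_i/dt = -y_i + sum_j w_ji z_j + sum_k g_ki (y_k - y_i) + I_i,

with release z_i = sigma(y_i + theta_i).  Interneurons receive the sensory
current only at AIY; motor neurons receive an antiphase sinusoidal drive of
period ``T`` plus their self-connection.  Integration is forward Euler with a
synchronous update: every right-hand-side term is evaluated at the previous
step, so the result does not depend on neuron ordering.

This module is the plain-numpy reference implementation used by the unit
fixtures and oracles; :mod:`klinosim._core` provides the compiled fast path
used by full assays, and the test suite checks the two against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circuit import (
    CircuitParameters,
    DORSAL_MOTOR,
    GAP_AIY,
    GAP_AIZ,
    MOTOR_NEURONS,
    STATE_NEURONS,
    VENTRAL_MOTOR,
)
from .errors import InvalidParameterError, NumericalDivergenceError


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)), elementwise."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def inverse_sigmoid(z, clip: float = 15.0):
    """Logit of z, clipped to [-clip, clip] so endpoint activations stay finite."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore"):
        y = np.log(z) - np.log1p(-z)
    return np.clip(y, -clip, clip)


def split_on_off(z: float) -> tuple[float, float]:
    """Split the signed concentration derivative into ON/OFF drive.

    Returns ``(z_on, z_off)`` with ``z_on = max(z, 0)`` feeding ASEL and
    ``z_off = max(-z, 0)`` feeding ASER; at most one is nonzero.
    """
    return (max(z, 0.0), max(-z, 0.0))


def is_unistable_self_weight(w_self: float) -> bool:
    """True when a self-connected sigmoid unit has a single stable branch.

    Self-weights below 4 keep the unit unistable, so its release responds
    smoothly (without hysteresis) to changes in input.
    """
    return w_self < 4.0


def oscillator_output(t: float, T: float) -> dict[str, float]:
    """Antiphase sinusoidal drive to the neck motor neurons at time ``t``.

    The dorsal pair receives sin(2*pi*t/T), the ventral pair the same signal
    shifted by half a cycle, so dorsal and ventral drives always sum to zero.
    """
    if T <= 0:
        raise InvalidParameterError("oscillation period T must be > 0")
    s = math.sin(2.0 * math.pi * t / T)
    out = {n: s for n in DORSAL_MOTOR}
    out.update({n: -s for n in VENTRAL_MOTOR})
    return out


# ---------------------------------------------------------------------------
# Concentration history
# ---------------------------------------------------------------------------


def window_steps(duration: float, dt: float) -> int:
    """Number of integration samples realizing an averaging window.

    Windows are realized as whole numbers of steps, at least one; the
    realized duration ``n*dt`` is what the transducer prefactor uses.
    """
    return max(1, int(round(duration / dt)))


class ConcentrationHistory:
    """Ring buffer of sensed concentration spanning both averaging windows.

    The buffer is pre-filled with the first pushed sample (the concentration
    at the start position), which makes the coarse-grained derivative zero at
    the start of a simulation.
    """

    def __init__(self, N: float, M: float, dt: float, c0: float = 0.0):
        if N <= 0 or M <= 0:
            raise InvalidParameterError("window durations N, M must be > 0")
        if dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        self.dt = dt
        self.n_recent = window_steps(N, dt)
        self.n_early = window_steps(M, dt)
        self._buf = np.full(self.n_recent + self.n_early, float(c0))

    def push(self, c: float) -> None:
        self._buf[:-1] = self._buf[1:]
        self._buf[-1] = float(c)

    @property
    def recent(self) -> np.ndarray:
        return self._buf[self.n_early:]

    @property
    def early(self) -> np.ndarray:
        return self._buf[: self.n_early]

    def derivative(self) -> float:
        """Coarse-grained derivative: 100 * (recent mean - earlier mean)."""
        return 100.0 * (float(self.recent.mean()) - float(self.early.mean()))


def sensory_derivative(history: ConcentrationHistory, N: float | None = None,
                       M: float | None = None) -> float:
    """Coarse-grained time derivative of the concentration history.

    Evaluates ``(100/N') * int_{t-N'}^{t} c dt  -  (100/M') * int earlier``
    as left-Riemann sums over the stored per-step samples, where N' and M'
    are the realized (whole-step) window durations.  ``N`` and ``M``, when
    given, must match the durations the history was built with.
    """
    if N is not None and window_steps(N, history.dt) != history.n_recent:
        raise InvalidParameterError("window N does not match history layout")
    if M is not None and window_steps(M, history.dt) != history.n_early:
        raise InvalidParameterError("window M does not match history layout")
    return history.derivative()


# ---------------------------------------------------------------------------
# Network state and stepping
# ---------------------------------------------------------------------------


@dataclass
class NetworkState:
    """Membrane potentials and releases of the eight stateful neurons."""

    y: dict[str, float]
    z: dict[str, float] = field(default_factory=dict)
    z_on: float = 0.0
    z_off: float = 0.0
    t: float = 0.0

    @classmethod
    def initial(cls, params: CircuitParameters,
                motor_z: dict[str, float] | None = None) -> "NetworkState":
        """Interneurons start at rest; motor releases may be prescribed."""
        y = {n: 0.0 for n in STATE_NEURONS}
        if motor_z:
            for n, z in motor_z.items():
                y[n] = float(inverse_sigmoid(z)) - params.theta[n]
        state = cls(y=y)
        state.refresh_release(params)
        return state

    def refresh_release(self, params: CircuitParameters) -> None:
        self.z = {n: float(sigmoid(self.y[n] + params.theta[n]))
                  for n in STATE_NEURONS}

    def y_array(self) -> np.ndarray:
        return np.array([self.y[n] for n in STATE_NEURONS])

    def z_array(self) -> np.ndarray:
        return np.array([self.z[n] for n in STATE_NEURONS])


def _input_current(name: str, state: NetworkState, params: CircuitParameters,
                   z_on: float, z_off: float) -> float:
    """Chemical, gap, sensory and oscillatory input current to one neuron."""
    y, z = state.y, state.z
    i = 0.0
    for (pre, post), w in params.w_chem.items():
        if post == name:
            i += w * z[pre]
    if name in ("AIYL", "AIYR"):
        other = "AIYR" if name == "AIYL" else "AIYL"
        i += params.g[GAP_AIY] * (y[other] - y[name])
        i += params.w_on[name] * z_on + params.w_off[name] * z_off
    elif name in ("AIZL", "AIZR"):
        other = "AIZR" if name == "AIZL" else "AIZL"
        i += params.g[GAP_AIZ] * (y[other] - y[name])
    elif name in MOTOR_NEURONS:
        side = "left" if name.endswith("L") else "right"
        i += params.w_self[side] * z[name]
        i += params.w_osc * oscillator_output(state.t, params.T)[name]
    return i


def step_network(state: NetworkState, params: CircuitParameters,
                 z_on: float, z_off: float, dt: float) -> NetworkState:
    """Advance all eight neurons by one synchronous forward-Euler step.

    Every right-hand-side term is evaluated on the incoming state, then all
    potentials are updated together and releases recomputed.  Raises
    :class:`NumericalDivergenceError` if the state leaves the finite range.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    new_y = {}
    for n in STATE_NEURONS:
        dy = (-state.y[n] + _input_current(n, state, params, z_on, z_off)) \
            / params.tau[n]
        new_y[n] = state.y[n] + dt * dy
    if not all(math.isfinite(v) for v in new_y.values()):
        raise NumericalDivergenceError("membrane potential became non-finite")
    out = NetworkState(y=new_y, z_on=z_on, z_off=z_off, t=state.t + dt)
    out.refresh_release(params)
    return out
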