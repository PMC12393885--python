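"""Chemotaxis assays: closed-loop integration of circuit and point worm.

The worm is a single point moving at constant speed v; its heading obeys
d(mu)/dt = phi with the turning rate

    phi = w_nmj * (z_SMBDL + z_SMBDR - z_SMBVL - z_SMBVR),

counterclockwise positive.  Each Euler step senses the local concentration,
advances the network, updates the heading from the fresh releases and then
displaces the worm by exactly v*dt along the new heading.

Chemotaxis performance is scored by the chemotaxis index

    CI = 1 - (1/T_sim) * int_0^{T_sim} h(t)/h(0) dt,

with h the distance to the gradient peak; CI is 0 for a worm that never
approaches the peak and 1 for a worm pinned at it.  An undulation penalty
of 0.008 is subtracted for every complete oscillator period whose turning
rate carries the same sign at the quarter- and three-quarter-cycle marks
(i.e. the worm is curving steadily rather than undulating); the total is
clamped to [0, 1] after the penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _core
from .circuit import (
    CircuitParameters,
    GAP_AIY,
    GAP_AIZ,
    MOTOR_NEURONS,
    STATE_NEURONS,
)
from .dynamics import inverse_sigmoid, window_steps
from .environment import Environment
from .errors import InvalidAssayError, InvalidParameterError, NumericalDivergenceError

#: Per-period chemotaxis-index deduction for non-undulating movement.
UNDULATION_PENALTY = 0.008


@dataclass
class Trajectory:
    """Per-step record of a simulated assay.

    All arrays have length ``n_steps + 1``; entry i is the state at time
    ``i*dt``.  ``phi[i]`` is the turning rate implied by the motor releases
    at that time.  When the assay was run with ``record_state`` the neuron
    potentials/releases and the sensory ON/OFF drives are included, in the
    canonical neuron order of :data:`klinosim.circuit.STATE_NEURONS`.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    phi: np.ndarray
    conc: np.ndarray
    dt: float
    y_state: np.ndarray | None = None
    z_state: np.ndarray | None = None
    z_on: np.ndarray | None = None
    z_off: np.ndarray | None = None

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def path_length(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    def to_dataframe(self):
        import pandas as pd

        cols = {"t": self.t, "x": self.x, "y": self.y,
                "heading": self.heading, "phi": self.phi, "conc": self.conc}
        if self.z_state is not None:
            for k, name in enumerate(STATE_NEURONS):
                cols[f"y_{name}"] = self.y_state[:, k]
                cols[f"z_{name}"] = self.z_state[:, k]
            cols["z_on"] = self.z_on
            cols["z_off"] = self.z_off
        return pd.DataFrame(cols)


@dataclass
class AssayConfig:
    """Configuration of a single chemotaxis assay.

    ``initial_heading`` and ``initial_motor_z`` default to None, in which
    case they are drawn from the seeded generator (heading uniform on
    [0, 2*pi), motor releases uniform on [0, 1], as in the fitness
    evaluation protocol).  Runs are deterministic given the seed.
    """

    environment: Environment
    duration: float = 1000.0
    dt: float = 0.01
    start: tuple[float, float] = (0.0, 0.0)
    initial_heading: float | None = None
    initial_motor_z: dict[str, float] | None = None
    seed: int | None = None
    record_state: bool = False
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise InvalidParameterError("dt and duration must be > 0")
        if self.record_stride < 1:
            raise InvalidParameterError("record_stride must be >= 1")


def turning_angle(z_motor: dict[str, float], w_nmj: float) -> float:
    """Turning rate (rad/s) from the four SMB releases, ccw positive."""
    dorsal = z_motor["SMBDL"] + z_motor["SMBDR"]
    ventral = z_motor["SMBVL"] + z_motor["SMBVR"]
    return w_nmj * (dorsal - ventral)


def step_worm(pos, mu: float, phi: float, v: float, dt: float):
    """One kinematic step: turn first, then move v*dt along the new heading."""
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    mu_new = mu + phi * dt
    x, y = pos
    return (x + v * dt * math.cos(mu_new), y + v * dt * math.sin(mu_new)), mu_new


def _pack_params(params: CircuitParameters):
    theta = np.array([params.theta[n] for n in STATE_NEURONS])
    tau = np.array([params.tau[n] for n in STATE_NEURONS])
    return dict(
        w_on=np.array([params.w_on["AIYL"], params.w_on["AIYR"]]),
        w_off=np.array([params.w_off["AIYL"], params.w_off["AIYR"]]),
        theta=theta, tau=tau,
        w_aiy_aiz=np.array([params.w_chem[("AIYL", "AIZL")],
                            params.w_chem[("AIYR", "AIZR")]]),
        g_aiy=params.g[GAP_AIY], g_aiz=params.g[GAP_AIZ],
        w_aiz_smb=np.array([params.w_chem[("AIZL", "SMBDL")],
                            params.w_chem[("AIZR", "SMBDR")]]),
        w_self=np.array([params.w_self["left"], params.w_self["right"]]),
        w_osc=params.w_osc, w_nmj=params.w_nmj,
        period=params.T, speed=params.v,
    )


def _initial_y(params: CircuitParameters, motor_z: dict[str, float]) -> np.ndarray:
    y = np.zeros(len(STATE_NEURONS))
    for name, z in motor_z.items():
        k = STATE_NEURONS.index(name)
        y[k] = float(inverse_sigmoid(z)) - params.theta[name]
    return y


def _env_args(env: Environment | None, conc_series: np.ndarray | None):
    if conc_series is not None:
        return dict(env_kind=_core.ENV_SERIES, peak_x=0.0, peak_y=0.0,
                    alpha=-1.0, c0=1.0, lam=1.0,
                    c_series=np.asarray(conc_series, dtype=float))
    empty = np.empty(0)
    if env.kind == "conical":
        return dict(env_kind=_core.ENV_CONICAL, peak_x=env.peak[0],
                    peak_y=env.peak[1], alpha=env.alpha, c0=0.0, lam=1.0,
                    c_series=empty)
    return dict(env_kind=_core.ENV_GAUSSIAN, peak_x=env.peak[0],
                peak_y=env.peak[1], alpha=-1.0, c0=env.C0, lam=env.lam,
                c_series=empty)


def run_assay(params: CircuitParameters, config: AssayConfig,
              conc_series: np.ndarray | None = None) -> Trajectory:
    """Run one closed-loop chemotaxis assay and return its trajectory.

    ``conc_series``, when given, replaces the spatial field with a
    prescribed, spatially uniform concentration time series of length
    ``n_steps + 1`` (used by step-response probes); the environment in the
    config is then ignored for sensing but the worm still moves.
    """
    n_steps = int(round(config.duration / config.dt))
    stride = config.record_stride
    if n_steps % stride != 0:
        raise InvalidParameterError(
            "record_stride must divide the number of steps")
    rng = np.random.default_rng(config.seed)
    heading0 = config.initial_heading
    if heading0 is None:
        heading0 = float(rng.uniform(0.0, 2.0 * math.pi))
    motor_z = config.initial_motor_z
    if motor_z is None:
        motor_z = {n: float(rng.uniform(0.0, 1.0)) for n in MOTOR_NEURONS}
    if conc_series is not None and len(conc_series) < n_steps + 1:
        raise InvalidParameterError(
            "conc_series must cover n_steps + 1 samples")

    pk = _pack_params(params)
    ek = _env_args(config.environment, conc_series)
    xs, ys, mus, phis, concs, y_rec, z_rec, zon, zoff, status = _core.simulate(
        n_steps, config.dt,
        window_steps(params.N, config.dt), window_steps(params.M, config.dt),
        pk["w_on"], pk["w_off"], pk["theta"], pk["tau"],
        pk["w_aiy_aiz"], pk["g_aiy"], pk["g_aiz"], pk["w_aiz_smb"],
        pk["w_self"], pk["w_osc"], pk["w_nmj"], pk["period"], pk["speed"],
        ek["env_kind"], ek["peak_x"], ek["peak_y"], ek["alpha"], ek["c0"],
        ek["lam"], ek["c_series"],
        float(config.start[0]), float(config.start[1]), heading0,
        _initial_y(params, motor_z),
        config.record_state, stride,
    )
    if status != 0:
        raise NumericalDivergenceError("network state diverged during assay")
    t = np.arange(n_steps // stride + 1) * (config.dt * stride)
    traj = Trajectory(t=t, x=xs, y=ys, heading=mus, phi=phis, conc=concs,
                      dt=config.dt * stride)
    if config.record_state:
        traj.y_state, traj.z_state = y_rec, z_rec
        traj.z_on, traj.z_off = zon, zoff
    return traj


# ---------------------------------------------------------------------------
# Chemotaxis index
# ---------------------------------------------------------------------------


def count_penalty_events(traj: Trajectory, T: float) -> int:
    """Complete oscillator periods whose quarter- and three-quarter-phase
    turning rates share a sign (both-zero counts as shared: no undulation)."""
    n_steps = len(traj.t) - 1
    events = 0
    k = 0
    while True:
        i_quarter = int(round((k + 0.25) * T / traj.dt))
        i_three_q = int(round((k + 0.75) * T / traj.dt))
        i_end = int(round((k + 1.0) * T / traj.dt))
        if i_end > n_steps:
            break
        if np.sign(traj.phi[i_quarter]) == np.sign(traj.phi[i_three_q]):
            events += 1
        k += 1
    return events


def chemotaxis_index(traj: Trajectory, env: Environment,
                     penalty_enabled: bool = True,
                     params: CircuitParameters | None = None,
                     h0: float | None = None) -> float:
    """Chemotaxis index of a trajectory, in [0, 1].

    The time average of h(t)/h(0) is a left-Riemann sum over the recorded
    steps.  When the penalty is enabled the per-period undulation deduction
    is subtracted before clamping to [0, 1].  ``params`` supplies the
    oscillator period for the penalty clock (required when penalty_enabled).
    ``h0`` overrides the normalizing start distance (by default the
    trajectory's own start-to-peak distance); an assay that starts on the
    peak without an override is ill-posed.
    """
    if len(traj.t) < 2:
        raise InvalidAssayError("trajectory must contain at least one step")
    h = np.hypot(traj.x - env.peak[0], traj.y - env.peak[1])
    if h0 is None:
        h0 = float(h[0])
    if h0 == 0.0:
        raise InvalidAssayError("worm starts on the gradient peak; h(0) = 0")
    ci = 1.0 - float(np.mean(h[:-1] / h0))
    if penalty_enabled:
        if params is None:
            raise InvalidParameterError(
                "params (oscillator period) required when penalty is enabled")
        ci -= UNDULATION_PENALTY * count_penalty_events(traj, params.T)
    return float(min(max(ci, 0.0), 1.0))
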