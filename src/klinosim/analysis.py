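"""Behavioral and circuit-perturbation analyses of klinotaxis.

The central behavioral quantity is the curving rate: over a window of six
undulation cycles the trajectory is reduced to three points (start, midpoint
after three cycles, end after six), giving two displacement vectors r1 and
r2.  The signed angle from r1 to r2 (counterclockwise positive) divided by
|r1| + |r2| measures how sharply the worm curves per unit path length.  The
curving rate is paired with the bearing (signed angle from the translational
movement vector to the peak direction) and with the salt-concentration
gradient normal to / along the movement direction, sampled at the window
midpoint.  Ensembles of short assays yield the statistics relating these
quantities; segments overlapping the first three cycles are discarded
because the sensory derivative is not meaningful while its averaging windows
still contain the pre-filled start concentration.

Circuit perturbations mirror the model experiments: sweeping the ASER->AIY
synapse from inhibitory to excitatory in increments of 1.5, scaling the
AIZ->SMB synapses and SMB self-connections by 0.9 (or lowering the SMB
biases) to inhibit the motor neurons, and zeroing the gap junctions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import CircuitParameters, MOTOR_NEURONS
from .environment import Environment, normal_gradient, translational_gradient
from .errors import (
    DegenerateSegmentError,
    InvalidParameterError,
    InvalidPerturbationError,
    UndefinedBearingError,
)
from .simulator import AssayConfig, Trajectory, run_assay

#: Half-window cycle count: each displacement vector spans n undulation cycles.
CYCLES_PER_SPAN = 3


# ---------------------------------------------------------------------------
# Cycle segments, curving rate, bearing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleSegment:
    """Three trajectory points spanning two spans of n undulation cycles.

    ``start``, ``mid`` and ``end`` are positions at oscillator phases 0,
    2*n*pi and 4*n*pi relative to the segment start.  ``r1 = mid - start``
    and ``r2 = end - mid`` are the span displacement vectors.
    """

    start: tuple[float, float]
    mid: tuple[float, float]
    end: tuple[float, float]

    @property
    def r1(self) -> np.ndarray:
        return np.asarray(self.mid) - np.asarray(self.start)

    @property
    def r2(self) -> np.ndarray:
        return np.asarray(self.end) - np.asarray(self.mid)


def _signed_angle(u: np.ndarray, w: np.ndarray) -> float:
    """Signed angle from u to w, counterclockwise positive, in (-pi, pi]."""
    cross = u[0] * w[1] - u[1] * w[0]
    dot = u[0] * w[0] + u[1] * w[1]
    ang = math.atan2(cross, dot)
    return math.pi if ang == -math.pi else ang


def curving_rate(segment: CycleSegment) -> float:
    """Turning angle over six cycles per unit path length (rad/cm).

    The angle between the two span vectors (ccw positive) divided by the sum
    of their lengths.
    """
    r1, r2 = segment.r1, segment.r2
    d = float(np.hypot(*r1) + np.hypot(*r2))
    if np.hypot(*r1) == 0.0 or np.hypot(*r2) == 0.0:
        raise DegenerateSegmentError("zero-length span vector")
    return _signed_angle(r1, r2) / d


def bearing(segment: CycleSegment, peak: tuple[float, float]) -> float:
    """Signed angle from the translational-movement vector to the peak
    direction, evaluated at the segment midpoint; ccw positive, in
    (-pi, pi] (the anti-parallel case maps to +pi)."""
    r1 = segment.r1
    if np.hypot(*r1) == 0.0:
        raise DegenerateSegmentError("zero-length translational vector")
    to_peak = np.asarray(peak, dtype=float) - np.asarray(segment.mid)
    if np.hypot(*to_peak) == 0.0:
        raise UndefinedBearingError("segment midpoint lies on the peak")
    return _signed_angle(r1, to_peak)


def cycle_segments(traj: Trajectory, period: float,
                   n: int = CYCLES_PER_SPAN,
                   skip_cycles: int = CYCLES_PER_SPAN) -> list[CycleSegment]:
    """Consecutive six-cycle segments of a trajectory on the oscillator clock.

    Segment k starts at t = (skip_cycles + k*n) * period; segments extending
    beyond the trajectory are dropped.  The default skips the first three
    cycles, whose sensory input is distorted by the history warm-up.
    """
    span = n * period
    segments = []
    t0 = skip_cycles * period
    duration = traj.duration
    while t0 + 2 * span <= duration + 1e-9:
        i0 = int(round(t0 / traj.dt))
        i1 = int(round((t0 + span) / traj.dt))
        i2 = int(round((t0 + 2 * span) / traj.dt))
        segments.append(CycleSegment(
            start=(traj.x[i0], traj.y[i0]),
            mid=(traj.x[i1], traj.y[i1]),
            end=(traj.x[i2], traj.y[i2]),
        ))
        t0 += span
    return segments


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------


@dataclass
class KlinotaxisStats:
    """Paired behavioral samples from an ensemble of assays.

    ``samples`` has one row per six-cycle segment with columns ``curving``
    (rad/cm), ``bearing`` (rad), ``normal_grad`` and ``trans_grad`` (mM/cm).
    """

    samples: pd.DataFrame

    def binned(self, x: str, y: str = "curving", bins: int = 8,
               min_count: int = 1) -> pd.DataFrame:
        """Mean and SD of ``y`` in equal-width bins of ``x``."""
        df = self.samples
        edges = np.linspace(df[x].min(), df[x].max(), bins + 1)
        idx = np.clip(np.digitize(df[x], edges) - 1, 0, bins - 1)
        grouped = df.assign(_bin=idx).groupby("_bin")[y]
        out = pd.DataFrame({
            "center": 0.5 * (edges[:-1] + edges[1:]),
            "mean": grouped.mean().reindex(range(bins)),
            "sd": grouped.std().reindex(range(bins)),
            "count": grouped.count().reindex(range(bins), fill_value=0),
        })
        return out[out["count"] >= min_count].reset_index(drop=True)

    def slope(self, x: str = "normal_grad", y: str = "curving") -> float:
        """Least-squares slope of y against x over all samples."""
        return float(np.polyfit(self.samples[x], self.samples[y], 1)[0])

    def signed_components(self, x: str = "trans_grad",
                          bins: int = 6) -> pd.DataFrame:
        """Binned means of the positive and negative curving components.

        Positive components sample leftward turns, negative components
        rightward turns; ``average`` is the mean of the two binned
        components, which dorsoventral symmetry keeps near zero.
        """
        df = self.samples
        edges = np.linspace(df[x].min(), df[x].max(), bins + 1)
        idx = np.clip(np.digitize(df[x], edges) - 1, 0, bins - 1)
        tagged = df.assign(_bin=idx)
        pos = tagged[tagged["curving"] > 0].groupby("_bin")["curving"].mean()
        neg = tagged[tagged["curving"] < 0].groupby("_bin")["curving"].mean()
        out = pd.DataFrame({
            "center": 0.5 * (edges[:-1] + edges[1:]),
            "positive": pos.reindex(range(bins)),
            "negative": neg.reindex(range(bins)),
        })
        out["average"] = (out["positive"] + out["negative"]) / 2.0
        return out


def trajectory_samples(traj: Trajectory, env: Environment,
                       period: float) -> list[dict]:
    """Per-segment (curving, bearing, gradients) samples of one trajectory.

    Gradients and bearing are evaluated at the segment midpoint with the
    movement direction taken from the first span vector.
    """
    rows = []
    for seg in cycle_segments(traj, period):
        r1 = seg.r1
        if np.hypot(*r1) == 0.0:
            continue
        heading = math.atan2(r1[1], r1[0])
        mid = seg.mid
        try:
            b = bearing(seg, env.peak)
        except UndefinedBearingError:
            continue
        rows.append({
            "curving": curving_rate(seg),
            "bearing": b,
            "normal_grad": normal_gradient(env, mid, heading),
            "trans_grad": translational_gradient(env, mid, heading),
        })
    return rows


def klinotaxis_ensemble(params: CircuitParameters, env: Environment,
                        n_runs: int, run_duration: float = 200.0,
                        dt: float = 0.01,
                        start_radius: float = 4.5,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None) -> KlinotaxisStats:
    """Behavioral statistics over an ensemble of short Gaussian-plate assays.

    Each run starts at a uniformly random position within ``start_radius``
    of the peak with random orientation and motor activations.  Returns the
    pooled per-segment samples.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for _ in range(n_runs):
        r = start_radius * math.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * math.pi)
        start = (env.peak[0] + r * math.cos(ang),
                 env.peak[1] + r * math.sin(ang))
        config = AssayConfig(
            environment=env, duration=run_duration, dt=dt, start=start,
            initial_heading=float(rng.uniform(0.0, 2.0 * math.pi)),
            initial_motor_z={n: float(rng.uniform()) for n in MOTOR_NEURONS},
        )
        traj = run_assay(params, config)
        rows.extend(trajectory_samples(traj, env, params.T))
    return KlinotaxisStats(samples=pd.DataFrame(
        rows, columns=["curving", "bearing", "normal_grad", "trans_grad"]))


# ---------------------------------------------------------------------------
# Step-response probes
# ---------------------------------------------------------------------------


@dataclass
class StepResponse:
    """Neuron traces of a concentration-step probe.

    ``traj`` carries the recorded z traces and turning rate of the probed
    circuit; ``reference`` is the same circuit with sensory weights zeroed
    (the no-input oscillatory baseline).  ``step_time`` is when the uniform
    concentration steps by ``magnitude`` (signed).
    """

    traj: Trajectory
    reference: Trajectory
    magnitude: float
    step_time: float


def step_response(params: CircuitParameters, magnitude: float,
                  sign: int = 1, phase_delay: float = 0.0,
                  base_conc: float = 1.0,
                  settle_periods: int = 12, total_periods: int = 24,
                  dt: float = 0.01) -> StepResponse:
    """Response of the circuit to a step in spatially uniform concentration.

    The concentration is uniform in space (the worm's own movement cannot
    change its sensory input) and steps by ``sign * magnitude`` at an
    oscillator-phase-locked time ``(settle_periods + phase_delay) * T``.
    ``phase_delay`` is a fraction of a cycle (0.5 delays the step by half a
    cycle).  Returns the probed and the sensory-silenced reference traces.
    """
    if magnitude < 0:
        raise InvalidParameterError("magnitude must be >= 0; use sign=-1")
    T = params.T
    duration = total_periods * T
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt
    step_time = (settle_periods + phase_delay) * T
    series = np.where(t < step_time, base_conc,
                      base_conc + sign * magnitude).astype(float)
    config = AssayConfig(
        environment=Environment.gaussian(), duration=duration, dt=dt,
        initial_heading=0.0,
        initial_motor_z={n: 0.5 for n in MOTOR_NEURONS},
        record_state=True,
    )
    traj = run_assay(params, config, conc_series=series)
    silenced = params.copy()
    silenced.w_on = {k: 0.0 for k in silenced.w_on}
    silenced.w_off = {k: 0.0 for k in silenced.w_off}
    reference = run_assay(silenced, config, conc_series=series)
    return StepResponse(traj=traj, reference=reference,
                        magnitude=sign * magnitude, step_time=step_time)


# ---------------------------------------------------------------------------
# Circuit perturbations
# ---------------------------------------------------------------------------


def aser_aiy_sweep(params: CircuitParameters, increment: float = 1.5,
                   n_steps: int = 15) -> list[CircuitParameters]:
    """Shift both ASER->AIY weights by k * increment, k = 0..n_steps.

    Variant #0 is the unmodified circuit; with the default increment the
    sweep carries an inhibitory synapse of the best evolved circuits into
    the excitatory range.  All other parameters are untouched.
    """
    variants = []
    for k in range(n_steps + 1):
        p = params.copy()
        p.w_off = {side: w + k * increment for side, w in params.w_off.items()}
        variants.append(p)
    return variants


def inhibit_smb(params: CircuitParameters, factor: float = 0.9,
                mode: str = "scale_weights",
                bias_delta: float = 1.0) -> CircuitParameters:
    """Inhibit the SMB motor neurons.

    ``scale_weights`` multiplies the AIZ->SMB synapses and the SMB
    self-connections by ``factor`` (must lie in (0, 1]); ``reduce_bias``
    subtracts ``bias_delta`` from the SMB biases instead.
    """
    p = params.copy()
    if mode == "scale_weights":
        if not 0.0 < factor <= 1.0:
            raise InvalidPerturbationError("factor must lie in (0, 1]")
        p.w_chem = {
            edge: (w * factor if edge[1] in MOTOR_NEURONS else w)
            for edge, w in params.w_chem.items()
        }
        p.w_self = {side: w * factor for side, w in params.w_self.items()}
    elif mode == "reduce_bias":
        p.theta = {
            n: (th - bias_delta if n in MOTOR_NEURONS else th)
            for n, th in params.theta.items()
        }
    else:
        raise InvalidPerturbationError(f"unknown mode {mode!r}")
    return p


def block_gap_junctions(params: CircuitParameters) -> CircuitParameters:
    """Zero all gap-junction conductances; everything else unchanged."""
    p = params.copy()
    p.g = {pair: 0.0 for pair in params.g}
    return p
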