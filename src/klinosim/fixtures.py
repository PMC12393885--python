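"""Hand-built mini-circuits with closed-form expected behavior.

Each fixture is expressed within the fixed ten-neuron topology by zeroing
the connections that play no role, so the same simulation machinery that
runs full assays also runs the fixtures.  Every fixture returns the circuit
together with a machine-checkable expectation descriptor used by the test
suite and by quick CLI sanity checks.
"""

from __future__ import annotations

from .circuit import (
    CircuitParameters,
    DEFAULT_TAU,
    GAP_AIY,
    GAP_AIZ,
    STATE_NEURONS,
)
from .errors import UnknownFixtureError


def blank_parameters(tau: float = DEFAULT_TAU, **overrides) -> CircuitParameters:
    """An all-zero circuit (every weight, bias and conductance zero).

    A worm driven by this circuit has all four motor releases equal (0.5),
    hence zero turning rate, and moves in a straight line.  Keyword
    overrides replace whole fields (e.g. ``w_osc=2.0``).
    """
    base = dict(
        N=1.0, M=1.0,
        w_on={"AIYL": 0.0, "AIYR": 0.0},
        w_off={"AIYL": 0.0, "AIYR": 0.0},
        theta={n: 0.0 for n in STATE_NEURONS},
        w_chem={
            ("AIYL", "AIZL"): 0.0, ("AIYR", "AIZR"): 0.0,
            ("AIZL", "SMBDL"): 0.0, ("AIZL", "SMBVL"): 0.0,
            ("AIZR", "SMBDR"): 0.0, ("AIZR", "SMBVR"): 0.0,
        },
        g={GAP_AIY: 0.0, GAP_AIZ: 0.0},
        w_self={"left": 0.0, "right": 0.0},
        w_osc=0.0, w_nmj=2.0,
        tau={n: tau for n in STATE_NEURONS},
    )
    base.update(overrides)
    return CircuitParameters(**base)


def _dead():
    params = blank_parameters()
    return params, {"kind": "straight_line",
                    "note": "zero circuit; constant heading, zero turning"}


def _osc_only():
    params = blank_parameters(w_osc=2.0)
    return params, {"kind": "heading_oscillation", "period": params.T,
                    "note": "oscillatory drive only; heading oscillates at T"}


def _gap_pair():
    params = blank_parameters()
    params.g = {GAP_AIY: 1.5, GAP_AIZ: 0.0}
    return params, {"kind": "gap_equalization", "pair": ("AIYL", "AIYR"),
                    "note": "antisymmetric AIY potentials decay to zero; "
                            "their sum is conserved under the gap current"}


def _single_neuron():
    params = blank_parameters()
    params.w_on = {"AIYL": 1.0, "AIYR": 0.0}
    return params, {"kind": "first_order_relaxation", "neuron": "AIYL",
                    "note": "constant sensory current I drives y to the "
                            "fixed point y* = w_on * I"}


def _inhibitory_chain():
    params = blank_parameters()
    params.w_off = {"AIYL": -8.0, "AIYR": 0.0}
    params.w_chem = dict(params.w_chem)
    params.w_chem[("AIYL", "AIZL")] = -8.0
    return params, {"kind": "sign_chain", "path": ("ASER", "AIYL", "AIZL"),
                    "note": "double inhibition: an OFF step raises AIZL "
                            "release above baseline"}


def _constant_turner():
    # bistable self-connections (w_self > 4) latch each motor neuron onto
    # the branch chosen by its initial activation; with dorsal started high
    # and ventral low the turning rate keeps a constant positive sign
    params = blank_parameters()
    params.w_self = {"left": 6.0, "right": 6.0}
    params.theta = dict(params.theta)
    for n in ("SMBDL", "SMBVL", "SMBDR", "SMBVR"):
        params.theta[n] = -3.0
    return params, {"kind": "constant_sign_phi",
                    "initial_motor_z": {"SMBDL": 0.9, "SMBDR": 0.9,
                                        "SMBVL": 0.1, "SMBVR": 0.1},
                    "note": "no oscillation; dorsoventral imbalance latched "
                            "by bistable self-connections, so every period "
                            "incurs the undulation penalty"}


_REGISTRY = {
    "dead": _dead,
    "osc_only": _osc_only,
    "gap_pair": _gap_pair,
    "single_neuron": _single_neuron,
    "inhibitory_chain": _inhibitory_chain,
    "constant_turner": _constant_turner,
}


def fixture_names() -> tuple[str, ...]:
    return tuple(_REGISTRY)


def make_fixture(name: str) -> tuple[CircuitParameters, dict]:
    """Return a named mini-circuit and its expectation descriptor."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; known: {sorted(_REGISTRY)}") from None
    return builder()
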