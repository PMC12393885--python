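"""Topology, parameters and genome encoding of the minimal klinotaxis circuit.

The circuit contains ten neurons: two salt-sensing amphid neurons (ASEL, the
ON cell, and ASER, the OFF cell), four interneurons (AIYL/R, AIZL/R) and four
neck motor neurons (SMBDL/VL/DR/VR).  Sensory neurons are stateless
transducers of the recent concentration history; the remaining eight neurons
are continuous-time sigmoid units.  Left/right AIY and AIZ pairs are coupled
by gap junctions, and the motor neurons carry self-connections plus a
constitutive oscillatory drive that paces the undulation.

Dorsoventral symmetry constraints tie the AIZ->SMB weights, the SMB biases
and the SMB self-weights together on each body side, which brings the number
of free electrophysiological parameters down to exactly 22.  Those 22 values
are what the evolutionary search manipulates, encoded as a genome of reals in
[-1, 1] that is linearly mapped onto the physiological ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import InvalidGenomeError, InvalidParameterError, UnreachableError

# ---------------------------------------------------------------------------
# Neuron identities
# ---------------------------------------------------------------------------

SENSORY_NEURONS: tuple[str, ...] = ("ASEL", "ASER")
INTERNEURONS: tuple[str, ...] = ("AIYL", "AIYR", "AIZL", "AIZR")
MOTOR_NEURONS: tuple[str, ...] = ("SMBDL", "SMBVL", "SMBDR", "SMBVR")
#: Canonical ordering of the eight neurons that carry membrane-potential state.
STATE_NEURONS: tuple[str, ...] = INTERNEURONS + MOTOR_NEURONS
ALL_NEURONS: tuple[str, ...] = SENSORY_NEURONS + STATE_NEURONS

DORSAL_MOTOR: tuple[str, ...] = ("SMBDL", "SMBDR")
VENTRAL_MOTOR: tuple[str, ...] = ("SMBVL", "SMBVR")

_NEURON_CLASS = {
    **{n: "sensory" for n in SENSORY_NEURONS},
    **{n: "interneuron" for n in INTERNEURONS},
    **{n: "motor" for n in MOTOR_NEURONS},
}


def neuron_class(name: str) -> str:
    """Return 'sensory', 'interneuron' or 'motor' for a neuron name."""
    try:
        return _NEURON_CLASS[name]
    except KeyError:
        raise InvalidParameterError(f"unknown neuron {name!r}") from None


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Topology:
    """Directed chemical synapses, undirected gap junctions and self-edges.

    ``chemical_edges`` are ordered (pre, post) pairs, ``gap_edges`` unordered
    pairs stored as frozensets, ``self_edges`` the motor neurons that carry a
    self-connection.
    """

    chemical_edges: frozenset[tuple[str, str]]
    gap_edges: frozenset[frozenset[str]]
    self_edges: frozenset[str]

    def without_gap_edges(self, *pairs: Iterable[str]) -> "Topology":
        """Return a copy with the given gap-junction pairs removed."""
        drop = {frozenset(p) for p in pairs} if pairs else set(self.gap_edges)
        return replace(self, gap_edges=frozenset(self.gap_edges - drop))

    def with_chemical_edge(self, pre: str, post: str) -> "Topology":
        return replace(
            self, chemical_edges=frozenset(self.chemical_edges | {(pre, post)})
        )

    def chemical_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(ALL_NEURONS)
        g.add_edges_from(self.chemical_edges)
        return g

    def write_edgelist(self, path) -> None:
        """Export as a plain-text edge list (one edge per line, with an
        edge-type column: chem, gap or self)."""
        lines = [f"{a}\t{b}\tchem" for a, b in sorted(self.chemical_edges)]
        lines += [f"{a}\t{b}\tgap" for a, b in
                  sorted(tuple(sorted(p)) for p in self.gap_edges)]
        lines += [f"{n}\t{n}\tself" for n in sorted(self.self_edges)]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def minimal_topology() -> Topology:
    """The connectome-derived minimal circuit (fixed in this package)."""
    chem = [
        ("ASEL", "AIYL"), ("ASEL", "AIYR"),
        ("ASER", "AIYL"), ("ASER", "AIYR"),
        ("AIYL", "AIZL"), ("AIYR", "AIZR"),
        ("AIZL", "SMBDL"), ("AIZL", "SMBVL"),
        ("AIZR", "SMBDR"), ("AIZR", "SMBVR"),
    ]
    gaps = [frozenset({"AIYL", "AIYR"}), frozenset({"AIZL", "AIZR"})]
    return Topology(
        chemical_edges=frozenset(chem),
        gap_edges=frozenset(gaps),
        self_edges=frozenset(MOTOR_NEURONS),
    )


MINIMAL_TOPOLOGY = minimal_topology()


def shortest_sensor_to_motor_path(topology: Topology) -> int:
    """Shortest directed chemical-synapse path length from any ASE to any SMB.

    Raises :class:`UnreachableError` when no motor neuron can be reached from
    either sensory neuron through chemical synapses.
    """
    g = topology.chemical_graph()
    best: int | None = None
    for src in SENSORY_NEURONS:
        lengths = nx.single_source_shortest_path_length(g, src)
        for dst in MOTOR_NEURONS:
            if dst in lengths:
                best = lengths[dst] if best is None else min(best, lengths[dst])
    if best is None:
        raise UnreachableError("no chemical path from ASE to SMB")
    return best


# Side-sharing of motor-neuron parameters: dorsal and ventral units on the
# same body side share their AIZ->SMB weight, bias and self-weight.
_SIDE_OF_MOTOR = {"SMBDL": "left", "SMBVL": "left", "SMBDR": "right", "SMBVR": "right"}


def count_free_parameters(topology: Topology) -> int:
    """Number of independent evolvable parameters of a circuit topology.

    Counts the two sensory averaging windows, one weight per chemical edge
    (with dorsoventral sharing collapsing the AIZ->SMB fan-outs per side),
    one bias per interneuron plus one shared bias per motor side, one
    conductance per gap junction pair, one shared self-weight per motor side
    with a self-edge, and the oscillator and neuromuscular gains.
    """
    n = 2  # sensory windows N, M
    chem_params: set[tuple[str, str]] = set()
    for pre, post in topology.chemical_edges:
        if post in _SIDE_OF_MOTOR:
            chem_params.add((pre, _SIDE_OF_MOTOR[post]))
        else:
            chem_params.add((pre, post))
    n += len(chem_params)
    n += len(INTERNEURONS)  # independent left/right interneuron biases
    n += len({_SIDE_OF_MOTOR[m] for m in MOTOR_NEURONS})  # shared motor biases
    n += len(topology.gap_edges)
    n += len({_SIDE_OF_MOTOR[m] for m in topology.self_edges})
    n += 2  # w_osc, w_nmj
    return n


# ---------------------------------------------------------------------------
# Circuit parameters
# ---------------------------------------------------------------------------

#: Undulation period on agar (s).
DEFAULT_PERIOD = 4.2
#: Constant crawling speed (cm/s).
DEFAULT_SPEED = 0.022
#: Membrane time constant applied to every stateful neuron (s).  The time
#: constants are not part of the evolved parameter set; a single configurable
#: value is used throughout.
DEFAULT_TAU = 0.1

AIY_SIDES = ("AIYL", "AIYR")
MOTOR_SIDES = ("left", "right")


@dataclass
class CircuitParameters:
    """Full parameter set of the ten-neuron klinotaxis circuit.

    Attributes
    ----------
    N, M
        Durations (s) of the recent and earlier concentration-averaging
        windows of the sensory transducer.
    w_on, w_off
        Synaptic weights from ASEL (ON cell) and ASER (OFF cell) onto each
        AIY interneuron, keyed by AIY name.
    theta
        Bias terms of the eight stateful neurons.  Dorsal/ventral motor
        biases are tied per side and must be equal.
    w_chem
        Chemical synaptic weights keyed by (pre, post).  The AIZ->SMB
        weights are tied dorsoventrally per side.
    g
        Gap-junction conductances keyed by unordered neuron pair (>= 0).
    w_self
        Motor self-connection weight per body side ('left', 'right'),
        shared by the dorsal and ventral unit of that side.
    w_osc
        Strength of the constitutive oscillatory motor drive (>= 0).
    w_nmj
        Neuromuscular gain converting the dorsoventral release difference
        into a turning rate (rad/s).
    tau
        Membrane time constants (s) per stateful neuron.
    T
        Undulation period of the oscillatory drive (s).
    v
        Crawling speed (cm/s).
    """

    N: float
    M: float
    w_on: dict[str, float]
    w_off: dict[str, float]
    theta: dict[str, float]
    w_chem: dict[tuple[str, str], float]
    g: dict[frozenset[str], float]
    w_self: dict[str, float]
    w_osc: float
    w_nmj: float
    tau: dict[str, float] = field(
        default_factory=lambda: {n: DEFAULT_TAU for n in STATE_NEURONS}
    )
    T: float = DEFAULT_PERIOD
    v: float = DEFAULT_SPEED

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.N > 0 and self.M > 0):
            raise InvalidParameterError("window durations N, M must be > 0")
        if any(t <= 0 for t in self.tau.values()):
            raise InvalidParameterError("time constants must be > 0")
        if any(c < 0 for c in self.g.values()):
            raise InvalidParameterError("gap conductances must be >= 0")
        if self.w_osc < 0:
            raise InvalidParameterError("oscillator strength must be >= 0")
        if self.T <= 0:
            raise InvalidParameterError("oscillation period must be > 0")
        # dorsoventral sharing on each side
        for side, (d, vn) in (("left", ("SMBDL", "SMBVL")),
                              ("right", ("SMBDR", "SMBVR"))):
            pre = "AIZL" if side == "left" else "AIZR"
            if self.w_chem[(pre, d)] != self.w_chem[(pre, vn)]:
                raise InvalidParameterError(
                    f"AIZ->SMB weights not dorsoventrally shared on {side}")
            if self.theta[d] != self.theta[vn]:
                raise InvalidParameterError(
                    f"SMB biases not dorsoventrally shared on {side}")

    def copy(self) -> "CircuitParameters":
        return CircuitParameters(
            N=self.N, M=self.M,
            w_on=dict(self.w_on), w_off=dict(self.w_off),
            theta=dict(self.theta),
            w_chem=dict(self.w_chem), g=dict(self.g),
            w_self=dict(self.w_self),
            w_osc=self.w_osc, w_nmj=self.w_nmj,
            tau=dict(self.tau), T=self.T, v=self.v,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "N": self.N, "M": self.M,
            "w_on": dict(self.w_on), "w_off": dict(self.w_off),
            "theta": dict(self.theta),
            "w_chem": {f"{a}->{b}": w for (a, b), w in sorted(self.w_chem.items())},
            "g": {"-".join(sorted(p)): c for p, c in self.g.items()},
            "w_self": dict(self.w_self),
            "w_osc": self.w_osc, "w_nmj": self.w_nmj,
            "tau": dict(self.tau), "T": self.T, "v": self.v,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CircuitParameters":
        w_chem = {}
        for key, w in d["w_chem"].items():
            pre, post = key.split("->")
            w_chem[(pre, post)] = float(w)
        g = {frozenset(k.split("-")): float(c) for k, c in d["g"].items()}
        return cls(
            N=float(d["N"]), M=float(d["M"]),
            w_on={k: float(v) for k, v in d["w_on"].items()},
            w_off={k: float(v) for k, v in d["w_off"].items()},
            theta={k: float(v) for k, v in d["theta"].items()},
            w_chem=w_chem, g=g,
            w_self={k: float(v) for k, v in d["w_self"].items()},
            w_osc=float(d["w_osc"]), w_nmj=float(d["w_nmj"]),
            tau={k: float(v) for k, v in d["tau"].items()},
            T=float(d["T"]), v=float(d["v"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CircuitParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


GAP_AIY = frozenset({"AIYL", "AIYR"})
GAP_AIZ = frozenset({"AIZL", "AIZR"})


# ---------------------------------------------------------------------------
# Genome encoding
# ---------------------------------------------------------------------------

GENOME_LENGTH = 22

#: Canonical gene order.  Windows, sensory weights, biases, chemical weights,
#: gap conductances, motor self-weights, oscillator and neuromuscular gains.
GENE_NAMES: tuple[str, ...] = (
    "N", "M",
    "w_on_AIYL", "w_on_AIYR", "w_off_AIYL", "w_off_AIYR",
    "theta_AIYL", "theta_AIYR", "theta_AIZL", "theta_AIZR",
    "theta_SMB_left", "theta_SMB_right",
    "w_AIYL_AIZL", "w_AIYR_AIZR",
    "w_AIZL_SMB", "w_AIZR_SMB",
    "g_AIY", "g_AIZ",
    "w_self_left", "w_self_right",
    "w_osc", "w_nmj",
)

_AIY_AIZ_GENES = (GENE_NAMES.index("w_AIYL_AIZL"), GENE_NAMES.index("w_AIYR_AIZR"))

_WINDOW_RANGE = (0.1, 4.2)
_WEIGHT_RANGE = (-15.0, 15.0)
_BIAS_RANGE = (-15.0, 15.0)
_GAP_RANGE = (0.0, 2.5)
_OSC_RANGE = (0.0, 15.0)
_NMJ_RANGE = (1.0, 3.0)


@dataclass(frozen=True)
class ParameterRanges:
    """Per-gene (lower, upper) bounds for the linear genome mapping."""

    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.bounds) != GENOME_LENGTH:
            raise InvalidParameterError(
                f"expected {GENOME_LENGTH} gene ranges, got {len(self.bounds)}")
        if any(hi < lo for lo, hi in self.bounds):
            raise InvalidParameterError("range upper bound below lower bound")

    @classmethod
    def default(cls) -> "ParameterRanges":
        per_gene = {
            "N": _WINDOW_RANGE, "M": _WINDOW_RANGE,
            "g_AIY": _GAP_RANGE, "g_AIZ": _GAP_RANGE,
            "w_osc": _OSC_RANGE, "w_nmj": _NMJ_RANGE,
        }
        bounds = []
        for name in GENE_NAMES:
            if name in per_gene:
                bounds.append(per_gene[name])
            elif name.startswith("theta"):
                bounds.append(_BIAS_RANGE)
            else:
                bounds.append(_WEIGHT_RANGE)
        return cls(bounds=tuple(bounds))

    def constrained_aiy_aiz(self) -> "ParameterRanges":
        """Ranges with the two AIY->AIZ weights restricted to [-15, 0]."""
        bounds = list(self.bounds)
        for idx in _AIY_AIZ_GENES:
            lo, _ = bounds[idx]
            bounds[idx] = (lo, 0.0)
        return ParameterRanges(bounds=tuple(bounds))


@dataclass(frozen=True)
class Genome:
    """A 22-element real vector in [-1, 1] encoding one circuit."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != GENOME_LENGTH:
            raise InvalidGenomeError(
                f"genome must have {GENOME_LENGTH} elements, got {len(self.values)}")
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidGenomeError("genome entries must be finite")
        if np.any(arr < -1.0) or np.any(arr > 1.0):
            raise InvalidGenomeError("genome entries must lie in [-1, 1]")

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "Genome":
        return cls(values=tuple(float(x) for x in arr))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @classmethod
    def random(cls, rng: np.random.Generator) -> "Genome":
        return cls.from_array(rng.uniform(-1.0, 1.0, GENOME_LENGTH))


def decode_genome(
    genome: Genome,
    ranges: ParameterRanges | None = None,
    constrain_aiy_aiz: bool = False,
    tau: float = DEFAULT_TAU,
) -> CircuitParameters:
    """Map a genome linearly onto circuit parameters.

    Each gene value ``x`` in [-1, 1] maps to ``lo + (x + 1)/2 * (hi - lo)``.
    When ``constrain_aiy_aiz`` is set the two AIY->AIZ weights are mapped
    into [-15, 0], keeping that synapse inhibitory for every genome while
    the search space stays box-shaped.  Dorsoventral sharing of the motor
    parameters is realized by expansion: one gene fills both the dorsal and
    ventral slot on its side.
    """
    if ranges is None:
        ranges = ParameterRanges.default()
    if constrain_aiy_aiz:
        ranges = ranges.constrained_aiy_aiz()
    x = genome.as_array()
    lo = np.array([b[0] for b in ranges.bounds])
    hi = np.array([b[1] for b in ranges.bounds])
    p = lo + (x + 1.0) / 2.0 * (hi - lo)
    val = dict(zip(GENE_NAMES, p))
    return CircuitParameters(
        N=val["N"], M=val["M"],
        w_on={"AIYL": val["w_on_AIYL"], "AIYR": val["w_on_AIYR"]},
        w_off={"AIYL": val["w_off_AIYL"], "AIYR": val["w_off_AIYR"]},
        theta={
            "AIYL": val["theta_AIYL"], "AIYR": val["theta_AIYR"],
            "AIZL": val["theta_AIZL"], "AIZR": val["theta_AIZR"],
            "SMBDL": val["theta_SMB_left"], "SMBVL": val["theta_SMB_left"],
            "SMBDR": val["theta_SMB_right"], "SMBVR": val["theta_SMB_right"],
        },
        w_chem={
            ("AIYL", "AIZL"): val["w_AIYL_AIZL"],
            ("AIYR", "AIZR"): val["w_AIYR_AIZR"],
            ("AIZL", "SMBDL"): val["w_AIZL_SMB"],
            ("AIZL", "SMBVL"): val["w_AIZL_SMB"],
            ("AIZR", "SMBDR"): val["w_AIZR_SMB"],
            ("AIZR", "SMBVR"): val["w_AIZR_SMB"],
        },
        g={GAP_AIY: val["g_AIY"], GAP_AIZ: val["g_AIZ"]},
        w_self={"left": val["w_self_left"], "right": val["w_self_right"]},
        w_osc=val["w_osc"], w_nmj=val["w_nmj"],
        tau={n: tau for n in STATE_NEURONS},
    )


def encode_parameters(
    params: CircuitParameters,
    ranges: ParameterRanges | None = None,
    constrain_aiy_aiz: bool = False,
) -> Genome:
    """Inverse of :func:`decode_genome` for in-range parameter sets."""
    if ranges is None:
        ranges = ParameterRanges.default()
    if constrain_aiy_aiz:
        ranges = ranges.constrained_aiy_aiz()
    val = {
        "N": params.N, "M": params.M,
        "w_on_AIYL": params.w_on["AIYL"], "w_on_AIYR": params.w_on["AIYR"],
        "w_off_AIYL": params.w_off["AIYL"], "w_off_AIYR": params.w_off["AIYR"],
        "theta_AIYL": params.theta["AIYL"], "theta_AIYR": params.theta["AIYR"],
        "theta_AIZL": params.theta["AIZL"], "theta_AIZR": params.theta["AIZR"],
        "theta_SMB_left": params.theta["SMBDL"],
        "theta_SMB_right": params.theta["SMBDR"],
        "w_AIYL_AIZL": params.w_chem[("AIYL", "AIZL")],
        "w_AIYR_AIZR": params.w_chem[("AIYR", "AIZR")],
        "w_AIZL_SMB": params.w_chem[("AIZL", "SMBDL")],
        "w_AIZR_SMB": params.w_chem[("AIZR", "SMBDR")],
        "g_AIY": params.g[GAP_AIY], "g_AIZ": params.g[GAP_AIZ],
        "w_self_left": params.w_self["left"],
        "w_self_right": params.w_self["right"],
        "w_osc": params.w_osc, "w_nmj": params.w_nmj,
    }
    genes = []
    for name, (lo, hi) in zip(GENE_NAMES, ranges.bounds):
        p = val[name]
        if hi == lo:
            genes.append(-1.0)
            continue
        x = 2.0 * (p - lo) / (hi - lo) - 1.0
        genes.append(float(np.clip(x, -1.0, 1.0)))
    return Genome.from_array(genes)
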