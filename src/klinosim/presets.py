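"""Bundled reference genomes produced by this package's own searches."""

from __future__ import annotations

import json
from importlib.resources import files

from .circuit import CircuitParameters, Genome, ParameterRanges, decode_genome


def _load(name: str) -> dict:
    return json.loads(files("klinosim.data").joinpath(name).read_text())


def best_constrained_genome() -> Genome:
    """Best genome found by a constrained evolutionary search.

    Produced by this package's genetic algorithm with the inhibitory
    AIY->AIZ mapping (see the bundled JSON for the search settings and the
    fitness it reached); used as the reference individual for the
    behavioral analyses.
    """
    return Genome.from_array(_load("best_constrained.json")["genome"])


def best_constrained_parameters() -> CircuitParameters:
    """Decoded circuit of :func:`best_constrained_genome`."""
    return decode_genome(best_constrained_genome(), ParameterRanges.default(),
                         constrain_aiy_aiz=True)


def best_constrained_metadata() -> dict:
    """Search settings and recorded scores of the bundled genome."""
    meta = _load("best_constrained.json")
    meta.pop("genome")
    return meta
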