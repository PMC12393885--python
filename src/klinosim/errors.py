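"""Exception hierarchy for klinosim."""


class KlinosimError(Exception):
    """Base class for all klinosim errors."""


class InvalidGenomeError(KlinosimError, ValueError):
    """Genome has the wrong length or entries outside [-1, 1]."""


class InvalidParameterError(KlinosimError, ValueError):
    """A circuit or configuration parameter violates its constraints."""


class UnreachableError(KlinosimError):
    """No directed chemical-synapse path exists between the requested neurons."""


class NumericalDivergenceError(KlinosimError, ArithmeticError):
    """Network state became non-finite during integration."""


class InvalidAssayError(KlinosimError, ValueError):
    """A chemotaxis assay is ill-posed (e.g. the worm starts on the peak)."""


class DegenerateSegmentError(KlinosimError, ValueError):
    """A locomotion segment has zero-length displacement vectors."""


class UndefinedBearingError(KlinosimError, ValueError):
    """Bearing is undefined (worm sits exactly on the gradient peak)."""


class InvalidPerturbationError(KlinosimError, ValueError):
    """A circuit perturbation was requested with an out-of-range factor."""


class UnknownFixtureError(KlinosimError, KeyError):
    """Requested fixture name is not registered."""
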