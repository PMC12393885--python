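"""Salt-concentration fields and finite-difference gradient probes.

Two field shapes are used.  A conical gradient, linear in the distance from
the peak with negative slope ``alpha``, drives the evolutionary search (its
local steepness is independent of the distance to the peak).  A Gaussian
plume with amplitude ``C0`` and length scale ``lam`` mimics the profile of a
laboratory chemotaxis plate and is used when evaluating evolved circuits.

The behavioral analysis probes the field with one-sided finite differences
offset by 0.001 cm, either perpendicular-left of the heading (normal
gradient) or along the heading (translational gradient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

#: Probe offset (cm) for the finite-difference gradients.
GRADIENT_STEP = 0.001

#: Gaussian plate defaults: peak amplitude (mM) and length scale (cm).
DEFAULT_C0 = 1.0
DEFAULT_LAMBDA = 1.61


@dataclass(frozen=True)
class Environment:
    """A salt-concentration field with a single peak.

    ``kind`` is 'conical' (c = alpha * distance, alpha < 0) or 'gaussian'
    (c = C0 * exp(-d^2 / (2 lam^2))).
    """

    kind: str
    peak: tuple[float, float]
    alpha: float = 0.0
    C0: float = DEFAULT_C0
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if self.kind == "conical":
            if not self.alpha < 0:
                raise InvalidParameterError("conical slope alpha must be < 0")
        elif self.kind == "gaussian":
            if not (self.C0 > 0 and self.lam > 0):
                raise InvalidParameterError("gaussian needs C0 > 0 and lam > 0")
        else:
            raise InvalidParameterError(f"unknown environment kind {self.kind!r}")

    @classmethod
    def conical(cls, alpha: float,
                peak: tuple[float, float] = (4.5, 0.0)) -> "Environment":
        return cls(kind="conical", peak=peak, alpha=alpha)

    @classmethod
    def gaussian(cls, C0: float = DEFAULT_C0, lam: float = DEFAULT_LAMBDA,
                 peak: tuple[float, float] = (4.5, 0.0)) -> "Environment":
        return cls(kind="gaussian", peak=peak, C0=C0, lam=lam)

    # -- field evaluation ---------------------------------------------------

    def concentration(self, pos) -> float | np.ndarray:
        """Concentration (mM) at a position or an (n, 2) array of positions."""
        pos = np.asarray(pos, dtype=float)
        dx = pos[..., 0] - self.peak[0]
        dy = pos[..., 1] - self.peak[1]
        d = np.hypot(dx, dy)
        if self.kind == "conical":
            c = self.alpha * d
        else:
            c = self.C0 * np.exp(-(d * d) / (2.0 * self.lam**2))
        return float(c) if c.ndim == 0 else c

    def analytic_gradient(self, pos) -> np.ndarray:
        """Exact spatial gradient (mM/cm) of the field at ``pos``."""
        pos = np.asarray(pos, dtype=float)
        delta = pos - np.asarray(self.peak)
        d = float(np.hypot(*delta))
        if d == 0.0:
            return np.zeros(2)
        if self.kind == "conical":
            return self.alpha * delta / d
        c = self.C0 * math.exp(-(d * d) / (2.0 * self.lam**2))
        return -c * delta / self.lam**2


def _directional_difference(env: Environment, pos, direction) -> float:
    pos = np.asarray(pos, dtype=float)
    shifted = pos + GRADIENT_STEP * np.asarray(direction)
    return (env.concentration(shifted) - env.concentration(pos)) / GRADIENT_STEP


def normal_gradient(env: Environment, pos, heading: float) -> float:
    """Concentration change per cm toward the left of the heading.

    One-sided difference between the position shifted 0.001 cm along the
    left-perpendicular of the movement direction (heading rotated +90 deg,
    counterclockwise positive) and the current position.
    """
    left = (-math.sin(heading), math.cos(heading))
    return _directional_difference(env, pos, left)


def translational_gradient(env: Environment, pos, heading: float) -> float:
    """Concentration change per cm along the heading (one-sided, 0.001 cm)."""
    ahead = (math.cos(heading), math.sin(heading))
    return _directional_difference(env, pos, ahead)
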