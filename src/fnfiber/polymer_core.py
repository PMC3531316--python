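"""Worm-like-chain (WLC) elasticity primitives.

A fibronectin dimer (and each unfolded-domain strand spawned from it) is
modelled as an entropic spring obeying the Marko-Siggia interpolation
formula.  For a segment of contour length ``L`` and persistence length
``A`` held at end-to-end extension ``z``,

    f(z) = (kB*T / A) * [ 1 / (4 (1 - z/L)^2) - 1/4 + z/L ],

so the tension vanishes at zero extension, grows linearly with slope
(3/2) kB*T / (A*L) at small ``z`` and diverges as ``z -> L``.  Everything
downstream (unfolding kinetics, fiber equilibration) is built on this
force law, its inverse, and the series-composition rule that extensions
of segments at a common tension add.

The inverse is computed analytically: writing ``x = z/L`` and
``phi = f*A/(kB*T)``, the interpolation formula rearranges to the cubic

    u^3 + (phi - 3/4) u^2 - 1/4 = 0,        u = 1 - x,

which has exactly one positive root for every ``phi >= 0``.  A
safeguarded Newton iteration on ``u`` (series expansion below
``phi = 1e-4`` to avoid cancellation in ``1 - u``) recovers it to
machine precision, which keeps the fiber equilibration loop cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "DEFAULT_TEMPERATURE_K",
    "DEFAULT_CONTEXT",
    "TautSegmentError",
    "WLCSegment",
    "ThermalContext",
    "SerialChain",
    "wlc_force",
    "wlc_extension",
    "chain_extension",
]

#: Boltzmann constant in pN nm / K (1.38065e-23 J/K).
BOLTZMANN_PN_NM_PER_K = 0.0138065

#: Room temperature; the in vitro fiber experiments were done at ambient
#: conditions, and kB*T varies by only ~1% between 298 K and 310 K.
DEFAULT_TEMPERATURE_K = 298.0

# Extension fractions beyond this are treated as a taut (unphysical) segment
# rather than silently returning a gigantic force.
_TAUT_FRACTION = 1.0 - 1e-9

# Below this phi the cubic root is solved by series expansion; at the
# threshold both branches agree to ~1e-12 relative.
_SERIES_PHI = 1e-4


class TautSegmentError(ValueError):
    """A WLC segment was driven to (or past) its contour length."""


@dataclass(frozen=True)
class WLCSegment:
    """One entropic spring: contour length and persistence length, both in nm."""

    contour_length: float
    persistence_length: float

    def __post_init__(self) -> None:
        if not self.contour_length > 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if not self.persistence_length > 0:
            raise ValueError(
                f"persistence_length must be > 0, got {self.persistence_length}"
            )


@dataclass(frozen=True)
class ThermalContext:
    """Temperature (K) and Boltzmann constant (pN nm / K)."""

    temperature: float = DEFAULT_TEMPERATURE_K
    boltzmann_constant: float = BOLTZMANN_PN_NM_PER_K

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if not self.boltzmann_constant > 0:
            raise ValueError("boltzmann_constant must be > 0")

    @property
    def kt(self) -> float:
        """Thermal energy kB*T in pN nm."""
        return self.boltzmann_constant * self.temperature


DEFAULT_CONTEXT = ThermalContext()


@dataclass(frozen=True)
class SerialChain:
    """Segments connected end to end; at a common tension their extensions add."""

    segments: tuple[WLCSegment, ...]

    def __init__(self, segments: Sequence[WLCSegment]):
        segs = tuple(segments)
        if not segs:
            raise ValueError("SerialChain requires at least one segment")
        object.__setattr__(self, "segments", segs)

    @property
    def contour_length(self) -> float:
        return sum(s.contour_length for s in self.segments)


def wlc_bracket(x):
    """The dimensionless part of the force law, 1/(4(1-x)^2) - 1/4 + x."""
    return 0.25 / (1.0 - x) ** 2 - 0.25 + x


def wlc_force(z: float, seg: WLCSegment, ctx: ThermalContext = DEFAULT_CONTEXT) -> float:
    """Tension (pN) of a WLC segment at end-to-end extension ``z`` (nm).

    Raises ``ValueError`` for negative extension and ``TautSegmentError``
    once ``z`` reaches the contour length (within the near-contour guard).
    """
    if z < 0:
        raise ValueError(f"extension must be >= 0, got {z}")
    x = z / seg.contour_length
    if x > _TAUT_FRACTION:
        raise TautSegmentError(
            f"extension {z} nm is at/beyond contour length "
            f"{seg.contour_length} nm (z/L = {x:.12g})"
        )
    return ctx.kt / seg.persistence_length * wlc_bracket(x)


def _frac_extension_scalar(phi: float) -> float:
    """Scalar fast path of :func:`_frac_extension` (plain-float Newton)."""
    if phi < 0:
        raise ValueError("dimensionless force must be >= 0")
    if phi < _SERIES_PHI:
        return phi * (2.0 / 3.0 + phi * (-2.0 / 9.0 + phi * (-4.0 / 81.0)))
    a1 = phi - 0.75
    u = min(1.0, 0.5 / a1**0.5) if a1 > 0 else 1.0
    for _ in range(12):
        g = u * u * (u + a1) - 0.25
        step = g / (u * (3.0 * u + 2.0 * a1))
        u -= step
        if abs(step) < 1e-15 * u:
            break
    return 1.0 - u


def _frac_extension(phi):
    """Fractional extension x = z/L at dimensionless force phi = f*A/(kB*T).

    Vectorized inverse of ``wlc_bracket``; accepts scalars or arrays.
    """
    if isinstance(phi, float):
        return _frac_extension_scalar(phi)
    arr = np.asarray(phi, dtype=float)
    scalar = arr.ndim == 0
    if scalar:
        return _frac_extension_scalar(float(arr))
    arr = np.atleast_1d(arr)
    if np.any(arr < 0):
        raise ValueError("dimensionless force must be >= 0")
    x = np.empty_like(arr)

    small = arr < _SERIES_PHI
    if small.any():
        p = arr[small]
        # x = (2/3) phi - (2/9) phi^2 - (4/81) phi^3 + O(phi^4)
        x[small] = p * (2.0 / 3.0 + p * (-2.0 / 9.0 + p * (-4.0 / 81.0)))
    big = ~small
    if big.any():
        p = arr[big]
        a1 = p - 0.75  # cubic: u^3 + a1*u^2 - 1/4 = 0
        u0 = np.where(
            a1 > 0.0,
            np.minimum(1.0, 0.5 / np.sqrt(np.maximum(a1, 1e-300))),
            1.0,
        )
        u = u0
        # g is convex along the descent path and g(u0) >= 0, so plain Newton
        # converges monotonically; 12 iterations reach machine precision.
        for _ in range(12):
            g = u * u * (u + a1) - 0.25
            gp = u * (3.0 * u + 2.0 * a1)
            u = u - g / gp
        x[big] = 1.0 - u
    return float(x[0]) if scalar else x


def _frac_extension_with_slope(phi):
    """Return (x, dx/dphi); used by equilibrium solvers for Newton steps."""
    if isinstance(phi, float) or np.ndim(phi) == 0:
        p = float(phi)
        x = _frac_extension_scalar(p)
        if p < _SERIES_PHI:
            return x, 2.0 / 3.0 + p * (-4.0 / 9.0 + p * (-4.0 / 27.0))
        u = 1.0 - x
        return x, u / (3.0 * u + 2.0 * (p - 0.75))
    arr = np.atleast_1d(np.asarray(phi, dtype=float))
    scalar = False
    x = np.asarray(np.atleast_1d(_frac_extension(arr)), dtype=float)
    slope = np.empty_like(arr)
    small = arr < _SERIES_PHI
    if small.any():
        p = arr[small]
        slope[small] = 2.0 / 3.0 + p * (-4.0 / 9.0 + p * (-4.0 / 27.0))
    big = ~small
    if big.any():
        u = 1.0 - x[big]
        a1 = arr[big] - 0.75
        # implicit differentiation of u^3 + (phi - 3/4) u^2 = 1/4
        slope[big] = u / (3.0 * u + 2.0 * a1)
    if scalar:
        return float(x[0]), float(slope[0])
    return x, slope


def wlc_extension(f: float, seg: WLCSegment, ctx: ThermalContext = DEFAULT_CONTEXT) -> float:
    """End-to-end extension (nm) of a WLC segment at tension ``f`` (pN).

    Exact inverse of :func:`wlc_force` (round-trips to ~1e-12 relative);
    the result lies in ``[0, L)``.
    """
    if f < 0:
        raise ValueError(f"tension must be >= 0, got {f}")
    phi = f * seg.persistence_length / ctx.kt
    return seg.contour_length * _frac_extension(phi)


def chain_extension(
    f: float, chain: SerialChain, ctx: ThermalContext = DEFAULT_CONTEXT
) -> float:
    """Total extension (nm) of segments in series at common tension ``f`` (pN)."""
    if f < 0:
        raise ValueError(f"tension must be >= 0, got {f}")
    return sum(wlc_extension(f, seg, ctx) for seg in chain.segments)
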