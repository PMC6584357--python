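"""Closed-form limiting-case model of spacing versus protrusion length.

Consider a differentiating cell whose protrusion of length l_max inhibits
differentiation within that range while present.  If the protrusion
extends instantaneously (fast limit), the next event falls uniformly on
(d + l_max, L), where d is the cell diameter and L the maximum analysis
distance, so E[dx] = (d + L)/2 + l_max/2.  If the protrusion is far too
slow to inhibit anyone (slow limit), the next event is uniform on (d, L)
and E[dx] = (d + L)/2, independent of the protrusion.  A real tissue lies
in between:

    mean dx = (d + L)/2 + phi * mean l_max,    0 <= phi <= 0.5,

where phi measures how effectively (how fast, relative to the
differentiation timescale) protrusions inhibit.  With the derivation's
values d = 10 um and L = 80 um the intercept is 45 um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LimitModel", "expected_dx", "infer_phi", "sweep_slope"]


@dataclass(frozen=True)
class LimitModel:
    """Geometry and efficacy of the limiting-case spacing model.

    ``d`` is the mean cell diameter (um), ``L`` the maximum analysis
    distance (um) and ``phi`` the inhibition-efficacy constant in
    [0, 0.5] (0 = slow limit, 0.5 = fast limit).
    """

    d: float = 10.0
    L: float = 80.0
    phi: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.d < self.L:
            raise ValueError("need 0 < d < L")
        if not 0.0 <= self.phi <= 0.5:
            raise ValueError("phi must lie in [0, 0.5]")

    @property
    def intercept(self) -> float:
        """(d + L)/2 — the expected spacing with no inhibition."""
        return (self.d + self.L) / 2.0


def expected_dx(lmax_mean: float, model: LimitModel) -> float:
    """Expected mean sequential distance: (d + L)/2 + phi * mean l_max."""
    if lmax_mean < 0:
        raise ValueError("lmax_mean must be non-negative")
    return model.intercept + model.phi * lmax_mean


def infer_phi(
    dx_mean: float, lmax_mean: float, d: float = 10.0, L: float = 80.0
) -> tuple[float, bool]:
    """Invert the spacing relation: phi = (dx_mean - (d + L)/2) / lmax_mean.

    Returns ``(phi, in_bounds)``; ``in_bounds`` flags whether the
    inferred value falls inside the theoretical [0, 0.5] band.  Out-of-
    band values are reported as-is, never clamped.
    """
    if lmax_mean <= 0:
        raise ValueError("lmax_mean must be positive to infer phi")
    phi = (dx_mean - (d + L) / 2.0) / lmax_mean
    return phi, bool(0.0 <= phi <= 0.5)


def sweep_slope(lmax_means: np.ndarray, dx_means: np.ndarray) -> tuple[float, float]:
    """Least-squares slope (and intercept) of mean dx on mean l_max.

    Used on protrusion-length sweeps of the simulator to test the linear
    spacing-versus-length relationship.
    """
    x = np.asarray(lmax_means, dtype=float)
    y = np.asarray(dx_means, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need >= 3 matched grid points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate grid: all l_max values identical")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
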