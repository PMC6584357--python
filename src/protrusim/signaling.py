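"""Notch-Delta lateral-inhibition dynamics on a row of cells.

The per-cell dynamics follow the classic mutual-inactivation form

    dN/dt = R_N * D_in^k / (a + D_in^k) - mu * N
    dD/dt = R_D / (1 + b * N^h)        - rho * D
    D_in  = alpha * sum_soma D + beta * sum_protrusions D

where ``N`` and ``D`` are the amounts of active Notch and Delta in a cell
and ``D_in`` is the total Delta signal it receives, a weighted sum over
soma-to-soma contacts (weight ``alpha``) and basal-protrusion contacts
(weight ``beta``).  The decision to enter differentiation is a Hill
function of Notch:

    P_diff = p * N_th^q / (N_th^q + N^q)

so cells become progressively more likely to differentiate as their Notch
level falls below the threshold ``N_th``.

Equations are integrated with the Euler method; a small additive Gaussian
noise term is applied to both concentrations at every step, and levels are
clamped at zero (concentrations cannot go negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable

import numpy as np

__all__ = [
    "Phase",
    "SignalParams",
    "DifferentiationRule",
    "SignalState",
    "compute_d_in",
    "euler_step",
    "differentiation_probability",
    "initialize_levels",
]


class Phase(IntEnum):
    """Life-cycle phase of a cell; transitions are strictly forward."""

    PROGENITOR = 0
    EXTENDING = 1
    RETRACTING = 2
    DIFFERENTIATED = 3


@dataclass(frozen=True)
class SignalParams:
    """Kinetic parameters of the lateral-inhibition circuit.

    Rates are in inverse simulation-time units; levels are arbitrary
    concentration units.  The defaults put the circuit in a bistable
    mutual-inhibition regime (Hill exponents of 2, trans-activation of
    Notch saturating near the uninhibited Delta level) with asymmetric
    Notch kinetics: production strongly outruns the threshold (R_N/mu >>
    N_th) so inhibition engages within a protrusion extension time, while
    the slow Notch decay (1/mu) keeps a cell refractory for a while after
    the inhibiting protrusion has retracted.  Delta is fast (1/rho) so
    committed cells present high Delta almost immediately.

    Attributes
    ----------
    R_N, R_D
        Baseline production rates of Notch and Delta.
    a, k
        Activation threshold (on ``D_in^k``) and Hill exponent for Notch
        induction by incoming Delta.
    b, h
        Inhibition strength and Hill exponent for Delta repression by
        Notch.
    mu, rho
        Degradation rates of Notch and Delta.
    alpha, beta
        Relative Delta signal weights at soma-to-soma contacts and in the
        basal protrusions.
    noise_frac
        Relative amplitude of the additive Gaussian noise applied to each
        concentration per Euler step (s.d. = ``noise_frac * R * sqrt(dt)``,
        the diffusion scaling, so realized fluctuations do not depend on
        the step size); 0 disables noise.
    """

    R_N: float = 80.0
    R_D: float = 20.0
    a: float = 0.01
    k: float = 2.0
    b: float = 100.0
    h: float = 2.0
    mu: float = 2.0
    rho: float = 20.0
    alpha: float = 0.0
    beta: float = 1.0
    noise_frac: float = 0.01

    def __post_init__(self) -> None:
        for name in ("R_N", "R_D", "a", "b", "mu", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k < 1 or self.h < 1:
            raise ValueError("Hill exponents k, h must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("contact weights alpha, beta must be non-negative")
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be non-negative")


@dataclass(frozen=True)
class DifferentiationRule:
    """Hill-function differentiation trigger.

    ``p`` is the upper limit of the per-step probability of entering
    differentiation, ``N_th`` the Notch threshold and ``q`` the exponent
    controlling the width of the decision window around the threshold.
    """

    p: float = 0.01
    N_th: float = 0.2
    q: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if self.N_th <= 0:
            raise ValueError("N_th must be positive")
        if self.q < 1:
            raise ValueError("q must be >= 1")


@dataclass
class SignalState:
    """Per-cell Notch/Delta levels and life-cycle phase for a whole row."""

    N: np.ndarray
    D: np.ndarray
    phase: np.ndarray  # Phase values, int array

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.phase = np.asarray(self.phase, dtype=np.int8)
        if not (self.N.shape == self.D.shape == self.phase.shape):
            raise ValueError("N, D and phase must have identical shapes")

    @property
    def n_cells(self) -> int:
        return self.N.size

    def copy(self) -> "SignalState":
        return SignalState(self.N.copy(), self.D.copy(), self.phase.copy())


def initialize_levels(
    n_cells: int,
    params: SignalParams,
    seed: int | np.random.Generator = 0,
) -> SignalState:
    """Initial Notch/Delta levels: N ~ Normal(R_N, noise_frac * R_N), D likewise.

    At the default ``noise_frac`` of 0.01 this is the 1% relative spread
    that breaks the initial symmetry; ``noise_frac = 0`` starts every
    cell exactly at (R_N, R_D).  All cells start as progenitors; negative
    draws are clamped to zero.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    N = rng.normal(params.R_N, params.noise_frac * params.R_N, size=n_cells)
    D = rng.normal(params.R_D, params.noise_frac * params.R_D, size=n_cells)
    return SignalState(
        N=np.clip(N, 0.0, None),
        D=np.clip(D, 0.0, None),
        phase=np.full(n_cells, Phase.PROGENITOR, dtype=np.int8),
    )


def compute_d_in(
    receiver: int,
    soma_contacts: Iterable[int],
    protrusion_contacts: Iterable[int],
    delta_levels: np.ndarray,
    alpha: float,
    beta: float,
) -> float:
    """Total incoming Delta for one receiver.

    ``D_in = alpha * sum(D over soma contacts) + beta * sum(D over
    protrusion contacts)``.  Contact sets must already exclude the
    receiver itself and any differentiated cell.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("contact weights must be non-negative")
    soma = list(soma_contacts)
    prot = list(protrusion_contacts)
    if receiver in soma or receiver in prot:
        raise ValueError("contact sets must exclude the receiver")
    delta_levels = np.asarray(delta_levels, dtype=float)
    return float(alpha * delta_levels[soma].sum() + beta * delta_levels[prot].sum())


def differentiation_probability(
    N: float | np.ndarray, rule: DifferentiationRule
) -> float | np.ndarray:
    """Per-step probability of entering differentiation at Notch level ``N``.

    Monotone non-increasing in ``N``; equals ``p`` at ``N = 0`` and
    ``p / 2`` at ``N = N_th``.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("Notch level must be non-negative")
    th = rule.N_th**rule.q
    out = rule.p * th / (th + N**rule.q)
    return float(out) if out.ndim == 0 else out


def euler_step(
    state: SignalState,
    d_in: np.ndarray,
    params: SignalParams,
    dt: float,
    rng: np.random.Generator | None = None,
    *,
    step_index: int | None = None,
) -> SignalState:
    """Advance Notch/Delta one Euler step (in place) and return the state.

    ``d_in`` is the per-cell incoming Delta already aggregated over the
    current contact sets (zero for cells that do not receive signal).
    Differentiated cells are frozen; all updated levels are clamped at
    zero.  Additive Gaussian noise with s.d. ``noise_frac * R`` is applied
    per step when ``rng`` is given and ``noise_frac > 0``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    d_in = np.asarray(d_in, dtype=float)
    active = state.phase != Phase.DIFFERENTIATED

    N, D = state.N, state.D
    dN = params.R_N * d_in**params.k / (params.a + d_in**params.k) - params.mu * N
    dD = params.R_D / (1.0 + params.b * N**params.h) - params.rho * D
    N_new = N + dt * dN
    D_new = D + dt * dD
    if rng is not None and params.noise_frac > 0:
        n = state.n_cells
        scale = np.sqrt(dt)  # diffusion scaling keeps noise step-size independent
        N_new = N_new + rng.normal(0.0, params.noise_frac * params.R_N * scale, size=n)
        D_new = D_new + rng.normal(0.0, params.noise_frac * params.R_D * scale, size=n)
    N_new = np.clip(N_new, 0.0, None)
    D_new = np.clip(D_new, 0.0, None)
    if not (np.all(np.isfinite(N_new[active])) and np.all(np.isfinite(D_new[active]))):
        at = f" at step {step_index}" if step_index is not None else ""
        raise FloatingPointError(f"non-finite Notch/Delta levels after update{at}")
    N[active] = N_new[active]
    D[active] = D_new[active]
    return state
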