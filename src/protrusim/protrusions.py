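"""Basal-protrusion life cycle and the geometric contact rule.

A cell that commits to differentiation extends two basal protrusions, one
anterior and one posterior, at constant speed until each arm reaches its
sampled maximum length ``l_max``; the arms then retract (faster than they
grew) and the cell counts as differentiated when both arms are fully
retracted.  While any arm has nonzero length it delivers Delta to every
soma it overlaps; protrusions send but do not receive signal.

Each arm's extension speed is ``l_max / T_ext``, so every arm caps at the
genotype's fixed extension duration ``T_ext`` and the whole cycle has a
deterministic duration ``T_ext + T_ret``.  Wild-type arms retract 1.7x
faster than they extend (``T_ret = T_ext / 1.7``); the Laminin-depleted
(lamc1) genotype has shorter arms (mean 12.3 um vs 42.6 um), extends 1.4x
slower per micron, and retracts in 1.1x its extension time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signaling import DifferentiationRule, Phase, differentiation_probability
from .tissue import CellRow

__all__ = [
    "GenotypeKinetics",
    "WILD_TYPE",
    "LAMC1",
    "ProtrusionState",
    "trigger_extension",
    "update_protrusion",
    "protrusion_contacts",
    "arm_lengths_at",
]

#: Wild-type maximum-protrusion-length distribution (um), in vivo.
_WT_LMAX_MEAN = 42.6
_WT_LMAX_SD = 20.2
#: lamc1-mutant maximum-protrusion-length distribution (um), in vivo.
_LAMC1_LMAX_MEAN = 12.3
_LAMC1_LMAX_SD = 4.7
#: Wild-type extension duration in simulation time units.
_WT_T_EXT = 0.05
#: Arms shorter than this floor are redrawn when sampling l_max.
_LMAX_FLOOR_UM = 0.5


@dataclass(frozen=True)
class GenotypeKinetics:
    """Protrusion kinetics of one genotype.

    Attributes
    ----------
    lmax_mean, lmax_sd
        Normal distribution of the per-arm maximum length, um.
    T_ext
        Duration of the extension phase, simulation time units.  All arms
        cap simultaneously because each extends at ``l_max / T_ext``.
    retraction_rate_factor
        Ratio of retraction speed to extension speed; the retraction
        phase lasts ``T_ext / retraction_rate_factor``.
    name
        Label used in event tables and configs.
    """

    lmax_mean: float
    lmax_sd: float
    T_ext: float
    retraction_rate_factor: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.lmax_mean <= 0:
            raise ValueError("lmax_mean must be positive")
        if self.lmax_sd < 0:
            raise ValueError("lmax_sd must be non-negative")
        if self.T_ext <= 0 or self.retraction_rate_factor <= 0:
            raise ValueError("T_ext and retraction_rate_factor must be positive")

    @property
    def T_ret(self) -> float:
        """Duration of the retraction phase."""
        return self.T_ext / self.retraction_rate_factor

    @property
    def cycle_time(self) -> float:
        """Total protrusion life cycle: extension plus retraction."""
        return self.T_ext + self.T_ret

    def extension_speed(self, lmax: float) -> float:
        """Extension speed (um per time unit) of an arm with cap ``lmax``."""
        return lmax / self.T_ext

    def sample_lmax(self, rng: np.random.Generator, size: int | tuple = 2) -> np.ndarray:
        """Sample per-arm caps, redrawing non-positive values."""
        l = rng.normal(self.lmax_mean, self.lmax_sd, size=size)
        bad = l <= _LMAX_FLOOR_UM
        while np.any(bad):
            l[bad] = rng.normal(self.lmax_mean, self.lmax_sd, size=int(bad.sum()))
            bad = l <= _LMAX_FLOOR_UM
        return l

    def with_lmax_mean(self, lmax_mean: float, lmax_sd: float | None = None) -> "GenotypeKinetics":
        """Copy with a different cap distribution (used by length sweeps)."""
        return GenotypeKinetics(
            lmax_mean=lmax_mean,
            lmax_sd=self.lmax_sd if lmax_sd is None else lmax_sd,
            T_ext=self.T_ext,
            retraction_rate_factor=self.retraction_rate_factor,
            name=f"{self.name}_lmax{lmax_mean:g}",
        )


#: Wild-type kinetics: arms cap in 0.05 time units, retract 1.7x faster.
WILD_TYPE = GenotypeKinetics(
    lmax_mean=_WT_LMAX_MEAN,
    lmax_sd=_WT_LMAX_SD,
    T_ext=_WT_T_EXT,
    retraction_rate_factor=1.7,
    name="wild_type",
)

#: lamc1 kinetics: short arms extending 1.4x slower per micron than wild
#: type (T_ext = 0.05 * (12.3 / 42.6) * 1.4) and retracting in 1.1x the
#: extension time.  In speed terms this makes mutant extension ~1.4x and
#: retraction ~2.6x slower than wild type.
LAMC1 = GenotypeKinetics(
    lmax_mean=_LAMC1_LMAX_MEAN,
    lmax_sd=_LAMC1_LMAX_SD,
    T_ext=_WT_T_EXT * (_LAMC1_LMAX_MEAN / _WT_LMAX_MEAN) * 1.4,
    retraction_rate_factor=1.0 / 1.1,
    name="lamc1",
)

GENOTYPES = {"wild_type": WILD_TYPE, "lamc1": LAMC1}


@dataclass
class ProtrusionState:
    """Arm lengths and caps of one differentiating cell.

    The phase clock ``t_since_trigger`` is continuous, so cap crossings
    and full retraction are honored exactly even when they fall between
    Euler steps.
    """

    left_lmax: float
    right_lmax: float
    t_since_trigger: float = 0.0
    phase: Phase = Phase.EXTENDING
    left_length: float = 0.0
    right_length: float = 0.0


def arm_lengths_at(
    t_since_trigger: float, kinetics: GenotypeKinetics, left_lmax: float, right_lmax: float
) -> tuple[float, float, Phase]:
    """Closed-form arm lengths and phase at a given time since trigger.

    During extension each arm grows linearly to its cap at ``T_ext``;
    during retraction both shrink linearly to zero at ``T_ext + T_ret``.
    """
    T_ext, T_ret = kinetics.T_ext, kinetics.T_ret
    if t_since_trigger < 0:
        raise ValueError("time since trigger must be non-negative")
    if t_since_trigger < T_ext:
        frac = t_since_trigger / T_ext
        return left_lmax * frac, right_lmax * frac, Phase.EXTENDING
    if t_since_trigger < T_ext + T_ret:
        frac = 1.0 - (t_since_trigger - T_ext) / T_ret
        return left_lmax * frac, right_lmax * frac, Phase.RETRACTING
    return 0.0, 0.0, Phase.DIFFERENTIATED


def trigger_extension(
    cell: int,
    N: np.ndarray,
    phase: np.ndarray,
    rule: DifferentiationRule,
    kinetics: GenotypeKinetics,
    rng: np.random.Generator,
) -> ProtrusionState | None:
    """Stochastically commit a progenitor to differentiation.

    With probability ``differentiation_probability(N[cell], rule)`` the
    cell enters the extending phase and both arm caps are sampled
    independently from the genotype's l_max normal.  From this step on
    the cell sends but no longer receives signal.  Returns the new
    protrusion state, or ``None`` if the cell did not trigger.
    """
    if phase[cell] != Phase.PROGENITOR:
        raise ValueError("only progenitors can trigger extension")
    if rng.random() >= differentiation_probability(float(N[cell]), rule):
        return None
    phase[cell] = Phase.EXTENDING
    left, right = kinetics.sample_lmax(rng, size=2)
    return ProtrusionState(left_lmax=float(left), right_lmax=float(right))


def update_protrusion(
    state: ProtrusionState, kinetics: GenotypeKinetics, dt: float
) -> ProtrusionState:
    """Advance a protrusion's continuous phase clock by ``dt`` (in place).

    Extension, the flip to retraction at the cap, and absorption into the
    differentiated phase are all computed from the closed-form length
    profile, so transitions that fall inside a step are exact.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if state.phase == Phase.DIFFERENTIATED:
        return state
    if state.phase not in (Phase.EXTENDING, Phase.RETRACTING):
        raise ValueError("protrusion updates apply to extending/retracting cells")
    state.t_since_trigger += dt
    left, right, phase = arm_lengths_at(
        state.t_since_trigger, kinetics, state.left_lmax, state.right_lmax
    )
    state.left_length, state.right_length, state.phase = left, right, phase
    return state


def protrusion_contacts(
    row: CellRow,
    source: int,
    state: ProtrusionState,
    differentiated: np.ndarray | None = None,
) -> set[int]:
    """Cells whose soma interval overlaps the source's protrusion arms.

    The arms span ``[center - left_length, center]`` and
    ``[center, center + right_length]``; a cell ``j != source`` is in
    contact when its soma interval ``[left_edge_j, left_edge_j + d_j)``
    overlaps either segment.  Reception is soma-only and differentiated
    cells (mask ``differentiated``) are excluded.
    """
    c = row.centers[source]
    lo = c - state.left_length
    hi = c + state.right_length
    if state.left_length <= 0 and state.right_length <= 0:
        return set()
    left = row.left_edges
    right = row.left_edges + row.diameters
    overlap = (left < hi) & (right > lo)
    out = set(np.nonzero(overlap)[0].tolist())
    out.discard(source)
    if differentiated is not None:
        out -= set(np.nonzero(differentiated)[0].tolist())
    return out
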