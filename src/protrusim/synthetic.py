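"""Synthetic in-vivo-style recordings of differentiation events.

Emulates the structure of time-lapse recordings of Vsx1:GFP neuron
births in the embryonic spinal cord: a 250-400 um stretch of one side of
the cord watched for ~8 h, in which differentiation events appear as
pairs of adjacent GFP+ daughters born from one non-apical-progenitor
division.  Each analysis event is emitted as two daughter records
sharing a pair id and birth time, offset by +/- half a cell diameter;
the statistics module collapses them back to the pair midpoint.

Two spacing regimes provide known ground truth for validating the
statistics end-to-end:

* ``random`` — positions and times uniform over the stretch and window;
* ``inhibition`` — a Matern-style spatiotemporal thinning: a candidate
  event is rejected if it falls within ``inhibition_range`` um of any
  accepted event whose birth lies within ``refractory_time`` h.  This is
  the simplest generator with a hard spatio-temporal core, deliberately
  independent of the mechanistic simulator.

The shipped presets match the study scale: wild-type-like, 34 stretches
and ~449 events (about 13 per stretch); mutant-like, 50 stretches and
~721 events (about 14 per stretch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StretchSpec",
    "SpacingRegime",
    "generate_stretch",
    "generate_cohort",
    "wt_preset",
    "lamc1_preset",
]

#: Mean cell diameter used for daughter offsets, um.
_CELL_DIAMETER_UM = 11.10


@dataclass(frozen=True)
class StretchSpec:
    """Geometry and sampling effort of one imaged stretch."""

    length_min: float = 250.0
    length_max: float = 400.0
    duration_h: float = 8.0
    target_events: int = 13
    side: str = "left"

    def __post_init__(self) -> None:
        if not 0 < self.length_min <= self.length_max:
            raise ValueError("need 0 < length_min <= length_max")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if self.target_events < 0:
            raise ValueError("target_events must be non-negative")


@dataclass(frozen=True)
class SpacingRegime:
    """Ground-truth spacing mechanism of the generator."""

    mode: str = "inhibition"  # or "random"
    inhibition_range: float = 42.6
    refractory_time: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "inhibition"):
            raise ValueError("mode must be 'random' or 'inhibition'")
        if self.inhibition_range < 0 or self.refractory_time < 0:
            raise ValueError("range and refractory time must be non-negative")


def generate_stretch(
    spec: StretchSpec,
    regime: SpacingRegime,
    seed: int | np.random.Generator = 0,
    stretch_id: int | str = 0,
) -> pd.DataFrame:
    """One stretch of daughter-pair events under the chosen regime.

    Events are placed sequentially in (uniform, sorted) time.  In the
    inhibition regime, candidates violating the spatio-temporal hard
    core are rejected and redrawn; if the core makes the target count
    infeasible the stretch saturates with a warning and fewer events.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    length = rng.uniform(spec.length_min, spec.length_max)
    times = np.sort(rng.uniform(0.0, spec.duration_h, size=spec.target_events))

    accepted_pos: list[float] = []
    accepted_t: list[float] = []
    max_attempts = 200
    for t in times:
        placed = False
        for _ in range(max_attempts):
            x = rng.uniform(0.0, length)
            if regime.mode == "random":
                placed = True
                break
            recent = [
                p
                for p, tt in zip(accepted_pos, accepted_t)
                if abs(t - tt) <= regime.refractory_time
            ]
            if all(abs(x - p) > regime.inhibition_range for p in recent):
                placed = True
                break
        if placed:
            accepted_pos.append(x)
            accepted_t.append(t)
    if len(accepted_pos) < spec.target_events:
        warnings.warn(
            f"stretch {stretch_id}: inhibition parameters saturated at "
            f"{len(accepted_pos)}/{spec.target_events} events"
        )

    half = _CELL_DIAMETER_UM / 2.0
    rows = []
    for k, (x, t) in enumerate(zip(accepted_pos, accepted_t)):
        pair = f"{stretch_id}_p{k}"
        for offset in (-half / 2.0, half / 2.0):  # daughters one half-soma apart
            rows.append(
                {
                    "stretch_id": stretch_id,
                    "cell_id": k,
                    "position_um": x + offset,
                    "time": t,
                    "genotype": regime.mode,
                    "pair_id": pair,
                }
            )
    columns = ["stretch_id", "cell_id", "position_um", "time", "genotype", "pair_id"]
    return pd.DataFrame(rows, columns=columns)


def generate_cohort(
    n_stretches: int,
    spec: StretchSpec,
    regime: SpacingRegime,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Independent stretches pooled, seeds spawned from the master seed."""
    if n_stretches < 1:
        raise ValueError("n_stretches must be >= 1")
    child_seeds = np.random.SeedSequence(master_seed).spawn(n_stretches)
    tables = [
        generate_stretch(spec, regime, np.random.default_rng(ss), stretch_id=i)
        for i, ss in enumerate(child_seeds)
    ]
    return pd.concat(tables, ignore_index=True)


def wt_preset() -> tuple[int, StretchSpec]:
    """Wild-type scale: 34 stretches, ~449 events (13.2 per stretch)."""
    return 34, StretchSpec(target_events=13)


def lamc1_preset() -> tuple[int, StretchSpec]:
    """Mutant scale: 50 stretches, ~721 events (14.4 per stretch)."""
    return 50, StretchSpec(target_events=14)
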