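"""Full lateral-inhibition simulations on a row of cells.

Each replicate builds a fresh row, initializes Notch/Delta levels with a
1% relative spread, and iterates Euler steps (dt = 0.01) until every cell
has differentiated.  Per step: contact sets are recomputed excluding
differentiated cells, incoming Delta is aggregated with the soma and
protrusion weights, Notch/Delta are updated with additive noise,
progenitors stochastically commit to differentiation through the Hill
trigger, and committed cells advance their protrusion cycle.  A cell's
differentiation event (its center position and the time both arms finish
retracting) is appended to the event table.

Signaling modes map onto the contact weights: ``protrusion_only`` is
(alpha=0, beta=1) — the headline model; ``soma_only`` silences the
protrusion term; ``soma_plus_protrusion`` keeps both.

The simulation clock is bridged to in-vivo hours by equating one
wild-type protrusion life cycle (T_ext * (1 + 1/1.7) ~ 0.0794 time units)
with the measured in-vivo protrusion lifetime of 6.8 h; time-conditioned
statistics use this calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protrusions import (
    GenotypeKinetics,
    ProtrusionState,
    WILD_TYPE,
    protrusion_contacts,
    update_protrusion,
)
from .signaling import (
    DifferentiationRule,
    Phase,
    SignalParams,
    differentiation_probability,
    euler_step,
    initialize_levels,
)
from .tissue import CellRow, build_row

__all__ = [
    "SimulationConfig",
    "run_replicate",
    "run_experiment",
    "HOURS_PER_TIME_UNIT",
    "EVENT_COLUMNS",
]

#: Simulation-time -> hours bridge: one wild-type protrusion cycle
#: (~0.0794 time units) corresponds to the 6.8 h in-vivo lifetime.
HOURS_PER_TIME_UNIT = 6.8 / WILD_TYPE.cycle_time

#: Canonical event-table columns shared by simulator, nulls and synthetic
#: generator.
EVENT_COLUMNS = ["stretch_id", "cell_id", "position_um", "time", "genotype", "pair_id"]

_MODES = ("protrusion_only", "soma_plus_protrusion", "soma_only", "random_null")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce a simulated experiment."""

    n_cells: int = 50
    diameter_mean: float = 11.10
    diameter_sd: float = 4.51
    params: SignalParams = field(default_factory=SignalParams)
    rule: DifferentiationRule = field(default_factory=DifferentiationRule)
    kinetics: GenotypeKinetics = field(default_factory=lambda: WILD_TYPE)
    dt: float = 0.01
    n_replicates: int = 100
    seed: int = 0
    mode: str = "protrusion_only"
    #: Soma weight used when the mode includes soma signaling; the default
    #: sits in the patterning (checkerboard) regime of the soma-only scan.
    soma_alpha: float = 0.5
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown signaling mode {self.mode!r}; choose from {_MODES}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def resolved_params(self) -> SignalParams:
        """Signal parameters with (alpha, beta) resolved from the mode."""
        if self.mode == "protrusion_only":
            return replace(self.params, alpha=0.0, beta=1.0)
        if self.mode == "soma_only":
            return replace(self.params, alpha=self.soma_alpha, beta=0.0)
        if self.mode == "soma_plus_protrusion":
            return replace(self.params, alpha=self.soma_alpha, beta=1.0)
        return self.params  # random_null: weights unused


def _soma_d_in(D: np.ndarray, receiving: np.ndarray, sending_ok: np.ndarray) -> np.ndarray:
    """Sum of neighbor Delta for every cell (senders masked by sending_ok)."""
    contrib = np.where(sending_ok, D, 0.0)
    out = np.zeros_like(D)
    out[:-1] += contrib[1:]
    out[1:] += contrib[:-1]
    return np.where(receiving, out, 0.0)


def run_replicate(
    config: SimulationConfig,
    seed: int | np.random.Generator,
    row: CellRow | None = None,
) -> pd.DataFrame:
    """Run one replicate to completion and return its event table.

    The loop ends when every cell has differentiated; if that has not
    happened within ``config.max_steps`` Euler steps a ``RuntimeError``
    reporting the last differentiation time is raised.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if row is None:
        row = build_row(config.n_cells, config.diameter_mean, config.diameter_sd, rng)
    n = row.n_cells
    params = config.resolved_params()
    state = initialize_levels(n, params, rng)
    protrusions: dict[int, ProtrusionState] = {}
    diff_time = np.full(n, np.nan)
    use_protrusions = params.beta > 0
    use_soma = params.alpha > 0

    t = 0.0
    last_event_time = np.nan
    for step in range(config.max_steps):
        phase = state.phase
        differentiated = phase == Phase.DIFFERENTIATED
        if differentiated.all():
            break
        progenitor = phase == Phase.PROGENITOR

        # --- incoming Delta (receivers are progenitors only: committed
        # cells send but do not receive, differentiated cells are out) ---
        d_in = np.zeros(n)
        if use_soma:
            d_in += params.alpha * _soma_d_in(state.D, progenitor, ~differentiated)
        if use_protrusions and protrusions:
            for s, pstate in protrusions.items():
                for j in protrusion_contacts(row, s, pstate, differentiated):
                    if progenitor[j]:
                        d_in[j] += params.beta * state.D[s]

        euler_step(state, d_in, params, config.dt, rng, step_index=step)

        # --- differentiation trigger for progenitors ---
        if progenitor.any():
            p_trig = differentiation_probability(state.N[progenitor], config.rule)
            hits = np.nonzero(progenitor)[0][rng.random(int(progenitor.sum())) < p_trig]
            for i in hits:
                state.phase[i] = Phase.EXTENDING
                left, right = config.kinetics.sample_lmax(rng, size=2)
                protrusions[int(i)] = ProtrusionState(
                    left_lmax=float(left), right_lmax=float(right)
                )

        # --- advance protrusion cycles; record completed differentiations ---
        t += config.dt
        done = []
        for i, pstate in protrusions.items():
            update_protrusion(pstate, config.kinetics, config.dt)
            state.phase[i] = pstate.phase
            if pstate.phase == Phase.DIFFERENTIATED:
                # exact completion time (sub-step) from the continuous clock
                diff_time[i] = t - (pstate.t_since_trigger - config.kinetics.cycle_time)
                last_event_time = diff_time[i]
                done.append(i)
        for i in done:
            del protrusions[i]
    else:
        raise RuntimeError(
            f"replicate did not terminate within {config.max_steps} steps; "
            f"last differentiation at t={last_event_time}"
        )

    return pd.DataFrame(
        {
            "stretch_id": 0,
            "cell_id": np.arange(n),
            "position_um": row.centers,
            "time": diff_time,
            "genotype": config.kinetics.name,
            "pair_id": pd.array([pd.NA] * n),
        }
    )


def run_experiment(
    config: SimulationConfig,
    n_replicates: int | None = None,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Run independent replicates and pool their event tables.

    Per-replicate seeds are spawned deterministically from the master
    seed via ``SeedSequence``, so the pooled table is reproducible and
    replicates are statistically independent.
    """
    n_rep = config.n_replicates if n_replicates is None else n_replicates
    seed = config.seed if master_seed is None else master_seed
    child_seeds = np.random.SeedSequence(seed).spawn(n_rep)
    tables = []
    for r, ss in enumerate(child_seeds):
        table = run_replicate(config, np.random.default_rng(ss))
        table = table.assign(stretch_id=r)
        tables.append(table)
    return pd.concat(tables, ignore_index=True)
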