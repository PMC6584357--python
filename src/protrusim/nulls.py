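"""Null models of differentiation order.

Two parameter-free comparators for the lateral-inhibition simulator:

* ``random_differentiation`` — the randomly differentiating tissue: a
  uniformly random permutation of the cells in a row, the i-th sampled
  cell being the i-th differentiation event (unit time spacing).  No
  signaling code path is touched, so its sequential-distance
  distribution depends only on the row geometry and the analysis window.
* ``randomize_event_table`` — a per-stretch randomization of an observed
  event table, used to build randomized comparators for proportion
  tests.  The default redraws each event's position uniformly over the
  stretch's observed position span while keeping times and counts; a
  time-shuffling variant (permute times, keep positions) is available
  behind a flag since the exact recipe is ambiguous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tissue import CellRow

__all__ = ["random_differentiation", "randomize_event_table", "random_null_experiment"]


def random_differentiation(
    row: CellRow,
    seed: int | np.random.Generator = 0,
    stretch_id: int = 0,
) -> pd.DataFrame:
    """Event table for a randomly differentiating row.

    Cells differentiate in a uniformly random order; the i-th sampled
    cell is the i-th event, at ordinal time i (1-based) and at its soma
    center.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = rng.permutation(row.n_cells)
    return pd.DataFrame(
        {
            "stretch_id": stretch_id,
            "cell_id": order,
            "position_um": row.centers[order],
            "time": np.arange(1, row.n_cells + 1, dtype=float),
            "genotype": "random_null",
            "pair_id": pd.array([pd.NA] * row.n_cells),
        }
    )


def random_null_experiment(
    n_rows: int = 100,
    n_cells: int = 50,
    diameter_mean: float = 11.10,
    diameter_sd: float = 4.51,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Pool ``n_rows`` independent randomly differentiating rows.

    Each replicate draws a fresh row from the diameter distribution and
    a fresh permutation; replicate seeds are spawned from the master
    seed.
    """
    from .tissue import build_row

    child_seeds = np.random.SeedSequence(master_seed).spawn(n_rows)
    tables = []
    for r, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        row = build_row(n_cells, diameter_mean, diameter_sd, rng)
        tables.append(random_differentiation(row, rng, stretch_id=r))
    return pd.concat(tables, ignore_index=True)


def randomize_event_table(
    events: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    method: str = "uniform_positions",
) -> pd.DataFrame:
    """Randomized comparator of an event table, stretch by stretch.

    ``uniform_positions`` (default) redraws every position uniformly on
    the stretch's observed [min, max] position span, keeping times and
    event counts; ``shuffle_times`` permutes the times over the observed
    positions instead.  Stretches with fewer than two events pass
    through unchanged.
    """
    if method not in ("uniform_positions", "shuffle_times"):
        raise ValueError(f"unknown randomization method {method!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = events.copy()
    out["position_um"] = out["position_um"].astype(float)
    out["time"] = out["time"].astype(float)
    for _, idx in events.groupby("stretch_id").groups.items():
        if len(idx) < 2:
            continue
        if method == "uniform_positions":
            pos = events.loc[idx, "position_um"].to_numpy(dtype=float)
            out.loc[idx, "position_um"] = rng.uniform(pos.min(), pos.max(), size=len(idx))
        else:
            times = events.loc[idx, "time"].to_numpy(dtype=float)
            out.loc[idx, "time"] = rng.permutation(times)
    return out
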