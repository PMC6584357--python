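"""1D tissue geometry: a row of cells with empirically distributed widths.

The spinal-cord stretch is modelled as a gap-free row of cells along the
anteroposterior axis.  Cell diameters are drawn from the measured
neuroepithelial width distribution (normal, mean 11.10 um, s.d. 4.51 um);
positions are expressed in microns with the left edge of cell 0 at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellRow",
    "build_row",
    "soma_neighbors",
    "DIAMETER_MEAN_UM",
    "DIAMETER_SD_UM",
]

#: Measured neuroepithelial cell width distribution (um).
DIAMETER_MEAN_UM = 11.10
DIAMETER_SD_UM = 4.51

#: Diameters at or below this floor are redrawn (normals can go negative).
_DIAMETER_FLOOR_UM = 1.0


@dataclass(frozen=True)
class CellRow:
    """An ordered, gap-free row of cells on the anteroposterior axis.

    Attributes
    ----------
    diameters
        Per-cell widths in um, strictly positive.
    left_edges
        Left edge of each cell; ``left_edges[0] == 0`` and
        ``left_edges[i+1] == left_edges[i] + diameters[i]``.
    centers
        Cell centers, strictly increasing.
    """

    diameters: np.ndarray
    left_edges: np.ndarray = field(init=False)
    centers: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or d.size < 1:
            raise ValueError("a row needs at least one cell")
        if np.any(d <= 0):
            raise ValueError("cell diameters must be positive")
        object.__setattr__(self, "diameters", d)
        left = np.concatenate([[0.0], np.cumsum(d)[:-1]])
        object.__setattr__(self, "left_edges", left)
        object.__setattr__(self, "centers", left + d / 2.0)

    @property
    def n_cells(self) -> int:
        return self.diameters.size

    @property
    def total_length(self) -> float:
        """Row length in um (sum of diameters)."""
        return float(self.diameters.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tabular form (index, left_edge_um, diameter_um) for serialization."""
        return pd.DataFrame(
            {
                "index": np.arange(self.n_cells),
                "left_edge_um": self.left_edges,
                "diameter_um": self.diameters,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CellRow":
        frame = frame.sort_values("index")
        return cls(diameters=frame["diameter_um"].to_numpy(dtype=float))


def build_row(
    n_cells: int,
    diameter_mean: float = DIAMETER_MEAN_UM,
    diameter_sd: float = DIAMETER_SD_UM,
    seed: int | np.random.Generator = 0,
) -> CellRow:
    """Sample a row of ``n_cells`` cells with normally distributed widths.

    Draws at or below 1 um are redrawn so every cell has positive width
    while the sample moments stay close to the configured mean/sd.

    Parameters
    ----------
    n_cells
        Number of cells (>= 1).
    diameter_mean, diameter_sd
        Mean and s.d. of the width normal, um.
    seed
        Integer seed or a ``numpy.random.Generator``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if diameter_mean <= 0:
        raise ValueError("diameter_mean must be positive")
    if diameter_sd < 0:
        raise ValueError("diameter_sd must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = rng.normal(diameter_mean, diameter_sd, size=n_cells)
    bad = d <= _DIAMETER_FLOOR_UM
    while np.any(bad):
        d[bad] = rng.normal(diameter_mean, diameter_sd, size=int(bad.sum()))
        bad = d <= _DIAMETER_FLOOR_UM
    return CellRow(diameters=d)


def soma_neighbors(row: CellRow, i: int) -> set[int]:
    """Indices of the cells whose somas touch cell ``i`` (at most {i-1, i+1})."""
    if not 0 <= i < row.n_cells:
        raise IndexError(f"cell index {i} out of range for row of {row.n_cells}")
    return {j for j in (i - 1, i + 1) if 0 <= j < row.n_cells}
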