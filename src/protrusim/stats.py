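"""Spatiotemporal statistics on differentiation event tables.

The common currency is the event table: one record per differentiation
event with a stretch (or replicate) id, a position in um, a time, and an
optional pair id for daughter pairs born from one non-apical-progenitor
division.  Records sharing a (stretch, pair) key are collapsed to a
single analysis event at the pair midpoint and shared birth time before
any statistic is computed — the in-vivo unit of observation is the pair,
not the individual daughter.

Statistics implemented:

* sequential dx — distance between temporally successive events within a
  stretch, retained when <= the 80 um analysis window;
* proportion of successive events within a threshold distance
  (default 42.6 um, the mean wild-type protrusion length);
* all-pairs (dx, dt) tables, Spearman rank correlation, distributions of
  pairwise dx conditioned on dt, and mean dt per dx bin;
* two-sample Kolmogorov-Smirnov comparisons of dx distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DxSummary",
    "collapse_pairs",
    "sequential_dx",
    "proportion_within",
    "pairwise_dxdt",
    "spearman_rho",
    "conditional_dx_distribution",
    "binned_mean_dt",
    "estimate_inhibition_range",
    "ks_compare",
]

#: Analysis window for sequential distances, um (about twice the mean
#: wild-type protrusion length).
DX_WINDOW_UM = 80.0
#: Mean wild-type protrusion length, um; threshold of the proportion test.
PROTRUSION_MEAN_UM = 42.6


@dataclass(frozen=True)
class DxSummary:
    """Sequential-distance distribution within the analysis window."""

    values: np.ndarray
    window: float = DX_WINDOW_UM
    bin_width: float = 10.0

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.n else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n > 1 else float("nan")

    def histogram(self) -> pd.DataFrame:
        """Counts in ``bin_width`` um bins over (0, window]."""
        edges = np.arange(0.0, self.window + self.bin_width, self.bin_width)
        counts, _ = np.histogram(self.values, bins=edges)
        return pd.DataFrame(
            {"bin_left_um": edges[:-1], "bin_right_um": edges[1:], "count": counts}
        )


def collapse_pairs(events: pd.DataFrame) -> pd.DataFrame:
    """Collapse daughter-pair records into one analysis event per pair.

    Records sharing (stretch_id, pair_id) become a single event at their
    mean position and shared (earliest) time; records without a pair id
    pass through.  Residual exact time ties within a stretch are broken
    by position order so downstream "successive event" definitions are
    deterministic.
    """
    events = events.copy()
    has_pair = events["pair_id"].notna() if "pair_id" in events else pd.Series(False, index=events.index)
    unpaired = events[~has_pair]
    if has_pair.any():
        paired = (
            events[has_pair]
            .groupby(["stretch_id", "pair_id"], as_index=False)
            .agg(
                cell_id=("cell_id", "first"),
                position_um=("position_um", "mean"),
                time=("time", "min"),
                genotype=("genotype", "first"),
            )
        )
        out = pd.concat([unpaired, paired], ignore_index=True)
    else:
        out = unpaired
    return out.sort_values(["stretch_id", "time", "position_um"], kind="mergesort").reset_index(
        drop=True
    )


def _per_stretch_dx(events: pd.DataFrame) -> dict:
    """|position difference| between consecutive-in-time events, per stretch."""
    collapsed = collapse_pairs(events)
    out = {}
    for sid, grp in collapsed.groupby("stretch_id"):
        pos = grp["position_um"].to_numpy(dtype=float)
        out[sid] = np.abs(np.diff(pos))
    return out


def sequential_dx(events: pd.DataFrame, window: float = DX_WINDOW_UM) -> DxSummary:
    """Distances between temporally successive events, within the window.

    Within each stretch, events are ordered by time (ties by position)
    and the absolute position difference between each event and the next
    is retained iff it is <= ``window``; transitions that jump farther
    than the window contribute nothing.  Values are pooled across
    stretches.
    """
    per = _per_stretch_dx(events)
    if all(v.size == 0 for v in per.values()):
        import warnings

        warnings.warn("no stretch has two or more events; dx summary is empty")
    vals = (
        np.concatenate([v[v <= window] for v in per.values()])
        if per
        else np.empty(0)
    )
    return DxSummary(values=vals, window=window)


def proportion_within(
    events: pd.DataFrame, threshold: float = PROTRUSION_MEAN_UM
) -> tuple[float, pd.Series]:
    """Fraction of successive differentiation events within ``threshold`` um.

    Computed over all consecutive-in-time transitions (no analysis-window
    cut: the threshold itself is the accounting interval).  Returns the
    pooled fraction and the per-stretch fractions for distribution-level
    comparisons.
    """
    per = _per_stretch_dx(events)
    per_stretch = pd.Series(
        {sid: float(np.mean(v <= threshold)) for sid, v in per.items() if v.size},
        name="proportion_within",
    )
    all_vals = np.concatenate(list(per.values())) if per else np.empty(0)
    pooled = float(np.mean(all_vals <= threshold)) if all_vals.size else float("nan")
    return pooled, per_stretch


def pairwise_dxdt(events: pd.DataFrame) -> pd.DataFrame:
    """(dx, dt) for every unordered within-stretch pair of events.

    Cross-stretch pairs are excluded; the pair count is
    sum over stretches of n_s (n_s - 1) / 2.
    """
    collapsed = collapse_pairs(events)
    rows = []
    for sid, grp in collapsed.groupby("stretch_id"):
        pos = grp["position_um"].to_numpy(dtype=float)
        t = grp["time"].to_numpy(dtype=float)
        n = pos.size
        if n < 2:
            continue
        iu, ju = np.triu_indices(n, k=1)
        rows.append(
            pd.DataFrame(
                {
                    "stretch_id": sid,
                    "dx": np.abs(pos[iu] - pos[ju]),
                    "dt": np.abs(t[iu] - t[ju]),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["stretch_id", "dx", "dt"])
    return pd.concat(rows, ignore_index=True)


def spearman_rho(pairs: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation of pairwise (dx, dt), with p-value.

    Average ranks handle ties; the p-value is from the large-sample rank
    test.  Constant dx or dt makes the correlation undefined.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a rank correlation")
    dx = pairs["dx"].to_numpy(dtype=float)
    dt = pairs["dt"].to_numpy(dtype=float)
    if np.all(dx == dx[0]) or np.all(dt == dt[0]):
        raise ValueError("rank correlation undefined for constant dx or dt")
    rho, p = sps.spearmanr(dx, dt)
    return float(rho), float(p)


def conditional_dx_distribution(
    pairs: pd.DataFrame, dt_max: float
) -> np.ndarray:
    """Pairwise dx values restricted to pairs with dt <= ``dt_max``.

    ``dt_max`` is in the time unit of the table (hours for in-vivo-style
    tables; simulation units otherwise — use the simulator's
    hours-per-time-unit bridge to convert).
    """
    if dt_max <= 0:
        raise ValueError("dt_max must be positive")
    sel = pairs.loc[pairs["dt"] <= dt_max, "dx"].to_numpy(dtype=float)
    if sel.size == 0:
        import warnings

        warnings.warn("no pairs satisfy the dt condition; empty distribution")
    return sel


def binned_mean_dt(pairs: pd.DataFrame, bin_width: float = 10.0) -> pd.DataFrame:
    """Mean pairwise dt per dx bin ([0,10), [10,20), ... um by default).

    Empty bins are absent from the output rather than reported as zero.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    dx = pairs["dx"].to_numpy(dtype=float)
    dt = pairs["dt"].to_numpy(dtype=float)
    bins = np.floor(dx / bin_width).astype(int)
    frame = pd.DataFrame({"bin": bins, "dt": dt})
    agg = frame.groupby("bin")["dt"].agg(["mean", "count"]).reset_index()
    agg["bin_left_um"] = agg["bin"] * bin_width
    agg["bin_right_um"] = (agg["bin"] + 1) * bin_width
    return agg[["bin_left_um", "bin_right_um", "mean", "count"]].rename(
        columns={"mean": "mean_dt", "count": "n_pairs"}
    )


def estimate_inhibition_range(
    curve: pd.DataFrame, baseline_from: float = 100.0, factor: float = 1.15
) -> float:
    """Read the spatial reach of inhibition off a binned mean-dt curve.

    Cells within the inhibited range differentiate further apart in time,
    so the leading dx bins sit above the long-range baseline.  The
    estimate is the right edge of the initial contiguous run of bins
    whose mean dt exceeds ``factor`` times the baseline (the mean over
    bins at or beyond ``baseline_from`` um); 0 if even the first bin is
    not elevated.
    """
    curve = curve.sort_values("bin_left_um")
    baseline = curve[curve["bin_left_um"] >= baseline_from]["mean_dt"].mean()
    if not np.isfinite(baseline):
        raise ValueError("no bins beyond baseline_from to set a baseline")
    reach = 0.0
    for _, row in curve.iterrows():
        if row["mean_dt"] > factor * baseline:
            reach = float(row["bin_right_um"])
        else:
            break
    return reach


def ks_compare(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on raw dx values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    stat, p = sps.ks_2samp(a, b, method="auto")
    return float(stat), float(p)
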