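"""Event-table and configuration I/O.

Event tables are UTF-8 tab-separated files with the header
``stretch_id  cell_id  position_um  time  genotype  pair_id`` (pair_id
may be empty).  Positions are um; times are simulation units or hours —
the unit is recorded in the JSON sidecar/manifest, not in the table.

Every CLI run can write a manifest: the resolved configuration, the
seeds used, and a SHA-256 checksum of each output file, so exact stages
are re-runnable bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .protrusions import GENOTYPES, GenotypeKinetics
from .signaling import DifferentiationRule, SignalParams
from .simulate import EVENT_COLUMNS, SimulationConfig

__all__ = [
    "read_events",
    "write_events",
    "load_config",
    "dump_params",
    "write_manifest",
    "default_config_path",
]


class EventFormatError(ValueError):
    """A malformed event table, with the offending line when known."""


def write_events(table: pd.DataFrame, path: str | Path) -> Path:
    """Write an event table as TSV with the canonical column order."""
    path = Path(path)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise EventFormatError(f"event table missing columns: {missing}")
    table[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate an event TSV; errors name the offending line."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype={"pair_id": "string"})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise EventFormatError(f"{path}: cannot parse as event TSV ({exc})") from exc
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise EventFormatError(f"{path}: missing columns {missing}")
    if table.empty:
        import warnings

        warnings.warn(f"{path}: header-only event file, empty table")
        return table
    for col in ("position_um", "time"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise EventFormatError(f"{path}: non-numeric {col} at line {line}")
        table[col] = vals
    neg = table["time"] < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise EventFormatError(f"{path}: negative time at line {line}")
    return table


def default_config_path() -> Path:
    """Path of the shipped default configuration (YAML)."""
    return Path(__file__).parent / "data" / "default_config.yaml"


def _build_kinetics(block: dict[str, Any], name: str) -> GenotypeKinetics:
    return GenotypeKinetics(
        lmax_mean=block["lmax_mean"],
        lmax_sd=block["lmax_sd"],
        T_ext=block["T_ext"],
        retraction_rate_factor=block["retraction_rate_factor"],
        name=name,
    )


def load_config(
    path: str | Path | None = None,
    genotype: str = "wild_type",
    **overrides: Any,
) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file.

    ``genotype`` selects a kinetics block from the file (keys
    ``wild_type`` and ``lamc1`` in the shipped config).  Keyword
    overrides replace top-level config fields (n_cells, mode, seed ...).
    """
    path = default_config_path() if path is None else Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    params = SignalParams(**raw.get("signal_params", {}))
    rule = DifferentiationRule(**raw.get("differentiation_rule", {}))
    genotypes = raw.get("genotypes", {})
    if genotype in genotypes:
        kinetics = _build_kinetics(genotypes[genotype], genotype)
    elif genotype in GENOTYPES:
        kinetics = GENOTYPES[genotype]
    else:
        raise KeyError(f"genotype {genotype!r} not in config or built-ins")
    sim = raw.get("simulation", {})
    fields = dict(
        n_cells=sim.get("n_cells", 50),
        diameter_mean=sim.get("diameter_mean", 11.10),
        diameter_sd=sim.get("diameter_sd", 4.51),
        dt=sim.get("dt", 0.01),
        n_replicates=sim.get("n_replicates", 100),
        seed=sim.get("seed", 0),
        mode=sim.get("mode", "protrusion_only"),
        soma_alpha=sim.get("soma_alpha", 1.0),
    )
    fields.update(overrides)
    return SimulationConfig(params=params, rule=rule, kinetics=kinetics, **fields)


def dump_params(config: SimulationConfig) -> dict[str, Any]:
    """Every numeric used in a run, as a JSON-serializable dict."""
    out = dataclasses.asdict(config)
    out["resolved_alpha"] = config.resolved_params().alpha
    out["resolved_beta"] = config.resolved_params().beta
    return json.loads(json.dumps(out, default=_jsonable))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def write_manifest(
    path: str | Path,
    config: dict[str, Any] | None,
    seeds: dict[str, int],
    outputs: list[str | Path],
    tool_version: str = "0.1.0",
) -> Path:
    """Write a run manifest: config snapshot, seeds, output checksums."""
    path = Path(path)
    artifacts = {}
    for out in outputs:
        out = Path(out)
        artifacts[out.name] = hashlib.sha256(out.read_bytes()).hexdigest()
    manifest = {
        "tool_version": tool_version,
        "config": config,
        "seeds": seeds,
        "outputs": artifacts,
    }
    path.write_text(json.dumps(manifest, indent=2, default=_jsonable))
    return path
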