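"""CSV/JSON/YAML readers and writers for datasets, fits and simulations.

Conventions: user-facing temperatures are °C, activation energies
kJ/mol; every JSON summary echoes the seed and configuration it was
produced with so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fitting import FitResult, IsothermalDataset
from .kinetics import TemperatureProfile
from .confidence import RegionBoundary
from .montecarlo import ShelfLifeDistribution
from .units import kelvin_to_celsius

__all__ = [
    "read_isothermal_csv",
    "write_isothermal_csv",
    "read_profile_csv",
    "write_profile_csv",
    "write_fit_json",
    "write_boundary_csv",
    "write_distribution",
    "write_manifest",
]

PathLike = Union[str, Path]


def read_isothermal_csv(path: PathLike) -> IsothermalDataset:
    """Load isothermal observations from CSV.

    Accepts either columns (temperature_C, time_days, retention) or
    (temperature_C, time_days, concentration, c0); concentrations are
    normalized per row.  Malformed rows are reported with their line
    numbers (header = line 1).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"temperature_C", "time_days"}.issubset(cols) and "retention" in cols:
        retention = df["retention"]
    elif {"temperature_C", "time_days", "concentration", "c0"}.issubset(cols):
        retention = df["concentration"] / df["c0"]
    else:
        raise InvalidInputError(
            f"{path}: need columns temperature_C, time_days and retention "
            "(or concentration + c0); found " + ", ".join(sorted(cols))
        )
    problems = []
    for idx in df.index:
        line = idx + 2  # header occupies line 1
        r = retention[idx]
        t = df["time_days"][idx]
        if not np.isfinite(r) or r <= 0:
            problems.append(f"line {line}: retention must be > 0 (got {r})")
        if not np.isfinite(t) or t < 0:
            problems.append(f"line {line}: time_days must be ≥ 0 (got {t})")
    if problems:
        raise InvalidInputError(f"{path}: " + "; ".join(problems))
    frame = pd.DataFrame(
        {
            "temperature_C": df["temperature_C"].astype(float),
            "time_days": df["time_days"].astype(float),
            "retention": retention.astype(float),
        }
    )
    return IsothermalDataset.from_dataframe(frame)


def write_isothermal_csv(dataset: IsothermalDataset, path: PathLike) -> None:
    dataset.to_dataframe().to_csv(path, index=False)


def read_profile_csv(path: PathLike) -> TemperatureProfile:
    """Load a stepwise profile from CSV (duration_days, temperature_C)."""
    df = pd.read_csv(path)
    missing = {"duration_days", "temperature_C"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    return TemperatureProfile.from_celsius_steps(
        list(zip(df["duration_days"].astype(float), df["temperature_C"].astype(float)))
    )


def write_profile_csv(profile: TemperatureProfile, path: PathLike, stages=None) -> None:
    frame = pd.DataFrame(
        {
            "duration_days": profile.durations,
            "temperature_C": kelvin_to_celsius(profile.temperatures),
        }
    )
    if stages is not None:
        frame["stage"] = stages
    frame.to_csv(path, index=False)


def write_fit_json(fit: FitResult, path: PathLike, seed: Optional[int] = None, extra: Optional[dict] = None) -> None:
    """FitResult → JSON (kJ/mol and per-day units, CIs, covariance, SSE)."""
    payload = fit.summary()
    if seed is not None:
        payload["seed"] = seed
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def write_boundary_csv(boundary: RegionBoundary, path: PathLike) -> None:
    """Joint-region boundary → CSV (k_ref_per_day, Ea_kJ_per_mol)."""
    pd.DataFrame(
        {"k_ref_per_day": boundary.k_ref, "Ea_kJ_per_mol": boundary.E_a / 1000.0}
    ).to_csv(path, index=False)


def write_distribution(
    dist: ShelfLifeDistribution,
    basename: PathLike,
    seed: Optional[int] = None,
    config_echo: Optional[dict] = None,
) -> tuple[Path, Path]:
    """Write <base>.csv (one shelf-life sample per row) and <base>.json summary."""
    base = Path(basename)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    pd.DataFrame({"shelf_life_days": dist.samples}).to_csv(csv_path, index=False)
    payload = dist.summary()
    if seed is not None:
        payload["seed"] = seed
    if config_echo:
        payload["config"] = config_echo
    json_path.write_text(json.dumps(payload, indent=2))
    return csv_path, json_path


def write_manifest(path: PathLike, seed: Optional[int], config: dict) -> None:
    """Record everything needed to reproduce a run (config + seed + version)."""
    from . import __version__

    Path(path).write_text(
        json.dumps({"version": __version__, "seed": seed, "config": config}, indent=2)
    )
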