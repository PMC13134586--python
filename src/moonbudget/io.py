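"""Schema-checked CSV input/output and run configuration.

All on-disk interchange is plain CSV with ISO-8601 UTC timestamps.
Readers validate headers up front and name the missing column; any
timestamp carrying a non-UTC offset is normalised to UTC with a
warning.  Run configuration is a flat YAML mapping validated against
the known keys (site coordinates, energy-model constants, thresholds,
seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from .energetics import EnergyParams
from .ephemeris import DONANA, Site

__all__ = [
    "SchemaError",
    "RunConfig",
    "SCHEMAS",
    "read_table",
    "write_csv",
    "load_config",
    "ensure_dir",
]


class SchemaError(ValueError):
    """A CSV does not match its declared schema."""


#: Required columns and timestamp columns per table kind.
SCHEMAS: dict[str, dict] = {
    "bursts": {
        "required": ["bird_id", "timestamp", "s1", "s2", "s3", "s4", "s5"],
        "timestamps": ["timestamp"],
    },
    "gps": {
        "required": ["bird_id", "timestamp", "lat", "lon"],
        "timestamps": ["timestamp"],
    },
    "captures": {
        "required": [
            "bird_id",
            "timestamp",
            "mass",
            "gizzard_score",
            "fat_score",
            "brood_patch",
        ],
        "timestamps": ["timestamp"],
    },
    "temps": {
        "required": ["bird_id", "hour_start", "tsk"],
        "timestamps": ["hour_start"],
    },
    "hourly": {
        "required": ["bird_id", "hour_start", "tf"],
        "timestamps": ["hour_start"],
    },
    "daily": {"required": ["day", "total_MEi", "total_Ee", "DEB"], "timestamps": []},
    "events": {
        "required": ["bird_id", "onset", "end", "min_tsk", "threshold"],
        "timestamps": ["onset", "end"],
    },
    "nights": {
        "required": ["date", "sunset_utc", "sunrise_utc", "illum_frac", "phase_class"],
        "timestamps": [],
    },
}


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate a CSV of the given kind.

    Raises SchemaError naming the first missing column; timestamp
    columns are parsed and normalised to UTC.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind: {kind!r}")
    df = pd.read_csv(path)
    schema = SCHEMAS[kind]
    for col in schema["required"]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r} for {kind}")
    for col in schema["timestamps"]:
        parsed = pd.to_datetime(df[col], format="ISO8601")
        if parsed.dt.tz is None:
            parsed = parsed.dt.tz_localize("UTC")
        else:
            offsets = parsed.dt.tz
            utc = parsed.dt.tz_convert("UTC")
            if not (parsed.astype("int64") == utc.astype("int64")).all() or str(
                offsets
            ) not in ("UTC", "utc"):
                if str(offsets) not in ("UTC", "utc"):
                    warnings.warn(f"{path}: {col} carried a non-UTC offset; normalised")
            parsed = utc
        df[col] = parsed
    return df


def write_csv(df: pd.DataFrame, path) -> str:
    """Write a CSV deterministically (ISO timestamps, fixed float format)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
        elif out[col].map(lambda v: hasattr(v, "isoformat")).any():
            out[col] = out[col].map(
                lambda v: v.isoformat() if hasattr(v, "isoformat") else v
            )
    out.to_csv(path, index=False, float_format="%.6g")
    return str(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for the pipeline."""

    site: Site = DONANA
    params: EnergyParams = EnergyParams()
    new_moon_max: float = 0.15
    full_moon_min: float = 0.85
    torpor_k_sd: float = 2.0
    displacement_km: float = 10.0
    seed: int = 0


_SITE_KEYS = {"latitude", "longitude", "label"}
_THRESHOLD_KEYS = {
    "new_moon_max",
    "full_moon_min",
    "torpor_k_sd",
    "displacement_km",
    "seed",
}


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys.

    Recognised top-level keys: ``site`` (latitude/longitude/label),
    ``energy`` (any EnergyParams field), and the threshold keys
    new_moon_max, full_moon_min, torpor_k_sd, displacement_km, seed.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    site = DONANA
    if "site" in raw:
        entry = raw.pop("site")
        unknown = set(entry) - _SITE_KEYS
        if unknown:
            raise SchemaError(f"{path}: unknown site keys {sorted(unknown)}")
        site = Site(**entry)
    params = EnergyParams()
    if "energy" in raw:
        entry = raw.pop("energy")
        valid = {f.name for f in fields(EnergyParams)}
        unknown = set(entry) - valid
        if unknown:
            raise SchemaError(f"{path}: unknown energy keys {sorted(unknown)}")
        params = EnergyParams(**entry)
    unknown = set(raw) - _THRESHOLD_KEYS
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(site=site, params=params, **raw)
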