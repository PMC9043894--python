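"""CSV / YAML input-output with provenance headers.

All tabular artifacts are plain CSV.  Output files start with ``#``
comment lines carrying provenance (seed, config hash, stage); readers
skip them.  Times are serialized with enough digits to keep the sub-day
sampling points exact on round trip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .simulate import MEASUREMENT_COLUMNS

__all__ = [
    "MeasurementFormatError",
    "read_measurements",
    "write_measurements",
    "write_table",
    "read_table_meta",
    "config_hash",
    "write_yaml",
    "read_yaml",
]

_FLOAT_FORMAT = "%.10g"
_KEY_COLS = ["condition_id", "replicate", "time_days"]


class MeasurementFormatError(ValueError):
    """A measurement CSV violates the table contract."""


def config_hash(obj: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(obj, sort_keys=True, separators=(",", ":"))
    return hashlib.sha1(blob.encode("utf-8")).hexdigest()[:12]


def write_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a CSV with leading ``# key: value`` provenance lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FORMAT)


def read_table_meta(path) -> dict:
    """Parse the leading ``# key: value`` comment lines of a CSV."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return meta


def write_measurements(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(table[MEASUREMENT_COLUMNS], path, meta)


def _fail(msg: str) -> None:
    raise MeasurementFormatError(msg)


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV.

    Checks column presence, numeric types, key uniqueness, and value
    ranges; error messages include 1-based data row numbers.  Rows are
    returned sorted by (condition_id, replicate, time_days).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        _fail(f"{path}: cannot parse CSV: {exc}")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        _fail(f"{path}: missing required columns: {', '.join(missing)}")
    df = df[MEASUREMENT_COLUMNS].copy()
    for col in ("temperature_C", "water_content_pct", "time_days",
                "concentration_ng_per_g"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 1
        if len(bad):
            _fail(f"{path}: non-numeric {col} in row(s) {list(bad[:5])}")
        if coerced.isna().any():
            _fail(f"{path}: missing {col} in row(s) "
                  f"{list((df.index[coerced.isna()] + 1)[:5])}")
        df[col] = coerced.astype(float)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    if df["replicate"].isna().any() or (df["replicate"] % 1 != 0).any():
        _fail(f"{path}: replicate must be an integer")
    df["replicate"] = df["replicate"].astype(int)
    if df["sterilized"].dtype != bool:
        mapping = {"true": True, "false": False, "1": True, "0": False}
        df["sterilized"] = (
            df["sterilized"].astype(str).str.strip().str.lower().map(mapping)
        )
        if df["sterilized"].isna().any():
            _fail(f"{path}: sterilized must be boolean")
        df["sterilized"] = df["sterilized"].astype(bool)

    neg = df.index[df["concentration_ng_per_g"] < 0] + 1
    if len(neg):
        _fail(f"{path}: negative concentration in row(s) {list(neg[:5])}")
    neg_t = df.index[df["time_days"] < 0] + 1
    if len(neg_t):
        _fail(f"{path}: negative time in row(s) {list(neg_t[:5])}")
    dup = df.duplicated(subset=_KEY_COLS, keep=False)
    if dup.any():
        first = df.loc[dup, _KEY_COLS].iloc[0]
        _fail(
            f"{path}: duplicate (condition, replicate, time) key "
            f"{tuple(first)} in row(s) {list((df.index[dup] + 1)[:5])}"
        )
    return df.sort_values(_KEY_COLS, kind="mergesort").reset_index(drop=True)
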