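"""Reading and writing cohort tables, brain maps, and result artifacts.

Canonical on-disk dialect is TSV with a header row (commas are autodetected
on read). Sex is stored as the strings ``male`` / ``female``; numeric
encodings are applied only when design matrices are built, because the two
modelling stages use opposite binary conventions. Missing disease duration
and missing SAA status are preserved as missing, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .regions import RegionRegistry, default_registry
from .synthetic import PARTICIPANT_COLUMNS

MANDATORY_COLUMNS = (
    "participant_id",
    "group",
    "pd_diagnosis",
    "lrrk2_carrier",
    "age",
    "sex",
    "site",
)


class SchemaError(ValueError):
    """A table violated the participant or morphometry schema."""


def _read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "," if header.count(",") > header.count("\t") else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col)


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read and validate a participant table.

    Raises :class:`SchemaError` with row/column context for missing
    mandatory columns, duplicate ids, or invariant violations (a PD
    participant must carry a disease duration; a non-PD participant must
    not).
    """
    df = _read_table(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    dup = df["participant_id"][df["participant_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate participant_id: {dup.iloc[0]!r}")
    for col in ("pd_diagnosis", "lrrk2_carrier"):
        vals = set(pd.unique(df[col].dropna()))
        if not vals <= {0, 1}:
            raise SchemaError(f"column {col!r} must be binary 0/1, got {sorted(vals)}")
    bad_sex = set(df["sex"].dropna()) - {"male", "female"}
    if bad_sex:
        raise SchemaError(f"column 'sex' must be 'male'/'female', got {sorted(bad_sex)}")
    if (df["age"] <= 0).any():
        i = int(np.argmax(df["age"].to_numpy() <= 0))
        raise SchemaError(f"row {i}: age must be > 0")
    if "disease_duration" in df.columns:
        dur_missing = df["disease_duration"].isna()
        bad = (df["pd_diagnosis"] == 1) & dur_missing
        if bad.any():
            rid = df.loc[bad, "participant_id"].iloc[0]
            raise SchemaError(
                f"participant {rid!r}: pd_diagnosis=1 requires a disease_duration"
            )
        bad = (df["pd_diagnosis"] == 0) & ~dur_missing
        if bad.any():
            rid = df.loc[bad, "participant_id"].iloc[0]
            raise SchemaError(
                f"participant {rid!r}: disease_duration must be missing when pd_diagnosis=0"
            )
    if "saa_status" in df.columns:
        bad = set(df["saa_status"].dropna()) - {"positive", "negative", "missing"}
        if bad:
            raise SchemaError(f"column 'saa_status': invalid value(s) {sorted(bad)}")
    return df


def write_participants(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_morphometry(path: str | Path, registry: RegionRegistry | None = None) -> pd.DataFrame:
    """Read a wide morphometry table; column order normalized to registry order."""
    registry = registry or default_registry()
    df = _read_table(path, index_col="participant_id")
    have = set(df.columns)
    want = set(registry.names)
    absent = sorted(want - have)
    extra = sorted(have - want)
    if absent or extra:
        parts = []
        if absent:
            parts.append(f"missing region column(s): {', '.join(absent)}")
        if extra:
            parts.append(f"unexpected column(s): {', '.join(extra)}")
        raise SchemaError("; ".join(parts))
    df = df[registry.names]
    if (df.to_numpy() <= 0).any():
        bad = df.columns[(df.to_numpy() <= 0).any(axis=0)][0]
        raise SchemaError(f"non-positive morphometry value in column {bad!r}")
    if df.index.duplicated().any():
        raise SchemaError(f"duplicate participant_id: {df.index[df.index.duplicated()][0]!r}")
    return df


def write_morphometry(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True, index_label="participant_id", float_format="%.10g")


def read_brain_map(path: str | Path) -> pd.Series:
    df = _read_table(path)
    if list(df.columns[:2]) != ["region", "value"]:
        raise SchemaError("brain map file must have columns: region, value")
    return pd.Series(df["value"].to_numpy(float), index=df["region"], name="value")


def write_brain_map(values: pd.Series, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame({"region": values.index, "value": values.to_numpy(float)})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_results(outdir: str | Path, artifacts: Mapping[str, Any]) -> dict:
    """Write a dict of result artifacts and return a manifest.

    Artifact values are dispatched on type: a ``pd.Series`` becomes a
    region/value TSV brain map, a ``pd.DataFrame`` a TSV table, and any
    JSON-serializable object (dataclasses included) a JSON file. The
    manifest lists every file written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, obj in artifacts.items():
        if isinstance(obj, pd.Series):
            fname = f"{name}.tsv"
            write_brain_map(obj, outdir / fname)
        elif isinstance(obj, pd.DataFrame):
            fname = f"{name}.tsv"
            obj.to_csv(outdir / fname, sep="\t", float_format="%.17g")
        else:
            fname = f"{name}.json"
            write_json(obj, outdir / fname)
        manifest[name] = fname
    write_json(manifest, outdir / "manifest.json")
    return manifest
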