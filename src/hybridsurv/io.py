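"""CSV schemas and validated readers/writers for the pipeline artifacts.

Detection tables emulate automated-telemetry exports: one row per detection
with ``bird_id, station_id, lat, lon, days_since_tag``.  Trait tables carry
one row per bird (unique ``bird_id``) with release metadata, morphology,
ancestry and heterozygosity; empty cells are missing values.  All files are
UTF-8 CSV with dot decimal separators, written to full float precision so a
write -> read round trip is the identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DETECTION_COLUMNS",
    "TRAIT_COLUMNS",
    "read_detections",
    "write_detections",
    "read_traits",
    "write_traits",
    "write_labels",
]

DETECTION_COLUMNS = ("bird_id", "station_id", "lat", "lon", "days_since_tag")

TRAIT_COLUMNS = (
    "bird_id", "release_year", "release_day", "release_lat", "release_lon",
    "sex", "ancestry", "heterozygosity", "wing_chord", "kipps", "distal",
    "p7", "p8", "p9", "p10", "tail", "tarsus", "weight",
)

#: Behavioural columns the simulator adds (derived from detections otherwise).
OPTIONAL_TRAIT_COLUMNS = ("fall_bearing", "fall_timing", "hybrid_class", "survived_true")


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns: {missing}")


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, DETECTION_COLUMNS, "detection table")
    for col in ("lat", "lon", "days_since_tag"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"detection table: non-numeric {col!r} at row {int(np.flatnonzero(bad)[0]) + 2}"
            )
        df[col] = pd.to_numeric(df[col])
    if (df["days_since_tag"] < 0).any():
        row = int(df.index[df["days_since_tag"] < 0][0]) + 2
        raise SchemaError(f"detection table: negative days_since_tag at row {row}")
    if ((df["lat"] < -90) | (df["lat"] > 90)).any() or ((df["lon"] < -180) | (df["lon"] > 180)).any():
        raise SchemaError("detection table: coordinates out of range")
    return df


def write_detections(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _require_columns(df, DETECTION_COLUMNS, "detection table")
    _write_with_header(df[list(DETECTION_COLUMNS)], path, seed)


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, TRAIT_COLUMNS, "trait table")
    if df["bird_id"].duplicated().any():
        dup = df.loc[df["bird_id"].duplicated(), "bird_id"].iloc[0]
        raise SchemaError(f"trait table: duplicate bird_id {dup!r}")
    numeric = [c for c in df.columns if c not in ("bird_id", "hybrid_class")]
    for col in numeric:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"trait table: non-numeric {col!r} at row {int(np.flatnonzero(bad)[0]) + 2}"
            )
        df[col] = pd.to_numeric(df[col])
    return df


def write_traits(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _require_columns(df, TRAIT_COLUMNS, "trait table")
    cols = list(TRAIT_COLUMNS) + [c for c in OPTIONAL_TRAIT_COLUMNS if c in df.columns]
    _write_with_header(df[cols], path, seed)


def write_labels(df: pd.DataFrame, path, seed: int | None = None) -> None:
    _require_columns(df, ("bird_id", "overall_survival_prob", "label"), "label table")
    _write_with_header(df, path, seed)


def _write_with_header(df: pd.DataFrame, path, seed: int | None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")
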