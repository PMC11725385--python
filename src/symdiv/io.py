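"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV (tab-delimited, UTF-8, Unix newlines) with samples as
rows and variants/DIV columns as columns; the profile registry is JSON.
Writers emit deterministic column order so identical inputs yield
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .div_overlay import (
    CollapsedCountTable,
    DIVProfile,
    DominantAssignment,
    ProfileRegistry,
    VariantCountTable,
    parse_profile_name,
)
from .diversity import DistanceMatrix
from .survival import KMCurve, SurvivalRecord, records_to_frame

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_registry",
    "write_registry",
    "read_survival",
    "write_survival",
    "read_dominant_assignments",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_km_curve",
]


class TableFormatError(ValueError):
    """A malformed cell or header in a TSV input, located by row/column."""


def read_count_table(path) -> VariantCountTable:
    """Read a samples x variants TSV with a leading ``sample_id`` column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise TableFormatError(f"{path}: first column must be 'sample_id'")
    df = df.set_index("sample_id")
    if df.isna().any().any():
        raise TableFormatError(f"{path}: ragged rows or missing cells")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            out[col] = df[col].astype(np.int64)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           | (pd.to_numeric(df[col], errors="coerce") % 1 != 0)]
            row = bad[0] if len(bad) else "?"
            raise TableFormatError(
                f"{path}: non-integer count at row {row!r}, column {col!r}"
            ) from None
    return VariantCountTable(data=out)


def write_count_table(table, path) -> None:
    """Write a VariantCountTable or CollapsedCountTable as TSV."""
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "treatment", "family", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing metadata columns {sorted(missing)}")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        raise TableFormatError(f"{path}: duplicate sample ids")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", lineterminator="\n")


def read_registry(path) -> ProfileRegistry:
    """Read the profile registry JSON, validating names against members."""
    with open(path) as fh:
        obj = json.load(fh)
    if "profiles" not in obj:
        raise TableFormatError(f"{path}: missing 'profiles' field")
    profiles = []
    for rec in obj["profiles"]:
        if "name" not in rec or "members" not in rec:
            raise TableFormatError(f"{path}: profile record missing name/members")
        members = tuple(rec["members"])
        if list(members) != parse_profile_name(rec["name"]):
            raise TableFormatError(
                f"{path}: profile name {rec['name']!r} inconsistent with members"
            )
        profiles.append(DIVProfile(name=rec["name"], members=members))
    if not profiles:
        import warnings

        warnings.warn(f"{path}: registry has no profiles")
    return ProfileRegistry(
        profiles=tuple(profiles),
        background_read_threshold=int(obj.get("background_read_threshold", 200)),
        low_depth_threshold=int(obj.get("low_depth_threshold", 1000)),
    )


def write_registry(registry: ProfileRegistry, path) -> None:
    obj = {
        "profiles": [
            {"name": p.name, "members": list(p.members)} for p in registry.profiles
        ],
        "background_read_threshold": registry.background_read_threshold,
        "low_depth_threshold": registry.low_depth_threshold,
    }
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def read_survival(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"individual_id", "stage", "treatment", "family", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing survival columns {sorted(missing)}")
    return [
        SurvivalRecord(
            individual_id=str(r.individual_id),
            stage=str(r.stage),
            treatment=str(r.treatment),
            family=str(r.family),
            time=float(r.time_days),
            event=int(r.event),
        )
        for r in df.itertuples()
    ]


def write_survival(records: list[SurvivalRecord], path) -> None:
    records_to_frame(records).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_dominant_assignments(path) -> DominantAssignment:
    """Externally supplied dominance: 2-column TSV (sample_id, profile)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "profile"]:
        raise TableFormatError(
            f"{path}: expected columns 'sample_id', 'profile'"
        )
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        raise TableFormatError(f"{path}: duplicate sample ids")
    out = pd.DataFrame(
        {
            "profile": df["profile"],
            "status": "assigned",
            "low_depth": False,
        }
    )
    return DominantAssignment(table=out)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.as_frame().rename_axis("sample_id").to_csv(
        path, sep="\t", lineterminator="\n"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(
        ids=tuple(str(i) for i in df.index), matrix=df.to_numpy(dtype=float)
    )


def write_km_curve(curve: KMCurve, path) -> None:
    curve.as_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")
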