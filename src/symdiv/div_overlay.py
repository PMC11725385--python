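"""Hybrid DIV-profile overlay for ITS2 amplicon count tables.

Symbiodiniaceae genomes carry multiple distinct ITS2 copies, so a single
symbiont taxon shows up in an amplicon table as a family of co-occurring
sequence variants (a "DIV profile", e.g. ``C15-C15dq-C15dr-C_1365``).
Diversity statistics computed on raw variant columns therefore over-count
taxa. This module collapses the member variants of each sample's dominant
profile into one column while retaining every other variant — including
rare background variants that profile-calling pipelines would discard — so
that low-abundance taxa remain observable across a time series.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantCountTable",
    "DIVProfile",
    "ProfileRegistry",
    "DominantAssignment",
    "CollapsedCountTable",
    "parse_profile_name",
    "build_registry",
    "assign_dominant_profile",
    "collapse_to_div",
    "infer_cooccurring_profiles",
]

PROFILE_DELIMITER = "-"

#: column-kind labels for CollapsedCountTable
KIND_DIV = "DIV"
KIND_VARIANT = "variant"
KIND_BACKGROUND = "background"


class ProfileNameError(ValueError):
    """Raised for malformed dash-delimited profile names."""


@dataclass(frozen=True)
class VariantCountTable:
    """Samples x sequence-variant integer read counts.

    ``data`` is a pandas DataFrame with sample ids as the index and variant
    names as columns; cells are non-negative integer read counts.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValueError("count table needs at least one sample and one variant")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate variant ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def row_totals(self) -> pd.Series:
        return self.data.sum(axis=1)


@dataclass(frozen=True)
class DIVProfile:
    """A named, ordered set of ITS2 variants residing in one genome."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ProfileNameError("profile has no members")
        if len(set(self.members)) != len(self.members):
            raise ProfileNameError(f"duplicate members in profile {self.name!r}")
        expected = PROFILE_DELIMITER.join(self.members)
        if self.name != expected:
            raise ProfileNameError(
                f"profile name {self.name!r} does not equal joined members {expected!r}"
            )

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def contains(self, other: "DIVProfile") -> bool:
        """Member-set containment: does this profile include all of *other*?"""
        return other.member_set <= self.member_set


@dataclass(frozen=True)
class ProfileRegistry:
    """Registered DIV profiles plus the dataset-level thresholds.

    ``background_read_threshold``: columns whose dataset-wide total is at or
    below this many reads are labelled background (never removed).
    ``low_depth_threshold``: samples below this total read count are flagged.
    """

    profiles: tuple[DIVProfile, ...]
    background_read_threshold: int = 200
    low_depth_threshold: int = 1000

    def __post_init__(self) -> None:
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate profile names in registry")
        if self.background_read_threshold < 0 or self.low_depth_threshold < 0:
            raise ValueError("thresholds must be >= 0")

    def __len__(self) -> int:
        return len(self.profiles)

    def get(self, name: str) -> DIVProfile:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.profiles]

    def member_variants(self) -> set[str]:
        """Union of member variants over all registered profiles."""
        out: set[str] = set()
        for p in self.profiles:
            out |= p.member_set
        return out

    def containment_pairs(self) -> list[tuple[str, str]]:
        """All ordered pairs (inner, outer) with inner ⊂ outer by member set."""
        pairs = []
        for a, b in itertools.permutations(self.profiles, 2):
            if a.member_set < b.member_set:
                pairs.append((a.name, b.name))
        return pairs


#: per-sample assignment statuses
STATUS_ASSIGNED = "assigned"
STATUS_FALLBACK = "singleton_fallback"
STATUS_UNASSIGNABLE = "unassignable"


@dataclass(frozen=True)
class DominantAssignment:
    """Dominant DIV profile per sample.

    ``table`` has one row per sample with columns ``profile`` (profile name,
    or the variant name of a singleton fallback; empty string if
    unassignable), ``status`` and ``low_depth`` (bool).
    """

    table: pd.DataFrame

    def profile_of(self, sample_id: str) -> str:
        return self.table.loc[sample_id, "profile"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class CollapsedCountTable:
    """Samples x (DIV columns + retained variant columns) after the overlay."""

    data: pd.DataFrame
    column_kind: pd.Series = field(repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.data.columns)

    def row_totals(self) -> pd.Series:
        return self.data.sum(axis=1)


def parse_profile_name(name: str) -> list[str]:
    """Split a dash-delimited DIV profile name into its ordered members.

    Variant names may contain underscores (``C_1365``) but never dashes, so
    ``"C15-C15dq-C15dr-C_1365"`` -> ``["C15", "C15dq", "C15dr", "C_1365"]``.
    """
    if not isinstance(name, str) or not name:
        raise ProfileNameError("profile name must be a nonempty string")
    tokens = name.split(PROFILE_DELIMITER)
    if any(t == "" for t in tokens):
        raise ProfileNameError(f"empty member token in profile name {name!r}")
    return tokens


def build_registry(
    profile_names: list[str],
    background_read_threshold: int = 200,
    low_depth_threshold: int = 1000,
) -> ProfileRegistry:
    """Parse profile names into a registry with queryable nesting relations."""
    profiles = tuple(
        DIVProfile(name=n, members=tuple(parse_profile_name(n))) for n in profile_names
    )
    return ProfileRegistry(
        profiles=profiles,
        background_read_threshold=background_read_threshold,
        low_depth_threshold=low_depth_threshold,
    )


def _detected_members(
    row: pd.Series, member_variants: set[str], detection_fraction: float
) -> set[str]:
    present = [v for v in member_variants if v in row.index]
    family_total = float(row[present].sum()) if present else 0.0
    if family_total <= 0:
        return set()
    thresh = detection_fraction * family_total
    return {v for v in present if row[v] >= thresh and row[v] > 0}


def assign_dominant_profile(
    table: VariantCountTable,
    registry: ProfileRegistry,
    detection_fraction: float = 0.01,
) -> DominantAssignment:
    """Assign each sample the longest registered profile it fully exhibits.

    A member variant counts as *detected* in a sample when its reads are at
    least ``detection_fraction`` of the summed reads over all registry member
    variants in that sample (relative detection: a sample can be dominated by
    bare C15 while carrying trace C15dq reads that stay below the cutoff and
    are retained as an individual column downstream). Among profiles whose
    every member is detected, the one with the most members wins; ties break
    by larger summed member count, then lexicographically smaller name. A
    sample exhibiting no registered profile falls back to the singleton of
    its most abundant variant and is flagged.
    """
    if not 0 <= detection_fraction < 1:
        raise ValueError("detection_fraction must be in [0, 1)")
    member_variants = registry.member_variants()
    rows = []
    for sid in table.sample_ids:
        row = table.data.loc[sid]
        total = int(row.sum())
        low_depth = total < registry.low_depth_threshold
        if total == 0:
            rows.append((sid, "", STATUS_UNASSIGNABLE, low_depth))
            continue
        detected = _detected_members(row, member_variants, detection_fraction)
        candidates = [p for p in registry.profiles if p.member_set <= detected]
        if candidates:
            def sort_key(p: DIVProfile):
                summed = int(row[[m for m in p.members if m in row.index]].sum())
                return (-len(p.members), -summed, p.name)

            best = min(candidates, key=sort_key)
            rows.append((sid, best.name, STATUS_ASSIGNED, low_depth))
        else:
            top = row.idxmax()
            rows.append((sid, str(top), STATUS_FALLBACK, low_depth))
    out = pd.DataFrame(
        rows, columns=["sample_id", "profile", "status", "low_depth"]
    ).set_index("sample_id")
    return DominantAssignment(table=out)


def collapse_to_div(
    table: VariantCountTable,
    registry: ProfileRegistry,
    assignment: DominantAssignment,
) -> CollapsedCountTable:
    """Collapse each sample's dominant-profile members into one DIV column.

    For each sample the reads of the member variants of *its* dominant
    profile are summed into a column named by that profile. Member variants
    outside the sample's dominant profile, and all non-member variants
    (including rare background ones), keep their reads in individual
    columns. Per-sample totals are conserved exactly. Columns whose
    dataset-wide total is at or below ``registry.background_read_threshold``
    are labelled background but never removed.
    """
    missing = set(table.sample_ids) - set(assignment.sample_ids)
    if missing:
        raise ValueError(f"assignment does not cover samples: {sorted(missing)}")
    variant_cols = table.variant_ids
    known = set(variant_cols)

    # DIV columns: registered profiles used as a dominant assignment whose
    # name is not already a variant column (singleton fallbacks and
    # single-member registered profiles collapse in place).
    used = set()
    for sid in table.sample_ids:
        rec = assignment.table.loc[sid]
        if rec["status"] == STATUS_UNASSIGNABLE:
            continue
        name = rec["profile"]
        if rec["status"] == STATUS_ASSIGNED:
            used.add(name)
        elif name not in known:
            raise ValueError(f"assignment references unknown profile/variant {name!r}")
    for name in used:
        registry.get(name)  # KeyError -> unknown profile
    new_cols = [n for n in registry.names if n in used and n not in known]
    out_cols = new_cols + variant_cols
    out = pd.DataFrame(
        np.zeros((len(table.sample_ids), len(out_cols)), dtype=np.int64),
        index=pd.Index(table.sample_ids, name=table.data.index.name),
        columns=out_cols,
    )
    out.loc[:, variant_cols] = table.data.to_numpy()
    for sid in table.sample_ids:
        rec = assignment.table.loc[sid]
        if rec["status"] != STATUS_ASSIGNED:
            continue  # fallback singletons stay in their own variant column
        profile = registry.get(rec["profile"])
        members = [m for m in profile.members if m in known]
        summed = int(out.loc[sid, members].sum())
        out.loc[sid, members] = 0
        out.loc[sid, profile.name] = out.loc[sid, profile.name] + summed

    totals = out.sum(axis=0)
    kinds = {}
    div_names = set(new_cols) | (used & known)
    for col in out_cols:
        if col in div_names:
            kinds[col] = KIND_DIV
        elif totals[col] <= registry.background_read_threshold:
            kinds[col] = KIND_BACKGROUND
        else:
            kinds[col] = KIND_VARIANT
    return CollapsedCountTable(data=out, column_kind=pd.Series(kinds)[out_cols])


def infer_cooccurring_profiles(
    table: VariantCountTable,
    codetection_jaccard_min: float = 0.9,
    background_read_threshold: int = 200,
    detection_fraction: float = 0.01,
) -> ProfileRegistry:
    """Greedy co-occurrence clustering of variants into candidate profiles.

    A simplified emulation of profile discovery from co-detection patterns:
    variants with a dataset-wide total at or below the read threshold are
    excluded from seeding; the rest are scanned in descending mean relative
    abundance, and a variant joins the profile under construction when the
    Jaccard similarity of its per-sample detection vector (detected =
    relative abundance >= ``detection_fraction``) with *every* current
    member is at least the cutoff. Candidate profile names join members by
    "-" in descending mean relative abundance.
    """
    n = len(table.sample_ids)
    if n == 0:
        raise ValueError("empty table")
    if n < 5:
        warnings.warn("co-occurrence inference is unreliable below 5 samples")
    rel = table.data.div(table.row_totals().replace(0, np.nan), axis=0).fillna(0.0)
    detected = rel >= detection_fraction
    totals = table.data.sum(axis=0)
    seeds = [v for v in table.variant_ids if totals[v] > background_read_threshold]
    order = sorted(seeds, key=lambda v: (-rel[v].mean(), v))

    def jaccard(a: str, b: str) -> float:
        da, db = detected[a].to_numpy(), detected[b].to_numpy()
        union = np.logical_or(da, db).sum()
        if union == 0:
            return 0.0
        return np.logical_and(da, db).sum() / union

    unassigned = list(order)
    profiles: list[DIVProfile] = []
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed]
        for v in list(unassigned):
            if all(jaccard(v, m) >= codetection_jaccard_min for m in members):
                members.append(v)
                unassigned.remove(v)
        members.sort(key=lambda v: (-rel[v].mean(), v))
        profiles.append(
            DIVProfile(name=PROFILE_DELIMITER.join(members), members=tuple(members))
        )
    return ProfileRegistry(
        profiles=tuple(profiles),
        background_read_threshold=background_read_threshold,
    )
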