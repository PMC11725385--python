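"""Synthetic coral symbiont communities and survival monitoring records.

The generator emulates the statistical structure of ITS2 amplicon data
from coral early life stages hosting a single dominant Cladocopium DIV
profile: every sample carries a nested family of intragenomic variants
(C15, C15dq, C15dr, C_1365) at fixed host-fraction proportions plus a
small pool of background variants from other Symbiodiniaceae genera
(*Symbiodinium* A, *Breviolum* B, *Durusdinium* D, *Fugacium* F and extra
*Cladocopium* C) totalling a few percent of reads. Heat stress expands the
background pool in larvae (multiplicatively on its expected relative
abundance) but not in juveniles. Compositions are drawn from a Dirichlet
around the expected relative abundances (overdispersion controlled by a
single concentration parameter) and read counts multinomially at a
log-normal library size.

Survival is exponential per stage x treatment cell, parameterised by its
median, and observed only at scheduled monitoring visits: the recorded
event time is the first visit at or after the latent death time, or a
censoring at the final visit.

A single global seed drives independent community and survival substreams
so either can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .div_overlay import (
    PROFILE_DELIMITER,
    DIVProfile,
    ProfileRegistry,
    VariantCountTable,
)
from .survival import SurvivalRecord

__all__ = [
    "CommunityConfig",
    "SurvivalConfig",
    "DEFAULT_DESIGN",
    "generate_profile_library",
    "generate_community_counts",
    "generate_survival_records",
    "generate_study_bundle",
]

#: dominant-profile members as fractions of the host-profile read share
DEFAULT_DOMINANT_MEMBERS = (
    ("C15", 0.70),
    ("C15dq", 0.15),
    ("C15dr", 0.10),
    ("C_1365", 0.05),
)

#: (variant, genus, baseline relative abundance); totals 3% at baseline
DEFAULT_BACKGROUND_VARIANTS = (
    ("A1", "Symbiodinium", 0.00375),
    ("A4", "Symbiodinium", 0.00375),
    ("B1", "Breviolum", 0.00375),
    ("B19", "Breviolum", 0.00375),
    ("D1", "Durusdinium", 0.00375),
    ("F1", "Fugacium", 0.00375),
    ("C3", "Cladocopium", 0.00375),
    ("C50", "Cladocopium", 0.00375),
)


@dataclass(frozen=True)
class CommunityConfig:
    """Expected community structure and sampling noise for the simulator.

    ``heat_background_multiplier_*`` scale the expected background
    relative abundance under heat; larvae default to an 8-fold expansion,
    juveniles to no change. ``dirichlet_concentration`` controls
    compositional overdispersion (larger = tighter around the expectation).
    Library sizes are log-normal (log-scale mean/sd of read counts).
    """

    dominant_profile_members: tuple[tuple[str, float], ...] = DEFAULT_DOMINANT_MEMBERS
    background_variants: tuple[tuple[str, str, float], ...] = (
        DEFAULT_BACKGROUND_VARIANTS
    )
    heat_background_multiplier_larva: float = 8.0
    heat_background_multiplier_juvenile: float = 1.0
    dirichlet_concentration: float = 100.0
    library_size_log_mean: float = float(np.log(5000.0))
    library_size_log_sd: float = 0.4
    n_per_group: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        props = [p for _, p in self.dominant_profile_members]
        if not props or any(p <= 0 or p >= 1 for p in props):
            raise ValueError("dominant proportions must lie in (0, 1)")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("dominant proportions must sum to 1")
        bg = [b for _, _, b in self.background_variants]
        if any(b <= 0 or b >= 1 for b in bg):
            raise ValueError("background abundances must lie in (0, 1)")
        if sum(bg) >= 1 - sum(bg):
            raise ValueError("baseline background must stay below the dominant total")
        for m in (
            self.heat_background_multiplier_larva,
            self.heat_background_multiplier_juvenile,
        ):
            if not np.isfinite(m) or m <= 0:
                raise ValueError("heat multipliers must be positive and finite")
        if not np.isfinite(self.dirichlet_concentration) or (
            self.dirichlet_concentration <= 0
        ):
            raise ValueError("dirichlet_concentration must be positive")
        if not np.isfinite(self.library_size_log_mean) or not np.isfinite(
            self.library_size_log_sd
        ):
            raise ValueError("library size parameters must be finite")

    def multiplier(self, stage: str, treatment: str) -> float:
        if treatment != "heat":
            return 1.0
        if stage == "larva":
            return self.heat_background_multiplier_larva
        if stage == "juvenile":
            return self.heat_background_multiplier_juvenile
        raise ValueError(f"unknown stage {stage!r}")

    def expected_abundances(self, stage: str, treatment: str) -> pd.Series:
        """Expected relative abundances per variant for one design cell."""
        mult = self.multiplier(stage, treatment)
        bg = {name: base * mult for name, _, base in self.background_variants}
        bg_total = sum(bg.values())
        if bg_total >= 1:
            raise ValueError("background expansion exceeds the whole community")
        dom = {
            name: prop * (1 - bg_total)
            for name, prop in self.dominant_profile_members
        }
        return pd.Series({**dom, **bg})

    @property
    def variant_names(self) -> list[str]:
        return [n for n, _ in self.dominant_profile_members] + [
            n for n, _, _ in self.background_variants
        ]


#: 21 larval monitoring visits over 0-57 d; 3 juvenile visits over 20 d
LARVA_SCHEDULE = tuple(int(round(d)) for d in np.linspace(0, 57, 21))
JUVENILE_SCHEDULE = (0, 10, 20)


@dataclass(frozen=True)
class SurvivalConfig:
    """Per-cell exponential survival medians and monitoring schedules.

    Heat medians follow the study system (~20 d for juveniles, ~57 d for
    larvae); ambient cells use a long 200 d median so that most ambient
    individuals are censored at the end of monitoring.
    """

    median_days: dict = field(
        default_factory=lambda: {
            ("larva", "heat"): 57.0,
            ("larva", "ambient"): 200.0,
            ("juvenile", "heat"): 20.0,
            ("juvenile", "ambient"): 200.0,
        }
    )
    monitoring_schedule: dict = field(
        default_factory=lambda: {
            "larva": LARVA_SCHEDULE,
            "juvenile": JUVENILE_SCHEDULE,
        }
    )
    n_individuals: dict = field(
        default_factory=lambda: {
            ("larva", "heat"): 192,
            ("larva", "ambient"): 192,
            ("juvenile", "heat"): 60,
            ("juvenile", "ambient"): 60,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cell, m in self.median_days.items():
            if not np.isfinite(m) or m <= 0:
                raise ValueError(f"median for {cell} must be positive")
        for stage, sched in self.monitoring_schedule.items():
            s = list(sched)
            if not s:
                raise ValueError(f"empty monitoring schedule for {stage!r}")
            if s[0] < 0 or any(b <= a for a, b in zip(s, s[1:])):
                raise ValueError(
                    f"schedule for {stage!r} must be strictly increasing, start >= 0"
                )


#: stage, treatment, family, timepoint, n — the study's bulk-culture design
DEFAULT_DESIGN = (
    ("larva", "ambient", "bulk", "end", 20),
    ("larva", "heat", "bulk", "end", 20),
    ("juvenile", "ambient", "bulk", "end", 20),
    ("juvenile", "heat", "bulk", "end", 20),
)


def _community_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 0]))


def _survival_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1]))


def generate_profile_library(
    member_names,
    proportions,
    background_variants=DEFAULT_BACKGROUND_VARIANTS,
    background_read_threshold: int = 200,
    low_depth_threshold: int = 1000,
) -> ProfileRegistry:
    """Registry of the nested prefix family plus background singletons.

    Each prefix of the ordered member list is registered as a profile, so
    members ``[C15, C15dq, C15dr, C_1365]`` yield the four overlapping
    profiles ``C15``, ``C15-C15dq``, ``C15-C15dq-C15dr`` and
    ``C15-C15dq-C15dr-C_1365``.
    """
    members = list(member_names)
    props = list(proportions)
    if not members:
        raise ValueError("member list is empty")
    if len(members) != len(props):
        raise ValueError("members and proportions differ in length")
    if any(p <= 0 for p in props):
        raise ValueError("proportions must be positive")
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    profiles = []
    for i in range(1, len(members) + 1):
        prefix = tuple(members[:i])
        profiles.append(
            DIVProfile(name=PROFILE_DELIMITER.join(prefix), members=prefix)
        )
    for name, _genus, _base in background_variants:
        profiles.append(DIVProfile(name=name, members=(name,)))
    return ProfileRegistry(
        profiles=tuple(profiles),
        background_read_threshold=background_read_threshold,
        low_depth_threshold=low_depth_threshold,
    )


def generate_community_counts(
    cfg: CommunityConfig, design=DEFAULT_DESIGN
) -> tuple[VariantCountTable, pd.DataFrame]:
    """Draw a variant count table and matching sample metadata.

    Per sample the realised composition is Dirichlet around the cell's
    expected relative abundances (concentration ``dirichlet_concentration``
    times the expectation) and counts are multinomial at a log-normal
    library size. Identical seeds give identical tables.
    """
    design = tuple(design)
    if not design:
        raise ValueError("empty design")
    rng = _community_rng(cfg.seed)
    variants = cfg.variant_names
    rows, meta_rows, sample_ids = [], [], []
    counter = 0
    for stage, treatment, family, timepoint, n in design:
        if n < 1:
            raise ValueError("design cell sizes must be >= 1")
        expect = cfg.expected_abundances(stage, treatment).reindex(variants)
        alpha = cfg.dirichlet_concentration * expect.to_numpy()
        for _ in range(n):
            counter += 1
            sid = f"S{counter:03d}"
            comp = rng.dirichlet(alpha)
            lib = max(
                1,
                int(
                    round(
                        rng.lognormal(
                            cfg.library_size_log_mean, cfg.library_size_log_sd
                        )
                    )
                ),
            )
            counts = rng.multinomial(lib, comp)
            rows.append(counts)
            sample_ids.append(sid)
            meta_rows.append((sid, stage, treatment, family, timepoint))
    table = VariantCountTable(
        data=pd.DataFrame(
            np.asarray(rows, dtype=np.int64),
            index=pd.Index(sample_ids, name="sample_id"),
            columns=variants,
        )
    )
    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "stage", "treatment", "family", "timepoint"],
    ).set_index("sample_id")
    return table, metadata


def generate_survival_records(cfg: SurvivalConfig) -> list[SurvivalRecord]:
    """Draw interval-monitored survival records for every design cell.

    Latent death times are exponential with rate ln(2)/median; the observed
    event time is the first monitoring visit at or after the latent time
    (event=1), or a censoring at the last visit (event=0).
    """
    rng = _survival_rng(cfg.seed)
    records: list[SurvivalRecord] = []
    counter = 0
    for (stage, treatment), median in sorted(cfg.median_days.items()):
        n = cfg.n_individuals.get((stage, treatment), 0)
        if n < 1:
            continue
        schedule = np.asarray(cfg.monitoring_schedule[stage], dtype=float)
        rate = np.log(2.0) / median
        latent = rng.exponential(1.0 / rate, size=n)
        for t in latent:
            counter += 1
            idx = np.searchsorted(schedule, t, side="left")
            if idx >= len(schedule):
                time, event = float(schedule[-1]), 0
            else:
                time, event = float(schedule[idx]), 1
            records.append(
                SurvivalRecord(
                    individual_id=f"I{counter:04d}",
                    stage=stage,
                    treatment=treatment,
                    family="bulk",
                    time=time,
                    event=event,
                )
            )
    return records


def generate_study_bundle(
    community_cfg: CommunityConfig,
    survival_cfg: SurvivalConfig,
    out_dir,
    design=DEFAULT_DESIGN,
) -> dict:
    """Write counts.tsv, metadata.tsv, registry.json and survival.tsv.

    The files round-trip losslessly through the package readers; two runs
    with the same configs produce byte-identical files.
    """
    from . import io as sio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, metadata = generate_community_counts(community_cfg, design)
    registry = generate_profile_library(
        [n for n, _ in community_cfg.dominant_profile_members],
        [p for _, p in community_cfg.dominant_profile_members],
        background_variants=community_cfg.background_variants,
    )
    records = generate_survival_records(survival_cfg)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "registry": out / "registry.json",
        "survival": out / "survival.tsv",
    }
    sio.write_count_table(table, paths["counts"])
    sio.write_metadata(metadata, paths["metadata"])
    sio.write_registry(registry, paths["registry"])
    sio.write_survival(records, paths["survival"])
    return {
        "paths": paths,
        "table": table,
        "metadata": metadata,
        "registry": registry,
        "records": records,
    }
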