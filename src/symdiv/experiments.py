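"""Seeded simulation experiments: calibration, power and recovery checks.

These drive the full pipeline (simulate -> collapse -> diversity/survival)
over many replicate synthetic datasets to measure its operating
characteristics: type-I error of the treatment tests under a null
generator, power to recover the planted larval community shift, the
juvenile no-effect control, Kaplan-Meier median calibration against the
configured hazards, beta-regression parameter recovery, and recovery of
the planted DIV profile from co-occurrence patterns.
"""

from __future__ import annotations

import numpy as np

from . import diversity as dv
from .div_overlay import assign_dominant_profile, collapse_to_div, infer_cooccurring_profiles
from .survival import km_estimator, logrank_test
from .synthetic import (
    CommunityConfig,
    SurvivalConfig,
    generate_community_counts,
    generate_profile_library,
    generate_survival_records,
)

__all__ = [
    "run_alpha_beta_analysis",
    "null_calibration",
    "effect_recovery",
    "km_median_calibration",
    "beta_recovery",
    "cooccurrence_recovery",
    "logrank_power",
]


def _registry_for(cfg: CommunityConfig):
    return generate_profile_library(
        [n for n, _ in cfg.dominant_profile_members],
        [p for _, p in cfg.dominant_profile_members],
        background_variants=cfg.background_variants,
    )


def _design(stage: str, n_per_group: int):
    return (
        (stage, "ambient", "bulk", "end", n_per_group),
        (stage, "heat", "bulk", "end", n_per_group),
    )


def run_alpha_beta_analysis(
    cfg: CommunityConfig,
    design,
    n_perm: int = 999,
    seed: int = 0,
    run_permanova: bool = True,
) -> dict:
    """One full pass: simulate, collapse, alpha contrast, optional PERMANOVA.

    Returns per-treatment mean Shannon diversity, the Holm-adjusted
    heat-vs-ambient evenness contrast p-value, and the PERMANOVA p-value on
    Bray-Curtis distances of the collapsed table.
    """
    registry = _registry_for(cfg)
    table, metadata = generate_community_counts(cfg, design)
    assignment = assign_dominant_profile(table, registry)
    collapsed = collapse_to_div(table, registry, assignment)
    h = dv.shannon_per_sample(collapsed.data)
    y = dv.squeeze_to_unit_interval(
        h.to_numpy(), "evenness", s_total=collapsed.data.shape[1]
    )
    fit = dv.fit_beta_regression(y, metadata["treatment"])
    pairwise = dv.pairwise_group_tests(fit, seed=seed)
    row = pairwise[
        (pairwise.group1 == "ambient") & (pairwise.group2 == "heat")
    ].iloc[0]
    out = {
        "mean_shannon": h.groupby(metadata["treatment"]).mean().to_dict(),
        "alpha_p_adj": float(row["p_adj"]),
        "beta_converged": fit.converged,
    }
    if run_permanova:
        dm = dv.bray_curtis(collapsed.data)
        res = dv.permanova(
            dm, metadata["treatment"].to_numpy(), n_perm=n_perm, seed=seed
        )
        out["permanova_p"] = res.p_value
    return out


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def null_calibration(
    n_reps: int = 500,
    seed: int = 0,
    n_per_group: int = 20,
    n_perm: int = 999,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of PERMANOVA and the evenness heat contrast.

    The generator is run with no heat effect (background multiplier 1) so
    both treatment groups are exchangeable; rejection rates at level
    ``alpha`` should sit near ``alpha``.
    """
    seeds = _child_seeds(seed, n_reps)
    perm_rej = beta_rej = 0
    for s in seeds:
        cfg = CommunityConfig(seed=int(s), heat_background_multiplier_larva=1.0)
        res = run_alpha_beta_analysis(
            cfg, _design("larva", n_per_group), n_perm=n_perm, seed=int(s)
        )
        perm_rej += res["permanova_p"] <= alpha
        beta_rej += res["alpha_p_adj"] <= alpha
    return {
        "n_reps": n_reps,
        "permanova_rejection_rate": perm_rej / n_reps,
        "beta_rejection_rate": beta_rej / n_reps,
    }


def effect_recovery(
    n_runs: int = 100,
    seed: int = 0,
    stage: str = "larva",
    n_per_group: int = 20,
    alpha: float = 0.05,
) -> dict:
    """Power of the alpha-diversity contrast at simulator defaults.

    For larvae (8x background expansion under heat) the heat group's mean
    Shannon diversity should exceed ambient and the adjusted contrast
    should reject; for juveniles (multiplier 1) it should not.
    """
    seeds = _child_seeds(seed, n_runs)
    detected = rejected = 0
    for s in seeds:
        cfg = CommunityConfig(seed=int(s))
        res = run_alpha_beta_analysis(
            cfg, _design(stage, n_per_group), run_permanova=False
        )
        ms = res["mean_shannon"]
        reject = res["alpha_p_adj"] < alpha
        rejected += reject
        detected += reject and (ms["heat"] > ms["ambient"])
    return {
        "n_runs": n_runs,
        "detection_rate": detected / n_runs,
        "rejection_rate": rejected / n_runs,
    }


def km_median_calibration(seed: int = 1, n: int = 500) -> dict:
    """KM medians for heat-treated stages on dense daily monitoring grids.

    Simulates ``n`` individuals per heat cell at the packaged default
    hazards, monitored daily (to day 80 for juveniles, day 120 for larvae),
    and reports the fitted Kaplan-Meier median per stage.
    """
    cfg = SurvivalConfig(
        monitoring_schedule={
            "juvenile": tuple(range(81)),
            "larva": tuple(range(121)),
        },
        n_individuals={("juvenile", "heat"): n, ("larva", "heat"): n},
        seed=seed,
    )
    records = generate_survival_records(cfg)
    out = {}
    for stage in ("juvenile", "larva"):
        sub = [r for r in records if r.stage == stage]
        out[stage] = {
            "median_days": km_estimator(sub).median,
            "n": len(sub),
            "configured_median": cfg.median_days[(stage, "heat")],
        }
    return out


def beta_recovery(
    n_runs: int = 100,
    seed: int = 0,
    n: int = 200,
    phi: float = 30.0,
    beta_true=(-0.5, 0.8),
) -> dict:
    """Parameter recovery for beta regression on data from its own model."""
    seeds = _child_seeds(seed, n_runs)
    groups = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    eta = np.where(groups == "a", beta_true[0], beta_true[0] + beta_true[1])
    mu = 1.0 / (1.0 + np.exp(-eta))
    all_within = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        y = rng.beta(mu * phi, (1 - mu) * phi)
        y = np.clip(y, 1e-12, 1 - 1e-12)
        fit = dv.fit_beta_regression(y, groups)
        est = fit.coef.to_numpy()
        se = fit.se.to_numpy()
        if np.all(np.abs(est - np.asarray(beta_true)) <= 2 * se):
            all_within += 1
    return {"n_runs": n_runs, "coverage_rate": all_within / n_runs}


def cooccurrence_recovery(
    n_runs: int = 100, seed: int = 0, n_per_group: int = 20
) -> dict:
    """How often co-occurrence clustering recovers the planted DIV family."""
    seeds = _child_seeds(seed, n_runs)
    hits = 0
    for s in seeds:
        cfg = CommunityConfig(seed=int(s))
        table, _ = generate_community_counts(cfg, _design("larva", n_per_group))
        candidates = infer_cooccurring_profiles(table)
        planted = frozenset(n for n, _ in cfg.dominant_profile_members)
        hits += any(p.member_set == planted for p in candidates.profiles)
    return {"n_runs": n_runs, "recovery_rate": hits / n_runs}


def logrank_power(
    n_runs: int = 100, seed: int = 0, n_per_arm: int = 100, alpha: float = 0.05
) -> dict:
    """Power of the log-rank test for juvenile heat vs ambient survival."""
    seeds = _child_seeds(seed, n_runs)
    rejections = 0
    for s in seeds:
        cfg = SurvivalConfig(
            n_individuals={
                ("juvenile", "heat"): n_per_arm,
                ("juvenile", "ambient"): n_per_arm,
            },
            seed=int(s),
        )
        records = generate_survival_records(cfg)
        res = logrank_test(records, "treatment")
        rejections += res.p_value < alpha
    return {"n_runs": n_runs, "rejection_rate": rejections / n_runs}
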