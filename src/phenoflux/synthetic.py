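"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the screening study's design: 11 staggered
sub-experiments of 4 genotypes each sharing one reference cultivar, n = 8
plants per treatment, multiplicative batch effects on size variables,
10-s balance logs over six 12 h/12 h days whose day-phase loss rate is
piecewise-constant with genotype-specific breakpoints, and top-view images
with a blue background and a red 10 × 5 cm reference.  Every generator
returns a machine-readable truth record alongside the data.

Noise is phenomenological: multiplicative Gaussian variation on morphology
(default CV 10%), additive Gaussian reading noise on the balances (default
σ = 0.05 g, a 0.01 g-accuracy balance plus vibration).  A fixed seed makes
all outputs bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CONTROL, STRESS, BalanceLog, ExperimentDesign, PhotoperiodSchedule
from .transpiration import (
    NIGHT_H,
    SegmentedFit,
    TranspirationVariables,
    extract_daily_variables,
    interpolate_mass,
)


@dataclass(frozen=True)
class GenotypeProfile:
    """Planted ground truth for one genotype.

    Transpiration rates are mL per hour per gram of plant; breakpoints are
    hours after lights-on.  ``transp_group`` "A" marks the water-saving
    phenotype (earlier afternoon reduction, lower maximum rate).
    """

    name: str
    b1: float
    b2: float
    s1: float
    s2: float
    s3: float
    night_rate: float
    control_growth: float       # mean above-ground growth (g) under control
    inhibition: float           # fractional growth loss under stress
    shoot_proportion: float
    root_investment: bool
    performance_tier: int       # planted tier 1 (vigorous) .. 5 (poor)
    transp_group: str           # "A" | "B"

    def __post_init__(self) -> None:
        if not 0 < self.b1 < self.b2 < 12:
            raise ValueError("breakpoints must satisfy 0 < b1 < b2 < 12")
        if min(self.s1, self.s2, self.s3, self.night_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.inhibition < 1:
            raise ValueError("inhibition must be in [0, 1)")


@dataclass
class GeneratorConfig:
    n_sub_experiments: int = 11
    genotypes_per_subexp: int = 4
    replicates_per_treatment: int = 8
    morphology_cv: float = 0.10
    batch_range: tuple[float, float] = (0.8, 1.25)
    balance_noise_sd: float = 0.05
    reading_interval_s: float = 10.0
    n_days: int = 6
    lysimeter_plants_per_genotype: int = 3
    seed: int = 0


REFERENCE_NAME = "REF"

#: absolute-size morphology variables that batch effects multiply
SIZE_VARIABLES = [
    "whole_mass_start", "aboveground_growth", "root_fresh", "root_dry",
    "pseudostem_fresh", "pseudostem_dry", "leaf_fresh", "leaf_dry",
    "leafAreaTot", "leafWidthTot", "leafLengthTot", "canopy_area",
    "plantTranspTot",
]


def default_profiles(n: int = 26) -> list[GenotypeProfile]:
    """Deterministic library of genotype profiles (first is the reference).

    Half the panel belongs to transpiration group A (earlier reduction onset,
    lower maximum rate), half to group B; the pre-night closure fraction
    (1 − s3/s2 = 0.45) is planted equal across groups.  Growth parameters
    span five performance tiers bracketing the observed screening range
    (control means ≈ 7–53 g, inhibition ≈ 0.10–0.65).
    """
    profiles: list[GenotypeProfile] = []
    n_a = (n + 1) // 2
    growth_by_tier = {1: 46.0, 2: 41.0, 3: 30.0, 4: 21.0, 5: 12.0}
    inhib_by_tier = {1: 0.36, 2: 0.58, 3: 0.42, 4: 0.40, 5: 0.35}
    for i in range(n):
        group = "A" if i < n_a else "B"
        j = i if group == "A" else i - n_a
        if group == "A":
            b2 = 6.6 + 0.16 * j
            s2 = 0.036 + 0.0013 * j
        else:
            b2 = 9.2 + 0.14 * j
            s2 = 0.062 + 0.0018 * j
        b1 = 1.6 + 0.07 * j
        tier = (i % 5) + 1
        growth = growth_by_tier[tier] * (1.0 + 0.05 * ((j % 5) - 2))
        inhib = min(max(inhib_by_tier[tier] + 0.02 * ((j % 3) - 1), 0.05), 0.9)
        name = REFERENCE_NAME if i == 0 else f"G{group}{j:02d}"
        s2 = round(s2, 5)
        profiles.append(
            GenotypeProfile(
                name=name,
                b1=round(b1, 3),
                b2=round(b2, 3),
                s1=0.60 * s2,
                s2=s2,
                s3=0.55 * s2,      # closure fraction exactly 0.45, all genotypes
                night_rate=0.18 * s2,
                control_growth=round(growth, 2),
                inhibition=round(inhib, 3),
                shoot_proportion=round(0.58 + 0.01 * (i % 5), 3),
                root_investment=(tier == 1),
                performance_tier=tier,
                transp_group=group,
            )
        )
    return profiles


def make_design(
    config: GeneratorConfig, profiles: list[GenotypeProfile]
) -> ExperimentDesign:
    """Assign profiles to sub-experiments; the reference sits in every batch."""
    non_ref = [p.name for p in profiles if p.name != REFERENCE_NAME]
    subs = [f"SE{i + 1:02d}" for i in range(config.n_sub_experiments)]
    per_sub = config.genotypes_per_subexp - 1
    layout: dict[str, list[str]] = {}
    k = 0
    for sub in subs:
        others = [non_ref[(k + j) % len(non_ref)] for j in range(per_sub)]
        k += per_sub
        layout[sub] = [REFERENCE_NAME, *others]
    return ExperimentDesign(
        sub_experiments=subs,
        genotypes_per_subexp=layout,
        reference_genotype=REFERENCE_NAME,
        replicates_per_treatment=config.replicates_per_treatment,
    )


def gen_morphology(
    config: GeneratorConfig,
    profiles: list[GenotypeProfile] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-plant morphology table with planted treatment and batch effects.

    Stress multiplies above-ground growth by (1 − inhibition), reduces leaf
    area/width and relative water contents, and—for root-investment
    genotypes—shifts dry-mass allocation toward the roots.  One multiplicative
    batch factor per sub-experiment scales every absolute-size variable
    (ratios, being scale-free, are untouched), emulating batch-to-batch
    vigor differences that the reference-cultivar normalization removes.
    """
    profiles = profiles if profiles is not None else default_profiles()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    by_name = {p.name: p for p in profiles}
    design = make_design(config, profiles)
    lo, hi = config.batch_range
    batch_factors = {sub: float(rng.uniform(lo, hi)) for sub in design.sub_experiments}
    cv = config.morphology_cv

    def jitter(size=None):
        return 1.0 + cv * rng.standard_normal(size) if cv > 0 else (
            np.ones(size) if size else 1.0
        )

    rows = []
    plant_no = 0
    for sub in design.sub_experiments:
        for geno in design.genotypes_per_subexp[sub]:
            p = by_name[geno]
            for treatment in (CONTROL, STRESS):
                stress = treatment == STRESS
                for _ in range(config.replicates_per_treatment):
                    plant_no += 1
                    whole0 = 9.0 * jitter()
                    growth = p.control_growth * (1.0 - p.inhibition * stress) * jitter()
                    shoot0 = whole0 * p.shoot_proportion
                    shoot_final = shoot0 + growth
                    leaf_fresh = 0.62 * shoot_final
                    ps_fresh = shoot_final - leaf_fresh
                    rwc_shoot = 0.90 - 0.03 * stress
                    leaf_dry = leaf_fresh * (1.0 - rwc_shoot)
                    ps_dry = ps_fresh * (1.0 - rwc_shoot)
                    root_shoot = 0.32 * (1.5 if (stress and p.root_investment) else
                                         (1.05 if stress else 1.0)) * jitter()
                    root_dry = root_shoot * (leaf_dry + ps_dry)
                    rwc_root = 0.93 - 0.02 * stress
                    root_fresh = root_dry / (1.0 - rwc_root)
                    leaf_area = 28.0 * leaf_fresh * (0.75 if stress else 1.0) * jitter()
                    leaf_width = 0.9 * leaf_area ** 0.5 * (0.85 if stress else 1.0)
                    leaf_len = 2.2 * leaf_area ** 0.5
                    transp_tot = (9.0 * growth) * (0.8 if stress else 1.0) * jitter()
                    values = {
                        "whole_mass_start": whole0,
                        "aboveground_growth": growth,
                        "root_fresh": root_fresh,
                        "root_dry": root_dry,
                        "pseudostem_fresh": ps_fresh,
                        "pseudostem_dry": ps_dry,
                        "leaf_fresh": leaf_fresh,
                        "leaf_dry": leaf_dry,
                        "leafAreaTot": leaf_area,
                        "leafWidthTot": leaf_width,
                        "leafLengthTot": leaf_len,
                        "canopy_area": 0.8 * leaf_area,
                        "plantTranspTot": transp_tot,
                    }
                    f = batch_factors[sub]
                    values = {k: v * (f if k in SIZE_VARIABLES else 1.0)
                              for k, v in values.items()}
                    values["rwcLeaf"] = rwc_shoot
                    values["rwcRoot"] = rwc_root
                    values["rwcPlant"] = 1.0 - (root_dry + leaf_dry + ps_dry) / (
                        root_fresh + leaf_fresh + ps_fresh
                    )
                    values["rootShootRatioDry"] = root_shoot
                    rows.append(
                        {
                            "plant_id": f"P{plant_no:04d}",
                            "genotype": geno,
                            "sub_experiment": sub,
                            "treatment": treatment,
                            **{k: float(v) for k, v in values.items()},
                        }
                    )
    truth = {
        "batch_factors": batch_factors,
        "genotypes": {
            p.name: {
                "control_growth": p.control_growth,
                "inhibition": p.inhibition,
                "shoot_proportion": p.shoot_proportion,
                "root_investment": p.root_investment,
                "performance_tier": p.performance_tier,
            }
            for p in profiles
        },
    }
    return pd.DataFrame(rows), truth


def _rate_profile(profile: GenotypeProfile, t_in_day_h: np.ndarray) -> np.ndarray:
    """Planted loss rate (mL/h per g) at trial-local hours within one day."""
    r = np.full(t_in_day_h.shape, profile.night_rate)
    day = t_in_day_h < 12.0
    r[day & (t_in_day_h < profile.b1)] = profile.s1
    r[day & (t_in_day_h >= profile.b1) & (t_in_day_h < profile.b2)] = profile.s2
    r[day & (t_in_day_h >= profile.b2)] = profile.s3
    return r


def gen_balance_log(
    config: GeneratorConfig,
    profile: GenotypeProfile,
    mass_before: float,
    mass_after: float,
    plant_id: str | None = None,
    rng: np.random.Generator | None = None,
    start_weight: float = 500.0,
) -> tuple[BalanceLog, dict]:
    """Six-day 10-s weight trace with the profile's piecewise day rates.

    Day-phase loss rate is s1 on [0, b1), s2 on [b1, b2), s3 on [b2, 12) and
    the night rate on [12, 24), all scaled by the day's linearly interpolated
    plant mass; additive Gaussian reading noise on top.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    dt = config.reading_interval_s
    n = int(round(config.n_days * 86400.0 / dt))
    t_s = np.arange(n) * dt
    t_h = t_s / 3600.0
    day_idx = np.minimum((t_h // 24.0).astype(int) + 1, config.n_days)
    daily_mass = np.array(
        [interpolate_mass(d, mass_before, mass_after, config.n_days)
         for d in range(1, config.n_days + 1)]
    )
    # exact cumulative of the piecewise-constant rate: per-gram knots over one day
    knots = np.array([0.0, profile.b1, profile.b2, 12.0, 24.0])
    seg_rates = np.array([profile.s1, profile.s2, profile.s3, profile.night_rate])
    knot_cum = np.concatenate([[0.0], np.cumsum(seg_rates * np.diff(knots))])
    day_total_per_g = knot_cum[-1]
    within = np.interp(t_h % 24.0, knots, knot_cum) * daily_mass[day_idx - 1]
    prior = np.concatenate([[0.0], np.cumsum(daily_mass)])[day_idx - 1] * day_total_per_g
    weight = start_weight - (prior + within)
    if config.balance_noise_sd > 0:
        weight = weight + config.balance_noise_sd * rng.standard_normal(n)
    weight = np.maximum(weight, 0.0)
    log = BalanceLog(
        plant_id=plant_id or profile.name,
        time_s=t_s,
        weight_g=weight,
        schedule=PhotoperiodSchedule(),
        mass_before_g=mass_before,
        mass_after_g=mass_after,
    )
    truth = {
        "profile": profile.name,
        "b1": profile.b1,
        "b2": profile.b2,
        "rates": (profile.s1, profile.s2, profile.s3, profile.night_rate),
        "daily_mass": [float(m) for m in daily_mass],
    }
    return log, truth


def planted_daily_variables(
    profile: GenotypeProfile, mass_g: float
) -> TranspirationVariables:
    """Exact 23-variable truth implied by a profile at a given plant mass."""
    d1, d2, d3 = profile.b1, profile.b2 - profile.b1, 12.0 - profile.b2
    slopes = (profile.s1 * mass_g, profile.s2 * mass_g, profile.s3 * mass_g)
    fit = SegmentedFit(
        b1=profile.b1, b2=profile.b2, slopes=slopes, intercept=0.0,
        rss=0.0, rss_line=0.0, n_points=0,
        volumes=(slopes[0] * d1, slopes[1] * d2, slopes[2] * d3),
        durations=(d1, d2, d3),
    )
    night_ml = profile.night_rate * mass_g * NIGHT_H
    return extract_daily_variables(fit, night_ml, mass_g, plant_id=profile.name)


def gen_gas_exchange_trace(
    decline_gs: float = 0.59,
    decline_a: float = 0.34,
    a_max: float = 6.0,
    gs_max: float = 0.25,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Per-minute day-long leaf gas-exchange trace with planted declines.

    Assimilation A (µmol CO₂/m²/s) and stomatal conductance g_s
    (mol H₂O/m²/s) hold a morning plateau, then ramp down between hours 9
    and 10 to afternoon plateaus lower by ``decline_a`` and ``decline_gs``.
    Reference window (2, 8) h and decline window (10, 12) h recover the
    planted percentages exactly in the noiseless case.
    """
    t_h = np.arange(0, 12 * 60) / 60.0
    ramp = np.clip((t_h - 9.0) / 1.0, 0.0, 1.0)
    gs = gs_max * (1.0 - decline_gs * ramp)
    a = a_max * (1.0 - decline_a * ramp)
    if noise_cv > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        gs = gs * (1.0 + noise_cv * rng.standard_normal(t_h.size))
        a = a * (1.0 + noise_cv * rng.standard_normal(t_h.size))
    truth = {"decline_gs_pct": 100 * decline_gs, "decline_a_pct": 100 * decline_a,
             "reference_window": (2.0, 8.0), "decline_window": (10.0, 12.0)}
    return t_h, a, gs, truth


def gen_topview_image(
    canopy_cm2: float,
    px_per_cm: float = 10.0,
    shape: tuple[int, int] = (400, 600),
    n_blobs: int = 3,
    antialias: bool = False,
) -> tuple[np.ndarray, dict]:
    """Synthetic top-view frame: blue field, red 10 × 5 cm reference, green blobs.

    The truth record carries the exact drawn pixel counts; the realized green
    area is within ±1 cm² of the request (disc rasterization granularity).
    """
    if canopy_cm2 < 0:
        raise ValueError("canopy_cm2 must be >= 0")
    h, w = shape
    img = np.zeros((h, w, 3), dtype=np.float64)
    img[:, :] = (0.10, 0.20, 0.85)                      # blue background
    ref_h, ref_w = int(round(5 * px_per_cm)), int(round(10 * px_per_cm))
    img[10:10 + ref_h, 10:10 + ref_w] = (0.85, 0.10, 0.10)  # red reference
    red_px = ref_h * ref_w

    target_px = canopy_cm2 * px_per_cm**2
    green_px = 0
    if target_px > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        per_blob = target_px / n_blobs
        centers_y = np.linspace(0.35, 0.75, n_blobs) * h
        centers_x = np.linspace(0.35, 0.8, n_blobs) * w
        mask = np.zeros((h, w), dtype=bool)
        for cy, cx in zip(centers_y, centers_x):
            r = np.sqrt(per_blob / np.pi)
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[mask] = (0.15, 0.70, 0.15)
        green_px = int(mask.sum())
    if antialias:
        from scipy.ndimage import uniform_filter

        img = uniform_filter(img, size=(2, 2, 1))
    truth = {
        "green_px": green_px,
        "red_px": red_px,
        "cm2_per_px": 1.0 / px_per_cm**2,
        "canopy_cm2_true": green_px / px_per_cm**2,
        "requested_cm2": canopy_cm2,
    }
    return (img * 255).astype(np.uint8), truth


def gen_lysimeter_panel(
    config: GeneratorConfig,
    profiles: list[GenotypeProfile] | None = None,
) -> tuple[list[tuple[BalanceLog, GenotypeProfile]], dict]:
    """Balance logs for the whole transpiration panel (all profiles).

    Each genotype contributes ``lysimeter_plants_per_genotype`` plants with
    slightly varying start masses; the truth maps plants to their planted
    transpiration group.
    """
    profiles = profiles if profiles is not None else default_profiles()
    rng = np.random.default_rng(config.seed)
    out = []
    truth: dict = {"groups": {p.name: p.transp_group for p in profiles}, "plants": {}}
    for p in profiles:
        for r in range(config.lysimeter_plants_per_genotype):
            mass_before = float(rng.uniform(15.0, 30.0))
            mass_after = mass_before * float(rng.uniform(1.2, 1.4))
            pid = f"{p.name}-L{r + 1}"
            log, t = gen_balance_log(
                config, p, mass_before, mass_after, plant_id=pid, rng=rng
            )
            truth["plants"][pid] = t
            out.append((log, p))
    return out, truth
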