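"""Shared domain types for the growth and transpiration pipelines.

Two lab models are represented here.  In the growth model, plants of many
genotypes are grown in sealed hydroponic containers under a control (0% PEG)
and a mild osmotic-stress (5% PEG-8000, ≈ −0.05 MPa) treatment, arranged in
successive sub-experiments that all share one reference cultivar.  In the
transpiration model, individual plants sit on precision balances (gravimetric
lysimeters) that log container weight every 10 s over several 12 h/12 h
photoperiod days; weight loss of a sealed container is transpiration.

Units used throughout: grams (mass and water, 1 mg water ≈ 1 µL), hours
(durations), centimetres / cm² (lengths and areas), millilitres (volumes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: treatment labels used across tables
CONTROL = "control"
STRESS = "stress"

#: measurement units for the columns the readers understand
UNITS = {
    "timestamp": "s (trial-local, 0 = first lights-on)",
    "weight_g": "g",
    "whole_mass_start": "g",
    "pseudostem_height_start": "cm",
    "pseudostem_height_end": "cm",
    "root_fresh": "g",
    "root_dry": "g",
    "pseudostem_fresh": "g",
    "pseudostem_dry": "g",
    "leaf_fresh": "g",
    "leaf_dry": "g",
    "leaf_count": "count",
    "canopy_area": "cm2",
    "cumulative_transpiration": "mL",
    "aboveground_growth": "g",
}


class FormatError(ValueError):
    """A file does not have the expected layout (missing columns, bad header)."""


class DataError(ValueError):
    """A file parses but its content violates an invariant."""


@dataclass(frozen=True)
class PhotoperiodSchedule:
    """Light regime of the growth chamber.

    ``lights_on_hour`` is the clock hour at which the photoperiod starts
    (the study's chambers switched at 12:00 and 00:00).  All pipeline
    bookkeeping is done in trial-local time, where t = 0 s is the first
    lights-on event, so the clock anchor matters only when parsing absolute
    timestamps.
    """

    lights_on_hour: float = 12.0
    photoperiod_h: float = 12.0
    scotoperiod_h: float = 12.0

    def __post_init__(self) -> None:
        if not np.isclose(self.photoperiod_h + self.scotoperiod_h, 24.0):
            raise ValueError("photoperiod + scotoperiod must equal 24 h")
        if not 0.0 <= self.lights_on_hour < 24.0:
            raise ValueError("lights_on_hour must be a clock hour in [0, 24)")

    def phase_of(self, t_h: float | np.ndarray) -> np.ndarray:
        """Return 'day'/'night' for trial-local times in hours."""
        frac = np.asarray(t_h, dtype=float) % 24.0
        return np.where(frac < self.photoperiod_h, "day", "night")


@dataclass
class ExperimentDesign:
    """Layout of the staggered multi-batch screening experiment.

    Every sub-experiment (batch) contains the shared reference cultivar plus
    a few other genotypes; the reference makes batches comparable through
    median-ratio normalization.
    """

    sub_experiments: list[str]
    genotypes_per_subexp: dict[str, list[str]]
    reference_genotype: str
    replicates_per_treatment: int = 8
    treatments: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 0.0, STRESS: 0.05}
    )

    def __post_init__(self) -> None:
        if self.replicates_per_treatment <= 0:
            raise ValueError("replicates_per_treatment must be > 0")
        if len(self.treatments) != 2:
            raise ValueError("exactly two treatments are required")
        for sub in self.sub_experiments:
            genos = self.genotypes_per_subexp.get(sub, [])
            if self.reference_genotype not in genos:
                raise ValueError(
                    f"reference genotype {self.reference_genotype!r} missing "
                    f"from sub-experiment {sub!r}"
                )

    @property
    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for sub in self.sub_experiments:
            for g in self.genotypes_per_subexp[sub]:
                seen.setdefault(g, None)
        return list(seen)


@dataclass
class QualityReport:
    """Per-log quality flags produced by the balance-log reader."""

    n_rows: int = 0
    n_rejected: int = 0
    gaps: list[tuple[float, float]] = field(default_factory=list)  # (t_start s, length s)
    notes: list[str] = field(default_factory=list)

    @property
    def n_gaps(self) -> int:
        return len(self.gaps)


@dataclass
class BalanceLog:
    """Raw gravimetric record of one plant.

    ``time_s`` is trial-local seconds (0 = first lights-on); readings are
    nominally 10 s apart.  ``mass_before_g`` / ``mass_after_g`` are the plant
    weights bracketing the trial, used for per-day size interpolation.
    """

    plant_id: str
    time_s: np.ndarray
    weight_g: np.ndarray
    schedule: PhotoperiodSchedule = field(default_factory=PhotoperiodSchedule)
    mass_before_g: float | None = None
    mass_after_g: float | None = None
    quality: QualityReport = field(default_factory=QualityReport)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.weight_g = np.asarray(self.weight_g, dtype=float)
        if self.time_s.shape != self.weight_g.shape:
            raise DataError("time and weight arrays differ in length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise DataError(f"timestamps of plant {self.plant_id!r} not strictly increasing")
        if np.any(self.weight_g < 0):
            raise DataError(f"negative weights in log of plant {self.plant_id!r}")

    @property
    def nominal_dt_s(self) -> float:
        if self.time_s.size < 2:
            return float("nan")
        return float(np.median(np.diff(self.time_s)))

    @property
    def n_days(self) -> int:
        """Number of 24 h cycles spanned (a full day of 10-s readings counts)."""
        if self.time_s.size < 2:
            return 0
        span = self.time_s[-1] - self.time_s[0] + self.nominal_dt_s
        return int(round(span / 86400.0))


@dataclass
class MorphologyRecord:
    """One plant's morphological measurements plus its design labels.

    ``values`` maps variable name -> value; derived ratios (relative water
    contents, allocation ratios, above-ground growth) are filled in by the
    reader when the underlying measurements are present.
    """

    plant_id: str
    genotype: str
    sub_experiment: str
    treatment: str
    values: dict[str, float] = field(default_factory=dict)
    extras: dict[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        for organ in ("root", "pseudostem", "leaf"):
            fresh = self.values.get(f"{organ}_fresh")
            dry = self.values.get(f"{organ}_dry")
            if fresh is not None and dry is not None and dry > fresh + 1e-12:
                raise DataError(
                    f"plant {self.plant_id!r}: {organ} dry mass {dry} exceeds "
                    f"fresh mass {fresh}"
                )
        for name, v in self.values.items():
            if name.endswith(("_fresh", "_dry", "_mass_start")) and v is not None and v < 0:
                raise DataError(f"plant {self.plant_id!r}: negative mass {name}={v}")


def derive_morphology_ratios(values: dict[str, float]) -> dict[str, float]:
    """Fill derived morphological variables from raw organ masses.

    Relative water content of an organ is (fresh − dry)/fresh; allocation
    ratios are dry-mass fractions.  Existing entries are never overwritten.
    Division by zero yields no entry rather than inf.
    """
    v = dict(values)

    def get(*names):
        out = [v.get(n) for n in names]
        return out if all(x is not None for x in out) else None

    def put(name, value):
        if name not in v and value is not None and np.isfinite(value):
            v[name] = value

    for organ, key in (("root", "rwcRoot"), ("leaf", "rwcLeaf")):
        pair = get(f"{organ}_fresh", f"{organ}_dry")
        if pair and pair[0] > 0:
            put(key, (pair[0] - pair[1]) / pair[0])
    whole = get("root_fresh", "pseudostem_fresh", "leaf_fresh",
                "root_dry", "pseudostem_dry", "leaf_dry")
    if whole:
        rf, pf, lf, rd, pd_, ld = whole
        fresh_tot, dry_tot = rf + pf + lf, rd + pd_ + ld
        if fresh_tot > 0:
            put("rwcPlant", (fresh_tot - dry_tot) / fresh_tot)
        if dry_tot > 0:
            put("rootPlantRatioDry", rd / dry_tot)
            put("leafPlantRatioDry", ld / dry_tot)
        if pd_ + ld > 0:
            put("rootShootRatioDry", rd / (pd_ + ld))
        if ld > 0:
            put("rootLeafRatioDry", rd / ld)
    heights = get("pseudostem_height_start", "pseudostem_height_end")
    if heights:
        put("psGrowthTot", heights[1] - heights[0])
    return v


@dataclass
class DesignReport:
    """Outcome of checking a morphology table against the intended design."""

    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def warn_all(self) -> None:
        for w in self.warnings:
            warnings.warn(w, stacklevel=2)
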