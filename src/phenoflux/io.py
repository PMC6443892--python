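"""Readers and writers for balance logs and morphology tables.

All files are plain comma-separated UTF-8 with a header row.  Balance logs
carry columns ``plant_id, timestamp, weight_g`` (timestamp in trial-local
seconds, or ISO datetimes which are converted against the schedule's
lights-on anchor).  Morphology tables carry the design columns
``plant_id, genotype, sub_experiment, treatment`` plus measurement columns;
unknown columns are preserved as extras.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CONTROL,
    STRESS,
    BalanceLog,
    DataError,
    DesignReport,
    ExperimentDesign,
    FormatError,
    MorphologyRecord,
    PhotoperiodSchedule,
    QualityReport,
    derive_morphology_ratios,
)

DESIGN_COLUMNS = ["plant_id", "genotype", "sub_experiment", "treatment"]
BALANCE_COLUMNS = ["plant_id", "timestamp", "weight_g"]

#: gaps longer than this are flagged in the quality report
GAP_THRESHOLD_S = 60.0


def _to_trial_seconds(ts: pd.Series, schedule: PhotoperiodSchedule) -> np.ndarray:
    numeric = pd.to_numeric(ts, errors="coerce")
    if not numeric.isna().any():
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(ts, errors="raise")
    day0 = parsed.iloc[0].normalize() + pd.Timedelta(hours=schedule.lights_on_hour)
    if parsed.iloc[0] < day0:
        day0 -= pd.Timedelta(days=1)
    return (parsed - day0).dt.total_seconds().to_numpy(dtype=float)


def read_balance_log(
    path: str | Path,
    schedule: PhotoperiodSchedule | None = None,
    plant_id: str | None = None,
    mass_before: float | None = None,
    mass_after: float | None = None,
) -> BalanceLog:
    """Read one plant's balance log from CSV.

    Rows are sorted by timestamp; duplicate timestamps are a :class:`DataError`.
    Gaps longer than 60 s are flagged (never filled) in ``log.quality``.
    """
    logs = read_balance_logs(path, schedule=schedule)
    if plant_id is None:
        if len(logs) != 1:
            raise DataError(
                f"{path}: contains {len(logs)} plants; pass plant_id to select one"
            )
        log = next(iter(logs.values()))
    else:
        if plant_id not in logs:
            raise DataError(f"{path}: no rows for plant {plant_id!r}")
        log = logs[plant_id]
    log.mass_before_g = mass_before
    log.mass_after_g = mass_after
    return log


def read_balance_logs(
    path: str | Path, schedule: PhotoperiodSchedule | None = None
) -> dict[str, BalanceLog]:
    """Read a multi-plant balance-log CSV into per-plant :class:`BalanceLog`."""
    schedule = schedule or PhotoperiodSchedule()
    df = pd.read_csv(path)
    missing = [c for c in BALANCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing balance-log columns {missing}")
    out: dict[str, BalanceLog] = {}
    for pid, sub in df.groupby("plant_id", sort=True):
        t = _to_trial_seconds(sub["timestamp"], schedule)
        order = np.argsort(t, kind="stable")
        t = t[order]
        w = sub["weight_g"].to_numpy(dtype=float)[order]
        keep = np.ones(t.size, dtype=bool)
        keep[1:] = np.diff(t) > 0
        n_dup = int((~keep).sum())
        if n_dup:
            raise DataError(f"{path}: plant {pid!r} has {n_dup} duplicate timestamps")
        quality = QualityReport(n_rows=int(sub.shape[0]), n_rejected=0)
        dt = np.diff(t)
        for i in np.nonzero(dt > GAP_THRESHOLD_S)[0]:
            quality.gaps.append((float(t[i]), float(dt[i])))
        if quality.gaps:
            quality.notes.append(f"{len(quality.gaps)} gap(s) > {GAP_THRESHOLD_S:.0f} s")
        out[str(pid)] = BalanceLog(
            plant_id=str(pid), time_s=t, weight_g=w, schedule=schedule, quality=quality
        )
    return out


def write_balance_log(log: BalanceLog, path: str | Path) -> None:
    pd.DataFrame(
        {"plant_id": log.plant_id, "timestamp": log.time_s, "weight_g": log.weight_g}
    ).to_csv(path, index=False, float_format="%.10g")


def read_morphology_table(path: str | Path) -> list[MorphologyRecord]:
    """Read a per-plant morphology CSV into records, deriving missing ratios.

    An empty file yields an empty list plus a warning.  A record whose dry
    mass exceeds the fresh mass of the same organ raises :class:`DataError`
    naming the plant.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty morphology table", stacklevel=2)
        return []
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing design columns {missing}")
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[MorphologyRecord]:
    records = []
    value_cols = [c for c in df.columns if c not in DESIGN_COLUMNS]
    for _, row in df.iterrows():
        values: dict[str, float] = {}
        extras: dict[str, object] = {}
        for c in value_cols:
            x = row[c]
            if isinstance(x, (int, float, np.integer, np.floating)) and not pd.isna(x):
                values[c] = float(x)
            elif not pd.isna(x):
                extras[c] = x
        rec = MorphologyRecord(
            plant_id=str(row["plant_id"]),
            genotype=str(row["genotype"]),
            sub_experiment=str(row["sub_experiment"]),
            treatment=str(row["treatment"]),
            values=derive_morphology_ratios(values),
            extras=extras,
        )
        rec.validate()
        records.append(rec)
    return records


def morphology_frame(records: list[MorphologyRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of morphology records (one row per plant)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "plant_id": r.plant_id,
            "genotype": r.genotype,
            "sub_experiment": r.sub_experiment,
            "treatment": r.treatment,
        }
        row.update(r.values)
        row.update(r.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def write_morphology_table(records: list[MorphologyRecord], path: str | Path) -> None:
    morphology_frame(records).to_csv(path, index=False, float_format="%.10g")


def validate_design(
    records: list[MorphologyRecord], design: ExperimentDesign
) -> DesignReport:
    """Check a morphology table against the intended experiment layout.

    Violations (missing reference plants in a sub-experiment/treatment,
    unknown treatments) block normalization; unbalanced replicate counts are
    reported as warnings only.
    """
    report = DesignReport()
    df = morphology_frame(records) if records else pd.DataFrame(columns=DESIGN_COLUMNS)
    known = set(design.treatments)
    for t in sorted(set(df["treatment"]) - known):
        report.violations.append(f"unknown treatment {t!r}")
    for sub in design.sub_experiments:
        sub_df = df[df["sub_experiment"] == sub]
        for treatment in design.treatments:
            cell = sub_df[sub_df["treatment"] == treatment]
            n_ref = int((cell["genotype"] == design.reference_genotype).sum())
            if n_ref == 0:
                report.violations.append(
                    f"sub-experiment {sub!r}, treatment {treatment!r}: "
                    "missing reference genotype"
                )
            for geno, n in cell.groupby("genotype").size().items():
                if n != design.replicates_per_treatment:
                    report.warnings.append(
                        f"sub-experiment {sub!r}, treatment {treatment!r}, "
                        f"genotype {geno!r}: n = {n} "
                        f"(expected {design.replicates_per_treatment})"
                    )
    return report


def load_table3() -> pd.DataFrame:
    """Packaged per-genotype growth summary fixture (31 printed rows).

    Columns: genotype, genome, control_mean, control_se, stress_mean,
    stress_se, inhibition_printed_pct, significance.  Means ± SE are
    above-ground growth in grams over 21 days at n = 8 per treatment; the
    reference cultivar's own row is not part of the printed table.
    """
    with resources.files("phenoflux.data").joinpath("genotype_growth_summary.csv").open() as fh:
        return pd.read_csv(fh)
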