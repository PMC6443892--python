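"""End-to-end orchestration: simulate → growth → transpiration → clustering.

Also reproduces the packaged per-genotype growth-summary fixture analyses
(inhibition column, control–stress regression, k-means performance grouping,
mean remaining growth) as a side-by-side report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import CONTROL, STRESS
from .growth import (
    control_stress_regression,
    genotype_growth_summary,
    mean_remaining_growth,
    normalize_morphology,
    performance_kmeans,
    summary_frame,
)
from .io import load_table3, morphology_frame, records_from_frame, validate_design
from .clustering import build_matrix, similarity_tree, test_variable_separation
from .synthetic import (
    GeneratorConfig,
    REFERENCE_NAME,
    default_profiles,
    gen_lysimeter_panel,
    gen_morphology,
    make_design,
)
from .transpiration import analyze_balance_log, medians_frame, variables_frame


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    seed: int
    config: dict
    stages: dict[str, str] = field(default_factory=dict)   # stage -> ok|failed|skipped
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    errors: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    out_dir: str | Path,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Deterministic synthetic end-to-end run; failures skip downstream stages.

    Writes, per stage: the simulated morphology table; the normalized
    genotype growth summary, regression and performance grouping; the
    per-plant-day and per-plant transpiration variable tables; and the
    similarity tree (newick) with group labels and per-variable tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or GeneratorConfig()
    if seed is not None:
        config.seed = seed
    manifest = RunManifest(version=__version__, seed=config.seed,
                           config=asdict(config))
    profiles = default_profiles()

    def register(path: Path) -> None:
        manifest.outputs[str(path.relative_to(out))] = _checksum(path)

    # --- simulate -----------------------------------------------------------
    morph = None
    try:
        morph, truth = gen_morphology(config, profiles)
        p = out / "morphology.csv"
        morph.to_csv(p, index=False)
        register(p)
        p = out / "simulation_truth.json"
        p.write_text(json.dumps(truth, indent=2, sort_keys=True))
        register(p)
        manifest.stages["simulate"] = "ok"
    except Exception as e:  # pragma: no cover - defensive
        manifest.stages["simulate"] = "failed"
        manifest.errors["simulate"] = repr(e)

    # --- growth stage -------------------------------------------------------
    if manifest.stages.get("simulate") == "ok":
        try:
            design = make_design(config, profiles)
            report = validate_design(records_from_frame(morph), design)
            if not report.ok:
                raise ValueError(f"design violations: {report.violations}")
            normalized, _ = normalize_morphology(morph, REFERENCE_NAME,
                                                 variables=["aboveground_growth"])
            summaries = genotype_growth_summary(normalized)
            sframe = summary_frame(summaries)
            p = out / "growth_summary.csv"
            sframe.to_csv(p, index=False)
            register(p)
            reg = control_stress_regression(sframe["control_mean"], sframe["stress_mean"])
            grouping = performance_kmeans(sframe, seed=config.seed)
            gframe = pd.DataFrame(
                {"genotype": list(grouping.labels),
                 "performance_group": list(grouping.labels.values())}
            )
            p = out / "performance_groups.csv"
            gframe.to_csv(p, index=False)
            register(p)
            p = out / "growth_report.json"
            p.write_text(json.dumps({
                "regression": asdict(reg),
                "captured_fraction": grouping.captured_fraction,
                "mean_remaining_growth_pct": mean_remaining_growth(sframe),
            }, indent=2))
            register(p)
            manifest.stages["growth"] = "ok"
        except Exception as e:
            manifest.stages["growth"] = "failed"
            manifest.errors["growth"] = repr(e)
    else:
        manifest.stages["growth"] = "skipped"

    # --- transpiration stage ------------------------------------------------
    plant_summaries = None
    if manifest.stages.get("simulate") == "ok":
        try:
            panel, panel_truth = gen_lysimeter_panel(config, profiles)
            results = [analyze_balance_log(log) for log, _ in panel]
            daily = variables_frame(results)
            if daily.empty:
                raise ValueError("no complete plant-days in any balance log")
            p = out / "transpiration_daily.csv"
            daily.to_csv(p, index=False)
            register(p)
            med = medians_frame(results)
            med["genotype"] = [pid.rsplit("-L", 1)[0] for pid in med["plant_id"]]
            p = out / "transpiration_plant_medians.csv"
            med.to_csv(p, index=False)
            register(p)
            plant_summaries = med
            manifest.stages["transpiration"] = "ok"
        except Exception as e:
            manifest.stages["transpiration"] = "failed"
            manifest.errors["transpiration"] = repr(e)
    else:
        manifest.stages["transpiration"] = "skipped"

    # --- clustering stage ---------------------------------------------------
    if manifest.stages.get("transpiration") == "ok":
        try:
            matrix = build_matrix(plant_summaries, reference_genotype=REFERENCE_NAME)
            tree = similarity_tree(matrix)
            p = out / "similarity_tree.nwk"
            p.write_text(tree.to_newick() + "\n")
            register(p)
            labels = pd.DataFrame(
                {"genotype": list(tree.group_labels),
                 "transpiration_group": list(tree.group_labels.values())}
            )
            p = out / "transpiration_groups.csv"
            labels.to_csv(p, index=False)
            register(p)
            tests = test_variable_separation(plant_summaries, tree.group_labels)
            p = out / "variable_separation.csv"
            tests.to_csv(p, index=False)
            register(p)
            manifest.stages["clustering"] = "ok"
        except Exception as e:
            manifest.stages["clustering"] = "failed"
            manifest.errors["clustering"] = repr(e)
    else:
        manifest.stages["clustering"] = "skipped"

    manifest.to_json(out / "manifest.json")
    return manifest


def table3_report(
    seed: int = 0, out_dir: str | Path | None = None
) -> dict:
    """Recompute the fixture's derived statistics and compare to its columns.

    Returns inhibition agreement (max absolute deviation from the printed
    percentages), the control–stress regression, the k-means captured SS
    fraction and the mean remaining growth, plus a note that the reference
    cultivar's own row is absent from the printed table (31 of 32 genotypes).
    """
    t3 = load_table3()
    inh = 100.0 * (1.0 - t3["stress_mean"] / t3["control_mean"])
    dev = (inh - t3["inhibition_printed_pct"]).abs()
    reg = control_stress_regression(t3["control_mean"], t3["stress_mean"])
    sframe = t3.rename(columns={})
    grouping = performance_kmeans(sframe, k=5, restarts=100, seed=seed)
    report = {
        "n_genotypes": int(t3.shape[0]),
        "missing_rows": ["reference cultivar (not printed; n = 32 in the study)"],
        "inhibition_max_abs_dev_pct": float(dev.max()),
        "inhibition_rows_within_0.1": int((dev <= 0.1).sum()),
        "regression": asdict(reg),
        "kmeans_captured_pct": 100.0 * grouping.captured_fraction,
        "mean_remaining_growth_pct": mean_remaining_growth(t3),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        side = t3[["genotype", "genome", "inhibition_printed_pct"]].copy()
        side["inhibition_recomputed_pct"] = inh.round(2)
        side.to_csv(out / "growth_fixture_comparison.csv", index=False)
        (out / "growth_fixture_report.json").write_text(json.dumps(report, indent=2))
    return report
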