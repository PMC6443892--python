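"""Stage-1 growth characterization under control vs. osmotic stress.

Covers above-ground growth estimation, reference-cultivar median-ratio
batch normalization, per-genotype summaries with growth inhibition,
control–stress regression, performance grouping by k-means on growth
ranks, and two-way ANOVA with Tukey HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .datamodel import CONTROL, STRESS


@dataclass(frozen=True)
class NormalizationFactor:
    """Multiplicative batch-correction factor for one variable/treatment/batch.

    factor = median over reference plants of all sub-experiments divided by
    the median over reference plants of this sub-experiment; applied
    multiplicatively to every plant of that sub-experiment and treatment.
    """

    variable: str
    treatment: str
    sub_experiment: str
    factor: float

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError("normalization factor must be positive")


@dataclass
class GenotypeGrowthSummary:
    genotype: str
    mean_control: float
    se_control: float
    n_control: int
    mean_stress: float
    se_stress: float
    n_stress: int
    inhibition_pct: float | None  # 100·(1 − stress/control); None if control ≤ 0
    p_value: float | None = None  # Welch t, control vs stress per-plant growth
    stars: str | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class PerformanceGrouping:
    labels: dict[str, int]  # genotype -> group 1..k
    k: int
    between_ss: float
    total_ss: float
    seed: int | None
    rank_matrix: pd.DataFrame

    @property
    def captured_fraction(self) -> float:
        return self.between_ss / self.total_ss if self.total_ss > 0 else 0.0


@dataclass(frozen=True)
class RegressionResult:
    intercept: float
    slope: float
    n: int
    r2_adj: float


@dataclass
class AnovaTable:
    p_treatment: float
    p_group: float
    p_interaction: float
    table: pd.DataFrame
    tukey: pd.DataFrame | None = None


def significance_stars(p: float | None) -> str:
    if p is None or np.isnan(p):
        return "nS"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "nS"


def initial_aboveground_mass(whole_mass_start: float, shoot_proportion: float) -> float:
    """Initial shoot mass from whole-plant mass and an allometric proportion.

    The proportion of above-ground to whole-plant mass is assumed stable over
    the trial and is estimated from destructively measured control plants of
    the same cultivar at trial end.
    """
    if not 0.0 < shoot_proportion <= 1.0:
        raise ValueError(f"shoot_proportion must be in (0, 1], got {shoot_proportion}")
    return whole_mass_start * shoot_proportion


def shoot_proportion_from_controls(
    final_shoot_mass: np.ndarray, final_whole_mass: np.ndarray
) -> float:
    """Cultivar-specific shoot proportion: mean shoot/whole over control plants."""
    shoot = np.asarray(final_shoot_mass, float)
    whole = np.asarray(final_whole_mass, float)
    if shoot.size == 0 or np.any(whole <= 0):
        raise ValueError("need control plants with positive whole mass")
    return float(np.mean(shoot / whole))


def aboveground_growth(final_shoot_mass: float, initial_shoot_mass: float) -> float:
    """Mass increase of pseudostem + leaves over the trial (the yield proxy)."""
    if final_shoot_mass < 0 or initial_shoot_mass < 0:
        raise ValueError("masses must be non-negative")
    growth = final_shoot_mass - initial_shoot_mass
    if growth < 0:
        warnings.warn("negative above-ground growth retained (not clipped)", stacklevel=2)
    return growth


def normalization_factor(
    all_ref_values: np.ndarray,
    subexp_ref_values: np.ndarray,
    variable: str = "",
    treatment: str = "",
    sub_experiment: str = "",
) -> NormalizationFactor:
    """Median-ratio factor from reference-cultivar plants (one batch)."""
    allv = np.asarray(all_ref_values, float)
    subv = np.asarray(subexp_ref_values, float)
    if allv.size == 0 or subv.size == 0:
        raise ValueError("reference value lists must be non-empty")
    sub_med = float(np.median(subv))
    if sub_med == 0:
        raise ZeroDivisionError(
            f"sub-experiment reference median is 0 for {variable!r}/{treatment!r}"
        )
    return NormalizationFactor(
        variable=variable,
        treatment=treatment,
        sub_experiment=sub_experiment,
        factor=float(np.median(allv)) / sub_med,
    )


def normalize_morphology(
    df: pd.DataFrame,
    reference_genotype: str,
    variables: list[str] | None = None,
) -> tuple[pd.DataFrame, list[NormalizationFactor]]:
    """Batch-normalize a per-plant table toward the shared reference cultivar.

    For every variable and treatment the factor median(all-batches reference)
    / median(this-batch reference) multiplies every plant of that batch and
    treatment, equalizing the reference medians across batches.
    """
    if variables is None:
        variables = [
            c
            for c in df.columns
            if c not in ("plant_id", "genotype", "sub_experiment", "treatment")
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    out = df.copy()
    factors: list[NormalizationFactor] = []
    ref = df[df["genotype"] == reference_genotype]
    if ref.empty:
        raise ValueError(f"no plants of reference genotype {reference_genotype!r}")
    for treatment, ref_t in ref.groupby("treatment"):
        for var in variables:
            all_vals = ref_t[var].dropna().to_numpy()
            if all_vals.size == 0:
                continue
            for sub, ref_ts in ref_t.groupby("sub_experiment"):
                sub_vals = ref_ts[var].dropna().to_numpy()
                if sub_vals.size == 0:
                    raise ValueError(
                        f"sub-experiment {sub!r}/{treatment!r} has no reference "
                        f"values for {var!r}; refusing to normalize"
                    )
                f = normalization_factor(all_vals, sub_vals, var, str(treatment), str(sub))
                factors.append(f)
                mask = (out["sub_experiment"] == sub) & (out["treatment"] == treatment)
                out.loc[mask, var] = out.loc[mask, var] * f.factor
    return out, factors


def genotype_growth_summary(
    df: pd.DataFrame, value: str = "aboveground_growth"
) -> list[GenotypeGrowthSummary]:
    """Per-genotype mean ± SE growth and inhibition percentage.

    SE = sd/√n per treatment; inhibition = 100·(1 − mean_stress/mean_control).
    Significance of the control–stress difference is a Welch two-sample t-test
    on per-plant growth.
    """
    summaries = []
    for geno, sub in df.groupby("genotype", sort=False):
        c = sub.loc[sub["treatment"] == CONTROL, value].dropna().to_numpy()
        s = sub.loc[sub["treatment"] == STRESS, value].dropna().to_numpy()
        flags = []
        mc, ms = float(np.mean(c)) if c.size else np.nan, float(np.mean(s)) if s.size else np.nan
        sec = float(np.std(c, ddof=1) / np.sqrt(c.size)) if c.size > 1 else np.nan
        ses = float(np.std(s, ddof=1) / np.sqrt(s.size)) if s.size > 1 else np.nan
        if mc <= 0 or np.isnan(mc):
            inhibition = None
            flags.append("inhibition undefined (control mean <= 0)")
        else:
            inhibition = 100.0 * (1.0 - ms / mc)
        if np.nanmin([mc, ms]) < 0:
            flags.append("negative mean growth")
        p = None
        if c.size > 1 and s.size > 1:
            p = float(stats.ttest_ind(c, s, equal_var=False).pvalue)
        summaries.append(
            GenotypeGrowthSummary(
                genotype=str(geno),
                mean_control=mc, se_control=sec, n_control=int(c.size),
                mean_stress=ms, se_stress=ses, n_stress=int(s.size),
                inhibition_pct=inhibition,
                p_value=p,
                stars=significance_stars(p) if p is not None else None,
                flags=flags,
            )
        )
    return summaries


def summary_frame(summaries: list[GenotypeGrowthSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genotype": [s.genotype for s in summaries],
            "control_mean": [s.mean_control for s in summaries],
            "control_se": [s.se_control for s in summaries],
            "stress_mean": [s.mean_stress for s in summaries],
            "stress_se": [s.se_stress for s in summaries],
            "inhibition_pct": [s.inhibition_pct for s in summaries],
            "significance": [s.stars for s in summaries],
        }
    )


def control_stress_regression(
    control_means: np.ndarray, stress_means: np.ndarray
) -> RegressionResult:
    """OLS of genotype control-growth means on stress-growth means.

    Adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2).
    """
    y = np.asarray(control_means, float)
    x = np.asarray(stress_means, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 genotypes")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("zero variance in stress means: singular fit")
    slope, intercept, r, _, _ = stats.linregress(x, y)
    r2_adj = 1.0 - (1.0 - r**2) * (n - 1) / (n - 2)
    return RegressionResult(intercept=float(intercept), slope=float(slope), n=n,
                            r2_adj=float(r2_adj))


def growth_rank_matrix(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-condition ranks of genotype mean growth (1 = lowest; average ties)."""
    return pd.DataFrame(
        {
            "rank_control": stats.rankdata(summary["control_mean"]),
            "rank_stress": stats.rankdata(summary["stress_mean"]),
        },
        index=summary["genotype"].to_numpy(),
    )


def performance_kmeans(
    summary: pd.DataFrame, k: int = 5, restarts: int = 100, seed: int | None = 0
) -> PerformanceGrouping:
    """k-means performance groups on the 2-column growth-rank matrix.

    Euclidean distance, best of ``restarts`` random initializations; the
    captured fraction is between-cluster SS over total SS.
    """
    ranks = growth_rank_matrix(summary)
    n = ranks.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds number of genotypes ({n})")
    X = ranks.to_numpy(dtype=float)
    total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
    if k == 1:
        labels = np.zeros(n, dtype=int)
        between = 0.0
    else:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels = km.fit_predict(X)
        between = total_ss - float(km.inertia_)
    return PerformanceGrouping(
        labels={g: int(l) + 1 for g, l in zip(ranks.index, labels)},
        k=k,
        between_ss=between,
        total_ss=total_ss,
        seed=seed,
        rank_matrix=ranks,
    )


def mean_remaining_growth(summary: pd.DataFrame) -> float:
    """Mean over genotypes of stress growth as % of control (100 − inhibition)."""
    inh = 100.0 * (1.0 - summary["stress_mean"] / summary["control_mean"])
    return float((100.0 - inh).mean())


def two_way_anova(
    values: np.ndarray,
    treatment_labels: np.ndarray,
    group_labels: np.ndarray,
    tukey: bool = True,
) -> AnovaTable:
    """Two-way ANOVA (treatment × group, Type-II SS) with optional Tukey HSD.

    Type-II sums of squares handle the unbalanced group sizes of the screening
    design; Tukey compares all treatment:group cell means.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {
            "value": np.asarray(values, float),
            "treatment": np.asarray(treatment_labels).astype(str),
            "group": np.asarray(group_labels).astype(str),
        }
    )
    counts = df.groupby(["treatment", "group"]).size()
    full = pd.MultiIndex.from_product(
        [sorted(df["treatment"].unique()), sorted(df["group"].unique())]
    )
    for cell in full:
        if counts.get(cell, 0) == 0:
            raise ValueError(f"empty cell treatment={cell[0]!r}, group={cell[1]!r}")
    model = ols("value ~ C(treatment) * C(group)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p = table["PR(>F)"]
    tukey_df = None
    if tukey:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        cells = (df["treatment"] + ":" + df["group"]).to_numpy()
        res = pairwise_tukeyhsd(df["value"].to_numpy(), cells)
        tukey_df = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return AnovaTable(
        p_treatment=float(p["C(treatment)"]),
        p_group=float(p["C(group)"]),
        p_interaction=float(p["C(treatment):C(group)"]),
        table=table,
        tukey=tukey_df,
    )
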