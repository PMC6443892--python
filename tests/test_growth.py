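"""Growth stage: allometry, batch normalization, summaries, grouping, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phenoflux.datamodel import CONTROL, STRESS
from phenoflux.growth import (
    aboveground_growth,
    control_stress_regression,
    genotype_growth_summary,
    growth_rank_matrix,
    initial_aboveground_mass,
    normalization_factor,
    normalize_morphology,
    performance_kmeans,
    shoot_proportion_from_controls,
    summary_frame,
    two_way_anova,
)
from phenoflux.synthetic import REFERENCE_NAME, GeneratorConfig, default_profiles, gen_morphology


def _plants(genotype, control_vals, stress_vals):
    rows = []
    for i, v in enumerate(control_vals):
        rows.append({"plant_id": f"{genotype}c{i}", "genotype": genotype,
                     "treatment": CONTROL, "aboveground_growth": v})
    for i, v in enumerate(stress_vals):
        rows.append({"plant_id": f"{genotype}s{i}", "genotype": genotype,
                     "treatment": STRESS, "aboveground_growth": v})
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "whole,prop,expected", [(10.0, 0.6, 6.0), (7.3, 1.0, 7.3)]
)
def test_initial_aboveground_mass(whole, prop, expected):
    assert initial_aboveground_mass(whole, prop) == pytest.approx(expected)


def test_shoot_proportion_outside_unit_interval_rejected():
    for bad in (0.0, 1.2, -0.1):
        with pytest.raises(ValueError):
            initial_aboveground_mass(10.0, bad)


def test_shoot_proportion_recovered_from_controls(rng):
    true = 0.55
    whole = 30.0 + 5.0 * rng.standard_normal(8)
    shoot = true * whole * (1 + 0.02 * rng.standard_normal(8))
    assert shoot_proportion_from_controls(shoot, whole) == pytest.approx(true, abs=0.02)


def test_aboveground_growth():
    assert aboveground_growth(46.95, 6.0) == pytest.approx(40.95)
    assert aboveground_growth(5.0, 5.0) == 0.0
    with pytest.warns(UserWarning, match="negative"):
        assert aboveground_growth(4.0, 5.0) == pytest.approx(-1.0)


def test_normalization_factor_median_ratio():
    f = normalization_factor([10, 20, 30], [20, 25, 30])
    assert f.factor == pytest.approx(20 / 25)
    assert normalization_factor([1, 2, 3], [1, 2, 3]).factor == 1.0
    with pytest.raises(ZeroDivisionError):
        normalization_factor([1.0], [0.0])


def test_batch_effects_removed_and_idempotent():
    """Median-ratio normalization equalizes reference medians across batches
    to 1e-9 and is a no-op when applied twice."""
    cfg = GeneratorConfig(batch_range=(0.8, 1.25))
    morph, _ = gen_morphology(cfg, default_profiles())
    norm, factors = normalize_morphology(morph, REFERENCE_NAME,
                                         variables=["aboveground_growth"])
    ref = norm[norm["genotype"] == REFERENCE_NAME]
    for _, grp in ref.groupby("treatment"):
        medians = grp.groupby("sub_experiment")["aboveground_growth"].median()
        assert np.ptp(medians.to_numpy()) < 1e-9
    _, again = normalize_morphology(norm, REFERENCE_NAME,
                                    variables=["aboveground_growth"])
    assert max(abs(f.factor - 1.0) for f in again) < 1e-9


def test_genotype_ranking_invariant_to_positive_scaling(table3):
    ranks = growth_rank_matrix(table3.rename(columns={}))
    scaled = table3.copy()
    scaled[["control_mean", "stress_mean"]] *= 3.7
    pd.testing.assert_frame_equal(ranks, growth_rank_matrix(scaled))


def test_summary_reproduces_printed_inhibition(rng):
    """Per-genotype inhibition from per-plant data matches the printed
    percentages for two fixture rows."""
    cases = [((40.95, 29.11), 28.9), ((13.3, 4.64), 65.1)]
    for (mc, ms), printed in cases:
        c = mc + rng.standard_normal(8)
        s = ms + rng.standard_normal(8)
        c = c - c.mean() + mc  # force exact means
        s = s - s.mean() + ms
        df = _plants("g", c, s)
        (summ,) = genotype_growth_summary(df)
        assert summ.inhibition_pct == pytest.approx(printed, abs=0.1)
        assert summ.se_control > 0 and summ.n_control == 8


def test_summary_zero_inhibition_and_undefined_control():
    (s,) = genotype_growth_summary(_plants("g", [5.0, 5.0], [5.0, 5.0]))
    assert s.inhibition_pct == pytest.approx(0.0)
    (u,) = genotype_growth_summary(_plants("g", [-1.0, 1.0], [2.0, 2.0]))
    assert u.inhibition_pct is None and u.flags


def test_regression_recovers_exact_line():
    x = np.array([1.0, 2, 3, 5, 8])
    res = control_stress_regression(2 * x + 1, x)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(1.0)
    assert res.r2_adj == pytest.approx(1.0)


def test_regression_destroyed_pairing_has_no_fit(rng):
    x = rng.uniform(5, 50, 200)
    y = 3.7 + 1.5 * x + rng.standard_normal(200)
    shuffled = control_stress_regression(y, rng.permutation(x))
    assert shuffled.r2_adj < 0.1
    assert control_stress_regression(y, x).r2_adj > 0.9


def test_regression_singular_on_constant_stress():
    with pytest.raises(np.linalg.LinAlgError):
        control_stress_regression([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])


class TestPerformanceKmeans:
    def _summary(self, control, stress):
        return pd.DataFrame(
            {"genotype": [f"g{i}" for i in range(len(control))],
             "control_mean": control, "stress_mean": stress}
        )

    def test_k1_captures_nothing(self):
        s = self._summary([1.0, 2, 3, 4, 5], [5.0, 4, 3, 2, 1])
        assert performance_kmeans(s, k=1).captured_fraction == 0.0

    def test_planted_separated_clusters_recovered(self, rng):
        # 5 tight blocks of consecutive ranks in both conditions
        base = np.repeat([0, 20, 40, 60, 80], 4) + rng.uniform(0, 3, 20)
        s = self._summary(base, base + rng.uniform(0, 1, 20))
        g = performance_kmeans(s, k=5, restarts=50, seed=0)
        truth = np.repeat(np.arange(5), 4)
        labels = [g.labels[f"g{i}"] for i in range(20)]
        assert adjusted_rand_score(truth, labels) == 1.0
        assert 0.0 <= g.captured_fraction <= 1.0

    def test_captured_fraction_monotone_in_k(self, table3):
        fracs = [performance_kmeans(table3, k=k, seed=0).captured_fraction
                 for k in (1, 2, 3, 5, 8)]
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_k_exceeding_genotypes_rejected(self):
        s = self._summary([1.0, 2], [2.0, 1])
        with pytest.raises(ValueError):
            performance_kmeans(s, k=5)


class TestTwoWayAnova:
    def test_planted_interaction_detected(self, rng):
        n = 50
        rows = []
        for tr in ("c", "s"):
            for g in ("g1", "g2"):
                mu = 10.0 + (3.0 if (tr == "s" and g == "g1") else 0.0)
                rows.extend((tr, g, v) for v in mu + rng.standard_normal(n))
        tr, g, v = zip(*rows)
        res = two_way_anova(np.array(v), np.array(tr), np.array(g))
        assert res.p_interaction < 0.001
        assert res.tukey is not None and not res.tukey.empty

    def test_identical_cell_patterns_give_p_one(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 4)
        tr = np.repeat(["c", "s"], 8)
        g = np.tile(np.repeat(["g1", "g2"], 4), 2)
        res = two_way_anova(vals, tr, g, tukey=False)
        assert min(res.p_treatment, res.p_group, res.p_interaction) > 0.9

    def test_empty_cell_is_named(self):
        vals = np.arange(6.0)
        tr = np.array(["c", "c", "c", "s", "s", "s"])
        g = np.array(["g1", "g1", "g1", "g2", "g2", "g2"])
        with pytest.raises(ValueError, match="g2"):
            two_way_anova(vals, tr, g)


def test_summary_frame_layout(table3):
    from phenoflux.growth import GenotypeGrowthSummary

    s = GenotypeGrowthSummary("g", 40.0, 1.0, 8, 30.0, 1.0, 8, 25.0, 0.01, "*")
    frame = summary_frame([s])
    assert list(frame.columns) == [
        "genotype", "control_mean", "control_se", "stress_mean", "stress_se",
        "inhibition_pct", "significance",
    ]
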