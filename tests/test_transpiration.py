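"""Cumulative conversion, segmented day fits, and the 23 variables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenoflux.datamodel import BalanceLog, DataError
from phenoflux.synthetic import (
    GeneratorConfig,
    GenotypeProfile,
    gen_balance_log,
    gen_gas_exchange_trace,
    planted_daily_variables,
)
from phenoflux.transpiration import (
    DiurnalSeries,
    LETTER_TO_TRAIT,
    SegmentedFit,
    afternoon_decline,
    analyze_balance_log,
    compute_iwue,
    extract_daily_variables,
    fit_day_segments,
    interpolate_mass,
    night_volume,
    summarize_plant,
    to_cumulative,
)


def _one_day_log(weight_fn, dt=10.0):
    t = np.arange(0, 86400.0, dt)
    return BalanceLog(plant_id="p", time_s=t, weight_g=weight_fn(t))


def _day_series(t_h, cum):
    return DiurnalSeries("p", 1, "day", np.asarray(t_h, float), np.asarray(cum, float))


class TestToCumulative:
    def test_constant_rate_gives_straight_line_to_total(self):
        log = _one_day_log(lambda t: 500.0 - (2.0 / (12 * 3600)) * np.minimum(t, 12 * 3600))
        series = to_cumulative(log)
        day = next(s for s in series if s.phase == "day")
        # last binned reading sits just short of the light switch
        assert day.cum_ml[-1] == pytest.approx(2.0, abs=0.01)
        resid = day.cum_ml - (2.0 / 12.0) * day.t_h
        assert np.max(np.abs(resid)) < 1e-9

    def test_constant_weight_gives_zero_series(self):
        log = _one_day_log(lambda t: np.full(t.size, 500.0))
        for s in to_cumulative(log):
            assert np.all(s.cum_ml == 0.0)

    def test_resets_to_zero_at_each_light_switch(self, aligned_profile):
        cfg = GeneratorConfig(balance_noise_sd=0.0, n_days=2)
        log, _ = gen_balance_log(cfg, aligned_profile, 20.0, 22.0)
        series = to_cumulative(log, bin_minutes=0)
        assert len(series) == 4  # 2 days + 2 nights
        for s in series:
            assert s.cum_ml[0] == 0.0

    def test_cumulative_tracks_planted_integral_within_noise(self, aligned_profile):
        cfg = GeneratorConfig(balance_noise_sd=0.05, n_days=1)
        log, _ = gen_balance_log(cfg, aligned_profile, 20.0, 20.0,
                                 rng=np.random.default_rng(7))
        day = next(s for s in to_cumulative(log) if s.phase == "day")
        p = aligned_profile
        knots = [0, p.b1, p.b2, 12.0]
        rates = 20.0 * np.array([p.s1, p.s2, p.s3])
        cum_knots = np.concatenate([[0], np.cumsum(rates * np.diff(knots))])
        dev = day.cum_ml - np.interp(day.t_h, knots, cum_knots)
        dev -= dev.mean()  # the noisy phase-start reading offsets the whole curve
        # binned mean of σ=0.05 g noise has sd ≈ 0.02 g; allow 5 sd
        assert np.max(np.abs(dev)) < 0.1


class TestSegmentedFit:
    def test_noiseless_breakpoints_recovered(self):
        t = np.linspace(0, 12, 721)
        y = 0.5 * t + 0.8 * np.maximum(t - 2.0, 0) - 0.9 * np.maximum(t - 8.5, 0)
        fit = fit_day_segments(_day_series(t, y))
        assert fit.b1 == pytest.approx(2.0, abs=5 / 60)
        assert fit.b2 == pytest.approx(8.5, abs=5 / 60)
        np.testing.assert_allclose(fit.slopes, (0.5, 1.3, 0.4), atol=1e-6)
        assert fit.rss < 1e-12

    def test_pure_line_flagged_no_breakpoint(self):
        t = np.linspace(0, 12, 200)
        fit = fit_day_segments(_day_series(t, 0.3 * t))
        assert fit.no_breakpoint
        total_ss = np.sum((0.3 * t - np.mean(0.3 * t)) ** 2)
        assert fit.rss_line - fit.rss < 1e-9 * total_ss

    def test_fit_never_worse_than_single_line(self, rng):
        t = np.linspace(0, 12, 300)
        y = 0.2 * t + 0.5 * np.maximum(t - 4, 0) + 0.05 * rng.standard_normal(300)
        fit = fit_day_segments(_day_series(t, y))
        assert fit.rss <= fit.rss_line + 1e-12

    def test_too_short_series_rejected(self):
        with pytest.raises(DataError):
            fit_day_segments(_day_series(np.linspace(0, 4, 100), np.zeros(100)))

    def test_continuity_at_breakpoints(self, rng):
        t = np.linspace(0, 12, 400)
        y = 0.1 * t + 0.9 * np.maximum(t - 3, 0) - 0.7 * np.maximum(t - 9, 0)
        fit = fit_day_segments(_day_series(t, y + 0.02 * rng.standard_normal(400)))
        for b in (fit.b1, fit.b2):
            below = fit.predict(np.array([b - 1e-9]))[0]
            above = fit.predict(np.array([b + 1e-9]))[0]
            assert below == pytest.approx(above, abs=1e-6)


def test_night_volume_constant_rate():
    t = np.arange(0, 12, 1 / 360)  # 10-s spacing in hours
    s = DiurnalSeries("p", 1, "night", t, 0.1 * t)
    assert night_volume(s) == pytest.approx(1.2)
    z = DiurnalSeries("p", 1, "night", t, np.zeros(t.size))
    assert night_volume(z) == pytest.approx(0.0)


@pytest.mark.parametrize(
    "day,before,after,n,expected",
    [(1, 10.0, 22.0, 6, 11.0), (3, 8.0, 8.0, 6, 8.0), (6, 10.0, 22.0, 6, 21.0)],
)
def test_interpolate_mass_midpoints(day, before, after, n, expected):
    assert interpolate_mass(day, before, after, n) == pytest.approx(expected)


def test_interpolate_mass_monotone_and_errors():
    masses = [interpolate_mass(d, 10.0, 22.0, 6) for d in range(1, 7)]
    assert all(b > a for a, b in zip(masses, masses[1:]))
    with pytest.raises(ValueError):
        interpolate_mass(0, 10, 22, 6)
    with pytest.raises(ValueError):
        interpolate_mass(1, -1.0, 22, 6)


def _fit_from_letters(A, B, C, E, F, G):
    return SegmentedFit(
        b1=A, b2=A + B, slopes=(E / A, F / B, G / C), intercept=0.0,
        rss=0.0, rss_line=0.0, n_points=0,
        volumes=(E, F, G), durations=(A, B, C),
    )


class TestExtractDailyVariables:
    def test_worked_example_from_formulas(self):
        v = extract_daily_variables(
            _fit_from_letters(2, 6, 4, 1.0, 4.0, 1.0), night_ml=0.5, mass_g=1.0
        ).values
        assert v["relTransp_Day"] == pytest.approx(6.0)
        assert v["relTransp_dayNight"] == pytest.approx(6.5)
        assert v["relTranspRate_Start"] == pytest.approx(0.5)
        assert v["relTranspRate_Maximum"] == pytest.approx(2 / 3)
        assert v["relTranspRate_Reduction"] == pytest.approx(0.25)
        assert v["closureProp"] == pytest.approx(0.625)
        assert v["relmLSave"] == pytest.approx(5 / 3)
        assert v["propSave"] == pytest.approx(1 - 6 / (5 + 8 / 3))

    def test_no_afternoon_reduction_means_zero_saving(self):
        # third-segment rate equal to the maximum rate: P = O
        v = extract_daily_variables(
            _fit_from_letters(2, 6, 4, 1.0, 3.0, 2.0), night_ml=0.4, mass_g=1.0
        ).values
        assert v["closureProp"] == pytest.approx(0.0, abs=1e-12)
        assert v["relmLSave"] == pytest.approx(0.0, abs=1e-12)
        assert v["propSave"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_night_marks_ratios_missing_not_infinite(self):
        out = extract_daily_variables(
            _fit_from_letters(2, 6, 4, 1.0, 4.0, 1.0), night_ml=0.0, mass_g=1.0
        )
        for letter in "QRST":
            assert np.isnan(out.values[LETTER_TO_TRAIT[letter]])

    def test_all_zero_volumes_flagged(self):
        out = extract_daily_variables(
            _fit_from_letters(2, 6, 4, 0.0, 0.0, 0.0), night_ml=0.0, mass_g=1.0
        )
        assert "proportions-undefined" in out.flags

    def test_volume_variables_scale_inversely_with_mass(self, aligned_profile):
        v1 = planted_daily_variables(aligned_profile, 10.0).values
        v2 = planted_daily_variables(aligned_profile, 20.0).values
        for letter in "ABC":  # durations invariant
            assert v1[LETTER_TO_TRAIT[letter]] == v2[LETTER_TO_TRAIT[letter]]
        for letter in "DEFGHINOP":  # per-gram volumes/rates: planted rates are
            trait = LETTER_TO_TRAIT[letter]   # per-gram, so mass cancels exactly
            assert v1[trait] == pytest.approx(v2[trait], rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    b1=st.floats(0.5, 5.0),
    width=st.floats(0.6, 6.0),
    s1=st.floats(0.001, 0.05),
    s2=st.floats(0.02, 0.1),
    closure=st.floats(0.0, 0.9),
    night=st.floats(0.0005, 0.02),
    mass=st.floats(5.0, 60.0),
)
def test_variable_identities_hold_for_any_profile(b1, width, s1, s2, closure, night, mass):
    """Structural identities of the 23 variables hold to 1e-9 for arbitrary
    planted day shapes: segment durations sum to 12 h, volume sums, the
    daily proportions sum to one, and the water-saving relations."""
    b2 = min(b1 + width, 11.4)
    p = GenotypeProfile(
        name="H", b1=b1, b2=b2, s1=s1, s2=s2, s3=s2 * (1 - closure),
        night_rate=night, control_growth=10.0, inhibition=0.1,
        shoot_proportion=0.6, root_investment=False, performance_tier=3,
        transp_group="A",
    )
    v = planted_daily_variables(p, mass).values
    g = lambda letter: v[LETTER_TO_TRAIT[letter]]
    assert g("A") + g("B") + g("C") == pytest.approx(12.0, abs=1e-9)
    assert g("H") == pytest.approx(g("E") + g("F") + g("G"), abs=1e-9)
    assert g("I") == pytest.approx(g("D") + g("H"), abs=1e-9)
    assert g("J") + g("K") + g("L") + g("M") == pytest.approx(1.0, abs=1e-9)
    assert g("V") == pytest.approx(1 - g("P") / g("O"), abs=1e-9)
    hyp = g("E") + g("F") + g("C") * g("O")
    assert g("U") == pytest.approx(hyp - g("H"), abs=1e-9)
    assert g("W") == pytest.approx(1 - g("H") / hyp, abs=1e-9)
    if g("P") <= g("O"):
        assert 0.0 <= g("V") <= 1.0 + 1e-12


def test_noiseless_pipeline_reproduces_planted_variables(aligned_profile):
    """Noiseless synthetic log → fitted variables equal the planted truth."""
    cfg = GeneratorConfig(balance_noise_sd=0.0, n_days=6)
    log, _ = gen_balance_log(cfg, aligned_profile, 20.0, 26.0)
    res = analyze_balance_log(log, bin_minutes=0)
    assert res.n_days_used == 6 and not res.excluded_days
    for d in res.daily:
        planted = planted_daily_variables(
            aligned_profile, interpolate_mass(d.day_index, 20.0, 26.0, 6)
        )
        for trait, truth in planted.values.items():
            assert d.values[trait] == pytest.approx(truth, rel=1e-6, abs=1e-6), trait


def test_uniform_day_shift_leaves_variables_unchanged(aligned_profile):
    cfg = GeneratorConfig(balance_noise_sd=0.0, n_days=3)
    log, _ = gen_balance_log(cfg, aligned_profile, 20.0, 20.0)
    shifted = BalanceLog(plant_id="p", time_s=log.time_s + 86400.0,
                         weight_g=log.weight_g, schedule=log.schedule)
    a = analyze_balance_log(log, bin_minutes=0, mass_before=20, mass_after=20)
    b = analyze_balance_log(shifted, bin_minutes=0, mass_before=20, mass_after=20)
    va = a.daily[0].as_series()
    vb = next(d for d in b.daily if d.day_index == 2).as_series()
    np.testing.assert_allclose(va.to_numpy(), vb.to_numpy(), rtol=1e-9)


def test_summarize_plant_medians(aligned_profile):
    days = [planted_daily_variables(aligned_profile, m) for m in (10.0, 20.0, 40.0)]
    med, n = summarize_plant(days)
    assert n == 3
    # odd day count: middle order statistic (mass 20 day)
    assert med["relTransp_Day"] == pytest.approx(days[1].values["relTransp_Day"])
    same, _ = summarize_plant([days[0], days[0]])
    assert same["relTransp_Night"] == pytest.approx(days[0].values["relTransp_Night"])


def test_iwue_ratio():
    assert compute_iwue(10.0, 0.2) == pytest.approx(50.0)
    assert compute_iwue(0.0, 0.2) == 0.0
    with pytest.raises(ValueError):
        compute_iwue(5.0, 0.0)


class TestAfternoonDecline:
    def test_flat_and_halving_traces(self):
        t = np.linspace(0, 12, 720)
        assert afternoon_decline(t, np.ones(720), (2, 8), (10, 12)) == pytest.approx(0.0)
        y = np.where(t < 9, 2.0, 1.0)
        assert afternoon_decline(t, y, (2, 8), (10, 12)) == pytest.approx(50.0)

    def test_empty_window_rejected(self):
        t = np.linspace(0, 12, 720)
        with pytest.raises(ValueError):
            afternoon_decline(t, np.ones(720), (2, 8), (13, 14))

    def test_planted_declines_recovered(self):
        t, a, gs, truth = gen_gas_exchange_trace(noise_cv=0.02,
                                                 rng=np.random.default_rng(3))
        ref, dec = truth["reference_window"], truth["decline_window"]
        assert afternoon_decline(t, gs, ref, dec) == pytest.approx(
            truth["decline_gs_pct"], abs=1.0)
        assert afternoon_decline(t, a, ref, dec) == pytest.approx(
            truth["decline_a_pct"], abs=1.0)

    def test_iwue_rises_when_conductance_falls_faster(self):
        t, a, gs, _ = gen_gas_exchange_trace()
        iwue = a / gs
        assert iwue[-1] / iwue[0] == pytest.approx((1 - 0.34) / (1 - 0.59), rel=1e-9)
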