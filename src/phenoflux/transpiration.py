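"""Diurnal transpiration dynamics from gravimetric balance logs.

The raw 10-s weight trace of a sealed container is converted, per
photoperiod phase, into cumulative transpiration that resets to zero at
every light switch.  The 12-h day curve is then fitted with a continuous
3-segment piecewise-linear model (two estimated breakpoints), the night is
one additional 12-h segment, and 23 named variables describing durations,
volumes, rates, rate ratios and the water saved by the pre-night rate
reduction are extracted per plant-day and summarized as per-plant medians.

Volumes are in mL (1 mg water ≈ 1 µL; density 1 g/mL), durations in hours,
and volume/rate variables are normalized by the plant's mass, linearly
interpolated per day between the weights before and after the trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .datamodel import BalanceLog, DataError

DAY_H = 12.0
NIGHT_H = 12.0

#: Table of the 23 extracted variables, keyed by their conventional letter.
LETTER_TO_TRAIT = {
    "A": "duration_Start",
    "B": "duration_Maximum",
    "C": "duration_Reduction",
    "D": "relTransp_Night",
    "E": "relTransp_Start",
    "F": "relTransp_Maximum",
    "G": "relTransp_Reduction",
    "H": "relTransp_Day",
    "I": "relTransp_dayNight",
    "J": "transp_Night_propDaily",
    "K": "transp_Start_propDaily",
    "L": "transp_Maximum_propDaily",
    "M": "transp_Reduction_propDaily",
    "N": "relTranspRate_Start",
    "O": "relTranspRate_Maximum",
    "P": "relTranspRate_Reduction",
    "Q": "transpRate_Start_propNight",
    "R": "transpRate_Maximum_propNight",
    "S": "transpRate_Reduction_propNight",
    "T": "transpRate_Day_propNight",
    "U": "relmLSave",
    "V": "closureProp",
    "W": "propSave",
}
TRAITS = list(LETTER_TO_TRAIT.values())


@dataclass
class DiurnalSeries:
    """Cumulative transpiration of one plant over one photoperiod phase."""

    plant_id: str
    day_index: int          # 1-based trial day
    phase: str              # "day" | "night"
    t_h: np.ndarray         # hours since phase start
    cum_ml: np.ndarray      # cumulative water loss since phase start
    completeness: float = 1.0  # fraction of expected readings present


@dataclass
class SegmentedFit:
    """Continuous 3-segment piecewise-linear fit of one day curve."""

    b1: float
    b2: float
    slopes: tuple[float, float, float]   # mL/h per segment
    intercept: float
    rss: float
    rss_line: float                      # single straight-line RSS
    n_points: int
    volumes: tuple[float, float, float] = (np.nan,) * 3  # fitted mL per segment
    durations: tuple[float, float, float] = (np.nan,) * 3
    flags: list[str] = field(default_factory=list)

    @property
    def no_breakpoint(self) -> bool:
        return "no-breakpoint" in self.flags

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        s1, s2, s3 = self.slopes
        return (
            self.intercept
            + s1 * t
            + (s2 - s1) * np.maximum(t - self.b1, 0.0)
            + (s3 - s2) * np.maximum(t - self.b2, 0.0)
        )


@dataclass
class TranspirationVariables:
    """The 23 per-plant-day transpiration variables (see LETTER_TO_TRAIT)."""

    plant_id: str
    day_index: int
    values: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def __getattr__(self, name: str):
        values = object.__getattribute__(self, "values")
        if name in values:
            return values[name]
        raise AttributeError(name)

    def as_series(self) -> pd.Series:
        return pd.Series({t: self.values.get(t, np.nan) for t in TRAITS})


def bin_series(t_h: np.ndarray, y: np.ndarray, bin_minutes: float = 1.0):
    """Bin an irregular series to fixed-width time-bin means."""
    if bin_minutes <= 0:
        return t_h, y
    width = bin_minutes / 60.0
    idx = np.floor(t_h / width).astype(int)
    order = np.argsort(idx, kind="stable")
    idx, t_h, y = idx[order], t_h[order], y[order]
    uniq, start = np.unique(idx, return_index=True)
    counts = np.diff(np.append(start, idx.size))
    t_b = np.add.reduceat(t_h, start) / counts
    y_b = np.add.reduceat(y, start) / counts
    return t_b, y_b


def to_cumulative(
    log: BalanceLog, bin_minutes: float = 1.0, min_readings: int = 10
) -> list[DiurnalSeries]:
    """Convert a balance log to per-phase cumulative transpiration series.

    Within each 12-h phase, cumulative loss at a reading is the sum of weight
    differences since the phase start (i.e. first weight minus current
    weight); values reset to zero at every light switch.  Readings are binned
    to ``bin_minutes`` means first.  Phases with fewer than ``min_readings``
    readings are skipped with a warning; missing readings are never imputed.
    """
    t_h = log.time_s / 3600.0
    if t_h.size and (t_h[-1] - t_h[0]) < 24.0:
        warnings.warn(f"plant {log.plant_id}: log spans < 1 complete 24 h cycle",
                      stacklevel=2)
    dt_h = log.nominal_dt_s / 3600.0
    series: list[DiurnalSeries] = []
    n_days = int(np.ceil(t_h[-1] / 24.0)) if t_h.size else 0
    for d in range(n_days):
        for phase, start, length in (
            ("day", 24.0 * d, DAY_H),
            ("night", 24.0 * d + DAY_H, NIGHT_H),
        ):
            sel = (t_h >= start) & (t_h < start + length)
            n = int(sel.sum())
            if n < min_readings:
                if n > 0:
                    warnings.warn(
                        f"plant {log.plant_id} day {d + 1} {phase}: only {n} "
                        "readings; phase skipped",
                        stacklevel=2,
                    )
                continue
            tp = t_h[sel] - start
            w = log.weight_g[sel]
            cum = w[0] - w  # sum of inter-reading differences since phase start
            tb, cb = bin_series(tp, cum, bin_minutes)
            expected = length / dt_h if dt_h > 0 else np.inf
            series.append(
                DiurnalSeries(
                    plant_id=log.plant_id,
                    day_index=d + 1,
                    phase=phase,
                    t_h=tb,
                    cum_ml=cb,
                    completeness=float(min(n / expected, 1.0)),
                )
            )
    return series


# ---------------------------------------------------------------------------
# segmented regression: continuous piecewise-linear fit with 2 breakpoints
# ---------------------------------------------------------------------------


class _HingeRSS:
    """Exact RSS of the basis {1, t, (t−b1)+, (t−b2)+} for any (b1, b2).

    Suffix prefix-sums over the sorted abscissa make every Gram-matrix entry
    an O(1) lookup, so the exhaustive breakpoint grid costs a batched 4×4
    solve instead of one least-squares per candidate pair.
    """

    def __init__(self, t: np.ndarray, y: np.ndarray):
        order = np.argsort(t, kind="stable")
        self.t = t[order]
        self.y = y[order]
        n = self.t.size
        rev = slice(None, None, -1)
        self.sN = np.concatenate([np.cumsum(np.ones(n)[rev])[rev], [0.0]])
        self.sT = np.concatenate([np.cumsum(self.t[rev])[rev], [0.0]])
        self.sT2 = np.concatenate([np.cumsum(self.t[rev] ** 2)[rev], [0.0]])
        self.sY = np.concatenate([np.cumsum(self.y[rev])[rev], [0.0]])
        self.sTY = np.concatenate([np.cumsum((self.t * self.y)[rev])[rev], [0.0]])
        self.N = float(n)
        self.S1 = self.sT[0]
        self.S2 = self.sT2[0]
        self.Sy = self.sY[0]
        self.Sty = self.sTY[0]
        self.Syy = float(self.y @ self.y)

    def _suffix(self, b: np.ndarray):
        i = np.searchsorted(self.t, b, side="left")
        return self.sN[i], self.sT[i], self.sT2[i], self.sY[i], self.sTY[i]

    def rss(self, b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
        """Vectorized RSS for pairs b1 < b2 (invalid/singular pairs -> inf)."""
        b1 = np.atleast_1d(np.asarray(b1, float))
        b2 = np.atleast_1d(np.asarray(b2, float))
        n1, t1, t2_1, y1, ty1 = self._suffix(b1)
        n2, t1_2, t2_2, y2, ty2 = self._suffix(b2)
        m = b1.size
        G = np.empty((m, 4, 4))
        h = np.empty((m, 4))
        h1 = t1 - b1 * n1                     # Σ (t-b1)+
        h2 = t1_2 - b2 * n2                   # Σ (t-b2)+
        h1sq = t2_1 - 2 * b1 * t1 + b1**2 * n1
        h2sq = t2_2 - 2 * b2 * t1_2 + b2**2 * n2
        th1 = t2_1 - b1 * t1
        th2 = t2_2 - b2 * t1_2
        h1h2 = t2_2 - (b1 + b2) * t1_2 + b1 * b2 * n2
        G[:, 0, 0] = self.N
        G[:, 0, 1] = G[:, 1, 0] = self.S1
        G[:, 0, 2] = G[:, 2, 0] = h1
        G[:, 0, 3] = G[:, 3, 0] = h2
        G[:, 1, 1] = self.S2
        G[:, 1, 2] = G[:, 2, 1] = th1
        G[:, 1, 3] = G[:, 3, 1] = th2
        G[:, 2, 2] = h1sq
        G[:, 2, 3] = G[:, 3, 2] = h1h2
        G[:, 3, 3] = h2sq
        h[:, 0] = self.Sy
        h[:, 1] = self.Sty
        h[:, 2] = ty1 - b1 * y1
        h[:, 3] = ty2 - b2 * y2
        out = np.full(m, np.inf)
        try:
            coef = np.linalg.solve(G, h[..., None])[..., 0]
            rss = self.Syy - np.einsum("mi,mi->m", coef, h)
        except np.linalg.LinAlgError:
            rss = np.full(m, np.nan)
            for i in range(m):
                try:
                    c = np.linalg.solve(G[i], h[i])
                    rss[i] = self.Syy - c @ h[i]
                except np.linalg.LinAlgError:
                    pass
        good = np.isfinite(rss) & (rss > -1e-9 * max(self.Syy, 1.0))
        out[good] = np.maximum(rss[good], 0.0)
        return out


def fit_day_segments(
    series: DiurnalSeries,
    grid_minutes: float = 5.0,
    min_segment_h: float = 0.5,
    refine: bool = True,
) -> SegmentedFit:
    """Fit the continuous 3-segment model to one day's cumulative curve.

    The breakpoint pair minimizing the RSS is found by exhaustive search on a
    ``grid_minutes`` grid (minimum segment length ``min_segment_h``) followed
    by derivative-free local refinement; the intercept is estimated rather
    than forced through zero (evaporation-offset tolerance).  Segment volumes
    are increments of the fitted line, not of the raw data.
    """
    if series.phase != "day":
        raise ValueError("segmented fit applies to the day phase")
    t, y = np.asarray(series.t_h, float), np.asarray(series.cum_ml, float)
    if t.size < 30 or (t.max() - t.min()) < 10.0:
        raise DataError(
            f"plant {series.plant_id} day {series.day_index}: need >= 30 day "
            "points spanning >= 10 h"
        )
    engine = _HingeRSS(t, y)
    step = grid_minutes / 60.0
    grid = np.arange(min_segment_h, DAY_H - min_segment_h + 1e-9, step)
    B1, B2 = np.meshgrid(grid, grid, indexing="ij")
    valid = (B2 - B1) >= min_segment_h - 1e-12
    b1s, b2s = B1[valid], B2[valid]
    rss = engine.rss(b1s, b2s)
    i = int(np.argmin(rss))
    b1, b2, best = float(b1s[i]), float(b2s[i]), float(rss[i])

    if refine:
        def objective(b):
            bb1, bb2 = b
            if not (min_segment_h <= bb1
                    and bb1 + min_segment_h <= bb2
                    and bb2 <= DAY_H - min_segment_h):
                return np.inf
            return float(engine.rss(bb1, bb2)[0])

        res = minimize(objective, x0=[b1, b2], method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-13 * max(engine.Syy, 1.0)})
        if np.isfinite(res.fun) and res.fun <= best:
            b1, b2 = float(res.x[0]), float(res.x[1])
            best = float(res.fun)

    X = np.column_stack(
        [np.ones_like(t), t, np.maximum(t - b1, 0.0), np.maximum(t - b2, 0.0)]
    )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss_fit = float(resid @ resid)
    c0, c1, c2, c3 = coef
    s1, s2, s3 = float(c1), float(c1 + c2), float(c1 + c2 + c3)

    line = np.polyfit(t, y, 1)
    rss_line = float(np.sum((y - np.polyval(line, t)) ** 2))
    tot_ss = float(np.sum((y - y.mean()) ** 2))

    durations = (b1, b2 - b1, DAY_H - b2)
    volumes = (s1 * durations[0], s2 * durations[1], s3 * durations[2])
    flags = []
    if rss_line - rss_fit < 1e-9 * max(tot_ss, 1e-30):
        flags.append("no-breakpoint")
    if not (s2 >= s1 >= s3):
        flags.append("shape-atypical")  # expected start ≤ maximum ≥ reduction order
    if not all(np.isfinite([s1, s2, s3])):
        flags.append("degenerate")
    return SegmentedFit(
        b1=b1, b2=b2, slopes=(s1, s2, s3), intercept=float(c0),
        rss=rss_fit, rss_line=rss_line, n_points=int(t.size),
        volumes=volumes, durations=durations, flags=flags,
    )


def night_volume(series: DiurnalSeries) -> float:
    """Total water lost over the 12-h dark phase (mL).

    The night is modelled as a single constant-rate segment: the rate is the
    least-squares slope of the cumulative curve and the volume is that rate
    over the full 12 h, which is robust to reading noise and to the last
    reading falling just short of the light switch.
    """
    if series.phase != "night":
        raise ValueError("night_volume needs a night-phase series")
    t, c = series.t_h, series.cum_ml
    if t.size < 2:
        return float(c[-1])
    slope = np.polyfit(t, c, 1)[0]
    return float(slope * NIGHT_H)


def interpolate_mass(
    day_index: int, mass_before: float, mass_after: float, n_days: int
) -> float:
    """Plant mass at the midpoint of a trial day, linear between endpoints."""
    if mass_before <= 0 or mass_after <= 0:
        raise ValueError("masses must be positive")
    if not 1 <= day_index <= n_days:
        raise ValueError(f"day_index {day_index} outside 1..{n_days}")
    return mass_before + (mass_after - mass_before) * (day_index - 0.5) / n_days


def extract_daily_variables(
    fit: SegmentedFit,
    night_ml: float | None,
    mass_g: float,
    plant_id: str = "",
    day_index: int = 0,
) -> TranspirationVariables:
    """Evaluate the 23 variables for one plant-day from the fitted segments.

    Durations come from the breakpoints, volumes from the fitted line divided
    by the interpolated plant mass, and the derived quantities follow the
    standard identities (H = E+F+G, I = D+H, V = 1−P/O, U = (E+F+C·O)−H,
    W = 1−H/(E+F+C·O)).  With no night data the night-referenced ratios are
    reported missing, never infinite.
    """
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    flags = list(fit.flags)
    A, B, C = fit.durations
    E, F, G = (v / mass_g for v in fit.volumes)
    D = np.nan
    if night_ml is None or not np.isfinite(night_ml):
        flags.append("night-missing")
    else:
        D = night_ml / mass_g
    H = E + F + G
    I = D + H
    nan = float("nan")
    if np.isfinite(I) and I != 0:
        J, K, L, M = D / I, E / I, F / I, G / I
    else:
        J = K = L = M = nan
        flags.append("proportions-undefined")
    N = E / A if A > 0 else nan
    O = F / B if B > 0 else nan
    P = G / C if C > 0 else nan
    if np.isfinite(D) and D > 0:
        night_rate = D / NIGHT_H
        Q, R, S, T = N / night_rate, O / night_rate, P / night_rate, H / D
    else:
        Q = R = S = T = nan
        if np.isfinite(D):
            flags.append("night-rate-zero")
    if np.isfinite(O) and O != 0:
        hypothetical = E + F + C * O   # day total had the maximum rate persisted
        U = hypothetical - H
        V = 1.0 - P / O
        W = 1.0 - H / hypothetical if hypothetical != 0 else nan
    else:
        U = V = W = nan
        flags.append("max-rate-undefined")
    letters = dict(A=A, B=B, C=C, D=D, E=E, F=F, G=G, H=H, I=I, J=J, K=K, L=L,
                   M=M, N=N, O=O, P=P, Q=Q, R=R, S=S, T=T, U=U, V=V, W=W)
    return TranspirationVariables(
        plant_id=plant_id,
        day_index=day_index,
        values={LETTER_TO_TRAIT[l]: float(v) for l, v in letters.items()},
        flags=flags,
    )


def summarize_plant(
    daily: list[TranspirationVariables],
) -> tuple[dict[str, float], int]:
    """Per-plant median of each variable across days (NaN-aware)."""
    if len(daily) < 2:
        warnings.warn("fewer than 2 valid days; medians are fragile", stacklevel=2)
    frame = pd.DataFrame([d.as_series() for d in daily])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = frame.median(axis=0, skipna=True)
    return med.to_dict(), len(daily)


def compute_iwue(assimilation: float, conductance: float) -> float:
    """Intrinsic water-use efficiency: CO₂ assimilation over stomatal conductance."""
    if conductance <= 0:
        raise ValueError("stomatal conductance must be positive")
    return assimilation / conductance


def afternoon_decline(
    t_h: np.ndarray,
    trace: np.ndarray,
    reference_window: tuple[float, float],
    decline_window: tuple[float, float],
) -> float:
    """Percent decline of a gas-exchange trace between two day windows."""
    t = np.asarray(t_h, float)
    y = np.asarray(trace, float)
    out = []
    for lo, hi in (reference_window, decline_window):
        sel = (t >= lo) & (t < hi)
        if not sel.any():
            raise ValueError(f"empty window [{lo}, {hi})")
        out.append(float(y[sel].mean()))
    ref, dec = out
    return 100.0 * (1.0 - dec / ref)


@dataclass
class PlantTranspirationResult:
    plant_id: str
    daily: list[TranspirationVariables]
    fits: dict[int, SegmentedFit]
    medians: dict[str, float]
    n_days_used: int
    excluded_days: list[int] = field(default_factory=list)


def analyze_balance_log(
    log: BalanceLog,
    mass_before: float | None = None,
    mass_after: float | None = None,
    bin_minutes: float = 1.0,
    night: str = "following",
    min_completeness: float = 0.9,
) -> PlantTranspirationResult:
    """Full per-plant pipeline: cumulative curves → day fits → 23 variables.

    A day contributes only if ≥ ``min_completeness`` of the expected readings
    are present in both its phases ("complete day").  ``night`` selects
    whether a day's night volume is the dark phase following ("following")
    or preceding ("preceding") the fitted photoperiod.
    """
    mass_before = mass_before if mass_before is not None else log.mass_before_g
    mass_after = mass_after if mass_after is not None else log.mass_after_g
    if mass_before is None or mass_after is None:
        raise ValueError("mass_before and mass_after are required")
    if night not in ("following", "preceding"):
        raise ValueError("night must be 'following' or 'preceding'")
    series = to_cumulative(log, bin_minutes=bin_minutes)
    days = {s.day_index: s for s in series if s.phase == "day"}
    nights = {s.day_index: s for s in series if s.phase == "night"}
    n_days = log.n_days
    daily: list[TranspirationVariables] = []
    fits: dict[int, SegmentedFit] = {}
    excluded: list[int] = []
    for d in sorted(days):
        night_idx = d if night == "following" else d - 1
        day_s = days[d]
        night_s = nights.get(night_idx)
        complete = day_s.completeness >= min_completeness and (
            night_s is not None and night_s.completeness >= min_completeness
        )
        if not complete:
            excluded.append(d)
            continue
        try:
            fit = fit_day_segments(day_s)
        except DataError:
            excluded.append(d)
            continue
        fits[d] = fit
        mass = interpolate_mass(d, mass_before, mass_after, max(n_days, d))
        nv = night_volume(night_s) if night_s is not None else None
        daily.append(
            extract_daily_variables(fit, nv, mass, plant_id=log.plant_id, day_index=d)
        )
    medians, n_used = summarize_plant(daily) if daily else ({}, 0)
    return PlantTranspirationResult(
        plant_id=log.plant_id, daily=daily, fits=fits, medians=medians,
        n_days_used=n_used, excluded_days=excluded,
    )


def variables_frame(results: list[PlantTranspirationResult]) -> pd.DataFrame:
    """Per-plant-day table with the 23 trait columns in canonical order."""
    rows = []
    for r in results:
        for d in r.daily:
            row = {"plant_id": d.plant_id, "day": d.day_index}
            row.update({t: d.values.get(t, np.nan) for t in TRAITS})
            rows.append(row)
    return pd.DataFrame(rows, columns=["plant_id", "day", *TRAITS])


def medians_frame(results: list[PlantTranspirationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"plant_id": r.plant_id, "n_days": r.n_days_used}
        row.update({t: r.medians.get(t, np.nan) for t in TRAITS})
        rows.append(row)
    return pd.DataFrame(rows, columns=["plant_id", "n_days", *TRAITS])
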