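"""Empirical leucine-to-carbon conversion factors by the cumulative method.

A dilution experiment (sample water diluted 1:10 with 0.2-um filtrate,
incubated in the dark and sampled daily until stationary phase) yields a
time course of prokaryotic biomass (ug C L^-1, from flow cytometry) and
leucine incorporation rate (pmol Leu L^-1 h^-1).  The cumulative method
regresses biomass (y) on time-integrated leucine incorporation (x, nmol Leu
L^-1): the OLS slope is the empirical conversion factor (eCF) directly in
kg C mol Leu^-1, because 1 ug/nmol == 1 kg/mol.

Grazing and viral lysis depress biomass without depressing incorporation,
so timepoints where biomass has dropped below the running maximum of the
retained series are excluded from the regression (cumulative leucine still
integrates across them).  Curves whose slope is not significant (two-sided
t-test, default alpha = 0.1) are discarded; remaining slopes are averaged
per sample, and sample means are averaged per depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

THEORETICAL_CF = 1.55
"""Conventional leucine-to-carbon factor (kg C mol Leu^-1), no isotope dilution."""

__all__ = [
    "THEORETICAL_CF",
    "IncubationTimeCourse",
    "CumulativeSeries",
    "CurveFit",
    "CFAggregate",
    "accumulate_curve",
    "fit_curve",
    "estimate_curve",
    "aggregate_sample",
    "aggregate_depth",
    "round_half_away",
]


@dataclass(frozen=True)
class IncubationTimeCourse:
    """One experiment curve: daily biomass and LIR observations."""

    station: str
    depth: float  # m
    curve_id: str
    times: tuple  # days, strictly increasing
    biomass: tuple  # ug C L^-1
    lir: tuple  # pmol Leu L^-1 h^-1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        b = np.asarray(self.biomass, dtype=float)
        l = np.asarray(self.lir, dtype=float)
        if len(t) < 4:
            raise ValueError("time course needs at least 4 timepoints")
        if not (len(t) == len(b) == len(l)):
            raise ValueError("times, biomass and lir must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(b < 0) or np.any(l < 0):
            raise ValueError("biomass and lir must be non-negative")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(b)) or not np.all(np.isfinite(l)):
            raise ValueError("non-finite values in time course")


@dataclass(frozen=True)
class CumulativeSeries:
    """Regression-ready series: retained points of a cumulative curve."""

    retained: tuple  # indices into the original time course
    cumulative_leucine: tuple  # nmol Leu L^-1 at retained times
    biomass: tuple  # ug C L^-1 at retained times
    excluded: tuple  # (index, reason) pairs
    usable: bool
    station: str = ""
    depth: float = float("nan")
    curve_id: str = ""


@dataclass(frozen=True)
class CurveFit:
    """Per-curve eCF: OLS slope of biomass on cumulative leucine."""

    ecf: float  # kg C mol Leu^-1
    se: float
    p_value: float
    n_points: int
    intercept: float
    station: str = ""
    depth: float = float("nan")
    curve_id: str = ""


@dataclass(frozen=True)
class CFAggregate:
    """Sample- or depth-level mean eCF (significant curves only)."""

    level: str  # 'sample' | 'depth'
    mean_ecf: Optional[float]  # None when no curve survived the filter
    sem: float
    n: int
    alpha: float = 0.1
    single: bool = False  # sem undefined (one member), reported as 0
    station: str = ""
    depth: float = float("nan")
    sample_id: str = ""

    @property
    def has_estimate(self) -> bool:
        return self.mean_ecf is not None


def accumulate_curve(tc: IncubationTimeCourse) -> CumulativeSeries:
    """Build the cumulative series and apply the biomass-decline exclusion.

    Cumulative leucine at time t_k is the trapezoidal integral of LIR from
    t_0, in nmol L^-1 (pmol L^-1 h^-1 x 24 h d^-1 / 1000).  A timepoint is
    excluded when its biomass is below the biomass of the previously
    *retained* timepoint (running reference); the first point is always
    retained, and integration continues across exclusions.
    """
    t = np.asarray(tc.times, dtype=float)
    b = np.asarray(tc.biomass, dtype=float)
    l = np.asarray(tc.lir, dtype=float)
    # trapezoid over days with rates per hour -> x24; pmol -> nmol: /1000
    increments = 0.5 * (l[1:] + l[:-1]) * np.diff(t) * 24.0 / 1000.0
    cum = np.concatenate([[0.0], np.cumsum(increments)])

    retained = [0]
    excluded = []
    for i in range(1, len(t)):
        if b[i] < b[retained[-1]]:
            excluded.append((i, "biomass decline"))
        else:
            retained.append(i)
    idx = np.array(retained)
    return CumulativeSeries(
        retained=tuple(retained),
        cumulative_leucine=tuple(cum[idx]),
        biomass=tuple(b[idx]),
        excluded=tuple(excluded),
        usable=len(retained) >= 3,
        station=tc.station,
        depth=tc.depth,
        curve_id=tc.curve_id,
    )


def fit_curve(series: CumulativeSeries) -> CurveFit:
    """OLS of biomass on cumulative leucine; the slope is the eCF.

    Two-sided t-test against zero slope.  A biomass series with zero
    variance gives slope 0 and p = 1 (no relationship); zero variance in
    cumulative leucine is rejected.
    """
    if not series.usable:
        raise ValueError(
            f"curve {series.curve_id or '<anon>'}: fewer than 3 retained points"
        )
    x = np.asarray(series.cumulative_leucine, dtype=float)
    y = np.asarray(series.biomass, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in cumulative leucine; cannot fit slope")
    if np.ptp(y) == 0:
        return CurveFit(
            ecf=0.0, se=0.0, p_value=1.0, n_points=len(x), intercept=float(y[0]),
            station=series.station, depth=series.depth, curve_id=series.curve_id,
        )
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    if math.isnan(p):  # perfect fit: t statistic degenerates
        p = 0.0
    return CurveFit(
        ecf=float(res.slope),
        se=float(res.stderr),
        p_value=p,
        n_points=len(x),
        intercept=float(res.intercept),
        station=series.station,
        depth=series.depth,
        curve_id=series.curve_id,
    )


def estimate_curve(tc: IncubationTimeCourse) -> CurveFit:
    """Convenience: accumulate then fit a single experiment curve."""
    return fit_curve(accumulate_curve(tc))


def aggregate_sample(fits: Sequence[CurveFit], alpha: float = 0.1) -> CFAggregate:
    """Mean eCF per sample over curves significant at ``alpha``.

    sem is the sample SD of the retained slopes over sqrt(n); with a single
    retained curve the sem is undefined and reported as 0 with the
    ``single`` flag set.  When no curve is significant an explicit
    no-estimate aggregate (mean_ecf None, n = 0) is returned.
    """
    if len(fits) < 1:
        raise ValueError("need at least one curve fit")
    kept = [f for f in fits if f.p_value < alpha]
    station = fits[0].station
    depth = fits[0].depth
    if not kept:
        return CFAggregate(level="sample", mean_ecf=None, sem=0.0, n=0,
                           alpha=alpha, station=station, depth=depth)
    vals = np.array([f.ecf for f in kept], dtype=float)
    if len(vals) == 1:
        return CFAggregate(level="sample", mean_ecf=float(vals[0]), sem=0.0,
                           n=1, alpha=alpha, single=True, station=station, depth=depth)
    sem = float(vals.std(ddof=1) / math.sqrt(len(vals)))
    return CFAggregate(level="sample", mean_ecf=float(vals.mean()), sem=sem,
                       n=len(vals), alpha=alpha, station=station, depth=depth)


def aggregate_depth(samples: Sequence[CFAggregate]) -> CFAggregate:
    """Final eCF per depth: unweighted mean of sample-level means."""
    usable = [s for s in samples if s.has_estimate]
    if not usable:
        raise ValueError("no sample aggregate carries an estimate")
    vals = np.array([s.mean_ecf for s in usable], dtype=float)
    station = usable[0].station
    depth = usable[0].depth
    alpha = usable[0].alpha
    if len(vals) == 1:
        return CFAggregate(level="depth", mean_ecf=float(vals[0]), sem=0.0,
                           n=1, alpha=alpha, single=True, station=station, depth=depth)
    sem = float(vals.std(ddof=1) / math.sqrt(len(vals)))
    return CFAggregate(level="depth", mean_ecf=float(vals.mean()), sem=sem,
                       n=len(vals), alpha=alpha, station=station, depth=depth)


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (matches printed-table rounding)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def curves_from_table(df: pd.DataFrame) -> list:
    """Split a tidy experiment table into IncubationTimeCourse objects.

    Expected columns: station, depth_m, curve_id, time_d,
    biomass_ugc_per_l, lir_pmol_per_l_h.
    """
    required = {"station", "depth_m", "curve_id", "time_d", "biomass_ugc_per_l", "lir_pmol_per_l_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"experiment table missing columns: {sorted(missing)}")
    out = []
    for (station, depth, curve), grp in df.groupby(["station", "depth_m", "curve_id"], sort=True):
        grp = grp.sort_values("time_d")
        out.append(
            IncubationTimeCourse(
                station=str(station),
                depth=float(depth),
                curve_id=str(curve),
                times=tuple(grp["time_d"]),
                biomass=tuple(grp["biomass_ugc_per_l"]),
                lir=tuple(grp["lir_pmol_per_l_h"]),
            )
        )
    return out
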