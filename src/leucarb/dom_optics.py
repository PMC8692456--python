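"""Hydrography, DOM optics, and the eCF correlation screen.

Each station/depth carries hydrographic variables (potential temperature,
salinity, oxygen), dissolved organic carbon, fluorescent-DOM peaks (peak M,
marine humic-like/refractory; peak T, protein-like/labile; both in quinine
sulfate units) and chromophoric-DOM absorption coefficients (a254, a340,
a365, m^-1) plus the 275-295 nm spectral slope.  Ratio indices (peak
M/peak T, peak M/a254, peak M/DOC) mix DOM quality and quantity signals.
The screen computes Pearson correlations of each variable against the
empirical conversion factors, flagging significance at a configurable
alpha (default 0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StationDepthRecord",
    "DOMIndexSet",
    "CorrelationResult",
    "dom_ratios",
    "correlation_screen",
    "SCREEN_VARIABLES",
]


@dataclass(frozen=True)
class StationDepthRecord:
    station: str
    depth: float  # m
    tpot: Optional[float] = None  # deg C
    sal: Optional[float] = None
    oxy: Optional[float] = None  # umol kg^-1
    doc: Optional[float] = None  # umol C L^-1
    peak_m: Optional[float] = None  # QSU
    peak_t: Optional[float] = None  # QSU
    a254: Optional[float] = None  # m^-1
    a340: Optional[float] = None
    a365: Optional[float] = None
    s275_295: Optional[float] = None  # nm^-1

    def __post_init__(self) -> None:
        if not self.depth > 0:
            raise ValueError("depth must be positive")
        if self.doc is not None and not self.doc > 0:
            raise ValueError("doc must be positive when present")
        for name in ("peak_m", "peak_t", "a254", "a340", "a365"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class DOMIndexSet:
    """Ratio indices; NaN marks an undefined ratio (zero denominator)."""

    peakM_over_peakT: float
    peakM_over_a254: float
    peakM_over_DOC: float

    @property
    def undefined(self) -> tuple:
        return tuple(
            f.name for f in fields(self) if math.isnan(getattr(self, f.name))
        )


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    pearson_r: float  # NaN when undefined (constant variable or n < 3)
    p_value: float
    n: int
    significant: bool
    alpha: float
    normality_p: Optional[float] = None  # Shapiro-Wilk of the variable (diagnostic)


def _ratio(num: Optional[float], den: Optional[float]) -> float:
    if num is None or den is None or den == 0:
        return float("nan")
    return num / den


def dom_ratios(rec: StationDepthRecord) -> DOMIndexSet:
    """Elementwise ratio indices; zero or missing denominators yield NaN
    (flagged via ``undefined``), never a silent zero."""
    return DOMIndexSet(
        peakM_over_peakT=_ratio(rec.peak_m, rec.peak_t),
        peakM_over_a254=_ratio(rec.peak_m, rec.a254),
        peakM_over_DOC=_ratio(rec.peak_m, rec.doc),
    )


SCREEN_VARIABLES = (
    "tpot", "sal", "oxy", "doc", "peak_m", "peak_t",
    "a254", "a340", "a365", "s275_295",
    "peakM_over_peakT", "peakM_over_a254", "peakM_over_DOC",
)


def records_to_frame(records: Sequence[StationDepthRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {f.name: getattr(rec, f.name) for f in fields(rec)}
        ratios = dom_ratios(rec)
        row.update(
            peakM_over_peakT=ratios.peakM_over_peakT,
            peakM_over_a254=ratios.peakM_over_a254,
            peakM_over_DOC=ratios.peakM_over_DOC,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_screen(
    ecfs: Sequence[float],
    records: Sequence[StationDepthRecord],
    alpha: float = 0.1,
    normality_check: bool = True,
) -> list:
    """Pearson screen of eCFs against hydrography/DOM variables.

    ``ecfs`` and ``records`` are paired by position.  Missing values are
    handled by pairwise-complete deletion per variable; a variable with
    fewer than 3 complete pairs or zero variance is flagged with NaN r.
    The optional Shapiro-Wilk p-value is a reported diagnostic only;
    Pearson is computed regardless.
    """
    if len(ecfs) != len(records):
        raise ValueError("ecfs and records must be paired")
    frame = records_to_frame(records)
    e = np.asarray(ecfs, dtype=float)
    out = []
    for var in SCREEN_VARIABLES:
        v = frame[var].to_numpy(dtype=float)
        mask = np.isfinite(v) & np.isfinite(e)
        n = int(mask.sum())
        norm_p = None
        if normality_check and n >= 3 and np.ptp(v[mask]) > 0:
            norm_p = float(stats.shapiro(v[mask]).pvalue)
        if n < 3 or np.ptp(v[mask]) == 0:
            out.append(CorrelationResult(var, float("nan"), float("nan"),
                                         n, False, alpha, norm_p))
            continue
        r, p = stats.pearsonr(e[mask], v[mask])
        out.append(CorrelationResult(var, float(r), float(p), n,
                                     bool(p < alpha), alpha, norm_p))
    return out


def screen_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "pearson_r": r.pearson_r,
                "p_value": r.p_value,
                "n": r.n,
                "significant": r.significant,
            }
            for r in results
        ]
    )
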