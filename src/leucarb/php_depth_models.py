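"""Prokaryotic heterotrophic production (PHP) and its depth dependence.

PHP (umol C m^-3 d^-1) is LIR times a conversion factor: the theoretical
constant 1.55 kg C mol Leu^-1 gives tPHP, depth-resolved empirical factors
give ePHP.  Depth structure is summarised two ways: (1) log10-log10
polynomial models of PHP against depth, degree 1 vs 2, selected by AIC;
(2) classical group comparisons (one-way ANOVA with Tukey HSD across the
four depth layers, two-sample t-test between sections).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .cf_estimator import THEORETICAL_CF

CARBON_MOLAR_MASS = 12.011  # g mol^-1

LAYERS = ("epipelagic", "upper_mesopelagic", "lower_mesopelagic", "bathypelagic")

__all__ = [
    "LAYERS",
    "PHPEstimate",
    "DepthModelFit",
    "assign_layer",
    "compute_php",
    "fit_polynomial_models",
    "fit_depth_model",
    "layer_comparisons",
    "ComparisonReport",
]


@dataclass(frozen=True)
class PHPEstimate:
    depth: float  # m
    lir: float  # pmol Leu L^-1 h^-1
    cf_used: float  # kg C mol Leu^-1
    php: float  # umol C m^-3 d^-1
    variant: str  # 'empirical' | 'theoretical'
    layer: str

    def __post_init__(self) -> None:
        if self.php < 0:
            raise ValueError("php must be non-negative")
        if self.variant not in ("empirical", "theoretical"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if (self.variant == "theoretical") != (self.cf_used == THEORETICAL_CF):
            raise ValueError("variant 'theoretical' if and only if cf_used is 1.55")


@dataclass(frozen=True)
class DepthModelFit:
    """Polynomial fit on the log10-log10 scale."""

    model: str  # 'linear' | 'quadratic'
    coefficients: tuple  # highest degree first (numpy polyfit order)
    r2: float
    aic: float
    n: int

    def predict(self, x):
        return np.polyval(self.coefficients, x)


def assign_layer(depth: float) -> str:
    """Depth-layer assignment: epipelagic [0, 100), upper mesopelagic
    [100, 450), lower mesopelagic [450, 1000], bathypelagic (1000, inf)."""
    if not depth > 0:
        raise ValueError("depth must be positive")
    if depth < 100:
        return "epipelagic"
    if depth < 450:
        return "upper_mesopelagic"
    if depth <= 1000:
        return "lower_mesopelagic"
    return "bathypelagic"


def compute_php(lir: float, cf: float) -> float:
    """PHP = LIR * CF, converted to umol C m^-3 d^-1.

    lir pmol Leu L^-1 h^-1 times cf kg C mol Leu^-1 is ng C L^-1 h^-1;
    x24 h d^-1, ng L^-1 == ug m^-3, divided by 12.011 ug umol^-1.
    """
    if lir < 0 or cf < 0:
        raise ValueError("lir and cf must be non-negative")
    return lir * cf * 24.0 / CARBON_MOLAR_MASS


def make_php_estimate(depth: float, lir: float, cf: float, variant: str) -> PHPEstimate:
    return PHPEstimate(
        depth=depth, lir=lir, cf_used=cf,
        php=compute_php(lir, cf), variant=variant, layer=assign_layer(depth),
    )


# Floor for the residual sum of squares inside the AIC log: an exact
# (zero-residual) fit otherwise sends n*ln(RSS/n) to -inf for every nested
# model at once and the parameter penalty could no longer break the tie.
_RSS_FLOOR_PER_POINT = 1e-300


def _aic(rss: float, n: int, n_coeff: int) -> float:
    k = n_coeff + 1  # +1 for the residual variance
    rss = max(rss, n * _RSS_FLOOR_PER_POINT)
    return n * math.log(rss / n) + 2 * k


def _poly_fit(x: np.ndarray, y: np.ndarray, degree: int) -> DepthModelFit:
    coeff = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeff, x)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return DepthModelFit(
        model="quadratic" if degree == 2 else "linear",
        coefficients=tuple(coeff),
        r2=r2,
        aic=_aic(rss, len(x), degree + 1),
        n=len(x),
    )


def fit_polynomial_models(x, y) -> tuple:
    """Degree-1 and degree-2 OLS of y on x with AIC selection.

    AIC = n ln(RSS/n) + 2k with k = number of coefficients + 1 (Gaussian
    likelihood up to a constant).  Returns (linear, quadratic, selected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    linear = _poly_fit(x, y, 1)
    quadratic = _poly_fit(x, y, 2)
    selected = quadratic if quadratic.aic < linear.aic else linear
    return linear, quadratic, selected


def fit_depth_model(depths, php) -> tuple:
    """Linear vs quadratic model of log10(PHP) against log10(depth).

    Returns (linear_fit, quadratic_fit, selected_fit); the model with the
    lower AIC is selected.  Non-positive depths or PHP values are rejected
    (log10 undefined), naming the offending row.
    """
    depths = np.asarray(depths, dtype=float)
    php = np.asarray(php, dtype=float)
    for i, (d, p) in enumerate(zip(depths, php)):
        if d <= 0 or p <= 0:
            raise ValueError(f"row {i}: non-positive value (depth={d}, php={p})")
    return fit_polynomial_models(np.log10(depths), np.log10(php))


@dataclass(frozen=True)
class ComparisonReport:
    anova_f: float
    anova_p: float
    tukey: tuple  # (group_a, group_b, meandiff, p_adj, reject)
    section_t: Optional[float]
    section_p: Optional[float]


def layer_comparisons(
    php_by_layer: Dict[str, Sequence[float]],
    php_by_section: Optional[Dict[str, Sequence[float]]] = None,
) -> ComparisonReport:
    """One-way ANOVA + Tukey HSD across depth layers; optional t-test
    between two sections.

    Every group needs >= 2 values.  When all observations are identical the
    F statistic is 0 with p = 1 (degenerate but well-defined limit).
    """
    if len(php_by_layer) < 2:
        raise ValueError("need at least two layer groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in php_by_layer.items()}
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")

    allvals = np.concatenate(list(groups.values()))
    if np.ptp(allvals) == 0:
        f, p = 0.0, 1.0
        tukey_rows = tuple(
            (a, b, 0.0, 1.0, False)
            for i, a in enumerate(groups) for b in list(groups)[i + 1:]
        )
    else:
        f, p = stats.f_oneway(*groups.values())
        labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
        res = pairwise_tukeyhsd(allvals, labels)
        tukey_rows = tuple(
            (str(r[0]), str(r[1]), float(r[2]), float(r[3]), bool(r[6]))
            for r in res.summary().data[1:]
        )

    t_stat = t_p = None
    if php_by_section is not None:
        if len(php_by_section) != 2:
            raise ValueError("section comparison needs exactly two groups")
        a, b = (np.asarray(v, dtype=float) for v in php_by_section.values())
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each section needs >= 2 values")
        t_stat, t_p = stats.ttest_ind(a, b)
        t_stat, t_p = float(t_stat), float(t_p)

    return ComparisonReport(anova_f=float(f), anova_p=float(p),
                            tukey=tukey_rows, section_t=t_stat, section_p=t_p)
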