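"""Multiple linear regression predicting conversion factors.

An exploratory model estimating the leucine-to-carbon conversion factor
from potential temperature and the two FDOM fluorescence peaks:

    CF = b_T * Tpot + b_M * peakM + b_T' * peakT + intercept

fitted by OLS in raw units (no standardization).  Intended as a cheap
proxy where dilution experiments are impractical: the predictors are
routine CTD and optical measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = ["CFRegressionModel", "fit_cf_model", "predict_cf", "CFPrediction"]

CONDITION_NUMBER_LIMIT = 1e12


@dataclass(frozen=True)
class CFRegressionModel:
    beta_tpot: float  # kg C mol Leu^-1 per deg C
    beta_peak_m: float  # kg C mol Leu^-1 per QSU
    beta_peak_t: float  # kg C mol Leu^-1 per QSU
    intercept: float  # kg C mol Leu^-1
    se_tpot: float
    se_peak_m: float
    se_peak_t: float
    se_intercept: float
    p_tpot: float
    p_peak_m: float
    p_peak_t: float
    p_intercept: float
    r2: float
    model_p: float
    n: int

    def __post_init__(self) -> None:
        if self.n <= 4:
            raise ValueError("n must exceed the number of coefficients (4)")
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("r2 must lie in [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CFRegressionModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_cf_model(
    ecfs: Sequence[float],
    tpot: Sequence[float],
    peak_m: Sequence[float],
    peak_t: Sequence[float],
) -> CFRegressionModel:
    """OLS of eCF on (Tpot, peak M, peak T) with intercept.

    Requires >= 5 complete cases.  A near-singular design (condition number
    above 1e12, e.g. a duplicated predictor) is rejected with the condition
    number in the message.
    """
    y = np.asarray(ecfs, dtype=float)
    X = np.column_stack([
        np.asarray(tpot, dtype=float),
        np.asarray(peak_m, dtype=float),
        np.asarray(peak_t, dtype=float),
    ])
    if len(y) != X.shape[0]:
        raise ValueError("response and predictors must be paired")
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[mask], X[mask]
    if len(y) < 5:
        raise ValueError("need at least 5 complete cases")
    design = sm.add_constant(X, prepend=False)
    cond = np.linalg.cond(design)
    if cond > CONDITION_NUMBER_LIMIT:
        raise ValueError(
            f"collinear predictors: design condition number {cond:.3g} "
            f"exceeds {CONDITION_NUMBER_LIMIT:.0e}"
        )
    res = sm.OLS(y, design).fit()
    params, bse, pvals = res.params, res.bse, res.pvalues
    model_p = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 0.0
    return CFRegressionModel(
        beta_tpot=float(params[0]), beta_peak_m=float(params[1]),
        beta_peak_t=float(params[2]), intercept=float(params[3]),
        se_tpot=float(bse[0]), se_peak_m=float(bse[1]),
        se_peak_t=float(bse[2]), se_intercept=float(bse[3]),
        p_tpot=float(pvals[0]), p_peak_m=float(pvals[1]),
        p_peak_t=float(pvals[2]), p_intercept=float(pvals[3]),
        r2=float(res.rsquared), model_p=model_p, n=int(len(y)),
    )


@dataclass(frozen=True)
class CFPrediction:
    cf: float  # kg C mol Leu^-1
    out_of_domain: bool  # negative prediction: outside calibration range


def predict_cf(model: CFRegressionModel, tpot, peak_m, peak_t) -> CFPrediction:
    """Evaluate the fitted linear model at the given predictors.

    A negative predicted conversion factor is physically impossible and is
    flagged (not clamped) as out of the model's calibration domain.
    """
    for name, v in (("tpot", tpot), ("peak_m", peak_m), ("peak_t", peak_t)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing predictor: {name}")
    cf = (
        model.beta_tpot * tpot
        + model.beta_peak_m * peak_m
        + model.beta_peak_t * peak_t
        + model.intercept
    )
    return CFPrediction(cf=float(cf), out_of_domain=bool(cf < 0))
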