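"""Published reference values bundled for worked examples and checks.

Per-curve empirical conversion-factor estimates from a north-east Atlantic
dilution-experiment campaign (two sections, Finisterre and Santander;
depths 50-2000 m; 20 experiment curves over 9 station/depth samples).
Stored as printed: eCF slope, its standard error and the two-sided slope
p-value per curve.  These feed the hierarchical aggregation (sample means
over curves significant at alpha = 0.1, then depth means over samples).
"""

from __future__ import annotations

import pandas as pd

from .cf_estimator import CurveFit

__all__ = ["published_curve_fits", "published_curve_table", "published_depth_ecfs"]

# station, depth_m, sample_id, curve ordinal, ecf, se, p
_CURVES = [
    ("FIN111", 50, "50", 1, 3.91, 0.45, 0.0003),
    ("FIN111", 100, "100", 1, 4.00, 1.09, 0.0573),
    ("FIN11", 500, "500", 1, 2.12, 0.43, 0.0378),
    ("FIN11", 1000, "1000_a", 1, 1.58, 0.36, 0.0473),
    ("FIN11", 1000, "1000_a", 2, 0.96, 0.15, 0.0033),
    ("FIN11", 1000, "1000_a", 3, 1.03, 0.15, 0.0020),
    ("FIN11", 1000, "1000_b", 1, 0.78, 0.16, 0.0340),
    ("FIN11", 1000, "1000_b", 2, 2.40, 0.24, 0.0020),
    ("FIN11", 1000, "1000_b", 3, 0.87, 0.65, 0.2705),
    ("FIN11", 2000, "2000", 1, 1.78, 0.33, 0.0057),
    ("FIN11", 2000, "2000", 2, 0.65, 0.27, 0.0515),
    ("FIN11", 2000, "2000", 3, 2.08, 0.75, 0.0512),
    ("SAN115", 500, "500", 1, 0.43, 0.13, 0.0260),
    ("SAN115", 500, "500", 2, 0.30, 0.05, 0.0040),
    ("SAN115", 500, "500", 3, 0.21, 0.03, 0.0039),
    ("SAN115", 1000, "1000", 1, 0.43, 0.09, 0.0057),
    ("SAN115", 1000, "1000", 2, 0.36, 0.11, 0.0305),
    ("SAN115", 1000, "1000", 3, 0.14, 0.04, 0.0195),
    ("SAN115", 2000, "2000", 1, 0.11, 0.04, 0.0483),
    ("SAN115", 2000, "2000", 2, 0.09, 0.00, 0.0075),
]


def published_curve_table() -> pd.DataFrame:
    """Tidy DataFrame of the published per-curve estimates."""
    return pd.DataFrame(
        _CURVES,
        columns=["station", "depth_m", "sample_id", "curve", "ecf", "se", "p_value"],
    )


def published_curve_fits() -> dict:
    """Per-sample lists of :class:`CurveFit` built from the published table.

    Keyed by (station, depth_m, sample_id); intercept is not printed and is
    recorded as NaN.
    """
    out: dict = {}
    for station, depth, sample, ordinal, ecf, se, p in _CURVES:
        fit = CurveFit(
            ecf=ecf, se=se, p_value=p, n_points=4, intercept=float("nan"),
            station=station, depth=float(depth), curve_id=f"{sample}.{ordinal}",
        )
        out.setdefault((station, depth, sample), []).append(fit)
    return out


def published_depth_ecfs() -> pd.DataFrame:
    """The eight published final depth-level eCFs (kg C mol Leu^-1)."""
    rows = [
        ("FIN", 50, 3.91), ("FIN", 100, 4.00), ("FIN", 500, 2.12),
        ("FIN", 1000, 1.39), ("FIN", 2000, 1.50),
        ("SAN", 500, 0.31), ("SAN", 1000, 0.31), ("SAN", 2000, 0.10),
    ]
    return pd.DataFrame(rows, columns=["section", "depth_m", "ecf"])
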