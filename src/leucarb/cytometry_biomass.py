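"""Flow-cytometry observations to carbon biomass.

Prokaryotic cells counted by flow cytometry are converted into carbon
biomass in three steps: (1) relative side scatter (population SSC divided
by reference-bead SSC) is mapped to cell diameter through a log-log
calibration; (2) the diameter gives a spherical biovolume; (3) biovolume is
converted to cellular carbon with the allometric power law
``C (pg cell^-1) = a * BBv^b`` (default a = 0.12 pg, b = 0.72).  Abundance
times per-cell carbon then yields a biomass concentration in ug C L^-1,
the y-axis of the cumulative conversion-factor regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellCarbonModel",
    "SSCCalibration",
    "ssc_to_biovolume",
    "cell_carbon",
    "biomass_concentration",
    "biomass_from_cytometry",
    "read_cytometry_csv",
]


@dataclass(frozen=True)
class CellCarbonModel:
    """Allometric biovolume-to-carbon model, ``C = a_coeff * BBv**b_exp``.

    Defaults are the marine-bacterioplankton coefficients (0.12 pg,
    exponent 0.72) commonly applied to cytometric biovolumes.
    """

    a_coeff: float = 0.12  # pg C at BBv = 1 um^3
    b_exp: float = 0.72

    def __post_init__(self) -> None:
        if not (self.a_coeff > 0):
            raise ValueError("a_coeff must be positive")
        if not (0 < self.b_exp <= 1):
            raise ValueError("b_exp must be in (0, 1]")


@dataclass(frozen=True)
class SSCCalibration:
    """Log-log mapping from relative side scatter to cell diameter.

    ``log10(diameter um) = slope * log10(relative SSC) + intercept``.
    The identity default (slope=1, intercept=0) reads relative SSC directly
    as diameter; instrument-specific calibrations replace it.
    """

    slope: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.intercept):
            raise ValueError("calibration coefficients must be finite")

    def diameter(self, relative_ssc):
        ssc = np.asarray(relative_ssc, dtype=float)
        if np.any(ssc <= 0):
            raise ValueError("relative SSC must be positive")
        return 10.0 ** (self.slope * np.log10(ssc) + self.intercept)


def ssc_to_biovolume(relative_ssc, cal: SSCCalibration = SSCCalibration()):
    """Cell biovolume (um^3) from relative side scatter, assuming spheres.

    The calibrated diameter d gives biovolume (pi/6) d^3.  Accepts scalars
    or arrays; rejects non-positive SSC.
    """
    d = cal.diameter(relative_ssc)
    bv = (math.pi / 6.0) * d**3
    return float(bv) if np.isscalar(relative_ssc) else bv


def cell_carbon(biovolume, model: CellCarbonModel = CellCarbonModel()):
    """Per-cell carbon (pg) from biovolume (um^3) via the allometric law."""
    bv = np.asarray(biovolume, dtype=float)
    if np.any(bv <= 0):
        raise ValueError("biovolume must be positive")
    c = model.a_coeff * bv**model.b_exp
    return float(c) if np.isscalar(biovolume) else c


def biovolume_from_carbon(carbon, model: CellCarbonModel = CellCarbonModel()):
    """Inverse of :func:`cell_carbon` (pg -> um^3)."""
    c = np.asarray(carbon, dtype=float)
    if np.any(c <= 0):
        raise ValueError("carbon must be positive")
    bv = (c / model.a_coeff) ** (1.0 / model.b_exp)
    return float(bv) if np.isscalar(carbon) else bv


def biomass_concentration(abundance, per_cell_c):
    """Biomass concentration in ug C L^-1.

    abundance in cells mL^-1, per_cell_c in pg C cell^-1:
    cells/mL * pg/cell * 1e3 mL/L * 1e-6 ug/pg = 1e-3 * abundance * pg.
    """
    ab = np.asarray(abundance, dtype=float)
    pc = np.asarray(per_cell_c, dtype=float)
    if np.any(ab < 0) or np.any(pc < 0):
        raise ValueError("abundance and per-cell carbon must be non-negative")
    b = ab * pc * 1e-3
    return float(b) if np.isscalar(abundance) and np.isscalar(per_cell_c) else b


def biomass_from_cytometry(
    df: pd.DataFrame,
    cal: SSCCalibration = SSCCalibration(),
    model: CellCarbonModel = CellCarbonModel(),
    per_timepoint: bool = True,
) -> pd.DataFrame:
    """Resolve a cytometry table into biomass concentrations.

    ``df`` needs columns ``abundance_cells_per_ml`` and ``relative_ssc``.
    With ``per_timepoint`` (default) each row uses its own biovolume;
    otherwise one mean biovolume is applied to every row of the table.
    Returns a copy with ``biovolume_um3``, ``cell_c_pg`` and
    ``biomass_ugc_per_l`` columns appended.
    """
    out = df.copy()
    bv = ssc_to_biovolume(out["relative_ssc"].to_numpy(), cal)
    if not per_timepoint:
        bv = np.full_like(bv, float(np.mean(bv)))
    cc = cell_carbon(bv, model)
    out["biovolume_um3"] = bv
    out["cell_c_pg"] = cc
    out["biomass_ugc_per_l"] = biomass_concentration(
        out["abundance_cells_per_ml"].to_numpy(), cc
    )
    return out


def read_cytometry_csv(path) -> pd.DataFrame:
    """Read a cytometry time-course CSV (time_d, abundance_cells_per_ml,
    relative_ssc); '#' lines are comments, 'NA' is missing."""
    df = pd.read_csv(path, comment="#", na_values=["NA"])
    required = {"time_d", "abundance_cells_per_ml", "relative_ssc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cytometry table missing columns: {sorted(missing)}")
    return df
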