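"""Deterministic laboratory arithmetic for the β-glucosidase / pigment assays.

Covers the colorimetric enzyme-activity calculation (p-nitrophenol release
at 400 nm), ordinary-least-squares standard curves used to convert optical
density to concentration, and the substrate molar-ratio bookkeeping used
when comparing geniposide and glycine doses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Molecular weights (g/mol) used for dose → mole conversion.
GENIPOSIDE_MW = 388.37
GLYCINE_MW = 75.07


class AssayError(ValueError):
    """Invalid assay inputs (non-positive volumes, degenerate fits, ...)."""


@dataclass(frozen=True)
class ActivityAssay:
    """Inputs of the colorimetric β-glucosidase activity measurement.

    One unit (U/mL) is the amount of enzyme producing 1 nmol p-nitrophenol
    per minute per mL of enzyme solution.
    """

    dilution: float  # dilution factor D, dimensionless
    delta_a_sample: float  # ΔA1, absorbance change of the sample
    delta_a_blank: float  # ΔA2, absorbance change of the blank
    total_volume_ml: float  # Vt, total reaction volume (mL)
    molar_absorption: float  # e, molar absorption coefficient of p-nitrophenol
    enzyme_volume_ml: float  # Vs, enzyme solution volume (mL)
    path_length_cm: float = 1.0  # d, cuvette path length (cm)

    def __post_init__(self) -> None:
        for name in ("total_volume_ml", "molar_absorption", "enzyme_volume_ml", "path_length_cm"):
            if getattr(self, name) <= 0:
                raise AssayError(f"{name} must be positive")
        if self.dilution < 1:
            raise AssayError("dilution factor must be >= 1")


def enzyme_activity(assay: ActivityAssay) -> float:
    """Activity in U/mL:  D · 10³ · (ΔA1 − ΔA2) · Vt / (e · Vs · d)."""
    num = assay.dilution * 1e3 * (assay.delta_a_sample - assay.delta_a_blank)
    num *= assay.total_volume_ml
    den = assay.molar_absorption * assay.enzyme_volume_ml * assay.path_length_cm
    return num / den


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line ``reading = slope · concentration + intercept``."""

    slope: float
    intercept: float
    r2: float
    slope_stderr: float


def fit_standard_curve(concentrations, readings) -> StandardCurve:
    """Ordinary least squares of readings (OD) on known concentrations."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(readings, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise AssayError("need >= 2 aligned calibration points")
    if np.allclose(x, x[0]):
        raise AssayError("calibration concentrations are all equal; fit degenerate")
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        slope_stderr=float(res.stderr),
    )


def invert_curve(curve: StandardCurve, reading: float) -> float:
    """Concentration corresponding to a reading: (reading − intercept)/slope."""
    if curve.slope == 0:
        raise AssayError("zero-slope curve cannot be inverted")
    return (reading - curve.intercept) / curve.slope


def micromoles(dose_mass_mg: float, molecular_weight: float) -> float:
    """μmol contained in a dose given in mg: mg / (g/mol) × 10³."""
    if dose_mass_mg <= 0 or molecular_weight <= 0:
        raise AssayError("dose and molecular weight must be positive")
    return dose_mass_mg / molecular_weight * 1e3


def molar_ratio(dose_a: float, mw_a: float, dose_b: float, mw_b: float) -> float:
    """Mole ratio (dose_a/mw_a) / (dose_b/mw_b) of two substrate doses.

    Passing molecular weights of 1 compares amounts already expressed in
    moles.  Display convention is two decimals (e.g. ``1.18``).
    """
    if min(dose_a, mw_a, dose_b, mw_b) <= 0:
        raise AssayError("doses and molecular weights must be positive")
    return (dose_a / mw_a) / (dose_b / mw_b)
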