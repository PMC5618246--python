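"""I-V curves, Ohmic fits, and cylindrical-pore conductance theory.

A nanopore (or blank electrolyte box) under a series of applied voltages
yields one (V, I_mean, I_err) point per run.  Within the linear range
(default +/-2 V; outside it the response turns sub-linear) the points are
fit by ordinary least squares with a free intercept; the slope is the
conductance G (nS), its reciprocal the resistance (reported in MOhm).

The theoretical reference for a cylindrical pore of diameter d and
effective height h in an electrolyte of specific conductance kappa is

    G = pi d^2 kappa / (4 h)

and a homogeneous conductor of cross-section A and length Lz converts an
I-V slope back to conductivity via kappa = G Lz / A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IVPoint",
    "IVDataset",
    "TheoryParams",
    "EXPERIMENTAL_MOLAR_CONDUCTIVITY",
    "fit_iv",
    "theoretical_conductance",
    "specific_from_molar",
    "molar_from_specific",
    "bulk_conductivity_from_fit",
    "percent_excess",
]

logger = logging.getLogger(__name__)

#: Handbook molar conductivity of 1.0 M KCl at 25 C, mS m^2 mol^-1; the
#: experimental reference against which simulated conductivities are
#: compared.
EXPERIMENTAL_MOLAR_CONDUCTIVITY = 9.8


@dataclass(frozen=True)
class IVPoint:
    voltage: float  # V
    current: float  # nA
    error: float = 0.0  # nA


@dataclass
class IVDataset:
    """I-V points with an Ohmic straight-line fit over the linear range."""

    points: list[IVPoint]
    fit_slope: float  # nS (conductance G)
    fit_intercept: float  # nA
    slope_stderr: float  # nS
    intercept_stderr: float  # nA
    linear_range: tuple[float, float]

    @property
    def conductance(self) -> float:
        """Conductance G, nS."""
        return self.fit_slope

    @property
    def resistance(self) -> float:
        """Resistance 1/G, MOhm."""
        if self.fit_slope == 0:
            raise ZeroDivisionError("zero conductance has no finite resistance")
        return 1e3 / self.fit_slope  # 1/nS = GOhm = 1e3 MOhm


def fit_iv(
    points: list[IVPoint] | list[tuple],
    linear_range: tuple[float, float] = (-2.0, 2.0),
) -> IVDataset:
    """Ordinary least-squares line through the in-range I-V points.

    Points outside ``linear_range`` are excluded (the response is
    sub-linear there).  The slope is the conductance in nS; the free
    intercept is retained as a sanity diagnostic and a warning is logged
    when it exceeds three times its standard error.
    """
    pts = [p if isinstance(p, IVPoint) else IVPoint(*p) for p in points]
    lo, hi = min(linear_range), max(linear_range)
    in_range = [p for p in pts if lo <= p.voltage <= hi]
    voltages = np.array([p.voltage for p in in_range])
    if len(set(voltages.tolist())) < 2:
        raise ValueError(
            "degenerate fit: need at least 2 distinct in-range voltages"
        )
    currents = np.array([p.current for p in in_range])
    res = stats.linregress(voltages, currents)
    if res.intercept_stderr and abs(res.intercept) > 3 * res.intercept_stderr:
        logger.warning(
            "I-V intercept %.3g nA exceeds 3 sigma (%.3g nA); "
            "check for drift or asymmetry",
            res.intercept,
            res.intercept_stderr,
        )
    return IVDataset(
        points=pts,
        fit_slope=float(res.slope),
        fit_intercept=float(res.intercept),
        slope_stderr=float(res.stderr) if res.stderr else 0.0,
        intercept_stderr=float(res.intercept_stderr)
        if res.intercept_stderr
        else 0.0,
        linear_range=(lo, hi),
    )


@dataclass(frozen=True)
class TheoryParams:
    """Geometry and electrolyte inputs of the cylindrical-pore model."""

    diameter: float  # nm
    effective_height: float  # nm
    kappa: float  # S/m

    def __post_init__(self) -> None:
        if self.diameter < 0 or self.effective_height <= 0 or self.kappa <= 0:
            raise ValueError("theory parameters must be positive (d may be 0)")


def theoretical_conductance(params: TheoryParams) -> float:
    """Cylindrical-pore conductance G = pi d^2 kappa / (4 h), in nS.

    With d and h in nm and kappa in S/m the formula evaluates directly
    in nS (the 1e-9 length factors cancel into the prefix).
    """
    return np.pi * params.diameter**2 * params.kappa / (4 * params.effective_height)


def specific_from_molar(molar_conductivity: float, concentration: float) -> float:
    """Specific conductance kappa (S/m) from molar conductivity.

    kappa = Lambda_m * c; with Lambda_m in mS m^2 mol^-1 and c in mol/L
    (= 1000 mol/m^3) the numerals multiply directly: 14.7 mS m^2 mol^-1 at
    1.0 M is 14.7 S/m.
    """
    if molar_conductivity < 0 or concentration < 0:
        raise ValueError("inputs must be non-negative")
    return molar_conductivity * concentration


def molar_from_specific(kappa: float, concentration: float) -> float:
    """Molar conductivity (mS m^2 mol^-1) from specific conductance (S/m)."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    return kappa / concentration


def bulk_conductivity_from_fit(
    iv: IVDataset, box_lengths: tuple[float, float, float]
) -> float:
    """Specific conductivity (S/m) of a homogeneous box from its I-V slope.

    kappa = G * Lz / (Lx * Ly) with G in nS and the box in nm: the slope
    of a blank-electrolyte I-V curve over the reference-box geometry
    (A = 26.316 nm^2, Lz = 10 nm) of 38.68 nS corresponds to 14.7 S/m.
    """
    lx, ly, lz = box_lengths
    if min(lx, ly, lz) <= 0:
        raise ValueError("box lengths must be positive")
    return iv.fit_slope * lz / (lx * ly)


def percent_excess(observed: float, reference: float) -> float:
    """Percent difference of ``observed`` relative to ``reference``."""
    if reference == 0:
        raise ZeroDivisionError("reference value must be nonzero")
    return 100.0 * (observed - reference) / reference
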