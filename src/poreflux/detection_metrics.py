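"""Detectability metrics for localized nucleoside modifications.

A nucleoside parked in the pore lumen blocks part of the ion pathway and
lowers the pore conductance.  Whether a modification is distinguishable
from the canonical nucleoside is quantified two ways:

* SNR — the conductance difference between canonical and modified
  nucleoside divided by the sum of their block-averaged standard
  deviations; SNR > 1 is the detectability criterion.
* gamma — the percent change in pore resistance of the modified relative
  to the canonical nucleoside (the "degree of sensitivity").

Both are computed per (modification, pore diameter) from
:class:`ConductanceSummary` rows and assembled into a sensitivity table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ConductanceSummary",
    "snr",
    "gamma",
    "sensitivity_scan",
    "DETECTABILITY_THRESHOLD",
]

#: SNR above which a modification is called detectable.
DETECTABILITY_THRESHOLD = 1.0


@dataclass(frozen=True)
class ConductanceSummary:
    """Block-averaged conductance of one pore/nucleoside combination.

    Resistance and its uncertainty follow from the conductance by
    first-order error propagation (sigma_R = sigma_G / G^2, in matching
    units).
    """

    label: str
    pore_diameter: float  # nm
    conductance: float  # nS
    conductance_error: float  # nS

    def __post_init__(self) -> None:
        if self.conductance_error < 0:
            raise ValueError("conductance error must be non-negative")

    @property
    def resistance(self) -> float:
        """Resistance, MOhm."""
        return 1e3 / self.conductance

    @property
    def resistance_error(self) -> float:
        """First-order propagated resistance uncertainty, MOhm."""
        return 1e3 * self.conductance_error / self.conductance**2


def snr(reference: ConductanceSummary, modified: ConductanceSummary) -> float:
    """Signal-to-noise ratio of a conductance difference.

    Signal: |G_ref - G_mod|.  Noise: sigma_ref + sigma_mod (block-derived
    standard deviations).  With both errors exactly zero and differing
    means the ratio is reported as ``inf`` (a flagged sentinel, not an
    exception).
    """
    if reference.pore_diameter != modified.pore_diameter:
        raise ValueError(
            f"pore diameters differ: {reference.pore_diameter} vs "
            f"{modified.pore_diameter} nm"
        )
    signal = abs(reference.conductance - modified.conductance)
    noise = reference.conductance_error + modified.conductance_error
    if noise == 0:
        return 0.0 if signal == 0 else math.inf
    return signal / noise


def gamma(reference: ConductanceSummary, modified: ConductanceSummary) -> float:
    """Percent resistance change of the modified relative to the reference.

    gamma = 100 (R_mod - R_ref) / R_ref; algebraically identical to
    100 (G_ref / G_mod - 1).
    """
    if reference.resistance <= 0:
        raise ValueError("reference resistance must be positive")
    return 100.0 * (modified.resistance - reference.resistance) / reference.resistance


def sensitivity_scan(
    summaries: list[ConductanceSummary],
    reference_label: str = "U",
    threshold: float = DETECTABILITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-(modification, diameter) sensitivity table.

    Requires the reference nucleoside at every pore diameter present.
    Columns: modification, pore_diameter, delta_g (G_ref - G_mod, nS),
    snr, gamma (%), detectable (snr > threshold).
    """
    diameters = sorted({s.pore_diameter for s in summaries})
    refs = {
        s.pore_diameter: s for s in summaries if s.label == reference_label
    }
    missing = [d for d in diameters if d not in refs]
    if missing:
        raise ValueError(
            f"reference {reference_label!r} missing at pore diameters {missing}"
        )
    rows = []
    for s in summaries:
        if s.label == reference_label:
            continue
        ref = refs[s.pore_diameter]
        ratio = snr(ref, s)
        rows.append(
            {
                "modification": s.label,
                "pore_diameter": s.pore_diameter,
                "delta_g": ref.conductance - s.conductance,
                "snr": ratio,
                "gamma": gamma(ref, s),
                "detectable": ratio > threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "modification",
            "pore_diameter",
            "delta_g",
            "snr",
            "gamma",
            "detectable",
        ],
    )
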