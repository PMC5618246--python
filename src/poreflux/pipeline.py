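"""End-to-end experiment orchestration.

Glue that wires the drift-diffusion simulator to the current, I-V and
detection analyses: sweep voltages to build an I-V dataset, measure a
single pore/nucleoside conductance with block-averaged errors, and scan
nucleosides across pore diameters into conductance summaries.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .current_analysis import analyze_trajectory
from .detection_metrics import ConductanceSummary
from .iv_conductance import IVDataset, IVPoint, fit_iv
from .synthetic_electrolyte import (
    NUCLEOSIDE_RADII_NM,
    ObstacleSpec,
    SimulationConfig,
    SlabSpec,
    run_simulation,
)

__all__ = [
    "derive_seed",
    "measure_iv",
    "measure_conductance",
    "nucleoside_summaries",
]

#: Voltage schedule of the reference I-V protocol, V.
DEFAULT_VOLTAGES = (-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0)


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic child seed below 2**31 for run ``indices``."""
    ss = np.random.SeedSequence([base_seed, *indices])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def measure_iv(
    base_config: SimulationConfig,
    voltages: tuple[float, ...] = DEFAULT_VOLTAGES,
    equilibration_fraction: float = 0.2,
    linear_range: tuple[float, float] = (-2.0, 2.0),
) -> IVDataset:
    """Run one simulation per voltage and fit the I-V line.

    Each voltage gets its own seed derived from ``base_config.seed`` so
    runs are independent but the whole sweep is reproducible.
    """
    points = []
    for k, v in enumerate(sorted(voltages)):
        config = replace(
            base_config, voltage=v, seed=derive_seed(base_config.seed, k)
        )
        traj = run_simulation(config)
        trace = analyze_trajectory(
            traj, equilibration_fraction=equilibration_fraction
        )
        points.append(IVPoint(voltage=v, current=trace.mean, error=trace.error))
    return fit_iv(points, linear_range=linear_range)


def measure_conductance(
    config: SimulationConfig,
    label: str = "empty",
    equilibration_fraction: float = 0.2,
) -> ConductanceSummary:
    """Single-voltage conductance G = I/V with block-propagated error.

    Cheaper than a full I-V sweep; adequate whenever the run sits inside
    the Ohmic range, which the +/-2 V protocol guarantees here.
    """
    if config.voltage == 0:
        raise ValueError("conductance needs a nonzero applied voltage")
    if config.slab is None:
        raise ValueError("conductance summaries describe a pore (slab) system")
    trace = analyze_trajectory(
        run_simulation(config), equilibration_fraction=equilibration_fraction
    )
    v = config.voltage
    return ConductanceSummary(
        label=label,
        pore_diameter=config.slab.pore_diameter,
        conductance=trace.mean / v,
        conductance_error=trace.error / abs(v),
    )


def nucleoside_summaries(
    base_config: SimulationConfig,
    pore_diameters: tuple[float, ...],
    labels: tuple[str, ...] = ("U", "cm5U", "mcm5U", "mcm5s2U", "mcm5Um"),
    voltage: float = 2.0,
    equilibration_fraction: float = 0.2,
) -> list[ConductanceSummary]:
    """Conductance summaries for every (pore diameter, nucleoside) pair.

    The slab is centered in the box; each nucleoside becomes an
    excluded-volume sphere of its default effective radius at the pore
    center.  Matched seeds: at a given diameter every nucleoside run
    shares the same child seed so conductance differences are not
    swamped by independent-seed noise.
    """
    lz = base_config.box_lengths[2]
    center = (
        base_config.box_lengths[0] / 2,
        base_config.box_lengths[1] / 2,
        lz / 2,
    )
    out = []
    for i, d in enumerate(pore_diameters):
        slab = SlabSpec(pore_diameter=d, center_z=lz / 2)
        seed = derive_seed(base_config.seed, i)
        for label in labels:
            obstacle = ObstacleSpec(
                radius=NUCLEOSIDE_RADII_NM[label], center=center, label=label
            )
            config = replace(
                base_config,
                slab=slab,
                obstacle=obstacle,
                voltage=voltage,
                seed=seed,
            )
            out.append(
                measure_conductance(
                    config,
                    label=label,
                    equilibration_fraction=equilibration_fraction,
                )
            )
    return out
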