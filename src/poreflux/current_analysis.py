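"""Ionic current from ion trajectories.

The instantaneous current through a periodic box under a z-directed bias
is estimated from the charge-weighted z displacements of all ions between
consecutive saved frames:

    I(t) = 1 / (dt * Lz) * sum_i q_i * [z_i(t) - z_i(t - dt)]

with dt the saved-frame spacing and Lz the box length along the field.
Displacements are taken under the minimum-image convention, which is
exact as long as no ion physically travels more than Lz/2 between saved
frames.  Summaries discard an equilibration transient and estimate the
error bar on the mean current by splitting the production series into
five contiguous blocks and taking the standard deviation of the block
means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import IonTrajectory, read_trajectory
from .units import CURRENT_UNIT_NA

__all__ = [
    "IonTrajectory",
    "CurrentTrace",
    "unwrap_displacement",
    "instantaneous_current",
    "species_currents",
    "running_average",
    "summarize",
    "trace_frame",
    "analyze_trajectory",
]


@dataclass
class CurrentTrace:
    """Summary of an instantaneous current series.

    ``instantaneous`` and ``running_average`` cover the production
    (post-equilibration) part only; ``equilibration_cut`` records how many
    leading frame-pairs were discarded.  ``error`` is the standard
    deviation of the block means (sample std, ddof=1).
    """

    times: np.ndarray
    instantaneous: np.ndarray
    running_average: np.ndarray
    equilibration_cut: int
    block_means: np.ndarray
    mean: float
    error: float


def unwrap_displacement(
    z_now: np.ndarray | float, z_prev: np.ndarray | float, lz: float
) -> np.ndarray | float:
    """Minimum-image displacement along a periodic axis of length ``lz``.

    The raw difference is shifted by a multiple of ``lz`` so the result
    lies in [-lz/2, lz/2].
    """
    if lz <= 0:
        raise ValueError("box length must be positive")
    delta = np.asarray(z_now, dtype=float) - np.asarray(z_prev, dtype=float)
    out = delta - lz * np.round(delta / lz)
    return out if out.ndim else float(out)


def instantaneous_current(traj: IonTrajectory) -> np.ndarray:
    """Per-frame-pair ionic current, nA (one value per consecutive pair)."""
    if traj.n_frames < 2:
        raise ValueError("no displacements: trajectory needs at least 2 frames")
    dz = unwrap_displacement(traj.frames[1:, :, 2], traj.frames[:-1, :, 2], traj.lz)
    weighted = dz @ traj.charges
    return weighted / (traj.frame_spacing * traj.lz) * CURRENT_UNIT_NA


def species_currents(traj: IonTrajectory) -> pd.DataFrame:
    """Per-species current decomposition (convenience; columns sum to total)."""
    if traj.n_frames < 2:
        raise ValueError("no displacements: trajectory needs at least 2 frames")
    dz = unwrap_displacement(traj.frames[1:, :, 2], traj.frames[:-1, :, 2], traj.lz)
    out = {}
    labels = np.asarray(traj.species)
    for sp in dict.fromkeys(traj.species):
        sel = labels == sp
        out[sp] = (
            dz[:, sel]
            @ traj.charges[sel]
            / (traj.frame_spacing * traj.lz)
            * CURRENT_UNIT_NA
        )
    return pd.DataFrame(out)


def running_average(values: np.ndarray) -> np.ndarray:
    """Cumulative mean of a series; the last element is the overall mean."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("running average of an empty series")
    return np.cumsum(values) / np.arange(1, values.size + 1)


def summarize(
    values: np.ndarray,
    equilibration_fraction: float = 0.2,
    n_blocks: int = 5,
    frame_spacing: float = 1.0,
) -> CurrentTrace:
    """Equilibration cut, running average and block-average error estimate.

    The leading ``equilibration_fraction`` of the series is discarded; the
    remaining production frames are split into ``n_blocks`` contiguous
    near-equal blocks.  The reported mean is the mean of the block means
    and the error is their sample standard deviation — a deliberately
    conservative error bar for correlated series.
    """
    values = np.asarray(values, dtype=float)
    if not 0 <= equilibration_fraction < 1:
        raise ValueError("equilibration_fraction must be in [0, 1)")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    cut = int(round(equilibration_fraction * values.size))
    production = values[cut:]
    if production.size < n_blocks:
        raise ValueError(
            f"only {production.size} production frames for {n_blocks} blocks"
        )
    blocks = np.array_split(production, n_blocks)
    block_means = np.array([b.mean() for b in blocks])
    mean = float(block_means.mean())
    error = float(block_means.std(ddof=1)) if n_blocks > 1 else 0.0
    times = (cut + 1 + np.arange(production.size)) * frame_spacing
    return CurrentTrace(
        times=times,
        instantaneous=production,
        running_average=running_average(production),
        equilibration_cut=cut,
        block_means=block_means,
        mean=mean,
        error=error,
    )


def trace_frame(trace: CurrentTrace) -> pd.DataFrame:
    """Tabular view of a trace (times, instantaneous, running average)."""
    return pd.DataFrame(
        {
            "time_ps": trace.times,
            "instantaneous_nA": trace.instantaneous,
            "running_average_nA": trace.running_average,
        }
    )


def analyze_trajectory(
    traj: IonTrajectory | str,
    equilibration_fraction: float = 0.2,
    n_blocks: int = 5,
) -> CurrentTrace:
    """Full pipeline: trajectory (object or file path) -> current summary."""
    if not isinstance(traj, IonTrajectory):
        traj = read_trajectory(traj)
    series = instantaneous_current(traj)
    return summarize(
        series,
        equilibration_fraction=equilibration_fraction,
        n_blocks=n_blocks,
        frame_spacing=traj.frame_spacing,
    )
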