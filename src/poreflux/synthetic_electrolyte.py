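"""Implicit-solvent drift-diffusion simulator for a monovalent electrolyte.

Generates ion trajectories with the statistical structure the downstream
current analysis assumes: non-interacting K+/Cl- point ions performing
overdamped Langevin dynamics in a periodic box, with a uniform electric
field E = V / Lz along z, optionally obstructed by a multilayer slab
pierced by a cylindrical pore and by a centered excluded-volume sphere
standing in for a localized nucleoside.

The per-species diffusion coefficient is the single transport parameter;
:func:`calibrate_diffusion` inverts the Nernst-Einstein relation so the
bulk electrolyte reproduces a chosen specific conductivity by
construction.  Water is implicit: the solvent enters only through D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .trajectory import IonTrajectory
from .units import (
    D_SI_TO_NM2_PER_PS,
    E_CHARGE,
    MOLAR_TO_PER_M3,
    MOLAR_TO_PER_NM3,
    NM,
    thermal_energy,
)

__all__ = [
    "SlabSpec",
    "ObstacleSpec",
    "SimulationConfig",
    "IonEnsemble",
    "NUCLEOSIDE_RADII_NM",
    "ion_pair_count",
    "nernst_einstein_kappa",
    "calibrate_diffusion",
    "accessible_volume",
    "initialize_ensemble",
    "step",
    "run_simulation",
]

#: Default effective excluded-volume radii (nm) for localized nucleosides,
#: ordered by molecular size: canonical pyrimidines < purines, and the
#: wobble-uridine modifications grow with the appended functional group.
#: These are model parameters of the coarse-grained obstacle, not measured
#: molecular radii; the thio modification is given the same radius as
#: mcm5U because sulfur substitution barely changes the steric footprint.
NUCLEOSIDE_RADII_NM: Mapping[str, float] = {
    "U": 0.45,
    "C": 0.46,
    "cm5U": 0.50,
    "mcm5U": 0.55,
    "mcm5s2U": 0.55,
    "mcm5Um": 0.60,
    "A": 0.52,
    "G": 0.54,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SlabSpec:
    """Multilayer slab pierced by a cylindrical pore, normal to z.

    ``thickness`` defaults to a five-layer graphene slab: four interlayer
    gaps of 0.335 nm plus one graphene thickness, 1.675 nm total.
    """

    pore_diameter: float
    center_z: float = 5.0
    thickness: float = 1.675

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ConfigurationError("slab thickness must be positive")
        if self.pore_diameter <= 0:
            raise ConfigurationError("pore_diameter must be positive")


@dataclass(frozen=True)
class ObstacleSpec:
    """Fixed excluded-volume sphere standing in for a localized nucleoside."""

    radius: float
    center: tuple[float, float, float]
    label: str = "U"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ConfigurationError("obstacle radius must be non-negative")

    @classmethod
    def for_nucleoside(
        cls, label: str, center: tuple[float, float, float]
    ) -> "ObstacleSpec":
        """Obstacle with the default effective radius for a nucleoside tag."""
        if label not in NUCLEOSIDE_RADII_NM:
            raise KeyError(
                f"unknown nucleoside {label!r}; known: "
                f"{sorted(NUCLEOSIDE_RADII_NM)}"
            )
        return cls(radius=NUCLEOSIDE_RADII_NM[label], center=center, label=label)


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one drift-diffusion run.

    Defaults reproduce the reference system: a 5.16 x 5.10 x 10.0 nm^3
    periodic box of 1.0 M monovalent electrolyte at 300 K, with per-species
    diffusion coefficients calibrated so the bulk specific conductivity is
    14.7 S/m.  Voltage is applied along z as a uniform field E = V / Lz.
    """

    seed: int
    n_steps: int
    box_lengths: tuple[float, float, float] = (5.16, 5.10, 10.0)
    concentration: float = 1.0
    temperature: float = 300.0
    voltage: float = 0.0
    timestep: float = 1.0
    save_every: int = 1
    equilibration_steps: int = 0
    diffusion_coefficients: Mapping[str, float] | None = None
    slab: SlabSpec | None = None
    obstacle: ObstacleSpec | None = None

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.box_lengths):
            raise ConfigurationError("box_lengths must be positive")
        if self.concentration < 0:
            raise ConfigurationError("concentration must be non-negative")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        if self.timestep <= 0:
            raise ConfigurationError("timestep must be positive")
        if self.n_steps < 0 or self.equilibration_steps < 0:
            raise ConfigurationError("step counts must be non-negative")
        if self.n_steps and self.n_steps <= self.equilibration_steps:
            raise ConfigurationError(
                "n_steps must exceed equilibration_steps"
            )
        if self.save_every < 1:
            raise ConfigurationError("save_every must be >= 1")
        self.validate_geometry()

    def validate_geometry(self) -> None:
        lx, ly, lz = self.box_lengths
        if self.slab is not None:
            if self.slab.pore_diameter >= min(lx, ly):
                raise ConfigurationError(
                    "pore_diameter must be smaller than the in-plane box"
                )
            if self.slab.thickness >= lz:
                raise ConfigurationError("slab thicker than the box")
            if not 0 <= self.slab.center_z <= lz:
                raise ConfigurationError("slab center outside the box")
        if self.obstacle is not None:
            if any(
                not 0 <= c <= l
                for c, l in zip(self.obstacle.center, self.box_lengths)
            ):
                raise ConfigurationError("obstacle center outside the box")
            if (
                self.slab is not None
                and self.obstacle.radius >= self.slab.pore_diameter / 2
            ):
                warnings.warn(
                    "obstacle radius does not fit inside the pore; the pore "
                    "is fully occluded at its waist",
                    stacklevel=2,
                )

    def resolved_diffusion(self) -> dict[str, float]:
        """Per-species diffusion coefficients, m^2/s.

        When unset, both species are calibrated via Nernst-Einstein to the
        reference bulk conductivity of 14.7 S/m at the configured
        concentration and temperature.
        """
        if self.diffusion_coefficients is not None:
            return dict(self.diffusion_coefficients)
        d = calibrate_diffusion(14.7, self.concentration, self.temperature)
        return {"K": d, "CL": d}

    @property
    def frame_spacing(self) -> float:
        """Time between saved frames, ps."""
        return self.timestep * self.save_every


@dataclass
class IonEnsemble:
    """Instantaneous state of the ion system (positions wrapped into the box)."""

    positions: np.ndarray
    charges: np.ndarray
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if abs(self.charges.sum()) > 1e-9:
            raise ValueError("ensemble must be charge neutral")

    @property
    def n_ions(self) -> int:
        return self.charges.shape[0]


def ion_pair_count(concentration: float, box_volume: float) -> int:
    """Number of cation/anion pairs for a molar concentration and nm^3 volume.

    Rounds ``concentration * N_A * volume`` to the nearest integer, so a
    1.0 M electrolyte in a 263.16 nm^3 box holds 158 pairs.
    """
    if concentration < 0 or box_volume <= 0:
        raise ValueError("concentration must be >= 0 and volume > 0")
    return int(round(concentration * MOLAR_TO_PER_NM3 * box_volume))


def nernst_einstein_kappa(
    diffusion: Mapping[str, float] | float,
    concentration: float,
    temperature: float = 300.0,
) -> float:
    """Specific conductivity (S/m) from the Nernst-Einstein relation.

    kappa = sum_i n_i q_i^2 D_i / (k_B T) for two monovalent species at
    number density n = concentration * N_A.
    """
    if concentration < 0 or temperature <= 0:
        raise ValueError("invalid concentration or temperature")
    n = concentration * MOLAR_TO_PER_M3
    if isinstance(diffusion, Mapping):
        d_values = list(diffusion.values())
    else:
        d_values = [diffusion, diffusion]
    return sum(n * E_CHARGE**2 * d / thermal_energy(temperature) for d in d_values)


def calibrate_diffusion(
    kappa_target: float, concentration: float, temperature: float = 300.0
) -> float:
    """Diffusion coefficient (m^2/s) reproducing a bulk conductivity.

    Inverts Nernst-Einstein for two species of equal D and unit charge:
    D = kappa k_B T / (2 n e^2).  For 14.7 S/m at 1.0 M and 300 K this
    gives 1.97e-9 m^2/s.
    """
    if kappa_target <= 0 or concentration <= 0 or temperature <= 0:
        raise ValueError(
            "kappa_target, concentration and temperature must be positive"
        )
    n = concentration * MOLAR_TO_PER_M3
    return kappa_target * thermal_energy(temperature) / (2 * n * E_CHARGE**2)


def _excluded_mask(positions: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """True for positions inside slab material or the obstacle sphere."""
    mask = np.zeros(len(positions), dtype=bool)
    slab = config.slab
    if slab is not None:
        lx, ly, _ = config.box_lengths
        in_layer = (
            np.abs(positions[:, 2] - slab.center_z) < slab.thickness / 2
        )
        r_xy = np.hypot(positions[:, 0] - lx / 2, positions[:, 1] - ly / 2)
        mask |= in_layer & (r_xy >= slab.pore_diameter / 2)
    obs = config.obstacle
    if obs is not None and obs.radius > 0:
        d2 = ((positions - np.asarray(obs.center)) ** 2).sum(axis=1)
        mask |= d2 < obs.radius**2
    return mask


def accessible_volume(config: SimulationConfig) -> float:
    """Box volume minus slab material and obstacle, nm^3.

    The obstacle sphere is assumed to sit inside the pore lumen (its usual
    placement); overlap of the sphere with slab material is not
    double-counted beyond clipping the sphere to the slab region.
    """
    lx, ly, lz = config.box_lengths
    vol = lx * ly * lz
    if config.slab is not None:
        a_pore = np.pi * (config.slab.pore_diameter / 2) ** 2
        vol -= (lx * ly - a_pore) * config.slab.thickness
    if config.obstacle is not None:
        vol -= 4 / 3 * np.pi * config.obstacle.radius**3
    return max(vol, 0.0)


def initialize_ensemble(
    config: SimulationConfig, rng: np.random.Generator
) -> IonEnsemble:
    """Place ion pairs uniformly in the accessible region of the box.

    The pair count follows the configured concentration applied to the
    accessible (solvent) volume, mirroring how a solvated system with an
    embedded slab holds fewer ions than the blank electrolyte.
    """
    n_pairs = ion_pair_count(config.concentration, accessible_volume(config))
    n = 2 * n_pairs
    box = np.asarray(config.box_lengths)
    positions = np.empty((n, 3))
    placed = 0
    while placed < n:
        batch = rng.uniform(0.0, 1.0, size=(max(n - placed, 16), 3)) * box
        ok = ~_excluded_mask(batch, config)
        take = batch[ok][: n - placed]
        positions[placed : placed + len(take)] = take
        placed += len(take)
    charges = np.concatenate([np.ones(n_pairs), -np.ones(n_pairs)])
    species = ["K"] * n_pairs + ["CL"] * n_pairs
    return IonEnsemble(positions=positions, charges=charges, species=species)


def step(
    ensemble: IonEnsemble,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    diffusion_noise: bool = True,
) -> IonEnsemble:
    """Advance the ensemble by one overdamped Langevin timestep.

    The update per ion is dr = (D q E / k_B T) dt zhat + sqrt(2 D dt) xi
    with xi a standard normal per axis; positions are wrapped periodically
    and moves into slab material or the obstacle are rejected (the ion
    keeps its previous position for that step).  ``diffusion_noise=False``
    suppresses the stochastic term (drift-only; used for limit checks).
    """
    if config.timestep == 0:
        return ensemble
    drift, sigma = _step_coefficients(config, ensemble)
    positions = _advance(
        ensemble.positions,
        config,
        rng,
        drift,
        sigma if diffusion_noise else np.zeros_like(sigma),
    )
    return IonEnsemble(
        positions=positions, charges=ensemble.charges, species=ensemble.species
    )


def _step_coefficients(
    config: SimulationConfig, ensemble: IonEnsemble
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ion drift displacement (nm, along z) and noise sigma (nm) per step."""
    kt = thermal_energy(config.temperature)
    e_field = config.voltage / (config.box_lengths[2] * NM)
    d_map = config.resolved_diffusion()
    labels = np.asarray(ensemble.species)
    d_si = np.empty(ensemble.n_ions)
    for sp in dict.fromkeys(ensemble.species):
        d_si[labels == sp] = d_map.get(sp, next(iter(d_map.values())))
    # drift velocity mu q E with mu = D / kT, converted m/s -> nm/ps
    v_drift = d_si / kt * ensemble.charges * E_CHARGE * e_field * 1e-3
    drift = v_drift * config.timestep
    sigma = np.sqrt(2.0 * d_si * D_SI_TO_NM2_PER_PS * config.timestep)
    return drift, sigma


def _advance(
    positions: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    drift: np.ndarray,
    sigma: np.ndarray,
) -> np.ndarray:
    """One Langevin update of a position array (precomputed coefficients)."""
    box = np.asarray(config.box_lengths)
    disp = sigma[:, None] * rng.standard_normal(positions.shape)
    disp[:, 2] += drift
    proposed = np.mod(positions + disp, box)
    if config.slab is not None or config.obstacle is not None:
        rejected = _excluded_mask(proposed, config)
        proposed[rejected] = positions[rejected]
    return proposed


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    _njit = None


def _kernel_source():
    """Compiled inner loop: advance positions over a chunk of steps."""

    def kernel(
        positions,
        noise,
        drift,
        sigma,
        box,
        has_slab,
        slab_cz,
        slab_half,
        pore_r,
        has_obs,
        obs_cx,
        obs_cy,
        obs_cz,
        obs_r2,
        save_every,
        step_offset,
        frames,
        saved_offset,
    ):
        n_steps, n_ions = noise.shape[0], noise.shape[1]
        saved = saved_offset
        for t in range(n_steps):
            for i in range(n_ions):
                px = positions[i, 0] + sigma[i] * noise[t, i, 0]
                py = positions[i, 1] + sigma[i] * noise[t, i, 1]
                pz = positions[i, 2] + (sigma[i] * noise[t, i, 2] + drift[i])
                px = px % box[0]
                py = py % box[1]
                pz = pz % box[2]
                blocked = False
                if has_slab:
                    dz = pz - slab_cz
                    if -slab_half < dz < slab_half:
                        rx = px - box[0] / 2
                        ry = py - box[1] / 2
                        if rx * rx + ry * ry >= pore_r * pore_r:
                            blocked = True
                if not blocked and has_obs:
                    ox = px - obs_cx
                    oy = py - obs_cy
                    oz = pz - obs_cz
                    if ox * ox + oy * oy + oz * oz < obs_r2:
                        blocked = True
                if not blocked:
                    positions[i, 0] = px
                    positions[i, 1] = py
                    positions[i, 2] = pz
            if (step_offset + t + 1) % save_every == 0:
                for i in range(n_ions):
                    frames[saved, i, 0] = positions[i, 0]
                    frames[saved, i, 1] = positions[i, 1]
                    frames[saved, i, 2] = positions[i, 2]
                saved += 1
        return saved

    return kernel


_advance_chunk = (
    _njit(cache=True)(_kernel_source()) if _njit is not None else _kernel_source()
)

#: Steps per RNG draw in :func:`run_simulation`; noise for a chunk is drawn
#: as one (chunk, n, 3) block, which consumes the generator stream exactly
#: as per-step (n, 3) draws would.
_CHUNK_STEPS = 4096


def run_simulation(config: SimulationConfig) -> IonTrajectory:
    """Run a full drift-diffusion simulation and return the saved trajectory.

    Frames are saved every ``save_every`` steps (the first saved frame is
    after the first interval, so ``n_steps = 0`` yields an empty
    trajectory).  The run is fully reproducible from ``config.seed``: ion
    placement and every noise draw come from one seeded generator.
    """
    config.validate_geometry()
    rng = np.random.default_rng(config.seed)
    ensemble = initialize_ensemble(config, rng)
    drift, sigma = _step_coefficients(config, ensemble)
    n_frames = config.n_steps // config.save_every
    frames = np.empty((n_frames, ensemble.n_ions, 3))
    positions = ensemble.positions.copy()
    box = np.asarray(config.box_lengths, dtype=float)
    slab, obs = config.slab, config.obstacle
    saved = 0
    done = 0
    while done < config.n_steps:
        m = min(_CHUNK_STEPS, config.n_steps - done)
        noise = rng.standard_normal((m, ensemble.n_ions, 3))
        saved = _advance_chunk(
            positions,
            noise,
            drift,
            sigma,
            box,
            slab is not None,
            slab.center_z if slab is not None else 0.0,
            slab.thickness / 2 if slab is not None else 0.0,
            slab.pore_diameter / 2 if slab is not None else 0.0,
            obs is not None and obs.radius > 0,
            obs.center[0] if obs is not None else 0.0,
            obs.center[1] if obs is not None else 0.0,
            obs.center[2] if obs is not None else 0.0,
            obs.radius**2 if obs is not None else 0.0,
            config.save_every,
            done,
            frames,
            saved,
        )
        done += m
    return IonTrajectory(
        frames=frames[:saved],
        charges=ensemble.charges,
        frame_spacing=config.frame_spacing,
        box_lengths=np.asarray(config.box_lengths),
        species=list(ensemble.species),
    )
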