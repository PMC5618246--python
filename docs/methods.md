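# Methods

## Scope and model

`poreflux` models the ionic-current readout of a multilayer graphene
nanopore immersed in a 1.0 M KCl-like electrolyte, and asks whether a
nucleoside parked in the pore lumen — in particular wobble-uridine
modifications (cm⁵U, mcm⁵U, mcm⁵s²U, mcm⁵Um) — changes the pore
resistance by enough to be detected. The reference study conditions are
a 5.16 × 5.10 × 10.0 nm³ periodic box at 300 K, a five-layer armchair
graphene slab pierced by a 1.5–4.0 nm cylindrical pore, and applied
biases within ±2 V along z.

The electrolyte is simulated at the implicit-solvent, non-interacting
level: each ion performs overdamped Langevin (drift–diffusion) dynamics

    Δr = (D q E / k_B T) Δt ẑ + √(2 D Δt) ξ,   ξ ~ N(0, 1) per axis,

with a uniform field E = V / L_z. Water enters only through the
diffusion coefficient D, which is set by inverting the Nernst–Einstein
relation κ = Σᵢ nᵢqᵢ²Dᵢ / (k_B T) so that the bulk specific conductivity
equals a chosen target — 14.7 S/m for the reference 1 M electrolyte,
giving D = 1.97 × 10⁻⁹ m²/s for both species. By construction the blank
box then reproduces that conductivity through the whole measurement
pipeline, which is the property the downstream analyses consume.
Ion–ion interactions, explicit water, electrostatic self-consistency and
nucleoside dynamics are deliberately absent.

Excluded volume (slab material outside the pore radius; a static sphere
standing in for the localized nucleoside) is enforced by move rejection:
a proposed step ending inside an excluded region leaves that ion in
place for that step. Rejection preserves the uniform equilibrium
density in the accessible region, which is what conductance ratios need;
it does not conserve momentum, which nothing here consumes.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| box | 5.16 × 5.10 × 10.0 nm³ | reference electrolyte box |
| concentration | 1.0 M | 158 ion pairs in the blank box (nearest integer to c·N_A·V); slab systems count pairs from the accessible volume (~133 pairs for the 1.5 nm five-layer system) |
| temperature | 300 K | thermostat setpoint of the reference study |
| timestep | 1 ps | equals the frame-save cadence; with no interparticle forces the Euler–Maruyama update is exact in distribution at any Δt, so nothing is gained by sub-stepping. `save_every` decouples saved-frame spacing from the integrator step when desired |
| D (per species) | 1.97 × 10⁻⁹ m²/s | Nernst–Einstein calibration to κ = 14.7 S/m at 1 M, 300 K |
| slab thickness | 1.675 nm | five layers at 0.335 nm AA stacking: 4 gaps + one graphene thickness; also the default effective pore height h in G = π d² κ / 4h |
| keep-annulus (trimming) | 1.3 nm | the nonbonded-cutoff reading: interior-layer atoms farther than the cutoff from the pore wall cannot influence pore contents |
| equilibration fraction | 0.2 | 2/10 ns (blank and empty-pore runs) and 10/50 ns (nucleoside runs) both reduce to one fifth |
| blocks | 5 | block-averaged error bar = sample standard deviation of the five block means — the conservative reading of "block averages were used to estimate the error bars" (not sd/√5; configurable) |
| obstacle radii | U 0.45, C 0.46, cm⁵U 0.50, A 0.52, G 0.54, mcm⁵U = mcm⁵s²U 0.55, mcm⁵Um 0.60 nm | ordered by molecular size; free model parameters, not measured radii. Giving mcm⁵s²U the mcm⁵U radius encodes that thio substitution is nearly size-neutral — the steric model cannot (and does not try to) reproduce the resistance anomaly that chemistry causes |
| detectability threshold | SNR > 1 | sub-one SNR = undetectable |

## Measurement protocols

**Current estimator.** I(t) = (1/Δt L_z) Σᵢ qᵢ [zᵢ(t) − zᵢ(t−Δt)] with
minimum-image displacements; at a 1 ps cadence no physical displacement
approaches L_z/2, so wrapping is unambiguous. One unit of e·nm/(ps·nm)
is 160.218 nA; all unit conversions live in `poreflux.units`.

**Empty-pore characterization.** One run per bias on the schedule
0, ±0.5, ±1, ±1.5, ±2 V; ordinary least squares with a free intercept
over the ±2 V window gives G (slope, nS) and R = 1/G (MΩ). The
intercept is a diagnostic; |intercept| > 3σ logs a warning. Unweighted
OLS by default; inverse-variance weighting is not implemented because
per-point errors are comparable across biases.

**Detection runs.** Conductance summaries for nucleoside-in-pore
systems are measured at a single 0.5 V bias as G = Ī/V with the
block-derived error. The bias choice is deliberate: with a uniform
field, transport at 2 V is advection-dominated and rate-limited by ions
finding the pore mouth, which suppresses the steric blockade signal
(ΔG between U and mcm⁵Um in a 1.5 nm pore is ~0.3 nS at 2 V but
~1.8 nS at 0.5 V). At 0.5 V the Péclet number over the pore height is
near one and the measured conductance is bias-independent, i.e. the
system is inside its own Ohmic window. SNR = |G_U − G_mod| /
(σ_U + σ_mod); gamma = 100 (R_mod − R_U)/R_U.

## Problem sizes used by the test suite and acceptance script

The bulk-conductivity recovery uses 10⁵ saved frames per bias across
nine biases (the acceptance script) or 2 × 10⁴ frames across four
biases (the test), both comfortably inside the stochastic tolerance:
the standard error of the fitted conductivity is ≈ 0.2% at the script's
sizes, and the dominant deviation is the deterministic −0.3% from
rounding 158.47 ion pairs to 158. Detection-trend tests use 1.5 × 10⁵
frames per run and average per-seed SNR over four replicate seeds,
because a single 5-block error estimate has ~50% relative scatter and
single-run SNRs at 2–3 nm pores would order unreliably.

## What the synthetic data does and does not emulate

The generator reproduces: Ohmic bulk conduction at a calibrated
conductivity, charge-neutral ion statistics, monotone pore conductance
in pore area, steric current blockade by a localized obstacle, and
block-structured noise on the current. It does not reproduce: field
focusing into the pore (the field is uniform), ion–ion correlations,
electro-osmosis, hydration-shell effects, chemistry-specific
nucleoside–wall interactions, or concentration polarization. Passing
trend tests therefore show that the *analysis pipeline* orders signals
correctly under the model's assumptions — not that a real device would
show the same absolute numbers.

Two consequences are worth stating plainly:

* **Conductance vs area.** All-atom MD (and experiment) find pore
  conductance proportional to cross-sectional area with a near-zero
  intercept, matching G = π d² κ/4h. In this model the uniform field
  adds a series bulk-and-access resistance, and at measurement biases
  the current is partially mouth-capture-limited, so measured G grows
  roughly linearly in *diameter* over 1.5–3.0 nm and an area-linear fit
  has a large positive intercept (~60% of the smallest conductance).
  The corresponding acceptance check fails and is expected to fail; the
  theory formula itself, and the long-pore limit where the cylinder
  dominates (h ≫ d; measured/theory = 0.95 at h = 7 nm, d = 1 nm), are
  verified instead.
* **mcm⁵s²U.** Its resistance anomaly is chemical, not steric; the
  excluded-volume model represents it only through a manually chosen
  effective radius.

## Numerical choices

* Trajectories are advanced in chunks: noise for a few thousand steps
  is drawn as one block from the seeded generator (identical stream to
  per-step draws) and consumed by a numba-compiled loop; `step()`
  remains a pure-numpy reference path and the two are asserted
  equivalent in the tests. Runs are bit-reproducible from the config
  seed.
* Carving keeps atoms at exactly the pore radius (strict inequality for
  removal), making carve and trim idempotent and counts reproducible.
* Block splitting uses contiguous near-equal blocks (`array_split`);
  the reported mean is the mean of block means.
* Degenerate inputs: zero-step runs return empty trajectories with
  valid metadata; Δt = 0 steps return the input unchanged; zero noise
  with zero field leaves positions fixed; a zero-noise SNR with
  differing means reports `inf` rather than raising.
* PDB/XYZ structure files are written in ångström (format convention)
  while the API is in nm; trajectory files are written in nm with a
  JSON metadata sidecar carrying charges, box and frame spacing.

## Known limitations

Beyond the emulation gaps above: the obstacle is static (no harmonic
restraint dynamics), conductance summaries assume the single-bias
measurement sits in the linear regime, and the access-resistance
physics of short pores is only qualitatively present. Absolute
per-nucleoside resistances are not comparable to the all-atom values;
only their ordering and the direction of the pore-size trends are.
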