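"""Drift-diffusion electrolyte: calibration, stepping, trajectories."""

from dataclasses import replace

import numpy as np
import pytest

from poreflux.current_analysis import analyze_trajectory, instantaneous_current
from poreflux.synthetic_electrolyte import (
    ConfigurationError,
    IonEnsemble,
    ObstacleSpec,
    SimulationConfig,
    SlabSpec,
    _excluded_mask,
    accessible_volume,
    calibrate_diffusion,
    initialize_ensemble,
    ion_pair_count,
    nernst_einstein_kappa,
    run_simulation,
    step,
)
from poreflux.units import E_CHARGE, NM, thermal_energy

REFERENCE_BOX_VOLUME = 5.16 * 5.10 * 10.0  # nm^3


class TestIonPairCount:
    def test_zero_concentration(self):
        assert ion_pair_count(0.0, REFERENCE_BOX_VOLUME) == 0

    def test_reference_box_at_one_molar(self):
        # 1.0 * 6.022e23 / L * 2.6316e-22 L = 158.47 -> 158
        assert ion_pair_count(1.0, REFERENCE_BOX_VOLUME) == 158

    def test_linearity_up_to_rounding(self):
        one = ion_pair_count(1.0, REFERENCE_BOX_VOLUME)
        two = ion_pair_count(1.0, 2 * REFERENCE_BOX_VOLUME)
        assert abs(two - 2 * one) <= 1

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            ion_pair_count(-1.0, REFERENCE_BOX_VOLUME)
        with pytest.raises(ValueError):
            ion_pair_count(1.0, -5.0)


class TestDiffusionCalibration:
    def test_reference_conductivity(self):
        # D = kappa k_B T / (2 n e^2) for 14.7 S/m, 1 M, 300 K
        assert calibrate_diffusion(14.7, 1.0, 300.0) == pytest.approx(
            1.97e-9, rel=1e-2
        )

    def test_linearity_in_target(self):
        d1 = calibrate_diffusion(7.0, 1.0, 300.0)
        d2 = calibrate_diffusion(14.0, 1.0, 300.0)
        assert d2 == pytest.approx(2 * d1)

    def test_round_trip_with_nernst_einstein(self):
        d = calibrate_diffusion(14.7, 1.0, 300.0)
        assert nernst_einstein_kappa(d, 1.0, 300.0) == pytest.approx(14.7)

    def test_zero_concentration_raises(self):
        with pytest.raises(ValueError):
            calibrate_diffusion(14.7, 0.0, 300.0)


class TestConfigValidation:
    def test_negative_box_raises(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=1, n_steps=10, box_lengths=(-1.0, 5.0, 5.0))

    def test_equilibration_exceeding_steps_raises(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=1, n_steps=10, equilibration_steps=10)

    def test_pore_wider_than_box_raises(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(
                seed=1, n_steps=10, slab=SlabSpec(pore_diameter=5.5)
            )

    def test_oversized_obstacle_warns(self):
        with pytest.warns(UserWarning, match="occluded"):
            SimulationConfig(
                seed=1,
                n_steps=10,
                slab=SlabSpec(pore_diameter=1.5),
                obstacle=ObstacleSpec(radius=0.9, center=(2.58, 2.55, 5.0)),
            )


class TestInitialization:
    def test_charge_neutral_and_inside_box(self, bulk_config, rng):
        ens = initialize_ensemble(bulk_config, rng)
        assert ens.charges.sum() == 0
        assert ens.n_ions == 2 * 158
        box = np.asarray(bulk_config.box_lengths)
        assert (ens.positions >= 0).all() and (ens.positions < box).all()

    def test_no_ion_inside_slab_or_obstacle(self, rng):
        config = SimulationConfig(
            seed=3,
            n_steps=10,
            slab=SlabSpec(pore_diameter=2.0, center_z=5.0),
            obstacle=ObstacleSpec(radius=0.5, center=(2.58, 2.55, 5.0)),
        )
        ens = initialize_ensemble(config, rng)
        assert not _excluded_mask(ens.positions, config).any()

    def test_slab_reduces_ion_count(self, rng, bulk_config, pore_config):
        bulk = initialize_ensemble(bulk_config, rng)
        pore = initialize_ensemble(pore_config, rng)
        # the reference five-layer slab displaces ~25 ion pairs
        assert pore.n_ions < bulk.n_ions
        assert accessible_volume(pore_config) < accessible_volume(bulk_config)


class TestStep:
    def test_zero_field_zero_diffusion_static(self, bulk_config, rng):
        config = replace(
            bulk_config, voltage=0.0, diffusion_coefficients={"K": 0.0, "CL": 0.0}
        )
        ens = initialize_ensemble(config, rng)
        after = step(ens, config, rng)
        np.testing.assert_array_equal(after.positions, ens.positions)

    def test_drift_only_displacement_is_mobility_times_field(self, rng):
        config = SimulationConfig(seed=1, n_steps=10, voltage=1.0)
        ens = IonEnsemble(
            positions=np.array([[2.0, 2.0, 5.0], [3.0, 3.0, 5.0]]),
            charges=np.array([1.0, -1.0]),
            species=["K", "CL"],
        )
        after = step(ens, config, rng, diffusion_noise=False)
        d = config.resolved_diffusion()["K"]
        e_field = config.voltage / (config.box_lengths[2] * NM)
        v = d / thermal_energy(config.temperature) * E_CHARGE * e_field  # m/s
        expected_dz = v * 1e-3 * config.timestep  # nm
        assert after.positions[0, 2] - 5.0 == pytest.approx(expected_dz)
        assert after.positions[1, 2] - 5.0 == pytest.approx(-expected_dz)

    def test_mean_drift_matches_mobility_over_many_steps(self, rng):
        config = SimulationConfig(seed=9, n_steps=10, voltage=2.0)
        ens = initialize_ensemble(config, rng)
        n_steps = 400
        total_dz = np.zeros(ens.n_ions)
        prev = ens.positions[:, 2]
        for _ in range(n_steps):
            ens = step(ens, config, rng)
            dz = ens.positions[:, 2] - prev
            dz -= config.box_lengths[2] * np.round(dz / config.box_lengths[2])
            total_dz += dz
            prev = ens.positions[:, 2]
        d = config.resolved_diffusion()["K"]
        e_field = config.voltage / (config.box_lengths[2] * NM)
        v = d / thermal_energy(config.temperature) * E_CHARGE * e_field * 1e-3
        expected = v * config.timestep * n_steps
        observed = (total_dz * ens.charges).mean()  # drift along the charge sign
        sigma = np.sqrt(2 * d * 1e6 * config.timestep * n_steps / ens.n_ions)
        assert observed == pytest.approx(expected, abs=4 * sigma)

    def test_rejected_moves_keep_position_outside_excluded_volume(self, rng):
        config = SimulationConfig(
            seed=5,
            n_steps=10,
            voltage=2.0,
            slab=SlabSpec(pore_diameter=1.5, center_z=5.0),
        )
        ens = initialize_ensemble(config, rng)
        for _ in range(50):
            ens = step(ens, config, rng)
            assert not _excluded_mask(ens.positions, config).any()


class TestRunSimulation:
    def test_zero_steps_empty_trajectory_with_metadata(self):
        traj = run_simulation(SimulationConfig(seed=1, n_steps=0))
        assert traj.n_frames == 0
        assert traj.n_ions == 2 * 158
        assert traj.lz == 10.0

    def test_chunked_run_matches_explicit_step_loop(self, pore_config):
        """The compiled trajectory loop reproduces per-step updates."""
        traj = run_simulation(pore_config)
        rng = np.random.default_rng(pore_config.seed)
        ens = initialize_ensemble(pore_config, rng)
        manual = []
        for _ in range(pore_config.n_steps):
            ens = step(ens, pore_config, rng)
            manual.append(ens.positions.copy())
        np.testing.assert_allclose(traj.frames, np.stack(manual), atol=1e-12)

    def test_same_seed_bit_identical(self, bulk_config):
        t1 = run_simulation(bulk_config)
        t2 = run_simulation(bulk_config)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_different_seeds_differ(self, bulk_config):
        t1 = run_simulation(bulk_config)
        t2 = run_simulation(replace(bulk_config, seed=43))
        assert not np.array_equal(t1.frames, t2.frames)

    def test_save_every_thins_frames_and_scales_spacing(self, bulk_config):
        config = replace(bulk_config, n_steps=100, save_every=10)
        traj = run_simulation(config)
        assert traj.n_frames == 10
        assert traj.frame_spacing == pytest.approx(10 * config.timestep)

    def test_charge_neutrality_every_frame(self, bulk_config):
        traj = run_simulation(bulk_config)
        assert traj.charges.sum() == 0

    def test_voltage_reversal_flips_current(self):
        means = []
        for v in (1.5, -1.5):
            config = SimulationConfig(seed=11, n_steps=3000, voltage=v)
            trace = analyze_trajectory(run_simulation(config))
            means.append((trace.mean, trace.error))
        (m_pos, e_pos), (m_neg, e_neg) = means
        assert m_pos > 0 > m_neg
        assert m_pos + m_neg == pytest.approx(0.0, abs=3 * (e_pos + e_neg))

    def test_zero_voltage_current_consistent_with_zero(self):
        config = SimulationConfig(seed=13, n_steps=4000, voltage=0.0)
        series = instantaneous_current(run_simulation(config))
        stderr = series.std(ddof=1) / np.sqrt(series.size)
        assert abs(series.mean()) < 3 * stderr

    def test_obstacle_reduces_current_in_pore(self):
        slab = SlabSpec(pore_diameter=1.5, center_z=5.0)
        means = []
        for radius in (0.0, 0.6):
            obstacle = (
                ObstacleSpec(radius=radius, center=(2.58, 2.55, 5.0))
                if radius
                else None
            )
            config = SimulationConfig(
                seed=17, n_steps=20000, voltage=0.5, slab=slab, obstacle=obstacle
            )
            means.append(analyze_trajectory(run_simulation(config)).mean)
        assert means[1] < means[0]

    def test_conductance_monotone_in_pore_diameter(self):
        means = []
        for d in (1.5, 2.5, 4.0):
            config = SimulationConfig(
                seed=19,
                n_steps=8000,
                voltage=2.0,
                slab=SlabSpec(pore_diameter=d, center_z=5.0),
            )
            means.append(analyze_trajectory(run_simulation(config)).mean)
        assert means[0] < means[1] < means[2]
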