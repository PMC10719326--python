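"""Metric unit tests against closed forms and hand computations."""

import numpy as np
import pytest

from memanchor import (
    Atom,
    Frame,
    Topology,
    Trajectory,
    block_std,
    density_profile,
    diffusion_coefficient,
    dipole_moment,
    free_energy_profile,
    make_residence_fixture,
    midplane_location,
    msd,
    residence_time,
)
from memanchor.metrics import MSDCurve, center_of_mass


# ---------------------------------------------------------------------------
# residence time
# ---------------------------------------------------------------------------

class TestResidenceTime:
    def test_worked_example_60_percent(self):
        """0.6 of a window within 0.3 nm of the lower leaflet -> 60 %."""
        traj = make_residence_fixture(0.6, 1000)
        topo = traj.topology
        res = residence_time(
            traj, topo.residue_indices("DRUG"), topo.leaflet_indices("lower")
        )
        assert res.value == pytest.approx(60.0, abs=1e-12)

    def test_far_drug_scores_zero_for_both_leaflets(self):
        traj = make_residence_fixture(0.0, 50)
        topo = traj.topology
        drug = topo.residue_indices("DRUG")
        for leaflet in ("upper", "lower"):
            res = residence_time(traj, drug, topo.leaflet_indices(leaflet))
            assert res.value == 0.0

    def test_ten_frame_toy_with_hand_set_distances(self):
        """Distances 0.25 x4 and 0.31 x6 against cutoff 0.3 -> 40 %."""
        atoms = [
            Atom(1, "P", "P", 100.0, 0.0, "DSPC", 1, leaflet="lower",
                 hbond_role="acceptor"),
            Atom(2, "DC", "C", 100.0, 0.0, "DRUG", 2),
        ]
        topo = Topology(atoms)
        dists = [0.25] * 4 + [0.31] * 6
        frames = [
            Frame(float(i), [5, 5, 5],
                  np.array([[2.5, 2.5, 2.5], [2.5, 2.5, 2.5 + d]]))
            for i, d in enumerate(dists)
        ]
        res = residence_time(Trajectory(topo, frames), [1], [0], cutoff=0.3)
        assert res.value == pytest.approx(40.0)

    def test_cutoff_boundary_is_inclusive(self):
        traj = make_residence_fixture(1.0, 5)
        topo = traj.topology
        res = residence_time(traj, topo.residue_indices("DRUG"),
                             topo.leaflet_indices("lower"), cutoff=0.25)
        assert res.value == pytest.approx(100.0)

    def test_monotone_non_decreasing_in_cutoff(self, small_run):
        topo, traj, _ = small_run
        drug = topo.residue_indices("DRUG")
        upper = topo.leaflet_indices("upper")
        values = [
            residence_time(traj, drug, upper, cutoff=c).value
            for c in (0.1, 0.3, 0.5, 1.0, 2.0)
        ]
        assert all(0.0 <= v <= 100.0 for v in values)
        assert values == sorted(values)

    def test_empty_window_raises(self):
        traj = make_residence_fixture(0.5, 10)
        topo = traj.topology
        with pytest.raises(ValueError, match="window"):
            residence_time(traj, topo.residue_indices("DRUG"),
                           topo.leaflet_indices("lower"),
                           window=(1e9, 2e9))


# ---------------------------------------------------------------------------
# block averaging
# ---------------------------------------------------------------------------

class TestBlockStd:
    def test_identical_blocks_give_zero(self):
        assert block_std(np.tile([1.0, 2.0, 3.0], 4), n_blocks=4) == 0.0

    def test_hand_computed_sample_std(self):
        """Block means 10, 20, 30, 40 -> sample std 12.909944."""
        assert block_std(np.array([10.0, 20.0, 30.0, 40.0]),
                         n_blocks=4) == pytest.approx(12.909944, abs=1e-6)

    def test_invariant_under_block_permutation(self):
        rng = np.random.default_rng(2)
        series = rng.normal(size=40)
        blocks = np.split(series, 4)
        s0 = block_std(series, n_blocks=4)
        s1 = block_std(np.concatenate([blocks[i] for i in (2, 0, 3, 1)]),
                       n_blocks=4)
        assert s0 == pytest.approx(s1)

    def test_rejects_fewer_than_two_blocks(self):
        with pytest.raises(ValueError, match="n_blocks"):
            block_std(np.arange(10.0), n_blocks=1)

    def test_rejects_series_shorter_than_blocks(self):
        with pytest.raises(ValueError, match="non-empty"):
            block_std(np.arange(3.0), n_blocks=4)


# ---------------------------------------------------------------------------
# MSD / diffusion
# ---------------------------------------------------------------------------

def _drug_only_traj(positions, box=(50.0, 50.0, 50.0), dt=1.0):
    topo = Topology([Atom(1, "DC", "C", 100.0, 0.0, "DRUG", 1)])
    frames = [
        Frame(dt * i, np.array(box), np.array([p], dtype=float))
        for i, p in enumerate(positions)
    ]
    return Trajectory(topo, frames)


class TestMSD:
    def test_stationary_particle_msd_is_zero(self):
        traj = _drug_only_traj([[1.0, 2.0, 3.0]] * 20)
        curve = msd(traj, [0])
        np.testing.assert_allclose(curve.total, 0.0, atol=1e-12)

    def test_msd_at_zero_lag_is_zero(self, small_run):
        topo, traj, _ = small_run
        curve = msd(traj, topo.residue_indices("DRUG"))
        assert curve.total[0] == 0.0

    def test_straight_line_motion_gives_v2_tau2(self):
        v = np.array([0.02, -0.01, 0.03])
        traj = _drug_only_traj([v * i for i in range(30)])
        curve = msd(traj, [0], max_lag_fraction=0.5)
        expected = np.sum(v**2) * curve.lags**2
        np.testing.assert_allclose(curve.total, expected, rtol=1e-9)

    def test_wrapped_lateral_path_is_unwrapped(self):
        # constant +x velocity that wraps several times in a 5 nm box
        xs = np.mod(0.1 * np.arange(40), 5.0)
        traj = _drug_only_traj([[x, 1.0, 1.0] for x in xs], box=(5.0, 5.0, 5.0))
        curve = msd(traj, [0], max_lag_fraction=0.3)
        np.testing.assert_allclose(curve.total, 0.01 * curve.lags**2, rtol=1e-9)

    def test_wrapped_z_jump_raises_unwrap_error(self):
        zs = np.mod(0.4 * np.arange(20), 5.0)  # wraps: 4.8 -> 0.2 jump
        traj = _drug_only_traj([[1.0, 1.0, z] for z in zs], box=(5.0, 5.0, 5.0))
        with pytest.raises(ValueError, match="unwrapped in z"):
            msd(traj, [0])

    def test_needs_ten_frames(self):
        traj = _drug_only_traj([[0, 0, 0]] * 5)
        with pytest.raises(ValueError, match="10 frames"):
            msd(traj, [0])


class TestDiffusionCoefficient:
    def test_exact_line_6_d_tau_recovers_d_with_r2_one(self):
        D = 3.2e-4
        lags = np.arange(100.0)
        curve = MSDCurve(lags=lags, total=6 * D * lags,
                         per_axis=np.outer(2 * D * lags, [1.0, 1.0, 1.0]))
        res = diffusion_coefficient(curve, dim=3)
        assert res.D == pytest.approx(D, rel=1e-12)
        assert res.fit_r2 == pytest.approx(1.0)
        np.testing.assert_allclose(res.per_axis_D, D, rtol=1e-9)

    def test_negative_slope_clamped_to_zero_with_warning(self):
        lags = np.arange(50.0)
        curve = MSDCurve(lags=lags, total=-0.01 * lags,
                         per_axis=np.outer(-0.01 * lags / 3, np.ones(3)))
        with pytest.warns(UserWarning, match="negative"):
            res = diffusion_coefficient(curve)
        assert res.D == 0.0

    def test_too_few_points_in_window_raises(self):
        lags = np.arange(100.0)
        curve = MSDCurve(lags=lags, total=lags, per_axis=np.zeros((100, 3)))
        with pytest.raises(ValueError, match="3"):
            diffusion_coefficient(curve, fit_window=(10.0, 11.0))

    def test_unit_conversion_to_1e5_cm2_per_s(self):
        lags = np.arange(100.0)
        D = 4.0e-4  # nm^2/ps = 4e-6 cm^2/s = 0.4 x 1e-5 cm^2/s
        curve = MSDCurve(lags=lags, total=6 * D * lags,
                         per_axis=np.outer(2 * D * lags, np.ones(3)))
        res = diffusion_coefficient(curve)
        assert res.D_1e5_cm2_per_s == pytest.approx(0.4, rel=1e-9)


# ---------------------------------------------------------------------------
# density profile
# ---------------------------------------------------------------------------

def _midplane_system(extra_atoms, extra_positions, box=(4.0, 5.0, 10.0)):
    """Two lipid beads defining a mid-plane at z=5 plus caller atoms."""
    atoms = [
        Atom(1, "P", "P", 100.0, 0.0, "DSPC", 1, leaflet="upper",
             hbond_role="acceptor"),
        Atom(2, "P", "P", 100.0, 0.0, "DSPC", 2, leaflet="lower",
             hbond_role="acceptor"),
    ] + extra_atoms
    topo = Topology(atoms)
    pos = np.vstack([[[1.0, 1.0, 7.0], [1.0, 1.0, 3.0]], extra_positions])
    frame = Frame(0.0, np.array(box), pos)
    return topo, Trajectory(topo, [frame])


class TestDensityProfile:
    def test_single_atom_closed_form(self):
        mass = 42.0
        topo, traj = _midplane_system(
            [Atom(3, "DC", "C", mass, 0.0, "DRUG", 3)],
            [[2.0, 2.0, 6.55]],  # z - z0 = 1.55 -> bin [1.5, 1.6)
        )
        prof = density_profile(traj, {"drug": [2]}, bin_width=0.1)
        area = 4.0 * 5.0
        expected = mass * 1.66053906660 / (area * 0.1)
        i = np.searchsorted(prof.bin_edges, 1.55) - 1
        assert prof.values["drug"][i] == pytest.approx(expected, rel=1e-9)
        assert np.count_nonzero(prof.values["drug"]) == 1

    def test_empty_group_gives_all_zero_profile(self):
        topo, traj = _midplane_system([], np.empty((0, 3)))
        prof = density_profile(traj, {"nothing": np.array([], dtype=int)})
        np.testing.assert_array_equal(prof.values["nothing"], 0.0)

    def test_mass_conservation_identity(self, small_run):
        """Sum over bins x bin volume recovers the group mass exactly."""
        topo, traj, _ = small_run
        groups = {"membrane": topo.lipid_indices(),
                  "drug": topo.residue_indices("DRUG")}
        prof = density_profile(traj, groups, bin_width=0.1,
                               z_range=(-6.0, 6.0))
        area = traj.frames[0].box[0] * traj.frames[0].box[1]
        for name, idx in groups.items():
            total = prof.values[name].sum() * area * 0.1 / 1.66053906660
            expected = topo.masses[idx].sum()
            assert total == pytest.approx(expected, rel=1e-9)

    def test_rejects_non_positive_bin_width(self):
        topo, traj = _midplane_system([], np.empty((0, 3)))
        with pytest.raises(ValueError, match="bin_width"):
            density_profile(traj, {}, bin_width=0.0)


# ---------------------------------------------------------------------------
# mid-plane location
# ---------------------------------------------------------------------------

class TestMidplaneLocation:
    def _traj_with_drug_z(self, z_values):
        atoms = [
            Atom(1, "P", "P", 100.0, 0.0, "DSPC", 1, leaflet="upper",
                 hbond_role="acceptor"),
            Atom(2, "P", "P", 100.0, 0.0, "DSPC", 2, leaflet="lower",
                 hbond_role="acceptor"),
            Atom(3, "DC", "C", 100.0, 0.0, "DRUG", 3),
        ]
        topo = Topology(atoms)
        frames = [
            Frame(float(i), [5, 5, 12],
                  np.array([[1, 1, 8.0], [1, 1, 4.0], [1, 1, 6.0 + z]]))
            for i, z in enumerate(z_values)
        ]
        return Trajectory(topo, frames), topo

    def test_drug_fixed_above_midplane(self):
        traj, topo = self._traj_with_drug_z([2.0] * 12)
        upper, lower = midplane_location(traj, [2])
        assert upper.value == pytest.approx(2.0)
        assert upper.n_frames == 12
        assert np.isnan(lower.value) and lower.n_frames == 0

    def test_alternating_sides_give_symmetric_means(self):
        traj, topo = self._traj_with_drug_z([1.5, -1.5] * 10)
        upper, lower = midplane_location(traj, [2])
        assert upper.value == pytest.approx(1.5)
        assert lower.value == pytest.approx(1.5)

    def test_deep_well_run_concentrates_in_the_well_band(self):
        """With a >=6 kT well the upper-side mean falls in the well band."""
        from memanchor import SyntheticParams, build_system, simulate_adsorption
        p = SyntheticParams(well_depth=7.0, n_steps=150_000, write_stride=100,
                            seed=21)
        topo, f0, _ = build_system(p)
        traj = simulate_adsorption(p, topo, f0)
        upper, lower = midplane_location(traj, topo.residue_indices("DRUG"))
        assert p.z_surface - p.well_width <= upper.value <= p.z_surface + 0.1


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

class TestFreeEnergyProfile:
    def test_uniform_occupancy_is_flat_zero(self):
        f = free_energy_profile(np.full(10, 7.0))
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_two_bins_with_ratio_e_differ_by_one_kt(self):
        f = free_energy_profile(np.array([np.e, 1.0]))
        assert f[0] == pytest.approx(0.0)
        assert f[1] == pytest.approx(1.0)

    def test_empty_bins_are_nan_not_infinite(self):
        f = free_energy_profile(np.array([10.0, 0.0, 5.0]))
        assert np.isnan(f[1])
        assert np.isfinite(f[[0, 2]]).all()

    def test_all_zero_histogram_raises(self):
        with pytest.raises(ValueError, match="zero"):
            free_energy_profile(np.zeros(5))

    def test_kj_per_mol_units_scale_by_kbt(self):
        f_kt = free_energy_profile(np.array([np.e, 1.0]))
        f_kj = free_energy_profile(np.array([np.e, 1.0]), temperature=310.0,
                                   units="kJ/mol")
        assert f_kj[1] == pytest.approx(f_kt[1] * 0.00831446261815324 * 310.0)


# ---------------------------------------------------------------------------
# dipole moment
# ---------------------------------------------------------------------------

class TestDipoleMoment:
    def test_coincident_opposite_charges_cancel(self):
        pos = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert dipole_moment(pos, np.array([0.5, -0.5])) == pytest.approx(0.0)

    def test_half_charge_pair_at_0p1_nm_is_2p4016_debye(self):
        pos = np.array([[0.0, 0.0, 0.1], [0.0, 0.0, 0.0]])
        mu = dipole_moment(pos, np.array([0.5, -0.5]))
        assert mu == pytest.approx(0.05 * 48.0321, rel=1e-9)

    def test_translation_invariance_for_neutral_sets(self):
        rng = np.random.default_rng(8)
        pos = rng.normal(size=(6, 3))
        q = rng.normal(size=6)
        q -= q.mean()  # enforce neutrality
        mu0 = dipole_moment(pos, q)
        mu1 = dipole_moment(pos + np.array([3.0, -7.0, 11.0]), q)
        assert mu0 == pytest.approx(mu1, rel=1e-9)

    def test_net_charge_warns_and_uses_center_of_mass(self):
        pos = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])
        with pytest.warns(UserWarning, match="net charge"):
            mu = dipole_moment(pos, np.array([1.0, 0.0]),
                               masses=np.array([1.0, 1.0]))
        assert mu == pytest.approx(1.0 * 48.0321, rel=1e-9)
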