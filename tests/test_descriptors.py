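"""Structural descriptor correctness on constructed fixtures."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from voltgate.core_io import Trajectory
from voltgate.descriptors import (
    ChargeGroupProxy,
    HelixDefinition,
    PoreRegion,
    block_average,
    charge_z_displacement,
    conductance,
    detect_permeations,
    helix_com_displacement,
    helix_tilt,
    pore_radius_profile,
    pore_water_count,
    rmsd,
)
from voltgate.synthetic_data import make_helix_bundle

BOX = np.array([200.0, 200.0, 200.0])


def bundle_traj(n_frames=3, **kw):
    atoms, coords = make_helix_bundle(1, kw.pop("tilt", 0.0), **kw)
    traj = Trajectory(coordinates=np.repeat(coords[None], n_frames, axis=0),
                      box=BOX)
    return atoms, traj


class TestChargeDisplacement:
    def test_static_trajectory_is_zero(self):
        names = ["ALA"] * 9
        names[4] = "ARG"
        atoms, traj = bundle_traj(n_residues=9, residue_names=names,
                                  first_residue=206)
        proxies = [ChargeGroupProxy.for_residue(atoms, 210)]
        df = charge_z_displacement(traj, proxies, atoms)
        assert np.allclose(df.dz, 0.0)

    def test_step_translation_read_back(self):
        names = ["ALA"] * 9
        names[4] = "GLU"
        atoms, traj = bundle_traj(n_frames=6, n_residues=9,
                                  residue_names=names, first_residue=206)
        coords = traj.coordinates.copy()
        coords[3:, :, 2] += 3.0
        traj = Trajectory(coordinates=coords, box=BOX)
        df = charge_z_displacement(
            traj, [ChargeGroupProxy(210, "CD")], atoms)
        series = df.dz.to_numpy()
        assert np.allclose(series[:3], 0.0)
        assert np.allclose(series[3:], 3.0)

    def test_missing_proxy_names_residue(self):
        atoms, traj = bundle_traj(n_residues=5)
        with pytest.raises(ValueError, match="3"):
            charge_z_displacement(traj, [ChargeGroupProxy(3, "CZ")], atoms)


class TestHelixTilt:
    def test_rigid_rotation_oracle(self, rng):
        """Tilt after a random rigid rotation equals the closed-form angle
        of the rotated original axis."""
        atoms, coords = make_helix_bundle(1, 0.0, n_residues=20)
        ca = coords[atoms.atom_name == "CA"]
        axis0 = np.linalg.svd(ca - ca.mean(axis=0))[2][0]
        for _ in range(5):
            rot = Rotation.random(random_state=rng.integers(2**31))
            rotated = rot.apply(coords)
            traj = Trajectory(coordinates=rotated[None], box=BOX)
            hd = HelixDefinition("H", 109, 128)
            measured = helix_tilt(traj, hd, atoms)[0]
            az = abs(rot.apply(axis0)[2])
            expected = np.degrees(np.arccos(np.clip(az, 0, 1)))
            assert measured == pytest.approx(expected, abs=0.5)

    def test_z_translation_invariance(self):
        atoms, coords = make_helix_bundle(1, 25.0, n_residues=20)
        t1 = Trajectory(coordinates=coords[None], box=BOX)
        t2 = Trajectory(coordinates=(coords + [0, 0, 30.0])[None], box=BOX)
        hd = HelixDefinition("H", 109, 128)
        assert helix_tilt(t1, hd, atoms)[0] == pytest.approx(
            helix_tilt(t2, hd, atoms)[0], abs=1e-9)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            HelixDefinition("H", 109, 111)


class TestComDisplacement:
    def test_translated_fixture_exact(self):
        atoms, traj = bundle_traj(n_frames=2, n_residues=10)
        coords = traj.coordinates.copy()
        coords[1] += np.array([2.0, -1.0, 3.0])
        traj = Trajectory(coordinates=coords, box=BOX)
        hd = HelixDefinition("H", 109, 118)
        d = helix_com_displacement(traj, hd, atoms)
        np.testing.assert_allclose(d[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(d[1], [2.0, -1.0, 3.0], atol=1e-12)

    def test_boltzmann_inversion_recovers_curvature(self, rng):
        """-RT ln P of Gaussian COM jitter is harmonic with k = RT/sigma^2."""
        from voltgate.descriptors import boltzmann_inversion_2d
        from voltgate.units import R_KCAL_MOL_K

        sigma = 0.5
        xy = rng.normal(0.0, sigma, size=(100_000, 2))
        g, xe, ye = boltzmann_inversion_2d(xy, bins=41)
        xc = (xe[:-1] + xe[1:]) / 2
        yc = (ye[:-1] + ye[1:]) / 2
        r2 = xc[:, None] ** 2 + yc[None, :] ** 2
        mask = np.isfinite(g) & (r2 < (2 * sigma) ** 2)
        k_fit = np.polyfit(r2[mask], g[mask], 1)[0]
        k_true = R_KCAL_MOL_K * 300.0 / (2 * sigma**2)
        assert k_fit == pytest.approx(k_true, rel=0.15)


class TestRmsd:
    def test_identical_structures_zero(self):
        atoms, traj = bundle_traj(n_residues=10)
        val = rmsd(traj, traj.coordinates[0], atoms, "name CA")
        assert np.allclose(val, 0.0, atol=1e-10)

    def test_rigid_translation_superposed_zero(self):
        atoms, traj = bundle_traj(n_frames=2, n_residues=10)
        coords = traj.coordinates.copy()
        coords[1] += np.array([5.0, 5.0, 5.0])
        traj = Trajectory(coordinates=coords, box=BOX)
        val = rmsd(traj, traj.coordinates[0], atoms, "name CA")
        assert val[1] < 1e-6

    def test_three_atom_brute_force_oracle(self):
        """Optimal-superposition RMSD of a 3-atom toy matches a brute-force
        scan over rotations."""
        ref = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0]])
        mob = np.array([[0.1, 0, 0], [1.4, 0.3, 0], [-0.2, 1.9, 0.2]])
        from conftest import make_ca_table
        atoms = make_ca_table(3)
        traj = Trajectory(coordinates=mob[None], box=BOX)
        val = rmsd(traj, ref, atoms, "name CA")[0]
        # brute force: dense rotation grid about all axes after centering
        refc = ref - ref.mean(axis=0)
        mobc = mob - mob.mean(axis=0)
        best = np.inf
        grid = np.linspace(-20, 20, 41)  # degrees, around the minimum
        for a in grid:
            for b in grid:
                for c in grid:
                    r = Rotation.from_euler("xyz", [a, b, c], degrees=True)
                    d = r.apply(mobc) - refc
                    best = min(best, np.sqrt((d**2).sum(axis=1).mean()))
        assert val == pytest.approx(best, abs=1e-3)

    def test_atom_count_mismatch(self):
        atoms, traj = bundle_traj(n_residues=10)
        with pytest.raises(ValueError):
            rmsd(traj, traj.coordinates[0, :5], atoms, "name CA")


class TestPore:
    def test_planted_water_count(self):
        from conftest import make_ca_table
        n_in, n_out = 12, 5
        rng = np.random.default_rng(0)
        inside = np.column_stack([
            rng.uniform(-3, 3, n_in), rng.uniform(-3, 3, n_in),
            rng.uniform(-4.5, 4.5, n_in)])
        outside = np.column_stack([
            rng.uniform(-3, 3, n_out), rng.uniform(-3, 3, n_out),
            rng.uniform(10, 20, n_out)])
        atoms = make_ca_table(n_in + n_out, resnames=["HOH"] * (n_in + n_out))
        atoms.atom_name[:] = "O"
        traj = Trajectory(coordinates=np.vstack([inside, outside])[None], box=BOX)
        region = PoreRegion(lower=-5.0, upper=5.0, radial_cutoff=8.0)
        assert pore_water_count(traj, region, atoms, "name O")[0] == n_in

    def test_empty_slab(self):
        from conftest import make_ca_table
        atoms = make_ca_table(4)
        coords = np.zeros((1, 4, 3)); coords[0, :, 2] = 50.0
        traj = Trajectory(coordinates=coords, box=BOX)
        region = PoreRegion(lower=-5.0, upper=5.0)
        assert pore_water_count(traj, region, atoms, "name CA")[0] == 0

    def test_inverted_bounds_error_names_frame(self):
        from conftest import make_ca_table
        atoms = make_ca_table(4)
        traj = Trajectory(coordinates=np.zeros((2, 4, 3)) + 1.0, box=BOX)
        region = PoreRegion(lower=5.0, upper=-5.0)
        with pytest.raises(ValueError, match="frame 0"):
            pore_water_count(traj, region, atoms, "name CA")

    def test_ring_radius_geometry(self):
        """Ring of 8 atoms at rho = 10 A with 2 A radii: r(0) = 8 A."""
        from conftest import make_ca_table
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = np.column_stack([10 * np.cos(ang), 10 * np.sin(ang), np.zeros(8)])
        atoms = make_ca_table(8)
        atoms.vdw_radius[:] = 2.0
        prof = pore_radius_profile(pts, atoms, z_range=(0.0, 0.0), dz=1.0)
        assert prof.radius.iloc[0] == pytest.approx(8.0, abs=1e-9)
        assert not prof.flagged.iloc[0]

    def test_no_atoms_flagged_max(self):
        from conftest import make_ca_table
        atoms = make_ca_table(1)
        pts = np.array([[0.0, 0.0, 100.0]])
        prof = pore_radius_profile(pts, atoms, z_range=(-2, 2), dz=1.0,
                                   max_probe=15.0)
        assert prof.flagged.all() and (prof.radius == 15.0).all()

    def test_stacked_rings_per_slice_minima(self):
        from conftest import make_ca_table
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ring1 = np.column_stack([10 * np.cos(ang), 10 * np.sin(ang), np.zeros(8)])
        ring2 = np.column_stack([6 * np.cos(ang), 6 * np.sin(ang), np.full(8, 5.0)])
        atoms = make_ca_table(16)
        atoms.vdw_radius[:] = 2.0
        prof = pore_radius_profile(np.vstack([ring1, ring2]), atoms,
                                   z_range=(0.0, 5.0), dz=1.0, slab_half=1.0)
        assert prof.radius.iloc[0] == pytest.approx(8.0, abs=1e-9)
        assert prof.radius.iloc[-1] == pytest.approx(4.0, abs=1e-9)
        assert prof.radius.iloc[0] > prof.radius.iloc[-1]


class TestPermeation:
    def test_retreat_through_entry_boundary_not_counted(self):
        z = np.array([-10.0, -2.0, 0.0, -8.0, -10.0])
        assert detect_permeations([(0, None, z)], -5.0, 5.0) == []

    def test_random_walk_matches_state_machine_oracle(self, rng):
        """Counts on random walks equal an independent two-state replay."""
        lo, hi = -5.0, 5.0
        for _ in range(20):
            z = np.cumsum(rng.normal(0, 3.0, size=400))
            ev = detect_permeations([(0, None, z)], lo, hi)
            # oracle: explicit boundary automaton
            ups = downs = 0
            state, entry = "out", 0
            reg = np.where(z < lo, -1, np.where(z >= hi, 1, 0))
            prev = reg[0]
            for cur in reg[1:]:
                if cur == prev:
                    continue
                if prev != 0 and cur == 0:
                    state, entry = "in", prev
                elif prev == 0 and cur != 0:
                    if state == "in" and cur == -entry:
                        ups += cur == 1
                        downs += cur == -1
                    state = "out"
                elif prev != 0 and cur == -prev:
                    ups += cur == 1
                    downs += cur == -1
                    state = "out"
                prev = cur
            got_up = sum(e.direction == "up" for e in ev)
            got_down = sum(e.direction == "down" for e in ev)
            assert (got_up, got_down) == (ups, downs)

    def test_time_reversal_flips_directions(self, rng):
        z = np.cumsum(rng.normal(0, 3.0, size=500))
        fwd = detect_permeations([(0, None, z)], -5.0, 5.0)
        rev = detect_permeations([(0, None, z[::-1])], -5.0, 5.0)
        fu = sum(e.direction == "up" for e in fwd)
        fd = sum(e.direction == "down" for e in fwd)
        ru = sum(e.direction == "up" for e in rev)
        rd = sum(e.direction == "down" for e in rev)
        assert (fu, fd) == (rd, ru)


class TestConductance:
    def test_zero_events(self):
        assert conductance((0, 0), 0.75, 2e-6) == 0.0

    def test_hand_arithmetic(self):
        """7 upward K+ crossings in 2 us at 750 mV: ~0.75 pS."""
        g = conductance((7, 0), 0.75, 2e-6)
        assert g == pytest.approx(7.48e-13, rel=1e-3)

    def test_linearity(self):
        g1 = conductance((3, 1), 0.5, 1e-6)
        assert conductance((6, 2), 0.5, 1e-6) == pytest.approx(2 * g1)
        assert conductance((3, 1), 1.0, 1e-6) == pytest.approx(g1 / 2)
        assert conductance((3, 1), 0.5, 2e-6) == pytest.approx(g1 / 2)

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValueError):
            conductance((1, 0), 0.0, 1e-6)


class TestBlockAverage:
    def test_constant_series(self):
        m, se = block_average(np.full(100, 3.3), 10)
        assert m == pytest.approx(3.3) and se == 0.0

    def test_hand_arithmetic(self):
        m, se = block_average([1.0, 1.0, 3.0, 3.0], 2)
        assert m == 2.0 and se == pytest.approx(1.0)

    def test_clt_scaling(self, rng):
        x = rng.standard_normal(10_000)
        _, se = block_average(x, 10)
        assert 0.01 / 1.5 < se < 0.01 * 1.5

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            block_average([1.0], 2)
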