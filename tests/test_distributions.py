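"""Radial distribution functions and 3-D density maps."""

import numpy as np
import pytest

from porewater.distributions import density_map, rdf
from porewater.model import GroupSpec, Trajectory
from porewater.synthetic import GeneratorConfig, concat_atoms, gen_brownian_bulk

from conftest import build_atoms, single_frame


def _group(atom_idx=0, gid="GLY643:C"):
    return GroupSpec(group_id=gid, central_atom=atom_idx, hydrogens=(), polarity="nonpolar", domain="filter")


def _center_atom_system(n_waters, box, n_frames, seed, diffusion=3.0):
    """One protein carbon at the box centre plus ideal-gas waters."""
    protein = build_atoms([("C", "C", "GLY", 643, "A")])
    cfg = GeneratorConfig(seed=seed, n_frames=n_frames, n_waters=n_waters, box=box, diffusion=diffusion)
    watoms, wtraj = gen_brownian_bulk(cfg)
    atoms = concat_atoms(protein, watoms)
    c = np.float32(box / 2)
    coords = np.concatenate(
        [np.full((n_frames, 1, 3), c, dtype=np.float32), wtraj.coords], axis=1
    )
    traj = Trajectory(times=wtraj.times, coords=coords, box=wtraj.box)
    return atoms, traj


class TestRDF:
    def test_ideal_gas_normalizes_to_unity(self):
        """g(r) of a homogeneous system is 1: the band average over
        well-sampled shells sits within ±0.02 and no bin strays far."""
        # large per-step displacement ⇒ frames are independent uniform draws
        atoms, traj = _center_atom_system(n_waters=900, box=30.0, n_frames=150, seed=8, diffusion=300.0)
        res = rdf(atoms, traj, _group(), r_max=8.0, dr=0.1)
        sel = res.r_centers >= 2.0
        band = res.g_values[sel]
        assert band.mean() == pytest.approx(1.0, abs=0.02)
        # per-bin deviations stay within 5σ of the Poisson expectation
        expected_counts = (
            res.reference_density * 4 * np.pi * res.r_centers[sel] ** 2 * 0.1 * traj.n_frames
        )
        assert np.all(np.abs(band - 1.0) < 5.0 / np.sqrt(expected_counts))

    def test_shell_of_waters_gives_single_peak(self):
        protein = build_atoms([("C", "C", "GLY", 643, "A")])
        from porewater.synthetic import _water_atom_table

        n = 50
        waters = _water_atom_table(n, False, first_resnum=100)
        atoms = concat_atoms(protein, waters)
        rng = np.random.default_rng(3)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        center = np.array([15.0, 15.0, 15.0])
        coords = np.vstack([center[None], center + 2.95 * u]).astype(np.float32)
        traj = single_frame(coords, box=[30.0, 30.0, 30.0])
        res = rdf(atoms, traj, _group(), r_max=6.0, dr=0.1)
        peak_bin = int(2.95 / 0.1)
        assert res.counts[peak_bin] == n
        assert res.counts.sum() == n
        assert res.coordination_number_3p5 == pytest.approx(n)

    def test_coordination_number_counts_shell_occupancy(self):
        """Mean count within 3.5 Å equals a direct distance count."""
        atoms, traj = _center_atom_system(n_waters=400, box=25.0, n_frames=25, seed=13)
        res = rdf(atoms, traj, _group(), r_max=6.0, dr=0.1)
        ow = atoms.water_oxygen_indices()
        direct = []
        for f in range(traj.n_frames):
            v = traj.coords[f, ow].astype(float) - traj.coords[f, 0].astype(float)
            v -= traj.box[f] * np.round(v / traj.box[f])
            direct.append(np.sum((v**2).sum(axis=1) <= 3.5**2))
        assert res.coordination_number_3p5 == pytest.approx(np.mean(direct), abs=1e-9)

    def test_running_coordination_consistent_with_quadrature(self):
        atoms, traj = _center_atom_system(n_waters=600, box=28.0, n_frames=40, seed=2)
        res = rdf(atoms, traj, _group(), r_max=6.0, dr=0.05)
        run = res.running_coordination()
        idx = int(3.5 / 0.05) - 1
        assert run[idx] == pytest.approx(res.coordination_number_3p5, rel=0.05)

    def test_pooled_groups_concatenate_histograms(self):
        atoms, traj = _center_atom_system(n_waters=200, box=25.0, n_frames=10, seed=6)
        g = _group()
        single = rdf(atoms, traj, g, r_max=5.0, dr=0.5)
        pooled = rdf(atoms, traj, [g, g], r_max=5.0, dr=0.5)
        np.testing.assert_allclose(pooled.g_values, single.g_values, rtol=1e-12)
        np.testing.assert_allclose(pooled.counts, 2 * single.counts)


class TestDensityMap:
    def test_single_static_water_occupies_one_voxel(self):
        from porewater.synthetic import _water_atom_table

        atoms = _water_atom_table(1, False)
        coords = np.array([[[2.5, 2.5, 2.5]]], dtype=np.float32)
        traj = Trajectory(times=np.array([0.0]), coords=coords)
        grid = density_map(atoms, traj, "water", origin=[0, 0, 0], dims=(5, 5, 5), spacing=1.0)
        assert grid.values[2, 2, 2] == pytest.approx(1.0)
        assert grid.values.sum() == pytest.approx(1.0)

    def test_grid_integral_conserves_counts(self):
        """Integrating the water grid over all voxels recovers the mean
        number of waters inside the region to machine precision."""
        cfg = GeneratorConfig(seed=17, n_frames=12, n_waters=300, box=20.0, diffusion=1.0)
        atoms, traj = gen_brownian_bulk(cfg)
        grid = density_map(atoms, traj, "water", origin=[2, 2, 2], dims=(16, 16, 16), spacing=1.0)
        ow = atoms.water_oxygen_indices()
        in_region = [
            np.sum(np.all((traj.coords[f, ow] >= 2.0) & (traj.coords[f, ow] < 18.0), axis=1))
            for f in range(traj.n_frames)
        ]
        assert grid.total_count() == pytest.approx(np.mean(in_region), abs=1e-9)

    def test_bulk_water_density_value(self):
        """Uniform bulk water at 0.0334 Å⁻³ gives voxel values near
        0.033 mol/Å³ on average."""
        box = 25.0
        n = int(round(0.0334 * box**3))
        cfg = GeneratorConfig(seed=19, n_frames=40, n_waters=n, box=box, diffusion=2.0)
        atoms, traj = gen_brownian_bulk(cfg)
        grid = density_map(atoms, traj, "water", origin=[2, 2, 2], dims=(21, 21, 21), spacing=1.0)
        assert grid.values.mean() == pytest.approx(0.0334, rel=0.03)

    def test_hbond_grid_counts_bound_oxygens(self, asn_water_system):
        from porewater.hbond import detect_hbonds

        atoms, coords = asn_water_system
        traj = single_frame(coords)
        records = [detect_hbonds(coords, atoms)]
        grid = density_map(
            atoms, traj, "hbond", origin=[-2, -2, -2], dims=(10, 10, 10), spacing=1.0,
            bound_records=records,
        )
        assert grid.total_count() == pytest.approx(1.0)  # one bound water
        # the occupied voxel is the bound water's oxygen position (4,0,0)
        assert grid.values[6, 2, 2] == pytest.approx(1.0)
        mid = density_map(
            atoms, traj, "hbond", origin=[-2, -2, -2], dims=(10, 10, 10), spacing=1.0,
            bound_records=records, hbond_placement="midpoint",
        )
        # donor-acceptor midpoint of the one bond is (2.6, 0, 0)
        assert mid.values[4, 2, 2] == pytest.approx(1.0)

    def test_dx_export_round_trips(self, tmp_path):
        from gridData import Grid

        cfg = GeneratorConfig(seed=1, n_frames=2, n_waters=20, box=10.0)
        atoms, traj = gen_brownian_bulk(cfg)
        grid = density_map(atoms, traj, "water", origin=[0, 0, 0], dims=(10, 10, 10), spacing=1.0)
        path = tmp_path / "w.dx"
        grid.write_dx(str(path))
        g2 = Grid(str(path))
        np.testing.assert_allclose(g2.grid, grid.values, rtol=1e-6)
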