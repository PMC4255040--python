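"""Structural observables: densities, distributions, -S_CD, thickness, APL."""

import numpy as np
import pytest

from npbilayer.model import Box, Frame, SiteRecord, Topology, Trajectory
from npbilayer.regions import LR, SR, RegionBoundaries, tag_trajectory
from npbilayer.structure import (
    U_PER_NM3_TO_KG_M3,
    angle_distribution,
    area_per_lipid_lr,
    density_map_2d,
    dihedral_distribution,
    distance_distribution,
    grid_thickness,
    order_parameter_scd,
    partial_density_profile,
    rdf,
)
from npbilayer.synth import GeneratorConfig, expected_scd, generate_trajectory

from conftest import point_trajectory


class TestDensityProfile:
    def test_uniform_gas_flat_profile_and_mass_conservation(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 5, size=(4000, 3))
        traj = point_trajectory(pts, box=(5, 5, 5))
        prof = partial_density_profile(traj, np.arange(4000), n_bins=10)
        expected = 4000 * 18.015 * U_PER_NM3_TO_KG_M3 / 125.0
        assert prof.values.mean() == pytest.approx(expected, rel=1e-9)
        assert prof.values.std() / prof.values.mean() < 0.1
        # integral * area = total mass (in kg/m3 * nm units -> convert back)
        total = prof.values.sum() * (5.0 / 10) * 25.0 / U_PER_NM3_TO_KG_M3
        assert total == pytest.approx(4000 * 18.015, rel=1e-9)

    def test_single_slab_bin(self):
        pts = np.full((10, 3), 2.55)
        traj = point_trajectory(pts, box=(5, 5, 5))
        prof = partial_density_profile(traj, np.arange(10), n_bins=10)
        nz = np.flatnonzero(prof.values)
        assert len(nz) == 1
        bin_vol = 25.0 * 0.5
        assert prof.values[nz[0]] == pytest.approx(
            10 * 18.015 * U_PER_NM3_TO_KG_M3 / bin_vol
        )

    def test_symmetric_bilayer_profile(self, np_system):
        traj, _, _ = np_system
        lipids = traj.topology.select(molecule_type="AOPC")
        prof = partial_density_profile(traj, lipids, n_bins=40)
        mid = traj.frames[0].box.lz / 2
        z = prof.centers
        occupied = prof.values > 0.2 * prof.values.max()
        v = prof.values[occupied]
        zo = z[occupied]
        # compare mirror pairs about the midplane
        mirrored = np.interp(2 * mid - zo, z, prof.values)
        asym = np.abs(v - mirrored).max() / v.max()
        assert asym < 0.35  # finite-sample noise; shape is symmetric

    def test_empty_selection_rejected(self, np_system):
        traj, _, _ = np_system
        with pytest.raises(ValueError):
            partial_density_profile(traj, np.array([], dtype=int))


class TestDensityMap:
    def test_uniform_gas_constant_map(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 4, size=(20000, 3))
        traj = point_trajectory(pts, box=(4, 4, 4))
        m = density_map_2d(traj, np.arange(len(pts)), bin_width=1.0)
        rho = 20000 / 64.0
        assert m.density.mean() == pytest.approx(rho, rel=1e-9)
        assert np.all(np.abs(m.density - rho) / rho < 0.2)

    def test_cluster_appears_as_localized_blob(self, np_system):
        traj, truth, cfg = np_system
        ow = traj.topology.select(molecule_type="SOL")
        m = density_map_2d(traj, ow, bin_width=0.2)
        frame = traj.frames[0]
        zmid = frame.box.lz / 2
        h = cfg.leaflet_separation
        zc = 0.5 * (m.z_edges[:-1] + m.z_edges[1:])
        xc = 0.5 * (m.x_edges[:-1] + m.x_edges[1:])
        # deep slab band well away from the particle footprint
        slab = (zc > zmid - h / 2 + 0.7) & (zc < zmid + h / 2 - 0.7)
        npx = truth.np_center_start[0]
        far = np.abs(xc - npx) > cfg.np_radius + 1.0
        assert np.all(m.density[np.ix_(far, slab)] == 0.0)
        near = np.abs(xc - npx) <= cfg.np_radius + 0.75
        assert m.density[np.ix_(near, slab)].max() > 0.0


class TestDistanceDistribution:
    def _gold_plus_sites(self, site_specs):
        """One gold atom at origin-ish plus named AOPC head sites around it."""
        sites = [SiteRecord(0, "AU", "AU1", 196.967)]
        pos = [[5.0, 5.0, 5.0]]
        # one AOPC lipid owning all requested sites (plus mandatory N/P)
        names = {name for name, _ in site_specs}
        mol_sites = []
        for j, (name, d) in enumerate(site_specs):
            mol_sites.append(name)
            pos.append([5.0 + d, 5.0, 5.0])
        for extra in ("N", "P"):
            if extra not in names:
                mol_sites.append(extra)
                pos.append([5.0, 5.0 + 0.45, 5.0])
        sites += [SiteRecord(1, "AOPC", n, 14.0) for n in mol_sites]
        topo = Topology(sites)
        frame = Frame(0.0, np.array(pos, float), Box(10, 10, 10))
        return Trajectory(topo, [frame])

    def test_delta_at_single_distance(self):
        traj = self._gold_plus_sites([("O4", 0.25), ("O5", 0.25)])
        h = distance_distribution(traj, ["O4", "O5"], np.array([0]),
                                  headgroup_sites=["O4", "O5", "N", "P"])
        i = np.digitize(0.25, h.edges) - 1
        assert h.heights[i] == pytest.approx(1.0 / h.bin_width)
        assert h.n_contributing == 2

    def test_far_sites_do_not_contribute(self):
        traj = self._gold_plus_sites([("O4", 3.0)])
        h = distance_distribution(traj, ["O4"], np.array([0]),
                                  headgroup_sites=["O4", "N", "P"])
        assert h.n_contributing == 0
        assert np.all(h.heights == 0)

    def test_oxygen_peak_nearer_and_higher_than_nitrogen(self):
        traj = self._gold_plus_sites([("O4", 0.25), ("N", 0.45)])
        h_o = distance_distribution(traj, ["O4"], np.array([0]),
                                    headgroup_sites=["O4", "N", "P"])
        h_n = distance_distribution(traj, ["N"], np.array([0]),
                                    headgroup_sites=["O4", "N", "P"])
        peak_o = h_o.centers[np.argmax(h_o.heights)]
        peak_n = h_n.centers[np.argmax(h_n.heights)]
        assert peak_o < peak_n

    def test_no_surface_atoms_rejected(self, np_system):
        traj, _, _ = np_system
        with pytest.raises(ValueError):
            distance_distribution(traj, ["N"], np.array([], dtype=int))


class TestRdf:
    def test_ideal_gas_g_of_r_near_one(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 6, size=(3000, 3))
        traj = point_trajectory(pts, box=(6, 6, 6))
        ref = np.arange(50)
        target = np.arange(len(pts))
        g = rdf(traj, ref, target, bin_width=0.1)
        tail = g.heights[5:]
        assert np.abs(tail.mean() - 1.0) < 0.05
        assert g.heights[-1] == pytest.approx(1.0, abs=0.2)

    def test_hard_exclusion_zone(self):
        rng = np.random.default_rng(6)
        center = np.array([3.0, 3.0, 3.0])
        pts = rng.uniform(0, 6, size=(6000, 3))
        pts = pts[np.linalg.norm(pts - center, axis=1) > 0.3][:3000]
        all_pts = np.vstack([center, pts])
        traj = point_trajectory(all_pts, box=(6, 6, 6))
        g = rdf(traj, np.array([0]), np.arange(1, len(all_pts)), bin_width=0.05)
        below = g.centers < 0.28
        assert np.all(g.heights[below] == 0.0)

    def test_rmax_clipped_with_warning(self):
        traj = point_trajectory(np.random.default_rng(0).uniform(0, 4, (100, 3)),
                                box=(4, 4, 4))
        with pytest.warns(UserWarning, match="clipped"):
            rdf(traj, np.arange(10), np.arange(100), r_max=5.0)


def _triplet_traj(p0, p1, p2):
    sites = [SiteRecord(0, "AOPC", n, 14.0) for n in ("N", "C25", "C24")]
    pos = np.array([p0, p1, p2], float)
    return Trajectory(Topology(sites), [Frame(0.0, pos, Box(10, 10, 10))])


class TestAnglesAndDihedrals:
    def test_collinear_triplet_is_180(self):
        traj = _triplet_traj([0, 0, 0], [0, 0, 1], [0, 0, 2])
        h = angle_distribution(traj, ["N", "C25", "C24"], bin_width_deg=2.0)
        assert h.centers[np.argmax(h.heights)] == pytest.approx(179.0, abs=1.0)

    def test_right_angle(self):
        traj = _triplet_traj([1, 0, 0], [0, 0, 0], [0, 1, 0])
        h = angle_distribution(traj, ["N", "C25", "C24"], bin_width_deg=2.0)
        assert h.centers[np.argmax(h.heights)] == pytest.approx(90.0, abs=1.1)

    def test_generator_head_geometry_is_delta_at_111(self, flat_bilayer):
        traj, _, _ = flat_bilayer
        h = angle_distribution(traj, ["N", "C25", "C24"], bin_width_deg=2.0)
        assert h.integral() == pytest.approx(1.0, abs=1e-9)
        peak = h.centers[np.argmax(h.heights)]
        assert abs(peak - 111.0) < 2.0
        assert h.heights.max() * h.bin_width == pytest.approx(1.0, abs=1e-9)

    def _quad_traj(self, phi_deg):
        """Four sites with dihedral phi about the central bond."""
        sites = [SiteRecord(0, "AOPC", n, 14.0) for n in ("N", "C25", "C24", "O6")]
        phi = np.radians(phi_deg)
        pos = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0],
                [0.0, 0.0, 1.0],
                [np.cos(phi), np.sin(phi), 1.0],
            ]
        )
        return Trajectory(Topology(sites), [Frame(0.0, pos, Box(10, 10, 10))])

    @pytest.mark.parametrize("phi", [180.0, 60.0, -60.0, 0.0])
    def test_dihedral_values(self, phi):
        traj = self._quad_traj(phi)
        h = dihedral_distribution(traj, ["N", "C25", "C24", "O6"], bin_width_deg=5.0)
        peak = h.centers[np.argmax(h.heights)]
        expect = 177.5 if phi == 180.0 else phi  # 180 falls in the last bin
        assert abs(peak - expect) <= 2.5

    def test_mirror_image_flips_sign(self):
        traj = self._quad_traj(60.0)
        mirrored = Trajectory(
            traj.topology,
            [Frame(0.0, traj.frames[0].positions * np.array([1, -1, 1]),
                   traj.frames[0].box)],
        )
        h1 = dihedral_distribution(traj, ["N", "C25", "C24", "O6"])
        h2 = dihedral_distribution(mirrored, ["N", "C25", "C24", "O6"])
        p1 = h1.centers[np.argmax(h1.heights)]
        p2 = h2.centers[np.argmax(h2.heights)]
        assert p1 == pytest.approx(-p2, abs=1e-9)

    def test_sr_equals_lr_without_nanoparticle(self, flat_bilayer):
        traj, _, _ = flat_bilayer
        tags = tag_trajectory(traj, None)
        h_all = dihedral_distribution(traj, ["N", "C25", "C24", "O6"],
                                      tags=tags, region=LR)
        h_none = dihedral_distribution(traj, ["N", "C25", "C24", "O6"])
        assert np.allclose(h_all.heights, h_none.heights)


class TestOrderParameter:
    def test_all_trans_upright_gives_half(self, flat_bilayer):
        traj, _, _ = flat_bilayer
        prof = order_parameter_scd(traj, chain="sn1")
        assert np.allclose(prof.minus_scd, 0.5, atol=1e-9)

    def test_range_bounds(self, np_system):
        traj, _, _ = np_system
        for chain in ("sn1", "sn2"):
            prof = order_parameter_scd(traj, chain=chain)
            assert np.all(prof.minus_scd >= -1.0 - 1e-9)
            assert np.all(prof.minus_scd <= 0.5 + 1e-9)

    def test_isotropic_orientations_give_zero(self):
        """Direct check of the molecular-frame math: 10^4 randomly oriented
        rigid 3-carbon segments must average to -S_CD = 0."""
        from scipy.spatial.transform import Rotation

        n = 10000
        seg = np.array([[0.0, 0.0, 0.0], [0.125, 0.0, 0.088], [0.0, 0.0, 0.176]])
        seg = seg - seg.mean(axis=0)
        rot = Rotation.random(n, random_state=12345)
        pos = np.einsum("nij,kj->nki", rot.as_matrix(), seg) + 5.0
        sites = []
        for m in range(n):
            sites += [SiteRecord(m, "AOPC", c, 14.0) for c in ("CA", "CB", "CC")]
        topo = Topology(sites, chains={"sn1": ["CA", "CB", "CC"]})
        frame = Frame(0.0, pos.reshape(-1, 3), Box(100, 100, 100))
        prof = order_parameter_scd(Trajectory(topo, [frame]), chain="sn1")
        assert abs(prof.minus_scd[0]) < 0.02

    def test_tilt_recovery_matches_closed_form(self):
        cfg = GeneratorConfig(
            n_lipids_per_leaflet=128, n_frames=2, dt=1.0, seed=21,
            np_radius=None, water_number_density=0.0,
            tilt_mean_cos2={SR: 0.8, "BUFFER": 0.8, LR: 0.8},
        )
        traj, _ = generate_trajectory(cfg)
        prof = order_parameter_scd(traj, chain="sn1")
        assert np.all(np.abs(prof.minus_scd - expected_scd(0.8)) < 0.02)

    def test_per_region_profiles(self, np_system):
        traj, truth, cfg = np_system
        tags = tag_trajectory(traj, RegionBoundaries(cfg.np_radius))
        for region in (SR, LR):
            prof = order_parameter_scd(traj, chain="sn1", tags=tags, region=region)
            assert abs(prof.minus_scd.mean() - truth.scd[region]) < 0.04

    def test_terminal_carbon_rejected(self, flat_bilayer):
        traj, _, _ = flat_bilayer
        with pytest.raises(ValueError, match="neighbour"):
            order_parameter_scd(traj, chain="sn1", carbons=["C2"])


class TestThickness:
    def test_flat_bilayer_delta_at_h(self, flat_bilayer):
        traj, truth, cfg = flat_bilayer
        field = grid_thickness(traj, grid=(10, 10))
        assert np.allclose(field.thickness, truth.thickness, atol=1e-9)
        d = field.distribution
        assert d.integral() == pytest.approx(1.0, abs=1e-9)
        peak = d.centers[np.argmax(d.heights)]
        assert abs(peak - truth.thickness) <= d.bin_width

    def test_noisy_bilayer_mean_recovered(self):
        cfg = GeneratorConfig(
            n_lipids_per_leaflet=256, n_frames=6, dt=1.0, seed=8,
            np_radius=None, water_number_density=0.0,
            z_fluctuation_sigma=0.1,
        )
        traj, truth = generate_trajectory(cfg)
        field = grid_thickness(traj, grid=(16, 16))
        mean = np.sum(field.distribution.centers * field.distribution.heights
                      ) * field.distribution.bin_width
        assert abs(mean - truth.thickness) < 0.02

    def test_lr_mask_excludes_np_footprint(self, np_system):
        traj, truth, cfg = np_system
        b = RegionBoundaries(cfg.np_radius)
        com = np.array(truth.np_center_start)
        field = grid_thickness(traj, grid=(20, 20), np_com=com, d_buf=b.d_buf)
        box = traj.frames[0].box
        cx = (np.arange(20) + 0.5) * box.lx / 20
        cy = (np.arange(20) + 0.5) * box.ly / 20
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        d = np.hypot(gx - com[0], gy - com[1])
        assert np.array_equal(field.mask, d >= b.d_buf)


class TestAreaPerLipid:
    def test_no_np_exact(self):
        cfg = GeneratorConfig(n_lipids_per_leaflet=50, lx=10.0, ly=10.0,
                              n_frames=2, seed=3, np_radius=None,
                              water_number_density=0.0)
        traj, truth = generate_trajectory(cfg)
        series = area_per_lipid_lr(traj, None, None)
        assert series.mean == pytest.approx(2.0)
        assert series.mean == pytest.approx(truth.area_per_lipid)

    def test_disc_subtraction_arithmetic(self):
        """(lx*ly - pi*d_buf^2)/n_LR for a hand-built tag set."""
        cfg = GeneratorConfig(n_lipids_per_leaflet=50, lx=10.0, ly=10.0,
                              n_frames=2, seed=3, np_radius=None,
                              water_number_density=0.0)
        traj, _ = generate_trajectory(cfg)
        from npbilayer.regions import RegionTags

        lipids = [int(m) for m in traj.topology.lipid_ids()]
        labels = {m: LR for m in lipids[:20]}
        labels.update({m: SR for m in lipids[20:]})
        tags = [RegionTags(0, 0.0, 100.0, labels)]
        series = area_per_lipid_lr(traj, tags, RegionBoundaries(1.0))
        assert series.mean == pytest.approx((100.0 - 9.0 * np.pi) / 20.0)

    def test_no_lr_lipids_raises(self):
        cfg = GeneratorConfig(n_lipids_per_leaflet=10, lx=10.0, ly=10.0,
                              n_frames=2, seed=3, np_radius=None,
                              water_number_density=0.0)
        traj, _ = generate_trajectory(cfg)
        from npbilayer.regions import RegionTags

        labels = {int(m): SR for m in traj.topology.lipid_ids()}
        tags = [RegionTags(0, 0.0, 100.0, labels)]
        with pytest.raises(ValueError, match="no LR"):
            area_per_lipid_lr(traj, tags, RegionBoundaries(1.0))
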