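"""Disk-electrode potentials, cross-resistances, and the FD Poisson oracle."""

import math

import numpy as np
import pytest

from pvretina.errors import DomainError, GeometryError
from pvretina.fields import (
    ElementaryFieldSet,
    Medium,
    access_resistance,
    cross_resistance_matrix,
    disk_potential,
)
from pvretina.geometry import ArrayLayout, ReturnRing, build_hex_array
from pvretina.oracle_fd import FDGrid, fd_ep_disk_resistance, graded_axis, solve_fd_poisson


@pytest.fixture(scope="module")
def disk_grid():
    """Graded grid resolving a 9 um disk, far field at ~200 um."""
    xy = graded_axis(27, 1.5, 200, ratio=1.35)
    z = graded_axis(30, 1.5, 200, ratio=1.35, one_sided=True)
    return FDGrid(xy, xy, z)


class TestDiskPotential:
    def test_ucd_on_axis_closed_form(self, medium_1ohm_m):
        # rho I / (pi a) at the disk surface for a 9 um UCD disk
        v = disk_potential(9.0, medium_1ohm_m, (0, 0, 0), "UCD")
        assert v == pytest.approx(1.0 / (math.pi * 9e-6), rel=1e-9)
        assert v * 1e-6 == pytest.approx(35.4e-3, rel=2e-3)

    def test_far_field_point_source_limit(self, medium_1ohm_m):
        v = disk_potential(9.0, medium_1ohm_m, (0, 0, 1000.0), "UCD")
        assert v == pytest.approx(1.0 / (2 * math.pi * 1e-3), rel=5e-5)

    def test_on_axis_strictly_decreasing(self, medium_1ohm_m):
        zs = [0, 2, 5, 10, 30, 100, 500]
        vals = [disk_potential(9.0, medium_1ohm_m, (0, 0, z)) for z in zs]
        assert np.all(np.diff(vals) < 0)

    def test_off_axis_continuity(self, medium_1ohm_m):
        near = disk_potential(9.0, medium_1ohm_m, (8.9, 0, 1.0))
        outer = disk_potential(9.0, medium_1ohm_m, (9.1, 0, 1.0))
        assert near == pytest.approx(outer, rel=0.05)

    def test_below_plane_rejected(self, medium_1ohm_m):
        with pytest.raises(DomainError):
            disk_potential(9.0, medium_1ohm_m, (0, 0, -1.0))


class TestAccessResistance:
    def test_ep_closed_form(self, medium_1ohm_m):
        assert access_resistance(9.0, medium_1ohm_m, "EP") == pytest.approx(
            1.0 / (4 * 9e-6), rel=1e-12
        )

    def test_ucd_disk_averaged(self, medium_1ohm_m):
        # 8 rho / (3 pi^2 a): quadrature of the UCD self potential
        expected = 8.0 / (3 * math.pi**2 * 9e-6)
        assert access_resistance(9.0, medium_1ohm_m, "UCD") == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(30.04e3, rel=1e-3)

    def test_linear_in_resistivity(self):
        r1 = access_resistance(9.0, Medium(100.0), "UCD")
        r2 = access_resistance(9.0, Medium(200.0), "UCD")
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_ep_matches_fd_oracle(self, disk_grid, medium_1ohm_m):
        r_fd = fd_ep_disk_resistance(disk_grid, (0, 0), 9.0, medium_1ohm_m)
        assert r_fd == pytest.approx(access_resistance(9.0, medium_1ohm_m, "EP"), rel=0.02)


class TestCrossResistance:
    def test_two_disk_mutual_near_point_source(self, medium):
        # two 9 um disks, 40 um apart, rho = 7 ohm-m
        layout = ArrayLayout(
            pixel_width=40.0,
            row_pitch=40.0 * math.cos(math.pi / 6),
            pixel_centers=np.array([[0.0, 0.0], [40.0, 0.0]]),
            electrode_radius=9.0,
            array_diameter=100.0,
        )
        C = cross_resistance_matrix(layout, medium)
        point = 7.0 / (2 * math.pi * 40e-6)  # ~27.9 kOhm
        assert C.R[0, 1] == pytest.approx(point, rel=0.03)
        assert C.R[0, 0] == pytest.approx(access_resistance(9.0, medium, "UCD"), rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reciprocity_on_random_layouts(self, seed, medium):
        rng = np.random.default_rng(seed)
        centers = []
        while len(centers) < 12:
            r = 200 * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            p = np.array([r * math.cos(th), r * math.sin(th)])
            if all(np.linalg.norm(p - q) > 25 for q in centers):
                centers.append(p)
        layout = ArrayLayout(
            pixel_width=40.0,
            row_pitch=40.0 * math.cos(math.pi / 6),
            pixel_centers=np.array(centers),
            electrode_radius=9.0,
            array_diameter=450.0,
            return_ring=ReturnRing(240.0, 270.0),
        )
        C = cross_resistance_matrix(layout, medium)
        asym = np.abs(C.R - C.R.T) / np.abs(C.R)
        assert asym.max() < 1e-6

    def test_diagonal_dominates_and_decays_with_distance(self, full_array):
        layout, C = full_array
        off = C.R - np.diag(np.diag(C.R))
        assert np.all(np.diag(C.R) > off.max(axis=1))
        # off-diagonals decay with distance for interior pixel pairs
        interior = np.where(layout.interior_mask(4))[0]
        i = interior[np.argmin(layout.radii[interior])]
        d = np.linalg.norm(layout.pixel_centers[interior] - layout.pixel_centers[i], axis=1)
        order = np.argsort(d)[1:40]
        vals = C.R[i, interior[order]]
        # allow tiny non-monotonicity from the ring-term variation
        assert np.all(np.diff(vals) < 0.02 * vals[:-1])

    def test_nearest_neighbors_in_printed_range(self, full_array):
        _, C = full_array
        nn = C.nearest_neighbor_values() / 1e3
        assert nn.min() >= 15.0 and nn.max() <= 30.0

    def test_overlapping_electrodes_rejected(self, medium):
        layout = ArrayLayout(
            pixel_width=40.0,
            row_pitch=40.0 * math.cos(math.pi / 6),
            pixel_centers=np.array([[0.0, 0.0], [10.0, 0.0]]),
            electrode_radius=9.0,
            array_diameter=100.0,
        )
        with pytest.raises(GeometryError):
            cross_resistance_matrix(layout, medium)


class TestFDOracle:
    def test_single_ucd_disk_on_axis_within_2pct(self, disk_grid, medium_1ohm_m):
        phi = solve_fd_poisson(disk_grid, [(0.0, 0.0, 9.0, 1e-6)], medium_1ohm_m)
        i0 = np.argmin(np.abs(disk_grid.x))
        for z_target in [0.0, 4.5, 10.5, 19.5, 30.0]:
            k = np.argmin(np.abs(disk_grid.z - z_target))
            exact = disk_potential(9.0, medium_1ohm_m, (0, 0, disk_grid.z[k])) * 1e-6
            assert phi[i0, i0, k] == pytest.approx(exact, rel=0.02)

    def test_zero_sources_zero_potential(self, disk_grid, medium_1ohm_m):
        phi = solve_fd_poisson(disk_grid, [], medium_1ohm_m, boundary="zero")
        assert np.all(phi == 0.0)

    def test_opposite_currents_antisymmetric(self, medium_1ohm_m):
        xy = graded_axis(42, 1.5, 250, ratio=1.4)
        z = graded_axis(30, 1.5, 250, ratio=1.4, one_sided=True)
        grid = FDGrid(xy, xy, z)
        phi = solve_fd_poisson(
            grid,
            [(-20.0, 0.0, 9.0, 1e-6), (20.0, 0.0, 9.0, -1e-6)],
            medium_1ohm_m,
            boundary="zero",
        )
        # dipole: each z-plane integrates to ~zero relative to its own scale
        dx = np.gradient(grid.x)
        w2 = np.outer(dx, dx)
        for k in [0, 5, 10]:
            tot = float(np.sum(phi[:, :, k] * w2))
            scale = float(np.sum(np.abs(phi[:, :, k]) * w2))
            assert abs(tot) < 1e-6 * max(scale, 1e-30) + 1e-12

    def test_grid_refinement_convergence(self, medium_1ohm_m):
        errs = []
        for h, ratio in [(1.5, 1.35), (0.75, math.sqrt(1.35))]:
            # halve every cell: the graded-region growth factor refines too
            xy = graded_axis(27, h, 200, ratio=ratio)
            z = graded_axis(30, h, 200, ratio=ratio, one_sided=True)
            grid = FDGrid(xy, xy, z)
            phi = solve_fd_poisson(grid, [(0.0, 0.0, 9.0, 1e-6)], medium_1ohm_m)
            i0 = np.argmin(np.abs(grid.x))
            k = np.argmin(np.abs(grid.z - 12.0))
            exact = disk_potential(9.0, medium_1ohm_m, (0, 0, grid.z[k])) * 1e-6
            errs.append(abs(phi[i0, i0, k] - exact) / exact)
        assert errs[1] <= errs[0] / 2 * 1.1  # halving h at least halves the error

    def test_under_resolved_grid_rejected(self, medium_1ohm_m):
        xy = graded_axis(30, 5.0, 100, ratio=1.4)
        z = graded_axis(30, 5.0, 100, ratio=1.4, one_sided=True)
        with pytest.raises(DomainError):
            solve_fd_poisson(FDGrid(xy, xy, z), [(0, 0, 9.0, 1e-6)], medium_1ohm_m)


def test_superposition_matches_fd_oracle_on_cluster(cluster_fd_comparison):
    layout, currents, grid, phi, kernels = cluster_fd_comparison
    iz = np.argmin(np.abs(grid.z - 10.5))
    z_um = grid.z[iz]
    pts = layout.pixel_centers
    K = kernels.kernel_matrix(pts, z_um)
    analytic = K @ currents
    ix = [np.argmin(np.abs(grid.x - p[0])) for p in pts]
    iy = [np.argmin(np.abs(grid.y - p[1])) for p in pts]
    fd = np.array([phi[i, j, iz] for i, j in zip(ix, iy)])
    scale = np.max(np.abs(analytic))
    assert np.all(np.abs(fd - analytic) <= 0.03 * scale)


def test_kernel_superposition_is_exact_by_construction(cluster7):
    layout, R, _ = cluster7
    kernels = ElementaryFieldSet(layout, Medium())
    K = kernels.kernel_matrix(layout.pixel_centers, 10.0)
    rng = np.random.default_rng(7)
    a = rng.normal(size=7)
    b = rng.normal(size=7)
    lhs = K @ (2.0 * a + 3.0 * b)
    rhs = 2.0 * (K @ a) + 3.0 * (K @ b)
    assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-15)
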