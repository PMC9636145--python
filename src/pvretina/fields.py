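"""Quasi-static volume-conduction fields of disk microelectrodes.

The medium is a homogeneous resistive half-space (z >= 0) bounded below by
the insulating implant face.  The potential of a point current source on an
insulating boundary is ``rho * I / (2 pi r)``; electrode fields are obtained
by integrating that kernel over the electrode footprint.

Active electrodes carry a uniform current density (UCD boundary condition,
appropriate for pulses much longer than the interface RC time); the
peripheral common return is treated as a collecting annulus.  For a UCD disk
of radius ``a`` the in-plane potential has a closed form in complete
elliptic integrals, the on-axis potential is ``rho*I*(sqrt(a^2+z^2)-z) /
(pi a^2)``, and the disk-averaged self potential (the UCD access
resistance) is ``8 rho / (3 pi^2 a)``.  An equipotential (EP) disk has
access resistance ``rho / (4 a)``.

Public API uses um for lengths and ohm-cm for resistivity; returned
potentials are in volts per ampere (ohms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline
from scipy.special import ellipe, ellipk

from .errors import DomainError, GeometryError
from .geometry import ArrayLayout

__all__ = [
    "Medium",
    "disk_potential",
    "access_resistance",
    "ucd_potential_profile",
    "annulus_potential_profile",
    "CrossResistanceMatrix",
    "cross_resistance_matrix",
    "ElementaryFieldSet",
]

UM = 1e-6


@dataclass(frozen=True)
class Medium:
    """Homogeneous volume conductor.

    ``resistivity`` in ohm-cm.  The default of 700 ohm-cm corresponds to the
    retina-mimicking dilution of phosphate-buffered saline to 10% by volume
    (full-strength DPBS is roughly 70 ohm-cm).
    """

    resistivity: float = 700.0
    description: str = "retina-mimicking 10% DPBS dilution"

    def __post_init__(self):
        if self.resistivity <= 0:
            raise DomainError("resistivity must be positive")

    @property
    def rho_si(self) -> float:
        """Resistivity in ohm-m."""
        return self.resistivity / 100.0


# ---------------------------------------------------------------------------
# dimensionless UCD-disk potentials (lengths in meters, per unit rho and I)
# ---------------------------------------------------------------------------


def _phi_inplane(r: np.ndarray, a: float) -> np.ndarray:
    """In-plane (z=0) potential of a UCD disk, per unit rho*I; closed form."""
    r = np.asarray(r, float)
    out = np.empty_like(r)
    inside = r <= a
    m_in = (r[inside] / a) ** 2
    out[inside] = 2.0 / (math.pi**2 * a) * ellipe(m_in)
    rb = r[~inside]
    m = (a / rb) ** 2
    out[~inside] = 2.0 * rb / (math.pi**2 * a**2) * (ellipe(m) - (1 - m) * ellipk(m))
    return out


def _phi_offplane_point(r: float, z: float, a: float) -> float:
    """Potential at (r, z>0), per unit rho*I, by radial quadrature."""
    if r == 0.0:
        return (math.hypot(a, z) - z) / (math.pi * a**2)

    def integrand(rp):
        s2 = (r + rp) ** 2 + z**2
        m = 4.0 * r * rp / s2
        return rp * ellipk(m) / math.sqrt(s2)

    pts = [r] if 0.0 < r < a else None
    val, _ = quad(integrand, 0.0, a, points=pts, limit=200)
    return 2.0 / (math.pi**2 * a**2) * val


@lru_cache(maxsize=128)
def _profile_spline(a: float, z: float, rmax: float) -> CubicSpline:
    """Radial spline of the UCD-disk potential at height z (SI, per rho*I)."""
    r_near = np.linspace(0.0, 4.0 * a, 80)
    r_far = np.geomspace(4.0 * a, max(rmax, 8.0 * a), 160)[1:]
    r = np.concatenate([r_near, r_far])
    vals = np.array([_phi_offplane_point(ri, z, a) for ri in r])
    return CubicSpline(r, vals)


def ucd_potential_profile(
    r_um: np.ndarray, z_um: float, a_um: float, medium: Medium
) -> np.ndarray:
    """Potential (V per A) of a UCD disk at lateral distances ``r_um``, height ``z_um``."""
    if z_um < 0:
        raise DomainError("evaluation points must lie in the half-space z >= 0")
    r = np.atleast_1d(np.asarray(r_um, float)) * UM
    a, z = a_um * UM, z_um * UM
    rho = medium.rho_si
    if z == 0.0:
        return rho * _phi_inplane(r, a)
    rmax = float(r.max()) if r.size else 8 * a
    far = r > 60.0 * a + 10.0 * z
    out = np.empty_like(r)
    if np.any(~far):
        spl = _profile_spline(a, z, max(rmax, 8 * a))
        out[~far] = spl(r[~far])
    out[far] = 1.0 / (2 * math.pi * np.hypot(r[far], z))
    return rho * out


def annulus_potential_profile(
    r_um: np.ndarray, z_um: float, r1_um: float, r2_um: float, medium: Medium
) -> np.ndarray:
    """Potential (V per A) of a uniformly collecting annulus injecting unit current.

    The annulus is the difference of two coplanar UCD disks sharing the same
    current density.
    """
    a1, a2 = r1_um, r2_um
    if not 0 < a1 < a2:
        raise GeometryError("annulus radii must satisfy 0 < inner < outer")
    w1, w2 = a1 * a1, a2 * a2
    p2 = ucd_potential_profile(r_um, z_um, a2, medium)
    p1 = ucd_potential_profile(r_um, z_um, a1, medium)
    return (w2 * p2 - w1 * p1) / (w2 - w1)


def disk_potential(
    electrode_radius_um: float,
    medium: Medium,
    point_um,
    mode: str = "UCD",
) -> float:
    """Potential (V per A of injected current) of a single disk electrode.

    ``point_um`` is (x, y, z) in um with z >= 0.  Mode ``"UCD"`` integrates
    the half-space point-source kernel over the disk; ``"EP"`` uses the
    closed form for an equipotential disk.
    """
    x, y, z = (float(v) for v in point_um)
    if z < 0:
        raise DomainError("point must lie in the half-space z >= 0")
    a = electrode_radius_um * UM
    r = math.hypot(x, y) * UM
    z *= UM
    rho = medium.rho_si
    if mode.upper() == "UCD":
        if z == 0.0:
            return float(rho * _phi_inplane(np.array([r]), a)[0])
        return rho * _phi_offplane_point(r, z, a)
    if mode.upper() == "EP":
        r1 = math.hypot(r - a, z)
        r2 = math.hypot(r + a, z)
        return rho / (2 * math.pi * a) * math.asin(min(1.0, 2 * a / (r1 + r2)))
    raise DomainError(f"unknown boundary mode {mode!r}")


def access_resistance(electrode_radius_um: float, medium: Medium, mode: str = "UCD") -> float:
    """Electrode access resistance (ohm) against a remote return.

    EP: ``rho/(4a)``.  UCD: disk-averaged self potential ``8 rho/(3 pi^2 a)``.
    """
    if electrode_radius_um <= 0:
        raise DomainError("radius must be positive")
    a = electrode_radius_um * UM
    rho = medium.rho_si
    mode = mode.upper()
    if mode == "EP":
        return rho / (4 * a)
    if mode == "UCD":
        return 8 * rho / (3 * math.pi**2 * a)
    raise DomainError(f"unknown boundary mode {mode!r}")


# ---------------------------------------------------------------------------
# disk-averaged mutual resistance
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def _mutual_spline() -> CubicSpline:
    """Disk-averaged in-plane potential of a unit UCD disk vs center distance.

    Dimensionless: lengths in units of the electrode radius, potential per
    unit rho*I*(1/a).  Valid for separations q = d/a in [2, 60]; beyond that
    the point-source limit 1/(2 pi q) is accurate to < 2e-5 relative.
    """
    q_grid = np.concatenate([np.linspace(2.0, 10.0, 81), np.geomspace(10.0, 60.0, 60)[1:]])
    nu, nth = 48, 48
    u, wu = np.polynomial.legendre.leggauss(nu)
    u = 0.5 * (u + 1.0)  # radius in [0, 1]
    wu = 0.5 * wu
    th, wth = np.polynomial.legendre.leggauss(nth)
    th = 0.5 * math.pi * (th + 1.0)  # angle in [0, pi], symmetric half
    wth = 0.5 * math.pi * wth
    U, TH = np.meshgrid(u, th, indexing="ij")
    W = np.outer(wu * u, wth) * 2.0 / math.pi  # normalized area weights
    vals = []
    for q in q_grid:
        r = np.sqrt(q * q + U * U + 2.0 * q * U * np.cos(TH))
        vals.append(float(np.sum(W * _phi_inplane(r, 1.0))))
    return CubicSpline(q_grid, np.array(vals))


def _disk_mutual(d: np.ndarray, a: float) -> np.ndarray:
    """Disk-averaged mutual potential per unit rho*I for center distances d (SI)."""
    q = np.asarray(d, float) / a
    out = np.empty_like(q)
    near = q < 59.0
    if np.any(near):
        out[near] = _mutual_spline()(q[near]) / a
    out[~near] = 1.0 / (2 * math.pi * np.asarray(d, float)[~near])
    return out


@dataclass(frozen=True)
class CrossResistanceMatrix:
    """Pairwise electrode couplings of a monopolar array.

    ``R`` is the symmetric return-referenced cross-resistance matrix: entry
    (i, j) is the disk-averaged potential rise at electrode i, measured
    relative to the common return electrode, per unit current injected from
    electrode j (whose counter-current is collected by the return).  This is
    the quantity that drives the coupled pixel circuit.  ``R_ground`` is the
    same coupling referenced to a remote ground instead of the return.

    ``w`` holds the ring-to-pixel mutual resistances and ``r0`` the access
    resistance of the return annulus itself (both zero when the layout has
    no return ring, in which case the return is at infinity and
    ``R == R_ground == R_disk``).
    """

    R: np.ndarray
    R_disk: np.ndarray
    w: np.ndarray
    r0: float
    layout: ArrayLayout
    medium: Medium
    boundary_mode: str = "UCD active / collecting annulus return"

    @property
    def n_pixels(self) -> int:
        return self.R.shape[0]

    @property
    def R_ground(self) -> np.ndarray:
        return self.R_disk - self.w[:, None]

    @property
    def return_access_resistance(self) -> float:
        """Access resistance of the common return (ohm); 0 if return at infinity."""
        return self.r0

    def nearest_neighbor_values(self) -> np.ndarray:
        pairs = self.layout.nearest_neighbor_pairs()
        return self.R[pairs[:, 0], pairs[:, 1]]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("R", data=self.R)
            fh.create_dataset("R_ground", data=self.R_ground)
            fh.create_dataset("w", data=self.w)
            fh.attrs["r0_ohm"] = self.r0
            fh.attrs["resistivity_ohm_cm"] = self.medium.resistivity
            fh.create_dataset("pixel_centers_um", data=self.layout.pixel_centers)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.R, delimiter=",")


def cross_resistance_matrix(layout: ArrayLayout, medium: Medium) -> CrossResistanceMatrix:
    """Cross-resistance matrix of all active electrodes of ``layout``.

    Off-diagonal entries are disk-averaged mutual resistances of coplanar
    UCD disks; diagonal entries are the UCD access resistance.  When the
    layout has a return ring, every elementary kernel includes the annular
    sink collecting the full counter-current, and the matrix is referenced
    to the return electrode surface (see :class:`CrossResistanceMatrix`).
    """
    if layout.n_pixels < 1:
        raise GeometryError("layout must contain at least one pixel")
    a = layout.electrode_radius * UM
    rho = medium.rho_si
    xy = layout.pixel_centers * UM
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    n = layout.n_pixels
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] < 2 * a * (1 - 1e-9)):
        raise GeometryError("electrodes overlap: center distance below one diameter")
    R_disk = np.empty((n, n))
    if n > 1:
        R_disk[off] = rho * _disk_mutual(d[off], a)
    np.fill_diagonal(R_disk, 8 * rho / (3 * math.pi**2 * a))
    ring = layout.return_ring
    if ring is None:
        w = np.zeros(n)
        r0 = 0.0
        R = R_disk
    else:
        w = annulus_potential_profile(
            layout.radii, 0.0, ring.inner_radius, ring.outer_radius, medium
        )
        r0 = _annulus_self_resistance(ring.inner_radius, ring.outer_radius, medium)
        R = R_disk - w[:, None] - w[None, :] + r0
    return CrossResistanceMatrix(R=R, R_disk=R_disk, w=w, r0=r0, layout=layout, medium=medium)


@lru_cache(maxsize=32)
def _annulus_self_cached(r1: float, r2: float, resistivity: float) -> float:
    med = Medium(resistivity, description="cache")
    x, wgt = np.polynomial.legendre.leggauss(64)
    r = 0.5 * (r2 - r1) * (x + 1.0) + r1
    wgt = 0.5 * (r2 - r1) * wgt
    phi = annulus_potential_profile(r, 0.0, r1, r2, med)
    area = math.pi * (r2**2 - r1**2)
    return float(np.sum(wgt * phi * 2 * math.pi * r) / area)


def _annulus_self_resistance(r1_um: float, r2_um: float, medium: Medium) -> float:
    """Surface-averaged self potential of the return annulus per unit current."""
    return _annulus_self_cached(r1_um, r2_um, medium.resistivity)


@dataclass(frozen=True)
class ElementaryFieldSet:
    """Per-pixel potential kernels phi_j(x, y, z) in volts per ampere.

    Each kernel is the field of pixel j injecting unit current with the
    counter-current collected by the return ring (if present).  Fields of
    arbitrary current vectors follow by superposition.
    """

    layout: ArrayLayout
    medium: Medium

    def kernel_matrix(self, points_um: np.ndarray, z_um: float) -> np.ndarray:
        """(M, N) kernel matrix at M lateral points on the plane z = z_um."""
        if z_um < 0:
            raise DomainError("evaluation plane must be at z >= 0")
        pts = np.atleast_2d(np.asarray(points_um, float))[:, :2]
        xy = self.layout.pixel_centers
        d = np.linalg.norm(pts[:, None, :] - xy[None, :, :], axis=-1)
        K = ucd_potential_profile(
            d.ravel(), z_um, self.layout.electrode_radius, self.medium
        ).reshape(d.shape)
        ring = self.layout.return_ring
        if ring is not None:
            r_pts = np.hypot(pts[:, 0], pts[:, 1])
            K = K - annulus_potential_profile(
                r_pts, z_um, ring.inner_radius, ring.outer_radius, self.medium
            )[:, None]
        return K

    def pixel_center_kernels(self, z_um: float) -> np.ndarray:
        """Kernels evaluated at the pixel centers (raster of the array itself)."""
        return self.kernel_matrix(self.layout.pixel_centers, z_um)

    def observer_coefficients(self, point_um=(0.0, 0.0, 5000.0)) -> np.ndarray:
        """(N,) far-field observer coefficients c_j (V per A) at a 3-D point.

        Default observer: on-axis, 5 mm above the implant — a fixed linear
        proxy for the corneal recording electrode.
        """
        x, y, z = (float(v) for v in point_um)
        if z < 0:
            raise DomainError("observer must be in the half-space z >= 0")
        xy = self.layout.pixel_centers
        d = np.hypot(xy[:, 0] - x, xy[:, 1] - y)
        c = np.array(
            [
                disk_potential(
                    self.layout.electrode_radius, self.medium, (di, 0.0, z), "UCD"
                )
                for di in d
            ]
        )
        ring = self.layout.return_ring
        if ring is not None:
            c = c - annulus_potential_profile(
                np.array([math.hypot(x, y)]), z, ring.inner_radius, ring.outer_radius,
                self.medium,
            )[0]
        return c
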