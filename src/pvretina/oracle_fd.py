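"""Finite-difference Poisson solver for the volume-conduction half-space.

A vertex-centered finite-volume discretization of ``div(sigma grad phi) = 0``
on a tensor-product (optionally graded) grid.  The plane z = 0 is insulating
(natural zero-flux boundary) except under electrode footprints, where disk
current sources inject a prescribed uniform current density.  Lateral and top
boundaries are Dirichlet, either grounded ("zero") or set to the analytic
point-source far field ("farfield"), which removes most of the truncation
error of a finite box.

This solver is the package's independent oracle for the closed-form and
quadrature-based electrode kernels in :mod:`pvretina.fields`; it is not used
in the production field pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg

from .errors import DomainError, SolverError
from .fields import Medium

UM = 1e-6

__all__ = ["FDGrid", "graded_axis", "solve_fd_poisson", "fd_ep_disk_resistance"]


def graded_axis(
    fine_halfwidth: float,
    h_fine: float,
    extent: float,
    ratio: float = 1.3,
    center: float = 0.0,
    one_sided: bool = False,
) -> np.ndarray:
    """Axis with uniform spacing ``h_fine`` near ``center``, geometric growth outside.

    ``one_sided=True`` returns an axis starting at ``center`` (used for z).
    All lengths in um.
    """
    n_fine = max(2, int(round(fine_halfwidth / h_fine)))
    pos = [center + i * h_fine for i in range(n_fine + 1)]
    h = h_fine
    while pos[-1] < center + extent:
        h *= ratio
        pos.append(pos[-1] + h)
    right = np.array(pos)
    if one_sided:
        return right
    left = center - (right[1:] - center)[::-1]
    return np.concatenate([left, right])


@dataclass(frozen=True)
class FDGrid:
    """Tensor-product grid (um); ``z[0]`` must be 0 (the insulating plane)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        for name in "xyz":
            ax = getattr(self, name)
            if np.any(np.diff(ax) <= 0):
                raise DomainError(f"{name}-axis must be strictly increasing")
        if abs(self.z[0]) > 1e-12:
            raise DomainError("z-axis must start at the electrode plane z = 0")

    @property
    def shape(self):
        return (len(self.x), len(self.y), len(self.z))


def _dual_widths(axis: np.ndarray) -> np.ndarray:
    d = np.empty_like(axis)
    d[1:-1] = (axis[2:] - axis[:-2]) / 2
    d[0] = (axis[1] - axis[0]) / 2
    d[-1] = (axis[-1] - axis[-2]) / 2
    return d


def _disk_node_weights(grid: FDGrid, x0, y0, a, subsample: int = 4) -> np.ndarray:
    """Fraction of each z=0 dual cell covered by the disk, normalized to sum 1."""
    dx, dy = _dual_widths(grid.x), _dual_widths(grid.y)
    frac = np.zeros((len(grid.x), len(grid.y)))
    off = (np.arange(subsample) + 0.5) / subsample - 0.5
    ii = np.where(np.abs(grid.x - x0) <= a + dx.max())[0]
    jj = np.where(np.abs(grid.y - y0) <= a + dy.max())[0]
    for i in ii:
        xs = grid.x[i] + off * dx[i]
        for j in jj:
            ys = grid.y[j] + off * dy[j]
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            inside = (X - x0) ** 2 + (Y - y0) ** 2 <= a * a
            frac[i, j] = inside.mean() * dx[i] * dy[j]
    s = frac.sum()
    if s <= 0:
        raise DomainError("disk footprint does not overlap the grid")
    return frac / s


def _check_resolution(grid: FDGrid, a: float):
    hx = np.diff(grid.x).min()
    hy = np.diff(grid.y).min()
    if min(hx, hy) > a / 6 * (1 + 1e-9):
        raise DomainError("grid must resolve the electrode radius with >= 6 nodes")


def _assemble(grid: FDGrid, medium: Medium):
    """Sparse conductance Laplacian (SI) and bookkeeping arrays."""
    x, y, z = grid.x * UM, grid.y * UM, grid.z * UM
    nx, ny, nz = grid.shape
    sigma = 1.0 / medium.rho_si
    dx, dy, dz = _dual_widths(x), _dual_widths(y), _dual_widths(z)
    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    rows, cols, vals = [], [], []

    def add_bonds(g, ia, ib):
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        vals.extend([-g, -g])

    # x bonds
    gx = sigma / np.diff(x)  # per unit area
    for i in range(nx - 1):
        area = np.outer(dy, dz)
        g = (gx[i] * area).ravel()
        add_bonds(g, idx[i].ravel(), idx[i + 1].ravel())
    gy = sigma / np.diff(y)
    for j in range(ny - 1):
        area = np.outer(dx, dz)
        g = (gy[j] * area).ravel()
        add_bonds(g, idx[:, j].ravel(), idx[:, j + 1].ravel())
    gz = sigma / np.diff(z)
    for k in range(nz - 1):
        area = np.outer(dx, dy)
        g = (gz[k] * area).ravel()
        add_bonds(g, idx[:, :, k].ravel(), idx[:, :, k + 1].ravel())

    rows = np.concatenate(rows) if rows else np.array([], int)
    cols = np.concatenate(cols) if cols else np.array([], int)
    vals = np.concatenate(vals)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(nx * ny * nz,) * 2).tocsr()
    diag = -np.asarray(A.sum(axis=1)).ravel()
    A = A + sp.diags(diag)
    return A


def _boundary_mask(grid: FDGrid) -> np.ndarray:
    nx, ny, nz = grid.shape
    m = np.zeros((nx, ny, nz), bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, -1] = True
    return m.ravel()


def _farfield_values(grid: FDGrid, disks, medium: Medium) -> np.ndarray:
    X, Y, Z = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij")
    phi = np.zeros_like(X, float)
    for x0, y0, a, cur in disks:
        r = np.sqrt((X - x0) ** 2 + (Y - y0) ** 2 + Z**2) * UM
        r = np.maximum(r, a * UM)
        phi += medium.rho_si * cur / (2 * math.pi * r)
    return phi.ravel()


def solve_fd_poisson(
    grid: FDGrid,
    disks,
    medium: Medium,
    boundary: str = "farfield",
    rtol: float = 1e-8,
    maxiter: int = 40000,
) -> np.ndarray:
    """Potential (V) on the grid for UCD disk sources on the z = 0 plane.

    ``disks`` is a sequence of ``(x0_um, y0_um, radius_um, current_A)``.
    ``boundary``: "zero" grounds the box faces; "farfield" (default) sets
    them to the superposed point-source potential of the sources.
    """
    for _, _, a, _ in disks:
        _check_resolution(grid, a)
    A = _assemble(grid, medium)
    n = A.shape[0]
    b = np.zeros(n)
    nz = len(grid.z)
    for x0, y0, a, cur in disks:
        wts = _disk_node_weights(grid, x0, y0, a)
        flat = np.zeros(grid.shape)
        flat[:, :, 0] = wts * cur
        b += flat.ravel()
    bmask = _boundary_mask(grid)
    if boundary == "farfield" and disks:
        phi_b = _farfield_values(grid, disks, medium)
    elif boundary == "zero" or not disks:
        phi_b = np.zeros(n)
    else:
        raise DomainError(f"unknown boundary treatment {boundary!r}")
    free = ~bmask
    Aff = A[free][:, free]
    b_eff = b[free] - A[free][:, bmask] @ phi_b[bmask]
    if not np.any(np.abs(b_eff) > 0):
        phi = np.zeros(n)
        phi[bmask] = phi_b[bmask]
        return phi.reshape(grid.shape)
    M = sp.diags(1.0 / Aff.diagonal())
    sol, info = cg(Aff, b_eff, rtol=rtol, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(Aff @ sol - b_eff) / np.linalg.norm(b_eff))
    if info != 0:
        raise SolverError(f"CG failed to converge (info={info})", residual=res)
    phi = np.empty(n)
    phi[free] = sol
    phi[bmask] = phi_b[bmask]
    return phi.reshape(grid.shape)


def fd_ep_disk_resistance(
    grid: FDGrid,
    center,
    radius_um: float,
    medium: Medium,
    rtol: float = 1e-8,
) -> float:
    """Access resistance of an equipotential disk, from a Dirichlet FD solve.

    The electrode nodes are clamped to 1 V, the box faces to 0 V; the
    resistance is 1 V over the total current leaving the electrode.
    """
    _check_resolution(grid, radius_um)
    x0, y0 = center
    A = _assemble(grid, medium)
    n = A.shape[0]
    shape = grid.shape
    elec = np.zeros(shape, bool)
    dist2 = (grid.x[:, None] - x0) ** 2 + (grid.y[None, :] - y0) ** 2
    elec[:, :, 0] = dist2 <= radius_um**2
    elec = elec.ravel()
    if not elec.any():
        raise DomainError("electrode footprint contains no grid nodes")
    bmask = _boundary_mask(grid)
    fixed = elec | bmask
    phi_fixed = np.where(elec, 1.0, 0.0)
    free = ~fixed
    Aff = A[free][:, free]
    b_eff = -A[free][:, fixed] @ phi_fixed[fixed]
    M = sp.diags(1.0 / Aff.diagonal())
    sol, info = cg(Aff, b_eff, rtol=rtol, maxiter=40000, M=M)
    if info != 0:
        raise SolverError(f"CG failed to converge (info={info})")
    phi = np.empty(n)
    phi[free] = sol
    phi[fixed] = phi_fixed[fixed]
    current = float(elec @ (A @ phi))
    if current <= 0:
        raise SolverError("nonpositive electrode current in EP solve")
    return 1.0 / current
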