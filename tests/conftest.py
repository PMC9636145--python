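"""Shared fixtures: small electrode clusters, reference oracles, and
session-scoped heavy computations reused by unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from pvretina.circuit import _solve_currents, default_params, photocurrent, simulate
from pvretina.fields import Medium, cross_resistance_matrix
from pvretina.geometry import SpatialPattern, build_hex_array, project_pattern


@pytest.fixture(scope="session")
def medium():
    return Medium()  # 700 ohm-cm retina surrogate


@pytest.fixture(scope="session")
def medium_1ohm_m():
    return Medium(100.0)


@pytest.fixture(scope="session")
def cluster7(medium):
    """Seven-pixel hexagonal cluster, return at infinity."""
    layout = build_hex_array(40, 81, 18, return_ring=None)
    assert layout.n_pixels == 7
    R = cross_resistance_matrix(layout, medium)
    return layout, R, default_params(layout, R)


@pytest.fixture(scope="session")
def cluster13(medium):
    """Thirteen-pixel cluster with a peripheral return ring."""
    layout = build_hex_array(40, 140, 18)
    R = cross_resistance_matrix(layout, medium)
    return layout, R, default_params(layout, R)


@pytest.fixture(scope="session")
def full_array(medium):
    """The full 1.5 mm, 40 um-pixel array and its cross-resistance matrix."""
    layout = build_hex_array(40, 1500, 18)
    R = cross_resistance_matrix(layout, medium)
    return layout, R


def implicit_euler_oracle(drive, R, params, dt_ms=1e-3):
    """Fixed-step backward-Euler reference integrator (default 1 us steps).

    Deliberately independent of the adaptive trapezoidal path in
    ``pvretina.circuit.simulate``: fixed steps, first order, no error
    control.  Returns (t_ms, u, I) sampled at every step.
    """
    M = R.R
    n = M.shape[0]
    ca = params.interface.active_capacitance
    cr = params.interface.return_capacitance
    cri = 0.0 if cr is None else 1.0 / cr
    u = np.zeros(n)
    ur = 0.0
    e0 = drive.irradiance_at(0.5e-9)
    I = _solve_currents(M, u - ur, photocurrent(e0, params.photo), params.diode)
    ts, us, Is = [0.0], [u.copy()], [I.copy()]
    t = 0.0
    while t < drive.duration - 1e-9:
        e = drive.irradiance_at(t + dt_ms / 2)
        i_ph = photocurrent(e, params.photo)
        dt_s = dt_ms * 1e-3
        A = M + np.diag(np.full(n, dt_s / ca)) + dt_s * cri
        I = _solve_currents(A, u - ur, i_ph, params.diode, guess=I)
        u = u + dt_s * I / ca
        ur = ur - dt_s * cri * I.sum()
        t += dt_ms
        ts.append(t), us.append(u.copy()), Is.append(I.copy())
    return np.array(ts), np.array(us), np.array(Is)


@pytest.fixture(scope="session")
def oracle_comparison(cluster13):
    """Adaptive solver vs 1 us implicit-Euler oracle over one 40 Hz cycle."""
    layout, R, params = cluster13
    drive = project_pattern(
        layout, SpatialPattern("full_field"), 1.0,
        pulse_width=10, repetition_rate=40, duration=25,
    )
    trace = simulate(drive, R, params, output_dt_ms=1e-3)
    ts, us, Is = implicit_euler_oracle(drive, R, params)
    m = len(ts)
    rms_u = np.sqrt(np.mean((trace.u[:m] - us) ** 2)) / np.sqrt(np.mean(us**2))
    rms_i = np.sqrt(np.mean((trace.I[:m] - Is) ** 2)) / np.sqrt(np.mean(Is**2))
    return {"rms_u": rms_u, "rms_i": rms_i, "trace": trace}


@pytest.fixture(scope="session")
def fullscale_contrast(full_array, medium):
    """Full 1.5 mm grating-contrast runs at both dark-pixel biases."""
    from pvretina.experiments import grating_contrast_run

    layout, R = full_array
    out = {}
    for bias in (0.5, 0.2):
        out[bias] = grating_contrast_run(layout, medium, bias, R=R)
    return out


@pytest.fixture(scope="session")
def sweep_response(medium):
    """Normalized far-field amplitude vs repetition rate on a 19-pixel array."""
    from pvretina.experiments import frequency_sweep_run

    layout = build_hex_array(40, 200, 18)
    return frequency_sweep_run(layout, medium, rates_hz=(1, 2, 5, 10, 20, 40, 64, 125))


@pytest.fixture(scope="session")
def field_stop_result(medium):
    """Field-stop closure transient on a 0.5 mm array."""
    from pvretina.experiments import field_stop_run

    layout = build_hex_array(40, 500, 18)
    return field_stop_run(layout, medium, n_post_periods=1)


@pytest.fixture(scope="session")
def cluster_fd_comparison(medium):
    """Kernel superposition vs the FD Poisson oracle on a 7-pixel cluster."""
    from pvretina.fields import ElementaryFieldSet
    from pvretina.oracle_fd import FDGrid, graded_axis, solve_fd_poisson

    layout = build_hex_array(40, 81, 18, return_ring=None)
    currents = np.array([1.0, -0.5, 0.8, 0.3, -0.2, 0.6, -1.0]) * 1e-6
    xy = graded_axis(66, 1.5, 350, ratio=1.4)
    z = graded_axis(40, 1.5, 350, ratio=1.4, one_sided=True)
    grid = FDGrid(xy, xy, z)
    disks = [
        (c[0], c[1], layout.electrode_radius, i)
        for c, i in zip(layout.pixel_centers, currents)
    ]
    phi = solve_fd_poisson(grid, disks, medium)
    kernels = ElementaryFieldSet(layout, medium)
    return layout, currents, grid, phi, kernels
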