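"""Coupled nonlinear dynamics of photovoltaic pixels in electrolyte.

Each pixel is a photocurrent source in parallel with a Si diode between the
pixel's two terminals.  The active (p+) terminal couples to the electrolyte
through the SIROF interface capacitance; all return (n+) terminals share the
common peripheral return with its own (much larger) interface capacitance.
Electrolyte coupling between pixels is the return-referenced cross-resistance
matrix ``R``: with pixel currents ``I`` (anodic positive, out of the active
electrode), the diode voltage of pixel i is

    V_D,i = u_i - u_r + sum_j R_ij I_j

where ``u_i`` is the active-interface capacitor voltage and ``u_r`` the
return-interface voltage.  The pixel current balance

    I_i = I_ph,i - I_dark(V_D,i)

is a monotone nonlinear algebraic system solved by damped Newton iteration;
the interface voltages evolve as ``C_a du_i/dt = I_i`` and
``C_r du_r/dt = -sum_i I_i`` (the return carries the full counter-current,
so charge is conserved identically).  Time integration is adaptive
trapezoidal with step-doubling error control.

Irradiance is in mW/mm^2 and time in ms at the API; currents in A and
voltages in V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DomainError,
    NonStationaryError,
    SolverError,
    StiffnessError,
)
from .fields import CrossResistanceMatrix
from .geometry import ArrayLayout, PixelDrive

__all__ = [
    "DiodeParams",
    "PhotoParams",
    "InterfaceParams",
    "PixelCircuitParams",
    "PixelState",
    "SimTrace",
    "default_params",
    "photocurrent",
    "diode_dark_current",
    "electrode_charge_density",
    "interface_voltage_step",
    "open_circuit_voltage",
    "solve_network_currents",
    "simulate",
    "run_to_steady_state",
    "precondition",
]


@dataclass(frozen=True)
class DiodeParams:
    """Shockley diode parameters.

    Defaults are calibrated so that (a) the turn-on voltage is about 0.5 V at
    stimulation-scale current (~0.5 uA) and (b) the open-circuit photovoltage
    stays below the 0.6 V single-junction limit at 8 mW/mm^2.
    """

    saturation_current: float = 1.2e-12  # A
    ideality: float = 1.5
    thermal_voltage: float = 0.025852  # V
    shunt_conductance: float = 0.0  # S, optional leakage across the diode

    def __post_init__(self):
        if self.saturation_current <= 0 or self.ideality < 1:
            raise DomainError("require I0 > 0 and ideality >= 1")

    @property
    def nvt(self) -> float:
        return self.ideality * self.thermal_voltage


@dataclass(frozen=True)
class PhotoParams:
    """Photodiode responsivity and geometry.

    ``photosensitive_area_cm2`` defaults to twice the active-electrode area
    (``area_ratio = 2``), as in the fabricated arrays.
    """

    responsivity: float = 0.51  # A/W
    photosensitive_area_cm2: float = 5.0894e-6  # 2 x 18 um-diameter disk
    area_ratio: float = 2.0


@dataclass(frozen=True)
class InterfaceParams:
    """Electrode-electrolyte interface capacitances.

    ``return_capacitance=None`` models an ideal (infinitely large) return:
    its interface voltage stays at zero.  With a finite value the return
    state relaxes with time constant ``return_capacitance *
    return_access_resistance``.
    """

    specific_capacitance: float = 6.0e-3  # F/cm^2 (SIROF)
    active_area_cm2: float = 2.5447e-6  # 18 um-diameter disk
    return_capacitance: float | None = None  # F
    return_access_resistance: float = 0.0  # ohm

    @property
    def active_capacitance(self) -> float:
        """Per-pixel active interface capacitance, F."""
        return self.specific_capacitance * self.active_area_cm2


@dataclass(frozen=True)
class PixelCircuitParams:
    diode: DiodeParams = field(default_factory=DiodeParams)
    photo: PhotoParams = field(default_factory=PhotoParams)
    interface: InterfaceParams = field(default_factory=InterfaceParams)


def default_params(
    layout: ArrayLayout,
    R: CrossResistanceMatrix | None = None,
    return_rc_ms: float = 40.0,
) -> PixelCircuitParams:
    """Default circuit parameters for a layout.

    The photosensitive area is twice the active electrode area; the return
    interface capacitance is chosen so that the return RC time equals
    ``return_rc_ms`` (the printed 40 ms) given the computed access
    resistance of the return annulus.
    """
    a_cm = layout.electrode_radius * 1e-4
    area = math.pi * a_cm**2
    photo = PhotoParams(photosensitive_area_cm2=2.0 * area)
    if R is not None and R.r0 > 0:
        interface = InterfaceParams(
            active_area_cm2=area,
            return_capacitance=return_rc_ms * 1e-3 / R.r0,
            return_access_resistance=R.r0,
        )
    else:
        interface = InterfaceParams(active_area_cm2=area)
    return PixelCircuitParams(photo=photo, interface=interface)


@dataclass
class PixelState:
    """Interface-capacitor voltages of the array at one instant."""

    u: np.ndarray  # (N,) active interface voltages, V
    u_r: float = 0.0  # return interface voltage, V
    t_ms: float = 0.0

    @classmethod
    def zero(cls, n_pixels: int) -> "PixelState":
        return cls(u=np.zeros(n_pixels))

    def copy(self) -> "PixelState":
        return PixelState(u=self.u.copy(), u_r=self.u_r, t_ms=self.t_ms)


def precondition(state: PixelState, pixels, bias: float) -> PixelState:
    """Set the active-interface voltage of the designated pixels to ``bias``.

    Emulates the optical pre-charging protocol that turns dark pixels into
    transient returns.  ``bias`` must lie within [-1, 1] V.
    """
    if not -1.0 <= bias <= 1.0:
        raise DomainError("precondition bias must lie within [-1, 1] V")
    pixels = np.asarray(pixels, int)
    if pixels.size and (pixels.min() < 0 or pixels.max() >= len(state.u)):
        raise IndexError("unknown pixel index in precondition set")
    out = state.copy()
    out.u[pixels] = bias
    return out


# ---------------------------------------------------------------------------
# elementary relations
# ---------------------------------------------------------------------------


def photocurrent(irradiance_mw_mm2, photo: PhotoParams) -> np.ndarray | float:
    """Photocurrent (A) for an irradiance in mW/mm^2; linear in irradiance."""
    irr = np.asarray(irradiance_mw_mm2, float)
    if np.any(irr < 0):
        raise DomainError("irradiance must be nonnegative")
    # 1 mW/mm^2 = 0.1 W/cm^2
    out = photo.responsivity * irr * 0.1 * photo.photosensitive_area_cm2
    return float(out) if np.isscalar(irradiance_mw_mm2) else out


_EXP_CLIP = 600.0


def _diode_iv(v, diode: DiodeParams):
    """Dark current and differential conductance at forward voltage v."""
    x = np.clip(np.asarray(v, float) / diode.nvt, -_EXP_CLIP, _EXP_CLIP)
    e = np.exp(x)
    i = diode.saturation_current * (e - 1.0) + diode.shunt_conductance * np.asarray(v)
    g = diode.saturation_current * e / diode.nvt + diode.shunt_conductance
    return i, g


def diode_dark_current(v, diode: DiodeParams | None = None) -> np.ndarray | float:
    """Shockley dark current ``I0 (exp(V/(n V_T)) - 1)`` (A); monotone in V."""
    diode = diode or DiodeParams()
    i, _ = _diode_iv(v, diode)
    return float(i) if np.isscalar(v) else i


def electrode_charge_density(
    irradiance_mw_mm2: float, pulse_width_ms: float, params: PixelCircuitParams
) -> float:
    """Charge injection density on the active electrode, mC/cm^2.

    Photocurrent divided by the electrode area, times the pulse duration:
    the area ratio between photosensitive region and electrode concentrates
    the photocurrent onto the smaller electrode.
    """
    if irradiance_mw_mm2 < 0 or pulse_width_ms <= 0:
        raise DomainError("irradiance must be >= 0 and pulse width > 0")
    i_ph = photocurrent(irradiance_mw_mm2, params.photo)
    j = i_ph / params.interface.active_area_cm2  # A/cm^2
    return j * pulse_width_ms  # (A/cm^2)(ms) = mC/cm^2


def interface_voltage_step(charge_density_mc_cm2: float, params: PixelCircuitParams) -> float:
    """Interface voltage excursion (V) for a charge density in mC/cm^2."""
    return charge_density_mc_cm2 * 1e-3 / params.interface.specific_capacitance


def open_circuit_voltage(
    irradiance_mw_mm2: float, params: PixelCircuitParams | None = None
) -> float:
    """Open-circuit photovoltage (V) with the electrolyte path removed.

    Solves ``I_ph = I_dark(V)``; for the pure Shockley diode this is
    ``n V_T ln(1 + I_ph / I0)``, clamped by the single-junction limit.
    """
    params = params or PixelCircuitParams()
    i_ph = photocurrent(irradiance_mw_mm2, params.photo)
    d = params.diode
    if d.shunt_conductance == 0.0:
        return d.nvt * math.log1p(i_ph / d.saturation_current)
    from scipy.optimize import brentq

    return brentq(lambda v: _diode_iv(v, d)[0] - i_ph, 0.0, 2.0, xtol=1e-12)


# ---------------------------------------------------------------------------
# network solve
# ---------------------------------------------------------------------------


def _as_matrix(R) -> np.ndarray:
    return R.R if isinstance(R, CrossResistanceMatrix) else np.asarray(R, float)


def _solve_currents(
    A: np.ndarray,
    b: np.ndarray,
    i_ph: np.ndarray,
    diode: DiodeParams,
    guess: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Solve ``I = i_ph - I_dark(b + A I)`` by damped Newton iteration.

    The system is monotone (the diode IV curve is increasing and A is a
    positive-semidefinite resistance operator), so the solution is unique.
    Rows whose diode conductance is negligible are handled in closed form,
    which shrinks the dense linear solve to the conducting subset.
    """
    n = len(i_ph)
    I = np.zeros(n) if guess is None else guess.copy()
    i_d, _ = _diode_iv(b + A @ I, diode)
    F = I - i_ph + i_d
    fnorm = np.max(np.abs(F))
    for _ in range(max_iter):
        if fnorm < tol:
            return I
        v = b + A @ I
        i_d, g = _diode_iv(v, diode)
        F = I - i_ph + i_d
        fnorm = np.max(np.abs(F))
        if fnorm < tol:
            return I
        act = g > 1e-10  # conducting diodes couple through A
        dI = -F.copy()
        if act.any():
            G = g[act]
            M = A[np.ix_(act, act)] * G[:, None]
            M[np.diag_indices_from(M)] += 1.0
            rhs = -F[act]
            if (~act).any():
                rhs = rhs - G * (A[np.ix_(act, ~act)] @ dI[~act])
            try:
                dI[act] = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise SolverError(f"Newton linear solve failed: {exc}", residual=fnorm)
        # damping: limit the diode-voltage excursion per iteration, then
        # backtrack on the residual norm
        dv = A @ dI
        scale = np.max(np.abs(dv))
        s = min(1.0, 10.0 * diode.nvt / scale) if scale > 0 else 1.0
        for _ in range(60):
            I_new = I + s * dI
            i_d_new, _ = _diode_iv(b + A @ I_new, diode)
            f_new = np.max(np.abs(I_new - i_ph + i_d_new))
            if f_new < fnorm * (1.0 - 1e-4 * s) or f_new < tol:
                break
            s *= 0.5
        else:
            raise SolverError("Newton line search stalled", residual=fnorm)
        I = I_new
        fnorm = f_new
    raise SolverError("network Newton did not converge", residual=fnorm)


def solve_network_currents(
    state: PixelState,
    irradiance_mw_mm2: np.ndarray,
    R: CrossResistanceMatrix | np.ndarray,
    params: PixelCircuitParams,
    guess: np.ndarray | None = None,
) -> np.ndarray:
    """Instantaneous pixel currents (A) for given interface voltages.

    Solves the nonlinear algebraic system ``I_i = I_ph,i - I_dark(V_D,i)``
    with ``V_D = u - u_r + R I`` to a residual below 1e-12 A.
    """
    M = _as_matrix(R)
    u = np.asarray(state.u, float)
    if M.shape[0] != len(u) or len(u) != len(np.atleast_1d(irradiance_mw_mm2)):
        raise DomainError("inconsistent dimensions between state, drive and R")
    i_ph = photocurrent(np.atleast_1d(irradiance_mw_mm2), params.photo)
    b = u - state.u_r
    return _solve_currents(M, b, i_ph, params.diode, guess=guess)


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------


@dataclass
class SimTrace:
    """Simulated time series on a regular output grid.

    ``u``: active-interface voltages (V); ``I``: pixel currents (A, anodic
    positive); ``phi``: ground-referenced electrolyte surface potentials at
    the electrodes (V); ``u_r``: return interface voltage (V).
    """

    t_ms: np.ndarray
    u: np.ndarray  # (T, N)
    I: np.ndarray  # (T, N)
    phi: np.ndarray  # (T, N)
    u_r: np.ndarray  # (T,)

    @property
    def n_pixels(self) -> int:
        return self.u.shape[1]

    def final_state(self) -> PixelState:
        return PixelState(u=self.u[-1].copy(), u_r=float(self.u_r[-1]), t_ms=float(self.t_ms[-1]))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("t", data=self.t_ms)
            fh.create_dataset("u", data=self.u)
            fh.create_dataset("I", data=self.I)
            fh.create_dataset("phi", data=self.phi)
            fh.create_dataset("u_r", data=self.u_r)

    def to_csv(self, path) -> None:
        import pandas as pd

        T, N = self.u.shape
        df = pd.DataFrame(
            {
                "t_ms": np.repeat(self.t_ms, N),
                "pixel": np.tile(np.arange(N), T),
                "u_V": self.u.ravel(),
                "I_A": self.I.ravel(),
                "phi_V": self.phi.ravel(),
            }
        )
        df.to_csv(path, index=False)


def _trapezoid_step(u, u_r, I0, dt_s, e_vec, M, ca, cr_inv, params, guess):
    """One implicit trapezoidal step; returns (u1, ur1, I1)."""
    i_ph = photocurrent(e_vec, params.photo)
    half = dt_s / 2.0
    b = u + half * I0 / ca - u_r + half * cr_inv * I0.sum()
    A_eff = M + np.diag(half / ca)
    if cr_inv > 0:
        A_eff = A_eff + half * cr_inv
    I1 = _solve_currents(A_eff, b, i_ph, params.diode, guess=guess)
    u1 = u + half * (I0 + I1) / ca
    ur1 = u_r - half * cr_inv * (I0.sum() + I1.sum())
    return u1, ur1, I1


def simulate(
    drive: PixelDrive,
    R: CrossResistanceMatrix | np.ndarray,
    params: PixelCircuitParams,
    init: PixelState | None = None,
    *,
    local_tol: float = 1e-6,
    min_step_ms: float = 1e-7,
    max_step_ms: float | None = None,
    output_dt_ms: float | None = None,
) -> SimTrace:
    """Integrate the coupled pixel dynamics over the drive duration.

    Adaptive trapezoidal rule with step-doubling local error control
    (``local_tol`` in volts); pulse edges and pattern reversals are exact
    step boundaries.  The trace is resampled onto a regular output grid.
    """
    M = _as_matrix(R)
    n = M.shape[0]
    if drive.n_pixels != n:
        raise DomainError("drive and cross-resistance dimensions differ")
    if drive.duration <= 0:
        raise DomainError("drive duration must be positive")
    ca = np.full(n, params.interface.active_capacitance)
    cr = params.interface.return_capacitance
    cr_inv = 0.0 if cr is None else 1.0 / cr
    state = init.copy() if init is not None else PixelState.zero(n)
    u, u_r = state.u.astype(float), float(state.u_r)

    edges = drive.breakpoints()
    ts, us, Is, urs = [], [], [], []
    I_guess = None
    dt_ms = None
    for t0, t1 in zip(edges[:-1], edges[1:]):
        e_vec = drive.irradiance_at(t0 + min(1e-9, (t1 - t0) / 2))
        i_ph = photocurrent(e_vec, params.photo)
        I0 = _solve_currents(M, u - u_r, i_ph, params.diode, guess=I_guess)
        ts.append(t0), us.append(u.copy()), Is.append(I0.copy()), urs.append(u_r)
        t = t0
        if dt_ms is None:
            dt_ms = (t1 - t0) / 16
        dt_ms = min(dt_ms, t1 - t0)
        while t < t1 - 1e-12:
            dt_ms = min(dt_ms, t1 - t)
            if dt_ms < min_step_ms:
                raise StiffnessError(
                    f"step size underflow at t = {t:.6f} ms (dt = {dt_ms:.3e} ms)"
                )
            dt_s = dt_ms * 1e-3
            try:
                uf, urf, If = _trapezoid_step(
                    u, u_r, I0, dt_s, e_vec, M, ca, cr_inv, params, I0
                )
                um, urm, Im = _trapezoid_step(
                    u, u_r, I0, dt_s / 2, e_vec, M, ca, cr_inv, params, I0
                )
                uh, urh, Ih = _trapezoid_step(
                    um, urm, Im, dt_s / 2, e_vec, M, ca, cr_inv, params, Im
                )
            except SolverError:
                dt_ms /= 4.0
                continue
            err = max(np.max(np.abs(uh - uf)), abs(urh - urf)) / 3.0
            if err <= local_tol:
                t += dt_ms
                u, u_r, I0 = uh, urh, Ih
                ts.append(t0 + (t - t0)), us.append(u.copy()), Is.append(I0.copy())
                urs.append(u_r)
                I_guess = I0
            factor = 0.9 * (local_tol / err) ** (1.0 / 3.0) if err > 0 else 4.0
            dt_ms *= min(4.0, max(0.2, factor))
            if max_step_ms is not None:
                dt_ms = min(dt_ms, max_step_ms)

    t_raw = np.array(ts)
    u_raw = np.array(us)
    I_raw = np.array(Is)
    ur_raw = np.array(urs)
    # keep both sides of each pulse-edge discontinuity, separated by a tiny dt
    for k in np.where(np.diff(t_raw) <= 1e-12)[0]:
        t_raw[k + 1] = t_raw[k] + 1e-9

    if output_dt_ms is None:
        output_dt_ms = max(drive.duration / 2000.0, drive.pulse_width / 50.0)
    t_out = np.arange(0.0, drive.duration + output_dt_ms / 2, output_dt_ms)
    t_out = np.clip(t_out, 0.0, t_raw[-1])

    def interp(arr):
        return np.array([np.interp(t_out, t_raw, arr[:, k]) for k in range(arr.shape[1])]).T

    u_out = interp(u_raw)
    I_out = interp(I_raw)
    ur_out = np.interp(t_out, t_raw, ur_raw)
    if isinstance(R, CrossResistanceMatrix):
        phi_out = I_out @ R.R_ground.T
    else:
        phi_out = I_out @ M.T
    return SimTrace(t_ms=t_out, u=u_out, I=I_out, phi=phi_out, u_r=ur_out)


def run_to_steady_state(
    drive: PixelDrive,
    R: CrossResistanceMatrix | np.ndarray,
    params: PixelCircuitParams,
    init: PixelState | None = None,
    *,
    tol_v: float = 10e-6,
    max_periods: int = 400,
    **sim_opts,
) -> SimTrace:
    """Iterate single periods of a periodic drive until the state repeats.

    Convergence criterion: the maximum interface-voltage change across one
    period falls below ``tol_v`` (default 10 uV).  Returns the trace of the
    last period.
    """
    n = _as_matrix(R).shape[0]
    state = init.copy() if init is not None else PixelState.zero(n)
    trace = None
    for _ in range(max_periods):
        u_start, ur_start = state.u.copy(), state.u_r
        trace = simulate(drive, R, params, init=state, **sim_opts)
        state = trace.final_state()
        delta = max(np.max(np.abs(state.u - u_start)), abs(state.u_r - ur_start))
        if delta < tol_v:
            return trace
    raise NonStationaryError(
        f"no periodic steady state within {max_periods} periods (delta = {delta:.3e} V)"
    )
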