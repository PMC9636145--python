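"""Tissue potential maps, stimulation-contrast metrics, far-field proxy.

The activating function of subretinal bipolar-cell stimulation is
approximated by the trans-cellular potential step: the difference between
the electrolyte potential 10 um above the implant (bottom of the bipolar
dendrites) and 57 um (middle of the inner plexiform layer, where the axonal
terminals sit).  Grating contrast compares this step above bright versus
dark pixel rows:

    contrast = 100 * (Vb - Vd) / Vb   [%]

so equal rows give 0% and contrast reaches or exceeds 100% exactly when the
dark-row step is driven to zero or below (dark pixels acting as transient
returns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, GeometryError
from .fields import ElementaryFieldSet
from .geometry import ArrayLayout, SpatialPattern
from .circuit import SimTrace

__all__ = [
    "FieldMap",
    "ContrastReport",
    "potential_map",
    "transcellular_step",
    "grating_contrast",
    "far_field_waveform",
    "peak_to_peak",
    "normalized_frequency_response",
]


@dataclass(frozen=True)
class FieldMap:
    """Scalar potential (V) sampled at lateral points for one or two z planes."""

    points_um: np.ndarray  # (M, 2)
    values: np.ndarray  # (M,)
    z_planes_um: tuple

    @property
    def values_mv(self) -> np.ndarray:
        return self.values * 1e3

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "x_um": self.points_um[:, 0],
                "y_um": self.points_um[:, 1],
                "potential_mV": self.values_mv,
            }
        ).to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("grid/x", data=self.points_um[:, 0])
            fh.create_dataset("grid/y", data=self.points_um[:, 1])
            fh.create_dataset("grid/z", data=np.asarray(self.z_planes_um))
            fh.create_dataset("phi", data=self.values)


def potential_map(
    currents: np.ndarray,
    kernels: ElementaryFieldSet,
    z_um: float,
    points_um: np.ndarray | None = None,
) -> FieldMap:
    """Electrolyte potential map: weighted sum of elementary kernels.

    ``currents`` in amperes, one entry per pixel; default evaluation raster
    is the pixel centers.
    """
    if z_um < 0:
        raise DomainError("z must be at or above the electrode plane")
    I = np.asarray(currents, float)
    if len(I) != kernels.layout.n_pixels:
        raise DomainError("current vector length must match the pixel count")
    pts = kernels.layout.pixel_centers if points_um is None else np.atleast_2d(points_um)
    K = kernels.kernel_matrix(pts, z_um)
    return FieldMap(points_um=pts, values=K @ I, z_planes_um=(z_um,))


def transcellular_step(
    currents: np.ndarray,
    kernels: ElementaryFieldSet,
    z_low_um: float = 10.0,
    z_high_um: float = 57.0,
    points_um: np.ndarray | None = None,
) -> FieldMap:
    """Trans-cellular potential step phi(z_low) - phi(z_high)."""
    if not z_low_um < z_high_um:
        raise DomainError("require z_low < z_high")
    low = potential_map(currents, kernels, z_low_um, points_um)
    high = potential_map(currents, kernels, z_high_um, points_um)
    return FieldMap(
        points_um=low.points_um,
        values=low.values - high.values,
        z_planes_um=(z_low_um, z_high_um),
    )


@dataclass(frozen=True)
class ContrastReport:
    """Bright-vs-dark row comparison of the trans-cellular step (mV / %)."""

    bright_mean_mv: float
    dark_mean_mv: float
    contrast_percent: float
    row_means_mv: dict
    n_bright: int
    n_dark: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "bright_mean_mV": self.bright_mean_mv,
                    "dark_mean_mV": self.dark_mean_mv,
                    "contrast_percent": self.contrast_percent,
                    "row_means_mV": {str(k): v for k, v in self.row_means_mv.items()},
                    "n_bright": self.n_bright,
                    "n_dark": self.n_dark,
                },
                fh,
                indent=1,
            )


def grating_contrast(
    step: FieldMap,
    pattern: SpatialPattern,
    layout: ArrayLayout,
    margin_rows: int = 2,
    frame: int = 0,
) -> ContrastReport:
    """Contrast of a trans-cellular step map under a row grating.

    ``step`` must be evaluated at the pixel centers.  Means are taken over
    interior pixels (at least ``margin_rows`` row pitches from the rim) to
    exclude edge effects near the return ring.
    """
    if pattern.kind != "grating":
        raise DomainError("contrast is defined for grating patterns")
    if step.values.shape[0] != layout.n_pixels:
        raise DomainError("step map must be sampled at the pixel centers")
    bright = pattern.mask(layout, frame) > 0.5
    interior = layout.interior_mask(margin_rows)
    nb = int(np.sum(bright & interior))
    nd = int(np.sum(~bright & interior))
    if nb == 0 or nd == 0:
        raise GeometryError("no interior bright/dark rows: array too small for contrast")
    vb = float(np.mean(step.values[bright & interior])) * 1e3
    vd = float(np.mean(step.values[~bright & interior])) * 1e3
    if vb == 0:
        raise DomainError("bright-row mean step is zero; contrast undefined")
    rows = layout.row_index()
    row_means = {}
    for r in np.unique(rows[interior]):
        sel = interior & (rows == r)
        row_means[int(r)] = float(np.mean(step.values[sel])) * 1e3
    return ContrastReport(
        bright_mean_mv=vb,
        dark_mean_mv=vd,
        contrast_percent=100.0 * (vb - vd) / vb,
        row_means_mv=row_means,
        n_bright=nb,
        n_dark=nd,
    )


def far_field_waveform(trace: SimTrace, observer_coeffs: np.ndarray) -> np.ndarray:
    """Far-field (corneal-proxy) waveform c . I(t), volts.

    ``observer_coeffs`` are the elementary-kernel potentials (V/A) at a
    fixed remote observer point; only the waveform shape and its relative
    frequency dependence are meaningful, not absolute corneal amplitudes.
    """
    c = np.asarray(observer_coeffs, float)
    if len(c) != trace.n_pixels:
        raise DomainError("coefficient length must match the pixel count")
    return trace.I @ c


def peak_to_peak(
    waveform: np.ndarray, t_ms: np.ndarray | None = None, window_ms: tuple | None = None
) -> float:
    """Max minus min of a waveform, optionally restricted to a time window."""
    w = np.asarray(waveform, float)
    if window_ms is not None:
        if t_ms is None:
            raise DomainError("a time axis is required with a window")
        lo, hi = window_ms
        sel = (t_ms >= lo) & (t_ms <= hi)
        if not np.any(sel):
            raise DomainError("empty peak-to-peak window")
        w = w[sel]
    return float(w.max() - w.min())


def normalized_frequency_response(
    rates_hz,
    run_one_rate,
) -> np.ndarray:
    """Peak-to-peak far-field amplitude per repetition rate, normalized to the
    lowest rate (the 1 Hz reference in the standard protocol).

    ``run_one_rate(rate) -> (t_ms, waveform)`` must return one steady-state
    period of the far-field waveform at that rate.
    """
    rates = list(rates_hz)
    if not rates:
        raise DomainError("rate list must not be empty")
    amps = []
    for rate in rates:
        t, w = run_one_rate(rate)
        amps.append(peak_to_peak(w))
    amps = np.asarray(amps)
    return amps / amps[0]
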