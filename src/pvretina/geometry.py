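"""Implant array layouts and projection of optical patterns onto pixels.

Coordinates are 2-D, in micrometers, with the origin at the array center.
Pixel rows run along the x axis; the hexagonal row pitch is the vertical
spacing ``pixel_width * cos(30 deg)``.  The z axis points from the implant
surface into the tissue, with z = 0 at the electrode plane.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, TimingError, DomainError

COS30 = math.cos(math.pi / 6)

__all__ = [
    "ReturnRing",
    "ArrayLayout",
    "SpatialPattern",
    "PixelDrive",
    "build_hex_array",
    "project_pattern",
]


@dataclass(frozen=True)
class ReturnRing:
    """Annular common return electrode at the array periphery (radii in um)."""

    inner_radius: float
    outer_radius: float

    def __post_init__(self):
        if not (0 < self.inner_radius < self.outer_radius):
            raise GeometryError("return ring radii must satisfy 0 < inner < outer")


@dataclass(frozen=True)
class ArrayLayout:
    """Hexagonal monopolar pixel array.

    Parameters
    ----------
    pixel_width:
        Center-to-center distance of nearest-neighbour pixels, um.
    row_pitch:
        Vertical spacing between pixel rows, um (``pixel_width * cos 30``).
    pixel_centers:
        (N, 2) array of pixel center coordinates, um.
    electrode_radius:
        Radius of the SIROF-coated active electrode disk, um.
    array_diameter:
        Diameter of the disc to which the lattice is clipped, um.
    return_ring:
        Peripheral common return, or ``None`` for an isolated cluster whose
        return is at infinity.
    device_thickness:
        Implant thickness, um (geometry metadata; the field model treats the
        implant face as an insulating plane).
    """

    pixel_width: float
    row_pitch: float
    pixel_centers: np.ndarray
    electrode_radius: float
    array_diameter: float
    return_ring: ReturnRing | None = None
    device_thickness: float = 30.0

    def __post_init__(self):
        object.__setattr__(
            self, "pixel_centers", np.atleast_2d(np.asarray(self.pixel_centers, float))
        )
        if abs(self.row_pitch - self.pixel_width * COS30) > 1e-9 * self.row_pitch:
            raise GeometryError("row_pitch must equal pixel_width * cos(30 deg)")
        r = np.hypot(self.pixel_centers[:, 0], self.pixel_centers[:, 1])
        if np.any(r > self.array_diameter / 2 * (1 + 1e-9)):
            raise GeometryError("pixel centers must lie within the array disc")

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_centers)

    @property
    def radii(self) -> np.ndarray:
        """Radial position of each pixel center, um."""
        return np.hypot(self.pixel_centers[:, 0], self.pixel_centers[:, 1])

    def row_index(self) -> np.ndarray:
        """Integer row index of each pixel (0 at y = 0)."""
        return np.rint(self.pixel_centers[:, 1] / self.row_pitch).astype(int)

    def interior_mask(self, margin_rows: int = 2) -> np.ndarray:
        """Pixels at least ``margin_rows`` row pitches away from the rim."""
        return self.radii <= self.array_diameter / 2 - margin_rows * self.row_pitch

    def nearest_neighbor_pairs(self) -> np.ndarray:
        """(M, 2) indices of pixel pairs at nearest-neighbour distance."""
        d = np.linalg.norm(
            self.pixel_centers[:, None, :] - self.pixel_centers[None, :, :], axis=-1
        )
        i, j = np.where(
            (d > 0) & (np.abs(d - self.pixel_width) < 1e-6 * self.pixel_width)
        )
        keep = i < j
        return np.column_stack([i[keep], j[keep]])

    # -- serialization -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pixel": np.arange(self.n_pixels),
                "x_um": self.pixel_centers[:, 0],
                "y_um": self.pixel_centers[:, 1],
                "electrode_radius_um": self.electrode_radius,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        d = {
            "pixel_width_um": self.pixel_width,
            "row_pitch_um": self.row_pitch,
            "electrode_radius_um": self.electrode_radius,
            "array_diameter_um": self.array_diameter,
            "device_thickness_um": self.device_thickness,
            "pixel_centers_um": self.pixel_centers.tolist(),
        }
        if self.return_ring is not None:
            d["return_ring_um"] = {
                "inner_radius": self.return_ring.inner_radius,
                "outer_radius": self.return_ring.outer_radius,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayLayout":
        ring = d.get("return_ring_um")
        return cls(
            pixel_width=d["pixel_width_um"],
            row_pitch=d["row_pitch_um"],
            pixel_centers=np.asarray(d["pixel_centers_um"], float),
            electrode_radius=d["electrode_radius_um"],
            array_diameter=d["array_diameter_um"],
            return_ring=ReturnRing(**ring) if ring else None,
            device_thickness=d.get("device_thickness_um", 30.0),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ArrayLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_hex_array(
    pixel_width: float,
    array_diameter: float,
    electrode_diameter: float,
    *,
    return_ring: ReturnRing | Literal["default"] | None = "default",
    device_thickness: float = 30.0,
) -> ArrayLayout:
    """Build a hexagonal lattice of monopolar pixels clipped to a disc.

    All lengths in um.  Pixel ordering is deterministic: row-major from the
    bottom row upward, then by increasing x within each row.

    ``return_ring="default"`` places a 30 um-wide collecting annulus 10 um
    outside the pixel disc, emulating the common return deposited along the
    implant edge.
    """
    if min(pixel_width, array_diameter, electrode_diameter) <= 0:
        raise GeometryError("all lengths must be positive")
    if electrode_diameter >= pixel_width:
        raise GeometryError("electrode diameter must be smaller than the pixel width")
    row_pitch = pixel_width * COS30
    radius = array_diameter / 2
    jmax = int(math.floor(radius / row_pitch + 1))
    centers = []
    for j in range(-jmax, jmax + 1):
        y = j * row_pitch
        x0 = (abs(j) % 2) * pixel_width / 2  # odd rows shifted half a pixel
        imax = int(math.floor((radius + pixel_width) / pixel_width + 1))
        for i in range(-imax, imax + 1):
            x = i * pixel_width + x0
            if x * x + y * y <= radius * radius * (1 + 1e-12):
                centers.append((x, y))
    centers = np.array(sorted(centers, key=lambda c: (c[1], c[0])), float)
    if return_ring == "default":
        return_ring = ReturnRing(radius + 10.0, radius + 40.0)
    return ArrayLayout(
        pixel_width=pixel_width,
        row_pitch=row_pitch,
        pixel_centers=centers,
        electrode_radius=electrode_diameter / 2,
        array_diameter=array_diameter,
        return_ring=return_ring,
        device_thickness=device_thickness,
    )


@dataclass(frozen=True)
class SpatialPattern:
    """Optical pattern projected onto the array.

    ``kind`` selects among a uniform full field, a square-wave grating with
    bars parallel to the pixel rows (optionally rotated by ``orientation``),
    a centered regular-octagon field stop, and an arbitrary per-pixel mask.
    ``phase`` shifts the grating along its modulation axis (um); at zero
    phase with ``bar_width == row_pitch`` the bright bars coincide with the
    even pixel rows exactly.
    """

    kind: Literal["full_field", "grating", "field_stop_octagon", "custom_mask"]
    bar_width: float | None = None
    phase: float = 0.0
    orientation: float = 0.0  # radians; 0 = bars parallel to pixel rows
    stop_width: float | None = None
    mask_values: np.ndarray | None = None

    def mask(self, layout: ArrayLayout, frame: int = 0) -> np.ndarray:
        """Per-pixel illumination mask (0/1 or scalar weights) for a frame.

        For gratings, ``frame=1`` is the contrast-reversed pattern (bright
        and dark bars swapped).  Other kinds ignore ``frame``.
        """
        xy = layout.pixel_centers
        if self.kind == "full_field":
            return np.ones(layout.n_pixels)
        if self.kind == "grating":
            if not self.bar_width or self.bar_width <= 0:
                raise GeometryError("grating requires a positive bar_width")
            axis = xy[:, 1] * math.cos(self.orientation) - xy[:, 0] * math.sin(
                self.orientation
            )
            band = np.floor((axis - self.phase) / self.bar_width + 1e-9).astype(int)
            return ((band + frame) % 2 == 0).astype(float)
        if self.kind == "field_stop_octagon":
            if not self.stop_width or self.stop_width <= 0:
                raise GeometryError("field stop requires a positive stop_width")
            h = self.stop_width / 2  # apothem of the regular octagon
            ax, ay = np.abs(xy[:, 0]), np.abs(xy[:, 1])
            inside = (ax <= h) & (ay <= h) & ((ax + ay) / math.sqrt(2) <= h)
            return inside.astype(float)
        if self.kind == "custom_mask":
            m = np.asarray(self.mask_values, float)
            if m.shape != (layout.n_pixels,):
                raise GeometryError("custom mask length must match the pixel count")
            return m
        raise GeometryError(f"unknown pattern kind {self.kind!r}")


@dataclass(frozen=True)
class PixelDrive:
    """Per-pixel irradiance waveforms: pattern frames gated by a pulse train.

    Irradiance is in mW/mm^2, all times in ms.  Pulses are rectangular:
    within a pulse the irradiance is constant at ``peak_irradiance`` times
    the pattern mask of the current frame.
    """

    layout: ArrayLayout
    frame_masks: np.ndarray  # (n_frames, n_pixels)
    peak_irradiance: float
    pulse_width: float
    repetition_rate: float  # Hz
    duration: float
    reversal_period: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "frame_masks", np.atleast_2d(self.frame_masks))
        if self.peak_irradiance < 0 or np.any(self.frame_masks < 0):
            raise DomainError("irradiance must be nonnegative")
        if self.pulse_width <= 0 or self.repetition_rate <= 0 or self.duration <= 0:
            raise TimingError("pulse width, rate and duration must be positive")
        if self.pulse_width >= self.period:
            raise TimingError("pulse_width must be shorter than the pulse period")

    @property
    def period(self) -> float:
        """Carrier pulse period, ms."""
        return 1000.0 / self.repetition_rate

    @property
    def n_pixels(self) -> int:
        return self.frame_masks.shape[1]

    def frame_at(self, t_ms: float) -> int:
        if self.reversal_period is None or self.frame_masks.shape[0] == 1:
            return 0
        return int(t_ms / self.reversal_period + 1e-9) % self.frame_masks.shape[0]

    def irradiance_at(self, t_ms: float) -> np.ndarray:
        """Irradiance vector (mW/mm^2) at time ``t_ms``."""
        if t_ms < 0 or t_ms >= self.duration:
            return np.zeros(self.n_pixels)
        if (t_ms % self.period) >= self.pulse_width:
            return np.zeros(self.n_pixels)
        return self.peak_irradiance * self.frame_masks[self.frame_at(t_ms)]

    def breakpoints(self) -> np.ndarray:
        """Sorted times (ms) of every pulse edge and frame reversal."""
        times = {0.0, self.duration}
        k = 0
        while k * self.period < self.duration:
            on = k * self.period
            off = on + self.pulse_width
            times.add(on)
            if off < self.duration:
                times.add(off)
            k += 1
        if self.reversal_period is not None:
            m = 1
            while m * self.reversal_period < self.duration:
                times.add(m * self.reversal_period)
                m += 1
        return np.array(sorted(times))

    def scaled(self, factor: float) -> "PixelDrive":
        return replace(self, peak_irradiance=self.peak_irradiance * factor)


def project_pattern(
    layout: ArrayLayout,
    pattern: SpatialPattern,
    peak_irradiance: float,
    *,
    pulse_width: float,
    repetition_rate: float,
    duration: float,
    reversal_period: float | None = None,
) -> PixelDrive:
    """Convert an optical pattern plus pulse timing into per-pixel waveforms.

    ``peak_irradiance`` in mW/mm^2; ``pulse_width``, ``duration`` and
    ``reversal_period`` in ms; ``repetition_rate`` in Hz.  For gratings with a
    reversal period the complementary bars are illuminated in alternate
    frames; other patterns repeat a single frame.
    """
    if peak_irradiance < 0:
        raise DomainError("peak_irradiance must be nonnegative")
    if pulse_width >= 1000.0 / repetition_rate:
        raise TimingError("pulse_width must be shorter than the repetition period")
    if pattern.kind == "grating" and reversal_period is not None:
        masks = np.stack([pattern.mask(layout, 0), pattern.mask(layout, 1)])
    else:
        masks = pattern.mask(layout, 0)[None, :]
    return PixelDrive(
        layout=layout,
        frame_masks=masks,
        peak_irradiance=peak_irradiance,
        pulse_width=pulse_width,
        repetition_rate=repetition_rate,
        duration=duration,
        reversal_period=reversal_period,
    )
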