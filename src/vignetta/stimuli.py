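"""Stimulus synthesis: oriented carriers, annulus vignettes, polar modulators.

A stimulus is the product of an oriented sinusoidal *carrier* grating, a
static polar-transformed *modulator* grating (radial rings or angular
wedges), and a raised-cosine *annulus* aperture, presented on a mean-gray
background:

    luminance = mean_lum + 0.5 * carrier * modulator * annulus

Orientation convention (package-wide): 0 deg = horizontal stripes
(luminance varies vertically), counterclockwise-positive, mod 180 deg.
With phase 0 the carrier attains ``+contrast`` at fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "DisplayGeometry",
    "CarrierSpec",
    "AnnulusSpec",
    "ModulatorSpec",
    "StimulusImage",
    "make_carrier",
    "make_annulus",
    "make_modulator",
    "compose_stimulus",
    "conventional_3t_geometry",
    "high_field_7t_geometry",
    "simulation_geometry",
]


@dataclass(frozen=True)
class DisplayGeometry:
    """Pixel grid calibrated in degrees of visual angle.

    ``center`` is the fixation position in (row, col) pixel coordinates;
    defaults to the image center.
    """

    shape: tuple[int, int]
    deg_per_pixel: float
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.deg_per_pixel <= 0:
            raise ValueError("deg_per_pixel must be > 0")
        if self.center is None:
            object.__setattr__(
                self, "center",
                ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0),
            )
        r0, c0 = self.center
        if not (0 <= r0 < self.shape[0] and 0 <= c0 < self.shape[1]):
            raise ValueError("fixation center must lie inside the image")

    @property
    def nyquist_cpd(self) -> float:
        return 0.5 / self.deg_per_pixel

    def grid_deg(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) in degrees; x rightward, y upward, origin at fixation."""
        rows = np.arange(self.shape[0])[:, None].astype(float)
        cols = np.arange(self.shape[1])[None, :].astype(float)
        x = (cols - self.center[1]) * self.deg_per_pixel
        y = (self.center[0] - rows) * self.deg_per_pixel
        return np.broadcast_arrays(x, y)

    def eccentricity_deg(self) -> np.ndarray:
        x, y = self.grid_deg()
        return np.hypot(x, y)

    def polar_angle_rad(self) -> np.ndarray:
        x, y = self.grid_deg()
        return np.arctan2(y, x)


def conventional_3t_geometry(shape: tuple[int, int] = (768, 1024)) -> DisplayGeometry:
    """Conventional 3T display: 31.6 x 23.7 deg field at 768 x 1024 px."""
    return DisplayGeometry(shape=shape, deg_per_pixel=31.6 / shape[1])


def high_field_7t_geometry(shape: tuple[int, int] = (768, 1024)) -> DisplayGeometry:
    return DisplayGeometry(shape=shape, deg_per_pixel=31.6 / shape[1])


def simulation_geometry(size: int = 256, field_deg: float = 24.0) -> DisplayGeometry:
    """Square desk-scale grid covering ``field_deg`` degrees."""
    return DisplayGeometry(shape=(size, size), deg_per_pixel=field_deg / size)


@dataclass(frozen=True)
class CarrierSpec:
    orientation_deg: float = 90.0
    sf_cpd: float = 0.5
    phase_rad: float = 0.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        if self.sf_cpd <= 0:
            raise ValueError("sf_cpd must be > 0")


@dataclass(frozen=True)
class AnnulusSpec:
    inner_deg: float = 5.0
    outer_deg: float = 9.0
    transition_deg: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.inner_deg < self.outer_deg:
            raise ValueError("require 0 <= inner_deg < outer_deg")
        if self.transition_deg < 0:
            raise ValueError("transition_deg must be >= 0")


@dataclass(frozen=True)
class ModulatorSpec:
    """Polar-transformed grating multiplied with the carrier.

    ``frequency`` is cycles/degree along eccentricity for a linear radial
    modulator, cycles/octave of eccentricity when ``log_scaled`` (rings
    scaled with eccentricity), or integer cycles/revolution for an angular
    modulator.
    """

    axis: Literal["radial", "angular"] = "radial"
    waveform: Literal["square", "sine"] = "sine"
    phase: Literal["sine", "cosine"] = "cosine"
    frequency: float = 0.5
    log_scaled: bool = False

    def __post_init__(self) -> None:
        if self.axis not in ("radial", "angular"):
            raise ValueError(f"unknown modulator axis {self.axis!r}")
        if self.frequency <= 0:
            raise ValueError("modulator frequency must be > 0")
        if self.axis == "angular" and self.frequency != int(self.frequency):
            raise ValueError(
                "angular modulator frequency must be an integer number of "
                "cycles per revolution (wrap continuity)"
            )


@dataclass
class StimulusImage:
    """Luminance image in [0, 1] display units on a calibrated grid."""

    luminance: np.ndarray
    geometry: DisplayGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lum = np.asarray(self.luminance, dtype=float)
        if lum.shape != self.geometry.shape:
            raise ValueError("luminance shape does not match geometry")
        if lum.min() < -1e-12 or lum.max() > 1 + 1e-12:
            raise ValueError("luminance must lie within [0, 1]")
        self.luminance = lum


def make_carrier(geom: DisplayGeometry, spec: CarrierSpec) -> np.ndarray:
    """Signed contrast map of the oriented sinusoidal carrier."""
    if spec.sf_cpd >= geom.nyquist_cpd:
        raise ValueError(
            f"carrier spatial frequency {spec.sf_cpd} cpd is at or above the "
            f"display Nyquist frequency {geom.nyquist_cpd:.3f} cpd"
        )
    x, y = geom.grid_deg()
    th = np.deg2rad(spec.orientation_deg)
    # coordinate along the normal to the stripes
    u = -x * np.sin(th) + y * np.cos(th)
    return spec.contrast * np.cos(2 * np.pi * spec.sf_cpd * u + spec.phase_rad)


def make_annulus(geom: DisplayGeometry, spec: AnnulusSpec) -> np.ndarray:
    """Annulus aperture with raised-cosine transitions centered on the edges.

    The mask equals 0.5 exactly at ``inner_deg`` and ``outer_deg``, 1 on the
    plateau between the transition zones, and 0 outside them.
    """
    r = geom.eccentricity_deg()
    t = spec.transition_deg
    if t == 0:
        mask = ((r >= spec.inner_deg) & (r <= spec.outer_deg)).astype(float)
        return mask
    half = t / 2.0

    def ramp_up(rr: np.ndarray, edge: float) -> np.ndarray:
        u = np.clip((rr - (edge - half)) / t, 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(np.pi * u))

    mask = ramp_up(r, spec.inner_deg) * (1.0 - ramp_up(r, spec.outer_deg))
    if spec.inner_deg == 0:
        mask = 1.0 - ramp_up(r, spec.outer_deg)
    return mask


def make_modulator(geom: DisplayGeometry, spec: ModulatorSpec) -> np.ndarray:
    """Signed modulator map in [-1, 1].

    Radial modulators depend on eccentricity only (rings); angular
    modulators depend on polar angle only (inward-pointing wedges).
    ``phase='sine'`` vs ``'cosine'`` differ by a quarter-period shift along
    the modulation axis.
    """
    if spec.axis == "radial":
        r = geom.eccentricity_deg()
        if spec.log_scaled:
            # rings scaled with eccentricity: periodic in log2(r)
            with np.errstate(divide="ignore"):
                arg = 2 * np.pi * spec.frequency * np.log2(np.maximum(r, 1e-9))
        else:
            arg = 2 * np.pi * spec.frequency * r
    else:
        theta = geom.polar_angle_rad()
        arg = spec.frequency * theta
    profile = np.sin(arg) if spec.phase == "sine" else np.cos(arg)
    if spec.waveform == "square":
        out = np.sign(profile)
        out[out == 0] = 1.0
        return out
    return profile


def compose_stimulus(
    carrier: np.ndarray,
    modulator: np.ndarray,
    annulus: np.ndarray,
    geom: DisplayGeometry,
    mean_lum: float = 0.5,
    meta: dict | None = None,
) -> StimulusImage:
    """``mean_lum + 0.5 * carrier * modulator * annulus`` as a StimulusImage."""
    if not carrier.shape == modulator.shape == annulus.shape == geom.shape:
        raise ValueError("carrier, modulator and annulus must share the geometry")
    lum = mean_lum + 0.5 * carrier * modulator * annulus
    if lum.min() < -1e-12 or lum.max() > 1 + 1e-12:
        raise ValueError(
            "composed luminance leaves [0, 1]; check carrier contrast and mean_lum"
        )
    return StimulusImage(luminance=np.clip(lum, 0.0, 1.0), geometry=geom,
                         meta=meta or {})
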