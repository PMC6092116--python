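"""Simulated voxel maps, orientation-bias maps and pRF tuning predictions.

The simulated fMRI response at each retinotopic location is the energy model
output summed across *all* orientation channels at the scale that responds
maximally to the stimulus family, averaged across carrier phases. Summing
across orientation channels removes any explicit orientation tuning, so any
orientation dependence that remains in the maps is produced by the vignette.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pyramid import FilterBank, build_filter_bank, PyramidConfig
from .stimuli import (
    AnnulusSpec,
    CarrierSpec,
    DisplayGeometry,
    ModulatorSpec,
    compose_stimulus,
    make_annulus,
    make_carrier,
    make_modulator,
)

__all__ = [
    "VoxelMap",
    "BiasMap",
    "PRF",
    "TuningPrediction",
    "simulate_voxel_map",
    "select_scale",
    "orientation_bias_map",
    "prf_weights",
    "predict_prf_tuning",
    "fit_orientation_cosine",
    "simulate_orientation_maps",
    "ORIENTATIONS_16",
    "CARRIER_PHASES_16",
]

ORIENTATIONS_16 = np.arange(16) * 11.25  # deg, the phase-encoded sequence
CARRIER_PHASES_16 = np.arange(16) / 16.0 * 2 * np.pi


@dataclass
class VoxelMap:
    """Simulated population response per retinotopic location, one condition."""

    response: np.ndarray  # (H, W), >= 0
    scale: int  # pyramid scale the map was read from
    geometry: DisplayGeometry


@dataclass
class BiasMap:
    """response(vertical carrier) - response(horizontal carrier)."""

    bias: np.ndarray
    geometry: DisplayGeometry


@dataclass(frozen=True)
class PRF:
    """Isotropic 2D Gaussian population receptive field (degrees)."""

    x0: float
    y0: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("pRF sigma must be > 0")


@dataclass
class TuningPrediction:
    responses: np.ndarray  # (16,), >= 0
    preferred_deg: float  # [0, 180); NaN when undefined
    amplitude: float  # >= 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.preferred_deg)


def _phase_energy(stimulus: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Per-scale energy totals (summed over pixels and orientations) of one
    image, computed in the frequency domain (Parseval)."""
    spectrum_power = np.abs(np.fft.fft2(stimulus)) ** 2
    n = stimulus.size
    return np.array(
        [(spectrum_power * bank.radial[s] ** 2).sum() / n for s in range(bank.n_scales)]
    )


def select_scale(stimuli: Sequence[np.ndarray], bank: FilterBank) -> int:
    """Scale with maximal total energy (pixels + orientations), averaged
    over the supplied stimulus images."""
    if len(stimuli) == 0:
        raise ValueError("empty stimulus set")
    totals = np.zeros(bank.n_scales)
    for stim in stimuli:
        totals += _phase_energy(np.asarray(stim, dtype=float), bank)
    return int(np.argmax(totals))


def _orientation_summed_energy(
    stimulus: np.ndarray, bank: FilterBank, scale: int
) -> np.ndarray:
    spectrum = np.fft.fft2(stimulus)
    out = np.zeros(stimulus.shape)
    for k in range(bank.n_orientations):
        z = np.fft.ifft2(spectrum * bank.analytic_transfer(scale, k))
        out += z.real**2 + z.imag**2
    return out


def simulate_voxel_map(
    stimuli: Sequence[np.ndarray],
    bank: FilterBank,
    geometry: DisplayGeometry,
    scale: int | None = None,
) -> VoxelMap:
    """Phase-averaged, orientation-summed energy map of one condition.

    ``stimuli`` are renditions of the same condition at different carrier
    phases (luminance or signed-contrast images; the DC level falls into the
    low-pass residual and does not affect band energies). If ``scale`` is
    None it is chosen by :func:`select_scale` from these stimuli; pass an
    explicit scale to keep selection global across a stimulus family.
    """
    if len(stimuli) == 0:
        raise ValueError("empty stimulus set")
    if scale is None:
        scale = select_scale(stimuli, bank)
    acc = np.zeros(geometry.shape)
    for stim in stimuli:
        acc += _orientation_summed_energy(np.asarray(stim, dtype=float), bank, scale)
    return VoxelMap(response=acc / len(stimuli), scale=scale, geometry=geometry)


def orientation_bias_map(map_v: VoxelMap, map_h: VoxelMap) -> BiasMap:
    """Vertical-minus-horizontal response difference, pixelwise."""
    if map_v.response.shape != map_h.response.shape:
        raise ValueError("voxel maps must share geometry")
    return BiasMap(bias=map_v.response - map_h.response, geometry=map_v.geometry)


def prf_weights(geom: DisplayGeometry, prf: PRF, truncate_sigma: float = 4.0) -> np.ndarray:
    """Gaussian pRF weight map, truncated at ``truncate_sigma`` and
    normalized to unit mass on the grid.

    Raises
    ------
    ValueError
        If essentially no pRF mass falls inside the field of view.
    """
    x, y = geom.grid_deg()
    d2 = (x - prf.x0) ** 2 + (y - prf.y0) ** 2
    w = np.exp(-d2 / (2.0 * prf.sigma**2))
    w[d2 > (truncate_sigma * prf.sigma) ** 2] = 0.0
    mass = w.sum()
    # unit-mass mass of a fully visible pRF, for the coverage check
    full = 2 * np.pi * (prf.sigma / geom.deg_per_pixel) ** 2
    if mass < 1e-3 * full:
        raise ValueError("pRF has (almost) no mass inside the field of view")
    return w / mass


def fit_orientation_cosine(
    responses: np.ndarray, orientations_deg: np.ndarray | None = None
) -> tuple[float, float]:
    """Best-fit single-cycle cosine over evenly spaced orientation samples.

    Returns ``(preferred_deg, amplitude)`` where the fit is
    ``mean + amplitude * cos(2*pi*(ori - preferred)/180)``. For complete,
    evenly spaced samples this equals the least-squares fit and is computed
    as the fundamental discrete Fourier component. ``preferred_deg`` is NaN
    when the amplitude is (numerically) zero.
    """
    r = np.asarray(responses, dtype=float)
    n = r.size
    if orientations_deg is not None:
        orientations_deg = np.asarray(orientations_deg, dtype=float)
        step = 180.0 / n
        if not np.allclose(np.diff(orientations_deg), step):
            raise ValueError("orientations must be evenly spaced over [0, 180)")
    c = np.sum(r * np.exp(-2j * np.pi * np.arange(n) / n))
    amplitude = 2.0 * np.abs(c) / n
    scale = max(np.max(np.abs(r)), 1.0)
    if amplitude <= 1e-12 * scale:
        return float("nan"), 0.0
    phase = np.angle(c)  # r_i ~ cos(2*pi*i/n - (-phase)) => peak index at -phase
    i_peak = -phase / (2 * np.pi) * n
    preferred = (i_peak * 180.0 / n) % 180.0
    if orientations_deg is not None:
        preferred = (orientations_deg[0] + i_peak * 180.0 / n) % 180.0
    if preferred >= 180.0 - 1e-9:  # float wrap: (x % 180) can return 180.0
        preferred = 0.0
    return float(preferred), float(amplitude)


def predict_prf_tuning(
    maps: Sequence[VoxelMap] | np.ndarray,
    prf: PRF,
    geometry: DisplayGeometry | None = None,
) -> TuningPrediction:
    """Sample 16 orientation maps with a Gaussian pRF and fit a cosine.

    ``maps`` is a sequence of 16 :class:`VoxelMap` (one per carrier
    orientation, in sequence order) or an array (16, H, W) with
    ``geometry`` supplied.
    """
    if isinstance(maps, np.ndarray):
        if geometry is None:
            raise ValueError("geometry required with raw arrays")
        arrs = maps
        geom = geometry
    else:
        if len(maps) != 16:
            raise ValueError("expected 16 orientation maps")
        geom = maps[0].geometry
        arrs = np.stack([m.response for m in maps])
    if arrs.shape[0] != 16:
        raise ValueError("expected 16 orientation maps")
    w = prf_weights(geom, prf)
    responses = np.tensordot(arrs, w, axes=([1, 2], [0, 1]))
    preferred, amplitude = fit_orientation_cosine(responses, ORIENTATIONS_16)
    return TuningPrediction(responses=responses, preferred_deg=preferred,
                            amplitude=amplitude)


def simulate_orientation_maps(
    geometry: DisplayGeometry,
    modulator: ModulatorSpec | None,
    annulus: AnnulusSpec,
    carrier: CarrierSpec | None = None,
    bank: FilterBank | None = None,
    orientations_deg: np.ndarray = ORIENTATIONS_16,
    carrier_phases: np.ndarray = CARRIER_PHASES_16,
    n_orientations_bank: int = 6,
    bandwidth: float = 0.5,
) -> tuple[np.ndarray, int]:
    """Simulated voxel maps for a family of carrier orientations.

    Renders ``carrier x modulator x annulus`` at every orientation and
    carrier phase, runs the energy model, and returns
    ``(maps, scale)`` where ``maps`` has shape (n_orientations, H, W).
    Scale selection is global across the whole family.
    """
    if bank is None:
        bank = build_filter_bank(
            PyramidConfig(
                image_shape=geometry.shape,
                n_orientations=n_orientations_bank,
                sf_bandwidth_octaves=bandwidth,
            )
        )
    base_carrier = carrier or CarrierSpec()
    mod = (
        np.ones(geometry.shape)
        if modulator is None
        else make_modulator(geometry, modulator)
    )
    ann = make_annulus(geometry, annulus)
    envelope = mod * ann

    def render(ori: float, ph: float) -> np.ndarray:
        car = make_carrier(
            geometry,
            CarrierSpec(
                orientation_deg=ori,
                sf_cpd=base_carrier.sf_cpd,
                phase_rad=ph,
                contrast=base_carrier.contrast,
            ),
        )
        return compose_stimulus(car, envelope, np.ones(geometry.shape), geometry).luminance

    # pass 1: global scale selection over the full family
    totals = np.zeros(bank.n_scales)
    for ori in orientations_deg:
        for ph in carrier_phases:
            totals += _phase_energy(render(ori, ph), bank)
    scale = int(np.argmax(totals))

    # pass 2: orientation-summed energy maps at the selected scale
    maps = np.zeros((len(orientations_deg),) + geometry.shape)
    for i, ori in enumerate(orientations_deg):
        for ph in carrier_phases:
            maps[i] += _orientation_summed_energy(render(ori, ph), bank, scale)
        maps[i] /= len(carrier_phases)
    return maps, scale
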