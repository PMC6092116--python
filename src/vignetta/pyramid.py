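"""Frequency-domain steerable-pyramid filter bank with quadrature pairs.

The bank decomposes an image into orientation x spatial-frequency channels.
Each channel holds an odd/even quadrature pair (analogous to odd- and
even-phase Gabor filters); the sum of their squared outputs is the channel's
*energy* response, a phase-invariant measure of local oriented spectral power.

Construction is done entirely on the 2D DFT grid (periodic boundaries):

* radial profiles are raised cosines in log2 spatial frequency, spaced
  ``sf_bandwidth_octaves`` apart, so adjacent squared profiles sum to one;
* angular profiles are the standard cos^(K-1) windows for K orientation
  bands, normalized so their squares tile orientation exactly;
* a high-pass and a low-pass residual absorb the spectrum outside the band
  peaks, making the squared amplitudes of all filters sum to exactly one at
  every frequency sample (checked by :func:`tiling_error`).

Orientation convention: 0 deg denotes horizontal stripes (luminance varies
vertically), angles grow counterclockwise, and all orientations are taken
mod 180 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "PyramidConfig",
    "FilterBank",
    "Coefficients",
    "ChannelEnergy",
    "plan_scales",
    "build_filter_bank",
    "tiling_error",
    "decompose",
    "channel_energy",
    "energy_maps",
]

MIN_IMAGE_DIM = 32


def plan_scales(image_shape: tuple[int, int], bandwidth: float) -> int:
    """Number of spatial-frequency channels for an image of ``image_shape``.

    Scales are spaced ``bandwidth`` octaves apart from just below Nyquist
    down to a fixed floor, giving

        n = floor((floor(log2(min(rows, cols))) - 2) / bandwidth) + 1

    For a 768 x 1024 image at 0.5 octaves this yields 15 channels.

    Raises
    ------
    ValueError
        If ``min(image_shape) < 32`` (too few pixels to place even one
        band between the Nyquist frequency and the low-frequency floor).
    """
    rows, cols = image_shape
    m = min(rows, cols)
    if m < MIN_IMAGE_DIM:
        raise ValueError(
            f"image too small: min dimension {m} < required minimum {MIN_IMAGE_DIM}"
        )
    if not 0 < bandwidth <= 1:
        raise ValueError(f"bandwidth must be in (0, 1] octaves, got {bandwidth}")
    n = int(math.floor((math.floor(math.log2(m)) - 2) / bandwidth)) + 1
    return max(n, 1)


@dataclass(frozen=True)
class PyramidConfig:
    """Parameters of the pyramid.

    ``n_scales`` is derived from the image shape and bandwidth via
    :func:`plan_scales` and must not be supplied.
    """

    image_shape: tuple[int, int]
    n_orientations: int = 6
    sf_bandwidth_octaves: float = 0.5

    def __post_init__(self) -> None:
        if self.n_orientations < 2:
            raise ValueError("n_orientations must be >= 2")
        if not 0 < self.sf_bandwidth_octaves <= 1:
            raise ValueError("sf_bandwidth_octaves must be in (0, 1]")
        plan_scales(self.image_shape, self.sf_bandwidth_octaves)  # validates shape

    @property
    def n_scales(self) -> int:
        return plan_scales(self.image_shape, self.sf_bandwidth_octaves)


def _frequency_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Radius (cycles/pixel) and spectral angle on the DFT grid.

    The spectral angle is measured with y pointing up (negative row
    direction) so that image-domain orientations follow the package-wide
    counterclockwise convention.
    """
    fr = np.fft.fftfreq(shape[0])[:, None]
    fc = np.fft.fftfreq(shape[1])[None, :]
    radius = np.hypot(fr, fc)
    angle = np.arctan2(-fr, fc)
    return radius, angle


@dataclass
class FilterBank:
    """Factored transfer-function amplitudes of the pyramid.

    Per-member amplitude of the (scale s, orientation k) quadrature pair is
    ``radial[s] * angular[k] / sqrt(2)``; odd and even members share this
    amplitude and differ by a 90 deg phase shift (the odd member's transfer
    is ``-i * sign * amplitude``). Squared amplitudes of all members plus
    the two residuals sum to one everywhere on the frequency grid.
    """

    config: PyramidConfig
    radial: np.ndarray  # (n_scales, H, W) raised-cosine log-frequency windows
    angular: np.ndarray  # (n_orientations, H, W) cos^(K-1) windows, >= 0
    sign: np.ndarray  # (n_orientations, H, W) half-plane sign in {-1, +1}
    residual_high: np.ndarray  # (H, W)
    residual_low: np.ndarray  # (H, W)
    peak_frequency: np.ndarray  # (n_scales,) cycles/pixel
    _zeroed: set = field(default_factory=set, repr=False)

    @property
    def n_scales(self) -> int:
        return self.radial.shape[0]

    @property
    def n_orientations(self) -> int:
        return self.angular.shape[0]

    @property
    def orientations_deg(self) -> np.ndarray:
        k = self.n_orientations
        return np.arange(k) * (180.0 / k)

    def amplitude(self, scale: int, orientation: int) -> np.ndarray:
        """Shared amplitude of the (scale, orientation) quadrature pair."""
        if (scale, orientation) in self._zeroed:
            return np.zeros(self.config.image_shape)
        return self.radial[scale] * self.angular[orientation] / math.sqrt(2.0)

    def analytic_transfer(self, scale: int, orientation: int) -> np.ndarray:
        """Complex transfer whose ifft2 yields even + i*odd coefficients."""
        amp = self.amplitude(scale, orientation)
        return amp * (1.0 + self.sign[orientation])

    def zero_channel(self, scale: int, orientation: int) -> "FilterBank":
        """Copy of the bank with one quadrature pair's amplitude removed."""
        out = FilterBank(
            config=self.config,
            radial=self.radial,
            angular=self.angular,
            sign=self.sign,
            residual_high=self.residual_high,
            residual_low=self.residual_low,
            peak_frequency=self.peak_frequency,
        )
        out._zeroed = set(self._zeroed) | {(scale, orientation)}
        return out

    def iter_squared_amplitudes(self) -> Iterator[np.ndarray]:
        """Squared amplitudes of every filter: both quadrature members of
        every (scale, orientation) pair, then the two residuals."""
        for s in range(self.n_scales):
            for k in range(self.n_orientations):
                a2 = self.amplitude(s, k) ** 2
                yield a2
                yield a2
        yield self.residual_high**2
        yield self.residual_low**2


def build_filter_bank(config: PyramidConfig) -> FilterBank:
    shape = config.image_shape
    b = config.sf_bandwidth_octaves
    n_scales = config.n_scales
    n_orient = config.n_orientations

    radius, angle = _frequency_grid(shape)
    with np.errstate(divide="ignore"):
        logr = np.log2(radius)  # -inf at DC, handled below

    peak_log = math.log2(0.5) - b * np.arange(n_scales)
    radial = np.zeros((n_scales,) + shape)
    for s in range(n_scales):
        u = (logr - peak_log[s]) / b
        inside = np.abs(u) < 1.0
        radial[s][inside] = np.cos(0.5 * np.pi * u[inside])

    # The DFT stores +/-Nyquist as a single sample, so the angular sign map
    # cannot be made odd-symmetric on the Nyquist lines; hand those samples
    # to the (symmetric) high-pass residual to keep the transform exactly
    # power-conserving.
    nyq = np.zeros(shape, dtype=bool)
    if shape[0] % 2 == 0:
        nyq[shape[0] // 2, :] = True
    if shape[1] % 2 == 0:
        nyq[:, shape[1] // 2] = True
    radial[:, nyq] = 0.0

    # Residuals absorb 1 - sum(radial^2) above the top peak / below the
    # bottom peak; in between the raised cosines tile exactly.
    total = np.sum(radial**2, axis=0)
    slack = np.sqrt(np.clip(1.0 - total, 0.0, None))
    residual_high = np.where((logr >= peak_log[0]) | nyq, slack, 0.0)
    residual_low = np.where((logr <= peak_log[-1]) & ~nyq, slack, 0.0)
    residual_low[radius == 0] = 1.0

    # cos^(K-1) angular windows; alpha normalizes sum of squares to one.
    k_ = n_orient
    alpha = (
        2.0 ** (k_ - 1)
        * math.factorial(k_ - 1)
        / math.sqrt(k_ * math.factorial(2 * (k_ - 1)))
    )
    angular = np.empty((k_,) + shape)
    sign = np.empty((k_,) + shape)
    for k in range(k_):
        # stimulus orientation k*180/K deg -> spectral energy 90 deg away
        theta_k = np.deg2rad(k * 180.0 / k_ + 90.0)
        c = np.cos(angle - theta_k)
        angular[k] = alpha * np.abs(c) ** (k_ - 1)
        sign[k] = np.where(c >= 0, 1.0, -1.0)

    return FilterBank(
        config=config,
        radial=radial,
        angular=angular,
        sign=sign,
        residual_high=residual_high,
        residual_low=residual_low,
        peak_frequency=2.0**peak_log,
    )


def tiling_error(bank: FilterBank | Iterable[np.ndarray]) -> float:
    """Max over frequency samples of |sum of squared amplitudes - 1|.

    Accepts a :class:`FilterBank` (both quadrature members and the residuals
    are counted) or any iterable of amplitude maps.
    """
    if isinstance(bank, FilterBank):
        maps = bank.iter_squared_amplitudes()
        total = None
        for a2 in maps:
            total = a2 if total is None else total + a2
    else:
        total = None
        for a in bank:
            a2 = np.asarray(a, dtype=float) ** 2
            total = a2 if total is None else total + a2
    if total is None:
        raise ValueError("empty filter bank")
    return float(np.max(np.abs(total - 1.0)))


@dataclass
class Coefficients:
    """Full-resolution linear coefficient maps of one image.

    ``even``/``odd`` have shape (n_scales, n_orientations, H, W); the
    residual maps have shape (H, W).
    """

    even: np.ndarray
    odd: np.ndarray
    residual_high: np.ndarray
    residual_low: np.ndarray


@dataclass
class ChannelEnergy:
    """Per-(scale, orientation) energy maps, units (contrast units)^2."""

    energy: np.ndarray  # (n_scales, n_orientations, H, W), >= 0


def decompose(image: np.ndarray, bank: FilterBank) -> Coefficients:
    """Linear subband decomposition of ``image``.

    Raises
    ------
    ValueError
        If the image shape does not match the bank's frequency grid.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != bank.config.image_shape:
        raise ValueError(
            f"image shape {image.shape} does not match bank grid "
            f"{bank.config.image_shape}"
        )
    spectrum = np.fft.fft2(image)
    s_n, k_n = bank.n_scales, bank.n_orientations
    even = np.empty((s_n, k_n) + image.shape)
    odd = np.empty_like(even)
    for s in range(s_n):
        for k in range(k_n):
            z = np.fft.ifft2(spectrum * bank.analytic_transfer(s, k))
            even[s, k] = z.real
            odd[s, k] = z.imag
    residual_high = np.fft.ifft2(spectrum * bank.residual_high).real
    residual_low = np.fft.ifft2(spectrum * bank.residual_low).real
    return Coefficients(even=even, odd=odd, residual_high=residual_high,
                        residual_low=residual_low)


def channel_energy(coefficients: Coefficients) -> ChannelEnergy:
    """Sum of squares of the quadrature pair, pixelwise."""
    if coefficients.even is None or coefficients.odd is None:
        raise ValueError("both quadrature phase members are required")
    if coefficients.even.shape != coefficients.odd.shape:
        raise ValueError("even/odd coefficient shapes differ")
    return ChannelEnergy(energy=coefficients.even**2 + coefficients.odd**2)


def energy_maps(image: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Convenience: (n_scales, n_orientations, H, W) energy of ``image``."""
    return channel_energy(decompose(image, bank)).energy
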