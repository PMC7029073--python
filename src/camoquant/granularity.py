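"""Granularity (energy-spectrum) pattern analysis.

A region of a calibrated image is decomposed into spatial-frequency bands
with an ideal isotropic Fourier band-pass filter bank.  The "energy" of a
band is the standard deviation of the band-filtered pixel reflectance over
the region — a measure of how much pattern contrast lives at that spatial
scale.  Plotting energy against filter size gives the region's energy
spectrum, from which three descriptors are taken:

``e_max``
    the spectrum maximum — contrast of the dominant marking;
``filter_max``
    the filter size (px) at which the maximum occurs — dominant marking
    size (ties broken toward the smallest size);
``e_prop``
    ``e_max`` as a proportion of the summed spectrum — the inverse of
    pattern diversity (1 means a single-scale pattern).

The default bank spans 15 filter sizes from 2 to 256 px in steps of sqrt(2),
and the analysed channel is the pixelwise mean of the red and green planes.

Band-edge convention: bands meet at the geometric midpoints between
neighbouring filter sizes (half a sqrt(2) step), so each band passes spatial
periods in ``[s/g, s*g)`` with ``g = sqrt(factor)``.  The smallest-size band
additionally keeps everything above its lower period edge out to the grid's
corner frequencies, and the largest-size band extends to period
``max_size*g``; the bank therefore partitions all non-DC frequencies
exactly, which makes Parseval-style checks assertable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import MultispectralStack, RegionMask

SQRT2 = math.sqrt(2.0)


class SpectrumError(ValueError):
    """Degenerate region or spectrum (e.g. constant region: all-zero energies)."""


@dataclass(frozen=True)
class FilterBank:
    """Geometric ladder of band-pass filter sizes in pixels."""

    sizes: tuple[float, ...]
    factor: float

    def __len__(self) -> int:
        return len(self.sizes)


@dataclass(frozen=True)
class EnergySpectrum:
    """Per-band energies (SD of band-filtered reflectance) for one region."""

    sizes: tuple[float, ...]
    energies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.energies):
            raise ValueError("sizes and energies must have equal length")
        if any(e < 0 for e in self.energies):
            raise ValueError("energies must be non-negative")


@dataclass(frozen=True)
class PatternDescriptors:
    """Summary descriptors of an energy spectrum (raw and log10 scales)."""

    e_max: float
    filter_max: float
    e_prop: float
    log10_e_max: float
    log10_filter_max: float
    log10_e_prop: float


def build_filter_bank(
    min_size: float = 2.0, max_size: float = 256.0, factor: float = SQRT2
) -> FilterBank:
    """Build the geometric filter-size ladder ``min_size * factor**k <= max_size``.

    The default (2, 256, sqrt(2)) gives the conventional 15-size bank.
    """
    if not (min_size > 0 and max_size > 0):
        raise ValueError("filter sizes must be positive")
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    if not factor > 1.0:
        raise ValueError("factor must be > 1")
    sizes = []
    s = float(min_size)
    while s <= max_size * (1.0 + 1e-9):
        sizes.append(s)
        s *= factor
    return FilterBank(sizes=tuple(sizes), factor=float(factor))


def pattern_channel(stack: MultispectralStack) -> np.ndarray:
    """Pixelwise mean of the red and green reflectance planes."""
    return (stack.reflectance[:, :, 0] + stack.reflectance[:, :, 1]) / 2.0


# Cache of boolean frequency-band selectors, keyed by (shape, bank).
_BAND_CACHE: dict[tuple, np.ndarray] = {}


def _band_selectors(shape: tuple[int, int], bank: FilterBank) -> np.ndarray:
    key = (shape, bank.sizes, bank.factor)
    sel = _BAND_CACHE.get(key)
    if sel is None:
        fy = np.fft.fftfreq(shape[0])[:, None]
        fx = np.fft.fftfreq(shape[1])[None, :]
        fmag = np.hypot(fy, fx)
        g = math.sqrt(bank.factor)
        sel = np.empty((len(bank.sizes), *shape), dtype=bool)
        for i, s in enumerate(bank.sizes):
            f_lo = 1.0 / (s * g)  # from period s*g (exclusive)
            # smallest size: keep everything up to the corner frequencies
            f_hi = np.inf if i == 0 else g / s  # to period s/g (inclusive)
            sel[i] = (fmag > f_lo) & (fmag <= f_hi)
        if len(_BAND_CACHE) > 16:
            _BAND_CACHE.clear()
        _BAND_CACHE[key] = sel
    return sel


def bandpass_energy(
    channel: np.ndarray, mask: RegionMask | np.ndarray, bank: FilterBank
) -> EnergySpectrum:
    """Band-pass energy spectrum of ``channel`` restricted to ``mask``.

    Pixels outside the mask are filled with the masked mean before the FFT
    (mean-fill suppresses boundary artifacts better than zero-fill); each
    band applies an ideal isotropic annular filter in the Fourier domain and
    the energy is the population SD of the filtered values over masked
    pixels only.
    """
    m = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask, dtype=bool)
    channel = np.asarray(channel, dtype=np.float64)
    if m.shape != channel.shape:
        raise ValueError("mask and channel shapes differ")
    if not m.any():
        raise SpectrumError("empty region mask")
    rows, cols = np.nonzero(m)
    if np.ptp(rows) < 1 or np.ptp(cols) < 1:
        raise SpectrumError("region bounding box smaller than 2x2 pixels")

    filled = np.where(m, channel, channel[m].mean())
    F = np.fft.fft2(filled)
    selectors = _band_selectors(channel.shape, bank)
    energies = []
    for sel in selectors:
        band = np.fft.ifft2(F * sel).real
        energies.append(float(band[m].std()))
    return EnergySpectrum(sizes=bank.sizes, energies=tuple(energies))


def descriptors(spectrum: EnergySpectrum) -> PatternDescriptors:
    """Summarise an energy spectrum into (e_max, filter_max, e_prop).

    Ties in the maximum go to the smallest filter size (``np.argmax`` takes
    the first index of an ascending size ladder).  A constant region (all
    energies zero) has no defined descriptors and raises
    :class:`SpectrumError`.
    """
    energies = np.asarray(spectrum.energies, dtype=np.float64)
    if not np.any(energies > 0):
        raise SpectrumError("all-zero energy spectrum: descriptors undefined")
    idx = int(np.argmax(energies))
    e_max = float(energies[idx])
    filter_max = float(spectrum.sizes[idx])
    e_prop = e_max / float(energies.sum())
    return PatternDescriptors(
        e_max=e_max,
        filter_max=filter_max,
        e_prop=e_prop,
        log10_e_max=math.log10(e_max),
        log10_filter_max=math.log10(filter_max),
        log10_e_prop=math.log10(e_prop),
    )
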