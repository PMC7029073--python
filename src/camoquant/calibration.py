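"""Reflectance calibration and scene I/O.

Field photographs of animals are taken together with gray reflectance
standards (e.g. the grayscale patches of an X-rite ColorChecker card) lying
in the same plane as the subject.  Because the standards have known diffuse
reflectance, a per-channel affine map from linear sensor values to
standardized reflectance can be fitted for every photograph, removing
differences in illumination between shots.  Calibrated images are kept on
the conventional 16-bit scale, so reflectance values run from 0 to 65,535
and a perfect white standard maps to the scale maximum.

This module provides the in-memory containers for raw and calibrated
imagery, the gray-standard calibration fit, spatial resampling to a common
working resolution (pixels per mm), and plain-text/PNG/TIFF scene I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import rescale as _sk_rescale

#: Top of the 16-bit reflectance scale used for calibrated imagery.
SCALE_MAX = 65535.0

CHANNELS = ("R", "G", "B")
ROLES = ("target", "background")


class CalibrationError(ValueError):
    """Degenerate gray-standard data: calibration line cannot be fitted."""


class SceneFormatError(ValueError):
    """A scene file on disk is malformed or inconsistent."""


@dataclass
class RawImage:
    """Linear (demosaiced, un-calibrated) RGB sensor values.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3)
        Linear sensor values per channel (R, G, B order).
    bit_depth : int
        8 or 16; pixel values must lie in ``[0, 2**bit_depth - 1]``.
    pixels_per_mm : float
        Spatial sampling of the photograph.
    """

    pixels: np.ndarray
    bit_depth: int
    pixels_per_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (H, W, 3)")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.pixels_per_mm > 0:
            raise ValueError("pixels_per_mm must be positive")
        top = 2.0**self.bit_depth - 1.0
        if self.pixels.min() < 0 or self.pixels.max() > top:
            raise ValueError(f"pixel values outside [0, {top:.0f}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class MultispectralStack:
    """Calibrated reflectance planes (R, G, B) on the 16-bit scale."""

    reflectance: np.ndarray  # (H, W, 3), values in [0, SCALE_MAX]
    pixels_per_mm: float

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        if self.reflectance.ndim != 3 or self.reflectance.shape[2] != 3:
            raise ValueError("reflectance must have shape (H, W, 3)")
        if not self.pixels_per_mm > 0:
            raise ValueError("pixels_per_mm must be positive")
        if self.reflectance.min() < 0 or self.reflectance.max() > SCALE_MAX:
            raise ValueError(f"reflectance values outside [0, {SCALE_MAX:.0f}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        return self.reflectance[:, :, CHANNELS.index(name)]


@dataclass
class RegionMask:
    """Boolean raster selecting a measurement region of a stack."""

    mask: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask selects no pixels")
        if self.role not in ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {ROLES}")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class GrayStandardSet:
    """Gray-standard patches of known reflectance within one photograph.

    ``patches`` pairs a boolean region mask with the patch's known diffuse
    reflectance as a fraction in [0, 1].  At least two patches with distinct
    reflectances are required to fit a calibration line.
    """

    patches: list[tuple[np.ndarray, float]]

    def __post_init__(self) -> None:
        if len(self.patches) < 2:
            raise CalibrationError("need at least 2 gray-standard patches")
        cleaned = []
        occupancy = None
        for mask, refl in self.patches:
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                raise ValueError("gray-standard patch mask is empty")
            if not 0.0 <= refl <= 1.0:
                raise ValueError("known reflectance must be a fraction in [0, 1]")
            if occupancy is None:
                occupancy = mask.copy()
            else:
                if (occupancy & mask).any():
                    raise ValueError("gray-standard patch regions overlap")
                occupancy |= mask
            cleaned.append((mask, float(refl)))
        self.patches = cleaned

    @property
    def known(self) -> np.ndarray:
        return np.array([r for _, r in self.patches])

    def measured_means(self, pixels: np.ndarray) -> np.ndarray:
        """Per-patch, per-channel mean of ``pixels`` (H, W, 3) -> (n, 3)."""
        pixels = np.asarray(pixels, dtype=np.float64)
        return np.array([[pixels[:, :, c][m].mean() for c in range(3)] for m, _ in self.patches])


@dataclass
class CalibrationMap:
    """Per-channel affine map: calibrated = gain * raw + offset."""

    gain: np.ndarray  # (3,)
    offset: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=np.float64).reshape(3)
        self.offset = np.asarray(self.offset, dtype=np.float64).reshape(3)
        if not np.all(self.gain > 0):
            raise CalibrationError("calibration gain must be positive in every channel")


def fit_gray_calibration(measured: np.ndarray, known: np.ndarray) -> CalibrationMap:
    """Fit the per-channel line mapping measured sensor values to reflectance.

    Parameters
    ----------
    measured : (n_patches, 3) array
        Per-patch, per-channel mean sensor values.
    known : (n_patches,) array
        Known patch reflectances as fractions in [0, 1].

    Returns
    -------
    CalibrationMap
        Least-squares line per channel mapping measured value to
        ``known * SCALE_MAX``.  With exactly two patches the line passes
        through both points exactly.
    """
    measured = np.asarray(measured, dtype=np.float64)
    known = np.asarray(known, dtype=np.float64)
    if measured.ndim != 2 or measured.shape[1] != 3:
        raise ValueError("measured must have shape (n_patches, 3)")
    n = measured.shape[0]
    if n < 2 or known.shape != (n,):
        raise CalibrationError("need at least 2 gray-standard patches")
    target = known * SCALE_MAX
    gain = np.empty(3)
    offset = np.empty(3)
    for c in range(3):
        x = measured[:, c]
        if np.ptp(x) == 0.0:
            raise CalibrationError(
                f"channel {CHANNELS[c]}: identical measured values on all patches"
            )
        A = np.column_stack([x, np.ones(n)])
        (gain[c], offset[c]), *_ = np.linalg.lstsq(A, target, rcond=None)
    return CalibrationMap(gain=gain, offset=offset)


def apply_calibration(raw: RawImage, cmap: CalibrationMap) -> MultispectralStack:
    """Map raw sensor values to reflectance, clipping to the 16-bit scale.

    Clipping (not wraparound) is the intended behaviour at the top of the
    scale: in the field the shutter is adjusted to avoid overexposure, so
    out-of-range values only arise from extrapolation of the gray line.
    """
    refl = raw.pixels * cmap.gain + cmap.offset
    np.clip(refl, 0.0, SCALE_MAX, out=refl)
    return MultispectralStack(reflectance=refl, pixels_per_mm=raw.pixels_per_mm)


def calibrate_scene(raw: RawImage, standards: GrayStandardSet) -> tuple[MultispectralStack, CalibrationMap]:
    """Fit the gray-standard line on ``raw`` and apply it."""
    cmap = fit_gray_calibration(standards.measured_means(raw.pixels), standards.known)
    return apply_calibration(raw, cmap), cmap


def rescale_to_resolution(stack: MultispectralStack, target_ppmm: float) -> MultispectralStack:
    """Bilinearly resample a stack to ``target_ppmm`` pixels per mm.

    Downsampling applies a Gaussian anti-aliasing prefilter; upsampling is
    performed but warned about, since it fabricates no information.
    """
    if not target_ppmm > 0:
        raise ValueError("target_ppmm must be positive")
    factor = target_ppmm / stack.pixels_per_mm
    if factor == 1.0:
        return MultispectralStack(stack.reflectance.copy(), stack.pixels_per_mm)
    if factor > 1.0:
        warnings.warn(
            f"upsampling from {stack.pixels_per_mm} to {target_ppmm} px/mm fabricates resolution",
            stacklevel=2,
        )
    out = _sk_rescale(
        stack.reflectance,
        factor,
        order=1,
        channel_axis=2,
        anti_aliasing=factor < 1.0,
        preserve_range=True,
        mode="reflect",
    )
    np.clip(out, 0.0, SCALE_MAX, out=out)
    return MultispectralStack(reflectance=out, pixels_per_mm=target_ppmm)


# ---------------------------------------------------------------------------
# Scene files
#
# A scene on disk is an RGB PNG/TIFF image, one single-channel PNG per mask
# (nonzero = inside), and a plain-text annotation file with lines:
#
#     pixels_per_mm = 17.0
#     mask = target_mask.png target
#     mask = background_mask.png background
#     patch = r0 c0 r1 c1 reflectance        # half-open pixel rectangle
# ---------------------------------------------------------------------------


def parse_annotation(path: str | Path) -> dict:
    """Parse a key-value scene annotation file."""
    info: dict = {"pixels_per_mm": None, "masks": {}, "patches": []}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SceneFormatError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "pixels_per_mm":
            info["pixels_per_mm"] = float(value)
        elif key == "mask":
            parts = value.split()
            if len(parts) != 2:
                raise SceneFormatError(f"{path}:{lineno}: mask needs 'filename role'")
            fname, role = parts
            if role not in ROLES:
                raise SceneFormatError(
                    f"{path}:{lineno}: unknown mask role {role!r}; expected one of {ROLES}"
                )
            info["masks"][fname] = role
        elif key == "patch":
            parts = value.split()
            if len(parts) != 5:
                raise SceneFormatError(f"{path}:{lineno}: patch needs 'r0 c0 r1 c1 reflectance'")
            r0, c0, r1, c1 = (int(p) for p in parts[:4])
            info["patches"].append((r0, c0, r1, c1, float(parts[4])))
        else:
            raise SceneFormatError(f"{path}:{lineno}: unknown key {key!r}")
    if info["pixels_per_mm"] is None:
        raise SceneFormatError(f"{path}: missing pixels_per_mm")
    return info


def load_scene(
    image_path: str | Path,
    mask_paths: list[str | Path],
    annotation_path: str | Path,
) -> tuple[RawImage, list[RegionMask], GrayStandardSet]:
    """Load a raw scene bundle (image, region masks, gray standards) from disk."""
    info = parse_annotation(annotation_path)
    try:
        arr = iio.imread(image_path)
    except OSError as exc:
        raise SceneFormatError(f"cannot read image {image_path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise SceneFormatError(f"{image_path}: expected an RGB image")
    arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise SceneFormatError(f"{image_path}: unsupported dtype {arr.dtype}")
    raw = RawImage(pixels=arr.astype(np.float64), bit_depth=bit_depth, pixels_per_mm=info["pixels_per_mm"])

    masks: list[RegionMask] = []
    for mpath in mask_paths:
        name = Path(mpath).name
        if name not in info["masks"]:
            raise SceneFormatError(f"annotation {annotation_path} lists no role for mask {name}")
        try:
            m = iio.imread(mpath)
        except OSError as exc:
            raise SceneFormatError(f"cannot read mask {mpath}: {exc}") from exc
        if m.ndim == 3:
            m = m[:, :, 0]
        if m.shape != raw.shape:
            raise SceneFormatError(
                f"mask {name} shape {m.shape} does not match image shape {raw.shape}"
            )
        masks.append(RegionMask(mask=m > 0, role=info["masks"][name]))

    patch_list = []
    for r0, c0, r1, c1, refl in info["patches"]:
        pm = np.zeros(raw.shape, dtype=bool)
        pm[r0:r1, c0:c1] = True
        patch_list.append((pm, refl))
    standards = GrayStandardSet(patches=patch_list)
    return raw, masks, standards


def write_stack_tiff(stack: MultispectralStack, path: str | Path) -> None:
    """Write a calibrated stack as a 16-bit RGB TIFF (values rounded)."""
    arr = np.rint(stack.reflectance).clip(0, SCALE_MAX).astype(np.uint16)
    iio.imwrite(Path(path), arr, extension=".tiff")


def read_stack_tiff(path: str | Path, pixels_per_mm: float) -> MultispectralStack:
    """Read a 16-bit RGB TIFF written by :func:`write_stack_tiff`."""
    arr = iio.imread(path)
    if arr.dtype != np.uint16 or arr.ndim != 3:
        raise SceneFormatError(f"{path}: expected a 16-bit RGB TIFF")
    return MultispectralStack(reflectance=arr[:, :, :3].astype(np.float64), pixels_per_mm=pixels_per_mm)
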