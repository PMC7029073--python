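"""Synthetic camouflage scenes with known ground truth.

Every measurement stage of the package can be exercised without field
photographs by rendering scenes that emulate the structure of a calibrated
field shot:

* a background of band-limited noise with a controllable dominant texture
  period and contrast;
* an elliptical banded target whose marking period, marking contrast,
  number of distinct band frequencies (pattern diversity) and mean-color
  offset from the background are all dialled in;
* "disruptive" elements — texture that crosses the target outline oriented
  across the boundary and phase-continuous over it, the image property the
  GabRat metric is designed to detect — controlled by a single parameter
  ``disruption`` in [0, 1];
* gray-standard patches of known reflectance rendered through a known
  per-channel calibration line, with additive Gaussian sensor noise applied
  on the raw (pre-calibration) scale;
* a background measurement annulus adjacent to the target whose area is
  within 10% of the target area.

Rendering is deterministic given the scene seed.  Cohorts of scenes are
organised by two crossed factors (species x sex) with per-cell parameter
distributions; per-individual seeds are split from a master seed through a
counter-based :class:`numpy.random.SeedSequence` scheme, so cohorts are
reproducible and order-independent.

Background-matching structure of a cohort cell follows a latent-variable
model: each individual sits in a microhabitat with an achromatic latent
brightness ``L``; its measured background mean is ``base + a_c * (L + e_x)``
and its dorsal mean is ``base + a_c * (slope_c * L + e_y)`` (channel
weights ``a_c``).  With ``slope_c = 1`` and equal error variances the true
major-axis slope is exactly 1, the symmetric errors-in-both-variables null
of the slope test.  Matching jitter may be drawn once per individual
("achromatic", brightness matching shared by all channels) or independently
per channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import (
    GrayStandardSet,
    RawImage,
    RegionMask,
    SCALE_MAX,
)

SQRT2 = math.sqrt(2.0)


class SceneSpecError(ValueError):
    """Inconsistent scene parameters (target too large, patch overlap...)."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Lengths are in pixels, reflectance quantities on the 16-bit scale.
    ``gray_patches`` pairs a known reflectance fraction with the patch's
    top-left corner ``(row, col)``; ``None`` auto-places three patches in
    the image corners.
    """

    image_size: int = 192
    pixels_per_mm: float = 17.0
    background_period: float = 24.0
    background_contrast: float = 1600.0
    background_mean: tuple[float, float, float] = (24000.0, 26000.0, 20000.0)
    channel_weights: tuple[float, float, float] = (1.0, 1.0, 0.6)
    ellipse_axes: tuple[float, float] = (55.0, 30.0)  # semi-axes (along cols, rows)
    band_period: float = 16.0
    band_contrast: float = 2000.0
    band_count_diversity: int = 1
    disruption: float = 0.0
    disruption_width: float = 10.0
    matching_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gray_patches: tuple[tuple[float, tuple[int, int] | None], ...] = (
        (0.9, None),
        (0.5, None),
        (0.2, None),
    )
    patch_size: int = 14
    cal_gain: tuple[float, float, float] = (1.15, 1.1, 1.2)
    cal_offset: tuple[float, float, float] = (500.0, 400.0, 600.0)
    noise_sd: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise SceneSpecError("image_size must be >= 32")
        for name in ("background_period", "band_period", "pixels_per_mm", "disruption_width"):
            if not getattr(self, name) > 0:
                raise SceneSpecError(f"{name} must be positive")
        for name in ("background_contrast", "band_contrast", "noise_sd"):
            if getattr(self, name) < 0:
                raise SceneSpecError(f"{name} must be non-negative")
        if not 0.0 <= self.disruption <= 1.0:
            raise SceneSpecError("disruption must lie in [0, 1]")
        if self.band_count_diversity < 1:
            raise SceneSpecError("band_count_diversity must be >= 1")
        if min(self.ellipse_axes) <= 2:
            raise SceneSpecError("ellipse axes too small")
        if max(self.ellipse_axes) >= self.image_size / 2 - 2:
            raise SceneSpecError("target does not fit inside the image")
        if not all(g > 0 for g in self.cal_gain):
            raise SceneSpecError("cal_gain must be positive")


@dataclass(frozen=True)
class SceneGroundTruth:
    """Rendered-scene truths the recovery tests assert against."""

    band_period: float
    band_contrast: float
    band_count_diversity: int
    disruption: float
    target_mean: tuple[float, float, float]  # pre-noise reflectance means
    background_mean: tuple[float, float, float]  # over the annulus
    matching_offset: tuple[float, float, float]
    cal_gain: tuple[float, float, float]
    cal_offset: tuple[float, float, float]
    background_period: float
    background_contrast: float
    seed: int


@dataclass(frozen=True)
class SceneBundle:
    """One rendered scene: raw image, masks, standards, ground truth."""

    raw: RawImage
    target: RegionMask
    background: RegionMask
    standards: GrayStandardSet
    truth: SceneGroundTruth
    spec: SceneSpec


def _patch_positions(spec: SceneSpec) -> list[tuple[float, tuple[int, int]]]:
    """Resolve gray-patch corners; ``None`` positions go to image corners."""
    n = spec.image_size
    ps = spec.patch_size
    margin = 6
    corners = [
        (margin, margin),
        (margin, n - margin - ps),
        (n - margin - ps, margin),
        (n - margin - ps, n - margin - ps),
    ]
    out = []
    auto = iter(corners)
    for refl, pos in spec.gray_patches:
        if pos is None:
            pos = next(auto)
        r, c = pos
        if r < 0 or c < 0 or r + ps > n or c + ps > n:
            raise SceneSpecError(f"gray patch at {pos} extends outside the image")
        out.append((refl, (int(r), int(c))))
    return out


def _band_limited_noise(rng: np.random.Generator, n: int, period: float) -> np.ndarray:
    """Unit-scale noise whose power lies in periods [period/sqrt2, period*sqrt2]."""
    white = rng.standard_normal((n, n))
    F = np.fft.fft2(white)
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    fmag = np.hypot(fy, fx)
    sel = (fmag > 1.0 / (period * SQRT2)) & (fmag <= SQRT2 / period)
    tex = np.fft.ifft2(F * sel).real
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def _annulus(target: np.ndarray, blocked: np.ndarray) -> np.ndarray:
    """Adjacent background region of area within 10% of the target area."""
    area = int(target.sum())
    dist = ndimage.distance_transform_edt(~target)
    candidates = ~target & ~blocked
    dvals = np.sort(dist[candidates])
    if dvals.size < area:
        raise SceneSpecError("not enough free background pixels for the annulus")
    threshold = dvals[area - 1]
    annulus = candidates & (dist <= threshold)
    got = int(annulus.sum())
    if abs(got - area) > 0.1 * area:
        raise SceneSpecError(
            f"annulus area {got} deviates more than 10% from target area {area}"
        )
    return annulus


def generate_scene(spec: SceneSpec) -> SceneBundle:
    """Render one synthetic scene deterministically from its spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    cy = cx = (n - 1) / 2.0
    rows = np.arange(n)[:, None]
    cols = np.arange(n)[None, :]
    a, b = spec.ellipse_axes
    target = ((cols - cx) / a) ** 2 + ((rows - cy) / b) ** 2 <= 1.0

    patches = _patch_positions(spec)
    blocked = np.zeros((n, n), dtype=bool)
    patch_masks = []
    for refl, (r, c) in patches:
        pm = np.zeros((n, n), dtype=bool)
        pm[r : r + spec.patch_size, c : c + spec.patch_size] = True
        if (pm & target).any():
            raise SceneSpecError("gray patch overlaps the target")
        patch_masks.append((pm, refl))
        blocked |= pm
    annulus = _annulus(target, blocked)

    # background texture, centred on the annulus so the rendered annulus
    # mean equals the nominal background mean exactly (pre-noise)
    bg_tex = _band_limited_noise(rng, n, spec.background_period) * spec.background_contrast
    bg_tex -= bg_tex[annulus].mean()

    # banded target texture: dominant sinusoid at band_period plus
    # band_count_diversity - 1 weaker components at sqrt(2)-spaced periods
    tex = np.zeros((n, n))
    u = cols - cx
    for j in range(spec.band_count_diversity):
        period = spec.band_period * (SQRT2**j)
        amp = 1.0 if j == 0 else 0.55
        phase = rng.uniform(0.0, 2.0 * math.pi)
        tex = tex + amp * np.cos(2.0 * math.pi * u / period + phase)
    tex_sd = tex[target].std()
    if tex_sd > 0 and spec.band_contrast > 0:
        tex = (tex - tex[target].mean()) * (spec.band_contrast / tex_sd)
    else:
        tex = np.zeros((n, n))

    # disruptive elements: radial spokes, phase-continuous across the
    # outline, windowed to a band around the boundary
    disrupt = np.zeros((n, n))
    if spec.disruption > 0:
        d_in = ndimage.distance_transform_edt(target)
        d_out = ndimage.distance_transform_edt(~target)
        signed = np.where(target, d_in, -d_out)
        w_sigma = spec.disruption_width / 2.0
        window = np.exp(-(signed**2) / (2.0 * w_sigma**2))
        phi = np.arctan2(rows - cy, cols - cx)
        perimeter = math.pi * (2.0 * math.sqrt((a**2 + b**2) / 2.0))
        m = max(4, int(round(perimeter / spec.band_period)))
        phase = rng.uniform(0.0, 2.0 * math.pi)
        disrupt = (
            spec.disruption
            * 2.0
            * spec.band_contrast
            * window
            * np.cos(m * phi + phase)
        )

    refl = np.empty((n, n, 3))
    for c in range(3):
        w = spec.channel_weights[c]
        base = np.where(
            target,
            spec.background_mean[c] + spec.matching_offset[c] + w * tex,
            spec.background_mean[c] + w * bg_tex,
        )
        refl[:, :, c] = base + w * disrupt
    for pm, patch_refl in patch_masks:
        refl[pm] = patch_refl * SCALE_MAX
    np.clip(refl, 0.0, SCALE_MAX, out=refl)

    truth = SceneGroundTruth(
        band_period=spec.band_period,
        band_contrast=spec.band_contrast,
        band_count_diversity=spec.band_count_diversity,
        disruption=spec.disruption,
        target_mean=tuple(float(refl[:, :, c][target].mean()) for c in range(3)),
        background_mean=tuple(float(refl[:, :, c][annulus].mean()) for c in range(3)),
        matching_offset=spec.matching_offset,
        cal_gain=spec.cal_gain,
        cal_offset=spec.cal_offset,
        background_period=spec.background_period,
        background_contrast=spec.background_contrast,
        seed=spec.seed,
    )

    raw_pixels = np.empty_like(refl)
    for c in range(3):
        raw_pixels[:, :, c] = (refl[:, :, c] - spec.cal_offset[c]) / spec.cal_gain[c]
    if spec.noise_sd > 0:
        raw_pixels = raw_pixels + rng.normal(0.0, spec.noise_sd, size=raw_pixels.shape)
    np.clip(raw_pixels, 0.0, SCALE_MAX, out=raw_pixels)

    return SceneBundle(
        raw=RawImage(pixels=raw_pixels, bit_depth=16, pixels_per_mm=spec.pixels_per_mm),
        target=RegionMask(mask=target, role="target"),
        background=RegionMask(mask=annulus, role="background"),
        standards=GrayStandardSet(patches=patch_masks),
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellSpec:
    """Parameter distributions for one species x sex cell."""

    n: int
    base: SceneSpec = field(default_factory=SceneSpec)
    band_period_sd: float = 2.0
    band_contrast_sd: float = 200.0
    disruption_sd: float = 0.05
    latent_sd: float = 2600.0  # SD of the achromatic microhabitat latent
    matching_slope: tuple[float, float, float] = (1.0, 1.0, 1.0)
    matching_jitter_sd: float = 700.0
    jitter_mode: str = "achromatic"  # or "per_channel"
    latent_weights: tuple[float, float, float] = (1.0, 1.0, 0.8)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise SceneSpecError("each cohort cell needs n >= 3")
        if self.jitter_mode not in ("achromatic", "per_channel"):
            raise SceneSpecError("jitter_mode must be 'achromatic' or 'per_channel'")


@dataclass(frozen=True)
class CohortSpec:
    """Two-factor cohort: (species, sex) -> CellSpec, plus a master seed."""

    cells: dict[tuple[str, str], CellSpec]
    master_seed: int = 0


@dataclass(frozen=True)
class Individual:
    """One cohort member with its rendered scene bundle."""

    individual_id: str
    species: str
    sex: str
    bundle: SceneBundle


def _individual_spec(
    cell: CellSpec, cell_index: int, i: int, master_seed: int
) -> tuple[SceneSpec, dict]:
    """Draw one individual's scene spec from its cell distributions."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index, i))
    rng = np.random.default_rng(ss)
    scene_seed = int(rng.integers(0, 2**31 - 1))

    band_period = max(4.0, rng.normal(cell.base.band_period, cell.band_period_sd))
    band_contrast = max(100.0, rng.normal(cell.base.band_contrast, cell.band_contrast_sd))
    disruption = float(np.clip(rng.normal(cell.base.disruption, cell.disruption_sd), 0.0, 1.0))

    latent = rng.normal(0.0, cell.latent_sd)
    e_x = rng.normal(0.0, cell.matching_jitter_sd)
    if cell.jitter_mode == "achromatic":
        e_y = np.full(3, rng.normal(0.0, cell.matching_jitter_sd))
    else:
        e_y = rng.normal(0.0, cell.matching_jitter_sd, size=3)

    bg_mean = []
    offset = []
    for c in range(3):
        a_c = cell.latent_weights[c]
        bg_c = cell.base.background_mean[c] + a_c * (latent + e_x)
        animal_c = cell.base.background_mean[c] + a_c * (
            cell.matching_slope[c] * latent + e_y[c]
        )
        bg_mean.append(float(np.clip(bg_c, 4000.0, SCALE_MAX - 8000.0)))
        offset.append(float(animal_c - bg_c))

    spec = replace(
        cell.base,
        band_period=float(band_period),
        band_contrast=float(band_contrast),
        disruption=disruption,
        background_mean=tuple(bg_mean),
        matching_offset=tuple(offset),
        seed=scene_seed,
    )
    meta = {"latent": float(latent), "scene_seed": scene_seed}
    return spec, meta


def generate_cohort(cohort: CohortSpec) -> tuple[list[Individual], pd.DataFrame]:
    """Render every individual of a cohort; return scenes and a truth table."""
    individuals: list[Individual] = []
    truth_rows = []
    for cell_index, ((species, sex), cell) in enumerate(sorted(cohort.cells.items())):
        for i in range(cell.n):
            spec, meta = _individual_spec(cell, cell_index, i, cohort.master_seed)
            bundle = generate_scene(spec)
            ind_id = f"{species}_{sex}_{i:03d}"
            individuals.append(
                Individual(individual_id=ind_id, species=species, sex=sex, bundle=bundle)
            )
            t = bundle.truth
            truth_rows.append(
                {
                    "id": ind_id,
                    "species": species,
                    "sex": sex,
                    "seed": t.seed,
                    "band_period": t.band_period,
                    "band_contrast": t.band_contrast,
                    "band_count_diversity": t.band_count_diversity,
                    "disruption": t.disruption,
                    "target_mean_R": t.target_mean[0],
                    "target_mean_G": t.target_mean[1],
                    "target_mean_B": t.target_mean[2],
                    "background_mean_R": t.background_mean[0],
                    "background_mean_G": t.background_mean[1],
                    "background_mean_B": t.background_mean[2],
                    "latent": meta["latent"],
                }
            )
    return individuals, pd.DataFrame(truth_rows)


def paper_mimic_cohort(
    master_seed: int = 0, n_per_cell: dict[tuple[str, str], int] | None = None
) -> CohortSpec:
    """Preset cohort reproducing the qualitative field contrasts.

    Two synthetic "species" in habitats of different visual complexity and
    two sexes with different cryptic strategies: males carry higher-contrast,
    more diverse, more disruptive markings and a background-matching deficit
    in the R channel (dorsal R mean decoupled from the background); females
    carry flatter patterns, low disruption, and achromatic brightness
    matching with true MA slope 1 in all channels.  Default cell sizes are
    35/44 (species A females/males) and 42/43 (species B females/males).
    """
    ns = {
        ("planum", "female"): 35,
        ("planum", "male"): 44,
        ("purpurascens", "female"): 42,
        ("purpurascens", "male"): 43,
    }
    if n_per_cell:
        ns.update(n_per_cell)

    habitats = {
        "planum": dict(
            background_mean=(26000.0, 23000.0, 16000.0),
            background_period=28.0,
            background_contrast=1200.0,
        ),
        "purpurascens": dict(
            background_mean=(21000.0, 25000.0, 15000.0),
            background_period=20.0,
            background_contrast=2000.0,
        ),
    }
    cells: dict[tuple[str, str], CellSpec] = {}
    for species, habitat in habitats.items():
        contrast_scale = 1.25 if species == "purpurascens" else 1.0
        for sex in ("female", "male"):
            if sex == "female":
                band_period = 26.0 if species == "purpurascens" else 18.0
                base = SceneSpec(
                    band_period=band_period,
                    band_contrast=1500.0 * contrast_scale,
                    band_count_diversity=1,
                    disruption=0.10,
                    **habitat,
                )
                cell = CellSpec(
                    n=ns[(species, sex)],
                    base=base,
                    band_period_sd=3.0,
                    disruption_sd=0.04,
                    matching_slope=(1.0, 1.0, 1.0),
                    matching_jitter_sd=700.0,
                    jitter_mode="achromatic",
                )
            else:
                base = SceneSpec(
                    band_period=12.0,
                    band_contrast=2400.0 * contrast_scale,
                    band_count_diversity=4 if species == "purpurascens" else 3,
                    disruption=0.70 if species == "purpurascens" else 0.65,
                    **habitat,
                )
                cell = CellSpec(
                    n=ns[(species, sex)],
                    base=base,
                    band_period_sd=2.5,
                    disruption_sd=0.06,
                    matching_slope=(0.2, 1.0, 1.0),
                    matching_jitter_sd=900.0,
                    jitter_mode="per_channel",
                )
            cells[(species, sex)] = cell
    return CohortSpec(cells=cells, master_seed=master_seed)


def smoke_cohort(master_seed: int = 0, n: int = 3) -> CohortSpec:
    """Tiny cohort (n per cell) for fast end-to-end runs."""
    return paper_mimic_cohort(
        master_seed=master_seed,
        n_per_cell={
            ("planum", "female"): n,
            ("planum", "male"): n,
            ("purpurascens", "female"): n,
            ("purpurascens", "male"): n,
        },
    )


# ---------------------------------------------------------------------------
# Disk output (16-bit PNGs + plain-text annotations + truth CSV)
# ---------------------------------------------------------------------------


def write_scene(bundle: SceneBundle, outdir: str | Path, stem: str) -> dict[str, Path]:
    """Write one scene: 16-bit TIFF image, PNG masks, key-value annotation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image_path = outdir / f"{stem}.tiff"
    iio.imwrite(image_path, np.rint(bundle.raw.pixels).astype(np.uint16))
    mask_paths = {}
    for region in (bundle.target, bundle.background):
        mpath = outdir / f"{stem}_{region.role}_mask.png"
        iio.imwrite(mpath, (region.mask.astype(np.uint8)) * 255)
        mask_paths[region.role] = mpath
    lines = [f"pixels_per_mm = {bundle.raw.pixels_per_mm}"]
    for role, mpath in mask_paths.items():
        lines.append(f"mask = {mpath.name} {role}")
    for pm, refl in bundle.standards.patches:
        rr, cc = np.nonzero(pm)
        lines.append(
            f"patch = {rr.min()} {cc.min()} {rr.max() + 1} {cc.max() + 1} {refl}"
        )
    ann_path = outdir / f"{stem}.txt"
    ann_path.write_text("\n".join(lines) + "\n")
    return {"image": image_path, "annotation": ann_path, **mask_paths}


def write_cohort(cohort: CohortSpec, outdir: str | Path) -> pd.DataFrame:
    """Render a cohort to disk; returns the truth table (also written as CSV)."""
    outdir = Path(outdir)
    individuals, truth = generate_cohort(cohort)
    for ind in individuals:
        write_scene(ind.bundle, outdir, ind.individual_id)
    truth.to_csv(outdir / "truth.csv", index=False)
    return truth
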