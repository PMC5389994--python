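"""Synthetic multispectral flower scenes with full ground truth.

The generator emits schematic scenes — a center disc inside a petal annulus
on a leaf background, with a gray-reference strip along the bottom — whose
spectral statistics carry the structure the analysis assumes about real
flowers:

* mean reflectance of every region class increases with wavelength;
* petals are brighter than leaves and centers at every band, while centers
  and leaves are darkest in the UV/blue bands;
* per-band pixel noise never decreases with wavelength, and petals are the
  most homogeneous region;
* across species, petal reflectance varies more at short than at long
  wavelengths (flower colors spread out in the UV/blue);
* the gray strip spans dark-to-light identically in every band.

Each scene can additionally be corrupted the way a scanned photograph is:
per-band affine gain/offset distortion and integer band misalignments. All
distortion parameters are recorded in :class:`GroundTruth`, so calibration
and alignment can be tested against the generator rather than against
themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .imaging import MultispectralStack, RegionMask, _translate
from .spectra import DEFAULT_BANDS_NM, Spectrum, WavelengthGrid

__all__ = [
    "SceneParams",
    "GroundTruth",
    "generate_region_spectrum",
    "generate_scene",
    "generate_species_set",
    "sample_petal_spectra",
]

_REGIONS = ("petal", "center", "leaf")


@dataclass(frozen=True)
class SceneParams:
    """Everything the scene generator needs; defaults are the study conditions.

    Region mean-reflectance curves are linear in wavelength between a level
    at the shortest band and one at the longest; pixel-noise SDs likewise
    interpolate between a short- and long-wavelength value (never
    decreasing). Gains/offsets and integer shifts model scan distortion and
    default to on; set ``gain_range=(1,1), offset_range=(0,0), shift_max=0``
    for clean scenes.
    """

    height: int = 160
    width: int = 160
    band_nm: tuple[float, ...] = DEFAULT_BANDS_NM
    # (level at first band, level at last band) per region class
    region_levels: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "petal": (0.10, 0.78),
            "leaf": (0.06, 0.45),
            "center": (0.05, 0.40),
        }
    )
    # per-pixel Gaussian noise SD, (at first band, at last band)
    region_noise_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "petal": (0.030, 0.050),
            "leaf": (0.050, 0.080),
            "center": (0.050, 0.090),
        }
    )
    # spectrum-level draw noise for generate_region_spectrum:
    # (SD of the base level, per-band SD of the nonnegative increments)
    spectrum_jitter: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "petal": (0.08, 0.020),
            "leaf": (0.03, 0.015),
            "center": (0.03, 0.015),
        }
    )
    # across-species jitter: short-wavelength-weighted petal term + level term
    species_shortwave_sd: float = 0.08
    species_level_sd: float = 0.02
    # shared additive texture (shading/surface structure common to all
    # bands — what makes cross-band registration well-posed on real photos)
    texture_amp: float = 0.03
    texture_block: int = 3
    # gray-reference strip
    strip_patches: int = 6
    strip_min: float = 0.0
    strip_max: float = 1.0
    strip_height: int = 16
    strip_noise_sd: float = 0.005
    # distortion
    gain_range: tuple[float, float] = (0.65, 0.90)
    offset_range: tuple[float, float] = (0.02, 0.08)
    shift_max: int = 2
    # geometry (fractions of the usable, above-strip image)
    petal_outer_frac: float = 0.60
    petal_inner_frac: float = 0.33
    center_frac: float = 0.25

    def __post_init__(self) -> None:
        for rc in _REGIONS:
            lo, hi = self.region_levels[rc]
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{rc} mean curve must be nondecreasing within [0, 1]")
            n0, n1 = self.region_noise_sd[rc]
            if n0 < 0 or n1 < n0:
                raise ValueError(f"{rc} noise SD must be >= 0 and nondecreasing")
        for band in self.band_nm:
            p = self.mean_level("petal", band)
            if not (p > self.mean_level("leaf", band) and p > self.mean_level("center", band)):
                raise ValueError("petal mean level must exceed leaf and center at every band")
        if self.strip_patches < 5:
            raise ValueError("gray strip needs at least 5 patches")
        if self.shift_max < 0:
            raise ValueError("shift_max must be >= 0")
        usable = self.height - self.strip_height
        r_out = self.petal_outer_frac * min(usable, self.width) / 2
        if r_out * 2 >= min(usable, self.width):
            raise ValueError("flower geometry exceeds image bounds")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.band_nm)

    def _interp(self, pair: tuple[float, float], nm: float) -> float:
        lo_nm, hi_nm = self.band_nm[0], self.band_nm[-1]
        t = (nm - lo_nm) / (hi_nm - lo_nm)
        return pair[0] + (pair[1] - pair[0]) * t

    def mean_level(self, region_class: str, nm: float) -> float:
        return self._interp(self.region_levels[region_class], nm)

    def noise_sd(self, region_class: str, nm: float) -> float:
        return self._interp(self.region_noise_sd[region_class], nm)

    def mean_curve(self, region_class: str) -> np.ndarray:
        return np.array([self.mean_level(region_class, nm) for nm in self.band_nm])

    def noise_curve(self, region_class: str) -> np.ndarray:
        return np.array([self.noise_sd(region_class, nm) for nm in self.band_nm])

    def clean(self) -> "SceneParams":
        """Same scene statistics without scan distortion or misalignment."""
        return replace(self, gain_range=(1.0, 1.0), offset_range=(0.0, 0.0), shift_max=0)

    def noiseless(self) -> "SceneParams":
        """Zero pixel noise everywhere (for exactness checks)."""
        zero = {rc: (0.0, 0.0) for rc in _REGIONS}
        return replace(self, region_noise_sd=zero, strip_noise_sd=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Everything generate_scene decided: the key to testing the pipeline."""

    reflectance: np.ndarray                      # H x W x B, noise included, pre-distortion
    shifts: tuple[tuple[int, int], ...]          # applied (dy, dx) per band
    gains: tuple[float, ...]
    offsets: tuple[float, ...]
    masks: Mapping[str, RegionMask]
    region_mean_spectra: Mapping[str, Spectrum]  # the class mean curves used
    seed: int


def generate_region_spectrum(
    region_class: str, params: SceneParams, rng: np.random.Generator
) -> Spectrum:
    """One random reflectance spectrum of the given region class.

    Construction is cumulative: a jittered base level at the shortest band,
    then nonnegative jittered increments per band. This makes every draw
    nondecreasing in wavelength by construction and makes the per-band SD of
    repeated draws nondecreasing in wavelength (variances accumulate) —
    matching the reflectance statistics the analysis assumes.
    """
    if region_class not in _REGIONS:
        raise ValueError(f"unknown region class {region_class!r}")
    mean = params.mean_curve(region_class)
    sd_base, sd_inc = params.spectrum_jitter[region_class]
    vals = np.empty(len(mean))
    vals[0] = mean[0] + rng.normal(0.0, sd_base)
    for k in range(1, len(mean)):
        inc = max(0.0, (mean[k] - mean[k - 1]) + rng.normal(0.0, sd_inc))
        vals[k] = vals[k - 1] + inc
    return Spectrum(params.grid, np.clip(vals, 0.0, 1.0), role="reflectance")


def sample_petal_spectra(n: int, seed: int, params: SceneParams | None = None) -> list[Spectrum]:
    """n independent petal reflectance spectra (stand-in for per-species petal colors)."""
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    return [generate_region_spectrum("petal", params, rng) for _ in range(n)]


def _scene_geometry(params: SceneParams) -> dict[str, np.ndarray]:
    """Boolean masks for petal annulus, center disc, leaf background."""
    H, W = params.height, params.width
    usable = H - params.strip_height
    cy, cx = usable / 2.0, W / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    r = np.hypot(yy - cy, xx - cx)
    scale = min(usable, W) / 2.0
    r_out = params.petal_outer_frac * scale
    r_in = params.petal_inner_frac * scale
    r_c = params.center_frac * scale
    above_strip = yy < usable
    petal = (r <= r_out) & (r > r_in) & above_strip
    center = (r <= r_c) & above_strip
    leaf = above_strip & (r > r_out + 2)
    return {"petal": petal, "center": center, "leaf": leaf}


def _strip_truth(params: SceneParams) -> np.ndarray:
    """H x W map of gray-strip levels (nan above the strip)."""
    H, W = params.height, params.width
    levels = np.linspace(params.strip_min, params.strip_max, params.strip_patches)
    out = np.full((H, W), np.nan)
    edges = np.linspace(0, W, params.strip_patches + 1).astype(int)
    for i, lvl in enumerate(levels):
        out[H - params.strip_height:, edges[i]:edges[i + 1]] = lvl
    return out


def generate_scene(
    params: SceneParams | None = None,
    seed: int = 0,
    region_curves: Mapping[str, np.ndarray] | None = None,
    stack_id: str = "",
) -> tuple[MultispectralStack, GroundTruth]:
    """Emit one scene: a distorted stack plus its complete ground truth.

    The truth cube is the noisy reflectance scene *before* distortion; the
    emitted stack applies per-band gain/offset and integer shifts on top.
    The band nearest 520 nm is never shifted (it is the registration
    reference), so detected displacements are directly comparable to the
    recorded ones. The gray-reference rectangle is inset from the strip by
    ``shift_max + 2`` pixels so white balance reads strip pixels in every
    band even when misaligned.
    """
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    H, W = params.height, params.width
    B = len(params.band_nm)
    geo = _scene_geometry(params)
    strip = _strip_truth(params)
    strip_mask = ~np.isnan(strip)

    # band-shared additive texture: blocky zero-mean field, identical in
    # every band, so co-registered structure exists even in the dark bands
    if params.texture_amp > 0:
        blk = params.texture_block
        coarse = rng.normal(0.0, 1.0, size=(H // blk + 1, W // blk + 1))
        texture = params.texture_amp * np.repeat(
            np.repeat(coarse, blk, axis=0), blk, axis=1
        )[:H, :W]
    else:
        texture = np.zeros((H, W))

    truth = np.empty((H, W, B))
    for b, nm in enumerate(params.band_nm):
        base = np.full((H, W), params.mean_level("leaf", nm))
        for rc in ("petal", "center"):
            base[geo[rc]] = params.mean_level(rc, nm)
        if region_curves:
            base = np.full((H, W), region_curves["leaf"][b])
            for rc in ("petal", "center"):
                base[geo[rc]] = region_curves[rc][b]
        base = base + texture
        base[strip_mask] = strip[strip_mask]
        noise_sd = np.full((H, W), params.noise_sd("leaf", nm))
        for rc in ("petal", "center"):
            noise_sd[geo[rc]] = params.noise_sd(rc, nm)
        noise_sd[strip_mask] = params.strip_noise_sd
        noisy = base + rng.normal(0.0, 1.0, size=(H, W)) * noise_sd
        truth[..., b] = np.clip(noisy, 0.0, 1.0)

    ref_band = int(np.argmin(np.abs(np.asarray(params.band_nm) - 520.0)))
    gains = rng.uniform(*params.gain_range, size=B)
    offsets = rng.uniform(*params.offset_range, size=B)
    shifts = []
    bands = np.empty_like(truth)
    for b in range(B):
        distorted = gains[b] * truth[..., b] + offsets[b]
        if b == ref_band or params.shift_max == 0:
            dy = dx = 0
        else:
            dy = int(rng.integers(-params.shift_max, params.shift_max + 1))
            dx = int(rng.integers(-params.shift_max, params.shift_max + 1))
        shifted, _ = _translate(distorted, dy, dx)
        bands[..., b] = shifted
        shifts.append((dy, dx))

    margin = params.shift_max + 2
    gray_ref = (margin, H - params.strip_height + margin, W - margin, H - margin)
    stack = MultispectralStack(
        bands=bands,
        band_nm=params.band_nm,
        gray_ref=gray_ref,
        balanced=False,
        aligned=params.shift_max == 0,
        stack_id=stack_id or f"scene{seed}",
    )
    mean_curves = region_curves or {rc: params.mean_curve(rc) for rc in _REGIONS}
    truth_obj = GroundTruth(
        reflectance=truth,
        shifts=tuple(shifts),
        gains=tuple(float(g) for g in gains),
        offsets=tuple(float(o) for o in offsets),
        masks={
            rc: RegionMask(geo[rc], rc, species_id=stack.stack_id) for rc in _REGIONS
        },
        region_mean_spectra={
            rc: Spectrum(params.grid, np.asarray(mean_curves[rc], dtype=float))
            for rc in _REGIONS
        },
        seed=seed,
    )
    return stack, truth_obj


def generate_species_set(
    k: int, params: SceneParams | None = None, seed: int = 0
) -> list[tuple[MultispectralStack, GroundTruth]]:
    """k scenes with per-species jitter of the region mean curves.

    Petal curves get a short-wavelength-weighted random offset (larger
    spread at 340–460 nm than at 640–700 nm: across species, flower colors
    vary most in the UV/blue) plus a small overall level shift; leaf and
    center curves get level shifts only. Jitter magnitudes are capped so
    every species' curves stay nondecreasing and petals stay brightest.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    params = params or SceneParams()
    master = np.random.default_rng(seed)
    scene_seeds = master.integers(0, 2**31 - 1, size=k)
    nm = np.asarray(params.band_nm)
    shortwave = 1.0 - 0.85 * (nm - nm[0]) / (nm[-1] - nm[0])  # 1.0 -> 0.15
    scenes = []
    for i in range(k):
        u = float(np.clip(master.normal(0.0, params.species_shortwave_sd), -0.20, 0.20))
        curves = {}
        for rc in _REGIONS:
            v = float(np.clip(master.normal(0.0, params.species_level_sd), -0.05, 0.05))
            curve = params.mean_curve(rc) + v
            if rc == "petal":
                curve = curve + u * shortwave
            curves[rc] = np.clip(curve, 0.0, 1.0)
        stack, truth = generate_scene(
            params,
            seed=int(scene_seeds[i]),
            region_curves=curves,
            stack_id=f"sp{i:03d}",
        )
        scenes.append((stack, truth))
    return scenes
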