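"""Multispectral stack I/O, white balance, band alignment, sampling, rendering.

A scene is a stack of B co-registered grayscale images, one per band-pass
filter, with an in-frame gray-reference strip. The processing chain mirrors
how the photographic scans are prepared for the receptor model:

1. :func:`read_stack` — load band images from a YAML manifest into [0, 1].
2. :func:`white_balance` — per band, map the darkest pixel of the gray
   reference to 0 and the lightest to 1 (affine, clipped).
3. :func:`align_bands` — integer-pixel translation per band, found by
   exhaustive normalized cross-correlation against a mid-spectrum reference.
4. :func:`sample_region` — reproducible random pixel samples from a mask.

Rendering (false color, heat maps, ommatidium-scale downsampling) is pure:
it never mutates the stack or the response maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "MultispectralStack",
    "RegionMask",
    "PixelSample",
    "DegenerateReferenceError",
    "StackLoadError",
    "read_stack",
    "read_masks",
    "write_stack",
    "white_balance",
    "align_bands",
    "sample_region",
    "false_color",
    "heat_map",
    "downsample_ommatidia",
]

REGION_CLASSES = ("petal", "center", "leaf")


class StackLoadError(ValueError):
    pass


class DegenerateReferenceError(ValueError):
    """The gray reference has no dynamic range in some band."""


@dataclass(frozen=True)
class MultispectralStack:
    """H x W x B reflectance cube with band wavelengths and gray-ref geometry.

    ``gray_ref`` is a half-open rectangle (x0, y0, x1, y1) in 0-based pixel
    coordinates. ``valid`` marks pixels with data in every band (alignment
    fills out-of-frame pixels with zeros and clears their validity).
    """

    bands: np.ndarray
    band_nm: tuple[float, ...]
    gray_ref: tuple[int, int, int, int]
    balanced: bool = False
    aligned: bool = False
    stack_id: str = ""
    valid: np.ndarray | None = None
    shifts: tuple[tuple[int, int], ...] | None = None  # detected (dy, dx) per band

    def __post_init__(self) -> None:
        bands = np.asarray(self.bands, dtype=float)
        if bands.ndim != 3:
            raise ValueError("bands must be an H x W x B array")
        object.__setattr__(self, "bands", bands)
        nm = tuple(float(x) for x in self.band_nm)
        object.__setattr__(self, "band_nm", nm)
        if bands.shape[2] != len(nm):
            raise ValueError("band count does not match band_nm")
        if not np.all(np.diff(nm) > 0):
            raise ValueError("band_nm must be strictly increasing")
        x0, y0, x1, y1 = self.gray_ref
        H, W, _ = bands.shape
        if not (0 <= x0 < x1 <= W and 0 <= y0 < y1 <= H):
            raise ValueError(f"gray_ref {self.gray_ref} outside image bounds {W}x{H}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bands.shape  # type: ignore[return-value]

    def band_index(self, nm: float) -> int:
        return int(np.argmin(np.abs(np.asarray(self.band_nm) - nm)))


@dataclass(frozen=True)
class RegionMask:
    """Boolean pixel mask for one petal / center / leaf area of one species."""

    mask: np.ndarray
    region_class: str
    species_id: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"region_class must be one of {REGION_CLASSES}")
        if not mask.any():
            raise ValueError("region mask is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PixelSample:
    """Random pixels from one region: coordinates, band vectors, provenance."""

    coords: np.ndarray          # (n, 2) row, col
    values: np.ndarray          # (n, B) reflectances
    band_nm: tuple[float, ...]
    seed: int
    region_class: str = ""
    species_id: str = ""
    with_replacement: bool = False

    @property
    def n(self) -> int:
        return self.coords.shape[0]


# --- I/O -------------------------------------------------------------------

def _load_gray_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    try:
        img = iio.imread(path)
    except FileNotFoundError as exc:
        raise StackLoadError(f"band image not found: {path.name}") from exc
    if img.ndim == 3:  # collapse trivially-replicated channels
        img = img[..., 0]
    info = np.iinfo(img.dtype) if np.issubdtype(img.dtype, np.integer) else None
    arr = img.astype(float)
    if info is not None:
        arr /= info.max
    return arr


def read_stack(manifest: str | Path) -> MultispectralStack:
    """Load a stack from a YAML manifest.

    The manifest lists ``bands: [{file, nm}]`` (paths relative to the
    manifest) and a ``gray_ref: [x0, y0, x1, y1]`` rectangle; integer pixel
    values are mapped to [0, 1] by dividing by the dtype maximum.
    """
    manifest = Path(manifest)
    try:
        doc = yaml.safe_load(manifest.read_text())
    except yaml.YAMLError as exc:
        raise StackLoadError(f"malformed manifest {manifest.name}: {exc}") from exc
    if not isinstance(doc, dict) or "bands" not in doc or "gray_ref" not in doc:
        raise StackLoadError(f"manifest {manifest.name} must declare 'bands' and 'gray_ref'")
    entries = sorted(doc["bands"], key=lambda e: float(e["nm"]))
    images, nms = [], []
    for entry in entries:
        arr = _load_gray_image(manifest.parent / entry["file"])
        images.append(arr)
        nms.append(float(entry["nm"]))
    shapes = {im.shape for im in images}
    if len(shapes) != 1:
        raise StackLoadError(f"manifest {manifest.name}: band image dimensions differ: {shapes}")
    return MultispectralStack(
        bands=np.stack(images, axis=-1),
        band_nm=tuple(nms),
        gray_ref=tuple(int(v) for v in doc["gray_ref"]),
        stack_id=doc.get("id", manifest.stem),
    )


def read_masks(manifest: str | Path) -> list[RegionMask]:
    """Load the region masks declared in a manifest (binary PNG files)."""
    manifest = Path(manifest)
    doc = yaml.safe_load(manifest.read_text())
    species = doc.get("id", manifest.stem)
    masks = []
    for entry in doc.get("masks", []):
        arr = _load_gray_image(manifest.parent / entry["file"])
        masks.append(RegionMask(arr > 0.5, entry["class"], species_id=species))
    return masks


def write_stack(
    stack: MultispectralStack,
    directory: str | Path,
    masks: Sequence[RegionMask] = (),
    bit_depth: int = 8,
) -> Path:
    """Write band PNGs, mask PNGs and a manifest; returns the manifest path."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    band_entries = []
    for i, nm in enumerate(stack.band_nm):
        fname = f"band_{int(nm)}.png"
        img = np.clip(np.round(stack.bands[..., i] * scale), 0, scale).astype(dtype)
        iio.imwrite(directory / fname, img)
        band_entries.append({"file": fname, "nm": float(nm)})
    mask_entries = []
    for mask in masks:
        fname = f"{stack.stack_id or 'scene'}_{mask.region_class}.png"
        iio.imwrite(directory / fname, (mask.mask.astype(np.uint8) * 255))
        mask_entries.append({"file": fname, "class": mask.region_class})
    doc = {
        "id": stack.stack_id or directory.name,
        "bands": band_entries,
        "gray_ref": list(stack.gray_ref),
    }
    if mask_entries:
        doc["masks"] = mask_entries
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


# --- calibration -----------------------------------------------------------

def white_balance(stack: MultispectralStack) -> MultispectralStack:
    """Per band, map the gray-reference extremes to exactly 0 and 1.

    The darkest and lightest pixels are searched inside the gray_ref
    rectangle only (the strip is the stated reference); values outside the
    corrected range clip to [0, 1]. Idempotent once the reference spans the
    full range.
    """
    x0, y0, x1, y1 = stack.gray_ref
    ref = stack.bands[y0:y1, x0:x1, :]
    out = np.empty_like(stack.bands)
    for b in range(stack.bands.shape[2]):
        d = float(ref[..., b].min())
        l = float(ref[..., b].max())
        if l <= d:
            raise DegenerateReferenceError(
                f"band {stack.band_nm[b]} nm: gray reference has no range (min==max=={d})"
            )
        out[..., b] = np.clip((stack.bands[..., b] - d) / (l - d), 0.0, 1.0)
    return replace(stack, bands=out, balanced=True)


# --- alignment -------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two equal-shape windows."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        return np.nan
    return float((a * b).sum() / denom)


def _translate(img: np.ndarray, dy: int, dx: int) -> tuple[np.ndarray, np.ndarray]:
    """Shift content by (dy, dx), zero-filling; returns (shifted, validity)."""
    H, W = img.shape
    out = np.zeros_like(img)
    valid = np.zeros((H, W), dtype=bool)
    ys = slice(max(dy, 0), H + min(dy, 0))
    xs = slice(max(dx, 0), W + min(dx, 0))
    ys_src = slice(max(-dy, 0), H + min(-dy, 0))
    xs_src = slice(max(-dx, 0), W + min(-dx, 0))
    out[ys, xs] = img[ys_src, xs_src]
    valid[ys, xs] = True
    return out, valid


def _best_shift(band: np.ndarray, ref: np.ndarray, max_shift: int) -> tuple[int, int] | None:
    """Displacement (dy, dx) of ``band`` relative to ``ref`` maximizing NCC.

    Exhaustive search over the (2*max_shift+1)^2 window; ties break toward
    the smaller displacement. Returns None when correlation is undefined
    (constant band).
    """
    if band.std() == 0.0 or ref.std() == 0.0:
        return None
    H, W = ref.shape
    best, best_key = None, None
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            # band[y, x] is compared against ref[y - dy, x - dx]
            ys_b = slice(max(dy, 0), H + min(dy, 0))
            xs_b = slice(max(dx, 0), W + min(dx, 0))
            ys_r = slice(max(-dy, 0), H + min(-dy, 0))
            xs_r = slice(max(-dx, 0), W + min(-dx, 0))
            score = _ncc(band[ys_b, xs_b], ref[ys_r, xs_r])
            if np.isnan(score):
                continue
            key = (-score, abs(dy) + abs(dx), dy, dx)
            if best_key is None or key < best_key:
                best_key, best = key, (dy, dx)
    return best


def align_bands(stack: MultispectralStack, max_shift: int = 10) -> MultispectralStack:
    """Register every band to a mid-spectrum reference by integer translation.

    The reference is the band nearest 520 nm (reflectance is typically
    strong there, giving good correlation contrast). For each other band the
    integer displacement within +/-max_shift that maximizes normalized
    cross-correlation is detected and undone; pixels translated in from
    outside the frame are zero-filled and dropped from ``valid``. Pixel
    values are never changed, only positions.
    """
    if not stack.balanced:
        raise ValueError("align_bands expects a white-balanced stack")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    ref_idx = stack.band_index(520.0)
    ref = stack.bands[..., ref_idx]
    H, W, B = stack.bands.shape
    out = np.empty_like(stack.bands)
    valid = np.ones((H, W), dtype=bool)
    shifts: list[tuple[int, int]] = []
    for b in range(B):
        if b == ref_idx:
            out[..., b] = stack.bands[..., b]
            shifts.append((0, 0))
            continue
        found = _best_shift(stack.bands[..., b], ref, max_shift)
        if found is None:
            warnings.warn(
                f"band {stack.band_nm[b]} nm is constant; alignment skipped",
                RuntimeWarning,
            )
            found = (0, 0)
        dy, dx = found
        if abs(dy) == max_shift or abs(dx) == max_shift:
            warnings.warn(
                f"band {stack.band_nm[b]} nm: best shift ({dy}, {dx}) touches the "
                f"+/-{max_shift} px search window; residual misalignment possible",
                RuntimeWarning,
            )
        shifted, v = _translate(stack.bands[..., b], -dy, -dx)
        out[..., b] = shifted
        valid &= v
        shifts.append((dy, dx))
    return replace(stack, bands=out, aligned=True, valid=valid, shifts=tuple(shifts))


# --- sampling --------------------------------------------------------------

def sample_region(
    stack: MultispectralStack, mask: RegionMask, n: int = 1000, seed: int = 0
) -> PixelSample:
    """Draw ``n`` uniform random pixels from a region, reproducibly.

    Sampling is without replacement when the mask holds at least ``n``
    pixels, with replacement otherwise (logged via a warning). The default
    n = 1000 is the sample size used for all region statistics.
    """
    if not stack.balanced:
        raise ValueError("sample_region expects a white-balanced stack")
    if not stack.aligned:
        raise ValueError("sample_region expects an aligned stack")
    if mask.mask.shape != stack.bands.shape[:2]:
        raise ValueError("mask shape does not match stack")
    available = mask.mask
    if stack.valid is not None:
        available = available & stack.valid
    rows, cols = np.nonzero(available)
    if rows.size == 0:
        raise ValueError("region mask has no valid pixels")
    rng = np.random.default_rng(seed)
    with_replacement = rows.size < n
    if with_replacement:
        warnings.warn(
            f"mask has {rows.size} pixels < n={n}; sampling with replacement",
            RuntimeWarning,
        )
    idx = rng.choice(rows.size, size=n, replace=with_replacement)
    coords = np.stack([rows[idx], cols[idx]], axis=1)
    values = stack.bands[coords[:, 0], coords[:, 1], :]
    return PixelSample(
        coords=coords,
        values=values,
        band_nm=stack.band_nm,
        seed=seed,
        region_class=mask.region_class,
        species_id=mask.species_id,
        with_replacement=with_replacement,
    )


# --- rendering -------------------------------------------------------------

#: Target wavelengths (nm) per false-color channel, by mode.
FALSE_COLOR_BANDS = {
    "human": {"R": 640.0, "G": 520.0, "B": 460.0},
    "bee": {"R": 580.0, "G": 460.0, "B": 340.0},
}
_BAND_TOLERANCE_NM = 30.0


def false_color(stack: MultispectralStack, mode: str = "bee") -> np.ndarray:
    """8-bit RGB rendering; bee mode shifts UV->blue, blue->green, yellow->red."""
    if mode not in FALSE_COLOR_BANDS:
        raise ValueError(f"mode must be one of {tuple(FALSE_COLOR_BANDS)}")
    channels = []
    for ch, target in FALSE_COLOR_BANDS[mode].items():
        idx = stack.band_index(target)
        if abs(stack.band_nm[idx] - target) > _BAND_TOLERANCE_NM:
            raise ValueError(f"no band near {target:.0f} nm for {mode} {ch} channel")
        channels.append(stack.bands[..., idx])
    rgb = np.stack(channels, axis=-1)
    return np.clip(np.floor(rgb * 255.0 + 0.5), 0, 255).astype(np.uint8)


def heat_map(maps, receptor: str) -> np.ndarray:
    """Render one receptor's E map to 8 bits: E in [0,1] -> [0,255], round-half-up."""
    if receptor not in maps.names:
        raise KeyError(f"unknown receptor {receptor!r}; have {maps.names}")
    E = maps[receptor]
    return np.clip(np.floor(E * 255.0 + 0.5), 0, 255).astype(np.uint8)


def downsample_ommatidia(image: np.ndarray, n_facets: int = 5000) -> np.ndarray:
    """Blocky downsampling to roughly one value per ommatidium.

    The image is partitioned into an aspect-preserving grid of about
    ``n_facets`` rectangular blocks; each block is replaced by its mean.
    Output keeps the input's H x W. Motivated by the compound eye's ~5000
    facets per eye: spatial detail below the facet grid is not resolved.
    """
    image = np.asarray(image, dtype=float)
    if n_facets < 1:
        raise ValueError("n_facets must be >= 1")
    H, W = image.shape[:2]
    if n_facets >= H * W:
        if n_facets > H * W:
            warnings.warn("n_facets exceeds pixel count; returning image unchanged", RuntimeWarning)
        return image.copy()
    n_rows = int(np.clip(round(np.sqrt(n_facets * H / W)), 1, H))
    n_cols = int(np.clip(round(n_facets / n_rows), 1, W))
    row_edges = np.linspace(0, H, n_rows + 1).astype(int)
    col_edges = np.linspace(0, W, n_cols + 1).astype(int)
    out = np.empty_like(image)
    for i in range(n_rows):
        for j in range(n_cols):
            block = image[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            out[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = block.mean(
                axis=(0, 1), keepdims=True
            )
    return out
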