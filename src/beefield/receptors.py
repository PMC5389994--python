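"""Photoreceptor model: quantum catch, von Kries adaptation, normalized response.

The chain for each receptor is

    P = R * sum_lambda I_s(l) S(l) D(l)        (quantum catch)
    R = 1 / sum_lambda I_B(l) S(l) D(l)        (von Kries sensitivity factor)
    E = P / (P + 1)                            (Naka-Rushton-type response)

where I_s is the stimulus reflectance, I_B the background the receptor is
adapted to, S the receptor sensitivity and D the illuminant, all on one
wavelength grid. The sensitivity factor makes the adaptation background yield
P = 1 and hence the half-maximal response E = 0.5; because R carries 1/D, a
rescaled illuminant cancels out of E entirely (von Kries invariance). The sums
are plain discrete sums: the grid-spacing factor cancels between P and R.

E is dimensionless in [0, 1): 0 for a black stimulus, approaching 1 only in
the limit of infinite quantum catch. The saturating form gives near-log
coding, so ratios of quantum catches map to differences of responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .spectra import ReceptorSet, Spectrum, WavelengthGrid, d65_illuminant, green_leaf_background

if TYPE_CHECKING:  # pragma: no cover
    from .imaging import MultispectralStack

__all__ = [
    "AdaptationState",
    "ResponseMaps",
    "DegenerateAdaptationError",
    "quantum_catch",
    "sensitivity_factor",
    "response",
    "respond_stack",
    "save_response_maps",
    "load_response_maps",
]


class DegenerateAdaptationError(ValueError):
    """Background, sensitivity and illuminant have no spectral overlap."""


def _check_same_grid(*spectra: Spectrum) -> WavelengthGrid:
    grids = {s.grid for s in spectra}
    if len(grids) != 1:
        raise ValueError("all spectra must share one wavelength grid")
    return next(iter(grids))


def sensitivity_factor(background: Spectrum, sensitivity: Spectrum, illuminant: Spectrum) -> float:
    """Von Kries adaptation scalar R = 1 / sum(I_B * S * D).

    Poorly stimulated receptors end up with large R (high gain), strongly
    stimulated ones with small R. A zero overlap between background,
    sensitivity and illuminant leaves the receptor without a usable
    adaptation level and raises :class:`DegenerateAdaptationError`.
    """
    _check_same_grid(background, sensitivity, illuminant)
    denom = float(np.sum(background.values * sensitivity.values * illuminant.values))
    if denom <= 0.0:
        raise DegenerateAdaptationError(
            "background x sensitivity x illuminant sums to zero; "
            "the receptor cannot adapt to this background"
        )
    return 1.0 / denom


def quantum_catch(
    stimulus: Spectrum, sensitivity: Spectrum, illuminant: Spectrum, R: float
) -> float:
    """Relative photon absorption P = R * sum(I_s * S * D), >= 0."""
    _check_same_grid(stimulus, sensitivity, illuminant)
    if R <= 0:
        raise ValueError("sensitivity factor R must be > 0")
    return R * float(np.sum(stimulus.values * sensitivity.values * illuminant.values))


def response(P):
    """Normalized receptor response E = P/(P+1); half-maximal at P = 1.

    Accepts scalars or arrays; negative quantum catches are a caller bug.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("quantum catch must be >= 0")
    E = P / (P + 1.0)
    return float(E) if E.ndim == 0 else E


@dataclass(frozen=True)
class AdaptationState:
    """The background/illuminant pair a receptor set is adapted to.

    ``R`` holds the per-receptor von Kries factor; by construction the
    background stimulus produces P = 1 (E = 0.5) in every receptor.
    """

    background: Spectrum
    illuminant: Spectrum
    receptors: ReceptorSet
    R: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # keep the background catch itself and compute it with the same
        # matrix product used for stimuli: dividing identical-arithmetic
        # sums makes the background's P == 1 (and E == 0.5) exact
        weights, catch = {}, {}
        for name, sens in self.receptors:
            sensitivity_factor(self.background, sens, self.illuminant)  # validates overlap
            w = sens.values * self.illuminant.values
            weights[name] = w
            catch[name] = float(np.sum(self.background.values * w))
        object.__setattr__(self, "_weights", weights)
        object.__setattr__(self, "_background_catch", catch)
        if not self.R:
            object.__setattr__(self, "R", {n: 1.0 / c for n, c in catch.items()})
        for name, r in self.R.items():
            if not (np.isfinite(r) and r > 0):
                raise ValueError(f"sensitivity factor for {name!r} must be finite and > 0")

    @classmethod
    def default(cls, receptors: ReceptorSet | None = None,
                background: Spectrum | None = None,
                illuminant: Spectrum | None = None) -> "AdaptationState":
        """D65 illumination, green-leaf background, template S/M/L receptors."""
        from .spectra import default_receptor_set

        receptors = receptors or default_receptor_set()
        grid = receptors.grid
        return cls(
            background=background or green_leaf_background(grid),
            illuminant=illuminant or d65_illuminant(grid),
            receptors=receptors,
        )

    def respond(self, stimulus: Spectrum) -> dict[str, float]:
        """E per receptor for one stimulus spectrum."""
        _check_same_grid(stimulus, self.background)
        out = {}
        for name in self.receptors.names:
            num = float(np.sum(stimulus.values * self._weights[name]))
            P = num / self._background_catch[name]
            out[name] = response(P)
        return out

    def respond_pixels(self, pixels: np.ndarray) -> dict[str, np.ndarray]:
        """Vectorized E for an (n, B) array of per-pixel reflectance vectors."""
        pixels = np.asarray(pixels, dtype=float)
        if pixels.shape[-1] != len(self.receptors.grid):
            raise ValueError("pixel band count does not match receptor grid")
        out = {}
        for name in self.receptors.names:
            w = self._weights[name]
            # accumulate band by band in fixed order: identical arithmetic
            # to the scalar sum, so background pixels hit P == 1 exactly
            num = np.zeros(pixels.shape[:-1])
            for b in range(pixels.shape[-1]):
                num += pixels[..., b] * w[b]
            out[name] = response(num / self._background_catch[name])
        return out


@dataclass(frozen=True)
class ResponseMaps:
    """Per-receptor H x W maps of E values for one stack."""

    maps: Mapping[str, np.ndarray]
    source_id: str = ""
    adaptation_id: str = ""

    def __post_init__(self) -> None:
        maps = {k: np.asarray(v, dtype=float) for k, v in self.maps.items()}
        shapes = {m.shape for m in maps.values()}
        if len(shapes) != 1:
            raise ValueError("all response maps must share one shape")
        for name, m in maps.items():
            if np.any(m < 0) or np.any(m >= 1.0):
                raise ValueError(f"map {name!r} has E outside [0, 1)")
        object.__setattr__(self, "maps", maps)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.maps)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def respond_stack(
    stack: "MultispectralStack", receptors: ReceptorSet, adaptation: AdaptationState
) -> ResponseMaps:
    """Apply the receptor chain to every pixel of a white-balanced stack.

    Each pixel's vector of band reflectances is treated as a stimulus
    spectrum on the receptor grid. White balance is a hard precondition:
    raw scans are in arbitrary per-band units and would silently corrupt
    the quantum catches.
    """
    if not stack.balanced:
        raise ValueError("stack must be white-balanced before computing responses")
    if tuple(stack.band_nm) != receptors.grid.wavelengths:
        raise ValueError(
            f"stack bands {tuple(stack.band_nm)} do not match receptor grid "
            f"{receptors.grid.wavelengths}"
        )
    H, W, B = stack.bands.shape
    flat = stack.bands.reshape(-1, B)
    responses = adaptation.respond_pixels(flat)
    maps = {name: E.reshape(H, W) for name, E in responses.items()}
    return ResponseMaps(maps, source_id=stack.stack_id, adaptation_id="")


# --- serialization ---------------------------------------------------------

def save_response_maps(maps: ResponseMaps, directory: str | Path, prefix: str = "response") -> None:
    """One 16-bit grayscale PNG per receptor (E scaled by 65535) + JSON sidecar."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, m in maps.maps.items():
        img = np.clip(np.round(m * 65535.0), 0, 65535).astype(np.uint16)
        iio.imwrite(directory / f"{prefix}_{name}.png", img)
    sidecar = {
        "receptors": list(maps.names),
        "source_id": maps.source_id,
        "adaptation_id": maps.adaptation_id,
        "scale": 65535,
    }
    (directory / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def load_response_maps(directory: str | Path, prefix: str = "response") -> ResponseMaps:
    import imageio.v3 as iio

    directory = Path(directory)
    sidecar = json.loads((directory / f"{prefix}.json").read_text())
    maps = {}
    for name in sidecar["receptors"]:
        img = iio.imread(directory / f"{prefix}_{name}.png")
        maps[name] = np.minimum(img.astype(float) / sidecar["scale"], 1.0 - 1e-9)
    return ResponseMaps(maps, sidecar.get("source_id", ""), sidecar.get("adaptation_id", ""))
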