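"""Spectra on a shared wavelength grid.

Everything downstream — quantum catches, adapted responses, the null-model
sweeps — operates on discrete spectra sampled at a common set of wavelengths.
The default grid is the seven band-pass filter peaks of the imaging setup
(340–700 nm in 60-nm steps), which is also the resolution at which receptor
sensitivities and the illuminant are used: all integrals reduce to plain sums
over this grid.

A :class:`Spectrum` plays one of four roles (reflectance, illuminant,
sensitivity, background); :class:`ReceptorSet` bundles named sensitivity
spectra with their peak wavelengths and relative total-sensitivity weights.
Receptor sensitivities can be loaded from CSV or generated from an A1
visual-pigment template (alpha band after Govardovskii et al. 2000, plus an
optional UV beta band).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DEFAULT_BANDS_NM",
    "WavelengthGrid",
    "Spectrum",
    "ReceptorSet",
    "resample",
    "template_sensitivity",
    "default_beta_fraction",
    "normalize_total",
    "flat_spectrum",
    "d65_illuminant",
    "green_leaf_background",
    "default_receptor_set",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_receptor_csv",
]

#: Peak transmission wavelengths (nm) of the seven band-pass filters.
DEFAULT_BANDS_NM: tuple[float, ...] = (340.0, 400.0, 460.0, 520.0, 580.0, 640.0, 700.0)

_ROLES = frozenset({"reflectance", "illuminant", "sensitivity", "background"})


class SpectrumRangeError(ValueError):
    """Requested wavelengths fall outside the source spectrum's grid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths (nm) within the 300–700 nm bee range."""

    wavelengths: tuple[float, ...] = DEFAULT_BANDS_NM

    def __post_init__(self) -> None:
        wl = tuple(float(w) for w in self.wavelengths)
        object.__setattr__(self, "wavelengths", wl)
        if len(wl) < 2:
            raise ValueError("a wavelength grid needs at least 2 points")
        arr = np.asarray(wl)
        if not np.all(np.diff(arr) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if arr[0] < 300.0 or arr[-1] > 700.0:
            raise ValueError("wavelengths must lie within [300, 700] nm")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.wavelengths, dtype=float)

    def __len__(self) -> int:
        return len(self.wavelengths)

    def nearest_index(self, nm: float) -> int:
        """Index of the grid point closest to ``nm`` (ties -> shorter wavelength)."""
        return int(np.argmin(np.abs(self.array - nm)))


@dataclass(frozen=True)
class Spectrum:
    """Nonnegative intensities on a :class:`WavelengthGrid`.

    ``role`` tags what the values mean physically; reflectance-role values are
    expected to lie in [0, 1] after white balance but this is not enforced
    here (raw scans legitimately exceed it before correction).
    """

    grid: WavelengthGrid
    values: np.ndarray
    role: str = "reflectance"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.grid),):
            raise ValueError(
                f"values shape {vals.shape} does not match grid length {len(self.grid)}"
            )
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite and >= 0")
        if self.role not in _ROLES:
            raise ValueError(f"unknown spectrum role {self.role!r}")

    def with_values(self, values: np.ndarray) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float))

    def total(self) -> float:
        """Plain discrete sum over the grid (the integral used throughout)."""
        return float(self.values.sum())

    def scaled(self, c: float) -> "Spectrum":
        if c < 0:
            raise ValueError("scale factor must be >= 0")
        return self.with_values(self.values * c)


@dataclass(frozen=True)
class ReceptorSet:
    """Ordered, named sensitivity spectra with peaks and total weights.

    ``total_weight`` records the intended relative summed sensitivity of each
    receptor; :func:`normalize_total` makes the actual sums honour it.
    """

    receptors: Mapping[str, Spectrum]
    peak_nm: Mapping[str, float]
    total_weight: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        recs = dict(self.receptors)
        peaks = dict(self.peak_nm)
        weights = dict(self.total_weight) or {name: 1.0 for name in recs}
        if set(recs) != set(peaks) or set(recs) != set(weights):
            raise ValueError("receptors, peak_nm and total_weight must share names")
        grids = {r.grid for r in recs.values()}
        if len(grids) != 1:
            raise ValueError("all receptor sensitivities must share one grid")
        for name, spec in recs.items():
            if spec.role != "sensitivity":
                raise ValueError(f"receptor {name!r} spectrum is not sensitivity-role")
        object.__setattr__(self, "receptors", recs)
        object.__setattr__(self, "peak_nm", peaks)
        object.__setattr__(self, "total_weight", weights)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.receptors)

    @property
    def grid(self) -> WavelengthGrid:
        return next(iter(self.receptors.values())).grid

    def __iter__(self):
        return iter(self.receptors.items())


def flat_spectrum(grid: WavelengthGrid, value: float, role: str = "reflectance") -> Spectrum:
    """Constant spectrum; the 'unit' reflectance/illuminant of the null model."""
    if value < 0:
        raise ValueError("flat spectrum value must be >= 0")
    return Spectrum(grid, np.full(len(grid), float(value)), role=role)


def resample(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``; extrapolation is refused.

    Exact (machine precision) when every target wavelength is a source grid
    point. Linear interpolation is deliberate: the analysis grid has only
    seven points, and higher-order schemes would add structure the data
    cannot support.
    """
    src = spectrum.grid.array
    tgt = target.array
    if tgt[0] < src[0] or tgt[-1] > src[-1]:
        raise SpectrumRangeError(
            f"target range [{tgt[0]}, {tgt[-1]}] nm outside source "
            f"range [{src[0]}, {src[-1]}] nm"
        )
    vals = np.interp(tgt, src, spectrum.values)
    return Spectrum(target, vals, role=spectrum.role)


# --- A1 visual-pigment template -------------------------------------------

# Govardovskii et al. (2000) alpha-band coefficients for A1 pigments.
_GOV_A, _GOV_B, _GOV_C, _GOV_D = 69.7, 28.0, -14.9, 0.674
_GOV_b, _GOV_c = 0.922, 1.104


def _alpha_band(wavelengths: np.ndarray, peak_nm: float) -> np.ndarray:
    a = 0.8795 + 0.0459 * np.exp(-((peak_nm - 300.0) ** 2) / 11940.0)
    x = peak_nm / wavelengths
    return 1.0 / (
        np.exp(_GOV_A * (a - x))
        + np.exp(_GOV_B * (_GOV_b - x))
        + np.exp(_GOV_C * (_GOV_c - x))
        + _GOV_D
    )


#: Center and width (nm) of the Gaussian UV beta band.
BETA_CENTER_NM = 340.0
BETA_SIGMA_NM = 25.0


def default_beta_fraction(peak_nm: float) -> float:
    """Beta-band amplitude used when sweeping template peaks.

    Linear in the alpha peak through the default anchors (0 at 344 nm,
    0.25 at 544 nm), floored at 0: the UV secondary peak grows as the main
    peak shifts toward longer wavelengths.
    """
    return max(0.0, 0.25 * (peak_nm - 344.0) / 200.0)


def template_sensitivity(
    peak_nm: float, grid: WavelengthGrid, beta_fraction: float = 0.0
) -> Spectrum:
    """A1 pigment template on ``grid``: alpha band (peak value 1) + UV beta band.

    The alpha band follows the Govardovskii A1 template, so its full width at
    half maximum grows with ``peak_nm``; the beta band is a Gaussian centered
    at 340 nm with amplitude ``beta_fraction`` relative to the alpha peak.
    """
    if not 300.0 <= peak_nm <= 700.0:
        raise ValueError(f"template peak {peak_nm} nm outside [300, 700]")
    if beta_fraction < 0:
        raise ValueError("beta_fraction must be >= 0")
    wl = grid.array
    alpha = _alpha_band(wl, peak_nm)
    alpha = alpha / _alpha_band(np.array([peak_nm]), peak_nm)[0]
    beta = beta_fraction * np.exp(-((wl - BETA_CENTER_NM) ** 2) / (2.0 * BETA_SIGMA_NM**2))
    return Spectrum(grid, alpha + beta, role="sensitivity")


def normalize_total(receptors: ReceptorSet, weights: Mapping[str, float] | None = None) -> ReceptorSet:
    """Rescale each sensitivity so its sum over the grid equals its weight.

    Shapes (ratios within one receptor) are preserved exactly; applying the
    operation twice with the same weights is a no-op. Holding summed
    sensitivities in fixed ratio across receptors is what makes receptor
    responses comparable when sensitivity shapes differ.
    """
    weights = dict(weights) if weights is not None else dict(receptors.total_weight)
    if set(weights) != set(receptors.names):
        raise ValueError("weights must name every receptor exactly once")
    if any(w <= 0 for w in weights.values()):
        raise ValueError("weights must be > 0")
    scaled: dict[str, Spectrum] = {}
    for name, spec in receptors:
        s = spec.total()
        if s == 0.0:
            raise ValueError(f"receptor {name!r} has zero total sensitivity")
        scaled[name] = spec.with_values(spec.values * (weights[name] / s))
    return ReceptorSet(scaled, dict(receptors.peak_nm), weights)


# --- packaged constants ----------------------------------------------------

# CIE standard illuminant D65, relative spectral power, 300-700 nm at 10 nm.
_D65_NM = np.arange(300, 701, 10, dtype=float)
_D65_SPD = np.array([
    0.0341, 3.2945, 20.236, 37.0535, 39.9488, 44.9117, 46.6383, 52.0891,
    49.9755, 54.6482, 82.7549, 91.486, 93.4318, 86.6823, 104.865, 117.008,
    117.812, 114.861, 115.923, 108.811, 109.354, 107.802, 104.790, 107.689,
    104.405, 104.046, 100.0, 96.3342, 95.788, 88.6856, 90.0062, 89.5991,
    87.6987, 83.2886, 83.6992, 80.0268, 80.2146, 82.2778, 78.2842, 69.7213,
    71.6091,
])

# Synthetic 'typical green leaf' reflectance on the 7-band grid: dark in the
# UV/blue, monotonically brighter toward long wavelengths. Used as the
# adaptation background when no leaf regions are available.
_GREEN_LEAF = np.array([0.06, 0.08, 0.12, 0.20, 0.28, 0.36, 0.45])


def d65_illuminant(grid: WavelengthGrid | None = None) -> Spectrum:
    """CIE D65 daylight, resampled onto ``grid`` (default: the 7-band grid)."""
    grid = grid or WavelengthGrid()
    fine = Spectrum(
        WavelengthGrid(tuple(_D65_NM)), _D65_SPD, role="illuminant"
    )
    return resample(fine, grid)


def green_leaf_background(grid: WavelengthGrid | None = None) -> Spectrum:
    """Packaged synthetic green-leaf reflectance (adaptation background fallback)."""
    grid = grid or WavelengthGrid()
    base = Spectrum(WavelengthGrid(DEFAULT_BANDS_NM), _GREEN_LEAF, role="background")
    if grid.wavelengths == DEFAULT_BANDS_NM:
        return base
    return replace(resample(base, grid), role="background")


#: Default peak wavelengths of the honeybee S/M/L receptors.
DEFAULT_PEAKS_NM: dict[str, float] = {"S": 344.0, "M": 436.0, "L": 544.0}
#: Default UV beta-band amplitudes per receptor.
DEFAULT_BETA_FRACTIONS: dict[str, float] = {"S": 0.0, "M": 0.1, "L": 0.25}


def default_receptor_set(
    grid: WavelengthGrid | None = None,
    peaks: Mapping[str, float] | None = None,
    beta_fractions: Mapping[str, float] | None = None,
    weights: Mapping[str, float] | None = None,
) -> ReceptorSet:
    """Template-based honeybee S/M/L receptor set, totals normalized.

    Peaks default to 344/436/544 nm; summed sensitivities default to equal
    (1:1:1) since the true relative totals are not published.
    """
    grid = grid or WavelengthGrid()
    peaks = dict(peaks or DEFAULT_PEAKS_NM)
    betas = dict(beta_fractions or DEFAULT_BETA_FRACTIONS)
    weights = dict(weights or {name: 1.0 for name in peaks})
    recs = {
        name: template_sensitivity(peaks[name], grid, betas.get(name, 0.0))
        for name in peaks
    }
    return normalize_total(ReceptorSet(recs, peaks, weights), weights)


# --- CSV interfaces --------------------------------------------------------

def read_spectrum_csv(path: str | Path, role: str = "reflectance") -> Spectrum:
    """Read one spectrum from a two-column ``wavelength_nm,value`` CSV."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "wavelength_nm" not in reader.fieldnames:
            raise ValueError(f"{path.name}: header must include 'wavelength_nm'")
        value_col = next(c for c in reader.fieldnames if c != "wavelength_nm")
        rows = [(float(r["wavelength_nm"]), float(r[value_col])) for r in reader]
    rows.sort()
    grid = WavelengthGrid(tuple(w for w, _ in rows))
    return Spectrum(grid, np.array([v for _, v in rows]), role=role)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path, value_col: str = "value") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", value_col])
        for w, v in zip(spectrum.grid.wavelengths, spectrum.values):
            writer.writerow([w, repr(float(v))])


def read_receptor_csv(
    path: str | Path,
    peaks: Mapping[str, float] | None = None,
    weights: Mapping[str, float] | None = None,
) -> ReceptorSet:
    """Read a receptor set from a ``wavelength_nm,S,M,L,...`` CSV.

    Peak wavelengths default to each column's argmax; weights default to the
    observed sums (i.e., the file is taken at face value).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "wavelength_nm" not in reader.fieldnames:
            raise ValueError(f"{path.name}: header must include 'wavelength_nm'")
        names = [c for c in reader.fieldnames if c != "wavelength_nm"]
        rows = sorted(
            (float(r["wavelength_nm"]), [float(r[n]) for n in names]) for r in reader
        )
    grid = WavelengthGrid(tuple(w for w, _ in rows))
    cols = np.array([vals for _, vals in rows])  # (n_wl, n_receptors)
    recs = {
        name: Spectrum(grid, cols[:, i], role="sensitivity")
        for i, name in enumerate(names)
    }
    peaks = dict(peaks) if peaks else {
        name: grid.wavelengths[int(np.argmax(cols[:, i]))] for i, name in enumerate(names)
    }
    weights = dict(weights) if weights else {name: recs[name].total() for name in names}
    return ReceptorSet(recs, peaks, weights)
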