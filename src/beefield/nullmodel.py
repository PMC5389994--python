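"""Factor-decomposition sweep: why does the long-wavelength channel win?

The receptor-response statistics that favor the L channel could come from
the eye (sensitivity shapes, adaptation) or from the flowers (reflectance
increasing with wavelength) or from the response nonlinearity. To separate
these, a *null model* replaces every component with its unit version —
flat background reflectance, flat illumination, and a one-hot 'sensitivity'
that samples a single band — and is run on random reflectance spectra. Each
factor (D65 illumination, average-leaf background, template-shaped
sensitivities, realistic petal reflectances) is then switched on in all
combinations, and for each combination the quantum catch P and response E
are swept across the seven possible peak wavelengths.

Expected structure: the null model on random spectra is flat across peaks;
on petal-like spectra its mean P rises with peak wavelength (flowers reflect
more long-wavelength light); the full bee model's E spread across peaks is
compressed relative to its P spread (the saturating P -> E transform brings
the means together).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .receptors import DegenerateAdaptationError, response
from .spectra import (
    Spectrum,
    WavelengthGrid,
    d65_illuminant,
    default_beta_fraction,
    flat_spectrum,
    green_leaf_background,
    template_sensitivity,
)

__all__ = [
    "FactorConfig",
    "SweepResult",
    "random_spectra",
    "run_sweep",
    "factor_table",
    "plot_factor_table",
]

_ILLUMINATIONS = ("unit", "D65")
_BACKGROUNDS = ("unit", "average_leaf")
_SENSITIVITIES = ("unit", "template")
_SOURCES = ("random", "petals")


@dataclass(frozen=True)
class FactorConfig:
    """One cell of the factor experiment.

    All-unit factors on random spectra is the null model; all realistic
    factors (D65, average leaf, template sensitivities) is the bee model.
    """

    illumination: str = "unit"
    background: str = "unit"
    sensitivity: str = "unit"
    reflectance_source: str = "random"
    n_spectra: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.illumination not in _ILLUMINATIONS:
            raise ValueError(f"illumination must be one of {_ILLUMINATIONS}")
        if self.background not in _BACKGROUNDS:
            raise ValueError(f"background must be one of {_BACKGROUNDS}")
        if self.sensitivity not in _SENSITIVITIES:
            raise ValueError(f"sensitivity must be one of {_SENSITIVITIES}")
        if self.reflectance_source not in _SOURCES:
            raise ValueError(f"reflectance_source must be one of {_SOURCES}")
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")

    @property
    def is_null(self) -> bool:
        return (self.illumination, self.background, self.sensitivity) == ("unit",) * 3

    @property
    def is_bee(self) -> bool:
        return (self.illumination, self.background, self.sensitivity) == (
            "D65", "average_leaf", "template",
        )

    @classmethod
    def null(cls, **kw) -> "FactorConfig":
        return cls(**kw)

    @classmethod
    def bee(cls, **kw) -> "FactorConfig":
        return cls(illumination="D65", background="average_leaf", sensitivity="template", **kw)


@dataclass(frozen=True)
class SweepResult:
    """Per-peak moments of P and E for one factor configuration."""

    config: FactorConfig
    table: pd.DataFrame  # columns: peak_nm, mean_P, sd_P, mean_E, sd_E, n

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)


def random_spectra(n: int, grid: WavelengthGrid | None = None, seed: int = 0,
                   distribution: str = "uniform",
                   beta_params: tuple[float, float] = (2.0, 2.0)) -> list[Spectrum]:
    """n random reflectance spectra, i.i.d. per band, reproducible under seed.

    Default distribution is Uniform(0, 1) per band; Beta(a, b) is available
    as a robustness alternative.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    grid = grid or WavelengthGrid()
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        vals = rng.uniform(0.0, 1.0, size=(n, len(grid)))
    elif distribution == "beta":
        vals = rng.beta(*beta_params, size=(n, len(grid)))
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return [Spectrum(grid, row) for row in vals]


def _values_matrix(spectra, grid: WavelengthGrid) -> np.ndarray:
    if isinstance(spectra, np.ndarray):
        mat = np.asarray(spectra, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != len(grid):
            raise ValueError("spectra array must be (n, n_bands)")
        return mat
    mats = []
    for s in spectra:
        if s.grid != grid:
            raise ValueError("all input spectra must share the sweep grid")
        mats.append(s.values)
    return np.asarray(mats)


def _make_sensitivity(kind: str, peak_index: int, grid: WavelengthGrid) -> np.ndarray:
    if kind == "unit":
        s = np.zeros(len(grid))
        s[peak_index] = 1.0
        return s
    peak_nm = grid.wavelengths[peak_index]
    t = template_sensitivity(peak_nm, grid, default_beta_fraction(peak_nm))
    return t.values / t.values.sum()  # constant total sensitivity across peaks


def run_sweep(config: FactorConfig, spectra, grid: WavelengthGrid | None = None) -> SweepResult:
    """Sweep the receptor peak across the grid for one factor configuration.

    For each of the grid's wavelengths, a sensitivity is built (one-hot for
    'unit', total-normalized pigment template otherwise), the von Kries
    factor is formed from the configured background and illuminant, and P
    and E are computed for every input spectrum. Moments use the population
    SD convention.
    """
    if grid is None:
        grid = spectra[0].grid if not isinstance(spectra, np.ndarray) else WavelengthGrid()
    V = _values_matrix(spectra, grid)
    D = (flat_spectrum(grid, 1.0, role="illuminant") if config.illumination == "unit"
         else d65_illuminant(grid)).values
    I_B = (flat_spectrum(grid, 1.0, role="background") if config.background == "unit"
           else green_leaf_background(grid)).values
    rows = []
    for k, peak_nm in enumerate(grid.wavelengths):
        S = _make_sensitivity(config.sensitivity, k, grid)
        denom = float(np.sum(I_B * S * D))
        if denom <= 0.0:
            raise DegenerateAdaptationError(
                f"zero background/sensitivity/illuminant overlap at peak {peak_nm} nm"
            )
        P = (V @ (S * D)) / denom
        E = response(P)
        rows.append(
            {
                "peak_nm": float(peak_nm),
                "mean_P": float(P.mean()),
                "sd_P": float(P.std()),
                "mean_E": float(E.mean()),
                "sd_E": float(E.std()),
                "n": V.shape[0],
            }
        )
    return SweepResult(config, pd.DataFrame(rows))


def factor_table(
    n: int = 10_000,
    seed: int = 0,
    grid: WavelengthGrid | None = None,
    petal_spectra: Sequence[Spectrum] | None = None,
    n_petals: int = 52,
) -> pd.DataFrame:
    """All 16 factor combinations, long format, deterministic under seed.

    One shared set of random spectra and one shared set of petal spectra
    feed every configuration, so rows differ only through the factors.
    Petal spectra default to synthetic per-species petal reflectances; real
    per-species means can be passed in when available.
    """
    grid = grid or WavelengthGrid()
    randoms = random_spectra(n, grid, seed)
    if petal_spectra is None:
        from .synth import sample_petal_spectra

        petal_spectra = sample_petal_spectra(n_petals, seed + 1)
    frames = []
    for source in _SOURCES:
        spectra = randoms if source == "random" else list(petal_spectra)
        for illum in _ILLUMINATIONS:
            for bg in _BACKGROUNDS:
                for sens in _SENSITIVITIES:
                    config = FactorConfig(
                        illumination=illum,
                        background=bg,
                        sensitivity=sens,
                        reflectance_source=source,
                        n_spectra=len(spectra),
                        seed=seed,
                    )
                    df = run_sweep(config, spectra).table.copy()
                    df.insert(0, "illumination", illum)
                    df.insert(1, "background", bg)
                    df.insert(2, "sensitivity", sens)
                    df.insert(3, "source", source)
                    df["seed"] = seed
                    frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plot_factor_table(table: pd.DataFrame, path) -> None:
    """Render the sweep as a panel grid (one panel per config, P and E curves)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    configs = table.groupby(
        ["source", "illumination", "background", "sensitivity"], sort=True
    )
    n = len(configs)
    ncols = 4
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for ax, (key, grp) in zip(axes.flat, configs):
        grp = grp.sort_values("peak_nm")
        ax.errorbar(grp.peak_nm, grp.mean_P, yerr=grp.sd_P, label="P", marker="o")
        ax.errorbar(grp.peak_nm, grp.mean_E, yerr=grp.sd_E, label="E", marker="s")
        ax.set_title("/".join(key), fontsize=8)
        ax.set_xlabel("peak (nm)")
        ax.legend(fontsize=7)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
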