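"""Per-region receptor-response statistics, SNR, aggregation and channel tests.

For each sampled region (petal, center or leaf of one species) the per-pixel
receptor responses E are summarized by their mean, standard deviation and
signal-to-noise ratio, SNR = mean/SD — a within-object homogeneity measure
(how consistently pixels of one object drive one receptor class), not a
photon-noise quantity. Region statistics are aggregated across species and
the three spectral channels compared with a Kruskal–Wallis test plus pairwise
Wilcoxon signed-rank tests paired by species.

Conventions: SD is the population SD (divide by n). SNR of a zero-variance
region is flagged infinite and excluded from aggregation with a logged count.
No multiple-testing correction is applied by default; Holm adjustment is
available behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .imaging import PixelSample
from .receptors import AdaptationState
from .spectra import ReceptorSet, Spectrum, WavelengthGrid

__all__ = [
    "RegionStats",
    "SummaryTable",
    "region_mean_spectrum",
    "mean_color_response",
    "region_snr",
    "aggregate",
    "compare_channels",
    "stats_to_frame",
]


@dataclass(frozen=True)
class RegionStats:
    """Mean, SD and SNR of per-pixel responses for one region of one species."""

    species_id: str
    region_class: str
    mean_E: Mapping[str, float]
    sd_E: Mapping[str, float]
    snr: Mapping[str, float]        # inf where sd_E == 0
    n: int
    seed: int

    @property
    def receptor_names(self) -> tuple[str, ...]:
        return tuple(self.mean_E)


@dataclass(frozen=True)
class SummaryTable:
    """Across-species mean/SD per region_class x receptor (infinite SNRs dropped)."""

    table: pd.DataFrame              # columns: region_class, receptor, statistic, mean, sd, n_species
    excluded_infinite: int = 0

    def cell(self, region_class: str, receptor: str, statistic: str = "snr") -> tuple[float, float, int]:
        df = self.table
        row = df[
            (df.region_class == region_class)
            & (df.receptor == receptor)
            & (df.statistic == statistic)
        ]
        if row.empty:
            raise KeyError(f"no cell ({region_class}, {receptor}, {statistic})")
        r = row.iloc[0]
        return float(r["mean"]), float(r["sd"]), int(r["n_species"])


def _pop_sd(x: np.ndarray) -> float:
    """Population SD (ddof=0); exactly 0.0 for constant input."""
    x = np.asarray(x)
    if x.size and np.ptp(x) == 0:
        return 0.0
    return float(np.std(x))


def region_mean_spectrum(sample: PixelSample) -> tuple[Spectrum, np.ndarray]:
    """Per-band mean (as a reflectance Spectrum) and population SD of a sample.

    This is the 'average color' of the region — the estimate used both for
    describing region reflectance functions and as input to
    :func:`mean_color_response`.
    """
    if sample.n == 0:
        raise ValueError("empty pixel sample")
    mean = sample.values.mean(axis=0)
    sd = np.where(np.ptp(sample.values, axis=0) == 0, 0.0, sample.values.std(axis=0))
    grid = WavelengthGrid(sample.band_nm)
    return Spectrum(grid, mean, role="reflectance"), sd


def mean_color_response(
    mean_spectrum: Spectrum, receptors: ReceptorSet, adaptation: AdaptationState
) -> dict[str, float]:
    """Receptor responses to a region's average reflectance spectrum.

    Note this is the response *to the mean spectrum*, not the mean of
    per-pixel responses: the saturating response makes the two differ
    (Jensen's inequality) except for zero-variance regions. Both paths are
    exposed deliberately — this one describes the region's color, while
    :func:`region_snr` describes its pixel-level signal statistics.
    """
    if mean_spectrum.grid != receptors.grid:
        raise ValueError("mean spectrum grid does not match receptor grid")
    return adaptation.respond(mean_spectrum)


def region_snr(
    sample: PixelSample, receptors: ReceptorSet, adaptation: AdaptationState
) -> RegionStats:
    """Per-pixel responses -> mean, population SD and SNR = mean/SD per receptor.

    A zero-variance region yields an infinite-flagged SNR rather than an
    exception; aggregation drops and counts such entries.
    """
    if sample.n == 0:
        raise ValueError("empty pixel sample")
    if tuple(sample.band_nm) != receptors.grid.wavelengths:
        raise ValueError("sample bands do not match receptor grid")
    responses = adaptation.respond_pixels(sample.values)
    mean_E, sd_E, snr = {}, {}, {}
    for name, E in responses.items():
        m = float(E.mean())
        s = _pop_sd(E)
        mean_E[name] = m
        sd_E[name] = s
        snr[name] = math.inf if s == 0.0 else m / s
    return RegionStats(
        species_id=sample.species_id,
        region_class=sample.region_class,
        mean_E=mean_E,
        sd_E=sd_E,
        snr=snr,
        n=sample.n,
        seed=sample.seed,
    )


def stats_to_frame(stats: Iterable[RegionStats]) -> pd.DataFrame:
    """Tidy long-format frame: species, region_class, receptor, mean_E, sd_E, snr, n, seed."""
    rows = []
    for st in stats:
        for name in st.receptor_names:
            rows.append(
                {
                    "species": st.species_id,
                    "region_class": st.region_class,
                    "receptor": name,
                    "mean_E": st.mean_E[name],
                    "sd_E": st.sd_E[name],
                    "snr": st.snr[name],
                    "n": st.n,
                    "seed": st.seed,
                    "sd_convention": "population",
                }
            )
    return pd.DataFrame(rows)


def aggregate(stats: Sequence[RegionStats]) -> SummaryTable:
    """Across-species mean and population SD per region_class x receptor.

    Summarizes mean_E and SNR; infinite SNRs (zero-variance regions) are
    excluded from the SNR cells and counted. Order of input is immaterial.
    """
    stats = list(stats)
    if not stats:
        raise ValueError("aggregate needs at least one RegionStats")
    df = stats_to_frame(stats)
    excluded = int(np.isinf(df["snr"]).sum())
    if excluded:
        warnings.warn(
            f"excluding {excluded} infinite SNR entries (zero-variance regions)",
            RuntimeWarning,
        )
    rows = []
    for statistic, col in (("mean_E", "mean_E"), ("snr", "snr")):
        sub = df if statistic != "snr" else df[np.isfinite(df["snr"])]
        for (rc, rec), grp in sub.groupby(["region_class", "receptor"], sort=True):
            vals = grp[col].to_numpy(dtype=float)
            rows.append(
                {
                    "region_class": rc,
                    "receptor": rec,
                    "statistic": statistic,
                    "mean": float(vals.mean()),
                    "sd": _pop_sd(vals),
                    "n_species": len(vals),
                }
            )
    return SummaryTable(pd.DataFrame(rows), excluded_infinite=excluded)


_PAIRS = (("S", "M"), ("S", "L"), ("M", "L"))


def compare_channels(
    stats: Sequence[RegionStats],
    region_class: str,
    holm: bool = False,
    min_species: int = 5,
) -> dict:
    """Kruskal–Wallis across the three receptors' SNRs + pairwise Wilcoxon tests.

    The Wilcoxon signed-rank tests are paired by species. Species with an
    infinite SNR in any channel are dropped from all tests. No multiplicity
    correction is applied unless ``holm=True`` (the correction is reported
    alongside, never in place of, the raw p-values).
    """
    sub = [s for s in stats if s.region_class == region_class]
    names = sub[0].receptor_names if sub else ("S", "M", "L")
    finite = [s for s in sub if all(math.isfinite(s.snr[n]) for n in names)]
    if len(finite) < min_species:
        raise ValueError(
            f"compare_channels needs >= {min_species} species with finite SNRs in "
            f"{region_class!r}; have {len(finite)}"
        )
    samples = {n: np.array([s.snr[n] for s in finite]) for n in names}
    pooled = np.concatenate(list(samples.values()))
    if np.ptp(pooled) == 0:  # all values identical: no evidence of any difference
        H, p_kw = 0.0, 1.0
    else:
        H, p_kw = sps.kruskal(*samples.values())
    report: dict = {
        "region_class": region_class,
        "n_species": len(finite),
        "kruskal": {"H": float(H), "p": float(p_kw)},
        "wilcoxon": {},
        "multiplicity_correction": "holm" if holm else "none",
    }
    pvals = []
    for a, b in _PAIRS:
        if a not in samples or b not in samples:
            continue
        diff = samples[a] - samples[b]
        if np.all(diff == 0):
            W, p = 0.0, 1.0
        else:
            W, p = sps.wilcoxon(samples[a], samples[b])
        report["wilcoxon"][f"{a}_vs_{b}"] = {"W": float(W), "p": float(p)}
        pvals.append((f"{a}_vs_{b}", float(p)))
    if holm and pvals:
        order = sorted(range(len(pvals)), key=lambda i: pvals[i][1])
        m = len(pvals)
        adj, prev = {}, 0.0
        for rank, i in enumerate(order):
            key, p = pvals[i]
            prev = max(prev, min(1.0, (m - rank) * p))
            adj[key] = prev
        for key, p_adj in adj.items():
            report["wilcoxon"][key]["p_holm"] = p_adj
    return report
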