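"""Region statistics: mean spectra, SNR, aggregation, channel comparisons."""

import math

import numpy as np
import pytest

from beefield.imaging import PixelSample
from beefield.stats import (
    RegionStats,
    aggregate,
    compare_channels,
    mean_color_response,
    region_mean_spectrum,
    region_snr,
)

BANDS = (340.0, 400.0, 460.0, 520.0, 580.0, 640.0, 700.0)


def _sample(values: np.ndarray, species="sp", rc="petal", seed=0) -> PixelSample:
    n = values.shape[0]
    coords = np.stack([np.arange(n), np.zeros(n, dtype=int)], axis=1)
    return PixelSample(coords, values, BANDS, seed, region_class=rc, species_id=species)


def _stats(species, rc, snrs, mean=0.5, sd=0.1) -> RegionStats:
    return RegionStats(
        species_id=species,
        region_class=rc,
        mean_E={k: mean for k in snrs},
        sd_E={k: sd for k in snrs},
        snr=dict(snrs),
        n=1000,
        seed=0,
    )


class TestRegionMeanSpectrum:
    def test_constant_region(self):
        spec, sd = region_mean_spectrum(_sample(np.full((50, 7), 0.3)))
        np.testing.assert_allclose(spec.values, 0.3)
        np.testing.assert_array_equal(sd, 0.0)
        assert spec.role == "reflectance"

    def test_two_pixel_population_sd(self):
        vals = np.zeros((2, 7))
        vals[1, 0] = 1.0
        spec, sd = region_mean_spectrum(_sample(vals))
        assert spec.values[0] == pytest.approx(0.5)
        assert sd[0] == pytest.approx(0.5)  # population convention

    def test_matches_brute_force_moments(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, (1000, 7))
        spec, sd = region_mean_spectrum(_sample(vals))
        for b in range(7):
            np.testing.assert_allclose(spec.values[b], sum(vals[:, b]) / 1000)
            np.testing.assert_allclose(sd[b], np.sqrt(((vals[:, b] - vals[:, b].mean()) ** 2).mean()))


class TestMeanColorResponse:
    def test_background_mean_spectrum_gives_half(self, receptors, adaptation):
        E = mean_color_response(adaptation.background, receptors, adaptation)
        assert all(v == 0.5 for v in E.values())

    def test_zero_spectrum_gives_zero(self, receptors, adaptation, grid):
        from beefield.spectra import flat_spectrum

        E = mean_color_response(flat_spectrum(grid, 0.0), receptors, adaptation)
        assert all(v == 0.0 for v in E.values())

    def test_equals_pixel_mean_only_without_variance(self, receptors, adaptation):
        vals = np.full((100, 7), 0.4)
        smp = _sample(vals)
        spec, _ = region_mean_spectrum(smp)
        E_mean = mean_color_response(spec, receptors, adaptation)
        st = region_snr(smp, receptors, adaptation)
        for k in E_mean:
            assert E_mean[k] == pytest.approx(st.mean_E[k], abs=1e-15)


class TestRegionSnr:
    def test_constant_region_flags_infinite(self, receptors, adaptation):
        st = region_snr(_sample(np.full((20, 7), 0.4)), receptors, adaptation)
        assert all(math.isinf(v) for v in st.snr.values())

    def test_matches_independent_scalar_pipeline(self, receptors, adaptation, grid):
        """Oracle: per-pixel scalar quantum_catch/response chain, then moments."""
        from beefield.receptors import quantum_catch, response
        from beefield.spectra import Spectrum

        rng = np.random.default_rng(8)
        vals = np.clip(rng.normal(0.4, 0.05, (300, 7)), 0, 1)
        st = region_snr(_sample(vals), receptors, adaptation)
        for name, sens in receptors:
            E = np.array([
                response(quantum_catch(Spectrum(grid, v), sens, adaptation.illuminant,
                                       adaptation.R[name]))
                for v in vals
            ])
            assert st.mean_E[name] == pytest.approx(E.mean(), rel=1e-12)
            assert st.sd_E[name] == pytest.approx(E.std(), rel=1e-9)
            assert st.snr[name] == pytest.approx(E.mean() / E.std(), rel=1e-9)

    def test_doubling_noise_decreases_every_snr(self, receptors, adaptation, scene_params):
        base = scene_params.mean_curve("petal")
        sd = scene_params.noise_curve("petal")

        def snr_at(noise_factor):
            rng = np.random.default_rng(4)  # same pixel draws, scaled noise
            vals = np.clip(base + rng.normal(size=(1000, 7)) * sd * noise_factor, 0, 1)
            return region_snr(_sample(vals), receptors, adaptation).snr

        low, high = snr_at(1.0), snr_at(2.0)
        assert all(high[k] < low[k] for k in low)


class TestAggregate:
    def test_single_species(self):
        st = _stats("a", "petal", {"S": 3.0, "M": 4.0, "L": 5.0})
        out = aggregate([st])
        mean, sd, n = out.cell("petal", "L", "snr")
        assert (mean, sd, n) == (5.0, 0.0, 1)

    def test_two_species_population_sd(self):
        out = aggregate([
            _stats("a", "leaf", {"L": 4.0}),
            _stats("b", "leaf", {"L": 6.0}),
        ])
        mean, sd, n = out.cell("leaf", "L", "snr")
        assert mean == 5.0 and sd == 1.0 and n == 2

    def test_order_invariant(self):
        stats = [
            _stats(f"s{i}", "petal", {"S": float(i), "L": 2.0 * i + 1}) for i in range(6)
        ]
        a = aggregate(stats).table
        b = aggregate(list(reversed(stats))).table
        import pandas as pd

        pd.testing.assert_frame_equal(a, b)

    def test_infinite_snrs_excluded_and_counted(self):
        stats = [
            _stats("a", "leaf", {"L": 4.0}),
            _stats("b", "leaf", {"L": math.inf}, sd=0.0),
            _stats("c", "leaf", {"L": 6.0}),
        ]
        with pytest.warns(RuntimeWarning, match="infinite"):
            out = aggregate(stats)
        mean, _, n = out.cell("leaf", "L", "snr")
        assert mean == 5.0 and n == 2 and out.excluded_infinite == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])


class TestCompareChannels:
    def _species(self, n, shift_L=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            s = float(abs(rng.normal(8, 3)))
            out.append(_stats(f"sp{i}", "petal", {
                "S": s, "M": s + rng.normal(0, 1), "L": s + shift_L + rng.normal(0, 1),
            }))
        return out

    def test_identical_channels_give_null_result(self):
        stats = [_stats(f"s{i}", "petal", {"S": 5.0, "M": 5.0, "L": 5.0}) for i in range(8)]
        rep = compare_channels(stats, "petal")
        assert rep["kruskal"]["H"] == 0.0 and rep["kruskal"]["p"] == 1.0
        assert all(v["p"] == 1.0 for v in rep["wilcoxon"].values())

    def test_shifted_channel_detected(self):
        rep = compare_channels(self._species(30, shift_L=5.0, seed=1), "petal")
        assert rep["wilcoxon"]["S_vs_L"]["p"] < 0.001

    def test_common_offset_invariance(self):
        stats = self._species(12, shift_L=1.0, seed=2)
        rng = np.random.default_rng(3)
        shifted = []
        for st in stats:
            c = float(rng.normal(0, 5))
            shifted.append(_stats(st.species_id, "petal",
                                  {k: v + c for k, v in st.snr.items()}))
        p0 = compare_channels(stats, "petal")["wilcoxon"]["S_vs_L"]["p"]
        p1 = compare_channels(shifted, "petal")["wilcoxon"]["S_vs_L"]["p"]
        assert p0 == pytest.approx(p1)

    def test_too_few_species_refused(self):
        with pytest.raises(ValueError, match=">= 5"):
            compare_channels(self._species(4), "petal")

    def test_holm_adjustment_reported_alongside(self):
        rep = compare_channels(self._species(10, shift_L=3.0, seed=4), "petal", holm=True)
        for v in rep["wilcoxon"].values():
            assert v["p_holm"] >= v["p"]
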