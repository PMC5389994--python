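"""Stack I/O, gray-reference white balance, NCC alignment, sampling, rendering."""

import numpy as np
import pytest
import yaml

from beefield.imaging import (
    DegenerateReferenceError,
    MultispectralStack,
    RegionMask,
    StackLoadError,
    _translate,
    align_bands,
    downsample_ommatidia,
    false_color,
    heat_map,
    read_masks,
    read_stack,
    sample_region,
    white_balance,
    write_stack,
)
from beefield.receptors import ResponseMaps
from beefield.synth import SceneParams, generate_scene

BANDS = (340.0, 400.0, 460.0, 520.0, 580.0, 640.0, 700.0)


def _simple_stack(values: np.ndarray, gray_ref=(0, 0, 4, 4), **kw) -> MultispectralStack:
    return MultispectralStack(values, BANDS, gray_ref, **kw)


class TestReadWriteStack:
    def test_round_trip_through_manifest(self, tmp_path, scene_params):
        stack, truth = generate_scene(scene_params.clean(), seed=1)
        write_stack(stack, tmp_path, masks=list(truth.masks.values()), bit_depth=16)
        back = read_stack(tmp_path / "manifest.yaml")
        assert back.band_nm == stack.band_nm
        assert back.gray_ref == stack.gray_ref
        np.testing.assert_allclose(back.bands, stack.bands, atol=1.0 / 65535)
        masks = read_masks(tmp_path / "manifest.yaml")
        assert {m.region_class for m in masks} == {"petal", "center", "leaf"}
        for m in masks:
            np.testing.assert_array_equal(m.mask, truth.masks[m.region_class].mask)

    def test_eight_bit_values_map_to_unit_interval(self, tmp_path):
        import imageio.v3 as iio

        for i, nm in enumerate(BANDS):
            iio.imwrite(tmp_path / f"b{i}.png", np.full((5, 5), 128, dtype=np.uint8))
        doc = {
            "bands": [{"file": f"b{i}.png", "nm": nm} for i, nm in enumerate(BANDS)],
            "gray_ref": [0, 0, 5, 5],
        }
        (tmp_path / "m.yaml").write_text(yaml.safe_dump(doc))
        stack = read_stack(tmp_path / "m.yaml")
        np.testing.assert_allclose(stack.bands, 128 / 255)
        assert not stack.balanced and not stack.aligned

    def test_missing_band_file_is_load_error(self, tmp_path):
        doc = {
            "bands": [{"file": "missing.png", "nm": 340.0}, {"file": "also.png", "nm": 400.0}],
            "gray_ref": [0, 0, 2, 2],
        }
        (tmp_path / "m.yaml").write_text(yaml.safe_dump(doc))
        with pytest.raises(StackLoadError, match="missing.png"):
            read_stack(tmp_path / "m.yaml")


class TestWhiteBalance:
    def test_reference_extremes_map_to_zero_and_one(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.2, 0.7, (6, 6, 7))
        vals[0, 0, :] = 0.2
        vals[1, 1, :] = 0.7
        out = white_balance(_simple_stack(vals, gray_ref=(0, 0, 6, 6)))
        assert out.balanced
        np.testing.assert_array_equal(out.bands[0, 0, :], 0.0)
        np.testing.assert_array_equal(out.bands[1, 1, :], 1.0)

    def test_affine_midpoint(self):
        vals = np.full((4, 4, 7), 0.45)
        vals[0, 0, :] = 0.2
        vals[0, 1, :] = 0.7
        out = white_balance(_simple_stack(vals))
        assert out.bands[2, 2, 0] == pytest.approx(0.5)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            white_balance(_simple_stack(np.full((4, 4, 7), 0.3)))

    def test_recovers_generator_truth_under_distortion(self, scene_params):
        """Known per-band gains/offsets are undone exactly (to quantization)."""
        from dataclasses import replace

        params = replace(scene_params.noiseless(), shift_max=0)
        stack, truth = generate_scene(params, seed=9)
        out = white_balance(stack)
        assert np.abs(out.bands - truth.reflectance).max() < 1.0 / 255

    def test_idempotent_once_reference_spans_full_range(self, scene_params):
        stack, _ = generate_scene(scene_params.clean(), seed=4)
        once = white_balance(stack)
        twice = white_balance(once)
        np.testing.assert_allclose(twice.bands, once.bands, atol=1e-12)


class TestAlignBands:
    def test_already_aligned_stack_detects_zero_shifts(self, scene_params):
        stack, _ = generate_scene(scene_params.clean(), seed=2)
        out = align_bands(white_balance(stack), max_shift=3)
        assert out.shifts == tuple((0, 0) for _ in BANDS)
        assert out.aligned

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_recovers_injected_shifts_exactly(self, scene_params, seed):
        stack, truth = generate_scene(scene_params, seed=seed)
        out = align_bands(white_balance(stack), max_shift=scene_params.shift_max + 2)
        assert out.shifts == truth.shifts

    def test_out_of_window_shift_warns_and_clamps(self, scene_params):
        from dataclasses import replace

        stack, _ = generate_scene(scene_params.clean(), seed=6)
        wb = white_balance(stack)
        bands = wb.bands.copy()
        bands[..., 0], _ = _translate(bands[..., 0], 5, 0)
        shifted = replace(wb, bands=bands)
        with pytest.warns(RuntimeWarning, match="search window"):
            out = align_bands(shifted, max_shift=3)
        dy, dx = out.shifts[0]
        assert abs(dy) <= 3 and abs(dx) <= 3

    def test_constant_band_warns_identity(self, scene_params):
        from dataclasses import replace

        stack, _ = generate_scene(scene_params.clean(), seed=7)
        wb = white_balance(stack)
        bands = wb.bands.copy()
        bands[..., 0] = 0.5
        with pytest.warns(RuntimeWarning, match="constant"):
            out = align_bands(replace(wb, bands=bands), max_shift=2)
        assert out.shifts[0] == (0, 0)

    def test_values_only_move_never_change(self, scene_params):
        stack, truth = generate_scene(scene_params, seed=8)
        wb = white_balance(stack)
        out = align_bands(wb, max_shift=scene_params.shift_max + 2)
        for b, (dy, dx) in enumerate(out.shifts):
            back, valid = _translate(out.bands[..., b], dy, dx)
            np.testing.assert_array_equal(back[valid], wb.bands[..., b][valid])

    def test_agrees_with_skimage_template_matching(self, scene_params):
        """Independent oracle: skimage match_template peak gives the same shift."""
        skimage = pytest.importorskip("skimage.feature")
        stack, truth = generate_scene(scene_params, seed=13)
        wb = white_balance(stack)
        out = align_bands(wb, max_shift=scene_params.shift_max + 2)
        ref = wb.bands[..., 3]
        m = 10  # interior template margin
        for b in (0, 5):
            tmpl = wb.bands[m:-m, m:-m, b]
            corr = skimage.match_template(ref, tmpl)
            peak = np.unravel_index(np.argmax(corr), corr.shape)
            dy, dx = m - peak[0], m - peak[1]
            assert (dy, dx) == out.shifts[b]


class TestSampleRegion:
    @pytest.fixture(scope="class")
    def prepared(self, scene_params):
        stack, truth = generate_scene(scene_params.clean(), seed=10)
        return white_balance(stack), truth

    def test_same_seed_reproduces_sample(self, prepared):
        stack, truth = prepared
        a = sample_region(stack, truth.masks["petal"], n=200, seed=17)
        b = sample_region(stack, truth.masks["petal"], n=200, seed=17)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.values, b.values)

    def test_exhaustive_when_mask_size_equals_n(self, prepared):
        stack, truth = prepared
        mask = truth.masks["center"]
        n = mask.n_pixels
        smp = sample_region(stack, mask, n=n, seed=1)
        assert not smp.with_replacement
        assert len({tuple(c) for c in smp.coords}) == n

    def test_small_mask_warns_and_resamples(self, prepared):
        stack, truth = prepared
        with pytest.warns(RuntimeWarning, match="replacement"):
            smp = sample_region(stack, truth.masks["center"], n=10_000, seed=2)
        assert smp.n == 10_000 and smp.with_replacement

    def test_constant_region_sample_is_constant(self, grid):
        bands = np.full((10, 10, 7), 0.3)
        bands[0, :, :] = np.linspace(0, 1, 10)[:, None]  # gray ref variation
        stack = _simple_stack(bands, gray_ref=(0, 0, 10, 1), balanced=True, aligned=True)
        mask = RegionMask(np.r_[np.zeros((1, 10)), np.ones((9, 10))].astype(bool), "petal")
        smp = sample_region(stack, mask, n=50, seed=3)
        assert smp.values.mean() == pytest.approx(0.3)
        assert np.ptp(smp.values) == 0.0


class TestRendering:
    def test_bee_mode_uv_becomes_blue(self):
        bands = np.zeros((4, 4, 7))
        bands[..., 0] = 1.0  # only the 340-nm band
        rgb = false_color(_simple_stack(bands, balanced=True), mode="bee")
        assert np.all(rgb[..., 2] == 255) and np.all(rgb[..., :2] == 0)

    def test_bee_mode_yellow_becomes_red(self):
        bands = np.zeros((4, 4, 7))
        bands[..., 4] = 1.0  # only the 580-nm band
        rgb = false_color(_simple_stack(bands, balanced=True), mode="bee")
        assert np.all(rgb[..., 0] == 255) and np.all(rgb[..., 1:] == 0)

    def test_human_mode_equal_bands_are_gray(self):
        bands = np.full((4, 4, 7), 0.5)
        rgb = false_color(_simple_stack(bands, balanced=True), mode="human")
        assert np.all(rgb == rgb[..., :1])

    def test_missing_band_named_in_error(self):
        stack = MultispectralStack(
            np.zeros((4, 4, 2)), (340.0, 400.0), (0, 0, 4, 4), balanced=True
        )
        with pytest.raises(ValueError, match="580"):
            false_color(stack, mode="bee")

    def test_heat_map_levels_and_monotonicity(self):
        E = np.array([[0.0, 0.5], [0.25, 0.999]])
        maps = ResponseMaps({"L": E})
        img = heat_map(maps, "L")
        assert img[0, 0] == 0 and img[0, 1] == 128 and img[1, 1] == 255
        assert img[0, 1] > img[1, 0] > img[0, 0]
        with pytest.raises(KeyError):
            heat_map(maps, "X")


class TestDownsampleOmmatidia:
    def test_identity_at_full_resolution(self):
        img = np.random.default_rng(0).uniform(size=(12, 16))
        np.testing.assert_array_equal(downsample_ommatidia(img, 12 * 16), img)

    def test_single_facet_is_global_mean(self):
        img = np.random.default_rng(1).uniform(size=(10, 10))
        out = downsample_ommatidia(img, 1)
        np.testing.assert_allclose(out, img.mean())

    def test_block_means_match_brute_force(self):
        """Oracle: direct per-block loop over the same grid boundaries."""
        img = np.random.default_rng(2).uniform(size=(37, 53))
        n_facets = 60
        out = downsample_ommatidia(img, n_facets)
        H, W = img.shape
        n_rows = int(np.clip(round(np.sqrt(n_facets * H / W)), 1, H))
        n_cols = int(np.clip(round(n_facets / n_rows), 1, W))
        re = np.linspace(0, H, n_rows + 1).astype(int)
        ce = np.linspace(0, W, n_cols + 1).astype(int)
        for i in range(n_rows):
            for j in range(n_cols):
                block = img[re[i]:re[i + 1], ce[j]:ce[j + 1]]
                np.testing.assert_allclose(
                    out[re[i]:re[i + 1], ce[j]:ce[j + 1]], block.mean(), atol=1e-12
                )

    def test_excess_facets_warns(self):
        img = np.ones((4, 4))
        with pytest.warns(RuntimeWarning):
            out = downsample_ommatidia(img, 1000)
        np.testing.assert_array_equal(out, img)
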