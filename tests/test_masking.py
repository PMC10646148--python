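"""Masking stage: contrast, filters, component cleanup, mask assembly."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.signal import convolve2d
from skimage import draw as skdraw

from neuromorph import (
    BinaryMask,
    MaskingParams,
    build_neurite_mask,
    build_nuclei_mask,
    enhance_contrast,
    expand_mask,
    gaussian_blur,
    log_filter,
    max_project,
    remove_small_components,
)
from neuromorph.image import CalibrationError

from .conftest import make_image

PX = 0.207


class TestMaxProject:
    def test_single_plane_identity(self, rng):
        img = make_image(rng.integers(0, 255, (8, 8)).astype(np.uint8))
        out = max_project([img])
        assert np.array_equal(out.values, img.values)

    def test_dominant_plane_wins(self, rng):
        a = make_image(rng.integers(0, 200, (8, 8)).astype(np.int64))
        b = a.with_values(a.values + 10)
        out = max_project([a, b])
        assert np.array_equal(out.values, b.values)

    def test_matches_per_pixel_bruteforce(self, rng):
        planes = [make_image(rng.integers(0, 255, (8, 8))) for _ in range(3)]
        out = max_project(planes)
        for r in range(8):
            for c in range(8):
                assert out.values[r, c] == max(p.values[r, c] for p in planes)

    def test_shape_mismatch_raises(self, rng):
        a = make_image(np.zeros((8, 8)))
        b = make_image(np.zeros((8, 9)))
        with pytest.raises(CalibrationError):
            max_project([a, b])


class TestEnhanceContrast:
    def test_full_range_zero_fraction_is_noop(self):
        vals = np.linspace(0, 255, 256).astype(np.uint8).reshape(16, 16)
        out = enhance_contrast(make_image(vals), 0.0)
        assert np.abs(out.values.astype(int) - vals.astype(int)).max() <= 1

    def test_constant_unchanged(self):
        img = make_image(np.full((8, 8), 42, dtype=np.uint8))
        out = enhance_contrast(img, 0.01)
        assert np.array_equal(out.values, img.values)

    def test_clip_bounds_are_order_statistics(self, rng):
        vals = rng.integers(0, 256, 1000).astype(np.uint8).reshape(40, 25)
        frac = 0.01
        out = enhance_contrast(make_image(vals), frac)
        s = np.sort(vals, axis=None)
        k = int(round(1000 * frac / 2))
        lo, hi = float(s[k]), float(s[-1 - k])
        expect = np.clip(
            np.rint((vals.astype(float) - lo) / (hi - lo) * 255), 0, 255
        )
        assert np.array_equal(out.values, expect.astype(np.uint8))

    def test_order_preserving_on_interior(self, rng):
        vals = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        out = enhance_contrast(make_image(vals), 0.02).values.astype(int)
        a, b = (5, 5), (10, 12)
        if vals[a] < vals[b]:
            assert out[a] <= out[b]


class TestGaussianBlur:
    def test_sigma_converted_to_pixels(self):
        # 2 um at 0.207 um/px is ~9.66 px; check via the impulse response width
        n = 129
        vals = np.zeros((n, n))
        vals[n // 2, n // 2] = 1.0
        out = gaussian_blur(make_image(vals, PX), 2.0)
        x = np.arange(n) - n // 2
        marg = out.values.sum(axis=0)
        sigma_px = np.sqrt(np.sum(marg * x**2) / marg.sum())
        assert sigma_px == pytest.approx(2.0 / PX, rel=0.02)

    def test_mean_preserved(self, rng):
        img = make_image(rng.integers(0, 255, (64, 64)).astype(float), PX)
        out = gaussian_blur(img, 2.0)
        assert out.values.mean() == pytest.approx(img.values.mean(), rel=1e-3)

    def test_constant_unchanged(self):
        img = make_image(np.full((32, 32), 7.0), PX)
        out = gaussian_blur(img, 2.0)
        assert np.allclose(out.values, 7.0)

    def test_impulse_normalized_and_symmetric(self):
        n = 129
        vals = np.zeros((n, n))
        vals[n // 2, n // 2] = 1.0
        out = gaussian_blur(make_image(vals, 1.0), 3.0).values
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(out, out.T, atol=1e-12)
        assert np.allclose(out, out[::-1, :], atol=1e-12)


class TestLogFilter:
    def test_constant_zero_response(self):
        out = log_filter(make_image(np.full((32, 32), 9.0), 1.0), 2.0)
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_bright_line_max_on_line(self):
        vals = np.zeros((33, 33))
        vals[16, :] = 100.0
        out = log_filter(make_image(vals, 1.0), 1.5).values
        assert set(np.argwhere(out == out.max())[:, 0]) == {16}

    def test_matches_direct_convolution(self, rng):
        sigma = 1.5
        vals = rng.random((16, 16)) * 100
        out = log_filter(make_image(vals, 1.0), sigma).values
        # sampled LoG kernel truncated at 4 sigma
        r = int(4 * sigma + 0.5)
        y, x = np.mgrid[-r : r + 1, -r : r + 1]
        g = np.exp(-(x**2 + y**2) / (2 * sigma**2))
        g /= g.sum()
        lap = (x**2 + y**2 - 2 * sigma**2) / sigma**4 * g
        expect = -convolve2d(vals, lap, mode="same", boundary="symm")
        core = (slice(r, 16 - r), slice(r, 16 - r))
        assert np.allclose(out[core], expect[core], atol=0.02 * np.abs(expect).max())


class TestRemoveSmallComponents:
    def test_disk_above_cutoff_unchanged(self):
        vals = np.zeros((64, 64), dtype=bool)
        rr, cc = skdraw.disk((32, 32), 25, shape=vals.shape)
        vals[rr, cc] = True
        out = remove_small_components(BinaryMask(vals, PX), 20)
        assert np.array_equal(out.values, vals)

    def test_small_square_removed(self):
        vals = np.zeros((32, 32), dtype=bool)
        vals[10:15, 10:15] = True  # area 25, equivalent radius ~2.82
        out = remove_small_components(BinaryMask(vals, PX), 20)
        assert not out.values.any()

    def test_matches_per_component_area_filter(self, rng):
        vals = rng.random((128, 128)) > 0.7
        min_r = 3
        out = remove_small_components(BinaryMask(vals, PX), min_r)
        labels, n = ndi.label(vals, structure=np.ones((3, 3)))
        expect = np.zeros_like(vals)
        for i in range(1, n + 1):
            comp = labels == i
            if np.sqrt(comp.sum() / np.pi) >= min_r:
                expect |= comp
        assert np.array_equal(out.values, expect)


class TestExpandMask:
    def test_zero_is_identity(self, rng):
        vals = rng.random((32, 32)) > 0.8
        out = expand_mask(BinaryMask(vals, PX), 0)
        assert np.array_equal(out.values, vals)

    def test_single_pixel_euclidean_disk(self):
        vals = np.zeros((21, 21), dtype=bool)
        vals[10, 10] = True
        out = expand_mask(BinaryMask(vals, PX), 5)
        expect = sum(
            1
            for dy in range(-10, 11)
            for dx in range(-10, 11)
            if dy * dy + dx * dx <= 25
        )
        assert out.values.sum() == expect  # enumeration gives 81 pixels
        ys, xs = np.nonzero(out.values)
        assert (((ys - 10) ** 2 + (xs - 10) ** 2) <= 25).all()

    def test_monotone_in_input(self, rng):
        a = rng.random((32, 32)) > 0.9
        b = a | (rng.random((32, 32)) > 0.9)
        ea = expand_mask(BinaryMask(a, PX), 3).values
        eb = expand_mask(BinaryMask(b, PX), 3).values
        assert (~ea | eb).all()  # expand(a) subset of expand(b)


def _nuclei_scene(centers, radius=22, shape=(256, 256), speckles=0, rng=None):
    vals = np.full(shape, 400, dtype=np.uint16)
    for c in centers:
        rr, cc = skdraw.disk(c, radius, shape=shape)
        vals[rr, cc] = 8000
    if speckles and rng is not None:
        for _ in range(speckles):
            r, c = rng.integers(0, shape[0]), rng.integers(0, shape[1])
            rr, cc = skdraw.disk((r, c), 3, shape=shape)
            vals[rr, cc] = 8000
    return make_image(vals)


class TestBuildNucleiMask:
    CENTERS = [(40, 40), (40, 200), (128, 128), (210, 60), (205, 205)]

    def test_clean_nuclei_recovered(self):
        img = _nuclei_scene(self.CENTERS)
        nuclei, soma = build_nuclei_mask(img)
        _, n = ndi.label(nuclei.values, structure=np.ones((3, 3)))
        assert n == 5
        # soma mask is a superset of each nucleus disk
        assert (~nuclei.values | soma.values).all()

    def test_speckles_removed(self, rng):
        img = _nuclei_scene(self.CENTERS, speckles=50, rng=rng)
        nuclei, _ = build_nuclei_mask(img)
        _, n = ndi.label(nuclei.values, structure=np.ones((3, 3)))
        assert n == 5


class TestBuildNeuriteMask:
    def test_blank_map2_gives_empty_mask(self):
        map2 = make_image(np.full((64, 64), 400, dtype=np.uint16))
        soma = BinaryMask(np.zeros((64, 64), dtype=bool), PX)
        out = build_neurite_mask(map2, soma)
        assert not out.values.any()

    def test_disjoint_from_soma(self, small_params):
        from neuromorph import generate_acquisition

        acq, _ = generate_acquisition(small_params)
        nuclei, soma = build_nuclei_mask(acq.dapi)
        out = build_neurite_mask(acq.map2, soma)
        assert not (out.values & soma.values).any()

    def test_union_algebra(self, small_params):
        from neuromorph import generate_acquisition
        from neuromorph.masking import _dtype_max, rescale_to_dtype
        from neuromorph.thresholds import apply_threshold, threshold_moments

        acq, _ = generate_acquisition(small_params)
        nuclei, soma = build_nuclei_mask(acq.dapi)
        p = MaskingParams()
        e = enhance_contrast(acq.map2, p.saturated_fraction)
        high_img = gaussian_blur(e, p.blur_sigma_um)
        high = apply_threshold(high_img, threshold_moments(high_img))
        resp = log_filter(e, p.log_sigma_um)
        scaled = rescale_to_dtype(resp.values, np.dtype(np.float64)) * _dtype_max(
            acq.map2.values.dtype
        )
        log = scaled > threshold_moments(scaled)
        union = high | log
        final = build_neurite_mask(acq.map2, soma).values
        assert union.sum() >= max(high.sum(), log.sum())
        assert final.sum() <= union.sum()
        assert np.array_equal(final, union & ~soma.values)

    def test_deterministic(self, small_params):
        from neuromorph import generate_acquisition

        acq, _ = generate_acquisition(small_params)
        nuclei, soma = build_nuclei_mask(acq.dapi)
        a = build_neurite_mask(acq.map2, soma)
        b = build_neurite_mask(acq.map2, soma)
        assert np.array_equal(a.values, b.values)

    def test_centerline_coverage_floor(self):
        """Most true centerline pixels (outside somata) end up in the mask.

        The floor is a regression bound: typical coverage is 75-85%, with
        the shortfall concentrated at branch tips, which erode by roughly
        the 2 um filter scale.
        """
        from neuromorph import GeneratorParams, generate_acquisition

        p = GeneratorParams(noise_model="none", seed=501)
        acq, truth = generate_acquisition(p)
        _, soma = build_nuclei_mask(acq.dapi)
        nm = build_neurite_mask(acq.map2, soma)
        n, px = p.grid_px, p.pixel_size_um
        centerline = np.zeros((n, n), dtype=bool)
        for e in truth.edges:
            pts = [
                (
                    min(max(int(round(y / px)), 0), n - 1),
                    min(max(int(round(x / px)), 0), n - 1),
                )
                for x, y in e.polyline
            ]
            for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
                rr, cc = skdraw.line(r0, c0, r1, c1)
                centerline[rr, cc] = True
        centerline &= ~soma.values
        coverage = (nm.values & centerline).sum() / centerline.sum()
        assert coverage >= 0.70
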