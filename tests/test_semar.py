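"""The three-pass MAR pipeline: segmentation, trace handling, blending."""

import numpy as np
import pytest

import semarct as sc
from semarct.semar import SemarParams, _interpolate_rows

from .oracles import interp_rows_bruteforce, normalized_interp_bruteforce


def _hu_image(values, spacing=1.0):
    return sc.AttenuationImage(np.asarray(values, dtype=float), spacing, unit="HU")


class TestSegmentMetal:
    def test_single_hot_pixel(self):
        img = np.full((32, 32), 40.0)
        img[5, 7] = 9000.0
        mask = sc.segment_metal(_hu_image(img), 2500.0)
        assert mask.values.sum() == 1
        assert mask.values[5, 7]

    def test_soft_tissue_only_is_empty(self):
        mask = sc.segment_metal(_hu_image(np.full((16, 16), 40.0)))
        assert mask.empty

    def test_first_pass_mask_close_to_ground_truth(self, stented_case):
        """Segmented metal count within 20% of the phantom's metal labels."""
        true_count = stented_case["map"].count("metal")
        seg_count = int(stented_case["result"].metal_mask.values.sum())
        assert abs(seg_count - true_count) <= 0.2 * true_count


class TestProjectMetalTrace:
    def test_empty_mask_empty_trace(self, small_geom):
        mask = sc.MetalMask(np.zeros((128, 128), dtype=bool), 2500.0)
        trace = sc.project_metal_trace(mask, small_geom)
        assert trace.empty

    def test_single_pixel_trace_is_thin_sinusoid_touching_every_view(self, small_geom):
        mask_arr = np.zeros((128, 128), dtype=bool)
        mask_arr[40, 80] = True
        trace = sc.project_metal_trace(
            sc.MetalMask(mask_arr, 2500.0), small_geom, epsilon=1e-6
        )
        per_view = trace.values.sum(axis=1)
        assert np.all(per_view >= 1)  # every view sees the metal
        assert np.all(per_view <= 3)  # and the trace stays thin
        # the trace bin tracks the pixel's analytic sinusoid
        center = (128 - 1) / 2.0
        dx, dy = 80 - center, center - 40
        nbins = trace.values.shape[1]
        for vi, theta in enumerate(np.deg2rad(small_geom.angles_deg)):
            expected = dx * np.cos(theta) + dy * np.sin(theta) + (nbins - 1) / 2.0
            hit_bins = np.nonzero(trace.values[vi])[0]
            assert np.min(np.abs(hit_bins - expected)) <= 1.5

    def test_nonempty_mask_touches_every_view(self, stented_case):
        trace = stented_case["result"].trace_mask
        assert np.all(trace.values.sum(axis=1) >= 1)


class TestInterpolateTrace:
    def test_bridges_interior_run_linearly(self, small_geom):
        nb = small_geom.n_detector_bins
        row = np.zeros(nb)
        row[:5] = [1.0, 2.0, 100.0, 100.0, 5.0]
        values = np.tile(row, (small_geom.n_views, 1))
        trace = np.zeros_like(values, dtype=bool)
        trace[:, 2:4] = True
        sino = sc.Sinogram(values, small_geom)
        out = sc.interpolate_trace(sino, sc.TraceMask(trace))
        assert np.allclose(out.values[:, :5], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.array_equal(out.values[:, 5:], values[:, 5:])

    def test_empty_trace_is_identity(self, stented_case):
        sino = stented_case["sino"]
        trace = sc.TraceMask(np.zeros(sino.shape, dtype=bool))
        assert np.array_equal(sc.interpolate_trace(sino, trace).values, sino.values)

    def test_matches_bruteforce_oracle_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            rows = rng.integers(2, 16)
            cols = rng.integers(4, 32)
            values = rng.normal(size=(rows, cols))
            trace = rng.random((rows, cols)) < 0.3
            trace[:, rng.integers(0, cols)] = False  # keep rows recoverable
            assert np.array_equal(
                _interpolate_rows(values, trace),
                interp_rows_bruteforce(values, trace),
            )

    def test_fully_traced_view_rejected(self, small_geom):
        values = np.ones((small_geom.n_views, small_geom.n_detector_bins))
        trace = np.zeros_like(values, dtype=bool)
        trace[3, :] = True
        with pytest.raises(ValueError, match="entirely"):
            sc.interpolate_trace(sc.Sinogram(values, small_geom), sc.TraceMask(trace))


class TestClassifyTissues:
    @pytest.mark.parametrize(
        "hu,expected",
        [(-1000.0, -1000.0), (-600.0, -1000.0), (40.0, 0.0), (300.0, 0.0), (700.0, 700.0)],
    )
    def test_default_class_values(self, hu, expected):
        img = _hu_image(np.full((8, 8), hu))
        prior = sc.classify_tissues(img, SemarParams())
        assert np.all(prior.values == expected)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError, match="thresholds"):
            SemarParams(air_threshold_hu=500.0, bone_threshold_hu=400.0)


class TestBlendWithPrior:
    @staticmethod
    def _setup(seed):
        rng = np.random.default_rng(seed)
        n = 32
        geom = sc.ScanGeometry(n_views=8, image_size_px=n)
        # water-ish prior with some retained-bone texture
        prior_hu = np.zeros((n, n))
        rr, cc = np.mgrid[0:n, 0:n]
        body = (rr - 15.5) ** 2 + (cc - 15.5) ** 2 <= 13**2
        prior_hu[~body] = -1000.0
        prior_hu[(rr > 20) & body] = 500.0
        prior = sc.AttenuationImage(prior_hu, unit="HU")
        original = sc.Sinogram(
            rng.uniform(0.5, 3.0, (geom.n_views, geom.n_detector_bins)), geom
        )
        trace = rng.random(original.shape) < 0.25
        trace[:, 0] = False
        trace[:, -1] = False
        return geom, prior, original, sc.TraceMask(trace)

    def test_beta_zero_equals_plain_interpolation(self):
        geom, prior, original, trace = self._setup(1)
        params = SemarParams(blend_weight=0.0)
        out = sc.blend_with_prior(original, prior, trace, geom, params)
        assert np.array_equal(
            out.values, sc.interpolate_trace(original, trace).values
        )

    def test_fixed_point_when_original_is_prior_projection(self):
        geom, prior, _, trace = self._setup(2)
        proj = sc.radon_forward(prior.to_mu(), geom)
        floored = sc.Sinogram(
            np.maximum(proj.values, SemarParams().prior_floor), geom
        )
        out = sc.blend_with_prior(floored, prior, trace, geom, SemarParams())
        assert np.allclose(out.values, floored.values, atol=1e-10)

    def test_beta_one_matches_normalized_oracle_exactly(self):
        params = SemarParams(blend_weight=1.0)
        for seed in range(100):
            geom, prior, original, trace = self._setup(seed)
            out = sc.blend_with_prior(original, prior, trace, geom, params)
            prior_proj = sc.radon_forward(prior.to_mu(), geom).values
            expected = normalized_interp_bruteforce(
                original.values, prior_proj, trace.values, params.prior_floor
            )
            assert np.array_equal(out.values, expected)

    def test_untouched_outside_trace(self):
        geom, prior, original, trace = self._setup(3)
        out = sc.blend_with_prior(original, prior, trace, geom, SemarParams())
        outside = ~trace.values
        assert np.array_equal(out.values[outside], original.values[outside])


class TestReinsertMetal:
    def test_substitution_contract(self):
        rng = np.random.default_rng(0)
        third = _hu_image(rng.normal(size=(16, 16)))
        first = _hu_image(rng.normal(size=(16, 16)))
        mask_arr = rng.random((16, 16)) < 0.2
        mask = sc.MetalMask(mask_arr, 2500.0)
        final = sc.reinsert_metal(third, first, mask)
        assert np.array_equal(final.values[mask_arr], first.values[mask_arr])
        assert np.array_equal(final.values[~mask_arr], third.values[~mask_arr])

    def test_empty_and_full_masks(self):
        third = _hu_image(np.full((8, 8), 1.0))
        first = _hu_image(np.full((8, 8), 2.0))
        empty = sc.MetalMask(np.zeros((8, 8), dtype=bool), 2500.0)
        full = sc.MetalMask(np.ones((8, 8), dtype=bool), 2500.0)
        assert np.array_equal(sc.reinsert_metal(third, first, empty).values, third.values)
        assert np.array_equal(sc.reinsert_metal(third, first, full).values, first.values)


class TestRunSemar:
    def test_metal_free_short_circuit_bit_identical(self, metal_free_case):
        result = sc.run_semar(metal_free_case["sino"])
        first = sc.fbp(metal_free_case["sino"], SemarParams().filter_name).to_hu()
        assert result.metal_mask.empty
        assert np.array_equal(result.final.values, result.first_pass.values)
        assert np.array_equal(result.final.values, first.values)

    def test_metal_preserved_from_first_pass(self, stented_case):
        result = stented_case["result"]
        m = result.metal_mask.values
        assert m.any()
        assert np.array_equal(result.final.values[m], result.first_pass.values[m])

    def test_blended_sinogram_untouched_outside_trace(self, stented_case):
        result = stented_case["result"]
        sino = stented_case["sino"]
        outside = ~result.trace_mask.values
        assert np.array_equal(
            result.blended_sinogram.values[outside], sino.values[outside]
        )

    def test_vessel_roi_improves(self, stented_case):
        """Noise SD drops and CNR rises in a stented vessel (headline direction)."""
        spec = stented_case["spec"]
        result = stented_case["result"]
        roi = sc.ROISpec(spec.vessels[1].center_px, 10.0, label="vessel")
        muscle = sc.ROISpec(spec.muscles[0].center_px, 10.0, label="muscle")
        air = sc.ROISpec((8.0, 63.5), 10.0, label="air")
        metrics = {}
        for name, img in (("std", result.first_pass), ("mar", result.final)):
            v = sc.roi_stats(img, roi)
            metrics[name] = (
                v.sd_hu,
                sc.cnr(sc.CNRInputs(v, sc.roi_stats(img, muscle), sc.roi_stats(img, air))),
            )
        assert metrics["mar"][0] < metrics["std"][0]
        assert metrics["mar"][1] > metrics["std"][1]

    def test_deterministic(self, stented_case):
        again = sc.run_semar(stented_case["sino"])
        assert np.array_equal(again.final.values, stented_case["result"].final.values)
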