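import dataclasses as dc

import numpy as np
import pytest

import nanofilm as nf
from nanofilm import segmentation


class TestLevelImage:
    def test_pure_plane_levels_to_zero(self):
        rows, cols = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        img = nf.ScanImage(1.5 + 0.02 * rows - 0.01 * cols, 10.0, "topography")
        out = nf.level_image(img, order=1)
        assert np.max(np.abs(out.values)) < 1e-10

    def test_two_level_step_preserved(self, two_level_image):
        rows, cols = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        tilted = two_level_image.with_values(
            two_level_image.values + 0.7 + 0.003 * rows + 0.005 * cols)
        mask = two_level_image.values > 0.1
        # masked flatten fits the plane on the background phase only, so
        # the two-level contrast survives levelling exactly
        out = nf.level_image(tilted, order=1, exclude_mask=mask)
        delta_before = two_level_image.values[mask].mean() - two_level_image.values[~mask].mean()
        delta_after = out.values[mask].mean() - out.values[~mask].mean()
        assert delta_after == pytest.approx(delta_before, abs=1e-9)

    def test_per_line_removes_streaks(self):
        spec = nf.MonolayerSpec(shape=(256, 256), coverage=0.2, seed=7,
                                streak_amplitude=0.3, streak_axis="x",
                                noise_sigma_h=0.01, tilt=(0.0, 0.0))
        topo, _ = nf.render_pair(nf.generate_mask(spec))
        raw_var = np.var(np.median(topo.values, axis=1))
        out = nf.level_image(topo, order=1, per_line=True)
        lev_var = np.var(np.median(out.values, axis=1))
        assert raw_var / lev_var >= 10

    def test_constant_image_warns_and_zeroes(self):
        img = nf.ScanImage(np.full((16, 16), 3.0), 1.0, "topography")
        with pytest.warns(UserWarning, match="constant"):
            out = nf.level_image(img)
        assert np.all(out.values == 0)

    def test_masked_flatten_ignores_domains(self, two_level_image):
        # shift rows through domains: unmasked line medians would break them
        out = nf.level_image(two_level_image, order=1, per_line=True,
                             exclude_mask=two_level_image.values > 0.1)
        mask = two_level_image.values > 0.1
        delta = np.median(out.values[mask]) - np.median(out.values[~mask])
        assert delta == pytest.approx(0.33, abs=1e-6)


class TestHistogramThreshold:
    def test_noiseless_two_level_threshold_interior(self, two_level_image):
        thr = nf.histogram_threshold(two_level_image)
        assert 0.0 < thr < 0.33
        coverage = (two_level_image.values > thr).mean()
        assert coverage == (two_level_image.values > 0.1).mean()

    def test_gaussian_mixture_coverage(self, rng):
        mask = rng.random((256, 256)) < 0.5
        values = np.where(mask, 0.33, 0.0) + rng.normal(0, 0.05, (256, 256))
        img = nf.ScanImage(values, 10.0, "topography")
        res = nf.coverage_histogram(img)
        assert res.coverage == pytest.approx(mask.mean(), abs=0.02)

    def test_constant_image_not_bimodal(self):
        img = nf.ScanImage(np.full((32, 32), 1.0), 1.0, "topography")
        with pytest.raises(nf.NotBimodalError):
            nf.histogram_threshold(img)

    def test_single_phase_noise_not_bimodal(self, rng):
        img = nf.ScanImage(rng.normal(0, 0.05, (64, 64)), 1.0, "topography")
        with pytest.raises(nf.NotBimodalError):
            nf.histogram_threshold(img)


class TestCoverageMethods:
    def test_histogram_equals_pixel_counting(self, two_level_image):
        res = nf.coverage_histogram(two_level_image)
        brute = np.count_nonzero(two_level_image.values > res.threshold)
        assert res.coverage == brute / two_level_image.values.size

    def test_particle_counts_squares(self):
        values = np.zeros((100, 100))
        for r0 in (5, 40, 80):
            values[r0:r0 + 10, 45:55] = 1.0
        img = nf.ScanImage(values, 1.0, "topography")
        res = nf.coverage_particle(img, threshold=0.5, min_area=0.0)
        assert len(res.particles) == 3
        assert res.coverage == pytest.approx(0.03)

    def test_particle_min_area_filters_speckles(self):
        values = np.zeros((100, 100))
        for r0 in (5, 40, 80):
            values[r0:r0 + 10, 45:55] = 1.0
        for r, c in [(2, 2), (20, 90), (60, 3), (95, 95), (50, 20)]:
            values[r, c] = 1.0
        img = nf.ScanImage(values, 1.0, "topography")
        res = nf.coverage_particle(img, threshold=0.5, min_area=2.0)
        assert len(res.particles) == 3
        assert res.coverage == pytest.approx(0.03)

    def test_particle_equals_histogram_on_noiseless_synthetic(self):
        spec = dc.replace(nf.control_like_spec(shape=(128, 128), n_domains=8, seed=6),
                          noise_sigma_h=0.0, noise_sigma_v=0.0,
                          streak_amplitude=0.0, tilt=(0.0, 0.0))
        topo, _ = nf.render_pair(nf.generate_mask(spec))
        hist = nf.coverage_histogram(topo)
        part = nf.coverage_particle(topo, threshold=hist.threshold, min_area=0.0)
        assert part.coverage == hist.coverage

    @staticmethod
    def _two_pass_coverage(topo):
        """Plane-only first pass seeds the exclusion mask for the final
        masked flatten — the chain the full pipeline uses."""
        seed_mask = nf.coverage_histogram(nf.level_image(topo, order=1)).mask
        lev = nf.level_image(topo, order=1, per_line=True, exclude_mask=seed_mask)
        return nf.coverage_histogram(lev)

    def test_recovers_ground_truth_across_seeds(self):
        # disks-mode synthetic with default noise: coverage within +/-0.02
        for seed in range(20):
            spec = nf.control_like_spec(shape=(128, 128), n_domains=8, seed=seed)
            truth = nf.generate_mask(spec)
            topo, _ = nf.render_pair(truth)
            res = self._two_pass_coverage(topo)
            assert res.coverage == pytest.approx(truth.realized_coverage, abs=0.02)

    def test_coverage_monotone_in_generator_coverage(self):
        estimates = []
        for coverage in (0.15, 0.3, 0.45):
            spec = nf.control_like_spec(shape=(256, 256), n_domains=12,
                                        coverage=coverage, seed=3)
            topo, _ = nf.render_pair(nf.generate_mask(spec))
            estimates.append(self._two_pass_coverage(topo).coverage)
        assert estimates[0] < estimates[1] < estimates[2]


class TestModelAverage:
    @pytest.mark.parametrize("a, b, expected", [
        ((29, 3), (25, 3), (27, 4)),
        ((55.6, 0.6), (53, 4), (54, 4)),
    ])
    def test_reproduces_published_rows(self, a, b, expected):
        assert nf.model_average(a, b) == expected

    def test_degenerate_margins(self):
        assert nf.model_average((40.0, 0.0), (40.0, 0.0)) == (40.0, 0.0)

    def test_full_precision_mode(self):
        value, margin = nf.model_average((29, 3), (25, 3), ndigits=None)
        assert value == pytest.approx(27.0)
        assert margin == pytest.approx(np.hypot(3, 3))

    def test_rejects_negative_margin(self):
        with pytest.raises(ValueError):
            nf.model_average((29, -3), (25, 3))
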