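import dataclasses as dc

import numpy as np
import pytest

import nanofilm as nf
from nanofilm.synth import COVERAGE_TOL, PRESETS


class TestGenerateMask:
    def test_disks_coverage_within_tolerance(self):
        spec = nf.MonolayerSpec(shape=(256, 256), coverage=0.27,
                                morphology="disks", seed=1)
        truth = nf.generate_mask(spec)
        assert 0.25 <= truth.realized_coverage <= 0.29
        assert truth.realized_coverage == truth.mask.mean()

    def test_coagulated_coverage_matches_quantile(self):
        spec = nf.MonolayerSpec(shape=(128, 128), coverage=0.5,
                                morphology="coagulated", seed=3)
        truth = nf.generate_mask(spec)
        granularity = 1.0 / truth.mask.size
        assert abs(truth.realized_coverage - 0.5) <= 2 * granularity

    def test_deterministic_under_seed(self):
        spec = nf.MonolayerSpec(shape=(128, 128), seed=9)
        a = nf.generate_mask(spec)
        b = nf.generate_mask(spec)
        np.testing.assert_array_equal(a.mask, b.mask)

    @pytest.mark.parametrize("morphology", ["disks", "coagulated"])
    def test_coverage_monotone_in_target(self, morphology):
        realized = []
        for coverage in (0.15, 0.3, 0.45):
            spec = nf.MonolayerSpec(shape=(256, 256), coverage=coverage,
                                    morphology=morphology, seed=5)
            realized.append(nf.generate_mask(spec).realized_coverage)
        assert realized[0] < realized[1] < realized[2]

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="coverage"):
            nf.MonolayerSpec(coverage=1.5)
        with pytest.raises(ValueError, match="morphology"):
            nf.MonolayerSpec(morphology="stripes")


class TestRenderPair:
    @staticmethod
    def _clean(spec):
        return dc.replace(spec, noise_sigma_h=0.0, noise_sigma_v=0.0,
                          streak_amplitude=0.0, tilt=(0.0, 0.0),
                          tip_blur_sigma=0.0)

    def test_noiseless_topography_is_two_level(self):
        spec = self._clean(nf.control_like_spec(shape=(128, 128), seed=2))
        topo, _ = nf.render_pair(nf.generate_mask(spec))
        levels = np.unique(topo.values)
        assert len(levels) == 2
        assert levels[1] - levels[0] == pytest.approx(spec.delta_h)

    def test_noiseless_histogram_two_bins(self):
        spec = self._clean(nf.control_like_spec(shape=(128, 128), seed=2))
        topo, _ = nf.render_pair(nf.generate_mask(spec))
        edges = np.arange(topo.values.min() - 1e-9,
                          topo.values.max() + spec.delta_h / 2, spec.delta_h / 2)
        hist, _ = np.histogram(topo.values, bins=edges)
        assert np.count_nonzero(hist) == 2

    def test_mean_conservation_noiseless(self):
        spec = self._clean(nf.control_like_spec(shape=(128, 128), seed=4))
        truth = nf.generate_mask(spec)
        topo, _ = nf.render_pair(truth)
        expected = spec.base_h + spec.delta_h * truth.realized_coverage
        assert topo.values.mean() == pytest.approx(expected, abs=1e-12)

    def test_blur_preserves_potential_mean(self):
        spec = dc.replace(nf.control_like_spec(shape=(128, 128), seed=4),
                          noise_sigma_v=0.0, noise_sigma_h=0.0)
        truth = nf.generate_mask(spec)
        _, pot = nf.render_pair(truth)
        expected = spec.base_v + spec.delta_v * truth.realized_coverage
        assert abs(pot.values.mean() - expected) / abs(expected) <= 1e-6

    def test_blur_keeps_plateau_extrema_in_large_domains(self):
        # two large disks: centres stay at full contrast under the tip blur
        spec = nf.MonolayerSpec(shape=(128, 128), coverage=0.15, n_domains=2,
                                morphology="disks", delta_v=336.0, seed=11,
                                noise_sigma_h=0.0, noise_sigma_v=0.0,
                                streak_amplitude=0.0, tilt=(0.0, 0.0))
        truth = nf.generate_mask(spec)
        _, pot = nf.render_pair(truth)
        assert pot.values.max() == pytest.approx(spec.base_v + spec.delta_v, abs=0.5)
        assert pot.values.min() == pytest.approx(spec.base_v, abs=0.5)

    def test_pair_is_deterministic(self):
        spec = nf.control_like_spec(shape=(64, 64), n_domains=6, seed=8)
        t1, p1 = nf.render_pair(nf.generate_mask(spec))
        t2, p2 = nf.render_pair(nf.generate_mask(spec))
        np.testing.assert_array_equal(t1.values, t2.values)
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_streaks_align_with_axis(self):
        spec = nf.MonolayerSpec(shape=(128, 128), coverage=0.2, seed=3,
                                noise_sigma_h=0.0, tilt=(0.0, 0.0),
                                streak_amplitude=0.5, streak_axis="x",
                                delta_h=0.0)
        truth = nf.generate_mask(spec)
        topo, _ = nf.render_pair(truth)
        # ridges along x: constant within each row
        assert np.ptp(topo.values, axis=1).max() == pytest.approx(0.0, abs=1e-12)


class TestPresets:
    def test_preset_contrasts(self):
        assert nf.control_like_spec().delta_v == 336.0
        assert nf.control_like_spec().delta_h == 0.33
        assert nf.gs12_like_spec().delta_v == 304.0
        assert nf.gs12_like_spec().delta_h == 0.28
        assert nf.gs16_like_spec().delta_v == 658.0
        assert nf.gs16_like_spec().delta_h == 0.57
        assert nf.gs16_like_spec().morphology == "coagulated"
        assert nf.control_like_spec().coverage == 0.27

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_presets_render(self, name):
        spec = PRESETS[name](shape=(128, 128), n_domains=8, seed=1)
        truth = nf.generate_mask(spec)
        topo, pot = nf.render_pair(truth)
        assert topo.shape == pot.shape == (128, 128)
        assert abs(truth.realized_coverage - spec.coverage) <= COVERAGE_TOL
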