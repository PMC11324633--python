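"""OSEM and the subtraction strategies: conservation, convergence,
degeneration identities, clipping and sign behavior."""

import numpy as np
import pytest
from scipy import ndimage

from spectsub.recon import (
    ReconSettings,
    SPECTSubtraction,
    image_addition,
    image_subtraction,
    osem,
    projection_addition,
    projection_subtraction,
    reconstruct_conventional,
)
from spectsub.system import ProjectionSet, add_poisson_noise


def _zero_scan_like(ps: ProjectionSet) -> ProjectionSet:
    return ProjectionSet(np.zeros_like(ps.counts), ps.angles_deg.copy(), noisy=True)


class TestOsem:
    def test_mlem_conserves_counts(self, flat_model, tiny_config):
        """With one subset, no attenuation and no PSF, the projected counts
        of every MLEM iterate match the measured counts."""
        rng = np.random.default_rng(0)
        truth = np.zeros((8, 8, 4))
        truth[2:6, 2:6, 1:3] = rng.random((4, 4, 2)) + 0.5
        y = add_poisson_noise(
            ProjectionSet(flat_model.forward(truth), flat_model.geom.angles_deg), 4
        )
        measured = y.total()
        seen = []
        osem(
            y,
            flat_model,
            ReconSettings(n_iterations=5, n_subsets=1),
            callback=lambda it, x: seen.append(flat_model.forward(x).sum()),
        )
        assert len(seen) == 5
        for projected in seen:
            assert projected == pytest.approx(measured, rel=1e-3)

    def test_converges_to_uniform_truth(self, flat_model):
        """Noise-free data of a uniform object reconstruct to the truth
        inside the eroded support."""
        x, y, _ = np.meshgrid(
            *[(np.arange(n) - (n - 1) / 2) * 20.0 for n in (8, 8, 4)], indexing="ij"
        )
        support = (x / 60.0) ** 2 + (y / 60.0) ** 2 <= 1.0
        truth = np.where(support, 1.0, 0.0)
        ps = ProjectionSet(flat_model.forward(truth), flat_model.geom.angles_deg)
        trace = osem(
            ps, flat_model, ReconSettings(n_iterations=2000, n_subsets=4, snapshot_every=2000)
        )
        eroded = ndimage.binary_erosion(support, iterations=1)
        np.testing.assert_allclose(trace.final[eroded], 1.0, rtol=0.05)

    def test_zero_data_gives_zero_trace(self, tiny_model, tiny_scans):
        trace = osem(
            _zero_scan_like(tiny_scans["y_post"]),
            tiny_model,
            ReconSettings(n_iterations=3, n_subsets=4),
        )
        for vol in trace.volumes:
            assert not vol.any()

    def test_iterates_non_negative(self, tiny_model, tiny_scans):
        trace = osem(tiny_scans["y_post"], tiny_model, ReconSettings(5, 4))
        for vol in trace.volumes:
            assert vol.min() >= 0

    def test_subsets_must_divide_views(self, tiny_model, tiny_scans):
        with pytest.raises(ValueError, match="divide"):
            osem(tiny_scans["y_post"], tiny_model, ReconSettings(2, 5))

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            ReconSettings(n_iterations=0)
        with pytest.raises(ValueError, match="unknown method"):
            ReconSettings(method="fourier")


@pytest.fixture(scope="module")
def setup(tiny_model, tiny_scans):
    y_post = tiny_scans["y_post"]
    y_zero = _zero_scan_like(y_post)
    settings = ReconSettings(n_iterations=3, n_subsets=4)
    reference = reconstruct_conventional(y_post, tiny_model, settings)
    return y_zero, y_post, tiny_model, settings, reference


class TestDegenerationToConventional:
    """With a zero-count baseline scan every strategy reduces exactly to a
    conventional reconstruction of the post scan."""

    def test_projection_subtraction(self, setup):
        y_zero, y_post, model, settings, ref = setup
        trace = projection_subtraction(y_zero, y_post, model, settings)
        for a, b in zip(trace.volumes, ref.volumes):
            np.testing.assert_array_equal(a, b)

    def test_projection_addition(self, setup):
        y_zero, y_post, model, settings, ref = setup
        trace = projection_addition(y_zero, y_post, model, settings)
        for a, b in zip(trace.volumes, ref.volumes):
            np.testing.assert_array_equal(a, b)

    def test_image_subtraction(self, setup):
        y_zero, y_post, model, settings, ref = setup
        trace = image_subtraction(y_zero, y_post, model, settings)
        for a, b in zip(trace.volumes, ref.volumes):
            np.testing.assert_array_equal(a, b)
        for pre_vol in trace.pre_volumes:
            assert not pre_vol.any()

    def test_image_addition(self, setup):
        y_zero, y_post, model, settings, ref = setup
        trace = image_addition(y_zero, y_post, model, settings)
        for a, b in zip(trace.volumes, ref.volumes):
            np.testing.assert_array_equal(a, b)
        for pre_vol in trace.pre_volumes:
            assert not pre_vol.any()


class TestMethodBehavior:
    def test_identical_scans_subtract_to_zero(self, tiny_model, tiny_scans):
        y = tiny_scans["y_post"]
        trace = image_subtraction(y, y, tiny_model, ReconSettings(3, 4))
        for vol in trace.volumes:
            np.testing.assert_array_equal(vol, 0.0)

    def test_image_subtraction_allows_negatives(self, tiny_model, tiny_scans):
        trace = image_subtraction(
            tiny_scans["y_pre"], tiny_scans["y_post"], tiny_model, ReconSettings(5, 4)
        )
        assert min(v.min() for v in trace.volumes) < 0

    def test_projection_subtraction_records_clipping(self, tiny_model, tiny_scans):
        trace = projection_subtraction(
            tiny_scans["y_pre"], tiny_scans["y_post"], tiny_model, ReconSettings(3, 4)
        )
        assert trace.provenance["clipped_fraction"] > 0
        for vol in trace.volumes:
            assert vol.min() >= 0

    def test_dominant_baseline_clips_to_zero_trace(self, tiny_model, tiny_scans):
        y_post = tiny_scans["y_post"]
        bigger = ProjectionSet(y_post.counts + 1.0, y_post.angles_deg, noisy=True)
        trace = projection_subtraction(bigger, y_post, tiny_model, ReconSettings(3, 4))
        for vol in trace.volumes:
            assert not vol.any()

    def test_projection_addition_non_negative(self, tiny_model, tiny_scans):
        trace = projection_addition(
            tiny_scans["y_pre"], tiny_scans["y_post"], tiny_model, ReconSettings(5, 4)
        )
        assert min(v.min() for v in trace.volumes) >= 0

    def test_image_addition_joint_traces(self, tiny_model, tiny_scans):
        trace = image_addition(
            tiny_scans["y_pre"], tiny_scans["y_post"], tiny_model, ReconSettings(5, 4)
        )
        assert len(trace.volumes) == len(trace.pre_volumes) == 5
        assert min(v.min() for v in trace.volumes) >= 0
        assert min(v.min() for v in trace.pre_volumes) >= 0
        # the baseline estimate carries activity comparable to the pre scan
        assert trace.pre_volumes[-1].sum() > 0

    def test_geometry_mismatch_rejected(self, tiny_model, tiny_scans):
        y = tiny_scans["y_post"]
        other = ProjectionSet(y.counts[:8], y.angles_deg[:8], noisy=True)
        with pytest.raises(ValueError, match="geometry"):
            image_subtraction(other, y, tiny_model, ReconSettings(2, 4))


class TestModelResultsAPI:
    def test_fit_returns_results_with_trace(self, tiny_model, tiny_scans):
        model = SPECTSubtraction(
            tiny_scans["y_post"],
            tiny_scans["y_pre"],
            tiny_model,
            method="projection_addition",
        )
        res = model.fit(n_iterations=3, n_subsets=4)
        assert res.difference.shape == tiny_model.grid_shape
        assert len(res.trace) == 3
        assert "projection_addition" in res.summary()

    def test_conventional_needs_no_baseline(self, tiny_model, tiny_scans):
        res = SPECTSubtraction(
            tiny_scans["y_diff"], mu=tiny_model, method="conventional"
        ).fit(n_iterations=2, n_subsets=4)
        assert res.pre_image is None

    def test_subtraction_requires_baseline(self, tiny_model, tiny_scans):
        with pytest.raises(ValueError, match="requires a pre-injection scan"):
            SPECTSubtraction(tiny_scans["y_post"], mu=tiny_model, method="image_addition")

    def test_unknown_method_rejected(self, tiny_model, tiny_scans):
        with pytest.raises(ValueError, match="unknown method"):
            SPECTSubtraction(tiny_scans["y_post"], mu=tiny_model, method="magic")
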