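"""Preprocessing pipeline: z-score, DFS background removal, clipping."""

import numpy as np
import pytest
from scipy import ndimage

from fieldgan import (
    DegenerateInputError,
    PreprocessConfig,
    ValidationError,
    Volume,
    clip_outliers,
    preprocess_volume,
    remove_background,
    zscore_normalize,
)


def flood_fill_oracle(data: np.ndarray, threshold: float, connectivity: int = 6):
    """Independent oracle: connected sub-threshold components touching a corner."""
    below = data < threshold
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, _ = ndimage.label(below, structure=structure)
    nx, ny, nz = data.shape
    corner_labels = {
        labels[i, j, k]
        for i in (0, nx - 1)
        for j in (0, ny - 1)
        for k in (0, nz - 1)
        if labels[i, j, k] != 0
    }
    return np.isin(labels, sorted(corner_labels))


def shell_volume(hole: bool = False) -> np.ndarray:
    """9^3 grid: bright spherical shell at radius ~3, dim inside and outside."""
    ax = np.arange(9) - 4.0
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
    data = np.where((r >= 2.5) & (r <= 3.5), 2.0, 0.0)
    if hole:
        data[4, 4, 1] = 0.0  # puncture the shell: (4,4,1) is at radius 3
    return data


class TestZscore:
    def test_binary_volume_maps_to_plus_minus_one(self):
        data = np.zeros((4, 4, 4))
        data.ravel()[::2] = 1.0  # half zeros, half ones: mean .5, pop SD .5
        out = zscore_normalize(Volume(data))
        assert set(np.unique(np.round(out.data, 12))) == {-1.0, 1.0}

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.standard_normal((6, 6, 6)))
        once = zscore_normalize(v)
        twice = zscore_normalize(once)
        assert np.allclose(once.data, twice.data, atol=1e-6)

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            zscore_normalize(Volume(np.zeros((3, 3, 3))))

    @pytest.mark.parametrize("a,b", [(2.0, 1.0), (0.5, -3.0), (10.0, 0.0)])
    def test_scale_shift_invariance(self, a, b):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 8, 8))
        ref = zscore_normalize(Volume(data)).data
        out = zscore_normalize(Volume(a * data + b)).data
        assert np.allclose(out, ref, atol=1e-6)


class TestBackgroundRemoval:
    def test_closed_shell_protects_interior(self):
        data = shell_volume()
        cfg = PreprocessConfig(shell_threshold=0.5, background_value=-1.0)
        out, mask = remove_background(Volume(data), cfg)
        ax = np.arange(9) - 4.0
        r = np.sqrt(
            ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        )
        exterior = r > 3.5
        interior = r < 2.5
        assert np.all(out.data[exterior] == -1.0)
        assert np.all(out.data[interior] == 0.0)  # unchanged
        assert np.array_equal(mask.data.astype(bool), exterior)

    def test_shell_with_hole_leaks_into_interior(self):
        data = shell_volume(hole=True)
        out, mask = remove_background(Volume(data), PreprocessConfig())
        expected = flood_fill_oracle(data, 0.5)
        assert np.array_equal(mask.data.astype(bool), expected)
        assert int(mask.data.sum()) == int(expected.sum())

    def test_everything_below_threshold_all_filled(self):
        data = np.zeros((5, 5, 5))
        out, mask = remove_background(Volume(data), PreprocessConfig())
        assert np.all(out.data == -1.0)
        assert mask.data.all()

    def test_bright_corner_blocks_seeding(self):
        data = np.zeros((5, 5, 5))
        data[0, 0, 0] = 2.0
        with pytest.raises(ValidationError, match="corner"):
            remove_background(Volume(data), PreprocessConfig())

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle_on_random_volumes(self, connectivity):
        rng = np.random.default_rng(42)
        cfg = PreprocessConfig(connectivity=connectivity)
        for _ in range(10):
            data = rng.normal(0.3, 0.35, size=(16, 16, 16))
            for idx in [(0, 0, 0), (0, 0, -1), (0, -1, 0), (0, -1, -1),
                        (-1, 0, 0), (-1, 0, -1), (-1, -1, 0), (-1, -1, -1)]:
                data[idx] = min(data[idx], 0.0)  # keep seeds open
            _, mask = remove_background(Volume(data), cfg)
            expected = flood_fill_oracle(data, cfg.shell_threshold, connectivity)
            assert np.array_equal(mask.data.astype(bool), expected)


class TestPropertyInvariants:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_zscore_invariant_under_affine_rescaling(self, a, b, seed):
        data = np.random.default_rng(seed).standard_normal((6, 6, 6))
        ref = zscore_normalize(Volume(data)).data
        out = zscore_normalize(Volume(a * data + b)).data
        assert np.allclose(out, ref, atol=1e-6)

    @given(
        lo=st.floats(min_value=-5.0, max_value=0.0),
        span=st.floats(min_value=0.5, max_value=10.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_clip_output_always_inside_bounds(self, lo, span, seed):
        cfg = PreprocessConfig(clip_low=lo, clip_high=lo + span, background_value=lo)
        data = np.random.default_rng(seed).normal(0, 5, size=(5, 5, 5))
        out = clip_outliers(Volume(data), cfg)
        assert out.data.min() >= lo and out.data.max() <= lo + span
        inside = (data >= lo) & (data <= lo + span)
        assert np.array_equal(out.data[inside], data[inside])


class TestClipping:
    def test_paper_range(self):
        out = clip_outliers(Volume(np.array([[[-3.0, 0.0, 5.0]]])))
        assert out.data.tolist() == [[[-1.0, 0.0, 2.5]]]

    def test_identity_inside_range_and_closed_boundary(self):
        data = np.array([[[-1.0, 0.3, 2.5]]])
        out = clip_outliers(Volume(data))
        assert np.array_equal(out.data, data)


class TestPipeline:
    def test_phantom_output_range_and_corners(self, cohort10):
        out = preprocess_volume(cohort10[0].low)
        assert out.data.min() >= -1.0 and out.data.max() <= 2.5
        assert out.data[0, 0, 0] == -1.0
        assert out.data[-1, -1, -1] == -1.0

    def test_pair_shapes_preserved(self, cohort10):
        p = cohort10[1]
        low = preprocess_volume(p.low)
        high = preprocess_volume(p.high)
        assert low.shape == high.shape == p.low.shape

    def test_constant_input_raises_from_zscore(self):
        with pytest.raises(DegenerateInputError):
            preprocess_volume(Volume(np.ones((5, 5, 5))))

    def test_background_mask_voxels_at_fill_value(self, cohort10):
        out, mask = preprocess_volume(cohort10[2].low, return_mask=True)
        assert np.all(out.data[mask.data.astype(bool)] == -1.0)

    def test_reclipping_idempotent(self, cohort10):
        once = preprocess_volume(cohort10[0].low)
        again = clip_outliers(once)
        assert np.array_equal(once.data, again.data)
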