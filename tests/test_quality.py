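"""Quality metrics: SNR, MSCN, generalized-Gaussian fits, BRISQUE, NIQE."""

import numpy as np
import pytest

from fieldgan import (
    DegenerateInputError,
    NiqePristineModel,
    ShapeError,
    Volume,
    brisque_features,
    fit_aggd,
    fit_ggd,
    fit_niqe_model,
    make_anatomy,
    mscn_coefficients,
    niqe_score,
    quality_report,
    snr_center_slice,
)
from fieldgan.quality import _downscale2, local_stats, rescale_to_255


def ggd_draws(alpha: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Oracle sampler: |x|^alpha is Gamma(1/alpha)-distributed for a GGD."""
    g = rng.gamma(1.0 / alpha, 1.0, size=n)
    return g ** (1.0 / alpha) * rng.choice([-1.0, 1.0], size=n)


def brain_volume_with_center_slice(values: np.ndarray) -> Volume:
    """Background -1 everywhere except a brain slab whose center slice is given."""
    data = np.full((8, 8, 9), -1.0)
    data[:, :, 2:7] = 0.5  # brain slab: z 2..6, center index 4
    data[:, :, 4] = values
    return Volume(data)


class TestSNR:
    def test_two_level_slice_gives_mean_over_sd(self):
        values = np.full((8, 8), 1.0)
        values[:4] = 3.0  # half 1, half 3: mean 2, population SD 1
        vol = brain_volume_with_center_slice(values)
        assert snr_center_slice(vol) == pytest.approx(2.0)

    def test_constant_slice_rejected(self):
        vol = brain_volume_with_center_slice(np.full((8, 8), 1.0))
        with pytest.raises(DegenerateInputError):
            snr_center_slice(vol)

    def test_deterministic(self, prepared10):
        s = prepared10[0]
        a = snr_center_slice(s.low, ~s.brain_mask)
        b = snr_center_slice(s.low, ~s.brain_mask)
        assert a == b

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateInputError):
            snr_center_slice(Volume(np.full((5, 5, 5), -1.0)))


class TestMSCN:
    def test_constant_slice_maps_to_zeros(self):
        out = mscn_coefficients(np.full((20, 20), 7.0))
        assert np.allclose(out, 0.0)

    def test_noise_slice_near_zero_mean(self):
        rng = np.random.default_rng(0)
        out = mscn_coefficients(rng.standard_normal((200, 200)))
        assert abs(float(out.mean())) < 0.02

    def test_matches_naive_windowed_computation(self):
        # independent oracle: explicit double loop over the 7x7 window
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, size=(18, 18))
        out = mscn_coefficients(img)
        half = (7 - 1) / 2.0
        xs = np.arange(7) - half
        k1 = np.exp(-(xs**2) / (2 * (7.0 / 6.0) ** 2))
        k = np.outer(k1, k1)
        k /= k.sum()
        for i, j in [(9, 9), (5, 11), (10, 4)]:  # interior pixels only
            win = img[i - 3 : i + 4, j - 3 : j + 4]
            mu = float((win * k).sum())
            sd = np.sqrt(max(float((win**2 * k).sum()) - mu**2, 0.0))
            assert out[i, j] == pytest.approx((img[i, j] - mu) / (sd + 1.0), rel=1e-9)

    def test_too_small_slice_rejected(self):
        with pytest.raises(ShapeError):
            mscn_coefficients(np.zeros((8, 8)))


class TestGeneralizedGaussianFits:
    def test_ggd_gaussian_shape_near_two(self):
        rng = np.random.default_rng(2)
        alpha, _ = fit_ggd(rng.standard_normal(100_000))
        assert 1.8 <= alpha <= 2.2

    def test_aggd_gaussian_and_laplace_shapes(self):
        rng = np.random.default_rng(3)
        a_gauss, _, _ = fit_aggd(rng.standard_normal(100_000))
        assert 1.8 <= a_gauss <= 2.2
        a_lap, _, _ = fit_aggd(rng.laplace(0, 1, 100_000))
        assert 0.9 <= a_lap <= 1.1

    def test_aggd_mirrored_samples_symmetric_scales(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.1, 2.0, 5000)
        sym = np.concatenate([x, -x])
        _, left, right = fit_aggd(sym)
        assert left == pytest.approx(right, abs=1e-6)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 4.0])
    def test_aggd_recovers_shape_within_ten_percent(self, alpha):
        rng = np.random.default_rng(5)
        x = ggd_draws(alpha, 100_000, rng)
        est, _, _ = fit_aggd(x)
        assert abs(est - alpha) <= 0.1 * alpha

    def test_degenerate_samples_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_aggd(np.ones(500))
        with pytest.raises(DegenerateInputError):
            fit_aggd(np.array([0.5, -0.5]))


class TestBrisqueFeatures:
    def test_dimension_and_determinism(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(0, 255, size=(64, 64))
        f1 = brisque_features(img)
        f2 = brisque_features(img.copy())
        assert f1.shape == (36,)
        assert np.array_equal(f1, f2)

    def test_gaussian_noise_mscn_shape_light_tailed(self):
        # MSCN of i.i.d. noise is near-Gaussian but self-normalization (each
        # pixel enters its own local SD) lightens the tails, so the fitted
        # shape sits somewhat above 2 rather than exactly at it
        rng = np.random.default_rng(7)
        img = 128 + 30 * rng.standard_normal((128, 128))
        feats = brisque_features(img)
        assert 2.0 <= feats[0] <= 3.5

    def test_scale_two_equals_downscaled_scale_one(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(0, 255, size=(96, 96))
        full = brisque_features(img)
        small = brisque_features(_downscale2(img))
        assert np.allclose(full[18:], small[:18])

    def test_small_slice_rejected(self):
        with pytest.raises(ShapeError):
            brisque_features(np.zeros((16, 16)))


@pytest.fixture(scope="module")
def pristine_slices(spec48):
    """Center slices of 12 jittered noise-free anatomies, on a 0-255 scale."""
    out = []
    for s in range(12):
        a = make_anatomy(spec48, "control", np.random.default_rng(100 + s))
        out.append(rescale_to_255(a.data[:, :, 24]))
    return out


class TestNiqe:
    def test_model_shape_and_psd_covariance(self, pristine_slices):
        model = fit_niqe_model(pristine_slices, patch_size=24)
        assert model.mean.shape == (36,)
        eig = np.linalg.eigvalsh(model.cov)
        assert eig.min() >= -1e-10

    def test_duplicate_corpus_identical_model(self, pristine_slices):
        m1 = fit_niqe_model(pristine_slices, patch_size=24)
        m2 = fit_niqe_model(list(pristine_slices), patch_size=24)
        assert np.array_equal(m1.mean, m2.mean)
        assert np.array_equal(m1.cov, m2.cov)

    def test_score_zero_when_statistics_match_model(self, pristine_slices):
        sl = pristine_slices[0]
        model = fit_niqe_model([sl] * 10, patch_size=24, sharpness_fraction=1.0)
        assert niqe_score(sl, model) == pytest.approx(0.0, abs=1e-8)

    def test_noise_increases_score(self, pristine_slices):
        model = fit_niqe_model(pristine_slices, patch_size=24)
        rng = np.random.default_rng(9)
        sl = pristine_slices[0]
        noisy = sl + rng.normal(0, 40, sl.shape)
        assert niqe_score(sl, model) < niqe_score(noisy, model)

    def test_too_few_slices_rejected(self, pristine_slices):
        with pytest.raises(DegenerateInputError):
            fit_niqe_model(pristine_slices[:5], patch_size=24)

    def test_json_round_trip(self, tmp_path, pristine_slices):
        model = fit_niqe_model(pristine_slices, patch_size=24)
        path = tmp_path / "niqe.json"
        model.to_json(path)
        loaded = NiqePristineModel.from_json(path)
        assert np.allclose(loaded.mean, model.mean)
        assert np.allclose(loaded.cov, model.cov)
        assert loaded.patch_size == 24


class TestQualityReport:
    def test_high_field_snr_exceeds_low_field(self, prepared10):
        snr_low = [snr_center_slice(s.low, ~s.brain_mask) for s in prepared10]
        snr_high = [snr_center_slice(s.high, ~s.brain_mask) for s in prepared10]
        assert np.mean(snr_high) > np.mean(snr_low)

    def test_fields_present_finite_and_deterministic(self, prepared10, pristine_slices):
        model = fit_niqe_model(pristine_slices, patch_size=24)
        s = prepared10[3]
        r1 = quality_report(s.low, model, mask=~s.brain_mask, scan_id="x")
        r2 = quality_report(s.low, model, mask=~s.brain_mask, scan_id="x")
        assert np.isfinite(r1.snr) and np.isfinite(r1.niqe)
        assert r1.snr == r2.snr and r1.niqe == r2.niqe
        assert r1.slice_index == r2.slice_index


def test_local_stats_sigma_nonnegative():
    rng = np.random.default_rng(10)
    _, sigma = local_stats(rng.uniform(0, 255, (32, 32)))
    assert sigma.min() >= 0.0
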