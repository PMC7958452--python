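"""No-reference image quality: center-slice SNR, BRISQUE features, NIQE.

SNR here is the simple ratio mean/SD of in-brain pixel intensities on the
center axial slice (center = middle slice of the brain bounding box along
the third voxel axis).  The natural-scene-statistics (NSS) metrics operate
on 2D slices rescaled to the 0–255 range their constants assume:

* **MSCN coefficients** — locally mean-subtracted, contrast-normalized
  residuals ``(I - mu) / (sigma + 1)`` with a 7x7 Gaussian window (SD 7/6);
* **BRISQUE features** — generalized-Gaussian fits of the MSCN field and
  asymmetric generalized-Gaussian (AGGD) fits of its four pairwise-product
  orientations, at two scales: 18 x 2 = 36 features.  The final BRISQUE
  *score* needs a regressor trained on a subjectively rated corpus; the
  module extracts features and accepts an optional external scorer;
* **NIQE** — a multivariate-Gaussian model (mean, covariance) of the 36
  features over sharp tiles of pristine images; the score of a test slice is
  the Mahalanobis-type distance between its feature statistics and the
  pristine model.  Lower is better; a pseudo-inverse handles singular
  covariances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import gamma as gamma_fn

from .types import DegenerateInputError, FieldganError, ShapeError, Volume

# Moment-matching lookup for the generalized-Gaussian shape parameter:
# rho(alpha) = Gamma(2/a)^2 / (Gamma(1/a) Gamma(3/a)) is monotone in alpha.
_GAM_GRID = np.arange(0.2, 10.0 + 1e-9, 0.001)
_RHO_GRID = gamma_fn(2.0 / _GAM_GRID) ** 2 / (
    gamma_fn(1.0 / _GAM_GRID) * gamma_fn(3.0 / _GAM_GRID)
)

_MSCN_C = 1.0  # stabilizer on the 0-255 intensity scale


def _gaussian_window(size: int = 7, sigma: float = 7.0 / 6.0) -> np.ndarray:
    half = (size - 1) / 2.0
    x = np.arange(size) - half
    g1 = np.exp(-(x**2) / (2 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


_WINDOW = _gaussian_window()


def center_slice_index(mask: np.ndarray) -> int:
    """Middle axial index of the non-background bounding box."""
    in_brain = np.where(mask.any(axis=(0, 1)))[0]
    if in_brain.size == 0:
        raise DegenerateInputError("empty brain mask: no in-brain voxels")
    return int((in_brain[0] + in_brain[-1]) // 2)


def _brain_mask(vol: Volume, mask, background_value: float) -> np.ndarray:
    if mask is not None:
        m = mask.data if isinstance(mask, Volume) else np.asarray(mask)
        return ~m.astype(bool) if m.dtype != bool else ~m
    return vol.data > background_value + 1e-6


def snr_center_slice(
    vol: Volume,
    mask: np.ndarray | Volume | None = None,
    *,
    background_value: float = -1.0,
) -> float:
    """mean/SD of in-brain pixels on the center axial slice.

    ``mask`` is the *background* mask from preprocessing; if omitted, brain
    voxels are taken as those above the background fill value.
    """
    brain = _brain_mask(vol, mask, background_value)
    z = center_slice_index(brain)
    pix = vol.data[:, :, z][brain[:, :, z]]
    if pix.size == 0:
        raise DegenerateInputError("center slice contains no in-brain pixels")
    sd = float(pix.std())
    if sd == 0.0:
        raise DegenerateInputError("center slice is constant: SD is zero")
    return float(pix.mean()) / sd


def rescale_to_255(img: np.ndarray) -> np.ndarray:
    """Affine map of an image onto [0, 255] (constant images map to 0)."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) * (255.0 / (hi - lo))


def local_stats(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-weighted local mean and SD fields (7x7 window, SD 7/6)."""
    img = np.asarray(img, dtype=np.float64)
    mu = ndimage.correlate(img, _WINDOW, mode="nearest")
    sigma_sq = ndimage.correlate(img * img, _WINDOW, mode="nearest") - mu * mu
    return mu, np.sqrt(np.maximum(sigma_sq, 0.0))


def mscn_coefficients(img: np.ndarray) -> np.ndarray:
    """Mean-subtracted contrast-normalized coefficients of a 2D image."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ShapeError(f"slice must be 2D and >= 16x16, got shape {img.shape}")
    mu, sigma = local_stats(img)
    return (img - mu) / (sigma + _MSCN_C)


def fit_ggd(samples: np.ndarray) -> tuple[float, float]:
    """Moment-matching fit of a zero-mean generalized Gaussian.

    Returns ``(alpha, variance)``.  Gaussian data gives alpha ~ 2, Laplacian
    alpha ~ 1.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    sigma_sq = float(np.mean(x * x))
    if sigma_sq == 0.0:
        raise DegenerateInputError("zero-variance sample for GGD fit")
    rho = float(np.mean(np.abs(x))) ** 2 / sigma_sq
    alpha = float(_GAM_GRID[np.argmin((_RHO_GRID - rho) ** 2)])
    return alpha, sigma_sq


def fit_aggd(samples: np.ndarray) -> tuple[float, float, float]:
    """Moment-matching fit of an asymmetric generalized Gaussian.

    Returns ``(alpha, left_scale, right_scale)`` — the shape parameter and
    the two side scale (beta) parameters.  Symmetric data yields equal
    scales; Gaussian data yields alpha ~ 2.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 100:
        raise DegenerateInputError(f"need >= 100 samples for AGGD fit, got {x.size}")
    neg = x[x < 0]
    pos = x[x >= 0]
    if neg.size == 0 or pos.size == 0 or float(np.mean(x * x)) == 0.0:
        raise DegenerateInputError("degenerate sample for AGGD fit (one-sided or zero)")
    left_std = float(np.sqrt(np.mean(neg * neg)))
    right_std = float(np.sqrt(np.mean(pos * pos)))
    if left_std == 0.0 or right_std == 0.0:
        raise DegenerateInputError("zero one-sided variance for AGGD fit")
    gammahat = left_std / right_std
    rhat = float(np.mean(np.abs(x))) ** 2 / float(np.mean(x * x))
    rhatnorm = (
        rhat * (gammahat**3 + 1) * (gammahat + 1) / (gammahat**2 + 1) ** 2
    )
    alpha = float(_GAM_GRID[np.argmin((_RHO_GRID - rhatnorm) ** 2)])
    conv = np.sqrt(gamma_fn(1.0 / alpha) / gamma_fn(3.0 / alpha))
    return alpha, left_std * conv, right_std * conv


def _aggd_mean(alpha: float, bl: float, br: float) -> float:
    return (br - bl) * gamma_fn(2.0 / alpha) / gamma_fn(1.0 / alpha)


def _downscale2(img: np.ndarray) -> np.ndarray:
    """2x2 block-average downsampling (odd trailing row/column dropped)."""
    h, w = img.shape[0] // 2, img.shape[1] // 2
    return img[: 2 * h, : 2 * w].reshape(h, 2, w, 2).mean(axis=(1, 3))


def _nss_features_one_scale(mscn: np.ndarray) -> np.ndarray:
    feats = list(fit_ggd(mscn))
    pairs = [
        mscn[:, :-1] * mscn[:, 1:],        # horizontal
        mscn[:-1, :] * mscn[1:, :],        # vertical
        mscn[:-1, :-1] * mscn[1:, 1:],     # main diagonal
        mscn[:-1, 1:] * mscn[1:, :-1],     # secondary diagonal
    ]
    for prod in pairs:
        alpha, bl, br = fit_aggd(prod)
        feats.extend([alpha, _aggd_mean(alpha, bl, br), bl**2, br**2])
    return np.array(feats)


def brisque_features(img: np.ndarray) -> np.ndarray:
    """36-dimensional NSS feature vector (18 features at each of 2 scales)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 32:
        raise ShapeError(f"slice must be 2D and >= 32x32, got shape {img.shape}")
    feats = []
    for scale in (1, 2):
        feats.append(_nss_features_one_scale(mscn_coefficients(img)))
        if scale == 1:
            img = _downscale2(img)
    return np.concatenate(feats)


@dataclass
class NiqePristineModel:
    """Multivariate-Gaussian model of pristine-image NSS features."""

    mean: np.ndarray
    cov: np.ndarray
    patch_size: int = 96
    sharpness_fraction: float = 0.75

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.cov = np.asarray(self.cov, dtype=np.float64)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ShapeError("covariance shape inconsistent with mean dimension")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise FieldganError("covariance must be symmetric")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean": self.mean.tolist(),
                    "cov": self.cov.tolist(),
                    "patch_size": self.patch_size,
                    "sharpness_fraction": self.sharpness_fraction,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NiqePristineModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["mean"]), np.array(d["cov"]),
            d["patch_size"], d["sharpness_fraction"],
        )


def _tile_features(img: np.ndarray, patch_size: int):
    """Per-tile 36-dim features and sharpness over a full-tile grid.

    Tiles whose MSCN field is (near-)constant — e.g. flat background — carry
    no scene statistics and are skipped.
    """
    img = np.asarray(img, dtype=np.float64)
    p = patch_size
    if min(img.shape) < p:
        raise ShapeError(f"slice shape {img.shape} smaller than tile size {p}")
    _, sigma = local_stats(img)
    mscn1 = mscn_coefficients(img)
    img2 = _downscale2(img)
    mscn2 = mscn_coefficients(img2) if min(img2.shape) >= 16 else None
    feats, sharps = [], []
    for i in range(0, img.shape[0] - p + 1, p):
        for j in range(0, img.shape[1] - p + 1, p):
            t1 = mscn1[i : i + p, j : j + p]
            if float(np.mean(t1 * t1)) < 1e-6:
                continue
            try:
                f1 = _nss_features_one_scale(t1)
                if mscn2 is not None:
                    h = p // 2
                    t2 = mscn2[i // 2 : i // 2 + h, j // 2 : j // 2 + h]
                    f2 = _nss_features_one_scale(t2)
                else:  # pragma: no cover - tiny-slice fallback
                    f2 = f1
            except DegenerateInputError:
                continue
            feats.append(np.concatenate([f1, f2]))
            sharps.append(float(sigma[i : i + p, j : j + p].mean()))
    return np.array(feats), np.array(sharps)


def fit_niqe_model(
    pristine_slices: list[np.ndarray],
    patch_size: int = 96,
    sharpness_fraction: float = 0.75,
) -> NiqePristineModel:
    """Fit the pristine model from undistorted slices (0-255 scale).

    Features are computed on ``patch_size`` tiles; only the sharpest
    ``sharpness_fraction`` of tiles (by mean local SD) enter the fit.
    """
    if len(pristine_slices) < 10:
        raise DegenerateInputError(
            f"need >= 10 pristine slices, got {len(pristine_slices)}"
        )
    all_feats, all_sharps = [], []
    for sl in pristine_slices:
        f, s = _tile_features(sl, patch_size)
        if f.size:
            all_feats.append(f)
            all_sharps.append(s)
    if not all_feats:
        raise DegenerateInputError("no usable tiles in the pristine corpus")
    feats = np.concatenate(all_feats)
    sharps = np.concatenate(all_sharps)
    thr = np.quantile(sharps, 1.0 - sharpness_fraction)
    keep = sharps >= thr
    if keep.sum() < 2:
        raise DegenerateInputError("fewer than 2 tiles pass the sharpness filter")
    sel = feats[keep]
    return NiqePristineModel(
        mean=sel.mean(axis=0),
        cov=np.cov(sel, rowvar=False),
        patch_size=patch_size,
        sharpness_fraction=sharpness_fraction,
    )


def niqe_score(img: np.ndarray, model: NiqePristineModel) -> float:
    """Distance of a test slice's feature statistics from the pristine model.

    ``sqrt((v1-v2)^T ((S1+S2)/2)^+ (v1-v2))``; zero when the test statistics
    equal the model statistics exactly.

    The test covariance S2 enters only when the slice yields more tiles than
    feature dimensions; a covariance estimated from fewer samples is
    rank-deficient noise that can swamp the pooled inverse, so it is shrunk
    to zero and the pristine covariance alone whitens the distance.
    """
    feats, _ = _tile_features(img, model.patch_size)
    if feats.size == 0:
        raise DegenerateInputError("no usable tiles in test slice")
    if feats.shape[1] != model.mean.size:
        raise FieldganError(
            f"feature dimension {feats.shape[1]} != model dimension {model.mean.size}"
        )
    nu2 = feats.mean(axis=0)
    cov2 = (
        np.cov(feats, rowvar=False)
        if feats.shape[0] > model.mean.size
        else np.zeros_like(model.cov)
    )
    diff = model.mean - nu2
    pooled = (model.cov + cov2) / 2.0
    d2 = float(diff @ np.linalg.pinv(pooled) @ diff)
    return float(np.sqrt(max(d2, 0.0)))


@dataclass
class QualityReport:
    scan_id: str
    snr: float
    niqe: float | None
    brisque: float | None
    slice_index: int


def quality_report(
    vol: Volume,
    niqe_model: NiqePristineModel | None = None,
    *,
    mask: np.ndarray | Volume | None = None,
    background_value: float = -1.0,
    brisque_scorer=None,
    scan_id: str = "",
) -> QualityReport:
    """SNR (+ NIQE, + optional external BRISQUE score) on the center slice.

    The slice is affinely rescaled to 0-255 before the NSS metrics; SNR uses
    the preprocessed intensities directly.
    """
    brain = _brain_mask(vol, mask, background_value)
    z = center_slice_index(brain)
    snr = snr_center_slice(vol, mask, background_value=background_value)
    sl = rescale_to_255(vol.data[:, :, z])
    niqe = niqe_score(sl, niqe_model) if niqe_model is not None else None
    brisque = None
    if brisque_scorer is not None:
        brisque = float(brisque_scorer(brisque_features(sl)))
    return QualityReport(scan_id=scan_id, snr=snr, niqe=niqe, brisque=brisque, slice_index=z)
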