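"""Image-quality battery: full-reference MSE/PSNR/SSIM and no-reference NIQE.

Metrics are computed on the stored-intensity scale (physical x 10) so
that the dynamic range L = 65,535 of a 16-bit DICOM pixel applies.
SSIM uses K1 = 0.01, K2 = 0.03 and local statistics from an 11 x 11
Gaussian window (sigma 1.5), the standard configuration of the index.

NIQE (naturalness image quality evaluator) scores the Mahalanobis-type
distance between the multivariate Gaussian of natural-scene-statistics
features of a test image and a pristine model fitted on a corpus of
good-quality images.  Features per scale: generalized-Gaussian (GGD)
shape/variance of the mean-subtracted contrast-normalized (MSCN)
coefficients plus asymmetric-GGD fits of the four-orientation pairwise
products — 18 features per scale, 36 with the default two scales.
Lower NIQE = more natural.  The pristine model here is fitted on
simulated routine-scan maps (no external model download); load any
external mean/covariance via ``NIQE`` attributes to substitute.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.special import gamma as gamma_fn
from sklearn.base import BaseEstimator

__all__ = ["SSIMParams", "mse", "psnr", "ssim", "NIQE",
           "fit_niqe_pristine", "niqe"]

L_DEFAULT = 65535.0

_GAM_GRID = np.arange(0.2, 10.0, 0.001)
_GGD_RATIO = gamma_fn(1.0 / _GAM_GRID) * gamma_fn(3.0 / _GAM_GRID) \
    / gamma_fn(2.0 / _GAM_GRID) ** 2
_AGGD_RATIO = gamma_fn(2.0 / _GAM_GRID) ** 2 / (
    gamma_fn(1.0 / _GAM_GRID) * gamma_fn(3.0 / _GAM_GRID))


class SSIMParams:
    """Stabilizing constants and window for the structural-similarity index."""

    def __init__(self, K1: float = 0.01, K2: float = 0.03, L: float = L_DEFAULT,
                 sigma: float = 1.5, truncate: float = 3.5):
        if K1 <= 0 or K2 <= 0 or L <= 0:
            raise ValueError("K1, K2, L must be positive")
        self.K1, self.K2, self.L = K1, K2, L
        self.sigma, self.truncate = sigma, truncate

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2

    @property
    def win_size(self) -> int:
        r = int(self.truncate * self.sigma + 0.5)
        return 2 * r + 1


def mse(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean squared error over all M x N pixels."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((ref - test) ** 2))


def psnr(ref: np.ndarray, test: np.ndarray, L: float = L_DEFAULT) -> float:
    """10 log10(L^2 / MSE) in dB; +inf when the images coincide."""
    err = mse(ref, test)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(L * L / err))


def _local(img: np.ndarray, params: SSIMParams) -> np.ndarray:
    return ndimage.gaussian_filter(img, params.sigma, truncate=params.truncate,
                                   mode="nearest")


def ssim(ref: np.ndarray, test: np.ndarray,
         params: SSIMParams | None = None) -> float:
    """Mean local structural similarity (Gaussian-window statistics).

    Per-window SSIM = ((2 mu_x mu_y + C1)(2 sigma_xy + C2)) /
    ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)), averaged over
    the image with the window-radius border cropped.
    """
    params = params or SSIMParams()
    x = np.asarray(ref, dtype=float)
    y = np.asarray(test, dtype=float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    ux, uy = _local(x, params), _local(y, params)
    uxx, uyy, uxy = _local(x * x, params), _local(y * y, params), _local(x * y, params)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    C1, C2 = params.C1, params.C2
    s = ((2 * ux * uy + C1) * (2 * vxy + C2)) / (
        (ux ** 2 + uy ** 2 + C1) * (vx + vy + C2))
    pad = (params.win_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


# ------------------------------------------------------------------- NIQE

def _ggd_fit(x: np.ndarray) -> tuple[float, float]:
    """Generalized-Gaussian shape and variance via moment matching."""
    x = x.ravel()
    e_abs = np.mean(np.abs(x))
    e_sq = np.mean(x * x)
    if e_abs < 1e-12:
        return 10.0, 0.0
    rho = e_sq / (e_abs * e_abs)
    shape = _GAM_GRID[np.argmin(np.abs(_GGD_RATIO - rho))]
    return float(shape), float(e_sq)


def _aggd_fit(x: np.ndarray) -> tuple[float, float, float, float]:
    """Asymmetric generalized-Gaussian fit: (shape, mean, l_var, r_var)."""
    x = x.ravel()
    left = x[x < 0]
    right = x[x >= 0]
    l_sq = np.mean(left ** 2) if left.size else 0.0
    r_sq = np.mean(right ** 2) if right.size else 0.0
    l_sd, r_sd = np.sqrt(l_sq), np.sqrt(r_sq)
    if l_sd < 1e-12 or r_sd < 1e-12:
        return 10.0, 0.0, float(l_sq), float(r_sq)
    gammahat = l_sd / r_sd
    rhat = np.mean(np.abs(x)) ** 2 / np.mean(x * x)
    rhatnorm = rhat * (gammahat ** 3 + 1) * (gammahat + 1) / (
        gammahat ** 2 + 1) ** 2
    shape = _GAM_GRID[np.argmin((_AGGD_RATIO - rhatnorm) ** 2)]
    mean_param = (r_sd - l_sd) * (gamma_fn(2.0 / shape) / gamma_fn(1.0 / shape)) \
        * np.sqrt(gamma_fn(1.0 / shape) / gamma_fn(3.0 / shape))
    return float(shape), float(mean_param), float(l_sq), float(r_sq)


def _mscn(img: np.ndarray, sigma: float = 7.0 / 6.0
          ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-subtracted contrast-normalized coefficients and the local-sigma
    (sharpness) field."""
    mu = ndimage.gaussian_filter(img, sigma, truncate=3.0, mode="nearest")
    var = ndimage.gaussian_filter(img * img, sigma, truncate=3.0,
                                  mode="nearest") - mu * mu
    sd = np.sqrt(np.clip(var, 0.0, None))
    return (img - mu) / (sd + 1.0), sd


def _patch_features(mscn: np.ndarray) -> np.ndarray:
    feats = list(_ggd_fit(mscn))
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]   # H, V, D1, D2 neighbours
    for dy, dx in shifts:
        prod = mscn * np.roll(np.roll(mscn, dy, axis=0), dx, axis=1)
        feats.extend(_aggd_fit(prod))
    return np.asarray(feats)


def _image_scale_features(img: np.ndarray, patch: int, sharp_frac: float | None
                          ) -> list[np.ndarray]:
    """18-feature vectors for every (optionally sharpness-selected) patch."""
    mscn, sd = _mscn(img)
    h, w = img.shape
    ny, nx = h // patch, w // patch
    if ny == 0 or nx == 0:
        raise ValueError("image smaller than the patch size")
    sharp = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            sharp[i, j] = sd[i * patch:(i + 1) * patch,
                             j * patch:(j + 1) * patch].mean()
    if sharp_frac is not None:
        keep = sharp >= sharp_frac * sharp.max()
        if not keep.any():
            keep = sharp == sharp.max()
    else:
        keep = np.ones_like(sharp, dtype=bool)
    out = []
    for i in range(ny):
        for j in range(nx):
            if keep[i, j]:
                blk = mscn[i * patch:(i + 1) * patch, j * patch:(j + 1) * patch]
                out.append(_patch_features(blk))
    return out


def _features(img: np.ndarray, patch_size: int, n_scales: int,
              sharp_frac: float | None) -> np.ndarray:
    """Stacked per-patch features over scales (patch halves with the image;
    sharpness selection applies at the first scale only)."""
    img = np.asarray(img, dtype=float)
    per_scale = []
    cur = img
    patch = patch_size
    for s in range(n_scales):
        frac = sharp_frac if s == 0 else None
        per_scale.append(_image_scale_features(cur, patch, frac))
        if s + 1 < n_scales:
            h, w = cur.shape
            cur = cur[:h - h % 2, :w - w % 2].reshape(
                h // 2, 2, w // 2, 2).mean(axis=(1, 3))
            patch //= 2
    n_keep = min(len(f) for f in per_scale)
    rows = [np.concatenate([per_scale[s][k] for s in range(len(per_scale))])
            for k in range(n_keep)]
    return np.vstack(rows)


class NIQE(BaseEstimator):
    """No-reference naturalness score as a scikit-learn style estimator.

    ``fit(images)`` builds the pristine multivariate-Gaussian feature
    model; ``score_image(image)`` returns the NIQE distance (lower =
    more natural).  ``patch_size`` is in pixels at the first scale
    (halved per scale); patches whose mean local sigma falls below
    ``sharpness_threshold`` x the sharpest patch are excluded at fit
    time only.

    Fitted attributes: ``mean_`` (36-vector), ``covariance_``
    (36 x 36, symmetric PSD), ``n_features_``.
    """

    def __init__(self, patch_size: int = 96, n_scales: int = 2,
                 sharpness_threshold: float = 0.75):
        self.patch_size = patch_size
        self.n_scales = n_scales
        self.sharpness_threshold = sharpness_threshold

    def fit(self, images):
        images = list(images)
        if len(images) < 10:
            raise ValueError("need at least 10 pristine images")
        feats = []
        for img in images:
            img = np.asarray(img, dtype=float)
            if np.ptp(img) == 0:
                continue
            feats.append(_features(img, self.patch_size, self.n_scales,
                                   self.sharpness_threshold))
        if not feats:
            raise ValueError("degenerate corpus: all images constant")
        feats = np.vstack(feats)
        self.mean_ = feats.mean(axis=0)
        centered = feats - self.mean_
        cov = centered.T @ centered / max(1, feats.shape[0] - 1)
        self.covariance_ = (cov + cov.T) / 2.0
        self.n_features_ = feats.shape[1]
        return self

    def score_image(self, image: np.ndarray) -> float:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "mean_")
        feats = _features(np.asarray(image, dtype=float), self.patch_size,
                          self.n_scales, None)
        mu = feats.mean(axis=0)
        centered = feats - mu
        cov = centered.T @ centered / max(1, feats.shape[0] - 1)
        pooled = (self.covariance_ + cov) / 2.0
        d = self.mean_ - mu
        return float(np.sqrt(max(0.0, d @ np.linalg.pinv(pooled) @ d)))


def fit_niqe_pristine(images, patch_size: int = 96, n_scales: int = 2,
                      sharpness_threshold: float = 0.75) -> NIQE:
    """Fit the pristine NIQE model on a corpus of good-quality images."""
    return NIQE(patch_size=patch_size, n_scales=n_scales,
                sharpness_threshold=sharpness_threshold).fit(images)


def niqe(image: np.ndarray, model: NIQE) -> float:
    """Score one image against a fitted pristine model (lower = better)."""
    return model.score_image(image)
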