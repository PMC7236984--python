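"""Spatial natural-scene-statistics features for wood-texture images.

A pristine photographic texture, after mean-subtraction and contrast
normalisation, has coefficients that are close to unit-variance Gaussian;
noise and blur push the coefficient histogram towards heavier or lighter
tails and skew the distributions of neighbouring-coefficient products.
This module measures those departures:

1. ``mscn_transform`` -- the Mean Subtracted Contrast Normalized field
   ``Î = (I - μ) / (σ + 1)`` with μ, σ the Gaussian-weighted local mean
   and local standard deviation over a (2K+1)×(2L+1) window.
2. ``fit_ggd`` -- a zero-mean generalized Gaussian (shape α, variance σ²)
   fitted to the MSCN coefficients by moment matching.
3. ``pairwise_products`` -- products of each MSCN coefficient with its
   horizontal, vertical and two diagonal neighbours (H1, V1, D1, D2; the
   four opposite orientations H2, V2, D3, D4 carry the same value
   multisets and are redundant).
4. ``fit_aggd`` -- an asymmetric generalized Gaussian (shape ν, mean
   offset η, left/right scales σl², σr²) fitted to each product field.
5. ``extract_features`` -- the full 36-dimensional descriptor: the 18
   parameters (2 GGD + 4×4 AGGD) at the original scale followed by the
   same 18 at half scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import gamma as gamma_fn
from skimage.transform import resize

from .errors import DegenerateInputError

__all__ = [
    "AGGDParams",
    "FEATURE_NAMES",
    "GGDParams",
    "MSCNField",
    "extract_features",
    "extract_features_table",
    "fit_aggd",
    "fit_ggd",
    "gaussian_window",
    "mscn_transform",
    "pairwise_products",
]

#: Default half-width of the local-statistics window (window is 7×7).
WINDOW_RADIUS = 3
#: Std of the Gaussian weights; radius/σ = 18/7 ≈ 3, i.e. the window spans
#: three standard deviations before rescaling to unit sum.
WINDOW_SIGMA = 7.0 / 6.0

# Shape-parameter search grid for the moment-matching inversions.
_GRID_LO, _GRID_HI, _GRID_STEP = 0.2, 10.0, 0.001


def _shape_grid() -> np.ndarray:
    return np.arange(_GRID_LO, _GRID_HI + _GRID_STEP / 2, _GRID_STEP)


def _rho_of_alpha(alpha: np.ndarray) -> np.ndarray:
    """Ratio function ρ(α) = Γ(1/α)Γ(3/α)/Γ(2/α)² used by both fits.

    For a GGD with shape α, E[x²]/E[|x|]² equals ρ(α); ρ is strictly
    decreasing on the grid, so matching the sample ratio inverts it.
    """
    return gamma_fn(1.0 / alpha) * gamma_fn(3.0 / alpha) / gamma_fn(2.0 / alpha) ** 2


_GRID = _shape_grid()
_RHO_GRID = _rho_of_alpha(_GRID)


@dataclass(frozen=True)
class MSCNField:
    """MSCN coefficients with the local statistics that produced them."""

    mscn: np.ndarray
    local_mean: np.ndarray
    local_std: np.ndarray

    def __post_init__(self):
        if not (self.mscn.shape == self.local_mean.shape == self.local_std.shape):
            raise ValueError("mscn, local_mean and local_std must share a shape")


@dataclass(frozen=True)
class GGDParams:
    """Generalized Gaussian parameters: shape alpha, variance sigma2.

    alpha = 2 is the Gaussian, alpha = 1 the Laplace; alpha < 2 means
    heavier-than-Gaussian tails.
    """

    alpha: float
    sigma2: float


@dataclass(frozen=True)
class AGGDParams:
    """Asymmetric generalized Gaussian parameters.

    ``nu`` is the shape, ``sigma_l2``/``sigma_r2`` the left/right scale
    parameters and ``eta`` the distribution mean implied by them:
    η = (βr − βl)·Γ(2/ν)/Γ(1/ν).
    """

    nu: float
    eta: float
    sigma_l2: float
    sigma_r2: float


def gaussian_window(radius: int = WINDOW_RADIUS, sigma: float = WINDOW_SIGMA) -> np.ndarray:
    """Circularly-symmetric 2D Gaussian weighting window, rescaled to unit sum."""
    coords = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-(coords**2) / (2.0 * sigma**2))
    w = np.outer(g1, g1)
    return w / w.sum()


def mscn_transform(
    img: np.ndarray,
    radius: int = WINDOW_RADIUS,
    sigma: float = WINDOW_SIGMA,
) -> MSCNField:
    """Compute the Mean Subtracted Contrast Normalized field of an image.

    μ(m,n) and σ(m,n) are the Gaussian-weighted local mean and local
    standard deviation over a (2·radius+1)² window with reflective
    boundary handling; the coefficients are (I − μ)/(σ + 1), the +1
    stabilizing the division on the 0–255 intensity scale.

    Parameters
    ----------
    img : 2D array
        Grayscale image with intensities on the 0–255 scale.

    Raises
    ------
    ValueError
        If the image is smaller than the window in either dimension.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {img.shape}")
    win = 2 * radius + 1
    if min(img.shape) < win:
        raise ValueError(f"image {img.shape} smaller than the {win}x{win} local window")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")

    coords = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-(coords**2) / (2.0 * sigma**2))
    g1 /= g1.sum()  # separable factors of the unit-sum 2D window

    def _smooth(field: np.ndarray) -> np.ndarray:
        out = ndimage.correlate1d(field, g1, axis=0, mode="reflect")
        return ndimage.correlate1d(out, g1, axis=1, mode="reflect")

    mu = _smooth(img)
    # E[I²] − μ² can dip slightly below zero in flat regions; clamp.
    var = np.clip(_smooth(img * img) - mu * mu, 0.0, None)
    sd = np.sqrt(var)
    mscn = (img - mu) / (sd + 1.0)
    return MSCNField(mscn=mscn, local_mean=mu, local_std=sd)


def _validated_samples(samples, min_n: int) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < min_n:
        raise DegenerateInputError(f"need at least {min_n} samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("samples contain non-finite values")
    if not np.any(x != 0.0):
        raise DegenerateInputError("all samples are zero; distribution fit undefined")
    return x


def fit_ggd(samples, min_n: int = 100) -> GGDParams:
    """Fit a zero-mean generalized Gaussian by moment matching.

    The sample ratio E[x²]/E[|x|]² is matched against
    ρ(α) = Γ(1/α)Γ(3/α)/Γ(2/α)² over a grid α ∈ [0.2, 10] with step
    0.001; σ² is the mean square about zero.
    """
    x = _validated_samples(samples, min_n)
    sigma2 = float(np.mean(x * x))
    mean_abs = float(np.mean(np.abs(x)))
    rho = sigma2 / mean_abs**2
    alpha = float(_GRID[np.argmin((_RHO_GRID - rho) ** 2)])
    return GGDParams(alpha=alpha, sigma2=sigma2)


def fit_aggd(samples, min_n: int = 100) -> AGGDParams:
    """Fit an asymmetric generalized Gaussian by left/right moment matching.

    σl and σr are the root mean squares of the negative and non-negative
    halves; with γ = σl/σr and r = E[|x|]²/E[x²], the generalized ratio
    R = r·(γ³+1)(γ+1)/(γ²+1)² is inverted on the shape grid for ν, and
    η follows from the fitted scales as (βr − βl)·Γ(2/ν)/Γ(1/ν).
    """
    x = _validated_samples(samples, min_n)
    left = x[x < 0]
    right = x[x > 0]
    sigma_l = float(np.sqrt(np.mean(left**2))) if left.size else 0.0
    sigma_r = float(np.sqrt(np.mean(right**2))) if right.size else 0.0
    if sigma_l == 0.0 and sigma_r == 0.0:
        raise DegenerateInputError("samples have no spread on either side of zero")

    if sigma_r == 0.0:
        # all-negative data: mirror, fit, and mirror back
        mirrored = fit_aggd(-x, min_n=min_n)
        return AGGDParams(
            nu=mirrored.nu,
            eta=-mirrored.eta,
            sigma_l2=mirrored.sigma_r2,
            sigma_r2=mirrored.sigma_l2,
        )

    gamma_hat = sigma_l / sigma_r
    r_hat = float(np.mean(np.abs(x))) ** 2 / float(np.mean(x * x))
    r_norm = r_hat * (gamma_hat**3 + 1.0) * (gamma_hat + 1.0) / (gamma_hat**2 + 1.0) ** 2
    nu = float(_GRID[np.argmin((1.0 / _RHO_GRID - r_norm) ** 2)])

    conv = np.sqrt(gamma_fn(1.0 / nu) / gamma_fn(3.0 / nu))
    beta_l = sigma_l * conv
    beta_r = sigma_r * conv
    eta = (beta_r - beta_l) * gamma_fn(2.0 / nu) / gamma_fn(1.0 / nu)
    return AGGDParams(nu=nu, eta=float(eta), sigma_l2=sigma_l**2, sigma_r2=sigma_r**2)


#: Orientation order of the product fields throughout the package.
ORIENTATIONS = ("H1", "V1", "D1", "D2")


def pairwise_products(mscn: np.ndarray | MSCNField) -> Dict[str, np.ndarray]:
    """Products of each MSCN coefficient with four of its neighbours.

    H1(m,n) = Î(m,n)Î(m,n+1)   horizontal
    V1(m,n) = Î(m,n)Î(m+1,n)   vertical
    D1(m,n) = Î(m,n)Î(m+1,n+1) main diagonal
    D2(m,n) = Î(m,n)Î(m+1,n−1) anti-diagonal

    each restricted to the index ranges where the neighbour exists. The
    mirror orientations (left, up, and the two opposite diagonals) yield
    the same value multisets and are therefore not computed.
    """
    if isinstance(mscn, MSCNField):
        mscn = mscn.mscn
    m = np.asarray(mscn, dtype=float)
    if m.ndim != 2 or min(m.shape) < 2:
        raise ValueError(f"MSCN field must be at least 2x2, got shape {m.shape}")
    return {
        "H1": m[:, :-1] * m[:, 1:],
        "V1": m[:-1, :] * m[1:, :],
        "D1": m[:-1, :-1] * m[1:, 1:],
        "D2": m[:-1, 1:] * m[1:, :-1],
    }


def _scale_feature_names(scale: int) -> list:
    names = [f"s{scale}_ggd_alpha", f"s{scale}_ggd_sigma2"]
    for orient in ORIENTATIONS:
        o = orient.lower()
        names += [
            f"s{scale}_{o}_nu",
            f"s{scale}_{o}_eta",
            f"s{scale}_{o}_sigma_l2",
            f"s{scale}_{o}_sigma_r2",
        ]
    return names


#: Documented order of the 36 features: 18 at the original scale (GGD α,
#: σ², then ν, η, σl², σr² for H1, V1, D1, D2), then the same 18 at half
#: scale. CSV columns f1..f36 follow this order.
FEATURE_NAMES = tuple(_scale_feature_names(1) + _scale_feature_names(2))


def _half_scale(img: np.ndarray) -> np.ndarray:
    """Reduce the image by a factor of 0.5 with bicubic interpolation."""
    h, w = img.shape
    return resize(
        img,
        (h // 2, w // 2),
        order=3,
        mode="reflect",
        anti_aliasing=True,
        preserve_range=True,
    )


def _scale_features(img: np.ndarray, radius: int, sigma: float) -> list:
    field = mscn_transform(img, radius=radius, sigma=sigma)
    ggd = fit_ggd(field.mscn)
    feats = [ggd.alpha, ggd.sigma2]
    products = pairwise_products(field)
    for orient in ORIENTATIONS:
        aggd = fit_aggd(products[orient])
        feats += [aggd.nu, aggd.eta, aggd.sigma_l2, aggd.sigma_r2]
    return feats


def extract_features(
    img: np.ndarray,
    radius: int = WINDOW_RADIUS,
    sigma: float = WINDOW_SIGMA,
) -> np.ndarray:
    """Extract the 36-dimensional NSS descriptor of a grayscale image.

    18 parameters (2 GGD on the MSCN coefficients + 4 AGGD parameters for
    each of the four product orientations) are computed at the original
    scale and again after bicubic reduction by a factor of 0.5; the two
    18-vectors are concatenated, original scale first (see
    ``FEATURE_NAMES`` for the exact order).
    """
    img = np.asarray(img, dtype=float)
    win = 2 * radius + 1
    if img.ndim != 2 or min(img.shape) < 2 * win:
        raise ValueError(
            f"image {img.shape} too small for the two-scale pass (needs >= {2 * win} per side)"
        )
    feats = []
    for scale, image in enumerate((img, _half_scale(img)), start=1):
        try:
            feats += _scale_features(image, radius, sigma)
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"scale {scale}: {exc}") from exc
    out = np.asarray(feats, dtype=float)
    assert out.shape == (36,)
    return out


def extract_features_table(
    images: Mapping[str, np.ndarray] | Iterable,
    radius: int = WINDOW_RADIUS,
    sigma: float = WINDOW_SIGMA,
) -> pd.DataFrame:
    """Extract features for a collection of images into a tidy table.

    ``images`` is a mapping image_id -> 2D array (or an iterable of such
    pairs). Returns a DataFrame with columns ``image_id, f1..f36`` where
    f1..f36 follow ``FEATURE_NAMES`` order.
    """
    if isinstance(images, Mapping):
        items = images.items()
    else:
        items = list(images)
    rows = []
    for image_id, img in items:
        vec = extract_features(img, radius=radius, sigma=sigma)
        rows.append([image_id] + list(vec))
    cols = ["image_id"] + [f"f{i}" for i in range(1, 37)]
    return pd.DataFrame(rows, columns=cols)
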