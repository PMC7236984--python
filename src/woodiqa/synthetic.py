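"""Procedural wood-like textures and synthetic opinion scores.

The photographic wood references and the human ratings behind the metric
are not redistributable, so this module provides seeded stand-ins with
the structural ingredients the NSS analysis responds to:

* ``make_texture`` renders a grayscale field with oriented periodic
  grain ridges (narrow dark latewood lines warped by smooth
  low-frequency noise) and darker elliptical pores placed by a Poisson
  count. Large smooth regions punctuated by sharp ridges and pores give
  the MSCN coefficients the heavy-tailed (shape α < 2) histogram that
  photographic wood shows, in contrast to pure noise (α ≈ 2).
* ``make_synthetic_ratings`` emulates a rating panel whose expected
  opinion decreases linearly with each distortion severity, is clamped
  to the 1–5 categorical scale, and carries i.i.d. Gaussian rater noise
  rounded to integer scores.

All randomness flows from explicit integer seeds through one
per-call generator, so identical specs reproduce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .distortions import DistortionSpec
from .subjective import RatingsTable

__all__ = [
    "SyntheticMOSSpec",
    "TextureSpec",
    "make_reference_set",
    "make_synthetic_ratings",
    "make_texture",
]


@dataclass(frozen=True)
class TextureSpec:
    """Parameters of a procedural wood texture.

    grain_period : spacing of grain ridges in pixels
    grain_angle  : ridge orientation in degrees (0 = vertical ridges)
    pore_density : expected pores per 10^4 px²
    pore_axes    : (major, minor) semi-axes of a pore in pixels
    contrast     : modulation depth in (0, 1]; 0 disables all modulation
    """

    width: int = 600
    height: int = 600
    grain_period: float = 24.0
    grain_angle: float = 15.0
    pore_density: float = 4.0
    pore_axes: Tuple[float, float] = (8.0, 4.0)
    contrast: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.width < 32 or self.height < 32:
            raise ValueError("texture must be at least 32x32 pixels")
        if min(self.pore_axes) < 1.0:
            raise ValueError("pore axes must be at least 1 px")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must lie in [0, 1]")
        if self.grain_period <= 0:
            raise ValueError("grain_period must be positive")
        if self.pore_density < 0:
            raise ValueError("pore_density must be non-negative")


@dataclass(frozen=True)
class SyntheticMOSSpec:
    """Parameters of the synthetic rating panel.

    A rater's latent opinion of an image distorted at (σ_GN, σ_MB) is
    ``base_quality − decay_gwn·σ_GN − decay_mb·σ_MB`` plus N(0, rater_sd)
    noise; the emitted score is that value rounded to the nearest integer
    and clamped to {1..5}. The defaults put the expected opinion at the
    floor of 1 for σ_GN ≥ 40 and near 1.5 at σ_MB = 10, matching how a
    human panel saturates at the heaviest distortion levels.
    """

    base_quality: float = 5.0
    decay_gwn: float = 0.1
    decay_mb: float = 0.35
    rater_sd: float = 0.5
    n_raters: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.base_quality > 5.0:
            raise ValueError("base_quality cannot exceed the top score of 5")
        if self.n_raters < 1:
            raise ValueError("need at least one rater")
        if self.rater_sd < 0:
            raise ValueError("rater_sd must be non-negative")

    def latent_quality(self, sigma_gn: float, sigma_mb: float) -> float:
        """Noise-free latent opinion before rounding/clamping."""
        return self.base_quality - self.decay_gwn * sigma_gn - self.decay_mb * sigma_mb

    def expected_score(self, sigma_gn: float, sigma_mb: float) -> float:
        """Exact expectation of an emitted integer score.

        Integrates the rounding/clamping of the latent opinion over the
        Gaussian rater noise: P(score=k) is the normal mass of the
        rounding cell [k−½, k+½), with the tails folded into 1 and 5.
        """
        q = self.latent_quality(sigma_gn, sigma_mb)
        if self.rater_sd == 0:
            return float(np.clip(np.rint(q), 1, 5))
        cuts = np.array([1.5, 2.5, 3.5, 4.5])
        upper = norm.cdf((cuts - q) / self.rater_sd)
        probs = np.diff(np.concatenate([[0.0], upper, [1.0]]))
        return float(np.dot(np.arange(1, 6), probs))


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-std low-frequency noise: blurred white noise, renormalized."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = field.std()
    return field / sd if sd > 0 else field


def make_texture(spec: TextureSpec) -> np.ndarray:
    """Render a wood-like grayscale texture in [0, 255].

    The image is a light background carrying narrow dark grain ridges at
    ``grain_angle`` with spacing ``grain_period``, warped by smooth
    low-frequency noise so the grain meanders as growth rings do, plus
    Poisson-placed dark elliptical pores and a little fine acquisition
    noise. ``contrast=0`` with ``pore_density=0`` yields a flat field.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    img = np.full((h, w), 200.0)
    if spec.contrast > 0:
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        theta = np.deg2rad(spec.grain_angle)
        u = (xx * np.cos(theta) + yy * np.sin(theta)) / spec.grain_period
        warp = 0.35 * _smooth_noise(rng, (h, w), sigma=max(h, w) / 12.0)
        u = u + warp
        # distance (in periods) to the nearest ridge line -> narrow ridges
        frac = u - np.rint(u)
        ridge = np.exp(-(frac**2) / (2.0 * 0.04**2))
        img -= spec.contrast * 110.0 * ridge
        img += spec.contrast * 25.0 * _smooth_noise(rng, (h, w), sigma=spec.grain_period / 2.0)
        img += spec.contrast * 1.0 * rng.standard_normal((h, w))

    n_pores = rng.poisson(spec.pore_density * h * w / 1e4) if spec.pore_density > 0 else 0
    a0, b0 = spec.pore_axes
    for _ in range(n_pores):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        scale = rng.uniform(0.7, 1.3)
        a, b = max(a0 * scale, 1.0), max(b0 * scale, 1.0)
        phi = np.deg2rad(spec.grain_angle + 90.0 + rng.normal(0.0, 10.0))
        depth = rng.uniform(50.0, 90.0)
        r = int(np.ceil(max(a, b))) + 1
        y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
        x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1].astype(float)
        dy, dx = ys - cy, xs - cx
        du = (dx * np.cos(phi) + dy * np.sin(phi)) / a
        dv = (-dx * np.sin(phi) + dy * np.cos(phi)) / b
        rho2 = du**2 + dv**2
        img[y0:y1, x0:x1] -= depth * np.clip(1.0 - rho2, 0.0, None)

    return np.clip(img, 0.0, 255.0)


def make_reference_set(seed: int, n: int = 10, size: int = 600) -> dict:
    """Generate ``n`` varied reference textures keyed ``ref01..refNN``.

    Grain spacing, orientation, pore geometry and contrast are drawn per
    species-like reference from one generator seeded by ``seed``, so the
    set spans the structural variety of a multi-species image panel.
    """
    rng = np.random.default_rng(seed)
    refs = {}
    for i in range(n):
        major = float(rng.uniform(5.0, 11.0))
        spec = TextureSpec(
            width=size,
            height=size,
            grain_period=float(rng.uniform(14.0, 40.0)),
            grain_angle=float(rng.uniform(0.0, 180.0)),
            pore_density=float(rng.uniform(1.5, 7.0)),
            pore_axes=(major, float(rng.uniform(0.4, 0.7)) * major),
            contrast=float(rng.uniform(0.4, 0.9)),
            seed=int(rng.integers(0, 2**31)),
        )
        refs[f"ref{i + 1:02d}"] = make_texture(spec)
    return refs


def make_synthetic_ratings(
    images_with_distortion: Sequence[Tuple[str, DistortionSpec]],
    spec: SyntheticMOSSpec,
) -> RatingsTable:
    """Simulate a rating panel over a set of distorted images.

    Every (rater, image) pair yields one integer score in {1..5}: the
    latent opinion for the image's severities plus Gaussian rater noise,
    rounded and clamped. Raters are labelled ``s01..sNN``.
    """
    items = list(images_with_distortion)
    if not items:
        raise ValueError("images_with_distortion must not be empty")
    rng = np.random.default_rng(spec.seed)
    rows: List[tuple] = []
    for image_id, dspec in items:
        q = spec.latent_quality(dspec.sigma_gn, dspec.sigma_mb)
        noise = rng.normal(0.0, spec.rater_sd, size=spec.n_raters) if spec.rater_sd else 0.0
        scores = np.clip(np.rint(q + noise), 1, 5).astype(int)
        scores = np.broadcast_to(scores, (spec.n_raters,))
        for i in range(spec.n_raters):
            rows.append((f"s{i + 1:02d}", str(image_id), int(scores[i])))
    frame = pd.DataFrame(rows, columns=["subject_id", "image_id", "score"])
    return RatingsTable(frame)
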