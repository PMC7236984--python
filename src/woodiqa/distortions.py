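"""Image degradations and dataset layouts.

Two distortions model what a timber-mill acquisition pipeline does to a
wood image: Gaussian white noise (sensor noise under poor illumination
and heat) and motion blur (relative motion between camera and wood
slice). Each is applied at five severity levels:

* noise standard deviation σ_GN ∈ {10, 20, 30, 40, 50} intensity units,
* blur severity σ_MB ∈ {2, 4, 6, 8, 10}.

Two dataset layouts are built from ten reference images:

* the training layout: 10 references + 10×5 noise + 10×5 blur
  = 110 images;
* the evaluation layout: per reference 1 + 5 noise + 5 blur + 25 mixed
  (every σ_GN × σ_MB, blur applied after noise) = 36, i.e. 360 images.

The blur severity is interpreted as a horizontal linear-motion averaging
kernel of length round(2·σ_MB + 1) pixels (angle configurable); a
Gaussian-blur interpretation is available via ``kind="gaussian"``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from ._seeds import derive_seed

__all__ = [
    "DatasetManifest",
    "DistortionSpec",
    "GWN_LEVELS",
    "MB_LEVELS",
    "add_gaussian_noise",
    "add_motion_blur",
    "apply_distortion",
    "build_eval_set",
    "build_training_set",
    "read_manifest",
]

GWN_LEVELS: Tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0)
MB_LEVELS: Tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0)

MANIFEST_COLUMNS = ["image_id", "reference_id", "kind", "sigma_gn", "sigma_mb", "path"]


@dataclass(frozen=True)
class DistortionSpec:
    """Distortion type and severity applied to a reference image.

    ``kind`` is one of ``reference``, ``gwn``, ``mb``, ``mixed``. For a
    mixed distortion the noise is applied first and the blur second.
    """

    kind: str
    sigma_gn: float = 0.0
    sigma_mb: float = 0.0

    def __post_init__(self):
        if self.kind not in ("reference", "gwn", "mb", "mixed"):
            raise ValueError(f"unknown distortion kind {self.kind!r}")
        if self.sigma_gn < 0 or self.sigma_mb < 0:
            raise ValueError("severities must be non-negative")
        if self.kind == "reference" and (self.sigma_gn or self.sigma_mb):
            raise ValueError("reference requires zero severities")
        if self.kind == "gwn" and self.sigma_mb:
            raise ValueError("gwn requires sigma_mb = 0")
        if self.kind == "mb" and self.sigma_gn:
            raise ValueError("mb requires sigma_gn = 0")
        if self.kind == "mixed" and not (self.sigma_gn > 0 and self.sigma_mb > 0):
            raise ValueError("mixed requires both severities > 0")


@dataclass
class DatasetManifest:
    """Record table of a generated dataset plus the in-memory images.

    ``frame`` has columns image_id, reference_id, kind, sigma_gn,
    sigma_mb, path (path empty when images were not written to disk).
    ``images`` maps image_id -> float array in [0, 255].
    """

    frame: pd.DataFrame
    images: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if list(self.frame.columns) != MANIFEST_COLUMNS:
            raise ValueError(f"manifest columns must be {MANIFEST_COLUMNS}")
        if self.frame["image_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["image_id"].duplicated(), "image_id"].tolist()
            raise ValueError(f"duplicate image ids in manifest: {dupes}")

    def counts_by_kind(self) -> Dict[str, int]:
        return self.frame["kind"].value_counts().to_dict()

    def spec_for(self, image_id: str) -> DistortionSpec:
        row = self.frame.loc[self.frame["image_id"] == image_id]
        if row.empty:
            raise KeyError(image_id)
        r = row.iloc[0]
        return DistortionSpec(kind=r["kind"], sigma_gn=r["sigma_gn"], sigma_mb=r["sigma_mb"])

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)


def read_manifest(path) -> DatasetManifest:
    """Read a manifest CSV written by ``DatasetManifest.write_csv``."""
    frame = pd.read_csv(path, keep_default_na=False)
    frame["sigma_gn"] = frame["sigma_gn"].astype(float)
    frame["sigma_mb"] = frame["sigma_mb"].astype(float)
    return DatasetManifest(frame=frame[MANIFEST_COLUMNS].copy())


def _as_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected 2D grayscale image, got shape {img.shape}")
    return img


def add_gaussian_noise(img: np.ndarray, sigma_gn: float, seed: int) -> np.ndarray:
    """Add zero-mean i.i.d. Gaussian noise of std ``sigma_gn`` and clip to [0, 255].

    Noise is added in float space; the output stays float so that
    quantization does not interact with the MSCN statistics.
    """
    img = _as_image(img)
    if sigma_gn < 0:
        raise ValueError("sigma_gn must be non-negative")
    if sigma_gn == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    noisy = img + rng.normal(0.0, sigma_gn, size=img.shape)
    return np.clip(noisy, 0.0, 255.0)


def _motion_kernel(length: int, angle: float) -> np.ndarray:
    """Normalized linear-motion kernel of ``length`` pixels at ``angle`` degrees."""
    if length <= 1:
        return np.ones((1, 1))
    if angle % 180 == 0:
        k = np.ones((1, length))
        return k / k.sum()
    theta = np.deg2rad(angle)
    half = (length - 1) / 2.0
    size = int(np.ceil(length * max(abs(np.cos(theta)), abs(np.sin(theta))))) | 1
    kernel = np.zeros((size, size))
    c = size // 2
    # rasterize the motion segment with nearest-pixel accumulation
    for t in np.linspace(-half, half, 4 * length + 1):
        r = int(round(c - t * np.sin(theta)))
        col = int(round(c + t * np.cos(theta)))
        kernel[r, col] = 1.0
    return kernel / kernel.sum()


def add_motion_blur(
    img: np.ndarray,
    sigma_mb: float,
    angle: float = 0.0,
    kind: str = "linear",
) -> np.ndarray:
    """Blur an image with severity ``sigma_mb``.

    ``kind="linear"`` (default) convolves with a normalized linear-motion
    averaging kernel of length round(2·sigma_mb + 1) pixels at ``angle``
    degrees; ``kind="gaussian"`` applies an isotropic Gaussian blur with
    std ``sigma_mb``. Boundaries are handled by reflection, so a constant
    image passes through unchanged and the global mean is preserved up to
    boundary effects.
    """
    img = _as_image(img)
    if sigma_mb < 0:
        raise ValueError("sigma_mb must be non-negative")
    if sigma_mb == 0:
        return img.copy()
    if kind == "gaussian":
        out = ndimage.gaussian_filter(img, sigma=sigma_mb, mode="reflect")
    elif kind == "linear":
        length = int(round(2.0 * sigma_mb + 1.0))
        kernel = _motion_kernel(length, angle)
        out = ndimage.convolve(img, kernel, mode="reflect")
    else:
        raise ValueError(f"unknown blur kind {kind!r}")
    return np.clip(out, 0.0, 255.0)


def apply_distortion(
    img: np.ndarray,
    spec: DistortionSpec,
    seed: int,
    blur_angle: float = 0.0,
    blur_kind: str = "linear",
) -> np.ndarray:
    """Apply a distortion spec to a reference image (noise first, then blur)."""
    out = _as_image(img)
    if spec.sigma_gn > 0:
        out = add_gaussian_noise(out, spec.sigma_gn, seed)
    if spec.sigma_mb > 0:
        out = add_motion_blur(out, spec.sigma_mb, angle=blur_angle, kind=blur_kind)
    if spec.kind == "reference":
        out = out.copy()
    return out


def _reference_items(references) -> List[Tuple[str, np.ndarray]]:
    if isinstance(references, Mapping):
        return [(str(k), _as_image(v)) for k, v in references.items()]
    return [(f"ref{i + 1:02d}", _as_image(img)) for i, img in enumerate(references)]


def _write_image(img: np.ndarray, out_dir, image_id: str) -> str:
    path = os.path.join(out_dir, f"{image_id}.png")
    iio.imwrite(path, np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return path


def _build_layout(
    references,
    seed: int,
    specs_per_reference,
    out_dir,
    relaxed: bool,
    expected_refs: int = 10,
) -> DatasetManifest:
    items = _reference_items(references)
    if not relaxed and len(items) != expected_refs:
        raise ValueError(
            f"layout requires exactly {expected_refs} reference images, got {len(items)} "
            "(pass relaxed=True to lift the count check)"
        )
    rows, images = [], {}
    for ref_id, ref_img in items:
        for suffix, spec in specs_per_reference:
            image_id = ref_id if spec.kind == "reference" else f"{ref_id}_{suffix}"
            img = apply_distortion(ref_img, spec, seed=derive_seed(seed, image_id))
            path = _write_image(img, out_dir, image_id) if out_dir is not None else ""
            rows.append([image_id, ref_id, spec.kind, spec.sigma_gn, spec.sigma_mb, path])
            images[image_id] = img
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return DatasetManifest(frame=frame, images=images)


def _fmt(level: float) -> str:
    return f"{level:g}"


def build_training_set(
    references,
    seed: int,
    out_dir=None,
    gwn_levels: Sequence[float] = GWN_LEVELS,
    mb_levels: Sequence[float] = MB_LEVELS,
    relaxed: bool = False,
) -> DatasetManifest:
    """Build the training layout: reference + single-distortion images.

    With ten references and five severity levels per distortion this
    yields 110 images: 10 references, 50 noise-distorted and 50
    blur-distorted. ``relaxed=True`` lifts the ten-reference requirement
    (the combinatorics scale accordingly).
    """
    specs = [("ref", DistortionSpec("reference"))]
    specs += [(f"gwn{_fmt(s)}", DistortionSpec("gwn", sigma_gn=s)) for s in gwn_levels]
    specs += [(f"mb{_fmt(s)}", DistortionSpec("mb", sigma_mb=s)) for s in mb_levels]
    return _build_layout(references, seed, specs, out_dir, relaxed)


def build_eval_set(
    references,
    seed: int,
    out_dir=None,
    gwn_levels: Sequence[float] = GWN_LEVELS,
    mb_levels: Sequence[float] = MB_LEVELS,
    relaxed: bool = False,
) -> DatasetManifest:
    """Build the evaluation layout including mixed distortions.

    Per reference: 1 reference + 5 noise + 5 blur + 25 mixed images
    (every σ_GN crossed with every σ_MB, blur applied after noise), i.e.
    36 per reference and 360 for the full ten-reference layout.
    """
    specs = [("ref", DistortionSpec("reference"))]
    specs += [(f"gwn{_fmt(s)}", DistortionSpec("gwn", sigma_gn=s)) for s in gwn_levels]
    specs += [(f"mb{_fmt(s)}", DistortionSpec("mb", sigma_mb=s)) for s in mb_levels]
    specs += [
        (
            f"gwn{_fmt(sg)}_mb{_fmt(sm)}",
            DistortionSpec("mixed", sigma_gn=sg, sigma_mb=sm),
        )
        for sg in gwn_levels
        for sm in mb_levels
    ]
    return _build_layout(references, seed, specs, out_dir, relaxed)
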