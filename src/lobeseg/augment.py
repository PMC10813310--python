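"""Expert-guided data augmentation for lobe segmentation training.

Two transform classes mirror the sources of variability in chest CT:

* patient-related (geometric): elastic deformation and grid distortion,
  emulating anatomical variation and pathologically deformed lungs; these
  warp image and mask with one shared displacement so they stay aligned
  (image bilinear, mask nearest-neighbor).
* scanner-related (photometric): motion blur, Gaussian noise, and
  brightness/contrast jitter, emulating acquisition and reconstruction
  differences; these never touch the mask.

Parameter names and semantics follow the widely used Albumentations
conventions; every transform is implemented here on scipy/numpy so the
semantics are pinned by this module's tests rather than a library version.
Defaults (probability, parameters) encode the expert-tuned policy:
ElasticTransform p=0.6, GridDistortion p=0.8, MotionBlur p=0.3,
GaussNoise p=0.5, RandomBrightnessContrast p=1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import SliceSample


class AugmentationError(ValueError):
    pass


_BORDER_MODES = {0: ("constant", "grid-constant"), 4: ("mirror", "reflect")}


def _border(border_mode: int) -> str:
    if border_mode not in _BORDER_MODES:
        raise AugmentationError(f"unsupported border_mode {border_mode}; use 0 or 4")
    return _BORDER_MODES[border_mode][0]


def _warp(image: np.ndarray, coords: np.ndarray, order: int, mode: str, cval: float) -> np.ndarray:
    return ndimage.map_coordinates(image, coords, order=order, mode=mode, cval=cval)


def elastic_transform(
    image: np.ndarray,
    mask: np.ndarray | None,
    rng: np.random.Generator,
    alpha: float = 1.0,
    sigma: float = 25.0,
    alpha_affine: float = 25.0,
    border_mode: int = 0,
    value: float = 0.0,
):
    """Random affine jitter plus a Gaussian-smoothed dense displacement field.

    The affine part perturbs three reference points by up to ``alpha_affine``
    pixels; the dense part is uniform noise smoothed with ``sigma`` and
    scaled by ``alpha``.  One field warps both image and mask.
    """
    if mask is not None and mask.shape != image.shape:
        raise AugmentationError(f"image {image.shape} and mask {mask.shape} are misaligned")
    h, w = image.shape
    center = np.array([h, w], dtype=float) / 2.0
    d = min(h, w) / 3.0
    src = np.array([center + [d, d], center + [d, -d], center + [-d, d]])
    dst = src + rng.uniform(-alpha_affine, alpha_affine, size=src.shape)
    # affine map (dest -> source) from the three point pairs
    a = np.hstack([dst, np.ones((3, 1))])
    coeffs = np.linalg.solve(a, src)  # (3, 2): rows*x + cols*y + 1*b
    ii, jj = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    rows = coeffs[0, 0] * ii + coeffs[1, 0] * jj + coeffs[2, 0]
    cols = coeffs[0, 1] * ii + coeffs[1, 1] * jj + coeffs[2, 1]
    di = ndimage.gaussian_filter(rng.uniform(-1, 1, size=image.shape), sigma) * alpha
    dj = ndimage.gaussian_filter(rng.uniform(-1, 1, size=image.shape), sigma) * alpha
    coords = np.stack([rows + di, cols + dj])
    mode = _border(border_mode)
    out_img = _warp(image, coords, order=1, mode=mode, cval=value)
    out_mask = None
    if mask is not None:
        out_mask = _warp(mask, coords, order=0, mode=mode, cval=0).astype(mask.dtype)
    return out_img, out_mask


def _distortion_map(n: int, num_steps: int, scales: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear source coordinates for one axis.

    Knots sit every ``n // num_steps`` pixels; each cell's width is scaled
    by its factor.  All factors 1 gives the exact identity map.
    """
    step = n // num_steps
    dest_knots = [0.0]
    src_knots = [0.0]
    pos = 0
    for k, s in enumerate(scales):
        width = step if k < num_steps else n - 1 - pos
        if width <= 0:
            break
        pos += width
        dest_knots.append(float(pos))
        src_knots.append(src_knots[-1] + width * float(s))
    return np.interp(np.arange(n, dtype=float), dest_knots, src_knots)


def grid_distortion(
    image: np.ndarray,
    mask: np.ndarray | None,
    rng: np.random.Generator,
    num_steps: int = 5,
    distort_limit: float = 0.3,
    interpolation: int = 1,
    border_mode: int = 4,
):
    """Piecewise-linear stretching of a num_steps x num_steps cell grid."""
    if mask is not None and mask.shape != image.shape:
        raise AugmentationError(f"image {image.shape} and mask {mask.shape} are misaligned")
    if num_steps < 1:
        raise AugmentationError(f"num_steps must be >= 1, got {num_steps}")
    h, w = image.shape
    sy = 1.0 + rng.uniform(-distort_limit, distort_limit, size=num_steps + 1)
    sx = 1.0 + rng.uniform(-distort_limit, distort_limit, size=num_steps + 1)
    rows = _distortion_map(h, num_steps, sy)
    cols = _distortion_map(w, num_steps, sx)
    coords = np.stack(np.meshgrid(rows, cols, indexing="ij"))
    mode = _border(border_mode)
    out_img = _warp(image, coords, order=interpolation, mode=mode, cval=0.0)
    out_mask = None
    if mask is not None:
        out_mask = _warp(mask, coords, order=0, mode=mode, cval=0).astype(mask.dtype)
    return out_img, out_mask


def motion_blur_kernel(size: int, angle: float) -> np.ndarray:
    """Directional line kernel of the given pixel length, mass normalized to 1."""
    k = np.zeros((size, size))
    c = (size - 1) / 2.0
    t = np.arange(size) - c
    ii = np.clip(np.round(c + t * np.sin(angle)).astype(int), 0, size - 1)
    jj = np.clip(np.round(c + t * np.cos(angle)).astype(int), 0, size - 1)
    k[ii, jj] = 1.0
    return k / k.sum()


def motion_blur(
    image: np.ndarray,
    rng: np.random.Generator,
    blur_limit: tuple[int, int] = (15, 15),
) -> np.ndarray:
    """Convolve with a randomly oriented line kernel (camera/patient motion analog)."""
    lo, hi = blur_limit
    sizes = [s for s in range(lo, hi + 1) if s % 2 == 1]
    if not sizes:
        raise AugmentationError(f"blur_limit {blur_limit} contains no odd kernel size")
    size = int(rng.choice(sizes))
    if size > min(image.shape):
        raise AugmentationError(f"kernel size {size} exceeds image side {min(image.shape)}")
    angle = rng.uniform(0.0, np.pi)
    return ndimage.convolve(image, motion_blur_kernel(size, angle), mode="reflect")


def gaussian_noise(
    image: np.ndarray,
    rng: np.random.Generator,
    var_limit: tuple[float, float] = (0.0, 0.0005),
    mean: float = 0.001,
) -> np.ndarray:
    """Additive Gaussian noise; variance drawn from var_limit, output clipped to [0,1]."""
    lo, hi = var_limit
    if lo < 0 or hi < lo:
        raise AugmentationError(f"var_limit must satisfy 0 <= lo <= hi, got {var_limit}")
    var = rng.uniform(lo, hi)
    noise = rng.normal(mean, np.sqrt(var), size=image.shape)
    return np.clip(image + noise, 0.0, 1.0)


def brightness_contrast(
    image: np.ndarray,
    rng: np.random.Generator,
    brightness_limit: tuple[float, float] = (-0.2, 0.2),
    contrast_limit: float | tuple[float, float] = 0.2,
) -> np.ndarray:
    """Affine intensity jitter: out = clip((1 + c) * img + b)."""
    if np.isscalar(contrast_limit):
        contrast_limit = (-float(contrast_limit), float(contrast_limit))
    c = rng.uniform(*contrast_limit)
    b = rng.uniform(*brightness_limit)
    return np.clip((1.0 + c) * image + b, 0.0, 1.0)


# registry: name -> (callable, takes_mask)
TRANSFORMS = {
    "elastic_transform": (elastic_transform, True),
    "grid_distortion": (grid_distortion, True),
    "motion_blur": (motion_blur, False),
    "gaussian_noise": (gaussian_noise, False),
    "brightness_contrast": (brightness_contrast, False),
}

# expert-tuned defaults, in canonical application order
DEFAULT_PARAMS: dict[str, dict] = {
    "elastic_transform": dict(alpha=1.0, sigma=25.0, alpha_affine=25.0, border_mode=0, value=0.0),
    "grid_distortion": dict(num_steps=5, distort_limit=0.3, interpolation=1, border_mode=4),
    "motion_blur": dict(blur_limit=(15, 15)),
    "gaussian_noise": dict(var_limit=(0.0, 0.0005), mean=0.001),
    "brightness_contrast": dict(brightness_limit=(-0.2, 0.2), contrast_limit=0.2),
}
DEFAULT_PROBS: dict[str, float] = {
    "elastic_transform": 0.6,
    "grid_distortion": 0.8,
    "motion_blur": 0.3,
    "gaussian_noise": 0.5,
    "brightness_contrast": 1.0,
}
PATIENT_TRANSFORMS = ["elastic_transform", "grid_distortion"]
SCANNER_TRANSFORMS = ["motion_blur", "gaussian_noise", "brightness_contrast"]


@dataclass
class AugmentationPolicy:
    """An ordered list of (name, probability, params) with a class tag."""

    transforms: list[tuple[str, float, dict]] = field(default_factory=list)
    class_tag: str = "none"

    def __post_init__(self):
        for name, prob, _ in self.transforms:
            if name not in TRANSFORMS:
                raise AugmentationError(f"unknown transform '{name}'")
            if not 0.0 <= prob <= 1.0:
                raise AugmentationError(f"probability for '{name}' must lie in [0,1], got {prob}")

    def to_dict(self) -> dict:
        return {
            "class_tag": self.class_tag,
            "transforms": [
                {"name": n, "probability": p, "params": {k: list(v) if isinstance(v, tuple) else v for k, v in prm.items()}}
                for n, p, prm in self.transforms
            ],
        }


def build_policy(class_tag: str) -> AugmentationPolicy:
    """Assemble the augmentation policy for one ablation arm.

    patient = geometric transforms, scanner = photometric transforms,
    combined = all five in canonical order, none = identity.
    """
    if class_tag == "none":
        names: list[str] = []
    elif class_tag == "patient":
        names = PATIENT_TRANSFORMS
    elif class_tag == "scanner":
        names = SCANNER_TRANSFORMS
    elif class_tag == "combined":
        names = list(DEFAULT_PARAMS)  # canonical row order
    else:
        raise AugmentationError(
            f"unknown augmentation class '{class_tag}'; use none|patient|scanner|combined"
        )
    return AugmentationPolicy(
        transforms=[(n, DEFAULT_PROBS[n], dict(DEFAULT_PARAMS[n])) for n in names],
        class_tag=class_tag,
    )


def apply_policy(
    policy: AugmentationPolicy,
    sample: SliceSample,
    rng: np.random.Generator,
    fired: list[str] | None = None,
) -> SliceSample:
    """Fire each transform independently with its probability, in order.

    Geometric transforms act on image and mask jointly; photometric ones on
    the image only.  The result is always a valid SliceSample.  If ``fired``
    is given, the names of the transforms that fired are appended to it.
    """
    image = sample.image[0].astype(np.float64)
    mask = sample.mask
    for name, prob, params in policy.transforms:
        if rng.random() >= prob:
            continue
        if fired is not None:
            fired.append(name)
        fn, takes_mask = TRANSFORMS[name]
        if takes_mask:
            image, mask = fn(image, mask, rng, **params)
        else:
            image = fn(image, rng, **params)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SliceSample(image[None], mask, sample.volume_id, sample.slice_index)
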