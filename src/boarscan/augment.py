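"""Region treatment and the two augmentation groups.

Two families of operators are kept strictly separable:

* *morphological* transforms - perspective, rotation, horizontal flip,
  vertical flip, random zoom out, random affine - move pixels around but
  leave the intensity scale alone (flips are exact permutations; the
  interpolating transforms drift the image mean only by interpolation and
  edge-padding effects), and
* *brightness* adjustments - color jitter (brightness/contrast scaling on
  grayscale), solarize, autocontrast, posterize, equalize, invert - remap
  the intensity histogram pointwise.

The *morphological* augmentation group applies only the first family; the
*comprehensive* group applies both.  Contrasting the two isolates the role
of absolute pixel brightness (echogenicity) in downstream classification.

All randomized operators draw from a seeded generator, so a pipeline built
with a fixed seed reproduces augmented batches bit for bit.  Interpolating
geometric operators fired for one image are composed into a single
homography and applied in one bilinear resampling pass with edge padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import CROPPED, UltrasoundImage, central_box

MORPHOLOGICAL_OPERATORS = ("perspective", "rotation", "horizontal_flip",
                           "vertical_flip", "zoom_out", "affine")
BRIGHTNESS_OPERATORS = ("color_jitter", "solarize", "autocontrast",
                        "posterize", "equalize", "invert")

MORPHOLOGICAL = "morphological"
COMPREHENSIVE = "comprehensive"


@dataclass(frozen=True)
class AugmentationGroup:
    """Named, ordered set of augmentation operators."""

    name: str
    operators: tuple[str, ...]


def morphological_group() -> AugmentationGroup:
    return AugmentationGroup(MORPHOLOGICAL, MORPHOLOGICAL_OPERATORS)


def comprehensive_group() -> AugmentationGroup:
    return AugmentationGroup(COMPREHENSIVE,
                             MORPHOLOGICAL_OPERATORS + BRIGHTNESS_OPERATORS)


@dataclass(frozen=True)
class AugmentationParams:
    """Operator magnitudes and the per-operator application probability."""

    probability: float = 0.5
    rotation_deg: float = 15.0
    perspective_distortion: float = 0.2
    zoom_out_max: float = 1.5
    jitter_lo: float = 0.6
    jitter_hi: float = 1.4
    solarize_threshold: int = 128
    posterize_bits: int = 4
    affine_translate: float = 0.05
    affine_scale: float = 0.1
    affine_shear_deg: float = 8.0


DEFAULT_AUG_PARAMS = AugmentationParams()


# ---------------------------------------------------------------------------
# region treatment
# ---------------------------------------------------------------------------

def crop_region(image: UltrasoundImage, fraction: float = 0.5) -> UltrasoundImage:
    """Crop to the central ``fraction`` of each dimension.

    The retained box is the simulated seminiferous-tubule region; the
    bright band / blob structures lie outside it by construction.
    """
    if image.region == CROPPED:
        raise ValueError("image is already cropped")
    h, w = image.pixels.shape
    rows, cols = central_box(h, w, fraction)
    return UltrasoundImage(image.boar_id, image.angle, CROPPED,
                           image.pixels[rows, cols].copy())


def crop_pixels(pixels: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    rows, cols = central_box(pixels.shape[0], pixels.shape[1], fraction)
    return pixels[rows, cols]


# ---------------------------------------------------------------------------
# geometric operators as homographies (inverse coordinate maps)
# ---------------------------------------------------------------------------

def _centered(mat: np.ndarray, h: int, w: int) -> np.ndarray:
    """Conjugate a matrix so it acts about the image center."""
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    to = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
    back = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
    return to @ mat @ back


def _rotation_h(h: int, w: int, degrees: float) -> np.ndarray:
    # inverse map of a rotation by +degrees is a rotation by -degrees
    t = np.deg2rad(-degrees)
    m = np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0],
                  [0, 0, 1]], dtype=float)
    return _centered(m, h, w)


def _flip_h(h: int, w: int, horizontal: bool) -> np.ndarray:
    if horizontal:  # mirror columns
        return np.array([[-1, 0, w - 1.0], [0, 1, 0], [0, 0, 1]])
    return np.array([[1, 0, 0], [0, -1, h - 1.0], [0, 0, 1]])


def _zoom_out_h(h: int, w: int, factor: float) -> np.ndarray:
    # content shrinks by 1/factor; inverse map scales coordinates up
    m = np.diag([factor, factor, 1.0])
    return _centered(m, h, w)


def _affine_h(h: int, w: int, rng: np.random.Generator,
              p: AugmentationParams) -> np.ndarray:
    sx, sy = rng.uniform(1 - p.affine_scale, 1 + p.affine_scale, size=2)
    shear = np.deg2rad(rng.uniform(-p.affine_shear_deg, p.affine_shear_deg))
    tx = rng.uniform(-p.affine_translate, p.affine_translate) * w
    ty = rng.uniform(-p.affine_translate, p.affine_translate) * h
    fwd = np.array([[sx, np.tan(shear) * sx, tx],
                    [0.0, sy, ty],
                    [0.0, 0.0, 1.0]])
    return _centered(np.linalg.inv(fwd), h, w)


def _four_point_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Homography H with dst ~ H @ src (points as columns of x, y, 1)."""
    a, b = [], []
    for (x, y), (u, v) in zip(src, dst):
        a.append([x, y, 1, 0, 0, 0, -u * x, -u * y])
        a.append([0, 0, 0, x, y, 1, -v * x, -v * y])
        b.extend([u, v])
    coeff = np.linalg.solve(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return np.append(coeff, 1.0).reshape(3, 3)


def _perspective_h(h: int, w: int, rng: np.random.Generator,
                   p: AugmentationParams) -> np.ndarray:
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
    jitter = rng.uniform(-p.perspective_distortion, p.perspective_distortion,
                         size=(4, 2)) * [w, h]
    # inverse map: output corner -> input (displaced) corner
    return _four_point_homography(corners, corners + jitter)


_GRID_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    if (h, w) not in _GRID_CACHE:
        yy, xx = np.mgrid[0:h, 0:w]
        _GRID_CACHE[(h, w)] = (yy.astype(np.float64), xx.astype(np.float64))
    return _GRID_CACHE[(h, w)]


def warp_homography(pixels: np.ndarray, hmat: np.ndarray) -> np.ndarray:
    """Bilinear resampling under an inverse-map homography, edge padded.

    A pure pixel-permutation matrix (e.g. a flip) maps output pixels onto
    exact input grid positions, so it reproduces intensities exactly.
    """
    h, w = pixels.shape
    yy, xx = _grid(h, w)
    den = hmat[2, 0] * xx + hmat[2, 1] * yy + hmat[2, 2]
    xs = (hmat[0, 0] * xx + hmat[0, 1] * yy + hmat[0, 2]) / den
    ys = (hmat[1, 0] * xx + hmat[1, 1] * yy + hmat[1, 2]) / den
    xs = np.clip(xs, 0.0, w - 1.000001)
    ys = np.clip(ys, 0.0, h - 1.000001)
    x0 = xs.astype(np.int32)
    y0 = ys.astype(np.int32)
    fx = (xs - x0).astype(np.float32)
    fy = (ys - y0).astype(np.float32)
    im = pixels.astype(np.float32)
    a = im[y0, x0]
    b = im[y0, x0 + 1]
    c = im[y0 + 1, x0]
    d = im[y0 + 1, x0 + 1]
    out = (a * (1 - fy) * (1 - fx) + b * (1 - fy) * fx
           + c * fy * (1 - fx) + d * fy * fx)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def rotate(pixels: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate by ``degrees`` (counter-clockwise) about the image center."""
    return warp_homography(pixels, _rotation_h(*pixels.shape, degrees))


# ---------------------------------------------------------------------------
# brightness operators as 8-bit lookup tables
# ---------------------------------------------------------------------------

_RAMP = np.arange(256, dtype=np.float64)


def _jitter_lut(rng: np.random.Generator, p: AugmentationParams) -> np.ndarray:
    brightness = rng.uniform(p.jitter_lo, p.jitter_hi)
    contrast = rng.uniform(p.jitter_lo, p.jitter_hi)
    v = (_RAMP - 127.5) * contrast + 127.5
    v = v * brightness
    return np.clip(np.rint(v), 0, 255).astype(np.uint8)


def _solarize_lut(threshold: int) -> np.ndarray:
    v = _RAMP.copy()
    v[v >= threshold] = 255 - v[v >= threshold]
    return v.astype(np.uint8)


def _posterize_lut(bits: int) -> np.ndarray:
    mask = 256 - (1 << (8 - bits))
    return (_RAMP.astype(np.uint8)) & np.uint8(mask)


_INVERT_LUT = (255 - _RAMP).astype(np.uint8)


def _autocontrast(pixels: np.ndarray) -> np.ndarray:
    lo, hi = int(pixels.min()), int(pixels.max())
    if hi <= lo:
        return pixels.copy()
    lut = np.clip(np.rint((_RAMP - lo) * 255.0 / (hi - lo)), 0, 255).astype(np.uint8)
    return lut[pixels]


def equalize_lut(pixels: np.ndarray) -> np.ndarray:
    """Classic histogram-equalization lookup table of an 8-bit image."""
    hist = np.bincount(pixels.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    nonzero = cdf[cdf > 0]
    if len(nonzero) == 0 or nonzero[0] == cdf[-1]:
        return _RAMP.astype(np.uint8)  # constant image: identity
    cdf_min = nonzero[0]
    lut = np.rint((cdf - cdf_min) / (cdf[-1] - cdf_min) * 255.0)
    return np.clip(lut, 0, 255).astype(np.uint8)


def _equalize(pixels: np.ndarray) -> np.ndarray:
    return equalize_lut(pixels)[pixels]


# ---------------------------------------------------------------------------
# single-operator application (uniformly random operator from a family)
# ---------------------------------------------------------------------------

def _apply_operator(pixels: np.ndarray, name: str, rng: np.random.Generator,
                    p: AugmentationParams) -> np.ndarray:
    h, w = pixels.shape
    if name == "perspective":
        return warp_homography(pixels, _perspective_h(h, w, rng, p))
    if name == "rotation":
        return warp_homography(
            pixels, _rotation_h(h, w, rng.uniform(-p.rotation_deg, p.rotation_deg)))
    if name == "horizontal_flip":
        return pixels[:, ::-1].copy()
    if name == "vertical_flip":
        return pixels[::-1, :].copy()
    if name == "zoom_out":
        return warp_homography(pixels,
                               _zoom_out_h(h, w, rng.uniform(1.0, p.zoom_out_max)))
    if name == "affine":
        return warp_homography(pixels, _affine_h(h, w, rng, p))
    if name == "color_jitter":
        return _jitter_lut(rng, p)[pixels]
    if name == "solarize":
        return _solarize_lut(p.solarize_threshold)[pixels]
    if name == "autocontrast":
        return _autocontrast(pixels)
    if name == "posterize":
        return _posterize_lut(p.posterize_bits)[pixels]
    if name == "equalize":
        return _equalize(pixels)
    if name == "invert":
        return _INVERT_LUT[pixels]
    raise ValueError(f"unknown operator {name!r}")


def _wrap_like(image, pixels: np.ndarray):
    if isinstance(image, UltrasoundImage):
        return UltrasoundImage(image.boar_id, image.angle, image.region, pixels)
    return pixels


def _pixels_of(image) -> np.ndarray:
    return image.pixels if isinstance(image, UltrasoundImage) else np.asarray(image)


def apply_morphological(image, seed: int = 0,
                        params: AugmentationParams = DEFAULT_AUG_PARAMS):
    """Apply one randomly chosen, randomly parameterized morphological operator."""
    rng = np.random.default_rng(seed)
    name = MORPHOLOGICAL_OPERATORS[rng.integers(len(MORPHOLOGICAL_OPERATORS))]
    return _wrap_like(image, _apply_operator(_pixels_of(image), name, rng, params))


def apply_brightness(image, seed: int = 0,
                     params: AugmentationParams = DEFAULT_AUG_PARAMS):
    """Apply one randomly chosen brightness/histogram operator."""
    rng = np.random.default_rng(seed)
    name = BRIGHTNESS_OPERATORS[rng.integers(len(BRIGHTNESS_OPERATORS))]
    return _wrap_like(image, _apply_operator(_pixels_of(image), name, rng, params))


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

class AugmentationPipeline:
    """Stochastic augmentation transform over a group's operator list.

    For each image, every operator in the group fires independently with
    probability ``params.probability`` (in the group's listed order).
    Interpolating geometric operators are composed into one homography and
    applied in a single resampling pass; flips compose into the same
    homography exactly.  Brightness operators apply as 8-bit lookup tables
    after the geometry.
    """

    def __init__(self, group: AugmentationGroup, seed: int = 0,
                 params: AugmentationParams = DEFAULT_AUG_PARAMS):
        if group.name not in (MORPHOLOGICAL, COMPREHENSIVE):
            raise ValueError(f"unknown augmentation group {group.name!r}")
        unknown = [op for op in group.operators
                   if op not in MORPHOLOGICAL_OPERATORS + BRIGHTNESS_OPERATORS]
        if unknown:
            raise ValueError(f"unknown operators {unknown}")
        self.group = group
        self.params = params
        self.rng = np.random.default_rng(seed)

    def transform_pixels(self, pixels: np.ndarray) -> np.ndarray:
        rng, p = self.rng, self.params
        h, w = pixels.shape
        hmat: np.ndarray | None = None  # pending composed inverse map
        out: np.ndarray | None = None

        def materialize() -> np.ndarray:
            nonlocal hmat, out
            base = pixels if out is None else out
            out = warp_homography(base, hmat) if hmat is not None else base.copy()
            hmat = None
            return out

        for name in self.group.operators:
            if rng.random() >= p.probability:
                continue
            if name in MORPHOLOGICAL_OPERATORS:
                if name == "perspective":
                    m = _perspective_h(h, w, rng, p)
                elif name == "rotation":
                    m = _rotation_h(h, w, rng.uniform(-p.rotation_deg, p.rotation_deg))
                elif name == "horizontal_flip":
                    m = _flip_h(h, w, True)
                elif name == "vertical_flip":
                    m = _flip_h(h, w, False)
                elif name == "zoom_out":
                    m = _zoom_out_h(h, w, rng.uniform(1.0, p.zoom_out_max))
                else:
                    m = _affine_h(h, w, rng, p)
                # ops apply in sequence; inverse maps compose left to right
                hmat = m if hmat is None else hmat @ m
            else:
                out = _apply_operator(materialize(), name, rng, p)
        if hmat is not None or out is None:
            out = materialize()
        return out

    def __call__(self, image):
        return _wrap_like(image, self.transform_pixels(_pixels_of(image)))


def build_pipeline(group: AugmentationGroup | str, seed: int = 0,
                   params: AugmentationParams = DEFAULT_AUG_PARAMS) -> AugmentationPipeline:
    """Build the augmentation transform for a group (or group name)."""
    if isinstance(group, str):
        if group == MORPHOLOGICAL:
            group = morphological_group()
        elif group == COMPREHENSIVE:
            group = comprehensive_group()
        else:
            raise ValueError(f"unknown augmentation group {group!r}")
    return AugmentationPipeline(group, seed=seed, params=params)
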