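"""Synthetic boar populations, semen-collection histories, and B-mode-like images.

This module generates the three data products the rest of the pipeline
consumes, with a *controllable* class signal so that every downstream stage
(labeling, augmentation, subject-level cross-validation, factorial analysis)
can be exercised and validated without any real farm data:

* a population of boars, each either ``high_quality`` or ``underperforming``,
* a longitudinal semen-collection history per boar (three quality metrics
  plus a technician trash flag, collected every 5-14 days), and
* grayscale testis images in two probe orientations whose echogenicity
  (pixel brightness) carries the class signal.

The image model is a deliberate caricature of B-mode ultrasound: a
multiplicative-speckle background (exponentially distributed intensity,
log-compressed to 8 bits), a bright band across the upper rows in the
vertical (longitudinal) view emulating the rete testis, and a compact bright
blob in the horizontal (transverse) view.  The central region - the
simulated seminiferous-tubule parenchyma, and exactly the region retained by
:func:`boarscan.augment.crop_region` - has its mean intensity offset by a
per-boar echogenicity shift whose class-conditional mean separates the two
classes.  The bright structures additionally carry a class-dependent
amplitude, so part of the class signal lives *outside* the central crop;
this is what plants the recall penalty for cropped-image configurations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats as sps

HIGH_QUALITY = "high_quality"
UNDERPERFORMING = "underperforming"
HORIZONTAL = "horizontal"
VERTICAL = "vertical"
FULL = "full"
CROPPED = "cropped"

#: quality criteria for a single collection (shared with :mod:`boarscan.labeling`)
COUNT_THRESHOLD = 20e9
MOTILITY_THRESHOLD = 70.0
MORPHOLOGY_THRESHOLD = 70.0


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable parameters of the synthetic-data generator.

    The defaults emulate a commercial stud population: 107 boars with a
    roughly 25/107 underperforming prevalence, 2-49 collections per boar (median
    about 30) at 5-14 day intervals starting at 200 days of age, and 9-17
    images per boar (median 12) split between the two probe orientations.
    """

    # population structure
    prevalence: float = 25.0 / 107.0
    collections_mean: float = 30.0
    collections_sd: float = 8.0
    collections_min: int = 2
    collections_max: int = 49
    images_mean: float = 12.0
    images_sd: float = 1.7
    images_min: int = 9
    images_max: int = 17
    min_images_per_angle: int = 3
    # collection timing (days)
    start_day: int = 200
    gap_min: int = 5
    gap_max: int = 14
    # semen metric distributions (good records are truncated to pass all
    # three criteria; bad records fail at least two by construction)
    good_count_mean: float = 60e9
    good_count_sd: float = 15e9
    good_pct_mean: float = 85.0
    good_pct_sd: float = 5.0
    bad_count_mean: float = 10e9
    bad_count_sd: float = 5e9
    bad_pct_mean: float = 55.0
    bad_pct_sd: float = 10.0
    # per-collection failure rates by class
    hq_bad_rate: float = 0.01
    hq_trash_rate: float = 0.005
    up_bad_rate: float = 0.30
    up_trash_rate: float = 0.05
    # image model
    image_size: int = 96
    speckle_gain: float = 5.0
    speckle_scale: float = 45.0
    crop_fraction: float = 0.5
    # the echogenicity shift applies to this central fraction (the
    # parenchyma fills most of the field of view; the 50% crop sits inside)
    parenchyma_fraction: float = 0.8
    band_row_lo: float = 0.08
    band_row_hi: float = 0.18
    # blob peak sits above the parenchyma box so its row profile reads the
    # structure amplitude uncontaminated by the parenchyma shift
    blob_row_frac: float = 0.085
    blob_col_frac: float = 0.15
    blob_radius_frac: float = 0.10
    band_base: float = 50.0
    band_class_gain: float = 30.0
    blob_base: float = 50.0
    blob_class_gain: float = 26.0
    structure_amp_sd: float = 3.0
    # per-boar echogenicity of the central (tubule) region.  A fixed
    # fraction of high-quality boars ("hidden" positives) carries the
    # central echogenicity of the underperforming class; their quality is
    # visible only in the bright structures outside the central crop, which
    # is what plants the recall penalty for cropped-image configurations.
    echo_shift_high: float = 16.0
    echo_shift_low: float = 0.0
    echo_shift_hidden: float = 0.0
    echo_shift_sd: float = 1.5
    hidden_high_fraction: float = 0.15


DEFAULT_PARAMS = GeneratorParams()


@dataclass(frozen=True)
class BoarProfile:
    """Ground-truth description of one simulated boar."""

    boar_id: str
    true_class: str
    n_collections: int
    n_images_horizontal: int
    n_images_vertical: int
    echogenicity_shift: float
    bad_rate: float
    trash_rate: float


@dataclass(frozen=True)
class SemenRecord:
    """One semen-collection event."""

    boar_id: str
    day: int
    total_sperm_count: float
    motility: float
    morphology: float
    trash_flag: bool


@dataclass
class UltrasoundImage:
    """8-bit grayscale testis image tagged with its acquisition context."""

    boar_id: str
    angle: str
    region: str
    pixels: np.ndarray  # uint8, H x W

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)


@dataclass
class Dataset:
    """In-memory bundle of profiles, collection records and images."""

    profiles: list[BoarProfile]
    records: pd.DataFrame
    images: list[UltrasoundImage]

    @property
    def manifest(self) -> pd.DataFrame:
        """One row per boar: ``boar_id`` and ground-truth ``true_class``."""
        rows = [(p.boar_id, p.true_class) for p in self.profiles]
        return pd.DataFrame(rows, columns=["boar_id", "true_class"])

    @property
    def true_classes(self) -> dict[str, str]:
        return {p.boar_id: p.true_class for p in self.profiles}


# ---------------------------------------------------------------------------
# geometry helpers shared with the imaging modules
# ---------------------------------------------------------------------------

def central_box(height: int, width: int, fraction: float = 0.5) -> tuple[slice, slice]:
    """Slices selecting the central ``fraction`` of each image dimension."""
    dh = int(round(height * fraction))
    dw = int(round(width * fraction))
    r0 = (height - dh) // 2
    c0 = (width - dw) // 2
    return slice(r0, r0 + dh), slice(c0, c0 + dw)


def band_row_range(size: int, params: GeneratorParams = DEFAULT_PARAMS) -> tuple[int, int]:
    """Row interval [lo, hi) occupied by the simulated rete-testis band."""
    return int(round(size * params.band_row_lo)), int(round(size * params.band_row_hi))


def blob_center(size: int, params: GeneratorParams = DEFAULT_PARAMS) -> tuple[int, int]:
    return (int(round(size * params.blob_row_frac)),
            int(round(size * params.blob_col_frac)))


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def simulate_population(
    n_boars: int,
    prevalence_underperforming: float | None = None,
    seed: int = 0,
    params: GeneratorParams = DEFAULT_PARAMS,
) -> list[BoarProfile]:
    """Draw a population of boar profiles.

    Each boar is independently assigned ``underperforming`` with probability
    ``prevalence_underperforming`` (default 25/107),
    together with its number of collections, per-angle image counts, failure
    rates, and per-boar central-region echogenicity shift.
    """
    if n_boars < 2:
        raise ValueError(f"n_boars must be >= 2, got {n_boars}")
    if prevalence_underperforming is None:
        prevalence_underperforming = params.prevalence
    if not 0.0 <= prevalence_underperforming <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_boars):
        under = rng.random() < prevalence_underperforming
        n_coll = int(np.clip(round(rng.normal(params.collections_mean, params.collections_sd)),
                             params.collections_min, params.collections_max))
        n_img = int(np.clip(round(rng.normal(params.images_mean, params.images_sd)),
                            params.images_min, params.images_max))
        m = params.min_images_per_angle
        n_h = int(np.clip(rng.binomial(n_img, 0.5), m, n_img - m))
        hidden = (not under) and rng.random() < params.hidden_high_fraction
        if under:
            shift_mean = params.echo_shift_low
        elif hidden:
            shift_mean = params.echo_shift_hidden
        else:
            shift_mean = params.echo_shift_high
        profiles.append(BoarProfile(
            boar_id=f"B{i:04d}",
            true_class=UNDERPERFORMING if under else HIGH_QUALITY,
            n_collections=n_coll,
            n_images_horizontal=n_h,
            n_images_vertical=n_img - n_h,
            echogenicity_shift=float(shift_mean + rng.normal(0.0, params.echo_shift_sd)),
            bad_rate=params.up_bad_rate if under else params.hq_bad_rate,
            trash_rate=params.up_trash_rate if under else params.hq_trash_rate,
        ))
    return profiles


# ---------------------------------------------------------------------------
# semen histories
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int | None = None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_semen_history(
    profile: BoarProfile,
    seed: int = 0,
    params: GeneratorParams = DEFAULT_PARAMS,
) -> list[SemenRecord]:
    """Draw ``profile.n_collections`` collection records for one boar.

    Good records are drawn truncated to satisfy all three quality criteria;
    with per-record probability ``profile.bad_rate`` a record is instead
    drawn to fail two or three criteria, and with probability
    ``profile.trash_rate`` the technician trash flag is set independently of
    the metric values.  Consecutive records are 5-14 days apart starting at
    200 days of age.
    """
    _validate_profile(profile, params)
    rng = np.random.default_rng(seed)
    records = []
    day = params.start_day
    for k in range(profile.n_collections):
        if k > 0:
            day += int(rng.integers(params.gap_min, params.gap_max + 1))
        trash = bool(rng.random() < profile.trash_rate)
        bad = rng.random() < profile.bad_rate
        if bad:
            n_fail = int(rng.integers(2, 4))  # fail 2 or 3 criteria
            failing = rng.choice(3, size=n_fail, replace=False)
        else:
            failing = np.empty(0, dtype=int)
        count = (_truncnorm(rng, params.bad_count_mean, params.bad_count_sd, 0.0,
                            COUNT_THRESHOLD - 1e6)
                 if 0 in failing else
                 _truncnorm(rng, params.good_count_mean, params.good_count_sd,
                            COUNT_THRESHOLD, np.inf))
        motility = (_truncnorm(rng, params.bad_pct_mean, params.bad_pct_sd, 0.0,
                               MOTILITY_THRESHOLD)
                    if 1 in failing else
                    _truncnorm(rng, params.good_pct_mean, params.good_pct_sd,
                               MOTILITY_THRESHOLD + 1e-6, 100.0))
        morphology = (_truncnorm(rng, params.bad_pct_mean, params.bad_pct_sd, 0.0,
                                 MORPHOLOGY_THRESHOLD)
                      if 2 in failing else
                      _truncnorm(rng, params.good_pct_mean, params.good_pct_sd,
                                 MORPHOLOGY_THRESHOLD + 1e-6, 100.0))
        records.append(SemenRecord(profile.boar_id, day, float(count),
                                   float(motility), float(morphology), trash))
    return records


def _validate_profile(profile: BoarProfile, params: GeneratorParams) -> None:
    if profile.n_collections < 1:
        raise ValueError("profile must have at least one collection")
    if not (0.0 <= profile.bad_rate <= 1.0 and 0.0 <= profile.trash_rate <= 1.0):
        raise ValueError("bad_rate and trash_rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def render_image(
    profile: BoarProfile,
    angle: str,
    size: int | None = None,
    seed: int = 0,
    params: GeneratorParams = DEFAULT_PARAMS,
) -> UltrasoundImage:
    """Render one synthetic B-mode-like image of the given boar.

    The background is log-compressed exponential speckle.  The central
    region (the box later retained by cropping) is offset by the boar's
    ``echogenicity_shift``.  The vertical view adds a bright horizontal band
    across the upper rows; the horizontal view adds a compact bright blob in
    the upper-left quadrant.  Both structures sit outside the central box
    and their amplitude carries a class-dependent gain.
    """
    if angle not in (HORIZONTAL, VERTICAL):
        raise ValueError(f"unknown angle {angle!r}")
    if size is None:
        size = params.image_size
    if size < 32:
        raise ValueError(f"image size must be >= 32, got {size}")
    rng = np.random.default_rng(seed)
    speckle = rng.exponential(1.0, size=(size, size))
    img = params.speckle_scale * np.log1p(params.speckle_gain * speckle)

    rows, cols = central_box(size, size, params.parenchyma_fraction)
    img[rows, cols] += profile.echogenicity_shift

    cls = 1.0 if profile.true_class == HIGH_QUALITY else 0.0
    if angle == VERTICAL:
        r0, r1 = band_row_range(size, params)
        amp = params.band_base + params.band_class_gain * cls \
            + rng.normal(0.0, params.structure_amp_sd)
        # smooth half-cosine envelope across the band rows
        w = np.sin(np.linspace(0.0, np.pi, r1 - r0))
        img[r0:r1, :] += amp * w[:, None]
    else:
        # compact bright blob, mildly elongated along the probe axis
        cy, cx = blob_center(size, params)
        sx = params.blob_radius_frac * size
        sy = sx / 2.5
        amp = params.blob_base + params.blob_class_gain * cls \
            + rng.normal(0.0, params.structure_amp_sd)
        yy, xx = np.ogrid[:size, :size]
        img += amp * np.exp(-((yy - cy) ** 2.0 / (2.0 * sy * sy)
                              + (xx - cx) ** 2.0 / (2.0 * sx * sx)))

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return UltrasoundImage(profile.boar_id, angle, FULL, pixels)


def simulate_images(
    profile: BoarProfile,
    seed: int = 0,
    size: int | None = None,
    params: GeneratorParams = DEFAULT_PARAMS,
) -> list[UltrasoundImage]:
    """Render all images of a boar (both probe orientations)."""
    n = profile.n_images_horizontal + profile.n_images_vertical
    children = np.random.SeedSequence([seed & 0x7FFFFFFF]).spawn(n)
    out = []
    for k in range(profile.n_images_horizontal):
        out.append(render_image(profile, HORIZONTAL, size,
                                seed=children[k], params=params))
    for k in range(profile.n_images_vertical):
        out.append(render_image(profile, VERTICAL, size,
                                seed=children[profile.n_images_horizontal + k],
                                params=params))
    return out


def records_to_frame(records: Iterable[SemenRecord]) -> pd.DataFrame:
    rows = [(r.boar_id, r.day, r.total_sperm_count, r.motility, r.morphology,
             r.trash_flag) for r in records]
    return pd.DataFrame(rows, columns=["boar_id", "day", "total_sperm_count",
                                       "motility", "morphology", "trash_flag"])


def make_dataset(
    n_boars: int,
    prevalence_underperforming: float | None = None,
    seed: int = 0,
    size: int | None = None,
    params: GeneratorParams = DEFAULT_PARAMS,
) -> Dataset:
    """Simulate a complete dataset: population, histories and images."""
    root = np.random.SeedSequence(seed)
    pop_seed, *boar_seeds = root.spawn(1 + 2 * n_boars)
    profiles = simulate_population(n_boars, prevalence_underperforming,
                                   seed=pop_seed, params=params)
    records: list[SemenRecord] = []
    images: list[UltrasoundImage] = []
    for i, profile in enumerate(profiles):
        records.extend(simulate_semen_history(profile, seed=boar_seeds[2 * i],
                                              params=params))
        hist_seed = int(boar_seeds[2 * i + 1].generate_state(1)[0] & 0x7FFFFFFF)
        images.extend(simulate_images(profile, seed=hist_seed, size=size,
                                      params=params))
    return Dataset(profiles, records_to_frame(records), images)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_dataset(
    profiles: Sequence[BoarProfile],
    records: pd.DataFrame,
    images: Sequence[UltrasoundImage],
    out_dir: str | os.PathLike,
) -> pd.DataFrame:
    """Write PNG images, a records CSV and a manifest CSV; return the manifest.

    Images are named ``<boar_id>_<angle>_<k>.png``.  The manifest has one
    row per image (boar_id, true_class, angle, file) so the reader can
    reconstruct the dataset losslessly.
    """
    if len(records) == 0:
        raise ValueError("record table is empty")
    known = {p.boar_id for p in profiles}
    rec_ids = set(records["boar_id"])
    img_ids = {im.boar_id for im in images}
    if not rec_ids <= known or not img_ids <= known:
        raise ValueError("records/images reference boar_ids absent from profiles: "
                         f"{sorted((rec_ids | img_ids) - known)}")
    out = os.fspath(out_dir)
    os.makedirs(os.path.join(out, "images"), exist_ok=True)
    true_class = {p.boar_id: p.true_class for p in profiles}
    counters: dict[tuple[str, str], int] = {}
    rows = []
    for im in images:
        k = counters.get((im.boar_id, im.angle), 0)
        counters[(im.boar_id, im.angle)] = k + 1
        name = f"{im.boar_id}_{im.angle}_{k}.png"
        Image.fromarray(im.pixels, mode="L").save(os.path.join(out, "images", name))
        rows.append((im.boar_id, true_class[im.boar_id], im.angle, im.region,
                     os.path.join("images", name)))
    manifest = pd.DataFrame(rows, columns=["boar_id", "true_class", "angle",
                                           "region", "file"])
    manifest.to_csv(os.path.join(out, "manifest.csv"), index=False)
    records.to_csv(os.path.join(out, "records.csv"), index=False)
    return manifest


def read_dataset(out_dir: str | os.PathLike) -> Dataset:
    """Read a dataset written by :func:`write_dataset`.

    Profiles are reconstructed from the manifest (only identity and true
    class are recoverable from disk; simulation-only fields are zeroed).
    """
    out = os.fspath(out_dir)
    manifest = pd.read_csv(os.path.join(out, "manifest.csv"))
    records = pd.read_csv(os.path.join(out, "records.csv"))
    images = []
    for row in manifest.itertuples(index=False):
        pixels = np.asarray(Image.open(os.path.join(out, row.file)))
        images.append(UltrasoundImage(row.boar_id, row.angle, row.region, pixels))
    profiles = []
    for boar_id, grp in manifest.groupby("boar_id", sort=True):
        n_h = int((grp["angle"] == HORIZONTAL).sum())
        n_v = int((grp["angle"] == VERTICAL).sum())
        n_coll = int((records["boar_id"] == boar_id).sum())
        profiles.append(BoarProfile(boar_id, grp["true_class"].iloc[0],
                                    max(n_coll, 1), n_h, n_v, 0.0, 0.0, 0.0))
    return Dataset(profiles, records, images)
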