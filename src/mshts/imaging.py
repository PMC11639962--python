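"""Well-image I/O and the image statistics of QD-based aggregation screening.

A well of the screening plate is imaged once; quantum-dot-labeled amyloid
aggregates appear as bright puncta on a dark background.  Two scalar
statistics summarize such images:

* the **aggregation score** — the standard deviation (SD) of pixel
  intensities inside the central 432 x 432 px crop of the well.  Uniform
  (fully inhibited) wells have low SD; wells full of bright aggregates have
  high SD.  The SD is shift-invariant and scales linearly with detector
  gain, so downstream normalization against control wells cancels gain.
* the **deposition score** — the mean gray value over five fixed areas
  (default 1608 x 1608 px each) of a cell-field image, quantifying amyloid
  deposited on the cell surface.

Plate bookkeeping lives in a manifest CSV with columns
``image_path, well_id, sample_id, conc_ug_ml, replicate, role`` where role
is one of ``test``, ``abeta_control`` (aggregation without inhibitor) or
``blank``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MANIFEST_COLUMNS",
    "ROLES",
    "WellImage",
    "AggregationScore",
    "DepositionScore",
    "CropError",
    "read_image",
    "write_image",
    "read_manifest",
    "write_manifest",
    "to_gray",
    "central_crop",
    "crop_origin",
    "sd_statistic",
    "default_areas",
    "mean_gray",
    "score_wells",
    "score_plate",
]

MANIFEST_COLUMNS = ["image_path", "well_id", "sample_id", "conc_ug_ml", "replicate", "role"]
ROLES = frozenset({"test", "abeta_control", "blank"})

#: RGB -> gray conversion policies.  "red" is the default: QD605 emission
#: imaged through a TRITC filter lands almost entirely on the red plane of
#: a color camera.  "luminance" uses the Rec. 601 weights.
GRAY_POLICIES = ("red", "green", "blue", "luminance", "mean")


class CropError(ValueError):
    """Requested crop does not fit inside the image."""


@dataclass
class WellImage:
    """One well's intensity raster plus minimal metadata.

    ``pixels`` is either a 2-D array (single channel) or an (H, W, 3) RGB
    array.  Intensities must be non-negative and within the bit-depth range.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    channel_tag: str = "gray"
    well_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError(f"3-D images must have 3 channels, got {self.pixels.shape[2]}")
        if min(self.pixels.shape[:2]) < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.size:
            lo = float(self.pixels.min())
            hi = float(self.pixels.max())
            if lo < 0 or hi > 2**self.bit_depth - 1:
                raise ValueError(
                    f"intensities [{lo}, {hi}] outside {self.bit_depth}-bit range"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class AggregationScore:
    """SD aggregation score of one well's central crop."""

    well_id: str
    sd_raw: float
    crop_origin: tuple[int, int]
    crop_size: int

    def __post_init__(self) -> None:
        if self.sd_raw < 0:
            raise ValueError("sd_raw must be >= 0")


@dataclass
class DepositionScore:
    """Mean gray values of five areas and their overall mean."""

    well_id: str
    area_means: list[float]
    mean_of_means: float
    area_size: int

    def __post_init__(self) -> None:
        if len(self.area_means) != 5:
            raise ValueError(f"exactly 5 areas required, got {len(self.area_means)}")
        expect = float(np.mean(self.area_means))
        if not np.isclose(self.mean_of_means, expect, rtol=1e-12, atol=1e-9):
            raise ValueError("mean_of_means must equal the mean of area_means")


# ---------------------------------------------------------------------------
# I/O

def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    return 16


def read_image(path: str | Path, well_id: str | None = None) -> WellImage:
    """Read a TIFF or PNG well image (8/16-bit, gray or RGB)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {path}")
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    tag = "gray" if arr.ndim == 2 else "rgb"
    return WellImage(arr, bit_depth=_bit_depth_of(arr), channel_tag=tag,
                     well_id=well_id or path.stem)


def write_image(image: WellImage, path: str | Path) -> Path:
    """Write a well image as TIFF or PNG, preserving bit depth."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    arr = np.asarray(np.clip(np.rint(image.pixels), 0, 2**image.bit_depth - 1), dtype=dtype)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image format: {path}")
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    bad = set(df["role"].unique()) - ROLES
    if bad:
        raise ValueError(f"manifest {path} has unknown roles {sorted(bad)}")
    df = df[MANIFEST_COLUMNS].copy()
    df["conc_ug_ml"] = df["conc_ug_ml"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest[MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# statistics

def to_gray(image: WellImage, policy: str = "red") -> WellImage:
    """Collapse an RGB well image to a single channel.

    Single-channel input passes through unchanged.  The default ``red``
    policy extracts the red plane, where the QD605/TRITC signal lives.
    """
    if policy not in GRAY_POLICIES:
        raise ValueError(f"unknown gray policy {policy!r}; choose from {GRAY_POLICIES}")
    if image.pixels.ndim == 2:
        return image
    planes = image.pixels.astype(float)
    if policy in ("red", "green", "blue"):
        gray = planes[:, :, ("red", "green", "blue").index(policy)]
    elif policy == "luminance":
        gray = 0.299 * planes[:, :, 0] + 0.587 * planes[:, :, 1] + 0.114 * planes[:, :, 2]
    else:  # mean
        gray = planes.mean(axis=2)
    return WellImage(gray, bit_depth=image.bit_depth, channel_tag="gray",
                     well_id=image.well_id)


def crop_origin(shape: tuple[int, int], size: int) -> tuple[int, int]:
    """0-based origin of the centered size x size crop: floor((dim - size)/2)."""
    h, w = shape[:2]
    if size > h or size > w:
        raise CropError(f"crop size {size} exceeds image shape {h}x{w}")
    return ((h - size) // 2, (w - size) // 2)


def central_crop(image: WellImage | np.ndarray, size: int = 432) -> tuple[np.ndarray, tuple[int, int]]:
    """Return the central size x size block (half-open indexing) and its origin."""
    pixels = image.pixels if isinstance(image, WellImage) else np.asarray(image)
    r0, c0 = crop_origin(pixels.shape[:2], size)
    return pixels[r0:r0 + size, c0:c0 + size], (r0, c0)


def sd_statistic(region: np.ndarray, ddof: int = 0) -> float:
    """Standard deviation of all intensities in a region.

    Population SD (divisor N, ``ddof=0``) by default, matching common
    image-measurement practice; the divisor is configurable.
    """
    region = np.asarray(region, dtype=float)
    if region.size == 0:
        raise ValueError("cannot compute SD of an empty region")
    return float(np.std(region, ddof=ddof))


def default_areas(shape: tuple[int, int], area_size: int) -> list[tuple[int, int]]:
    """Five area origins: four corners + center.  Areas may overlap on small fields."""
    h, w = shape[:2]
    if area_size > h or area_size > w:
        raise CropError(f"area size {area_size} exceeds image shape {h}x{w}")
    r1, c1 = h - area_size, w - area_size
    return [(0, 0), (0, c1), (r1, 0), (r1, c1), (r1 // 2, c1 // 2)]


def mean_gray(image: WellImage, areas: Sequence[tuple[int, int]] | None = None,
              area_size: int = 1608, gray_policy: str = "red") -> DepositionScore:
    """Deposition score: mean gray value in five areas plus their overall mean.

    ``areas`` are 0-based (row, col) origins of area_size x area_size blocks;
    the default layout is four corners + center of the field.
    """
    gray = to_gray(image, gray_policy)
    pixels = np.asarray(gray.pixels, dtype=float)
    if areas is None:
        areas = default_areas(pixels.shape, area_size)
    if len(areas) != 5:
        raise ValueError(f"exactly 5 areas required, got {len(areas)}")
    h, w = pixels.shape[:2]
    means = []
    for i, (r0, c0) in enumerate(areas):
        if r0 < 0 or c0 < 0 or r0 + area_size > h or c0 + area_size > w:
            raise CropError(
                f"area {i} at origin ({r0}, {c0}) size {area_size} "
                f"does not fit inside {h}x{w} image"
            )
        means.append(float(pixels[r0:r0 + area_size, c0:c0 + area_size].mean()))
    return DepositionScore(well_id=image.well_id, area_means=means,
                           mean_of_means=float(np.mean(means)), area_size=area_size)


# ---------------------------------------------------------------------------
# plate scoring

_SCORE_COLUMNS = ["well_id", "sample_id", "conc_ug_ml", "replicate", "role", "sd_raw",
                  "crop_origin_row", "crop_origin_col", "crop_size", "error"]


def _score_one(image: WellImage, crop_size: int, ddof: int, gray_policy: str) -> AggregationScore:
    gray = to_gray(image, gray_policy)
    region, origin = central_crop(gray, crop_size)
    return AggregationScore(well_id=image.well_id, sd_raw=sd_statistic(region, ddof=ddof),
                            crop_origin=origin, crop_size=crop_size)


def _assemble(manifest: pd.DataFrame, results: list[dict]) -> pd.DataFrame:
    out = pd.DataFrame(results, columns=_SCORE_COLUMNS)
    n_fail = int(out["error"].notna().sum())
    if len(out) and n_fail / len(out) > 0.5:
        raise RuntimeError(
            f"{n_fail} of {len(out)} wells failed to score; aborting "
            "(more than half the plate is unreadable)"
        )
    return out


def score_wells(manifest: pd.DataFrame, images: Mapping[str, WellImage],
                crop_size: int = 432, ddof: int = 0, gray_policy: str = "red") -> pd.DataFrame:
    """Score in-memory well images against a manifest (one row per well)."""
    results = []
    for row in manifest.itertuples(index=False):
        rec = dict(well_id=row.well_id, sample_id=row.sample_id, conc_ug_ml=row.conc_ug_ml,
                   replicate=row.replicate, role=row.role, sd_raw=np.nan,
                   crop_origin_row=-1, crop_origin_col=-1, crop_size=crop_size, error=None)
        try:
            score = _score_one(images[row.well_id], crop_size, ddof, gray_policy)
            rec.update(sd_raw=score.sd_raw, crop_origin_row=score.crop_origin[0],
                       crop_origin_col=score.crop_origin[1])
        except Exception as exc:  # per-well failures are recorded, not raised
            rec["error"] = f"{type(exc).__name__}: {exc}"
        results.append(rec)
    return _assemble(manifest, results)


def score_plate(manifest: pd.DataFrame | str | Path, base_dir: str | Path | None = None,
                crop_size: int = 432, ddof: int = 0, gray_policy: str = "red") -> pd.DataFrame:
    """Score every well image referenced by a manifest.

    Unreadable or undersized images produce a per-row ``error`` entry rather
    than a silent skip; if more than half the rows fail, a run-level error
    is raised.
    """
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        if base_dir is None:
            base_dir = path.parent
        manifest = read_manifest(path)
    base = Path(base_dir) if base_dir is not None else Path(".")
    results = []
    for row in manifest.itertuples(index=False):
        rec = dict(well_id=row.well_id, sample_id=row.sample_id, conc_ug_ml=row.conc_ug_ml,
                   replicate=row.replicate, role=row.role, sd_raw=np.nan,
                   crop_origin_row=-1, crop_origin_col=-1, crop_size=crop_size, error=None)
        img_path = Path(row.image_path)
        if not img_path.is_absolute():
            img_path = base / img_path
        try:
            image = read_image(img_path, well_id=row.well_id)
            score = _score_one(image, crop_size, ddof, gray_policy)
            rec.update(sd_raw=score.sd_raw, crop_origin_row=score.crop_origin[0],
                       crop_origin_col=score.crop_origin[1])
        except Exception as exc:
            rec["error"] = f"{type(exc).__name__}: {exc}"
        results.append(rec)
    return _assemble(manifest, results)
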