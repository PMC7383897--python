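"""Threshold-based image analysis of stained cell fields and channel frames.

Two imaging tasks back the purification workflow:

* **Cytospin fields** — Giemsa-type bright-field images of cells spun
  onto a slide: dark objects on a light background.  Objects are
  detected by global thresholding and connected components, then sorted
  into three classes from two features: projected area and the fraction
  of object pixels darker than a nuclear-stain cutoff ("dark fraction").
  Small, uniformly dark objects are free nuclei; larger objects with a
  dark core are nucleated cells; larger objects without one are
  enucleated cells.
* **In-channel frames** — high-speed snapshots of cells inside the
  spiral channel; detected centroids are converted to lateral positions
  in µm from the outer wall.

A synthetic renderer produces both kinds of image with exact ground
truth, so every detection/classification rule is testable against known
fields.  Deformable cells spread on the slide and appear larger than
they are; the renderer exposes this as an optional per-class area
inflation factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import draw, filters, measure

from .errors import ConfigError, InputError

#: default grey levels of the renderer (8-bit, dark objects on light field)
DEFAULT_LEVELS = {"background": 220.0, "cytoplasm": 150.0, "nucleus": 60.0}
#: intensity below which a pixel counts as nuclear (dense chromatin) stain;
#: midway between the typical cytoplasm and nuclear grey levels
DEFAULT_DARK_CUTOFF = 110.0


@dataclass(frozen=True)
class PlantedObject:
    """Ground-truth object: class, centre (px), physical diameter (µm)."""

    cell_class: str
    x_px: float
    y_px: float
    diameter_um: float


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for a rendered field with ground truth."""

    shape_px: tuple[int, int]  # (height, width)
    um_per_px: float
    objects: Sequence[PlantedObject] = ()
    background: float = DEFAULT_LEVELS["background"]
    noise_sd: float = 0.0
    levels: Mapping[str, float] | None = None
    nucleus_core_ratio: float = 0.55  # core diameter / cell diameter
    spread_factors: Mapping[str, float] | None = None  # per-class area inflation
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ConfigError("um_per_px must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def _radius_px(obj: PlantedObject, spec: SyntheticImageSpec) -> float:
    inflate = (spec.spread_factors or {}).get(obj.cell_class, 1.0)
    # an area inflation factor f scales the radius by sqrt(f)
    return (obj.diameter_um / 2.0) * math.sqrt(inflate) / spec.um_per_px


def render_cytospin(
    spec: SyntheticImageSpec, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a field and return (uint8 image, ground-truth table).

    Enucleated cells are uniform mid-grey disks; nucleated cells carry a
    darker concentric core; free nuclei are small dark disks.  Gaussian
    noise of ``noise_sd`` grey levels is added.  Objects must lie fully
    inside the frame, and must not overlap unless the spec allows it.
    """
    levels = dict(DEFAULT_LEVELS, **(spec.levels or {}))
    h, w = spec.shape_px
    img = np.full((h, w), float(spec.background))
    occupied = np.zeros((h, w), dtype=bool)
    truth = []
    for i, obj in enumerate(spec.objects):
        r = _radius_px(obj, spec)
        if not (r <= obj.x_px <= w - 1 - r and r <= obj.y_px <= h - 1 - r):
            raise ConfigError(f"object {i} not fully inside the frame")
        rr, cc = draw.disk((obj.y_px, obj.x_px), r, shape=(h, w))
        if not spec.allow_overlap and occupied[rr, cc].any():
            raise ConfigError(f"object {i} overlaps an earlier object")
        occupied[rr, cc] = True
        if obj.cell_class == "nucleus":
            img[rr, cc] = levels["nucleus"]
        else:
            img[rr, cc] = levels["cytoplasm"]
            if obj.cell_class == "nucleated":
                rr2, cc2 = draw.disk(
                    (obj.y_px, obj.x_px), r * spec.nucleus_core_ratio, shape=(h, w)
                )
                img[rr2, cc2] = levels["nucleus"]
        truth.append(
            {
                "object_id": i,
                "class": obj.cell_class,
                "x_px": obj.x_px,
                "y_px": obj.y_px,
                "diameter_um": obj.diameter_um,
                "area_um2": math.pi * obj.diameter_um**2 / 4.0,
            }
        )
    if spec.noise_sd:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    columns = ["object_id", "class", "x_px", "y_px", "diameter_um", "area_um2"]
    return img, pd.DataFrame(truth, columns=columns)


# ------------------------------------------------------------ segmentation


@dataclass
class SegmentedObject:
    """One detected connected component and its extracted features."""

    object_id: int
    centroid_x_px: float
    centroid_y_px: float
    area_um2: float
    equivalent_diameter_um: float
    mean_intensity: float
    dark_fraction: float
    assigned_class: str | None = None


def segment_objects(
    image: np.ndarray,
    um_per_px: float,
    threshold: float | None = None,
    min_area_um2: float = 15.0,
    dark_cutoff: float = DEFAULT_DARK_CUTOFF,
    invert: bool = False,
    smooth_sigma_px: float = 1.0,
) -> list[SegmentedObject]:
    """Detect dark objects by global thresholding + connected components.

    The image is lightly Gaussian-smoothed (``smooth_sigma_px``, set 0 to
    disable) before thresholding so shot noise does not shatter into
    spurious components.  The threshold defaults to Otsu's bimodal split
    of the grey histogram; pass a fixed value to override.  Components
    smaller than ``min_area_um2`` are dropped.  ``dark_fraction`` of each
    object is the share of its pixels below ``dark_cutoff`` — the feature
    that reveals a stained nucleus.  A blank or constant image yields an
    empty list.  Set ``invert`` for light-objects-on-dark imagery.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InputError("expected a single-channel (grayscale) image")
    if invert:
        img = img.max() - img
    if um_per_px <= 0:
        raise InputError("um_per_px must be positive")
    if np.ptp(img) == 0:
        return []
    smoothed = (
        filters.gaussian(img, sigma=smooth_sigma_px, preserve_range=True)
        if smooth_sigma_px > 0
        else img
    )
    thr = (
        float(filters.threshold_otsu(smoothed)) if threshold is None else float(threshold)
    )
    mask = smoothed < thr
    labelled = measure.label(mask, connectivity=2)
    objects: list[SegmentedObject] = []
    scale2 = um_per_px**2
    for prop in measure.regionprops(labelled, intensity_image=img):
        area_um2 = prop.area * scale2
        if area_um2 < min_area_um2:
            continue
        pixels = prop.image_intensity[prop.image]
        objects.append(
            SegmentedObject(
                object_id=len(objects),
                centroid_x_px=float(prop.centroid[1]),
                centroid_y_px=float(prop.centroid[0]),
                area_um2=float(area_um2),
                equivalent_diameter_um=float(2.0 * math.sqrt(area_um2 / math.pi)),
                mean_intensity=float(pixels.mean()),
                dark_fraction=float(np.mean(pixels < dark_cutoff)),
            )
        )
    return objects


def classify_objects(
    objects: Sequence[SegmentedObject],
    nucleus_max_area_um2: float = 35.0,
    dark_fraction_cut: float = 0.1,
) -> tuple[list[SegmentedObject], dict[str, int]]:
    """Assign the three classes from area and dark fraction.

    Small dark objects are free nuclei; larger objects with at least
    ``dark_fraction_cut`` dark pixels are nucleated, the rest enucleated.
    Returns the objects (with ``assigned_class`` set) and class counts.
    """
    counts = {"enucleated": 0, "nucleated": 0, "nucleus": 0}
    out = []
    for obj in objects:
        if obj.dark_fraction >= dark_fraction_cut:
            cls = "nucleus" if obj.area_um2 <= nucleus_max_area_um2 else "nucleated"
        else:
            cls = "enucleated"
        obj.assigned_class = cls
        counts[cls] += 1
        out.append(obj)
    return out, counts


def objects_to_frame(objects: Sequence[SegmentedObject]) -> pd.DataFrame:
    """Feature table in the canonical CSV column order."""
    return pd.DataFrame(
        [
            {
                "object_id": o.object_id,
                "class": o.assigned_class,
                "area_um2": o.area_um2,
                "diameter_um": o.equivalent_diameter_um,
                "dark_fraction": o.dark_fraction,
                "x_px": o.centroid_x_px,
                "y_px": o.centroid_y_px,
            }
            for o in objects
        ],
        columns=[
            "object_id", "class", "area_um2", "diameter_um",
            "dark_fraction", "x_px", "y_px",
        ],
    )


# -------------------------------------------------------- channel frames


@dataclass(frozen=True)
class ChannelFrameSpec:
    """Geometry linking a channel snapshot to physical lateral positions.

    The lateral axis is x; ``wall_x_px`` is the pixel column of the outer
    wall and ``direction`` +1 when the channel interior lies toward
    larger x.  Positions are (x - wall) * um_per_px * direction.
    """

    wall_x_px: float
    um_per_px: float
    channel_width_um: float = 170.0
    direction: int = 1

    def __post_init__(self) -> None:
        if self.um_per_px <= 0 or self.channel_width_um <= 0:
            raise ConfigError("scale and channel width must be positive")
        if self.direction not in (-1, 1):
            raise ConfigError("direction must be +1 or -1")

    def position_um(self, x_px: float) -> float:
        return (x_px - self.wall_x_px) * self.um_per_px * self.direction


def extract_lateral_positions(
    frame: np.ndarray,
    spec: ChannelFrameSpec,
    threshold: float | None = None,
    min_area_um2: float = 5.0,
) -> tuple[np.ndarray, int]:
    """Detected-cell lateral positions, µm from the outer wall.

    Objects are detected as in :func:`segment_objects`; centroids mapping
    outside [0, channel width] are flagged and excluded.  Returns the
    kept positions and the number excluded.
    """
    objects = segment_objects(
        frame, spec.um_per_px, threshold=threshold, min_area_um2=min_area_um2
    )
    positions = np.array([spec.position_um(o.centroid_x_px) for o in objects])
    in_range = (positions >= 0) & (positions <= spec.channel_width_um)
    return positions[in_range], int((~in_range).sum())


def render_channel_frame(
    spec: ChannelFrameSpec,
    positions_um: Sequence[float],
    diameter_um: float = 8.0,
    spacing_px: int = 25,
    background: float = DEFAULT_LEVELS["background"],
    level: float = 80.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic in-channel frame: one blob per requested position.

    Blobs are laid out down the flow axis at ``spacing_px`` intervals at
    the pixel columns implied by the frame geometry; positions must
    leave the blob fully inside the channel image.
    """
    r_px = (diameter_um / 2.0) / spec.um_per_px
    margin = int(math.ceil(r_px)) + 2
    span_px = spec.channel_width_um / spec.um_per_px
    far_edge = spec.wall_x_px + (span_px if spec.direction == 1 else 0.0)
    width_px = int(math.ceil(far_edge)) + margin
    height_px = spacing_px * (len(positions_um) + 1)
    img = np.full((height_px, width_px), float(background))
    h, w = img.shape
    for i, pos in enumerate(positions_um):
        x = spec.wall_x_px + spec.direction * pos / spec.um_per_px
        y = spacing_px * (i + 1)
        if not (r_px <= x <= w - 1 - r_px):
            raise ConfigError(f"position {pos} µm does not fit in the frame")
        rr, cc = draw.disk((y, x), r_px, shape=img.shape)
        img[rr, cc] = level
    if noise_sd:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# -------------------------------------------------------------------- I/O


def write_image(image: np.ndarray, path) -> None:
    iio.imwrite(path, image)


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB(A) scans to grey
        img = img[..., :3].mean(axis=-1)
    return np.asarray(img)
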