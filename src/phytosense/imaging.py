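"""Plant segmentation and image-derived phenotyping indices.

From each plant's three-view RGB/NIR image set the pipeline derives:

* digital biovolume  DB = (A_side0 + A_side90 + log10(A_top)) / 3, a pixel
  proxy for aerial mass built from the two side silhouettes and the top view,
* plant height, the vertical pixel extent of the side-view silhouettes,
* compactness  C = plant area / convex-hull area (canopy closure; top view
  by default),
* green index  GI, the fraction of plant pixels whose hue falls in a green
  window (healthy vs chlorotic/necrotic tissue),
* NIR intensity  NI, the 128-bin weighted-mean intensity of plant pixels in
  the near-infrared image, a hydration proxy.

Segmentation is a hue/saturation gate (vegetation hue band against a uniform
non-plant background) followed by a largest-connected-component filter; NIR
views are thresholded against the stated background level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage.color import rgb2hsv
from skimage.measure import label

__all__ = [
    "PlantImageSet",
    "PlantMask",
    "IndexRecord",
    "SegmentationSpec",
    "ImagingConfig",
    "EmptyMaskError",
    "segment_plant",
    "compute_biovolume",
    "compute_height",
    "compute_compactness",
    "compute_green_index",
    "compute_nir_index",
    "extract_indices",
]

VIEWS = ("side0", "side90", "top")


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty plant mask."""


@dataclass
class PlantImageSet:
    """Three-view RGB + NIR images of one plant at one timepoint.

    ``images`` maps (view, modality) to 8-bit arrays (RGB: HxWx3, NIR: HxW),
    row 0 at the top of the image. ``truth_masks`` is optional renderer ground
    truth used in validation, never by the pipeline itself.
    """

    plant_id: str
    day: int
    images: dict[tuple[str, str], np.ndarray]
    truth_masks: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        shapes = {img.shape[:2] for img in self.images.values()}
        if len(shapes) > 1:
            raise ValueError("all views in a set must share dimensions")
        for key, img in self.images.items():
            if img.dtype != np.uint8:
                raise ValueError(f"image {key} is not 8-bit")


@dataclass
class PlantMask:
    mask: np.ndarray
    view: str

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def empty(self) -> bool:
        return self.area_px == 0


@dataclass
class IndexRecord:
    """The five image-derived indices for one plant-timepoint.

    Missing views yield None fields, never silent zeros.
    """

    plant_id: str
    day: int
    biovolume: float | None
    height_px: float | None
    compactness: float | None
    green_index: float | None
    nir_index: float | None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SegmentationSpec:
    """Background/foreground separation parameters.

    Vegetation hue spans green, yellow and brown bands; saturation must exceed
    ``sat_min`` so the near-neutral background cannot leak in. ``nir_background``
    is the uniform background level of NIR views.
    """

    vegetation_hue_deg: tuple[float, float] = (25.0, 185.0)
    sat_min: float = 0.15
    value_min: float = 0.05
    nir_background: float = 20.0
    nir_margin: float = 15.0


@dataclass(frozen=True)
class ImagingConfig:
    segmentation: SegmentationSpec = field(default_factory=SegmentationSpec)
    green_hue_deg: tuple[float, float] = (60.0, 180.0)
    compactness_view: str = "top"
    biovolume_log_view: str = "top"


def segment_plant(
    image: np.ndarray, modality: str, spec: SegmentationSpec | None = None,
    view: str = "",
) -> PlantMask:
    """Segment plant pixels in one view.

    RGB: keep pixels whose hue lies in the vegetation window and whose
    saturation (and value) pass the thresholds. NIR: keep pixels brighter than
    the background level plus a margin. Only the largest connected component
    is retained; an empty result is returned flagged (``PlantMask.empty``),
    not raised, so callers can record missing indices.
    """
    spec = spec or SegmentationSpec()
    if modality == "rgb":
        hsv = rgb2hsv(image)
        hue = hsv[..., 0] * 360.0
        lo, hi = spec.vegetation_hue_deg
        raw = (
            (hue >= lo) & (hue <= hi)
            & (hsv[..., 1] > spec.sat_min)
            & (hsv[..., 2] > spec.value_min)
        )
    elif modality == "nir":
        raw = image.astype(float) > spec.nir_background + spec.nir_margin
    else:
        raise ValueError(f"unknown modality {modality!r}")

    if not raw.any():
        return PlantMask(np.zeros_like(raw, dtype=bool), view)
    lab = label(raw, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return PlantMask(lab == int(np.argmax(counts)), view)


def compute_biovolume(
    area_side0: "PlantMask | int",
    area_side90: "PlantMask | int",
    area_top: "PlantMask | int",
) -> float:
    """Digital biovolume (A_side0 + A_side90 + log10(A_top)) / 3.

    A zero top area sets the log term to 0 with a warning.
    """
    a0 = area_side0.area_px if isinstance(area_side0, PlantMask) else int(area_side0)
    a90 = area_side90.area_px if isinstance(area_side90, PlantMask) else int(area_side90)
    at = area_top.area_px if isinstance(area_top, PlantMask) else int(area_top)
    if at > 0:
        log_term = math.log10(at)
    else:
        warnings.warn("top-view area is 0; log term set to 0", stacklevel=2)
        log_term = 0.0
    return (a0 + a90 + log_term) / 3.0


def _extent_rows(mask: np.ndarray) -> int:
    rows = np.nonzero(mask.any(axis=1))[0]
    return int(rows[-1] - rows[0] + 1)


def compute_height(
    mask_side0: PlantMask | None, mask_side90: PlantMask | None
) -> float:
    """Mean vertical pixel extent over the available (non-empty) side views."""
    extents = [
        _extent_rows(m.mask)
        for m in (mask_side0, mask_side90)
        if m is not None and not m.empty
    ]
    if not extents:
        raise EmptyMaskError("both side views empty")
    return float(np.mean(extents))


def compute_compactness(mask: PlantMask) -> float:
    """Plant area over the area of the convex hull of the plant region.

    The hull is taken over the corner points of the occupied pixel squares
    (not pixel centers), so a filled convex region scores exactly 1.
    """
    if mask.empty:
        raise EmptyMaskError("cannot compute compactness of an empty mask")
    rr, cc = np.nonzero(mask.mask)
    corners = np.concatenate(
        [
            np.stack([rr, cc], axis=1),
            np.stack([rr + 1, cc], axis=1),
            np.stack([rr, cc + 1], axis=1),
            np.stack([rr + 1, cc + 1], axis=1),
        ]
    ).astype(float)
    hull_area = ConvexHull(corners).volume  # 2-D "volume" is area
    return mask.area_px / hull_area


def compute_green_index(
    rgb: np.ndarray, mask: PlantMask, hue_window_deg: tuple[float, float] = (60.0, 180.0)
) -> float:
    """Fraction of plant pixels whose hue lies in the green window."""
    if mask.empty:
        raise EmptyMaskError("cannot compute green index of an empty mask")
    hue = rgb2hsv(rgb)[..., 0][mask.mask] * 360.0
    lo, hi = hue_window_deg
    return float(np.mean((hue >= lo) & (hue <= hi)))


def compute_nir_index(nir: np.ndarray, mask: PlantMask, n_bins: int = 128) -> float:
    """Weighted-mean plant-pixel NIR intensity over ``n_bins`` equal bins.

    Intensities are histogrammed into ``n_bins`` bins spanning [0, 256); the
    index is sum(bin_center * count) / sum(count), which stays within half a
    bin width of the plain pixel mean.
    """
    if mask.empty:
        raise EmptyMaskError("cannot compute NIR index of an empty mask")
    px = nir[mask.mask].astype(float)
    width = 256.0 / n_bins
    idx = np.clip((px // width).astype(int), 0, n_bins - 1)
    centers = (idx + 0.5) * width
    return float(np.mean(centers))


def extract_indices(
    image_set: PlantImageSet, config: ImagingConfig | None = None
) -> IndexRecord:
    """Segment every view and compute all five indices for one image set."""
    config = config or ImagingConfig()
    flags: list[str] = []

    rgb_masks: dict[str, PlantMask | None] = {}
    nir_masks: dict[str, PlantMask | None] = {}
    for view in VIEWS:
        for modality, store in (("rgb", rgb_masks), ("nir", nir_masks)):
            img = image_set.images.get((view, modality))
            if img is None:
                store[view] = None
                flags.append(f"missing:{view}/{modality}")
                continue
            m = segment_plant(img, modality, config.segmentation, view)
            if m.empty:
                flags.append(f"empty_mask:{view}/{modality}")
                store[view] = None
            else:
                store[view] = m

    if all(m is None for m in rgb_masks.values()):
        raise EmptyMaskError(f"no plant found in any view of {image_set.plant_id}")

    biovolume = None
    if all(rgb_masks.get(v) is not None for v in VIEWS):
        biovolume = compute_biovolume(
            rgb_masks["side0"], rgb_masks["side90"], rgb_masks["top"]
        )

    height = None
    if rgb_masks.get("side0") is not None or rgb_masks.get("side90") is not None:
        height = compute_height(rgb_masks.get("side0"), rgb_masks.get("side90"))

    compactness = None
    cmask = rgb_masks.get(config.compactness_view)
    if cmask is not None:
        compactness = compute_compactness(cmask)

    green = None
    gmask = rgb_masks.get("top") or rgb_masks.get("side0")
    if gmask is not None:
        green = compute_green_index(
            image_set.images[(gmask.view, "rgb")], gmask, config.green_hue_deg
        )

    nir_index = None
    nmask = nir_masks.get("top") or nir_masks.get("side0")
    if nmask is not None:
        nir_index = compute_nir_index(image_set.images[(nmask.view, "nir")], nmask)

    return IndexRecord(
        plant_id=image_set.plant_id,
        day=image_set.day,
        biovolume=biovolume,
        height_px=height,
        compactness=compactness,
        green_index=green,
        nir_index=nir_index,
        flags=tuple(flags),
    )


def indices_to_frame(records: list[IndexRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plant_id": r.plant_id,
                "day": r.day,
                "biovolume": r.biovolume,
                "height_px": r.height_px,
                "compactness": r.compactness,
                "green_index": r.green_index,
                "nir_index": r.nir_index,
            }
            for r in records
        ]
    )
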