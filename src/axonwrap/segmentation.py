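"""Binary-mask generation and object detection on assay stacks.

Turns the three intensity channels into thresholded binary masks, detects
axon pillars as per-slice connected components linked across z by centroid
proximity (pillars are vertical, so no general 3D tracking is needed), and
counts nuclei on a maximum-intensity projection of the nuclei masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from .io import ImageStack, ValidationError

__all__ = [
    "SegmentationConfig",
    "BinaryMaskStack",
    "AxonRegion",
    "threshold_channel",
    "detect_axons",
    "count_nuclei",
]

logger = logging.getLogger(__name__)

THRESHOLD_METHODS = ("otsu_per_slice", "otsu_global", "fixed")


@dataclass
class SegmentationConfig:
    """Thresholding and object-detection parameters (pixel units)."""

    threshold_method: str = "otsu_per_slice"
    threshold_value: float | None = None  # for method="fixed"
    # Channels that may contain signal-free slices (myelin, nuclei) default to
    # a global Otsu threshold: per-slice Otsu misbehaves on unimodal
    # noise-only slices, flooding them with false foreground.
    myelin_threshold_method: str = "otsu_global"
    nuclei_threshold_method: str = "otsu_global"
    cleanup_min_area_px: int = 0  # remove smaller objects from masks (0 = off)
    fill_holes: bool = False
    axon_link_tolerance_px: float = 6.0  # ~ pillar radius at 0.65 um/px
    axon_min_area_px: int = 10
    axon_max_area_px: int = 100_000
    nuclei_min_area_px: int = 5
    nuclei_watershed: bool = False


@dataclass
class BinaryMaskStack:
    """Boolean masks (z, y, x) for one channel plus the threshold record."""

    masks: np.ndarray
    method: str
    thresholds: list[float | None]  # per-slice threshold actually applied

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValidationError("masks must be (z, y, x)")
        if len(self.thresholds) != self.masks.shape[0]:
            raise ValidationError("one threshold record required per slice")


@dataclass
class AxonRegion:
    """One pillar tracked across z-slices.

    ``slice_pixels`` maps slice index -> (rows, cols) pixel coordinate arrays;
    a pillar may be absent from some slices.  ``border_touching`` regions are
    flagged here and excluded from all downstream counts, since a pillar cut
    by the field border has an unobservable circumference.
    """

    axon_id: int
    slice_pixels: dict[int, tuple[np.ndarray, np.ndarray]]
    centroid: tuple[float, float]  # reference (y, x), px
    border_touching: bool = False

    @property
    def slices_present(self) -> list[int]:
        return sorted(self.slice_pixels)


def _threshold_slice(plane: np.ndarray, method: str, value: float | None):
    if method == "fixed":
        return plane > value, float(value)
    if plane.max() == plane.min():
        logger.warning("constant-intensity slice: falling back to all-background")
        return np.zeros(plane.shape, dtype=bool), None
    t = float(threshold_otsu(plane))
    return plane > t, t


def threshold_channel(
    stack: ImageStack,
    channel: str,
    config: SegmentationConfig | None = None,
    method: str | None = None,
) -> BinaryMaskStack:
    """Threshold one channel of a stack into per-slice binary masks.

    Methods: ``otsu_per_slice`` (default; independent Otsu threshold per
    z-slice), ``otsu_global`` (one Otsu threshold over the whole channel) or
    ``fixed`` (explicit ``threshold_value``).  A constant-intensity slice
    under Otsu falls back to all-background with a logged warning.  Optional
    cleanup removes objects below ``cleanup_min_area_px`` and fills holes.
    """
    config = config or SegmentationConfig()
    if method is None:
        method = config.threshold_method
    if method not in THRESHOLD_METHODS:
        raise ValidationError(
            f"unknown threshold method {method!r}; choose from {THRESHOLD_METHODS}"
        )
    if method == "fixed" and config.threshold_value is None:
        raise ValidationError("fixed thresholding requires threshold_value")
    data = stack.channel(channel)
    masks = np.zeros(data.shape, dtype=bool)
    thresholds: list[float | None] = []
    if method == "otsu_global":
        if data.max() == data.min():
            logger.warning("constant-intensity channel: all-background masks")
            thresholds = [None] * data.shape[0]
        else:
            t = float(threshold_otsu(data))
            masks = data > t
            thresholds = [t] * data.shape[0]
    else:
        value = config.threshold_value
        slice_method = "fixed" if method == "fixed" else "otsu"
        for z in range(data.shape[0]):
            masks[z], t = _threshold_slice(data[z], slice_method, value)
            thresholds.append(t)
    if config.cleanup_min_area_px > 1:
        for z in range(masks.shape[0]):
            masks[z] = _drop_small(masks[z], config.cleanup_min_area_px)
    if config.fill_holes:
        for z in range(masks.shape[0]):
            masks[z] = ndimage.binary_fill_holes(masks[z])
    return BinaryMaskStack(masks, method, thresholds)


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components with area below min_area (8-connectivity)."""
    lbl = label(mask, connectivity=2)
    if lbl.max() == 0:
        return mask
    counts = np.bincount(lbl.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[lbl]


def detect_axons(
    axon_masks: BinaryMaskStack, config: SegmentationConfig | None = None
) -> list[AxonRegion]:
    """Detect pillars as 8-connected components linked across z.

    Components within one slice whose area is outside
    ``[axon_min_area_px, axon_max_area_px]`` are discarded.  A component is
    attached to the existing region whose reference centroid is nearest and
    within ``axon_link_tolerance_px``; otherwise it founds a new region.
    Regions touching the field border in any slice are flagged
    ``border_touching``.
    """
    config = config or SegmentationConfig()
    masks = axon_masks.masks
    nz, h, w = masks.shape
    regions: list[dict] = []  # working records
    for z in range(nz):
        lbl = label(masks[z], connectivity=2)
        for prop in regionprops(lbl):
            if not (config.axon_min_area_px <= prop.area <= config.axon_max_area_px):
                continue
            cy, cx = prop.centroid
            best, best_d = None, np.inf
            for rec in regions:
                if z in rec["slice_pixels"]:
                    continue  # one component per region per slice
                d = np.hypot(cy - rec["centroid"][0], cx - rec["centroid"][1])
                if d < best_d:
                    best, best_d = rec, d
            rows, cols = np.nonzero(lbl == prop.label)
            touches = (
                rows.min() == 0 or cols.min() == 0
                or rows.max() == h - 1 or cols.max() == w - 1
            )
            if best is not None and best_d <= config.axon_link_tolerance_px:
                best["slice_pixels"][z] = (rows, cols)
                best["border"] = best["border"] or touches
            else:
                regions.append(
                    {
                        "slice_pixels": {z: (rows, cols)},
                        "centroid": (cy, cx),
                        "border": touches,
                    }
                )
    out = [
        AxonRegion(
            axon_id=i,
            slice_pixels=rec["slice_pixels"],
            centroid=rec["centroid"],
            border_touching=rec["border"],
        )
        for i, rec in enumerate(regions)
    ]
    logger.info(
        "detected %d axon regions (%d border-touching)",
        len(out), sum(r.border_touching for r in out),
    )
    return out


def count_nuclei(
    nuclei_masks: BinaryMaskStack, config: SegmentationConfig | None = None
) -> int:
    """Count nuclei on the maximum-intensity projection of the nuclei masks.

    Connected components (8-connectivity) of the projected mask are counted
    after removing objects below ``nuclei_min_area_px``; an optional
    distance-transform watershed splits touching blobs.
    """
    config = config or SegmentationConfig()
    proj = nuclei_masks.masks.any(axis=0)
    if config.nuclei_min_area_px > 1:
        proj = _drop_small(proj, config.nuclei_min_area_px)
    if not proj.any():
        return 0
    if config.nuclei_watershed:
        dist = ndimage.distance_transform_edt(proj)
        # seeds: local maxima of the distance map, one per nucleus lobe
        maxima = (dist == ndimage.maximum_filter(dist, size=5)) & proj
        markers = label(maxima, connectivity=2)
        lbl = watershed(-dist, markers, mask=proj)
        return int(lbl.max())
    return int(label(proj, connectivity=2).max())
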