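"""2D oligodendrocyte differentiation readout: MBP-positive membrane area.

The companion assay images single-plane fields of cells on flat glass and
quantifies the thresholded MBP-positive area per field of view as a measure
of differentiation.  The same thresholding engine as the 3D pipeline is
used, and the resulting per-FOV areas feed the same dose-response machinery
with ``response="mbp_area"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageStack, ValidationError
from .segmentation import SegmentationConfig, threshold_channel, count_nuclei, BinaryMaskStack

__all__ = ["AreaMetrics", "mbp_area"]


@dataclass
class AreaMetrics:
    """MBP-positive area of one single-plane field of view."""

    well_id: str
    fov_id: str
    mbp_area_um2: float
    mbp_pixels: int
    n_nuclei: int | None
    threshold_method: str
    threshold_value: float | None


def mbp_area(
    image: ImageStack,
    config: SegmentationConfig | None = None,
    count_cells: bool = False,
) -> AreaMetrics:
    """Total MBP-positive area (μm²) of a single-plane image.

    The myelin channel is thresholded with the shared segmentation engine
    and the foreground pixel count is converted via ``pixel_size**2``.  Area
    is total per field of view (not per cell).  With ``count_cells`` the
    nuclei channel, if present, is counted too.
    """
    if image.n_slices != 1:
        raise ValidationError(
            f"2D differentiation expects a single-plane image, got {image.n_slices} slices"
        )
    if "myelin" not in image.channels:
        raise ValidationError("image has no myelin channel")
    config = config or SegmentationConfig()
    masks = threshold_channel(image, "myelin", config)
    n_px = int(np.count_nonzero(masks.masks))
    nuclei = None
    if count_cells and "nuclei" in image.channels:
        nuclei = count_nuclei(threshold_channel(image, "nuclei", config), config)
    return AreaMetrics(
        well_id=image.well_id,
        fov_id=image.fov_id,
        mbp_area_um2=n_px * image.pixel_size**2,
        mbp_pixels=n_px,
        n_nuclei=nuclei,
        threshold_method=masks.method,
        threshold_value=masks.thresholds[0],
    )
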