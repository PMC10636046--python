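"""Per-axon circumferential myelin-wrapping quantification.

This is the core readout of the assay.  For each detected pillar and each
z-slice:

1. trace a 1-px inner outline of the pillar mask (region minus its erosion
   by a 3x3 structuring element) — the discretized circumference;
2. build the *overlap mask*: outline pixels that are myelin-positive get
   value 255, outline pixels without myelin get 0;
3. the wrap fraction is the 255-pixel count divided by the outline size —
   the fraction of the circumference covered by myelin in that slice.

Per-slice fractions are then aggregated along z: maximal runs of consecutive
slices with fraction > 0.8 form *ensheathed segments* whose physical length
is slice-count x z-step.  A pillar is *fully wrapped* when some segment is at
least 6 μm long (three slices at the 2 μm z-step).  The field-level
*wrapping index* is the number of fully wrapped pillars divided by the
number of nuclei.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ValidationError
from .segmentation import AxonRegion, BinaryMaskStack

__all__ = [
    "WrapConfig",
    "Segment",
    "AxonWrapProfile",
    "FieldMetrics",
    "outline",
    "overlap_mask",
    "wrap_fraction",
    "build_profile",
    "field_metrics",
    "CATEGORY_LABELS",
]

logger = logging.getLogger(__name__)

OVERLAP_VALUE = 255

# Exclusive wrapping-extent categories by maximum per-slice fraction.
CATEGORY_LABELS = ("0-20%", "20-50%", "50-80%", "80-100%")
DEFAULT_BIN_EDGES = (0.2, 0.5, 0.8)

_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


@dataclass
class WrapConfig:
    """Thresholds of the wrapping classifier.

    ``wrap_threshold`` is strict (fraction must exceed it) and
    ``min_segment_length_um`` is inclusive (>= 6 μm qualifies, i.e. three
    slices at a 2 μm z-step).
    """

    wrap_threshold: float = 0.8
    min_segment_length_um: float = 6.0
    bin_edges: tuple[float, float, float] = DEFAULT_BIN_EDGES


@dataclass
class Segment:
    """One contiguous ensheathed segment along a pillar."""

    start_slice: int
    n_slices: int
    length_um: float


@dataclass
class AxonWrapProfile:
    """Wrapping readout of one pillar across the stack."""

    axon_id: int
    wrap_fractions: dict[int, float]  # slice -> fraction, present slices only
    segments: list[Segment]
    max_fraction: float
    category: str
    fully_wrapped: bool
    border_touching: bool = False

    def max_segment_length(self) -> float:
        return max((s.length_um for s in self.segments), default=0.0)


@dataclass
class FieldMetrics:
    """Aggregate wrapping metrics of one field of view."""

    well_id: str
    fov_id: str
    n_axons: int
    category_counts: dict[str, int]
    n_fully_wrapped: int
    n_nuclei: int
    wrapping_index: float  # NaN when n_nuclei == 0
    valid: bool = True


def outline(
    region_pixels: tuple[np.ndarray, np.ndarray], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """1-px inner outline of a region: the region minus its 3x3 erosion.

    Every outline pixel has at least one background 8-neighbour; a region of
    any positive area yields a non-empty outline (a single pixel is its own
    outline).
    """
    rows, cols = region_pixels
    if len(rows) == 0:
        raise ValidationError("outline of an empty region is undefined")
    # work on a padded local crop for speed and correct border handling
    r0, c0 = rows.min(), cols.min()
    crop = np.zeros((rows.max() - r0 + 3, cols.max() - c0 + 3), dtype=bool)
    crop[rows - r0 + 1, cols - c0 + 1] = True
    eroded = ndimage.binary_erosion(crop, structure=_STRUCT_3X3, border_value=0)
    ring = crop & ~eroded
    rr, cc = np.nonzero(ring)
    return rr + r0 - 1, cc + c0 - 1


def overlap_mask(
    outline_pixels: tuple[np.ndarray, np.ndarray], myelin_slice: np.ndarray
) -> np.ndarray:
    """Binary overlap image: 255 at myelin-positive outline pixels, else 0.

    Outline pixels not covered by myelin are 0, as is the (non-outline)
    background, so the image directly encodes the covered circumference.
    """
    rows, cols = outline_pixels
    out = np.zeros(myelin_slice.shape, dtype=np.uint8)
    covered = myelin_slice[rows, cols].astype(bool)
    out[rows[covered], cols[covered]] = OVERLAP_VALUE
    return out


def wrap_fraction(
    outline_pixels: tuple[np.ndarray, np.ndarray], myelin_slice: np.ndarray
) -> float:
    """Fraction of outline pixels that are myelin-positive, in [0, 1]."""
    rows, cols = outline_pixels
    if len(rows) == 0:
        raise ValidationError("wrap fraction of an empty outline is undefined")
    return float(np.count_nonzero(myelin_slice[rows, cols])) / len(rows)


def _segments_from_fractions(
    fractions: dict[int, float], z_step: float, wrap_threshold: float
) -> list[Segment]:
    """Maximal runs of consecutive present slices with fraction > threshold.

    Slices where the pillar is undetected break contiguity: the circumference
    is unmeasurable there, so a run cannot be assumed to continue across.
    """
    qualifying = sorted(z for z, f in fractions.items() if f > wrap_threshold)
    segments: list[Segment] = []
    i = 0
    while i < len(qualifying):
        j = i
        while j + 1 < len(qualifying) and qualifying[j + 1] == qualifying[j] + 1:
            j += 1
        n = j - i + 1
        segments.append(Segment(qualifying[i], n, n * z_step))
        i = j + 1
    return segments


def categorize(max_fraction: float, bin_edges=DEFAULT_BIN_EDGES) -> str:
    """Exclusive wrapping category of a pillar by its maximum slice fraction.

    Bins are [0, 0.2], (0.2, 0.5], (0.5, 0.8], (0.8, 1.0].
    """
    for edge, name in zip(bin_edges, CATEGORY_LABELS):
        if max_fraction <= edge:
            return name
    return CATEGORY_LABELS[-1]


def build_profile(
    region: AxonRegion,
    myelin_masks: BinaryMaskStack | np.ndarray,
    z_step: float,
    config: WrapConfig | None = None,
) -> AxonWrapProfile:
    """Compute the full wrapping profile of one detected pillar.

    Wrap fractions are computed for every slice where the region is present;
    segments are maximal consecutive runs of fractions strictly above
    ``wrap_threshold`` (absent slices break runs); the pillar is fully
    wrapped when some segment length (slices x z_step) reaches
    ``min_segment_length_um``.
    """
    config = config or WrapConfig()
    masks = myelin_masks.masks if isinstance(myelin_masks, BinaryMaskStack) else myelin_masks
    fractions: dict[int, float] = {}
    for z, pixels in sorted(region.slice_pixels.items()):
        ring = outline(pixels, masks[z].shape)
        fractions[z] = wrap_fraction(ring, masks[z])
    segments = _segments_from_fractions(fractions, z_step, config.wrap_threshold)
    max_fraction = max(fractions.values())
    fully = any(
        s.length_um >= config.min_segment_length_um - 1e-9 for s in segments
    )
    return AxonWrapProfile(
        axon_id=region.axon_id,
        wrap_fractions=fractions,
        segments=segments,
        max_fraction=max_fraction,
        category=categorize(max_fraction, config.bin_edges),
        fully_wrapped=fully,
        border_touching=region.border_touching,
    )


def field_metrics(
    profiles: list[AxonWrapProfile],
    n_nuclei: int,
    well_id: str = "",
    fov_id: str = "",
) -> FieldMetrics:
    """Aggregate one field of view into counts and the wrapping index.

    Border-touching pillars are excluded entirely.  Category counts tally
    only myelin-engaged pillars (max fraction > 0).  The wrapping index is
    fully-wrapped pillars / nuclei; a field with zero nuclei is flagged
    invalid (index NaN) and must be excluded from condition averages.
    """
    if n_nuclei < 0:
        raise ValidationError("n_nuclei must be >= 0")
    kept = [p for p in profiles if not p.border_touching]
    counts = {name: 0 for name in CATEGORY_LABELS}
    for p in kept:
        if p.max_fraction > 0:
            counts[p.category] += 1
    n_full = sum(p.fully_wrapped for p in kept)
    if n_nuclei == 0:
        logger.warning(
            "field %s/%s has zero nuclei; wrapping index undefined", well_id, fov_id
        )
        return FieldMetrics(
            well_id, fov_id, len(kept), counts, n_full, 0, float("nan"), valid=False
        )
    return FieldMetrics(
        well_id,
        fov_id,
        len(kept),
        counts,
        n_full,
        n_nuclei,
        n_full / n_nuclei,
    )
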