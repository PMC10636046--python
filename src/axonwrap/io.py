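"""Image-stack and plate-layout I/O.

Stacks are multi-page TIFFs in channel-major page order (all z of channel 0,
then all z of channel 1, ...) with a JSON sidecar carrying the physical
metadata (``pixel_size_um``, ``z_step_um``, ``channel_order``, ``well_id``,
``fov_id``).  Plate layouts are plain CSV, one row per well.

Conventions used throughout the package:

* array axes are ``(channel, z, y, x)``, 0-based, z monotone in acquisition
  order;
* physical lengths are derived only through the declared ``pixel_size``
  (μm/px) and ``z_step`` (μm);
* channels are identified by name (``axon``, ``myelin``, ``nuclei``), never
  by page-order heuristics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "PlateLayout",
    "FormatError",
    "ValidationError",
    "read_stack",
    "write_stack",
    "read_layout",
    "write_layout",
]

CHANNEL_NAMES = ("axon", "myelin", "nuclei")

LAYOUT_COLUMNS = ("well", "compound", "concentration_nM", "role", "replicate")
LAYOUT_ROLES = ("vehicle", "reference", "test")


class FormatError(ValueError):
    """A file does not match the declared on-disk format."""


class ValidationError(ValueError):
    """Data are well-formed but violate an invariant of the assay model."""


@dataclass
class ImageStack:
    """A multi-channel confocal z-stack of one field of view.

    Parameters
    ----------
    data
        Intensity array indexed ``(channel, z, y, x)``.
    channels
        Channel names, one per leading axis entry; must be unique.
    pixel_size
        Lateral sampling in μm per pixel.
    z_step
        Axial distance between consecutive slices, μm.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size: float
    z_step: float
    well_id: str = ""
    fov_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channels = tuple(self.channels)
        if self.data.ndim != 4:
            raise ValidationError(
                f"stack data must be (channel, z, y, x), got ndim={self.data.ndim}"
            )
        if len(self.channels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} planes"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError(f"channel names not unique: {self.channels}")
        if not (self.pixel_size > 0 and self.z_step > 0):
            raise ValidationError("pixel_size and z_step must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(z, y, x)`` intensity array of one named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None
        return self.data[idx]


@dataclass
class PlateLayout:
    """Well-to-condition mapping for one plate.

    One row per well with columns ``well``, ``compound``, ``concentration_nM``,
    ``role`` (vehicle | reference | test) and ``replicate``.  Exactly one
    compound is flagged ``reference`` (the normalisation standard, T3 in the
    original assay) and at least one well must be a vehicle control.
    """

    table: pd.DataFrame
    require_reference: bool = True

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"layout missing columns: {missing}")
        if df["well"].duplicated().any():
            dups = sorted(df.loc[df["well"].duplicated(), "well"].unique())
            raise FormatError(f"duplicate well ids in layout: {dups}")
        bad_roles = set(df["role"]) - set(LAYOUT_ROLES)
        if bad_roles:
            raise FormatError(f"unknown roles in layout: {sorted(bad_roles)}")
        if not (df["role"] == "vehicle").any():
            raise ValidationError("layout has no vehicle well")
        ref = df.loc[df["role"] == "reference", "compound"].unique()
        if self.require_reference and len(ref) != 1:
            raise ValidationError(
                f"layout must flag exactly one reference compound, found {list(ref)}"
            )
        self.table = df.reset_index(drop=True)

    @property
    def reference_compound(self) -> str | None:
        ref = self.table.loc[self.table["role"] == "reference", "compound"].unique()
        return str(ref[0]) if len(ref) else None

    def condition_of(self, well: str) -> pd.Series:
        rows = self.table[self.table["well"] == well]
        if rows.empty:
            raise ValidationError(f"well {well!r} not present in layout")
        return rows.iloc[0]

    def __len__(self) -> int:
        return len(self.table)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a channel-major multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    c, z, y, x = stack.data.shape
    pages = stack.data.reshape(c * z, y, x)
    tifffile.imwrite(path, pages)
    meta = {
        "pixel_size_um": stack.pixel_size,
        "z_step_um": stack.z_step,
        "channel_order": list(stack.channels),
        "n_slices": z,
        "well_id": stack.well_id,
        "fov_id": stack.fov_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(
    path: str | Path,
    channel_map: Sequence[str] | None = None,
    pixel_size: float | None = None,
    z_step: float | None = None,
) -> ImageStack:
    """Read a channel-major multi-page TIFF written by :func:`write_stack`.

    Metadata come from the JSON sidecar when present; ``channel_map``,
    ``pixel_size`` and ``z_step`` override or replace sidecar values.  The
    page count must equal ``len(channels) * n_slices``.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    channels = tuple(channel_map) if channel_map is not None else tuple(
        meta.get("channel_order", ())
    )
    if not channels:
        raise FormatError(f"{path}: no channel mapping supplied and no sidecar")
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    z_step = z_step if z_step is not None else meta.get("z_step_um")
    if pixel_size is None or z_step is None:
        raise FormatError(f"{path}: pixel_size/z_step missing (no sidecar, no flags)")
    n_pages = pages.shape[0]
    if n_pages % len(channels) != 0:
        raise FormatError(
            f"{path}: {n_pages} pages not divisible by {len(channels)} channels"
        )
    n_slices = meta.get("n_slices", n_pages // len(channels))
    if n_pages != len(channels) * n_slices:
        raise FormatError(
            f"{path}: expected {len(channels)}x{n_slices} pages, found {n_pages}"
        )
    data = pages.reshape(len(channels), n_slices, *pages.shape[1:])
    return ImageStack(
        data=data,
        channels=channels,
        pixel_size=float(pixel_size),
        z_step=float(z_step),
        well_id=str(meta.get("well_id", "")),
        fov_id=str(meta.get("fov_id", "")),
    )


def write_layout(layout: PlateLayout, path: str | Path) -> Path:
    path = Path(path)
    layout.table.to_csv(path, index=False)
    return path


def read_layout(path: str | Path, require_reference: bool = True) -> PlateLayout:
    """Read and validate a plate-layout CSV; concentrations parsed as nM."""
    df = pd.read_csv(path)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: layout missing columns {missing}")
    df["concentration_nM"] = pd.to_numeric(df["concentration_nM"])
    df["replicate"] = df["replicate"].astype(int)
    return PlateLayout(df, require_reference=require_reference)
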