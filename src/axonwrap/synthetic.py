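"""Synthetic artificial-axon assay data with known ground truth.

The real assay images vertical hydrogel micropillars ("artificial axons",
~8 μm diameter, 20 μm center-to-center spacing, ~20 μm tall) in three
confocal channels — pillars (rhodamine), myelin membrane (MBP immunostain)
and nuclei (DAPI) — as 10 z-slices at 2 μm steps.  No public image set is
deposited, so this module renders fields with that geometry and controlled,
exactly-known myelin coverage, plus tabular dose–response series drawn from
a four-parameter logistic (4PL).  Every downstream stage of the pipeline is
validated against the ground truth returned here.

Rendering model (deliberately simple):

* pillars are filled discs on a square grid, present in every slice they
  span;
* myelin is an annular arc concentric with the pillar whose angular extent
  equals the requested per-slice coverage fraction, at a seeded random start
  angle;
* nuclei are disjoint discs in a single designated slice;
* a constant background plus additive Gaussian noise is applied per channel.

No optics (PSF, bleaching) or cell morphology is simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ImageStack, PlateLayout, ValidationError, write_stack, write_layout

__all__ = [
    "SimulationConfig",
    "AxonGroundTruth",
    "DoseResponseTruth",
    "PlateDataset",
    "pillar_centers",
    "generate_field",
    "generate_dose_series",
    "generate_plate",
    "random_coverage_spec",
    "logistic_4pl",
    "true_segments_from_coverage",
]

FOREGROUND = 200.0  # rendered signal amplitude, arbitrary intensity units

# Classification thresholds mirrored by the ground truth: a pillar counts as
# fully wrapped when some run of consecutive slices, each with > 80% angular
# coverage, spans at least 6 um axially (3 slices at the 2 um z-step).
WRAP_THRESHOLD = 0.8
MIN_SEGMENT_LENGTH_UM = 6.0


@dataclass
class SimulationConfig:
    """Geometry, optics sampling and noise of a simulated field of view.

    Defaults reproduce the assay's imaging protocol: 512x512 fields at
    0.65 μm/px (a typical 20x air objective sampling), 10 slices at 2 μm,
    8 μm pillars on a 20 μm square grid.
    """

    pixel_size: float = 0.65  # um / px
    fov_shape: tuple[int, int] = (512, 512)  # (height, width) px
    n_slices: int = 10
    z_step: float = 2.0  # um
    pillar_diameter: float = 8.0  # um
    pillar_spacing: float = 20.0  # um, center-to-center
    pillar_height_slices: int | None = None  # None = spans all slices
    n_nuclei: int = 40
    nucleus_radius_px: float = 4.0
    myelin_ring_thickness: float = 2.0  # px
    noise_sd: float = 2.0  # intensity units
    background_level: float = 10.0  # intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pillar_diameter >= self.pillar_spacing:
            raise ValidationError("pillar_diameter must be < pillar_spacing")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        if self.z_step <= 0 or self.pixel_size <= 0:
            raise ValidationError("z_step and pixel_size must be positive")
        if min(self.fov_shape) <= 0 or self.pillar_diameter <= 0:
            raise ValidationError("all dimensions must be positive")

    @property
    def pillar_radius_px(self) -> float:
        return self.pillar_diameter / 2.0 / self.pixel_size

    @property
    def pillar_slices(self) -> int:
        return self.n_slices if self.pillar_height_slices is None else min(
            self.pillar_height_slices, self.n_slices
        )


@dataclass
class AxonGroundTruth:
    """True rendering parameters of one simulated pillar."""

    axon_id: int
    centroid_xy: tuple[float, float]  # (y, x) px
    per_slice_coverage: np.ndarray  # angular fraction per z-slice, in [0, 1]
    true_segments: list[tuple[int, int]]  # (start_slice, n_slices)
    true_fully_wrapped: bool


@dataclass
class DoseResponseTruth:
    """True 4PL parameters and design of a simulated concentration series."""

    bottom: float
    top: float
    ec50: float  # nM
    hill: float = 1.0
    concentrations: np.ndarray = field(
        default_factory=lambda: serial_dilution_series()
    )
    replicate_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.top < self.bottom:
            raise ValidationError("top must be >= bottom")
        if self.ec50 <= 0:
            raise ValidationError("ec50 must be positive")
        if np.any(np.diff(self.concentrations) >= 0):
            raise ValidationError("concentrations must be strictly decreasing")

    def response_at(self, concentration: float | np.ndarray) -> np.ndarray:
        return logistic_4pl(concentration, self.bottom, self.top, self.ec50, self.hill)


def serial_dilution_series(
    top_nM: float = 10_000.0, fold: float = 3.0, n_points: int = 9
) -> np.ndarray:
    """Descending serial-dilution series (default 9 points, 3x from 10 μM)."""
    return top_nM / fold ** np.arange(n_points)


def logistic_4pl(
    c: float | np.ndarray, bottom: float, top: float, ec50: float, hill: float
) -> np.ndarray:
    """Four-parameter logistic R(c) = bottom + (top-bottom)/(1 + (ec50/c)^hill).

    Defined as ``bottom`` at c = 0 (the limit of the expression).
    """
    c = np.asarray(c, dtype=float)
    out = np.full(c.shape, float(bottom))
    pos = c > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (ec50 / c[pos]) ** hill)
    return out if out.ndim else float(out)


def true_segments_from_coverage(
    coverage: np.ndarray,
    wrap_threshold: float = WRAP_THRESHOLD,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive slices with coverage > wrap_threshold."""
    above = np.asarray(coverage) > wrap_threshold
    segments: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append((start, i - start))
            start = None
    if start is not None:
        segments.append((start, len(above) - start))
    return segments


def _is_fully_wrapped(
    segments: Iterable[tuple[int, int]], z_step: float,
    min_segment_length: float = MIN_SEGMENT_LENGTH_UM,
) -> bool:
    return any(n * z_step >= min_segment_length for _, n in segments)


def pillar_centers(config: SimulationConfig) -> list[tuple[float, float]]:
    """Centers (y, x) in px of the square pillar grid fitting the field.

    Only pillars whose disc plus myelin ring lies fully inside the field are
    placed, so no rendered pillar touches the border.
    """
    h, w = config.fov_shape
    spacing = config.pillar_spacing / config.pixel_size
    margin = config.pillar_radius_px + config.myelin_ring_thickness + 2.0
    ys = np.arange(margin, h - margin + 1e-9, spacing)
    xs = np.arange(margin, w - margin + 1e-9, spacing)
    if len(ys) == 0 or len(xs) == 0:
        raise ValidationError(
            f"pillar grid does not fit a {h}x{w} field at spacing {spacing:.1f} px"
        )
    return [(float(y), float(x)) for y in ys for x in xs]


def _render_pillar(
    axon_plane: np.ndarray, cy: float, cx: float, radius: float
) -> None:
    y0, y1, x0, x1 = _bbox(axon_plane.shape, cy, cx, radius + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    axon_plane[y0:y1, x0:x1][disc] = FOREGROUND


def _render_arc(
    myelin_plane: np.ndarray,
    cy: float,
    cx: float,
    radius: float,
    thickness: float,
    coverage: float,
    start_angle: float,
) -> None:
    """Render an annular arc of given angular coverage around a pillar.

    The annulus spans radii [radius - 2, radius + thickness] so it always
    covers the 1-px inner outline of the rasterized pillar disc; a pixel
    belongs to the arc when its angle from the center (mod 2π) falls within
    ``coverage`` turns of ``start_angle``.
    """
    if coverage <= 0:
        return
    r_in, r_out = radius - 2.0, radius + thickness
    y0, y1, x0, x1 = _bbox(myelin_plane.shape, cy, cx, r_out + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    rr2 = dy**2 + dx**2
    annulus = (rr2 >= r_in**2) & (rr2 <= r_out**2)
    if coverage >= 1.0:
        sector = annulus
    else:
        ang = (np.arctan2(dy, dx) - start_angle) % (2 * math.pi)
        sector = annulus & (ang <= coverage * 2 * math.pi)
    myelin_plane[y0:y1, x0:x1][sector] = FOREGROUND


def _bbox(shape, cy, cx, r) -> tuple[int, int, int, int]:
    return (
        max(0, int(cy - r)),
        min(shape[0], int(cy + r) + 2),
        max(0, int(cx - r)),
        min(shape[1], int(cx + r) + 2),
    )


def _render_nuclei(
    plane: np.ndarray, n: int, radius: float, rng: np.random.Generator
) -> int:
    """Place n disjoint nuclear discs by rejection sampling; returns count."""
    h, w = plane.shape
    centers: list[tuple[float, float]] = []
    min_sep2 = (2 * radius + 2) ** 2
    attempts = 0
    while len(centers) < n and attempts < 200 * max(n, 1):
        cy = rng.uniform(radius + 1, h - radius - 1)
        cx = rng.uniform(radius + 1, w - radius - 1)
        attempts += 1
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep2 for y, x in centers):
            centers.append((cy, cx))
    for cy, cx in centers:
        _render_pillar(plane, cy, cx, radius)
    return len(centers)


def generate_field(
    config: SimulationConfig,
    coverage_spec: np.ndarray | Sequence[Sequence[float]],
    n_nuclei: int | None = None,
    rng: np.random.Generator | None = None,
    well_id: str = "",
    fov_id: str = "",
) -> tuple[ImageStack, list[AxonGroundTruth], int]:
    """Render one field of view with exactly known per-pillar myelin coverage.

    Parameters
    ----------
    coverage_spec
        Array of shape ``(n_pillars, n_slices)`` of angular coverage
        fractions in [0, 1]; one row per pillar of the grid.
    n_nuclei
        Override of ``config.n_nuclei`` (used to simulate cytotoxic loss).
    rng
        Random generator; defaults to ``default_rng(config.seed)``.

    Returns
    -------
    (stack, truths, nuclei_count)
        The rendered 3-channel stack, per-pillar ground truth, and the number
        of nuclei actually rendered.
    """
    centers = pillar_centers(config)
    coverage = np.asarray(coverage_spec, dtype=float)
    if coverage.ndim != 2 or coverage.shape != (len(centers), config.n_slices):
        raise ValidationError(
            f"coverage_spec must be ({len(centers)}, {config.n_slices}), "
            f"got {coverage.shape}"
        )
    if np.any((coverage < 0) | (coverage > 1)):
        raise ValidationError("coverage fractions must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_nuclei is None:
        n_nuclei = config.n_nuclei

    h, w = config.fov_shape
    data = np.zeros((3, config.n_slices, h, w), dtype=np.float32)
    axon_ch, myelin_ch, nuclei_ch = data
    radius = config.pillar_radius_px

    truths: list[AxonGroundTruth] = []
    for i, (cy, cx) in enumerate(centers):
        start_angles = rng.uniform(0, 2 * math.pi, size=config.n_slices)
        for z in range(config.pillar_slices):
            _render_pillar(axon_ch[z], cy, cx, radius)
            _render_arc(
                myelin_ch[z], cy, cx, radius,
                config.myelin_ring_thickness, coverage[i, z], start_angles[z],
            )
        segs = true_segments_from_coverage(coverage[i])
        truths.append(
            AxonGroundTruth(
                axon_id=i,
                centroid_xy=(cy, cx),
                per_slice_coverage=coverage[i].copy(),
                true_segments=segs,
                true_fully_wrapped=_is_fully_wrapped(segs, config.z_step),
            )
        )

    nuclei_slice = config.n_slices // 2
    n_rendered = _render_nuclei(
        nuclei_ch[nuclei_slice], n_nuclei, config.nucleus_radius_px, rng
    )

    data += config.background_level
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape).astype(np.float32)

    stack = ImageStack(
        data=data,
        channels=("axon", "myelin", "nuclei"),
        pixel_size=config.pixel_size,
        z_step=config.z_step,
        well_id=well_id,
        fov_id=fov_id,
    )
    return stack, truths, n_rendered


def random_coverage_spec(
    rng: np.random.Generator,
    n_pillars: int,
    n_slices: int,
    p_full: float = 0.3,
    z_step: float = 2.0,
    min_segment_length: float = MIN_SEGMENT_LENGTH_UM,
) -> np.ndarray:
    """Draw per-pillar coverage profiles with unambiguous wrap labels.

    A fraction ``p_full`` of pillars receives a contiguous high-coverage run
    (coverage >= 0.92) long enough to qualify as fully wrapped; the rest get
    coverages <= 0.7 everywhere.  Keeping all values at least 0.1 away from
    the 0.8 classification threshold makes the true labels robust to
    rasterization error, so noiseless analysis must recover them exactly.
    """
    min_run = max(1, math.ceil(min_segment_length / z_step))
    spec = np.empty((n_pillars, n_slices))
    for i in range(n_pillars):
        full = rng.random() < p_full
        spec[i] = rng.uniform(0.0, 0.7, size=n_slices)
        if full:
            run = int(rng.integers(min_run, n_slices + 1))
            start = int(rng.integers(0, n_slices - run + 1))
            spec[i, start : start + run] = rng.uniform(0.92, 1.0, size=run)
            # keep neighbours low so the qualifying run is exactly as drawn
            if start > 0:
                spec[i, start - 1] = min(spec[i, start - 1], 0.5)
            if start + run < n_slices:
                spec[i, start + run] = min(spec[i, start + run], 0.5)
    return spec


def generate_dose_series(truth: DoseResponseTruth) -> pd.DataFrame:
    """Simulate replicate responses of a 4PL dose–response experiment.

    Returns a tidy table with columns ``concentration_nM``, ``replicate``,
    ``response``; Gaussian replicate noise with SD ``truth.replicate_sd``,
    deterministic under ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    rows = []
    for c in truth.concentrations:
        mean = truth.response_at(c)
        noise = rng.normal(0.0, truth.replicate_sd, size=truth.n_replicates)
        for rep in range(truth.n_replicates):
            rows.append(
                {
                    "concentration_nM": float(c),
                    "replicate": rep,
                    "response": float(mean + noise[rep]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PlateDataset:
    """A simulated plate: stacks plus layout plus complete ground truth."""

    stacks: list[ImageStack]
    layout: PlateLayout
    axon_truth: pd.DataFrame  # per-axon rows incl. well/fov/true labels
    condition_truth: pd.DataFrame  # per (compound, concentration) true response
    truths_4pl: dict[str, DoseResponseTruth]
    nuclei_truth: pd.DataFrame  # per-FOV rendered nuclei counts

    def write(self, outdir: str | Path) -> None:
        """Serialize stacks (TIFF + sidecar), layout CSV and truth tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for stack in self.stacks:
            write_stack(stack, outdir / f"{stack.well_id}_{stack.fov_id}.tif")
        write_layout(self.layout, outdir / "layout.csv")
        self.axon_truth.to_csv(outdir / "axon_truth.csv", index=False)
        self.condition_truth.to_csv(outdir / "condition_truth.csv", index=False)
        self.nuclei_truth.to_csv(outdir / "nuclei_truth.csv", index=False)
        truth_json = {
            name: {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(t).items()
            }
            for name, t in self.truths_4pl.items()
        }
        (outdir / "truth_4pl.json").write_text(json.dumps(truth_json, indent=1))


def generate_plate(
    compound_truths: Mapping[str, DoseResponseTruth],
    config: SimulationConfig,
    reference: str,
    vehicle_name: str = "DMSO",
    n_wells_per_condition: int = 3,
    n_fov_per_well: int = 9,
    nuclei_multiplier: Mapping[tuple[str, float], float] | None = None,
) -> PlateDataset:
    """Simulate a full dosing plate with image stacks and ground truth.

    For each (compound, concentration) condition the per-pillar probability of
    full wrapping is chosen so that the *expected wrapping index* (fully
    wrapped pillars / nuclei) equals the condition's true 4PL response.
    Vehicle wells are generated at the reference truth's ``bottom`` response.

    ``nuclei_multiplier`` optionally scales the rendered nuclei count of
    specific conditions to emulate cytotoxic cell loss at high doses.
    """
    if reference not in compound_truths:
        raise ValidationError(f"reference compound {reference!r} missing from truths")
    n_pillars = len(pillar_centers(config))
    rng = np.random.default_rng(config.seed)

    conditions: list[tuple[str, float, str]] = [(vehicle_name, 0.0, "vehicle")]
    for name, truth in compound_truths.items():
        role = "reference" if name == reference else "test"
        for c in truth.concentrations:
            conditions.append((name, float(c), role))

    stacks: list[ImageStack] = []
    layout_rows = []
    axon_rows = []
    cond_rows = []
    nuc_rows = []
    well_counter = 0
    for compound, conc, role in conditions:
        if role == "vehicle":
            true_resp = float(compound_truths[reference].bottom)
        else:
            true_resp = float(compound_truths[compound].response_at(conc))
        mult = 1.0
        if nuclei_multiplier:
            mult = float(nuclei_multiplier.get((compound, conc), 1.0))
        n_nuc = max(1, round(config.n_nuclei * mult))
        p_full = float(np.clip(true_resp * n_nuc / n_pillars, 0.0, 1.0))
        cond_rows.append(
            {
                "compound": compound,
                "concentration_nM": conc,
                "role": role,
                "true_response": true_resp,
                "p_full": p_full,
                "n_nuclei": n_nuc,
            }
        )
        for rep in range(n_wells_per_condition):
            well_counter += 1
            well = f"W{well_counter:03d}"
            layout_rows.append(
                {
                    "well": well,
                    "compound": compound,
                    "concentration_nM": conc,
                    "role": role,
                    "replicate": rep,
                }
            )
            for f in range(n_fov_per_well):
                fov = f"F{f + 1}"
                full_flags = rng.random(n_pillars) < p_full
                spec = random_coverage_spec(
                    rng, n_pillars, config.n_slices, p_full=0.0,
                    z_step=config.z_step,
                )
                full_spec = random_coverage_spec(
                    rng, n_pillars, config.n_slices, p_full=1.0,
                    z_step=config.z_step,
                )
                spec[full_flags] = full_spec[full_flags]
                stack, truths, n_rendered = generate_field(
                    config, spec, n_nuclei=n_nuc, rng=rng,
                    well_id=well, fov_id=fov,
                )
                stacks.append(stack)
                nuc_rows.append({"well": well, "fov": fov, "n_nuclei_true": n_rendered})
                for t in truths:
                    axon_rows.append(
                        {
                            "well": well,
                            "fov": fov,
                            "axon_id": t.axon_id,
                            "true_fully_wrapped": t.true_fully_wrapped,
                            "true_max_coverage": float(t.per_slice_coverage.max()),
                        }
                    )

    layout = PlateLayout(pd.DataFrame(layout_rows))
    return PlateDataset(
        stacks=stacks,
        layout=layout,
        axon_truth=pd.DataFrame(axon_rows),
        condition_truth=pd.DataFrame(cond_rows),
        truths_4pl=dict(compound_truths),
        nuclei_truth=pd.DataFrame(nuc_rows),
    )
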