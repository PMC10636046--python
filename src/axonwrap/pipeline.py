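"""End-to-end orchestration: simulate -> quantify -> dose-response -> report.

The pipeline takes either a directory of acquired stacks plus a plate-layout
CSV, or a simulation specification, and produces the standard result bundle:
per-axon, per-FOV, per-condition, dose-response and sheath-length tables,
the Fig.-style category-progression summary, and a run manifest (config
hash, seed, package version) that makes any run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _version
from .io import ImageStack, PlateLayout, ValidationError, read_stack, read_layout
from .segmentation import (
    SegmentationConfig,
    threshold_channel,
    detect_axons,
    count_nuclei,
)
from .wrapping import (
    WrapConfig,
    AxonWrapProfile,
    build_profile,
    field_metrics,
    CATEGORY_LABELS,
)
from .sheath import sheath_lengths, length_stats, index_at_length_threshold
from .dose_response import (
    aggregate,
    exclude_cytotoxic,
    fit_4pl,
    efficacy_and_relative,
    rank_compounds,
    dose_response_table,
)
from .synthetic import SimulationConfig, DoseResponseTruth, generate_plate

__all__ = [
    "RunConfig",
    "PipelineResult",
    "quantify_stack",
    "quantify_stacks",
    "run_pipeline",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be given: ``stacks_dir`` + ``layout_path``
    for acquired images, or ``simulation`` for a synthetic plate.
    """

    outdir: str | Path = "axonwrap_out"
    seed: int = 0
    stacks_dir: str | Path | None = None
    layout_path: str | Path | None = None
    simulation: dict | None = None  # see run_pipeline docstring
    reference: str = "T3"
    response: str = "wrapping_index"
    viability_fraction: float = 0.5
    alt_length_thresholds: tuple[float, ...] = (6.0, 10.0)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    wrapping: WrapConfig = field(default_factory=WrapConfig)
    log_level: str = "INFO"

    def validate(self) -> None:
        has_images = self.stacks_dir is not None and self.layout_path is not None
        if has_images == (self.simulation is not None):
            raise ValidationError(
                "exactly one of (stacks_dir + layout_path) or simulation required"
            )


@dataclass
class PipelineResult:
    per_axon: pd.DataFrame
    per_fov: pd.DataFrame
    condition_table: pd.DataFrame
    dose_response: pd.DataFrame
    sheath_table: pd.DataFrame
    progression: pd.DataFrame
    manifest: dict
    profiles: dict[tuple[str, str], list[AxonWrapProfile]]
    layout: PlateLayout


def quantify_stack(
    stack: ImageStack,
    seg_config: SegmentationConfig | None = None,
    wrap_config: WrapConfig | None = None,
):
    """Quantify one stack: segment, profile every pillar, aggregate the field.

    Returns ``(profiles, metrics)`` where profiles cover all detected pillars
    (border-touching ones flagged) and metrics is the field-level summary.
    """
    seg_config = seg_config or SegmentationConfig()
    wrap_config = wrap_config or WrapConfig()
    axon_masks = threshold_channel(stack, "axon", seg_config)
    myelin_masks = threshold_channel(
        stack, "myelin", seg_config, method=seg_config.myelin_threshold_method
    )
    nuclei_masks = threshold_channel(
        stack, "nuclei", seg_config, method=seg_config.nuclei_threshold_method
    )
    regions = detect_axons(axon_masks, seg_config)
    n_nuclei = count_nuclei(nuclei_masks, seg_config)
    profiles = [
        build_profile(r, myelin_masks, stack.z_step, wrap_config) for r in regions
    ]
    metrics = field_metrics(profiles, n_nuclei, stack.well_id, stack.fov_id)
    return profiles, metrics


def _axon_rows(
    profiles: list[AxonWrapProfile], n_slices: int, well: str, fov: str
) -> list[dict]:
    rows = []
    for p in profiles:
        row = {
            "well": well,
            "fov": fov,
            "axon_id": p.axon_id,
            "max_fraction": p.max_fraction,
            "category": p.category,
            "n_segments": len(p.segments),
            "max_segment_length_um": p.max_segment_length(),
            "fully_wrapped": p.fully_wrapped,
            "border_touching": p.border_touching,
        }
        for z in range(n_slices):
            row[f"frac_z{z}"] = p.wrap_fractions.get(z, np.nan)
        rows.append(row)
    return rows


def quantify_stacks(
    stacks: list[ImageStack],
    seg_config: SegmentationConfig | None = None,
    wrap_config: WrapConfig | None = None,
):
    """Quantify a list of stacks into per-axon and per-FOV tables."""
    axon_rows: list[dict] = []
    fov_rows: list[dict] = []
    profiles_by_fov: dict[tuple[str, str], list[AxonWrapProfile]] = {}
    for stack in stacks:
        profiles, metrics = quantify_stack(stack, seg_config, wrap_config)
        profiles_by_fov[(stack.well_id, stack.fov_id)] = profiles
        axon_rows.extend(
            _axon_rows(profiles, stack.n_slices, stack.well_id, stack.fov_id)
        )
        row = {
            "well": stack.well_id,
            "fov": stack.fov_id,
            "n_axons": metrics.n_axons,
            "n_fully_wrapped": metrics.n_fully_wrapped,
            "n_nuclei": metrics.n_nuclei,
            "wrapping_index": metrics.wrapping_index,
            "valid": metrics.valid,
        }
        for name in CATEGORY_LABELS:
            row[f"n_{name}"] = metrics.category_counts[name]
        fov_rows.append(row)
    return pd.DataFrame(axon_rows), pd.DataFrame(fov_rows), profiles_by_fov


def summarize(
    per_axon: pd.DataFrame, per_fov: pd.DataFrame, layout: PlateLayout
) -> pd.DataFrame:
    """Category-progression table per condition (wrapping-extent summary).

    For each (compound, concentration): the percentage of myelin-engaged
    pillars (max fraction > 0, border excluded) in each wrapping category,
    the percentage fully wrapped, and the mean wrapping index.  Percentages
    sum to 100 over the four categories; a condition with no engaged pillars
    is flagged with ``zero_denominator``.
    """
    axons = per_axon[~per_axon["border_touching"]].merge(
        layout.table, on="well", how="left"
    )
    fov = per_fov.merge(layout.table, on="well", how="left")
    rows = []
    for (compound, conc), grp in axons.groupby(["compound", "concentration_nM"]):
        engaged = grp[grp["max_fraction"] > 0]
        n = len(engaged)
        row = {"compound": compound, "concentration_nM": conc, "n_engaged": n,
               "zero_denominator": n == 0}
        for name in CATEGORY_LABELS:
            row[f"pct_{name}"] = (
                100.0 * (engaged["category"] == name).mean() if n else 0.0
            )
        row["pct_fully_wrapped"] = (
            100.0 * engaged["fully_wrapped"].mean() if n else 0.0
        )
        sub = fov[
            (fov["compound"] == compound) & (fov["concentration_nM"] == conc)
            & fov["valid"]
        ]
        row["wrapping_index"] = float(sub["wrapping_index"].mean()) if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _sheath_table(
    profiles_by_fov: dict,
    per_fov: pd.DataFrame,
    layout: PlateLayout,
    alt_thresholds: tuple[float, ...],
) -> pd.DataFrame:
    """Per-condition sheath-length stats and alternative-threshold indices."""
    fov = per_fov.merge(layout.table, on="well", how="left")
    rows = []
    for (compound, conc), grp in fov.groupby(["compound", "concentration_nM"]):
        profiles = [
            p
            for _, r in grp.iterrows()
            for p in profiles_by_fov.get((r["well"], r["fov"]), [])
        ]
        lengths = sheath_lengths(profiles)
        row: dict = {
            "compound": compound,
            "concentration_nM": conc,
            "n_segments": len(lengths),
        }
        if lengths:
            st = length_stats(lengths)
            row.update(
                median_um=st.median, q1_um=st.q1, q3_um=st.q3, iqr_um=st.iqr,
                whisker_low_um=st.whisker_low, whisker_high_um=st.whisker_high,
                n_outliers=len(st.outliers),
            )
        for thr in alt_thresholds:
            vals = []
            for _, r in grp.iterrows():
                if r["n_nuclei"] > 0:
                    vals.append(
                        index_at_length_threshold(
                            profiles_by_fov.get((r["well"], r["fov"]), []),
                            int(r["n_nuclei"]),
                            thr,
                        )
                    )
            row[f"wrapping_index_ge_{thr:g}um"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, Path):
            return str(o)
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_stacks(stacks_dir: Path) -> list[ImageStack]:
    paths = sorted(stacks_dir.glob("*.tif")) + sorted(stacks_dir.glob("*.tiff"))
    if not paths:
        raise ValidationError(f"no TIFF stacks found in {stacks_dir}")
    return [read_stack(p) for p in paths]


def _simulate(spec: dict, seed: int):
    """Build a synthetic plate from a simulation spec dictionary.

    Recognised keys: ``compounds`` (name -> {bottom, top, ec50_nM, hill,
    concentrations?}), ``reference``, ``n_wells_per_condition``,
    ``n_fov_per_well``, ``nuclei_multiplier`` and any
    :class:`~axonwrap.synthetic.SimulationConfig` field under ``field``.
    """
    field_kwargs = dict(spec.get("field", {}))
    field_kwargs.setdefault("seed", seed)
    if "fov_shape" in field_kwargs:
        field_kwargs["fov_shape"] = tuple(field_kwargs["fov_shape"])
    config = SimulationConfig(**field_kwargs)
    truths = {}
    for name, t in spec["compounds"].items():
        kwargs = dict(
            bottom=t["bottom"], top=t["top"], ec50=t["ec50_nM"],
            hill=t.get("hill", 1.0), seed=seed,
        )
        if "concentrations" in t:
            kwargs["concentrations"] = np.asarray(t["concentrations"], dtype=float)
        truths[name] = DoseResponseTruth(**kwargs)
    nuclei_multiplier = {
        (c, float(conc)): float(m)
        for c, conc, m in spec.get("nuclei_multiplier", [])
    }
    return generate_plate(
        truths,
        config,
        reference=spec["reference"],
        n_wells_per_condition=int(spec.get("n_wells_per_condition", 3)),
        n_fov_per_well=int(spec.get("n_fov_per_well", 9)),
        nuclei_multiplier=nuclei_multiplier or None,
    )


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Run the full analysis and (optionally) write the result bundle.

    Stages: acquire (load or simulate) -> segment & profile every FOV ->
    aggregate per condition with cytotoxicity exclusion -> 4PL fits, EC50,
    efficacy, relative efficacy and ranks -> sheath-length analysis ->
    category-progression summary.  Deterministic for a fixed config and
    seed.  Any stage error aborts with a stage-tagged message.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    outdir = Path(config.outdir)

    def stage(name: str):
        logger.info("stage: %s", name)

    try:
        stage("acquire")
        if config.simulation is not None:
            plate = _simulate(config.simulation, config.seed)
            stacks, layout = plate.stacks, plate.layout
        else:
            stacks = _load_stacks(Path(config.stacks_dir))
            layout = read_layout(Path(config.layout_path))
    except Exception as exc:
        raise ValidationError(f"[acquire] {exc}") from exc

    try:
        stage("quantify")
        per_axon, per_fov, profiles_by_fov = quantify_stacks(
            stacks, config.segmentation, config.wrapping
        )
    except Exception as exc:
        raise ValidationError(f"[quantify] {exc}") from exc

    try:
        stage("dose-response")
        series = aggregate(per_fov, layout, response=config.response)
        vehicle = [s for s in series if s.role == "vehicle"]
        if vehicle and vehicle[0].mean_nuclei is not None:
            vehicle_nuclei = float(np.mean(vehicle[0].mean_nuclei))
            for s in series:
                if s.role != "vehicle":
                    exclude_cytotoxic(s, vehicle_nuclei, config.viability_fraction)
        fits = {}
        for s in series:
            if s.role == "vehicle":
                continue
            n_usable = int((s.included & (s.concentrations > 0)).sum())
            if n_usable >= 4:
                fits[s.compound] = fit_4pl(s)
        compound_series = [s for s in series if s.role != "vehicle"]
        results = efficacy_and_relative(compound_series, config.reference, fits)
        results = rank_compounds(results, compound_series)
        dr_table = dose_response_table(results)
    except Exception as exc:
        raise ValidationError(f"[dose-response] {exc}") from exc

    try:
        stage("report")
        sheath_table = _sheath_table(
            profiles_by_fov, per_fov, layout, config.alt_length_thresholds
        )
        progression = summarize(per_axon, per_fov, layout)
        cond_rows = []
        for s in series:
            for i, c in enumerate(s.concentrations):
                cond_rows.append(
                    {
                        "compound": s.compound,
                        "role": s.role,
                        "concentration_nM": c,
                        "mean_response": s.mean_response[i],
                        "sem": s.sem[i],
                        "n_fov": s.n_fov[i],
                        "included": bool(s.included[i]),
                    }
                )
        condition_table = pd.DataFrame(cond_rows)
        manifest = {
            "package": "axonwrap",
            "version": _version,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_stacks": len(stacks),
            "reference": config.reference,
            "response": config.response,
        }
    except Exception as exc:
        raise ValidationError(f"[report] {exc}") from exc

    result = PipelineResult(
        per_axon=per_axon,
        per_fov=per_fov,
        condition_table=condition_table,
        dose_response=dr_table,
        sheath_table=sheath_table,
        progression=progression,
        manifest=manifest,
        profiles=profiles_by_fov,
        layout=layout,
    )
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        per_axon.to_csv(outdir / "per_axon.csv", index=False)
        per_fov.to_csv(outdir / "per_fov.csv", index=False)
        condition_table.to_csv(outdir / "per_condition.csv", index=False)
        dr_table.to_csv(outdir / "dose_response.csv", index=False)
        sheath_table.to_csv(outdir / "sheath.csv", index=False)
        progression.to_csv(outdir / "progression.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.info("wrote result bundle to %s", outdir)
    return result
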