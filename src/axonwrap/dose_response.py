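"""Condition aggregation, 4PL dose-response fitting and compound ranking.

Field-of-view responses (wrapping index for the 3D assay, MBP-positive area
for the 2D assay) are averaged per (compound, concentration) condition with
SEM over all fields.  Each compound's series is fitted with the
four-parameter logistic

    R(c) = bottom + (top - bottom) / (1 + (EC50 / c)^hill)

in log-concentration space.  Potency is the fitted EC50, declared
*undetermined* when the series shows no plateau within the tested range (the
fasudil-type case).  Efficacy is the maximum *observed* condition mean — by
design taken from the raw data, never from the fitted top — and relative
efficacy divides it by the reference compound's efficacy (T3 in the original
assay).  Compounds are ranked by efficacy with statistical ties: adjacent
compounds share a rank when a two-group one-way ANOVA on their FOV-level
peak-dose responses is not significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import PlateLayout, ValidationError

__all__ = [
    "ConditionSeries",
    "FourPLFit",
    "DoseResponseResult",
    "aggregate",
    "exclude_cytotoxic",
    "fit_4pl",
    "ec50_with_plateau_check",
    "efficacy_and_relative",
    "rank_compounds",
    "dose_response_table",
]

logger = logging.getLogger(__name__)

EC50_BOUND_FACTOR = 100.0  # EC50 constrained to [c_min/100, c_max*100]
PLATEAU_EXCESS = 0.2  # fitted top may exceed the observed max by <= 20%


@dataclass
class ConditionSeries:
    """Per-concentration aggregated response of one compound.

    Concentrations are stored descending; ``included`` marks concentrations
    retained for fitting (cytotoxic doses are excluded).  ``fov_responses``
    keeps the FOV-level values per concentration for ranking statistics.
    """

    compound: str
    role: str
    concentrations: np.ndarray  # nM, descending
    mean_response: np.ndarray
    sem: np.ndarray
    n_fov: np.ndarray
    included: np.ndarray  # bool
    fov_responses: dict[float, np.ndarray] = field(default_factory=dict)
    mean_nuclei: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.concentrations)
        for name in ("mean_response", "sem", "n_fov", "included"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length != number of concentrations")
        if np.any(self.sem < 0):
            raise ValidationError("sem must be non-negative")


@dataclass
class FourPLFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    converged: bool
    rss: float = float("nan")
    n_points: int = 0
    message: str = ""

    def predict(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        out = np.full(c.shape, self.bottom)
        pos = c > 0
        out[pos] = self.bottom + (self.top - self.bottom) / (
            1.0 + (self.ec50 / c[pos]) ** self.hill
        )
        return out


@dataclass
class DoseResponseResult:
    compound: str
    fit: FourPLFit | None
    ec50: float | None  # nM; None = undetermined
    plateau_reached: bool
    efficacy: float
    efficacy_sem: float
    peak_concentration: float
    relative_efficacy: float
    relative_efficacy_sem: float
    rank: int | None = None


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size <= 1:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def aggregate(
    fov_table: pd.DataFrame,
    layout: PlateLayout,
    response: str = "wrapping_index",
) -> list[ConditionSeries]:
    """Aggregate FOV-level metrics into per-compound concentration series.

    ``fov_table`` needs columns ``well``, ``fov``, the chosen ``response``
    and (optionally) ``n_nuclei``; every well must appear in the layout.
    Mean and SEM are taken over all FOVs pooled across replicate wells.  The
    vehicle condition becomes its own series with a single concentration-0
    baseline row.
    """
    required = {"well", "fov", response}
    missing = required - set(fov_table.columns)
    if missing:
        raise ValidationError(f"fov table missing columns: {sorted(missing)}")
    merged = fov_table.merge(layout.table, on="well", how="left", validate="m:1")
    if merged["compound"].isna().any():
        orphans = sorted(merged.loc[merged["compound"].isna(), "well"].unique())
        raise ValidationError(f"FOVs from wells missing in layout: {orphans}")
    has_nuclei = "n_nuclei" in merged.columns
    series: list[ConditionSeries] = []
    for (compound, role), group in merged.groupby(["compound", "role"], sort=False):
        concs: list[float] = []
        means, sems, ns, nucs = [], [], [], []
        fovs: dict[float, np.ndarray] = {}
        for conc, sub in group.groupby("concentration_nM"):
            vals = sub[response].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                logger.warning(
                    "condition %s @ %g nM has no valid FOVs; skipped", compound, conc
                )
                continue
            concs.append(float(conc))
            means.append(float(vals.mean()))
            sems.append(_sem(vals))
            ns.append(int(vals.size))
            fovs[float(conc)] = vals
            if has_nuclei:
                nucs.append(float(sub["n_nuclei"].mean()))
        order = np.argsort(concs)[::-1]
        series.append(
            ConditionSeries(
                compound=str(compound),
                role=str(role),
                concentrations=np.asarray(concs)[order],
                mean_response=np.asarray(means)[order],
                sem=np.asarray(sems)[order],
                n_fov=np.asarray(ns)[order],
                included=np.ones(len(concs), dtype=bool),
                fov_responses=fovs,
                mean_nuclei=np.asarray(nucs)[order] if has_nuclei else None,
            )
        )
    return series


def exclude_cytotoxic(
    series: ConditionSeries,
    vehicle_nuclei_mean: float,
    viability_fraction: float = 0.5,
) -> ConditionSeries:
    """Mark cytotoxic concentrations as excluded from the fit.

    The lowest concentration whose mean nuclei count falls below
    ``viability_fraction`` of the vehicle mean, and every concentration above
    it, are excluded; lower concentrations are untouched.  Requires
    ``series.mean_nuclei``; a series without nuclei data is returned intact.
    """
    if series.mean_nuclei is None:
        return series
    cutoff = viability_fraction * vehicle_nuclei_mean
    toxic = series.mean_nuclei < cutoff  # aligned with descending concentrations
    if toxic.any():
        # exclusion applies from the lowest toxic concentration upward
        lowest_toxic_conc = series.concentrations[toxic].min()
        series.included = series.included & (
            series.concentrations < lowest_toxic_conc
        )
        logger.info(
            "%s: excluded %d cytotoxic concentrations (>= %g nM)",
            series.compound,
            int((~series.included).sum()),
            lowest_toxic_conc,
        )
    return series


def fit_4pl(series: ConditionSeries) -> FourPLFit:
    """Least-squares 4PL fit on the included, positive concentrations.

    Fitting runs in log10(EC50) space with EC50 bounded to
    [c_min/100, c_max*100]; initialization: bottom = min mean, top = max
    mean, EC50 = geometric mean of tested concentrations, hill = 1.  A flat
    series (zero observed range) or optimizer failure yields
    ``converged=False``.
    """
    use = series.included & (series.concentrations > 0) & np.isfinite(
        series.mean_response
    )
    c = series.concentrations[use]
    y = series.mean_response[use]
    if c.size < 4:
        raise ValidationError(
            f"{series.compound}: need >= 4 included concentrations, have {c.size}"
        )
    y_range = float(y.max() - y.min())
    if y_range == 0.0:
        return FourPLFit(
            bottom=float(y[0]), top=float(y[0]), ec50=float("nan"), hill=1.0,
            converged=False, n_points=int(c.size), message="flat series",
        )
    log_c = np.log10(c)
    lo, hi = log_c.min() - np.log10(EC50_BOUND_FACTOR), log_c.max() + np.log10(
        EC50_BOUND_FACTOR
    )

    def residuals(params: np.ndarray) -> np.ndarray:
        bottom, top, log_ec50, hill = params
        pred = bottom + (top - bottom) / (1.0 + 10 ** ((log_ec50 - log_c) * hill))
        return pred - y

    x0 = np.array([y.min(), y.max(), log_c.mean(), 1.0])
    bounds = (
        [-np.inf, -np.inf, lo, 1e-3],
        [np.inf, np.inf, hi, 20.0],
    )
    try:
        sol = optimize.least_squares(residuals, x0, bounds=bounds, xtol=1e-12,
                                     ftol=1e-12, gtol=1e-12)
    except Exception as exc:  # pragma: no cover - optimizer hard failure
        return FourPLFit(
            float("nan"), float("nan"), float("nan"), float("nan"),
            converged=False, n_points=int(c.size), message=str(exc),
        )
    bottom, top, log_ec50, hill = sol.x
    return FourPLFit(
        bottom=float(bottom),
        top=float(top),
        ec50=float(10**log_ec50),
        hill=float(hill),
        converged=bool(sol.success),
        rss=float(2 * sol.cost),
        n_points=int(c.size),
        message=str(sol.message),
    )


def ec50_with_plateau_check(
    series: ConditionSeries, fit: FourPLFit
) -> tuple[float | None, bool]:
    """EC50 with a plateau sanity check; returns ``(ec50, plateau_reached)``.

    EC50 is undetermined (None) when: (a) the fit did not converge; (b) the
    maximum included mean sits at the highest included concentration *and*
    the fitted top exceeds it by more than 20% (the response is still
    rising); or (c) the fitted EC50 is at or above the highest included
    concentration.  Undetermined EC50 implies ``plateau_reached=False``.
    """
    if not fit.converged or not np.isfinite(fit.ec50):
        return None, False
    use = series.included & (series.concentrations > 0)
    c = series.concentrations[use]
    y = series.mean_response[use]
    c_max = float(c.max())
    y_at_top = float(y[np.argmax(c)])
    y_max = float(y.max())
    still_rising = y_max == y_at_top and (
        fit.top - y_max > PLATEAU_EXCESS * abs(y_max)
    )
    if still_rising or fit.ec50 >= c_max:
        return None, False
    return float(fit.ec50), True


def efficacy_and_relative(
    series_list: list[ConditionSeries],
    reference: str,
    fits: dict[str, FourPLFit] | None = None,
) -> list[DoseResponseResult]:
    """Efficacy, relative efficacy and EC50 per compound.

    Efficacy is the maximum included condition mean (raw data, never the
    fitted top), with the SEM of that peak condition.  Relative efficacy
    divides by the reference compound's efficacy — exactly 1 for the
    reference itself — with first-order SEM propagation of the ratio.
    Vehicle series are carried through with the same normalisation.
    """
    by_name = {s.compound: s for s in series_list}
    if reference not in by_name:
        raise ValidationError(f"reference compound {reference!r} not in series")

    def peak(s: ConditionSeries) -> tuple[float, float, float]:
        idx = np.flatnonzero(s.included)
        if idx.size == 0:
            raise ValidationError(f"{s.compound}: all concentrations excluded")
        best = idx[np.argmax(s.mean_response[idx])]
        return (
            float(s.mean_response[best]),
            float(s.sem[best]),
            float(s.concentrations[best]),
        )

    ref_eff, ref_sem, _ = peak(by_name[reference])
    if ref_eff == 0:
        raise ValidationError("reference efficacy is zero; normalisation undefined")
    results = []
    for s in series_list:
        eff, eff_sem, peak_c = peak(s)
        if s.compound == reference:
            rel, rel_sem = 1.0, 0.0
        else:
            rel = eff / ref_eff
            rel_sem = (
                abs(rel) * np.hypot(
                    eff_sem / eff if eff else 0.0, ref_sem / ref_eff
                )
            )
        fit = fits.get(s.compound) if fits else None
        if fit is not None:
            ec50, plateau = ec50_with_plateau_check(s, fit)
        else:
            ec50, plateau = None, False
        results.append(
            DoseResponseResult(
                compound=s.compound,
                fit=fit,
                ec50=ec50,
                plateau_reached=plateau,
                efficacy=eff,
                efficacy_sem=eff_sem,
                peak_concentration=peak_c,
                relative_efficacy=rel,
                relative_efficacy_sem=float(rel_sem),
            )
        )
    return results


def two_group_anova_p(a: np.ndarray, b: np.ndarray) -> float:
    """One-way ANOVA p-value for two groups (identical to a two-sided t-test)."""
    return float(stats.f_oneway(a, b).pvalue)


def rank_compounds(
    results: list[DoseResponseResult],
    series_list: list[ConditionSeries],
    alpha: float = 0.05,
) -> list[DoseResponseResult]:
    """Competition-rank compounds by efficacy with statistical ties.

    Compounds are sorted by efficacy (descending); a compound joins the tie
    group of its predecessor when the two-group one-way ANOVA on their
    FOV-level responses at each compound's own peak dose yields p >= alpha.
    Tie groups share the rank of their first member (competition ranking).
    Ranks are written into the results and the sorted list is returned.
    """
    if len(results) < 2:
        for r in results:
            r.rank = 1
        return results
    fov_at_peak = {}
    for s in series_list:
        res = next((r for r in results if r.compound == s.compound), None)
        if res is None:
            continue
        fov_at_peak[s.compound] = s.fov_responses.get(
            res.peak_concentration, np.asarray([res.efficacy])
        )
    ordered = sorted(results, key=lambda r: r.efficacy, reverse=True)
    ranks = [1]
    for i in range(1, len(ordered)):
        a = fov_at_peak.get(ordered[i - 1].compound)
        b = fov_at_peak.get(ordered[i].compound)
        if a is not None and b is not None and len(a) > 1 and len(b) > 1:
            tied = two_group_anova_p(a, b) >= alpha
        else:
            tied = ordered[i].efficacy == ordered[i - 1].efficacy
        ranks.append(ranks[-1] if tied else i + 1)
    for r, rank in zip(ordered, ranks):
        r.rank = rank
    return ordered


def dose_response_table(results: list[DoseResponseResult]) -> pd.DataFrame:
    """Flatten results into the per-compound summary table."""
    rows = []
    for r in results:
        rows.append(
            {
                "compound": r.compound,
                "efficacy": r.efficacy,
                "efficacy_sem": r.efficacy_sem,
                "relative_efficacy": r.relative_efficacy,
                "relative_efficacy_sem": r.relative_efficacy_sem,
                "rank": r.rank,
                "ec50_nM": r.ec50 if r.ec50 is not None else np.nan,
                "plateau_reached": r.plateau_reached,
                "peak_concentration_nM": r.peak_concentration,
                "hill": r.fit.hill if r.fit and r.fit.converged else np.nan,
            }
        )
    return pd.DataFrame(rows)
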