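import numpy as np
import pandas as pd
import pytest
from scipy import stats

import axonwrap as aw
from axonwrap.io import PlateLayout, ValidationError
from axonwrap.dose_response import two_group_anova_p
from axonwrap.synthetic import serial_dilution_series


def _layout(compounds, n_wells=3, concentrations=None):
    concentrations = (
        serial_dilution_series() if concentrations is None else concentrations
    )
    rows = []
    w = 0
    for rep in range(n_wells):
        w += 1
        rows.append({"well": f"V{w}", "compound": "DMSO", "concentration_nM": 0.0,
                     "role": "vehicle", "replicate": rep})
    for i, comp in enumerate(compounds):
        role = "reference" if i == 0 else "test"
        for c in concentrations:
            for rep in range(n_wells):
                w += 1
                rows.append({"well": f"W{w}", "compound": comp,
                             "concentration_nM": float(c), "role": role,
                             "replicate": rep})
    return PlateLayout(pd.DataFrame(rows))


def _fov_table(layout, truths, n_fov=9, noise_sd=0.0, seed=0, nuclei=40):
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in layout.table.iterrows():
        if r["role"] == "vehicle":
            mean = min(t.bottom for t in truths.values())
        else:
            mean = truths[r["compound"]].response_at(r["concentration_nM"])
        for f in range(n_fov):
            rows.append({"well": r["well"], "fov": f"F{f}",
                         "wrapping_index": mean + rng.normal(0, noise_sd),
                         "n_nuclei": nuclei})
    return pd.DataFrame(rows)


@pytest.fixture
def truth():
    return aw.DoseResponseTruth(bottom=0.02, top=0.12, ec50=100.0, hill=1.0)


# ------------------------------------------------------------- aggregate


def test_aggregate_pools_27_fov_across_replicate_wells(truth):
    layout = _layout(["T3"])
    fov = _fov_table(layout, {"T3": truth})
    series = aw.aggregate(fov, layout)
    t3 = next(s for s in series if s.compound == "T3")
    assert np.all(t3.n_fov == 27)
    assert np.all(np.diff(t3.concentrations) < 0)
    # identical FOV values -> SEM zero (up to float accumulation)
    assert np.all(t3.sem < 1e-12)
    vehicle = next(s for s in series if s.role == "vehicle")
    assert list(vehicle.concentrations) == [0.0]


def test_aggregate_mean_and_sem_hand_computed():
    layout = _layout(["T3"], n_wells=2, concentrations=[100.0, 10.0, 3.0, 1.0])
    vals = {"W3": 1.0, "W4": 2.0}  # the two 100 nM wells
    rows = []
    for _, r in layout.table.iterrows():
        base = vals.get(r["well"], 0.5)
        for f, off in enumerate((-0.1, 0.0, 0.1)):
            rows.append({"well": r["well"], "fov": f"F{f}",
                         "wrapping_index": base + off})
    series = aw.aggregate(pd.DataFrame(rows), layout)
    t3 = next(s for s in series if s.compound == "T3")
    at_100 = list(t3.concentrations).index(100.0)
    sample = [0.9, 1.0, 1.1, 1.9, 2.0, 2.1]
    assert t3.mean_response[at_100] == pytest.approx(np.mean(sample))
    assert t3.sem[at_100] == pytest.approx(
        np.std(sample, ddof=1) / np.sqrt(len(sample))
    )


def test_aggregate_rejects_unmapped_wells(truth):
    layout = _layout(["T3"])
    fov = _fov_table(layout, {"T3": truth})
    fov.loc[0, "well"] = "ZZ9"
    with pytest.raises(ValidationError):
        aw.aggregate(fov, layout)


# ----------------------------------------------------------- cytotoxicity


def _series(concs, means, nuclei=None, sems=None, fovs=None):
    concs = np.asarray(concs, dtype=float)
    return aw.ConditionSeries(
        compound="X", role="test", concentrations=concs,
        mean_response=np.asarray(means, dtype=float),
        sem=np.asarray(sems if sems is not None else np.zeros_like(concs)),
        n_fov=np.asarray(fovs if fovs is not None else np.full(len(concs), 27)),
        included=np.ones(len(concs), dtype=bool),
        mean_nuclei=None if nuclei is None else np.asarray(nuclei, dtype=float),
    )


def test_no_cytotoxicity_keeps_everything():
    s = _series([100, 10, 1], [0.1, 0.05, 0.02], nuclei=[38, 40, 41])
    aw.exclude_cytotoxic(s, vehicle_nuclei_mean=40.0)
    assert s.included.all()


def test_top_dose_cytotoxicity_excluded():
    s = _series([100, 10, 1], [0.1, 0.05, 0.02], nuclei=[12, 40, 41])
    aw.exclude_cytotoxic(s, vehicle_nuclei_mean=40.0)  # 12 < 0.5 * 40
    assert list(s.included) == [False, True, True]


def test_exclusion_applies_from_lowest_toxic_dose_upward():
    # recovery above a toxic dose must not be re-included
    s = _series([100, 10, 1], [0.1, 0.05, 0.02], nuclei=[39, 15, 41])
    aw.exclude_cytotoxic(s, vehicle_nuclei_mean=40.0)
    assert list(s.included) == [False, False, True]


# ----------------------------------------------------------------- 4PL fit


def test_noiseless_fit_recovers_parameters(truth):
    concs = serial_dilution_series()
    s = _series(concs, truth.response_at(concs))
    fit = aw.fit_4pl(s)
    assert fit.converged
    assert fit.ec50 == pytest.approx(100.0, rel=1e-6)
    assert fit.hill == pytest.approx(1.0, rel=1e-4)
    assert fit.bottom == pytest.approx(0.02, abs=1e-6)
    assert fit.top == pytest.approx(0.12, abs=1e-6)


@pytest.mark.parametrize("ec50", [10.0, 100.0, 1000.0])
@pytest.mark.parametrize("hill", [0.7, 1.0, 2.0])
def test_noiseless_recovery_across_parameter_grid(ec50, hill):
    concs = serial_dilution_series()
    s = _series(concs, aw.logistic_4pl(concs, 0.0, 1.0, ec50, hill))
    fit = aw.fit_4pl(s)
    assert fit.ec50 == pytest.approx(ec50, rel=1e-5)
    assert fit.hill == pytest.approx(hill, rel=1e-4)


def test_flat_series_is_degenerate():
    concs = serial_dilution_series()
    s = _series(concs, np.full(len(concs), 0.07))
    fit = aw.fit_4pl(s)
    assert not fit.converged
    ec50, plateau = aw.ec50_with_plateau_check(s, fit)
    assert ec50 is None and plateau is False


def test_fit_requires_four_included_points(truth):
    concs = serial_dilution_series()[:3]
    s = _series(concs, truth.response_at(concs))
    with pytest.raises(ValidationError):
        aw.fit_4pl(s)


def test_noisy_ec50_bias_within_5pct_at_low_noise(truth):
    """Geometric-mean EC50 over seeded repeats stays near truth at 5% noise."""
    concs = serial_dilution_series()
    clean = truth.response_at(concs)
    estimates = []
    for seed in range(60):
        rng = np.random.default_rng(seed)
        s = _series(concs, clean + rng.normal(0, 0.05 * truth.top, len(concs)))
        fit = aw.fit_4pl(s)
        if fit.converged:
            estimates.append(fit.ec50)
    gmean = float(np.exp(np.mean(np.log(estimates))))
    assert abs(gmean - truth.ec50) / truth.ec50 < 0.05


# --------------------------------------------------------- plateau check


def test_saturating_series_returns_ec50(truth):
    concs = serial_dilution_series()
    s = _series(concs, truth.response_at(concs))
    fit = aw.fit_4pl(s)
    ec50, plateau = aw.ec50_with_plateau_check(s, fit)
    assert plateau and ec50 == pytest.approx(100.0, rel=1e-6)


def test_strictly_rising_series_is_undetermined():
    # fasudil-type response: no bend within the tested range
    concs = serial_dilution_series()
    means = aw.logistic_4pl(concs, 0.02, 0.30, 5e5, 1.0)  # EC50 50x top dose
    s = _series(concs, means)
    fit = aw.fit_4pl(s)
    ec50, plateau = aw.ec50_with_plateau_check(s, fit)
    assert ec50 is None and plateau is False


def test_ec50_beyond_top_dose_is_undetermined():
    concs = serial_dilution_series()  # top dose 10 uM
    means = aw.logistic_4pl(concs, 0.0, 1.0, 5e4, 2.0)  # true EC50 50 uM
    s = _series(concs, means)
    fit = aw.fit_4pl(s)
    ec50, plateau = aw.ec50_with_plateau_check(s, fit)
    assert ec50 is None and plateau is False


# ------------------------------------------------- efficacy and ranking


def test_reference_relative_efficacy_is_exactly_one(truth):
    concs = serial_dilution_series()
    ref = _series(concs, truth.response_at(concs))
    ref.compound, ref.role = "T3", "reference"
    test = _series(concs, 2 * truth.response_at(concs))
    results = aw.efficacy_and_relative([ref, test], "T3")
    by = {r.compound: r for r in results}
    assert by["T3"].relative_efficacy == 1.0
    assert by["T3"].relative_efficacy_sem == 0.0
    assert by["X"].relative_efficacy == pytest.approx(2.0)


def test_efficacy_taken_at_peak_not_top_dose():
    concs = np.array([1000.0, 100.0, 10.0, 1.0])
    s = _series(concs, [0.08, 0.12, 0.05, 0.02])  # decline after the peak
    s.compound, s.role = "T3", "reference"
    res = aw.efficacy_and_relative([s], "T3")[0]
    assert res.efficacy == pytest.approx(0.12)
    assert res.peak_concentration == 100.0


def test_efficacy_ignores_excluded_concentrations():
    concs = np.array([1000.0, 100.0, 10.0, 1.0])
    s = _series(concs, [0.5, 0.12, 0.05, 0.02])
    s.compound, s.role = "T3", "reference"
    s.included[0] = False  # cytotoxic artifact at top dose
    res = aw.efficacy_and_relative([s], "T3")[0]
    assert res.efficacy == pytest.approx(0.12)


def test_relative_efficacy_scale_invariant(truth):
    concs = serial_dilution_series()
    for scale in (1.0, 7.3):
        ref = _series(concs, scale * truth.response_at(concs))
        ref.compound, ref.role = "T3", "reference"
        other = _series(concs, scale * 1.7 * truth.response_at(concs))
        res = {r.compound: r for r in aw.efficacy_and_relative([ref, other], "T3")}
        assert res["X"].relative_efficacy == pytest.approx(1.7)


def _ranked(means, sds, n=27, seed=0):
    """Build compounds with exact FOV-level sample means and rank them."""
    rng = np.random.default_rng(seed)
    series, results = [], None
    concs = np.array([100.0, 10.0, 3.0, 1.0])
    slist = []
    for i, (mu, sd) in enumerate(zip(means, sds)):
        noise = rng.normal(0, sd, n)
        vals = mu + noise - noise.mean()  # sample mean exactly mu
        s = _series(concs, [mu, mu * 0.6, mu * 0.3, mu * 0.1])
        s.compound = f"C{i}" if i else "T3"
        s.role = "reference" if i == 0 else "test"
        s.fov_responses = {100.0: vals}
        s.sem[:] = sd / np.sqrt(n)
        slist.append(s)
    results = aw.efficacy_and_relative(slist, "T3")
    return aw.rank_compounds(results, slist)


def test_clearly_separated_compounds_get_distinct_ranks():
    ranked = _ranked([10.0, 7.0, 4.0], [0.5, 0.5, 0.5])
    assert [r.rank for r in ranked] == [1, 2, 3]


def test_identical_conditions_share_a_rank():
    ranked = _ranked([5.0, 5.0], [0.5, 0.5])
    assert [r.rank for r in ranked] == [1, 1]


def test_competition_ranking_with_statistical_tie():
    # means 10.1 vs 10 (sd 1, n 27): ANOVA cannot separate them; 5 can be
    ranked = _ranked([10.0, 10.1, 5.0], [1.0, 1.0, 1.0])
    by = {r.compound: r.rank for r in ranked}
    assert by["C1"] == by["T3"] == 1
    assert by["C2"] == 3


def test_two_group_anova_equals_t_test(rng):
    for _ in range(100):
        a = rng.normal(0, 1, rng.integers(5, 30))
        b = rng.normal(0.3, 1.5, rng.integers(5, 30))
        p_anova = two_group_anova_p(a, b)
        p_t = stats.ttest_ind(a, b).pvalue
        f = stats.f_oneway(a, b).statistic
        t = stats.ttest_ind(a, b).statistic
        assert p_anova == pytest.approx(p_t, abs=1e-10)
        assert f == pytest.approx(t**2, rel=1e-9)
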