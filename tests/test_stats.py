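"""Statistics: OLS against normal equations, exact Mann-Whitney, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from placseg.relaxometry import T2StarMap
from placseg.stats import (GA_BIN_NAMES, SubjectRecord, assign_ga_bin,
                           brain_placenta_correlations, ga_binned_comparison,
                           layerwise_trend, linreg, mann_whitney,
                           pl_group_analysis, significance_stars,
                           summarize_brain, _enumerate_p)


def _rec(sid, ga, comp_t2=None, **kw):
    comp = {}
    if comp_t2 is not None:
        comp = {name: {"t2star": v} for name, v in comp_t2.items()}
    defaults = dict(ga_delivery_weeks=39.0, group="healthy",
                    compartment_means=comp)
    defaults.update(kw)
    return SubjectRecord(subject_id=sid, ga_mri_weeks=ga, **defaults)


# ---------------------------------------------------------------- linreg

def test_perfect_line():
    x = np.arange(10.0)
    reg = linreg(x, 2 * x + 1)
    assert np.isclose(reg.slope, 2.0) and np.isclose(reg.intercept, 1.0)
    assert np.isclose(reg.r_squared, 1.0)


def test_constant_response():
    reg = linreg(np.arange(5.0), np.full(5, 3.0))
    assert reg.slope == 0.0 and reg.r_squared == 0.0


def test_ols_matches_normal_equation_oracle():
    """Slope/intercept/R^2/p agree with the closed-form normal equations
    plus t CDF to 1e-10 on a fixed n=8 fixture."""
    rng = np.random.default_rng(123)
    x = rng.uniform(0, 10, 8)
    y = 1.7 * x - 3.0 + rng.normal(0, 2.0, 8)
    reg = linreg(x, y)

    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(x) - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta[1] / np.sqrt(cov[1, 1])
    p = 2 * sps.t.sf(abs(t), len(x) - 2)
    r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

    assert abs(reg.intercept - beta[0]) < 1e-10
    assert abs(reg.slope - beta[1]) < 1e-10
    assert abs(reg.slope_se - np.sqrt(cov[1, 1])) < 1e-10
    assert abs(reg.r_squared - r2) < 1e-10
    assert abs(reg.p_value - p) < 1e-10


def test_ci_band_matches_statsmodels_formula():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 10, 12)
    y = 0.5 * x + rng.normal(0, 1, 12)
    reg = linreg(x, y)
    grid = np.linspace(0, 10, 5)
    fit, lo, hi = reg.ci_band(grid)
    # independent formula
    tcrit = sps.t.ppf(0.975, 10)
    se = np.sqrt(reg.sigma2 * (1 / 12 + (grid - x.mean()) ** 2
                               / ((x - x.mean()) ** 2).sum()))
    assert np.allclose(hi - fit, tcrit * se, atol=1e-12)
    assert np.all(lo < fit) and np.all(fit < hi)


def test_linreg_validation():
    with pytest.raises(ValueError, match="constant"):
        linreg(np.ones(5), np.arange(5.0))
    with pytest.raises(ValueError, match="3 points"):
        linreg(np.arange(2.0), np.arange(2.0))


# ----------------------------------------------------------- mann-whitney

def test_fully_separated_small_samples():
    """a={1,2,3} vs b={4,5,6}: U=0 and exact two-sided p = 2/20 = 0.1."""
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.u_statistic == 0.0
    assert np.isclose(res.p_value, 0.1)
    assert res.method == "exact"


def test_identical_samples():
    res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.u_statistic == 4.5
    assert res.p_value == 1.0


def test_exact_equals_full_enumeration_tie_free():
    rng = np.random.default_rng(8)
    for _ in range(5):
        a = rng.normal(size=5)
        b = rng.normal(0.5, 1.0, size=4)
        res = mann_whitney(a, b)
        ranks = sps.rankdata(np.concatenate([a, b]))
        p_enum = _enumerate_p(ranks, len(a), res.u_statistic)
        assert res.method == "exact"
        assert np.isclose(res.p_value, p_enum, atol=1e-12)


def test_normal_approximation_close_to_exact():
    """Large samples take the tie-corrected normal path, which stays within
    0.01 of scipy's exact enumeration-equivalent null distribution."""
    rng = np.random.default_rng(9)
    a = rng.normal(size=25)
    b = rng.normal(0.4, 1.0, size=25)
    res = mann_whitney(a, b)
    assert res.method == "normal_approx"
    exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert abs(res.p_value - exact.pvalue) < 0.01


def test_tied_small_samples_enumerated():
    res = mann_whitney([1, 2, 2, 3], [2, 4, 5])
    assert res.method == "enumeration"
    assert 0 < res.p_value <= 1


def test_empty_sample_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        mann_whitney([], [1.0])


# ------------------------------------------------------------ GA binning

def test_bin_convention_closed_lower_edge():
    assert assign_ga_bin(24.999) == "<25"
    assert assign_ga_bin(25.0) == "25-35"
    assert assign_ga_bin(35.0) == "25-35"
    assert assign_ga_bin(35.001) == ">35"


def test_binned_comparison_detects_planted_trend():
    """A strong negative IVS trend separates the <25 and >35 week bins."""
    rng = np.random.default_rng(2)
    recs = []
    ga_vals = np.r_[rng.uniform(20, 24.5, 7), rng.uniform(25, 35, 10),
                    rng.uniform(35.5, 38, 5)]
    for i, ga in enumerate(ga_vals):
        t2 = 100.0 - 2.0 * ga + rng.normal(0, 2.0)  # ~2 SD per 2 weeks
        recs.append(_rec(f"s{i}", float(ga), {"C1-IVS": t2}))
    res = ga_binned_comparison(recs, compartment="C1-IVS")
    assert res[("<25", ">35")].p_value < 0.05


def test_binned_comparison_skips_empty_bin():
    recs = [_rec(f"s{i}", 30.0 + i * 0.1, {"C1-IVS": 60.0}) for i in range(4)]
    with pytest.warns(UserWarning, match="skipped"):
        res = ga_binned_comparison(recs, compartment="C1-IVS")
    assert res == {}


def test_holm_adjustment_monotone():
    rng = np.random.default_rng(3)
    recs = []
    for i in range(18):
        ga = float(rng.uniform(20, 38))
        recs.append(_rec(f"s{i}", ga, {"C1-IVS": 90 - 1.5 * ga
                                       + rng.normal(0, 3)}))
    raw = ga_binned_comparison(recs, compartment="C1-IVS")
    adj = ga_binned_comparison(recs, compartment="C1-IVS", holm=True)
    for k in raw:
        assert adj[k].p_value >= raw[k].p_value - 1e-12


# --------------------------------------------------- group / brain / PL

def test_pl_group_analysis_contrast_and_regression():
    rng = np.random.default_rng(4)
    recs = []
    for i in range(20):
        recs.append(_rec(f"h{i}", 30.0, pl_fraction=float(
            rng.uniform(0.02, 0.05)), ga_delivery_weeks=float(
            rng.uniform(38, 41))))
    for i in range(5):
        f = float(rng.uniform(0.15, 0.35))
        recs.append(_rec(f"c{i}", 30.0, pl_fraction=f, group="complicated",
                         ga_delivery_weeks=40.0 - 12.0 * f))
    test, reg = pl_group_analysis(recs)
    assert test.p_value < 0.05
    assert reg.slope < 0  # heavier lesion burden, earlier delivery


def test_pl_group_all_zero_is_null():
    recs = [_rec(f"h{i}", 30.0, pl_fraction=0.0) for i in range(4)]
    recs += [_rec(f"c{i}", 30.0, pl_fraction=0.0, group="complicated",
                  ga_delivery_weeks=38.0 + 0.2 * i) for i in range(3)]
    test, _ = pl_group_analysis(recs)
    assert test.p_value == 1.0


def test_brain_identity_coupling_gives_r2_one():
    recs = []
    for i in range(8):
        t2 = 60.0 + i
        recs.append(_rec(f"s{i}", 30.0, {"C1-IVS": t2, "C2-PV": 50.0 + 2 * i,
                                         "C3-PT": 45.0, "total": 52.0 + i},
                         brain_t2star_ms=t2))
    res = brain_placenta_correlations(recs)
    assert np.isclose(res["C1-IVS"].r_squared, 1.0)
    assert list(res)[0] == "C1-IVS"  # ranked first by R^2


def test_brain_missing_records_dropped_with_warning():
    recs = [_rec(f"s{i}", 30.0, {"C1-IVS": 60.0 + i, "C2-PV": 50.0,
                                 "C3-PT": 45.0, "total": 50.0},
                 brain_t2star_ms=(70.0 + i if i < 5 else None))
            for i in range(8)]
    with pytest.warns(UserWarning, match="dropped"):
        res = brain_placenta_correlations(recs)
    assert res["C1-IVS"].n == 5


def test_summarize_brain_arithmetic():
    shape = (10, 10, 10)
    mask = np.zeros(shape, bool)
    mask.flat[:1000] = True
    t2 = np.full(shape, 80.0)
    t2map = T2StarMap(t2star=t2, s0=None, fit_valid=np.ones(shape, bool))
    vol, mean = summarize_brain(t2map, mask, (1.0, 1.0, 1.0))
    assert np.isclose(vol, 1.0)
    assert np.isclose(mean, 80.0)
    with pytest.raises(ValueError, match="empty"):
        summarize_brain(t2map, np.zeros(shape, bool), (1, 1, 1))


def test_layerwise_trend_recovers_planted_slope_ordering():
    """Steepest decline in the chorionic layer, positive at the basal
    layer, mirrors the planted per-layer slopes."""
    rng = np.random.default_rng(6)
    slopes = {"B": -2.0, "C": -1.5, "D": -1.0, "E": 0.0, "F": 0.8}
    rows = []
    for i in range(20):
        ga = float(rng.uniform(20, 38))
        for layer, sl in slopes.items():
            rows.append({"subject_id": f"s{i}", "layer": layer,
                         "ga_mri_weeks": ga,
                         "t2star_mean": 70 + sl * (ga - 29)
                         + rng.normal(0, 1.5)})
    tab = layerwise_trend(pd.DataFrame(rows))
    fitted = dict(zip(tab["layer"], tab["slope"]))
    order = sorted(slopes, key=slopes.get)
    assert sorted(fitted, key=fitted.get) == order
    assert fitted["B"] < fitted["F"]


def test_layerwise_trend_omits_sparse_layer():
    rows = []
    for i in range(10):
        rows.append({"subject_id": f"s{i}", "layer": "B",
                     "ga_mri_weeks": 20.0 + i, "t2star_mean": 60.0 - i})
        if i < 2:
            rows.append({"subject_id": f"s{i}", "layer": "F",
                         "ga_mri_weeks": 20.0 + i, "t2star_mean": 50.0})
    with pytest.warns(UserWarning, match="omitted"):
        tab = layerwise_trend(pd.DataFrame(rows))
    assert list(tab["layer"]) == ["B"]


def test_significance_stars_tiers():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.004) == "***"
    assert significance_stars(0.2) == ""


def test_record_validation():
    with pytest.raises(ValueError):
        SubjectRecord("x", 10.0, 39.0, "healthy")
    with pytest.raises(ValueError):
        SubjectRecord("x", 30.0, 39.0, "healthy", pl_fraction=1.5)
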