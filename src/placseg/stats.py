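"""Cohort statistics: GA trends, group tests and brain-placenta coupling.

Implements the study's statistical toolkit: ordinary least-squares
regression with pointwise 95% confidence bands (compartment or layer T2*
versus gestational age, lesion burden versus GA at delivery, fetal-brain
T2* versus compartment T2*), Mann-Whitney U comparisons between
gestational-age bins (<25, 25-35, >35 weeks) and between healthy and
complicated groups, and fetal-brain volume/T2* summaries.  Raw two-sided
p-values are reported (star tiers *P<0.05, **P<0.01, ***P<0.005); an
optional Holm adjustment is available for the binned comparisons.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

GA_BIN_EDGES = (25.0, 35.0)
GA_BIN_NAMES = ("<25", "25-35", ">35")


@dataclass
class SubjectRecord:
    """Scalar per-subject measurements entering the cohort analyses."""

    subject_id: str
    ga_mri_weeks: float
    ga_delivery_weeks: float
    group: str  # healthy | complicated
    compartment_means: dict = field(default_factory=dict)
    pl_fraction: float = 0.0
    brain_volume_cm3: float | None = None
    brain_t2star_ms: float | None = None

    def __post_init__(self):
        if not 18.0 <= self.ga_mri_weeks <= 43.0:
            raise ValueError("GA at MRI outside plausible range [18, 43]")
        if not 0.0 <= self.pl_fraction <= 1.0:
            raise ValueError("pl_fraction must lie in [0, 1]")

    def feature_mean(self, compartment: str, feature: str = "t2star"):
        comp = self.compartment_means.get(compartment)
        if comp is None:
            return None
        return comp.get(feature)


@dataclass
class RegressionResult:
    """OLS slope/intercept with R^2, two-sided slope t-test and CI band."""

    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    x_mean: float = 0.0
    sxx: float = 1.0
    sigma2: float = 0.0

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, float)

    def ci_band(self, x, level: float = 0.95):
        """Pointwise CI of the mean response at x: (fit, lower, upper)."""
        x = np.asarray(x, float)
        fit = self.predict(x)
        if self.n <= 2:
            half = np.full_like(fit, np.inf)
        else:
            tcrit = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
            se = np.sqrt(self.sigma2 * (1.0 / self.n
                                        + (x - self.x_mean) ** 2 / self.sxx))
            half = tcrit * se
        return fit, fit - half, fit + half

    @property
    def ci95_slope(self):
        tcrit = sps.t.ppf(0.975, self.n - 2)
        return (self.slope - tcrit * self.slope_se,
                self.slope + tcrit * self.slope_se)


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares of y on x (closed-form normal equations)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    sigma2 = ss_res / (n - 2)
    se = math.sqrt(sigma2 / sxx)
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return RegressionResult(slope=float(slope), slope_se=float(se),
                            intercept=float(intercept), r_squared=float(r2),
                            p_value=max(p, np.finfo(float).tiny), n=n,
                            x_mean=float(xm), sxx=float(sxx),
                            sigma2=float(sigma2))


@dataclass
class GroupTestResult:
    """Mann-Whitney U with the p-value method actually used."""

    u_statistic: float
    p_value: float
    method: str  # exact | enumeration | normal_approx
    n1: int
    n2: int


_MAX_ENUMERATION = 200_000  # arrangements; full enumeration above is infeasible


def mann_whitney(a, b) -> GroupTestResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    Tie-free samples with n1*n2 <= 400 use the exact null distribution
    (identical to full enumeration).  Tied small samples are enumerated
    outright when feasible; otherwise a tie-corrected normal approximation
    with continuity correction is used.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    small = n1 * n2 <= 400

    if small and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return GroupTestResult(float(res.statistic), float(res.pvalue),
                               "exact", n1, n2)
    if small and math.comb(n1 + n2, n1) <= _MAX_ENUMERATION:
        p = _enumerate_p(ranks, n1, u1)
        return GroupTestResult(float(u1), p, "enumeration", n1, n2)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return GroupTestResult(float(u1), 1.0, "normal_approx", n1, n2)
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return GroupTestResult(float(u1), p, "normal_approx", n1, n2)


def _enumerate_p(ranks, n1, u_obs):
    """Exact two-sided p over all C(n, n1) group assignments of the ranks."""
    n = ranks.size
    offset = n1 * (n1 + 1) / 2.0
    mu = n1 * (n - n1) / 2.0
    lo = hi = total = 0
    eps = 1e-9
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - offset
        total += 1
        if u <= u_obs + eps:
            lo += 1
        if u >= u_obs - eps:
            hi += 1
    # match the conventional 2*min-tail definition, capped at 1
    return float(min(1.0, 2.0 * min(lo, hi) / total))


def assign_ga_bin(ga_weeks: float) -> str:
    """Bin GA as <25, 25-35 (lower edge closed) or >35 weeks."""
    if ga_weeks < GA_BIN_EDGES[0]:
        return GA_BIN_NAMES[0]
    if ga_weeks <= GA_BIN_EDGES[1]:
        return GA_BIN_NAMES[1]
    return GA_BIN_NAMES[2]


def ga_binned_comparison(records, feature: str = "t2star",
                         compartment: str = "C1-IVS",
                         holm: bool = False) -> dict:
    """Pairwise Mann-Whitney tests of a compartment feature between GA bins."""
    bins: dict[str, list] = {name: [] for name in GA_BIN_NAMES}
    for rec in records:
        val = rec.feature_mean(compartment, feature)
        if val is not None:
            bins[assign_ga_bin(rec.ga_mri_weeks)].append(val)
    results = {}
    for lo, hi in itertools.combinations(GA_BIN_NAMES, 2):
        if not bins[lo] or not bins[hi]:
            warnings.warn(f"GA bin pair {lo} vs {hi} skipped (empty bin)")
            continue
        results[(lo, hi)] = mann_whitney(bins[lo], bins[hi])
    if holm and results:
        results = _holm_adjust(results)
    return results


def _holm_adjust(results):
    keys = sorted(results, key=lambda k: results[k].p_value)
    m = len(keys)
    running = 0.0
    out = dict(results)
    for i, k in enumerate(keys):
        adj = min(1.0, (m - i) * results[k].p_value)
        running = max(running, adj)
        r = results[k]
        out[k] = GroupTestResult(r.u_statistic, running, r.method, r.n1, r.n2)
    return out


def pl_group_analysis(records):
    """Lesion burden: healthy-vs-complicated test and regression on GA at delivery.

    Returns ``(GroupTestResult, RegressionResult)`` — the Mann-Whitney
    comparison of pl_fraction between groups and the pooled OLS of
    pl_fraction on GA at delivery.
    """
    healthy = [r.pl_fraction for r in records if r.group == "healthy"]
    complicated = [r.pl_fraction for r in records if r.group == "complicated"]
    if not healthy or not complicated:
        raise ValueError("both groups must be non-empty")
    test = mann_whitney(healthy, complicated)
    x = [r.ga_delivery_weeks for r in records]
    y = [r.pl_fraction for r in records]
    reg = linreg(x, y)
    return test, reg


def brain_placenta_correlations(records,
                                compartments=("C1-IVS", "C2-PV", "C3-PT",
                                              "total")) -> dict:
    """OLS of fetal-brain T2* on each compartment's T2*, ranked by R^2."""
    usable = [r for r in records if r.brain_t2star_ms is not None]
    dropped = len(records) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} records without brain T2* dropped")
    results = {}
    for comp in compartments:
        pairs = [(r.feature_mean(comp), r.brain_t2star_ms) for r in usable
                 if r.feature_mean(comp) is not None]
        if len(pairs) < 3:
            continue
        x, y = zip(*pairs)
        try:
            results[comp] = linreg(x, y)
        except ValueError as err:
            warnings.warn(f"compartment {comp} skipped: {err}")
    return dict(sorted(results.items(), key=lambda kv: -kv[1].r_squared))


def summarize_brain(t2map, brain_mask, voxel_size):
    """Fetal-brain volume (cm^3) and mean T2* (ms) over valid-fit voxels."""
    brain_mask = np.asarray(brain_mask, bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    voxel_mm3 = float(np.prod(voxel_size))
    volume_cm3 = brain_mask.sum() * voxel_mm3 / 1000.0
    ok = brain_mask & t2map.fit_valid
    mean_t2 = float(np.nanmean(t2map.t2star[ok])) if ok.any() else np.nan
    return float(volume_cm3), mean_t2


def layerwise_trend(layer_table: pd.DataFrame, value: str = "t2star_mean",
                    ga: str = "ga_mri_weeks") -> pd.DataFrame:
    """Per-layer OLS of layer-mean T2* on GA across subjects.

    ``layer_table`` needs columns (subject_id, layer, ga, value).  Layers
    present in at most half the subjects are omitted with a warning.
    """
    n_subjects = layer_table["subject_id"].nunique()
    rows = []
    for layer, grp in layer_table.groupby("layer", sort=True):
        if grp["subject_id"].nunique() < max(3, n_subjects / 2.0):
            warnings.warn(f"layer {layer} missing in too many subjects; "
                          "omitted")
            continue
        reg = linreg(grp[ga].to_numpy(), grp[value].to_numpy())
        lo, hi = reg.ci95_slope
        rows.append({"layer": layer, "slope": reg.slope,
                     "slope_ci_low": lo, "slope_ci_high": hi,
                     "r_squared": reg.r_squared, "p_value": reg.p_value,
                     "n": reg.n})
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Star tiers: *P<0.05, **P<0.01, ***P<0.005."""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
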