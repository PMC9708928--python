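"""Fuzzy Gaussian-mixture segmentation of dual-contrast placental features.

A K-component Gaussian mixture (default K = 3, the physiological
compartments) is fitted by expectation-maximization to z-scored
(ADC, FA, AD, RD, T2*) voxel vectors.  Soft assignment uses the posterior
responsibilities ("fuzzy" membership).  Voxels atypical for *every*
component are assigned to an additional lesion cluster: per component, the
typicality is the upper-tail probability of the squared Mahalanobis
distance under a chi-square law with 5 degrees of freedom, and a voxel is
flagged when all typicalities fall below the threshold (default 0.05).
Since normalized posteriors over K components cannot all be below 0.05,
this typicality reading is the coherent formulation of an
"unassignable-to-any-cluster" rule at that threshold; by construction it
flags a fraction ~alpha of voxels that truly belong to a well-separated
fitted mixture, which is why :func:`estimate_lesion_burden` subtracts that
known null rate when quantifying a planted/true lesion load.

Components are mapped to anatomical names from their de-standardized
feature means: highest FA -> PV (coherent vessel flow), then higher T2* of
the remaining two -> IVS (oxygenated maternal blood), the other -> PT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from scipy.stats import chi2
from sklearn.cluster import kmeans_plusplus

from .phantom import FEATURES

_LOG2PI = np.log(2.0 * np.pi)

#: Canonical cluster names in report order.
CLUSTER_NAMES = ("C1-IVS", "C2-PV", "C3-PT", "C4-PL")


@dataclass
class FeatureTable:
    """Masked-voxel feature matrix with a back-map into the volume.

    ``values`` is (n_voxels, 5) in FEATURES order, finite everywhere;
    ``voxel_index`` is the (n_voxels, 3) array of 0-based voxel coordinates;
    ``shape`` the source volume shape.
    """

    values: np.ndarray
    voxel_index: np.ndarray | None = None
    shape: tuple | None = None

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[1] != len(FEATURES):
            raise ValueError(f"values must be (n, {len(FEATURES)})")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature table contains non-finite values")
        self.values = v

    def __len__(self):
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(FEATURES))


def build_feature_table(t2map, tensors, mask) -> FeatureTable:
    """Assemble (ADC, FA, AD, RD, T2*) rows for valid-fit voxels in mask."""
    mask = np.asarray(mask, bool)
    ok = mask & t2map.fit_valid & tensors.fit_valid
    idx = np.argwhere(ok)
    values = np.column_stack([
        tensors.adc[ok], tensors.fa[ok], tensors.ad[ok], tensors.rd[ok],
        t2map.t2star[ok]])
    return FeatureTable(values=values, voxel_index=idx, shape=mask.shape)


@dataclass
class MixtureModel:
    """Fitted Gaussian mixture in standardized feature space."""

    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, p) standardized
    covariances: np.ndarray      # (K, p, p)
    center: np.ndarray           # per-feature standardization offset
    scale: np.ndarray            # per-feature standardization scale
    loglik_trace: list = field(default_factory=list)
    seed: int = 0
    converged: bool = True
    feature_names: tuple = FEATURES

    @property
    def n_components(self) -> int:
        return self.weights.size

    def standardize(self, X) -> np.ndarray:
        return (np.asarray(X, float) - self.center) / self.scale

    def destandardized_means(self) -> np.ndarray:
        """Component means on the original feature scale."""
        return self.center + self.means * self.scale

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "seed": int(self.seed),
            "converged": bool(self.converged),
            "feature_names": list(self.feature_names),
            "loglik_trace": [float(v) for v in self.loglik_trace],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            weights=np.asarray(d["weights"], float),
            means=np.asarray(d["means"], float),
            covariances=np.asarray(d["covariances"], float),
            center=np.asarray(d["center"], float),
            scale=np.asarray(d["scale"], float),
            loglik_trace=list(d.get("loglik_trace", [])),
            seed=int(d.get("seed", 0)),
            converged=bool(d.get("converged", True)),
            feature_names=tuple(d.get("feature_names", FEATURES)))


def _log_components(Z, weights, means, covs):
    """Weighted log densities (n, K) and squared Mahalanobis distances."""
    n, p = Z.shape
    K = weights.size
    logp = np.empty((n, K))
    d2 = np.empty((n, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        sol = solve_triangular(L, (Z - means[k]).T, lower=True)
        dk = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        d2[:, k] = dk
        logp[:, k] = np.log(weights[k]) - 0.5 * (dk + logdet + p * _LOG2PI)
    return logp, d2


def _m_step(Z, gamma, ridge):
    n, p = Z.shape
    nk = gamma.sum(axis=0)
    weights = nk / n
    means = (gamma.T @ Z) / nk[:, None]
    covs = np.empty((nk.size, p, p))
    for k in range(nk.size):
        diff = Z - means[k]
        cov = (gamma[:, k][:, None] * diff).T @ diff / nk[k]
        covs[k] = cov + (ridge * np.trace(cov) / p) * np.eye(p)
    return weights, means, covs


def fit_mixture(features, K: int = 3, seed: int = 0, *,
                n_restarts: int = 5, max_iter: int = 500, tol: float = 1e-7,
                ridge: float = 1e-6) -> MixtureModel:
    """Fit a K-component full-covariance Gaussian mixture by EM.

    Features are z-scored on the training pool (the standardizer is stored
    in the model so new subjects project consistently).  Responsibilities
    are initialized from k-means++ centers; the best of ``n_restarts`` runs
    by final log-likelihood is kept.  Each M-step adds a relative ridge
    ``ridge * trace(cov)/p`` to the covariance diagonal to guard the near
    collinearity of ADC with AD and RD.
    """
    X = features.values if isinstance(features, FeatureTable) else \
        np.asarray(features, float)
    n, p = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= 2 and n < 50 * K:
        raise ValueError(f"need >= {50 * K} voxels to fit K={K} components")

    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale

    if K == 1:
        cov = np.cov(Z.T, bias=True).reshape(p, p)
        cov = cov + (ridge * np.trace(cov) / p) * np.eye(p)
        ll = float(logsumexp(_log_components(
            Z, np.ones(1), Z.mean(0)[None], cov[None])[0], axis=1).sum())
        return MixtureModel(np.ones(1), Z.mean(0)[None], cov[None],
                            center, scale, [ll], seed, True)

    best = None
    failures = []
    for restart in range(n_restarts):
        rs = seed + 1000 * restart
        try:
            model = _fit_once(Z, K, rs, max_iter, tol, ridge)
        except np.linalg.LinAlgError as err:
            failures.append(str(err))
            continue
        if best is None or model[-1][-1] > best[-1][-1]:
            best = model
    if best is None:
        raise RuntimeError(
            "all EM restarts failed with singular covariances: "
            + "; ".join(failures))
    weights, means, covs, converged, trace = best
    return MixtureModel(weights, means, covs, center, scale, trace, seed,
                        converged)


def _fit_once(Z, K, seed, max_iter, tol, ridge):
    n, p = Z.shape
    centers, _ = kmeans_plusplus(Z, n_clusters=K, random_state=seed)
    # one-hot responsibilities from nearest center
    d = ((Z[:, None, :] - centers[None]) ** 2).sum(-1) if n * K * p < 5e7 \
        else None
    if d is None:
        d = np.empty((n, K))
        for k in range(K):
            d[:, k] = ((Z - centers[k]) ** 2).sum(1)
    gamma = np.zeros((n, K))
    gamma[np.arange(n), d.argmin(1)] = 1.0
    gamma = np.clip(gamma, 1e-10, None)
    gamma /= gamma.sum(1, keepdims=True)

    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        weights, means, covs = _m_step(Z, gamma, ridge)
        logp, _ = _log_components(Z, weights, means, covs)
        norm = logsumexp(logp, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        gamma = np.exp(logp - norm[:, None])
        if ll - prev < tol * max(1.0, abs(ll)) and np.isfinite(prev):
            converged = True
            break
        prev = ll
    return weights, means, covs, converged, trace


def posterior_probabilities(model: MixtureModel, features) -> np.ndarray:
    """Per-voxel posterior responsibilities gamma (rows sum to 1)."""
    X = features.values if isinstance(features, FeatureTable) else \
        np.asarray(features, float)
    Z = model.standardize(X)
    logp, _ = _log_components(Z, model.weights, model.means,
                              model.covariances)
    norm = logsumexp(logp, axis=1)
    gamma = np.exp(logp - norm[:, None])
    bad = ~np.isfinite(norm)
    if bad.any():
        gamma[bad] = np.nan
    return gamma


def mahalanobis_sq(model: MixtureModel, features) -> np.ndarray:
    X = features.values if isinstance(features, FeatureTable) else \
        np.asarray(features, float)
    Z = model.standardize(X)
    _, d2 = _log_components(Z, model.weights, model.means, model.covariances)
    return d2


def typicality(model: MixtureModel, features) -> np.ndarray:
    """Per-component chi-square(p) upper-tail probability of Mahalanobis^2."""
    d2 = mahalanobis_sq(model, features)
    return chi2.sf(d2, df=len(model.feature_names))


def flag_outliers(model: MixtureModel, features, alpha: float = 0.05):
    """Flag voxels atypical for every component (the lesion cluster).

    Returns ``(pl_mask, typicality)``; a voxel is flagged when its
    typicality is below ``alpha`` for all components.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    typ = typicality(model, features)
    return np.all(typ < alpha, axis=1), typ


def label_compartments(model: MixtureModel) -> dict[int, str]:
    """Map component indices to anatomical names from their feature means.

    Highest de-standardized FA mean -> C2-PV; of the remaining two, higher
    T2* -> C1-IVS and the other -> C3-PT.  Requires K = 3.
    """
    if model.n_components != 3:
        raise ValueError("compartment naming requires K = 3")
    means = model.destandardized_means()
    i_fa = FEATURES.index("fa")
    i_t2 = FEATURES.index("t2star")
    fa = means[:, i_fa]
    order = np.argsort(fa)
    if abs(fa[order[2]] - fa[order[1]]) < 1e-6:
        raise ValueError("FA means tied; manual compartment mapping required")
    pv = int(order[2])
    rest = [int(order[0]), int(order[1])]
    t2 = means[rest, i_t2]
    if abs(t2[0] - t2[1]) < 1e-6:
        raise ValueError("T2* means tied; manual compartment mapping required")
    ivs = rest[int(np.argmax(t2))]
    pt = rest[1 - int(np.argmax(t2))]
    return {ivs: "C1-IVS", pv: "C2-PV", pt: "C3-PT"}


@dataclass
class SegmentationResult:
    """Fuzzy and hard segmentation of one feature table."""

    posterior: np.ndarray       # (n, K)
    typicality: np.ndarray      # (n, K)
    hard_label: np.ndarray      # (n,) strings from CLUSTER_NAMES
    pl_mask: np.ndarray         # (n,) bool
    pl_fraction: float
    component_names: dict       # component index -> name
    alpha: float


def segment(model: MixtureModel, features, alpha: float = 0.05
            ) -> SegmentationResult:
    """Full fuzzy segmentation: posteriors, typicalities, names, PL flag."""
    gamma = posterior_probabilities(model, features)
    pl, typ = flag_outliers(model, features, alpha)
    names = label_compartments(model)
    hard = np.array([names[k] for k in gamma.argmax(axis=1)], dtype=object)
    hard[pl] = "C4-PL"
    return SegmentationResult(
        posterior=gamma, typicality=typ, hard_label=hard, pl_mask=pl,
        pl_fraction=float(pl.mean()), component_names=names, alpha=alpha)


def pl_fraction(segresult: SegmentationResult,
                placental_mask: np.ndarray | None = None,
                voxel_index: np.ndarray | None = None):
    """Lesion-cluster voxels as a proportion of placental voxels.

    Without a mask, the denominator is every voxel in the feature table.
    With a mask (and the table's voxel back-map) the per-slice (axial)
    fractions are also returned as a DataFrame.
    """
    if placental_mask is None:
        return float(segresult.pl_mask.mean())
    placental_mask = np.asarray(placental_mask, bool)
    n_total = int(placental_mask.sum())
    if n_total == 0:
        raise ValueError("placental mask is empty")
    frac = float(segresult.pl_mask.sum()) / n_total
    if voxel_index is None:
        return frac
    rows = []
    for z in np.unique(voxel_index[:, 2]):
        in_slice = voxel_index[:, 2] == z
        denom = int((placental_mask & (np.arange(placental_mask.shape[2])
                                       == z)[None, None, :]).sum())
        rows.append({"slice": int(z),
                     "pl_fraction": float(segresult.pl_mask[in_slice].sum())
                     / max(denom, 1)})
    return frac, pd.DataFrame(rows)


def estimate_lesion_burden(pl_frac: float, alpha: float = 0.05) -> float:
    """Null-corrected estimate of the true lesion volume fraction.

    The all-components typicality rule flags ~alpha of voxels that truly
    belong to the fitted mixture, so the raw PL fraction of a placenta with
    lesion fraction f is ~ f + (1 - f) alpha.  Inverting gives
    (raw - alpha) / (1 - alpha), clipped below at 0.
    """
    return float(max(0.0, (pl_frac - alpha) / (1.0 - alpha)))


def match_components(reference_means: np.ndarray, means: np.ndarray
                     ) -> np.ndarray:
    """Hungarian matching: permutation p with means[p[k]] ~ reference[k]."""
    cost = np.linalg.norm(reference_means[:, None, :] - means[None, :, :],
                          axis=2)
    _, col = linear_sum_assignment(cost)
    return col


def subsample_stability(features, n_voxels: int = 10_000, repeats: int = 10,
                        seed: int = 0, K: int = 3, **fit_kw):
    """Refit the mixture on random voxel subsamples and summarize dispersion.

    Mirrors the repeat-training reproducibility check: ``repeats``
    independent subsamples of ``n_voxels`` are each refitted and matched to
    the full-data fit by Hungarian assignment on de-standardized means.
    Returns ``(per_repeat, summary)`` DataFrames; the summary carries the
    across-repeat mean and coefficient of variation per component and
    feature (CV absent when repeats == 1).
    """
    X = features.values if isinstance(features, FeatureTable) else \
        np.asarray(features, float)
    n = X.shape[0]
    if n_voxels > n:
        raise ValueError(f"n_voxels={n_voxels} exceeds available rows ({n})")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")

    reference = fit_mixture(X, K=K, seed=seed, **fit_kw)
    ref_means = reference.destandardized_means()
    names = label_compartments(reference) if K == 3 else \
        {k: f"component-{k}" for k in range(K)}

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        idx = rng.choice(n, size=n_voxels, replace=False)
        model = fit_mixture(X[idx], K=K, seed=seed + rep, **fit_kw)
        perm = match_components(ref_means, model.destandardized_means())
        means = model.destandardized_means()[perm]
        for k in range(K):
            for j, feat in enumerate(FEATURES):
                rows.append({"repeat": rep, "component": names[k],
                             "feature": feat, "mean": means[k, j]})
    per_repeat = pd.DataFrame(rows)
    summary = (per_repeat.groupby(["component", "feature"])["mean"]
               .agg(["mean", "std"]).reset_index())
    if repeats > 1:
        summary["cv"] = summary["std"] / summary["mean"].abs()
    else:
        summary["cv"] = np.nan
        summary["std"] = np.nan
    return per_repeat, summary
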