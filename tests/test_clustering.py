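"""Fuzzy mixture model: EM recovery, posteriors, outlier rule, stability."""

import numpy as np
import pytest
from scipy.stats import chi2
from sklearn.mixture import GaussianMixture

import placseg as ps
from placseg.clustering import (FeatureTable, MixtureModel, fit_mixture,
                                flag_outliers, label_compartments,
                                match_components, pl_fraction,
                                posterior_probabilities, segment,
                                subsample_stability, typicality)
from placseg.phantom import LABEL_CODES, sample_gaussian_mixture


def _truth_means(X, y):
    return np.array([X[y == c].mean(axis=0) for c in (1, 2, 3)])


def test_em_recovers_well_separated_components(separated_mixture_sample):
    """Means within 2% of the generating truth and >= 99% label agreement
    after Hungarian matching on a well-separated 3-component mixture."""
    X, y = separated_mixture_sample
    X, y = X[:10_000], y[:10_000]
    model = fit_mixture(X, K=3, seed=0)
    truth = _truth_means(X, y)
    perm = match_components(truth, model.destandardized_means())
    fitted = model.destandardized_means()[perm]
    assert np.all(np.abs(fitted - truth) / np.abs(truth) < 0.02)

    gamma = posterior_probabilities(model, X)
    hard = gamma.argmax(axis=1)
    # map truth codes 1..3 onto matched component indices
    code_to_comp = {c: perm[i] for i, c in enumerate((1, 2, 3))}
    agree = np.mean([code_to_comp[c] == h for c, h in zip(y, hard)])
    assert agree >= 0.99


def test_em_loglik_monotone(separated_mixture_sample):
    X, _ = separated_mixture_sample
    model = fit_mixture(X[:5000], K=3, seed=1)
    trace = np.asarray(model.loglik_trace)
    assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))


def test_single_component_is_sample_moments(separated_mixture_sample):
    """K=1 EM fixed point: z-space mean 0 and ML (1/n) covariance."""
    X, _ = separated_mixture_sample
    X = X[:2000]
    model = fit_mixture(X, K=1, seed=0)
    Z = model.standardize(X)
    assert np.allclose(model.means[0], Z.mean(axis=0), atol=1e-12)
    assert np.allclose(model.covariances[0], np.cov(Z.T, bias=True),
                       atol=1e-5)


def test_duplication_invariance(separated_mixture_sample):
    """Duplicating every row leaves the fitted model (same seed) unchanged
    up to EM convergence tolerance."""
    X, _ = separated_mixture_sample
    X = X[:3000]
    m1 = fit_mixture(X, K=3, seed=5)
    m2 = fit_mixture(np.vstack([X, X]), K=3, seed=5)
    perm = match_components(m1.destandardized_means(),
                            m2.destandardized_means())
    assert np.allclose(m1.destandardized_means(),
                       m2.destandardized_means()[perm], rtol=1e-4)
    assert np.allclose(np.sort(m1.weights), np.sort(m2.weights), atol=1e-4)


def test_refit_same_seed_identical(separated_mixture_sample):
    X, _ = separated_mixture_sample
    m1 = fit_mixture(X[:3000], K=3, seed=9)
    m2 = fit_mixture(X[:3000], K=3, seed=9)
    assert np.array_equal(m1.means, m2.means)
    assert np.array_equal(m1.covariances, m2.covariances)


def test_sklearn_cross_check(separated_mixture_sample):
    """Independent EM implementation agrees on the component means."""
    X, y = separated_mixture_sample
    X = X[:8000]
    model = fit_mixture(X, K=3, seed=0)
    Z = model.standardize(X)
    sk = GaussianMixture(3, covariance_type="full", random_state=0,
                         n_init=3).fit(Z)
    perm = match_components(model.means, sk.means_)
    assert np.allclose(model.means, sk.means_[perm], atol=0.02)


def test_posterior_normalization_and_symmetry():
    rng = np.random.default_rng(0)
    mean = np.zeros(5)
    cov = np.eye(5)
    model = MixtureModel(weights=np.full(3, 1 / 3),
                         means=np.tile(mean, (3, 1)),
                         covariances=np.tile(cov, (3, 1, 1)),
                         center=np.zeros(5), scale=np.ones(5))
    X = rng.normal(size=(100, 5))
    gamma = posterior_probabilities(model, X)
    assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
    assert np.allclose(gamma, 1.0 / 3.0, atol=1e-12)


def test_posterior_peaks_at_component_mean():
    """A voxel at a well-separated component's mean takes gamma > 0.99
    there (density-ratio argument: the other components are > 5 sigma
    away, so their weighted densities are vanishing)."""
    means = np.array([[0.0] * 5, [8.0] * 5, [-8.0] * 5])
    model = MixtureModel(weights=np.full(3, 1 / 3), means=means,
                         covariances=np.tile(np.eye(5), (3, 1, 1)),
                         center=np.zeros(5), scale=np.ones(5))
    gamma = posterior_probabilities(model, means[0][None])
    assert gamma[0, 0] > 0.99


def test_typicality_one_at_mean_and_outlier_rule():
    means = np.array([[0.0] * 5, [10.0] * 5, [-10.0] * 5])
    model = MixtureModel(weights=np.full(3, 1 / 3), means=means,
                         covariances=np.tile(np.eye(5), (3, 1, 1)),
                         center=np.zeros(5), scale=np.ones(5))
    typ = typicality(model, means[0][None])
    assert np.isclose(typ[0, 0], 1.0)
    pl, _ = flag_outliers(model, means[0][None])
    assert not pl[0]


def test_planted_contaminants_flagged():
    """Points >= 6 Mahalanobis units from every component exceed the
    chi-square(5) 0.05 cut (9.24 units) and are flagged."""
    rng = np.random.default_rng(4)
    means = np.array([[0.0] * 5, [12.0] * 5, [-12.0] * 5])
    model = MixtureModel(weights=np.full(3, 1 / 3), means=means,
                         covariances=np.tile(np.eye(5), (3, 1, 1)),
                         center=np.zeros(5), scale=np.ones(5))
    # contaminants on a sphere of radius 6 around component 0, far from all
    dirs = rng.normal(size=(1000, 5))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # keep those also >= 6 away from the other two components
    pts = 6.0 * dirs
    d1 = np.linalg.norm(pts - means[1], axis=1)
    d2 = np.linalg.norm(pts - means[2], axis=1)
    pts = pts[(d1 >= 6) & (d2 >= 6)]
    assert chi2.sf(36.0, df=5) < 0.05
    pl, _ = flag_outliers(model, pts)
    assert pl.mean() >= 0.99


def test_null_outlier_rate_close_to_alpha(separated_mixture_sample):
    """In-model voxels of a well-separated fitted mixture are flagged at
    ~ the 0.05 threshold rate."""
    X, _ = separated_mixture_sample
    model = fit_mixture(X, K=3, seed=0)
    pl, _ = flag_outliers(model, X, alpha=0.05)
    assert abs(pl.mean() - 0.05) < 0.01


def test_alpha_validated(separated_mixture_sample):
    X, _ = separated_mixture_sample
    model = fit_mixture(X[:1000], K=3, seed=0)
    with pytest.raises(ValueError, match="alpha"):
        flag_outliers(model, X[:10], alpha=1.5)


def test_label_compartments_by_signatures(separated_mixture_sample):
    """High-FA component -> PV; of the rest, high T2* -> IVS, low -> PT."""
    X, y = separated_mixture_sample
    model = fit_mixture(X[:10_000], K=3, seed=0)
    names = label_compartments(model)
    truth = _truth_means(X[:10_000], y[:10_000])
    perm = match_components(truth, model.destandardized_means())
    # perm[i] is the component matching truth code i+1 (IVS, PV, PT)
    assert names[perm[0]] == "C1-IVS"
    assert names[perm[1]] == "C2-PV"
    assert names[perm[2]] == "C3-PT"


def test_label_compartments_permutation_invariant(separated_mixture_sample):
    X, _ = separated_mixture_sample
    model = fit_mixture(X[:5000], K=3, seed=0)
    names = label_compartments(model)
    order = [2, 0, 1]
    permuted = MixtureModel(
        weights=model.weights[order], means=model.means[order],
        covariances=model.covariances[order], center=model.center,
        scale=model.scale)
    names_p = label_compartments(permuted)
    assert {names[k] for k in range(3)} == {names_p[k] for k in range(3)}
    for new_idx, old_idx in enumerate(order):
        assert names_p[new_idx] == names[old_idx]


def test_tied_means_demand_manual_mapping():
    model = MixtureModel(weights=np.full(3, 1 / 3),
                         means=np.zeros((3, 5)),
                         covariances=np.tile(np.eye(5), (3, 1, 1)),
                         center=np.zeros(5), scale=np.ones(5))
    with pytest.raises(ValueError, match="tied"):
        label_compartments(model)


def test_pl_fraction_edge_cases(separated_mixture_sample):
    X, _ = separated_mixture_sample
    model = fit_mixture(X[:2000], K=3, seed=0)
    seg = segment(model, X[:2000])
    seg.pl_mask[:] = False
    assert pl_fraction(seg) == 0.0
    seg.pl_mask[:] = True
    assert pl_fraction(seg) == 1.0
    with pytest.raises(ValueError, match="empty"):
        pl_fraction(seg, placental_mask=np.zeros((4, 4, 4), bool))


def test_case4_lesion_voxels_labelled_pl(healthy_pooled_model):
    """Lesion voxels drawn from the Case 4 parameter quintuple planted in a
    healthy phantom are predominantly assigned to the lesion cluster."""
    from conftest import phantom_features

    features, truth, _, _ = phantom_features(seed=201, lesion_fraction=0.15)
    seg = segment(healthy_pooled_model, features)
    labels = truth.label_volume[tuple(features.voxel_index.T)]
    lesion_rows = labels == LABEL_CODES["PL"]
    assert (seg.hard_label[lesion_rows] == "C4-PL").mean() > 0.5
    healthy_rows = ~lesion_rows
    assert (seg.hard_label[healthy_rows] == "C4-PL").mean() < 0.1


def test_feature_table_rejects_nonfinite():
    with pytest.raises(ValueError, match="non-finite"):
        FeatureTable(values=np.array([[1.0, np.nan, 1, 1, 1]]))


def test_subsample_stability_deterministic_and_tight():
    specs = ps.default_compartment_specs()
    X, _ = sample_gaussian_mixture(specs, 25_000, 21)
    per1, summ1 = subsample_stability(X, n_voxels=8000, repeats=4, seed=3)
    per2, summ2 = subsample_stability(X, n_voxels=8000, repeats=4, seed=3)
    assert per1.equals(per2)
    assert (summ1["cv"] < 0.05).all()


def test_subsample_stability_single_repeat_has_no_dispersion():
    specs = ps.default_compartment_specs()
    X, _ = sample_gaussian_mixture(specs, 12_000, 2)
    _, summ = subsample_stability(X, n_voxels=5000, repeats=1, seed=0)
    assert summ["cv"].isna().all()


def test_subsample_stability_validates_n():
    X, _ = sample_gaussian_mixture(ps.default_compartment_specs(), 1000, 0)
    with pytest.raises(ValueError, match="exceeds"):
        subsample_stability(X, n_voxels=2000, repeats=2, seed=0)


def test_model_json_round_trip(separated_mixture_sample):
    X, _ = separated_mixture_sample
    model = fit_mixture(X[:2000], K=3, seed=0)
    clone = MixtureModel.from_dict(model.to_dict())
    assert np.allclose(clone.means, model.means)
    assert np.allclose(clone.covariances, model.covariances)
    assert np.allclose(posterior_probabilities(clone, X[:50]),
                       posterior_probabilities(model, X[:50]))
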