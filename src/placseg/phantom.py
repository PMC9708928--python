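"""Synthetic dual-contrast placental MRI phantoms.

Generates multi-echo gradient-echo and diffusion-weighted volumes for a
slab-shaped placenta partitioned into cotyledons, each containing the three
physiological compartments seen on dual-contrast MRI — intervillous space
(IVS: maternal blood, high T2*, high nearly-isotropic diffusivity), placental
vessels (PV: coherent flow, high fractional anisotropy) and placental tissue
(PT: villous parenchyma, low T2* and diffusivity) — plus optionally planted
lesions (PL) with parameters measured in complicated pregnancies.

Every voxel's generative parameters are recorded in :class:`PhantomTruth`,
which serves as the oracle for all downstream validation.  Cohort generation
adds gestational-age trends (IVS/PV T2* declining, PT flat) and a fetal brain
whose T2* is linearly coupled to the subject's IVS T2*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Feature order used throughout the package.
FEATURES = ("adc", "fa", "ad", "rd", "t2star")
FEATURE_UNITS = {
    "adc": "1e-3 mm^2/s",
    "fa": "",
    "ad": "1e-3 mm^2/s",
    "rd": "1e-3 mm^2/s",
    "t2star": "ms",
}

COMPARTMENTS = ("IVS", "PV", "PT")
LABEL_CODES = {"background": 0, "IVS": 1, "PV": 2, "PT": 3, "PL": 4}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}

# Mean +/- SD of (ADC, FA, AD, RD, T2*) in the lesion cluster of the five
# complicated pregnancies; diffusivities in 1e-3 mm^2/s, T2* in ms.
LESION_CASE_MEANS = {
    1: (1.43, 0.27, 1.67, 1.33, 44.2),
    2: (2.29, 0.21, 2.43, 2.22, 60.6),
    3: (2.12, 0.22, 2.41, 2.35, 61.4),
    4: (1.26, 0.49, 2.01, 1.01, 32.9),
    5: (2.98, 0.43, 3.93, 1.95, 33.6),
}
LESION_CASE_SDS = {
    1: (0.28, 0.06, 0.80, 0.26, 9.9),
    2: (0.34, 0.05, 0.93, 0.22, 9.4),
    3: (0.31, 0.04, 0.67, 0.26, 14.0),
    4: (0.12, 0.07, 0.51, 0.15, 5.4),
    5: (0.17, 0.06, 0.61, 0.17, 6.7),
}


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy of a tensor with eigenvalues (l1, l2, l3)."""
    l1, l2, l3 = (np.asarray(x, dtype=float) for x in (l1, l2, l3))
    mean = (l1 + l2 + l3) / 3.0
    num = (l1 - mean) ** 2 + (l2 - mean) ** 2 + (l3 - mean) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


@dataclass(frozen=True)
class CompartmentSpec:
    """Generative feature distribution of one placental compartment.

    ``mean`` and ``cov`` are over (ADC, FA, AD, RD, T2*); diffusivities in
    1e-3 mm^2/s, T2* in ms.  ``volume_fraction`` is the compartment's share
    of placental voxels.
    """

    name: str
    mean: np.ndarray
    cov: np.ndarray
    volume_fraction: float

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if self.name not in LABEL_CODES or self.name == "background":
            raise ValueError(f"unknown compartment name {self.name!r}")
        if mean.shape != (5,) or cov.shape != (5, 5):
            raise ValueError("mean must be length 5 and cov 5x5")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive definite")
        if not 0.0 <= mean[1] <= 1.0:
            raise ValueError("FA mean must lie in [0, 1]")
        if np.any(mean[[0, 2, 3, 4]] <= 0):
            raise ValueError("diffusivity and T2* means must be positive")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError("volume_fraction must lie in [0, 1]")

    def with_t2star(self, t2star_ms: float) -> "CompartmentSpec":
        mean = self.mean.copy()
        mean[4] = t2star_ms
        return CompartmentSpec(self.name, mean, self.cov, self.volume_fraction)


def _diag_spec(name, mean, sd, volume_fraction):
    return CompartmentSpec(name, np.asarray(mean, float),
                           np.diag(np.asarray(sd, float) ** 2), volume_fraction)


def default_compartment_specs() -> list[CompartmentSpec]:
    """Healthy IVS/PV/PT feature distributions at mid-gestation (~30 weeks).

    FA and ADC means are the values implied by the axially symmetric tensor
    built from the AD/RD means, so the five features are mutually consistent.
    """
    return [
        _diag_spec("IVS", (3.10, 0.056, 3.30, 3.00, 90.0),
                   (0.15, 0.020, 0.18, 0.15, 6.0), 0.30),
        _diag_spec("PV", (1.87, 0.552, 3.20, 1.20, 70.0),
                   (0.12, 0.040, 0.20, 0.10, 5.0), 0.25),
        _diag_spec("PT", (1.53, 0.149, 1.80, 1.40, 45.0),
                   (0.10, 0.030, 0.12, 0.10, 4.0), 0.45),
    ]


def lesion_spec(case: int = 4, volume_fraction: float = 0.15) -> CompartmentSpec:
    """Lesion compartment parameterized by one of the five measured cases."""
    return _diag_spec("PL", LESION_CASE_MEANS[case], LESION_CASE_SDS[case],
                      volume_fraction)


def validate_fractions(specs) -> None:
    total = sum(s.volume_fraction for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"compartment volume fractions sum to {total}, not 1")


@dataclass(frozen=True)
class Acquisition:
    """Echo times (ms) plus diffusion b-values (s/mm^2) and unit b-vectors."""

    echo_times: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3), unit norm for b > 0

    def __post_init__(self):
        te = np.asarray(self.echo_times, float)
        bvals = np.asarray(self.bvals, float)
        bvecs = np.asarray(self.bvecs, float)
        object.__setattr__(self, "echo_times", te)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if te.size < 3 or np.any(np.diff(te) <= 0) or te[0] <= 0:
            raise ValueError("need >= 3 strictly increasing positive echo times")
        if bvals.shape[0] != bvecs.shape[0] or bvecs.shape[1] != 3:
            raise ValueError("bvals and bvecs lengths differ")
        if (bvals == 0).sum() < 1 or (bvals > 0).sum() < 6:
            raise ValueError("need >= 1 b=0 and >= 6 diffusion-weighted volumes")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-zero-b vectors must be unit norm")


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n roughly uniformly spread unit vectors on the upper hemisphere."""
    golden = (1 + math.sqrt(5)) / 2
    i = np.arange(n)
    z = (i + 0.5) / n
    theta = 2 * math.pi * i / golden
    r = np.sqrt(1 - z**2)
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def default_acquisition(n_echoes: int = 10, te_range=(5.0, 90.0),
                        b: float = 700.0, n_dirs: int = 12) -> Acquisition:
    te = np.linspace(te_range[0], te_range[1], n_echoes)
    dirs = fibonacci_hemisphere(n_dirs)
    bvals = np.concatenate([[0.0], np.full(n_dirs, b)])
    bvecs = np.vstack([np.zeros(3), dirs])
    return Acquisition(te, bvals, bvecs)


@dataclass
class PhantomTruth:
    """Per-voxel generative ground truth — the oracle for all validation."""

    label_volume: np.ndarray       # int codes per LABEL_CODES
    lesion_mask: np.ndarray
    chorion_mask: np.ndarray
    basal_mask: np.ndarray
    placental_mask: np.ndarray
    brain_mask: np.ndarray
    ga_weeks: float
    ga_delivery_weeks: float
    true_params: dict
    voxel_size: tuple
    seed: int
    true_features: np.ndarray      # (X, Y, Z, 5) in FEATURES order
    true_s0: np.ndarray
    true_tensor: np.ndarray        # (X, Y, Z, 3, 3), 1e-3 mm^2/s

    def __post_init__(self):
        if np.any(self.lesion_mask & ~self.placental_mask):
            raise ValueError("lesion mask must lie inside the placental mask")
        if np.any(self.chorion_mask & self.basal_mask):
            raise ValueError("chorionic and basal surface masks overlap")
        labels = self.label_volume[self.placental_mask]
        if np.any(labels == 0):
            raise ValueError("every placental voxel needs a compartment label")

    @property
    def true_t2star(self) -> np.ndarray:
        return self.true_features[..., 4]


def draw_features(spec: CompartmentSpec, n: int, rng: np.random.Generator,
                  max_attempts: int = 100) -> np.ndarray:
    """Draw n mutually consistent feature quintuples from a compartment.

    The tensor model is axially symmetric (eigenvalues AD, RD, RD), so ADC
    and FA are determined by AD and RD.  A draw is accepted when AD >= RD > 0,
    1 < T2* < 300 ms and the drawn ADC agrees with (AD + 2 RD)/3 within 5%;
    otherwise the whole quintuple is re-drawn.  Returned features carry the
    derived ADC and FA so the truth is exactly what the tensor generates.
    """
    out = np.empty((n, 5))
    pending = np.arange(n)
    redraws = 0
    for _ in range(max_attempts):
        if pending.size == 0:
            break
        draws = rng.multivariate_normal(spec.mean, spec.cov, size=pending.size)
        adc_d, _fa_d, ad, rd, t2 = draws.T
        derived_adc = (ad + 2.0 * rd) / 3.0
        ok = (
            (rd > 0)
            & (ad >= rd)
            & (t2 > 1.0)
            & (t2 < 300.0)
            & (np.abs(adc_d - derived_adc) <= 0.05 * derived_adc)
        )
        accepted = pending[ok]
        out[accepted, 0] = derived_adc[ok]
        out[accepted, 1] = fa_from_eigenvalues(ad[ok], rd[ok], rd[ok])
        out[accepted, 2] = ad[ok]
        out[accepted, 3] = rd[ok]
        out[accepted, 4] = t2[ok]
        redraws += int((~ok).sum())
        pending = pending[~ok]
    if pending.size:
        raise RuntimeError(
            f"could not draw feasible features for {spec.name} after "
            f"{max_attempts} attempts ({pending.size} voxels unresolved)")
    if redraws:
        logger.warning("%s: %d infeasible feature draws were re-drawn",
                       spec.name, redraws)
    return out


def sample_feature_table(specs, n_total: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample labelled feature vectors from compartment distributions.

    Counts follow the specs' volume fractions (largest-remainder rounding).
    Returns (features (n_total, 5), integer labels per LABEL_CODES).
    """
    rng = np.random.default_rng(rng)
    counts = _apportion(n_total, [s.volume_fraction for s in specs])
    xs, labs = [], []
    for spec, n in zip(specs, counts):
        if n == 0:
            continue
        xs.append(draw_features(spec, n, rng))
        labs.append(np.full(n, LABEL_CODES[spec.name]))
    X = np.concatenate(xs)
    y = np.concatenate(labs)
    perm = rng.permutation(n_total)
    return X[perm], y[perm]


def sample_gaussian_mixture(specs, n_total: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample exactly-Gaussian labelled vectors (no consistency re-draws)."""
    rng = np.random.default_rng(rng)
    counts = _apportion(n_total, [s.volume_fraction for s in specs])
    xs, labs = [], []
    for spec, n in zip(specs, counts):
        xs.append(rng.multivariate_normal(spec.mean, spec.cov, size=n))
        labs.append(np.full(n, LABEL_CODES[spec.name]))
    X = np.concatenate(xs)
    y = np.concatenate(labs)
    perm = rng.permutation(n_total)
    return X[perm], y[perm]


def _apportion(n_total: int, fractions) -> list[int]:
    """Integer counts proportional to fractions, summing exactly to n_total."""
    raw = np.asarray(fractions, float) * n_total
    counts = np.floor(raw).astype(int)
    remainder = n_total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


def _cotyledon_centers(n: int, center, a, b, rng) -> np.ndarray:
    """One central + (n-1) peripheral in-plane cotyledon seed points."""
    pts = [np.asarray(center, float)]
    for k in range(n - 1):
        ang = 2 * math.pi * k / (n - 1) + rng.uniform(-0.15, 0.15)
        pts.append(np.array([center[0] + 0.55 * a * math.cos(ang),
                             center[1] + 0.55 * b * math.sin(ang)]))
    return np.array(pts)


def _build_geometry(shape, n_cotyledons, lesion_fraction, fractions, rng,
                    brain: bool):
    """Slab placenta with cotyledons; returns masks and an int label volume.

    Compartments are assigned by sorting voxels on geometric plausibility
    scores and taking exact counts, so realized volume fractions match the
    requested ones to within rounding.
    """
    nx, ny, nz = shape
    z0, z1 = 2, nz - 7
    if z1 - z0 < 3:
        raise ValueError(f"volume too thin in z for a slab phantom: {shape}")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    a, b = 0.42 * nx, 0.42 * ny

    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    in_ellipse = ((ix - cx) / a) ** 2 + ((iy - cy) / b) ** 2 <= 1.0
    placental = in_ellipse & (iz >= z0) & (iz <= z1)
    chorion = in_ellipse & (iz == z1 + 1)   # fetal side, top face
    basal = in_ellipse & (iz == z0 - 1)     # maternal side, bottom face

    brain_mask = np.zeros(shape, bool)
    if brain:
        bc = np.array([0.16 * nx, 0.16 * ny, nz - 4.0])
        r = max(2.0, 0.09 * min(nx, ny))
        brain_mask = ((ix - bc[0]) ** 2 + (iy - bc[1]) ** 2
                      + (iz - bc[2]) ** 2) <= r**2
        brain_mask &= ~(placental | chorion | basal)

    vox = np.argwhere(placental)
    n_vox = len(vox)
    depth = (z1 - vox[:, 2]) / max(z1 - z0, 1)   # 0 at chorionic side
    centers = _cotyledon_centers(n_cotyledons, (cx, cy), a, b, rng)
    d_center = np.min(
        np.linalg.norm(vox[:, None, :2] - centers[None, :, :], axis=2), axis=1)
    d_center = d_center / max(d_center.max(), 1e-9)

    labels = np.zeros(shape, np.int16)
    assigned = np.zeros(n_vox, bool)

    n_pl = int(round(lesion_fraction * n_vox))
    if n_pl > 0:
        les_center = centers[rng.integers(len(centers))]
        les_z = z1 - rng.uniform(0.35, 0.65) * (z1 - z0)
        d_les = np.sqrt(((vox[:, 0] - les_center[0]) / 1.6) ** 2
                        + ((vox[:, 1] - les_center[1]) / 1.6) ** 2
                        + (vox[:, 2] - les_z) ** 2)
        idx = np.argsort(d_les)[:n_pl]
        labels[tuple(vox[idx].T)] = LABEL_CODES["PL"]
        assigned[idx] = True

    n_rest = n_vox - n_pl
    n_ivs, n_pv, n_pt = _apportion(n_rest, fractions)

    jitter = rng.uniform(0, 1, size=n_vox)
    # vessels: chorionic-plate network plus stem vessels descending along
    # cotyledon centers toward the basal plate
    score_pv = np.minimum(depth + 0.25 * d_center, 0.28 + 1.5 * d_center) \
        + 0.05 * jitter
    score_pv[assigned] = np.inf
    idx = np.argsort(score_pv)[:n_pv]
    labels[tuple(vox[idx].T)] = LABEL_CODES["PV"]
    assigned[idx] = True

    score_ivs = d_center + 0.6 * np.abs(depth - 0.5) + 0.05 * jitter
    score_ivs[assigned] = np.inf
    idx = np.argsort(score_ivs)[:n_ivs]
    labels[tuple(vox[idx].T)] = LABEL_CODES["IVS"]
    assigned[idx] = True

    labels[tuple(vox[~assigned].T)] = LABEL_CODES["PT"]
    lesion_mask = labels == LABEL_CODES["PL"]
    return labels, lesion_mask, placental, chorion, basal, brain_mask


def generate_phantom(
    specs=None,
    *,
    shape=(48, 48, 24),
    voxel_size=(2.0, 2.0, 2.5),
    acquisition: Acquisition | None = None,
    snr: float = 25.0,
    n_cotyledons: int = 5,
    lesion_fraction: float = 0.0,
    lesion: CompartmentSpec | None = None,
    brain_t2star: float | None = None,
    ga_weeks: float = 30.0,
    ga_delivery_weeks: float = 39.0,
    s0: float = 100.0,
    seed: int = 0,
):
    """Simulate one subject's dual-contrast acquisition.

    Returns ``(multi_echo, dwi, truth)`` where ``multi_echo`` has one volume
    per echo time, ``dwi`` one per (b, g) measurement, and ``truth`` records
    every voxel's generative parameters.  Signals follow
    ``S(TE) = S0 exp(-TE/T2*)`` and ``S(b, g) = S0 exp(-b g^T D g)`` with an
    axially symmetric tensor matched to each voxel's (AD, RD) draw.  Rician
    noise at the given SNR (defined against S0) is added unless ``snr`` is
    infinite.  Identical seeds give bit-identical output.
    """
    if specs is None:
        specs = default_compartment_specs()
    validate_fractions(specs)
    if acquisition is None:
        acquisition = default_acquisition()
    if not snr > 0:
        raise ValueError("snr must be positive (np.inf disables noise)")
    rng = np.random.default_rng(seed)

    spec_map = {s.name: s for s in specs}
    if lesion_fraction > 0:
        les = lesion if lesion is not None else lesion_spec()
        spec_map["PL"] = les
    elif lesion is not None:
        spec_map["PL"] = lesion
        lesion_fraction = lesion.volume_fraction

    fractions = [spec_map[c].volume_fraction for c in COMPARTMENTS]
    labels, lesion_mask, placental, chorion, basal, brain_mask = _build_geometry(
        shape, n_cotyledons, lesion_fraction, fractions, rng,
        brain=brain_t2star is not None)

    features = np.zeros(shape + (5,))
    s0_vol = np.zeros(shape)
    tensor = np.zeros(shape + (3, 3))

    def fill(mask, feats):
        features[mask] = feats
        s0_vol[mask] = s0
        e = rng.normal(size=(mask.sum(), 3))
        e /= np.linalg.norm(e, axis=1, keepdims=True)
        ad, rd = feats[:, 2], feats[:, 3]
        tensor[mask] = (rd[:, None, None] * np.eye(3)
                        + (ad - rd)[:, None, None]
                        * e[:, :, None] * e[:, None, :])

    for name in ("IVS", "PV", "PT", "PL"):
        mask = labels == LABEL_CODES[name]
        if not mask.any():
            continue
        fill(mask, draw_features(spec_map[name], int(mask.sum()), rng))

    if brain_mask.any():
        n_b = int(brain_mask.sum())
        t2_b = np.clip(rng.normal(brain_t2star, 2.0, size=n_b), 5.0, 299.0)
        feats = np.column_stack([
            np.full(n_b, 1.2), np.zeros(n_b), np.full(n_b, 1.2),
            np.full(n_b, 1.2), t2_b])
        fill(brain_mask, feats)

    signal_mask = placental | brain_mask
    te = acquisition.echo_times
    t2 = features[..., 4]
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-te[None, None, None, :]
                       / np.where(t2 > 0, t2, np.inf)[..., None])
    multi_echo = s0_vol[..., None] * decay * signal_mask[..., None]

    b = acquisition.bvals
    g = acquisition.bvecs
    # exponent b * g^T D g with D in 1e-3 mm^2/s and b in s/mm^2
    gdg = np.einsum("mi,...ij,mj->...m", g, tensor, g)  # (X,Y,Z,m)
    dwi = s0_vol[..., None] * np.exp(-b * gdg * 1e-3) * signal_mask[..., None]

    if np.isfinite(snr):
        sigma = s0 / snr
        multi_echo = add_rician_noise(multi_echo, sigma, rng)
        dwi = add_rician_noise(dwi, sigma, rng)

    truth = PhantomTruth(
        label_volume=labels, lesion_mask=lesion_mask, chorion_mask=chorion,
        basal_mask=basal, placental_mask=placental, brain_mask=brain_mask,
        ga_weeks=ga_weeks, ga_delivery_weeks=ga_delivery_weeks,
        true_params={n: s for n, s in spec_map.items()},
        voxel_size=tuple(voxel_size), seed=seed, true_features=features,
        true_s0=s0_vol, true_tensor=tensor)
    return multi_echo, dwi, truth


def add_rician_noise(signal, sigma, rng):
    """Magnitude-MRI (Rician) noise: |S + n1 + i n2| with n ~ N(0, sigma)."""
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


@dataclass
class CohortDesign:
    """Conditions for a gestational-age-spanning synthetic cohort.

    ``trend_slopes`` are T2*-vs-GA slopes in ms/week applied around
    ``ga_ref``; ``brain_coupling`` links fetal-brain T2* linearly to the
    subject's realized IVS T2*; ``subject_sd`` is between-subject T2*
    scatter (ms).
    """

    n_subjects: int = 22
    ga_range: tuple = (20.0, 38.0)
    trend_slopes: dict = field(
        default_factory=lambda: {"IVS": -1.5, "PV": -1.8, "PT": 0.0})
    brain_coupling: float = 1.3
    brain_noise_sd: float = 2.0
    subject_sd: float = 3.0
    lesion_prevalence: float = 0.0
    lesion_fraction: float = 0.15
    noise_snr: float = 25.0
    ga_ref: float = 29.0
    #: optional (n_low, n_mid, n_high) subject counts for the <25, 25-35 and
    #: >35 week bins (the healthy-cohort design had 7/10/5); must sum to
    #: n_subjects when given.  None draws GA uniformly over ga_range.
    ga_bin_counts: tuple | None = None
    shape: tuple = (48, 48, 24)
    voxel_size: tuple = (2.0, 2.0, 2.5)
    with_brain: bool = True

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects (regression undefined)")
        if not (18.0 <= self.ga_range[0] < self.ga_range[1] <= 42.0):
            raise ValueError("ga_range must lie within [18, 42] weeks")
        if not self.noise_snr > 0:
            raise ValueError("noise_snr must be positive")
        if self.ga_bin_counts is not None and \
                sum(self.ga_bin_counts) != self.n_subjects:
            raise ValueError("ga_bin_counts must sum to n_subjects")


@dataclass
class SubjectSim:
    """One simulated subject: volumes, truth and scalar metadata."""

    subject_id: str
    multi_echo: np.ndarray
    dwi: np.ndarray
    truth: PhantomTruth
    acquisition: Acquisition
    ga_mri_weeks: float
    ga_delivery_weeks: float
    group: str
    true_compartment_t2star: dict
    true_brain_t2star: float | None


def generate_cohort(design: CohortDesign, seed: int = 0) -> list[SubjectSim]:
    """Simulate a cohort with GA-dependent compartment T2* trends.

    Per subject, compartment T2* means follow ``base + slope * (GA - ga_ref)``
    plus N(0, subject_sd) between-subject scatter; fetal-brain T2* is
    ``brain_coupling * (subject IVS T2*) + noise``.  GA at MRI is uniform over
    ``ga_range``.  Subjects with planted lesions (per ``lesion_prevalence``)
    form the "complicated" group and deliver earlier on average.
    """
    rng = np.random.default_rng(seed)
    base = {s.name: s for s in default_compartment_specs()}
    subject_seeds = np.random.SeedSequence(seed).spawn(design.n_subjects)

    if design.ga_bin_counts is None:
        ga = rng.uniform(*design.ga_range, size=design.n_subjects)
    else:
        lo, hi = design.ga_range
        edges = [(lo, min(25.0, hi)), (max(25.0, lo), min(35.0, hi)),
                 (max(35.0, lo), hi)]
        parts = [rng.uniform(a, b, size=n)
                 for (a, b), n in zip(edges, design.ga_bin_counts) if n > 0]
        ga = rng.permutation(np.concatenate(parts))
    n_les = int(round(design.lesion_prevalence * design.n_subjects))
    lesioned = np.zeros(design.n_subjects, bool)
    lesioned[rng.choice(design.n_subjects, size=n_les, replace=False)] = True

    subjects = []
    for i in range(design.n_subjects):
        t2_means = {}
        specs = []
        for name in COMPARTMENTS:
            slope = design.trend_slopes.get(name, 0.0)
            t2 = (base[name].mean[4] + slope * (ga[i] - design.ga_ref)
                  + rng.normal(0.0, design.subject_sd))
            t2 = float(np.clip(t2, 8.0, 290.0))
            t2_means[name] = t2
            specs.append(base[name].with_t2star(t2))

        brain_t2 = None
        if design.with_brain:
            brain_t2 = float(np.clip(
                design.brain_coupling * t2_means["IVS"]
                + rng.normal(0.0, design.brain_noise_sd), 8.0, 290.0))

        frac = design.lesion_fraction if lesioned[i] else 0.0
        if lesioned[i]:
            ga_del = 40.0 - 12.0 * frac + rng.normal(0.0, 1.0)
        else:
            ga_del = rng.normal(39.5, 1.2)
        ga_del = float(np.clip(ga_del, max(ga[i], 28.0), 42.0))

        sub_seed = int(subject_seeds[i].generate_state(1)[0] % (2**31))
        mecho, dwi, truth = generate_phantom(
            specs, shape=design.shape, voxel_size=design.voxel_size,
            snr=design.noise_snr, lesion_fraction=frac,
            brain_t2star=brain_t2, ga_weeks=float(ga[i]),
            ga_delivery_weeks=ga_del, seed=sub_seed)
        subjects.append(SubjectSim(
            subject_id=f"sub-{i + 1:02d}", multi_echo=mecho, dwi=dwi,
            truth=truth, acquisition=default_acquisition(),
            ga_mri_weeks=float(ga[i]), ga_delivery_weeks=ga_del,
            group="complicated" if lesioned[i] else "healthy",
            true_compartment_t2star=t2_means, true_brain_t2star=brain_t2))
    return subjects
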