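"""End-to-end orchestration: maps -> clustering -> layers -> statistics.

The pipeline mirrors the study design: parametric maps (T2*, tensor
metrics) are fitted per subject, the Gaussian mixture is trained on the
pooled features of healthy subjects (so lesions stay outliers relative to
healthy statistics), every subject is segmented with the pooled model, the
vessel compartment is parcellated into depth layers, and the cohort
statistics are assembled.  Everything is deterministic under a fixed
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .clustering import (FeatureTable, build_feature_table,
                         estimate_lesion_burden, fit_mixture, segment)
from .diffusion import DiffusionScheme, fit_tensor
from .geometry import depth_field, layer_summary
from .phantom import FEATURES, CohortDesign, SubjectSim, generate_cohort
from .relaxometry import EchoTrain, fit_t2star
from .stats import (RegressionResult, SubjectRecord,
                    brain_placenta_correlations, ga_binned_comparison,
                    layerwise_trend, linreg, pl_group_analysis,
                    summarize_brain)

logger = logging.getLogger(__name__)

_COMP_OF_LABEL = {"C1-IVS": "C1-IVS", "C2-PV": "C2-PV", "C3-PT": "C3-PT",
                  "C4-PL": "C4-PL"}


@dataclass
class PipelineConfig:
    """Options controlling one pipeline run."""

    data_dir: str | None = None
    out_dir: str | None = None
    n_components: int = 3
    alpha: float = 0.05
    seed: int = 0
    n_restarts: int = 5
    pooled: bool = True
    n_layers: int = 5
    max_train_voxels: int = 150_000
    layer_compartment: str = "C2-PV"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")

    def validate_paths(self):
        if self.data_dir is not None and not Path(self.data_dir).is_dir():
            raise FileNotFoundError(f"data_dir not found: {self.data_dir}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SubjectAnalysis:
    """Fitted maps, features and segmentation of one subject."""

    subject_id: str
    features: FeatureTable
    t2map: object
    tensors: object
    segmentation: object
    record: SubjectRecord
    layer_table: pd.DataFrame


@dataclass
class CohortResult:
    """Bundle of everything the pipeline computes for a cohort."""

    model: object
    subjects: list
    records: list
    compartment_trends: dict        # compartment -> RegressionResult
    binned_tests: dict
    pl_test: object | None
    pl_delivery_regression: RegressionResult | None
    brain_correlations: dict
    layer_trends: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def fit_subject_maps(subject: SubjectSim):
    """Fit T2* and tensor maps over the placenta (plus brain if present)."""
    truth = subject.truth
    fit_mask = truth.placental_mask | truth.brain_mask
    train = EchoTrain(subject.multi_echo, subject.acquisition.echo_times)
    t2map = fit_t2star(train, fit_mask)
    scheme = DiffusionScheme(subject.acquisition.bvals,
                             subject.acquisition.bvecs)
    tensors = fit_tensor(subject.dwi, scheme, fit_mask)
    features = build_feature_table(t2map, tensors, truth.placental_mask)
    return t2map, tensors, features


def _compartment_means(features: FeatureTable, hard_label) -> dict:
    means = {"total": {f: float(m) for f, m in
                       zip(FEATURES, features.values.mean(axis=0))}}
    for label, comp in _COMP_OF_LABEL.items():
        sel = hard_label == label
        if sel.any():
            means[comp] = {f: float(m) for f, m in
                           zip(FEATURES, features.values[sel].mean(axis=0))}
    return means


def analyze_cohort(subjects: list[SubjectSim],
                   config: PipelineConfig | None = None) -> CohortResult:
    """Run the full analysis on in-memory simulated subjects."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)

    per_subject = []
    for sub in subjects:
        t2map, tensors, features = fit_subject_maps(sub)
        per_subject.append((sub, t2map, tensors, features))

    if config.pooled:
        healthy = [f.values for s, _, _, f in per_subject
                   if s.group == "healthy"]
        train = np.concatenate(healthy if healthy
                               else [f.values for _, _, _, f in per_subject])
        if train.shape[0] > config.max_train_voxels:
            idx = rng.choice(train.shape[0], config.max_train_voxels,
                             replace=False)
            train = train[idx]
        model = fit_mixture(train, K=config.n_components, seed=config.seed,
                            n_restarts=config.n_restarts)
    else:
        model = None

    analyses = []
    layer_rows = []
    for sub, t2map, tensors, features in per_subject:
        sub_model = model if config.pooled else fit_mixture(
            features, K=config.n_components, seed=config.seed,
            n_restarts=config.n_restarts)
        seg = segment(sub_model, features, alpha=config.alpha)
        truth = sub.truth
        dfld = depth_field(truth.placental_mask, truth.chorion_mask,
                           truth.basal_mask, truth.voxel_size,
                           n_layers=config.n_layers)
        try:
            ltab = layer_summary(t2map, seg, features.voxel_index, dfld,
                                 compartment=config.layer_compartment)
        except ValueError:
            ltab = pd.DataFrame()
        if not ltab.empty:
            ltab["subject_id"] = sub.subject_id
            ltab["ga_mri_weeks"] = sub.ga_mri_weeks
            layer_rows.append(ltab)

        brain_vol = brain_t2 = None
        if truth.brain_mask.any():
            brain_vol, brain_t2 = summarize_brain(t2map, truth.brain_mask,
                                                  truth.voxel_size)
        record = SubjectRecord(
            subject_id=sub.subject_id, ga_mri_weeks=sub.ga_mri_weeks,
            ga_delivery_weeks=sub.ga_delivery_weeks, group=sub.group,
            compartment_means=_compartment_means(features, seg.hard_label),
            pl_fraction=seg.pl_fraction, brain_volume_cm3=brain_vol,
            brain_t2star_ms=brain_t2)
        analyses.append(SubjectAnalysis(
            subject_id=sub.subject_id, features=features, t2map=t2map,
            tensors=tensors, segmentation=seg, record=record,
            layer_table=ltab))

    records = [a.record for a in analyses]
    healthy_recs = [r for r in records if r.group == "healthy"]

    trends = {}
    for comp in ("total", "C1-IVS", "C2-PV", "C3-PT"):
        pairs = [(r.ga_mri_weeks, r.feature_mean(comp)) for r in healthy_recs
                 if r.feature_mean(comp) is not None]
        if len(pairs) >= 3:
            x, y = zip(*pairs)
            if np.ptp(x) > 0:
                trends[comp] = linreg(x, y)

    binned = ga_binned_comparison(healthy_recs) if len(healthy_recs) >= 4 \
        else {}

    pl_test = pl_reg = None
    groups = {r.group for r in records}
    if {"healthy", "complicated"} <= groups:
        pl_test, pl_reg = pl_group_analysis(records)

    brain = brain_placenta_correlations(
        [r for r in records if r.brain_t2star_ms is not None]) \
        if any(r.brain_t2star_ms is not None for r in records) else {}

    layer_df = pd.concat(layer_rows, ignore_index=True) if layer_rows \
        else pd.DataFrame()
    layer_trends = layerwise_trend(layer_df) if not layer_df.empty \
        else pd.DataFrame()

    manifest = {"config": asdict(config), "config_hash": config.digest(),
                "n_subjects": len(subjects),
                "n_train_voxels": int(train.shape[0]) if config.pooled
                else None}
    return CohortResult(
        model=model, subjects=analyses, records=records,
        compartment_trends=trends, binned_tests=binned, pl_test=pl_test,
        pl_delivery_regression=pl_reg, brain_correlations=brain,
        layer_trends=layer_trends, manifest=manifest)


def records_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "ga_mri_weeks": r.ga_mri_weeks,
               "ga_delivery_weeks": r.ga_delivery_weeks, "group": r.group,
               "pl_fraction": r.pl_fraction,
               "lesion_burden": estimate_lesion_burden(r.pl_fraction),
               "brain_volume_cm3": r.brain_volume_cm3,
               "brain_t2star_ms": r.brain_t2star_ms}
        for comp, feats in r.compartment_means.items():
            for f, v in feats.items():
                row[f"{comp}_{f}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def trends_frame(result: CohortResult) -> pd.DataFrame:
    rows = []
    for comp, reg in result.compartment_trends.items():
        lo, hi = reg.ci95_slope
        rows.append({"quantity": f"{comp} T2* vs GA", "slope": reg.slope,
                     "slope_ci_low": lo, "slope_ci_high": hi,
                     "r_squared": reg.r_squared, "p_value": reg.p_value,
                     "n": reg.n})
    for comp, reg in result.brain_correlations.items():
        lo, hi = reg.ci95_slope
        rows.append({"quantity": f"brain T2* vs {comp} T2*",
                     "slope": reg.slope, "slope_ci_low": lo,
                     "slope_ci_high": hi, "r_squared": reg.r_squared,
                     "p_value": reg.p_value, "n": reg.n})
    if result.pl_delivery_regression is not None:
        reg = result.pl_delivery_regression
        lo, hi = reg.ci95_slope
        rows.append({"quantity": "pl_fraction vs GA at delivery",
                     "slope": reg.slope, "slope_ci_low": lo,
                     "slope_ci_high": hi, "r_squared": reg.r_squared,
                     "p_value": reg.p_value, "n": reg.n})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig,
                 subjects: list[SubjectSim] | None = None,
                 design: CohortDesign | None = None) -> CohortResult:
    """Disk-facing entry point: load or simulate subjects, analyze, write.

    With ``subjects`` given they are used directly; otherwise ``data_dir``
    must contain serialized subjects (``sub-*/``) or a ``design`` must be
    provided to simulate a cohort.  Results are written under ``out_dir``
    when set: records and trend tables as CSV, the mixture model and run
    manifest as JSON.
    """
    config.validate_paths()
    if subjects is None:
        if design is not None:
            subjects = generate_cohort(design, seed=config.seed)
        elif config.data_dir is not None:
            subjects = load_subjects_dir(config.data_dir)
        else:
            raise ValueError("need subjects, a design, or a data_dir")

    result = analyze_cohort(subjects, config)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_frame(result.records).to_csv(out / "subjects.csv",
                                             index=False)
        trends_frame(result).to_csv(out / "trends.csv", index=False)
        if not result.layer_trends.empty:
            result.layer_trends.to_csv(out / "layer_trends.csv", index=False)
        if result.model is not None:
            (out / "model.json").write_text(
                json.dumps(result.model.to_dict(), indent=1))
        (out / "manifest.json").write_text(
            json.dumps(result.manifest, indent=1, default=str))
        logger.info("pipeline outputs written to %s", out)
    return result


def load_subjects_dir(data_dir) -> list[SubjectSim]:
    """Reload serialized subjects (see io.write_subject) for analysis."""
    from .phantom import PhantomTruth

    subjects = []
    for subdir in sorted(Path(data_dir).glob("sub-*")):
        mecho, dwi, acq, voxel_size, masks, meta = pio.load_subject(subdir)
        shape = masks["placenta"].shape
        truth = PhantomTruth(
            label_volume=pio.load_nifti(subdir / "truth_labels.nii.gz")[0]
            .astype(np.int16),
            lesion_mask=masks["lesion"], chorion_mask=masks["chorion"],
            basal_mask=masks["basal"], placental_mask=masks["placenta"],
            brain_mask=masks["brain"], ga_weeks=meta["ga_mri_weeks"],
            ga_delivery_weeks=meta["ga_delivery_weeks"], true_params={},
            voxel_size=voxel_size, seed=meta.get("seed", 0),
            true_features=np.zeros(shape + (5,)),
            true_s0=np.zeros(shape), true_tensor=np.zeros(shape + (3, 3)))
        subjects.append(SubjectSim(
            subject_id=meta["subject_id"], multi_echo=mecho, dwi=dwi,
            truth=truth, acquisition=acq,
            ga_mri_weeks=meta["ga_mri_weeks"],
            ga_delivery_weeks=meta["ga_delivery_weeks"], group=meta["group"],
            true_compartment_t2star=meta.get("true_compartment_t2star", {}),
            true_brain_t2star=meta.get("true_brain_t2star")))
    if not subjects:
        raise FileNotFoundError(f"no sub-* directories under {data_dir}")
    return subjects
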