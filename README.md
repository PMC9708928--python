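# placseg

Tissue-specific analysis of dual-contrast placental MRI (T2* relaxometry +
diffusion-weighted imaging). Most in-vivo placental imaging reports a single
value averaged over the whole organ, even though the placenta is a mosaic of
compartments with very different physiology: the intervillous space (IVS,
maternal blood — high T2*, high near-isotropic diffusivity), placental
vessels (PV — coherent flow, high fractional anisotropy) and placental
tissue (PT, villous parenchyma — low T2* and diffusivity). `placseg`
segments the placenta into these compartments voxel by voxel, flags voxels
that fit none of them as lesion (PL), and quantifies how each compartment's
oxygenation proxy (T2*) evolves over gestation and relates to fetal brain
oxygenation.

It is aimed at placental/fetal MRI researchers who have co-registered
multi-echo gradient-echo and DWI volumes with a placental mask, and at
methods developers who want a fully synthetic, ground-truthed test bed: the
package ships a digital placental phantom that emulates the statistical
structure such studies assume.

## Method

Per voxel inside the placental mask, five features are computed:

- **T2\*** from the mono-exponential decay `S(TE) = S0 exp(-TE/T2*)`,
  fitted by weighted log-linear least squares (weights ∝ S²);
- **ADC, FA, AD, RD** from the diffusion tensor `ln S = ln S0 − b gᵀDg`
  (log-linear fit, eigen-decomposition; AD = λ₁, RD = (λ₂+λ₃)/2,
  ADC = trace(D)/3).

The feature vectors **x** = (ADC, FA, AD, RD, T2*) are z-scored and fitted
with a K = 3 Gaussian mixture by expectation–maximization. Soft ("fuzzy")
membership is the posterior responsibility

γₖ(x) ∝ πₖ · N(x; μₖ, Σₖ).

Components are named from their de-standardized means: highest FA → C2-PV;
of the remaining two, higher T2* → C1-IVS, the other → C3-PT.

Voxels atypical for *every* component form the lesion cluster C4-PL: per
component, the typicality is the upper-tail probability of the squared
Mahalanobis distance dₖ² under a χ²(5) law, and a voxel is flagged when all
typicalities fall below α = 0.05. Because this rule flags ≈ α of voxels
that truly belong to the mixture, the planted/true lesion load is estimated
with the null-corrected burden `(PL fraction − α)/(1 − α)`.

Downstream analyses mirror the study design: OLS regressions with 95%
confidence bands (compartment T2* vs gestational age, lesion burden vs GA
at delivery, fetal-brain T2* vs compartment T2*), Mann–Whitney U tests
between GA bins (<25, 25–35, >35 weeks) and between healthy/complicated
groups, and a five-layer chorionic→basal parcellation using the normalized
depth `d_chorion / (d_chorion + d_basal)` from Euclidean distance
transforms.

## Worked example

```python
import placseg as ps
from placseg.pipeline import PipelineConfig, run_pipeline, records_frame

design = ps.CohortDesign(n_subjects=16, shape=(32, 32, 16),
                         lesion_prevalence=0.25)
subjects = ps.generate_cohort(design, seed=7)
result = run_pipeline(PipelineConfig(seed=0, out_dir="demo_out"),
                      subjects=subjects)

for name in ("C1-IVS", "C2-PV", "C3-PT"):
    reg = result.compartment_trends[name]
    lo, hi = reg.ci95_slope
    print(f"{name} T2* vs GA: slope {reg.slope:+.2f} ms/week "
          f"(95% CI {lo:+.2f} to {hi:+.2f}), R^2 {reg.r_squared:.2f}, "
          f"P {reg.p_value:.1e}")
```

prints

```
C1-IVS T2* vs GA: slope -1.69 ms/week (95% CI -2.10 to -1.29), R^2 0.90, P 3.1e-06
C2-PV T2* vs GA: slope -1.87 ms/week (95% CI -2.37 to -1.37), R^2 0.87, P 8.3e-06
C3-PT T2* vs GA: slope -0.01 ms/week (95% CI -0.36 to +0.33), R^2 0.00, P 9.3e-01
```

The cohort was simulated with declining IVS/PV T2* (−1.5 and −1.8 ms/week)
and flat PT; the pipeline recovers the declines and the flat tissue trend
from the noisy images alone. The same `result` object carries the group
contrast and brain coupling:

```
PL fraction: healthy mean 0.041 (n=12) vs complicated 0.169 (n=4)
             U=0, P=0.0011 (exact Mann-Whitney)
best brain correlate: C1-IVS (R^2 0.95)
```

i.e. subjects with planted lesions are cleanly separated by their lesion
fraction, and the intervillous space — the compartment the fetal-brain T2*
was generated from — ranks first among the brain–placenta regressions.

A command-line interface wraps the same steps:

```bash
placseg simulate --config design.yaml --seed 3 --out data/
placseg run-all data/ out/
```

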