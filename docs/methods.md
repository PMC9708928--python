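# Methods

## Signal models and map fitting

**T2\* relaxometry.** Multi-echo gradient-echo magnitude data follow
`S(TE) = S0 exp(-TE/T2*)`. The default estimator is weighted log-linear
least squares on `ln S = ln S0 − TE/T2*` with weights ∝ S², the first-order
variance weighting for log-transformed noisy magnitudes; it is closed-form
and deterministic. Voxels with fewer than three positive echoes, a
non-positive estimated decay rate, or T2* above a 300 ms cap are flagged
invalid and excluded from every downstream statistic — the cap keeps
near-flat decays (whose T2* is numerically unbounded) out of the clustering
feature space. A per-voxel Levenberg–Marquardt refinement of the
exponential model is available (`nonlinear_refine=True`) but is not the
default: at the SNRs of interest the median bias of the log-linear fit is
well under the ~3 ms Monte-Carlo tolerance the tests enforce, and
determinism plus speed matter more for a clustering front-end.

**Diffusion tensor.** Standard log-linear DTI with a 7-parameter design
matrix (six tensor components + ln S0) over all measurements including
b = 0. Eigenvalues are sorted descending; negative eigenvalues are clipped
to zero and the voxel flagged, mirroring common DTI practice so masks stay
comparable across features. Scalar metrics follow the usual definitions
(AD = λ₁, RD = (λ₂+λ₃)/2, ADC = trace/3, FA the normalized eigenvalue
dispersion). Tensors are carried in units of 10⁻³ mm²/s throughout, so
physiologic placental diffusivities are order 1–4; this also matches how
lesion parameters are tabulated. Robust/weighted iterative variants are
deliberately out of scope; the log-linear fit recovers noiseless phantoms
to machine precision and is adequate at the phantom SNR.

## Fuzzy mixture segmentation

Features (ADC, FA, AD, RD, T2*) are z-scored on the training pool; the
standardizer is stored in the model so new subjects project consistently
(the features span three orders of magnitude, so unstandardized EM would be
dominated by T2*). EM uses full covariances with a relative ridge
(10⁻⁶ · trace(Σ)/5 added to the diagonal each M-step) to guard the near
collinearity of ADC with AD and RD, k-means++-seeded responsibilities, five
restarts and a fixed user seed; the best restart by final log-likelihood is
kept, and the log-likelihood trace is stored so the monotonicity of EM is
auditable. K = 3 is fixed by design — the three physiological compartments
— with lesions handled outside the mixture rather than as a fourth fitted
component, so that a lesion-free subject does not force a spurious fourth
cluster.

**Compartment naming** uses the de-standardized component means: the
highest-FA component is the vessel cluster (coherent flow), and of the
remaining two the higher-T2* one is the intervillous space (oxygenated
maternal blood) and the other villous tissue. Ties within 10⁻⁶ raise an
error demanding a manual mapping rather than guessing.

**Lesion rule.** A voxel is assigned to the lesion cluster when it is
atypical for every component: per component the typicality is
`P(χ²₅ ≥ d²ₖ)` for squared Mahalanobis distance d²ₖ, and all typicalities
must fall below α = 0.05. Normalized posteriors over three components
cannot all be below 0.05 (they sum to 1), so a per-component tail test is
the coherent formulation of an "unassignable at 0.05" rule; the threshold
semantics are preserved exactly. Two consequences are worth stating
plainly:

- *Null rate.* For data truly generated by a well-separated fitted
  mixture, the rule flags ≈ α of voxels (each voxel's own-component
  typicality is uniform under the null). A lesion-free placenta therefore
  shows a PL fraction near 5%, which is why the raw fraction is reported
  as-is and the **lesion burden** estimator subtracts the known null rate:
  `burden = max(0, (PL fraction − α)/(1 − α))`.
- *Detection ceiling.* Lesions whose parameter distribution overlaps a
  physiological compartment are only partially detectable. With the
  default lesion parameterization (the measured case with high FA and low
  T2*), roughly 90% of lesion voxels are separable from tissue; the
  remaining tail is genuinely tissue-like in feature space and no
  threshold rule can recover it. Recovered burdens for large planted
  lesions therefore run ~2–4 percentage points low, and the test suite
  records this as a known limitation rather than papering over it.

Hard labels for non-lesion voxels use the argmax posterior. The mixture may
be trained pooled across subjects (default — lesions stay outliers relative
to healthy statistics, and lesioned subjects are excluded from the training
pool) or per subject.

## Synthetic phantom

The phantom emulates the statistical structure the analyses assume, not
scanner physics (no k-space, motion or perfusion modeling).

**Geometry.** An elliptic slab on a configurable grid (default 48×48×24
voxels of 2×2×2.5 mm) with five cotyledons (Voronoi regions of seed
points), chorionic and basal surface masks as the one-voxel faces adjacent
to the slab, IVS cores at cotyledon centers and mid-depth, a vessel network
near the chorionic plate plus stem vessels descending along cotyledon
centers, tissue elsewhere, and lesions as planted ellipsoids. Compartment
assignment sorts voxels by geometric plausibility scores and takes exact
counts, so realized volume fractions match the request to rounding.

**Feature draws.** Each compartment has a 5-feature Gaussian
(mean, covariance). The tensor is axially symmetric with λ₁ = AD,
λ₂ = λ₃ = RD and a random principal direction, so ADC and FA are determined
by (AD, RD); a draw is accepted when AD ≥ RD > 0, 1 < T2* < 300 ms and the
drawn ADC agrees with (AD + 2RD)/3 within 5%, otherwise the quintuple is
re-drawn (capped at 100 attempts). The recorded truth carries the derived
ADC and FA, i.e. exactly what the tensor generates. One side effect: for
parameter sets with wide AD spreads the AD ≥ RD truncation biases the
realized AD mean upward relative to the nominal mean; the truth maps, not
the nominal spec, are the oracle for recovery tests.

**Default healthy parameters.** The compartment means are not tabulated in
the source material, so they were fixed once at physiologically plausible
mid-gestation values whose implied FA/ADC are self-consistent:
IVS (ADC 3.10, FA 0.056, AD 3.30, RD 3.00, T2* 90 ms), PV (1.87, 0.552,
3.20, 1.20, 70), PT (1.53, 0.149, 1.80, 1.40, 45), with volume fractions
0.30/0.25/0.45 and diagonal covariances. Pairwise Mahalanobis separations
exceed 5, matching the well-separated regime the validation targets.
Lesions default to the measured complicated-pregnancy case with
(ADC 1.26, FA 0.49, AD 2.01, RD 1.01, T2* 32.9); all five measured cases
are available (`lesion_spec(case=...)`). The low-FA cases are nearly
indistinguishable from healthy tissue under the axially symmetric tensor
construction and are retained for exactly that reason — they exercise the
detection ceiling.

**Acquisition and noise.** Default acquisition: 10 echoes, 5–90 ms;
b = 0 plus b = 700 s/mm² along 12 Fibonacci-hemisphere directions. These
are typical of placental protocols and fully configurable. Noise is Rician
(magnitude MRI) with SNR defined against S0, default 25; `snr=inf`
disables it. Identical seeds give bit-identical volumes.

**Cohorts.** Per subject, compartment T2* means follow
`base + slope·(GA − 29)` plus N(0, 3 ms) between-subject scatter, with
default slopes −1.5 (IVS), −1.8 (PV) and 0 (PT) ms/week over GA drawn
uniformly in 20–38 weeks (optionally stratified to 7/10/5 subjects in the
<25 / 25–35 / >35 week bins, the healthy-cohort design). Fetal-brain T2* is
`1.3 × (subject IVS T2*) + N(0, 2 ms)`, rendered in a small spherical
"brain" outside the placenta, so the brain–placenta regressions have a
known best correlate. Lesioned subjects ("complicated") deliver earlier on
average (`40 − 12·lesion_fraction` weeks), planting a negative
burden-vs-delivery-GA association.

What the phantom does **not** emulate — and what passing tests therefore do
not demonstrate about clinical data: partial-volume mixing at compartment
boundaries, spatially correlated noise and motion, B0 inhomogeneity,
perfusion (IVIM) signal, non-Gaussian within-compartment distributions,
and registration error between the T2* and DWI volumes.

## Geometry and layers

Depth is `d_c/(d_c + d_b)` from Euclidean distance transforms (in mm) to
the chorionic and basal surface masks — simple, monotone in slab
geometries, and accurate to O(voxel/thickness) against the continuum
normalized distance; a Laplace-equation streamline depth was considered and
rejected as unnecessary for slab-like organs. Layers are equal-width depth
bins (default five, labelled B chorionic → F basal, with depth 1.0 closed
into F); equal-count binning is the obvious alternative and the bin mode is
the one place the parcellation is genuinely a convention rather than a
derived quantity.

## Statistics

OLS is computed from the closed-form normal equations (slope p from the
t distribution with n−2 df; pointwise CI band from the standard
mean-response formula). Mann–Whitney U uses midranks; tie-free samples
with n₁·n₂ ≤ 400 use the exact null distribution (identical to full
enumeration), small tied samples are enumerated outright (up to 2×10⁵
arrangements), and larger samples use the tie-corrected normal
approximation with continuity correction — the result records which method
was used. GA bins are closed on the lower edge (<25, [25, 35], >35). Raw
two-sided p-values are reported with the star tiers *P<0.05, **P<0.01,
***P<0.005; an optional Holm adjustment is exposed for the binned
comparisons but is off by default to match the raw-p reporting convention.
Exact-test discreteness makes the binned comparison slightly conservative
at small bin sizes (empirical type-I error ~0.04 at nominal 0.05).

## Problem sizes in the test suite

Validation runs on deliberately small instances chosen so each check is
statistically decisive: 32×32×16-voxel phantoms (~4,500 placental voxels),
30,000-voxel mixture samples for the null outlier rate, 10,000-voxel
subsamples × 10 repeats for stability, 22-subject cohorts for trend
recovery, and 1,000 simulated null cohorts for the type-I error of the
binned comparison. Monte-Carlo tolerances in the tests are set from the
corresponding sampling distributions, not tuned to outcomes.

## Known limitations

- K is fixed at 3; no automatic model selection.
- No spatial regularization (each voxel is classified independently).
- The lesion rule's null rate is α by construction; burden estimates for
  compartment-overlapping lesions are biased low (see detection ceiling).
- Surface masks are inputs; plate detection is out of scope.
- The phantom's acquisition defaults are plausible stand-ins, not a
  reproduction of any specific protocol.
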