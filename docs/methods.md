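# Methods

This note documents the models, parameter defaults, numerical choices
and limitations of `vtamap`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Enhancement image

The MT enhancement image is the voxelwise ratio MT / non-MT of two
coregistered acquisitions on a shared grid (coregistration itself is
out of scope; inputs must already share shape and voxel size). The
division is restricted to a brain mask and to voxels whose non-MT
intensity is at least `min_denominator`, which defaults to
10⁻⁶ × median(non-MT within brain) — the ratio is otherwise undefined
near zero-signal voxels. Excluded voxels carry the sentinel −1
(enhancement ratios are strictly positive) and are absent from the
returned validity mask. No smoothing or bias-field correction is
applied before the division.

## Mixture classification

In-brain enhancement intensities are modeled as a univariate finite
Gaussian mixture fitted by EM, written in this package:

* **Responsibilities** are computed in the log domain (logsumexp), so
  well-separated components cannot underflow.
* **Initialization.** The first start places the k means at the data
  quantiles `linspace(0, 1, k)` — *including* the minimum and maximum.
  The extremes matter: the neuromelanin class can be under 1% of
  in-brain voxels, and interior quantiles would seed every component
  inside the dominant white-matter mode, leaving the bright tail
  unmodeled. The remaining `n_init − 1` starts (default total 10) use
  seeded random distinct data points; the start with the highest final
  log-likelihood wins. The first start is deterministic, so fits are
  reproducible given the seed.
* **Convergence** when the relative log-likelihood gain drops below
  `tol = 10⁻⁶` (cap 500 iterations). A variance floor of
  `10⁻¹⁰ ×` the pooled sample variance guards against collapse on
  repeated values (e.g. noiseless phantoms). The log-likelihood trace
  is recorded and is non-decreasing; tests assert this on every fit.
* k = 1 reduces to the closed-form sample mean and ML variance.

**Tissue roles** (k = 3): CSF = lowest mean, white matter = middle,
neuromelanin-related = highest. Hard assignment by maximum posterior;
exact posterior ties break toward the higher-mean component, which
favors the rarer, brighter nucleus class and is deterministic.

**VTA/SN split** (k = 4 inside the neuromelanin class): components are
grouped into a low-mean and a high-mean set by an exact weighted
two-partition of the sorted component means (1-D weighted k-means over
the k − 1 contiguous split points). The low group is the VTA candidate,
the high group the SN candidate. This rule was chosen over "the two
highest-mean components are the nuclei" because when the neuromelanin
mask contains essentially only the two nuclei — the usual situation
after a clean k = 3 classification — a 4-component fit places two
components per nucleus, and the top-two rule would then label both SN
sub-components as the nuclei. The alternative rule remains available
as `grouping="top_two"` for data where the neuromelanin class retains
substantial non-nucleus tissue. If the class carries fewer than 4
distinct intensities, `split_vta_sn` raises a degeneracy error by
contract; the pipeline wrapper then refits with k reduced to the number
of distinct values (flagged in the report), which is what makes the
noiseless phantom exactly recoverable. A single-tier class yields the
whole class as the VTA candidate with an empty, flagged SN.

**Anatomical constraints.** The medial–lateral bound is implemented as
a maximum distance (default 8 mm) from a sagittal midline plane,
supplied explicitly or estimated as the midbrain mask's center of mass
along the left–right axis; a coordinate recipe for "parallel to the
fourth ventricle" does not exist, and the midline-distance form is the
simplest faithful surrogate. Candidates are also clipped to the
midbrain mask. Connected components are labeled at 26-connectivity by
default (standard for small compact ROIs at this resolution; 6 and 18
are available) and the largest component per side of the midline is
retained, with discarded satellite sizes reported.

## ROI metrics and reliability

Volume is voxel count × voxel volume; intensity is the arithmetic mean
of the enhancement over the ROI. Both are normalized against
whole-brain volume by ratio scaling to a reference brain volume
(the HC-group mean in the pipeline): `x_norm = x · V_ref / V_subject`.
Applying the same ratio to intensity is unusual but follows the
normalization contract used for both measures; raw and normalized
values are always emitted together. Percentage overlap is reported as
100 × Dice, with Jaccard also emitted since overlap conventions vary.
ICC defaults to the two-way random-effects, absolute-agreement,
single-measurement form ICC(A,1) from the Shrout–Fleiss mean-square
formulas, with the consistency form ICC(C,1) available. Note that
ICC(A,1) ≤ ICC(C,1) holds only in the positive-reliability regime
(subject and session mean squares both above the residual); the
implementation returns whatever the formulas give, flagging negative
estimates.

## Motivation model

Effort (3–70 presses) and reward ($0.25–$2.00) are min–max normalized
to [0, 1] against the printed task ranges — not per-subject ranges —
so parameters are comparable across subjects. External-condition
acceptance follows `p = logistic((r − e − bias)/σ)`: `bias` is
literally a left–right translation of the psychometric curve along the
effort axis, and σ is the inverse gradient, with small σ producing the
near-binary phenotype. The internal condition (self-generated effort)
uses a logistic density with location `r − bias` and scale σ,
truncated and renormalized to the admissible effort interval; this
likelihood is this package's own specification, since no closed form
is published for the internal condition.

Fitting is multi-start MAP over (bias, log σ) with weakly-informative
priors bias ~ N(0, 1), log σ ~ N(log 0.3, 1), 8 quasi-Newton
(L-BFGS-B) starts, and a Laplace-approximate log evidence at the mode
for model comparison. All-accept/all-reject external data is fitted
but flagged: the bias estimate is then prior-driven. Full variational
inversion is out of scope; the MAP + Laplace pair plays the same role.

A note on identifiability: with a single pass over the 8 × 8 factorial
design (64 Bernoulli trials) the Fisher information at (bias 0.1,
σ 0.3) bounds the achievable accuracy at sd(bias) ≈ 0.09 — no
estimator can reliably localize bias to ±0.05 from one pass. The
parameter-recovery study therefore uses the design repeated 10×
(640 trials) for its headline accuracy figures and verifies that
errors shrink monotonically across 64 → 256 → 1024 trials.

## Cohort statistics

Default two-sample test is Welch's (Student's pooled-variance variant
exposed); p-values are two-sided by default with a one-sided flag.
Pearson p uses the t transform; Spearman p uses exact permutation
enumeration for n ≤ 10 without ties and the t-approximation otherwise.
"Controlling for sex" is OLS of the outcome on the predictor plus a
sex indicator, with inference on the predictor coefficient
(df = n − 3) and the equivalent partial correlation r = t/√(t² + df)
reported alongside; the OLS is closed-form in numpy and cross-checked
against statsmodels in the tests. The battery runs 15 tests — three
group comparisons (normalized VTA volume, normalized VTA intensity,
SN intensity as the specificity control), four sex-adjusted regressions
of VTA intensity on the z-scored behavioral parameters, and Spearman
correlations of VTA intensity with four symptom scales across the
cohort and again within the MA group — reports the test count, applies
no multiplicity correction by default (Benjamini–Hochberg optional),
and marks significance at α = 0.05.

## Synthetic data

**Phantoms.** A 64 × 64 × 48 grid at 0.4 mm isotropic (the
acquisition's voxel scale). A brain-shaped ellipsoid is filled with
enhancement tiers csf 0.85 < wm 0.95 < vta 1.08 < sn 1.12 — invented
values that respect the in-vivo SN > VTA ordering and give a solvable
but non-trivial mixture problem (tier gaps of 4–13 noise SDs at the
default noise). Bilateral ellipsoidal nuclei sit inside a midbrain
ellipsoid, mirror-symmetric about the sagittal midline; a CSF
compartment sits posterior to the midbrain. The non-MT volume is a
clean constant baseline and the MT volume is baseline × tier + noise
(SD = noise_sd × baseline, on the MT image only), so the enhancement
noise SD equals `noise_sd` exactly and the noiseless ratio reproduces
the tier map voxel-for-voxel. Geometry violating containment or
nucleus disjointness raises a geometry error. Default noise_sd 0.01.

**Cohorts.** Two groups, default 22 HC / 21 MA. Marginal anchors
follow the published subject-characteristics table: external σ
0.450 ± 0.09 (HC), internal σ 0.491 ± 0.10, external bias 0.034 ± 0.57,
internal bias 0.545 ± 0.46, symptom scales per their printed group
means/SDs. Planted standardized group effects (MA − HC, in SDs)
default to +0.8 on normalized VTA volume, −0.8 on normalized VTA
intensity, −3.2 on σ (the magnitude implied by the printed group
sigmas), 0 on SN intensity; VTA intensity and external bias are drawn
bivariate-normal with r = +0.4. The volume/intensity/correlation
magnitudes are the package's own choice of a clearly detectable effect
in a 43-subject cohort, matching the reported directions; the raw
cohort is not available, so printed t statistics are not reproduction
targets. Setting every effect (and the symptom-effect scale) to zero
gives the null generator used for type-I calibration. Sigmas are
clipped at 0.01 to stay strictly positive; sex is Bernoulli(0.5)
independent of group. Planted intensity/volume are defined on the
brain-normalized scale and the per-subject phantoms share brain
geometry, so whole-brain normalization in the imaging pipeline cannot
inject noise that would drown a sub-percent intensity effect.

**Trials.** Factorial 8 × 8 effort × reward designs within the printed
ranges; external responses are Bernoulli draws from the acceptance
sigmoid, internal responses inverse-CDF draws from the truncated
logistic choice density, and a random 30% of trials carry the
work-required flag (execution of the work phase is not modeled).

What the generators do *not* emulate: anatomically realistic nucleus
shapes, partial-volume effects, B1/MT-pulse physics, spatially
correlated noise, registration error, or response-time structure.
Passing tests therefore demonstrate the correctness and calibration of
the algorithms under their stated assumptions, not performance on real
scans.

## Problem sizes in the validation studies

Chosen as the package's own defaults: phantom recovery on 1 noiseless
+ 10 noisy phantoms, intensity ordering on 20 phantoms, EM benchmark
at n = 1000 (two components, means 0/5, unit SD), choice recovery on
100 subjects per trial count, calibration and power on 1000 simulated
cohorts, effect-direction detection on 20 cohorts, and an 8-subject
end-to-end demo (`configs/demo.json`).

## Known limitations

* The VTA/SN split assumes the two nuclei dominate the neuromelanin
  class; heavy contamination would require the `top_two` grouping or a
  spatial prior (out of scope).
* Recovered bias/σ are comparable in role, not absolute scale, to
  estimates from other inversion schemes, since the observation model
  for the internal condition is this package's specification.
* No multivariate mixtures, Markov-random-field regularization, or
  atlas registration; one enhancement contrast only.
* The ICC is computed on complete tables only; missing sessions are
  not imputed.
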