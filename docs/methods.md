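# Methods

This note documents the models, numerical choices and known limitations of
the package: what is simulated, how the quantification chain works, where
the design was genuinely open and what was decided, and what the passing
test suite does and does not establish about real data.

## Forward model and simulated cohorts

**Kinetics.** All tissue curves follow the simplified reference tissue model
(SRTM): a target region with relative delivery R1, apparent efflux rate k2a
(per minute) and target efflux k2 = R1·k2′ obeys

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·[C_R ⊗ e^(−k2a·t)](t),

with binding potential BP_ND = k2/k2a − 1. The reference curve C_R is the
one-tissue response C_R = K1·[C_p ⊗ e^(−k2′·t)] to a Feng-type
tri-exponential arterial input C_p (parameters `FENG_DEFAULT`: sharp peak
near 0.24 min, bi-exponential washout). Defaults: k2′ = 0.05/min,
K1 = 0.1/min, per-region baseline BP between 0 (cerebellar grey) and 1.0
(thalamus), R1 between 0.85 and 1.10. A blood-pool region carries the input
function itself so that blood-voxel selection has a target.

**Acquisition.** The 60-min schedule has 32 frames (six 10-s, eight 30-s,
five 1-min, five 2-min, eight 5-min). Frame values are averages of the fine
curve over the frame interval. All fine-grid computation uses a 1-s uniform
grid with trapezoidal quadrature; the exponential convolutions use the exact
one-step recursion (an O(N) IIR filter), so simulation and fitting share
consistent numerics. An independent Runge–Kutta oracle bounds the simulator
error below 0.1%.

**Phantom geometry.** 36×36×16 voxels at 4 mm: a white-matter slab with 16
carved cuboid regions — 13 hypothesis VOIs (brainstem, thalamus, caudate,
pallidum, putamen, corpus callosum, ACC, PCC, mPFC, precuneus, superior
parietal, cuneus, hippocampus), the precentral control region, cerebellar
grey (512 voxels), and a 50-voxel blood pool. Every analysis VOI has at
least 100 voxels. The regions carrying implanted anoxic effects cover ~10%
of the brain; this matters because the per-frame z-normalization couples all
voxels: the larger the elevated fraction, the more a patient's normalized
curves shift relative to control-derived classes (see *Pseudo-reference
sensitivity* below).

**Cohorts.** `simulate_cohort` defaults to the study composition — 24
controls, 6 anoxic, 11 traumatic. Anoxic subjects receive BP increments
drawn from U(0.5, 1.0) in thalamus, pallidum, putamen, PCC, mPFC, precuneus
and cuneus; traumatic subjects in mPFC only; the precentral control region
is never incremented. Genotypes are HAB/MAB (1:1), with MAB binding scaled
by 0.8; a configurable LAB fraction (default 0 — the analyzed cohort
contains no low-affinity binders, which the pipeline would exclude) flags
subjects for exclusion. CRS-R outcomes follow a logistic link: the mean true
BP over pallidum/putamen/PCC is mapped through
23·logistic(−(x − 0.9)/0.25), plus Gaussian noise (SD 2), rounded into
[0, 23]; scores < 8 become VS-UWS or deceased (unfavourable), 8–15 MCS,
≥ 16 EMCS. Controls carry CRS-R 23/EMCS and never enter outcome analyses.

**Noise and heterogeneity.** Frame noise is Gaussian with
SD = scale·sqrt(mean brain activity / frame duration), the standard
dynamic-PET variance proxy; the cohort default scale 0.3 corresponds to a
late-frame voxel coefficient of variation of ≈ 2.5% — a high-count
acquisition. Each voxel's curve is additionally scaled by a mean-one
lognormal factor (SD 3%, `voxel_scale_sd`), emulating smooth within-parcel
variation in delivery/binding density. `build_phantom` defaults both to
zero, giving exactly homogeneous regions for oracle tests.

`simulate_bp_cohort` generates subjects directly at the BP-map level (true
regional BP plus i.i.d. voxel noise, SD 0.2, emulating kinetic-fit error).
It shares the group/genotype/outcome machinery with the full simulator and
is used for the replicate-heavy statistical calibrations (200 null cohorts,
100 detection replicates), where rendering and fitting thousands of 4-D
images would be prohibitive. Those suites therefore validate the statistical
pipeline, not the kinetic stage — the kinetic stage is validated separately
by the recovery tests on full dynamic simulations.

## Quantification chain

**Normalization** uses the population (divide-by-n) SD; out-of-brain voxels
are stored as 0 with the brain mask as the validity mask.

**SVCA classes.** Blood = top-40 voxels by duration-weighted activity over
frames ending within 180 s (deterministic lexicographic tie-break);
specific GM = eroded thalamus; non-specific GM = eroded cerebellar GM;
white matter = eroded supratentorial WM; erosion is one 6-connected
iteration. Selection is per subject. Class sets are built independently for
HAB and MAB controls. The outlier rule (the exclusion criterion is not
otherwise fixed by the procedure): a control is dropped when the RMS
deviation of its non-specific-GM curve from the leave-one-out mean exceeds
3× the group's median RMS deviation — deterministic, scale-free, and it
isolates a single inverted-profile control on a constructed fixture.

**Unmixing and reference.** Voxel-wise NNLS (`scipy.optimize.nnls`) onto the
four class curves. The "low-binding grey matter weight ratio" is defined as
the non-specific-GM weight over the sum of all four weights; voxels with
ratio > 0.9 (strict) form the pseudo-reference. The reference TAC averages
**raw** activity (not z-scores) over that mask: kinetic modelling needs
activity units, and SRTM on z-scored curves would be dimensionally unsound.
Voxels outside the brain mask carry NaN weights ("not computed"), never 0.

**SRTM2 fitting.** Basis-function search over 256 log-spaced k2a values in
[0.006, 0.6]/min. At each k2a the subproblem is linear (two parameters for
the first SRTM pass, one for SRTM2); the grid minimum is then refined once
by a parabolic fit of the residual in log k2a, re-solving at the refined
value. Without refinement, grid quantization alone (±0.9% in k2a) maps to
several percent BP error at low BP via the (1+BP)/BP amplification; with
it, noiseless end-to-end recovery bias is below 0.1%. The reference TAC is
lifted to the fine grid by monotone PCHIP interpolation through frame
mid-times anchored at (0, 0), plus an iterated per-frame constant correction
that makes the fine curve's frame averages match the measured TAC exactly.

**Global k2′.** The first-pass SRTM is run on anatomical region-mean TACs
(high SNR), and k2′ = median over regions with first-pass BP > 0.1 — at
near-zero binding k2′ is unidentifiable. A per-voxel route (median over
above-floor voxels, deterministic subsampling) exists but is noise-fragile:
per-voxel k2′ estimates are strongly BP-dependent under noise (measured
medians 0.072 at BP 0.1–0.3 versus 0.018 at BP > 1 for a true 0.05/min), so
the region route is the pipeline default. Negative-BP voxels are retained
(not clipped) so group statistics stay unbiased; clipping is behind a flag.

### Pseudo-reference sensitivity (known limitation)

The ratio > 0.9 rule is a hard selector. With exactly homogeneous regions it
conditions **only on noise**, and the conditional mean of the selected
voxels' noise is non-zero — the extracted reference is then biased by
several percent of its amplitude, which the BP scale inherits multiplied by
(1+BP)/BP. With realistic within-parcel heterogeneity the selection keys
mostly on true kinetic variation and the bias shrinks; but a patient's
z-normalization shift (from elevated regions) still steers selection toward
higher-scale voxels, leaving a residual negative BP bias of a few percent.
The calibration scan over (noise, heterogeneity) showed regional BP RMSE
growing from ~5% at the default conditions to > 20% at 10% heterogeneity or
several-fold higher noise. The defaults model a high-quality acquisition;
conclusions about the method's robustness at ROI level do not transfer to
very noisy voxel-level data, where the selection-induced reference bias is a
real failure mode of this class of methods.

## Statistics

* Voxel-wise tests are pooled-variance two-tailed t (Welch behind a flag);
  BH FDR runs across in-mask voxels; z = Φ⁻¹(1 − p/2)·sign(t), zeroed where
  q > 0.05 (positive z = first group higher); Cohen's d uses the pooled SD,
  with the moderate/large/very-large partition at 0.80 and 1.20.
* The VOI ANOVA is `bp ~ group + voi + group:voi + genotype` with type-II
  sums of squares (standard for the unbalanced 24/6/11 design); the genotype
  covariate enters as an additive fixed factor.
* Tukey-HSD is computed directly on the studentized range distribution
  (`scipy.stats.studentized_range`), which reproduces the pooled t-test
  exactly at k = 2; the per-VOI group comparisons are drawn from one Tukey
  family over all group × VOI cell means, the post hoc that matches pairwise
  VOI reporting after a two-way ANOVA.
* Spearman uses mid-rank ties with exact permutation p for n ≤ 9 and the
  t-approximation above; lesion-overlapping VOI rows are flagged, never
  silently dropped.
* PLS1 is NIPALS with deflation, columns centered but not variance-scaled
  (BP maps share units; VIP values depend on this choice, scaling is behind
  a flag). VIP_j = sqrt(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a); mean
  squared VIP is 1 by construction and importance is strict VIP > 1. The
  outcome target is continuous CRS-R with deceased subjects entering at
  their (low) scores; leave-one-out prediction picks the component count per
  fold by an inner leave-one-out RMSE criterion capped at 5.

## Problem sizes

Suites use the sizes at which each question is answerable: full dynamic
simulations (36×36×16 × 32 frames) for kinetic recovery — noiseless bias is
checked against a cohort whose regional BP spans [0.2, 2], noisy RMSE on a
9-subject cohort at the default conditions; BP-map cohorts at the study
composition for the 200-replicate null FDR and 100-replicate detection
calibrations; and small random matrices for solver-vs-oracle checks (NNLS
exhaustive-support enumeration, full-permutation Spearman, closed-form
ANOVA/Tukey oracles).
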