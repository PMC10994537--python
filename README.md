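# tspopet

Dynamic TSPO-PET quantification and group statistics for studying in-vivo
neuroimmune activation in acute coma, exercised end-to-end on synthetic
dynamic-PET cohorts with known kinetic ground truth.

## The problem

The 18-kDa translocator protein (TSPO) is overexpressed by activated
microglia, so the binding of TSPO radioligands such as ¹⁸F-DPA-714 is an
in-vivo readout of neuroimmune activation. Quantifying that binding in
severely brain-injured patients is hard for two reasons: arterial blood
sampling is impractical in critical care, and TSPO is expressed throughout
the brain, so no anatomical region can serve as a true reference. This
package implements the reference-free quantification chain used in that
setting, plus the group and outcome statistics applied downstream, for
anyone who wants to study, stress-test or extend the method:

1. **Frame normalization** — each frame of the dynamic image is z-scored
   over the brain (subtract the within-brain mean, divide by the within-brain
   SD of the frame).
2. **SVCA kinetic classes** — from control subjects, four class
   time-activity curves are built per binding-affinity genotype (HAB/MAB):
   blood (the 40 voxels with most activity in the first 3 min), specific
   binding grey matter (eroded thalamus), non-specific binding grey matter
   (eroded cerebellar GM), and white matter. Controls with a deviant
   non-specific profile are excluded.
3. **NNLS unmixing and reference extraction** — every brain voxel's
   normalized curve is decomposed onto the four classes by non-negative
   least squares; voxels whose non-specific GM weight ratio exceeds 0.9 form
   the subject's ad hoc pseudo-reference region, whose raw-activity mean TAC
   is the reference curve.
4. **SRTM2 parametric mapping** — the simplified reference tissue model

   C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·[C_R ⊗ e^(−k2a·t)](t)

   is fitted voxel-wise by basis-function search over k2a. The reference
   efflux rate k2' = k2/R1 is estimated in a first three-parameter pass and
   then fixed globally, leaving a one-parameter fit per basis function and
   giving the non-displaceable binding potential BP_ND = R1·k2'/k2a − 1
   ("TSPO level") per voxel.
5. **Statistics** — voxel-wise two-sample t maps with Benjamini–Hochberg
   FDR, signed z maps thresholded at corrected P = 0.05, Cohen's d maps
   (moderate < 0.80 ≤ large ≤ 1.20 < very large); VOI tables over 13
   hypothesis regions plus a precentral-gyrus control region; two-way
   group × VOI ANOVA with the TSPO genotype as covariate and Tukey-HSD post
   hocs; Spearman correlations against the 23-point CRS-R outcome scale;
   and whole-brain PLS regression of CRS-R on voxel-wise BP with variable
   importance in projection (VIP) maps and leave-one-out cross-validated
   prediction.

Because no real patient data are distributable, the `synthetic` module is a
first-class component: it simulates dynamic-PET cohorts (default 24 controls,
6 anoxic, 11 traumatic) from a Feng-type arterial input function and the
SRTM forward model, with region-specific binding elevated in
mesocircuit/posteromedial regions for anoxic subjects and in medial
prefrontal cortex for traumatic subjects, HAB/MAB genotypes, and CRS-R
outcomes negatively linked to pallidal/putaminal/PCC binding. Every stage of
the pipeline is validated against this known ground truth.

## Worked example

The `analysis/` scripts run the whole study on a simulated cohort
(`--seed 11` by default):

```bash
python analysis/01_simulate_cohort.py     # cohort + ground truth tables
python analysis/02_build_classes.py       # SVCA class sets per genotype
python analysis/03_quantify_subjects.py   # NNLS + SRTM2 for all subjects
python analysis/04_group_statistics.py    # voxel + VOI group statistics
python analysis/05_outcome_pls.py         # PLS/VIP outcome model
```

Output of the quantification and statistics stages on that seed:

```
quantified 41 subjects
global k2' median 0.0459 /min (range 0.0387-0.0487); reference masks 20-114 voxels
mean VOI BP by group: {'anoxic': 0.87, 'control': 0.422, 'traumatic': 0.506}

voxel-wise q<=0.05 discoveries: {'anoxic_vs_control': 2235, 'traumatic_vs_control': 146}
CRS-R vs globus_pallidus: rho=-0.66 p=0.00361
CRS-R vs putamen: rho=-0.69 p=0.00216
CRS-R vs pcc: rho=-0.70 p=0.00194
CRS-R vs precentral: rho=-0.20 p=0.447

highest mean VIP: [('globus_pallidus', 3.75), ('thalamus', 3.32), ('pcc', 3.16),
                   ('putamen', 3.15), ('precuneus', 3.1)]
LOO prediction: Spearman rho=+0.55 (p=0.0232)
```

Reading: the estimated global efflux rate sits near the simulated truth of
0.05/min; anoxic subjects show widespread significant binding elevation while
traumatic subjects show a focal one; CRS-R correlates negatively with binding
in the outcome-driving regions but not in the control region; and the PLS
VIP map localizes outcome information to the implanted mesocircuit regions,
with leave-one-out predictions rank-correlated with the simulated outcomes.
Tables and JSON reports land in `results/`; voxel maps in `scratch/`.

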