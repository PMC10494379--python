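# multibdwi

Multi-b-value diffusion-weighted MRI (DWI) model fitting and diagnostic
statistics, built around the clinical problem of telling true tumour
progression from pseudoprogression in glioblastoma patients after
chemoradiation. Both present as new or growing enhancing lesions on
conventional MRI; quantitative diffusion parameters separate them because
progressing tumour is more cellular (restricted, heterogeneous diffusion)
and more vascular (stronger perfusion signal).

The package is aimed at imaging scientists who want a transparent,
scriptable re-implementation of the workstation pipeline: voxel-wise model
fitting, ROI summarization, and the full two-group statistics chain,
together with a synthetic phantom cohort so every stage can be exercised
and tested without patient data.

## Models

For signal S(b) at diffusion weighting b (s/mm²), normalized by S(0):

- **Monoexponential** — S(b)/S(0) = exp(−b·ADC), with ADC from the
  conventional two-point form (b = 0, 1000 s/mm²).
- **Biexponential (IVIM)** — S(b)/S(0) = (1−f)·exp(−b·D) + f·exp[−b·(D*+D)],
  separating true tissue diffusion D from capillary pseudodiffusion D*
  weighted by the perfusion fraction f. Fitted by segmented nonlinear least
  squares (high-b log-linear fit for D and f, global 1-D search for D*,
  bounded full refinement).
- **Stretched exponential** — S(b)/S(0) = exp[−(b·DDC)^α], with distributed
  diffusion coefficient DDC and heterogeneity index α ∈ (0, 1]; α = 1
  recovers monoexponential decay.

The default acquisition grid is the 12-point scheme
(0, 10, 20, 40, 60, 70, 80, 100, 200, 400, 800, 1000) s/mm².

Statistics per parameter: Lilliefors-corrected Kolmogorov–Smirnov
normality, pooled-variance two-sample t-test, ICC(2,1) with F-based 95% CI
and Bland–Altman limits of agreement for interobserver reproducibility,
empirical ROC with Youden-optimal cutoff, DeLong AUC confidence intervals
and pairwise DeLong AUC comparisons.

## Worked example

A complete synthetic study — 22 "progression" and 18 "pseudoprogression"
ellipsoidal lesions whose biexponential truths are drawn from the two
groups' published means/SDs, imaged at SNR 50 with Rician noise, fitted
voxel-wise, measured by two readers (the second with jittered tracings):

```python
from multibdwi.pipeline import run_study

result = run_study(seed=1)
print(result.report.group_comparison_table().round(3))
```

```
  parameter  mean_pos  sd_pos  mean_neg  sd_neg       t      p    icc
0       adc     1.292   0.154     1.716   0.190   7.790  0.000  0.354
1         d     0.967   0.102     1.473   0.172  11.540  0.000  0.443
2    d_star    56.188  24.567    40.044  12.080   2.544  0.015  0.656
3         f     0.268   0.074     0.207   0.061   2.792  0.008  0.692
4       ddc     1.718   0.607     2.130   0.417   2.440  0.019  0.436
5     alpha     0.592   0.106     0.741   0.082   4.866  0.000  0.501
```

Progression lesions sit lower on ADC, D, DDC and α (denser, more
heterogeneous tissue) and higher on D* and f (more microvascular flow);
all six parameters separate the groups at p < 0.05. Diffusivities are
reported ×10⁻³ mm²/s. `result.report.diagnostic_table()` adds AUC, the
Youden-optimal cutoff, sensitivity and specificity per parameter, and
`result.report.delong_pairs` holds the 15 pairwise AUC-comparison p-values.

The same pipeline is scriptable from the shell:

```
multibdwi simulate --seed 1 --out cohort/          # NIfTI volumes + truth CSV
multibdwi fit --dwi cohort/sub-001/dwi.nii.gz \
    --bvals cohort/bvals.txt --mask cohort/sub-001/mask.nii.gz --out maps/
multibdwi run-all --seed 1 --out study/            # end-to-end + report
```

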