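# cvrkit

Breath-hold cerebrovascular reactivity (CVR) mapping from concurrently
acquired multi-weighting fMRI: arterial spin labeling (ASL), gradient-echo
BOLD (GE, T2\*-weighted) and spin-echo BOLD (SE, T2-weighted).

## The problem

CVR — the capacity of cerebral vessels to dilate and raise blood flow under
a vasodilatory stimulus — is quantified here as the regression slope of an
fMRI signal on end-tidal CO2 pressure (PetCO2) during a repeated
breath-hold task:

```
CVR_w = beta from  y_w(t) = beta * PetCO2(t - lag) + intercept,   |lag| <= 10 s
```

with `y_ASL` the percent CBF change from the tag/control perfusion
difference (units %CBF/mmHg) and `y_GE`, `y_SE` the percent BOLD change
(% BOLD/mmHg).  ASL gives the physiological reference but has low SNR;
GE-BOLD has high SNR but is contaminated by the macrovascular venous
compartment (large draining veins dominate the voxel deoxyhemoglobin
volume); SE-BOLD is selectively microvascular.  The package implements the
whole chain and the group-level comparisons that ask whether SE-BOLD tracks
the ASL reference more closely than GE-BOLD — plus a synthetic cohort
generator with lossless ground truth so every stage is verifiable by
parameter recovery.

## Pipeline

1. **capnography** — expiratory-peak detection on the raw expired-CO2
   trace, linear end-tidal interpolation, resampling at the fMRI TR
   (with a sampling-line delay shift), zero-phase order-4 Butterworth
   band-pass between 150 s and 10.1 s cutoff periods (6.7–99 mHz).
2. **signal_prep** — surround subtraction (ASL perfusion) / surround
   averaging (BOLD de-contamination) of the interleaved tag/control
   frames, fractional change from the first-50-s baseline, voxelwise
   band-pass.
3. **cvr_mapping** — mass-univariate lagged GLM (`LaggedCVRRegressor`,
   sklearn-style): the PetCO2 regressor shifts on a ±10 s grid, the lag
   maximising R² is kept, beta/SE gives the confidence z-score.
4. **group_analysis** — gray-matter summaries under ASL-z thresholding,
   across-subject and spatial correlations, per-ROI Fisher-z maps with a
   venous-density stratification, Steiger tests with BH-FDR, bootstrap
   spatial-correlation-vs-n curves, second-level t-maps, CoV.
5. **synthetic** — the forward model: breathing-shaped capnography for the
   60 s baseline + 10 × (20 s breath-hold + 40 s recovery) protocol, lagged
   linear CBF responses, interleaved ASL contrast, and micro/macrovascular
   BOLD coupling with a per-ROI venous-density table.

## Worked example

```python
import numpy as np
from cvrkit import gm_summary
from cvrkit.experiments import run_cohort

cvr_set, cohort = run_cohort(n_subjects=20, seed=42)   # simulate + full pipeline
df = gm_summary(cvr_set, z_thr=-np.inf)                # per-subject GM means
print(df.mean().round(3).to_dict())
print("true:", round(np.mean([t.cvr_asl_mean for t in cohort.subjects]), 3))
```

prints (seed 42):

```
{'asl': 5.901, 'ge': 0.186, 'se': 0.101}
true: 5.854
```

i.e. the cohort's recovered group-mean CVRs: 5.90 %CBF/mmHg for ASL —
within Monte-Carlo error of the 5.85 %/mmHg injected for this particular
cohort (a high draw from the 5.3 ± 1.8 population) — and 0.186 / 0.101
% BOLD/mmHg for GE / SE.

The same chain is scriptable from a shell:

```bash
cvrkit simulate --n-subjects 20 --seed 17 --out sim/
cvrkit extract-petco2 sim/sub-01/capno.txt --n-frames 132 --out sub01_petco2.txt
cvrkit prep sim/sub-01/bold_asl.nii.gz --weighting asl --out sub01_prep_asl.nii.gz
cvrkit map-cvr sub01_prep_asl.nii.gz --petco2 sub01_petco2.txt \
    --weighting asl --mask sim/gm_mask.nii.gz --out maps/sub-01
cvrkit group maps/ --gm-mask sim/gm_mask.nii.gz --out group/
```

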