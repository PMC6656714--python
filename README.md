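# dkimri

Diffusion kurtosis imaging (DKI) analysis for multi-b-value diffusion-weighted
MRI, aimed at tumour-response biomarker studies: voxel-wise fitting of the
kurtosis signal model and of the conventional apparent diffusion coefficient,
pooling of tumour ROIs into per-patient volume-of-interest (VOI) metrics, and
the small-cohort statistics that turn those metrics into a biomarker claim —
responder vs non-responder comparison, rank correlation with histology
(cellularity, Ki-67), and observer-agreement ICCs. A synthetic phantom and
cohort generator makes the whole pipeline runnable and testable without any
patient data.

## The model

Conventional diffusion MRI assumes Gaussian water displacement, giving the
mono-exponential decay

```
S(b) = S0 · exp(−b · ADC)
```

with the apparent diffusion coefficient ADC in mm²/s. In cellular, heterogeneous
tissue the displacement distribution is leptokurtic, and at high diffusion
weighting the decay deviates from mono-exponential. DKI captures this with one
extra parameter per voxel, the apparent kurtosis K_app:

```
S(b) = S0 · exp(−b · D_app + (1/6) · b² · D_app² · K_app)
```

where D_app (mm²/s) is the kurtosis-corrected apparent diffusivity and K_app
(unitless, ≥ 0) grows with microstructural heterogeneity. Both models are
fitted per voxel: the kurtosis model by bound-constrained nonlinear least
squares on the raw signal (analytic Jacobian, exact log-quadratic OLS
initialisation), the ADC by log-linear OLS over a low-b subset
(default b = 100, 500, 900 s/mm²). The default acquisition grid is
b = 100, 500, 900, 1300, 1700 s/mm²; no b = 0 image is assumed — S0 is always
an extrapolated free parameter.

## Worked example

```python
import numpy as np
from dkimri import (BValueScheme, DiffusionKurtosisModel, dki_signal,
                    add_rician_noise, make_phantom, fit_volume,
                    combine_rois_to_voi, summarize_voi, simulate_study,
                    run_cohort_analysis)
from dkimri.phantom import default_lesions

scheme = BValueScheme([100, 500, 900, 1300, 1700])

# single-voxel fit
signal = dki_signal(scheme.as_array(), s0=1000, d_app=1.44e-3, k_app=0.69)
print(DiffusionKurtosisModel(signal, scheme).fit().summary())
```

```
Diffusion kurtosis fit
======================
n obs (b-values)  5
converged         True
S0           1000.0000  (se 6.3e-14)
D_app          0.00144  mm2/s  (se 2.83e-19)
K_app             0.69  (se 3.23e-16)
RSS        3.23117e-27
```

On a noiseless signal the fitter returns the generating parameters to machine
precision — here D_app = 1.44 × 10⁻³ mm²/s and K_app = 0.69, with a residual
sum of squares at the numerical floor.

```python
# phantom -> parameter maps -> per-patient VOI
series, truth, mask = make_phantom((48, 48, 12), default_lesions(), scheme, seed=7)
noisy = add_rician_noise(series, sigma=17.0, seed=8)
maps = fit_volume(noisy, mask)
voi = summarize_voi(maps, combine_rois_to_voi(mask))
print(f"VOI over {voi.n_used} voxels: K_app = {voi.k_app_voi:.3f}, ...")

# synthetic 17-patient cohort -> inference chain
print(run_cohort_analysis(simulate_study(seed=11)).summary())
```

```
VOI over 1739 voxels: K_app = 0.581, D_app = 1.47e-3 mm2/s, ADC = 1.24e-3 mm2/s

Cohort analysis report
======================
*  K_app: responders 0.754 ± 0.0369 (n=5) vs non-responders 0.486 ± 0.102 (n=10); student_t P = 8.15e-05
   D_app: responders 0.00123 ± 0.000364 (n=5) vs non-responders 0.0015 ± 0.000221 (n=10); student_t P = 0.0921
     ADC: responders 0.00146 ± 0.000285 (n=5) vs non-responders 0.00134 ± 0.000204 (n=10); student_t P = 0.332
  K_app vs cellularity: rho = 0.46, P = 0.0611 (n=17)
  D_app vs cellularity: rho = -0.34, P = 0.181 (n=17)
  ADC vs cellularity: rho = -0.28, P = 0.273 (n=17)
* K_app vs Ki-67: rho = 0.62, P = 0.00792 (n=17)
  D_app vs Ki-67: rho = -0.39, P = 0.119 (n=17)
  ADC vs Ki-67: rho = 0.41, P = 0.103 (n=17)
```

The phantom's two lesions were generated with mean K_app 0.69 and 0.51, so the
pooled VOI mean lands between them; in the simulated cohort the kurtosis
metric separates the response groups (starred rows are significant at 0.05)
while the Gaussian diffusivities do not — the behaviour the generator is
designed to emulate.

The same chain is available from the shell:

```bash
dkimri simulate --seed 5 --out-dir sim/ --cohort-out cohort.csv
dkimri fit --dwi sim/dwi.nii --bvals sim/dwi.bval --mask sim/mask.nii --out-dir maps/
dkimri summarize --maps-dir maps/ --mask sim/mask.nii --patient-id P01 --append-to patients.csv
dkimri analyze --cohort cohort.csv --out report.json
dkimri pipeline --seed 42 --out-dir run/     # all of the above, deterministically
```

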