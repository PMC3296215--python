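# mrsikit

Reconstruction and quantification toolkit for **multisection proton MR
spectroscopic imaging (MRSI)** acquired with a multichannel receive coil as
**severely truncated full echoes**.

Multisection MRSI excites and samples several slices within one repetition
time (`TR = T_sec × N_sec`). Covering 7 contiguous slices in a 2.3 s TR
forces the acquisition window down to 256 complex points at SW = 2000 Hz
(`T_acq = N/SW = 128 ms`), so each echo is cut off before it has decayed.
Fitting such spectra in the frequency domain suffers from low digital
resolution and the sinc wiggles introduced by zero filling; fitting the echo
directly in the time domain does not. `mrsikit` implements that processing
chain end to end, together with a seeded synthetic-data generator that
reproduces the acquisition's statistical structure (8-channel array, 7
slices, phase encoding, coil phase dispersion, slice crosstalk, complex
Gaussian noise), so every stage is testable without scanner data.

## The model

A full echo is sampled symmetrically about the echo top,
`t_n = (n − N/2)·dt`, and modeled as a sum of M damped sinusoids

```
S(t) = Σ_m  A_m · exp(i(2π f_m t + φ_m)) · exp(−α_m|t| − β_m t²)
```

with amplitude `A_m`, frequency offset `f_m` (Hz from the carrier), phase
`φ_m`, Lorentzian decay `α_m` (s⁻¹) and Gaussian decay `β_m` (s⁻²).
Three lineshape families are supported: pure Lorentzian (all `β_m = 0`),
pure Gaussian (all `α_m = 0`), and Voigtian (one `β` shared by all peaks).
Parameters are estimated by nonlinear least squares on the concatenated
real/imaginary samples, with analytic Jacobians and Cramér–Rao lower bounds
(CRLBs) from the Fisher information of the same observation model.

The multichannel combination follows five steps per voxel: (1) matrix-pencil
water removal (components within a configurable band of the carrier are
estimated and subtracted), (2) replacement of the first corrupted echo
samples by model extrapolation, (3) Gaussian apodization `exp(−βt²)`,
(4) phase alignment at the echo top, and (5) weighted summation with
weights ∝ amplitude / noise variance (the max-SNR rule). Slice-crosstalk
losses between two acquisitions are quantified per metabolite by
`d_m = (A_m,w·sp − A_m,wo·sp) / A_m,w·sp`.

## Worked example

Fit a noisy 256-point three-singlet echo (NAA/Cr/Cho at 48:36:24 a.u.,
10 Hz Lorentzian linewidth, SW 2000 Hz):

```python
from mrsikit import EchoModel, make_echo, metabolite_components

comps = metabolite_components(kind="lorentzian")          # NAA 48, Cr 36, Cho 24
echo = make_echo(comps, spectral_width=2000.0, n_points=256, noise_sd=0.8, seed=7)
res = EchoModel(echo, lineshape="lorentzian").fit()
print(res.summary(noise_sd=0.8))
```

```
Echo model fit
==============================================================
lineshape: lorentzian   domain: time
n points:  256          converged: True (6 evals)
residual norm: 1.6948e+01 (data norm 5.2809e+02)
--------------------------------------------------------------
  peak          A     f (Hz)  phi (rad)     alpha      beta
     0    47.8374   -343.601     0.0014    31.228       0.0
     1    36.0646   -213.318     0.0031    31.712       0.0
     2    23.8929   -189.054     0.0033    31.082       0.0
--------------------------------------------------------------
amplitude CRLBs at noise_sd=0.8:
  A[0] >= +/- 0.1508
  A[1] >= +/- 0.1791
  A[2] >= +/- 0.1778
==============================================================
```

The three singlets are recovered within fractions of an amplitude unit of
their true values (48/36/24); the fitted decays sit at the programmed
α = π·10 ≈ 31.4 s⁻¹, and the CRLBs state the best SD any unbiased estimator
could achieve at this noise level — the deviations above are of exactly
that order.

The full pipeline runs from the shell:

```bash
mrsikit simulate --seed 1 --out brain.h5 --grid 16 --slices 7 --noise-sd 0.3
mrsikit run brain.h5 --out results/        # fits.csv, PNG + NIfTI maps
mrsikit timing --t-sec 575 --n-sec 4       # T_sec = 575 ms, TR = 2300 ms
```

Real data enter through the documented HDF5 container (`mrsikit.io`):
`/kspace` complex (channel × slice × ky × kx × time) plus `/meta`
acquisition attributes.

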