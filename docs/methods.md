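# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `mrsikit`, and what the synthetic experiments do and do not show
about scanner data.

## Signal model and units

Each voxel echo is modeled as `S(t) = Σ_m A_m e^{i(2πf_m t + φ_m)}
e^{−α_m|t| − β_m t²}` on the symmetric grid `t_n = (n − N/2)/SW`,
`n = 0…N−1`. Units: `A` in arbitrary signal units, `f` in Hz relative to the
carrier (placed on water), `φ` in radians wrapped to (−π, π], `α` in s⁻¹,
`β` in s⁻². The two-sided envelope `e^{−α|t|−βt²}` encodes the full-echo
symmetry: a spin echo rebuilds toward `t = 0` and decays afterwards, so the
magnitude spectrum needs no phase correction.

Lineshape families impose constraint patterns rather than separate formulas:
`lorentzian` fixes every `β_m = 0`, `gaussian` fixes every `α_m = 0`, and
`voigt` frees per-peak `α_m` with a single `β` shared by all peaks (the
Gaussian broadening — field inhomogeneity — is a property of the voxel, not
of a metabolite).

Linewidths are specified as FWHM in Hz and converted by
`α = π·FWHM` and `β = π²FWHM²/(4 ln 2)`. The simulation default is a 10 Hz
linewidth for single-shape models and 2.5 Hz Lorentzian + 7.5 Hz Gaussian
FWHM contributions for the Voigtian model. We read these stated "decays in
Hz" as spectral widths rather than rate constants because Hz measures a
width in the spectrum, not a time constant; a decay-rate reading
(`α = 2π·value`) remains available by passing decay constants directly.

Default metabolite positions are NAA 2.01, Cr 3.03, Cho 3.22 ppm against
water at 4.70 ppm, converted to Hz with a configurable proton frequency
(default 127.74 MHz, 3 T): −343.6, −213.3 and −189.1 Hz. These are not
critical — every frequency-dependent test passes for any well-separated
triplet — but they reproduce the clinically relevant 24 Hz Cr–Cho gap that
makes low-resolution frequency-domain fitting hard.

## CRLB computation

The noise model is i.i.d. circular complex Gaussian with SD `σ` per real
channel. Stacking real and imaginary samples gives a real Gaussian
regression whose Fisher information is `F = Re(Jᴴ J)/σ²`, with `J` the
complex Jacobian of the model in the kind's free parameters (analytic,
verified against central differences). Bounds are `sqrt(diag(F⁻¹))`; they
scale exactly linearly in `σ`. A condition number above 1e14 raises an
identifiability error naming frequency-colliding components. A `free=`
argument restricts the bound to any parameter subset (e.g. the amplitude-only
closed form `σ/√(Σ e^{−2α|t_n|})`, used as a test oracle).

## Time-domain and frequency-domain fitting

`EchoModel.fit()` minimizes the concatenated real/imaginary residual with
`scipy.optimize.least_squares` (TRF), analytic Jacobian, bounds
`A, α, β ≥ 0`, tolerances 1e-10 and a 500-evaluation cap; hitting the cap
sets `converged=False` instead of raising. Initial values come from the
magnitude spectrum of the echo zero-padded to 4096 points: local maxima
above a prominence threshold (5× a MAD-based noise floor, never below 1% of
the spectrum maximum), FWHM by interpolated half-height crossings, and
amplitudes corrected by the height of a unit-amplitude peak with the same
decay simulated on the same grid — this folds the truncation bias of the
peak height into the correction. The global initial phase is the phase of
the echo-top sample.

Truncation sidelobes are a real hazard for peak picking: a 256-point echo
zero-padded 16-fold shows ripple maxima up to ~11% of the main peak. The
picker therefore rejects a candidate whose height falls below
`s/|Δf|` times the height of an already-accepted peak at distance `Δf`
(`s` = 3 Hz by default, an empirical envelope of the ripple decay). On
noise-free three-singlet fixtures exactly three peaks survive.

The frequency-domain fit compares the complex DFT of the (optionally
zero-padded) echo against the *continuous* lineshape spectra sampled at the
grid frequencies — Lorentzian `2α/(α²+(2πΔf)²)`, Gaussian
`√(π/β)e^{−(πΔf)²/β}`, Voigt `√(π/β)·Re w((2πΔf+iα)/(2√β))` with the
Faddeeva function — divided by the dwell time to match DFT scaling. This is
the model-mismatch formulation: the continuous shape is what the
spectroscopist believes the line to be, while the data carry truncation
wiggles and finite resolution. Complex (not magnitude) spectra are fitted;
magnitude fitting would add a noise-floor bias. Decays get a strictly
positive floor (1e-6) because the analytic shapes are degenerate at zero.

Known behavior worth stating: at 256 points (7.8 Hz grid) the complex
frequency-domain fit has a *narrow-line degeneracy* — a tall line narrower
than the grid spacing can thread between the sample frequencies and lower
the least-squares cost, so amplitude errors can reach tens of percent and,
for the Gaussian shape, above 100%. This is not an optimizer failure (it
persists when started at the truth); it is one more way in which fitting
truncated data in the frequency domain is unreliable. The package asserts
only the ordering — time-domain error < frequency-domain error, for all
three lineshapes, truncated and zero-padded — which is robust to where in
that failure regime the frequency-domain fit lands.

With the full-length 1024-point signal the frequency-domain fit recovers
amplitudes to ≤ 0.05% (residual discrepancy ~`e^{−αT/2}` plus aliased
Lorentzian tails, both ≲ 3·10⁻⁴ relative), and the 256-point time-domain
fit recovers all three lineshapes to machine precision.

## Monte-Carlo study

`run_monte_carlo` adds complex Gaussian noise to the noiseless 256-point
echo, re-initializes from the magnitude spectrum, fits in the time domain,
and matches fitted to true components by frequency (nearest-neighbor within
4 resolution elements; unresolved realizations are excluded and counted).
The reported `sd_over_crlb` uses bounds computed at the *true* parameters.
Because the original study reports CRLBs but not its noise SD, experiments
calibrate `σ` so the NAA amplitude bound equals the reported per-lineshape
value (0.1574 Lorentzian, 0.1858 Voigtian) — bounds are linear in `σ`, so
this is exact. At that SNR the estimator is essentially efficient:
SD/CRLB ≈ 1.0–1.1 across metabolites, comfortably below the factor-2
benchmark, and means land within Monte-Carlo error of 48/36/24.

## Matrix pencil: water removal and point repair

The pencil operates on the causal half of the echo (`t ≥ 0`), where each
Lorentzian component is one damped complex exponential; full echoes are not
globally single-exponential, so the estimated components are referred to
`t = 0` and reconstructed with the `e^{−α|t|}` two-sided symmetry. The
implementation is the standard Hankel/SVD subspace method: pencil parameter
`L = ⌊n_causal/3⌋` by default, order chosen by singular values above
`ε·σ_max` with `ε = 10⁻³`, raised adaptively to 3× a noise-floor estimate
(median of the smaller half of the singular values) on noisy data. On noisy
echoes individual pencil components may carry slightly negative decays;
they are kept as estimated so that reconstruction + residual equals the
input exactly, while user-facing model evaluation rejects negative decays.

Water removal subtracts every component within ±60 Hz of the carrier
(~0.47 ppm at 3 T, configurable); the number of water components is not
fixed. The removed fraction is measured as water-band spectral energy
before vs after. On the 10×-water fixture the step removes > 99.99% of the
water-band energy while shifting metabolite amplitudes by < 2%.
Corrupted-point repair (default: the first 6 samples, which live in the
early negative-`t` tail and never intersect the causal estimation window
for `n_bad < N/4`) replaces them with the model's extrapolation. For
Gaussian-decaying data both steps are approximations (a Gaussian envelope
is not a finite sum of exponentials); the quantitative guarantees are
stated for Lorentzian content.

## Reconstruction and channel combination

k-space planes are multiplied by a separable Hamming window
(`0.54 + 0.46·cos`, peak 1.0 at the k-space center index `N/2`, 0.08 at the
grid edge) and transformed with centered orthonormal 2D FFTs, so image and
k-space energies agree (Parseval) and a uniform unit object yields unit
voxel amplitude. The windowed point-spread function's peak amplitude
sidelobe on a 16-point grid is ~1.04% versus ~21.7% unwindowed — note the
discrete 16-point window sits slightly above the asymptotic −42.7 dB
Hamming figure.

Channel noise levels are measured once per channel as the SD of the real
part of signal-free spectral regions (default 300–900 Hz, away from water
and the upfield metabolites) over a block of central voxels, and reused for
every voxel — per-voxel noise estimates would add variance without bias
benefit under spatially stationary noise. Echoes are phase-aligned by
rotating the maximum-magnitude sample (ties to the earlier index) to the
positive real axis, then summed with `w_i ∝ a_i/σ_i²` normalized to
`Σ w_i = 1`. The normalization makes C identical channels combine to a
single channel; among all weights with that normalization, the default rule
maximizes combined SNR (Cauchy–Schwarz), and combined noise variance is
`Σ w_i²σ_i²`. An `a_i/σ_i` variant is available behind a flag.

## Synthetic data

The generator emulates: 8 receive channels at 45° angular increments with
smooth quadratic sensitivity roll-off and channel-specific phases (the
phase-dispersion problem the alignment step solves), mildly unequal channel
noise (up to +5%), 7 slices of 10 mm with 4 or 0 mm spacing, 16×16 (or any)
phase encodings, SW 2000 Hz, 256-point echoes, TR/TE 2300/144 ms defaults,
metabolite amplitudes 48:36:24 in labeled 2D compartments, optional
residual water (two broad components within 20 Hz of the carrier, summed
amplitude a configurable multiple of NAA), and complex Gaussian noise added
in k-space per channel. Everything is a pure function of (spec, seed).

Crosstalk is modeled as a scalar amplitude attenuation `γ(spacing)` applied
to slices that have a spatially adjacent, temporally earlier neighbor under
the interleaved excitation order (odd slices then even, 1-3-5-7-2-4-6; for
7 slices that attenuates slices 2, 4, 6 — including the central 4th slice
used for the comparison). `γ` rises linearly from `γ₀` at 0 mm to 1 at
4 mm. This captures the *net amplitude effect* the `d_m` statistic
measures; it deliberately does not Bloch-simulate slice profiles, T₁
saturation dynamics, B₀ inhomogeneity, eddy currents or lipid
contamination. Paired with/without-spacing volumes share one noise stream,
so `γ₀ = 1` yields bit-identical volumes — convenient for testing, but
real repeated scans have independent noise, and the crosstalk SDs measured
here are correspondingly optimistic. Pipeline problem sizes in the tests
(8×8–12×12 grids, central-slice fitting) were chosen as the smallest stacks
that exercise every stage with healthy voxel counts.

Consequently, passing tests demonstrate correctness of the algorithms under
the stated statistical model — they do not certify performance under
in vivo lineshape distortions, motion, or scanner-specific artifacts, whose
raw data are not available.

## Pipeline and outputs

Stage order: Hamming filter → centered 2D FFT → per-channel water removal
and point repair (optional) → apodization (0/4/10 Hz Gaussian line
broadening; 10 Hz suits phantom-like SNR, 4 Hz in vivo-like) → phase
alignment → weighted combination → time-domain fit per voxel (voxels above
a root-sum-of-squares echo-top threshold, default 25% of the maximum) →
metabolite maps by nearest-frequency assignment within ±25 Hz. Outputs are
CSV fit tables (slice, y, x, metabolite, A, f, phi, alpha, beta,
residual_norm, converged), PNG and NIfTI maps; every output embeds a SHA-256
hash of the configuration, and runs are deterministic given the config.

The timing calculator implements `TR = T_sec × N_sec` and `T_acq = N/SW`,
taking TE as given. When `T_sec` is assembled from a budget it uses
`T_p + τ₁/2 + TE + T_acq/2`, treating the pre-acquisition delay as part of
the TE interval; the remaining hardware constants are not derivable from
published timing alone, so `T_sec` can always be supplied directly.
Circular k-space sampling counts integer lattice points with radius ≤ half
the grid width (DC included): 804 encodings for 32×32, ≈ 30.8 min at
TR 2.3 s.

## Limitations

Singlet models only (no J-coupled multiplets or macromolecule baselines);
no relaxation-corrected absolute quantification; no parallel-imaging
acceleration or sensitivity mapping from reference scans; crosstalk is a
free modeling knob, never an estimated physical slice profile.
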