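# Methods

This note records the models, numerical choices and known limitations behind
the package, in the spirit of a reconstruction-methods appendix. Nothing
here states a number that the test suite or `scripts/acceptance.py` does not
itself recompute.

## Sampling geometry

A TURBINE shot is an EPI blade: Cartesian phase encoding along kz (with
optional CAIPI-style shifting so that any R consecutive shots jointly visit
every partition), radial readout encoding in-plane. Blade n is rotated by
n·180°/φ about kz, reduced modulo 180° because a blade spans both k-space
half-planes; golden-angle increments make any contiguous window of shots
near-uniform in angle (the frame-coverage test checks the maximum angular gap
of a Nyquist-sized window is below twice the uniform spacing). Angles
accumulate continuously across volumes by default; a `start_index` argument
resets or offsets the counter.

Coordinates are in cycles/FOV: unit Cartesian spacing, readout samples at
`i − N/2` for `i = 0..N−1`, k-space centre at index `N/2`. Full radial
Nyquist coverage of an N-point plane needs `⌈N·π/2⌉` blades; the total
acceleration factor of a protocol is `(N · R / shots_per_volume) · π/2`.
Readout-onset shifts that keep the effective TE constant under CAIPI
shifting, RF/gradient spoiling and fat suppression are recorded as protocol
metadata only — they do not change sample coordinates or simulated physics.

## Forward model and simulator

The simulator evaluates, per shot and coil,

    y = NUFFT_blade( FFT_kz( C_c · ρ · task(volume) · e^{2πi·b0·TE} ) ) · e^{i·k0(t)}

plus i.i.d. complex Gaussian noise, and generates three non-phase-encoded
(kz = 0) navigator lines per shot with the same corruptions. Artifact
mechanisms:

* **Nyquist ghost** — odd acquisition-order lines carry a hybrid-space phase
  `φ0 + 2π·δ·x/N` (constant phase plus sub-sample readout shift δ; defaults
  0.3 rad / 0.8 samples). The centre navigator line has odd polarity.
* **k0 phase** — respiratory (0.3 rad at 0.3 Hz) and cardiac (0.1 rad at
  1 Hz) sinusoids plus an optional random-walk drift, sampled at the shot TR
  (tens of ms, far above Nyquist for both). Amplitudes are plausible for a
  head at high field; the drift models scanner/physiology slow wander.
* **Off-resonance** — a per-voxel phase at the echo time, static
  (`b0_map_hz`) or dynamic (a callable `t → map`, used by the ±5/±10 Hz
  field-fluctuation experiment with a smooth low-order spatial pattern —
  the spatial form of such fluctuations is a modelling choice, not a
  measured quantity).
* **BOLD** — per-volume multiplicative boxcar (OFF first, 30 s blocks by
  default) on a designated ROI; no haemodynamic convolution in the ground
  truth (the GLM regressor can optionally convolve a double-gamma HRF, so
  regressor/response mismatch is testable).

The digital phantom is an ellipse-based head-like object with GM/WM/CSF
compartments and an activation ROI, Gaussian-apodized in-plane (σ = 1.2
voxels, support cut on a dilated ellipse where the tail is ~10⁻³) so that it
is essentially band-limited to the radially sampled disc — a hard-edged
object would put irreducible energy into the unsampled k-space corners and
contaminate recovery metrics with a model-mismatch floor. What the simulator
deliberately does *not* model: relaxation and steady-state effects, slab
excitation profiles, intra-readout off-resonance accrual (phase is applied
at TE only), coil electromagnetics, motion. Passing tests therefore validate
the algorithmic chain, not robustness to those physical effects.

## NUFFT

Type-2/type-1 transforms by Kaiser-Bessel gridding: oversampling 2, kernel
width 6 (Beatty's β), apodization from the kernel's analytic Fourier
transform, sparse-matrix interpolation so a plan is built once per
coordinate set and the oversampled spectrum of an image can be shared across
all blades of a volume. Accuracy versus a direct DFT is ~10⁻⁶ relative; the
forward/adjoint pair is exact to machine precision by construction (tests
assert < 10⁻⁴ and < 10⁻¹², respectively).

## Corrections

Order: ghost first, then k0 (the ghost correction also serves as the radial
trajectory correction since it aligns all blade echoes).

* **Ghost**: per shot, navigator lines are inverse-transformed along the
  readout; the odd/even phase difference is fitted as a linear phase with
  magnitude weighting restricted to samples above 10% of peak (edge samples
  are noise-dominated), the slope estimated from the lag-1 phase increment
  (wrap-immune). Odd/even lines then receive ∓½ of the estimated phase, so
  re-estimation is a fixed point. Per-shot estimates are the default, with
  optional run-median pooling. The correction is unitary per readout line
  (a pure phase in hybrid space); the k0 correction is a pure per-sample
  phase in k-space.
* **k0**: per shot, θ = arg Σ conj(reference column)·(shot column) over the
  repeatedly sampled central kz column — the least-squares constant-phase
  alignment — with the first shot as default reference. Under CAIPI
  undersampling the inner product is restricted to shared kz lines; shots
  sharing none fall back to the first shot of their own CAIPI phase. The
  series is wrapped to (−π, π]; unwrapping is for diagnostics only.
* **Band decomposition** (diagnostics): brick-wall zero-phase FFT masks,
  default respiratory < 0.5 Hz and cardiac 0.6–2 Hz; named bands plus the
  residual reconstruct the input exactly.

## Reconstruction

`(EᴴE + λ∇ₜᵀ∇ₜ)x = Eᴴk` by conjugate gradients from x = 0, tolerance 10⁻⁶
on the relative residual, iteration cap 200 (configurable). ∇ₜ is the
forward first difference with a free endpoint. Slab-2D mode inverse-FFTs kz
first and solves independent per-slice problems; full-3D keeps kz inside the
operator (samples grouped by CAIPI parity). Data are normalized so
‖Eᴴk‖∞ = 1 before solving and rescaled after; λ values are quoted on that
scale, and with the unnormalized-DFT convention of the NUFFT the sweep
λ ∈ {10³, 10⁴, 10⁵} spans weak-to-dominant regularization at the package's
problem sizes.

Two numerical choices matter:

* **Preconditioning.** The gram of radial sampling is, to first order, a
  convolution with transfer `N²(n_blades/π)/max(|k|,½)` (verified
  numerically); the temporal gram is diagonalized by the DCT. CG is
  preconditioned by dividing the joint (k, DCT) spectrum by
  `density + λμ_j`, which cuts the iteration count by roughly an order of
  magnitude — unpreconditioned CG does not reach useful accuracy within the
  200-iteration cap on these problems.
* **Disc restriction.** Frequencies outside the sampled disc |k| ≤ N/2 see
  only interpolation-kernel spillover (near-null singular values); the
  normal equations are solved restricted to the disc subspace (projector on
  the right-hand side, operator output and preconditioner), which both
  prevents corner junk in the solution and removes a spurious residual
  floor. The discarded corner content is a kernel artifact, not signal.

Self-calibration: the temporal mean (all shots in one bin) is gridded per
coil with density compensation, and adaptive-combine (Walsh) maps are taken
as the dominant eigenvector of the locally smoothed (7-voxel window) coil
covariance, phase-referenced to the strongest coil, RSS-normalized, and
zeroed where the calibration signal vanishes. SVD coil compression projects
onto the top right-singular vectors of the (sample × coil) matrix (12
virtual channels by default, capped at the physical count).

### Density compensation (calibration/adjoint imaging only)

Ramp weights `|k|·π/n_blades`; the DC cell — crossed by *every* blade — is
the half-radius disc (area π/4) shared equally among the DC samples.
Weighting each DC sample at half the innermost ring weight would over-count
the centre n_blades-fold. Against a Voronoi-cell-area oracle the ramp
weights agree closely (tested within 1.3× of Voronoi's reconstruction
error). A static-DCF adjoint is still not an inverse: for objects filling
the FOV the spectrum varies within the ring spacing and the reconstruction
carries a low-frequency halo at the tens-of-percent level (Voronoi
included). This is why density compensation is used only for calibration —
where coil-map ratios cancel the common halo — and never inside the
iterative solve, which handles density implicitly and reaches < 1% NRMSE.

## Statistics

* **Effective DOF**: one-sided periodogram of the demeaned series, DC (and
  unpaired Nyquist) bins dropped, moving-average smoothed over Nb/16 bins
  (the raw periodogram's bin-to-bin χ² fluctuation would bias the ratio down
  by ~2× while leaving truly flat spectra exact);
  `DOF = Nt·(ΣP)²/(Nb·ΣP²)` — exactly Nt for a flat spectrum, ≤ Nt always
  (Cauchy-Schwarz), within 10% of Nt for white noise, and decreasing under
  temporal smoothing. Multi-voxel input pools by the median.
* **Adjusted tSNR**: `mean(|x|)/SD(|x|) · √(DOF/Nt)` — statistical power
  scales with the square root of the number of independent samples, which
  makes the statistic approximately invariant under pure smoothing (the
  linear factor `DOF/Nt` is exposed as an option). Zero-SD voxels are NaN.
* **GLM**: design = [task (optionally HRF-convolved), intercept, DCT drift
  columns below the 60 s cutoff]; OLS per voxel; residual variance uses the
  classical dof (Nt − p) so it stays unbiased, while the t reference uses
  `effective DOF − p` — smoothing leaves variance estimable but shrinks the
  number of independent samples. This post-hoc DOF calibration replaces
  prewhitening: null false-positive rates at |z| > 1.96 land in [0.03, 0.07]
  where plugging in the nominal Nt on smoothed data is anticonservative.
  No spatial smoothing anywhere.
* **Layer profiles**: nearest-neighbour upsampling (factor 4), relative
  depth `d_WM/(d_WM + d_CSF)` from Euclidean distance transforms, 20
  equal-width depth bins (0 = WM boundary), per-bin mean z and across-slice
  SD; empty bins are NaN, never zero.

## Problem sizes

The shipped experiments run at desk scale, chosen so each completes in
seconds while staying in the regime the method targets: corrections at
64×64×8 with full radial frames (isolating the phase-error contribution to
temporal SD from frame-to-frame angle aliasing), encoding fidelity at
96×96×8 coils, the λ sweep at 64×64 with ~11× radial undersampling per frame
(matching the slab protocol's acceleration), statistics at Nt = 512 (DOF)
and Nt = 129 / TR 2.32 s (GLM, the slab protocol's 5-minute run). The
statistics power check pools the time-course over a 50-voxel ROI; at
tSNR 10 with a 2% effect and 129 volumes a *single-voxel* z is ~1 by closed
form, so per-voxel maps at this depth localize rather than detect.

## Known limitations

* The ghost model is zeroth + first order on alternating lines; no 2D or
  higher-order ghost fields.
* k0 correction is global (zeroth order); spatially resolved phase
  navigation is out of scope, which is exactly why the simulated dynamic
  field fluctuations leave monotonically growing residual artifacts.
* The absolute λ scale is tied to this package's data normalization; only
  the qualitative sweep behaviour (roughness and streak energy decreasing
  in λ) is asserted.
* Self-calibration requires fully sampled kz; CAIPI-undersampled runs need
  externally supplied maps (or a calibration pass at R = 1).
* HDF5 raw files store complex64; round-trips are bit-exact at that
  precision.
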