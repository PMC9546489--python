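# turbine

Golden-angle radial-Cartesian ("TURBINE") fMRI acquisition and
reconstruction, end to end on synthetic data: blade trajectory design,
multi-coil raw k-space simulation with realistic artifact mechanisms,
self-navigated k-space corrections, temporally regularized iterative image
reconstruction, and degrees-of-freedom-adjusted BOLD statistics.

## The problem

High-resolution fMRI with EPI suffers from distortion, dropout and T2\*
blurring along the long phase-encode echo train. TURBINE sidesteps this by
hybrid encoding: each shot is an EPI "blade" that is Cartesian along kz and
radial in the kx-ky plane, with successive blades rotated about kz by the
golden angle 180°/φ ≈ 111.25°. Any run of consecutive shots then covers
angles near-uniformly, so temporal resolution and undersampling can be chosen
*after* acquisition, the sequence is self-calibrating (coil maps from the
temporal mean), and self-navigating (a central k-space column is re-sampled
every shot, exposing shot-to-shot phase from respiration and cardiac
pulsation).

The reconstruction solves

```
min_x ‖E x − k‖₂² + λ‖∇ₜ x‖₂²
```

where `E` combines coil sensitivities, Cartesian kz encoding and a
non-uniform FFT over the rotated blades, `k` is the corrected multi-coil
k-space, and `∇ₜ` is the temporal finite-difference operator. Conjugate
gradients on the normal equations solve slab-wise 2D problems (fully sampled
kz) or a joint 3D problem (CAIPI-undersampled kz). Temporal smoothing buys
SNR at the cost of independent time-points, so statistics use the effective
temporal DOF estimated from the deviation of the power spectrum from
flatness: tSNR is scaled by √(DOF/Nt) and GLM z-statistics use a t reference
with DOF-adjusted degrees of freedom.

## Worked example

```bash
cat > demo.yaml <<'YAML'
grid: 32
n_partitions: 2
n_coils: 3
n_volumes: 10
shots_per_volume: 12
noise_sd: 0.005
block_s: 1.5
recon: {lambda_t: 100.0, max_iter: 12, n_virtual_coils: 3}
YAML
turbine demo --outdir demo_out --seed 3 --config demo.yaml
```

prints

```
effective DOF: 6.3 / 10 frames
median in-object adjusted tSNR: 10.86
max |z|: 2.49
```

The pipeline simulated a 12-shot-per-volume acquisition of a digital phantom
with a flashing-block activation ROI, applied the navigator ghost correction
and zero-order (k0) phase alignment, reconstructed with λ = 100, and ran the
statistics. The effective DOF (6.3 of 10 frames) quantifies the temporal
smoothing introduced by the regularization; the adjusted tSNR discounts it;
the z-map picks up the activation ROI (weakly, at this tiny demo size).
`demo_out/` holds the raw/corrected HDF5, NIfTI maps and a provenance
manifest.

Other subcommands: `turbine simulate`, `correct` (with `--k0-csv` band
decomposition export), `recon`, `analyze`, `psf`. Protocol presets
`slab_0p67` (0.67 mm isotropic slab, 40 shots, TRvol 2.32 s) and
`wholebrain_0p8` (0.8×0.8×2.0 mm, R=2 CAIPI, TRvol 2.4 s) ship with the
package.

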