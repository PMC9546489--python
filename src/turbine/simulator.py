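"""Synthetic multi-coil TURBINE raw k-space.

The simulator plays the role of the scanner: it evaluates the forward model
(coil-weighted object -> Cartesian kz encoding -> radial-blade NUFFT) shot by
shot and injects the artifact mechanisms the correction chain is designed to
remove:

* odd/even readout-line phase errors (the EPI Nyquist-ghost mechanism),
* shot-to-shot global phase with respiratory (~0.3 Hz) and cardiac (~1 Hz)
  sinusoids plus a slow random-walk drift, sampled once per shot TR,
* static or dynamic off-resonance applied as a per-voxel TE phase,
* block-design BOLD modulation of an activation ROI (boxcar, OFF first),
* i.i.d. complex Gaussian noise per sample.

Everything is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidArgumentError
from .nufft import KbGridder
from .trajectory import BladeSampling, TurbineProtocol, make_blades

LABEL_BACKGROUND = 0
LABEL_GM = 1
LABEL_WM = 2
LABEL_CSF = 3
LABEL_ACTIVATION = 4


@dataclass
class DigitalPhantom:
    """Ellipse-based head-like digital object.

    ``proton_density`` is the simulated baseline magnitude image,
    ``tissue_labels`` assigns background / GM / WM / CSF / activation-ROI
    labels, and ``b0_map_hz`` is per-voxel off-resonance.
    """

    proton_density: np.ndarray
    tissue_labels: np.ndarray
    b0_map_hz: np.ndarray

    @property
    def activation_mask(self) -> np.ndarray:
        return self.tissue_labels == LABEL_ACTIVATION

    @property
    def object_mask(self) -> np.ndarray:
        return self.proton_density > 0


@dataclass
class PhysioPhaseModel:
    """Shot-to-shot global (k0) phase fluctuation model.

    Respiratory and cardiac sinusoids plus a slow random-walk drift; sampled
    at the shot TR (tens of ms), well above Nyquist for both components.
    """

    respiratory_amp_rad: float = 0.3
    respiratory_freq_hz: float = 0.3
    cardiac_amp_rad: float = 0.1
    cardiac_freq_hz: float = 1.0
    drift_amp_rad: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.respiratory_freq_hz <= 0 or self.cardiac_freq_hz <= 0:
            raise InvalidArgumentError("physio frequencies must be > 0")
        if min(self.respiratory_amp_rad, self.cardiac_amp_rad, self.drift_amp_rad) < 0:
            raise InvalidArgumentError("physio amplitudes must be >= 0")

    def phase(self, t_s: np.ndarray) -> np.ndarray:
        """k0 phase (radians) at shot times ``t_s`` (seconds)."""
        t_s = np.asarray(t_s, dtype=float)
        rng = np.random.default_rng(self.seed)
        k0 = (self.respiratory_amp_rad * np.sin(2 * np.pi * self.respiratory_freq_hz * t_s)
              + self.cardiac_amp_rad * np.sin(2 * np.pi * self.cardiac_freq_hz * t_s + 1.0))
        if self.drift_amp_rad > 0 and t_s.size > 1:
            walk = np.cumsum(rng.standard_normal(t_s.size))
            walk -= walk[0]
            scale = np.max(np.abs(walk))
            if scale > 0:
                walk *= self.drift_amp_rad / scale
            k0 = k0 + walk
        return k0


@dataclass
class GhostModel:
    """Odd-line phase error producing the EPI Nyquist ghost.

    Odd acquisition-order lines carry, in readout hybrid space, the phase
    exp(i * (constant_phase_rad + 2*pi*linear_shift_samples * x / N)) with
    x = n - N/2, i.e. a sub-sample readout shift plus a constant phase.
    """

    constant_phase_rad: float = 0.3
    linear_shift_samples: float = 0.8

    def __post_init__(self):
        if abs(self.linear_shift_samples) >= 5:
            raise InvalidArgumentError("|linear_shift_samples| must be < 5")

    def hybrid_phase(self, n_readout: int) -> np.ndarray:
        x = np.arange(n_readout) - n_readout // 2
        return self.constant_phase_rad + 2 * np.pi * self.linear_shift_samples * x / n_readout


@dataclass
class ImageSeries:
    """Image time-series on the protocol voxel grid (x, y, z, t)."""

    data: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    tr_vol_s: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


@dataclass
class RawKspace:
    """Multi-shot, multi-coil TURBINE raw data.

    ``data`` is indexed (shot, coil, pe_line, readout_sample) with pe lines in
    acquisition order; ``navigators`` is (shot, coil, nav_line, readout_sample)
    with the centre navigator line of opposite readout polarity.
    """

    data: np.ndarray
    navigators: np.ndarray
    blades: list
    protocol: TurbineProtocol
    noise_sd: float = 0.0
    truth: Optional[ImageSeries] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.shape[0] != self.navigators.shape[0] or len(self.blades) != self.data.shape[0]:
            raise InvalidArgumentError("shot counts of data/navigators/blades disagree")
        if self.navigators.shape[2] != self.protocol.n_navigators:
            raise InvalidArgumentError("navigator line count does not match protocol")

    @property
    def n_shots(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]

    @property
    def n_readout(self) -> int:
        return self.data.shape[3]

    def copy(self) -> "RawKspace":
        return RawKspace(self.data.copy(), self.navigators.copy(), list(self.blades),
                         self.protocol, self.noise_sd, self.truth, dict(self.meta))


def _ellipse(grid, center, semi, shape):
    # z semi-axes are clamped so thin slabs (few partitions) keep >= 1 slice
    semi = list(semi[:2]) + [max(a, 0.51) for a in semi[2:]]
    axes = np.ix_(*[np.arange(s) for s in shape])
    acc = np.zeros(shape)
    for ax, c, a in zip(axes, center, semi):
        acc = acc + ((ax - c) / a) ** 2
    return acc <= 1.0


def make_phantom(grid, seed: int = 0, b0_amp_hz: float = 0.0) -> DigitalPhantom:
    """Head-like digital phantom on a 2D or 3D grid.

    An outer "GM" ellipse contains a "WM" ellipse, a small "CSF" ventricle and
    a designated activation ROI placed fully inside the object.  ``b0_amp_hz``
    scales a smooth low-order off-resonance field (0 disables it).  The object
    is apodized with a small Gaussian edge roll-off so that the discrete
    forward model is not dominated by ring artifacts of an ideal hard edge.
    """
    grid = tuple(int(g) for g in grid)
    if any(g < 16 for g in grid[:2]):
        raise InvalidArgumentError("in-plane grid must be >= 16")
    rng = np.random.default_rng(seed)
    shape = grid
    # in-plane centres follow the k-space-centre convention (index n/2);
    # z centres sit on the voxel-centre grid so thin slabs stay symmetric
    center = [shape[0] / 2.0, shape[1] / 2.0] + [(s - 1) / 2.0 for s in shape[2:]]
    semi_head = [0.40 * shape[0], 0.34 * shape[1]] + ([0.36 * s for s in shape[2:]])

    pd = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int8)
    head = _ellipse(grid, center, semi_head, shape)
    pd[head] = 1.0
    labels[head] = LABEL_GM

    semi_wm = [0.6 * s for s in semi_head]
    wm = _ellipse(grid, center, semi_wm, shape)
    pd[wm] = 0.75
    labels[wm] = LABEL_WM

    csf_center = list(center)
    csf_center[1] += 0.08 * shape[1]
    csf = _ellipse(grid, csf_center, [0.07 * shape[0], 0.10 * shape[1]] + [0.2 * s for s in shape[2:]], shape)
    pd[csf] = 1.2
    labels[csf] = LABEL_CSF

    # a few random internal blobs for texture, deterministic in the seed
    for _ in range(3):
        c = [center[i] + rng.uniform(-0.15, 0.15) * shape[i] for i in range(len(shape))]
        blob = _ellipse(grid, c, [0.05 * s for s in shape], shape) & head
        pd[blob] *= rng.uniform(0.85, 1.1)

    roi_center = list(center)
    roi_center[0] -= 0.22 * shape[0]
    roi = _ellipse(grid, roi_center, [0.07 * shape[0], 0.07 * shape[1]] + [0.25 * s for s in shape[2:]], shape)
    roi &= head
    labels[roi] = LABEL_ACTIVATION

    # smooth in-plane edge roll-off so the object is essentially band-limited
    # (hard edges would put signal beyond the radially sampled k-space disc);
    # the support cut sits on a dilated ellipse where the tail is ~1e-3
    from scipy.ndimage import gaussian_filter
    sigma = [1.2, 1.2] + [0.0] * (len(shape) - 2)
    pd = gaussian_filter(pd, sigma)
    head_outer = _ellipse(grid, center, [1.12 * s for s in semi_head[:2]] + semi_head[2:], shape)
    pd[~head_outer] = 0.0

    if b0_amp_hz != 0.0:
        b0 = _smooth_field(shape) * b0_amp_hz
    else:
        b0 = np.zeros(shape)
    return DigitalPhantom(proton_density=pd, tissue_labels=labels, b0_map_hz=b0)


def _smooth_field(shape) -> np.ndarray:
    """Smooth low-order spatial field, normalized to max |.| = 1."""
    axes = np.ix_(*[(np.arange(s) - s / 2.0) / s for s in shape])
    f = np.zeros(shape)
    f = f + 2.0 * axes[0] + 1.2 * axes[1] + 3.0 * axes[0] * axes[1] + 1.5 * (axes[0] ** 2 - axes[1] ** 2)
    return f / np.max(np.abs(f))


def make_coil_sensitivities(grid, n_coils: int, seed: int = 0) -> np.ndarray:
    """Smooth complex coil maps, shape (coil, *grid), RSS-normalized to 1.

    Gaussian-lobe magnitudes centred on a ring around the object with smooth
    low-order phase.  ``n_coils=1`` returns a uniform unit map.
    """
    grid = tuple(int(g) for g in grid)
    if n_coils < 1:
        raise InvalidArgumentError("n_coils must be >= 1")
    if n_coils == 1:
        return np.ones((1,) + grid, dtype=complex)
    rng = np.random.default_rng(seed)
    nx, ny = grid[0], grid[1]
    x = (np.arange(nx) - nx / 2)[:, None]
    y = (np.arange(ny) - ny / 2)[None, :]
    maps2d = np.empty((n_coils, nx, ny), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cx = 0.55 * nx * np.cos(ang)
        cy = 0.55 * ny * np.sin(ang)
        w = 0.55 * nx * rng.uniform(0.9, 1.1)
        mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * w**2))
        ph = (rng.uniform(-1, 1) * x / nx + rng.uniform(-1, 1) * y / ny
              + rng.uniform(-0.5, 0.5) * x * y / (nx * ny)) * 2 * np.pi * 0.4
        maps2d[c] = mag * np.exp(1j * ph)
    rss = np.sqrt(np.sum(np.abs(maps2d) ** 2, axis=0))
    maps2d /= rss
    if len(grid) == 2:
        return maps2d
    return np.repeat(maps2d[..., None], grid[2], axis=-1)


def make_task_timeseries(n_volumes: int, tr_vol_s: float, block_s: float = 30.0,
                         effect_fraction: float = 0.02) -> np.ndarray:
    """Per-volume activation multipliers for a block design (OFF first).

    The boxcar alternates every ``block_s`` seconds; ON volumes multiply the
    ROI signal by (1 + effect_fraction).  Volume state is evaluated at the
    volume's mid-acquisition time.
    """
    if block_s <= tr_vol_s:
        raise InvalidArgumentError("block_s must exceed tr_vol_s")
    t_mid = (np.arange(n_volumes) + 0.5) * tr_vol_s
    on = (np.floor(t_mid / block_s).astype(int) % 2) == 1
    return 1.0 + effect_fraction * on


def task_boxcar(n_volumes: int, tr_vol_s: float, block_s: float = 30.0) -> np.ndarray:
    """0/1 boxcar regressor matching :func:`make_task_timeseries`."""
    mult = make_task_timeseries(n_volumes, tr_vol_s, block_s, effect_fraction=1.0)
    return mult - 1.0


def _shifted_fft_z(vol: np.ndarray) -> np.ndarray:
    """Cartesian kz encoding: centred unnormalized DFT along the last axis."""
    return np.fft.fftshift(np.fft.fft(np.fft.ifftshift(vol, axes=-1), axis=-1), axes=-1)


def simulate_acquisition(phantom: DigitalPhantom, coils: np.ndarray, blades,
                         physio: Optional[PhysioPhaseModel] = None,
                         ghost: Optional[GhostModel] = None,
                         noise_sd: float = 0.0,
                         task: Optional[np.ndarray] = None,
                         protocol: Optional[TurbineProtocol] = None,
                         seed: int = 0,
                         b0_te_s: Optional[float] = None,
                         dynamic_b0=None) -> RawKspace:
    """Simulate multi-shot, multi-coil TURBINE raw k-space.

    Parameters
    ----------
    phantom, coils
        Object and coil maps on the same (2D or 3D) grid; 2D grids are
        treated as a single-partition slab.
    blades
        Per-shot :class:`~turbine.trajectory.BladeSampling`; shots are grouped
        into volumes of ``protocol.shots_per_volume``.
    physio, ghost
        Optional artifact models (None disables the mechanism).
    task
        Per-volume activation multipliers applied to the ROI (None = rest).
    b0_te_s
        TE (seconds) at which the static ``phantom.b0_map_hz`` phase accrues;
        defaults to the protocol TE.
    dynamic_b0
        Optional callable ``t_s -> b0_map_hz`` overriding the static map with
        a per-shot field (used for field-fluctuation experiments; forces the
        slow per-shot evaluation path).

    Returns
    -------
    RawKspace
        With the ground-truth magnitude series and the injected k0 series in
        ``meta['k0_truth_rad']``.
    """
    if protocol is None:
        raise InvalidArgumentError("protocol is required")
    pd = phantom.proton_density
    if pd.ndim == 2:
        pd = pd[..., None]
        labels = phantom.tissue_labels[..., None]
        b0 = phantom.b0_map_hz[..., None]
    else:
        labels = phantom.tissue_labels
        b0 = phantom.b0_map_hz
    if coils.ndim == pd.ndim:  # maps without z axis on a 3D-normalized object
        coils = coils[..., None] if coils.shape[1:] != pd.shape else coils
    if coils.shape[1:] != pd.shape:
        raise InvalidArgumentError("coil maps and phantom grids disagree")
    n = protocol.n_readout
    nz = pd.shape[2]
    if pd.shape[0] != n or pd.shape[1] != n:
        raise InvalidArgumentError("phantom in-plane grid must match protocol matrix")
    if nz != protocol.n_partitions:
        raise InvalidArgumentError("phantom partitions must match protocol matrix[2]")

    n_shots = len(blades)
    spv = protocol.shots_per_volume
    n_volumes = int(np.ceil(n_shots / spv))
    if task is not None and len(task) < n_volumes:
        raise InvalidArgumentError("task series shorter than number of volumes")
    n_coils = coils.shape[0]
    tr_s = protocol.tr_shot_ms / 1000.0
    te_s = protocol.te_ms / 1000.0 if b0_te_s is None else b0_te_s
    t_shot = np.arange(n_shots) * tr_s

    k0 = physio.phase(t_shot) if physio is not None else np.zeros(n_shots)
    ghost_phase = ghost.hybrid_phase(n) if ghost is not None else None
    rng = np.random.default_rng(seed)
    gridder = KbGridder(n)
    plans = {}

    def plan_for(blade: BladeSampling):
        key = round(blade.angle_deg, 9)
        if key not in plans:
            plans[key] = gridder.plan(blade.readout_coords[0, :, :2])
        return plans[key]

    n_pe = len(blades[0].pe_indices)
    for b in blades:
        if len(b.pe_indices) != n_pe:
            raise InvalidArgumentError(
                "all shots must sample the same number of pe lines "
                "(choose matrix[2] divisible by r_inplane)")

    data = np.empty((n_shots, n_coils, n_pe, n), dtype=complex)
    navs = np.empty((n_shots, n_coils, protocol.n_navigators, n), dtype=complex)
    truth = np.empty(pd.shape + (n_volumes,))

    static_b0_phase = np.exp(2j * np.pi * b0 * te_s) if np.any(b0) else None

    for vol in range(n_volumes):
        mult = np.ones(pd.shape)
        if task is not None:
            mult[labels == LABEL_ACTIVATION] = task[vol]
        obj = pd * mult
        truth[..., vol] = obj
        obj_c = obj.astype(complex)
        if static_b0_phase is not None:
            obj_c = obj_c * static_b0_phase
        shots = range(vol * spv, min((vol + 1) * spv, n_shots))
        if dynamic_b0 is None:
            # static object within the volume: cache the oversampled spectra
            spectra = np.empty((n_coils, nz, gridder.grid, gridder.grid), dtype=complex)
            for c in range(n_coils):
                ksp_z = _shifted_fft_z(coils[c] * obj_c)
                for z in range(nz):
                    spectra[c, z] = gridder.spectrum(ksp_z[:, :, z])
            for s in shots:
                _sample_shot(data, navs, s, blades[s], plan_for(blades[s]), spectra,
                             k0[s], ghost_phase, nz)
        else:
            for s in shots:
                b0_t = np.asarray(dynamic_b0(t_shot[s]))
                if b0_t.ndim == 2:
                    b0_t = b0_t[..., None]
                obj_t = obj_c * np.exp(2j * np.pi * b0_t * te_s)
                spectra = np.empty((n_coils, nz, gridder.grid, gridder.grid), dtype=complex)
                for c in range(n_coils):
                    ksp_z = _shifted_fft_z(coils[c] * obj_t)
                    for z in range(nz):
                        spectra[c, z] = gridder.spectrum(ksp_z[:, :, z])
                _sample_shot(data, navs, s, blades[s], plan_for(blades[s]), spectra,
                             k0[s], ghost_phase, nz)

    if noise_sd > 0:
        data += noise_sd * (rng.standard_normal(data.shape)
                            + 1j * rng.standard_normal(data.shape))
        navs += noise_sd * (rng.standard_normal(navs.shape)
                            + 1j * rng.standard_normal(navs.shape))

    truth_series = ImageSeries(truth.astype(complex), protocol.voxel_size_mm,
                               tr_vol_s=spv * tr_s)
    return RawKspace(data=data, navigators=navs, blades=list(blades),
                     protocol=protocol, noise_sd=noise_sd, truth=truth_series,
                     meta={"k0_truth_rad": k0, "seed": seed})


def _sample_shot(data, navs, s, blade, plan, spectra, k0_s, ghost_phase, nz):
    n_coils = spectra.shape[0]
    phase = np.exp(1j * k0_s)
    for c in range(n_coils):
        for i, pe in enumerate(blade.pe_indices):
            line = plan.sample(spectra[c, pe])
            data[s, c, i] = line
        nav_line = plan.sample(spectra[c, nz // 2])  # kz = 0 partition row
        for ln in range(navs.shape[2]):
            navs[s, c, ln] = nav_line
    if ghost_phase is not None:
        gp = np.exp(1j * ghost_phase)
        _apply_hybrid_phase(data[s], gp, odd_only=True)
        _apply_hybrid_phase(navs[s], gp, odd_only=True)
    data[s] *= phase
    navs[s] *= phase


def _apply_hybrid_phase(lines, phase_factor, odd_only=True, half=None):
    """Multiply readout lines (last axis) by a phase in readout hybrid space.

    ``lines`` is (..., n_line, n_read); odd line indices get the phase when
    ``odd_only``; ``half`` applies +/- half phases to even/odd lines instead
    (the correction convention).
    """
    hyb = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(lines, axes=-1), axis=-1), axes=-1)
    if half is not None:
        hyb[..., 1::2, :] *= np.conj(half)
        hyb[..., 0::2, :] *= half
    elif odd_only:
        hyb[..., 1::2, :] *= phase_factor
    else:
        hyb *= phase_factor
    return_lines = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(hyb, axes=-1), axis=-1), axes=-1)
    lines[...] = return_lines
    return lines


def simulate_field_fluctuation_experiment(amplitude_hz: float, seed: int = 0,
                                          grid: int = 64, n_coils: int = 4,
                                          n_volumes: int = 4, shots_per_volume: int = 24,
                                          freq_hz: float = 0.3, lam: float = 10.0):
    """Dynamic-field experiment: zeroth-order correction only.

    Simulates a slab acquisition with a smoothly varying off-resonance field
    oscillating at ``freq_hz`` with peak amplitude ``amplitude_hz``, applies
    only the global (k0) phase correction, reconstructs, and returns
    ``(truth, recon)`` image series.  Residual artifact is quantified by the
    caller (e.g. NRMSE versus truth); spatially varying phase cannot be
    removed by a global correction, so the residual grows with amplitude.
    """
    if amplitude_hz < 0:
        raise InvalidArgumentError("amplitude must be >= 0")
    from .corrections import estimate_k0, apply_k0_correction
    from .recon import ReconConfig, reconstruct

    protocol = TurbineProtocol(fov_mm=(192.0, 192.0, 8.0), matrix=(grid, grid, 1),
                               shots_per_volume=shots_per_volume, r_inplane=1,
                               te_ms=23.0, tr_shot_ms=58.0)
    phantom = make_phantom((grid, grid, 1), seed=seed)
    coils = make_coil_sensitivities((grid, grid, 1), n_coils, seed=seed + 1)
    blades = make_blades(protocol, n_volumes * shots_per_volume)
    pattern = _smooth_field((grid, grid, 1))

    dyn = None
    if amplitude_hz > 0:
        def dyn(t_s, _p=pattern):
            return _p * amplitude_hz * np.sin(2 * np.pi * freq_hz * t_s)

    raw = simulate_acquisition(phantom, coils, blades, physio=None, ghost=None,
                               noise_sd=0.0, task=None, protocol=protocol,
                               seed=seed, dynamic_b0=dyn)
    k0 = estimate_k0(raw)
    corrected = apply_k0_correction(raw, k0)
    cfg = ReconConfig(lambda_t=lam, max_iter=60, mode="slab2d",
                      shots_per_frame=shots_per_volume)
    recon = reconstruct(corrected, coils, cfg)
    return raw.truth, recon
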