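"""BOLD time-series statistics for temporally regularized reconstructions.

Temporal regularization smooths the reconstructed time-series, so the number
of statistically independent time-points drops below the nominal frame count.
This module estimates the effective temporal degrees of freedom (DOF) from
the deviation of the power spectrum from flatness, uses it to de-bias tSNR,
and calibrates GLM z-statistics with the same DOF.  A minimal equidistant
cortical-depth profile analysis is included for laminar work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.ndimage import distance_transform_edt, uniform_filter1d

from .errors import DegenerateDataError, InvalidArgumentError


@dataclass
class TsnrMap:
    """DOF-adjusted temporal SNR map."""

    tsnr: np.ndarray
    dof_effective: float
    n_timepoints: int
    adjusted: bool = True


@dataclass
class ActivationMap:
    """GLM activation statistics (no spatial smoothing)."""

    zstat: np.ndarray
    beta: np.ndarray
    tstat: np.ndarray
    design: dict = field(default_factory=dict)
    highpass_cutoff_s: Optional[float] = None


@dataclass
class LayerProfile:
    """Pooled z-statistics across equidistant relative cortical depths."""

    depths: np.ndarray        # bin centres in [0, 1], 0 = WM boundary
    pooled_z: np.ndarray      # per-bin mean (NaN where a bin is empty)
    spread: np.ndarray        # per-bin SD across slices (or voxels in 2D)
    counts: np.ndarray


def effective_dof(timeseries: np.ndarray, axis: int = -1,
                  smooth_bins: Optional[int] = None) -> float:
    """Effective temporal DOF from the flatness of the power spectrum.

    The series is demeaned and its one-sided periodogram P_k computed over
    the Nb non-zero-frequency bins; the spectral flatness ratio
    (sum P)^2 / sum P^2 (= Nb for an exactly flat spectrum, smaller for any
    concentration of power) is rescaled so a flat spectrum returns Nt:

        DOF = Nt * (sum P)^2 / (Nb * sum P^2).

    By Cauchy-Schwarz, DOF <= Nt always.  The raw periodogram of even a white
    series fluctuates bin to bin, which would bias the ratio down; a modest
    moving-average smoothing of P (default Nb/16 bins) stabilizes it while
    leaving genuinely flat spectra exactly flat.  For multi-voxel input the
    pooled estimate is the median over voxels.
    """
    x = np.asarray(timeseries, dtype=float)
    x = np.moveaxis(x, axis, -1)
    nt = x.shape[-1]
    if nt < 8:
        raise InvalidArgumentError("need at least 8 time-points")
    x = x - x.mean(axis=-1, keepdims=True)
    if not np.any(x):
        raise DegenerateDataError("constant time-series has no spectral content")
    p = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    p = p[..., 1:]  # drop DC
    if nt % 2 == 0:
        p = p[..., :-1] if p.shape[-1] > 1 else p  # drop unpaired Nyquist bin
    nb = p.shape[-1]
    if smooth_bins is None:
        smooth_bins = max(1, nb // 16)
    if smooth_bins > 1:
        p = uniform_filter1d(p, size=smooth_bins, axis=-1, mode="nearest")
    num = p.sum(axis=-1) ** 2
    den = (p**2).sum(axis=-1)
    ok = den > 0
    if not np.any(ok):
        raise DegenerateDataError("constant time-series has no spectral content")
    ratio = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
    dof = nt * ratio / nb
    return float(np.nanmedian(dof))


def adjusted_tsnr(series: np.ndarray, dof: Optional[float] = None,
                  nt: Optional[int] = None, axis: int = -1,
                  sqrt_adjustment: bool = True) -> TsnrMap:
    """DOF-adjusted temporal SNR.

    tSNR = mean(|x|) / SD(|x|) * sqrt(DOF / Nt) (per voxel, across time).
    The sqrt form reflects that statistical power scales with the square root
    of the number of independent samples; ``sqrt_adjustment=False`` applies
    the linear factor DOF/Nt instead.  With DOF = Nt this is the plain
    mean/SD ratio.  Zero-SD voxels are marked NaN (invalid), not infinite.
    """
    x = np.abs(np.moveaxis(np.asarray(series), axis, -1))
    n = x.shape[-1]
    if nt is None:
        nt = n
    if dof is None:
        dof = effective_dof(x, axis=-1)
    if dof > nt * 1.05:
        raise InvalidArgumentError("dof exceeds n_timepoints beyond estimator tolerance")
    mean = x.mean(axis=-1)
    sd = x.std(axis=-1, ddof=1)
    factor = np.sqrt(dof / nt) if sqrt_adjustment else dof / nt
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0) * factor, np.nan)
    return TsnrMap(tsnr=tsnr, dof_effective=float(dof), n_timepoints=int(nt))


def hrf_double_gamma(t_s: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, unit peak."""
    t = np.asarray(t_s, dtype=float)
    g1 = stats.gamma.pdf(t, peak_s)
    g2 = stats.gamma.pdf(t, undershoot_s)
    h = g1 - ratio * g2
    return h / np.max(np.abs(h))


def dct_highpass_basis(nt: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift regressors with periods longer than ``cutoff_s``.

    Column k is cos(pi k (t + 1/2) / Nt) with frequency k / (2 Nt TR); all
    components slower than the cutoff are returned (to be projected out).
    """
    t = np.arange(nt)
    ks = []
    k = 1
    while k / (2 * nt * tr_s) < 1.0 / cutoff_s:
        ks.append(k)
        k += 1
    if not ks:
        return np.empty((nt, 0))
    basis = np.stack([np.cos(np.pi * k * (t + 0.5) / nt) for k in ks], axis=1)
    return basis / np.linalg.norm(basis, axis=0)


def glm_activation(series: np.ndarray, task: np.ndarray, tr_s: float,
                   highpass_s: Optional[float] = 60.0, hrf: bool = False,
                   dof_effective: Optional[float] = None,
                   axis: int = -1) -> ActivationMap:
    """Block-design GLM with DCT high-pass and DOF-calibrated z-statistics.

    The design is [task regressor, intercept, DCT drift columns]; ordinary
    least squares per voxel, t = beta / SE, and z maps t through the
    t-distribution with ``dof_effective - p`` degrees of freedom, where the
    effective DOF (estimated from the data if not given) accounts for the
    temporal smoothing introduced upstream.  No spatial smoothing is applied.
    """
    x = np.moveaxis(np.asarray(series, dtype=float), axis, -1)
    nt = x.shape[-1]
    task = np.asarray(task, dtype=float)
    if task.shape[0] != nt:
        raise InvalidArgumentError("task regressor length must match time axis")
    reg = task.copy()
    if hrf:
        t = np.arange(nt) * tr_s
        h = hrf_double_gamma(np.arange(0, 32.0, tr_s))
        reg = np.convolve(task, h)[:nt]
    reg = reg - reg.mean()
    cols = [reg, np.ones(nt)]
    if highpass_s is not None:
        drift = dct_highpass_basis(nt, tr_s, highpass_s)
        cols.extend(drift.T)
    design = np.stack(cols, axis=1)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise InvalidArgumentError("design matrix is rank deficient")
    p = design.shape[1]

    flat = x.reshape(-1, nt).T  # (nt, vox)
    pinv = np.linalg.pinv(design)
    beta = pinv @ flat
    resid = flat - design @ beta
    if dof_effective is None:
        try:
            dof_effective = effective_dof(resid.T, axis=-1)
        except DegenerateDataError:  # (near) noise-free fit
            dof_effective = float(nt)
    dof = max(min(dof_effective, nt) - p, 1.0)
    # unbiased residual variance uses the classical dof; the *effective* dof
    # only sets the reference t distribution (temporal smoothing leaves the
    # variance estimable but shrinks the number of independent samples)
    sigma2 = np.sum(resid**2, axis=0) / (nt - p)
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[0, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta[0] / np.where(se > 0, se, 1.0),
                         np.sign(beta[0]) * np.inf)
        tstat = np.where(np.abs(beta[0]) > 0, tstat, 0.0)
    z = np.sign(tstat) * stats.norm.isf(stats.t.sf(np.abs(tstat), dof))
    z = np.nan_to_num(np.clip(z, -40, 40), nan=0.0, posinf=40, neginf=-40)
    shape = x.shape[:-1]
    return ActivationMap(
        zstat=z.reshape(shape), beta=beta[0].reshape(shape),
        tstat=tstat.reshape(shape),
        design={"n_regressors": p, "dof_effective": float(dof_effective),
                "dof_resid": float(dof), "hrf": hrf},
        highpass_cutoff_s=highpass_s,
    )


def _upsample_nn(arr: np.ndarray, factor: int, axes) -> np.ndarray:
    out = arr
    for ax in axes:
        out = np.repeat(out, factor, axis=ax)
    return out


def layer_profile(zmap: np.ndarray, wm_mask: np.ndarray, csf_mask: np.ndarray,
                  roi_mask: np.ndarray, n_layers: int = 20,
                  upsample: int = 4, slice_axis: Optional[int] = None) -> LayerProfile:
    """Equidistant-depth laminar profile of a z-statistic map.

    All inputs are upsampled by nearest neighbour (factor ``upsample``,
    in-plane); each ROI voxel gets a relative cortical depth
    d_wm / (d_wm + d_csf) from Euclidean distance transforms to the WM and
    CSF boundary masks, and is assigned to one of ``n_layers`` equal-width
    depth bins (0 = WM side, 1 = CSF/pial side).  ``pooled_z`` is the mean z
    per bin; ``spread`` is the SD of per-slice bin means along ``slice_axis``
    (per-bin voxel SD for 2D input).  Empty bins are NaN, not zero.
    """
    zmap = np.asarray(zmap, dtype=float)
    wm = np.asarray(wm_mask, dtype=bool)
    csf = np.asarray(csf_mask, dtype=bool)
    roi = np.asarray(roi_mask, dtype=bool)
    if not (zmap.shape == wm.shape == csf.shape == roi.shape):
        raise InvalidArgumentError("zmap and masks must share a shape")
    if np.any(wm & csf) or np.any(roi & wm) or np.any(roi & csf):
        raise InvalidArgumentError("wm/csf/roi masks must be disjoint")
    if not roi.any():
        raise InvalidArgumentError("empty ROI")

    axes = (0, 1)
    if upsample > 1:
        zmap = _upsample_nn(zmap, upsample, axes)
        wm = _upsample_nn(wm, upsample, axes)
        csf = _upsample_nn(csf, upsample, axes)
        roi = _upsample_nn(roi, upsample, axes)

    d_wm = distance_transform_edt(~wm)
    d_csf = distance_transform_edt(~csf)
    with np.errstate(invalid="ignore"):
        depth = d_wm / (d_wm + d_csf)
    depth = np.clip(np.nan_to_num(depth, nan=0.5), 0.0, 1.0)
    bins = np.minimum((depth * n_layers).astype(int), n_layers - 1)

    pooled = np.full(n_layers, np.nan)
    counts = np.zeros(n_layers, dtype=int)
    for b in range(n_layers):
        sel = roi & (bins == b)
        counts[b] = int(sel.sum())
        if counts[b]:
            pooled[b] = float(zmap[sel].mean())

    spread = np.full(n_layers, np.nan)
    if slice_axis is not None and zmap.ndim == 3:
        nsl = zmap.shape[slice_axis]
        per_slice = np.full((nsl, n_layers), np.nan)
        for s in range(nsl):
            sl = [slice(None)] * 3
            sl[slice_axis] = s
            sl = tuple(sl)
            for b in range(n_layers):
                sel = roi[sl] & (bins[sl] == b)
                if sel.any():
                    per_slice[s, b] = zmap[sl][sel].mean()
        with np.errstate(invalid="ignore"):
            spread = np.nanstd(per_slice, axis=0)
    else:
        for b in range(n_layers):
            sel = roi & (bins == b)
            if sel.sum() > 1:
                spread[b] = float(zmap[sel].std())

    centres = (np.arange(n_layers) + 0.5) / n_layers
    return LayerProfile(depths=centres, pooled_z=pooled, spread=spread, counts=counts)
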