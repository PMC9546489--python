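"""Self-navigated k-space corrections.

Order matters and mirrors the reconstruction pipeline: (1) navigator-based
Nyquist-ghost / trajectory correction, which aligns odd and even readout
lines within each shot (and thereby the echoes of all blades), then (2) the
zero-order (k0) correction, which removes the shot-to-shot global phase that
respiration, cardiac pulsation and scanner drift impose on every sample of a
shot.  Both corrections are pure per-sample phases, so they preserve sample
magnitudes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DegenerateDataError, InvalidArgumentError
from .simulator import RawKspace, _apply_hybrid_phase


@dataclass
class GhostEstimate:
    """Per-shot odd/even phase mismatch: readout shift (samples) + constant."""

    linear_shift_samples: np.ndarray
    constant_phase_rad: np.ndarray

    def pooled(self) -> "GhostEstimate":
        """Run-median pooled estimate (one value broadcast to all shots)."""
        n = len(self.linear_shift_samples)
        return GhostEstimate(
            np.full(n, np.median(self.linear_shift_samples)),
            np.full(n, np.median(self.constant_phase_rad)),
        )


@dataclass
class K0Series:
    """Zero-order phase per shot, zero at the reference shot, wrapped to (-pi, pi]."""

    phase_rad: np.ndarray
    reference_shot: int = 0
    shot_rate_hz: Optional[float] = None
    filtered_bands: dict = field(default_factory=dict)

    def unwrapped(self) -> np.ndarray:
        """Nearest-branch continuation over shots (diagnostics only)."""
        return np.unwrap(self.phase_rad)


def _wrap(phase: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * phase))


def estimate_ghost(navigators: np.ndarray, magnitude_floor: float = 0.10) -> GhostEstimate:
    """Estimate odd/even readout phase mismatch from 3-line navigators.

    Each navigator line is inverse-transformed along the readout; the phase
    difference between the centre (odd-polarity) line and the mean of its two
    neighbours is fitted as a linear phase by magnitude-weighted regression
    restricted to samples above ``magnitude_floor`` of the peak magnitude.
    The slope is estimated robustly from the lag-1 phase increment (immune to
    wrapping), coil-combined by magnitude weighting.

    Returns shift in readout samples and constant phase, per shot.
    """
    navigators = np.asarray(navigators)
    if navigators.ndim != 4 or navigators.shape[2] < 3:
        raise InvalidArgumentError("navigators must be (shot, coil, >=3 lines, samples)")
    if not np.any(navigators):
        raise DegenerateDataError("navigators are identically zero")
    n_shots, _, _, n = navigators.shape
    hyb = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(navigators, axes=-1), axis=-1), axes=-1)
    odd = hyb[:, :, 1, :]
    even = 0.5 * (hyb[:, :, 0, :] + hyb[:, :, 2, :])
    d = odd * np.conj(even)  # phase(d) = odd/even phase difference

    mag = np.abs(d)
    floor = magnitude_floor * np.max(mag, axis=-1, keepdims=True)
    w = np.where(mag >= floor, mag, 0.0)

    shifts = np.empty(n_shots)
    consts = np.empty(n_shots)
    x = np.arange(n) - n // 2
    for s in range(n_shots):
        ds, ws = d[s], w[s]
        # slope from weighted lag-1 autocorrelation of the phase ramp
        ac = np.sum(ds[:, 1:] * np.conj(ds[:, :-1]) * np.sqrt(ws[:, 1:] * ws[:, :-1]))
        if ac == 0:
            raise DegenerateDataError(f"navigator signal vanishes for shot {s}")
        slope = np.angle(ac)  # rad per hybrid sample
        resid = ds * np.exp(-1j * slope * x)
        const = np.angle(np.sum(resid * ws))
        shifts[s] = slope * n / (2 * np.pi)
        consts[s] = const
    return GhostEstimate(linear_shift_samples=shifts, constant_phase_rad=consts)


def apply_ghost_correction(raw: RawKspace, est: GhostEstimate) -> RawKspace:
    """Split the estimated odd/even offset half-and-half between line parities.

    Odd lines receive -1/2 and even lines +1/2 of the estimated linear +
    constant phase in readout hybrid space, aligning all readout lines within
    each shot and across shots (this doubles as the radial trajectory
    correction, since all blade echoes end up on a common grid).
    """
    if not (np.all(np.isfinite(est.linear_shift_samples))
            and np.all(np.isfinite(est.constant_phase_rad))):
        raise InvalidArgumentError("ghost estimate must be finite")
    out = raw.copy()
    n = raw.n_readout
    x = np.arange(n) - n // 2
    for s in range(raw.n_shots):
        phi = est.constant_phase_rad[s] + 2 * np.pi * est.linear_shift_samples[s] * x / n
        half = np.exp(0.5j * phi)
        if np.all(phi == 0):
            continue
        _apply_hybrid_phase(out.data[s], None, half=half)
        _apply_hybrid_phase(out.navigators[s], None, half=half)
    applied = dict(out.meta.get("corrections", {}))
    applied["ghost"] = True
    out.meta["corrections"] = applied
    return out


def _center_columns(raw: RawKspace):
    """(shot, coil, pe) samples of the kz column through the k-space origin."""
    n = raw.n_readout
    cols = raw.data[:, :, :, n // 2]
    return cols


def estimate_k0(raw: RawKspace, reference_shot: int = 0) -> K0Series:
    """Shot-to-shot zero-order phase from the repeatedly sampled centre column.

    For each shot, theta = arg sum_{coils,kz} conj(ref_column) * shot_column,
    the least-squares optimal constant phase aligning the shot to the
    reference (default: first shot).  With in-plane reduction R > 1 the
    comparison is restricted to kz lines shared with the reference; shots
    sharing none are aligned to the first shot of their own CAIPI phase.
    """
    if not (0 <= reference_shot < raw.n_shots):
        raise InvalidArgumentError("reference_shot out of range")
    cols = _center_columns(raw)
    if not np.any(cols):
        raise InvalidArgumentError("centre k-space column is missing or zero")
    pe_sets = [b.pe_indices for b in raw.blades]
    r = raw.protocol.r_inplane
    ref_for_parity = {}
    for s in range(min(r, raw.n_shots)):
        ref_for_parity[s % r] = s
    ref_for_parity[reference_shot % r] = reference_shot

    theta = np.empty(raw.n_shots)
    for s in range(raw.n_shots):
        ref = reference_shot
        if not np.intersect1d(pe_sets[s], pe_sets[reference_shot]).size:
            ref = ref_for_parity[s % r]
        mask = np.isin(pe_sets[s], pe_sets[ref])
        ref_mask = np.isin(pe_sets[ref], pe_sets[s])
        inner = np.sum(np.conj(cols[ref][:, ref_mask]) * cols[s][:, mask])
        theta[s] = np.angle(inner)
    theta[reference_shot] = 0.0
    shot_rate = 1000.0 / raw.protocol.tr_shot_ms
    return K0Series(phase_rad=_wrap(theta), reference_shot=reference_shot,
                    shot_rate_hz=shot_rate)


def apply_k0_correction(raw: RawKspace, k0: K0Series) -> RawKspace:
    """Multiply every sample of shot s (data and navigators) by exp(-i theta_s)."""
    if len(k0.phase_rad) != raw.n_shots:
        raise InvalidArgumentError("one phase per shot required")
    out = raw.copy()
    phase = np.exp(-1j * k0.phase_rad)[:, None, None, None]
    out.data *= phase
    out.navigators *= phase
    applied = dict(out.meta.get("corrections", {}))
    applied["k0"] = True
    out.meta["corrections"] = applied
    return out


def correct(raw: RawKspace, ghost: bool = True, k0: bool = True,
            reference_shot: int = 0, pooled_ghost: bool = False) -> RawKspace:
    """Full Fig-2A-style correction chain: ghost first, then k0."""
    out = raw
    if ghost:
        est = estimate_ghost(out.navigators)
        if pooled_ghost:
            est = est.pooled()
        out = apply_ghost_correction(out, est)
    if k0:
        series = estimate_k0(out, reference_shot=reference_shot)
        out = apply_k0_correction(out, series)
    return out


DEFAULT_BANDS = {"respiratory": (0.0, 0.5), "cardiac": (0.6, 2.0)}


def filter_k0(k0: K0Series, shot_rate_hz: Optional[float] = None,
              bands: Optional[dict] = None) -> K0Series:
    """Zero-phase band decomposition of the k0 series (diagnostics).

    ``bands`` maps names to (low_hz, high_hz) edges; defaults separate the
    respiratory (< 0.5 Hz) and cardiac (0.6-2 Hz) contributions.  Filtering is
    done by brick-wall masking of the FFT (exactly zero-phase), and a
    ``residual`` band holds everything not claimed by a named band, so the
    named bands plus residual sum to the input exactly.
    """
    phase = np.asarray(k0.phase_rad, dtype=float)
    if phase.size < 8:
        raise InvalidArgumentError("need at least 8 shots to filter")
    fs = shot_rate_hz if shot_rate_hz is not None else k0.shot_rate_hz
    if fs is None:
        raise InvalidArgumentError("shot rate unknown; pass shot_rate_hz")
    bands = DEFAULT_BANDS if bands is None else bands
    nyq = fs / 2.0
    for name, (lo, hi) in bands.items():
        if not (0 <= lo < hi):
            raise InvalidArgumentError(f"band {name!r} edges must satisfy 0 <= lo < hi")
        if hi > nyq:
            raise InvalidArgumentError(f"band {name!r} exceeds Nyquist ({nyq:g} Hz)")

    x = np.unwrap(phase)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    claimed = np.zeros(freqs.size, dtype=bool)
    out = dict(k0.filtered_bands)
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs <= hi) & ~claimed
        claimed |= mask
        out[name] = np.fft.irfft(spec * mask, n=x.size)
    out["residual"] = np.fft.irfft(spec * ~claimed, n=x.size)
    return K0Series(phase_rad=k0.phase_rad, reference_shot=k0.reference_shot,
                    shot_rate_hz=fs, filtered_bands=out)
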