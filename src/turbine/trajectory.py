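"""TURBINE blade geometry and protocol arithmetic.

TURBINE is a hybrid radial-Cartesian 3D acquisition: each shot is an EPI
"blade" that encodes the through-plane axis (kz) Cartesian-wise while the
readout direction of the whole blade is rotated about kz from shot to shot by
the golden angle, 180/phi ~= 111.25 degrees.  Consecutive blades therefore
tile the kx-ky plane near-uniformly for *any* number of shots, which is what
gives the sequence its flexible post-hoc spatio-temporal binning.

Units: k-space coordinates are expressed in cycles/FOV, i.e. Cartesian sample
spacing is exactly 1 and the edge of k-space along the readout is at
``matrix/2``.  Grid indices are 0-based with the k-space centre at index
``matrix // 2`` (even-size convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .errors import InvalidArgumentError

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0
#: Golden-angle increment in degrees (180/phi ~= 111.246...).
GOLDEN_ANGLE_DEG = 180.0 / GOLDEN_RATIO


@dataclass
class TurbineProtocol:
    """Acquisition geometry and timing for a TURBINE protocol.

    Parameters
    ----------
    fov_mm : tuple of 3 floats
        Physical field of view (x, y, z) in millimetres.
    matrix : tuple of 3 ints
        Reconstruction grid (readout, readout, partitions).  The first two
        entries must be equal (square radial plane).
    shots_per_volume : int
        Number of blades binned into one nominal volume.
    r_inplane : int
        In-plane (phase-encode / kz) reduction factor; CAIPI-style shifting
        guarantees that any ``r_inplane`` consecutive shots jointly sample
        every partition.
    te_ms, tr_shot_ms, echo_spacing_ms : float
        Echo time, shot repetition time and EPI echo spacing in ms.
    flip_angle_deg : float
        Excitation flip angle.
    n_navigators : int
        Non-phase-encoded navigator lines acquired before each blade.
    meta : dict
        Free-form sequence metadata (RF spoiling increment, fat suppression,
        readout-onset shifts, ...) recorded but not simulated.
    """

    fov_mm: tuple = (192.0, 192.0, 16.0)
    matrix: tuple = (288, 288, 24)
    shots_per_volume: int = 40
    r_inplane: int = 1
    te_ms: float = 23.0
    tr_shot_ms: float = 58.0
    echo_spacing_ms: float = 1.22
    flip_angle_deg: float = 13.0
    n_navigators: int = 3
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = tuple(int(m) for m in self.matrix)
        self.fov_mm = tuple(float(f) for f in self.fov_mm)
        if len(self.matrix) != 3 or len(self.fov_mm) != 3:
            raise InvalidArgumentError("matrix and fov_mm must have 3 entries")
        if any(m < 1 for m in self.matrix):
            raise InvalidArgumentError("matrix entries must be >= 1")
        if self.matrix[0] != self.matrix[1]:
            raise InvalidArgumentError("radial plane must be square (matrix[0] == matrix[1])")
        if not (1 <= self.r_inplane <= self.matrix[2]):
            raise InvalidArgumentError("require 1 <= r_inplane <= matrix[2]")
        if not (self.tr_shot_ms >= self.te_ms > 0):
            raise InvalidArgumentError("require tr_shot_ms >= te_ms > 0")
        if self.shots_per_volume < 1:
            raise InvalidArgumentError("shots_per_volume must be positive")

    @property
    def n_readout(self) -> int:
        return self.matrix[0]

    @property
    def n_partitions(self) -> int:
        return self.matrix[2]

    @property
    def voxel_size_mm(self) -> tuple:
        return tuple(f / m for f, m in zip(self.fov_mm, self.matrix))

    def to_dict(self) -> dict:
        return {
            "fov_mm": list(self.fov_mm),
            "matrix": list(self.matrix),
            "shots_per_volume": self.shots_per_volume,
            "r_inplane": self.r_inplane,
            "te_ms": self.te_ms,
            "tr_shot_ms": self.tr_shot_ms,
            "echo_spacing_ms": self.echo_spacing_ms,
            "flip_angle_deg": self.flip_angle_deg,
            "n_navigators": self.n_navigators,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TurbineProtocol":
        known = {k: d[k] for k in (
            "fov_mm", "matrix", "shots_per_volume", "r_inplane", "te_ms",
            "tr_shot_ms", "echo_spacing_ms", "flip_angle_deg", "n_navigators",
        ) if k in d}
        if "fov_mm" in known:
            known["fov_mm"] = tuple(known["fov_mm"])
        if "matrix" in known:
            known["matrix"] = tuple(known["matrix"])
        return cls(**known)


def load_protocol(path_or_preset) -> TurbineProtocol:
    """Load a protocol from a YAML file path or a shipped preset name.

    Shipped presets: ``"slab_0p67"`` (0.67 mm isotropic thin slab) and
    ``"wholebrain_0p8"`` (0.8 x 0.8 x 2.0 mm anisotropic whole brain).
    """
    name = str(path_or_preset)
    if name in ("slab_0p67", "wholebrain_0p8"):
        text = resources.files("turbine").joinpath(f"presets/{name}.yaml").read_text()
    else:
        with open(name) as fh:
            text = fh.read()
    return TurbineProtocol.from_dict(yaml.safe_load(text))


@dataclass
class BladeSampling:
    """Sampling description of one TURBINE shot (blade).

    ``readout_coords`` has shape (n_pe, n_readout, 3) holding (kx, ky, kz) in
    cycles/FOV for every sample of the blade; ``navigator_coords`` has shape
    (n_navigators, n_readout, 3) with kz = 0 (non-phase-encoded lines through
    the centre column).
    """

    shot_index: int
    angle_deg: float
    pe_indices: np.ndarray
    readout_coords: np.ndarray
    navigator_coords: np.ndarray


def golden_angle_sequence(n_shots: int, wrap_180: bool = True) -> np.ndarray:
    """Blade angles (degrees) of ``n_shots`` consecutive golden-angle shots.

    angle[n] = n * 180/phi, reduced modulo 180 when ``wrap_180`` (each blade
    covers both k-space half-planes, so angles are unique modulo 180).
    """
    if n_shots < 1:
        raise InvalidArgumentError("n_shots must be >= 1")
    raw = np.arange(n_shots) * GOLDEN_ANGLE_DEG
    return np.mod(raw, 180.0) if wrap_180 else raw


def caipi_pe_pattern(n_partitions: int, r_inplane: int, shot_index: int) -> np.ndarray:
    """Partition (kz) indices sampled by a given shot under CAIPI shifting.

    Shot ``s`` samples ``{(s mod R) + m R}``; the pattern is periodic in the
    shot index with period R, and the union over any R consecutive shots is
    the full partition set.
    """
    if not (1 <= r_inplane <= n_partitions):
        raise InvalidArgumentError("require 1 <= r_inplane <= n_partitions")
    return np.arange(shot_index % r_inplane, n_partitions, r_inplane)


def blade_coordinates(protocol: TurbineProtocol, shot_index: int,
                      start_index: int = 0) -> BladeSampling:
    """k-space coordinates of one blade.

    The blade angle accumulates continuously across volumes by default
    (``start_index`` offsets the golden-angle counter, e.g. to reset per run).
    Readout samples span [-kmax, +kmax) at unit (Cartesian) spacing; kz values
    follow the CAIPI pattern; navigators are ``n_navigators`` copies of the
    kz = 0 line.
    """
    if shot_index < 0:
        raise InvalidArgumentError("shot_index must be >= 0")
    n = protocol.n_readout
    nz = protocol.n_partitions
    angle = float(np.mod((start_index + shot_index) * GOLDEN_ANGLE_DEG, 180.0))
    theta = np.deg2rad(angle)
    kr = np.arange(n) - n // 2
    kx = kr * np.cos(theta)
    ky = kr * np.sin(theta)
    pe = caipi_pe_pattern(nz, protocol.r_inplane, shot_index)
    kz = pe - nz // 2
    coords = np.empty((len(pe), n, 3))
    coords[..., 0] = kx
    coords[..., 1] = ky
    coords[..., 2] = kz[:, None]
    nav = np.empty((protocol.n_navigators, n, 3))
    nav[..., 0] = kx
    nav[..., 1] = ky
    nav[..., 2] = 0.0
    return BladeSampling(shot_index=shot_index, angle_deg=angle, pe_indices=pe,
                         readout_coords=coords, navigator_coords=nav)


def make_blades(protocol: TurbineProtocol, n_shots: int, start_index: int = 0):
    """Blade descriptions for ``n_shots`` consecutive shots."""
    return [blade_coordinates(protocol, s, start_index=start_index) for s in range(n_shots)]


def acceleration_factor(protocol: TurbineProtocol) -> float:
    """Total acceleration relative to a fully sampled radial-Cartesian k-space.

    A full radial plane needs matrix * pi/2 blades to meet Nyquist at the
    k-space edge, so

        R_total = (matrix[0] * r_inplane / shots_per_volume) * pi / 2.
    """
    return (protocol.matrix[0] * protocol.r_inplane / protocol.shots_per_volume) * np.pi / 2.0


def nominal_volume_tr(protocol: TurbineProtocol) -> float:
    """Nominal volume TR in seconds: shots_per_volume * tr_shot_ms / 1000."""
    return protocol.shots_per_volume * protocol.tr_shot_ms / 1000.0


def full_radial_shots(n: int) -> int:
    """Number of blades for full radial Nyquist sampling of an n-point plane."""
    return int(np.ceil(n * np.pi / 2.0))


@dataclass
class PsfImage:
    """Point-spread function of a sampling pattern (peak normalized to 1)."""

    grid: np.ndarray
    peak_location: tuple
    normalization: float


def radial_density_weights(kr: np.ndarray, n_blades: int) -> np.ndarray:
    """Ramp density-compensation weights for golden-angle radial sampling.

    w = |k| * (pi / n_blades): polar-quadrature area elements, so a
    density-compensated adjoint approximates the inverse Fourier transform
    over the sampled disc.  The k-space centre is crossed by *every* blade,
    so its cell (the half-radius disc, area pi/4 -- half the innermost ring's
    unit-width annulus per unit angle) is shared equally among the DC
    samples; weighting each DC sample at half the innermost ring weight would
    over-count the centre n_blades-fold.  Matches Voronoi cell areas closely.
    """
    w = np.abs(np.asarray(kr, dtype=float)) * (np.pi / n_blades)
    dc = w == 0
    n_dc = int(dc.sum())
    if n_dc:
        w[dc] = (np.pi / 4.0) / n_dc
    return w


def psf_from_coords(coords: np.ndarray, grid_size: int,
                    weights=None) -> np.ndarray:
    """Adjoint-gridded image of unit k-space samples (un-normalized PSF)."""
    from .nufft import KbGridder

    coords = np.asarray(coords, dtype=float).reshape(-1, coords.shape[-1])[:, :2]
    gridder = KbGridder(grid_size)
    plan = gridder.plan(coords)
    ones = np.ones(coords.shape[0], dtype=complex)
    if weights is not None:
        ones = ones * weights
    return plan.adjoint(ones) / grid_size**2


def sampling_psf(blades, grid_size: int, density_compensated: bool = True) -> PsfImage:
    """In-plane sampling PSF of a set of blades.

    Each blade contributes its (unique) radial readout line; coordinates are
    rescaled so the blade kmax maps to the Nyquist edge of ``grid_size``.
    """
    if not blades:
        raise InvalidArgumentError("need at least one blade")
    n0 = blades[0].readout_coords.shape[1]
    coords = np.concatenate([b.readout_coords[0, :, :2] for b in blades], axis=0)
    coords = coords * (grid_size / n0)
    w = None
    if density_compensated:
        kr = np.hypot(coords[:, 0], coords[:, 1])
        w = radial_density_weights(kr, len(blades))
    grid = psf_from_coords(coords, grid_size, weights=w)
    peak = np.unravel_index(np.argmax(np.abs(grid)), grid.shape)
    norm = float(np.abs(grid[peak]))
    return PsfImage(grid=grid / norm, peak_location=tuple(int(p) for p in peak),
                    normalization=norm)
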