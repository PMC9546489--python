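import warnings

import numpy as np
import pytest

from turbine import simulator as sim
from turbine import trajectory as tj

warnings.filterwarnings("ignore", category=RuntimeWarning, message="CG did not reach")


def small_protocol(grid=32, nz=1, shots=None, r_inplane=1, tr_shot_ms=58.0):
    if shots is None:
        shots = tj.full_radial_shots(grid)
    return tj.TurbineProtocol(fov_mm=(192.0, 192.0, 2.0 * nz), matrix=(grid, grid, nz),
                              shots_per_volume=shots, r_inplane=r_inplane,
                              te_ms=23.0, tr_shot_ms=tr_shot_ms)


def direct_nufft2(image, coords):
    """Direct-DFT oracle for the type-2 NUFFT (small grids only)."""
    n = image.shape[0]
    r = np.arange(n) - n // 2
    ex = np.exp(-2j * np.pi * np.outer(coords[:, 0], r) / n)
    ey = np.exp(-2j * np.pi * np.outer(coords[:, 1], r) / n)
    return np.einsum("mi,mj,ij->m", ex, ey, image.astype(complex))


def direct_adjoint2(samples, coords, n):
    """Direct-DFT oracle for the type-1 (adjoint) NUFFT."""
    r = np.arange(n) - n // 2
    ex = np.exp(2j * np.pi * np.outer(coords[:, 0], r) / n)
    ey = np.exp(2j * np.pi * np.outer(coords[:, 1], r) / n)
    return np.einsum("m,mi,mj->ij", samples.astype(complex), ex, ey)


def nrmse(a, b):
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)) / np.linalg.norm(b))


@pytest.fixture(scope="session")
def slab_raw():
    """Small fully sampled slab acquisition shared across tests (no artifacts)."""
    grid, nz = 32, 4
    protocol = small_protocol(grid, nz)
    phantom = sim.make_phantom((grid, grid, nz), seed=0)
    coils = sim.make_coil_sensitivities((grid, grid, nz), 4, seed=1)
    blades = tj.make_blades(protocol, 2 * protocol.shots_per_volume)
    raw = sim.simulate_acquisition(phantom, coils, blades, protocol=protocol, seed=0)
    return {"raw": raw, "phantom": phantom, "coils": coils, "protocol": protocol}


@pytest.fixture(scope="session")
def corrupted_raw():
    """Slab acquisition with ghost + physiological phase corruption."""
    grid, nz = 32, 8
    protocol = small_protocol(grid, nz, shots=40)
    phantom = sim.make_phantom((grid, grid, nz), seed=3)
    coils = sim.make_coil_sensitivities((grid, grid, nz), 4, seed=4)
    blades = tj.make_blades(protocol, 4 * protocol.shots_per_volume)
    physio = sim.PhysioPhaseModel(respiratory_amp_rad=0.3, respiratory_freq_hz=0.3,
                                  cardiac_amp_rad=0.1, drift_amp_rad=0.0, seed=5)
    ghost = sim.GhostModel(constant_phase_rad=0.3, linear_shift_samples=0.8)
    raw = sim.simulate_acquisition(phantom, coils, blades, physio=physio, ghost=ghost,
                                   protocol=protocol, seed=6)
    return {"raw": raw, "phantom": phantom, "coils": coils, "protocol": protocol,
            "ghost": ghost, "physio": physio}
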