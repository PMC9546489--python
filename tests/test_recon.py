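import numpy as np
import pytest

from turbine import recon
from turbine import simulator as sim
from turbine import trajectory as tj
from turbine.errors import DegenerateDataError, InvalidArgumentError
from turbine.nufft import KbGridder

from conftest import direct_adjoint2, nrmse, small_protocol


class TestBinShots:
    def test_frame_arithmetic(self, slab_raw):
        raw = slab_raw["raw"]
        frames = recon.bin_shots(raw, raw.protocol.shots_per_volume)
        assert len(frames) == 2
        assert all(len(f) == raw.protocol.shots_per_volume for f in frames)

    def test_single_calibration_frame(self, slab_raw):
        raw = slab_raw["raw"]
        frames = recon.bin_shots(raw, raw.n_shots)
        assert len(frames) == 1 and len(frames[0]) == raw.n_shots

    def test_partial_trailing_bin_dropped(self, slab_raw):
        raw = slab_raw["raw"]
        frames = recon.bin_shots(raw, raw.n_shots - 1)
        assert len(frames) == 1

    def test_golden_angle_frame_coverage_has_no_large_gap(self):
        """>= matrix*pi/2 consecutive golden-angle shots leave angular gaps
        below twice the uniform spacing."""
        n = 64
        count = tj.full_radial_shots(n)
        angles = np.sort(tj.golden_angle_sequence(count))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 180.0]]))
        assert gaps.max() < 2 * (180.0 / count)

    def test_invalid_binning_rejected(self, slab_raw):
        with pytest.raises(InvalidArgumentError):
            recon.bin_shots(slab_raw["raw"], 0)


class TestGridAdjoint:
    def test_delta_object_round_trip_peak(self):
        n = 32
        g = KbGridder(n)
        shots = tj.full_radial_shots(n)
        protocol = small_protocol(n, 1, shots=shots)
        coords = np.concatenate(
            [b.readout_coords[0, :, :2] for b in tj.make_blades(protocol, shots)])
        delta = np.zeros((n, n), complex)
        delta[20, 11] = 1.0
        samples = g.plan(coords).forward(delta)
        img = recon.grid_adjoint(samples, coords, n)
        assert np.unravel_index(np.argmax(np.abs(img)), img.shape) == (20, 11)

    def test_matches_direct_dft_oracle(self):
        n = 32
        shots = tj.full_radial_shots(n)
        protocol = small_protocol(n, 1, shots=shots)
        coords = np.concatenate(
            [b.readout_coords[0, :, :2] for b in tj.make_blades(protocol, shots)])
        ph = sim.make_phantom((n, n), seed=0)
        samples = KbGridder(n).plan(coords).forward(ph.proton_density.astype(complex))
        img = recon.grid_adjoint(samples, coords, n)
        kr = np.hypot(coords[:, 0], coords[:, 1])
        w = tj.radial_density_weights(kr, shots)
        ref = direct_adjoint2(w * samples, coords, n) / n**2
        assert nrmse(img, ref) < 1e-4

    def test_accuracy_comparable_to_voronoi_oracle(self):
        """Ramp DCF reconstruction error within 1.3x of Voronoi-weight DCF."""
        from scipy.spatial import Voronoi
        from shapely.geometry import Polygon

        n = 48
        shots = tj.full_radial_shots(n)
        protocol = small_protocol(n, 1, shots=shots)
        coords = np.concatenate(
            [b.readout_coords[0, :, :2] for b in tj.make_blades(protocol, shots)])
        ph = sim.make_phantom((n, n), seed=0)
        obj = ph.proton_density.astype(complex)
        plan = KbGridder(n).plan(coords)
        samples = plan.forward(obj)
        img_ramp = recon.grid_adjoint(samples, coords, n)

        uniq, inv, cnt = np.unique(np.round(coords, 9), axis=0,
                                   return_inverse=True, return_counts=True)
        ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        ring = (n / 2 + 1.5) * np.stack([np.cos(ang), np.sin(ang)], 1)
        vor = Voronoi(np.vstack([uniq, ring]))
        areas = np.zeros(len(uniq))
        for i in range(len(uniq)):
            reg = vor.regions[vor.point_region[i]]
            if -1 not in reg and reg:
                areas[i] = Polygon(vor.vertices[reg]).area
        w_vor = (areas / cnt)[inv]
        img_vor = plan.adjoint(w_vor * samples) / n**2

        assert nrmse(img_ramp, obj) < 1.3 * nrmse(img_vor, obj)

    def test_linearity_in_samples(self):
        n = 32
        rng = np.random.default_rng(0)
        coords = rng.uniform(-14, 14, size=(64, 2))
        y1 = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        y2 = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        a = recon.grid_adjoint(3.0 * y1 - y2, coords, n, density_compensate=False)
        b = (3.0 * recon.grid_adjoint(y1, coords, n, density_compensate=False)
             - recon.grid_adjoint(y2, coords, n, density_compensate=False))
        assert np.allclose(a, b)

    def test_empty_samples_rejected(self):
        with pytest.raises(InvalidArgumentError):
            recon.grid_adjoint(np.empty(0), np.empty((0, 2)), 32)


class TestSensitivities:
    def test_single_uniform_coil_gives_unit_map(self):
        calib = np.ones((1, 32, 32), complex)
        assert np.allclose(recon.estimate_sensitivities(calib), 1.0)

    def test_smooth_maps_recovered_inside_object(self):
        ph = sim.make_phantom((48, 48), seed=0)
        coils = sim.make_coil_sensitivities((48, 48), 6, seed=1)
        rng = np.random.default_rng(2)
        calib = coils * ph.proton_density + 0.003 * (
            rng.standard_normal((6, 48, 48)) + 1j * rng.standard_normal((6, 48, 48)))
        maps = recon.estimate_sensitivities(calib)
        obj = ph.proton_density > 0.3
        for c in range(1, 6):
            # reference-free comparison through relative-phase products
            a = (maps[c] * np.conj(maps[0]))[obj]
            b = (coils[c] * np.conj(coils[0]))[obj]
            corr = abs(np.vdot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b))
            assert corr > 0.99

    def test_combined_image_is_phase_aligned(self):
        ph = sim.make_phantom((48, 48), seed=0)
        coils = sim.make_coil_sensitivities((48, 48), 4, seed=3)
        calib = coils * ph.proton_density
        maps = recon.estimate_sensitivities(calib)
        combined = np.sum(np.conj(maps) * calib, axis=0)
        obj = ph.proton_density > 0.3
        assert np.all(combined[obj].real > 0)

    def test_invariant_to_global_scaling(self):
        ph = sim.make_phantom((32, 32), seed=0)
        coils = sim.make_coil_sensitivities((32, 32), 3, seed=1)
        calib = coils * ph.proton_density
        assert np.allclose(recon.estimate_sensitivities(calib),
                           recon.estimate_sensitivities(7.0 * calib))

    def test_all_zero_calibration_rejected(self):
        with pytest.raises(DegenerateDataError):
            recon.estimate_sensitivities(np.zeros((4, 16, 16), complex))


class TestCoilCompression:
    def test_keeping_all_coils_is_lossless(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((5, 100)) + 1j * rng.standard_normal((5, 100))
        _, v, energy = recon.compress_coils(data, 5, coil_axis=0)
        assert energy == pytest.approx(1.0)
        assert np.allclose(v.conj().T @ v, np.eye(5), atol=1e-10)

    def test_smooth_coils_compress_well(self):
        coils = sim.make_coil_sensitivities((32, 32), 8, seed=2)
        ph = sim.make_phantom((32, 32), seed=0)
        imgs = coils * ph.proton_density
        _, _, energy = recon.compress_coils(imgs, 4, coil_axis=0)
        assert energy > 0.95

    def test_rawkspace_compression_consistent(self, slab_raw):
        raw = slab_raw["raw"]
        out, v, energy = recon.compress_coils(raw, 2)
        assert out.data.shape[1] == 2
        assert out.navigators.shape[1] == 2
        assert 0.5 < energy <= 1.0

    def test_invalid_virtual_count_rejected(self):
        with pytest.raises(InvalidArgumentError):
            recon.compress_coils(np.zeros((4, 8), complex), 0, coil_axis=1)
        with pytest.raises(InvalidArgumentError):
            recon.compress_coils(np.zeros((8, 4), complex), 5, coil_axis=1)


class TestEncodingOperator:
    @pytest.mark.parametrize("mode", ["slab2d", "full3d"])
    def test_adjoint_identity_to_machine_precision(self, slab_raw, mode):
        raw, coils = slab_raw["raw"], slab_raw["coils"]
        frames = recon.bin_shots(raw, raw.protocol.shots_per_volume)
        rng = np.random.default_rng(0)
        if mode == "slab2d":
            op = recon.EncodingOperator(raw, coils[..., 0], frames, mode)
            for _ in range(10):
                x = rng.standard_normal((32, 32, 2)) + 1j * rng.standard_normal((32, 32, 2))
                y = [rng.standard_normal((4, p.n_samples)) + 1j * rng.standard_normal((4, p.n_samples))
                     for p in op.plans]
                lhs = sum(np.vdot(yt, ft) for yt, ft in zip(y, op.forward_slice(x)))
                rhs = np.vdot(op.adjoint_slice(y), x)
                assert abs(lhs - rhs) / abs(lhs) < 1e-6
        else:
            op = recon.EncodingOperator(raw, coils, frames, mode)
            for _ in range(10):
                x = rng.standard_normal((32, 32, 4, 2)) + 1j * rng.standard_normal((32, 32, 4, 2))
                fx = op.forward_volume(x)
                y = [[rng.standard_normal(c.shape) + 1j * rng.standard_normal(c.shape)
                      for c in frame] for frame in fx]
                lhs = sum(np.vdot(yc, fc) for yt, ft in zip(y, fx) for yc, fc in zip(yt, ft))
                rhs = np.vdot(op.adjoint_volume(y), x)
                assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_slab2d_requires_full_kz(self):
        protocol = small_protocol(32, 4, shots=8, r_inplane=2)
        ph = sim.make_phantom((32, 32, 4), seed=0)
        coils = sim.make_coil_sensitivities((32, 32, 4), 2, seed=1)
        raw = sim.simulate_acquisition(ph, coils, tj.make_blades(protocol, 8),
                                       protocol=protocol, seed=0)
        with pytest.raises(InvalidArgumentError):
            recon.EncodingOperator(raw, coils[..., 0], recon.bin_shots(raw, 8), "slab2d")


class TestReconstruct:
    def test_zero_data_gives_zero_image(self, slab_raw):
        raw = slab_raw["raw"].copy()
        raw.data[:] = 0.0
        cfg = recon.ReconConfig(lambda_t=0.0, max_iter=5)
        series = recon.reconstruct(raw, slab_raw["coils"], cfg)
        assert np.all(series.data == 0)

    def test_fully_sampled_noise_free_recovers_truth(self):
        grid = 64
        shots = tj.full_radial_shots(grid)
        protocol = small_protocol(grid, 1, shots=shots)
        ph = sim.make_phantom((grid, grid, 1), seed=0)
        coils = sim.make_coil_sensitivities((grid, grid, 1), 3, seed=1)
        raw = sim.simulate_acquisition(ph, coils, tj.make_blades(protocol, shots),
                                       protocol=protocol, seed=0)
        cfg = recon.ReconConfig(lambda_t=0.0, max_iter=40, cg_tolerance=1e-9)
        series = recon.reconstruct(raw, coils, cfg)
        assert nrmse(series.magnitude(), raw.truth.magnitude()) < 0.01

    def test_cg_residual_decreases_to_tolerance(self, slab_raw):
        cfg = recon.ReconConfig(lambda_t=10.0, max_iter=60)
        series = recon.reconstruct(slab_raw["raw"], slab_raw["coils"], cfg)
        res = np.asarray(series.meta["cg_residuals"])
        assert res[-1] < 1e-3
        assert res[-1] == np.min(res)

    def test_slab2d_and_full3d_agree_on_full_kz(self, slab_raw):
        raw, coils = slab_raw["raw"], slab_raw["coils"]
        out = {}
        for mode in ("slab2d", "full3d"):
            cfg = recon.ReconConfig(lambda_t=1.0, max_iter=30, cg_tolerance=1e-9, mode=mode)
            out[mode] = recon.reconstruct(raw, coils, cfg)
        assert nrmse(out["full3d"].data, out["slab2d"].data) < 0.01

    def test_caipi_undersampled_full3d_recovers_truth(self):
        """R=2 partition undersampling is resolved by coil encoding in 3D."""
        grid, nz = 32, 4
        shots = tj.full_radial_shots(grid)
        protocol = small_protocol(grid, nz, shots=shots, r_inplane=2)
        ph = sim.make_phantom((grid, grid, nz), seed=0)
        coils = sim.make_coil_sensitivities((grid, grid, nz), 6, seed=1)
        raw = sim.simulate_acquisition(ph, coils, tj.make_blades(protocol, shots),
                                       protocol=protocol, seed=0)
        cfg = recon.ReconConfig(lambda_t=0.0, max_iter=60, cg_tolerance=1e-9, mode="full3d")
        series = recon.reconstruct(raw, coils, cfg)
        assert nrmse(series.magnitude(), raw.truth.magnitude()) < 0.05

    def test_lambda_sweep_roughness_strictly_decreasing(self):
        from turbine.experiments import lambda_sweep_metrics

        m = lambda_sweep_metrics(seed=0, grid=32, n_coils=3, shots_per_frame=5,
                                 n_frames=8, max_iter=40)
        r = [m["roughness_lambda_1000"], m["roughness_lambda_10000"],
             m["roughness_lambda_100000"]]
        assert r[0] > r[1] > r[2]

    def test_temporal_gram_matches_explicit_differences(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 3, 6)).astype(complex)
        d = np.diff(x, axis=-1)
        explicit = np.zeros_like(x)
        explicit[..., 0] = -d[..., 0]
        explicit[..., -1] = d[..., -1]
        explicit[..., 1:-1] = d[..., :-1] - d[..., 1:]
        assert np.allclose(recon.temporal_diff_gram(x), explicit)

    def test_activation_time_course_recovered_under_regularization(self):
        """Simulated block task survives temporally regularized recon."""
        grid = 32
        spf = 8
        n_vols = 24
        protocol = small_protocol(grid, 1, shots=spf, tr_shot_ms=58.0)
        ph = sim.make_phantom((grid, grid, 1), seed=0)
        coils = sim.make_coil_sensitivities((grid, grid, 1), 4, seed=1)
        tr_vol = tj.nominal_volume_tr(protocol)
        task = sim.make_task_timeseries(n_vols, tr_vol, block_s=3.0, effect_fraction=0.05)
        raw = sim.simulate_acquisition(ph, coils, tj.make_blades(protocol, n_vols * spf),
                                       task=task, noise_sd=0.002, protocol=protocol, seed=2)
        cfg = recon.ReconConfig(lambda_t=1e4, max_iter=40, shots_per_frame=spf)
        series = recon.reconstruct(raw, coils, cfg)
        tc = series.magnitude()[ph.activation_mask].mean(axis=0)
        boxcar = task - task.mean()
        r = np.corrcoef(tc, boxcar)[0, 1]
        assert r > 0.5
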