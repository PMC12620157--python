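import numpy as np
import pytest
from fractions import Fraction
from scipy.ndimage import binary_erosion

from slabkq.dae_prior import DAEModel
from slabkq.fourier import cfftn
from slabkq.phantom import (
    ShotPhaseSet,
    build_phantom,
    simulate_acquisition,
    simulate_coils,
    simulate_shot_phases,
)
from slabkq.protocol import SamplingConfig, build_protocol, generate_caipi_masks
from slabkq.recon import (
    DWVolumeSet,
    ReconConfig,
    cg_sense_navigator,
    cg_solve,
    combine_slabs,
    estimate_navigator_phases,
    qmodel_reconstruct,
    sense_adjoint,
    sense_forward,
    tv_norm,
    tv_prox,
)

SHAPE = (32, 33, 6)


@pytest.fixture(scope="module")
def phantom():
    return build_phantom(SHAPE, seed=0)


@pytest.fixture(scope="module")
def undersampled(protocol_tiny):
    cfg = SamplingConfig(Ry=3, Rz=Fraction(3), seed=1)
    return generate_caipi_masks(protocol_tiny, cfg)


@pytest.fixture(scope="module")
def phases(protocol_tiny, undersampled):
    return simulate_shot_phases(protocol_tiny, undersampled, (32, 33),
                                severity=0.5, seed=2)


class TestSenseOperators:
    def test_adjointness(self, phantom, protocol_tiny, undersampled, phases,
                         rng):
        n_vol = protocol_tiny.n_volumes
        x = (rng.standard_normal((n_vol,) + SHAPE)
             + 1j * rng.standard_normal((n_vol,) + SHAPE))
        y = (rng.standard_normal((n_vol, 8) + SHAPE)
             + 1j * rng.standard_normal((n_vol, 8) + SHAPE))
        Ax = sense_forward(x, phantom.coil_sens, phases.phase_maps,
                           undersampled)
        Ahy = sense_adjoint(y, phantom.coil_sens, phases.phase_maps,
                            undersampled)
        err = abs(np.vdot(y, Ax) - np.vdot(Ahy, x))
        assert err / (np.linalg.norm(x) * np.linalg.norm(y)) < 1e-10

    def test_forward_is_masked_fft(self, protocol_tiny, undersampled, rng):
        x = (rng.standard_normal((protocol_tiny.n_volumes,) + SHAPE)
             + 1j * rng.standard_normal((protocol_tiny.n_volumes,) + SHAPE))
        coils = np.ones((1,) + SHAPE, dtype=complex)
        zero_ph = np.zeros((protocol_tiny.n_volumes, 2, 32, 33))
        Y = sense_forward(x, coils, zero_ph, undersampled)
        for q, m in enumerate(undersampled):
            ref = np.where(m.grid[None], cfftn(x[q], axes=(1, 2)), 0.0)
            assert np.allclose(Y[q, 0], ref)

    def test_sample_count(self, phantom, protocol_tiny, undersampled,
                          phases, rng):
        x = rng.standard_normal((protocol_tiny.n_volumes,) + SHAPE) + 0j
        Y = sense_forward(x, phantom.coil_sens, phases.phase_maps,
                          undersampled)
        expected = sum(int(m.grid.sum()) for m in undersampled) \
            * phantom.coil_sens.shape[0] * SHAPE[0]
        assert int(np.count_nonzero(Y)) == expected

    def test_roundtrip_full_mask(self, protocol_tiny, rng):
        cfg = SamplingConfig(Ry=1, Rz=Fraction(1), seed=0)
        masks = generate_caipi_masks(protocol_tiny, cfg)
        coils = np.ones((1,) + SHAPE, dtype=complex)
        zero_ph = np.zeros((protocol_tiny.n_volumes, SHAPE[2], 32, 33))
        x = (rng.standard_normal((protocol_tiny.n_volumes,) + SHAPE)
             + 1j * rng.standard_normal((protocol_tiny.n_volumes,) + SHAPE))
        back = sense_adjoint(sense_forward(x, coils, zero_ph, masks),
                             coils, zero_ph, masks)
        assert np.allclose(back, x, atol=1e-12)

    def test_zero_input(self, phantom, protocol_tiny, undersampled, phases):
        y = np.zeros((protocol_tiny.n_volumes, 8) + SHAPE, dtype=complex)
        out = sense_adjoint(y, phantom.coil_sens, phases.phase_maps,
                            undersampled)
        assert not out.any()


class TestCgSolve:
    def test_solves_spd_system(self, rng):
        A = rng.standard_normal((20, 20))
        A = A @ A.T + 20 * np.eye(20)
        b = rng.standard_normal(20)
        x, info = cg_solve(lambda v: A @ v, b, tol=1e-12, max_iters=100)
        assert np.allclose(A @ x, b, atol=1e-8)

    def test_objective_monotone(self, rng):
        A = rng.standard_normal((40, 40))
        A = A @ A.T + np.eye(40)
        b = rng.standard_normal(40)
        _, info = cg_solve(lambda v: A @ v, b, tol=1e-14, max_iters=40)
        obj = info["objective"]
        assert all(b <= a + 1e-10 for a, b in zip(obj, obj[1:]))


class TestQModelReconstruct:
    def test_noiseless_fully_sampled_exact(self, protocol_tiny):
        ph = build_phantom(SHAPE, seed=0)
        cfg = SamplingConfig(Ry=1, Rz=Fraction(1), seed=0)
        masks = generate_caipi_masks(protocol_tiny, cfg)
        kdata, _ = simulate_acquisition(ph, protocol_tiny, masks,
                                        snr=np.inf, seed=0)
        out = qmodel_reconstruct(kdata, ph.coil_sens, None, None,
                                 ReconConfig())
        gt = ph.signal_volumes(protocol_tiny)
        nrmse = np.linalg.norm(np.abs(out.data) - gt) / np.linalg.norm(gt)
        assert nrmse < 1e-6

    def test_data_consistency_at_convergence(self, protocol_tiny):
        ph = build_phantom(SHAPE, seed=0)
        cfg = SamplingConfig(Ry=1, Rz=Fraction(1), seed=0)
        masks = generate_caipi_masks(protocol_tiny, cfg)
        kdata, _ = simulate_acquisition(ph, protocol_tiny, masks,
                                        snr=np.inf, seed=0)
        rc = ReconConfig(cg_tol=1e-8, cg_max_iters=60)
        out = qmodel_reconstruct(kdata, ph.coil_sens, None, None, rc)
        zero_ph = np.zeros((protocol_tiny.n_volumes, SHAPE[2], 32, 33))
        resid = sense_forward(out.data, ph.coil_sens, zero_ph, masks) \
            - kdata.data
        assert (np.linalg.norm(resid) / np.linalg.norm(kdata.data)
                < rc.cg_tol * 10)

    def test_missing_dae_rejected(self, protocol_tiny, phantom,
                                  undersampled):
        kdata, _ = simulate_acquisition(phantom, protocol_tiny, undersampled,
                                        snr=np.inf, seed=0)
        with pytest.raises(ValueError):
            qmodel_reconstruct(kdata, phantom.coil_sens, None, None,
                               ReconConfig(lambda2=0.5))

    def test_toy_dense_solve_equivalence(self, rng):
        """On an 8x8x4, 2-coil, 3-volume toy the CG reconstruction matches
        the dense normal-equations solution to 1e-8."""
        shape = (8, 8, 4)
        proto = build_protocol([1000.0], 3, Ny=8, FOVz=4.0)
        cfg = SamplingConfig(Ry=2, Rz=Fraction(2), seed=0)
        masks = generate_caipi_masks(proto, cfg)
        coils = simulate_coils(2, shape, seed=1)
        ph_maps = rng.standard_normal((3, 2, 8, 8)) * 0.4
        n = 3 * np.prod(shape)
        basis = np.eye(n)
        cols = []
        for j in range(n):
            e = basis[j].reshape(3, *shape).astype(complex)
            cols.append(sense_forward(e, coils, ph_maps, masks).ravel())
        A = np.stack(cols, axis=1)
        x_true = (rng.standard_normal((3,) + shape)
                  + 1j * rng.standard_normal((3,) + shape))
        y = sense_forward(x_true, coils, ph_maps, masks)
        x_dense, *_ = np.linalg.lstsq(A, y.ravel(), rcond=None)

        from slabkq.phantom import KSpaceData
        kdata = KSpaceData(data=y, masks=masks, noise_sigma=0.0)
        out = qmodel_reconstruct(
            kdata, coils, ph_maps, None,
            ReconConfig(cg_tol=1e-12, cg_max_iters=400))
        err = np.linalg.norm(out.data.ravel() - x_dense) \
            / np.linalg.norm(x_dense)
        assert err < 1e-8

    def test_frozen_denoiser_objective_monotone(self, rng):
        """With the denoiser output held fixed, the full objective is
        non-increasing across outer iterations."""
        shape = (8, 8, 4)
        proto = build_protocol([1000.0], 3, Ny=8, FOVz=4.0)
        cfg = SamplingConfig(Ry=2, Rz=Fraction(2), seed=0)
        masks = generate_caipi_masks(proto, cfg)
        coils = simulate_coils(2, shape, seed=1)
        zero_ph = np.zeros((3, 2, 8, 8))
        x_true = np.abs(rng.standard_normal((3,) + shape)) + 0j
        y = sense_forward(x_true, coils, zero_ph, masks)
        # constant-output net: no hidden layers, zero weight, fixed bias
        z_vec = np.full(3, 0.3)
        frozen = DAEModel(weights=[np.zeros((3, 3)), z_vec],
                          shell_weights=np.ones(3))
        from slabkq.phantom import KSpaceData
        kdata = KSpaceData(data=y, masks=masks, noise_sigma=0.0)
        lam2 = 0.4
        objs = []
        for outer in (1, 2, 3, 4):
            rc = ReconConfig(lambda2=lam2, outer_iters=outer,
                             cg_max_iters=6)
            out = qmodel_reconstruct(kdata, coils, zero_ph, frozen, rc)
            S = out.data
            Z = np.broadcast_to(z_vec[:, None, None, None], S.shape)
            f = (np.linalg.norm(sense_forward(S, coils, zero_ph, masks)
                                - y) ** 2
                 + lam2 * np.linalg.norm(S - Z) ** 2)
            objs.append(f)
        assert all(b <= a + 1e-8 for a, b in zip(objs, objs[1:]))


class TestTvProx:
    def test_zero_weight_identity(self, rng):
        S = rng.standard_normal((2, 8, 8, 4)) + 0j
        assert np.array_equal(tv_prox(S, 0.0), S)

    def test_constant_unchanged(self):
        S = np.full((1, 8, 8, 4), 2.5, dtype=complex)
        out = tv_prox(S, 0.5, inner_iters=20)
        assert np.allclose(np.abs(out), 2.5, atol=1e-10)

    def test_tv_decreases(self, rng):
        S = np.abs(rng.standard_normal((1, 12, 12, 4))) + 0j
        out = tv_prox(S, 0.3, inner_iters=20)
        assert tv_norm(np.abs(out[0])) <= tv_norm(np.abs(S[0]))

    def test_phase_preserved(self, rng):
        mag = np.abs(rng.standard_normal((1, 8, 8, 4)))
        ph = rng.uniform(-np.pi, np.pi, (1, 8, 8, 4))
        S = mag * np.exp(1j * ph)
        out = tv_prox(S, 0.2, inner_iters=10)
        moved = np.abs(out) > 1e-12
        assert np.allclose(np.angle(out)[moved], ph[moved], atol=1e-10)


class TestCombineSlabs:
    def test_single_slab_identity(self, rng):
        vol = rng.standard_normal((2, 6, 6, 8))
        prof = np.ones(8)
        out = combine_slabs([vol], [prof], [0])
        assert np.allclose(out, vol)

    def test_two_abutting_rectangular(self, rng):
        a = rng.standard_normal((1, 4, 4, 5))
        b = rng.standard_normal((1, 4, 4, 5))
        out = combine_slabs([a, b], [np.ones(5), np.ones(5)], [0, 5])
        assert np.allclose(out, np.concatenate([a, b], axis=-1))

    def test_overlap_constant_no_banding(self):
        nz = 10
        ramp_down = np.concatenate([np.ones(6), 0.5 * (1 + np.cos(
            np.pi * (np.arange(4) + 1) / 5))])
        ramp_up = ramp_down[::-1]
        const = np.ones((1, 4, 4, nz))
        out = combine_slabs([const, const],
                            [ramp_down, ramp_up], [0, 6], nz_total=16)
        assert np.abs(out - 1.0).max() < 1e-10

    def test_gap_rejected(self, rng):
        a = rng.standard_normal((1, 4, 4, 4))
        with pytest.raises(ValueError):
            combine_slabs([a, a], [np.ones(4), np.ones(4)], [0, 6],
                          nz_total=10)


@pytest.fixture(scope="module")
def nav_setup():
    proto = build_protocol([1000.0], 4, Ny=33, FOVz=6.0)
    cfg = SamplingConfig(Ry=3, Rz=Fraction(3), seed=3)
    masks = generate_caipi_masks(proto, cfg)
    ph = build_phantom(SHAPE, seed=0)
    phases = simulate_shot_phases(proto, masks, (32, 33), 0.5, seed=6)
    fg = binary_erosion(ph.foreground[:, :, SHAPE[2] // 2], iterations=2)
    return proto, masks, ph, phases, fg


class TestNavigatorPhases:
    @staticmethod
    def _rmse(est, phases, fg):
        errs = []
        for q in range(phases.phase_maps.shape[0]):
            for s in range(phases.phase_maps.shape[1]):
                d = np.exp(1j * (est[q, s] - phases.phase_maps[q, s]))
                d = d * np.exp(-1j * np.angle(d[fg].mean()))
                errs.append(np.sqrt(np.mean(np.angle(d)[fg] ** 2)))
        return float(np.mean(errs))

    def test_fully_sampled_single_coil(self, nav_setup):
        proto, masks, ph, phases, fg = nav_setup
        ph1 = build_phantom(SHAPE, seed=0)
        ph1.coil_sens = simulate_coils(1, SHAPE, seed=0)
        _, nav = simulate_acquisition(ph1, proto, masks, phases,
                                      snr=np.inf, seed=0, ry_nav=1)
        est = estimate_navigator_phases(nav, (32, 33))
        assert self._rmse(est, phases, fg) < 0.02

    def test_zero_phase_estimated_near_zero(self, nav_setup):
        proto, masks, ph, phases, fg = nav_setup
        ph1 = build_phantom(SHAPE, seed=0)
        ph1.coil_sens = simulate_coils(1, SHAPE, seed=0)
        zeros = ShotPhaseSet(np.zeros_like(phases.phase_maps), 0.0)
        _, nav = simulate_acquisition(ph1, proto, masks, zeros,
                                      snr=np.inf, seed=0, ry_nav=1)
        est = estimate_navigator_phases(nav, (32, 33))
        assert np.abs(est[:, :, fg]).max() < 0.02

    def test_undersampled_multicoil_noisy(self, nav_setup):
        proto, masks, ph, phases, fg = nav_setup
        _, nav = simulate_acquisition(ph, proto, masks, phases,
                                      snr=20.0, seed=1, ry_nav=3)
        est = estimate_navigator_phases(nav, (32, 33), smooth_sigma=2.0)
        assert self._rmse(est, phases, fg) < 0.1

    def test_lowres_phase_maps_shape(self, nav_setup):
        proto, masks, ph, phases, fg = nav_setup
        _, nav = simulate_acquisition(ph, proto, masks, phases,
                                      snr=np.inf, seed=0)
        lowres = cg_sense_navigator(nav)
        assert lowres.shape == (proto.n_volumes,
                                phases.phase_maps.shape[1], 32, 32)
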