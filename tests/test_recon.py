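"""Model-based reconstruction tests: operators, prox, solver, recovery."""

import dataclasses

import numpy as np
import pytest

from t1shot import ReconConfig, Unknowns, get_protocol
from t1shot.recon import (SliceModel, _Vec, fista_solve, forward_model,
                          joint_l1_prox, project_domain, sobolev_kernel,
                          sobolev_unweight, sobolev_weight)
from conftest import make_single_compartment_kdata


def _tiny_model(n_spokes=24, n=16, binned=6, n_coils=2,
                dtype="complex128"):
    kdata, seq, _ = make_single_compartment_kdata(
        n=n, n_spokes=n_spokes, binned=binned, n_coils=n_coils)
    return SliceModel(kdata, 0, ReconConfig(dtype=dtype)), kdata, seq


def _random_state(model, rng, positive_r1=True):
    p = rng.normal(size=(3, model.n, model.n)) \
        + 1j * rng.normal(size=(3, model.n, model.n))
    p[2] = np.abs(p[2].real) if positive_r1 else p[2].real
    c = rng.normal(size=(model.n_coils, model.n, model.n)) \
        + 1j * rng.normal(size=(model.n_coils, model.n, model.n))
    return _Vec(p.astype(model.dtype), c.astype(model.dtype))


class TestConfig:
    def test_alpha_schedule_with_floor(self):
        cfg = ReconConfig(alpha0=1.0, alpha_min=0.0015, n_gn_steps=10)
        sched = cfg.alpha_schedule()
        expect = [1.0, 1 / 3, 1 / 9, 1 / 27, 1 / 81, 1 / 243]
        assert np.allclose(sched[:6], expect)
        # 1/3^6 ~ 1.37e-3 already sits below alpha_min = 1.5e-3
        assert np.allclose(sched[6:], 0.0015)

    def test_beta_has_no_floor(self):
        cfg = ReconConfig(n_gn_steps=10)
        assert cfg.beta_schedule()[-1] == pytest.approx(1 / 3**9)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig(alpha0=0.001, alpha_min=0.0015)
        with pytest.raises(ValueError):
            ReconConfig(reduction=0.9)
        with pytest.raises(ValueError):
            ReconConfig(n_gn_steps=0)

    def test_yaml_round_trip(self):
        cfg = ReconConfig(alpha_min=0.001, n_fista_max=77)
        assert ReconConfig.from_yaml(cfg.to_yaml()) == cfg


class TestSobolev:
    def test_dc_unweighted_and_monotone(self):
        w = sobolev_kernel(32, 220.0, 32.0)
        assert w[16, 16] == 1.0
        center = w[16, 16:]
        assert np.all(np.diff(center) > 0)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=(3, 32, 32)) + 1j * rng.normal(size=(3, 32, 32))
        back = sobolev_unweight(sobolev_weight(c, 220.0, 32.0), 220.0, 32.0)
        assert np.allclose(back, c, rtol=1e-12, atol=1e-12)


class TestJointL1Prox:
    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(3, 32, 32)) + 1j * rng.normal(size=(3, 32, 32))
        assert np.allclose(joint_l1_prox(p, 0.0), p, atol=1e-10)

    def test_group_shrinkage_matches_numeric_minimizer(self):
        """Single wavelet coefficient triple: prox equals the argmin of
        0.5 ||z - w||^2 + tau ||z||_2 found by direct optimization."""
        import pywt
        from scipy.optimize import minimize

        rng = np.random.default_rng(2)
        n, tau = 16, 0.35
        coeffs = pywt.wavedec2(np.zeros((3, n, n), dtype=complex), "db4",
                               mode="periodization", level=2, axes=(-2, -1))
        w_triple = rng.normal(size=3) + 1j * rng.normal(size=3)
        coeffs[1][0][:, 1, 1] = w_triple       # one detail coefficient
        params = pywt.waverec2(coeffs, "db4", mode="periodization",
                               axes=(-2, -1))
        out = joint_l1_prox(params, tau, wavelet="db4", levels=2)
        out_c = pywt.wavedec2(out, "db4", mode="periodization", level=2,
                              axes=(-2, -1))
        got = out_c[1][0][:, 1, 1]

        def objective(v):
            z = v[:3] + 1j * v[3:]
            return (0.5 * np.sum(np.abs(z - w_triple) ** 2)
                    + tau * np.linalg.norm(z))
        v0 = np.concatenate([w_triple.real, w_triple.imag])
        ref = minimize(objective, v0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000}).x
        assert np.allclose(got, ref[:3] + 1j * ref[3:], atol=1e-5)

    def test_support_never_grows(self):
        import pywt

        rng = np.random.default_rng(3)
        n = 32
        coeffs = pywt.wavedec2(np.zeros((3, n, n)), "db4",
                               mode="periodization", level=3, axes=(-2, -1))
        # sparse input: a few nonzero detail coefficients
        coeffs[2][1][:, 2, 3] = rng.normal(size=3)
        coeffs[3][0][:, 5, 1] = rng.normal(size=3)
        params = pywt.waverec2(coeffs, "db4", mode="periodization",
                               axes=(-2, -1))
        out_c = pywt.wavedec2(joint_l1_prox(params, 0.05, levels=3), "db4",
                              mode="periodization", level=3, axes=(-2, -1))
        in_c = pywt.wavedec2(params, "db4", mode="periodization", level=3,
                             axes=(-2, -1))
        for d_in, d_out in zip(in_c[1:], out_c[1:]):
            for b_in, b_out in zip(d_in, d_out):
                zero = np.abs(b_in) < 1e-12
                assert np.all(np.abs(b_out[zero]) < 1e-8)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            joint_l1_prox(np.zeros((3, 16, 16)), -1.0)


class TestProjectDomain:
    def test_behavior(self):
        p = np.zeros((3, 4, 4), dtype=complex)
        p[2] = -0.1
        out = project_domain(p)
        assert np.all(out[2].real == 0.0)
        p[2] = 0.7
        assert np.allclose(project_domain(p), p)
        once = project_domain(p)
        assert np.array_equal(project_domain(once), once)


class TestForwardModel:
    def test_zero_rate_pins_signal_at_inversion(self):
        """With R1* = 0 nothing recovers: every bin image equals -M0."""
        model, kdata, seq = _tiny_model()
        rng = np.random.default_rng(4)
        x = _random_state(model, rng)
        x.p[2] = 0.0
        pred = model.forward(x)
        x2 = x.copy()
        x2.p[0] = 7.7 - 1.3j        # Mss is irrelevant at R1* = 0
        assert np.allclose(model.forward(x2), pred, atol=1e-10)

    def test_homogeneous_in_linear_parameters(self):
        model, kdata, seq = _tiny_model()
        rng = np.random.default_rng(5)
        x = _random_state(model, rng)
        x2 = x.copy()
        x2.p[0] *= 2.0
        x2.p[1] *= 2.0
        assert np.allclose(model.forward(x2), 2.0 * model.forward(x),
                           rtol=1e-10, atol=1e-12)

    def test_matches_per_spoke_pixelwise_simulation(self):
        """Bin-discretized forward at truth equals a per-spoke pixelwise
        simulation when every bin holds one spoke."""
        from t1shot import coil_profiles, rasterize_truth
        from t1shot.encoding import GriddingOperator, GridSpec
        from t1shot.phantom import make_t1_phantom
        from t1shot.signal_model import relaxation_signal, RelaxationTriple

        seq = dataclasses.replace(get_protocol("head1", 1 / 12),
                                  binned_spokes=1, spokes_per_slice=30)
        ph = make_t1_phantom()
        coils = coil_profiles(n_coils=2)
        from t1shot import build_schedule, analytic_kspace
        sched = build_schedule(seq)
        kdata = analytic_kspace(ph, coils, sched, seq)
        n = seq.base_resolution
        truth = rasterize_truth(ph, n, seq)
        cimg = coils.evaluate(n)
        x = Unknowns(mss=truth.mss, m0=truth.m0,
                     r1_star=np.nan_to_num(truth.r1_star_per_ms) * 1000.0,
                     coils=cimg)
        pred = forward_model(x, kdata, 0)          # (bins=spokes, C, samp)

        spec = GridSpec(n)
        for s in (0, 13, 29):
            t = kdata.times_ms[0, s] + seq.te_ms
            img = (truth.mss - (truth.mss + truth.m0)
                   * np.exp(-t * np.nan_to_num(truth.r1_star_per_ms)))
            op = GriddingOperator(kdata.traj[0, s], spec)
            ref = op.forward(img[None] * cimg)
            assert np.linalg.norm(pred[s] - ref) / np.linalg.norm(ref) < 1e-3


class TestJacobian:
    def test_adjoint_dot_product(self):
        model, *_ = _tiny_model()
        rng = np.random.default_rng(6)
        x = _random_state(model, rng)
        model.linearize(x)
        dx = _random_state(model, rng, positive_r1=False)
        dy = (rng.normal(size=model.y.shape)
              + 1j * rng.normal(size=model.y.shape)).astype(model.dtype)
        lhs = np.vdot(dy, model.jacobian_apply(dx)).real
        rhs = model.jacobian_adjoint(dy).dot(dx)
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_taylor_remainder_second_order(self):
        model, *_ = _tiny_model()
        rng = np.random.default_rng(7)
        x = _random_state(model, rng)
        dx = _random_state(model, rng, positive_r1=False)
        model.linearize(x)
        jdx = model.jacobian_apply(dx)
        f0 = model.forward(x)
        ratios = []
        for eps in (1e-3, 1e-4, 1e-5):
            xe = _Vec(x.p + eps * dx.p, x.c + eps * dx.c)
            err = np.linalg.norm(model.forward(xe) - f0 - eps * jdx)
            ratios.append(err / eps**2)
        ratios = np.asarray(ratios)
        assert np.all(np.abs(ratios / ratios[0] - 1.0) < 0.05)

    def test_zero_perturbation_maps_to_zero(self):
        model, *_ = _tiny_model()
        rng = np.random.default_rng(8)
        x = _random_state(model, rng)
        model.linearize(x)
        dz = _Vec.zeros_like(x)
        assert np.all(model.jacobian_apply(dz) == 0)


class TestFista:
    def test_quadratic_subproblem_matches_lsqr_oracle(self):
        """With L2 penalties the subproblem is linear least squares; FISTA
        must agree with an independent augmented-system solver."""
        from scipy.sparse.linalg import LinearOperator, lsqr

        model, *_ = _tiny_model(n_spokes=8, n=8, binned=4, n_coils=2)
        rng = np.random.default_rng(9)
        x = _random_state(model, rng)
        model.linearize(x)
        residual = (rng.normal(size=model.y.shape)
                    + 1j * rng.normal(size=model.y.shape))
        alpha, beta = 0.3, 0.5

        npix = model.n * model.n
        n_p, n_c = 3 * npix, model.n_coils * npix
        ndim = 2 * n_p + 2 * n_c
        m_data = 2 * model.y.size

        def unpack(v):
            p = (v[:n_p] + 1j * v[n_p:2 * n_p]).reshape(3, model.n, model.n)
            c = (v[2 * n_p:2 * n_p + n_c] + 1j * v[2 * n_p + n_c:]
                 ).reshape(model.n_coils, model.n, model.n)
            return _Vec(p.astype(model.dtype), c.astype(model.dtype))

        def pack(vec):
            return np.concatenate([vec.p.real.ravel(), vec.p.imag.ravel(),
                                   vec.c.real.ravel(), vec.c.imag.ravel()])

        def pack_y(yc):
            return np.concatenate([yc.real.ravel(), yc.imag.ravel()])

        def matvec(v):
            vec = unpack(v)
            jd = model.jacobian_apply(vec)
            return np.concatenate([
                pack_y(jd),
                np.sqrt(alpha) * np.concatenate([vec.p.real.ravel(),
                                                 vec.p.imag.ravel()]),
                np.sqrt(beta) * np.concatenate([vec.c.real.ravel(),
                                                vec.c.imag.ravel()]),
            ])

        def rmatvec(u):
            uy = (u[:model.y.size].reshape(model.y.shape)
                  + 1j * u[model.y.size:m_data].reshape(model.y.shape))
            g = model.jacobian_adjoint(uy.astype(model.dtype))
            extra = unpack(u[m_data:])
            g.p = g.p + np.sqrt(alpha) * extra.p
            g.c = g.c + np.sqrt(beta) * extra.c
            return pack(g)
        rhs = np.concatenate([
            pack_y(residual),
            -np.sqrt(alpha) * np.concatenate([x.p.real.ravel(),
                                              x.p.imag.ravel()]),
            -np.sqrt(beta) * np.concatenate([x.c.real.ravel(),
                                             x.c.imag.ravel()]),
        ])
        op = LinearOperator((m_data + ndim, ndim), matvec=matvec,
                            rmatvec=rmatvec)
        sol = lsqr(op, rhs, atol=1e-12, btol=1e-12, iter_lim=4000)[0]
        d_ref = unpack(sol)

        lam_p, lam_c, *_ = model.block_norms(40)
        cfg = ReconConfig(dtype="complex128", fista_tol=0.0,
                          n_fista_max=4000)
        d, _ = fista_solve(model, residual.astype(model.dtype), x, alpha,
                           beta, (lam_p, lam_c), cfg, n_iter=4000,
                           l2_params=True)
        num = (d - d_ref).norm()
        den = d_ref.norm()
        assert num / den < 1e-4

    def test_zero_residual_shrinks_toward_regularizer(self):
        model, *_ = _tiny_model(n_spokes=8, n=8, binned=4, n_coils=2)
        rng = np.random.default_rng(10)
        x = _random_state(model, rng)
        model.linearize(x)
        lam = model.block_norms(20)[:2]
        cfg = ReconConfig(dtype="complex128")
        d, _ = fista_solve(model, np.zeros_like(model.y), x, 1e-6, 10.0,
                           lam, cfg, n_iter=200)
        # heavy coil penalty with no data mismatch pulls coils toward -x_c
        assert (x.c + d.c).__abs__().mean() < 0.25 * np.abs(x.c).mean()


class TestIrgnm:
    def test_single_compartment_noiseless_recovery(self):
        """Uniform 800 ms disk, densely sampled: T1 within 1% everywhere."""
        from t1shot import InversionRecoveryModel
        from t1shot.postprocess import compute_t1_map

        kdata, seq, ph = make_single_compartment_kdata(
            n=32, t1_ms=800.0, n_spokes=220, n_coils=4, binned=8)
        cfg = ReconConfig(n_fista_start=25, n_fista_max=150, power_iters=8)
        fit = InversionRecoveryModel(kdata, cfg).fit()
        t1map = compute_t1_map(fit.unknowns[0], seq)
        from t1shot import rasterize_truth
        truth = rasterize_truth(ph, 32, seq)
        roi = truth.roi_masks["background"]     # sole compartment
        vals = t1map.values_ms[roi & t1map.mask]
        assert np.median(np.abs(vals - 800.0)) / 800.0 < 0.01
        assert np.abs(np.mean(vals) - 800.0) / 800.0 < 0.01

    def test_scaling_equivariance(self):
        """Scaling the data scales Mss, M0 and leaves R1* unchanged."""
        from t1shot.recon import irgnm

        kdata, seq, ph = make_single_compartment_kdata(
            n=16, t1_ms=600.0, n_spokes=48, n_coils=2, binned=4)
        cfg = ReconConfig(n_gn_steps=5, n_fista_start=20, n_fista_max=60,
                          power_iters=6)
        u1, _ = irgnm(kdata, cfg)
        u3, _ = irgnm(kdata.with_y(3.0 * kdata.y), cfg)
        mask = np.abs(u1[0].m0) > 0.3 * np.abs(u1[0].m0).max()
        ratio = (u3[0].m0[mask] / u1[0].m0[mask]).real
        assert np.median(ratio) == pytest.approx(3.0, rel=1e-3)
        r1a, r1b = u1[0].r1_star[mask], u3[0].r1_star[mask]
        assert np.allclose(r1a, r1b, rtol=5e-3, atol=5e-3)

    def test_residual_decreases_over_gn_steps(self):
        from t1shot import InversionRecoveryModel

        kdata, seq, _ = make_single_compartment_kdata(
            n=16, t1_ms=500.0, n_spokes=48, n_coils=2, binned=4)
        cfg = ReconConfig(n_gn_steps=6, n_fista_start=20, n_fista_max=60,
                          power_iters=6)
        fit = InversionRecoveryModel(kdata, cfg).fit()
        res = [d["residual"] for d in fit.diagnostics[0]]
        assert np.all(np.diff(res) < 0)
        assert "alpha" in fit.summary() or "GN" in fit.summary() \
            or len(fit.summary()) > 0
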