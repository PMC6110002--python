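"""Model-based T1 reconstruction: joint estimation of parameter and coil maps.

The forward model maps the unknowns ``x = (x_p, x_c)`` — parameter maps
``x_p = (Mss, M0, R1*)`` and coil sensitivities ``x_c = (c_1..c_N)`` — to
binned radial k-space:

    y_{k,j} = A_k F ( M_{t_k} . c_j ),
    M_{t_k} = Mss - (Mss + M0) exp(-t_k R1*),

with ``A_k`` the gridding interpolation at bin k's spoke positions.  The
regularized nonlinear problem

    min_{x in D} ||F(x) - y||^2 + alpha R(x_p) + beta Q(x_c),
    D = { R1* >= 0 },

(R a joint wavelet-L1 penalty, Q a Sobolev norm) is solved by the
iteratively regularized Gauss-Newton method: each linearization is solved
by FISTA, and alpha, beta shrink by a fixed factor per outer step with a
floor on alpha only.

Coil unknowns are kept in Sobolev-preconditioned form (k-space multiplied
by ``(1 + s |k|^2)^{l/2}``) so a plain L2 penalty on the stored variable
equals the Sobolev penalty on the sensitivity.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
import scipy.fft as sfft
import yaml

from .containers import KSpaceData
from .encoding import GridSpec, GriddingOperator, compress_coils
from .sequences import SequenceParams

__all__ = [
    "ReconConfig", "Unknowns", "ReconDiverged",
    "sobolev_weight", "sobolev_unweight", "joint_l1_prox", "project_domain",
    "forward_model", "jacobian_apply", "jacobian_adjoint",
    "fista_solve", "irgnm",
    "InversionRecoveryModel", "T1FitResults",
]


class ReconDiverged(RuntimeError):
    """Raised when the Gauss-Newton residual grows over consecutive steps."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class ReconConfig:
    """Settings of the model-based reconstruction.

    ``alpha0``/``beta0`` start at 1 and shrink by ``reduction`` per
    Gauss-Newton step; ``alpha`` is floored at ``alpha_min`` (0.0015 for
    head protocols, 0.001 for abdomen), ``beta`` has no floor.
    ``r1_scale`` rescales the internal R1* unknown (in 1/s) so the three
    Jacobian blocks have comparable norms.
    """

    alpha0: float = 1.0
    beta0: float = 1.0
    reduction: float = 3.0
    alpha_min: float = 0.0015
    n_gn_steps: int = 10
    n_fista_start: int = 22
    n_fista_max: int = 110
    fista_tol: float = 5e-5
    sobolev_s: float = 220.0
    sobolev_l: float = 32.0
    wavelet: str = "db4"
    wavelet_levels: int = 4
    r1_scale: float = 1.0
    oversampling: float = 2.0
    kernel_width: int = 4
    n_virtual_coils: int = 8
    data_norm: float = 100.0
    power_iters: int = 10
    init_mss: float = 1.0
    init_m0: float = 1.0
    init_r1s: float = 1.5          # 1/s
    dtype: str = "complex64"

    def __post_init__(self) -> None:
        if not self.alpha0 > self.alpha_min >= 0:
            raise ValueError("need alpha0 > alpha_min >= 0")
        if self.reduction <= 1:
            raise ValueError("reduction factor must exceed 1")
        if self.n_gn_steps < 1:
            raise ValueError("n_gn_steps must be >= 1")

    def alpha_schedule(self) -> np.ndarray:
        n = np.arange(self.n_gn_steps)
        return np.maximum(self.alpha0 / self.reduction**n, self.alpha_min)

    def fista_schedule(self) -> np.ndarray:
        """Inner-iteration budget per Gauss-Newton step (doubling ramp).

        Early linearizations are crude, so few inner iterations suffice;
        late steps (small alpha) need an accurately solved subproblem.
        """
        n = np.arange(self.n_gn_steps)
        return np.minimum(self.n_fista_start * 2 ** (n // 2),
                          self.n_fista_max).astype(int)

    def beta_schedule(self) -> np.ndarray:
        n = np.arange(self.n_gn_steps)
        return self.beta0 / self.reduction**n

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ReconConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class Unknowns:
    """Estimated maps of one slice: parameters plus coil sensitivities."""

    mss: np.ndarray        # complex (N, N)
    m0: np.ndarray         # complex (N, N)
    r1_star: np.ndarray    # real (N, N), 1/s
    coils: np.ndarray      # complex (C, N, N), image space

    @property
    def grid(self) -> int:
        return self.mss.shape[-1]


# ---------------------------------------------------------------------------
# centered orthonormal FFT helpers
def _fft_c(x):
    return sfft.fftshift(
        sfft.fft2(sfft.ifftshift(x, axes=(-2, -1)), axes=(-2, -1),
                  norm="ortho"), axes=(-2, -1))


def _ifft_c(x):
    return sfft.fftshift(
        sfft.ifft2(sfft.ifftshift(x, axes=(-2, -1)), axes=(-2, -1),
                   norm="ortho"), axes=(-2, -1))


def sobolev_kernel(n: int, s: float, l: float) -> np.ndarray:
    """k-space weights (1 + s |k|^2)^(l/2) on the centered N x N grid."""
    k = (np.arange(n) - n // 2) / n
    kx, ky = np.meshgrid(k, k, indexing="ij")
    return (1.0 + s * (kx**2 + ky**2)) ** (l / 2.0)


def sobolev_weight(coils: np.ndarray, s: float, l: float) -> np.ndarray:
    """Image-space coils -> Sobolev-weighted k-space representation."""
    w = sobolev_kernel(coils.shape[-1], s, l)
    return w * _fft_c(coils)


def sobolev_unweight(ck: np.ndarray, s: float, l: float) -> np.ndarray:
    """Inverse of :func:`sobolev_weight`."""
    w = sobolev_kernel(ck.shape[-1], s, l)
    return _ifft_c(ck / w)


def project_domain(params: np.ndarray) -> np.ndarray:
    """Clip the R1* map (row 2) at zero; idempotent."""
    out = params.copy()
    out[2] = np.maximum(out[2].real, 0.0)
    return out


def joint_l1_prox(params: np.ndarray, threshold: float,
                  wavelet: str = "db4", levels: int = 4) -> np.ndarray:
    """Proximal map of the joint (group) wavelet-L1 penalty.

    The three parameter maps are wavelet transformed together and each
    coefficient triple is soft-thresholded on its joint l2 magnitude, so
    the maps share wavelet-domain support.  The coarsest approximation
    band is left untouched (it carries the mean signal level, not edges).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if threshold == 0:
        return params.copy()
    # periodization keeps the transform orthogonal at any depth; cap the
    # level by the grid size only (pywt warns about boundary effects)
    levels = min(levels, int(math.log2(min(params.shape[-2:]))) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(params, wavelet, mode="periodization",
                               level=levels, axes=(-2, -1))
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        shrunk = []
        for band in detail:
            mag = np.sqrt(np.sum(np.abs(band) ** 2, axis=0, keepdims=True))
            factor = np.maximum(1.0 - threshold / np.maximum(mag, 1e-30), 0.0)
            shrunk.append(band * factor)
        out.append(tuple(shrunk))
    return pywt.waverec2(out, wavelet, mode="periodization", axes=(-2, -1))


# ---------------------------------------------------------------------------
@dataclass
class _Vec:
    """Stacked unknown vector: parameter maps + weighted coil k-space."""

    p: np.ndarray   # (3, N, N) complex; row 2 kept real-valued
    c: np.ndarray   # (C, N, N) complex

    def copy(self):
        return _Vec(self.p.copy(), self.c.copy())

    def __add__(self, other):
        return _Vec(self.p + other.p, self.c + other.c)

    def __sub__(self, other):
        return _Vec(self.p - other.p, self.c - other.c)

    def __mul__(self, a: float):
        return _Vec(self.p * a, self.c * a)

    __rmul__ = __mul__

    def dot(self, other) -> float:
        return float(np.vdot(self.p, other.p).real
                     + np.vdot(self.c, other.c).real)

    def norm(self) -> float:
        return math.sqrt(self.dot(self))

    @classmethod
    def zeros_like(cls, other):
        return cls(np.zeros_like(other.p), np.zeros_like(other.c))


class SliceModel:
    """Forward model, Jacobian and adjoint for one slice of binned data."""

    def __init__(self, kdata: KSpaceData, axis_index: int,
                 config: ReconConfig):
        seq = kdata.seq
        self.seq = seq
        self.config = config
        self.n = seq.base_resolution
        self.dtype = np.dtype(config.dtype)
        m = seq.binned_spokes
        n_bins = kdata.n_spokes // m
        if n_bins < 1:
            raise ValueError("fewer spokes than one bin")
        keep = n_bins * m
        nsamp = kdata.n_samples

        traj = kdata.traj[axis_index, :keep].reshape(n_bins, m, nsamp, 2)
        times = kdata.times_ms[axis_index, :keep].reshape(n_bins, m)
        self.t_bins_s = (times.mean(axis=1) + seq.te_ms) / 1000.0
        spec = GridSpec(base_resolution=self.n,
                        oversampling=config.oversampling,
                        kernel_width=config.kernel_width)
        # one gridding plan per bin: small per-bin arrays stay cache-resident
        self.plans = [
            GriddingOperator(traj[k].reshape(-1, 2), spec, dtype=self.dtype)
            for k in range(n_bins)
        ]
        y = kdata.y[axis_index, :keep].reshape(n_bins, m * nsamp, -1)
        self.y = np.ascontiguousarray(
            np.transpose(y, (0, 2, 1))).astype(self.dtype)  # (K, C, M)
        self.n_bins = n_bins
        self.n_coils = self.y.shape[1]
        self.data_scale = 1.0
        self._sob = sobolev_kernel(self.n, config.sobolev_s, config.sobolev_l)
        self._lin = None

    # -- data scaling -------------------------------------------------------
    def scale_data(self) -> float:
        nrm = float(np.linalg.norm(self.y))
        self.data_scale = self.config.data_norm / max(nrm, 1e-30)
        self.y = self.y * self.dtype.type(self.data_scale)
        return self.data_scale

    # -- state helpers ------------------------------------------------------
    def initial_state(self) -> _Vec:
        cfg = self.config
        p = np.zeros((3, self.n, self.n), dtype=self.dtype)
        p[0] = cfg.init_mss
        p[1] = cfg.init_m0
        p[2] = cfg.init_r1s / cfg.r1_scale
        c = np.zeros((self.n_coils, self.n, self.n), dtype=self.dtype)
        return _Vec(p, c)

    def coils_image(self, ck: np.ndarray) -> np.ndarray:
        return _ifft_c(ck / self._sob).astype(self.dtype)

    def _bin_images(self, x: _Vec):
        """E_k and M_k stacks for the current parameter maps."""
        r1s = x.p[2].real * self.config.r1_scale
        e = np.exp(-self.t_bins_s[:, None, None] * r1s[None])
        m = x.p[0][None] - (x.p[0] + x.p[1])[None] * e
        return e.astype(np.float32 if self.dtype == np.complex64 else float), \
            m.astype(self.dtype)

    # -- nonlinear forward --------------------------------------------------
    def forward(self, x: _Vec) -> np.ndarray:
        """Predicted samples, shape (n_bins, n_coils, samples_per_bin)."""
        c = self.coils_image(x.c)
        _, m_k = self._bin_images(x)
        out = np.empty_like(self.y)
        for k in range(self.n_bins):
            out[k] = self.plans[k].forward(m_k[k][None] * c)
        return out

    # -- linearization ------------------------------------------------------
    def linearize(self, x: _Vec) -> None:
        e_k, m_k = self._bin_images(x)
        w_k = (self.config.r1_scale * self.t_bins_s[:, None, None]
               * (x.p[0] + x.p[1])[None] * e_k).astype(self.dtype)
        self._lin = {
            "e": e_k, "m": m_k, "w": w_k,
            "c": self.coils_image(x.c),
        }

    def jacobian_apply(self, dx: _Vec) -> np.ndarray:
        lin = self._lin
        e, w, c, m = lin["e"], lin["w"], lin["c"], lin["m"]
        dc = self.coils_image(dx.c)
        dp2 = dx.p[2].real
        dm = (dx.p[0][None] * (1.0 - e) - dx.p[1][None] * e
              + w * dp2[None])
        out = np.empty_like(self.y)
        for k in range(self.n_bins):
            out[k] = self.plans[k].forward(dm[k][None] * c + m[k][None] * dc)
        return out

    def jacobian_adjoint(self, dy: np.ndarray) -> _Vec:
        lin = self._lin
        e, w, c, m = lin["e"], lin["w"], lin["c"], lin["m"]
        cbar = np.conj(c)
        gp = np.zeros((3, self.n, self.n), dtype=self.dtype)
        gc_img = np.zeros_like(c)
        for k in range(self.n_bins):
            z = self.plans[k].adjoint(dy[k])          # (C, N, N)
            zc = np.einsum("cij,cij->ij", cbar, z)    # coil-combined
            gp[0] += (1.0 - e[k]) * zc
            gp[1] -= e[k] * zc
            gp[2] += (np.conj(w[k]) * zc).real
            gc_img += np.conj(m[k]) * z
        gp[2] = gp[2].real
        gck = _fft_c(gc_img) / self._sob
        return _Vec(gp, gck.astype(self.dtype))

    def normal_norm(self, n_iter: int, v0: _Vec | None = None,
                    seed: int = 0):
        """Largest eigenvalue of J'J by power iteration (warm-startable)."""
        if v0 is None:
            v0 = self._random_vec(seed)
        v = v0
        lam = 0.0
        for _ in range(n_iter):
            u = self.jacobian_adjoint(self.jacobian_apply(v))
            lam = u.norm()
            if lam == 0:
                return 0.0, v
            v = u * (1.0 / lam)
        return lam, v

    def _random_vec(self, seed: int = 0, param_only: bool = False,
                    coil_only: bool = False) -> _Vec:
        rng = np.random.default_rng(seed)
        p = np.zeros((3, self.n, self.n), dtype=self.dtype)
        c = np.zeros((self.n_coils, self.n, self.n), dtype=self.dtype)
        if not coil_only:
            p = (rng.normal(size=p.shape)
                 + 1j * rng.normal(size=p.shape)).astype(self.dtype)
            p[2] = p[2].real
        if not param_only:
            c = (rng.normal(size=c.shape)
                 + 1j * rng.normal(size=c.shape)).astype(self.dtype)
        return _Vec(p, c)

    def block_norms(self, n_iter: int, vp: _Vec | None = None,
                    vc: _Vec | None = None):
        """Per-block largest eigenvalues of J'J (parameter / coil block).

        The linearized normal operator is majorized by twice its block
        diagonal, so separate step sizes per block are a valid FISTA
        metric while respecting each block's very different curvature.
        """
        if vp is None:
            vp = self._random_vec(1, param_only=True)
        if vc is None:
            vc = self._random_vec(2, coil_only=True)
        lam_p = lam_c = 0.0
        for _ in range(n_iter):
            u = self.jacobian_adjoint(self.jacobian_apply(vp))
            u.c[:] = 0
            lam_p = u.norm()
            if lam_p > 0:
                vp = u * (1.0 / lam_p)
            u = self.jacobian_adjoint(self.jacobian_apply(vc))
            u.p[:] = 0
            lam_c = u.norm()
            if lam_c > 0:
                vc = u * (1.0 / lam_c)
        return lam_p, lam_c, vp, vc


# ---------------------------------------------------------------------------
def fista_solve(model: SliceModel, residual: np.ndarray, x: _Vec,
                alpha: float, beta: float, lip: tuple,
                config: ReconConfig, n_iter: int | None = None,
                l2_params: bool = False):
    """Solve one linearized Gauss-Newton subproblem with FISTA.

    Minimizes over the update ``d``

        1/2 ||J d - r||^2 + beta/2 ||x_c + d_c||^2 + alpha R(x_p + d_p)
        + indicator(R1* >= 0),

    where R is the joint wavelet-L1 penalty (or, with ``l2_params=True``,
    alpha/2 times a plain L2 norm on ``x_p + d_p``, which makes the whole
    problem quadratic — used for verification against a dense solver).

    ``lip`` holds the per-block largest eigenvalues ``(lam_p, lam_c)`` of
    J'J; steps use the block-diagonal majorizer 2 diag(lam_p, lam_c).
    Nesterov momentum with gradient-based adaptive restart; early stop on
    the relative step size.

    Returns ``(d, info)`` with the iteration count and last relative step.
    """
    lam_p, lam_c = lip
    update_params = lam_p > 1e-9 * max(lam_c, 1.0)
    step_p = 1.0 / (2.05 * lam_p + alpha * l2_params) if update_params else 0.0
    step_c = 1.0 / (2.05 * lam_c + beta + 1e-30)
    if n_iter is None:
        n_iter = config.n_fista_max
    d = _Vec.zeros_like(x)
    z = d.copy()
    t_mom = 1.0
    n_used, rel = 0, np.inf
    for it in range(n_iter):
        jz = model.jacobian_apply(z)
        g = model.jacobian_adjoint(jz - residual)
        g.c += beta * (x.c + z.c)
        if not update_params:
            new_p = x.p + z.p
        elif l2_params:
            # fully quadratic variant (verification against a dense solver)
            g.p += alpha * (x.p + z.p)
            new_p = x.p + z.p - step_p * g.p
        else:
            new_p = joint_l1_prox(x.p + z.p - step_p * g.p, alpha * step_p,
                                  config.wavelet, config.wavelet_levels)
            new_p = project_domain(new_p)
        d_new = _Vec(new_p - x.p, z.c - step_c * g.c)
        # gradient-based adaptive restart (O'Donoghue & Candes)
        if (z - d_new).dot(d_new - d) > 0:
            t_mom = 1.0
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_mom**2))
        z = d_new + ((t_mom - 1.0) / t_new) * (d_new - d)
        rel = (d_new - d).norm() / max(d_new.norm(), 1e-30)
        d, t_mom = d_new, t_new
        n_used = it + 1
        if not np.isfinite(rel):
            raise ReconDiverged("nonfinite FISTA iterate")
        if rel < config.fista_tol:
            break
    return d, {"n_fista": n_used, "last_rel_step": float(rel)}


def _run_slice(model: SliceModel, verbose: bool = False):
    cfg = model.config
    model.scale_data()
    x = model.initial_state()
    alphas, betas = cfg.alpha_schedule(), cfg.beta_schedule()
    budgets = cfg.fista_schedule()
    diagnostics = []
    vp = vc = None
    n_increase = 0
    prev_res = np.inf
    for step_idx in range(cfg.n_gn_steps):
        alpha, beta = float(alphas[step_idx]), float(betas[step_idx])
        residual = model.y - model.forward(x)
        res_norm = float(np.linalg.norm(residual))
        if res_norm > prev_res * (1.0 + 1e-6):
            n_increase += 1
            if n_increase >= 3:
                raise ReconDiverged(
                    "residual increased over 3 consecutive Gauss-Newton steps",
                    diagnostics)
        else:
            n_increase = 0
        prev_res = res_norm
        model.linearize(x)
        # warm-started power iterations: accurate early, cheap refresh later
        n_pow = cfg.power_iters if step_idx < 2 else max(cfg.power_iters // 3, 2)
        lam_p, lam_c, vp, vc = model.block_norms(n_pow, vp, vc)
        d, info = fista_solve(model, residual, x, alpha, beta,
                              (lam_p, lam_c), cfg,
                              n_iter=int(budgets[step_idx]))
        x = x + d
        x.p = project_domain(x.p)
        diagnostics.append({
            "step": step_idx + 1, "alpha": alpha, "beta": beta,
            "residual": res_norm, "lambda_p": float(lam_p),
            "lambda_c": float(lam_c), **info,
        })
        if verbose:
            print(f"  GN {step_idx + 1:2d}: residual {res_norm:10.4f} "
                  f"alpha {alpha:.5f} fista {info['n_fista']}")
    return x, diagnostics


def _to_unknowns(model: SliceModel, x: _Vec) -> Unknowns:
    """Convert the internal state to physical-scale maps.

    The internal solve normalizes the data norm; dividing the linear maps
    by that factor restores scaling equivariance (data scaled by c gives
    Mss, M0 scaled by c; R1* is scale-free).
    """
    cfg = model.config
    undo = 1.0 / model.data_scale
    return Unknowns(
        mss=np.asarray(x.p[0], dtype=np.complex128) * undo,
        m0=np.asarray(x.p[1], dtype=np.complex128) * undo,
        r1_star=np.asarray(x.p[2].real, dtype=float) * cfg.r1_scale,
        coils=np.asarray(model.coils_image(x.c), dtype=np.complex128),
    )


def forward_model(x: Unknowns, kdata: KSpaceData, axis_index: int = 0,
                  config: ReconConfig | None = None) -> np.ndarray:
    """Nonlinear forward model at explicit unknowns (bin-discretized).

    Convenience wrapper used in tests and diagnostics; returns samples of
    shape (n_bins, n_coils, binned samples) on the *unscaled* data level.
    """
    cfg = config or ReconConfig(dtype="complex128")
    model = SliceModel(kdata, axis_index, cfg)
    vec = _Vec(
        np.stack([x.mss, x.m0, x.r1_star / cfg.r1_scale]).astype(model.dtype),
        sobolev_weight(x.coils, cfg.sobolev_s, cfg.sobolev_l).astype(model.dtype),
    )
    return model.forward(vec)


def jacobian_apply(x: Unknowns, dx: Unknowns, kdata: KSpaceData,
                   axis_index: int = 0,
                   config: ReconConfig | None = None) -> np.ndarray:
    """Directional derivative of :func:`forward_model` (functional API)."""
    cfg = config or ReconConfig(dtype="complex128")
    model = SliceModel(kdata, axis_index, cfg)
    model.linearize(_Vec(
        np.stack([x.mss, x.m0, x.r1_star / cfg.r1_scale]).astype(model.dtype),
        sobolev_weight(x.coils, cfg.sobolev_s, cfg.sobolev_l).astype(model.dtype),
    ))
    return model.jacobian_apply(_Vec(
        np.stack([dx.mss, dx.m0, dx.r1_star / cfg.r1_scale]).astype(model.dtype),
        sobolev_weight(dx.coils, cfg.sobolev_s, cfg.sobolev_l).astype(model.dtype),
    ))


def jacobian_adjoint(x: Unknowns, dy: np.ndarray, kdata: KSpaceData,
                     axis_index: int = 0,
                     config: ReconConfig | None = None) -> Unknowns:
    """Adjoint of :func:`jacobian_apply` under the same parametrization."""
    cfg = config or ReconConfig(dtype="complex128")
    model = SliceModel(kdata, axis_index, cfg)
    model.linearize(_Vec(
        np.stack([x.mss, x.m0, x.r1_star / cfg.r1_scale]).astype(model.dtype),
        sobolev_weight(x.coils, cfg.sobolev_s, cfg.sobolev_l).astype(model.dtype),
    ))
    g = model.jacobian_adjoint(np.asarray(dy, dtype=model.dtype))
    return Unknowns(
        mss=np.asarray(g.p[0], dtype=np.complex128),
        m0=np.asarray(g.p[1], dtype=np.complex128),
        r1_star=np.asarray(g.p[2].real, dtype=float) / cfg.r1_scale,
        coils=np.asarray(sobolev_unweight(g.c, cfg.sobolev_s, cfg.sobolev_l),
                         dtype=np.complex128),
    )


def irgnm(kdata: KSpaceData, config: ReconConfig | None = None,
          slices: tuple | None = None, verbose: bool = False):
    """Reconstruct parameter and coil maps per stored slice.

    Returns ``(unknowns, diagnostics)``: dicts keyed by protocol slice
    index.  Slices are independent — the interleave couples only timing.
    """
    cfg = config or ReconConfig()
    if slices is None:
        slices = kdata.slices
    if kdata.n_coils > cfg.n_virtual_coils:
        kdata, _ = compress_coils(kdata, cfg.n_virtual_coils)
    unknowns, diags = {}, {}
    for s in slices:
        ai = kdata.slice_index(s)
        model = SliceModel(kdata, ai, cfg)
        if verbose:
            print(f"slice {s}: {model.n_bins} bins, "
                  f"{model.n_coils} coils, grid {model.n}")
        x, d = _run_slice(model, verbose=verbose)
        unknowns[s] = _to_unknowns(model, x)
        diags[s] = d
    return unknowns, diags


# ---------------------------------------------------------------------------
class InversionRecoveryModel:
    """Model-based T1 mapping bound to one k-space data set.

    Examples
    --------
    >>> model = InversionRecoveryModel(kdata)          # doctest: +SKIP
    >>> res = model.fit(slices=(0,))                   # doctest: +SKIP
    >>> print(res.summary())                           # doctest: +SKIP
    """

    def __init__(self, data: KSpaceData, config: ReconConfig | None = None):
        self.data = data
        self.config = config or ReconConfig()

    @classmethod
    def from_file(cls, path, config: ReconConfig | None = None):
        return cls(KSpaceData.load(path), config)

    def fit(self, slices: tuple | None = None,
            verbose: bool = False) -> "T1FitResults":
        unknowns, diags = irgnm(self.data, self.config, slices, verbose)
        return T1FitResults(model=self, unknowns=unknowns,
                            diagnostics=diags)


@dataclass
class T1FitResults:
    """Estimates, diagnostics and derived maps of a fitted reconstruction."""

    model: InversionRecoveryModel
    unknowns: dict
    diagnostics: dict
    _t1_cache: dict = field(default_factory=dict, repr=False)

    @property
    def seq(self) -> SequenceParams:
        return self.model.data.seq

    @property
    def slices(self) -> tuple:
        return tuple(sorted(self.unknowns))

    def t1_map(self, slice_index: int | None = None):
        """T1 map (ms) of one slice; see :func:`t1shot.postprocess.compute_t1_map`."""
        from .postprocess import compute_t1_map

        s = self.slices[0] if slice_index is None else slice_index
        if s not in self._t1_cache:
            self._t1_cache[s] = compute_t1_map(self.unknowns[s], self.seq)
        return self._t1_cache[s]

    def roi_stats(self, rois: dict, slice_index: int | None = None):
        from .postprocess import roi_stats

        return roi_stats(self.t1_map(slice_index), rois)

    def summary(self) -> str:
        lines = [
            "Model-based Look-Locker T1 reconstruction",
            "=" * 57,
            f"protocol: {self.seq.n_slices} slice(s), TR {self.seq.tr_ms} ms, "
            f"flip {self.seq.flip_deg} deg, matrix {self.seq.base_resolution}",
            f"spokes/slice {self.seq.spokes_per_slice}, "
            f"binned {self.seq.binned_spokes} "
            f"(bin {self.seq.bin_duration_ms:.1f} ms)",
            "",
            f"{'slice':>5} {'GN steps':>8} {'final residual':>15} "
            f"{'final alpha':>12}",
        ]
        for s in self.slices:
            d = self.diagnostics[s]
            lines.append(f"{s:>5} {len(d):>8} {d[-1]['residual']:>15.4f} "
                         f"{d[-1]['alpha']:>12.5f}")
        return "\n".join(lines)
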