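"""Analytical T1 phantom: inverse-crime-free k-space simulation.

The phantom is a set of ellipse compartments (a large background disk plus
three circular inserts with distinct T1).  Its radial k-space is evaluated
in closed form from the Fourier transform of an ellipse, with the
Look-Locker signal evolution applied per compartment at the *exact*
per-spoke time, and coil sensitivities expressed as a short sum of complex
plane waves so that coil modulation is a set of analytic frequency shifts.
Simulated data therefore never pass through the reconstruction's discrete
gridding, and the reconstruction's temporal binning is honestly stressed.

Coordinates: image positions in FOV fractions (the FOV is [-0.5, 0.5)^2),
k-space sample positions in 1/pixel units in [-0.5, 0.5); the analytic
transform is evaluated at k_cycles = base_resolution * k_pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import j1

from .containers import KSpaceData
from .sequences import SequenceParams
from .signal_model import t1_from_parameters, triple_for_t1
from .trajectory import SpokeSchedule

__all__ = [
    "Ellipse",
    "PhantomDef",
    "CoilModel",
    "TruthMaps",
    "make_t1_phantom",
    "perturb_phantom",
    "coil_profiles",
    "analytic_kspace",
    "add_noise",
    "rasterize_truth",
]


@dataclass(frozen=True)
class Ellipse:
    """One elliptical region; lengths are FOV fractions."""

    cx: float
    cy: float
    a: float          # semi-axis along the (rotated) x direction
    b: float
    rot_deg: float
    amplitude: complex
    t1_ms: float

    def contains(self, x, y):
        phi = math.radians(self.rot_deg)
        dx, dy = x - self.cx, y - self.cy
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0

    def fourier(self, kx, ky):
        """Closed-form transform A pi a b jinc at k in cycles/FOV."""
        phi = math.radians(self.rot_deg)
        ku = kx * math.cos(phi) + ky * math.sin(phi)
        kv = -kx * math.sin(phi) + ky * math.cos(phi)
        rho = 2.0 * np.pi * np.hypot(self.a * ku, self.b * kv)
        jinc = np.where(rho > 1e-12, 2.0 * j1(np.maximum(rho, 1e-12)) / np.maximum(rho, 1e-12), 1.0)
        phase = np.exp(-2j * np.pi * (kx * self.cx + ky * self.cy))
        return self.amplitude * math.pi * self.a * self.b * jinc * phase


@dataclass(frozen=True)
class PhantomDef:
    """Ordered compartments; the first is the background, later ones override.

    ``compartments`` carry the *semantic* regions (each pixel belongs to the
    last compartment covering it).  For simulation the override semantics
    are realized additively: each insert contributes its own ellipse plus a
    negative copy of the background restricted to the same ellipse, so the
    superposed k-space is exact while every pixel follows a single T1.
    """

    compartments: tuple

    def __post_init__(self) -> None:
        for e in self.compartments:
            if abs(e.cx) + max(e.a, e.b) > 0.5 or abs(e.cy) + max(e.a, e.b) > 0.5:
                raise ValueError("ellipse extends beyond the FOV")

    def simulation_terms(self) -> list[Ellipse]:
        """Additive ellipse terms realizing the override semantics."""
        bg = self.compartments[0]
        terms = [bg]
        for ins in self.compartments[1:]:
            terms.append(ins)
            terms.append(replace(ins, amplitude=-bg.amplitude, t1_ms=bg.t1_ms))
        return terms

    @property
    def t1_values(self) -> tuple:
        return tuple(e.t1_ms for e in self.compartments)


def make_t1_phantom(
    t1_background_ms: float = 2000.0,
    t1_inserts_ms: tuple = (300.0, 800.0, 1500.0),
    background_radius: float = 0.40,
    insert_radius: float = 0.09,
    insert_distance: float = 0.20,
    amplitude: complex = 1.0 + 0.0j,
) -> PhantomDef:
    """Default four-compartment T1 phantom.

    A background disk (T1 2000 ms by default) with three circular inserts
    (300 / 800 / 1500 ms) placed at equal angles around the center.
    """
    comps = [Ellipse(0.0, 0.0, background_radius, background_radius, 0.0,
                     amplitude, t1_background_ms)]
    angles = np.deg2rad([90.0, 210.0, 330.0])[: len(t1_inserts_ms)]
    for t1, th in zip(t1_inserts_ms, angles):
        comps.append(Ellipse(insert_distance * math.cos(th),
                             insert_distance * math.sin(th),
                             insert_radius, insert_radius, 0.0,
                             amplitude, t1))
    return PhantomDef(compartments=tuple(comps))


def perturb_phantom(ph: PhantomDef, shift: float, seed: int) -> PhantomDef:
    """Jitter insert positions by up to ``shift`` (FOV fractions).

    Used to give each slice of a multislice simulation its own in-plane
    geometry; the background ellipse is left in place.
    """
    rng = np.random.default_rng(seed)
    comps = [ph.compartments[0]]
    for e in ph.compartments[1:]:
        dx, dy = rng.uniform(-shift, shift, size=2)
        comps.append(replace(e, cx=e.cx + dx, cy=e.cy + dy))
    return PhantomDef(compartments=tuple(comps))


@dataclass(frozen=True)
class CoilModel:
    """Coil sensitivities as short sums of complex plane waves.

    ``profile_j(r) = sum_t weights[j, t] * exp(2i pi freqs[t] . r)`` with r
    in FOV fractions and frequencies in cycles/FOV (not necessarily
    integer).  Modulating an ellipse by such a profile shifts its analytic
    transform by ``freqs[t]``.
    """

    freqs: np.ndarray     # (n_terms, 2)
    weights: np.ndarray   # (n_coils, n_terms) complex

    @property
    def n_coils(self) -> int:
        return self.weights.shape[0]

    def evaluate(self, grid: int) -> np.ndarray:
        """Profiles on a grid of pixel centers, shape (n_coils, N, N)."""
        r = (np.arange(grid) - grid // 2) / grid
        x, y = np.meshgrid(r, r, indexing="ij")
        basis = np.exp(2j * np.pi * (self.freqs[:, 0, None, None] * x
                                     + self.freqs[:, 1, None, None] * y))
        return np.tensordot(self.weights, basis, axes=(1, 0))


def _loop_profile(x, y, cx, cy, softening):
    """Smooth surface-coil falloff h^2 / (h^2 + |r - r_c|^2)."""
    return softening**2 / (softening**2 + (x - cx) ** 2 + (y - cy) ** 2)


def coil_profiles(
    n_coils: int = 4,
    n_terms: int = 9,
    distance: float = 0.6,
    softening: float = 0.6,
    freq_spacing: float = 1.0 / 3.0,
    fit_grid: int = 64,
) -> CoilModel:
    """Circular coil array around the phantom, plane-wave approximated.

    Coils sit at equal angles at ``distance`` (FOV fractions) from the
    center, i.e. outside the FOV circle.  Each inverse-distance loop
    profile is least-squares fitted over the FOV by ``n_terms`` plane waves
    on a low-frequency lattice with spacing ``freq_spacing`` cycles/FOV.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    m = 0
    while (2 * m + 1) ** 2 < n_terms:
        m += 1
    lattice = np.array([(fx, fy)
                        for fx in range(-m, m + 1)
                        for fy in range(-m, m + 1)], dtype=float)
    lattice = lattice[np.argsort(np.hypot(lattice[:, 0], lattice[:, 1]),
                                 kind="stable")][:n_terms]
    freqs = lattice * freq_spacing

    r = (np.arange(fit_grid) - fit_grid // 2) / fit_grid
    x, y = np.meshgrid(r, r, indexing="ij")
    basis = np.stack(
        [np.exp(2j * np.pi * (fx * x + fy * y)).ravel() for fx, fy in freqs],
        axis=1,
    )
    weights = np.empty((n_coils, n_terms), dtype=complex)
    for j in range(n_coils):
        th = 2.0 * np.pi * j / n_coils
        prof = _loop_profile(x, y, distance * math.cos(th),
                             distance * math.sin(th), softening)
        # constant per-coil phase: coils share no common reference
        prof = prof.astype(complex) * np.exp(1j * 2.0 * np.pi * j / max(n_coils, 2) * 0.3)
        w, *_ = np.linalg.lstsq(basis, prof.ravel(), rcond=None)
        weights[j] = w
    return CoilModel(freqs=freqs, weights=weights)


def analytic_kspace(
    ph: PhantomDef,
    coils: CoilModel,
    sched: SpokeSchedule,
    seq: SequenceParams,
    slices: tuple | None = None,
    normalize: bool = True,
) -> KSpaceData:
    """Closed-form multi-coil radial k-space of the relaxing phantom.

    Every sample is evaluated at the exact echo time of its spoke
    (pulse time + TE); no gridding, rasterization or binning enters.  With
    ``normalize=True`` data are scaled so that the root-sum-of-squares DC
    magnitude of the coil array at steady state equals ``base_resolution``
    (the documented reference scale for the noise standard deviation).
    """
    if sched.seq is not seq and sched.seq != seq:
        raise ValueError("schedule was built for a different protocol")
    if slices is None:
        slices = tuple(range(seq.n_slices))
    n = seq.base_resolution
    nsamp = seq.readout_samples
    terms = ph.simulation_terms()
    triples = [triple_for_t1(e.t1_ms, seq, m0=e.amplitude) for e in terms]

    # normalization from the steady-state DC response of the coil array
    dc = np.zeros(coils.n_coils, dtype=complex)
    for e, tri in zip(terms, triples):
        s0 = e.fourier(-coils.freqs[:, 0], -coils.freqs[:, 1])  # (n_terms,)
        dc += (tri.m_ss / e.amplitude) * (coils.weights @ s0)
    scale = n**2  # matches the discrete Fourier sum of a rasterized image
    norm = 1.0
    if normalize:
        rss = np.sqrt(np.sum(np.abs(scale * dc) ** 2))
        norm = n / rss

    traj_all = sched.trajectory(nsamp)
    y = np.zeros((len(slices), sched.spokes_per_slice, nsamp, coils.n_coils),
                 dtype=np.complex128)
    for out_idx, s in enumerate(slices):
        k = traj_all[s] * n                        # cycles/FOV, (spokes, samp, 2)
        t = sched.times_ms[s] + seq.te_ms          # echo times, (spokes,)
        for e, tri in zip(terms, triples):
            shifted = np.stack(
                [e.fourier(k[..., 0] - fx, k[..., 1] - fy)
                 for fx, fy in coils.freqs], axis=0)          # (n_terms, spokes, samp)
            per_coil = np.tensordot(coils.weights, shifted, axes=(1, 0))
            m_t = (tri.m_ss - (tri.m_ss + tri.m_0)
                   * np.exp(-t * tri.r1_star)) / e.amplitude   # (spokes,)
            y[out_idx] += np.transpose(per_coil, (1, 2, 0)) * m_t[:, None, None]
    y *= scale * norm

    return KSpaceData(
        y=y,
        traj=traj_all[list(slices)],
        times_ms=sched.times_ms[list(slices)],
        angles_deg=sched.angles_deg[list(slices)],
        seq=seq,
        slices=tuple(slices),
        normalization=float(norm * scale),
    )


def add_noise(kdata: KSpaceData, sd: float, seed: int) -> KSpaceData:
    """Add i.i.d. complex Gaussian noise of standard deviation ``sd``.

    ``sd`` is the total complex SD (sd/sqrt(2) per real component),
    referenced to the normalized data scale.  Deterministic under ``seed``.
    """
    if sd < 0:
        raise ValueError("noise sd must be nonnegative")
    if sd == 0:
        return kdata.with_y(kdata.y.copy(), noise_sd=0.0, noise_seed=seed)
    rng = np.random.default_rng(seed)
    s = sd / math.sqrt(2.0)
    noise = rng.normal(scale=s, size=kdata.y.shape) \
        + 1j * rng.normal(scale=s, size=kdata.y.shape)
    return kdata.with_y(kdata.y + noise, noise_sd=sd, noise_seed=seed)


@dataclass(frozen=True)
class TruthMaps:
    """Rasterized ground truth with boundary-free ROI masks."""

    t1_ms: np.ndarray           # NaN outside the phantom
    amplitude: np.ndarray       # complex proton-density amplitude
    mss: np.ndarray
    m0: np.ndarray
    r1_star_per_ms: np.ndarray
    labels: np.ndarray          # compartment index, -1 outside
    roi_masks: dict = field(repr=False, default_factory=dict)


def rasterize_truth(ph: PhantomDef, grid: int, seq: SequenceParams,
                    erode_px: int = 2) -> TruthMaps:
    """Pixel-center rasterization of the phantom and its truth maps.

    ROI masks (one per compartment, keyed ``roi1..roiK`` in definition
    order with the background last as ``background``) are eroded by
    ``erode_px`` pixels so boundary pixels never enter ROI statistics.
    """
    if grid < 16:
        raise ValueError("grid must be >= 16")
    r = (np.arange(grid) - grid // 2) / grid
    x, y = np.meshgrid(r, r, indexing="ij")
    labels = np.full((grid, grid), -1, dtype=int)
    for idx, e in enumerate(ph.compartments):
        labels[e.contains(x, y)] = idx

    t1 = np.full((grid, grid), np.nan)
    amp = np.zeros((grid, grid), dtype=complex)
    mss = np.zeros((grid, grid), dtype=complex)
    m0 = np.zeros((grid, grid), dtype=complex)
    r1s = np.zeros((grid, grid))
    for idx, e in enumerate(ph.compartments):
        sel = labels == idx
        tri = triple_for_t1(e.t1_ms, seq, m0=e.amplitude)
        t1[sel] = e.t1_ms
        amp[sel] = e.amplitude
        mss[sel] = tri.m_ss
        m0[sel] = tri.m_0
        r1s[sel] = tri.r1_star

    masks = {}
    names = ["background"] + [f"roi{i}" for i in range(1, len(ph.compartments))]
    for idx, name in enumerate(names):
        mask = labels == idx
        if erode_px > 0:
            mask = ndimage.binary_erosion(mask, iterations=erode_px)
        masks[name] = mask
    # sanity: conversion of the truth triple must reproduce T1 exactly
    check = t1_from_parameters(mss, m0, r1s, seq.slice_tr_ms)
    inside = labels >= 0
    assert np.allclose(check[inside], t1[inside], rtol=1e-9)
    return TruthMaps(t1_ms=t1, amplitude=amp, mss=mss, m0=m0,
                     r1_star_per_ms=r1s, labels=labels, roi_masks=masks)
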