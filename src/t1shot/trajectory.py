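"""Spoke-interleaved multislice golden-angle radial schedules.

Spokes are acquired round-robin over slices: global pulse index ``j`` goes
to slice ``j mod n_slices`` at time ``j * TR`` after the inversion.  Each
slice runs its own small-golden-angle sequence, so any window of
consecutive spokes of a slice covers k-space near-uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import GOLDEN_RATIO, SequenceParams

__all__ = [
    "small_golden_angle",
    "SpokeSchedule",
    "BinnedSchedule",
    "build_schedule",
    "bin_spokes",
    "spoke_coordinates",
]


def small_golden_angle(n: int) -> float:
    """Small golden angle psi_N = 180 / (tau + N - 1) degrees, tau golden ratio.

    psi_1 is the classic golden angle (~111.25 deg); higher indices give
    smaller increments suited to windowed (binned) reconstruction.
    """
    if n < 1:
        raise ValueError("golden-angle index must be >= 1")
    return 180.0 / (GOLDEN_RATIO + n - 1)


@dataclass(frozen=True)
class SpokeSchedule:
    """Per-slice spoke angles, pulse timestamps and global indices.

    Arrays are shaped ``(n_slices, spokes_per_slice)``.  ``times_ms`` are
    pulse times since the inversion (slice s, spoke i at
    ``(i * n_slices + s) * TR``); the sampling instant of the echo is
    ``times_ms + te_ms``.
    """

    seq: SequenceParams
    angles_deg: np.ndarray
    times_ms: np.ndarray
    global_index: np.ndarray

    @property
    def n_slices(self) -> int:
        return self.angles_deg.shape[0]

    @property
    def spokes_per_slice(self) -> int:
        return self.angles_deg.shape[1]

    def trajectory(self, n_samples: int | None = None) -> np.ndarray:
        """k-space positions, shape (n_slices, spokes, n_samples, 2)."""
        n = n_samples or self.seq.readout_samples
        return spoke_coordinates(self.angles_deg, n)


@dataclass(frozen=True)
class BinnedSchedule:
    """Grouping of consecutive spokes into temporal bins.

    ``angles_deg``/``times_ms`` have shape ``(n_slices, n_bins, m)``;
    ``bin_times_ms`` is the mean member pulse time per bin, the single
    evaluation time t_k of the relaxation model during reconstruction.
    """

    seq: SequenceParams
    m: int
    angles_deg: np.ndarray
    times_ms: np.ndarray
    bin_times_ms: np.ndarray
    n_dropped: int = field(default=0)

    @property
    def n_bins(self) -> int:
        return self.angles_deg.shape[1]

    @property
    def bin_duration_ms(self) -> float:
        return self.m * self.seq.slice_tr_ms

    def trajectory(self, n_samples: int | None = None) -> np.ndarray:
        """Positions shaped (n_slices, n_bins, m, n_samples, 2)."""
        n = n_samples or self.seq.readout_samples
        return spoke_coordinates(self.angles_deg, n)


def build_schedule(seq: SequenceParams) -> SpokeSchedule:
    """Deterministic schedule for one protocol."""
    nsl, nsp = seq.n_slices, seq.spokes_per_slice
    psi = small_golden_angle(seq.golden_index)
    i = np.arange(nsp)
    s = np.arange(nsl)[:, None]
    gidx = i[None, :] * nsl + s
    angles = np.mod(i[None, :] * psi, 360.0) * np.ones((nsl, 1))
    times = gidx * seq.tr_ms
    return SpokeSchedule(seq=seq, angles_deg=angles, times_ms=times.astype(float),
                         global_index=gidx)


def bin_spokes(schedule: SpokeSchedule, m: int | None = None) -> BinnedSchedule:
    """Group each slice's spokes into consecutive bins of ``m``.

    A trailing group with fewer than ``m`` spokes is discarded so every bin
    has the same duration ``m * n_slices * TR``.
    """
    if m is None:
        m = schedule.seq.binned_spokes
    if m < 1:
        raise ValueError("bin size must be >= 1")
    nsp = schedule.spokes_per_slice
    if m > nsp:
        raise ValueError("bin size exceeds spokes per slice")
    n_bins = nsp // m
    keep = n_bins * m
    angles = schedule.angles_deg[:, :keep].reshape(schedule.n_slices, n_bins, m)
    times = schedule.times_ms[:, :keep].reshape(schedule.n_slices, n_bins, m)
    return BinnedSchedule(
        seq=schedule.seq, m=m, angles_deg=angles, times_ms=times,
        bin_times_ms=times.mean(axis=2), n_dropped=nsp - keep,
    )


def spoke_coordinates(angle_deg, n_samples: int) -> np.ndarray:
    """Sample positions of radial spokes through the k-space origin.

    ``n_samples`` evenly spaced points with radius in [-0.5, 0.5) in units
    of 1/pixel (2x readout oversampling relative to the base matrix is the
    package convention, i.e. n_samples = 2 * base_resolution).  For array
    input the result has shape ``angle.shape + (n_samples, 2)``.
    """
    if n_samples % 2:
        raise ValueError("n_samples must be even")
    angle = np.asarray(angle_deg, dtype=float)
    radius = (np.arange(n_samples) - n_samples // 2) / n_samples
    theta = np.deg2rad(angle)[..., None]
    kx = radius * np.cos(theta)
    ky = radius * np.sin(theta)
    return np.stack([kx, ky], axis=-1)
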