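"""Acquisition protocol descriptions for inversion-recovery radial FLASH.

A :class:`SequenceParams` instance describes one single-shot IR experiment:
after a nonselective inversion pulse, radial spokes are acquired continuously
with repetition time ``tr_ms``, cycling through ``n_slices`` slices in a
spoke-interleaved fashion, so each slice sees an effective repetition time of
``n_slices * tr_ms``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import yaml

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class SequenceParams:
    """Timing, flip angle and geometry of one IR FLASH protocol.

    Parameters
    ----------
    n_slices : int
        Number of interleaved slices (>= 1).
    tr_ms : float
        Repetition time between successive RF pulses, ms.
    te_ms : float
        Echo time, ms (sampling instant relative to the pulse).
    flip_deg : float
        Excitation flip angle in degrees, 0 < flip < 90.
    acq_time_s : float
        Nominal total acquisition time in seconds.
    spokes_per_slice : int
        Number of radial spokes acquired for each slice.
    binned_spokes : int
        Number of consecutive spokes (per slice) sharing one model
        evaluation time during reconstruction.
    golden_index : int
        Index N of the small golden angle psi_N = 180 / (golden ratio + N - 1).
    readout_samples : int
        Complex samples per spoke (2x readout oversampling by convention).
    fov_mm : float
        Field of view, mm.
    base_resolution : int
        Image matrix size (pixels along one dimension).
    """

    n_slices: int
    tr_ms: float
    te_ms: float
    flip_deg: float
    acq_time_s: float
    spokes_per_slice: int
    binned_spokes: int
    golden_index: int
    readout_samples: int
    fov_mm: float
    base_resolution: int

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if not 0.0 < self.flip_deg < 90.0:
            raise ValueError("flip_deg must lie in (0, 90)")
        if self.golden_index < 1:
            raise ValueError("golden_index must be >= 1")
        if not self.spokes_per_slice >= self.binned_spokes >= 1:
            raise ValueError("need spokes_per_slice >= binned_spokes >= 1")

    # -- derived quantities -------------------------------------------------
    @property
    def flip_rad(self) -> float:
        return math.radians(self.flip_deg)

    @property
    def slice_tr_ms(self) -> float:
        """Effective repetition time per slice, n_slices * TR."""
        return self.n_slices * self.tr_ms

    @property
    def golden_angle_deg(self) -> float:
        return 180.0 / (GOLDEN_RATIO + self.golden_index - 1)

    @property
    def bin_duration_ms(self) -> float:
        """Temporal width of one reconstruction bin."""
        return self.binned_spokes * self.slice_tr_ms

    @property
    def resolution_mm(self) -> float:
        return self.fov_mm / self.base_resolution

    def scaled(self, factor: float) -> "SequenceParams":
        """Desk-scale variant: matrix and spoke count reduced jointly.

        The undersampling ratio (spokes relative to matrix size) and the
        binning are preserved; timing and flip angle are untouched.
        """
        if not 0.0 < factor <= 1.0:
            raise ValueError("scale factor must lie in (0, 1]")
        n = int(round(self.base_resolution * factor))
        return dataclasses.replace(
            self,
            base_resolution=n,
            readout_samples=2 * n,
            spokes_per_slice=max(int(self.spokes_per_slice * factor),
                                 self.binned_spokes),
        )

    # -- YAML protocol blocks ----------------------------------------------
    def to_yaml(self) -> str:
        block = {
            "fov_mm": self.fov_mm,
            "matrix": self.base_resolution,
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "flip_deg": self.flip_deg,
            "n_slices": self.n_slices,
            "spokes_per_slice": self.spokes_per_slice,
            "binned_spokes": self.binned_spokes,
            "golden_angle_deg": round(self.golden_angle_deg, 2),
            "acq_time_s": self.acq_time_s,
        }
        return yaml.safe_dump(block, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SequenceParams":
        block = yaml.safe_load(text)
        angle = float(block["golden_angle_deg"])
        # invert psi_N = 180 / (tau + N - 1) and round to nearest index
        index = int(round(180.0 / angle - GOLDEN_RATIO + 1.0))
        return cls(
            n_slices=int(block["n_slices"]),
            tr_ms=float(block["tr_ms"]),
            te_ms=float(block["te_ms"]),
            flip_deg=float(block["flip_deg"]),
            acq_time_s=float(block["acq_time_s"]),
            spokes_per_slice=int(block["spokes_per_slice"]),
            binned_spokes=int(block["binned_spokes"]),
            golden_index=index,
            readout_samples=2 * int(block["matrix"]),
            fov_mm=float(block["fov_mm"]),
            base_resolution=int(block["matrix"]),
        )


def _head(n_slices, flip, spokes, binned, gindex):
    return SequenceParams(
        n_slices=n_slices, tr_ms=3.81, te_ms=2.60, flip_deg=flip,
        acq_time_s=4.0, spokes_per_slice=spokes, binned_spokes=binned,
        golden_index=gindex, readout_samples=768, fov_mm=192.0,
        base_resolution=384,
    )


def _abdomen(n_slices, flip, spokes, binned, gindex):
    return SequenceParams(
        n_slices=n_slices, tr_ms=2.98, te_ms=2.20, flip_deg=flip,
        acq_time_s=4.0, spokes_per_slice=spokes, binned_spokes=binned,
        golden_index=gindex, readout_samples=512, fov_mm=320.0,
        base_resolution=256,
    )


#: Published phantom/head and abdomen protocols, keyed by short name.
PROTOCOLS: dict[str, SequenceParams] = {
    "head1": _head(1, 6.0, 1064, 21, 8),
    "head3": _head(3, 10.0, 364, 7, 4),
    "head5": _head(5, 12.0, 225, 4, 2),
    "head7": _head(7, 14.0, 156, 3, 2),
    "abdomen1": _abdomen(1, 6.0, 1344, 21, 8),
    "abdomen3": _abdomen(3, 10.0, 456, 7, 4),
}


def get_protocol(name: str, scale: float = 1.0) -> SequenceParams:
    """Look up a named protocol, optionally desk-scaled."""
    try:
        seq = PROTOCOLS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; choose from {sorted(PROTOCOLS)}"
        ) from None
    return seq if scale == 1.0 else seq.scaled(scale)
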