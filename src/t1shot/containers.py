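"""k-space data container with trajectory and timing attached (HDF5-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .sequences import SequenceParams

__all__ = ["KSpaceData"]


@dataclass
class KSpaceData:
    """Multi-coil radial samples of one IR experiment.

    ``y`` is indexed ``(slice, spoke, readout sample, coil)`` where the
    slice axis runs over ``slices`` (a subset of the protocol's slices may
    be stored).  ``traj`` holds positions in 1/pixel units in [-0.5, 0.5),
    ``times_ms`` the pulse times since inversion.
    """

    y: np.ndarray            # (S, spokes, samples, coils) complex
    traj: np.ndarray         # (S, spokes, samples, 2) float
    times_ms: np.ndarray     # (S, spokes) float
    angles_deg: np.ndarray   # (S, spokes) float
    seq: SequenceParams
    slices: tuple = ()       # protocol slice indices stored along axis 0
    noise_sd: float = 0.0
    noise_seed: int | None = None
    normalization: float = 1.0
    compression_energy: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.slices:
            self.slices = tuple(range(self.y.shape[0]))
        if self.y.shape[:3] != self.traj.shape[:3]:
            raise ValueError("y and traj disagree on (slice, spoke, sample)")
        if self.y.shape[:2] != self.times_ms.shape:
            raise ValueError("times_ms shape mismatch")

    @property
    def n_coils(self) -> int:
        return self.y.shape[-1]

    @property
    def n_spokes(self) -> int:
        return self.y.shape[1]

    @property
    def n_samples(self) -> int:
        return self.y.shape[2]

    def slice_index(self, protocol_slice: int) -> int:
        """Axis-0 index holding data of the given protocol slice."""
        try:
            return self.slices.index(protocol_slice)
        except ValueError:
            raise KeyError(f"slice {protocol_slice} not stored") from None

    def with_y(self, y: np.ndarray, **updates) -> "KSpaceData":
        return replace(self, y=y, **updates)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("y", data=self.y)
            f.create_dataset("traj", data=self.traj)
            f.create_dataset("times_ms", data=self.times_ms)
            f.create_dataset("angles", data=self.angles_deg)
            f.attrs["sequence_yaml"] = self.seq.to_yaml()
            f.attrs["golden_index"] = self.seq.golden_index
            f.attrs["slices"] = np.asarray(self.slices)
            f.attrs["noise_sd"] = self.noise_sd
            f.attrs["noise_seed"] = -1 if self.noise_seed is None else self.noise_seed
            f.attrs["normalization"] = self.normalization

    @classmethod
    def load(cls, path) -> "KSpaceData":
        import dataclasses

        with h5py.File(path, "r") as f:
            seq = SequenceParams.from_yaml(f.attrs["sequence_yaml"])
            # golden_angle_deg in YAML is rounded; restore the exact index
            seq = dataclasses.replace(seq, golden_index=int(f.attrs["golden_index"]))
            seed = int(f.attrs["noise_seed"])
            return cls(
                y=f["y"][...],
                traj=f["traj"][...],
                times_ms=f["times_ms"][...],
                angles_deg=f["angles"][...],
                seq=seq,
                slices=tuple(int(s) for s in f.attrs["slices"]),
                noise_sd=float(f.attrs["noise_sd"]),
                noise_seed=None if seed < 0 else seed,
                normalization=float(f.attrs["normalization"]),
            )
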