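"""T1 maps, ROI statistics and difference maps from estimated parameters."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recon import Unknowns
from .sequences import SequenceParams
from .signal_model import t1_from_parameters

__all__ = ["T1Map", "compute_t1_map", "roi_stats", "difference_map",
           "save_t1_nifti", "save_map_png"]


@dataclass
class T1Map:
    """Quantitative T1 map in ms with a validity mask.

    ``mask`` is True on valid pixels; invalid pixels (background below the
    magnitude threshold or pixels where the exact conversion formula has no
    solution) hold NaN.
    """

    values_ms: np.ndarray
    mask: np.ndarray
    n_invalid: int = 0          # conversion failures inside the foreground

    @property
    def grid(self) -> int:
        return self.values_ms.shape[-1]

    @property
    def masked_fraction(self) -> float:
        return 1.0 - float(np.mean(self.mask))


def compute_t1_map(x_p, seq: SequenceParams,
                   background_frac: float = 0.05) -> T1Map:
    """Pixelwise exact Look-Locker conversion of (Mss, M0, R1*) to T1.

    Parameters may be an :class:`~t1shot.recon.Unknowns` (R1* in 1/s) or a
    tuple ``(mss, m0, r1_star_per_ms)``.  Pixels with |M0| below
    ``background_frac`` of its 99th percentile are masked as background;
    pixels where the logarithm in the conversion leaves its domain are
    masked and counted in ``n_invalid``.
    """
    if isinstance(x_p, Unknowns):
        mss, m0 = x_p.mss, x_p.m0
        r1s_per_ms = x_p.r1_star / 1000.0
    else:
        mss, m0, r1s_per_ms = x_p
    mag = np.abs(m0)
    thresh = background_frac * np.percentile(mag, 99.0)
    foreground = mag >= thresh
    t1 = t1_from_parameters(mss, m0, r1s_per_ms, seq.slice_tr_ms)
    valid = foreground & np.isfinite(t1) & (t1 > 0)
    n_invalid = int(np.sum(foreground & ~valid))
    out = np.where(valid, t1, np.nan)
    return T1Map(values_ms=out, mask=valid, n_invalid=n_invalid)


def roi_stats(t1map: T1Map, rois: dict) -> pd.DataFrame:
    """Mean and sample SD (n-1) of T1 per ROI, masked pixels excluded.

    ``rois`` maps name -> boolean mask.  Raises if an ROI is empty after
    masking.
    """
    rows = []
    for name, mask in rois.items():
        sel = np.asarray(mask, bool) & t1map.mask
        n = int(np.sum(sel))
        if n == 0:
            raise ValueError(f"ROI {name!r} is empty after masking")
        vals = t1map.values_ms[sel]
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        rows.append({"roi": name, "n_pixels": n,
                     "mean_ms": float(np.mean(vals)), "sd_ms": sd})
    return pd.DataFrame(rows)


def difference_map(a: T1Map, b: T1Map) -> np.ndarray:
    """a - b with the union of invalid pixels masked (NaN)."""
    if a.values_ms.shape != b.values_ms.shape:
        raise ValueError("T1 maps have different shapes")
    both = a.mask & b.mask
    return np.where(both, a.values_ms - b.values_ms, np.nan)


def save_map_png(values: np.ndarray, path, vmin=None, vmax=None,
                 cmap: str = "viridis", title: str | None = None) -> None:
    """Render a T1 or difference map to PNG (NaN pixels drawn dark)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
    im = ax.imshow(values.T, origin="lower", vmin=vmin, vmax=vmax,
                   cmap=cmap, interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8, label="ms")
    if title:
        ax.set_title(title)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def save_t1_nifti(t1map: T1Map, path, voxel_mm: float = 1.0) -> None:
    """Write the T1 map (ms, float32, NaN on masked pixels) as NIfTI."""
    import nibabel as nib

    affine = np.diag([voxel_mm, voxel_mm, 1.0, 1.0])
    img = nib.Nifti1Image(t1map.values_ms.astype(np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
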