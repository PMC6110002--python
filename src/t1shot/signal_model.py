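"""Three-parameter Look-Locker relaxation model for IR FLASH readouts.

During a continuously pulsed inversion recovery the longitudinal
magnetization of a slice relaxes toward a *driven* steady state ``Mss``
rather than the thermal equilibrium ``M0``, with an apparent rate

    R1* = 1/T1 - ln(cos alpha) / (n_sl * TR),

faster than the true ``R1 = 1/T1``.  The observed signal is

    M(t) = Mss - (Mss + M0) * exp(-t * R1*),

starting from perfect inversion ``M(0) = -M0``.  The true T1 is recovered
from the fitted triple ``(Mss, M0, R1*)`` by an exact closed-form
correction (:func:`t1_exact`).  All times are in ms, rates in 1/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sequences import SequenceParams

__all__ = [
    "RelaxationTriple",
    "effective_rate",
    "relaxation_signal",
    "steady_state_ratio",
    "t1_exact",
    "t1_from_parameters",
    "triple_for_t1",
    "bloch_flash_oracle",
]


@dataclass(frozen=True)
class RelaxationTriple:
    """Parameters of the driven relaxation curve.

    ``m_ss`` and ``m_0`` are complex (they share the receive phase);
    ``r1_star`` is the real, nonnegative effective rate in 1/ms.
    """

    m_ss: complex
    m_0: complex
    r1_star: float

    def __post_init__(self) -> None:
        if self.r1_star < 0:
            raise ValueError("r1_star must be nonnegative")


def effective_rate(t1_ms: float, seq: SequenceParams) -> float:
    """Apparent relaxation rate R1* (1/ms) under continuous readout.

    The flip-angle term uses the effective per-slice repetition time
    ``n_slices * TR``: in a spoke-interleaved acquisition each slice is
    excited only every ``n_slices``-th pulse.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    cos_a = math.cos(seq.flip_rad)
    if cos_a <= 0:
        raise ValueError("flip angle must be < 90 degrees")
    out = 1.0 / t1 - math.log(cos_a) / seq.slice_tr_ms
    return float(out) if np.isscalar(t1_ms) else out


def relaxation_signal(triple: RelaxationTriple, t_ms):
    """Model magnetization M(t) = Mss - (Mss + M0) exp(-t R1*)."""
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    val = triple.m_ss - (triple.m_ss + triple.m_0) * np.exp(-t * triple.r1_star)
    return complex(val) if np.isscalar(t_ms) else val


def steady_state_ratio(t1_ms: float, seq: SequenceParams) -> float:
    """Driven steady state Mss/M0 of a spoiled FLASH train.

    Standard result (1 - E1) / (1 - E1 cos(alpha)) with
    E1 = exp(-n_sl TR / T1); equals the fixed point of the pulse-to-pulse
    Bloch recursion, see :func:`bloch_flash_oracle`.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    e1 = np.exp(-seq.slice_tr_ms / t1)
    out = (1.0 - e1) / (1.0 - e1 * math.cos(seq.flip_rad))
    return float(out) if np.isscalar(t1_ms) else out


def t1_from_parameters(mss, m0, r1_star, slice_tr_ms: float):
    """Exact T1 from (Mss, M0, R1*) maps; vectorized core of :func:`t1_exact`.

    T1 = -n_sl TR / ln(1 - (Mss/M0) (1 - exp(-n_sl TR R1*)))

    ``mss``/``m0`` may be complex: the ratio is taken as the real part of
    Mss/M0 after global-phase alignment to M0, i.e.
    Re(Mss conj(M0)) / |M0|^2.  Pixels where the log argument is not in
    (0, 1] or where M0 vanishes come back as NaN.
    """
    mss = np.asarray(mss)
    m0 = np.asarray(m0)
    r1 = np.asarray(r1_star, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.abs(m0) ** 2
        ratio = np.real(mss * np.conj(m0)) / denom
        arg = 1.0 - ratio * (1.0 - np.exp(-slice_tr_ms * r1))
        bad = ~np.isfinite(arg) | (arg <= 0) | (denom == 0)
        arg = np.where(bad, 1.0, arg)
        log = np.log(arg)
        bad |= log >= 0  # arg >= 1 would give T1 <= 0
        t1 = np.where(bad, np.nan, -slice_tr_ms / np.where(log == 0, -1.0, log))
    return t1


def t1_exact(triple: RelaxationTriple, seq: SequenceParams) -> float:
    """Exact Look-Locker correction for a single parameter triple (ms)."""
    if triple.r1_star <= 0:
        raise ValueError("r1_star must be positive for T1 conversion")
    out = t1_from_parameters(triple.m_ss, triple.m_0, triple.r1_star,
                             seq.slice_tr_ms)
    return float(out)


def triple_for_t1(t1_ms: float, seq: SequenceParams,
                  m0: complex = 1.0 + 0.0j) -> RelaxationTriple:
    """Forward map T1 -> (Mss, M0, R1*) for a given protocol."""
    return RelaxationTriple(
        m_ss=m0 * steady_state_ratio(t1_ms, seq),
        m_0=m0,
        r1_star=effective_rate(t1_ms, seq),
    )


def bloch_flash_oracle(t1_ms: float, seq: SequenceParams,
                       n_pulses: int, m0: float = 1.0) -> np.ndarray:
    """Discrete pulse-to-pulse recursion for one slice of the interleave.

    Returns the longitudinal magnetization immediately before each of the
    ``n_pulses`` excitations of the slice, starting at perfect inversion
    (-M0 before the first pulse).  Between consecutive excitations of a
    slice a time ``n_slices * TR`` elapses; ideal spoiling is assumed, so

        M[k+1] = M[k] cos(alpha) E1 + M0 (1 - E1),   E1 = exp(-n_sl TR/T1).

    This recursion is an independent check of the exponential model: since
    cos(alpha) E1 = exp(-n_sl TR R1*), the iterates coincide with
    M(t = k n_sl TR) of :func:`relaxation_signal` exactly.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    e1 = math.exp(-seq.slice_tr_ms / t1_ms)
    cos_a = math.cos(seq.flip_rad)
    out = np.empty(n_pulses, dtype=float)
    m = -m0
    for k in range(n_pulses):
        out[k] = m
        m = m * cos_a * e1 + m0 * (1.0 - e1)
    return out
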