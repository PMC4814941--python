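"""Band-limiting pretreatment of raw pulse channels.

The whole record is taken to the cosine-transform domain (orthonormal
DCT-II), coefficients whose equivalent frequency f_k = k*fs/(2N) falls
outside the pass band are zeroed, and the inverse transform is returned.
The default band is 0.5-48 Hz: the lower edge removes the respiratory
baseline wander and the DC offset, the upper edge removes sensor noise
while keeping every harmonic of a <=180 bpm pulse up to order 12.

Masking is a projection, so the filter is linear and idempotent.  The hard
mask can ring at the record edges; an optional raised-cosine taper softens
the band edges.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.fft import dct, idct

from .errors import PulseError


@dataclasses.dataclass(frozen=True)
class FilterBand:
    """Pass band in Hz, inclusive on both edges."""

    lo: float = 0.5
    hi: float = 48.0

    def validate(self, fs: float) -> None:
        if not (0.0 <= self.lo < self.hi):
            raise PulseError(f"invalid band [{self.lo}, {self.hi}] Hz")
        if self.hi > fs / 2:
            raise PulseError(
                f"band edge {self.hi} Hz exceeds Nyquist {fs / 2} Hz at fs={fs}"
            )


DEFAULT_BAND = FilterBand()


def dct_bandpass(signal: np.ndarray, fs: float, band: FilterBand = DEFAULT_BAND,
                 taper_hz: float = 0.0) -> np.ndarray:
    """Band-limit a record by DCT-domain masking; output length == input length.

    Parameters
    ----------
    signal : full-record sample array (length >= 2).
    fs : sampling rate in Hz; must exceed 2*band.hi.
    band : pass band; coefficients with f_k outside [lo, hi] are zeroed
        (the k=0 DC term is always removed when lo > 0).
    taper_hz : optional raised-cosine transition width at each band edge;
        0 gives the default hard mask.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise PulseError("signal must be a 1-D array of length >= 2")
    band.validate(fs)
    n = len(x)
    X = dct(x, type=2, norm="ortho")
    f = np.arange(n) * fs / (2.0 * n)
    if taper_hz <= 0:
        mask = ((f >= band.lo) & (f <= band.hi)).astype(float)
    else:
        mask = np.ones(n)
        ramp_lo = (f - (band.lo - taper_hz)) / taper_hz
        ramp_hi = ((band.hi + taper_hz) - f) / taper_hz
        mask = np.minimum(np.clip(ramp_lo, 0, 1), np.clip(ramp_hi, 0, 1))
        mask = 0.5 - 0.5 * np.cos(np.pi * mask)  # raised cosine in [0,1]
        if band.lo > 0:
            mask[f < band.lo - taper_hz] = 0.0
        mask[f > band.hi + taper_hz] = 0.0
    return idct(X * mask, type=2, norm="ortho")


def zero_align(signal: np.ndarray, onsets: np.ndarray | None = None) -> np.ndarray:
    """Adjust the cycle start points to zero without changing intra-cycle amplitudes.

    With detected ``onsets``, the piecewise-linear interpolation of the
    signal values at the onsets is subtracted, so every cycle starts exactly
    at zero while amplitude differences between landmarks within a cycle are
    preserved up to the (slow) baseline slope.  Before segmentation is
    available the record minimum is subtracted instead — a visualization
    fallback only.
    """
    x = np.asarray(signal, dtype=float)
    if onsets is None or len(onsets) < 2:
        return x - x.min()
    onsets = np.asarray(onsets, dtype=int)
    baseline = np.interp(np.arange(len(x)), onsets, x[onsets])
    return x - baseline
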