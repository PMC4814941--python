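"""Multi-cycle harmonic modelling and the 193-parameter feature vector.

Each heart cycle of length L samples is fitted separately by ordinary least
squares to a 12-harmonic trigonometric model

    y_t = a0 + sum_{k=1..12} ( a_k cos(2 pi k t / L) + b_k sin(2 pi k t / L) )

so cycles of different length share one coefficient vocabulary.  Per-channel
coefficients are then aggregated across the n cycles with period weights
T_i / T (T = sum T_i), giving one representative cycle model per channel:

    a_k = sum_i (T_i / T) a_{i,k},   b_k = sum_i (T_i / T) b_{i,k}.

From the aggregate come the harmonic amplitudes C_k = sqrt(a_k^2 + b_k^2),
phases F_k = atan2(b_k, a_k), and — via the reconstructed mean cycle — the
classical sphygmogram time-domain landmarks (systolic peak h1/t1, tidal
wave h3, dicrotic notch h4/t4, dicrotic wave h5/t5, main-wave width w).

The per-subject feature vector holds, for each of the six channels,
C1..C12, F1..F12 and the eight time-domain parameters
{h1, t1, h3/h1, h4/h1, h5/h1, w, t4, t5}, plus one global mean cycle
period t: 32 x 6 + 1 = 193 named parameters.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import N_HARMONICS, render_harmonics
from .errors import ExtractionError, FeatureError, PulseError, SegmentationError
from .filters import DEFAULT_BAND, FilterBand, dct_bandpass, zero_align
from .io import CHANNELS, PulseRecording, TIME_PARAMS, feature_names
from .segmentation import DEFAULT_HR_BAND, CycleSet, detect_onsets, segment


@dataclasses.dataclass
class CycleFit:
    """Least-squares 12-harmonic fit of one cycle."""

    a0: float
    a: np.ndarray
    b: np.ndarray
    L: int
    rmse: float


@dataclasses.dataclass
class ChannelHarmonics:
    """Period-weighted aggregate coefficients for one channel."""

    a0: float
    a: np.ndarray
    b: np.ndarray

    @property
    def C(self) -> np.ndarray:
        return np.hypot(self.a, self.b)

    @property
    def F(self) -> np.ndarray:
        return np.arctan2(self.b, self.a)


@dataclasses.dataclass
class TimeDomainFeatures:
    """Sphygmogram landmarks of the reconstructed mean cycle.

    Amplitudes are measured above the cycle-onset value; times in seconds
    from the onset.  ``fallback`` flags landmarks that had to be estimated
    from inflection points because the notch or tidal wave is absent.
    """

    h1: float
    t1: float
    h3: float
    h4: float
    h5: float
    t4: float
    t5: float
    w: float
    period: float
    fallback: tuple[str, ...] = ()


def design_matrix(L: int, p: int = N_HARMONICS) -> np.ndarray:
    """OLS design {1, cos(2 pi k t / L), sin(2 pi k t / L)} for t = 0..L-1."""
    t = np.arange(L)
    k = np.arange(1, p + 1)
    ang = 2.0 * np.pi * np.outer(t, k) / L
    return np.hstack([np.ones((L, 1)), np.cos(ang), np.sin(ang)])


def fit_cycle(y: np.ndarray, p: int = N_HARMONICS) -> CycleFit:
    """Separate least-squares fit of one cycle to the p-harmonic model."""
    y = np.asarray(y, dtype=float)
    L = len(y)
    if L < 2 * p + 1:
        raise PulseError(
            f"cycle of {L} samples cannot identify {2 * p + 1} coefficients"
        )
    X = design_matrix(L, p)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return CycleFit(a0=float(coef[0]), a=coef[1:p + 1], b=coef[p + 1:],
                    L=L, rmse=float(np.sqrt(np.mean(resid ** 2))))


def aggregate(fits: list[CycleFit], T_i: np.ndarray) -> ChannelHarmonics:
    """Aggregate per-cycle coefficients with period weights T_i / T."""
    if len(fits) == 0:
        raise PulseError("cannot aggregate an empty list of cycle fits")
    T_i = np.asarray(T_i, dtype=float)
    if len(T_i) != len(fits):
        raise PulseError("need one period per cycle fit")
    w = T_i / T_i.sum()
    a0 = float(np.sum(w * np.array([f.a0 for f in fits])))
    a = np.sum(w[:, None] * np.array([f.a for f in fits]), axis=0)
    b = np.sum(w[:, None] * np.array([f.b for f in fits]), axis=0)
    return ChannelHarmonics(a0=a0, a=a, b=b)


def reconstruct(ch: ChannelHarmonics, L: int) -> np.ndarray:
    """Forward evaluation of the aggregated model over one cycle of L samples."""
    return render_harmonics(ch.a0, ch.a, ch.b, L)


def _local_extrema(y: np.ndarray, min_swing: float = 0.0) -> list[tuple[int, str]]:
    """Interior local extrema as (index, 'max'|'min'), in order.

    Micro-ripples are suppressed: an extremum is kept only if the excursion
    to both neighbouring kept extrema is at least ``min_swing``.
    """
    d = np.diff(y)
    s = np.sign(d)
    # collapse zero-slope plateaus onto the following sign
    for i in range(len(s) - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    out = []
    for i in range(1, len(s)):
        if s[i - 1] > 0 and s[i] < 0:
            out.append((i, "max"))
        elif s[i - 1] < 0 and s[i] > 0:
            out.append((i, "min"))
    if min_swing <= 0 or len(out) < 2:
        return out
    # drop the shallowest adjacent pair until all swings are significant
    pts = out[:]
    changed = True
    while changed and len(pts) >= 2:
        changed = False
        swings = [abs(y[pts[i + 1][0]] - y[pts[i][0]]) for i in range(len(pts) - 1)]
        j = int(np.argmin(swings))
        if swings[j] < min_swing:
            del pts[j:j + 2]  # remove the ripple pair, keeping alternation
            changed = True
    return pts


def _width_at_fraction(y: np.ndarray, i_peak: int, level: float, fs: float) -> float:
    """Width (s) of the contiguous region around the peak with y >= level."""
    left = i_peak
    while left > 0 and y[left - 1] >= level:
        left -= 1
    right = i_peak
    while right < len(y) - 1 and y[right + 1] >= level:
        right += 1
    # linear sub-sample interpolation at both crossings
    lf = 0.0 if left == 0 else (y[left] - level) / max(y[left] - y[left - 1], 1e-12)
    rf = 0.0 if right == len(y) - 1 else (y[right] - level) / max(y[right] - y[right + 1], 1e-12)
    return (right - left + lf + rf) / fs


def time_features(ch: ChannelHarmonics, mean_L: int, fs: float,
                  width_fraction: float = 2.0 / 3.0) -> TimeDomainFeatures:
    """Landmark features from the reconstructed mean cycle.

    The main wave is the global maximum; then, following the falling limb:
    the next local maximum is the tidal wave, the local minimum after it the
    dicrotic notch, and the subsequent local maximum the dicrotic wave.
    When the tidal wave is only a shoulder (no local maximum before the
    notch) it is placed at the flattest point of the descent; when neither
    notch nor dicrotic wave exists (e.g. a single-harmonic cycle) both are
    estimated from the inflection points of the falling limb.  Fallbacks are
    flagged, never raised.
    """
    y = reconstruct(ch, mean_L)
    base = y[0]
    i1 = int(np.argmax(y))
    h1 = float(y[i1] - base)
    if h1 <= 0 or np.ptp(y) < 1e-12:
        raise FeatureError("flat cycle: no main wave")

    ext = [(i, kind) for i, kind in _local_extrema(y, min_swing=0.02 * h1)
           if i > i1]
    fallback: list[str] = []

    # the dicrotic notch is the deepest local minimum in the physiological
    # window [0.22 T, 0.65 T]: the inter-wave dip sits earlier, tail ripples
    # of the aggregate later
    notch_lo, notch_hi = int(0.22 * mean_L), int(0.65 * mean_L)
    window_minima = [i for i, k in ext if k == "min" and notch_lo <= i <= notch_hi]
    if window_minima:
        i4 = min(window_minima, key=lambda i: y[i])
        later_max = [i for i, k in ext if k == "max" and i > i4]
        if later_max:
            i5 = later_max[0]
        else:
            dy = np.abs(np.gradient(y))
            tail = np.arange(i4 + 1, mean_L - 1)
            i5 = int(tail[np.argmin(dy[tail])]) if len(tail) else i4
            fallback.append("dicrotic")
        between_maxima = [i for i, k in ext if k == "max" and i1 < i < i4]
        if between_maxima:
            i3 = max(between_maxima, key=lambda i: y[i])
        else:
            # shoulder-type tidal wave: flattest point of the descent
            dy = np.abs(np.gradient(y))
            i3 = i1 + 1 + int(np.argmin(dy[i1 + 1:i4])) if i4 > i1 + 1 else i4
            fallback.append("tidal")
    else:
        # incomplete notch (no local minimum in the window): localize it at
        # the point of maximal upward curvature of the falling limb — the
        # standard proxy when valve closure leaves only a concavity change
        fallback.extend(["tidal", "notch", "dicrotic"])
        d2 = np.gradient(np.gradient(y))
        lo = max(notch_lo, i1 + 2)
        win = np.arange(lo, max(notch_hi, lo + 1))
        i4 = int(win[np.argmax(d2[win])])
        later_max = [i for i, k in ext if k == "max" and i > i4]
        if later_max:
            i5 = later_max[0]
        else:
            dy = np.abs(np.gradient(y))
            tail = np.arange(i4 + 1, min(mean_L - 1, int(0.85 * mean_L)))
            i5 = int(tail[np.argmin(dy[tail])]) if len(tail) else i4
        dy = np.abs(np.gradient(y))
        i3 = i1 + 1 + int(np.argmin(dy[i1 + 1:i4])) if i4 > i1 + 1 else i4

    feats = TimeDomainFeatures(
        h1=h1,
        t1=i1 / fs,
        h3=float(y[i3] - base),
        h4=float(y[i4] - base),
        h5=float(y[i5] - base),
        t4=i4 / fs,
        t5=i5 / fs,
        w=_width_at_fraction(y - base, i1, width_fraction * h1, fs),
        period=mean_L / fs,
        fallback=tuple(fallback),
    )
    return feats


def extract_channel(x: np.ndarray, fs: float, band: FilterBand = DEFAULT_BAND,
                    hr_band=DEFAULT_HR_BAND, bandpass: bool = True,
                    onsets: np.ndarray | None = None
                    ) -> tuple[ChannelHarmonics, TimeDomainFeatures, CycleSet]:
    """Full single-channel chain: filter, segment, align, fit, aggregate."""
    if bandpass:
        x = dct_bandpass(x, fs, band)
    if onsets is None:
        onsets = detect_onsets(x, fs, hr_band)
    cs = segment(x, onsets, fs, hr_band)
    if len(cs) == 0:
        raise SegmentationError("no in-band cycles after segmentation")
    x = zero_align(x, cs.onsets)
    fits = [fit_cycle(x[s:s + L]) for s, L in zip(cs.starts, cs.lengths)]
    agg = aggregate(fits, cs.T_i)
    mean_L = int(round(cs.lengths.mean()))
    tdf = time_features(agg, mean_L, fs)
    return agg, tdf, cs


def extract_features(rec: PulseRecording, band: FilterBand = DEFAULT_BAND,
                     hr_band=DEFAULT_HR_BAND, bandpass: bool = True,
                     onsets: np.ndarray | None = None
                     ) -> tuple[pd.Series, dict]:
    """Assemble the 193-entry named feature vector for one subject.

    Returns the vector (index = the fixed feature vocabulary) and a QC
    report (cycles kept/dropped and landmark fallback flags per channel).
    ``onsets`` may inject known cycle starts (e.g. synthetic ground truth);
    ``bandpass=False`` skips pretreatment for already-clean signals.
    """
    missing = rec.missing_channels
    if missing:
        raise ExtractionError(f"subject {rec.subject_id}: missing channel(s) {missing}")
    values: dict[str, float] = {}
    qc: dict = {"subject_id": rec.subject_id, "channels": {}}
    periods = []
    for chname in CHANNELS:
        try:
            agg, tdf, cs = extract_channel(rec.channels[chname], rec.fs, band,
                                           hr_band, bandpass, onsets)
        except (SegmentationError, FeatureError) as exc:
            raise ExtractionError(
                f"subject {rec.subject_id}: channel {chname!r} failed: {exc}"
            ) from exc
        C, F = agg.C, agg.F
        for k in range(N_HARMONICS):
            values[f"C{k + 1}_{chname}"] = float(C[k])
            values[f"F{k + 1}_{chname}"] = float(F[k])
        td = {"h1": tdf.h1, "t1": tdf.t1, "h3_h1": tdf.h3 / tdf.h1,
              "h4_h1": tdf.h4 / tdf.h1, "h5_h1": tdf.h5 / tdf.h1,
              "w": tdf.w, "t4": tdf.t4, "t5": tdf.t5}
        for p in TIME_PARAMS:
            values[f"{p}_{chname}"] = float(td[p])
        periods.append(tdf.period)
        qc["channels"][chname] = {"n_cycles": len(cs), "n_dropped": cs.n_dropped,
                                  "fallback": list(tdf.fallback)}
    values["t"] = float(np.mean(periods))
    vec = pd.Series(values, dtype=float).reindex(feature_names())
    assert not vec.isna().any()
    return vec, qc


def extract_cohort(recordings: list[PulseRecording], **kwargs
                   ) -> tuple[pd.DataFrame, list[dict]]:
    """Extract features for many recordings; failures are reported, not raised.

    Returns the feature matrix (rows = successfully processed subjects, with
    ``subject_id`` and ``group`` columns) and the per-subject QC reports
    (including failure reasons for excluded subjects).
    """
    rows, qcs = [], []
    for rec in recordings:
        try:
            vec, qc = extract_features(rec, **kwargs)
        except ExtractionError as exc:
            qcs.append({"subject_id": rec.subject_id, "error": str(exc)})
            continue
        row = {"subject_id": rec.subject_id, "group": rec.group}
        row.update(vec.to_dict())
        rows.append(row)
        qcs.append(qc)
    matrix = pd.DataFrame(rows)
    return matrix, qcs
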