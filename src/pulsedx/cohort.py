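"""Synthetic pulse-wave cohorts with known ground truth.

Real radial-artery recordings are quasi-periodic: successive heart cycles
share a common shape but differ in length (beat-to-beat jitter), ride on a
slow respiratory baseline, and carry sensor noise.  This module emulates
exactly those ingredients so that every pipeline stage — filtering,
segmentation, harmonic fitting, feature extraction, group classification —
can be tested against a known generating truth.

A cycle shape is built from explicit time-domain landmarks (onset, systolic
peak, tidal wave, dicrotic notch, dicrotic wave) by monotone piecewise-cubic
interpolation, then projected onto a 12-harmonic Fourier series; the 25
coefficients (a0, a1..a12, b1..b12) *are* the generating template, and the
rendered cycle is their exact trigonometric evaluation.  Group effects are
planted either on the coefficients (harmonic amplitude C_k / phase F_k
shifts) or on the landmark knots (time-feature shifts), keeping the planted
truth expressible in the 193-name feature vocabulary.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import PulseError
from .io import (CHANNELS, CohortManifest, PulseRecording, feature_names,
                 write_manifest, write_recording)

import pandas as pd

N_HARMONICS = 12
MIN_CYCLE_SAMPLES = 25  # 2*12 harmonics + offset must be identifiable
PERIOD_BAND_S = (60.0 / 180.0, 60.0 / 40.0)  # physiological 40-180 bpm


def render_harmonics(a0: float, a: np.ndarray, b: np.ndarray, L: int) -> np.ndarray:
    """Evaluate y_t = a0 + sum_k a_k cos(2πkt/L) + b_k sin(2πkt/L), t=0..L-1."""
    if L < MIN_CYCLE_SAMPLES:
        raise PulseError(
            f"cycle length {L} < {MIN_CYCLE_SAMPLES} samples: a 12-harmonic "
            f"model (25 coefficients) is not identifiable"
        )
    t = np.arange(L)
    k = np.arange(1, len(a) + 1)
    ang = 2.0 * np.pi * np.outer(t, k) / L
    return a0 + np.cos(ang) @ a + np.sin(ang) @ b


@dataclasses.dataclass
class CycleTemplate:
    """12-harmonic Fourier coefficients of one canonical pulse cycle."""

    a0: float
    a: np.ndarray  # (12,) cosine coefficients
    b: np.ndarray  # (12,) sine coefficients

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != (N_HARMONICS,) or self.b.shape != (N_HARMONICS,):
            raise PulseError(f"template must carry exactly {N_HARMONICS} harmonic orders")

    @property
    def C(self) -> np.ndarray:
        """Harmonic amplitudes sqrt(a_k^2 + b_k^2)."""
        return np.hypot(self.a, self.b)

    @property
    def F(self) -> np.ndarray:
        """Harmonic phases atan2(b_k, a_k) in (−π, π]."""
        return np.arctan2(self.b, self.a)

    def render(self, L: int) -> np.ndarray:
        return render_harmonics(self.a0, self.a, self.b, L)


def render_cycle(template: CycleTemplate, L: int) -> np.ndarray:
    """Render one cycle of ``L`` samples from a template (exact evaluation)."""
    return template.render(L)


# --- landmark-based shape construction -------------------------------------

#: (role, time as fraction of the period, amplitude relative to the peak).
#: PCHIP is monotone between knots, so each interior knot is an exact local
#: extremum of the continuous shape: systolic peak, inter-wave dip, tidal
#: wave, dicrotic notch, dicrotic wave, then diastolic decay back to the foot.
DEFAULT_KNOTS: tuple[tuple[str, float, float], ...] = (
    ("onset", 0.00, 0.00),
    ("peak", 0.13, 1.00),
    ("dip", 0.18, 0.46),
    ("tidal", 0.23, 0.52),
    ("notch", 0.44, 0.30),
    ("dicrotic", 0.55, 0.44),
    ("tail", 0.76, 0.10),
    ("end", 1.00, 0.00),
)

#: time-domain feature name -> knot role whose time it controls
_TIME_FEATURE_KNOT = {"t1": "peak", "t4": "notch", "t5": "dicrotic"}


def shape_from_knots(knots, n_grid: int = 4096) -> np.ndarray:
    """Sample one period of the PCHIP shape through the landmark knots."""
    times = np.array([t for _, t, _ in knots])
    amps = np.array([v for _, _, v in knots])
    if np.any(np.diff(times) <= 0):
        raise PulseError("landmark knot times must be strictly increasing")
    u = np.arange(n_grid) / n_grid
    return PchipInterpolator(times, amps)(u)


def project_shape(shape: np.ndarray, p: int = N_HARMONICS) -> CycleTemplate:
    """Project one sampled period onto its first ``p`` Fourier harmonics."""
    n = len(shape)
    X = np.fft.rfft(shape)
    a0 = X[0].real / n
    a = 2.0 * X[1:p + 1].real / n
    b = -2.0 * X[1:p + 1].imag / n
    return CycleTemplate(a0=a0, a=a, b=b)


def landmark_template(knots=DEFAULT_KNOTS, amplitude: float = 1000.0,
                      n_grid: int = 4096) -> CycleTemplate:
    """Build a 12-harmonic template from landmark knots.

    ``amplitude`` scales the whole waveform (instrument units; the default
    mimics raw ADC counts of order 10^3).
    """
    tpl = project_shape(shape_from_knots(knots, n_grid))
    return CycleTemplate(a0=tpl.a0 * amplitude, a=tpl.a * amplitude, b=tpl.b * amplitude)


# --- group effects ----------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FeatureShift:
    """A planted group effect on one named feature of the generating template.

    ``add`` is an additive shift (units of the feature: instrument units for
    C_k, radians for F_k, seconds for t1/t4/t5); ``mul`` a multiplicative
    factor applied before the shift.
    """

    feature: str
    add: float = 0.0
    mul: float = 1.0

    def __post_init__(self) -> None:
        if self.feature not in feature_names():
            raise PulseError(f"unknown feature name {self.feature!r} in group effect")
        param, _ = self.feature.rsplit("_", 1)
        if not (param.startswith(("C", "F")) or param in _TIME_FEATURE_KNOT
                or param == "h1"):
            raise PulseError(
                f"planting on feature {self.feature!r} is not supported "
                f"(supported: C_k, F_k, t1/t4/t5, h1)"
            )

    @property
    def param(self) -> str:
        return self.feature.rsplit("_", 1)[0]

    @property
    def channel(self) -> str:
        return self.feature.rsplit("_", 1)[1]


#: Planted-effect templates modelled on the sparse two-group discriminants
#: the method is meant to recover: an FLD-like contrast on
#: {C2_zuocun, t4_zuochi, F2_youchi} and a cirrhosis-like contrast on
#: {C2_youguan, F1_youchi}.  Shifts are fixed in the "large effect" regime:
#: roughly 3-6 within-group SDs of the extracted feature, the largest that
#: still leave every waveform a single-footed, physiologically shaped pulse.
FLD_EFFECTS: tuple[FeatureShift, ...] = (
    FeatureShift("C2_zuocun", add=130.0),
    FeatureShift("t4_zuochi", add=-0.13),
    FeatureShift("F2_youchi", add=-0.55),
)
CIRRHOSIS_EFFECTS: tuple[FeatureShift, ...] = (
    FeatureShift("C2_youguan", add=-100.0),
    FeatureShift("F1_youchi", add=-0.45),
)


# --- cohort specification ---------------------------------------------------

@dataclasses.dataclass
class SyntheticCohortSpec:
    """Generating conditions for a synthetic cohort.

    Defaults emulate a resting adult at 75 bpm recorded for 40 s at 200 Hz
    with ~2.5% beat-to-beat period jitter, 0.25 Hz respiratory baseline
    wander and additive sensor noise at 2% of the systolic amplitude.
    """

    n_healthy: int = 20
    n_fld: int = 20
    n_cirrhosis: int = 10
    fs: float = 200.0
    duration_s: float = 40.0
    mean_period_s: float = 0.8
    subject_period_sd: float = 0.04   # between-subject heart-period SD (s)
    period_jitter_sd: float = 0.02    # within-subject beat-to-beat SD (s)
    wander_freq_hz: float = 0.25
    wander_amp: float = 150.0         # instrument units (~15% of peak)
    noise_sd: float = 20.0            # instrument units (~2% of peak)
    amplitude: float = 1000.0         # base systolic amplitude
    knot_time_jitter_s: float = 0.008  # per-subject landmark time SD (s)
    knot_amp_jitter: float = 0.05     # per-subject landmark amplitude SD (rel.)
    channel_gain_sd: float = 0.05     # per-channel gain SD (rel.)
    harmonic_amp_jitter: float = 0.05   # amplitude SD of harmonic k: this * sqrt(k)
    harmonic_phase_jitter: float = 0.02  # phase SD of harmonic k: this * k (rad)
    group_effects: dict = dataclasses.field(default_factory=lambda: {
        "fld": FLD_EFFECTS, "cirrhosis": CIRRHOSIS_EFFECTS})
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = PERIOD_BAND_S
        if not (lo < self.mean_period_s < hi):
            raise PulseError(f"mean period {self.mean_period_s}s outside the "
                             f"physiological band {PERIOD_BAND_S}")
        if self.wander_freq_hz >= 0.5:
            raise PulseError("respiratory wander frequency must be < 0.5 Hz "
                             "so pretreatment removes it")
        if self.fs <= 96.0:
            raise PulseError("fs must exceed 96 Hz (2 x 48 Hz filter edge)")
        for effects in self.group_effects.values():
            for e in effects:
                if not isinstance(e, FeatureShift):
                    raise PulseError("group effects must be FeatureShift instances")


@dataclasses.dataclass
class GroundTruth:
    """Generating truth for one recording (shared across the 6 channels)."""

    onsets: np.ndarray            # exact cycle-start sample indices
    lengths: np.ndarray           # per-cycle length in samples
    periods_s: np.ndarray         # per-cycle period in seconds
    templates: dict[str, CycleTemplate]  # group-shifted template per channel


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Deterministic per-subject substream from (cohort seed, subject id)."""
    return np.random.default_rng([seed, zlib.crc32(subject_id.encode())])


#: anchors that stay fixed when a landmark time is warped
_WARP_ANCHORS = {"peak": ("onset", "dip"), "notch": ("tidal", "dicrotic"),
                 "dicrotic": ("notch", "tail")}


def _apply_effects_to_knots(knots, effects, channel: str, period_s: float):
    """Apply time-landmark shifts (seconds) by anchored piecewise-linear warp.

    The target knot moves by the full shift; knots between it and the fixed
    anchors on either side move proportionally, so the landmark ordering and
    relative gaps are preserved (a local monotone time warp of the shape).
    """
    out = list(knots)
    for e in effects:
        if e.channel != channel or e.param not in _TIME_FEATURE_KNOT:
            continue
        role = _TIME_FEATURE_KNOT[e.param]
        lo_role, hi_role = _WARP_ANCHORS[role]
        times = {r: t for r, t, _ in out}
        t_old = times[role]
        t_new = t_old * e.mul + e.add / period_s
        t_lo, t_hi = times[lo_role], times[hi_role]
        if not (t_lo + 0.02 < t_new < t_hi - 0.02):
            raise PulseError(
                f"time shift on {e.feature!r} moves the {role} landmark "
                f"outside ({lo_role}, {hi_role})"
            )

        def warp(t: float) -> float:
            if t <= t_lo or t >= t_hi:
                return t
            if t <= t_old:
                return t_lo + (t - t_lo) * (t_new - t_lo) / (t_old - t_lo)
            return t_hi - (t_hi - t) * (t_hi - t_new) / (t_hi - t_old)

        out = [(r, warp(t), v) for r, t, v in out]
    return out


def _realign_foot(a: np.ndarray, b: np.ndarray,
                  n_grid: int = 1024) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the time origin so the waveform foot (global minimum) is t = 0.

    Coefficient surgery (amplitude scaling, phase rotation) displaces the
    cycle minimum away from t = 0; since rendered cycles start at t = 0 and
    the extractor references every phase and landmark to the detected foot,
    an unaligned template would leak a rigid time shift into *all* features
    of the channel.
    """
    y = render_harmonics(0.0, a, b, n_grid)
    delta = int(np.argmin(y))
    if delta == 0:
        return a, b
    k = np.arange(1, len(a) + 1)
    rot = np.exp(2j * np.pi * k * delta / n_grid)
    c = (a - 1j * b) * rot
    return c.real, -c.imag


def _prompt_rise(a: np.ndarray, b: np.ndarray, n_grid: int = 512) -> bool:
    """True when the foot-to-peak limb has no pre-systolic dip.

    Random per-harmonic jitter occasionally creates an oscillation between
    the diastolic foot and the systolic upstroke; such shapes have no
    well-defined onset and are not pulse-like.
    """
    y = render_harmonics(0.0, a, b, n_grid)
    i_peak = int(np.argmax(y))
    lo = max(2, int(0.04 * n_grid))
    if i_peak <= lo:
        return False
    limb_min = float(np.min(y[lo:i_peak]))
    return limb_min >= y.min() + 0.08 * np.ptp(y)


def _apply_effects_to_template(tpl: CycleTemplate, effects, channel: str) -> CycleTemplate:
    """Apply harmonic-amplitude/phase and overall-gain shifts."""
    a, b, a0 = tpl.a.copy(), tpl.b.copy(), tpl.a0
    for e in effects:
        if e.channel != channel:
            continue
        if e.param.startswith("C") and e.param[1:].isdigit():
            k = int(e.param[1:]) - 1
            c = np.hypot(a[k], b[k])
            factor = (c * e.mul + e.add) / c if c > 0 else 1.0
            a[k] *= factor
            b[k] *= factor
        elif e.param.startswith("F") and e.param[1:].isdigit():
            k = int(e.param[1:]) - 1
            phi = e.add
            a[k], b[k] = (a[k] * np.cos(phi) - b[k] * np.sin(phi),
                          b[k] * np.cos(phi) + a[k] * np.sin(phi))
        elif e.param == "h1":
            a, b, a0 = a * e.mul, b * e.mul, a0 * e.mul
    a, b = _realign_foot(a, b)
    return CycleTemplate(a0=a0, a=a, b=b)


def _subject_knots(rng: np.random.Generator, spec: SyntheticCohortSpec,
                   base=DEFAULT_KNOTS, period_s: float | None = None):
    """Jitter the landmark knots for one subject/channel."""
    sd_frac = spec.knot_time_jitter_s / (period_s or spec.mean_period_s)
    knots = []
    for role, t, v in base:
        if role in ("onset", "end"):
            knots.append((role, t, v))
            continue
        tj = t + rng.normal(0.0, sd_frac)
        vj = v * np.exp(rng.normal(0.0, spec.knot_amp_jitter))
        knots.append((role, tj, vj))
    # keep ordering with a minimal gap so PCHIP stays well posed
    for i in range(1, len(knots)):
        r, t, v = knots[i]
        knots[i] = (r, max(t, knots[i - 1][1] + 0.01), v)
    return knots


def generate_recording(spec: SyntheticCohortSpec, group: str, subject_id: str,
                       rng: np.random.Generator | None = None
                       ) -> tuple[PulseRecording, GroundTruth]:
    """Generate one 6-channel recording plus its generating ground truth.

    All channels share the cardiac rhythm (same onsets/periods); each channel
    has its own jittered shape template and gain.  The signal is the exact
    concatenation of rendered cycles plus sinusoidal baseline wander plus
    white noise; with zero noise and zero wander it equals the rendered
    cycles sample-for-sample.
    """
    if rng is None:
        rng = _subject_rng(spec.seed, subject_id)
    effects = tuple(spec.group_effects.get(group, ()))
    lo, hi = PERIOD_BAND_S
    n_samples = int(round(spec.fs * spec.duration_s))

    mean_period = float(np.clip(
        rng.normal(spec.mean_period_s, spec.subject_period_sd), lo + 0.05, hi - 0.05))
    lengths = []
    total = 0
    while total < n_samples:
        p = float(np.clip(rng.normal(mean_period, spec.period_jitter_sd), lo, hi))
        L = max(MIN_CYCLE_SAMPLES, int(round(p * spec.fs)))
        lengths.append(L)
        total += L
    lengths = np.array(lengths)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])

    channels: dict[str, np.ndarray] = {}
    templates: dict[str, CycleTemplate] = {}
    for ch in CHANNELS:
        # systolic landmark times are nearly rate-insensitive in seconds
        # (ejection time varies far less than the heart period), so the
        # systolic knots keep their absolute timing while diastole absorbs
        # the subject's period; reference timing is defined at the cohort
        # mean period
        scale = spec.mean_period_s / mean_period
        knots = [(r, t * scale if r in ("peak", "dip", "tidal", "notch",
                                        "dicrotic") else t, v)
                 for r, t, v in DEFAULT_KNOTS]
        knots = _apply_effects_to_knots(knots, effects, ch, mean_period)
        knots = _subject_knots(rng, spec, base=knots,
                               period_s=mean_period)
        gain = spec.amplitude * np.exp(rng.normal(0.0, spec.channel_gain_sd))
        tpl = landmark_template(knots, amplitude=gain)
        # independent per-harmonic morphological variability: subjects differ
        # in every shape detail, not only in the landmark positions, and the
        # higher harmonics of real pulses are progressively less stable
        if spec.harmonic_amp_jitter > 0 or spec.harmonic_phase_jitter > 0:
            k = np.arange(1, N_HARMONICS + 1)
            # redraw until the jittered shape is still a plausible pulse
            # (no pre-systolic dip: a real foot rises promptly to the peak)
            for _ in range(20):
                amp = np.exp(rng.normal(0.0, 1.0, N_HARMONICS)
                             * spec.harmonic_amp_jitter * np.sqrt(k))
                phi = (rng.normal(0.0, 1.0, N_HARMONICS)
                       * spec.harmonic_phase_jitter * k)
                a, b = tpl.a * amp, tpl.b * amp
                a, b = (a * np.cos(phi) - b * np.sin(phi),
                        b * np.cos(phi) + a * np.sin(phi))
                a, b = _realign_foot(a, b)
                if _prompt_rise(a, b):
                    break
            tpl = CycleTemplate(a0=tpl.a0, a=a, b=b)
        tpl = _apply_effects_to_template(tpl, effects, ch)
        templates[ch] = tpl

        x = np.concatenate([tpl.render(L) for L in lengths])[:n_samples]
        if spec.wander_amp > 0:
            t = np.arange(n_samples) / spec.fs
            phase = rng.uniform(0, 2 * np.pi)
            x = x + spec.wander_amp * np.sin(2 * np.pi * spec.wander_freq_hz * t + phase)
        if spec.noise_sd > 0:
            x = x + rng.normal(0.0, spec.noise_sd, size=n_samples)
        channels[ch] = x

    in_record = starts < n_samples
    truth = GroundTruth(onsets=starts[in_record].astype(int),
                        lengths=lengths[in_record].astype(int),
                        periods_s=lengths[in_record] / spec.fs,
                        templates=templates)
    rec = PulseRecording(subject_id=subject_id, group=group, fs=spec.fs,
                         channels=channels)
    return rec, truth


def generate_cohort(spec: SyntheticCohortSpec
                    ) -> tuple[CohortManifest, list[PulseRecording], list[GroundTruth]]:
    """Generate all recordings of a cohort in memory, manifest included."""
    rows, recs, truths = [], [], []
    for group, prefix, n in (("healthy", "H", spec.n_healthy),
                             ("fld", "F", spec.n_fld),
                             ("cirrhosis", "C", spec.n_cirrhosis)):
        for i in range(n):
            sid = f"{prefix}{i + 1:03d}"
            rec, truth = generate_recording(spec, group, sid)
            rows.append({"subject_id": sid, "group": group,
                         "file": f"{sid}.csv", "fs": spec.fs})
            recs.append(rec)
            truths.append(truth)
    manifest = CohortManifest(table=pd.DataFrame(rows))
    return manifest, recs, truths


def write_cohort(spec: SyntheticCohortSpec, outdir) -> CohortManifest:
    """Generate a cohort and write waveforms, manifest and ground truth."""
    outdir = Path(outdir)
    (outdir / "waveforms").mkdir(parents=True, exist_ok=True)
    manifest, recs, truths = generate_cohort(spec)
    manifest.table["file"] = ["waveforms/" + f for f in manifest.table["file"]]
    for rec, row in zip(recs, manifest.table.itertuples()):
        write_recording(rec, outdir / row.file)
    write_manifest(manifest, outdir / "manifest.csv")

    onset_rows = []
    tpl_rows = []
    for rec, truth in zip(recs, truths):
        for i, (o, L) in enumerate(zip(truth.onsets, truth.lengths)):
            onset_rows.append({"subject_id": rec.subject_id, "cycle": i,
                               "onset": int(o), "length": int(L)})
        for ch, tpl in truth.templates.items():
            row = {"subject_id": rec.subject_id, "channel": ch, "a0": tpl.a0}
            for k in range(N_HARMONICS):
                row[f"a{k + 1}"] = tpl.a[k]
                row[f"b{k + 1}"] = tpl.b[k]
            tpl_rows.append(row)
    pd.DataFrame(onset_rows).to_csv(outdir / "truth_onsets.csv", index=False)
    pd.DataFrame(tpl_rows).to_csv(outdir / "truth_templates.csv", index=False)
    with open(outdir / "spec.json", "w") as fh:
        json.dump({k: v for k, v in dataclasses.asdict(spec).items()
                   if k != "group_effects"}
                  | {"group_effects": {g: [dataclasses.asdict(e) for e in eff]
                                       for g, eff in spec.group_effects.items()}},
                  fh, indent=2)
    return manifest
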