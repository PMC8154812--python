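"""Synthetic LVAD sound generator with exhaustive ground truth.

Emulates the acoustic structure of an axial-flow pump heard through the chest
wall: a harmonic stack at the impeller rotation frequency f0 = rpm/60, the
intermittent-low-speed (ILS) protocol (speed drop to ~7000 rpm for 8 s every
64 s so the native aortic valve can open), cardiac frequency modulation of
the fundamental (the pump speed wobbles at the heart rate as preload swings),
respiratory amplitude modulation, and band-limited non-harmonic noise.

The generator is the study-conditions oracle: every planted parameter is
echoed in a :class:`GroundTruth` sidecar so downstream extraction can be
scored against it.  AR(+) recordings differ from AR(-) recordings through
per-class parameter distributions patterned on the clinical cohort contrasts
(lower ILS speed, smaller ILS amplitude variation, slightly weaker first
harmonic, larger normal-rotation amplitude variation).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.fft as sfft

from .dsp import Recording, write_wav
from .errors import EmptyCohortError, ParameterError

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


@dataclass
class PumpSoundParams:
    """Everything that defines one synthetic pump-sound recording.

    Units: rpm for speeds, seconds for times/durations, Hz for frequency
    deviations, beats (breaths) per minute for physiologic rates.  Amplitude
    modulation depths are dimensionless fractions of the carrier amplitude;
    ``band_noise_levels`` are noise amplitudes for the low/middle/high bands
    relative to the first-harmonic amplitude (the bands are delimited by the
    fundamental and the second harmonic).
    """

    normal_rpm: float = 10000.0
    ils_rpm: float = 7000.0
    ils_duration: float = 8.0
    ils_period: float = 64.0
    ils_offset: float = 30.0          # start of the first ILS window
    ramp_time: float = 1.0            # raised-cosine speed ramp, centred on boundaries
    n_harmonics: int = 3
    harmonic_amplitudes: tuple = (1.0, 0.13, 0.16)
    heart_rate: float = 84.0
    freq_mod_depth: float = 4.2       # Hz, peak deviation of f0 at cardiac rate
    ils_freq_mod_depth: float = 5.5   # Hz, same during ILS
    resp_rate: float = 20.0
    amp_mod_depth: float = 0.079      # fractional AM at respiratory rate
    ils_amp_mod_depth: float = 0.043  # fractional AM at cardiac rate during ILS
    # low / middle / high band noise, relative to the first-harmonic
    # amplitude; preserves the clinical low > middle > high ordering at a
    # level where all 19 features stay measurable within two ILS cycles
    band_noise_levels: tuple = (0.12, 0.048, 0.02)
    duration: float = 128.0
    sample_rate: float = 40000.0
    seed: int = 0

    def __post_init__(self):
        self.harmonic_amplitudes = tuple(float(a) for a in self.harmonic_amplitudes)
        self.band_noise_levels = tuple(float(v) for v in self.band_noise_levels)

    def validate(self) -> None:
        if not self.ils_rpm < self.normal_rpm:
            raise ParameterError("ils_rpm", "must be below normal_rpm")
        if not 0 < self.ils_duration < self.ils_period:
            raise ParameterError("ils_duration", "must satisfy 0 < ils_duration < ils_period")
        if not 0.5 < self.heart_rate / 60.0 < 3.0:
            raise ParameterError("heart_rate", "must correspond to 0.5-3 Hz")
        if not self.resp_rate / 60.0 < 0.5:
            raise ParameterError("resp_rate", "must correspond to < 0.5 Hz")
        if self.duration < self.ils_period:
            raise ParameterError("duration", "must cover at least one ILS cycle")
        if self.n_harmonics < 1:
            raise ParameterError("n_harmonics", "must be >= 1")
        if len(self.harmonic_amplitudes) != self.n_harmonics:
            raise ParameterError("harmonic_amplitudes",
                                 f"needs {self.n_harmonics} entries")
        if any(a < 0 for a in self.harmonic_amplitudes):
            raise ParameterError("harmonic_amplitudes", "must be non-negative")
        if any(v < 0 for v in self.band_noise_levels) or len(self.band_noise_levels) != 3:
            raise ParameterError("band_noise_levels", "three non-negative values")
        if self.sample_rate <= 2.0 * self.n_harmonics * self.normal_rpm / 60.0:
            raise ParameterError("sample_rate",
                                 "must exceed twice the highest harmonic frequency")
        if not 0 <= self.amp_mod_depth < 1 or not 0 <= self.ils_amp_mod_depth < 1:
            raise ParameterError("amp_mod_depth", "modulation depths must be in [0, 1)")
        if self.freq_mod_depth < 0 or self.ils_freq_mod_depth < 0:
            raise ParameterError("freq_mod_depth", "must be non-negative")
        if self.ils_offset < self.ramp_time / 2:
            raise ParameterError("ils_offset", "first ILS ramp would precede t=0")

    def ils_segments(self) -> list[tuple[float, float]]:
        """Nominal (start, end) of every ILS window fully inside the recording."""
        out = []
        s = self.ils_offset
        while s + self.ils_duration + self.ramp_time / 2 <= self.duration:
            out.append((s, s + self.ils_duration))
            s += self.ils_period
        return out


@dataclass
class GroundTruth:
    """Planted parameters + derived ILS boundaries + class label."""

    params: PumpSoundParams
    ils_segment_boundaries: list
    ar_label: int = 0

    def __post_init__(self):
        self.ils_segment_boundaries = [tuple(float(v) for v in seg)
                                       for seg in self.ils_segment_boundaries]
        d = self.params.duration
        last_end = -np.inf
        for s, e in self.ils_segment_boundaries:
            if not (0 <= s < e <= d):
                raise ParameterError("ils_segment_boundaries",
                                     "segments must lie within [0, duration]")
            if s < last_end:
                raise ParameterError("ils_segment_boundaries",
                                     "segments must be disjoint and ordered")
            last_end = e


def _ils_envelope(t: np.ndarray, params: PumpSoundParams) -> np.ndarray:
    """Smooth 0->1 pulse train: 1 inside ILS windows, raised-cosine ramps
    of width ``ramp_time`` centred on each nominal boundary."""
    w = np.zeros_like(t)
    r = params.ramp_time
    for s, e in params.ils_segments():
        if r > 0:
            rise = (t >= s - r / 2) & (t < s + r / 2)
            w[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - (s - r / 2)) / r))
            fall = (t >= e - r / 2) & (t < e + r / 2)
            w[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - (e - r / 2)) / r))
            w[(t >= s + r / 2) & (t < e - r / 2)] = 1.0
        else:
            w[(t >= s) & (t < e)] = 1.0
    return w


def _band_noise(n: int, fs: float, f1: float, levels: tuple,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary noise shaped into the three bands delimited by the
    fundamental and second harmonic; each band scaled to the requested
    RMS amplitude (brick-wall edges in the frequency domain)."""
    white = rng.standard_normal(n)
    spec = sfft.rfft(white)
    freqs = sfft.rfftfreq(n, 1.0 / fs)
    nyq = fs / 2.0
    edges = [(20.0, f1), (f1, 2 * f1), (2 * f1, min(2000.0, nyq))]
    out = np.zeros(n)
    for (lo, hi), level in zip(edges, levels):
        if level <= 0 or hi <= lo:
            continue
        band = (freqs >= lo) & (freqs < hi)
        frac = band.sum() / freqs.size
        if frac == 0:
            continue
        shaped = np.zeros_like(spec)
        shaped[band] = spec[band]
        out += (level / np.sqrt(frac)) * sfft.irfft(shaped, n)
    return out


def simulate_recording(params: PumpSoundParams,
                       recording_id: str = "synthetic",
                       ar_label: int = 0) -> tuple[Recording, GroundTruth]:
    """Render one synthetic recording and its ground truth.

    The waveform is ``env(t) * sum_k a_k sin(k * phi(t)) + noise`` with
    ``phi(t) = 2*pi * integral of f0``; frequency modulation enters through
    the phase integral (phase-continuous), never by naive frequency
    multiplication.  Modulator phases are fixed at zero so the envelope and
    instantaneous frequency are exactly reconstructible from the ground
    truth; harmonic and noise phases are drawn from the seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sample_rate))
    fs = params.sample_rate
    t = np.arange(n) / fs

    w = _ils_envelope(t, params)
    rpm_t = params.normal_rpm - (params.normal_rpm - params.ils_rpm) * w
    fm_depth = (params.freq_mod_depth
                + (params.ils_freq_mod_depth - params.freq_mod_depth) * w)
    f_heart = params.heart_rate / 60.0
    f_resp = params.resp_rate / 60.0
    f0 = rpm_t / 60.0 + fm_depth * np.sin(TWO_PI * f_heart * t)
    phase = TWO_PI * np.cumsum(f0) / fs

    harm_phases = rng.uniform(0, TWO_PI, params.n_harmonics)
    carrier = np.zeros(n)
    for k in range(1, params.n_harmonics + 1):
        a = params.harmonic_amplitudes[k - 1]
        if a > 0:
            carrier += a * np.sin(k * phase + harm_phases[k - 1])

    env = (1.0 + params.amp_mod_depth * np.sin(TWO_PI * f_resp * t)) * \
          (1.0 + params.ils_amp_mod_depth * w * np.sin(TWO_PI * f_heart * t))
    x = env * carrier

    a1 = params.harmonic_amplitudes[0]
    if a1 > 0 and any(v > 0 for v in params.band_noise_levels):
        x = x + a1 * _band_noise(n, fs, params.normal_rpm / 60.0,
                                 params.band_noise_levels, rng)

    rec = Recording(x, fs, recording_id=recording_id, ar_label=ar_label)
    gt = GroundTruth(params=params, ils_segment_boundaries=params.ils_segments(),
                     ar_label=ar_label)
    return rec, gt


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

#: per-class clinical feature statistics, (mean, sd) keyed by feature name,
#: values for the AR(-) and AR(+) classes.  These drive both the parametric
#: feature-table sampler and (for the fields the generator owns) the audio
#: cohort's per-recording parameter draws.
CLASS_FEATURE_STATS = {
    "f1_hz":              ((163.0, 15.0), (165.0, 16.0)),
    "f2_hz":              ((326.0, 41.0), (328.0, 32.0)),
    "f3_hz":              ((487.0, 34.0), (493.0, 43.0)),
    "freq_var_h1_hz":     ((4.2, 5.0), (3.9, 3.8)),
    "freq_var_h2_hz":     ((24.0, 22.0), (16.0, 13.0)),
    "freq_var_h3_hz":     ((3.1, 9.0), (1.5, 2.9)),
    "amp_h1_au":          ((63.0, 15.0), (60.0, 17.0)),
    "amp_h2_au":          ((8.4, 9.8), (7.9, 7.3)),
    "amp_h3_au":          ((10.0, 11.0), (8.0, 8.0)),
    "amp_var_h1_au":      ((7.1, 5.3), (7.6, 3.4)),
    "nonharm_low_au":     ((6.6, 7.8), (6.2, 2.7)),
    "nonharm_mid_au":     ((4.4, 3.1), (3.7, 2.2)),
    "nonharm_high_au":    ((1.2, 1.4), (0.9, 0.9)),
    "normal_rpm":         ((10033.0, 809.0), (10170.0, 514.0)),
    "ils_freq_var_h1_hz": ((5.5, 4.9), (5.6, 5.3)),
    "ils_amp_var_h1_au":  ((3.9, 3.5), (2.5, 2.1)),
    "ils_rpm":            ((7440.0, 904.0), (7072.0, 1001.0)),
    "heart_rate_bpm":     ((84.0, 14.0), (79.0, 13.0)),
    "resp_rate_per_min":  ((20.0, 10.0), (20.0, 6.0)),
}

#: a.u.-to-modulation-depth conversion used to map the cohort's amplitude
#: variation statistics (a.u.) onto generator AM depths: the first-harmonic
#: ridge sits near 90 a.u. on a normalized default map.
_AU_PER_DEPTH = 90.0

#: generator parameters planted per class in audio cohorts:
#: field -> ((neg mean, neg sd), (pos mean, pos sd), (clip lo, clip hi))
COHORT_PARAM_STATS = {
    "normal_rpm": ((10033.0, 809.0), (10170.0, 514.0), (8000.0, 12000.0)),
    "ils_rpm": ((7440.0, 904.0), (7072.0, 1001.0), (6200.0, 7900.0)),
    "heart_rate": ((84.0, 14.0), (79.0, 13.0), (45.0, 150.0)),
    "resp_rate": ((20.0, 10.0), (20.0, 6.0), (8.0, 29.0)),
    "freq_mod_depth": ((4.2, 5.0), (3.9, 3.8), (1.0, 15.0)),
    "ils_freq_mod_depth": ((5.5, 4.9), (5.6, 5.3), (1.0, 15.0)),
    # floor at 3% AM: every patient breathes, and a sub-1 a.u. respiratory
    # swing is below anything the clinical table reports
    "amp_mod_depth": ((7.1 / _AU_PER_DEPTH, 5.3 / _AU_PER_DEPTH),
                      (7.6 / _AU_PER_DEPTH, 3.4 / _AU_PER_DEPTH),
                      (0.03, 0.35)),
    "ils_amp_mod_depth": ((3.9 / _AU_PER_DEPTH, 3.5 / _AU_PER_DEPTH),
                          (2.5 / _AU_PER_DEPTH, 2.1 / _AU_PER_DEPTH),
                          (0.005, 0.30)),
}


@dataclass
class CohortSpec:
    """A labeled cohort of synthetic recordings.

    ``param_stats`` maps generator fields to per-class (mean, sd) pairs plus
    clip bounds; defaults follow the clinical cohort contrasts.
    ``effect_multiplier`` scales the AR-vs-non-AR mean shifts (0 removes the
    class effect entirely — used for ablation and null experiments).
    """

    n_recordings: int = 245
    ar_prevalence: float = 26.0 / 245.0
    base_params: PumpSoundParams = field(default_factory=PumpSoundParams)
    param_stats: dict = field(default_factory=lambda: dict(COHORT_PARAM_STATS))
    effect_multiplier: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_recordings <= 0:
            raise EmptyCohortError("n_recordings must be positive")
        if not 0.0 <= self.ar_prevalence <= 1.0:
            raise ParameterError("ar_prevalence", "must be in [0, 1]")
        for name, ((m0, s0), (m1, s1), _clip) in self.param_stats.items():
            if s0 < 0 or s1 < 0:
                raise ParameterError(name, "standard deviations must be >= 0")


def _draw_params(spec: CohortSpec, label: int,
                 rng: np.random.Generator, seed: int) -> PumpSoundParams:
    p = dataclasses.replace(spec.base_params, seed=seed)
    for name, ((m0, s0), (m1, s1), (lo, hi)) in spec.param_stats.items():
        mean = m0 + spec.effect_multiplier * (m1 - m0) if label else m0
        sd = s1 if label else s0
        val = float(np.clip(rng.normal(mean, sd), lo, hi))
        setattr(p, name, val)
    # keep the protocol invariant ils_rpm < normal_rpm under extreme draws
    if p.ils_rpm >= p.normal_rpm - 500:
        p.ils_rpm = p.normal_rpm - 500
    return p


def simulate_cohort(spec: CohortSpec, render_audio: bool = True
                    ) -> tuple[list[Recording | None], list[GroundTruth]]:
    """Generate a labeled cohort.

    The number of AR(+) recordings is round(n * prevalence), assigned to
    deterministically shuffled positions.  Per-recording seeds are derived
    from the root seed by counter, so cohorts are reproducible and any
    single recording can be regenerated in isolation.  With
    ``render_audio=False`` only parameters and ground truth are produced
    (recordings list holds ``None``), which is cheap at large n.
    """
    spec.validate()
    n_pos = int(round(spec.n_recordings * spec.ar_prevalence))
    labels = np.zeros(spec.n_recordings, dtype=int)
    labels[:n_pos] = 1
    rng = np.random.default_rng([spec.seed, 0xC0F])
    rng.shuffle(labels)

    recordings, truths = [], []
    for i, label in enumerate(labels):
        sub = np.random.default_rng([spec.seed, i])
        sub_seed = int(sub.integers(0, 2**31 - 1))
        params = _draw_params(spec, int(label), sub, sub_seed)
        rid = f"rec{i:04d}"
        if render_audio:
            rec, gt = simulate_recording(params, recording_id=rid,
                                         ar_label=int(label))
        else:
            params.validate()
            rec = None
            gt = GroundTruth(params=params,
                             ils_segment_boundaries=params.ils_segments(),
                             ar_label=int(label))
        recordings.append(rec)
        truths.append(gt)
    return recordings, truths


def sample_feature_table(n: int = 245, ar_prevalence: float = 26.0 / 245.0,
                         seed: int = 0, effect_multiplier: float = 1.0,
                         stats: dict | None = None) -> pd.DataFrame:
    """Draw a ready-made feature table from the per-class feature statistics.

    Parametric counterpart of running the full audio pipeline over a cohort:
    each of the 19 features is drawn from its class-conditional Gaussian
    (clipped at zero for non-negative quantities).  Used for modeling-scale
    experiments where rendering and analyzing hundreds of recordings would
    dominate the cost without changing what is being tested.
    """
    if n <= 0:
        raise EmptyCohortError("n must be positive")
    stats = stats or CLASS_FEATURE_STATS
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * ar_prevalence))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    cols = {}
    for name, ((m0, s0), (m1, s1)) in stats.items():
        m1_eff = m0 + effect_multiplier * (m1 - m0)
        mean = np.where(labels == 1, m1_eff, m0)
        sd = np.where(labels == 1, s1, s0)
        vals = rng.normal(mean, sd)
        cols[name] = np.maximum(vals, 0.0)
    df = pd.DataFrame(cols)
    df.insert(0, "recording_id", [f"rec{i:04d}" for i in range(n)])
    df["ar_label"] = labels
    return df


# --------------------------------------------------------------------------
# ground-truth sidecars and manifests
# --------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, path) -> None:
    """Serialize ground truth as a JSON sidecar (lossless round-trip)."""
    payload = {
        "params": dataclasses.asdict(gt.params),
        "ils_segment_boundaries": [list(seg) for seg in gt.ils_segment_boundaries],
        "ar_label": int(gt.ar_label),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    params = PumpSoundParams(**payload["params"])
    return GroundTruth(params=params,
                       ils_segment_boundaries=[tuple(s) for s in
                                               payload["ils_segment_boundaries"]],
                       ar_label=int(payload["ar_label"]))


def write_cohort(recordings: list, truths: list, outdir) -> Path:
    """Write WAVs + JSON sidecars + a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["recording_id", "path", "ar_label"])
        for rec, gt in zip(recordings, truths):
            wav = outdir / f"{rec.recording_id}.wav"
            write_wav(rec, wav)
            write_ground_truth(gt, wav.with_suffix(".json"))
            writer.writerow([rec.recording_id, wav.name, int(gt.ar_label)])
    return manifest
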