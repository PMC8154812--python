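"""Harmonic ridge tracking, ILS segmentation and the 19-feature catalogue.

From a normalized scalogram this module tracks the impeller's first three
harmonic ridges, splits the recording into normal-speed and
intermittent-low-speed (ILS) operation, and condenses everything into the
fixed 19-feature vector used for classification:

normal operation  — harmonic frequencies f1..f3 (Hz), frequency-variation
                    amplitudes of harmonics 1-3 (Hz), harmonic amplitudes
                    1-3 (a.u.), amplitude-variation amplitude of harmonic 1
                    (a.u.), non-harmonic band amplitudes low/middle/high
                    (a.u.), rotational speed (rpm);
ILS operation     — frequency-variation amplitude, amplitude-variation
                    amplitude (harmonic 1), rotational speed (rpm);
physiology        — heart rate (bpm, from the 0.7-3 Hz peak of the
                    fundamental's frequency fluctuation spectrum) and
                    respiratory rate (per minute, from the <0.5 Hz peak of
                    its amplitude fluctuation spectrum).

"Variation amplitude" means the amplitude of the dominant non-DC peak of the
fluctuation spectrum of a tracked component — the quantity a strong
physiologic modulation produces — not an RMS or peak-to-peak range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy import signal

from .dsp import (DEFAULT_Q, Recording, TimeFrequencyMap, bandlimit,
                  default_freq_grid, gabor_scalogram, normalize_amplitude)
from .errors import (DegenerateInputError, InsufficientDataError,
                     ParameterError, UnanalyzableRecordingError)

logger = logging.getLogger(__name__)

#: the fixed catalogue order of the 19 features
FEATURE_NAMES = (
    "f1_hz", "f2_hz", "f3_hz",
    "freq_var_h1_hz", "freq_var_h2_hz", "freq_var_h3_hz",
    "amp_h1_au", "amp_h2_au", "amp_h3_au",
    "amp_var_h1_au",
    "nonharm_low_au", "nonharm_mid_au", "nonharm_high_au",
    "normal_rpm",
    "ils_freq_var_h1_hz", "ils_amp_var_h1_au", "ils_rpm",
    "heart_rate_bpm", "resp_rate_per_min",
)

ILS_FEATURES = ("ils_freq_var_h1_hz", "ils_amp_var_h1_au", "ils_rpm")


def rpm_to_hz(rpm: float) -> float:
    """Rotational speed to acoustic fundamental: Hz = rpm / 60."""
    if np.any(np.asarray(rpm) < 0):
        raise ParameterError("rpm", "must be non-negative")
    return rpm / 60.0


def hz_to_rpm(hz: float) -> float:
    """Acoustic fundamental to rotational speed: rpm = 60 * Hz."""
    if np.any(np.asarray(hz) < 0):
        raise ParameterError("hz", "must be non-negative")
    return hz * 60.0


@dataclass
class PeakTrack:
    """Instantaneous frequency and amplitude of one tracked spectral ridge.

    Gaps (no credible peak in the search band) are NaN — explicitly marked,
    never silently interpolated.
    """

    times: np.ndarray
    frequency: np.ndarray
    amplitude: np.ndarray
    harmonic_index: int = 1

    def __post_init__(self):
        if not (len(self.times) == len(self.frequency) == len(self.amplitude)):
            raise ParameterError("track", "times/frequency/amplitude lengths differ")

    @property
    def time_step(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else np.nan

    @property
    def gap_fraction(self) -> float:
        return float(np.mean(np.isnan(self.frequency)))


@dataclass
class SegmentLabeling:
    """Ordered, non-overlapping (start, end, kind) segments; kind in
    {"normal", "ILS", "transition"}."""

    segments: list

    def of_kind(self, kind: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, k in self.segments if k == kind]

    @property
    def ils_segments(self) -> list[tuple[float, float]]:
        return self.of_kind("ILS")

    @property
    def normal_segments(self) -> list[tuple[float, float]]:
        return self.of_kind("normal")


@dataclass
class FluctuationSpectrum:
    """Amplitude spectrum (0 to ~5 Hz) of a tracked component's time course.

    Units follow the input: Hz for frequency tracks, a.u. for amplitude
    tracks.  Scaled so a pure sinusoidal modulation of peak deviation D shows
    a peak of amplitude D.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        if np.any(self.amplitudes < 0):
            raise ParameterError("amplitudes", "must be non-negative")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class FeatureVector:
    """The 19 named acoustic features of one recording, in catalogue order.

    Missing features (e.g. no ILS window in the recording) are NaN and
    listed in ``missing`` — never zero-filled.
    """

    values: dict
    missing: tuple = ()
    recording_id: str = ""
    ar_label: int | None = None

    def __post_init__(self):
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ParameterError("values", "must contain exactly the 19 catalogue "
                                           "features in order")
        self.missing = tuple(self.missing)

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=float)

    def to_series(self):
        import pandas as pd
        s = pd.Series(self.values, dtype=float)
        s["recording_id"] = self.recording_id
        if self.ar_label is not None:
            s["ar_label"] = self.ar_label
        return s


@dataclass
class FeatureConfig:
    """Tunable extraction parameters (all frequencies in Hz, times in s)."""

    freq_min: float = 20.0
    freq_max: float = 2000.0
    bins_per_octave: int = 48
    time_step: float = 0.01
    q: float = DEFAULT_Q
    rpm_hint_range: tuple = (6300.0, 12800.0)
    min_normal_rpm: float = 8000.0
    ils_protocol: tuple = (7000.0, 8.0, 64.0)   # (rpm, duration s, period s)
    min_dwell: float = 2.0                      # minimum ILS dwell time
    boundary_guard: float = 0.75                # excluded around segment edges
    hr_band: tuple = (0.7, 3.0)                 # cardiac search band
    rr_band: tuple = (0.08, 0.5)                # respiratory search band
    fluct_band: tuple = (0.08, 3.0)             # generic variation search band
    ils_fluct_band: tuple = (0.6, 3.0)
    min_segment: float = 10.0                   # fluctuation analysis, normal
    ils_min_segment: float = 4.0                # fluctuation analysis, ILS
    track_floor_au: float = 0.5                 # ridge acceptance floor
    track_snr: float = 2.0
    peak_snr: float = 4.0                       # fluctuation peak vs spectrum median
    hr_min_amp: float = 0.5                     # Hz, minimum credible FM deviation
    rr_min_amp: float = 1.0                     # a.u., minimum credible AM amplitude
    compensate_smoothing: bool = True


# --------------------------------------------------------------------------
# ridge tracking
# --------------------------------------------------------------------------

def _quad_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three (x, y) points (unequal spacing).

    For a Gaussian ridge sampled in log-amplitude this is exact, which is
    what makes sub-bin frequency refinement unbiased on a log grid.
    """
    d1 = (y[1] - y[0]) / (x[1] - x[0])
    d2 = (y[2] - y[1]) / (x[2] - x[1])
    a = (d2 - d1) / (x[2] - x[0])
    if a >= 0:  # not a local maximum: keep the grid point
        return float(x[1]), float(y[1])
    xv = 0.5 * (x[0] + x[1]) - d1 / (2 * a)
    yv = y[0] + d1 * (xv - x[0]) + a * (xv - x[0]) * (xv - x[1])
    return float(xv), float(yv)


def track_harmonic(tfmap: TimeFrequencyMap,
                   rpm_hint_range: tuple = (6300.0, 12800.0),
                   harmonic_index: int = 1,
                   margin_hz: float = 12.0,
                   floor_au: float = 0.5,
                   snr: float = 2.0,
                   guide: "PeakTrack | None" = None) -> PeakTrack:
    """Track the k-th harmonic ridge of the impeller sound.

    At each time step the ridge is the amplitude argmax inside the harmonic's
    search band, refined by parabolic interpolation of log-amplitude across
    the three neighbouring bins (exact for the bank's Gaussian ridge shape).
    Frames whose best peak is below the acceptance floor (absolute, or
    relative to the in-band median) are marked as gaps.

    Without a ``guide`` the search band is k x the fundamental band implied
    by ``rpm_hint_range`` (widened by a modulation margin).  With a ``guide``
    (a previously tracked fundamental) the band narrows per frame to
    k x guide frequency +- (2 FWHM + 5 Hz) — hierarchical tracking that keeps
    higher harmonics from locking onto a neighbouring ridge when noise
    momentarily favours it.
    """
    if harmonic_index < 1:
        raise ParameterError("harmonic_index", "must be >= 1")
    k = harmonic_index
    lo = k * (rpm_hint_range[0] / 60.0 - margin_hz)
    hi = k * (rpm_hint_range[1] / 60.0 + margin_hz)
    freqs = tfmap.frequencies
    band = np.flatnonzero((freqs >= lo) & (freqs <= hi))
    if band.size < 3:
        raise ParameterError("rpm_hint_range",
                             "search band covers fewer than 3 grid bins")
    scale = tfmap.amplitudes.max()
    floor = floor_au if tfmap.normalized else floor_au / 100.0 * scale

    sub = tfmap.amplitudes[band, :]
    bf = freqs[band]
    if guide is None:
        j = np.argmax(sub, axis=0)
    else:
        centers = k * guide.frequency
        half = 2.0 * tfmap.fwhm(np.nanmedian(centers)) + 5.0
        j = np.full(sub.shape[1], -1)
        for c in range(sub.shape[1]):
            if not np.isfinite(centers[c]):
                continue
            local = np.flatnonzero(np.abs(bf - centers[c]) <= half)
            if local.size:
                j[c] = local[np.argmax(sub[local, c])]
    cols = np.arange(sub.shape[1])
    peak = np.where(j >= 0, sub[j, cols], 0.0)
    med = np.median(sub, axis=0)
    ok = (j >= 0) & (peak > 0) & (peak >= floor) & (peak >= snr * med)

    freq = np.full(sub.shape[1], np.nan)
    amp = np.full(sub.shape[1], np.nan)
    eps = 1e-12
    for c in np.flatnonzero(ok):
        jj = j[c]
        if 0 < jj < band.size - 1:
            xs = bf[jj - 1:jj + 2]
            ys = np.log(sub[jj - 1:jj + 2, c].astype(np.float64) + eps)
            fv, lv = _quad_vertex(xs, ys)
            freq[c] = min(max(fv, bf[0]), bf[-1])
            amp[c] = np.exp(lv)
        else:
            freq[c] = bf[jj]
            amp[c] = peak[c]
    return PeakTrack(times=tfmap.times, frequency=freq, amplitude=amp,
                     harmonic_index=k)


# --------------------------------------------------------------------------
# ILS segmentation
# --------------------------------------------------------------------------

def detect_ils(track: PeakTrack,
               protocol: tuple = (7000.0, 8.0, 64.0),
               min_normal_rpm: float = 8000.0,
               min_dwell: float = 2.0,
               transition_pad: float = 0.75,
               min_separation_hz: float = 8.0) -> SegmentLabeling:
    """Label the recording as normal / ILS / transition operation.

    The low-speed threshold is data-driven: the midpoint of the track's 10th
    and 90th frequency percentiles.  The protocol keeps the pump in its ILS
    window ~1/8 of the time, so with a real speed drop the 10th percentile
    sits on the ILS plateau and the 90th on the normal plateau; actual ILS
    speeds scatter around (and above) the programmed setting, which a fixed
    protocol-based threshold would miss.  When the track shows no bimodality
    (percentile separation below ``min_separation_hz``) the midpoint of the
    programmed ILS and minimum-normal fundamentals is used instead.

    Candidate runs shorter than ``min_dwell`` are discarded (robust to
    cardiac modulation excursions).  A ``transition_pad`` margin on each side
    of every ILS segment is labeled "transition" so ramp frames never
    contaminate per-segment statistics.  If the recording should contain an
    ILS window but none is found, a warning is logged and an all-normal
    labeling returned.
    """
    ils_rpm, ils_duration, ils_period = protocol
    f = track.frequency
    t = track.times
    if f.size < 2:
        raise InsufficientDataError("track too short to segment")
    if np.mean(np.isnan(f)) > 0.5:
        raise InsufficientDataError("fundamental track has >50% gaps")
    dt = track.time_step
    q10, q90 = np.percentile(f[np.isfinite(f)], [10, 90])
    if q90 - q10 > min_separation_hz:
        thr = 0.5 * (q10 + q90)
    else:
        thr = 0.5 * (ils_rpm / 60.0 + min_normal_rpm / 60.0)
    below = np.where(np.isnan(f), False, f < thr)

    segments = []
    edges = np.flatnonzero(np.diff(below.astype(int)))
    starts = [0] if below[0] else []
    starts += [int(i) + 1 for i in edges if not below[i]]
    ends = [int(i) + 1 for i in edges if below[i]]
    if below[-1]:
        ends.append(below.size)
    ils = []
    for s_i, e_i in zip(starts, ends):
        dur = (e_i - s_i) * dt
        if dur >= min_dwell:
            ils.append((t[s_i], t[s_i] + dur))

    span = (t[-1] - t[0]) + dt
    if not ils:
        if span > ils_period:
            logger.warning("no ILS segment found in a %.0f s recording "
                           "(period %.0f s); labeling all-normal", span, ils_period)
        return SegmentLabeling([(float(t[0]), float(t[-1] + dt), "normal")])

    pieces = []
    cursor = float(t[0])
    end_all = float(t[-1] + dt)
    for s, e in ils:
        ts = max(cursor, s - transition_pad)
        te = min(end_all, e + transition_pad)
        if ts > cursor:
            pieces.append((cursor, ts, "normal"))
        if ts < s:
            pieces.append((ts, s, "transition"))
        pieces.append((float(s), float(e), "ILS"))
        if e < te:
            pieces.append((float(e), te, "transition"))
        cursor = te
    if cursor < end_all:
        pieces.append((cursor, end_all, "normal"))
    return SegmentLabeling(pieces)


# --------------------------------------------------------------------------
# fluctuation spectra
# --------------------------------------------------------------------------

def fluctuation_spectrum(values: np.ndarray, time_step: float,
                         min_duration: float = 10.0,
                         max_gap_fraction: float = 0.10,
                         max_freq: float = 5.0,
                         pad_factor: int = 4) -> FluctuationSpectrum:
    """Amplitude spectrum of a uniformly sampled track component.

    Mean-detrended, Hann-windowed, zero-padded FFT, amplitude-scaled by
    2 / sum(window) so a sinusoidal modulation of peak deviation D reads D
    at the modulation frequency.  NaN gaps up to ``max_gap_fraction`` are
    linearly bridged (with a log note); more is an error, as is a component
    shorter than ``min_duration``.
    """
    v = np.asarray(values, dtype=np.float64)
    if time_step <= 0:
        raise ParameterError("time_step", "must be positive")
    if v.size * time_step < min_duration:
        raise InsufficientDataError(
            f"component spans {v.size * time_step:.1f} s < {min_duration} s")
    gaps = np.isnan(v)
    gap_frac = gaps.mean()
    if gap_frac > max_gap_fraction:
        raise InsufficientDataError(
            f"gap fraction {gap_frac:.0%} exceeds {max_gap_fraction:.0%}")
    if gaps.any():
        logger.info("bridging %.1f%% track gaps linearly", 100 * gap_frac)
        idx = np.arange(v.size)
        v = v.copy()
        v[gaps] = np.interp(idx[gaps], idx[~gaps], v[~gaps])
    v = v - v.mean()
    win = signal.windows.hann(v.size, sym=False)
    n_fft = pad_factor * v.size
    spec = np.abs(sfft.rfft(v * win, n_fft)) * (2.0 / win.sum())
    freqs = sfft.rfftfreq(n_fft, time_step)
    keep = freqs <= max_freq
    return FluctuationSpectrum(frequencies=freqs[keep], amplitudes=spec[keep])


def dominant_peak(fs: FluctuationSpectrum, band: tuple,
                  min_amp: float = 0.0, snr: float = 4.0
                  ) -> tuple[float, float]:
    """(frequency, amplitude) of the strongest credible peak within ``band``.

    Parabolic refinement on log-amplitude; returns (nan, nan) when the best
    in-band peak fails the absolute floor or the prominence-vs-median check
    ("missing", rather than a fabricated value).
    """
    mask = (fs.frequencies >= band[0]) & (fs.frequencies <= band[1])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return (np.nan, np.nan)
    j = idx[np.argmax(fs.amplitudes[idx])]
    amp = fs.amplitudes[j]
    noise = np.median(fs.amplitudes[fs.frequencies > fs.frequencies[1]])
    if amp < min_amp or amp < snr * noise:
        return (np.nan, np.nan)
    # a genuine peak is a local maximum; an in-band argmax sitting on the
    # rising skirt of an out-of-band component (e.g. leakage toward DC) has
    # a larger immediate neighbour outside the band and is not credible
    if ((j > 0 and fs.amplitudes[j - 1] > amp)
            or (j < fs.amplitudes.size - 1 and fs.amplitudes[j + 1] > amp)):
        return (np.nan, np.nan)
    if 0 < j < fs.amplitudes.size - 1:
        xs = fs.frequencies[j - 1:j + 2]
        ys = np.log(fs.amplitudes[j - 1:j + 2] + 1e-300)
        fv, lv = _quad_vertex(xs, ys)
        return (fv, float(np.exp(lv)))
    return (float(fs.frequencies[j]), float(amp))


def extract_heart_rate(fs: FluctuationSpectrum, band: tuple = (0.7, 3.0),
                       min_amp: float = 0.5, snr: float = 4.0) -> float:
    """Heart rate (bpm) from the cardiac peak of a frequency-fluctuation
    spectrum; NaN when no sufficiently prominent peak exists."""
    f, _a = dominant_peak(fs, band, min_amp=min_amp, snr=snr)
    return 60.0 * f if np.isfinite(f) else np.nan


def extract_respiratory_rate(fs: FluctuationSpectrum, band: tuple = (0.08, 0.5),
                             min_amp: float = 1.0, snr: float = 4.0) -> float:
    """Respiratory rate (per minute) from the sub-0.5 Hz peak of an
    amplitude-fluctuation spectrum (DC excluded); NaN when missing."""
    f, _a = dominant_peak(fs, band, min_amp=min_amp, snr=snr)
    return 60.0 * f if np.isfinite(f) else np.nan


def smoothing_correction(mod_freq: float, carrier_freq: float,
                         q: float = DEFAULT_Q, cap: float = 3.0) -> float:
    """Undo the wavelet's temporal smoothing of a tracked modulation.

    The Gabor analysis window (sigma_t = q / (2 pi f_carrier)) low-passes the
    ridge's frequency/amplitude time course, attenuating a sinusoidal
    modulation at f_mod by exp(-(2 pi f_mod sigma_t)^2 / 2).  Variation
    amplitudes are multiplied by the inverse factor (capped for safety).
    """
    if not np.isfinite(mod_freq) or not np.isfinite(carrier_freq) or carrier_freq <= 0:
        return 1.0
    z = mod_freq * q / carrier_freq
    return float(min(np.exp(0.5 * z * z), cap))


# --------------------------------------------------------------------------
# band amplitudes
# --------------------------------------------------------------------------

def band_amplitudes(tfmap: TimeFrequencyMap, f1: float, f2: float,
                    time_mask: np.ndarray | None = None,
                    max_harmonic: int = 8,
                    excision_fwhm: float = 2.0) -> tuple[float, float, float]:
    """Mean non-harmonic amplitude in the low / middle / high bands (a.u.).

    Bands: below f1, between f1 and f2, above f2.  A +-``excision_fwhm`` FWHM
    neighbourhood around every harmonic (k*f1 up to ``max_harmonic``, plus f2
    itself) is excised so ridge leakage does not read as noise; at 2 FWHM the
    Gaussian skirt of a full-scale ridge is < 0.01 a.u.  Averaged over the
    supplied time columns (typically normal-operation frames).
    """
    if not np.isfinite(f1):
        return (np.nan, np.nan, np.nan)
    if not np.isfinite(f2):
        f2 = 2.0 * f1
    freqs = tfmap.frequencies
    if time_mask is None:
        time_mask = tfmap.time_mask()
    excise = np.zeros(freqs.size, dtype=bool)
    centers = [k * f1 for k in range(1, max_harmonic + 1)] + [f2]
    for c in centers:
        if c > freqs[-1] * 1.1:
            break
        half = excision_fwhm * tfmap.fwhm(c)
        excise |= (freqs >= c - half) & (freqs <= c + half)
    out = []
    for lo, hi in ((freqs[0], f1), (f1, f2), (f2, freqs[-1] + 1.0)):
        sel = (freqs >= lo) & (freqs < hi) & ~excise
        if not sel.any() or not time_mask.any():
            out.append(np.nan)
        else:
            out.append(float(tfmap.amplitudes[np.ix_(sel, time_mask)].mean()))
    return tuple(out)


# --------------------------------------------------------------------------
# full extraction
# --------------------------------------------------------------------------

def _segment_frames(track: PeakTrack, seg: tuple[float, float],
                    guard: float) -> np.ndarray:
    lo, hi = seg[0] + guard, seg[1] - guard
    return (track.times >= lo) & (track.times <= hi)


def _segments_mask(track: PeakTrack, segs: list, guard: float,
                   valid: tuple[float, float]) -> np.ndarray:
    mask = np.zeros(track.times.size, dtype=bool)
    for seg in segs:
        mask |= _segment_frames(track, seg, guard)
    mask &= (track.times >= valid[0]) & (track.times <= valid[1])
    return mask


def _longest(segs: list, valid: tuple[float, float], guard: float
             ) -> tuple[float, float] | None:
    best, best_len = None, 0.0
    for s, e in segs:
        s2, e2 = max(s + guard, valid[0]), min(e - guard, valid[1])
        if e2 - s2 > best_len:
            best, best_len = (s2, e2), e2 - s2
    return best


def _avg_fluct_spectrum(track: PeakTrack, component: str, segs: list,
                        min_duration: float) -> FluctuationSpectrum | None:
    """Fluctuation spectrum averaged over segments (Welch-style).

    Every usable segment is trimmed to the shortest one's frame count so the
    frequency grids coincide; coherent planted modulations keep their
    amplitude while incoherent noise averages down.
    """
    windows = []
    for seg in segs:
        frames = (track.times >= seg[0]) & (track.times <= seg[1])
        vals = getattr(track, component)[frames]
        if vals.size * track.time_step >= min_duration:
            windows.append(vals)
    if not windows:
        return None
    n = min(w.size for w in windows)
    spectra = []
    for w in windows:
        try:
            spectra.append(fluctuation_spectrum(w[:n], track.time_step,
                                                min_duration=min_duration))
        except InsufficientDataError:
            continue
    if not spectra:
        return None
    amps = np.mean([s.amplitudes for s in spectra], axis=0)
    return FluctuationSpectrum(frequencies=spectra[0].frequencies,
                               amplitudes=amps)


def _variation_amplitude(track: PeakTrack, component: str,
                         segs: list, cfg: FeatureConfig,
                         band: tuple, min_duration: float,
                         carrier: float) -> float:
    fs = _avg_fluct_spectrum(track, component, segs, min_duration)
    if fs is None:
        return np.nan
    f, a = dominant_peak(fs, band, snr=cfg.peak_snr)
    if not np.isfinite(a):
        return np.nan
    if cfg.compensate_smoothing:
        a *= smoothing_correction(f, carrier, cfg.q)
    return a


def extract_features(rec: Recording,
                     config: FeatureConfig | None = None
                     ) -> FeatureVector:
    """Run the full per-recording analysis and return the 19-feature vector.

    Pipeline: band-limit -> Gabor scalogram -> a.u. normalization ->
    harmonic tracking (harmonics 1-3) -> ILS segmentation -> per-segment
    statistics.  Rotational speeds are derived acoustically (60 x median
    tracked fundamental).  ILS features are NaN (flagged in ``missing``)
    when the recording holds no usable ILS window; an unusable fundamental
    raises :class:`UnanalyzableRecordingError` instead of returning a
    partial result.
    """
    cfg = config or FeatureConfig()
    if rec.duration < 60.0:
        logger.warning("%s: %.0f s recording; >= 60 s preferred",
                       rec.recording_id, rec.duration)

    nyq = rec.sample_rate / 2.0
    high = min(cfg.freq_max, 0.9 * nyq)
    rec_f = bandlimit(rec, cfg.freq_min, high)
    grid = default_freq_grid(cfg.freq_min, min(cfg.freq_max, 0.42 * rec.sample_rate),
                             cfg.bins_per_octave)
    tfmap = gabor_scalogram(rec_f, freq_grid=grid, time_step=cfg.time_step,
                            q=cfg.q)
    try:
        tfmap = normalize_amplitude(tfmap)
    except DegenerateInputError as exc:
        raise UnanalyzableRecordingError(rec.recording_id, str(exc)) from exc

    tr1 = track_harmonic(tfmap, cfg.rpm_hint_range, 1,
                         floor_au=cfg.track_floor_au, snr=cfg.track_snr)
    valid_frames = tfmap.time_mask()
    if np.mean(np.isnan(tr1.frequency[valid_frames])) > 0.5:
        raise UnanalyzableRecordingError(rec.recording_id,
                                         "no fundamental ridge found")
    tracks = {1: tr1}
    for k in (2, 3):
        tracks[k] = track_harmonic(tfmap, cfg.rpm_hint_range, k,
                                   floor_au=cfg.track_floor_au,
                                   snr=cfg.track_snr, guide=tr1)

    labeling = detect_ils(tr1, cfg.ils_protocol, cfg.min_normal_rpm,
                          cfg.min_dwell, cfg.boundary_guard)
    valid = tfmap.valid_time
    normal_mask = _segments_mask(tr1, labeling.normal_segments,
                                 cfg.boundary_guard, valid)
    ils_mask = _segments_mask(tr1, labeling.ils_segments,
                              cfg.boundary_guard, valid)

    vals: dict[str, float] = {}
    with np.errstate(invalid="ignore"):
        harm_freq = {k: float(np.nanmedian(tracks[k].frequency[normal_mask]))
                     if normal_mask.any() else np.nan for k in (1, 2, 3)}
        harm_amp = {k: float(np.nanmedian(tracks[k].amplitude[normal_mask]))
                    if normal_mask.any() else np.nan for k in (1, 2, 3)}
    vals["f1_hz"], vals["f2_hz"], vals["f3_hz"] = (harm_freq[k] for k in (1, 2, 3))

    longest_normal = _longest(labeling.normal_segments, valid, cfg.boundary_guard)
    for k in (1, 2, 3):
        name = f"freq_var_h{k}_hz"
        vals[name] = (_variation_amplitude(tracks[k], "frequency",
                                           [longest_normal], cfg,
                                           cfg.fluct_band, cfg.min_segment,
                                           harm_freq[k])
                      if longest_normal else np.nan)
    vals["amp_h1_au"], vals["amp_h2_au"], vals["amp_h3_au"] = (
        harm_amp[k] for k in (1, 2, 3))
    vals["amp_var_h1_au"] = (_variation_amplitude(tr1, "amplitude",
                                                  [longest_normal], cfg,
                                                  cfg.fluct_band, cfg.min_segment,
                                                  harm_freq[1])
                             if longest_normal else np.nan)

    low, mid, highb = band_amplitudes(tfmap, harm_freq[1], harm_freq[2],
                                      time_mask=normal_mask)
    vals["nonharm_low_au"], vals["nonharm_mid_au"], vals["nonharm_high_au"] = \
        low, mid, highb

    vals["normal_rpm"] = hz_to_rpm(harm_freq[1]) if np.isfinite(harm_freq[1]) else np.nan

    with np.errstate(invalid="ignore"):
        ils_f1 = float(np.nanmedian(tr1.frequency[ils_mask])) if ils_mask.any() else np.nan
    ils_trimmed = [(max(s + cfg.boundary_guard, valid[0]),
                    min(e - cfg.boundary_guard, valid[1]))
                   for s, e in labeling.ils_segments]
    ils_trimmed = [seg for seg in ils_trimmed
                   if seg[1] - seg[0] >= cfg.ils_min_segment]
    if ils_trimmed and np.isfinite(ils_f1):
        fs_ils_f = _avg_fluct_spectrum(tr1, "frequency", ils_trimmed,
                                       cfg.ils_min_segment)
        fs_ils_a = _avg_fluct_spectrum(tr1, "amplitude", ils_trimmed,
                                       cfg.ils_min_segment)
        f_card, a_fm = (dominant_peak(fs_ils_f, cfg.ils_fluct_band,
                                      snr=cfg.peak_snr)
                        if fs_ils_f else (np.nan, np.nan))
        corr = (smoothing_correction(f_card, ils_f1, cfg.q)
                if cfg.compensate_smoothing else 1.0)
        vals["ils_freq_var_h1_hz"] = a_fm * corr if np.isfinite(a_fm) else np.nan
        # amplitude variation is read at the cardiac frequency located on the
        # frequency track: the fast ILS frequency sweeps leave a spurious
        # amplitude component at twice the cardiac rate (ridge-sweep dips)
        # that a plain band argmax would pick up instead
        amp_band = ((f_card - 0.2, f_card + 0.2) if np.isfinite(f_card)
                    else cfg.ils_fluct_band)
        if fs_ils_a is not None:
            f_am, a_am = dominant_peak(fs_ils_a, amp_band, snr=cfg.peak_snr)
            corr_a = (smoothing_correction(f_am, ils_f1, cfg.q)
                      if cfg.compensate_smoothing else 1.0)
            vals["ils_amp_var_h1_au"] = (a_am * corr_a if np.isfinite(a_am)
                                         else np.nan)
        else:
            vals["ils_amp_var_h1_au"] = np.nan
        vals["ils_rpm"] = hz_to_rpm(ils_f1)
    else:
        vals["ils_freq_var_h1_hz"] = np.nan
        vals["ils_amp_var_h1_au"] = np.nan
        vals["ils_rpm"] = np.nan

    if longest_normal is not None:
        frames = (tr1.times >= longest_normal[0]) & (tr1.times <= longest_normal[1])
        try:
            fs_f = fluctuation_spectrum(tr1.frequency[frames], tr1.time_step,
                                        min_duration=cfg.min_segment)
            vals["heart_rate_bpm"] = extract_heart_rate(
                fs_f, cfg.hr_band, min_amp=cfg.hr_min_amp, snr=cfg.peak_snr)
        except InsufficientDataError:
            vals["heart_rate_bpm"] = np.nan
        try:
            fs_a = fluctuation_spectrum(tr1.amplitude[frames], tr1.time_step,
                                        min_duration=cfg.min_segment)
            vals["resp_rate_per_min"] = extract_respiratory_rate(
                fs_a, cfg.rr_band, min_amp=cfg.rr_min_amp, snr=cfg.peak_snr)
        except InsufficientDataError:
            vals["resp_rate_per_min"] = np.nan
    else:
        vals["heart_rate_bpm"] = np.nan
        vals["resp_rate_per_min"] = np.nan

    ordered = {k: float(vals[k]) for k in FEATURE_NAMES}
    missing = tuple(k for k in FEATURE_NAMES if not np.isfinite(ordered[k]))
    return FeatureVector(values=ordered, missing=missing,
                         recording_id=rec.recording_id, ar_label=rec.ar_label)
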