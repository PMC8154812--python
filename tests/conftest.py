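"""Shared fixtures: expensive synthetic recordings and their analyses are
session-scoped so the full 128-s pipeline runs once for the whole suite."""

import pytest

from lvadsound import synthio
from lvadsound.acoustic_features import (FeatureConfig, detect_ils,
                                         extract_features, track_harmonic)
from lvadsound.dsp import bandlimit, gabor_scalogram, normalize_amplitude

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_recording():
    """128-s default recording: 10,000 rpm, ILS 7000 rpm for 8 s every 64 s,
    HR 84 bpm, RR 20/min, moderate band noise."""
    params = synthio.PumpSoundParams(seed=DEFAULT_SEED)
    return synthio.simulate_recording(params, recording_id="default")


@pytest.fixture(scope="session")
def default_features(default_recording):
    rec, _gt = default_recording
    return extract_features(rec)


@pytest.fixture(scope="session")
def default_analysis(default_recording):
    """Normalized scalogram + fundamental track + segmentation of the
    default recording (intermediate pipeline products)."""
    rec, gt = default_recording
    tfmap = normalize_amplitude(gabor_scalogram(bandlimit(rec, 20.0, 2000.0)))
    tr1 = track_harmonic(tfmap)
    labeling = detect_ils(tr1)
    return {"map": tfmap, "track": tr1, "labeling": labeling, "gt": gt}


#: cheap generator settings for recordings that only need the harmonic band
FAST_KW = dict(duration=64.0, sample_rate=10000.0)
FAST_CONFIG = FeatureConfig(freq_max=700.0)


def fast_params(**overrides) -> synthio.PumpSoundParams:
    kw = dict(FAST_KW)
    kw.update(overrides)
    return synthio.PumpSoundParams(**kw)


@pytest.fixture(scope="session")
def recovery_cohort():
    """20 recordings planting the clinical non-AR means for speed, heart and
    respiratory rate exactly (zero spread) and drawing the remaining
    parameters from the cohort distributions; extracted with the
    harmonic-band configuration."""
    stats = dict(synthio.COHORT_PARAM_STATS)
    for name, mean in (("normal_rpm", 10033.0), ("heart_rate", 84.0),
                       ("resp_rate", 20.0)):
        (_m0, _s0), pos, clip = stats[name]
        stats[name] = ((mean, 0.0), pos, clip)
    spec = synthio.CohortSpec(
        n_recordings=20, ar_prevalence=0.0, seed=11,
        base_params=fast_params(), param_stats=stats)
    recordings, truths = synthio.simulate_cohort(spec)
    features = [extract_features(rec, FAST_CONFIG) for rec in recordings]
    return features, truths
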