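import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cardiokit as ck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free 30 s record at 60 bpm: every interval known exactly."""
    return ck.EcgSynthSpec(
        duration_s=30.0, heart_rate_bpm=60.0,
        baseline_amp=0.0, powerline_amp=0.0, white_sigma=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def clean_record(clean_spec):
    return ck.synth_ecg(clean_spec)


@pytest.fixture(scope="session")
def noisy_record():
    """Default-noise record at 72 bpm."""
    spec = ck.EcgSynthSpec(duration_s=30.0, heart_rate_bpm=72.0, seed=11)
    return ck.synth_ecg(spec)


@pytest.fixture(scope="session")
def detected_features(noisy_record):
    """Full pipeline output on the noisy record: cleaned, detected, featured."""
    sig, truth = noisy_record
    clean = ck.clean(sig)
    peaks = ck.detect_rpeaks(clean)
    feats = ck.extract_feature_matrix(clean, peaks)
    return clean, peaks, feats


def match_rate(detected: np.ndarray, truth: np.ndarray, tol: int) -> float:
    """Fraction of true positions with a detection within ±tol samples."""
    if truth.size == 0:
        return 1.0
    return float(np.mean([np.any(np.abs(detected - r) <= tol) for r in truth]))
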