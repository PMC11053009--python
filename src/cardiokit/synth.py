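"""Synthetic ECG records and clinical tables with exact ground truth.

The ECG generator places one beat per entry of an RR schedule and builds
its waveform from additive parametric components: Gaussian P and T waves
and a piecewise-linear (triangular) QRS complex. A parametric morphology
is used instead of a dynamical-model simulator precisely so that every
fiducial index and interval duration is known exactly by construction.
On top of the clean waveform the generator can add the three artefacts an
ambulatory recording shows: low-frequency baseline wander (respiration),
50 Hz powerline pickup, and white measurement noise.

Anomalies are planted per beat: a long RR gap (dropped/escape beat) or a
widened QRS, optionally with a shortened premature RR (the PVC pattern).
Ground-truth labels are obtained by running the rule engine on the
*programmed* intervals, so the generated record and its labels are
consistent by construction (closed loop, independent of any detector).

The clinical generator emulates a 13-attribute heart-disease table:
attributes are drawn within their conventional value sets, the binary
outcome follows a linear score over a known informative subset, and a
chosen number of rows receive planted missing cells.

Wave "widths" are full widths at half maximum (FWHM), matching the
half-amplitude convention of the feature extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beat_rules import classify_beats
from .core import ECGSignal
from .fiducials import FEATURE_COLUMNS

__all__ = ["EcgSynthSpec", "EcgTruth", "synth_ecg", "synth_clinical", "synth_linear_table",
           "ClinicalTruth", "CLINICAL_ATTRIBUTES"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class EcgSynthSpec:
    """Everything needed to generate one synthetic ECG record."""

    fs: float = 360.0
    duration_s: float = 30.0
    heart_rate_bpm: float = 60.0
    # morphology (amplitudes relative to R = 1.0; widths/durations in seconds)
    r_amp: float = 1.0
    q_amp: float = -0.15
    s_amp: float = -0.15
    p_amp: float = 0.15
    p_fwhm_s: float = 0.09
    t_amp: float = 0.30
    t_fwhm_s: float = 0.16
    qrs_base_s: float = 0.10
    pr_s: float = 0.16
    qt_s: float = 0.40
    polarity: int = 1  # -1 inverts the whole lead
    # anomaly plan: beat index -> overrides {"rr_s": ..., "qrs_s": ...}
    anomalies: dict[int, dict[str, float]] = field(default_factory=dict)
    # noise plan
    baseline_amp: float = 0.1
    baseline_hz: float = 0.3
    powerline_amp: float = 0.05
    powerline_hz: float = 50.0
    white_sigma: float = 0.02
    seed: int = 0
    record_id: str = "synth"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        for name in ("r_amp", "q_amp", "s_amp", "p_amp", "t_amp"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class EcgTruth:
    """Programmed ground truth for a generated record."""

    r_indices: np.ndarray
    p_indices: np.ndarray
    q_indices: np.ndarray
    s_indices: np.ndarray
    t_indices: np.ndarray
    features: pd.DataFrame  # programmed per-beat intervals, fpi layout
    labels: list[str]       # rule labels of the programmed intervals


def _rr_schedule(spec: EcgSynthSpec) -> np.ndarray:
    """Beat times (s); anomaly beat i overrides the RR interval ending at i."""
    base_rr = 60.0 / spec.heart_rate_bpm
    margin_left = 0.30
    margin_right = 0.40
    times = [margin_left]
    i = 1
    while True:
        rr = spec.anomalies.get(i, {}).get("rr_s", base_rr)
        t = times[-1] + rr
        if t > spec.duration_s - margin_right:
            break
        times.append(t)
        i += 1
    return np.asarray(times)


def synth_ecg(spec: EcgSynthSpec) -> tuple[ECGSignal, EcgTruth]:
    """Generate one record and its exact ground truth; deterministic per seed."""
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    t_grid = np.arange(n) / fs
    x = np.zeros(n)

    beat_times = _rr_schedule(spec)
    qrs_w = np.full(beat_times.size, spec.qrs_base_s)
    for i, plan in spec.anomalies.items():
        if 0 <= i < beat_times.size and "qrs_s" in plan:
            qrs_w[i] = plan["qrs_s"]
    rr = np.diff(beat_times)
    if rr.size and np.any(rr < qrs_w[1:] + 0.05):
        raise ValueError("infeasible schedule: QRS complexes would overlap")

    sig_p = spec.p_fwhm_s * _FWHM_TO_SIGMA
    sig_t = spec.t_fwhm_s * _FWHM_TO_SIGMA
    eps = 0.01  # QRS baseline take-off/return (s)

    p_idx, q_idx, s_idx, t_idx, r_idx = [], [], [], [], []
    rows = []
    for i, (rt, w) in enumerate(zip(beat_times, qrs_w)):
        q_t, s_t = rt - w / 2, rt + w / 2
        p_t = rt - spec.pr_s
        # programmed QT runs from Q to the T half-amplitude decay point
        t_off_t = q_t + spec.qt_s
        t_c = t_off_t - spec.t_fwhm_s / 2

        # triangular QRS
        knots_t = [q_t - eps, q_t, rt, s_t, s_t + eps]
        knots_v = [0.0, spec.q_amp, spec.r_amp, spec.s_amp, 0.0]
        lo = max(0, int(np.floor((q_t - eps) * fs)))
        hi = min(n, int(np.ceil((s_t + eps) * fs)) + 1)
        x[lo:hi] += np.interp(t_grid[lo:hi], knots_t, knots_v, left=0.0, right=0.0)
        # Gaussian P and T
        for c, a, s_ in ((p_t, spec.p_amp, sig_p), (t_c, spec.t_amp, sig_t)):
            lo_g = max(0, int((c - 5 * s_) * fs))
            hi_g = min(n, int((c + 5 * s_) * fs) + 1)
            x[lo_g:hi_g] += a * np.exp(-0.5 * ((t_grid[lo_g:hi_g] - c) / s_) ** 2)

        r_idx.append(int(round(rt * fs)))
        p_idx.append(int(round(p_t * fs)))
        q_idx.append(int(round(q_t * fs)))
        s_idx.append(int(round(s_t * fs)))
        t_idx.append(int(round(t_c * fs)))
        rr_i = beat_times[i] - beat_times[i - 1] if i > 0 else np.nan
        rows.append(
            (spec.record_id, r_idx[-1], rr_i, w, spec.qt_s, spec.pr_s,
             spec.p_fwhm_s, spec.t_fwhm_s)
        )

    x *= spec.polarity
    rng = np.random.default_rng(spec.seed)
    phase_b, phase_p = rng.uniform(0, 2 * np.pi, size=2)
    if spec.baseline_amp:
        x += spec.baseline_amp * np.sin(2 * np.pi * spec.baseline_hz * t_grid + phase_b)
    if spec.powerline_amp:
        x += spec.powerline_amp * np.sin(2 * np.pi * spec.powerline_hz * t_grid + phase_p)
    if spec.white_sigma:
        x += rng.normal(0.0, spec.white_sigma, size=n)

    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    labels = classify_beats(features)["label"].tolist()
    truth = EcgTruth(
        np.asarray(r_idx), np.asarray(p_idx), np.asarray(q_idx),
        np.asarray(s_idx), np.asarray(t_idx), features, labels,
    )
    return ECGSignal(x, fs, spec.record_id), truth


# ---------------------------------------------------------------------------
# clinical tables

CLINICAL_ATTRIBUTES = {
    # name: (kind, low, high) or (kind, values)
    "age": ("int", 29, 77),
    "sex": ("choice", (0, 1)),
    "cp": ("choice", (1, 2, 3, 4)),
    "trestbps": ("int", 94, 200),
    "chol": ("int", 126, 564),
    "fbs": ("choice", (0, 1)),
    "restecg": ("choice", (0, 1, 2)),
    "thalach": ("int", 71, 202),
    "exang": ("choice", (0, 1)),
    "oldpeak": ("float", 0.0, 6.2),
    "slope": ("choice", (1, 2, 3)),
    "ca": ("choice", (0, 1, 2, 3)),
    "thal": ("choice", (3, 6, 7)),
}

DEFAULT_INFORMATIVE = {
    "cp": 1.0,
    "thalach": -1.0,
    "exang": 0.8,
    "oldpeak": 0.8,
    "slope": 0.6,
    "ca": 1.0,
    "thal": 0.8,
}


@dataclass(frozen=True)
class ClinicalTruth:
    informative: tuple[str, ...]
    coefficients: dict[str, float]
    missing_rows: tuple[int, ...]


def synth_clinical(
    n: int = 303,
    informative: dict[str, float] | None = None,
    missing_rows: int = 33,
    noise_sigma: float = 0.5,
    seed: int = 0,
    outcome: str = "target",
) -> tuple[pd.DataFrame, ClinicalTruth]:
    """Generate a heart-disease-style table with a known informative subset.

    The outcome is 1 where a linear score over the standardized informative
    attributes (plus Gaussian noise of ``noise_sigma``) exceeds zero; with
    an empty ``informative`` mapping the outcome is pure coin-flip noise.
    ``missing_rows`` rows receive one missing predictor cell each.
    """
    if informative is None:
        informative = dict(DEFAULT_INFORMATIVE)
    unknown = set(informative) - set(CLINICAL_ATTRIBUTES)
    if unknown:
        raise ValueError(f"unknown informative attributes: {sorted(unknown)}")
    if not n > len(informative) + 1:
        raise ValueError("need more rows than informative attributes + 1")
    if not 0 <= missing_rows <= n:
        raise ValueError("missing_rows out of range")

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for name, spec_ in CLINICAL_ATTRIBUTES.items():
        if spec_[0] == "int":
            cols[name] = rng.integers(spec_[1], spec_[2] + 1, size=n).astype(float)
        elif spec_[0] == "float":
            cols[name] = np.round(rng.uniform(spec_[1], spec_[2], size=n), 1)
        else:
            cols[name] = rng.choice(spec_[1], size=n).astype(float)
    frame = pd.DataFrame(cols)

    if informative:
        score = np.zeros(n)
        for name, coef in informative.items():
            v = frame[name].to_numpy()
            sd = v.std()
            z = (v - v.mean()) / sd if sd > 0 else v * 0.0
            score += coef * z
        score += rng.normal(0.0, noise_sigma, size=n)
        frame[outcome] = (score > 0).astype(int)
    else:
        frame[outcome] = rng.integers(0, 2, size=n)

    rows = rng.choice(n, size=missing_rows, replace=False)
    predictors = list(CLINICAL_ATTRIBUTES)
    for r in rows:
        frame.loc[r, predictors[rng.integers(len(predictors))]] = np.nan

    truth = ClinicalTruth(
        tuple(sorted(informative)), dict(informative), tuple(sorted(int(r) for r in rows))
    )
    return frame, truth


def synth_linear_table(
    n: int = 150,
    coefs: dict[str, float] | None = None,
    n_noise: int = 4,
    sigma: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Gaussian linear-model data for stepwise-selection studies.

    y = sum_k beta_k * x_k + eps with standard-normal predictors and
    eps ~ N(0, sigma^2); ``n_noise`` additional independent noise
    predictors carry no signal. Returns (X, y, true coefficients).
    """
    if coefs is None:
        coefs = {"x1": 1.0, "x2": -0.8, "x3": 0.6}
    rng = np.random.default_rng(seed)
    names = list(coefs) + [f"noise{j}" for j in range(1, n_noise + 1)]
    X = pd.DataFrame(rng.standard_normal((n, len(names))), columns=names)
    y = X[list(coefs)].to_numpy() @ np.array(list(coefs.values()))
    y = pd.Series(y + rng.normal(0.0, sigma, size=n), name="y")
    return X, y, dict(coefs)
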