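"""Run configuration and record specification.

Every pipeline constant lives here with its conventional default: 360 Hz
sampling, a 0.5 Hz baseline-wander high-pass, a 50 Hz notch, the 5–15 Hz
detector band with a 0.150 s integration window and 0.2 s refractory period,
the 200-sample beat window with 75 samples left of R, the clinical rule
thresholds (1.2 s RR, 0.12–0.20 s QRS and PR, 0.44 s QT), the 80/20 split
and 10-fold cross-validation. A YAML mapping with any subset of the field
names overrides the defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # sampling / filtering
    fs: float = 360.0
    baseline_cutoff_hz: float = 0.5
    notch_hz: float = 50.0
    notch_q: float = 30.0
    # detector (bandpass -> derivative -> square -> integrate)
    band_low_hz: float = 5.0
    band_high_hz: float = 15.0
    integration_window_s: float = 0.150
    refractory_s: float = 0.2
    segment_s: float = 3.0  # segmentation width for thresholding
    # beat window
    window_samples: int = 200
    window_left: int = 75
    # fiducial search; the Q/S radius must exceed half the widest QRS the
    # rules must measure (PVC rule needs QRS > 0.20 s to be observable)
    qs_radius_s: float = 0.15
    pt_guard_s: float = 0.02
    pt_min_rel_amp: float = 0.02
    # clinical rule thresholds (seconds)
    rr_max_s: float = 1.2
    qrs_range_s: tuple[float, float] = (0.12, 0.20)
    qt_max_s: float = 0.44
    pr_range_s: tuple[float, float] = (0.12, 0.20)
    rr_irregular_frac: float = 0.20
    # evaluation
    split_ratio: float = 0.8
    cv_folds: int = 10
    seed: int = 0
    excluded_records: tuple[str, ...] = ("102", "104", "107", "217")
    # stepwise selection tolerances
    p_enter: float = 0.05
    p_exit: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split ratio must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if not 0 <= self.window_left < self.window_samples:
            raise ValueError("left offset must be smaller than the window length")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.p_enter <= self.p_exit:
            raise ValueError("p_enter must not exceed p_exit")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config from a YAML key/value file; missing keys keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a key/value mapping")
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("qrs_range_s", "pr_range_s", "excluded_records"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("qrs_range_s", "pr_range_s", "excluded_records"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass(frozen=True)
class RecordSpec:
    """Where to find one ECG record and how to read it."""

    record_id: str
    signal_path: Path
    fs: float = 360.0
    lead: str = "MLII"
    annotation_path: Path | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal_path", Path(self.signal_path))
        if self.annotation_path is not None:
            object.__setattr__(self, "annotation_path", Path(self.annotation_path))
        if not self.fs > 0:
            raise ValueError("fs must be positive")
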