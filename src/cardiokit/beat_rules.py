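"""Rule-based beat behaviour classification and detection-quality scoring.

Each beat is labelled normal / abnormal / arrhythmic from its interval
features using four clinically grounded rules:

* RR rule       — consecutive R-peaks must not be more than 1.2 s apart;
                  a longer gap marks the beat arrhythmic.
* PVC rule      — a QRS wider than 0.20 s coinciding with an irregular RR
                  pattern marks a premature ventricular contraction
                  (arrhythmic); PVCs show widened, high-amplitude QRS with
                  disturbed timing.
* QRS rule      — QRS duration outside [0.12, 0.20] s is abnormal.
* QT rule       — QT must be below 0.44 s; at or above is abnormal.
* PR rule       — PR outside [0.12, 0.20] s is abnormal.

Precedence is arrhythmic > abnormal > normal: the rhythm-level rules are
checked first because the procedure exists to separate arrhythmic beats,
and the PVC rule needs the joint QRS+RR condition. Range bounds are
inclusive; the RR and QT comparisons are strict, following the rules'
wording ("greater than 1.2 s", "less than 0.44 s").

Detection quality per record is scored from the total beat count N, the
correctly identified beats CB and the missed beats NMB:

    SE%  = 100 * CB / N
    ACC% = 100 * (CB - NMB) / N
    DER% = 100 * (2 * NMB) / N    (a missed beat counts once as a false
                                   negative and once as a false positive)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "classify_beat",
    "classify_beats",
    "rr_irregularity",
    "detection_score",
    "DetectionScore",
]


def rr_irregularity(
    rr_window: list[float] | np.ndarray, current_rr: float, frac: float = 0.20
) -> bool:
    """True when ``current_rr`` deviates from the window median by more than ``frac``.

    ``rr_window`` holds the recent RR history (at least one value).
    """
    rr = np.asarray(rr_window, dtype=float)
    rr = rr[np.isfinite(rr)]
    if rr.size == 0:
        return False
    med = float(np.median(rr))
    if med <= 0:
        return False
    return abs(current_rr - med) / med > frac


def classify_beat(
    features: pd.Series | dict,
    prev_rr_context: list[float] | np.ndarray = (),
    config: RunConfig | None = None,
) -> tuple[str, list[str]]:
    """Label one beat from its interval features (seconds).

    ``features`` must expose RR_s, QRS_s, QT_s, PR_s (NaN where undefined;
    the first beat of a record has no RR and is judged on the remaining
    rules). Returns the label and the identifiers of the triggered rules.

    Raises
    ------
    ValueError
        If every feature is missing (unscorable beat).
    """
    cfg = config or RunConfig()
    get = features.get if hasattr(features, "get") else features.__getitem__

    def _val(name: str) -> float:
        v = get(name)
        return float(v) if v is not None else np.nan

    rr, qrs, qt, pr = (_val(k) for k in ("RR_s", "QRS_s", "QT_s", "PR_s"))
    if all(np.isnan(v) for v in (rr, qrs, qt, pr)):
        raise ValueError("unscorable beat: all interval features missing")

    triggered: list[str] = []
    qrs_lo, qrs_hi = cfg.qrs_range_s
    pr_lo, pr_hi = cfg.pr_range_s

    if np.isfinite(rr) and rr > cfg.rr_max_s:
        triggered.append("rr_long")
    if (
        np.isfinite(qrs)
        and qrs > qrs_hi
        and np.isfinite(rr)
        and rr_irregularity(prev_rr_context, rr, cfg.rr_irregular_frac)
    ):
        triggered.append("pvc")
    if triggered:
        return "arrhythmic", triggered

    if np.isfinite(qrs) and not qrs_lo <= qrs <= qrs_hi:
        triggered.append("qrs_out_of_range")
    if np.isfinite(qt) and not qt < cfg.qt_max_s:
        triggered.append("qt_long")
    if np.isfinite(pr) and not pr_lo <= pr <= pr_hi:
        triggered.append("pr_out_of_range")
    if triggered:
        return "abnormal", triggered
    return "normal", triggered


def classify_beats(
    features: pd.DataFrame, config: RunConfig | None = None, context: int = 8
) -> pd.DataFrame:
    """Label every row of a feature matrix, threading the rolling RR context.

    Returns the input with ``label`` and ``rules`` columns appended; rule
    identifiers are "+"-joined. Exactly one label per beat.
    """
    cfg = config or RunConfig()
    labels, rules = [], []
    rr_hist: list[float] = []
    for _, row in features.iterrows():
        label, trig = classify_beat(row, rr_hist, cfg)
        labels.append(label)
        rules.append("+".join(trig))
        rr = row.get("RR_s")
        if rr is not None and np.isfinite(rr):
            rr_hist.append(float(rr))
            if len(rr_hist) > context:
                rr_hist.pop(0)
    out = features.copy()
    out["label"] = labels
    out["rules"] = rules
    return out


@dataclass(frozen=True)
class DetectionScore:
    n: int
    cb: int
    nmb: int
    se_pct: float
    acc_pct: float
    der_pct: float


def detection_score(n: int, cb: int, nmb: int) -> DetectionScore:
    """Per-record detection quality from beat counts (percentages, 2 decimals)."""
    if n <= 0:
        raise ValueError("total beat count must be positive")
    if not 0 <= nmb <= cb <= n:
        raise ValueError("require 0 <= NMB <= CB <= N")
    se = 100.0 * cb / n
    acc = 100.0 * (cb - nmb) / n
    der = 100.0 * (2 * nmb) / n
    rnd = lambda v: float(np.round(v, 2))  # numpy rounds half to even
    return DetectionScore(n, cb, nmb, rnd(se), rnd(acc), rnd(der))
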