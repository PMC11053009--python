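"""P/Q/S/T localization around each R-peak and the per-beat feature matrix.

Each beat is analysed inside a fixed asymmetric window (default 200 samples
with 75 to the left of R, matched to ~0.55 s at 360 Hz). Q and S are the
signal minima just left and right of R (maxima for inverted beats); P and T
are the most prominent extrema in the remaining left/right portions of the
window, guarded away from the QRS by 20 ms and required to exceed 2% of the
R amplitude. The per-beat feature matrix ("fpi") carries six interval
features in seconds:

    RR   — time since the previous R-peak (defined from the second beat)
    QRS  — S minus Q
    QT   — Q to the T-wave offset (half-amplitude decay point after T)
    PR   — P peak to R peak
    P, T — wave widths between the half-amplitude crossings around the peak

Beats whose window would cross a record boundary are skipped with a
warning rather than zero-padded; absent P/T leave their dependent features
missing (NaN) rather than raising.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import RunConfig
from .core import BeatFiducials, BeatWindow, ECGSignal, RPeakSet
from .rpeak import extract_extrema

__all__ = [
    "extract_beat_window",
    "locate_qs",
    "locate_pt",
    "compute_features",
    "extract_feature_matrix",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["record", "r_sample", "RR_s", "QRS_s", "QT_s", "PR_s", "P_s", "T_s"]


def extract_beat_window(
    signal: ECGSignal, r_index: int, length: int = 200, left: int = 75
) -> BeatWindow:
    """Window of exactly ``length`` samples with R at offset ``left``.

    Raises ValueError when the window would cross the record boundary;
    callers skip such edge beats instead of padding.
    """
    start = r_index - left
    stop = start + length
    if start < 0 or stop > len(signal):
        raise ValueError(
            f"beat window [{start}, {stop}) exceeds signal bounds [0, {len(signal)})"
        )
    return BeatWindow(r_index, start, stop, signal.samples[start:stop])


def locate_qs(window: BeatWindow, fs: float, radius_s: float = 0.15) -> tuple[int, int]:
    """Q and S troughs: extreme values just left and right of R.

    For an upright beat (R amplitude positive relative to the window
    median) Q and S are minima; for an inverted beat the roles swap and
    they are maxima, so inverted records yield the same indices.
    Returned indices are absolute sample positions.
    """
    x = window.samples
    r_off = window.r_offset
    radius = max(1, int(round(radius_s * fs)))
    left_lo = max(0, r_off - radius)
    right_hi = min(x.size, r_off + radius + 1)
    if left_lo >= r_off or r_off + 1 >= right_hi:
        raise ValueError("empty Q/S search interval")
    upright = x[r_off] >= np.median(x)
    pick = np.argmin if upright else np.argmax
    q_off = left_lo + int(pick(x[left_lo:r_off]))
    s_off = r_off + 1 + int(pick(x[r_off + 1 : right_hi]))
    return window.start + q_off, window.start + s_off


def locate_pt(
    window: BeatWindow,
    q: int,
    s: int,
    fs: float,
    guard_s: float = 0.02,
    min_rel_amp: float = 0.02,
) -> tuple[int | None, int | None]:
    """P and T peaks: most prominent extrema outside the QRS guard bands.

    P is searched in [window start, q - guard]; T in [s + guard, window
    stop). P and T share the R wave's polarity, so the winning extremum is
    the one with the largest amplitude *in R's direction* — on a clean
    upright beat this is simply the largest-|amplitude| extremum, but it
    stays robust against the opposite-sign undershoot that high-pass
    filtering leaves around a large QRS, and it makes inverted records
    yield the same indices as upright ones. Either peak is reported absent
    (None) when no extremum exceeds ``min_rel_amp`` times the |R|
    amplitude. Indices are absolute.
    """
    x = window.samples
    guard = int(round(guard_s * fs))
    r_off = window.r_offset
    sign = 1.0 if x[r_off] >= np.median(x) else -1.0
    floor = min_rel_amp * abs(x[r_off])

    def _best(lo_off: int, hi_off: int) -> int | None:
        if hi_off - lo_off < 3:
            return None
        seg = x[lo_off:hi_off]
        try:
            ext = extract_extrema(seg)
        except ValueError:
            return None
        if len(ext) == 0:
            return None
        directed = sign * ext.amplitudes
        best = int(np.argmax(directed))
        if directed[best] <= floor:
            return None
        return window.start + lo_off + int(ext.indices[best])

    p = _best(0, max(0, q - window.start - guard + 1))
    t = _best(min(x.size, s - window.start + guard), x.size)
    return p, t


def _half_amp_bounds(
    x: np.ndarray, peak: int, baseline: float = 0.0, sign: float = 1.0, max_walk: int = 120
) -> tuple[int, int]:
    """Half-amplitude crossing samples around a wave peak.

    The wave height is measured in the beat's polarity direction relative
    to ``baseline`` (the local isoelectric level), and the walk stops where
    the directed height decays below half of it. Capping the walk at
    ``max_walk`` samples per side keeps a wave that never decays
    (pathological overlap) from swallowing its neighbours.
    """
    d = sign * (x - baseline)
    half = d[peak] / 2.0
    lo = peak
    while lo > max(0, peak - max_walk) and d[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi < min(x.size - 1, peak + max_walk) and d[hi + 1] >= half:
        hi += 1
    return lo, hi


def locate_fiducials(
    signal: ECGSignal, window: BeatWindow, config: RunConfig | None = None
) -> BeatFiducials:
    """All five landmarks for one beat, plus wave onset/offset bounds.

    Q and S are measured on the raw window (the QRS is sharp); the P and T
    waves are low-frequency and are localized and measured on a zero-phase
    moving-average smoothed copy (~20 ms) so that sample-level noise does
    not corrupt the half-amplitude crossings. The smoothed segment extends
    past the window's right edge because the T offset may fall there.
    """
    cfg = config or RunConfig(fs=signal.fs)
    fs = signal.fs
    q, s = locate_qs(window, fs, cfg.qs_radius_s)

    x = signal.samples
    k = max(1, int(round(0.02 * fs)))
    pad = int(round(0.3 * fs))
    seg_lo = max(0, window.start - k)
    seg_hi = min(x.size, window.stop + pad + k)
    smooth = ndimage.uniform_filter1d(x[seg_lo:seg_hi], size=k, mode="nearest")

    smooth_window = BeatWindow(
        window.r_index, window.start, window.stop,
        smooth[window.start - seg_lo : window.stop - seg_lo],
    )
    p, t = locate_pt(smooth_window, q, s, fs, cfg.pt_guard_s, cfg.pt_min_rel_amp)
    sign = 1.0 if x[window.r_index] >= np.median(window.samples) else -1.0
    guard = int(round(cfg.pt_guard_s * fs))

    def _iso_level(a: int, b: int) -> float:
        # isoelectric reference from the inter-wave segment [a, b): a low
        # quantile of the directed amplitude, robust to the wave's own flank
        seg = sign * smooth[max(0, a - seg_lo) : max(0, b - seg_lo)]
        if seg.size == 0:
            return 0.0
        return sign * float(np.percentile(seg, 25))

    p_on = p_off = t_on = t_off = None
    if p is not None:
        base_p = _iso_level(p, q - guard)  # PQ segment
        lo, hi = _half_amp_bounds(smooth, p - seg_lo, base_p, sign)
        p_on, p_off = lo + seg_lo, hi + seg_lo
    if t is not None:
        base_t = _iso_level(s + guard, t)  # ST segment
        lo, hi = _half_amp_bounds(smooth, t - seg_lo, base_t, sign)
        t_on, t_off = lo + seg_lo, hi + seg_lo
    return BeatFiducials(
        r=window.r_index, q=q, s=s, p=p, t=t,
        t_offset=t_off, p_onset=p_on, p_offset=p_off, t_onset=t_on,
    )


def compute_features(
    fiducials: list[BeatFiducials], rpeaks: RPeakSet, fs: float
) -> pd.DataFrame:
    """Assemble the per-beat interval feature matrix ("fpi"), all in seconds.

    RR_i = (r_i - r_{i-1}) / fs (NaN for each record's first beat);
    QRS = (s - q)/fs; QT = (t_offset - q)/fs; PR = (r - p)/fs;
    P_s and T_s are half-amplitude widths. Beats with absent P or T
    propagate NaN into the dependent columns.
    """
    if len(fiducials) < 2:
        raise ValueError("need at least 2 beats to define RR intervals")
    by_r = {f.r: f for f in fiducials}
    rows = []
    prev_r: int | None = None
    for r in rpeaks.indices:
        f = by_r.get(int(r))
        if f is None:
            prev_r = int(r)
            continue
        rr = (r - prev_r) / fs if prev_r is not None else np.nan
        qrs = (f.s - f.q) / fs
        qt = (f.t_offset - f.q) / fs if f.t_offset is not None else np.nan
        pr = (f.r - f.p) / fs if f.p is not None else np.nan
        p_w = (f.p_offset - f.p_onset) / fs if f.p is not None else np.nan
        t_w = (f.t_offset - f.t_onset) / fs if f.t is not None else np.nan
        rows.append((rpeaks.record_id, int(r), rr, qrs, qt, pr, p_w, t_w))
        prev_r = int(r)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def extract_feature_matrix(
    signal: ECGSignal, rpeaks: RPeakSet, config: RunConfig | None = None
) -> pd.DataFrame:
    """Window every beat, locate its fiducials, and build the feature matrix.

    Edge beats whose window does not fit are skipped with a warning.
    """
    cfg = config or RunConfig(fs=signal.fs)
    fids: list[BeatFiducials] = []
    for r in rpeaks.indices:
        try:
            win = extract_beat_window(signal, int(r), cfg.window_samples, cfg.window_left)
        except ValueError:
            warnings.warn(f"skipping edge beat at sample {int(r)}")
            continue
        try:
            fids.append(locate_fiducials(signal, win, cfg))
        except ValueError:
            warnings.warn(f"skipping unresolvable beat at sample {int(r)}")
    return compute_features(fids, rpeaks, signal.fs)
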