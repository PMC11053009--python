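"""R-peak detection for QRS complexes of either polarity.

The classical Pan–Tompkins chain (bandpass, derivative, squaring,
moving-window integration) produces a nonnegative envelope whose local
maxima mark QRS complexes regardless of polarity — the squaring stage
discards the sign. Candidate envelope peaks are separated from noise
peaks by a two-cluster amplitude threshold

    th = (max(w0) + min(w1)) / 2,

the midpoint between the boundary of the low-amplitude cluster w0 and the
high-amplitude cluster w1 of an exact 1-D 2-means partition. Within each
accepted envelope region the R-peak is then localized on the *original*
signal as the most persistent extremum of largest absolute amplitude,
after cancelling low-persistence extrema pairs (LMMD — local
maxima/minima difference cancellation, a discrete-Morse-style
simplification). Because every stage is either linear, sign-free, or
driven by |amplitude|, detection is invariant to inverting the lead.
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .config import RunConfig
from .core import ClusterSplit, ECGSignal, ExtremaSequence, RPeakSet

__all__ = [
    "pan_tompkins_envelope",
    "extract_extrema",
    "lmmd_cancel",
    "kmeans_threshold",
    "detect_rpeaks",
]


def pan_tompkins_envelope(
    signal: ECGSignal,
    band_hz: tuple[float, float] = (5.0, 15.0),
    integ_window_s: float = 0.150,
) -> ECGSignal:
    """Bandpass -> derivative -> square -> moving-window integration.

    Returns a nonnegative envelope of the same length as the input whose
    local maxima align with QRS complexes.
    """
    low, high = band_hz
    fs = signal.fs
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band {band_hz} for fs={fs}")
    if integ_window_s <= 0:
        raise ValueError("integration window must be positive")

    numtaps = int(round(fs / low)) | 1
    numtaps = max(numtaps, 5)
    if numtaps >= len(signal) // 3:
        numtaps = max(5, ((len(signal) // 3) - 1) | 1)
    taps = sps.firwin(numtaps, [low, high], fs=fs, pass_zero=False, window="hamming")
    padlen = min(3 * numtaps, len(signal) - 1)
    band = sps.filtfilt(taps, [1.0], signal.samples, padtype="even", padlen=padlen)

    deriv = np.gradient(band) * fs
    squared = deriv * deriv
    win = max(1, int(round(integ_window_s * fs)))
    envelope = ndimage.uniform_filter1d(squared, size=win, mode="nearest")
    return signal.replace(envelope)


def extract_extrema(signal: ECGSignal | np.ndarray) -> ExtremaSequence:
    """All strict local maxima and minima in index order.

    Plateaus are represented by their first sample; a monotone signal has
    no extrema and yields an empty sequence. The result strictly
    alternates between maxima and minima by construction.
    """
    x = signal.samples if isinstance(signal, ECGSignal) else np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to define interior extrema")
    d = np.sign(np.diff(x))
    nz = d != 0
    if not nz.any():
        return ExtremaSequence(np.empty(0, int), np.empty(0), np.empty(0, bool))
    # backward-fill zero slopes (each plateau takes the sign of the next
    # nonzero slope) so a plateau's turning point lands on its first sample
    if not nz.all():
        pos = np.where(nz)[0]
        nxt = np.searchsorted(pos, np.arange(d.size), side="left")
        filled = d[pos[np.minimum(nxt, pos.size - 1)]]
    else:
        filled = d
    changes = np.where(filled[1:] * filled[:-1] < 0)[0]
    indices = changes + 1
    is_max = filled[changes] > 0
    return ExtremaSequence(indices, x[indices], is_max)


def lmmd_cancel(extrema: ExtremaSequence, min_persistence: float) -> ExtremaSequence:
    """Cancel adjacent max/min pairs whose amplitude difference is small.

    Repeatedly removes the adjacent pair with the smallest amplitude
    difference until every remaining adjacent pair differs by at least
    ``min_persistence``. Removing an adjacent pair of an alternating
    sequence keeps it alternating, so prominent deflections of either
    polarity survive intact.
    """
    if min_persistence < 0:
        raise ValueError("min_persistence must be nonnegative")
    if min_persistence == 0 or len(extrema) < 2:
        return extrema
    amp = extrema.amplitudes
    n = len(extrema)
    nxt = list(range(1, n)) + [-1]
    prv = [-1] + list(range(n - 1))
    alive = [True] * n
    heap = [(abs(amp[i + 1] - amp[i]), i, i + 1) for i in range(n - 1)]
    heapq.heapify(heap)
    while heap:
        diff, left, right = heapq.heappop(heap)
        if not (alive[left] and alive[right] and nxt[left] == right):
            continue  # stale pair
        if diff >= min_persistence:
            break
        alive[left] = alive[right] = False
        a, b = prv[left], nxt[right]
        if a != -1:
            nxt[a] = b
        if b != -1:
            prv[b] = a
        if a != -1 and b != -1:
            heapq.heappush(heap, (abs(amp[b] - amp[a]), a, b))
    keep = np.array([i for i in range(n) if alive[i]], int)
    return ExtremaSequence(
        extrema.indices[keep], amp[keep], extrema.is_max[keep]
    )


def kmeans_threshold(amplitudes: np.ndarray) -> ClusterSplit:
    """Exact 1-D two-means split of peak amplitudes with midpoint threshold.

    The optimal 2-means partition of scalars is a split of the sorted
    values; the split minimizing within-cluster sum of squares is found by
    an exhaustive scan with prefix sums (deterministic, no RNG). The
    threshold is th = (max(w0) + min(w1)) / 2.
    """
    a = np.sort(np.asarray(amplitudes, dtype=float).ravel())
    if a.size < 2 or a[0] == a[-1]:
        raise ValueError("cannot split one cluster: need >= 2 distinct amplitudes")
    csum = np.cumsum(a)
    csq = np.cumsum(a * a)
    n = a.size
    best_cost, best_k = np.inf, 1
    for k in range(1, n):  # w0 = a[:k], w1 = a[k:]
        s0, s1 = csum[k - 1], csum[-1] - csum[k - 1]
        q0, q1 = csq[k - 1], csq[-1] - csq[k - 1]
        cost = (q0 - s0 * s0 / k) + (q1 - s1 * s1 / (n - k))
        if cost < best_cost - 1e-15:
            best_cost, best_k = cost, k
    w0, w1 = a[:best_k], a[best_k:]
    th = (w0.max() + w1.min()) / 2.0
    return ClusterSplit(w0, w1, th)


def _default_persistence(extrema: ExtremaSequence) -> float:
    """LMMD cancellation threshold: 2-means split of adjacent |differences|."""
    diffs = extrema.adjacent_differences()
    if diffs.size < 2 or np.ptp(diffs) == 0:
        return 0.0
    return kmeans_threshold(diffs).th


def detect_rpeaks(signal: ECGSignal, config: RunConfig | None = None) -> RPeakSet:
    """Detect R-peaks of either polarity on a normalized, filtered signal.

    Envelope peaks above the two-means threshold define QRS regions; inside
    each region the R-peak is the surviving LMMD extremum with the largest
    |amplitude| on the original signal (ties broken toward the earlier
    sample). A refractory period (default 0.2 s) suppresses the weaker of
    two candidates that fall too close together.
    """
    cfg = config or RunConfig(fs=signal.fs)
    fs = signal.fs
    env = pan_tompkins_envelope(
        signal, (cfg.band_low_hz, cfg.band_high_hz), cfg.integration_window_s
    )
    try:
        env_ext = extract_extrema(env)
    except ValueError:
        env_ext = None
    if env_ext is None or not env_ext.is_max.any() or np.ptp(env.samples) == 0:
        warnings.warn(f"no candidate peaks in record {signal.record_id!r}")
        return RPeakSet(signal.record_id, np.empty(0, int), np.empty(0), fs)

    peak_idx = env_ext.indices[env_ext.is_max]
    peak_amp = env_ext.amplitudes[env_ext.is_max]
    if np.unique(peak_amp).size >= 2:
        th = kmeans_threshold(peak_amp).th
    else:
        th = peak_amp[0] / 2.0
    accepted = peak_idx[peak_amp >= th]
    if accepted.size == 0:
        warnings.warn(f"no envelope peaks above threshold in {signal.record_id!r}")
        return RPeakSet(signal.record_id, np.empty(0, int), np.empty(0), fs)

    # prominent extrema of the raw signal, after LMMD cancellation
    sig_ext = extract_extrema(signal)
    sig_ext = lmmd_cancel(sig_ext, _default_persistence(sig_ext))

    half = max(1, int(round(cfg.integration_window_s * fs)))
    n = len(signal)

    def _localize(c: int) -> tuple[int, float]:
        """R position in the original signal for an envelope peak at ``c``."""
        lo, hi = max(0, c - half), min(n, c + half + 1)
        mask = (sig_ext.indices >= lo) & (sig_ext.indices < hi)
        if mask.any():
            sub_idx = sig_ext.indices[mask]
            sub_amp = sig_ext.amplitudes[mask]
        else:  # no prominent extremum survived here: fall back to raw samples
            sub_idx = np.arange(lo, hi)
            sub_amp = signal.samples[lo:hi]
        best = int(np.argmax(np.abs(sub_amp)))  # argmax takes the earliest tie
        return int(sub_idx[best]), float(sub_amp[best])

    def _apply_refractory(cands: list[tuple[int, float]]) -> list[tuple[int, float]]:
        kept: list[tuple[int, float]] = []
        for i, a in sorted(set(cands)):
            if kept and i - kept[-1][0] < refractory:
                if abs(a) > abs(kept[-1][1]):
                    kept[-1] = (i, a)
            else:
                kept.append((i, a))
        return kept

    refractory = int(round(cfg.refractory_s * fs))
    kept = _apply_refractory([_localize(c) for c in accepted])

    # search-back: a beat whose envelope peak missed the threshold (e.g. a
    # wide, low-slope PVC) leaves an anomalously long RR gap. Re-scan each
    # gap longer than 1.5x the median RR once: localize the strongest
    # remaining envelope peak inside it and accept the beat only if its
    # signal amplitude stands up against the established R peaks (>= half
    # their median |amplitude|), which keeps T waves and noise out.
    if len(kept) >= 3:
        kept_idx = np.array([i for i, _ in kept])
        med_rr = float(np.median(np.diff(kept_idx)))
        med_amp = float(np.median(np.abs([a for _, a in kept])))
        below = peak_amp < th
        rescued: list[tuple[int, float]] = []
        for left, right in zip(kept_idx[:-1], kept_idx[1:]):
            if right - left <= 1.5 * med_rr:
                continue
            inside = below & (peak_idx > left + refractory) & (peak_idx < right - refractory)
            if not inside.any():
                continue
            strongest = peak_idx[inside][int(np.argmax(peak_amp[inside]))]
            cand = _localize(int(strongest))
            if abs(cand[1]) >= 0.5 * med_amp:
                rescued.append(cand)
        if rescued:
            kept = _apply_refractory(kept + rescued)

    idx = np.array([i for i, _ in kept], int)
    amp = np.array([a for _, a in kept])
    return RPeakSet(signal.record_id, idx, amp, fs)
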