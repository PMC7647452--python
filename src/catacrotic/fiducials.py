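"""Systolic-peak and trough detection on pulse waveforms.

Peaks: candidate local maxima are located by a sign change of the first
difference, then verified against a sliding window (0.6 s by default,
longer than half a pulse cycle) centered on the candidate: a candidate is
a systolic peak iff it is the first sample attaining the maximum of its
window.  Windows are clipped at record edges.  Troughs: the minimum of
the signal on the open interval between adjacent systolic peaks
(first-occurrence sample on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "FiducialSet",
    "DetectionScore",
    "FiducialDetector",
    "detect_peaks",
    "detect_troughs",
    "detect_fiducials",
    "match_events",
    "score_detection",
]


@dataclass
class FiducialSet:
    """Alternating trough/peak sample indices defining pulse cycles."""

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        self.trough_indices = np.asarray(self.trough_indices, dtype=np.int64)
        for name, idx in (("peak", self.peak_indices), ("trough", self.trough_indices)):
            if idx.size > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError(f"{name} indices must be strictly increasing")
        # interior troughs: exactly one between each adjacent peak pair
        if self.trough_indices.size:
            if self.trough_indices.size != self.peak_indices.size - 1:
                raise ValueError("expected exactly one trough per adjacent-peak pair")
            lo = self.peak_indices[:-1]
            hi = self.peak_indices[1:]
            if not np.all((self.trough_indices > lo) & (self.trough_indices < hi)):
                raise ValueError("troughs must interleave strictly with peaks")

    @property
    def peak_times(self) -> np.ndarray:
        return self.peak_indices / self.fs

    @property
    def trough_times(self) -> np.ndarray:
        return self.trough_indices / self.fs


@dataclass
class DetectionScore:
    """Match counts of detected against true fiducials."""

    n_true: int
    n_detected: int
    n_matched: int
    tol_s: float

    @property
    def accuracy(self) -> float:
        denom = max(self.n_true, self.n_detected)
        return self.n_matched / denom if denom else 1.0


def detect_peaks(signal, fs: float, window_s: float = 0.6) -> np.ndarray:
    """Systolic-peak sample indices."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = np.asarray(signal, dtype=float).ravel()
    n = x.size
    win = int(round(window_s * fs))
    if n < win:
        return np.empty(0, dtype=np.int64)

    d = np.diff(x)
    # local maximum at i: rising into i, non-rising out of i
    cand = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1

    half = win // 2
    peaks = []
    for i in cand:
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        w = x[lo:hi]
        jmax = lo + int(np.argmax(w))  # first sample attaining the window max
        if jmax == i:
            peaks.append(i)
    return np.asarray(peaks, dtype=np.int64)


def detect_troughs(signal, peak_indices) -> np.ndarray:
    """One trough per adjacent-peak pair: the argmin of the signal on the
    open interval between them (first occurrence on ties)."""
    x = np.asarray(signal, dtype=float).ravel()
    peaks = np.asarray(peak_indices, dtype=np.int64)
    if peaks.size < 2:
        return np.empty(0, dtype=np.int64)
    troughs = []
    for p, q in zip(peaks[:-1], peaks[1:]):
        seg = x[p + 1 : q]
        troughs.append(p + 1 + int(np.argmin(seg)))
    return np.asarray(troughs, dtype=np.int64)


def detect_fiducials(signal, fs: float, window_s: float = 0.6) -> FiducialSet:
    """Peaks then troughs, packaged as a :class:`FiducialSet`."""
    peaks = detect_peaks(signal, fs, window_s)
    troughs = detect_troughs(signal, peaks)
    return FiducialSet(peaks, troughs, fs)


def match_events(true_times, detected_times, tol_s: float) -> int:
    """Greedy nearest-neighbor matching of event times within ``tol_s``;
    each event is matched at most once.  Returns the match count."""
    t = np.asarray(true_times, dtype=float)
    d = np.asarray(detected_times, dtype=float)
    if t.size == 0 or d.size == 0:
        return 0
    dt = np.abs(t[:, None] - d[None, :])
    ti, di = np.nonzero(dt <= tol_s)
    order = np.argsort(dt[ti, di], kind="stable")
    used_t = np.zeros(t.size, dtype=bool)
    used_d = np.zeros(d.size, dtype=bool)
    matched = 0
    for k in order:
        i, j = ti[k], di[k]
        if not used_t[i] and not used_d[j]:
            used_t[i] = used_d[j] = True
            matched += 1
    return matched


def score_detection(detected: FiducialSet, truth, tol_s: float = 0.05) -> DetectionScore:
    """Score detected fiducials against ground truth.

    ``truth`` needs ``peak_times`` and ``trough_times`` attributes (either
    another :class:`FiducialSet` or a generator ground-truth object).
    Peaks and troughs are matched separately, then pooled:
    ``accuracy = n_matched / max(n_true, n_detected)``.
    """
    tp = np.asarray(truth.peak_times, dtype=float)
    tt = np.asarray(truth.trough_times, dtype=float)
    matched = match_events(tp, detected.peak_times, tol_s) + match_events(
        tt, detected.trough_times, tol_s
    )
    n_true = tp.size + tt.size
    n_det = detected.peak_indices.size + detected.trough_indices.size
    return DetectionScore(n_true=n_true, n_detected=n_det, n_matched=matched, tol_s=tol_s)


class FiducialDetector(BaseEstimator):
    """Sliding-window systolic-peak and trough detector (estimator surface).

    Attributes
    ----------
    peak_indices_, trough_indices_ : ndarray of int
        Detected fiducials after :meth:`fit`.
    fiducials_ : FiducialSet
    """

    def __init__(self, fs: float = 100.0, window_s: float = 0.6):
        self.fs = fs
        self.window_s = window_s

    def fit(self, X, y=None):
        fid = detect_fiducials(X, self.fs, self.window_s)
        self.fiducials_ = fid
        self.peak_indices_ = fid.peak_indices
        self.trough_indices_ = fid.trough_indices
        return self

    def fit_detect(self, X) -> FiducialSet:
        return self.fit(X).fiducials_
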