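"""Per-cycle baseline removal and amplitude normalization.

Each pulse cycle runs over the half-open sample interval ``(t(i), t(i+1)]``
between adjacent troughs.  Baseline drift is removed by subtracting the
straight line through the two trough samples, which maps both cycle
endpoints exactly to zero; the cycle is then divided by its adjusted
systolic-peak amplitude so the peak is exactly 1.  Degenerate cycles
(non-positive adjusted peak) are dropped rather than propagated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fiducials import FiducialSet

__all__ = ["NormalizedCycle", "remove_baseline", "normalize_amplitude", "normalize_cycles"]


@dataclass
class NormalizedCycle:
    """One baseline-adjusted, amplitude-normalized pulse cycle.

    ``samples`` covers the cycle domain ``(start, end]``; ``samples[k]``
    is the signal at absolute index ``start + 1 + k``.  The value at the
    end trough is exactly 0 and at the systolic peak exactly 1.
    """

    start: int  # start-trough sample index (belongs to the previous cycle)
    end: int  # end-trough sample index
    peak: int  # systolic-peak sample index, start < peak <= end
    samples: np.ndarray

    @property
    def peak_offset(self) -> int:
        """Index of the systolic peak within ``samples``."""
        return self.peak - self.start - 1


def remove_baseline(signal, trough_indices) -> list[np.ndarray]:
    """Piecewise-linear baseline removal per cycle.

    For cycle ``i`` with troughs ``t(i) < t(i+1)``, subtracts
    ``P(t(i)) + k (j - t(i))`` with ``k`` the chord slope between the two
    trough samples, over ``t(i) < j <= t(i+1)``.  Returns one adjusted
    sample vector per cycle; with fewer than two troughs the result is
    empty.
    """
    x = np.asarray(signal, dtype=float).ravel()
    troughs = np.asarray(trough_indices, dtype=np.int64)
    if troughs.size < 2:
        return []
    if troughs[0] < 0 or troughs[-1] >= x.size:
        raise ValueError("trough indices out of range")
    if not np.all(np.diff(troughs) > 0):
        raise ValueError("trough indices must be strictly increasing")
    cycles = []
    for t0, t1 in zip(troughs[:-1], troughs[1:]):
        j = np.arange(t0 + 1, t1 + 1)
        # fraction form makes the end trough map to exactly 0
        frac = (j - t0) / (t1 - t0)
        baseline = x[t0] + (x[t1] - x[t0]) * frac
        cycles.append(x[t0 + 1 : t1 + 1] - baseline)
    return cycles


def normalize_amplitude(adjusted_cycle, start: int, end: int, peak: int) -> NormalizedCycle | None:
    """Divide an adjusted cycle by its systolic-peak amplitude.

    Returns ``None`` for degenerate beats whose adjusted peak amplitude is
    not positive.
    """
    v = np.asarray(adjusted_cycle, dtype=float)
    if not (start < peak <= end):
        raise ValueError("peak index must lie inside the cycle (start, end]")
    if v.size != end - start:
        raise ValueError("cycle length does not match trough indices")
    peak_amp = v[peak - start - 1]
    if peak_amp <= 0:
        return None
    return NormalizedCycle(start=int(start), end=int(end), peak=int(peak), samples=v / peak_amp)


def normalize_cycles(signal, fiducials: FiducialSet) -> tuple[list[NormalizedCycle], int]:
    """Full per-cycle normalization for a detected record.

    Pairs each adjacent trough pair with the systolic peak between them,
    removes the baseline and rescales.  Returns the valid cycles and the
    number of degenerate beats dropped.
    """
    troughs = fiducials.trough_indices
    adjusted = remove_baseline(signal, troughs)
    cycles: list[NormalizedCycle] = []
    dropped = 0
    for k, v in enumerate(adjusted):
        t0, t1 = int(troughs[k]), int(troughs[k + 1])
        inside = fiducials.peak_indices[
            (fiducials.peak_indices > t0) & (fiducials.peak_indices <= t1)
        ]
        if inside.size != 1:
            dropped += 1
            continue
        cyc = normalize_amplitude(v, t0, t1, int(inside[0]))
        if cyc is None:
            dropped += 1
        else:
            cycles.append(cyc)
    return cycles, dropped
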