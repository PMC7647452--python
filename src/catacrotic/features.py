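"""Beat-level parameters of the catacrotic (falling) limb.

Six parameters per beat, computed on baseline-adjusted, amplitude-
normalized cycles (peak value 1, end-trough value 0):

- ``PBI``  pulse beat interval, time between the two troughs [s]
- ``DI``   diastolic interval, systolic peak to end trough [s]
- ``DS``   diastolic slope, chord-slope magnitude peak-to-trough; equals
           ``1/DI`` on normalized cycles [1/s]
- ``DSmin`` magnitude of the steepest instantaneous slope on the
           catacrotic limb (central differences; absolute value) [1/s]
- ``DTI``  time from the DSmin sample to the end trough [s]
- ``ADR``  area difference ratio ``(S_tri - S_curve) / S_tri`` with
           ``S_tri = DI * peak / 2`` the right-triangle area under the
           peak-to-trough chord and ``S_curve`` the trapezoidal area under
           the catacrotic limb above the trough level [dimensionless]

Per-beat parameters are normalized against the pre-stimulus window with
``(par - mean_pre) / RMS_pre`` where ``RMS_pre = sqrt(mean(par^2))`` over
the beats of the -70..-10 s window, and summarized into a pre-value and a
post-value (window averages of the normalized series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cycles import NormalizedCycle

__all__ = [
    "PARAMETERS",
    "NormalizedSeries",
    "beat_features",
    "normalize_parameters",
    "window_summary",
    "summarize_beats",
]

PARAMETERS = ("PBI", "DI", "DS", "DSmin", "DTI", "ADR")

#: analysis windows relative to the stimulus, in seconds (half-open)
PRE_WINDOW = (-70.0, -10.0)
POST_WINDOW = (10.0, 70.0)


@dataclass
class NormalizedSeries:
    """Per-beat normalized values of one parameter."""

    name: str
    values: np.ndarray  # aligned with the beat table
    mean_pre: float
    rms_pre: float


def _beat_row(cycle: NormalizedCycle, fs: float) -> dict | None:
    v = cycle.samples
    peak_off = cycle.peak_offset
    seg = v[peak_off:]  # catacrotic limb: systolic peak .. end trough
    if seg.size < 3:
        return None
    pbi = (cycle.end - cycle.start) / fs
    di = (cycle.end - cycle.peak) / fs
    ds = (seg[0] - seg[-1]) / di  # = 1/DI: peak is 1, trough is 0
    deriv = np.gradient(seg, 1.0 / fs)
    k_min = int(np.argmin(deriv))  # first sample attaining the minimum
    dsmin = abs(float(deriv[k_min]))
    dti = (seg.size - 1 - k_min) / fs
    s_tri = 0.5 * di * seg[0]
    s_curve = float(np.trapezoid(seg, dx=1.0 / fs))
    adr = (s_tri - s_curve) / s_tri
    return {
        "beat_time": cycle.end / fs,
        "PBI": pbi,
        "DI": di,
        "DS": ds,
        "DSmin": dsmin,
        "DTI": dti,
        "ADR": adr,
    }


def beat_features(cycles: list[NormalizedCycle], fs: float) -> pd.DataFrame:
    """Per-beat parameter table; beats whose catacrotic segment is shorter
    than 3 samples are dropped.

    Beat times are the end-trough times (each beat is anchored to the
    trough that closes it).
    """
    if not cycles:
        raise ValueError("need at least one normalized cycle")
    rows = [r for c in cycles if (r := _beat_row(c, fs)) is not None]
    return pd.DataFrame(rows, columns=["beat_time", *PARAMETERS])


def _pre_mask(beat_times: np.ndarray, stimulus_time: float,
              window: tuple[float, float]) -> np.ndarray:
    lo, hi = stimulus_time + window[0], stimulus_time + window[1]
    return (beat_times >= lo) & (beat_times < hi)


def normalize_parameters(
    table: pd.DataFrame,
    stimulus_time: float,
    pre_window: tuple[float, float] = PRE_WINDOW,
) -> dict[str, NormalizedSeries]:
    """Normalize each parameter by its pre-stimulus mean and RMS.

    ``par_norm = (par - mean_pre) / RMS_pre`` with both moments taken over
    beats whose end-trough time lies in the pre window.  Parameters whose
    pre-window RMS is zero are flagged by omission from the result.
    """
    times = table["beat_time"].to_numpy()
    mask = _pre_mask(times, stimulus_time, pre_window)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 beats in the pre-stimulus window "
            f"[{stimulus_time + pre_window[0]}, {stimulus_time + pre_window[1]}) s, "
            f"got {int(mask.sum())}"
        )
    out: dict[str, NormalizedSeries] = {}
    for name in PARAMETERS:
        par = table[name].to_numpy(dtype=float)
        mean_pre = float(np.mean(par[mask]))
        rms_pre = float(np.sqrt(np.mean(par[mask] ** 2)))
        if rms_pre == 0.0:
            continue  # non-normalizable for this subject
        out[name] = NormalizedSeries(
            name=name,
            values=(par - mean_pre) / rms_pre,
            mean_pre=mean_pre,
            rms_pre=rms_pre,
        )
    return out


def window_summary(
    series: dict[str, NormalizedSeries],
    beat_times: np.ndarray,
    stimulus_time: float,
    pre_window: tuple[float, float] = PRE_WINDOW,
    post_window: tuple[float, float] = POST_WINDOW,
) -> pd.DataFrame:
    """Average the normalized series inside each analysis window.

    Beats in the +-10 s band around the stimulus lie outside both windows
    and are discarded by construction.  Rows: parameter; columns:
    ``pre_value``, ``post_value`` (NaN when a window holds no beats).
    """
    times = np.asarray(beat_times, dtype=float)
    pre = _pre_mask(times, stimulus_time, pre_window)
    post = _pre_mask(times, stimulus_time, post_window)
    rows = {}
    for name, s in series.items():
        rows[name] = {
            "pre_value": float(np.mean(s.values[pre])) if pre.any() else float("nan"),
            "post_value": float(np.mean(s.values[post])) if post.any() else float("nan"),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("parameter")


def summarize_beats(
    table: pd.DataFrame,
    stimulus_time: float,
    pre_window: tuple[float, float] = PRE_WINDOW,
    post_window: tuple[float, float] = POST_WINDOW,
) -> pd.DataFrame:
    """Normalization and window summary in one step."""
    series = normalize_parameters(table, stimulus_time, pre_window)
    return window_summary(
        series, table["beat_time"].to_numpy(), stimulus_time, pre_window, post_window
    )
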