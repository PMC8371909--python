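"""EMG activity at the jump time points.

The published chain — rectify, average, integrate (iEMG), time-normalize to
1 s, MVC-normalize — composes to the mean rectified amplitude over the
+/-25 ms window divided by the MVC reference amplitude, which is what
``window_activity`` computes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DegenerateReferenceError, Trace, log


@dataclass
class ActivitySample:
    muscle: str                 # "GM" or "TA"
    mark: str                   # phase label
    iemg_norm: float            # mean rectified amplitude / MVC reference
    window: tuple[float, float]  # seconds
    clipped: bool = False


@dataclass
class RatioSample:
    mark: str
    gm_ta: float
    log_gm_ta: float            # base-10
    undefined: bool = False


def mvc_reference(mvc: Trace, halfwidth_s: float = 0.025) -> float:
    """Mean rectified amplitude over the MVC peak +/- 25 ms."""
    if mvc.duration <= 2 * halfwidth_s:
        raise ValueError("MVC trace shorter than the reference window")
    rect = np.abs(mvc.values)
    # ties (a flat plateau at the maximum) center the window on the plateau
    at_max = np.flatnonzero(rect == rect.max())
    breaks = np.flatnonzero(np.diff(at_max) > 1)
    run = at_max[: breaks[0] + 1] if breaks.size else at_max
    peak = int(run[len(run) // 2])
    half = int(round(halfwidth_s * mvc.rate))
    lo = max(peak - half, 0)
    hi = min(peak + half, len(rect) - 1)
    ref = float(np.mean(rect[lo : hi + 1]))
    if ref == 0.0:
        raise DegenerateReferenceError("MVC trace is all-zero; no reference amplitude")
    return ref


def window_activity(
    emg: Trace,
    center: int,
    mvc_ref: float,
    halfwidth_s: float = 0.025,
    muscle: str = "",
    mark: str = "",
) -> ActivitySample:
    """iEMG over the +/-25 ms window, time-normalized and MVC-normalized."""
    if not mvc_ref > 0:
        raise ValueError("MVC reference must be positive")
    half = int(round(halfwidth_s * emg.rate))
    lo, hi = center - half, center + half
    if hi < 0 or lo >= len(emg):
        raise ValueError(
            f"activity window [{lo}, {hi}] lies entirely outside the record"
        )
    clipped = lo < 0 or hi >= len(emg)
    if clipped:
        log.warning("activity window for %s at %s clipped at the record edge",
                    muscle or "EMG", mark or f"sample {center}")
        lo, hi = max(lo, 0), min(hi, len(emg) - 1)
    mean_rect = float(np.mean(np.abs(emg.values[lo : hi + 1])))
    return ActivitySample(
        muscle=muscle, mark=mark,
        iemg_norm=mean_rect / mvc_ref,
        window=(emg.time_at(lo), emg.time_at(hi)),
        clipped=clipped,
    )


def gm_ta_ratio(gm: ActivitySample, ta: ActivitySample) -> RatioSample:
    """Agonist/antagonist activity ratio with its base-10 log."""
    if gm.mark != ta.mark:
        raise ValueError(f"mark mismatch: {gm.mark!r} vs {ta.mark!r}")
    if ta.iemg_norm == 0.0:
        log.warning("TA activity is zero at %s; GM/TA ratio undefined", gm.mark)
        return RatioSample(gm.mark, math.nan, math.nan, undefined=True)
    r = gm.iemg_norm / ta.iemg_norm
    return RatioSample(gm.mark, r, math.log10(r) if r > 0 else math.nan,
                       undefined=r <= 0)
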