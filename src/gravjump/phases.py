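"""Detection of the five drop-jump time points from force and kinematic traces.

DO (drop-off, 12 ms before fall onset), PRE100 (100 ms before ground
contact), GC (summed vertical GRF exceeding 20 N after the flight phase),
MAJ (minimum ankle angle, end of braking), and PO (last loaded sample before
take-off flight).  Threshold crossings are debounced: the signal must hold
past the 20 N gate for at least 5 ms, since plate noise can chatter at the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FRAME_RATE_HZ, PHASES, DetectionError, Trace, Trial, log
from .config import AnalysisConfig


@dataclass
class PhaseMarks:
    """The five jump time points as indices on the GRF reference clock."""

    rate: float
    t0: float
    do_idx: int
    pre100_idx: int
    gc_idx: int
    maj_idx: int
    po_idx: int
    maj_time_kinematic: float = float("nan")  # MAJ on the ankle clock
    pre100_clipped: bool = False

    def __post_init__(self):
        order = [self.do_idx, self.pre100_idx, self.gc_idx, self.maj_idx, self.po_idx]
        if not all(a <= b for a, b in zip(order, order[1:])):
            raise ValueError(f"phase marks out of order: {order}")
        if not self.do_idx < self.gc_idx:
            raise ValueError("DO must precede GC")

    def index(self, mark: str) -> int:
        return {
            "DO": self.do_idx, "PRE100": self.pre100_idx, "GC": self.gc_idx,
            "MAJ": self.maj_idx, "PO": self.po_idx,
        }[mark]

    def time(self, mark: str) -> float:
        return self.t0 + self.index(mark) / self.rate

    @property
    def times(self) -> dict:
        return {m: self.time(m) for m in PHASES}

    def frame_index(self, mark: str, frame_rate: float = FRAME_RATE_HZ,
                    frame_t0: float = 0.0) -> int:
        """Nearest-neighbor ultrasound frame for a mark (no interpolation)."""
        return int(round((self.time(mark) - frame_t0) * frame_rate))

    def frame_indices(self, frame_rate: float = FRAME_RATE_HZ,
                      frame_t0: float = 0.0) -> dict:
        return {m: self.frame_index(m, frame_rate, frame_t0) for m in PHASES}


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop is exclusive."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_ground_contact(
    grf_total: Trace,
    threshold: float = 20.0,
    debounce_s: float = 0.005,
    min_flight_s: float = 0.050,
    trial_id: str = "",
) -> int:
    """First sample after the flight interval at which GRF exceeds ``threshold``.

    A preceding below-threshold run of at least ``min_flight_s`` is required,
    and the signal must stay above threshold for ``debounce_s``.
    """
    v = grf_total.values
    above = v > threshold
    n_flight = max(int(round(min_flight_s * grf_total.rate)), 1)
    n_deb = max(int(round(debounce_s * grf_total.rate)), 1)
    for start, stop in _runs(above):
        if start < n_flight:
            continue  # needs a full flight interval before contact
        if not np.all(v[start - n_flight : start] <= threshold):
            continue
        if stop - start >= n_deb:
            return int(start)
    raise DetectionError(
        f"no ground contact: GRF never exceeds {threshold} N after a flight "
        f"interval{' in trial ' + trial_id if trial_id else ''}"
    )


def detect_push_off(
    grf_total: Trace,
    after: int,
    threshold: float = 20.0,
    min_flight_s: float = 0.050,
    trial_id: str = "",
) -> int:
    """Last sample at or above ``threshold`` before the take-off flight.

    Scans forward from ``after`` for a below-threshold run that lasts at
    least ``min_flight_s`` (or reaches the end of the record).
    """
    v = grf_total.values
    below = v < threshold
    n_flight = max(int(round(min_flight_s * grf_total.rate)), 1)
    for start, stop in _runs(below):
        if start <= after:
            continue
        if stop - start >= n_flight or stop >= len(v):
            return int(start - 1)
    raise DetectionError(
        f"no take-off: GRF never falls below {threshold} N after sample {after}"
        f"{' in trial ' + trial_id if trial_id else ''}"
    )


def detect_fall_onset(
    platform_load: Trace,
    unload_fraction: float = 0.2,
    baseline_s: float = 0.3,
    trial_id: str = "",
) -> int:
    """First sample where the platform load drops below a fraction of standing load."""
    v = platform_load.values
    n_base = max(int(round(baseline_s * platform_load.rate)), 1)
    standing = float(np.median(v[:n_base]))
    if standing <= 0:
        raise DetectionError(
            f"platform never loaded{' in trial ' + trial_id if trial_id else ''}"
        )
    idx = np.flatnonzero(v < unload_fraction * standing)
    idx = idx[idx >= n_base // 2]
    if idx.size == 0:
        raise DetectionError(
            f"no unload transition on the platform channel"
            f"{' in trial ' + trial_id if trial_id else ''}"
        )
    return int(idx[0])


def detect_drop_off(
    platform_load: Trace,
    lead: float = 0.012,
    unload_fraction: float = 0.2,
    trial_id: str = "",
) -> int:
    """DO = fall onset minus the 12 ms lead."""
    fall = detect_fall_onset(platform_load, unload_fraction, trial_id=trial_id)
    return max(fall - int(round(lead * platform_load.rate)), 0)


def detect_min_ankle_angle(ankle: Trace, t_lo: float, t_hi: float) -> int:
    """Index of the minimum ankle angle in [t_lo, t_hi]; ties -> earliest."""
    i0, i1 = ankle.span(t_lo, t_hi)  # raises on an empty window
    return int(i0 + np.argmin(ankle.values[i0 : i1 + 1]))


def mark_phases(trial: Trial, config: AnalysisConfig | None = None) -> PhaseMarks:
    """Assemble all five marks for one trial on the GRF reference clock."""
    cfg = config or AnalysisConfig()
    grf = trial.grf_total()
    if cfg.per_plate_threshold:
        # gate on either plate alone (configurable alternative reading of the
        # 20 N rule); contact = earliest plate crossing
        gc = min(
            detect_ground_contact(tr, cfg.grf_threshold_n, cfg.debounce_s,
                                  cfg.min_flight_s, trial.trial_id)
            for tr in (trial.grf_left, trial.grf_right)
        )
    else:
        gc = detect_ground_contact(grf, cfg.grf_threshold_n, cfg.debounce_s,
                                   cfg.min_flight_s, trial.trial_id)
    po = detect_push_off(grf, gc, cfg.grf_threshold_n, cfg.min_flight_s,
                         trial.trial_id)
    fall = detect_fall_onset(trial.platform_load, cfg.unload_fraction,
                             trial_id=trial.trial_id)
    do = max(fall - int(round(cfg.do_lead_s * grf.rate)), 0)

    pre100 = gc - int(round(cfg.pre_gc_s * grf.rate))
    clipped = False
    if pre100 < fall:
        log.warning(
            "trial %s: flight shorter than %.0f ms; PRE100 clipped to fall onset",
            trial.trial_id, cfg.pre_gc_s * 1e3,
        )
        pre100 = fall
        clipped = True

    maj_ank = detect_min_ankle_angle(trial.ankle, grf.time_at(gc), grf.time_at(po))
    maj_time = trial.ankle.time_at(maj_ank)
    maj = int(np.clip(round((maj_time - grf.t0) * grf.rate), gc, po))

    return PhaseMarks(
        rate=grf.rate, t0=grf.t0,
        do_idx=do, pre100_idx=pre100, gc_idx=gc, maj_idx=maj, po_idx=po,
        maj_time_kinematic=maj_time, pre100_clipped=clipped,
    )
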