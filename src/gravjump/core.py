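"""Shared containers and error types for the drop-jump analysis pipeline.

Everything downstream consumes uniformly sampled scalar time series
(:class:`Trace`) plus a bundle of synchronized streams for one jump
(:class:`Trial`).  Synthetic trials additionally carry a
:class:`GroundTruth` block so every detector and measurement stage can be
scored against known values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

log = logging.getLogger("gravjump")

PHASES = ("DO", "PRE100", "GC", "MAJ", "PO")

FRAME_RATE_HZ = 82.0  # B-mode ultrasound frame rate


class GravjumpError(Exception):
    """Base class for pipeline errors."""


class DetectionError(GravjumpError):
    """An event detector found no qualifying transition."""


class SegmentationError(GravjumpError):
    """Aponeurosis segmentation failed; carries a diagnostic mask."""

    def __init__(self, message: str, mask: Optional[np.ndarray] = None):
        super().__init__(message)
        self.mask = mask


class InvalidFiberError(GravjumpError):
    """A fiber line cannot intersect both aponeurosis fits."""


class DegenerateReferenceError(GravjumpError):
    """MVC reference amplitude is zero or undefined."""


class UndefinedStatisticError(GravjumpError):
    """A statistic (ICC, correlation, ratio) is undefined for the input."""


class EmptyResultError(GravjumpError):
    """An aggregation was asked for with no usable input."""


@dataclass
class Trace:
    """Uniformly sampled scalar time series.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    rate : float
        Sampling rate, Hz. Must be positive.
    values : array-like
        Ordered scalar samples.
    units : str
        Unit label (``"N"``, ``"deg"``, ``"mV"``, ``"g"``).
    """

    t0: float
    rate: float
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace values must be a non-empty 1-D array")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + (self.values.size - 1) / self.rate

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.rate

    def index_at(self, t: float, clip: bool = False) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        i = int(round((t - self.t0) * self.rate))
        if clip:
            return int(np.clip(i, 0, len(self) - 1))
        if i < 0 or i >= len(self):
            raise ValueError(
                f"time {t:.4f} s outside trace [{self.t0:.4f}, {self.t_end:.4f}] s"
            )
        return i

    def time_at(self, i: int) -> float:
        return self.t0 + i / self.rate

    def value_at(self, t: float) -> float:
        return float(self.values[self.index_at(t)])

    def span(self, t_lo: float, t_hi: float) -> tuple[int, int]:
        """Inclusive index bounds of the closed interval [t_lo, t_hi]."""
        if t_hi < t_lo:
            raise ValueError("interval end precedes start")
        i0 = int(np.ceil((t_lo - self.t0) * self.rate - 1e-9))
        i1 = int(np.floor((t_hi - self.t0) * self.rate + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, len(self) - 1)
        if i1 < i0:
            raise ValueError("interval contains no samples")
        return i0, i1

    def segment(self, t_lo: float, t_hi: float) -> np.ndarray:
        i0, i1 = self.span(t_lo, t_hi)
        return self.values[i0 : i1 + 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "value": self.values, "units": self.units}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError("trace CSV needs at least two samples to infer rate")
        rate = 1.0 / np.median(np.diff(t))
        units = str(df["units"].iloc[0]) if "units" in df else ""
        return cls(t0=float(t[0]), rate=float(rate), values=df["value"].to_numpy(), units=units)


@dataclass
class SubjectParams:
    """Per-subject constants.

    ``lf_stand_mm`` is the gastrocnemius medialis fascicle length during
    bipedal standing (ankle at 110 deg); ``sl_ref_um`` the in vivo sarcomere
    length measured in the same posture.  MVC amplitudes are the reference
    mean rectified EMG amplitudes obtained from maximal isometric efforts.
    """

    lf_stand_mm: float = 57.4
    sl_ref_um: float = 3.09
    mvc_gm: float = 1.0
    mvc_ta: float = 1.0
    drop_height_cm: float = 25.0
    body_mass_kg: float = 72.0

    def __post_init__(self):
        for name in ("lf_stand_mm", "sl_ref_um", "drop_height_cm", "body_mass_kg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Known event times and trajectories for a synthetic trial (oracle only)."""

    fall_onset: float
    gc: float
    maj: float
    po: float
    lf_traj: Optional[Trace] = None
    lf_marks: dict = field(default_factory=dict)
    ankle_do: float = float("nan")
    fiber_thickness_mm: float = float("nan")
    gravity_profile: dict = field(default_factory=dict)
    delta_grf: float = float("nan")

    def __post_init__(self):
        if not (self.fall_onset < self.gc <= self.maj <= self.po):
            raise ValueError(
                "ground-truth ordering fall_onset < gc <= maj <= po violated: "
                f"{self.fall_onset}, {self.gc}, {self.maj}, {self.po}"
            )


@dataclass
class Trial:
    """One drop jump: synchronized signal streams + ultrasound frames."""

    grf_left: Trace
    grf_right: Trace
    platform_load: Trace
    ankle: Trace
    emg_gm: Trace
    emg_ta: Trace
    gravity_z: Trace
    frames: object = None  # FrameSequence or None
    subject: SubjectParams = field(default_factory=SubjectParams)
    truth: Optional[GroundTruth] = None
    trial_id: str = "trial"
    is_reference: bool = False

    def __post_init__(self):
        if (
            self.grf_left.rate != self.grf_right.rate
            or self.grf_left.t0 != self.grf_right.t0
            or len(self.grf_left) != len(self.grf_right)
        ):
            raise ValueError("left/right GRF traces must share one sampling grid")

    def grf_total(self) -> Trace:
        """Summed vertical GRF of both plates (the contact-gating signal)."""
        return Trace(
            t0=self.grf_left.t0,
            rate=self.grf_left.rate,
            values=self.grf_left.values + self.grf_right.values,
            units=self.grf_left.units,
        )


def save_trial(trial: Trial, out_dir, render_frames: bool = False) -> Path:
    """Serialize a trial to a directory: tidy CSV traces + JSON manifest.

    Frames, when requested, are written as a multi-page uint8 TIFF.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces = {
        "grf_left": trial.grf_left,
        "grf_right": trial.grf_right,
        "platform_load": trial.platform_load,
        "ankle": trial.ankle,
        "emg_gm": trial.emg_gm,
        "emg_ta": trial.emg_ta,
        "gravity_z": trial.gravity_z,
    }
    for name, tr in traces.items():
        tr.to_csv(out / f"{name}.csv")
    manifest = {
        "trial_id": trial.trial_id,
        "is_reference": trial.is_reference,
        "subject": dataclasses.asdict(trial.subject),
        "traces": {k: f"{k}.csv" for k in traces},
    }
    if trial.truth is not None:
        truth = dataclasses.asdict(trial.truth)
        lf_traj = truth.pop("lf_traj", None)
        if lf_traj is not None:
            trial.truth.lf_traj.to_csv(out / "truth_lf_traj.csv")
            truth["lf_traj_csv"] = "truth_lf_traj.csv"
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
        manifest["truth"] = "truth.json"
    if render_frames and trial.frames is not None:
        import tifffile

        stack = np.stack(
            [np.clip(trial.frames.frame(i) * 255, 0, 255).astype(np.uint8)
             for i in range(len(trial.frames))]
        )
        tifffile.imwrite(out / "frames.tif", stack)
        manifest["frames"] = "frames.tif"
        manifest["mm_per_px"] = trial.frames.imaging.mm_per_px
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def load_trial(trial_dir) -> Trial:
    """Load a trial saved by :func:`save_trial`. Frames are not reloaded."""
    d = Path(trial_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    traces = {k: Trace.from_csv(d / v) for k, v in manifest["traces"].items()}
    truth = None
    if "truth" in manifest:
        raw = json.loads((d / manifest["truth"]).read_text())
        lf_csv = raw.pop("lf_traj_csv", None)
        raw.pop("lf_traj", None)
        truth = GroundTruth(**raw)
        if lf_csv:
            truth.lf_traj = Trace.from_csv(d / lf_csv)
    return Trial(
        grf_left=traces["grf_left"],
        grf_right=traces["grf_right"],
        platform_load=traces["platform_load"],
        ankle=traces["ankle"],
        emg_gm=traces["emg_gm"],
        emg_ta=traces["emg_ta"],
        gravity_z=traces["gravity_z"],
        subject=SubjectParams(**manifest["subject"]),
        truth=truth,
        trial_id=manifest["trial_id"],
        is_reference=manifest.get("is_reference", False),
    )


def _subseed(seed: int, *salt: int) -> int:
    """Derive a reproducible child seed below 2**31 from (seed, salt...)."""
    ss = np.random.SeedSequence([int(seed) % (2**31)] + [int(s) % (2**31) for s in salt])
    return int(ss.generate_state(1)[0] % (2**31))
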