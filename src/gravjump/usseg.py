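"""Semi-automatic ultrasound frame analysis.

Aponeuroses are segmented automatically (median smoothing, quantile
threshold, flat-element morphological opening/closing, area and width
filters) and summarized by straight-line fits with linear extrapolation;
fiber directions are an *input* — three operator-drawn (or synthetic-truth)
lines — exactly as in the semi-automatic protocol this reimplements.
Fascicle length is the chord of each fiber line between its intersections
with the two aponeurosis fits, averaged over the three fibers.

Image convention: grayscale, row 0 at the skin (superficial) side, a
declared mm/px scale; line fits are ``row = slope * col + intercept``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .core import (
    InvalidFiberError,
    SegmentationError,
    UndefinedStatisticError,
    log,
)
from .config import AnalysisConfig


@dataclass
class ImagingParams:
    """Rendering/acquisition geometry for synthetic B-mode-like frames."""

    depth_mm: float = 50.0
    width_mm: float = 60.0
    mm_per_px: float = 0.2
    superficial_depth_mm: float = 8.0
    thickness_mm: float = 18.0          # orthogonal aponeurosis separation
    slope_deg: float = 0.0              # band inclination (rotation tests)
    band_sigma_mm: float = 0.5
    stripe_period_mm: float = 2.0
    speckle_sd: float = 0.25            # multiplicative log-normal sigma


@dataclass
class FiberLine:
    """An operator-drawn (or synthetic-truth) fiber direction, px endpoints."""

    x1: float
    y1: float
    x2: float
    y2: float
    provenance: str = "operator"

    def __post_init__(self):
        if self.x1 == self.x2 and self.y1 == self.y2:
            raise ValueError("fiber endpoints must be distinct")


@dataclass
class LineFit:
    """Straight line row = slope * col + intercept, with its fitted extent."""

    slope: float
    intercept: float
    col_min: float
    col_max: float

    def row_at(self, col):
        return self.slope * np.asarray(col) + self.intercept


@dataclass
class AponeurosisPair:
    superficial: LineFit
    deep: LineFit
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.mask is not None:
            cols = np.arange(self.mask.shape[1])
            if np.any(self.deep.row_at(cols) <= self.superficial.row_at(cols)):
                raise SegmentationError(
                    "deep aponeurosis does not lie strictly below the superficial one",
                    self.mask,
                )


@dataclass
class FascicleMeasurement:
    lf_mean: float
    lf_sd: float
    angle_mean: float      # deg vs image horizontal
    angle_sd: float
    pennation: float       # deg vs deep aponeurosis fit
    pennation_sd: float
    thickness_mean: float  # mm, orthogonal inter-aponeurosis distance
    thickness_sd: float
    scale: float           # mm/px
    lf_each: tuple = ()

    def __post_init__(self):
        if not self.lf_mean > 0:
            raise ValueError("fascicle length must be positive")
        if not 0.0 < self.pennation < 90.0:
            raise ValueError(f"pennation {self.pennation:.1f} deg outside (0, 90)")


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_aponeuroses(
    image: np.ndarray,
    config: AnalysisConfig | None = None,
) -> AponeurosisPair:
    """Detect the two bright elongated aponeurosis bands and fit lines.

    Pipeline: 3x3 median smoothing -> intensity threshold at a configurable
    quantile -> morphological opening then closing with a flat rectangular
    element (wide and short, favoring horizontal bands) -> connected
    components filtered by area and lateral coverage -> per-column centroid
    depths -> least-squares straight-line fit per band.
    """
    cfg = config or AnalysisConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    smoothed = ndimage.median_filter(img, size=3)
    thresh = np.quantile(smoothed, cfg.threshold_quantile)
    binary = smoothed > thresh
    footprint = np.ones((cfg.selem_rows, cfg.selem_cols), dtype=bool)
    binary = skmorph.opening(binary, footprint)
    binary = skmorph.closing(binary, footprint)

    labels = skmeasure.label(binary)
    H, W = img.shape
    candidates = []
    for region in skmeasure.regionprops(labels):
        if region.area < cfg.min_band_area_px:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        coverage = np.unique(cc).size / W
        if coverage < cfg.min_band_coverage:
            continue
        candidates.append((region.area, rr, cc))
    if len(candidates) < 2:
        raise SegmentationError(
            f"found {len(candidates)} aponeurosis band(s); need 2", binary
        )
    candidates.sort(key=lambda c: -c[0])
    fits = []
    for _, rr, cc in candidates[:2]:
        # per-column centroid depth, then a straight-line fit
        depth_sum = np.bincount(cc, weights=rr, minlength=W)
        count = np.bincount(cc, minlength=W)
        cols = np.flatnonzero(count)
        depths = depth_sum[cols] / count[cols]
        slope, intercept = np.polyfit(cols, depths, 1)
        fits.append(LineFit(float(slope), float(intercept),
                            float(cols.min()), float(cols.max())))
    fits.sort(key=lambda f: f.row_at(W / 2))
    return AponeurosisPair(superficial=fits[0], deep=fits[1], mask=binary)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _intersect(fiber: FiberLine, line: LineFit) -> tuple[float, float]:
    """Intersection (col, row) of an infinite fiber line with an apo fit."""
    dx = fiber.x2 - fiber.x1
    dy = fiber.y2 - fiber.y1
    if dx == 0.0:  # vertical fiber
        return fiber.x1, float(line.row_at(fiber.x1))
    mf = dy / dx
    denom = mf - line.slope
    if abs(math.degrees(math.atan(mf)) - math.degrees(math.atan(line.slope))) < 1.0:
        raise InvalidFiberError(
            "fiber line is (near-)parallel to an aponeurosis fit; no intersection"
        )
    bf = fiber.y1 - mf * fiber.x1
    x = (line.intercept - bf) / denom
    return float(x), float(line.row_at(x))


def measure_fascicles(
    apo: AponeurosisPair,
    fibers: Sequence[FiberLine],
    scale: float,
    image_width: Optional[int] = None,
) -> FascicleMeasurement:
    """Fascicle geometry from three fiber lines and the aponeurosis fits."""
    if len(fibers) != 3:
        raise ValueError(f"exactly three fiber lines required, got {len(fibers)}")
    if not scale > 0:
        raise ValueError("mm/px scale must be positive")
    lengths, angles, pennations = [], [], []
    for fib in fibers:
        xs, ys = _intersect(fib, apo.superficial)
        xd, yd = _intersect(fib, apo.deep)
        lf = math.hypot(xd - xs, yd - ys) * scale
        lengths.append(lf)
        # inclination above the horizontal in y-up coordinates (y = -row)
        ang = math.degrees(math.atan2(abs(yd - ys), abs(xd - xs)))
        angles.append(ang)
        deep_ang = math.degrees(math.atan(-apo.deep.slope))
        fib_ang = math.degrees(math.atan2(-(yd - ys), xd - xs))
        pen = abs(fib_ang - deep_ang)
        pennations.append(min(pen, 180.0 - pen))
    w = image_width or int(max(apo.superficial.col_max, apo.deep.col_max)) + 1
    cols = np.arange(w)
    vert = (apo.deep.row_at(cols) - apo.superficial.row_at(cols)) * scale
    orth = vert * math.cos(math.atan(apo.deep.slope))
    return FascicleMeasurement(
        lf_mean=float(np.mean(lengths)),
        lf_sd=float(np.std(lengths, ddof=0)),
        angle_mean=float(np.mean(angles)),
        angle_sd=float(np.std(angles, ddof=0)),
        pennation=float(np.mean(pennations)),
        pennation_sd=float(np.std(pennations, ddof=0)),
        thickness_mean=float(np.mean(orth)),
        thickness_sd=float(np.std(orth, ddof=0)),
        scale=scale,
        lf_each=tuple(lengths),
    )


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def icc_agreement(series_a, series_b) -> float:
    """Two-way random, absolute-agreement, single-measure ICC (ICC2).

    The agreement statistic used to validate the frame analysis against a
    reference measurement series.
    """
    import pingouin as pg  # deferred: heavy import

    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be paired 1-D arrays")
    if a.size < 5:
        raise ValueError("need at least 5 pairs for a meaningful ICC")
    if np.var(a) == 0 and np.var(b) == 0:
        raise UndefinedStatisticError("zero variance in both series; ICC undefined")
    n = a.size
    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "score": np.concatenate([a, b]),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        res = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="score")
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]  # label changed across versions
    return float(row["ICC"].iloc[0])


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def track_sequence(
    frames,
    frame_indices: Iterable[int],
    fiber_source,
    scale: Optional[float] = None,
    config: AnalysisConfig | None = None,
    phase_labels: Optional[dict] = None,
    normalize_do: bool = False,
) -> pd.DataFrame:
    """Measure fascicle geometry on selected frames of a sequence.

    Parameters
    ----------
    frames
        A :class:`~gravjump.synthgen.FrameSequence` (``frame(i)`` +
        ``truth_fibers(i)``) or a sequence of 2-D arrays.
    frame_indices
        Frames to analyze (the five marks, plus the braking interval when
        requested).
    fiber_source
        ``"truth"`` to use the sequence's synthetic-truth fiber lines, a
        mapping ``frame_idx -> [FiberLine, ...]``, or a callable.
    normalize_do
        Add an ``lf_norm_do`` column using the frame labelled ``DO``.

    Frames whose segmentation fails are skipped with a log entry; an empty
    result with every frame failed raises :class:`SegmentationError`.
    """
    cfg = config or AnalysisConfig()
    phase_labels = phase_labels or {}
    if scale is None:
        scale = getattr(getattr(frames, "imaging", None), "mm_per_px", None)
        if scale is None:
            raise ValueError("mm/px scale required when frames carry no imaging info")

    def get_frame(i):
        return frames.frame(i) if hasattr(frames, "frame") else frames[i]

    def get_fibers(i):
        if fiber_source == "truth":
            return frames.truth_fibers(i)
        if callable(fiber_source):
            return fiber_source(i)
        return fiber_source[i]

    rows, failures = [], []
    for i in sorted(set(int(j) for j in frame_indices)):
        try:
            img = get_frame(i)
            apo = segment_aponeuroses(img, cfg)
            meas = measure_fascicles(apo, get_fibers(i), scale,
                                     image_width=img.shape[1])
        except (SegmentationError, InvalidFiberError) as exc:
            log.warning("frame %d skipped: %s", i, exc)
            failures.append((i, str(exc)))
            continue
        rows.append({
            "frame_idx": i,
            "phase": phase_labels.get(i, ""),
            "lf_mm": meas.lf_mean,
            "lf_sd_mm": meas.lf_sd,
            "angle_deg": meas.angle_mean,
            "pennation_deg": meas.pennation,
            "thickness_mm": meas.thickness_mean,
        })
    if not rows:
        raise SegmentationError(
            f"all {len(failures)} selected frames failed segmentation: {failures}"
        )
    df = pd.DataFrame(rows)
    if normalize_do:
        do_rows = df.loc[df["phase"] == "DO", "lf_mm"]
        if do_rows.empty:
            raise ValueError("no DO frame available for normalization")
        df["lf_norm_do"] = df["lf_mm"] / float(do_rows.iloc[0])
    return df


def read_fiber_lines(path) -> dict:
    """Read operator fiber lines: CSV with frame_idx, x1, y1, x2, y2."""
    df = pd.read_csv(path)
    out: dict[int, list[FiberLine]] = {}
    for _, row in df.iterrows():
        out.setdefault(int(row["frame_idx"]), []).append(
            FiberLine(row["x1"], row["y1"], row["x2"], row["y2"], "operator")
        )
    return out


def write_fiber_lines(fibers: dict, path) -> None:
    rows = [
        {"frame_idx": i, "x1": f.x1, "y1": f.y1, "x2": f.x2, "y2": f.y2}
        for i, fl in fibers.items()
        for f in fl
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
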