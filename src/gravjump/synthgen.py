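"""Synthetic drop-jump trials with full ground truth.

No public recordings of parabolic-flight drop jumps exist, so every stage of
the pipeline is exercised against generated trials that reproduce the signal
*shapes* the detectors and measurement code rely on:

* vertical ground reaction force (2 kHz) that is ~0 N in flight, crosses the
  20 N gate steeply at ground contact, peaks during braking and falls back to
  0 N at push-off;
* a platform-load channel that unloads abruptly at fall onset;
* an ankle-angle trace (100 Hz) with a unique minimum at the end of braking;
* surface EMG (2 kHz) built as band-limited noise modulated by an activation
  envelope with a pre-activation burst and a post-braking drop;
* a gravity channel following a parabolic-flight profile;
* B-mode-like ultrasound frames (82 Hz) rendered from a programmed fascicle
  trajectory with known aponeurosis geometry.

The mechanics are a deliberate minimum — a point mass falling under the
recorded gravity trace, with prescribed contact-force and activation shapes —
not a musculoskeletal simulation.  All randomness flows from the explicit
``seed`` argument of each call; there is no hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .core import (
    FRAME_RATE_HZ,
    GroundTruth,
    SubjectParams,
    Trace,
    Trial,
    _subseed,
    log,
)

G0 = 9.81  # m/s^2 per g-unit

GRAVITY_PROFILES = ("steady", "hypo", "hyper", "transition")

#: Table of nine gravity clusters: name -> (programmed mean, between-trial SD).
CLUSTER_LEVELS = {
    "0-0.25": (0.19, 0.06),
    "0.25-0.5": (0.39, 0.08),
    "0.5-0.75": (0.62, 0.08),
    "0.75-1": (0.91, 0.07),
    "1g": (1.00, 0.05),
    "1-1.25": (1.11, 0.08),
    "1.25-1.5": (1.41, 0.07),
    "1.5-1.75": (1.64, 0.08),
    "1.75-2": (1.81, 0.05),
}


# ---------------------------------------------------------------------------
# gravity
# ---------------------------------------------------------------------------

def simulate_parabola_gravity(
    profile: str,
    level: float,
    noise_sd: float,
    duration: float,
    seed: int,
    rate: float = 1000.0,
    ramp_amplitude: float = 0.1,
) -> Trace:
    """Cabin-floor-normal acceleration in g-units for one jump window.

    ``steady`` / ``hypo`` / ``hyper`` hold ``level`` with additive Gaussian
    noise; ``transition`` adds a zero-mean linear ramp of half-amplitude
    ``ramp_amplitude`` (the aircraft moving between phases), so the mean over
    the window still equals ``level``.
    """
    if profile not in GRAVITY_PROFILES:
        raise ValueError(f"unknown gravity profile {profile!r}")
    if not 0.0 <= level <= 2.0:
        raise ValueError(f"gravity level must lie in [0, 2] g, got {level}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(_subseed(seed, 101))
    n = int(round(duration * rate)) + 1
    g = np.full(n, float(level))
    if profile == "transition":
        g += np.linspace(-ramp_amplitude, ramp_amplitude, n)
    if noise_sd > 0:
        g += rng.normal(0.0, noise_sd, n)
    tr = Trace(t0=0.0, rate=rate, values=g, units="g")
    tr.profile = {"label": profile, "level": level, "noise_sd": noise_sd}
    return tr


# ---------------------------------------------------------------------------
# programmed jump shape as a function of gravity level
# ---------------------------------------------------------------------------

_LEVEL_GRID = np.array([0.0, 0.19, 0.39, 0.62, 0.91, 1.0, 1.11, 1.41, 1.64, 1.81, 2.0])
# fraction of standing fascicle length at drop-off
_LF_DO_FRAC = np.array([0.70, 0.706, 0.715, 0.73, 0.74, 0.810, 0.70, 0.66, 0.64, 0.62, 0.61])
# fractional fascicle shortening DO -> GC (pre-activation)
_PREACT_SHORT = np.array([0.09, 0.10, 0.152, 0.18, 0.21, 0.259, 0.22, 0.21, 0.205, 0.20, 0.20])
# fractional fascicle length change GC -> MAJ (braking); <0 = keeps shortening
_LENGTHENING = np.array([0.05, 0.04, 0.03, 0.02, 0.01, -0.052, 0.16, 0.18, 0.19, 0.20, 0.20])
# push-off fascicle length as a fraction of DO length
_PO_FRAC = np.array([0.75, 0.748, 0.70, 0.66, 0.62, 0.584, 0.66, 0.70, 0.71, 0.72, 0.72])
# ankle angle at drop-off, deg (plantar-flexed away from 1 g)
_ANKLE_DO = np.array([138.0, 137.1, 137.5, 137.5, 136.5, 130.4, 137.0, 138.0, 139.0, 139.9, 140.0])


def programmed_shape(level: float) -> dict:
    """The generator's stated jump shape at a nominal gravity level.

    Interpolated between the nine cluster anchors; these fractions define
    the programmed fascicle trajectory (and hence the recovery targets of
    the end-to-end tests).
    """
    level = float(level)
    return {
        "lf_do_frac": float(np.interp(level, _LEVEL_GRID, _LF_DO_FRAC)),
        "preact_shortening": float(np.interp(level, _LEVEL_GRID, _PREACT_SHORT)),
        "lengthening": float(np.interp(level, _LEVEL_GRID, _LENGTHENING)),
        "po_frac": float(np.interp(level, _LEVEL_GRID, _PO_FRAC)),
        "ankle_do": float(np.interp(level, _LEVEL_GRID, _ANKLE_DO)),
    }


@dataclass
class ActivationParams:
    """Timing/gain knobs of the prescribed jump mechanics and activation."""

    gm_gain: float = 1.0
    ta_gain: float = 1.0
    preact_lead_s: float = 0.150     # GM burst begins this long before GC
    braking_s: float = 0.130         # GC -> MAJ
    push_s: float = 0.170            # MAJ -> PO
    impact_scale: float = 2.0        # braking peak = m*g0*(0.5 + scale*level)
    emg_baseline: float = 0.05       # resting envelope, fraction of MVC
    lengthening: Optional[float] = None          # None -> programmed_shape(level)
    preact_shortening: Optional[float] = None
    lf_do_frac: Optional[float] = None
    po_frac: Optional[float] = None
    ankle_dip_deg: float = 22.0

    def __post_init__(self):
        if self.gm_gain < 0 or self.ta_gain < 0:
            raise ValueError("activation gains must be non-negative")
        if self.braking_s <= 0 or self.push_s <= 0:
            raise ValueError("contact phase durations must be positive")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _bandlimited_noise(rng: np.random.Generator, n: int, rate: float,
                       lo: float = 20.0, hi: float = 450.0,
                       stabilize_s: float = 0.0125) -> np.ndarray:
    """Zero-mean band-pass noise with unit mean rectified amplitude.

    The local amplitude is stabilized (each sample divided by the moving
    mean rectified amplitude over ``stabilize_s``) so that windowed EMG
    statistics track the programmed activation envelope instead of the
    slow amplitude modulation that raw filtered noise carries.
    """
    white = rng.standard_normal(n + 400)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, white)[200:-200]
    from scipy.ndimage import uniform_filter1d

    k = max(int(round(stabilize_s * rate)), 3)
    local = uniform_filter1d(np.abs(x), size=k, mode="nearest")
    x = x / np.maximum(local, 1e-12)
    m = np.mean(np.abs(x))
    return x / m if m > 0 else x


def _envelope(t: np.ndarray, points: list[tuple[float, float]]) -> np.ndarray:
    ts, vs = zip(*points)
    return np.interp(t, ts, vs)


# ---------------------------------------------------------------------------
# the drop jump
# ---------------------------------------------------------------------------

def simulate_drop_jump(
    subject: SubjectParams,
    gravity: Trace,
    activation: Optional[ActivationParams] = None,
    seed: int = 0,
    *,
    is_reference: bool = False,
    trial_id: str = "trial",
    stand_s: float = 0.8,
    grf_rate: float = 2000.0,
    ankle_rate: float = 100.0,
    imaging: "ImagingParams | None" = None,
) -> Trial:
    """Simulate one drop jump under the supplied gravity trace.

    The participant stands on the platform until ``stand_s`` (fall onset),
    free-falls from ``subject.drop_height_cm`` under the *recorded* gravity
    (numerically integrated, so drifting gravity shifts the landing), then
    runs a prescribed braking/push-off contact profile.  Ground truth for
    every downstream stage is attached to the returned trial.
    """
    from .usseg import ImagingParams  # local import to avoid cycle

    act = activation or ActivationParams()
    level = float(np.mean(gravity.values))
    shape = programmed_shape(level)
    lf_do_frac = act.lf_do_frac if act.lf_do_frac is not None else shape["lf_do_frac"]
    preact = (act.preact_shortening if act.preact_shortening is not None
              else shape["preact_shortening"])
    lengthening = act.lengthening if act.lengthening is not None else shape["lengthening"]
    po_frac = act.po_frac if act.po_frac is not None else shape["po_frac"]
    ankle_do = shape["ankle_do"]

    rng = np.random.default_rng(_subseed(seed, 7))

    # --- timeline: integrate the gravity trace through the fall -------------
    fall_onset = stand_s
    if fall_onset >= gravity.t_end:
        raise ValueError("gravity trace does not span the standing phase")
    h = subject.drop_height_cm / 100.0
    gt = gravity.times
    gv = np.clip(gravity.values, 0.0, None) * G0
    mask = gt >= fall_onset
    tt = gt[mask]
    aa = gv[mask]
    dt = 1.0 / gravity.rate
    vel = np.cumsum(aa) * dt
    dist = np.cumsum(vel) * dt
    idx = np.searchsorted(dist, h)
    if idx >= len(tt):
        raise ValueError(
            f"gravity trace too short or too weak to land from {h*100:.0f} cm "
            f"(mean level {level:.2f} g)"
        )
    gc = float(tt[idx])
    maj = gc + act.braking_s
    po_end = maj + act.push_s  # force returns to zero here
    duration = gravity.t_end
    if po_end + 0.2 > duration:
        raise ValueError("gravity trace must span the jump plus 0.2 s of take-off flight")

    m = subject.body_mass_kg
    f_peak = m * G0 * (0.5 + act.impact_scale * max(level, 0.05))

    # --- GRF on the 2 kHz grid ---------------------------------------------
    # plates on the cabin floor read ~0 N until landing (the participant
    # stands on the raised platform, whose load is a separate channel)
    n_grf = int(round(duration * grf_rate)) + 1
    t = np.arange(n_grf) / grf_rate
    f = np.zeros(n_grf)
    contact = (t >= gc) & (t <= po_end)
    tau = t[contact] - gc
    prof = np.where(
        tau <= act.braking_s,
        f_peak * np.sin(np.pi * tau / (2 * act.braking_s)),
        f_peak * np.cos(np.pi * (tau - act.braking_s) / (2 * act.push_s)),
    )
    f[contact] = np.clip(prof, 0.0, None)

    # truth GC / PO on the GRF grid against the 20 N gate (noise-free profile)
    thr = 20.0
    in_contact = np.flatnonzero((t >= gc) & (f > thr))
    truth_gc = float(t[in_contact[0]])
    truth_po = float(t[in_contact[-1]])
    truth_delta = float(np.max(f[(t >= truth_gc) & (t <= maj)]) - f[in_contact[0]])

    noise = rng.normal(0.0, 0.7, (2, n_grf))
    grf_left = Trace(0.0, grf_rate, 0.5 * f + noise[0], "N")
    grf_right = Trace(0.0, grf_rate, 0.5 * f + noise[1], "N")

    # standing load on the platform channel, unloading at fall onset
    load = np.where(t < fall_onset, m * G0 * max(level, 0.05), 0.0)
    load = load + rng.normal(0.0, 2.0, n_grf)
    platform = Trace(0.0, grf_rate, load, "N")

    # --- ankle angle (100 Hz) ----------------------------------------------
    a0 = ankle_do
    pts_t = [0.0, fall_onset, gc, maj, po_end, duration]
    pts_a = [a0, a0, a0 + 3.0, a0 + 3.0 - act.ankle_dip_deg,
             a0 + 3.0 - act.ankle_dip_deg + 35.0,
             a0 + 3.0 - act.ankle_dip_deg + 35.0]
    ankle_f = PchipInterpolator(pts_t, pts_a)
    n_ank = int(round(duration * ankle_rate)) + 1
    t_ank = np.arange(n_ank) / ankle_rate
    ankle = Trace(0.0, ankle_rate, ankle_f(t_ank) + rng.normal(0, 0.02, n_ank), "deg")

    # --- EMG (2 kHz): envelope-modulated band-limited noise ----------------
    b = act.emg_baseline
    env_gm = _envelope(t, [
        (0.0, b), (fall_onset, b), (max(gc - act.preact_lead_s, fall_onset), b),
        (gc, 0.55), (maj, 0.95), (po_end, 0.12), (min(po_end + 0.2, duration), b),
        (duration, b),
    ]) * act.gm_gain
    env_ta = _envelope(t, [
        (0.0, b), (fall_onset, b), (max(gc - 0.12, fall_onset), b),
        (gc, 0.35), (maj, 0.30), (po_end, 0.10), (min(po_end + 0.2, duration), b),
        (duration, b),
    ]) * act.ta_gain
    emg_gm = Trace(0.0, grf_rate,
                   env_gm * subject.mvc_gm * _bandlimited_noise(rng, n_grf, grf_rate),
                   "mV")
    emg_ta = Trace(0.0, grf_rate,
                   env_ta * subject.mvc_ta * _bandlimited_noise(rng, n_grf, grf_rate),
                   "mV")

    # --- fascicle trajectory and frames ------------------------------------
    lf_do = subject.lf_stand_mm * lf_do_frac
    lf_gc = lf_do * (1.0 - preact)
    lf_maj = lf_gc * (1.0 + lengthening)
    lf_po = lf_do * po_frac
    lf_f = PchipInterpolator(
        [0.0, fall_onset, truth_gc, maj, truth_po, duration],
        [lf_do, lf_do, lf_gc, lf_maj, lf_po, lf_po],
    )
    n_fr = int(math.floor(duration * FRAME_RATE_HZ)) + 1
    t_fr = np.arange(n_fr) / FRAME_RATE_HZ
    lf_traj = Trace(0.0, FRAME_RATE_HZ, lf_f(t_fr), "mm")

    do = fall_onset - 0.012
    pre100 = max(truth_gc - 0.100, fall_onset)
    lf_marks = {
        "DO": float(lf_f(do)),
        "PRE100": float(lf_f(pre100)),
        "GC": float(lf_f(truth_gc)),
        "MAJ": float(lf_f(maj)),
        "PO": float(lf_f(truth_po)),
    }

    imaging = imaging or ImagingParams()
    frames = FrameSequence(lf_traj, imaging=imaging, seed=_subseed(seed, 21))

    profile_meta = getattr(gravity, "profile", {"label": "external", "level": level})
    truth = GroundTruth(
        fall_onset=fall_onset, gc=truth_gc, maj=maj, po=truth_po,
        lf_traj=lf_traj, lf_marks=lf_marks, ankle_do=a0,
        fiber_thickness_mm=imaging.thickness_mm,
        gravity_profile=dict(profile_meta), delta_grf=truth_delta,
    )
    return Trial(
        grf_left=grf_left, grf_right=grf_right, platform_load=platform,
        ankle=ankle, emg_gm=emg_gm, emg_ta=emg_ta, gravity_z=gravity,
        frames=frames, subject=subject, truth=truth,
        trial_id=trial_id, is_reference=is_reference,
    )


# ---------------------------------------------------------------------------
# ultrasound rendering
# ---------------------------------------------------------------------------

def render_ultrasound_frame(
    lf_mm: float,
    imaging: "ImagingParams | None" = None,
    fiber_angle_deg: Optional[float] = None,
    thickness_mm: Optional[float] = None,
    seed: int = 0,
):
    """Render one B-mode-like frame for a programmed fascicle length.

    Two bright quasi-linear bands (the aponeuroses) are separated by the
    orthogonal ``thickness_mm``; oriented fascicle texture fills the muscle
    belly at the pennation angle implied by the chord geometry,
    ``asin(thickness / lf)``.  Multiplicative log-normal speckle is applied
    at ``imaging.speckle_sd``.  Row 0 is the skin (superficial) side.

    Returns ``(image, truth)`` where ``truth`` is a :class:`FrameTruth` with
    the aponeurosis lines (px), the pixel scale, and three ground-truth
    fiber lines.
    """
    from .usseg import FiberLine, ImagingParams  # avoid import cycle

    imaging = imaging or ImagingParams()
    thickness = imaging.thickness_mm if thickness_mm is None else float(thickness_mm)
    if lf_mm <= 0 or thickness <= 0:
        raise ValueError("fascicle length and thickness must be positive")
    if thickness >= imaging.depth_mm - imaging.superficial_depth_mm:
        raise ValueError("aponeurosis separation exceeds the imaging depth")
    if lf_mm <= thickness * 1.001:
        raise ValueError(
            f"geometry cannot admit lf={lf_mm:.1f} mm between aponeuroses "
            f"{thickness:.1f} mm apart"
        )
    theta = math.degrees(math.asin(thickness / lf_mm))
    if fiber_angle_deg is not None:
        if fiber_angle_deg < 1.0:
            raise ValueError("fiber angle below 1 deg cannot intersect both aponeuroses")
        if abs(fiber_angle_deg - theta) > 0.5:
            raise ValueError(
                f"fiber angle {fiber_angle_deg:.2f} deg inconsistent with "
                f"lf={lf_mm:.1f} mm and thickness={thickness:.1f} mm "
                f"(implies {theta:.2f} deg)"
            )
        theta = float(fiber_angle_deg)

    scale = imaging.mm_per_px
    H = int(round(imaging.depth_mm / scale))
    W = int(round(imaging.width_mm / scale))
    rows = (np.arange(H)[:, None] + 0.5) * scale   # depth, mm
    cols = (np.arange(W)[None, :] + 0.5) * scale   # lateral position, mm

    phi = math.radians(imaging.slope_deg)          # band inclination vs horizontal
    # band center depths at lateral position x (depth grows with +slope to the right)
    d_sup = imaging.superficial_depth_mm + math.tan(phi) * (cols - imaging.width_mm / 2)
    d_deep = d_sup + thickness / math.cos(phi)

    w_band = imaging.band_sigma_mm
    img = np.full((H, W), 0.12)
    between = (rows > d_sup) & (rows < d_deep)
    img[between] = 0.22

    # fascicle texture: stripes constant along the fiber direction.
    # In y-up coordinates (y = -depth) a band whose depth grows with +x has
    # inclination -phi, so a fiber at angle theta above the band runs at
    # theta - phi versus the horizontal.
    alpha = math.radians(theta) - phi
    u = -cols * math.sin(alpha) - rows * math.cos(alpha)  # y = -depth
    stripes = 0.10 * np.cos(2 * np.pi * u / imaging.stripe_period_mm)
    img = np.where(between, img + stripes, img)

    dist_orth = math.cos(phi)
    for d_line in (d_sup, d_deep):
        img += 0.85 * np.exp(-((rows - d_line) * dist_orth) ** 2 / (2 * w_band**2))

    if imaging.speckle_sd > 0:
        rng = np.random.default_rng(_subseed(seed, 33))
        sd = imaging.speckle_sd
        img *= rng.lognormal(mean=-0.5 * sd**2, sigma=sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    # line fits in pixel space: row = slope*col + intercept
    px_slope = math.tan(phi)  # d(depth px)/d(col px) equals d(mm)/d(mm)
    sup_b = (imaging.superficial_depth_mm - math.tan(phi) * imaging.width_mm / 2) / scale - 0.5
    deep_b = sup_b + thickness / math.cos(phi) / scale
    # three truth fiber chords anchored on the deep aponeurosis
    span_x = lf_mm * math.cos(alpha)
    x0_center = (imaging.width_mm - span_x) / 2
    if x0_center < 1.0 or x0_center + span_x > imaging.width_mm - 1.0:
        raise ValueError("image width cannot admit the fascicle chord")
    fibers = []
    for off in (-3.0, 0.0, 3.0):
        xa = min(max(x0_center + off, 1.0), imaging.width_mm - span_x - 1.0)
        da = imaging.superficial_depth_mm + thickness / math.cos(phi) + math.tan(phi) * (
            xa - imaging.width_mm / 2)
        xb = xa + span_x
        db = da - lf_mm * math.sin(alpha)
        fibers.append(FiberLine(
            x1=xa / scale - 0.5, y1=da / scale - 0.5,
            x2=xb / scale - 0.5, y2=db / scale - 0.5,
            provenance="synthetic-truth",
        ))
    truth = FrameTruth(
        sup_slope=px_slope, sup_intercept=sup_b,
        deep_slope=px_slope, deep_intercept=deep_b,
        fiber_angle_deg=theta, lf_mm=lf_mm, thickness_mm=thickness,
        mm_per_px=scale, fibers=fibers,
    )
    return img, truth


@dataclass
class FrameTruth:
    """Ground-truth geometry of one rendered frame (pixel coordinates)."""

    sup_slope: float
    sup_intercept: float
    deep_slope: float
    deep_intercept: float
    fiber_angle_deg: float
    lf_mm: float
    thickness_mm: float
    mm_per_px: float
    fibers: list = field(default_factory=list)


class FrameSequence:
    """Lazy 82 Hz ultrasound frame sequence driven by a fascicle trajectory.

    Frames are rendered on demand (rendering and segmenting every frame of
    every trial would dominate runtime for cohort-scale analyses) and cached.
    """

    rate = FRAME_RATE_HZ

    def __init__(self, lf_traj: Trace, imaging, seed: int = 0):
        self.lf_traj = lf_traj
        self.imaging = imaging
        self.seed = int(seed)
        self.t0 = lf_traj.t0
        self._cache: dict[int, tuple] = {}

    def __len__(self) -> int:
        return len(self.lf_traj)

    def time_at(self, i: int) -> float:
        return self.lf_traj.time_at(i)

    def index_at(self, t: float) -> int:
        return self.lf_traj.index_at(t, clip=True)

    def _render(self, i: int):
        if i not in self._cache:
            lf = float(self.lf_traj.values[i])
            self._cache[i] = render_ultrasound_frame(
                lf, imaging=self.imaging, seed=_subseed(self.seed, i))
        return self._cache[i]

    def frame(self, i: int) -> np.ndarray:
        return self._render(i)[0]

    def truth(self, i: int) -> FrameTruth:
        return self._render(i)[1]

    def truth_fibers(self, i: int) -> list:
        return self.truth(i).fibers


# ---------------------------------------------------------------------------
# MVC
# ---------------------------------------------------------------------------

def simulate_mvc(
    subject: SubjectParams,
    seed: int = 0,
    muscle: str = "gm",
    rate: float = 2000.0,
    burst_s: float = 3.0,
    noiseless: bool = False,
) -> Trace:
    """A 3 s maximal isometric effort flanked by rest.

    The burst is calibrated so its mean rectified amplitude equals the
    subject's programmed MVC amplitude; ``noiseless=True`` returns the bare
    envelope (a square burst) for closed-form checks.
    """
    amp = {"gm": subject.mvc_gm, "ta": subject.mvc_ta}[muscle.lower()]
    dur = burst_s + 2.0
    n = int(round(dur * rate)) + 1
    t = np.arange(n) / rate
    env = _envelope(t, [(0.0, 0.0), (0.9, 0.0), (1.1, 1.0),
                        (0.9 + burst_s, 1.0), (1.1 + burst_s, 0.0), (dur, 0.0)])
    if noiseless:
        return Trace(0.0, rate, env * amp, "mV")
    rng = np.random.default_rng(_subseed(seed, 55))
    x = env * amp * _bandlimited_noise(rng, n, rate)
    # calibrate on the reference statistic itself: the mean rectified
    # amplitude over the rectified peak +/- 25 ms must equal the programmed
    # MVC amplitude (the generator's contract with the normalization stage)
    if amp > 0:
        rect = np.abs(x)
        p = int(np.argmax(rect))
        half = int(round(0.025 * rate))
        ref = np.mean(rect[max(p - half, 0) : min(p + half, n - 1) + 1])
        if ref > 0:
            x *= amp / ref
    return Trace(0.0, rate, x, "mV")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def make_trial(
    level: float,
    seed: int,
    subject: Optional[SubjectParams] = None,
    profile: str = "steady",
    noise_sd: float = 0.02,
    is_reference: bool = False,
    trial_id: Optional[str] = None,
    activation: Optional[ActivationParams] = None,
    duration: float = 3.5,
    imaging=None,
) -> Trial:
    """Convenience wrapper: gravity profile + drop jump in one call."""
    subject = subject or SubjectParams()
    grav = simulate_parabola_gravity(profile, level, noise_sd, duration,
                                     seed=_subseed(seed, 1))
    return simulate_drop_jump(
        subject, grav, activation=activation, seed=_subseed(seed, 2),
        is_reference=is_reference,
        trial_id=trial_id or f"trial_L{level:.2f}_s{seed}",
        imaging=imaging,
    )


def simulate_cohort(
    seed: int,
    n_subjects: int = 15,
    jumps_per_cluster: int = 3,
    clusters: Optional[dict] = None,
    noise_sd: float = 0.02,
    imaging=None,
):
    """Yield trials for a full gravity-cluster cohort.

    Defaults reproduce the stated study structure: 15 pseudo-subjects, up to
    three jumps per gravity cluster, nine clusters programmed at the
    published mean +/- SD levels.  The ``1g`` cluster is generated as flagged
    reference jumps at steady 1 g.
    """
    clusters = clusters or CLUSTER_LEVELS
    rng = np.random.default_rng(_subseed(seed, 999))
    for si in range(n_subjects):
        subj_seed = _subseed(seed, 1000 + si)
        subject = SubjectParams(
            lf_stand_mm=float(np.clip(rng.normal(57.4, 4.0), 45.0, 70.0)),
            body_mass_kg=float(np.clip(rng.normal(72.0, 12.0), 50.0, 100.0)),
        )
        for ci, (name, (mu, sd)) in enumerate(clusters.items()):
            is_ref = name == "1g"
            for j in range(jumps_per_cluster):
                lvl = 1.0 if is_ref else float(np.clip(rng.normal(mu, sd), 0.08, 2.0))
                yield make_trial(
                    lvl,
                    seed=_subseed(subj_seed, ci * 101 + j),
                    subject=subject,
                    noise_sd=noise_sd,
                    is_reference=is_ref,
                    trial_id=f"S{si:02d}_{name}_j{j}",
                    imaging=imaging,
                )
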