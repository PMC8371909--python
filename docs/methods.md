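# Methods

`gravjump` reimplements, as a tested pipeline, the analysis chain used to
study gastrocnemius medialis (GM) fascicle and sarcomere behavior during
drop jumps performed at gravity levels between 0 and 2 g (parabolic flight).
This note documents the models, the tunable parameters, the synthetic-data
generator, and the numerical choices where the original description left the
design open.

## The analysis chain

A trial is one drop jump: bilateral vertical ground reaction force (GRF,
2 kHz), a platform-load channel, ankle angle (100 Hz), GM and tibialis
anterior (TA) surface EMG (2 kHz), floor-normal acceleration (g-units), and
a B-mode ultrasound frame sequence (82 Hz), plus two subject constants (the
standing fascicle length `Lf_stand` and the MVC reference amplitudes).

1. **Phase detection** (`phases`). Five time points per jump:
   - *DO* (drop-off): 12 ms before fall onset. Fall onset is detected as the
     first sample where the platform load drops below a configurable
     fraction (default 0.2) of the standing load. The original protocol
     identified fall onset by visual video inspection; an automatic unload
     detector replaces it so the pipeline is testable.
   - *PRE100*: 100 ms before ground contact. If the fall is shorter than
     100 ms (possible under strong hyper-gravity from a low platform),
     PRE100 is clipped to fall onset and flagged with a logged warning.
   - *GC*: first sample after the flight interval at which the summed GRF of
     both plates exceeds 20 N. Onset comparisons are strict (`>`) and
     debounced: the signal must hold past the threshold for ≥ 5 ms, because
     2 kHz plate noise can chatter at 20 N. Whether the published 20 N rule
     applied per plate or to the sum is not stated; the sum is the default
     and per-plate gating is a config switch.
   - *MAJ*: minimum ankle angle within [GC, PO] (end of braking), detected
     on the kinematic clock; ties break to the earliest sample.
   - *PO*: last sample at or above 20 N before the take-off flight.
   Marks are associated with ultrasound frames by nearest-neighbor in time
   (no interpolation).

2. **Gravity clustering** (`gravity`). Per jump, the floor-normal
   acceleration is summarized at three instants (GC−150 ms, GC, PO) and two
   intervals (GC→PO and GC−150 ms→PO). Cluster assignment bins the mean
   over the *wider* interval into eight 0.25 g-wide, lower-inclusive bins
   between 0 and 2 g (the top bin closes at 2.0); the reserved `1g` cluster
   is for flagged reference jumps (pre-flight ground or steady flight), not
   a numeric bin. A jump whose maximum absolute excursion from the interval
   mean exceeds 0.3 g is excluded as unstable. The exclusion statistic is
   the *excursion*, not the SD: the published rule ("deviations above 0.3 g,
   above the 0.25 g range of each cluster") reads as an excursion bound and
   is motivated by the bin width; the limit is configurable.

3. **EMG activity** (`emg`). The published chain — rectify, average,
   integrate (iEMG), time-normalize to 1 s, normalize to MVC — composes to
   one number: the mean rectified amplitude over the ±25 ms window around
   each mark, divided by the MVC reference (the mean rectified amplitude
   over the MVC peak ± 25 ms). The GM/TA ratio is taken per mark and
   log-transformed in base 10 (the base is not stated in the source; the
   magnitudes are consistent with base 10). Logs are taken per trial and
   then averaged — the published summary tables are evidently built the same
   way, since their printed log rows are not the logs of the printed means.
   Zero TA activity flags the ratio undefined rather than erroring. No
   filtering beyond the acquisition band (20 Hz–1 kHz) is applied.

4. **Ultrasound fascicle measurement** (`usseg`). Semi-automatic, matching
   the original software's division of labor:
   - *Automatic*: aponeurosis segmentation — 3×3 median smoothing, an
     intensity threshold at a configurable quantile (default 0.92), then
     morphological opening and closing with a flat rectangular structuring
     element (default 3×15 px, wide and short to favor horizontal bands),
     connected components filtered by area (default ≥ 400 px) and lateral
     coverage (≥ 60 % of image width), per-column centroid depths, and a
     straight-line fit per band. The original reports the shape family of
     the element but not its size or the threshold; these defaults are
     calibration choices exposed in the config. Aponeuroses are represented
     by straight-line fits with linear extrapolation: GM aponeuroses are
     near-linear at this field of view, and the fascicle length is defined
     by line intersections.
   - *Manual input*: three fiber lines per frame (operator CSV, or the
     generator's ground-truth lines in synthetic work). Fascicle length is
     the Euclidean chord of each fiber between its intersections with the
     two fits, × mm/px; outputs are the mean and SD over the three fibers,
     the fiber angle versus the horizontal, the pennation angle versus the
     deep aponeurosis, and the mean/SD per-column orthogonal
     inter-aponeurosis distance (thickness).
   - *Agreement*: `icc_agreement` computes the two-way random,
     absolute-agreement, single-measure ICC (ICC2; the concrete form is not
     stated in the source and was fixed here), via `pingouin`.

5. **Sarcomere estimation** (`sarcomere`). Serial sarcomere count
   `n = Lf_stand / 3.09 µm` (the in vivo GM sarcomere length at the same
   110° standing posture), kept real-valued — it is a scaling constant, and
   rounding would break the identity `SL = 3.09 · Lf / Lf_stand`. Operating
   sarcomere length per phase is `SL = Lf / n`; lengths are also normalized
   to the DO value. Relative force capacity comes from a piecewise-linear
   human length–tension curve with breakpoints

   | length (µm) | 1.27 | 1.67 | 2.64 | 2.81 | 4.24 |
   |---|---|---|---|---|---|
   | relative force | 0 | 0.677 | 1.0 | 1.0 | 0 |

   These follow human filament geometry (thick filament 1.60 µm, thin
   1.32 µm, bare zone 0.17 µm → plateau 2.64–2.81 µm, descending limb zero
   at 4.24 µm) with the ascending-limb junction at 1.67 µm chosen so the
   standard anchors hold: ≈ 40 % of maximum at 1.5 µm, ≈ 70 % at 1.74 µm,
   > 90 % at 2.50 µm. Force is 0 outside [1.27, 4.24] µm and exactly 1 on
   the plateau; breakpoints are config-overridable. Percent force values are
   reported rounded to the nearest 10 when echoing "about N %" statements.

6. **Orchestration** (`pipeline`). `analyze_trial` chains the stages into a
   five-row per-phase report; `aggregate` produces per-cluster per-phase
   mean ± SD tables (sample SD; a single trial reports SD 0). ΔGRF over
   braking defaults to (interval peak in [GC, MAJ]) − (GRF at GC); the
   instantaneous MAJ−GC variant is config-selectable because the source
   caption is ambiguous between the two readings. Mixed-model inference and
   post-hoc testing are deliberately out of scope: the aggregation tables
   are the hand-off point to standard statistical software.

## The synthetic-data generator

No public recordings of parabolic-flight drop jumps exist, so `synthgen`
produces trials with *known ground truth*. It is a stated world, not a
physiological simulation: a point mass falls from the 25 cm platform under
the recorded gravity trace (numerically integrated, so a 1 g jump lands
after the closed-form 0.226 s), then follows a prescribed contact-force
profile (sine-lobed braking peaking at MAJ, cosine push-off), a prescribed
ankle trajectory with its unique minimum at MAJ, and envelope-modulated
band-limited EMG noise with a pre-activation burst and a post-braking drop.
The per-cluster jump shape (DO fascicle length fraction, pre-activation
shortening, braking lengthening, push-off fraction, DO ankle angle) is
interpolated between anchors set at the nine cluster levels from the
published per-cluster values: quasi-isometric braking at 1 g (−5.2 %),
small stretch in hypo-gravity, +16–20 % stretch in hyper-gravity.

Ultrasound frames are rendered in pixel space at 0.2 mm/px (50 × 60 mm
field, row 0 at the skin): two Gaussian-profile bright bands separated by
the orthogonal thickness (default 18 mm), oriented stripe texture between
them at the pennation angle implied by the chord geometry
(`θ = asin(thickness / Lf)`), and multiplicative log-normal speckle
(σ = 0.25 by default). Frames are rendered lazily and cached, so cohort
runs only pay for the frames actually analyzed. EMG noise is
amplitude-stabilized (each sample divided by the local 12.5 ms mean
rectified amplitude) so that windowed statistics track the programmed
envelope; the MVC burst is calibrated so the standard peak ± 25 ms
reference extraction recovers the programmed amplitude. All randomness
flows from one explicit seed per call.

What a green test does and does not establish: the generator reproduces the
signal *shapes* the detectors rely on, with realistic rates, thresholds and
noise floors. It does not model tendon mechanics, probe motion, curved
fascicles, out-of-plane motion, vibration/turbulence artifacts beyond
additive gravity noise, or EMG stretch-reflex components — so green tests
validate the measurement chain, not any physiological claim, and accuracy
bounds on real images may be wider than the synthetic 2–5 % ones.

## Numerical choices and degenerate inputs

- Threshold crossings: strict `>` for onsets with 5 ms debounce; `≥` for
  the last loaded sample at push-off; flight intervals must last ≥ 50 ms.
- Interval statistics use closed sample intervals; "value at" a time point
  is the nearest sample.
- Tie-breaks: minimum ankle angle → earliest sample; MVC peak plateau →
  window centered on the plateau.
- Exclusion (gravity instability, out-of-range mean) is a *value* on the
  cluster label, not an error; detection failures, degenerate MVC
  references, undefined ICC and empty aggregations raise typed errors.
- A unit guard rejects standing fascicle lengths below 1 mm (almost
  certainly meters or µm passed where mm were meant).
- Sample SD with n = 1 is reported as 0 in cluster and aggregation tables.

## Known limitations

- Fiber lines are inputs; there is no automatic fascicle tracking.
- The unload-fraction DO detector replaces human video inspection and has
  no validation against real video-derived fall onsets.
- The published cross-software agreement (ICC 0.83 against manual ImageJ
  analysis of real frames) cannot be reproduced without the original
  recordings; the pipeline instead bounds agreement against synthetic
  ground truth (ICC ≥ 0.90 at default speckle), which is a different and
  easier comparison.
- Real-data results (per-cluster GRF deltas, EMG ratio tables, the
  Lf–ankle-angle correlation coefficient) are data-dependent and are
  computed by the pipeline but not asserted against published values.
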