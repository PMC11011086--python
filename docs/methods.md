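# Methods

## Model

A dog that is behaviourally asleep is, to a fixed camera, a static patch of
pixels. `dogsleep` operationalises sleep as *absence of pixel motion inside
the subject's bounding box sustained over a decision window*. The method
therefore has three layers with distinct assumptions:

1. **Localisation** is delegated to a detector interface. The package
   assumes some upstream component can put a box around each dog in each
   frame; it ships a ground-truth replay detector (synthetic validation), a
   static region-of-interest detector (single-kennel footage with a fixed
   resting spot), and accepts any user detector with the same
   `detect(frame) -> [Detection]` signature. Track identity across frames
   is greedy highest-IoU matching with a minimum-overlap threshold
   (default 0.3). Greedy matching rather than optimal assignment is
   deliberate: with at most two slowly moving dogs per kennel, boxes
   overlap their own predecessor far more than each other's, and ties are
   broken deterministically (by IoU, then detection order).

2. **Motion detection** is classical frame differencing on the cropped box
   content of consecutive frames: grayscale (ITU-R BT.601 luminance,
   rounded to uint8) → Gaussian blur → per-pixel absolute delta →
   binarization (strictly greater than the threshold) → square-element
   dilation → 8-connected component areas. Both crops use the *current*
   frame's box, so slow box drift from the tracker is not itself scored as
   motion. The qualifying area sums **all** components at least
   `min_component_area` pixels large, not only the largest: limb movement
   and whole-body movement should both count, and a dog shifting two paws
   produces two small components.

3. **Sleep scoring** applies a trailing window to the per-frame moved
   flags: ASLEEP at frame *t* when at most `max_awake_frames_in_window` of
   the window's measured frames moved, else AWAKE; frames with no
   measurement (missed detection, or the first frame of a session, which
   has no predecessor to difference against) are UNKNOWN and are never
   interpolated by default. The first `window − 1` measured frames of a
   track inherit the first full-window state. Maximal ASLEEP runs are
   sleeping bouts; UNKNOWN breaks a run.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `blur_kernel` | 21 | px | suppress sensor noise/compression artefacts on low-quality CCTV; sigma follows the 8-bit video convention 0.3·((k−1)/2−1)+0.8, reflect borders |
| `delta_threshold` | 25 | intensity | the standard frame-differencing operating point; ignores illumination drift of a few units |
| `dilate_kernel`, `dilate_iterations` | 3, 2 | px, — | fuse fragmented motion pixels into coherent components |
| `min_component_area` | 25 | px | a moving paw at typical box scale; smaller specks are noise |
| `min_motion_fraction` | 0.005 | fraction of box | scale-free moved/still decision across box sizes |
| `window` | 3 s of frames | frames | short enough to catch the brief arousals that delimit bouts, long enough that one noisy frame cannot wake a sleeping dog |
| `max_awake_frames_in_window` | 0 | frames | strictest reading of "no movement"; raise on noisy footage |
| `min_iou` | 0.3 | — | kennel dogs move a small fraction of their body length per frame |

All are configuration (`motion:`/`state:` YAML blocks, CLI overrides). The
camera frame rate is never assumed: it is read from container metadata or
must be supplied (`fps`) for image directories, and all timing is
`frame_index / fps`.

Two documented policy switches in bout extraction: boundary sleep runs
count as bouts by default (`strict_wsw: true` restores the literal
wake→sleep→wake definition; without it, overnight sessions that begin or
end asleep would be systematically undercounted), and UNKNOWN gaps inside
sleep are bridged only by explicit opt-in (`bridge_unknown_max_s`).

## Statistics

Paired t-test: t = mean(d)/(sd(d)/√n) with the sample (n−1) standard
deviation, df = n−1, two-sided p from the Student-t distribution (computed
through the regularized incomplete beta function). Zero-variance
differences raise an explicit degenerate-result error which the report
renders as "identical" rather than a fabricated statistic. The sample-sd
convention is used everywhere and stated here because published summary
tables do not always distinguish the two conventions; bout-count columns
are robust to the choice.

Anderson–Darling normality: A² on the standardized sorted sample with
estimated mean and sd, Stephens' small-sample correction
A\*² = A²(1 + 0.75/n + 2.25/n²), rejection when A\*² > 0.752 (α = 0.05,
normal case with estimated parameters). The decision and corrected
statistic are reported; no p-value is interpolated. Under the null
(normal data, n = 30) the implementation rejects at 0.042/0.05 nominal
over 1000 seeded replicates (recomputed by `scripts/acceptance.py`).

Frame-level agreement between two state sequences is the percentage of
jointly known (non-UNKNOWN) frames carrying the same label; 5340 matches
among 6000 jointly known frames is 89.0%.

No multiple-testing correction is applied across the three session-level
tests; each is reported at raw α = 0.05.

### Percent-of-time comparison on the bundled reference dataset

The bundled 11-night dataset publishes total sleep (H:MM:SS), bout counts,
and per-night percent-difference columns, but not the per-night
observation-window lengths, so percent of time asleep cannot be recomputed
from it directly (back-solving the published percent differences implies
no consistent denominator). The report therefore (a) runs a true paired
t-test on `percent_asleep` whenever both summaries carry it (the synthetic
pipeline path), and (b) on the reference dataset falls back to a
one-sample t-test on the published percent-difference values, signed by
which method recorded more sleep — algebraically a paired t-test on the
percentages given their differences. The package also computes its own
clearly labelled symmetric percent difference, 100·|a−b|/((a+b)/2), per
session. The bout percent-difference column is carried as supplied data
only and never recomputed (its published denominator is not derivable from
the counts).

## Synthetic generator

Scenarios render 0–2 dogs as ellipses with a fixed per-dog pseudo-random
texture on a uniform arena, grayscale (night vision) or colour (day).
Awake dogs take a zero-mean Gaussian random walk (default sd 2 px/frame)
and their texture phase jitters (limb motion); asleep dogs are
pixel-static apart from optional one-frame twitches (probability per
asleep frame, amplitude in px). Nuisances are applied globally after
compositing: integer global translation per frame (camera shake, with
ground-truth boxes shifted accordingly — so frame differencing against the
previous frame's content sees the shake, exactly as with real wind),
sinusoidal intensity flicker (lights), and per-pixel Gaussian sensor
noise. One seed sequence per scenario spawns independent substreams per
dog and for the nuisances, so enabling a nuisance never changes a dog's
trajectory. Frames are written as a PNG directory for bit-reproducibility.

What the generator does *not* emulate: dog morphology and posture change,
occlusion between dogs, shadows, gradual illumination ramps at dawn/dusk,
compression artefacts, and detector error (boxes are exact). Passing the
end-to-end tests therefore demonstrates the correctness of the motion →
state → summary chain under the method's own assumptions, not detector
robustness on real footage.

The observer error model perturbs a true state sequence the way a human
might: each bout boundary is jittered by a seeded zero-mean normal draw
and each bout is missed entirely with a lapse probability — enough
structure to exercise the comparison module with known disagreement.

## Numerical and degenerate-input choices

- Binarization is strict (`delta > threshold`); a delta exactly at the
  threshold is background.
- Blur accumulates in float64 and rounds once to uint8 at the end;
  dilation truncates the structuring element at image edges.
- With `min_motion_fraction = 0` every frame is flagged moved by
  definition (0 ≥ 0); the default is strictly positive.
- Bout times are end-exclusive frame counts / fps, so bout durations sum
  to total sleep exactly; H:MM:SS rendering truncates sub-second parts.
- An all-UNKNOWN session reports `percent_asleep` as missing rather than
  dividing by zero; frame agreement raises if no frame is jointly known.
- Event-log reading snaps interval endpoints to the frame grid by
  rounding, which makes the write→read round trip exact.
- Anderson–Darling clips standardized CDF values away from 0/1 so extreme
  outliers keep finite logs; n < 5 is rejected outright.

## Problem sizes

The validation suite and the acceptance script use five-minute scenarios
at 5 fps, 160×120 px (1500 frames) — long relative to the 3 s decision
window, in the same proportion as an overnight recording is to typical
40-minute dog sleep bouts — plus 1000 replicates for the normality-test
calibration and 200 randomized sequences for the annotation round trip.
The whole suite runs in well under a minute.

## Known limitations

- Sleep onset is confirmed only after one full decision window without
  motion, so every wake→sleep transition is scored one window (default
  3 s) late; wake onsets are immediate. On realistic bout lengths this
  bias is negligible (< 0.2% of a 40-minute bout) but it bounds per-frame
  agreement on heavily fragmented schedules.
- No global shake compensation or background modelling: sustained camera
  motion inflates apparent wakefulness monotonically (verified in tests),
  mirroring why windy nights must be excluded from field data.
- Re-identification after long occlusion is out of scope; a lost track
  resumes under a fresh subject id.
- Sleep stages (REM/NREM) and posture are not inferred; immobility is the
  whole signal.
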