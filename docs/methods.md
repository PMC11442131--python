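# Methods

`graspquant` implements a pipeline for quantifying which taxonomy
grasps a finger adopts during activities of daily living (ADL), from
four joint angles per finger — DIP flexion, PIP flexion, MCP flexion
and MCP abduction/adduction, all in degrees — sampled at 125 Hz. Four
fingers are modelled (index, middle, ring, little); the thumb is out
of scope.

## Pipeline model

1. **Kinematics.** Joint angles come either directly from a tidy angle
   CSV or from per-segment marker trajectories. Segment frames are
   built from ≥3 non-collinear markers (origin at the first marker, X
   toward the second, Z normal to the marker plane, Y completing the
   right-handed triad) and adjacent frames are decomposed by the
   Cardan XYZ sequence `R = Rx(x)·Ry(y)·Rz(z)`: x is read as flexion
   (positive palmar), z as abduction (positive away from the middle
   finger, MCP only), y reported but unused. A flat-hand calibration
   recording, averaged over 1 s, defines the per-joint zero baseline
   subtracted from every stream.
2. **Filtering.** A fourth-order zero-lag low-pass Butterworth filter
   (forward–backward `sosfiltfilt`, symmetric reflection padding of
   length 3·(order+1)) is applied at 15 Hz to marker trajectories and
   5 Hz to angle streams. The forward–backward pass squares the
   magnitude response, so the amplitude gain at the cut-off is 0.5 and
   the net phase is zero; DC passes unchanged.
3. **Segmentation.** Training trials are averaged over their first
   second into one posture. ADL streams are partitioned into maximal
   runs in which no angle changes by more than 1° between
   *consecutive* frames; a supra-threshold change in *any* of the four
   angles starts a new segment at the later frame (half-open
   intervals, tiling the stream). Each run's mean is one grasp
   instance. The consecutive-frame/any-angle reading is the strictest
   interpretation and makes the partition well defined in one pass;
   the alternative (comparison to the segment's first frame) is a
   different rule, deliberately not implemented.
4. **Encoding.** A static 4-angle posture carries no time structure,
   so it is embedded as a deterministic signal before the wavelet
   step: a mixture of four sinusoids at 8, 16, 32 and 64 cycles per
   1024-sample window, with amplitudes equal to the angles normalized
   to [−1, 1] by their anatomical ranges (flexion [−10, 110]°,
   abduction [−30, 30]°). The embedding is injective up to that
   normalization and gives each joint its own scalogram ridge. The
   magnitude of a Morlet continuous wavelet transform over 64
   log-spaced scales (covering 4–128 cycles per window) is min–max
   normalized per image, gamma-stretched (γ = 0.5), posterized into 32
   intensity bands, mapped through a packaged 256-entry high-contrast
   RGB lookup table, and resampled bilinearly to 224×224. Per-image
   normalization means absolute angle magnitude is encoded in ridge
   amplitude *ratios*, not overall brightness; posterization turns
   ridges into contour-like bands that are robust to sub-band
   magnitude jitter between noisy replicates of the same grasp.
5. **Classification.** One classifier per finger, over exactly that
   finger's training subset of the 13 taxonomy grasps (index 13,
   middle 12, ring 8, little 8 — the ring and little fingers flex out
   of the way in finger extension, light tool, palmar pinch, tripod
   and writing tripod; the middle finger takes no part in the palmar
   pinch). The model is a frozen image-feature extractor with a
   trained neural-network head: by default 16×16 block-average pooling
   of the raster (588 features) into a one-hidden-layer (64-unit)
   perceptron; an alternative backbone prepends a fixed, seeded random
   convolutional filter bank with ReLU — the frozen-backbone /
   replaced-head transfer-learning arrangement at desk scale. The
   training protocol is fixed: stratified 30% validation split,
   SGD with momentum 0.9 at base learning rate 0.001, mini-batch 32,
   100 epochs, no augmentation, no early stopping. With 10 images per
   class the validation accuracy is quantized in steps of
   1/(3·n_classes).
6. **Quantification.** One labeled segmentation run is one grasp
   instance. Instances are tabulated per activity and in total per
   finger; percentages are reported to one decimal under round-half-up
   — the convention that reproduces every cell of the packaged
   reference occurrence tables. Top-k coverage sorts grasps by
   descending count (alphabetical tie-break) and reports the smallest
   k whose cumulative share exceeds a threshold (default 80%).

## Synthetic data

The generator produces the three inputs the analysis needs, with
known ground truth, so the whole pipeline is testable without any
recording:

* **Templates.** No per-grasp joint angles are published for this
  protocol, so the per-finger template table is a plausible, versioned
  package constant. Its one load-bearing property is separation: the
  13 base postures sit on a 15° grid with all 4-tuples distinct, which
  guarantees both ≥15° Euclidean and ≥15° single-angle separation
  between any two grasps of a finger; both are asserted at
  construction, not assumed. The single-angle guarantee matters
  because the 5 Hz zero-lag filter limits a step's frame-to-frame
  slope to about 0.081 × step at 125 Hz, so a grasp change must move
  some one angle by more than ~12.5° for the 1° rule to detect it at
  all. Constant per-finger offsets (distance-preserving) make
  same-grasp templates differ across fingers.
* **Static trials.** 1 s at 125 Hz, template mean plus i.i.d. Gaussian
  noise, default SD 2° per joint — comparable to marker-derived angle
  noise after 5 Hz filtering. Ten trials per grasp per finger.
* **ADL streams.** Piecewise-constant plateaus (0.8–2 s) joined by
  cubic smoothstep ramps (default 80 ms; at the guaranteed ≥15°
  per-angle separation these ramps exceed the 1° rule even after
  filtering, so transitions segment out as their own short runs,
  which the instance counts then include — as real transition frames
  would). Plateau jitter is *band-limited* noise (white Gaussian
  low-passed at 5 Hz, rescaled to the requested SD, default 0.5°)
  rather than i.i.d.: post-filter hold-still jitter must be smooth
  frame to frame — if plateau deltas routinely crossed 1°, the
  segmentation rule would shred every recording, so i.i.d. noise at
  realistic SDs would contradict the piecewise-constant premise the
  rule rests on. Ground-truth plateau intervals are 0-based half-open
  frame indices; transition frames belong to no plateau.
* **Marker chain.** A four-segment rigid chain (metacarpal 65 mm,
  proximal 40, middle 25, distal 18) with an axis-aligned marker triad
  per segment, posed by Rx(flexion) per joint plus Rz(abduction) at
  the MCP. Used only to round-trip-test the angle computation
  (recovery < 0.1°, in practice ~1e-13).

**What the generator does not emulate:** soft-tissue artefact, marker
occlusion and gap-filling, inter-joint coupling within a grasp,
within-subject drift, or realistic grasp-transition dynamics beyond a
smooth ramp. Passing tests therefore demonstrate that the pipeline's
stages are individually and jointly correct under the stated
statistical structure — not that the classifier would reach the same
accuracy on human recordings, where within-class variability and
between-class overlap are larger and not controlled by construction.

## Numerical choices

* Angles are degrees at every module boundary.
* Gimbal lock (|y| = 90°, physiologically unreachable for finger
  joints) is flagged with a warning and resolved by assigning the
  whole x/z ambiguity to x (z := 0).
* Filtering requires more than 3·(order+1) samples; shorter series
  are rejected explicitly.
* Segment boundaries: the frame after a supra-threshold change owns
  the new segment. No minimum segment duration by default
  (`min_frames = 1`); transition frames therefore appear as short
  instances, matching the counting convention of the reference
  tables.
* Percentages use exact decimal arithmetic with half-up rounding to
  one decimal; cumulative coverage shares are kept unrounded.
* Scalogram scales map frequency f (cycles/window) to scale
  0.8125·L/f (Morlet center frequency 0.8125); the grid is geometric
  with 64 points.
* PNG output is written with a pinned compression level; posture →
  image is a pure function and byte-stable across reruns.
* Seeds: every stochastic step (trial noise, ADL noise, activity
  composition, train/validation split, head initialization) derives
  its seed deterministically from the single pipeline seed; derived
  seeds stay below 2³¹.

## Default problem sizes

The default configuration trains on 10 images per grasp per finger
(410 images total across the four fingers) and evaluates three
synthetic activities of six plateaus per finger; the full pipeline
runs in well under a minute on one CPU and reproduces its occurrence
tables byte for byte at a fixed seed. These sizes mirror the static
training protocol (ten 1-s repetitions per grasp) and keep the
regression suite fast; larger studies are a matter of configuration,
not code.

## Known limitations

* The sinusoid-mixture posture embedding is this package's design; any
  deterministic injective embedding would serve, and results depend on
  it only through the classifier's features.
* The reference per-ADL table for the middle finger contains one row
  with no printed percentage and one duplicated grasp row in its
  totals table; the fixtures preserve both verbatim, and the duplicate
  is kept as two distinct rows rather than merged.
* C3D marker files are not read; marker input enters as in-memory
  trajectories or is synthesized. The canonical interchange format is
  the tidy angle CSV.
* Training metrics quantize coarsely at 10 images per class; reported
  validation accuracies on synthetic data should be read as regression
  bounds, not generalization estimates.
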