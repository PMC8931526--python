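# Methods

## The tracking model

`siamtrack` is a model-free single-object tracker for behaviour videos.
The user's first-frame bounding box defines a *template*: a context-padded
square crop around the box (side `s = sqrt((w+p)(h+p))`, `p = 0.5(w+h)`),
resampled to 127 px and converted to a feature map.  On every later frame
a *search region* — the same geometry scaled to 255 px, centred on the
previous box — is featured the same way, and the template is slid over it
(valid-mode cross-correlation) to produce a response map whose peak
locates the target.  Five aspect-ratio hypotheses (1/3, 1/2, 1, 2, 3)
crossed with three scale steps (0.96, 1, 1.04) each score their own
response; the winner re-shapes the box, damped by a factor of 0.3 per
frame.  A raised-cosine window centred on the previous position (weight
0.35) acts as a motion prior.  The template is never updated
automatically — only a human correction replaces it, and a detector
re-seed moves the box but not the template.

### Features

The default extractor, `pix-grad`, is deterministic and handcrafted:
locally mean-subtracted intensity (11 px window) plus horizontal and
vertical gradients, each box-smoothed 3×3, scaled to unit Frobenius
norm.  It is stride-1 translation-equivariant, which is the property the
correlation machinery needs.  The extractor sits behind a registry so a
learned backbone can be swapped in without touching the pipeline.  For
correlation, features are anti-alias pooled to a working grid of 24×24
template cells (≈5.3 px of patch per cell); this sets the compute cost
per frame and, through the search-crop scale, a localization granularity
of ~1.7 image px per response cell for a 20 px target.

### Centre-weighted templates and cosine scoring

Templates are multiplied by a separable raised-cosine taper: full weight
over the annotated box, falling to 0.15 at the context edge.  Context
still contributes (it disambiguates nearby clutter) but cannot dominate:
without the taper, a bright object sitting in the crop margin — the
identical-twin hazard this package is built to survive — outweighs the
annotated target in the unit-norm template, and a template re-seeded next
to such an object tracks the *neighbour* instead of the target.  Response
scores are normalized per window by the taper-weighted feature energy
(computed in the frequency domain alongside the correlations), so every
score is a true cosine similarity in the taper-weighted space: 1.0 for a
perfect match, near 0 on unrelated texture, comparable across frames.
This calibration is what makes the fixed confidence and gating thresholds
meaningful.

### Output confidence

Confidence is the softmax probability mass (temperature 0.1) in the 3×3
neighbourhood of the response peak, computed on the winning candidate's
*unsuppressed* map — suppression rescales the peak neighbourhood and
would depress confidence even when tracking is clean.  On cosine-scaled
scores this lands near 1.0 for a clean match, near the uniform baseline
`min(9, N)/N` for a featureless map, and below ~0.2 when the target has
left the search region; the detection gate at 0.3 separates the last case
well on the synthetic scenes.  Ties in the argmax resolve toward the map
centre so the constant-map identity is exact.

### Distractor suppression

After correlation, the mean correlation of remembered *distractor*
features is subtracted from every candidate's response map (weight
`alpha = 0.5`, shared across candidates by bilinear resampling).
Distractors are mined per frame from the identity candidate's map:
3×3 local maxima scoring at least 0.8 of the top raw peak, at least half
a template-box width (in cells) away from the *chosen* target location.
Three bookkeeping choices matter and were each forced by a failure mode:

- the score floor references the map's top peak, not the chosen cell —
  otherwise a weak (dim, occluded) target lets background ripples flood
  the memory and dilute the subtraction;
- the exclusion zone centres on the box the tracker chose, not the raw
  argmax — during an ambiguous crossing the raw argmax may sit on the
  distractor, and mining relative to it would memorise the target itself;
- snapshots expire after 2 frames (memory holds ≤5, newest kept).  A
  distractor snapshot discriminates between identical twins only through
  its surrounding-context constellation, which is valid for as long as
  the scene geometry it captured persists.  A stale snapshot anchors
  suppression at positions the target may now occupy; on a crossing path
  this actively pushes the tracker onto the distractor.

With pixel-identical twins that fully merge and separate, no
appearance-based mechanism can decide which blob is which — the
information is simply not in the images.  The suppression mechanism's
value shows in near-miss passes (twin within the search region but
resolvable), where frame-fresh constellations keep the tracker on a
weakened target that it would otherwise abandon.

### Human correction and label effort

A correction rebuilds the template from the corrected frame and box,
moves the box, clears the distractor memory and resets confidence to 1.
The first-frame annotation is counted as `source = corrected` in the
trajectory but excluded from label-effort percentages, which count only
corrections made during tracking (`100 · corrections / frames`).  The
`track_with_oracle` utility emulates an attentive operator by correcting
with ground truth whenever overlap drops below 0.5; it produces the
label-effort numbers reported by the acceptance script.

### Tracking with detection

Confident automatic outputs (`source = auto`, confidence ≥ 0.6) are
harvested into an exemplar bank (≤50, seeded reservoir sampling).  When a
step's confidence falls below the activation threshold (0.3), the
detector scans the whole frame: windows on a stride-8 lattice are
featured exactly like templates, block-averaged 3× (coarser cells widen
the match basin so the lattice cannot step over the target) and scored by
best cosine against the bank; the top five lattice candidates are refined
locally at stride 2 then 1.  A detection is accepted at ≥0.7 of the
bank's self-match score and re-seeds the box (source `detected`); the
template is untouched, and on no-detection the tracker's own output
stands — the detector is advisory.

## The synthetic scenes

The generator renders anti-aliased soft-edged blobs (disc, ellipse,
rounded rectangle; ~1 px edge ramp, optional internal speckle that moves
with the blob) over a flat or smooth-textured static background, with
linear / sinusoidal / random-walk / waypoint motion, identical-twin
distractors, multiplicative illumination drift and interval occlusion
(the target's rendering alpha drops, emulating a shadow or hide).  Ground
truth is the circumscribed rectangle of the rendered target, exact by
construction and recorded after the clamping that keeps the target in
frame.  Everything is a pure function of the scene config including its
seed.

Named fixtures pin the study conditions: `easy` (200 frames, 2 px/frame,
no distractors), `crossing` (an identical twin flies in along the path,
merges with the target and parks just behind the crossing point — the
drift trap used for the correction-rescue experiment), `crossing-easy`
(near-miss pass at ~14 px while the target crosses a 65% shadow — the
scene where suppression demonstrably rescues), `drifty-light`
(illumination ramp), `occluded` (5-frame full occlusion), `dash` (a
single 60 px jump beyond the search radius — the scenario the detection
fallback exists for; a failure here coincides with low confidence, which
is what makes detection gating able to fire), and `long` (3000 frames of
confined random walk with identical twins sweeping the arena on a fixed,
density-increasing schedule).

What the generator does **not** emulate: articulated or deforming bodies,
photometric noise, camera motion, motion blur, and appearance change of
the target itself.  Passing these benchmarks therefore demonstrates the
mechanics of matching, suppression, correction and gated detection — not
performance on real animal footage.

## Numerical choices

- Correlations run in the frequency domain; the search FFT is computed
  once per frame and template FFTs are cached until a correction replaces
  the template.  Window energies use the same transforms.  Results match
  the direct triple-loop computation to ~1e-12.
- Crops use bilinear resampling; out-of-frame content is filled with the
  frame's mean intensity.
- Response ties break row-major in `locate_peak` (documented degenerate
  rule: an all-equal map yields the centre cell); candidate ties break by
  candidate order with the identity hypothesis first; the confidence
  argmax tie-breaks toward the map centre.
- Candidate ranking uses one min-max normalization *shared* across all
  candidate maps; per-map normalization would erase the between-candidate
  score differences the ranking needs.
- The box centre is clamped to stay inside the frame.

## Problem sizes

The bundled benchmarks run at desk scale: 144² px scenes (192² for the
long runs), 20 px targets, 60–200 frames per scene and 10 seeds for the
seed-averaged comparisons; the long-run analysis uses 3000 frames × 10
seeds in the test suite and 5 seeds in the acceptance script.  All sizes
are set in `standard_fixtures()` and scale linearly.

## Known limitations

- The pix-grad features are gain-invariant (cosine scoring) but not
  rotation- or deformation-invariant; a rotating elongated target will
  shed overlap unless the aspect candidates catch it.
- Identical twins that fully merge are genuinely ambiguous (see above);
  the tracker resolves such events by motion priors only, and the
  correction workflow exists precisely for the cases it gets wrong.
- The exemplar detector assumes the target's appearance at detection time
  resembles some harvested exemplar; it will not re-find a target that
  changed appearance while lost.
- Confidence calibration (and hence the 0.3 gate) is validated on the
  synthetic scenes; real footage may need the threshold re-tuned, which
  is why it is exposed in `DetectionConfig`.
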