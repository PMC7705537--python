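# Methods

This note documents the models, the numerical choices, the synthetic data
the tests rely on, and the limits of what those tests show.

## Coordinate conventions

Images are `(row, col)` arrays with y growing downward; points are `(x, y)`
with `x` the column. The snout line is given by two endpoints `p0, p1`; its
along-unit-vector `u` defines the ρ axis and its normal `n` (by default `u`
rotated −90° in image coordinates, i.e. pointing up for a left-to-right
horizontal line) points toward the whisker side. A whisker's chord direction
is `cos θ · u + sin θ · n`, so θ ∈ (0, π) for anything on the whisker side.
Angles are radians everywhere, including on disk; tangent directions of
centerline points live on the half-turn domain [0, π) because a ridge has no
orientation sign.

## Pixel-level stage

**Background.** Per-pixel maximum over `n_samples = 20` frames spread evenly
across the video. With sensor noise σ the sampled maximum sits ≈2σ above the
true backlight; this bias is constant and removed with everything else by
subtraction, and is far below whisker contrast (≥100 grey levels in the
generator).

**Silhouette.** Otsu binarisation of the subtracted frame, morphological
opening to delete thin (whisker-width) structures, dilation to pad the
remaining blob. The module default opening radius is 2 px; the pipeline's
default configuration uses 3 px because a disk(2) opening retains shafts
whose binarised width reaches 4 px (the upper end of realistic whisker
widths at this zoom) and would mask them. Because the silhouette edge moves
(breathing), the pipeline additionally zeroes everything within
`side_margin = 8 px` of the snout line on top of restricting processing to
the configured side; detection therefore starts a few pixels above the line
and the basal position ρ is obtained by extrapolation of the fitted model,
not by reading a pixel at the line.

**Ridge detection.** Five Gaussian partial derivatives at scale
σ = 1.5 px (reflect boundary). Per pixel, the Hessian's strongest negative
eigenvalue gives the cross-ridge curvature (strength) and its eigenvector
the ridge normal; the 1-D second-order Taylor model along the normal is
solved for the zero of the first directional derivative and accepted when
|offset| ≤ 0.5 px, yielding at most one point per pixel. The strength
threshold is either fixed (pipeline default 4.0 grey/px², appropriate for
≥100-grey-level whiskers under σ = 2 noise) or calibrated as the 99th
percentile of strengths on a reference frame. Sub-pixel bias of the Taylor
step on Gaussian profiles is ≤0.04 px at the acceptance window's edge;
measured RMSE on noiseless rendered ridges is ≈0.01 px. Detection cannot
form points within ≈3σ of an intensity cut (mask or margin edge), which is
why downstream snout-attachment checks allow `side_margin + 3σ` of slack.

## Clustering

Two initial algorithms, selectable per run: DBSCAN (eps 2.5 px, min 3
points) for interrupted or rough centerlines, and the direction-guided
mutual-nearest-neighbour rule for smooth ones. In the latter, each point
proposes its nearest neighbour within ±30° of its +tangent and −tangent,
searching the 8-neighbourhood and the Chebyshev ring one pixel further (a
single missing point does not break a chain); an edge requires mutual
proposals, making every node degree ≤ 2, and clusters are the connected
components ordered by path traversal. The 30° tolerance is chosen to sit
between the per-point direction noise (≲10° on noisy video) and the
smallest whisker-crossing angle we expect to separate (≈40°); a wider
tolerance lets chains cross over at X-junctions. DBSCAN clusters are
ordered by projection onto their principal axis, which is monotone along
the curve as long as the tangent turns by less than 90° over the whisker —
true for the bending range the shape model targets.

**Stitching.** A line is fitted to the last 20 px of arclength of each
cluster (for fragments shorter than that, the circular mean of the
detector's per-point tangents stands in) and extended tip-ward. Candidate
clusters must have their base within 3 px of the line, within 30 px along
it, and — beyond proximity — must *continue* in the same direction: the
candidate's base-to-tip direction has to lie within 30° of the extension.
The direction gate is what keeps the two arms of an X-crossing from being
stitched onto each other, since at the junction all fragment endpoints are
near both lines. The closest candidate base (Euclidean, then lowest index)
is merged; iteration to fixpoint terminates because each merge reduces the
cluster count.

**Base overlap.** A whisker-length cluster whose base hangs more than the
attachment distance above the snout line, but whose extrapolated basal line
passes within 3 px of a snout-connected cluster's basal segment, receives a
copy of that segment (flagged `copied`) so both whiskers can be
parameterised down to the line. Only clusters at least `min_whisker_len`
long qualify — otherwise a stray speck near a whisker would adopt a copy of
its base and duplicate it.

**Fur.** Removed by length (`min_whisker_len = 40 px`) plus, at the
pipeline level, a base-angle gate (fitted θ within 10° of the snout line is
rejected): chance alignments of fur fragments stitch into chains that can
exceed the length threshold but run nearly parallel to the snout, which no
whisker does.

## Parameter fitting

L is definitional: the Euclidean base-to-tip distance of the cluster.
(ρ, θ, b) minimise Σ(dᵢ − b·xᵢ²)², where (xᵢ, dᵢ) are each point's chord
and perpendicular coordinates in the frame anchored at ρ — i.e. the
residual is evaluated at matched chord coordinate, avoiding a nested
foot-point solve. `x` is chord distance, not arclength (closed-form
evaluation; for the bending range |b|·L ≲ 0.5 the two differ negligibly).
Initialisation: principal direction of the basal quarter of the points
gives θ₀ and, intersected with the snout line, ρ₀; b₀ = 0. Solved by
trust-region least squares with θ bounded to (0, π), tolerance 1e-10,
≤300 residual evaluations. The fit is invariant to point-order reversal
because orientation is re-derived from the snout line. Fitted L on real
detections runs ~5–10 px short of the drawn whisker because ridge tips
fade below the detection threshold; position and angle are unaffected.

## Tracking and recognition

Kalman state (ρ, θ, ρ̇, θ̇, b, L): constant velocity in position/angle,
random walk in shape/length. Process noise uses the discrete
white-acceleration model with per-frame accelerations q_ρ = 0.1 px/frame²
and q_θ = 2×10⁻³ rad/frame² (an 8 Hz, 0.3 rad whisk at 1,000 fps peaks at
≈8×10⁻⁴ rad/frame², so the filter tracks whisking with headroom);
measurement noise matches fit accuracy (0.5 px, 4 mrad, 10⁻⁴ px⁻¹, 1 px).
Assignment between predictions and detections minimises total cost by the
Hungarian algorithm on (ρ, cot θ, b, L) differences, each axis scaled by
its running standard deviation over the training window (floored at
1 px / 0.05 / 10⁻⁴ px⁻¹ / 1 px); pairs costing over 3.0 normalised units
are rejected.

Identities are fixed by the first frame (ordered by ρ). During the
bootstrap (50 frames by default) assignment is purely Kalman, and accepted
matches seed the classifier's training window. Afterwards each frame runs
classifier → N-expert → P-expert in that order. The classifier is a
one-vs-one ensemble of linear soft-margin SVMs (liblinear, C = 1.0) on the
6-D standardised features (L, b, ρ, cot θ, ρ − mean ρ_prev,
cot θ − mean cot θ_prev), retrained every 25 frames on the last 2,000
frames; identities with fewer than 20 window samples sit out a cycle, and
vote ties resolve by distance to the class centroid. The N-expert marks a
classification false-positive when |Δθ| > 10°/frame or |Δρ| > 15 px/frame
against that identity's previous frame (strict inequality); flagged
detections never reach the output or the training window. The same
plausibility gate is applied to every acceptance path, bootstrap and
P-expert included, so the accepted output contains no above-threshold
frame-to-frame jumps by construction. The P-expert matches leftover
detections to the Kalman predictions of unclaimed identities under the
same cost rule; an identity found by neither coasts on its prediction
("estimated", excluded from output) for up to 100 frames, then freezes.

Pivot estimation: OLS of ρ on cot θ (slope = pivot depth L_f, intercept =
pivot foot ρ_f), flagged degenerate below 50 samples or 10° of θ spread.

## Metrics

SNR of an angle trace: subtract the trace mean, smooth with a quadratic
Savitzky–Golay filter, and take 10·log₁₀ of smooth-to-residual power.
Standard S-G needs an odd window, so the nominal 10-frame window is
realised as the centred 11-frame window. The smoother absorbs a known
fraction of white-noise power (the hat-matrix diagonal, c₀ = 89/429 at
interior samples), so the raw residual underestimates noise by ≈1 dB;
the residual power is therefore normalised by the residual degrees of
freedom N − tr S (computed exactly, edge rows included), the standard
unbiased residual-variance correction. Verified against known
signal/noise mixtures to <0.1 dB across 20–60 dB true SNR. Segments
shorter than the window are excluded; zero residual returns +inf.

Identity scoring against ground truth maps each detection to the nearest
true whisker in normalised (ρ, θ) space — position and angle determine
*which* whisker a detection is, while b and L are appearance and are
systematically truncated by detection. A switch is a change of mapping for
a continuing identity; consistency is the fraction of detections carrying
their identity's modal mapping.

## Synthetic scenes

The generator renders what the pixel-level model assumes: a bright static
backlight with smooth texture (amplitude 6 grey levels), a dark snout
silhouette whose edge breathes sinusoidally (±5 px at 3 Hz, soft 1.5 px
edge), short jittering fur fragments near the snout, and N dark whiskers
drawn as analytically-evaluated Gaussian-profile ridges (no rasterisation:
the crest position is exact, enabling sub-0.1 px accuracy claims), plus
white sensor noise (σ = 2). Whiskers rotate about fixed hidden pivots, so
ground-truth (ρ, θ) satisfies ρ = L_f·cot θ + ρ_f identically; whisking is
sinusoidal at 8 Hz (inside the biological 5–30 Hz band) with 0.3 rad
amplitude, near-common phase across the field, plus 1.5 mrad per-frame
angular jitter. Crossings are scripted as transient raised-cosine bending
excursions that sweep one whisker's tip across a neighbour; occlusions
simply skip rendering a whisker. Frame i is a pure function of
(config, seed, i), so access order, re-runs and sub-sampling are all
bit-reproducible.

The default benchmark ("benchmark-B") is 10 whiskers on 480×512 px at a
1 kHz-equivalent rate for 2,000 frames, with two scripted crossings and one
20-frame occlusion. Problem sizes elsewhere (500-frame clustering scenes at
256×320, 1,000-trial fit/pivot ensembles, 600-frame hygiene runs) were
chosen as the smallest sets whose pass/fail state is stable across seeds.

**What passing does not show.** The generator's whiskers are exactly
quadratic, its background truly static, its noise white and Gaussian, and
its whisking stationary and near-common-phase. Real videos add non-static
backgrounds, whisker-object contact (which breaks the one-coefficient shape
model), irregular whisking with phase splay, out-of-plane motion, and
optical blur that varies along the shaft. Results on the synthetic
benchmark bound what the algorithms can do under their own assumptions;
they do not certify performance on any particular recording rig.

## Known limitations

* 2-D only; no object-contact shape terms (the quadratic model would need
  extending).
* No track birth: whiskers absent from frame 0 are never assigned an
  identity.
* AVI/MP4 input requires an ffmpeg-backed imageio plugin; TIFF stacks and
  image directories are the supported offline paths.
* Three-way overlaps in a single frame are not resolved; the experts merely
  keep such frames out of the training data.
* Very long runs can still accumulate recognition errors once the training
  window fills with drift; a post-hoc jump detector over whole traces would
  be the next defence and is not implemented.
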