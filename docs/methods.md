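# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `vfoct`. It is the place where design decisions that are not
obvious from the code are justified.

## Coordinate and unit conventions

Image row 0 is superior (toward the scanner); rows increase inferiorly.
All modules share this convention. A-lines are image columns. Axial pixel
pitch in air (`axial_pitch_air`, μm/px) divided by a bulk soft-tissue
refractive index (default n = 1.4) gives the tissue pitch used for every
thickness and displacement conversion; for the default instrument,
5.94 / 1.4 = 4.242857… μm/px. Pitches are stored at full float precision
and rounded only for display — this is why the display aspect ratio
(lateral / tissue pitch = 2.5042…) reports as 2.50 at two decimals rather
than 2.51. The lateral pitch is the mean of the fan widths at the top and
bottom of the frame divided by the A-line count ((7.8 + 9.2)/2 mm / 800 =
10.625 μm/px); the fan propagates in air, so no refractive correction is
applied, and the value is treated as depth-constant even though the true
fan widens ~±8% across the frame. Depth-dependent lateral correction is
out of scope.

## Synthetic phantom

`vfoct.phantom` renders the scene the pipeline is validated on: two
opposed folds on a uniform noise floor, each a rigid two-layer slab (EP
over LP) whose superior surface follows

    row(t) = rest_row + taper·|x − center| − A·d(x)·sin(2π f t + φ_side)

with per-side phase φ (default π/2, so the folds render out of phase the
way sub-Nyquist sampling of real folds does), an optional linear lateral
taper (default 0.05 px/px, a gentle dome that makes the superior-medial
point unique), and an optional lateral decay of amplitude d(x) (default
none; used to emulate medial edges vibrating faster than the lateral
surface). Medial edges move laterally with the same oscillator, closing
the glottal gap when the lateral amplitude exceeds the rest half-gap.

Intensities are tri-modal by construction — noise 25, EP 95, LP 200 on an
8-bit scale — because dense, scattering LP returns more signal than EP.
Tissue intensity decays as exp(−depth/1000 μm) below the surface,
mimicking the ~1 mm penetration limit; boundaries are rendered with
partial-volume mixing so that iso-contours can recover sub-pixel boundary
positions; speckle is multiplicative log-normal (σ = 0.12 by default,
mean-preserving). This is a first-order surrogate: real OCT speckle is
correlated interferometric noise, real folds deform non-rigidly, and the
fan geometry is not rendered (measurements in the pipeline are made on the
rectilinear pixel grid either way). Passing the phantom suite therefore
demonstrates correctness of the measurement chain — thresholds, contours,
calibration arithmetic, kinematics — not robustness to every property of
clinical images.

Default study conditions: 250 Hz frame rate, 110 Hz fundamental, 1.33 mm
vertical amplitude at the medial edge, 100 μm EP, 420 μm detectable LP,
200 μm rest half-gap, 25 rest frames followed by 3 s of phonation. A
validation pass rejects any configuration whose motion or layer stack
does not fit the frame, naming the offending parameter. With the default
pitches a 1.33 mm amplitude spans ±313 tissue pixels, so amplitude-scale
phantoms use ~780-row frames.

The generator also simulates the axial calibration experiment: a mirror
stepped 0 → 12 mm in 0.5 mm increments (25 observations), mirror row =
round(position / axial pitch), optional integer jitter. OLS of row on
position recovers the pitch; with quantization as the only noise the fit's
R² is ≈ 1 − 10⁻⁷, comfortably above the 0.999 the real experiment achieved.

## Preprocessing

Stabilization maximizes normalized cross-correlation of a user-chosen
template region against a reference frame (default: the first frame),
searching integer shifts within a margin. Integer-pixel only: downstream
thickness is measured in whole A-lines, and sub-pixel stabilization would
buy nothing. The matching metric is this package's choice; offsets are
recorded so the transform is invertible. Templates should span structure
in both axes (e.g. the glottal gap region); a template lying on
horizontally uniform tissue cannot constrain lateral shifts.

Cropping records its origin so segmentation coordinates map back to
acquisition coordinates. Denoising is split-Bregman total variation with
weight 0.1, run on the native intensity scale — the TV weight balances a
linear roughness term against a quadratic fidelity term, so rescaling the
image to [0, 1] first would change the effective smoothing by the scale
factor. Pipeline order is fixed: stabilize → crop → denoise.

## Segmentation

Per frame, a 256-bin histogram over the occupied intensity range is
smoothed with a quadratic univariate spline. The smoothing factor (allowed
sum of squared residuals) is 2 × the pixel count: per-bin counting noise
has variance ≈ count, so residuals of that order are noise, not structure.

Peak handling needs care because depth attenuation smears the LP mode over
a wide intensity band with internal wiggles. Local maxima of the spline
are therefore (a) merged when the trough between two neighbors fails to
drop below half the lower flank — such a trough separates wiggles, not
modes; (b) dropped when their basin holds under 1% of total counts
(spline artifacts over empty bins). If three or more peaks survive, the
three with greatest basin mass are kept and the two troughs between them
become the thresholds. Within an inter-peak interval the trough is placed
at the center of a dominant zero run of the raw counts (one covering at
least half the interval — truly separated modes), otherwise at the center
of the near-minimum plateau (within 2% of the segment's dynamic range) of
the smoothed curve; both rules make the placement deterministic on flat
or empty gaps. Frames without three significant modes reuse the previous
accepted frame's thresholds (frames 4 ms apart are temporally coherent)
or, lacking any, place thresholds at 0.25 / 0.55 of the occupied range —
values chosen once as fractions that fall inside the noise/EP and EP/LP
gaps across the phantom's default intensity triplet.

Contours come from marching squares at the two threshold levels, on a
frame padded with its minimum so border-touching structures close. Closed
contours under 50 px² are discarded (below any plausible fold
cross-section at these pitches; removes speckle islands). The glottal
midline is the least-occupancy column between the two largest tissue
components — computed per frame, then fixed per sequence as the median so
that frames of full glottal closure inherit a stable midline. Per side,
the upper/lower envelopes of the tissue-level contours give the EP outer
and deep-LP boundaries and the upper envelope of the LP-level contours
gives the EP/LP interface; A-lines crossing a contour more than twice use
the outermost pair.

**Edge relocalization.** An iso-contour at level t crosses a one-pixel
partial-volume edge between plateaus a and b at an offset of
(t − (a+b)/2)/(b − a) px from the true 50%-coverage boundary. A single
histogram trough cannot sit at the midpoint of *all three* edges it cuts
(surface, interface, deep transition have different plateau pairs —
attenuation makes the LP value adjacent to the interface much brighter
than the LP value adjacent to the noise floor), leaving each boundary a
systematic sub-pixel bias of up to ~0.5 px, and the LP thickness (which
accumulates two of them with the same sign) up to ~1.1 px. Sampling the
plateaus 2 px on either side of each crossing and applying the first-order
correction above (clamped to ±0.5 px) removes most of this bias; with it,
noiseless-phantom boundary errors stay below ~0.6 px and per-A-line layer
thickness within 1 px × pitch.

Ordering (EP outer < interface < LP deep) is enforced per A-line,
discarding violators, and asserted — never assumed — in tests. Temporal
alignment is monitored by comparing each side's median EP-outer row with
the previous accepted frame; jumps beyond 25 px (about a quarter of the
default fold depth) flag the frame (`alignment_ok=False`) while keeping
the raw segmentation, since forcing a snap would corrupt genuine large
excursions. Frames that cannot be segmented are flagged, never fatal.

## Morphometry

Thickness is measured **along A-lines** (vertical pixel count × tissue
pitch), not along the surface normal; near the medial edge, where the
layers stretch and steepen, this inflates values relative to normal
thickness. That is a property of the measurement definition and is
reproduced, not corrected. `combined = ep + lp` holds exactly by
construction wherever both layers exist; absent layers are NaN, never 0.

The superior-medial point of a fold is the minimum-row EP-outer point
within a medial band (default: 10% of fold width nearest the midline; the
band width is a free parameter), ties broken toward the midline. Vertical
position converts via the tissue pitch; the displacement baseline is the
mean position over frames labeled rest (phase labels come from the
protocol/sidecar, not from voicing detection), and amplitude is the
largest absolute displacement during phonation. With no rest frames the
first segmented frame serves as baseline and the series is flagged.

Summaries report mean ± sample SD (ddof = 1) of the full distribution and
of a "select" distribution limited to points within ±3 SD of the full
mean. The exclusion is single-pass — it is not iterated to convergence.

## Kinematics

30 points per fold, equidistant in x between the medial free edge and the
lateral end of the detected superior contour, rows interpolated from the
per-A-line surface profile. Correspondence across frames is index-wise at
fixed relative x positions — deliberately *not* feature tracking, since
with single-plane imaging and out-of-plane motion, surface points cannot
be followed with certainty anyway; velocities are finite differences of
index-paired points times the frame rate. Sign conventions: +v_y superior
(toward row 0), +v_x toward the anatomic midline (so the two folds'
medial motions have the same sign). Gaps from unsegmentable frames yield
NaN velocity pairs and are never interpolated. Velocity fields are
antisymmetric under time reversal, and on phantoms whose amplitude decays
laterally the medial-edge points show the highest time-RMS speed — both
are regression-tested.

Sampling at 250 Hz is below the Nyquist rate of most human fundamentals;
the measured dominant frequency of v_y(t) equals f for f < 125 Hz and
frame_rate − f for 125 < f < 250 Hz. The pipeline reports what it
measures; no de-aliasing is attempted.

## Kymography

A depth-resolved videokymogram is a [frames × A-lines] matrix of one
layer's thickness with a reserved AIR sentinel (−1.0, outside the valid
thickness range) where an A-line holds no tissue; AIR renders light gray
and is never conflated with 0 μm. Cells equal the thickness-profile
values exactly; row r maps to time r/frame_rate exactly. Color scales are
per-kymograph min/max by default with optional fixed bounds for
cross-subject comparison. Band periodicity is the dominant rFFT peak of
the per-band mean signal (AIR counted as 0 so gap alternation registers),
with two floors: bands with signal SD under 5 μm are reported absent —
that floor sits above sub-pixel quantization ripple (~1 px × pitch spread
over a band) and below any real gap/thickness oscillation — as are bands
whose peak carries <5% of the variance. Left/right symmetry compares
mirrored bands' periods and mean thicknesses.

Velocity maps place both folds on one shared 2×30-point axis with the
medial edges meeting at the center, so "toward the center = medial" holds
for arrows in vector maps (up = superior). The numeric matrix is exported
alongside every rendering and is bit-identical to the field values.

## Reproducibility and problem sizes

All randomness flows through explicit seeds (`numpy.random.default_rng`);
identical config + seed gives byte-identical frames and numeric outputs,
and the pipeline manifest echoes every parameter. The test suite validates
the chain at three scales: small phantoms (200×240 px, ≤30 frames) for
unit behavior; a noiseless full vibration cycle at 420×400 px for
boundary-accuracy bounds; and one full-scale sustained-phonation run
(780×400 px, 775 frames, speckle + TV denoising) verifying that the
1.33 mm configured amplitude is recovered within 5% (measured: <1% error).
These sizes were chosen as the smallest that exercise each property fully.

## Known limitations

- The LP reported is the *detectable* LP: signal dies ~1 mm below the
  surface, so the LP/vocalis boundary and LP sublayers are out of reach —
  a hardware property the phantom reproduces via its attenuation model.
- Trough thresholds are biased estimators of edge midpoints under depth
  attenuation; the edge relocalization corrects to first order only and
  assumes locally flat plateaus two pixels from each boundary.
- The phantom's rigid motion cannot probe segmentation under strong
  non-rigid deformation or mucosal-wave phase lag along the surface.
- Lateral pitch is treated as depth-constant despite the fan geometry.
- Index-wise point correspondence approximates material-point velocity;
  it is exact only for purely vertical motion.
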