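# Methods

## Measurement model

A record is one annotation event: one subject's third molar region (FDI 38
or 48) annotated by one rater in one session. Eight landmarks are used,
in raster pixel coordinates (origin top-left, x rightward, y downward, so
the apical direction of a mandibular tooth is +y):

* the two anchors of the simplified occlusal plane (M1 mesial cusp, M2
  distal cusp);
* the mesial CEJ of the second and third molars (the measurement points);
* two points on each of the M2 and M3 long axes (only for the angulation
  eligibility check).

The occlusal plane is the infinite line through the two anchors; the
perpendicular foot of the M3 CEJ routinely falls distal to the anchor
segment, so no clamping is applied. Perpendicular distances are signed:
positive on the apical side of the line, defined independently of anchor
order (the sign of the cross product is flipped when the line's x-direction
is negative, with the y-direction as tie-break for exactly vertical lines).
A non-positive distance means the CEJ sits on or above the occlusal plane —
geometrically outside the method's assumptions — and excludes the record
(`NONPOSITIVE_DISTANCE`) rather than producing a sign-flipped quotient.

**Quotient direction.** The default is Q = d(M2)/d(M3), which rises toward
≈ 1 as the third molar erupts and therefore correlates *positively* with
age. The reciprocal is available as a configuration switch and is stamped
into every output.

**Units and rounding.** Distances are computed in pixels and converted to
millimetres when the record carries a `mm_per_px` calibration. In rounded
mode (the default for the study pipeline) each length is rounded half-up to
one decimal place in mm *before* the division, mirroring clinical recording
of lengths to 0.1 mm; unrounded values are kept alongside. Rounding is
only meaningful in millimetres: without calibration it is skipped with a
warning (rounding pixels would make the result scale-dependent). Unrounded
mode is used wherever exact invariance matters (similarity-invariance
checks, exact rank-fidelity comparisons), since 0.1 mm quantisation
introduces ties.

**Angulation and eligibility.** Angulation is the acute angle between the
M3 and M2 long axes (a Winter-style tooth-to-tooth comparison, not an angle
to the occlusal plane), signed positive when the M3 crown tilts mesially.
"Mesial" in image coordinates depends on the side and the panoramic
orientation (standard: patient's left on the viewer's right); the
orientation is configurable. Exclusion rules: mesial angulation strictly
greater than 30° (the boundary value is still included), or any distal
angulation beyond the configured tolerance (default 0°). Records without
axis landmarks cannot be assessed for angulation and are *not* excluded for
that; the result is flagged "not assessed". All exclusion reasons are
accumulated, not short-circuited, so the exclusion tally reflects every
violated rule.

## Agreement statistics

**Spearman's ρ** is the Pearson correlation of mid-ranks (ties get the mean
of the ranks they span). The default 95% CI uses the Fisher z transform
with the Bonett–Wright standard error √((1 + ρ²/2)/(n − 3)); |ρ| = 1 gives
a flagged degenerate interval. The CI method name is recorded in every
result, since analytic and bootstrap intervals differ slightly and
published intervals rarely state their construction.

**Krippendorff's α** = 1 − D_o/D_e for a units × observers matrix of
continuous ratings with missing entries. Units with fewer than two ratings
carry no agreement information; they are dropped and counted. D_o averages
the squared differences over ordered within-unit pairs (each unit weighted
by m_u − 1); D_e averages over all ordered pairs of pooled pairable values.
The interval metric (c − k)² is the default for continuous measurements and
is invariant to affine rescaling of all ratings; the ratio metric
((c − k)/(c + k))² is offered because the quotient is a ratio-scale
quantity, and is invariant to positive rescaling. When all pooled values
are identical, D_e = 0 and α is reported as undefined rather than 1:
agreement is vacuous without variation.

The implementation is vectorised through the identity
Σ_ordered-pairs (c−k)² = 2(mΣc² − (Σc)²); the test suite checks it to
1e-12 against a literal enumeration of every ordered pair on random small
matrices.

**Bootstrap CI for α.** Units (radiographs) are resampled with replacement
and α recomputed — a cluster bootstrap, chosen over Krippendorff's own
pair-resampling algorithm because it is simpler, well-defined for
continuous data, and respects the unit as the independent sampling entity.
Resamples with undefined α are redrawn (capped at 100 retries each); fewer
than 20 valid resamples is an error. Percentile intervals; deterministic
given an explicit seed (all stochastic operations here require one — there
is no hidden global state).

## Study pipeline

Eligibility filtering, quotient measurement, then three tables with one
cell per tooth (38/48) × sex:

* **Correlation** — ρ(Q, age) with CI, computed on a single rater-session
  (default rater 1, session 2, i.e. the second assessment run of the
  dual-session examiner). Cells with n < 5 are flagged not estimable (the
  point estimate is still recorded when n ≥ 3, without a CI).
* **Intra-rater** — α between sessions 1 and 2 of rater 1.
* **Inter-rater** — α between rater 1 (default: session 2; which run feeds
  this comparison is a config switch) and rater 2.

Left and right third molars are analysed as separate cells and never
pooled; no within-subject correlation adjustment and no multiple-testing
correction are applied (per-cell CIs are reported instead). Reports
(three TSVs + full-precision JSON) are a byte-deterministic function of
records, configuration and seed; the JSON embeds the complete
configuration and software version as provenance.

## Synthetic cohort generator

The generator's defaults define the study conditions used throughout the
tests; no public annotation data exist for this measurement protocol.

Per subject: exact age uniform within its one-year age × sex cell of the
packaged cohort table (423 subjects: 220 female, 203 male, ages 15–25).
Per side: a latent logistic eruption trajectory s = expit(β(age − t0))
with slope β = 0.8 /y and midpoint t0 ~ N(19.5 y, 2.5 y), correlated 0.8
between a subject's two sides; d_M2 ~ N(4.5 mm, 0.6 mm);
d_M3 = d_M2 + (1 − s)·depth with depth ~ N(12 mm, 2 mm). The midpoint mean
places the steepest eruption change in the middle of the 15–25 window;
4.5 mm and 12 mm are anatomically plausible CEJ offsets for an erupted
second molar and an unerupted third molar. The same midpoint mean is used
for both sexes (the generator accepts per-sex means). Angulation magnitude
is half-normal (σ = 8°), distal with probability 0.05, so the eligibility
filter has non-trivial work.

Landmarks are laid on a canonical millimetre template in which the
occlusal plane is the x-axis, so the CEJ perpendicular distances equal
d_M2/d_M3 *exactly* by construction (verified against the geometry module
to 1e-9). Rendering applies per radiograph one occlusal tilt
(N(0°, 4°)), one magnification (N(1.25, 0.05), the typical panoramic
magnification range) and one random translation — shared across raters,
who read the same image; this sharing is what lets inter-rater α approach
1 despite projection variability, as in the real study design. Each
rater × session then gets iid Gaussian jitter (default 1.5 px ≈ 0.12 mm
anatomical at 0.1 mm/px pitch) on every landmark. Rater 1 is emitted for
sessions 1 and 2, further raters for session 1. Emitted calibration is
`mm_per_px_true / magnification`, i.e. back to anatomical millimetres.

What the generator does *not* emulate: real panoramic distortion is
non-uniform across the image (here magnification is uniform per image, so
the quotient's magnification invariance is exact rather than approximate);
rater error is iid Gaussian per landmark rather than structured (real
raters disagree systematically on ambiguous CEJs); pathology, restorations
and missing teeth are absent (representable only as missing-landmark
records); and the eruption kinetics (logistic, β = 0.8/y) are a plausible
invention, not estimates from data. Passing recovery tests therefore show
the *pipeline* is correct and well-conditioned under these conditions, not
that real-world reliability would match.

## Numerical choices and degenerate inputs

* Coincident occlusal anchors (< 1e-9 px apart) → `OCCLUSAL_PLANE_UNDEFINED`.
* Rounding is half-up (ties away from zero), applied only in mm.
* α with all pooled values identical, ρ of a constant vector, CI at
  |ρ| = 1: all flagged/degenerate rather than silently clamped.
* Bootstrap seeds are derived per table cell from the study seed so that
  cells are independent but the full report is reproducible.
* Problem sizes: simulation-based tests run the full 423-subject cohort
  (2538 records, ~0.15 s per replicate); the noise-monotonicity check uses
  20 replicates per noise level over {0.5, 1.5, 3, 6} px.

## Known limitations

* Which printed length is "A" and which "B" in clinical figures is a
  convention; here A = M2 distance, B = M3 distance (aliases only).
* The Bonett–Wright interval assumes approximate normality of the
  transformed ρ; for n < 5 no CI is attempted.
* The cluster bootstrap for α can be anti-conservative for very few units;
  cells report their unit counts so this is visible.
* No age-prediction regression is provided: the package quantifies the
  marker's correlation and reliability, not reference values for casework.
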