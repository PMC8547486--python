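# Methods

`hipmorph` implements a landmark-based hip-morphometry pipeline: an ordered
85-point outline of the left proximal femur and acetabulum (millimetre
coordinates) is reduced to three scalar measures — alpha angle (AA), lateral
centre-edge angle (LCEA) and minimum joint-space width (mJSW) — which are
then graded into radiographic hip osteoarthritis (rHOA) phenotypes and fed
into a logistic association suite. A synthetic cohort generator with exact
geometric and statistical ground truth closes the loop, so every stage can
be validated without imaging data.

## Coordinate conventions

All geometry lives in a canonical left-hip radiographic frame: superior is
+y, lateral is −x. Landmark indices are 1-based and index ranges are
inclusive on both ends, matching the "point 78" style of the clinical
literature. The template defaults are: head-circle fit on points 15–28,
mJSW between acetabular points 78–84 and femoral points 22–31, lateral
acetabular edge at point 78. The neck border ranges (superior 41–52,
inferior 53–64) are this package's own convention — the full anatomic
layout of the 85-point template is not fixed by the measurement definitions
— and are configurable.

## Geometric measures

**Circle of best fit.** The femoral-head circle minimises the geometric
objective Σ(‖pᵢ − c‖ − r)². A linear algebraic (Kasa) fit seeds a
Gauss–Newton refinement with the radius profiled out as the mean distance to
the centre (termination at parameter steps of 10⁻¹⁴ mm). The solution is
permutation-invariant and rigid-motion-equivariant to ~10⁻⁹ relative;
collinear or <3-point inputs raise a degenerate-geometry error.

**Neck axis.** The femoral-neck centre is the midpoint of the minimum-width
cross-section between the superior and inferior neck border polylines
(global minimum over point-to-segment distances in both directions); the
axis runs from the fitted head centre through that midpoint. This is a
documented stand-in for "the centre of the femoral head and neck": the
construction is simple, deterministic, and exact on symmetric necks, but it
is one of several defensible definitions, so the neck ranges and hence the
axis are configuration, recorded with each run.

**Alpha angle.** Walking the outline from the last head-circle index toward
the neck, the departure point is the first location where the radial
distance from the fitted centre exceeds `radius × (1 + tol)` (default
tolerance 2% of the radius, configurable in (0, 0.2)); the crossing is
linearly interpolated between the last interior and first exterior points,
and AA is the angle at the head centre between the neck-axis direction and
the crossing direction. Three denoising steps wrap the raw rule, each an
exact identity when the radial profile is monotone (i.e. on noiseless
outlines):

1. a median-of-3 prefilter removes isolated landmark-noise spikes;
2. an isotonic (monotone non-decreasing) fit pools the pre-departure
   plateau, since the underlying radial excess over the head circle can
   only grow along the junction;
3. the threshold is re-anchored on the larger of the fitted radius and the
   median of the scan's own pre-departure plateau, iterated to a fixed
   point (≤4 passes). The circle extrapolated beyond its fit arc carries
   more radial error than the plateau itself, and a 2% margin (~0.5 mm on
   a 25 mm head) is otherwise eaten by that extrapolation error.

With 0.3 mm isotropic landmark jitter this detector achieves a mean
absolute AA error below 3° over the 40–110° range (the naive first-
exceedance rule exceeds 13°); on noiseless outlines the sweep error is at
most ~1.4°, dominated by linear interpolation across the ~8.6° landmark
spacing of the junction. If no scanned point exceeds the tolerance the
record is flagged (AA undefined) rather than invented; flagged records are
kept for LCEA-based analyses and excluded from cam analyses.

**LCEA.** The signed angle at the head centre between the vertical
(perpendicular to the image x-axis) and the segment to the lateral edge
point; positive when the edge lies lateral of the vertical, negative
(extreme dysplasia) when medial. No pelvic-tilt correction is attempted —
impossible from a single-hip outline.

**mJSW.** The minimum Euclidean distance between the acetabular and femoral
polylines, as the minimum over all point-to-segment distances in both
directions (exact for non-crossing polylines, symmetric in its arguments).

## Grading

Osteophyte areas (mm², three sites: lateral acetabulum, superolateral and
inferomedial femoral head) map to ordinal grades 0–3 by strictly increasing
cutpoints, grade g iff area ∈ [cut_g, cut_{g+1}). JSN grading is the mirror
image on height-adjusted mJSW: smaller adjusted mJSW ⇒ higher grade. Height
adjustment is a per-sex linear-regression residual shift,
`adjusted = mjsw − slope_sex × (height − mean_height_sex)`; with slope 0 it
is the identity. Cutpoints are either configuration or ROC-calibrated
against semi-quantitative reference grades: the calibrated cutpoint
maximises Youden's J (a closest-to-(0,1) criterion is available), scanning
all midpoints between consecutive sorted unique values, ties resolved to
the midpoint of the tied interval so separable classes yield the centre of
the separating gap. The numeric default cutpoints shipped in configuration
are synthetic placeholders on plausible scales, not published values — the
study's actual cutpoints are not in the public record.

Binary phenotypes use inclusive bounds exactly as defined clinically:
cam = AA ≥ 60°, pincer = LCEA ≥ 45°, acetabular dysplasia (AD) =
LCEA < 25° (pincer and AD can never co-occur); rHOA = grade ≥1 JSN together
with a grade ≥1 osteophyte at any site; the stricter "grade ≥2" variant
requires grade ≥2 of each, so it implies rHOA.

## Association statistics

Every exposure (cam, pincer, AD) × outcome (rHOA, three per-site osteophyte
presences, JSN, hip pain) × stratum (male, female, combined) ×
{unadjusted, adjusted} cell is one maximum-likelihood logistic fit (IRLS on
a binomial GLM via statsmodels, |Δ| < 10⁻⁸ or 50 iterations). Adjusted
models include age, height, weight and one-hot ethnicity with White as the
reference (97% of the emulated population); combined models add sex. The
report per cell is OR = exp(β), Wald 95% CI exp(β ± 1.96·SE) and a
two-sided Wald p — so the CI excludes 1 exactly when p < 0.05 — plus the
complete-case n actually used. Perfect or quasi-separation is detected and
emitted as a flagged result, never a silent number; a Firth
(Jeffreys-penalised) estimate is available behind a flag. Single-class
cells are emitted as logged skips; the suite never aborts on one failed
cell and never omits a cell silently. No multiple-testing correction is
applied (per-cell p-values are reported as such).

Two sensitivity analyses mirror the main suite: (1) pincer and AD compared
against a restricted reference of LCEA ∈ [25°, 45°), dropping rows carrying
the other morphology; (2) cam → hip-pain models adding, in turn, each
osteophyte-presence indicator and all three together, to probe attenuation
of the association through osteophyte formation (explicitly not a formal
mediation analysis).

Repeatability metrics: Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from
marginal products (undefined and flagged when both raters are constant and
identical), percent agreement = 100·p_o, and Lin's concordance correlation
coefficient CCC = 2·cov(x,y)/(var x + var y + (mean x − mean y)²) with
population (1/n) moments. Descriptive tables report counts and percentages
(1 decimal, rounded half away from zero on the shortest decimal
representation) and mean/range for continuous measures.

## Synthetic cohorts

The outline generator inverts the measurement definitions so ground truth
is exact by construction:

- head points lie on a circle of radius ~25 mm; the fit-range points span a
  wide (~242°) arc including the superior pole, as on a real articular
  outline — a short arc would leave the fitted radius too uncertain for a
  2% departure margin under realistic landmark jitter;
- the cam bump is a smoothstep radial excess (rise width 20°, amplitude
  10% of the radius by default) whose crossing of `radius × (1 + tol)` is
  analytically placed at the requested departure angle, so the true AA is
  exact;
- the mJSW-bearing acetabular roof points (79–84) lie on the tangent line
  to the joint-space-offset circle at the superior pole, with the lateral
  edge (78) on the same line at the LCEA ray. A concentric polyline's
  chords would cut inside the offset arc by far more than the 10⁻³ mm
  round-trip tolerance; the tangent-line roof makes the minimum polyline
  distance equal the configured gap exactly, because a fit vertex sits
  exactly at the pole;
- the neck is symmetric about the configured axis with a quadratic-waist
  width profile, so the minimum-width midpoint lies on the axis exactly;
- optional isotropic Gaussian jitter (default 0.3 mm in cohorts, the scale
  of point-placement uncertainty) is added after construction.

The outcome model generates, in causal order, morphology → osteophytes/JSN
→ pain: sex-specific morphology prevalences (defaults 15.4%/1.8% cam,
8.9%/8.1% pincer, 5.6%/7.0% AD, male/female, pincer and AD mutually
exclusive); per-site osteophyte presence from logistic models whose default
cam log-odds echo the published estimates (acetabular 1.87, superior 1.94,
inferior 4.75 as ORs), grade given presence from a categorical distribution
and area given grade from gamma distributions with grade-increasing scale;
JSN grade from a cumulative-logit model (default ORs 1.53 cam, 4.03 pincer,
0.29 AD) with an adjusted-mJSW value drawn inside the grade's band and a
raw value carrying a 0.012 mm/cm height slope; hip pain from a logistic
model with a small direct cam effect (OR 1.15) plus per-site osteophyte
effects, so osteophyte adjustment partially attenuates the cam→pain OR.
These defaults are configuration echoing the published tables, not
estimates from data. Covariates (age, height, weight by sex; ethnicity
proportions) follow the published descriptive statistics. All randomness
flows through one `numpy.random.Generator`: identical seeds give
byte-identical outputs.

What the generator does **not** emulate: pixel-level DXA appearance and
reader-specific landmark-placement error structure (noise is isotropic and
independent across points), osteophyte-induced distortion of the outline
itself, pelvic tilt and rotation, correlation between head size and
morphology, and real covariate–morphology confounding beyond sex. Passing
round-trip and recovery tests therefore demonstrates internal consistency
of the measurement/grading/inference chain, not field accuracy on real
scans.

## Validation problem sizes

The validation suite uses: geometry sweeps AA 40–110° and LCEA 5–60°
(noiseless, tolerances 1.5°/0.5°/10⁻³ mm); 500 hips at 0.3 mm jitter for
noise robustness; Wald CI coverage of a true OR 4.75 at n = 5,000 over 200
replicates (band 95% ± 4%); type-I error over the full unadjusted
association grid at n = 5,000 over 200 replicates (band 0.05 ± 0.02) under
a global null with sex-equal exposure prevalences — with sex-dependent
prevalences the unadjusted combined-sex cells would be genuinely
confounded by sex, which is a real association, not a false positive; and
mediation-structured attenuation (no direct cam→pain path) at n = 6,000
over 200 replicates (attenuation in ≥95%). Replicate sizes were chosen so
that each check has adequate power against its band.

## Known limitations

- The neck-axis construction and the height-adjustment form are documented
  stand-ins; results depending on them (AA most of all) are conditional on
  those choices.
- Grading cutpoints are synthetic defaults unless calibrated on a
  reference; calibrated cutpoints inherit the reference's noise, and tied
  adjacent-boundary cutpoints in degenerate small samples are separated by
  a negligible (10⁻⁹) nudge to keep the grade map valid.
- Wald intervals are first-order; for sparse cells they can be
  anticonservative, which is why separation is flagged and Firth estimation
  is offered rather than silently reported.
- Threshold phenotypes inherit measurement noise asymmetrically: with
  0.3 mm jitter, more non-cam hips sit just below the 60° cutoff than cam
  hips just above it, so measured cam prevalence runs above the latent
  prevalence (e.g. ~23% measured vs 15.4% latent in a male cohort at
  default settings), and boundary misclassification attenuates fitted ORs
  toward the null. This mirrors the behaviour of any hard-threshold
  phenotype on a noisy continuous measure.
- The pipeline is 2-D by design: out-of-plane morphology, pelvic tilt and
  3-D joint-space geometry are out of scope.
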