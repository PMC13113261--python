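# Methods

## The asymmetry measure

A face photographed frontally is treated as a set of indexed 2-D
landmarks in pixel coordinates (x rightward, y downward). Landmarks come
in mirror-corresponding left/right pairs; on a perfectly symmetric,
upright face every pair's connecting segment is horizontal. The method
quantifies asymmetry as the departure of those segments from horizontal.

**Midline fit and alignment.** The midline landmarks (central-axis
points; 20 for the dense registry, 6 for 68-point layouts, in both cases
excluding mouth-axis points whose position depends strongly on
expression) are fit by ordinary least squares as `x = a + b·y`.
Regressing x on y is deliberate: for an upright face the midline is
vertical up to head tilt of a few tens of degrees, which makes x-on-y
well-posed exactly where y-on-x degenerates. A horizontal row of midline
points (no y spread) is rejected as degenerate geometry. All landmarks
are then rotated rigidly about the pivot `((w−1)/2, (h−1)/2)` by
`α = atan(b)` using

    x' = cx + (x−cx)·cos α − (y−cy)·sin α
    y' = cy + (x−cx)·sin α + (y−cy)·cos α

which makes the fitted midline exactly vertical: with this matrix and
this sign convention the re-fitted slope of an exactly collinear midline
is 0 to machine precision. The reported `rotation_deg` is α in degrees.
Rotation acts on coordinates, never by resampling pixels, so the
metrology path carries no interpolation error; any fixed pivot yields
identical angles because the transform is rigid. A single fit-and-rotate
pass is applied (no iteration). With exactly collinear midline points
alignment is exactly equivariant — a pre-rotation of the input about the
pivot changes nothing downstream — which is the analytic basis of the
rotation-robustness tests. With noisy midline points OLS is not exactly
rotation-equivariant; residual deviations of order 10⁻³ degree per 25°
rotation at 1 px landmark noise are expected and measured by the
robustness module rather than assumed away.

**Angles and score.** Per pair, `θ = (180/π)·atan2(y_R−y_L, x_R−x_L)`
(signed; positive = right side lower; coincident points give θ = 0 with
a warning). Angles are stored signed — direction matters for rendering
and future weighting — and only the score takes magnitudes:
`Score_AI = mean |θᵢ|` over a pair subset, in degrees, 0 ≤ score ≤ 180.
The full-subset score equals the pair-count-weighted mean of its
regional (eye/nose/mouth) scores by construction; this identity is
asserted in the tests at 1e−12. The per-dataset "all" value is the
unweighted mean of the nine per-expression scores.

**Pair registries are data.** The published dense-mesh pair assignment
is not available, so the shipped `dense-225` registry is a synthetic
reconstruction: 478 indices of our own layout with 225 symmetric pairs,
20 midline indices, 8 mouth-axis points excluded from the midline fit,
and nested stored subsets of 140/91/50/21 pairs whose 91-pair member
splits 24 eye / 23 nose / 44 mouth. The `sparse-29`/`sparse-21`
registries use the canonical 68-point left/right correspondence (29
pairs; 21 after dropping the 8 jaw-contour pairs; midline = chin + nose
bridge/tip, excluding the 4 mouth-axis points). Every pipeline stage is
registry-parametric, so matching a particular detector's topology is a
JSON swap, not a code change. `scripts/make_registries.py` regenerates
the assets byte-identically.

## Pair selection against clinical grades

Grades are the Stennert index: rest 0–4, movement 0–6, higher = worse.
Analysis units default to sessions (one value per dataset: the mean
absolute angle over its nine expressions) because grades are recorded
per session and patients' grades change under therapy; `unit="patient"`
pools a patient's sessions but insists on constant grades (strict
reducer) and otherwise directs the caller back to sessions. Datasets
without grades are dropped from selection with a logged count and still
participate in the image-based analyses.

Per pair and condition, η² = SS_between/SS_total from one-way ANOVA
(η² := 0 when SS_total = 0; single-observation groups are retained — the
SS arithmetic is valid — with a logged warning). The sweep applies
thresholds 0.001–0.400 in 0.001 steps, retaining pairs *strictly*
exceeding the threshold in **both** conditions; subset size is therefore
a non-increasing step function of the threshold and subsets are nested.
Each distinct non-empty subset is scored per unit and rated by
tie-corrected Kruskal–Wallis H across rest grades and across movement
grades (p from χ² with k−1 df). The chosen subset maximizes
`H_rest + H_move`; `min(H_rest, H_move)` is available by configuration.
The sum treats both conditions symmetrically; ties break toward smaller
subsets, then larger thresholds. If the chosen subset separates neither
condition at p < 0.05 it is flagged non-discriminative. Raw p-values
drive everything; a Benjamini–Hochberg column is emitted in the
correlation report for reference but never used for selection.
Spearman ρ (average ranks, two-sided t-approximation) between subset
scores and grades is reported per expression 1–9 and "all", per
condition, per subset; undefined cells (constant input) are NA with a
note, never an exception.

η², Kruskal–Wallis and Spearman are thin, validated wrappers: η² is
direct sum-of-squares arithmetic (cross-checked in the tests against
brute-force sums and against an independent ANOVA implementation), the
rank tests call scipy.stats and are cross-checked against hand rank
formulas; the 10 000-replicate null calibration in the acceptance suite
verifies the Kruskal–Wallis type-I error at α = 0.05 to ±0.01.

The selection stage is exposed as a scikit-learn selector
(`EtaThresholdPairSelector`, a `SelectorMixin`): `fit(X, y)` takes the
(units × pairs) deviation matrix and an (units × 2) grade array and
exposes `support_`, `threshold_`, `min_eta2_` and the full `sweep_`
trace; `transform` restricts a deviation matrix to the chosen pairs.

## The synthetic cohort generator

The generator emulates the *structure* of a PFP photo archive — patients
× sessions × nine standardized expressions — with controlled ground
truth. Per patient: a movement grade uniform on 0–6, a rest grade
`clip(round(move·4/6 + jitter), 0, 4)` with jitter ∈ {−1, 0, 1}
(correlated two-scale grading), and a mean-1 lognormal severity
multiplier (σ = 0.4) capturing that equally graded patients differ —
clinical within-grade score SDs run 40–60% of the mean, which a
grade-deterministic model cannot reproduce. Per image, starting from a
bilaterally symmetric template:

* **Signal.** Each informative pair's right landmark is displaced
  vertically so its angle equals
  `droop_per_grade · (move + rest_coupling·rest) · gain(expression,
  region) · severity` exactly (droop_per_grade = 0.8°/grade,
  rest_coupling = 0.75: resting asymmetry persists through every
  expression). Expression-region gains couple eye pairs to the eye
  closures (expressions 2–4) and nose/mouth pairs to nose wrinkling and
  the mouth movements (5–7, 9), with the eye region only weakly
  grade-coupled during mouth expressions — the pattern seen in clinical
  region-specific correlation tables.
* **Structural baseline asymmetry.** Every pair carries a per-patient,
  grade-independent baseline angle (σ = 1°, within-region correlation
  0.8, constant across sessions): healthy and palsied faces alike are
  not perfectly symmetric, which is why clinical grade-0 cohorts score
  ≈ 0.9 ± 0.5° rather than zero.
* **Noise and pose.** Isotropic Gaussian landmark noise (1 px) and a
  random in-plane head tilt (±15°) per image.

The template is a parametric schematic (feature bands per region), not a
real mesh: midline points sit exactly on the vertical axis and pair
halfwidths within each region descend with ordinal rank, from lateral
wide pairs (the stored informative subsets) to near-midline narrow ones
— in a dense mesh, near-midline pairs turn pixel jitter into degrees of
angle noise, and the template reproduces that. Defaults: 60 patients,
one session, 512×512 canvas, seed-reproducible to the byte.

**What passing tests do and do not show.** The generator produces
plausible marginal distributions (grade-0 scores ≈ 0.8–1°, strong
mouth-region amplification for expressions 5–7, Spearman ρ ≈ 0.7–0.9
between the "all" score and movement grade) but it is not real data: no
out-of-plane pose, no detector-specific error structure, no occlusion,
no expression-execution variability beyond the gain table, and baseline
asymmetry modelled at region granularity only. Green tests certify the
pipeline's arithmetic, invariances and statistical machinery under
controlled conditions, not clinical performance.

**Planted-recovery benchmark.** Exact recovery of a planted informative
set by the in-sample Kruskal–Wallis argmax is only statistically
identifiable when the objective is curved around the planted boundary.
On small cohorts with clutter on every pair the objective is nearly flat
in subset size — shared patient-level clutter removes the benefit of
averaging more pairs, while any pair-idiosyncratic clutter rewards
in-sample sub-selection — so the argmax wanders among statistically
equivalent subsets. The recovery benchmark
(`synthetic.recovery_benchmark_config`) therefore uses a clinical-
archive-scale cohort (400 sessions), 30 planted pairs of homogeneous
intermediate width carrying clean grade signal, structural clutter
(1.5°, correlation 0.3) plus landmark noise on the remaining 195 pairs,
and a narrow severity spread (σ = 0.15). Under these documented
conditions dropping a planted pair costs averaging and adding a clutter
pair costs rank fidelity, the objective peaks at the planted boundary,
and the sweep recovers the planted set at precision/recall ≥ 0.9
(verified across 20+ generator seeds after the design was frozen). The
default cohort still exercises the sweep's structural properties
(nestedness, monotone subset size, discriminativeness flag).

## Rotation robustness

Every image is rotated on a grid (default −25°…25°, 1° steps, 0
excluded), the full pipeline is re-run, and `|Score(r) − Score(0)|` is
aggregated per rotation (mean, median) and overall (mean ± SD); all
(dataset, expression) images weigh equally. `transform` mode rotates
landmark coordinates — with collinear midline points deviations are
float noise (< 1e−6°), and an optional per-rotation landmark-noise
re-draw turns the sweep into a seeded Monte-Carlo sensitivity analysis
whose deviation grows monotonically with the noise level. `redetect`
mode re-runs a detector adapter on the resampled image (bilinear,
border-replicated) and is the fidelity path when a detector is
configured; it is the regime in which real archives show mean absolute
deviations of a few tenths of a degree.

## Rendering

Angle maps draw one segment per pair from the left to the right
landmark of the aligned face, coloured by |θ| clipped at `clip_deg`
(default 5°): linear RGB interpolation from blue (0, 0, 255) at 0° to
red (255, 0, 0) at the clip, monotone in |θ|, identical red for
everything at or beyond the clip. Single maps are written as
deterministic SVG text (byte-identical for identical inputs; blank
white background, no photographic content — the maps are
privacy-preserving by construction). Longitudinal grids (sessions ×
expressions, chronological rows, per-row score labels) and
cohort-percentile grids (max/75th/median/25th/min by "all" score) render
via matplotlib; missing cells become labelled empty slots.

## Numerical and interface choices

* OLS midline via centred normal equations: exactly zero slope for an
  exactly vertical midline (an SVD least-squares solve leaves ~1e−19
  residue that breaks the score = 0 contract for symmetric faces).
* CSV round trips use shortest-round-trip float text on write and
  `float_precision="round_trip"` parsing on read, so writer→reader is
  bit-exact.
* Landmark files are long format (one row per landmark), making every
  reader/writer n_landmarks-agnostic.
* "Exceeding the threshold" in the sweep is strict (`>`);
  at 0.001 granularity the choice is immaterial and is switchable.
* Coincident pair points score θ = 0 (atan2(0,0) convention), logged,
  never fatal; dataset-level problems (a missing expression) exclude the
  dataset with a logged count, while structural corruption (duplicate
  landmark indices) fails fast.
* CLI exit codes: 0 success, 2 usage, 3 data integrity, 4 missing
  capability (e.g. image input without a detector adapter), 5 degenerate
  statistics. Every command writes a manifest (resolved configuration,
  seed, version, config hash); reruns from a manifest are byte-identical.
* Problem sizes in the test and acceptance runs: the reference cohort is
  60 patients × 9 expressions × 478 landmarks, the recovery benchmark
  400 sessions, the null calibration 10 000 replicates of 3 × 8 values —
  sizes at which every statistical check is stable while the whole suite
  stays fast.

## Known limitations

* Bilateral palsy is out of scope: the measure compares left against
  right within one face and has no healthy side to anchor on.
* Out-of-plane pose (yaw/pitch) is not normalized; only in-plane
  rotation is handled.
* The dense registry is a faithful-by-symmetry reconstruction, not the
  original mesh assignment; results on real detector output require a
  registry matching that detector.
* In-sample subset selection is exploratory: the chosen subset maximizes
  the same statistic it is evaluated on, and on small cohorts the
  optimum is statistically fuzzy (see the benchmark discussion above).
  No cross-validation machinery is provided.
* Pair weights are uniform; learned weighting is deliberately left out.
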