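# Methods

## Recording model

A session is a timestamped series of six anatomical landmarks (MH, MN,
C7, L5, FC, LM) in camera coordinates (X lateral, Y vertical up, Z depth,
metres), split into four protocol windows: 5 s relaxed and 5 s corrected
stance, facing the camera (frontal) and after a 90° turn (lateral).  The
camera is assumed level; no gravity calibration is applied, so the
vertical reference VL is the camera Y axis.  Window boundaries come from
file metadata when present; otherwise the default script (first 5 s
relaxed, next 5 s corrected, anchored at each view's first frame) is
inferred.  Inference refuses overlapping views rather than guessing.

When the input is a Kinect-v2 skeleton instead of landmarks, the mapping
is MH=Head, MN=Neck, C7=SpineShoulder, L5=SpineBase (remappable via the
config file), LM = midpoint of the available ankles (one ankle suffices;
the sides differ by a few centimetres at most in quiet standing, and the
features use only the sagittal/coronal projections).  FC, the most convex
point of the spine, has no Kinect joint; it is operationalized as the
point of maximal perpendicular distance to the C7–L5 chord along a
quadratic Bezier curve through (SpineShoulder, SpineMid, SpineBase),
sampled at 51 parameters, distance taken in the sagittal projection, ties
resolved toward the cranial end.  51 samples keep the discretization
error of D1 well below 1 mm on smooth spines (tested against a
10,001-point search), i.e. far below sensor noise.

## Features and aggregation

F1–F3 are unsigned acute angles to the vertical, arctan(|Δu|/|Δv|) in
[0°, 90°]; F4/F5 use the deviation-from-collinearity convention (180°
minus the angle between L5→LM and L5→C7 or L5→FC), so an erect stance
scores 0 on everything.  Signed conventions were rejected because the
published healthy-control means are small and positive, which only a
magnitude convention produces.  F7 = 100·D1/D2 uses the infinite line
through C7 and L5, and is scale-free by construction (it removes
anthropometric differences); all features are invariant under uniform
scaling and translation of the skeleton.

Per-session values are per-frame **medians** over the selected window
(frontal window for F1/F2, lateral for F3–F7).  The median, not the mean,
is used because depth-camera tracking produces transient glitches; fewer
than half the frames being corrupted leaves the value unchanged.  Frames
with degenerate geometry (coincident landmarks) are dropped with a
warning; an all-degenerate window is an error.  The relaxed window is the
default (`window_policy="relaxed"`) since the features quantify the
habitual stance; the corrected stance remains available for reporting.

## The index

IPA = 0.132·F1 + 0.126·F2 + 0.165·F3 + 0.113·F4 + 0.067·F5 + 0.400·F7.
The weights are the published feature importances of the decision-tree
model the feature set came from and are treated as fixed constants; they
sum to 1.003 and are deliberately **not renormalized**, because the
published group-mean index values reproduce only under the printed
weights.  Classification uses the published cut-offs 12.96 and 20.14 with
boundary values classified positive (the convention is unstated at the
source; "≥" preserves the reported sensitivity when a score ties the
cut-off).

## Statistics

* Normality gate: one-sample Kolmogorov–Smirnov with estimated parameters
  (Lilliefors) at α = 0.05; groups with fewer than 4 observations or zero
  range are treated as non-normal.  Both groups normal → Student's t,
  otherwise Mann–Whitney U (exact p for tie-free groups of ≤ 12, else the
  normal approximation with continuity correction).  A `test=` override
  exists for forcing either branch.
* Chi-square for categorical variables is Pearson's **without** Yates
  continuity correction; this is what reproduces the published gender
  comparison (χ² = 5.62, p = 0.018 on the 48/22 vs 13/17 table).
* Spearman correlation uses average ranks; bands at |r_s| = 0.10 / 0.40 /
  0.70 / 0.90 (negligible/weak/moderate/strong/very strong).  Pairwise-
  complete deletion handles missing values.
* Simple regression: OLS; standardized β is the slope of the z-scored
  fit (= Pearson r for one predictor); adjusted R² = 1 − (1 − R²)(n −
  1)/(n − 2), which can be negative for null fits.
* ROC: AUC is the normalized Mann–Whitney statistic with ties counted ½;
  candidate cut-offs are midpoints between adjacent distinct scores plus
  sentinels beyond the extremes; the cut-off maximizes Youden's J with
  ties broken toward higher specificity (the screening use-case); the 95%
  CI is DeLong's normal approximation, intentionally not clipped to
  [0, 1] (matching the convention that can print an upper bound above 1).
  Accuracy bands: < 0.7 low, 0.7–0.9 moderate, > 0.9 high.
* p-values are reported raw; no multiple-testing correction, matching the
  source workflow.

## Synthetic data

### Skeletons

`make_posture` inverts the feature definitions.  Lateral view: LM at the
origin, L5 straight above at leg length (0.80 m default), L5→C7 at F4
from vertical (trunk 0.50 m), FC on the ray from L5 at F5 from vertical
with its distance solved so that 100·D1/D2 = F7 (D1 grows linearly along
the ray while D2 is fixed), MN on the C7→MH segment with MH placed so
MH–MN makes F3 with vertical (head offset 0.25 m).  Frontal view:
vertical leg, C7–L5 at F2, MH–C7 at F1.  Targets are unsatisfiable when
F7 > 0 with F4 = F5 (the fulcrum must leave the chord) or when the
implied fulcrum distance exceeds 2 trunk lengths (anatomical bound);
both raise.  Noise is isotropic Gaussian per landmark per frame (default
5 mm, the scale of depth-camera landmark jitter), 150 frames per 5-s
window at 30 fps.  At zero noise, extraction recovers the targets to
machine precision; this forward/inverse identity is the backbone of the
geometry tests.  The corrected-stance windows repeat the same posture
with fresh noise — active correction is not modelled.

### Cohorts

`simulate_cohort` draws per-subject feature vectors for the four
published study groups (healthy controls, PD without and with postural
abnormalities, and the pooled all-PD marginal), with group means/SDs
defaulting to the published group summaries.  Two deliberate departures
from the simplest recipe:

* **Within-group correlation.**  The published tables report not only the
  per-feature SDs but the SD of the index itself in every group, and the
  two are mutually inconsistent under feature independence (independent
  features give an index SD of ≈ 5.0 where ≈ 7.3 is printed, because the
  index variance of correlated features carries the cross terms).  Each
  group therefore uses a one-factor equicorrelated Gaussian whose common
  correlation is identified in closed form from the printed index SD:
  ρ = (Var(IPA) − Σw²σ²)/((Σwσ)² − Σw²σ²), giving ρ ≈ 0.09 (HC), 0.34,
  0.45, 0.52.  Setting `ipa_sds=None` recovers the independent design.
* **Nonnegativity by compensated censoring.**  Angles cannot be negative,
  but no ≥0-truncated normal can match a marginal like 0.3 ± 0.6 (its
  coefficient of variation cannot exceed 1), and conditional truncation
  at the printed parameters would shift that mean by +0.30.  The
  generator instead censors at zero (clips) and root-finds the underlying
  mean so the censored marginal mean equals the printed mean **exactly**;
  the marginal SD is then slightly shrunk by censoring (≲ 5–8% in the
  worst groups), which the tests accept.

Under this design the simulated healthy-control index mean is 8.02 and
the pooled-PD-vs-HC discrimination agrees with binormal theory,
Φ((21.6 − 8.0)/√(6.6² + 1.6²)) ≈ 0.977; at 500 subjects per group the
empirical AUC falls within Monte-Carlo error of that value (e.g. 0.980
at one fixed seed), and the subgroup contrast gives AUC ≈ 0.79.  Note
that the pooled-PD arm must be simulated from the published all-PD
marginal: a pool of the two separately-simulated subgroups is a mixture
whose true AUC (≈ 0.992) exceeds the pooled-moment binormal value, so
the mixture route would not be comparable against binormal theory.

What the simulator does **not** emulate: skewness of real feature
distributions, richer-than-equicorrelated dependence, medication state,
or any within-subject frame dynamics beyond white jitter.  The source
study's empirical PD-vs-HC AUC (0.999) exceeds any normal-marginal
emulation of its group summaries; passing synthetic tests therefore
demonstrates correctness of the pipeline and internal consistency with
the published summary statistics, not real-world discriminability.

## Problem sizes and numerical choices

Tests run the geometry round trip at 2 frames/window (it is exact, more
frames add nothing), noise checks at 150 frames/window, cohort moment
checks at 10,000 subjects/group, and the discrimination study at
500/group — sizes at which Monte-Carlo error is far smaller than the
effects asserted.  The acceptance script uses 30 noise-free frames per
window per group.  Root-finding for censoring compensation uses Brent's
method bracketed at [μ − 12σ, μ]; the compensation is skipped when
μ/σ > 8 (censored mass < 1e-15).  Float round trips in the CSV dialects
use shortest-repr writing and round-trip float parsing.

## Known limitations

No camera-tilt calibration (a tilted camera biases every angle); no
multi-person or occlusion handling; the two-view protocol assumes the
posture is stationary between views; the FC search assumes a single-bow
spine shape (a quadratic curve cannot represent S-shaped scoliosis); the
covariate-adjusted AUC variants reported alongside the published ROC
results are excluded because no standard method is implied by their
description.
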