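# Methods

`antmimic` quantifies how accurately ant-mimicking arthropods resemble their
ant models in four trait categories — color, shape, size and movement — and
analyses how those accuracies co-evolve on a phylogeny of the mimics.  This
note records the models, the measurement conventions, the numerical choices,
and what the synthetic-data generator does and does not emulate.

## Study design and data model

The unit of design is the *triplet*: a mimic species, its putative ant model,
and a closely related non-mimetic control, sampled together and measured with
the same instruments.  Triplets are nested in eight taxonomic groups (six
spider groups, two insect groups).  A model or control species shared by
several triplets keeps a separate measurement set per triplet, so species
summaries are keyed by (triplet, role) rather than by species name alone.

Per specimen the raw inputs are:

- a binary silhouette mask (8-bit PNG, foreground > 127) with a body-only
  variant (appendages removed) and twelve appendage landmarks (femur, tibia,
  tarsus midpoints of four appendages, with local axis directions);
- reflectance spectra of the anterior and posterior body halves, standardized
  against white/black references and resampled to 400 points on 300–700 nm,
  concatenated to an 800-value vector;
- a 60 s centroid trajectory at 30 fps (cm), with an optional per-frame
  body-pixel-change fraction.

## Trait extraction

**Shape.**  Circularity is 4πA/P², 1 for a disk and smaller for elongated,
articulated bodies.  The perimeter is estimated subpixel: the mask is
smoothed with a σ = 1.5 px Gaussian and the 0.5 iso-contour polygon length is
measured.  This estimator reproduces the closed forms for a rasterized disk
(0.998), an axis-aligned square (0.796 vs π/4) and a 4:1 ellipse (0.535 vs
the Ramanujan-perimeter value 0.536); pixel-edge counting and Crofton-type
line-integral estimators miss one or another of these by several hundredths.

The outline profile is measured on a *straightened* body.  The body-only
mask is skeletonized; the longest geodesic path through the skeleton graph
(8-connected, edge weights 1/√2) is the initial axis; ends are trimmed where
the distance-transform clearance drops below 80% of the body's typical
half-width (skeletons fork toward corners of blunt shapes), the path is
extended along its end tangents (estimated by PCA over the terminal 15% of
points) to the silhouette tips, smoothed with a moving average of window 5%
of its length, and resampled at 1 px.  Two refinement passes then re-centre
each axis point on the midpoint of the mask chord along its local normal.
Cross-sections are rebuilt from subpixel chord edges (linear interpolation of
the 0.5 crossing on a lightly smoothed field, sampled at 0.25 px): each
straightened column receives round(chord width) rows centred on the chord
midpoint, which avoids re-binarization flicker.  On test shapes this
reconstructs a rotated rectangle with IoU ≥ 0.98 against its unrotated
original and recovers generated spines with ≤ 0.5 px RMS error.

Forty stations are placed at the centres of forty equal slices of the body
length; at each, the distance from the axis to the body edge is averaged
over both sides (making the profile exactly mirror-symmetric).  Species mean
outlines are pointwise means of raw profiles, standardized to their maximum.

**Size.**  Body length is the axis arc length times the mm/px scale.
Appendage thickness is the subpixel chord width perpendicular to each
landmark's axis direction, measured on the full mask; the twelve values are
averaged.

**Movement.**  Four traits per recording: mean velocity (path length /
duration, cm/s); locomotion (time in the "moving" state, assigned by a speed
hysteresis: enter above 0.50 cm/s, leave below 0.25 cm/s, on a 5-frame
smoothed speed signal); absolute angular velocity (mean |heading change| per
second over steps whose displacement exceeds 0.02 cm — shorter steps carry no
heading and are skipped); mobility (% of centroid-stationary frames whose
body-change fraction exceeds 0.05).  Commercial tracking software does not
publish its internal thresholds, so these are explicit `MotionParams`
defaults, configurable per study.

## Accuracy distances

Mimetic accuracy is distance — smaller is more accurate.  Color and outline
distances are Euclidean distances between species-mean vectors.  Scalar
traits (circularity, body length, mean thickness, and the four movement
traits) are first scaled by their pooled SD across all species summaries,
then differenced absolutely.  Category scores average their member traits
(movement: 4, size: 2, shape: 2, color: 1) and are finally divided by the
SD of the mimic–ant scores of that category, putting the four categories on
a common scale; mimic–control scores are divided by the same SD so the two
pair types remain comparable.

## Mixed models

Specimen-level trait comparisons among the three mimetic types use linear
mixed models with random intercepts for taxonomic group and for triplet
nested in group; velocity and mobility are square-root transformed and
proportions arcsin-√ transformed before fitting.  Variance components
(group, triplet, residual) are reported as percentages of their sum.
Estimation is REML via statsmodels `MixedLM` (L-BFGS, then a conjugate-
gradient polish to gtol 1e-14 — the unpolished optimum is visibly off the
closed-form ANOVA estimators on balanced designs).  Fixed factors are tested
with Wald-type F statistics; the denominator df is the residual df
n − rank(X).  Per-pair distance comparisons (mimic–ant vs mimic–control) use
the mimetic pair as random intercept; the four scaled category scores are
compared with the pair as random intercept likewise.

## Phylogenetic comparative analysis

Species-level accuracies are not independent: relatives resemble each other.
Under Brownian trait evolution the expected covariance between tips is the
depth of their most recent common ancestor, computed here directly from the
Newick tree.  Three error-covariance families are supported:

- Brownian: V = C;
- Pagel: V(λ) multiplies the off-diagonal of C by λ (0 = star phylogeny,
  1 = Brownian; negative λ is admitted down to the positive-definiteness
  limit of the particular C);
- Martins (Ornstein–Uhlenbeck): correlation exp(−α d) in patristic distance.

GLS fits use the Cholesky factor of V; the ML residual variance and Gaussian
log-likelihood are exact, and AIC = −2 logLik + 2k counts mean parameters,
the variance scale, and any estimated structure parameter.

**λ estimation.**  λ is profiled over [λ_min, 1] with bounded scalar
minimization (tolerance 1e-6).  Two numerical choices matter:

1. *Search bound.*  Within ~1e-3 of the exact PD limit the profile
   likelihood develops a spurious spike — a near-zero eigenvalue of C(λ)
   acts as an almost-deterministic constraint that the data satisfy by
   chance.  The search therefore keeps the smallest correlation eigenvalue
   ≥ 0.05 (λ_min = −0.95/μ_max), which still admits clearly negative
   estimates while removing a 26%-of-replicates pile-up at the boundary.
2. *REML profile.*  The plain ML profile is biased toward 0 at intermediate
   signal on trees of this study's size (mean λ̂ ≈ 0.27–0.42 at λ_true = 0.5
   across 70-tip pure-birth trees; an independent R implementation of the
   same ML criterion lands at 0.39 on identical data).  The restricted
   likelihood removes essentially all of this bias (0.45–0.49), so λ is
   profiled by REML by default.  AIC comparisons across covariance
   structures use the ML likelihood (`method="ml"`), where likelihoods are
   comparable by construction.

**ANCOVA.**  Each pair of category accuracies is related by
y ~ x × taxon (insects vs spiders) under a Pagel structure with jointly
profiled λ; per-level slopes are the reference slope and slope +
interaction.  Terms are tested by drop-one Wald F with residual denominator
df.  Phylogenetic Pearson correlations whiten both variables by the inverse
Cholesky factor of the fitted structure (one λ maximizing the summed
intercept-only profiles) before correlating; with the identity structure
this is exactly ordinary Pearson.  Bonferroni correction uses m = 6, the six
pairwise relationships among four categories.

## Synthetic data

The generator produces every input with known ground truth.  A pure-birth
tree (depth normalized to 1) relates the mimic species; because the
simulator stops exactly at the n-th birth — which would leave a zero-length
cherry and a singular covariance — all pendant edges are extended by the
exponential waiting time to the next event before normalization.

Phenotypes are built per triplet.  Ant and control presets differ in the
directions observed in real myrmecomorph assemblages: ants are elongated and
articulated (deep constrictions at 1/3 and 2/3 body length, thin
appendages), move fast and turn little; controls are rounder, thicker-limbed
and slower.  The mimic phenotype is the convex combination θ·ant +
(1−θ)·control, θ ∈ [0,1], drawn per category with SD 0.10 deviations that
evolve on the tree with category-specific λ (defaults 0.0 / 0.30 / 0.36 /
0.48 for color / movement / shape / size, matching the weak-to-moderate
signal ordering such studies report).  The color position is additionally
coupled to the shape position with slope +0.8 for insects and −0.8 for
spiders, producing the opposite-sign co-evolution pattern the ANCOVA is
designed to detect.  Default scenario: 72 triplets in 8 groups, 3 specimens
per species, 60 s trajectories at 30 fps, θ = 0.8.

Silhouettes are rendered as a variable-half-width tube around a gently
curved, x-monotonic spine (superelliptical envelope with Gaussian
constrictions), plus tapered three-segment appendages; landmark positions
and all generating parameters are returned as ground truth.  Trajectories
are correlated random walks with two-state (stop/go) Markov switching, mean
bout length 3 s, Gaussian turning kernel, and a body-change channel;
reported ground truth is computed from the realized path.  Spectra are sums
of Gaussian bumps over 300–700 nm with per-specimen jitter.

What the generator does **not** emulate: photographic segmentation errors,
within-specimen measurement correlation, asymmetric or damaged bodies,
receiver (predator) vision, and real spectral shapes beyond smooth bumps.
Passing recovery tests on these data demonstrates the pipeline's estimators
are correct and calibrated under the stated noise model — not that field
images or spectra of arbitrary quality will be measured equally well.

## Problem sizes used in checks

Simulation checks run at sizes chosen to exercise the study's structure
while staying desk-scale: λ recovery uses 200 replicates per λ on a 70-tip
tree; ANCOVA sign recovery 200 replicates and null calibration 500; variance
-component recovery 100 replicates of the full 8 × 9 × 3 × 10 design; the
end-to-end pair-type check 100 replicates of a 16-triplet, 2-specimen
scenario at θ = 0.8.  The `scripts/acceptance.py` entry point recomputes all
of these from scratch for any seed.

## Known limitations

- Straightening assumes one dominant medial axis; it warns (and may be
  unstable) when the body is as wide as it is long.
- The outline half-width uses the chord through the axis, so deeply
  non-convex cross-sections (e.g. overlapping appendage stubs) are read as
  their central chord.
- Mobility depends on a tracking-software-style body-change channel; it is
  an operational reconstruction, not a standardized quantity.
- The Martins structure is provided for AIC comparison; its α is not
  estimated by ML (the comparative analysis estimates λ only, reflecting
  which structure such analyses actually select).
- MixedLM occasionally fails to converge on degenerate inputs; the fit
  chain retries with three optimizers before raising.
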