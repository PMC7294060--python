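# Methods

This note documents the models, conventions and numerical choices behind
`fcgraph`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Node atlas and networks

Nodes are the 264 putative functional areas (10 mm spheres) of the Power
atlas.  The partition into functional systems defines five analysis
networks: *global* (all 232 nodes assigned to any of the 12 named
systems), and the four largest systems — default mode (DMN, 58 nodes),
fronto-parietal task control (FPCN, 25), hand somatosensory-motor
(HSMN, 30) and visual (VN, 31).  Systems with fewer than 20 nodes are not
analyzed separately, since graph statistics on very small networks are
unstable; `build_networks` enforces the 20-node minimum.  The packaged
table carries the published MNI coordinates, but its node→system column is
a synthetic block reconstruction: it reproduces the published system
*sizes* exactly (including 32 unassigned nodes = the "Uncertain" and
cerebellar sets), while the node-level identity of individual assignments
is not publicly fixed and is not used by any computation here — only
membership counts and disjointness matter.

## Temporal preprocessing

The pipeline order is fixed: nuisance regression → linear detrend →
band-pass → scrubbing, and is recorded in every run manifest.

* **Nuisance regression.** OLS residuals on [intercept | 6 motion
  parameters | white-matter, CSF, whole-brain signals] (K = 9 canonical).
  A rank-deficient design is an error that names the collinear columns.
  The tissue/global signals cannot be derived from node series, so they
  are accepted as inputs (or generated synthetically).
* **Band-pass, 0.01–0.08 Hz.** Second-order Butterworth applied
  forward–backward (`sosfiltfilt`), i.e. zero phase and squared magnitude
  response.  The series is mirror-extended (`padtype="even"`) by its full
  length before filtering: the 0.01 Hz edge has an impulse response of
  several hundred seconds and the default padding leaves visible edge
  transients.  With this choice a 0.04 Hz tone passes within 0.5 % and a
  0.5 Hz tone is attenuated below 0.1 % in the steady-state region.
* **Framewise displacement.** FD_t = Σ|Δd| over the three translations
  (mm) plus 50 mm · Σ|Δθ| over the three rotations (radians) — the
  small-angle arc length on a 50 mm sphere; FD_0 = 0 by convention.
* **Scrubbing.** FD > 0.5 mm censors the volume plus one preceding and
  two subsequent volumes; windows union and clip at the boundaries.
  Kept volumes are concatenated — no interpolation across gaps — because
  scrubbing is the last temporal step.  A subject/visit is excluded when
  the retained duration falls below 300 s (correlation estimates
  stabilize at about five minutes of data).  Mean FD, the head-motion
  covariate, is summarized on the pre-scrub trace (both pre- and
  post-scrub summaries are computable; pre-scrub is the default because
  it reflects the acquisition, not the censoring).

## Connectivity and thresholding

Edges are Pearson correlations over the kept volumes; the diagonal is set
to zero and no Fisher transform is applied.  Subnetwork matrices are
computed directly on the member-node columns (identical, for Pearson, to
masking a full-atlas matrix; asserted by a test).  Proportional
thresholding keeps exactly round(density · N(N−1)/2) strongest edges by
*signed* value — ranking by absolute value would make the "densities
above 45 % admit negative edges" rationale incoherent.  Rounding is
half-away-from-zero; ties among equal weights break by ascending
(row, col), which makes the retained edge set at density d a superset of
the set at any smaller density and the whole sweep deterministic.  If the
retained set reaches into non-positive weights the graph is still
produced and a warning is recorded.  Overall connectivity — the mean of
strictly positive edges of the *unthresholded* matrix — is carried along
as the control variable for the known proportional-thresholding pitfall
(density is equalized, overall strength is not).

## Graph metrics

Conventions follow the Brain Connectivity Toolbox's weighted-undirected
routines:

* **Global efficiency.**  Edge lengths L = 1/w; all-pairs shortest paths
  (compiled Floyd–Warshall); GE = mean over ordered pairs of 1/d, with
  disconnected pairs contributing 0 (the d → ∞ limit).  At 5 % density
  fragmentation is common and must not be an error.  Nodes isolated by
  thresholding are retained (they lower GE and CC), matching BCT
  defaults.
* **Clustering coefficient.**  Onnela variant: weights normalized by the
  graph maximum, per-node coefficient = triangle intensity sum
  (geometric-mean cube roots) over k(k−1), zero for degree < 2; the
  network value is the unweighted mean over all nodes.  Scaling all
  weights by c > 0 therefore scales GE by c and leaves CC unchanged.

Both are verified to 1e-10 against brute-force oracles (pure-python
relaxation; exhaustive triple-sum) and cross-checked against networkx.

## Statistical layer

* **Yeo-Johnson.**  Applied to every continuous variable before
  modelling (binary covariates exempt).  The ML lambda is searched on
  [−5, 5] with a bounded Brent iteration (tolerance 1e-6); the
  implementation agrees with `scipy.stats.yeojohnson` to ~1e-7 and is an
  order of magnitude faster inside the regression sweep.  Lambdas are
  recorded per variable in the manifest.
* **Simple regressions.**  Standardized beta = Pearson r of the z-scored
  variables, adjusted R², two-sided t-test p, Bonferroni correction with
  n = 10 — the 5 networks × 2 measures; the 9-density sweep is not
  counted because measures are strongly dependent across thresholds.
* **Mediation.**  Point estimates are OLS on standardized variables
  (correlation algebra for one predictor / one mediator); indirect = a·b
  and indirect + direct = total holds to machine precision.  Inference
  resamples subjects with replacement (default 50,000 draws), re-deriving
  the standardized paths on each resample; p = 2·min(Pr*(θ≤0), Pr*(θ≥0))
  (percentile, chosen for robustness over the normal approximation, which
  is also emitted), with percentile CIs.  Degenerate resamples (zero
  variance) are redrawn and counted.  A perfectly collinear mediator
  (r_xm = ±1) is handled by attributing the whole effect to the mediated
  path, the limit consistent with the decomposition identity.
* **Gate logic.**  Mediation runs only for (network, measure, density)
  cells whose *both* simple-regression families are Bonferroni
  significant, and by default only for the best such cell — smallest
  worst-family corrected p, preferring the canonical (DMN, GE, 20 %)
  cell on ties.  This mirrors picking the density of minimum corrected p
  among significant cells.
* **ICC(1,1).**  One-way random-effects ANOVA; for unbalanced designs
  the effective replicate count k0 = (N − Σk_i²/N)/(n−1); 95 % CI from
  the F distribution of MS_B/MS_W.  Subjects with one visit are excluded
  with a warning (the pipeline itself requires ≥ 3 visits).  Verified
  against pingouin on balanced designs.
* **Longitudinal trend.**  Linear mixed model with fixed time slope and
  random intercept + slope per subject, fit by REML (statsmodels).  Time
  is internally rescaled to [0, 1]: slope variance components in raw days
  are ~1e-6 and make the optimization badly conditioned; estimates are
  rescaled back.  A non-converged or singular random-slope fit falls back
  to random-intercept only and is flagged.  The slope p-value is a Wald t
  with between-within degrees of freedom (n_subjects − 2), named in the
  output; its calibration is established by simulation (type-I ≈ 0.05 at
  44 × 8, 2-SE coverage ≈ 96 %).
* **Across-visit variability.**  Per-subject sample SD (and CV) of each
  measure over ≥ 3 visits; the SDs are Yeo-Johnson transformed and
  regressed on all ten explanatory variables (age, sex, mean FD, FW,
  brain volume, WMH volume, four vascular risk factors) *simultaneously*,
  one multiple regression per (network, measure); each covariate's p is
  Bonferroni corrected with n = 10.  Near-collinear covariates
  (|r| > 0.999) are an error naming the pair.

## Synthetic cohorts

The generator emulates exactly the second-order structure the analysis
consumes; it is not a biophysical BOLD simulation.

* **Time series.**  Stationary AR(1)-smoothed multivariate Gaussian
  draws (φ = 0.4 by default, giving power inside 0.01–0.08 Hz at short
  TR) with block covariance: within-system correlation 0.30, between
  0.05, and a within-DMN correlation attenuated linearly in the
  subject's standardized FW plus subject-level noise.  Low-frequency
  confounds are mixed into the node series and echoed as nuisance
  regressors so nuisance regression has real work to do.  Non
  positive-definite block settings are an error naming the values.
* **Motion.**  Slow random-walk drift plus sparse persistent steps whose
  FD magnitudes are drawn from 0.6–2.0 mm, exercising the scrub rule; the
  expected censored time follows from the spike rate.
* **Covariates.**  FW truncated-normal on [0.18, 0.56] (mean 0.28), ages,
  sex and vascular risk frequencies at the cross-sectional arm's
  marginals; the TMT-B score is generated from the subject's ground-truth
  DMN integration and FW with configurable slopes.
* **The planted-mediation regime** (`CohortConfig.cadasil_like()`) sets
  latent paths (FW→DMN −0.05 per SD, integration→TMT-B +0.65, direct
  −0.2, outcome noise 0.6) sized so that, *after* estimation noise at the
  simulated scan length, the measured associations sit where the
  cross-sectional analysis operates (|standardized beta| ≈ 0.45–0.55).
  The latent total effect is necessarily stronger (≈ −0.7) than its
  measured counterpart.
* **Serial designs.**  Metric values are subject mean + visit noise with
  a configurable between/within variance ratio (ICC ground truth =
  ratio/(1+ratio)); optional within-SD inflation with age emulates higher
  across-visit variability in older subjects.  Serial FW has a stable
  subject level (between-SD 0.03), small visit noise (0.0033) and a slow
  common drift (1.7e-4 per day).  Note the drift itself contributes to
  the one-way within-subject variance, so the serial-FW ICC computed on
  raw values (~0.85) is lower than the no-drift variance ratio would
  suggest.
* Everything is reproducible from (config, seed); ground-truth parameters
  are echoed back so calibration tests need no hidden state.

What the generator does **not** emulate: spatial structure (no images,
lesions or registration errors), hemodynamic/neurovascular coupling,
non-Gaussian BOLD features, scanner drift beyond a linear trend, and any
dependence between motion and disease burden.  Passing tests therefore
establish the *statistical machinery* — estimator correctness,
calibration, planted-effect recovery — not claims about real patient
data.

## Problem sizes

Simulation-based tests run at deliberately reduced scale, chosen once:
a 100-node five-system atlas, TR 2.0 s with 165 volumes (330 s acquired,
so the 300 s duration gate is still live), 41 subjects cross-sectionally
and 44 × 8 serially; 200 end-to-end replicates, 500/200 mixed-model
cohorts, 1,000 mediation datasets with 2,000 bootstrap draws (scaled down
from the 50,000 used for a single confirmatory analysis).  These sizes
keep the whole suite to minutes on one CPU while leaving the Monte-Carlo
error well inside the asserted tolerance bands.

## Known limitations

* The mediation p-value is percentile-bootstrap; lavaan-style
  delta-method p-values on the bootstrap SE are emitted for comparison
  but not used for the gate.
* The mixed-model p-value is a between-within Wald t, not Satterthwaite;
  at very small subject counts it may be mildly anti-conservative.
* The ICC confidence interval assumes the one-way F distribution; no
  small-sample correction beyond that.
* Proportional thresholding with heavy ties (constant matrices) is
  deterministic but arbitrary in which tied edges it keeps.
* The packaged atlas partition reproduces system sizes, not node-level
  identities; analyses that depend on *which* specific nodes are in a
  system (e.g. spatial plots) should supply their own atlas table.
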