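# Methods

`connectoflex` implements a computational chain linking the rigid topology of
structural brain networks to the flexible dynamics of functional networks:
static participation coefficients on both modalities, a hierarchical
boundary-controllability heuristic on the structural connectome, signed
multilayer modularity and flexibility on windowed functional connectivity,
and the statistical machinery (spin tests, covariate-adjusted regression,
FDR, bootstrap serial mediation) that relates the four nodal markers.
Everything is exercised end-to-end on synthetic cohorts with known ground
truth.

## Network metrics

**Participation coefficient.** For node *i* under a module partition with
modules *s*,

    pc_i = 1 − Σ_s (l_si / d_i)²,

where `l_si` is *i*'s summed edge weight into module *s* and
`d_i = Σ_s l_si`. Both structural (nonnegative) and functional (signed
correlation) networks are fully weighted, so the "number of links" is
computed on strengths. For functional networks the default excludes
negative weights (`mode="positive_only"`): a negative affiliation has no
meaning in the squared-fraction form. A signed variant (`mode="all"`) is a
config switch. Isolated nodes score 0 with a logged warning rather than
aborting a cohort loop. Bounds: `0 ≤ pc_i ≤ 1 − 1/N_m`; the measure is
invariant to global weight rescaling and equivariant under node
permutation (property-tested).

**Boundary controllability.** Nodes are ranked by how early they appear on
inter-community boundaries during recursive partitioning. Level 0: every
node with at least one positive-weight edge crossing the initial partition
(by default the eight predefined functional systems) receives value 1.
Each community is then bisected — spectral sign split of the leading
eigenvector of the community's Newman modularity matrix, disconnected
communities split along components first, seeded random sides for zero
loadings — and nodes newly exposed on a within-community cut receive
`(N − C)/N`, where `N` is the total node count and `C` counts nodes already
valued ("cumulative" convention; values then decrease strictly with
depth). A "per_step" variant (count of boundary nodes at the current level
only) is available behind a switch but does not guarantee monotonicity, so
it is clamped to remain strictly decreasing. Recursion ends when all nodes
are valued or only singletons remain; stragglers get the smallest assigned
value minus `1/N`, floored at `1/N`. All values lie in `(0, 1]`.

**Temporal networks and flexibility.** The regional BOLD matrix (N×T) is
cut into nonoverlapping windows (default 10; remainder TRs discarded with
a warning; zero-variance regions are an error naming region and window).
Each window's Pearson correlation matrix is one layer. Partition quality
is the signed multilayer modularity

    Q = Σ_t Σ_ij [(A⁺_ijt − γP⁺_ijt) − (A⁻_ijt − γP⁻_ijt)] δ(g_it, g_jt)
        + Σ_{t=1}^{T_w−1} Σ_i ω δ(g_it, g_i,t+1),

with A⁺/A⁻ the positive/negative parts of each layer, P± the per-layer
Newman–Girvan null `k_i k_j / 2m` on the corresponding part (a part with
zero total weight contributes nothing), γ = ω = 1 by default. The
inter-layer sum runs to `T_w − 1`: couplings are ordinal and
nearest-neighbour only. Q is used unnormalized; only the argmax partition
matters downstream.

Maximization is Louvain-style on the supra representation (layer blocks on
the diagonal, ω/2 on the two symmetric coupling entries so ordered-pair
summation recovers ω per persistent label): seeded random sweep order,
moves only on strictly positive gain (ties go to the incumbent community),
aggregation, repeat. The engine's bookkeeping Q is tested to equal a
from-scratch evaluation of the definition to 1e−9, and to attain the
exhaustive-search optimum on all-label enumerations of 4-node, 2-layer
instances. Flexibility `f_i` is the fraction of adjacent window pairs in
which node *i* changes community label, averaged across optimization
restarts (the library default is 100 restarts; cohort-scale analyses in
the tests and acceptance script use 3–10, which reproduce the same
detection outcomes at a fraction of the cost).

## Statistics

* **Spin test.** Spatial-permutation null for the correlation of two
  cortical maps. Each hemisphere's coordinates live on their own full unit
  sphere (the surface-registration convention). Per permutation one
  Haar-uniform rotation is drawn (QR of a Gaussian matrix, sign-fixed),
  applied to the left hemisphere and its x-mirror to the right, and the
  map is re-assigned by *optimal one-to-one* matching on cosine similarity
  (Hungarian algorithm). One-to-one matching preserves the permuted map's
  variance; many-to-one nearest-neighbour assignment shrinks it and makes
  the test anticonservative (we measured type-I ≈ 0.13 with
  nearest-neighbour vs ≈ 0.06 with matching at α = 0.05 on smooth-map
  pairs). p is two-tailed on |r| with the +1 correction; non-cortical
  nodes never enter. Default 100,000 permutations (tests use fewer).
* **Serial mediation.** Three nested OLS equations (M1 ~ X; M2 ~ X + M1;
  Y ~ X + M1 + M2, each optionally + covariates) plus the total-effect
  equation. Indirect effects a1·b1, a2·b2, a1·d21·b2 and their sum; the
  identity c = c′ + total indirect holds to 1e−8 by construction and is
  asserted. Percentile bootstrap over case resamples (default 10,000)
  gives CIs for all three indirect paths, their sum, and the direct and
  total effects; significance = CI excluding zero. X, M1, M2, Y can be
  rescaled to [0, 1] first (the mediation convention used throughout the
  pipeline); covariates are never rescaled.
* **Moderated mediation.** The moderator (age, centered) interacts with X
  on every X-originating path (a1, a2, c′); mediator-to-mediator and
  mediator-to-outcome paths are not X paths and stay unmoderated. The
  conditional serial indirect `(a1 + a1w·w)·d21·b2` and its bootstrap CI
  are reported at moderator mean ± 1 SD.
* **VIF, FDR, adjusted regression.** VIF_j = 1/(1 − R²_j) with an
  intercept, perfect collinearity reported as inf; Benjamini–Hochberg
  step-up via statsmodels; covariate-adjusted OLS reports the focal
  coefficient, t, p, and partial correlation `t/√(t² + dof)`. Exact fits
  (zero residual variance) are special-cased: the focal predictor's
  partial r is ±1 if it carries the signal and 0 with p = 1 if a covariate
  does.

## The synthetic cohort generator

The generator is the package's study design: it emulates a developmental
cohort (ages 8–22, binary sex, positive motion) whose four subject-level
markers follow a serial causal chain

    X (structural participation) → M1 (boundary controllability)
      → M2 (functional participation) → Y (flexibility).

Standardized latents follow the chain with path strengths
a1 = 0.8, d21 = 0.9, b2 = 0.9 (a2 = b1 = 0.15, c′ = 0.1) and disturbance
sd 0.8; standardized age loads on all four latents with weight −0.2
(developmental decline, removable by covariate adjustment). Each latent is
squashed to (0, 1) by the Gaussian CDF of its standardized value — every
knob sweeps its full response range regardless of path strengths — and
drives one generator knob:

| latent | knob | range | metric it controls |
|---|---|---|---|
| X | cross-module weight scale | 0.15–0.70 | structural PC |
| M1 | boundary breadth (fraction of nodes with any cross edge) | 0.50–0.90 | boundary controllability |
| M2 | window-1 global-signal mixing | 0.00–0.45 | functional PC (window 1) |
| Y | community switch rate ρ per window transition | 0.05–0.55 | flexibility (windows 2–10) |

Three design devices make the four knobs nearly orthogonal in their
effects, which is what makes the chain identifiable:

1. **Threshold vs magnitude.** Boundary membership is a threshold effect
   (any positive cross edge), participation a continuous one. Cross-module
   fractions follow a *geometric* schedule (0.02–1.0) with
   *multiplicative* coupling `w_ij ∝ f_i·f_j`, so the low-schedule nodes
   that the breadth knob silences carry almost no participation weight:
   breadth moves mean boundary controllability strongly while barely
   moving mean structural PC. The breadth range stays above 0.5 because
   below it mean BC is non-monotone in breadth under the cumulative
   convention (mean BC ≈ b + (1 − b)²).
2. **Window confinement.** The global-signal mixing that raises functional
   participation is planted only in window 1 — exactly the window the
   pipeline reads the static functional metric from — so it cannot
   interfere with the planted switching that drives flexibility in
   windows 2–10.
3. **Nodal profiles.** The functional knobs carry unit-mean nodal profiles
   following their own serial chain seeded by the structural schedule rank
   (rank → participation profile → switching profile, independent nodal
   disturbances). Regionally this plants the connector-hub cascade — nodes
   with more cross-module structure participate more and switch more —
   with identifiable serial structure rather than one deterministic common
   driver.

Edge weights are truncated normal on [0, 1] (mimicking fractional
anisotropy); BOLD is block-covariance white noise per window (community
signal + independent noise, sd 0.5), with no hemodynamics — the generator
reproduces the *statistical* structure the analysis assumes, not
biophysics. Consequences for interpretation: passing tests show the
pipeline recovers planted modular, hierarchical and dynamic structure and
planted causal chains at realistic noise; they say nothing about
tractography biases, autocorrelated BOLD, or spatial smoothness of real
metric maps (the spin-test calibration uses explicitly smoothed maps for
that reason).

**Problem sizes.** Defaults are desk-scale: 50 subjects, 60 nodes in 8
modules, T = 360 TRs in 10 nonoverlapping windows. Eight modules match the
predefined functional systems the boundary hierarchy starts from and also
average window-sampling noise over more module pairs. T = 360 (36-TR
windows) is the smallest scan length at which the window-1 functional PC
and flexibility track their knobs with reliability ≈ 0.90/0.95; at
T = 120 (12-TR windows) both saturate near 0.8 and subject-level power for
the full serial chain is capped around 55%. Heavy analyses scale down
`n_runs` (3) and `n_boot` (600–2,000) from the library defaults (100 and
10,000); we verified the scaled and full settings give identical detection
outcomes on the same cohorts.

## Pipeline tracks

Per subject: structural PC and boundary controllability from the
connectome and the predefined partition; functional PC from window 1
only; flexibility from multilayer community detection on windows 2–10.
Computing the static functional marker strictly before the dynamic one
builds temporal directionality into the mediation; a sensitivity mode
(`temporal_split="all_windows"`) computes both from all windows.

* **Region-wide**: nodal maps averaged across subjects; Pearson r for all
  six metric pairs with spin-test p for the within-modality pairs; VIF
  checks; serial mediation across regions with [0, 1] rescaling and no
  covariates.
* **Subject-wide**: per-subject global means; six pairwise regressions
  adjusted for age, sex and motion in one Benjamini–Hochberg family;
  covariate-adjusted serial mediation; age-moderated mediation (sex and
  motion still covariates).
* **Developmental**: each global metric regressed on age with sex and
  motion partialled out; FDR over the four tests; signed partial
  correlations.

Every report echoes its full configuration; rerunning with the same
config and seed reproduces outputs exactly (spawned `SeedSequence` streams
throughout).

## Measured operating characteristics

Computed by the test suite and `scripts/acceptance.py`, not asserted from
theory: spin-test type-I error ≈ 0.04–0.06 at α = 0.05 on smooth-map
pairs; null-mediation serial-indirect false-positive rate ≤ 5% at nominal
95% CIs; planted-switcher flexibility exceeds non-switchers in ≈ 100% of
seeds; the planted subject-level serial chain is detected (serial-indirect
CI excluding 0, covariate-adjusted, n = 50) in about 80% of cohort
replicates, and never on null-chain cohorts. The 80% reflects a real
ceiling: the latent chain is significant in every failing replicate, but
measurement attenuation — chiefly the single 36-TR window behind the
functional-PC marker — bounds what any estimator can recover at this
sample size; a Monte Carlo at the measured marker reliabilities puts the
best attainable power near 93% and the implemented effect-size design is
the optimum of that scan.

## Known limitations

* Boundary controllability depends on the bisection heuristic; spectral
  bisection is deterministic and testable but not the only reasonable
  choice, and the original heuristic's hierarchy procedure is
  under-specified (within-community re-identification and the cumulative
  count convention are this package's choices, both switchable).
* The BOLD generator has no temporal autocorrelation within windows, so
  effective sample sizes per window are optimistic relative to real fMRI.
* Regional mediation at 60 nodes is under-powered for per-cohort CI
  claims (the cascade is reliably positive; significance stabilizes from
  roughly 120 nodes × 30 subjects).
* The spin test assumes each hemisphere's nodes are registered to a full
  sphere; maps sampled on a half-sphere geometry will be anticonservative.
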