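# Methods

## The model

`mlgmsim` studies a two-level (multilevel) latent growth model (MLGM) for
repeated measures on individuals nested in groups — the canonical example
being achievement scores of students nested in schools, observed at T = 5
waves. Writing `y_gi` for the T-vector of individual *i* in group *g*,

    y_gi = (Λ η_B,g + ε_B,g) + (Λ η_W,gi + ε_W,gi),

where `Λ` is the T × q polynomial growth-basis matrix (column k equals the
wave time codes raised to the power k − 1; q = 3 for quadratic growth),
`η_B,g ~ N(α_B, Φ_B)` and `ε_B,g ~ N(0, diag θ_B)` are the group-level
growth factors and wave residuals, and `η_W,gi ~ N(0, Φ_W)`,
`ε_W,gi ~ N(0, diag θ_W)` their individual-level counterparts. All observed
means are carried at the group level. The implied moments are

    μ = Λ α_B,   Σ_W = Λ Φ_W Λ' + diag θ_W,   Σ_B = Λ Φ_B Λ' + diag θ_B.

The default population parameters are calibrated to a longitudinal study of
adolescent achievement (score units; intercept/linear/quadratic factors):

    α_B = (49.96, 4.32, −0.13)
    Φ_B = [[16.2, 2.82, 0], [2.82, 0.61, 0], [0, 0, 0.02]]
    Φ_W = [[71.45, 6.76, 0], [6.76, 14.76, 0], [0, 0, 0.07]]
    θ_B = (11.91, 15.25, 10.32, 12.59, 1.93)
    θ_W = (1.80, 1.28, 0.06, 0.54, 0.31)

Wave time codes default to 0, 1, 2, 3, 4 (integer coding, the convention of
the simulation literature this design follows; configurable). Under these
values the implied intraclass correlations run from about 0.13 to 0.28
across waves, so the group level cannot be ignored.

## Study design

The Monte Carlo grid crosses the number of groups NG ∈ {50, 100, 200} with
three *unbalanced* group-size (GS) conditions 5/15, 10/30 and 25/75: exactly
half the groups take the small size and half the large, with
large = 3 × small. That ratio fixes the coefficient of variation of cluster
sizes at exactly 0.5 — a moderate, constant degree of imbalance — and gives
per-cell totals N from 500 to 10,000. The reference design uses 1,000
replications per cell; the reproduction scripts in this package use 200 per
cell so the full grid runs in minutes on one CPU (Monte Carlo standard
errors are reported alongside; e.g. the mean of a χ²₄-distributed statistic
is then estimated to ±0.2).

The generator draws group components `b_g = Λη_B + ε_B` once per group and
adds independent individual components per member; it is vectorized and
deterministic given a seed. Replication r of condition c uses the
counter-based child seed `SeedSequence(root, spawn_key=(c, r))`, so any
single replication can be reproduced in isolation (`mlgm replay`).

What the generator does *not* emulate: non-normal outcomes, missing waves,
more than two size classes, or group-size/outcome dependence. Passing tests
therefore speak to the behaviour of fit indices under exact normality and
the stated design, not to robustness against those violations.

## Estimation

For a cluster of size n the stacked outcome vector is normal with mean
`1 ⊗ μ` and covariance `I ⊗ Σ_W + J ⊗ Σ_B`. The log-likelihood separates
into a pooled within-cluster part and a cluster-mean part with covariance
`V_n = Σ_B + Σ_W/n`, so the data enter only through the pooled within
scatter and, per distinct cluster size, the count, mean and scatter of the
cluster means. With two size classes each likelihood evaluation is a handful
of 5 × 5 operations regardless of N. A brute-force evaluator that builds the
Kronecker covariance explicitly serves as the test oracle (agreement to
1e-8 on small instances is asserted).

Analysis models are *templates*: each of (within covariance, between
covariance, mean vector) is saturated, growth-structured, or an
independence/equal-means baseline. Free-parameter counts and degrees of
freedom follow from the block modes; the saturated reference has
2·T(T+1)/2 + T = 35 parameters and the two partially saturated models have
df = 4. Structured blocks free the full q(q+1)/2 covariance matrix Φ —
including elements the population sets to zero — which is the only counting
consistent with df = 4 and makes the partially saturated models correctly
specified.

Every template is a linear covariance structure, so the primary optimizer is
**Fisher scoring with the exact expected information** (a Wishart term on
Σ_W with N − G degrees of freedom plus a normal term per size class on
V_d), started from moment estimates: S_PW for Σ_W, the PSD-projected
between mean square minus S_PW/n̄ for Σ_B, the weighted grand mean for μ.
Scoring typically converges in 1–10 iterations.

The parameter space is defined by the *assembled* matrices: Σ_W positive
definite and Σ_B positive semidefinite, for every template. This puts all
models on one feasible set, so likelihood-ratio deviances between nested
templates remain χ²-calibrated; individual structured-block parameters are
otherwise free, and Heywood solutions surface as negative residual-variance
estimates with Σ_B exactly on the PSD boundary (the convention of standard
SEM software). Scoring preserves feasibility by step-halving with a
second-order correction that pushes a slightly negative eigenvalue back to
the boundary; on an active face it takes equality-constrained
(KKT-system) steps, and a boundary solution counts as converged only when
the gradient projected onto feasible directions falls below the tolerance.
The rare fit scoring cannot finish falls back to L-BFGS-B on a
log-Cholesky parameterization plus a modified-Newton polish; the better
admissible solution is kept, with a 5·10⁻³ log-likelihood guard against
the log-Cholesky parameterization's spurious rank-deficient stationary
points.

Numerical knobs (all in `OptimOptions`): convergence is sup-norm of the
gradient of the per-observation deviance (−2·loglik/N) below `tol = 1e-5`;
iteration cap 500 with one ×1.1-jittered restart; variance floors 1e-4 when
projecting moment starts. Plain ML is used throughout: the simulated data
are exactly multivariate normal, so robust (sandwich/scaled) corrections
would converge to the plain-ML quantities that the study's outcomes use.

## Fit indices

For each comparison the deviance χ² = 2(loglik_saturated − loglik_model) is
referred to χ² on the parameter-count difference. Derived indices use the
conventional formulas:

* RMSEA = √(max(χ² − df, 0)/(df · N)) with N the **total individual
  count** for every index; using the group count instead would inflate the
  between-side RMSEA an order of magnitude beyond the reference values.
* CFI = 1 − max(χ² − df, 0)/max(χ²_base − df_base, χ² − df, 0), clamped to
  [0, 1]; TLI = ((χ²_b/df_b) − (χ²/df))/((χ²_b/df_b) − 1), stored
  unclamped (values above 1 occur by construction).
* SRMR at a level = RMS of the standardized residuals between the saturated
  model's covariance estimate at that level and the hypothesized model's
  implied matrix, standardized by the saturated variances, over the
  T(T+1)/2 unique elements. Mean residuals are excluded at the between
  level because the partially saturated between model carries saturated
  means (they vanish identically).

Baselines for CFI/TLI are a design choice (no reference definition exists
for the level-specific case): the level-specific baseline keeps the other
level saturated and restricts the target level's covariance to a diagonal
(independence) structure, df = 10; the mean-structure baseline is the
equal-means model, df = 4.

Target-specific (TS) comparisons follow the literal construction — TS_COV
(between covariance structured, means and within saturated) coincides with
the between partially-saturated model and is stored under both names;
TS_MEAN structures only the mean vector (μ = Λα, df = 2). Because the
reference tables report TS statistics that grow with total sample size —
impossible for these correctly specified templates — a probe variant
(`ts_variant="diagonal_growth"`) is provided in which TS templates keep the
hypothesized within-level growth structure and fix all growth-factor
covariances to zero. Against the default population (which has nonzero
intercept–linear covariances 2.82 and 6.76) these templates are
deliberately misspecified and reproduce the qualitative growth of TS χ²
with N. No TS number is treated as a quantitative target.

## Summaries and ANOVA

Per cell and index, the study reports the mean and sample SD (divisor
n − 1) over converged replications, and per-cell convergence rates. The
sensitivity analysis is a two-factor fixed-effects ANOVA per index with
η²_f = SS_f/SS_total for the NG main effect, the GS main effect and their
interaction; with equal cell counts the design is orthogonal and the sums
of squares are computed directly from cell means (Type I = Type III), with
a sum-coded Type III OLS fallback (statsmodels) for unbalanced tables. A
factor is flagged practically influential when η² ≥ 0.0588 unless the
index's pooled SD falls below 0.005 (the low-variability override; the
threshold is a configurable choice — the reference only says "close to 0").

## Known limitations

* The between-level slope and quadratic factor variances (0.61 and 0.02)
  are weakly identified at these designs: their per-replication sampling
  SDs at NG=200/GS=25/75 are several times the parameter values. Point
  recovery is only meaningful for the intercept variances.
* Between-level SRMR under this construction has magnitude
  ≈ √(2·df/(G · T(T+1)/2)) — a few hundredths at G = 200 — because the
  saturated between estimate carries cluster-level noise. Reference values
  an order of magnitude smaller (and scaling with total N) cannot be
  produced by any saturated-vs-structured between-covariance contrast; see
  the discussion above on index constructions that the reference tables do
  not pin down.
* Deviances are exactly χ²-calibrated at fixed G across group-size
  conditions; gradients of the between-side χ² with total N reported
  elsewhere are not reproduced by plain ML on correctly specified data.
* Runtimes: the full 9-cell grid at 200 replications per cell takes
  about four minutes on one CPU; the problem sizes used by the shipped
  scripts were chosen so a desk-scale reproduction completes comfortably.
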