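# Methods

## Design and data model

The framework targets a nested full-sibling design: K families (pair
spawns), each assigned to exactly one exposure environment, with n_k
individuals measured per family. Two endpoint layers share the same
family structure: a behavioral endpoint (one number per larva) and
per-gene normalized expression (one number per larva and gene). Sample
metadata carries a boolean exclusion flag (death or abnormal morphology
at screening); excluded individuals are dropped before any endpoint is
computed, never imputed.

Because each family sits in a single environment, the family main effect
and the family-by-exposure interaction are not separated by design — only
by the heteroscedasticity pattern they imply (see *Identifiability*
below). A crossed design (families split across environments) is
accepted by the data model but flagged, since the analyses interpret the
family blocks differently.

## Behavioral endpoint

The photomotor assay runs `n_cycles` (default 4) cycles of
`phase_seconds` (default 180 s) light then dark, with locomotion
integrated over `bin_seconds` (default 6 s) bins — 240 bins in 24 min.
Bins are half-open `[t, t + 6)` intervals assigned to the phase
containing their start time. The endpoint is the summed dark-phase
distance over cycles 2..n; the whole first cycle is treated as
acclimation and discarded. Light-phase totals are computed but unused.
Traces with missing or surplus bins are an error (fail-fast): gaps are a
hardware/QC problem that imputation would silently hide.

## One-way REML and the ICC

Within one environment the model is `Y = μ + S_k + E`, and the ICC
`σ²_S/(σ²_S+σ²_E)` is the full-sib resemblance. The REML criterion is
profiled down to one dimension: for a given ratio λ = σ²_S/σ²_E the GLS
mean and σ²_E have closed forms from per-family sufficient statistics
(size, sum, sum of squares), and λ is found by bounded scalar
minimization on [0, 1e6] (absolute tolerance 1e-10). The ANOVA moment
estimator (σ̂²_E = MSW, σ̂²_S = max(0, (MSB − MSW)/n₀) with the standard
unbalanced n₀) is always evaluated as a candidate: on balanced designs
with MSB ≥ MSW it is the exact REML optimum, and near-flat criteria are
resolved toward it when the criterion values tie within 1e-9.

Degenerate inputs are graded: a constant response is an error (σ²_E
unidentifiable); zero within-family variance with distinct family means
returns ICC = 1 with a `degenerate` flag, because per-gene scans meet
near-constant genes routinely and must not abort. Negative moment
estimates truncate to zero, so ICC ∈ [0, 1] always.

## Interaction LMM

The cross-environment model adds a fixed exposure slope and two random
terms: `y = μ + α x + b_k + c_k x + ε` with b, c, ε independent normals.
The exposure code x is configurable — concentration in µM (0 / 16.4 /
74.8), ordinal (0/1/2), or a `cell` variant in which the interaction is
an effect per family-exposure cell rather than a slope. Intercept and
slope are uncorrelated by construction; under nesting a covariance would
not be identifiable anyway.

REML again reduces to per-family sufficient statistics: the marginal
covariance of family k is σ²_E(I + a_k J) with
a_k = θ²_G + θ²_GxE x_k² (θ = SD relative to residual SD), so each
criterion evaluation is O(K) with hand-rolled 2×2 GLS algebra. The
primary fit minimizes the profiled criterion by Nelder–Mead from the
3×3 start grid θ ∈ {0.1, 1, 10}², plus bounded 1-D profiles along each
axis and the origin as explicit candidates; a boundary candidate within
1e-6 of the best interior value wins, so null components are reported as
exactly zero. Bootstrap refits use a cheaper but equivalent route:
bounded L-BFGS-B on (θ²_G, θ²_GxE) with the analytic gradient of the
profiled criterion, started from the data-generating estimates and one
default point, with the same boundary candidates. The two optimizers
were cross-checked to agree to optimizer precision on datasets spanning
null to strong interaction.

### Identifiability

With families nested in exposures, σ²_G and σ²_GxE are separated only by
how family-level variance grows with x² across exposure groups. The fit
warns when x² is constant across families (no leverage). A practical
consequence, visible in the power simulations: a large family-intercept
variance erodes power to detect the interaction, because boundary
refits can reallocate slope variance to the intercept.

## Parametric bootstrap test

Significance of σ²_GxE follows the CI-excludes-zero rule: simulate
`n_boot` datasets from the fitted model on the original design (fresh
b*, c*, ε* at the fitted variances), refit each, and take the percentile
interval of the refit σ̂²_GxE at the requested level (default 95%,
`n_boot` default 1000). A percentile interval was chosen over BCa
because the parameter sits on a boundary, where BCa's bias and
acceleration corrections are fragile. Failed refits are replaced by
fresh draws up to 2·n_boot total attempts and their count surfaced; more
than 50% failures aborts as model instability.

Exact zeros matter here: because boundary fits return σ̂²_GxE = 0
identically, the lower percentile is exactly zero whenever ≥ 2.5% of
replicates hit the boundary, and the test is conservative rather than
anti-conservative under the null (measured type-I ≈ 0.01–0.04 at nominal
0.05 on the 12-family design).

## Expression scan

Counts are filtered by the permissive low-expression rule — a gene
survives if some treatment group has ≥ `min_frac` (default 25%) of its
samples at count ≥ `min_count` (default 20) and it is nonzero somewhere;
a strict any-group variant is a flag. Normalization is log2-CPM with a
pseudocount of 1 by default; plain CPM and median-of-ratios size factors
are available. The per-gene ICC table, the paired Wilcoxon signed-rank
comparison between environments (exact null up to 25 effective pairs,
normal approximation with continuity correction beyond, zeros
discarded), and the per-gene bootstrap scan all run on that normalized
matrix. Per-gene scan seeds derive from the master seed and the gene ID
(not position), so results are order-invariant and reproducible gene by
gene; genes whose base fit fails (e.g. constant after normalization) are
reported `unfit`, never significant.

The global apportionment treats one environment's full matrix as a long
vector with crossed random gene and family effects. Every sample
measures every gene, so cell frequencies are proportional and the
two-way additive sums of squares are orthogonal; Henderson Method III
reduces to three moment equations,

    E[SS_gene]   = (G−1)(S·σ²_gene + σ²_E)
    E[SS_family] = (J−1)σ²_E + G(S − Σs_j²/S)·σ²_family
    E[SS_resid]  = (N−G−J+1)·σ²_E,

solved directly and truncated at zero. A REML option (statsmodels
variance components) exists for small instances and doubles as the
cross-check in the tests (agreement within 5% on a 60-gene slice).

## Synthetic data

The generator is the package's stand-in for the unavailable raw study
data and mirrors the design sizes: 3 environments × 4 families, 35–48
larvae per family for behavior (per the post-QC design table), 6 per
family (72 samples) for expression. Behavioral endpoints follow the
interaction LMM exactly. Traces are gamma-distributed per bin with a
higher dark than light activity level and, by default, are rescaled so
the extracted endpoint reproduces each individual's phenotype value
exactly — endpoint tests are therefore exact round trips; a free-running
mode skips the rescale. Counts are negative binomial
(variance = µ + φµ², φ default 0.1) with log-normal library sizes
(median 1e6) and normal log-scale baselines; effect genes partition into
a family-intercept class and a GxE-slope class with per-(gene, family)
draws. `gxe_sd_relative` pins each true gene's slope SD to a multiple of
its own log-scale residual SD (delta method), making effect strength
uniform on the analysis scale. Assignment of effect genes is the first
⌊frac·G⌋ positions of a seeded shuffle, so truth labels are reproducible.

What the generator does not emulate: count outliers and batch effects,
gene–gene correlation, exposure main effects on expression, morphology
endpoints beyond a Bernoulli exclusion flag, and within-trace temporal
autocorrelation beyond the light/dark contrast. Passing tests therefore
demonstrate correct estimator behavior under the assumed model, not
robustness to those real-data features.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script are desk scale,
chosen to exercise the claims at useful Monte-Carlo precision: bootstrap
calibration uses 100–200 datasets at n_boot = 200 (scaled from the
production default of 1000), the scan benchmark 300–500 genes, and ICC
recovery 200 families × 40. Master seeds fan out to stages and genes via
SHA-256-based child seeds below 2³¹. All file formats are plain text
(TSV, MatrixMarket, YAML, JSON); result tables render floats at 6
significant digits with NA for missing, sorted by ID for determinism.

## Known limitations

* Under nesting, σ²_G and σ²_GxE separate only through the x²
  heteroscedasticity pattern; with 4 families per environment the
  bootstrap test has limited power at effect sizes below roughly
  2–4× the residual variance, and realizations at the published
  behavioral effect size are called significant only some of the time.
* The per-gene scan inherits Gaussian-residual assumptions on log2-CPM
  values; very low-count genes violate them most, which the count filter
  only partly mitigates.
* The "significant gene" count is a CI-excludes-zero rule with no
  multiplicity control by design; a BH layer is deliberately not part of
  the scan's contract, which is the per-gene CI rule.
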