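# Methods

## The pairwise model

Each (expression probeset, methylation probe) pair of a gene is modeled by

    y_i = b0 + b1 * x_i + b2 * ER_i + b3[subtype_i] + e_i,   e_i ~ N(0, s^2),

over i = 1..40 cell lines, where `y` is RMA-style log2 expression, `x` the
probe's M-value, ER status and tumor subtype treatment-coded indicators
(references ER- and Luminal).  The fit is ordinary least squares
(statsmodels); the reported `beta1_p` is by default the marginal (partial)
two-sided t-test of b1 from the full model, i.e. adjusted for ER and
subtype.  A sequential alternative (`anova="sequential"`) computes the
Type I F-test for methylation entered first — SS(meth | intercept) against
the full model's residual mean square.  The marginal test is the default
because a sequential test with methylation first does *not* adjust the
methylation sum of squares for the covariates, which contradicts the point
of including them; for balanced, orthogonal designs the two coincide.

Degenerate designs are detected before testing and flagged rather than
fitted through: fewer usable samples than coefficients, rank deficiency
(constant methylation, collinear covariates), and perfect fits (residual
sum of squares at numerical zero, tolerance 1e-10 relative).  Coefficients
are still reported when the design has full rank; the p-value is left
unset.  Missing values are handled by pairwise deletion per pair, with the
per-pair sample count recorded.  Phenotype levels absent from the cohort
drop their indicator column (reduced design) instead of erroring; when the
subtype reference level (Luminal) itself is absent, the first present
level takes its place — any full-rank coding leaves the b1 inference
unchanged, which is all that is reported.

Probesets are screened for normality with the Shapiro-Wilk test before
pair enumeration; the default excludes on raw p < 0.05 (a
Benjamini-Hochberg-adjusted variant is available).  Probesets with fewer
than three values cannot be tested and are excluded with a logged reason;
constant probesets are treated as non-normal.

## Gene-level aggregation

All threshold comparisons are strict ("more than"), so exact-boundary
cases fail:

* length class: long iff m > 2 probesets or n > 20 probes (annotation
  counts, before the normality screen);
* significant-pair fraction: > 15% for long genes, > 30% for short ones,
  counted over non-degenerate pairs only — degenerate pairs are excluded
  from numerator *and* denominator (counting them in the denominator would
  silently dilute fractions; their count is reported so the choice is
  auditable);
* direction: positive (negative) iff strictly more than half of the
  non-degenerate pairs have b1 > 0 (< 0); a coefficient of exactly zero
  counts for neither side;
* large-coefficient filters: pairs with b1 > c (or < -c) and p < 0.05 for
  c in {0.5, 1.0}, reported as pair counts and unique-gene sets;
* final lists: merged long+short significant lists intersected with the
  c = 0.5 large-coefficient gene sets, per sign.

Every cutoff (2, 20, 15%, 30%, 0.5, 1.0, alpha = 0.05) is a configuration
key with these values as defaults.

## Hyper-/hypomethylation calls

Per probe, a two-sided one-sample t-test of the mean M-value against zero;
hyper iff mean > 0 and p < 0.05, hypo iff mean < 0 and p < 0.05, N/A
otherwise.  The test is two-sided because the sign gate supplies the
direction; a one-sided test would only rescale p.  Zero-variance probes or
probes with fewer than two values are degenerate N/A calls, flagged
separately.  Per-gene percentages are rounded half-up to two decimals
(e.g. 24/41 -> 58.54).  A gene is "majority hypermethylated" when its
hyper probes strictly outnumber hypo and N/A combined.  Probesets whose
maximum expression across samples sits strictly below 8 — the level at or
above which housekeeping genes sit on this scale — are flagged as
low-expressed.

## Hub identification

Interaction networks are consumed as exported edge lists (undirected,
canonicalized node order, self-loops dropped, optional filters on
interaction type and confidence), never fetched from a live service.
Nodes absent from the input gene list are intermediates and remain
hub-eligible.  Hubs are defined reproducibly rather than by visual
inspection: `top_k` (default k = 8) keeps the k highest-degree nodes
including every node tied with the k-th degree (dropping an arbitrary tied
node would make the result order-dependent); `degree_min` keeps all nodes
at or above a degree floor.  The full degree table is always emitted so
users can apply their own judgment.

## The synthetic-data generator

`generate_dataset` emulates the shape of the 40-cell-line study: ER
assigned Bernoulli(0.5), subtype uniform over three levels, per-gene m
probesets and n probes drawn from configurable intervals.  For gene g,
probe p, sample s:

    x[p, s] = mu_g + e[p, s],        e ~ N(0, meth_sd^2), equicorrelation rho
    y[k, s] = b0_k + b1_g * mean_p x[p, s] + b2 * ER_s + b3[subtype_s] + N(0, sigma^2)

with `mu_g` uniform on `meth_mu_range` and `b0_k` uniform on
`beta0_range`; expression is clipped to [2, 13.5] (clipping events are
counted and kept rare under the defaults — resampling instead of clipping
would distort the error distribution).  Equicorrelation rather than an
autoregressive structure is used for optional probe dependence: observed
inter-probe correlations on these arrays are weak (roughly -0.3..0.3) and
show no usable spatial model.  Negative rho is supported down to the
equicorrelation bound -1/(n-1) via an explicit covariance factorization.

Coupling expression to the *across-probe mean* methylation makes a gene's
m x n pairs correlated — some but not all pairs of a truly associated gene
reach significance, as in real probe-level data.  The flip side is
attenuation: a single-probe regression estimates
`b1 * (rho + (1 - rho) / n)`, not `b1`.  The default configuration is
therefore the identifiable one-probeset x one-probe design (100 genes, 30
positive / 30 negative / 40 null, |b1| = 1, sigma = 1, meth_sd = 1.5,
baselines in [7, 8]), where the fitted model equals the generative model
and coefficient recovery is meaningful; multi-probe shapes are requested
explicitly (the demonstration study in `analysis/` uses m in 1..3, n in
2..30, rho = 0.3 and |b1| = 2, chosen so that truly associated genes still
clear the |b1| > 0.5 filter at realistic probe counts).  Effect sizes are
not claimed to be realistic — no effect-size distribution is available for
real genes — they are chosen for clear power separation and are fully
config-exposed.

What the generator does **not** emulate: array spatial artifacts, dye
bias, batch effects, genomic probe coordinates, or region-varying spatial
correlation.  Passing tests on synthetic data therefore demonstrate the
statistical machinery (calibration, adjustment, aggregation, determinism),
not robustness to those real-data pathologies.

## Calibration and recovery studies

`methexpr.experiments` fixes the evaluation conditions shared by the
analysis drivers, the test suite, and `scripts/acceptance.py`:

* **Null calibration** — 5000 null genes of one pair each, so the 5000
  beta1 p-values are mutually independent and a Kolmogorov-Smirnov
  uniformity test is valid (pairs within a multi-probe gene share the
  response and are weakly dependent).  The normality screen is not applied
  here: conditioning on a statistic of the response would perturb the
  exact null law of the p-values.
* **Covariate adjustment** — the same design with a pure ER effect
  (b2 = 2, b1 = 0) injected; the empirical size of the b1 test must stay
  at the nominal level.
* **Recovery** — the default 100-gene study through the full pipeline;
  scored by per-group mean b1 estimate, the fraction of true-effect genes
  entering the correct final list (denominator includes genes lost to the
  normality screen, which removes about 5% of normal probesets by
  construction), the wrong-direction rate, and a 3x3 confusion matrix of
  true versus called direction (called = majority direction when the
  significant-fraction threshold is passed, else null).

Problem sizes (5000 pairs, 100 genes, 40 samples) keep each study within
tens of seconds while leaving Monte-Carlo error well inside the assessed
tolerances (the binomial standard error of the type-I rate at 5000 pairs
is about 0.003 against an assessed band of 0.040-0.060).

## Numerical and reproducibility choices

All randomness flows from a single integer seed through numpy's
`default_rng`/`SeedSequence`; reruns with the same configuration and seed
produce byte-identical result tables (fixed float format `%.10g`, "NA" for
missing, deterministic lexicographic output order).  The run manifest
records the configuration, seed, library versions, per-stage wall times,
and the filter-count audit table.  File formats are TSV (CSV by
extension), UTF-8, features as rows with sample IDs in the header;
phenotype vocabulary synonyms ("ER+", "Basal B") are normalized on read.

## Known limitations

* Probe-to-gene assignment is taken as given input; no distance rule or
  promoter definition is applied.
* No multiple-testing correction across pairs or genes: the method uses
  raw p < 0.05 throughout, by design; the large-coefficient and fraction
  filters — not FDR control — provide the stringency.
* Hypermethylation is defined against zero M-value, not against
  normal-tissue controls (none exist in this design).
* Spatially correlated probe models, mixed models, and robust regression
  are out of scope; the equicorrelation option is a coarse stand-in for
  local dependence.
* The published headline gene counts depend on the original microarray
  data and are not recomputable from synthetic data; what the package
  reproduces exactly is the list arithmetic and the probe-percentage
  engine, and what it validates stochastically is calibration and
  recovery under known ground truth.
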