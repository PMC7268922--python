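# Methods

## Scope and model

`megalfc` implements individual-level cross-study pooling ("mega-analysis")
of case/control expression data. Each study contributes, per gene, a log2
fold change `y = mean(log2 expr | case) − mean(log2 expr | control)`. The
package treats these per-study effects with the standard two-stage
meta-analytic machinery:

* **Fixed-effect model** — one common true effect; inverse-variance weights
  `w_i = 1/se_i²`; pooled estimate `Σw_i y_i / Σw_i` with standard error
  `(Σw_i)^{-1/2}`.
* **Random-effects model (DerSimonian–Laird)** — study-specific true
  effects with between-study variance τ² estimated by the method of
  moments, `τ² = max(0, (Q − df)/C)`, `C = Σw − Σw²/Σw`, and re-weighting
  by `1/(se_i² + τ²)`.
* **Heterogeneity** — Cochran's `Q` with `df = k − 1`;
  `ISq = 100%·(Q − df)/Q` truncated at zero; `p–Q` the upper chi-square
  tail of Q at df (defined as 1 when k = 1). Heterogeneity statistics are
  always computed from the *fixed-effect* weights, whichever model is
  returned, so that ISq reporting is a property of the collection rather
  than of the model choice.
* **Model selection ("auto")** — ISq = 0 (equivalently Q ≤ df) selects the
  fixed-effect model; any positive ISq selects the random-effects model.
  This makes `model = fixed ⟺ ISq = 0` an exact invariant of auto mode.

Two-sided p-values for the pooled effect use the standard normal reference
(consistent with the magnitudes the procedure is designed to report, e.g.
p ≈ 1e−9 at k = 9); the 95% CI multiplier is Φ⁻¹(0.975) = 1.959964.

### Effect-size standard error

No single convention exists for the SE of a per-study LFC from raw arms;
the package uses the Welch two-sample form
`sqrt(s²_case/n_case + s²_ctrl/n_ctrl)` with unbiased per-arm variances,
isolated in one function (`megalfc.effects`). A floor of `1e−6` (log2
scale) guards degenerate zero-variance arms: it only ever binds on
pathological toy inputs and keeps meta-analytic weights finite. Shrunken or
moderated variance estimators are deliberately out of scope.

### Partial mega-analysis

For each gene independently, the `floor(k/2)` studies with the largest |y|
are re-pooled (at least one study when k = 1); 9 studies pool 4, 8 studies
pool 4. Ties on |y| break by smaller se, then lexicographic study id, so
the selected *set* is invariant to input order. This is a sensitivity
analysis: selection on |y| biases the pooled magnitude upward by
construction, so partial results are reported *alongside* full results,
never instead of them, and discordant genes (significant under one analysis
only) are surfaced rather than resolved.

### Significance filter

`p < 1e−7` and pooled LFC `> 0.49` or `< −0.74`, all strict. The asymmetric
gates are log2 of a 40% increase (log2 1.4 ≈ 0.485 → 0.49) and a 40%
decrease (log2 0.6 ≈ −0.737 → −0.74). The filter applies to the *pooled*
estimate of each analysis. No multiple-testing correction is applied at
this stage — the raw threshold is stringent by design; BH-FDR appears only
in the enrichment module. All thresholds are configurable
(`AnalysisConfig`, CLI flags, YAML).

## Gene sets

Overlap significance is the upper hypergeometric tail
`P(X ≥ n_overlap)` for draws of size |B| from a universe containing |A|
marked genes, computed with `scipy.stats.hypergeom.sf` (numerically stable
far below 1e−60; tests verify it against independent log-space
enumeration exhaustively for universes ≤ 60). The background universe is a
required, explicit parameter (default 20,000, roughly the protein-coding
gene count): overlap p-values are meaningless without it, and published
values that omit their background cannot — and should not — be reproduced
by tuning it. Enrichment is one-sided Fisher over-representation per GMT
term with BH adjustment over all tested terms (statsmodels
`multipletests`); ranked (Kolmogorov–Smirnov-style) GSEA is a non-goal.

## Moderator regression

Per gene, per-study effects are regressed on total sample size, study year
and region: OLS (optionally inverse-variance WLS) with treatment-coded
region dummies against the most frequent level. Region is tested as a whole
factor by the nested-model F-test; numeric moderators get t-based CIs with
residual degrees of freedom. Because region levels proliferate in small
collections, levels are merged through a configurable continent map when
there are more than 3 levels or any level holds a single study — but the
coarser grouping is only adopted when it actually reduces the level count
while keeping at least two levels (a two-level design with a singleton
level is estimable and must not be collapsed). Every merge is recorded in
the fit's design note. Designs with fewer than two residual degrees of
freedom beyond the parameters, or rank-deficient designs, are rejected with
an error naming the offending factor.

## Preprocessing

Expression matrices are auto-detected as linear-scale when the maximum
value exceeds 50 (log2 data essentially never exceed 50; linear intensities
routinely do), then transformed by `log2(x + 1)`; the threshold is logged
and can be overridden. Cross-sample normalization defaults to per-sample
median alignment (each sample shifted so medians agree, preserving
within-sample contrasts); quantile normalization and `none` are offered.
Both the log step and each normalization are idempotent. Genes with any
missing value are dropped per study (the simplest policy consistent with
per-gene study counts varying across the collection); duplicate gene rows
keep the row with the highest mean. Studies with fewer than 10 samples are
flagged, not rejected. Normalization matters for the validation design:
when a simulation plants a nonzero effect in *every* gene, global
normalization would absorb the shift, so recovery experiments run with
`normalization="none"`.

## Synthetic data generator

The generator emulates a collection of K independent case/control studies:
per-gene log2 baselines (default 7.0, a typical microarray log-intensity),
Gaussian within-arm noise with SD σ (default 0.5 on the log2 scale, a
realistic per-gene residual SD for expression arrays), planted per-gene
true log2 fold changes θ_g, and optional between-study heterogeneity — a
per-study deviation δ_gs ~ N(0, τ²_g) added to the case-arm shift. Matrices
are exported on the linear scale (2^x) so the pipeline's own transform is
exercised. Defaults mirror the reference nine-study collection the
pipeline was built around: nine studies with the published per-arm sizes
(controls 20, 6, 24, 9, 135, 6, 10, 27, 19; cases 18, 10, 30, 23, 22, 6,
10, 36, 16), regions drawn from its six source countries, years uniform on
2008–2016. Per-(gene, study) Bernoulli dropout exercises variable per-gene
study counts. Every study draws from an RNG stream keyed on (seed,
study index), so identical configs are bit-reproducible and studies are
independent of generation order. The planted truth (θ_g, τ²_g) is exported
alongside the data for recovery tests.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: probe-level microarray structure and
probe→gene collapsing, platform/batch effects, count-based (RNA-seq) noise,
correlated genes, and non-Gaussian heavy tails. Calibration and recovery
results certify the statistical machinery under its stated model, not
robustness to those violations.

## Numerical choices and problem sizes

* ISq truncation: `Q ≤ df` or `Q = 0` gives exactly 0 (no negative ISq).
* τ² truncation at 0 (statsmodels reports the untruncated moment estimate;
  the cross-check tests account for this).
* Validation problem sizes were chosen for statistical resolution: type-I
  calibration uses 2,000 null genes at K = 9, n = 15/15 (band
  [0.035, 0.065] ≈ ±3 binomial SD around 0.05); planted-effect recovery
  uses 500 genes at θ = 0.51, K = 9, n = 20/20, σ = 0.5; the moderator
  null calibration uses 1,000 genes so the same band is ≥ 2 binomial SD.
* Detection in the recovery setting counts a gene as found when *either*
  the full or the partial analysis passes the filter — the same
  disjunctive rule the reporting layer uses for discordant genes.
* QQ tables use plotting positions `(i − 0.5)/m`.

## Known limitations

* The per-study SE convention (Welch) is one of several defensible
  choices; rankings are insensitive but absolute p-values shift slightly
  under alternatives.
* DL is the only τ² estimator (no REML/Paule–Mandel, no Hartung–Knapp).
* The GEO series-matrix reader is best-effort and experimental: it parses
  the expression block and sample characteristics but leaves case/control
  assignment from free text to the caller.
* Mixed-effects meta-regression and moderator interactions are out of
  scope.
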