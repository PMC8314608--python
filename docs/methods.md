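# Methods

## The screening model

The pipeline treats target nomination as three nested filters over a log2
expression compendium of `G` genes measured in tumors and in a multi-tissue
normal reference, with matched patient follow-up:

1. **Overexpression.** For gene g, `FC_g = mean_tumor(g) − ref_normal(g)`,
   both on log2 scale, so FC is a log2 fold increase. The normal reference
   is either the pooled mean over all normal samples or (default) the mean
   of per-tissue means. The per-tissue default weights each tissue type
   equally and is robust to unbalanced compendium sampling; with balanced
   tissues the two coincide. Candidates are genes with `FC_g ≥ t` (inclusive
   cutoff, default t = 2 log2 units, i.e. 4-fold on the linear scale).
2. **Survival.** Per candidate, patients are dichotomized at the empirical
   quantile `q` of the gene's expression (linear-interpolation quantile;
   "high" is strictly greater than the cutoff, ties go to low). The two
   groups are compared with the two-group log-rank (Mantel–Haenszel)
   statistic `(Σ(O−E))² / ΣV` with the hypergeometric variance per event
   time (`V = d·(n₁/n)(1−n₁/n)(n−d)/(n−1)`, zero when only one subject is at
   risk), p from χ²₁. Ties of events and censorings at the same time are
   resolved events-first. Bonferroni multiplies each p by the number of
   genes *actually tested* m (candidates missing from the survival matrix
   or unstratifiable are reported untested, not failed). A gene passes iff
   adjusted p < α (default 0.05) and the high-expression group has more
   observed than expected events ("high worse") — the direction requirement
   is part of the screen, since the object is genes whose overexpression
   predicts poor outcome.
3. **Druggability.** Keep genes annotated with enzymatic function AND an
   available specific inhibitor AND pharmacokinetic data AND not already
   tested in the disease. Missing annotations count as not druggable (a
   warning lists the genes). Final ranking: adjusted p ascending, then fold
   increase descending, then gene id — the survival signal dominates.

The stratification percentile is an explicit policy: `fixed(q)` (default
q = 0.78, the exemplar reproduction cutoff) or `scan(grid)`, which reports
the minimum raw p over the grid per gene. Scan mode applies no within-gene
correction across grid points; its optimism is recorded in the result
metadata and should be treated as hypothesis-generating.

## Synthetic data: what it emulates, what it does not

Generators draw genes independently as Gaussians on the log2 scale
(`baseline_mean` 7, `baseline_sd` 1 by default — typical microarray
intensity scale), shift planted genes' tumor samples by `delta_log2`, and
tie survival to expression through an exponential event-time model: hazard
`h_i = h₀ · exp(Σ log HR · 1[x_ig > Q_g(q)])`, independent exponential
censoring plus administrative censoring at `max_followup`. This matches
exactly the step-function effect the screen tests (dichotomization at a
quantile), making planted hazard ratios directly recoverable. IRS scores
(intensity 0–3 × proportion 0–4, hence values {0,1,2,3,4,6,8,9,12}) are
produced by binning a latent risk score (standardized −log latent event
time mixed with unit noise at weight `association_strength`) into cohort
quartiles/quintiles, so strength 0 gives outcome-independent IRS.

Plates are 4PL viability curves
`y = bottom + (top − bottom)/(1 + (x/EC50)^h)` plus homoscedastic Gaussian
noise clipped to [0, 1.05] (slight super-control viability occurs on real
plates). Combination grids carry single-agent inhibition
(1 − viability/control) on the dose-0 margins and
`y_a + y_b − y_a·y_b + δ` in the interior, with δ the planted Bliss
deviation, clipped to [0, 1].

Not emulated: probe-level artifacts, batch effects, tissue-specific
covariance, gene–gene correlation in the compendium (the co-expression
analysis builds an explicit latent-factor module instead), non-proportional
hazards, informative censoring, and plate edge effects. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted effects under the assumed models — not robustness
to those real-data features.

## Canonical study conditions

The funnel scenario uses 200 genes, 250 tumors/patients, 10 normal tissues
× 15 samples; one planted target (+3 log2, hazard ratio 3 above its 78th
percentile, druggable), five overexpressed-only and three prognostic-only
distractors; baseline hazard 0.1/month, censoring 0.02/month, 120-month
administrative cap. These sizes give a stage-1 fold-estimate standard error
of ≈ 0.1 log2 units (so the ±2 cutoff is ≈ 10 SE away from null genes and
≈ 10 SE below the planted +3) and > 99% log-rank power for HR = 3 at a
22/78 split after Bonferroni over the ≈ 6–9 stage-1 candidates — chosen so
exact recovery is expected in ≥ 95% of seeds while the whole acceptance
suite runs in minutes on one CPU. Null calibration uses 500 replicates of a
200-gene screen over 100-patient cohorts; enrichment exactness sweeps all
universes of size ≤ 12 by literal subset enumeration.

## Pharmacology

* **4PL fitting** uses least squares on (bottom, top, log EC50, hill) with
  5 deterministic initializations (hill ∈ {0.5, 1, 2, −1} and shifted
  log-EC50 starts); best SSE wins, ties by first. The parameterization is
  canonicalized to bottom < top (swapping asymptotes and negating the slope
  leaves the curve invariant). Flat data returns `converged = False`.
* **Absolute IC50** is the dose where the fitted curve crosses 0.5 on the
  control-normalized scale — `EC50 · ((top − 0.5)/(0.5 − bottom))^{1/h}` —
  reported as "not reached" (None) when 0.5 is outside (bottom, top), never
  extrapolated. It equals the relative EC50 only when bottom = 0, top = 1;
  absolute IC50 is the comparison quantity across cell types with different
  floors.
* **Median-effect / CI.** `log(fa/(1−fa))` is regressed on `log d` (points
  with fa ∈ {0, 1} excluded, counted); `CI = d_a/Dx_a + d_b/Dx_b` with
  `Dx = Dm·(fa/(1−fa))^{1/m}` at each measured cell's observed effect, so
  non-constant-ratio designs are supported. The effect metric is inhibition
  (fraction affected); CI is invariant to a joint rescaling of
  concentration units.
* **ZIP delta.** Single-agent margins are fitted with a 0→1 logistic in
  log dose; each interior row/column is fitted with a logistic whose dose-0
  asymptote is pinned at the fitted single-agent effect of the other drug;
  per cell, delta = mean of the two directional fits minus the Bliss
  expectation of the fitted margins, ×100, so the ±10 interpretation
  thresholds apply directly. Rows/columns whose fit fails are excluded and
  counted. A grid whose interior equals the Bliss product of its own
  logistic margins scores exactly 0, because
  `y_b + (1−y_b)·logistic(x)` is itself of the pinned-logistic form.

## Numerical and design notes

* Log-rank, KM and Bonferroni are implemented in-package (vectorized
  numpy): the calibration simulations run ~10⁵ tests and the screen fixes
  conventions (events-first ties, n = 1 variance terms, per-group O/E
  direction) that must hold exactly. lifelines serves as an independent
  oracle in the test suite and agrees to ≤ 1e−9.
* All generators take one integer seed and are bit-reproducible; writers
  emit plain TSV (`%.10g`) so identical config + seed gives byte-identical
  outputs.
* Degenerate inputs are hard errors, not silent repairs: missing expression
  values, all-identical stratification values, zero-variance correlation
  targets, fa at 0/1 for CI, fewer than 4 distinct doses for 4PL.

## Known limitations

* **Deep-tail anti-conservatism at extreme splits.** At an extreme
  stratification percentile (e.g. 0.78 → a 22/78 split) the χ²
  approximation of the log-rank test is anti-conservative in the far tail
  (p ≲ 10⁻³·m⁻¹) at cohort sizes of a few hundred, so a Bonferroni screen
  over hundreds of genes at such a split can exceed its nominal FWER even
  under the null. This is a property of the test, not of the
  implementation (verified against an independent implementation). The
  null-calibration check therefore runs at the balanced median split, where
  the screen is well calibrated; extreme-percentile screens at desk-scale
  n should be interpreted with this in mind, and permutation p-values are
  the natural extension.
* Scan-mode percentile optimization is reported without within-gene
  correction (flagged in output metadata).
* CI and ZIP answer different questions: a grid constructed exactly
  Bliss-independent scores ZIP ≈ 0 but mean CI < 1, since Loewe additivity
  (the CI reference) and Bliss independence disagree except for mutually
  exclusive drugs — both are reported rather than reconciled.
* The IRS generator couples scores to latent (pre-censoring) event times;
  with heavy censoring the realized IRS–outcome association weakens
  accordingly.
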