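# targetfunnel

A tested, reusable implementation of a multi-stage computational screen for
nominating therapeutic targets from bulk tumor transcriptomics — the kind of
funnel that surfaces an overexpressed, prognostic, druggable enzyme (such as
the ribonucleotide reductase subunit RRM2 in Ewing sarcoma) — together with
the downstream quantitative pharmacology used to characterize an inhibitor
against such a target.

## Who this is for

Computational biologists who want to run, stress-test, or extend a
biomarker/target screen of the form:

1. **Overexpression screen** — per-gene log2 fold increase of a tumor cohort
   over a multi-tissue normal compendium, with candidates at
   `log2 FC >= 2` (tumor mean minus normal reference on the log2 scale; the
   normal reference is, by default, the mean of per-tissue means so every
   tissue type weighs equally).
2. **Survival screen** — per candidate gene, patients are stratified at an
   expression percentile (default the 78th), compared by the log-rank
   (Mantel–Haenszel) test, Bonferroni-corrected across the m genes actually
   covered by the survival dataset; a gene passes only if adjusted p < 0.05
   *and* the high-expression group fares worse. Equivalent IRS-based
   stratification (immunoreactive score, low ≤ 2 vs high > 2) supports
   protein-level validation cohorts.
3. **Druggability filter** — keep genes with enzymatic function, an
   available specific inhibitor with pharmacokinetic data, not yet
   (pre)clinically tested in the disease.

plus co-expression (Pearson `|r| > 0.5`), one-sided hypergeometric gene-set
enrichment, perturbation-signature intersection, and pharmacology:
four-parameter logistic (4PL) dose–response fits with absolute IC50,
fold-resistance, the Chou–Talalay combination index
`CI = d_a/Dx_a + d_b/Dx_b` (CI < 1 synergistic, = 1 additive, > 1
antagonistic) and ZIP delta synergy scores on the ×100 scale (> 10
synergistic, < −10 antagonistic).

Because real tumor compendia and patient cohorts are not redistributable,
the package ships a first-class synthetic-data module
(`targetfunnel.synth`) that generates every input with planted, recoverable
ground truth: overexpressed genes, hazard effects dichotomized at a chosen
quantile, outcome-coupled IRS scores, 4PL plates and two-drug grids with a
controllable deviation from Bliss independence.

## Worked example

```bash
python analysis/01_simulate_inputs.py --seed 1
python analysis/02_target_funnel.py   --seed 1
```

prints

```
funnel summary:
 stage                                description  count
     1        overexpressed (log2 fold >= cutoff)      6
     2 negative survival association (Bonferroni)      1
     3             druggable, untested in disease      1

final target: RRM2L (log2 fold 2.96, Bonferroni-adjusted p 2.28e-12, high expression worse)
log-rank at 78th percentile: chi2=52.7, p=3.79e-13, worse group: high
IRS stratification (low<=2 vs high>2): p=3.30e-48, worse group: high
```

Six genes clear the overexpression cutoff (the planted target plus five
overexpressed-only distractors); only the planted target also predicts worse
survival after Bonferroni correction, and it alone survives the druggability
filter — the funnel narrows 200 → 6 → 1 → 1 and recovers exactly the gene
whose effects were planted. `analysis/03_coexpression_enrichment.py` and
`analysis/04_pharmacology.py` continue the study: the target's co-expression
module is recovered at |r| > 0.5 and its planted gene set ranks first in
enrichment; the dose–response panel recovers planted IC50s of
0.35 / 1.63 / 101.63 µM and a ~2000-fold acquired-resistance shift, the sham
combination gives CI = 1, and grids with a +0.15 Bliss deviation score a
mean ZIP delta of ≈ +14.5 ("synergistic" by the > 10 rule).

A `targetfunnel` console command exposes the same operations
(`simulate`, `screen`, `coexpress`, `enrich`, `intersect`, `synergy`) over
plain TSV/GMT files; run `targetfunnel --help`.

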