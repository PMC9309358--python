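# trimodal

Coupling analysis of blood monocyte gene expression, cortical thickness and
cognition in two-group (patient vs control) cohorts.

## The scientific problem

Immune dysregulation, cortical thinning and cognitive deficits co-occur in
first-episode schizophrenia (FES), but each is usually analysed in isolation.
This package implements the tri-modal analysis that ties them together for a
case–control study design:

1. **Preprocessing.** Bulk RNA-seq counts are filtered (mean raw count < 4,
   then the lowest 15% of the variance distribution), normalized to log2
   counts-per-million, and restricted to a panel of monocyte subset signature
   genes (pan / classical / intermediate / nonclassical, by CD14/CD16 class).
   Cortical thickness tables over the 34 Desikan–Killiany regions are averaged
   across hemispheres. Cognition enters as the seven MCCB domain T-scores.
2. **Group statistics.** Demographics tests (Student's *t*, Mann–Whitney *Z*
   with Shapiro–Wilk dispatch, Pearson χ² without continuity correction),
   ANCOVA-style covariate-adjusted group comparisons (partial *F*-test in a
   linear model), a per-gene linear differential-expression screen, and
   Benjamini–Hochberg FDR.
3. **Coupling (the core).** For each group separately, every pairwise partial
   correlation *r* within and between the gene, cortex and cognition blocks
   is computed by residualizing both features on the covariates (age + sex;
   plus education when cognition is involved) and correlating the residuals.
   Correlations are mapped to Fisher *Z*<sub>r</sub> = atanh(*r*); matched
   *Z*<sub>r</sub> profiles of the two groups are compared by paired
   *t*-test, overall, per module pair and per monocyte subset, with BH-FDR
   across scopes; individual gene × region pairs are screened at a nominal
   *p* < 0.01 with FDR over the full 54 × 34 family.
4. **Mediation.** A three-variable model X (gene) → M (region thickness) →
   Y (cognition domain) with covariates: least-squares paths *a*, *b*, *c′*,
   *c*, indirect effect *ab*, a percentile bootstrap 95% CI for *ab* (5000
   resamples by default), and a full/partial/none mediation classification
   (full = significant indirect path with non-significant direct path).

No subject-level data ship with the package. Instead, `trimodal.synthetic`
generates two-group cohorts with the full statistical structure the analysis
assumes — group mean shifts in every modality plus cross-modal coupling from
one shared latent factor per subject with group-specific loadings — and a
closed-form oracle for every implied correlation, so the whole pipeline can
be exercised and validated end to end.

## Worked example

```python
from trimodal import PipelineConfig, run_pipeline
import pandas as pd

run_pipeline(PipelineConfig(synthetic=True, seed=1, n_boot=2000), "demo")
comp = pd.read_csv("demo/paired_comparisons.tsv", sep="\t", comment="#")
print(comp[["scope", "mean_a", "mean_b", "t_statistic", "q_value"]].head())
```

prints (mean_a = control group, mean_b = patient group):

```
           scope  mean_a  mean_b  t_statistic  p_value  q_value
       gene-gene  0.3928  0.3346     -17.6998   0.0000   0.0000
   cortex-cortex  0.0426  0.0026      -6.9057   0.0000   0.0000
     gene-cortex -0.1254 -0.0381      29.3406   0.0000   0.0000
  gene-cognition -0.1005  0.1017      32.8796   0.0000   0.0000
cortex-cognition  0.0303 -0.0018      -3.9927   0.0001   0.0001
```

Reading: in controls the signature genes couple negatively with cortical
thickness (mean *Z*<sub>r</sub> ≈ −0.13) and cognition (≈ −0.10); in patients
the gene–cortex coupling is attenuated (≈ −0.04) and the gene–cognition
coupling reverses sign (≈ +0.10) — the positive paired *t* statistics flag
exactly this weakening/reversal, and the within-module coupling (gene–gene,
cortex–cortex) is attenuated in patients (negative *t*). `demo/` also
contains the per-group *Z*<sub>r</sub> matrices, the gene × region screen
(`screen_hits.tsv`), the ANCOVA table, and `mediation.json` for the top
patient-group gene–region pair.

The same pipeline runs from the command line:

```bash
trimodal simulate --preset paper-like --seed 1 --outdir inputs/
trimodal run --synthetic --seed 1 --outdir results/
trimodal mediate --phenotypes inputs/phenotypes.tsv --expression results/expression.tsv \
    --thickness results/thickness_averaged.tsv --x RNASE2 --m lateraloccipital \
    --y visual_learning --out mediation.json
```

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-cohort
generator and its calibration, numerical choices and known limitations.
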