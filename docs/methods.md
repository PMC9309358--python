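# Methods

## The analysis model

The pipeline quantifies *coupling* — covariate-adjusted partial correlation —
between three per-subject feature blocks in each of two groups (HC controls,
FES patients):

* **genes** — log2-CPM expression of 54 monocyte subset signature genes
  (4 pan, 9 classical, 20 intermediate, 21 nonclassical, by CD14/CD16 class);
* **cortex** — bilaterally averaged thickness (mm) of the 34 Desikan–Killiany
  regions;
* **cognition** — the seven MCCB domain T-scores.

For features x, y and covariate matrix C, the partial correlation is the
Pearson correlation of the least-squares residuals of x and y on
[1 | C]; the two-sided p-value uses t = r·sqrt(df/(1−r²)) with
df = n − 2 − k. Covariates are age + sex, with education added whenever a
cognition block is involved. Subjects enter each analysis pairwise: a
missing MCCB or subset value drops the subject from that analysis only,
mirroring study designs where imaging/cognition/flow-cytometry sub-cohorts
overlap but differ.

Correlations are variance-stabilized as Fisher Z_r = atanh(r) (|r| clipped
at 1 − 1e−12). Two groups' coupling profiles are compared by a paired
t-test over matched entries — all entries for a between-module matrix, the
strict upper triangle for a within-module matrix (the diagonal is r = 1 and
carries no information; reported within-module means are only meaningful
without it). Pairing is by identical (feature_i, feature_j) entry, the only
pairing that makes "paired" meaningful for two independent cohorts. BH-FDR
is applied across the scopes of one figure-level family (the five module
scopes; separately, the subset-stratified scopes; separately, the full
gene × feature family of the pairwise screen, e.g. 54 × 34).

**Caveat (entry dependence).** Entries of a coupling matrix share subjects
and are therefore statistically dependent; the paired t-test treats them as
exchangeable pairs, exactly as the profile-level analysis defines it. The
0.05 type-I calibration asserted in the tests holds for independent-entry
profiles; on real (dependent) coupling matrices the test over-states
certainty for small true differences, so block-level p-values should be
read as descriptive rankings rather than exact error rates. This also means
a truly null stratum can be flagged alongside a strongly affected one; the
affected stratum is identified by effect size (mean Z_r shift), which the
recovery tests assert.

Degenerate paired comparisons are flagged: a zero-variance difference vector
yields t = 0, p = 1 when the mean difference is zero and t = ±inf, p = 0
when the profiles differ by an exact constant (difference vectors whose
spread is below 1e−10 × |mean| count as constant, absorbing float rounding).

### Group statistics

* ANCOVA is the univariate-GLM form: one linear model
  y ~ 1 + group + covariates, partial F-test with 1 numerator df (F = t²),
  adjusted means at the covariate means. If the covariates explain y
  exactly (residual variance at rounding level), the group effect is
  reported as F = 0 (or F = inf if the coefficient is genuinely nonzero)
  rather than a 0/0 artifact.
* Pearson χ² on 2×2 tables uses N(ad−bc)²/(r₁r₂c₁c₂) with no continuity
  correction — this reproduces published cohort statistics (1.338 for the
  sex table, 1.854 for smoking) that the Yates-corrected form does not.
* Mann–Whitney uses midranks, tie-corrected variance, no continuity
  correction; Z is negative when the first sample has the smaller rank sum.
  Continuous demographics dispatch to Student's t when Shapiro–Wilk accepts
  normality in both groups at α = 0.05, else to Mann–Whitney.
* The differential-expression screen is an ordinary least-squares model of
  log2-CPM on group + covariates per gene (log2FC = group coefficient,
  t-test p, BH q over genes). It is deliberately *not* a count-model
  (negative-binomial) fit; it stands in for one where only direction and
  approximate magnitude of fold changes are needed.

### Mediation

X → M → Y with covariates, all of x, m, y z-scored by default so
coefficients are standardized betas (raw scale via `standardize=False`).
Three OLS fits give a (M ~ X + C), b and c′ (Y ~ X + M + C) and c
(Y ~ X + C); on complete data c = c′ + a·b exactly. The indirect effect
a·b gets a percentile bootstrap CI (whole subject rows resampled jointly;
2.5/97.5 percentiles; resamples with a constant variable are redrawn).
Percentile rather than bias-corrected intervals are the default of the
common macro implementations of this model. Classification: *full* if the
CI excludes zero and c′ is not significant at 0.05, *partial* if both are
significant, *none* otherwise.

## The synthetic cohort generator

The generator emulates a two-group case–control study (defaults: 111 HC /
128 FES) with group mean shifts in every modality and cross-modal coupling
produced by **one shared latent factor u ~ N(0,1) per subject** with
group-specific per-feature loadings (λ for genes, μ for regions, ν for
cognition domains). Group differences in coupling are encoded by the
loadings, not by different factors — the simplest structure that yields
"weakened or even reversed" coupling with a closed-form oracle:

    corr(feature_i, feature_j) = l_i l_j / sqrt((l_i² + u_i)(l_j² + u_j))

with unique variance u = 1 for noise-free signals. Because all cross-modal
dependence flows through u, covariate terms cancel under partial
correlation and the formula needs no adjustment for them.

**Observation model for genes.** Counts are negative-binomial
(gamma–Poisson) around libsize·2^(base + FC·[FES] + σx·x)/1e6 with
dispersion φ = 0.2 and log-normal library sizes around 2×10⁷ — typical bulk
RNA-seq magnitudes. On the log2-CPM scale this adds measurement noise with
variance τ² = (1/mean_count + ψ₁(1/φ))/ln2², where ψ₁ is the trigamma
function (the exact log-variance of the gamma mixing term). The implied
coupling of the *observable* expression therefore uses unique variance
1 + τ²/σx² for the gene block (`implied_coupling(..., measurement_noise=True)`,
the default); `measurement_noise=False` gives the noise-free latent form.

The count matrix also carries 260 unannotated background genes spanning
very low to housekeeping-level abundance (log2-CPM −4 to 15.5). They serve
two purposes: the abundance and variance filters have realistic material to
remove, and the library totals are dominated by genes without latent
signal. The latter matters: log2-CPM is compositional, and if the signature
genes contributed a large share of the total, normalization would subtract
part of their shared latent signal and bias the coupling (an effect the
closed form does not model; with the default background it is < 0.01 on a
block-mean correlation).

**Other modalities.** Thickness: t = T_j + Δ_j·[FES] + γ_age(age−ā) +
s_T(μ_j u + e) mm, with hemisphere values t ± N(0, 0.02) so bilateral
averaging is a real (and exactly noise-cancelling) operation. Baselines
spread around 2.59 mm; patient shifts average −0.053 mm (eight parietal/
temporal/occipital regions at −0.10, pericalcarine and lingual at +0.04).
Cognition: c = C_k + δ_k·[FES] + γ_edu(edu−ē) + s_C(ν_k u + e) with
s_C = 9 T-points; domain baselines and patient deficits follow the study's
cognitive battery table; the composite is the mean of the seven domains
(the battery's norm-standardized composite would need a normative sample
the generator does not model, so its printed deficit of ≈ −13.8 corresponds
to ≈ −11 on this mean-composite scale). Covariates: group-specific
truncated-normal age (18–55) and education, Bernoulli sex and smoking with
the study's frequencies. Monocyte subset percentages are logistic-normal
(σ = 0.4) over classical/intermediate/nonclassical against a fixed residual
component; the location parameters are bias-corrected by deterministic
quasi-random calibration so the *mean* percentages hit their targets
(nonclassical 7.61% in HC vs 5.27% in FES; classical and intermediate equal
across groups).

**Preset calibration.** The `paper-like` preset assigns each feature a
deterministic loading weight (genes spread 0.7–1.3, regions 0.7–1.3,
domains 0.8–1.2, giving heterogeneous pairwise correlations) and solves for
the loading scales by root finding on the measurement-noise closed form so
the observable block-mean Z_r hits the study's printed values exactly:
within-gene 0.388 (HC) / 0.335 (FES), gene–cortex −0.116 / −0.025,
gene–cognition −0.088 / +0.085. A single shared factor cannot also
reproduce the strong printed within-cortex coupling (0.449/0.346): with one
factor, cross-module coupling is the geometric mean of the within-module
couplings, so matching within-gene and gene–cortex pins within-cortex near
0.036. This is the main structural limitation of the one-factor design; a
two-factor generator would trade away the closed-form oracle. `null` zeroes
all loadings and group effects; `strong-coupling` uses uniform large
loadings (every implied |corr| ≥ 0.3).

**What passing tests show.** The generator reproduces block-level coupling
structure, group mean shifts and realistic marginals, and the pipeline
recovers them; it does not emulate full transcriptomes, batch effects,
non-linear age effects, spatially correlated cortical noise, or the
dependence of real MCCB domains beyond the single factor — so passing tests
validate the statistical machinery, not biological discovery on real data.

## Numerical choices

* Gene filtering: mean raw count < 4 removes a gene (a per-cell reading
  would remove nearly everything); then the floor(q·n) lowest raw-count
  variances among survivors are removed (q = 15% by default), ties resolved
  by removing the smaller mean first, then the lexicographically later
  symbol. A rank-based percentile filter is a fixed point only once
  floor(q·n) = 0; re-running it on a large filtered matrix removes a
  further tranche, so filtering is done once per pipeline run.
* Normalization: log2(count/total × 10⁶ + 1), pseudocount after scaling so
  zero counts map to exactly 0; totals default to the input matrix's column
  sums, and the pipeline passes pre-filter totals so filtering does not
  change the library denominator.
* Partial correlations within one block pair are computed by one
  residualization of each block followed by a cross-correlation product
  (numerically identical to the per-pair route, ~1000× faster).
* Fisher transform clips |r| ≥ 1 − 1e−12 (logged). Bootstrap mediation
  solves batched normal equations over resamples (chunked einsum + batched
  solve), making 5000 resamples effectively instant.
* All output tables are written with a fixed %.10g float format and a
  header carrying the package version, config hash and seed; identical
  config + seed reproduce byte-identical files.

## Validation scales

The statistical validation experiments use: generator fidelity at n = 5000
per group against the closed form (block-mean deviations; per-entry maxima
over ~1800 correlated entries would exceed a 3/√n band by order statistics
alone even for a perfect generator); pipeline recovery at study scale
(111/128) over 50 seeds; paired-test type-I calibration on 500
independent-entry null profile pairs; bootstrap CI coverage over 300
simulated chains at n = 200 with 1000 resamples. These sizes keep the full
suite in tens of seconds while leaving Monte-Carlo error well inside the
asserted tolerances.
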