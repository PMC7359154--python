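# Methods

## The analysis model

The pipeline treats an untargeted plasma metabolomics cohort as a
participant × metabolite matrix of positive ion intensities in
arbitrary units, annotated with a two-tier pathway structure
(subpathway → superpathway) and clinical metadata (diagnostic group ∈
{bvFTD, nfvPPA, PSP, CBS, Control}, age, sex, and for patients the days
from blood draw to death or censoring).

**Missingness model.** A missing cell is read as "below the limit of
detection", not missing at random. This motivates both rules used:
metabolites missing in *strictly more than* half of the participants
are dropped (a metabolite missing in exactly half is retained), and the
remaining missing cells are imputed at half the metabolite's minimum
observed positive value — the conventional point surrogate for a
left-censored value. Drug and drug-pathway metabolites are removed by
the per-metabolite exogenous flag, *not* by discarding the Xenobiotics
superpathway wholesale: dietary xenobiotics (benzoate-like compounds)
are legitimate analytes. Removal order is missingness filter →
exogenous removal → imputation → z-scaling, so half-minimums are never
computed for columns that will be dropped; the preprocessing report
reconciles the counts exactly. Z-scaling uses the sample (n−1) standard
deviation; constant columns scale to zeros with a warning and must be
excluded before PCA.

**Differential abundance.** Each z-scored metabolite is regressed on a
disease indicator plus age and sex (ordinary least squares — with a
Gaussian response and identity link this *is* the generalised linear
model, and z-scored targets admit no other coherent family). The group
coefficient's two-sided Wald p enters Benjamini–Hochberg correction at
q < 0.01; Storey's q-values (λ = 0.5) are available as an option, and a
Bonferroni flag (p < α/m, strict) is reported alongside with the caveat
that metabolite correlation makes it conservative. Fold change is the
ratio of arithmetic group means on the unscaled *imputed* matrix
(observed-only means are a flag away). Because the design matrix is
shared across metabolites the scan is one vectorised least-squares
solve; a unit test pins it to statsmodels OLS at 1e-10.

**Two-level PCA.** Level one: a PCA of the correlation matrix of each
subpathway's z-scored block (columns are already unit variance, so
Kaiser's eigenvalue-1 reference is meaningful; total variance equals
the metabolite count). Components with eigenvalue > 1 are retained. A
single-metabolite subpathway has eigenvalue exactly 1 and fails the
strict criterion; the default policy passes the metabolite through as
its own component so no pathway is silently lost (a `drop` policy is
available). Retained component scores are compared between patients and
controls by two-sample t-tests with FDR correction applied jointly
across all components; a subpathway is called significant if any of its
components is. Level two: all retained local scores are standardised to
unit variance (so large subpathways cannot dominate by eigenvalue
scale) and eigendecomposed again. Global retention is Kaiser by
default, or a fixed top-k. Loading vectors at both levels are flipped
so their largest-magnitude entry is positive, with magnitude ties
(within 1e-9 relative) broken toward the lowest index — this makes
repeated runs bit-identical and stable across eigensolvers, including
the equal-magnitude eigenvectors of 2×2 correlation blocks.

**Classification.** Eleven comparisons: the ten unordered group pairs
plus combined FTLD vs control. For each, the larger class is randomly
subsampled to the size of the smaller (fresh draw each repetition),
features (global component scores) are min-max rescaled to [−1, 1] over
the pair's full dataset before CV — mirroring the emulated protocol; a
leakage-safe per-fold option exists — and a linear SVM (cost C = 1, the
LIBSVM default) is evaluated by stratified ten-fold CV. Stratification
is a deliberate choice: with ~30 cases per class, unstratified folds
can degenerate to one class. Backward sequential feature selection then
greedily removes, at each step, the component whose removal yields the
highest CV accuracy, stopping only when every candidate removal would
strictly decrease accuracy (ties favour the smaller model); one fold
partition per repetition drives all evaluations, so selection reflects
feature content rather than fold noise, and at least one feature always
survives. The whole procedure repeats 10 times; a comparison's
consensus set is the intersection of its per-repetition selections, and
the pipeline's *consensus component* is whatever lies in the consensus
of all five disease-vs-control classifiers (the four syndromes plus
combined FTLD) — possibly nothing, which the pipeline reports rather
than errors on. The 5×5 accuracy matrix holds pairwise means
off-diagonal and size-matched one-vs-rest accuracies on the diagonal.
Note the reported post-selection accuracy is optimistically biased by
construction (selection maximises CV accuracy); the chance-level
calibration test therefore permutes labels against the *full* feature
set.

**Survival.** Patients only. The consensus component score is
standardised across patients ("per SD" hazard ratios) and enters a Cox
proportional-hazards model (Efron ties, Newton convergence tightened to
1e-12 so cross-implementation checks hold at 1e-6) with age, a male
indicator and FTLD-group indicators (reference bvFTD — alphabetically
first; the group hazard ratios are reported, not interpreted). For
illustration, patients are stratified at |z| = 1 — boundaries inclusive
in the medium stratum — and compared by Kaplan–Meier curves with a
log-rank test; empty strata are excluded with a warning.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with every planted quantity recorded for recovery testing:

* **Design.** Groups of 30/26/45/33 patients + 32 controls; 842
  endogenous metabolites in 91 subpathways (sizes drawn from a skewed
  random partition, or fixed explicitly) plus 12 drug metabolites in 3
  wholly exogenous drug subpathways. Age and sex are sampled per group
  around the emulated cohort's demographics (e.g. bvFTD mean age 64.5,
  controls 68.7; male fraction 0.38–0.62).
* **Abundances.** log X = baseline + δ·(patient) + λ·s + σ·ε with
  baseline ~ U(4, 12), noise sd σ ~ U(0.2, 0.5) — log-normal intensities
  with 20–60% coefficients of variation, the typical plasma range. The
  planted shifts δ (±0.35 by default on 49 metabolites, i.e. fold
  changes ≈ 0.70 or 1.42 and per-metabolite effects around Cohen's d ≈
  1) reproduce the regime where moderate fold changes reach p ≈ 1e-4 to
  1e-8 at n ≈ 166. The latent severity s is standard-normal within
  group with a +2.0 shift in patients, standardised to mean 0, variance
  1 over the cohort; loadings λ = ±0.6 (full scale) are confined to 12
  designated subpathways. The severity shift was set so that
  disease-vs-control SVM accuracies land in the high-80s-to-90s range
  while the four (identically distributed) disease groups stay near
  chance against each other.
* **Missingness.** A configurable fraction of metabolites (default
  30%) receives a censor quantile q ~ U(0.05, 0.6); values below the
  column's empirical q-quantile become missing. This is genuine left
  censoring — the missing cells are exactly the smallest values — and
  quantiles above 0.5 exercise the exclusion rule.
* **Survival.** Exponential proportional hazards for patients:
  baseline median 1460 days, linear predictor β·s + 0.03·(age −
  mean age), β = log 0.74 per severity SD by default (higher score
  protective). Independent exponential censoring calibrated to a 30%
  censor fraction; controls carry no survival data.

**What the generator does not emulate** — and hence what green tests do
*not* establish about real cohorts: batch and instrument drift, isomer
ambiguity, correlated metabolite noise beyond the single severity
factor, non-proportional hazards, informative censoring, and real
between-syndrome metabolic differences (the four disease groups share
one distribution by default, so disease-vs-disease accuracy is near
chance by design, whereas real syndromes separate partially).

A noted interaction: *stronger* factor loadings can *worsen* factor
recovery, because left-censoring then selects on the factor itself and
half-minimum imputation flattens the low-severity tail of every loaded
metabolite. Recovery assertions use moderate loadings (0.8 on unit-sd
noise at test scale) for this reason.

## Problem sizes and numerical choices

The validation suite scales designs down so the full run stays modest
on one CPU, keeping group sizes at the study's 134 + 32:

* Null calibration: 200 zero-effect cohorts × 200 metabolites; FDR
  count bound 0.01·m in mean, pooled KS on raw p at α = 0.01.
* PCA oracle: 50 random blocks (n 15–40, p 2–7) against an independent
  SVD eigendecomposition at 1e-8; variance conservation at 1e-8.
* Factor recovery / consensus: 100 cohorts of 8 uniform subpathways × 5
  metabolites (4 subpathways loaded at 0.8), top-5 global components;
  |r| > 0.9 required in ≥ 95, consensus membership in all five
  disease-vs-control classifiers in ≥ 90. Uniform block sizes are used
  because a random partition occasionally gives a factor subpathway 1–2
  metabolites, which destroys identifiability at this scale.
* Cox coverage: 200 replicates at β = log 0.74, 134 patients, ~30%
  censoring; Wald 95% CI coverage required in 93–97%.
* Cross-implementation: lifelines vs scikit-survival (both Efron) on a
  fixed 50-patient cohort at 1e-6.

Other numerical choices: eigendecomposition via symmetric `eigh` on the
correlation matrix with a stable descending sort (exact eigenvalue ties
keep input order); SVM evaluations reuse one fold partition per
repetition; repetition seeds derive as master seed + repetition index,
stage seeds as fixed offsets of the single pipeline seed; all CSVs are
written at repr precision so round trips are exact and manifests
checksum-stable.

## Known limitations

The consensus component is identified by the selection procedure, not
by a fixed index — its sign and rank are data-dependent, so downstream
reports orient it by correlation with a reference where one exists.
Kaiser retention on near-identity correlation inputs is unstable (all
eigenvalues ≈ 1); the fixed-k option exists for exactly that regime.
Storey's estimator uses a single λ rather than the smoothed fit. The
backward elimination uses the same CV split for selection and for the
reported accuracy, so that accuracy is an optimistic estimate — the
package reports it as the emulated protocol defines it rather than
nesting a second CV.
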