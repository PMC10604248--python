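# Methods

## The modelling problem

An essential oil (EO) is a mixture characterised by GC-MS as a vector of
component percentages. Its antioxidant potency in a given in vitro assay is
summarised by an EC50 (μg/mL; lower = more potent), possibly right-censored
("EC50 > 1 μg/mL"), or — for DNA-protection gels — by an RBD50. A
quantitative composition–activity relationship (QCAR) model maps the
composition vector to a binary potency class (active/inactive at an EC50
threshold) and is then interrogated to name the chemical components that
drive or suppress the activity.

The package implements the full chain: assay quantification, dataset
pretreatment, classifier search, and interpretation, with a synthetic-data
module standing in for laboratory measurements.

## Assay quantification

- **Percent inhibition**: `(A_c − A_t)/A_c × 100` from control and sample
  absorbances. Negative values (pro-oxidant behaviour) are reported raw.
- **EC50**: least-squares fit of a four-parameter logistic (4PL) in log10
  concentration, `r(c) = bottom + (top − bottom)/(1 + 10^{h·(log EC50 − log c)})`,
  via `scipy.optimize.curve_fit` with bounds top ∈ [50, 110] %,
  bottom ∈ [−10, 50] %, hill ∈ [0.2, 10], log10 EC50 within one decade of
  the tested concentration range. The 4PL was chosen as the canonical
  "dose–response sigmoidal curve" of assay software. A flat series, an
  optimizer failure, or an optimum pinned (to within a ppm margin) at the
  EC50 range bound yields `converged=False`, never an exception; fewer than
  4 points is an error. Initialisation: top/bottom from the observed
  extremes, unit hill, EC50 at the point nearest the response midpoint;
  tight tolerances (1e−14) give noiseless recovery to better than 1e−6
  relative.
- **RBD50**: the smallest concentration at which relative band density
  reaches 1.5 × the radical-damaged control's RBD, by linear interpolation
  in log10 concentration; `None` ("undetermined") if never reached. The
  50% increase is defined relative to the damaged control lane; relative to
  the damaged→undamaged span is available via `span_reference=True`. The
  choice of reference is a genuine ambiguity in how such gels are reported;
  the control-lane reading is the default because the damaged lane is the
  measured baseline of every series.
- **Comet scores**: TCS = Σ i·n_i over damage classes T0–T4;
  %R = (TCS⁺ − TCS_t)/(TCS⁺ − TCS⁻) × 100 against positive (damage) and
  negative (untreated) controls, reported unclipped. This is the standard
  comet-assay reduction formula.
- **Cross-assay regression**: OLS of one assay's EC50 vector on another's
  (censored values excluded by the caller), r² = squared Pearson r.

## Pretreatment

Four parameters define a pretreatment: EC50 **threshold** (active iff
uncensored and EC50 ≤ threshold — censored oils are inactive at any
threshold at or below their limit), **n-level** ∈ {0..4} (drop components
with ≤ n strictly-positive training occurrences; a 0.01% trace counts),
**min–max scaling** (per component, to [0,1] on the training rows; constant
columns map to 0; applied rows are not clipped), and **PCA level**
∈ {none, 0.60, 0.70, 0.80, 0.90, 0.99} (centered PCA, smallest axis count
whose cumulative explained variance reaches the level).

Stage order is binarize → filter → scale → PCA: scaling precedes PCA so
that variance fractions are comparable across components of very different
magnitudes. Every statistic is fitted on training rows only and applied to
held-out rows; this leakage control is what makes selection by held-out MCC
meaningful.

## Model search

The search space is the Cartesian product of pretreatment settings and five
classifier families (SVM, random forest, gradient boosting, decision tree,
k-NN) with small per-family hyperparameter grids (all configurable).
Scoring: a stratified 80:20 split (test size = ⌈n/5⌉, so 13 of 61), fit on
the training split, Matthews correlation of the test-split predictions
(MCC_pred), with ACC and F1 recorded alongside. nMCC = (MCC + 1)/2 rescales
[−1, 1] to [0, 1]; MCC with a zero denominator factor is defined as 0.
Degenerate candidates (single-class labels at a threshold, empty feature
set after filtering) become sentinel results with MCC_pred = −1 and a
reason code rather than errors, so a search over thousands of combinations
never aborts.

Phase 1 samples `coarse_budget` combinations uniformly without replacement
(budgets at or above the space size enumerate it); the top 25% of
(family × pretreatment) cells by best coarse MCC_pred survive; phase 2
samples `refined_budget` combinations restricted to those cells. The final
choice is the MCC_pred argmax over both phases, ties broken toward fewer
features and then the lexicographically smallest combination. One split
seed (the run seed) is shared by all evaluations of a run — a single
train/test division, re-stratified per threshold because the labels change.
Default budgets are 100/1000, a desk-scale setting; both are plain
arguments.

The winner is refitted on the full dataset (training metrics reported) and
its robustness characterised by 50 iterations of freshly seeded stratified
5-fold CV, pretreatment refitted inside every training fold, MCC computed
on pooled out-of-fold predictions per iteration (MCC_CV). CV is
deliberately not part of selection.

## Interpretation

- **Feature importance (FI)**: permutation importance — per component, the
  mean decrease in full-data MCC over 20 seeded column permutations,
  negative values floored at 0, normalised to sum 1. One model-agnostic
  definition serves all five families; tree impurity importances are not
  used.
- **Partial dependence (PD)**: mean predicted active-class probability with
  the component forced along a 20-point grid from 0 to its observed
  maximum. Probabilities come from `predict_proba` where available and from
  a logistic map of the SVM decision function otherwise.
- **WFI** = FI × ρ, where ρ is the Spearman correlation of the PD curve
  (grid vs PD values). ρ on the 20-point grid is the default; the
  per-sample variant (observed percentages vs per-sample PD) is available
  as `spearman_weight_samples`. Components with |ρ| < 0.1 are reported
  neutral — no sign call on a flat curve.
- **Report**: components sorted by |WFI|, top-20 by convention. Sign
  convention: activity labels are 1 = potent, so a component whose
  percentage raises predicted activity has positive WFI. A generative
  driver with negative β on log10 EC50 (lowers EC50, raises potency)
  therefore surfaces with a **positive** WFI.

Interpretation always runs in original component space: forced values pass
through the fitted pretreatment (including PCA) before prediction.

## Synthetic data

The generator emulates the statistical structure of a commercial EO panel:

- **Compositions** (61 oils × 50 components by default): per oil,
  1 + Poisson(dominance − 1) major components (default dominance 2.0,
  i.e. oils carried by one to a few majors) chosen with 1/rank popularity
  weights so a few components recur across many oils; stick-breaking
  percentages scaled to a total in [60, 95] with the largest share forced
  above 10%; a handful of sub-percent traces. Rows are sparse and sum to
  ≤ 100.
- **Activity**: log10 EC50 = intercept + Σ β_j x_j + ε, ε ~ N(0, noise_sd);
  EC50 above the censoring limit (default 1 μg/mL) is reported censored at
  the limit, so actives fall in the sub-μg/mL range and inactives read
  "> 1". The planted-signal study condition used by the tests and the
  acceptance script is a 61 × 40 panel, drivers β = −0.04 and +0.04 per
  percentage point on the two most popular components, noise_sd = 0.05,
  intercept 0 — strong, learnable signal with realistic class balance
  (roughly one-third active at a 0.25 μg/mL threshold).
- **Dose–response curves**: 4PL plus Gaussian noise over a two-fold
  dilution grid (2 → 0.0078 μg/mL by default).
- **Gel series**: a saturating (or decaying) logistic RBD profile built to
  cross the 1.5 × baseline protection target exactly at the requested
  concentration, clipped to (0, 1.2].
- **Comet counts**: per-cell damage class Binomial(4, mean/4), so TCS/n
  averages to the requested mean class.

What the generator does **not** emulate: real GC-MS co-occurrence
chemistry (chemotypes, constant-sum closure effects beyond the ≤100% cap),
inter-assay correlation structure, or measurement error in the percentages.
Passing tests therefore demonstrate that the pipeline recovers the signal
it is pointed at under realistic sparsity, censoring and noise — not that
any particular real oil's potency is predicted.

## Numerical and design choices

- All randomness flows from integer seeds through `numpy.random.default_rng`;
  the generator fans a global seed out to per-operation child seeds by fixed
  offsets so partial re-runs reproduce.
- Stratified splitting and k-fold, MinMaxScaler-equivalent scaling, PCA and
  the classifier families are scikit-learn; the metrics, search logic,
  permutation FI and PD are implemented here.
- Null-calibration checks (permuted labels must yield |MCC| ≈ 0) are run
  with a k-NN classifier: on a 13-sample test set the null MCC distribution
  of a flexible tree is discrete and heavy-tailed, and occasionally exceeds
  0.5 in magnitude by chance even though its mean is 0. k-NN's low variance
  makes the calibration property visible at the stated rate.
- Test and acceptance problem sizes (61-oil panels, 200 noisy curves or
  permutation seeds, 50 recovery panels, compact dt/knn/rf search grids)
  are the package's chosen desk-scale defaults; the full five-family grids
  and larger budgets remain available through `SearchSpace`.

## Known limitations

- Censored EC50s contribute only as "inactive" labels; no survival-style
  likelihood is attempted, and censored values are excluded from cross-assay
  regression.
- The coarse→refined restriction ("top 25% of cells") is one reasonable
  reading of pruning non-selected settings; the fraction is an argument.
- Permutation FI on strongly correlated components splits importance
  between them; WFI signs remain directionally meaningful but magnitudes
  should be read per model, not as causal effect sizes.
- `repeated_cv` requires every class to have at least k members; very
  extreme thresholds are rejected rather than silently merged.
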