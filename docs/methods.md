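# Methods

## Outcome model and criterion standard

The outcome is ordinal dehydration severity, Y ∈ {none < some < severe}.
The criterion standard is percent weight change with rehydration:
100 × (stable − admission) / stable, where the stable weight is the mean
of the two highest consecutive four-hourly weights that differ by less
than 2%. Categories: severe > 9%, some 3–9% (both endpoints included),
none < 3%. Two conventions the source description leaves open are fixed
here and surfaced in the API docs: the <2% criterion is taken relative to
the **larger** weight of the pair, and when two qualifying pairs tie on
their mean the **earliest** pair wins (determinism; clinically
immaterial). A series with no qualifying pair returns a "not stabilized"
signal rather than a number.

## Predictors and design matrices

Fourteen candidate predictors: eight categorical clinical signs, three
count/duration variables on a binned categorical scale (vomiting episodes
<1 / 1–5 / 6–10 / >10; diarrheal episodes <10 / 10–19 / >19; duration <13
/ 13–23 / >23 h; printed integer endpoints are inclusive), and three
continuous measurements (age, supine systolic blood pressure, mid-upper
arm circumference). Categorical coding is by indicators against the first
("normal") level. Four encodings feed the regression families:

1. indicators + linear continuous terms (23 columns);
2. set 1 plus all two-way interactions of set-1 variables (266);
3. indicators + restricted cubic splines, 3 knots at the 10th/50th/90th
   training percentiles, basis dimension 2, linear beyond the boundary
   knots (26);
4. set 3 plus all two-way interactions of set-3 variables (338).

Interactions are column-block products of the two parent variables;
self-interactions are excluded and the main-effect hierarchy always holds.
Tree families use set 1 only. Interaction columns that are constant in the
training data (level combinations never observed) are dropped and the
retained-column list is frozen into the encoder, together with level maps
and spline knots, so external data are encoded exactly as training was;
unseen categorical levels raise rather than impute.

## Model families

All families satisfy one contract: `predict_proba` returns rows on the
3-simplex (within 1e-10), deterministically given the fit.

**POLR / RIDGE.** Parallel cumulative-logit likelihood
P(Y ≤ k | x) = logistic(θ_k − xβ), ascending θ, one shared slope vector.
One optimizer serves both: L-BFGS on the negative log-likelihood plus
λ‖β‖² on internally standardized columns (intercepts unpenalized,
estimates mapped back to the original scale), thresholds parameterized as
θ₁ plus positive gaps. Gradients are analytic; tolerance 1e-8, max 500
iterations, single start. λ = 0 reproduces the unpenalized fit; the fit is
cross-checked against an independent implementation of the same likelihood
in the test suite. Rank-deficient designs, absent outcome categories and
separation/divergence (standardized slope beyond 30) raise errors rather
than returning silently broken fits. Stepwise selection is greedy forward
over whole variable blocks (a categorical's indicators or a continuous
predictor's spline columns enter together), scored by fitted
log-likelihood; interaction candidates are restricted to pairs of selected
main effects.

**CART.** Recursive partitioning with ordinal costs. The default split
criterion minimizes total labelling cost with absolute rank distance
|i − j| (each child labelled by its cost-minimizing category, i.e., its
weighted median); a generalized Gini impurity with the same linear costs,
and squared-distance variants of both, sit behind a switch. Pruning is
weakest-link: a split survives only if it lowers total cost by more than
cp × (root cost) per added leaf. Terminal prediction is the **modal**
category of the leaf (the convention of the ordinal-partitioning
literature), with leaf class proportions kept for probability output; the
labelling cost used for splitting/pruning intentionally uses the
cost-minimizing label, which differs from the modal label only in skewed
leaves.

**RF.** Bagged ordinal trees: unpruned, minimum node size 5 (2 in
deliberately overfit configurations), mtry variable *blocks* sampled at
every split, default 500 trees, per-tree in-bag indices recorded,
probabilities averaged over trees. Forest trees default to the generalized
Gini criterion because plain cost reduction plateaus on noisy nodes and
would starve deep growth. This is deliberately **not** the published
ordinal-forest score-set optimization (nsets / ntreeperdiv / npermtrial
machinery): only mtry is tuned, the remaining machinery having been
reported insensitive in the study this framework operationalizes. Tree
growth is numba-compiled for the bootstrap-heavy workloads, with an
equivalent pure-NumPy grower as reference and fallback; the two produce
identical trees under the shared tie-break (lowest column, then lowest
cut, strict-improvement threshold 1e-12).

## Tuning

K = 10 stratified folds (shuffled within outcome category, dealt
cyclically through one global counter, so overall fold sizes differ by at
most 1 and every fold carries all categories when feasible; categories
rarer than K trigger a best-effort warning). For each grid candidate the
model is fitted on K−1 folds and scored on the held-out fold by the sum of
log predicted probabilities of the observed categories; the candidate with
the best fold-averaged score wins, exact ties going to the most
parsimonious candidate (smallest size, largest λ, largest cp then
minsplit, smallest mtry). The final model is refitted on all rows. POLR
tunes main-effect count first, then (for interaction sets) the number of
interactions, re-running selection inside each training fold both times.
Default grids: POLR size 0–14 (+0–5 interactions); λ log-spaced 1e-3–1e3
(25 points); cp {0.001, 0.005, 0.01, 0.02, 0.05} × minsplit {10, 20, 50,
100}; mtry {1, 2, 3, 4, 6, 8, 11, 14}. Whether folds should be stratified
and which grids to use are judgment calls; both are configurable and
logged with every run.

## Discrimination indices

Models are reduced to a scalar risk score, by default the expected
category rank Σ k·p_k, applied uniformly to all four families so the
comparison is fair; P(top category) and a cumulative-probability score are
available behind a switch. Ties count ½ everywhere (Mann–Whitney
convention — required for the 0.5 chance anchor). ORC defaults to the
unweighted mean over **all** category pairs; an adjacent-pairs variant
(adjacency among categories actually present) is provided because both
readings exist in the literature. GC is computed as the weighted mean of
pairwise AUCs and verified in tests against direct pooled-pair counting.
A category pair with an empty side is dropped from ORC's mean with a
warning; GC pools the remaining pairs. Confidence intervals are 95%
percentile bootstrap (B = 1000 by default); resamples that lose all but
one category are redrawn up to 10 times, then dropped with a warning.

## Internal and external validation

Optimism correction reruns the **full** modeling procedure — encoding,
variable-set selection, CV tuning, fitting — inside each of B bootstrap
resamples (size n, with replacement). Per replicate b: A_b on the
resample, O_b on the original data, OOB_b on the out-of-bag rows. The
corrected estimates are Harrell A − mean(A_b − O_b); Efron 0.632
0.368·A + 0.632·mean(OOB_b); and 0.632+ with
R = (A − mean(OOB_b))/(A − γ) clipped to [0, 1] (R = 0 when the OOB mean
is no worse than apparent), w = 0.632/(1 − 0.368·R), estimate
(1 − w)·A + w·mean(OOB_b), all clipped to [0, 1]. γ = 0.5 for every
c-index (the chance anchor); a permutation estimate of γ is available for
non-standard scores. OOB indices are computed per replicate and averaged,
not pooled; pooling is an option. CIs for corrected estimates are
percentile intervals over the per-replicate corrected components and are
labelled as such — whether a nested bootstrap would be more faithful is an
open question this implementation does not resolve. Replicates whose OOB
index is undefined are dropped; more than 20% dropped is an error.
External validation applies the frozen training scorer to a second cohort
with no refitting.

## Synthetic cohorts

The generator draws predictor marginals (categorical signs multinomial
with mass on the normal level; age lognormal with median 35 y, SD-scale
22 y for standardization; systolic BP and MUAC truncated normals), builds
a latent linear predictor from configurable per-level effects plus a
quadratic age term and a skin-pinch × eyes interaction in the defaults —
so that the variable-set comparison has something to find — and draws the
outcome from the cumulative-logit model with intercepts calibrated by
root-finding on the empirical latent sample so the expected marginals hit
the configured prevalences (derivation 431/1431/277 of 2139 ≈
20.1/66.9/12.9%; shifted validation wave 301/1159/120 of 1580 ≈
19.1/73.4/7.6%, with age shifted −7 y). Calibrating on the empirical
sample rather than analytically keeps arbitrary effect maps exact. One
master seed feeds named substreams per stage, so cohorts are bit-identical
across runs.

What the generator does **not** emulate: the joint covariate correlations
of any real cohort (marginals are independent stand-ins and must not be
read as estimates of the study population), missingness beyond an
optional MCAR flag, repeated measures beyond the weight series, or
measurement error in the clinical signs. Passing tests therefore
demonstrate the correctness and honest behavior of the *machinery* —
calibration, selection, optimism correction, transportability loss under
covariate and prevalence shift — not clinical performance on real
patients.

Weight courses rise linearly from the admission weight
(stable × (1 − percent/100), exact) to a three-point plateau at the stable
weight, with Gaussian measurement noise on post-admission weights; the
stable-weight rule recovers the plateau exactly in the noise-free case and
within ±0.5 percentage points (mean over 200 draws) at 0.1 kg noise.

## Problem sizes and numerical choices

Analyses and tests run at reduced scale as the package's own defaults for
routine runs: the end-to-end comparison at n = 200/150 with B = 50 and
coarse grids; the null-data overfitting study at n = 300, B = 100, 100
trees, 20 seeds on a 5-predictor schema; anchor checks at n = 5000 over
50 seeds. Full-scale settings (n = 2139/1580, B = 1000, full grids) are
plain configuration changes. Probabilities are clipped at 1e-12 inside
log-likelihood scoring so a single vanishing held-out probability penalizes
a candidate finitely instead of voiding the fold. Degenerate inputs have
defined behavior throughout: n = 0 cohorts keep full schema; minsplit > n
gives a root-only tree (warning-free); an empty candidate set gives an
empty stepwise path; an intercept-only fit reproduces empirical category
frequencies.

## Known limitations

* The forest is a bagging scheme, not the published ordinal-forest
  algorithm; agreement with it is expected only qualitatively.
* The exact split/prune variant of score-based ordinal partitioning is not
  pinned by its source; absolute-cost splitting with cost pruning is the
  default and quadratic variants are switches, so small trees may differ
  from other implementations near cost ties.
* Percentile CIs for corrected estimates reuse the same B replicates
  rather than a nested bootstrap.
* Non-proportional-odds models, LASSO (hierarchical selection over
  indicator blocks is unsolved in available penalized-ordinal software),
  calibration, decision curves and net benefit are out of scope.
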