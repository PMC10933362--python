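# Methods

## Compositional model

Tissue tests are compositions: the 11 assayed nutrients plus a filling value
Fv = κ − Σ cᵢ (κ = 1000 g kg⁻¹ dry matter) form a D = 12-part vector on the
simplex. All statistics are computed on the centered log-ratio scale,
clrᵢ = ln(xᵢ/G) with G the geometric mean over all D parts, which maps the
simplex isometrically to the sum-zero hyperplane of ℝ¹²; the inverse is the
closure of the exponentiated vector, xᵢ = κ·exp(clrᵢ)/Σⱼ exp(clrⱼ). The
back-transform deliberately accepts inputs that do not sum exactly to zero
(closure absorbs any constant offset); a warning is logged beyond 1e−6 so
that rounded published vectors can be processed while genuine errors remain
visible. Zero or censored concentrations are rejected rather than imputed
with detection-limit replacements — callers must pre-treat censored data.

Cultivar nutrient standards are per-part clr sample means and SDs over
true-negative specimens with a two-sided Student-t confidence interval,
mean ± t₁₋α/₂,ₙ₋₁·SD/√n at α = 0.01. The t-interval on the mean is the
standard small-sample choice; the specimen count behind the published
intervals is not recoverable, so no attempt is made to match their exact
widths — only the midpoints (and hence centroids) are fixed points.
Diagnosis uses indices Iᵢ = (clrᵢ − clrᵢ*)/SDᵢ*; the verdict threshold
defaults to |I| = 1 (one SD) and is exposed as configuration. Compositional
proximity to the balanced reference bank is the Euclidean distance between
clr vectors, with ties in neighbor search broken by bank order so output is
deterministic.

The canonical part order N, P, K, Ca, Mg, S, B, Cu, Zn, Mn, Fe, Fv is fixed
package-wide so vectors are comparable across modules. The published
reference table stores the Valessul K lower bound as printed with a slash
typo ("3/234"); the interval parser reads a slash as a decimal point with a
warning, and the stored value is the corrected 3.234.

## Climate and soil features

SDI = −Σ pᵢ ln pᵢ / ln n over daily rainfall shares pᵢ, with 0·ln 0 ≡ 0;
n = 1 is an error (the normalizer ln n vanishes) rather than a zero.
Degree-days use the simple averaging method, Σ max(0, (Tmin+Tmax)/2 − 5 °C);
only the base temperature is prescribed by the underlying protocol, and the
daily mean is the agronomic default. Exchangeable acidity from SMP buffer pH
is exposed in two variants: the *literal* published form
10·exp(7.76 + 1.053·pH_SMP), which increases with pH and contradicts buffer
chemistry, and the *corrected* decreasing calibration
10^(7.76 − 1.053·pH_SMP), which is the default (with a warning on the
literal variant). CEC = Ca + Mg + K + acidity and base saturation is the
cation share of CEC.

## Feature table

Categorical features (cultivar, establishment, tillage, previous crop,
municipality) are integer-encoded against a stored codebook; tree ensembles
split on the codes natively, so one-hot expansion is not used and no scaling
is applied (trees are scale-invariant). Strata for partitioning are the
cultivar × establishment × municipality combinations, with combinations
under 4 rows collapsed into one pooled stratum. Train counts per stratum are
rounded half-up and then nudged ±1 to hit the global 70% within one row;
singleton strata go to the training set with a warning.

Missing cells are filled by iterative random-forest imputation: each
incomplete column is regressed on the others (scikit-learn's iterative
imputer with a 10-tree random-forest estimator), cycling up to 10 rounds
with tolerance 1e−3. Observed cells are never altered and categorical codes
are rounded back to valid levels. The procedure is seeded and reproducible.

## Relevance ranking

RReliefF is implemented directly (no established Python package provides the
regression Relief estimator): for each sampled instance the k = 10 nearest
neighbors under range-normalized Manhattan distance (categorical features
contribute 0/1) are weighted by rank, w_r ∝ exp(−(r/σ)², σ = 20, normalized
per instance, and the weighted frequencies of target difference, feature
difference and their co-occurrence accumulate into
W[f] = N_dC&dF/N_dC − (N_dF − N_dC&dF)/(m − N_dC). By default every
instance is visited once, which makes the estimator exactly invariant under
row permutation. k, σ and the iteration count follow the defaults of the
visual-programming toolchain that popularized the score; none are prescribed
by the analysis itself. Gain ratio discretizes continuous features into 4
equal-frequency bins (features with at most 4 distinct values keep their own
levels) and returns information gain over split information, with 0 when the
split information vanishes.

## Yield models

Regression and classification share one protocol: stratified 70:30
partitions repeated (default 100×), a fresh ensemble per repeat, metrics
averaged. Learners are a random forest with 10 trees per bag and extreme
gradient boosting with 100 trees (depth 6, learning rate 0.3 — the
ecosystem defaults, recorded in the report). R² is 1 − SSE/SST on the test
fold. Both mean and median absolute error are computed; the reported MAE is
the mean form, whose ratio to RMSE (~0.75) matches the published accuracy
tables, while the median form is kept alongside.

Classification labels specimens by yield > 50 Mg ha⁻¹ from cultivar +
tissue features only. Each specimen's confusion quadrant (TN/FN/FP/TP,
positive = predicted nutritionally imbalanced ≡ predicted below cutoff)
comes from the majority vote of its out-of-fold predictions across repeats,
ties counting as balanced; how repeated partitions collapse to one confusion
matrix is not otherwise prescribed, and majority voting is the documented
choice here. Specimens that never reach a test fold (possible with few
repeats or singleton strata) fall back to an in-sample prediction with a
warning. A leakage test asserts that out-of-fold predictions never come from
a model whose training fold contained the specimen.

## Synthetic trial generator

The generator emulates the statistical structure of a 13-year,
multi-environment fertilizer-trial database: 26 N, 5 K and 3 P dose-gradient
trials (~35 plots each, four blocks, ≈1190 plot-seasons), N doses 0–370,
K 0–667, P 0–349 kg ha⁻¹, four municipalities with transplanting or direct
seeding, daily rainfall from a dry-day/gamma mixture and sinusoidal
temperatures summarized into SDI, degree-days and season descriptors.

Tissue ionomes are logistic-normal: Gaussian draws in clr space (diagonal
SD 0.15) around per-cultivar centres seeded from the published reference
intervals, projected onto the sum-zero hyperplane and back-transformed.
The natural generative model consistent with clr statistics is the
logistic-normal; the real covariance structure among soil, climate and
tissue variables is unknown, so draws are independent — a documented
simplification.

Yield (kg ha⁻¹) is a cultivar intercept (32 000–40 000) plus a
quadratic-plateau response to the split-N dose (optimum 160 kg N ha⁻¹, gain
22 000), small centered linear terms in soil S, B, Zn, Mn and Fe, Gaussian
noise (SD 3 000), truncated at zero. Quadratic-plateau is chosen over a pure
quadratic because the descending arm of a quadratic exaggerates the cost of
extra N and inflates recommendations. A latent balance state couples tissue
to yield: with probability 0.35 a plot is *imbalanced*, its clr vector
shifted ±1.0 on S (about a 2.5-fold tissue-S excess or shortage) and its
yield reduced by 16 000 kg ha⁻¹. Without such a coupling the classification
stage would have nothing to learn from tissue features; S is the shifted
nutrient because it is the most diagnostic element for this high-S-demanding
crop. These numbers give a complete-data Bayes R² ≈ 0.93, matching the
accuracy regime the analysis is designed for.

Missingness (13%, completely at random) is injected into numeric soil and
climate columns only — never the target, the doses, the categorical
variables or the tissue tests, since specimens without tissue analyses are
treated as excluded from the study population. The generating parameters and
latent flags are returned verbatim for recovery tests.

The *balanced-management scenario* (`GeneratorConfig.balanced_management`)
fixes every plot at the recommended split-N dose with complete records, so
class membership at the cutoff is governed by cultivar and nutritional
balance; it is the setting for balance classification and standards
derivation, where dose gradients would otherwise dominate the class label
through a feature the classifier is not given.

## Problem sizes and statistical power

Test and driver problem sizes are chosen so that every stochastic check sits
several standard errors from its bound: regression properties use the
default ~1190-row trial set (R² 0.80–0.82 across seeds against the 0.75
floor, and ≤ 0 under target permutation — tree ensembles on a permuted
target give slightly negative out-of-fold R², the expected null behaviour);
classification uses ~1700 rows (AUC ≈ 0.97 against the 0.9 floor). For
centre recovery, the per-part relative error of a back-transformed centroid
has SE ≈ √2·0.15/√n, so with the minimal 200-specimen TN pools the 2%
recovery check would sit at roughly one expected maximum error across 48
cultivar × part cells; the recovery experiment therefore uses ~1200 TN
specimens per cultivar (max observed error ≈ 1.3%), well above that floor.

## What passing tests do and do not show

The generator reproduces the marginal structure the pipeline assumes —
compositional ionomes with cultivar centres, a dominant split-N response,
MCAR missingness — but not real-world features: correlated soil–climate–
tissue structure, informative missingness, spatial/temporal autocorrelation
within trials, measurement bias between laboratories, or cultivar ×
environment interactions beyond the planted ones. Passing acceptance on
synthetic data validates the machinery (transforms, protocols, estimators,
selection logic), not the agronomic accuracy of any particular standard on
field data; published accuracy tables can only be reproduced exactly with
the original trial database.

## Known limitations

- The SMP acidity calibration constant pair (7.76, 1.053) is retained from
  the printed source; the corrected variant restores the physically sensible
  sign but the original calibration data are not recoverable.
- Standards assume a common within-cultivar clr covariance and report
  per-part intervals only; no multivariate (Mahalanobis-type) envelope.
- Gradient-boosting hyperparameters are fixed defaults; no tuning stage.
- Diagnosis thresholds (|I| = 1) are conventional, not calibrated against
  field response data.
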