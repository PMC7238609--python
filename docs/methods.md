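# Methods

## Problem and model

The package addresses a small-sample, high-dimensional prediction problem
from paired-design transcriptomics: given one blood sample per breast-cancer
case and one from an age-matched control, the data reduce to an n × p matrix
X of log2 fold changes, x_ig = log2(case_ig) − log2(control_ig), and a binary
outcome y (metastatic spread present at diagnosis). The matched control acts
as a per-pair normaliser, so a pair is a single statistical unit everywhere,
including resampling.

The model is logistic regression,

    logit p(m | x) = β0 + β1 x1 + … + βp xp,

estimated by maximizing the Bernoulli log-likelihood penalized by the
elastic net,

    λ [ α Σ|βj| + (1−α)/2 Σ βj² ],        intercept unpenalized.

With α = 0.5 (the default, fixed a priori) the absolute and squared terms
carry equal weight, so this Lagrangian coincides with the constraint form
"Σ|βj| + Σβj² ≤ t" up to the usual ½ convention on the quadratic term; only
the path of solutions matters, so the two parameterizations are
interchangeable here. The L1 component performs variable selection; the L2
component stabilizes groups of correlated predictors (two identical columns
receive identical coefficients, a property the test suite verifies).

### Penalty selection

λ is scanned over a 100-point geometric grid from λ_max (the smallest value
whose L1 component zeroes every slope; the fit there is exactly the
intercept-only model) down to λ_max × 10⁻³. Each fit is scored by the
modified Akaike criterion

    AIC′ = LR χ² − 2k = 2 (ℓ − ℓ0) − 2k ,

where ℓ is the *unpenalized* log-likelihood at the penalized estimates, ℓ0
the intercept-only maximum, and k the number of nonzero slopes. The fit
maximizing AIC′ is selected; ties break toward larger λ (the sparser model).
This choice avoids the extra variance of cross-validation splitting at small
n. Two conventions deserve emphasis:

- k counts raw nonzeros, ignoring shrinkage. This overstates the effective
  degrees of freedom and therefore penalizes model size conservatively. It
  follows that the null model (AIC′ = 0 exactly) is a strong competitor:
  on data with no signal, the selected model is usually the intercept-only
  fit, because a spurious gene rarely buys the 2 log-likelihood units its
  inclusion costs. This is deliberate behavior, not a defect, and it shapes
  what the validation can show (see "What passing tests show" below).
- ℓ is evaluated without the penalty, which is the only reading under which
  the null model scores exactly 0.

An optional small-sample variant, AICc′ = AIC′ − 2k(k+1)/(n−k−1) (−∞ when
k ≥ n−1), is available behind the `criterion` switch and off by default.

### Numerics of the path fit

The fitter is a glmnet-style proximal Newton scheme (numba-compiled):
an outer IRLS linearization at the current linear predictor (weights
w = p(1−p) floored at 10⁻⁵) and an inner cyclical coordinate descent with
soft-thresholding on the weighted working response, warm-started along the
grid. Predictors are standardized internally to zero mean and unit
(population) variance — the penalty is scale-sensitive — and coefficients
are reported back on the data scale; constant columns are left at zero.
Convergence is declared when the largest weighted squared parameter change
in a sweep falls below `tol` (default 10⁻⁷); unconverged fits are flagged,
not raised, so a path point cannot abort a bootstrap. The λ_max fit is
pinned to the closed-form null model. A caveat: along a direction in which
the likelihood is exactly flat (duplicated columns), the objective's only
curvature is λ(1−α), so at the small-λ end coordinate descent approaches
the symmetric optimum at a per-sweep contraction of about λ(1−α)/v and
tolerance-level symmetry is only observed at moderate penalties; this is
shared by all cyclic-descent implementations.

## Validation

### Optimism-corrected bootstrap

Apparent (training-data) performance of a selected model overstates
generalization. For B bootstrap replicates (default 500) the *entire*
procedure — path fit plus AIC′ selection — is refit on a with-replacement
resample of the pairs; the refit model is scored both on its own resample
(M_boot) and on the original data (M_orig). The correction is

    corrected = apparent − mean_b (M_boot,b − M_orig,b).

The same subtraction is applied to every metric: for concordance the
optimism term is typically positive, for Brier typically negative (training
understates error), and in both cases the correction moves the estimate in
the honest direction. Per-replicate values `apparent − optimism_b` define
the reported bootstrap distribution; its 0.1 and 0.9 empirical quantiles
(linear interpolation between order statistics) give the middle-.8
interval. The calibration curve is corrected pointwise on one 50-point grid
spanning the apparent-prediction range.

Resamples are redrawn (up to `max_redraws`) until they contain at least two
*distinct* pairs of each outcome class — duplicated copies of a single
positive pair do not count, since such a resample carries no usable
class contrast. Replicates whose fit fails are skipped and logged; at least
90% must succeed. One master seed spawns an independent substream per
replicate, so reports are bit-reproducible and order-independent.

### Metrics

- **Brier score** B̄ = n⁻¹ Σ (ŷi − yi)²; the constant-prevalence predictor
  scores exactly p̄(1−p̄) (0.1875 at 25% prevalence), the natural
  null-model reference.
- **Concordance / AUC** via midranks: (wins + ties/2) / (n₊ n₋); ties count
  ½, the Mann–Whitney convention, so any constant predictor scores 0.5.
- **Calibration curve**: LOWESS (tricube kernel, local linear, span 2/3) of
  the 0/1 outcome on the predictions, clipped to [0, 1]. Robustness
  iterations are **off** by default: bisquare reweighting by residual size
  systematically suppresses the minority class of a binary outcome (at a
  true event rate of 0.1 the rare events carry residual 0.9 and get
  down-weighted), which we measured as a ~0.07 downward bias on
  diagonal-truth data versus ~0.01 without; the iteration count remains a
  parameter. Smoothing is delegated to statsmodels; an independently coded
  smoother serves as the test oracle.

### Stability

From the same replicates: per-gene selection probability (fraction of
replicates with a nonzero coefficient), pairwise co-selection (both nonzero;
the diagonal equals the selection probability), and the Jaccard overlap
|S₁∩S₂|/|S₁∪S₂| over all replicate pairs (subsampled beyond
`max_jaccard_pairs`, default 10 000). Pairs of two empty sets are excluded
(0/0) and counted; empty-vs-nonempty scores 0. The stability point estimate
is the mean pairwise Jaccard — chosen over the replicate-vs-original variant
because stability concerns different realizations of the procedure, though
the alternative is available via `jaccard_pairing="vs_original"`. The
expected overlap between two realizations is round(stability × |selected
set|), banker's rounding.

## Synthetic data

The generator emulates the study design, not the assay: n pairs (default
88), p genes (default 2000, scaled down from microarray width; full width
supported), fold changes standard normal marginally with within-block
correlation ρ (default 0.5, blocks of 10) — co-regulation is what makes
selection unstable — a sparse signal of `n_signal` genes (default 10) with
alternating-sign coefficients of magnitude `effect_size` (default 0.5 per
SD) spread across distinct blocks, and an intercept calibrated by Brent
root-finding on a 100 000-draw auxiliary sample so the population
prevalence hits `target_prevalence` (default 0.25) within 0.005. Ground
truth (support, intercept, per-sample probabilities) is recorded.

It does **not** emulate: heavy-tailed or skewed intensity noise, batch
structure beyond what pairing removes, missing values, probe-level
artifacts, or correlation between the outcome and design covariates (age,
smoking, BMI). Passing recovery tests therefore show the estimator and its
validation machinery are correct under the stated generative model; they do
not certify performance on real microarray data.

### What passing tests show, and the null-data caveat

Recovery tests run at sizes where the criterion has power (n = 300,
p = 500, effect 1.0): there the corrected estimates land closer to
large-sample held-out truth than apparent ones, and true-support genes
separate cleanly from noise genes in selection probability. At n = 88 with
no signal, the AIC′ guard selects the null model for most datasets; the
procedure then sits at a selection boundary where the optimism correction
is conservative (replicate refits on resamples — whose duplicated rows
inflate spurious likelihood gains — select genes the full-data fit does
not, pushing the corrected concordance below 0.5). The test suite contains
a red test documenting this regime honestly rather than loosening its
bounds.

## Problem sizes in the test suite

Bootstrap-heavy checks use B = 50–100 replicates and p ≤ 500, sizes chosen
so the full suite exercises every code path at desk scale; all defaults
(B = 500, p = 2000) remain the analysis-scale settings.

## Known limitations

- AIC′ selection is conservative by construction; analyses expecting a
  large gene list at n ≪ p (as in the motivating study) will often get the
  null model instead under this criterion.
- Optimism correction is biased near the null-selection boundary (above).
- The co-selection table is stored sparsely over genes that were selected
  at least once; for very unstable selections at large B it can still be
  sizeable.
- No missing-value support by design; impute or filter upstream.
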