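# Methods

## Model overview and assumptions

cytotax treats community flow cytometry as a noisy, taxonomically blind
projection of community composition. Its working assumptions are:

- each taxon occupies a characteristic, reasonably stable region of the
  (FSC, SSC, FL1, FL3) measurement space *in the studied system* (the
  models are trained in situ, so a taxon whose phenotype depends on its
  community context is learned as it appears in that context, not as it
  appears in axenic culture);
- cluster occupancy fractions of a dataset-level Gaussian mixture are a
  sufficient summary of a sample's fingerprint;
- 16S relative abundances, after detection-limit filtering, are a usable
  (if imperfect) ground truth for what the cytometer can see.

The per-taxon predictor is hurdle-style because per-taxon abundance
vectors are zero-inflated: a binary presence stage (random forest) and a
positive-abundance stage (regression ensemble) are trained separately
and combined by superimposition — regression output is zeroed where the
classifier votes absent. Superimposition exists because a squared-loss
regression trained on zero-inflated, logit-transformed targets has no
incentive to push absent samples decisively below the 1% presence
criterion; the classifier, trained on 0/1 loss, is much sharper at that
boundary.

## Preprocessing chain and its order

`read → arcsinh → gate → normalize`, fixed. Gates are drawn in
arcsinh-transformed coordinates (a polygon on the two primary
fluorescence channels; boundary points count as inside). Normalization
divides **all** channels by one dataset-wide constant — the maximum
transformed FL1 (SYBR green I) intensity over all training samples —
computed after gating so background events cannot set it. The constant
is stored in the model bundle and reused verbatim at prediction time;
a deployment sample brighter than anything seen in training yields
values > 1 and a logged warning, not an error.

## Fingerprinting

The mixture mask is fitted with full covariances (cytometric clusters
are elongated and channel-correlated) on events pooled at equal depth
per sample (default 5,000; samples shallower than that contribute all
their events, with a warning). K is selected by BIC over the candidate
grid {5, 10, 20, 40, 80, 128} by default; analyses in this repository
that target few-cluster ground truths use denser low-K grids (e.g.
1–8), which is a parameter choice, not a code path difference. Cells are
hard-assigned to their maximum-posterior component. Counts get a +1
pseudocount before closure so the clr is defined at zero occupancy; clr
is applied to the closed relative values (clr itself is
scale-invariant, so closure only interacts with the pseudocount).

## Targets

- Rescaling: proportions × minimum library size (a fractional analogue
  of rarefying that keeps all reads).
- Detection limit: entries with relative × density < 10³ cells/ml are
  zeroed and rows are *not* re-closed — re-closure would silently change
  other taxa's presence labels.
- Presence: relative abundance ≥ 1%; equality counts as present (the
  boundary must be deterministic and the wording "lower than 1% ...
  higher than 1%" leaves it open).

## Per-taxon models

**Feature selection (classifier only).** Recursive feature elimination
with 25 stratified 75/25 resamples: rank clusters by forest impurity
importance on the training part, evaluate nested subsets of sizes
{1, 2, 4, …, K} on the held-out part, average the accuracy profile, and
keep the smallest subset within 0.5 percentage points of the maximum.
Ties in ranking break by cluster id. The elimination forests use 100
trees (the profile needs ~150 fits; the final classifier uses the full
500) — a cost choice that leaves rankings essentially unchanged.

**Why the regressor sees all clusters.** A single cluster's clr value is
ln(xⱼ) minus the log geometric mean of the whole composition, so it is
confounded by every other cluster: a sample mono-dominated by a
*different* taxon shifts the focal cluster's clr upward without any
focal signal. A classifier can survive this on selected features (the
decision boundary adapts), but a regression restricted to one or two
selected clusters becomes non-monotone in the true abundance; ablation
on the mock scenario showed held-out R² collapsing from ≥ 0.95 to
0.36–0.83. The regression ensemble therefore uses the full fingerprint
while the classifier uses the selected subset; both feature lists are
stored in the model bundle.

**Transforms.** Abundance targets are logit-transformed; zeros are first
replaced by one-tenth of the smallest nonzero **measured** training
abundance. The replacement constant is deliberately computed before
augmentation: synthetic convex combinations carry nonzero targets as
small as min/n_new (a mixing-weight artifact), which would otherwise
drag the constant toward zero and make it depend on augmentation size.
Mono-dominant samples (abundance exactly 1, e.g. pure strains) are
clipped to 1 − replacement before the logit, mirroring the zero
replacement at the top end. Both constants are stored for deployment.

**Regression ensemble.** Gradient boosting (200 rounds; depth and
learning rate tuned on a 2×2 grid) and a polynomial-kernel SVR
(standardized inputs; C ∈ {0.1, 1, 10}, degree ∈ {2, 3}) are each tuned
by inner 5-fold CV, then combined by a linear regression fitted on
out-of-fold base predictions — fitting the combiner on resubstitution
predictions would overweight whichever base overfits more.

**Decision rule.** Presence = classifier probability ≥ 0.5 (the
default threshold is stored per model and adjustable).

**Importances.** Forest and boosting submodels: permutation importance —
mean increase in error over 5 shuffles of one feature on the training
data, clipped at zero and normalized so the top feature scores 1. (The
per-tree out-of-bag variant would need private scikit-learn APIs; the
training-set variant preserves ranking on the scales used here.) SVR
submodel: per-feature R² of a loess fit of the target on that feature
against the intercept-only model, as is conventional for kernel models
without native importances. Clusters dropped by elimination report 0 in
the classifier submodel.

## Augmentation

Zero-inflation is countered by in-silico mixing: a synthetic training
row is w·a + (1−w)·b, w ~ Uniform(0,1), applied identically to the
relative-space fingerprint (then clr) and the taxon target — the
composition of a physical 50:50 mix of two equal-density communities is
the convex combination of theirs. A density-weighted mode
(w′ = w·d_a / (w·d_a + (1−w)·d_b)) is available when source densities
differ. The default adds as many synthetic rows as there are original
training rows. Augmentation happens strictly inside each training fold,
and every synthetic row records its source sample ids; an audit
function asserts that no validation id appears in any training-row
provenance (this audit runs inside every nested-CV repeat).

## Validation machinery

Outer loop: 20% stratified holdout (by presence label, so both classes
appear in validation when possible), repeated 3×; inner loop: 5-fold CV
for all tuning. One master seed deterministically spawns per-repeat and
per-model seeds. R² is 1 − SS_res/SS_tot on validation data, floored at
0 for reporting; MAE is reported in percentage points; false
positives/negatives (at the 1% criterion on predicted abundance) are
normalized per 100 validation samples. A single-class validation fold
reports accuracy but a missing AUC, with a warning. Tank-holdout
evaluation (train on all groups but one, validate on the held-out
group) measures reliance on within-tank co-occurrence rather than the
taxon's own signal.

## Synthetic data: what it emulates, what it does not

Signatures are Gaussians placed on a jittered 4-D lattice whose spacing
is `separation` × the within-cluster sd (0.3 transformed units);
`separation` is the single knob for taxonomic resolvability, and 0
collapses all taxa onto one signature. Compositions are zero-inflated
Gamma/Dirichlet draws carried through a Gaussian copula with AR(1)
temporal correlation within each simulated tank; a sample never loses
all taxa (the largest latent survives zeroing). Densities are
log-normal around 10⁶ cells/ml (σ = 0.5 log-units). Events are
allocated multinomially to taxa plus a 5% low-fluorescence background
population that the shipped rectangular gate (FL1 ∈ [3, 13],
FL3 ∈ [2, 13], transformed units) removes. Sequencing counts are
multinomial at the configured depth (a Dirichlet-multinomial
overdispersion option exists for stress tests).

The packaged mock-community scenario (`mock3_scenario`) is 3 taxa at
separation 8, 60 samples on the regular simplex grid with step 1/10
(including pure-strain vertices), 5,000 events and 5,000 reads per
sample — the simplest community on which the full pipeline should be
near-perfect, and measured so: nested-CV AUC 1.0 and R² 0.93–0.97 per
taxon at the default seed.

What the generator does **not** emulate: spillover/compensation,
doublets, instrument drift, phenotypic drift of signatures over time
(available as an option but off by default), chimeras or any
read-level sequencing artifacts. Passing tests on synthetic data
therefore demonstrate the statistical machinery — discretization,
transforms, leakage-free validation, the superimposition trade-off —
not robustness to instrument physics.

The false-positive stress regime (`hurdle_stress_dataset`) is a
deliberate worst case for the raw regression: a taxon absent in half
the samples but ≥ 12% abundant when present, whose presence is signaled
noisily by one cluster while its magnitude is independent of all
features. One-tenth of the smallest nonzero abundance then exceeds the
1% criterion, so the raw regression cannot express "below 1%" at all —
at the default seed it false-positives 48 of every 100 validation
samples, cut ~9× by superimposition while false negatives rise by ~3
per 100 and MAE drops. This reproduces the qualitative behaviour that
motivates the hurdle design.

## Numerical choices and degenerate inputs

- GMM fits use `reg_covar = 1e-6`; a candidate K whose fit degenerates
  (singular covariance, non-finite BIC) is skipped with a warning, and
  fitting fails only if every K degenerates.
- Inner CV folds shrink automatically when a class has fewer members
  than folds (never below 2).
- Taxa never or always present at the cutoff are rejected for training
  (nested CV) or skipped with a warning (batch training).
- A gate that removes all events of a sample yields an empty matrix
  carrying a warning; fingerprinting such a sample is an error naming
  it.
- Learning-curve fractions too small to retain both classes are skipped
  with a warning.

## Problem sizes used in the shipped analyses

The repository's own validation runs use desk-scale sizes chosen as
reasonable study conditions: the mock scenario as above (fingerprint
mask fitted at 2,000 events/sample over the 1–8 K grid); the
localization analysis with 10 taxa × 120 samples × 3,000 events,
mask grid {8, 12, 16, 24} at 1,000 pooled events/sample, and 200-tree
forests; the stress regime with 150 samples × 8 clusters; learning
curves at the 20% and 80% fractions with 5 subsample repeats.

## Known limitations

- Performance on real instruments will be lower than on the synthetic
  scenarios; the generator's Gaussian, drift-free signatures are an
  idealization.
- clr features couple clusters through the geometric mean; rare-taxon
  regressions inherit noise from dominant clusters.
- The classifier's probability is not calibrated; the 0.5 threshold is
  a convention, not an optimum.
- Multi-output joint modeling across taxa (which could enforce
  compositional coherence of the predictions) is out of scope; per-taxon
  predictions need not sum to 1.
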