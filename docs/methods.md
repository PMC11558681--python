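# Methods

This note documents the models behind `htsval`, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and
do not establish.

## Data model and splits

A screen table has one row per compound: a SMILES structure, an
activity score normalized to [0, 100], a binary primary-screen label,
and — for a subset of the primary actives — a binary confirmatory
label.  A primary active with confirmatory 0 is a false positive; with
confirmatory 1, a true positive.  Structures are sanitized and rewritten
as RDKit canonical SMILES; records whose canonical forms collide are
merged keeping the first occurrence, with labels aggregated by max
(active wins) and the score by max.  Scores outside [0, 100] are
min-max rescaled per dataset.  Both rules cover situations the data
sources leave unspecified; merges and rescales are recorded in the
dataset's metadata.

The validation split is the `round(0.10·n)` compounds with the highest
activity scores — the convention used when a valuation engine needs a
held-out target set — with score ties broken by ascending record index
so splits are deterministic.  Active-learning initialisation draws a
stratified random `round(0.015·n)`-sized batch preserving the
active:inactive ratio.

## Representations

* Morgan (ECFP-like) fingerprints, radius 2, folded to 1024 binary
  bits.  Workflows treat them as binary vectors, not counts.
* 208 RDKit physicochemical descriptors: the full `Descriptors.descList`
  of the pinned RDKit version minus `Ipc` and `AvgIpc`, which overflow
  for medium-sized molecules.  Non-finite values are imputed to the
  finite column median and the imputation is recorded; a column more
  than half non-finite triggers a warning.

## Valuation engines

**MVS-A.** A LightGBM classifier (100 rounds, λ = 1.0, column
subsampling 0.95, `boost_from_average=False` so the initial raw score
is 0 and the first round sees p = 0.5 for every sample).  With the
running predictions *before* round i giving gradient g_ij = p_ij − y_j
and Hessian h_ij = p_ij(1 − p_ij), the score is

    score_j = Σ_i sqrt(g_ij² + λ·h_ij²),

the sampling weight minimal-variance sampling assigns to large-gradient
samples, summed over every boosting round.  The combination is isolated
in `mvsa._round_contribution` so the functional form can be swapped in
one place.  Scores are nonnegative and bounded by rounds·sqrt(1 + λ/4).

**KNN-Shapley.** For each validation point, training points are sorted
by ascending Euclidean distance (ties by index) and the exact Shapley
values of the KNN utility v(S) = (1/K)·Σ_{k≤min(K,|S|)} 1[y_{α_k} = y_t]
are computed by the closed-form recursion from farthest to nearest.
The empty-coalition utility is 0; under that convention the recursion
is the exact Shapley value (verified against subset enumeration) and
per-validation-point efficiency Σ_j s_j = v(full) − v(∅) holds to
machine precision.  K defaults to 5 (exposed in `KNNConfig`).  Because
the exact computation scales poorly, the majority class is first
randomly undersampled to minority:majority = 0.2 (seeded); removed
samples score 0 and are flagged.

**Leaf influence.** LightGBM supplies only the per-round tree
*structures* (leaf assignments); leaf values are re-derived from the
running gradient/Hessian statistics as value(L) = −lr·ΣG/(ΣH + λ), so
the additive model is fully self-consistent.  Removing sample j deletes
its g, h contribution from its leaf at every round sequentially and
propagates the resulting leaf-value shifts to target samples sharing
those leaves.  Cross-round coupling — other training samples' gradients
shifting because their own predictions moved — is ignored; this is the
same first-order approximation class as fast leaf-refit influence
methods, and for a single-round model the computation is exact (the
test suite checks it against brute-force frozen-structure retraining to
1e-10).  Sign convention: positive = removal increases target loss =
the sample helps.  `test` mode targets the validation set, `self` mode
the active training samples.

**TracIn.** A feed-forward network — three dense hidden layers of 512
ELU units, dropout 0.5, L2 1e-4, sigmoid output, binary cross-entropy,
Adam at 1e-3 — implemented directly in NumPy (float64, fully seeded;
no framework dependency) with parameter snapshots at epochs 30/60/90.
Gradients are taken w.r.t. the last two weight layers only.  Since
those per-sample gradients factor into outer products (delta ×
activation), squared norms and pairwise dot products are assembled from
the factors without materialising per-sample gradient vectors.  Modes:
`self` = Σ_checkpoints ‖∇ℓ_j‖² (no learning-rate weight); `test` =
Σ_checkpoints η·∇ℓ_j·mean_val ∇ℓ_v; `pos` = `test` with validation
restricted to actives.  η is the optimizer's base learning rate at each
checkpoint (constant here; per-step schedules are not modelled).
Checkpoint gradients are evaluated in inference mode (no dropout).

**DVRL.** A value-estimator MLP (ReLU; hidden 100, combined 10, Adam at
0.01) maps [features, label, marginal] to a selection probability,
where *marginal* is |y − p_oof(x)| from 5-fold out-of-fold predictions
of the LightGBM predictor — out-of-fold so a mislabeled sample shows a
large gap instead of being memorised.  Each iteration samples Bernoulli
selection vectors from the probabilities, fits the predictor on the
selected subset, and scores validation ROC-AUC; the estimator takes a
REINFORCE step on the reward (AUC minus a moving-average baseline
initialised at the full-data model's AUC).  Three stabilisers matter at
desk scale and are documented as such: the reward is normalised by its
running standard deviation (floored, clipped to ±2) so small AUC
differences still move the policy; the policy gradient is averaged over
a few (default 4) selection samples per iteration; and a range penalty
pushes the mean selection probability back inside [0.1, 0.9] so the
policy cannot collapse to select-all/none.  Hidden ReLU layers get a
+0.1 bias initialisation so the narrow combined layer cannot be dead at
init.  Desk defaults are 200 iterations × batch 1000 (the full-scale
setting of 1000 × 5000 is supported but not the default).

## Workflows

**Active learning.**  Batch size is `round(0.015·n)` of the *full*
library, recomputed each step.  `random` shuffles the remainder
(seeded); `greedy` ranks the remainder by a LightGBM classifier's
predicted active probability; `importance` scores the screened
compounds with a valuation engine (MVS-A by default — a self-importance
engine that needs no held-out set), fits a regressor features →
importance, and takes the remainder's top predicted importance.  The
regressor is a Gaussian process with an RBF kernel whose length scale
is set by the median heuristic on the labeled set and then held fixed
(no marginal-likelihood optimisation): on 1024-bit binary vectors the
default unit length scale would make every kernel entry vanish.  A
single-class labeled set falls back to random for that step (logged);
a remainder smaller than the batch is returned whole and flagged.

**Triage.**  Primary actives are ranked by the orientation rule —
self-importance engines: highest score = FP nominee; test-importance
engines: lowest = FP — stored as a data table so new engines declare
their polarity.  Nominee sets are the extreme `round(0.10·n_actives)`
(interpreting "top/bottom 10%" as a fraction; an absolute top-k is also
supported since the two conventions conflict in common usage).
Evaluation restricts to confirmatory-labeled actives — unlabeled
nominees occupy slots but are skipped in the metrics — and reports
precision over the nominated decile, relative precision (precision −
base rate), EF@10% and BEDROC(α=20).  The filter benchmark counts
matched alerts from the RDKit Glaxo (GSK) hard-filter catalog plus the
seven REOS property-range rules (MW 200–500, logP −5..5, HBD ≤ 5,
HBA ≤ 10, charge −2..+2, rotatable bonds ≤ 8, heavy atoms 15–50);
catalog identity is pinned in the output metadata because hit counts
are catalog-version dependent.  A mean pairwise Tanimoto similarity of
the FP nominees is available as a structural-diversity readout; no
directional claim is attached to it.

**Undersampling.**  Importance is computed once on the full training
split (not per step).  Each step removes `round(0.05·n_train)`
inactives — highest-score first, lowest first, or seeded-random — until
95% of the training set is gone or inactives are exhausted (flagged);
ties at a removal boundary break by ascending index.  After every step
a LightGBM classifier with fixed default hyperparameters (no per-step
re-tuning) is retrained and scored by average precision on the
validation split.  Actives are never removed, so class balance improves
monotonically under every policy.

## Metrics and statistics

BEDROC follows the standard early-recognition parameterisation
(exponential weight exp(−α·r/N), RIE normalised to [0, 1]); the
derivation constants are in the code.  The enrichment-factor cutoff is
⌈fraction·N⌉ (ceiling, documented, since the convention is unstated in
common usage).  Average precision is the mean of precision at each
positive's rank.  Ranking ties are resolved by stable sort on index
before any metric.  Method comparison runs a Friedman omnibus test,
then pairwise two-sided Wilcoxon signed-rank tests against a reference
with Benjamini–Hochberg step-up adjustment at α = 0.05; all-zero
difference pairs are flagged degenerate with p = 1 (zero differences
are otherwise discarded, the signed-rank default).

## Synthetic screens

The generator emulates the statistical structure the workflows assume:
latent binary cluster prototypes (density 0.1) with per-bit flip noise
0.05; a small active rate (default 2%); planted false positives as
*structurally isolated* compounds — independent random bit vectors far
from every active prototype — labeled primary-active with confirmatory
0 (default 30% of actives); Gaussian activity scores (actives 60 ± 15,
inactives 40 ± 15, clipped to [0, 100]) so scores correlate with labels
but the top-score validation split still leaves roughly half the
actives in training, as in real screens where the activity call is not
a pure score threshold.  Structural isolation plus the label flip is
exactly the signal self-importance detectors exploit; the generator
does not model specific interference mechanisms (aggregation,
fluorescence), chemical similarity between SMILES and feature vectors
(the attached fixture SMILES exist only to exercise RDKit-facing code),
assay plate effects, or dose-response structure.  Passing the synthetic
benchmarks therefore shows the machinery is correct and the detectors
respond to the intended signal — not that the same margins will hold on
any particular public bioassay.

## Benchmark problem sizes

The validation studies (`htsval.benchmarks`, asserted by the test suite
and reported by `scripts/acceptance.py`) use desk-scale sizes chosen
once: oracle checks on instances small enough for exhaustive
computation (N ≤ 8 subset enumeration; single-tree retraining with
n = 80; finite differences on an 8-unit network); MVS-A mislabel
recovery on n = 500, d = 32 screens with exhaustive leave-one-out
retraining of all 500 models; triage on n = 3000, d = 1024 with 30%
planted FPs; active learning on n = 5000, d = 1024 libraries with 2%
actives and five 1.5% steps; undersampling on n = 1500, d = 128 screens
to 95% removal — each with 10 replicate seeds and paired signed-rank
tests.  Stochastic recovery checks are asserted on across-seed medians.
The LOO-Spearman check deserves a caveat: leave-one-out deltas for the
~490 benign compounds are dominated by tree-structure instability, so
the correlation is small (across-seed medians around 0.1) though
consistently positive; the planted mislabeled compounds, whose deltas
are large, are the reliably recovered part.

## Known limitations

* The leaf-influence engine reads LightGBM's structures but re-derives
  leaf values with the plain second-order formula; LightGBM's own leaf
  values (which honour `min_sum_hessian`, smoothing, etc.) can differ
  slightly, so influence is defined w.r.t. the reconstructed model.
* TracIn restricts gradients to the last two layers (as is standard for
  scalability); influence mediated by earlier layers is invisible.
* DVRL at desk scale is the least stable engine; its scores should be
  read as a coarse ordering, not calibrated probabilities.
* The KNN-Shapley engine's undersampling means scores for removed
  majority-class samples are 0 by construction, not "measured zero".
* Descriptor lists and alert catalogs are pinned to the installed RDKit
  version; counts are not comparable across versions.
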